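"""Published 2x2 worked-example counts from the OAI knee-replacement cohort.

The source study's contingency tables print, for each extracted rule
against the consequent "low PCS at 2 years postoperatively" (N = 44,
consequent prior 32/44), the counts

    a = applicable & low PCS,      b = applicable & high PCS,
    c = non-applicable & low PCS,  d = non-applicable & high PCS.

These counts are inputs to the audit path (``verify-counts``): every
published support / confidence / lift value is exactly recomputable
from them, which is what the acceptance checks do.  Keys are internal
rule slugs; values are (a, b, c, d).
"""

from __future__ import annotations

N_TOTAL = 44
#: participants with a low 2-year PCS (the consequent margin a + c)
N_LOW_PCS_2Y = 32

#: single (one-condition) rules for low 2-year PCS
SINGLE_RULE_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "comorbidities": (10, 0, 22, 12),
    "high_womac_physfunc": (20, 2, 12, 10),
    "high_womac_pain": (19, 2, 13, 10),
    "low_pcs_pre": (24, 3, 8, 9),
    "decreased_stand": (19, 3, 13, 9),
    "old_age": (22, 4, 10, 8),
    "high_womac_stiffness": (15, 3, 17, 9),
    "low_pcs_1y": (22, 5, 10, 7),
}

#: combined (two-condition) rules for low 2-year PCS
COMBINED_RULE_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "comorbidities+unilateral": (9, 0, 23, 12),
    "comorbidities+low_mcs_pre": (1, 0, 31, 12),
    "comorbidities+nondepressive": (9, 0, 23, 12),
    "comorbidities+decreased_stand": (8, 0, 24, 12),
    "old_age+high_womac_pain": (13, 0, 19, 12),
    "old_age+high_womac_stiffness": (10, 0, 22, 12),
    "old_age+high_womac_physfunc": (15, 0, 17, 12),
    "decreased_stand+high_womac_pain": (11, 0, 21, 12),
    "decreased_stand+high_womac_physfunc": (13, 0, 19, 12),
    "decreased_stand+old_age": (15, 1, 17, 11),
    "decreased_stand+unilateral": (18, 2, 14, 10),
    "high_womac_physfunc+low_pcs_pre": (17, 1, 15, 11),
    "high_womac_physfunc+high_mcs_1y": (14, 1, 16, 11),
    "high_womac_physfunc+high_womac_pain": (17, 2, 15, 10),
    "high_womac_pain+high_womac_stiffness": (13, 2, 19, 10),
    "high_womac_pain+low_pcs_pre": (16, 1, 16, 11),
    "low_pcs_pre+female": (15, 0, 17, 12),
    "low_pcs_pre+low_pcs_1y": (17, 2, 15, 10),
    "low_pcs_pre+decreased_stand": (16, 0, 16, 12),
}

#: item (variable, state) pairs behind each single-rule slug, for
#: reconstructing boolean matrices that realize the published margins
SLUG_ITEMS: dict[str, tuple[str, str]] = {
    "comorbidities": ("cci", "high"),
    "high_womac_physfunc": ("womac_physfunc", "high"),
    "high_womac_pain": ("womac_pain", "high"),
    "low_pcs_pre": ("pcs_pre", "low"),
    "decreased_stand": ("sit_to_stand_s", "high"),
    "old_age": ("age", "high"),
    "high_womac_stiffness": ("womac_stiffness", "high"),
    "low_pcs_1y": ("pcs_1y", "low"),
    "unilateral": ("joint_type", "unilateral"),
    "low_mcs_pre": ("mcs_pre", "low"),
    "nondepressive": ("cesd", "low"),
    "high_mcs_1y": ("mcs_1y", "high"),
    "female": ("sex", "female"),
}
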
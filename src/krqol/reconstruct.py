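"""Reconstruct boolean item matrices that realize given 2x2 margins.

The audit path for published rule tables: given the (a, b, c, d)
counts of applicable/non-applicable x outcome tables, build a concrete
participants x items matrix on which ``count_rule`` reproduces those
counts exactly, so the full mining path can be exercised without
individual-level data.

Single-condition tables against one common consequent can all be
realized *simultaneously*: fix the consequent column (a+c low, b+d
high), then choose each antecedent's applicable set independently among
the low- and high-outcome participants.  Joint structure between
antecedent variables is arbitrary and irrelevant to single-rule counts.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .discretize import HIGH, LOW, Item, ItemMatrix


def _paired_items(variable: str, state: str) -> tuple[Item, Item]:
    """The item for ``state`` and its complement item."""
    if state in (HIGH, LOW):
        other = LOW if state == HIGH else HIGH
    else:  # categorical: synthesize a complement level
        other = f"not_{state}"
    return Item(variable, state), Item(variable, other)


def matrix_from_counts(
    antecedent: Sequence[tuple[str, str]],
    consequent: tuple[str, str],
    a: int,
    b: int,
    c: int,
    d: int,
) -> ItemMatrix:
    """A matrix realizing one rule's 2x2 counts exactly.

    Applicable participants carry every antecedent item; non-applicable
    participants carry none of them (each variable set to its
    complement state), so the conjunction count equals ``a + b``.
    """
    n = a + b + c + d
    applicable = np.zeros(n, dtype=bool)
    applicable[: a + b] = True
    outcome = np.zeros(n, dtype=bool)
    outcome[:a] = True
    outcome[a + b : a + b + c] = True

    items: list[Item] = []
    columns: list[np.ndarray] = []
    for variable, state in antecedent:
        item, complement = _paired_items(variable, state)
        items += [item, complement]
        columns += [applicable.copy(), ~applicable]
    c_item, c_complement = _paired_items(*consequent)
    items += [c_item, c_complement]
    columns += [outcome, ~outcome]
    return ItemMatrix(
        participants=[f"P{i:04d}" for i in range(n)],
        items=items,
        membership=np.column_stack(columns),
    )


def matrix_from_single_rule_counts(
    counts: Mapping[str, tuple[int, int, int, int]],
    slug_items: Mapping[str, tuple[str, str]],
    consequent: tuple[str, str] = ("pcs_2y", LOW),
) -> ItemMatrix:
    """A matrix realizing *all* single-rule tables against one consequent.

    Every table must share N and the consequent margin a + c.  Keys of
    ``counts`` are rule slugs resolved to (variable, state) via
    ``slug_items``.
    """
    tables = list(counts.items())
    n_values = {sum(t) for _, t in tables}
    if len(n_values) != 1:
        raise ValueError(f"tables disagree on N: {sorted(n_values)}")
    n = n_values.pop()
    margins = {t[0] + t[2] for _, t in tables}
    if len(margins) != 1:
        raise ValueError(f"tables disagree on the consequent margin: {sorted(margins)}")
    n_low = margins.pop()

    # participants 0..n_low-1 have the consequent state
    outcome = np.zeros(n, dtype=bool)
    outcome[:n_low] = True

    items: list[Item] = []
    columns: list[np.ndarray] = []
    for slug, (a, b, _c, _d) in tables:
        variable, state = slug_items[slug]
        applicable = np.zeros(n, dtype=bool)
        applicable[:a] = True  # a of the low-outcome participants
        applicable[n_low : n_low + b] = True  # b of the high-outcome ones
        item, complement = _paired_items(variable, state)
        items += [item, complement]
        columns += [applicable, ~applicable]
    c_item, c_complement = _paired_items(*consequent)
    items += [c_item, c_complement]
    columns += [outcome, ~outcome]
    return ItemMatrix(
        participants=[f"P{i:04d}" for i in range(n)],
        items=items,
        membership=np.column_stack(columns),
    )
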
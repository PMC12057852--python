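"""Dichotomization of clinical variables and the boolean item matrix.

Every analysis variable is reduced to a pair of mutually exclusive
*items* — e.g. ``(age, high)`` / ``(age, low)`` — either at a fixed
literature cut-off (inclusive on the high side) or by an equal-frequency
split at the sample median.  Categorical variables contribute one item
per observed level.  Both states of each variable are kept as items so
that either may appear as a rule condition (e.g. "Non-depressive
symptoms" or "Female sex").

Median-split tie rule: strictly greater than the median is "high"; ties
at the median fall to the low group.  The median is that of the full
analysis sample, so with an even N and no ties the split is exactly
N/2 : N/2, and ties at the median enlarge the low group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CATEGORICAL_LEVELS, CohortTable, VariableSpec
from .errors import ConfigError, DegenerateDataError, ValidationError

HIGH, LOW = "high", "low"


@dataclass(frozen=True)
class Item:
    """One state of one variable, e.g. ``(womac_pain, high)``."""

    variable: str
    state: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(self, "label", f"{self.variable}={self.state}")

    # identity ignores the display label
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Item):
            return NotImplemented
        return (self.variable, self.state) == (other.variable, other.state)

    def __hash__(self) -> int:
        return hash((self.variable, self.state))

    def key(self) -> tuple[str, str]:
        return (self.variable, self.state)


@dataclass
class ItemMatrix:
    """Participants x items boolean membership matrix."""

    participants: list[str]
    items: list[Item]
    membership: np.ndarray = field(repr=False)  # bool, shape (N, n_items)

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != (len(self.participants), len(self.items)):
            raise ValueError("membership shape does not match participants x items")
        keys = [it.key() for it in self.items]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate items in matrix")

    @property
    def n(self) -> int:
        return len(self.participants)

    def find(self, variable: str, state: str) -> Item:
        for it in self.items:
            if it.key() == (variable, state):
                return it
        raise KeyError(f"no item ({variable}, {state})")

    def column(self, item: Item) -> np.ndarray:
        try:
            idx = self.items.index(item)
        except ValueError:
            raise KeyError(f"item {item.key()} not in matrix") from None
        return self.membership[:, idx]

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(
            [it.key() for it in self.items], names=["variable", "state"]
        )
        return pd.DataFrame(self.membership, index=self.participants, columns=cols)


def dichotomize_fixed(
    values: Sequence[float] | np.ndarray, cutoff: float, high_if: str = "ge"
) -> np.ndarray:
    """Fixed-cutoff split; returns a boolean vector (True = high state).

    ``high_if='ge'`` (the default) puts values equal to the cut-off in
    the high group, matching the "16 or higher" / ">= 60 years"
    conventions for CES-D and age.
    """
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    bad = ~np.isfinite(arr)
    if bad.any():
        raise ValidationError(f"non-finite value at position {int(np.where(bad)[0][0])}")
    if high_if == "ge":
        return arr >= cutoff
    if high_if == "gt":
        return arr > cutoff
    raise ConfigError(f"unknown orientation {high_if!r}")


def dichotomize_median(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Equal-frequency split at the sample median (True = high state).

    High means strictly greater than the median of all N values (for
    even N, the midpoint of the two central order statistics); ties at
    the median go low.  Raises for a single-valued vector, which admits
    no split.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("median split needs at least 2 values")
    bad = ~np.isfinite(arr)
    if bad.any():
        raise ValidationError(f"non-finite value at position {int(np.where(bad)[0][0])}")
    if np.all(arr == arr[0]):
        raise DegenerateDataError("degenerate variable: single-valued")
    return arr > np.median(arr)


def _dichotomize(spec: VariableSpec, values: pd.Series) -> np.ndarray:
    if spec.method == "fixed_cutoff":
        assert spec.cutoff is not None
        return dichotomize_fixed(values.to_numpy(dtype=float), spec.cutoff, spec.high_if)
    if spec.method == "median_split":
        return dichotomize_median(values.to_numpy(dtype=float))
    raise ConfigError(f"{spec.variable}: not a dichotomizable method")


def build_item_matrix(cohort: CohortTable, specs: Sequence[VariableSpec]) -> ItemMatrix:
    """Assemble the boolean item matrix for a cohort.

    Each dichotomized variable contributes a high and a low item (exactly
    one true per participant); each categorical variable contributes one
    item per observed level.
    """
    items: list[Item] = []
    columns: list[np.ndarray] = []
    n = len(cohort)
    for spec in specs:
        values = cohort.column(spec.variable)
        if spec.method == "categorical_passthrough":
            levels = CATEGORICAL_LEVELS.get(
                spec.variable, tuple(pd.unique(values.astype(str)))
            )
            for i, level in enumerate(levels):
                mask = (values.astype(str) == level).to_numpy()
                if mask.any():
                    label = spec.labels[i] if i < len(spec.labels) else level
                    items.append(Item(spec.variable, level, label=label))
                    columns.append(mask)
        else:
            high = _dichotomize(spec, values)
            items.append(Item(spec.variable, HIGH, label=spec.labels[0]))
            columns.append(high)
            items.append(Item(spec.variable, LOW, label=spec.labels[1]))
            columns.append(~high)
    membership = np.column_stack(columns) if columns else np.zeros((n, 0), dtype=bool)
    return ItemMatrix(
        participants=cohort.participant_ids, items=items, membership=membership
    )


def matrix_audit_frame(matrix: ItemMatrix) -> pd.DataFrame:
    """0/1 dump of the binarized matrix for audit TSVs."""
    frame = matrix.to_frame().astype(int)
    frame.columns = [f"{v}:{s}" for v, s in frame.columns]
    frame.index.name = "participant_id"
    return frame
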
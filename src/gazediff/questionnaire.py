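"""Gambling Craving Scale (GACS) scoring, reliability and median split.

The GACS is a 9-item measure of gambling-related craving answered on a
1-7 Likert scale, with three 3-item subscales: anticipation, desire and
relief.  Subscale scores are item sums, the total is the sum of all nine
items (range 9-63).  Participants are split into low/high craving groups
at the sample median of the total score.

The published instrument does not fix which item index belongs to which
subscale, so the mapping here is a package convention
(:data:`DEFAULT_SUBSCALE_MAP`) and can be overridden, e.g. from a YAML
config.  Totals, and hence the median split, do not depend on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

N_ITEMS = 9
ITEM_MIN, ITEM_MAX = 1, 7
SUBSCALES = ("anticipation", "desire", "relief")

#: Convention: items 1-3 anticipation, 4-6 desire, 7-9 relief (0-based indices).
DEFAULT_SUBSCALE_MAP: dict[str, tuple[int, ...]] = {
    "anticipation": (0, 1, 2),
    "desire": (3, 4, 5),
    "relief": (6, 7, 8),
}


class GacsValidationError(ValueError):
    """Raised for malformed questionnaire responses."""


class DegenerateSplitError(ValueError):
    """Raised when a median split cannot separate participants at all."""


class ZeroVarianceError(ValueError):
    """Raised when Cronbach's alpha is undefined (zero total-score variance)."""


@dataclass(frozen=True)
class GacsResponse:
    """One participant's raw item responses (nine integers in 1..7)."""

    participant_id: str
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise GacsValidationError(
                f"{self.participant_id}: expected {N_ITEMS} items, got {len(self.items)}"
            )
        for i, v in enumerate(self.items):
            if not (ITEM_MIN <= v <= ITEM_MAX):
                raise GacsValidationError(
                    f"{self.participant_id}: item {i + 1} = {v} outside "
                    f"[{ITEM_MIN}, {ITEM_MAX}]"
                )


@dataclass(frozen=True)
class GacsScore:
    """Subscale sums and total for one participant."""

    participant_id: str
    total: int
    anticipation: int
    desire: int
    relief: int


@dataclass
class GroupAssignment:
    """Low/high craving labels from a median split of GACS totals."""

    labels: dict[str, str]
    split_value: float
    tie_policy: str = "low"

    def group(self, label: str) -> list[str]:
        return [p for p, g in self.labels.items() if g == label]

    @property
    def n_low(self) -> int:
        return sum(1 for g in self.labels.values() if g == "low")

    @property
    def n_high(self) -> int:
        return sum(1 for g in self.labels.values() if g == "high")


def _validate_subscale_map(subscale_map: Mapping[str, Sequence[int]]) -> None:
    if set(subscale_map) != set(SUBSCALES):
        raise GacsValidationError(f"subscale map must define exactly {SUBSCALES}")
    indices = [i for idx in subscale_map.values() for i in idx]
    if sorted(indices) != list(range(N_ITEMS)) or any(len(v) != 3 for v in subscale_map.values()):
        raise GacsValidationError("subscale map must partition items 0..8 into three triples")


def score_gacs(
    response: GacsResponse,
    subscale_map: Mapping[str, Sequence[int]] = DEFAULT_SUBSCALE_MAP,
) -> GacsScore:
    """Score one response: subscale sums of three items each, total of nine."""
    _validate_subscale_map(subscale_map)
    items = response.items
    sums = {name: int(sum(items[i] for i in idx)) for name, idx in subscale_map.items()}
    return GacsScore(
        participant_id=response.participant_id,
        total=int(sum(items)),
        anticipation=sums["anticipation"],
        desire=sums["desire"],
        relief=sums["relief"],
    )


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha for a participants x items score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total),
    with unbiased (n-1 denominator) sample variances throughout.
    """
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise GacsValidationError("need at least 2 participants and 2 items")
    k = m.shape[1]
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ZeroVarianceError("total-score variance is zero; alpha undefined")
    item_var = m.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def median_split(
    totals: Mapping[str, float],
    tie_policy: str = "low",
) -> GroupAssignment:
    """Split participants into low/high groups at the median total score.

    Under the default ``tie_policy="low"`` a participant is labelled high
    iff their total is strictly greater than the median; ``"high"`` labels
    median-valued participants high instead.  A split that leaves one side
    empty (all mass at the median on one side) triggers a warning; fully
    identical totals are an error.
    """
    if tie_policy not in ("low", "high"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    if len(totals) < 2:
        raise GacsValidationError("need at least 2 participants for a median split")
    values = np.array(list(totals.values()), dtype=float)
    if np.ptp(values) == 0:
        raise DegenerateSplitError("all totals identical; median split undefined")
    median = float(np.median(values))
    if tie_policy == "low":
        labels = {p: ("high" if v > median else "low") for p, v in totals.items()}
    else:
        labels = {p: ("high" if v >= median else "low") for p, v in totals.items()}
    assignment = GroupAssignment(labels=labels, split_value=median, tie_policy=tie_policy)
    if assignment.n_low == 0 or assignment.n_high == 0:
        warnings.warn(
            f"degenerate median split: low={assignment.n_low}, high={assignment.n_high}",
            stacklevel=2,
        )
    return assignment


def read_questionnaire_csv(path) -> list[GacsResponse]:
    """Read responses from a CSV with columns participant_id,item1..item9."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    cols = [f"item{i}" for i in range(1, N_ITEMS + 1)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise GacsValidationError(f"{path}: missing columns {missing}")
    return [
        GacsResponse(str(row["participant_id"]), tuple(int(row[c]) for c in cols))
        for _, row in df.iterrows()
    ]


def write_questionnaire_csv(responses: Sequence[GacsResponse], path) -> None:
    rows = [
        {"participant_id": r.participant_id, **{f"item{i + 1}": v for i, v in enumerate(r.items)}}
        for r in responses
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def split_from_responses(
    responses: Sequence[GacsResponse],
    subscale_map: Mapping[str, Sequence[int]] = DEFAULT_SUBSCALE_MAP,
    tie_policy: str = "low",
) -> tuple[list[GacsScore], GroupAssignment]:
    """Score all responses and median-split the cohort in one step."""
    scores = [score_gacs(r, subscale_map) for r in responses]
    totals = {s.participant_id: float(s.total) for s in scores}
    return scores, median_split(totals, tie_policy)
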
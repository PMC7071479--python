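"""Semiquantitative chromogenic (DAB) intensity scoring.

Each neuron in ten high-magnification fields per case receives an integer
score 0 (negative), 1+ (mild), 2+ (moderate) or 3+ (strong).  Case-level
mean scores are the arithmetic mean of a case's neuron scores; group means
are the unweighted mean of case means (per-case averages first, then group
averages).  Scoring is visual in the original protocol, so the primary
input path is a pre-scored table; an intensity-threshold auto-scorer with
user-configurable cut points is provided as a secondary path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_SCORES = (0, 1, 2, 3)


@dataclass(frozen=True)
class NeuronScore:
    case_id: str
    field_id: int
    score: int

    def __post_init__(self) -> None:
        if self.score not in VALID_SCORES:
            raise ValueError(f"score must be one of {VALID_SCORES}, got {self.score}")
        if not 1 <= self.field_id <= 10:
            raise ValueError("field_id must be in 1..10")


@dataclass(frozen=True)
class CaseRecord:
    """One case's metadata plus its aggregate labelling intensity."""

    case_id: str
    region: str
    stage: str
    age: float
    final_mmse: float
    apoe: str | None
    mean_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_score <= 3.0:
            raise ValueError("mean_score must be in [0, 3]")


def score_from_intensity(mean_od: float, cut_points: Sequence[float]) -> int:
    """Auto-score from a mean optical density: count cut points strictly below.

    ``cut_points`` are three strictly ascending thresholds; a value equal to
    a cut point takes the lower score.  Monotone non-decreasing in mean_od.
    """
    cuts = list(cut_points)
    if len(cuts) != 3 or any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cut_points must be 3 strictly ascending values")
    return sum(mean_od > c for c in cuts)


def case_mean_score(scores: Iterable[int | NeuronScore]) -> float:
    """Arithmetic mean of one case's integer neuron scores."""
    vals = [s.score if isinstance(s, NeuronScore) else int(s) for s in scores]
    if not vals:
        raise ValueError("cannot average an empty list of scores")
    bad = [v for v in vals if v not in VALID_SCORES]
    if bad:
        raise ValueError(f"invalid scores {sorted(set(bad))}; expected {VALID_SCORES}")
    return float(np.mean(vals))


def group_mean_score(case_means: Iterable[float | CaseRecord]) -> float:
    """Unweighted mean of case mean scores within one group."""
    vals = [c.mean_score if isinstance(c, CaseRecord) else float(c) for c in case_means]
    if not vals:
        raise ValueError("cannot average an empty group")
    return float(np.mean(vals))


def case_table(neurons: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-neuron score table to one row per case.

    Requires columns case_id and score; group/region/stage columns, when
    present, are carried through (they are constant within a case).
    """
    if neurons.empty:
        raise ValueError("empty neuron score table")
    keep = [c for c in ("group", "region", "stage") if c in neurons.columns]
    grouped = neurons.groupby("case_id", sort=True)
    out = grouped.agg(
        mean_score=("score", "mean"), n_neurons=("score", "size")
    ).reset_index()
    for col in keep:
        out[col] = grouped[col].first().to_numpy()
    return out


def group_mean_scores(cases: pd.DataFrame) -> dict[str, float]:
    """Group label -> unweighted mean of the group's case mean scores."""
    if "group" not in cases.columns or "mean_score" not in cases.columns:
        raise ValueError("cases table needs 'group' and 'mean_score' columns")
    return {
        g: group_mean_score(sub["mean_score"].tolist())
        for g, sub in cases.groupby("group", sort=True)
    }
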
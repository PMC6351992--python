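"""Linear creation-time cost model for value-set construction.

Building a value set in terminology-management software has a fixed setup
cost (configuring the set's common settings) plus a roughly constant
per-concept cost for adding each enumerated concept. That makes creation
time affine in the number of concepts:

    time (min) = slope * n_concepts + intercept

The model is fit by ordinary least squares on measured timing observations
and then used to estimate the creation time of large enumerations that
were not timed directly. The reference coefficients for the published
study conditions are slope 0.4177 min/concept (about 25 s per concept) and
intercept 3.8707 min (just under 4 minutes of obligate setup); they live
with the study fixture in :mod:`hierset.study`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from ._rounding import round_minutes, round_ratio


@dataclass(frozen=True)
class TimeModel:
    """Affine creation-time model: minutes = slope * n_concepts + intercept."""

    slope: float
    intercept: float


@dataclass(frozen=True)
class TimingObservation:
    """One measured build: concept count and wall-clock minutes.

    ``measured`` distinguishes directly timed builds from rows whose time
    was estimated with a fitted model; only measured rows belong in a fit.
    """

    label: str
    n_concepts: int
    minutes: float
    measured: bool = True

    def __post_init__(self) -> None:
        if self.n_concepts < 0:
            raise ValidationError("n_concepts must be >= 0")
        if self.minutes < 0:
            raise ValidationError("minutes must be >= 0")


def fit_time_model(observations: Sequence[TimingObservation]) -> TimeModel:
    """Ordinary least-squares fit of the affine time model.

    Requires at least two observations spanning at least two distinct
    concept counts; an all-equal design has no identifiable slope.
    """
    if len(observations) < 2:
        raise ValidationError("need at least 2 timing observations to fit")
    n = np.array([o.n_concepts for o in observations], dtype=float)
    y = np.array([o.minutes for o in observations], dtype=float)
    if np.unique(n).size < 2:
        raise ValidationError(
            "degenerate design: all observations share one concept count"
        )
    design = np.column_stack([n, np.ones_like(n)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    return TimeModel(slope=float(slope), intercept=float(intercept))


def predict_time(model: TimeModel, n_concepts: int) -> Tuple[float, int]:
    """Predicted minutes for a build of ``n_concepts`` concepts.

    Returns ``(unrounded_minutes, rounded_minutes)``; the rounded value is
    the nearest whole minute, half away from zero.
    """
    if n_concepts < 0:
        raise ValidationError("n_concepts must be >= 0")
    minutes = model.slope * n_concepts + model.intercept
    return minutes, round_minutes(minutes)


@dataclass(frozen=True)
class TimeComparison:
    """Extensional-minus-intensional build time, and their ratio."""

    difference: float
    ratio: float


def time_comparison(ext_minutes: float, int_minutes: float) -> TimeComparison:
    """Compare build times; operates on unrounded minutes.

    ``difference`` is exact; ``ratio`` is reported to one decimal.
    """
    if int_minutes <= 0:
        raise ValidationError("intensional build time must be > 0")
    return TimeComparison(
        difference=ext_minutes - int_minutes,
        ratio=round_ratio(ext_minutes / int_minutes),
    )


# ---------------------------------------------------------------------------
# timing-file I/O
# ---------------------------------------------------------------------------


def load_timing_observations(path: str) -> List[TimingObservation]:
    """Read a ``label<TAB>n_concepts<TAB>minutes<TAB>measured(0/1)`` TSV."""
    import pandas as pd

    from .errors import FormatError

    df = pd.read_csv(path, sep="\t", dtype=str, quoting=3, keep_default_na=False)
    required = ("label", "n_concepts", "minutes", "measured")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return [
        TimingObservation(
            label=str(r.label),
            n_concepts=int(r.n_concepts),
            minutes=float(r.minutes),
            measured=str(r.measured) == "1",
        )
        for r in df.itertuples(index=False)
    ]


def write_timing_observations(
    observations: Sequence[TimingObservation], path: str
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("label\tn_concepts\tminutes\tmeasured\n")
        for o in observations:
            fh.write(
                f"{o.label}\t{o.n_concepts}\t{o.minutes!r}\t{1 if o.measured else 0}\n"
            )
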
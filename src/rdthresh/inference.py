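"""Bootstrap and subsampled-bootstrap inference for pipeline estimators.

The whole estimation pipeline (bandwidth selection, side fits, root finding)
is re-run on each resample, so the bootstrap spread reflects every
data-dependent choice the estimator makes.  Resamples that fail to produce
an estimate (e.g. no root within the window) are dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._exceptions import InferenceError, RDThreshError, ValidationError
from .data import RDDataset

#: resamples default to this size when the dataset is larger than
#: SUBSAMPLE_TRIGGER observations
SUBSAMPLE_TRIGGER = 100_000
SUBSAMPLE_SIZE = 10_000

DEFAULT_REPS = 100


@dataclass(frozen=True)
class BootstrapResult:
    """Full-sample estimate plus bootstrap distribution summaries."""

    estimate_full: float
    mean_boot: float
    se_boot: float
    reps: int
    subsample: int | None
    failures: int
    seed: int

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + level / 2))
        return (
            self.estimate_full - z * self.se_boot,
            self.estimate_full + z * self.se_boot,
        )


def _resample(
    data: RDDataset, rng: np.random.Generator, size: int, stratify: bool
) -> RDDataset:
    if stratify:
        below = np.nonzero(data.x < data.c)[0]
        above = np.nonzero(data.x >= data.c)[0]
        n_b = max(int(round(size * len(below) / data.n)), 2)
        n_a = max(size - n_b, 2)
        idx = np.concatenate(
            [rng.choice(below, size=n_b), rng.choice(above, size=n_a)]
        )
    else:
        idx = rng.integers(0, data.n, size=size)
    t = None if data.t is None else data.t[idx]
    return RDDataset(
        x=data.x[idx],
        y=data.y[idx],
        t=t,
        c=data.c,
        treated_above=data.treated_above,
        design=data.design,
    )


def bootstrap(
    estimator: Callable[[RDDataset], float],
    data: RDDataset,
    reps: int = DEFAULT_REPS,
    subsample: int | None = None,
    seed: int = 0,
    *,
    stratify_by_side: bool = False,
) -> BootstrapResult:
    """Nonparametric bootstrap of a scalar pipeline estimator.

    Observations are resampled with replacement (both sides pooled by
    default; ``stratify_by_side`` preserves the side split when imbalance
    would starve a fit).  ``subsample`` draws smaller resamples — set
    automatically to 10,000 for datasets above 100,000 rows.  Deterministic
    given ``seed``.
    """
    if reps < 2:
        raise ValidationError("need at least 2 bootstrap repetitions")
    if subsample is None and data.n > SUBSAMPLE_TRIGGER:
        subsample = SUBSAMPLE_SIZE
    size = subsample if subsample is not None else data.n
    if size < 4:
        raise ValidationError("resample size must be at least 4")
    estimate_full = float(estimator(data))
    rng = np.random.default_rng(seed)
    values: list[float] = []
    failures = 0
    failure_notes: dict[str, int] = {}
    for _ in range(reps):
        sample = None
        try:
            sample = _resample(data, rng, size, stratify_by_side)
            values.append(float(estimator(sample)))
        except RDThreshError as err:
            failures += 1
            key = type(err).__name__
            failure_notes[key] = failure_notes.get(key, 0) + 1
    if failures > reps / 2:
        raise InferenceError(
            f"{failures}/{reps} bootstrap repetitions failed: {failure_notes}"
        )
    arr = np.asarray(values, float)
    return BootstrapResult(
        estimate_full=estimate_full,
        mean_boot=float(arr.mean()),
        se_boot=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        reps=reps,
        subsample=subsample,
        failures=failures,
        seed=seed,
    )
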
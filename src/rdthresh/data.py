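"""Datasets, delimited-file I/O, and seeded simulators for RD designs.

A regression-discontinuity (RD) dataset pairs a running variable ``x`` with an
outcome ``y``; treatment is assigned by comparing ``x`` to a policy threshold
``c``.  In a *sharp* design crossing the threshold determines treatment
deterministically; in a *fuzzy* design it only shifts the probability of
treatment, and the realized treatment indicator ``t`` must be observed.

The simulators draw from piecewise-linear potential-outcome surfaces with
Gaussian noise — the setting in which the downstream local-linear estimators
are exactly correctly specified — and, in fuzzy mode, from per-side linear
compliance-probability lines with a discontinuity at the threshold.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ValidationError

Design = Literal["sharp", "fuzzy"]

#: Half-width of the extrapolation window conventionally used with the
#: built-in scenario presets (their x_range spans ``c ± 5``).
PRESET_BANDWIDTH = 5.0


@dataclass(frozen=True)
class RDDataset:
    """Observations of an RD design plus its policy convention.

    Parameters
    ----------
    x, y
        Running variable and outcome, same length, all finite.
    t
        Realized binary treatment indicator; required for fuzzy designs,
        optional (and redundant) for sharp ones.
    c
        Policy threshold, in the units of ``x``.  ``x == c`` belongs to the
        treated side when ``treated_above``.
    treated_above
        Assignment convention: treated iff ``x >= c`` (default) or iff
        ``x < c``.
    design
        ``"sharp"`` or ``"fuzzy"``.
    """

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray | None = None
    c: float = 0.0
    treated_above: bool = True
    design: Design = "sharp"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise ValidationError("x and y must be 1-d arrays of equal length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValidationError("x and y must be finite")
        if self.design not in ("sharp", "fuzzy"):
            raise ValidationError(f"unknown design {self.design!r}")
        if self.t is not None:
            t = np.asarray(self.t, dtype=float)
            object.__setattr__(self, "t", t)
            if len(t) != len(x):
                raise ValidationError("t must match x in length")
            if not np.all(np.isin(t, (0.0, 1.0))):
                raise ValidationError("t must be binary")
        elif self.design == "fuzzy":
            raise ValidationError("fuzzy design requires a treatment column t")
        n_below = int(np.sum(x < self.c))
        n_above = int(np.sum(x >= self.c))
        if n_below < 2 or n_above < 2:
            side = "below" if n_below < 2 else "above"
            raise ValidationError(
                f"need at least 2 observations {side} the threshold c={self.c}"
            )
        if self.design == "sharp" and self.t is not None:
            assigned = (x >= self.c) if self.treated_above else (x < self.c)
            if not np.array_equal(self.t.astype(bool), assigned):
                raise ValidationError(
                    "sharp design: t must equal the threshold-assignment indicator"
                )

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def n_below(self) -> int:
        return int(np.sum(self.x < self.c))

    @property
    def n_above(self) -> int:
        return int(np.sum(self.x >= self.c))

    def mirrored(self) -> "RDDataset":
        """Reflect the design about the threshold (x -> -x, c -> -c).

        Mapping a treated-below design through this reflection yields an
        equivalent treated-above design, which is the convention the solvers
        work in; returned thresholds are mapped back by negation.
        """
        t = None if self.t is None else self.t.copy()
        return RDDataset(
            x=-self.x,
            y=self.y.copy(),
            t=t,
            c=-self.c,
            treated_above=not self.treated_above,
            design=self.design,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"x": self.x, "y": self.y}
        if self.t is not None:
            cols["t"] = self.t.astype(int)
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class LoadReport:
    """Accounting of a delimited-file load."""

    n_read: int
    n_kept: int
    n_dropped: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        noun = "row" if self.n_dropped == 1 else "rows"
        return f"{self.n_dropped} {noun} dropped ({self.n_kept}/{self.n_read} kept)"


def read_dataset(
    path: str | Path | io.IOBase,
    c: float,
    *,
    design: Design = "sharp",
    treated_above: bool = True,
    columns: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> tuple[RDDataset, LoadReport]:
    """Read a delimited file into an :class:`RDDataset`.

    Rows with missing or non-numeric values in the mapped columns are dropped
    and counted in the returned :class:`LoadReport`; nothing is imputed.

    Parameters
    ----------
    columns
        Maps logical names ``{"x", "y", "t"}`` to file column names; defaults
        to the identity mapping.
    """
    colmap = {"x": "x", "y": "y", "t": "t"}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    needed = [colmap["x"], colmap["y"]]
    if design == "fuzzy":
        if colmap["t"] not in df.columns:
            raise ValidationError(
                f"fuzzy design requires a treatment column {colmap['t']!r}, "
                f"not found in {sorted(df.columns)}"
            )
        needed.append(colmap["t"])
    missing = [col for col in needed if col not in df.columns]
    if missing:
        raise ValidationError(f"columns not found in file: {missing}")

    n_read = len(df)
    sub = df[needed].apply(pd.to_numeric, errors="coerce")
    keep = sub.notna().all(axis=1)
    sub = sub[keep]
    n_kept = len(sub)

    x = sub[colmap["x"]].to_numpy(float)
    y = sub[colmap["y"]].to_numpy(float)
    t = sub[colmap["t"]].to_numpy(float) if design == "fuzzy" else None
    if n_kept == 0:
        raise ValidationError("no usable rows in file")
    for side, mask in (("below", x < c), ("above", x >= c)):
        if not np.any(mask):
            raise ValidationError(
                f"no observations {side} the threshold c={c}: threshold "
                "outside the observed running-variable range"
            )
    data = RDDataset(
        x=x, y=y, t=t, c=c, treated_above=treated_above, design=design
    )
    return data, LoadReport(n_read=n_read, n_kept=n_kept, n_dropped=n_read - n_kept)


def write_dataset(data: RDDataset, path: str | Path | io.IOBase) -> None:
    """Write observations as CSV (columns x,y[,t]) at full float precision."""
    df = data.to_frame()
    # pandas prints shortest round-trip reprs, so read-back is bit-exact
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

#: per-side compliance-probability lines f(x) = a + b*(x - c)
ComplianceLines = tuple[float, float, float, float]  # a_below, b_below, a_above, b_above


@dataclass(frozen=True)
class ScenarioSpec:
    """Generating model for a simulated RD scenario.

    The two potential-outcome surfaces are lines in ``x - c``:
    control ``alpha0 + beta0*(x-c)`` and treated ``alpha1 + beta1*(x-c)``,
    each observed with N(0, sigma^2) noise.  ``compliance`` (fuzzy mode only)
    gives per-side treatment-probability lines ``(a0, b0, a1, b1)`` so that
    P(T=1|x) = a0 + b0*(x-c) below the threshold and a1 + b1*(x-c) at or
    above it.
    """

    alpha0: float
    beta0: float
    alpha1: float
    beta1: float
    sigma: float
    c: float
    x_range: tuple[float, float]
    n: int
    density: str | Sequence[float] = "uniform"
    compliance: ComplianceLines | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.x_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValidationError("x_range must be a nondegenerate finite interval")
        if not (lo <= self.c <= hi):
            raise ValidationError("x_range must contain the threshold c")
        if self.sigma < 0:
            raise ValidationError("sigma must be nonnegative")
        if self.n < 4:
            raise ValidationError("need n >= 4")
        if self.compliance is not None:
            a0, b0, a1, b1 = self.compliance
            for a, b, seg in (
                (a0, b0, (lo - self.c, 0.0)),
                (a1, b1, (0.0, hi - self.c)),
            ):
                vals = (a + b * seg[0], a + b * seg[1])
                if min(vals) < 0.0 or max(vals) > 1.0:
                    raise ValidationError(
                        "compliance lines must stay within [0, 1] over x_range; "
                        f"got endpoint probabilities {vals}"
                    )

    # --- model evaluation helpers used by generators and test oracles ---

    def control_line(self, x: np.ndarray) -> np.ndarray:
        return self.alpha0 + self.beta0 * (np.asarray(x, float) - self.c)

    def treated_line(self, x: np.ndarray) -> np.ndarray:
        return self.alpha1 + self.beta1 * (np.asarray(x, float) - self.c)

    @property
    def late(self) -> float:
        """True local average treatment effect at the threshold."""
        return self.alpha1 - self.alpha0

    @property
    def ted(self) -> float:
        """True treatment-effect derivative at the threshold."""
        return self.beta1 - self.beta0

    @property
    def root(self) -> float | None:
        """Running-variable value where the true effect line crosses zero."""
        if self.ted == 0:
            return None
        return self.c - self.late / self.ted


def _draw_x(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.x_range
    if isinstance(spec.density, str):
        if spec.density == "uniform":
            return rng.uniform(lo, hi, size=spec.n)
        if spec.density == "triangular":
            # peak at the threshold: mass concentrates where the design
            # has identifying power
            return rng.triangular(lo, spec.c, hi, size=spec.n)
        raise ValidationError(f"unknown density {spec.density!r}")
    weights = np.asarray(spec.density, dtype=float)
    if weights.ndim != 1 or len(weights) == 0 or np.any(weights < 0):
        raise ValidationError("piecewise-constant density needs nonnegative weights")
    total = weights.sum()
    if total <= 0:
        raise ValidationError("density weights must not all be zero")
    probs = weights / total
    edges = np.linspace(lo, hi, len(weights) + 1)
    bins = rng.choice(len(weights), size=spec.n, p=probs)
    u = rng.uniform(size=spec.n)
    return edges[bins] + u * (edges[bins + 1] - edges[bins])


def generate_sharp(spec: ScenarioSpec) -> RDDataset:
    """Simulate a sharp design from piecewise-linear surfaces.

    Deterministic given ``spec.seed``: the same spec yields a bit-identical
    dataset.
    """
    if spec.compliance is not None:
        raise ValidationError("sharp generation must not specify compliance lines")
    rng = np.random.default_rng(spec.seed)
    x = _draw_x(spec, rng)
    above = x >= spec.c
    y = np.where(above, spec.treated_line(x), spec.control_line(x))
    if spec.sigma > 0:
        y = y + rng.normal(0.0, spec.sigma, size=spec.n)
    return RDDataset(x=x, y=y, c=spec.c, design="sharp")


def generate_fuzzy(spec: ScenarioSpec) -> RDDataset:
    """Simulate a fuzzy design: Bernoulli compliance, no defiers.

    Treatment is drawn as T ~ Bernoulli(f_side(x)) from the per-side
    compliance lines, and the outcome follows the treated or control surface
    according to the *realized* treatment.
    """
    if spec.compliance is None:
        raise ValidationError("fuzzy generation requires compliance lines")
    a0, b0, a1, b1 = spec.compliance
    rng = np.random.default_rng(spec.seed)
    x = _draw_x(spec, rng)
    above = x >= spec.c
    f = np.where(above, a1 + b1 * (x - spec.c), a0 + b0 * (x - spec.c))
    t = (rng.uniform(size=spec.n) < f).astype(float)
    y = np.where(t == 1.0, spec.treated_line(x), spec.control_line(x))
    if spec.sigma > 0:
        y = y + rng.normal(0.0, spec.sigma, size=spec.n)
    return RDDataset(x=x, y=y, t=t, c=spec.c, design="fuzzy")


_PRESETS = {
    # alpha0, beta0, alpha1, beta1 around c=10 on [5, 15]
    # canonical: positive LATE (2) and positive TED difference (1);
    # the effect line crosses zero at x = 8, inside the window, left of c.
    "canonical": dict(alpha0=2.0, beta0=0.5, alpha1=4.0, beta1=1.5),
    # flat_ted: positive LATE, identical slopes; no root, boundary optimum.
    "flat_ted": dict(alpha0=2.0, beta0=0.5, alpha1=4.0, beta1=0.5),
    # adversarial: LATE and TED difference of opposite signs; the effect
    # line crosses zero at x = 14, on the treated side.
    "adversarial": dict(alpha0=2.0, beta0=1.5, alpha1=4.0, beta1=1.0),
}


def scenario_preset(
    name: str,
    *,
    n: int = 500,
    sigma: float = 1.0,
    seed: int = 0,
    compliance: ComplianceLines | None = None,
) -> ScenarioSpec:
    """Return one of the three canonical scenario taxonomies.

    All presets put the threshold at c=10 with support [5, 15] (so the
    conventional extrapolation half-width is :data:`PRESET_BANDWIDTH`) and a
    true treatment effect of +2 outcome units at the threshold.
    """
    try:
        lines = _PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return ScenarioSpec(
        **lines,
        sigma=sigma,
        c=10.0,
        x_range=(5.0, 15.0),
        n=n,
        density="uniform",
        compliance=compliance,
        seed=seed,
    )
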
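"""Welfare over a binned density and the family of optimal thresholds.

The welfare of implementing the policy at threshold ``t`` is the cumulative
treatment effect over the treated population,

    W(t) = integral from t to x_max of pi(x) p(x) dx,

estimated as a Riemann sum of the effect curve against a histogram density.
Within the extrapolation window [c-h, c+h] an interior optimum is a root of
``pi(x)`` (or ``pi(x) = z`` with a per-subject treatment cost ``z``);
otherwise the optimum sits on a window boundary.  The conservative
(risk-averse) threshold stops where the one-sided lower confidence bound of
the effect curve hits zero, and the budget-constrained variant caps the
number of treated subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from ._exceptions import ExtrapolationWarning, ValidationError
from .data import RDDataset
from .llr import EffectCurve, SideFit, estimate_late, estimate_ted

#: default histogram bin width, in running-variable units
DEFAULT_BIN_WIDTH = 0.40

#: resolution of the root-scanning grid used by the numeric solver
ROOT_GRID_POINTS = 2001

CaseLabel = Literal["canonical", "undefined", "adversarial"]


@dataclass(frozen=True)
class BinnedDensity:
    """Histogram estimate of the running-variable density."""

    edges: np.ndarray
    mass: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, float)
        mass = np.asarray(self.mass, float)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "mass", mass)
        if len(edges) != len(mass) + 1 or np.any(np.diff(edges) <= 0):
            raise ValidationError("edges must strictly increase and bound every bin")
        if np.any(mass < 0) or abs(mass.sum() - 1.0) > 1e-12:
            raise ValidationError("bin masses must be nonnegative and sum to 1")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def mass_between(self, lo: float, hi: float) -> float:
        """Probability mass on [lo, hi], partial bins weighted by overlap."""
        if hi <= lo:
            return 0.0
        left = np.maximum(self.edges[:-1], lo)
        right = np.minimum(self.edges[1:], hi)
        frac = np.clip(right - left, 0.0, None) / np.diff(self.edges)
        return float(np.sum(frac * self.mass))

    def mass_above(self, t: float) -> float:
        return self.mass_between(t, float(self.edges[-1]))

    def shifted(self, delta: float) -> "BinnedDensity":
        return BinnedDensity(
            edges=self.edges + delta, mass=self.mass.copy(), bin_width=self.bin_width
        )


def estimate_density(
    data: RDDataset,
    bin_width: float = DEFAULT_BIN_WIDTH,
    range: tuple[float, float] | None = None,
) -> BinnedDensity:
    """Histogram frequencies normalized to unit mass over ``range``.

    Bins are half-open [e_i, e_{i+1}) with the last bin closed, anchored at
    the lower end of the range.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    lo, hi = range if range is not None else (float(data.x.min()), float(data.x.max()))
    if not hi > lo:
        raise ValidationError("range must be nondegenerate")
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-12))
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)  # last bin absorbs any remainder and is closed
    counts, _ = np.histogram(data.x, bins=edges)
    total = counts.sum()
    if total == 0:
        raise ValidationError(f"no observations in range [{lo}, {hi}]")
    return BinnedDensity(edges=edges, mass=counts / total, bin_width=bin_width)


def welfare(
    curve: EffectCurve,
    density: BinnedDensity,
    t: float,
    upper: float | None = None,
    *,
    cost: float = 0.0,
) -> float:
    """Riemann-sum welfare of treating everyone with x in [t, upper].

    Each bin contributes the effect at the midpoint of its overlap with
    [t, upper], weighted by the overlapping share of its mass; fuzzy curves
    additionally weight by the complier share.  ``cost`` subtracts a
    per-subject treatment cost z from the integrand (marginal-cost version
    of the objective).
    """
    if upper is None:
        upper = float(density.edges[-1])
    if t >= upper:
        return 0.0
    left = np.maximum(density.edges[:-1], t)
    right = np.minimum(density.edges[1:], upper)
    widths = np.diff(density.edges)
    frac = np.clip(right - left, 0.0, None) / widths
    active = frac > 0
    if not np.any(active):
        return 0.0
    mids = 0.5 * (left[active] + right[active])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        vals = np.asarray(curve.value(mids), float) - cost
        if curve.complier_share is not None:
            vals = vals * np.asarray(curve.complier_share(mids), float)
    return float(np.sum(vals * frac[active] * density.mass[active]))


@dataclass(frozen=True)
class ThresholdResult:
    """A candidate threshold with solver diagnostics."""

    value: float
    boundary_hit: bool = False
    flag: str = ""


def classify_case(below: SideFit, above: SideFit, *, tol: float = 1e-12) -> CaseLabel:
    """Label the fitted scenario by the signs of the LATE and the TED.

    ``canonical``: effect and derivative share a sign, so the effect line
    crosses zero on the untreated side of the cutoff.  ``undefined``: the
    derivative vanishes — the effect never crosses zero and the threshold
    problem is locally undefined.  ``adversarial``: opposite signs — the
    crossing is on the treated side (the treatment stops being effective for
    large running-variable values).
    """
    late = estimate_late(below, above).value
    ted = estimate_ted(below, above).value
    if abs(ted) <= tol:
        return "undefined"
    return "canonical" if late * ted > 0 else "adversarial"


def optimal_threshold_closed_form(
    below: SideFit,
    above: SideFit,
    c: float,
    h: float,
    cost: float = 0.0,
) -> ThresholdResult:
    """Closed-form optimum of the local-linear effect curve.

    The interior optimum solves ``pi(x) = z``:
    ``c - ((alpha1 - z) - alpha0) / (beta1 - beta0)``, clamped to
    [c-h, c+h].  With equal slopes the root is undefined and the
    welfare-preferred boundary is returned.
    """
    late = estimate_late(below, above).value
    ted = estimate_ted(below, above).value
    if abs(ted) < 1e-12:
        # constant effect line: treat everyone (left boundary) if the net
        # effect is positive, no one extra (right boundary) otherwise
        value = c - h if late - cost > 0 else c + h
        return ThresholdResult(value=value, boundary_hit=True, flag="undefined-root")
    raw = c - (late - cost) / ted
    if raw < c - h:
        return ThresholdResult(value=c - h, boundary_hit=True)
    if raw > c + h:
        return ThresholdResult(value=c + h, boundary_hit=True)
    return ThresholdResult(value=float(raw))


def _root_candidates(
    curve: EffectCurve, lo: float, hi: float, cost: float
) -> list[float]:
    grid = np.linspace(lo, hi, ROOT_GRID_POINTS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        g = np.asarray(curve.value(grid), float) - cost
    roots: list[float] = [float(grid[i]) for i in np.nonzero(g == 0.0)[0]]
    sign_change = np.nonzero(g[:-1] * g[1:] < 0)[0]
    h = hi - lo
    for i in sign_change:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            root = brentq(
                lambda x: float(np.asarray(curve.value(np.atleast_1d(x)))[0]) - cost,
                grid[i],
                grid[i + 1],
                xtol=1e-8 * h,
            )
        roots.append(float(root))
    return roots


def optimal_threshold_numeric(
    curve: EffectCurve,
    density: BinnedDensity,
    c: float,
    h: float,
    cost: float = 0.0,
) -> ThresholdResult:
    """Welfare argmax over sign-change roots of the effect curve and the
    window endpoints.

    Works for any effect curve (linear or GP); for a local-linear sharp curve
    it agrees with :func:`optimal_threshold_closed_form` to solver precision.
    """
    lo, hi = c - h, c + h
    candidates = _root_candidates(curve, lo, hi, cost) + [lo, hi]
    scores = [welfare(curve, density, t, upper=hi, cost=cost) for t in candidates]
    best = int(np.argmax(scores))
    value = candidates[best]
    boundary = best >= len(candidates) - 2
    return ThresholdResult(value=float(value), boundary_hit=boundary)


def conservative_threshold(
    curve: EffectCurve,
    alpha: float,
    c: float,
    h: float,
    c_star: float | None = None,
) -> ThresholdResult:
    """Risk-averse threshold: lower one-sided confidence bound hits zero.

    Solves ``pi(x) - Z_alpha * se(x) = 0`` on the segment between the
    unconstrained optimum and the current threshold — the furthest move that
    still guarantees, with confidence 1 - alpha, a nonnegative effect at the
    new threshold.  If even the current threshold's effect is not
    significantly positive the threshold cannot be moved at all.
    """
    if not 0 < alpha < 0.5:
        raise ValidationError("alpha must be in (0, 0.5)")
    z = float(norm.ppf(1 - alpha))

    def g(x: float) -> float:
        xa = np.atleast_1d(float(x))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            return float(np.asarray(curve.value(xa))[0] - z * np.asarray(curve.se(xa))[0])

    if c_star is None:
        uniform = _uniform_density(c - h, c + h)
        c_star = optimal_threshold_numeric(curve, uniform, c, h).value
    if g(c) <= 0:
        return ThresholdResult(value=c, boundary_hit=False, flag="cannot move")
    if g(c_star) >= 0:
        # lower bound positive along the whole segment: the full move is safe
        return ThresholdResult(value=float(c_star))
    lo, hi = (c_star, c) if c_star <= c else (c, c_star)
    root = brentq(g, lo, hi, xtol=1e-10 * max(h, 1.0))
    return ThresholdResult(value=float(root))


def _uniform_density(lo: float, hi: float, n_bins: int = 64) -> BinnedDensity:
    edges = np.linspace(lo, hi, n_bins + 1)
    return BinnedDensity(
        edges=edges, mass=np.full(n_bins, 1.0 / n_bins), bin_width=float(edges[1] - edges[0])
    )


def budget_constrained_threshold(
    curve: EffectCurve,
    density: BinnedDensity,
    c: float,
    h: float,
    population: float,
    budget: float,
    *,
    cost: float = 0.0,
    per_subject_cost_budget: bool = False,
) -> tuple[ThresholdResult, bool]:
    """Welfare argmax subject to a cap on treated subjects (or spend).

    The constraint counts treated subjects: ``N * mass(x >= t) <= B``.  With
    ``per_subject_cost_budget`` the cap is on spend, ``N * z * mass <= B``.
    Returns ``(threshold, binding)``.
    """
    if population <= 0:
        raise ValidationError("population size must be positive")
    if budget < 0:
        raise ValidationError("budget must be nonnegative")
    unit = cost if per_subject_cost_budget else 1.0
    if per_subject_cost_budget and cost <= 0:
        raise ValidationError("per-subject-cost budget needs a positive cost z")

    def load(t: float) -> float:
        return population * unit * density.mass_above(t)

    lo, hi = c - h, c + h
    if load(hi) > budget:
        raise ValidationError(
            "budget below current policy load: even the least generous "
            "threshold in the window exceeds the budget"
        )
    unconstrained = optimal_threshold_numeric(curve, density, c, h, cost=cost)
    if load(unconstrained.value) <= budget:
        return unconstrained, False
    # binding: smallest t with load(t) <= budget (load is continuous and
    # nonincreasing in t thanks to partial-bin overlap weighting)
    t_bind = brentq(lambda t: load(t) - budget, lo, hi, xtol=1e-10 * max(h, 1.0))
    grid = np.linspace(t_bind, hi, 501)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        vals = np.asarray(curve.value(grid), float) - cost
    if np.all(vals >= 0):
        return ThresholdResult(value=float(t_bind), flag="budget-binding"), True
    feasible = grid
    scores = [welfare(curve, density, t, upper=hi, cost=cost) for t in feasible]
    best = float(feasible[int(np.argmax(scores))])
    return ThresholdResult(value=best, flag="budget-binding"), True


@dataclass(frozen=True)
class GainsRecord:
    """Welfare-gain accounting for a move from ``c_old`` to ``c_new``."""

    gain_pp: float
    gain_value_per_unit: float | None
    gain_total: float | None
    n_affected: int


def policy_gains(
    curve: EffectCurve,
    density: BinnedDensity,
    data: RDDataset,
    c_new: float,
    c_old: float,
    *,
    outcome_is_pct_of_x: bool = True,
) -> GainsRecord:
    """Expected gains for the newly treated population in [c_new, c_old].

    ``gain_pp`` is the density-weighted mean effect over the interval (bin
    masses renormalized to the interval, so it reads as outcome units per
    newly treated unit).  When the outcome is declared a percentage of the
    running variable (the tipping-study convention), ``gain_value_per_unit``
    monetizes it as ``sum (pi/100) * x * p(x)`` and ``gain_total`` scales by
    the observed count of affected units.
    """
    lo, hi = (c_new, c_old) if c_new <= c_old else (c_old, c_new)
    left = np.maximum(density.edges[:-1], lo)
    right = np.minimum(density.edges[1:], hi)
    frac = np.clip(right - left, 0.0, None) / np.diff(density.edges)
    active = frac > 0
    weights = frac[active] * density.mass[active]
    if lo == hi or weights.sum() == 0:
        return GainsRecord(
            gain_pp=0.0,
            gain_value_per_unit=0.0 if outcome_is_pct_of_x else None,
            gain_total=0.0 if outcome_is_pct_of_x else None,
            n_affected=0,
        )
    weights = weights / weights.sum()
    mids = 0.5 * (left[active] + right[active])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        effects = np.asarray(curve.value(mids), float)
        if curve.complier_share is not None:
            effects = effects * np.asarray(curve.complier_share(mids), float)
    gain_pp = float(np.sum(effects * weights))
    n_affected = int(np.sum((data.x >= lo) & (data.x < hi)))
    if outcome_is_pct_of_x:
        per_unit = float(np.sum(effects / 100.0 * mids * weights))
        total = per_unit * n_affected
    else:
        per_unit = None
        total = None
    return GainsRecord(
        gain_pp=gain_pp,
        gain_value_per_unit=per_unit,
        gain_total=total,
        n_affected=n_affected,
    )


@dataclass(frozen=True)
class PolicyResult:
    """Bundle of thresholds, welfare values, and gains for one analysis."""

    c_star: float
    c_alpha: float | None = None
    c_cost: float | None = None
    c_budget: float | None = None
    welfare_at: dict = field(default_factory=dict)
    gains: GainsRecord | None = None
    boundary_hit: bool = False
    budget_binding: bool = False
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "c_star": self.c_star,
            "c_alpha": self.c_alpha,
            "c_cost": self.c_cost,
            "c_budget": self.c_budget,
            "welfare_at": {str(k): v for k, v in self.welfare_at.items()},
            "boundary_hit": self.boundary_hit,
            "budget_binding": self.budget_binding,
            "diagnostics": self.diagnostics,
        }
        if self.gains is not None:
            out["gains"] = {
                "gain_pp": self.gains.gain_pp,
                "gain_value_per_unit": self.gains.gain_value_per_unit,
                "gain_total": self.gains.gain_total,
                "n_affected": self.gains.n_affected,
            }
        return out
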
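"""Local linear regression at the cutoff: LATE, TED, and the effect curve.

With a rectangular kernel, local linear regression within a bandwidth ``h``
reduces to ordinary least squares of ``y`` on ``(x - c)`` run separately on
each side of the threshold.  The two side fits identify

* the local average treatment effect (LATE) ``pi(c) = alpha1 - alpha0``,
* the treatment-effect derivative (TED) ``pi'(c) = beta1 - beta0``, which
  under policy invariance equals the marginal threshold treatment effect
  (MTTE), and
* the extrapolated effect curve ``pi(x) = (alpha1-alpha0) +
  (beta1-beta0)*(x-c)`` with delta-method pointwise standard errors, valid on
  ``[c-h, c+h]``.

Fuzzy designs add a second pair of side fits on the realized-treatment
indicator; the complier effect is the ratio of the outcome discontinuity to
the compliance discontinuity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
import statsmodels.api as sm

from ._exceptions import (
    EstimationError,
    ExtrapolationWarning,
    WeakIdentificationError,
)
from .data import RDDataset

Side = Literal["below", "above"]

#: Minimum absolute compliance discontinuity accepted for fuzzy ratios.
JUMP_FLOOR = 0.05


@dataclass(frozen=True)
class SideFit:
    """One-sided OLS fit of the outcome on ``(x - c)`` within the bandwidth."""

    alpha: float
    beta: float
    cov: np.ndarray  # 2x2 covariance of (alpha, beta)
    sigma2: float
    n_used: int
    side: Side
    c: float
    h: float

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        """Fitted conditional mean ``alpha + beta*(x - c)``."""
        return self.alpha + self.beta * (np.asarray(x, float) - self.c)

    def predict_var(self, x: np.ndarray | float) -> np.ndarray | float:
        """Variance of the fitted mean at ``x`` from the coefficient covariance."""
        d = np.asarray(x, float) - self.c
        return self.cov[0, 0] + d**2 * self.cov[1, 1] + 2 * d * self.cov[0, 1]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "cov": np.asarray(self.cov).tolist(),
            "sigma2": self.sigma2,
            "n_used": self.n_used,
            "side": self.side,
            "c": self.c,
            "h": self.h,
        }


@dataclass(frozen=True)
class Estimate:
    """A scalar estimate with its standard error."""

    value: float
    se: float
    note: str = ""

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        return (self.value - z * self.se, self.value + z * self.se)


@dataclass(frozen=True)
class EffectCurve:
    """Treatment-effect estimate as a function of the running variable.

    ``value(x)`` and ``se(x)`` are vectorized callables; the estimate is
    trusted only on ``interval`` = [c-h, c+h] and evaluation outside it emits
    an :class:`ExtrapolationWarning`.  ``complier_share`` (fuzzy designs)
    gives the estimated complier density weight used by the welfare
    integrand.
    """

    value: Callable[[np.ndarray], np.ndarray]
    se: Callable[[np.ndarray], np.ndarray]
    interval: tuple[float, float]
    source: Literal["llr", "gpr"]
    design: Literal["sharp", "fuzzy"] = "sharp"
    complier_share: Callable[[np.ndarray], np.ndarray] | None = None

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        self._check_domain(x)
        return self.value(np.asarray(x, float))

    def stderr(self, x: np.ndarray | float) -> np.ndarray | float:
        self._check_domain(x)
        return self.se(np.asarray(x, float))

    def _check_domain(self, x) -> None:
        x = np.asarray(x, float)
        lo, hi = self.interval
        if np.any(x < lo) or np.any(x > hi):
            warnings.warn(
                f"effect curve evaluated outside its validity interval "
                f"[{lo:g}, {hi:g}]",
                ExtrapolationWarning,
                stacklevel=3,
            )


def _window_mask(data: RDDataset, side: Side, h: float) -> np.ndarray:
    # [c-h, c) below; [c, c+h] above — x == c sits on the above side
    if side == "below":
        return (data.x >= data.c - h) & (data.x < data.c)
    return (data.x >= data.c) & (data.x <= data.c + h)


def fit_side(
    data: RDDataset,
    side: Side,
    h: float,
    *,
    outcome: Literal["y", "t"] = "y",
    robust: bool = False,
) -> SideFit:
    """OLS of the outcome on ``(x - c)`` over one side's bandwidth window.

    Parameters
    ----------
    outcome
        ``"y"`` fits the outcome (default); ``"t"`` fits the realized
        treatment indicator (fuzzy designs: a linear probability model for
        the compliance line).
    robust
        Use HC1 heteroskedasticity-robust coefficient covariance instead of
        the classical homoskedastic one.
    """
    if h <= 0:
        raise EstimationError("bandwidth must be positive")
    mask = _window_mask(data, side, h)
    x = data.x[mask]
    if outcome == "t":
        if data.t is None:
            raise EstimationError("dataset has no treatment column to fit")
        resp = data.t[mask]
    else:
        resp = data.y[mask]
    lo, hi = (data.c - h, data.c) if side == "below" else (data.c, data.c + h)
    if len(np.unique(x)) < 2:
        raise EstimationError(
            f"fewer than 2 distinct running-variable values on the {side} side "
            f"within window [{lo:g}, {hi:g})"
        )
    design = sm.add_constant(x - data.c)
    res = sm.OLS(resp, design).fit(cov_type="HC1" if robust else "nonrobust")
    resid = resp - res.fittedvalues
    dof = max(len(x) - 2, 1)
    sigma2 = float(resid @ resid) / dof
    return SideFit(
        alpha=float(res.params[0]),
        beta=float(res.params[1]),
        cov=np.asarray(res.cov_params()),
        sigma2=sigma2,
        n_used=len(x),
        side=side,
        c=data.c,
        h=h,
    )


def fit_both_sides(
    data: RDDataset, h: float, *, outcome: Literal["y", "t"] = "y", robust: bool = False
) -> tuple[SideFit, SideFit]:
    """Convenience: (below, above) fits at the same bandwidth."""
    return (
        fit_side(data, "below", h, outcome=outcome, robust=robust),
        fit_side(data, "above", h, outcome=outcome, robust=robust),
    )


def estimate_late(below: SideFit, above: SideFit) -> Estimate:
    """Sharp LATE: difference of the side intercepts at the threshold."""
    value = above.alpha - below.alpha
    se = float(np.sqrt(above.cov[0, 0] + below.cov[0, 0]))
    return Estimate(value=value, se=se)


def estimate_ted(below: SideFit, above: SideFit) -> Estimate:
    """Treatment-effect derivative: difference of the side slopes."""
    value = above.beta - below.beta
    se = float(np.sqrt(above.cov[1, 1] + below.cov[1, 1]))
    return Estimate(value=value, se=se)


def estimate_mtte(below: SideFit, above: SideFit) -> Estimate:
    """Marginal threshold treatment effect.

    Under policy invariance (potential outcomes mean-independent of the
    implemented threshold given the running variable) the MTTE equals the
    TED, so this returns the TED flagged accordingly.
    """
    ted = estimate_ted(below, above)
    return Estimate(value=ted.value, se=ted.se, note="equals TED under policy invariance")


def effect_curve(below: SideFit, above: SideFit, h: float | None = None) -> EffectCurve:
    """Extrapolated sharp effect curve with delta-method standard errors.

    ``value(x)`` is affine in ``x``; ``se(x)`` expands each side's fitted-mean
    variance through its coefficient covariance and adds the two (the sides
    are fit on disjoint samples and treated as independent).
    """
    if h is None:
        h = below.h
    c = below.c

    def value(x: np.ndarray) -> np.ndarray:
        return above.predict(x) - below.predict(x)

    def se(x: np.ndarray) -> np.ndarray:
        v = above.predict_var(x) + below.predict_var(x)
        return np.sqrt(np.maximum(v, 0.0))

    return EffectCurve(
        value=value, se=se, interval=(c - h, c + h), source="llr", design="sharp"
    )


# ---------------------------------------------------------------------------
# fuzzy designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FuzzyComponents:
    """Side fits on the outcome and on the realized-treatment probability."""

    outcome_below: SideFit
    outcome_above: SideFit
    treatment_below: SideFit
    treatment_above: SideFit

    @property
    def compliance_jump(self) -> float:
        """Estimated complier share at the threshold, f1(c) - f0(c)."""
        return self.treatment_above.alpha - self.treatment_below.alpha

    @property
    def compliance_slopes(self) -> tuple[float, float]:
        return (self.treatment_below.beta, self.treatment_above.beta)

    @property
    def compliance_jump_var(self) -> float:
        return float(self.treatment_above.cov[0, 0] + self.treatment_below.cov[0, 0])

    def __post_init__(self) -> None:
        jump = self.compliance_jump
        if not -1.0 - 1e-9 <= jump <= 1.0 + 1e-9:
            raise EstimationError(
                f"estimated compliance jump {jump:.3f} outside [-1, 1]"
            )


def fit_fuzzy(data: RDDataset, h: float, *, robust: bool = False) -> FuzzyComponents:
    """Fit the four one-sided regressions a fuzzy design needs."""
    if data.t is None:
        raise EstimationError("fuzzy estimation requires a treatment column t")
    ob, oa = fit_both_sides(data, h, outcome="y", robust=robust)
    tb, ta = fit_both_sides(data, h, outcome="t", robust=robust)
    return FuzzyComponents(
        outcome_below=ob, outcome_above=oa, treatment_below=tb, treatment_above=ta
    )


def fuzzy_late(fc: FuzzyComponents, *, jump_floor: float = JUMP_FLOOR) -> Estimate:
    """Complier LATE: outcome discontinuity over compliance discontinuity.

    The standard error comes from the delta method for the ratio, with the
    numerator and denominator treated as independent.
    """
    jump = fc.compliance_jump
    if abs(jump) < jump_floor:
        raise WeakIdentificationError(
            f"compliance discontinuity {jump:.4f} below floor {jump_floor}: "
            "the treatment probability barely moves at the threshold "
            "(strong-monotonicity assumption violated in sample)"
        )
    num = estimate_late(fc.outcome_below, fc.outcome_above)
    value = num.value / jump
    var = num.se**2 / jump**2 + value**2 * fc.compliance_jump_var / jump**2
    return Estimate(value=value, se=float(np.sqrt(var)))


def fuzzy_ted(fc: FuzzyComponents, pi_f_at_c: float | None = None) -> Estimate:
    """Complier treatment-effect derivative at the threshold.

    ``(beta1 - beta0)/p_f(c) - p_f'(c) * pi_f(c) / p_f(c)`` where ``p_f`` is
    the complier share and ``p_f'`` its slope discontinuity.  Reduces to the
    sharp TED when ``p_f(c)=1`` and ``p_f'(c)=0``.
    """
    p = fc.compliance_jump
    if p <= 0:
        raise WeakIdentificationError(
            f"compliance jump {p:.4f} must be positive for the fuzzy TED"
        )
    if pi_f_at_c is None:
        pi_f_at_c = fuzzy_late(fc).value
    slope_b, slope_a = fc.compliance_slopes
    p_prime = slope_a - slope_b
    outcome_ted = estimate_ted(fc.outcome_below, fc.outcome_above)
    value = outcome_ted.value / p - p_prime * pi_f_at_c / p
    # first-order SE, holding the plug-in pi_f fixed
    se = outcome_ted.se / p
    return Estimate(value=value, se=float(se))


def fuzzy_effect_curve(
    fc: FuzzyComponents, h: float | None = None, *, jump_floor: float = JUMP_FLOOR
) -> EffectCurve:
    """Plug-in complier effect curve on [c-h, c+h].

    ``pi_f(x) = (mu1(x) - mu0(x)) / (f1(x) - f0(x))`` from the one-sided
    outcome and treatment-probability lines, with pointwise delta-method
    standard errors.  The compliance denominator must stay at or above
    ``jump_floor`` throughout the interval.
    """
    if h is None:
        h = fc.outcome_below.h
    c = fc.outcome_below.c
    lo, hi = c - h, c + h

    def denom(x: np.ndarray) -> np.ndarray:
        return np.asarray(
            fc.treatment_above.predict(x) - fc.treatment_below.predict(x), float
        )

    grid = np.linspace(lo, hi, 501)
    dvals = denom(grid)
    bad = dvals < jump_floor
    if np.any(bad):
        x0 = float(grid[np.argmax(bad)])
        raise WeakIdentificationError(
            f"estimated complier share falls below {jump_floor} within the "
            f"bandwidth, first at x = {x0:.4g}"
        )

    def value(x: np.ndarray) -> np.ndarray:
        num = fc.outcome_above.predict(x) - fc.outcome_below.predict(x)
        return num / denom(x)

    def se(x: np.ndarray) -> np.ndarray:
        num = fc.outcome_above.predict(x) - fc.outcome_below.predict(x)
        den = denom(x)
        var_num = fc.outcome_above.predict_var(x) + fc.outcome_below.predict_var(x)
        var_den = fc.treatment_above.predict_var(x) + fc.treatment_below.predict_var(x)
        var = var_num / den**2 + num**2 * var_den / den**4
        return np.sqrt(np.maximum(var, 0.0))

    return EffectCurve(
        value=value,
        se=se,
        interval=(lo, hi),
        source="llr",
        design="fuzzy",
        complier_share=denom,
    )
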
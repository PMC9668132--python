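"""High-level analysis: from a dataset to a full policy report.

Ties the modules together in the order a user would: bandwidth selection,
one-sided fits, effect-curve construction (local-linear or GP), density
estimation, and the family of threshold solvers.  The treated-below
convention is handled here by mirroring the data about the cutoff, running
every solver in the treated-above convention, and mapping returned
thresholds back — so the sign logic lives in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from ._exceptions import ValidationError
from .bandwidth import ik_bandwidth
from .data import RDDataset
from .gp import fit_gp_side, gp_effect_curve
from .llr import (
    EffectCurve,
    Estimate,
    effect_curve,
    estimate_late,
    estimate_mtte,
    estimate_ted,
    fit_both_sides,
    fit_fuzzy,
    fuzzy_effect_curve,
    fuzzy_late,
    fuzzy_ted,
)
from .optimize import (
    DEFAULT_BIN_WIDTH,
    BinnedDensity,
    PolicyResult,
    budget_constrained_threshold,
    classify_case,
    conservative_threshold,
    estimate_density,
    optimal_threshold_closed_form,
    optimal_threshold_numeric,
    policy_gains,
    welfare,
)

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the pipeline needs beyond the data itself."""

    bandwidth: float | None = None
    estimator: Literal["llr", "gpr"] = "llr"
    alpha: float = 0.05
    cost: float = 0.0
    budget: float | None = None
    population: float | None = None
    bin_width: float = DEFAULT_BIN_WIDTH
    outcome_is_pct_of_x: bool = False
    robust: bool = False
    gp_hyper: str = "default"  # or "cv"
    gp_kernel: Literal["sqexp", "laplace"] = "sqexp"
    seed: int = 0


def analyze(data: RDDataset, config: AnalysisConfig = AnalysisConfig()) -> dict:
    """Run the full threshold-optimization pipeline and return a JSON-able
    report (including a :class:`PolicyResult` under ``"policy"``).
    """
    mirrored = not data.treated_above
    work = data.mirrored() if mirrored else data
    back = (lambda v: None if v is None else -v) if mirrored else (lambda v: v)

    h = config.bandwidth
    if h is None:
        h = ik_bandwidth(work)
    h = float(h)
    if h <= 0:
        raise ValidationError("bandwidth must be positive")
    c = work.c

    density = estimate_density(work, bin_width=config.bin_width)

    below, above = fit_both_sides(work, h, robust=config.robust)
    case = classify_case(below, above)

    if work.design == "fuzzy":
        if config.estimator == "gpr":
            raise ValidationError(
                "GP estimation is implemented for sharp designs only"
            )
        fc = fit_fuzzy(work, h, robust=config.robust)
        late = fuzzy_late(fc)
        ted = fuzzy_ted(fc, late.value)
        curve: EffectCurve = fuzzy_effect_curve(fc, h)
        closed = None
    elif config.estimator == "gpr":
        gp_below = fit_gp_side(
            work, "below", h, config.gp_hyper, kernel=config.gp_kernel,
            cv_seed=config.seed,
        )
        gp_above = fit_gp_side(
            work, "above", h, config.gp_hyper, kernel=config.gp_kernel,
            cv_seed=config.seed,
        )
        curve = gp_effect_curve(gp_below, gp_above, c, h)
        late = Estimate(
            value=float(curve.value(np.atleast_1d(c))[0]),
            se=float(curve.se(np.atleast_1d(c))[0]),
        )
        ted = estimate_ted(below, above)  # linear fits still report the TED
        closed = None
    else:
        late = estimate_late(below, above)
        ted = estimate_ted(below, above)
        curve = effect_curve(below, above, h)
        closed = optimal_threshold_closed_form(below, above, c, h, cost=config.cost)

    star = optimal_threshold_numeric(curve, density, c, h, cost=0.0)
    cons = conservative_threshold(curve, config.alpha, c, h, c_star=star.value)
    c_cost = (
        optimal_threshold_numeric(curve, density, c, h, cost=config.cost)
        if config.cost
        else None
    )
    c_budget = None
    budget_binding = False
    if config.budget is not None:
        population = config.population if config.population is not None else work.n
        c_budget_res, budget_binding = budget_constrained_threshold(
            curve, density, c, h, population, config.budget, cost=config.cost
        )
        c_budget = c_budget_res.value

    gains = policy_gains(
        curve, density, work, star.value, c,
        outcome_is_pct_of_x=config.outcome_is_pct_of_x,
    )
    welfare_at = {
        "c": welfare(curve, density, c, upper=c + h),
        "c_star": welfare(curve, density, star.value, upper=c + h),
        "c_alpha": welfare(curve, density, cons.value, upper=c + h),
    }

    policy = PolicyResult(
        c_star=back(star.value),
        c_alpha=back(cons.value),
        c_cost=back(c_cost.value) if c_cost is not None else None,
        c_budget=back(c_budget),
        welfare_at=welfare_at,
        gains=gains,
        boundary_hit=star.boundary_hit,
        budget_binding=budget_binding,
        diagnostics={
            "case": case,
            "conservative_flag": cons.flag,
            "mirrored": mirrored,
        },
    )

    report = {
        "schema_version": SCHEMA_VERSION,
        "design": data.design,
        "estimator": config.estimator,
        "n": data.n,
        "threshold": data.c,
        "treated_above": data.treated_above,
        "bandwidth": h,
        "bandwidth_source": "ik" if config.bandwidth is None else "user",
        "case": case,
        "late": {"value": late.value, "se": late.se},
        "ted": {"value": ted.value, "se": ted.se},
        "mtte_note": "equals TED under policy invariance",
        "fits": {"below": below.to_dict(), "above": above.to_dict()},
        "closed_form_c_star": back(closed.value) if closed is not None else None,
        "policy": policy.to_dict(),
        "defaults_used": {
            "alpha": config.alpha,
            "cost": config.cost,
            "bin_width": config.bin_width,
            "robust": config.robust,
            "gp_hyper": config.gp_hyper if config.estimator == "gpr" else None,
            "gp_kernel": config.gp_kernel if config.estimator == "gpr" else None,
        },
    }
    report["_policy_result"] = policy  # non-serialized convenience handle
    return report


def mtte(data: RDDataset, h: float, **kwargs) -> Estimate:
    """Marginal threshold treatment effect at the current cutoff."""
    below, above = fit_both_sides(data, h, **kwargs)
    return estimate_mtte(below, above)
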
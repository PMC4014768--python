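"""Benchmark dose (BMD) and profile-likelihood lower bound (BMDL).

The BMD is the dose producing the benchmark response (BMR): 10% extra risk
for dichotomous and cancer endpoints, a change in the mean equal to one
control-group SD for continuous endpoints.  The control SD is the
model-estimated (not observed) control SD: sigma-hat in constant-variance
mode, sqrt(alpha |mu(0)|^rho) in modeled-variance mode.

The BMDL is the one-sided 95% profile-likelihood lower confidence limit: the
smallest dose D below the BMD at which the likelihood, re-maximized over all
remaining parameters with the BMD constrained to D, stays within
chi2_1(0.90)/2 = 1.35277 of the unconstrained maximum (profile deviance
2.70554).  The constraint is imposed exactly by solving one slope-type
parameter of each model family in closed form from the fixed BMD.

Warnings follow the standard batch-reporting rules: a BMD or BMDL more than
3x below the lowest non-zero dose flags low-dose extrapolation, and a
BMD/BMDL ratio above 5 flags an unstable lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, special, stats

from .datasets import DoseResponseDataset
from .fitting import DoseResponseResults, _loglik_full, _LL_BAD
from .models import ContinuousSpec

#: BMD search ceiling: no root beyond 100x the highest tested dose
_SEARCH_CEILING = 100.0
#: BMDL search floor relative to the highest tested dose
_SEARCH_FLOOR = 1e-8

WARN_BMD_EXTRAP = "bmd_extrap_gt3x"
WARN_BMDL_EXTRAP = "bmdl_extrap_gt3x"
WARN_RATIO_GT5 = "ratio_gt5"


@dataclass
class BmdResult:
    """BMD and BMDL for one fitted model at a stated BMR."""

    bmr_type: str  # extra_risk | one_control_sd
    bmr_value: float
    bmd: Optional[float]
    bmdl: Optional[float]
    confidence: float = 0.95
    warnings: set = field(default_factory=set)
    #: profile deviance 2*(LLmax - LL_profile) at the returned BMDL
    profile_deviance: Optional[float] = None

    @property
    def ratio(self) -> Optional[float]:
        if self.bmd is None or self.bmdl is None or self.bmdl <= 0:
            return None
        return self.bmd / self.bmdl


# ======================================================================
# BMD (point estimate)


def _bmr_for(fit: DoseResponseResults, bmr_value: Optional[float]) -> tuple:
    """(bmr_type, bmr_value) appropriate for the fitted data type."""
    if fit.dataset.is_dichotomous:
        return "extra_risk", (fit.config.bmr_dichotomous if bmr_value is None else bmr_value)
    return "one_control_sd", (fit.config.bmr_continuous_sd if bmr_value is None else bmr_value)


def compute_bmd(fit: DoseResponseResults, bmr_value: Optional[float] = None) -> Optional[float]:
    """Dose at the benchmark response; None when not estimable.

    Closed forms are used where the family admits them; otherwise the unique
    root is bracketed on a dose grid and polished with Brent's method to
    relative tolerance 1e-8.  No root in (0, 100 x max dose] => not estimable.
    """
    _, bmr = _bmr_for(fit, bmr_value)
    spec, params = fit.spec, fit.params
    dmax = fit.dataset.max_dose

    if fit.dataset.is_dichotomous:
        target_arg = bmr

        def excess(D):
            return float(spec.extra_risk(params, np.array([D]))[0]) - bmr

        f = excess
    else:
        sigma0 = spec.sigma0(params)
        if not np.isfinite(sigma0) or sigma0 <= 0:
            return None
        target_arg = bmr * sigma0
        mu0 = spec.background(params)

        def change(D):
            return abs(float(spec.predict(params, np.array([D]))[0]) - mu0) - target_arg

        f = change

    closed = spec.bmd_closed(params, target_arg)
    if closed is not None and np.isfinite(closed) and 0 < closed <= _SEARCH_CEILING * dmax:
        return float(closed)
    if closed is not None:
        return None  # closed form exists but lies outside the search window

    # numeric: first sign change on a log-spaced grid, then Brent
    grid = np.geomspace(dmax * _SEARCH_FLOOR, dmax * _SEARCH_CEILING, 600)
    vals = np.array([f(D) for D in grid])
    if vals[0] >= 0:
        return float(grid[0]) if vals[0] == 0 else None  # degenerate
    crossings = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
    if crossings.size == 0:
        return None
    i = int(crossings[0])
    root = optimize.brentq(f, grid[i], grid[i + 1], rtol=1e-10, xtol=grid[i] * 1e-10)
    return float(root)


# ======================================================================
# Profile likelihood


def profile_loglik(fit: DoseResponseResults, D: float,
                   bmr_value: Optional[float] = None,
                   warm=None) -> tuple:
    """Log-likelihood maximized over nuisance parameters with BMD fixed at D.

    Returns ``(loglik, rest_solution)``; the solution can warm-start the next
    profile point.
    """
    _, bmr = _bmr_for(fit, bmr_value)
    spec, ds = fit.spec, fit.dataset
    idx = spec.profile_param
    lo, hi = spec.bounds()
    rest_lo = np.delete(lo, idx)
    rest_hi = np.delete(hi, idx)
    mle_rest = np.delete(fit.params, idx)

    def nll(rest):
        full = spec.profile_fill(np.asarray(rest, float), D, bmr)
        if full is None:
            return 1e10
        ll = _loglik_full(spec, full, ds)
        return -ll if np.isfinite(ll) else -_LL_BAD

    dim = len(mle_rest)
    if dim == 0:
        return -nll(np.empty(0)), np.empty(0)

    if dim == 1 and np.isfinite(rest_lo[0]) and np.isfinite(rest_hi[0]):
        res = optimize.minimize_scalar(
            lambda x: nll([x]), bounds=(rest_lo[0], rest_hi[0]),
            method="bounded", options={"xatol": 1e-10},
        )
        best_x, best_f = np.array([res.x]), float(res.fun)
        for cand in ([warm, mle_rest] if warm is not None else [mle_rest]):
            fc = nll(cand)
            if fc < best_f:
                best_x, best_f = np.asarray(cand, float), fc
        return -best_f, best_x

    bounds = list(zip(rest_lo, rest_hi))
    starts = [s for s in (warm, mle_rest) if s is not None]
    best_x, best_f = None, np.inf
    for x0 in starts:
        x0 = np.minimum(np.maximum(np.asarray(x0, float), rest_lo), rest_hi)
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead", bounds=bounds,
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400 * (dim + 1)},
        )
        if res.fun < best_f:
            best_x, best_f = np.asarray(res.x), float(res.fun)
    return -best_f, best_x


def compute_bmdl(fit: DoseResponseResults,
                 bmd: Optional[float] = None,
                 bmr_value: Optional[float] = None,
                 level: Optional[float] = None) -> tuple:
    """One-sided profile-likelihood lower bound on the BMD.

    Returns ``(bmdl, profile_deviance_at_bmdl)``; ``(None, None)`` when the
    profile never crosses the deviance cutoff above the search floor
    (flat likelihood), which downstream classification treats as Questionable.
    """
    if bmd is None:
        bmd = compute_bmd(fit, bmr_value)
    if bmd is None:
        return None, None
    level = fit.config.bmdl_level if level is None else level
    # one-sided bound via the chi2_1 quantile at confidence 2*level - 1
    cutoff = float(stats.chi2.ppf(2 * level - 1, 1))

    ll_at_bmd, warm = profile_loglik(fit, bmd, bmr_value)
    llmax = max(fit.loglik, ll_at_bmd)
    ll_crit = llmax - cutoff / 2.0

    floor = fit.dataset.max_dose * _SEARCH_FLOOR
    if bmd <= floor:
        return None, None

    cache = {"warm": warm}

    def gap(lnD):
        ll, sol = profile_loglik(fit, float(np.exp(lnD)), bmr_value, warm=cache["warm"])
        cache["warm"] = sol
        return ll - ll_crit

    ln_hi = np.log(bmd)
    g_hi = cutoff / 2.0  # gap at the BMD itself
    step = 0.05
    ln_lo = ln_hi
    g_lo = g_hi
    ln_floor = np.log(floor)
    while ln_lo > ln_floor:
        ln_next = max(ln_lo - step, ln_floor)
        g_next = gap(ln_next)
        if g_next < 0:
            ln_hi, g_hi = ln_lo, g_lo
            ln_lo, g_lo = ln_next, g_next
            break
        ln_hi, g_hi = ln_next, g_next
        ln_lo, g_lo = ln_next, g_next
        step *= 1.8
    else:
        return None, None
    if g_lo >= 0:
        return None, None

    root = optimize.brentq(gap, ln_lo, ln_hi, xtol=1e-6)
    bmdl = float(np.exp(root))
    ll_at_bmdl, _ = profile_loglik(fit, bmdl, bmr_value, warm=cache["warm"])
    dev = 2.0 * (llmax - ll_at_bmdl)
    return bmdl, float(dev)


# ======================================================================
# Assembled result with warnings


def compute_bmd_result(fit: DoseResponseResults,
                       bmr_value: Optional[float] = None,
                       level: Optional[float] = None) -> BmdResult:
    """BMD + BMDL + warning flags for one fitted model."""
    bmr_type, bmr = _bmr_for(fit, bmr_value)
    level = fit.config.bmdl_level if level is None else level
    bmd = compute_bmd(fit, bmr) if fit.converged else None
    bmdl, dev = compute_bmdl(fit, bmd, bmr, level) if bmd is not None else (None, None)
    result = BmdResult(
        bmr_type=bmr_type, bmr_value=bmr, bmd=bmd, bmdl=bmdl,
        confidence=level, profile_deviance=dev,
    )
    return attach_warnings(result, fit.dataset,
                           extrap_factor=fit.config.rules.extrap_factor,
                           ratio_warn=fit.config.rules.ratio_warn)


def attach_warnings(result: BmdResult, dataset: DoseResponseDataset,
                    extrap_factor: float = 3.0,
                    ratio_warn: float = 5.0) -> BmdResult:
    """Set the non-fatal warning flags on a computed BMD result."""
    low = dataset.lowest_nonzero_dose
    if result.bmd is not None and np.isfinite(low) and result.bmd < low / extrap_factor:
        result.warnings.add(WARN_BMD_EXTRAP)
    if result.bmdl is not None and np.isfinite(low) and result.bmdl < low / extrap_factor:
        result.warnings.add(WARN_BMDL_EXTRAP)
    if result.ratio is not None and result.ratio > ratio_warn:
        result.warnings.add(WARN_RATIO_GT5)
    return result


# ======================================================================
# Rationale constant for the 1-SD continuous BMR


def one_sd_excess_fraction(tail: float = 0.02) -> float:
    """Excess fraction beyond the control ``tail`` percentile after a 1-SD
    mean shift, for a normally distributed response.

    With the control tail at the 2nd percentile this evaluates to
    Phi(1 - z_0.98) - 0.02 = 0.126, the calculation behind the rule of thumb
    that a 1-SD change in the mean corresponds to roughly 10% excess risk.
    """
    z = special.ndtri(1.0 - tail)
    return float(special.ndtr(1.0 - z) - tail)
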
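"""Maximum-likelihood fitting and fit diagnostics.

Binomial likelihood for dichotomous data (binomial-coefficient constants
omitted, consistently across models, so the saturated log-likelihood has the
familiar ``sum y ln p + (n-y) ln(1-p)`` form); full-constant normal likelihood
for continuous summary data, so the fitted model's log-likelihood is directly
comparable with the saturated-model hierarchy used by the likelihood-ratio
variance and mean-fit tests:

* A1 - group means, constant variance
* A2 - group means, per-group variances (the fully saturated model)
* A3 - group means, power-of-the-mean variance model (A1 when the fitted
  model uses constant variance)
* R  - single mean, constant variance

Test 1 (A2 vs R) asks whether there is any response at all; Test 2 (A2 vs A1)
tests variance homogeneity; Test 3 (A2 vs A3) tests adequacy of the modeled
variance; Test 4 (A3 vs fitted model) tests the mean model.

Optimization is deterministic: a ladder of moment-style starting values per
model family, Nelder-Mead within bounds, then an L-BFGS-B polish; the best
final likelihood wins, ties broken by first found.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import RunConfig
from .datasets import DoseResponseDataset
from .models import ContinuousSpec, ModelSpec, detect_direction, model_suite

_P_CLIP = 1e-8
_LL_BAD = -1e12
_LOG2PI = float(np.log(2.0 * np.pi))


# ======================================================================
# Log-likelihoods


def loglik_dichotomous(spec: ModelSpec, params, dataset: DoseResponseDataset) -> float:
    """Binomial log-likelihood (constants omitted); always finite."""
    p = spec.predict(np.asarray(params, float), dataset.doses)
    if not np.all(np.isfinite(p)):
        return _LL_BAD
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    y = dataset.incidence
    n = dataset.n
    return float(np.sum(y * np.log(p) + (n - y) * np.log1p(-p)))


def _loglik_normal_suffstats(n, m, s, mu, var) -> float:
    """Normal log-likelihood from per-group sufficient statistics."""
    if np.any(~np.isfinite(mu)) or np.any(~np.isfinite(var)) or np.any(var <= 0):
        return _LL_BAD
    rss = (n - 1) * s**2 + n * (m - mu) ** 2
    ll = np.sum(-(n / 2.0) * (_LOG2PI + np.log(var)) - rss / (2.0 * var))
    return float(ll) if np.isfinite(ll) else _LL_BAD


def loglik_continuous(
    spec: ContinuousSpec,
    mean_params,
    variance_params,
    dataset: DoseResponseDataset,
) -> float:
    """Normal log-likelihood (full constants) from summary statistics.

    ``variance_params`` is ``(ln_sigma2,)`` in constant mode or
    ``(ln_alpha, rho)`` in modeled mode, Var(d) = alpha * |mu(d)|^rho.
    """
    params = np.concatenate([np.asarray(mean_params, float), np.asarray(variance_params, float)])
    return _loglik_full(spec, params, dataset)


def _loglik_full(spec: ModelSpec, params, dataset: DoseResponseDataset) -> float:
    """Log-likelihood at a full parameter vector, dispatching on data type."""
    if dataset.is_dichotomous:
        return loglik_dichotomous(spec, params, dataset)
    params = np.asarray(params, float)
    mu = spec.predict(params, dataset.doses)
    if not np.all(np.isfinite(mu)):
        return _LL_BAD
    var = spec.group_variances(params, mu)
    return _loglik_normal_suffstats(
        dataset.n.astype(float), dataset.mean, dataset.sd, mu, var
    )


def saturated_loglik_dichotomous(dataset: DoseResponseDataset) -> float:
    """Log-likelihood with p_i fixed at the observed proportions."""
    y = dataset.incidence.astype(float)
    n = dataset.n.astype(float)
    p = np.clip(y / n, _P_CLIP, 1 - _P_CLIP)
    return float(np.sum(y * np.log(p) + (n - y) * np.log1p(-p)))


# ======================================================================
# Continuous saturated-model hierarchy

_VAR_FLOOR = 1e-12


def continuous_anova(dataset: DoseResponseDataset) -> dict:
    """Closed-form (A1, A2, R) and profiled (A3) saturated log-likelihoods.

    Returns a dict with log-likelihoods and parameter counts for each model.
    """
    n = dataset.n.astype(float)
    m = dataset.mean
    s = dataset.sd
    g = dataset.n_groups
    N = float(np.sum(n))
    within = (n - 1) * s**2

    # A1: mu_i = m_i, common variance (MLE: pooled within-group SS / N)
    var1 = max(float(np.sum(within) / N), _VAR_FLOOR)
    ll_a1 = _loglik_normal_suffstats(n, m, s, m, np.full(g, var1))

    # A2: mu_i = m_i, per-group variances sigma_i^2 = (n_i - 1) s_i^2 / n_i
    var2 = np.maximum(within / n, _VAR_FLOOR)
    ll_a2 = _loglik_normal_suffstats(n, m, s, m, var2)

    # A3: mu_i = m_i, Var = alpha |m_i|^rho; alpha has a closed form given rho
    absm = np.maximum(np.abs(m), 1e-8)
    lnm = np.log(absm)

    def nll_a3(rho):
        alpha = max(float(np.sum(within / absm**rho) / N), _VAR_FLOOR)
        return -(-N / 2.0 * (_LOG2PI + np.log(alpha)) - rho / 2.0 * float(np.sum(n * lnm)) - N / 2.0)

    res = optimize.minimize_scalar(nll_a3, bounds=(-18.0, 18.0), method="bounded",
                                   options={"xatol": 1e-10})
    rho_hat = float(res.x)
    candidates = [rho_hat, 0.0]
    ll_a3, rho_best = max((-nll_a3(r), r) for r in candidates)

    # R: single mean, single variance
    mu_r = float(np.sum(n * m) / N)
    var_r = max(float((np.sum(within) + np.sum(n * (m - mu_r) ** 2)) / N), _VAR_FLOOR)
    ll_r = _loglik_normal_suffstats(n, m, s, np.full(g, mu_r), np.full(g, var_r))

    return {
        "A1": (ll_a1, g + 1),
        "A2": (ll_a2, 2 * g),
        "A3": (ll_a3, g + 2),
        "R": (ll_r, 2),
        "rho_a3": rho_best,
    }


def _lr_pvalue(ll_general, ll_restricted, df):
    if df < 1:
        return None
    stat = max(2.0 * (ll_general - ll_restricted), 0.0)
    return float(stats.chi2.sf(stat, df))


def tests_continuous(dataset: DoseResponseDataset, fit: "DoseResponseResults") -> dict:
    """Likelihood-ratio tests 1-4 for a continuous fit (see module docstring)."""
    an = continuous_anova(dataset)
    g = dataset.n_groups
    ll_a1, k_a1 = an["A1"]
    ll_a2, k_a2 = an["A2"]
    ll_a3, k_a3 = an["A3"]
    ll_r, k_r = an["R"]
    out = {
        "test1_p": _lr_pvalue(ll_a2, ll_r, k_a2 - k_r),
        "test2_p": _lr_pvalue(ll_a2, ll_a1, k_a2 - k_a1),
        "test3_p": _lr_pvalue(ll_a2, ll_a3, k_a2 - k_a3),
    }
    if fit is not None:
        spec = fit.spec
        if spec.variance_mode == "constant":
            ll_sat = ll_a1
        else:
            ll_sat = ll_a3
        df4 = g - spec.n_mean_params
        out["test4_p"] = _lr_pvalue(ll_sat, fit.loglik, df4) if df4 >= 1 else None
    return out


# ======================================================================
# Goodness of fit (dichotomous)


def gof_dichotomous(fit: "DoseResponseResults", dataset: DoseResponseDataset):
    """Pearson chi-squared GOF p-value; None when residual df < 1."""
    p_hat = np.clip(fit.predicted, _P_CLIP, 1 - _P_CLIP)
    n = dataset.n.astype(float)
    y = dataset.incidence.astype(float)
    var = np.maximum(n * p_hat * (1 - p_hat), 1e-8)
    chi2 = float(np.sum((y - n * p_hat) ** 2 / var))
    df = dataset.n_groups - fit.n_params
    if df < 1:
        return None, chi2, df
    return float(stats.chi2.sf(chi2, df)), chi2, df


# ======================================================================
# Results container


@dataclass
class DoseResponseResults:
    """Maximum-likelihood fit of one dose-response model.

    Carries the estimates and diagnostics; BMD/BMDL computations hang off
    :meth:`bmd`, :meth:`bmdl` and :meth:`bmd_result`.
    """

    spec: ModelSpec
    dataset: DoseResponseDataset
    params: np.ndarray
    loglik: float
    converged: bool
    config: RunConfig = field(default_factory=RunConfig, repr=False)
    gof_pvalue: Optional[float] = None
    gof_stat: Optional[float] = None
    gof_df: Optional[int] = None
    tests: Optional[dict] = None
    scaled_residuals: Optional[np.ndarray] = None

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def predicted(self) -> np.ndarray:
        return self.spec.predict(self.params, self.dataset.doses)

    def predict(self, doses) -> np.ndarray:
        """Predicted probability / mean at arbitrary doses (never clipped)."""
        return self.spec.predict(self.params, np.asarray(doses, float))

    # -- BMD interface (delegates to the bmd engine) --------------------
    def bmd(self, bmr_value: Optional[float] = None):
        from . import bmd as _bmd

        return _bmd.compute_bmd(self, bmr_value=bmr_value)

    def bmdl(self, bmr_value: Optional[float] = None, level: Optional[float] = None):
        from . import bmd as _bmd

        res = _bmd.compute_bmd_result(self, bmr_value=bmr_value, level=level)
        return res.bmdl

    def bmd_result(self, bmr_value: Optional[float] = None, level: Optional[float] = None):
        from . import bmd as _bmd

        return _bmd.compute_bmd_result(self, bmr_value=bmr_value, level=level)

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary table."""
        lines = [
            f"Model: {self.spec.label}   data: {self.dataset.dataset_id} ({self.dataset.dtype})",
            f"converged: {self.converged}   log-likelihood: {self.loglik:.4f}   AIC: {self.aic:.4f}",
        ]
        if self.gof_pvalue is not None:
            lines.append(f"goodness of fit: chi2 = {self.gof_stat:.4f}, df = {self.gof_df}, p = {self.gof_pvalue:.4f}")
        if self.tests:
            pretty = ", ".join(
                f"{k.replace('_p', '')} p = {v:.4f}" if v is not None else f"{k.replace('_p', '')} n/a"
                for k, v in self.tests.items()
            )
            lines.append(f"variance/mean tests: {pretty}")
        lines.append("parameters:")
        for name, val in zip(self.spec.param_names, self.params):
            lines.append(f"  {name:>10s} = {val: .6g}")
        if self.scaled_residuals is not None:
            resid = ", ".join(f"{r: .3f}" for r in self.scaled_residuals)
            lines.append(f"scaled residuals: [{resid}]")
        return "\n".join(lines)

    def plot(self, ax=None, n_points: int = 200):
        """Plot the fitted curve over the observed group summaries."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ds = self.dataset
        grid = np.linspace(0, ds.max_dose, n_points)
        ax.plot(grid, self.predict(grid), "-", label=self.spec.label)
        if ds.is_dichotomous:
            obs = ds.incidence / ds.n
            ax.plot(ds.doses, obs, "o", color="k", label="observed")
            ax.set_ylabel("proportion affected")
        else:
            ax.errorbar(ds.doses, ds.mean, yerr=ds.sd / np.sqrt(ds.n), fmt="o",
                        color="k", label="observed")
            ax.set_ylabel("response mean")
        ax.set_xlabel(f"dose {ds.dose_units}".rstrip())
        ax.legend()
        return ax


# ======================================================================
# The model object


class DoseResponseModel:
    """A dose-response model bound to a dataset, fit by maximum likelihood.

    Examples
    --------
    >>> from bmdbatch import DoseResponseDataset, DoseResponseModel
    >>> from bmdbatch.models import Multistage
    >>> ds = DoseResponseDataset("ex", "dichotomous", [0, 10, 100],
    ...                          [10, 10, 10], incidence=[0, 2, 8])
    >>> res = DoseResponseModel(ds, Multistage(degree=2)).fit()
    >>> res.converged
    True
    """

    def __init__(self, dataset: DoseResponseDataset, spec: ModelSpec,
                 config: Optional[RunConfig] = None):
        self.dataset = dataset
        self.config = config or RunConfig()
        self.spec = spec.copy()
        if isinstance(self.spec, ContinuousSpec):
            override = self.config.direction_override.get(dataset.dataset_id)
            self.spec.direction = override if override else detect_direction(dataset)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ModelSpec,
                       dataset_id: str = "df", dtype: Optional[str] = None,
                       config: Optional[RunConfig] = None) -> "DoseResponseModel":
        """Build from a long-format DataFrame (columns dose, n, and either
        incidence or mean/sd)."""
        dtype = dtype or spec.dtype
        kwargs = dict(
            dataset_id=dataset_id,
            dtype=dtype,
            doses=df["dose"].to_numpy(float),
            n=df["n"].to_numpy(),
        )
        if "incidence" in df.columns and df["incidence"].notna().all():
            kwargs["incidence"] = df["incidence"].to_numpy()
        else:
            kwargs["mean"] = df["mean"].to_numpy(float)
            kwargs["sd"] = df["sd"].to_numpy(float)
        return cls(DoseResponseDataset(**kwargs), spec, config=config)

    # ------------------------------------------------------------------
    def loglik(self, params) -> float:
        return _loglik_full(self.spec, params, self.dataset)

    def predict(self, params, doses=None) -> np.ndarray:
        doses = self.dataset.doses if doses is None else np.asarray(doses, float)
        return self.spec.predict(np.asarray(params, float), doses)

    def fit(self) -> DoseResponseResults:
        """Maximize the likelihood from the deterministic start ladder."""
        spec, ds, cfg = self.spec, self.dataset, self.config
        lo, hi = spec.bounds()
        bounds = list(zip(lo, hi))

        def nll(x):
            return -_loglik_full(spec, x, ds)

        best_x, best_f, any_success = None, np.inf, False
        starts = spec.starts(ds)[: max(cfg.optimizer_starts, 1) * 3]
        for x0 in starts:
            x0 = np.minimum(np.maximum(np.asarray(x0, float), lo), hi)
            try:
                res = optimize.minimize(
                    nll, x0, method="Nelder-Mead", bounds=bounds,
                    options={"xatol": cfg.optimizer_tol ** 0.5,
                             "fatol": cfg.optimizer_tol,
                             "maxiter": 200 * (len(x0) + 1),
                             "adaptive": len(x0) > 4},
                )
            except (ValueError, FloatingPointError):  # pragma: no cover
                continue
            if res.fun < best_f - 1e-12:
                best_x, best_f = np.asarray(res.x), float(res.fun)
                any_success = res.success or any_success
            elif best_x is None:
                best_x, best_f = np.asarray(res.x), float(res.fun)

        converged = False
        if best_x is not None and best_f < -_LL_BAD / 2:
            # polish with a gradient method, keep whichever is better
            try:
                lb = [None if not np.isfinite(a) else a for a in lo]
                ub = [None if not np.isfinite(b) else b for b in hi]
                pol = optimize.minimize(nll, best_x, method="L-BFGS-B",
                                        bounds=list(zip(lb, ub)))
                if np.isfinite(pol.fun) and pol.fun <= best_f:
                    best_x, best_f = np.asarray(pol.x), float(pol.fun)
            except (ValueError, FloatingPointError):  # pragma: no cover
                pass
            # one refinement pass of Nelder-Mead around the incumbent
            res = optimize.minimize(
                nll, best_x, method="Nelder-Mead", bounds=bounds,
                options={"xatol": cfg.optimizer_tol ** 0.5,
                         "fatol": cfg.optimizer_tol,
                         "maxiter": 200 * (len(best_x) + 1)},
            )
            if res.fun <= best_f:
                best_x, best_f = np.asarray(res.x), float(res.fun)
            converged = np.isfinite(best_f) and best_f < -_LL_BAD / 2

        if best_x is None:  # pragma: no cover - starts always exist
            best_x = np.minimum(np.maximum(starts[0], lo), hi)
            best_f = nll(best_x)

        result = DoseResponseResults(
            spec=spec, dataset=ds, params=best_x, loglik=-best_f,
            converged=bool(converged), config=cfg,
        )
        self._attach_diagnostics(result)
        return result

    def _attach_diagnostics(self, result: DoseResponseResults) -> None:
        ds = self.dataset
        if ds.is_dichotomous:
            p, chi2, df = gof_dichotomous(result, ds)
            result.gof_pvalue, result.gof_stat, result.gof_df = p, chi2, df
            p_hat = np.clip(result.predicted, _P_CLIP, 1 - _P_CLIP)
            se = np.sqrt(np.maximum(ds.n * p_hat * (1 - p_hat), 1e-8))
            result.scaled_residuals = (ds.incidence - ds.n * p_hat) / se
        else:
            result.tests = tests_continuous(ds, result)
            result.gof_pvalue = result.tests.get("test4_p")
            mu = result.predicted
            var = result.spec.group_variances(result.params, mu)
            se = np.sqrt(np.maximum(var / ds.n, 1e-300))
            result.scaled_residuals = (ds.mean - mu) / se


def fit_mle(spec: ModelSpec, dataset: DoseResponseDataset,
            config: Optional[RunConfig] = None) -> DoseResponseResults:
    """Fit one model spec to a dataset (functional form of
    :class:`DoseResponseModel` + ``fit``)."""
    return DoseResponseModel(dataset, spec, config=config).fit()


def fit_suite(dataset: DoseResponseDataset,
              config: Optional[RunConfig] = None) -> list:
    """Fit the full candidate suite appropriate for the dataset's type."""
    config = config or RunConfig()
    suite = model_suite(
        dataset.dtype, dataset.n_groups,
        restricted=config.restrictions,
        max_degree=config.max_degree,
        models=config.models,
        variance_modes=config.variance_modes,
    )
    return [fit_mle(spec, dataset, config) for spec in suite]
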
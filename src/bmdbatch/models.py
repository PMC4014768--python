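"""Parametric dose-response model suites.

Defines every model in the standard benchmark-dose suites:

* dichotomous (binomial): Logistic, LogLogistic, Probit, LogProbit, Weibull,
  Gamma, Multistage (degree = groups - 1) and Dichotomous Hill;
* continuous (normal): Exponential 2-5, Hill, Power, Polynomial
  (degree = groups - 1) and Linear, each fitted under a constant variance
  sigma^2 and a modeled ("power of the mean") variance alpha * |mu|^rho;
* dichotomous-cancer: the multistage-cancer family at every degree from 1 to
  groups - 1.

Each :class:`ModelSpec` subclass carries the functional form, parameter names
and bounds, deterministic starting-value anchors for the optimizer, closed-form
benchmark-dose expressions where they exist, and the constrained
reparameterization used for profile-likelihood lower bounds (one slope-type
parameter is solved exactly from a fixed BMD).

Power-type restrictions (shape/power parameters >= 1) follow the usual
risk-assessment defaults and can be switched off per suite.
"""

from __future__ import annotations

import copy
from typing import Optional, Sequence

import numpy as np
from scipy import special

from .datasets import (
    CONTINUOUS,
    DICHOTOMOUS,
    DICHOTOMOUS_CANCER,
    DoseResponseDataset,
)

_EXPIT_CLIP = 36.0  # expit saturates beyond this; avoids overflow warnings


def _expit(x):
    return special.expit(np.clip(x, -500, 500))


def _logit(p):
    return special.logit(p)


# ======================================================================
# Base classes


class ModelSpec:
    """A parametric dose-response model: form, parameters, bounds.

    Attributes
    ----------
    name : str
        Family name (``Multistage``, ``Hill``, ...), without degree or
        variance-mode decorations; see :attr:`label` for the full label.
    dtype : str
        Data type the model applies to.
    param_names : tuple of str
    degree : int or None
        Polynomial / multistage order.
    variance_mode : str or None
        ``constant`` or ``modeled`` (continuous models only).
    direction : int
        Adversity direction for continuous models (+1 increasing,
        -1 decreasing); set from the data before fitting.
    restricted : bool
        Whether power-type restrictions (shape >= 1) are active.
    """

    name: str = ""
    dtype: str = ""
    degree: Optional[int] = None
    variance_mode: Optional[str] = None
    #: index (into the full parameter vector) of the parameter solved
    #: analytically during profile-likelihood computation
    profile_param: int = 0
    #: indices of slope/scale-like parameters multiplied by the start ladder
    scale_params: tuple = ()

    def __init__(self, restricted: bool = True):
        self.restricted = restricted
        self.direction = 1

    # -- interface -----------------------------------------------------
    @property
    def param_names(self) -> tuple:
        raise NotImplementedError

    def bounds(self):
        """Return (lower, upper) arrays for the full parameter vector."""
        raise NotImplementedError

    def predict(self, params, doses):
        """Predicted probability p(d) or mean mu(d) at each dose."""
        raise NotImplementedError

    def background(self, params) -> float:
        """The model's response at dose 0 (limit value for log-dose forms)."""
        return float(self.predict(params, np.array([0.0]))[0])

    def starts(self, dataset: DoseResponseDataset) -> list:
        """Deterministic ladder of starting parameter vectors."""
        anchors = self._anchors(dataset)
        lo, hi = self.bounds()
        out = []
        for anchor in anchors:
            for fac in (1.0, 0.25, 4.0):
                s = np.array(anchor, dtype=float)
                for i in self.scale_params:
                    s[i] = s[i] * fac
                s = np.minimum(np.maximum(s, lo), hi)
                # keep strictly inside open-ended lower bounds where possible
                out.append(s)
        # de-duplicate while preserving order
        seen = set()
        uniq = []
        for s in out:
            key = tuple(np.round(s, 12))
            if key not in seen:
                seen.add(key)
                uniq.append(s)
        return uniq

    def _anchors(self, dataset) -> list:
        raise NotImplementedError

    def copy(self) -> "ModelSpec":
        return copy.copy(self)

    # -- BMD machinery -------------------------------------------------
    def bmd_closed(self, params, bmr: float):
        """Closed-form BMD at the given BMR, or None if unavailable.

        For dichotomous models ``bmr`` is the extra risk; for continuous
        models it is the absolute change in the mean (already scaled by the
        control SD).
        """
        return None

    def profile_fill(self, rest, D: float, bmr: float):
        """Reconstruct a full parameter vector with BMD fixed at ``D``.

        ``rest`` is the parameter vector with the :attr:`profile_param`
        entry removed.  Returns None when no in-bounds value of the solved
        parameter can place the BMD at ``D``.
        """
        raise NotImplementedError

    def _insert(self, rest, value):
        full = np.insert(np.asarray(rest, dtype=float), self.profile_param, value)
        lo, hi = self.bounds()
        v = full[self.profile_param]
        if not np.isfinite(v) or v < lo[self.profile_param] - 1e-12 or v > hi[self.profile_param] + 1e-12:
            return None
        return full

    @property
    def label(self) -> str:
        parts = [self.name]
        if self.degree is not None:
            parts.append(str(self.degree))
        lbl = "-".join(parts)
        if self.variance_mode is not None:
            lbl += f" ({self.variance_mode} variance)"
        return lbl

    def __repr__(self):
        return f"<{type(self).__name__} {self.label}>"


class DichotomousSpec(ModelSpec):
    dtype = DICHOTOMOUS

    def extra_risk(self, params, doses):
        p = self.predict(params, np.atleast_1d(np.asarray(doses, float)))
        p0 = self.background(params)
        return (p - p0) / max(1.0 - p0, 1e-12)

    @staticmethod
    def _obs_props(dataset):
        y = dataset.incidence.astype(float)
        n = dataset.n.astype(float)
        return (y + 0.5) / (n + 1.0)

    @staticmethod
    def _obs_extra_risk(p_obs, gamma0):
        er = (p_obs - gamma0) / max(1.0 - gamma0, 1e-9)
        return np.clip(er, 1e-4, 1 - 1e-4)


class ContinuousSpec(ModelSpec):
    """Continuous model: mean-function parameters + variance parameters.

    The full parameter vector is ``mean params + variance params`` where the
    variance block is ``(ln_sigma2,)`` in constant mode or
    ``(ln_alpha, rho)`` in modeled mode: Var(d) = alpha * |mu(d)|^rho.
    """

    dtype = CONTINUOUS
    n_mean_params: int = 0

    def __init__(self, restricted: bool = True, variance_mode: str = "constant"):
        super().__init__(restricted)
        if variance_mode not in ("constant", "modeled"):
            raise ValueError(f"unknown variance mode {variance_mode!r}")
        self.variance_mode = variance_mode

    # -- variance block ------------------------------------------------
    @property
    def variance_param_names(self) -> tuple:
        return ("ln_sigma2",) if self.variance_mode == "constant" else ("ln_alpha", "rho")

    def variance_bounds(self):
        if self.variance_mode == "constant":
            return [-100.0], [100.0]
        return [-100.0, -18.0], [100.0, 18.0]

    def group_variances(self, params, mu):
        """Per-group variances implied by the variance model at means ``mu``."""
        if self.variance_mode == "constant":
            return np.full_like(np.atleast_1d(mu), np.exp(params[self.n_mean_params]))
        ln_alpha, rho = params[self.n_mean_params], params[self.n_mean_params + 1]
        with np.errstate(over="ignore"):
            return np.exp(ln_alpha) * np.maximum(np.abs(mu), 1e-8) ** rho

    def sigma0(self, params) -> float:
        """Modeled control-group SD (used as the 1-SD benchmark unit)."""
        mu0 = self.background(params)
        return float(np.sqrt(self.group_variances(params, np.array([mu0]))[0]))

    def _variance_starts(self, dataset):
        n = dataset.n.astype(float)
        pooled = float(np.sum((n - 1) * dataset.sd**2) / max(np.sum(n - 1), 1.0))
        pooled = max(pooled, 1e-12)
        if self.variance_mode == "constant":
            return [[np.log(pooled)]]
        # least-squares of ln s^2 on ln |m| for a rho anchor
        s2 = np.maximum(dataset.sd**2, 1e-12)
        m = np.maximum(np.abs(dataset.mean), 1e-8)
        if np.ptp(np.log(m)) > 1e-12:
            rho = float(np.polyfit(np.log(m), np.log(s2), 1)[0])
        else:
            rho = 0.0
        rho = float(np.clip(rho, -18, 18))
        alpha = float(np.exp(np.mean(np.log(s2) - rho * np.log(m))))
        return [[np.log(max(alpha, 1e-300)), rho], [np.log(pooled), 0.0]]

    # -- mean block ----------------------------------------------------
    @property
    def param_names(self):
        return self.mean_param_names + self.variance_param_names

    @property
    def mean_param_names(self) -> tuple:
        raise NotImplementedError

    def bounds(self):
        mlo, mhi = self.mean_bounds()
        vlo, vhi = self.variance_bounds()
        return np.array(list(mlo) + vlo), np.array(list(mhi) + vhi)

    def mean_bounds(self):
        raise NotImplementedError

    def _anchors(self, dataset):
        out = []
        for mean_anchor in self._mean_anchors(dataset):
            for var_anchor in self._variance_starts(dataset):
                out.append(list(mean_anchor) + list(var_anchor))
        return out

    def _mean_anchors(self, dataset) -> list:
        raise NotImplementedError

    # continuous profile target: |mu(D) - mu(0)| = bmr_sd * sigma0, signed by
    # the fitted adversity direction
    def profile_fill(self, rest, D, bmr):
        full0 = np.insert(np.asarray(rest, float), self.profile_param, 0.0)
        t = bmr * self.sigma0(full0)
        if not np.isfinite(t) or t <= 0:
            return None
        value = self._solve_mean_param(full0, D, self.direction * t)
        if value is None or not np.isfinite(value):
            return None
        full0[self.profile_param] = value
        lo, hi = self.bounds()
        i = self.profile_param
        if full0[i] < lo[i] - 1e-12 or full0[i] > hi[i] + 1e-12:
            return None
        return full0

    def _solve_mean_param(self, full0, D, delta):
        """Value of the solved parameter making mu(D) - mu(0) equal ``delta``."""
        raise NotImplementedError


# ======================================================================
# Dichotomous families


class Logistic(DichotomousSpec):
    """p(d) = 1 / (1 + exp(-(a + b d))); background expit(a)."""

    name = "Logistic"
    profile_param = 1
    scale_params = (1,)

    @property
    def param_names(self):
        return ("a", "b")

    def bounds(self):
        return np.array([-_EXPIT_CLIP, 0.0]), np.array([_EXPIT_CLIP, np.inf])

    def predict(self, params, doses):
        a, b = params
        return _expit(a + b * np.asarray(doses, float))

    def _anchors(self, dataset):
        p = self._obs_props(dataset)
        z = _logit(np.clip(p, 1e-4, 1 - 1e-4))
        a, b = _wls_line(dataset.doses, z, dataset.n)
        return [[np.clip(a, -10, 10), max(b, 1e-8)]]

    def bmd_closed(self, params, bmr):
        a, b = params
        if b <= 0:
            return None
        p0 = _expit(a)
        t = p0 + bmr * (1 - p0)
        return (_logit(t) - a) / b

    def profile_fill(self, rest, D, bmr):
        a = rest[0]
        p0 = _expit(a)
        t = p0 + bmr * (1 - p0)
        return self._insert(rest, (_logit(t) - a) / D)


class Probit(DichotomousSpec):
    """p(d) = Phi(a + b d)."""

    name = "Probit"
    profile_param = 1
    scale_params = (1,)

    @property
    def param_names(self):
        return ("a", "b")

    def bounds(self):
        return np.array([-18.0, 0.0]), np.array([18.0, np.inf])

    def predict(self, params, doses):
        a, b = params
        return special.ndtr(a + b * np.asarray(doses, float))

    def _anchors(self, dataset):
        p = self._obs_props(dataset)
        z = special.ndtri(np.clip(p, 1e-4, 1 - 1e-4))
        a, b = _wls_line(dataset.doses, z, dataset.n)
        return [[np.clip(a, -6, 6), max(b, 1e-8)]]

    def bmd_closed(self, params, bmr):
        a, b = params
        if b <= 0:
            return None
        p0 = special.ndtr(a)
        t = p0 + bmr * (1 - p0)
        return (special.ndtri(t) - a) / b

    def profile_fill(self, rest, D, bmr):
        a = rest[0]
        p0 = special.ndtr(a)
        t = p0 + bmr * (1 - p0)
        return self._insert(rest, (special.ndtri(t) - a) / D)


class _LogDoseSpec(DichotomousSpec):
    """Shared scaffolding for log-dose background models (gamma + slope on ln d)."""

    profile_param = 1  # a
    scale_params = (2,)

    @property
    def param_names(self):
        return ("gamma", "a", "b")

    def bounds(self):
        blo = 1.0 if self.restricted else 1e-8
        return np.array([0.0, -40.0, blo]), np.array([1 - 1e-6, 40.0, 18.0])

    def _linkinv(self, x):
        raise NotImplementedError

    def _link(self, q):
        raise NotImplementedError

    def predict(self, params, doses):
        gamma, a, b = params
        d = np.asarray(doses, float)
        out = np.full(d.shape, gamma, dtype=float)
        pos = d > 0
        out[pos] = gamma + (1 - gamma) * self._linkinv(a + b * np.log(d[pos]))
        return out

    def background(self, params):
        return float(params[0])

    def _anchors(self, dataset):
        p = self._obs_props(dataset)
        gamma0 = float(np.clip(p[0], 1e-3, 0.9))
        er = self._obs_extra_risk(p, gamma0)
        pos = dataset.doses > 0
        a, b = _wls_line(np.log(dataset.doses[pos]), self._link(er[pos]), dataset.n[pos])
        return [[gamma0, np.clip(a, -30, 30), np.clip(b, 1e-6, 18)]]

    def bmd_closed(self, params, bmr):
        _, a, b = params
        return float(np.exp((self._link(bmr) - a) / b))

    def profile_fill(self, rest, D, bmr):
        b = rest[1]
        a = self._link(bmr) - b * np.log(D)
        return self._insert(rest, a)


class LogLogistic(_LogDoseSpec):
    """p(d) = gamma + (1 - gamma) expit(a + b ln d); p(0) = gamma."""

    name = "LogLogistic"

    def _linkinv(self, x):
        return _expit(x)

    def _link(self, q):
        return _logit(q)


class LogProbit(_LogDoseSpec):
    """p(d) = gamma + (1 - gamma) Phi(a + b ln d); p(0) = gamma."""

    name = "LogProbit"

    def _linkinv(self, x):
        return special.ndtr(x)

    def _link(self, q):
        return special.ndtri(q)


class Weibull(DichotomousSpec):
    """p(d) = gamma + (1 - gamma)(1 - exp(-b d^a))."""

    name = "Weibull"
    profile_param = 2  # b
    scale_params = (2,)

    @property
    def param_names(self):
        return ("gamma", "a", "b")

    def bounds(self):
        alo = 1.0 if self.restricted else 1e-8
        return np.array([0.0, alo, 0.0]), np.array([1 - 1e-6, 18.0, np.inf])

    def predict(self, params, doses):
        gamma, a, b = params
        d = np.asarray(doses, float)
        with np.errstate(over="ignore"):
            return gamma + (1 - gamma) * (-np.expm1(-b * np.power(d, a)))

    def background(self, params):
        return float(params[0])

    def _anchors(self, dataset):
        p = self._obs_props(dataset)
        gamma0 = float(np.clip(p[0], 1e-3, 0.9))
        er = self._obs_extra_risk(p, gamma0)
        pos = dataset.doses > 0
        z = np.log(-np.log1p(-er[pos]))
        lnb, a = 0.0, 1.0
        if pos.sum() >= 2:
            # z = ln b + a ln d, so intercept = ln b and slope = a
            lnb, a = _wls_line(np.log(dataset.doses[pos]), z, dataset.n[pos])
        a = float(np.clip(a, 1.0 if self.restricted else 0.1, 8.0))
        b = float(np.clip(np.exp(np.clip(lnb, -300, 300)), 1e-12, 1e12))
        return [[gamma0, a, b], [gamma0, 1.0, b]]

    def bmd_closed(self, params, bmr):
        _, a, b = params
        if b <= 0:
            return None
        return float((-np.log1p(-bmr) / b) ** (1.0 / a))

    def profile_fill(self, rest, D, bmr):
        a = rest[1]
        b = -np.log1p(-bmr) / D**a
        return self._insert(rest, b)


class Gamma(DichotomousSpec):
    """p(d) = gamma + (1 - gamma) G(b d; a), G the gamma CDF with shape a."""

    name = "Gamma"
    profile_param = 2  # b
    scale_params = (2,)

    @property
    def param_names(self):
        return ("gamma", "a", "b")

    def bounds(self):
        alo = 1.0 if self.restricted else 0.2
        return np.array([0.0, alo, 0.0]), np.array([1 - 1e-6, 18.0, np.inf])

    def predict(self, params, doses):
        gamma, a, b = params
        d = np.asarray(doses, float)
        return gamma + (1 - gamma) * special.gammainc(a, np.maximum(b * d, 0.0))

    def background(self, params):
        return float(params[0])

    def _anchors(self, dataset):
        p = self._obs_props(dataset)
        gamma0 = float(np.clip(p[0], 1e-3, 0.9))
        er = self._obs_extra_risk(p, gamma0)
        top = float(er[-1])
        out = []
        for a0 in (1.0, 2.0):
            b0 = special.gammaincinv(a0, top) / dataset.max_dose
            out.append([gamma0, a0, max(float(b0), 1e-12)])
        return out

    def bmd_closed(self, params, bmr):
        _, a, b = params
        if b <= 0:
            return None
        return float(special.gammaincinv(a, bmr) / b)

    def profile_fill(self, rest, D, bmr):
        a = rest[1]
        b = special.gammaincinv(a, bmr) / D
        return self._insert(rest, b)


class Multistage(DichotomousSpec):
    """p(d) = gamma + (1 - gamma)(1 - exp(-sum_i beta_i d^i)), beta_i >= 0."""

    name = "Multistage"
    profile_param = 1  # beta_1
    dtype = DICHOTOMOUS

    def __init__(self, degree: int, restricted: bool = True, cancer: bool = False):
        super().__init__(restricted)
        if degree < 1:
            raise ValueError("multistage degree must be >= 1")
        self.degree = degree
        self.cancer = cancer
        if cancer:
            self.name = "Multistage-Cancer"
            self.dtype = DICHOTOMOUS_CANCER
        self.scale_params = tuple(range(1, degree + 1))

    @property
    def param_names(self):
        return ("gamma",) + tuple(f"beta{i}" for i in range(1, self.degree + 1))

    def bounds(self):
        k = self.degree
        return np.array([0.0] + [0.0] * k), np.array([1 - 1e-6] + [np.inf] * k)

    def _poly(self, params, d):
        betas = params[1:]
        acc = np.zeros_like(d)
        for i, beta in enumerate(betas, start=1):
            acc += beta * d**i
        return acc

    def predict(self, params, doses):
        gamma = params[0]
        d = np.asarray(doses, float)
        with np.errstate(over="ignore"):
            return gamma + (1 - gamma) * (-np.expm1(-self._poly(params, d)))

    def background(self, params):
        return float(params[0])

    def _anchors(self, dataset):
        p = self._obs_props(dataset)
        gamma0 = float(np.clip(p[0], 1e-3, 0.9))
        er = self._obs_extra_risk(p, gamma0)
        load = -np.log1p(-float(er[-1]))  # total cumulative hazard at top dose
        k = self.degree
        dmax = dataset.max_dose
        spread = [gamma0] + [load / (k * dmax**i) for i in range(1, k + 1)]
        first = [gamma0, load / dmax] + [1e-10 / dmax**i for i in range(2, k + 1)]
        return [first, spread]

    def bmd_closed(self, params, bmr):
        load = -np.log1p(-bmr)
        betas = np.asarray(params[1:], dtype=float)
        if self.degree == 1:
            return float(load / betas[0]) if betas[0] > 0 else None
        if not np.any(betas > 0):
            return None
        # smallest positive real root of sum beta_i D^i = load
        coeffs = np.concatenate(([-load], betas))  # ascending powers
        roots = np.polynomial.polynomial.polyroots(coeffs)
        real = roots[np.abs(roots.imag) < 1e-9 * np.maximum(np.abs(roots.real), 1)].real
        pos = real[real > 0]
        return float(np.min(pos)) if pos.size else None

    def profile_fill(self, rest, D, bmr):
        load = -np.log1p(-bmr)
        higher = 0.0
        for i, beta in enumerate(rest[1:], start=2):
            higher += beta * D**i
        beta1 = (load - higher) / D
        return self._insert(rest, beta1)


class DichotomousHill(DichotomousSpec):
    """p(d) = gamma nu + nu (1 - gamma) expit(a + b ln d); plateau nu, p(0) = gamma nu."""

    name = "DichotomousHill"
    profile_param = 2  # a
    scale_params = (3,)

    @property
    def param_names(self):
        return ("gamma", "nu", "a", "b")

    def bounds(self):
        blo = 1.0 if self.restricted else 1e-8
        return (
            np.array([0.0, 1e-8, -40.0, blo]),
            np.array([1 - 1e-6, 1.0, 40.0, 18.0]),
        )

    def predict(self, params, doses):
        gamma, nu, a, b = params
        d = np.asarray(doses, float)
        out = np.full(d.shape, gamma * nu, dtype=float)
        pos = d > 0
        out[pos] = gamma * nu + nu * (1 - gamma) * _expit(a + b * np.log(d[pos]))
        return out

    def background(self, params):
        return float(params[0] * params[1])

    def _anchors(self, dataset):
        p = self._obs_props(dataset)
        nu0 = float(np.clip(np.max(p) * 1.05, 0.05, 1.0))
        gamma0 = float(np.clip(p[0] / nu0, 1e-3, 0.9))
        frac = np.clip((p - gamma0 * nu0) / (nu0 * (1 - gamma0)), 1e-4, 1 - 1e-4)
        pos = dataset.doses > 0
        a, b = _wls_line(np.log(dataset.doses[pos]), _logit(frac[pos]), dataset.n[pos])
        return [[gamma0, nu0, np.clip(a, -30, 30), np.clip(b, 1e-6, 18)]]

    def _q(self, gamma, nu, bmr):
        denom = nu * (1 - gamma)
        if denom <= 0:
            return None
        q = bmr * (1 - gamma * nu) / denom
        if q <= 0 or q >= 1:
            return None
        return q

    def bmd_closed(self, params, bmr):
        gamma, nu, a, b = params
        q = self._q(gamma, nu, bmr)
        if q is None or b <= 0:
            return None
        return float(np.exp((_logit(q) - a) / b))

    def profile_fill(self, rest, D, bmr):
        gamma, nu, b = rest
        q = self._q(gamma, nu, bmr)
        if q is None:
            return None
        a = _logit(q) - b * np.log(D)
        return self._insert(rest, a)


# ======================================================================
# Continuous families


class Polynomial(ContinuousSpec):
    """mu(d) = beta0 + sum_i beta_i d^i (Linear is degree 1)."""

    name = "Polynomial"
    profile_param = 1  # beta1

    def __init__(self, degree: int, restricted: bool = True, variance_mode: str = "constant"):
        super().__init__(restricted, variance_mode)
        if degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        self.degree = degree
        if degree == 1:
            self.name = "Linear"
        self.n_mean_params = degree + 1
        self.scale_params = tuple(range(1, degree + 1))

    @property
    def label(self):
        if self.name == "Linear":
            return f"Linear ({self.variance_mode} variance)"
        return super().label

    @property
    def mean_param_names(self):
        return tuple(f"beta{i}" for i in range(self.degree + 1))

    def mean_bounds(self):
        k = self.degree + 1
        return [-np.inf] * k, [np.inf] * k

    def predict(self, params, doses):
        d = np.asarray(doses, float)
        mu = np.zeros_like(d) + params[0]
        for i in range(1, self.degree + 1):
            mu = mu + params[i] * d**i
        return mu

    def background(self, params):
        return float(params[0])

    def _mean_anchors(self, dataset):
        # weighted LS polynomial fit of group means on dose
        w = np.sqrt(dataset.n.astype(float))
        V = np.vander(dataset.doses, self.degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(V * w[:, None], dataset.mean * w, rcond=None)
        return [list(coef)]

    def bmd_closed(self, params, target):
        if self.degree == 1:
            b1 = params[1]
            if b1 == 0:
                return None
            return float(target / abs(b1))
        return None

    def _solve_mean_param(self, full0, D, delta):
        higher = 0.0
        for i in range(2, self.degree + 1):
            higher += full0[i] * D**i
        return (delta - higher) / D


class Power(ContinuousSpec):
    """mu(d) = gamma + beta d^delta."""

    name = "Power"
    profile_param = 1  # beta
    n_mean_params = 3
    scale_params = (1,)

    @property
    def mean_param_names(self):
        return ("gamma", "beta", "delta")

    def mean_bounds(self):
        dlo = 1.0 if self.restricted else 1e-8
        return [-np.inf, -np.inf, dlo], [np.inf, np.inf, 18.0]

    def predict(self, params, doses):
        gamma, beta, delta = params[:3]
        d = np.asarray(doses, float)
        return gamma + beta * np.power(d, delta)

    def background(self, params):
        return float(params[0])

    def _mean_anchors(self, dataset):
        m = dataset.mean
        gamma0 = float(m[0])
        pos = dataset.doses > 0
        resp = m[pos] - gamma0
        sgn = self.direction
        mag = np.maximum(np.abs(resp), 1e-12)
        delta0, lnb = 1.0, np.log(max(np.abs(resp[-1]), 1e-12) / dataset.max_dose)
        if pos.sum() >= 2 and np.ptp(np.log(dataset.doses[pos])) > 0:
            delta0, lnb = np.polyfit(np.log(dataset.doses[pos]), np.log(mag), 1)
        delta0 = float(np.clip(delta0, 1.0 if self.restricted else 0.1, 8.0))
        beta0 = sgn * float(np.exp(np.clip(lnb, -300, 300)))
        return [[gamma0, beta0, delta0], [gamma0, sgn * np.abs(resp[-1]) / dataset.max_dose, 1.0]]

    def bmd_closed(self, params, target):
        beta, delta = params[1], params[2]
        if beta == 0:
            return None
        return float((target / abs(beta)) ** (1.0 / delta))

    def _solve_mean_param(self, full0, D, delta_mu):
        return delta_mu / D ** full0[2]


class Hill(ContinuousSpec):
    """mu(d) = gamma + nu d^h / (k^h + d^h); half-maximal response at d = k."""

    name = "Hill"
    profile_param = 1  # nu
    n_mean_params = 4
    scale_params = (2,)

    @property
    def mean_param_names(self):
        return ("gamma", "nu", "k", "h")

    def mean_bounds(self):
        hlo = 1.0 if self.restricted else 1e-8
        return [-np.inf, -np.inf, 1e-12, hlo], [np.inf, np.inf, np.inf, 18.0]

    def predict(self, params, doses):
        gamma, nu, k, h = params[:4]
        d = np.asarray(doses, float)
        dh = np.power(d, h)
        return gamma + nu * dh / (k**h + dh)

    def background(self, params):
        return float(params[0])

    def _mean_anchors(self, dataset):
        m = dataset.mean
        gamma0 = float(m[0])
        nu0 = float(m[-1] - m[0])
        if nu0 == 0:
            nu0 = self.direction * max(np.ptp(m), 1e-6)
        doses = dataset.doses[dataset.doses > 0]
        kmid = float(np.sqrt(doses[0] * doses[-1]))
        return [[gamma0, nu0, kmid, 1.0], [gamma0, nu0 * 1.5, kmid, 3.0]]

    def bmd_closed(self, params, target):
        nu, k, h = params[1], params[2], params[3]
        if abs(nu) <= target:
            return None
        r = target / abs(nu)
        return float(k * (r / (1 - r)) ** (1.0 / h))

    def _solve_mean_param(self, full0, D, delta_mu):
        k, h = full0[2], full0[3]
        return delta_mu * (k**h + D**h) / D**h


class _ExponentialSpec(ContinuousSpec):
    """Shared scaffolding for the exponential family (forms 2-5)."""

    def background(self, params):
        return float(params[0])

    def _resp_ratio(self, dataset):
        m = dataset.mean
        a0 = float(m[0]) if m[0] != 0 else float(np.mean(m))
        if a0 == 0:
            a0 = 1.0
        return a0, float(m[-1] / a0) if a0 != 0 else 1.0


class Exponential2(_ExponentialSpec):
    """mu(d) = a exp(s b d), s the adversity direction."""

    name = "Exponential2"
    profile_param = 1  # b
    n_mean_params = 2
    scale_params = (1,)

    @property
    def mean_param_names(self):
        return ("a", "b")

    def mean_bounds(self):
        return [1e-12, 0.0], [np.inf, np.inf]

    def predict(self, params, doses):
        a, b = params[:2]
        d = np.asarray(doses, float)
        with np.errstate(over="ignore"):
            return a * np.exp(np.clip(self.direction * b * d, -500, 500))

    def _mean_anchors(self, dataset):
        a0, ratio = self._resp_ratio(dataset)
        ratio = max(ratio, 1e-6)
        b0 = abs(np.log(ratio)) / dataset.max_dose
        return [[max(a0, 1e-8), max(b0, 1e-10)]]

    def bmd_closed(self, params, target):
        a, b = params[:2]
        if b <= 0 or a <= 0:
            return None
        if self.direction > 0:
            return float(np.log1p(target / a) / b)
        if target >= a:
            return None
        return float(-np.log1p(-target / a) / b)

    def _solve_mean_param(self, full0, D, delta_mu):
        a = full0[0]
        arg = 1.0 + delta_mu / a
        if arg <= 0:
            return None
        return self.direction * np.log(arg) / D


class Exponential3(_ExponentialSpec):
    """mu(d) = a exp(s (b d)^g)."""

    name = "Exponential3"
    profile_param = 1  # b
    n_mean_params = 3
    scale_params = (1,)

    @property
    def mean_param_names(self):
        return ("a", "b", "g")

    def mean_bounds(self):
        glo = 1.0 if self.restricted else 1e-8
        return [1e-12, 0.0, glo], [np.inf, np.inf, 18.0]

    def predict(self, params, doses):
        a, b, g = params[:3]
        d = np.asarray(doses, float)
        with np.errstate(over="ignore"):
            return a * np.exp(np.clip(self.direction * np.power(b * d, g), -500, 500))

    def _mean_anchors(self, dataset):
        a0, ratio = self._resp_ratio(dataset)
        ratio = max(ratio, 1e-6)
        b0 = abs(np.log(ratio)) / dataset.max_dose
        return [[max(a0, 1e-8), max(b0, 1e-10), 1.0], [max(a0, 1e-8), max(b0, 1e-10), 2.0]]

    def bmd_closed(self, params, target):
        a, b, g = params[:3]
        if b <= 0 or a <= 0:
            return None
        if self.direction > 0:
            z = np.log1p(target / a)
        else:
            if target >= a:
                return None
            z = -np.log1p(-target / a)
        return float(z ** (1.0 / g) / b)

    def _solve_mean_param(self, full0, D, delta_mu):
        a, g = full0[0], full0[2]
        arg = 1.0 + delta_mu / a
        if arg <= 0:
            return None
        z = self.direction * np.log(arg)
        if z <= 0:
            return None
        return z ** (1.0 / g) / D


class Exponential4(_ExponentialSpec):
    """mu(d) = a (c - (c - 1) exp(-b d)); plateau at a c."""

    name = "Exponential4"
    profile_param = 1  # b
    n_mean_params = 3
    scale_params = (1,)

    @property
    def mean_param_names(self):
        return ("a", "b", "c")

    def mean_bounds(self):
        if self.direction > 0:
            return [1e-12, 0.0, 1.0 + 1e-9], [np.inf, np.inf, np.inf]
        return [1e-12, 0.0, 1e-9], [np.inf, np.inf, 1.0 - 1e-9]

    def predict(self, params, doses):
        a, b, c = params[:3]
        d = np.asarray(doses, float)
        with np.errstate(over="ignore"):
            return a * (c - (c - 1) * np.exp(-np.clip(b * d, -500, 500)))

    def _mean_anchors(self, dataset):
        a0, ratio = self._resp_ratio(dataset)
        c0 = max(ratio * 1.1, 1.05) if self.direction > 0 else min(max(ratio * 0.9, 1e-3), 0.95)
        dmid = float(np.median(dataset.doses[dataset.doses > 0]))
        return [[max(a0, 1e-8), 1.0 / max(dmid, 1e-12), c0]]

    def bmd_closed(self, params, target):
        a, b, c = params[:3]
        span = a * abs(c - 1)
        if b <= 0 or span <= target:
            return None
        return float(-np.log1p(-target / span) / b)

    def _solve_mean_param(self, full0, D, delta_mu):
        a, c = full0[0], full0[2]
        span = a * (c - 1)  # signed; matches direction through bounds on c
        r = delta_mu / span
        if not np.isfinite(r) or r <= 0 or r >= 1:
            return None
        return -np.log1p(-r) / D


class Exponential5(_ExponentialSpec):
    """mu(d) = a (c - (c - 1) exp(-(b d)^g))."""

    name = "Exponential5"
    profile_param = 1  # b
    n_mean_params = 4
    scale_params = (1,)

    @property
    def mean_param_names(self):
        return ("a", "b", "c", "g")

    def mean_bounds(self):
        glo = 1.0 if self.restricted else 1e-8
        if self.direction > 0:
            return [1e-12, 0.0, 1.0 + 1e-9, glo], [np.inf, np.inf, np.inf, 18.0]
        return [1e-12, 0.0, 1e-9, glo], [np.inf, np.inf, 1.0 - 1e-9, 18.0]

    def predict(self, params, doses):
        a, b, c, g = params[:4]
        d = np.asarray(doses, float)
        with np.errstate(over="ignore"):
            return a * (c - (c - 1) * np.exp(-np.clip(np.power(b * d, g), 0, 500)))

    def _mean_anchors(self, dataset):
        base = Exponential4(self.restricted, self.variance_mode)
        base.direction = self.direction
        out = []
        for anchor in base._mean_anchors(dataset):
            out.append(anchor + [1.0])
            out.append(anchor + [2.0])
        return out

    def bmd_closed(self, params, target):
        a, b, c, g = params[:4]
        span = a * abs(c - 1)
        if b <= 0 or span <= target:
            return None
        return float((-np.log1p(-target / span)) ** (1.0 / g) / b)

    def _solve_mean_param(self, full0, D, delta_mu):
        a, c, g = full0[0], full0[2], full0[3]
        span = a * (c - 1)
        r = delta_mu / span
        if not np.isfinite(r) or r <= 0 or r >= 1:
            return None
        return (-np.log1p(-r)) ** (1.0 / g) / D


# ======================================================================
# Suite assembly


DICHOTOMOUS_FAMILIES = (
    "Gamma",
    "DichotomousHill",
    "Logistic",
    "LogLogistic",
    "Probit",
    "LogProbit",
    "Weibull",
    "Multistage",
)
CONTINUOUS_FAMILIES = (
    "Exponential2",
    "Exponential3",
    "Exponential4",
    "Exponential5",
    "Hill",
    "Power",
    "Polynomial",
    "Linear",
)


def model_suite(
    dtype: str,
    n_groups: int,
    restricted: bool = True,
    max_degree: int = 8,
    models: Optional[Sequence[str]] = None,
    variance_modes: Sequence[str] = ("constant", "modeled"),
) -> list:
    """Build the standard candidate-model suite for a dataset.

    Dichotomous data get the 8-model suite (multistage at degree
    ``n_groups - 1``); continuous data get the 8 base forms, each duplicated
    for constant and modeled variance; dichotomous-cancer data get the
    multistage-cancer model at every degree from 1 to ``n_groups - 1``.
    Polynomial/multistage degrees are capped at ``max_degree``.

    ``models`` optionally restricts the suite to a subset of family names.
    """
    if n_groups < 3:
        raise ValueError("datasets with fewer than 3 dose groups cannot be modeled")
    deg = min(n_groups - 1, max_degree)

    def wanted(name):
        return models is None or name in models

    suite: list[ModelSpec] = []
    if dtype == DICHOTOMOUS:
        builders = {
            "Gamma": lambda: Gamma(restricted),
            "DichotomousHill": lambda: DichotomousHill(restricted),
            "Logistic": lambda: Logistic(restricted),
            "LogLogistic": lambda: LogLogistic(restricted),
            "Probit": lambda: Probit(restricted),
            "LogProbit": lambda: LogProbit(restricted),
            "Weibull": lambda: Weibull(restricted),
            "Multistage": lambda: Multistage(deg, restricted),
        }
        for fam in DICHOTOMOUS_FAMILIES:
            if wanted(fam):
                suite.append(builders[fam]())
    elif dtype == CONTINUOUS:
        builders = {
            "Exponential2": lambda vm: Exponential2(restricted, vm),
            "Exponential3": lambda vm: Exponential3(restricted, vm),
            "Exponential4": lambda vm: Exponential4(restricted, vm),
            "Exponential5": lambda vm: Exponential5(restricted, vm),
            "Hill": lambda vm: Hill(restricted, vm),
            "Power": lambda vm: Power(restricted, vm),
            "Polynomial": lambda vm: Polynomial(deg, restricted, vm),
            "Linear": lambda vm: Polynomial(1, restricted, vm),
        }
        for fam in CONTINUOUS_FAMILIES:
            if fam == "Polynomial" and deg == 1:
                continue  # identical to Linear; avoid duplicating the form
            if wanted(fam):
                for vm in variance_modes:
                    suite.append(builders[fam](vm))
    elif dtype == DICHOTOMOUS_CANCER:
        for k in range(1, deg + 1):
            if wanted("Multistage-Cancer") or wanted("Multistage"):
                suite.append(Multistage(k, restricted, cancer=True))
    else:
        raise ValueError(f"unknown dtype {dtype!r}")
    return suite


def detect_direction(dataset: DoseResponseDataset) -> int:
    """Adversity direction of a continuous dataset: sign of the weighted
    least-squares slope of group means on dose (+1 if flat)."""
    slope = _wls_line(dataset.doses, dataset.mean, dataset.n)[1]
    return -1 if slope < 0 else 1


def _wls_line(x, z, w):
    """Weighted least squares line fit; returns (intercept, slope)."""
    x = np.asarray(x, float)
    z = np.asarray(z, float)
    w = np.asarray(w, float)
    if x.size < 2 or np.ptp(x) == 0:
        return float(np.average(z, weights=w)), 0.0
    W = np.sum(w)
    xb = np.sum(w * x) / W
    zb = np.sum(w * z) / W
    sxx = np.sum(w * (x - xb) ** 2)
    slope = np.sum(w * (x - xb) * (z - zb)) / sxx
    return float(zb - slope * xb), float(slope)
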
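"""Cross-dataset and cross-chemical summaries.

Compares batch-calculated benchmark doses with points of departure (PODs)
reported in existing assessments: ratio distributions (median and 5th-95th
percentile range of BMD:NOAEL-style ratios), Pearson/Spearman correlations of
paired POD sets (optionally on log10 scale), chi-squared trend tests for
proportions across ordered design factors, two-sample comparisons of group
means, and candidate reference values (a BMDL divided by the product of
uncertainty factors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datasets import SessionRecord


@dataclass
class PodComparison:
    """A chemical's batch-calculated BMD/BMDL next to a reported POD."""

    chemical_id: str
    batch_bmd: Optional[float]
    batch_bmdl: Optional[float]
    pod_type: str
    pod_value: float

    @property
    def ratio_bmd_pod(self) -> Optional[float]:
        if self.batch_bmd and self.batch_bmd > 0 and self.pod_value > 0:
            return self.batch_bmd / self.pod_value
        return None

    @property
    def ratio_bmdl_pod(self) -> Optional[float]:
        if self.batch_bmdl and self.batch_bmdl > 0 and self.pod_value > 0:
            return self.batch_bmdl / self.pod_value
        return None


def pod_comparisons(records: Sequence[SessionRecord], pods: dict) -> list:
    """Pair modeled session records with reported PODs keyed by chemical."""
    out = []
    for rec in records:
        if rec.outcome != "modeled" or rec.selected is None:
            continue
        pod = pods.get(rec.chemical_id) or pods.get(rec.dataset_id)
        if pod is None:
            continue
        pod_type, pod_value = pod
        out.append(
            PodComparison(
                chemical_id=rec.chemical_id or rec.dataset_id,
                batch_bmd=rec.selected.bmd,
                batch_bmdl=rec.selected.bmdl,
                pod_type=pod_type,
                pod_value=float(pod_value),
            )
        )
    return out


def ratio_distribution(comparisons: Sequence[PodComparison],
                       which: str = "bmd") -> dict:
    """Median and empirical 5th/95th percentiles of batch-POD ratios.

    Percentiles use linear interpolation between order statistics.  Ratios
    with non-positive POD or missing batch value are excluded (with a note in
    the returned dict).
    """
    if which not in ("bmd", "bmdl"):
        raise ValueError("which must be 'bmd' or 'bmdl'")
    attr = "ratio_bmd_pod" if which == "bmd" else "ratio_bmdl_pod"
    ratios = [getattr(c, attr) for c in comparisons]
    excluded = sum(r is None for r in ratios)
    ratios = np.array([r for r in ratios if r is not None], dtype=float)
    if ratios.size == 0:
        raise ValueError("no defined ratios to summarize")
    return {
        "n": int(ratios.size),
        "n_excluded": int(excluded),
        "median": float(np.median(ratios)),
        "p5": float(np.percentile(ratios, 5)),
        "p95": float(np.percentile(ratios, 95)),
        "log10_ratios": np.log10(ratios),
    }


def correlate_pods(x, y, log_transform: bool = True) -> dict:
    """Squared Pearson and Spearman correlation of paired positive PODs.

    Pearson is computed on log10 values when ``log_transform`` (the usual
    choice for skewed dose scales).  Also returns the best-fit line and the
    regression through the origin, on the analysis scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("PODs must be positive")
    xa, ya = (np.log10(x), np.log10(y)) if log_transform else (x, y)
    out: dict = {"log_transform": log_transform, "n": int(x.size)}
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        out.update(pearson_r2=None, spearman_rho=None, fit_line=None, origin_line=None)
        return out
    r, _ = stats.pearsonr(xa, ya)
    rho, _ = stats.spearmanr(x, y)
    slope, intercept, *_ = stats.linregress(xa, ya)
    origin_slope = float(np.sum(xa * ya) / np.sum(xa * xa))
    out.update(
        pearson_r2=float(r**2),
        spearman_rho=float(rho),
        fit_line=(float(slope), float(intercept)),
        origin_line=(origin_slope, 0.0),
    )
    return out


def trend_in_proportions(successes, totals, scores) -> dict:
    """Cochran-Armitage chi-squared test for trend in proportions (1 df).

    ``scores`` are the ordered level values (e.g. number of dose groups).
    Levels with total 0 are excluded.  Returns the statistic and its
    two-sided p-value from the chi-squared(1) upper tail.
    """
    y = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    s = np.asarray(scores, dtype=float)
    keep = n > 0
    y, n, s = y[keep], n[keep], s[keep]
    if y.size < 2:
        raise ValueError("need at least two levels with nonzero totals")
    N = n.sum()
    pbar = y.sum() / N
    sbar = float(np.sum(n * s) / N)
    denom = pbar * (1 - pbar) * float(np.sum(n * (s - sbar) ** 2))
    num = float(np.sum(y * s) - pbar * np.sum(n * s))
    if denom <= 0:
        return {"statistic": 0.0, "pvalue": 1.0, "df": 1}
    stat = num**2 / denom
    return {"statistic": float(stat), "pvalue": float(stats.chi2.sf(stat, 1)), "df": 1}


def compare_group_means(a, b, equal_var: bool = False) -> dict:
    """Two-tailed unpaired t-test (Welch by default).

    Degenerate zero-variance samples with equal means return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return {"statistic": 0.0, "pvalue": 1.0}
        return {"statistic": np.inf, "pvalue": 0.0}
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"statistic": float(t), "pvalue": float(p)}


@dataclass
class CandidateRefValue:
    """A candidate reference value: BMDL over the uncertainty-factor product."""

    bmdl: float
    uf_a: float = 10.0  # interspecies uncertainty
    uf_h: float = 10.0  # intraspecies (human) variability
    uf_s: float = 1.0   # subchronic-to-chronic extrapolation
    uf_d: float = 1.0   # database incompleteness

    def __post_init__(self):
        for name in ("bmdl", "uf_a", "uf_h", "uf_s", "uf_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def uf_product(self) -> float:
        return self.uf_a * self.uf_h * self.uf_s * self.uf_d

    @property
    def crv(self) -> float:
        return self.bmdl / self.uf_product


def candidate_reference_value(bmdl: float, uf_a: float = 10.0, uf_h: float = 10.0,
                              uf_s: float = 1.0, uf_d: float = 1.0) -> CandidateRefValue:
    """Divide a BMDL by the product of uncertainty factors."""
    return CandidateRefValue(bmdl=bmdl, uf_a=uf_a, uf_h=uf_h, uf_s=uf_s, uf_d=uf_d)


def ratio_histogram(dist: dict, ax=None, bins: int = 20):
    """Histogram of log10 batch:POD ratios with the 5th/95th percentile marks."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(dist["log10_ratios"], bins=bins, color="steelblue", edgecolor="k")
    for key in ("p5", "p95"):
        ax.axvline(np.log10(dist[key]), linestyle="--", color="gray")
    ax.axvline(np.log10(dist["median"]), color="firebrick")
    ax.set_xlabel("log10(batch value / reported POD)")
    ax.set_ylabel("frequency")
    return ax
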
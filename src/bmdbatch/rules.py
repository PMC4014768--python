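"""Automated decision logic: classify fits, select models, run batches.

Every fitted model is assigned one of three viability classes:

* **Unusable** - the optimizer failed, or neither a BMD nor a BMDL could be
  estimated;
* **Questionable** - a fatal adequacy problem: goodness-of-fit p below alpha,
  poorly modeled variance (constant-variance fit failing the homogeneity test,
  or modeled-variance fit failing the variance-model adequacy test), a BMDL
  above the highest tested dose, a BMD/BMDL ratio above the failure threshold,
  or a non-estimable BMDL;
* **Viable** - selectable, possibly carrying non-fatal warnings (low-dose
  extrapolation, BMD/BMDL ratio above the warning threshold, marginal
  mean-model fit).

Among Viable fits the one with the lowest AIC is selected when the BMDLs are
sufficiently close (no more than a configurable fold-difference, default 3);
otherwise the fit with the lowest BMDL.  Fits tying on the lowest AIC with
differing BMD/BMDLs have their BMDs and BMDLs averaged.  When no fit is
Viable, the highest dose group is dropped and the suite re-run, as long as at
least three dose groups (including control) remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bmd import BmdResult, compute_bmd_result
from .config import RuleConfig, RunConfig
from .datasets import (
    AttemptRecord,
    DoseResponseDataset,
    FitRecord,
    Selection,
    SessionRecord,
)
from .fitting import DoseResponseResults, fit_suite

UNUSABLE = "Unusable"
QUESTIONABLE = "Questionable"
VIABLE = "Viable"


@dataclass
class ViabilityClass:
    """Viability class with the reasons (fatal) and warnings (non-fatal)."""

    viability: str
    reasons: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        if self.viability in (UNUSABLE, QUESTIONABLE) and not self.reasons:
            raise ValueError(f"{self.viability} classification requires a reason")


def classify(fit: DoseResponseResults, bmdres: BmdResult,
             dataset: DoseResponseDataset,
             rules: Optional[RuleConfig] = None) -> ViabilityClass:
    """Assign Unusable / Questionable / Viable to one fitted model."""
    rules = rules or RuleConfig()

    if not fit.converged:
        return ViabilityClass(UNUSABLE, reasons=["optimizer did not converge"])
    if bmdres.bmd is None and bmdres.bmdl is None:
        return ViabilityClass(UNUSABLE, reasons=["BMD and BMDL not estimable"])

    reasons = []
    if fit.gof_pvalue is not None and fit.gof_pvalue < rules.gof_alpha:
        reasons.append(
            f"goodness of fit p = {fit.gof_pvalue:.4g} < {rules.gof_alpha:g}"
        )
    if fit.tests is not None:
        if fit.spec.variance_mode == "constant":
            p2 = fit.tests.get("test2_p")
            if p2 is not None and p2 < rules.variance_alpha:
                reasons.append(
                    f"non-homogeneous variance (Test 2 p = {p2:.4g}) under constant-variance fit"
                )
        else:
            p3 = fit.tests.get("test3_p")
            if p3 is not None and p3 < rules.variance_alpha:
                reasons.append(
                    f"variance model poorly fit (Test 3 p = {p3:.4g})"
                )
    if bmdres.bmdl is None:
        reasons.append("BMDL not estimable")
    else:
        if bmdres.bmdl > dataset.max_dose:
            reasons.append("BMDL higher than highest dose")
        ratio = bmdres.ratio
        if ratio is not None and ratio > rules.ratio_fail:
            reasons.append(f"BMD/BMDL ratio {ratio:.3g} > {rules.ratio_fail:g}")
    if reasons:
        return ViabilityClass(QUESTIONABLE, reasons=reasons)

    warnings = sorted(bmdres.warnings)
    if (rules.marginal_gof_warning and fit.gof_pvalue is not None
            and rules.gof_alpha <= fit.gof_pvalue < 2 * rules.gof_alpha):
        warnings.append(f"marginal goodness of fit (p = {fit.gof_pvalue:.4g})")
    return ViabilityClass(VIABLE, warnings=warnings)


# ======================================================================
# Model selection


def select_model(viable: Sequence[tuple], rules: Optional[RuleConfig] = None) -> Selection:
    """Select the recommended model among Viable (fit, BmdResult) pairs.

    Lowest AIC when the Viable BMDLs span no more than the configured
    fold-difference; otherwise the lowest BMDL.  Ties on the lowest AIC with
    differing BMD/BMDL values are averaged (arithmetic mean) and all tying
    model names recorded.
    """
    rules = rules or RuleConfig()
    if not viable:
        raise ValueError("select_model requires at least one Viable fit")

    bmdls = np.array([res.bmdl for _, res in viable], dtype=float)
    aics = np.array([fit.aic for fit, _ in viable], dtype=float)

    spread_ok = bmdls.max() / bmdls.min() <= rules.bmdl_close_factor
    if spread_ok:
        best_aic = aics.min()
        tied = [i for i in range(len(viable)) if aics[i] <= best_aic + rules.aic_tie_tol]
        if len(tied) > 1:
            bmds = np.array([viable[i][1].bmd for i in tied], dtype=float)
            tl = np.array([viable[i][1].bmdl for i in tied], dtype=float)
            if np.ptp(bmds) > 0 or np.ptp(tl) > 0:
                return _make_selection(
                    [viable[i] for i in tied],
                    bmd=float(bmds.mean()), bmdl=float(tl.mean()),
                    rule="aic_tie_average",
                )
            tied = tied[:1]
        i = tied[0]
        return _make_selection([viable[i]], bmd=viable[i][1].bmd,
                               bmdl=viable[i][1].bmdl, rule="lowest_aic")
    i = int(np.argmin(bmdls))
    return _make_selection([viable[i]], bmd=viable[i][1].bmd,
                           bmdl=viable[i][1].bmdl, rule="lowest_bmdl")


def _make_selection(chosen, bmd, bmdl, rule) -> Selection:
    warnings = sorted({w for _, res in chosen for w in res.warnings})
    return Selection(
        model_names=[fit.spec.label for fit, _ in chosen],
        bmd=float(bmd), bmdl=float(bmdl), selection_rule=rule, warnings=warnings,
    )


# ======================================================================
# Per-dataset orchestration


def run_dataset(dataset: DoseResponseDataset,
                config: Optional[RunConfig] = None) -> SessionRecord:
    """Fit the full suite, classify, retry with dose drops, and select.

    Never raises for modeling failures; every outcome is recorded in the
    returned :class:`SessionRecord`.
    """
    config = config or RunConfig()
    rules = config.rules

    record = SessionRecord(
        dataset_id=dataset.dataset_id,
        outcome="too_few_doses",
        chemical_id=dataset.chemical_id,
        endpoint=dataset.endpoint,
    )
    if dataset.n_groups < rules.min_groups:
        record.reason = (
            f"{dataset.n_groups} dose groups; at least {rules.min_groups} "
            "(including control) are required"
        )
        return record

    current = dataset
    dropped = 0
    while True:
        fits = fit_suite(current, config)
        evaluated = []
        fit_records = []
        for fit in fits:
            bmdres = compute_bmd_result(fit)
            vc = classify(fit, bmdres, current, rules)
            evaluated.append((fit, bmdres, vc))
            fit_records.append(_fit_record(fit, bmdres, vc))
        record.attempts.append(AttemptRecord(doses_used=current.n_groups, fits=fit_records))

        viable = [(f, r) for f, r, vc in evaluated if vc.viability == VIABLE]
        if viable:
            record.outcome = "modeled"
            record.dropped_doses = dropped
            record.selected = select_model(viable, rules)
            return record

        if current.n_groups - 1 < rules.min_groups:
            record.outcome = "failed_modeling"
            record.dropped_doses = dropped
            record.reason = "no Viable fit; cannot drop further doses"
            return record
        current = current.drop_highest_dose()
        dropped += 1


def _fit_record(fit: DoseResponseResults, bmdres: BmdResult, vc: ViabilityClass) -> FitRecord:
    return FitRecord(
        model=fit.spec.label,
        params=[float(v) for v in fit.params],
        param_names=list(fit.spec.param_names),
        loglik=float(fit.loglik),
        aic=float(fit.aic),
        converged=bool(fit.converged),
        gof_pvalue=None if fit.gof_pvalue is None else float(fit.gof_pvalue),
        bmd=None if bmdres.bmd is None else float(bmdres.bmd),
        bmdl=None if bmdres.bmdl is None else float(bmdres.bmdl),
        viability=vc.viability,
        reasons=list(vc.reasons),
        warnings=list(vc.warnings) + sorted(bmdres.warnings - set(vc.warnings)),
        variance_mode=fit.spec.variance_mode,
        degree=fit.spec.degree,
        tests=fit.tests,
    )


def run_batch(datasets: Sequence[DoseResponseDataset],
              config: Optional[RunConfig] = None) -> list:
    """Run every dataset independently; input order never affects results."""
    config = config or RunConfig()
    return [run_dataset(ds, config) for ds in datasets]


# ======================================================================
# Per-chemical selection


@dataclass
class ChemicalSummary:
    """Selections for one chemical across its modeled datasets.

    ``lowest_bmd`` is the lowest selected BMD (preferring warning-free
    selections when any exist) with its own BMDL; ``lowest_bmdl`` is the
    lowest BMDL across all selections when it differs from the former.
    """

    chemical_id: str
    modeled: bool
    lowest_bmd: Optional[float] = None
    lowest_bmd_bmdl: Optional[float] = None
    lowest_bmd_dataset: Optional[str] = None
    lowest_bmd_has_warnings: bool = False
    lowest_bmdl: Optional[float] = None
    lowest_bmdl_dataset: Optional[str] = None
    n_datasets: int = 0
    n_modeled: int = 0


def select_for_chemical(records: Sequence[SessionRecord],
                        chemical_id: Optional[str] = None) -> ChemicalSummary:
    """Apply the per-chemical selection across a chemical's session records."""
    if chemical_id is None:
        ids = {r.chemical_id for r in records if r.chemical_id}
        chemical_id = ids.pop() if len(ids) == 1 else "unknown"
    modeled = [r for r in records if r.outcome == "modeled" and r.selected]
    summary = ChemicalSummary(
        chemical_id=chemical_id,
        modeled=bool(modeled),
        n_datasets=len(records),
        n_modeled=len(modeled),
    )
    if not modeled:
        return summary

    clean = [r for r in modeled if not r.selected.warnings]
    pool = clean if clean else modeled
    pick = min(pool, key=lambda r: r.selected.bmd)
    summary.lowest_bmd = pick.selected.bmd
    summary.lowest_bmd_bmdl = pick.selected.bmdl
    summary.lowest_bmd_dataset = pick.dataset_id
    summary.lowest_bmd_has_warnings = bool(pick.selected.warnings)

    low = min(modeled, key=lambda r: r.selected.bmdl)
    if low.selected.bmdl != summary.lowest_bmd_bmdl:
        summary.lowest_bmdl = low.selected.bmdl
        summary.lowest_bmdl_dataset = low.dataset_id
    return summary


def summarize_chemicals(records: Sequence[SessionRecord]) -> list:
    """Group session records by chemical and apply the selection to each."""
    groups: dict = {}
    for r in records:
        groups.setdefault(r.chemical_id or r.dataset_id, []).append(r)
    return [select_for_chemical(v, k) for k, v in groups.items()]
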
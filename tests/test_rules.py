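"""Viability classification, model selection, dose-drop retries, batch runs."""

import json

import numpy as np
import pytest

from bmdbatch import (
    BmdResult,
    DoseResponseDataset,
    RuleConfig,
    RunConfig,
    classify,
    run_batch,
    run_dataset,
    select_for_chemical,
    select_model,
)
from bmdbatch.datasets import Selection, SessionRecord
from bmdbatch.fitting import DoseResponseResults
from bmdbatch.models import Multistage, Polynomial
from bmdbatch.rules import QUESTIONABLE, UNUSABLE, VIABLE


def fake_fit(aic=100.0, gof_p=0.5, converged=True, variance_mode=None,
             tests=None, label="M"):
    """Hand-built fit carrying exactly the fields the decision logic reads."""
    ds = DoseResponseDataset("f", "dichotomous", [0, 10, 100], [10, 10, 10],
                             incidence=[0, 2, 5])
    spec = Multistage(1) if variance_mode is None else Polynomial(1, variance_mode=variance_mode)
    spec.name = label
    k = 2 if variance_mode is None else 3
    params = np.zeros(k)
    loglik = (2 * k - aic) / 2.0  # aic = -2 ll + 2 k
    fit = DoseResponseResults(spec, ds, params, loglik, converged)
    fit.gof_pvalue = gof_p
    fit.tests = tests
    return fit


def bmdres(bmd=10.0, bmdl=8.0, warnings=()):
    return BmdResult("extra_risk", 0.10, bmd, bmdl, warnings=set(warnings))


DS = DoseResponseDataset("f", "dichotomous", [0, 10, 100], [10, 10, 10],
                         incidence=[0, 2, 5])


class TestClassify:
    def test_gof_failure_questionable(self):
        vc = classify(fake_fit(gof_p=0.03), bmdres(), DS)
        assert vc.viability == QUESTIONABLE
        assert any("goodness of fit" in r for r in vc.reasons)

    def test_ratio_above_20_questionable(self):
        vc = classify(fake_fit(), bmdres(bmd=25.0, bmdl=1.0), DS)
        assert vc.viability == QUESTIONABLE
        assert any("ratio" in r for r in vc.reasons)

    def test_bmdl_above_highest_dose_questionable(self):
        vc = classify(fake_fit(), bmdres(bmd=200.0, bmdl=150.0), DS)
        assert vc.viability == QUESTIONABLE
        assert any("highest dose" in r for r in vc.reasons)

    def test_bmdl_not_estimable_questionable(self):
        vc = classify(fake_fit(), bmdres(bmd=10.0, bmdl=None), DS)
        assert vc.viability == QUESTIONABLE

    def test_not_converged_unusable(self):
        vc = classify(fake_fit(converged=False), bmdres(), DS)
        assert vc.viability == UNUSABLE

    def test_both_not_estimable_unusable(self):
        vc = classify(fake_fit(), bmdres(bmd=None, bmdl=None), DS)
        assert vc.viability == UNUSABLE

    def test_clean_fit_viable_no_warnings(self):
        vc = classify(fake_fit(gof_p=0.6), bmdres(bmd=10.0, bmdl=7.0), DS)
        assert vc.viability == VIABLE
        assert vc.warnings == []

    def test_warnings_are_not_fatal(self):
        res = bmdres(bmd=10.0, bmdl=1.8,
                     warnings={"bmd_extrap_gt3x", "ratio_gt5"})
        vc = classify(fake_fit(), res, DS)
        assert vc.viability == VIABLE
        assert set(vc.warnings) == {"bmd_extrap_gt3x", "ratio_gt5"}

    def test_constant_variance_fit_fails_test2(self):
        fit = fake_fit(variance_mode="constant", tests={"test2_p": 0.01, "test3_p": 0.5})
        vc = classify(fit, bmdres(), DS)
        assert vc.viability == QUESTIONABLE
        assert any("variance" in r for r in vc.reasons)

    def test_modeled_variance_fit_fails_test3(self):
        fit = fake_fit(variance_mode="modeled", tests={"test2_p": 0.01, "test3_p": 0.02})
        vc = classify(fit, bmdres(), DS)
        assert vc.viability == QUESTIONABLE

    def test_modeled_variance_fit_ignores_test2(self):
        fit = fake_fit(variance_mode="modeled", tests={"test2_p": 0.01, "test3_p": 0.6})
        vc = classify(fit, bmdres(), DS)
        assert vc.viability == VIABLE

    def test_tightening_gof_alpha_never_decreases_viable_count(self):
        fits = [(fake_fit(gof_p=p), bmdres()) for p in
                (0.005, 0.02, 0.04, 0.06, 0.2, 0.8)]
        counts = {}
        for alpha in (0.05, 0.01):
            rules = RuleConfig(gof_alpha=alpha)
            counts[alpha] = sum(
                classify(f, r, DS, rules).viability == VIABLE for f, r in fits
            )
        assert counts[0.01] >= counts[0.05]


class TestSelectModel:
    def test_lowest_aic_when_bmdls_close(self):
        viable = [
            (fake_fit(aic=100.2, label="m1"), bmdres(bmd=2.0, bmdl=1.0)),
            (fake_fit(aic=99.1, label="m2"), bmdres(bmd=5.0, bmdl=2.9)),
        ]
        sel = select_model(viable)
        assert sel.selection_rule == "lowest_aic"
        assert sel.bmdl == 2.9

    def test_lowest_bmdl_when_spread_exceeds_3x(self):
        viable = [
            (fake_fit(aic=100.2, label="m1"), bmdres(bmd=2.0, bmdl=1.0)),
            (fake_fit(aic=99.1, label="m2"), bmdres(bmd=5.0, bmdl=3.5)),
        ]
        sel = select_model(viable)
        assert sel.selection_rule == "lowest_bmdl"
        assert sel.bmdl == 1.0

    def test_aic_tie_averages(self):
        viable = [
            (fake_fit(aic=99.1, label="m1"), bmdres(bmd=8.0, bmdl=4.0)),
            (fake_fit(aic=99.1, label="m2"), bmdres(bmd=10.0, bmdl=6.0)),
        ]
        sel = select_model(viable)
        assert sel.selection_rule == "aic_tie_average"
        assert sel.bmd == pytest.approx(9.0)
        assert sel.bmdl == pytest.approx(5.0)
        assert len(sel.model_names) == 2

    def test_identical_tied_values_no_averaging(self):
        viable = [
            (fake_fit(aic=99.1, label="m1"), bmdres(bmd=8.0, bmdl=4.0)),
            (fake_fit(aic=99.1, label="m2"), bmdres(bmd=8.0, bmdl=4.0)),
        ]
        sel = select_model(viable)
        assert sel.selection_rule == "lowest_aic"

    def test_empty_list_is_contract_violation(self):
        with pytest.raises(ValueError):
            select_model([])


class TestRunDataset:
    def test_two_groups_too_few(self):
        ds = DoseResponseDataset("two", "dichotomous", [0, 10], [10, 10],
                                 incidence=[0, 3])
        rec = run_dataset(ds)
        assert rec.outcome == "too_few_doses"
        assert rec.attempts == []

    def test_three_groups_never_retries(self):
        # flat noise: no model is Viable, and dropping would leave 2 groups
        ds = DoseResponseDataset("flat3", "dichotomous", [0, 10, 100],
                                 [10, 10, 10], incidence=[1, 1, 1])
        cfg = RunConfig(models=["Multistage"], max_degree=1)
        rec = run_dataset(ds, cfg)
        assert rec.outcome == "failed_modeling"
        assert len(rec.attempts) == 1
        assert rec.dropped_doses == 0

    def test_dose_drop_recovers_modeling(self):
        # clean monotone response over 4 groups, then a crash at the top dose
        # that no monotone model fits
        ds = DoseResponseDataset(
            "drop", "dichotomous", [0, 5, 15, 50, 150],
            [100, 100, 100, 100, 100],
            incidence=[5, 15, 35, 70, 2],
        )
        rec = run_dataset(ds)
        assert rec.outcome == "modeled"
        assert rec.dropped_doses == 1
        assert len(rec.attempts) == 2
        assert rec.attempts[0].doses_used == 5
        assert rec.attempts[1].doses_used == 4
        assert all(f.viability != VIABLE for f in rec.attempts[0].fits)

    def test_retry_never_runs_when_first_attempt_viable(self, dich_dataset):
        rec = run_dataset(dich_dataset, RunConfig(models=["Multistage"], max_degree=2))
        assert rec.outcome == "modeled"
        assert len(rec.attempts) == 1
        assert rec.dropped_doses == 0

    def test_determinism_byte_identical(self, dich_dataset):
        cfg = RunConfig(models=["Multistage", "LogLogistic"], max_degree=2)
        a = json.dumps(run_dataset(dich_dataset, cfg).to_dict(), sort_keys=True)
        b = json.dumps(run_dataset(dich_dataset, cfg).to_dict(), sort_keys=True)
        assert a == b

    def test_batch_order_independence(self, dich_dataset, cancer_dataset):
        cfg = RunConfig(models=["Multistage"], max_degree=1)
        fwd = run_batch([dich_dataset, cancer_dataset], cfg)
        rev = run_batch([cancer_dataset, dich_dataset], cfg)
        by_id_fwd = {r.dataset_id: r for r in fwd}
        by_id_rev = {r.dataset_id: r for r in rev}
        for k in by_id_fwd:
            assert json.dumps(by_id_fwd[k].to_dict(), sort_keys=True) == \
                json.dumps(by_id_rev[k].to_dict(), sort_keys=True)

    def test_selection_only_uses_viable(self, dich_dataset):
        rec = run_dataset(dich_dataset, RunConfig(models=["Multistage", "Logistic"]))
        if rec.outcome == "modeled":
            viable_models = {
                f.model for a in rec.attempts for f in a.fits if f.viability == VIABLE
            }
            assert set(rec.selected.model_names) <= viable_models


class TestChemicalSelection:
    def _rec(self, ds_id, bmd, bmdl, warnings=(), chem="chem-1"):
        return SessionRecord(
            dataset_id=ds_id, outcome="modeled", chemical_id=chem,
            selected=Selection(["m"], bmd, bmdl, "lowest_aic", list(warnings)),
        )

    def test_prefers_warning_free_lowest_bmd(self):
        recs = [
            self._rec("a", 10.0, 4.0, warnings=["ratio_gt5"]),
            self._rec("b", 12.0, 6.0),
        ]
        summary = select_for_chemical(recs)
        assert summary.lowest_bmd == 12.0
        assert summary.lowest_bmd_bmdl == 6.0
        assert summary.lowest_bmdl == 4.0  # reported separately
        assert summary.lowest_bmdl_dataset == "a"

    def test_single_record_no_separate_bmdl(self):
        summary = select_for_chemical([self._rec("a", 10.0, 4.0)])
        assert summary.lowest_bmd == 10.0
        assert summary.lowest_bmd_bmdl == 4.0
        assert summary.lowest_bmdl is None

    def test_lowest_bmd_also_carries_lowest_bmdl(self):
        recs = [self._rec("a", 5.0, 2.0), self._rec("b", 9.0, 3.0)]
        summary = select_for_chemical(recs)
        assert summary.lowest_bmd == 5.0
        assert summary.lowest_bmd_bmdl == 2.0
        assert summary.lowest_bmdl is None

    def test_no_modeled_records(self):
        recs = [SessionRecord(dataset_id="a", outcome="failed_modeling",
                              chemical_id="chem-1")]
        summary = select_for_chemical(recs)
        assert not summary.modeled
        assert summary.lowest_bmd is None

    def test_all_with_warnings_falls_back_to_overall(self):
        recs = [
            self._rec("a", 10.0, 4.0, warnings=["ratio_gt5"]),
            self._rec("b", 12.0, 6.0, warnings=["bmd_extrap_gt3x"]),
        ]
        summary = select_for_chemical(recs)
        assert summary.lowest_bmd == 10.0
        assert summary.lowest_bmd_has_warnings
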
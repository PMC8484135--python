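"""Covariate screening statistics and the stepwise search decision logic.

The stepwise tests drive the search with a stubbed fitting backend so the
add/remove/threshold rules are exercised exactly; full fitting-based search
recovery is covered by the end-to-end acceptance suite.
"""

import numpy as np
import pandas as pd
import pytest

import popkin.covariates as cov_mod
from popkin.covariates import backward_eliminate, forward_include, screen, weight_base_model_step
from popkin.dataset import Dataset
from popkin.estimation import FitConfig, FitResult
from popkin.population import CovariateEffect, base_model, final_model


def _fake_fit_result(model, ofv, ebes=None, shrinkage=None):
    n = 0 if ebes is None else len(ebes)
    return FitResult(
        estimates=model,
        ofv=ofv,
        ebes=ebes if ebes is not None else pd.DataFrame(columns=["CL", "Vc", "Vp"]),
        eta_shrinkage=shrinkage or {"CL": 10.0, "Vc": 12.0, "Vp": 20.0},
        eps_shrinkage=12.0,
        cwres=np.zeros(n),
        convergence="converged",
        n_iter=1,
        config=FitConfig(),
    )


def _covariate_dataset(n=173, seed=71, wt_effect_on_cl=0.0):
    """Dataset stub + EBE table: etas with an optional leaked WT trend."""
    rng = np.random.default_rng(seed)
    wt = np.exp(rng.normal(np.log(64.0), 0.2, n))
    ldh = np.exp(rng.normal(np.log(215.0), 0.4, n))
    sex = rng.choice(["M", "F"], n)
    ids = [f"S{i:03d}" for i in range(n)]
    rows = []
    for i in range(n):
        rows.append(dict(ID=ids[i], TIME=0.0, EVID=1, AMT=900.0, DUR=0.02, DV=np.nan,
                         MDV=1, WT=wt[i], ALB=38.0, SEX=sex[i], THERAPY="mono", LDH=ldh[i]))
        rows.append(dict(ID=ids[i], TIME=1.0, EVID=0, AMT=0.0, DUR=0.0, DV=100.0,
                         MDV=0, WT=wt[i], ALB=38.0, SEX=sex[i], THERAPY="mono", LDH=ldh[i]))
    ds = Dataset(pd.DataFrame(rows))
    eta_cl = rng.normal(0.0, 0.29, n) + wt_effect_on_cl * np.log(wt / 64.0)
    ebes = pd.DataFrame({"CL": eta_cl, "Vc": rng.normal(0, 0.15, n),
                         "Vp": rng.normal(0, 0.6, n)}, index=ids)
    return ds, ebes


class TestScreen:
    def test_detects_leaked_weight_effect(self):
        ds, ebes = _covariate_dataset(wt_effect_on_cl=0.695)
        res = screen(_fake_fit_result(base_model(), 0.0, ebes), ds, parameters=("CL",))
        row = res[(res["parameter"] == "CL") & (res["covariate"] == "WT")].iloc[0]
        assert row["p_value"] < 0.05
        assert row["direction"] > 0

    def test_null_covariate_rarely_significant(self):
        hits = 0
        for seed in range(40):
            ds, ebes = _covariate_dataset(n=80, seed=100 + seed)
            res = screen(_fake_fit_result(base_model(), 0.0, ebes), ds,
                         parameters=("CL",), covariates=("LDH",))
            hits += int(res["p_value"].iloc[0] < 0.05)
        assert hits <= 7  # ~5% false-positive rate over 40 null replicates

    def test_categorical_uses_anova(self):
        ds, ebes = _covariate_dataset()
        res = screen(_fake_fit_result(base_model(), 0.0, ebes), ds, parameters=("Vc",),
                     covariates=("SEX",))
        assert (res["test"] == "anova").all()

    def test_constant_covariate_skipped(self):
        ds, ebes = _covariate_dataset()
        res = screen(_fake_fit_result(base_model(), 0.0, ebes), ds,
                     covariates=("ALB",))  # ALB constant in this stub
        assert res.empty


class _StubFitter:
    """Maps a model's covariate-effect name set to a preset OFV."""

    def __init__(self, ofvs: dict[frozenset, float]):
        self.ofvs = ofvs
        self.calls = 0

    def __call__(self, model, ds, config=None):
        self.calls += 1
        key = frozenset(e.name for e in model.covariate_effects)
        return _fake_fit_result(model, self.ofvs[key])


BASE_EFFECTS = frozenset(e.name for e in base_model().covariate_effects)


def _with(*names):
    return BASE_EFFECTS | set(names)


class TestForwardLogic:
    def test_subthreshold_candidate_not_added(self, monkeypatch):
        # dOFV 6.0 on 1 df misses the 6.635 threshold at p < 0.01
        stub = _StubFitter({frozenset(BASE_EFFECTS): 100.0,
                            frozenset(_with("ALB->CL")): 94.0})
        monkeypatch.setattr(cov_mod, "fit", stub)
        cand = [CovariateEffect("CL", "ALB", 0.0, "power", reference=38.0)]
        trace = forward_include(base_model(), cand, ds=None)
        assert trace.accepted_effects == []
        assert trace.steps[-1].accepted is False

    def test_largest_drop_wins_then_next(self, monkeypatch):
        stub = _StubFitter({
            frozenset(BASE_EFFECTS): 100.0,
            frozenset(_with("ALB->CL")): 88.0,
            frozenset(_with("SEX->Vc")): 85.0,
            frozenset(_with("ALB->CL", "SEX->Vc")): 75.0,
        })
        monkeypatch.setattr(cov_mod, "fit", stub)
        cands = [CovariateEffect("CL", "ALB", 0.0, "power", reference=38.0),
                 CovariateEffect("Vc", "SEX", 0.0, "categorical", category="F")]
        trace = forward_include(base_model(), cands, ds=None)
        assert trace.accepted_effects == ["SEX->Vc", "ALB->CL"]

    def test_stops_when_no_candidate_qualifies(self, monkeypatch):
        stub = _StubFitter({
            frozenset(BASE_EFFECTS): 100.0,
            frozenset(_with("ALB->CL")): 90.0,
            frozenset(_with("SEX->Vc")): 98.0,
            frozenset(_with("ALB->CL", "SEX->Vc")): 87.0,
        })
        monkeypatch.setattr(cov_mod, "fit", stub)
        cands = [CovariateEffect("CL", "ALB", 0.0, "power", reference=38.0),
                 CovariateEffect("Vc", "SEX", 0.0, "categorical", category="F")]
        trace = forward_include(base_model(), cands, ds=None)
        assert trace.accepted_effects == ["ALB->CL"]  # second add: dOFV 3 only


class TestBackwardLogic:
    def test_weak_effect_removed_strong_retained(self, monkeypatch):
        full = final_model()
        names = frozenset(e.name for e in full.covariate_effects)
        ofvs = {names: 100.0}
        for n in names:
            # removing ALB->CL costs only 5; everything else costs > 10.83
            ofvs[frozenset(names - {n})] = 105.0 if n == "ALB->CL" else 120.0
        reduced = names - {"ALB->CL"}
        for n in reduced:
            ofvs[frozenset(reduced - {n})] = 130.0
        stub = _StubFitter(ofvs)
        monkeypatch.setattr(cov_mod, "fit", stub)
        trace = backward_eliminate(full, ds=None)
        removed = [s.effect for s in trace.steps if s.accepted]
        assert removed == ["ALB->CL"]
        assert {e.name for e in trace.final.covariate_effects} == reduced

    def test_empty_effect_set_is_empty_trace(self, monkeypatch):
        import dataclasses

        bare = dataclasses.replace(final_model(), covariate_effects=())
        stub = _StubFitter({frozenset(): 100.0})
        monkeypatch.setattr(cov_mod, "fit", stub)
        trace = backward_eliminate(bare, ds=None)
        assert trace.steps == []


class TestWeightStep:
    def test_joint_add_then_prune(self, monkeypatch):
        # mirrors the narrative: adding weight on all four parameters drops
        # the OFV by 72.2 (p < 0.01, 4 df); removing it from Q and Vp costs
        # only 6.558 (p = 0.038 >= 0.01 on 2 df), so the pruned model wins
        import dataclasses

        bare = dataclasses.replace(base_model(), covariate_effects=())
        all4 = {"WT->CL", "WT->Vc", "WT->Q", "WT->Vp"}
        stub = _StubFitter({
            frozenset(): -3200.8,
            frozenset(all4): -3273.0,
            frozenset({"WT->CL", "WT->Vc"}): -3266.442,
        })
        monkeypatch.setattr(cov_mod, "fit", stub)
        trace = weight_base_model_step(bare, ds=None)
        assert trace.steps[0].accepted and trace.steps[0].df == 4
        assert trace.steps[0].dofv == pytest.approx(72.2, abs=0.01)
        assert trace.steps[1].accepted  # prune kept
        assert trace.steps[1].p_value == pytest.approx(0.038, abs=0.001)
        assert {e.name for e in trace.final.covariate_effects} == {"WT->CL", "WT->Vc"}

    def test_prune_rejected_when_weight_matters_on_q_vp(self, monkeypatch):
        import dataclasses

        bare = dataclasses.replace(base_model(), covariate_effects=())
        all4 = {"WT->CL", "WT->Vc", "WT->Q", "WT->Vp"}
        stub = _StubFitter({
            frozenset(): 0.0,
            frozenset(all4): -72.0,
            frozenset({"WT->CL", "WT->Vc"}): -50.0,  # rise 22, p << 0.01
        })
        monkeypatch.setattr(cov_mod, "fit", stub)
        trace = weight_base_model_step(bare, ds=None)
        assert not trace.steps[1].accepted
        assert {e.name for e in trace.final.covariate_effects} == all4
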
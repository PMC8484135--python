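"""Mixed-effects engine: conditional modes, OFV, residuals, outlier loop,
shrinkage and the likelihood-ratio test."""

import dataclasses
import math

import numpy as np
import pytest

from conftest import perturbed_start
from popkin import estimation
from popkin.dataset import Dataset
from popkin.estimation import FitConfig, cwres, ebe_estimate, fit, lrt, ofv, outlier_refit
from popkin.population import CovariateRecord, OmegaSpec, PopulationModel, final_model
from popkin.structural import Regimen, solve_profile
from popkin.synth import DesignSpec, generate_dataset

SMALL_CONFIG = FitConfig()


def _zero_omega(model: PopulationModel, sigma=None) -> PopulationModel:
    return dataclasses.replace(
        model,
        omega=OmegaSpec(model.omega.names, np.zeros((len(model.omega.names),) * 2)),
        sigma=sigma if sigma is not None else model.sigma,
    )


def _small_population(n, seed=0):
    rng = np.random.default_rng(seed)
    return [
        CovariateRecord(
            wt=float(rng.uniform(45, 95)),
            alb=float(rng.uniform(28, 46)),
            sex=rng.choice(["M", "F"]),
            therapy=rng.choice(["mono", "combo"]),
        )
        for _ in range(n)
    ]


class TestLrt:
    def test_reported_thresholds(self):
        assert lrt(10.83, 0.0, 1) == pytest.approx(0.001, rel=5e-3)
        assert lrt(6.635, 0.0, 1) == pytest.approx(0.01, rel=5e-3)
        assert lrt(6.558, 0.0, 2) == pytest.approx(0.038, abs=5e-4)

    def test_agrees_with_closed_forms(self):
        # chi-squared survival: df=1 -> erfc(sqrt(x/2)); df=2 -> exp(-x/2)
        for x in (0.5, 2.0, 6.635, 10.83, 20.0):
            assert lrt(x, 0.0, 1) == pytest.approx(math.erfc(math.sqrt(x / 2.0)), abs=1e-10)
            assert lrt(x, 0.0, 2) == pytest.approx(math.exp(-x / 2.0), abs=1e-10)

    def test_negative_delta_reports_one(self):
        assert lrt(5.0, 6.0, 1) == 1.0


class TestEbes:
    def test_zero_omega_gives_zero_ebes(self):
        model = _zero_omega(final_model())
        pop = _small_population(4, seed=1)
        ds = generate_dataset(pop, DesignSpec(15.0), model, seed=2, method="analytic")
        ebes = ebe_estimate(model, ds)
        assert np.allclose(ebes.to_numpy(), 0.0)

    def test_recovers_generative_eta_at_vanishing_noise(self):
        model = final_model()
        true_eta = {"CL": 0.25, "Vc": -0.12, "Vp": 0.4}
        quiet = dataclasses.replace(model, sigma=1e-5)
        from popkin.population import individual_params

        cov = CovariateRecord(wt=64.0)
        p = individual_params(quiet, cov, true_eta)
        des = DesignSpec(15.0, sample_times=tuple(np.linspace(0.05, 110.0, 14)))
        reg = des.regimen(cov.wt)
        conc = solve_profile(p, reg, des.sample_times, method="ode").concentrations
        import pandas as pd

        rows = [dict(ID="X", TIME=t, EVID=1, AMT=a, DUR=d, DV=np.nan, MDV=1,
                     WT=64.0, ALB=38.0, SEX="M", THERAPY="mono")
                for t, a, d in des.dose_events(cov.wt)]
        rows += [dict(ID="X", TIME=t, EVID=0, AMT=0.0, DUR=0.0, DV=c, MDV=0,
                      WT=64.0, ALB=38.0, SEX="M", THERAPY="mono")
                 for t, c in zip(des.sample_times, conc)]
        ds = Dataset(pd.DataFrame(sorted(rows, key=lambda r: (r["TIME"], r["EVID"]))))
        ebes = ebe_estimate(quiet, ds)
        for k, v in true_eta.items():
            assert ebes.loc["X", k] == pytest.approx(v, abs=1e-3)


class TestOfv:
    def test_collapses_to_fixed_effects_likelihood_without_iiv(self):
        model = _zero_omega(final_model())
        pop = _small_population(3, seed=3)
        ds = generate_dataset(pop, DesignSpec(15.0), model, seed=4, method="analytic")
        value = ofv(model, ds)
        # independent route: population predictions via the structural solver
        from popkin.population import individual_params

        expected = 0.0
        for sid in ds.subject_ids:
            sub = ds.frame[ds.frame["ID"] == sid]
            obs = sub[(sub["EVID"] == 0) & (sub["MDV"] == 0)]
            doses = sub[sub["EVID"] == 1]
            reg = Regimen.from_arrays(doses["TIME"], doses["AMT"], doses["DUR"].to_numpy())
            p = individual_params(model, ds.covariate_record(sid))
            p = dataclasses.replace(p, Vmax=0.0)
            pred = solve_profile(p, reg, obs["TIME"].to_numpy(), method="analytic")
            z = (np.log(obs["DV"].to_numpy()) - np.log(pred.concentrations)) / model.sigma
            expected += float(np.sum(z**2 + math.log(2 * math.pi * model.sigma**2)))
        assert value == pytest.approx(expected, rel=1e-6)

    def test_duplicating_subjects_doubles_ofv(self):
        model = final_model()
        pop = _small_population(5, seed=5)
        ds = generate_dataset(pop, DesignSpec(15.0), model, seed=6, method="analytic")
        f = ds.frame
        f2 = f.copy()
        f2["ID"] = f2["ID"] + "dup"
        import pandas as pd

        doubled = Dataset(pd.concat([f, f2], ignore_index=True))
        assert ofv(model, doubled) == pytest.approx(2 * ofv(model, ds), rel=1e-8)


@pytest.fixture(scope="module")
def quiet_dataset():
    model = _zero_omega(final_model(), sigma=1e-3)
    pop = _small_population(30, seed=7)
    return model, generate_dataset(pop, DesignSpec(15.0), model, seed=8, method="analytic")


class TestFit:
    #: the deterministic regression limit: Omega = 0 and sigma known
    FIXED = FitConfig(estimate_omega=False, estimate_sigma=False)

    def test_recovers_theta_in_low_noise_limit(self, quiet_dataset):
        model, ds = quiet_dataset
        start = perturbed_start(model, 1.3)
        res = fit(start, ds, self.FIXED)
        tv, truth = res.estimates.typical_values(), model.typical_values()
        for p in ("CL", "Vc", "Q", "Vp"):
            assert tv[p] == pytest.approx(truth[p], rel=0.01)

    def test_optimum_independent_of_start(self, quiet_dataset):
        model, ds = quiet_dataset
        sa = dataclasses.replace(perturbed_start(model, 2.0), sigma=model.sigma)
        sb = dataclasses.replace(perturbed_start(model, 0.75), sigma=model.sigma)
        a = fit(sa, ds, self.FIXED)
        b = fit(sb, ds, self.FIXED)
        assert a.estimates.typical_values()["CL"] == pytest.approx(
            b.estimates.typical_values()["CL"], rel=5e-3
        )
        assert a.ofv == pytest.approx(b.ofv, abs=0.5)


@pytest.fixture(scope="module")
def planted():
    model = final_model()
    pop = _small_population(30, seed=9)
    clean = generate_dataset(pop, DesignSpec(15.0), model, seed=10, method="analytic")
    dirty = generate_dataset(pop, DesignSpec(15.0), model, seed=10, method="analytic",
                             plant_outliers=3)
    ratio = dirty.observations()["DV"].to_numpy() / clean.observations()["DV"].to_numpy()
    planted_idx = np.flatnonzero(np.abs(np.log(ratio)) > 1e-9)
    return model, dirty, planted_idx


class TestCwresAndOutliers:
    def test_planted_outliers_exceed_threshold(self, planted):
        model, dirty, planted_idx = planted
        w = cwres(model, dirty)
        flagged = set(np.flatnonzero(np.abs(w) > 5.0))
        assert set(planted_idx) <= flagged
        # whitening can drag same-subject neighbours of an outlier over the
        # threshold, but never observations in clean subjects
        obs_ids = dirty.observations()["ID"].to_numpy()
        dirty_subjects = set(obs_ids[list(planted_idx)])
        assert set(obs_ids[list(flagged)]) == dirty_subjects

    def test_outlier_refit_excludes_exactly_the_planted_points(self, planted):
        model, dirty, planted_idx = planted
        res, excluded = outlier_refit(model, dirty, threshold=5.0)
        assert len(excluded) == len(planted_idx)
        obs = dirty.observations().reset_index()
        assert set(excluded["TIME"]) == set(obs.loc[planted_idx, "TIME"])

    def test_infinite_threshold_is_plain_fit(self):
        model = final_model()
        pop = _small_population(10, seed=11)
        ds = generate_dataset(pop, DesignSpec(15.0), model, seed=12, method="analytic")
        res, excluded = outlier_refit(model, ds, threshold=np.inf)
        assert excluded.empty
        assert res.ofv == pytest.approx(fit(model, ds).ofv, abs=0.2)


class TestShrinkage:
    def test_shrinkage_increases_with_sparsity(self):
        model = final_model()
        pop = _small_population(60, seed=13)
        rich = generate_dataset(pop, DesignSpec(15.0), model, seed=14, method="analytic")
        sparse_design = DesignSpec(15.0, sample_times=(1.0, 14.0))
        sparse = generate_dataset(pop, sparse_design, model, seed=14, method="analytic")

        def cl_shrink(ds):
            ebes = ebe_estimate(model, ds)
            omega_cl = math.sqrt(model.omega.variance("CL"))
            return 100.0 * (1.0 - ebes["CL"].std() / omega_cl)

        rich_s, sparse_s = cl_shrink(rich), cl_shrink(sparse)
        assert rich_s < 20.0
        assert sparse_s > rich_s
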
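"""Covariate model, IIV sampling, residual model and reporting conventions."""

import math

import numpy as np
import pytest

from popkin.population import (
    CovariateEffect,
    CovariateRecord,
    OmegaSpec,
    PopulationModel,
    base_model,
    covariate_factor,
    final_model,
    iiv_cv_percent,
    individual_params,
    log_likelihood_term,
    observe,
    sample_etas,
)

REF = CovariateRecord(wt=64.0, alb=38.0, sex="M", therapy="mono")


class TestCovariateFactor:
    @pytest.mark.parametrize(
        "effect, cov, expected",
        [
            # 10% weight decrease: (57.6/64)^0.695 = 0.9294 -> 7.06% lower CL
            (CovariateEffect("CL", "WT", 0.695, "power", reference=64.0),
             CovariateRecord(wt=57.6), 0.9294),
            # 10% albumin decrease: (34.2/38)^-0.657 -> 7.17% higher CL
            (CovariateEffect("CL", "ALB", -0.657, "power", reference=38.0),
             CovariateRecord(wt=64.0, alb=34.2), 1.0717),
            # female: exp(-0.164) -> 15.1% smaller Vc
            (CovariateEffect("Vc", "SEX", -0.164, "categorical", category="F"),
             CovariateRecord(wt=64.0, sex="F"), math.exp(-0.164)),
            # combotherapy: exp(-0.200) -> 18.1% lower CL
            (CovariateEffect("CL", "THERAPY", -0.200, "categorical", category="combo"),
             CovariateRecord(wt=64.0, therapy="combo"), math.exp(-0.200)),
        ],
    )
    def test_reported_effect_sizes(self, effect, cov, expected):
        assert covariate_factor(effect, cov) == pytest.approx(expected, rel=5e-4)

    def test_identity_at_reference(self):
        for e in final_model().covariate_effects:
            assert covariate_factor(e, REF) == pytest.approx(1.0)

    def test_percent_change_identities(self):
        assert 1 - 0.9**0.695 == pytest.approx(0.0706, abs=5e-4)
        assert 1 - 0.9**0.369 == pytest.approx(0.0381, abs=5e-4)
        assert 0.9**-0.657 - 1 == pytest.approx(0.0717, abs=5e-4)
        assert 1 - math.exp(-0.164) == pytest.approx(0.151, abs=5e-4)
        assert 1 - math.exp(-0.200) == pytest.approx(0.181, abs=5e-4)


class TestIndividualParams:
    def test_reference_patient_reproduces_typical_values(self):
        p = individual_params(final_model(), REF)
        assert p.CL == pytest.approx(0.311)
        assert p.Vc == pytest.approx(3.58)
        assert p.Q == pytest.approx(0.952)
        assert p.Vp == pytest.approx(2.71)
        assert p.Vmax == pytest.approx(2.80)
        assert p.Km == pytest.approx(4.45)

    def test_ten_percent_lighter_patient(self):
        p = individual_params(final_model(), CovariateRecord(wt=57.6))
        assert p.CL == pytest.approx(0.289, rel=5e-3)
        assert p.Vc == pytest.approx(3.45, rel=5e-3)

    def test_effect_order_irrelevant(self):
        m = final_model()
        shuffled = PopulationModel(
            m.theta, m.omega, m.sigma, tuple(reversed(m.covariate_effects))
        )
        cov = CovariateRecord(wt=50.0, alb=30.0, sex="F", therapy="combo")
        a, b = individual_params(m, cov), individual_params(shuffled, cov)
        assert a == b

    def test_eta_acts_multiplicatively(self):
        p0 = individual_params(final_model(), REF)
        p1 = individual_params(final_model(), REF, {"CL": 0.3})
        assert p1.CL == pytest.approx(p0.CL * math.exp(0.3))


class TestSampleEtas:
    def test_zero_omega_gives_zero_etas(self):
        omega = OmegaSpec.from_variances({"CL": 0.0, "Vc": 0.0})
        etas = sample_etas(omega, 50, seed=1)
        assert (etas.to_numpy() == 0).all()

    def test_cl_vc_correlation_matches_omega(self):
        # corr = 0.0128 / sqrt(0.0854 * 0.0221) = 0.295
        etas = sample_etas(final_model().omega, 100_000, seed=2)
        r = np.corrcoef(etas["CL"], etas["Vc"])[0, 1]
        assert r == pytest.approx(0.295, abs=0.01)

    def test_geometric_mean_of_exp_eta_is_one(self):
        etas = sample_etas(final_model().omega, 200_000, seed=3)
        gm = np.exp(np.log(np.exp(etas["CL"])).mean())
        assert gm == pytest.approx(1.0, abs=0.01)

    def test_reproducible_under_seed(self):
        a = sample_etas(final_model().omega, 100, seed=7)
        b = sample_etas(final_model().omega, 100, seed=7)
        assert (a.to_numpy() == b.to_numpy()).all()


class TestResidualModel:
    def test_sigma_zero_is_identity(self):
        pred = np.array([1.0, 50.0, 300.0])
        assert np.array_equal(observe(pred, 0.0, seed=1), pred)

    def test_residual_cv_matches_reported(self):
        # sigma = 0.146 -> CV = sqrt(exp(sigma^2) - 1) = 14.68%
        rng = np.random.default_rng(4)
        y = observe(np.full(200_000, 100.0), 0.146, rng)
        cv = y.std() / y.mean()
        assert cv == pytest.approx(math.sqrt(math.expm1(0.146**2)), abs=0.002)
        assert 0.140 < cv < 0.152  # the reported 14.5-14.6% band, within MC error

    def test_loglik_maximal_at_obs_equal_pred(self):
        at_pred = log_likelihood_term(50.0, 50.0, 0.146)
        assert at_pred > log_likelihood_term(55.0, 50.0, 0.146)
        assert at_pred > log_likelihood_term(45.0, 50.0, 0.146)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            log_likelihood_term(-1.0, 50.0, 0.146)
        with pytest.raises(ValueError):
            observe(np.array([0.0]), 0.1, seed=1)


class TestIivReporting:
    @pytest.mark.parametrize(
        "omega_sq, expected",
        [(0.0854, 29.2), (0.0221, 14.9), (0.0, 0.0)],
    )
    def test_cv_percent_convention(self, omega_sq, expected):
        assert iiv_cv_percent(omega_sq) == pytest.approx(expected, abs=0.05)

    def test_variance_reduction_base_to_final(self):
        red_cl = 1 - 0.0854 / 0.111
        red_vc = 1 - 0.0221 / 0.0270
        assert red_cl == pytest.approx(0.231, abs=0.0015)
        assert red_vc == pytest.approx(0.184, abs=0.005)

    def test_lognormal_convention_available(self):
        assert iiv_cv_percent(0.0854, "lognormal") == pytest.approx(
            100 * math.sqrt(math.expm1(0.0854)), rel=1e-12
        )


class TestSerialization:
    def test_yaml_round_trip(self, tmp_path):
        m = final_model()
        path = tmp_path / "model.yaml"
        m.save(path)
        back = PopulationModel.load(path)
        assert back.typical_values() == pytest.approx(m.typical_values())
        assert back.sigma == pytest.approx(m.sigma)
        assert np.allclose(back.omega.matrix, m.omega.matrix)
        assert back.covariate_effects == m.covariate_effects

    def test_base_model_is_weight_only(self):
        names = {e.name for e in base_model().covariate_effects}
        assert names == {"WT->CL", "WT->Vc"}


class TestValidation:
    def test_omega_must_be_psd(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            OmegaSpec(("CL", "Vc"), np.array([[0.01, 0.5], [0.5, 0.01]]))

    def test_covariate_record_levels(self):
        with pytest.raises(ValueError):
            CovariateRecord(wt=60.0, sex="X")
        with pytest.raises(ValueError):
            CovariateRecord(wt=-5.0)
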
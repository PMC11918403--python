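"""Hierarchical model log-densities, fitting machinery and diagnostics."""

import arviz as az
import numpy as np
import pandas as pd
import pytest

from ordrisk import ModelSpec, SamplerSettings, fit_model
from ordrisk.inference import diagnostics, extract_subject_estimates
from ordrisk.inference.hierarchical import (
    PosteriorFit,
    _build_model,
    load_fit,
    save_fit,
)

ALL_SPECS = [
    ModelSpec("classic_utility"),
    ModelSpec("classic_utility", "trembling_hand"),
    ModelSpec("estimated_value"),
    ModelSpec("no_subjective_params"),
]

FAST = SamplerSettings(draws=120, tune=120, chains=2, seed=3)


class TestModelSpec:
    def test_trembling_requires_classic(self):
        with pytest.raises(ValueError):
            ModelSpec("estimated_value", "trembling_hand")

    def test_unknown_names_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("prospect_theory")
        with pytest.raises(ValueError):
            ModelSpec("classic_utility", "probit")


class TestLogDensityGradients:
    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.name)
    def test_gradient_matches_finite_differences(self, spec, small_filtered):
        model, _ = _build_model(spec, small_filtered)
        rng = np.random.default_rng(8)
        z = rng.normal(0.0, 0.6, model.ndim)
        lp, grad = model.logp_grad(z)
        assert np.isfinite(lp)
        eps = 1e-6
        for i in rng.choice(model.ndim, size=min(model.ndim, 12), replace=False):
            zp, zm = z.copy(), z.copy()
            zp[i] += eps
            zm[i] -= eps
            num = (model.logp_grad(zp)[0] - model.logp_grad(zm)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-6)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.name)
    def test_pointwise_loglik_sums_into_joint(self, spec, small_filtered):
        # the likelihood part of logp equals the pointwise sum: shifting one
        # choice flips exactly that trial's contribution
        model, td = _build_model(spec, small_filtered)
        z = np.random.default_rng(0).normal(0.0, 0.3, model.ndim)
        ll = model.pointwise_loglik(z)
        assert ll.shape == (td.n_trials,)
        assert np.all(ll < 0)
        lp_before = model.logp_grad(z)[0]
        model.d.choice = model.d.choice.copy()
        model.d.choice[0] = 1.0 - model.d.choice[0]
        delta_joint = model.logp_grad(z)[0] - lp_before
        delta_point = model.pointwise_loglik(z)[0] - ll[0]
        assert delta_joint == pytest.approx(delta_point)


@pytest.fixture(scope="module")
def classic_fit(small_filtered):
    return fit_model(ModelSpec("classic_utility"), small_filtered, FAST)


@pytest.fixture(scope="module")
def ev_fit(small_filtered):
    return fit_model(ModelSpec("estimated_value"), small_filtered, FAST)


class TestFitModel:
    def test_posterior_shapes_and_support(self, classic_fit, small_filtered):
        post = classic_fit.idata.posterior
        S = small_filtered.n_subjects
        assert post["alpha"].shape == (2, 120, S)
        assert float(post["alpha"].min()) > 0
        assert float(post["alpha"].max()) < 2
        assert float(np.abs(post["beta"]).max()) <= 1.5
        assert float(post["gamma"].min()) > 0

    def test_pointwise_loglik_attached(self, classic_fit, small_filtered):
        ll = classic_fit.pointwise_loglik
        n_trials = (~small_filtered.table["is_catch"]).sum()
        assert ll.shape == (240, n_trials)
        assert np.all(np.isfinite(ll))

    def test_nu_cumulative_monotone_in_every_draw(self, ev_fit):
        nu = ev_fit.idata.posterior["nu"].to_numpy()
        cum = np.cumsum(nu, axis=-1)
        assert np.all(np.diff(cum, axis=-1) >= 0)

    def test_better_than_shuffled_choices(self, small_filtered):
        # the model's predictive density collapses when choices are shuffled
        fit = fit_model(ModelSpec("no_subjective_params"), small_filtered, FAST)
        mean_ll = fit.pointwise_loglik.sum(axis=1).mean()
        shuffled = small_filtered.table.copy()
        rng = np.random.default_rng(1)
        shuffled["chose_lottery"] = rng.permutation(
            shuffled["chose_lottery"].to_numpy()
        )
        from ordrisk.simulate import ChoiceDataset

        fit_shuf = fit_model(
            ModelSpec("no_subjective_params"),
            ChoiceDataset(table=shuffled),
            FAST,
        )
        mean_ll_shuf = fit_shuf.pointwise_loglik.sum(axis=1).mean()
        assert np.isfinite(mean_ll) and np.isfinite(mean_ll_shuf)
        assert mean_ll > mean_ll_shuf

    def test_medical_domain_rejects_classic_model(self):
        from ordrisk import build_design, draw_agents, simulate_choices
        from ordrisk.simulate import ChoiceDataset

        rng = np.random.default_rng(0)
        monetary = simulate_choices(
            draw_agents(3, rng, 0.3), build_design("in_person", "monetary"), rng
        )
        medical = ChoiceDataset(
            table=monetary.table.assign(domain="medical"),
        )
        with pytest.raises(ValueError, match="amounts"):
            fit_model(ModelSpec("classic_utility"), medical, FAST)


class TestDiagnostics:
    def _fit_from_draws(self, draws):
        idata = az.from_dict(
            posterior={"x": draws},
            log_likelihood={"chose_lottery": np.zeros((*draws.shape[:2], 3))},
            sample_stats={"diverging": np.zeros(draws.shape[:2], dtype=bool)},
        )
        return PosteriorFit(
            idata=idata,
            spec=ModelSpec("no_subjective_params"),
            subject_ids=[],
            n_trials=3,
        )

    def test_identical_chains_have_unit_rhat(self):
        # split R-hat still halves each chain, so copies give ~1, not exactly 1
        chain = np.random.default_rng(0).normal(size=(1, 400))
        fit = self._fit_from_draws(np.repeat(chain, 4, axis=0))
        assert diagnostics(fit)["max_rhat"] == pytest.approx(1.0, abs=0.01)

    def test_white_noise_chains_pass(self):
        draws = np.random.default_rng(1).normal(size=(4, 1000))
        d = diagnostics(self._fit_from_draws(draws))
        assert d["max_rhat"] < 1.01
        assert d["min_ess"] > 3000

    def test_offset_chain_detected(self):
        draws = np.random.default_rng(2).normal(size=(4, 500))
        draws[0] += 10.0
        assert diagnostics(self._fit_from_draws(draws))["max_rhat"] > 1.5

    def test_single_chain_rejected(self):
        draws = np.random.default_rng(3).normal(size=(1, 500))
        with pytest.raises(ValueError, match="chains"):
            diagnostics(self._fit_from_draws(draws))


class TestSubjectEstimates:
    def test_classic_columns(self, classic_fit, small_filtered):
        est = extract_subject_estimates(classic_fit)
        assert len(est) == small_filtered.n_subjects
        for col in ("alpha_mean", "beta_mean", "gamma_mean", "alpha_sd"):
            assert col in est.columns

    def test_ev_increment_columns_nonnegative(self, ev_fit):
        est = extract_subject_estimates(ev_fit)
        for lvl in (1, 2, 3, 4):
            assert (est[f"nu{lvl}_mean"] >= 0).all()

    def test_baseline_has_empty_table(self, small_filtered):
        fit = fit_model(ModelSpec("no_subjective_params"), small_filtered, FAST)
        assert extract_subject_estimates(fit).empty

    def test_absent_parameter_request_errors(self, classic_fit):
        est = extract_subject_estimates(classic_fit, parameters=["beta"])
        assert list(est.columns) == ["beta_mean", "beta_sd"]
        with pytest.raises(KeyError, match="nu"):
            extract_subject_estimates(classic_fit, parameters=["nu"])


class TestReproducibility:
    def test_same_settings_same_posterior(self, small_filtered):
        settings = SamplerSettings(draws=100, tune=100, chains=2, seed=77)
        a = fit_model(ModelSpec("no_subjective_params"), small_filtered, settings)
        b = fit_model(ModelSpec("no_subjective_params"), small_filtered, settings)
        assert np.array_equal(
            a.idata.posterior["gamma_shared"].to_numpy(),
            b.idata.posterior["gamma_shared"].to_numpy(),
        )


class TestPersistence:
    def test_roundtrip(self, classic_fit, tmp_path):
        path = save_fit(classic_fit, tmp_path / "fit.nc")
        idata = load_fit(path)
        assert np.allclose(
            idata.posterior["alpha"].to_numpy(),
            classic_fit.idata.posterior["alpha"].to_numpy(),
        )
        assert np.allclose(
            idata.log_likelihood["chose_lottery"].to_numpy(),
            classic_fit.idata.log_likelihood["chose_lottery"].to_numpy(),
        )
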
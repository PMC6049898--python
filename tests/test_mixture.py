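"""The two-component product-marginal mixture: densities, EM, posteriors."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from cpiem import (
    DegenerateDataError,
    MarginalParams,
    MixtureModel,
    classify_pairs,
    fit_mixture_em,
    log_likelihood,
    marginal_density,
    posterior_coop,
    read_model,
    write_model,
)
from cpiem.simulate import SimulationConfig, simulate_intensity_pairs

REF = SimulationConfig()  # 4000 pairs, w=0.4, reference lognormal marginals


def _model(family, ct, cp, nt, npart, w):
    mk = lambda loc_scale: MarginalParams(family, *loc_scale)
    return MixtureModel(
        family=family, coop_target=mk(ct), coop_partner=mk(cp),
        noncoop_target=mk(nt), noncoop_partner=mk(npart), weight=w,
        log_likelihood=0.0, n_iterations=0, converged=True,
    )


class TestMarginalDensity:
    def test_lognormal_at_one(self):
        p = MarginalParams("lognormal", 0.0, 1.0)
        assert marginal_density(p, 1.0) == pytest.approx(1 / math.sqrt(2 * math.pi))

    def test_lognormal_closed_form_at_e(self):
        # (1/(x sigma sqrt(2 pi))) exp(-(ln x - mu)^2 / (2 sigma^2)) at x = e
        p = MarginalParams("lognormal", 0.0, 1.0)
        expected = math.exp(-0.5) / (math.e * math.sqrt(2 * math.pi))
        assert marginal_density(p, math.e) == pytest.approx(expected, rel=1e-12)

    def test_gamma_shape_one_is_exponential(self):
        p = MarginalParams("gamma", 1.0, 2.0)
        assert marginal_density(p, 2.0) == pytest.approx(0.5 * math.exp(-1.0))

    def test_gaussian_at_mean(self):
        p = MarginalParams("gaussian", 3.0, 2.0)
        assert marginal_density(p, 3.0) == pytest.approx(
            1 / (2.0 * math.sqrt(2 * math.pi))
        )

    @pytest.mark.parametrize("family", ["lognormal", "gamma"])
    def test_nonpositive_support_error(self, family):
        p = MarginalParams(family, 1.0, 1.0)
        with pytest.raises(ValueError):
            marginal_density(p, -1.0)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            MarginalParams("lognormal", 0.0, 0.0)


class TestPosterior:
    def test_identical_components_return_weight(self):
        m = _model("lognormal", (1, 0.5), (2, 0.6), (1, 0.5), (2, 0.6), w=0.37)
        x = np.array([0.5, 1.0, 5.0, 50.0])
        assert posterior_coop(m, (x, x)) == pytest.approx([0.37] * 4)

    def test_hand_computed_bayes_ratio(self):
        # partner marginals identical across components, so they cancel
        m = _model("lognormal", (0, 1), (0, 1), (1, 1), (0, 1), w=0.5)
        fc = 1 / math.sqrt(2 * math.pi)
        fn = fc * math.exp(-0.5)
        expected = fc / (fc + fn)  # = 0.39894/(0.39894+0.24197) = 0.6224...
        assert posterior_coop(m, (np.array([1.0]), np.array([1.0])))[
            0
        ] == pytest.approx(expected, rel=1e-10)

    def test_weak_target_tail_dominates(self):
        m = _model("lognormal", (0, 1), (0, 1), (1, 1), (0, 1), w=0.5)
        post = posterior_coop(m, (np.array([1e-8]), np.array([1.0])))
        assert post[0] > 0.999

    def test_bounds(self):
        m = _model("lognormal", (1, 0.5), (2, 0.6), (2.5, 0.5), (2.1, 0.6), 0.4)
        xy, _ = simulate_intensity_pairs(REF, seed=5)
        post = posterior_coop(m, (xy[:, 0], xy[:, 1]))
        assert np.all((post >= 0) & (post <= 1))


class TestClassify:
    def test_strictly_greater_than_alpha(self):
        calls = classify_pairs([0.6, 0.5, 0.4], alpha=0.5)
        assert calls.tolist() == [True, False, False]

    def test_alpha_zero_calls_everything_positive(self):
        assert classify_pairs([0.01, 0.99], alpha=0.0).all()


class TestFitMixtureEM:
    def test_recovers_generating_parameters(self):
        xy, _ = simulate_intensity_pairs(REF, seed=7)
        m = fit_mixture_em((xy[:, 0], xy[:, 1]), seed=7)
        assert m.converged
        assert m.weight == pytest.approx(0.4, abs=0.05)
        assert m.coop_target.location == pytest.approx(1.0, abs=0.1)
        assert m.coop_partner.location == pytest.approx(2.0, abs=0.1)
        assert m.noncoop_target.location == pytest.approx(2.5, abs=0.1)
        assert m.noncoop_partner.location == pytest.approx(2.1, abs=0.1)

    def test_log_likelihood_consistent_with_stored_parameters(self):
        xy, _ = simulate_intensity_pairs(REF, seed=7)
        m = fit_mixture_em((xy[:, 0], xy[:, 1]), seed=7)
        assert log_likelihood(m, (xy[:, 0], xy[:, 1])) == pytest.approx(
            m.log_likelihood, rel=1e-9
        )

    def test_trace_is_monotone(self):
        xy, _ = simulate_intensity_pairs(REF, seed=8)
        m = fit_mixture_em((xy[:, 0], xy[:, 1]), seed=8)
        diffs = np.diff(m.ll_trace)
        assert np.all(diffs >= -1e-8 * (1 + np.abs(m.ll_trace[:-1])))

    def test_identical_generating_components_fit_converges(self):
        # a single-component truth is a degenerate ridge of the likelihood;
        # the fit must still converge cleanly (the posterior-equals-weight
        # property is checked on an identical-component *model* above)
        cfg = SimulationConfig(
            n_pairs=1500,
            coop_target=(2.0, 0.5),
            noncoop_target=(2.0 + 1e-9, 0.5),
            coop_partner=(2.0, 0.5),
            noncoop_partner=(2.0, 0.5),
        )
        xy, _ = simulate_intensity_pairs(cfg, seed=9)
        m = fit_mixture_em((xy[:, 0], xy[:, 1]), seed=9, max_iter=300)
        assert m.converged
        post = posterior_coop(m, (xy[:, 0], xy[:, 1]))
        assert np.all((post >= 0) & (post <= 1))

    def test_all_identical_pairs_degenerate_error(self):
        x = np.full(100, 3.0)
        with pytest.raises(DegenerateDataError):
            fit_mixture_em((x, x))

    def test_too_few_pairs_error(self):
        x = np.linspace(1, 2, 10)
        with pytest.raises(ValueError, match="at least 20"):
            fit_mixture_em((x, x))

    def test_component_identity_low_target_mean_is_cooperative(self):
        xy, _ = simulate_intensity_pairs(REF, seed=10)
        for fam in ("lognormal", "gamma", "gaussian"):
            m = fit_mixture_em((xy[:, 0], xy[:, 1]), family=fam, seed=10)
            assert m.coop_target.axis_mean <= m.noncoop_target.axis_mean

    def test_restarts_never_reduce_likelihood(self):
        cfg = SimulationConfig(n_pairs=600)
        xy, _ = simulate_intensity_pairs(cfg, seed=12)
        m1 = fit_mixture_em((xy[:, 0], xy[:, 1]), n_restarts=1, seed=12)
        m3 = fit_mixture_em((xy[:, 0], xy[:, 1]), n_restarts=3, seed=12)
        assert m3.log_likelihood >= m1.log_likelihood - 1e-6

    def test_fitted_marginals_normalize(self):
        cfg = SimulationConfig(n_pairs=800)
        xy, _ = simulate_intensity_pairs(cfg, seed=13)
        m = fit_mixture_em((xy[:, 0], xy[:, 1]), seed=13)
        for params in (m.coop_target, m.noncoop_target):
            total, _ = quad(
                lambda v: marginal_density(params, v), 1e-12, np.inf, limit=200
            )
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_lognormal_beats_other_families_on_lognormal_data(self):
        cfg = SimulationConfig(n_pairs=1500)
        xy, _ = simulate_intensity_pairs(cfg, seed=14)
        lls = {
            fam: fit_mixture_em(
                (xy[:, 0], xy[:, 1]), family=fam, seed=14
            ).log_likelihood
            for fam in ("lognormal", "gamma", "gaussian")
        }
        assert lls["lognormal"] > lls["gaussian"]
        assert lls["lognormal"] > lls["gamma"]


def test_model_serialization_round_trip(tmp_path):
    xy, _ = simulate_intensity_pairs(SimulationConfig(n_pairs=500), seed=15)
    m = fit_mixture_em((xy[:, 0], xy[:, 1]), seed=15)
    path = tmp_path / "model.txt"
    write_model(m, path)
    m2 = read_model(path)
    assert m2.weight == m.weight
    assert m2.coop_target == m.coop_target
    assert m2.log_likelihood == m.log_likelihood
    assert m2.converged == m.converged
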
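"""Lindley approximation: third derivatives, priors, contractions and the
four approximate Bayes estimators."""

import numpy as np
import pytest

import frechetbayes as fb
from frechetbayes import FrechetParams, Sample
from frechetbayes.distribution import loglik_hessian
from frechetbayes.lindley import (
    EstimatorUndefinedError,
    LossSpec,
    PriorSpec,
    lindley_terms,
    posterior_loss_estimate,
    prior_gradient,
    third_derivatives,
)
from conftest import random_params


def test_third_derivatives_match_finite_differences():
    rng = np.random.default_rng(11)
    for _ in range(10):
        p = random_params(rng)
        data = fb.sample(p, 60, seed=int(rng.integers(2**31)))
        T = third_derivatives(p, data)
        # symmetry under index permutation
        assert np.allclose(T, np.transpose(T, (1, 0, 2)), rtol=1e-8)
        assert np.allclose(T, np.transpose(T, (2, 1, 0)), rtol=1e-8)
        th = p.as_array()
        for i in range(3):
            step = 2e-5 * max(1.0, abs(th[i]))
            tp, tm = th.copy(), th.copy()
            tp[i] += step
            tm[i] -= step
            fd = (
                loglik_hessian(FrechetParams(*tp), data)
                - loglik_hessian(FrechetParams(*tm), data)
            ) / (2 * step)
            assert np.allclose(T[i], fd, rtol=1e-3, atol=1e-3)


def test_third_derivative_pure_shape_closed_form():
    """n=1 at x = eta + lambda: the standardized log vanishes, so
    d^3 L / d alpha^3 reduces to its 2n/alpha^3 term exactly."""
    for alpha in (0.7, 1.0, 2.5):
        p = FrechetParams(alpha, 1.5, 2.0)
        data = Sample(np.array([p.eta + p.lam]))
        T = third_derivatives(p, data)
        assert T[0, 0, 0] == pytest.approx(2.0 / alpha**3, rel=1e-12)


def test_prior_gradient_values_and_limits():
    p = FrechetParams(1.0, 2.0, 3.0)
    rho = prior_gradient(PriorSpec("noninformative"), p)
    assert np.allclose(rho, [-1.0, -0.5, -1.0 / 3.0])

    rho_g = prior_gradient(PriorSpec("gamma_scale", a=2.0, b=1.0), p)
    assert rho_g[1] == pytest.approx((2.0 - 1.0) / 2.0 - 1.0)
    assert rho_g[0] == -1.0 and rho_g[2] == pytest.approx(-1.0 / 3.0)

    flat = prior_gradient(PriorSpec("gamma_scale", a=1.0, b=1e-12), p)
    assert flat[1] == pytest.approx(0.0, abs=1e-10)

    with pytest.raises(ValueError):
        prior_gradient(PriorSpec("noninformative"), FrechetParams(1.0, 2.0, 0.0))
    with pytest.raises(ValueError):
        PriorSpec("gamma_scale", a=None, b=1.0)


def test_lindley_contractions_equal_brute_force(sim_data_123, sim_fit_123):
    ml, fisher = sim_fit_123
    terms = lindley_terms(ml.params, sim_data_123, PriorSpec("noninformative"), fisher)
    sigma = fisher.sigma
    Lam = np.zeros(3)
    for k in range(3):
        for i in range(3):
            for j in range(3):
                Lam[k] += terms.L3[i, j, k] * sigma[i, j]
    assert np.allclose(terms.Lambda, Lam, rtol=1e-12)
    b = np.array([sum(terms.rho[j] * sigma[i, j] for j in range(3)) for i in range(3)])
    assert np.allclose(terms.b_lin, b, rtol=1e-12)


def test_linex_small_k_limit_is_lindley_posterior_mean(sim_data_123, sim_fit_123):
    ml, fisher = sim_fit_123
    prior = PriorSpec("noninformative")
    terms = lindley_terms(ml.params, sim_data_123, prior, fisher)
    post_mean = ml.params.as_array() + terms.b_lin + 0.5 * (fisher.sigma @ terms.Lambda)
    tiny = fb.estimate_linex(
        sim_data_123, prior, LossSpec("linex", 1e-7), ml, fisher, variant="derived"
    )
    assert np.allclose(tiny.params.as_array(), post_mean, atol=1e-6)


def test_gentropy_k_minus_one_is_posterior_mean(sim_data_123, sim_fit_123):
    ml, fisher = sim_fit_123
    prior = PriorSpec("noninformative")
    terms = lindley_terms(ml.params, sim_data_123, prior, fisher)
    post_mean = ml.params.as_array() + terms.b_lin + 0.5 * (fisher.sigma @ terms.Lambda)
    ge = fb.estimate_gentropy(
        sim_data_123, prior, LossSpec("gen_entropy", -1.0), ml, fisher, variant="derived"
    )
    assert np.allclose(ge.params.as_array(), post_mean, rtol=1e-12)


def test_linex_monotone_nonincreasing_in_k(sim_data_123, sim_fit_123):
    ml, fisher = sim_fit_123
    prior = PriorSpec("noninformative")
    ks = [0.1, 0.25, 0.5, 1.0, 1.5, 2.0]
    ests = np.array([
        fb.estimate_linex(sim_data_123, prior, LossSpec("linex", k), ml, fisher,
                          variant="derived").params.as_array()
        for k in ks
    ])
    assert np.all(np.diff(ests, axis=0) <= 1e-10)


@pytest.mark.parametrize("loss_kind", ["linex", "gen_entropy"])
@pytest.mark.parametrize("seed", [42, 7, 424242])
def test_derived_variant_tracks_exact_posterior_at_n200(loss_kind, seed):
    """At n=200 the derived Lindley estimates sit within a tenth of a
    posterior standard deviation of the exact-posterior Bayes rules
    (quadrature reference), for every parameter and both losses."""
    truth = FrechetParams(1.0, 2.0, 3.0)
    prior = PriorSpec("noninformative")
    loss = LossSpec(loss_kind, 1.0)
    fn = fb.estimate_linex if loss_kind == "linex" else fb.estimate_gentropy
    data = fb.sample(truth, 200, seed=seed)
    ml = fb.fit_mle(data)
    fisher = fb.observed_fisher(ml.params, data)
    approx = fn(data, prior, loss, ml, fisher, variant="derived").params.as_array()
    exact = posterior_loss_estimate(data, prior, loss, ml, fisher)
    assert np.all(np.abs(approx - exact) <= 0.1 * fisher.std_errors)


def test_correction_shrinks_like_one_over_n():
    """The posterior-mean correction (b + sigma.Lambda/2) is O(1/n): on a
    common data stream it roughly halves when n doubles."""
    truth = FrechetParams(1.0, 2.0, 3.0)
    stream = fb.sample(truth, 800, seed=55).values
    prior = PriorSpec("noninformative")
    sizes = (200, 400, 800)
    corr = {}
    for n in sizes:
        data = Sample(stream[:n])
        ml = fb.fit_mle(data)
        fisher = fb.observed_fisher(ml.params, data)
        terms = lindley_terms(ml.params, data, prior, fisher)
        corr[n] = np.linalg.norm(terms.b_lin + 0.5 * (fisher.sigma @ terms.Lambda))
    assert corr[800] < corr[400] < corr[200]
    assert 1.2 < corr[200] / corr[400] < 4.0
    assert 1.2 < corr[400] / corr[800] < 4.0


def test_bracket_failure_raises_and_estimate_all_degrades(sim_data_123, sim_fit_123):
    ml, fisher = sim_fit_123
    prior = PriorSpec("noninformative")
    # an absurdly large loss constant drives the as-printed bracket negative
    with pytest.raises(EstimatorUndefinedError) as exc:
        fb.estimate_linex(sim_data_123, prior, LossSpec("linex", 1e6), ml, fisher)
    assert exc.value.bracket <= 0
    assert exc.value.param in ("alpha", "lambda", "eta")

    results = fb.estimate_all(sim_data_123, config=fb.HyperConfig(k=1e6), mle=ml)
    by_method = {r.method: r for r in results}
    assert set(by_method) == {"ML", "BLNP", "BGENP", "BLGP", "BGEGP"}
    for m in ("BLNP", "BLGP"):
        assert any(w.startswith("bracket_failure") for w in by_method[m].warnings)
        # degraded methods fall back to the ML triple, flagged, not silent
        assert by_method[m].params == ml.params


def test_estimate_all_shares_mle_and_records_hyperparameters(sim_data_123):
    config = fb.HyperConfig(k=0.5, a=2.0, b=1.5, variant="derived")
    results = fb.estimate_all(sim_data_123, config=config)
    by_method = {r.method: r for r in results}
    ml_direct = fb.fit_mle(sim_data_123)
    assert by_method["ML"].params == ml_direct.params
    for r in results:
        assert r.meta["k"] == 0.5
        assert r.meta["variant"] == "derived" or r.method == "ML"
    blgp = by_method["BLGP"]
    assert blgp.meta["prior"] == "gamma_scale" and blgp.meta["a"] == 2.0


def test_estimators_collapse_to_mle_for_large_samples():
    truth = FrechetParams(1.0, 2.0, 3.0)
    data = fb.sample(truth, 10_000, seed=77)
    for variant in ("as_printed", "derived"):
        results = fb.estimate_all(data, config=fb.HyperConfig(variant=variant))
        arrays = np.array([r.params.as_array() for r in results])
        spread = np.ptp(arrays, axis=0) / np.abs(arrays[0])
        assert np.all(spread < 0.01)
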
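import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import chi2, halfnorm, norm

from ugtvar.io import Parameter, Route
from ugtvar.model import (
    FullParams,
    McmcConfig,
    PosteriorDraws,
    PriorConfig,
    build_model_spec,
    convergence_diagnostics,
    log_posterior,
    marginal_log_posterior,
    run_mcmc,
)
from ugtvar.standardize import NormalizedObservation


def obs(substrate, n, ln_gm, ln_gsd, study="s", route=Route.ORAL, parameter=Parameter.AUC):
    return NormalizedObservation(
        substrate_id=substrate,
        route=route,
        parameter=parameter,
        n_subjects=n,
        ln_gm=ln_gm,
        ln_gsd=ln_gsd,
        source_study_id=study,
    )


# ---------------------------------------------------------------- model spec


def test_build_model_spec_groups_substrates():
    spec1 = build_model_spec([obs("a", 10, 1.0, 0.3) for _ in range(3)], PriorConfig())
    assert spec1.n_substrates == 1 and not spec1.pooled
    spec2 = build_model_spec(
        [obs("a", 10, 1.0, 0.3), obs("b", 10, 2.0, 0.4)], PriorConfig()
    )
    assert spec2.n_substrates == 2 and spec2.pooled
    assert spec2.substrate_ids == ("a", "b")


def test_build_model_spec_rejects_empty_and_mixed():
    with pytest.raises(ValueError, match="empty"):
        build_model_spec([], PriorConfig())
    mixed = [obs("a", 10, 1.0, 0.3), obs("a", 10, 1.0, 0.3, route=Route.IV)]
    with pytest.raises(ValueError, match="mix"):
        build_model_spec(mixed, PriorConfig())


def test_single_subject_studies_have_no_dispersion_term():
    spec = build_model_spec(
        [obs("a", 1, 1.0, 0.0), obs("a", 12, 1.0, 0.4)], PriorConfig()
    )
    assert list(spec.has_gsd) == [False, True]


# ------------------------------------------------------------- log posterior


def _oracle_one_substrate(spec_obs, mu, s_ind, s_study, m_effects, priors):
    """Term-by-term density for a single-substrate model, coded from scratch."""
    total = norm.logpdf(mu, priors.mu_prior[0], priors.mu_prior[1])
    total += halfnorm.logpdf(s_ind, scale=priors.sigma_ind_scale)
    total += halfnorm.logpdf(s_study, scale=priors.sigma_study_scale)
    k = 0
    for o in spec_obs:
        if o.n_subjects >= 2 and o.ln_gsd > 0:
            m = m_effects[k]
            k += 1
            total += norm.logpdf(m, mu, s_study)
            total += norm.logpdf(o.ln_gm, m, s_ind / math.sqrt(o.n_subjects))
            q = (o.n_subjects - 1) * o.ln_gsd**2 / s_ind**2
            total += chi2.logpdf(q, o.n_subjects - 1) + math.log(
                (o.n_subjects - 1) / s_ind**2
            )
        else:
            total += norm.logpdf(o.ln_gm, mu, math.sqrt(s_study**2 + s_ind**2 / o.n_subjects))
    return float(total)


def test_log_posterior_matches_independent_oracle():
    observations = [
        obs("a", 12, 4.8, 0.42, study="s1"),
        obs("a", 25, 5.1, 0.38, study="s2"),
    ]
    priors = PriorConfig()
    spec = build_model_spec(observations, priors)
    params = FullParams(
        mu=np.array([5.0]),
        sigma_ind=np.array([0.45]),
        sigma_study=np.array([0.2]),
        study_effects=np.array([4.9, 5.05]),
    )
    expected = _oracle_one_substrate(
        observations, 5.0, 0.45, 0.2, [4.9, 5.05], priors
    )
    assert log_posterior(spec, params) == pytest.approx(expected, abs=1e-10)


def test_log_posterior_single_subject_study_marginal_term():
    observations = [obs("a", 1, 4.7, 0.0, study="s1"), obs("a", 12, 5.0, 0.4, study="s2")]
    priors = PriorConfig()
    spec = build_model_spec(observations, priors)
    params = FullParams(
        mu=np.array([5.0]),
        sigma_ind=np.array([0.5]),
        sigma_study=np.array([0.25]),
        study_effects=np.array([5.1]),
    )
    expected = _oracle_one_substrate(observations, 5.0, 0.5, 0.25, [5.1], priors)
    assert log_posterior(spec, params) == pytest.approx(expected, abs=1e-10)


def test_log_posterior_pooled_hyper_terms():
    observations = [obs("a", 10, 4.8, 0.4, "s1"), obs("b", 15, 3.1, 0.5, "s2")]
    priors = PriorConfig()
    spec = build_model_spec(observations, priors)
    mu = np.array([4.9, 3.0])
    si = np.array([0.45, 0.5])
    ss = np.array([0.2, 0.3])
    m = np.array([4.85, 3.05])
    got = log_posterior(
        spec,
        FullParams(mu=mu, sigma_ind=si, sigma_study=ss, study_effects=m,
                   hyper_m=-0.8, hyper_s=0.3),
    )
    expected = 0.0
    for j, o in enumerate(observations):
        expected += norm.logpdf(mu[j], 0.0, 10.0)
        expected += halfnorm.logpdf(ss[j], scale=1.0)
        # exchangeable lognormal prior on sigma_ind
        expected += norm.logpdf(math.log(si[j]), -0.8, 0.3) - math.log(si[j])
        expected += norm.logpdf(m[j], mu[j], ss[j])
        expected += norm.logpdf(o.ln_gm, m[j], si[j] / math.sqrt(o.n_subjects))
        q = (o.n_subjects - 1) * o.ln_gsd**2 / si[j] ** 2
        expected += chi2.logpdf(q, o.n_subjects - 1) + math.log(
            (o.n_subjects - 1) / si[j] ** 2
        )
    expected += norm.logpdf(-0.8, -1.0, 1.0) + halfnorm.logpdf(0.3, scale=0.5)
    assert got == pytest.approx(expected, abs=1e-10)


def test_log_posterior_rejects_nonpositive_sd_with_minus_inf():
    spec = build_model_spec([obs("a", 10, 1.0, 0.3)], PriorConfig())
    params = FullParams(
        mu=np.array([1.0]),
        sigma_ind=np.array([-0.1]),
        sigma_study=np.array([0.2]),
        study_effects=np.array([1.0]),
    )
    assert log_posterior(spec, params) == -np.inf


def test_duplicating_data_doubles_the_likelihood_part():
    observations = [obs("a", 12, 4.8, 0.42, "s1"), obs("a", 25, 5.1, 0.38, "s2")]
    priors = PriorConfig()
    spec1 = build_model_spec(observations, priors)
    spec2 = build_model_spec(observations * 2, priors)
    p1 = FullParams(
        mu=np.array([5.0]), sigma_ind=np.array([0.45]), sigma_study=np.array([0.2]),
        study_effects=np.array([4.9, 5.05]),
    )
    p2 = FullParams(
        mu=p1.mu, sigma_ind=p1.sigma_ind, sigma_study=p1.sigma_study,
        study_effects=np.array([4.9, 5.05, 4.9, 5.05]),
    )
    prior = (
        norm.logpdf(5.0, 0, 10)
        + halfnorm.logpdf(0.45, scale=1)
        + halfnorm.logpdf(0.2, scale=1)
    )
    lp1 = log_posterior(spec1, p1)
    lp2 = log_posterior(spec2, p2)
    assert lp2 - prior == pytest.approx(2.0 * (lp1 - prior), rel=1e-12)


def test_marginal_matches_numerical_integration_over_study_effects():
    # integrate the full posterior over both study effects by quadrature
    observations = [obs("a", 12, 4.8, 0.42, "s1"), obs("a", 25, 5.1, 0.38, "s2")]
    priors = PriorConfig()
    spec = build_model_spec(observations, priors)
    mu, s_ind, s_study = 5.0, 0.45, 0.2

    def integral_for(o):
        f = lambda m: norm.pdf(m, mu, s_study) * norm.pdf(
            o.ln_gm, m, s_ind / math.sqrt(o.n_subjects)
        )
        val, _ = integrate.quad(f, mu - 10, mu + 10)
        return math.log(val)

    base = _oracle_one_substrate(observations, mu, s_ind, s_study, [0.0, 0.0], priors)
    # strip the conditional study terms the oracle added, re-add the integrals
    for o, m in zip(observations, [0.0, 0.0]):
        base -= norm.logpdf(m, mu, s_study)
        base -= norm.logpdf(o.ln_gm, m, s_ind / math.sqrt(o.n_subjects))
    expected = base + sum(integral_for(o) for o in observations)
    got = marginal_log_posterior(
        spec, np.array([mu]), np.array([s_ind]), np.array([s_study])
    )
    assert got == pytest.approx(expected, rel=1e-9)


# -------------------------------------------------------------------- MCMC


def _small_spec():
    rng = np.random.default_rng(0)
    observations = [
        obs("a", 20, float(rng.normal(5.0, 0.25)), float(abs(rng.normal(0.45, 0.05))), f"s{i}")
        for i in range(8)
    ]
    return build_model_spec(observations, PriorConfig())


def test_identical_seed_gives_identical_draws():
    spec = _small_spec()
    cfg = McmcConfig(chains=2, warmup_draws=150, kept_draws=150, seed=123, min_ess=1)
    d1 = run_mcmc(spec, cfg)
    d2 = run_mcmc(spec, cfg)
    assert np.array_equal(d1.mu, d2.mu)
    assert np.array_equal(d1.sigma_ind, d2.sigma_ind)
    assert np.array_equal(d1.sigma_study, d2.sigma_study)


def test_different_seed_gives_different_draws():
    spec = _small_spec()
    d1 = run_mcmc(spec, McmcConfig(chains=2, warmup_draws=150, kept_draws=150, seed=1, min_ess=1))
    d2 = run_mcmc(spec, McmcConfig(chains=2, warmup_draws=150, kept_draws=150, seed=2, min_ess=1))
    assert not np.array_equal(d1.mu, d2.mu)


def test_single_giant_study_concentrates_on_observed_lngsd():
    # with n = 10^4 the dispersion term pins sigma_ind at the sample lnGSD
    spec = build_model_spec([obs("a", 10_000, 2.0, 0.40)], PriorConfig())
    draws = run_mcmc(
        spec, McmcConfig(chains=2, warmup_draws=500, kept_draws=800, seed=9, min_ess=50)
    )
    med = float(np.median(draws.flat("sigma_ind", "a")))
    assert 0.38 <= med <= 0.42


def test_identical_substrates_are_exchangeable():
    rng = np.random.default_rng(4)
    base = [
        (20, float(rng.normal(5.0, 0.25)), float(abs(rng.normal(0.45, 0.05))))
        for _ in range(10)
    ]
    observations = [
        obs(sub, n, g, s, f"{sub}{i}")
        for sub in ("a", "b")
        for i, (n, g, s) in enumerate(base)
    ]
    spec = build_model_spec(observations, PriorConfig())
    draws = run_mcmc(
        spec, McmcConfig(chains=2, warmup_draws=800, kept_draws=1200, seed=3, min_ess=50)
    )
    med_a = float(np.median(draws.flat("sigma_ind", "a")))
    med_b = float(np.median(draws.flat("sigma_ind", "b")))
    assert med_a == pytest.approx(med_b, abs=0.03)


def test_posterior_long_export_round_trips(default_fit):
    _, draws, _ = default_fit
    frame = draws.to_long_dataframe()
    again = PosteriorDraws.from_long_dataframe(frame)
    assert again.substrate_ids == draws.substrate_ids
    assert np.allclose(again.mu, draws.mu)
    assert np.allclose(again.hyper_s, draws.hyper_s)


# -------------------------------------------------------------- diagnostics


def _draws_from(mu_grid: np.ndarray) -> PosteriorDraws:
    c, d = mu_grid.shape
    shape3 = mu_grid[..., None]
    return PosteriorDraws(
        substrate_ids=("x",),
        mu=shape3,
        sigma_ind=np.abs(shape3) + 0.5,
        sigma_study=np.abs(shape3) + 0.5,
        hyper_m=None,
        hyper_s=None,
        seed=0,
    )


def test_iid_chains_pass_rhat():
    rng = np.random.default_rng(8)
    report = convergence_diagnostics(
        _draws_from(rng.standard_normal((4, 1000))), McmcConfig(min_ess=100)
    )
    assert report.rhat["mu[x]"] == pytest.approx(1.0, abs=0.01)
    assert report.passed


def test_shifted_chain_fails_rhat():
    rng = np.random.default_rng(8)
    grid = rng.standard_normal((4, 1000))
    grid[0] += 3.0
    report = convergence_diagnostics(_draws_from(grid), McmcConfig(min_ess=100))
    assert report.rhat["mu[x]"] > 1.05
    assert not report.passed


def test_constant_chains_are_flagged():
    report = convergence_diagnostics(_draws_from(np.ones((2, 200))), McmcConfig())
    assert not report.passed
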
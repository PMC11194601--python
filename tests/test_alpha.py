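"""Richness-model density, sampler correctness, diagnostics, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from holcbio import alpha, synthetic
from holcbio.errors import ConfigurationError


def _table(n_per=3, cities=("X",), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for city in cities:
        for g in alpha.GRADES:
            for k in range(n_per):
                rows.append(
                    {
                        "neighborhood_id": f"{city}-{g}-{k}",
                        "city": city,
                        "holc_grade": g,
                        "area_km2": rng.uniform(0.5, 2.0),
                        "impervious": rng.uniform(20, 80),
                        "richness": int(rng.integers(5, 40)),
                        "n_obs": int(rng.integers(10, 200)),
                    }
                )
    return pd.DataFrame(rows)


def _zero_params(cities=("X",), **overrides):
    params = dict(
        b0=0.0,
        b_grade={"B": 0.0, "C": 0.0, "D": 0.0},
        b_imp=0.0,
        u_intercept={c: 0.0 for c in cities},
        u_slope={g: {c: 0.0 for c in cities} for g in ("B", "C", "D")},
        sigma_intercept=1.0,
        sigma_slope={g: 1.0 for g in ("B", "C", "D")},
    )
    params.update(overrides)
    return alpha.Params(**params)


# ---------------------------------------------------------------------------
# Model data
# ---------------------------------------------------------------------------


def test_offset_is_log_area_plus_log_obs():
    tab = _table()
    tab.loc[0, ["area_km2", "n_obs"]] = [2.0, 3]
    data = alpha.build_model_data(tab)
    assert data.offset[0] == pytest.approx(math.log(6.0))
    data_sum = alpha.build_model_data(tab, offset_mode="sum")
    assert data_sum.offset[0] == pytest.approx(math.log(5.0))


def test_impervious_is_standardized():
    data = alpha.build_model_data(_table(n_per=10))
    assert abs(data.x.mean()) < 1e-12
    assert data.x.std() == pytest.approx(1.0, abs=1e-12)


def test_zero_observation_neighborhood_rejected():
    tab = _table()
    tab.loc[2, "n_obs"] = 0
    with pytest.raises(ConfigurationError, match=tab.loc[2, "neighborhood_id"]):
        alpha.build_model_data(tab)


# ---------------------------------------------------------------------------
# Linear predictor and density
# ---------------------------------------------------------------------------


def test_log_mean_examples():
    p = _zero_params()
    assert math.exp(alpha.log_mean(p, math.log(6), "A", "X", 0.0)) == pytest.approx(6.0)
    p2 = _zero_params(b_grade={"B": 0.0, "C": 0.0, "D": -0.5})
    assert math.exp(alpha.log_mean(p2, 0.0, "D", "X", 0.0)) == pytest.approx(
        math.exp(-0.5)
    )
    # adding 1 to b0 multiplies every mu by e
    p3 = _zero_params(b0=1.0)
    assert alpha.log_mean(p3, 0.3, "B", "X", 0.7) == pytest.approx(
        alpha.log_mean(_zero_params(), 0.3, "B", "X", 0.7) + 1.0
    )
    with pytest.raises(ValueError):
        alpha.log_mean(p, 0.0, "E", "X", 0.0)
    with pytest.raises(ValueError):
        alpha.log_mean(p, 0.0, "A", "Y", 0.0)


def _oracle_log_posterior(params, data, priors):
    """Term-by-term density via scipy.stats, coded independently."""
    lp = 0.0
    fixed = [params.b0, params.b_grade["B"], params.b_grade["C"],
             params.b_grade["D"], params.b_imp]
    lp += scipy.stats.norm.logpdf(fixed, 0, priors.fixed_sd).sum()
    sigmas = [params.sigma_intercept] + [
        params.sigma_slope[g] for g in ("B", "C", "D")
    ]
    lp += scipy.stats.gamma.logpdf(
        sigmas, priors.gamma_shape, scale=1.0 / priors.gamma_rate
    ).sum()
    for city in data.city_labels:
        lp += scipy.stats.norm.logpdf(
            params.u_intercept[city], 0, params.sigma_intercept
        )
        for g in ("B", "C", "D"):
            lp += scipy.stats.norm.logpdf(
                params.u_slope[g][city], 0, params.sigma_slope[g]
            )
    for i in range(data.n):
        grade = data.grade_labels[data.grade_idx[i]]
        city = data.city_labels[data.city_idx[i]]
        eta = data.offset[i] + params.b0 + params.u_intercept[city]
        eta += params.b_imp * data.x[i]
        if grade != "A":
            eta += params.b_grade[grade] + params.u_slope[grade][city]
        lp += scipy.stats.poisson.logpmf(data.y[i], math.exp(eta))
    return float(lp)


def test_log_posterior_matches_brute_force_oracle():
    data = alpha.build_model_data(_table(n_per=1, cities=("X", "Y"), seed=3))
    priors = alpha.PriorConfig()
    rng = np.random.default_rng(5)
    for _ in range(5):
        params = _zero_params(
            cities=("X", "Y"),
            b0=rng.normal(), b_imp=rng.normal(scale=0.3),
            b_grade={g: rng.normal(scale=0.5) for g in ("B", "C", "D")},
            u_intercept={c: rng.normal(scale=0.3) for c in ("X", "Y")},
            u_slope={g: {c: rng.normal(scale=0.2) for c in ("X", "Y")}
                     for g in ("B", "C", "D")},
            sigma_intercept=rng.uniform(0.2, 1.5),
            sigma_slope={g: rng.uniform(0.2, 1.5) for g in ("B", "C", "D")},
        )
        assert alpha.log_posterior(params, data, priors) == pytest.approx(
            _oracle_log_posterior(params, data, priors), rel=1e-12
        )


def test_log_posterior_rejects_nonpositive_sigma():
    data = alpha.build_model_data(_table())
    params = _zero_params(sigma_intercept=-0.5)
    assert alpha.log_posterior(params, data, alpha.PriorConfig()) == -math.inf


def test_single_neighborhood_unit_likelihood_term():
    # y = 1, mu = 1 -> Poisson log-likelihood term log(e^-1) = -1
    tab = _table(n_per=1)[:1]
    tab.loc[0, ["area_km2", "n_obs", "richness"]] = [1.0, 1, 1]
    data = alpha.build_model_data(tab)
    priors = alpha.PriorConfig()
    lp = alpha.log_posterior(_zero_params(), data, priors)
    prior_only = lp - scipy.stats.poisson.logpmf(1, 1.0)
    assert lp - prior_only == pytest.approx(-1.0)


def test_scaling_response_changes_only_likelihood():
    tab = _table(seed=9)
    data1 = alpha.build_model_data(tab)
    tab2 = tab.assign(richness=tab["richness"] * 2)
    data2 = alpha.build_model_data(tab2)
    priors = alpha.PriorConfig()
    p = _zero_params(b0=0.3)
    delta = alpha.log_posterior(p, data2, priors) - alpha.log_posterior(
        p, data1, priors
    )
    mus = np.exp(
        [alpha.log_mean(p, data1.offset[i], data1.grade_labels[data1.grade_idx[i]],
                        "X", data1.x[i]) for i in range(data1.n)]
    )
    expected = (
        scipy.stats.poisson.logpmf(data2.y, mus).sum()
        - scipy.stats.poisson.logpmf(data1.y, mus).sum()
    )
    assert delta == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# Gelman-Rubin
# ---------------------------------------------------------------------------


def test_gelman_rubin_identical_chains():
    chain = np.arange(10.0)
    rhat = alpha.gelman_rubin(np.stack([chain, chain]))
    assert rhat == pytest.approx(math.sqrt(9 / 10))


def test_gelman_rubin_hand_example():
    rhat = alpha.gelman_rubin(np.array([[0.0, 2.0], [1.0, 3.0]]))
    # W = 2, B = 1: sqrt(1/2 + 1/4)
    assert rhat == pytest.approx(math.sqrt(0.75))


def test_gelman_rubin_separated_chains_exceed_threshold():
    rhat = alpha.gelman_rubin(
        np.array([[1.0, 2.0, 1.0, 2.0], [101.0, 102.0, 101.0, 102.0]])
    )
    assert rhat > 1.10


def test_gelman_rubin_degenerate_chains_error():
    with pytest.raises(ValueError):
        alpha.gelman_rubin(np.array([[1.0, 1.0], [1.0, 1.0]]))
    with pytest.raises(ValueError):
        alpha.gelman_rubin(np.array([[1.0, 2.0]]))


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def fitted():
    region = synthetic.make_region(
        synthetic.RegionConfig(n_cities=2, neighborhoods_per_grade_per_city=8,
                               grid_cell_km=0.5),
        seed=31,
    )
    rich, truth = synthetic.simulate_richness(region, synthetic.TruthParams(), 32)
    data = alpha.build_model_data(rich)
    samples = alpha.sample_posterior(
        data, mcmc=alpha.McmcConfig.test_profile(seed=33)
    )
    return data, samples, truth


def test_sampler_is_reproducible_given_seed(fitted):
    data, samples, _ = fitted
    again = alpha.sample_posterior(
        data, mcmc=alpha.McmcConfig.test_profile(seed=33)
    )
    assert np.array_equal(samples.theta, again.theta)


def test_posterior_matches_fine_grid_integration():
    """Two-parameter reduction: MCMC vs numerical integration.

    Single city, deviation SDs pinned near zero, impervious centered so only
    (b0, b_D) inform the likelihood via grades A and D.
    """
    rng = np.random.default_rng(17)
    n = 30
    y_a = rng.poisson(8.0, n)  # grade A, mu = exp(b0_true) ~ 8
    y_d = rng.poisson(3.0, n)
    tab = pd.DataFrame(
        {
            "neighborhood_id": [f"n{i}" for i in range(2 * n)],
            "city": "X",
            "holc_grade": ["A"] * n + ["D"] * n,
            "area_km2": 1.0,
            "impervious": 50.0,  # constant -> x = 0, b_imp out of likelihood
            "richness": np.concatenate([y_a, y_d]),
            "n_obs": 1,
        }
    )
    data = alpha.build_model_data(tab)
    pin = {k: 1e-8 for k in ("intercept", "B", "C", "D")}
    samples = alpha.sample_posterior(
        data,
        mcmc=alpha.McmcConfig(burn_in=3000, samples=5000, chains=4, seed=71),
        pin_sigma=pin,
    )
    draws = samples.natural_draws()

    # independent grid integration of the 2-parameter posterior
    b0g = np.linspace(0, 4, 401)
    bdg = np.linspace(-3, 1, 401)
    B0, BD = np.meshgrid(b0g, bdg, indexing="ij")
    loglik = (
        y_a.sum() * B0 - n * np.exp(B0)
        + y_d.sum() * (B0 + BD) - n * np.exp(B0 + BD)
    )
    logprior = -(B0**2) / 8 - (BD**2) / 8
    post = np.exp(loglik + logprior - (loglik + logprior).max())
    post /= post.sum()
    m_b0 = (post * B0).sum()
    sd_b0 = math.sqrt((post * (B0 - m_b0) ** 2).sum())
    m_bd = (post * BD).sum()
    sd_bd = math.sqrt((post * (BD - m_bd) ** 2).sum())

    assert draws["b0"].mean() == pytest.approx(m_b0, abs=0.02 * max(1, abs(m_b0)))
    assert draws["b0"].std() == pytest.approx(sd_b0, rel=0.05)
    assert draws["b_D"].mean() == pytest.approx(m_bd, abs=0.02 * max(1, abs(m_bd)))
    assert draws["b_D"].std() == pytest.approx(sd_bd, rel=0.05)


def test_offset_contract_shifts_intercept(fitted):
    data, samples, _ = fitted
    region = synthetic.make_region(
        synthetic.RegionConfig(n_cities=2, neighborhoods_per_grade_per_city=8,
                               grid_cell_km=0.5),
        seed=31,
    )
    rich, _ = synthetic.simulate_richness(region, synthetic.TruthParams(), 32)
    c = 10.0
    rich2 = rich.assign(area_km2=rich["area_km2"] * c)
    data2 = alpha.build_model_data(rich2)
    samples2 = alpha.sample_posterior(
        data2, mcmc=alpha.McmcConfig.test_profile(seed=33)
    )
    b0_1 = np.median(samples.natural_draws()["b0"])
    b0_2 = np.median(samples2.natural_draws()["b0"])
    assert b0_2 - b0_1 == pytest.approx(-math.log(c), abs=0.15)
    con1 = alpha.grade_contrasts(samples, data, level="city")
    con2 = alpha.grade_contrasts(samples2, data2, level="city")
    assert (con1["significant"] == con2["significant"]).mean() > 0.9


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def _degenerate_samples():
    C = 1
    P = 9 + 4 * C
    theta = np.zeros((2, 5, P))
    theta[..., 0] = 1.0  # b0 = 1 in every draw
    return alpha.PosteriorSamples(
        theta=theta, city_labels=["X"], config=alpha.McmcConfig.test_profile(),
        pinned_sigma={k: 1e-12 for k in ("intercept", "B", "C", "D")},
    )


def _tiny_data():
    tab = pd.DataFrame(
        {
            "neighborhood_id": ["a", "b"],
            "city": "X",
            "holc_grade": ["A", "D"],
            "area_km2": 1.0,
            "impervious": 50.0,
            "richness": [3, 2],
            "n_obs": [1, 1],
        }
    )
    return alpha.build_model_data(tab)


def test_degenerate_posterior_gives_zero_width_intervals():
    samples = _degenerate_samples()
    data = _tiny_data()
    pred = alpha.predict_neighborhood_richness(samples, data)
    assert (pred["upper"] - pred["lower"]).abs().max() == pytest.approx(0.0)
    assert pred["predicted"].iloc[0] == pytest.approx(math.e)  # offset 0, b0 = 1
    summ = alpha.summarize_grades(samples, data, level="city")
    assert summ["mean_richness"].iloc[0] == pytest.approx(math.e)


def test_contrast_of_grade_with_itself_is_zero():
    samples = _degenerate_samples()
    data = _tiny_data()
    con = alpha.grade_contrasts(
        samples, data, level="city", pairs=(("A", "A"),)
    )
    assert con["median"].iloc[0] == 0.0
    assert con["lower"].iloc[0] == 0.0 and con["upper"].iloc[0] == 0.0
    assert not con["significant"].iloc[0]


def test_overall_intervals_at_least_as_wide_as_city_intervals(fitted):
    data, samples, _ = fitted
    overall = alpha.summarize_grades(samples, data, level="overall", seed=1)
    city = alpha.summarize_grades(samples, data, level="city")
    for g in alpha.GRADES:
        w_all = overall.set_index("holc_grade").loc[g]
        width_all = w_all["upper"] - w_all["lower"]
        sub = city[city["holc_grade"] == g]
        width_city = (sub["upper"] - sub["lower"]).max()
        assert width_all >= width_city * 0.9  # overall adds between-city variance


def test_neighborhood_intervals_cover_truth():
    """Pooled over replicates, 95% intervals for mu_i cover the truth."""
    covered = []
    for seed in (40, 41, 42):
        region = synthetic.make_region(
            synthetic.RegionConfig(n_cities=2, neighborhoods_per_grade_per_city=8,
                                   grid_cell_km=0.5),
            seed,
        )
        rich, truth = synthetic.simulate_richness(
            region, synthetic.TruthParams(), seed + 100
        )
        data = alpha.build_model_data(rich)
        samples = alpha.sample_posterior(
            data, mcmc=alpha.McmcConfig.test_profile(seed=seed)
        )
        pred = alpha.predict_neighborhood_richness(samples, data)
        eff = truth.city_effects
        mu_true = []
        for i in range(data.n):
            grade = data.grade_labels[data.grade_idx[i]]
            city = data.city_labels[data.city_idx[i]]
            eta = data.offset[i] + truth.b0 + eff["intercept"][city]
            eta += truth.b_imp * data.x[i]
            if grade != "A":
                eta += truth.b_grade[grade] + eff["slope"][grade][city]
            mu_true.append(math.exp(eta))
        mu_true = np.array(mu_true)
        covered.append(
            ((pred["lower"] <= mu_true) & (mu_true <= pred["upper"])).to_numpy()
        )
    assert np.concatenate(covered).mean() >= 0.85


def test_convergence_report_structure(fitted):
    _, samples, _ = fitted
    report = alpha.convergence_report(samples)
    assert {"b0", "b_B", "b_imp", "sigma_intercept"} <= set(report.rhat)
    assert all(v >= 0 for v in report.rhat.values())
    d = report.to_dict()
    assert d["passed"] == (d["max_rhat"] < 1.10)
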
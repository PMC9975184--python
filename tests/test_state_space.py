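"""State-space model: density oracle, design assembly, fitting, summaries."""

import numpy as np
import pytest
from scipy import stats

from seizurespan import (
    NormalizedSeries,
    BinnedSeries,
    assemble_design,
    decide_separation,
    fit_posterior,
    log_posterior,
    simulate_from_state_space,
    summarize_effect,
)
from seizurespan.statespace import (
    DesignError,
    Priors,
    StateSpaceData,
    StateSpaceParams,
    StateSpacePosterior,
)


def oracle_log_posterior(params, data, priors):
    """Independent term-by-term density oracle (explicit loops, scipy.stats)."""
    lp = 0.0
    T = data.bin_start_min.size
    for s in range(data.y.shape[0]):
        for t in range(T):
            y = data.y[s, t]
            if np.isnan(y):
                continue
            mean = params.yhat[t] + data.u[s] * params.d_M + data.v[s] * params.d_T[t]
            lp += stats.norm.logpdf(y, loc=mean, scale=params.sigma)
    lp += stats.norm.logpdf(params.d_M, loc=0.0, scale=params.sigma_M)
    for t in range(2, T):
        lp += stats.norm.logpdf(
            params.yhat[t] - params.yhat[t - 1],
            loc=params.yhat[t - 1] - params.yhat[t - 2],
            scale=params.sigma_y,
        )
    c = params.sigma_T**2 if priors.cauchy_square_scale else params.sigma_T
    for t in range(1, T):
        lp += stats.cauchy.logpdf(params.d_T[t], loc=params.d_T[t - 1], scale=c)
    lp += stats.norm.logpdf(params.yhat[0], scale=priors.init_sd)
    if T > 1:
        lp += stats.norm.logpdf(params.yhat[1], scale=priors.init_sd)
    lp += stats.norm.logpdf(params.d_T[0], scale=priors.init_sd)
    for s in (params.sigma, params.sigma_M, params.sigma_y, params.sigma_T):
        lp += stats.halfcauchy.logpdf(s, scale=priors.scale_prior_scale)
    return float(lp)


def random_case(rng, T=None, S=None, missing=False):
    T = T or int(rng.integers(3, 12))
    S = S or int(rng.integers(2, 6))
    t = np.arange(-(T // 2), T - T // 2, dtype=float)
    u = rng.choice([-1.0, 1.0], size=S)
    v = rng.choice([0.0, 1.0], size=S)
    y = rng.normal(1.0, 0.5, size=(S, T))
    if missing:
        # knock out interior cells only, keeping one pre and one post bin
        drop = rng.uniform(size=(S, T)) < 0.15
        drop[:, 0] = drop[:, -1] = False
        y[drop] = np.nan
    data = StateSpaceData(bin_start_min=t, y=y, u=u, v=v)
    params = StateSpaceParams(
        yhat=rng.normal(1.0, 0.3, size=T),
        d_M=float(rng.normal(0, 0.3)),
        d_T=rng.normal(0, 0.4, size=T),
        sigma=float(rng.uniform(0.02, 1.0)),
        sigma_M=float(rng.uniform(0.02, 1.0)),
        sigma_y=float(rng.uniform(0.02, 1.0)),
        sigma_T=float(rng.uniform(0.02, 1.0)),
    )
    return params, data


class TestLogPosterior:
    def test_matches_independent_oracle_50_draws(self, rng):
        priors = Priors()
        for k in range(50):
            params, data = random_case(rng, missing=(k % 3 == 0))
            lp = log_posterior(params, data, priors)
            assert lp == pytest.approx(oracle_log_posterior(params, data, priors), abs=1e-8)

    def test_squared_scale_variant_matches_oracle(self, rng):
        priors = Priors(cauchy_square_scale=True)
        for _ in range(10):
            params, data = random_case(rng)
            assert log_posterior(params, data, priors) == pytest.approx(
                oracle_log_posterior(params, data, priors), abs=1e-8
            )

    def test_residual_term_is_gaussian_quadratic(self, rng):
        params, data = random_case(rng, T=6, S=2)
        lp0 = log_posterior(params, data)
        y2 = data.y.copy()
        s_idx, t_idx = 0, 2
        delta = 0.37
        mean = (params.yhat[t_idx] + data.u[s_idx] * params.d_M
                + data.v[s_idx] * params.d_T[t_idx])
        r_old = data.y[s_idx, t_idx] - mean
        y2[s_idx, t_idx] += delta
        data2 = StateSpaceData(data.bin_start_min, y2, data.u, data.v)
        lp1 = log_posterior(params, data2)
        expected = -((r_old + delta) ** 2 - r_old**2) / (2 * params.sigma**2)
        assert lp1 - lp0 == pytest.approx(expected, abs=1e-10)

    def test_sign_symmetry_in_subject_coding(self, rng):
        params, data = random_case(rng, T=8, S=4)
        flipped_data = StateSpaceData(data.bin_start_min, data.y, -data.u, data.v)
        flipped_params = StateSpaceParams(
            params.yhat, -params.d_M, params.d_T,
            params.sigma, params.sigma_M, params.sigma_y, params.sigma_T,
        )
        assert log_posterior(params, data) == pytest.approx(
            log_posterior(flipped_params, flipped_data), abs=1e-10
        )

    def test_vehicle_sessions_do_not_inform_treatment_effect(self, rng):
        """Changing d_T changes the likelihood only through DCZ sessions:
        the change in log posterior is identical after deleting all
        vehicle sessions."""
        params, data = random_case(rng, T=8, S=6)
        data = StateSpaceData(data.bin_start_min, data.y, data.u,
                              np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0]))
        alt = StateSpaceParams(
            params.yhat, params.d_M, params.d_T + 0.25,
            params.sigma, params.sigma_M, params.sigma_y, params.sigma_T,
        )
        full_delta = log_posterior(alt, data) - log_posterior(params, data)
        dcz_only = StateSpaceData(data.bin_start_min, data.y[:3], data.u[:3], data.v[:3])
        dcz_delta = log_posterior(alt, dcz_only) - log_posterior(params, dcz_only)
        assert full_delta == pytest.approx(dcz_delta, abs=1e-10)

    def test_nonpositive_scale_rejected(self, rng):
        params, data = random_case(rng)
        bad = StateSpaceParams(params.yhat, params.d_M, params.d_T,
                               0.0, params.sigma_M, params.sigma_y, params.sigma_T)
        with pytest.raises(ValueError, match="sigma"):
            log_posterior(bad, data)


def series_for(t, values):
    base = BinnedSeries(np.asarray(t, float), np.asarray(values, float))
    return NormalizedSeries(raw=base, values=base.values,
                            baseline_window_min=(-15.0, 0.0),
                            baseline_mean=1.0, baseline_p95=1.0)


class TestAssembleDesign:
    def sessions(self, n_dcz=6, n_veh=4):
        t = np.arange(-5, 5, dtype=float)
        out = []
        for i in range(n_dcz + n_veh):
            subj = "monkey1" if i % 2 == 0 else "monkey2"
            treat = "DCZ" if i < n_dcz else "vehicle"
            out.append((series_for(t, np.ones(10)), subj, treat, f"s{i:02d}"))
        return out

    def test_cohort_coding(self):
        design = assemble_design(self.sessions(), bin_range_min=(-5, 5))
        assert design.y.shape == (10, 10)
        assert int(design.v.sum()) == 6
        assert set(design.u) == {-1.0, 1.0}

    def test_single_subject_rejected(self):
        t = np.arange(-2, 2, dtype=float)
        sess = [(series_for(t, np.ones(4)), "monkey1", "DCZ", f"s{i}") for i in range(3)]
        with pytest.raises(DesignError, match="two subjects"):
            assemble_design(sess, bin_range_min=(-2, 2))

    def test_shuffled_input_gives_identical_design(self, rng):
        sess = self.sessions()
        shuffled = list(sess)
        rng.shuffle(shuffled)
        d1 = assemble_design(sess, bin_range_min=(-5, 5))
        d2 = assemble_design(shuffled, bin_range_min=(-5, 5))
        np.testing.assert_array_equal(d1.y, d2.y)
        np.testing.assert_array_equal(d1.u, d2.u)
        assert d1.session_ids == d2.session_ids


def fitted_small_posterior(seed=1, **kw):
    t = np.arange(-8, 8, dtype=float)
    u = np.array([-1.0, -1.0, 1.0, 1.0])
    v = np.array([1.0, 0.0, 1.0, 0.0])
    draw = simulate_from_state_space(
        t, u, v, sigma=0.05, sigma_M=0.1, sigma_y=0.03, sigma_T=0.1,
        seed=99, d_T_path=np.where(t >= 0, -0.6, 0.0),
    )
    data = StateSpaceData(t, draw.y, u, v)
    post = fit_posterior(data, chains=2, draws=kw.pop("draws", 200),
                         warmup=kw.pop("warmup", 200), seed=seed, **kw)
    return draw, data, post


class TestFit:
    def test_same_seed_identical_draws(self):
        _, _, p1 = fitted_small_posterior(seed=4, draws=80, warmup=80)
        _, _, p2 = fitted_small_posterior(seed=4, draws=80, warmup=80)
        np.testing.assert_array_equal(p1.yhat, p2.yhat)
        np.testing.assert_array_equal(p1.sigma, p2.sigma)
        np.testing.assert_array_equal(p1.log_post, p2.log_post)

    def test_map_recovers_step_effect(self):
        draw, data, post = fitted_small_posterior(seed=2, draws=300, warmup=250)
        truth = draw.yhat[(data.bin_start_min >= 0) & (data.bin_start_min < 3)].mean() - 0.6
        assert post.map_window_effect(1, (0, 3)) == pytest.approx(truth, abs=0.15)

    def test_vehicle_group_summary_is_trend_only(self):
        _, _, post = fitted_small_posterior(seed=3, draws=100, warmup=100)
        mask = post.data.window_mask(0, 3)
        trend_only = post.flat(post.yhat)[:, mask].mean(axis=1)
        np.testing.assert_allclose(post.window_effect_draws(0, (0, 3)), trend_only)

    def test_window_mean_linearity(self):
        _, _, post = fitted_small_posterior(seed=5, draws=100, warmup=100)
        mask = post.data.window_mask(-3, 0)
        per_bin = post.flat(post.yhat) + post.flat(post.d_T)
        expected = per_bin[:, mask].mean(axis=1).mean()
        assert post.window_effect_draws(1, (-3, 0)).mean() == pytest.approx(expected)


class TestSummaries:
    def degenerate_posterior(self):
        t = np.arange(-4, 4, dtype=float)
        T = t.size
        y = np.ones((2, T))
        data = StateSpaceData(t, y, np.array([-1.0, 1.0]), np.array([0.0, 1.0]))
        yhat = np.ones((1, 4, T))
        d_T = np.full((1, 4, T), -0.5)
        scalar = np.full((1, 4), 0.1)
        post = StateSpacePosterior(
            data=data, priors=Priors(), yhat=yhat, d_M=np.zeros((1, 4)), d_T=d_T,
            sigma=scalar, sigma_M=scalar, sigma_y=scalar, sigma_T=scalar,
            log_post=np.zeros((1, 4)),
        )
        post.map_params = StateSpaceParams(
            yhat=np.ones(T), d_M=0.0, d_T=np.full(T, -0.5),
            sigma=0.1, sigma_M=0.1, sigma_y=0.1, sigma_T=0.1,
        )
        return post

    def test_degenerate_noiseless_summary_arithmetic(self):
        post = self.degenerate_posterior()
        summ = summarize_effect(post)
        assert summ["DCZ_post"].map_value == pytest.approx(0.5)
        assert summ["DCZ_post"].interval == (pytest.approx(0.5), pytest.approx(0.5))
        assert summ["vehicle_post"].map_value == pytest.approx(1.0)


class TestSeparation:
    def test_disjoint_intervals(self):
        rep = decide_separation((0.1, 0.4), (0.5, 0.9))
        assert rep.separated and rep.gap == pytest.approx(0.1)

    def test_touching_endpoints_overlap(self):
        rep = decide_separation((0.1, 0.5), (0.5, 0.9))
        assert not rep.separated

    def test_order_symmetric(self):
        assert decide_separation((0.5, 0.9), (0.1, 0.4)).separated

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            decide_separation((0.1, np.inf), (0.5, 0.9))
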
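"""Tests for the dual MAM-PF: search, marginalized EKF, stepping, tracking."""

import copy

import numpy as np
import pytest

from ppvtrack import mampf
from ppvtrack.mampf import (
    DegenerateFilterError,
    _initial_grid,
    ekf_update_cloud,
    initialize,
    search_ancestors,
    step,
    track,
)
from ppvtrack.model import CoefficientLayout, ModelConfig, clip_frequency
from ppvtrack.synth import default_spec, generate


def tracking_cfg(signal, n_particles=100, seed=0, **kw):
    return ModelConfig.from_signal(
        signal - signal.mean(), 40.0, n_cardiac_harmonics=5, n_resp_harmonics=2,
        n_particles_per_space=n_particles, rng_seed=seed, **kw)


class TestInitialize:
    def test_even_grid_before_jitter(self):
        np.testing.assert_allclose(_initial_grid(0.1, 0.5, 5, np.zeros(5)),
                                   [0.1, 0.2, 0.3, 0.4, 0.5])

    def test_uniform_scores_and_bounds(self, small_cfg):
        rng = np.random.default_rng(0)
        st = initialize(small_cfg, rng)
        for cloud, lo, hi in ((st.resp, small_cfg.f_resp_min, small_cfg.f_resp_max),
                              (st.card, small_cfg.f_card_min, small_cfg.f_card_max)):
            assert cloud.n_particles == small_cfg.n_particles_per_space
            assert np.all((cloud.f > lo - 1e-12) & (cloud.f <= hi + 1e-12))
            np.testing.assert_allclose(
                cloud.log_score, -np.log(small_cfg.n_particles_per_space))
            from scipy.special import logsumexp
            assert logsumexp(cloud.log_score) == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_identical(self, small_cfg):
        a = initialize(small_cfg, np.random.default_rng(3))
        b = initialize(small_cfg, np.random.default_rng(3))
        np.testing.assert_array_equal(a.resp.f, b.resp.f)
        np.testing.assert_array_equal(a.card.mean, b.card.mean)


class TestSearchAncestors:
    def test_prior_score_decides_on_equal_transition(self):
        # both ancestors predict the same frequency: the bigger score wins
        f_prev = np.array([0.3, 0.3])
        k, base = search_ancestors(np.array([0.31]), f_prev, f_prev,
                                   np.log([0.2, 0.8]), 1e-4, 0.95)
        assert k[0] == 1

    def test_gaussian_mode_decides_on_equal_scores(self):
        f_prev = np.array([0.30, 0.35])
        scores = np.log([0.5, 0.5])
        k, _ = search_ancestors(np.array([0.30]), f_prev, f_prev, scores,
                                1e-4, 1.0)
        assert k[0] == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = 10
            f_prev = rng.uniform(0.8, 2.3, n)
            f_mean = rng.uniform(0.8, 2.3, n)
            scores = rng.normal(0, 5, n)
            proposed = rng.uniform(0.8, 2.3, n)
            q, ar = 10 ** rng.uniform(-6, -2), 0.95
            k, base = search_ancestors(proposed, f_prev, f_mean, scores, q, ar)
            for i in range(n):
                best_val, best_k = -np.inf, -1
                for kk in range(n):
                    pred = f_mean[kk] + ar * (f_prev[kk] - f_mean[kk])
                    val = scores[kk] - 0.5 * (proposed[i] - pred) ** 2 / q
                    if val > best_val:
                        best_val, best_k = val, kk
                assert k[i] == best_k
                assert base[i] == pytest.approx(best_val)


class TestEkfUpdate:
    def test_textbook_scalar_case(self):
        """One active coefficient with unit gradient: prior N(0, 1), noise
        r = 1, measurement 2 -> posterior N(1, 0.5)."""
        lay = CoefficientLayout(1, 1)
        mean = np.zeros((1, lay.size))
        cov = np.zeros((1, lay.size, lay.size))
        cov[0, lay.c1.start, lay.c1.start] = 1.0
        mean_out, cov_out, nu, loglik, s = ekf_update_cloud(
            mean, cov, 2.0, 0.0, 0.0, lay, 1.0)
        assert nu[0] == pytest.approx(2.0)
        assert s[0] == pytest.approx(2.0)
        assert mean_out[0, lay.c1.start] == pytest.approx(1.0)
        assert cov_out[0, lay.c1.start, lay.c1.start] == pytest.approx(0.5)

    def test_zero_innovation_shrinks_covariance_only(self):
        lay = CoefficientLayout(1, 1)
        mean = np.zeros((1, lay.size))
        mean[0, lay.c1.start] = 3.0
        cov = np.eye(lay.size)[None] * 0.5
        y = 3.0  # exactly the prediction at theta = 0
        mean_out, cov_out, nu, _, _ = ekf_update_cloud(
            mean.copy(), cov.copy(), y, 0.0, 0.0, lay, 1.0)
        assert nu[0] == pytest.approx(0.0)
        np.testing.assert_allclose(mean_out, mean)
        assert np.trace(cov_out[0]) < np.trace(cov[0])

    def test_matches_exact_linear_kalman_filter(self):
        """With the modulation block frozen at zero the model is linear in
        the (r, c) coefficients; the marginalized EKF must match a textbook
        Kalman filter to near machine precision over 200 steps."""
        lay = CoefficientLayout(3, 2)
        rng = np.random.default_rng(2)
        n_rc = 2 * (lay.n_resp + lay.n_card)
        r_var = 0.5
        q_rc = 1e-4
        truth_coeff = rng.normal(0, 1.0, n_rc)

        mean = np.zeros((1, lay.size))
        cov = np.zeros((1, lay.size, lay.size))
        rc = np.r_[np.arange(lay.r1.start, lay.r2.stop),
                   np.arange(lay.c1.start, lay.c2.stop)]
        cov[0, rc, rc] = 1.0

        kf_mean = np.zeros(n_rc)
        kf_cov = np.eye(n_rc)

        jj = np.arange(1, lay.n_resp + 1)
        kk = np.arange(1, lay.n_card + 1)
        worst = 0.0
        for n in range(200):
            th_r, th_c = 2 * np.pi * 0.25 * n / 40, 2 * np.pi * 1.2 * n / 40
            h_lin = np.concatenate([np.cos(jj * th_r), np.sin(jj * th_r),
                                    np.cos(kk * th_c), np.sin(kk * th_c)])
            y = h_lin @ truth_coeff + rng.normal(0, np.sqrt(r_var))
            # marginalized EKF time + measurement update (m block frozen)
            cov[0, rc, rc] += q_rc
            mean, cov, _, _, _ = ekf_update_cloud(mean, cov, y, th_r, th_c,
                                                  lay, r_var)
            # textbook linear KF (predict-update with Joseph form)
            kf_cov = kf_cov + q_rc * np.eye(n_rc)
            s = h_lin @ kf_cov @ h_lin + r_var
            k_gain = kf_cov @ h_lin / s
            kf_mean = kf_mean + k_gain * (y - h_lin @ kf_mean)
            ikh = np.eye(n_rc) - np.outer(k_gain, h_lin)
            kf_cov = ikh @ kf_cov @ ikh.T + r_var * np.outer(k_gain, k_gain)
            worst = max(worst, np.max(np.abs(mean[0, rc] - kf_mean)))
        assert worst < 1e-8
        # the frozen modulation block never moves
        np.testing.assert_array_equal(mean[0, lay.m1], 0.0)


def enumerate_step(state, y_n, cfg, noise):
    """Straight-line scalar enumeration of one filter step (independent of
    the vectorized implementation); ``noise`` holds the per-space
    (u_fbar, u_f) draws.  Returns per-space dicts of expected arrays."""
    out = []
    frozen = state.frozen_theta_cum.copy()
    two_pi = 2 * np.pi
    lay = cfg.layout
    for j, cloud in enumerate((state.resp, state.card)):
        lo, hi = ((cfg.f_resp_min, cfg.f_resp_max) if j == 0
                  else (cfg.f_card_min, cfg.f_card_max))
        q = cfg.q_freq_resp if j == 0 else cfg.q_freq_card
        u_fbar, u_f = noise[j]
        n_p = cloud.n_particles
        f_new = np.empty(n_p)
        fbar_new = np.empty(n_p)
        th_new = np.empty(n_p)
        scores = np.empty(n_p)
        means = np.empty_like(cloud.mean)
        covs = np.empty_like(cloud.cov)
        for i in range(n_p):
            th_new[i] = cloud.theta_cum[i] + two_pi * cfg.sample_period * cloud.f[i]
            fbar_new[i] = clip_frequency(cloud.f_mean[i] + u_fbar[i], lo, hi)
            f_new[i] = clip_frequency(
                cloud.f_mean[i] + cfg.ar_coeff * (cloud.f[i] - cloud.f_mean[i]) + u_f[i],
                lo, hi)
        for i in range(n_p):
            best_val, best_k = -np.inf, -1
            for k in range(n_p):
                pred = cloud.f_mean[k] + cfg.ar_coeff * (cloud.f[k] - cloud.f_mean[k])
                val = cloud.log_score[k] - 0.5 * (f_new[i] - pred) ** 2 / q
                if val > best_val:
                    best_val, best_k = val, k
            p = cloud.cov[i] + np.diag(lay.process_noise_diag(cfg))
            mean_i = cloud.mean[i].copy()
            th_r = th_new[i] if j == 0 else frozen[0]
            th_c = frozen[1] if j == 0 else th_new[i]
            from ppvtrack.model import measure_flat, measurement_gradient_flat
            y_hat, *_ = measure_flat(th_r % two_pi, th_c % two_pi, mean_i, lay)
            h = measurement_gradient_flat(th_r % two_pi, th_c % two_pi, mean_i, lay)
            s = float(h @ p @ h) + cfg.meas_noise_var
            gain = p @ h / s
            nu = y_n - float(y_hat)
            mean_i = mean_i + gain * nu
            ikh = np.eye(lay.size) - np.outer(gain, h)
            p = ikh @ p @ ikh.T + cfg.meas_noise_var * np.outer(gain, gain)
            scores[i] = best_val - 0.5 * (nu ** 2 / s + np.log(s))
            means[i] = mean_i
            covs[i] = p
        m = scores.max()
        scores = scores - (m + np.log(np.sum(np.exp(scores - m))))
        out.append(dict(f=f_new, f_mean=fbar_new, theta_cum=th_new,
                        log_score=scores, mean=means, cov=covs))
    return out


class TestStep:
    def test_matches_straight_line_enumeration(self):
        """One full dual step on a 3-particle toy agrees with an independent
        scalar enumeration of the search/update/selection recursion."""
        cfg = ModelConfig(
            n_cardiac_harmonics=2, n_resp_harmonics=1, n_particles_per_space=3,
            meas_noise_var=0.5, q_resp_coeff=1e-3, q_card_coeff=1e-3,
            q_mod_coeff=1e-5, init_resp_amp=0.5, init_card_amp=1.0,
            init_mod_amp=0.01, rng_seed=21)
        rng = np.random.default_rng(cfg.rng_seed)
        state = initialize(cfg, rng)
        step(state, 0.7, cfg, rng, first=True)
        snapshot = copy.deepcopy(state)
        # replay the rng draws the next step will consume
        rng_tape = np.random.default_rng(cfg.rng_seed)
        _ = initialize(cfg, rng_tape)
        n_p = cfg.n_particles_per_space
        noise = []
        for space, q in ((0, cfg.q_freq_resp), (1, cfg.q_freq_card)):
            u_fbar = rng_tape.normal(0.0, np.sqrt(q), n_p)
            u_f = rng_tape.normal(0.0, np.sqrt(q), n_p)
            noise.append((u_fbar, u_f))
        expected = enumerate_step(snapshot, -0.4, cfg, noise)
        step(state, -0.4, cfg, rng, first=False)
        for cloud, exp in zip((state.resp, state.card), expected):
            np.testing.assert_allclose(cloud.f, exp["f"], atol=1e-12)
            np.testing.assert_allclose(cloud.f_mean, exp["f_mean"], atol=1e-12)
            np.testing.assert_allclose(cloud.theta_cum, exp["theta_cum"], atol=1e-12)
            np.testing.assert_allclose(cloud.log_score, exp["log_score"], atol=1e-9)
            np.testing.assert_allclose(cloud.mean, exp["mean"], atol=1e-9)
            np.testing.assert_allclose(cloud.cov, exp["cov"], atol=1e-9)

    def test_map_selection_prefers_higher_alpha(self, small_cfg):
        rng = np.random.default_rng(1)
        state = initialize(small_cfg, rng)
        step(state, 0.5, small_cfg, rng, first=True)
        i1, i2 = state.i_star
        a1 = state.resp.log_score[i1]
        a2 = state.card.log_score[i2]
        expected = 0 if a1 >= a2 else 1
        assert state.i_star_map == expected

    def test_degenerate_input_raises(self, small_cfg):
        rng = np.random.default_rng(1)
        state = initialize(small_cfg, rng)
        with pytest.raises(DegenerateFilterError):
            step(state, np.nan, small_cfg, rng, first=True)


@pytest.fixture(scope="module")
def short_run():
    spec = default_spec(duration=30.0, seed=6)
    signal, truth = generate(spec)
    cfg = tracking_cfg(signal, n_particles=40, seed=5)
    return signal, truth, cfg, track(signal, cfg)


class TestTrack:

    def test_deterministic_given_seed(self, short_run):
        signal, _, cfg, res = short_run
        res2 = track(signal, cfg)
        np.testing.assert_array_equal(res.f_resp, res2.f_resp)
        np.testing.assert_array_equal(res.f_card, res2.f_card)
        np.testing.assert_array_equal(res.coeff_means, res2.coeff_means)
        np.testing.assert_array_equal(res.y_hat, res2.y_hat)

    def test_map_frequencies_within_bounds(self, short_run):
        _, _, cfg, res = short_run
        assert np.all((res.f_resp > cfg.f_resp_min - 1e-12)
                      & (res.f_resp <= cfg.f_resp_max + 1e-12))
        assert np.all((res.f_card > cfg.f_card_min - 1e-12)
                      & (res.f_card <= cfg.f_card_max + 1e-12))

    def test_result_shapes_and_times(self, short_run):
        signal, _, cfg, res = short_run
        n = signal.size
        assert res.t.shape == res.f_resp.shape == res.y_hat.shape == (n,)
        assert res.coeff_means.shape == (n, cfg.layout.size)
        assert res.t[1] - res.t[0] == pytest.approx(cfg.sample_period)

    def test_particle_budget_constant(self, small_cfg):
        """The filter always carries exactly 2 N_p particles."""
        rng = np.random.default_rng(0)
        state = initialize(small_cfg, rng)
        n_p = small_cfg.n_particles_per_space
        for n in range(30):
            step(state, np.sin(0.3 * n), small_cfg, rng, first=(n == 0))
            assert state.resp.n_particles == n_p
            assert state.card.n_particles == n_p
            from scipy.special import logsumexp
            assert logsumexp(state.resp.log_score) == pytest.approx(0.0, abs=1e-9)
            assert logsumexp(state.card.log_score) == pytest.approx(0.0, abs=1e-9)
            assert np.isfinite(state.resp.log_score.max())

    def test_cardiac_frequency_recovery_short(self):
        """The cardiac rate of a clean synthetic record is recovered within
        a few beats' worth of samples."""
        spec = default_spec(duration=40.0, seed=2)
        signal, _ = generate(spec)
        cfg = tracking_cfg(signal, n_particles=80, seed=3)
        res = track(signal, cfg)
        assert np.median(np.abs(res.f_card[800:] - 1.2)) < 0.05


class TestRejuvenation:
    def test_respread_preserves_budget_and_bounds(self, small_cfg):
        cfg = small_cfg.replace(rejuvenate=True, rejuv_patience=1, rejuv_gap=1.0,
                                n_particles_per_space=10)
        rng = np.random.default_rng(4)
        state = initialize(cfg, rng)
        # make the scores grossly degenerate
        state.resp.log_score[:] = -200.0
        state.resp.log_score[3] = 0.0
        for n in range(5):
            step(state, 0.1 * n, cfg, rng, first=(n == 0))
        assert state.resp.n_particles == 10
        assert np.all(state.resp.f > cfg.f_resp_min - 1e-12)
        assert np.all(state.resp.f <= cfg.f_resp_max + 1e-12)


class TestParticleCountMonotonicity:
    def test_more_particles_do_not_hurt(self):
        """90th-percentile steady-state cardiac frequency error does not
        increase (beyond Monte-Carlo slack) when the particle budget grows."""
        errs = {50: [], 150: []}
        for seed in range(4):
            spec = default_spec(duration=60.0, seed=seed)
            signal, _ = generate(spec)
            for n_p in errs:
                cfg = tracking_cfg(signal, n_particles=n_p, seed=50 + seed)
                res = track(signal, cfg)
                errs[n_p].append(np.abs(res.f_card[1200:] - 1.2))
        p90 = {n_p: np.percentile(np.concatenate(v), 90) for n_p, v in errs.items()}
        assert p90[150] <= p90[50] + 0.02
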
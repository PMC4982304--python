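"""Dual maximum a-posteriori marginalized particle filter (dual MAM-PF).

The tracker estimates, per sample, the instantaneous respiratory and cardiac
frequencies and the sinusoidal/modulation coefficients of the ABP model.
The two instantaneous frequencies have multimodal posteriors and are
estimated with particles; the coefficients are conditionally (almost)
linear-Gaussian and are marginalized with an extended Kalman filter carried
by every particle (Rao-Blackwellization).

Instead of one particle cloud over the 2-D (respiratory, cardiac) frequency
space, the filter runs two 1-D clouds of N_p particles each — 2*N_p
particles total rather than N_p^2 — assuming the two frequencies are
independent.  Each cloud treats the *other* rhythm's kinematics as known,
frozen at the most recent MAP estimate of the other cloud (the "dual"
contract, borrowed from dual Kalman filtering).

Per step, for each space: every particle proposes a new frequency from its
own process model, then searches all previous particles for the best
ancestor by accumulated MAP score plus transition density (a Viterbi-style
trajectory search that replaces weight-proportional resampling), inherits
the ancestor's Kalman state, performs the EKF time and measurement updates,
and accumulates its score.  The per-space MAP particle supplies the
frequency estimates; the Kalman estimate is taken from whichever space holds
the larger (normalized) MAP score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import (
    CoefficientLayout,
    ConfigError,
    ModelConfig,
    clip_frequency,
    measure_flat,
    measurement_gradient_flat,
)

__all__ = ["SpaceCloud", "FilterState", "TrackResult", "initialize",
           "search_ancestors", "ekf_update_cloud", "step", "track"]

RESP, CARD = 0, 1


class DegenerateFilterError(RuntimeError):
    """All particles reached -inf score; the filter lost the signal."""


@dataclass
class SpaceCloud:
    """One 1-D particle space: N_p hypotheses about a single rhythm.

    ``f``/``f_mean``: instantaneous and mean frequency per particle (Hz);
    ``theta``/``theta_cum``: wrapped and cumulative angle; ``mean``/``cov``:
    marginalized Kalman state (flat coefficient vector) per particle;
    ``log_score``: accumulated MAP score (normalized so logsumexp = 0);
    ``ancestors``: ancestor index chosen by the last trajectory search.
    """

    f: np.ndarray
    f_mean: np.ndarray
    theta: np.ndarray
    theta_cum: np.ndarray
    mean: np.ndarray
    cov: np.ndarray
    log_score: np.ndarray
    ancestors: np.ndarray
    last_s: np.ndarray | None = None
    degeneracy_run: int = 0

    @property
    def n_particles(self) -> int:
        return self.f.shape[0]

    @property
    def map_index(self) -> int:
        return int(np.argmax(self.log_score))


@dataclass
class FilterState:
    """Both particle spaces plus the shared (frozen) cross-space estimates."""

    resp: SpaceCloud
    card: SpaceCloud
    # MAP estimates of the previous completed step (the dual contract):
    map_f: np.ndarray          # (2,) [f_resp, f_card]
    map_theta: np.ndarray      # (2,) wrapped
    map_theta_cum: np.ndarray  # (2,)
    map_coeff: np.ndarray      # (d,) Kalman estimate of the winning space
    # consensus phase clocks: cumulative angles advanced by the MAP
    # frequencies each step; continuous by construction, these are the
    # cross-space angles each cloud's EKFs condition on
    frozen_theta_cum: np.ndarray = field(default_factory=lambda: np.zeros(2))
    i_star: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=int))
    i_star_map: int = RESP

    def spaces(self):
        return (self.resp, self.card)


@dataclass
class TrackResult:
    """Per-sample MAP trajectory of a tracking run."""

    t: np.ndarray
    f_resp: np.ndarray
    f_card: np.ndarray
    theta_resp: np.ndarray
    theta_card: np.ndarray
    theta_resp_cum: np.ndarray
    theta_card_cum: np.ndarray
    coeff_means: np.ndarray    # (N, d)
    y_hat: np.ndarray
    gamma_hat: np.ndarray
    innovation: np.ndarray
    log_evidence: np.ndarray   # per-sample proxy: sum of per-space score shifts
    config: ModelConfig
    signal_mean: float = 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.t,
            "f_resp_hz": self.f_resp,
            "f_card_hz": self.f_card,
            "theta_resp": self.theta_resp,
            "theta_card": self.theta_card,
            "theta_resp_cum": self.theta_resp_cum,
            "y_hat": self.y_hat + self.signal_mean,
            "gamma_hat": self.gamma_hat,
            "innovation": self.innovation,
        })


def _initial_grid(f_min: float, f_max: float, n: int, jitter: np.ndarray) -> np.ndarray:
    grid = np.linspace(f_min, f_max, n)
    return clip_frequency(grid + jitter, f_min, f_max)


def initialize(cfg: ModelConfig, rng: np.random.Generator) -> FilterState:
    """Spread particles evenly over each frequency range and seed the EKFs.

    Frequencies (instantaneous and mean) start on a deterministic grid over
    [f_min, f_max] plus a small jitter (1/20 of the grid step); angles start
    at 0; coefficient means are zero except the first-harmonic amplitudes,
    which take the configured initial scales; the coefficient covariance is
    diagonal with each block's initial amplitude squared.  Scores start
    uniform (logsumexp = 0).
    """
    layout = cfg.layout
    n_p = cfg.n_particles_per_space
    clouds = []
    for space in (RESP, CARD):
        f_min, f_max = ((cfg.f_resp_min, cfg.f_resp_max) if space == RESP
                        else (cfg.f_card_min, cfg.f_card_max))
        step_sz = (f_max - f_min) / max(n_p - 1, 1)
        jitter = rng.normal(0.0, step_sz / 20.0, size=n_p)
        f = _initial_grid(f_min, f_max, n_p, jitter)
        mean = np.zeros((n_p, layout.size))
        mean[:, layout.r1.start] = cfg.init_resp_amp
        mean[:, layout.c1.start] = cfg.init_card_amp
        mean[:, layout.m1.start] = cfg.init_mod_amp
        diag = np.empty(layout.size)
        diag[layout.r1] = diag[layout.r2] = cfg.init_resp_amp ** 2
        diag[layout.c1] = diag[layout.c2] = cfg.init_card_amp ** 2
        diag[layout.m1] = diag[layout.m2] = cfg.init_mod_amp ** 2
        cov = np.zeros((n_p, layout.size, layout.size))
        cov[:, np.arange(layout.size), np.arange(layout.size)] = diag
        clouds.append(SpaceCloud(
            f=f.copy(), f_mean=f.copy(),
            theta=np.zeros(n_p), theta_cum=np.zeros(n_p),
            mean=mean, cov=cov,
            log_score=np.full(n_p, -np.log(n_p)),
            ancestors=np.arange(n_p),
        ))
    resp, card = clouds
    i0 = np.array([resp.map_index, card.map_index])
    return FilterState(
        resp=resp, card=card,
        map_f=np.array([resp.f[i0[0]], card.f[i0[1]]]),
        map_theta=np.zeros(2), map_theta_cum=np.zeros(2),
        map_coeff=resp.mean[i0[0]].copy(),
        i_star=i0, i_star_map=RESP,
    )


def search_ancestors(f_proposed: np.ndarray, f_prev: np.ndarray,
                     f_mean_prev: np.ndarray, log_score_prev: np.ndarray,
                     q_freq: float, ar_coeff: float,
                     meas_loglik: np.ndarray | None = None):
    """Viterbi-style best-ancestor search for a whole cloud.

    For each proposed frequency the best previous particle k maximizes the
    accumulated score ``log_score_prev[k]`` plus the transition log-density
    ``log N(f_proposed; f_mean[k] + ar*(f[k]-f_mean[k]), q)`` plus — in the
    exact form — the measurement log-likelihood of the proposal under
    ancestor k's predicted Kalman state (``meas_loglik``, shape
    (proposer, ancestor)).  With ``meas_loglik=None`` the likelihood term is
    dropped (the approximation in which it is evaluated with the proposer's
    own Kalman prediction and hence cancels from the argmax).  Ties break
    toward the lowest index.

    The likelihood term participates only in the *choice* of ancestor; the
    returned base score is the ancestor's score plus the transition density
    (the measurement likelihood enters the score recursion once, after the
    EKF update).  Additive constants are dropped; they vanish in the
    per-space normalization.

    Returns ``(ancestor_indices, base_scores)``.
    """
    pred = f_mean_prev + ar_coeff * (f_prev - f_mean_prev)  # (N_p,)
    log_trans = -0.5 * (f_proposed[:, None] - pred[None, :]) ** 2 / q_freq
    total = log_score_prev[None, :] + log_trans
    if meas_loglik is not None:
        k_star = np.argmax(total + meas_loglik, axis=1)
    else:
        k_star = np.argmax(total, axis=1)
    base = total[np.arange(total.shape[0]), k_star]
    return k_star, base


def cross_measurement_loglik(y_n: float, theta_own: np.ndarray, theta_frozen: float,
                             own_is_resp: bool, mean_prev: np.ndarray,
                             s_prev: np.ndarray, layout: CoefficientLayout):
    """Log-likelihood of y_n for every (proposer angle, ancestor Kalman state) pair.

    ``theta_own``: (N_p,) proposed angles of this space; ``mean_prev``:
    (N_p, d) candidate ancestors' coefficient means; ``s_prev``: (N_p,)
    innovation variances from the ancestors' last update (reused as the
    likelihood scale).  Returns an (N_p, N_p) matrix, proposers by ancestors.
    """
    n_p = mean_prev.shape[0]
    if own_is_resp:
        th_r = np.asarray(theta_own, float)
        cr, sr = _resp_trig(th_r, layout.n_resp)        # (N_i, Nr)
        cc, sc = _card_trig(float(theta_frozen), layout.n_card)  # (Nc,)
        gamma = cr @ mean_prev[:, layout.r1].T + sr @ mean_prev[:, layout.r2].T
        kappa = mean_prev[:, layout.c1] * cc + mean_prev[:, layout.c2] * sc  # (N_k, Nc)
        m1 = mean_prev[:, layout.m1].reshape(n_p, layout.n_card, layout.n_resp)
        m2 = mean_prev[:, layout.m2].reshape(n_p, layout.n_card, layout.n_resp)
        rho = 1.0 + np.einsum("ij,kKj->ikK", cr, m1) + np.einsum("ij,kKj->ikK", sr, m2)
        y_hat = gamma + np.einsum("ikK,kK->ik", rho, kappa)
    else:
        th_c = np.asarray(theta_own, float)
        cr, sr = _resp_trig(float(theta_frozen), layout.n_resp)  # (Nr,)
        cc, sc = _card_trig(th_c, layout.n_card)        # (N_i, Nc)
        gamma = mean_prev[:, layout.r1] @ cr + mean_prev[:, layout.r2] @ sr  # (N_k,)
        m1 = mean_prev[:, layout.m1].reshape(n_p, layout.n_card, layout.n_resp)
        m2 = mean_prev[:, layout.m2].reshape(n_p, layout.n_card, layout.n_resp)
        rho = 1.0 + m1 @ cr + m2 @ sr                    # (N_k, Nc)
        y_hat = gamma[None, :] + np.einsum("iK,kK->ik", cc, rho * mean_prev[:, layout.c1]) \
            + np.einsum("iK,kK->ik", sc, rho * mean_prev[:, layout.c2])
    nu = y_n - y_hat
    return -0.5 * (nu ** 2 / s_prev[None, :] + np.log(s_prev[None, :]))


def _resp_trig(theta, n_resp: int):
    a = np.multiply.outer(np.asarray(theta, float), np.arange(1, n_resp + 1))
    return np.cos(a), np.sin(a)


def _card_trig(theta, n_card: int):
    a = np.multiply.outer(np.asarray(theta, float), np.arange(1, n_card + 1))
    return np.cos(a), np.sin(a)


def ekf_update_cloud(mean: np.ndarray, cov: np.ndarray, y_n: float,
                     theta_r, theta_c, layout: CoefficientLayout,
                     meas_noise_var: float):
    """Vectorized EKF measurement update for a whole cloud.

    ``mean``: (N_p, d), ``cov``: (N_p, d, d); ``theta_r``/``theta_c`` scalars
    or (N_p,).  Linearizes the bilinear measurement at the predicted mean and
    updates mean and covariance *in place* (optimal-gain Joseph form, which
    stays symmetric by construction); returns them with the innovation, the
    per-particle Gaussian log-likelihood increment (2*pi constant dropped)
    and the innovation variance.
    """
    n_p = mean.shape[0]
    th_r = np.broadcast_to(np.asarray(theta_r, float), (n_p,))
    th_c = np.broadcast_to(np.asarray(theta_c, float), (n_p,))
    y_hat, _, _, _ = measure_flat(th_r, th_c, mean, layout)
    h = measurement_gradient_flat(th_r, th_c, mean, layout)  # (N_p, d)
    nu = y_n - y_hat
    ph = (cov @ h[:, :, None])[:, :, 0]
    s = np.einsum("id,id->i", h, ph) + meas_noise_var
    bad = s <= 0
    if np.any(bad):
        # covariance lost PSD numerically: re-symmetrize and floor eigenvalues
        for i in np.where(bad)[0]:
            c = 0.5 * (cov[i] + cov[i].T)
            w, v = np.linalg.eigh(c)
            cov[i] = (v * np.maximum(w, 0.0)) @ v.T
        ph = (cov @ h[:, :, None])[:, :, 0]
        s = np.einsum("id,id->i", h, ph) + meas_noise_var
        s = np.maximum(s, np.finfo(float).tiny)
    # optimal-gain Joseph form collapses to P - (PH)(PH)^T / S, which is
    # symmetric by construction; mean and cov are updated in place
    mean += ph * (nu / s)[:, None]
    cov -= ph[:, :, None] * (ph / s[:, None])[:, None, :]
    loglik = -0.5 * (nu ** 2 / s + np.log(s))
    return mean, cov, nu, loglik, s


def _rejuvenate(cloud: SpaceCloud, cfg: ModelConfig, f_min: float, f_max: float) -> None:
    """Re-spread the weakest particles when the cloud stays degenerate.

    Triggered when the top score has exceeded the median by ``rejuv_gap`` for
    ``rejuv_patience`` consecutive steps; the lowest-scoring fraction is
    re-spread evenly over the frequency range, keeping the MAP particle's
    angle and Kalman state.  Deterministic (no RNG draws).
    """
    gap = cloud.log_score.max() - np.median(cloud.log_score)
    if gap <= cfg.rejuv_gap:
        cloud.degeneracy_run = 0
        return
    cloud.degeneracy_run += 1
    if cloud.degeneracy_run < cfg.rejuv_patience:
        return
    cloud.degeneracy_run = 0
    n_re = max(1, int(cfg.rejuv_fraction * cloud.n_particles))
    order = np.argsort(cloud.log_score)
    worst = order[:n_re]
    i_map = cloud.map_index
    new_f = np.linspace(f_min, f_max, n_re + 2)[1:-1]
    cloud.f[worst] = new_f
    cloud.f_mean[worst] = new_f
    cloud.theta[worst] = cloud.theta[i_map]
    cloud.theta_cum[worst] = cloud.theta_cum[i_map]
    cloud.mean[worst] = cloud.mean[i_map]
    cloud.cov[worst] = cloud.cov[i_map]
    # re-entry at the middle of the pack: a respread hypothesis cannot
    # displace the MAP outright but overtakes within seconds if its per-step
    # likelihood is genuinely better
    cloud.log_score[worst] = np.median(cloud.log_score)
    cloud.log_score -= logsumexp(cloud.log_score)


def step(state: FilterState, y_n: float, cfg: ModelConfig,
         rng: np.random.Generator, first: bool = False,
         frozen_override: np.ndarray | None = None):
    """Advance both particle spaces by one measurement.

    Spaces are processed in fixed order (respiratory, then cardiac), both
    using the *previous* step's opposite-space MAP kinematics advanced one
    sample deterministically.  Returns the per-sample MAP summary dict.
    RNG draw order: per space, mean-frequency noise vector then
    instantaneous-frequency noise vector.
    """
    layout = cfg.layout
    q_diag = layout.process_noise_diag(cfg)
    two_pi = 2.0 * np.pi
    # frozen cross-estimates: the consensus clocks (continuous cumulative
    # angles advanced by the MAP frequencies), already at this sample's time
    if frozen_override is not None:
        frozen_theta = np.asarray(frozen_override, float)
    else:
        frozen_theta = state.frozen_theta_cum
    new_clouds = []
    for space, cloud in zip((RESP, CARD), state.spaces()):
        f_min, f_max = ((cfg.f_resp_min, cfg.f_resp_max) if space == RESP
                        else (cfg.f_card_min, cfg.f_card_max))
        q_freq = cfg.q_freq_resp if space == RESP else cfg.q_freq_card
        n_p = cloud.n_particles
        if first:
            f_new = cloud.f
            f_mean_new = cloud.f_mean
            theta_new = cloud.theta
            theta_cum_new = cloud.theta_cum
            k_star = np.arange(n_p)
            base = cloud.log_score.copy()
            mean = cloud.mean.copy()
            cov = cloud.cov.copy()
        else:
            u_fbar = rng.normal(0.0, np.sqrt(q_freq), size=n_p)
            u_f = rng.normal(0.0, np.sqrt(q_freq), size=n_p)
            dth = two_pi * cfg.sample_period * cloud.f
            theta_new = np.mod(cloud.theta + dth, two_pi)
            theta_cum_new = cloud.theta_cum + dth
            f_mean_new = clip_frequency(cloud.f_mean + u_fbar, f_min, f_max)
            f_new = clip_frequency(
                cloud.f_mean + cfg.ar_coeff * (cloud.f - cloud.f_mean) + u_f,
                f_min, f_max)
            meas_ll = None
            if cfg.exact_search and cloud.last_s is not None:
                frozen = (frozen_theta[CARD] if space == RESP
                          else frozen_theta[RESP]) % two_pi
                meas_ll = cross_measurement_loglik(
                    y_n, theta_new, frozen, space == RESP,
                    cloud.mean, cloud.last_s, layout)
            k_star, base = search_ancestors(
                f_new, cloud.f, cloud.f_mean, cloud.log_score,
                q_freq, cfg.ar_coeff, meas_ll)
            if cfg.inherit_kalman:
                mean = cloud.mean[k_star]
                cov = cloud.cov[k_star]
            else:
                # each particle's EKF evolves in its own lineage; the arrays
                # are consumed and rebound below, so update in place
                mean = cloud.mean
                cov = cloud.cov
            cov[:, np.arange(layout.size), np.arange(layout.size)] += q_diag
        if space == RESP:
            th_r, th_c = theta_new, frozen_theta[CARD] % two_pi
        else:
            th_r, th_c = frozen_theta[RESP] % two_pi, theta_new
        mean, cov, nu, loglik, s_vec = ekf_update_cloud(
            mean, cov, y_n, th_r, th_c, layout, cfg.meas_noise_var)
        score = base + loglik
        if not np.any(np.isfinite(score)):
            raise DegenerateFilterError(
                f"all particles of space {space} at -inf score "
                f"(y_n={y_n!r}); signal scaling or noise config is off")
        peak = score.max()
        shift = peak + np.log(np.sum(np.exp(score - peak)))
        score = score - shift
        new_cloud = SpaceCloud(
            f=f_new.copy() if first else f_new,
            f_mean=f_mean_new.copy() if first else f_mean_new,
            theta=theta_new.copy() if first else theta_new,
            theta_cum=theta_cum_new.copy() if first else theta_cum_new,
            mean=mean, cov=cov, log_score=score, ancestors=k_star,
            last_s=s_vec, degeneracy_run=cloud.degeneracy_run,
        )
        if cfg.rejuvenate and not first:
            _rejuvenate(new_cloud, cfg, f_min, f_max)
        new_clouds.append((new_cloud, shift, nu))
    resp, shift_r, nu_r = new_clouds[0]
    card, shift_c, nu_c = new_clouds[1]
    # sticky MAP extraction: the incumbent keeps the title unless beaten by
    # the hysteresis margin (prevents phase flapping between near-ties)
    i_star = []
    for j, cloud in enumerate((resp, card)):
        cand = cloud.map_index
        prev = int(state.i_star[j])
        if first or cloud.log_score[cand] - cloud.log_score[prev] >= cfg.map_hysteresis:
            i_star.append(cand)
        else:
            i_star.append(prev)
    i1, i2 = i_star
    prev_winner = state.i_star_map
    a1, a2 = resp.log_score[i1], card.log_score[i2]
    if first:
        winner = RESP if a1 >= a2 else CARD
    elif prev_winner == RESP:
        winner = CARD if a2 - a1 >= cfg.map_hysteresis else RESP
    else:
        winner = RESP if a1 - a2 >= cfg.map_hysteresis else CARD
    win_cloud, win_idx = (resp, i1) if winner == RESP else (card, i2)
    state.resp, state.card = resp, card
    state.map_f = np.array([resp.f[i1], card.f[i2]])
    state.map_theta = np.array([resp.theta[i1], card.theta[i2]])
    state.map_theta_cum = np.array([resp.theta_cum[i1], card.theta_cum[i2]])
    state.map_coeff = win_cloud.mean[win_idx].copy()
    state.i_star = np.array([i1, i2])
    state.i_star_map = winner
    # report the angle pair the winning EKF was conditioned on this step
    if winner == RESP:
        th_r_cum, th_c_cum = resp.theta_cum[i1], frozen_theta[CARD]
    else:
        th_r_cum, th_c_cum = frozen_theta[RESP], card.theta_cum[i2]
    y_hat, gamma, _, _ = measure_flat(th_r_cum % two_pi, th_c_cum % two_pi,
                                      state.map_coeff, layout)
    # advance the consensus clocks to the next sample with the new MAP rates
    state.frozen_theta_cum = state.frozen_theta_cum \
        + two_pi * cfg.sample_period * state.map_f
    return {
        "f_resp": resp.f[i1], "f_card": card.f[i2],
        "theta_resp": th_r_cum % two_pi, "theta_card": th_c_cum % two_pi,
        "theta_resp_cum": th_r_cum, "theta_card_cum": th_c_cum,
        "coeff": state.map_coeff, "y_hat": float(y_hat),
        "gamma_hat": float(gamma), "innovation": float(y_n - y_hat),
        "log_evidence": float(shift_r + shift_c),
    }


def track(signal: np.ndarray, cfg: ModelConfig,
          signal_mean: float | None = None) -> TrackResult:
    """Run the dual MAM-PF over a full (mean-centered) signal.

    ``signal`` must be mean-centered (the model has no DC state); pass the
    removed mean as ``signal_mean`` so exported envelopes can be re-offset.
    If the signal mean is not negligible it is removed here and a warning
    would be in order upstream.  Deterministic given ``cfg.rng_seed``.
    """
    y = np.asarray(signal, dtype=float)
    if signal_mean is None:
        signal_mean = float(np.mean(y))
        y = y - signal_mean
    n_t = y.shape[0]
    layout = cfg.layout
    rng = np.random.default_rng(cfg.rng_seed)
    state = initialize(cfg, rng)
    out = {k: np.empty(n_t) for k in
           ("f_resp", "f_card", "theta_resp", "theta_card",
            "theta_resp_cum", "theta_card_cum", "y_hat", "gamma_hat",
            "innovation", "log_evidence")}
    coeffs = np.empty((n_t, layout.size))
    for n in range(n_t):
        est = step(state, y[n], cfg, rng, first=(n == 0))
        for k in out:
            out[k][n] = est[k]
        coeffs[n] = est["coeff"]
    return TrackResult(
        t=np.arange(n_t) * cfg.sample_period,
        f_resp=out["f_resp"], f_card=out["f_card"],
        theta_resp=out["theta_resp"], theta_card=out["theta_card"],
        theta_resp_cum=out["theta_resp_cum"], theta_card_cum=out["theta_card_cum"],
        coeff_means=coeffs, y_hat=out["y_hat"], gamma_hat=out["gamma_hat"],
        innovation=out["innovation"], log_evidence=out["log_evidence"],
        config=cfg, signal_mean=signal_mean,
    )
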
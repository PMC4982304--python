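"""State-space model of an amplitude-modulated multi-harmonic ABP signal.

The arterial blood pressure waveform of a spontaneously breathing subject is
modeled as the sum of a respiratory baseline and a cardiac harmonic series
whose per-harmonic amplitude is modulated at respiratory harmonics:

    y_n = gamma_n + sum_k rho_{k,n} * kappa_{k,n} + v_n

    gamma_n   = sum_j r_{1,j} cos(j th_r) + r_{2,j} sin(j th_r)     (respiration)
    rho_{k,n} = 1 + sum_j m_{1,k,j} cos(j th_r) + m_{2,k,j} sin(j th_r)
    kappa_{k,n} = c_{1,k} cos(k th_c) + c_{2,k} sin(k th_c)         (k-th cardiac partial)

with white Gaussian measurement noise v_n of variance ``r``.  The hidden
state splits into *kinematic* variables (instantaneous angles, instantaneous
frequencies, instantaneous mean frequencies of the two rhythms) and
*coefficient* variables (the sinusoidal coefficients above).  Mean
frequencies follow random walks reflected at known physiological bounds;
instantaneous frequencies mean-revert toward them with AR coefficient
``ar_coeff``; coefficients follow independent random walks.

Everything here is shared between the synthetic-signal generator
(:mod:`ppvtrack.synth`) and the tracker (:mod:`ppvtrack.mampf`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ConfigError",
    "FrequencyOvershootError",
    "ModelConfig",
    "ParticleKinematics",
    "CoefficientState",
    "CoefficientLayout",
    "clip_frequency",
    "measure",
    "measurement_gradient",
    "propagate_kinematics",
    "propagate_coefficients",
]


class ConfigError(ValueError):
    """Invalid model configuration (bounds, dimensions, variances)."""


class FrequencyOvershootError(ValueError):
    """A frequency overshoots its bound by more than the bound range.

    One reflection at the bound must suffice; a larger excursion indicates a
    mis-scaled frequency process-noise variance.
    """


@dataclass
class ModelConfig:
    """All user-specified design parameters of the tracker.

    Frequency bounds and counts default to the published design table; the
    signal-dependent scales (measurement noise variance, coefficient process
    noise variances, initial coefficient amplitudes) have no universal
    default and are derived from the signal by :meth:`from_signal`.

    Units: frequencies in Hz, ``sample_period`` in s, ``meas_noise_var`` and
    the coefficient variances in squared signal units (mm Hg^2) per step,
    frequency variances in Hz^2 per step, initial amplitudes in signal units.
    """

    n_cardiac_harmonics: int = 10
    n_resp_harmonics: int = 3
    n_particles_per_space: int = 250
    f_resp_min: float = 6.0 / 60.0
    f_resp_max: float = 30.0 / 60.0
    f_card_min: float = 50.0 / 60.0
    f_card_max: float = 140.0 / 60.0
    sample_period: float = 1.0 / 40.0
    meas_noise_var: float = 1.0
    q_freq_resp: float = 1e-6 / 40.0
    q_freq_card: float = 1e-6 / 40.0
    q_resp_coeff: float = 1e-6 / 40.0
    q_mod_coeff: float = 1e-8 / 40.0
    q_card_coeff: float = 1e-6 / 40.0
    init_resp_amp: float = 0.1
    init_mod_amp: float = 1e-3
    init_card_amp: float = 0.1
    ar_coeff: float = 0.95
    angle_grid_size: int = 256
    rng_seed: int = 0
    # rejuvenation of degenerate particle clouds (no classic resampling);
    # off by default: re-seeded hypotheses carry a transplanted coefficient
    # state whose phase pairing decays, and in simulation they destabilize
    # the tracked modulation more often than they rescue a stuck cloud
    rejuvenate: bool = False
    rejuv_gap: float = 50.0
    rejuv_patience: int = 80
    rejuv_fraction: float = 0.1
    # ancestor search: if True, include the measurement likelihood of each
    # candidate ancestor's predicted Kalman state in the trajectory search
    # (the exact form); if False, use the prior-score + transition-density
    # approximation only
    exact_search: bool = False
    # if True, a particle adopts its chosen ancestor's Kalman state; if
    # False (default) the search reassigns only the accumulated score and
    # each particle's EKF evolves within its own lineage.  Transplanting
    # coefficient states across particles whose angle histories have
    # diverged corrupts the receiving EKF, so the default keeps lineages.
    inherit_kalman: bool = False
    # MAP extraction hysteresis (nats): the reported MAP particle changes
    # only when a challenger beats the incumbent by this margin.  Keeps the
    # reported phase trajectory from flapping between near-tied particles
    # whose angle histories differ.
    map_hysteresis: float = 3.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.f_resp_min < self.f_resp_max):
            raise ConfigError("need 0 < f_resp_min < f_resp_max")
        if not (0 < self.f_card_min < self.f_card_max):
            raise ConfigError("need 0 < f_card_min < f_card_max")
        if self.sample_period <= 0:
            raise ConfigError("sample_period must be > 0")
        for name in ("meas_noise_var", "q_freq_resp", "q_freq_card",
                     "q_resp_coeff", "q_mod_coeff", "q_card_coeff"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_particles_per_space < 2:
            raise ConfigError("n_particles_per_space must be >= 2")
        if self.angle_grid_size < 8:
            raise ConfigError("angle_grid_size must be >= 8")
        if not (0 < self.ar_coeff <= 1):
            raise ConfigError("ar_coeff must be in (0, 1]")
        if self.n_cardiac_harmonics < 1 or self.n_resp_harmonics < 1:
            raise ConfigError("harmonic counts must be >= 1")

    @classmethod
    def from_signal(cls, signal: np.ndarray, sample_rate: float,
                    **overrides) -> "ModelConfig":
        """Build a config with the signal-dependent design-table scalings.

        ``r = var(y)/1e3``; frequency variances ``1e-6 * T_s``; respiratory
        and cardiac coefficient variances ``var(y) * 1e-6 * T_s``; modulation
        variances ``var(y) * 1e-8 * T_s``; initial respiratory/cardiac
        amplitudes ``std(y)/10``; initial modulation amplitude ``std(y)/1e3``.
        """
        y = np.asarray(signal, dtype=float)
        v = float(np.var(y))
        s = float(np.std(y))
        ts = 1.0 / float(sample_rate)
        params = dict(
            sample_period=ts,
            meas_noise_var=v / 1e3,
            q_freq_resp=1e-6 * ts,
            q_freq_card=1e-6 * ts,
            q_resp_coeff=v * 1e-6 * ts,
            q_card_coeff=v * 1e-6 * ts,
            q_mod_coeff=v * 1e-8 * ts,
            init_resp_amp=s / 1e1,
            init_card_amp=s / 1e1,
            init_mod_amp=s / 1e3,
        )
        params.update(overrides)
        return cls(**params)

    @property
    def n_particles_total(self) -> int:
        return 2 * self.n_particles_per_space

    @property
    def layout(self) -> "CoefficientLayout":
        return CoefficientLayout(self.n_cardiac_harmonics, self.n_resp_harmonics)

    def replace(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


class CoefficientLayout:
    """Bijective map between structured coefficient blocks and a flat vector.

    Order: respiratory block (component 1 then 2, harmonic ascending),
    cardiac block likewise, modulation block (component 1 then 2; within a
    component cardiac index k outer, respiratory index j inner).  The order
    is arbitrary but fixed for the life of a run.
    """

    def __init__(self, n_card: int, n_resp: int):
        self.n_card = int(n_card)
        self.n_resp = int(n_resp)
        nr, nc = self.n_resp, self.n_card
        self.size = 2 * nr + 2 * nc + 2 * nc * nr
        self.r1 = slice(0, nr)
        self.r2 = slice(nr, 2 * nr)
        self.c1 = slice(2 * nr, 2 * nr + nc)
        self.c2 = slice(2 * nr + nc, 2 * nr + 2 * nc)
        self.m1 = slice(2 * nr + 2 * nc, 2 * nr + 2 * nc + nc * nr)
        self.m2 = slice(2 * nr + 2 * nc + nc * nr, self.size)

    def __eq__(self, other) -> bool:
        return (isinstance(other, CoefficientLayout)
                and (self.n_card, self.n_resp) == (other.n_card, other.n_resp))

    def flatten(self, resp: np.ndarray, card: np.ndarray, mod: np.ndarray) -> np.ndarray:
        resp = np.asarray(resp, float)
        card = np.asarray(card, float)
        mod = np.asarray(mod, float)
        if resp.shape != (2, self.n_resp) or card.shape != (2, self.n_card) \
                or mod.shape != (2, self.n_card, self.n_resp):
            raise ConfigError("coefficient block shapes inconsistent with layout")
        vec = np.empty(self.size)
        vec[self.r1], vec[self.r2] = resp[0], resp[1]
        vec[self.c1], vec[self.c2] = card[0], card[1]
        vec[self.m1] = mod[0].reshape(-1)
        vec[self.m2] = mod[1].reshape(-1)
        return vec

    def unflatten(self, vec: np.ndarray):
        """Inverse of :meth:`flatten`; supports leading batch dimensions."""
        vec = np.asarray(vec, float)
        if vec.shape[-1] != self.size:
            raise ConfigError("flat vector length inconsistent with layout")
        lead = vec.shape[:-1]
        resp = np.stack([vec[..., self.r1], vec[..., self.r2]], axis=-2)
        card = np.stack([vec[..., self.c1], vec[..., self.c2]], axis=-2)
        mod = np.stack([
            vec[..., self.m1].reshape(lead + (self.n_card, self.n_resp)),
            vec[..., self.m2].reshape(lead + (self.n_card, self.n_resp)),
        ], axis=-3)
        return resp, card, mod

    def process_noise_diag(self, cfg: ModelConfig) -> np.ndarray:
        """Diagonal of the coefficient random-walk covariance Q."""
        q = np.empty(self.size)
        q[self.r1] = q[self.r2] = cfg.q_resp_coeff
        q[self.c1] = q[self.c2] = cfg.q_card_coeff
        q[self.m1] = q[self.m2] = cfg.q_mod_coeff
        return q


@dataclass
class ParticleKinematics:
    """Kinematic state of one hypothesis: frequencies and angles (both rhythms).

    Angles are stored wrapped to [0, 2pi); the unwrapped cumulative angles are
    carried alongside so respiratory cycles can be counted downstream.
    """

    f_resp: float
    f_card: float
    f_resp_mean: float
    f_card_mean: float
    theta_resp: float
    theta_card: float
    theta_resp_cum: float = 0.0
    theta_card_cum: float = 0.0


@dataclass
class CoefficientState:
    """Gaussian belief over the sinusoidal coefficients.

    ``resp_coeffs``: (2, N_r), ``card_coeffs``: (2, N_c), ``mod_coeffs``:
    (2, N_c, N_r); ``covariance`` over the flattened vector (see
    :class:`CoefficientLayout`).
    """

    resp_coeffs: np.ndarray
    card_coeffs: np.ndarray
    mod_coeffs: np.ndarray
    covariance: np.ndarray | None = None

    @classmethod
    def zeros(cls, layout: CoefficientLayout) -> "CoefficientState":
        return cls(
            resp_coeffs=np.zeros((2, layout.n_resp)),
            card_coeffs=np.zeros((2, layout.n_card)),
            mod_coeffs=np.zeros((2, layout.n_card, layout.n_resp)),
            covariance=np.zeros((layout.size, layout.size)),
        )

    def flat_mean(self, layout: CoefficientLayout) -> np.ndarray:
        return layout.flatten(self.resp_coeffs, self.card_coeffs, self.mod_coeffs)

    @classmethod
    def from_flat(cls, vec: np.ndarray, layout: CoefficientLayout,
                  covariance: np.ndarray | None = None) -> "CoefficientState":
        resp, card, mod = layout.unflatten(vec)
        return cls(resp, card, mod, covariance)


def clip_frequency(f, f_min: float, f_max: float):
    """Reflecting clip confining a frequency to (f_min, f_max].

    In-range values pass unchanged; an overshoot bounces back off the nearest
    bound (``f_max - (f - f_max)`` above, ``f_min + (f_min - f)`` at or
    below the lower bound).  A hard saturation would work too, but saturated
    particles stick to the bound and never leave it; the reflection keeps
    them moving.  Scalar or ndarray input.
    """
    if not f_min < f_max:
        raise ConfigError("clip_frequency requires f_min < f_max")
    f = np.asarray(f, dtype=float)
    span = f_max - f_min
    if np.any(np.abs(np.where(f > f_max, f - f_max, np.minimum(f - f_min, 0.0))) >= span):
        raise FrequencyOvershootError(
            "frequency overshoots its bound by more than the bound range; "
            "check the frequency process-noise variance")
    out = np.where(f > f_max, 2 * f_max - f, np.where(f <= f_min, 2 * f_min - f, f))
    return float(out) if out.ndim == 0 else out


def _resp_basis(theta_r, n_resp: int):
    j = np.arange(1, n_resp + 1)
    a = np.multiply.outer(np.asarray(theta_r, float), j)  # (..., Nr)
    return np.cos(a), np.sin(a)


def _card_basis(theta_c, n_card: int):
    k = np.arange(1, n_card + 1)
    a = np.multiply.outer(np.asarray(theta_c, float), k)  # (..., Nc)
    return np.cos(a), np.sin(a)


def measure_flat(theta_r, theta_c, vec: np.ndarray, layout: CoefficientLayout):
    """Noise-free measurement mean and its decomposition, batched.

    ``theta_r``, ``theta_c`` broadcast against the leading dims of ``vec``
    (shape ``(..., layout.size)``).  Returns ``(y, gamma, rho, kappa)`` with
    ``rho``/``kappa`` of shape ``(..., N_c)``.
    """
    vec = np.asarray(vec, float)
    if vec.shape[-1] != layout.size:
        raise ConfigError("flat vector length inconsistent with layout")
    cr, sr = _resp_basis(theta_r, layout.n_resp)
    cc, sc = _card_basis(theta_c, layout.n_card)
    gamma = np.sum(vec[..., layout.r1] * cr + vec[..., layout.r2] * sr, axis=-1)
    m_shape = vec.shape[:-1] + (layout.n_card, layout.n_resp)
    m1 = vec[..., layout.m1].reshape(m_shape)
    m2 = vec[..., layout.m2].reshape(m_shape)
    rho = 1.0 + np.sum(m1 * cr[..., None, :] + m2 * sr[..., None, :], axis=-1)
    kappa = vec[..., layout.c1] * cc + vec[..., layout.c2] * sc
    y = gamma + np.sum(rho * kappa, axis=-1)
    return y, gamma, rho, kappa


def measure(kin: ParticleKinematics, coeffs: CoefficientState, cfg: ModelConfig):
    """Measurement mean y = gamma + sum_k rho_k kappa_k plus its parts.

    Returns ``(y, gamma, rho, kappa)`` where ``rho`` and ``kappa`` are the
    per-cardiac-harmonic modulation factors and partials.
    """
    layout = cfg.layout
    vec = coeffs.flat_mean(layout)
    return measure_flat(kin.theta_resp, kin.theta_card, vec, layout)


def measurement_gradient_flat(theta_r, theta_c, vec: np.ndarray,
                              layout: CoefficientLayout) -> np.ndarray:
    """Gradient of the measurement mean w.r.t. the flat coefficient vector.

    The model is bilinear in (c, m): the gradient entries are
    cos(j th_r)/sin(j th_r) for the r block, rho_k cos(k th_c)/sin(k th_c)
    for the c block, and kappa_k cos(j th_r)/sin(j th_r) for the m block,
    all evaluated at the supplied coefficients.  Batched like
    :func:`measure_flat`.
    """
    vec = np.asarray(vec, float)
    _, _, rho, kappa = measure_flat(theta_r, theta_c, vec, layout)
    cr, sr = _resp_basis(theta_r, layout.n_resp)
    cc, sc = _card_basis(theta_c, layout.n_card)
    lead = np.broadcast_shapes(vec.shape[:-1], np.shape(np.asarray(theta_r, float)))
    grad = np.empty(lead + (layout.size,))
    grad[..., layout.r1] = np.broadcast_to(cr, lead + (layout.n_resp,))
    grad[..., layout.r2] = np.broadcast_to(sr, lead + (layout.n_resp,))
    grad[..., layout.c1] = rho * cc
    grad[..., layout.c2] = rho * sc
    grad[..., layout.m1] = (kappa[..., :, None] * cr[..., None, :]).reshape(
        lead + (layout.n_card * layout.n_resp,))
    grad[..., layout.m2] = (kappa[..., :, None] * sr[..., None, :]).reshape(
        lead + (layout.n_card * layout.n_resp,))
    return grad


def measurement_gradient(kin: ParticleKinematics, coeffs: CoefficientState,
                         cfg: ModelConfig) -> np.ndarray:
    layout = cfg.layout
    return measurement_gradient_flat(kin.theta_resp, kin.theta_card,
                                     coeffs.flat_mean(layout), layout)


def propagate_kinematics(kin: ParticleKinematics, cfg: ModelConfig,
                         noise: Sequence[float] = (0.0, 0.0, 0.0, 0.0)
                         ) -> ParticleKinematics:
    """One step of the kinematic process model with supplied noise draws.

    ``noise = (u_fbar_resp, u_fbar_card, u_f_resp, u_f_card)`` in Hz.  Angles
    advance by 2*pi*T_s*f using the pre-step instantaneous frequencies; mean
    frequencies follow reflected random walks; instantaneous frequencies
    mean-revert toward the (pre-step) mean with coefficient ``ar_coeff`` and
    are confined to the same bounds by the same reflection.
    """
    u_fbar_r, u_fbar_c, u_f_r, u_f_c = noise
    two_pi = 2.0 * np.pi
    dth_r = two_pi * cfg.sample_period * kin.f_resp
    dth_c = two_pi * cfg.sample_period * kin.f_card
    fbar_r = clip_frequency(kin.f_resp_mean + u_fbar_r, cfg.f_resp_min, cfg.f_resp_max)
    fbar_c = clip_frequency(kin.f_card_mean + u_fbar_c, cfg.f_card_min, cfg.f_card_max)
    f_r = kin.f_resp_mean + cfg.ar_coeff * (kin.f_resp - kin.f_resp_mean) + u_f_r
    f_c = kin.f_card_mean + cfg.ar_coeff * (kin.f_card - kin.f_card_mean) + u_f_c
    f_r = clip_frequency(f_r, cfg.f_resp_min, cfg.f_resp_max)
    f_c = clip_frequency(f_c, cfg.f_card_min, cfg.f_card_max)
    return ParticleKinematics(
        f_resp=f_r, f_card=f_c, f_resp_mean=fbar_r, f_card_mean=fbar_c,
        theta_resp=(kin.theta_resp + dth_r) % two_pi,
        theta_card=(kin.theta_card + dth_c) % two_pi,
        theta_resp_cum=kin.theta_resp_cum + dth_r,
        theta_card_cum=kin.theta_card_cum + dth_c,
    )


def propagate_coefficients(coeffs: CoefficientState, cfg: ModelConfig) -> CoefficientState:
    """Random-walk time update: mean unchanged, covariance grows by diag(Q)."""
    layout = cfg.layout
    if coeffs.covariance is None:
        raise ConfigError("coefficient state has no covariance to propagate")
    cov = np.array(coeffs.covariance, dtype=float, copy=True)
    if cov.shape != (layout.size, layout.size):
        raise ConfigError("covariance shape inconsistent with layout")
    cov[np.diag_indices_from(cov)] += layout.process_noise_diag(cfg)
    return CoefficientState(coeffs.resp_coeffs.copy(), coeffs.card_coeffs.copy(),
                            coeffs.mod_coeffs.copy(), cov)
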
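"""Signal envelopes, pulse-pressure envelopes and the continuous PPV index.

Given per-sample estimates of the model coefficients and the respiratory
angle, the upper/lower envelopes of the ABP oscillation are found by
maximizing/minimizing the modulated cardiac sum over the cardiac angle; the
pulse-pressure (PP) envelopes by optimizing the modulated PP expression over
the respiratory angle; and the continuous PPV index as

    PPV (%) = 100 * (eps_u - eps_l) / ((eps_u + eps_l) / 2)

where eps_u, eps_l are the upper/lower PP envelopes (the continuous
counterparts of PP_max and PP_min of a respiratory cycle).  The traditional
once-per-cycle PPV from beat annotations is provided as the comparator.

Both angle optimizations are over trigonometric polynomials; they are solved
with a coarse grid over [0, 2pi) followed by a golden-section refinement,
vectorized over samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import CoefficientLayout, ModelConfig

__all__ = [
    "EnvelopeTraces",
    "CyclePPV",
    "abp_envelopes",
    "pp_envelopes",
    "ppv_continuous",
    "ppv_per_cycle",
    "compute_envelope_traces",
    "respiratory_cycle_bounds",
]

log = logging.getLogger(__name__)

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class EnvelopeTraces:
    """Per-sample envelope and PPV traces (signal units; PPV in %)."""

    e_upper: np.ndarray
    e_lower: np.ndarray
    pp_upper: np.ndarray
    pp_lower: np.ndarray
    ppv: np.ndarray


@dataclass
class CyclePPV:
    """Traditional per-respiratory-cycle PPV from beat-wise pulse pressures."""

    t_start: float
    t_end: float
    pp_max: float
    pp_min: float
    ppv: float


def _trig_poly_argopt(w_cos, w_sin, grid_size: int, maximize: bool,
                      n_refine: int = 40):
    """arg-opt over theta of sum_k w_cos[k] cos(k th) + w_sin[k] sin(k th).

    ``w_cos``/``w_sin``: (N, K) per-sample weights.  Coarse grid of
    ``grid_size`` points on [0, 2pi) (grid ties broken toward the smaller
    angle) then ``n_refine`` golden-section iterations in the bracketing
    interval.  Returns (theta, value), each (N,).
    """
    w_cos = np.atleast_2d(np.asarray(w_cos, float))
    w_sin = np.atleast_2d(np.asarray(w_sin, float))
    n, k_max = w_cos.shape
    sign = 1.0 if maximize else -1.0
    kk = np.arange(1, k_max + 1)
    grid = np.linspace(0.0, 2.0 * np.pi, grid_size, endpoint=False)
    basis = np.multiply.outer(grid, kk)  # (G, K)
    vals = w_cos @ np.cos(basis).T + w_sin @ np.sin(basis).T  # (N, G)
    idx = np.argmax(sign * vals, axis=1)
    step = 2.0 * np.pi / grid_size

    def f(theta):
        a = theta[:, None] * kk
        return sign * (np.sum(w_cos * np.cos(a), axis=1)
                       + np.sum(w_sin * np.sin(a), axis=1))

    lo = grid[idx] - step
    hi = grid[idx] + step
    x1 = hi - _GOLDEN * (hi - lo)
    x2 = lo + _GOLDEN * (hi - lo)
    f1, f2 = f(x1), f(x2)
    for _ in range(n_refine):
        take_left = f1 >= f2  # keep [lo, x2]
        hi = np.where(take_left, x2, hi)
        lo = np.where(take_left, lo, x1)
        x1 = hi - _GOLDEN * (hi - lo)
        x2 = lo + _GOLDEN * (hi - lo)
        f1, f2 = f(x1), f(x2)
    theta = 0.5 * (lo + hi)
    f_theta = f(theta)
    # keep the grid point if refinement did not improve on it (flat regions)
    grid_f = sign * vals[np.arange(n), idx]
    worse = f_theta < grid_f
    theta = np.where(worse, grid[idx], theta)
    f_best = np.where(worse, grid_f, f_theta)
    return np.mod(theta, 2.0 * np.pi), sign * f_best


def _gamma_rho(vecs: np.ndarray, theta_r: np.ndarray, layout: CoefficientLayout):
    j = np.arange(1, layout.n_resp + 1)
    a = np.multiply.outer(np.asarray(theta_r, float), j)  # (N, Nr)
    cr, sr = np.cos(a), np.sin(a)
    gamma = np.sum(vecs[..., layout.r1] * cr + vecs[..., layout.r2] * sr, axis=-1)
    m_shape = vecs.shape[:-1] + (layout.n_card, layout.n_resp)
    m1 = vecs[..., layout.m1].reshape(m_shape)
    m2 = vecs[..., layout.m2].reshape(m_shape)
    rho = 1.0 + np.sum(m1 * cr[..., None, :] + m2 * sr[..., None, :], axis=-1)
    return gamma, rho, m1, m2


def abp_envelopes(coeff_means: np.ndarray, theta_resp: np.ndarray,
                  cfg: ModelConfig):
    """Upper/lower ABP envelopes and the per-harmonic extremal partials.

    ``coeff_means``: (N, d) flat coefficient estimates; ``theta_resp``: (N,)
    respiratory angles.  For each sample the cardiac angle that maximizes
    (minimizes) sum_k rho_k [c1k cos(k th) + c2k sin(k th)] is found; the
    envelopes are gamma + sum_k rho_k kappa_{max/min,k}.

    Returns ``(e_upper, e_lower, kappa_max, kappa_min, gamma, rho)`` with
    kappa arrays of shape (N, N_c).
    """
    layout = cfg.layout
    vecs = np.atleast_2d(np.asarray(coeff_means, float))
    theta_resp = np.atleast_1d(np.asarray(theta_resp, float))
    gamma, rho, _, _ = _gamma_rho(vecs, theta_resp, layout)
    c1 = vecs[..., layout.c1]
    c2 = vecs[..., layout.c2]
    th_max, _ = _trig_poly_argopt(rho * c1, rho * c2, cfg.angle_grid_size, True)
    th_min, _ = _trig_poly_argopt(rho * c1, rho * c2, cfg.angle_grid_size, False)
    k = np.arange(1, layout.n_card + 1)
    a_max = th_max[:, None] * k
    a_min = th_min[:, None] * k
    kappa_max = c1 * np.cos(a_max) + c2 * np.sin(a_max)
    kappa_min = c1 * np.cos(a_min) + c2 * np.sin(a_min)
    e_upper = gamma + np.sum(rho * kappa_max, axis=-1)
    e_lower = gamma + np.sum(rho * kappa_min, axis=-1)
    return e_upper, e_lower, kappa_max, kappa_min, gamma, rho


def pp_envelopes(coeff_means: np.ndarray, kappa_max: np.ndarray,
                 kappa_min: np.ndarray, cfg: ModelConfig, clamp: bool = True):
    """Upper/lower pulse-pressure envelopes.

    The PP expression sum_k (1 + rho_k(th)) (kappa_max,k - kappa_min,k) is
    optimized over the free respiratory angle th; rho_k(th) is the modulation
    series evaluated at th.  This collapses to a trigonometric polynomial in
    th with weights sum_k m_{.,k,j} dkappa_k.  Negative envelope values (early
    transients) are clamped at 0 when ``clamp`` is set; the count is logged.
    """
    layout = cfg.layout
    vecs = np.atleast_2d(np.asarray(coeff_means, float))
    dk = np.asarray(kappa_max, float) - np.asarray(kappa_min, float)  # (N, Nc)
    m_shape = vecs.shape[:-1] + (layout.n_card, layout.n_resp)
    m1 = vecs[..., layout.m1].reshape(m_shape)
    m2 = vecs[..., layout.m2].reshape(m_shape)
    base = np.sum(dk, axis=-1)
    w_cos = np.sum(m1 * dk[..., :, None], axis=-2)  # (N, Nr)
    w_sin = np.sum(m2 * dk[..., :, None], axis=-2)
    th_max, v_max = _trig_poly_argopt(w_cos, w_sin, cfg.angle_grid_size, True)
    th_min, v_min = _trig_poly_argopt(w_cos, w_sin, cfg.angle_grid_size, False)
    pp_upper = base + v_max
    pp_lower = base + v_min
    if clamp:
        n_neg = int(np.sum(pp_lower < 0) + np.sum(pp_upper < 0))
        if n_neg:
            log.info("clamped %d negative PP-envelope samples at 0", n_neg)
        pp_upper = np.maximum(pp_upper, 0.0)
        pp_lower = np.maximum(pp_lower, 0.0)
    return pp_upper, pp_lower


def ppv_continuous(pp_upper: np.ndarray, pp_lower: np.ndarray) -> np.ndarray:
    """Continuous PPV (%) from the PP envelopes; 0 where both envelopes are 0."""
    u = np.asarray(pp_upper, float)
    l = np.asarray(pp_lower, float)
    if np.any(u < 0) or np.any(l < 0):
        raise ValueError("PP envelopes must be nonnegative")
    if np.any(u < l):
        raise ValueError("upper PP envelope below lower PP envelope")
    mean = 0.5 * (u + l)
    out = np.zeros_like(mean)
    nz = mean > 0
    out[nz] = 100.0 * (u[nz] - l[nz]) / mean[nz]
    return out


def compute_envelope_traces(coeff_means: np.ndarray, theta_resp: np.ndarray,
                            cfg: ModelConfig, offset: float = 0.0) -> EnvelopeTraces:
    """Full chain: ABP envelopes -> PP envelopes -> continuous PPV.

    ``offset`` is added back to the ABP envelopes (signals are tracked
    mean-centered; envelopes are usually wanted in mm Hg).
    """
    e_u, e_l, k_max, k_min, _, _ = abp_envelopes(coeff_means, theta_resp, cfg)
    pp_u, pp_l = pp_envelopes(coeff_means, k_max, k_min, cfg)
    return EnvelopeTraces(e_u + offset, e_l + offset, pp_u, pp_l,
                          ppv_continuous(pp_u, pp_l))


def respiratory_cycle_bounds(theta_resp_cum: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Times at which the unwrapped respiratory angle crosses multiples of 2pi.

    Linear interpolation between samples; returns the crossing times, which
    delimit complete respiratory cycles.
    """
    th = np.asarray(theta_resp_cum, float)
    t = np.asarray(times, float)
    first = int(np.ceil(th[0] / (2 * np.pi)))
    last = int(np.floor(th[-1] / (2 * np.pi)))
    bounds = []
    targets = 2 * np.pi * np.arange(first, last + 1)
    idx = np.searchsorted(th, targets)
    for target, i in zip(targets, idx):
        if i == 0:
            bounds.append(t[0])
            continue
        i = min(i, len(th) - 1)
        frac = (target - th[i - 1]) / (th[i] - th[i - 1])
        bounds.append(t[i - 1] + frac * (t[i] - t[i - 1]))
    return np.asarray(bounds)


def ppv_per_cycle(peak_times, peak_values, trough_values, cycle_bounds) -> list[CyclePPV]:
    """Traditional once-per-cycle PPV from annotated beats.

    Each beat contributes PP = systolic - diastolic; within each respiratory
    cycle [t0, t1) the beats whose systolic peak falls in the cycle give
    PP_max and PP_min and PPV = 100 (PP_max - PP_min)/((PP_max + PP_min)/2).
    Cycles with fewer than two beats are flagged (logged) and skipped.
    """
    peak_times = np.asarray(peak_times, float)
    pp = np.asarray(peak_values, float) - np.asarray(trough_values, float)
    if peak_times.shape != pp.shape:
        raise ValueError("peak and trough annotation lengths differ")
    bounds = np.asarray(cycle_bounds, float)
    out: list[CyclePPV] = []
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        sel = (peak_times >= t0) & (peak_times < t1)
        if np.sum(sel) < 2:
            log.warning("respiratory cycle [%.2f, %.2f) s has < 2 beats; skipped", t0, t1)
            continue
        pp_max = float(np.max(pp[sel]))
        pp_min = float(np.min(pp[sel]))
        ppv = 100.0 * (pp_max - pp_min) / ((pp_max + pp_min) / 2.0)
        out.append(CyclePPV(float(t0), float(t1), pp_max, pp_min, ppv))
    return out
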
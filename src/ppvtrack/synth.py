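"""Synthetic ABP-like signal generator with exact ground truth.

Signals are rendered from the same forward model the tracker assumes: a
respiratory baseline plus an amplitude-modulated cardiac harmonic series,
with white Gaussian noise and a DC offset added on top.  Frequency
trajectories are deterministic profiles (constant, linear chirp, sinusoidal
drift) with closed-form phase integrals, so the true angles, coefficients,
envelopes and continuous PPV trace are known exactly — which is what makes
parameter-recovery tests unambiguous.  The generator emulates the harmonic
structure and respiratory modulation of real ABP, not the detailed pressure
morphology (no dicrotic notch, no arrhythmia).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .envelopes import EnvelopeTraces, compute_envelope_traces
from .model import ConfigError, ModelConfig, measure_flat

__all__ = [
    "FrequencyProfile",
    "ConstantProfile",
    "LinearChirp",
    "SinusoidalDrift",
    "SyntheticSpec",
    "SyntheticTruth",
    "generate",
    "truth_ppv_at",
    "default_spec",
    "write_truth_csv",
]


class FrequencyProfile:
    """Deterministic instantaneous-frequency trajectory f(t) with exact phase.

    ``phase(t)`` returns the cumulative integral of f from 0 to t (in cycles);
    the instantaneous angle is ``2*pi*phase(t)``.
    """

    def freq(self, t: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def phase(self, t: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass
class ConstantProfile(FrequencyProfile):
    f0: float

    def freq(self, t):
        return np.full_like(np.asarray(t, float), self.f0)

    def phase(self, t):
        return self.f0 * np.asarray(t, float)


@dataclass
class LinearChirp(FrequencyProfile):
    """Frequency ramping linearly from f0 at t=0 to f1 at t=duration."""

    f0: float
    f1: float
    duration: float

    def freq(self, t):
        t = np.asarray(t, float)
        return self.f0 + (self.f1 - self.f0) * t / self.duration

    def phase(self, t):
        t = np.asarray(t, float)
        return self.f0 * t + 0.5 * (self.f1 - self.f0) * t ** 2 / self.duration


@dataclass
class SinusoidalDrift(FrequencyProfile):
    """f(t) = f0 + amp * sin(2 pi t / period)."""

    f0: float
    amp: float
    period: float

    def freq(self, t):
        t = np.asarray(t, float)
        return self.f0 + self.amp * np.sin(2 * np.pi * t / self.period)

    def phase(self, t):
        t = np.asarray(t, float)
        w = 2 * np.pi / self.period
        return self.f0 * t + self.amp / w * (1.0 - np.cos(w * t))


@dataclass
class SyntheticSpec:
    """Everything needed to render one synthetic record.

    Coefficient arrays follow the model convention: ``resp_coeff_values``
    (2, N_r) in mm Hg, ``card_coeff_values`` (2, N_c) in mm Hg,
    ``mod_coeff_values`` (2, N_c, N_r) dimensionless.  The per-harmonic total
    modulation must satisfy sum_j |m| < 1 so modulation never inverts a
    cardiac partial.
    """

    duration: float
    sample_rate: float
    resp_freq_profile: FrequencyProfile
    card_freq_profile: FrequencyProfile
    resp_coeff_values: np.ndarray
    card_coeff_values: np.ndarray
    mod_coeff_values: np.ndarray
    baseline_offset: float = 90.0
    noise_std: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        self.resp_coeff_values = np.atleast_2d(np.asarray(self.resp_coeff_values, float))
        self.card_coeff_values = np.atleast_2d(np.asarray(self.card_coeff_values, float))
        self.mod_coeff_values = np.asarray(self.mod_coeff_values, float)
        if self.noise_std < 0:
            raise ConfigError("noise_std must be >= 0")
        if self.mod_coeff_values.ndim != 3:
            raise ConfigError("mod_coeff_values must be (2, N_c, N_r)")
        mod_total = np.sum(np.abs(self.mod_coeff_values), axis=(0, 2))
        if np.any(mod_total >= 1.0):
            raise ConfigError("per-harmonic modulation sum_j |m| must be < 1")

    @property
    def n_card(self) -> int:
        return self.card_coeff_values.shape[1]

    @property
    def n_resp(self) -> int:
        return self.resp_coeff_values.shape[1]


@dataclass
class SyntheticTruth:
    """Per-sample ground truth for a rendered record."""

    t: np.ndarray
    theta_resp: np.ndarray
    theta_card: np.ndarray
    theta_resp_cum: np.ndarray
    theta_card_cum: np.ndarray
    f_resp: np.ndarray
    f_card: np.ndarray
    clean: np.ndarray          # noise-free signal incl. baseline offset
    envelopes: EnvelopeTraces  # on the true coefficients; ABP envelopes incl. offset
    coeff_means: np.ndarray    # (N, d) true flat coefficient vectors

    @property
    def ppv(self) -> np.ndarray:
        return self.envelopes.ppv


def _check_profile(profile: FrequencyProfile, t: np.ndarray,
                   f_min: float, f_max: float, name: str) -> None:
    f = profile.freq(t)
    if np.any(f <= f_min) or np.any(f > f_max):
        raise ConfigError(
            f"{name} frequency profile leaves the configured range "
            f"({f_min:.4g}, {f_max:.4g}] Hz")


def generate(spec: SyntheticSpec, cfg: ModelConfig | None = None):
    """Render a synthetic record; returns ``(signal, truth)``.

    The returned ``signal`` includes the baseline offset and noise; the
    truth holds the noise-free decomposition and the envelope/PPV traces
    evaluated on the true coefficients.
    """
    if cfg is None:
        cfg = ModelConfig()
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    _check_profile(spec.resp_freq_profile, t, cfg.f_resp_min, cfg.f_resp_max, "respiratory")
    _check_profile(spec.card_freq_profile, t, cfg.f_card_min, cfg.f_card_max, "cardiac")
    truth_cfg = cfg.replace(n_cardiac_harmonics=spec.n_card,
                            n_resp_harmonics=spec.n_resp)
    layout = truth_cfg.layout
    th_r_cum = 2 * np.pi * spec.resp_freq_profile.phase(t)
    th_c_cum = 2 * np.pi * spec.card_freq_profile.phase(t)
    vec = layout.flatten(spec.resp_coeff_values, spec.card_coeff_values,
                         spec.mod_coeff_values)
    vecs = np.broadcast_to(vec, (n, layout.size))
    clean_centered, _, _, _ = measure_flat(th_r_cum, th_c_cum, vecs, layout)
    envelopes = compute_envelope_traces(vecs, th_r_cum, truth_cfg,
                                        offset=spec.baseline_offset)
    rng = np.random.default_rng(spec.rng_seed)
    noise = rng.normal(0.0, spec.noise_std, size=n) if spec.noise_std > 0 else 0.0
    clean = clean_centered + spec.baseline_offset
    signal = clean + noise
    truth = SyntheticTruth(
        t=t,
        theta_resp=np.mod(th_r_cum, 2 * np.pi),
        theta_card=np.mod(th_c_cum, 2 * np.pi),
        theta_resp_cum=th_r_cum,
        theta_card_cum=th_c_cum,
        f_resp=spec.resp_freq_profile.freq(t),
        f_card=spec.card_freq_profile.freq(t),
        clean=clean,
        envelopes=envelopes,
        coeff_means=np.array(vecs),
    )
    return signal, truth


def truth_ppv_at(truth: SyntheticTruth, t: float | np.ndarray):
    """True continuous PPV (%) at time ``t`` by linear interpolation."""
    t_arr = np.asarray(t, float)
    if np.any(t_arr < truth.t[0]) or np.any(t_arr > truth.t[-1]):
        raise ValueError("t outside the generated record")
    out = np.interp(t_arr, truth.t, truth.envelopes.ppv)
    return float(out) if np.ndim(t) == 0 else out


def default_spec(duration: float = 120.0, sample_rate: float = 40.0,
                 seed: int = 0, resp_freq: float = 0.25, card_freq: float = 1.2,
                 ppv_pct: float = 15.0, noise_std: float = 1.0,
                 card_profile: FrequencyProfile | None = None) -> SyntheticSpec:
    """Mid-range test spec: 3 cardiac harmonics of (30, 12, 6) mm Hg, a small
    two-harmonic respiratory baseline, and modulation depth giving the
    requested true PPV (uniform first-respiratory-harmonic modulation depth
    m = PPV/200 on every cardiac partial)."""
    n_card, n_resp = 3, 2
    card = np.zeros((2, n_card))
    card[0] = [30.0, 12.0, 6.0]
    resp = np.zeros((2, n_resp))
    resp[0] = [3.0, 1.0]
    mod = np.zeros((2, n_card, n_resp))
    mod[0, :, 0] = ppv_pct / 200.0
    return SyntheticSpec(
        duration=duration,
        sample_rate=sample_rate,
        resp_freq_profile=ConstantProfile(resp_freq),
        card_freq_profile=card_profile or ConstantProfile(card_freq),
        resp_coeff_values=resp,
        card_coeff_values=card,
        mod_coeff_values=mod,
        noise_std=noise_std,
        rng_seed=seed,
    )


def write_truth_csv(path, signal: np.ndarray, truth: SyntheticTruth) -> None:
    """Write signal plus ground-truth columns to CSV."""
    df = pd.DataFrame({
        "time_s": truth.t,
        "abp_mmhg": signal,
        "true_clean": truth.clean,
        "true_theta_resp": truth.theta_resp,
        "true_theta_card": truth.theta_card,
        "true_f_resp_hz": truth.f_resp,
        "true_f_card_hz": truth.f_card,
        "true_e_upper": truth.envelopes.e_upper,
        "true_e_lower": truth.envelopes.e_lower,
        "true_pp_upper": truth.envelopes.pp_upper,
        "true_pp_lower": truth.envelopes.pp_lower,
        "true_ppv_pct": truth.envelopes.ppv,
    })
    df.to_csv(path, index=False)
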
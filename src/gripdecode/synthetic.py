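"""Synthetic grip-session generator with known ground truth.

Creates multichannel recordings carrying the statistical structure the
decoding pipeline assumes: movement-locked beta-power suppression and
gamma-power increase whose magnitudes scale with the per-trial self-rated
effort (SRE), a 1/f background plus a common-mode artifact shared by all
contacts, and a force channel produced by driving a known first-order
lag + dead-time model with the band-power envelopes.

Envelopes are defined on POWER: carriers are scaled by ``sqrt(1 + env)`` so
the extracted relative power change matches the envelope.  All randomness
flows from one seeded generator, so a fixed seed reproduces the session
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from gripdecode.exceptions import ConfigError, InputError
from gripdecode.features import (
    BANDS,
    DECODE_WINDOW,
    BandPowerTrace,
    ContinuousRecording,
    feature_times,
)
from gripdecode.models import get_model, params_to_dict, simulate_forward

__all__ = [
    "SyntheticConfig",
    "SyntheticSession",
    "DEFAULT_TRUE_PARAMS",
    "generate_band_envelopes",
    "synthesize_lfp",
    "generate_force",
    "generate_session",
]

#: Reference generating parameters per model id, chosen so that force stays
#: non-negative (gamma dominates) and peaks near 1 at maximal effort.
DEFAULT_TRUE_PARAMS: dict[int, tuple[float, ...]] = {
    1: (1.5, 0.2, 0.2),
    2: (2.0, -1.0, 0.2, 0.2),
    3: (1.5, 0.15, 0.15, -1.0, 0.3, 0.25),
    4: (1.5, -1.0, 0.5, 0.2, 0.2),
    5: (1.2, 0.15, 0.15, -0.8, 0.3, 0.25, 0.8, 0.25, 0.25),
    6: (2.0, 0.25, 0.2),
    7: (-2.0, 0.2, 0.2),
    8: (2.0, 0.2, 0.2),
}

#: Per-band monopolar carrier gains (contacts 0-3, caudal->cranial).  The
#: large gain step between contacts 1 and 2 concentrates the modulated
#: carrier in bipolar pair 12, making it the most reactive pair by
#: construction (pairs 01 and 23 see almost none of it).
CONTACT_GAINS: dict[str, tuple[float, float, float, float]] = {
    "alpha": (1.0, 1.35, 2.05, 1.75),
    "beta": (1.0, 1.35, 2.20, 1.90),
    "gamma": (1.0, 1.30, 2.10, 1.80),
}

#: Gains of an additional UNmodulated background carrier per band.  Its
#: contribution nearly cancels on pair 12 but dominates pairs 01 and 23, so
#: the off-pairs show small, stable relative power changes instead of
#: noise-driven spurious suppressions, keeping channel selection reliable.
BACKGROUND_GAINS: dict[str, tuple[float, float, float, float]] = {
    "alpha": (1.5, 0.70, 0.75, 1.50),
    "beta": (1.5, 0.70, 0.75, 1.50),
    "gamma": (1.5, 0.70, 0.75, 1.50),
}


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults mirror the experimental paradigm."""

    n_trials: int = 30
    fs: float = 512.0
    trial_spacing: tuple[float, float] = (11.0, 13.0)  # uniform, seconds
    cue_duration: float = 3.0
    sre_levels: Sequence[int] | None = None  # explicit per-trial SRE, else sampled
    true_model_id: int = 2
    true_params: Sequence[float] | None = None  # defaults per model id
    beta_mod_depth: float = -0.3  # fractional power change at maximal effort
    gamma_mod_depth: float = 0.3
    alpha_mod_depth: float = 0.3
    envelope_rise_tau: float = 0.15  # seconds
    #: Per-band envelope timing.  The bands are given clearly distinct time
    #: courses -- gamma a fast onset transient, beta a slower sustained
    #: suppression, alpha a late slow component -- so the multi-branch
    #: models remain identifiable from the generated data.
    band_latency: dict[str, float] = field(
        default_factory=lambda: {"alpha": 0.9, "beta": 0.45, "gamma": 0.25}
    )
    band_tau_scale: dict[str, float] = field(
        default_factory=lambda: {"alpha": 2.5, "beta": 2.0, "gamma": 0.5}
    )
    #: Transient onset overshoot above the sustained plateau (fraction of the
    #: plateau) and its decay constant.
    band_overshoot: dict[str, float] = field(
        default_factory=lambda: {"alpha": 0.0, "beta": 0.0, "gamma": 1.2}
    )
    overshoot_tau: float = 0.3
    #: "linear" (default) and "saturating" apply one mapping to every band;
    #: "per_band" uses band_effort_scaling below.
    effort_scaling: str = "linear"
    #: Effort->plateau mapping per band (effort_scaling="per_band").  Beta
    #: saturating over the low effort range while gamma scales across the
    #: whole range (alpha convex) decorrelates the band amplitudes across
    #: trials, which the noisy multi-branch recovery analyses need.
    band_effort_scaling: dict[str, str] = field(
        default_factory=lambda: {
            "alpha": "convex", "beta": "saturating", "gamma": "linear",
        }
    )
    noise_sd: float = 0.0  # force noise, fraction of max force
    common_mode_amp: float = 0.5
    pink_noise_amp: float = 0.2
    pink_noise_exponent: float = 1.0
    carrier_amp: float = 1.0
    feature_rate: float = 100.0
    lead_in: float = 5.0  # seconds before the first cue
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 2:
            raise ConfigError("need at least 2 trials")
        if self.fs <= 2 * BANDS["gamma"][1]:
            raise ConfigError(
                f"fs={self.fs} Hz too low for the gamma band "
                f"(need > {2 * BANDS['gamma'][1]} Hz)"
            )
        if self.sre_levels is not None:
            sre = np.asarray(self.sre_levels)
            if len(sre) != self.n_trials:
                raise ConfigError("sre_levels length must equal n_trials")
            if np.any((sre < 0) | (sre > 10)):
                raise ConfigError("sre_levels must lie in [0, 10]")
        if self.effort_scaling not in ("per_band", "linear", "saturating"):
            raise ConfigError(f"unknown effort_scaling {self.effort_scaling!r}")
        for kind in self.band_effort_scaling.values():
            if kind not in ("linear", "saturating", "convex"):
                raise ConfigError(f"unknown band effort scaling {kind!r}")
        get_model(self.true_model_id)

    @property
    def depths(self) -> dict[str, float]:
        return {
            "alpha": self.alpha_mod_depth,
            "beta": self.beta_mod_depth,
            "gamma": self.gamma_mod_depth,
        }

    def resolved_params(self) -> np.ndarray:
        p = (
            DEFAULT_TRUE_PARAMS[self.true_model_id]
            if self.true_params is None
            else self.true_params
        )
        p = np.asarray(p, dtype=float)
        params_to_dict(get_model(self.true_model_id), p)  # shape check
        return p


@dataclass
class SyntheticSession:
    """Generated recording plus the ground truth used to build it."""

    recording: ContinuousRecording
    true_envelopes: list[BandPowerTrace]  # per trial, on the feature grid
    true_force: np.ndarray  # (n_trials, n_feat), noiseless, feature rate
    observed_force: np.ndarray  # (n_trials, n_feat), with noise, clamped at 0
    true_params: np.ndarray
    true_model_id: int
    config: SyntheticConfig


def _effort_scale(sre: float, kind: str) -> float:
    """Monotone effort->modulation mapping on [0, 1], anchored at the extremes."""
    s = sre / 10.0
    if kind == "linear":
        return s
    if kind == "saturating":  # concave: most sensitive at low efforts
        return float((1.0 - np.exp(-2.5 * s)) / (1.0 - np.exp(-2.5)))
    if kind == "convex":  # most sensitive at high efforts
        return float(s ** 1.8)
    raise ConfigError(f"unknown effort scaling {kind!r}")


def _band_effort_kind(band: str, config: SyntheticConfig) -> str:
    if config.effort_scaling == "per_band":
        return config.band_effort_scaling[band]
    return config.effort_scaling


def _envelope_fn(band: str, sre: int, config: SyntheticConfig) -> Callable:
    """Vectorised fractional-power envelope as a function of time re cue.

    Smooth rise starting ``band_latency`` after the cue with the band's time
    constant, settling at ``depth * effort_scale`` (the plateau); an optional
    onset overshoot decays back to the plateau.  Zero before the latency,
    exponential return to zero after the grip ends.
    """
    depth = config.depths[band]
    amp = depth * _effort_scale(sre, _band_effort_kind(band, config))
    lat = config.band_latency[band]
    tau = config.envelope_rise_tau * config.band_tau_scale[band]
    over = config.band_overshoot.get(band, 0.0)
    tau_o = config.overshoot_tau
    dur = config.cue_duration

    def shape(dt):
        rise = 1.0 - np.exp(-dt / tau)
        return rise * (1.0 + over * np.exp(-dt / tau_o))

    end_val = amp * shape(np.asarray(dur - lat))

    def env(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        rising = (t >= lat) & (t < dur)
        out[rising] = amp * shape(t[rising] - lat)
        fall = t >= dur
        out[fall] = end_val * np.exp(-(t[fall] - dur) / tau)
        return out

    return env


def generate_band_envelopes(sre: int, config: SyntheticConfig) -> BandPowerTrace:
    """Ground-truth band envelopes for one trial over the decode window.

    Beta is non-positive and gamma non-negative during the grip, both zero
    through the pre-cue baseline second; plateau magnitudes scale with SRE
    (linearly by default).
    """
    if not 0 <= sre <= 10:
        raise InputError(f"sre={sre} outside [0, 10]")
    t = feature_times(DECODE_WINDOW, config.feature_rate)
    return BandPowerTrace(
        times=t, **{b: _envelope_fn(b, sre, config)(t) for b in BANDS}
    )


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise via spectral shaping, unit variance, flat below 1 Hz bin."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)  # bin index scale; only the shape matters
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _band_carrier(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance band-limited stochastic carrier with a stabilised envelope.

    Band-pass filtered white noise whose instantaneous amplitude is
    compressed towards a constant (random phase is kept).  A raw Gaussian
    carrier's chi-squared power fluctuations would swamp the imposed
    power modulation in single sessions; stabilising the amplitude keeps the
    wavelet-extracted envelope close to the generating one while still
    spreading energy across the whole band.
    """
    lo, hi = band
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    for _ in range(2):
        env = np.abs(hilbert(x))
        env = np.maximum(env, 1e-3 * env.mean())
        x = sosfiltfilt(sos, x / env)
    return x / x.std()


def _session_envelopes(
    cue_times: np.ndarray,
    sre: np.ndarray,
    config: SyntheticConfig,
    n_samples: int,
) -> dict[str, np.ndarray]:
    """Full-timeline power envelopes per band at the raw sampling rate."""
    t = np.arange(n_samples) / config.fs
    out = {b: np.zeros(n_samples) for b in BANDS}
    for cue, s in zip(cue_times, sre):
        seg = (t >= cue) & (t < cue + config.cue_duration + 5.0)
        for b in BANDS:
            out[b][seg] += _envelope_fn(b, int(s), config)(t[seg] - cue)
    return out


def synthesize_lfp(
    envelopes: dict[str, np.ndarray],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Four monopolar contact signals whose band power tracks the envelopes.

    Each contact is the gain-weighted sum over bands of a shared band-limited
    noise carrier scaled by ``sqrt(1 + envelope)``, plus independent pink
    noise and a common-mode artifact identical on all contacts (which the
    bipolar derivation removes exactly).
    """
    n = len(next(iter(envelopes.values())))
    fs = config.fs
    contacts = np.zeros((4, n))
    for b in BANDS:
        env = np.clip(envelopes[b], -0.999, None)
        carrier = config.carrier_amp * _band_carrier(n, fs, BANDS[b], rng)
        modulated = carrier * np.sqrt(1.0 + env)
        gains = np.asarray(CONTACT_GAINS[b])
        contacts += gains[:, None] * modulated[None, :]
        background = config.carrier_amp * _band_carrier(n, fs, BANDS[b], rng)
        bg_gains = np.asarray(BACKGROUND_GAINS[b])
        contacts += bg_gains[:, None] * background[None, :]
    for i in range(4):
        contacts[i] += config.pink_noise_amp * _pink_noise(
            n, config.pink_noise_exponent, rng
        )
    if config.common_mode_amp:
        t = np.arange(n) / fs
        mains = np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        drift = _pink_noise(n, 2.0, rng)
        contacts += config.common_mode_amp * (mains + drift)[None, :]
    return contacts


def generate_force(
    envelopes: BandPowerTrace | dict[str, np.ndarray],
    true_model_id: int,
    true_params: Sequence[float],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    fs: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless and observed force for given envelopes.

    The noiseless trace is the forward simulation of the generating model;
    the observed trace adds Gaussian measurement noise with s.d.
    ``noise_sd`` (as a fraction of the maximal noiseless force) and is
    clamped at zero, as a dynamometer cannot read negative grip force.
    """
    fs = config.feature_rate if fs is None else fs
    spec = get_model(true_model_id)
    clean = simulate_forward(spec, true_params, envelopes, fs, clamp=True)
    observed = clean
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        scale = config.noise_sd * max(float(np.max(clean)), 1e-12)
        observed = clean + rng.normal(0.0, scale, size=clean.shape)
    return clean, np.maximum(observed, 0.0)


def _draw_sre(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Stratified effort levels: 2-3 maximal, 2-3 minimal, the rest spread.

    Guarantees at least one SRE=10 trial (needed for force normalisation)
    and non-empty low (<=5) and high (>5) effort halves.
    """
    if config.sre_levels is not None:
        return np.asarray(config.sre_levels, dtype=int)
    n = config.n_trials
    levels = [10] * min(3, max(1, n // 10 + 1)) + [0] * min(3, max(1, n // 10 + 1))
    levels = levels[: max(2, n)]
    rest = n - len(levels)
    if rest > 0:
        levels += list(rng.integers(1, 10, size=rest))
    arr = np.array(levels[:n])
    rng.shuffle(arr)
    return arr


def generate_session(config: SyntheticConfig) -> SyntheticSession:
    """Build one complete synthetic session, deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    sre = _draw_sre(config, rng)
    spacing = rng.uniform(*config.trial_spacing, size=config.n_trials - 1)
    cue_times = config.lead_in + np.concatenate([[0.0], np.cumsum(spacing)])
    duration = cue_times[-1] + config.cue_duration + config.lead_in
    n_samples = int(round(duration * config.fs))

    raw_env = _session_envelopes(cue_times, sre, config, n_samples)
    monopolar = synthesize_lfp(raw_env, config, rng)

    true_params = config.resolved_params()
    force_clean, force_raw = generate_force(
        raw_env, config.true_model_id, true_params, config, rng=rng, fs=config.fs
    )

    true_envelopes, true_rows, obs_rows = [], [], []
    for s in sre:
        env = generate_band_envelopes(int(s), config)
        clean, observed = generate_force(
            env, config.true_model_id, true_params, config, rng=rng
        )
        true_envelopes.append(env)
        true_rows.append(clean)
        obs_rows.append(observed)

    recording = ContinuousRecording(
        monopolar=monopolar,
        force=force_raw,
        fs=config.fs,
        cue_times=cue_times,
        sre=sre,
        meta={"source": "synthetic", "true_model_id": config.true_model_id},
    )
    return SyntheticSession(
        recording=recording,
        true_envelopes=true_envelopes,
        true_force=np.vstack(true_rows),
        observed_force=np.vstack(obs_rows),
        true_params=true_params,
        true_model_id=config.true_model_id,
        config=config,
    )
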
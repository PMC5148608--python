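"""Band-power feature extraction from multichannel recordings.

Turns raw 4-contact recordings into per-trial band-power traces and
modulation statistics: bipolar derivation, Morlet continuous wavelet
transform (7 cycles), baseline normalisation against the pre-cue second,
channel selection by deepest beta suppression, the percentile-based
modulation-significance rule, epoching into the decode window, force
normalisation and force yank.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from gripdecode.exceptions import DegenerateDataError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ContinuousRecording",
    "TimeFrequencyMap",
    "BandPowerTrace",
    "BandModulation",
    "ModulationReport",
    "Trial",
    "BANDS",
    "DECODE_WINDOW",
    "BIPOLAR_PAIRS",
    "derive_bipolar",
    "morlet_cwt",
    "relative_power_change",
    "band_rows",
    "band_trace",
    "bin_average",
    "epoch_trials",
    "select_channel",
    "pick_deepest",
    "assess_modulation",
    "modulation_report",
    "detect_onset",
    "normalize_force",
    "force_yank",
]

#: Inclusive band limits in Hz: theta/alpha, beta, gamma.
BANDS: dict[str, tuple[float, float]] = {
    "alpha": (4.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (55.0, 90.0),
}

#: Decode window in seconds relative to cue onset.
DECODE_WINDOW: tuple[float, float] = (-1.0, 2.8)

#: Bipolar pair labels in row order of :func:`derive_bipolar`.
BIPOLAR_PAIRS = ("01", "12", "23")

DEFAULT_FREQS = np.arange(1.0, 91.0)  # 1-90 Hz, 1 Hz steps
DEFAULT_FEATURE_RATE = 100.0
ONSET_FALLBACK_S = 0.3  # cue->movement fallback when force onset is undefined


@dataclass
class ContinuousRecording:
    """Raw multichannel session: 4 monopolar contacts + force + cue events."""

    monopolar: np.ndarray  # (4, n_samples), contacts 0-3 caudal->cranial
    force: np.ndarray  # (n_samples,), arbitrary units
    fs: float
    cue_times: np.ndarray  # seconds, strictly increasing
    sre: np.ndarray  # per-trial self-rated effort, 0-10
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.monopolar = np.asarray(self.monopolar, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.cue_times = np.asarray(self.cue_times, dtype=float)
        self.sre = np.asarray(self.sre, dtype=int)

    @property
    def n_samples(self) -> int:
        return self.monopolar.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if well-formed)."""
        v = []
        if self.monopolar.ndim != 2 or self.monopolar.shape[0] != 4:
            v.append(
                f"expected 4 monopolar contacts, got shape {self.monopolar.shape}"
            )
        if self.force.ndim != 1 or (
            self.monopolar.ndim == 2 and self.force.size != self.monopolar.shape[1]
        ):
            v.append("force channel length does not match LFP channels")
        if self.fs <= 180.0:
            v.append(f"sampling rate {self.fs} Hz too low (need > 180 Hz)")
        if len(self.cue_times) != len(self.sre):
            v.append("cue_times and sre lengths differ")
        if len(self.cue_times) and np.any(np.diff(self.cue_times) <= 0):
            v.append("cue_times not strictly increasing")
        if np.any((self.sre < 0) | (self.sre > 10)):
            v.append("sre values outside 0-10")
        if len(self.cue_times) and (
            self.cue_times[-1] + DECODE_WINDOW[1] > self.duration
        ):
            v.append("last cue's decode window extends past end of recording")
        return v


@dataclass
class TimeFrequencyMap:
    """Wavelet power map |W|^2 on a frequency x time grid."""

    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray  # (n_freqs, n_times), >= 0
    edge_mask: np.ndarray | None = None  # True where within 2 temporal sd of an edge


@dataclass
class BandPowerTrace:
    """Per-trial fractional power change per band over the decode window.

    0 means power equal to the pre-cue baseline, +1 a doubling.  Values are
    fractions internally; conversion to percent happens only for display.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    times: np.ndarray | None = None  # seconds relative to cue

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"alpha": self.alpha, "beta": self.beta, "gamma": self.gamma}


@dataclass
class BandModulation:
    """Significance-rule outcome for one band."""

    mean_change: float  # fractional change averaged over 1 s post movement onset
    significant: bool
    direction: str  # "ERD", "ERS" or "none"


@dataclass
class ModulationReport:
    bands: dict[str, BandModulation]
    pair_beta_reduction: dict[str, float] | None = None  # per bipolar pair


@dataclass
class Trial:
    """One epoched trial: band traces + normalised force over the window."""

    band_trace: BandPowerTrace
    force: np.ndarray
    sre: int
    cue_time: float
    onset_time: float | None = None  # seconds re cue; None if undetectable


# ---------------------------------------------------------------------------
# signal-level operations


def derive_bipolar(monopolar: np.ndarray) -> np.ndarray:
    """Bipolar pairs 01, 12, 23: row k = contact k - contact k+1.

    Any additive signal common to all contacts cancels exactly.
    """
    monopolar = np.asarray(monopolar, dtype=float)
    if monopolar.ndim != 2 or monopolar.shape[0] != 4:
        raise InputError(f"expected a 4 x n matrix, got shape {monopolar.shape}")
    return monopolar[:-1] - monopolar[1:]


def _morlet_bank(freqs: np.ndarray, fs: float, n_cycles: int) -> np.ndarray:
    """Complex Morlet wavelets, one per frequency, centred in equal-length rows.

    Temporal s.d. at frequency f is n_cycles / (2 pi f); rows span +/- 4 s.d.
    of the lowest frequency and are L1-normalised so a stationary sinusoid
    yields constant power.
    """
    sigmas = n_cycles / (2.0 * np.pi * freqs)
    half = int(np.ceil(4.0 * sigmas.max() * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-(t[None, :] ** 2) / (2.0 * sigmas[:, None] ** 2))
    carrier = np.exp(2j * np.pi * freqs[:, None] * t[None, :])
    bank = envelope * carrier
    bank /= np.sum(np.abs(bank), axis=1, keepdims=True)
    return bank


def morlet_cwt(
    signal: np.ndarray,
    fs: float,
    freqs: np.ndarray = DEFAULT_FREQS,
    n_cycles: int = 7,
    t0: float = 0.0,
) -> TimeFrequencyMap:
    """Morlet continuous wavelet transform power of a 1-D signal.

    Power is the squared magnitude of the complex transform.  Samples lying
    within 2 temporal s.d. of either edge are flagged in ``edge_mask``.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise InputError("morlet_cwt expects a 1-D signal")
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= fs / 2):
        raise InputError(
            f"frequencies up to {freqs.max()} Hz exceed Nyquist ({fs / 2} Hz)"
        )
    bank = _morlet_bank(freqs, fs, n_cycles)
    n = signal.size
    L = bank.shape[1]
    nfft = int(2 ** np.ceil(np.log2(n + L - 1)))
    X = np.fft.fft(signal, nfft)
    W = np.fft.fft(bank, nfft, axis=-1)
    full = np.fft.ifft(X[None, :] * W, axis=-1)[:, : n + L - 1]
    start = (L - 1) // 2  # centre of the 'full' convolution
    w = full[:, start : start + n]
    power = np.abs(w) ** 2
    times = t0 + np.arange(n) / fs
    sigmas = n_cycles / (2.0 * np.pi * freqs)
    edge = (2.0 * sigmas[:, None] * fs).astype(int)
    idx = np.arange(n)[None, :]
    edge_mask = (idx < edge) | (idx >= n - edge)
    return TimeFrequencyMap(freqs=freqs, times=times, power=power, edge_mask=edge_mask)


def relative_power_change(
    tf: TimeFrequencyMap, baseline: tuple[float, float]
) -> np.ndarray:
    """Fractional power change vs the mean power in the baseline window.

    ``value = P(f, t) / mean_baseline P(f) - 1``; 0 means power equal to
    baseline, positive is ERS, negative is ERD.
    """
    t0, t1 = baseline
    sel = (tf.times >= t0) & (tf.times < t1)
    if not np.any(sel):
        raise InputError(f"baseline window {baseline} outside the map")
    base = tf.power[:, sel].mean(axis=1)
    if np.any(base <= 0):
        raise DegenerateDataError("zero baseline power at some frequency")
    return tf.power / base[:, None] - 1.0


def band_rows(freqs: np.ndarray, band: str | tuple[float, float]) -> np.ndarray:
    """Boolean mask of grid rows within a band's inclusive limits."""
    lo, hi = BANDS[band] if isinstance(band, str) else band
    return (freqs >= lo) & (freqs <= hi)


def band_trace(rel_map: np.ndarray, freqs: np.ndarray, band) -> np.ndarray:
    """Simple mean over the band's frequency rows of a fractional-change map."""
    mask = band_rows(freqs, band)
    if not np.any(mask):
        raise InputError(f"no grid rows inside band {band!r}")
    return rel_map[mask].mean(axis=0)


def bin_average(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Decimate by averaging over consecutive time bins of width 1/fs_out.

    Bin ``k`` averages the raw samples whose index falls in
    ``[k*fs_in/fs_out, (k+1)*fs_in/fs_out)``; the last partial bin is dropped.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    n_bins = int(np.floor(n * fs_out / fs_in))
    edges = np.floor(np.arange(n_bins + 1) * fs_in / fs_out).astype(int)
    sums = np.add.reduceat(x[..., : edges[-1]], edges[:-1], axis=-1)
    counts = np.diff(edges)
    return sums / counts


def feature_times(
    window: tuple[float, float] = DECODE_WINDOW, rate: float = DEFAULT_FEATURE_RATE
) -> np.ndarray:
    """Bin-centre time stamps of the decimated feature grid, re cue."""
    n = int(round((window[1] - window[0]) * rate))
    return window[0] + (np.arange(n) + 0.5) / rate


# ---------------------------------------------------------------------------
# trial-level operations


def detect_onset(
    force: np.ndarray,
    times: np.ndarray,
    sustain_s: float = 0.1,
) -> float | None:
    """Force onset: first post-cue threshold crossing sustained >= 100 ms.

    Threshold is baseline mean + max(5% of trial peak, 3 x baseline s.d.),
    with the baseline taken from the pre-cue samples (times < 0).  Returns
    the onset time in seconds relative to cue, or None if never exceeded.
    """
    force = np.asarray(force, dtype=float)
    times = np.asarray(times, dtype=float)
    pre = times < 0.0
    if not np.any(pre) or not np.any(~pre):
        raise InputError("need samples on both sides of the cue")
    base_mean = force[pre].mean()
    base_sd = force[pre].std()
    thr = base_mean + max(0.05 * force.max(), 3.0 * base_sd)
    dt = float(np.median(np.diff(times)))
    need = max(1, int(round(sustain_s / dt)))
    above = (force > thr) & (times >= 0.0)
    # first run of `need` consecutive supra-threshold samples
    run = 0
    for i, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run >= need:
            return float(times[i - need + 1])
    return None


def epoch_trials(
    recording: ContinuousRecording,
    pair: int,
    window: tuple[float, float] = DECODE_WINDOW,
    feature_rate: float = DEFAULT_FEATURE_RATE,
    freqs: np.ndarray = DEFAULT_FREQS,
    n_cycles: int = 7,
    pad_s: float = 2.0,
    baseline: str = "pooled",
) -> list[Trial]:
    """Cut the session into per-trial band-power traces + force.

    For each cue the bipolar signal is epoched with ``pad_s`` of context on
    both sides, wavelet-transformed, normalised against the pre-cue second,
    averaged into band traces, cropped to the decode window and decimated to
    the feature rate by bin averaging.  Trials whose decode window leaves
    the recording are dropped with a warning.

    ``baseline="pooled"`` normalises every trial against the session-mean
    pre-cue power per frequency; with roughly six independent power samples
    per pre-cue second at beta frequencies (7-cycle wavelets), a per-trial
    baseline ratio carries a large inverse-moment bias, which pooling
    removes.  ``baseline="per_trial"`` uses each trial's own pre-cue second.
    """
    if baseline not in ("pooled", "per_trial"):
        raise InputError(f"unknown baseline mode {baseline!r}")
    bipolar = derive_bipolar(recording.monopolar)[pair]
    fs = recording.fs
    n_feat = int(round((window[1] - window[0]) * feature_rate))
    seg_len = int(round((window[1] - window[0]) * fs))
    times = feature_times(window, feature_rate)

    kept: list[tuple[float, int, np.ndarray, np.ndarray, np.ndarray]] = []
    for cue, sre in zip(recording.cue_times, recording.sre):
        i0 = int(round((cue + window[0]) * fs))
        i1 = i0 + seg_len
        if i0 < 0 or i1 > recording.n_samples:
            warnings.warn(
                f"trial at cue {cue:.2f}s dropped: decode window outside recording"
            )
            continue
        p0 = max(0, i0 - int(round(pad_s * fs)))
        p1 = min(recording.n_samples, i1 + int(round(pad_s * fs)))
        seg_t0 = p0 / fs - cue
        tf = morlet_cwt(bipolar[p0:p1], fs, freqs=freqs, n_cycles=n_cycles, t0=seg_t0)
        bsl = (tf.times >= -1.0) & (tf.times < 0.0)
        base = tf.power[:, bsl].mean(axis=1)
        crop = slice(i0 - p0, i1 - p0)
        kept.append((float(cue), int(sre), tf.power[:, crop], base,
                     recording.force[i0:i1]))
    if not kept:
        return []

    pooled = np.mean([base for *_, base, _ in kept], axis=0)
    if np.any(pooled <= 0):
        raise DegenerateDataError("zero pooled baseline power at some frequency")

    trials: list[Trial] = []
    for cue, sre, power, base, force_raw in kept:
        ref = pooled if baseline == "pooled" else base
        if np.any(ref <= 0):
            raise DegenerateDataError("zero baseline power at some frequency")
        rel = power / ref[:, None] - 1.0
        traces = {
            b: bin_average(band_trace(rel, freqs, b), fs, feature_rate)[:n_feat]
            for b in BANDS
        }
        force_ds = bin_average(force_raw, fs, feature_rate)[:n_feat]
        onset = detect_onset(force_ds, times)
        trials.append(
            Trial(
                band_trace=BandPowerTrace(times=times, **traces),
                force=force_ds,
                sre=sre,
                cue_time=cue,
                onset_time=onset,
            )
        )
    return trials


def _max_effort_indices(sre: np.ndarray, n: int = 3) -> np.ndarray:
    """Indices of (up to) the n trials with the highest effort rating."""
    sre = np.asarray(sre)
    if sre.size == 0:
        raise InputError("no trials available")
    top = sre.max()
    idx = np.flatnonzero(sre == top)
    return idx[:n]


def select_channel(
    recording: ContinuousRecording,
    window_after_onset: float = 1.0,
    **epoch_kw,
) -> tuple[int, dict[str, float]]:
    """Pick the bipolar pair with the deepest movement-related beta suppression.

    Beta change is averaged over the second after movement onset across the
    (up to three) maximal-effort trials, per pair; the most negative mean
    wins, ties going to the lowest pair index.  Returns the pair index and
    the per-pair mean beta change.
    """
    idx = _max_effort_indices(recording.sre)
    if idx.size == 0:
        raise InputError("no maximal-effort trials to select a channel on")
    reductions = {}
    means = []
    for pair in range(len(BIPOLAR_PAIRS)):
        trials = epoch_trials(recording, pair, **epoch_kw)
        sel = [trials[i] for i in idx if i < len(trials)]
        vals = []
        for tr in sel:
            onset = tr.onset_time if tr.onset_time is not None else ONSET_FALLBACK_S
            t = tr.band_trace.times
            m = (t >= onset) & (t < onset + window_after_onset)
            vals.append(tr.band_trace.beta[m].mean())
        mean_beta = float(np.mean(vals))
        reductions[BIPOLAR_PAIRS[pair]] = mean_beta
        means.append(mean_beta)
    return pick_deepest(means), reductions


def pick_deepest(beta_changes: Sequence[float]) -> int:
    """Index of the most negative beta change; ties go to the lowest index."""
    if len(beta_changes) == 0:
        raise InputError("no pairs to choose from")
    return int(np.argmin(beta_changes))


def assess_modulation(
    baseline_power: np.ndarray,
    post_onset_power: np.ndarray,
    lo_pct: float = 5.0,
    hi_pct: float = 95.0,
) -> BandModulation:
    """Percentile significance rule for movement-related modulation.

    Boundaries are the 5th/95th percentiles of the trial-averaged band power
    during the pre-movement second.  The modulation is a significant ERD
    (ERS) when at least 50% of the trial-averaged power samples during the
    second after movement onset fall below (above) the lower (upper)
    boundary; the comparison of the 50% fraction is inclusive.
    """
    baseline_power = np.asarray(baseline_power, dtype=float)
    post = np.asarray(post_onset_power, dtype=float)
    if baseline_power.size == 0 or post.size == 0:
        raise InputError("empty baseline or post-onset samples")
    lo = np.percentile(baseline_power, lo_pct)
    hi = np.percentile(baseline_power, hi_pct)
    frac_below = np.mean(post < lo)
    frac_above = np.mean(post > hi)
    erd = frac_below >= 0.5
    ers = frac_above >= 0.5
    base_mean = baseline_power.mean()
    if base_mean <= 0:
        raise DegenerateDataError("non-positive mean baseline power")
    mean_change = float(post.mean() / base_mean - 1.0)
    if erd and not ers:
        direction = "ERD"
    elif ers and not erd:
        direction = "ERS"
    elif erd and ers:  # cannot happen with sensible data; be explicit
        direction = "ERD" if frac_below >= frac_above else "ERS"
    else:
        direction = "none"
    return BandModulation(
        mean_change=mean_change, significant=bool(erd or ers), direction=direction
    )


def modulation_report(
    recording: ContinuousRecording,
    pair: int | None = None,
    freqs: np.ndarray = DEFAULT_FREQS,
    n_cycles: int = 7,
) -> ModulationReport:
    """Movement-related modulation summary for one bipolar pair.

    Power is averaged over the maximal-effort trials; per band, the pre-cue
    second provides the percentile boundaries and the second after movement
    onset is tested with :func:`assess_modulation`.  When ``pair`` is None
    the beta-selection rule picks it (and the per-pair beta reductions are
    included in the report).
    """
    reductions = None
    if pair is None:
        pair, reductions = select_channel(recording, freqs=freqs, n_cycles=n_cycles)
    bipolar = derive_bipolar(recording.monopolar)[pair]
    fs = recording.fs
    idx = _max_effort_indices(recording.sre)
    seg_len = int(round(3.8 * fs))
    pad = int(round(2.0 * fs))
    t = np.arange(seg_len) / fs - 1.0
    power_sum = np.zeros((len(freqs), seg_len))
    onsets = []
    for i in idx:
        cue = recording.cue_times[i]
        i0 = int(round((cue - 1.0) * fs))
        i1 = i0 + seg_len
        p0 = max(0, i0 - pad)
        p1 = min(recording.n_samples, i1 + pad)
        tf = morlet_cwt(bipolar[p0:p1], fs, freqs=freqs, n_cycles=n_cycles)
        power_sum += tf.power[:, i0 - p0 : i1 - p0]
        onset = detect_onset(recording.force[i0:i1], t)
        if onset is not None:
            onsets.append(onset)
    power = power_sum / len(idx)
    onset = float(np.mean(onsets)) if onsets else ONSET_FALLBACK_S
    if not onsets:
        warnings.warn("force onset undefined for all maximal-effort trials; "
                      f"falling back to cue + {ONSET_FALLBACK_S} s")
    bands = {}
    for b in BANDS:
        trace = power[band_rows(freqs, b)].mean(axis=0)
        baseline = trace[(t >= -1.0) & (t < 0.0)]
        post = trace[(t >= onset) & (t < onset + 1.0)]
        bands[b] = assess_modulation(baseline, post)
    return ModulationReport(bands=bands, pair_beta_reduction=reductions)


def normalize_force(trials: Sequence[Trial]) -> list[Trial]:
    """Scale force to fractions of the mean maximal-effort peak force.

    The divisor is the mean over maximal-effort trials (SRE = 10, else the
    three largest-peak trials as a logged stand-in) of the per-trial peak.
    After normalisation the maximal-effort peaks average exactly 1.
    """
    if not trials:
        raise InputError("no trials to normalise")
    peaks = np.array([t.force.max() for t in trials])
    sre = np.array([t.sre for t in trials])
    max_idx = np.flatnonzero(sre == 10)
    if max_idx.size == 0:
        logger.warning(
            "no SRE=10 trials; using the three largest-peak trials for normalisation"
        )
        max_idx = np.argsort(peaks)[-3:]
    divisor = peaks[max_idx].mean()
    if divisor <= 0:
        raise DegenerateDataError("cannot normalise: maximal-effort peak force is 0")
    out = []
    for t in trials:
        out.append(
            Trial(
                band_trace=t.band_trace,
                force=t.force / divisor,
                sre=t.sre,
                cue_time=t.cue_time,
                onset_time=t.onset_time,
            )
        )
    return out


def force_yank(
    force: np.ndarray,
    fs: float,
    times: np.ndarray | None = None,
    init_window: tuple[float, float] = (0.0, 1.0),
) -> tuple[np.ndarray, float]:
    """Force yank (dF/dt, central differences) and its peak during initialisation.

    The peak is taken over the first second after the cue when ``times``
    (re cue) are given, otherwise over the whole trace.
    """
    force = np.asarray(force, dtype=float)
    if force.size < 2:
        raise InputError("need at least 2 samples to differentiate")
    yank = np.gradient(force) * fs
    if times is not None:
        m = (np.asarray(times) >= init_window[0]) & (np.asarray(times) < init_window[1])
        peak = float(yank[m].max()) if np.any(m) else float(yank.max())
    else:
        peak = float(yank.max())
    return yank, peak
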
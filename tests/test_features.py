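import numpy as np
import pytest

from gripdecode import features as F
from gripdecode import synthetic as S
from gripdecode.exceptions import DegenerateDataError, InputError

from conftest import FAST_KW


# ---------------------------------------------------------------------------
# bipolar derivation


def test_bipolar_three_pairs():
    mono = np.arange(8.0).reshape(4, 2)
    bip = F.derive_bipolar(mono)
    assert bip.shape == (3, 2)
    assert F.BIPOLAR_PAIRS == ("01", "12", "23")


def test_bipolar_common_mode_cancels():
    mono = np.tile(np.random.default_rng(0).standard_normal(100), (4, 1))
    assert np.all(F.derive_bipolar(mono) == 0)


def test_bipolar_direct_subtraction():
    c = np.random.default_rng(1).standard_normal(50)
    a = 0.7
    mono = np.vstack([c, c + a, c, c])
    bip = F.derive_bipolar(mono)
    np.testing.assert_allclose(bip[0], -a)
    np.testing.assert_allclose(bip[1], +a)
    np.testing.assert_allclose(bip[2], 0.0, atol=1e-15)


def test_bipolar_wrong_rows():
    with pytest.raises(InputError):
        F.derive_bipolar(np.zeros((3, 10)))


# ---------------------------------------------------------------------------
# Morlet CWT


def test_cwt_peak_frequency():
    fs = 512.0
    t = np.arange(int(4 * fs)) / fs
    tf = F.morlet_cwt(np.sin(2 * np.pi * 20 * t), fs)
    assert tf.freqs[np.argmax(tf.power.mean(axis=1))] == 20.0


def test_cwt_power_is_quadratic():
    fs = 256.0
    rng = np.random.default_rng(2)
    x = rng.standard_normal(int(3 * fs))
    p1 = F.morlet_cwt(x, fs).power
    p2 = F.morlet_cwt(2 * x, fs).power
    np.testing.assert_allclose(p2, 4 * p1, rtol=1e-10)


def test_cwt_zero_signal():
    tf = F.morlet_cwt(np.zeros(512), 256.0)
    assert np.all(tf.power == 0)


def test_cwt_rejects_super_nyquist():
    with pytest.raises(InputError):
        F.morlet_cwt(np.zeros(512), 100.0, freqs=np.array([60.0]))


def test_cwt_edge_mask_flags_two_sd():
    fs = 256.0
    tf = F.morlet_cwt(np.zeros(int(4 * fs)), fs, freqs=np.array([10.0]))
    sigma = 7 / (2 * np.pi * 10.0)
    n_edge = int(2 * sigma * fs)
    assert tf.edge_mask[0, : n_edge].all()
    assert not tf.edge_mask[0, n_edge + 1 : -n_edge - 1].any()


# ---------------------------------------------------------------------------
# relative power change and band traces


def _flat_map(power_value=1.0, n=300, fs=100.0):
    freqs = np.arange(1.0, 91.0)
    power = np.full((len(freqs), n), power_value)
    times = np.arange(n) / fs - 1.0
    return F.TimeFrequencyMap(freqs=freqs, times=times, power=power)


def test_relative_change_doubling_is_plus_one():
    tf = _flat_map()
    tf.power[:, tf.times >= 0] = 2.0
    rel = F.relative_power_change(tf, baseline=(-1.0, 0.0))
    assert np.all(rel[:, tf.times >= 0] == 1.0)
    assert np.all(rel[:, tf.times < 0] == 0.0)


def test_relative_change_zero_baseline_errors():
    tf = _flat_map(0.0)
    with pytest.raises(DegenerateDataError):
        F.relative_power_change(tf, baseline=(-1.0, 0.0))


def test_relative_change_baseline_outside_map():
    tf = _flat_map()
    with pytest.raises(InputError):
        F.relative_power_change(tf, baseline=(-10.0, -9.0))


def test_band_rows_inclusive_limits():
    freqs = np.arange(1.0, 91.0)
    assert F.band_rows(freqs, "beta").sum() == 18  # 13..30 inclusive
    assert F.band_rows(freqs, "alpha").sum() == 9  # 4..12
    assert F.band_rows(freqs, "gamma").sum() == 36  # 55..90


def test_stationary_band_trace_near_zero():
    # a single 1-s baseline carries a large inverse-moment sampling bias at
    # low frequencies, so use a longer baseline window for this invariant
    fs = 256.0
    rng = np.random.default_rng(3)
    x = rng.standard_normal(int(10 * fs))
    tf = F.morlet_cwt(x, fs)
    rel = F.relative_power_change(tf, baseline=(2.0, 6.0))
    interior = (tf.times > 2.0) & (tf.times < 8.0)  # avoid wavelet edges
    for band in F.BANDS:
        tr = F.band_trace(rel, tf.freqs, band)
        assert abs(tr[interior].mean()) < 0.3


def test_epoch_pooled_baseline_stationary_near_zero():
    # end-to-end stationarity: zero modulation depths -> band traces ~ 0
    cfg = S.SyntheticConfig(
        n_trials=8, seed=7, sre_levels=[10] * 8, beta_mod_depth=0.0,
        gamma_mod_depth=0.0, alpha_mod_depth=0.0, **FAST_KW
    )
    trials = F.epoch_trials(S.generate_session(cfg).recording, pair=1)
    for band in F.BANDS:
        v = np.mean([getattr(t.band_trace, band).mean() for t in trials])
        assert abs(v) < 0.15


# ---------------------------------------------------------------------------
# bin averaging / feature grid


def test_bin_average_exact_mean():
    x = np.arange(10.0)
    out = F.bin_average(x, fs_in=10.0, fs_out=5.0)
    np.testing.assert_allclose(out, [0.5, 2.5, 4.5, 6.5, 8.5])


def test_feature_grid_length():
    assert len(F.feature_times()) == 380  # 3.8 s at 100 Hz


def test_bin_average_non_integer_ratio():
    x = np.ones(1946)
    out = F.bin_average(x, 512.0, 100.0)
    assert len(out) == 380
    np.testing.assert_allclose(out, 1.0)


# ---------------------------------------------------------------------------
# onset detection


def test_onset_flat_force_undefined():
    times = F.feature_times()
    assert F.detect_onset(np.zeros_like(times), times) is None


def test_onset_ideal_step():
    times = F.feature_times()
    force = np.where(times >= 0.35, 1.0, 0.0)
    onset = F.detect_onset(force, times)
    assert onset == pytest.approx(0.35, abs=0.011)


def test_onset_noisy_ramp_near_analytic_crossing():
    rng = np.random.default_rng(4)
    times = F.feature_times()
    ramp = np.clip((times - 0.3) / 0.5, 0, None)
    force = np.clip(ramp + 0.01 * rng.standard_normal(len(times)), 0, None)
    peak = force.max()
    base = force[times < 0]
    thr = base.mean() + max(0.05 * peak, 3 * base.std())
    analytic = 0.3 + 0.5 * thr  # ramp slope is 2 per second
    onset = F.detect_onset(force, times)
    assert onset is not None
    assert abs(onset - analytic) <= 0.02


# ---------------------------------------------------------------------------
# epoching


@pytest.fixture(scope="module")
def small_session():
    return S.generate_session(
        S.SyntheticConfig(n_trials=6, seed=11, noise_sd=0.02, **FAST_KW)
    )


def test_epoch_counts_and_length(small_session):
    trials = F.epoch_trials(small_session.recording, pair=1)
    assert len(trials) == 6
    for tr in trials:
        assert len(tr.force) == 380
        assert len(tr.band_trace.beta) == 380


def test_epoch_preserves_sre_pairing(small_session):
    trials = F.epoch_trials(small_session.recording, pair=1)
    np.testing.assert_array_equal(
        [t.sre for t in trials], small_session.recording.sre
    )


def test_epoch_drops_edge_trial(small_session):
    rec = small_session.recording
    early = F.ContinuousRecording(
        monopolar=rec.monopolar,
        force=rec.force,
        fs=rec.fs,
        cue_times=np.concatenate([[0.5], rec.cue_times]),
        sre=np.concatenate([[5], rec.sre]),
    )
    with pytest.warns(UserWarning, match="dropped"):
        trials = F.epoch_trials(early, pair=1)
    assert len(trials) == 6


def test_feature_pipeline_amplitude_invariance(small_session):
    rec = small_session.recording
    scaled = F.ContinuousRecording(
        monopolar=3.7 * rec.monopolar,
        force=rec.force,
        fs=rec.fs,
        cue_times=rec.cue_times,
        sre=rec.sre,
    )
    t1 = F.epoch_trials(rec, pair=1)
    t2 = F.epoch_trials(scaled, pair=1)
    for a, b in zip(t1, t2):
        np.testing.assert_allclose(a.band_trace.beta, b.band_trace.beta, atol=1e-10)
        np.testing.assert_allclose(a.band_trace.gamma, b.band_trace.gamma, atol=1e-10)


# ---------------------------------------------------------------------------
# channel selection


def test_pick_deepest_argmin():
    assert F.pick_deepest([-0.05, -0.20, -0.01]) == 1  # pair 12


def test_pick_deepest_tie_rule():
    assert F.pick_deepest([-0.2, -0.2, 0.0]) == 0  # tie -> pair 01


def test_select_channel_construction(small_session):
    idx, reductions = F.select_channel(small_session.recording)
    assert idx == 1  # pair 12 most beta-reactive by construction
    assert set(reductions) == {"01", "12", "23"}


def test_select_channel_needs_trials():
    with pytest.raises(InputError):
        F._max_effort_indices(np.array([]))


# ---------------------------------------------------------------------------
# modulation significance


def test_assess_modulation_inclusive_fifty_percent():
    baseline = np.arange(100.0)  # 5th pct = 4.95, 95th = 94.05
    lo = np.percentile(baseline, 5)
    post = np.concatenate([np.full(50, lo - 1.0), np.full(50, 50.0)])
    mod = F.assess_modulation(baseline, post)
    assert mod.significant and mod.direction == "ERD"
    post49 = np.concatenate([np.full(49, lo - 1.0), np.full(51, 50.0)])
    assert not F.assess_modulation(baseline, post49).significant


def test_assess_modulation_sustained_ers():
    rng = np.random.default_rng(5)
    baseline = 1.0 + 0.05 * rng.standard_normal(100)
    post = 1.5 * (1.0 + 0.05 * rng.standard_normal(100))
    mod = F.assess_modulation(baseline, post)
    assert mod.significant and mod.direction == "ERS"
    assert mod.mean_change == pytest.approx(0.5, abs=0.05)


def test_modulation_report_on_synthetic():
    # three maximal-effort trials, as in the paradigm; construction oracle
    cfg = S.SyntheticConfig(
        n_trials=6, seed=0, noise_sd=0.02, sre_levels=[10, 10, 2, 10, 5, 8],
        **FAST_KW
    )
    report = F.modulation_report(S.generate_session(cfg).recording)
    assert report.bands["beta"].direction == "ERD"
    assert report.bands["gamma"].direction == "ERS"
    assert report.bands["beta"].significant
    assert report.bands["gamma"].significant
    assert report.pair_beta_reduction is not None


# ---------------------------------------------------------------------------
# force normalisation and yank


def _mk_trial(force, sre, times=None):
    times = F.feature_times() if times is None else times
    z = np.zeros_like(times)
    return F.Trial(
        band_trace=F.BandPowerTrace(alpha=z, beta=z, gamma=z, times=times),
        force=np.asarray(force, dtype=float),
        sre=sre,
        cue_time=0.0,
    )


def test_normalize_force_divisor_is_mean_max_peak():
    times = F.feature_times()
    shape = np.clip(times, 0, None) / times.max()
    trials = [
        _mk_trial(10 * shape, 10),
        _mk_trial(12 * shape, 10),
        _mk_trial(8 * shape, 10),
        _mk_trial(5 * shape, 4),
    ]
    out = F.normalize_force(trials)
    peaks = [t.force.max() for t in out]
    assert np.mean(peaks[:3]) == pytest.approx(1.0)
    assert peaks[3] == pytest.approx(0.5)


def test_normalize_force_without_max_effort_logs(caplog):
    times = F.feature_times()
    shape = np.clip(times, 0, None) / times.max()
    trials = [_mk_trial((i + 1) * shape, 5) for i in range(4)]
    import logging

    with caplog.at_level(logging.WARNING, logger="gripdecode.features"):
        out = F.normalize_force(trials)
    assert "largest-peak" in caplog.text
    assert np.mean([t.force.max() for t in out[1:]]) == pytest.approx(1.0)


def test_normalize_force_all_zero_errors():
    trials = [_mk_trial(np.zeros(380), 10) for _ in range(3)]
    with pytest.raises(DegenerateDataError):
        F.normalize_force(trials)


def test_yank_constant_and_ramp():
    fs = 100.0
    yank, _ = F.force_yank(np.full(100, 0.7), fs)
    np.testing.assert_allclose(yank, 0.0)
    m = 2.5
    yank, _ = F.force_yank(m * np.arange(100) / fs, fs)
    np.testing.assert_allclose(yank, m, rtol=1e-9)


def test_yank_peak_of_first_order_step():
    # first-order step response: max derivative Kp/Tp right after onset
    fs, kp, tp = 100.0, 2.0, 0.2
    times = F.feature_times()
    resp = np.where(times >= 0, kp * (1 - np.exp(-np.clip(times, 0, None) / tp)), 0)
    _, peak = F.force_yank(resp, fs, times)
    assert peak == pytest.approx(kp / tp, rel=0.1)
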
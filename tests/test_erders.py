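"""Band power, windowed medians, the ERD/ERS formula, ROI aggregation."""

import numpy as np
import pytest

from arithmeeg.erders import (
    BANDS,
    DEFAULT_ROI_MAP,
    BandDefinition,
    TrialPower,
    WindowSpec,
    bandpass_power,
    condition_erders,
    roi_aggregate,
    trial_band_power,
)

FS = 512.0


def _tp(b, a, usable=True, trial=0):
    return TrialPower(trial, "C3", "theta", b, a, 1.0, 1.0, usable)


class TestBandpassPower:
    def test_sinusoid_power_matches_analytic_value(self):
        t = np.arange(int(30 * FS)) / FS
        a = 7.0
        x = a * np.sin(2 * np.pi * 4.5 * t)
        p = bandpass_power(x, BANDS["theta"], FS)
        central = p[int(5 * FS) : int(25 * FS)]
        assert central.mean() == pytest.approx(a**2 / 2, rel=0.02)

    def test_stopband_attenuation(self):
        t = np.arange(int(30 * FS)) / FS
        a = 7.0
        x = a * np.sin(2 * np.pi * 20.0 * t)
        p = bandpass_power(x, BANDS["theta"], FS)
        central = p[int(5 * FS) : int(25 * FS)]
        assert central.mean() < 0.01 * a**2 / 2

    def test_zero_signal_gives_zero_power(self):
        p = bandpass_power(np.zeros(int(10 * FS)), BANDS["theta"], FS)
        assert np.allclose(p, 0.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_power(np.zeros(1024), BandDefinition("hf", 100.0, 300.0), FS)

    def test_band_edges_validated(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 6.0, 3.0)


class TestTrialBandPower:
    def test_constant_power(self):
        p = np.full(int(20 * FS), 3.5)
        tp = trial_band_power(p, onset=10.0, rt=2.0, sfreq=FS)
        assert tp.baseline == pytest.approx(3.5)
        assert tp.activity == pytest.approx(3.5)
        assert tp.usable

    def test_step_function(self):
        n = int(20 * FS)
        p = np.ones(n)
        p[int(10 * FS) :] = 2.0  # onset sample belongs to activity
        tp = trial_band_power(p, onset=10.0, rt=2.0, sfreq=FS)
        assert (tp.baseline, tp.activity) == (1.0, 2.0)

    def test_majority_masked_baseline_is_unusable(self):
        n = int(20 * FS)
        p = np.ones(n)
        mask = np.zeros(n, dtype=bool)
        # cover 60% of the baseline window [-1.25, -0.25) relative to onset 10 s
        b0 = int((10 - 1.25) * FS)
        mask[b0 : b0 + int(0.6 * FS)] = True
        tp = trial_band_power(p, onset=10.0, rt=2.0, sfreq=FS, mask=mask)
        assert not tp.usable
        assert tp.usable_baseline_fraction == pytest.approx(0.4, abs=0.01)

    def test_nonpositive_rt_rejected(self):
        with pytest.raises(ValueError):
            trial_band_power(np.ones(1024), onset=1.5, rt=0.0, sfreq=FS)

    def test_window_outside_recording_rejected(self):
        with pytest.raises(ValueError):
            trial_band_power(np.ones(1024), onset=0.5, rt=5.0, sfreq=FS)


class TestConditionErders:
    def test_identity_case(self):
        assert condition_erders([_tp(4.0, 4.0)])[0] == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        assert condition_erders([_tp(10.0, 5.0)])[0] == pytest.approx(-50.0)

    def test_hand_computed_medians(self):
        trials = [_tp(1, 2, trial=0), _tp(2, 4, trial=1), _tp(9, 18, trial=2)]
        value, n = condition_erders(trials)
        assert value == pytest.approx(100.0)
        assert n == 3

    def test_vertical_averaging_precedes_ratio(self):
        # medians B=2, A=5 -> +150%; the per-trial-ratio-then-median order
        # would give median{400%, 100%, 10%} = 100% and must NOT be produced
        trials = [_tp(1, 5), _tp(2, 4), _tp(10, 11)]
        value, _ = condition_erders(trials)
        assert value == pytest.approx(150.0)
        assert value != pytest.approx(100.0)

    def test_unusable_trials_excluded(self):
        trials = [_tp(1, 2), _tp(100, 1, usable=False)]
        value, n = condition_erders(trials)
        assert value == pytest.approx(100.0) and n == 1

    def test_empty_or_zero_baseline_is_missing(self):
        assert condition_erders([]) is None
        assert condition_erders([_tp(0.0, 1.0)]) is None

    def test_lower_bound(self, rng):
        b = rng.uniform(0.1, 10, size=20)
        a = rng.uniform(0.0, 10, size=20)
        value, _ = condition_erders([_tp(bi, ai, trial=i) for i, (bi, ai) in enumerate(zip(b, a))])
        assert value > -100.0


class TestRoiAggregate:
    def test_arithmetic_mean(self):
        vals = {"PO3": 10.0, "O1": 20.0}
        out = roi_aggregate(vals, {("PO", "left"): ("PO3", "O1")})
        assert out[("PO", "left")] == pytest.approx(15.0)

    def test_bad_channel_excluded(self):
        vals = {"Fp1": 10.0, "AF3": 20.0, "F7": 600.0, "F3": 30.0}
        out = roi_aggregate(
            vals, {("F", "left"): ("Fp1", "AF3", "F7", "F3")}, bad_channels={"F7"}
        )
        assert out[("F", "left")] == pytest.approx(20.0)

    def test_duplicate_assignment_rejected(self):
        with pytest.raises(ValueError, match="assigned to both"):
            roi_aggregate({}, {("F", "left"): ("F3",), ("FTC", "left"): ("F3",)})

    def test_midline_channels_never_in_roi(self):
        with pytest.raises(ValueError, match="midline"):
            roi_aggregate({}, {("F", "left"): ("Fz",)})

    def test_all_bad_roi_is_missing_with_warning(self):
        with pytest.warns(UserWarning, match="no good channels"):
            out = roi_aggregate(
                {"PO3": 1.0}, {("PO", "left"): ("PO3", "O1")}, bad_channels={"PO3", "O1"}
            )
        assert out[("PO", "left")] is None

    def test_default_roi_map_covers_non_midline_montage(self):
        from arithmeeg.synthdata import BIOSEMI32
        from arithmeeg.erders import MIDLINE_CHANNELS

        mapped = {ch for chans in DEFAULT_ROI_MAP.values() for ch in chans}
        assert mapped == set(BIOSEMI32) - set(MIDLINE_CHANNELS)


def test_scale_invariance_of_full_erders_chain(rng):
    """Multiplying the recording by any c > 0 leaves ERD/ERS unchanged."""
    from arithmeeg.erders import TrialWindow, compute_participant_erders

    fs = 256.0
    n = int(60 * fs)
    data = rng.normal(0, 10, (4, n))
    t = np.arange(n) / fs
    data += 20 * np.sin(2 * np.pi * 4.5 * t)  # shared theta rhythm
    channels = ("PO3", "O1", "PO4", "O2")
    twins = [
        TrialWindow(i, onset, 2.0, "retrieve", "subtraction")
        for i, onset in enumerate((10.0, 25.0, 40.0))
    ]
    roi_map = {("PO", "left"): ("PO3", "O1"), ("PO", "right"): ("PO4", "O2")}
    base = compute_participant_erders(data, channels, fs, twins, roi_map=roi_map)
    for c in (1e-3, 3.7, 250.0):
        scaled = compute_participant_erders(c * data, channels, fs, twins, roi_map=roi_map)
        for r0, r1 in zip(base, scaled):
            assert r1.value == pytest.approx(r0.value, abs=1e-8)


def test_window_spec_validation():
    with pytest.raises(ValueError):
        WindowSpec(baseline_start=-0.25, baseline_end=-1.25)
    with pytest.raises(ValueError):
        WindowSpec(baseline_start=-1.0, baseline_end=0.5)
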
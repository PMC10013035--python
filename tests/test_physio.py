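import logging

import numpy as np
import pytest

from physiocausal.physio import (
    EventSeries,
    Hypnogram,
    coarse_grain,
    eeg_alpha_amplitude,
    partition_by_stage,
    rate_from_events,
)
from physiocausal.signals import Signal


class TestRateFromEvents:
    def test_uniform_one_second_events(self):
        sig = rate_from_events(np.arange(0.0, 61.0))
        assert np.allclose(sig.values, 1.0)
        assert sig.dt == 1.0

    def test_uniform_half_second_events(self):
        sig = rate_from_events(np.arange(0.0, 30.0, 0.5))
        assert np.allclose(sig.values, 2.0)

    def test_alternating_intervals_linear_interpolation(self):
        # RR alternating 0.8/1.2 s: rate samples 1.25 and 0.8333 at the
        # closing beat times; grid values hand-derived
        times = np.cumsum([0.0, 0.8, 1.2, 0.8, 1.2, 0.8, 1.2, 0.8, 1.2, 0.8])
        sig = rate_from_events(times)
        # rate sample times: 0.8,2.0,2.8,4.0,4.8,6.0,6.8,8.0,8.8
        # grid t=1: between (0.8, 1.25) and (2.0, 0.8333)
        expect_t1 = 1.25 + (1.0 - 0.8) / 1.2 * (1 / 1.2 - 1.25)
        assert sig.values[0] == pytest.approx(expect_t1, abs=1e-12)
        # grid t=4 coincides with an event time: exact rate 1/1.2
        assert sig.values[3] == pytest.approx(1 / 1.2, abs=1e-12)

    def test_previous_interpolation_option(self):
        times = np.array([0.0, 0.8, 2.0])
        sig = rate_from_events(times, kind="previous")
        # grid covers [1, 2]; at t=1 the last known rate is 1/0.8
        assert sig.values[0] == pytest.approx(1.25)

    def test_validation(self):
        with pytest.raises(ValueError):
            EventSeries(np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            EventSeries(np.array([1.0]))


class TestEegAlphaAmplitude:
    def test_in_band_sine_amplitude_recovered(self):
        fs = 128.0
        t = np.arange(0, 20, 1 / fs)
        raw = Signal(2.0 * np.sin(2 * np.pi * 10.0 * t), dt=1 / fs)
        out = eeg_alpha_amplitude(raw)
        assert np.allclose(out.values[2:-2], 2.0, rtol=0.05)

    def test_out_of_band_sine_suppressed(self):
        fs = 128.0
        t = np.arange(0, 20, 1 / fs)
        raw = Signal(2.0 * np.sin(2 * np.pi * 30.0 * t), dt=1 / fs)
        out = eeg_alpha_amplitude(raw)
        assert np.all(out.values[2:-2] < 0.1)

    def test_zero_signal(self):
        raw = Signal(np.zeros(1280), dt=1 / 128.0)
        assert np.allclose(eeg_alpha_amplitude(raw).values, 0.0, atol=1e-10)

    def test_rectified_variant(self):
        fs = 128.0
        t = np.arange(0, 20, 1 / fs)
        raw = Signal(2.0 * np.sin(2 * np.pi * 10.0 * t), dt=1 / fs)
        out = eeg_alpha_amplitude(raw, method="rectified")
        assert np.allclose(out.values[2:-2], 2.0, rtol=0.05)

    def test_sampling_rate_too_low(self):
        with pytest.raises(ValueError):
            eeg_alpha_amplitude(Signal(np.zeros(100), dt=1 / 25.0))


class TestCoarseGrain:
    def test_block_means(self):
        out = coarse_grain(Signal([1.0, 2.0, 3.0, 4.0]), 2)
        assert np.allclose(out.values, [1.5, 3.5])
        assert out.dt == 2.0

    def test_constant_preserved(self):
        out = coarse_grain(Signal(np.full(30, 7.0)), 5)
        assert np.allclose(out.values, 7.0)

    def test_floor_rule(self):
        assert coarse_grain(Signal(np.arange(61.0)), 10).n == 6

    def test_commutes_with_affine_maps(self):
        rng = np.random.default_rng(0)
        x = Signal(rng.standard_normal(100))
        a = coarse_grain(Signal(3.0 * x.values - 2.0), 7).values
        b = 3.0 * coarse_grain(x, 7).values - 2.0
        assert np.allclose(a, b)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            coarse_grain(Signal(np.arange(10.0)), 0)


class TestHypnogram:
    def test_rk_mapping(self):
        h = Hypnogram.from_codes(["0", "1", "2", "3", "4", "5", "R", "W"], rk=True)
        assert h.stages == ("W", "LS", "LS", "DS", "DS", "REM", "REM", "W")

    def test_bad_code_rejected(self):
        with pytest.raises(ValueError):
            Hypnogram(("LS", "XX"))
        with pytest.raises(ValueError):
            Hypnogram(())


class TestPartitionByStage:
    def _triple(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return [Signal(rng.standard_normal(n), label=lab) for lab in "HBE"]

    def test_run_lengths(self):
        hyp = Hypnogram(("LS", "LS", "DS", "DS", "DS"))
        patches = partition_by_stage(self._triple(150), hyp, resolution=1.0)
        assert [(p.stage, p.n) for p in patches] == [("LS", 60), ("DS", 90)]

    def test_wake_excluded(self):
        hyp = Hypnogram(("W", "W", "W"))
        assert partition_by_stage(self._triple(90), hyp) == []

    def test_patches_standardized(self):
        hyp = Hypnogram(("LS", "REM"))
        for p in partition_by_stage(self._triple(60, seed=1), hyp):
            for ch in p.channels:
                assert ch.values.mean() == pytest.approx(0.0, abs=1e-12)
                assert ch.values.var() == pytest.approx(1.0, rel=1e-12)

    def test_every_nonwake_epoch_covered_once(self):
        hyp = Hypnogram(("LS", "W", "DS", "DS", "REM", "LS"))
        patches = partition_by_stage(self._triple(180, seed=2), hyp)
        covered = sorted((p.start, p.end) for p in patches)
        assert covered == [(0, 30), (60, 120), (120, 150), (150, 180)]

    def test_zero_variance_patch_dropped(self, caplog):
        rng = np.random.default_rng(3)
        H = np.concatenate([np.zeros(30), rng.standard_normal(30)])
        B, E = rng.standard_normal((2, 60))
        hyp = Hypnogram(("LS", "DS"))
        with caplog.at_level(logging.WARNING):
            patches = partition_by_stage(
                [Signal(H, label="H"), Signal(B, label="B"), Signal(E, label="E")], hyp
            )
        assert [p.stage for p in patches] == ["DS"]
        assert "zero variance" in caplog.text

    def test_coarser_resolution_counts(self):
        hyp = Hypnogram(("LS", "LS", "DS", "DS"))
        triple = self._triple(12, seed=4)  # 10 s resolution: 3 samples/epoch
        patches = partition_by_stage(triple, hyp, resolution=10.0)
        assert [(p.stage, p.n) for p in patches] == [("LS", 6), ("DS", 6)]

    def test_hypnogram_must_cover_series(self):
        hyp = Hypnogram(("LS",))
        with pytest.raises(ValueError):
            partition_by_stage(self._triple(90), hyp, resolution=1.0)
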
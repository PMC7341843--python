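import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import circawave as cw
from circawave import behavior


def block_profile(n_bins=135, on_start=30, on_len=60, high=1.0, low=0.0):
    v = np.full(n_bins, low)
    v[on_start: on_start + on_len] = high
    return cw.ActivityProfile(v, 27.0, 12.0)


class TestPeriodogram:
    def test_nocturnal_27h_recovered(self):
        act, _ = cw.make_actogram(period=27.0, days=10,
                                  night_fraction_of_activity=0.64, bin=6.0, seed=1)
        _, best, amp = cw.chi_square_periodogram(act, (20.0, 34.0), 6.0)
        assert best == pytest.approx(27.0, abs=0.2)
        assert amp > 0

    def test_uniform_counts_rarely_significant(self):
        neg = 0
        for seed in range(50):
            counts = np.random.default_rng(seed).poisson(5.0, 2400)
            _, _, amp = cw.chi_square_periodogram(
                cw.Actogram(counts, 6.0), (20.0, 34.0), 6.0
            )
            if amp <= 0:
                neg += 1
        assert neg >= 45

    def test_block_activity_peak_at_block_period(self):
        # perfect 24 h on/off blocks, 6-min bins
        counts = np.tile(np.r_[np.full(120, 10.0), np.zeros(120)], 10)
        act = cw.Actogram(counts, 6.0)
        curve, best, _ = cw.chi_square_periodogram(act, (20.0, 28.0), 6.0)
        assert best == pytest.approx(24.0, abs=0.05)

    def test_short_record_rejected(self):
        act = cw.Actogram(np.ones(100), 6.0)
        with pytest.raises(cw.InsufficientDataError):
            cw.chi_square_periodogram(act, (20.0, 34.0), 6.0)


class TestRelativeAmplitude:
    def test_all_activity_in_ten_hours_is_one(self):
        counts = np.tile(np.r_[np.full(100, 8.0), np.zeros(140)], 10)
        act = cw.Actogram(counts, 6.0)
        assert cw.relative_amplitude(act, 24.0) == pytest.approx(1.0)

    def test_constant_activity_is_zero(self):
        act = cw.Actogram(np.full(2400, 5.0), 6.0)
        assert cw.relative_amplitude(act, 24.0) == 0.0

    def test_block_design_closed_form(self):
        # expected RA for a 64/36 block design is (0.64-0.36)/(0.64+0.36)
        act, _ = cw.make_actogram(period=27.0, days=10,
                                  night_fraction_of_activity=0.64, bin=6.0, seed=2)
        ra = cw.relative_amplitude(act, 27.0)
        assert ra == pytest.approx(0.28, abs=0.05)

    def test_all_zero_undefined(self):
        act = cw.Actogram(np.zeros(2400), 6.0)
        assert np.isnan(cw.relative_amplitude(act, 24.0))


class TestDetectOnset:
    def test_block_start_found(self):
        assert cw.detect_onset(block_profile()) == 30

    def test_isolated_early_spike_ignored(self):
        p = block_profile()
        v = p.values.copy()
        v[20] = 1.0
        assert cw.detect_onset(cw.ActivityProfile(v, 27.0, 12.0)) == 30

    def test_onset_accuracy_across_seeds(self):
        errs = []
        for seed in range(20):
            act, _ = cw.make_actogram(period=27.0, days=10,
                                      night_fraction_of_activity=0.64,
                                      bin=6.0, seed=seed)
            prof = cw.single_profile(act, 27.0, 12.0, 7.0)
            t0 = act.span_h - 7 * 24.0
            true_pos = ((0.0 - t0) % 27.0) / 27.0 * prof.n_bins
            err = ((prof.onset_bin - true_pos + prof.n_bins / 2)
                   % prof.n_bins) - prof.n_bins / 2
            errs.append(err)
        assert np.max(np.abs(errs)) <= 3

    def test_silent_profile_undefined(self):
        with pytest.raises(cw.DegenerateInputError):
            cw.detect_onset(cw.ActivityProfile(np.zeros(135), 27.0, 12.0))


class TestAlignedProfile:
    def _deterministic_actogram(self, offset_h=0.0, days=10):
        bw_h = 0.1
        t = np.arange(int(days * 24 / bw_h)) * bw_h
        night = np.mod(t - offset_h, 27.0) < 13.5
        return cw.Actogram(np.where(night, 20.0, 2.0), 6.0)

    def test_identical_animals_zero_sem(self):
        a = self._deterministic_actogram()
        ap = cw.aligned_profile([a, cw.Actogram(a.counts.copy(), 6.0)])
        assert np.allclose(ap.sem, 0.0)

    def test_offset_animals_superpose_after_alignment(self):
        ap = cw.aligned_profile(
            [self._deterministic_actogram(0.0), self._deterministic_actogram(2.0)]
        )
        assert np.nanmax(ap.sem) < 0.02

    def test_onset_centred_at_midpoint(self):
        ap = cw.aligned_profile([self._deterministic_actogram(5.0)])
        mid = ap.n_bins // 2
        # activity rises exactly at the centre of the profile
        assert ap.values[mid] > 0.9
        assert ap.values[mid - 3] < 0.2

    def test_arrhythmic_animal_excluded(self):
        flat = cw.Actogram(np.zeros(2400), 6.0)
        good = self._deterministic_actogram()
        with pytest.warns(UserWarning):
            ap = cw.aligned_profile([good, flat])
        assert ap.n_animals == 1

    def test_global_rotation_invariance(self):
        animals = [self._deterministic_actogram(o) for o in (0.0, 4.0)]
        rolled = [cw.Actogram(np.roll(a.counts, 270), 6.0) for a in animals]
        ap1 = cw.aligned_profile(animals)
        ap2 = cw.aligned_profile(rolled)       # 27 h roll = whole cycles
        assert np.allclose(ap1.values, ap2.values, atol=1e-9)


class TestDayNightSplit:
    def test_activity_confined_to_night(self):
        p = block_profile(on_start=30, on_len=60)
        prof = cw.ActivityProfile(p.values, 27.0, 12.0, onset_bin=30)
        day, night = cw.day_night_split(prof)
        assert day == pytest.approx(0.0)
        assert night == pytest.approx(100.0)

    def test_uniform_fifty_fifty(self):
        prof = cw.ActivityProfile(np.full(135, 1.0), 27.0, 12.0, onset_bin=17)
        assert cw.day_night_split(prof) == (pytest.approx(50.0), pytest.approx(50.0))

    def test_generator_night_fraction_recovered(self):
        nights = []
        for seed in range(10):
            act, _ = cw.make_actogram(period=27.0, days=10,
                                      night_fraction_of_activity=0.64,
                                      bin=6.0, seed=seed)
            prof = cw.single_profile(act, 27.0, 12.0, 7.0)
            nights.append(cw.day_night_split(prof)[1])
        assert np.mean(nights) == pytest.approx(64.0, abs=2.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 100), onset=st.integers(0, 134))
    def test_percentages_conserve_total(self, seed, onset):
        rng = np.random.default_rng(seed)
        prof = cw.ActivityProfile(rng.uniform(0.1, 1.0, 135), 27.0, 12.0,
                                  onset_bin=onset)
        day, night = cw.day_night_split(prof)
        assert day + night == pytest.approx(100.0, abs=1e-9)


def test_double_plot_render(tmp_path):
    act, _ = cw.make_actogram(period=27.0, days=5, bin=6.0, seed=0)
    out = tmp_path / "actogram.png"
    behavior.double_plot_actogram(act, out, plot_period=27.0)
    assert out.stat().st_size > 0
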
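import numpy as np
import pytest
from scipy.stats import f_oneway

from tonecortex.electrode_stats import (SpeechResponsiveSelector, _max_run_2d,
                                        anova_f_series, speech_responsive,
                                        tone_discriminant)
from tonecortex.io_formats import SampledTrack
from tonecortex.signal_preproc import Epochs


def _epochs(data, labels):
    data = np.asarray(data, dtype=float)
    return Epochs(data=data, time_axis=np.arange(data.shape[2]) / 100.0,
                  labels=np.asarray(labels),
                  electrode_ids=[f"e{k}" for k in range(data.shape[1])])


class TestAnova:
    def test_hand_case_f_equals_8(self):
        # two groups {1,2} and {3,4}: SSB=4 (df 1), SSW=1 (df 2) -> F=8
        data = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        f, p = anova_f_series(data, np.array([1, 1, 2, 2]))
        assert f[0, 0] == pytest.approx(8.0, abs=1e-12)

    def test_matches_scipy(self, rng):
        data = rng.standard_normal((24, 3, 5))
        labels = np.repeat([1, 2, 3, 4], 6)
        f, p = anova_f_series(data, labels)
        for e in range(3):
            for t in range(5):
                ref = f_oneway(*[data[labels == g, e, t] for g in (1, 2, 3, 4)])
                assert f[e, t] == pytest.approx(ref.statistic, abs=1e-10)
                assert p[e, t] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_affine_invariance(self, rng):
        data = rng.standard_normal((40, 2, 10))
        labels = np.repeat([1, 2, 3, 4], 10)
        f1, _ = anova_f_series(data, labels)
        f2, _ = anova_f_series(3.0 * data + 7.0, labels)
        assert np.allclose(f1, f2, atol=1e-9)


class TestToneDiscriminant:
    def test_strong_separation_detected(self, rng):
        n_per = 12
        data = rng.standard_normal((4 * n_per, 2, 50))
        labels = np.repeat([1, 2, 3, 4], n_per)
        for g in range(4):  # 5-SD separation over a 200 ms span on electrode 0
            data[labels == g + 1, 0, 20:40] += 5.0 * g
        res = tone_discriminant(_epochs(data, labels), n_electrodes_total=64)
        assert res.discriminant[0]
        assert not res.discriminant[1]
        assert res.n_consecutive_significant[0] >= 10

    def test_missing_tone_group_rejected(self, rng):
        data = rng.standard_normal((30, 2, 10))
        labels = np.repeat([1, 2, 3], 10)
        with pytest.raises(ValueError, match="four"):
            tone_discriminant(_epochs(data, labels))

    def test_subset_keeps_family_threshold(self, rng):
        """A marginal electrode must not become significant when tested alone."""
        n_per = 10
        data = rng.standard_normal((4 * n_per, 1, 50))
        labels = np.repeat([1, 2, 3, 4], n_per)
        data[labels == 1, 0, 10:30] += 0.9
        lone = tone_discriminant(_epochs(data, labels), n_electrodes_total=1)
        family = tone_discriminant(_epochs(data, labels), n_electrodes_total=256)
        assert family.n_consecutive_significant[0] <= lone.n_consecutive_significant[0]


class TestMaxRun:
    def test_threshold_edge(self):
        nine = np.zeros((1, 20), dtype=bool)
        nine[0, 2:11] = True  # 9 consecutive
        ten = np.zeros((1, 20), dtype=bool)
        ten[0, 2:12] = True   # 10 consecutive
        assert _max_run_2d(nine)[0] == 9
        assert _max_run_2d(ten)[0] == 10

    def test_interrupted_run(self):
        m = np.zeros((1, 25), dtype=bool)
        m[0, :9] = True
        m[0, 10:19] = True  # 9 + gap + 9, never 10
        assert _max_run_2d(m)[0] == 9


class TestSpeechResponsive:
    def _track_with_boxcars(self, rng, n_onsets=30, amp=0.0, dur_s=200.0):
        rate = 100.0
        n = int(dur_s * rate)
        x = rng.standard_normal(n)
        onsets = np.linspace(5.0, dur_s - 5.0, n_onsets)
        for t in onsets:
            i = int(t * rate)
            x[i:i + 15] += amp
        return SampledTrack(x, 0.0, rate), onsets

    def test_injected_response_detected(self, rng):
        track, onsets = self._track_with_boxcars(rng, amp=10.0)
        res = speech_responsive(track, onsets, seed=0)
        assert res["responsive"]

    def test_noise_not_flagged(self, rng):
        track, onsets = self._track_with_boxcars(rng, amp=0.0)
        res = speech_responsive(track, onsets, seed=0)
        assert not res["responsive"]

    def test_constant_shift_invariance(self, rng):
        track, onsets = self._track_with_boxcars(rng, amp=10.0)
        shifted = SampledTrack(track.values + 100.0, 0.0, 100.0)
        a = speech_responsive(track, onsets, seed=0)
        b = speech_responsive(shifted, onsets, seed=0)
        assert np.allclose(a["margin"], b["margin"], rtol=1e-9)
        assert a["responsive"] == b["responsive"]

    def test_too_few_onsets_rejected(self, rng):
        track, _ = self._track_with_boxcars(rng)
        with pytest.raises(ValueError, match="onsets"):
            speech_responsive(track, np.array([5.0, 6.0]), seed=0)

    def test_selector_wrapper_matrix_input(self, rng):
        rate = 100.0
        X = rng.standard_normal((3, 20000))
        onsets = np.linspace(5.0, 195.0, 30)
        for t in onsets:
            X[0, int(t * rate):int(t * rate) + 15] += 10.0
        sel = SpeechResponsiveSelector(seed=0).fit(X, onsets, rate=rate,
                                                   start_time=0.0)
        assert sel.responsive_[0]
        assert not sel.responsive_[1:].any()
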
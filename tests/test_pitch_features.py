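import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tonecortex.io_formats import SampledTrack
from tonecortex.pitch_features import (BLOCK_DIMS, ToneContourPCA, binary_pitch,
                                       binned_onehot, make_features,
                                       pitch_change, pitch_height, read_features,
                                       warp_contours, write_features)


class TestElementaryFeatures:
    def test_height_is_log(self):
        tr = SampledTrack(np.full(20, 100.0), 0.0, 100.0)
        h = pitch_height(tr)
        assert np.allclose(h.values, np.log(100.0))

    def test_height_missing_propagates(self):
        tr = SampledTrack([100.0, np.nan, 120.0], 0.0, 100.0)
        h = pitch_height(tr)
        assert np.isnan(h.values[1]) and np.isfinite(h.values[[0, 2]]).all()

    def test_height_doubling_adds_log2(self):
        v = np.array([100.0, 150.0, 200.0])
        a = pitch_height(SampledTrack(v, 0.0, 100.0)).values
        b = pitch_height(SampledTrack(2 * v, 0.0, 100.0)).values
        assert np.allclose(b - a, np.log(2.0))

    def test_nonpositive_voiced_rejected(self):
        with pytest.raises(ValueError):
            pitch_height(SampledTrack([100.0, -5.0], 0.0, 100.0))

    def test_change_constant_is_zero(self):
        h = SampledTrack(np.full(10, 4.6), 0.0, 100.0)
        c = pitch_change(h)
        assert np.isnan(c.values[0]) and np.allclose(c.values[1:], 0.0)

    def test_change_exponential_closed_form(self):
        t = np.arange(100) / 100.0
        f0 = 100.0 * np.exp(0.5 * t)
        c = pitch_change(pitch_height(SampledTrack(f0, 0.0, 100.0)))
        assert np.allclose(c.values[1:], 0.005)

    def test_change_missing_at_voicing_boundary(self):
        tr = SampledTrack([100.0, np.nan, 120.0, 125.0], 0.0, 100.0)
        c = pitch_change(pitch_height(tr))
        assert np.isnan(c.values[1]) and np.isnan(c.values[2])
        assert np.isfinite(c.values[3])

    def test_binary_pitch(self):
        tr = SampledTrack([100.0, np.nan, 120.0], 0.0, 100.0)
        assert np.allclose(binary_pitch(tr).values, [1, 0, 1])
        assert np.allclose(binary_pitch(tr).values,
                           1.0 - np.isnan(tr.values))


class TestBinnedOnehot:
    def test_out_of_range_to_extreme_bins(self, rng):
        v = np.concatenate([rng.random(500), [-10.0, 10.0]])
        out = binned_onehot(v)
        assert out[-2, 0] == 1.0 and out[-1, -1] == 1.0

    def test_missing_rows_all_zero(self, rng):
        v = rng.random(100)
        v[3] = np.nan
        out = binned_onehot(v)
        assert out[3].sum() == 0.0
        assert np.all(np.isin(out.sum(axis=1), [0.0, 1.0]))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            binned_onehot(np.full(100, 2.0))

    def test_uniform_occupancy(self, rng):
        v = rng.random(100_000)
        occ = binned_onehot(v).sum(axis=0) / v.size
        # interior bins hold 9.5% each; extreme bins add the 2.5% tails
        assert np.allclose(occ[1:-1], 0.095, atol=0.003)
        assert np.allclose(occ[[0, -1]], 0.12, atol=0.003)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-50, 50), min_size=30, max_size=60, unique=True))
    def test_bin_index_monotone_in_value(self, vals):
        v = np.asarray(vals)
        out = binned_onehot(v)
        idx = out.argmax(axis=1)[np.argsort(v)]
        assert np.all(np.diff(idx) >= 0)


class TestMakeFeatures:
    def test_block_dims_and_alignment(self, tiny_dataset):
        ds, truth = tiny_dataset
        feats = make_features(ds, truth.trial_commands)
        assert feats.dims() == BLOCK_DIMS
        assert feats.n_times == ds.contour.n
        assert np.allclose(feats.times, ds.contour.times)

    def test_pitch_blocks_zero_in_silence(self, tiny_dataset):
        ds, truth = tiny_dataset
        feats = make_features(ds, truth.trial_commands)
        silent = ~np.isfinite(ds.contour.values)
        assert feats.blocks["pitch_height"][silent].sum() == 0
        assert feats.blocks["binary_pitch"][silent].sum() == 0

    def test_tone_category_matches_binary_pitch_on_trial(self, tiny_dataset):
        ds, truth = tiny_dataset
        feats = make_features(ds, truth.trial_commands)
        row = ds.events.iloc[0]
        i0 = int(round(row["acoustic_onset"] * ds.rate))
        i1 = int(round(row["offset"] * ds.rate))
        col = int(row["tone"]) - 1
        assert np.allclose(feats.blocks["tone_category"][i0:i1, col],
                           feats.blocks["binary_pitch"][i0:i1, 0])

    def test_missing_fit_listed(self, tiny_dataset):
        ds, truth = tiny_dataset
        fits = dict(truth.trial_commands)
        fits.pop(0)
        with pytest.raises(ValueError, match=r"\[0\]"):
            make_features(ds, fits)

    def test_hdf5_round_trip(self, tiny_dataset, tmp_path):
        ds, truth = tiny_dataset
        feats = make_features(ds, truth.trial_commands)
        p = tmp_path / "f.h5"
        write_features(feats, p)
        back = read_features(p)
        for name, b in feats.blocks.items():
            assert np.allclose(back.blocks[name], b)


class TestWarp:
    def test_identity_for_40_samples(self):
        v = np.linspace(100, 150, 40)
        out = warp_contours([SampledTrack(v, 0.0, 100.0)])
        assert out.shape == (1, 40)
        assert np.allclose(out[0], v)

    def test_downsample_ramp_keeps_endpoints(self):
        v = np.linspace(100, 180, 80)
        out = warp_contours([SampledTrack(v, 0.0, 100.0)])
        assert out.shape == (1, 40)
        assert out[0, 0] == pytest.approx(100.0)
        assert out[0, -1] == pytest.approx(180.0)
        assert np.allclose(np.diff(out[0]), np.diff(out[0])[0])

    def test_short_contours_skipped(self):
        good = SampledTrack(np.linspace(100, 120, 30), 0.0, 100.0)
        bad = SampledTrack([np.nan, 100.0, np.nan], 0.0, 100.0)
        out = warp_contours([good, bad])
        assert out.shape == (1, 40)


class TestPCA:
    def test_rank_one(self, rng):
        base = rng.standard_normal(40)
        X = np.outer(np.arange(1, 11, dtype=float), base)
        est = ToneContourPCA().fit(X)
        assert est.n_components_ == 1
        assert est.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_exact_reconstruction_and_orthonormal_weights(self, rng):
        X = rng.standard_normal((60, 40))
        est = ToneContourPCA().fit(X)
        recon = est.scores_ @ est.weights_.T + est.mean_
        assert np.abs(recon - X).max() < 1e-9
        assert np.abs(est.weights_.T @ est.weights_ - np.eye(40)).max() < 1e-9

    def test_rank_zero_rejected(self):
        with pytest.raises(ValueError):
            ToneContourPCA().fit(np.ones((5, 40)))
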
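import numpy as np
import pytest

from tonecortex.encoding import (TemporalReceptiveField, build_design,
                                 encode_vs_discriminate, fisher_z_compare,
                                 fit_trf, unique_variance)
from tonecortex.pitch_features import FeatureMatrix


def _features(blocks):
    return FeatureMatrix(blocks={k: np.atleast_2d(v.T).T for k, v in blocks.items()},
                         order=list(blocks.keys()))


class TestBuildDesign:
    def test_zero_lag_is_identity(self, rng):
        x = rng.standard_normal(50)
        D, colmap, lags = build_design(_features({"a": x}), (0.0, 0.0))
        assert D.shape == (50, 1)
        assert np.allclose(D[:, 0], x)

    def test_lag_shifts_with_zero_pad(self, rng):
        x = rng.standard_normal(30)
        D, colmap, lags = build_design(_features({"a": x}), (-0.01, 0.01))
        assert D.shape == (30, 3)
        assert np.allclose(lags, [-0.01, 0.0, 0.01])
        assert np.allclose(D[:-1, 0], x[1:]) and D[-1, 0] == 0.0  # future lag
        assert np.allclose(D[1:, 2], x[:-1]) and D[0, 2] == 0.0   # past lag

    def test_column_count(self, rng):
        blocks = {"a": rng.standard_normal((40, 3)), "b": rng.standard_normal(40)}
        D, colmap, lags = build_design(_features(blocks), (-0.02, 0.02))
        assert D.shape[1] == (3 + 1) * 5 == len(colmap)

    def test_too_wide_window_rejected(self, rng):
        with pytest.raises(ValueError, match="lag window"):
            build_design(_features({"a": rng.standard_normal(20)}), (-0.2, 0.2))


class TestFitTRF:
    def test_known_weight_recovery(self, rng):
        n = 3000
        x = rng.standard_normal(n)
        y = np.zeros(n)
        y[2:] = 1.5 * x[:-2]  # true lag +0.02 s
        feats = _features({"a": x})
        model, r2 = fit_trf(feats, y, lag_window=(-0.05, 0.05),
                            lambda_grid=[1e-3, 1e-1], seed=0)
        assert r2[0] >= 0.999
        w = model.weight_tensor("a")[0, :, 0]
        assert model.lag_grid[np.argmax(np.abs(w))] == pytest.approx(0.02)

    def test_null_r2_near_zero(self, rng):
        n = 2000
        feats = _features({"a": rng.standard_normal(n)})
        r2s = [fit_trf(feats, rng.standard_normal(n), lag_window=(-0.02, 0.02),
                       lambda_grid=[1e0, 1e2], seed=s)[1][0] for s in range(10)]
        assert 0 <= np.mean(r2s) < 0.02

    def test_infinite_ridge_shrinks_to_zero(self, rng):
        n = 1000
        x = rng.standard_normal(n)
        y = x + 0.1 * rng.standard_normal(n)
        est = TemporalReceptiveField(lag_window=(0.0, 0.0),
                                     lambda_grid=[1e12], seed=0)
        est.fit(_features({"a": x}), y)
        assert np.abs(est.model_.weights).max() < 1e-6
        pred = est.predict(_features({"a": x}))
        assert np.ptp(pred) < 1e-5

    def test_degenerate_y_rejected(self, rng):
        feats = _features({"a": rng.standard_normal(500)})
        with pytest.raises(ValueError, match="variance"):
            fit_trf(feats, np.zeros(500))

    def test_affine_y_invariance_of_r2(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        y = np.roll(x, 1) + 0.5 * rng.standard_normal(n)
        feats = _features({"a": x})
        _, r2a = fit_trf(feats, y, lag_window=(-0.03, 0.03), seed=1)
        _, r2b = fit_trf(feats, 5.0 * y - 2.0, lag_window=(-0.03, 0.03), seed=1)
        assert r2a[0] == pytest.approx(r2b[0], abs=1e-9)


class TestUniqueVariance:
    def test_driven_feature_owns_variance(self, rng):
        n = 4000
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = np.roll(x, 1)  # noiseless: driven only by "target"
        feats = _features({"target": x, "other": z})
        res = unique_variance(feats, y, ["target", "other"],
                              lag_window=(-0.03, 0.03), seed=0)
        assert res["dr2"]["target"][0] >= 0.9 * res["full_r2"][0]
        assert res["dr2"]["other"][0] <= 0.05

    def test_duplicated_feature_has_no_unique_variance(self, rng):
        n = 4000
        x = rng.standard_normal(n)
        y = np.roll(x, 1) + 0.3 * rng.standard_normal(n)
        feats = _features({"a": x, "b": x.copy()})
        res = unique_variance(feats, y, ["a", "b"], lag_window=(-0.03, 0.03),
                              seed=0)
        assert abs(res["dr2"]["a"][0]) < 0.05
        assert abs(res["dr2"]["b"][0]) < 0.05
        assert res["full_r2"][0] > 0.5

    def test_null_dr2_near_zero(self, rng):
        n = 2000
        feats = _features({"a": rng.standard_normal(n),
                           "b": rng.standard_normal(n)})
        vals = []
        for s in range(8):
            res = unique_variance(feats, rng.standard_normal(n), ["a"],
                                  lag_window=(-0.02, 0.02), seed=s)
            vals.append(res["dr2"]["a"][0])
        assert abs(np.mean(vals)) < 0.02

    def test_unknown_set_rejected(self, rng):
        feats = _features({"a": rng.standard_normal(500),
                           "b": rng.standard_normal(500)})
        with pytest.raises(ValueError, match="nope"):
            unique_variance(feats, rng.standard_normal(500), ["nope"])


class TestCorrelationAnalyses:
    def test_exact_line_gives_r_one(self, rng):
        x = rng.random(20)
        y = 2 * x + 1
        sig = np.ones(20, bool)
        res = encode_vs_discriminate(x, y, sig, np.zeros(20, bool))
        assert res["r"] == pytest.approx(1.0)
        assert res["n"] == 20

    def test_too_few_electrodes_rejected(self, rng):
        with pytest.raises(ValueError, match="3"):
            encode_vs_discriminate(np.ones(5), np.ones(5),
                                   np.array([1, 1, 0, 0, 0], bool),
                                   np.zeros(5, bool))

    def test_fisher_z_zero_for_equal_r(self):
        z, p = fisher_z_compare(0.4, 50, 0.4, 80)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_fisher_z_closed_form(self):
        z, _ = fisher_z_compare(0.5, 103, 0.0, 103)
        assert z == pytest.approx(np.arctanh(0.5) / np.sqrt(2 / 100), abs=1e-3)

    def test_fisher_z_antisymmetric(self):
        z1, _ = fisher_z_compare(0.6, 40, 0.2, 60)
        z2, _ = fisher_z_compare(0.2, 60, 0.6, 40)
        assert z1 == pytest.approx(-z2)

    def test_fisher_z_degenerate_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_compare(1.0, 50, 0.2, 50)
        with pytest.raises(ValueError):
            fisher_z_compare(0.5, 3, 0.2, 50)


def test_encode_vs_discriminate_result_objects(rng):
    from tonecortex.electrode_stats import SelectionResult
    from tonecortex.encoding import EncodingResult, encode_vs_discriminate_results

    n = 12
    dr2 = rng.random(n)
    F = np.tile((10 * dr2 + 1)[:, None], (1, 5))
    enc = EncodingResult(electrode_ids=[f"e{k}" for k in range(n)],
                         full_r2=dr2 * 2, cv_correlations=np.zeros((5, n)),
                         unique_dr2={"tone_command": dr2},
                         perm_p={"tone_command": np.full(n, 1 / 201)})
    sel = SelectionResult(electrode_ids=[f"e{k}" for k in range(n)],
                          discriminant=np.zeros(n, bool), F_series=F,
                          n_consecutive_significant=np.zeros(n, int))
    res = encode_vs_discriminate_results(enc, sel)
    assert res["n"] == n
    assert res["r"] == pytest.approx(1.0)
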
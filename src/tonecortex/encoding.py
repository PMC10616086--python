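"""Lagged linear (temporal receptive field) encoding models.

Per electrode, high-gamma y(t) is modelled as a lagged linear function of
the speech features::

    y(t) = sum_f sum_tau  beta_f(tau) . x_f(t - tau) + eps

fitted by ridge regression with the penalty chosen on a validation split.
The data are divided into contiguous 80/10/10 train/validation/test chunks
(contiguous, to avoid autocorrelation leakage), the procedure is repeated
five times, and performance is the mean across the five test sets of the
squared held-out Pearson correlation.

The unique contribution of a feature set is the drop in held-out R^2 when
that set is excluded from the full model (same folds for full and reduced
models).  Its significance comes from a permutation test that shuffles
whole-syllable feature trajectories across syllable tokens, destroying the
feature-neural alignment while preserving within-syllable dynamics.

All models over one dataset share the design matrix, so reduced models are
solved on sub-blocks of a single Gram matrix; this is exact, not an
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .pitch_features import FeatureMatrix

__all__ = [
    "TRFModel",
    "EncodingResult",
    "TemporalReceptiveField",
    "build_design",
    "fit_trf",
    "unique_variance",
    "permutation_null",
    "encode_vs_discriminate",
    "encode_vs_discriminate_results",
    "fisher_z_compare",
    "shuffle_features_between_syllables",
]

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-2, 5, 8))


@dataclass
class TRFModel:
    """Fitted lag weights per feature set."""

    lag_grid: np.ndarray                      # seconds
    column_map: list[tuple[str, int, float]]  # (feature set, dim, lag)
    weights: np.ndarray                       # columns x electrodes
    ridge_lambda: np.ndarray                  # folds x electrodes
    intercept: np.ndarray                     # electrodes

    def weight_tensor(self, feature_set: str) -> np.ndarray:
        """Weights for one set as (dims, lags, electrodes)."""
        idx = [k for k, (s, _, _) in enumerate(self.column_map) if s == feature_set]
        dims = sorted({d for s, d, _ in self.column_map if s == feature_set})
        return self.weights[idx].reshape(len(dims), self.lag_grid.size, -1)


@dataclass
class EncodingResult:
    """Per-electrode encoding performance and variance partitioning."""

    electrode_ids: list[str]
    full_r2: np.ndarray
    cv_correlations: np.ndarray                       # folds x electrodes
    unique_dr2: dict[str, np.ndarray] = field(default_factory=dict)
    perm_p: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        d = {"electrode_id": self.electrode_ids, "full_R2": self.full_r2}
        for k, v in self.unique_dr2.items():
            d[f"dR2_{k}"] = v
        for k, v in self.perm_p.items():
            d[f"p_{k}"] = v
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def build_design(features: FeatureMatrix, lag_window: tuple[float, float] = (-0.4, 0.4),
                 sets: list[str] | None = None
                 ) -> tuple[np.ndarray, list[tuple[str, int, float]], np.ndarray]:
    """Time-lagged design matrix with one column per (set, dim, lag).

    A column at lag tau holds x(t - tau): positive lags look back in time,
    negative lags ahead (features that follow the neural activity).
    Out-of-range samples are zero-padded.
    """
    rate = features.rate
    lo = int(round(lag_window[0] * rate))
    hi = int(round(lag_window[1] * rate))
    if not np.isclose(lag_window[0] * rate, lo) or not np.isclose(lag_window[1] * rate, hi):
        raise ValueError("lag bounds must be multiples of the sample period")
    lags = np.arange(lo, hi + 1)
    X, base_map = features.stacked(sets)
    n, d = X.shape
    if lags.size >= n:
        raise ValueError("lag window wider than the data")
    D = np.zeros((n, d * lags.size))
    colmap: list[tuple[str, int, float]] = []
    col = 0
    for (name, dim) in base_map:
        x = X[:, [k for k, bm in enumerate(base_map) if bm == (name, dim)][0]]
        for L in lags:
            if L > 0:
                D[L:, col] = x[:-L]
            elif L < 0:
                D[:L, col] = x[-L:]
            else:
                D[:, col] = x
            colmap.append((name, dim, L / rate))
            col += 1
    return D, colmap, lags / rate


# ---------------------------------------------------------------------------
# Shared-Gram ridge engine
# ---------------------------------------------------------------------------


def make_folds(n: int, n_splits: int = 5, seed: int = 0) -> list[dict]:
    """Contiguous-chunk 80/10/10 splits, repeated ``n_splits`` times.

    The time axis is cut into 2*n_splits contiguous chunks; each repeat
    takes one chunk as test and another as validation, training on the
    rest.  Chunk roles are assigned by a seeded permutation.
    """
    n_chunks = 2 * n_splits
    edges = np.linspace(0, n, n_chunks + 1).astype(int)
    chunks = [np.arange(edges[k], edges[k + 1]) for k in range(n_chunks)]
    perm = np.random.default_rng(seed).permutation(n_chunks)
    folds = []
    for r in range(n_splits):
        test_c = int(perm[r])
        val_c = int(perm[r + n_splits])
        train_c = [c for c in range(n_chunks) if c not in (test_c, val_c)]
        folds.append({"train_chunks": train_c, "val_chunk": val_c,
                      "test_chunk": test_c, "chunks": chunks})
    return folds


class _GramCache:
    """Per-chunk sufficient statistics so every model/fold reuses one pass."""

    def __init__(self, D: np.ndarray, Y: np.ndarray, folds: list[dict]):
        chunks = folds[0]["chunks"]
        self.G = [D[c].T @ D[c] for c in chunks]
        self.S = [D[c].sum(axis=0) for c in chunks]
        self.XtY = [D[c].T @ Y[c] for c in chunks]
        self.Ysum = [Y[c].sum(axis=0) for c in chunks]
        self.counts = [c.size for c in chunks]
        self.D = D
        self.Y = Y

    def train_stats(self, fold: dict):
        tc = fold["train_chunks"]
        G = sum(self.G[c] for c in tc)
        s = sum(self.S[c] for c in tc)
        XtY = sum(self.XtY[c] for c in tc)
        ysum = sum(self.Ysum[c] for c in tc)
        n = sum(self.counts[c] for c in tc)
        mu = s / n
        ybar = ysum / n
        G_c = G - n * np.outer(mu, mu)
        XtY_c = XtY - n * np.outer(mu, ybar)
        return G_c, XtY_c, mu, ybar


def _corr_cols(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of two (n, E) arrays."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    num = (A * B).sum(axis=0)
    den = np.sqrt((A**2).sum(axis=0) * (B**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return r


def _ridge_cv_model(cache: _GramCache, folds: list[dict], col_idx: np.ndarray,
                    lambda_grid, collect_weights: bool = False) -> dict:
    """Cross-validated ridge on a column subset; shared across electrodes.

    Per fold, solutions for every penalty are computed from the training
    Gram sub-block; the penalty is chosen per electrode on the validation
    chunk (ties toward stronger regularisation) and performance is the test
    Pearson correlation at the chosen penalty.
    """
    lambdas = np.asarray(list(lambda_grid), dtype=float)
    D, Y = cache.D, cache.Y
    E = Y.shape[1]
    n_folds = len(folds)
    fold_r = np.zeros((n_folds, E))
    chosen = np.zeros((n_folds, E))
    W_acc = None
    b_acc = np.zeros(E)
    for fi, fold in enumerate(folds):
        G, XtY, mu, ybar = cache.train_stats(fold)
        A = G[np.ix_(col_idx, col_idx)]
        B = XtY[col_idx]
        chunks = fold["chunks"]
        Dv = D[chunks[fold["val_chunk"]]][:, col_idx] - mu[col_idx]
        Dt = D[chunks[fold["test_chunk"]]][:, col_idx] - mu[col_idx]
        Yv = Y[chunks[fold["val_chunk"]]]
        Yt = Y[chunks[fold["test_chunk"]]]
        Ws = []
        val_r = np.full((lambdas.size, E), -np.inf)
        for li, lam in enumerate(lambdas):
            M = A + lam * np.eye(A.shape[0])
            try:
                cf = linalg.cho_factor(M, lower=True, check_finite=False)
                W = linalg.cho_solve(cf, B, check_finite=False)
            except linalg.LinAlgError:
                W = np.linalg.lstsq(M, B, rcond=None)[0]
            Ws.append(W)
            val_r[li] = _corr_cols(Dv @ W, Yv)
        # ascending grid + >= keeps the largest lambda among ties
        best_li = np.zeros(E, dtype=int)
        best_v = np.full(E, -np.inf)
        for li in range(lambdas.size):
            upd = val_r[li] >= best_v - 1e-12
            best_li[upd] = li
            best_v[upd] = np.maximum(best_v[upd], val_r[li][upd])
        test_pred = np.empty_like(Yt)
        for li in np.unique(best_li):
            cols = best_li == li
            test_pred[:, cols] = Dt @ Ws[li][:, cols]
        fold_r[fi] = _corr_cols(test_pred, Yt)
        chosen[fi] = lambdas[best_li]
        if collect_weights:
            Wsel = np.stack([Ws[best_li[e]][:, e] for e in range(E)], axis=1)
            W_acc = Wsel if W_acc is None else W_acc + Wsel
            b_acc += ybar - mu[col_idx] @ Wsel
    out = {"fold_r": fold_r, "r2": (fold_r**2).mean(axis=0), "lambda": chosen}
    if collect_weights:
        out["weights"] = W_acc / n_folds
        out["intercept"] = b_acc / n_folds
    return out


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class TemporalReceptiveField:
    """Ridge TRF over all electrodes at once, sklearn-style.

    Parameters
    ----------
    lag_window : (tau_min, tau_max) seconds; symmetric +/-0.4 s by default
        so both feed-forward (neural leads) and feedback lags are covered.
    lambda_grid : ridge penalties searched on the validation chunk.
    n_splits : number of 80/10/10 repeats.
    seed : seeds the chunk-role permutation.

    Fitted attributes: ``model_`` (TRFModel), ``r2_`` (squared held-out
    correlation per electrode), ``cv_correlations_`` (folds x electrodes).
    """

    def __init__(self, lag_window=(-0.4, 0.4), lambda_grid=DEFAULT_LAMBDA_GRID,
                 n_splits: int = 5, seed: int = 0):
        self.lag_window = lag_window
        self.lambda_grid = lambda_grid
        self.n_splits = n_splits
        self.seed = seed

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in ("lag_window", "lambda_grid",
                                              "n_splits", "seed")}

    def set_params(self, **p):
        for k, v in p.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, features: FeatureMatrix, Y: np.ndarray):
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] != features.n_times:
            Y = Y.T
        if Y.shape[0] != features.n_times:
            raise ValueError("Y rows must match the feature time axis")
        if np.any(Y.std(axis=0) < 1e-12):
            raise ValueError("degenerate electrode track: zero variance")
        D, colmap, lag_grid = build_design(features, self.lag_window)
        folds = make_folds(D.shape[0], self.n_splits, self.seed)
        cache = _GramCache(D, Y, folds)
        res = _ridge_cv_model(cache, folds, np.arange(D.shape[1]),
                              self.lambda_grid, collect_weights=True)
        self.model_ = TRFModel(lag_grid=lag_grid, column_map=colmap,
                               weights=res["weights"], ridge_lambda=res["lambda"],
                               intercept=res["intercept"])
        self.cv_correlations_ = res["fold_r"]
        self.r2_ = res["r2"]
        self._cache = cache
        self._folds = folds
        self._colmap = colmap
        return self

    def predict(self, features: FeatureMatrix) -> np.ndarray:
        D, _, _ = build_design(features, self.lag_window)
        return D @ self.model_.weights + self.model_.intercept


def _columns_of(colmap, drop_set: str | None) -> np.ndarray:
    if drop_set is None:
        return np.arange(len(colmap))
    return np.array([k for k, (s, _, _) in enumerate(colmap) if s != drop_set])


def fit_trf(features: FeatureMatrix, y: np.ndarray,
            lag_window=(-0.4, 0.4), lambda_grid=DEFAULT_LAMBDA_GRID,
            n_splits: int = 5, seed: int = 0) -> tuple[TRFModel, np.ndarray]:
    """Fit the full TRF; returns the model and per-electrode held-out R^2."""
    est = TemporalReceptiveField(lag_window, lambda_grid, n_splits, seed).fit(features, y)
    return est.model_, est.r2_


def unique_variance(features: FeatureMatrix, Y: np.ndarray,
                    feature_sets: list[str] | None = None,
                    lag_window=(-0.4, 0.4), lambda_grid=DEFAULT_LAMBDA_GRID,
                    n_splits: int = 5, seed: int = 0,
                    _reuse: tuple | None = None) -> dict:
    """Unique dR^2 per feature set: full R^2 minus the drop-one R^2.

    The same folds serve the full and every reduced model.  Returns a dict
    with ``full_r2``, ``fold_r`` and ``dr2`` (set name -> per-electrode).
    """
    if feature_sets is None:
        feature_sets = [n for n in features.order if n in features.blocks]
    unknown = [s for s in feature_sets if s not in features.blocks]
    if unknown:
        raise ValueError(f"unknown feature sets {unknown}")
    if len(features.blocks) < 2:
        raise ValueError("unique variance needs >= 2 feature sets")
    if _reuse is not None:
        cache, folds, colmap = _reuse
    else:
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] != features.n_times:
            Y = Y.T
        D, colmap, _ = build_design(features, lag_window)
        folds = make_folds(D.shape[0], n_splits, seed)
        cache = _GramCache(D, Y, folds)
    full = _ridge_cv_model(cache, folds, _columns_of(colmap, None), lambda_grid)
    dr2 = {}
    for s in feature_sets:
        red = _ridge_cv_model(cache, folds, _columns_of(colmap, s), lambda_grid)
        dr2[s] = full["r2"] - red["r2"]
    return {"full_r2": full["r2"], "fold_r": full["fold_r"], "dr2": dr2}


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


def shuffle_features_between_syllables(features: FeatureMatrix,
                                       events: pd.DataFrame,
                                       rng: np.random.Generator) -> FeatureMatrix:
    """Reassign whole-syllable feature trajectories across syllable tokens.

    Each syllable span (acoustic onset to offset) receives the trajectory of
    a randomly chosen other syllable, truncated or zero-padded to its own
    duration; silence between syllables is untouched.  All blocks are
    shuffled jointly, preserving within-syllable feature covariation.
    """
    rate = features.rate
    spans = [(int(round((row["acoustic_onset"] - features.start_time) * rate)),
              int(round((row["offset"] - features.start_time) * rate)))
             for _, row in events.iterrows()]
    perm = rng.permutation(len(spans))
    new_blocks = {}
    for name, b in features.blocks.items():
        b2 = b.copy()
        for (i0, i1), src in zip(spans, perm):
            j0, j1 = spans[src]
            m = min(i1 - i0, j1 - j0)
            b2[i0:i1] = 0.0
            b2[i0:i0 + m] = b[j0:j0 + m]
        new_blocks[name] = b2
    return FeatureMatrix(blocks=new_blocks, start_time=features.start_time,
                         rate=features.rate, order=features.order)


def permutation_null(features: FeatureMatrix, Y: np.ndarray, events: pd.DataFrame,
                     feature_sets: list[str] | None = None, n_perm: int = 200,
                     alpha: float = 0.005, lag_window=(-0.4, 0.4),
                     lambda_grid=DEFAULT_LAMBDA_GRID, n_splits: int = 5,
                     seed: int = 0) -> dict:
    """Permutation significance of unique dR^2 per feature set.

    p = (1 + #{null >= observed}) / (n_perm + 1), one-sided.  Also returns
    the observed dR^2 and significance flags at ``alpha``.
    """
    if len(events) < 10:
        raise ValueError("permutation test needs >= 10 syllables")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != features.n_times:
        Y = Y.T
    if feature_sets is None:
        feature_sets = [n for n in features.order if n in features.blocks]
    obs = unique_variance(features, Y, feature_sets, lag_window, lambda_grid,
                          n_splits, seed)
    rng = np.random.default_rng(seed)
    exceed = {s: np.zeros(Y.shape[1]) for s in feature_sets}
    for _ in range(n_perm):
        shuffled = shuffle_features_between_syllables(features, events, rng)
        null = unique_variance(shuffled, Y, feature_sets, lag_window,
                               lambda_grid, n_splits, seed)
        for s in feature_sets:
            exceed[s] += (null["dr2"][s] >= obs["dr2"][s]).astype(float)
    p = {s: (1.0 + exceed[s]) / (n_perm + 1.0) for s in feature_sets}
    return {"p": p, "observed": obs, "significant":
            {s: p[s] < alpha for s in feature_sets}}


# ---------------------------------------------------------------------------
# Electrode-level correlation analyses
# ---------------------------------------------------------------------------


def encode_vs_discriminate_results(encoding: "EncodingResult", selection,
                                   x_set: str = "tone_command",
                                   alpha: float = 0.005) -> dict:
    """Result-object convenience wrapper over :func:`encode_vs_discriminate`.

    x = unique dR^2 of ``x_set``, y = each electrode's max F statistic;
    electrodes enter if their permutation p for ``x_set`` is below ``alpha``
    or they are tone-discriminant.
    """
    if list(encoding.electrode_ids) != list(selection.electrode_ids):
        raise ValueError("encoding and selection electrode ids must align")
    sig_enc = encoding.perm_p[x_set] < alpha if x_set in encoding.perm_p \
        else np.zeros(len(encoding.electrode_ids), bool)
    return encode_vs_discriminate(encoding.unique_dr2[x_set],
                                  selection.F_series.max(axis=1),
                                  sig_enc, selection.discriminant)


def encode_vs_discriminate(dr2: np.ndarray, max_f: np.ndarray,
                           significant_encoding: np.ndarray,
                           significant_discriminant: np.ndarray) -> dict:
    """Pearson correlation of unique dR^2 vs max F over significant electrodes.

    The sample is the union of electrodes significant on either axis.
    """
    keep = np.asarray(significant_encoding, bool) | np.asarray(significant_discriminant, bool)
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"only {n} qualifying electrodes; >= 3 required")
    r, p = stats.pearsonr(np.asarray(dr2)[keep], np.asarray(max_f)[keep])
    return {"r": float(r), "p": float(p), "n": n}


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher z test for the difference of two independent correlations."""
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
        if n <= 3:
            raise ValueError("need n > 3 per sample")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
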
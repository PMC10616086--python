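"""Sliding-window pairwise tone decoding from population high-gamma.

For each 50 ms window (5 samples at 100 Hz) sliding over vowel-aligned
epochs, each of the C(4,2) = 6 tone pairs is classified from the
concatenated (electrodes x samples) activity with L2-penalised logistic
regression under nested cross-validation: stratified 5-fold outer CV
estimates accuracy, and a stratified 10-fold inner CV on each training set
selects the penalty (ties broken toward stronger regularisation).  Folds
are grouped by cue so the three repetitions of one cue never straddle a
train/test boundary.  The decoding timecourse is the unweighted mean of
the six pairwise accuracies per window; chance is 0.5 by class balance.

Single-dataset significance uses label permutations per window (the
across-subject t-test variant is available for multi-dataset input).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .signal_preproc import Epochs

__all__ = ["DecodingTimecourse", "sliding_windows", "pairwise_decode",
           "decode_timecourse", "PairwiseToneDecoder", "ttest_across_datasets"]

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 3, 7))
TONE_PAIRS = tuple(combinations((1, 2, 3, 4), 2))


@dataclass
class DecodingTimecourse:
    window_centers: np.ndarray
    pair_accuracies: np.ndarray      # 6 x n_windows
    mean_accuracy: np.ndarray        # n_windows
    significant: np.ndarray | None   # per window (may be None if not tested)
    perm_p: np.ndarray | None
    peak_window: int
    peak_weights: np.ndarray | None  # per electrode, mean |weight| at peak
    null_mean_accuracy: np.ndarray | None = None  # mean permutation accuracy

    def to_frame(self) -> pd.DataFrame:
        d = {"window_center_s": self.window_centers}
        for k, pair in enumerate(TONE_PAIRS):
            d[f"acc_pair_{pair[0]}{pair[1]}"] = self.pair_accuracies[k]
        d["mean_acc"] = self.mean_accuracy
        if self.significant is not None:
            d["significant"] = self.significant.astype(int)
            d["perm_p"] = self.perm_p
        return pd.DataFrame(d)


def sliding_windows(time_axis: np.ndarray, length: float = 0.05,
                    step: float = 0.01) -> list[tuple[int, float]]:
    """Maximal list of fully contained (start_index, center_time) windows."""
    time_axis = np.asarray(time_axis, dtype=float)
    rate = 1.0 / np.median(np.diff(time_axis))
    n_len = int(round(length * rate))
    n_step = int(round(step * rate))
    if not (np.isclose(length * rate, n_len) and np.isclose(step * rate, n_step)):
        raise ValueError("window length and step must be multiples of the sample period")
    if n_len > time_axis.size:
        raise ValueError("window longer than the epoch time axis")
    if n_len < 1 or n_step < 1:
        raise ValueError("window length and step must be at least one sample")
    starts = range(0, time_axis.size - n_len + 1, n_step)
    return [(s, float(time_axis[s:s + n_len].mean())) for s in starts]


def _standardize(train: np.ndarray, *others: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return tuple((x - mu) / sd for x in (train, *others))


def _outer_folds(y: np.ndarray, groups: np.ndarray | None, k: int, seed: int):
    """Stratified outer folds that never split a cue across folds.

    Cues are label-pure (all repetitions of a cue share one tone), so
    grouped folds can be stratified exactly by folding over the cues
    themselves; heterogeneous groups fall back to StratifiedGroupKFold.
    """
    if groups is None:
        k = min(k, int(np.bincount(y).min()))
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(cv.split(np.zeros_like(y), y))
    ug, first = np.unique(groups, return_index=True)
    if len({(g, lab) for g, lab in zip(groups, y)}) == ug.size:  # label-pure
        # cap folds at the scarcest class's cue count
        k = min(k, int(np.bincount(y[first]).min()))
        if k < 2:
            raise ValueError("need at least 2 cues per class for grouped CV")
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = []
        for tr_g, te_g in cv.split(np.zeros(ug.size), y[first]):
            tr = np.flatnonzero(np.isin(groups, ug[tr_g]))
            te = np.flatnonzero(np.isin(groups, ug[te_g]))
            folds.append((tr, te))
        return folds
    cv = StratifiedGroupKFold(n_splits=min(k, ug.size), shuffle=True,
                              random_state=seed)
    return list(cv.split(np.zeros_like(y), y, groups))


def _inner_select_lambda(Xtr: np.ndarray, ytr: np.ndarray, lambda_grid,
                         inner_k: int, seed: int) -> float:
    """Pick the penalty by stratified inner CV; ties -> larger lambda."""
    inner_k = min(inner_k, np.bincount(ytr).min())
    lambdas = np.sort(np.asarray(list(lambda_grid), dtype=float))
    if inner_k < 2:
        return float(lambdas[len(lambdas) // 2])
    cv = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    splits = list(cv.split(Xtr, ytr))
    acc = np.zeros(lambdas.size)
    for tr, va in splits:
        Xa, Xb = _standardize(Xtr[tr], Xtr[va])
        for li, lam in enumerate(lambdas):
            clf = LogisticRegression(C=1.0 / lam, solver="liblinear",
                                     random_state=0)
            clf.fit(Xa, ytr[tr])
            acc[li] += clf.score(Xb, ytr[va])
    # iterate ascending with >= so ties keep the strongest penalty
    best, best_acc = lambdas[0], -np.inf
    for lam, a in zip(lambdas, acc):
        if a >= best_acc - 1e-12:
            best, best_acc = lam, max(best_acc, a)
    return float(best)


def pairwise_decode(epochs: Epochs, pair: tuple[int, int],
                    window: tuple[int, int] | None = None, outer_k: int = 5,
                    inner_k: int = 10, lambda_grid=DEFAULT_LAMBDA_GRID,
                    seed: int = 0, return_details: bool = False):
    """Nested-CV accuracy for one tone pair in one sliding window.

    ``window`` is (start_index, n_samples) into the epoch time axis; None
    uses the whole axis.  Features are the per-trial concatenation of
    (electrodes x window samples), standardised within each outer training
    fold.
    """
    labels = np.asarray(epochs.labels)
    sel = np.isin(labels, pair)
    for tone in pair:
        if (labels == tone).sum() < outer_k:
            raise ValueError(f"tone {tone} has fewer than {outer_k} trials")
    data = epochs.data[sel]
    if window is not None:
        s, n = window
        data = data[:, :, s:s + n]
    X = data.reshape(data.shape[0], -1)
    y = (labels[sel] == pair[1]).astype(int)
    groups = epochs.groups[sel] if epochs.groups is not None else None

    folds = _outer_folds(y, groups, outer_k, seed)
    accs, details = [], []
    for fi, (tr, te) in enumerate(folds):
        lam = _inner_select_lambda(X[tr], y[tr], lambda_grid, inner_k,
                                   seed + 17 * fi)
        Xa, Xb = _standardize(X[tr], X[te])
        clf = LogisticRegression(C=1.0 / lam, solver="liblinear",
                                 random_state=0)
        clf.fit(Xa, y[tr])
        accs.append(clf.score(Xb, y[te]))
        if return_details:
            details.append({"lambda": lam, "train": tr, "test": te,
                            "weights": clf.coef_[0].copy()})
    acc = float(np.mean(accs))
    return (acc, details) if return_details else acc


def _null_accuracy(X, y, folds, lambdas, rng) -> float:
    """One label-permutation accuracy, reusing the per-fold chosen penalty."""
    yp = rng.permutation(y)
    accs = []
    for (tr, te), lam in zip(folds, lambdas):
        Xa, Xb = _standardize(X[tr], X[te])
        clf = LogisticRegression(C=1.0 / lam, solver="liblinear",
                                 random_state=0)
        clf.fit(Xa, yp[tr])
        accs.append(clf.score(Xb, yp[te]))
    return float(np.mean(accs))


def decode_timecourse(epochs: Epochs, length: float = 0.05, step: float = 0.01,
                      outer_k: int = 5, inner_k: int = 10,
                      lambda_grid=DEFAULT_LAMBDA_GRID, seed: int = 0,
                      significance: str | None = None, n_perm: int = 500,
                      alpha: float = 0.05) -> DecodingTimecourse:
    """Mean pairwise accuracy vs time, optionally with permutation tests.

    ``significance='permutation'`` permutes labels per window (re-using the
    regularisation selected on the observed labels) and Bonferroni-corrects
    p over the number of windows tested.
    """
    rate = 1.0 / np.median(np.diff(epochs.time_axis))
    windows = sliding_windows(epochs.time_axis, length, step)
    n_len = int(round(length * rate))
    n_w = len(windows)
    pair_acc = np.zeros((len(TONE_PAIRS), n_w))
    perm_means = np.zeros((n_perm, n_w)) if significance == "permutation" else None
    peak_weight_acc: dict[int, np.ndarray] = {}

    labels = np.asarray(epochs.labels)
    for pi, pair in enumerate(TONE_PAIRS):
        sel = np.isin(labels, pair)
        groups = epochs.groups[sel] if epochs.groups is not None else None
        y = (labels[sel] == pair[1]).astype(int)
        folds = _outer_folds(y, groups, outer_k, seed)
        for wi, (s, _) in enumerate(windows):
            X = epochs.data[sel][:, :, s:s + n_len].reshape(sel.sum(), -1)
            accs, lams, wsum = [], [], 0.0
            for fi, (tr, te) in enumerate(folds):
                lam = _inner_select_lambda(X[tr], y[tr], lambda_grid, inner_k,
                                           seed + 17 * fi)
                Xa, Xb = _standardize(X[tr], X[te])
                clf = LogisticRegression(C=1.0 / lam,
                                         solver="liblinear", random_state=0)
                clf.fit(Xa, y[tr])
                accs.append(clf.score(Xb, y[te]))
                lams.append(lam)
                wsum = wsum + np.abs(clf.coef_[0])
            pair_acc[pi, wi] = np.mean(accs)
            peak_weight_acc.setdefault(wi, np.zeros(X.shape[1]))
            peak_weight_acc[wi] += wsum / len(folds) / len(TONE_PAIRS)
            if significance == "permutation":
                rng = np.random.default_rng(seed + 1000 * wi + 13 * pi)
                for b in range(n_perm):
                    perm_means[b, wi] += _null_accuracy(X, y, folds, lams, rng) \
                        / len(TONE_PAIRS)

    mean_acc = pair_acc.mean(axis=0)
    sig = p = null_mean = None
    if significance == "permutation":
        p = (1.0 + (perm_means >= mean_acc[None, :]).sum(axis=0)) / (n_perm + 1.0)
        sig = p < alpha / n_w
        null_mean = perm_means.mean(axis=0)
    peak = int(np.argmax(mean_acc))
    n_elec = len(epochs.electrode_ids)
    pw = peak_weight_acc[peak].reshape(n_elec, n_len).mean(axis=1)
    return DecodingTimecourse(
        window_centers=np.array([c for _, c in windows]),
        pair_accuracies=pair_acc, mean_accuracy=mean_acc,
        significant=sig, perm_p=p, peak_window=peak, peak_weights=pw,
        null_mean_accuracy=null_mean)


def ttest_across_datasets(accuracies: np.ndarray, chance: float = 0.5,
                          alpha: float = 0.05) -> dict:
    """Multi-dataset significance: two-sided t-test per window vs chance,
    Bonferroni corrected over windows.  ``accuracies`` is datasets x windows."""
    acc = np.atleast_2d(np.asarray(accuracies, dtype=float))
    if acc.shape[0] < 2:
        raise ValueError("t-test mode needs >= 2 datasets")
    t, p = stats.ttest_1samp(acc, chance, axis=0)
    return {"t": t, "p": p, "significant": p < alpha / acc.shape[1]}


class PairwiseToneDecoder:
    """Estimator wrapper: fit(Epochs) -> timecourse_ (DecodingTimecourse)."""

    def __init__(self, window_length: float = 0.05, step: float = 0.01,
                 outer_k: int = 5, inner_k: int = 10,
                 lambda_grid=DEFAULT_LAMBDA_GRID, seed: int = 0,
                 significance: str | None = None, n_perm: int = 500,
                 alpha: float = 0.05):
        self.window_length = window_length
        self.step = step
        self.outer_k = outer_k
        self.inner_k = inner_k
        self.lambda_grid = lambda_grid
        self.seed = seed
        self.significance = significance
        self.n_perm = n_perm
        self.alpha = alpha

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("window_length", "step", "outer_k", "inner_k", "lambda_grid",
                 "seed", "significance", "n_perm", "alpha")}

    def set_params(self, **p):
        for k, v in p.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, epochs: Epochs, y=None):
        self.timecourse_ = decode_timecourse(
            epochs, self.window_length, self.step, self.outer_k, self.inner_k,
            self.lambda_grid, self.seed, self.significance, self.n_perm,
            self.alpha)
        self.peak_accuracy_ = float(self.timecourse_.mean_accuracy.max())
        return self
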
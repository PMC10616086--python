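"""Speech features for the encoding models and the tone-space PCA.

Feature sets, all on the shared 100 Hz time base:

============== ===== ==========================================================
block           dim   definition
============== ===== ==========================================================
intensity        1   sound intensity, z-scored within each recording block
pitch_height    10   one-hot binned ln F0 (optionally speaker-normalised)
pitch_change    10   one-hot binned first difference of ln F0
binary_pitch     1   1 on voiced frames, 0 elsewhere
syllable_onset   1   impulse at each acoustic onset
articulator      1   1 during the consonant span (acoustic to vowel onset)
tone_command     1   signed Fujisaki tone-command amplitude A(t)
tone_category    4   one-hot lexical tone over the trial's voiced span
============== ===== ==========================================================

Pitch one-hot bins are equal-width between the 2.5th and 97.5th percentile
of the finite values; out-of-range values land in the extreme bins and
unvoiced frames produce all-zero rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .fujisaki import FujisakiCommandSet, command_track
from .io_formats import Dataset, SampledTrack

__all__ = [
    "FeatureMatrix",
    "pitch_height",
    "pitch_change",
    "binary_pitch",
    "binned_onehot",
    "make_features",
    "warp_contours",
    "tone_pca",
    "ToneContourPCA",
]

logger = logging.getLogger(__name__)

BLOCK_ORDER = ["intensity", "pitch_height", "pitch_change", "binary_pitch",
               "syllable_onset", "articulator", "tone_command", "tone_category"]
BLOCK_DIMS = {"intensity": 1, "pitch_height": 10, "pitch_change": 10,
              "binary_pitch": 1, "syllable_onset": 1, "articulator": 1,
              "tone_command": 1, "tone_category": 4}


@dataclass
class FeatureMatrix:
    """Named feature blocks sharing one time axis."""

    blocks: dict[str, np.ndarray]
    start_time: float = 0.0
    rate: float = 100.0
    order: list[str] = field(default_factory=lambda: list(BLOCK_ORDER))

    def __post_init__(self) -> None:
        lengths = {name: b.shape[0] for name, b in self.blocks.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"feature blocks disagree on time length: {lengths}")

    @property
    def n_times(self) -> int:
        return next(iter(self.blocks.values())).shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_times) / self.rate

    def stacked(self, names: list[str] | None = None
                ) -> tuple[np.ndarray, list[tuple[str, int]]]:
        """Horizontally stacked matrix plus a (block, dim) column map."""
        names = names or [n for n in self.order if n in self.blocks]
        mats, colmap = [], []
        for n in names:
            b = self.blocks[n]
            b = b[:, None] if b.ndim == 1 else b
            mats.append(b)
            colmap += [(n, d) for d in range(b.shape[1])]
        return np.hstack(mats), colmap

    def dims(self) -> dict[str, int]:
        return {n: (1 if b.ndim == 1 else b.shape[1]) for n, b in self.blocks.items()}


# ---------------------------------------------------------------------------
# Elementary pitch features
# ---------------------------------------------------------------------------


def pitch_height(contour: SampledTrack) -> SampledTrack:
    """h(t) = ln F0(t) in ln-Hz; missing propagates."""
    v = contour.values
    voiced = np.isfinite(v)
    if np.any(v[voiced] <= 0):
        raise ValueError("voiced F0 values must be positive")
    out = np.full_like(v, np.nan)
    out[voiced] = np.log(v[voiced])
    return SampledTrack(out, contour.start_time, contour.rate)


def pitch_change(height: SampledTrack) -> SampledTrack:
    """c(t) = h(t) - h(t-1); missing at the first sample and across any
    voicing boundary (differencing over a gap is undefined)."""
    h = height.values
    out = np.full_like(h, np.nan)
    out[1:] = h[1:] - h[:-1]
    return SampledTrack(out, height.start_time, height.rate)


def binary_pitch(contour: SampledTrack) -> SampledTrack:
    """1 on voiced frames, 0 on unvoiced."""
    return SampledTrack(np.isfinite(contour.values).astype(float),
                        contour.start_time, contour.rate)


def binned_onehot(values: np.ndarray, nbins: int = 10,
                  edges: tuple[float, float] | None = None) -> np.ndarray:
    """One-hot encoding into equal-width bins over the middle 95% range.

    Bin edges run from the 2.5th to the 97.5th percentile of the finite
    values; values below/above land in the bottom/top bin; non-finite rows
    are all zeros.
    """
    v = np.asarray(values, dtype=float).ravel()
    finite = np.isfinite(v)
    if edges is None:
        vals = v[finite]
        if np.unique(vals).size < nbins:
            raise ValueError(f"need >= {nbins} distinct finite values to bin")
        lo, hi = np.percentile(vals, [2.5, 97.5])
    else:
        lo, hi = edges
    if not hi > lo:
        raise ValueError("degenerate bin range: input is (near-)constant")
    rows = np.nonzero(finite)[0]
    idx = np.floor((v[rows] - lo) / (hi - lo) * nbins).astype(int)
    idx = np.clip(idx, 0, nbins - 1)
    out = np.zeros((v.size, nbins))
    out[rows, idx] = 1.0
    return out


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------


def _block_spans(dataset: Dataset) -> list[tuple[int, int, int]]:
    """(block_id, start_sample, stop_sample) partitioning the recording."""
    ev = dataset.events
    n = dataset.contour.n
    rate = dataset.rate
    blocks = sorted(ev["block_id"].unique())
    spans = []
    prev_stop = 0
    for k, b in enumerate(blocks):
        sub = ev[ev["block_id"] == b]
        if k == len(blocks) - 1:
            stop = n
        else:
            nxt = ev[ev["block_id"] == blocks[k + 1]]["acoustic_onset"].min()
            stop = int(round((sub["offset"].max() + nxt) / 2 * rate))
        spans.append((int(b), prev_stop, stop))
        prev_stop = stop
    return spans


def make_features(dataset: Dataset, fujisaki_fits: dict[int, FujisakiCommandSet],
                  nbins: int = 10, speaker_normalize: bool = True) -> FeatureMatrix:
    """Assemble every feature block over the full recording time axis.

    ``fujisaki_fits`` maps trial_id to its fitted command set in absolute
    recording time; a missing fit raises with the offending trials listed.
    """
    ev = dataset.events
    missing = [int(t) for t in ev["trial_id"] if int(t) not in fujisaki_fits]
    if missing:
        raise ValueError(f"missing Fujisaki fit for trials {missing}")
    rate = dataset.rate
    times = dataset.contour.times
    n = dataset.contour.n

    h = pitch_height(dataset.contour)
    hv = h.values.copy()
    if speaker_normalize:
        m = np.isfinite(hv)
        hv[m] = (hv[m] - hv[m].mean()) / hv[m].std()
    c = pitch_change(h)
    b = binary_pitch(dataset.contour)

    intensity = dataset.intensity.values.copy()
    for _, i0, i1 in _block_spans(dataset):
        seg = intensity[i0:i1]
        sd = seg.std()
        intensity[i0:i1] = (seg - seg.mean()) / (sd if sd > 1e-12 else 1.0)

    onset = np.zeros(n)
    onset[np.round(ev["acoustic_onset"].to_numpy() * rate).astype(int)] = 1.0

    articulator = np.zeros(n)
    tone_cat = np.zeros((n, 4))
    a_total = np.zeros(n)
    for _, row in ev.iterrows():
        i0 = int(round(row["acoustic_onset"] * rate))
        iv = int(round(row["vowel_onset"] * rate))
        i1 = int(round(row["offset"] * rate))
        articulator[i0:iv] = 1.0
        tone_cat[i0:i1, int(row["tone"]) - 1] = b.values[i0:i1]
        a_total += command_track(fujisaki_fits[int(row["trial_id"])], times)

    blocks = {
        "intensity": intensity[:, None],
        "pitch_height": binned_onehot(hv, nbins),
        "pitch_change": binned_onehot(c.values, nbins),
        "binary_pitch": b.values[:, None],
        "syllable_onset": onset[:, None],
        "articulator": articulator[:, None],
        "tone_command": a_total[:, None],
        "tone_category": tone_cat,
    }
    return FeatureMatrix(blocks=blocks, start_time=dataset.contour.start_time,
                         rate=rate)


# ---------------------------------------------------------------------------
# Tone-space PCA
# ---------------------------------------------------------------------------


def warp_contours(contours: list[SampledTrack], n_points: int = 40) -> np.ndarray:
    """Proportionally time-warp each contour's voiced span to ``n_points``.

    Interior unvoiced gaps are linearly interpolated; contours with fewer
    than two voiced samples are skipped with a log entry.
    """
    rows = []
    for k, ct in enumerate(contours):
        v = ct.values
        finite = np.flatnonzero(np.isfinite(v))
        if finite.size < 2:
            logger.warning("warp_contours: contour %d has <2 voiced samples; skipped", k)
            continue
        seg = v[finite[0]:finite[-1] + 1]
        x = np.arange(seg.size, dtype=float)
        m = np.isfinite(seg)
        seg = np.interp(x, x[m], seg[m])
        target = np.linspace(0, seg.size - 1, n_points)
        rows.append(np.interp(target, x, seg))
    if not rows:
        raise ValueError("no contour had >= 2 voiced samples")
    return np.vstack(rows)


class ToneContourPCA(BaseEstimator, TransformerMixin):
    """PCA of time-warped tone contours, X = L W^T + mean.

    ``n_components_`` is the minimal number of components whose cumulative
    explained-variance ratio reaches ``var_threshold`` (0.95 by default).
    The matrix is column-centered (the mean contour is removed) before the
    decomposition, so reconstruction from all components is exact.
    """

    def __init__(self, var_threshold: float = 0.95):
        self.var_threshold = var_threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need an n x p matrix with n >= 2 rows")
        if not np.isfinite(X).all():
            raise ValueError("PCA input must be finite")
        if np.allclose(X, X[0]):
            raise ValueError("rank-0 input: all contours identical")
        k_full = min(X.shape)
        self._pca = PCA(n_components=k_full, svd_solver="full")
        self.scores_ = self._pca.fit_transform(X)
        self.weights_ = self._pca.components_.T  # p x k, column-orthonormal
        self.mean_ = self._pca.mean_
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        cum = np.cumsum(self.explained_variance_ratio_)
        self.n_components_ = int(np.searchsorted(cum, self.var_threshold) + 1)
        return self

    def transform(self, X):
        return self._pca.transform(np.asarray(X, dtype=float))

    def inverse_transform(self, L):
        return self._pca.inverse_transform(np.asarray(L, dtype=float))


def tone_pca(matrix: np.ndarray, var_threshold: float = 0.95
             ) -> tuple[np.ndarray, np.ndarray, int]:
    """Scores L, weights W and the component count reaching 95% variance."""
    est = ToneContourPCA(var_threshold=var_threshold).fit(matrix)
    return est.scores_, est.weights_, est.n_components_


def write_features(features: FeatureMatrix, path) -> None:
    """Serialise a FeatureMatrix to HDF5 with one group per block."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["start_time"] = features.start_time
        f.attrs["rate"] = features.rate
        f.attrs["order"] = ",".join(features.order)
        g = f.create_group("blocks")
        for name, b in features.blocks.items():
            g.create_dataset(name, data=b)


def read_features(path) -> FeatureMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        blocks = {name: f["blocks"][name][()] for name in f["blocks"]}
        return FeatureMatrix(blocks=blocks, start_time=float(f.attrs["start_time"]),
                             rate=float(f.attrs["rate"]),
                             order=str(f.attrs["order"]).split(","))
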
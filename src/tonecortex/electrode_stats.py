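"""Electrode selection: speech responsiveness and tone discrimination.

Two bespoke procedures:

* **Speech responsiveness** — the electrode's mean high-gamma timecourse
  around real speech onsets (window -300..+100 ms) is compared against a
  null built from 1000 random alignment times; the electrode is responsive
  if at least 100 ms (10 consecutive samples at 100 Hz) of the real mean
  falls outside the permutation mean +/- 5 SD.

* **Tone discrimination** — per-timepoint one-way ANOVA of high-gamma
  across the four tones over -300..+200 ms (50 timepoints), Bonferroni
  corrected for electrodes x timepoints, with the same 10-consecutive-
  significant-points rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SampledTrack
from .signal_preproc import Epochs

__all__ = ["SelectionResult", "speech_responsive", "tone_discriminant",
           "anova_f_series", "SpeechResponsiveSelector", "ToneDiscriminantSelector"]


@dataclass
class SelectionResult:
    """Per-electrode selection flags and statistics."""

    electrode_ids: list[str]
    responsive: np.ndarray | None = None
    responsive_margin: np.ndarray | None = None  # max |mean_real - mean_perm| / SD_perm
    discriminant: np.ndarray | None = None
    F_series: np.ndarray | None = None           # electrodes x timepoints
    n_consecutive_significant: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"electrode_id": self.electrode_ids}
        if self.responsive is not None:
            d["responsive"] = self.responsive.astype(int)
            d["margin"] = self.responsive_margin
        if self.discriminant is not None:
            d["discriminant"] = self.discriminant.astype(int)
            d["max_F"] = self.F_series.max(axis=1)
            d["n_consec"] = self.n_consecutive_significant
        return pd.DataFrame(d)


def _max_run(mask: np.ndarray) -> int:
    """Longest run of True along the last axis (1-D input)."""
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def _max_run_2d(mask: np.ndarray) -> np.ndarray:
    """Longest True run per row of a 2-D boolean array, vectorised."""
    n, t = mask.shape
    run = np.zeros(n, dtype=int)
    best = np.zeros(n, dtype=int)
    for j in range(t):
        run = np.where(mask[:, j], run + 1, 0)
        best = np.maximum(best, run)
    return best


# ---------------------------------------------------------------------------
# Speech responsiveness
# ---------------------------------------------------------------------------


def speech_responsive(track: SampledTrack | np.ndarray, onsets: np.ndarray,
                      n_perm: int = 1000, window: tuple[float, float] = (-0.3, 0.1),
                      sd_threshold: float = 5.0, n_consecutive: int = 10,
                      seed: int = 0, rate: float | None = None,
                      start_time: float | None = None,
                      exclusion_radius: float = 0.0) -> dict:
    """Permutation test for speech-locked responses on one or many electrodes.

    ``track`` may be a single SampledTrack or an (electrodes, samples)
    array (then ``rate``/``start_time`` are required).  Returns a dict with
    ``responsive`` flag(s), ``margin``, and the real/permutation statistics.
    Onsets must each be preceded by enough silence per the event table; that
    precondition is the caller's (it cannot be checked from the track alone).
    """
    if isinstance(track, SampledTrack):
        mat = track.values[None, :]
        rate = track.rate
        start_time = track.start_time
        squeeze = True
    else:
        mat = np.atleast_2d(np.asarray(track, dtype=float))
        if rate is None or start_time is None:
            raise ValueError("rate and start_time required for array input")
        squeeze = False

    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 10:
        raise ValueError(f"need >= 10 onsets, got {onsets.size}")
    t_min, t_max = window
    n_t = int(round((t_max - t_min) * rate))
    n_samples = mat.shape[1]
    pre = int(round(-t_min * rate))
    if n_samples <= n_t:
        raise ValueError("track too short for the analysis window")

    idx0 = np.round((onsets + t_min - start_time) * rate).astype(int)
    if idx0.min() < 0 or (idx0 + n_t).max() > n_samples:
        raise ValueError("onset window exceeds track extent")
    rel = np.arange(n_t)
    real = mat[:, idx0[:, None] + rel[None, :]]           # elec x onsets x time
    mean_real = real.mean(axis=1)

    rng = np.random.default_rng(seed)
    lo, hi = 0, n_samples - n_t
    perm0 = rng.integers(lo, hi, size=n_perm)
    if exclusion_radius > 0:
        r = int(round(exclusion_radius * rate))
        onset_idx = idx0 + pre
        for _ in range(20):  # resample draws that land near a real onset
            near = np.min(np.abs(perm0[:, None] + pre - onset_idx[None, :]), axis=1) < r
            if not near.any():
                break
            perm0[near] = rng.integers(lo, hi, size=near.sum())
    perm = mat[:, perm0[:, None] + rel[None, :]]          # elec x n_perm x time
    mean_perm = perm.mean(axis=1)
    sd_perm = perm.std(axis=1, ddof=0)

    dev = np.abs(mean_real - mean_perm)
    with np.errstate(divide="ignore", invalid="ignore"):
        margin = np.where(sd_perm > 0, dev / sd_perm, np.inf)
    outside = dev > sd_threshold * sd_perm
    runs = _max_run_2d(outside)
    flags = runs >= n_consecutive

    out = {"responsive": flags, "margin": margin.max(axis=1),
           "mean_real": mean_real, "mean_perm": mean_perm, "sd_perm": sd_perm,
           "n_consecutive": runs}
    if squeeze:
        out = {k: (v[0] if isinstance(v, np.ndarray) and v.shape[:1] == (1,) else v)
               for k, v in out.items()}
        out["responsive"] = bool(flags[0])
    return out


# ---------------------------------------------------------------------------
# Tone discrimination (per-timepoint one-way ANOVA)
# ---------------------------------------------------------------------------


def anova_f_series(data: np.ndarray, labels: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way ANOVA across label groups.

    ``data`` is (trials, electrodes, time); returns F and p arrays of shape
    (electrodes, time).  Works for any number of groups >= 2.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("ANOVA needs at least two groups")
    n_total = data.shape[0]
    grand = data.mean(axis=0)
    ssb = np.zeros(grand.shape)
    ssw = np.zeros(grand.shape)
    for g in groups:
        sub = data[labels == g]
        if sub.shape[0] < 2:
            raise ValueError(f"group {g} has fewer than 2 trials")
        m = sub.mean(axis=0)
        ssb += sub.shape[0] * (m - grand) ** 2
        ssw += ((sub - m) ** 2).sum(axis=0)
    df_b = groups.size - 1
    df_w = n_total - groups.size
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    f = np.where(np.isfinite(f), f, 0.0)
    p = stats.f.sf(f, df_b, df_w)
    return f, p


def tone_discriminant(epochs: Epochs, alpha: float = 0.05,
                      n_electrodes_total: int | None = None,
                      n_consecutive: int = 10,
                      require_four_tones: bool = True) -> SelectionResult:
    """ANOVA-based tone-discriminant electrode selection.

    Significance threshold is Bonferroni-corrected for the *total* number of
    electrodes in the recording times the number of timepoints, so running
    the test on a subset never silently relaxes the criterion —
    ``n_electrodes_total`` is therefore required when epochs are a subset.
    """
    labels = np.asarray(epochs.labels)
    if require_four_tones and set(np.unique(labels)) != {1, 2, 3, 4}:
        raise ValueError(f"expected all four tone labels, got {sorted(set(labels))}")
    if n_electrodes_total is None:
        n_electrodes_total = len(epochs.electrode_ids)
    f, p = anova_f_series(epochs.data, labels)
    n_times = epochs.data.shape[2]
    threshold = alpha / (n_electrodes_total * n_times)
    sig = p < threshold
    runs = _max_run_2d(sig)
    flags = runs >= n_consecutive
    return SelectionResult(electrode_ids=list(epochs.electrode_ids),
                           discriminant=flags, F_series=f,
                           n_consecutive_significant=runs)


# ---------------------------------------------------------------------------
# Estimator-style wrappers
# ---------------------------------------------------------------------------


class SpeechResponsiveSelector:
    """Estimator wrapper: fit((electrodes, samples), onsets) -> responsive_."""

    def __init__(self, n_perm: int = 1000, window: tuple[float, float] = (-0.3, 0.1),
                 sd_threshold: float = 5.0, n_consecutive: int = 10,
                 seed: int = 0, exclusion_radius: float = 0.0):
        self.n_perm = n_perm
        self.window = window
        self.sd_threshold = sd_threshold
        self.n_consecutive = n_consecutive
        self.seed = seed
        self.exclusion_radius = exclusion_radius

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in ("n_perm", "window", "sd_threshold",
                                              "n_consecutive", "seed",
                                              "exclusion_radius")}

    def set_params(self, **p):
        for k, v in p.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, onsets: np.ndarray, rate: float = 100.0,
            start_time: float = 0.0):
        res = speech_responsive(X, onsets, n_perm=self.n_perm, window=self.window,
                                sd_threshold=self.sd_threshold,
                                n_consecutive=self.n_consecutive, seed=self.seed,
                                rate=rate, start_time=start_time,
                                exclusion_radius=self.exclusion_radius)
        self.responsive_ = np.atleast_1d(res["responsive"])
        self.margin_ = np.atleast_1d(res["margin"])
        self.mean_real_ = np.atleast_2d(res["mean_real"])
        self.mean_perm_ = np.atleast_2d(res["mean_perm"])
        self.sd_perm_ = np.atleast_2d(res["sd_perm"])
        return self


class ToneDiscriminantSelector:
    """Estimator wrapper: fit(Epochs) -> discriminant_, F_series_."""

    def __init__(self, alpha: float = 0.05, n_electrodes_total: int | None = None,
                 n_consecutive: int = 10, require_four_tones: bool = True):
        self.alpha = alpha
        self.n_electrodes_total = n_electrodes_total
        self.n_consecutive = n_consecutive
        self.require_four_tones = require_four_tones

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in ("alpha", "n_electrodes_total",
                                              "n_consecutive", "require_four_tones")}

    def set_params(self, **p):
        for k, v in p.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, epochs: Epochs, y=None):
        res = tone_discriminant(epochs, alpha=self.alpha,
                                n_electrodes_total=self.n_electrodes_total,
                                n_consecutive=self.n_consecutive,
                                require_four_tones=self.require_four_tones)
        self.result_ = res
        self.discriminant_ = res.discriminant
        self.F_series_ = res.F_series
        return self
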
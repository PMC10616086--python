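"""Tone-command tuning curves and polarity classification.

The tuning curve of an electrode is its mean high-gamma as a function of
the binned tone-command amplitude A(t).  Commands are discretised into 12
bins uniformly spanning the middle 99-percentile range of A over the whole
recording (per subject); bin edges are the empirical quantiles at levels
0.005 + 0.99*(i-1)/12, i = 1..13, so the outermost edges sit at the 0.5th
and 99.5th percentiles.  An OLS line y = a*x + b through (bin index, bin
mean) determines the polarity: positive slopes mark electrodes driven by
pitch-raising commands, negative slopes by pitch-lowering commands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TuningCurve", "quantile_bins", "tuning_curve",
           "classify_population", "ToneCommandTuning"]

N_BINS = 12


@dataclass
class TuningCurve:
    bin_edges: np.ndarray    # 13 quantile edges, command units
    bin_means: np.ndarray    # 12 values, z-units (NaN for empty bins)
    bin_sds: np.ndarray
    bin_counts: np.ndarray
    slope: float
    intercept: float

    @property
    def polarity(self) -> str:
        return "positive" if self.slope >= 0 else "negative"


def quantile_bins(command: np.ndarray, n_bins: int = N_BINS,
                  strict_compat: bool = False) -> np.ndarray:
    """13 quantile edges spanning the middle 99% of the command distribution.

    Quantile levels are 0.005 + 0.99*(i-1)/n for i = 1..n+1.  With
    ``strict_compat`` the levels are (i-1)/n + 0.005 clamped at 1.0 — the
    literal textbook form, whose top level overshoots 1 — kept only for
    comparison.
    """
    v = np.asarray(command, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 100:
        raise ValueError(f"need >= 100 finite command samples, got {v.size}")
    if np.ptp(v) < 1e-12:
        raise ValueError("constant command track: bins are degenerate")
    i = np.arange(n_bins + 1)
    if strict_compat:
        levels = np.minimum(i / n_bins + 0.005, 1.0)
    else:
        levels = 0.005 + 0.99 * i / n_bins
    return np.quantile(v, levels)


def tuning_curve(command: np.ndarray, hga: np.ndarray,
                 edges: np.ndarray | None = None,
                 mask: np.ndarray | None = None,
                 max_empty_bins: int = 6) -> TuningCurve:
    """Bin high-gamma by command amplitude and fit the polarity line.

    ``command`` and ``hga`` must be time-aligned; ``mask`` restricts the
    analysis (e.g. to voiced speech samples, where A(t) is defined).
    Samples outside the outermost edges are outside the middle 99% and are
    excluded; a value exactly on an interior edge goes to the higher bin.
    """
    a = np.asarray(command, dtype=float)
    h = np.asarray(hga, dtype=float)
    if a.shape != h.shape:
        raise ValueError("command and high-gamma tracks must be time-aligned")
    keep = np.isfinite(a) & np.isfinite(h)
    if mask is not None:
        keep &= np.asarray(mask, bool)
    a, h = a[keep], h[keep]
    if edges is None:
        edges = quantile_bins(a)
    edges = np.asarray(edges, dtype=float)
    n_bins = edges.size - 1

    inside = (a >= edges[0]) & (a <= edges[-1])
    a, h = a[inside], h[inside]
    idx = np.clip(np.searchsorted(edges, a, side="right") - 1, 0, n_bins - 1)

    means = np.full(n_bins, np.nan)
    sds = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            means[b] = h[sel].mean()
            sds[b] = h[sel].std(ddof=0)
    n_empty = int((counts == 0).sum())
    if n_empty > max_empty_bins:
        raise ValueError(f"{n_empty} empty tuning bins (> {max_empty_bins})")

    x = np.arange(1, n_bins + 1, dtype=float)
    ok = counts > 0
    slope, intercept = np.polyfit(x[ok], means[ok], 1)
    return TuningCurve(bin_edges=edges, bin_means=means, bin_sds=sds,
                       bin_counts=counts, slope=float(slope),
                       intercept=float(intercept))


def classify_population(curves: dict[str, TuningCurve],
                        significant: dict[str, bool]) -> dict:
    """Partition significant electrodes by tuning polarity."""
    pos = [e for e, c in curves.items() if significant.get(e, False)
           and c.polarity == "positive"]
    neg = [e for e, c in curves.items() if significant.get(e, False)
           and c.polarity == "negative"]
    table = pd.DataFrame({
        "electrode_id": pos + neg,
        "polarity": ["positive"] * len(pos) + ["negative"] * len(neg),
        "slope": [curves[e].slope for e in pos + neg],
    })
    return {"n_positive": len(pos), "n_negative": len(neg),
            "n_significant": len(pos) + len(neg),
            "positive": pos, "negative": neg, "table": table}


class ToneCommandTuning:
    """Estimator wrapper: fit(A(t), hga matrix) -> curves_, polarities_."""

    def __init__(self, n_bins: int = N_BINS, strict_compat: bool = False,
                 max_empty_bins: int = 6):
        self.n_bins = n_bins
        self.strict_compat = strict_compat
        self.max_empty_bins = max_empty_bins

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in ("n_bins", "strict_compat",
                                              "max_empty_bins")}

    def set_params(self, **p):
        for k, v in p.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, command: np.ndarray, H: np.ndarray,
            mask: np.ndarray | None = None,
            electrode_ids: list[str] | None = None):
        H = np.atleast_2d(np.asarray(H, dtype=float))
        if H.shape[1] != np.asarray(command).size:
            raise ValueError("H must be (electrodes, samples) aligned to command")
        ids = electrode_ids or [f"e{k:03d}" for k in range(H.shape[0])]
        base = np.asarray(command, dtype=float)
        sel = np.isfinite(base)
        if mask is not None:
            sel &= np.asarray(mask, bool)
        self.bin_edges_ = quantile_bins(base[sel], self.n_bins, self.strict_compat)
        self.curves_ = {eid: tuning_curve(base, H[k], self.bin_edges_, mask=mask,
                                          max_empty_bins=self.max_empty_bins)
                        for k, eid in enumerate(ids)}
        self.slopes_ = np.array([self.curves_[e].slope for e in ids])
        self.polarities_ = np.array([self.curves_[e].polarity for e in ids])
        self.electrode_ids_ = ids
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.electrode_ids_:
            c = self.curves_[e]
            rows.append({"electrode_id": e, "slope": c.slope,
                         "intercept": c.intercept, "polarity": c.polarity,
                         **{f"mean_{b + 1}": c.bin_means[b] for b in range(c.bin_means.size)}})
        return pd.DataFrame(rows)
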
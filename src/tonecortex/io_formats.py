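"""On-disk formats and core containers for the tone-production pipeline.

Everything downstream operates on uniformly sampled tracks at a single
pipeline rate (100 Hz by default): F0 contours in Hz with NaN on unvoiced
frames, z-scored high-gamma per electrode, and intensity.  Event tables
carry absolute times in recording coordinates (seconds); epoching converts
to event-relative time.

Readers and writers are lossless round trips at the stated tolerances.
Unvoiced gaps are never interpolated at the I/O layer — interpolation is an
explicit step of the Fujisaki inverse fit only — so the voicing pattern
survives into the binary-pitch feature.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = [
    "SampledTrack",
    "Dataset",
    "PipelineConfig",
    "ConfigError",
    "FormatError",
    "validate_events",
    "read_pitchtier",
    "write_pitchtier",
    "read_events",
    "write_events",
    "read_dataset",
    "write_dataset",
    "load_config",
    "derive_seed",
]

PIPELINE_RATE = 100.0

EVENT_COLUMNS = [
    "trial_id",
    "syllable",
    "tone",
    "acoustic_onset",
    "vowel_onset",
    "offset",
    "block_id",
]


class FormatError(ValueError):
    """Malformed on-disk artifact."""


class ConfigError(ValueError):
    """Invalid or incomplete configuration."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class SampledTrack:
    """A uniformly sampled time series.

    Sample ``k`` sits at ``start_time + k / rate`` seconds.  Missing values
    (unvoiced F0 frames) are NaN; neural tracks never contain NaN.
    """

    values: np.ndarray
    start_time: float = 0.0
    rate: float = PIPELINE_RATE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("SampledTrack values must be 1-D")
        if self.values.size < 1:
            raise ValueError("SampledTrack must hold at least one sample")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        self.start_time = float(self.start_time)
        self.rate = float(self.rate)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + (self.n - 1) / self.rate

    def index_of(self, t: float) -> int:
        """Index of the sample nearest to absolute time ``t``."""
        return int(round((t - self.start_time) * self.rate))

    def voiced_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def copy(self) -> "SampledTrack":
        return SampledTrack(self.values.copy(), self.start_time, self.rate)


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial-event table and normalise dtypes.

    Required columns: trial_id, syllable, tone, acoustic_onset, vowel_onset,
    offset, block_id.  An optional ``cue_id`` column groups the repetitions
    of a single cue (words are produced three times per cue) and is used to
    keep cross-validation folds leak-free.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"event table missing columns: {missing}")
    ev = events.copy()
    for col in ("trial_id", "tone", "block_id"):
        ev[col] = ev[col].astype(int)
    for col in ("acoustic_onset", "vowel_onset", "offset"):
        ev[col] = ev[col].astype(float)
    if ev["trial_id"].duplicated().any():
        raise FormatError("trial_ids must be unique")
    if not ev["tone"].isin([1, 2, 3, 4]).all():
        raise FormatError("tone labels must be in {1,2,3,4}")
    bad = ~((ev["acoustic_onset"] <= ev["vowel_onset"]) & (ev["vowel_onset"] < ev["offset"]))
    if bad.any():
        raise FormatError(
            f"event ordering violated (acoustic_onset <= vowel_onset < offset) "
            f"for trials {ev.loc[bad, 'trial_id'].tolist()}"
        )
    return ev


@dataclass
class Dataset:
    """A complete recording: neural tracks, contour, intensity, events."""

    neural: dict[str, SampledTrack]
    contour: SampledTrack
    intensity: SampledTrack
    events: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = validate_events(self.events)
        rates = {t.rate for t in self.neural.values()}
        rates.add(self.contour.rate)
        rates.add(self.intensity.rate)
        if len(rates) != 1:
            raise ValueError(f"all tracks must share one rate, got {sorted(rates)}")
        tmin = min(t.start_time for t in self.all_tracks())
        tmax = max(t.end_time for t in self.all_tracks())
        ev = self.events
        if (ev["acoustic_onset"].min() < tmin) or (ev["offset"].max() > tmax):
            raise ValueError("event times fall outside track extents")

    def all_tracks(self):
        yield from self.neural.values()
        yield self.contour
        yield self.intensity

    @property
    def rate(self) -> float:
        return self.contour.rate

    def neural_matrix(self) -> tuple[list[str], np.ndarray]:
        """Electrode ids and an (electrodes, samples) matrix."""
        ids = list(self.neural.keys())
        return ids, np.stack([self.neural[i].values for i in ids])


# ---------------------------------------------------------------------------
# PitchTier
# ---------------------------------------------------------------------------


def _parse_pitchtier_text(text: str) -> tuple[float, float, np.ndarray, np.ndarray]:
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln]
    if len(lines) < 2 or "ooTextFile" not in lines[0] or "PitchTier" not in lines[1]:
        raise FormatError("not a Praat PitchTier file (bad header)")
    body = lines[2:]

    def num(token: str) -> float:
        # long-dialect lines look like "xmin = 0" or "number = 0.05"
        return float(token.split("=")[-1].strip())

    if any("=" in ln for ln in body[:3]):  # long dialect
        xmin = num(body[0])
        xmax = num(body[1])
        size = int(num(body[2]))
        ts, vs = [], []
        for ln in body[3:]:
            if "number" in ln:
                ts.append(num(ln))
            elif "value" in ln:
                vs.append(num(ln))
        if len(ts) != size or len(vs) != size:
            raise FormatError(f"PitchTier declares {size} points, found {len(ts)}/{len(vs)}")
    else:  # short dialect: xmin, xmax, size, then time/value pairs
        try:
            xmin = float(body[0])
            xmax = float(body[1])
            size = int(float(body[2]))
            rest = [float(x) for x in body[3:]]
        except ValueError as exc:
            raise FormatError(f"malformed short PitchTier: {exc}") from exc
        if len(rest) != 2 * size:
            raise FormatError(f"PitchTier declares {size} points, found {len(rest) // 2}")
        ts = rest[0::2]
        vs = rest[1::2]
    return xmin, xmax, np.asarray(ts, dtype=float), np.asarray(vs, dtype=float)


def _parse_tsv_points(path: Path) -> tuple[float, float, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("pitch TSV needs two columns (time, f0_hz)")
    ts = df.iloc[:, 0].to_numpy(dtype=float)
    vs = df.iloc[:, 1].to_numpy(dtype=float)
    keep = np.isfinite(vs)
    ts, vs = ts[keep], vs[keep]
    if ts.size == 0:
        raise FormatError("pitch TSV holds no voiced points")
    return float(ts.min()), float(ts.max()), ts, vs


def read_pitchtier(path: str | os.PathLike, rate: float = PIPELINE_RATE,
                   span: tuple[float, float] | None = None) -> SampledTrack:
    """Read a Praat PitchTier (short or long dialect) or 2-column TSV.

    Points are snapped to the nearest sample of a uniform grid at ``rate``;
    grid samples with no point become NaN (unvoiced).  No interpolation is
    performed across gaps.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("File type"):
        xmin, xmax, ts, vs = _parse_pitchtier_text(text)
    else:
        xmin, xmax, ts, vs = _parse_tsv_points(path)
    if ts.size > 1 and np.any(np.diff(ts) <= 0):
        raise FormatError("PitchTier point times must be strictly increasing")
    if span is not None:
        xmin, xmax = span
    n = int(round((xmax - xmin) * rate)) + 1
    values = np.full(max(n, 1), np.nan)
    if ts.size:
        idx = np.round((ts - xmin) * rate).astype(int)
        ok = (idx >= 0) & (idx < values.size)
        values[idx[ok]] = vs[ok]
    return SampledTrack(values, start_time=xmin, rate=rate)


def write_pitchtier(track: SampledTrack, path: str | os.PathLike,
                    dialect: str = "short") -> None:
    """Write the voiced samples of ``track`` as a Praat PitchTier."""
    path = Path(path)
    mask = track.voiced_mask()
    ts = track.times[mask]
    vs = track.values[mask]
    xmin = track.start_time
    xmax = track.end_time
    lines = ['File type = "ooTextFile"', 'Object class = "PitchTier"', ""]
    if dialect == "short":
        lines += [f"{xmin:.17g}", f"{xmax:.17g}", f"{ts.size}"]
        for t, v in zip(ts, vs):
            lines += [f"{t:.17g}", f"{v:.17g}"]
    elif dialect == "long":
        lines += [f"xmin = {xmin:.17g}", f"xmax = {xmax:.17g}",
                  f"points: size = {ts.size}"]
        for k, (t, v) in enumerate(zip(ts, vs), start=1):
            lines += [f"points [{k}]:", f"    number = {t:.17g}", f"    value = {v:.17g}"]
    else:
        raise ValueError(f"unknown PitchTier dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------


def read_events(path: str | os.PathLike) -> pd.DataFrame:
    return validate_events(pd.read_csv(path, sep="\t"))


def write_events(events: pd.DataFrame, path: str | os.PathLike) -> None:
    ev = validate_events(events)
    cols = EVENT_COLUMNS + [c for c in ev.columns if c not in EVENT_COLUMNS]
    ev[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Dataset HDF5 + manifest
# ---------------------------------------------------------------------------


def _write_track_tsv(track: SampledTrack, path: Path) -> None:
    df = pd.DataFrame({"time": track.times, "value": track.values})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="")


def _read_track_tsv(path: Path, rate: float) -> SampledTrack:
    df = pd.read_csv(path, sep="\t")
    return SampledTrack(df["value"].to_numpy(dtype=float),
                        start_time=float(df["time"].iloc[0]), rate=rate)


def write_dataset(dataset: Dataset, path: str | os.PathLike) -> dict:
    """Write a dataset directory atomically; returns the manifest.

    Layout: ``neural.h5`` (electrodes x samples), ``events.tsv``,
    ``contour.pitchtier``, ``intensity.tsv``, ``manifest.json``.  Files are
    staged in a temporary sibling directory and renamed into place so a
    partial write never leaves a manifest behind.
    """
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=out.name + ".tmp.", dir=out.parent))
    try:
        ids, mat = dataset.neural_matrix()
        with h5py.File(tmp / "neural.h5", "w") as f:
            d = f.create_dataset("high_gamma", data=mat)
            d.attrs["rate"] = dataset.rate
            d.attrs["start_time"] = dataset.neural[ids[0]].start_time if ids else 0.0
            f.create_dataset("electrode_ids", data=np.array(ids, dtype="S"))
        write_events(dataset.events, tmp / "events.tsv")
        write_pitchtier(dataset.contour, tmp / "contour.pitchtier")
        _write_track_tsv(dataset.intensity, tmp / "intensity.tsv")
        manifest = {
            "format": "tonecortex-dataset",
            "version": 1,
            "rate": dataset.rate,
            "n_electrodes": len(ids),
            "n_trials": int(len(dataset.events)),
            "contour_start": dataset.contour.start_time,
            "intensity_start": dataset.intensity.start_time,
            "files": ["neural.h5", "events.tsv", "contour.pitchtier", "intensity.tsv"],
            "metadata": _jsonable(dataset.metadata),
        }
        with open(tmp / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, sort_keys=True)
        if out.exists():
            raise FileExistsError(f"refusing to overwrite existing dataset at {out}")
        os.rename(tmp, out)
    finally:
        if tmp.exists():
            import shutil

            shutil.rmtree(tmp, ignore_errors=True)
    return manifest


def read_dataset(path: str | os.PathLike) -> Dataset:
    root = Path(path)
    with open(root / "manifest.json") as f:
        manifest = json.load(f)
    rate = float(manifest["rate"])
    with h5py.File(root / "neural.h5", "r") as f:
        mat = f["high_gamma"][()]
        start = float(f["high_gamma"].attrs["start_time"])
        ids = [s.decode() for s in f["electrode_ids"][()]]
    neural = {i: SampledTrack(mat[k], start_time=start, rate=rate) for k, i in enumerate(ids)}
    contour = read_pitchtier(root / "contour.pitchtier", rate=rate)
    contour.start_time = float(manifest.get("contour_start", contour.start_time))
    intensity = _read_track_tsv(root / "intensity.tsv", rate)
    events = read_events(root / "events.tsv")
    return Dataset(neural=neural, contour=contour, intensity=intensity,
                   events=events, metadata=manifest.get("metadata", {}))


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FujisakiSection(_Section):
    alpha: float = 3.0      # phrase mechanism natural frequency, 1/s
    beta: float = 20.0      # tone mechanism natural frequency, 1/s
    gamma: float = 0.9      # ceiling of the tone step response
    n_starts: int = 8       # random multistarts in the inverse fit
    phrase_mode: str = "off"


class FeaturesSection(_Section):
    nbins_pitch: int = 10
    speaker_normalize: bool = True


class SelectionSection(_Section):
    n_perm: int = 1000
    window: tuple[float, float] = (-0.3, 0.1)
    sd_threshold: float = 5.0
    n_consecutive: int = 10
    anova_alpha: float = 0.05
    anova_window: tuple[float, float] = (-0.3, 0.2)


class EncodingSection(_Section):
    lag_min: float = -0.4
    lag_max: float = 0.4
    lambda_grid: list[float] = Field(
        default_factory=lambda: list(np.logspace(-2, 5, 8)))
    n_splits: int = 5
    n_perm: int = 200
    alpha: float = 0.005


class TuningSection(_Section):
    n_bins: int = 12
    strict_compat: bool = False


class DecodingSection(_Section):
    window_length: float = 0.05
    step: float = 0.01
    outer_k: int = 5
    inner_k: int = 10
    lambda_grid: list[float] = Field(
        default_factory=lambda: list(np.logspace(-3, 3, 7)))
    n_perm: int = 500
    alpha: float = 0.05
    epoch_window: tuple[float, float] = (-0.3, 0.2)


class SyntheticSection(_Section):
    n_trials_per_tone: int = 60
    n_electrodes: int = 64
    prop_positive: float = 0.15
    prop_negative: float = 0.20
    prop_onset: float = 0.15
    prop_noise: float = 0.50
    gain: float = 1.5               # z-units per command-unit
    gain_spread: float = 0.5        # per-electrode gain ~ U[1-s, 1+s] * gain
    neural_latency: float = -0.08   # s; negative = neural leads acoustics
    kernel_width: float = 0.10      # s, Gaussian response kernel FWHM-ish
    noise_sd: float = 1.0
    amp_jitter_cv: float = 0.15
    timing_jitter_sd: float = 0.02
    lnf0_noise_sd: float = 0.02
    unvoiced_frac: float = 0.10
    fb_mean: float = 120.0
    fb_sd: float = 10.0


class PipelineConfig(_Section):
    """Full pipeline configuration with every default filled."""

    rate: float = PIPELINE_RATE
    seed: int = 0
    fujisaki: FujisakiSection = Field(default_factory=FujisakiSection)
    features: FeaturesSection = Field(default_factory=FeaturesSection)
    selection: SelectionSection = Field(default_factory=SelectionSection)
    encoding: EncodingSection = Field(default_factory=EncodingSection)
    tuning: TuningSection = Field(default_factory=TuningSection)
    decoding: DecodingSection = Field(default_factory=DecodingSection)
    synthetic: SyntheticSection = Field(default_factory=SyntheticSection)


def load_config(path: str | os.PathLike | None = None) -> PipelineConfig:
    """Load a YAML/JSON config; missing keys get defaults, unknown keys fail."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return PipelineConfig(**data)
    except ValidationError as exc:
        fields = ", ".join(".".join(str(p) for p in e["loc"]) for e in exc.errors())
        raise ConfigError(f"invalid configuration ({fields}): {exc}") from exc


def derive_seed(master: int, name: str) -> int:
    """A stable named sub-seed below 2**31, derived from the master seed."""
    import zlib

    return (int(master) * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)
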
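"""Ground-truth dataset generator for the tone-production analyses.

Emulates the statistical structure the pipeline assumes, so that every
downstream stage (electrode selection, encoding, tuning, decoding) can be
validated against known truth:

* **Task timing** — words of 0.4-0.6 s separated by 0.4-0.6 s gaps, three
  repetitions per cue, an unvoiced consonant prefix of 0.05-0.12 s per word.
* **Pitch** — each trial's contour is synthesized from the canonical
  tone-command template of its lexical tone, with trial-to-trial jitter on
  amplitudes (CV 0.15) and timings (SD 20 ms), a per-trial baseline Fb drawn
  around 120 Hz, additive ln-domain noise, and random unvoiced dropout.
* **Neural populations** — electrodes are positive-tuned (drive =
  half-wave-rectified positive tone command), negative-tuned (rectified
  negative command), onset-only (impulse at each acoustic onset), or pure
  noise, mixed 0.15/0.20/0.15/0.50 by default.  Drives are shifted by the
  neural latency (negative = motor cortex leads the acoustics), convolved
  with a Gaussian response kernel, corrupted with Gaussian noise and
  z-scored per block, mimicking high-gamma preprocessing output.

The generator emits high-gamma directly; raw-voltage synthesis is exercised
separately in the signal-preprocessing tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fujisaki import FujisakiCommandSet, command_track, log_f0, tone_template
from .io_formats import Dataset, SampledTrack, SyntheticSection, derive_seed

__all__ = ["SyntheticConfig", "GroundTruth", "generate_trials",
           "generate_neural", "make_dataset"]

# SyntheticSection doubles as the public config record
SyntheticConfig = SyntheticSection

ROLES = ("positive", "negative", "onset", "noise")


@dataclass
class GroundTruth:
    """Planted parameters aligned to Dataset trial/electrode ids."""

    trial_commands: dict[int, FujisakiCommandSet] = field(default_factory=dict)
    electrode_roles: dict[str, str] = field(default_factory=dict)
    electrode_gains: dict[str, float] = field(default_factory=dict)
    electrode_latencies: dict[str, float] = field(default_factory=dict)

    def planted_electrodes(self) -> list[str]:
        """Electrodes with tone-command coding (positive or negative)."""
        return [e for e, r in self.electrode_roles.items()
                if r in ("positive", "negative")]

    def to_json(self) -> str:
        return json.dumps({
            "trial_commands": {str(k): v.to_dict() for k, v in self.trial_commands.items()},
            "electrode_roles": self.electrode_roles,
            "electrode_gains": self.electrode_gains,
            "electrode_latencies": self.electrode_latencies,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            trial_commands={int(k): FujisakiCommandSet.from_dict(v)
                            for k, v in d["trial_commands"].items()},
            electrode_roles=d["electrode_roles"],
            electrode_gains=d["electrode_gains"],
            electrode_latencies=d["electrode_latencies"],
        )


def _validate(config: SyntheticConfig) -> None:
    props = (config.prop_positive, config.prop_negative,
             config.prop_onset, config.prop_noise)
    if not np.isclose(sum(props), 1.0):
        raise ValueError(f"electrode role proportions must sum to 1, got {sum(props)}")
    if config.n_trials_per_tone <= 0 or config.n_electrodes <= 0:
        raise ValueError("counts must be positive")
    if not config.noise_sd > 0:
        raise ValueError("noise_sd must be positive")


def generate_trials(config: SyntheticConfig, seed: int = 0, rate: float = 100.0,
                    ) -> tuple[pd.DataFrame, SampledTrack, GroundTruth]:
    """Generate the event table, the continuous F0 contour and ground truth.

    Trials are balanced across the four tones and grouped into cues of three
    consecutive repetitions of the same syllable (``cue_id`` column).
    """
    _validate(config)
    rng = np.random.default_rng(derive_seed(seed, "trials"))

    reps = 3
    n_cues_per_tone = int(np.ceil(config.n_trials_per_tone / reps))
    cues: list[int] = []
    for tone in (1, 2, 3, 4):
        cues += [tone] * n_cues_per_tone
    rng.shuffle(cues)

    per_tone_count = {1: 0, 2: 0, 3: 0, 4: 0}
    rows = []
    truth = GroundTruth()
    t = 1.0  # lead-in silence
    trial_id = 0
    syllables = {1: "ma1", 2: "ma2", 3: "ma3", 4: "ma4"}
    for cue_id, tone in enumerate(cues):
        for _ in range(reps):
            if per_tone_count[tone] >= config.n_trials_per_tone:
                continue
            per_tone_count[tone] += 1
            prefix = rng.uniform(0.05, 0.12)
            dur = rng.uniform(0.4, 0.6)
            gap = rng.uniform(0.4, 0.6)
            onset = t
            vowel = onset + prefix
            offset = onset + dur
            voiced_dur = dur - prefix

            template = tone_template(tone, voiced_dur, Fb=rng.normal(config.fb_mean,
                                                                     config.fb_sd))
            cmds = []
            for at, t1, t2 in template.tone_commands:
                at = at * (1.0 + config.amp_jitter_cv * rng.standard_normal())
                t1 = t1 + config.timing_jitter_sd * rng.standard_normal()
                t2 = t2 + config.timing_jitter_sd * rng.standard_normal()
                if t2 - t1 < 0.05:
                    t2 = t1 + 0.05
                cmds.append((float(at), float(t1), float(t2)))
            true_cmds = FujisakiCommandSet(
                Fb=template.Fb, alpha=template.alpha, beta=template.beta,
                gamma=template.gamma, tone_commands=cmds).shifted(vowel)
            truth.trial_commands[trial_id] = true_cmds

            rows.append({"trial_id": trial_id, "syllable": syllables[tone],
                         "tone": tone, "acoustic_onset": onset,
                         "vowel_onset": vowel, "offset": offset,
                         "block_id": 0, "cue_id": cue_id})
            trial_id += 1
            t = offset + gap
        t += rng.uniform(0.0, 0.2)  # small extra pause between cues

    events = pd.DataFrame(rows)
    total = t + 1.0
    n = int(round(total * rate)) + 1
    contour = np.full(n, np.nan)
    grid = np.arange(n) / rate
    for _, row in events.iterrows():
        cmds = truth.trial_commands[row["trial_id"]]
        i0 = int(round(row["vowel_onset"] * rate))
        i1 = int(round(row["offset"] * rate))
        tt = grid[i0:i1]
        lny = log_f0(cmds, tt) + config.lnf0_noise_sd * rng.standard_normal(tt.size)
        f0 = np.exp(lny)
        drop = rng.random(tt.size) < config.unvoiced_frac
        f0[drop] = np.nan
        contour[i0:i1] = f0
    return events, SampledTrack(contour, 0.0, rate), truth


def _gaussian_kernel(width: float, rate: float) -> np.ndarray:
    """Unit-area Gaussian response kernel; ``width`` ~ 2 sigma in seconds."""
    sigma = max(width / 2.0, 1.0 / rate)
    half = int(np.ceil(4 * sigma * rate))
    x = np.arange(-half, half + 1) / rate
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _shift(x: np.ndarray, n_samples: int) -> np.ndarray:
    """x(t - n/rate) with zero padding (positive n delays the signal)."""
    out = np.zeros_like(x)
    if n_samples > 0:
        out[n_samples:] = x[:-n_samples]
    elif n_samples < 0:
        out[:n_samples] = x[-n_samples:]
    else:
        out[:] = x
    return out


def total_command_track(events: pd.DataFrame, truth: GroundTruth,
                        times: np.ndarray) -> np.ndarray:
    """Ground-truth signed command amplitude A(t) over the whole recording."""
    a = np.zeros(times.size)
    for tid in events["trial_id"]:
        a += command_track(truth.trial_commands[int(tid)], times)
    return a


def generate_neural(config: SyntheticConfig, events: pd.DataFrame,
                    truth: GroundTruth, n_samples: int, seed: int = 0,
                    rate: float = 100.0) -> dict[str, SampledTrack]:
    """Synthesize per-electrode high-gamma tracks with planted coding.

    Populates ``truth.electrode_*`` in place and returns the track mapping.
    """
    _validate(config)
    rng = np.random.default_rng(derive_seed(seed, "neural"))
    grid = np.arange(n_samples) / rate
    a_track = total_command_track(events, truth, grid)
    kernel = _gaussian_kernel(config.kernel_width, rate)
    lat_samples = int(round(config.neural_latency * rate))

    n = config.n_electrodes
    counts = [int(round(p * n)) for p in (config.prop_positive, config.prop_negative,
                                          config.prop_onset)]
    counts.append(n - sum(counts))  # remainder -> noise
    roles = [r for r, c in zip(ROLES, counts) for _ in range(c)]

    onset_impulses = np.zeros(n_samples)
    onset_idx = np.round(events["acoustic_onset"].to_numpy() * rate).astype(int)
    onset_impulses[onset_idx] = 1.0 / (kernel.max())  # unit peak after convolution

    tracks: dict[str, SampledTrack] = {}
    for k, role in enumerate(roles):
        eid = f"e{k:03d}"
        gain = config.gain * rng.uniform(1.0 - config.gain_spread,
                                         1.0 + config.gain_spread)
        if role == "positive":
            drive = gain * np.maximum(_shift(a_track, lat_samples), 0.0)
        elif role == "negative":
            drive = gain * np.maximum(-_shift(a_track, lat_samples), 0.0)
        elif role == "onset":
            drive = gain * _shift(onset_impulses, lat_samples)
        else:
            drive = np.zeros(n_samples)
        sig = np.convolve(drive, kernel, mode="same")
        sig = sig + config.noise_sd * rng.standard_normal(n_samples)
        sig = (sig - sig.mean()) / sig.std()  # z-score per block
        tracks[eid] = SampledTrack(sig, 0.0, rate)
        truth.electrode_roles[eid] = role
        truth.electrode_gains[eid] = float(gain)
        truth.electrode_latencies[eid] = float(config.neural_latency)
    return tracks


def _intensity_track(events: pd.DataFrame, n_samples: int,
                     rate: float) -> SampledTrack:
    """Smooth 0/1 speech-intensity envelope with 50 ms cosine ramps."""
    x = np.zeros(n_samples)
    ramp = int(round(0.05 * rate))
    for _, row in events.iterrows():
        i0 = int(round(row["acoustic_onset"] * rate))
        i1 = int(round(row["offset"] * rate))
        x[i0:i1] = 1.0
    if ramp > 1:
        win = np.hanning(2 * ramp + 1)
        win /= win.sum()
        x = np.convolve(x, win, mode="same")
    return SampledTrack(x, 0.0, rate)


def make_dataset(config: SyntheticConfig | None = None, seed: int = 0,
                 rate: float = 100.0) -> tuple[Dataset, GroundTruth]:
    """Compose the trial and neural generators into a full dataset."""
    config = config or SyntheticConfig()
    events, contour, truth = generate_trials(config, seed=seed, rate=rate)
    tracks = generate_neural(config, events, truth, contour.n, seed=seed, rate=rate)
    intensity = _intensity_track(events, contour.n, rate)
    ds = Dataset(neural=tracks, contour=contour, intensity=intensity,
                 events=events,
                 metadata={"subject": "synthetic", "hemisphere": "n/a",
                           "seed": int(seed),
                           "synthetic_config": config.model_dump()})
    return ds, truth
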
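"""End-to-end stage runners shared by the CLI and the analysis scripts.

Each function consumes a Dataset (plus earlier stage outputs) and a
PipelineConfig and returns plain result objects; the CLI is a thin shell
around these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import decoding as dec
from . import encoding as enc
from .electrode_stats import SelectionResult, speech_responsive, tone_discriminant
from .fujisaki import FujisakiCommandSet, FujisakiEstimator, tone_template
from .io_formats import Dataset, PipelineConfig, SampledTrack, derive_seed
from .pitch_features import FeatureMatrix, make_features
from .signal_preproc import Epochs, epoch
from .synthetic_data import total_command_track
from .tuning import ToneCommandTuning

__all__ = ["trial_contour", "fit_fujisaki_per_trial", "run_selection",
           "run_encoding", "run_tuning", "run_decoding", "fitted_command_track"]


def trial_contour(dataset: Dataset, trial_id: int) -> SampledTrack:
    """The F0 segment of one trial (vowel onset to offset), absolute time."""
    row = dataset.events.set_index("trial_id").loc[trial_id]
    i0 = dataset.contour.index_of(row["vowel_onset"])
    i1 = dataset.contour.index_of(row["offset"])
    return SampledTrack(dataset.contour.values[i0:i1 + 1],
                        start_time=dataset.contour.start_time + i0 / dataset.rate,
                        rate=dataset.rate)


def fit_fujisaki_per_trial(dataset: Dataset, config: PipelineConfig | None = None,
                           template_from_label: bool = True,
                           ) -> tuple[dict[int, FujisakiCommandSet], pd.DataFrame]:
    """Inverse-fit tone commands for every trial.

    With ``template_from_label`` the trial's lexical tone seeds the fit with
    its canonical command template (scaled to the voiced span); otherwise
    the extremum heuristic initialises and BIC chooses the command count.
    """
    config = config or PipelineConfig()
    fz = config.fujisaki
    fits: dict[int, FujisakiCommandSet] = {}
    rows = []
    for _, row in dataset.events.iterrows():
        tid = int(row["trial_id"])
        ct = trial_contour(dataset, tid)
        init = None
        if template_from_label:
            dur = float(np.clip(row["offset"] - row["vowel_onset"], 0.2, 1.0))
            voiced = ct.values[np.isfinite(ct.values)]
            fb = float(np.exp(np.median(np.log(voiced)))) if voiced.size else 120.0
            init = tone_template(int(row["tone"]), dur, Fb=fb, alpha=fz.alpha,
                                 beta=fz.beta, gamma=fz.gamma
                                 ).shifted(row["vowel_onset"])
        est = FujisakiEstimator(
            n_tone_commands="auto", alpha=fz.alpha, beta=fz.beta, gamma=fz.gamma,
            n_starts=fz.n_starts, phrase_mode=fz.phrase_mode,
            seed=derive_seed(config.seed, f"fujisaki/{tid}"))
        est.fit(ct, init=init)
        fits[tid] = est.commands_
        rows.append({"trial_id": tid, "tone": int(row["tone"]),
                     "rmse_lnhz": est.rmse_, "n_commands": est.n_commands_,
                     "converged": est.converged_})
    return fits, pd.DataFrame(rows)


def fitted_command_track(dataset: Dataset,
                         fits: dict[int, FujisakiCommandSet]) -> np.ndarray:
    """Signed command amplitude A(t) over the recording from per-trial fits."""
    from .fujisaki import command_track

    a = np.zeros(dataset.contour.n)
    times = dataset.contour.times
    for tid, cmds in fits.items():
        a += command_track(cmds, times)
    return a


def run_selection(dataset: Dataset, config: PipelineConfig | None = None
                  ) -> SelectionResult:
    """Speech-responsive and tone-discriminant electrode selection."""
    config = config or PipelineConfig()
    sel = config.selection
    ids, mat = dataset.neural_matrix()
    onsets = dataset.events["acoustic_onset"].to_numpy()
    resp = speech_responsive(mat, onsets, n_perm=sel.n_perm, window=sel.window,
                             sd_threshold=sel.sd_threshold,
                             n_consecutive=sel.n_consecutive,
                             seed=derive_seed(config.seed, "responsive"),
                             rate=dataset.rate,
                             start_time=dataset.contour.start_time)
    ep = epoch(dataset.neural, dataset.events, align="vowel_onset",
               window=sel.anova_window)
    disc = tone_discriminant(ep, alpha=sel.anova_alpha,
                             n_electrodes_total=len(ids),
                             n_consecutive=sel.n_consecutive)
    return SelectionResult(electrode_ids=ids, responsive=resp["responsive"],
                           responsive_margin=resp["margin"],
                           discriminant=disc.discriminant,
                           F_series=disc.F_series,
                           n_consecutive_significant=disc.n_consecutive_significant)


def run_encoding(dataset: Dataset, fits: dict[int, FujisakiCommandSet],
                 config: PipelineConfig | None = None,
                 feature_sets: list[str] | None = None,
                 n_perm: int | None = None) -> enc.EncodingResult:
    """TRF unique-variance partitioning, optionally with permutation p."""
    config = config or PipelineConfig()
    ec = config.encoding
    feats = make_features(dataset, fits, nbins=config.features.nbins_pitch,
                          speaker_normalize=config.features.speaker_normalize)
    ids, Y = dataset.neural_matrix()
    lag_window = (ec.lag_min, ec.lag_max)
    seed = derive_seed(config.seed, "encoding")
    if n_perm is None:
        n_perm = ec.n_perm
    if n_perm > 0:
        res = enc.permutation_null(feats, Y.T, dataset.events,
                                   feature_sets=feature_sets, n_perm=n_perm,
                                   alpha=ec.alpha, lag_window=lag_window,
                                   lambda_grid=ec.lambda_grid,
                                   n_splits=ec.n_splits, seed=seed)
        obs = res["observed"]
        return enc.EncodingResult(electrode_ids=ids, full_r2=obs["full_r2"],
                                  cv_correlations=obs["fold_r"],
                                  unique_dr2=obs["dr2"], perm_p=res["p"])
    obs = enc.unique_variance(feats, Y.T, feature_sets, lag_window,
                              ec.lambda_grid, ec.n_splits, seed)
    return enc.EncodingResult(electrode_ids=ids, full_r2=obs["full_r2"],
                              cv_correlations=obs["fold_r"],
                              unique_dr2=obs["dr2"])


def run_tuning(dataset: Dataset, fits: dict[int, FujisakiCommandSet] | None = None,
               config: PipelineConfig | None = None,
               use_truth=None) -> ToneCommandTuning:
    """Tone-command tuning curves over voiced speech samples.

    ``use_truth`` may carry a GroundTruth to tune against the planted
    commands instead of fitted ones (validation only).
    """
    config = config or PipelineConfig()
    if use_truth is not None:
        a = total_command_track(dataset.events, use_truth, dataset.contour.times)
    else:
        if fits is None:
            raise ValueError("either fits or use_truth is required")
        a = fitted_command_track(dataset, fits)
    ids, Y = dataset.neural_matrix()
    mask = np.zeros(dataset.contour.n, dtype=bool)
    rate = dataset.rate
    for _, row in dataset.events.iterrows():
        i0 = int(round(row["vowel_onset"] * rate))
        i1 = int(round(row["offset"] * rate))
        mask[i0:i1] = True
    tun = ToneCommandTuning(n_bins=config.tuning.n_bins,
                            strict_compat=config.tuning.strict_compat)
    tun.fit(a, Y, mask=mask, electrode_ids=ids)
    return tun


def run_decoding(dataset: Dataset, electrode_ids: list[str] | None = None,
                 config: PipelineConfig | None = None,
                 significance: str | None = None,
                 n_perm: int | None = None) -> dec.DecodingTimecourse:
    """Sliding-window pairwise decoding on (a subset of) electrodes."""
    config = config or PipelineConfig()
    dc = config.decoding
    ep = epoch(dataset.neural, dataset.events, align="vowel_onset",
               window=dc.epoch_window)
    if electrode_ids:
        ep = ep.select_electrodes(electrode_ids)
    return dec.decode_timecourse(
        ep, length=dc.window_length, step=dc.step, outer_k=dc.outer_k,
        inner_k=dc.inner_k, lambda_grid=dc.lambda_grid,
        seed=derive_seed(config.seed, "decoding"), significance=significance,
        n_perm=n_perm if n_perm is not None else dc.n_perm, alpha=dc.alpha)


def epochs_for(dataset: Dataset, window=(-0.3, 0.2),
               align: str = "vowel_onset") -> Epochs:
    return epoch(dataset.neural, dataset.events, align=align, window=window)
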
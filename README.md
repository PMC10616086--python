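# tonecortex

Analysis pipeline for studying how laryngeal motor cortex encodes Mandarin
lexical tone production: Fujisaki-model decomposition of pitch contours
into positive and negative tone commands, permutation- and ANOVA-based
electrode selection, lagged linear (temporal receptive field) encoding
models with unique-variance partitioning, tone-command tuning curves, and
sliding-window population decoding of the four tones — exercised
end-to-end on a synthetic-data generator that plants known neural coding,
so every stage can be validated against ground truth.

## The model at the core

Pitch is modelled in the log domain as baseline plus phrase and tone
components:

    ln F0(t) = ln Fb + Σᵢ Ap,ᵢ Gp(t − T0ᵢ) + Σⱼ At,ⱼ [Gt(t − T1ⱼ) − Gt(t − T2ⱼ)]

    Gp(t) = α² t e^(−αt)                    Gt(t) = min[1 − (1 + βt) e^(−βt), γ]

Tone commands (At, T1, T2) are signed rectangular drives of the laryngeal
musculature: positive commands raise pitch, negative commands lower it.
The four Mandarin tones correspond to characteristic command patterns
(tone 1: long positive; tone 2: negative then positive; tone 3: long
negative; tone 4: positive then negative).  The package provides forward
synthesis, seeded inverse estimation of commands from partly unvoiced
contours, and the downstream analyses that relate commands to high-gamma
activity:

* `electrode_stats` — speech-responsive (permutation, ±5 SD, 100 ms rule)
  and tone-discriminant (per-timepoint ANOVA, Bonferroni, 10-consecutive
  rule) electrode selection;
* `encoding` — ridge TRF models `y(t) = Σ_f Σ_τ β_f(τ)·x_f(t−τ) + ε` with
  80/10/10 chunked cross-validation, unique ΔR² per feature set and a
  syllable-shuffling permutation null;
* `tuning` — 12-quantile-bin tuning curves over the middle 99% of the
  command distribution, OLS slope polarity;
* `decoding` — 50 ms sliding-window pairwise logistic regression with
  nested (5-fold / 10-fold) cross-validation;
* `pitch_features`, `signal_preproc`, `io_formats`, `synthetic_data`,
  `pipeline`, `cli` — features, preprocessing, formats and orchestration.

## Worked example

```python
import numpy as np
from tonecortex.fujisaki import tone_template, synthesize_f0, estimate_commands
from tonecortex.io_formats import SampledTrack

# synthesize a falling tone-4 contour from its canonical command pattern
template = tone_template(4, duration=0.5, Fb=120.0)
t = np.arange(0.0, 0.5, 0.01)
f0 = synthesize_f0(template, t)
print(f"F0 start {f0[0]:.1f} Hz, peak {f0.max():.1f} Hz, end {f0[-1]:.1f} Hz")

# invert the noisy contour back to commands
noisy = f0 * np.exp(0.02 * np.random.default_rng(0).standard_normal(t.size))
commands, diag = estimate_commands(SampledTrack(noisy, 0.0, 100.0),
                                   init=template, n_starts=1)
for at, t1, t2 in commands.tone_commands:
    print(f"command At={at:+.3f} on [{t1*1000:.0f}, {t2*1000:.0f}] ms")
print(f"fit RMSE {diag['rmse']:.4f} ln-Hz")
```

Output:

```
F0 start 120.0 Hz, peak 205.9 Hz, end 77.9 Hz
command At=+0.588 on [3, 223] ms
command At=-0.496 on [223, 466] ms
fit RMSE 0.0156 ln-Hz
```

The contour rises above 200 Hz under the early positive command and falls
below baseline under the late negative command — the classic falling
tone — and the inverse fit recovers both commands (true +0.60 on
[0, 225] ms, −0.50 on [225, 475] ms) with a residual near the injected
noise level.  With the default eight random multistarts the optimiser
explores alternative command placements as well and keeps whichever
reconstructs the contour best.

The same analyses run from the shell on a simulated dataset:

```bash
tonecortex simulate      --config cfg.yaml --out run/
tonecortex fit-fujisaki  --data run/ --out run/
tonecortex encode        --data run/ --fits run/fujisaki.json --out run/
tonecortex tune          --data run/ --fits run/fujisaki.json --out run/
tonecortex decode        --data run/ --out run/
tonecortex report        --results run/ --out run/
```

Equal configs and seeds produce byte-identical result tables.

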
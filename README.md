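# lcmem

Analysis pipeline for studies of arousal-related emotional memory that combine
a face-name recognition/recollection task with online autonomic measures
(pulse-oximeter heart-rate variability, serial salivary alpha-amylase) and
extracted region-of-interest BOLD time series — in particular the locus
coeruleus (LC), the brainstem hub of the noradrenergic arousal system.  It is
aimed at cognitive-neuroscience groups who already have trial tables, beat
timelines, ROI time courses and saliva panels on disk and want a tested,
reproducible implementation of the non-imaging statistics.

## What it computes

**Behavior.**  Under the equal-variance Gaussian signal-detection model,
sensitivity, criterion and likelihood-ratio response bias are

d′ = z(H) − z(F),  c = −(z(H) + z(F))/2,  β = exp(d′·c),

with hit/false-alarm rates pulled off the 0/1 boundaries by the 1/(2N) rule.
β is regressed out of the per-valence recollection rates across subjects
(OLS residuals, re-centered at the mean), and the adjusted emotional memory
score is E/(E+N) of the two bias-corrected rates.  Paired contrasts use the
Wilcoxon signed-rank Z (normal approximation with tie and continuity
correction) or the paired t test.

**Physiology.**  Beat timelines are cleaned with physiological rate bounds
(25–200 bpm) plus an adaptive running-mean filter; rMSSD is computed on the
raw accepted R-R intervals, and the HRV series (successive R-R differences)
is cubic-spline interpolated onto an equidistant grid for spectral analysis.
ΔsAA = sAA at stage end − sAA at stage beginning.  Arousal events are HRV
local minima over a rolling 15 s window, convolved with a canonical
double-gamma HRF when a regressor is needed.

**Spectra.**  Welch-averaged cross-spectra (Hamming tapers, 20 % overlap,
90 one-sided bins on 0–0.5 Hz by default) give the magnitude-squared
coherence C_AB(f) = |P_AB|² / (P_AA·P_BB) and the phase lag as the
four-quadrant angle of the cross-spectrum (positive phase ⇒ the first series
leads).  The band of maximum coherence is the bootstrap CI of the median
per-subject argmax frequency; band-median coherence/phase per subject × stage
feed the group statistics.  Significance is assessed against surrogate nulls
that redraw each series from its fitted AR(1); partial coherence between two
series given the rest comes from the inverse spectral matrix.

**Associations.**  Repeated-measures correlation (ANCOVA formulation, F-test
p, subject-bootstrap CI), Pearson correlations, random-intercept linear
mixed models over task stages (ML) with Tukey-adjusted marginal-mean
contrasts, Johnson–Neyman regions of significance for stage × frequency
interactions, and Benjamini–Hochberg FDR.

A first-class synthetic-data generator (`lcmem.synthetic_data`) produces
study-shaped datasets with known ground truth — SDT-parameterized trials,
beat timelines whose R-R differences carry a band-limited latent shared with
the LC channel at a controlled coherence and phase, and stage-structured sAA
— so every stage of the chain is testable without access to any real data.

## Worked example

```python
import numpy as np
from lcmem.config import CohortConfig, CouplingSpec, BehaviorSpec, RunConfig
from lcmem.synthetic_data import gen_stage_dataset
from lcmem.pipeline import run_all

cfg = CohortConfig(n_subjects=12, seed=7)           # TR 2 s, 4 stages, 12 min each
coupling = {s: CouplingSpec(band_center=0.2, band_width=0.02,
                            target_msc=0.7, target_phase=np.pi / 2)
            for s in cfg.stages}
dataset = gen_stage_dataset(cfg, coupling_by_stage=coupling,
                            behavior=BehaviorSpec(),
                            saa_effects={"consolidation": 60.0})
results = run_all(dataset, RunConfig(seed=1, n_boot=1000, n_surrogates=100))
```

This prints (via the snippets in the report, `make_report(results)`):

```
band median 0.202 Hz, CI [0.194, 0.208]
median band coherence 0.684
median band phase 1.566
rmcorr dsaa~rmssd r=-0.318 p=0.0547 CI [-0.49, -0.10]
adjusted emotional score median 0.495
null test Z=3.02 p=0.002526
```

The generated LC–HRV coupling at 0.2 Hz is recovered as the band of maximum
coherence (0.202 Hz, one bin from truth); the band coherence (0.68) and
phase (+1.57 ≈ +π/2, i.e. the LC leading) match the generator's targets; the
latent arousal factor produces the expected negative within-subject
ΔsAA–rMSSD correlation; the adjusted emotional score sits near 0.5 because
the default behavior spec pits a neutral d′ advantage against an emotional
recollection advantage; and the observed coherence clearly exceeds the
AR(1)-surrogate null (Z = 3.02).

The same chain is available from a shell:

```sh
lcmem simulate --config cfg.yaml --out study/
lcmem run --config cfg.yaml --data study/ --out out/   # writes out/report.md
```

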
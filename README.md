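# arithmeeg

Oscillatory EEG analysis of arithmetic problem solving: from continuous
multi-channel recordings and trial events to per-condition **ERD/ERS**
(event-related desynchronization/synchronization) values, behavioral
summaries, strategy-report agreement, and mixed-effects inference.

## The scientific problem

Children (and adults) solve arithmetic problems either by **fact retrieval**
(recalling `6 − 2 = 4` directly from memory) or by a **procedure** (counting,
decomposition).  The two routes leave distinct oscillatory signatures in the
EEG: retrieval is associated with theta-band (3–6 Hz) power *increases*
(ERS), procedures with alpha-band (8–13 Hz) power *decreases* (ERD).
Because problem size proxies strategy — small problems (both operands ≤ 10)
are usually retrieved, large problems usually require a procedure — a
paradigm can cross operand size with operation (subtraction ×
multiplication) and validate the proxy against trial-by-trial verbal
strategy reports.

This package implements that full analysis as a tested, reusable pipeline
for 32-channel / 512 Hz recordings of 31 participants × 80 trials, and
ships a synthetic-data generator with the same statistical structure so the
whole pipeline runs end to end without any data download.

## The core statistic

For each trial and channel, band power (zero-phase FIR band-pass, squared
samples) is summarized by its **median** over two windows: a baseline
window **B** at [−1.25 s, −0.25 s) before problem onset and an activity
window **A** at [0, RT).  Per condition (strategy × operation), baseline
and activity medians are taken *across trials* first (vertical averaging),
and only then combined:

```
ERD/ERS = (A − B) / B × 100%
```

Negative values are ERD (power decrease), positive values ERS (increase).
Per-channel values are averaged within four regions of interest (frontal,
fronto-temporo-central, centro-parietal, parieto-occipital) per hemisphere;
midline channels (Fz, Cz, Pz, Oz) belong to no ROI.

Inference uses a random-intercept mixed model per band
(`value ~ operation * strategy * roi * hemisphere + (1 | participant)`),
an inverse-Gaussian GLMM with identity link for response times, a binomial
GLMM for accuracy, and Tukey-corrected pairwise contrasts on estimated
marginal means.

## Worked example

```python
import pandas as pd
from arithmeeg import RunConfig, run_pipeline

cfg = RunConfig(seed=7, output_dir="demo-run")
cfg.simulation.n_participants = 8        # a smaller run for illustration
manifest = run_pipeline(cfg)

print(manifest["stages"]["consistency_filter"])
print(manifest["stages"]["erders"])
erders = pd.read_csv("demo-run/erders.csv")
print(erders.groupby(["band", "strategy"])["value"].mean().round(2))
```

Output from this exact run:

```
{'trials_in': 640, 'trials_retained': 544, 'trials_excluded': 96, 'n_unknown': 4, 'agreement': 0.8553, 'kappa': 0.7107}
{'n_records': 768}
band         strategy
lower_alpha  procedure    -1.83
             retrieve      3.37
theta        procedure    10.86
             retrieve     20.69
upper_alpha  procedure   -11.60
             retrieve     -8.66
```

Reading this: of 640 simulated trials, 544 had verbal strategy reports
consistent with problem size (agreement 0.86, Cohen's κ 0.71 — close to the
configured misreport rate).  The pipeline recovers the generator's injected
condition effects: theta ERS is about twice as strong for retrieval
(+20.7%) as for procedures (+10.9%), retrieval shows slight lower-alpha ERS
(+3.4%) where procedures show ERD (−1.8%), and upper-alpha ERD is strongest
for procedures (−11.6%).  `effects.csv` holds the per-term χ²/F tests and
`contrasts_theta_strategy_roi_hemisphere.csv` the 120 Tukey-corrected
post-hoc contrasts of the strategy × ROI × hemisphere cells.

The same run is available from the shell:

```bash
arithmeeg run --seed 7 --participants 8 --out demo-run
arithmeeg validate-stimuli
arithmeeg simulate --participants 2 --out raw/   # EDF + events TSV per participant
arithmeeg run --input-dir raw/ --out from-files-run
```

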
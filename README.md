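# connpred

Parcel-wise prediction of individual task activation from resting-state
functional connectivity (rsFC), with a robust extreme-value
probabilistic index that flags the parcels whose between-participant
activation differences are *consistently* best predicted.

## Who this is for

Researchers asking whether the individual differences in a task
contrast within a brain parcel can be predicted from the participant's
resting-state connectome, and — across a whole parcellation — which
parcels are predicted better than chance retraining variability would
explain. The package implements the full analysis chain on parcel-level
data (time-series matrices and contrast tables, delimited text), plus a
seeded synthetic-cohort generator so every stage can be exercised and
validated without access to any imaging data.

## The model

For each parcel *j* of a P-parcel parcellation, the outcome is the
N-vector *y<sub>j</sub>* of participants' parcel-mean contrast values,
and the predictors X are the N × P(P−1)/2 participant-by-edge matrix of
Fisher-z Pearson correlations between parcel time courses (upper
triangle, column-standardized). A ridge regression

&nbsp;&nbsp;&nbsp;&nbsp;β̂<sub>j</sub> = argmin<sub>β</sub> ‖y<sub>j</sub> − Xβ‖² + λ‖β‖²

is evaluated with fourfold nested cross-validation (inner folds select
λ from a 17-point log grid spanning 1e−4…1e4 by mean squared prediction
error; outer folds provide pooled out-of-sample predictions), repeated
over 100 runs with re-randomized fold assignments. Accuracy is the
Pearson correlation r(j, n) between predicted and observed contrasts
for parcel j in run n.

The P × 100 accuracy table is then summarized two ways:

1. **Top-tail counts** — fit one Gaussian to all pooled r(j, n),
   z-score every cell, and count per parcel how many runs exceed
   z = 1.96 (the conventional top-5% threshold).
2. **Probabilistic index** — per parcel, form a robust "block maximum"
   as the 90% trimmed mean of its top 10% of z-scores, fit a Gumbel
   extreme-value distribution across the parcels' block maxima, and
   report each parcel's upper-tail probability under that fit. Low
   values mark parcels that are robust positive outliers in prediction
   accuracy.

Parcel-level inputs can also be produced from voxel-level arrays via
the parcellation module: dual regression (group maps → participant
time courses → participant maps), binarization with overlap removal,
and parcel-mean contrast extraction.

## Worked example

Run the full pipeline on a synthetic 52-participant, 22-parcel cohort
in which parcel 5 carries a planted linear effect explaining 60% of its
contrast variance:

```python
from connpred.pipeline import run_pipeline, summarize_results

cfg = {"cohort": {"signal_parcels": [5], "effect_strength": 0.6, "master_seed": 7},
       "prediction": {"n_runs": 100}}
run_pipeline(cfg, "demo_run")
print(summarize_results("demo_run").head(4))
```

which prints (abridged):

```
           top_tail_count  block_max_z  prob_index  rank_by_count  rank_by_index
parcel
parcel_05             100     3.336079    0.004032              1              1
parcel_07              19     2.385118    0.025699              2              2
parcel_17               2     1.480815    0.141983              3              3
parcel_06               0     1.344208    0.181374              4              4
```

The planted parcel lands in the pooled top-5% tail in 100 of 100 runs,
its block-maximum z-score is 3.34, and its probability under the fitted
Gumbel law of block maxima is 0.004 — a strong positive outlier.
Null parcels sit near the fitted accuracy distribution's bulk
(pooled mean −0.03, SD 0.18 in this run) and draw indices ≥ 0.14.

The same stages are available as CLI subcommands
(`connpred simulate | fc | predict | probindex | run-all | summarize`),
all writing TSV/JSON under a run directory together with a manifest of
config, seeds and file digests.

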
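# poolsig

Pooled-microarray analysis pipeline for predicting five-year breast-cancer
recurrence from gene expression.

Early-stage (lymph-node-negative) breast-cancer cohorts profiled on the
same oligonucleotide array can be pooled to gain the sample size that
single studies lack — but only after the cohorts are forced onto a common
expression scale and the subjects are filtered to a clinically comparable
set. `poolsig` implements that whole workflow as a tested, reusable Python
library for methodologists and bioinformaticians who want to study pooled
prognostic-signature construction end to end, offline, on synthetic data
with known ground truth.

## What it computes

1. **Synthetic cohorts** (`poolsig.simulate`) — multi-cohort probe-level
   expression with 1–14 probes per gene, per-cohort affine distortions of
   a shared log2 scale, exponential survival with hazard
   h₀·exp(Σₛ wₛ·zₛ) over planted signal genes, right censoring, and
   clinical covariates with node-positive/missing records.
2. **Harmonization** (`poolsig.harmonize`) — affine-log conversion
   y = log₂(a·x + b) per cohort (parameters given or estimated by
   moment matching), probe→gene collapse by the per-sample median,
   per-gene z-standardization within cohort, merging, and quantile
   normalization; plus the subject exclusion cascade (missing relapse
   status → node-positive/missing → event-free follow-up < 5 y).
3. **Gene ranking** (`poolsig.ranking`) — a 200-subject subsample, 200
   bootstrap rounds of two-sided Mann–Whitney U p-values per gene, a 5%
   symmetric trimmed mean of each gene's p-values (180 of 200 retained),
   and selection of the 100 smallest-p genes.
4. **Classifier suite** (`poolsig.models`) — decision tree (Gini,
   cost-complexity pruning by internal 10-fold CV), ridge-guarded
   logistic regression, and single-hidden-layer neural networks with
   "over-training prevention" (ANN80 holds out 20% of training rows for
   accuracy-based early stopping; ANN100 trains a fixed budget), plus
   DT-filtered composites (DL, DA80, DA100), evaluated over the
   best-balanced of 400 random 370:387 train/test splits by
   ACC, rank-formulation AUC, and the extrapolation differences
   ΔACC = ACC_train − ACC_test, ΔAUC likewise.
5. **Risk signature** (`poolsig.signature`) — Borda integration of the
   four single models' variable importances orders the genes; genes enter
   a standardized Cox proportional-hazards fit one at a time; the gene
   count k\* maximizing test AUC against the five-year relapse label is
   selected; a sensitivity ≥ 80% cutoff dichotomizes the risk score
   Σ βⱼzⱼ; the high/low groups are compared by Kaplan–Meier curves, the
   log-rank test, unadjusted and clinically adjusted hazard ratios, and
   the net reclassification improvement over a clinical-only model.

## Worked example

```python
import numpy as np
from poolsig import SimConfig, generate_cohorts, harmonize_pipeline, rank_genes
from poolsig.pipeline import five_year_label

cfg = SimConfig(n_cohorts=2, subjects_per_cohort=(150, 150), n_genes=500,
                n_signal_genes=10, cohort_transforms=((1.0, 0.0), (2.2, -8.0)),
                seed=42)
bundles, truth, probe_map = generate_cohorts(cfg)
merged, cascade = harmonize_pipeline(bundles, probe_map, params="given")
print(f"retained {cascade.after_followup} of {cascade.initial} subjects")

labels = five_year_label(merged.clinical)
ranked = rank_genes(merged.expression.values, labels, n_subsample=150,
                    B=200, trim=0.05, k=50, rng=np.random.default_rng(0))
top = ranked.loc[ranked.selected, "gene_id"]
hits = sum(g in set(truth.signal_gene_ids) for g in top)
print(f"top-50 ranking recovers {hits} of {cfg.n_signal_genes} planted genes")
print(ranked.head(3).to_string(index=False))
```

Output:

```
retained 212 of 300 subjects
top-50 ranking recovers 10 of 10 planted genes
gene_id    trimmed_p  rank  selected
 g00244 2.937633e-08     1      True
 g00071 2.340856e-07     2      True
 g00335 5.911327e-07     3      True
```

The exclusion cascade removed 88 of the 300 simulated subjects (missing
relapse status, node-positive/missing, or under five event-free years of
follow-up); the bootstrap trimmed-mean ranking then placed all ten
planted recurrence genes inside the top 50, with trimmed-mean p-values
orders of magnitude below the null genes'.

The full pipeline — through classifiers, importance integration and the
incremental Cox signature — runs from one config:

```python
from poolsig import PipelineConfig, run_pipeline
res = run_pipeline(PipelineConfig(seed=1), outdir="artifacts")
print(res["signature"].k_star, res["survival"].logrank_p)
```

or from the shell: `poolsig run --out artifacts --seed 1`
(subcommands `simulate`, `harmonize`, `rank`, `run` mirror the stages).

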
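# immunoprog

Immune-repertoire diversity metrics and the HER2-EveNT prognostic score for
HER2-positive breast cancer treated with neoadjuvant anti-HER2 therapy.

Tumors mount B- and T-cell responses whose clonal structure carries
prognostic information. From bulk RNA-seq, tools such as MiXCR export
clonotype tables — one row per clone, identified by its CDR3 nucleotide
sequence, with a read count and V/D/J/C gene calls. This package turns such
tables into per-sample diversity metrics, combines the key metric (BCR
evenness) with clinical covariates into a validated linear risk score, and
evaluates the resulting risk groups against event-free survival (EFS). It
is aimed at translational biostatisticians who want the full pipeline —
including the exact published constants — as tested, reusable code, plus
synthetic-data generators so every stage can be exercised without access to
controlled trial data.

## What it computes

**Repertoire metrics** per sample and scope (global BCR, global TCR, each
of the 7 chains, each of the 5 IGH isotypes), with clone fractions
`p_i = reads_i / Σ reads`:

- normalized reads = (scope reads / total transcriptome-mapped reads) × 1000
- number of clones; unweighted mean CDR3 length (nt); top and second clone
  proportions
- Gini index `G = Σ_ij |x_i − x_j| / (2 n² x̄)` (no small-sample correction)
- Gini–Simpson index `1 − Σ p_i²`
- evenness `−Σ p_i log_N(p_i)` = Shannon entropy / ln(N clones)

Edge rules: Gini and Gini–Simpson are 0 for a single clone; evenness and
the second-clone proportion need at least two clones; empty scopes yield
explicit missing values.

Clones are assigned to a chain when their gene calls agree (an ambiguous
slot can be rescued by a univocal compatible gene); irreconcilable calls
leave the chain missing while keeping the clone in its global BCR/TCR
scope. IGH isotypes come from the constant-region gene.

**The HER2-EveNT score** (hormone receptor, pCR, **Eve**nness, **N**odal
status, **T**ILs):

```
score = 0.300436587 · evenness_std − 0.024107504 · TILs%
      − 0.568111234 · pCR − 0.525011259 · HR+ − 0.504914127 · cN0
```

with `evenness_std = (BCR evenness − 0.7917893) / 0.1004482` and tertile
cutoffs −1.3763 / −0.8143; patients with score ≤ −1.3763 form the
good-prognosis group. The coefficients are log hazard ratios from a Cox
model for EFS, so lower scores mean lower modeled relapse risk.

**Model development machinery**: Shapiro–Francia-driven log10 transform
decisions with a small constant of (10% quantile)/10 when zeros are
present, centering/scaling, weighted-mean gene-signature scoring, Cox
proportional-hazards fitting (Efron ties) and forward stepwise selection by
AIC from a null model.

**Survival evaluation**: Kaplan–Meier with log-log confidence intervals,
fixed-horizon rates, log-rank tests, Harrell's C-index
(higher score = higher risk), likelihood-ratio Cox reports, and
Benjamini–Hochberg FDR.

## Worked example

```python
from immunoprog import (CohortSimConfig, simulate_cohort, encode_clinical_frame,
                        published_her2event, score_frame, assign_groups,
                        kaplan_meier, survival_at, log_rank, harrell_c)

clinical, _ = simulate_cohort(CohortSimConfig(seed=11, n_patients=250))
features = encode_clinical_frame(clinical)
model = published_her2event()
groups = assign_groups(score_frame(features, model), model)
print(groups.head(3).round(4))
```

```
             score  tertile group
patient_id
P0000      -1.2073        2  poor
P0001      -0.7397        3  poor
P0002      -0.5138        3  poor
```

Each patient gets the linear score, the tertile implied by the published
cutoffs, and the merged good/poor group (82 good, 168 poor here). The
groups separate survival as built into the generator:

```python
merged = groups.join(features[["efs_time", "efs_event"]])
for name, sub in merged.groupby("group"):
    rate, ci = survival_at(kaplan_meier(sub.efs_time, sub.efs_event), 5.0)
    print(f"{name}: 5-year EFS {rate:.2f} (95% CI {ci[0]:.2f}-{ci[1]:.2f})")
stat, p = log_rank(merged.group, merged.efs_time, merged.efs_event)
c = harrell_c(merged.score, merged.efs_time, merged.efs_event).c_index
```

```
good: 5-year EFS 0.71 (95% CI 0.59-0.80)
poor: 5-year EFS 0.38 (95% CI 0.30-0.46)
log-rank chi2 = 35.00, p = 3.30e-09
C-index = 0.6743
```

The synthetic cohort uses a higher baseline hazard than the trials it
mimics, so absolute rates sit lower; the ordering (good ≫ poor) and a
discriminating C-index are structural.

A command-line interface mirrors the library:

```bash
immunoprog simulate cohort --seed 11 --n 250 --out clinical.csv
immunoprog score --clinical clinical.csv --out scores.tsv
immunoprog evaluate --assignments scores.tsv --clinical clinical.csv --out report.json
immunoprog repertoire --clones clones/ --totals totals.tsv --out metrics/
immunoprog run --config pipeline.yaml   # full pipeline with manifest
```

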
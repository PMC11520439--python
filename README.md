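# pairdx

Batch-effect-invariant **gene-pair features** for cross-cohort cancer
transcriptomics: case/control classification and survival prognosis built
on the within-sample ordering of gene pairs rather than absolute
expression.

## The problem

Transcriptome cohorts measured on different microarray or sequencing
platforms cannot be pooled naively: per-cohort technical effects dwarf
the biology, and batch-correcting absolute intensities is fragile.  The
pairwise strategy implemented here (developed for oral squamous cell
carcinoma, but generic) sidesteps the problem by reducing each sample to
binary *relative-expression* features

```
r_k(i, j) = +1  if g_ik > g_jk
            -1  otherwise        (ties -> -1)
```

where `g_ik` is the log2 expression of gene *i* in sample *k*.  Because
`r_k` depends only on which of two genes is higher *within the same
sample*, it is unchanged by any strictly increasing per-sample transform
and by cohort-wide shifts — so cohorts can be concatenated without batch
correction.  Candidate pairs are restricted to genes sharing an annotated
pathway (GMT input): ~10,000 common genes would otherwise give more than
57 million pairs.

The pipeline:

1. **Screen** — for each candidate pair, a 2×2 table of feature state
   (+1/−1) × group (case/control) is tested with Fisher's exact test
   (two-sided); Bonferroni-adjusted p < 10⁻²⁰ defines *differential gene
   pairs* (DGPs).
2. **Diagnose** — stability selection: 100 random stratified 80/20
   splits, an L1-penalized logistic regression per split (penalty by
   cross-validated AUC with the one-standard-error rule), and an
   occurrence count per pair gated on that split's held-out AUC > 0.8.
   Pairs selected in more than a (tunable) threshold of repeats enter a
   final 10-fold-CV LASSO-logistic model; random-forest and
   gradient-boosted-tree baselines are fit for comparison.
3. **Prognose** — univariate Cox filter (p < 0.05), LASSO-Cox with the
   penalty chosen by cross-validated partial likelihood, linear risk
   score `s_k = Σ β_p r_pk`, median split into high/low risk, KM curves
   with the log-rank test, and IPCW cumulative/dynamic AUC at fixed
   horizons.
4. **Enrich** — hypergeometric over-representation of the model's genes
   against any GMT collection.

A seeded synthetic-study generator (`pairdx.simulate`) produces
multi-cohort data with per-cohort batch shifts, per-sample monotone
distortions, *planted* reversed pairs and proportional-hazards survival
with known coefficients, so every stage has a ground-truth recovery test.

## Worked example

```python
from pairdx import (generate_study, candidate_pairs, concat_cohorts,
                    screen_pairs, stability_select, select_candidates,
                    fit_final_model, split_discovery, auc)
from pairdx.presets import recovery_synthetic_config

study = generate_study(recovery_synthetic_config(seed=1))   # 3 cohorts, 5 planted pairs
pairs = candidate_pairs(study.gene_sets, set(study.cohorts[0][0].gene_ids))
features, labels = concat_cohorts(study.cohorts, pairs)
print(len(pairs))                                           # 1140 candidate pairs

sig = [r.pair for r in screen_pairs(features, labels) if r.significant]
print([str(p) for p in sig])
# ['G0001|G0002', 'G0003|G0004', 'G0021|G0022', 'G0041|G0042', 'G0061|G0062']

feats = features.subset(sig)
train, test = split_discovery(labels, seed=1)
stab = stability_select(feats.select_samples(train), labels[train], seed=1)
model = fit_final_model(feats.select_samples(train), labels[train],
                        select_candidates(stab, 50), seed=1)
print(len(model.pairs),
      round(auc(model.decision_function(feats.select_samples(test)), labels[test]), 4))
# 5 0.9972
```

The screen recovers exactly the five planted reversed pairs (despite
per-cohort batch shifts with SD 2 and per-sample affine distortions), and
the stability-selected sparse model separates held-out samples with AUC
0.997.

The same flow is available from the shell:

```sh
pairdx simulate --seed 1 --out fixtures/
pairdx run --config config.yaml --out results/     # full pipeline + manifest
```

where `config.yaml` can be as small as

```yaml
seed: 1
synthetic: {preset: small}
```

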
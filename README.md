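# steatomir

Discovery of small serum microRNA panels that quantitatively predict liver
steatosis.

Hepatic steatosis — triglyceride accumulation in hepatocytes, the hallmark
of early NAFLD — can currently be quantified only by biopsy or imaging.
Because the liver releases miRNAs into the circulation, and steatosis
perturbs that release, a handful of serum miRNAs can act as a quantitative
proxy for liver fat. `steatomir` implements the full computational workflow
for finding such panels from paired liver/serum small-RNA-seq cohorts, for
bioinformaticians and biomarker researchers working with count tables of
modest cohorts (n ≈ 20–25, p ≈ 150–400 miRNAs).

## The method

Given a miRNA-by-sample count matrix **X** and a continuous steatosis
response **y** (liver TG in µg/mg protein, or biopsy fat %), the pipeline
runs:

1. **Clean-up** — keep miRNAs detected (count ≥ 1) in ≥ ⌈f·n⌉ samples per
   tissue (defaults f = 0.90 liver, 0.825 serum) and whose median raw count
   is not higher in serum than in liver; then per-tissue median-of-ratios
   normalization (size factor of sample *j* is the median over all-positive
   rows *i* of xᵢⱼ / geomeanᵢ).
2. **Screening** — per-miRNA Pearson correlation with y (p-value from
   t = r√((n−2)/(1−r²)), df = n−2, no multiplicity correction) and PCA of
   the autoscaled profiles.
3. **PLS1 regression** — NIPALS partial least squares with a single
   response, suited to p ≫ n collinear predictors. Features and response
   are autoscaled; the number of latent variables A minimizes the
   leave-one-out RMSECV = √(mean(y − ŷ₋ᵢ)²), with autoscaling recomputed
   inside every fold. Model significance is assessed by permutation testing
   (default B = 500): p = fraction of permuted responses achieving a lower
   RMSECV.
4. **Recursive feature elimination** — refit, score features by VIP
   (VIPⱼ = √(p·Σₐ SSYₐ wₐⱼ²/Σₐ SSYₐ), Σ VIP² = p), drop the least important
   feature, repeat to one feature; read the optimal subset (default size
   50) off the RMSECV trajectory.
5. **Cross-tissue intersection** — miRNAs selected in both the liver arm
   (TG on liver miRNAs) and the serum arm (fat % on serum miRNAs).
6. **Exhaustive small-panel search** — every 2- and 3-miRNA subset of the
   intersected panel fitted and ranked by RMSECV (a 19-miRNA panel gives
   171 + 969 = 1140 models).
7. **Biological ranking** — additive penalty over configurable criteria:
   passenger strand, non-significant correlations, few predicted
   lipid-metabolism target genes, low liver/serum abundance ratio.

A synthetic paired-cohort generator (negative-binomial counts with a latent
steatosis driver and known informative miRNAs, a configurable fraction with
opposite liver/serum effect signs) makes every stage testable end to end.

## Worked example

```python
import steatomir as sm

cohort = sm.generate_cohort(sm.CohortConfig(seed=7))          # 154 miRNAs, n=20/23
retained = sm.common_feature_set(cohort.liver_counts, cohort.serum_counts)
norm = sm.normalize(cohort.serum_counts.subset(retained))

X = norm.values.T                                # samples x miRNAs
y = cohort.serum_fat.align(norm.sample_ids)      # biopsy fat %
res = sm.PLS1Model(y, X).fit()                   # latent variables by LOOCV
print(res.summary(top=5))
print("permutation p =", res.permutation_test(B=100, seed=7).p_value)
```

prints

```
   PLS1 regression
======================
----------------------
     No. samples    23
    No. features   140
Latent variables    10
  RMSECV (LOOCV) 7.481
----------------------
=======================================
    feature      VIP  coef (autoscaled)
---------------------------------------
hsa-miR-9059-3p 2.587           +0.0662
hsa-miR-9053-3p 2.555           -0.0669
hsa-miR-9000-5p 2.513           +0.0508
hsa-miR-9096-5p 2.510           +0.0534
hsa-miR-9074-5p 2.432           +0.0535
---------------------------------------
permutation p = 0.0
```

140 of 154 miRNAs survive clean-up; a 10-latent-variable PLS model predicts
biopsy fat % with a leave-one-out error of 7.5 percentage points, far better
than any of 100 permuted responses (p = 0). The VIP column ranks miRNAs by
their contribution to the prediction; these seed the RFE stage.

The same workflow runs from the shell:

```sh
steatomir simulate --seed 7 --outdir cohort/
steatomir -v run --seed 7 --outdir run/        # full pipeline, synthetic mode
```

producing normalized matrices, correlation tables, PCA scores, model
summaries, RFE traces, the intersected panel, its biological ranking, the
ranked 2–3-miRNA combination table, and a manifest with content hashes that
makes the run byte-for-byte reproducible.

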
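# demeta

Cross-study differential-expression meta-analysis for small-n two-group
perturbation studies (knockout vs wild-type, treatment vs control) run on
different tissues and platforms — the setting of caspase-1 / IL-1β / IL-18
/ Sirt-1 transcriptome integration, where a handful of 3–5-replicate
microarray contrasts per tissue must be combined before any global
regulatory signal becomes visible.

The package is for computational biologists who have per-study
log2-normalized expression matrices (gene- or probe-level) and want to

1. run moderated two-group differential expression per study,
2. combine studies into per-gene global effect estimates,
3. partition significant genes by tissue specificity, and
4. test whether two regulators act on the same genes with the sign
   relation their biochemistry predicts ("cooperation analysis").

## The statistics

**Per study (empirical-Bayes moderated t).** For gene *g* with pooled
residual variance s²_g on d = n₁+n₂−2 degrees of freedom, the variances
are assumed exchangeable around a prior s₀² with d₀ degrees of freedom;
(d₀, s₀²) are estimated by moment matching on log s²_g. The posterior
variance and moderated statistic are

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d)
    t̃_g  = log2FC_g / (s̃_g·√(1/n₁+1/n₂)),   t̃_g ~ t(d + d₀) under H₀

with two-sided p-values and Benjamini–Hochberg adjustment.

**Across studies (fixed-effect inverse variance).** Each study contributes
a Hedges-type unbiased standardized mean difference

    d = t̃·√(1/n₁+1/n₂),   d′ = J·d,   J = 1 − 3/(4m−1),  m = d + d₀
    var(d′) = (1/n₁+1/n₂) + d′²/(2(n₁+n₂))

combined with weights w = 1/var: d̄ = Σwd′/Σw, se = √(1/Σw),
z = d̄/se, p = 2(1−Φ(|z|)), BH-adjusted. The log2 fold change itself is
combined the same way (se = s̃·√(1/n₁+1/n₂)), with an optional
DerSimonian–Laird random-effects model. Study orientations
(loss- vs gain-of-function) are sign-harmonized first.

**Venn partitioning.** Each gene significant anywhere gets a membership
pattern over tissues, a kT category (1T = one tissue … all-T = shared
core) and an up/down/mixed direction-concordance label.

**Cooperation analysis.** For two contrasts, genes significant in both
with linear fold change ≥ a gate (default 2) on both axes are classified
into semantic quadrants: I/III when the two fold changes show the sign
relation the regulator pair predicts (`expected_sign = −1` for
opposite-sign cooperation, e.g. a protease knockout vs a knockout of the
substrate it degrades), II/IV otherwise. Reported: quadrant counts, the
cooperative percentage, and the FC/FC R².

A synthetic multi-study generator (`demeta.simulate`) plants global,
tissue-specific, null and cooperative genes with known truth, so the whole
pipeline is testable without any external download.

## Worked example

```python
import demeta as dm

cfg = dm.SyntheticConfig(n_genes=2000, n_studies=4, n_global=25, n_specific=60,
                         delta_global=2.5, delta_specific=2.0)
studies, truth = dm.generate_multistudy(cfg, seed=11)
tables = [dm.empirical_bayes(dm.fit_two_group(s)) for s in studies]
for t in tables:
    frac = dm.significant_fraction(t)
    print(f"{t.study_id}: {frac.n_sig}/{frac.n_total} genes at p<0.05 "
          f"({frac.pct}%), prior df d0={t.d0:.2f}, prior var s0^2={t.s0_sq:.3f}")

meta = dm.meta_analyze(tables)
hits = dm.meta_significant(meta, alpha_adj=0.05)
print(f"{len(hits)} genes at adjusted p<0.05:",
      dict(hits["direction"].value_counts()))
print(dm.evaluate_recovery(hits.index, truth))
print(dm.forest_rows(meta, hits.index[0]).round(3).to_string(index=False))
```

prints

```
study1: 177/2000 genes at p<0.05 (8.8%), prior df d0=4.35, prior var s0^2=0.256
study2: 170/2000 genes at p<0.05 (8.5%), prior df d0=4.13, prior var s0^2=0.255
study3: 145/2000 genes at p<0.05 (7.2%), prior df d0=4.16, prior var s0^2=0.258
study4: 182/2000 genes at p<0.05 (9.1%), prior df d0=4.01, prior var s0^2=0.245
26 genes at adjusted p<0.05: {'promoted': 15, 'inhibited': 11}
{'n_called': 26, 'n_true': 25, 'tp': 25, 'fp': 1, 'sensitivity': 1.0,
 'fdr': 0.0385, 'per_class': {'global': 25, 'specific': 1}}
   label  estimate  ci_low  ci_high
  study1    -4.762  -7.190   -2.335
  study2    -2.394  -4.018   -0.770
  study3    -3.646  -5.669   -1.624
  study4    -3.031  -4.848   -1.214
combined    -3.216  -4.171   -2.261
```

The per-study estimates of the variance prior recover the generating
values (d₀ = 4, s₀² = 0.25); each study alone flags under 10% of genes,
but the combined analysis recovers all 25 planted global genes at one
false positive; the forest rows show four noisy per-study effects tighten
into a decisive combined estimate. `promoted`/`inhibited` are regulator
semantics under the loss-of-function convention: a gene *down* in the
knockout is a gene the regulator *promotes*.

There is also a CLI (`demeta simulate|de|meta|venn|coop|run|report`) for
config-driven runs; `demeta run --config pipeline.yaml` executes every
stage and writes TSV/JSON artifacts plus a checksummed manifest.

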
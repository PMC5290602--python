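# Methods

## Scope and data model

`demeta` integrates several independent two-group expression contrasts
("studies"), each a log2-normalized matrix with ≥2 perturbed and ≥2
control samples. Studies with any group below 2 samples are rejected at
ingestion (no p-value is computable from one replicate). The pipeline
never normalizes: matrices are assumed log2-scale and
platform-normalized upstream. Gene identifiers are taken verbatim and
case-sensitively; no alias resolution is attempted. The cross-study gene
universe is the exact intersection of the studies' gene sets, reported
and lexicographically ordered.

Probe-level matrices are collapsed to genes before analysis. The default
`max_mean` rule keeps the single probe with the highest mean intensity
across all samples verbatim — every gene-level value is then traceable
to one input row and no values are invented; `median` (per-sample median
over a gene's probes) is available. Ties under `max_mean` go to the
lexicographically smallest probe id so collapse is deterministic.

Each study carries an orientation: `loss_of_function` (knockout,
knockdown) or `gain_of_function` (transgene, agonist treatment). Before
any cross-study step, fold-change and effect signs are negated where
needed to put every study on one axis (default: loss of function);
p-values and variances are untouched and the flip is recorded.
Orientation is declared metadata, never inferred from the data.

## Per-study model

For gene *g*: `log2fc = mean(perturbed) − mean(control)`, pooled
residual variance `s²` on `d = n₁+n₂−2` df, unscaled standard deviation
`√(1/n₁+1/n₂)`. The gene-wise variances are modelled as exchangeable
draws from a scaled inverse-chi-squared prior `(d₀, s₀²)`, giving the
posterior variance `s̃² = (d₀s₀² + d·s²)/(d₀+d)` and the moderated
`t̃ = log2fc/(s̃·√(1/n₁+1/n₂))` on `d+d₀` df.

`(d₀, s₀²)` are estimated in closed form by moment matching on
`e = log s² − ψ(d/2) + log(d/2)`: the excess of `var(e)` over `ψ′(d/2)`
equals `ψ′(d₀/2)`, inverted by Newton iteration; `s₀²` follows from
`mean(e)`. When the excess is non-positive (all variances equal, or
under-dispersed) the prior degenerates to `d₀ = ∞` and `s₀² = mean(s²)`
— the pooled-variance MLE in that limit, which makes `s̃² = s²` exactly
when all variances are equal and hence the moderated t coincide with the
ordinary pooled t. If the Newton step ever fails the same fallback is
used with a logged warning. Genes with `s² = 0` receive the prior-only
posterior `d₀s₀²/(d₀+d)`. No trend or robust variants are offered.
The implementation is cross-checked in the test suite against the
Bioconductor reference implementation on the same matrix.

Benjamini–Hochberg adjustment is applied within each study (and again to
the combined p-values). Per-study "significantly changed" summaries use
raw p < 0.05 by default — adjusted p is retained and selectable — because
single-study calls at these group sizes are intentionally permissive and
the meta-analysis stage is where FDR control is applied. Both thresholds
are exposed in configuration.

## Cross-study combination

Effect sizes: `d = t̃·√(1/n₁+1/n₂)`, small-sample bias correction
`J = 1 − 3/(4m−1)` with `m = d+d₀` (J→1 as m→∞), `d′ = J·d`,
`var(d′) = (1/n₁+1/n₂) + d′²/(2(n₁+n₂))`. Fixed-effect combination with
weights `w = 1/var`: `d̄ = Σwd′/Σw`, `se = √(1/Σw)`, `z = d̄/se`,
two-sided normal p, BH-adjusted. Fixed effect is the default throughout;
it matches the single-combined-statistic, normal-p behaviour of the
direct effect-size-combination approach this pipeline reimplements.

Combined fold change: same inverse-variance scheme on `log2fc` with
`se = s̃·√(1/n₁+1/n₂)`. A DerSimonian–Laird random-effects option
(`τ² = max(0, (Q−(k−1))/(Σw−Σw²/Σw))`, weights `1/(se²+τ²)`) is exposed
because heterogeneity across tissues is plausible; `τ²` is defined as 0
for k = 1. Both routes are cross-checked against the CRAN meta-analysis
reference in the tests.

Genes absent from some studies are combined over the studies that
measured them, with k recorded, rather than dropped — the per-study
universes genuinely differ across platforms. Combined calls use
adjusted p < 0.05, optionally with a linear fold-change gate. Direction
labels are regulator semantics under the chosen convention: with loss of
function, combined fold change < 0 ⇒ the regulator *promotes* the gene,
> 0 ⇒ *inhibits* it.

Forest rows per gene are `d′ ± 1.96·√var` per study plus
`d̄ ± 1.96·se` combined.

## Venn partitioning and cooperation analysis

Venn partitioning is exact set algebra over 2–6 per-tissue significant
sets: each union gene gets one membership bit pattern, a kT category and
an up/down/mixed direction label from the signs in its member tissues
(mixed ⇔ signs disagree). The shared core is the exactly-k (default:
all-tissue) class. `lookup_genes` cross-examines a gene list against
external DE tables, reporting promoted/inhibited/not-significant/absent
per table under a loss-of-function reading.

Cooperation analysis pairs two contrasts over their shared genes.
Quadrants are *semantic*: with `expected_sign = −1` (cooperation
predicts opposite fold-change signs), quadrant I is reference-up &
comparator-down and III its mirror; II and IV are the non-cooperative
sign pairs. Geometric axis orientation therefore never needs flipping
when one side is a knockout and the other a treatment — the sign
relation is the single declared parameter. Gating requires raw p <
alpha in *both* contrasts and linear fold change ≥ the gate (default 2,
"no less than" semantics; 1.5 also used in practice) on *both* axes.
The cooperative percentage is 100·(I+III)/gated, to one decimal. R² is
the squared Pearson correlation over *all* paired genes by default — the
natural description of the whole scatter — with a gated-only option,
since either convention is defensible. Genes with a fold change of
exactly 0 on either axis carry no sign and are excluded from quadrant
counts and reported; this is measure-zero on real data but matters for
integer-valued toys.

## Synthetic data

The generator draws per-gene variances from a scaled inverse-chi-squared
prior (`d₀ = 4`, `s₀² = 0.25` by default — heavy-tailed enough that
shrinkage matters, residual SD ≈ 0.5 log2 units as typical of gene-level
microarray noise), baselines from N(8, 1.5²) log2 units, and normal
noise — deliberately the moderated-t model's own assumptions, so
parameter-recovery tests have a correctly-specified baseline. Effects
are planted in units of each gene's σ. Defaults for the multi-study
design: 4 studies of 5 vs 5, 5000 genes, 40 global genes at |d| = 1.2
with one shared sign, 150 tissue-specific genes per study at |d| = 1.5.
The paired design plants 250 both-contrast genes at |d| = 4 (≈ 2 log2FC,
so the linear-FC ≥ 2 gate is informative), 80% of them with the
cooperative sign product, plus 100 reference-only genes. A master seed
spawns independent per-study substreams, so each study's matrix depends
only on the master seed and its own index. An optional contamination
knob inflates the noise SD of a fraction of samples for robustness
checks (off by default).

What the generator does *not* emulate: probe-level intensities, batch
and platform effects, correlated genes, non-normal noise (unless
contaminated), missing values. Passing recovery tests therefore
demonstrate correctness of the estimators under their own model, not
robustness to real microarray artifacts.

## Numerical and design notes

- Trigamma inversion: Newton from `y = 0.5 + 1/x` with asymptotic
  shortcuts for extreme arguments; relative tolerance 1e-8.
- `df = ∞` t-distributions are evaluated as normal.
- BH ties are handled by stable sorting; adjusted p are monotone in raw
  p and ≥ raw p.
- All TSV artifacts are written with `%.10g` floats so reruns are
  byte-identical and manifests can carry sha256 checksums.
- Simulation-based checks in the test suite and the acceptance script
  use 20 replicates of the 5000-gene 4-study design, 3 replicates of a
  10,000-gene null, and 20 replicates of the 5000-gene paired design —
  sizes at which every sampling-noise tolerance used is comfortably
  met in a few seconds.

## Known limitations

- Two-group contrasts only; no multi-factor designs, array weights or
  duplicate-correlation structure.
- Fixed-effect effect-size combination assumes a common true effect per
  gene; the DL option covers fold changes only.
- Meta-analysis sensitivity at small standardized effects is modest:
  with 4 studies of 5 vs 5 and |d| = 1.2 the expected combined |z| is
  ≈ 3.3, while BH at 5% on 5000 genes demands |z| ≳ 3.8–4.2 at realistic
  discovery counts, so most such genes are missed even though FDR
  control and the advantage over any single study hold. Power reaches
  ~70% only around |d| ≈ 1.7 under these conditions.
- Gene symbols are matched verbatim; cross-platform identifier drift
  must be resolved upstream.
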
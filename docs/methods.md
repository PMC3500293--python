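# Methods

## The classification problem

Two UCP1-positive brown adipocyte types exist in rodents — classical brown
adipocytes (Myf-5 lineage) and inducible beige/brite cells — and a tissue
sample's identity can be read off its transcriptome in two steps: derive
marker-gene groups that separate the cell types in a controlled
three-condition experiment, then measure which marker group an independent
tissue panel's expression tracks. `batsig` implements both steps plus the
simulation machinery needed to validate them without access to cohort data.

## Marker discovery

Input is a genes × samples matrix of linear-scale, non-negative expression
with three condition labels (white, beige, brown), each with ≥ 2 replicates.

**DE filter.** A gene is differentially expressed when any pairwise contrast
shows fold ≥ `min_fold` (either direction) with p ≤ `max_p`. Defaults:
`min_fold = 2`, `max_p = 0.05`, two-sided equal-variance Student's t
(the classic microarray-era convention; Welch available by flag), raw
p-values (Benjamini–Hochberg available by flag, off by default because the
four-group design was defined on raw p < 0.05). Ties at exactly the
thresholds are included (≥ / ≤). Condition means are floored at a small
epsilon (default: half the smallest positive value in the matrix) before
folds are computed, because array floors and "nearly undetectable" qPCR
values would otherwise produce zero divisions.

**Four-group rule.** The combination rule for "enriched" is conjunctive and
checked in this order:

1. single-condition labels (WHITE / BEIGE_ONLY / CLASSICAL_ONLY): the
   candidate condition's mean must be ≥ `min_fold` × *each* other condition
   with *both* contrasts significant;
2. COMMON_BROWN: beige and brown each enriched over white (fold +
   significance) *and* within `min_fold` of each other in both directions —
   otherwise the gene belongs to the dominant single group, which is why
   the single-condition patterns are tested first;
3. anything else stays UNCLASSIFIED.

The conjunctive reading is a design choice (a disjunctive rule would let a
gene significant against only one condition claim a group); it is the rule
the test-suite oracle re-derives independently. Degenerate t-tests (both
groups constant and equal) return p = 1 by convention.

Overlap fractions are reported as 100 · common/total with nearest-integer
rounding alongside the exact value (29/323 → 8.98 % → "9 %").

## ΔΔCt quantification

Relative expression from raw Ct tables assumes perfect amplification
efficiency (factor 2 per cycle): ΔCt = Ct_target − Ct_reference against an
endogenous control (TBP role), and expression = 2^−(ΔCt_sample −
ΔCt_calibrator), exactly 1.0 at the calibrator for every gene. Without a
calibrator the output is 2^−ΔCt, a per-gene rescaling that leaves all
downstream correlations unchanged. Missing Ct values propagate as NaN and
are handled by pairwise-complete correlation — never imputed. Efficiency
correction and multi-reference normalization are out of scope.

## Gene-set concordance

**Outlier screen.** Per gene, quartiles are computed by linear interpolation
between order statistics (numpy's default, the "type 7" convention — the
original analysis names no method, and this is the common default in
JMP-/R-style box plots); the whisker edges are the outermost data points
within quartile ± 1.5·IQR, and samples strictly beyond the fences are
flagged. Genes whose flagged fraction exceeds `max_outlier_fraction`
(default 0.2 — no number was stated for "too many"; one in five samples is
where a 13–15-sample panel's correlation becomes outlier-driven) are
excluded from all correlation analyses. Genes with < 4 finite values are
reported as insufficient, not excluded.

**Integration.** Member correlations use pairwise-complete Pearson r
(undefined when either vector has zero variance on the complete pairs; such
members are dropped). Fisher weights wᵢ = nᵢ − 3 are the inverse asymptotic
variance of zᵢ; on a complete panel all weights are equal and the weighted
average reduces to the plain mean, so this reading is compatible with any
interpretation of a "weighted average of z-scores". |r| = 1 (duplicate-like
genes, common in synthetic fixtures) is clamped to 1 − 10⁻⁶ with a warning
instead of erroring.

**Standard error and Z-test.** The variance of z̄ is not identified without
knowing the inter-member correlation structure, so two modes ship:

* `conservative` (default): SE = 1/√(ñ−3), ñ the weight-weighted mean
  member n — the whole set treated as one correlated measurement. Honest
  because members share samples and, under the one-factor biology, one
  driver; under null simulations the resulting test rejects at well below
  nominal α (measured ≲ 1 % at α = 5 %).
* `independent`: SE = 1/√Σwᵢ — correct only for independent members,
  anti-conservative here; provided for comparison and recorded in output.

The two-set comparison Z = (z̄ₐ − z̄_b)/√(SEₐ² + SE_b²) treats the two
integrated coefficients as independent (no dependent-correlation correction
is applied; Steiger/Williams-type tests are out of scope). The dependence
caveat is embedded in the verdict JSON.

**Correlation scale.** Correlations default to linear-scale relative
expression (matching the scatter-plot convention for these data); a `log2`
option (pseudocount = half the minimum positive value) is available and is
used wherever results are compared against the simulator's factor model,
which is defined on log2 scale (below).

**Clustering.** Average linkage (UPGMA) on d = 1 − r, delegated to
scipy's linkage after sorting items lexicographically so equal-distance
merges resolve deterministically. Heights are reported at full precision;
the dendrogram exports to Newick with branch length = parent height −
child height.

## Synthetic data

The generator defines the conditions under which the pipeline is validated.

**Cell-type profiles.** Planted marker groups (defaults 32 white / 141
beige-only / 29 common / 294 classical-only, in a 1000-gene background)
have their linear-scale mean multiplied by `fold_effect` (default 8) in the
conditions the group implies. Replicate noise is multiplicative log-normal
with coefficient of variation `noise_cv` (default 0.2), mean-preserving:
m·exp(σZ − σ²/2), σ = √ln(1+cv²) — expression is positive and
heteroscedastic, which additive Gaussian noise would misrepresent.
Replicates per condition default to 3 (unstated in the original design;
typical for primary-culture arrays) and are configurable.

**Tissue panel.** One latent beige-activity factor F ~ N(0,1) per tissue
(a single factor, following the one-dominant-pathway biology; multi-factor
generation is a non-goal). On log2 scale, every beige-set gene, common-set
gene and anchor is `base_log2 + λ·F + ε`, ε ~ N(0, σ); defaults λ = 0.9,
σ = 0.3, `base_log2` = 4. Classical-only genes are factor-free at
`classical_level` (default 0.05 linear units — just above the detection
floor so they retain variance; at the floor they would clip to a constant
and be dropped as undefined correlations). The matrix is exported as
2^log2, clipped at a detection floor of 10⁻³ × baseline, emulating
"nearly undetectable" classical markers without zeros. Which marker sets
load on the factor is set by `factor_set_labels` (default beige + common).
Between two factor-driven genes the population log-scale correlation is
λ²/(λ²+σ²); this closed form is the Monte-Carlo target of the generator's
own tests, which is why those checks (and the headline concordance
analysis) correlate on log2 scale.

**Ct tables.** Ct_target = Ct_reference − log2(relative expression) +
Gaussian cycle noise, efficiency fixed at 2 — the exact inverse of the
ΔΔCt stage at zero noise.

**Seeding.** One top-level seed; every gene draws from a sub-stream keyed
by (seed, block, gene index), so enlarging a simulation never reshuffles
existing genes, and identical configs are byte-identical after
serialization.

**What the simulation does not emulate.** Probe-level microarray effects
and normalization, batch effects, qPCR efficiency ≠ 2, multiple latent
factors, and the real covariance of human postmortem tissue. Passing tests
therefore demonstrate the statistical machinery's correctness and
calibration under the stated generative model, not performance on the
original cohort; the published 496-gene list and the human-panel
correlation values are not reproducible without the deposited microarray
data and are covered only by these simulation analogs.

## Validation setup

Problem sizes used by the test suite and acceptance script: 200 seeded
15-tissue panels for the beige-vs-classical verdict rate (8-gene beige set
vs 8-gene classical set, λ = 0.9, σ = 0.3, p < 0.01 threshold); a 30-tissue
panel at λ = 1.0, σ = 0.2 for the cross-correlation structure (theoretical
pairwise r ≈ 0.96); 2000 null replicates for type-I calibration; planted
profile experiments of 240–1000 genes for label recovery; brute-force
oracles on ≤ 20 genes (discovery), ≤ 8-sample vectors (outlier rule) and
6-item matrices (UPGMA).

## Known limitations

* The Z-test ignores dependence between the two competing sets (both are
  correlated with the same anchor on the same samples); the conservative
  SE mode compensates in practice but is not a formal dependent test.
* Single-factor simulation cannot probe robustness to mixed tissue
  composition.
* The report layer exports data (scaled matrices, ellipse parameters,
  Newick trees), not rendered figures; color schemes are metadata strings.
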
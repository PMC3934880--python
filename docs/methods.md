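# Methods

## Model and scope

The package treats a bulk RNA-seq experiment as depth allocation over
relative abundances. Sample *j* contains per-embryo transcript abundances
T_ij (arbitrary molecule units) with total content C_j = Σ_i T_ij; the
sequencer draws R_j ≈ D_j total reads with per-gene means
μ_ij = D_j · T_ij / C_j. Depth D_j is a property of the library, not of the
biology, so raw counts are informative about T_ij only up to the per-sample
constant C_j / D_j. Normalization is the attempt to remove that constant;
the disagreement between methods is entirely about what they assume of C_j.

* **RPM/RPKM** set every sample's total to 10⁶ (optionally per kilobase):
  implicitly C_j constant.
* **TMM-scaled log2 values** additionally equalize the trimmed-mean log
  ratio of the bulk of genes against a reference sample: robustly C_j
  constant for the unchanged majority.
* **BSN** estimates concentrations E_ij = R_ij/R_j, then reassigns a
  *pseudo library* L_j = R̄ · Z_j, with R̄ the mean of the raw library sizes
  and Z_j an external estimate of C_j/C_ref. Fold changes then estimate
  T-ratios rather than concentration ratios.

The identity worth internalizing (and tested exactly): BSN and RPM values
differ per sample by the constant R̄·Z_j/10⁶, so for every gene
log2FC_BSN = log2FC_RPM + log2(Z_num/Z_den). BSN is RPM plus the content
trajectory; nothing else changes.

## Scale estimators

**Laboratory (`bio_scales`).** Inputs are replicated per-stage measurements
of total RNA and polyA⁺ RNA amounts (ng per fixed embryo count). Per stage
the polyA⁺ percentage p_j = mean(polyA)/mean(total) × 100 is formed by
averaging *amounts* across replicates before taking the ratio (one
percentage per stage; a mean of ratios would weight noisy small-denominator
replicates), then Z_j = p_j/p_ref with Z_ref ≡ 1. Percentages make the
estimator unit-free and robust to stage-level differences in extraction
yield; a replicate with polyA > total is flagged, not rejected, since both
instruments are noisy at nanogram amounts.

**Count-derived (`tmm_factors`, `tmm_content_scales`).** The TMM factor of
sample k against reference r is 2 to the precision-weighted mean of the
per-gene log ratios M_g = log2((R_gk/R_k)/(R_gr/R_r)) after a double trim:
drop the bottom/top 30% by M-rank and 5% by A-rank (A_g = average log2
relative abundance), rank windows floor(n·trim)+1 … n−floor(n·trim) with
average ranks on ties; weights are the inverse delta-method variances
1/w_g, w_g = (R_k−R_gk)/(R_k·R_gk) + (R_r−R_gr)/(R_r·R_gr). Genes with a
zero count in either sample are excluded first. The reference sample is the
one whose 75th percentile of count fractions (linear interpolation between
order statistics) is nearest the mean of those percentiles, ties to the
lowest index. Factors are renormalized to geometric mean 1. Degenerate
cases (no shared expressed gene, everything trimmed, non-finite mean,
max |M| < 1e-6) clamp to factor 1 with a warning. Every constant (trim
fractions, weighting) is an argument. The implementation agrees with
edgeR's `calcNormFactors` (default settings) to ~1e-9 on shared matrices;
that cross-check is part of the test suite, run through `Rscript`.

**Orientation.** The TMM factor moves *inversely* with content: if sample k
gained mRNA, its unchanged genes are diluted, M is negative for the
majority, and the factor falls below 1. The estimator of C_j/C_ref — the
quantity comparable to the laboratory scales and the one BSN needs — is
therefore the *reciprocal* of the factor, rebased so the reference stage is
1. `tmm_content_scales` packages exactly that; `tmm_factors` keeps the raw
normalization-factor orientation that `tmm_log2` (voom-style
log2((R+0.5)/(R_j·Z_j+1)·10⁶)) requires. `ScaleSet` records which
convention a set of scales is in (geometric-mean-1 vs
relative-to-reference) and consumers refuse the wrong one.

**Square-root compression (`sqrt_transform`).** A legacy conservative
variant that pulls every scale toward 1. Provided for comparison; the
untransformed scales are more accurate against qPCR benchmarks and are the
default everywhere.

**Replicate-aware BSN (`bsn_replicates`).** With several samples per stage:
(a) replicates are put on their stage's mean library size; (b) a stage
matrix is formed by genewise averaging; (c) scales are estimated on that
stage matrix (TMM content scales by default, or supplied, e.g. laboratory,
scales); (d) R̄ is the mean over *all* original samples; (e) each replicate
is normalized to its stage's pseudo size. For the TMM path the stage
averages are rounded to integers before factor estimation; at library sizes
of 10⁵ and up this perturbs factors far below every tolerance used here.

## qPCR benchmark arithmetic

Ct values are referenced against an exogenous polyadenylated spike-in
(kanamycin RNA added at a fixed amount per embryo pool, so its Ct is flat
across stages) and expressed versus a control stage. Livak:
FC = 2^−ΔΔCt with ΔCt = Ct_target − Ct_ref per stage. Pfaffl replaces the
assumed doubling with measured primer efficiencies:
FC = E_t^(ΔCt_t(ctl−s)) / E_ref^(ΔCt_ref(ctl−s)); at E = 2 everywhere the
two coincide exactly (tested as an identity). Replicates are paired by
replicate id (missing pairings fall back to the replicate mean), the
reported FC is the geometric mean across replicates (fold changes are
multiplicative), dispersion is the sd of the per-replicate log2 values, and
a replicate spread above one cycle is flagged, never rejected. Efficiencies
are inputs in (1, 2.2]; standard-curve fitting is out of scope.

## Simulator

`simulate_truth` draws baseline abundances log-normal(meanlog 4, sdlog 1.5)
— a realistic several-orders-of-magnitude expression range — and applies a
multiplicative shift m_i to a seeded random fraction *f* of genes, with
log-normal magnitudes whose mean is set so the expected content ratio at
full shift equals the scenario target; the per-stage exponent
(``progress``) ramps the shift in. The *realized* scales from summing the
emitted abundances are stored as truth, not the nominal target. Scenario
defaults are the measured regimes: pre-ZGA polyadenylation (f = 0.7, content
target 1.55, i.e. within the measured 1.5–1.7× rise, stages 1-cell → 3.5 hpf)
and post-ZGA decay (f = 0.7, target 0.65, within the measured 0.6–0.7× fall,
3.5 → 5.3 hpf). `simulate_counts` allocates depth by relative abundance
(μ_ij = D_j·T_ij/C_j — expected column totals equal the depths regardless
of content, which is the entire problem) and draws gamma–Poisson counts
with var = μ + φμ², φ defaulting to 0.1 and φ = 0 giving Poisson. Depths
default to 5×10⁶, equal across stages to isolate the composition effect,
with optional log-normal jitter. `simulate_qpcr` writes matched Ct tables
(Ct = intercept − log_E T + noise, spike-in flat), so noise-free tables
invert exactly to the true fold changes, and analysing E<2 data with the
Livak assumption reproduces the closed-form bias FC^(log_E 2).

What the simulator does **not** model: gene length and GC bias, isoform
structure, correlated shift programs (shifted genes are drawn
independently of abundance), batch effects, or amplification artifacts.
Passing tests therefore demonstrate correctness of the normalization
arithmetic and the composition mechanism, not robustness to every real
library artifact.

## Benchmark statistics

Per stage pair (numerator/denominator), per-gene log2 fold changes:
linear-space matrices use log2((N₁+c)/(N₂+c)) with c = 0.5 applied only
when either value is zero (flagged); log2-space matrices subtract. The
closest-method tally credits, per gene, the method with the smallest
|log2FC − benchmark|, exact ties sharing 1/k credit each so counts conserve
the gene total; tallies are split by benchmark sign. Percent excess of
method A over B is the mean over genes of (2^lfcA/2^lfcB − 1)·100 — mean of
per-gene ratios, not ratio of means, because under the BSN/RPM identity
that choice has the exact closed form (Z_num/Z_den − 1)·100 on any
offset-free gene set, which the tests assert.

## Numerical and design choices

* Library sizes are exact integer column sums; R̄ uses the raw sizes, not
  effective ones. BSN outputs are real-valued, never re-rounded to counts.
* Zero-count genes stay at 0 in all linear methods; offsets exist only in
  `tmm_log2` (the 0.5/+1 convention of its log-CPM definition) and in the
  fold-change step (c = 0.5 on zeros only), keeping normalization itself
  offset-free.
* Value spaces are explicit (`linear` vs `log2`); mixed-space arithmetic is
  refused rather than guessed.
* HTSeq summary rows (ids starting ``__``) are stripped before library
  sizes are formed and reported separately; column order for per-sample
  files is lexicographic by filename unless an explicit order is given.
* Determinism: every stochastic routine takes a seed (`numpy` Generator);
  identical config + seed gives bit-identical output.

## Known limitations

* TMM content recovery is attenuated by between-sample overdispersion.
  With a one-sided 30% decay the estimator lands within ~5% of the true
  content ratio under Poisson (pooled-library) noise at depth 2×10⁶, but
  independent per-gene dispersion φ = 0.1 between the compared samples
  blurs the shifted-gene M-component into the unchanged majority and the
  symmetric trim then truncates the unchanged component asymmetrically;
  the estimate shrinks substantially toward 1 (the acceptance script
  reports both regimes side by side). Pooled designs — many embryos per
  library — are the favourable case.
* TMM cannot, by construction, see a shift shared by all genes: with f = 1
  and a uniform shift the factor is ≈ 1, not the shift. Laboratory scales
  or spike-ins are the only estimators in that regime; the failure is
  reproduced as a test and reported by the acceptance script.
* The weighted TMM factor is only asymptotically invariant to rescaling one
  library's depth (the precision weights carry a library-size term); the
  unweighted variant (`weighted=False`) is exactly invariant and is
  provided for sensitivity analysis.
* BSN's accuracy is bounded by the accuracy of Z_j; it corrects the global
  component of bias only. Per-gene technical effects pass through
  untouched.

## Problem sizes used in the shipped experiments

The simulation experiments in the test suite and acceptance script use
5000 genes, depths 2–5×10⁶, 10 seeds for the bias/closest-method study and
single seeded runs for the scale-recovery checks: large enough that the
realized content ratio concentrates within the scenario band and mean
biases are stable to the second decimal, small enough to keep the whole
suite in seconds.
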
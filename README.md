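# bsnorm

Between-sample normalization for RNA-seq when total mRNA content is **not**
equal between samples — with the baselines it is compared against, the
RT-qPCR benchmark arithmetic, and a ground-truth simulator of global
expression shifts.

## The problem

Standard RNA-seq normalizations assume that compared samples contain the
same total amount of (polyA⁺) mRNA per cell, embryo or organism. That
assumption fails in many real settings: early embryogenesis (cytoplasmic
polyadenylation raises the polyA⁺ pool ~1.5–1.7× before zygotic genome
activation, and miR-430–driven decay then shrinks it ~0.6–0.7×),
transcriptional amplification, cancer versus normal tissue, heat shock.
Because sequencing depth is allocated by *relative* abundance
(reads for gene *i* in sample *j* follow R_ij ∝ R_j · T_ij / Σ_i T_ij),
raw counts carry no trace of a global shift, and per-million scaling (RPM/
RPKM) or trimmed-mean-of-M-values (TMM) normalization actively removes
whatever trace remains: every fold change is then biased by the hidden
content ratio.

## Biological scaling normalization

BSN re-injects the content trajectory through per-sample global scales Z_j:

1. concentrations  E_ij = R_ij / R_j
2. average library size  R̄ = (1/n) Σ_j R_j
3. pseudo library size  L_j = R̄ · Z_j
4. normalized values  N_ij = E_ij · L_j

The scales can be **laboratory-derived** (`bio_scales`: polyA⁺ percentage of
total RNA per stage, relative to a reference stage) or **count-derived**
(`tmm_content_scales`: the reciprocal of the pairwise TMM factor, rebased to
the reference — a sample that gained content has its unchanged genes diluted
and its TMM factor drops below 1, so content is the factor's inverse). A
replicate-aware variant (`bsn_replicates`) averages replicates within stages
before the scales are estimated. Since BSN and RPM differ per sample only by
the constant R̄·Z_j/10⁶, their log2 fold changes differ *exactly* by
log2(Z_num/Z_den) for every gene — the whole disagreement between methods is
the content ratio.

Also included: `rpm`/`rpkm`, edgeR-convention `tmm_factors` (doubly trimmed,
precision-weighted; verified against `calcNormFactors` to ~1e-9), voom-style
`tmm_log2` values, Livak 2^−ΔΔCt and Pfaffl efficiency-calibrated qPCR fold
changes against a spike-in reference, and a negative-binomial simulator whose
stored ground truth makes every method's bias measurable.

## Worked example

```python
import pandas as pd
from bsnorm import CountMatrix, ScaleSet, bsn, rpm

counts = CountMatrix(pd.DataFrame(
    {"1-cell": [50, 30, 20], "3.5hpf": [100, 60, 40]},
    index=["g1", "g2", "g3"]))
z = ScaleSet(["1-cell", "3.5hpf"], [1.0, 1.5], kind="user", reference="1-cell")
print(bsn(counts, z).values)
```

prints

```
    1-cell  3.5hpf
g1    75.0   112.5
g2    45.0    67.5
g3    30.0    45.0
```

Library sizes are (100, 200), so R̄ = 150 and the pseudo sizes are
L = (150, 225): each column now sums to R̄·Z_j. Gene g1 has identical
*concentration* (0.5) in both samples — RPM would call it unchanged — but
because the 3.5 hpf embryo holds 1.5× the mRNA, BSN reports the biologically
real 1.5-fold increase (log2 FC ≈ 0.585).

The same pipeline from the shell:

```sh
bsnorm --seed 7 simulate --scenario pre_zga_polyadenylation -o sim/
bsnorm scales bio --measurements polyA.csv --reference 1-cell -o zbio.tsv
bsnorm normalize --counts sim/counts.tsv --method bsn --scales zbio.tsv -o bsn.tsv
bsnorm benchmark qpcr --ct sim/qpcr.csv --control 1-cell -o qfc.tsv
bsnorm benchmark compare --counts sim/counts.tsv --scales zbio.tsv \
    --qpcr qfc.tsv --pairs "3.5hpf/1-cell" -o report.json
```

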
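"""Between-sample normalizations: BSN, RPM/RPKM, and TMM-scaled log2 values.

Biological scaling normalization (BSN) is the four-step procedure

1. concentrations  E_ij = R_ij / R_j
2. average library size  R̄ = (1/n) Σ_j R_j
3. pseudo library size  L_j = R̄ · Z_j  for a per-sample global scale Z_j
4. normalized values  N_ij = E_ij · L_j

so each sample's column total is steered to R̄·Z_j: the normalized data
reproduce the global mRNA-content trajectory encoded in the scales instead
of forcing all samples to the same total. RPM (N_ij = E_ij·1e6) is the
Z ≡ constant special case; consequently BSN and RPM fold changes between two
samples differ *exactly* by the scale ratio Z_num/Z_den, gene by gene.

``tmm_log2`` produces the log2 counts-per-million values of a TMM-scaled
effective library (count offset 0.5, library offset 1), the representation
conventionally used downstream of TMM factors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import (
    ConcentrationMatrix,
    CountMatrix,
    NormalizedMatrix,
    PseudoLibrary,
    TranscriptLengths,
)
from .scaling import ScaleSet, tmm_content_scales

__all__ = [
    "concentrations",
    "pseudo_library",
    "bsn",
    "bsn_replicates",
    "rpm",
    "rpkm",
    "tmm_log2",
]


def _require_positive_libs(counts: CountMatrix) -> pd.Series:
    libs = counts.lib_sizes
    if (libs == 0).any():
        bad = libs.index[libs == 0].tolist()
        raise ValueError(f"zero library size for sample(s) {bad}")
    return libs.astype(float)


def _scale_series(scales: ScaleSet, sample_ids) -> pd.Series:
    s = scales.as_series()
    missing = [x for x in sample_ids if x not in s.index]
    if missing:
        raise ValueError(f"scale set missing sample(s) {missing}")
    z = s.reindex(sample_ids)
    if (z <= 0).any() or not np.isfinite(z.to_numpy()).all():
        raise ValueError("scales must be positive and finite")
    return z


def concentrations(counts: CountMatrix) -> ConcentrationMatrix:
    """Relative abundances E_ij = R_ij / R_j (each column sums to 1)."""
    libs = _require_positive_libs(counts)
    vals = counts.counts.astype(float) / libs
    return ConcentrationMatrix(values=vals, source_lib_sizes=counts.lib_sizes)


def pseudo_library(counts: CountMatrix, scales: ScaleSet) -> PseudoLibrary:
    """Average library size R̄ and pseudo sizes L_j = R̄ · Z_j."""
    z = _scale_series(scales, counts.sample_ids)
    r_bar = float(counts.lib_sizes.mean())
    return PseudoLibrary(mean_lib_size=r_bar, scales=z)


def bsn(counts: CountMatrix, scales: ScaleSet) -> NormalizedMatrix:
    """Biological scaling normalization: N_ij = E_ij · R̄ · Z_j.

    Column j of the result sums exactly to the pseudo library size
    L_j = R̄·Z_j. Values are real-valued (no rounding back to counts) and
    linear-space.
    """
    libs = _require_positive_libs(counts)
    pl = pseudo_library(counts, scales)
    e = counts.counts.astype(float) / libs
    vals = e * pl.pseudo_sizes
    return NormalizedMatrix(
        vals,
        method="bsn",
        space="linear",
        scale_provenance=f"{scales.kind}:{';'.join(scales.provenance) or 'unspecified'}",
    )


def bsn_replicates(
    counts: CountMatrix,
    groups: dict[str, str],
    scales_source: str | ScaleSet = "tmm",
) -> NormalizedMatrix:
    """Replicate-aware BSN for designs with several samples per stage.

    Steps: (a) within each stage, replicates are put on the stage's mean
    library size, N'_ij = E_ij · mean(R_j within stage); (b) a stage-level
    matrix is formed by genewise averaging of those values; (c) per-stage
    scales come either from TMM content estimation on the stage-averaged
    matrix (``scales_source="tmm"``) or from a supplied :class:`ScaleSet`
    keyed by stage; (d) the overall average library size R̄ is taken across
    *all* original samples and L_stage = R̄·Z_stage; (e) every replicate is
    normalized as N_ij = E_ij · L_stage(j).
    """
    missing = [s for s in counts.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"samples not mapped to a stage: {missing}")
    stages = list(dict.fromkeys(groups[s] for s in counts.sample_ids))
    members = {st: [s for s in counts.sample_ids if groups[s] == st] for st in stages}
    for st, mem in members.items():
        if not mem:
            raise ValueError(f"stage {st!r} has no samples")

    libs = _require_positive_libs(counts)
    e = counts.counts.astype(float) / libs

    stage_avg = {}
    for st, mem in members.items():
        mean_lib = libs[mem].mean()
        stage_avg[st] = (e[mem] * mean_lib).mean(axis=1)
    stage_df = pd.DataFrame(stage_avg)

    if isinstance(scales_source, ScaleSet):
        z = _scale_series(scales_source, stages)
        prov = f"supplied {scales_source.kind} scales"
    elif scales_source == "tmm":
        stage_counts = CountMatrix(stage_df.round().astype(np.int64))
        zset = tmm_content_scales(stage_counts)
        z = zset.as_series().reindex(stages)
        prov = "tmm content scales on stage-averaged values"
    else:
        raise ValueError(f"unknown scales_source {scales_source!r}")

    r_bar = float(libs.mean())
    l_stage = r_bar * z
    vals = e * pd.Series(
        {s: l_stage[groups[s]] for s in counts.sample_ids}
    )
    return NormalizedMatrix(
        vals, method="bsn", space="linear", scale_provenance=f"replicate-aware; {prov}"
    )


def rpm(counts: CountMatrix) -> NormalizedMatrix:
    """Reads per million mapped reads: N_ij = R_ij / R_j × 1e6."""
    libs = _require_positive_libs(counts)
    vals = counts.counts.astype(float) / libs * 1e6
    return NormalizedMatrix(vals, method="rpm", space="linear")


def rpkm(counts: CountMatrix, lengths: TranscriptLengths) -> NormalizedMatrix:
    """Reads per kilobase of transcript per million mapped reads."""
    libs = _require_positive_libs(counts)
    lens = lengths.for_genes(counts.gene_ids).astype(float)
    vals = counts.counts.astype(float).div(libs / 1e6, axis=1).div(lens / 1e3, axis=0)
    return NormalizedMatrix(vals, method="rpkm", space="linear")


def tmm_log2(counts: CountMatrix, factors: ScaleSet) -> NormalizedMatrix:
    """log2 counts-per-million on TMM effective library sizes.

    N_ij = log2( (R_ij + 0.5) / (R_j·Z_j + 1) × 1e6 ). The 0.5/1 offsets
    keep zero counts finite. ``factors`` must be TMM normalization factors
    in the geometric-mean-1 convention (the raw factor orientation, not
    content scales).
    """
    if factors.kind != "tmm" or factors.convention != "geometric-mean-1":
        raise ValueError(
            "tmm_log2 needs TMM factors in the geometric-mean-1 convention"
        )
    libs = _require_positive_libs(counts)
    z = _scale_series(factors, counts.sample_ids)
    eff = libs * z + 1.0
    vals = np.log2((counts.counts.astype(float) + 0.5) / eff * 1e6)
    return NormalizedMatrix(
        vals,
        method="tmm-log2",
        space="log2",
        scale_provenance=f"tmm:{';'.join(factors.provenance) or 'unspecified'}",
    )
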
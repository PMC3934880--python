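"""Per-sample global fold-change scales Z_j.

Two estimators of the "global fold-change" — the ratio of a sample's total
polyA+ mRNA content to a reference sample's — are provided:

* ``bio_scales``: laboratory route. Per stage, the polyA+ percentage of
  total RNA (replicates averaged as amounts first), divided by the reference
  stage's percentage. Z at the reference is exactly 1.
* ``tmm_factors`` / ``tmm_content_scales``: count-derived route via the
  trimmed mean of M-values (TMM). ``tmm_factors`` reproduces the standard
  normalization factors (doubly trimmed, precision-weighted mean of per-gene
  log2 ratios against a reference sample, renormalized to geometric mean 1).
  Those factors move *inversely* with content: a sample that gained mRNA has
  its unchanged genes diluted, so its factor drops below 1.
  ``tmm_content_scales`` therefore reports the reciprocal factor rebased to
  a reference sample, which is the count-derived estimate of C_j / C_ref and
  the quantity comparable to ``bio_scales``.

TMM by construction cannot see a shift shared by *all* genes: if every gene
changes by the same factor, relative abundances are unchanged and the factor
stays at 1. That failure mode is inherent and reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import CountMatrix
from .measurements import RnaMeasurements

__all__ = [
    "ScaleSet",
    "TmmPairStats",
    "bio_scales",
    "sqrt_transform",
    "tmm_reference",
    "tmm_pair_factor",
    "tmm_pair_stats",
    "tmm_factors",
    "tmm_content_scales",
    "rebase_scales",
]

KINDS = ("bio", "tmm", "user")
CONVENTIONS = ("relative-to-reference", "geometric-mean-1")


@dataclass
class ScaleSet:
    """Per-sample positive scales Z_j with provenance.

    ``convention`` records whether the scales are anchored at the reference
    sample (Z_ref = 1) or renormalized to geometric mean 1 (the TMM output
    convention).
    """

    sample_ids: list[str]
    scales: np.ndarray
    kind: str
    reference: str | None = None
    convention: str = "relative-to-reference"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.scales = np.asarray(self.scales, dtype=float)
        if self.kind not in KINDS:
            raise ValueError(f"unknown scale kind {self.kind!r}")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")
        if len(self.sample_ids) != self.scales.size:
            raise ValueError("sample_ids and scales length mismatch")
        if not np.all(np.isfinite(self.scales)) or np.any(self.scales <= 0):
            raise ValueError("scales must be positive and finite")
        if self.kind == "bio" and self.convention == "relative-to-reference":
            if self.reference is None or self.reference not in self.sample_ids:
                raise ValueError("bio scales need a reference sample in the set")
            if self.scales[self.sample_ids.index(self.reference)] != 1.0:
                raise ValueError("bio scales must be exactly 1 at the reference")
        if self.kind == "tmm" and self.convention == "geometric-mean-1":
            gm = np.exp(np.mean(np.log(self.scales)))
            if abs(gm - 1.0) > 1e-12:
                raise ValueError(f"tmm scales must have geometric mean 1, got {gm}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.scales, index=self.sample_ids, name="Z")

    def __getitem__(self, sample: str) -> float:
        try:
            return float(self.scales[self.sample_ids.index(sample)])
        except ValueError:
            raise KeyError(f"sample {sample!r} not in scale set") from None

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class TmmPairStats:
    """Per-gene M/A/weight statistics for one sample-vs-reference pair.

    M_g is the log2 relative-abundance ratio, A_g the average log2 relative
    abundance, and ``variance`` the delta-method (binomial) variance of M_g
    whose inverse is the precision weight. ``kept`` marks genes surviving
    the double trim (intersection of the M-rank and A-rank windows).
    """

    gene_ids: list[str]
    m_values: np.ndarray
    a_values: np.ndarray
    variance: np.ndarray
    kept: np.ndarray


def bio_scales(meas: RnaMeasurements, reference_stage: str) -> ScaleSet:
    """Laboratory scales Z_j^Bio from polyA+ percentage of total RNA.

    Per stage the percentage p_j = mean(polyA ng) / mean(total ng) × 100 is
    taken across replicates (amounts averaged before the ratio), then
    divided by the reference stage's percentage, so Z_ref is exactly 1.
    Unit-free: any consistent amount unit gives identical scales.
    """
    means = meas.stage_means()
    if reference_stage not in means.index:
        raise ValueError(f"reference stage {reference_stage!r} not measured")
    if (means["total_ng"] == 0).any():
        bad = means.index[means["total_ng"] == 0].tolist()
        raise ValueError(f"zero mean total RNA for stage(s) {bad}")
    pct = means["polya_ng"] / means["total_ng"] * 100.0
    p_ref = pct.loc[reference_stage]
    if p_ref == 0:
        raise ValueError(
            f"reference stage {reference_stage!r} has zero polyA+ percentage"
        )
    z = (pct / p_ref).to_numpy(dtype=float)
    z[list(means.index).index(reference_stage)] = 1.0
    return ScaleSet(
        sample_ids=list(means.index),
        scales=z,
        kind="bio",
        reference=reference_stage,
        convention="relative-to-reference",
        provenance=[f"polyA+ percentage relative to {reference_stage!r}"],
    )


def sqrt_transform(scales: ScaleSet) -> ScaleSet:
    """Square-root–compress a scale set (the legacy conservative variant).

    Pulls every Z_j toward 1; both anchoring conventions are preserved
    (sqrt of 1 is 1 and sqrt commutes with the geometric mean).
    """
    return ScaleSet(
        sample_ids=list(scales.sample_ids),
        scales=np.sqrt(scales.scales),
        kind=scales.kind,
        reference=scales.reference,
        convention=scales.convention,
        provenance=scales.provenance + ["sqrt transform"],
    )


def tmm_reference(counts: CountMatrix) -> str:
    """Pick the TMM reference sample by the upper-quartile rule.

    Returns the sample whose 75th percentile of count fractions R_ij/R_j
    (linear interpolation between order statistics) is closest to the mean
    of those percentiles across samples; ties break to the lowest column
    index.
    """
    if counts.n_samples < 2:
        raise ValueError("need >=2 samples to choose a TMM reference")
    libs = counts.lib_sizes.to_numpy(dtype=float)
    if (libs == 0).any():
        bad = [s for s, l in zip(counts.sample_ids, libs) if l == 0]
        raise ValueError(f"sample(s) with zero library size: {bad}")
    frac = counts.counts.to_numpy(dtype=float) / libs
    f75 = np.quantile(frac, 0.75, axis=0)
    return counts.sample_ids[int(np.argmin(np.abs(f75 - f75.mean())))]


def _pair_arrays(counts: CountMatrix, sample: str, ref: str):
    obs = counts.column(sample).astype(float)
    refc = counts.column(ref).astype(float)
    n_obs = obs.sum()
    n_ref = refc.sum()
    if n_obs == 0 or n_ref == 0:
        raise ValueError("zero library size in TMM pair")
    keep = (obs > 0) & (refc > 0)
    return obs, refc, n_obs, n_ref, keep


def tmm_pair_stats(
    counts: CountMatrix,
    sample: str,
    ref: str,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> TmmPairStats:
    """M/A/weight statistics and trim mask for one sample vs the reference.

    Genes with a zero count in either sample are excluded before anything
    else (their M is undefined). The double trim drops, by rank, the lowest
    and highest ``trim_m`` fraction of M and ``trim_a`` fraction of A; a
    gene must survive both windows to be retained. Rank windows follow the
    standard floor(n·trim)+1 … n−floor(n·trim) cut with average ranks for
    ties.
    """
    obs, refc, n_obs, n_ref, keep = _pair_arrays(counts, sample, ref)
    genes = np.asarray(counts.gene_ids, dtype=object)[keep]
    o, r = obs[keep], refc[keep]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = m.size
    if n == 0:
        return TmmPairStats(list(genes), m, a, v, np.zeros(0, dtype=bool))
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return TmmPairStats(list(genes), m, a, v, kept)


def tmm_pair_factor(
    counts: CountMatrix,
    sample: str,
    ref: str,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    weighted: bool = True,
) -> float:
    """TMM factor of one sample against the reference.

    2 to the power of the precision-weighted (weights 1/variance) mean of
    the doubly trimmed M values. Degenerate cases — no gene expressed in
    both samples, everything trimmed away, or a non-finite mean — fall back
    to a factor of exactly 1 with a warning. When every retained |M| is
    below 1e-6 the factor is exactly 1 (identity / pure depth change).
    """
    stats = tmm_pair_stats(counts, sample, ref, trim_m=trim_m, trim_a=trim_a)
    if stats.m_values.size == 0:
        warnings.warn(
            f"no gene expressed in both {sample!r} and {ref!r}; TMM factor set to 1",
            UserWarning,
            stacklevel=2,
        )
        return 1.0
    if np.max(np.abs(stats.m_values)) < 1e-6:
        return 1.0
    if not stats.kept.any():
        warnings.warn(
            f"double trim removed all genes for {sample!r} vs {ref!r}; factor set to 1",
            UserWarning,
            stacklevel=2,
        )
        return 1.0
    m = stats.m_values[stats.kept]
    if weighted:
        w = 1.0 / stats.variance[stats.kept]
        f = np.sum(m * w) / np.sum(w)
    else:
        f = np.mean(m)
    if not np.isfinite(f):
        warnings.warn("non-finite trimmed mean; TMM factor set to 1", UserWarning)
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    weighted: bool = True,
) -> ScaleSet:
    """TMM normalization factors for all samples, geometric mean 1.

    The reference sample comes from :func:`tmm_reference`; each sample gets
    its pairwise factor against it (the reference's own factor is 1), and
    the vector is divided by its geometric mean.
    """
    ref = tmm_reference(counts)
    raw = np.array(
        [
            tmm_pair_factor(counts, s, ref, trim_m=trim_m, trim_a=trim_a, weighted=weighted)
            for s in counts.sample_ids
        ]
    )
    gm = np.exp(np.mean(np.log(raw)))
    return ScaleSet(
        sample_ids=counts.sample_ids,
        scales=raw / gm,
        kind="tmm",
        reference=ref,
        convention="geometric-mean-1",
        provenance=[
            f"TMM factors vs reference {ref!r} "
            f"(trim_m={trim_m}, trim_a={trim_a}, weighted={weighted})"
        ],
    )


def tmm_content_scales(
    counts: CountMatrix,
    rebase_to: str | None = None,
    **tmm_kwargs,
) -> ScaleSet:
    """Count-derived estimate of relative mRNA content, Z_j^TMM = C_j / C_ref.

    The TMM factor of a sample varies inversely with its content (a content
    gain dilutes the unchanged genes), so the content estimate is the
    reciprocal of each factor, rebased so the reference sample sits at 1.
    ``rebase_to`` defaults to the upper-quartile TMM reference sample.
    """
    factors = tmm_factors(counts, **tmm_kwargs)
    ref = rebase_to if rebase_to is not None else factors.reference
    inv = ScaleSet(
        sample_ids=list(factors.sample_ids),
        scales=1.0 / factors.scales,
        kind="tmm",
        reference=factors.reference,
        convention="geometric-mean-1",
        provenance=factors.provenance + ["reciprocal (content orientation)"],
    )
    return rebase_scales(inv, ref)


def rebase_scales(scales: ScaleSet, reference_sample: str) -> ScaleSet:
    """Re-anchor scales so Z at ``reference_sample`` is exactly 1."""
    if reference_sample not in scales.sample_ids:
        raise ValueError(f"reference sample {reference_sample!r} not in scale set")
    z_ref = scales[reference_sample]
    z = scales.scales / z_ref
    z[scales.sample_ids.index(reference_sample)] = 1.0
    return ScaleSet(
        sample_ids=list(scales.sample_ids),
        scales=z,
        kind=scales.kind,
        reference=reference_sample,
        convention="relative-to-reference",
        provenance=scales.provenance + [f"rebased to {reference_sample!r}"],
    )
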
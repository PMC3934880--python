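"""Core containers for count and normalized expression matrices.

The central object is :class:`CountMatrix`, a genes × samples table of raw
read counts R_ij with derived library sizes R_j (column sums). Normalized
values live in :class:`NormalizedMatrix`, which records the method that
produced them and whether the values are on a linear or log2 scale —
operations downstream refuse to mix value spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ConcentrationMatrix",
    "NormalizedMatrix",
    "PseudoLibrary",
    "TranscriptLengths",
    "ParseReport",
]

VALID_METHODS = ("bsn", "rpm", "rpkm", "tmm-log2", "raw")


@dataclass
class ParseReport:
    """What a count-table parser dropped or flagged.

    ``special_rows`` maps a special feature id (HTSeq summary rows such as
    ``__no_feature``) to its per-sample counts; these never enter library
    sizes.
    """

    special_rows: dict[str, dict[str, int]] = field(default_factory=dict)
    n_genes: int = 0
    n_samples: int = 0

    @property
    def n_special_rows(self) -> int:
        return len(self.special_rows)


class CountMatrix:
    """Raw read counts R_ij for genes (rows) × samples (columns).

    Counts must be non-negative integers; gene and sample identifiers must
    be unique. Library sizes R_j are always the exact column sums.
    """

    def __init__(self, counts: pd.DataFrame, parse_report: ParseReport | None = None):
        counts = pd.DataFrame(counts)
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            frac = arr != np.floor(arr)
            if frac.any():
                i, j = np.argwhere(frac)[0]
                raise ValueError(
                    f"non-integer count {arr[i, j]!r} at gene "
                    f"{counts.index[i]!r}, sample {counts.columns[j]!r}"
                )
            counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if arr.size and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {counts.index[i]!r}, "
                f"sample {counts.columns[j]!r}"
            )
        self.counts = counts.astype(np.int64)
        self.parse_report = parse_report

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def column(self, sample: str) -> np.ndarray:
        if sample not in self.counts.columns:
            raise KeyError(f"unknown sample {sample!r}")
        return self.counts[sample].to_numpy()

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"CountMatrix({self.n_genes} genes x {self.n_samples} samples)"


@dataclass
class ConcentrationMatrix:
    """Relative transcript abundances E_ij = R_ij / R_j; columns sum to 1."""

    values: pd.DataFrame
    source_lib_sizes: pd.Series

    def __post_init__(self):
        arr = self.values.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("concentrations must be non-negative")
        colsums = arr.sum(axis=0)
        pos = self.source_lib_sizes.to_numpy() > 0
        if arr.size and not np.allclose(colsums[pos], 1.0, atol=1e-9):
            raise ValueError("concentration columns must sum to 1")


@dataclass
class PseudoLibrary:
    """Average library size R̄ and per-sample pseudo sizes L_j = R̄ · Z_j."""

    mean_lib_size: float
    scales: pd.Series  # Z_j indexed by sample

    @property
    def pseudo_sizes(self) -> pd.Series:
        return self.mean_lib_size * self.scales


class NormalizedMatrix:
    """Normalized expression values N_ij with method and value-space tags."""

    def __init__(
        self,
        values: pd.DataFrame,
        method: str,
        space: str = "linear",
        scale_provenance: str | None = None,
    ):
        if method not in VALID_METHODS:
            raise ValueError(f"unknown method {method!r}")
        if space not in ("linear", "log2"):
            raise ValueError(f"unknown value space {space!r}")
        if method == "tmm-log2" and space != "log2":
            raise ValueError("tmm-log2 values are log2-space by definition")
        self.values = pd.DataFrame(values).astype(float)
        self.method = method
        self.space = space
        self.scale_provenance = scale_provenance

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def __repr__(self) -> str:
        return (
            f"NormalizedMatrix(method={self.method!r}, space={self.space!r}, "
            f"{self.values.shape[0]} genes x {self.values.shape[1]} samples)"
        )


class TranscriptLengths:
    """Gene id → transcript length in bases (for the per-kilobase term of RPKM)."""

    def __init__(self, lengths: Mapping[str, int] | pd.Series):
        s = pd.Series(lengths, dtype=np.int64)
        if (s < 1).any():
            bad = s.index[s < 1].tolist()
            raise ValueError(f"transcript lengths must be >= 1; offending: {bad}")
        self.lengths = s

    def for_genes(self, gene_ids) -> pd.Series:
        missing = [g for g in gene_ids if g not in self.lengths.index]
        if missing:
            raise KeyError(f"missing transcript lengths for genes: {missing[:10]}")
        return self.lengths.reindex(gene_ids)
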
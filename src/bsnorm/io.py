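"""Readers and writers for the plain-text formats the package exchanges.

Count matrices travel as TSV (genes in rows, samples in columns, first
column gene id) or as a directory of per-sample HTSeq-count two-column
files. HTSeq appends five summary rows whose ids start with ``__``
(``__no_feature`` etc.); these are stripped from the counts — they must not
inflate library sizes — and tallied in the parse report. Measurement and Ct
tables are CSV. Written matrices carry ``#``-prefixed header comments
recording the method and scale provenance, and integer matrices round-trip
bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CountMatrix, NormalizedMatrix, ParseReport, TranscriptLengths
from .measurements import RnaMeasurements
from .qpcr import QpcrTable
from .scaling import ScaleSet

__all__ = [
    "read_count_table",
    "read_measurements",
    "read_qpcr_table",
    "read_lengths",
    "read_scales",
    "write_matrix",
    "write_scales",
]

HTSEQ_SPECIAL_PREFIX = "__"


def _validate_count_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{source}: non-integer count at gene {gene!r}, sample {col!r}"
            )
        neg = vals < 0
        if neg.any():
            gene = df.index[neg.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{source}: negative count at gene {gene!r}, sample {col!r}"
            )
        df[col] = vals.astype(np.int64)
    return df


def _split_special(df: pd.DataFrame) -> tuple[pd.DataFrame, ParseReport]:
    special_mask = df.index.astype(str).str.startswith(HTSEQ_SPECIAL_PREFIX)
    special = df[special_mask]
    genes = df[~special_mask]
    report = ParseReport(
        special_rows={
            str(idx): {c: int(v) for c, v in row.items()}
            for idx, row in special.iterrows()
        },
        n_genes=genes.shape[0],
        n_samples=genes.shape[1],
    )
    return genes, report


def read_count_table(
    path: str | Path,
    dialect: str = "matrix-tsv",
    sample_order: list[str] | None = None,
) -> CountMatrix:
    """Read raw counts from a TSV matrix or an HTSeq-count directory.

    ``matrix-tsv``: header row of sample ids, first column gene ids,
    ``#`` comment lines ignored. ``htseq-dir``: one two-column TSV per
    sample, sample named after the file stem, columns ordered
    lexicographically by filename unless ``sample_order`` is given; all
    files must cover the identical gene set. Gene order is first-seen
    order; HTSeq ``__*`` summary rows are removed and recorded in the
    returned matrix's ``parse_report``.
    """
    path = Path(path)
    if dialect == "matrix-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"{path}: duplicate gene id(s) {dups}")
        df = _validate_count_frame(df, str(path))
    elif dialect == "htseq-dir":
        files = sorted(p for p in path.iterdir() if p.is_file())
        if not files:
            raise ValueError(f"{path}: no HTSeq count files found")
        cols = {}
        for f in files:
            one = pd.read_csv(
                f, sep="\t", header=None, names=["gene", f.stem], index_col=0,
                comment="#", dtype=str,
            )
            if one.index.has_duplicates:
                dups = one.index[one.index.duplicated()].unique().tolist()
                raise ValueError(f"{f}: duplicate gene id(s) {dups}")
            cols[f.stem] = _validate_count_frame(one, str(f))[f.stem]
        first = next(iter(cols))
        ref_genes = set(cols[first].index)
        for name, s in cols.items():
            if set(s.index) != ref_genes:
                diff = sorted(set(s.index) ^ ref_genes)
                raise ValueError(
                    f"inconsistent gene sets between {first!r} and {name!r}; "
                    f"symmetric difference: {diff[:20]}"
                )
        order = list(cols[first].index)  # first-seen gene order
        df = pd.DataFrame({n: s.reindex(order) for n, s in cols.items()})
        if sample_order is not None:
            missing = [s for s in sample_order if s not in df.columns]
            if missing:
                raise ValueError(f"sample_order names unknown samples: {missing}")
            df = df[sample_order]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    genes, report = _split_special(df)
    return CountMatrix(genes, parse_report=report)


def read_measurements(path: str | Path) -> RnaMeasurements:
    """Read a stage/replicate total & polyA+ RNA amount CSV."""
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: no measurements")
    return RnaMeasurements(df)


def read_qpcr_table(
    path: str | Path,
    reference_gene: str = "kanamycin",
    efficiencies_path: str | Path | None = None,
) -> QpcrTable:
    """Read a Ct CSV (gene, stage, replicate, ct) and optional efficiencies.

    The efficiencies file is a two-column CSV (gene, efficiency).
    """
    df = pd.read_csv(path)
    eff = None
    if efficiencies_path is not None:
        e = pd.read_csv(efficiencies_path)
        eff = dict(zip(e.iloc[:, 0], e.iloc[:, 1].astype(float)))
    return QpcrTable(df, reference_gene=reference_gene, efficiencies=eff)


def read_lengths(path: str | Path) -> TranscriptLengths:
    """Read a two-column TSV of gene id and transcript length (bases)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "length"], comment="#")
    return TranscriptLengths(pd.Series(df["length"].values, index=df["gene"]))


def write_matrix(matrix: CountMatrix | NormalizedMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with ``#`` header comments.

    Raw counts are written as integers (bit-exact round trip); normalized
    values with 6 significant digits. The first comment line records the
    method tag, later ones the value space and scale provenance.
    """
    path = Path(path)
    if isinstance(matrix, CountMatrix):
        header = ["# method=raw"]
        df = matrix.counts
        fmt = None
    else:
        header = [f"# method={matrix.method}", f"# space={matrix.space}"]
        if matrix.scale_provenance:
            header.append(f"# scales={matrix.scale_provenance}")
        df = matrix.values
        fmt = "%.6g"
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index_label="gene", float_format=fmt)


def write_scales(scales: ScaleSet, path: str | Path) -> None:
    """Write scales as a two-column TSV plus a sibling .json provenance file."""
    path = Path(path)
    scales.as_series().to_csv(path, sep="\t", index_label="sample", header=["Z"])
    meta = {
        "kind": scales.kind,
        "reference": scales.reference,
        "convention": scales.convention,
        "provenance": scales.provenance,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_scales(path: str | Path) -> ScaleSet:
    """Read scales written by :func:`write_scales` (JSON sidecar optional)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ScaleSet(
        sample_ids=list(df.iloc[:, 0].astype(str)),
        scales=df.iloc[:, 1].to_numpy(dtype=float),
        kind=meta.get("kind", "user"),
        reference=meta.get("reference"),
        convention=meta.get("convention", "relative-to-reference"),
        provenance=meta.get("provenance", [f"read from {path.name}"]),
    )
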
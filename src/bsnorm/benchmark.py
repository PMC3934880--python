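"""Fold-change computation and method-vs-benchmark comparison.

Given normalized matrices from several methods and a benchmark (RT-qPCR
fold changes or simulation ground truth), this module computes per-gene
log2 fold changes for stage pairs (e.g. "pre-ZGA" = 3.5 hpf vs 1-cell,
"post-ZGA" = 5.3 hpf vs 3.5 hpf), counts which method lands closest to the
benchmark per gene, and summarizes the mean percent excess of one method's
linear fold changes over another's.

Because linear BSN and RPM values differ per sample only by the factor
R̄·Z_j/1e6, their fold changes differ exactly by Z_num/Z_den for every gene;
percent_excess(BSN, RPM) is therefore (Z_num/Z_den − 1)·100 on any
offset-free gene set — the closed form behind summary statements like
"pre-ZGA fold changes were 55% higher for BSN than RPM".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import NormalizedMatrix
from .qpcr import QpcrFoldChanges
from .simulate import SimTruth

__all__ = [
    "FoldChangeTable",
    "ComparisonReport",
    "fold_changes",
    "build_fold_change_table",
    "benchmark_from_truth",
    "benchmark_from_qpcr",
    "compare",
    "percent_excess",
]

ZERO_OFFSET = 0.5  # added to both values of a ratio only when either is 0


def _pair_label(num: str, den: str) -> str:
    return f"{num}/{den}"


def fold_changes(
    norm: NormalizedMatrix, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Per-gene log2 fold changes for (numerator, denominator) sample pairs.

    Linear-space matrices use log2((N_num + c)/(N_den + c)) with c = 0.5
    applied only when either value is zero (flagged in ``offset_used``);
    log2-space matrices subtract. Returns a tidy frame with columns
    gene, pair, log2_fc, offset_used.
    """
    frames = []
    for num, den in pairs:
        for s in (num, den):
            if s not in norm.values.columns:
                raise ValueError(f"unknown sample/stage {s!r}")
        a = norm.values[num].to_numpy(dtype=float)
        b = norm.values[den].to_numpy(dtype=float)
        if norm.space == "log2":
            lfc = a - b
            offset = np.zeros(a.size, dtype=bool)
        else:
            offset = (a == 0) | (b == 0)
            aa = np.where(offset, a + ZERO_OFFSET, a)
            bb = np.where(offset, b + ZERO_OFFSET, b)
            lfc = np.log2(aa / bb)
        frames.append(
            pd.DataFrame(
                {
                    "gene": norm.gene_ids,
                    "pair": _pair_label(num, den),
                    "log2_fc": lfc,
                    "offset_used": offset,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def benchmark_from_truth(
    truth: SimTruth, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Benchmark frame (gene, pair, log2_fc) from simulation ground truth."""
    frames = []
    for num, den in pairs:
        lfc = truth.log2_fold_changes(num, den)
        frames.append(
            pd.DataFrame(
                {"gene": lfc.index, "pair": _pair_label(num, den), "log2_fc": lfc.to_numpy()}
            )
        )
    return pd.concat(frames, ignore_index=True)


def benchmark_from_qpcr(
    fc: QpcrFoldChanges, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Benchmark frame from qPCR fold changes (both stages vs the control).

    The pair's log2 FC is log2FC(num) − log2FC(den); a pair member equal to
    the control stage contributes 0 by construction.
    """
    t = fc.table.set_index(["gene", "stage"])["log2_fc"]
    rows = []
    for num, den in pairs:
        genes = sorted({g for g, s in t.index if s in (num, den, fc.control_stage)})
        for g in genes:
            def stage_lfc(stage):
                if stage == fc.control_stage and (g, stage) not in t.index:
                    return 0.0
                return t.get((g, stage), np.nan)

            val = stage_lfc(num) - stage_lfc(den)
            if np.isfinite(val):
                rows.append({"gene": g, "pair": _pair_label(num, den), "log2_fc": val})
    return pd.DataFrame(rows)


@dataclass
class FoldChangeTable:
    """Wide per-gene log2 fold changes: one column per method + benchmark.

    ``table`` is indexed by (gene, pair); method columns are the method
    names passed to :func:`build_fold_change_table`, plus ``benchmark``.
    """

    table: pd.DataFrame
    methods: list[str]

    def for_pair(self, pair: str) -> pd.DataFrame:
        sub = self.table.xs(pair, level="pair")
        if sub.empty:
            raise KeyError(f"unknown stage pair {pair!r}")
        return sub

    @property
    def pairs(self) -> list[str]:
        return list(self.table.index.get_level_values("pair").unique())


def build_fold_change_table(
    norms: dict[str, NormalizedMatrix],
    pairs: list[tuple[str, str]],
    benchmark: pd.DataFrame | None = None,
) -> FoldChangeTable:
    """Assemble the wide method × benchmark fold-change table.

    ``benchmark`` is a tidy (gene, pair, log2_fc) frame, e.g. from
    :func:`benchmark_from_truth` or :func:`benchmark_from_qpcr`; when given,
    only genes with a benchmark value are retained.
    """
    if not norms:
        raise ValueError("no normalized matrices supplied")
    merged = None
    for name, nm in norms.items():
        f = fold_changes(nm, pairs)[["gene", "pair", "log2_fc"]].rename(
            columns={"log2_fc": name}
        )
        merged = f if merged is None else merged.merge(f, on=["gene", "pair"], how="inner")
    if benchmark is not None:
        b = benchmark[["gene", "pair", "log2_fc"]].rename(columns={"log2_fc": "benchmark"})
        merged = merged.merge(b, on=["gene", "pair"], how="inner")
    return FoldChangeTable(
        table=merged.set_index(["gene", "pair"]).sort_index(),
        methods=list(norms.keys()),
    )


@dataclass
class ComparisonReport:
    """Closest-method tallies per stage pair and benchmark direction.

    ``closest_counts`` rows: pair, direction (up/down/all by benchmark
    sign), n_genes, and one (possibly fractional, from ties) count column
    per method; counts sum to n_genes per row. ``deltas`` holds the
    per-gene |method − benchmark| distances in log2 units.
    """

    closest_counts: pd.DataFrame
    deltas: pd.DataFrame
    methods: list[str]

    def winner(self, pair: str, direction: str = "all") -> str:
        row = self.closest_counts[
            (self.closest_counts["pair"] == pair)
            & (self.closest_counts["direction"] == direction)
        ]
        if row.empty:
            raise KeyError(f"no tally for ({pair!r}, {direction!r})")
        return row[self.methods].iloc[0].idxmax()


def compare(fc: FoldChangeTable) -> ComparisonReport:
    """Count, per gene, which method's log2 FC is closest to the benchmark.

    Exact ties share a gene's credit equally (1/k each), so per-row counts
    always sum to the number of genes. Tallies are reported per stage pair
    for all genes and split by benchmark sign (up/down).
    """
    if "benchmark" not in fc.table.columns:
        raise ValueError("fold-change table has no benchmark column")
    methods = fc.methods
    t = fc.table.dropna(subset=["benchmark", *methods])
    dist = (t[methods].sub(t["benchmark"], axis=0)).abs()
    min_dist = dist.min(axis=1)
    is_closest = dist.eq(min_dist, axis=0)
    credit = is_closest.div(is_closest.sum(axis=1), axis=0)

    deltas = dist.copy()
    deltas["benchmark_sign"] = np.sign(t["benchmark"])

    rows = []
    pairs = t.index.get_level_values("pair")
    for pair in pd.unique(pairs):
        sel = pairs == pair
        sub_credit = credit[sel]
        sign = np.sign(t.loc[sel, "benchmark"].to_numpy())
        for direction, mask in (
            ("all", np.ones(sign.size, dtype=bool)),
            ("up", sign > 0),
            ("down", sign < 0),
        ):
            row = {"pair": pair, "direction": direction, "n_genes": int(mask.sum())}
            row.update(sub_credit[mask].sum().to_dict())
            rows.append(row)
    return ComparisonReport(
        closest_counts=pd.DataFrame(rows), deltas=deltas.reset_index(), methods=methods
    )


def percent_excess(
    fc: FoldChangeTable,
    method_a: str,
    method_b: str,
    pair: str,
    gene_set: list[str] | None = None,
) -> float:
    """Mean percent by which method A's linear FC exceeds method B's.

    mean over genes of (2^log2FC_a / 2^log2FC_b − 1) × 100. Positive means
    A's fold changes run higher; the symmetric "B lower than A" statement
    is percent_excess(b, a).
    """
    for m in (method_a, method_b):
        if m not in fc.table.columns:
            raise ValueError(f"method {m!r} not in fold-change table")
    sub = fc.for_pair(pair)
    if gene_set is not None:
        missing = [g for g in gene_set if g not in sub.index]
        if missing:
            raise ValueError(f"genes not in table: {missing[:10]}")
        sub = sub.loc[gene_set]
    if len(sub) == 0:
        raise ValueError("empty gene set")
    ratio = np.exp2(sub[method_a] - sub[method_b])
    return float((ratio - 1.0).mean() * 100.0)
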
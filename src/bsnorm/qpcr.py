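"""RT-qPCR fold-change benchmarks: spike-in–referenced ΔΔCt and Pfaffl.

Ct values for target genes are anchored against an exogenous spike-in
reference (added at a fixed amount per embryo pool, so its Ct is flat across
stages) and expressed as fold change versus a control stage:

* Livak:  ΔCt_s = Ct_target,s − Ct_ref,s;  ΔΔCt = ΔCt_s − ΔCt_control;
  FC = 2^−ΔΔCt — assumes perfect doubling per cycle.
* Pfaffl: FC = E_target^(Ct_target,ctl − Ct_target,s) /
  E_ref^(Ct_ref,ctl − Ct_ref,s) — calibrated with measured primer-pair
  amplification efficiencies E ∈ (1, 2]. At E = 2 everywhere the two
  coincide exactly.

Replicates are paired by replicate id (falling back to the mean over
available replicates when a pairing is missing); the reported fold change is
the geometric mean across replicates, with the sd of the log2 values as the
dispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QpcrTable", "QpcrFoldChanges", "livak", "pfaffl", "log2_fold_changes"]

REQUIRED_COLUMNS = ("gene", "stage", "replicate", "ct")


class QpcrTable:
    """Ct values per (gene, stage, replicate) with a spike-in reference gene.

    ``efficiencies`` maps a gene id to its primer-pair amplification
    efficiency E (fold amplification per cycle; 2 is perfect doubling).
    Values must lie in (1, 2.2] — slightly above 2 is tolerated as
    calibration noise.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        reference_gene: str = "kanamycin",
        efficiencies: dict[str, float] | None = None,
    ):
        missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        t = table.loc[:, list(REQUIRED_COLUMNS)].copy()
        t["ct"] = t["ct"].astype(float)
        if not np.isfinite(t["ct"]).all() or (t["ct"] <= 0).any():
            raise ValueError("Ct values must be finite and > 0")
        if reference_gene not in set(t["gene"]):
            raise ValueError(f"reference gene {reference_gene!r} has no Ct values")
        ref_stages = set(t.loc[t["gene"] == reference_gene, "stage"])
        target_stages = set(t.loc[t["gene"] != reference_gene, "stage"])
        orphan = target_stages - ref_stages
        if orphan:
            raise ValueError(f"stages with target Ct but no reference Ct: {sorted(orphan)}")
        if efficiencies:
            bad = {g: e for g, e in efficiencies.items() if not (1.0 < e <= 2.2)}
            if bad:
                raise ValueError(f"efficiencies outside (1, 2.2]: {bad}")
        self.table = t
        self.reference_gene = reference_gene
        self.efficiencies = dict(efficiencies or {})

    @property
    def target_genes(self) -> list[str]:
        return [g for g in pd.unique(self.table["gene"]) if g != self.reference_gene]

    @property
    def stages(self) -> list[str]:
        return list(pd.unique(self.table["stage"]))

    def ct(self, gene: str, stage: str) -> pd.Series:
        """Ct values for one gene at one stage, indexed by replicate id."""
        sel = self.table[(self.table["gene"] == gene) & (self.table["stage"] == stage)]
        return sel.set_index("replicate")["ct"]


@dataclass
class QpcrFoldChanges:
    """Fold changes vs a control stage, one row per (gene, stage).

    ``table`` columns: gene, stage, fc (linear), log2_fc, sd_log2 (NaN with
    a single replicate). Control-stage rows are 1 / 0 by construction.
    """

    table: pd.DataFrame
    method: str
    control_stage: str

    def fc(self, gene: str, stage: str) -> float:
        sel = self.table[(self.table["gene"] == gene) & (self.table["stage"] == stage)]
        if len(sel) != 1:
            raise KeyError(f"no fold change for ({gene!r}, {stage!r})")
        return float(sel["fc"].iloc[0])


def _paired(values: pd.Series, other_index) -> pd.Series:
    """Align one replicate-indexed Ct series onto another's replicate ids.

    Replicates present in both keep their own value; missing pairings get
    the series mean.
    """
    out = values.reindex(other_index)
    return out.fillna(values.mean())


def _per_replicate_log2fc(
    table: QpcrTable, gene: str, stage: str, control_stage: str, method: str
) -> np.ndarray:
    ref = table.reference_gene
    ct_t_s = table.ct(gene, stage)
    ct_t_c = table.ct(gene, control_stage)
    ct_r_s = table.ct(ref, stage)
    ct_r_c = table.ct(ref, control_stage)
    if ct_t_s.empty or ct_t_c.empty:
        raise ValueError(f"missing Ct for gene {gene!r}")
    reps = ct_t_s.index
    # pair everything onto the sample stage's replicate ids
    t_c = _paired(ct_t_c, reps)
    r_s = _paired(ct_r_s, reps)
    r_c = _paired(ct_r_c, reps)
    if method == "livak":
        d_s = ct_t_s - r_s
        d_c = t_c - r_c
        log2fc = -(d_s - d_c)
    elif method == "pfaffl":
        try:
            e_t = table.efficiencies[gene]
            e_r = table.efficiencies[ref]
        except KeyError as exc:
            raise ValueError(f"missing primer efficiency for {exc.args[0]!r}") from None
        if e_t <= 1.0 or e_r <= 1.0:
            raise ValueError("primer efficiencies must exceed 1")
        log2fc = (t_c - ct_t_s) * np.log2(e_t) - (r_c - r_s) * np.log2(e_r)
    else:  # pragma: no cover
        raise ValueError(f"unknown method {method!r}")
    vals = log2fc.to_numpy(dtype=float)
    if vals.size > 1 and (vals.max() - vals.min()) > 1.0:
        warnings.warn(
            f"replicate ΔCt spread exceeds 1 cycle for ({gene!r}, {stage!r})",
            UserWarning,
            stacklevel=3,
        )
    return vals


def _fold_changes(table: QpcrTable, control_stage: str, method: str) -> QpcrFoldChanges:
    if control_stage not in table.stages:
        raise ValueError(f"control stage {control_stage!r} not in Ct table")
    rows = []
    for gene in table.target_genes:
        gene_stages = pd.unique(
            table.table.loc[table.table["gene"] == gene, "stage"]
        )
        for stage in gene_stages:
            log2fc = _per_replicate_log2fc(table, gene, stage, control_stage, method)
            mean_log2 = float(np.mean(log2fc))
            sd_log2 = float(np.std(log2fc, ddof=1)) if log2fc.size > 1 else np.nan
            rows.append(
                {
                    "gene": gene,
                    "stage": stage,
                    "fc": 2.0**mean_log2,
                    "log2_fc": mean_log2,
                    "sd_log2": sd_log2,
                }
            )
    return QpcrFoldChanges(
        table=pd.DataFrame(rows), method=method, control_stage=control_stage
    )


def livak(table: QpcrTable, control_stage: str) -> QpcrFoldChanges:
    """Spike-in–referenced 2^−ΔΔCt fold changes vs the control stage."""
    return _fold_changes(table, control_stage, "livak")


def pfaffl(table: QpcrTable, control_stage: str) -> QpcrFoldChanges:
    """Efficiency-calibrated fold changes vs the control stage."""
    return _fold_changes(table, control_stage, "pfaffl")


def log2_fold_changes(fc: QpcrFoldChanges) -> pd.DataFrame:
    """Per (gene, stage) log2 fold-change table."""
    return fc.table[["gene", "stage", "log2_fc"]].copy()
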
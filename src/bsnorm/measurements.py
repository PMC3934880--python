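"""Per-stage total and polyA+ RNA amount measurements.

These are bench measurements (ng per fixed number of embryos) of total RNA
and of the polyA+ fraction, replicated per developmental stage. They are the
laboratory route to the global scaling factors: the polyA+ percentage of
total RNA per stage, divided by the reference stage's percentage.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = ["RnaMeasurements"]

REQUIRED_COLUMNS = ("stage", "replicate", "total_ng", "polya_ng")


class RnaMeasurements:
    """Replicated total / polyA+ RNA amounts (ng) per stage.

    A replicate where the polyA+ amount exceeds the total is flagged with a
    warning rather than rejected: both quantities are measured on different
    instruments with high variance at small amounts.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"measurement table missing columns: {missing}")
        if len(table) == 0:
            raise ValueError("no measurements")
        t = table.loc[:, list(REQUIRED_COLUMNS)].copy()
        t["total_ng"] = t["total_ng"].astype(float)
        t["polya_ng"] = t["polya_ng"].astype(float)
        if (t["total_ng"] < 0).any() or (t["polya_ng"] < 0).any():
            raise ValueError("RNA amounts must be non-negative")
        excess = t["polya_ng"] > t["total_ng"]
        if excess.any():
            rows = t.loc[excess, ["stage", "replicate"]].itertuples(index=False)
            warnings.warn(
                "polyA+ amount exceeds total RNA in replicate(s): "
                + ", ".join(f"{r.stage}/{r.replicate}" for r in rows),
                UserWarning,
                stacklevel=2,
            )
        self.table = t

    @property
    def stages(self) -> list[str]:
        return list(pd.unique(self.table["stage"]))

    def stage_means(self) -> pd.DataFrame:
        """Mean total and polyA+ amount per stage (amounts averaged first)."""
        g = self.table.groupby("stage", sort=False)[["total_ng", "polya_ng"]].mean()
        return g

    def __len__(self) -> int:
        return len(self.table)
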
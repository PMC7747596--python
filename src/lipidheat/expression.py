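"""Relative gene expression by the delta-delta-CT method.

qRT-PCR cycle-threshold values for target genes (here the fatty-acid
desaturases FAD2-1, FAD2-2, FAD3-1, FAD3-2) are normalized to a reference
gene (Actin-7) per biological replicate (technical replicates averaged
first), and expressed as a fold change of the heat treatment relative to the
ambient calibrator:

    dCT   = CT_target - CT_reference          (per biological replicate)
    ddCT  = mean dCT(HT) - mean dCT(AT)
    fold  = 2 ** -ddCT

Amplification efficiency is fixed at 2 (no efficiency correction).  A fold
change beyond a threshold (1.5 by default) in either direction is called
up/down; no statistical test is attached to the call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union
from pathlib import Path

import numpy as np
import pandas as pd

CT_COLUMNS = ["genotype", "treatment", "biological_rep", "technical_rep", "gene", "ct"]
DEFAULT_REFERENCE = "Actin-7"
DEFAULT_FOLD_THRESHOLD = 1.5


class ExpressionError(ValueError):
    pass


def read_ct_csv(path: Union[str, Path]) -> pd.DataFrame:
    ct = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ExpressionError(f"CT table missing column(s): {missing}")
    return ct


class RelativeExpression:
    """ddCT model over a long-format CT table.

    Parameters
    ----------
    ct_table : DataFrame with columns genotype, treatment, biological_rep,
        technical_rep, gene, ct.
    reference : reference (housekeeping) gene name.
    calibrator : treatment level used as the calibrator (denominator).
    """

    def __init__(
        self,
        ct_table: pd.DataFrame,
        reference: str = DEFAULT_REFERENCE,
        calibrator: str = "AT",
    ):
        missing = [c for c in CT_COLUMNS if c not in ct_table.columns]
        if missing:
            raise ExpressionError(f"CT table missing column(s): {missing}")
        if (ct_table["ct"] <= 0).any():
            bad = ct_table.loc[ct_table["ct"] <= 0]
            raise ExpressionError(f"non-positive CT values in {len(bad)} row(s)")
        if reference not in set(ct_table["gene"]):
            raise ExpressionError(f"reference gene {reference!r} absent from CT table")
        self.ct = ct_table.copy()
        self.reference = reference
        self.calibrator = calibrator

    def fit(self, threshold: float = DEFAULT_FOLD_THRESHOLD) -> "ExpressionResults":
        # technical replicates first, then dCT per biological replicate
        bio = (
            self.ct.groupby(
                ["genotype", "treatment", "biological_rep", "gene"], observed=True
            )["ct"]
            .mean()
            .reset_index()
        )
        ref = bio[bio["gene"] == self.reference].rename(columns={"ct": "ct_ref"})
        targets = bio[bio["gene"] != self.reference]
        merged = targets.merge(
            ref[["genotype", "treatment", "biological_rep", "ct_ref"]],
            on=["genotype", "treatment", "biological_rep"],
            how="left",
        )
        if merged["ct_ref"].isna().any():
            bad = merged.loc[merged["ct_ref"].isna(),
                             ["genotype", "treatment", "biological_rep"]]
            raise ExpressionError(
                f"missing reference-gene rows for: {bad.drop_duplicates().to_dict('records')}"
            )
        merged["dct"] = merged["ct"] - merged["ct_ref"]

        rows = []
        for (g, gene), sub in merged.groupby(["genotype", "gene"], observed=True):
            cal = sub.loc[sub["treatment"] == self.calibrator, "dct"]
            other = sub.loc[sub["treatment"] != self.calibrator]
            if cal.empty or other.empty:
                raise ExpressionError(
                    f"{g}/{gene}: need both treatments (calibrator {self.calibrator})"
                )
            treatment = other["treatment"].iloc[0]
            ddct = other["dct"].mean() - cal.mean()
            fold = float(2.0 ** (-ddct))
            rows.append(
                {"genotype": g, "gene": gene, "treatment": treatment,
                 "ddct": float(ddct), "fold": fold}
            )
        table = pd.DataFrame(rows)
        return ExpressionResults(table=table, threshold=threshold,
                                 reference=self.reference, calibrator=self.calibrator)


@dataclass
class ExpressionResults:
    """Fold changes (2^-ddCT) per genotype x gene with direction calls."""

    table: pd.DataFrame
    threshold: float
    reference: str
    calibrator: str

    def calls(self, threshold: Optional[float] = None) -> pd.DataFrame:
        """Direction call per genotype x gene: 'up' if fold > threshold,
        'down' if fold < 1/threshold, else 'nc'."""
        th = self.threshold if threshold is None else threshold
        out = self.table.copy()
        out["call"] = np.where(
            out["fold"] > th, "up", np.where(out["fold"] < 1.0 / th, "down", "nc")
        )
        return out

    def summary(self) -> str:
        out = self.calls()
        return (
            f"Relative expression (2^-ddCT) vs {self.reference}, "
            f"calibrator {self.calibrator}, call threshold {self.threshold}\n"
            + out.to_string(index=False, float_format=lambda v: f"{v:.3f}")
        )


def ddct_fold_change(
    ct_table: pd.DataFrame,
    reference: str = DEFAULT_REFERENCE,
    calibrator: str = "AT",
    threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> ExpressionResults:
    """Functional wrapper around :class:`RelativeExpression`."""
    return RelativeExpression(ct_table, reference, calibrator).fit(threshold)
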
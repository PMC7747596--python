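"""Lipid signal tables: containers, CSV I/O, normalization, and QC filtering.

A study is a wide sample x analyte matrix of normalized mass-spectral signal
per mg anther dry weight (1.0 = signal of 1 nmol internal standard) together
with sample metadata (genotype, treatment AT/HT, year, block, replicate, and a
QC-pool flag).  Analytes are dropped when their mean signal falls below the
limit of detection or their coefficient of variation over the quality-control
pool exceeds a cutoff in any year.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .nomenclature import LipidSpecies, format_lipid_name, parse_lipid_name

#: Default limit of detection, in normalized-signal units (nmol equivalents).
DEFAULT_LOD = 0.00005
#: Default maximum coefficient of variation over QC-pool samples.
DEFAULT_COV_MAX = 0.3

META_COLUMNS = ["genotype", "treatment", "year", "block", "replicate", "is_qc_pool"]


class Unit(str, Enum):
    SIGNAL = "signal_per_mg_dw"
    PERCENT = "percent_of_total"


class DatasetError(ValueError):
    pass


@dataclass
class LipidDataset:
    """Sample metadata plus a samples x analytes signal matrix.

    ``values``: DataFrame indexed by sample_id with analyte shorthand columns.
    ``meta``: DataFrame indexed by sample_id with columns
    genotype/treatment/year/block/replicate/is_qc_pool.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    unit: Unit = Unit.SIGNAL

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise DatasetError(f"duplicate sample_id(s): {dupes}")
        missing = self.values.index.difference(self.meta.index)
        if len(missing):
            raise DatasetError(f"samples missing from metadata: {list(missing)}")
        if (self.values.to_numpy() < 0).any():
            raise DatasetError("negative signal values")
        self.meta = self.meta.loc[self.values.index]

    # -- basic views ------------------------------------------------------

    @property
    def analyte_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def species(self) -> list[LipidSpecies]:
        return [parse_lipid_name(c) for c in self.values.columns]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    def experimental(self) -> "LipidDataset":
        """Subset to non-QC-pool samples."""
        keep = ~self.meta["is_qc_pool"].astype(bool)
        return LipidDataset(self.values.loc[keep], self.meta.loc[keep], self.unit)

    def qc_pool(self) -> "LipidDataset":
        keep = self.meta["is_qc_pool"].astype(bool)
        return LipidDataset(self.values.loc[keep], self.meta.loc[keep], self.unit)

    def select_analytes(self, names: Sequence[str]) -> "LipidDataset":
        return LipidDataset(self.values[list(names)], self.meta, self.unit)

    # -- I/O --------------------------------------------------------------

    def to_csv(self, values_path: Union[str, Path], meta_path: Union[str, Path]) -> None:
        self.values.rename_axis("sample_id").to_csv(values_path)
        self.meta.rename_axis("sample_id").to_csv(meta_path)


def read_lipid_csv(
    path: Union[str, Path],
    meta_path: Union[str, Path],
    unit: Unit = Unit.SIGNAL,
) -> LipidDataset:
    """Read a wide lipid CSV (first column sample_id, remaining columns lipid
    shorthand names) and its metadata CSV keyed by sample_id.

    Every header must parse as a lipid name; offenders are reported together.
    """
    values = pd.read_csv(path, index_col=0)
    values.index = values.index.astype(str)
    meta = pd.read_csv(meta_path, index_col=0)
    meta.index = meta.index.astype(str)

    bad = []
    for col in values.columns:
        try:
            parse_lipid_name(col)
        except Exception:
            bad.append(col)
    if bad:
        raise DatasetError(f"unparseable analyte headers: {bad}")

    missing_meta = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_meta:
        raise DatasetError(f"metadata missing columns: {missing_meta}")
    meta["is_qc_pool"] = meta["is_qc_pool"].astype(bool)
    return LipidDataset(values, meta, unit)


def percent_of_total(ds: LipidDataset) -> LipidDataset:
    """Convert each sample row to percent of its total signal (rows sum to 100)."""
    if ds.unit is Unit.PERCENT:
        raise DatasetError("dataset already in percent_of_total units")
    totals = ds.values.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise DatasetError(f"zero total signal for sample(s): {list(zero.index)}")
    vals = ds.values.div(totals, axis=0) * 100.0
    return LipidDataset(vals, ds.meta, Unit.PERCENT)


@dataclass
class QCReport:
    """Per-analyte, per-year LOD/CoV statistics and verdicts.

    ``table`` columns: analyte, year, mean_signal, qc_cov, verdict
    (pass | below_LOD | high_CoV). An analyte is dropped globally if it fails
    in any year.
    """

    table: pd.DataFrame
    lod: float
    cov_max: float

    @property
    def kept(self) -> list[str]:
        failed = set(self.table.loc[self.table["verdict"] != "pass", "analyte"])
        seen: list[str] = []
        for a in self.table["analyte"]:
            if a not in failed and a not in seen:
                seen.append(a)
        return seen

    @property
    def dropped(self) -> list[str]:
        failed = []
        for a in self.table["analyte"]:
            if a not in failed and (self.table.loc[self.table["analyte"] == a, "verdict"] != "pass").any():
                failed.append(a)
        return failed

    def to_csv(self, path: Union[str, Path]) -> None:
        self.table.to_csv(path, index=False)


def qc_filter(
    ds: LipidDataset,
    qc_pool: Optional[LipidDataset] = None,
    lod: float = DEFAULT_LOD,
    cov_max: float = DEFAULT_COV_MAX,
) -> tuple[LipidDataset, QCReport]:
    """Drop analytes below the limit of detection or with excessive QC-pool
    coefficient of variation in any year.

    The LOD test is on the analyte's mean signal over experimental samples
    within each year; the CoV is the sample (n-1) standard deviation divided
    by the mean over QC-pool samples within each year.  ``qc_pool`` defaults
    to the QC-flagged rows of ``ds`` itself.
    """
    if ds.unit is not Unit.SIGNAL:
        raise DatasetError("qc_filter requires raw signal units")
    exp = ds.experimental()
    if qc_pool is None:
        qc_pool = ds.qc_pool()
    qc = qc_pool.qc_pool() if qc_pool.meta["is_qc_pool"].astype(bool).any() else qc_pool

    years = sorted(exp.meta["year"].unique())
    rows = []
    for year in years:
        e = exp.values.loc[exp.meta["year"] == year]
        q = qc.values.loc[qc.meta["year"] == year]
        if q.shape[0] < 2:
            raise DatasetError(f"year {year}: fewer than 2 QC-pool samples, CoV undefined")
        means = e.mean(axis=0)
        qmean = q.mean(axis=0)
        qsd = q.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = qsd / qmean
        for analyte in ds.analyte_names:
            m = means[analyte]
            cv = cov[analyte]
            if m < lod:
                verdict = "below_LOD"
            elif not np.isfinite(cv) or cv > cov_max:
                verdict = "high_CoV"
            else:
                verdict = "pass"
            rows.append(
                {"analyte": analyte, "year": year, "mean_signal": m,
                 "qc_cov": cv, "verdict": verdict}
            )
    report = QCReport(pd.DataFrame(rows), lod=lod, cov_max=cov_max)
    kept = report.kept
    return ds.select_analytes(kept), report


def group_cells(
    ds: LipidDataset, by: Sequence[str]
) -> "pd.core.groupby.generic.DataFrameGroupBy":
    """Group experimental samples by metadata columns (e.g. genotype, treatment)."""
    exp = ds.experimental()
    bad = [c for c in by if c not in exp.meta.columns]
    if bad:
        raise DatasetError(f"unknown grouping column(s): {bad}")
    keys = [exp.meta[c] for c in by]
    return exp.values.groupby(keys)
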
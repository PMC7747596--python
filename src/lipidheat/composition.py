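"""Descriptive lipidome metrics.

Class and molecular-species composition, unsaturation indices (double bonds
per acyl chain, amount-weighted at the class level), occurrence-weighted
fatty-acid totals and HT/AT fold changes, the PC 18:3/18:2 fatty-acid ratio,
and the TAG:PC ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import DatasetError, LipidDataset, Unit
from .nomenclature import (
    AcylChain,
    AmbiguousCompositionError,
    Headgroup,
    LipidSpecies,
    assigned_chains,
    chain_count,
    parse_lipid_name,
)

#: Default molecular-species pooling set: the diacyl "structural glycerolipid"
#: classes (TAG and sterol lipids excluded).
STRUCTURAL_GLYCEROLIPIDS = frozenset(
    {
        Headgroup.PC,
        Headgroup.PE,
        Headgroup.PI,
        Headgroup.PA,
        Headgroup.PG,
        Headgroup.MGDG,
        Headgroup.SQDG,
        Headgroup.DAG,
    }
)

#: Fatty acids tracked in the decomposition tables.
MAJOR_FATTY_ACIDS = (
    AcylChain(16, 0),
    AcylChain(16, 1),
    AcylChain(18, 0),
    AcylChain(18, 1),
    AcylChain(18, 2),
    AcylChain(18, 3),
)


def _grouped_means(ds: LipidDataset, by: Optional[Sequence[str]]) -> pd.DataFrame:
    """Mean analyte values per grouping cell (or a single pooled cell)."""
    exp = ds.experimental()
    if not by:
        return exp.values.mean(axis=0).to_frame(name="all").T
    keys = [exp.meta[c] for c in by]
    out = exp.values.groupby(keys, observed=True).mean()
    if out.isna().any().any() or out.shape[0] == 0:
        raise DatasetError("empty grouping cell")
    return out


def class_composition(
    ds: LipidDataset, by: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Percent of total signal per headgroup class, averaged per grouping cell.

    Requires percent-of-total units; rows (cells) sum to 100.
    """
    if ds.unit is not Unit.PERCENT:
        raise DatasetError("class_composition requires percent_of_total units")
    classes = pd.Index([sp.headgroup.value for sp in ds.species])
    means = _grouped_means(ds, by)
    return means.T.groupby(classes).sum().T


def species_composition(
    ds: LipidDataset,
    classes: Iterable[Headgroup] = STRUCTURAL_GLYCEROLIPIDS,
    by: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pool analytes of the selected classes by total carbons:double bonds and
    express each key as percent of the pooled total, per grouping cell."""
    if ds.unit is not Unit.PERCENT:
        raise DatasetError("species_composition requires percent_of_total units")
    classes = frozenset(classes)
    if not classes:
        raise DatasetError("empty class set")
    cols, keys = [], []
    for name, sp in zip(ds.analyte_names, ds.species):
        if sp.headgroup in classes:
            cols.append(name)
            keys.append(f"{sp.total_carbons}:{sp.total_double_bonds}")
    if not cols:
        raise DatasetError("class set selects no analytes")
    means = _grouped_means(ds.select_analytes(cols), by)
    pooled = means.T.groupby(pd.Index(keys)).sum().T
    return pooled.div(pooled.sum(axis=1), axis=0) * 100.0


def unsaturation_index_species(species: LipidSpecies) -> float:
    """Double bonds per acyl chain for one molecular species."""
    n = chain_count(species)
    if n == 0:
        raise DatasetError(f"{species}: no acyl chains, unsaturation index undefined")
    return species.total_double_bonds / n


def unsaturation_index_class(
    ds: LipidDataset,
    headgroup: Headgroup,
    by: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Amount-weighted mean of species unsaturation indices within one class,
    per grouping cell. Cells with zero class total come back as NaN."""
    cols, ui = [], []
    for name, sp in zip(ds.analyte_names, ds.species):
        if sp.headgroup is headgroup:
            cols.append(name)
            ui.append(unsaturation_index_species(sp))
    if not cols:
        raise DatasetError(f"no analytes in class {headgroup.value}")
    means = _grouped_means(ds.select_analytes(cols), by)
    w = np.asarray(ui)
    totals = means.sum(axis=1)
    num = means.to_numpy() @ w
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(totals.to_numpy() > 0, num / totals.to_numpy(), np.nan)
    return pd.Series(idx, index=means.index, name=f"UI_{headgroup.value}")


def unsaturation_index_per_sample(
    ds: LipidDataset, headgroup: Headgroup
) -> pd.Series:
    """Per-sample class unsaturation index (for downstream cell-mean models)."""
    cols, ui = [], []
    for name, sp in zip(ds.analyte_names, ds.species):
        if sp.headgroup is headgroup:
            cols.append(name)
            ui.append(unsaturation_index_species(sp))
    if not cols:
        raise DatasetError(f"no analytes in class {headgroup.value}")
    vals = ds.experimental().values[cols]
    totals = vals.sum(axis=1)
    num = vals.to_numpy() @ np.asarray(ui)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(totals.to_numpy() > 0, num / totals.to_numpy(), np.nan)
    return pd.Series(out, index=vals.index, name=f"UI_{headgroup.value}")


@dataclass
class FattyAcidTable:
    """Occurrence-weighted fatty-acid amounts (and optionally fold changes)
    for one lipid class, with the species excluded as ambiguous."""

    amounts: pd.Series           # fatty acid label -> summed amount
    excluded: list[str]          # analyte names with ambiguous composition
    fold_change: Optional[pd.Series] = None  # HT/AT; NaN = undefined


def fatty_acid_totals(
    ds: LipidDataset,
    headgroup: Headgroup,
    assignment: Optional[Mapping] = None,
    fatty_acids: Sequence[AcylChain] = MAJOR_FATTY_ACIDS,
    per_sample: bool = False,
):
    """Sum amount x occurrences of each fatty acid over the class's
    unambiguously assignable species.

    Species with neither explicit chains nor an assignment contribute nothing
    and are listed in the exclusion log.  With ``per_sample`` a DataFrame of
    per-sample totals is returned instead of the mean over samples.
    """
    fa_labels = [str(fa) for fa in fatty_acids]
    occ = []  # (analyte, occurrence vector)
    excluded = []
    for name, sp in zip(ds.analyte_names, ds.species):
        if sp.headgroup is not headgroup:
            continue
        try:
            chains = assigned_chains(sp, assignment)
        except AmbiguousCompositionError:
            excluded.append(name)
            continue
        occ.append((name, [sum(1 for ch in chains if ch == fa) for fa in fatty_acids]))
    exp = ds.experimental()
    if not occ:
        zeros = pd.Series(0.0, index=fa_labels)
        if per_sample:
            return pd.DataFrame(0.0, index=exp.values.index, columns=fa_labels), excluded
        return FattyAcidTable(zeros, excluded)
    names = [n for n, _ in occ]
    w = np.asarray([v for _, v in occ], dtype=float)  # species x fa
    per = pd.DataFrame(
        exp.values[names].to_numpy() @ w, index=exp.values.index, columns=fa_labels
    )
    if per_sample:
        return per, excluded
    return FattyAcidTable(per.mean(axis=0), excluded)


def fatty_acid_fold_change(
    ds: LipidDataset,
    headgroup: Headgroup,
    genotype: Optional[str] = None,
    assignment: Optional[Mapping] = None,
    fatty_acids: Sequence[AcylChain] = MAJOR_FATTY_ACIDS,
) -> FattyAcidTable:
    """HT/AT ratio of the mean occurrence-weighted fatty-acid sums, optionally
    within one genotype. Zero AT denominators yield NaN (flagged undefined)."""
    per, excluded = fatty_acid_totals(
        ds, headgroup, assignment, fatty_acids, per_sample=True
    )
    meta = ds.experimental().meta
    mask = np.ones(len(meta), dtype=bool)
    if genotype is not None:
        mask = (meta["genotype"] == genotype).to_numpy()
    treat = meta["treatment"].to_numpy()
    at = per.loc[mask & (treat == "AT")]
    ht = per.loc[mask & (treat == "HT")]
    if len(at) == 0 or len(ht) == 0:
        raise DatasetError("both AT and HT samples are required for fold change")
    at_mean = at.mean(axis=0)
    ht_mean = ht.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = ht_mean / at_mean
    fold = fold.where(at_mean > 0, np.nan)
    return FattyAcidTable(at_mean, excluded, fold_change=fold)


def pc_18_3_to_18_2_ratio(
    ds: LipidDataset,
    by: Optional[Sequence[str]] = None,
    assignment: Optional[Mapping] = None,
) -> pd.Series:
    """Ratio of occurrence-weighted 18:3 to 18:2 totals within PC, computed
    per sample and averaged per grouping cell.  Zero denominators give NaN."""
    per, _ = fatty_acid_totals(
        ds, Headgroup.PC, assignment,
        fatty_acids=(AcylChain(18, 3), AcylChain(18, 2)), per_sample=True,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = per["18:3"] / per["18:2"]
    ratio = ratio.where(per["18:2"] > 0, np.nan)
    meta = ds.experimental().meta
    if not by:
        return pd.Series({"all": ratio.mean()}, name="PC_18:3/18:2")
    return ratio.groupby([meta[c] for c in by], observed=True).mean()


def tag_pc_ratio(
    ds: LipidDataset, by: Optional[Sequence[str]] = None
) -> pd.Series:
    """Per-sample TAG total over PC total, averaged per grouping cell."""
    tag_cols = [n for n, sp in zip(ds.analyte_names, ds.species) if sp.headgroup is Headgroup.TAG]
    pc_cols = [n for n, sp in zip(ds.analyte_names, ds.species) if sp.headgroup is Headgroup.PC]
    if not tag_cols or not pc_cols:
        raise DatasetError("dataset lacks TAG or PC analytes")
    exp = ds.experimental()
    pc_tot = exp.values[pc_cols].sum(axis=1)
    zero = pc_tot[pc_tot == 0]
    if len(zero):
        raise DatasetError(f"zero PC total for sample(s): {list(zero.index)}")
    ratio = exp.values[tag_cols].sum(axis=1) / pc_tot
    if not by:
        return pd.Series({"all": ratio.mean()}, name="TAG:PC")
    return ratio.groupby([exp.meta[c] for c in by], observed=True).mean()
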
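"""Lipid co-occurrence analysis: Spearman correlation over samples,
single-linkage hierarchical clustering, threshold groups, and heat-response
direction annotation.

Lipids undergoing coordinated metabolism rise and fall together across
samples; they are detected as groups in which each member correlates with at
least one other member at Spearman rho >= a threshold (0.90 by default).
Those groups are exactly the size->=2 connected components of the graph with
an edge wherever rho >= threshold, which in turn equal the clusters obtained
by cutting the single-linkage tree (distance 1 - rho) at the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .dataset import LipidDataset


class CooccurrenceError(ValueError):
    pass


def spearman_matrix(ds: LipidDataset) -> pd.DataFrame:
    """Pairwise Spearman rho over experimental samples (average ranks for
    ties).  Zero-variance analytes get NaN rows/columns (excluded from
    clustering) and a warning."""
    exp = ds.experimental()
    if exp.n_samples < 3:
        raise CooccurrenceError("need >= 3 samples for a Spearman matrix")
    vals = exp.values.to_numpy()
    names = exp.analyte_names
    const = [n for n, v in zip(names, vals.T) if np.ptp(v) == 0]
    if const:
        warnings.warn(f"zero-variance analyte(s) excluded: {const}", stacklevel=2)
    ranks = np.apply_along_axis(stats.rankdata, 0, vals)  # average ranks for ties
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    out = pd.DataFrame(rho, index=names, columns=names)
    np.fill_diagonal(out.to_numpy(), 1.0)
    for n in const:
        out.loc[n, :] = np.nan
        out.loc[:, n] = np.nan
    return out


def single_linkage_tree(rho: pd.DataFrame) -> np.ndarray:
    """Single-linkage merge tree on distance d = 1 - rho (NaN analytes must be
    removed first).  Returns a scipy linkage matrix whose heights are the
    1 - rho merge distances."""
    valid = rho.notna().all(axis=1)
    r = rho.loc[valid, valid].to_numpy()
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    condensed = d[np.triu_indices_from(d, k=1)]
    return hierarchy.linkage(condensed, method="single")


def extract_groups(rho: pd.DataFrame, threshold: float = 0.90) -> list[set[str]]:
    """Connected components (size >= 2) of the graph with an edge where
    rho >= threshold; identical to cutting the single-linkage tree at the
    threshold similarity.  Groups come back sorted by size then name."""
    names = [n for n in rho.index if rho.loc[n].notna().all()]
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if rho.loc[a, b] >= threshold:
                parent[find(a)] = find(b)
    comps: dict[str, set[str]] = {}
    for n in names:
        comps.setdefault(find(n), set()).add(n)
    groups = [g for g in comps.values() if len(g) >= 2]
    groups.sort(key=lambda g: (-len(g), sorted(g)[0]))
    return groups


def export_newick(tree: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Newick string for a linkage tree, ultrametric branch lengths derived
    from the 1 - rho merge heights (each child branch spans the height
    difference to its parent; leaves sit at height 0)."""
    n = len(leaf_names)
    if tree.shape[0] != n - 1:
        raise CooccurrenceError("leaf count does not match the merge tree")
    height = {i: 0.0 for i in range(n)}
    label = {i: _quote(leaf_names[i]) for i in range(n)}
    for k, (i, j, dist, _) in enumerate(tree):
        node = n + k
        h = dist / 2.0  # ultrametric: both subtrees sit at half the merge distance
        i, j = int(i), int(j)
        bi = max(h - height[i], 0.0)
        bj = max(h - height[j], 0.0)
        label[node] = f"({label[i]}:{bi:g},{label[j]}:{bj:g})"
        height[node] = h
    return label[2 * n - 2] + ";"


def _quote(name: str) -> str:
    # Newick reserves ()[]:;, and whitespace; quote labels containing them
    if any(c in name for c in "()[]:;, '"):
        return "'" + name.replace("'", "''") + "'"
    return name


class Cooccurrence:
    """Co-occurrence model over a lipid dataset.

    Parameters
    ----------
    ds : LipidDataset (all experimental samples, treatments pooled).
    threshold : Spearman rho defining group membership (default 0.90).
    """

    def __init__(self, ds: LipidDataset, threshold: float = 0.90):
        if not -1 <= threshold <= 1:
            raise CooccurrenceError("threshold must be a correlation in [-1, 1]")
        self.ds = ds
        self.threshold = threshold

    def fit(self, stats_results: Optional[pd.DataFrame] = None) -> "CooccurrenceResults":
        """Compute the Spearman matrix, merge tree, and threshold groups.

        ``stats_results`` (optional) is a per-analyte AT-vs-HT table with
        columns ``diff_ht_minus_at`` and ``significant`` (as produced by the
        factorial model per analyte) used to annotate directions.
        """
        rho = spearman_matrix(self.ds)
        valid = [n for n in rho.index if rho.loc[n].notna().all()]
        tree = single_linkage_tree(rho)
        groups = extract_groups(rho, self.threshold)
        directions = None
        if stats_results is not None:
            directions = annotate_directions(rho.index, stats_results)
        return CooccurrenceResults(
            rho=rho, merge_tree=tree, leaf_names=valid,
            groups=groups, threshold=self.threshold, directions=directions,
        )


def annotate_directions(
    analytes: Sequence[str], stats_results: pd.DataFrame
) -> pd.Series:
    """Per-analyte heat response: 'up'/'down' when the AT-vs-HT contrast is
    significant, 'ns' otherwise (or when the analyte is missing from stats)."""
    out = {}
    for name in analytes:
        if name not in stats_results.index:
            warnings.warn(f"analyte {name!r} missing from stats; marked ns", stacklevel=2)
            out[name] = "ns"
            continue
        row = stats_results.loc[name]
        if bool(row["significant"]):
            out[name] = "up" if row["diff_ht_minus_at"] > 0 else "down"
        else:
            out[name] = "ns"
    return pd.Series(out, name="direction")


@dataclass
class CooccurrenceResults:
    rho: pd.DataFrame
    merge_tree: np.ndarray
    leaf_names: list[str]
    groups: list[set[str]]
    threshold: float
    directions: Optional[pd.Series] = None

    def to_newick(self) -> str:
        return export_newick(self.merge_tree, self.leaf_names)

    def group_table(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.groups, start=1):
            for name in sorted(g):
                rows.append({"group": i, "analyte": name,
                             "direction": None if self.directions is None
                             else self.directions.get(name, "ns")})
        return pd.DataFrame(rows, columns=["group", "analyte", "direction"])

    def summary(self) -> str:
        lines = [
            f"Co-occurrence groups at rho >= {self.threshold}",
            f"{len(self.leaf_names)} analytes clustered, {len(self.groups)} group(s)",
        ]
        for i, g in enumerate(self.groups, start=1):
            members = ", ".join(sorted(g))
            lines.append(f"  group {i} ({len(g)}): {members}")
        return "\n".join(lines)
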
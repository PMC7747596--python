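"""Cell-mean estimation and Fisher's LSD comparisons for the factorial field
design (treatment x genotype, blocked by year and block-within-year).

The study design is a two-factor factorial with temperature treatment (AT/HT)
and genotype as fixed effects, replicated over years and blocks.  The year and
block strata are absorbed as fixed blocking terms in an ordinary linear model;
least-squares (model-adjusted) cell means are obtained by averaging model
predictions over the blocking levels observed for each cell.  AT-vs-HT flags
and compact letter displays use Fisher's least significant difference at a
configurable alpha, with t = diff / (s * sqrt(1/n1 + 1/n2)) on the residual
degrees of freedom.

This is a fixed-effects approximation of a mixed model with random year and
block effects: with only two years, variance components are poorly estimable,
while the fixed blocking terms preserve the treatment and genotype contrasts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats


class DesignError(ValueError):
    pass


@dataclass
class DesignSpec:
    """Model specification: response column, factor columns, and alpha."""

    response: str = "value"
    treatment: str = "treatment"
    genotype: str = "genotype"
    year: str = "year"
    block: str = "block"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DesignError(f"alpha must be in (0,1), got {self.alpha}")


class FactorialLSD:
    """Least-squares cell means with LSD comparisons for one response.

    Parameters
    ----------
    data : DataFrame with the response and factor columns of ``design``.
    design : DesignSpec (defaults to the standard column names, alpha 0.05).
    """

    def __init__(self, data: pd.DataFrame, design: Optional[DesignSpec] = None):
        self.design = design or DesignSpec()
        d = self.design
        cols = [d.response, d.treatment, d.genotype, d.year, d.block]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise DesignError(f"data missing column(s): {missing}")
        self.data = data.dropna(subset=[d.response]).copy()
        counts = self.data.groupby([d.genotype, d.treatment], observed=True).size()
        thin = counts[counts < 2]
        if len(thin):
            raise DesignError(
                f"treatment x genotype cell(s) with < 2 observations: {list(thin.index)}"
            )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str = "value", **kw) -> "FactorialLSD":
        return cls(data, DesignSpec(response=response, **kw))

    def fit(self) -> "FactorialLSDResults":
        d = self.design
        df = self.data
        formula = (
            f"Q('{d.response}') ~ C(Q('{d.treatment}')) * C(Q('{d.genotype}'))"
            f" + C(Q('{d.year}')) + C(Q('{d.year}')):C(Q('{d.block}'))"
        )
        y, X = patsy.dmatrices(formula, df, return_type="dataframe")
        Xm = X.to_numpy()
        rank = np.linalg.matrix_rank(Xm)
        beta, *_ = np.linalg.lstsq(Xm, y.to_numpy().ravel(), rcond=None)
        resid = y.to_numpy().ravel() - Xm @ beta
        df_resid = len(df) - rank
        if df_resid <= 0:
            raise DesignError("no residual degrees of freedom (saturated design)")
        s2 = float(resid @ resid) / df_resid
        XtX_pinv = np.linalg.pinv(Xm.T @ Xm)

        # LS mean per (genotype, treatment) cell: average prediction over the
        # year x block combinations in which that genotype was observed.
        cells = []
        cell_rows: dict[tuple, np.ndarray] = {}
        design_info = X.design_info
        for (g, t), sub in df.groupby([d.genotype, d.treatment], observed=True):
            blocks = (
                df.loc[df[d.genotype] == g, [d.year, d.block]]
                .drop_duplicates()
                .reset_index(drop=True)
            )
            grid = blocks.copy()
            grid[d.treatment] = t
            grid[d.genotype] = g
            grid[d.response] = 0.0
            Xg = patsy.dmatrix(design_info, grid, return_type="dataframe").to_numpy()
            c = Xg.mean(axis=0)
            mean = float(c @ beta)
            se = float(np.sqrt(s2 * (c @ XtX_pinv @ c)))
            cells.append(
                {"genotype": g, "treatment": t, "lsmean": mean, "se": se, "n": len(sub)}
            )
            cell_rows[(g, t)] = c
        cell_df = pd.DataFrame(cells).set_index(["genotype", "treatment"])
        return FactorialLSDResults(
            model=self, cell_means=cell_df, sigma2=s2, df_resid=df_resid,
            _beta=beta, _xtx_pinv=XtX_pinv, _cell_rows=cell_rows,
        )


@dataclass
class FactorialLSDResults:
    """Fitted cell means plus LSD machinery.

    ``cell_means`` is indexed by (genotype, treatment) with columns
    lsmean / se / n; ``sigma2`` is the residual mean square on ``df_resid``
    degrees of freedom.
    """

    model: FactorialLSD
    cell_means: pd.DataFrame
    sigma2: float
    df_resid: int
    _beta: Optional[np.ndarray] = None
    _xtx_pinv: Optional[np.ndarray] = None
    _cell_rows: Optional[dict] = field(default=None, repr=False)

    @property
    def alpha(self) -> float:
        return self.model.design.alpha

    def _t_crit(self, alpha: Optional[float] = None) -> float:
        a = self.alpha if alpha is None else alpha
        return float(stats.t.ppf(1 - a / 2, self.df_resid))

    def _lsd_significant(self, m1, n1, m2, n2, alpha=None) -> bool:
        if np.isclose(m1, m2, rtol=1e-9, atol=1e-12):
            return False
        s = np.sqrt(self.sigma2)
        if s == 0:  # zero-residual (degenerate) fit
            return True
        t = abs(m1 - m2) / (s * np.sqrt(1.0 / n1 + 1.0 / n2))
        return t > self._t_crit(alpha)

    # -- AT vs HT ---------------------------------------------------------

    def at_vs_ht(self, alpha: Optional[float] = None) -> pd.DataFrame:
        """Per-genotype AT-vs-HT contrast: difference (HT - AT), t statistic,
        p value, and LSD significance flag."""
        rows = []
        s = np.sqrt(self.sigma2)
        for g in self.cell_means.index.get_level_values("genotype").unique():
            try:
                at = self.cell_means.loc[(g, "AT")]
                ht = self.cell_means.loc[(g, "HT")]
            except KeyError:
                continue
            diff = float(ht["lsmean"] - at["lsmean"])
            denom = s * np.sqrt(1.0 / at["n"] + 1.0 / ht["n"])
            t = diff / denom if denom > 0 else np.inf * np.sign(diff) if diff else 0.0
            p = 2 * stats.t.sf(abs(t), self.df_resid) if np.isfinite(t) else 0.0
            rows.append(
                {
                    "genotype": g,
                    "diff_ht_minus_at": diff,
                    "t": t,
                    "p": p,
                    "significant": self._lsd_significant(
                        at["lsmean"], at["n"], ht["lsmean"], ht["n"], alpha
                    ),
                }
            )
        return pd.DataFrame(rows).set_index("genotype")

    def treatment_effect(self, alpha: Optional[float] = None) -> dict:
        """Pooled AT-vs-HT main-effect contrast (HT - AT averaged over
        genotypes) with its standard error from the coefficient covariance."""
        if self._beta is None or self._cell_rows is None:
            raise DesignError("fit did not retain contrast information")
        genotypes = sorted({g for g, _ in self._cell_rows})
        contrasts = []
        for g in genotypes:
            if (g, "AT") in self._cell_rows and (g, "HT") in self._cell_rows:
                contrasts.append(self._cell_rows[(g, "HT")] - self._cell_rows[(g, "AT")])
        if not contrasts:
            raise DesignError("no genotype has both AT and HT cells")
        c = np.mean(contrasts, axis=0)
        diff = float(c @ self._beta)
        se = float(np.sqrt(self.sigma2 * (c @ self._xtx_pinv @ c)))
        if se > 0:
            t = diff / se
            p = float(2 * stats.t.sf(abs(t), self.df_resid))
        else:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            p = 1.0 if diff == 0 else 0.0
        a = self.alpha if alpha is None else alpha
        return {"diff_ht_minus_at": diff, "se": se, "t": t, "p": p,
                "significant": p < a}

    # -- compact letter display -------------------------------------------

    def lsd_letters(
        self,
        within: str,
        levels: Optional[Sequence[str]] = None,
        alpha: Optional[float] = None,
    ) -> pd.Series:
        """Compact letter display over genotype LS means within one treatment.

        Levels sharing a letter are not significantly different by Fisher's
        LSD.  Uses insert-and-absorb lettering on the pairwise significance
        matrix, with levels processed in descending-mean order.
        """
        cm = self.cell_means.xs(within, level="treatment")
        if levels is not None:
            cm = cm.loc[list(levels)]
        order = cm.sort_values("lsmean", ascending=False).index.tolist()
        sig = {
            (a, b): self._lsd_significant(
                cm.loc[a, "lsmean"], cm.loc[a, "n"], cm.loc[b, "lsmean"], cm.loc[b, "n"], alpha
            )
            for a, b in itertools.combinations(order, 2)
        }
        columns: list[set] = [set(order)]
        for a, b in itertools.combinations(order, 2):
            if not sig[(a, b)]:
                continue
            for col in [c for c in columns if a in c and b in c]:
                columns.remove(col)
                ca, cb = col - {b}, col - {a}
                for new in (ca, cb):
                    if not any(new <= other for other in columns):
                        columns.append(new)
        # absorb: drop columns that are subsets of others
        columns = [c for c in columns if not any(c < o for o in columns)]
        # letter order follows descending means of the best member
        columns.sort(key=lambda c: min(order.index(l) for l in c))
        letters = {lvl: "" for lvl in order}
        for i, col in enumerate(columns):
            ch = chr(ord("a") + i)
            for lvl in order:
                if lvl in col:
                    letters[lvl] += ch
        return pd.Series(letters, name=f"letters_{within}")

    def summary(self) -> str:
        lines = ["Factorial LS means with Fisher's LSD",
                 f"residual MS = {self.sigma2:.6g} on {self.df_resid} df, "
                 f"alpha = {self.alpha}", ""]
        lines.append(self.cell_means.to_string(float_format=lambda v: f"{v:.4f}"))
        try:
            flags = self.at_vs_ht()
            lines += ["", "AT vs HT per genotype:", flags.to_string(
                float_format=lambda v: f"{v:.4f}")]
        except Exception:
            pass
        return "\n".join(lines)


def fit_cell_means(
    table: pd.DataFrame, design: Optional[DesignSpec] = None
) -> FactorialLSDResults:
    """Functional wrapper: fit a :class:`FactorialLSD` model and return results."""
    return FactorialLSD(table, design).fit()


def benjamini_hochberg(pvalues: pd.Series, alpha: float = 0.05) -> pd.Series:
    """FDR-adjusted significance across a family of per-analyte p values.

    Off by default throughout the pipeline (per-analyte arrows are
    descriptive); opt in when a controlled family-wise claim is needed.
    """
    from statsmodels.stats.multitest import multipletests

    mask = pvalues.notna()
    out = pd.Series(False, index=pvalues.index)
    if mask.sum():
        reject, *_ = multipletests(pvalues[mask], alpha=alpha, method="fdr_bh")
        out[mask] = reject
    return out
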
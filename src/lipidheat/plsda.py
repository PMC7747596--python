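"""Two-class partial least squares discriminant analysis with VIP scores.

The discriminant model regresses a centered 0/1 treatment code on the
mean-centered analyte matrix by sequential NIPALS extraction (for a single
response the weight at each stage is simply X'y normalized, so the algorithm
is deterministic with no iteration).  No unit-variance scaling is applied by
default: the analysis runs on the data as provided, matching common
chemometrics practice for percent-of-total lipidomics tables.

Variable importance in projection follows Wold's definition

    VIP_j = sqrt( p * sum_a SS_a * w_ja^2 / sum_a SS_a ),

where SS_a = q_a^2 * t_a't_a is the response sum of squares explained by
component a and p is the number of analytes; mean(VIP^2) = 1 identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union
import warnings

import numpy as np
import pandas as pd


class PLSDAError(ValueError):
    pass


class PLSDA:
    """Two-class PLS-DA model builder.

    Parameters
    ----------
    X : (n_samples, n_analytes) matrix or DataFrame.
    y : binary class labels (two distinct values, e.g. "AT"/"HT"). The
        lexicographically larger label is coded 1.
    n_components : number of latent components (default 2, matching a
        two-axis scores plot).
    scale : if True, also divide columns by their standard deviation
        (off by default; mean-centering only).
    """

    def __init__(
        self,
        X: Union[np.ndarray, pd.DataFrame],
        y: Sequence,
        n_components: int = 2,
        scale: bool = False,
    ):
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(X.columns)
            self.X = X.to_numpy(dtype=float)
        else:
            self.X = np.asarray(X, dtype=float)
            self.feature_names = [f"x{j}" for j in range(self.X.shape[1])]
        labels = pd.unique(pd.Series(list(y)))
        if len(labels) != 2:
            raise PLSDAError(f"need exactly 2 classes, got {list(labels)}")
        self.classes_ = tuple(sorted(map(str, labels)))
        ystr = np.asarray([str(v) for v in y])
        self.y = (ystr == self.classes_[1]).astype(float)
        if self.X.shape[0] != len(self.y):
            raise PLSDAError("X and y have different numbers of samples")
        for cls, code in zip(self.classes_, (0.0, 1.0)):
            if (self.y == code).sum() < 2:
                raise PLSDAError(f"class {cls}: fewer than 2 samples")
        self.n_components = int(n_components)
        self.scale = scale

    def fit(self) -> "PLSDAResults":
        X = self.X.copy()
        y = self.y.copy()
        x_mean = X.mean(axis=0)
        X -= x_mean
        x_std = np.ones(X.shape[1])
        if self.scale:
            x_std = X.std(axis=0, ddof=1)
            x_std[x_std == 0] = 1.0
            X /= x_std
        y_mean = y.mean()
        yc = y - y_mean

        rank = np.linalg.matrix_rank(X)
        A = self.n_components
        if A > rank:
            raise PLSDAError(f"n_components={A} exceeds rank {rank} of centered X")

        n, p = X.shape
        W = np.zeros((p, A))
        T = np.zeros((n, A))
        P = np.zeros((p, A))
        q = np.zeros(A)
        ss = np.zeros(A)
        Xa = X.copy()
        ya = yc.copy()
        for a in range(A):
            w = Xa.T @ ya
            norm = np.linalg.norm(w)
            if norm == 0:
                raise PLSDAError(f"component {a + 1}: zero weight vector (y exhausted)")
            w /= norm
            # fix sign: largest-magnitude weight entry positive
            jmax = int(np.argmax(np.abs(w)))
            if w[jmax] < 0:
                w = -w
            t = Xa @ w
            tt = float(t @ t)
            pa = Xa.T @ t / tt
            qa = float(ya @ t) / tt
            Xa = Xa - np.outer(t, pa)
            ya = ya - qa * t
            W[:, a], T[:, a], P[:, a], q[a] = w, t, pa, qa
            ss[a] = qa * qa * tt

        return PLSDAResults(
            model=self,
            x_mean=x_mean,
            x_std=x_std,
            y_mean=y_mean,
            weights=W,
            scores=T,
            x_loadings=P,
            y_loadings=q,
            explained_ss=ss,
            x_residual=Xa,
        )


@dataclass
class PLSDAResults:
    """Fitted PLS-DA decomposition.

    ``weights`` (p x A, unit columns), ``scores`` (n x A, mutually
    orthogonal), ``x_loadings`` (p x A), ``y_loadings`` (A,), and the
    response sum of squares ``explained_ss`` per component.
    """

    model: PLSDA
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    weights: np.ndarray
    scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    explained_ss: np.ndarray
    x_residual: np.ndarray

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return self.model.feature_names

    def vip_scores(self) -> pd.Series:
        """Wold's VIP per analyte; mean of squared VIP equals 1."""
        ss = self.explained_ss
        total = ss.sum()
        if total == 0:
            raise PLSDAError("no explained response variance; VIP undefined")
        p = self.weights.shape[0]
        v = np.sqrt(p * (self.weights**2 @ ss) / total)
        return pd.Series(v, index=self.feature_names, name="vip")

    def rank_top_k(self, k: int = 15) -> pd.DataFrame:
        """Top-k analytes by VIP, descending; ties broken by analyte name."""
        vip = self.vip_scores()
        if k > len(vip):
            warnings.warn(
                f"k={k} exceeds the {len(vip)} analytes; returning all", stacklevel=2
            )
            k = len(vip)
        order = sorted(vip.index, key=lambda name: (-vip[name], name))[:k]
        out = pd.DataFrame({"analyte": order, "vip": vip[order].to_numpy()})
        out.index = np.arange(1, len(out) + 1)
        out.index.name = "rank"
        return out

    def scores_frame(self, sample_ids: Optional[Sequence] = None) -> pd.DataFrame:
        cols = {f"component_{a+1}": self.scores[:, a] for a in range(self.n_components)}
        df = pd.DataFrame(cols)
        df["class"] = np.where(
            self.model.y == 1.0, self.model.classes_[1], self.model.classes_[0]
        )
        if sample_ids is not None:
            df.index = list(sample_ids)
        return df

    def summary(self) -> str:
        ss = self.explained_ss
        frac = ss / ss.sum() if ss.sum() else ss
        lines = [
            f"PLS-DA ({self.model.classes_[0]} vs {self.model.classes_[1]}), "
            f"{self.n_components} components, "
            f"{'centered+scaled' if self.model.scale else 'mean-centered'}",
            "explained response SS per component: "
            + ", ".join(f"{v:.4g} ({f:.1%})" for v, f in zip(ss, frac)),
            "",
            "Top analytes by VIP:",
            self.rank_top_k(min(15, len(self.feature_names))).to_string(
                float_format=lambda v: f"{v:.3f}"
            ),
        ]
        return "\n".join(lines)


def fit_plsda(
    X, y, n_components: int = 2, scale: bool = False
) -> PLSDAResults:
    """Functional wrapper around :class:`PLSDA`."""
    return PLSDA(X, y, n_components=n_components, scale=scale).fit()
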
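"""Pearson correlation screening and Ward hierarchical clustering.

The correlation screen mirrors the all-pairs analysis of the mutant-CHIP
biochemical variables: pairwise-complete Pearson rho, two-sided p from the
t transform, and BH Q values computed across the strict upper triangle.
Clustering standardizes variables (sample SD) and applies Ward's
minimum-variance linkage to the rows; merge costs equal the increase in
the error sum of squares at each agglomeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .screening import bh_adjust

__all__ = ["CorrMatrix", "Dendrogram", "correlation_screen", "ward_cluster"]


@dataclass
class CorrMatrix:
    """Symmetric correlation summary: rho, raw p, BH Q and n per pair."""

    variables: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n: pd.DataFrame
    fdr: float = 0.10

    def to_long(self) -> pd.DataFrame:
        """Long-format export: one row per unordered variable pair."""
        rows = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1:]:
                rows.append(
                    {
                        "var1": a,
                        "var2": b,
                        "rho": self.rho.loc[a, b],
                        "p": self.p.loc[a, b],
                        "q": self.q.loc[a, b],
                        "n": self.n.loc[a, b],
                        "flagged": bool(self.q.loc[a, b] < self.fdr)
                        if pd.notna(self.q.loc[a, b])
                        else False,
                    }
                )
        return pd.DataFrame(rows)


def correlation_screen(
    table: pd.DataFrame, variables: list[str] | None = None, fdr: float = 0.10,
    min_pairs: int = 3,
) -> CorrMatrix:
    """Pairwise-complete Pearson correlations with FDR control.

    A zero-variance variable (or a pair with fewer than ``min_pairs``
    complete cases) yields missing entries rather than an error.
    """
    variables = list(variables or table.select_dtypes("number").columns)
    k = len(variables)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables, dtype=float)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables, dtype=float)
    n = pd.DataFrame(0, index=variables, columns=variables, dtype=int)
    for v in variables:
        n.loc[v, v] = int(table[v].notna().sum())
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = variables[i], variables[j]
            sub = table[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(sub)
            if len(sub) < min_pairs or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                rho.loc[a, b] = rho.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
            else:
                r, pv = stats.pearsonr(sub[a], sub[b])
                rho.loc[a, b] = rho.loc[b, a] = float(r)
                p.loc[a, b] = p.loc[b, a] = float(pv)
            pairs.append((a, b))
    q = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables, dtype=float)
    upper = [(a, b) for a, b in pairs if pd.notna(p.loc[a, b])]
    qs = bh_adjust([p.loc[a, b] for a, b in upper], family_label="correlation_screen")
    q.loc[:, :] = np.nan
    np.fill_diagonal(q.values, 0.0)
    for (a, b), qv in zip(upper, qs):
        q.loc[a, b] = q.loc[b, a] = float(qv)
    return CorrMatrix(variables, rho, p, q, n, fdr=fdr)


@dataclass
class Dendrogram:
    """Agglomeration result: scipy linkage matrix plus row labels.

    ``merge_costs`` converts Ward linkage heights to error-sum-of-squares
    increases (height^2 / 2), which is what the minimum-variance criterion
    minimizes at each step.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    @property
    def merge_costs(self) -> np.ndarray:
        return self.linkage[:, 2] ** 2 / 2.0

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, n_clusters: int) -> dict[str, int]:
        assign = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assign)}

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def ward_cluster(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    labels: list[str] | None = None,
    standardize: bool = True,
) -> Dendrogram:
    """Ward minimum-variance clustering of table rows.

    Variables are standardized to mean 0, sample SD 1 before computing
    distances, making the result invariant to per-variable rescaling.
    Rows with missing values in the chosen variables are not allowed.
    """
    variables = list(variables or table.select_dtypes("number").columns)
    X = table[variables].to_numpy(float)
    if len(X) < 2:
        raise ValueError("need >= 2 rows to cluster")
    if np.isnan(X).any():
        raise ValueError("rows must be complete for the chosen variables")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = hierarchy.linkage(X, method="ward")
    if labels is None:
        labels = [str(i) for i in table.index]
    return Dendrogram(Z, list(labels))
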
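"""Signed, weighted element-association networks and expected influence.

Nodes are elements; edge weights are pairwise associations between their
concentration profiles across samples (Spearman by default — robust to
the heavy-tailed marginals of polluted-site surveys). Edges that fail the
retention rule (Benjamini-Hochberg-adjusted p-value by default) are set
to zero. Expected influence (EI) is the one-step signed centrality: the
sum of a node's signed edge weights, so strongly negatively associated
nodes can carry negative EI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import GraphicalLasso
from statsmodels.stats.multitest import multipletests

from .sampletable import SampleTable

__all__ = ["RetainRule", "ElementNetwork", "build_network", "expected_influence"]


@dataclass(frozen=True)
class RetainRule:
    """Edge retention: significance threshold (with optional BH adjustment
    across all pairs) and/or a minimum absolute weight."""

    alpha: float | None = 0.05
    adjust: str = "bh"  # "bh" or "none"
    min_abs: float = 0.0


@dataclass
class ElementNetwork:
    """Symmetric signed adjacency over elements, zero diagonal."""

    nodes: list[str]
    adjacency: pd.DataFrame
    method: str

    def __post_init__(self) -> None:
        A = self.adjacency.to_numpy()
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.abs(np.diag(A)).max() > 0:
            raise ValueError("self-loops are not allowed")
        if np.abs(A).max() > 1 + 1e-9:
            raise ValueError("weights must lie in [-1, 1]")

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.nodes):
            for j in range(i + 1, len(self.nodes)):
                w = self.adjacency.iat[i, j]
                if w != 0:
                    rows.append((a, self.nodes[j], w))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, (a, b, w) in self.edge_list().iterrows():
            g.add_edge(a, b, weight=w)
        return g


def _pairwise(X: np.ndarray, estimator: str) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix and p-value matrix for the chosen estimator."""
    m = X.shape[1]
    corr = np.eye(m)
    pval = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            if estimator == "spearman":
                r, p = stats.spearmanr(X[:, i], X[:, j])
            elif estimator == "pearson":
                r, p = stats.pearsonr(X[:, i], X[:, j])
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
            corr[i, j] = corr[j, i] = r
            pval[i, j] = pval[j, i] = p
    return corr, pval


def build_network(
    table: SampleTable,
    estimator: str = "spearman",
    retain_rule: RetainRule | None = None,
    glasso_alpha: float = 0.05,
) -> ElementNetwork:
    """Estimate the element-association network.

    ``estimator`` is one of ``spearman`` (default), ``pearson`` or
    ``partial`` (graphical-lasso regularised partial correlations, for
    which the retention rule applies only through ``min_abs`` since no
    p-values exist).
    """
    retain = retain_rule or RetainRule()
    conc = table.conc
    if len(conc) < 4 or conc.shape[1] < 2:
        raise ValueError("need at least 4 samples and 2 elements")
    constant = conc.columns[conc.std(ddof=1) == 0]
    if len(constant):
        raise ValueError(
            f"constant column(s) make correlation undefined: {', '.join(constant)}"
        )
    X = conc.to_numpy(dtype=float)
    elements = list(conc.columns)
    m = len(elements)

    if estimator == "partial":
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        gl = GraphicalLasso(alpha=glasso_alpha).fit(Z)
        P = gl.precision_
        d = np.sqrt(np.diag(P))
        W = -P / np.outer(d, d)
        np.fill_diagonal(W, 0.0)
        W[np.abs(W) < retain.min_abs] = 0.0
        W = np.clip((W + W.T) / 2.0, -1.0, 1.0)
    else:
        W, pvals = _pairwise(X, estimator)
        np.fill_diagonal(W, 0.0)
        iu = np.triu_indices(m, k=1)
        keep = np.ones(len(iu[0]), dtype=bool)
        if retain.alpha is not None:
            p_flat = pvals[iu]
            if retain.adjust == "bh":
                keep &= multipletests(p_flat, alpha=retain.alpha, method="fdr_bh")[0]
            elif retain.adjust == "none":
                keep &= p_flat < retain.alpha
            else:
                raise ValueError(f"unknown adjustment {retain.adjust!r}")
        keep &= np.abs(W[iu]) >= retain.min_abs
        mask = np.zeros((m, m), dtype=bool)
        mask[iu] = keep
        mask |= mask.T
        W = np.where(mask, W, 0.0)
        W = np.clip(W, -1.0, 1.0)

    adj = pd.DataFrame(W, index=elements, columns=elements)
    return ElementNetwork(nodes=elements, adjacency=adj, method=estimator)


def expected_influence(
    network: ElementNetwork, variant: str = "signed", standardize: bool = False
) -> pd.Series:
    """One-step expected influence per node.

    ``signed`` (default) sums the signed edge weights, so nodes whose
    associations are predominantly negative get negative EI; ``absolute``
    sums |weights| (strength centrality). ``standardize`` reports z-scores
    across nodes, the convention used when comparing EI magnitudes across
    studies.
    """
    if not network.nodes:
        raise ValueError("empty network")
    A = network.adjacency.to_numpy()
    if variant == "signed":
        ei = A.sum(axis=1)
    elif variant == "absolute":
        ei = np.abs(A).sum(axis=1)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    ei = pd.Series(ei, index=network.nodes, name="expected_influence")
    if standardize:
        sd = ei.std(ddof=1)
        if sd == 0:
            return ei * 0.0
        ei = (ei - ei.mean()) / sd
    return ei
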
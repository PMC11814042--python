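"""Compositional data analysis in clr coordinates.

Concentrations are compositional: only relative information is meaningful
once the parts are closed to a constant sum. The centred log-ratio (clr)
transform maps each strictly positive composition to log-ratios against
its geometric mean, removing closure artefacts; a singular value
decomposition of the column-centred clr matrix yields the clr biplot
(sample scores, element rays), and k-means on the clr coordinates groups
samples by geochemical association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .sampletable import SampleTable

__all__ = [
    "ClrMatrix",
    "BiplotResult",
    "close",
    "clr",
    "clr_table",
    "zero_replace",
    "clr_biplot",
    "kmeans_clusters",
]


@dataclass
class ClrMatrix:
    """clr coordinates (samples x elements) plus per-sample geometric means."""

    values: pd.DataFrame
    geometric_means: pd.Series

    def __post_init__(self) -> None:
        rowsum = self.values.to_numpy().sum(axis=1)
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("clr coordinates must be finite (replace zeros first)")
        if np.abs(rowsum).max() > 1e-10:
            raise ValueError("clr rows must sum to zero")


@dataclass
class BiplotResult:
    """SVD biplot of the centred clr matrix.

    ``form='covariance'`` scales rays so their squared length equals the
    clr variance of the element; ``form='form'`` puts the singular values
    on the scores instead.
    """

    scores: pd.DataFrame  # samples x axes
    rays: pd.DataFrame  # elements x axes
    explained_variance_pct: np.ndarray
    form: str


def close(parts: np.ndarray, kappa: float = 1e6) -> np.ndarray:
    """Scale a positive composition to sum to ``kappa`` (default 1e6,
    i.e. mg/kg closure)."""
    parts = np.asarray(parts, dtype=float)
    if (parts <= 0).any():
        raise ValueError("composition parts must be strictly positive")
    return kappa * parts / parts.sum(axis=-1, keepdims=True)


def clr(composition: np.ndarray) -> np.ndarray:
    """Centred log-ratio: log(part / geometric mean of the row).

    Scale-invariant (clr(lambda * x) = clr(x)); each output row sums to 0.
    """
    x = np.asarray(composition, dtype=float)
    if (x <= 0).any():
        raise ValueError("clr requires strictly positive parts")
    logx = np.log(x)
    return logx - logx.mean(axis=-1, keepdims=True)


def zero_replace(
    conc: pd.DataFrame, mdl: dict[str, float], factor: float = 0.65
) -> pd.DataFrame:
    """Multiplicative simple replacement of zeros at ``factor * MDL``."""
    out = conc.copy()
    for el in out.columns:
        repl = factor * mdl.get(el, 0.0)
        zero = out[el] <= 0
        if zero.any():
            if repl <= 0:
                raise ValueError(f"zeros in {el} but no positive MDL to replace with")
            out.loc[zero, el] = repl
    return out


def clr_table(
    table: SampleTable, mdl: dict[str, float] | None = None, kappa: float = 1e6
) -> ClrMatrix:
    """Zero-replace, close and clr-transform a :class:`SampleTable`."""
    conc = table.conc
    if mdl is not None:
        conc = zero_replace(conc, mdl)
    closed = close(conc.to_numpy(), kappa)
    vals = clr(closed)
    gmean = np.exp(np.log(closed).mean(axis=1))
    return ClrMatrix(
        values=pd.DataFrame(vals, index=conc.index, columns=conc.columns),
        geometric_means=pd.Series(gmean, index=conc.index),
    )


def clr_biplot(clrm: ClrMatrix, form: str = "covariance") -> BiplotResult:
    """SVD biplot of the column-centred clr matrix.

    In the covariance biplot the ray for element j has squared length
    equal to the clr variance of j (summed over all axes), so ray length
    is directly proportional to clr standard deviation.
    """
    Z = clrm.values.to_numpy()
    n, m = Z.shape
    if n < 3 or m < 3:
        raise ValueError("biplot needs at least 3 samples and 3 elements")
    Zc = Z - Z.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    if s[0] <= 1e-12:
        raise ValueError("degenerate (rank-0) clr matrix")
    # clr data are rank-deficient by construction (rows sum to 0); drop
    # numerically null axes whose direction is arbitrary
    rank = int((s > 1e-12 * s[0]).sum())
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
    if form == "covariance":
        scores = U * np.sqrt(n - 1)
        rays = Vt.T * (s / np.sqrt(n - 1))[None, :]
    elif form == "form":
        scores = U * s[None, :]
        rays = Vt.T
    else:
        raise ValueError(f"unknown biplot form {form!r}")
    var = s**2
    explained = 100.0 * var / var.sum()
    axes = [f"PC{k + 1}" for k in range(len(s))]
    return BiplotResult(
        scores=pd.DataFrame(scores, index=clrm.values.index, columns=axes),
        rays=pd.DataFrame(rays, index=clrm.values.columns, columns=axes),
        explained_variance_pct=explained,
        form=form,
    )


def kmeans_clusters(
    scores: pd.DataFrame | np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
) -> np.ndarray:
    """k-means labels on clr (or biplot) coordinates; deterministic per seed."""
    X = np.asarray(scores, dtype=float)
    if k > len(X):
        raise ValueError("k cannot exceed the number of samples")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(X)
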
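"""Receptor models for source identification.

Two complementary approaches:

* principal component analysis on standardised concentrations with
  varimax rotation and Kaiser (eigenvalue > 1) retention — the classical
  eigenvector method; and
* positive matrix factorisation (PMF): a weighted non-negative factor
  model X = GF + E fitted by minimising

      Q = sum_ij ((x_ij - sum_k g_ik f_kj) / mu_ij)^2

  subject to G >= 0, F >= 0, where mu_ij is the per-cell measurement
  uncertainty. The optimiser alternates exact non-negative weighted least
  squares over the rows of G and the columns of F, which makes Q
  non-increasing at every iteration; multiple seeded random restarts
  guard against local minima and the best-Q solution is returned.

Per-cell uncertainties follow the EPA PMF convention: for detected values

    mu_ij = sqrt((sigma_j * x_ij)^2 + (0.5 * MDL_j)^2)

and for values at or below the detection limit mu_ij = 5/6 * MDL_j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls
from statsmodels.multivariate.factor_rotation import rotate_factors

from .sampletable import SampleTable

__all__ = [
    "PcaResult",
    "UncertaintySpec",
    "FactorModel",
    "pca_varimax",
    "uncertainty_matrix",
    "pmf_fit",
    "pmf_diagnostics",
    "q_scan",
    "match_factors",
]


# --------------------------------------------------------------------------
# PCA with varimax rotation
# --------------------------------------------------------------------------

@dataclass
class PcaResult:
    loadings: pd.DataFrame  # elements x components, varimax-rotated
    variance_pct: np.ndarray  # per retained component, % of total variance
    scores: pd.DataFrame  # samples x components (regression method)
    eigenvalues: np.ndarray  # all eigenvalues of the correlation matrix


def pca_varimax(table: SampleTable, n_components: int | str = "auto") -> PcaResult:
    """Correlation-matrix PCA with Kaiser retention and varimax rotation.

    Columns are z-scored before eigendecomposition, so components are
    eigenvectors of the correlation matrix. With ``n_components='auto'``
    all components with eigenvalue > 1 are retained. Rotation uses Kaiser
    row-normalisation; communalities are invariant under the (orthogonal)
    rotation. Scores follow the regression method, S = Z R^{-1} L.
    """
    conc = table.conc
    if len(conc) < 3:
        raise ValueError("need at least 3 samples")
    sd = conc.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(
            f"constant column(s): {', '.join(conc.columns[sd == 0])}"
        )
    Z = ((conc - conc.mean()) / sd).to_numpy()
    n, m = Z.shape
    R = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    if n_components == "auto":
        k = int((eigval > 1.0).sum())
        if k == 0:
            raise ValueError("no eigenvalue exceeds 1; nothing to retain")
    else:
        k = int(n_components)
        if k < 1 or k > m:
            raise ValueError("n_components out of range")
    if np.any(np.abs(eigval - 1.0) < 0.05):
        warnings.warn(
            "eigenvalue(s) within 0.05 of the Kaiser cutoff: component "
            "retention is unstable",
            stacklevel=2,
        )

    loadings = eigvec[:, :k] * np.sqrt(eigval[:k])[None, :]
    if k > 1:
        # Kaiser normalisation: rotate unit-communality rows, then rescale
        comm = np.sqrt((loadings**2).sum(axis=1))
        rotated, _ = rotate_factors(loadings / comm[:, None], "varimax")
        rotated *= comm[:, None]
    else:
        rotated = loadings.copy()
    # sign convention: dominant loading positive; order by rotated variance
    rot_var = (rotated**2).sum(axis=0)
    order_k = np.argsort(rot_var)[::-1]
    rotated = rotated[:, order_k]
    rot_var = rot_var[order_k]
    signs = np.sign(rotated[np.abs(rotated).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    rotated *= signs[None, :]

    variance_pct = 100.0 * rot_var / m
    scores = Z @ np.linalg.solve(R, rotated)
    comps = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        loadings=pd.DataFrame(rotated, index=conc.columns, columns=comps),
        variance_pct=variance_pct,
        scores=pd.DataFrame(scores, index=conc.index, columns=comps),
        eigenvalues=eigval,
    )


# --------------------------------------------------------------------------
# Uncertainty matrix
# --------------------------------------------------------------------------

@dataclass
class UncertaintySpec:
    """Per-element relative SD sigma (fraction) and detection limit MDL."""

    sigma: dict[str, float]
    mdl: dict[str, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.sigma.values()):
            raise ValueError("sigma must be positive")
        if any(v < 0 for v in self.mdl.values()):
            raise ValueError("MDL must be non-negative")


def uncertainty_matrix(
    conc: pd.DataFrame, spec: UncertaintySpec, dialect: str = "standard"
) -> pd.DataFrame:
    """Per-cell uncertainty mu_ij.

    ``standard`` dialect: cells with concentration > MDL get
    sqrt((sigma*conc)^2 + (0.5*MDL)^2); cells at or below MDL get
    (5/6)*MDL. The ``literal`` dialect instead applies the 5/6 rule
    whenever MDL <= the error-propagation value (a published variant whose
    trigger references the uncertainty itself).
    """
    X = conc.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative concentration")
    sigma = np.array([spec.sigma[e] for e in conc.columns])
    mdl = np.array([spec.mdl.get(e, 0.0) for e in conc.columns])
    propagated = np.sqrt((sigma[None, :] * X) ** 2 + (0.5 * mdl[None, :]) ** 2)
    below = mdl[None, :] * (5.0 / 6.0)
    if dialect == "standard":
        mu = np.where(X <= mdl[None, :], np.where(mdl[None, :] > 0, below, propagated), propagated)
    elif dialect == "literal":
        mu = np.where(mdl[None, :] <= propagated, below, propagated)
        mu = np.where(mdl[None, :] > 0, mu, propagated)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if (mu <= 0).any():
        raise ValueError("uncertainty matrix contains non-positive entries")
    return pd.DataFrame(mu, index=conc.index, columns=conc.columns)


# --------------------------------------------------------------------------
# PMF
# --------------------------------------------------------------------------

@dataclass
class FactorModel:
    """Fitted PMF solution (best of the random restarts)."""

    G: pd.DataFrame  # samples x factors, non-negative contributions
    F: pd.DataFrame  # factors x elements, non-negative profiles (mg/kg)
    Q: float
    scaled_residuals: pd.DataFrame  # (X - GF) / mu
    profile_pct: pd.DataFrame  # factors x elements, columns sum to 100
    explained_variance_pct: np.ndarray  # per factor
    diagnostics: pd.DataFrame | None = None
    q_history: list[np.ndarray] = field(default_factory=list)
    run_seeds: list[int] = field(default_factory=list)
    converged: bool = True

    @property
    def n_factors(self) -> int:
        return self.F.shape[0]

    def reconstruction(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.G.to_numpy() @ self.F.to_numpy(),
            index=self.G.index,
            columns=self.F.columns,
        )


def _wnnls_rows(X: np.ndarray, F: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row-wise weighted NNLS: argmin_{g>=0} ||(x_i - g F) * w_i||^2."""
    n = X.shape[0]
    k = F.shape[0]
    G = np.empty((n, k))
    for i in range(n):
        A = (F * W[i][None, :]).T  # m x k
        G[i], _ = nnls(A, X[i] * W[i])
    return G


def _q_value(X: np.ndarray, G: np.ndarray, F: np.ndarray, W: np.ndarray) -> float:
    r = (X - G @ F) * W
    return float((r * r).sum())


def _single_pmf_run(
    X: np.ndarray,
    W: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool]:
    n, m = X.shape
    col_scale = X.mean(axis=0) / max(k, 1)
    G = rng.uniform(0.0, 1.0, size=(n, k)) + 1e-3
    F = rng.uniform(0.0, 1.0, size=(k, m)) * col_scale[None, :] + 1e-9
    history = [np.inf]
    converged = False
    for _ in range(max_iter):
        G = _wnnls_rows(X, F, W)
        F = _wnnls_rows(X.T, G.T, W.T)  # columns of F via the transposed problem
        F = F.T
        q = _q_value(X, G, F, W)
        prev = history[-1]
        history.append(q)
        if np.isfinite(prev) and prev - q <= tol * max(prev, 1e-300):
            converged = True
            break
    return G, F, history[-1], np.asarray(history[1:]), converged


def pmf_fit(
    X: pd.DataFrame,
    mu: pd.DataFrame,
    n_factors: int,
    n_runs: int = 20,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> FactorModel:
    """Fit PMF by alternating weighted NNLS with seeded random restarts.

    The per-run alternating solves are exact in each block, so Q is
    non-increasing within every run; ``n_runs`` restarts are drawn from a
    generator seeded with ``seed`` and the lowest-Q solution is kept.
    Factors are ordered by explained variance, descending.
    """
    Xv = X.to_numpy(dtype=float)
    if (Xv < 0).any():
        raise ValueError("X must be non-negative (use substitute values)")
    if (mu.to_numpy() <= 0).any():
        raise ValueError("mu must be strictly positive")
    Wv = 1.0 / mu.to_numpy(dtype=float)
    n, m = Xv.shape
    if not 0 < n_factors < min(n, m):
        raise ValueError("n_factors must lie in (0, min(samples, elements))")

    seed_seq = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % 2**31) for s in seed_seq.spawn(n_runs)]
    best = None
    histories = []
    any_nonconverged = False
    for run_seed in run_seeds:
        rng = np.random.default_rng(run_seed)
        G, F, q, hist, conv = _single_pmf_run(Xv, Wv, n_factors, rng, max_iter, tol)
        histories.append(hist)
        if not conv:
            any_nonconverged = True
        if best is None or q < best[2]:
            best = (G, F, q)
    if any_nonconverged:
        warnings.warn(
            "PMF did not converge within max_iter in at least one run; "
            "best iterate returned",
            stacklevel=2,
        )
    G, F, q = best

    recon = G @ F
    total = (recon**2).sum()
    per_factor = np.array(
        [((np.outer(G[:, k], F[k]) ** 2).sum()) for k in range(n_factors)]
    )
    explained = 100.0 * per_factor / total if total > 0 else per_factor
    order = np.argsort(explained)[::-1]
    G, F, explained = G[:, order], F[order], explained[order]

    factors = [f"Factor{k + 1}" for k in range(n_factors)]
    Gd = pd.DataFrame(G, index=X.index, columns=factors)
    Fd = pd.DataFrame(F, index=factors, columns=X.columns)
    scaled = pd.DataFrame(
        (Xv - G @ F) * Wv, index=X.index, columns=X.columns
    )
    colsum = F.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(colsum[None, :] > 0, 100.0 * F / colsum[None, :], 0.0)
    model = FactorModel(
        G=Gd,
        F=Fd,
        Q=q,
        scaled_residuals=scaled,
        profile_pct=pd.DataFrame(pct, index=factors, columns=X.columns),
        explained_variance_pct=explained,
        q_history=histories,
        run_seeds=run_seeds,
        converged=not any_nonconverged,
    )
    model.diagnostics = pmf_diagnostics(model, X, mu)
    return model


def pmf_diagnostics(
    model: FactorModel, X: pd.DataFrame, mu: pd.DataFrame
) -> pd.DataFrame:
    """Per-element fit diagnostics.

    * ``pct_resid_in_3``: share of scaled residuals within [-3, 3];
    * ``snr``: signal-to-noise, sqrt(sum max(x-mu, 0)^2 / sum mu^2);
    * ``r2``: squared Pearson correlation of observed vs reconstructed.
    """
    Xv = X.to_numpy(dtype=float)
    Mv = mu.to_numpy(dtype=float)
    recon = model.G.to_numpy() @ model.F.to_numpy()
    scaled = (Xv - recon) / Mv
    within = 100.0 * (np.abs(scaled) <= 3).mean(axis=0)
    signal = np.clip(Xv - Mv, 0.0, None)
    snr = np.sqrt((signal**2).sum(axis=0) / (Mv**2).sum(axis=0))
    r2 = np.empty(Xv.shape[1])
    for j in range(Xv.shape[1]):
        obs, rec = Xv[:, j], recon[:, j]
        so, sr = obs.std(), rec.std()
        r2[j] = np.corrcoef(obs, rec)[0, 1] ** 2 if so > 0 and sr > 0 else 1.0
    return pd.DataFrame(
        {"pct_resid_in_3": within, "snr": snr, "r2": r2}, index=X.columns
    )


def q_scan(
    X: pd.DataFrame,
    mu: pd.DataFrame,
    k_values: list[int],
    n_runs: int = 5,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Best Q per candidate factor count; no automatic choice is made."""
    rows = []
    for k in k_values:
        model = pmf_fit(X, mu, k, n_runs=n_runs, seed=seed, **kwargs)
        rows.append((k, model.Q))
    return pd.DataFrame(rows, columns=["n_factors", "Q"]).set_index("n_factors")


def match_factors(estimated: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match estimated factor profiles to true ones by optimal assignment
    on cosine similarity (resolves permutation ambiguity).

    Returns (permutation, cosine similarities): ``estimated[permutation[k]]``
    pairs with ``truth[k]``.
    """
    est = np.asarray(estimated, float)
    tru = np.asarray(truth, float)
    en = np.linalg.norm(est, axis=1, keepdims=True)
    tn = np.linalg.norm(tru, axis=1, keepdims=True)
    cos = (tru / np.where(tn > 0, tn, 1)) @ (est / np.where(en > 0, en, 1)).T
    rows, cols = linear_sum_assignment(-cos)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm, cos[rows, cols]
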
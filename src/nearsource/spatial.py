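"""Spatial weights, Moran's I, and maximum-likelihood spatial regression.

Implements the spatial-statistics layer used by the equity analysis:
symmetric k-nearest-neighbor weights, global Moran's I with a permutation
test, and the two classical simultaneous-autoregressive models —

* Spatial Lag Model (SLM):   y = rho * W y + X b + eps
* Spatial Error Model (SEM): y = X b + u,  u = lambda * W u + eps

both fit by profile maximum likelihood. The Jacobian term ln|I - rho W| is
computed from the eigenvalues of the row-standardized W; W = D^-1 A with A
symmetric is similar to a symmetric matrix, so its spectrum is real and
the spatial parameter is constrained to (1/omega_min, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree


@dataclass
class SpatialWeights:
    """Neighbor lists + weights per observation.

    ``neighbors[i]`` lists the neighbor indices of observation ``i`` and
    ``weights[i]`` the matching weights. No self-neighbors; when
    ``row_standardized`` every non-island row sums to 1.
    """

    neighbors: list
    weights: list
    ids: list
    row_standardized: bool = True

    def __post_init__(self):
        for i, nbrs in enumerate(self.neighbors):
            if i in nbrs:
                raise ValueError(f"observation {i} is its own neighbor")
            if len(nbrs) != len(self.weights[i]):
                raise ValueError("neighbors/weights length mismatch")
        if self.row_standardized:
            for i, w in enumerate(self.weights):
                if w and abs(sum(w) - 1.0) > 1e-9:
                    raise ValueError(f"row {i} weights sum to {sum(w)}, not 1")

    @property
    def n(self) -> int:
        return len(self.neighbors)

    def dense(self) -> np.ndarray:
        W = np.zeros((self.n, self.n))
        for i, (nbrs, ws) in enumerate(zip(self.neighbors, self.weights)):
            W[i, nbrs] = ws
        return W

    @classmethod
    def from_adjacency(cls, adj: dict, ids=None, row_standardize: bool = True):
        """Build from {index: [neighbor indices]} (symmetric not required)."""
        n = len(adj)
        neighbors, weights = [], []
        for i in range(n):
            nbrs = sorted(adj[i])
            if row_standardize and nbrs:
                w = [1.0 / len(nbrs)] * len(nbrs)
            else:
                w = [1.0] * len(nbrs)
            neighbors.append(nbrs)
            weights.append(w)
        return cls(neighbors=neighbors, weights=weights,
                   ids=list(ids) if ids is not None else list(range(n)),
                   row_standardized=row_standardize)


def build_weights(block_groups, k: int = 8) -> SpatialWeights:
    """Symmetric k-nearest-neighbor weights over block-group centroids.

    kNN graphs are directed; the union symmetrization adds the reverse of
    every edge, after which rows are standardized to sum to 1.
    """
    n = len(block_groups)
    if n <= k:
        raise ValueError(f"need more observations ({n}) than neighbors k={k}")
    pts = np.array([[bg.centroid_x, bg.centroid_y] for bg in block_groups])
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)  # first hit is the point itself
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in idx[i, 1:]:
            adj[i].add(int(j))
            adj[int(j)].add(i)  # symmetrize by union
    return SpatialWeights.from_adjacency({i: adj[i] for i in range(n)},
                                         ids=[bg.bg_id for bg in block_groups])


def morans_i(values, w: SpatialWeights, permutations: int = 999,
             seed: int = 0) -> tuple:
    """Global Moran's I and a permutation p-value.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    The p-value is the two-sided pseudo p from ``permutations`` random
    relabelings (+1 correction), seeded.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n != w.n:
        raise ValueError("values and weights have different lengths")
    z = x - x.mean()
    den = float(z @ z)
    if den == 0:
        raise ValueError("Moran's I undefined for constant values")
    W = w.dense()
    s0 = W.sum()

    def stat(zv):
        return n / s0 * float(zv @ W @ zv) / float(zv @ zv)

    i_obs = stat(z)
    if permutations <= 0:
        return i_obs, float("nan")
    rng = np.random.default_rng(seed)
    sims = np.empty(permutations)
    for p in range(permutations):
        sims[p] = stat(rng.permutation(z))
    e_i = -1.0 / (n - 1)
    extreme = np.sum(np.abs(sims - e_i) >= abs(i_obs - e_i))
    pval = (extreme + 1) / (permutations + 1)
    return i_obs, float(pval)


@dataclass
class RegressionResult:
    model: str                      # OLS | SLM | SEM
    params: pd.Series               # intercept + covariate coefficients
    bse: pd.Series                  # standard errors
    spatial_param: float | None     # rho (SLM) / lambda (SEM); None for OLS
    spatial_param_name: str | None
    log_likelihood: float
    morans_i_residuals: float
    morans_i_pvalue: float
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)


def _design(X: pd.DataFrame) -> tuple:
    names = ["intercept"] + list(X.columns)
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return mat, names


def _resid_moran(resid, w, seed=0):
    try:
        return morans_i(resid, w, permutations=999, seed=seed)
    except ValueError:
        return float("nan"), float("nan")


def ols_fit(y, X: pd.DataFrame, w: SpatialWeights | None = None,
            seed: int = 0) -> RegressionResult:
    """OLS of exposure on demographic covariates, with residual Moran's I."""
    import statsmodels.api as sm

    yv = np.asarray(y, dtype=float)
    mat, names = _design(X)
    res = sm.OLS(yv, mat).fit()
    mi, mp = _resid_moran(res.resid, w, seed) if w is not None else (float("nan"),) * 2
    return RegressionResult(
        model="OLS",
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        spatial_param=None, spatial_param_name=None,
        log_likelihood=float(res.llf),
        morans_i_residuals=mi, morans_i_pvalue=mp)


def _spatial_ml(y, X, w, kind, seed):
    yv = np.asarray(y, dtype=float)
    mat, names = _design(X)
    n = len(yv)
    W = w.dense()
    omega = np.linalg.eigvals(W)
    if np.max(np.abs(omega.imag)) > 1e-8:
        raise ValueError("weights spectrum is not real; use symmetric kNN weights")
    omega = np.sort(omega.real)
    lo = 1.0 / omega[0] + 1e-6 if omega[0] < 0 else -0.999999
    hi = 1.0 - 1e-6
    Wy = W @ yv

    def concentrated_negll(a):
        logdet = float(np.sum(np.log(1.0 - a * omega)))
        if kind == "SLM":
            yt = yv - a * Wy
            b, *_ = np.linalg.lstsq(mat, yt, rcond=None)
            e = yt - mat @ b
        else:  # SEM: spatially filter both sides
            A = np.eye(n) - a * W
            ys, Xs = A @ yv, A @ mat
            b, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
            e = ys - Xs @ b
        sig2 = float(e @ e) / n
        ll = -0.5 * n * (np.log(2 * np.pi) + 1.0) - 0.5 * n * np.log(sig2) + logdet
        return -ll

    opt = minimize_scalar(concentrated_negll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    a = float(opt.x)
    converged = bool(opt.success)

    # coefficients and conditional-on-a covariance at the optimum
    if kind == "SLM":
        yt = yv - a * Wy
        b, *_ = np.linalg.lstsq(mat, yt, rcond=None)
        e = yt - mat @ b
        XtXi = np.linalg.inv(mat.T @ mat)
    else:
        A = np.eye(n) - a * W
        ys, Xs = A @ yv, A @ mat
        b, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        e = ys - Xs @ b
        XtXi = np.linalg.inv(Xs.T @ Xs)
    sig2 = float(e @ e) / n
    bse = np.sqrt(np.diag(sig2 * XtXi))
    ll = -float(concentrated_negll(a))
    mi, mp = _resid_moran(e, w, seed)
    return RegressionResult(
        model=kind,
        params=pd.Series(b, index=names),
        bse=pd.Series(bse, index=names),
        spatial_param=a,
        spatial_param_name="rho" if kind == "SLM" else "lambda",
        log_likelihood=ll,
        morans_i_residuals=mi, morans_i_pvalue=mp,
        converged=converged,
        diagnostics={"sigma2": sig2, "bounds": (lo, hi),
                     "optimizer_message": str(opt.message)})


def slm_fit(y, X: pd.DataFrame, w: SpatialWeights, seed: int = 0) -> RegressionResult:
    """Spatial Lag Model y = rho W y + X b + eps by profile ML."""
    if w.n <= 5:
        raise ValueError("SLM needs n > 5")
    return _spatial_ml(y, X, w, "SLM", seed)


def sem_fit(y, X: pd.DataFrame, w: SpatialWeights, seed: int = 0) -> RegressionResult:
    """Spatial Error Model y = X b + u, u = lambda W u + eps by profile ML."""
    if w.n <= 5:
        raise ValueError("SEM needs n > 5")
    return _spatial_ml(y, X, w, "SEM", seed)
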
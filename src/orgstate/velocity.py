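"""Steady-state RNA velocity and Markov-chain startpoint/endpoint tracing.

The velocity of a gene is ``v = u - gamma * s``, the imbalance between its
unspliced and spliced abundance relative to the steady-state ratio ``gamma``
(estimated per gene by regression through the origin on cells in the extreme
quantiles of spliced expression).  Velocities drive a row-stochastic
transition matrix over a kNN graph in embedding space: the probability of
stepping from cell i to neighbor j grows with the cosine correlation between
cell i's velocity vector and the displacement towards j.  Propagating a
uniform distribution forward through the chain concentrates mass on likely
trajectory endpoints; propagating through the reversed chain marks likely
startpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA as _SKPCA
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError

__all__ = [
    "pool_layers",
    "fit_gamma",
    "velocity_field",
    "embed_for_velocity",
    "project_velocity",
    "transition_matrix",
    "markov_endpoints",
    "start_end_by_cluster",
    "VelocityModel",
    "velocity_pipeline",
]


def _as_dense(m) -> np.ndarray:
    if sp.issparse(m):
        return np.asarray(m.todense(), dtype=np.float64)
    return np.asarray(m, dtype=np.float64)


def pool_layers(
    spliced, unspliced, k: int = 30, n_pcs: int = 30, normalize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """kNN-smooth both layers (neighbors found in PC space of log1p spliced).

    With ``normalize`` both layers are first scaled per cell by the spliced
    total (to the median total), so sequencing-depth differences do not
    dominate the neighbor graph or the embedding downstream; the
    unspliced/spliced ratio per cell is unaffected.  Pooling over k = 30
    neighbors is the standard variance-reduction step before the steady-state
    fit; pass the raw layers downstream to skip it.
    """
    s = _as_dense(spliced)
    u = _as_dense(unspliced)
    if s.shape != u.shape:
        raise ConfigurationError("spliced and unspliced layers differ in shape")
    n = s.shape[0]
    if k >= n:
        raise ConfigurationError(f"k={k} must be smaller than the number of cells ({n})")
    if normalize:
        totals = s.sum(axis=1)
        if np.all(totals > 0):
            scale = np.median(totals) / totals
            s = s * scale[:, None]
            u = u * scale[:, None]
    logs = np.log1p(s)
    n_pcs = min(n_pcs, min(logs.shape) - 1)
    pcs = _SKPCA(n_components=n_pcs, random_state=0).fit_transform(logs)
    _, idx = NearestNeighbors(n_neighbors=k).fit(pcs).kneighbors(pcs)
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix((np.full(n * k, 1.0 / k), (rows, idx.ravel())), shape=(n, n))
    return A @ s, A @ u


def fit_gamma(
    spliced, unspliced, quantile: float = 0.05, min_cells: int = 30
) -> np.ndarray:
    """Per-gene degradation ratio from the extreme-quantile steady-state fit.

    For each gene, cells in the top and bottom ``quantile`` of spliced
    expression are pooled and gamma is the slope of the regression of u on s
    through the origin, clipped at zero.  Genes detected in fewer than
    ``min_cells`` cells get gamma = NaN and are excluded from the velocity
    field.
    """
    s = _as_dense(spliced)
    u = _as_dense(unspliced)
    if s.shape != u.shape:
        raise ConfigurationError("spliced and unspliced layers differ in shape")
    n = s.shape[0]
    lo = np.quantile(s, quantile, axis=0)
    hi = np.quantile(s, 1.0 - quantile, axis=0)
    sel = (s <= lo[None, :]) | (s >= hi[None, :])
    ss = np.where(sel, s, 0.0)
    us = np.where(sel, u, 0.0)
    denom = (ss * ss).sum(axis=0)
    numer = (us * ss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(denom > 0, numer / denom, 0.0)
    gamma = np.clip(gamma, 0.0, None)
    expressed = (s > 0).sum(axis=0)
    gamma[expressed < min_cells] = np.nan
    return gamma


def velocity_field(
    spliced, unspliced, gamma, recenter: bool = False, floor_quantile: float = 0.5
) -> np.ndarray:
    """Velocity matrix ``v = u - gamma * s``; genes with NaN gamma get v = 0.

    With ``recenter`` the per-gene median of ``v / s`` over well-expressed
    cells (spliced above the ``floor_quantile`` of the *expressing* cells) is
    subtracted times ``s``.  Most well-expressed cells are near steady state,
    so this median isolates any residual bias of the fitted gamma; without it
    such a bias turns into a spurious velocity of identical direction for
    every cell expressing the gene, which badly distorts downstream Markov
    tracing.  Restricting to well-expressed cells matters for genes private
    to a subpopulation, where ratios of near-zero counts are skewed.
    """
    s = _as_dense(spliced)
    u = _as_dense(unspliced)
    gamma = np.asarray(gamma, dtype=np.float64)
    if s.shape != u.shape or gamma.shape[0] != s.shape[1]:
        raise ConfigurationError("layer/gamma shapes do not match")
    g = np.where(np.isnan(gamma), 0.0, gamma)
    v = u - g[None, :] * s
    v[:, np.isnan(gamma)] = 0.0
    if recenter:
        for col in range(v.shape[1]):
            sg = s[:, col]
            expressed = sg > 0
            if expressed.sum() < 20:
                continue
            sel = sg > np.quantile(sg[expressed], floor_quantile)
            if sel.sum() >= 20:
                v[:, col] -= np.median(v[sel, col] / sg[sel]) * sg
    return v


def embed_for_velocity(spliced, n_pcs: int = 50) -> tuple[np.ndarray, _SKPCA]:
    """PC embedding of log1p spliced expression used for the transition kernel."""
    logs = np.log1p(_as_dense(spliced))
    n_pcs = min(n_pcs, min(logs.shape) - 1)
    model = _SKPCA(n_components=n_pcs, random_state=0)
    return model.fit_transform(logs), model


def project_velocity(velocity: np.ndarray, spliced, pca_model: _SKPCA) -> np.ndarray:
    """Carry velocities into the embedding space of :func:`embed_for_velocity`.

    Applies the chain rule of the log1p transform (``d log(1+s)/dt =
    v / (1+s)``) and the PCA loadings, so velocity and displacement live in
    the same coordinates.
    """
    s = _as_dense(spliced)
    return (velocity / (1.0 + s)) @ pca_model.components_.T


def transition_matrix(
    velocity_emb: np.ndarray,
    embeddings: np.ndarray,
    k: int = 50,
    sigma: float = 0.05,
    max_dist_factor: float = 3.0,
    magnitude_scaling: bool = True,
    diffusion: float = 0.3,
) -> sp.csr_matrix:
    """Row-stochastic velocity-driven transition matrix on the kNN graph.

    ``T[i, j] ∝ exp(corr(v_i, x_j - x_i) * m_i / sigma)`` for the k nearest
    neighbors j of i (plus the self edge at correlation 0); ``corr`` is the
    cosine correlation, defined as 0 when either vector vanishes.  With
    ``magnitude_scaling`` the sharpness of each row scales with the cell's
    relative velocity magnitude ``m_i`` (norm over the median norm, capped at
    1): cells with confident, fast velocity step decisively along it while
    near-steady-state cells, whose velocity direction is mostly noise,
    diffuse over their neighborhood.  Neighbors farther than
    ``max_dist_factor`` times the global median neighbor distance are
    dropped, so small isolated populations are not forced to exchange
    probability with remote cells.  A ``diffusion`` fraction of each row is
    spread uniformly over the neighborhood; without it, sharp kernels form
    two-cell cycles with noisy velocities and probability stops propagating.
    """
    v = np.asarray(velocity_emb, dtype=np.float64)
    x = np.asarray(embeddings, dtype=np.float64)
    if v.shape != x.shape:
        raise ConfigurationError("velocity and embeddings must have matching shape")
    n = x.shape[0]
    if k >= n:
        raise ConfigurationError(f"k={k} must be smaller than the number of cells ({n})")
    dist, idx = NearestNeighbors(n_neighbors=k + 1).fit(x).kneighbors(x)  # self + k
    cutoff = max_dist_factor * np.median(dist[:, 1:]) if max_dist_factor else np.inf

    rows, cols, vals = [], [], []
    vnorm = np.linalg.norm(v, axis=1)
    med = np.median(vnorm[vnorm > 0]) if np.any(vnorm > 0) else 1.0
    mag = np.minimum(vnorm / med, 1.0) if magnitude_scaling else np.ones(n)
    for i in range(n):
        keep = dist[i] <= cutoff
        keep[0] = True  # self edge always retained
        nbrs = idx[i][keep]
        delta = x[nbrs] - x[i]
        dnorm = np.linalg.norm(delta, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (delta @ v[i]) / (dnorm * vnorm[i])
        corr[~np.isfinite(corr)] = 0.0
        w = np.exp(corr * mag[i] / sigma)
        w /= w.sum()
        if diffusion > 0:
            w = (1.0 - diffusion) * w + diffusion / len(nbrs)
        rows.extend([i] * len(nbrs))
        cols.extend(nbrs.tolist())
        vals.extend(w.tolist())
    T = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    T.sum_duplicates()
    return T


def _check_stochastic(T: sp.csr_matrix) -> None:
    rowsums = np.asarray(T.sum(axis=1)).ravel()
    if np.any(T.data < -1e-12) or np.any(np.abs(rowsums - 1.0) > 1e-9):
        raise ConfigurationError("transition matrix is not row-stochastic")


def markov_endpoints(T: sp.csr_matrix, n_steps: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Startpoint and endpoint probabilities by finite-step propagation.

    The endpoint distribution propagates a uniform vector ``n_steps`` times
    through T; the startpoint distribution does the same through the
    row-normalized transpose (the reversed chain).  Both are renormalized to
    sum to one.
    """
    T = sp.csr_matrix(T)
    _check_stochastic(T)
    n = T.shape[0]

    def _propagate(M):
        p = np.full(n, 1.0 / n)
        for _ in range(n_steps):
            p = p @ M
            total = p.sum()
            if total <= 0:
                raise ConfigurationError("probability mass vanished during propagation")
            p /= total
        return p

    end_prob = _propagate(T)
    R = sp.csr_matrix(T.T).tolil()
    rowsums = np.asarray(R.sum(axis=1)).ravel()
    dead = rowsums == 0
    for i in np.flatnonzero(dead):  # pure sources: absorbing in the reversed chain
        R[i, i] = 1.0
    rowsums[dead] = 1.0
    R = sp.diags(1.0 / rowsums) @ sp.csr_matrix(R)
    start_prob = _propagate(R)
    return start_prob, end_prob


def start_end_by_cluster(start_prob, end_prob, clusters) -> pd.DataFrame:
    """Mean startpoint minus mean endpoint probability per cluster.

    Positive differences mark start-like (source) clusters, negative
    differences end-like (sink) clusters.
    """
    df = pd.DataFrame(
        {
            "cluster": np.asarray(clusters),
            "start_prob": np.asarray(start_prob, dtype=float),
            "end_prob": np.asarray(end_prob, dtype=float),
        }
    )
    g = df.groupby("cluster")
    out = pd.DataFrame(
        {
            "n": g.size(),
            "mean_start": g["start_prob"].mean(),
            "mean_end": g["end_prob"].mean(),
        }
    )
    out["start_minus_end"] = out["mean_start"] - out["mean_end"]
    return out.sort_values("start_minus_end", ascending=False)


@dataclass
class VelocityModel:
    """Fitted velocity model: gamma, velocities, transition chain, probabilities."""

    gamma: pd.Series
    velocity: np.ndarray
    embeddings: np.ndarray
    transition: sp.csr_matrix
    start_prob: np.ndarray
    end_prob: np.ndarray
    n_steps: int


def velocity_pipeline(
    adata,
    n_pcs: int = 50,
    pool_k: int = 30,
    field_pool_k: int = 10,
    quantile: float = 0.05,
    min_cells: int = 30,
    k_transition: int = 50,
    sigma: float = 0.2,
    diffusion: float = 0.3,
    n_steps: int = 200,
) -> VelocityModel:
    """Layers -> pooled gamma fit -> velocity -> transition -> start/end tracing.

    Gamma is fitted on heavily pooled layers (``pool_k``, variance
    reduction); the velocity field is computed on lightly pooled layers
    (``field_pool_k``) so that narrow transition regions between states are
    not smeared away.  Endpoint probabilities propagate a uniform
    distribution through the velocity-driven chain; startpoint probabilities
    propagate through the chain built from the negated velocity field, which
    traces the same flow backwards without the in-degree artifacts of a
    transposed kernel.
    """
    if "spliced" not in adata.layers or "unspliced" not in adata.layers:
        raise ConfigurationError("adata must carry spliced and unspliced layers")
    s_pool, u_pool = pool_layers(adata.layers["spliced"], adata.layers["unspliced"], k=pool_k)
    gamma = fit_gamma(s_pool, u_pool, quantile=quantile, min_cells=min_cells)
    s_f, u_f = pool_layers(
        adata.layers["spliced"], adata.layers["unspliced"], k=min(field_pool_k, adata.n_obs - 1)
    )
    v = velocity_field(s_f, u_f, gamma, recenter=True)
    emb, model = embed_for_velocity(s_f, n_pcs=n_pcs)
    v_emb = project_velocity(v, s_f, model)
    k_t = min(k_transition, adata.n_obs - 1)
    T = transition_matrix(v_emb, emb, k=k_t, sigma=sigma, diffusion=diffusion,
                          magnitude_scaling=False)
    T_rev = transition_matrix(-v_emb, emb, k=k_t, sigma=sigma, diffusion=diffusion,
                              magnitude_scaling=False)
    _, end = markov_endpoints(T, n_steps=n_steps)
    _, start = markov_endpoints(T_rev, n_steps=n_steps)
    return VelocityModel(
        gamma=pd.Series(gamma, index=adata.var_names, name="gamma"),
        velocity=v,
        embeddings=emb,
        transition=T,
        start_prob=start,
        end_prob=end,
        n_steps=n_steps,
    )
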
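"""Bifurcation trajectory: signed-PC projection, MST pseudotime, branch genes.

The four clusters around the trajectory bifurcation are projected onto the
two signed combinations of the first three principal components,

    u = -PC1 + (PC2 + PC3)        w = -PC1 - (PC2 + PC3),

which spread the cycling -> differentiated axis and the branch contrast into
a plane.  A random subset of at most 3,000 cells is linked by a Euclidean
minimum spanning tree; pseudotime is tree path length from a root cell (by
default the cell with the highest velocity startpoint probability), and the
bifurcation node is the tree node that best splits the remaining cells into
two large subtrees, whose members become branch-A and branch-B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse import csgraph
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "bifurcation_projection",
    "BifurcationTrajectory",
    "mst_pseudotime",
    "branch_dynamic_genes",
    "BranchProfile",
    "score_pc_correlation",
]


def bifurcation_projection(pcs: np.ndarray) -> np.ndarray:
    """Map cells to (u, w) = (-PC1 + (PC2+PC3), -PC1 - (PC2+PC3))."""
    pcs = np.asarray(pcs, dtype=np.float64)
    if pcs.ndim != 2 or pcs.shape[1] < 3:
        raise ConfigurationError("bifurcation projection needs at least 3 PCs")
    pc1, pc23 = pcs[:, 0], pcs[:, 1] + pcs[:, 2]
    return np.column_stack([-pc1 + pc23, -pc1 - pc23])


@dataclass
class BifurcationTrajectory:
    """MST trajectory over a subsample of cells in the (u, w) plane."""

    coords: np.ndarray  # subsample x 2
    cell_indices: np.ndarray  # positions of the subsample in the input
    edges: np.ndarray  # (n-1) x 3 array: node_i, node_j, weight
    root: int  # index into the subsample
    pseudotime: np.ndarray
    branch: np.ndarray  # 'trunk' | 'branch-A' | 'branch-B'
    bifurcation_node: int

    @property
    def n_cells(self) -> int:
        return len(self.cell_indices)

    @property
    def pseudotime_scaled(self) -> np.ndarray:
        """Pseudotime rescaled to [0, 1]."""
        span = self.pseudotime.max()
        return self.pseudotime / span if span > 0 else self.pseudotime.copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_index": self.cell_indices,
                "u": self.coords[:, 0],
                "w": self.coords[:, 1],
                "pseudotime": self.pseudotime,
                "pseudotime_scaled": self.pseudotime_scaled,
                "branch": self.branch,
            }
        )


def _tree_children(edges: np.ndarray, n: int, root: int):
    """Orient MST edges away from the root; returns children lists and order."""
    adj = [[] for _ in range(n)]
    for i, j, _ in edges:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    parent = np.full(n, -1, dtype=np.int64)
    order = [root]
    seen = np.zeros(n, dtype=bool)
    seen[root] = True
    head = 0
    while head < len(order):
        node = order[head]
        head += 1
        for nb in adj[node]:
            if not seen[nb]:
                seen[nb] = True
                parent[nb] = node
                order.append(nb)
    children = [[] for _ in range(n)]
    for node in order[1:]:
        children[parent[node]].append(node)
    return children, np.array(order), parent


def mst_pseudotime(
    coords: np.ndarray,
    eligible,
    max_cells: int = 3000,
    root: int | None = None,
    start_prob=None,
    seed: int = 0,
) -> BifurcationTrajectory:
    """Locate cells along a bifurcating trajectory with an MST.

    ``eligible`` is a boolean mask or index array over the rows of ``coords``
    (typically cells in the four clusters around the bifurcation).  When more
    than ``max_cells`` are eligible a seeded subsample without replacement is
    taken.  The root is the eligible cell with the highest ``start_prob``
    (per-cell, aligned with ``coords``) unless ``root`` gives an explicit cell
    index; pseudotime is MST path length from the root.  The bifurcation node
    maximizes the smaller of its two largest child subtrees; those two
    subtrees become branch-A (the larger) and branch-B, everything else is
    trunk.
    """
    coords = np.asarray(coords, dtype=np.float64)
    eligible = np.asarray(eligible)
    idx = np.flatnonzero(eligible) if eligible.dtype == bool else eligible.astype(np.int64)
    if idx.size < 4:
        raise ConfigurationError(f"only {idx.size} eligible cells; need at least 4")
    rng = np.random.default_rng(seed)
    if idx.size > max_cells:
        sub = rng.choice(idx, size=max_cells, replace=False)
        if root is not None and root not in sub:
            sub[-1] = root
        idx = np.sort(sub)
    pts = coords[idx]
    n = len(idx)
    dist = squareform(pdist(pts))
    mst = csgraph.minimum_spanning_tree(dist)
    mst_coo = mst.tocoo()
    edges = np.column_stack([mst_coo.row, mst_coo.col, mst_coo.data])
    sym = mst + mst.T

    if root is not None:
        pos = np.flatnonzero(idx == root)
        if pos.size == 0:
            raise ConfigurationError("explicit root is not among the eligible cells")
        root_local = int(pos[0])
    elif start_prob is not None:
        # candidate roots are the termini of the tree (the ends of long
        # paths), scored by the mean startpoint probability of their local
        # neighborhood; this keeps tracing noise in the interior of the
        # trajectory from capturing the root
        sp_sub = np.asarray(start_prob)[idx]
        degree = np.asarray((sym > 0).sum(axis=1)).ravel()
        candidates = np.flatnonzero(degree == 1)
        if candidates.size == 0:
            candidates = np.arange(n)
        m = min(100, n)
        scores = []
        for leaf in candidates:
            nearest = np.argsort(dist[leaf])[:m]
            scores.append(sp_sub[nearest].mean())
        root_local = int(candidates[int(np.argmax(scores))])
    else:
        raise ConfigurationError("provide either an explicit root or start_prob")

    pseudotime = csgraph.dijkstra(sym, directed=False, indices=root_local)

    children, order, parent = _tree_children(edges, n, root_local)
    sizes = np.ones(n, dtype=np.int64)
    for node in order[::-1]:
        for ch in children[node]:
            sizes[node] += sizes[ch]

    best_node, best_pair, best_key = -1, None, None
    for node in range(n):
        ch = children[node]
        if len(ch) < 2:
            continue
        ranked = sorted(ch, key=lambda c: (-sizes[c], c))
        # maximize the smaller of the two largest child subtrees;
        # ties go to the deeper node, then the smaller index, deterministically
        key = (sizes[ranked[1]], pseudotime[node], -node)
        if best_key is None or key > best_key:
            best_node, best_pair, best_key = node, (ranked[0], ranked[1]), key

    branch = np.full(n, "trunk", dtype=object)
    if best_node >= 0:
        for label, top in zip(("branch-A", "branch-B"), best_pair):
            stack = [top]
            while stack:
                node = stack.pop()
                branch[node] = label
                stack.extend(children[node])
    else:  # degenerate path-like tree: no branching at all
        best_node = int(np.argmax(pseudotime))

    return BifurcationTrajectory(
        coords=pts,
        cell_indices=idx,
        edges=edges,
        root=root_local,
        pseudotime=pseudotime,
        branch=branch.astype(str),
        bifurcation_node=int(best_node),
    )


@dataclass
class BranchProfile:
    """Smoothed pseudotime expression profiles for one branch."""

    genes: np.ndarray  # top_n gene names, ranked by smoothed variance
    profiles: pd.DataFrame  # cells (ordered by pseudotime) x top_n genes
    variances: pd.Series  # smoothed-profile variance for every gene
    linkage: np.ndarray | None  # complete-linkage tree on correlation distance


def branch_dynamic_genes(
    nm,
    trajectory: BifurcationTrajectory,
    window_frac: float = 0.1,
    top_n: int = 50,
    min_branch_cells: int = 20,
) -> dict[str, BranchProfile]:
    """Genes with dynamic expression along each branch.

    Cells of each branch are ordered by pseudotime; expression is smoothed by
    a centered rolling mean spanning ``window_frac`` of the branch; genes are
    ranked by the variance of the smoothed profile and the ``top_n`` are
    hierarchically clustered (complete linkage, correlation distance).
    """
    out = {}
    X = nm.X
    X = np.asarray(X.todense(), dtype=np.float64) if sp.issparse(X) else np.asarray(X, dtype=np.float64)
    for label in pd.unique(trajectory.branch):
        sel = trajectory.branch == label
        if sel.sum() < min_branch_cells:
            warnings.warn(f"branch {label!r} has fewer than {min_branch_cells} cells; skipped")
            continue
        cells = trajectory.cell_indices[sel]
        pt = trajectory.pseudotime[sel]
        order = np.argsort(pt, kind="stable")
        expr = pd.DataFrame(X[cells[order]], columns=nm.var_names)
        window = max(1, int(round(window_frac * len(cells))))
        smooth = expr.rolling(window, center=True, min_periods=1).mean()
        var = smooth.var(axis=0)
        dynamic = var[var > 0]  # flat genes are never dynamic
        top = dynamic.sort_values(ascending=False, kind="stable").head(top_n).index.to_numpy()
        link = None
        if len(top) >= 2:
            profs = smooth[top].to_numpy().T
            link = linkage(profs, method="complete", metric="correlation")
        out[label] = BranchProfile(
            genes=top, profiles=smooth[top], variances=var, linkage=link
        )
    return out


def score_pc_correlation(
    s_moff, pc1, n_bins: int = 20
) -> tuple[float, float, pd.DataFrame]:
    """Binned linear regression of the combined subtype score on PC1.

    Cells are binned into ``n_bins`` equal-width bins along each of the two
    variables; within each non-empty bin the means of both variables form one
    point; ordinary least squares over the pooled points gives the slope and
    Pearson r.
    """
    s = np.asarray(s_moff, dtype=np.float64)
    p = np.asarray(pc1, dtype=np.float64)
    if s.shape != p.shape:
        raise ConfigurationError("S_moff and PC1 must be aligned per cell")

    points = []
    for values, tag in ((s, "S_moff"), (p, "PC1")):
        lo, hi = values.min(), values.max()
        if hi == lo:
            continue
        bins = np.clip(((values - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
        for b in np.unique(bins):
            sel = bins == b
            points.append((tag, b, s[sel].mean(), p[sel].mean(), int(sel.sum())))
    table = pd.DataFrame(points, columns=["binned_by", "bin", "mean_S_moff", "mean_PC1", "n"])
    if len(table) < 3:
        raise ConfigurationError("fewer than 3 non-empty bins; cannot regress")
    fit = stats.linregress(table["mean_PC1"], table["mean_S_moff"])
    return float(fit.slope), float(fit.rvalue), table
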
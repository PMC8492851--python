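"""Gene-set module scores, cell-cycle phase calls and PDAC subtype scores.

A module score is the mean log-normalized expression of a gene set minus the
mean of expression-matched control genes: all genes are binned by average
expression, and for every signature gene ``n_ctrl`` control genes are sampled
from its bin.  The combined subtype score per cell is

    S_moff = max(0, S_cla) - max(0, S_bas)

so positive values indicate a classical-leaning cell and negative values a
basal-like-leaning cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError
from .signatures import (
    GeneSignature,
    g2m_signature,
    moffitt_basal,
    moffitt_classical,
    s_phase_signature,
)

__all__ = [
    "module_score",
    "cell_cycle_scores",
    "combined_moffitt",
    "moffitt_scores",
    "score_cells",
    "classify_subtype_heterogeneity",
    "HeterogeneityCall",
]


def _dense(nm: ad.AnnData, cols: np.ndarray) -> np.ndarray:
    X = nm.X
    if sp.issparse(X):
        return np.asarray(X[:, cols].todense(), dtype=np.float64)
    return np.asarray(X[:, cols], dtype=np.float64)


def module_score(
    nm: ad.AnnData,
    sig: GeneSignature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-matched module score per cell for one gene signature.

    Genes are ranked by mean expression and split into ``n_bins``
    equal-frequency bins; each signature gene draws ``n_ctrl`` control genes
    from its own bin (with replacement when the bin holds fewer than
    ``n_ctrl`` genes).  The score is mean(signature) - mean(controls).
    Signature genes absent from the matrix are dropped with a warning.
    """
    present = [g for g in sig.genes if g in nm.var_names]
    missing = set(sig.genes) - set(present)
    if not present:
        raise ConfigurationError(f"no gene of signature {sig.name!r} present in matrix")
    if missing:
        warnings.warn(
            f"signature {sig.name!r}: {len(missing)} gene(s) absent from matrix, dropped"
        )

    X = nm.X
    gene_means = (
        np.asarray(X.mean(axis=0)).ravel() if sp.issparse(X) else X.mean(axis=0)
    )
    n_bins = min(n_bins, nm.n_vars)
    # equal-frequency bins over mean expression (rank-based)
    order = np.argsort(gene_means, kind="stable")
    bin_of = np.empty(nm.n_vars, dtype=np.int64)
    bin_of[order] = np.minimum(
        (np.arange(nm.n_vars) * n_bins) // nm.n_vars, n_bins - 1
    )

    var_index = pd.Index(nm.var_names)
    sig_cols = var_index.get_indexer(present)
    rng = np.random.default_rng(seed)
    ctrl_cols = []
    for col in sig_cols:
        pool = np.flatnonzero(bin_of == bin_of[col])
        replace = pool.size < n_ctrl
        ctrl_cols.append(rng.choice(pool, size=min(n_ctrl, pool.size) if not replace else n_ctrl, replace=replace))
    ctrl_cols = np.concatenate(ctrl_cols)

    sig_mean = _dense(nm, sig_cols).mean(axis=1)
    ctrl_mean = _dense(nm, ctrl_cols).mean(axis=1)
    return pd.Series(sig_mean - ctrl_mean, index=nm.obs_names, name=sig.name)


def cell_cycle_scores(
    nm: ad.AnnData,
    s_sig: GeneSignature | None = None,
    g2m_sig: GeneSignature | None = None,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """S-phase and G2/M scores plus a discrete phase call per cell.

    Phase rule: G2M when ``g2m > s`` and ``g2m > 0``; S when ``s >= g2m`` and
    ``s > 0``; otherwise G1.
    """
    s_sig = s_sig or s_phase_signature()
    g2m_sig = g2m_sig or g2m_signature()
    s = module_score(nm, s_sig, n_bins, n_ctrl, seed=seed)
    g2m = module_score(nm, g2m_sig, n_bins, n_ctrl, seed=seed + 1)
    phase = np.where(
        (g2m.to_numpy() > s.to_numpy()) & (g2m.to_numpy() > 0),
        "G2M",
        np.where((s.to_numpy() >= g2m.to_numpy()) & (s.to_numpy() > 0), "S", "G1"),
    )
    return pd.DataFrame(
        {"s_score": s, "g2m_score": g2m, "phase": pd.Categorical(phase, ["G1", "S", "G2M"])},
        index=nm.obs_names,
    )


def combined_moffitt(s_cla, s_bas):
    """Combined subtype score max(0, S_cla) - max(0, S_bas), elementwise."""
    return np.maximum(0.0, np.asarray(s_cla, dtype=float)) - np.maximum(
        0.0, np.asarray(s_bas, dtype=float)
    )


def moffitt_scores(
    nm: ad.AnnData,
    cla_sig: GeneSignature | None = None,
    bas_sig: GeneSignature | None = None,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell classical (S_cla), basal-like (S_bas) and combined (S_moff) scores."""
    cla_sig = cla_sig or moffitt_classical()
    bas_sig = bas_sig or moffitt_basal()
    s_cla = module_score(nm, cla_sig, n_bins, n_ctrl, seed=seed)
    s_bas = module_score(nm, bas_sig, n_bins, n_ctrl, seed=seed + 1)
    return pd.DataFrame(
        {
            "S_cla": s_cla,
            "S_bas": s_bas,
            "S_moff": combined_moffitt(s_cla.to_numpy(), s_bas.to_numpy()),
        },
        index=nm.obs_names,
    )


def score_cells(nm: ad.AnnData, seed: int = 0) -> pd.DataFrame:
    """Convenience: subtype and cell-cycle scores in one table."""
    sub = moffitt_scores(nm, seed=seed)
    cc = cell_cycle_scores(nm, seed=seed + 10)
    return pd.concat([sub, cc], axis=1)


@dataclass
class HeterogeneityCall:
    """Per-organoid subtype heterogeneity verdict."""

    label: str  # homogeneous-classical | homogeneous-basal | heterogeneous
    table: pd.DataFrame  # per-cluster: n, frac, median S_moff, call
    indeterminate: bool = False


def classify_subtype_heterogeneity(
    s_moff: pd.Series,
    clusters,
    tau: float = 0.1,
    min_cluster_frac: float = 0.01,
) -> HeterogeneityCall:
    """Call an organoid homogeneous or heterogeneous from per-cluster medians.

    A cluster is classical when its median S_moff exceeds ``tau``, basal when
    below ``-tau``, else indeterminate.  The organoid is heterogeneous iff at
    least one classical and one basal cluster each hold at least
    ``min_cluster_frac`` of cells; otherwise homogeneous toward the majority
    call (ties / all-indeterminate lean with the overall median, flagged).
    """
    labels = np.asarray(clusters)
    df = pd.DataFrame({"cluster": labels, "S_moff": np.asarray(s_moff, dtype=float)})
    grouped = df.groupby("cluster")["S_moff"]
    table = pd.DataFrame(
        {"n": grouped.size(), "median_S_moff": grouped.median()}
    )
    table["frac"] = table["n"] / len(df)
    table["call"] = np.where(
        table["median_S_moff"] > tau,
        "classical",
        np.where(table["median_S_moff"] < -tau, "basal", "indeterminate"),
    )

    big = table[table["frac"] >= min_cluster_frac]
    has_cla = (big["call"] == "classical").any()
    has_bas = (big["call"] == "basal").any()
    if has_cla and has_bas:
        return HeterogeneityCall("heterogeneous", table)

    cla_cells = int(table.loc[table["call"] == "classical", "n"].sum())
    bas_cells = int(table.loc[table["call"] == "basal", "n"].sum())
    if cla_cells > bas_cells:
        return HeterogeneityCall("homogeneous-classical", table)
    if bas_cells > cla_cells:
        return HeterogeneityCall("homogeneous-basal", table)
    lean = "classical" if df["S_moff"].median() >= 0 else "basal"
    return HeterogeneityCall(f"homogeneous-{lean}", table, indeterminate=True)
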
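"""Synthetic PDAC-organoid cohorts with known ground truth.

The generator emulates the structure of the study cohort: a number of
patient-derived organoid lines, each a mixture of nine shared cell states —
five cycling states, two non-cycling (secretory/differentiated) states and
two smaller interferon- and chemokine-program states — arranged on a
cycling -> differentiated hierarchy with a bifurcation at a G1-like state
(``Cycling-5``) where cells either re-enter the cycle (via ``Cycling-1``) or
differentiate (``Noncycling-1`` -> ``Noncycling-2``).  The trunk starts at
``Cycling-4``, the designated trajectory source; ``Noncycling-2`` is the
designated sink.

Counts follow a negative-binomial model whose log-mean adds up gene programs:

* per-state marker blocks gated by smooth temporal windows over latent time,
* S-phase and G2/M gene lists active in the S-like and G2/M-like states,
* a "maturation" program of staggered transient bumps along the trunk (this
  is what gives cells within a state a resolvable ordering),
* branch-private bump programs after the bifurcation,
* classical/basal subtype programs weighted by a per-cell subtype weight
  (line-specific base mixture plus a trend along latent time, mirroring the
  coupling between subtype and differentiation),
* patient-private marker genes and a mild patient-specific wobble,
* mitochondrial genes whose expected count fraction is drawn per cell from a
  Beta distribution.

Spliced/unspliced layers follow first-order kinetics with splicing rate
beta = 1: deep inside a state the expected unspliced/spliced ratio of a gene
equals its true degradation rate ``gamma_true``; transient cells carry the
extra term ``ds/dt`` so that induced genes have positive velocity
``u - gamma * s``.

Every generator is deterministic given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError
from .signatures import g2m_signature, moffitt_basal, moffitt_classical, s_phase_signature

__all__ = [
    "STATE_NAMES",
    "DEFAULT_DRUGS",
    "CohortConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_kinetic_layers",
    "generate_drug_plate",
    "FishLayout",
    "FishImageSet",
    "generate_fish_images",
    "toy_fixture",
    "write_cohort",
    "sample_negative_binomial",
]

# ---------------------------------------------------------------------------
# state layout

STATE_NAMES = (
    "Cycling-1",
    "Cycling-2",
    "Cycling-3",
    "Cycling-4",
    "Cycling-5",
    "Noncycling-1",
    "Noncycling-2",
    "IFN-1",
    "CXC-1",
)

# (state, t_on, t_off, branch scope); trunk windows apply to every on-path cell
_TRUNK_SEGMENTS = (
    ("Cycling-4", 0.0, 1.0),
    ("Cycling-2", 1.0, 2.0),
    ("Cycling-3", 2.0, 3.0),
    ("Cycling-5", 3.0, 4.0),
)
_REENTRY_SEGMENTS = (("Cycling-1", 4.0, 6.0),)
_DIFF_SEGMENTS = (("Noncycling-1", 4.0, 5.0), ("Noncycling-2", 5.0, 6.0))
# expression windows on the differentiation branch are NESTED: the secretory
# Noncycling-1 program stays on for the rest of the branch and Noncycling-2
# markers switch on on top of it — so the branch identity, not the
# within-branch maturation step, dominates the principal axes
_DIFF_WINDOWS = (("Noncycling-1", 4.0, 6.0), ("Noncycling-2", 5.0, 6.0))
_OFF_PATH = ("IFN-1", "CXC-1")

T_MAX = 6.0
BIFURCATION_TIME = 4.0
SOURCE_STATE = "Cycling-4"
SINK_STATE = "Noncycling-2"

#: clusters linked by the bifurcation MST in the downstream analysis
BIFURCATION_CLUSTERS = ("Cycling-1", "Cycling-5", "Noncycling-1", "Noncycling-2")

DEFAULT_DRUGS = ("5-FU", "Gemcitabine", "Irinotecan", "Paclitaxel", "Erlotinib", "Oxaliplatin")
_DRUG_SHIFTS = {
    "5-FU": 0.00,
    "Gemcitabine": 0.08,
    "Irinotecan": -0.06,
    "Paclitaxel": 0.04,
    "Erlotinib": -0.10,
    "Oxaliplatin": 0.02,
}

_DEFAULT_STATE_FRACS = {
    "Cycling-4": 0.14,
    "Cycling-2": 0.13,
    "Cycling-3": 0.13,
    "Cycling-5": 0.14,
    "Cycling-1": 0.11,
    "Noncycling-1": 0.13,
    "Noncycling-2": 0.14,
    "IFN-1": 0.04,
    "CXC-1": 0.04,
}

_MITO_GENES = (
    "MT-ND1",
    "MT-ND2",
    "MT-CO1",
    "MT-CO2",
    "MT-ATP6",
    "MT-ATP8",
    "MT-CYB",
    "MT-ND3",
    "MT-ND4",
    "MT-RNR1",
)


def _smoothstep(x):
    """C1 ramp with compact support: 0 below 0, 1 above 1, 3x^2 - 2x^3 between."""
    xc = np.clip(x, 0.0, 1.0)
    return xc * xc * (3.0 - 2.0 * xc)


def _dsmoothstep(x):
    xc = np.clip(x, 0.0, 1.0)
    inside = (x > 0) & (x < 1)
    return np.where(inside, 6.0 * xc * (1.0 - xc), 0.0)


def _window(t, a, b, w):
    """Plateau window: smoothstep rise over [a, a+w], fall over [b-w, b].

    Exactly 0 outside [a, b] and exactly 1 on the interior plateau, so cells
    there are at a true kinetic steady state.
    """
    return _smoothstep((t - a) / w) * _smoothstep((b - t) / w)


def _dwindow(t, a, b, w):
    ra = _smoothstep((t - a) / w)
    rb = _smoothstep((b - t) / w)
    return (_dsmoothstep((t - a) / w) * rb - ra * _dsmoothstep((b - t) / w)) / w


# ---------------------------------------------------------------------------
# configuration


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort (defaults are the study conditions)."""

    n_lines: int = 12
    cells_per_line: int = 800
    n_genes: int = 2500
    n_states: int = 9
    subtype_mix: Sequence[float] | None = None  # per-line classical base weight
    noise_level: float = 1.0  # scales NB overdispersion (1/theta)
    qc_fail_frac: float = 0.04
    target_counts: float = 6000.0
    base_theta: float = 10.0
    state_fracs: Mapping[str, float] | None = None
    n_state_markers: int = 25
    n_maturation: int = 60
    n_branch_genes: int = 20
    n_line_private: int = 4
    amp_state: float = 3.0
    amp_cc: float = 1.8
    amp_maturation: float = 1.5
    amp_branch: float = 2.0
    amp_subtype: float = 0.9
    amp_line_private: float = 2.0
    line_private_baseline: float = 0.2
    line_wobble_sd: float = 0.05
    subtype_trend: float = 0.5
    subtype_noise: float = 0.05
    lib_sd: float = 0.35
    offpath_coupling: float = 0.0
    window_width: float = 0.2
    ramp_width: float = 0.2
    baseline_meanlog: float = -1.8
    baseline_sdlog: float = 1.0
    structured_meanlog: float = -1.0
    structured_sdlog: float = 0.4
    dispersion_factors: Mapping[str, float] | None = None

    def validate(self):
        if self.n_lines < 1:
            raise ConfigurationError("n_lines must be >= 1")
        if self.cells_per_line < 50:
            raise ConfigurationError("cells_per_line must be >= 50")
        if self.n_genes < 500:
            raise ConfigurationError("n_genes must be >= 500")
        if self.n_states != 9:
            raise ConfigurationError("only the default 9-state layout is supported")
        if self.subtype_mix is not None:
            mix = np.asarray(self.subtype_mix, dtype=float)
            if len(mix) != self.n_lines:
                raise ConfigurationError("subtype_mix must have one entry per line")
            if np.any((mix < 0) | (mix > 1)):
                raise ConfigurationError("subtype_mix entries must lie in [0, 1]")
        if not 0 <= self.qc_fail_frac < 1:
            raise ConfigurationError("qc_fail_frac must lie in [0, 1)")
        if self.noise_level < 0:
            raise ConfigurationError("noise_level must be >= 0")

    def line_mix(self) -> np.ndarray:
        if self.subtype_mix is not None:
            return np.asarray(self.subtype_mix, dtype=float)
        if self.n_lines == 1:
            return np.array([0.5])
        return np.linspace(0.15, 0.85, self.n_lines)


# ---------------------------------------------------------------------------
# gene panel


@dataclass
class GenePanel:
    names: np.ndarray
    mito: np.ndarray  # index arrays into names
    classical: np.ndarray
    basal: np.ndarray
    s_phase: np.ndarray
    g2m: np.ndarray
    state_markers: dict  # state -> index array
    maturation: np.ndarray
    mat_mid: np.ndarray
    mat_sign: np.ndarray
    reentry: np.ndarray
    reentry_mid: np.ndarray
    diff: np.ndarray
    diff_mid: np.ndarray
    line_private: dict  # line index -> index array


def _build_panel(cfg: CohortConfig, rng: np.random.Generator) -> GenePanel:
    names: list[str] = []

    def _add(block):
        start = len(names)
        names.extend(block)
        return np.arange(start, len(names))

    mito = _add(_MITO_GENES)
    classical = _add(moffitt_classical().genes)
    basal = _add(moffitt_basal().genes)
    s_phase = _add(s_phase_signature().genes)
    g2m = _add(g2m_signature().genes)
    state_markers = {
        st: _add(f"MK-{st}-{j + 1:02d}" for j in range(cfg.n_state_markers))
        for st in STATE_NAMES
    }
    maturation = _add(f"MAT-{j + 1:03d}" for j in range(cfg.n_maturation))
    reentry = _add(f"REE-{j + 1:02d}" for j in range(cfg.n_branch_genes))
    diff = _add(f"DIF-{j + 1:02d}" for j in range(cfg.n_branch_genes))
    line_private = {
        l: _add(f"LIN{l:02d}-{j + 1:02d}" for j in range(cfg.n_line_private))
        for l in range(cfg.n_lines)
    }
    if len(names) > cfg.n_genes:
        raise ConfigurationError(
            f"n_genes={cfg.n_genes} too small for the gene panel ({len(names)} structured genes)"
        )
    _add(f"GENE{j + 1:05d}" for j in range(cfg.n_genes - len(names)))

    # half the maturation genes are transient bumps (centers kept away from
    # the segment ends so both limbs are populated; the range extends through
    # the bifurcation so a shared early-branch program links the trunk to
    # both branches); the other half are cumulative steps that switch on at
    # staggered onsets and stay on, elongating the trajectory continuously
    # bump centers kept away from the ends of their segments so that every
    # gene's rising and falling limbs are populated with cells; the range
    # extends through the bifurcation so a shared early-branch program links
    # the trunk to both branches
    n_mat = cfg.n_maturation
    mat_mid = rng.uniform(0.6, 4.3, size=n_mat)
    mat_sign = np.ones(n_mat)  # all transient bumps
    reentry_mid = rng.uniform(4.7, 5.3, size=cfg.n_branch_genes)
    diff_mid = rng.uniform(4.7, 5.3, size=cfg.n_branch_genes)

    return GenePanel(
        names=np.array(names),
        mito=mito,
        classical=classical,
        basal=basal,
        s_phase=s_phase,
        g2m=g2m,
        state_markers=state_markers,
        maturation=maturation,
        mat_mid=mat_mid,
        mat_sign=mat_sign,
        reentry=reentry,
        reentry_mid=reentry_mid,
        diff=diff,
        diff_mid=diff_mid,
        line_private=line_private,
    )


# ---------------------------------------------------------------------------
# cohort model (everything needed to recompute expected means analytically)


@dataclass
class CohortModel:
    config: CohortConfig
    panel: GenePanel
    baseline: np.ndarray  # per-gene baseline mean (before effects)
    theta: np.ndarray  # per-gene NB size parameter
    line_wobble: np.ndarray  # n_lines x n_genes
    cells: pd.DataFrame  # per-cell latent variables (indexed by barcode)
    global_scale: float = 1.0

    def _temporal_effects(self, cells: pd.DataFrame, derivative: bool = False):
        """Log-scale temporal effect matrix E (and dE/dt if requested)."""
        cfg = self.config
        p = self.panel
        t = cells["latent_time"].to_numpy()
        branch = cells["branch_id"].to_numpy()
        on_path = cells["on_path"].to_numpy()
        n, g = len(cells), len(p.names)
        E = np.zeros((n, g))
        D = np.zeros((n, g)) if derivative else None
        w = cfg.window_width
        rw = cfg.ramp_width
        coup = np.where(on_path, 1.0, cfg.offpath_coupling)

        def _apply(cols, amp, win, dwin, mask=None):
            weight = coup if mask is None else coup * mask
            E[:, cols] += (amp * win * weight)[:, None]
            if derivative:
                D[:, cols] += (amp * dwin * weight)[:, None]

        segments = (
            [(st, a, b, None) for st, a, b in _TRUNK_SEGMENTS]
            + [(st, a, b, "cycle-reentry") for st, a, b in _REENTRY_SEGMENTS]
            + [(st, a, b, "differentiation") for st, a, b in _DIFF_WINDOWS]
        )
        for st, a, b, scope in segments:
            mask = None if scope is None else (branch == scope).astype(float)
            # walls centered on the segment boundaries so that consecutive
            # state programs cross-fade instead of leaving an unmarked gap
            win = _window(t, a - w / 2, b + w / 2, w)
            dwin = _dwindow(t, a - w / 2, b + w / 2, w)
            _apply(p.state_markers[st], cfg.amp_state, win, dwin, mask)
            if st == "Cycling-2":
                _apply(p.s_phase, cfg.amp_cc, win, dwin, mask)
            if st == "Cycling-3":
                _apply(p.g2m, cfg.amp_cc, win, dwin, mask)
            if st == "Cycling-4":
                _apply(p.g2m, 0.6 * cfg.amp_cc, win, dwin, mask)

        # staggered maturation bumps along the trunk: a wave train of
        # symmetric windows whose overlap encodes a continuous ordering in
        # latent time; plateaus are kept wider than walls so most expressing
        # cells sit at a kinetic steady state
        half = rw + 0.3
        a_m, b_m = p.mat_mid[None, :] - half, p.mat_mid[None, :] + half
        E[:, p.maturation] += (
            cfg.amp_maturation * _window(t[:, None], a_m, b_m, rw) * coup[:, None]
        )
        if derivative:
            D[:, p.maturation] += (
                cfg.amp_maturation * _dwindow(t[:, None], a_m, b_m, rw) * coup[:, None]
            )

        # branch-private bump programs after the bifurcation; sharper walls
        # keep them near zero at the bifurcation itself so expression stays
        # continuous across the branch point
        bw, bhalf = 0.15, 0.45
        for cols, mids, scope in (
            (p.reentry, p.reentry_mid, "cycle-reentry"),
            (p.diff, p.diff_mid, "differentiation"),
        ):
            mask = (branch == scope).astype(float) * coup
            a_b, b_b = mids[None, :] - bhalf, mids[None, :] + bhalf
            E[:, cols] += cfg.amp_branch * _window(t[:, None], a_b, b_b, bw) * mask[:, None]
            if derivative:
                D[:, cols] += (
                    cfg.amp_branch * _dwindow(t[:, None], a_b, b_b, bw) * mask[:, None]
                )

        # off-path state indicators
        state = cells["state_label"].to_numpy()
        for st in _OFF_PATH:
            sel = state == st
            if sel.any():
                E[np.ix_(sel, p.state_markers[st])] += cfg.amp_state

        # subtype programs: quasi-static for the kinetics (subtype identity
        # drifts on a much longer timescale than mRNA splicing/degradation,
        # so it contributes expression but no unspliced imbalance)
        wsub = cells["subtype_weight"].to_numpy()
        E[:, p.classical] += cfg.amp_subtype * wsub[:, None]
        E[:, p.basal] += cfg.amp_subtype * (1.0 - wsub)[:, None]
        return E, D

    def mean_matrix(self, cells: pd.DataFrame | None = None, derivative: bool = False):
        """Expected count matrix (and its latent-time derivative).

        The derivative covers the temporal programs only; static patient,
        library and mitochondrial factors multiply both identically.
        """
        cfg = self.config
        p = self.panel
        cells = self.cells if cells is None else cells
        E, D = self._temporal_effects(cells, derivative=derivative)

        line_idx = cells["line_index"].to_numpy()
        E += self.line_wobble[line_idx]
        for l, cols in p.line_private.items():
            sel = line_idx == l
            if sel.any():
                E[np.ix_(sel, cols)] += cfg.amp_line_private

        mu = self.baseline[None, :] * np.exp(E)
        lib = cells["lib_factor"].to_numpy()
        mu *= lib[:, None]

        # mitochondrial genes: expected count fraction f per cell
        f = cells["mito_target"].to_numpy()
        nonmito = np.delete(np.arange(mu.shape[1]), p.mito)
        row = mu[:, nonmito].sum(axis=1)
        props = np.linspace(1.0, 2.0, len(p.mito))
        props /= props.sum()
        mu[:, p.mito] = (f / (1.0 - f) * row)[:, None] * props[None, :]

        mu *= self.global_scale
        if derivative:
            # D is the logarithmic time derivative: ds/dt = mu * D
            return mu, D
        return mu


# ---------------------------------------------------------------------------
# truth container


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a synthetic cohort."""

    cells: pd.DataFrame  # state_label, latent_time, branch_id, subtype_weight, ...
    gamma_true: pd.Series
    sensitivity: pd.DataFrame  # lines x drugs, in [0, 1]
    model: CohortModel
    source_state: str = SOURCE_STATE
    sink_state: str = SINK_STATE
    bifurcation_time: float = BIFURCATION_TIME
    t_max: float = T_MAX

    @property
    def state_labels(self) -> pd.Series:
        return self.cells["state_label"]


def sample_negative_binomial(mean, theta, rng: np.random.Generator) -> np.ndarray:
    """NB counts with mean ``mean`` and variance ``mean + mean**2 / theta``."""
    mean = np.asarray(mean, dtype=np.float64)
    theta = np.broadcast_to(np.asarray(theta, dtype=np.float64), mean.shape)
    p = theta / (theta + np.maximum(mean, 1e-300))
    out = rng.negative_binomial(theta, p)
    return np.where(mean > 0, out, 0)


def generate_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Generate a synthetic organoid cohort with ground truth.

    Returns a cells x genes AnnData of raw integer counts (CSR) together with
    a :class:`SyntheticTruth`.  Identical (config, seed) pairs produce
    bitwise-identical output.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    panel = _build_panel(cfg, rng)
    n_genes = len(panel.names)
    n_cells = cfg.n_lines * cfg.cells_per_line

    baseline = np.exp(rng.normal(cfg.baseline_meanlog, cfg.baseline_sdlog, size=n_genes))
    # structured programs share a moderate baseline so "on" states stand out
    structured = np.concatenate(
        [panel.classical, panel.basal, panel.s_phase, panel.g2m]
        + [panel.state_markers[st] for st in STATE_NAMES]
        + [panel.maturation, panel.reentry, panel.diff]
        + list(panel.line_private.values())
    )
    baseline[structured] = np.exp(
        rng.normal(cfg.structured_meanlog, cfg.structured_sdlog, size=structured.size)
    )
    # patient-private markers: essentially silent outside their line
    for cols in panel.line_private.values():
        baseline[cols] = cfg.line_private_baseline
    baseline[panel.mito] = 1e-6  # replaced by the per-cell mito model

    theta = np.full(n_genes, cfg.base_theta)
    if cfg.noise_level > 0:
        theta /= cfg.noise_level
    if cfg.dispersion_factors:
        name_index = pd.Index(panel.names)
        for gene, factor in cfg.dispersion_factors.items():
            col = name_index.get_loc(gene)
            theta[col] /= factor

    line_wobble = rng.normal(0.0, cfg.line_wobble_sd, size=(cfg.n_lines, n_genes))

    fracs = dict(cfg.state_fracs or _DEFAULT_STATE_FRACS)
    states = np.array(list(fracs))
    pvec = np.array([fracs[s] for s in states], dtype=float)
    pvec /= pvec.sum()

    seg_by_state = {st: (a, b) for st, a, b in _TRUNK_SEGMENTS + _REENTRY_SEGMENTS + _DIFF_SEGMENTS}
    branch_of = {st: "trunk" for st, _, _ in _TRUNK_SEGMENTS}
    branch_of.update({st: "cycle-reentry" for st, _, _ in _REENTRY_SEGMENTS})
    branch_of.update({st: "differentiation" for st, _, _ in _DIFF_SEGMENTS})

    mix = cfg.line_mix()
    rows = []
    for l in range(cfg.n_lines):
        line_id = f"line{l:02d}"
        patient_id = f"p{101 + l}"
        state = rng.choice(states, size=cfg.cells_per_line, p=pvec)
        for i, st in enumerate(state):
            if st in seg_by_state:
                a, b = seg_by_state[st]
                t = rng.uniform(a, b)
                branch = branch_of[st]
                on_path = True
            else:
                t = rng.uniform(2.0, 4.0)
                branch = "trunk"
                on_path = False
            # subtype couples to differentiation progress: classical weight
            # rises along trunk and differentiation branch, and folds back
            # toward the cycling phenotype on the re-entry branch
            t_eff = BIFURCATION_TIME - (t - BIFURCATION_TIME) if branch == "cycle-reentry" else t
            wsub = mix[l] + cfg.subtype_trend * (t_eff / T_MAX - 0.5) * on_path
            wsub = float(np.clip(wsub + rng.normal(0.0, cfg.subtype_noise), 0.0, 1.0))
            rows.append(
                {
                    "barcode": f"{line_id}_BC{l * cfg.cells_per_line + i:05d}",
                    "line_id": line_id,
                    "patient_id": patient_id,
                    "line_index": l,
                    "state_label": st,
                    "latent_time": t,
                    "branch_id": branch,
                    "on_path": on_path,
                    "subtype_weight": wsub,
                }
            )
    cells = pd.DataFrame(rows).set_index("barcode")
    cells["lib_factor"] = np.exp(rng.normal(0.0, cfg.lib_sd, size=n_cells))
    cells["mito_target"] = rng.beta(2.0, 38.0, size=n_cells)
    cells["qc_fail"] = "none"

    # inject QC-failing cells with truth flags
    n_fail = int(round(cfg.qc_fail_frac * n_cells))
    if n_fail:
        fail_idx = rng.choice(n_cells, size=n_fail, replace=False)
        modes = np.array(["low_genes", "high_mito", "high_reads"])[
            np.arange(n_fail) % 3
        ]
        lib = cells["lib_factor"].to_numpy()
        mito = cells["mito_target"].to_numpy()
        qc = cells["qc_fail"].to_numpy(dtype=object)
        for idx, mode in zip(fail_idx, modes):
            qc[idx] = mode
            if mode == "low_genes":
                lib[idx] *= 0.008
            elif mode == "high_reads":
                lib[idx] *= 120.0
            else:
                mito[idx] = rng.uniform(0.25, 0.5)
        cells["lib_factor"] = lib
        cells["mito_target"] = mito
        cells["qc_fail"] = qc

    model = CohortModel(
        config=cfg,
        panel=panel,
        baseline=baseline,
        theta=theta,
        line_wobble=line_wobble,
        cells=cells,
    )
    mu = model.mean_matrix()
    healthy = (cells["qc_fail"] == "none").to_numpy()
    model.global_scale = cfg.target_counts / mu[healthy].sum(axis=1).mean()
    mu *= model.global_scale

    if cfg.noise_level > 0:
        counts = sample_negative_binomial(mu, theta[None, :], rng)
    else:
        counts = np.rint(mu).astype(np.int64)

    var = pd.DataFrame(index=pd.Index(panel.names, name="symbol"))
    var["gene_id"] = [f"SYN{j:05d}" for j in range(n_genes)]
    var["is_mito"] = var.index.str.startswith("MT-")
    obs = cells[["line_id", "patient_id", "state_label"]].copy()
    obs["site"] = "primary"
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    adata.uns["provenance"] = {"seed": int(seed), "generator": "orgstate.synth.generate_cohort"}

    gamma_true = pd.Series(rng.uniform(0.25, 0.9, size=n_genes), index=panel.names, name="gamma_true")

    sens = {}
    for drug in DEFAULT_DRUGS:
        shift = _DRUG_SHIFTS.get(drug, 0.0)
        sens[drug] = np.clip(0.12 + 0.7 * mix + shift, 0.02, 0.98)
    sensitivity = pd.DataFrame(sens, index=[f"line{l:02d}" for l in range(cfg.n_lines)])

    truth = SyntheticTruth(
        cells=cells,
        gamma_true=gamma_true,
        sensitivity=sensitivity,
        model=model,
    )
    return adata, truth


def generate_kinetic_layers(
    adata: ad.AnnData,
    truth: SyntheticTruth,
    beta_per_state: Mapping[str, float] | None = None,
    noise_level: float = 1.0,
    seed: int = 0,
) -> ad.AnnData:
    """Attach spliced/unspliced layers consistent with the cohort's kinetics.

    ``s = mu`` and ``u = s * (gamma + r) / beta`` where ``r`` is the
    logarithmic rate of change of the expected expression, rate-limited to
    ``[-gamma/2, +gamma/2]``: transcriptional modulation is slower than
    transcript turnover, bounding the unspliced imbalance symmetrically in
    both directions.  Deep inside a state ``r = 0`` and
    ``u / s = gamma_true`` exactly; transient induced genes have positive
    velocity ``u - gamma * s = s * r > 0`` and repressed genes negative.
    ``noise_level = 0`` stores the expectations as floats; otherwise both
    layers are Poisson draws around the expectations.
    """
    if truth.gamma_true is None or len(truth.gamma_true) != adata.n_vars:
        raise ConfigurationError("truth.gamma_true missing or mismatched with the matrix")
    cells = truth.cells.loc[adata.obs_names]
    mu, logderiv = truth.model.mean_matrix(cells, derivative=True)
    gamma = truth.gamma_true.loc[adata.var_names].to_numpy()

    beta = np.ones(adata.n_obs)
    if beta_per_state:
        state = cells["state_label"].to_numpy()
        for st, b in beta_per_state.items():
            if b <= 0:
                raise ConfigurationError(f"beta for state {st!r} must be positive")
            beta[state == st] = float(b)

    s_mean = mu
    # transcriptional modulation is rate-limited to half the turnover rate
    rate = np.clip(logderiv, -0.5 * gamma[None, :], 0.5 * gamma[None, :])
    u_mean = s_mean * (gamma[None, :] + rate) / beta[:, None]

    if noise_level > 0:
        rng = np.random.default_rng(seed)
        spliced = rng.poisson(s_mean).astype(np.float32)
        unspliced = rng.poisson(u_mean).astype(np.float32)
    else:
        # exact expectations; keep double precision for steady-state identities
        spliced, unspliced = s_mean, u_mean

    adata.layers["spliced"] = sp.csr_matrix(spliced)
    adata.layers["unspliced"] = sp.csr_matrix(unspliced)
    return adata


# ---------------------------------------------------------------------------
# drug plates


def _death_curve(conc, sens, d0=0.05, hill=1.5):
    dmax = d0 + 0.85 * sens
    ec50 = 10.0 ** (1.0 - 2.2 * sens)
    c = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        frac = np.where(c > 0, 1.0 / (1.0 + (ec50 / np.maximum(c, 1e-300)) ** hill), 0.0)
    return d0 + (dmax - d0) * frac


def _inhibition_curve(conc, sens, hill=1.5):
    ec50 = 10.0 ** (1.0 - 2.2 * sens)
    c = np.asarray(conc, dtype=float)
    return np.where(c > 0, (0.9 * sens) / (1.0 + (ec50 / np.maximum(c, 1e-300)) ** hill), 0.0)


def default_concentration_grid(c_max: float = 10.0, n: int = 8) -> np.ndarray:
    """1:3 dilution series from ``c_max`` downward (µM), highest first."""
    return c_max / 3.0 ** np.arange(n)


def generate_drug_plate(
    truth: SyntheticTruth,
    drugs: Sequence[str] | None = None,
    conc_grid: Sequence[float] | None = None,
    n_replicates: int = 3,
    noise_level: float = 0.05,
    baseline_area: float = 5000.0,
    control_growth: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a DeathPro-style imaging plate from the cohort's sensitivities.

    Death follows a logistic dose-response whose amplitude and EC50 scale with
    the line x drug sensitivity; total area follows exponential growth slowed
    by a logistic inhibition curve, so at ``noise_level = 0`` the recovered
    proliferation inhibition equals the generating inhibition exactly.  A c=0
    control well is always included.
    """
    drugs = tuple(drugs) if drugs is not None else tuple(truth.sensitivity.columns)
    grid = np.asarray(
        conc_grid if conc_grid is not None else default_concentration_grid(), dtype=float
    )
    if np.any(grid <= 0):
        raise ConfigurationError("concentrations must be positive (control c=0 is added automatically)")
    concs = np.concatenate([[0.0], np.sort(grid)])
    rng = np.random.default_rng(seed)

    rows = []
    for line in truth.sensitivity.index:
        for drug in drugs:
            if drug not in truth.sensitivity.columns:
                raise ConfigurationError(f"no sensitivity recorded for drug {drug!r}")
            s = float(truth.sensitivity.loc[line, drug])
            death = _death_curve(concs, s)
            fold = control_growth ** (1.0 - _inhibition_curve(concs, s))
            for ci, c in enumerate(concs):
                for rep in range(n_replicates):
                    def _jit():
                        return np.exp(rng.normal(0.0, noise_level)) if noise_level > 0 else 1.0

                    a0 = baseline_area * _jit()
                    a72 = a0 * fold[ci] * _jit()
                    dead = a72 * min(death[ci] * _jit(), 1.0)
                    rows.append(
                        {
                            "line_id": line,
                            "drug": drug,
                            "concentration": float(c),
                            "replicate": rep,
                            "A_total_0h": a0,
                            "A_total_72h": a72,
                            "A_dead_72h": dead,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FISH image sets


@dataclass
class FishLayout:
    """Geometry and signal content of a synthetic FISH field."""

    n_nuclei: int = 12
    shape: tuple[int, int] = (360, 360)
    radius: int = 13
    probe_coverage: Mapping[str, float | Sequence[float]] = field(
        default_factory=lambda: {"probe": 0.2}
    )
    gate_positive_frac: float = 1.0
    overlap_frac: float = 0.0
    noise_sd: float = 0.03
    blur_sigma: float = 1.5


@dataclass
class FishImageSet:
    """Named channels of one field plus the per-nucleus truth table."""

    channels: dict
    truth: pd.DataFrame
    sample_id: str = "synthetic"
    pixel_size: float | None = None

    def save(self, directory: str | Path) -> None:
        import tifffile

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, img in self.channels.items():
            tifffile.imwrite(directory / f"{name}.tif", img.astype(np.float32))
        self.truth.to_csv(directory / "truth.csv")


def generate_fish_images(layout: FishLayout | None = None, seed: int = 0) -> FishImageSet:
    """Render DAPI / gate / probe channels with known per-nucleus densities.

    Nuclei are disks placed without overlap (unless ``overlap_frac > 0``, in
    which case that fraction of nuclei is placed adjacent to another and
    flagged in the truth table).  Each probe channel lights up a specified
    fraction of each nucleus' pixels; the truth table records the realized
    fraction exactly.
    """
    lay = layout or FishLayout()
    if lay.n_nuclei < 1:
        raise ConfigurationError("n_nuclei must be >= 1")
    rng = np.random.default_rng(seed)
    h, wd = lay.shape
    r = lay.radius
    margin = r + 4
    min_sep = 2.6 * r

    centers: list[tuple[int, int]] = []
    overlapping: list[bool] = []
    n_overlap = int(round(lay.overlap_frac * lay.n_nuclei))
    attempts = 0
    while len(centers) < lay.n_nuclei and attempts < 20000:
        attempts += 1
        want_overlap = len(centers) >= lay.n_nuclei - n_overlap and centers
        if want_overlap:
            base = centers[rng.integers(len(centers))]
            ang = rng.uniform(0, 2 * np.pi)
            c = (
                int(np.clip(base[0] + 1.4 * r * np.sin(ang), margin, h - margin)),
                int(np.clip(base[1] + 1.4 * r * np.cos(ang), margin, wd - margin)),
            )
            centers.append(c)
            overlapping.append(True)
            continue
        c = (int(rng.integers(margin, h - margin)), int(rng.integers(margin, wd - margin)))
        if all((c[0] - y) ** 2 + (c[1] - x) ** 2 >= min_sep**2 for y, x in centers):
            centers.append(c)
            overlapping.append(False)
    if len(centers) < lay.n_nuclei:
        raise ConfigurationError("could not place all nuclei; reduce n_nuclei or radius")

    yy, xx = np.mgrid[0:h, 0:wd]
    dapi = np.zeros((h, wd))
    gate = np.zeros((h, wd))
    probes = {name: np.zeros((h, wd)) for name in lay.probe_coverage}

    gated = rng.random(lay.n_nuclei) < lay.gate_positive_frac
    records = []
    for k, (cy, cx) in enumerate(centers):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        dapi[disk] = 0.85
        if gated[k]:
            halo = (yy - cy) ** 2 + (xx - cx) ** 2 <= (r + 4) ** 2
            gate[halo] = 0.7
        rec = {"nucleus_id": k, "center_y": cy, "center_x": cx, "gated": bool(gated[k]),
               "overlapping": overlapping[k]}
        pix = np.flatnonzero(disk.ravel())
        for name, cov in lay.probe_coverage.items():
            frac = float(cov[k]) if np.ndim(cov) else float(cov)
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"probe coverage for {name!r} outside [0, 1]")
            n_on = int(round(frac * pix.size))
            chosen = rng.choice(pix, size=n_on, replace=False)
            flat = probes[name].ravel()
            flat[chosen] = 1.0
            rec[f"coverage_{name}"] = n_on / pix.size
        records.append(rec)

    from scipy.ndimage import gaussian_filter

    dapi = gaussian_filter(dapi, lay.blur_sigma)
    gate = gaussian_filter(gate, lay.blur_sigma)
    channels = {"dapi": dapi, "gate": gate}
    channels.update(probes)
    if lay.noise_sd > 0:
        for name in channels:
            channels[name] = np.clip(
                channels[name] + rng.normal(0.0, lay.noise_sd, size=(h, wd)), 0.0, None
            )
    truth = pd.DataFrame(records).set_index("nucleus_id")
    return FishImageSet(channels=channels, truth=truth)


# ---------------------------------------------------------------------------
# fixtures and provenance


_TOY_COUNTS = np.array(
    [
        [5, 0, 2, 0, 1, 3, 1, 0],
        [0, 4, 0, 1, 0, 2, 0, 6],
        [3, 1, 0, 0, 2, 0, 1, 2],
        [0, 0, 7, 2, 0, 1, 0, 0],
        [2, 3, 1, 0, 4, 0, 2, 1],
        [1, 0, 0, 5, 0, 0, 3, 0],
    ],
    dtype=np.int64,
)
_TOY_GENES = ("AGR2", "TFF1", "KRT17", "S100A2", "MKI67", "PCNA", "MT-CO1", "GENE00001")


def toy_fixture() -> tuple[ad.AnnData, dict]:
    """A hard-coded 6-cell x 8-gene count matrix used in worked examples."""
    var = pd.DataFrame(index=pd.Index(_TOY_GENES, name="symbol"))
    var["gene_id"] = [f"TOY{j:03d}" for j in range(len(_TOY_GENES))]
    var["is_mito"] = var.index.str.startswith("MT-")
    obs = pd.DataFrame(
        {"line_id": ["lineA"] * 3 + ["lineB"] * 3},
        index=pd.Index([f"TOYBC{i:02d}" for i in range(6)], name="barcode"),
    )
    adata = ad.AnnData(X=sp.csr_matrix(_TOY_COUNTS.copy()), obs=obs, var=var)
    meta = {"n_cells": 6, "n_genes": 8, "description": "toy fixture for worked examples"}
    return adata, meta


def write_cohort(adata: ad.AnnData, truth: SyntheticTruth, path: str | Path, seed: int | None = None) -> None:
    """Write the cohort as a 10x-convention directory plus truth and provenance."""
    from . import io_qc

    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    io_qc.write_counts_10x(adata, directory)
    truth.cells.to_csv(directory / "truth_cells.csv")
    truth.gamma_true.to_csv(directory / "truth_gamma.csv")
    truth.sensitivity.to_csv(directory / "truth_sensitivity.csv")
    cfg = {k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
           for k, v in vars(truth.model.config).items()
           if isinstance(v, (int, float, str, tuple, list, type(None), np.ndarray))}
    prov = {"config": cfg, "seed": seed if seed is not None else adata.uns.get("provenance", {}).get("seed")}
    (directory / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))
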
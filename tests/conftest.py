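"""Shared fixtures: synthetic cohorts generated once per session."""

from types import SimpleNamespace

import pytest

from orgstate import cluster, io_qc, synth


@pytest.fixture(scope="session")
def small_cohort():
    """A 2-line, 300-cell cohort for cheap unit tests."""
    cfg = synth.CohortConfig(n_lines=2, cells_per_line=150, n_genes=600)
    return synth.generate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort (12 lines x 800 cells), generated once."""
    return synth.generate_cohort(seed=1)


@pytest.fixture(scope="session")
def processed_cohort(default_cohort):
    """Default cohort taken through QC -> normalization -> HVG -> PCA."""
    adata, truth = default_cohort
    filtered, report = io_qc.qc_filter(adata)
    nm = io_qc.lognormalize(filtered)
    io_qc.select_hvg(nm, n=2000)
    scaled = io_qc.scale_center(nm)
    pca_model = cluster.pca(scaled, n_pcs=50)
    return SimpleNamespace(
        truth=truth,
        nm=nm,
        scaled=scaled,
        pca=pca_model,
        report=report,
    )
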
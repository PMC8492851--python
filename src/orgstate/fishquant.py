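"""RNA FISH quantification: nucleus segmentation and per-nucleus signal density.

Nuclei are segmented from the DAPI channel by Gaussian smoothing, Otsu
binarization and marker-based watershed on the distance transform.  Each
probe channel is Otsu-binarized and its signal density per nucleus is the
fraction of probe-positive pixels within the nucleus mask.  Nuclei are gated
on a marker channel (e.g. KRT19 for tumor cells); densities are normalized
across samples by the mean density of a reference sample.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import relabel_sequential, watershed

from .errors import ConfigurationError, FormatError

__all__ = [
    "read_channel_tiff",
    "segment_nuclei",
    "probe_density",
    "normalize_density",
]


def read_channel_tiff(path: str | Path) -> np.ndarray:
    """Load a single-channel TIFF as a float 2-D image."""
    import tifffile

    img = np.asarray(tifffile.imread(path), dtype=np.float64)
    if img.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel 2-D image, got shape {img.shape}")
    return img


def _binarize(image: np.ndarray) -> np.ndarray:
    """Otsu binarization; a (near-)constant image yields an empty mask."""
    if np.ptp(image) == 0:
        return np.zeros_like(image, dtype=bool)
    return image > threshold_otsu(image)


def segment_nuclei(
    dapi: np.ndarray,
    sigma: float = 2.0,
    min_distance: int = 10,
    min_area: int = 50,
) -> np.ndarray:
    """Label image of nuclei from a DAPI channel.

    Gaussian smoothing (``sigma`` px) -> Otsu binarization -> Euclidean
    distance transform -> local peaks at least ``min_distance`` px apart as
    watershed markers -> watershed; objects below ``min_area`` px are
    removed.  A blank image yields zero labels.
    """
    dapi = np.asarray(dapi, dtype=np.float64)
    if dapi.ndim != 2:
        raise FormatError("DAPI image must be 2-D")
    smooth = gaussian(dapi, sigma=sigma, preserve_range=True)
    mask = _binarize(smooth)
    if not mask.any():
        return np.zeros(dapi.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(distance, min_distance=min_distance, labels=mask)
    markers = np.zeros(dapi.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask)
    sizes = np.bincount(labels.ravel())
    too_small = np.flatnonzero(sizes < min_area)
    labels[np.isin(labels, too_small)] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def probe_density(
    labels: np.ndarray,
    probe: np.ndarray | Mapping[str, np.ndarray],
    gate: np.ndarray,
    gate_frac: float = 0.1,
) -> pd.DataFrame:
    """Per-nucleus binarized signal density for one or more probe channels.

    A nucleus is gated when at least ``gate_frac`` of its pixels are positive
    in the Otsu-binarized gate channel.  The density of a probe is the
    fraction of probe-positive pixels within the nucleus mask (in [0, 1]).
    Ungated nuclei are retained, flagged, and excluded from summaries.
    """
    labels = np.asarray(labels)
    probes = probe if isinstance(probe, Mapping) else {"probe": probe}
    for name, img in probes.items():
        if np.asarray(img).shape != labels.shape:
            raise FormatError(f"probe channel {name!r} shape differs from label image")
    if np.asarray(gate).shape != labels.shape:
        raise FormatError("gate channel shape differs from label image")

    gate_mask = _binarize(np.asarray(gate, dtype=np.float64))
    probe_masks = {n: _binarize(np.asarray(img, dtype=np.float64)) for n, img in probes.items()}

    rows = []
    for region in regionprops(labels):
        sel = labels == region.label
        area = int(sel.sum())
        gated = gate_mask[sel].mean() >= gate_frac
        rec = {
            "nucleus_id": region.label,
            "area": area,
            "centroid_y": region.centroid[0],
            "centroid_x": region.centroid[1],
            "gated": bool(gated),
        }
        for name, mask in probe_masks.items():
            rec[f"density_{name}"] = float(mask[sel].mean())
        rows.append(rec)
    table = pd.DataFrame(
        rows,
        columns=["nucleus_id", "area", "centroid_y", "centroid_x", "gated"]
        + [f"density_{n}" for n in probe_masks],
    )
    if len(table) and not table["gated"].any():
        warnings.warn("no nucleus passes the gate; summaries will be empty")
    return table


def normalize_density(
    tables: Mapping[str, pd.DataFrame], reference_sample: str
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Normalize per-nucleus densities to the reference sample's mean density.

    For every probe, each sample's densities (gated nuclei only) are divided
    by the reference sample's mean density for that probe, so the reference
    normalizes to mean 1.  Returns the augmented per-sample tables and a
    summary with mean normalized density and its standard error per
    sample x probe.  Probes whose reference mean is 0 are skipped with a
    warning.
    """
    if reference_sample not in tables:
        raise ConfigurationError(f"reference sample {reference_sample!r} not among tables")
    ref = tables[reference_sample]
    ref_gated = ref[ref["gated"]]
    if ref_gated.empty:
        raise ConfigurationError("reference sample has no gated nucleus")

    probe_cols = [c for c in ref.columns if c.startswith("density_")]
    ref_means = {}
    for col in probe_cols:
        m = float(ref_gated[col].mean())
        if m == 0:
            warnings.warn(f"reference mean density is 0 for {col!r}; normalization skipped")
            continue
        ref_means[col] = m

    out_tables = {}
    summary_rows = []
    for sample, table in tables.items():
        table = table.copy()
        gated = table["gated"]
        for col, m in ref_means.items():
            table[f"norm_{col[len('density_'):]}"] = table[col] / m
        out_tables[sample] = table
        for col, m in ref_means.items():
            vals = table.loc[gated, col] / m
            summary_rows.append(
                {
                    "sample": sample,
                    "probe": col[len("density_"):],
                    "n_nuclei": int(gated.sum()),
                    "mean_norm_density": float(vals.mean()) if len(vals) else np.nan,
                    "sem": float(vals.sem(ddof=1)) if len(vals) > 1 else np.nan,
                }
            )
    return out_tables, pd.DataFrame(summary_rows)
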
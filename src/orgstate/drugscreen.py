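"""DeathPro-style quantification of drug-induced death and growth inhibition.

From binarized imaging areas at 0 h and 72 h the module derives, per
organoid line and drug:

* ``cd(c)`` — death fraction, dead-cell area over total cell area at 72 h;
* ``pi(c)`` — proliferation inhibition, ``1 - ln g(c) / ln g(0)`` clamped to
  [0, 1], where ``g = A_total_72h / A_total_0h`` is the growth fold;
* AUCd / AUCpi — trapezoidal integrals over log10 concentration, normalized
  by the log-concentration range so both live in [0, 1]; control death is
  subtracted inside AUCd;
* an LD50 from a 4-parameter logistic fit of cd against log10 concentration,
  reported only when a one-way ANOVA across concentration groups is
  significant at the gate (p < 0.0005).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, FormatError

__all__ = [
    "validate_plate",
    "death_fraction",
    "proliferation_inhibition",
    "auc_metrics",
    "ld50_fit",
    "LD50Result",
    "drug_response",
    "subtype_drug_correlation",
    "response_overview",
]

PLATE_COLUMNS = (
    "line_id",
    "drug",
    "concentration",
    "replicate",
    "A_total_0h",
    "A_total_72h",
    "A_dead_72h",
)


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Schema and invariant checks for a drug-screen plate table."""
    missing = set(PLATE_COLUMNS) - set(plate.columns)
    if missing:
        raise FormatError(f"plate table missing columns: {sorted(missing)}")
    if (plate["concentration"] < 0).any():
        raise FormatError("negative concentrations in plate")
    if (plate["A_dead_72h"] > plate["A_total_72h"] + 1e-9).any():
        raise FormatError("dead-cell area exceeds total area in some well")
    for (line, drug), grp in plate.groupby(["line_id", "drug"]):
        concs = np.sort(grp["concentration"].unique())
        if concs[0] != 0:
            raise FormatError(f"{line}/{drug}: no c=0 control well")
        if (concs > 0).sum() < 3:
            raise FormatError(f"{line}/{drug}: fewer than 3 nonzero concentrations")
    return plate


def death_fraction(plate: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged death fraction cd(c) per line x drug x concentration."""
    zero = plate["A_total_72h"] <= 0
    if zero.any():
        row = plate[zero].iloc[0]
        raise FormatError(
            f"zero total area at 72h in well {row['line_id']}/{row['drug']}"
            f"/c={row['concentration']}/rep={row['replicate']}"
        )
    df = plate.copy()
    df["cd"] = df["A_dead_72h"] / df["A_total_72h"]
    return (
        df.groupby(["line_id", "drug", "concentration"], as_index=False)["cd"]
        .mean()
        .sort_values(["line_id", "drug", "concentration"], kind="stable")
        .reset_index(drop=True)
    )


def proliferation_inhibition(plate: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged proliferation inhibition pi(c) per line x drug x conc.

    Growth normalization is the log-ratio ``ln g(c) / ln g(0)``; control
    growth must exceed 1 or inhibition is undefined.
    """
    df = plate.copy()
    if (df["A_total_0h"] <= 0).any():
        raise FormatError("zero total area at 0h in some well")
    df["growth"] = df["A_total_72h"] / df["A_total_0h"]
    out = []
    for (line, drug), grp in df.groupby(["line_id", "drug"]):
        ctrl = grp.loc[grp["concentration"] == 0, "growth"]
        if ctrl.empty:
            raise FormatError(f"{line}/{drug}: no c=0 control well")
        g0 = ctrl.mean()
        if g0 <= 1:
            raise ConfigurationError(
                f"{line}/{drug}: control growth g(0)={g0:.3f} <= 1; inhibition undefined"
            )
        ghat = np.log(grp["growth"].to_numpy()) / np.log(g0)
        pi = np.clip(1.0 - ghat, 0.0, 1.0)
        sub = grp[["line_id", "drug", "concentration"]].copy()
        sub["pi"] = pi
        out.append(sub)
    res = pd.concat(out, ignore_index=True)
    return (
        res.groupby(["line_id", "drug", "concentration"], as_index=False)["pi"]
        .mean()
        .sort_values(["line_id", "drug", "concentration"], kind="stable")
        .reset_index(drop=True)
    )


def _normalized_auc(y: np.ndarray, logc: np.ndarray) -> float:
    span = logc[-1] - logc[0]
    if span <= 0:
        raise ConfigurationError("degenerate concentration range")
    return float(np.trapezoid(y, logc) / span)


def auc_metrics(cd, pi, concentrations) -> tuple[float, float]:
    """Normalized AUC of death (baseline-subtracted) and inhibition curves.

    ``cd`` and ``pi`` are aligned with ``concentrations`` (which must include
    the c=0 control for the death baseline); the integrals run over log10 of
    the nonzero concentrations, divided by the log10 range, so both values
    lie in [0, 1].  Unordered concentrations are sorted; duplicates averaged.
    """
    conc = np.asarray(concentrations, dtype=float)
    cd = np.asarray(cd, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if not (len(conc) == len(cd) == len(pi)):
        raise ConfigurationError("cd, pi and concentrations must be aligned")
    frame = (
        pd.DataFrame({"c": conc, "cd": cd, "pi": pi})
        .groupby("c", as_index=False)
        .mean()
        .sort_values("c", kind="stable")
    )
    cd0 = float(frame.loc[frame["c"] == 0, "cd"].iloc[0]) if (frame["c"] == 0).any() else 0.0
    nz = frame[frame["c"] > 0]
    if len(nz) < 3:
        raise ConfigurationError("need at least 3 nonzero concentrations")
    logc = np.log10(nz["c"].to_numpy())
    auc_d = _normalized_auc(np.clip(nz["cd"].to_numpy() - cd0, 0.0, 1.0), logc)
    auc_pi = _normalized_auc(np.clip(nz["pi"].to_numpy(), 0.0, 1.0), logc)
    return auc_d, auc_pi


@dataclass
class LD50Result:
    """Gated logistic-fit midpoint; ``ld50`` is None when the gate fails."""

    ld50: float | None
    anova_p: float
    converged: bool = True


def _logistic4(logc, lo, hi, mid, slope):
    return lo + (hi - lo) / (1.0 + 10.0 ** (slope * (mid - logc)))


def ld50_fit(
    cd_replicates: pd.DataFrame, gate_p: float = 0.0005
) -> LD50Result:
    """ANOVA-gated 4-parameter logistic LD50 for one line x drug series.

    ``cd_replicates`` holds replicate-level death fractions with columns
    ``concentration`` and ``cd`` (the c=0 control included).  A one-way ANOVA
    across concentration groups gates the fit; when significant, the logistic
    midpoint of mean cd against log10 concentration is reported in the same
    concentration units.
    """
    if not {"concentration", "cd"} <= set(cd_replicates.columns):
        raise FormatError("cd_replicates needs 'concentration' and 'cd' columns")
    groups = [g["cd"].to_numpy() for _, g in cd_replicates.groupby("concentration")]
    if len(groups) < 2:
        raise ConfigurationError("need at least two concentration groups for the ANOVA gate")
    anova_p = float(stats.f_oneway(*groups).pvalue)
    if not anova_p < gate_p:
        return LD50Result(ld50=None, anova_p=anova_p)

    means = (
        cd_replicates[cd_replicates["concentration"] > 0]
        .groupby("concentration")["cd"]
        .mean()
        .sort_index()
    )
    logc = np.log10(means.index.to_numpy())
    y = means.to_numpy()
    p0 = (max(y.min(), 0.0), min(max(y.max(), 0.1), 1.0), float(np.median(logc)), 1.0)
    try:
        popt, _ = optimize.curve_fit(
            _logistic4,
            logc,
            y,
            p0=p0,
            bounds=([0, 0, logc.min() - 2, 0.1], [1, 1.5, logc.max() + 2, 10]),
            maxfev=10000,
        )
    except RuntimeError:
        return LD50Result(ld50=None, anova_p=anova_p, converged=False)
    return LD50Result(ld50=float(10.0 ** popt[2]), anova_p=anova_p)


def drug_response(plate: pd.DataFrame, gate_p: float = 0.0005) -> pd.DataFrame:
    """Full per line x drug response table: AUCd, AUCpi, gated LD50, ANOVA p."""
    validate_plate(plate)
    cd = death_fraction(plate)
    pi = proliferation_inhibition(plate)
    merged = cd.merge(pi, on=["line_id", "drug", "concentration"])
    reps = plate.copy()
    reps["cd"] = reps["A_dead_72h"] / reps["A_total_72h"]
    rows = []
    for (line, drug), grp in merged.groupby(["line_id", "drug"]):
        auc_d, auc_pi = auc_metrics(grp["cd"], grp["pi"], grp["concentration"])
        sub = reps[(reps["line_id"] == line) & (reps["drug"] == drug)]
        ld = ld50_fit(sub[["concentration", "cd"]], gate_p=gate_p)
        rows.append(
            {
                "line_id": line,
                "drug": drug,
                "AUCd": auc_d,
                "AUCpi": auc_pi,
                "LD50": ld.ld50,
                "anova_p": ld.anova_p,
                "ld50_converged": ld.converged,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["auc_scale"] = "normalized trapezoid over log10 concentration"
    return out


def subtype_drug_correlation(
    s_moff_per_line: pd.Series,
    aucpi: pd.DataFrame,
    method: str = "pearson",
    min_lines: int = 4,
) -> pd.DataFrame:
    """Correlation between per-line median subtype score and AUCpi, per drug.

    ``aucpi`` is a long table with columns line_id, drug, AUCpi (as produced
    by :func:`drug_response`).  Drugs with fewer than ``min_lines`` paired
    observations are skipped with a warning; constant AUCpi yields an absent
    (NaN) coefficient.
    """
    if method not in ("pearson", "spearman"):
        raise ConfigurationError("method must be 'pearson' or 'spearman'")
    rows = []
    for drug, grp in aucpi.groupby("drug"):
        paired = grp.set_index("line_id")["AUCpi"].dropna()
        shared = paired.index.intersection(s_moff_per_line.index)
        if len(shared) < min_lines:
            warnings.warn(f"drug {drug!r}: only {len(shared)} paired lines; skipped")
            continue
        x = s_moff_per_line.loc[shared].to_numpy(dtype=float)
        y = paired.loc[shared].to_numpy(dtype=float)
        if np.std(y) == 0 or np.std(x) == 0:
            rows.append({"drug": drug, "r": np.nan, "p": np.nan, "n": len(shared)})
            continue
        if method == "pearson":
            r, p = stats.pearsonr(x, y)
        else:
            r, p = stats.spearmanr(x, y)
        rows.append({"drug": drug, "r": float(r), "p": float(p), "n": len(shared)})
    return pd.DataFrame(rows)


def response_overview(
    s_moff_per_line: pd.Series,
    cc_score_per_line: pd.Series,
    aucpi_per_line: pd.Series,
) -> pd.DataFrame:
    """Z-scored per-line overview: subtype score, cell-cycle score, AUCpi."""
    df = pd.DataFrame(
        {
            "S_moff": s_moff_per_line,
            "cell_cycle": cc_score_per_line,
            "AUCpi": aucpi_per_line,
        }
    ).dropna()
    z = (df - df.mean()) / df.std(ddof=0).replace(0, np.nan)
    return z
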
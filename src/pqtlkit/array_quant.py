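"""Raw array features -> normalized, filtered protein matrix.

Stages (in pipeline order):

1. :func:`background_correct` — subtract local background; negative corrected
   intensities are excluded.
2. :func:`snr_filter` — drop features with signal-to-noise ratio < 3
   (one-sided normal z test at the same boundary).
3. :func:`quantile_normalize` — log2-quantile normalization of the feature
   intensity distributions across the arrays of a print group, so array-wide
   hybridization-efficiency differences cancel.
4. :func:`load_normalize` — remove the per-sample load effect lambda_j,
   estimated as the median of the sample's normalized intensities across all
   arrays of the print (median sample-load normalization; housekeeping-protein
   normalization is deliberately not the default because housekeeping levels
   co-vary with growth rate).
5. :func:`batch_correct` — per-antibody per-batch median shift for MWA gels.
6. :func:`aggregate_replicates` — average technical replicates, resolve
   dual-platform antibodies by the platform with the higher median
   background-corrected intensity, keep the biological-replicate axis.
7. :func:`qc_filter` — drop antibodies in the bottom quantile of median
   intensity or median SNR or the top quantile of technical CV (quartile or
   decile mode).

:func:`quantify` chains all stages. :func:`classify_antibody` implements the
screening rule assigning antibodies to RPPA (single predominant on-size band)
or MWA (on-size band plus extras).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ProteinMatrix

__all__ = [
    "BandProfile",
    "background_correct",
    "snr_filter",
    "classify_antibody",
    "quantile_normalize",
    "load_normalize",
    "batch_correct",
    "aggregate_replicates",
    "qc_filter",
    "antibody_pair_concordance",
    "quantify",
]


@dataclass
class BandProfile:
    """Screening lane profile for one antibody: bands with signal and SNR."""

    antibody_id: str
    bands: list[tuple[float, float, float]]  # (mw_kda, signal, snr)
    predicted_mw: float

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("a band profile needs at least one band")
        if any(sig < 0 for _, sig, _ in self.bands):
            raise ValueError("band signals must be nonnegative")


def background_correct(features: pd.DataFrame) -> pd.DataFrame:
    """Attach background-corrected intensity; flag negative values excluded."""
    if "background" not in features.columns:
        raise ValueError("feature table lacks a 'background' column")
    out = features.copy()
    out["corrected_intensity"] = out["raw_intensity"] - out["background"]
    out["excluded"] = out.get("excluded", False) | (out["corrected_intensity"] < 0)
    out.loc[out["corrected_intensity"] < 0, "exclusion_reason"] = "negative_intensity"
    return out


def snr_filter(features: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """Flag features whose SNR = corrected / noise_sd falls below ``threshold``.

    The boundary is inclusive: SNR exactly at the threshold is retained. A
    one-sided normal tail probability of the SNR is attached as ``snr_p``.
    """
    if (features["noise_sd"] <= 0).any():
        raise ValueError("noise_sd must be positive for every feature")
    out = features.copy()
    out["snr"] = out["corrected_intensity"] / out["noise_sd"]
    out["snr_p"] = stats.norm.sf(out["snr"])
    low = (out["snr"] < threshold) & ~out["excluded"]
    out.loc[low, "exclusion_reason"] = "low_snr"
    out["excluded"] = out["excluded"] | low
    return out


def classify_antibody(
    profile: BandProfile, mw_tolerance_frac: float = 0.15
) -> str:
    """Screening decision: ``"RPPA"``, ``"MWA"`` or ``"FAIL"``.

    An antibody qualifies for RPPA when a band within ``mw_tolerance_frac``
    of the predicted molecular weight has SNR >= 3 and carries more than 75%
    of the total lane signal; with a qualifying on-size band but <= 75% of
    the signal it goes to MWA; otherwise it fails screening.
    """
    if profile.predicted_mw <= 0:
        raise ValueError("predicted molecular weight must be positive")
    total = sum(sig for _, sig, _ in profile.bands)
    tol = mw_tolerance_frac * profile.predicted_mw
    best = None
    for mw, sig, snr in profile.bands:
        if abs(mw - profile.predicted_mw) <= tol and snr >= 3.0:
            if best is None or sig > best:
                best = sig
    if best is None:
        return "FAIL"
    if total > 0 and best / total > 0.75:
        return "RPPA"
    return "MWA"


def quantile_normalize(
    arrays: dict[str, np.ndarray], log2: bool = True
) -> dict[str, np.ndarray]:
    """Quantile-normalize intensity vectors across arrays.

    Each array's sorted values are replaced by the across-array mean of the
    order statistics and reassigned by rank; tied values receive the average
    of the order-statistic values they span. With ``log2=True`` the inputs
    are log2-transformed first (all values must then be positive).

    Arrays of unequal length are mapped through the mean distribution by
    linear interpolation on the common quantile grid.
    """
    if len(arrays) < 2:
        raise ValueError("quantile normalization needs at least two arrays")
    prepared = {}
    for name, vec in arrays.items():
        vec = np.asarray(vec, dtype=float)
        if log2:
            if np.any(vec <= 0):
                raise ValueError(
                    f"array {name!r} has nonpositive intensities; "
                    "excluded features must be removed before normalization"
                )
            vec = np.log2(vec)
        prepared[name] = vec

    lengths = {v.size for v in prepared.values()}
    n_ref = max(lengths)
    grid = np.linspace(0.0, 1.0, n_ref)
    sorted_on_grid = []
    for vec in prepared.values():
        s = np.sort(vec)
        if s.size == n_ref:
            sorted_on_grid.append(s)
        else:
            sorted_on_grid.append(
                np.interp(grid, np.linspace(0.0, 1.0, s.size), s)
            )
    mean_sorted = np.mean(sorted_on_grid, axis=0)

    out = {}
    for name, vec in prepared.items():
        n = vec.size
        # average fractional ranks handle ties: interpolate between the
        # order-statistic values the tie group would have received
        ranks = stats.rankdata(vec, method="average") - 1.0
        if n == n_ref:
            ref = mean_sorted
        else:
            ref = np.interp(np.linspace(0.0, 1.0, n), grid, mean_sorted)
        out[name] = np.interp(ranks, np.arange(n), ref)
    return out


def load_normalize(features: pd.DataFrame, value_col: str = "norm_log2") -> pd.DataFrame:
    """Subtract the per-sample load effect within each print.

    lambda_j is the median of sample j's normalized log2 intensities across
    all arrays in the print; the residual per-sample median within the print
    is therefore exactly 0.
    """
    out = features.copy()
    for print_id, sub in out.groupby("print_id", sort=False):
        if sub.empty:
            raise ValueError(f"empty print group {print_id!r}")
        lam = sub.groupby("sample_id")[value_col].median()
        out.loc[sub.index, "load_effect"] = sub["sample_id"].map(lam).to_numpy()
    out["residual"] = out[value_col] - out["load_effect"]
    return out


def batch_correct(features: pd.DataFrame, value_col: str = "residual") -> pd.DataFrame:
    """Remove the per-antibody per-batch median from MWA residuals.

    RPPA rows pass through unchanged (their single batch term is absorbed by
    quantile normalization); single-batch MWA antibodies are centered.
    """
    out = features.copy()
    is_mwa = out["platform"] == "MWA"
    if is_mwa.any():
        med = out[is_mwa].groupby(["antibody_id", "batch_id"])[value_col].transform(
            "median"
        )
        out.loc[is_mwa, value_col] = out.loc[is_mwa, value_col] - med
    return out


def _tech_cv(linear: pd.Series) -> float:
    m = linear.mean()
    return float(linear.std(ddof=1) / m) if m > 0 and len(linear) > 1 else np.nan


def aggregate_replicates(features: pd.DataFrame) -> ProteinMatrix:
    """Average technical replicates and build the protein matrix.

    Technical replicates are averaged within (individual, biological
    replicate, antibody, platform). Antibodies measured on both platforms
    keep the platform with the higher median background-corrected intensity.
    The biological-replicate axis is preserved (for mixed-model validation)
    alongside the per-individual collapsed mean.

    Per-antibody metadata recorded: platform, median background-corrected
    intensity, median SNR, and the median technical CV (CV of linear
    background-corrected intensities across technical replicates).
    """
    if features.empty:
        raise ValueError("no features to aggregate")
    f = features[~features["excluded"]].copy()

    med_int = f.groupby(["antibody_id", "platform"])["corrected_intensity"].median()
    chosen = (
        med_int.reset_index()
        .sort_values(["antibody_id", "corrected_intensity", "platform"])
        .groupby("antibody_id")
        .last()
    )
    keep = pd.MultiIndex.from_frame(chosen.reset_index()[["antibody_id", "platform"]])
    f = f.set_index(["antibody_id", "platform"]).loc[
        f.set_index(["antibody_id", "platform"]).index.isin(keep)
    ].reset_index()

    cell = f.groupby(["individual_id", "bio_rep", "antibody_id"], sort=True)
    rep = cell["residual"].mean().unstack("antibody_id")
    rep.columns.name = "trait_id"

    cv = (
        cell["corrected_intensity"]
        .apply(_tech_cv)
        .groupby(level="antibody_id")
        .median()
    )
    info = pd.DataFrame(
        {
            "platform": chosen["platform"],
            "median_intensity": chosen["corrected_intensity"],
            "median_snr": f.groupby("antibody_id")["snr"].median(),
            "tech_cv": cv,
        }
    )
    info.index.name = "trait_id"

    n_cells = features.groupby(
        ["individual_id", "bio_rep", "antibody_id"]
    ).size()
    missing = n_cells.index.difference(cell.size().index)
    dropped = pd.DataFrame(
        {
            "trait": [m[2] for m in missing],
            "reason": "all_replicates_excluded_for_some_sample",
        }
    ).drop_duplicates()
    return ProteinMatrix(rep, info.loc[rep.columns], dropped)


def qc_filter(matrix: ProteinMatrix, mode: str = "quartile") -> ProteinMatrix:
    """Drop low-quality antibodies by intensity, SNR and CV quantile bounds.

    ``quartile`` mode removes traits below the 25th percentile of median
    intensity or median SNR, or above the 75th percentile of technical CV;
    ``decile`` mode uses 10%/90%. Quantiles use linear interpolation and the
    boundaries are inclusive for retention, so when all traits tie on a
    metric none are dropped by it.
    """
    if mode not in {"quartile", "decile"}:
        raise ValueError(f"unknown qc mode {mode!r}")
    info = matrix.trait_info
    if len(info) < 4:
        raise ValueError("qc_filter needs at least 4 traits to define quantiles")
    lo = 0.25 if mode == "quartile" else 0.10
    hi = 1.0 - lo
    int_min = info["median_intensity"].quantile(lo)
    snr_min = info["median_snr"].quantile(lo)
    cv_max = info["tech_cv"].quantile(hi)
    bad = info.index[
        (info["median_intensity"] < int_min)
        | (info["median_snr"] < snr_min)
        | (info["tech_cv"] > cv_max)
    ]
    return matrix.drop_traits(list(bad), f"qc_{mode}")


def antibody_pair_concordance(
    matrix: ProteinMatrix, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Spearman correlation across individuals for antibody pairs that target
    the same protein; reports how many pairs have rho > 0."""
    vals = matrix.values
    rows = []
    for a, b in pairs:
        if a not in vals.columns or b not in vals.columns:
            rows.append((a, b, np.nan, np.nan))
            continue
        sub = vals[[a, b]].dropna()
        if len(sub) < 3:
            rows.append((a, b, np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(sub[a], sub[b])
        rows.append((a, b, rho, p))
    out = pd.DataFrame(rows, columns=["antibody_a", "antibody_b", "rho", "p"])
    out.attrs["n_positive"] = int((out["rho"] > 0).sum())
    return out


def quantify(
    features: pd.DataFrame,
    snr_threshold: float = 3.0,
    qc_mode: str = "quartile",
    apply_qc: bool = True,
) -> ProteinMatrix:
    """Full quantification pipeline from raw feature table to protein matrix."""
    f = background_correct(features)
    f = snr_filter(f, threshold=snr_threshold)
    usable = f[~f["excluded"] & (f["corrected_intensity"] > 0)].copy()
    if usable.empty:
        raise ValueError("no usable features after background/SNR filtering")

    usable["norm_log2"] = np.nan
    for _, sub in usable.groupby("print_id", sort=False):
        groups = {aid: g["corrected_intensity"].to_numpy()
                  for aid, g in sub.groupby("array_id", sort=False)}
        if len(groups) < 2:
            # single-array print: plain log2, nothing to equalize against
            usable.loc[sub.index, "norm_log2"] = np.log2(
                sub["corrected_intensity"].to_numpy()
            )
            continue
        normed = quantile_normalize(groups, log2=True)
        for aid, g in sub.groupby("array_id", sort=False):
            usable.loc[g.index, "norm_log2"] = normed[aid]

    usable = load_normalize(usable)
    usable = batch_correct(usable)
    matrix = aggregate_replicates(usable)
    if apply_qc:
        matrix = qc_filter(matrix, mode=qc_mode)
    return matrix
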
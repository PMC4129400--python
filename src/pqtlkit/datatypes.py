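"""Core in-memory containers shared across pipeline stages.

All tabular data live in pandas objects; the thin dataclasses below bundle
related tables and enforce the invariants the pipeline relies on (dosage
range, replicate structure, trait/variant id resolvability).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Columns required of a raw array feature table (one row per printed feature).
FEATURE_COLUMNS = [
    "array_id",
    "print_id",
    "batch_id",
    "platform",
    "feature_id",
    "sample_id",
    "individual_id",
    "bio_rep",
    "tech_rep",
    "antibody_id",
    "band_mw_kda",
    "raw_intensity",
    "background",
    "noise_sd",
]


class ConfigurationError(ValueError):
    """Raised for invalid simulation or pipeline configuration."""


@dataclass
class GenotypeMatrix:
    """Mean genotype dosages for a cohort.

    Parameters
    ----------
    dosages
        individuals x variants dataframe of mean dosages in [0, 2]
        (rows indexed by individual id, columns by variant id).
    variants
        Per-variant metadata indexed by variant id with columns
        ``chrom``, ``pos`` (1-based), ``ref``, ``alt`` and optionally ``maf``
        (the generating allele frequency for synthetic data).
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.variants.index):
            self.variants = self.variants.loc[self.dosages.columns]
        vals = self.dosages.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie within [0, 2]")
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"variant positions must be strictly increasing on {chrom}"
                )

    @property
    def individuals(self) -> pd.Index:
        return self.dosages.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def empirical_maf(self) -> pd.Series:
        """Empirical minor allele frequency per variant (from mean dosage)."""
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq).rename("maf")

    def subset_variants(self, ids: Sequence[str]) -> "GenotypeMatrix":
        ids = pd.Index(ids)
        return GenotypeMatrix(self.dosages.loc[:, ids], self.variants.loc[ids])


@dataclass
class ProteinMatrix:
    """Normalized protein levels with a biological-replicate axis.

    ``replicate_values`` is indexed by (individual_id, bio_rep); ``values``
    holds the per-individual collapsed mean used for the primary association
    scan. ``trait_info`` carries per-antibody metadata: platform, median
    background-corrected intensity, median SNR, technical CV, and QC flags.
    """

    replicate_values: pd.DataFrame
    trait_info: pd.DataFrame
    dropped_traits: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["trait", "reason"])
    )

    @property
    def values(self) -> pd.DataFrame:
        """Per-individual collapsed means (individuals x traits)."""
        return self.replicate_values.groupby(level="individual_id", sort=True).mean()

    @property
    def traits(self) -> pd.Index:
        return self.replicate_values.columns

    @property
    def individuals(self) -> pd.Index:
        return self.values.index

    def drop_traits(self, traits: Sequence[str], reason: str) -> "ProteinMatrix":
        traits = [t for t in traits if t in self.replicate_values.columns]
        dropped = pd.concat(
            [
                self.dropped_traits,
                pd.DataFrame({"trait": traits, "reason": reason}),
            ],
            ignore_index=True,
        )
        return ProteinMatrix(
            self.replicate_values.drop(columns=traits),
            self.trait_info.drop(index=traits, errors="ignore"),
            dropped,
        )


@dataclass
class SurrogateVariableSet:
    """Orthonormal surrogate variables (individuals x k) with per-SV p-values."""

    svs: pd.DataFrame
    pvalues: pd.Series

    @property
    def k(self) -> int:
        return self.svs.shape[1]


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort generator.

    Defaults follow the study design the pipeline targets: 68 individuals,
    three independently thawed biological replicates, four (RPPA) or three
    (MWA) technical replicates, ~441 antibody traits, genotypes with
    MAF >= 0.05 in LD blocks, planted cis effects of |R| ~ 0.3-0.65,
    multiplicative per-sample load effects, per-batch shifts and additive
    scanner background noise.
    """

    n_individuals: int = 68
    n_variants: int = 5000
    n_traits: int = 441
    n_bio_replicates: int = 3
    n_tech_replicates_rppa: int = 4
    n_tech_replicates_mwa: int = 3
    n_chromosomes: int = 4
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_length: int = 50
    ld_rho: float = 0.999
    ld_decay: float = 0.0
    variant_spacing: int = 10_000
    load_effect_sd: float = 0.25
    batch_effect_sd: float = 0.25
    bio_rep_sd: float = 0.3
    background_mean: float = 200.0
    noise_sd: float = 30.0
    gain: float = 1.0e4
    mwa_fraction: float = 0.53
    dual_platform_fraction: float = 0.016
    arrays_per_print: int = 8
    expression_noise_sd: float = 0.5
    missing_fraction: float = 0.0
    gene_length: int = 20_000
    effects: list[dict] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_individuals": self.n_individuals,
            "n_variants": self.n_variants,
            "n_traits": self.n_traits,
            "n_bio_replicates": self.n_bio_replicates,
            "n_tech_replicates_rppa": self.n_tech_replicates_rppa,
            "n_tech_replicates_mwa": self.n_tech_replicates_mwa,
            "n_chromosomes": self.n_chromosomes,
            "ld_block_length": self.ld_block_length,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        for name in ("load_effect_sd", "batch_effect_sd", "bio_rep_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if not 0 <= self.mwa_fraction <= 1:
            raise ConfigurationError("mwa_fraction must lie in [0, 1]")
        if not 0 <= self.missing_fraction < 1:
            raise ConfigurationError("missing_fraction must lie in [0, 1)")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def make_effect(
    variant: str,
    trait: str,
    beta: float,
    mode: str = "cis",
    target: str = "protein",
) -> dict:
    """Build one planted-effect record for :class:`SimulationConfig`.

    ``mode`` is cis/trans (controls where the trait's gene is placed relative
    to the variant); ``target`` selects which molecular layer carries the
    effect: protein, mRNA, both, or phospho-only.
    """
    if mode not in {"cis", "trans"}:
        raise ValueError(f"mode must be cis or trans, got {mode!r}")
    if target not in {"protein", "mRNA", "both", "phospho-only"}:
        raise ValueError(f"unknown effect target {target!r}")
    if not np.isfinite(beta):
        raise ValueError("effect beta must be finite")
    return {
        "variant_id": variant,
        "trait_id": trait,
        "beta": float(beta),
        "mode": mode,
        "target": target,
    }
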
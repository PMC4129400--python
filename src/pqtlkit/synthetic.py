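"""Synthetic cohort generator with planted genetic effects.

Emulates the statistical structure the analysis pipeline assumes: a cohort of
unrelated individuals genotyped at biallelic variants arranged in LD blocks,
antibody traits measured in biological and technical replicates on RPPA and
MWA platforms with multiplicative sample-load effects, per-batch intensity
shifts and additive scanner background noise, plus cellular covariates and a
paired mRNA expression matrix that shares a controllable subset of the
genetic effects.

Raw intensities are generated on a linear scale as
``gain * 2**(latent + load + batch) + background + noise`` so that the
downstream log2-quantile/median-load normalization inverts the generating
model; with all technical noise disabled the recovered protein matrix equals
the latent traits up to an affine map.

Every generator is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    FEATURE_COLUMNS,
    ConfigurationError,
    GenotypeMatrix,
    SimulationConfig,
)

__all__ = [
    "SyntheticCohort",
    "simulate_genotypes",
    "simulate_gene_models",
    "simulate_true_traits",
    "simulate_array_features",
    "simulate_covariates",
    "simulate_expression",
    "simulate_cohort",
]


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    # independent substream per generator stage, all derived from config.seed
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), salt]))


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Generate an LD-block-structured genotype matrix and recombination map.

    Variants are biallelic with allele frequencies drawn uniformly from
    ``config.maf_range``. Haplotypes are simulated with a Gaussian copula:
    within each block of ``ld_block_length`` consecutive variants every
    haplotype carries a shared latent normal, so dosages are correlated
    within blocks (correlation controlled by ``ld_rho``, optionally decaying
    along the block via ``ld_decay``) and independent across blocks.

    The returned recombination map places >10 cM/Mb rate spikes at block
    boundaries and a 1 cM/Mb baseline inside blocks, so that
    :func:`pqtlkit.qtl_map.blocks_from_recomb_map` reconstructs the planted
    blocks exactly.

    Returns
    -------
    (GenotypeMatrix, DataFrame)
        The genotypes and a map with columns ``chrom``, ``pos``,
        ``rate_cm_mb``.
    """
    rng = _rng(config, 1)
    n, m = config.n_individuals, config.n_variants
    lo, hi = config.maf_range

    # assign variants to chromosomes in contiguous runs
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    chrom = np.repeat(
        [f"chr{i + 1}" for i in range(config.n_chromosomes)], per_chrom
    )
    offset = np.concatenate([np.arange(c) for c in per_chrom if c > 0])
    pos = (offset + 1) * config.variant_spacing

    # block index within each chromosome
    block_of = offset // config.ld_block_length
    chrom_idx = np.repeat(np.arange(config.n_chromosomes), per_chrom)
    global_block = chrom_idx * (10**9) + block_of  # unique per (chrom, block)

    # variants within an LD block share their allele frequency: tightly
    # linked variants in real genomes have matching frequencies (a pair in
    # strong LD cannot differ much in MAF), and this is what lets
    # within-block dosage r^2 reach the 0.9+ regime the block-best
    # reduction presupposes; each variant's marginal stays exact
    uniq_first, inverse_first = np.unique(global_block, return_inverse=True)
    block_maf = rng.uniform(lo, hi, size=uniq_first.size)
    maf = block_maf[inverse_first]

    thresh = stats.norm.ppf(maf)  # allele "1" is the minor allele
    within = offset % config.ld_block_length
    w = np.sqrt(config.ld_rho) * np.power(
        max(config.ld_rho, 1e-12), 0.5 * config.ld_decay * within
    )
    w = np.clip(w, 0.0, 1.0)

    haplos = np.empty((2 * n, m), dtype=np.int8)
    uniq, inverse = uniq_first, inverse_first
    z_block = rng.standard_normal((2 * n, uniq.size))
    eps = rng.standard_normal((2 * n, m))
    z = z_block[:, inverse] * w + eps * np.sqrt(1.0 - w**2)
    haplos[:] = z < thresh
    dosages = haplos[0::2] + haplos[1::2]

    ids = [f"snp{i:06d}" for i in range(m)]
    individuals = [f"NA{18500 + i:05d}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "maf": maf,
            "block": [f"{c}_b{b}" for c, b in zip(chrom, block_of)],
        },
        index=pd.Index(ids, name="variant_id"),
    )
    gm = GenotypeMatrix(
        pd.DataFrame(
            dosages.astype(float),
            index=pd.Index(individuals, name="individual_id"),
            columns=pd.Index(ids, name="variant_id"),
        ),
        variants,
    )

    rows = []
    spacing = config.variant_spacing
    for c in range(config.n_chromosomes):
        sub = variants[variants["chrom"] == f"chr{c + 1}"]
        if sub.empty:
            continue
        cuts = sub.groupby("block", sort=False)["pos"].max().to_numpy()
        first = sub["pos"].iloc[0]
        rows.append((f"chr{c + 1}", max(first - spacing // 2, 1), 50.0))
        for j, cut in enumerate(cuts):
            rows.append((f"chr{c + 1}", cut + spacing // 4, 1.0))
            rows.append((f"chr{c + 1}", cut + spacing // 2, 50.0))
    recomb = pd.DataFrame(rows, columns=["chrom", "pos", "rate_cm_mb"])
    return gm, recomb


def _effects_frame(effects) -> pd.DataFrame:
    if isinstance(effects, pd.DataFrame):
        frame = effects.copy()
    else:
        frame = pd.DataFrame(
            list(effects),
            columns=["variant_id", "trait_id", "beta", "mode", "target"],
        )
    if "target" not in frame.columns:
        frame["target"] = "protein"
    if "mode" not in frame.columns:
        frame["mode"] = "cis"
    if len(frame) and not np.all(np.isfinite(frame["beta"].astype(float))):
        raise ValueError("all planted betas must be finite")
    return frame


def simulate_true_traits(
    genotypes: GenotypeMatrix,
    effects,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build latent per-individual trait values carrying the planted effects.

    Each trait is ``sum_k beta_k * standardize(dosage_k) + e`` with the
    residual variance chosen so every trait has unit population variance;
    ``beta`` is therefore the population correlation between dosage and
    trait. Effects with target ``mRNA`` act only on the mRNA layer, target
    ``protein``/``phospho-only`` only on the protein layer, ``both`` on both
    (emulating the largely discordant eQTL/pQTL architecture the pipeline is
    designed to resolve).

    Returns (latent_protein, latent_mrna), both individuals x traits.
    """
    frame = _effects_frame(effects)
    unknown_v = set(frame["variant_id"].dropna()) - set(genotypes.variant_ids)
    if unknown_v:
        raise KeyError(f"unknown effect variant ids: {sorted(unknown_v)[:5]}")
    traits = [f"ab{i:04d}" for i in range(config.n_traits)]
    unknown_t = set(frame["trait_id"]) - set(traits)
    if unknown_t:
        raise KeyError(f"unknown effect trait ids: {sorted(unknown_t)[:5]}")

    rng = _rng(config, 2)
    n = genotypes.n_individuals
    d = genotypes.dosages.to_numpy()
    sd = d.std(axis=0, ddof=0)

    out = {}
    for layer, targets in (
        ("protein", {"protein", "both", "phospho-only"}),
        ("mRNA", {"mRNA", "both"}),
    ):
        mat = np.zeros((n, config.n_traits))
        explained = np.zeros(config.n_traits)
        for _, row in frame.iterrows():
            if row["target"] not in targets:
                continue
            t = traits.index(row["trait_id"])
            j = genotypes.variant_ids.get_loc(row["variant_id"])
            if sd[j] == 0:
                raise ValueError(f"monomorphic effect variant {row['variant_id']}")
            z = (d[:, j] - d[:, j].mean()) / sd[j]
            mat[:, t] += float(row["beta"]) * z
            explained[t] += float(row["beta"]) ** 2
        if np.any(explained > 1):
            raise ConfigurationError(
                "planted betas explain more than unit variance for some trait"
            )
        resid_sd = np.sqrt(1.0 - explained)
        mat += rng.standard_normal((n, config.n_traits)) * resid_sd
        out[layer] = pd.DataFrame(
            mat, index=genotypes.individuals, columns=pd.Index(traits, name="trait_id")
        )
    return out["protein"], out["mRNA"]


def simulate_gene_models(
    genotypes: GenotypeMatrix,
    effects,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Place a gene model (chrom, TSS, TES, strand) for every trait.

    Traits with a planted cis effect get their gene within the cis window of
    the effect variant; traits with a planted trans effect get their gene on
    a different chromosome from the variant. Remaining traits are placed
    uniformly. TSS/TES are stored in transcription orientation (TSS > TES on
    the minus strand).
    """
    frame = _effects_frame(effects)
    rng = _rng(config, 3)
    traits = [f"ab{i:04d}" for i in range(config.n_traits)]
    chroms = sorted(genotypes.variants["chrom"].unique())
    span = {
        c: int(genotypes.variants.loc[genotypes.variants["chrom"] == c, "pos"].max())
        for c in chroms
    }

    records = {}
    for _, row in frame.iterrows():
        v = genotypes.variants.loc[row["variant_id"]]
        if row["mode"] == "cis":
            start = int(v["pos"]) + int(rng.integers(-200_000, 200_000))
            records[row["trait_id"]] = (v["chrom"], max(start, 1))
        else:
            others = [c for c in chroms if c != v["chrom"]] or chroms
            c = others[int(rng.integers(len(others)))]
            records.setdefault(
                row["trait_id"], (c, int(rng.integers(1, span[c] + 1)))
            )
    rows = []
    for t in traits:
        if t in records:
            c, start = records[t]
        else:
            c = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(1, span[c] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        end = start + config.gene_length
        tss, tes = (start, end) if strand == "+" else (end, start)
        rows.append((t, f"gene_{t}", c, tss, tes, strand))
    return pd.DataFrame(
        rows, columns=["trait_id", "gene_id", "chrom", "tss", "tes", "strand"]
    ).set_index("trait_id")


def _replicate_latent(
    latent: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Latent value per (individual, bio replicate): adds the thaw effect."""
    n, t = latent.shape
    b = config.n_bio_replicates
    vals = np.repeat(latent.to_numpy(), b, axis=0)
    vals = vals + rng.standard_normal(vals.shape) * config.bio_rep_sd
    idx = pd.MultiIndex.from_product(
        [latent.index, [f"bio{i + 1}" for i in range(b)]],
        names=["individual_id", "bio_rep"],
    )
    return pd.DataFrame(vals, index=idx, columns=latent.columns)


@dataclass
class ArrayTruth:
    """Ground-truth technical effects planted into the feature tables."""

    antibody_info: pd.DataFrame
    load_effects: pd.DataFrame  # columns print_id, individual_id, bio_rep, lam
    batch_effects: pd.DataFrame  # columns antibody_id, batch_id, beta
    replicate_latent: pd.DataFrame


def simulate_array_features(
    latent: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, ArrayTruth]:
    """Emit raw array feature tables for the latent protein traits.

    Antibodies are split into RPPA (single-band) and MWA (multi-band)
    platforms per ``mwa_fraction``; a small ``dual_platform_fraction`` is
    measured on both so the downstream platform-selection rule has work to
    do. RPPA antibodies occupy one array each, grouped into prints of
    ``arrays_per_print`` arrays sharing one spotting of all samples; a
    per-(print, sample) load effect lambda ~ N(0, load_effect_sd) is applied
    on the log2 scale. MWA antibodies are run once per biological replicate
    (each thaw on its own gel, the gel being the batch) with an additional
    per-(antibody, batch) shift ~ N(0, batch_effect_sd).

    Raw linear intensity is ``gain * 2**(log2 signal) + background + noise``.
    """
    rng = _rng(config, 4)
    traits = list(latent.columns)
    n_traits = len(traits)
    individuals = list(latent.index)
    bio = [f"bio{i + 1}" for i in range(config.n_bio_replicates)]

    rep_latent = _replicate_latent(latent, config, rng)
    rl = rep_latent.to_numpy().reshape(
        len(individuals), config.n_bio_replicates, n_traits
    )

    n_mwa = int(round(config.mwa_fraction * n_traits))
    perm = rng.permutation(n_traits)
    mwa_set = {traits[i] for i in perm[:n_mwa]}
    n_dual = int(round(config.dual_platform_fraction * n_traits))
    dual = {traits[i] for i in perm[:n_dual]}  # dual antibodies drawn from MWA set
    predicted_mw = pd.Series(
        rng.uniform(20, 150, size=n_traits).round(1), index=traits, name="predicted_mw"
    )

    rppa_abs = [t for t in traits if t not in mwa_set or t in dual]
    mwa_abs = [t for t in traits if t in mwa_set]

    frames: list[pd.DataFrame] = []
    load_rows: list[pd.DataFrame] = []
    batch_rows: list[tuple] = []

    def emit(platform: str, ab_list: list[str], n_tech: int) -> None:
        if not ab_list:
            return
        app = config.arrays_per_print
        n_ind, n_bio = len(individuals), config.n_bio_replicates
        for chunk_start in range(0, len(ab_list), app):
            chunk = ab_list[chunk_start : chunk_start + app]
            if platform == "RPPA":
                print_ids = [f"printR{chunk_start // app:03d}"]
                batches = [None]
            else:
                # one print (and gel batch) per biological replicate
                print_ids = [
                    f"printM{chunk_start // app:03d}_{b}" for b in bio
                ]
                batches = bio
            for print_id, batch in zip(print_ids, batches):
                lam = rng.normal(0.0, config.load_effect_sd, size=(n_ind, n_bio))
                bio_here = bio if batch is None else [batch]
                lam_here = lam if batch is None else lam[:, [bio.index(batch)]]
                load_rows.append(
                    pd.DataFrame(
                        {
                            "print_id": print_id,
                            "individual_id": np.repeat(individuals, len(bio_here)),
                            "bio_rep": np.tile(bio_here, n_ind),
                            "lam": lam_here.ravel(),
                        }
                    )
                )
                for ab in chunk:
                    t_idx = traits.index(ab)
                    if batch is None:
                        b_eff = 0.0
                        batch_id = f"{platform}_{ab}_batch1"
                        array_id = f"RPPA_{ab}"
                        bsel = slice(None)
                    else:
                        b_eff = rng.normal(0.0, config.batch_effect_sd)
                        batch_id = f"MWA_{ab}_{batch}"
                        array_id = f"MWA_{ab}_{batch}"
                        bsel = [bio.index(batch)]
                        batch_rows.append((ab, batch_id, b_eff))
                    sig = rl[:, bsel, t_idx] + lam_here + b_eff
                    sig = np.repeat(sig.ravel(), n_tech)
                    linear = config.gain * np.exp2(sig)
                    noise = (
                        rng.normal(0.0, config.noise_sd, size=sig.size)
                        if config.noise_sd > 0
                        else 0.0
                    )
                    raw = linear + config.background_mean + noise
                    nb = len(bio_here)
                    frames.append(
                        pd.DataFrame(
                            {
                                "array_id": array_id,
                                "print_id": print_id,
                                "batch_id": batch_id,
                                "platform": platform,
                                "feature_id": [
                                    f"{array_id}_f{i:05d}" for i in range(sig.size)
                                ],
                                "sample_id": np.repeat(
                                    [
                                        f"{i}_{b}"
                                        for i in individuals
                                        for b in bio_here
                                    ],
                                    n_tech,
                                ),
                                "individual_id": np.repeat(
                                    individuals, nb * n_tech
                                ),
                                "bio_rep": np.tile(
                                    np.repeat(bio_here, n_tech), n_ind
                                ),
                                "tech_rep": np.tile(
                                    [f"tech{i + 1}" for i in range(n_tech)],
                                    n_ind * nb,
                                ),
                                "antibody_id": ab,
                                "band_mw_kda": predicted_mw[ab],
                                "raw_intensity": raw,
                                "background": config.background_mean,
                                "noise_sd": max(config.noise_sd, 1.0),
                            }
                        )
                    )

    emit("RPPA", rppa_abs, config.n_tech_replicates_rppa)
    emit("MWA", mwa_abs, config.n_tech_replicates_mwa)

    features = pd.concat(frames, ignore_index=True)[FEATURE_COLUMNS]
    if config.missing_fraction > 0:
        keep = rng.random(len(features)) >= config.missing_fraction
        features = features[keep].reset_index(drop=True)

    info = pd.DataFrame(
        {
            "platform": [
                "both" if t in dual else ("MWA" if t in mwa_set else "RPPA")
                for t in traits
            ],
            "predicted_mw": predicted_mw,
        },
        index=pd.Index(traits, name="antibody_id"),
    )
    truth = ArrayTruth(
        antibody_info=info,
        load_effects=pd.concat(load_rows, ignore_index=True),
        batch_effects=pd.DataFrame(
            batch_rows, columns=["antibody_id", "batch_id", "beta"]
        ),
        replicate_latent=rep_latent,
    )
    return features, truth


def simulate_covariates(
    latent: pd.DataFrame,
    config: SimulationConfig,
    planted: dict[str, tuple[list[str], float]] | None = None,
) -> pd.DataFrame:
    """Generate per-individual cellular covariates.

    ``planted`` maps a covariate name to ``(trait_ids, r)``: the covariate is
    constructed to have population correlation ``r`` with each listed trait
    (requires ``r <= 1/sqrt(len(traits))``). Unplanted covariates are
    independent of everything. Sex is drawn with a fixed 50/50 proportion and
    phase uniformly from three categories.
    """
    rng = _rng(config, 5)
    planted = planted or {}
    n = len(latent.index)
    z = latent.to_numpy()
    z = (z - z.mean(axis=0)) / np.where(z.std(axis=0) > 0, z.std(axis=0), 1.0)

    def covariate(name: str) -> np.ndarray:
        if name in planted:
            trait_ids, r = planted[name]
            k = len(trait_ids)
            if not 0 < r <= 1.0 / np.sqrt(k):
                raise ConfigurationError(
                    f"planted correlation {r} infeasible for {k} traits"
                )
            cols = [latent.columns.get_loc(t) for t in trait_ids]
            b = np.sqrt(1.0 / r**2 - k)
            c = z[:, cols].sum(axis=1) + b * rng.standard_normal(n)
            return c / np.sqrt(k + b**2)
        return rng.standard_normal(n)

    table = pd.DataFrame(index=latent.index.rename("individual_id"))
    table["ebv_copies"] = 500.0 + 120.0 * covariate("ebv_copies")
    table["mtdna_copies"] = 1000.0 + 200.0 * covariate("mtdna_copies")
    table["atp_baseline"] = 100.0 + 15.0 * covariate("atp_baseline")
    table["growth_rate"] = covariate("growth_rate")
    table["sex"] = np.where(rng.random(n) < 0.5, "F", "M")
    table["phase"] = rng.integers(1, 4, size=n)
    return table


def simulate_expression(
    latent_mrna: pd.DataFrame,
    gene_models: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Noisy expression matrices (two platforms) paired to the protein traits.

    Each platform observes ``latent_mrna + N(0, expression_noise_sd)`` with
    independent noise, gene-indexed via the trait->gene mapping.
    """
    rng = _rng(config, 6)
    genes = gene_models["gene_id"]
    out = {}
    for platform in ("array", "rnaseq"):
        noise = rng.standard_normal(latent_mrna.shape) * config.expression_noise_sd
        mat = latent_mrna.to_numpy() + noise
        out[platform] = pd.DataFrame(
            mat, index=latent_mrna.index, columns=genes.loc[latent_mrna.columns].values
        )
    mapping = pd.DataFrame(
        {"gene_id": genes.loc[latent_mrna.columns].values,
         "antibody_id": latent_mrna.columns}
    )
    return out, mapping


@dataclass
class SyntheticCohort:
    """Everything one simulated study produces, plus its ground truth."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    recomb_map: pd.DataFrame
    gene_models: pd.DataFrame
    effects: pd.DataFrame
    latent_protein: pd.DataFrame
    latent_mrna: pd.DataFrame
    features: pd.DataFrame
    array_truth: ArrayTruth
    covariates: pd.DataFrame
    expression: dict[str, pd.DataFrame] = field(default_factory=dict)
    gene_antibody_map: pd.DataFrame | None = None


def _resolve_effects(
    effects: pd.DataFrame, genotypes: GenotypeMatrix, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill in unspecified effect variants with randomly chosen polymorphic ones."""
    effects = effects.copy()
    pool = genotypes.variant_ids.to_numpy()
    taken = set(effects["variant_id"].dropna())
    for i, row in effects.iterrows():
        if pd.isna(row["variant_id"]):
            while True:
                v = pool[int(rng.integers(pool.size))]
                if v not in taken:
                    break
            effects.loc[i, "variant_id"] = v
            taken.add(v)
    return effects


def simulate_cohort(
    config: SimulationConfig,
    covariate_plant: dict[str, tuple[list[str], float]] | None = None,
) -> SyntheticCohort:
    """Run every generator stage under one configuration seed."""
    genotypes, recomb = simulate_genotypes(config)
    effects = _resolve_effects(
        _effects_frame(config.effects), genotypes, _rng(config, 7)
    )
    latent_p, latent_m = simulate_true_traits(genotypes, effects, config)
    gene_models = simulate_gene_models(genotypes, effects, config)
    features, truth = simulate_array_features(latent_p, config)
    covs = simulate_covariates(latent_p, config, covariate_plant)
    expression, mapping = simulate_expression(latent_m, gene_models, config)
    return SyntheticCohort(
        config=config,
        genotypes=genotypes,
        recomb_map=recomb,
        gene_models=gene_models,
        effects=effects,
        latent_protein=latent_p,
        latent_mrna=latent_m,
        features=features,
        array_truth=truth,
        covariates=covs,
        expression=expression,
        gene_antibody_map=mapping,
    )
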
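"""Permutation-based empirical FDR for cis and trans associations.

Significance of the genome-wide scan is calibrated by permuting individual
labels of the trait matrix (destroying genotype-trait links while preserving
the trait distributions and, in the default joint mode, the within-individual
replicate correlation), re-running the full scan and block-best reduction,
and keeping the best (minimum) p-value per trait separately in the cis and
trans strata. The empirical FDR at a threshold is the permutation-mean count
of trait-best null p-values below the threshold divided by the observed hit
count below it, capped at 1 and computed separately per stratum, exactly the
construction used to derive separate cis and trans significance thresholds
at a target FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .qtl_map import association_scan, classify_cis_trans, select_block_best

__all__ = [
    "PermutationNull",
    "permute_phenotypes",
    "build_permutation_null",
    "empirical_fdr",
    "threshold_for_fdr",
]


@dataclass
class PermutationNull:
    """Null association p-values from permuted re-scans, by cis/trans stratum.

    ``null_p`` has columns replicate, trait_id, stratum, p and holds every
    block-best association of every permuted scan (the permuted data pass
    through the identical per-window best-SNV reduction as the observed
    data). ``best_p`` reduces it to the single best p per (replicate, trait,
    stratum). The resolution floor of a trait-best FDR computed from this
    null is 1/(n_replicates * n_traits).
    """

    null_p: pd.DataFrame
    n_replicates: int
    n_traits: int
    seed: int

    @property
    def best_p(self) -> pd.DataFrame:
        return (
            self.null_p.groupby(["replicate", "trait_id", "stratum"], observed=True)[
                "p"
            ]
            .min()
            .reset_index()
        )

    @property
    def resolution_floor(self) -> float:
        return 1.0 / (self.n_replicates * max(self.n_traits, 1))


def permute_phenotypes(
    traits: pd.DataFrame,
    seed: int | np.random.Generator,
    mode: str = "joint",
) -> pd.DataFrame:
    """Shuffle individual labels of a trait matrix.

    With a plain (individuals x traits) frame, rows are permuted jointly for
    all traits. With a replicate-axis frame (MultiIndex individual_id,
    bio_rep), ``mode="joint"`` applies one permutation of individuals to
    every biological replicate (preserving within-individual replicate
    correlation); ``mode="per_replicate"`` draws an independent permutation
    per replicate. Each trait's multiset of values is preserved exactly.
    """
    if mode not in {"joint", "per_replicate"}:
        raise ValueError(f"unknown permutation mode {mode!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if not isinstance(traits.index, pd.MultiIndex):
        if len(traits) < 2:
            raise ValueError("need at least 2 individuals to permute")
        perm = rng.permutation(len(traits))
        return pd.DataFrame(
            traits.to_numpy()[perm], index=traits.index, columns=traits.columns
        )

    individuals = traits.index.get_level_values("individual_id").unique()
    n = len(individuals)
    if n < 2:
        raise ValueError("need at least 2 individuals to permute")
    out = traits.copy()
    reps = traits.index.get_level_values("bio_rep").unique()
    joint_perm = individuals[rng.permutation(n)]
    joint_map = dict(zip(individuals, joint_perm))
    for b in reps:
        if mode == "per_replicate":
            perm = individuals[rng.permutation(n)]
            mapping = dict(zip(individuals, perm))
        else:
            mapping = joint_map
        mask = out.index.get_level_values("bio_rep") == b
        row_inds = out.index.get_level_values("individual_id")[mask]
        src = traits.xs(b, level="bio_rep").loc[[mapping[i] for i in row_inds]]
        out.loc[mask, :] = src.to_numpy()
    return out


def build_permutation_null(
    traits: pd.DataFrame,
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    blocks: pd.DataFrame,
    gene_models: pd.DataFrame,
    n_replicates: int = 3,
    seed: int = 0,
    window: int = 1_000_000,
    mode: str = "joint",
) -> PermutationNull:
    """Re-scan permuted traits and collect trait-best p per stratum.

    ``traits`` are collapsed per-individual values (the same matrix the
    observed scan used); each permutation replicate shuffles individuals,
    re-runs the scan, block-best reduction and cis/trans classification
    against each trait's own gene model, and records the per-trait minimum p
    in each stratum.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        permuted = permute_phenotypes(traits, rng, mode=mode)
        scan = association_scan(permuted, genotypes)
        best = select_block_best(scan, variants, blocks)
        best = classify_cis_trans(best, variants, gene_models, window=window)
        best = best.dropna(subset=["locus_class"])
        per = best[["trait_id", "locus_class", "p"]].copy()
        per.insert(0, "replicate", rep)
        rows.append(per)
    null_p = pd.concat(rows, ignore_index=True).rename(
        columns={"locus_class": "stratum"}
    )
    return PermutationNull(
        null_p=null_p,
        n_replicates=n_replicates,
        n_traits=traits.shape[1],
        seed=seed,
    )


def empirical_fdr(
    observed: pd.DataFrame,
    null: PermutationNull,
    p_threshold: float,
    stratum: str,
    mode: str = "hits",
) -> float:
    """Empirical FDR at ``p_threshold`` in one stratum.

    FDR = mean over permutation replicates of the number of null hits below
    the threshold, divided by the number of observed (block-reduced) hits
    below it; capped at 1. Returns NaN when there are no observed hits
    (0/0 undefined).

    ``mode="hits"`` (default) counts permuted hits exactly as observed ones
    — every block-best association below the threshold — so on fully null
    data the estimate is near 1 at any threshold. ``mode="per_trait_best"``
    counts at most one null hit per (trait, replicate), a family-wise-style
    null per phenotype; it is conservative against a trait contributing
    several true loci but understates the FDR wherever a null trait could
    pass the threshold in more than one block.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    if mode not in {"hits", "per_trait_best"}:
        raise ValueError(f"unknown FDR mode {mode!r}")
    obs = int(
        ((observed["locus_class"] == stratum) & (observed["p"] < p_threshold)).sum()
    )
    if obs == 0:
        return float("nan")
    table = null.null_p if mode == "hits" else null.best_p
    sub = table[table["stratum"] == stratum]
    null_hits = (
        sub[sub["p"] < p_threshold].groupby("replicate").size()
        .reindex(range(null.n_replicates), fill_value=0)
    )
    return float(min(null_hits.mean() / obs, 1.0))


def threshold_for_fdr(
    observed: pd.DataFrame,
    null: PermutationNull,
    target_fdr: float,
    stratum: str,
    mode: str = "hits",
) -> tuple[float | None, pd.DataFrame]:
    """Largest p threshold on the observed grid meeting the target FDR.

    Candidate thresholds are taken just above each observed p in the stratum
    (so the strict ``p < threshold`` counting includes the grid point). The
    returned hit table holds the observed hits passing the chosen threshold;
    when no threshold achieves the target, ``(None, empty table)`` is
    returned.
    """
    sub = observed[observed["locus_class"] == stratum]
    if sub.empty:
        return None, sub.copy()
    grid = np.nextafter(np.sort(sub["p"].unique()), 1.0)
    chosen = None
    for thr in grid[::-1]:
        fdr = empirical_fdr(observed, null, float(thr), stratum, mode=mode)
        if np.isfinite(fdr) and fdr <= target_fdr:
            chosen = float(thr)
            break
    if chosen is None:
        return None, sub.iloc[0:0].copy()
    hits = sub[sub["p"] < chosen].sort_values("p").reset_index(drop=True)
    return chosen, hits
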
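"""Genome-wide association scans for protein traits.

Trait values are inverse-normal transformed (Blom offset c = 3/8), genotypes
are filtered on minor allele frequency and exact Hardy-Weinberg equilibrium,
and each (trait, variant) pair is tested by simple linear regression of the
transformed trait on mean dosage. Per trait, only the most significant
variant within each recombination block (genome intervals flanked by
>10 cM/Mb recombination) is retained; hits are classified cis when the
variant lies within 1 Mb upstream of the trait gene's TSS through 1 Mb
downstream of its TES (endpoints inclusive), else trans. Strong hits are
re-tested with a replicate-level mixed model (fixed dosage, random
per-individual thaw intercept).

The scan is fully vectorized: correlations come from the cross-product of
standardized trait and dosage matrices, so a 200-trait x 50,000-variant scan
is a single matrix multiplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, ProteinMatrix

__all__ = [
    "inverse_normal_transform",
    "hwe_exact_p",
    "filter_genotypes",
    "association_scan",
    "ScanResult",
    "blocks_from_recomb_map",
    "assign_blocks",
    "select_block_best",
    "classify_cis_trans",
    "mixed_model_validate",
]

P_FLOOR = 1e-300  # avoid exact-fit underflow to 0
BLOM_C = 0.375


def inverse_normal_transform(values, c: float = BLOM_C) -> np.ndarray:
    """Rank-based inverse normal transform.

    Maps value ranks through Phi^-1((rank - c) / (n - 2c + 1)) with the Blom
    offset c = 3/8; tied values share their average rank. The result is a
    monotone (rank-preserving) map of the input, so any monotone transform
    of the raw trait yields the identical output.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("inverse normal transform needs at least 3 values")
    if np.all(v == v[0]):
        raise ValueError("inverse normal transform undefined for a constant vector")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - c) / (v.size - 2.0 * c + 1.0))


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Conditional on the observed allele counts, the probability of every
    possible heterozygote count is enumerated and the p-value is the sum of
    probabilities no larger than that of the observed configuration
    (two-sided exact convention).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_a = 2 * n_hom_ref + n_het  # copies of one allele
    rare = min(n_a, 2 * n - n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_het = h | allele counts) for all feasible h
    logp = np.array(
        [
            lgamma(n + 1)
            - lgamma((rare - h) // 2 + 1)
            - lgamma(h + 1)
            - lgamma((2 * n - rare - h) // 2 + 1)
            + h * np.log(2.0)
            for h in hets
        ]
    )
    logp += lgamma(rare + 1) + lgamma(2 * n - rare + 1) - lgamma(2 * n + 1)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_het)]
    return float(min(probs[probs <= obs * (1.0 + 1e-12)].sum(), 1.0))


def filter_genotypes(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.001,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Exclude variants with MAF < ``maf_min`` or exact HWE p < ``hwe_alpha``.

    Dosages are rounded to hard calls for the HWE genotype counts. Returns
    the filtered matrix and per-rule exclusion counts.
    """
    if genotypes.n_variants == 0:
        raise ValueError("empty genotype matrix")
    maf = genotypes.empirical_maf().to_numpy()
    keep_maf = maf >= maf_min

    calls = np.clip(np.rint(genotypes.dosages.to_numpy()), 0, 2).astype(int)
    keep_hwe = np.ones(genotypes.n_variants, dtype=bool)
    cache: dict[tuple[int, int, int], float] = {}
    for j in np.flatnonzero(keep_maf):
        counts = (
            int((calls[:, j] == 0).sum()),
            int((calls[:, j] == 1).sum()),
            int((calls[:, j] == 2).sum()),
        )
        p = cache.get(counts)
        if p is None:
            p = hwe_exact_p(*counts)
            cache[counts] = p
        keep_hwe[j] = p >= hwe_alpha
    keep = keep_maf & keep_hwe
    report = {
        "n_input": genotypes.n_variants,
        "n_excluded_maf": int((~keep_maf).sum()),
        "n_excluded_hwe": int((keep_maf & ~keep_hwe).sum()),
        "n_retained": int(keep.sum()),
    }
    return genotypes.subset_variants(genotypes.variant_ids[keep]), report


@dataclass
class ScanResult:
    """Dense association scan results for traits x variants.

    ``r`` holds the trait-dosage correlations; ``p`` the two-sided t-test
    p-values with n-2 degrees of freedom (floored at 1e-300); ``beta`` the
    regression slopes of the (transformed) trait on dosage; ``n`` the
    per-trait sample size after listwise deletion.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    beta: pd.DataFrame
    n: pd.Series
    skipped_variants: list[str]

    def to_frame(self, p_max: float | None = None) -> pd.DataFrame:
        """Long-format results, optionally keeping only p <= p_max."""
        long = self.p.stack().rename("p").reset_index()
        long.columns = ["trait_id", "variant_id", "p"]
        long["r"] = self.r.stack().to_numpy()
        long["beta"] = self.beta.stack().to_numpy()
        long["n"] = self.n.loc[long["trait_id"]].to_numpy()
        if p_max is not None:
            long = long[long["p"] <= p_max].reset_index(drop=True)
        return long


def _pvalue_from_r(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    df = np.maximum(n - 2, 1)
    r2 = np.clip(r**2, 0.0, 1.0 - 1e-16)
    t = np.abs(r) * np.sqrt(df / (1.0 - r2))
    return np.maximum(2.0 * stats.t.sf(t, df=df), P_FLOOR)


def association_scan(
    traits: pd.DataFrame,
    genotypes: GenotypeMatrix,
    transform: bool = True,
) -> ScanResult:
    """Linear-regression scan of every trait against every variant.

    ``traits`` is individuals x traits (collapsed per-individual values);
    with ``transform=True`` each trait is inverse-normal transformed first.
    Missing trait values are dropped listwise per trait; missing dosages are
    mean-imputed per variant. Zero-variance dosage columns (after deletion)
    are skipped and reported.
    """
    common = traits.index.intersection(genotypes.individuals)
    T = traits.loc[common]
    D = genotypes.dosages.loc[common].to_numpy(dtype=float)
    col_mean = np.nanmean(D, axis=0)
    nan_mask = np.isnan(D)
    if nan_mask.any():
        D[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])

    sd = D.std(axis=0, ddof=0)
    skipped = list(genotypes.variant_ids[sd == 0])
    ok = sd > 0
    Dz = (D[:, ok] - D[:, ok].mean(axis=0)) / sd[ok]
    vids = genotypes.variant_ids[ok]

    n_ind = len(common)
    missing_any = T.isna().any().any()
    r = np.empty((T.shape[1], ok.sum()))
    nvec = np.empty(T.shape[1], dtype=int)
    beta = np.empty_like(r)
    if not missing_any:
        Y = np.column_stack(
            [inverse_normal_transform(T[c].to_numpy()) if transform else T[c].to_numpy()
             for c in T.columns]
        )
        sy = Y.std(axis=0, ddof=0)
        Yz = (Y - Y.mean(axis=0)) / np.where(sy > 0, sy, 1.0)
        r = (Yz.T @ Dz) / n_ind
        nvec[:] = n_ind
        beta = r * sy[:, None]  # dosage standardized: slope on z-dosage scale
        sx = sd[ok]
        beta = (r * sy[:, None]) / sx[None, :]
    else:
        for i, c in enumerate(T.columns):
            y = T[c].to_numpy(dtype=float)
            m = np.isfinite(y)
            yv = inverse_normal_transform(y[m]) if transform else y[m]
            d = D[np.ix_(m, ok)]
            dsd = d.std(axis=0, ddof=0)
            dz = (d - d.mean(axis=0)) / np.where(dsd > 0, dsd, 1.0)
            sy = yv.std(ddof=0)
            yz = (yv - yv.mean()) / (sy if sy > 0 else 1.0)
            r[i] = (yz @ dz) / m.sum()
            r[i, dsd == 0] = 0.0
            nvec[i] = m.sum()
            beta[i] = r[i] * sy / np.where(dsd > 0, dsd, 1.0)

    p = _pvalue_from_r(r, nvec[:, None])
    traits_idx = pd.Index(T.columns, name="trait_id")
    return ScanResult(
        r=pd.DataFrame(r, index=traits_idx, columns=vids),
        p=pd.DataFrame(p, index=traits_idx, columns=vids),
        beta=pd.DataFrame(beta, index=traits_idx, columns=vids),
        n=pd.Series(nvec, index=traits_idx, name="n"),
        skipped_variants=skipped,
    )


def blocks_from_recomb_map(
    recomb_map: pd.DataFrame, threshold: float = 10.0
) -> pd.DataFrame:
    """Partition each chromosome into recombination blocks.

    Positions with recombination rate above ``threshold`` cM/Mb are block
    boundaries; blocks are the intervals between consecutive boundaries
    (1-based inclusive at I/O, covering the whole chromosome).
    """
    rows = []
    for chrom, sub in recomb_map.groupby("chrom", sort=False):
        cuts = np.sort(sub.loc[sub["rate_cm_mb"] > threshold, "pos"].to_numpy())
        edges = np.concatenate([[0], cuts, [np.iinfo(np.int64).max - 1]])
        edges = np.unique(edges)
        for i in range(len(edges) - 1):
            rows.append(
                (chrom, int(edges[i]) + 1, int(edges[i + 1]), f"{chrom}_blk{i:05d}")
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "block_id"])


def assign_blocks(variants: pd.DataFrame, blocks: pd.DataFrame) -> pd.Series:
    """Map each variant to the block containing its position."""
    out = pd.Series(index=variants.index, dtype=object)
    for chrom, sub in variants.groupby("chrom", sort=False):
        b = blocks[blocks["chrom"] == chrom].sort_values("start")
        if b.empty:
            raise ValueError(f"no blocks on chromosome {chrom}")
        idx = np.searchsorted(b["start"].to_numpy(), sub["pos"].to_numpy(), side="right") - 1
        if (idx < 0).any() or (sub["pos"].to_numpy() > b["end"].to_numpy()[idx]).any():
            raise ValueError(f"variant outside all blocks on {chrom}")
        out.loc[sub.index] = b["block_id"].to_numpy()[idx]
    return out


def select_block_best(
    scan: ScanResult,
    variants: pd.DataFrame,
    blocks: pd.DataFrame,
) -> pd.DataFrame:
    """Keep, per (trait, block), only the most significant variant.

    Ties on p are broken by smaller position, then lexicographic variant id.
    Returns a long dataframe with columns trait_id, variant_id, block_id,
    beta, r, p, n.
    """
    block_of = assign_blocks(variants.loc[scan.p.columns], blocks)
    order = variants.loc[scan.p.columns].assign(
        block=block_of.values, _id=scan.p.columns
    )
    order = order.sort_values(["block", "pos", "_id"], kind="mergesort").drop(
        columns="_id"
    )
    cols = order.index  # variants sorted by (block, pos, id)
    P = scan.p.loc[:, cols].to_numpy()
    blk = order["block"].to_numpy()
    starts = np.flatnonzero(np.r_[True, blk[1:] != blk[:-1]])
    ends = np.r_[starts[1:], blk.size]

    rows = []
    col_pos = {c: i for i, c in enumerate(cols)}
    for t_i, trait in enumerate(scan.p.index):
        prow = P[t_i]
        mins = np.minimum.reduceat(prow, starts)
        for s, e, mn in zip(starts, ends, mins):
            j = s + int(np.argmax(prow[s:e] == mn))  # first occurrence = pos/id tiebreak
            rows.append((trait, cols[j], blk[s]))
    out = pd.DataFrame(rows, columns=["trait_id", "variant_id", "block_id"])
    ti = out["trait_id"].to_numpy()
    vi = out["variant_id"].to_numpy()
    t_idx = scan.p.index.get_indexer(ti)
    v_idx = [col_pos[v] for v in vi]
    out["beta"] = scan.beta.loc[:, cols].to_numpy()[t_idx, v_idx]
    out["r"] = scan.r.loc[:, cols].to_numpy()[t_idx, v_idx]
    out["p"] = P[t_idx, v_idx]
    out["n"] = scan.n.loc[ti].to_numpy()
    return out


def classify_cis_trans(
    results: pd.DataFrame,
    variants: pd.DataFrame,
    gene_models: pd.DataFrame,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Label each association cis or trans.

    cis: same chromosome and variant position within [TSS - window,
    TES + window] measured in transcription orientation (endpoints
    inclusive); trans otherwise. Traits without a gene model are left
    unlabeled with a warning.
    """
    out = results.copy()
    v = variants.loc[out["variant_id"]]
    out["variant_chrom"] = v["chrom"].to_numpy()
    out["variant_pos"] = v["pos"].to_numpy()
    known = out["trait_id"].isin(gene_models.index)
    if (~known).any():
        warnings.warn(
            f"no gene model for {out.loc[~known, 'trait_id'].nunique()} trait(s); "
            "cis/trans classification skipped for them"
        )
    out["locus_class"] = pd.NA
    g = gene_models.loc[out.loc[known, "trait_id"]]
    lo = np.minimum(g["tss"].to_numpy(), g["tes"].to_numpy()) - window
    hi = np.maximum(g["tss"].to_numpy(), g["tes"].to_numpy()) + window
    same = g["chrom"].to_numpy() == out.loc[known, "variant_chrom"].to_numpy()
    pos = out.loc[known, "variant_pos"].to_numpy()
    cis = same & (pos >= lo) & (pos <= hi)
    out.loc[known, "locus_class"] = np.where(cis, "cis", "trans")
    return out.drop(columns=["variant_chrom", "variant_pos"])


def mixed_model_validate(
    replicate_values: pd.Series | pd.DataFrame,
    dosage: pd.Series,
    trait_id: str | None = None,
) -> float:
    """Replicate-level mixed-model p-value for one hit.

    Fits trait ~ dosage with a random per-individual (thaw) intercept on the
    (individual, bio_rep)-indexed replicate values and returns the Wald-t
    p-value for the dosage effect with n_individuals - 2 denominator df.
    """
    import statsmodels.api as sm

    if isinstance(replicate_values, pd.DataFrame):
        if trait_id is None:
            raise ValueError("trait_id required with a replicate matrix")
        y = replicate_values[trait_id]
    else:
        y = replicate_values
    y = y.dropna()
    ind = y.index.get_level_values("individual_id")
    g = dosage.loc[ind].to_numpy(dtype=float)
    if np.std(g) == 0:
        raise ValueError("zero-variance dosage in validation model")
    exog = np.column_stack([np.ones(len(y)), g])
    n_groups = ind.nunique()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.MixedLM(y.to_numpy(dtype=float), exog, groups=ind.to_numpy()).fit(
                reml=True, method="lbfgs", maxiter=200
            )
            t = fit.fe_params[1] / fit.bse_fe[1]
        except Exception:
            ols = sm.OLS(y.to_numpy(dtype=float), exog).fit()
            t = ols.tvalues[1]
    return float(max(2.0 * stats.t.sf(abs(t), df=max(n_groups - 2, 1)), P_FLOOR))
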
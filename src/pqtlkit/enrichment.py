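"""Functional-annotation enrichment and GWAS-catalog overlap testing.

QTL variants (block-reduced hits at a nominal threshold) are tested for
enrichment of each functional annotation class against the full annotated
variant background with a two-sided Fisher exact test. Overlap with
complex-trait GWAS-catalog SNPs is assessed empirically: catalog SNPs are
LD-expanded (r^2 > 0.8 within a local window), and the observed per-trait
overlap count is compared with the overlaps of MAF-matched random variant
sets (same size and identical per-5%-MAF-bin composition as the catalog).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix

__all__ = [
    "ANNOTATION_CLASSES",
    "fisher_exact_p",
    "annotation_enrichment",
    "ld_expand",
    "maf_matched_sets",
    "gwas_overlap_empirical_p",
]

#: The fixed functional-class vocabulary for variant annotations.
ANNOTATION_CLASSES = [
    "coding-synonymous",
    "intergenic",
    "intron",
    "missense",
    "near-gene-3",
    "near-gene-5",
    "nonsense",
    "splice-3",
    "splice-5",
    "utr-3",
    "utr-5",
]


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Computed by direct hypergeometric enumeration in exact integer
    arithmetic: conditional on the margins, the probability of every
    achievable table is proportional to C(c1, k) * C(n - c1, r1 - k); the
    two-sided p sums the probabilities of all tables no more likely than
    the observed one (the standard exact-test convention). Exact integers
    make tie handling unambiguous.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be nonnegative")
    import math

    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    weights = [
        math.comb(c1, k) * math.comb(n - c1, r1 - k) for k in range(lo, hi + 1)
    ]
    obs = weights[a - lo]
    from fractions import Fraction

    # Fraction division is safe for margins whose binomials overflow float
    return float(Fraction(sum(w for w in weights if w <= obs), math.comb(n, r1)))


def annotation_enrichment(
    qtl_variants,
    background_variants,
    annotations: pd.Series,
) -> pd.DataFrame:
    """Per-class odds ratio and two-sided Fisher exact p for QTL variants.

    For each annotation class the 2x2 table is (in QTL set vs rest of
    background) x (in class vs not). The odds ratio uses the Haldane 0.5
    continuity correction when any cell is zero.
    """
    qtl = pd.Index(pd.unique(pd.Series(list(qtl_variants))))
    background = pd.Index(pd.unique(pd.Series(list(background_variants))))
    if len(qtl) == 0:
        raise ValueError("empty QTL variant set")
    if not qtl.isin(background).all():
        raise ValueError("QTL set must be a subset of the background")
    ann = annotations.reindex(background)
    in_qtl = background.isin(qtl)

    rows = []
    for cls in ANNOTATION_CLASSES:
        in_cls = (ann == cls).to_numpy()
        a = int(np.sum(in_qtl & in_cls))
        b = int(np.sum(in_qtl & ~in_cls))
        c = int(np.sum(~in_qtl & in_cls))
        d = int(np.sum(~in_qtl & ~in_cls))
        p = fisher_exact_p(a, b, c, d)
        if min(a, b, c, d) == 0:
            orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orat = (a * d) / (b * c)
        rows.append((cls, a, b, c, d, orat, p))
    return pd.DataFrame(
        rows,
        columns=["annotation", "qtl_in", "qtl_out", "bg_in", "bg_out", "odds_ratio", "p"],
    )


def ld_expand(
    snps,
    genotypes: GenotypeMatrix,
    r2_min: float = 0.8,
    window: int = 1_000_000,
) -> pd.Index:
    """Expand a SNP set with all local variants in LD (r^2 > ``r2_min``).

    For each seed SNP, every variant on the same chromosome within
    ``window`` bp whose dosage correlation squared exceeds ``r2_min`` is
    added; seeds are always included. Seeds missing from the genotype pool
    are skipped with a warning. Under block-structured LD the expansion is
    idempotent: re-expanding an expanded set adds nothing new.
    """
    import warnings

    out = set()
    D = genotypes.dosages
    v = genotypes.variants
    for s in snps:
        if s not in D.columns:
            warnings.warn(f"seed SNP {s} absent from genotypes; skipped")
            continue
        out.add(s)
        chrom, pos = v.loc[s, "chrom"], v.loc[s, "pos"]
        near = v[(v["chrom"] == chrom) & (v["pos"] - pos).abs().le(window)].index
        x = D[s].to_numpy()
        if x.std() == 0:
            continue
        sub = D[near].to_numpy()
        sd = sub.std(axis=0)
        ok = sd > 0
        xz = (x - x.mean()) / x.std()
        r = np.zeros(len(near))
        r[ok] = (xz @ ((sub[:, ok] - sub[:, ok].mean(axis=0)) / sd[ok])) / len(x)
        out.update(near[(r**2) > r2_min])
    return pd.Index(sorted(out))


def _maf_bin(maf: np.ndarray, bin_width: float) -> np.ndarray:
    # half-open [k*w, (k+1)*w), top bin closed at 0.5
    b = np.floor(np.asarray(maf) / bin_width).astype(int)
    top = int(np.floor(0.5 / bin_width))
    return np.minimum(b, top - 1) if top > 0 else b


def maf_matched_sets(
    catalog_snps,
    pool: GenotypeMatrix,
    n_sets: int = 1000,
    bin_width: float = 0.05,
    seed: int = 0,
) -> list[pd.Index]:
    """Random variant sets matching the catalog's MAF-bin composition.

    Each returned set has the catalog's size with exactly the catalog's
    per-bin counts, sampled without replacement within a set and
    independently across sets. The sets are index-aligned to the catalog:
    position i of every set is a random same-bin partner of catalog SNP i,
    so any partition of the catalog (e.g. by GWAS trait) induces matched
    partitions of the null sets.
    """
    rng = np.random.default_rng(seed)
    catalog = pd.Index(list(catalog_snps))
    maf = pool.empirical_maf()
    missing = catalog.difference(maf.index)
    if len(missing):
        raise KeyError(f"catalog SNPs absent from pool: {list(missing)[:5]}")
    cat_bins = _maf_bin(maf.loc[catalog].to_numpy(), bin_width)
    pool_bins = _maf_bin(maf.to_numpy(), bin_width)

    by_bin: dict[int, np.ndarray] = {}
    for b in np.unique(cat_bins):
        members = maf.index.to_numpy()[pool_bins == b]
        quota = int(np.sum(cat_bins == b))
        if quota > members.size:
            raise ValueError(
                f"MAF bin [{b * bin_width:.2f}, {(b + 1) * bin_width:.2f}) needs "
                f"{quota} variants but the pool holds only {members.size}"
            )
        by_bin[b] = members

    sets = []
    for _ in range(n_sets):
        chosen = np.empty(len(catalog), dtype=object)
        for b, members in by_bin.items():
            slots = np.flatnonzero(cat_bins == b)
            pick = rng.choice(members, size=slots.size, replace=False)
            chosen[slots] = pick
        sets.append(pd.Index(chosen))
    return sets


def gwas_overlap_empirical_p(
    qtl_variants,
    catalog: pd.DataFrame,
    matched_sets: list[pd.Index],
    min_overlap: int = 3,
    add_one: bool = False,
) -> pd.DataFrame:
    """Per-GWAS-trait empirical p for QTL overlap beyond MAF-matched chance.

    ``catalog`` needs columns ``snp_id`` and ``trait``. For each trait with
    at least ``min_overlap`` observed overlaps, p is the fraction of matched
    sets whose (trait-aligned) overlap strictly exceeds the observed count;
    zero exceedances are reported as censored at 1/n_sets. ``add_one``
    applies the (k+1)/(n+1) smoothing instead.
    """
    qtl = set(qtl_variants)
    n_sets = len(matched_sets)
    cat = catalog.reset_index(drop=True)
    rows = []
    for trait, sub in cat.groupby("trait"):
        idx = sub.index.to_numpy()
        observed = sum(1 for s in sub["snp_id"] if s in qtl)
        if observed < min_overlap:
            rows.append((trait, observed, np.nan, np.nan, True))
            continue
        exceed = 0
        for ms in matched_sets:
            null_overlap = sum(1 for s in ms[idx] if s in qtl)
            if null_overlap > observed:
                exceed += 1
        if add_one:
            p = (exceed + 1) / (n_sets + 1)
            censored = False
        else:
            p = exceed / n_sets if exceed > 0 else 1.0 / n_sets
            censored = exceed == 0
        rows.append((trait, observed, exceed, p, censored))
    out = pd.DataFrame(
        rows, columns=["trait", "observed_overlap", "n_exceed", "empirical_p", "censored"]
    )
    out["censored"] = out["censored"].astype(object)
    out.loc[out["observed_overlap"] < min_overlap, "censored"] = pd.NA
    return out
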
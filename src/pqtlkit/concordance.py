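"""Cross-platform concordance, replication-rate curves, and the knockdown rule.

Three small, self-contained analyses that characterize how well protein
measurements agree with paired measurements from other platforms:

* per-gene Spearman correlation of interindividual rank order between two
  matrices (protein vs mRNA platform, or two mRNA platforms);
* replication-rate curves: for hits discovered in one cohort, the fraction
  that replicate in a second cohort (nominal p < 0.05 with concordant effect
  direction) as a function of discovery significance, against the 0.025 null
  expectation (5% significance x 1/2 direction);
* the siRNA knockdown significance rule: a knockdown counts as significant
  when the percentage reduction exceeds twice its percentage standard error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "interindividual_correlation",
    "replication_rate",
    "knockdown_significant",
    "NULL_REPLICATION_RATE",
]

#: Chance replication rate: p < 0.05 combined with a coin-flip direction.
NULL_REPLICATION_RATE = 0.025


def interindividual_correlation(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    mapping: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman rho across shared individuals for each mapped column pair.

    ``mapping`` has two columns naming a column of ``matrix_a`` and of
    ``matrix_b`` respectively (many-to-one mappings allowed; every pair is
    reported, no averaging). Pairs with fewer than 3 shared individuals are
    reported as missing. The summary (median and quartiles of rho) is
    attached in ``DataFrame.attrs["summary"]``.
    """
    if mapping.empty:
        raise ValueError("empty mapping")
    col_a, col_b = mapping.columns[:2]
    shared = matrix_a.index.intersection(matrix_b.index)
    rows = []
    for _, pair in mapping.iterrows():
        a, b = pair[col_a], pair[col_b]
        if a not in matrix_a.columns or b not in matrix_b.columns:
            rows.append((a, b, np.nan, 0))
            continue
        sub = pd.concat(
            [matrix_a.loc[shared, a], matrix_b.loc[shared, b]], axis=1
        ).dropna()
        if len(sub) < 3:
            rows.append((a, b, np.nan, len(sub)))
            continue
        rho = stats.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1]).statistic
        rows.append((a, b, rho, len(sub)))
    out = pd.DataFrame(rows, columns=[col_a, col_b, "rho", "n_shared"])
    rho = out["rho"].dropna()
    out.attrs["summary"] = {
        "median": float(rho.median()) if len(rho) else np.nan,
        "q1": float(rho.quantile(0.25)) if len(rho) else np.nan,
        "q3": float(rho.quantile(0.75)) if len(rho) else np.nan,
        "n": int(len(rho)),
    }
    return out


def replication_rate(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    p_bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Replication rate per discovery-significance bin.

    Both inputs need columns trait_id, variant_id, beta, p; rows are matched
    on (trait_id, variant_id). A discovery hit replicates when its
    replication p < 0.05 and the effect directions agree. Default bins are
    p-value decades (1e-2, 1e-3, ...); each row reports the rate among hits
    with discovery p below that bin edge, alongside the 0.025 chance level.
    """
    keys = ["trait_id", "variant_id"]
    merged = discovery.merge(
        replication[keys + ["beta", "p"]], on=keys, suffixes=("_disc", "_rep")
    )
    if merged.empty:
        raise ValueError("no shared (trait, variant) keys between cohorts")
    merged["replicated"] = (merged["p_rep"] < 0.05) & (
        np.sign(merged["beta_disc"]) == np.sign(merged["beta_rep"])
    )
    if p_bins is None:
        lo = np.floor(np.log10(max(merged["p_disc"].min(), 1e-300)))
        p_bins = 10.0 ** np.arange(-2, lo - 1, -1)
    rows = []
    for edge in np.sort(np.asarray(p_bins))[::-1]:
        sub = merged[merged["p_disc"] < edge]
        rate = float(sub["replicated"].mean()) if len(sub) else np.nan
        rows.append((edge, len(sub), rate, NULL_REPLICATION_RATE))
    out = pd.DataFrame(
        rows, columns=["p_max", "n_hits", "replication_rate", "null_expectation"]
    )
    out.attrs["pairs"] = merged
    return out


def knockdown_significant(percent_remaining: float, percent_se: float) -> bool:
    """Knockdown call: protein reduced by more than twice its percentage SE.

    ``percent_remaining`` is the targeted-siRNA protein level as a
    percentage of the scrambled control; the reduction
    (100 - percent_remaining) must exceed 2 x ``percent_se`` (roughly a
    one-sided p < 0.05 z criterion).
    """
    if percent_se < 0:
        raise ValueError("percentage standard error must be nonnegative")
    if percent_remaining < 0:
        raise ValueError("percent remaining must be nonnegative")
    return (100.0 - percent_remaining) > 2.0 * percent_se
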
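"""Known cellular covariates and hidden confounders on the protein matrix.

The covariate model is a linear mixed-effects model per protein trait:

    y ~ EBV + mtDNA + ATP + growth + sex + phase + SV_1..k + (1 | individual)

fit on replicate-level values (one row per individual x biological
replicate). Each biological replicate is an independent freeze-thaw of the
cell line, so the thaw random effect is carried by the per-individual random
intercept; with a single observation per thaw, a separate thaw-level
intercept is not identifiable from the residual.

Hidden confounders are estimated by a permutation-calibrated surrogate
variable analysis: singular vectors of the centered residual matrix are
retained while their explained-variance share beats the permutation null
(per-trait independent column permutations), a parallel-analysis style
selection.

False discovery rates for covariate associations use Storey's q-value method
with the lambda-smoothing pi0 estimate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .datatypes import ProteinMatrix, SurrogateVariableSet

__all__ = [
    "fit_covariate_model",
    "estimate_surrogate_variables",
    "storey_qvalues",
    "residualize",
]

_NUMERIC_COVS = ["ebv_copies", "mtdna_copies", "atp_baseline", "growth_rate"]


def _design(
    covariates: pd.DataFrame, svs: SurrogateVariableSet | None, index: pd.Index
) -> tuple[pd.DataFrame, list[str]]:
    """Fixed-effect design matrix (standardized numerics, coded categoricals)."""
    X = pd.DataFrame(index=index)
    dropped = []
    cov = covariates.loc[index.get_level_values("individual_id")]
    for c in _NUMERIC_COVS:
        if c not in covariates.columns:
            continue
        v = cov[c].to_numpy(dtype=float)
        if np.std(v) == 0:
            dropped.append(c)
            continue
        X[c] = (v - v.mean()) / v.std()
    for c in ("sex", "phase"):
        if c not in covariates.columns:
            continue
        codes, uniq = pd.factorize(cov[c])
        if len(uniq) < 2:
            dropped.append(c)
            continue
        for level in range(1, len(uniq)):
            X[f"{c}[{uniq[level]}]"] = (codes == level).astype(float)
    if svs is not None and svs.k > 0:
        sv = svs.svs.loc[index.get_level_values("individual_id")]
        for j, name in enumerate(svs.svs.columns):
            X[name] = sv.iloc[:, j].to_numpy()
    if dropped:
        warnings.warn(f"constant covariates dropped from design: {dropped}")
    return X, dropped


def _fit_mixed_trait(
    y: np.ndarray, X: pd.DataFrame, groups: np.ndarray, n_groups: int
) -> pd.DataFrame:
    """One-trait mixed model; Wald-t p-values with between-individual df."""
    import statsmodels.api as sm

    exog = sm.add_constant(X.to_numpy(), has_constant="add")
    names = ["const"] + list(X.columns)
    df_denom = max(n_groups - exog.shape[1], 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, exog, groups=groups)
            fit = model.fit(reml=True, method="lbfgs", maxiter=200)
            params = fit.fe_params
            bse = fit.bse_fe
        except Exception:
            ols = sm.OLS(y, exog).fit()
            params, bse = ols.params, ols.bse
    tvals = params / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=df_denom)
    return pd.DataFrame(
        {"beta": params, "se": bse, "t": tvals, "p": pvals}, index=names
    ).drop(index="const")


def fit_covariate_model(
    matrix: ProteinMatrix,
    covariates: pd.DataFrame,
    svs: SurrogateVariableSet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the replicate-level mixed model to every trait.

    Returns ``(report, residuals)``: a long dataframe of per-trait
    per-covariate effect estimates and p-values (with Storey q-values per
    covariate), and the per-individual residual matrix after removing the
    fitted fixed effects (used as SVA input and for optional adjusted scans).
    """
    rep = matrix.replicate_values
    missing = set(rep.index.get_level_values("individual_id")) - set(covariates.index)
    if missing:
        raise ValueError(f"covariates missing for individuals: {sorted(missing)[:5]}")
    X, _ = _design(covariates, svs, rep.index)
    groups = rep.index.get_level_values("individual_id").to_numpy()
    n_groups = len(np.unique(groups))

    rows = []
    resid_cols = {}
    Xc = np.column_stack([np.ones(len(X)), X.to_numpy()])
    for trait in rep.columns:
        y = rep[trait].to_numpy(dtype=float)
        ok = np.isfinite(y)
        res = _fit_mixed_trait(y[ok], X.loc[ok], groups[ok], n_groups)
        res.insert(0, "trait", trait)
        rows.append(res.reset_index(names="covariate"))
        beta_full = np.linalg.lstsq(Xc[ok], y[ok], rcond=None)[0]
        r = np.full(len(y), np.nan)
        r[ok] = y[ok] - Xc[ok] @ beta_full
        resid_cols[trait] = r

    report = pd.concat(rows, ignore_index=True)
    report["q"] = np.nan
    for cov_name, sub in report.groupby("covariate"):
        report.loc[sub.index, "q"] = storey_qvalues(sub["p"].to_numpy())
    residuals = (
        pd.DataFrame(resid_cols, index=rep.index)
        .groupby(level="individual_id", sort=True)
        .mean()
    )
    return report, residuals


def residualize(values: pd.DataFrame, svs: SurrogateVariableSet) -> pd.DataFrame:
    """Project trait values onto the orthocomplement of the surrogate variables."""
    if svs.k == 0:
        return values - values.mean()
    U = svs.svs.loc[values.index].to_numpy()
    Y = values.to_numpy() - values.to_numpy().mean(axis=0)
    return pd.DataFrame(
        Y - U @ (U.T @ Y), index=values.index, columns=values.columns
    )


def estimate_surrogate_variables(
    residuals: pd.DataFrame,
    n_permutations: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> SurrogateVariableSet:
    """Permutation-calibrated selection of significant singular vectors.

    The centered residual matrix (individuals x traits) is decomposed by SVD;
    component k is retained while its explained-variance share exceeds the
    (1 - alpha) quantile of the share obtained from matrices whose columns
    were permuted independently (which preserves per-trait marginals but
    destroys inter-trait structure). Selection stops at the first
    non-significant component, and the retained left singular vectors are
    returned as orthonormal surrogate variables.
    """
    if n_permutations < 20:
        raise ValueError("n_permutations must be at least 20 for a usable null")
    rng = np.random.default_rng(seed)
    Y = residuals.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)
    n, m = Y.shape
    U, s, _ = np.linalg.svd(Y, full_matrices=False)
    share = s**2 / np.sum(s**2)

    k_max = min(n, m) - 1
    null_share = np.empty((n_permutations, min(n, m)))
    Yp = np.empty_like(Y)
    for b in range(n_permutations):
        for j in range(m):
            Yp[:, j] = Y[rng.permutation(n), j]
        Yp -= Yp.mean(axis=0)
        sp = np.linalg.svd(Yp, compute_uv=False)
        null_share[b] = sp**2 / np.sum(sp**2)

    pvals = []
    k = 0
    for comp in range(k_max):
        p = (1.0 + np.sum(null_share[:, comp] >= share[comp])) / (n_permutations + 1.0)
        pvals.append(p)
        if p < alpha:
            k += 1
        else:
            break
    sv = pd.DataFrame(
        U[:, :k],
        index=residuals.index,
        columns=[f"SV{i + 1}" for i in range(k)],
    )
    return SurrogateVariableSet(sv, pd.Series(pvals[:k], index=sv.columns, name="p"))


def storey_qvalues(
    pvalues: np.ndarray,
    lambdas: np.ndarray | None = None,
    pi0: float | None = None,
) -> np.ndarray:
    """Storey q-values with the lambda-smoothing pi0 estimate.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the
    default grid 0.05, 0.10, ..., 0.95, smoothed with a cubic smoothing
    spline and read off at the largest lambda, then clipped to (0, 1].
    q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j), which is
    monotone nondecreasing in p and bounded by 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        counts = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
        if np.all(counts == counts[0]) or m < 100:
            pi0 = float(min(counts[-1], 1.0)) if m >= 100 else 1.0
        else:
            spline = interpolate.UnivariateSpline(lambdas, counts, k=3)
            pi0 = float(spline(lambdas[-1]))
        pi0 = min(max(pi0, 1.0 / m), 1.0)

    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
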
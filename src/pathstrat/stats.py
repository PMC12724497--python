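"""Post hoc statistics linking pathway scores and clusters to clinical outcomes.

Rank-based association (Spearman rho with percentile-bootstrap CIs and
Benjamini-Hochberg FDR across the pathway x outcome family), Kruskal-Wallis
omnibus tests with the rank eta-squared effect size

    eta^2 = (H - k + 1) / (n - k),

Cliff's delta dominance effect sizes with bootstrap CIs, chi-square/Fisher
categorical association with Cramer's V, covariate-adjusted OLS (with
partial R^2 for cluster-indicator blocks), and pathway-vs-global partition
concordance (NMI/ARI) with add-one permutation p-values.

Spearman p-values use the large-sample normal approximation
z = rho * sqrt(n - 1); CIs come from resampling subjects with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .stability import ari as _ari, nmi as _nmi


class DegenerateDataError(ValueError):
    pass


class RankDeficiencyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# rank correlation + FDR


@dataclass
class AssociationResult:
    pathway: str
    outcome: str
    rho: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    q: float = np.nan


def spearman_with_ci(x, y, B: int = 1000, seed: int = 0,
                     pathway: str = "", outcome: str = "") -> AssociationResult:
    """Spearman rho (average ranks for ties), bootstrap 95% CI, normal-approx p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise DegenerateDataError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; Spearman rho undefined, emitting NaN")
        return AssociationResult(pathway, outcome, np.nan, np.nan, np.nan, np.nan, n)
    rho = float(sps.spearmanr(x, y).statistic)
    z = abs(rho) * np.sqrt(n - 1)
    p = float(2.0 * sps.norm.sf(z))
    rng = np.random.default_rng(seed)
    boot = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            boot[b] = sps.spearmanr(x[idx], y[idx]).statistic
    boot = boot[np.isfinite(boot)]
    lo, hi = np.percentile(boot, [2.5, 97.5]) if len(boot) else (np.nan, np.nan)
    return AssociationResult(pathway, outcome, rho, float(lo), float(hi), p, n)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def association_table(mpis_scores: pd.DataFrame, clinical: pd.DataFrame,
                      outcomes=("updrs3", "moca", "quip_sum"),
                      B: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Tidy pathway x outcome association table; one BH family per table."""
    rows = []
    for pathway in mpis_scores.columns:
        for outcome in outcomes:
            try:
                r = spearman_with_ci(mpis_scores[pathway], clinical[outcome],
                                     B=B, seed=seed, pathway=pathway, outcome=outcome)
            except DegenerateDataError:
                continue
            rows.append(r.__dict__)
    table = pd.DataFrame(rows)
    if not table.empty:
        finite = np.isfinite(table.p)
        q = np.full(len(table), np.nan)
        if finite.any():
            q[finite.to_numpy()] = bh_fdr(table.p[finite])
        table["q"] = q
    return table


# ---------------------------------------------------------------------------
# Kruskal-Wallis with rank eta-squared


@dataclass
class ClusterTestResult:
    variable: str
    H: float
    k: int
    n: int
    eta2: float
    p: float
    q: float = np.nan


def eta_squared(H: float, n: int, k: int) -> float:
    """Rank eta-squared from the Kruskal-Wallis statistic: (H - k + 1)/(n - k)."""
    if n <= k:
        raise ValueError("need n > k")
    return (H - k + 1) / (n - k)


def kruskal_eta2(values, group_labels, variable: str = "") -> ClusterTestResult:
    """Tie-corrected Kruskal-Wallis H, chi-square p (k-1 df) and eta^2."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise DegenerateDataError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise DegenerateDataError("every group must be nonempty")
    n, k = len(values), len(groups)
    if n <= k:
        raise DegenerateDataError("need n > k")
    H, _ = sps.kruskal(*groups)
    p = float(sps.chi2.sf(H, k - 1))
    return ClusterTestResult(variable=variable, H=float(H), k=k, n=n,
                             eta2=float(eta_squared(H, n, k)), p=p)


# ---------------------------------------------------------------------------
# effect sizes


@dataclass
class EffectSizeResult:
    contrast: tuple
    delta: float
    ci_low: float
    ci_high: float


def _delta(a: np.ndarray, b: np.ndarray) -> float:
    # wins minus losses over all |a| x |b| pairs, via rank counting
    gt = (a[:, None] > b[None, :]).sum()
    lt = (a[:, None] < b[None, :]).sum()
    return float((gt - lt) / (len(a) * len(b)))


def cliffs_delta(a, b, B: int = 1000, seed: int = 0,
                 contrast: tuple = ("a", "b")) -> EffectSizeResult:
    """Cliff's delta with a percentile bootstrap CI (both groups resampled)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateDataError("both samples must be nonempty")
    d = _delta(a, b)
    rng = np.random.default_rng(seed)
    boot = np.empty(B)
    for i in range(B):
        boot[i] = _delta(a[rng.integers(0, len(a), len(a))],
                         b[rng.integers(0, len(b), len(b))])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return EffectSizeResult(contrast=contrast, delta=d,
                            ci_low=float(lo), ci_high=float(hi))


def cramers_v(table) -> float:
    """Cramer's V from the Pearson chi-square (no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("contingency table must be 2-D and nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateDataError("contingency table has empty margins")
    chi2 = sps.chi2_contingency(t, correction=False).statistic
    n = t.sum()
    return float(np.sqrt(chi2 / (n * (min(t.shape) - 1))))


def categorical_association(table) -> dict:
    """Chi-square test, or Fisher's exact for sparse 2x2 tables.

    Fisher is used when any expected cell count is below 5 and the table is
    2x2; larger sparse tables fall back to chi-square with a warning.
    """
    t = np.asarray(table, dtype=float)
    res = sps.chi2_contingency(t, correction=False)
    sparse = (res.expected_freq < 5).any()
    if sparse and t.shape == (2, 2):
        p = float(sps.fisher_exact(t).pvalue)
        test = "fisher"
    else:
        if sparse:
            warnings.warn("sparse table larger than 2x2; chi-square p may be unreliable")
        p = float(res.pvalue)
        test = "chi2"
    return {"test": test, "p": p, "statistic": float(res.statistic),
            "cramers_v": cramers_v(t)}


# ---------------------------------------------------------------------------
# covariate-adjusted regression


@dataclass
class RegressionResult:
    outcome: str
    predictor: str
    beta: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    covariates: tuple
    partial_r2: float = np.nan
    f_p: float = np.nan
    q: float = np.nan


def _design(df: pd.DataFrame) -> pd.DataFrame:
    """One-hot categorical columns (first level is the reference)."""
    out = {}
    for col in df.columns:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            for c in dummies.columns:
                out[c] = dummies[c]
        else:
            out[col] = s.astype(float)
    return pd.DataFrame(out, index=df.index)


def adjusted_regression(outcome, predictor_block, covariates=None,
                        outcome_name: str = "outcome") -> RegressionResult:
    """OLS of the outcome on a predictor block plus covariates (with intercept).

    ``predictor_block`` may be a single numeric series (e.g. a pathway MPIS) or
    a DataFrame of cluster indicators; for a block, the partial R^2
    (SSE_reduced - SSE_full)/SSE_reduced and a global F-test are reported and
    ``beta`` refers to the block's first column. Listwise deletion of
    incomplete cases; rank-deficient designs raise, naming the collinear
    columns.
    """
    y = pd.Series(np.asarray(outcome, dtype=float), name=outcome_name)
    block = pd.DataFrame(predictor_block)
    if block.shape[1] == 0:
        raise ValueError("empty predictor block")
    block = block.reset_index(drop=True)
    y = y.reset_index(drop=True)
    parts = [block]
    if covariates is not None:
        cov = _design(pd.DataFrame(covariates).reset_index(drop=True))
        parts.append(cov)
    x = pd.concat(parts, axis=1)
    keep = np.isfinite(y) & np.isfinite(x).all(axis=1)
    y, x = y[keep], x[keep]
    n = len(y)

    design = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise RankDeficiencyError(f"design is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(y, design).fit()
    block_cols = list(block.columns)
    first = str(block_cols[0])
    ci = fit.conf_int().loc[first]
    result = RegressionResult(
        outcome=outcome_name, predictor=",".join(map(str, block_cols)),
        beta=float(fit.params[first]), ci_low=float(ci[0]), ci_high=float(ci[1]),
        p=float(fit.pvalues[first]), n=n,
        covariates=tuple(c for c in x.columns if c not in block_cols))
    if len(block_cols) > 1 or covariates is not None:
        reduced_x = x.drop(columns=block_cols)
        reduced = sm.OLS(y, sm.add_constant(reduced_x, has_constant="add")).fit()
        sse_full = float(fit.ssr)
        sse_red = float(reduced.ssr)
        result.partial_r2 = (sse_red - sse_full) / sse_red if sse_red > 0 else np.nan
        f_res = fit.compare_f_test(reduced)
        result.f_p = float(f_res[1])
    return result


def _collinear_columns(design: pd.DataFrame) -> list:
    """Columns whose removal restores full rank (greedy scan)."""
    cols = list(design.columns)
    mat = design.to_numpy()
    full = np.linalg.matrix_rank(mat)
    return [c for i, c in enumerate(cols)
            if np.linalg.matrix_rank(np.delete(mat, i, axis=1)) == full]


# ---------------------------------------------------------------------------
# partition concordance


@dataclass
class ConcordanceResult:
    pathway: str
    nmi: float
    ari: float
    perm_p_nmi: float
    perm_p_ari: float
    n_perm: int


def concordance_permutation(pathway_labels, global_labels, n_perm: int = 1000,
                            seed: int = 0, pathway: str = "") -> ConcordanceResult:
    """Observed NMI/ARI with permutation p-values (add-one rule, never 0)."""
    a = np.asarray(pathway_labels)
    b = np.asarray(global_labels)
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    obs_nmi = _nmi(a, b)
    obs_ari = _ari(a, b)
    rng = np.random.default_rng(seed)
    ge_nmi = ge_ari = 0
    for _ in range(n_perm):
        perm = rng.permutation(a)
        if _nmi(perm, b) >= obs_nmi:
            ge_nmi += 1
        if _ari(perm, b) >= obs_ari:
            ge_ari += 1
    return ConcordanceResult(
        pathway=pathway, nmi=obs_nmi, ari=obs_ari,
        perm_p_nmi=(1 + ge_nmi) / (1 + n_perm),
        perm_p_ari=(1 + ge_ari) / (1 + n_perm), n_perm=n_perm)


# ---------------------------------------------------------------------------
# cluster composition


def summarize_clusters(clinical: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-cluster composition: n, diagnosis counts, mean +/- SD, percentages."""
    labels = np.asarray(labels)
    df = clinical.reset_index(drop=True).copy()
    df["cluster"] = labels
    rows = []
    for cl, sub in df.groupby("cluster"):
        row = {"cluster": cl, "n": len(sub)}
        if "diagnosis" in sub:
            for dx, cnt in sub["diagnosis"].value_counts().items():
                row[f"n_{dx}"] = int(cnt)
        for col in ("age", "education", "disease_duration",
                    "updrs3", "moca", "quip_sum"):
            if col in sub:
                row[f"{col}_mean"] = float(sub[col].mean())
                row[f"{col}_sd"] = float(sub[col].std(ddof=1))
        if "sex" in sub:
            row["pct_female"] = float(100.0 * (sub["sex"] == "F").mean())
        if "medication_status" in sub:
            row["pct_on_medication"] = float(100.0 * (sub["medication_status"] == "on").mean())
        if "field_strength" in sub:
            row["pct_3T"] = float(100.0 * (sub["field_strength"] == "3T").mean())
        rows.append(row)
    return pd.DataFrame(rows).fillna({"n_PD": 0, "n_HC": 0, "n_SWEDD": 0})
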
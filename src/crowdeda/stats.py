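"""Study-level statistics for repeated-measures EDA designs.

The harness mirrors the analysis pipeline of within-subject crowd
experiments: a Lilliefors-type Kolmogorov–Smirnov normality screen per
condition cell decides between a repeated-measures ANOVA with
Greenhouse–Geisser correction and the nonparametric Friedman test; pairwise
post-hoc comparisons use paired t-tests with Bonferroni adjustment; group
moderation questions are answered by a linear mixed model with a random
intercept per subject and a condition x moderator interaction; effect sizes
are Cohen's d with pooled SD.

Repeated-measures analyses use complete cases only (subjects missing any
condition are dropped, never imputed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "RmMatrix",
    "StatReport",
    "MixedModelSpec",
    "ks_normality",
    "friedman",
    "rm_anova_gg",
    "posthoc_t_bonferroni",
    "mixed_mediation",
    "cohens_d",
    "analyze_study",
]


@dataclass
class RmMatrix:
    """Complete-case subjects x conditions matrix for one feature."""

    values: np.ndarray            # shape (n_subjects, k_conditions)
    labels: list[str]
    subjects: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x conditions)")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 conditions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix must be complete (finite) — drop "
                             "incomplete subjects first")

    @classmethod
    def from_table(cls, table: pd.DataFrame, value_col: str,
                   labels: list[str] | None = None,
                   subject_col: str = "subject_id",
                   label_col: str = "label") -> "RmMatrix":
        """Pivot a tidy feature table; incomplete subjects are dropped."""
        wide = table.pivot_table(index=subject_col, columns=label_col,
                                 values=value_col, aggfunc="first")
        if labels is not None:
            wide = wide[labels]
        wide = wide.dropna(axis=0, how="any")
        return cls(values=wide.to_numpy(dtype=float),
                   labels=[str(c) for c in wide.columns],
                   subjects=[str(i) for i in wide.index])

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class StatReport:
    """Result of one omnibus test plus its post-hoc matrix."""

    test: str
    statistic: float
    df1: float
    df2: float | None
    p: float
    epsilon: float | None = None
    posthoc: pd.DataFrame | None = None
    effect_sizes: dict = field(default_factory=dict)
    feature: str = ""

    def to_dict(self) -> dict:
        d = {
            "feature": self.feature, "test": self.test,
            "statistic": self.statistic, "df1": self.df1, "df2": self.df2,
            "p": self.p, "epsilon": self.epsilon,
            "effect_sizes": self.effect_sizes,
        }
        if self.posthoc is not None:
            d["posthoc"] = {
                f"{a} vs {b}": float(self.posthoc.loc[a, b])
                for a, b in combinations(self.posthoc.index, 2)
            }
        return d


@dataclass(frozen=True)
class MixedModelSpec:
    """Fixed/random structure for the moderation mixed model."""

    response: str                  # z-standardized feature column
    condition: str                 # numeric within-subject variable (speed)
    moderator: str                 # between-subject grouping / mediator
    subject: str = "subject_id"


def ks_normality(x: np.ndarray, n_sims: int = 1000,
                 seed: int = 1234) -> tuple[float, float]:
    """Kolmogorov–Smirnov normality check with estimated parameters.

    One-sample KS distance against a normal with the sample mean and SD
    (the Lilliefors variant); since the null distribution then depends on
    the estimation, the p-value comes from a seeded Monte-Carlo null of
    ``n_sims`` standard-normal samples of the same size.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality check undefined")

    def lillie_stat(sample: np.ndarray) -> np.ndarray:
        z = np.sort(sample, axis=-1)
        z = (z - z.mean(axis=-1, keepdims=True)) / z.std(axis=-1, ddof=1,
                                                         keepdims=True)
        cdf = sst.norm.cdf(z)
        i = np.arange(1, n + 1)
        d_plus = (i / n - cdf).max(axis=-1)
        d_minus = (cdf - (i - 1) / n).max(axis=-1)
        return np.maximum(d_plus, d_minus)

    d_obs = float(lillie_stat(x))
    rng = np.random.default_rng(seed)
    null = lillie_stat(rng.standard_normal((n_sims, n)))
    p = (1.0 + np.sum(null >= d_obs)) / (n_sims + 1.0)
    return d_obs, float(p)


def _friedman_q(ranks: np.ndarray) -> float:
    """Uncorrected Friedman statistic from a matrix of within-row ranks."""
    n, k = ranks.shape
    rj = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * float(rj @ rj) - 3.0 * n * (k + 1)


# largest permutation count for which the exact Friedman p is enumerated
_EXACT_PERM_LIMIT = 500_000


def friedman(m: RmMatrix, p_method: str = "auto") -> StatReport:
    """Friedman rank test across conditions (mid-ranks, tie-corrected).

    The uncorrected statistic is ``Q = 12/(n k (k+1)) * sum_j R_j^2
    - 3 n (k+1)``; ties within a subject's row are mid-ranked and the
    statistic is divided by the standard tie-correction factor.  Fully tied
    data yield Q = 0, p = 1.

    The chi-square reference distribution (k-1 df) is a large-sample
    approximation that can miss the exact tail probability by > 0.1 for
    a handful of subjects, so for small tables (``k!**n`` within an
    enumeration budget) the p-value is computed exactly by enumerating all
    within-row rank permutations; ``p_method`` forces ``"chi2"`` or
    ``"exact"``.
    """
    if m.n < 2:
        raise ValueError("need at least 2 complete subjects")
    n, k = m.n, m.k
    ranks = np.apply_along_axis(sst.rankdata, 1, m.values)
    q = _friedman_q(ranks)

    ties = 0.0
    for row in m.values:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts ** 3 - counts))
    correction = 1.0 - ties / (n * k * (k * k - 1))
    if correction <= 0:
        return StatReport(test="friedman", statistic=0.0, df1=k - 1,
                          df2=None, p=1.0, posthoc=posthoc_t_bonferroni(m))
    q_corr = q / correction

    import math as _math
    n_perms = _math.factorial(k) ** n
    if p_method == "exact" or (p_method == "auto"
                               and n_perms <= _EXACT_PERM_LIMIT):
        from itertools import permutations, product

        # permute each subject's observed (mid-)ranks within the row; the
        # tie-correction factor is permutation-invariant, so comparing the
        # uncorrected statistic is equivalent
        row_perms = [np.array(list({p: None for p in
                                    permutations(row)}.keys()))
                     for row in ranks]
        hits = total = 0
        for combo in product(*row_perms):
            total += 1
            if _friedman_q(np.vstack(combo)) >= q - 1e-9:
                hits += 1
        p = hits / total
        method = "exact"
    else:
        p = float(sst.chi2.sf(q_corr, k - 1))
        method = "chi2"
    return StatReport(test=f"friedman[{method}]", statistic=q_corr,
                      df1=k - 1, df2=None, p=p,
                      posthoc=posthoc_t_bonferroni(m))


def gg_epsilon(values: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the condition covariance matrix."""
    k = values.shape[1]
    if k == 2:
        return 1.0
    s = np.cov(values, rowvar=False, ddof=1)
    h = np.eye(k) - np.ones((k, k)) / k
    c = h @ s @ h
    tr2 = float(np.trace(c @ c))
    if tr2 <= 0:
        raise ValueError(
            "singular condition covariance (too few subjects for the "
            f"epsilon estimate; its lower bound is 1/(k-1) = {1.0 / (k - 1):.4f})"
        )
    eps = float(np.trace(c)) ** 2 / ((k - 1) * tr2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(m: RmMatrix) -> StatReport:
    """One-way repeated-measures ANOVA with Greenhouse–Geisser correction.

    The F statistic is the usual within-subject one; its degrees of freedom
    ``(k-1, (k-1)(n-1))`` are multiplied by the epsilon estimated from the
    sample covariance of condition scores, compensating violations of
    sphericity.
    """
    if m.n < 2:
        raise ValueError("need at least 2 complete subjects")
    x = m.values
    n, k = m.n, m.k
    grand = x.mean()
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    resid = x - cond_means[None, :] - subj_means[:, None] + grand
    ss_err = float(np.sum(resid ** 2))
    df1, df2 = k - 1.0, (k - 1.0) * (n - 1.0)
    if ss_err == 0:
        raise ValueError("zero within-subject error variance")
    f_stat = (ss_cond / df1) / (ss_err / df2)
    eps = gg_epsilon(x)
    p = float(sst.f.sf(f_stat, eps * df1, eps * df2))
    # generalized eta squared is reported alongside, as a magnitude cue
    ss_subj = k * float(np.sum((subj_means - grand) ** 2))
    eta = ss_cond / (ss_cond + ss_subj + ss_err)
    return StatReport(test="rm_anova_gg", statistic=f_stat,
                      df1=eps * df1, df2=eps * df2, p=p, epsilon=eps,
                      posthoc=posthoc_t_bonferroni(m),
                      effect_sizes={"eta_squared_generalized": eta})


def posthoc_t_bonferroni(m: RmMatrix) -> pd.DataFrame:
    """Pairwise paired t-tests, Bonferroni-adjusted over all k(k-1)/2 pairs.

    Returns a symmetric matrix of adjusted p-values with unit diagonal.
    A zero-variance difference vector gives p = 0 when the mean difference
    is non-zero (with a warning) and p = 1 when it is zero.
    """
    k = m.k
    n_pairs = k * (k - 1) // 2
    out = pd.DataFrame(np.ones((k, k)), index=m.labels, columns=m.labels)
    for i, j in combinations(range(k), 2):
        diff = m.values[:, i] - m.values[:, j]
        if np.allclose(diff.std(ddof=1), 0.0):
            if abs(diff.mean()) > 0:
                warnings.warn(
                    f"zero-variance non-zero difference between "
                    f"{m.labels[i]!r} and {m.labels[j]!r}; p set to 0",
                    stacklevel=2,
                )
                p_raw = 0.0
            else:
                p_raw = 1.0
        else:
            p_raw = float(sst.ttest_rel(m.values[:, i], m.values[:, j]).pvalue)
        p_adj = min(1.0, n_pairs * p_raw)
        out.iloc[i, j] = out.iloc[j, i] = p_adj
    return out


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d between two independent groups, pooled SD with n-1 weights."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD")
    return float((a.mean() - b.mean()) / pooled)


def mixed_mediation(table: pd.DataFrame,
                    spec: MixedModelSpec) -> pd.DataFrame:
    """Moderation mixed model: response ~ condition * moderator + (1|subject).

    Fits a linear mixed model with a random intercept per subject and fixed
    effects for the within-subject condition value, the moderator, and
    their interaction; reports beta, t and p per term (t against residual
    degrees of freedom).  A singular random-effects fit falls back to an
    ordinary least-squares model with a warning.
    """
    for col in (spec.response, spec.condition, spec.moderator, spec.subject):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from table")
    med = table[spec.moderator].to_numpy(dtype=float)
    if np.allclose(med.std(), 0.0):
        raise ValueError(f"moderator {spec.moderator!r} is constant; "
                         "the interaction is not identifiable")
    counts = table.groupby(spec.subject).size()
    if (counts < 2).any():
        raise ValueError("need >= 2 observations per subject")

    y = table[spec.response].to_numpy(dtype=float)
    x1 = table[spec.condition].to_numpy(dtype=float)
    design = pd.DataFrame({
        "Intercept": np.ones(len(table)),
        spec.condition: x1,
        spec.moderator: med,
        f"{spec.condition}:{spec.moderator}": x1 * med,
    })

    import statsmodels.api as sm

    rows = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, design.to_numpy(), groups=table[spec.subject])
            fit = model.fit(reml=True, method="lbfgs")
        if np.isfinite(fit.params[: design.shape[1]]).all() and \
                np.isfinite(fit.bse[: design.shape[1]]).all() and \
                (fit.bse[: design.shape[1]] > 0).all():
            df_resid = len(table) - design.shape[1]
            beta = np.asarray(fit.params[: design.shape[1]])
            se = np.asarray(fit.bse[: design.shape[1]])
            tval = beta / se
            pval = 2 * sst.t.sf(np.abs(tval), df_resid)
            rows = (beta, tval, pval)
    except (np.linalg.LinAlgError, ValueError):
        rows = None
    if rows is None:
        warnings.warn("singular random-effects fit; falling back to a "
                      "fixed-effects (OLS) model", stacklevel=2)
        fit = sm.OLS(y, design.to_numpy()).fit()
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(fit.bse > 0, fit.params / fit.bse, np.inf)
        pval = 2 * sst.t.sf(np.abs(tval), fit.df_resid)
        rows = (np.asarray(fit.params), tval, pval)

    beta, tval, pval = rows
    return pd.DataFrame({
        "parameter": list(design.columns),
        "beta": beta, "t": tval, "p": pval,
    })


def analyze_study(features: pd.DataFrame, feature_cols: list[str],
                  labels: list[str] | None = None,
                  alpha_normality: float = 0.05,
                  ks_seed: int = 1234) -> dict[str, StatReport]:
    """Run the per-feature omnibus + post-hoc analysis of a study.

    For each feature a complete-case subjects x conditions matrix is built;
    every condition cell is screened with the KS normality check at
    ``alpha_normality``.  If any cell rejects, the Friedman test is used,
    otherwise the Greenhouse–Geisser-corrected repeated-measures ANOVA;
    post-hoc Bonferroni paired t-tests are attached either way.
    """
    if labels is not None and len(labels) < 2:
        raise ValueError("need at least 2 conditions to compare")
    reports: dict[str, StatReport] = {}
    for feat in feature_cols:
        m = RmMatrix.from_table(features, feat, labels=labels)
        normal = True
        for j in range(m.k):
            try:
                _, p = ks_normality(m.values[:, j], seed=ks_seed)
            except ValueError:
                normal = False
                break
            if p < alpha_normality:
                normal = False
                break
        report = rm_anova_gg(m) if normal else friedman(m)
        report.feature = feat
        reports[feat] = report
    return reports
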
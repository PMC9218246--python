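"""Cohort-level statistics and interobserver agreement.

Implements the statistical layer of the analysis: normality-gated
two-group comparisons (Shapiro-Wilk at alpha = 0.05 deciding between the
pooled-variance t-test and the Mann-Whitney U test), chi-squared /
Fisher comparisons of categorical variables, Pearson (optionally
Spearman) correlation of hemodynamic parameters with aortic growth rate,
conditional backward-stepwise logistic regression over the univariately
significant predictors, post-hoc power of the two-sample t-test via the
noncentral t distribution, and the interobserver agreement suite
(ICC(2,1), Bland-Altman, Sorensen-Dice with bootstrap confidence
intervals).

The cohort table is a pandas DataFrame with one row per subject; group
labels are binary columns and missing values are permitted (dropped
pairwise per comparison). No multiple-testing correction is applied;
alpha = 0.05 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
LOGISTIC_REMOVAL_P = 0.10
MANN_WHITNEY_EXACT_MAX_N = 20


class InsufficientDataError(ValueError):
    pass


@dataclass
class GroupComparison:
    variable: str
    test: str  # "t" | "mann-whitney"
    group_summaries: dict
    p_value: float
    normality_p: dict
    statistic: float = float("nan")


@dataclass
class CategoricalComparison:
    variable: str
    method: str  # "chi-squared" | "fisher"
    statistic: float
    p_value: float
    flags: list[str] = field(default_factory=list)


@dataclass
class LogisticModelReport:
    retained: list[str]
    wald_p: dict
    coefficients: dict
    odds_ratios: dict
    removal_trace: list[tuple[str, float]]
    converged: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class AgreementReport:
    icc: dict  # per parameter: {"icc": ..., "p": ...}
    bland_altman: dict  # per parameter: {"bias": ..., "loa_low": ..., "loa_high": ...}
    dice: dict  # per lumen: {"dice": ..., "ci_low": ..., "ci_high": ...}


def _two_groups(table: pd.DataFrame, variable: str, grouping: str):
    sub = table[[variable, grouping]].dropna()
    levels = sorted(x.item() if hasattr(x, "item") else x for x in sub[grouping].unique())
    if len(levels) != 2:
        raise ValueError(f"grouping {grouping!r} must have exactly 2 levels, got {levels}")
    a = sub.loc[sub[grouping] == levels[0], variable].to_numpy(dtype=float)
    b = sub.loc[sub[grouping] == levels[1], variable].to_numpy(dtype=float)
    return levels, a, b


def compare_groups(
    table: pd.DataFrame, variable: str, grouping: str, force: str | None = None
) -> GroupComparison:
    """Shapiro-Wilk-gated two-group comparison.

    Both groups normal at alpha = 0.05 -> two-sided pooled-variance
    t-test, summarized as mean +/- sd; otherwise Mann-Whitney U (exact
    for small samples without ties, normal approximation with tie
    correction otherwise), summarized as median [min, max]. ``force``
    ("t" or "mann-whitney") bypasses the normality gate.
    """
    levels, a, b = _two_groups(table, variable, grouping)
    if min(len(a), len(b)) < 3:
        raise InsufficientDataError(
            f"{variable}: need >= 3 subjects per group, got {len(a)}/{len(b)}"
        )
    sw = {}
    for level, x in zip(levels, (a, b)):
        if np.ptp(x) == 0:  # Shapiro-Wilk undefined for constant data
            sw[level] = 0.0
        else:
            sw[level] = float(stats.shapiro(x).pvalue)
    normal = all(p > ALPHA for p in sw.values())
    if force is not None:
        normal = force == "t"
    if normal:
        res = stats.ttest_ind(a, b, equal_var=True)
        test = "t"
        summaries = {
            level: {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)), "n": len(x)}
            for level, x in zip(levels, (a, b))
        }
    else:
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = (
            "exact"
            if (max(len(a), len(b)) <= MANN_WHITNEY_EXACT_MAX_N and not has_ties)
            else "asymptotic"
        )
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test = "mann-whitney"
        summaries = {
            level: {
                "median": float(np.median(x)),
                "min": float(np.min(x)),
                "max": float(np.max(x)),
                "n": len(x),
            }
            for level, x in zip(levels, (a, b))
        }
    return GroupComparison(
        variable=variable,
        test=test,
        group_summaries=summaries,
        p_value=float(res.pvalue),
        normality_p=sw,
        statistic=float(res.statistic),
    )


def compare_categorical(
    table: pd.DataFrame, variable: str, grouping: str
) -> CategoricalComparison:
    """Chi-squared (no continuity correction); Fisher exact if sparse 2x2."""
    sub = table[[variable, grouping]].dropna()
    ct = pd.crosstab(sub[grouping], sub[variable]).to_numpy()
    if ct.shape[0] < 2 or ct.shape[1] < 2 or (ct.sum(axis=0) == 0).any() or (
        ct.sum(axis=1) == 0
    ).any():
        raise ValueError("degenerate contingency table")
    chi2, p, _, expected = stats.chi2_contingency(ct, correction=False)
    flags = []
    if (expected < 5).any():
        flags.append("expected cell < 5")
        if ct.shape == (2, 2):
            odds, p = stats.fisher_exact(ct)
            return CategoricalComparison(
                variable=variable, method="fisher", statistic=float(odds), p_value=float(p),
                flags=flags,
            )
        flags.append("table larger than 2x2; chi-squared retained")
    return CategoricalComparison(
        variable=variable, method="chi-squared", statistic=float(chi2), p_value=float(p),
        flags=flags,
    )


def correlate_with_growth(
    table: pd.DataFrame,
    variable: str,
    growth_column: str = "growth_rate_mm_per_year",
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation of a parameter with growth rate (Pearson by default)."""
    sub = table[[variable, growth_column]].dropna()
    if len(sub) < 4:
        raise InsufficientDataError("need >= 4 paired observations")
    x = sub[variable].to_numpy(dtype=float)
    y = sub[growth_column].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def univariate_screen(
    table: pd.DataFrame, outcome: str, variables: list[str], alpha: float = ALPHA
) -> list[str]:
    """Variables whose two-group comparison against the outcome has p < alpha."""
    selected = []
    for var in variables:
        try:
            if compare_groups(table, var, outcome).p_value < alpha:
                selected.append(var)
        except (InsufficientDataError, ValueError):
            continue
    return selected


def backward_logistic(
    table: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    removal_p: float = LOGISTIC_REMOVAL_P,
) -> LogisticModelReport:
    """Backward-stepwise logistic regression with likelihood-ratio removal.

    Fits the full maximum-likelihood logistic model on the candidates and
    iteratively removes the variable with the largest likelihood-ratio
    p-value until every remaining variable has LR p below ``removal_p``
    (ties broken by larger p then column order). Wald p-values are
    reported for the retained set. Quasi-separation and non-convergence
    are flagged rather than raised.
    """
    import statsmodels.api as sm

    sub = table[[outcome, *candidates]].dropna()
    y = sub[outcome].to_numpy(dtype=float)
    flags: list[str] = []
    n_events = int(y.sum())
    if candidates and n_events < len(candidates):
        flags.append(f"only {n_events} events for {len(candidates)} candidates")

    def fit(cols):
        X = sm.add_constant(sub[cols].to_numpy(dtype=float)) if cols else np.ones((len(sub), 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, X)
            try:
                res = model.fit(disp=0, maxiter=200)
            except Exception:
                res = model.fit(disp=0, maxiter=200, method="bfgs")
        return res

    current = list(candidates)
    trace: list[tuple[str, float]] = []
    converged = True
    while current:
        full = fit(current)
        converged = bool(getattr(full, "mle_retvals", {}).get("converged", True))
        lr_p = {}
        for var in current:
            reduced = fit([c for c in current if c != var])
            lr = 2.0 * (full.llf - reduced.llf)
            lr_p[var] = float(stats.chi2.sf(max(lr, 0.0), df=1))
        worst = max(current, key=lambda v: lr_p[v])  # first-seen wins ties (column order)
        if lr_p[worst] >= removal_p:
            trace.append((worst, lr_p[worst]))
            current.remove(worst)
        else:
            break

    if current:
        final = fit(current)
        if not bool(getattr(final, "mle_retvals", {}).get("converged", True)):
            flags.append("final model did not converge (possible separation)")
        params = final.params[1:]
        wald_p = {v: float(p) for v, p in zip(current, final.pvalues[1:])}
        coefficients = {v: float(b) for v, b in zip(current, params)}
        # clip to avoid overflow under separation (flagged above)
        odds_ratios = {v: float(np.exp(min(b, 700.0))) for v, b in zip(current, params)}
    else:
        wald_p, coefficients, odds_ratios = {}, {}, {}
    return LogisticModelReport(
        retained=current,
        wald_p=wald_p,
        coefficients=coefficients,
        odds_ratios=odds_ratios,
        removal_trace=trace,
        converged=converged,
        flags=flags,
    )


def posthoc_power_ttest(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    alpha: float = ALPHA,
) -> float:
    """Post-hoc power of the two-sided two-sample pooled-variance t-test.

    Effect size d = |mean1 - mean2| / s_pooled, noncentrality
    delta = d * sqrt(n1*n2 / (n1+n2)); power is the probability that |T'|
    exceeds the two-sided critical value under the noncentral t with
    n1 + n2 - 2 degrees of freedom.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    s_pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    d = abs(mean1 - mean2) / s_pooled
    delta = d * np.sqrt(n1 * n2 / (n1 + n2))
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    power = stats.nct.sf(t_crit, df, delta) + stats.nct.cdf(-t_crit, df, delta)
    return float(power)


def icc_two_way(
    data: np.ndarray, form: str = "ICC(2,1)"
) -> tuple[float, float]:
    """Intraclass correlation from an (n subjects x k raters) matrix.

    ICC(2,1): two-way random effects, absolute agreement, single
    measurement. ICC(3,1): two-way mixed, consistency. Returns (icc, p)
    with p from the F-test of between-subject variance against residual.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_rater = n * ((rater_means - grand) ** 2).sum()
    resid = data - subj_means[:, None] - rater_means[None, :] + grand
    ss_err = (resid**2).sum()
    msr = ss_subj / (n - 1)
    msc = ss_rater / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "ICC(2,1)":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "ICC(3,1)":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unsupported ICC form {form!r}")
    icc = 1.0 if denom == 0 and msr > 0 else ((msr - mse) / denom if denom > 0 else np.nan)
    if mse == 0:
        p = 0.0 if msr > 0 else np.nan
    else:
        p = float(stats.f.sf(msr / mse, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


def bland_altman(x1: np.ndarray, x2: np.ndarray) -> dict:
    """Bias (mean difference) and 95% limits of agreement."""
    d = np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float)
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return {"bias": bias, "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd, "sd": sd}


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Sorensen-Dice overlap, 2|A&B| / (|A| + |B|)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return float("nan")
    return 2.0 * int((a & b).sum()) / denom


def interobserver_suite(
    observer1: pd.DataFrame,
    observer2: pd.DataFrame,
    masks1: dict[str, list[np.ndarray]] | None = None,
    masks2: dict[str, list[np.ndarray]] | None = None,
    icc_form: str = "ICC(2,1)",
    n_boot: int = 1000,
    seed: int = 0,
) -> AgreementReport:
    """Agreement between two observers on the same subjects.

    ``observer1`` / ``observer2`` are per-subject parameter tables with
    identical columns and row order; ``masks1`` / ``masks2`` optionally
    map lumen name -> list of per-subject binary masks. Dice confidence
    intervals are percentile bootstrap over subjects.
    """
    if len(observer1) != len(observer2):
        raise ValueError("observer tables must have equal length")
    icc_out, ba_out = {}, {}
    for col in observer1.columns:
        x1 = observer1[col].to_numpy(dtype=float)
        x2 = observer2[col].to_numpy(dtype=float)
        icc, p = icc_two_way(np.column_stack([x1, x2]), form=icc_form)
        icc_out[col] = {"icc": icc, "p": p}
        ba_out[col] = bland_altman(x1, x2)

    dice_out: dict = {}
    if masks1 is not None and masks2 is not None:
        rng = np.random.default_rng(seed)
        for lumen in masks1:
            per_subject = np.array(
                [dice_coefficient(a, b) for a, b in zip(masks1[lumen], masks2[lumen])]
            )
            n = len(per_subject)
            if n > 1:
                boot = np.empty(n_boot)
                for i in range(n_boot):
                    boot[i] = per_subject[rng.integers(0, n, n)].mean()
                ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
            else:
                ci_low = ci_high = per_subject.mean()
            dice_out[lumen] = {
                "dice": float(per_subject.mean()),
                "ci_low": float(ci_low),
                "ci_high": float(ci_high),
            }
    return AgreementReport(icc=icc_out, bland_altman=ba_out, dice=dice_out)
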
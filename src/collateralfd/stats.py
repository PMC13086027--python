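"""Cohort-level statistical evaluation of the mFD biomarker.

Implements the evaluation battery applied to the stroke cohort: group
comparisons (Welch/Student t, Mann-Whitney U, chi-square, Fisher exact),
Spearman rank correlation, the Wilcoxon signed-rank test for paired
visual scores, ROC analysis with a DeLong-variance confidence interval
and Youden-index cutoff, the DeLong test for paired AUCs, and
crude/adjusted logistic regression with Hosmer-Lemeshow calibration and
AIC.

Standard univariate tests are delegated to :mod:`scipy.stats` and the
logistic maximum-likelihood fit to :mod:`statsmodels`; the ROC/DeLong
machinery, Youden selection, the signed-rank normal approximation with
tie correction, and the Hosmer-Lemeshow statistic are implemented here.
No multiple-comparison correction is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "StatTestResult",
    "ROCCurve",
    "LogisticFit",
    "roc_analysis",
    "delong_paired_test",
    "fit_logistic",
    "spearman_correlation",
    "wilcoxon_signed_rank",
    "group_compare",
    "hosmer_lemeshow",
    "reproduce_paper_tables",
    "render_report_markdown",
]


@dataclass(frozen=True)
class StatTestResult:
    """One hypothesis-test outcome (statistic, p, n, method notes)."""

    statistic_name: str  # one of: t, U, Z, chi2, rho, fisher_or
    value: float
    p_value: float
    n: int
    notes: dict = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC with DeLong-variance CI and the Youden operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    auc_ci_95: tuple[float, float]
    p_value: float  # vs the chance AUC of 0.5
    youden_threshold: float
    youden_j: float
    youden_sensitivity: float
    youden_specificity: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class LogisticFit:
    """Logistic-regression fit: ORs with Wald CIs, AIC, HL calibration."""

    predictors: tuple[str, ...]
    coefficients: dict
    std_errors: dict
    odds_ratios: dict
    or_ci_95: dict
    p_values: dict
    aic: float
    log_likelihood: float
    hosmer_lemeshow: tuple[float, int, float] | None
    converged: bool
    n: int
    flags: tuple[str, ...] = ()


# --------------------------------------------------------------------------
# ROC / AUC / DeLong


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative), and AUC.

    V10_i = P(score_neg < s_i) + 0.5 P(score_neg = s_i) estimated
    empirically; AUC = mean(V10) = 1 - mean(V01).  Computed with
    midranks, O(n log n).
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = v10.mean()
    return v10, v01, float(auc)


def _as_binary_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype == bool:
        lab = lab.astype(int)
    lab = lab.astype(int)
    uniq = set(np.unique(lab).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(uniq)}")
    if uniq != {0, 1}:
        raise ValueError("both classes must be present")
    return lab


def roc_analysis(scores, labels) -> ROCCurve:
    """Empirical ROC for a higher-is-positive score.

    A case is called positive when its score is strictly above the
    threshold, matching the strict-``>`` semantics of the mFD cutoff.
    AUC equals the Mann-Whitney concordance (ties counted half); its
    standard error is the single-curve DeLong variance, the 95% CI a
    normal interval truncated to [0, 1], and the p-value tests
    AUC = 0.5.  The Youden point maximises J = sens + spec - 1; ties are
    broken toward the higher (more specific) threshold.
    """
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    lab = _as_binary_labels(labels)
    if len(s) != len(lab):
        raise ValueError("scores and labels length mismatch")

    thresholds = np.unique(s)  # candidate cuts; rule is score > t
    sens = np.array([(s[lab == 1] > t).mean() for t in thresholds])
    spec = np.array([(s[lab == 0] <= t).mean() for t in thresholds])

    v10, v01, auc = _delong_placements(s, lab)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = float(np.sqrt(var))
    z975 = sps.norm.ppf(0.975)
    ci = (max(0.0, auc - z975 * se), min(1.0, auc + z975 * se))
    if se > 0:
        z = (auc - 0.5) / se
        p = 2.0 * sps.norm.sf(abs(z))
    else:
        p = 1.0 if auc == 0.5 else 0.0

    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())[-1]  # thresholds ascending: last = highest
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_se=se,
        auc_ci_95=ci,
        p_value=float(p),
        youden_threshold=float(thresholds[best]),
        youden_j=float(j[best]),
        youden_sensitivity=float(sens[best]),
        youden_specificity=float(spec[best]),
        n_pos=m,
        n_neg=n,
    )


def delong_paired_test(scores_a, scores_b, labels) -> StatTestResult:
    """DeLong test for two correlated AUCs measured on the same cases.

    Uses the placement-value covariance of the paired scores to get the
    variance of the AUC difference; reports a two-sided normal p.  A
    zero-variance difference (e.g. identical score vectors) is returned
    as a degenerate result with p = 1 rather than an error.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    lab = _as_binary_labels(labels)
    if not (len(a) == len(b) == len(lab)):
        raise ValueError("paired scores and labels must have equal length")

    v10a, v01a, auc_a = _delong_placements(a, lab)
    v10b, v01b, auc_b = _delong_placements(b, lab)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    notes = {"auc_a": auc_a, "auc_b": auc_b, "auc_difference": diff}
    if var_diff <= 0:
        return StatTestResult(
            statistic_name="Z", value=0.0, p_value=1.0, n=m + n,
            notes={**notes, "reason": "zero variance of AUC difference"},
            degenerate=True,
        )
    z = diff / np.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return StatTestResult(statistic_name="Z", value=float(z), p_value=float(p), n=m + n, notes=notes)


# --------------------------------------------------------------------------
# Logistic regression


def hosmer_lemeshow(y, p_hat, n_groups: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow calibration chi-square over risk deciles.

    Cases are binned by deciles of predicted probability; the statistic
    sums (O - E)^2 / (E (1 - E/n_g)) over bins, df = n_groups - 2.
    """
    y = np.asarray(y, dtype=float)
    p_hat = np.asarray(p_hat, dtype=float)
    order = np.argsort(p_hat, kind="stable")
    y, p_hat = y[order], p_hat[order]
    bins = np.array_split(np.arange(len(y)), n_groups)
    chi2 = 0.0
    used = 0
    for idx in bins:
        if len(idx) == 0:
            continue
        obs = y[idx].sum()
        exp = p_hat[idx].sum()
        ng = len(idx)
        denom = exp * (1.0 - exp / ng)
        if denom > 0:
            chi2 += (obs - exp) ** 2 / denom
            used += 1
    df = max(used - 2, 1)
    p = float(sps.chi2.sf(chi2, df))
    return float(chi2), df, p


def fit_logistic(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    hl_groups: int = 10,
) -> LogisticFit:
    """Maximum-likelihood logistic fit with Wald ORs and fit diagnostics.

    Fit via iteratively reweighted least squares (GLM/binomial,
    tolerance 1e-8, max 100 iterations).  Complete separation or
    non-convergence is flagged in the result instead of silently
    reporting unstable estimates.
    """
    if not predictors:
        raise ValueError("need at least one predictor")
    missing = [c for c in [outcome, *predictors] if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = table[[outcome, *predictors]].dropna()
    y = _as_binary_labels(df[outcome].values)
    n = len(df)
    if n <= len(predictors) + 1:
        raise ValueError(f"n = {n} too small for {len(predictors)} predictors")

    X = df[predictors].copy()
    for col in X.columns:  # map binary categoricals (e.g. sex) to 0/1
        if X[col].dtype == object or str(X[col].dtype) == "category":
            levels = sorted(X[col].astype(str).unique())
            if len(levels) != 2:
                raise ValueError(f"non-binary categorical predictor {col!r}: {levels}")
            X[col] = (X[col].astype(str) == levels[1]).astype(float)
    X = X.astype(float)
    X = sm.add_constant(X, has_constant="add")

    flags = []
    model = sm.GLM(y, X, family=sm.families.Binomial())
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            res = model.fit(maxiter=100, tol=1e-8)
            for w in caught:
                msg = str(w.message).lower()
                if "separation" in msg or "convergence" in msg or "divide" in msg:
                    flags.append(str(w.message))
    except PerfectSeparationError as exc:
        nan_map = {k: float("nan") for k in ["const", *predictors]}
        return LogisticFit(
            predictors=tuple(predictors),
            coefficients=nan_map,
            std_errors=dict(nan_map),
            odds_ratios={k: float("nan") for k in predictors},
            or_ci_95={k: (float("nan"), float("nan")) for k in predictors},
            p_values=dict(nan_map),
            aic=float("nan"),
            log_likelihood=float("nan"),
            hosmer_lemeshow=None,
            converged=False,
            n=n,
            flags=(f"complete separation: {exc}",),
        )
    converged = bool(getattr(res, "converged", True)) and not flags
    p_hat = np.asarray(res.predict(X))
    if np.any(np.abs(res.params[1:]) > 15):
        flags.append("extreme coefficients suggest (quasi-)separation")
        converged = False

    names = list(X.columns)
    coeffs = dict(zip(names, map(float, res.params)))
    ses = dict(zip(names, map(float, res.bse)))
    z975 = sps.norm.ppf(0.975)
    with np.errstate(over="ignore"):  # inf CI bound on a separated fit is meaningful
        ors = {k: float(np.exp(v)) for k, v in coeffs.items() if k != "const"}
        cis = {
            k: (
                float(np.exp(coeffs[k] - z975 * ses[k])),
                float(np.exp(coeffs[k] + z975 * ses[k])),
            )
            for k in ors
        }
    pvals = dict(zip(names, map(float, res.pvalues)))
    hl = hosmer_lemeshow(y, p_hat, hl_groups) if n >= 2 * hl_groups else None
    llf = float(res.llf)
    return LogisticFit(
        predictors=tuple(predictors),
        coefficients=coeffs,
        std_errors=ses,
        odds_ratios=ors,
        or_ci_95=cis,
        p_values=pvals,
        aic=float(2 * len(names) - 2 * llf),
        log_likelihood=llf,
        hosmer_lemeshow=hl,
        converged=converged,
        n=n,
        flags=tuple(flags),
    )


# --------------------------------------------------------------------------
# Rank statistics and group comparisons


def spearman_correlation(x, y) -> StatTestResult:
    """Spearman rho with average ranks for ties; p by t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return StatTestResult(statistic_name="rho", value=float(rho), p_value=float(p), n=len(x))


def wilcoxon_signed_rank(
    paired_a, paired_b, continuity_correction: bool = False
) -> StatTestResult:
    """Wilcoxon signed-rank test on paired samples, normal approximation.

    Zero differences are dropped (Wilcoxon's original treatment);
    absolute differences get average ranks; the variance carries the
    tie correction sum(t^3 - t)/48.  Z is signed by (a - b): a
    predominance of negative differences gives negative Z.  Continuity
    correction is off by default (toggle for the alternative
    convention); p is two-sided.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("samples must be paired")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        raise ValueError("degenerate signed-rank variance")
    num = w_plus - mu
    if continuity_correction and num != 0:
        num -= 0.5 * np.sign(num)
    z = num / np.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    return StatTestResult(
        statistic_name="Z",
        value=float(z),
        p_value=float(min(p, 1.0)),
        n=n,
        notes={
            "w_plus": w_plus,
            "n_zero_dropped": int(len(a) - n),
            "tie_correction": tie_term,
            "continuity_correction": continuity_correction,
        },
    )


def _fisher_exact_2x2(table_2x2: np.ndarray) -> StatTestResult:
    odds, p = sps.fisher_exact(table_2x2, alternative="two-sided")
    return StatTestResult(
        statistic_name="fisher_or",
        value=float(odds) if np.isfinite(odds) else float("inf"),
        p_value=float(p),
        n=int(table_2x2.sum()),
        notes={"table": table_2x2.tolist()},
    )


def group_compare(
    table: pd.DataFrame,
    variable: str,
    group: str,
    kind: str | None = None,
    rank_based: bool = False,
) -> StatTestResult:
    """Two-group comparison with standard test dispatch.

    Continuous variables: Welch t-test by default, Mann-Whitney U with
    ``rank_based=True``.  Categorical variables: chi-square, switching
    to Fisher's exact test when any expected cell count is below 5.
    ``kind`` may force ``"continuous"`` or ``"categorical"``; by default
    numeric columns with > 2 distinct values are treated as continuous.
    """
    for col in (variable, group):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    df = table[[variable, group]].dropna()
    levels = df[group].unique()
    if len(levels) != 2:
        raise ValueError(f"group column must have exactly 2 levels, got {len(levels)}")
    g0 = df.loc[df[group] == levels[0], variable]
    g1 = df.loc[df[group] == levels[1], variable]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both groups must be non-empty")

    if kind is None:
        numeric = pd.api.types.is_numeric_dtype(df[variable])
        kind = "continuous" if numeric and df[variable].nunique() > 2 else "categorical"

    if kind == "continuous":
        if rank_based:
            u, p = sps.mannwhitneyu(g0, g1, alternative="two-sided")
            return StatTestResult(
                statistic_name="U", value=float(u), p_value=float(p), n=len(df),
                notes={"groups": list(map(str, levels))},
            )
        if np.ptp(df[variable].values) == 0:
            return StatTestResult(
                statistic_name="t", value=0.0, p_value=1.0, n=len(df),
                notes={"reason": "identical groups"}, degenerate=True,
            )
        t, p = sps.ttest_ind(g0, g1, equal_var=False)
        if np.isnan(p):  # zero within-group variance with equal means
            t, p = 0.0, 1.0
        return StatTestResult(
            statistic_name="t", value=float(t), p_value=float(p), n=len(df),
            notes={"welch": True, "groups": list(map(str, levels))},
        )

    ct = pd.crosstab(df[variable], df[group]).values
    if ct.shape[0] < 2:
        return StatTestResult(
            statistic_name="chi2", value=0.0, p_value=1.0, n=len(df),
            notes={"reason": "variable constant within cohort"}, degenerate=True,
        )
    expected = sps.contingency.expected_freq(ct)
    if ct.shape == (2, 2) and (expected < 5).any():
        return _fisher_exact_2x2(ct)
    chi2, p, dof, _ = sps.chi2_contingency(ct, correction=False)
    return StatTestResult(
        statistic_name="chi2", value=float(chi2), p_value=float(p), n=len(df),
        notes={"df": int(dof)},
    )


# --------------------------------------------------------------------------
# Cohort report

REQUIRED_COHORT_COLUMNS = ("mfd", "vcs_scta", "vcs_mcta", "age", "sex", "pre_nihss", "mrs_90")
ADJUSTMENT_COVARIATES = ("age", "sex", "pre_nihss", "ldl")


def reproduce_paper_tables(table: pd.DataFrame, threshold: float = 0.9307) -> dict:
    """Full cohort evaluation report (the Table-1/Table-2 surface).

    Emits group summaries with comparison p-values for the imaging
    biomarkers and covariates, the mFD/vCS-mCTA rank statistics, ROC
    analyses with Youden operating points, the DeLong paired-AUC
    comparison, crude logistic odds ratios for dichotomized mFD and for
    vCS-mCTA, and — when the adjustment covariates (age, sex,
    pre-NIHSS, LDL) are all present — the adjusted models with AIC and
    Hosmer-Lemeshow calibration.  Adjusted models are labelled with the
    covariates actually used and are never silently downgraded.
    """
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    df = table.copy()
    if "outcome" not in df.columns:
        df["outcome"] = (df["mrs_90"] <= 2).astype(int)

    report: dict = {"n": int(len(df))}
    fav = df[df["outcome"] == 1]
    unf = df[df["outcome"] == 0]
    report["n_favorable"] = int(len(fav))
    report["n_unfavorable"] = int(len(unf))

    def _summary(col):
        return {
            "all_mean": float(df[col].mean()),
            "all_sd": float(df[col].std(ddof=1)),
            "favorable_mean": float(fav[col].mean()),
            "favorable_sd": float(fav[col].std(ddof=1)),
            "unfavorable_mean": float(unf[col].mean()),
            "unfavorable_sd": float(unf[col].std(ddof=1)),
        }

    groups: dict = {}
    continuous_vars = [
        c for c in ("age", "pre_nihss", "mfd", "vcs_scta", "vcs_mcta", "ldl")
        if c in df.columns
    ]
    for col in continuous_vars:
        t_res = group_compare(df, col, "outcome")
        u_res = group_compare(df, col, "outcome", rank_based=True)
        groups[col] = {
            **_summary(col),
            "p_value": t_res.p_value,
            "p_value_rank": u_res.p_value,
            "test": t_res.statistic_name,
        }
    for col in ("sex", "dyslipidemia", "hypertension"):
        if col in df.columns:
            res = group_compare(df, col, "outcome", kind="categorical")
            groups[col] = {"p_value": res.p_value, "test": res.statistic_name}
    report["group_comparisons"] = groups

    sp = spearman_correlation(df["mfd"], df["vcs_mcta"])
    report["spearman_mfd_vcs_mcta"] = {"rho": sp.value, "p_value": sp.p_value}
    wc = wilcoxon_signed_rank(df["vcs_scta"], df["vcs_mcta"])
    report["wilcoxon_scta_vs_mcta"] = {
        "z": wc.value, "p_value": wc.p_value, "n_nonzero": wc.n,
    }

    roc_mfd = roc_analysis(df["mfd"], df["outcome"])
    roc_mcta = roc_analysis(df["vcs_mcta"], df["outcome"])
    roc_scta = roc_analysis(df["vcs_scta"], df["outcome"])

    def _roc_dict(r: ROCCurve) -> dict:
        return {
            "auc": r.auc,
            "auc_ci_95": list(r.auc_ci_95),
            "p_value": r.p_value,
            "youden_threshold": r.youden_threshold,
            "youden_j": r.youden_j,
            "sensitivity_pct": 100.0 * r.youden_sensitivity,
            "specificity_pct": 100.0 * r.youden_specificity,
        }

    report["roc"] = {
        "mfd": _roc_dict(roc_mfd),
        "vcs_mcta": _roc_dict(roc_mcta),
        "vcs_scta": _roc_dict(roc_scta),
    }
    dl = delong_paired_test(df["mfd"], df["vcs_mcta"], df["outcome"])
    report["delong_mfd_vs_vcs_mcta"] = {
        "z": dl.value, "p_value": dl.p_value, **dl.notes,
    }

    df["mfd_above_threshold"] = (df["mfd"] > threshold).astype(int)
    report["mfd_threshold"] = threshold

    def _fit_dict(fit: LogisticFit, key: str) -> dict:
        return {
            "or": fit.odds_ratios.get(key),
            "or_ci_95": list(fit.or_ci_95.get(key, ())),
            "p_value": fit.p_values.get(key),
            "aic": fit.aic,
            "hosmer_lemeshow": list(fit.hosmer_lemeshow) if fit.hosmer_lemeshow else None,
            "converged": fit.converged,
            "predictors": list(fit.predictors),
            "all_or": fit.odds_ratios,
            "all_p": fit.p_values,
        }

    crude_mfd = fit_logistic(df, "outcome", ["mfd_above_threshold"])
    crude_mcta = fit_logistic(df, "outcome", ["vcs_mcta"])
    report["crude_models"] = {
        "mfd_above_threshold": _fit_dict(crude_mfd, "mfd_above_threshold"),
        "vcs_mcta": _fit_dict(crude_mcta, "vcs_mcta"),
    }

    available = [c for c in ADJUSTMENT_COVARIATES if c in df.columns]
    if set(available) == set(ADJUSTMENT_COVARIATES):
        adj1 = fit_logistic(df, "outcome", ["mfd_above_threshold", *available])
        adj2 = fit_logistic(df, "outcome", ["vcs_mcta", *available])
        report["adjusted_models"] = {
            "covariates": available,
            "model1_mfd": _fit_dict(adj1, "mfd_above_threshold"),
            "model2_vcs_mcta": _fit_dict(adj2, "vcs_mcta"),
        }
    else:
        report["adjusted_models"] = {
            "skipped": True,
            "reason": f"adjustment covariates missing: "
                      f"{sorted(set(ADJUSTMENT_COVARIATES) - set(available))}",
        }

    labels = None
    try:
        from .scoring import quartile_stratify

        labels = quartile_stratify(df["mfd"])
    except ValueError:
        pass
    if labels is not None:
        counts = pd.Series(labels).value_counts().to_dict()
        report["mfd_quartiles"] = {q: int(counts.get(q, 0)) for q in ("Q1", "Q2", "Q3", "Q4")}
    return report


def render_report_markdown(report: dict) -> str:
    """Human-readable Markdown rendering of a cohort report."""
    lines = [
        "# Cohort evaluation report",
        "",
        f"N = {report['n']} (favorable {report['n_favorable']}, "
        f"unfavorable {report['n_unfavorable']})",
        "",
        "## Group comparisons (favorable vs unfavorable)",
        "",
        "| Variable | All | Favorable | Unfavorable | p |",
        "|---|---|---|---|---|",
    ]
    for var, row in report["group_comparisons"].items():
        if "all_mean" in row:
            lines.append(
                f"| {var} | {row['all_mean']:.3f} ± {row['all_sd']:.3f} "
                f"| {row['favorable_mean']:.3f} ± {row['favorable_sd']:.3f} "
                f"| {row['unfavorable_mean']:.3f} ± {row['unfavorable_sd']:.3f} "
                f"| {row['p_value']:.3g} |"
            )
        else:
            lines.append(f"| {var} | – | – | – | {row['p_value']:.3g} |")
    sp = report["spearman_mfd_vcs_mcta"]
    wc = report["wilcoxon_scta_vs_mcta"]
    lines += [
        "",
        f"Spearman rho(mFD, vCS-mCTA) = {sp['rho']:.3f} (p = {sp['p_value']:.3g})",
        f"Wilcoxon signed-rank vCS-sCTA vs vCS-mCTA: Z = {wc['z']:.3f} "
        f"(p = {wc['p_value']:.3g})",
        "",
        "## ROC analysis",
        "",
        "| Score | AUC (95% CI) | p | Youden cutoff | Sens % | Spec % |",
        "|---|---|---|---|---|---|",
    ]
    for name, r in report["roc"].items():
        lo, hi = r["auc_ci_95"]
        lines.append(
            f"| {name} | {r['auc']:.2f} ({lo:.2f}–{hi:.2f}) | {r['p_value']:.3g} "
            f"| {r['youden_threshold']:.4f} | {r['sensitivity_pct']:.1f} "
            f"| {r['specificity_pct']:.1f} |"
        )
    dl = report["delong_mfd_vs_vcs_mcta"]
    lines += [
        "",
        f"DeLong paired test mFD vs vCS-mCTA: Z = {dl['z']:.3f}, p = {dl['p_value']:.3g}",
        "",
        "## Logistic models",
        "",
    ]
    for name, fit in report["crude_models"].items():
        lo, hi = fit["or_ci_95"]
        lines.append(
            f"- Crude {name}: OR = {fit['or']:.2f} ({lo:.2f}–{hi:.2f}), "
            f"p = {fit['p_value']:.3g}"
        )
    adj = report["adjusted_models"]
    if adj.get("skipped"):
        lines.append(f"- Adjusted models skipped: {adj['reason']}")
    else:
        for key in ("model1_mfd", "model2_vcs_mcta"):
            fit = adj[key]
            lo, hi = fit["or_ci_95"]
            hl = fit["hosmer_lemeshow"]
            hl_txt = f", HL chi2 = {hl[0]:.2f} (df {hl[1]}, p {hl[2]:.3g})" if hl else ""
            lines.append(
                f"- Adjusted {key} (covariates: {', '.join(adj['covariates'])}): "
                f"OR = {fit['or']:.2f} ({lo:.2f}–{hi:.2f}), p = {fit['p_value']:.3g}, "
                f"AIC = {fit['aic']:.2f}{hl_txt}"
            )
    if "mfd_quartiles" in report:
        q = report["mfd_quartiles"]
        lines += ["", "mFD quartile counts: " + ", ".join(f"{k} = {v}" for k, v in q.items())]
    return "\n".join(lines) + "\n"
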
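"""Cohort heterogeneity assessment.

Two layers, mirroring standard multi-center practice: univariate
comparisons of clinical variables (rank-sum test for continuous,
chi-square for categorical, deliberately uncorrected for multiple
testing), and the pairwise cohort-differences (CD) model — a logistic
regression predicting cohort membership from the model covariates. A CD
AUC near 0.5 means external validation tests reproducibility; a high AUC
means it tests transferability to a genuinely different population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

# ---------------------------------------------------------------------------
# ROC / AUC with Mann-Whitney confidence interval
# ---------------------------------------------------------------------------


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by concordant-pair counting (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum())
                 / (len(pos) * len(neg)))


def auc_ci(auc: float, n_pos: int, n_neg: int,
           level: float = 0.95) -> tuple[float, float]:
    """Hanley-McNeil normal-approximation CI for the AUC."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """(FPR, TPR) at every distinct threshold, descending."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    labels = np.asarray(labels)[order]
    tps = np.cumsum(labels == 1)
    fps = np.cumsum(labels == 0)
    tpr = np.concatenate([[0.0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0.0], fps / max(fps[-1], 1)])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


# ---------------------------------------------------------------------------
# Univariate clinical comparisons
# ---------------------------------------------------------------------------

CONTINUOUS_VARIABLES = ("age", "rt_dose", "interval_prePET_RT",
                        "interval_RT_duringPET", "interval_between_PETs")
CATEGORICAL_VARIABLES = ("gender", "stage", "histology", "chemo_timing")


def _wilcoxon_ranksum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample rank-sum p-value; exact enumeration when both groups are
    small (n <= 10) and tie-free, normal approximation with tie correction
    otherwise."""
    method = ("exact" if len(a) <= 10 and len(b) <= 10
              and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
              else "asymptotic")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def _chi_square(a: pd.Series, b: pd.Series) -> float:
    """Chi-square on the cohort x category table, without continuity
    correction; levels absent from both cohorts are dropped."""
    tab = pd.crosstab(
        np.concatenate([np.zeros(len(a), int), np.ones(len(b), int)]),
        pd.concat([a, b], ignore_index=True))
    tab = tab.loc[:, tab.sum(axis=0) > 0]
    if tab.shape[1] < 2 or tab.shape[0] < 2:
        return 1.0  # degenerate: no variation to test
    return float(stats.chi2_contingency(tab.values, correction=False)[1])


def univariate_cohort_tests(records: pd.DataFrame,
                            variables: list[str] | None = None,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise per-variable cohort comparisons.

    Continuous variables get a Wilcoxon rank-sum test, categorical ones a
    chi-square test on the contingency table. P-values are reported
    uncorrected; ``significant`` flags p < alpha.
    """
    if variables is None:
        variables = [v for v in CONTINUOUS_VARIABLES + CATEGORICAL_VARIABLES
                     if v in records.columns]
    cohorts = sorted(records["cohort"].unique())
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts")
    rows = []
    for ca, cb in combinations(cohorts, 2):
        sub_a = records[records["cohort"] == ca]
        sub_b = records[records["cohort"] == cb]
        for var in variables:
            if var in CONTINUOUS_VARIABLES or pd.api.types.is_numeric_dtype(records[var]):
                va, vb = sub_a[var].to_numpy(float), sub_b[var].to_numpy(float)
                if np.ptp(np.concatenate([va, vb])) == 0:
                    p = 1.0  # identical constants: nothing to test
                else:
                    p = _wilcoxon_ranksum(va, vb)
                kind = "wilcoxon"
            else:
                p = _chi_square(sub_a[var], sub_b[var])
                kind = "chi-square"
            rows.append({"variable": var, "cohort_a": ca, "cohort_b": cb,
                         "test": kind, "p_value": p,
                         "significant": p < alpha})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort-differences model
# ---------------------------------------------------------------------------

#: Stage dummy coding: three categories with stage II as reference;
#: stage IV patients fall into the IIIb/IV category.
STAGE_DUMMY_LEVELS = ("IIIa", "IIIb/IV")


def stage_dummies(stage: pd.Series) -> pd.DataFrame:
    merged = stage.replace({"IIIb": "IIIb/IV", "IV": "IIIb/IV"})
    out = pd.DataFrame(index=stage.index)
    for level in STAGE_DUMMY_LEVELS:
        out[f"stage_{level}"] = (merged == level).astype(float)
    return out


@dataclass
class CdModelResult:
    cohort_pair: tuple[str, str]
    covariate_set: str
    coefficients: pd.Series
    predicted: pd.Series
    auc: float
    auc_ci: tuple[float, float]
    roc: pd.DataFrame
    separation: bool = False
    n_excluded: int = 0


def _design_matrix(records: pd.DataFrame, features: pd.DataFrame,
                   include_clinical: bool) -> pd.DataFrame:
    X = features.loc[records.index].copy()
    X["two_year_survival"] = records["two_year_survival"]
    if include_clinical:
        X["gender_male"] = (records["gender"] == "male").astype(float)
        X = pd.concat([X, stage_dummies(records["stage"])], axis=1)
    return X


def fit_cd_model(records: pd.DataFrame, features: pd.DataFrame,
                 cohort_a: str, cohort_b: str,
                 include_clinical: bool = False) -> CdModelResult:
    """Logistic regression predicting cohort membership (B vs A).

    Covariates are the supplied radiomic features plus the binary
    two-year-survival endpoint, optionally plus gender and overall-stage
    dummies (stage II reference). Patients whose two-year endpoint is
    undefined (censored before two years) are excluded. The fit is
    unpenalized maximum likelihood scored in sample; complete separation
    is reported via a flag with AUC 1.0 rather than divergent
    coefficients.
    """
    sub = records[records["cohort"].isin([cohort_a, cohort_b])]
    defined = sub["two_year_survival"].notna()
    n_excluded = int((~defined).sum())
    sub = sub[defined]
    if sub.empty or sub["cohort"].nunique() < 2:
        raise ValueError("both cohorts must be nonempty after exclusions")
    y = (sub["cohort"] == cohort_b).astype(int).to_numpy()
    X = _design_matrix(sub, features, include_clinical)
    Xv = X.to_numpy(dtype=float)
    mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xv - mu) / sd
    model = LogisticRegression(C=np.inf, max_iter=2000, solver="lbfgs")
    model.fit(Xs, y)
    prob = model.predict_proba(Xs)[:, 1]
    auc = auc_mann_whitney(prob, y)
    separation = bool(auc == 1.0)
    coefs = pd.Series(model.coef_[0] / sd, index=X.columns)
    return CdModelResult(
        cohort_pair=(cohort_a, cohort_b),
        covariate_set=("radiomics+outcome+clinical" if include_clinical
                       else "radiomics+outcome"),
        coefficients=coefs,
        predicted=pd.Series(prob, index=sub.index),
        auc=auc, auc_ci=auc_ci(auc, int(y.sum()), int((1 - y).sum())),
        roc=roc_curve_points(prob, y),
        separation=separation, n_excluded=n_excluded)


def all_pairs_cd(records: pd.DataFrame, features: pd.DataFrame,
                 include_clinical: bool = False) -> dict[tuple[str, str], CdModelResult]:
    """CD model for every unordered cohort pair."""
    cohorts = sorted(records["cohort"].unique())
    return {(a, b): fit_cd_model(records, features, a, b, include_clinical)
            for a, b in combinations(cohorts, 2)}


def cd_summary(results: dict[tuple[str, str], CdModelResult]) -> pd.DataFrame:
    rows = [{"cohort_a": a, "cohort_b": b, "auc": r.auc,
             "ci_low": r.auc_ci[0], "ci_high": r.auc_ci[1],
             "separation": r.separation}
            for (a, b), r in results.items()]
    df = pd.DataFrame(rows)
    return df
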
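"""Penalized Cox prognostic modeling and validation.

The development procedure: features are standardized on the training
cohort, a LASSO-penalized Cox model is fit along a regularization path,
the penalty is chosen by repeated k-fold cross-validation on the partial-
likelihood deviance (curves averaged over repeats, then minimized), and
the final model is refit on the full training data. The resulting linear
predictor — the prognostic index PI = sum_i beta_i x_i — is scored on
external cohorts with Harrell's concordance index. The empty model (all
coefficients shrunk to zero) is a legitimate outcome and is reported as
such, not as an error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Harrell's concordance index
# ---------------------------------------------------------------------------

@dataclass
class CIndexResult:
    estimate: float
    lower95: float
    upper95: float
    n_pairs: int

    @property
    def significant(self) -> bool:
        """CI excludes 0.5 (the operational 'significant' of validation tables)."""
        return not (self.lower95 <= 0.5 <= self.upper95)


def _concordance_sums(pi, time, event):
    """Per-subject concordant (ties half) and usable-pair counts.

    A pair is usable when the earlier time carries an observed event;
    equal PI values count one half.
    """
    pi = np.asarray(pi, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = len(pi)
    usable = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    diff = pi[:, None] - pi[None, :]
    conc = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0)) * usable
    c_i = conc.sum(axis=1) + conc.sum(axis=0)
    p_i = usable.sum(axis=1) + usable.sum(axis=0)
    return c_i, p_i, float(conc.sum()), int(usable.sum())


def harrell_cindex(pi, time, event) -> CIndexResult:
    """Harrell's c-index with a jackknife normal-approximation 95% CI.

    1.0 is perfect discrimination, 0.5 chance level. A constant PI scores
    exactly 0.5 by the tie convention.
    """
    c_i, p_i, c_tot, p_tot = _concordance_sums(pi, time, event)
    if p_tot == 0:
        raise ValueError("no usable (orderable) pairs under censoring")
    est = c_tot / p_tot
    n = len(c_i)
    # leave-one-out estimates from the precomputed per-subject sums
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (c_tot - c_i) / (p_tot - p_i)
    loo = np.where(np.isfinite(loo), loo, est)
    se = np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum())
    z = stats.norm.ppf(0.975)
    return CIndexResult(float(est), max(0.0, est - z * se),
                        min(1.0, est + z * se), p_tot)


# ---------------------------------------------------------------------------
# Breslow partial likelihood (for CV deviance)
# ---------------------------------------------------------------------------

def breslow_loglik(pi, time, event) -> float:
    """Breslow-approximation Cox partial log-likelihood of a linear score."""
    pi = np.asarray(pi, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(-time, kind="stable")
    pi, time, event = pi[order], time[order], event[order]
    exp_pi = np.exp(pi - pi.max())
    log_cum = np.log(np.cumsum(exp_pi)) + pi.max()
    ll = 0.0
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        at_risk = log_cum[j - 1]
        for k in range(i, j):
            if event[k] == 1:
                ll += pi[k] - at_risk
        i = j
    return float(ll)


# ---------------------------------------------------------------------------
# LASSO Cox with repeated cross-validation
# ---------------------------------------------------------------------------

@dataclass
class PenalizedCoxResult:
    image_set: str
    training_cohort: str
    lambda_path: np.ndarray
    chosen_lambda: float
    coefficients: pd.Series          # nonzero features only
    feature_means: pd.Series
    feature_sds: pd.Series
    feature_names: list[str]
    training_pi: pd.Series
    empty_model: bool
    cv_deviance: np.ndarray = field(default=None, repr=False)

    def prognostic_index(self, features: pd.DataFrame) -> pd.Series:
        """PI = sum_i beta_i x_i on standardized features.

        Standardization reuses the *training* means and sds, so scoring
        the training set reproduces the training PIs exactly.
        """
        if self.empty_model:
            return pd.Series(0.0, index=features.index)
        X = features[self.feature_names]
        Xs = (X - self.feature_means) / self.feature_sds
        beta = pd.Series(0.0, index=self.feature_names)
        beta[self.coefficients.index] = self.coefficients.values
        return Xs.fillna(0.0) @ beta


def _clean_feature_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pre-filter: drop features with missing values or zero variance."""
    X = features.dropna(axis=1)
    keep = X.std(ddof=0) > 0
    return X.loc[:, keep]


def fit_lasso_cox(features: pd.DataFrame, time, event,
                  n_folds: int = 10, n_repeats: int = 200,
                  seed: int = 0, image_set: str = "",
                  training_cohort: str = "",
                  n_alphas: int = 50,
                  lambda_rule: str = "1se") -> PenalizedCoxResult:
    """LASSO-penalized Cox model with repeated-CV lambda selection.

    Cross-validated deviance curves (Verweij & Van Houwelingen form) are
    averaged over ``n_repeats`` shuffled k-fold partitions. The penalty
    is chosen by the one-standard-error rule by default — the largest
    lambda whose mean deviance is within one SE of the minimum, the
    standard stabilizer for repeated CV — or by the raw minimum with
    ``lambda_rule='min'``. When there are fewer events than folds the
    fold count is reduced with a warning. All-zero solutions are
    returned as the empty model, which is a legitimate outcome.
    """
    if lambda_rule not in ("1se", "min"):
        raise ValueError("lambda_rule must be '1se' or 'min'")
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    X = _clean_feature_matrix(features)
    names = list(X.columns)
    if not names:
        return _empty_result(features, image_set, training_cohort)
    mu = X.mean()
    sd = X.std(ddof=0)
    Xs = ((X - mu) / sd).to_numpy()
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    n_events = int(event.sum())
    if n_events < 2:
        return _empty_result(features, image_set, training_cohort, mu, sd, names)
    if n_events < n_folds:
        logger.warning("only %d events; reducing folds from %d to %d",
                       n_events, n_folds, n_events)
        n_folds = max(2, n_events)

    base = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                  alpha_min_ratio=0.05, fit_baseline_model=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base.fit(Xs, y)
    alphas = np.asarray(base.alphas_)

    rng = np.random.default_rng(seed)
    n = len(time)
    fold_devs = []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        for hold in folds:
            tr = np.setdiff1d(perm, hold, assume_unique=False)
            if event[tr].sum() < 2 or event[hold].sum() < 1:
                continue
            est = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                         fit_baseline_model=False)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(Xs[tr], y[tr])
            except (ValueError, ArithmeticError):
                continue
            coefs = est.coef_  # (n_features, n_fit_alphas)
            fit_alphas = np.asarray(est.alphas_)
            # Verweij & Van Houwelingen cross-validated deviance:
            # -2 * (full-data loglik - train-only loglik) at the train fit,
            # which is stable even when held-out folds carry few events
            pi_all = Xs @ coefs
            fold_dev = np.array([
                -2.0 * (breslow_loglik(pi_all[:, a], time, event)
                        - breslow_loglik(pi_all[tr, a], time[tr], event[tr]))
                for a in range(coefs.shape[1])])
            fold_devs.append(np.interp(alphas[::-1], fit_alphas[::-1],
                                       fold_dev[::-1])[::-1])
    if not fold_devs:
        return _empty_result(features, image_set, training_cohort, mu, sd, names)
    fold_devs = np.asarray(fold_devs)
    dev = fold_devs.mean(axis=0)
    i_min = int(np.argmin(dev))
    if lambda_rule == "min":
        chosen = float(alphas[i_min])
    else:
        se = fold_devs[:, i_min].std(ddof=1) / np.sqrt(len(fold_devs)) \
            if len(fold_devs) > 1 else 0.0
        # alphas descend along the path: the largest acceptable penalty is
        # the earliest index whose mean deviance is within one SE
        ok = np.flatnonzero(dev <= dev[i_min] + se)
        chosen = float(alphas[int(ok[0])])

    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[chosen],
                                   fit_baseline_model=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(Xs, y)
    beta = final.coef_[:, 0]
    nz = beta != 0
    coefficients = pd.Series(beta[nz], index=np.asarray(names)[nz])
    empty = not nz.any()
    result = PenalizedCoxResult(
        image_set=image_set, training_cohort=training_cohort,
        lambda_path=alphas, chosen_lambda=chosen,
        coefficients=coefficients, feature_means=mu, feature_sds=sd,
        feature_names=names,
        training_pi=pd.Series(Xs @ beta, index=features.index),
        empty_model=empty, cv_deviance=dev)
    return result


def _empty_result(features, image_set, training_cohort,
                  mu=None, sd=None, names=None) -> PenalizedCoxResult:
    names = names if names is not None else []
    return PenalizedCoxResult(
        image_set=image_set, training_cohort=training_cohort,
        lambda_path=np.array([]), chosen_lambda=float("nan"),
        coefficients=pd.Series(dtype=float),
        feature_means=mu if mu is not None else pd.Series(dtype=float),
        feature_sds=sd if sd is not None else pd.Series(dtype=float),
        feature_names=names,
        training_pi=pd.Series(0.0, index=features.index),
        empty_model=True)


def prognostic_index(model: PenalizedCoxResult,
                     features: pd.DataFrame) -> pd.Series:
    """Per-patient prognostic index (empty model scores everyone 0)."""
    return model.prognostic_index(features)


def pi_range_summary(pi: pd.Series, cohorts: pd.Series) -> pd.DataFrame:
    """Min/median/max PI per cohort (spread comparison across datasets)."""
    df = pd.DataFrame({"pi": pi, "cohort": cohorts})
    return df.groupby("cohort")["pi"].agg(["min", "median", "max"])


# ---------------------------------------------------------------------------
# Train-on-one / validate-on-rest and combined-split experiments
# ---------------------------------------------------------------------------

def cross_cohort_experiment(feature_tables: dict[str, pd.DataFrame],
                            clinical: pd.DataFrame,
                            n_folds: int = 10, n_repeats: int = 10,
                            seed: int = 0) -> pd.DataFrame:
    """For each image set and each training cohort: fit, validate on the rest.

    Returns one row per (image_set, train_cohort, eval_cohort, role) with
    the c-index, its CI and the significance flag (CI excludes 0.5).
    Empty models yield NaN c-index, mirroring '-' table cells.
    """
    cohorts = sorted(clinical["cohort"].unique())
    rows = []
    for image_set, table in feature_tables.items():
        for train_cohort in cohorts:
            tr_idx = clinical.index[clinical["cohort"] == train_cohort]
            tr_idx = tr_idx.intersection(table.index)
            clin_tr = clinical.loc[tr_idx]
            model = fit_lasso_cox(table.loc[tr_idx],
                                  clin_tr["survival_time"], clin_tr["event"],
                                  n_folds=n_folds, n_repeats=n_repeats,
                                  seed=seed, image_set=image_set,
                                  training_cohort=train_cohort)
            for eval_cohort in cohorts:
                ev_idx = clinical.index[clinical["cohort"] == eval_cohort]
                ev_idx = ev_idx.intersection(table.index)
                clin_ev = clinical.loc[ev_idx]
                role = "train" if eval_cohort == train_cohort else "validate"
                if model.empty_model:
                    rows.append({"image_set": image_set,
                                 "train_cohort": train_cohort,
                                 "eval_cohort": eval_cohort, "role": role,
                                 "c_index": np.nan, "ci_low": np.nan,
                                 "ci_high": np.nan, "significant": False,
                                 "empty_model": True})
                    continue
                pi = model.prognostic_index(table.loc[ev_idx])
                ci = harrell_cindex(pi.to_numpy(),
                                    clin_ev["survival_time"].to_numpy(),
                                    clin_ev["event"].to_numpy())
                rows.append({"image_set": image_set,
                             "train_cohort": train_cohort,
                             "eval_cohort": eval_cohort, "role": role,
                             "c_index": ci.estimate, "ci_low": ci.lower95,
                             "ci_high": ci.upper95,
                             "significant": ci.significant,
                             "empty_model": False})
    return pd.DataFrame(rows)


def combined_split_experiment(feature_tables: dict[str, pd.DataFrame],
                              clinical: pd.DataFrame,
                              train_frac: float = 0.75, seed: int = 0,
                              n_folds: int = 10,
                              n_repeats: int = 10) -> pd.DataFrame:
    """Pool all cohorts, split into train/validation by simple (unstratified)
    random sampling, and fit/validate per image set."""
    rng = np.random.default_rng(seed)
    ids = clinical.index.to_numpy()
    perm = rng.permutation(len(ids))
    n_train = int(round(train_frac * len(ids)))
    train_ids = pd.Index(ids[perm[:n_train]])
    valid_ids = pd.Index(ids[perm[n_train:]])
    rows = []
    for image_set, table in feature_tables.items():
        tr = train_ids.intersection(table.index)
        va = valid_ids.intersection(table.index)
        clin_tr, clin_va = clinical.loc[tr], clinical.loc[va]
        model = fit_lasso_cox(table.loc[tr], clin_tr["survival_time"],
                              clin_tr["event"], n_folds=n_folds,
                              n_repeats=n_repeats, seed=seed,
                              image_set=image_set, training_cohort="combined")
        for role, idx, clin in (("train", tr, clin_tr),
                                ("validate", va, clin_va)):
            if model.empty_model:
                rows.append({"image_set": image_set, "role": role,
                             "c_index": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "significant": False,
                             "empty_model": True, "n": len(idx)})
                continue
            pi = model.prognostic_index(feature_tables[image_set].loc[idx])
            ci = harrell_cindex(pi.to_numpy(),
                                clin["survival_time"].to_numpy(),
                                clin["event"].to_numpy())
            rows.append({"image_set": image_set, "role": role,
                         "c_index": ci.estimate, "ci_low": ci.lower95,
                         "ci_high": ci.upper95, "significant": ci.significant,
                         "empty_model": False, "n": len(idx)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier median follow-up (reverse censoring)
# ---------------------------------------------------------------------------

def km_median_followup(time, event) -> dict:
    """Median follow-up by the reverse Kaplan-Meier estimator.

    Event roles are swapped: deaths are treated as censored, censorings as
    events. The median is the first time the product-limit curve drops to
    0.5 or below; if it never does, the median is reported as not reached
    (inf).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=1 - event)
    median = float(kmf.median_survival_time_)
    return {"median_followup": median,
            "not_reached": not np.isfinite(median),
            "min_time": float(time.min()), "max_time": float(time.max())}


# ---------------------------------------------------------------------------
# Univariable PET-metric analysis
# ---------------------------------------------------------------------------

PET_METRICS = ("volume", "suvmax", "suvmean", "suvpeak", "mtv50", "tlg50")


def compute_pet_metrics(pet_img, mask) -> dict[str, float]:
    """The six commonly assessed PET metrics for one scan."""
    from .features import ivh_features, suv_peak

    x = pet_img.values[mask.values]
    curve, _ = ivh_features(pet_img, mask)
    i50 = curve.thresholds.index(50)
    return {"volume": mask.volume_mm3,
            "suvmax": float(x.max()),
            "suvmean": float(x.mean()),
            "suvpeak": suv_peak(pet_img, mask),
            "mtv50": float(curve.mtv[i50]),
            "tlg50": float(curve.tlg[i50])}


def univariable_pet_metrics(metrics_pre: pd.DataFrame,
                            metrics_during: pd.DataFrame,
                            time, event,
                            metrics: tuple[str, ...] = PET_METRICS) -> pd.DataFrame:
    """Univariable Cox models on the fractional change of each PET metric.

    The covariate is (during - pre)/pre per patient; the table reports the
    hazard ratio per unit fractional change with Wald 95% CI and p-value,
    plus the single-covariate c-index.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    rows = []
    for metric in metrics:
        pre = metrics_pre[metric].to_numpy(float)
        during = metrics_during[metric].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            change = np.where(pre != 0, (during - pre) / pre, np.nan)
        ok = np.isfinite(change)
        df = pd.DataFrame({"x": change[ok], "time": time[ok],
                           "event": event[ok]})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        beta = float(cph.params_["x"])
        lo, hi = cph.confidence_intervals_.loc["x"]
        p = float(cph.summary.loc["x", "p"])
        ci = harrell_cindex(beta * df["x"].to_numpy(), df["time"].to_numpy(),
                            df["event"].to_numpy())
        rows.append({"metric": metric,
                     "pct_change_mean": float(np.nanmean(change) * 100),
                     "pct_change_sd": float(np.nanstd(change) * 100),
                     "log_hr": beta, "hr": float(np.exp(beta)),
                     "hr_ci_low": float(np.exp(lo)),
                     "hr_ci_high": float(np.exp(hi)), "p_value": p,
                     "c_index": ci.estimate})
    return pd.DataFrame(rows).set_index("metric")
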
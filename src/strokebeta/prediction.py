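"""Recovery prediction: stepwise logistic regression with honest LOOCV.

The outcome is improvement status (improved = 0, didn't improve = 1).
Candidate predictors are z-scored; collinear candidates (VIF > 2.5) are
merged by averaging their z-scores; forward stepwise selection adds the
candidate with the smallest Wald p when p < 0.15 and removes included
predictors whose p rises to >= 0.15 (a backward variant checks stability).
Performance is reported from leave-one-out cross-validation in which the
entire pipeline — merge, selection, fit — is re-run on every training
fold, plus a full-sample fit for coefficient interpretation. Metrics:
Brier score, rank-based AUC with midrank ties, and contingency-table
accuracy/sensitivity/specificity/PPV/NPV with exact Clopper–Pearson 95%
confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "LogisticModel",
    "PerformanceReport",
    "standardize",
    "vif",
    "vif_screen",
    "logistic_fit",
    "forward_stepwise",
    "backward_stepwise",
    "brier_score",
    "auc_score",
    "clopper_pearson",
    "contingency_report",
    "loocv_evaluate",
    "PredictionPipeline",
]


@dataclass
class LogisticModel:
    features: list
    coefficients: np.ndarray        # aligned with features
    intercept: float
    wald_z: np.ndarray
    wald_p: np.ndarray
    converged: bool
    separation: bool = False

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        z = self.intercept + X[self.features].to_numpy() @ self.coefficients
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class PerformanceReport:
    brier: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int
    metrics: dict                   # name -> (estimate, lo, hi)
    positive_label: int = 1
    metrics_flipped: dict = field(default_factory=dict)
    selected_features: list = field(default_factory=list)
    probabilities: np.ndarray = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def standardize(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series,
                                                 pd.Series]:
    """z-transform columns (mean 0, sd 1 with denominator n-1)."""
    mu = features.mean()
    sd = features.std(ddof=1)
    bad = sd[sd == 0].index.tolist()
    if bad:
        raise ValueError(f"constant column(s): {bad}")
    return (features - mu) / sd, mu, sd


def vif(features: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R^2) per column."""
    X = features.to_numpy(dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need n > n_features + 1 for VIF")
    out = {}
    for j, col in enumerate(features.columns):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = resid @ resid
        ss_tot = ((y - y.mean()) ** 2).sum()
        if ss_tot == 0:
            raise np.linalg.LinAlgError(f"column {col} has zero variance")
        r2 = 1.0 - ss_res / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_screen(features: pd.DataFrame, threshold: float = 2.5,
               corr_threshold: float = 0.7
               ) -> tuple[pd.DataFrame, list]:
    """Merge collinear predictors.

    Columns whose VIF exceeds ``threshold`` are grouped by pairwise
    correlation (|r| >= ``corr_threshold`` links two columns) and each
    group is replaced by the mean of its z-scored members. Input must
    already be z-scored.

    Returns (screened features, list of merged groups).
    """
    v = vif(features)
    high = [c for c in features.columns if v[c] > threshold]
    if not high:
        return features.copy(), []
    corr = features[high].corr().abs()
    # union-find over highly correlated high-VIF columns
    parent = {c: c for c in high}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(high):
        for b in high[i + 1:]:
            if corr.loc[a, b] >= corr_threshold:
                parent[find(a)] = find(b)

    groups: dict = {}
    for c in high:
        groups.setdefault(find(c), []).append(c)
    merged_groups = [sorted(g) for g in groups.values() if len(g) > 1]

    out = features.copy()
    for grp in merged_groups:
        name = "mean_" + "_".join(grp)
        out[name] = features[grp].mean(axis=1)
        out = out.drop(columns=grp)
    return out, merged_groups


def _fit_glm(X: np.ndarray, y: np.ndarray, ridge: float = 0.0):
    """IRLS logistic fit through statsmodels; optional ridge fallback."""
    design = sm.add_constant(X, has_constant="add")
    if ridge > 0.0:
        model = sm.GLM(y, design, family=sm.families.Binomial())
        # penalized IRLS: L2 on all but the intercept
        res = model.fit_regularized(alpha=ridge, L1_wt=0.0)
        # refit covariance at the penalized solution for Wald statistics
        p = 1.0 / (1.0 + np.exp(-design @ res.params))
        W = p * (1 - p)
        pen = ridge * np.eye(design.shape[1])
        pen[0, 0] = 0.0
        cov = np.linalg.inv(design.T * W @ design + pen)
        return res.params, np.sqrt(np.diag(cov)), True
    res = sm.Logit(y, design).fit(disp=0, maxiter=100, tol=1e-8)
    return res.params, res.bse, res.mle_retvals["converged"]


def logistic_fit(X: pd.DataFrame, y, ridge_fallback: float = 1e-4
                 ) -> LogisticModel:
    """Maximum-likelihood logistic regression with Wald statistics.

    Complete or quasi-complete separation (diverging coefficients or a
    singular information matrix) is detected and flagged; the model is
    then refit with a small ridge penalty so small cohorts never crash.
    """
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary 0/1")
    if len(y) < X.shape[1] + 2:
        raise ValueError("need n >= n_features + 2")
    Xa = X.to_numpy(dtype=float)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            params, bse, converged = _fit_glm(Xa, y)
            if (not converged or not np.isfinite(bse).all()
                    or np.abs(params).max() > 20.0):
                raise np.linalg.LinAlgError("separation suspected")
        except (np.linalg.LinAlgError, Exception):
            separation = True
            params, bse, converged = _fit_glm(Xa, y,
                                              ridge=ridge_fallback)
    z = params / bse
    from scipy.stats import norm

    p = 2.0 * norm.sf(np.abs(z))
    return LogisticModel(features=list(X.columns),
                         coefficients=np.asarray(params[1:]),
                         intercept=float(params[0]),
                         wald_z=np.asarray(z[1:]),
                         wald_p=np.asarray(p[1:]),
                         converged=bool(converged),
                         separation=separation)


def forward_stepwise(candidates: pd.DataFrame, y,
                     alpha_enter: float = 0.15,
                     alpha_remove: float = 0.15) -> LogisticModel:
    """Forward stepwise selection on Wald p-values.

    Repeatedly adds the candidate whose Wald p (in a fit together with the
    current model) is smallest and below ``alpha_enter``; after each
    addition removes any included predictor whose p is >= ``alpha_remove``;
    stops at a fixed point. Returns the fit on the final selection (the
    intercept-only model when nothing enters).
    """
    y = np.asarray(y)
    included: list = []
    seen = {frozenset()}
    while True:
        changed = False
        remaining = [c for c in candidates.columns if c not in included]
        best_p, best_c = np.inf, None
        for c in remaining:
            m = logistic_fit(candidates[included + [c]], y)
            p = m.wald_p[-1]
            if p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p < alpha_enter:
            included.append(best_c)
            changed = True
        # backward sweep on the current selection
        while included:
            m = logistic_fit(candidates[included], y)
            worst = int(np.argmax(m.wald_p))
            if m.wald_p[worst] >= alpha_remove:
                included.pop(worst)
                changed = True
            else:
                break
        state = frozenset(included)
        if not changed or state in seen:
            break   # fixed point, or an add/remove cycle revisiting a state
        seen.add(state)
    return logistic_fit(candidates[included], y) if included else \
        _intercept_only(y, list(candidates.columns))


def backward_stepwise(candidates: pd.DataFrame, y,
                      alpha_enter: float = 0.15,
                      alpha_remove: float = 0.15) -> LogisticModel:
    """Backward variant (stability check): start full, drop predictors
    with Wald p >= alpha_remove, re-admitting dropped ones that reach
    p < alpha_enter."""
    y = np.asarray(y)
    included = list(candidates.columns)
    seen = {frozenset(included)}
    while True:
        changed = False
        while included:
            m = logistic_fit(candidates[included], y)
            worst = int(np.argmax(m.wald_p))
            if m.wald_p[worst] >= alpha_remove:
                included.pop(worst)
                changed = True
            else:
                break
        dropped = [c for c in candidates.columns if c not in included]
        best_p, best_c = np.inf, None
        for c in dropped:
            m = logistic_fit(candidates[included + [c]], y)
            if m.wald_p[-1] < best_p:
                best_p, best_c = m.wald_p[-1], c
        if best_c is not None and best_p < alpha_enter:
            included.append(best_c)
            changed = True
        state = frozenset(included)
        if not changed or state in seen:
            break
        seen.add(state)
    return logistic_fit(candidates[included], y) if included else \
        _intercept_only(y, list(candidates.columns))


def _intercept_only(y, candidate_names) -> LogisticModel:
    rate = float(np.mean(y))
    rate = min(max(rate, 1e-9), 1 - 1e-9)
    return LogisticModel(features=[], coefficients=np.array([]),
                         intercept=float(np.log(rate / (1 - rate))),
                         wald_z=np.array([]), wald_p=np.array([]),
                         converged=True)


# ---------------------------------------------------------------------------
# performance metrics

def brier_score(probs, labels) -> float:
    """Mean squared error of probabilities against 0/1 labels."""
    p = np.asarray(probs, dtype=float)
    return float(np.mean((p - np.asarray(labels)) ** 2))


def auc_score(probs, labels) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(p)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def clopper_pearson(successes: int, n: int,
                    conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval (beta quantiles)."""
    lo, hi = proportion_confint(successes, n, alpha=1 - conf,
                                method="beta")
    return float(lo), float(hi)


def contingency_report(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Accuracy/sensitivity/specificity/PPV/NPV with exact 95% CIs."""
    def prop(k, m):
        if m == 0:
            return (np.nan, np.nan, np.nan)
        lo, hi = clopper_pearson(k, m)
        return (k / m, lo, hi)

    n = tp + fp + tn + fn
    return {
        "accuracy": prop(tp + tn, n),
        "sensitivity": prop(tp, tp + fn),
        "specificity": prop(tn, tn + fp),
        "ppv": prop(tp, tp + fp),
        "npv": prop(tn, tn + fn),
    }


class PredictionPipeline:
    """VIF merge + forward stepwise + logistic fit, as one fitted object.

    Stores the training-fold standardization and merge map so held-out
    subjects are transformed exactly as the training data were.
    """

    def __init__(self, vif_threshold: float = 2.5,
                 alpha_enter: float = 0.15, alpha_remove: float = 0.15):
        self.vif_threshold = vif_threshold
        self.alpha_enter = alpha_enter
        self.alpha_remove = alpha_remove

    def fit(self, X: pd.DataFrame, y) -> "PredictionPipeline":
        y = np.asarray(y)
        self.single_class_ = len(np.unique(y)) < 2
        if self.single_class_:
            self.rate_ = float(np.mean(y))
            return self
        Xz, self.mu_, self.sd_ = standardize(X)
        Xs, self.merged_ = vif_screen(Xz, self.vif_threshold)
        self.model_ = forward_stepwise(Xs, y, self.alpha_enter,
                                       self.alpha_remove)
        return self

    def _transform(self, X: pd.DataFrame) -> pd.DataFrame:
        Xz = (X - self.mu_) / self.sd_
        for grp in self.merged_:
            Xz["mean_" + "_".join(grp)] = Xz[grp].mean(axis=1)
            Xz = Xz.drop(columns=grp)
        return Xz

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        if self.single_class_:
            return np.full(len(X), self.rate_)
        return self.model_.predict_proba(self._transform(X))

    @property
    def selected_features(self) -> list:
        if self.single_class_:
            return []
        return list(self.model_.features)


def loocv_evaluate(features: pd.DataFrame, y, threshold: float = 0.5,
                   vif_threshold: float = 2.5, alpha_enter: float = 0.15,
                   alpha_remove: float = 0.15) -> PerformanceReport:
    """Honest leave-one-out evaluation of the full selection pipeline.

    For every held-out subject the merge + stepwise + fit sequence is
    re-run on the other n-1; the held-out probability never sees its own
    row. Folds whose training labels collapse to a single class fall back
    to the intercept-only rate (flagged via a warning).

    The positive class for sensitivity/PPV follows the outcome coding
    (didn't improve = 1); ``metrics_flipped`` reports the other
    orientation to avoid ambiguity.
    """
    y = np.asarray(y)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 subjects for LOOCV")
    probs = np.empty(n)
    for k in range(n):
        mask = np.ones(n, dtype=bool)
        mask[k] = False
        pipe = PredictionPipeline(vif_threshold, alpha_enter,
                                  alpha_remove).fit(
            features.iloc[mask].reset_index(drop=True), y[mask])
        if getattr(pipe, "single_class_", False):
            warnings.warn(f"fold {k}: single-class training labels; "
                          "intercept-only probability used")
        probs[k] = float(pipe.predict_proba(features.iloc[[k]])[0])

    pred = (probs >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    full = PredictionPipeline(vif_threshold, alpha_enter,
                              alpha_remove).fit(features, y)
    return PerformanceReport(
        brier=brier_score(probs, y), auc=auc_score(probs, y),
        tp=tp, fp=fp, tn=tn, fn=fn,
        metrics=contingency_report(tp, fp, tn, fn),
        metrics_flipped=contingency_report(tn, fn, tp, fp),
        selected_features=full.selected_features,
        probabilities=probs)
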
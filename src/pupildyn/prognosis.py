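"""Day-by-day outcome prediction from cumulative pupillary indices.

For each number of days of observation ND (cumulative window [0, 24*(ND+1))
hours) the module screens each index with the point-biserial correlation
against the dichotomized outcome (favorable = 1, unfavorable = 0), then runs
an exhaustive logistic model-selection sweep over all 15 non-empty subsets of
the four indices. Each model is scored three ways: likelihood-ratio p-value
against the intercept-only model, BIC = k*ln(n) - 2*lnL with k = number of
predictors + 1, and leave-one-out cross-validated accuracy at a 0.5
probability cutoff. With ~20 patients and strong predictors, maximum
likelihood frequently separates; separated fits are flagged and refit with
Firth's Jeffreys-prior penalty, whose penalized likelihood then feeds the
LR test and BIC so the score grid stays finite.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .cohort import Outcome, PatientRecord
from .indices import INDEX_NAMES, JumpDenominator, cohort_cumulative_table

logger = logging.getLogger(__name__)

#: |coefficient| beyond which an MLE fit is treated as (quasi-)separated.
SEPARATION_BOUND = 30.0


@dataclass
class PredictorMatrix:
    """Per-patient predictor values for one ND window plus the 0/1 outcome."""

    X: pd.DataFrame            # rows = patients, columns = predictor subset
    y: np.ndarray              # 1 = favorable, 0 = unfavorable
    nd: int
    patient_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("PredictorMatrix must have no missing cells")
        if len(np.unique(self.y)) < 2:
            raise ValueError("both outcome classes must be present")


@dataclass(frozen=True)
class ModelScore:
    predictor_subset: tuple[str, ...]
    nd: int
    lr_pvalue: float
    bic: float
    loocv_accuracy: float
    separation_flag: bool
    loglik: float              # scoring log-likelihood (penalized if separated)
    mle_loglik: float          # numerical supremum of the unpenalized one
    n: int


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    nd: int


@dataclass(frozen=True)
class LogisticFit:
    params: np.ndarray         # intercept first
    loglik: float              # penalized when firth=True
    converged: bool
    separation_flag: bool
    firth: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xd = np.column_stack([np.ones(len(X)), X])
        return expit(Xd @ self.params)


def point_biserial(values, outcomes) -> tuple[float, float]:
    """Point-biserial correlation of an index with the 0/1 outcome coding.

    Equals the Pearson correlation against the binary coding; the two-sided p
    comes from the t transform with n - 2 df.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(x) < 3:
        raise ValueError("point-biserial needs >= 3 patients")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in index values: correlation undefined")
    r, p = sps.pointbiserialr(y, x)
    return float(r), float(p)


def _loglik(beta: np.ndarray, Xd: np.ndarray, y: np.ndarray) -> float:
    eta = Xd @ beta
    # numerically stable log-likelihood sum(y*eta - log(1+exp(eta)))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_firth(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Firth-penalized logistic regression (Jeffreys-prior score adjustment).

    Newton iterations on the modified score U* = X'(y - p + h*(1/2 - p)),
    where h is the leverage under the current weights; finite estimates exist
    even under complete separation. Returns the *penalized* log-likelihood
    lnL + 0.5*ln det(X'WX).
    """
    Xd = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    y = np.asarray(y, dtype=float)
    beta = np.zeros(Xd.shape[1])
    converged = False
    for _ in range(max_iter):
        p = expit(Xd @ beta)
        w = np.clip(p * (1 - p), 1e-12, None)
        XtW = Xd.T * w
        info = XtW @ Xd
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", Xd, info_inv, Xd) * w
        score = Xd.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # damped step for stability on tiny samples
        while np.max(np.abs(step)) > 5.0:
            step /= 2.0
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    p = expit(Xd @ beta)
    w = np.clip(p * (1 - p), 1e-12, None)
    info = (Xd.T * w) @ Xd
    sign, logdet = np.linalg.slogdet(info)
    pen_ll = _loglik(beta, Xd, y) + 0.5 * logdet
    return LogisticFit(params=beta, loglik=pen_ll, converged=converged,
                       separation_flag=True, firth=True)


def fit_logistic(X, y) -> LogisticFit:
    """Maximum-likelihood logit with intercept; Firth refit on separation.

    Separation is flagged on non-convergence, an MLE error, or any
    |coefficient| exceeding SEPARATION_BOUND; the returned fit is then the
    Firth-penalized one (used for prediction and scoring).
    """
    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    Xd = sm.add_constant(X, has_constant="add")
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=200, warn_convergence=False)
        params = np.asarray(res.params, dtype=float)
        converged = bool(res.mle_retvals.get("converged", False))
        if not converged or not np.all(np.isfinite(params)) or np.max(np.abs(params)) > SEPARATION_BOUND:
            separated = True
        else:
            return LogisticFit(params=params, loglik=float(res.llf), converged=True,
                               separation_flag=False, firth=False)
    except Exception:
        separated = True
    assert separated
    return fit_firth(X, y)


def max_loglik(X, y) -> float:
    """Numerical supremum of the unpenalized log-likelihood.

    Under (quasi-)separation the MLE diverges but the log-likelihood still has
    a finite supremum, approached along the separating direction; a bounded
    quasi-Newton run gets within optimizer tolerance of it. This is the
    quantity that is monotone under predictor nesting, so it backs the
    nested-deviance checks while the Firth-penalized value backs scoring.
    """
    from scipy.optimize import minimize

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    Xd = np.column_stack([np.ones(len(y)), X])

    def nll(beta):
        eta = Xd @ beta
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    def grad(beta):
        return -Xd.T @ (y - expit(Xd @ beta))

    res = minimize(nll, np.zeros(Xd.shape[1]), jac=grad, method="L-BFGS-B",
                   options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10})
    return float(-res.fun)


def intercept_only_loglik(y) -> float:
    """Closed form: n1*ln(n1/n) + n0*ln(n0/n)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    n1 = y.sum()
    n0 = n - n1
    ll = 0.0
    if n1 > 0:
        ll += n1 * np.log(n1 / n)
    if n0 > 0:
        ll += n0 * np.log(n0 / n)
    return float(ll)


def _null_fit(y: np.ndarray, firth: bool) -> float:
    """Log-likelihood of the intercept-only model, on the matching scale."""
    if not firth:
        return intercept_only_loglik(y)
    return fit_firth(np.empty((len(y), 0)), y).loglik


def _loocv_accuracy(X: np.ndarray, y: np.ndarray) -> float:
    """Fraction of held-out patients with predicted probability on the
    correct side of 0.5; single-class training folds fall back to the
    training-set majority."""
    n = len(y)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ytr = y[mask]
        if len(np.unique(ytr)) < 2:
            pred = float(ytr.mean() > 0.5)
            logger.info("LOOCV fold %d: single-class training set, majority prediction", i)
            correct += pred == y[i]
            continue
        fit = fit_logistic(X[mask], ytr)
        prob = float(fit.predict(X[i][None, :])[0])
        correct += (prob > 0.5) == bool(y[i])
    return correct / n


def build_predictor_matrix(
    cohort: list[PatientRecord],
    nd: int,
    predictors: tuple[str, ...] = INDEX_NAMES,
    denominator: JumpDenominator = "per_measurement",
) -> PredictorMatrix:
    """Evaluate the chosen indices on the cumulative ND window for each patient.

    Patients with any undefined index in the window are dropped (and logged).
    """
    table = cohort_cumulative_table(cohort, max_nd=nd, denominator=denominator)
    sub = table[table["nd"] == nd].set_index("patient_id")
    X = sub[list(predictors)]
    ok = X.notna().all(axis=1)
    dropped = list(X.index[~ok])
    if dropped:
        logger.info("ND=%d: dropped patients with missing indices: %s", nd, dropped)
    X = X[ok]
    y = (sub.loc[ok, "outcome"] == Outcome.FAVORABLE.value).to_numpy().astype(int)
    return PredictorMatrix(X=X.reset_index(drop=True), y=y, nd=nd,
                           patient_ids=list(X.index))


def score_model(pm: PredictorMatrix, loocv: bool = True) -> ModelScore:
    """Score one (ND, predictor subset) cell: LR p-value, BIC, LOOCV accuracy."""
    X = pm.X.to_numpy(dtype=float)
    y = pm.y.astype(float)
    n, k = X.shape
    fit = fit_logistic(X, y)
    ll_null = _null_fit(y, firth=fit.firth)
    lr = max(0.0, 2.0 * (fit.loglik - ll_null))
    lr_p = float(sps.chi2.sf(lr, df=k))
    bic = (k + 1) * np.log(n) - 2.0 * fit.loglik
    acc = _loocv_accuracy(X, y) if loocv else float("nan")
    return ModelScore(
        predictor_subset=tuple(pm.X.columns),
        nd=pm.nd,
        lr_pvalue=lr_p,
        bic=float(bic),
        loocv_accuracy=acc,
        separation_flag=fit.separation_flag,
        loglik=float(fit.loglik),
        mle_loglik=max_loglik(X, y),
        n=n,
    )


def all_predictor_subsets(names: tuple[str, ...] = INDEX_NAMES) -> list[tuple[str, ...]]:
    """All 2^m - 1 non-empty subsets, smallest first then lexicographic."""
    subsets = []
    for r in range(1, len(names) + 1):
        subsets.extend(itertools.combinations(sorted(names), r))
    return subsets


def model_selection_sweep(
    cohort: list[PatientRecord],
    nd_range=range(0, 11),
    denominator: JumpDenominator = "per_measurement",
    loocv: bool = True,
) -> pd.DataFrame:
    """Score every predictor subset at every ND; returns the long score grid.

    NDs where fewer than 3 patients per class have complete indices are
    skipped with a log entry. Columns: nd, subset, lr_pvalue, bic,
    loocv_accuracy, separation_flag, loglik, n.
    """
    rows = []
    for nd in nd_range:
        try:
            full = build_predictor_matrix(cohort, nd, INDEX_NAMES, denominator)
        except ValueError as e:
            logger.warning("ND=%d skipped: %s", nd, e)
            continue
        counts = np.bincount(full.y, minlength=2)
        if counts.min() < 3:
            logger.warning("ND=%d skipped: < 3 patients in a class (%s)", nd, counts)
            continue
        for subset in all_predictor_subsets():
            pm = PredictorMatrix(X=full.X[list(subset)], y=full.y, nd=nd,
                                 patient_ids=full.patient_ids)
            s = score_model(pm, loocv=loocv)
            rows.append(
                {
                    "nd": nd,
                    "subset": "+".join(subset),
                    "n_predictors": len(subset),
                    "lr_pvalue": s.lr_pvalue,
                    "bic": s.bic,
                    "loocv_accuracy": s.loocv_accuracy,
                    "separation_flag": s.separation_flag,
                    "loglik": s.loglik,
                    "mle_loglik": s.mle_loglik,
                    "n": s.n,
                }
            )
    return pd.DataFrame(rows)


def best_models(grid: pd.DataFrame) -> pd.DataFrame:
    """Per-ND best model under each criterion separately.

    Ties are broken by smaller subset size, then lexicographically by subset
    label. Returns columns: nd, criterion, subset, value.
    """
    out = []
    for nd, g in grid.groupby("nd"):
        for crit, ascending in (("lr_pvalue", True), ("bic", True), ("loocv_accuracy", False)):
            gg = g.sort_values(
                [crit, "n_predictors", "subset"], ascending=[ascending, True, True]
            )
            top = gg.iloc[0]
            out.append({"nd": nd, "criterion": crit, "subset": top["subset"],
                        "value": float(top[crit])})
    return pd.DataFrame(out)


def roc_auc(scores, outcomes, nd: int = -1) -> RocResult:
    """ROC curve and trapezoidal AUC for one score vector.

    The AUC equals the Mann-Whitney U statistic divided by n1*n0, with ties
    contributing 1/2.
    """
    from sklearn import metrics

    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if np.ptp(s) == 0:
        # all-tied predictor: chance performance by the tie convention
        return RocResult(np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                         np.array([np.inf, s[0]]), 0.5, nd)
    fpr, tpr, thr = metrics.roc_curve(y, s)
    return RocResult(fpr, tpr, thr, float(metrics.auc(fpr, tpr)), nd)


def roc_for_predictor(
    cohort: list[PatientRecord],
    nd: int,
    predictor: str = "ps_isochoria_pct",
    mode: str = "in_sample",
    denominator: JumpDenominator = "per_measurement",
) -> RocResult:
    """ROC/AUC of the single-predictor logistic model at one ND.

    ``in_sample`` scores every patient with the model fitted on the full
    cohort (AUC is then identical to ranking by the raw index, up to the
    fitted slope's sign); ``loocv`` scores each patient with the model fitted
    on the other n-1.
    """
    pm = build_predictor_matrix(cohort, nd, (predictor,), denominator)
    X = pm.X.to_numpy(dtype=float)
    y = pm.y
    if mode == "in_sample":
        probs = fit_logistic(X, y).predict(X)
    elif mode == "loocv":
        n = len(y)
        probs = np.empty(n)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            ytr = y[mask]
            if len(np.unique(ytr)) < 2:
                probs[i] = float(ytr.mean())
                continue
            probs[i] = fit_logistic(X[mask], ytr).predict(X[i][None, :])[0]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return roc_auc(probs, y, nd=nd)


def correlation_sweep(
    cohort: list[PatientRecord],
    nd_range=range(0, 11),
    denominator: JumpDenominator = "per_measurement",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Point-biserial correlation of each index with outcome at each ND.

    Significance (two-sided p < alpha, uncorrected) marks the correlations a
    screening plot would show as filled points.
    """
    rows = []
    for nd in nd_range:
        pm = build_predictor_matrix(cohort, nd, INDEX_NAMES, denominator)
        for name in INDEX_NAMES:
            r, p = point_biserial(pm.X[name], pm.y)
            rows.append({"nd": nd, "index": name, "r": r, "p": p,
                         "significant": p < alpha})
    return pd.DataFrame(rows)
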
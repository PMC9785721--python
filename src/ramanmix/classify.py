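"""Downstream statistics on resolved concentration profiles.

Single-score ROC/AUC with DeLong confidence intervals, unregularized binary
logistic regression with Wald predictor significance, PLS-DA with stratified
10-fold cross-validation, box-plot summaries, and the standard contrast
battery over the five-class cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, ndtri
from scipy.stats import rankdata
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .spectra import CLASS_LABELS

__all__ = [
    "ContrastSpec",
    "RocResult",
    "LogisticReport",
    "BoxplotGroup",
    "roc_auc",
    "fit_logistic",
    "pls_da",
    "boxplot_summary",
    "run_contrasts",
    "PER_COMPONENT_CONTRASTS",
    "MODEL_CONTRASTS",
]


@dataclass(frozen=True)
class ContrastSpec:
    """A binary contrast between two disjoint groups of class labels."""

    name: str
    positive_classes: tuple
    negative_classes: tuple

    def __post_init__(self) -> None:
        pos, neg = set(self.positive_classes), set(self.negative_classes)
        if not pos or not neg:
            raise ValueError("both class groups must be non-empty")
        if pos & neg:
            raise ValueError("positive and negative class groups must be disjoint")

    def select(self, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (row mask, binary response) for the samples in this contrast."""
        labels = np.asarray(labels, dtype=object)
        unknown = set(labels) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        mask = np.isin(labels, self.positive_classes + self.negative_classes)
        y = np.isin(labels[mask], self.positive_classes).astype(float)
        return mask, y


#: Per-component score contrasts (single-concentration discriminators).
PER_COMPONENT_CONTRASTS = (
    ContrastSpec("BCC_vs_rest", ("BCC",), ("NS", "K", "MM", "PN")),
    ContrastSpec("BCC_vs_MM", ("BCC",), ("MM",)),
    ContrastSpec("malignant_vs_benign", ("MM", "BCC"), ("K", "PN")),
    ContrastSpec("MM_vs_PN", ("MM",), ("PN",)),
)

#: Model-based (logistic / PLS-DA) contrasts.
MODEL_CONTRASTS = (
    ContrastSpec("malignant_vs_benign", ("MM", "BCC"), ("K", "PN")),
    ContrastSpec("MM_vs_KPN", ("MM",), ("K", "PN")),
)


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int
    ci_method: str = "delong"

    def __post_init__(self) -> None:
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("CI must contain the point AUC")


@dataclass
class LogisticReport:
    coefficients: np.ndarray
    intercept: float
    wald_p_values: np.ndarray
    predicted_probabilities: np.ndarray
    converged: bool
    separation_flag: bool = False


@dataclass
class BoxplotGroup:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray = field(default_factory=lambda: np.array([]))


def _auc_mann_whitney(scores: np.ndarray, y: np.ndarray) -> float:
    # AUC == U / (n1*n0), ties counted 1/2, via midranks
    ranks = rankdata(scores)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _delong_variance(scores: np.ndarray, y: np.ndarray) -> float:
    """DeLong variance of the AUC from the placement components."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)  # per-positive placements
    v01 = psi.mean(axis=0)  # per-negative placements
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def _roc_points(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep one point per distinct threshold
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), y.size - 1]
    tpr = np.r_[0.0, tps[distinct] / tps[-1]]
    fpr = np.r_[0.0, fps[distinct] / fps[-1]]
    return fpr, tpr


def roc_auc(
    scores,
    binary_labels,
    level: float = 0.95,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC curve with AUC and a confidence interval.

    The AUC equals the Mann-Whitney statistic ``U / (n1 * n0)`` with ties
    counted one half; the default CI uses the DeLong variance estimator, a
    percentile bootstrap is available via ``ci_method='bootstrap'``.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(binary_labels, dtype=float).ravel()
    if scores.size != y.size:
        raise ValueError("scores and labels must have equal length")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    auc = _auc_mann_whitney(scores, y)
    fpr, tpr = _roc_points(scores, y)
    z = ndtri(0.5 + level / 2.0)
    if ci_method == "delong":
        se = np.sqrt(_delong_variance(scores, y))
        lo, hi = auc - z * se, auc + z * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.r_[rng.choice(pos_idx, n_pos), rng.choice(neg_idx, n_neg)]
            reps[b] = _auc_mann_whitney(scores[idx], y[idx])
        lo, hi = np.quantile(reps, [(1 - level) / 2, 0.5 + level / 2])
    else:
        raise ValueError("ci_method must be 'delong' or 'bootstrap'")
    return RocResult(
        auc=auc,
        ci_low=float(min(max(lo, 0.0), auc)),
        ci_high=float(max(min(hi, 1.0), auc)),
        fpr=fpr,
        tpr=tpr,
        n_pos=n_pos,
        n_neg=n_neg,
        ci_method=ci_method,
    )


def fit_logistic(
    predictors,
    response,
    standardize: bool = False,
    maxiter: int = 200,
) -> LogisticReport:
    """Maximum-likelihood binary logistic regression (no regularization).

    Wald z-test p-values are reported per predictor.  Complete separation is
    flagged (not raised); the finite-iteration estimate is returned.
    """
    x = np.atleast_2d(np.asarray(predictors, dtype=float))
    y = np.asarray(response, dtype=float).ravel()
    if x.shape[0] != y.size:
        raise ValueError("predictors and response must align")
    if min(int(y.sum()), int((1 - y).sum())) < 2:
        raise ValueError("need at least 2 samples in each class")
    if standardize:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd

    # constant predictors carry no information and make the Hessian singular;
    # they are dropped from the fit and reported with coefficient 0, p = 1
    informative = x.std(axis=0) > 0
    design = sm.add_constant(x[:, informative], has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=maxiter)
        except Exception:  # perfect separation aborts Newton; fall back
            separation = True
            res = sm.Logit(y, design).fit(disp=0, maxiter=maxiter, method="bfgs")
    separation_msgs = [
        str(w.message) for w in caught if "separation" in str(w.message).lower()
    ]
    if separation_msgs:
        separation = True
    if separation:
        warnings.warn(
            "possible complete separation; returning the finite-iteration "
            "estimate",
            RuntimeWarning,
            stacklevel=2,
        )
    params = np.asarray(res.params, dtype=float)
    pvals = np.asarray(res.pvalues, dtype=float)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    coefficients = np.zeros(x.shape[1])
    coefficients[informative] = params[1:]
    wald_p = np.ones(x.shape[1])
    wald_p[informative] = pvals[1:]
    probs = expit(float(params[0]) + x[:, informative] @ params[1:])
    return LogisticReport(
        coefficients=coefficients,
        intercept=float(params[0]),
        wald_p_values=wald_p,
        predicted_probabilities=probs,
        converged=bool(res.mle_retvals.get("converged", True)),
        separation_flag=separation,
    )


def pls_da(
    features,
    response,
    n_latent: int | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, RocResult, int]:
    """PLS-DA: PLS regression on a 0/1 response with stratified k-fold CV.

    Out-of-fold predictions are concatenated over a seeded stratified
    partition; the ROC is computed on those predictions.  When ``n_latent``
    is None it is chosen by inner-CV AUC over 1..10.

    Returns ``(oof_predictions, roc, n_latent_used)``.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(response, dtype=float).ravel()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if min(int(y.sum()), int((1 - y).sum())) < folds:
        raise ValueError("each class needs at least `folds` samples for stratified CV")
    max_latent = min(10, x.shape[1], x.shape[0] - 1)
    if n_latent is None:
        n_latent = _choose_n_latent(x, y, max_latent, seed)
    if n_latent > x.shape[1]:
        raise ValueError("n_latent exceeds the feature dimension")

    oof = np.empty(y.size)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(x, y):
        model = PLSRegression(n_components=n_latent)
        model.fit(x[train], y[train])
        oof[test] = model.predict(x[test]).ravel()
    return oof, roc_auc(oof, y), n_latent


def _choose_n_latent(x: np.ndarray, y: np.ndarray, max_latent: int, seed: int) -> int:
    best_a, best_auc = 1, -np.inf
    inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed + 1)
    for a in range(1, max_latent + 1):
        preds = np.empty(y.size)
        try:
            for train, test in inner.split(x, y):
                m = PLSRegression(n_components=a)
                m.fit(x[train], y[train])
                preds[test] = m.predict(x[test]).ravel()
            auc = _auc_mann_whitney(preds, y)
        except Exception:
            break
        if auc > best_auc + 1e-12:
            best_a, best_auc = a, auc
    return best_a


def boxplot_summary(values, group_labels) -> dict[str, BoxplotGroup]:
    """Quartiles (linear interpolation), 1.5-IQR whiskers and outliers per group."""
    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(group_labels, dtype=object).ravel()
    if values.size != groups.size:
        raise ValueError("values and group labels must align")
    out: dict[str, BoxplotGroup] = {}
    for g in dict.fromkeys(groups):  # preserve first-seen order
        v = values[groups == g]
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        in_fence = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
        out[str(g)] = BoxplotGroup(
            q1=float(q1),
            median=float(med),
            q3=float(q3),
            whisker_low=float(in_fence.min()),
            whisker_high=float(in_fence.max()),
            outliers=np.sort(v[(v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)]),
        )
    return out


def run_contrasts(
    concentrations,
    labels,
    component_names: tuple | None = None,
    seed: int = 0,
    n_latent: int | None = None,
) -> dict:
    """Evaluate the full contrast battery on a concentration matrix.

    Per-component ROC for BCC-vs-rest, BCC-vs-MM, malignant-vs-benign and
    MM-vs-PN; logistic-regression and PLS-DA ROC for malignant-vs-benign and
    MM-vs-(K+PN).  Box-plot summaries accompany each per-component contrast.
    """
    c = np.atleast_2d(np.asarray(concentrations, dtype=float))
    labels = np.asarray(labels, dtype=object).ravel()
    if c.shape[0] != labels.size:
        raise ValueError("labels must align with the concentration rows")
    names = tuple(component_names) if component_names else tuple(
        f"component_{k + 1}" for k in range(c.shape[1])
    )
    report: dict = {"per_component": {}, "logistic": {}, "plsda": {}, "boxplots": {}}

    for contrast in PER_COMPONENT_CONTRASTS:
        mask, y = contrast.select(labels)
        per_comp = {}
        for k, name in enumerate(names):
            per_comp[name] = roc_auc(c[mask, k], y)
        report["per_component"][contrast.name] = per_comp
        report["boxplots"][contrast.name] = {
            name: boxplot_summary(c[mask, k], labels[mask])
            for k, name in enumerate(names)
        }

    for contrast in MODEL_CONTRASTS:
        mask, y = contrast.select(labels)
        logit = fit_logistic(c[mask], y)
        report["logistic"][contrast.name] = {
            "report": logit,
            "roc": roc_auc(logit.predicted_probabilities, y),
        }
        # small cohorts: shrink the fold count to the minority class size
        folds = max(2, min(10, int(y.sum()), int(y.size - y.sum())))
        oof, roc, used = pls_da(c[mask], y, n_latent=n_latent, folds=folds, seed=seed)
        report["plsda"][contrast.name] = {
            "predictions": oof,
            "roc": roc,
            "n_latent": used,
        }
    return report
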
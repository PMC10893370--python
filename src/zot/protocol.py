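"""Study protocols: normalisation, feature selection, oversampling,
margin-stratified splitting, the SVM training loop, the univariate screen,
and the clinical metric suite.

Two protocols are covered.  The multivariate protocol (dual-phase design):
quartile scaling + standardisation, LASSO screening with 5-fold CV and
prior-probability sample weights, exhaustive search over feature quadruples
with a pairwise-correlation filter (|rho| >= 0.3 discards), Wilcoxon
rank-sum significance of each quadruple's linear-SVM projection with
Holm-Bonferroni correction (alpha = 1e-3), KDE + Latin-hypercube
oversampling that preserves the correlation structure, an SVM-margin
stratified train/holdout split, and 100 runs of 3-fold CV with
overfitting-aware model selection.  The univariate protocol (small
single-phase cohorts): Holm-corrected Wilcoxon over single features at
alpha = 0.05, reporting the best significant feature by informedness.

Classification metrics follow the clinical convention: sensitivity,
specificity, accuracy, predictive values, informedness (SN + SP - 1 at the
Youden cutoff) and the diagnostic odds ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import cumulative_trapezoid
from scipy.stats import qmc
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.linear_model import LassoCV, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "QuartileScaler",
    "normalize",
    "lasso_screen",
    "count_quadruples",
    "filter_quadruples",
    "QuadrupleResult",
    "rank_quadruples",
    "kde_lhs_oversample",
    "SplitPlan",
    "margin_stratified_split",
    "MarginSvmClassifier",
    "train_svm_protocol",
    "UnivariateResult",
    "univariate_screen",
    "confusion_metrics",
    "roc_analysis",
    "largest_remainder",
]


# ---------------------------------------------------------------------------
# metrics


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Clinical metrics of a confusion matrix (percentages unrounded)."""

    sn: float
    sp: float
    acc: float
    npv: float
    ppv: float
    informedness: float
    dor: float
    auc: float | None = None
    youden_cutoff: float | None = None

    def printed(self) -> dict:
        """Values rounded the way clinical tables print them.

        Percentages half-away-from-zero to integers, informedness to two
        decimals, DOR to an integer (infinite DOR stays infinite).
        """
        return {
            "SN": _round_half_away(self.sn),
            "SP": _round_half_away(self.sp),
            "ACC": _round_half_away(self.acc),
            "NPV": _round_half_away(self.npv),
            "PPV": _round_half_away(self.ppv),
            "I": round(self.informedness + 1e-12, 2),
            "DOR": math.inf if math.isinf(self.dor) else _round_half_away(self.dor),
        }


def confusion_metrics(c: ConfusionCounts) -> MetricSet:
    """SN, SP, ACC, NPV, PPV, informedness and DOR from raw counts.

    SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/n, NPV = TN/(TN+FN),
    PPV = TP/(TP+FP), I = SN + SP - 1 (as fractions), DOR = TP*TN/(FP*FN)
    (+inf when FP*FN = 0, no continuity correction).
    """
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("both classes must be present")
    sn = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.tn + c.fp)
    acc = (c.tp + c.tn) / c.n
    npv = c.tn / (c.tn + c.fn) if (c.tn + c.fn) else float("nan")
    ppv = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else float("nan")
    dor = (c.tp * c.tn) / (c.fp * c.fn) if c.fp * c.fn > 0 else math.inf
    return MetricSet(
        sn=100 * sn,
        sp=100 * sp,
        acc=100 * acc,
        npv=100 * npv,
        ppv=100 * ppv,
        informedness=sn + sp - 1,
        dor=dor,
    )


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> tuple[MetricSet, ConfusionCounts]:
    """Empirical ROC of a score: AUC, Youden-optimal cutoff and its counts.

    Positives are labelled 1 and are predicted where ``score >= cutoff``.
    The cutoff maximises SN + SP - 1; ties take the lower threshold.  The
    trapezoidal AUC equals the Mann-Whitney pairwise-comparison statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(set(labels)) != 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best = None
    for thr in np.unique(scores):  # ascending: later ties keep lower threshold via strict >
        sn = float((pos >= thr).mean())
        sp = float((neg < thr).mean())
        j = sn + sp - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, thr)
    _, cutoff = best
    counts = ConfusionCounts(
        tp=int((pos >= cutoff).sum()),
        tn=int((neg < cutoff).sum()),
        fp=int((neg >= cutoff).sum()),
        fn=int((pos < cutoff).sum()),
    )
    m = confusion_metrics(counts)
    return (
        MetricSet(
            sn=m.sn, sp=m.sp, acc=m.acc, npv=m.npv, ppv=m.ppv,
            informedness=m.informedness, dor=m.dor, auc=auc, youden_cutoff=float(cutoff),
        ),
        counts,
    )


def largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Apportion ``total`` into integer parts proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if total < 0 or weights.sum() <= 0:
        raise ValueError("invalid apportionment")
    quota = total * weights / weights.sum()
    parts = np.floor(quota).astype(int)
    rem = quota - parts
    short = total - parts.sum()
    for i in np.argsort(-rem)[:short]:
        parts[i] += 1
    return parts


def _prior_weights(y: np.ndarray) -> np.ndarray:
    """Per-sample weight equal to the empirical prior of the sample's class."""
    y = np.asarray(y).astype(int)
    p1 = y.mean()
    return np.where(y == 1, p1, 1 - p1)


# ---------------------------------------------------------------------------
# normalisation


class QuartileScaler(BaseEstimator, TransformerMixin):
    """Per-feature quartile scaling followed by standardisation.

    Each feature is linearly mapped so its first and third training
    quartiles land on 0 and 1, then standardised to zero mean and unit
    variance on the training data.  Parameters are learned in ``fit`` and
    frozen for later ``transform`` calls.  Zero-IQR features skip the
    quartile map (flagged in ``zero_iqr_``) and are standardised only;
    fully constant features map to zero.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.q1_, self.q3_ = np.percentile(X, [25, 75], axis=0)
        iqr = self.q3_ - self.q1_
        self.zero_iqr_ = iqr == 0
        self.scale_ = np.where(self.zero_iqr_, 1.0, iqr)
        scaled = (X - self.q1_) / self.scale_
        self.mean_ = scaled.mean(axis=0)
        sd = scaled.std(axis=0)
        self.std_ = np.where(sd == 0, 1.0, sd)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        scaled = (X - self.q1_) / self.scale_
        return (scaled - self.mean_) / self.std_

    def quartile_transform(self, X):
        """The intermediate quartile map alone (Q1 -> 0, Q3 -> 1)."""
        return (np.asarray(X, dtype=float) - self.q1_) / self.scale_


def normalize(table: pd.DataFrame) -> tuple[pd.DataFrame, QuartileScaler]:
    """Fit a :class:`QuartileScaler` on a feature table and transform it."""
    scaler = QuartileScaler().fit(table.values)
    out = pd.DataFrame(scaler.transform(table.values), columns=table.columns, index=table.index)
    return out, scaler


# ---------------------------------------------------------------------------
# feature selection


def lasso_screen(X, y, folds: int = 5, seed: int = 0, max_iter: int = 50_000) -> list:
    """Features with non-zero LASSO coefficient at the CV-selected penalty.

    5-fold cross-validated LASSO on the (0/1) outcome with each sample
    weighted by its class prior.  Returns column names for DataFrames,
    integer indices otherwise; the list may be empty.
    """
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(y) < folds:
        raise ValueError("need at least as many samples as folds")
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LassoCV(cv=cv, random_state=seed, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xv, y, sample_weight=_prior_weights(y))
    idx = np.flatnonzero(model.coef_ != 0)
    return [cols[i] for i in idx] if cols is not None else idx.tolist()


def count_quadruples(n: int) -> int:
    """Number of 4-feature subsets of ``n`` retained features: C(n, 4)."""
    if n < 4:
        raise ValueError("need at least 4 features")
    return math.comb(n, 4)


def filter_quadruples(
    quads: list[tuple], X, rho: float = 0.3, signed: bool = False
) -> list[tuple]:
    """Drop quadruples containing a correlated pair (|rho| >= threshold).

    Pearson correlation is computed once on the full table.  By default the
    absolute correlation is thresholded (a strong negative correlation is
    equally redundant); ``signed=True`` thresholds the raw coefficient.
    The boundary value itself is discarded.
    """
    Xv = X.values if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    corr = np.corrcoef(Xv, rowvar=False)
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(Xv.shape[1]))
    pos = {c: i for i, c in enumerate(cols)}
    out = []
    for quad in quads:
        ids = [pos[f] for f in quad]
        vals = [corr[a, b] for a, b in combinations(ids, 2)]
        vals = vals if signed else [abs(v) for v in vals]
        if all(v < rho for v in vals):
            out.append(quad)
    return out


@dataclass
class QuadrupleResult:
    """The winning quadruple of the selection search."""

    features: tuple
    scores: np.ndarray  # signed distances to the separating hyperplane
    p_adjusted: float
    informedness: float
    auc: float
    n_tested: int = 0
    n_significant: int = 0


def rank_quadruples(
    quads: list[tuple], X, y, alpha: float = 1e-3
) -> QuadrupleResult | None:
    """Pick the most informative statistically significant quadruple.

    For each quadruple a linear-kernel SVM hyperplane is fitted and samples
    are projected to their signed distance; the class difference of the
    projections is tested with the Wilcoxon rank-sum test, Holm-Bonferroni
    corrected over all tested quadruples.  Among the significant ones the
    quadruple with the highest informedness of the projection ROC wins.
    Returns None when nothing is significant.
    """
    if not quads:
        raise ValueError("no quadruples to rank")
    df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int)
    all_scores, pvals = [], []
    for quad in quads:
        sub = df[list(quad)].values
        svc = SVC(kernel="linear", C=1.0)
        svc.fit(sub, y, sample_weight=_prior_weights(y))
        s = svc.decision_function(sub)
        all_scores.append(s)
        pvals.append(float(stats.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided").pvalue))
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    best: QuadrupleResult | None = None
    for quad, s, ok, p in zip(quads, all_scores, reject, p_adj):
        if not ok:
            continue
        m, _ = roc_analysis(s, y)
        if best is None or m.informedness > best.informedness:
            best = QuadrupleResult(
                features=tuple(quad),
                scores=s,
                p_adjusted=float(p),
                informedness=m.informedness,
                auc=m.auc,
            )
    if best is not None:
        best.n_tested = len(quads)
        best.n_significant = int(reject.sum())
    return best


# ---------------------------------------------------------------------------
# oversampling


def _kde_quantile(values: np.ndarray, grid_size: int = 512):
    """Numerical quantile function of a univariate Gaussian KDE."""
    kde = stats.gaussian_kde(values)
    h = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, grid_size)
    pdf = kde(grid)
    cdf = cumulative_trapezoid(pdf, grid, initial=0.0)
    cdf /= cdf[-1]
    # make strictly increasing for interpolation
    cdf = np.maximum.accumulate(cdf)
    uniq = np.concatenate([[True], np.diff(cdf) > 0])
    return lambda u: np.interp(u, cdf[uniq], grid[uniq])


def kde_lhs_oversample(
    X,
    y,
    target_total: int | None = None,
    class_targets: dict[int, int] | None = None,
    runs: int = 1_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Augment a labelled table by KDE + Latin-hypercube sampling.

    Synthetic rows are drawn per class: each feature's univariate KDE
    supplies a quantile function and a Latin hypercube supplies the joint
    uniforms.  Among ``runs`` candidate hypercube draws the one minimising
    the Frobenius distance between the original and augmented correlation
    matrices is kept.  Original rows are retained verbatim.

    Class targets default to the largest-remainder apportionment of
    ``target_total`` by the class proportions; explicit ``class_targets``
    override it (they are part of a study's configuration).
    """
    df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    counts = {c: int((y == c).sum()) for c in classes}
    if class_targets is None:
        if target_total is None:
            raise ValueError("give target_total or class_targets")
        parts = largest_remainder(target_total, np.array([counts[c] for c in classes]))
        class_targets = {c: int(p) for c, p in zip(classes, parts)}
    for c in classes:
        if class_targets.get(c, 0) < counts[c]:
            raise ValueError(f"target for class {c} below its current count")
    rng = np.random.default_rng(seed)
    out_X = [df]
    out_y = [y]
    for c in classes:
        m = class_targets[c] - counts[c]
        if m == 0:
            continue
        sub = df[y == c].values
        quantiles = [_kde_quantile(sub[:, j]) for j in range(sub.shape[1])]
        ref_corr = np.corrcoef(sub, rowvar=False) if sub.shape[1] > 1 else None
        best_rows, best_cost = None, np.inf
        sampler = qmc.LatinHypercube(d=sub.shape[1], seed=rng)
        for _ in range(max(1, runs)):
            u = sampler.random(m)
            rows = np.column_stack([quantiles[j](u[:, j]) for j in range(sub.shape[1])])
            if ref_corr is None:
                best_rows = rows
                break
            aug = np.vstack([sub, rows])
            cost = float(np.linalg.norm(np.corrcoef(aug, rowvar=False) - ref_corr))
            if cost < best_cost:
                best_cost, best_rows = cost, rows
        out_X.append(pd.DataFrame(best_rows, columns=df.columns))
        out_y.append(np.full(m, c, dtype=int))
    X_aug = pd.concat(out_X, ignore_index=True)
    y_aug = np.concatenate(out_y)
    return X_aug, y_aug


# ---------------------------------------------------------------------------
# splitting


@dataclass
class SplitPlan:
    """A margin-stratified train/holdout partition."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    margin_class: np.ndarray  # per sample: 'correct' | 'in_margin' | 'misclassified'
    train_counts: dict[int, int] = field(default_factory=dict)
    test_counts: dict[int, int] = field(default_factory=dict)


def margin_classes(X, y) -> np.ndarray:
    """Partition samples by the signed margin of a whole-data SVM.

    ``correct`` where the signed margin exceeds 1, ``in_margin`` in [0, 1],
    ``misclassified`` below 0.
    """
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    svc = SVC(kernel="rbf", gamma="scale", C=1.0)
    svc.fit(Xv, y, sample_weight=_prior_weights(y))
    signed = (2 * y - 1) * svc.decision_function(Xv)
    out = np.where(signed > 1, "correct", np.where(signed >= 0, "in_margin", "misclassified"))
    return out.astype(object)


def margin_stratified_split(X, y, train_n: int, seed: int = 0) -> SplitPlan:
    """Random split preserving label and margin-class proportions.

    The per-label training counts follow the largest-remainder
    apportionment of ``train_n`` by label frequency; within each label the
    count is further apportioned across the three margin classes.  The
    leftover samples form the holdout set.
    """
    y = np.asarray(y).astype(int)
    n = len(y)
    if not 0 < train_n < n:
        raise ValueError("train_n must lie strictly between 0 and n")
    mc = margin_classes(X, y)
    rng = np.random.default_rng(seed)
    labels = np.unique(y)
    label_counts = np.array([(y == c).sum() for c in labels])
    label_train = largest_remainder(train_n, label_counts)
    train_idx: list[int] = []
    for c, t in zip(labels, label_train):
        idx_c = np.flatnonzero(y == c)
        cats = np.unique(mc[idx_c])
        cat_counts = np.array([(mc[idx_c] == g).sum() for g in cats])
        if (cat_counts < 2).any():
            warnings.warn("margin class with fewer than 2 members; degenerate assignment")
        cat_train = largest_remainder(int(t), cat_counts)
        for g, k in zip(cats, cat_train):
            pool = idx_c[mc[idx_c] == g]
            pick = rng.choice(pool, size=int(k), replace=False)
            train_idx.extend(pick.tolist())
    train = np.sort(np.array(train_idx, dtype=int))
    test = np.setdiff1d(np.arange(n), train)
    return SplitPlan(
        train_idx=train,
        test_idx=test,
        margin_class=mc,
        train_counts={int(c): int((y[train] == c).sum()) for c in labels},
        test_counts={int(c): int((y[test] == c).sum()) for c in labels},
    )


# ---------------------------------------------------------------------------
# SVM training loop


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold assignment, classes apportioned by largest remainder."""
    n = len(y)
    assign = np.empty(n, dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        sizes = largest_remainder(len(idx), np.ones(folds))
        # rotate which fold gets the remainder so folds stay balanced overall
        start = int(rng.integers(folds))
        sizes = np.roll(sizes, start)
        bounds = np.cumsum(sizes)[:-1]
        for f, part in enumerate(np.split(idx, bounds)):
            assign[part] = f
    return assign


def _cv_auc(Xv, y, gamma, C, assign, folds):
    """Mean train-fold and validation-fold AUC of an SVM at (gamma, C)."""
    aucs_tr, aucs_va = [], []
    for f in range(folds):
        tr = assign != f
        va = ~tr
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            continue
        svc = SVC(kernel="rbf", gamma=gamma, C=C)
        svc.fit(Xv[tr], y[tr], sample_weight=_prior_weights(y[tr]))
        aucs_tr.append(roc_auc_score(y[tr], svc.decision_function(Xv[tr])))
        aucs_va.append(roc_auc_score(y[va], svc.decision_function(Xv[va])))
    if not aucs_tr:
        return 0.0, 0.0
    return float(np.mean(aucs_tr)), float(np.mean(aucs_va))


@dataclass
class ProtocolModel:
    """Final model of the CV training loop, with its audit trail."""

    svc: SVC
    calibrator: LogisticRegression
    gamma: float
    C: float
    train_metrics: MetricSet
    train_counts: ConfusionCounts
    n_surviving_runs: int
    fallback: bool = False

    def decision_function(self, X) -> np.ndarray:
        return self.svc.decision_function(np.asarray(X, dtype=float))

    def predict_proba(self, X) -> np.ndarray:
        return self.calibrator.predict_proba(self.decision_function(X).reshape(-1, 1))

    def predict(self, X) -> np.ndarray:
        cut = self.train_metrics.youden_cutoff or 0.0
        return (self.decision_function(X) >= cut).astype(int)

    def evaluate(self, X, y) -> tuple[MetricSet, ConfusionCounts]:
        """Holdout metrics at the training Youden cutoff."""
        s = self.decision_function(X)
        y = np.asarray(y).astype(int)
        cut = self.train_metrics.youden_cutoff or 0.0
        counts = ConfusionCounts(
            tp=int(((s >= cut) & (y == 1)).sum()),
            tn=int(((s < cut) & (y == 0)).sum()),
            fp=int(((s >= cut) & (y == 0)).sum()),
            fn=int(((s < cut) & (y == 1)).sum()),
        )
        m = confusion_metrics(counts)
        auc = float(roc_auc_score(y, s))
        return (
            MetricSet(
                sn=m.sn, sp=m.sp, acc=m.acc, npv=m.npv, ppv=m.ppv,
                informedness=m.informedness, dor=m.dor, auc=auc, youden_cutoff=cut,
            ),
            counts,
        )


def train_svm_protocol(
    X,
    y,
    runs: int = 100,
    folds: int = 3,
    seed: int = 0,
    tune_evals: int = 16,
    gamma_range: tuple[float, float] = (1e-3, 1e2),
    C_range: tuple[float, float] = (1e-2, 1e3),
) -> ProtocolModel:
    """The repeated-CV SVM training loop with overfitting-aware selection.

    Per run, folds are re-drawn stratified and the RBF-SVM hyperparameters
    (gamma, C) are tuned by seeded random search over log-space on the mean
    validation-fold AUC (any derivative-free tuner with the same budget is
    protocol-equivalent).  Runs whose train-fold AUC is lower than their
    validation-fold AUC are discarded as overfitting-suspect; among the
    survivors the run with the highest train-fold AUC leads, every survivor
    is refitted on all folds, and the ultimate model maximises
    (informedness, AUC) on the training set.  Probabilities come from a
    binomial-logit calibration of the decision values.  If every run is
    discarded the best validation-AUC run is kept with a warning.
    """
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    records = []
    for r in range(runs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        assign = _stratified_folds(y, folds, rng)
        log_g = rng.uniform(np.log10(gamma_range[0]), np.log10(gamma_range[1]), tune_evals)
        log_c = rng.uniform(np.log10(C_range[0]), np.log10(C_range[1]), tune_evals)
        best = None
        for g, c in zip(10.0**log_g, 10.0**log_c):
            auc_tr, auc_va = _cv_auc(Xv, y, g, c, assign, folds)
            if best is None or auc_va > best[1]:
                best = (auc_tr, auc_va, g, c)
        records.append(best)
    surviving = [rec for rec in records if rec[0] >= rec[1]]
    fallback = not surviving
    if fallback:
        warnings.warn("all runs discarded by the overfitting rule; keeping best validation AUC")
        surviving = [max(records, key=lambda rec: rec[1])]
    surviving.sort(key=lambda rec: -rec[0])  # highest train-fold AUC leads
    best_model = None
    for auc_tr, auc_va, g, c in surviving:
        svc = SVC(kernel="rbf", gamma=g, C=c)
        svc.fit(Xv, y, sample_weight=_prior_weights(y))
        m, counts = roc_analysis(svc.decision_function(Xv), y)
        key = (m.informedness, m.auc)
        if best_model is None or key > best_model[0]:
            best_model = (key, svc, m, counts, g, c)
    _, svc, m, counts, g, c = best_model
    calib = LogisticRegression()
    calib.fit(svc.decision_function(Xv).reshape(-1, 1), y)
    return ProtocolModel(
        svc=svc,
        calibrator=calib,
        gamma=g,
        C=c,
        train_metrics=m,
        train_counts=counts,
        n_surviving_runs=len(surviving) if not fallback else 0,
        fallback=fallback,
    )


class MarginSvmClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style front end to the repeated-CV SVM protocol.

    ``fit`` runs :func:`train_svm_protocol`; predictions threshold the
    decision value at the training Youden cutoff, and ``predict_proba``
    uses the binomial-logit calibration.
    """

    def __init__(
        self,
        runs: int = 100,
        folds: int = 3,
        seed: int = 0,
        tune_evals: int = 16,
        gamma_range: tuple[float, float] = (1e-3, 1e2),
        C_range: tuple[float, float] = (1e-2, 1e3),
    ):
        self.runs = runs
        self.folds = folds
        self.seed = seed
        self.tune_evals = tune_evals
        self.gamma_range = gamma_range
        self.C_range = C_range

    def fit(self, X, y):
        self.model_ = train_svm_protocol(
            X,
            y,
            runs=self.runs,
            folds=self.folds,
            seed=self.seed,
            tune_evals=self.tune_evals,
            gamma_range=self.gamma_range,
            C_range=self.C_range,
        )
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        return self.model_.decision_function(X)

    def predict(self, X):
        return self.model_.predict(X)

    def predict_proba(self, X):
        return self.model_.predict_proba(X)


# ---------------------------------------------------------------------------
# univariate screen


@dataclass
class UnivariateResult:
    """Best significant single feature of the univariate screen."""

    feature: object
    p_adjusted: float
    metrics: MetricSet
    counts: ConfusionCounts
    median_pos: float
    iqr_pos: float
    median_neg: float
    iqr_neg: float
    flipped: bool  # True when lower values indicate the positive class


def univariate_screen(X, y, alpha: float = 0.05) -> UnivariateResult | None:
    """Holm-corrected Wilcoxon screen over single features.

    Every feature is rank-sum tested between the classes (two-sided) and
    Holm-Bonferroni corrected; among the significant ones the feature whose
    ROC attains the highest informedness is reported with its Youden-cutoff
    metrics and per-class median/IQR.  Returns None when no feature is
    significant — a valid outcome on small cohorts.
    """
    df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    pvals = [
        float(stats.mannwhitneyu(df[c][y == 1], df[c][y == 0], alternative="two-sided").pvalue)
        for c in df.columns
    ]
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    best: UnivariateResult | None = None
    for col, ok, p in zip(df.columns, reject, p_adj):
        if not ok:
            continue
        v = df[col].values.astype(float)
        flipped = roc_auc_score(y, v) < 0.5
        m, counts = roc_analysis(-v if flipped else v, y)
        if best is None or m.informedness > best.metrics.informedness:
            vp, vn = v[y == 1], v[y == 0]
            best = UnivariateResult(
                feature=col,
                p_adjusted=float(p),
                metrics=m,
                counts=counts,
                median_pos=float(np.median(vp)),
                iqr_pos=float(np.subtract(*np.percentile(vp, [75, 25]))),
                median_neg=float(np.median(vn)),
                iqr_neg=float(np.subtract(*np.percentile(vn, [75, 25]))),
                flipped=bool(flipped),
            )
    return best
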
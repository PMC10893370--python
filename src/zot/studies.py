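"""End-to-end study drivers tying the protocol stages together.

``run_multivariate_study`` is the dual-phase design: normalisation, LASSO
screening, quadruple search with correlation filter and Holm-corrected
Wilcoxon significance, KDE+LHS oversampling of the winning quadruple,
margin-stratified train/holdout split and the repeated-CV SVM loop.
``run_univariate_study`` is the small-cohort design: a Holm-corrected
Wilcoxon screen of single features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .protocol import (
    ConfusionCounts,
    MetricSet,
    ProtocolModel,
    QuadrupleResult,
    SplitPlan,
    UnivariateResult,
    count_quadruples,
    filter_quadruples,
    kde_lhs_oversample,
    lasso_screen,
    margin_stratified_split,
    normalize,
    rank_quadruples,
    train_svm_protocol,
    univariate_screen,
)

__all__ = ["MultivariateStudyResult", "run_multivariate_study", "run_univariate_study"]


@dataclass
class MultivariateStudyResult:
    """Audit trail of one dual-phase study."""

    retained: list
    n_quadruples: int
    n_uncorrelated: int
    quadruple: QuadrupleResult | None
    split: SplitPlan | None = None
    model: ProtocolModel | None = None
    train_metrics: MetricSet | None = None
    train_counts: ConfusionCounts | None = None
    test_metrics: MetricSet | None = None
    test_counts: ConfusionCounts | None = None
    oversampled_n: dict[int, int] = field(default_factory=dict)


def run_multivariate_study(
    table: pd.DataFrame,
    label_col: str = "label",
    seed: int = 0,
    rho: float = 0.3,
    alpha: float = 1e-3,
    class_targets: dict[int, int] | None = None,
    oversample_factor: float = 169 / 89,
    train_fraction: float = 117 / 169,
    runs: int = 100,
    folds: int = 3,
    tune_evals: int = 16,
    lhs_runs: int = 1_000,
    max_quadruples: int | None = None,
) -> MultivariateStudyResult:
    """Full feature-selection + SVM protocol on a labelled feature table.

    The oversampling target defaults to ``oversample_factor`` times the
    cohort size (the reference design augments 89 to 169) and the training
    share to ``train_fraction`` of the augmented cohort (117 of 169);
    explicit ``class_targets`` override the per-class oversampling counts.
    ``max_quadruples`` caps the exhaustive search for very wide screens.
    """
    y = table[label_col].to_numpy().astype(int)
    X = table.drop(columns=[label_col])
    X = X.loc[:, X.notna().all()]  # drop features with undefined values
    Xn, _ = normalize(X)
    retained = lasso_screen(Xn, y, seed=seed)
    if len(retained) < 4:
        return MultivariateStudyResult(
            retained=list(retained), n_quadruples=0, n_uncorrelated=0, quadruple=None
        )
    quads = list(combinations(retained, 4))
    n_quads = count_quadruples(len(retained))
    surviving = filter_quadruples(quads, Xn[retained], rho=rho)
    n_uncorr = len(surviving)
    if max_quadruples is not None and len(surviving) > max_quadruples:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(surviving), size=max_quadruples, replace=False)
        surviving = [surviving[i] for i in sorted(keep)]
    best = rank_quadruples(surviving, Xn, y, alpha=alpha) if surviving else None
    result = MultivariateStudyResult(
        retained=list(retained),
        n_quadruples=n_quads,
        n_uncorrelated=n_uncorr,
        quadruple=best,
    )
    if best is None:
        return result
    Xq = Xn[list(best.features)]
    if class_targets is None:
        target_total = int(round(oversample_factor * len(y)))
        X_aug, y_aug = kde_lhs_oversample(Xq, y, target_total=target_total, runs=lhs_runs, seed=seed)
    else:
        X_aug, y_aug = kde_lhs_oversample(Xq, y, class_targets=class_targets, runs=lhs_runs, seed=seed)
    result.oversampled_n = {int(c): int((y_aug == c).sum()) for c in np.unique(y_aug)}
    train_n = int(round(train_fraction * len(y_aug)))
    split = margin_stratified_split(X_aug, y_aug, train_n=train_n, seed=seed)
    result.split = split
    model = train_svm_protocol(
        X_aug.iloc[split.train_idx],
        y_aug[split.train_idx],
        runs=runs,
        folds=folds,
        seed=seed,
        tune_evals=tune_evals,
    )
    result.model = model
    result.train_metrics = model.train_metrics
    result.train_counts = model.train_counts
    result.test_metrics, result.test_counts = model.evaluate(
        X_aug.iloc[split.test_idx], y_aug[split.test_idx]
    )
    return result


def run_univariate_study(
    table: pd.DataFrame, label_col: str = "label", alpha: float = 0.05
) -> UnivariateResult | None:
    """Univariate Wilcoxon screen on a labelled feature table."""
    y = table[label_col].to_numpy().astype(int)
    X = table.drop(columns=[label_col])
    X = X.loc[:, X.notna().all()]
    Xn, _ = normalize(X)
    return univariate_screen(Xn, y, alpha=alpha)
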
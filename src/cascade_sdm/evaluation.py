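"""Model validation: confusion matrices, Cohen's kappa, ROC cutoffs, k-fold CV.

Kappa is the chance-corrected agreement

    k = [(TP+TN) - E] / [n - E],   E = [(TP+FN)(TP+FP) + (FP+TN)(FN+TN)] / n,

interpreted heuristically on the Landis–Koch scale.  The asymptotic
confidence interval uses the large-sample kappa variance of Fleiss, Cohen &
Everitt (1969).  Network outputs are binarized at the cutoff maximizing
Youden's J on a ROC curve, because class imbalance usually pushes the best
threshold away from the neutral 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .dataset import SurveyDataset, stratified_folds
from .exceptions import ConfigError, DegenerateError, DomainError

__all__ = [
    "ConfusionMatrix",
    "KappaResult",
    "RocResult",
    "CvReport",
    "FoldResult",
    "binarize",
    "confusion",
    "cohen_kappa",
    "kappa_ci",
    "landis_koch",
    "roc_analysis",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts of binary predictions against observations."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DomainError("counts must be nonnegative")
        if self.n < 1:
            raise DomainError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def scaled(self, factor: int) -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp * factor, self.fp * factor, self.fn * factor, self.tn * factor
        )


@dataclass(frozen=True)
class KappaResult:
    k: float
    ci_low: float
    ci_high: float
    ci_method: str
    label: str


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    best_cutoff: float


def binarize(scores, cutoff: float) -> np.ndarray:
    """1 where score >= cutoff, else 0 (score equal to the cutoff counts as presence)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise DomainError("scores must lie in [0, 1]")
    return (scores >= cutoff).astype(int)


def confusion(pred, obs) -> ConfusionMatrix:
    pred = np.asarray(pred)
    obs = np.asarray(obs)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size == 0:
        raise DomainError(f"expected equal-length non-empty vectors, got {pred.shape}, {obs.shape}")
    return ConfusionMatrix(
        tp=int(((pred == 1) & (obs == 1)).sum()),
        fp=int(((pred == 1) & (obs == 0)).sum()),
        fn=int(((pred == 0) & (obs == 1)).sum()),
        tn=int(((pred == 0) & (obs == 0)).sum()),
    )


def _expected_agreement(m: ConfusionMatrix) -> float:
    return ((m.tp + m.fn) * (m.tp + m.fp) + (m.fp + m.tn) * (m.fn + m.tn)) / m.n


def cohen_kappa(m: ConfusionMatrix, alpha: float = 0.05, ci_method: str = "asymptotic") -> KappaResult:
    """Cohen's kappa of a confusion matrix, with CI and Landis–Koch label."""
    e = _expected_agreement(m)
    if m.n - e == 0:
        raise DegenerateError("chance agreement equals n; kappa undefined")
    k = ((m.tp + m.tn) - e) / (m.n - e)
    low, high = kappa_ci(m, alpha)
    return KappaResult(k=float(k), ci_low=low, ci_high=high, ci_method=ci_method, label=landis_koch(k))


def kappa_ci(m: ConfusionMatrix, alpha: float = 0.05) -> tuple[float, float]:
    """Normal-approximation interval k +/- z * SE(k), clipped to [-1, 1].

    SE is the large-sample standard error of Fleiss, Cohen & Everitt (1969).
    """
    e = _expected_agreement(m)
    if m.n - e == 0:
        raise DegenerateError("chance agreement equals n; kappa undefined")
    n = m.n
    k = ((m.tp + m.tn) - e) / (n - e)
    pe = e / n

    # cell proportions: rows = predicted class (0, 1), cols = observed class
    p = np.array([[m.tn, m.fn], [m.fp, m.tp]], dtype=float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    a = sum(
        p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - k)) ** 2 for i in range(2)
    )
    b = (1.0 - k) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    c = (k - pe * (1.0 - k)) ** 2
    var = max(a + b - c, 0.0) / (n * (1.0 - pe) ** 2)
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return (float(max(k - half, -1.0)), float(min(k + half, 1.0)))


_LANDIS_KOCH = (
    (0.0, "poor"),
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "almost_perfect"),
)

#: coarser field-usage aliases for the top two Landis–Koch bands
LANDIS_KOCH_ALIASES = {"substantial": "good", "almost_perfect": "very good"}


def landis_koch(k: float, alias: bool = False) -> str:
    """Landis–Koch agreement band of a kappa value (upper bounds inclusive)."""
    if not -1.0 <= k <= 1.0:
        raise DomainError(f"kappa must lie in [-1, 1], got {k}")
    for upper, label in _LANDIS_KOCH:
        if k <= upper:
            return LANDIS_KOCH_ALIASES.get(label, label) if alias else label
    raise AssertionError("unreachable")


def roc_analysis(scores, obs) -> RocResult:
    """ROC curve over all distinct score thresholds, AUC, and best cutoff.

    The best cutoff maximizes Youden's J = sensitivity + specificity - 1 over
    the midpoints between adjacent distinct scores; exact ties are broken
    toward the candidate nearest 0.5.  With fewer than two distinct scores
    the cutoff falls back to the neutral 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    obs = np.asarray(obs)
    if scores.shape != obs.shape or scores.ndim != 1:
        raise DomainError("scores and observations must be equal-length vectors")
    pos = obs == 1
    neg = obs == 0
    if not pos.any() or not neg.any():
        raise DegenerateError("observations contain a single class; ROC undefined")
    n_pos, n_neg = int(pos.sum()), int(neg.sum())

    distinct = np.unique(scores)
    sens = np.array([(scores[pos] >= t).sum() / n_pos for t in distinct])
    spec = np.array([(scores[neg] < t).sum() / n_neg for t in distinct])

    # AUC by trapezoid over (FPR, TPR), with the (0,0) endpoint above max score
    fpr = np.concatenate([[0.0], (1.0 - spec)[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    auc = float(np.trapezoid(tpr, fpr))

    if distinct.size < 2:
        best = 0.5
    else:
        candidates = (distinct[:-1] + distinct[1:]) / 2.0
        js = np.array(
            [
                (scores[pos] >= c).sum() / n_pos + (scores[neg] < c).sum() / n_neg - 1.0
                for c in candidates
            ]
        )
        top = np.flatnonzero(js == js.max())
        best = float(candidates[top[np.argmin(np.abs(candidates[top] - 0.5))]])
    return RocResult(
        thresholds=distinct,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        best_cutoff=best,
    )


# -- cross-validation ---------------------------------------------------------


@dataclass(frozen=True)
class FoldResult:
    fold: int
    matrix: ConfusionMatrix
    kappa: KappaResult
    cutoff: float


@dataclass
class CvReport:
    """Per-fold confusion matrices and kappas, their median, and the median fold."""

    folds: list[FoldResult]
    median_k: float
    median_fold_matrix: ConfusionMatrix
    ci_method: str = "asymptotic"
    fold_ci: tuple[float, float] | None = field(default=None)

    def median_fold(self) -> FoldResult:
        deltas = [abs(f.kappa.k - self.median_k) for f in self.folds]
        return self.folds[int(np.argmin(deltas))]

    def kappa_interval(self) -> tuple[float, float]:
        """CI on the median-fold matrix (asymptotic) or across fold kappas."""
        if self.ci_method == "folds":
            assert self.fold_ci is not None
            return self.fold_ci
        return kappa_ci(self.median_fold_matrix)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "fold": f.fold,
                    "TP": f.matrix.tp,
                    "FP": f.matrix.fp,
                    "FN": f.matrix.fn,
                    "TN": f.matrix.tn,
                    "kappa": f.kappa.k,
                    "cutoff": f.cutoff,
                }
                for f in self.folds
            ]
        )

    def to_json_dict(self) -> dict:
        m = self.median_fold_matrix
        return {
            "folds": self.to_frame().to_dict(orient="records"),
            "median_k": self.median_k,
            "median_fold_matrix": {"TP": m.tp, "FP": m.fp, "FN": m.fn, "TN": m.tn},
            "ci_method": self.ci_method,
        }


def _fold_kappa(matrix: ConfusionMatrix) -> KappaResult:
    try:
        return cohen_kappa(matrix)
    except DegenerateError:
        # a fold where kappa's denominator vanishes carries no agreement
        # information beyond chance; score it as chance-level
        return KappaResult(0.0, 0.0, 0.0, "degenerate", landis_koch(0.0))


def cross_validate(
    data: SurveyDataset,
    target: str,
    model_factory,
    folds: int = 5,
    seed: int = 0,
    cutoff_mode: str = "test",
    ci_method: str = "asymptotic",
    alpha: float = 0.05,
) -> CvReport:
    """Stratified k-fold cross-validation of any trainable occurrence model.

    ``model_factory(train_data, seed)`` must return an object with a
    ``predict_scores(data) -> probabilities`` method.  Per fold, the ROC
    cutoff is chosen on the held-out fold's scores (``cutoff_mode="test"``,
    mirroring cutoff selection "taking into account the test set") or on the
    training scores (``cutoff_mode="train"``, leakage-free).
    """
    if cutoff_mode not in ("test", "train"):
        raise ConfigError(f"unknown cutoff_mode {cutoff_mode!r}")
    assignment = stratified_folds(data, target, k=folds, seed=seed)
    fold_seeds = np.random.SeedSequence(seed).generate_state(folds)
    results: list[FoldResult] = []
    for i in range(folds):
        train_data = data.subset_sites(np.flatnonzero(assignment != i))
        test_data = data.subset_sites(np.flatnonzero(assignment == i))
        model = model_factory(train_data, int(fold_seeds[i]))
        scores = np.asarray(model.predict_scores(test_data), dtype=float)
        y_test = test_data.species_vector(target)
        if cutoff_mode == "test":
            cutoff = roc_analysis(scores, y_test).best_cutoff
        else:
            train_scores = np.asarray(model.predict_scores(train_data), dtype=float)
            cutoff = roc_analysis(train_scores, train_data.species_vector(target)).best_cutoff
        matrix = confusion(binarize(scores, cutoff), y_test)
        results.append(FoldResult(i, matrix, _fold_kappa(matrix), cutoff))

    ks = np.array([f.kappa.k for f in results])
    median_k = float(np.median(ks))
    median_fold = results[int(np.argmin(np.abs(ks - median_k)))]
    fold_ci = None
    if ci_method == "folds":
        sd = float(ks.std(ddof=1))
        half = float(t_dist.ppf(1.0 - alpha / 2.0, folds - 1)) * sd / np.sqrt(folds)
        mean = float(ks.mean())
        fold_ci = (max(mean - half, -1.0), min(mean + half, 1.0))
    return CvReport(
        folds=results,
        median_k=median_k,
        median_fold_matrix=median_fold.matrix,
        ci_method=ci_method,
        fold_ci=fold_ci,
    )
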
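"""Gene-centric evaluation of triage classifiers.

Article-level recall alone does not tell a curation team what it cares
about: how many of the curator-accepted *genes* survive the triage cut.
This module therefore implements, besides the usual confusion-matrix
metrics, the gene-centric ones:

* **gene recall** — unique curated genes recoverable from articles the
  classifier labels positive, over the genes in all truly positive
  articles;
* **F-gene score** — harmonic mean of gene recall and precision;
* **workload saving** — (TN + FN) / N, the fraction of articles excused
  from manual reading;
* the **95%-gene-recall operating point** — the largest probability
  threshold that still recovers at least 95% of the curated genes, which
  by construction maximises workload saving subject to that constraint.

Ranking quality is measured by AUROC (Mann-Whitney rank form), the
interpolated area under the precision-recall curve, DeLong's paired test
for comparing correlated ROC curves, and cross-validated AUCPR
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ScoredTestSet",
    "ConfusionSummary",
    "MetricReport",
    "ThresholdResult",
    "GeneBookkeepingError",
    "confusion_at",
    "triage_metrics",
    "gene_recall_threshold",
    "roc_auc",
    "roc_auc_scores",
    "roc_curve_points",
    "pr_auc",
    "pr_curve_points",
    "delong_test",
    "cv_aucpr_ci",
    "evaluate_cell",
    "evaluate_grid",
]


class GeneBookkeepingError(ValueError):
    """Gene sets are inconsistent with the labels (e.g. empty gene union)."""


@dataclass
class ScoredTestSet:
    """Probabilities and ground truth for one scored test corpus."""

    pmids: list[str]
    labels: np.ndarray
    probabilities: np.ndarray
    gene_sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if not (len(self.pmids) == len(self.labels) == len(self.probabilities)):
            raise ValueError("pmids, labels and probabilities must be equal length")
        positives = {p for p, y in zip(self.pmids, self.labels) if y == 1}
        stray = set(self.gene_sets) - positives
        if stray:
            raise GeneBookkeepingError(
                f"gene sets recorded for non-positive pmids: {sorted(stray)[:5]}"
            )


@dataclass(frozen=True)
class ConfusionSummary:
    TP: int
    FP: int
    TN: int
    FN: int
    threshold: float

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricReport:
    recall: float
    precision: float
    gene_recall: float
    workload_saving: float
    f1: float
    f_gene: float
    threshold: float
    auroc: float = float("nan")
    aucpr: float = float("nan")
    aucpr_ci: tuple[float, float] = (float("nan"), float("nan"))

    def as_dict(self) -> dict[str, float]:
        d = self.__dict__.copy()
        lo, hi = d.pop("aucpr_ci")
        d["aucpr_ci_low"], d["aucpr_ci_high"] = lo, hi
        return d


@dataclass
class ThresholdResult:
    threshold: float
    confusion: ConfusionSummary
    report: MetricReport


def confusion_at(scored: ScoredTestSet, threshold: float) -> ConfusionSummary:
    """Confusion summary with predicted positive iff probability >= threshold."""
    pred = scored.probabilities >= threshold
    y = scored.labels == 1
    return ConfusionSummary(
        TP=int(np.sum(pred & y)),
        FP=int(np.sum(pred & ~y)),
        TN=int(np.sum(~pred & ~y)),
        FN=int(np.sum(~pred & y)),
        threshold=float(threshold),
    )


def _harmonic(a: float, b: float) -> float:
    return 2 * a * b / (a + b) if (a + b) > 0 else 0.0


def _gene_recall(scored: ScoredTestSet, threshold: float) -> float:
    all_genes: set[str] = set()
    found_genes: set[str] = set()
    for pmid, y, p in zip(scored.pmids, scored.labels, scored.probabilities):
        if y == 1:
            genes = scored.gene_sets.get(pmid, set())
            all_genes |= genes
            if p >= threshold:
                found_genes |= genes
    if not all_genes:
        raise GeneBookkeepingError("no curated genes recorded for any positive article")
    return len(found_genes) / len(all_genes)


def triage_metrics(confusion: ConfusionSummary, scored: ScoredTestSet) -> MetricReport:
    """Recall, precision, gene recall, workload saving, F1 and F-gene.

    Conventions: precision is 0 when nothing is predicted positive;
    recall is 0 when there are no positives; an empty union of curated
    genes over the positive articles is an error, not a 0/0.
    """
    tp, fp, tn, fn = confusion.TP, confusion.FP, confusion.TN, confusion.FN
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    gene_recall = _gene_recall(scored, confusion.threshold)
    workload_saving = (tn + fn) / confusion.n if confusion.n else 0.0
    return MetricReport(
        recall=recall,
        precision=precision,
        gene_recall=gene_recall,
        workload_saving=workload_saving,
        f1=_harmonic(recall, precision),
        f_gene=_harmonic(gene_recall, precision),
        threshold=confusion.threshold,
    )


def gene_recall_threshold(scored: ScoredTestSet, target: float = 0.95) -> ThresholdResult:
    """Largest probability threshold with gene recall >= ``target``.

    Candidate thresholds are the distinct predicted probabilities,
    scanned in descending order; because gene recall is non-decreasing
    as the threshold drops, the first feasible candidate is the largest,
    and it maximises workload saving subject to the gene-recall
    constraint.
    """
    if not any(
        scored.gene_sets.get(p) for p, y in zip(scored.pmids, scored.labels) if y == 1
    ):
        raise GeneBookkeepingError("need at least one positive article with genes")
    all_genes: set[str] = set()
    for pmid, y in zip(scored.pmids, scored.labels):
        if y == 1:
            all_genes |= scored.gene_sets.get(pmid, set())
    order = np.argsort(-scored.probabilities, kind="stable")
    covered: set[str] = set()
    chosen: float | None = None
    thresholds = np.unique(scored.probabilities)[::-1]
    ti = 0
    i = 0
    for t in thresholds:
        while i < len(order) and scored.probabilities[order[i]] >= t:
            k = order[i]
            if scored.labels[k] == 1:
                covered |= scored.gene_sets.get(scored.pmids[k], set())
            i += 1
        if len(covered) / len(all_genes) >= target:
            chosen = float(t)
            break
        ti += 1
    if chosen is None:
        raise GeneBookkeepingError(
            "gene-recall target unreachable even at the lowest threshold; "
            "check gene bookkeeping"
        )
    confusion = confusion_at(scored, chosen)
    report = triage_metrics(confusion, scored)
    return ThresholdResult(threshold=chosen, confusion=confusion, report=report)


def _check_two_classes(labels: np.ndarray) -> tuple[int, int]:
    m = int(np.sum(labels == 1))
    n = int(np.sum(labels == 0))
    if m == 0 or n == 0:
        raise ValueError("AUROC undefined with a single class")
    return m, n


def roc_auc_scores(labels, probabilities) -> float:
    """AUROC as the Mann-Whitney statistic P(s+ > s-) + 0.5 P(tie)."""
    labels = np.asarray(labels, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    m, n = _check_two_classes(labels)
    ranks = rankdata(probabilities)  # midranks handle ties
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2) / (m * n))


def roc_auc(scored: ScoredTestSet) -> float:
    return roc_auc_scores(scored.labels, scored.probabilities)


def roc_curve_points(labels, probabilities) -> pd.DataFrame:
    """Empirical ROC points (threshold, FPR, TPR), thresholds descending."""
    labels = np.asarray(labels, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    m, n = _check_two_classes(labels)
    rows = [{"threshold": np.inf, "fpr": 0.0, "tpr": 0.0}]
    for t in np.unique(probabilities)[::-1]:
        pred = probabilities >= t
        rows.append(
            {
                "threshold": float(t),
                "fpr": float(np.sum(pred & (labels == 0)) / n),
                "tpr": float(np.sum(pred & (labels == 1)) / m),
            }
        )
    return pd.DataFrame(rows)


def roc_auc_trapezoid(labels, probabilities) -> float:
    """Trapezoidal area under the empirical ROC curve (cross-check form)."""
    pts = roc_curve_points(labels, probabilities)
    return float(np.trapezoid(pts["tpr"], pts["fpr"]))


def _pr_operating_points(labels, probabilities) -> list[tuple[int, int]]:
    """(TP, FP) at each distinct threshold, descending, starting at (0, 0)."""
    labels = np.asarray(labels, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    pts = [(0, 0)]
    for t in np.unique(probabilities)[::-1]:
        pred = probabilities >= t
        pts.append(
            (int(np.sum(pred & (labels == 1))), int(np.sum(pred & (labels == 0))))
        )
    return pts


def pr_auc_scores(labels, probabilities) -> float:
    """Interpolated area under the precision-recall curve.

    Between consecutive operating points, TP and FP are interpolated
    linearly and precision is integrated over recall in closed form
    (the continuous estimator, as in the PRROC R package), rather than
    the step-function average-precision estimator.
    """
    labels = np.asarray(labels, dtype=int)
    P = int(np.sum(labels == 1))
    if P == 0:
        raise ValueError("AUCPR undefined with no positive articles")
    pts = _pr_operating_points(labels, probabilities)
    area = 0.0
    for (tp1, fp1), (tp2, fp2) in zip(pts[:-1], pts[1:]):
        dtp = tp2 - tp1
        if dtp == 0:
            continue  # no recall change on this segment
        dfp = fp2 - fp1
        a, b = float(tp1), float(dtp)
        c, d = float(tp1 + fp1), float(dtp + dfp)
        # integral of precision over the segment, s in [0, 1]:
        #   I = \int (a + b s) / (c + d s) ds
        if c == 0.0 and a == 0.0:
            seg = b / d  # precision constant along a segment from the origin
        elif d == 0.0:
            seg = (a + b / 2.0) / c
        else:
            seg = b / d + (a - b * c / d) * np.log((c + d) / c) / d
        area += (dtp / P) * seg
    return float(area)


def pr_auc(scored: ScoredTestSet) -> float:
    return pr_auc_scores(scored.labels, scored.probabilities)


def pr_curve_points(labels, probabilities) -> pd.DataFrame:
    """Empirical precision-recall points at each distinct threshold."""
    labels = np.asarray(labels, dtype=int)
    P = int(np.sum(labels == 1))
    rows = []
    for (tp, fp), t in zip(
        _pr_operating_points(labels, probabilities)[1:],
        np.unique(np.asarray(probabilities, dtype=float))[::-1],
    ):
        rows.append(
            {
                "threshold": float(t),
                "recall": tp / P,
                "precision": tp / (tp + fp) if (tp + fp) else 1.0,
            }
        )
    return pd.DataFrame(rows)


def _midrank(x: np.ndarray) -> np.ndarray:
    return rankdata(x)


def delong_test(
    scored_a: ScoredTestSet, scored_b: ScoredTestSet
) -> tuple[float, float, float, float]:
    """DeLong's paired test comparing two correlated ROC AUCs.

    Both scorers must score the same articles with the same labels.
    Uses the placement-value (structural-component) formulation with
    midranks for ties; returns (auc_a, auc_b, z, two-sided p).
    """
    if scored_a.pmids != scored_b.pmids or not np.array_equal(
        scored_a.labels, scored_b.labels
    ):
        raise ValueError("DeLong comparison requires paired test sets")
    labels = scored_a.labels
    m, n = _check_two_classes(labels)
    pos = labels == 1
    scores = np.vstack([scored_a.probabilities, scored_b.probabilities])
    k = scores.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        x, y = scores[r, pos], scores[r, ~pos]
        tx = _midrank(x)
        ty = _midrank(y)
        tz = _midrank(np.concatenate([x, y]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
        v01[r] = (tz[:m] - tx) / n  # placement of each positive among negatives
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01)
    s10 = np.cov(v10)
    var = s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    var = var / m + (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n
    diff = aucs[0] - aucs[1]
    if var <= 0:
        z = 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    else:
        z = float(diff / np.sqrt(var))
    p = float(2 * norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), z, p


def cv_aucpr_ci(
    X,
    y,
    spec,
    folds: int = 5,
    seed: int = 0,
    t_interval: bool = False,
) -> tuple[float, tuple[float, float], list[float]]:
    """Stratified k-fold cross-validated AUCPR with a 95% CI.

    Each fold's AUCPR is computed on the held-out articles of a model
    fitted on the remaining folds.  The default interval is the normal
    one, mean +/- 1.96 sd/sqrt(k); ``t_interval`` switches to the
    t-quantile version.
    """
    from .classify import train as _train, predict_proba as _predict

    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**32))
    per_fold: list[float] = []
    for tr, te in skf.split(np.zeros(len(y)), y):
        if len(np.unique(y[te])) < 2:
            raise ValueError("a CV fold lacks positives; use fewer folds or more data")
        Xtr = X[tr] if sp.issparse(X) else np.asarray(X)[tr]
        Xte = X[te] if sp.issparse(X) else np.asarray(X)[te]
        model = _train(spec, Xtr, y[tr])
        per_fold.append(pr_auc_scores(y[te], _predict(model, Xte)))
    mean = float(np.mean(per_fold))
    sd = float(np.std(per_fold, ddof=1)) if folds > 1 else 0.0
    if t_interval:
        from scipy.stats import t as tdist

        q = float(tdist.ppf(0.975, folds - 1))
    else:
        q = 1.96
    half = q * sd / np.sqrt(folds)
    return mean, (mean - half, mean + half), per_fold


def score_test_set(model, test_matrix, test_corpus) -> ScoredTestSet:
    """Score a labeled test corpus with a trained model."""
    from .classify import predict_proba as _predict

    probs = _predict(model, test_matrix)
    labels = np.array([a.label for a in test_corpus.articles])
    gene_sets = {
        a.pmid: set(a.curated_genes)
        for a in test_corpus.articles
        if a.label == 1 and a.curated_genes
    }
    return ScoredTestSet(
        pmids=test_corpus.pmids, labels=labels, probabilities=probs, gene_sets=gene_sets
    )


def evaluate_cell(
    train_corpus,
    test_corpus,
    set_name: str,
    family: str,
    preset: dict[str, Any] | None = None,
    cfg=None,
    imbalance=None,
    seed: int = 0,
    target: float = 0.95,
    compute_ci: bool = False,
) -> MetricReport:
    """End-to-end evaluation of one (classifier, feature set) cell.

    Fits the vocabulary on the training corpus, trains the classifier
    under the imbalance strategy, scores the test corpus, selects the
    95%-gene-recall threshold and fills a full MetricReport.
    """
    from .classify import ClassifierSpec, train as _train
    from .experiment import REFERENCE_PRESETS, ImbalanceStrategy, apply_imbalance
    from .features import build_feature_set

    preset = preset if preset is not None else REFERENCE_PRESETS[family]
    imbalance = imbalance if imbalance is not None else ImbalanceStrategy(seed=seed)
    train_fm = build_feature_set(train_corpus, set_name, cfg=cfg, fit=True)
    test_fm = build_feature_set(
        test_corpus, set_name, cfg=cfg, fit=False, vocabulary=train_fm.vocabulary
    )
    y_train = np.array([a.label for a in train_corpus.articles])
    X, y, weights = apply_imbalance(train_fm.values, y_train, imbalance)
    spec = ClassifierSpec(family=family, hyper_parameters=preset, seed=seed)
    model = _train(spec, X, y, weights=weights)
    model.vocabulary = train_fm.vocabulary
    scored = score_test_set(model, test_fm, test_corpus)
    result = gene_recall_threshold(scored, target=target)
    report = result.report
    report.auroc = roc_auc(scored)
    report.aucpr = pr_auc(scored)
    if compute_ci:
        _, ci, _ = cv_aucpr_ci(train_fm.values, y_train, spec, folds=5, seed=seed)
        report.aucpr_ci = ci
    return report


def evaluate_grid(
    train_corpus,
    test_corpus,
    set_names,
    families,
    presets: dict[str, dict[str, Any]] | None = None,
    cfg=None,
    imbalance=None,
    seed: int = 0,
    target: float = 0.95,
    compute_ci: bool = False,
) -> pd.DataFrame:
    """Metric rows for every requested (family, feature set) pair."""
    rows = []
    for family in families:
        for set_name in set_names:
            preset = (presets or {}).get(family)
            report = evaluate_cell(
                train_corpus, test_corpus, set_name, family,
                preset=preset, cfg=cfg, imbalance=imbalance, seed=seed,
                target=target, compute_ci=compute_ci,
            )
            rows.append({"classifier": family, "feature_set": set_name, **report.as_dict()})
    return pd.DataFrame(rows)
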
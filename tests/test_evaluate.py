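"""Gene-centric metrics, threshold selection, ROC/PR areas and DeLong."""

import shutil
import subprocess

import numpy as np
import pytest

from genetriage.evaluate import (
    GeneBookkeepingError,
    ScoredTestSet,
    confusion_at,
    cv_aucpr_ci,
    delong_test,
    evaluate_cell,
    evaluate_grid,
    gene_recall_threshold,
    pr_auc_scores,
    roc_auc_scores,
    roc_auc_trapezoid,
    triage_metrics,
)
from genetriage.classify import ClassifierSpec

from conftest import random_scored


def brute_force_metrics(scored, threshold):
    """Independent enumeration of every reported metric."""
    tp = fp = tn = fn = 0
    all_genes, found = set(), set()
    for pmid, y, p in zip(scored.pmids, scored.labels, scored.probabilities):
        pred = p >= threshold
        if y == 1:
            genes = scored.gene_sets.get(pmid, set())
            all_genes |= genes
            if pred:
                tp += 1
                found |= genes
            else:
                fn += 1
        else:
            if pred:
                fp += 1
            else:
                tn += 1
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    gr = len(found) / len(all_genes)
    ws = (tn + fn) / (tp + fp + tn + fn)
    f1 = 2 * recall * precision / (recall + precision) if recall + precision else 0.0
    fg = 2 * gr * precision / (gr + precision) if gr + precision else 0.0
    return (tp, fp, tn, fn), (recall, precision, gr, ws, f1, fg)


def brute_force_threshold(scored, target):
    """Exhaustive scan over all distinct probabilities (descending)."""
    for t in sorted(set(scored.probabilities), reverse=True):
        _, (_, _, gr, *_rest) = brute_force_metrics(scored, t)
        if gr >= target:
            return t
    return None


class TestConfusionAndMetrics:
    def test_extreme_thresholds(self):
        s = ScoredTestSet(["a", "b"], [1, 0], [0.9, 0.2], {"a": {"G"}})
        c0 = confusion_at(s, 0.0)
        assert (c0.TN, c0.FN) == (0, 0)
        c_hi = confusion_at(s, 0.95)
        assert c_hi.TP + c_hi.FP == 0

    def test_enumerated_example(self):
        s = ScoredTestSet(
            ["a", "b", "c", "d"], [1, 1, 0, 0], [0.9, 0.6, 0.4, 0.1], {"a": {"G"}}
        )
        c = confusion_at(s, 0.5)
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)

    def test_gene_recall_set_union(self):
        s = ScoredTestSet(
            ["a", "b", "c"], [1, 1, 0], [0.9, 0.3, 0.1],
            {"a": {"A", "B"}, "b": {"B", "C"}},
        )
        rep = triage_metrics(confusion_at(s, 0.5), s)
        assert rep.gene_recall == pytest.approx(2 / 3)

    def test_perfect_and_degenerate_corners(self):
        s = ScoredTestSet(["a", "b"], [1, 0], [0.9, 0.2], {"a": {"G"}})
        perfect = triage_metrics(confusion_at(s, 0.5), s)
        assert (perfect.recall, perfect.precision, perfect.gene_recall,
                perfect.f1, perfect.f_gene) == (1, 1, 1, 1, 1)
        nothing = triage_metrics(confusion_at(s, 0.95), s)
        assert nothing.workload_saving == 1.0 and nothing.recall == 0.0

    def test_agrees_with_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            s = random_scored(rng)
            t = float(rng.random())
            c = confusion_at(s, t)
            rep = triage_metrics(c, s)
            (tp, fp, tn, fn), (re, pr, gr, ws, f1, fg) = brute_force_metrics(s, t)
            assert (c.TP, c.FP, c.TN, c.FN) == (tp, fp, tn, fn)
            for got, want in zip(
                (rep.recall, rep.precision, rep.gene_recall,
                 rep.workload_saving, rep.f1, rep.f_gene),
                (re, pr, gr, ws, f1, fg),
            ):
                assert got == pytest.approx(want, abs=1e-12)

    def test_empty_gene_union_is_an_error(self):
        s = ScoredTestSet(["a", "b"], [1, 0], [0.9, 0.2], {})
        with pytest.raises(GeneBookkeepingError):
            triage_metrics(confusion_at(s, 0.5), s)


class TestGeneRecallThreshold:
    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            s = random_scored(rng)
            target = float(rng.choice([0.5, 0.8, 0.95, 1.0]))
            res = gene_recall_threshold(s, target=target)
            assert res.threshold == brute_force_threshold(s, target)
            assert res.report.gene_recall >= target

    def test_single_positive_forces_its_probability(self):
        s = ScoredTestSet(
            ["a", "b", "c"], [1, 0, 0], [0.7, 0.9, 0.1], {"a": {"G1", "G2"}}
        )
        assert gene_recall_threshold(s, 0.95).threshold == pytest.approx(0.7)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        s = random_scored(rng, n_min=20, n_max=40)
        grid = sorted(set(s.probabilities), reverse=True)
        reports = [triage_metrics(confusion_at(s, t), s) for t in grid]
        for a, b in zip(reports[:-1], reports[1:]):
            assert b.recall >= a.recall
            assert b.gene_recall >= a.gene_recall
            assert b.workload_saving <= a.workload_saving

    def test_positive_without_genes_anywhere_is_error(self):
        s = ScoredTestSet(["a", "b"], [1, 0], [0.9, 0.2], {})
        with pytest.raises(GeneBookkeepingError):
            gene_recall_threshold(s)


class TestROC:
    def test_known_values(self):
        assert roc_auc_scores([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0
        assert roc_auc_scores([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5
        assert roc_auc_scores([1, 0, 1, 0], [0.8, 0.7, 0.6, 0.5]) == 0.75

    def test_rank_and_trapezoid_forms_agree(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            p = np.round(rng.random(n), int(rng.integers(1, 3)))  # force ties
            assert roc_auc_scores(y, p) == pytest.approx(
                roc_auc_trapezoid(y, p), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_scores([1, 1], [0.2, 0.4])


class TestPR:
    def test_known_values(self):
        assert pr_auc_scores([1, 1, 0], [0.9, 0.8, 0.3]) == pytest.approx(1.0)
        assert pr_auc_scores([1, 0], [0.9, 0.1]) == pytest.approx(1.0)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(11)
        y = (rng.random(20000) < 0.25).astype(int)
        p = rng.random(20000)
        assert pr_auc_scores(y, p) == pytest.approx(0.25, abs=0.02)

    def test_in_unit_interval(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, n)
            if y.sum() == 0:
                continue
            assert 0.0 <= pr_auc_scores(y, rng.random(n)) <= 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_auc_scores([0, 0], [0.1, 0.2])


class TestDeLong:
    def _paired(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        pm = [str(i) for i in range(n)]
        signal = y + rng.normal(size=n)
        a = ScoredTestSet(pm, y, 1 / (1 + np.exp(-signal)))
        b = ScoredTestSet(pm, y, rng.random(n))
        return a, b

    def test_self_comparison_null(self):
        a, _ = self._paired()
        auc_a, auc_b, z, p = delong_test(a, a)
        assert auc_a == auc_b and z == 0.0 and p == 1.0

    def test_swap_symmetry(self):
        a, b = self._paired(1)
        _, _, z_ab, p_ab = delong_test(a, b)
        _, _, z_ba, p_ba = delong_test(b, a)
        assert z_ab == pytest.approx(-z_ba) and p_ab == pytest.approx(p_ba)

    def test_unpaired_inputs_rejected(self):
        a, b = self._paired(2)
        b.pmids = list(reversed(b.pmids))
        with pytest.raises(ValueError, match="paired"):
            delong_test(a, b)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_pROC_reference(self, tmp_path):
        """Independent oracle: pROC's roc.test(method='delong')."""
        a, b = self._paired(5, n=40)
        auc_a, auc_b, z, p = delong_test(a, b)
        script = tmp_path / "delong.R"
        script.write_text(
            "suppressMessages(library(pROC))\n"
            f"y <- c({', '.join(map(str, a.labels))})\n"
            f"pa <- c({', '.join(str(v) for v in a.probabilities)})\n"
            f"pb <- c({', '.join(str(v) for v in b.probabilities)})\n"
            "t <- roc.test(roc(y, pa, quiet=TRUE), roc(y, pb, quiet=TRUE),"
            " method='delong', paired=TRUE)\n"
            "cat(sprintf('%.10f %.10f\\n', t$statistic, t$p.value))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        z_ref, p_ref = map(float, out.stdout.split())
        assert z == pytest.approx(z_ref, abs=1e-6)
        assert p == pytest.approx(p_ref, abs=1e-6)


class TestCrossValidatedAUCPR:
    def test_seeded_and_reproducible(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(120, 3))
        y = (X[:, 0] + 0.5 * rng.normal(size=120) > 0.5).astype(int)
        spec = ClassifierSpec("logistic", {"max_iter": 300})
        m1, ci1, folds1 = cv_aucpr_ci(X, y, spec, folds=5, seed=4)
        m2, ci2, folds2 = cv_aucpr_ci(X, y, spec, folds=5, seed=4)
        assert folds1 == folds2 and ci1 == ci2
        assert ci1[0] <= m1 <= ci1[1]

    def test_strong_signal_ci_above_prevalence(self, strong_split):
        from genetriage.features import build_feature_set

        train_c, _ = strong_split
        fm = build_feature_set(train_c, "S2")
        y = np.array([a.label for a in train_c.articles])
        spec = ClassifierSpec("logistic", {"max_iter": 300})
        _, (low, _), _ = cv_aucpr_ci(fm.values, y, spec, folds=5, seed=1)
        assert low > y.mean()


class TestEvaluateCell:
    def test_end_to_end_row_contract(self, strong_split):
        train_c, test_c = strong_split
        report = evaluate_cell(train_c, test_c, "S2", "logistic", seed=3)
        assert report.gene_recall >= 0.95
        assert report.workload_saving > 0.0
        assert 0.0 <= report.auroc <= 1.0

    def test_grid_shape(self, strong_split):
        train_c, test_c = strong_split
        table = evaluate_grid(
            train_c, test_c, ["GeneCount", "S3"], ["logistic"], seed=3
        )
        assert len(table) == 2
        assert set(table["feature_set"]) == {"GeneCount", "S3"}
        assert (table["gene_recall"] >= 0.95).all()
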
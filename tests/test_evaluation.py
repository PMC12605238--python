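"""Evaluation tests: metric formulas against hand-worked tables, the
clustering coefficient against exhaustive triangle counting, voting rules,
and LOSO isolation/determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cogmi.evaluation import (
    ConfusionCounts, clustering_coefficient, compare_strong_weak_networks,
    confusion_and_metrics, kappa, loso_cv, summarize_reports, vote_action,
)
from cogmi.mgcn import TrainConfig
from cogmi.mi_labeling import label_subject


def brute_force_clustering(B):
    """Triangle-enumeration oracle for binary graphs."""
    n = len(B)
    cis = []
    for i in range(n):
        nbrs = [j for j in range(n) if B[i, j]]
        k = len(nbrs)
        if k < 2:
            cis.append(0.0)
            continue
        tri = sum(B[a, b] for ai, a in enumerate(nbrs)
                  for b in nbrs[ai + 1:])
        cis.append(tri / (k * (k - 1) / 2))
    return float(np.mean(cis)), np.array(cis)


class TestMetrics:
    def test_perfect_predictions(self):
        labels = np.array([1] * 25 + [0] * 50)
        counts, m = confusion_and_metrics(labels, labels)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (25, 50, 0, 0)
        assert m["accuracy"] == 1.0 and m["f1"] == 1.0
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0
        assert m["kappa"] == 1.0

    def test_hand_worked_table(self):
        """TP=19, FN=6, FP=14, TN=36: ACC 55/75, sens .76, spec .72,
        F1 38/58, p_e .52, kappa .4444 (hand arithmetic)."""
        counts = ConfusionCounts(tp=19, fn=6, fp=14, tn=36)
        assert np.isclose((counts.tp + counts.tn) / counts.total, 55 / 75)
        preds = np.array([1] * 19 + [0] * 6 + [1] * 14 + [0] * 36)
        labels = np.array([1] * 25 + [0] * 50)
        got, m = confusion_and_metrics(preds, labels)
        assert (got.tp, got.fn, got.fp, got.tn) == (19, 6, 14, 36)
        assert np.isclose(m["accuracy"], 0.73333, atol=1e-4)
        assert np.isclose(m["sensitivity"], 0.76)
        assert np.isclose(m["specificity"], 0.72)
        assert np.isclose(m["f1"], 38 / 58, atol=1e-9)
        assert np.isclose(m["kappa"], (55 / 75 - 0.52) / (1 - 0.52), atol=1e-9)
        assert np.isclose(m["kappa"], 0.4444, atol=1e-4)

    def test_all_weak_boundary(self):
        preds = np.zeros(75, dtype=int)
        labels = np.array([1] * 25 + [0] * 50)
        counts, m = confusion_and_metrics(preds, labels)
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0
        assert not np.isnan(m["f1"])  # F1 = 0/(0+0+25) is defined here
        assert m["f1"] == 0.0
        # fully degenerate: no positives anywhere
        counts2, m2 = confusion_and_metrics(np.zeros(4, int), np.zeros(4, int))
        assert np.isnan(m2["f1"])
        assert "f1" in m2["undefined"]

    def test_independent_predictions_zero_kappa(self):
        # cells equal to row*col products / n: 2x2 table 10,10 / 10,10
        counts = ConfusionCounts(tp=10, fn=10, fp=10, tn=10)
        assert np.isclose(kappa(counts), 0.0)

    def test_degenerate_table_flagged(self):
        assert np.isnan(kappa(ConfusionCounts(tp=5, fn=0, fp=0, tn=0)))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30))
    def test_metric_identities(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        preds = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn)
        labels = np.array([1] * (tp + fn) + [0] * (fp + tn))
        counts, m = confusion_and_metrics(preds, labels)
        if tp + fn > 0:
            assert np.isclose(m["sensitivity"] * (tp + fn), tp)
        assert np.isclose(m["accuracy"] * counts.total, tp + tn)
        k = m["kappa"]
        if not np.isnan(k) and (tp + fn) and (fp + tn):
            assert np.isclose(k, 1.0) == (fp == 0 and fn == 0)
        if not np.isnan(k):
            assert -1 - 1e-9 <= k <= 1 + 1e-9


class TestClustering:
    def test_complete_graph(self):
        a = np.ones((4, 4)) - np.eye(4)
        c, ci = clustering_coefficient(a)
        assert c == 1.0
        assert np.all(ci == 1.0)

    def test_star_graph(self):
        a = np.zeros((5, 5))
        a[0, 1:] = a[1:, 0] = 1.0
        c, _ = clustering_coefficient(a)
        assert c == 0.0

    def test_matches_triangle_enumeration(self, rng):
        """Proportionally thresholded random weighted graphs match the
        exhaustive triangle-count oracle exactly."""
        for n in range(3, 9):
            for _ in range(20):
                w = rng.uniform(0, 1, (n, n))
                w = (w + w.T) / 2
                np.fill_diagonal(w, 0.0)
                c, ci = clustering_coefficient(w, 0.4)
                cut = np.quantile(w[~np.eye(n, dtype=bool)], 0.6)
                B = ((w >= cut) & ~np.eye(n, dtype=bool)).astype(int)
                c_oracle, ci_oracle = brute_force_clustering(B)
                assert np.isclose(c, c_oracle)
                assert np.allclose(ci, ci_oracle)

    def test_matches_networkx(self, rng):
        import networkx as nx
        for _ in range(10):
            B = (rng.uniform(0, 1, (7, 7)) > 0.5).astype(int)
            B = np.triu(B, 1)
            B = B + B.T
            if B.sum() == 0:
                continue
            g = nx.from_numpy_array(B)
            want = np.mean(list(nx.clustering(g).values()))
            got, _ = clustering_coefficient(B.astype(float), 0.5)
            # proportional threshold keeps all 1-entries of a binary graph
            assert np.isclose(got, want)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            clustering_coefficient(np.zeros((0, 0)))
        with pytest.raises(ValueError):
            clustering_coefficient(np.ones((3, 3)), 1.5)


class TestVote:
    def test_plain_majority(self):
        actions = np.repeat([0, 1, 2], 25)
        preds = np.zeros(75, dtype=int)
        preds[:20] = 1           # 20 strong votes for action 0
        preds[25:30] = 1         # 5 for action 1
        preds[50:53] = 1         # 3 for action 2
        chosen, counts, tie = vote_action(preds, actions)
        assert chosen == 0
        assert counts == {0: 20, 1: 5, 2: 3}
        assert not tie

    def test_tie_lowest_index(self):
        actions = np.repeat([0, 1, 2], 12)
        preds = np.zeros(36, dtype=int)
        preds[:10] = 1
        preds[12:22] = 1
        preds[24:26] = 1
        chosen, counts, tie = vote_action(preds, actions)
        assert chosen == 0 and tie
        assert counts == {0: 10, 1: 10, 2: 2}

    def test_all_weak_degenerate(self):
        actions = np.repeat([0, 1, 2], 4)
        chosen, counts, tie = vote_action(np.zeros(12, dtype=int), actions)
        assert chosen == 0 and tie
        assert all(v == 0 for v in counts.values())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vote_action(np.array([]), np.array([]))


@pytest.fixture(scope="module")
def loso_setup(small_cohort):
    labelings = [label_subject(s) for s in small_cohort]
    cfg = TrainConfig(epochs=40, seed=5)
    reports = loso_cv(small_cohort, cfg, labelings=labelings)
    return small_cohort, labelings, cfg, reports


class TestLOSO:
    def test_each_subject_tested_once(self, loso_setup):
        cohort, _, _, reports = loso_setup
        assert sorted(r.subject_id for r in reports) == \
            sorted(s.subject_id for s in cohort)
        for r in reports:
            assert len(r.predictions) == cohort[0].cognitive_epochs.n_trials

    def test_isolation_from_test_subject(self, loso_setup):
        """Replacing the held-out subject's cognitive data leaves that
        fold's training artifacts (CSP + weights) bit-identical."""
        cohort, labelings, cfg, reports = loso_setup
        corrupted = list(cohort)
        import copy
        mutant = copy.deepcopy(cohort[0])
        rng = np.random.default_rng(99)
        mutant.cognitive_epochs.data[:] = rng.standard_normal(
            mutant.cognitive_epochs.data.shape)
        corrupted[0] = mutant
        reports2 = loso_cv(corrupted, cfg, labelings=labelings)
        assert reports[0].artifact_hashes == reports2[0].artifact_hashes

    def test_deterministic_repeat(self, loso_setup):
        cohort, labelings, cfg, reports = loso_setup
        reports2 = loso_cv(cohort, cfg, labelings=labelings)
        for a, b in zip(reports, reports2):
            assert a.artifact_hashes == b.artifact_hashes
            assert np.array_equal(a.predictions, b.predictions)

    def test_summary_consistent(self, loso_setup):
        _, _, _, reports = loso_setup
        table, pooled = summarize_reports(reports)
        assert len(table) == len(reports)
        total = sum(r.counts.total for r in reports)
        assert pooled["n_trials"] == total
        correct = sum(r.counts.tp + r.counts.tn for r in reports)
        assert np.isclose(pooled["accuracy"], correct / total)

    def test_single_subject_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            loso_cv(small_cohort[:1])


class TestNetworkContrast:
    def test_strong_networks_more_clustered(self, subject_graphs):
        triples, strong_mask = subject_graphs
        for t, is_strong in zip(triples, strong_mask):
            for g in t:
                g.annotations["label"] = int(is_strong)
        contrast = compare_strong_weak_networks(triples, n_permutations=200,
                                                seed=1)
        assert contrast.ccoef_diff["time"] > 0
        # the condition-mean time-domain network is also more clustered
        c_strong, _ = clustering_coefficient(
            contrast.mean_adjacency["time"]["strong"])
        c_weak, _ = clustering_coefficient(
            contrast.mean_adjacency["time"]["weak"])
        assert c_strong >= c_weak
        for d in ("time", "frequency", "spatial"):
            for cond in ("strong", "weak"):
                m = contrast.mean_adjacency[d][cond]
                assert np.allclose(m, m.T, atol=1e-10)
                assert np.allclose(np.diag(m), 1.0)

    def test_null_pvalues_calibrated(self, rng):
        """With no real effect the permutation p-values are roughly
        uniform: the 5% rejection rate over 100 replicates stays in a
        wide binomial band."""
        from cogmi.brain_networks import AdjacencyMatrix, DomainGraph, \
            NodeFeatureMatrix
        rejections = 0
        n_rep = 100
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            triples = []
            for i in range(24):
                a = r.uniform(0, 1, (8, 8))
                a = (a + a.T) / 2
                np.fill_diagonal(a, 1.0)
                g = DomainGraph(
                    NodeFeatureMatrix(r.standard_normal((8, 2)), "time"),
                    AdjacencyMatrix(a, "time"),
                    {"label": i % 2, "subject_id": i // 12})
                triples.append((g,))
            contrast = compare_strong_weak_networks(
                triples, n_permutations=99, seed=rep)
            if contrast.p_value["time"] <= 0.05:
                rejections += 1
        assert 0 <= rejections <= 13  # 99.9% band around 5/100
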
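"""Rank-annotation scoring: cosine similarity, percentiles, omnibus, LOOCV."""

import math

import numpy as np
import pytest

from tofrank import (
    FeatureSource,
    SimConfig,
    TrainingSet,
    loocv_roc,
    omnibus_scores,
    percentile_ranks,
    score_source,
    simulate_sources,
)
from tofrank.ranking import _roc_curve, _trapezoid_auc


def brute_cosine_scores(source, training_genes, exclude=None):
    """Independent oracle: explicit-loop standardization, centroid, cosine."""
    m = source.matrix
    n, f = m.shape
    cols = []
    for j in range(f):
        col = [m[i, j] for i in range(n)]
        mu = sum(col) / n
        sd = math.sqrt(sum((v - mu) ** 2 for v in col) / n)
        if sd > 0:
            cols.append([(v - mu) / sd for v in col])
    z = [[cols[j][i] for j in range(len(cols))] for i in range(n)]
    train = [g for g in training_genes if g != exclude]
    t_idx = [source.genes.index(g) for g in train]
    centroid = [sum(z[i][j] for i in t_idx) / len(t_idx) for j in range(len(cols))]
    out = {}
    for i, g in enumerate(source.genes):
        dot = sum(a * b for a, b in zip(z[i], centroid))
        na = math.sqrt(sum(a * a for a in z[i]))
        nb = math.sqrt(sum(b * b for b in centroid))
        out[g] = dot / (na * nb) if na * nb > 0 else 0.0
    return out


def brute_percentiles(raw):
    """Sort-based midrank percentile oracle."""
    vals = list(raw.values())
    n = len(vals)
    out = {}
    for g, v in raw.items():
        below = sum(1 for u in vals if u < v)
        ties = sum(1 for u in vals if u == v)
        out[g] = 100.0 * (below + 0.5 * ties) / n
    return out


class TestScoreSource:
    def test_matches_brute_force_cosine(self, toy_source):
        training = TrainingSet("t", frozenset({"g1", "g3"}))
        got = score_source(toy_source, training)
        want = brute_cosine_scores(toy_source, ["g1", "g3"])
        for g in toy_source.genes:
            assert got[g] == pytest.approx(want[g], abs=1e-12)

    def test_exclusion_matches_brute_force(self, toy_source):
        training = TrainingSet("t", frozenset({"g1", "g3", "g5"}))
        got = score_source(toy_source, training, exclude="g3")
        want = brute_cosine_scores(toy_source, ["g1", "g3", "g5"], exclude="g3")
        for g in toy_source.genes:
            assert got[g] == pytest.approx(want[g], abs=1e-12)

    def test_matches_sklearn_cosine_similarity(self, planted):
        from sklearn.metrics.pairwise import cosine_similarity

        _, sources, training = planted
        src = sources[0]
        got = score_source(src, training)
        Z = src.standardized()
        idx = [src.genes.index(g) for g in sorted(training.genes)]
        centroid = Z[idx].mean(axis=0, keepdims=True)
        want = cosine_similarity(Z, centroid)[:, 0]
        np.testing.assert_allclose(
            [got[g] for g in src.genes], want, atol=1e-10)

    def test_centroid_gene_scores_one_and_orthogonal_scores_zero(self):
        # columns already mean 0, sd 1, so standardization is the identity
        src = FeatureSource(
            "sym", ["a", "b", "c", "d"],
            np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], float),
        )
        sim = score_source(src, TrainingSet("t", frozenset({"a"})))
        assert sim["a"] == pytest.approx(1.0)
        assert sim["b"] == pytest.approx(0.0, abs=1e-12)
        assert sim["c"] == pytest.approx(0.0, abs=1e-12)
        assert sim["d"] == pytest.approx(-1.0)

    def test_zero_variance_feature_dropped_with_warning(self, caplog):
        m = np.random.default_rng(0).normal(size=(6, 3))
        m[:, 1] = 4.2
        src = FeatureSource("zv", [f"g{i}" for i in range(6)], m)
        with caplog.at_level("WARNING"):
            score_source(src, TrainingSet("t", frozenset({"g0", "g1"})))
        assert "zero-variance" in caplog.text

    def test_empty_training_after_exclusion_rejected(self, toy_source):
        training = TrainingSet("t", frozenset({"g1"}))
        with pytest.raises(ValueError, match="empty after exclusion"):
            score_source(toy_source, training, exclude="g1")

    def test_missing_training_gene_named_in_error(self, toy_source):
        with pytest.raises(ValueError, match="gX"):
            score_source(toy_source, TrainingSet("t", frozenset({"g1", "gX"})))


class TestPercentileRanks:
    def test_distinct_values_midrank(self):
        got = percentile_ranks({"a": 1, "b": 2, "c": 3, "d": 4, "e": 5})
        assert got == {"a": 10, "b": 30, "c": 50, "d": 70, "e": 90}

    def test_full_tie_maps_to_fifty(self):
        got = percentile_ranks({g: 7.0 for g in "abcd"})
        assert all(v == 50.0 for v in got.values())

    def test_against_sort_based_oracle(self):
        rng = np.random.default_rng(5)
        vals = np.round(rng.normal(size=1000), 2)  # rounding forces ties
        raw = {f"g{i}": float(v) for i, v in enumerate(vals)}
        got = percentile_ranks(raw)
        want = brute_percentiles(raw)
        for g in raw:
            assert got[g] == pytest.approx(want[g], abs=1e-9)

    def test_median_is_fifty(self):
        rng = np.random.default_rng(6)
        raw = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=200))}
        assert np.median(list(percentile_ranks(raw).values())) == pytest.approx(50.0)


class TestOmnibus:
    def test_single_source_is_identity(self, toy_source):
        training = TrainingSet("t", frozenset({"g1", "g3"}))
        ann = omnibus_scores([toy_source], training)
        pct = percentile_ranks(score_source(toy_source, training))
        for g in toy_source.genes:
            assert ann.scores[g] == pytest.approx(pct[g])

    def test_duplicated_source_is_idempotent(self, toy_source):
        training = TrainingSet("t", frozenset({"g1", "g3"}))
        twin = FeatureSource("toy2", list(toy_source.genes), toy_source.matrix.copy())
        one = omnibus_scores([toy_source], training)
        two = omnibus_scores([toy_source, twin], training)
        for g in toy_source.genes:
            assert two.scores[g] == pytest.approx(one.scores[g])

    def test_planted_training_genes_rank_high(self, planted):
        _, sources, training = planted
        ann = omnibus_scores(sources, training)
        assert all(ann.scores[g] > 80.0 for g in training.genes)

    def test_score_bounds_and_median(self, planted):
        _, sources, training = planted
        vals = np.array(list(omnibus_scores(sources, training).scores.values()))
        assert vals.min() >= 0.0 and vals.max() <= 100.0
        assert abs(np.median(vals) - 50.0) <= 100.0 / len(vals)

    def test_gene_universe_mismatch_lists_difference(self, toy_source):
        other = FeatureSource(
            "other", ["g1", "g2", "g3", "g4", "g9"],
            np.random.default_rng(1).normal(size=(5, 3)),
        )
        with pytest.raises(ValueError, match="g5.*g9|g9.*g5"):
            omnibus_scores([toy_source, other],
                           TrainingSet("t", frozenset({"g1"})))

    def test_gene_order_permutation_invariance(self, planted):
        _, sources, training = planted
        perm = np.random.default_rng(2).permutation(sources[0].n_genes)
        shuffled = [
            FeatureSource(s.name, [s.genes[i] for i in perm], s.matrix[perm])
            for s in sources
        ]
        a = omnibus_scores(sources, training).scores
        b = omnibus_scores(shuffled, training).scores
        for g in a:
            assert a[g] == pytest.approx(b[g], abs=1e-9)


class TestLoocvRoc:
    def test_curve_shape_and_bounds(self, planted):
        _, sources, training = planted
        roc = loocv_roc(sources, training)
        for curve in [roc.omnibus_curve, *roc.per_source_curves.values()]:
            xs = [p[0] for p in curve]
            ys = [p[1] for p in curve]
            assert curve[0] == (0.0, 0.0) and curve[-1] == (1.0, 1.0)
            assert all(b >= a for a, b in zip(xs, xs[1:]))
            assert all(b >= a for a, b in zip(ys, ys[1:]))
        assert -0.5 <= roc.auc_above_diagonal <= 0.5
        assert set(roc.loo_percentiles) == training.genes

    def test_perfect_separation_geometric_limit(self):
        # T training genes uniquely at the top of an N-gene list: the curve is
        # (0,0) -> (T/N, 1) -> (1,1), so AUC - 0.5 = 0.5 - T/(2N).
        n, t = 100, 5
        combined = np.linspace(1, 100, n)  # top t values are the "training" genes
        pos = combined[-t:]
        thresholds = np.unique(np.concatenate([pos, [0.0, 100.0]]))[::-1]
        curve = _roc_curve(combined, pos, thresholds)
        auc = _trapezoid_auc(curve) - 0.5
        assert auc == pytest.approx(0.5 - t / (2 * n))

    def test_trapezoid_matches_manual_sum(self):
        curve = [(0.0, 0.0), (0.1, 0.6), (0.4, 0.8), (1.0, 1.0)]
        manual = sum(
            (x2 - x1) * (y1 + y2) / 2
            for (x1, y1), (x2, y2) in zip(curve, curve[1:])
        )
        assert _trapezoid_auc(curve) == pytest.approx(manual, abs=1e-12)

    def test_planted_signal_has_positive_auc(self, planted):
        _, sources, training = planted
        roc = loocv_roc(sources, training)
        assert roc.auc_above_diagonal > 0
        assert np.median(list(roc.loo_percentiles.values())) > 90.0

    def test_monotone_response_to_enrichment(self):
        medians = []
        for enrichment in (0.0, 1.5, 3.0):
            cfg = SimConfig(n_genes=500, n_sources=2, enrichment=enrichment,
                            seed=21)
            sources = simulate_sources(cfg)
            training = TrainingSet("t", frozenset(cfg.resolved_training_genes()))
            roc = loocv_roc(sources, training)
            medians.append(np.median(list(roc.loo_percentiles.values())))
        assert medians[0] <= medians[1] <= medians[2]

    def test_small_training_set_rejected(self, toy_source):
        with pytest.raises(ValueError, match="at least 3"):
            loocv_roc([toy_source], TrainingSet("t", frozenset({"g1", "g2"})))

    def test_loocv_roc_matches_brute_force_on_small_fixture(self):
        # 8 genes, 2 sources: recompute everything with loops and compare.
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(8)]
        sources = [FeatureSource(f"s{k}", genes, rng.normal(size=(8, 4)))
                   for k in range(2)]
        training = TrainingSet("t", frozenset({"g0", "g1", "g2"}))
        roc = loocv_roc(sources, training)

        # brute-force LOO percentile per training gene
        for held in sorted(training.genes):
            per_source_pct = []
            for src in sources:
                raw = brute_cosine_scores(src, sorted(training.genes),
                                          exclude=held)
                per_source_pct.append(brute_percentiles(raw))
            mean_pct = {g: sum(p[g] for p in per_source_pct) / 2 for g in genes}
            omni = brute_percentiles(mean_pct)
            assert roc.loo_percentiles[held] == pytest.approx(omni[held], abs=1e-9)
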
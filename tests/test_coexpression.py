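"""Weighted correlation, empirical thresholds, prioritization, leave-one-out."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from pvnhkit import (
    CoexpressionPrioritizer,
    ExpressionDataset,
    QueryGeneSet,
    SimulationConfig,
    empirical_threshold,
    leave_one_out,
    prioritize,
    query_set_cohesion,
    simulate_expression,
    weighted_correlation,
)


def make_dataset(expr: np.ndarray, genes, donors=None, ages=None, name="ds"):
    n_s = expr.shape[1]
    samples = pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(n_s)],
            "donor": donors if donors is not None else [f"d{i}" for i in range(n_s)],
            "age": ages if ages is not None else np.full(n_s, 20.0),
        }
    )
    frame = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples["sample"])
    return ExpressionDataset(frame, samples, name)


class TestWeightedCorrelation:
    def test_equal_weights_reduce_to_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r = weighted_correlation(x, y, np.ones(30))
        assert r == pytest.approx(pearsonr(x, y)[0], abs=1e-12)

    def test_affine_relation_gives_unit_correlation(self):
        x = np.arange(5.0)
        w = np.array([0.3, 1.0, 2.0, 0.5, 0.1])
        assert weighted_correlation(x, 2 * x + 1, w) == pytest.approx(1.0)
        assert weighted_correlation(x, -3 * x + 2, w) == pytest.approx(-1.0)

    def test_hand_expanded_weighted_moments(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        w = np.array([0.5, 0.125, 0.125, 0.125, 0.125])
        wn = w / w.sum()
        mx, my = wn @ x, wn @ y
        cov = wn @ ((x - mx) * (y - my))
        oracle = cov / np.sqrt((wn @ (x - mx) ** 2) * (wn @ (y - my) ** 2))
        assert weighted_correlation(x, y, w) == pytest.approx(oracle, abs=1e-12)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y, w = rng.normal(size=10), rng.normal(size=10), rng.uniform(0.1, 1, 10)
        assert weighted_correlation(x, y, w) == pytest.approx(weighted_correlation(y, x, w))
        assert weighted_correlation(5 * x + 3, y, w) == pytest.approx(
            weighted_correlation(x, y, w)
        )

    def test_zero_variance_gives_nan_sentinel(self):
        assert np.isnan(weighted_correlation([1, 1, 1], [1, 2, 3], [1, 1, 1]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            weighted_correlation([1, 2], [1, 2], [1, 1])
        with pytest.raises(ValueError):
            weighted_correlation([1, 2, 3], [1, 2, 3], [1, -1, 1])


class TestDonorWeights:
    def test_inverse_sample_count_rule(self):
        donors = ["a"] * 10 + ["b"]
        expr = np.zeros((2, 11))
        ds = make_dataset(expr, ["g1", "g2"], donors=donors)
        assert ds.weights[:10] == pytest.approx(np.full(10, 0.1))
        assert ds.weights[10] == pytest.approx(1.0)

    def test_window_restriction(self):
        ages = [2.0, 10.0, 38.0, 50.0]
        ds = make_dataset(np.zeros((1, 4)), ["g"], ages=ages)
        kept = ds.restrict_window()
        assert list(kept.samples["age"]) == [10.0, 38.0]


class TestEmpiricalThreshold:
    def test_degenerate_equal_correlations(self):
        # every gene identical to the query gene: all |r| = 1, threshold = 1
        n_s = 10
        base = np.random.default_rng(0).normal(size=n_s)
        expr = np.tile(base, (6, 1))
        ds = make_dataset(expr, [f"g{i}" for i in range(5)] + ["q"])
        thr = empirical_threshold(ds, QueryGeneSet(("q",)), set_size=3, n_sets=10, seed=1)
        assert thr == pytest.approx(1.0)

    def test_null_threshold_near_analytic_quantile(self):
        rng = np.random.default_rng(2)
        n_s, n_g = 500, 80
        expr = rng.normal(size=(n_g, n_s))
        genes = [f"g{i}" for i in range(n_g)]
        ds = make_dataset(expr, genes)
        query = QueryGeneSet((genes[0],))
        thr = empirical_threshold(ds, query, set_size=40, n_sets=30, quantile=0.2, seed=3)
        # |r| of independent normals: sqrt(chi2_1 / n) scale ~ N(0, 1/sqrt(n));
        # 80th percentile of |r| ~ 1.2816 / sqrt(n)
        analytic = 1.2816 / np.sqrt(n_s)
        assert thr == pytest.approx(analytic, rel=0.25)

    def test_monotone_in_quantile(self):
        rng = np.random.default_rng(4)
        expr = rng.normal(size=(40, 60))
        genes = [f"g{i}" for i in range(40)]
        ds = make_dataset(expr, genes)
        query = QueryGeneSet((genes[0], genes[1]))
        thrs = [
            empirical_threshold(ds, query, set_size=20, n_sets=20, quantile=q, seed=5)
            for q in (0.1, 0.2, 0.4)
        ]
        assert thrs[0] >= thrs[1] >= thrs[2]

    def test_set_size_exceeding_background_errors(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(4, 10)), list("abcd"))
        with pytest.raises(ValueError):
            empirical_threshold(ds, QueryGeneSet(("a",)), set_size=4, n_sets=2)


def planted_dataset(seed=0, n_module=8, n_background=80, n_s=200, loading=0.9):
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=n_s)
    resid = np.sqrt(1 - loading**2)
    module = loading * latent + resid * rng.normal(size=(n_module, n_s))
    background = rng.normal(size=(n_background, n_s))
    genes = [f"m{i}" for i in range(n_module)] + [f"b{i}" for i in range(n_background)]
    return make_dataset(np.vstack([module, background]), genes), genes[:n_module]


class TestPrioritize:
    def test_perfectly_correlated_candidate_prioritized(self):
        ds, module = planted_dataset(seed=1, loading=1.0)
        query = QueryGeneSet(tuple(module[:4]))
        res = prioritize([module[5]], [ds], query, set_size=20, n_sets=20, seed=0)
        assert res.prioritized == [module[5]]

    def test_candidate_must_exceed_in_every_dataset(self):
        ds1, module = planted_dataset(seed=2, loading=0.95)
        # second dataset: same genes but the candidate is pure noise
        rng = np.random.default_rng(3)
        expr2 = rng.normal(size=ds1.expression.shape)
        ds2 = make_dataset(expr2, list(ds1.genes), name="ds2")
        query = QueryGeneSet(tuple(module[:4]))
        res = prioritize([module[5]], [ds1, ds2], query, set_size=20, n_sets=20, seed=1)
        assert res.prioritized == []

    def test_absent_candidate_reported_not_prioritized(self):
        ds, module = planted_dataset(seed=4)
        query = QueryGeneSet(tuple(module[:4]))
        res = prioritize(["missing_gene"], [ds], query, set_size=20, n_sets=20, seed=0)
        assert res.prioritized == []
        assert np.isnan(res.table.loc["missing_gene", "ds"])

    def test_planted_module_candidates_recovered(self):
        ds, module = planted_dataset(seed=5, n_module=8, loading=0.9)
        query = QueryGeneSet(tuple(module[:3]))
        candidates = module[3:]
        res = prioritize(candidates, [ds], query, set_size=30, n_sets=40, seed=2)
        assert set(res.prioritized) == set(candidates)


class TestLeaveOneOut:
    def test_planted_module_reprioritizes_fully(self):
        ds, module = planted_dataset(seed=6, n_module=6, loading=0.9)
        out = leave_one_out(
            QueryGeneSet(tuple(module)), [ds], set_size=20, n_sets=30, n_chance=60, seed=0
        )
        assert out["reprioritization_rate"] == 1.0
        assert out["chance_rate"] < 0.5
        assert out["binomial_p"] < 0.05

    def test_independent_query_near_chance(self):
        rng = np.random.default_rng(7)
        ds = make_dataset(rng.normal(size=(60, 150)), [f"g{i}" for i in range(60)])
        query = QueryGeneSet(tuple(f"g{i}" for i in range(6)))
        out = leave_one_out(query, [ds], set_size=20, n_sets=30, n_chance=60, seed=1)
        assert abs(out["reprioritization_rate"] - out["chance_rate"]) < 0.45

    def test_two_gene_query_degenerates_gracefully(self):
        ds, module = planted_dataset(seed=8, n_module=4)
        out = leave_one_out(
            QueryGeneSet(tuple(module[:2])), [ds], set_size=10, n_sets=10, n_chance=20, seed=0
        )
        assert set(out["flags"]) == set(module[:2])

    def test_single_gene_query_rejected(self):
        ds, module = planted_dataset(seed=9)
        with pytest.raises(ValueError):
            leave_one_out(QueryGeneSet((module[0],)), [ds])


class TestCohesion:
    def test_planted_module_in_top_percentile(self):
        ds, module = planted_dataset(seed=10, n_module=8, loading=0.9)
        out = query_set_cohesion(QueryGeneSet(tuple(module)), ds, n_random=100, seed=0)
        assert out["percentile"] > 0.99

    def test_random_query_unremarkable(self):
        rng = np.random.default_rng(11)
        ds = make_dataset(rng.normal(size=(60, 100)), [f"g{i}" for i in range(60)])
        out = query_set_cohesion(
            QueryGeneSet(tuple(f"g{i}" for i in range(8))), ds, n_random=100, seed=1
        )
        assert 0.0 <= out["percentile"] <= 1.0


class TestSimulatedExpressionIntegration:
    def test_module_genes_prioritize_each_other(self):
        cfg = SimulationConfig(
            n_genes=120, expression_module_size=10, module_loading=0.9,
            n_expression_samples=250, seed=21,
        )
        ds, truth = simulate_expression(cfg)
        module = sorted(truth.module_gene_ids)
        query = QueryGeneSet(tuple(module[:5]))
        res = prioritize(module[5:], [ds], query, set_size=30, n_sets=40, seed=3)
        assert len(res.prioritized) >= 4
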
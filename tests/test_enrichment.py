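import itertools
import math

import numpy as np
import pandas as pd
import pytest

from coexmod import (
    SimulationConfig,
    class_rankings,
    combined_enrichment_score,
    enrichment_score,
    gsea,
    ora,
    simulate_modular_expression,
)


def hypergeom_upper_tail(overlap, universe, set_size, module_size):
    """Exact upper tail by direct combinatorial enumeration."""
    total = math.comb(universe, module_size)
    s = 0
    for x in range(overlap, min(set_size, module_size) + 1):
        s += math.comb(set_size, x) * math.comb(universe - set_size, module_size - x)
    return s / total


def _assignment(universe, module_genes):
    labels = ["M1" if g in module_genes else "Uncorrelated" for g in universe]
    return pd.Series(labels, index=universe, name="module")


class TestOra:
    def test_worked_example(self):
        universe = [f"g{i}" for i in range(100)]
        module = universe[:10]
        gene_set = universe[6:11]  # overlap = 4
        rows = ora(_assignment(universe, set(module)), {"S": ("d", gene_set)})
        expected = hypergeom_upper_tail(4, 100, 5, 10)
        assert rows.iloc[0]["overlap"] == 4
        assert rows.iloc[0]["p"] == pytest.approx(expected, abs=1e-12)

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(20)]
        rows = ora(
            _assignment(universe, set(universe[:5])),
            {"S": ("d", universe[10:15])},
        )
        assert rows.iloc[0]["p"] == pytest.approx(1.0)

    def test_module_equal_universe_forces_p_one(self):
        universe = [f"g{i}" for i in range(15)]
        rows = ora(
            _assignment(universe, set(universe)),
            {"S": ("d", universe[:4]), "T": ("d", universe[4:10])},
        )
        assert np.allclose(rows["p"], 1.0)

    def test_matches_enumeration_on_small_universes(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            n_uni = int(rng.integers(5, 31))
            universe = [f"g{i}" for i in range(n_uni)]
            module = set(rng.choice(universe, size=int(rng.integers(1, n_uni)), replace=False))
            gene_set = list(rng.choice(universe, size=int(rng.integers(1, n_uni)), replace=False))
            rows = ora(_assignment(universe, module), {"S": ("d", gene_set)})
            expected = hypergeom_upper_tail(
                int(rows.iloc[0]["overlap"]), n_uni, len(set(gene_set)), len(module)
            )
            assert rows.iloc[0]["p"] == pytest.approx(expected, abs=1e-12)

    def test_bh_within_module_and_sorted(self):
        universe = [f"g{i}" for i in range(50)]
        module = set(universe[:10])
        sets = {f"S{i}": ("d", universe[i : i + 8]) for i in range(0, 40, 8)}
        rows = ora(_assignment(universe, module), sets)
        assert (rows["adj_p"] >= rows["p"] - 1e-15).all()
        assert rows["adj_p"].is_monotonic_increasing


class TestClassRankings:
    def test_weighted_mean_across_classes_is_zero(self, planted):
        expr, _, ann = planted
        rk = class_rankings(expr, ann)
        weights = ann.value_counts()[rk.columns].to_numpy()
        combined = (rk * weights).sum(axis=1) / weights.sum()
        np.testing.assert_allclose(combined, 0.0, atol=1e-12)

    def test_planted_shift_has_positive_score_in_active_class(self):
        cfg = SimulationConfig(seed=11, class_shifts={(0, "disease"): 2.0})
        expr, truth, ann = simulate_modular_expression(cfg)
        rk = class_rankings(expr, ann)
        m1 = truth.index[truth == "M1"]
        assert rk.loc[m1, "disease"].mean() > 0
        assert rk.loc[m1, "control"].mean() < 0

    def test_single_class_scores_near_zero(self, small_expr):
        ann = pd.Series("only", index=small_expr.columns)
        rk = class_rankings(small_expr, ann)
        np.testing.assert_allclose(rk["only"], 0.0, atol=1e-12)


def brute_force_es(scores: pd.Series, members: set, weight=1.0):
    """Independent running-sum evaluation, step by step."""
    order = scores.sort_values(ascending=False, kind="stable")
    hits = [g in members for g in order.index]
    n, n_hit = len(order), sum(hits)
    total_w = sum(abs(s) ** weight for g, s in order.items() if g in members)
    running, best = 0.0, 0.0
    for (g, s), h in zip(order.items(), hits):
        if h:
            running += (abs(s) ** weight) / total_w if total_w else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


class TestEnrichmentScore:
    def test_top_ranked_module_is_maximal_over_placements(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(100)]
        scores = pd.Series(np.sort(rng.standard_normal(100))[::-1], index=genes)
        k = 10
        top = set(genes[:k])
        es_top = enrichment_score(scores, top)
        assert es_top > 0
        for start in range(1, 100 - k):
            es = enrichment_score(scores, set(genes[start : start + k]))
            assert es <= es_top + 1e-12

    def test_evenly_interleaved_members_near_zero(self):
        # hits spread uniformly through the ranking with equal magnitudes:
        # hit gains and miss losses cancel, so the running sum stays small
        genes = [f"g{i}" for i in range(100)]
        signs = np.where(np.arange(100) < 50, 1.0, -1.0)
        scores = pd.Series(signs, index=genes)
        members = {genes[i] for i in range(0, 100, 10)}
        assert abs(enrichment_score(scores, members)) <= 0.1 + 1e-12

    def test_matches_brute_force_on_random_rankings(self):
        rng = np.random.default_rng(19)
        genes = [f"g{i}" for i in range(100)]
        for _ in range(50):
            scores = pd.Series(rng.standard_normal(100), index=genes)
            members = set(rng.choice(genes, size=int(rng.integers(3, 40)), replace=False))
            assert enrichment_score(scores, members) == pytest.approx(
                brute_force_es(scores, members), abs=1e-12
            )

    def test_equal_magnitudes_reduce_to_classic_ks(self):
        rng = np.random.default_rng(23)
        genes = [f"g{i}" for i in range(60)]
        signs = rng.choice([-1.0, 1.0], size=60)
        scores = pd.Series(signs, index=genes)  # all |score| = 1
        members = set(rng.choice(genes, size=15, replace=False))
        order = scores.sort_values(ascending=False, kind="stable")
        hits = np.array([g in members for g in order.index])
        running = np.cumsum(np.where(hits, 1 / 15, -1 / 45))
        classic = running[np.argmax(np.abs(running))]
        assert enrichment_score(scores, members) == pytest.approx(classic, abs=1e-12)

    def test_full_coverage_rejected(self):
        scores = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError):
            enrichment_score(scores, {"a", "b"})


class TestGsea:
    def test_planted_active_module_detected(self, planted):
        expr, truth, ann = planted  # module 1 shifted +1 sd in "disease"
        rk = class_rankings(expr, ann)
        out = gsea(rk, truth, n_perm=1000, seed=99)
        row = out[(out["module"] == "M1") & (out["class"] == "disease")].iloc[0]
        assert row["nes"] > 0
        assert row["adj_p"] < 0.05
        opp = out[(out["module"] == "M1") & (out["class"] == "control")].iloc[0]
        assert opp["nes"] < 0

    def test_bit_reproducible_under_seed(self, planted):
        expr, truth, ann = planted
        sub_truth = truth.iloc[:150]
        a = gsea(class_rankings(expr.iloc[:150], ann), sub_truth, n_perm=100, seed=5)
        b = gsea(class_rankings(expr.iloc[:150], ann), sub_truth, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_sign_consistency_and_adjustment(self, planted):
        expr, truth, ann = planted
        out = gsea(class_rankings(expr, ann), truth, n_perm=200, seed=1)
        assert (np.sign(out["nes"]) == np.sign(out["es"])).all()
        assert (out["adj_p"] >= out["p"] - 1e-15).all()


class TestCombinedEnrichmentScore:
    def _rows(self, minima):
        rows = []
        for i, m in enumerate(minima):
            rows.append({"module": f"M{i+1}", "gene_set": "S", "p": m, "adj_p": m})
        return pd.DataFrame(rows)

    def test_all_ones_gives_one(self):
        ces, _ = combined_enrichment_score(self._rows([1.0, 1.0]))
        assert ces == pytest.approx(1.0)

    def test_single_module_passthrough(self):
        ces, _ = combined_enrichment_score(self._rows([0.01]))
        assert ces == pytest.approx(0.01)

    def test_geometric_mean(self):
        ces, _ = combined_enrichment_score(self._rows([0.01, 1.0]))
        assert ces == pytest.approx(0.1)

    def test_strictly_decreasing_in_any_minimum(self):
        base, _ = combined_enrichment_score(self._rows([0.2, 0.5]))
        better, _ = combined_enrichment_score(self._rows([0.1, 0.5]))
        assert better < base
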
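import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allelospec.io_formats import GeneSet
from allelospec.selection import (
    ase_variance,
    call_selection,
    gene_selection_scores,
    geneset_binomial,
    lfc_to_ratio_deviation,
    mann_whitney,
    population_deviations,
    preranked_enrichment,
    preranked_enrichment_batch,
)
from allelospec.synthetic_data import simulate_population_ase


class TestAseVariance:
    def test_low_count_individual_excluded(self):
        ref = pd.DataFrame({"i1": [11], "i2": [40], "i3": [50]}, index=["g"])
        alt = pd.DataFrame({"i1": [2], "i2": [60], "i3": [50]}, index=["g"])
        out = ase_variance(ref, alt, min_count=10)
        assert out.loc["g", "n_individuals_used"] == 2
        assert out.loc["g", "excluded_samples"] == 1

    def test_hand_computed_variance(self):
        # ratios 0.4, 0.5, 0.6 -> sample variance 0.01
        ref = pd.DataFrame({"i1": [40], "i2": [50], "i3": [60]}, index=["g"])
        alt = pd.DataFrame({"i1": [60], "i2": [50], "i3": [40]}, index=["g"])
        out = ase_variance(ref, alt)
        assert out.loc["g", "ase_variance"] == pytest.approx(0.01)

    def test_identical_ratios_zero_variance(self):
        ref = pd.DataFrame({"i1": [50], "i2": [100]}, index=["g"])
        alt = pd.DataFrame({"i1": [50], "i2": [100]}, index=["g"])
        assert ase_variance(ref, alt).loc["g", "ase_variance"] == 0.0

    def test_fewer_than_two_usable_gives_nan(self):
        ref = pd.DataFrame({"i1": [5], "i2": [50]}, index=["g"])
        alt = pd.DataFrame({"i1": [5], "i2": [50]}, index=["g"])
        out = ase_variance(ref, alt)
        assert np.isnan(out.loc["g", "ase_variance"])
        assert out.loc["g", "n_individuals_used"] == 1


def permutation_oracle_p(x, y):
    """Independent tie-aware oracle: count label arrangements by U extremity."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    mu = nx * len(y) / 2.0
    u_obs = sum(
        1.0 if xv > yv else (0.5 if xv == yv else 0.0)
        for xv in x for yv in y
    )
    hits = total = 0
    for idx in combinations(range(len(pooled)), nx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(1.0 if a > b else (0.5 if a == b else 0.0)
                for a in xs for b in ys)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_identical_multisets_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_complete_separation_small(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / 20)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_regime_matches_scipy_without_ties(self, rng):
        for _ in range(200):
            nx, ny = rng.integers(2, 7, size=2)
            x = rng.normal(size=int(nx))
            y = rng.normal(size=int(ny))
            u, p = mann_whitney(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_regime_matches_enumeration_oracle_with_ties(self, rng):
        for _ in range(40):
            nx, ny = rng.integers(2, 6, size=2)
            x = rng.integers(0, 4, size=int(nx)).astype(float)
            y = rng.integers(0, 4, size=int(ny)).astype(float)
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(permutation_oracle_p(x, y), abs=1e-12)

    def test_approx_regime_matches_scipy_asymptotic(self, rng):
        for _ in range(50):
            x = rng.normal(size=60)
            y = rng.normal(0.3, 1.0, size=50)
            u, p = mann_whitney(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic")
            assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestGeneSelectionScores:
    @staticmethod
    def _inputs(lfc_sign):
        pop = pd.DataFrame(
            np.abs(np.random.default_rng(1).normal(0, 0.05, size=(1, 30))),
            index=["g"],
        )
        inter = pd.DataFrame([[lfc_sign * 2.0] * 4], index=["g"])
        return pop, inter

    def test_large_divergence_gives_large_positive_score(self):
        pop, inter = self._inputs(+1)
        scores = gene_selection_scores(pop, inter)
        assert scores.loc["g", "direction"] == "human"
        assert scores.loc["g", "signed_score"] > 1.0

    def test_sign_flip_flips_score_exactly(self):
        pop, inter_pos = self._inputs(+1)
        _, inter_neg = self._inputs(-1)
        s_pos = gene_selection_scores(pop, inter_pos)
        s_neg = gene_selection_scores(pop, inter_neg)
        assert s_pos.loc["g", "signed_score"] == \
            pytest.approx(-s_neg.loc["g", "signed_score"])

    def test_typical_divergence_scores_near_zero(self):
        rng = np.random.default_rng(2)
        pop = pd.DataFrame(np.abs(rng.normal(0, 0.05, size=(1, 30))),
                           index=["g"])
        # interspecies deviation placed at the population median
        med_dev = float(np.median(pop.to_numpy()))
        r = 0.5 + med_dev
        lfc = math.log2(r / (1 - r))
        inter = pd.DataFrame([[lfc] * 4], index=["g"])
        scores = gene_selection_scores(pop, inter)
        assert abs(scores.loc["g", "signed_score"]) < 1.0

    def test_lfc_to_ratio_deviation(self):
        assert lfc_to_ratio_deviation(0.0) == pytest.approx(0.0)
        assert lfc_to_ratio_deviation(1.0) == pytest.approx(2 / 3 - 0.5)
        assert lfc_to_ratio_deviation(-1.0) == pytest.approx(2 / 3 - 0.5)


def exact_binom_two_sided(k, n):
    lower = sum(math.comb(n, i) for i in range(0, k + 1)) / 2 ** n
    upper = sum(math.comb(n, i) for i in range(k, n + 1)) / 2 ** n
    return min(1.0, 2.0 * min(lower, upper))


class TestGenesetBinomial:
    @staticmethod
    def _directions(n_human, n_chimp):
        genes = [f"g{i}" for i in range(n_human + n_chimp)]
        return pd.Series(["human"] * n_human + ["chimp"] * n_chimp,
                         index=genes), GeneSet("s", frozenset(genes))

    def test_balanced_set_p_one(self):
        d, gs = self._directions(5, 5)
        out = geneset_binomial(d, [gs])
        assert out.loc["s", "binom_p"] == 1.0

    def test_strongly_biased_set_tail_summation(self):
        # 15 of 18 chimp-biased: p = 2 * (1 + 18 + 153 + 816) / 2^18
        d, gs = self._directions(3, 15)
        out = geneset_binomial(d, [gs])
        assert out.loc["s", "binom_p"] == pytest.approx(2 * 988 / 2 ** 18)

    def test_relabel_invariance(self, rng):
        for _ in range(50):
            nh, nc = (int(v) for v in rng.integers(0, 30, size=2))
            if nh + nc == 0:
                continue
            d1, gs1 = self._directions(nh, nc)
            d2, gs2 = self._directions(nc, nh)
            p1 = geneset_binomial(d1, [gs1]).loc["s", "binom_p"]
            p2 = geneset_binomial(d2, [gs2]).loc["s", "binom_p"]
            assert p1 == pytest.approx(p2)
            assert p1 == pytest.approx(exact_binom_two_sided(nh, nh + nc))


def oracle_es(scores_desc, in_set, weight=1.0):
    """Scalar-loop enrichment score, independent of the vectorized path."""
    w = [abs(s) ** weight for s in scores_desc]
    denom = sum(wi for wi, hit in zip(w, in_set) if hit)
    n_miss = sum(1 for hit in in_set if not hit)
    run, best = 0.0, 0.0
    for wi, hit in zip(w, in_set):
        run += wi / denom if hit else -1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


class TestPrerankedEnrichment:
    def test_top_k_set_has_extreme_positive_es(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(np.sort(rng.normal(size=1000))[::-1],
                           index=[f"g{i}" for i in range(1000)])
        gs = GeneSet("top", frozenset(f"g{i}" for i in range(10)))
        es, p = preranked_enrichment(scores, gs, n_perm=1000, seed=3)
        assert es > 0.8
        assert p <= 2 / 1001

    def test_tiny_case_matches_loop_oracle_for_all_placements(self):
        scores = pd.Series([3.0, 2.0, -1.0, -2.0, -4.0],
                           index=list("abcde"))
        for pair in combinations("abcde", 2):
            gs = GeneSet("s", frozenset(pair))
            es, _ = preranked_enrichment(scores, gs, n_perm=10, seed=0)
            in_set = [g in pair for g in "abcde"]
            assert es == pytest.approx(oracle_es(scores.tolist(), in_set))

    def test_perm_p_approaches_full_enumeration(self):
        scores = pd.Series([3.0, 2.0, -1.0, -2.0, -4.0], index=list("abcde"))
        gs = GeneSet("s", frozenset("ab"))
        es_obs, p = preranked_enrichment(scores, gs, n_perm=2000, seed=5)
        es_all = [
            abs(oracle_es(scores.tolist(), [g in pair for g in "abcde"]))
            for pair in combinations("abcde", 2)
        ]
        enum_p = np.mean([e >= abs(es_obs) - 1e-12 for e in es_all])
        assert p == pytest.approx(enum_p, abs=0.1)

    def test_whole_ranking_as_set_is_degenerate(self):
        scores = pd.Series([2.0, 1.0, -1.0], index=list("abc"))
        gs = GeneSet("all", frozenset("abc"))
        es, p = preranked_enrichment(scores, gs, n_perm=100, seed=0)
        # all-increment walk: the maximum deviation is the final value 1
        assert es == pytest.approx(1.0)
        assert p == 1.0

    def test_perm_p_floor(self):
        scores = pd.Series(np.linspace(3, -3, 50),
                           index=[f"g{i}" for i in range(50)])
        gs = GeneSet("top", frozenset(f"g{i}" for i in range(5)))
        _, p = preranked_enrichment(scores, gs, n_perm=200, seed=1)
        assert p >= 1 / 201

    def test_empty_intersection_rejected(self):
        scores = pd.Series([1.0, -1.0], index=["a", "b"])
        with pytest.raises(ValueError, match="no genes"):
            preranked_enrichment(scores, GeneSet("x", frozenset({"zz"})))


class TestCallSelection:
    @staticmethod
    def _frames(binom_fdr, es_fdr):
        binom = pd.DataFrame({
            "n_human_biased": [40], "n_chimp_biased": [10], "n": [50],
            "binom_p": [binom_fdr], "binom_fdr": [binom_fdr],
        }, index=pd.Index(["s"], name="set_name"))
        es = pd.DataFrame({
            "es": [0.7], "es_perm_p": [es_fdr], "es_fdr": [es_fdr],
        }, index=pd.Index(["s"], name="set_name"))
        return binom, es

    def test_both_criteria_required(self):
        both = call_selection(*self._frames(0.01, 0.1))
        assert both.loc["s", "selected"]
        assert both.loc["s", "direction"] == "human"
        binom_only = call_selection(*self._frames(0.01, 0.5))
        assert not binom_only.loc["s", "selected"]
        es_only = call_selection(*self._frames(0.5, 0.1))
        assert not es_only.loc["s", "selected"]


def test_injected_shift_detected_end_to_end():
    """A 1-log2 directional shift on a 50-gene set is called selected."""
    genes = [f"gene{i:05d}" for i in range(400)]
    target = GeneSet("target", frozenset(genes[:50]))
    nulls = [GeneSet(f"null{j}", frozenset(genes[50 + 50 * j: 100 + 50 * j]))
             for j in range(4)]
    out = simulate_population_ase(
        400, 40, depth=100.0, constraint_profile=0.05,
        geneset_shift=(target, "human", 1.0), seed=123,
    )
    dev = population_deviations(out["ref_counts"], out["alt_counts"])
    scores = gene_selection_scores(dev, out["interspecies_lfc"])
    binom = geneset_binomial(scores["direction"], [target] + nulls)
    es = preranked_enrichment_batch(scores["signed_score"], [target] + nulls,
                                    n_perm=500, seed=7)
    result = call_selection(binom, es)
    assert result.loc["target", "selected"]
    assert result.loc["target", "direction"] == "human"
    assert not result.loc[[f"null{j}" for j in range(4)], "selected"].any()
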
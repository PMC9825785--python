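"""AUC scoring, Monte Carlo / exact permutation nulls, harmonic-mean
combination and the full enrichment pass."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import toxpaths as tp
from toxpaths.ppea import DegenerateSetError

from conftest import make_scores, random_score_vector


def brute_force_auc(score_map: dict[str, int], gene_set: set[str]) -> float:
    """All in/out pairs, ties credited 0.5."""
    ins = [score_map[g] for g in score_map if g in gene_set]
    outs = [score_map[g] for g in score_map if g not in gene_set]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in ins for b in outs)
    return wins / (len(ins) * len(outs))


class TestAucScore:
    def test_complete_ties_give_half(self):
        scores = make_scores({f"g{i}": 2 for i in range(6)})
        assert tp.auc_score(scores, {"g0", "g3"}) == 0.5

    def test_perfect_separation_gives_one(self):
        scores = make_scores({"a": 5, "b": 4, "c": 1, "d": 0})
        assert tp.auc_score(scores, {"a", "b"}) == 1.0

    def test_worked_example_five_sixths(self):
        scores = make_scores({"g1": 3, "g2": 2, "g3": 1, "g4": 0, "g5": 0})
        assert tp.auc_score(scores, {"g1", "g3"}) == pytest.approx(5 / 6, abs=1e-12)

    def test_genes_outside_universe_are_ignored(self):
        scores = make_scores({"a": 3, "b": 1, "c": 0})
        assert tp.auc_score(scores, {"a", "zzz"}) == tp.auc_score(scores, {"a"})

    @pytest.mark.parametrize("bad_set", [set(), {"zzz"}, {"a", "b", "c"}])
    def test_degenerate_sets_rejected(self, bad_set):
        scores = make_scores({"a": 3, "b": 1, "c": 0})
        with pytest.raises(DegenerateSetError):
            tp.auc_score(scores, bad_set)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 15))
        score_map = {f"g{i}": int(rng.integers(0, 4)) for i in range(n)}
        k = int(rng.integers(1, n))
        gene_set = set(rng.choice(sorted(score_map), size=k, replace=False))
        got = tp.auc_score(make_scores(score_map), gene_set)
        assert got == pytest.approx(brute_force_auc(score_map, gene_set), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = random_score_vector(rng, 10)
        k = int(rng.integers(1, 10))
        subset = set(rng.choice(scores.universe, size=k, replace=False))
        complement = set(scores.universe) - subset
        assert tp.auc_score(scores, subset) == pytest.approx(
            1.0 - tp.auc_score(scores, complement), abs=1e-12
        )

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(5)
        base = {f"g{i}": int(rng.integers(0, 5)) for i in range(12)}
        squared = {g: v * v + 7 for g, v in base.items()}
        gene_set = {"g0", "g3", "g7"}
        assert tp.auc_score(make_scores(base), gene_set) == pytest.approx(
            tp.auc_score(make_scores(squared), gene_set), abs=1e-12
        )


class TestMonteCarloPvalue:
    def test_all_ties_give_one(self):
        scores = make_scores({f"g{i}": 1 for i in range(8)})
        for seed in (0, 1, 99):
            assert tp.monte_carlo_pvalue(scores, 3, 0.5, 200, seed) == 1.0

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        scores = random_score_vector(rng, 20)
        a = tp.monte_carlo_pvalue(scores, 5, 0.8, 500, seed=42)
        b = tp.monte_carlo_pvalue(scores, 5, 0.8, 500, seed=42)
        assert a == b

    def test_respects_add_one_lower_bound_and_upper_bound(self):
        rng = np.random.default_rng(4)
        scores = random_score_vector(rng, 15)
        for observed in (0.0, 0.5, 1.0, 1.5):
            p = tp.monte_carlo_pvalue(scores, 4, observed, 99, seed=0)
            assert 1 / 100 <= p <= 1.0

    def test_non_increasing_in_observed_auc(self):
        rng = np.random.default_rng(6)
        scores = random_score_vector(rng, 15)
        ps = [tp.monte_carlo_pvalue(scores, 4, obs, 2000, seed=8)
              for obs in (0.0, 0.3, 0.5, 0.7, 0.9, 1.0)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("bad_size", [0, 6, 10])
    def test_invalid_set_size_rejected(self, bad_size):
        scores = make_scores({f"g{i}": i for i in range(6)})
        with pytest.raises(ValueError, match="set_size"):
            tp.monte_carlo_pvalue(scores, bad_size, 0.5, 10, seed=0)

    def test_agrees_with_exact_enumeration_on_six_genes(self):
        scores = make_scores({f"g{i}": i for i in range(6)})  # distinct scores
        observed = tp.auc_score(scores, {"g5", "g3"})
        exact = tp.exact_permutation_pvalue(scores, 2, observed)
        n = 10_000
        mc = tp.monte_carlo_pvalue(scores, 2, observed, n, seed=17)
        mc_raw = (mc * (n + 1) - 1) / n  # undo the add-one correction
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(mc_raw - exact) <= 3 * se


class TestExactPermutationPvalue:
    def test_observed_zero_makes_every_subset_qualify(self):
        rng = np.random.default_rng(7)
        scores = random_score_vector(rng, 8)
        assert tp.exact_permutation_pvalue(scores, 3, 0.0) == 1.0

    def test_max_auc_on_distinct_scores_is_one_over_ten(self):
        scores = make_scores({f"g{i}": i for i in range(5)})
        best = tp.auc_score(scores, {"g4", "g3"})  # the strict top-2 set
        assert tp.exact_permutation_pvalue(scores, 2, best) == pytest.approx(1 / 10)

    def test_all_ties_at_half_give_one(self):
        scores = make_scores({f"g{i}": 1 for i in range(6)})
        assert tp.exact_permutation_pvalue(scores, 2, 0.5) == 1.0

    def test_cap_is_enforced(self):
        rng = np.random.default_rng(8)
        scores = random_score_vector(rng, 30)
        with pytest.raises(ValueError, match="cap"):
            tp.exact_permutation_pvalue(scores, 15, 0.5, cap=1000)


class TestHarmonicMean:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ((0.01, 0.01), 0.01),
            ((0.02, 0.05), 2 / 70),
            ((0.3,), 0.3),
            ((1.0, 1.0, 1.0), 1.0),
        ],
    )
    def test_worked_examples(self, values, expected):
        assert tp.harmonic_mean_combine(values) == pytest.approx(expected, abs=1e-12)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            tp.harmonic_mean_combine([])
        with pytest.raises(ValueError):
            tp.harmonic_mean_combine([0.5, 0.0])
        with pytest.raises(ValueError):
            tp.harmonic_mean_combine([0.5, -0.1])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
    def test_bounded_by_min_and_max_and_permutation_invariant(self, ps):
        hm = tp.harmonic_mean_combine(ps)
        assert min(ps) - 1e-12 <= hm <= max(ps) + 1e-12
        assert tp.harmonic_mean_combine(list(reversed(ps))) == pytest.approx(hm)


class TestInVitroPathwayHits:
    def test_intersection_per_pathway(self, toy_kb):
        hits = tp.in_vitro_pathway_hits(toy_kb, "CPD1")
        # independent recount: CPD1 targets HG1, HG2
        expected = {}
        targets = {h.target_gene_id for h in toy_kb.in_vitro_hits if h.compound_id == "CPD1"}
        for pid, pw in toy_kb.pathways.items():
            ov = targets & pw.human_gene_ids
            if ov:
                expected[pid] = ov
        assert hits == expected
        assert hits["PWY1"] == {"HG1", "HG2"}

    def test_compound_without_hits_yields_empty_mapping(self, toy_kb):
        assert tp.in_vitro_pathway_hits(toy_kb, "CPD3") == {}

    def test_unknown_compound_rejected(self, toy_kb):
        with pytest.raises(ValueError, match="unknown compound"):
            tp.in_vitro_pathway_hits(toy_kb, "CPD99")


class TestRunPpea:
    def test_planted_pathway_ranks_first(self, planted_world):
        kb, cfg, observations, truth = planted_world
        results = tp.run_ppea(kb, observations, n_samples=1000, seed=5,
                              compound_id=truth.compound_id)
        assert results[0].pathway_id == truth.target_pathway_id
        assert results[0].rank == 1
        assert results[0].evidence.in_vitro_targets
        assert results[0].evidence.nonmammalian_phenotypes
        assert [r.rank for r in results] == list(range(1, len(results) + 1))

    def test_no_matching_phenotypes_raises_no_evidence(self, toy_kb):
        obs = [tp.ObservedPhenotypeSet("CPD1", "celegans", frozenset({"WBP:9999"}))]
        with pytest.raises(tp.NoEvidenceError, match="no evidence"):
            tp.run_ppea(toy_kb, obs, n_samples=50, seed=0)

    def test_single_species_combined_p_equals_species_p(self, planted_world):
        kb, cfg, observations, truth = planted_world
        single = [o for o in observations if o.species_id == observations[0].species_id]
        results = tp.run_ppea(kb, single, n_samples=200, seed=3)
        for r in results:
            assert len(r.per_species) == 1
            assert r.combined_p == r.per_species[0].p_value

    def test_combined_p_is_harmonic_mean_of_species_p(self, planted_world):
        kb, cfg, observations, _ = planted_world
        results = tp.run_ppea(kb, observations, n_samples=200, seed=3)
        for r in results:
            expected = tp.harmonic_mean_combine([e.p_value for e in r.per_species])
            assert r.combined_p == pytest.approx(expected, rel=1e-12)

    def test_bit_reproducible_for_fixed_inputs(self, planted_world):
        kb, cfg, observations, _ = planted_world
        a = tp.run_ppea(kb, observations, n_samples=300, seed=9)
        b = tp.run_ppea(kb, observations, n_samples=300, seed=9)
        assert [(r.pathway_id, r.combined_p) for r in a] == [
            (r.pathway_id, r.combined_p) for r in b
        ]
        pa = [e.p_value for r in a for e in r.per_species]
        pb = [e.p_value for r in b for e in r.per_species]
        assert pa == pb


class TestFilterResults:
    @staticmethod
    def _result(pid, nonmam, mam, vitro):
        return tp.EnrichmentResult(
            pathway_id=pid, pathway_name=pid, per_species=[], combined_p=0.5,
            evidence=tp.EvidenceFlags(nonmam, mam, vitro),
        )

    def test_modes(self):
        results = [
            self._result("A", True, False, False),
            self._result("B", True, True, False),
            self._result("C", True, True, True),
            self._result("D", False, False, False),
        ]
        keep = lambda mode: [r.pathway_id for r in
                             tp.filter_results(results, tp.EvidenceFilter(mode))]
        assert keep("nonmammalian_phenotypes") == ["A", "B", "C"]
        assert keep("mammalian_phenotypes") == ["B", "C"]
        assert keep("in_vitro_targets") == ["C"]
        assert keep("all_evidence") == ["C"]
        assert keep("any_evidence") == ["A", "B", "C"]

    def test_any_evidence_is_identity_when_all_flagged(self):
        results = [self._result(p, True, False, False) for p in "XYZ"]
        assert tp.filter_results(results, tp.EvidenceFilter("any_evidence")) == results

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown filter mode"):
            tp.EvidenceFilter("everything")
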
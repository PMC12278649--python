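"""Discovery tests: candidate-triplet combinatorics, gene-pair construction,
SDL filtering, patient labels, Fisher's exact test against full enumeration,
and the DDI class network against a brute-force re-derivation."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from pairview.discovery import (ContingencyTable2x2, GenePairSet,
                                build_gene_pairs, ddi_class_network,
                                enumerate_candidate_triplets, filter_sdl,
                                fishers_exact, patient_pathway_label)


class TestCandidateTriplets:
    def test_paper_scale_ordered_count(self):
        drugs = [f"d{i}" for i in range(63)]
        contexts = [f"c{i}" for i in range(125)]
        ordered, novel = enumerate_candidate_triplets(drugs, contexts, [])
        assert ordered == 488_250
        assert len(novel) == 63 * 62 // 2 * 125

    def test_three_drugs_one_context(self):
        ordered, novel = enumerate_candidate_triplets(list("abc"), ["c1"], [])
        assert ordered == 6
        assert len(novel) == 3

    def test_observed_in_either_order_excluded(self):
        ordered, novel = enumerate_candidate_triplets(
            list("abc"), ["c1"], [("b", "a", "c1")])
        assert ("a", "b", "c1") not in novel
        assert len(novel) == 2

    def test_matches_bruteforce_set_difference(self, rng):
        drugs = [f"d{i}" for i in range(8)]
        contexts = [f"c{i}" for i in range(5)]
        observed = []
        for _ in range(30):
            a, b = rng.choice(8, size=2, replace=False)
            observed.append((drugs[a], drugs[b], contexts[rng.integers(5)]))
        _, novel = enumerate_candidate_triplets(drugs, contexts, observed)
        obs = {(a, b, c) for a, b, c in observed}
        expected = set()
        for a, b in itertools.combinations(drugs, 2):
            for c in contexts:
                if (a, b, c) not in obs and (b, a, c) not in obs:
                    expected.add((a, b, c))
        assert set(novel) == expected

    def test_unknown_observed_drug_rejected(self):
        with pytest.raises(ValueError):
            enumerate_candidate_triplets(["a"], ["c"], [("a", "zz", "c")])

    @pytest.mark.parametrize("n,m", [(2, 1), (5, 3), (10, 7)])
    def test_ordered_count_closed_form(self, n, m):
        drugs = [f"d{i}" for i in range(n)]
        contexts = [f"c{i}" for i in range(m)]
        ordered, _ = enumerate_candidate_triplets(drugs, contexts, [])
        assert ordered == n * (n - 1) * m


class TestGenePairs:
    def test_single_triplet_cartesian_product(self):
        out = build_gene_pairs(
            [(("a", "b", "c1"), 0.95)], 0.9,
            {"a": {"T1"}, "b": set()}, {"c1": {"G1", "G2"}})
        assert out.pairs == {("G1", "T1"), ("G2", "T1")}
        assert out.support[("G1", "T1")] == 1

    def test_all_below_threshold_gives_empty(self):
        out = build_gene_pairs([(("a", "b", "c"), 0.5)], 0.9,
                               {"a": {"T"}}, {"c": {"G"}})
        assert out.pairs == set()

    def test_self_pairs_excluded(self):
        out = build_gene_pairs([(("a", "b", "c"), 0.99)], 0.9,
                               {"a": {"G1"}}, {"c": {"G1", "G2"}})
        assert out.pairs == {("G2", "G1")}

    def test_matches_nested_loop_oracle(self, rng):
        drugs = {f"d{i}": set(rng.choice([f"g{j}" for j in range(10)],
                                         size=3, replace=False).tolist())
                 for i in range(6)}
        over = {f"c{i}": set(rng.choice([f"g{j}" for j in range(10)],
                                        size=4, replace=False).tolist())
                for i in range(3)}
        preds = []
        for _ in range(20):
            a, b = rng.choice(6, size=2, replace=False)
            preds.append(((f"d{a}", f"d{b}", f"c{rng.integers(3)}"),
                          float(rng.uniform(0.5, 0.999))))
        out = build_gene_pairs(preds, 0.9, drugs, over)
        expected = {}
        for (a, b, c), p in preds:
            if p < 0.9:
                continue
            for g_over in over[c]:
                for g_ess in drugs[a] | drugs[b]:
                    if g_over != g_ess:
                        k = (g_over, g_ess)
                        expected[k] = expected.get(k, 0) + 1
        assert out.support == expected

    def test_skip_counted_for_triplets_without_genes(self):
        out = build_gene_pairs([(("a", "b", "c"), 0.95)], 0.9, {}, {})
        assert out.pairs == set() and out.skipped == 1


class TestSdlFilter:
    def test_empty_sdl_gives_empty_result(self):
        gp = GenePairSet(support={("G", "T"): 2})
        res = filter_sdl(gp, set())
        assert res.pairs == set() and res.genes == set()

    def test_subset_is_identity(self):
        gp = GenePairSet(support={("G", "T"): 2, ("H", "T"): 1})
        sdl = {("G", "T"), ("H", "T"), ("X", "Y")}
        res = filter_sdl(gp, sdl)
        assert res.pairs == gp.pairs
        assert res.genes == {"G", "H", "T"}

    def test_matches_set_intersection_oracle(self, rng):
        genes = [f"g{i}" for i in range(12)]
        pairs = {(genes[a], genes[b]): int(rng.integers(1, 5))
                 for a, b in rng.integers(0, 12, size=(30, 2)) if a != b}
        sdl = {(genes[a], genes[b])
               for a, b in rng.integers(0, 12, size=(25, 2)) if a != b}
        res = filter_sdl(GenePairSet(support=pairs), sdl)
        assert res.pairs == set(pairs) & sdl


class TestPatientLabel:
    def _cohort(self, rng, genes=("G", "T"), n=100):
        return pd.DataFrame(rng.normal(size=(len(genes), n)), index=genes,
                            columns=[f"p{i}" for i in range(n)])

    def test_mutated_essential_with_high_overactive_activates(self, rng):
        cohort = self._cohort(rng)
        pathway_result = filter_sdl(GenePairSet(support={("G", "T"): 1}),
                                    {("G", "T")})
        expr = {"G": cohort.loc["G"].max() + 1.0, "T": 0.0}
        assert patient_pathway_label(expr, {"T"}, pathway_result, cohort)

    def test_no_pair_satisfied_is_not_activated(self, rng):
        cohort = self._cohort(rng)
        pathway_result = filter_sdl(GenePairSet(support={("G", "T"): 1}),
                                    {("G", "T")})
        median = {g: float(np.median(cohort.loc[g])) for g in ("G", "T")}
        expr = {"G": median["G"], "T": median["T"]}
        assert not patient_pathway_label(expr, set(), pathway_result, cohort)

    def test_matches_rule_oracle_on_synthetic_cohort(self, rng):
        genes = ["G1", "G2", "T1", "T2"]
        cohort = self._cohort(rng, genes=genes)
        pw = filter_sdl(GenePairSet(support={("G1", "T1"): 1, ("G2", "T2"): 1}),
                        {("G1", "T1"), ("G2", "T2")})
        p70 = {g: np.percentile(cohort.loc[g].values, 70) for g in genes}
        p30 = {g: np.percentile(cohort.loc[g].values, 30) for g in genes}
        for patient in cohort.columns[:50]:
            expr = cohort[patient]
            muts = {"T1"} if rng.random() < 0.3 else set()
            got = patient_pathway_label(expr, muts, pw, cohort)
            expected = False
            for g_over, g_ess in [("G1", "T1"), ("G2", "T2")]:
                high = expr[g_over] > p70[g_over]
                inhib = g_ess in muts or expr[g_ess] < p30[g_ess]
                expected = expected or (high and inhib)
            assert got == expected

    def test_invariant_to_patient_column_order(self, rng):
        cohort = self._cohort(rng)
        pw = filter_sdl(GenePairSet(support={("G", "T"): 1}), {("G", "T")})
        expr = {"G": 0.9, "T": -0.9}
        shuffled = cohort[list(rng.permutation(cohort.columns))]
        assert (patient_pathway_label(expr, set(), pw, cohort)
                == patient_pathway_label(expr, set(), pw, shuffled))


def _enumerate_fisher(a, b, c, d, sided):
    """Independent oracle: exact enumeration over the hypergeometric support
    using integer binomial coefficients."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    total = comb(n, col1)
    probs = {x: comb(row1, x) * comb(n - row1, col1 - x) / total
             for x in range(lo, hi + 1)}
    if sided == "greater":
        return sum(p for x, p in probs.items() if x >= a)
    return sum(p for p in probs.values() if p <= probs[a] * (1 + 1e-9))


class TestFishersExact:
    def test_balanced_table_two_sided_is_one(self):
        assert fishers_exact(ContingencyTable2x2(5, 5, 5, 5),
                             "two-sided") == pytest.approx(1.0)

    def test_perfect_association_point_mass(self):
        p = fishers_exact(ContingencyTable2x2(10, 0, 0, 10), "greater")
        assert p == pytest.approx(1 / comb(20, 10), rel=1e-9)

    def test_degenerate_margins_give_one(self):
        assert fishers_exact(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    @pytest.mark.parametrize("sided", ["greater", "two-sided"])
    def test_matches_enumeration_oracle(self, sided):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 31, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            got = fishers_exact(ContingencyTable2x2(int(a), int(b), int(c),
                                                    int(d)), sided)
            expected = _enumerate_fisher(int(a), int(b), int(c), int(d), sided)
            assert abs(got - expected) < 1e-12

    def test_agrees_with_scipy_reference(self):
        from scipy.stats import fisher_exact as scipy_fisher

        tbl = ContingencyTable2x2(8, 2, 1, 5)
        assert fishers_exact(tbl, "greater") == pytest.approx(
            scipy_fisher([[8, 2], [1, 5]], alternative="greater")[1], rel=1e-9)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 0)


class TestDdiClassNetwork:
    def test_all_below_threshold_gives_empty_network(self):
        preds = [("a", "b", "t1", 0.5), ("a", "c", "t1", 0.2)]
        classes = {"a": {"A"}, "b": {"B"}, "c": {"B"}}
        assert ddi_class_network(preds, classes) == []

    def test_concentrated_type_yields_significant_edge(self):
        # type t1 occurs only between classes A and B; background balanced
        preds = []
        for i in range(8):
            preds.append((f"a{i}", f"b{i}", "t1", 0.95))
        for i in range(8):
            preds.append((f"x{i}", f"y{i}", "t2", 0.95))
        classes = {}
        for i in range(8):
            classes[f"a{i}"] = {"A"}; classes[f"b{i}"] = {"B"}
            classes[f"x{i}"] = {"X"}; classes[f"y{i}"] = {"Y"}
        edges = ddi_class_network(preds, classes, top_types=50,
                                  prob_threshold=0.9, per_drug_cap=100,
                                  alpha=0.05)
        assert ("A", "B", "t1") in {(e[0], e[1], e[2]) for e in edges}
        assert all(e[3] < 0.05 for e in edges)

    def test_matches_bruteforce_rederivation(self, rng):
        drugs = [f"d{i}" for i in range(12)]
        types = [f"t{i}" for i in range(4)]
        classes = {d: {f"C{rng.integers(3)}"} for d in drugs}
        preds = []
        for _ in range(60):
            a, b = rng.choice(12, size=2, replace=False)
            preds.append((drugs[a], drugs[b], types[rng.integers(4)],
                          float(rng.uniform(0.5, 1.0))))
        top_types, thr, cap, alpha = 3, 0.8, 5, 0.2
        edges = ddi_class_network(preds, classes, top_types=top_types,
                                  prob_threshold=thr, per_drug_cap=cap,
                                  alpha=alpha)
        # brute-force re-derivation of the same filtering + testing pipeline
        from collections import Counter

        freq = Counter(t for _, _, t, _ in preds)
        kept_types = set(sorted(freq, key=lambda t: (-freq[t], t))[:top_types])
        conf = [r for r in preds if r[2] in kept_types and r[3] >= thr]
        by_drug = {}
        for r in conf:
            by_drug.setdefault(r[0], []).append(r)
            by_drug.setdefault(r[1], []).append(r)
        allowed = set()
        for d, rs in by_drug.items():
            rs = sorted(rs, key=lambda r: (-r[3], r[0], r[1], r[2]))
            allowed |= {id(r) for r in rs[:cap]}
        surv = [r for r in conf if id(r) in allowed]
        occ, ptot, ttot, total = Counter(), Counter(), Counter(), 0
        for a, b, t, _ in surv:
            for cp in {tuple(sorted((ca, cb))) for ca in classes[a]
                       for cb in classes[b]}:
                occ[(cp, t)] += 1; ptot[cp] += 1; ttot[t] += 1; total += 1
        expected = []
        for (cp, t), k in occ.items():
            p = _enumerate_fisher(k, ptot[cp] - k, ttot[t] - k,
                                  total - ptot[cp] - ttot[t] + k, "greater")
            if p < alpha:
                expected.append((cp[0], cp[1], t))
        assert {(e[0], e[1], e[2]) for e in edges} == set(expected)
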
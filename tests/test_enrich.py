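"""Nearest-TSS mapping, hypergeometric enrichment, permutation calibration."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from endogwas.enrich import (
    GenomeAnnotation,
    GeneSetCollection,
    hypergeom_enrichment,
    list_overlap_test,
    nearest_tss_map,
    permutation_calibrate,
)


def hypergeom_tail_enumeration(k, N, K, n) -> float:
    """Independent oracle: exact upper tail by direct summation."""
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / total


def annotation_from(rows):
    return GenomeAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    )


def assoc_table(chroms, positions, pvals):
    m = len(positions)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "beta": np.zeros(m),
            "se": np.ones(m),
            "p": pvals,
            "n": np.full(m, 100),
            "maf": np.full(m, 0.2),
        }
    )


class TestNearestTss:
    def test_variant_exactly_at_tss(self):
        ann = annotation_from([("GA", "1", 250, "+"), ("GB", "1", 900, "-")])
        assert ann.nearest_gene("1", 250) == "GA"

    def test_nearest_by_distance(self):
        ann = annotation_from([("GA", "1", 100, "+"), ("GB", "1", 500, "+")])
        assert ann.nearest_gene("1", 250) == "GA"  # 150 < 250
        assert ann.nearest_gene("1", 350) == "GB"

    def test_distance_tie_prefers_smaller_tss(self):
        ann = annotation_from([("GB", "1", 100, "+"), ("GA", "1", 300, "+")])
        assert ann.nearest_gene("1", 200) == "GB"

    def test_equal_tss_tie_prefers_lexicographic_id(self):
        ann = annotation_from([("GZ", "1", 100, "+"), ("GA", "1", 100, "-")])
        assert ann.nearest_gene("1", 140) == "GA"

    def test_deduplication_and_threshold(self):
        ann = annotation_from([("GA", "1", 100, "+"), ("GB", "2", 100, "+")])
        table = assoc_table(["1", "1", "2", "2"], [90, 110, 100, 5000], [1e-5, 1e-5, 1e-5, 0.5])
        selected, assignment = nearest_tss_map(table, 5e-4, ann)
        assert selected == {"GA", "GB"}  # two variants collapse onto GA
        assert len(assignment) == 3

    def test_unannotated_chromosome_warns_not_errors(self):
        ann = annotation_from([("GA", "1", 100, "+")])
        table = assoc_table(["1", "7"], [90, 100], [1e-5, 1e-5])
        with pytest.warns(UserWarning, match="without annotated genes"):
            selected, assignment = nearest_tss_map(table, 5e-4, ann)
        assert selected == {"GA"}
        assert assignment["gene_id"].isna().sum() == 1


def collection(universe_size, sets):
    universe = [f"g{i}" for i in range(universe_size)]
    return GeneSetCollection(
        sets={sid: (sid, frozenset(members)) for sid, members in sets.items()},
        universe=universe,
    ), universe


class TestHypergeomEnrichment:
    def test_zero_overlap(self):
        sets, universe = collection(20, {"S": {"g0", "g1", "g2"}})
        (res,) = hypergeom_enrichment({"g10", "g11"}, sets)
        assert res.k == 0 and res.fold == 0.0 and res.p_hyper == 1.0

    def test_full_enumeration_example(self):
        sets, universe = collection(10, {"S": {"g0", "g1", "g2"}})
        (res,) = hypergeom_enrichment({"g0", "g1", "g2", "g3", "g4"}, sets)
        assert res.p_hyper == pytest.approx(21 / 252, rel=1e-12)

    def test_matches_enumeration_all_small_cases(self):
        """Full sweep over N <= 25 against the direct tail summation."""
        rng = np.random.default_rng(0)
        for N in range(2, 26):
            universe = [f"g{i}" for i in range(N)]
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    members = frozenset(universe[:K])
                    selected = set(rng.choice(universe, size=n, replace=False))
                    sets = GeneSetCollection(sets={"S": ("S", members)}, universe=universe)
                    (res,) = hypergeom_enrichment(selected, sets)
                    k = len(selected & members)
                    assert res.k == k
                    assert res.p_hyper == pytest.approx(
                        hypergeom_tail_enumeration(k, N, K, n), rel=1e-10
                    )

    def test_fold_identity(self):
        sets, _ = collection(100, {"S": {f"g{i}" for i in range(10)}})
        (res,) = hypergeom_enrichment({f"g{i}" for i in range(0, 40, 2)}, sets)
        assert res.fold * (res.K / res.N) * res.n == pytest.approx(res.k, rel=1e-12)

    def test_selected_outside_universe_dropped(self):
        sets, _ = collection(10, {"S": {"g0"}})
        with pytest.warns(UserWarning):
            (res,) = hypergeom_enrichment({"g0", "not_a_gene"}, sets)
        assert res.n == 1


class TestListOverlap:
    def test_worked_example(self):
        universe = [f"g{i}" for i in range(20)]
        a = set(universe[:5])
        b = set(universe[:5]) | set(universe[10:13])
        k, p = list_overlap_test(a, b, universe)
        assert k == 5
        assert p == pytest.approx(56 / 15504, rel=1e-10)

    def test_disjoint_lists(self):
        universe = [f"g{i}" for i in range(10)]
        k, p = list_overlap_test(set(universe[:3]), set(universe[7:]), universe)
        assert k == 0 and p == 1.0

    def test_identical_full_lists(self):
        universe = [f"g{i}" for i in range(6)]
        k, p = list_overlap_test(set(universe), set(universe), universe)
        assert k == 6 and p == 1.0

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            list_overlap_test({"a"}, {"a"}, [])


class TestPermutationCalibrate:
    def _fixture(self):
        ann = annotation_from(
            [("GA", "1", 100, "+"), ("GB", "1", 10_000, "+")]
        )
        table = assoc_table(
            ["1"] * 4, [90, 110, 9_990, 10_010], [1e-6, 0.9, 0.8, 0.7]
        )
        sets = GeneSetCollection(
            sets={"S": ("S", frozenset({"GA"}))}, universe=["GA", "GB"]
        )
        return table, ann, sets

    def test_enumerated_shuffles_match_hand_computation(self):
        """Replay the recorded shuffles and recompute each statistic directly."""
        table, ann, sets = self._fixture()
        B, seed = 4, 42
        (res,) = permutation_calibrate(table, 5e-4, ann, sets, B=B, seed=seed)
        # independent replay of the same permutation stream
        rng = np.random.default_rng(seed)
        pvec = table["p"].to_numpy()
        gene_of = np.array(["GA", "GA", "GB", "GB"])

        def stat(pcol):
            genes = set(gene_of[pcol <= 5e-4])
            n = len(genes)
            if n == 0:
                return 1.0
            k = len(genes & {"GA"})
            return hypergeom_tail_enumeration(k, 2, 1, n)

        observed = stat(pvec)
        b = sum(stat(rng.permutation(pvec)) <= observed for _ in range(B))
        assert res.p_perm == pytest.approx((b + 1) / (B + 1), rel=1e-12)

    def test_never_beaten_gives_floor(self):
        # 30 variants, each nearest a distinct gene; the 5 selected variants
        # exactly cover the 5-gene set, so the observed statistic 1/C(30,5)
        # is (essentially surely) never matched by a permutation
        ann = annotation_from([(f"G{i:02d}", "1", 1000 * (i + 1), "+") for i in range(30)])
        p = np.full(30, 0.9)
        p[:5] = 1e-6
        table = assoc_table(["1"] * 30, 1000 * (np.arange(30) + 1), p)
        sets = GeneSetCollection(
            sets={"S": ("S", frozenset({f"G{i:02d}" for i in range(5)}))},
            universe=[f"G{i:02d}" for i in range(30)],
        )
        (res,) = permutation_calibrate(table, 5e-4, ann, sets, B=9, seed=0)
        assert res.p_perm == pytest.approx(1 / 10, rel=1e-12)

    def test_always_beaten_gives_one(self):
        # observed selection empty -> observed statistic 1, every permuted
        # statistic is <= 1, so p_perm = (B+1)/(B+1) = 1
        table, ann, sets = self._fixture()
        table = table.assign(p=[0.9, 0.9, 0.8, 0.7])
        (res,) = permutation_calibrate(table, 5e-4, ann, sets, B=20, seed=0)
        assert res.p_perm == 1.0

    def test_monotone_in_observed_statistic(self):
        """For a fixed stream, a larger observed p_hyper never lowers p_perm."""
        ann = annotation_from([(f"G{i}", "1", 1000 * (i + 1), "+") for i in range(20)])
        rng = np.random.default_rng(5)
        positions = 1000 * (np.arange(20) + 1)
        sets = GeneSetCollection(
            sets={"S": ("S", frozenset({f"G{i}" for i in range(8)}))},
            universe=[f"G{i}" for i in range(20)],
        )
        results = []
        for n_hits in (6, 4, 2):  # weaker and weaker observed enrichment
            p = np.full(20, 0.9)
            p[:n_hits] = 1e-6
            table = assoc_table(["1"] * 20, positions, p)
            (res,) = permutation_calibrate(table, 5e-4, ann, sets, B=200, seed=77)
            results.append((res.p_hyper, res.p_perm))
        hyper = [r[0] for r in results]
        perm = [r[1] for r in results]
        assert hyper == sorted(hyper)
        assert perm == sorted(perm)

    def test_floor_and_range(self):
        table, ann, sets = self._fixture()
        (res,) = permutation_calibrate(table, 5e-4, ann, sets, B=2000, seed=3)
        assert 1 / 2001 <= res.p_perm <= 1.0

    def test_b_zero_rejected(self):
        table, ann, sets = self._fixture()
        with pytest.raises(ValueError):
            permutation_calibrate(table, 5e-4, ann, sets, B=0, seed=0)
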
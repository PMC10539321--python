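"""Clumping, score building and score-trait association."""

import numpy as np
import pandas as pd
import pytest

from endogwas import (
    AssocConfig,
    ClumpParams,
    SimConfig,
    associate_score,
    build_score,
    ld_clump,
    simulate_base_gwas,
    simulate_cohort,
)
from endogwas.prs import LDReference
from conftest import make_cohort


def stats_table(positions, pvals, chrom="1"):
    m = len(positions)
    return pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": positions,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "effect_allele": ["G"] * m,
            "beta": np.ones(m),
            "se": np.ones(m),
            "p": pvals,
            "maf": np.full(m, 0.2),
            "n": np.full(m, 1000),
        }
    )


def matrix_ld(r2, positions, chrom="1"):
    variants = pd.DataFrame({"chrom": [chrom] * len(positions), "pos": positions})
    return np.asarray(r2, dtype=float), variants


def greedy_clump_oracle(stats, r2_lookup, params):
    """Independent reimplementation of the greedy clumping definition."""
    remaining = [
        row
        for _, row in stats.iterrows()
        if row["p"] <= params.p_threshold
    ]
    remaining.sort(key=lambda r: (r["p"], str(r["chrom"]), int(r["pos"])))
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append((str(index["chrom"]), int(index["pos"])))
        survivors = []
        for row in remaining:
            same_chrom = str(row["chrom"]) == str(index["chrom"])
            in_window = abs(int(row["pos"]) - int(index["pos"])) <= params.window_kb * 1000
            if same_chrom and in_window:
                r2 = r2_lookup(
                    (str(index["chrom"]), int(index["pos"])),
                    (str(row["chrom"]), int(row["pos"])),
                )
                if r2 >= params.r2_threshold:
                    continue
            survivors.append(row)
        remaining = survivors
    return sorted(kept)


class TestLdClump:
    def test_no_ld_keeps_all_below_threshold(self):
        positions = [1000, 2000, 3000, 4000]
        r2, variants = matrix_ld(np.eye(4), positions)
        stats = stats_table(positions, [1e-8, 1e-6, 0.02, 0.5])
        out = ld_clump(stats, r2, ClumpParams(p_threshold=0.05), variants=variants)
        assert sorted(out["pos"]) == [1000, 2000, 3000]

    def test_hand_simulated_greedy_pass(self):
        positions = [1000, 2000, 3000]
        r2 = np.eye(3)
        r2[0, 1] = r2[1, 0] = 0.5
        _, variants = matrix_ld(r2, positions)
        stats = stats_table(positions, [1e-8, 1e-6, 1e-4])
        out = ld_clump(stats, r2, ClumpParams(r2_threshold=0.1, window_kb=250), variants=variants)
        assert sorted(out["pos"]) == [1000, 3000]  # variant 2 pruned by variant 1

    def test_window_rule(self):
        positions = [1000, 600_000]  # 599 kb apart, r2 = 0.9
        r2 = np.array([[1.0, 0.9], [0.9, 1.0]])
        _, variants = matrix_ld(r2, positions)
        stats = stats_table(positions, [1e-8, 1e-6])
        out = ld_clump(stats, r2, ClumpParams(r2_threshold=0.1, window_kb=250), variants=variants)
        assert len(out) == 2  # outside the window: both retained

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(11)
        positions = list(range(1000, 13_000, 1000))
        A = rng.random((12, 12))
        r2 = np.clip((A + A.T) / 2, 0, 1)
        np.fill_diagonal(r2, 1.0)
        _, variants = matrix_ld(r2, positions)
        stats = stats_table(positions, rng.uniform(1e-8, 1.0, size=12))
        params = ClumpParams(r2_threshold=0.3, window_kb=5)
        baseline = ld_clump(stats, r2, params, variants=variants)["pos"].tolist()
        for _ in range(50):
            shuffled = stats.sample(frac=1.0, random_state=int(rng.integers(1 << 30)))
            out = ld_clump(shuffled, r2, params, variants=variants)["pos"].tolist()
            assert out == baseline

    def test_matches_independent_greedy_oracle(self):
        rng = np.random.default_rng(21)
        params = ClumpParams(r2_threshold=0.25, window_kb=4)
        for trial in range(25):
            positions = sorted(rng.choice(np.arange(1000, 30_000, 500), 12, replace=False))
            A = rng.random((12, 12))
            r2 = np.clip((A + A.T) / 2, 0, 1)
            np.fill_diagonal(r2, 1.0)
            _, variants = matrix_ld(r2, positions)
            stats = stats_table(positions, rng.uniform(0, 1, size=12))
            out = ld_clump(stats, r2, params, variants=variants)
            got = sorted(zip(out["chrom"].astype(str), out["pos"].astype(int)))
            lookup = {(str(c), int(p)): j for j, (c, p) in enumerate(zip(variants["chrom"], variants["pos"]))}
            expected = greedy_clump_oracle(
                stats, lambda a, b: r2[lookup[a], lookup[b]], params
            )
            assert got == expected, f"trial {trial}"
            # post-hoc audit: no retained pair within window has r2 >= cut
            for i in range(len(got)):
                for j in range(i + 1, len(got)):
                    if abs(got[i][1] - got[j][1]) <= params.window_kb * 1000:
                        assert r2[lookup[got[i]], lookup[got[j]]] < params.r2_threshold


class TestBuildScore:
    def test_zero_weights_zero_scores(self):
        g = np.array([[0.0, 1.0], [2.0, 1.0]])
        cohort = make_cohort(g, np.zeros(2))
        weights = stats_table([1000, 2000], [0.5, 0.5]).assign(weight=[0.0, 0.0])
        np.testing.assert_array_equal(build_score(weights, cohort), np.zeros(2))

    def test_hand_computed_centred_scores(self):
        g = np.array([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0]])
        cohort = make_cohort(g, np.zeros(2))
        weights = stats_table([1000, 2000, 3000], [0.5] * 3).assign(weight=[0.5, -1.0, 0.25])
        scores = build_score(weights, cohort)
        np.testing.assert_allclose(scores, [-0.25, 0.25], atol=1e-12)

    def test_centring_identity(self, continuous_cohort):
        base = simulate_base_gwas(continuous_cohort, h2=0.2, seed=5)
        scores = build_score(base.rename(columns={"beta": "weight"}), continuous_cohort)
        assert abs(scores.sum()) < 1e-8

    def test_ref_effect_allele_flips_sign(self):
        g = np.array([[0.0], [1.0], [2.0]])
        cohort = make_cohort(g, np.zeros(3))
        alt = stats_table([1000], [0.5]).assign(weight=[1.0])
        ref = alt.assign(effect_allele=["A"])
        np.testing.assert_allclose(build_score(ref, cohort), -build_score(alt, cohort), atol=1e-12)

    def test_ambiguous_variants_dropped(self):
        g = np.array([[0.0, 1.0], [2.0, 1.0], [1.0, 0.0]])
        cohort = make_cohort(g, np.zeros(3), ref="A", alt="T")  # both A/T: ambiguous
        weights = stats_table([1000, 2000], [0.5, 0.5]).assign(weight=[1.0, 1.0])
        with pytest.raises(ValueError, match="no variants overlap"):
            with pytest.warns(UserWarning, match="ambiguous"):
                build_score(weights, cohort)


class TestAssociateScore:
    def test_bonferroni_family_of_five(self, continuous_cohort):
        scores = np.asarray(continuous_cohort.dosages[:, 0], dtype=float)
        result = associate_score(scores, continuous_cohort, n_scores_in_family=5)
        assert result.bonferroni_alpha == pytest.approx(0.01)

    def test_perfect_predictor(self, continuous_cohort):
        result = associate_score(
            continuous_cohort.phenotype.copy(), continuous_cohort, n_scores_in_family=1
        )
        assert result.beta == pytest.approx(1.0, abs=1e-10)
        assert result.p <= np.finfo(float).tiny * 10

    def test_constant_score_rejected(self, continuous_cohort):
        with pytest.raises(ValueError):
            associate_score(np.zeros(continuous_cohort.n_individuals), continuous_cohort)


class TestSharedArchitectureRecovery:
    def test_prs_sign_and_power_over_seeds(self):
        """A base GWAS sharing the cohort's causal variants yields a score
        that associates positively with the trait in nearly every seed."""
        positive, significant = 0, 0
        n_seeds = 40
        for seed in range(n_seeds):
            cohort = simulate_cohort(
                SimConfig(
                    n_individuals=2000,
                    n_variants=100,
                    n_blocks=10,
                    causal_spec=[(15, 0.04), (35, 0.04), (60, 0.04), (85, 0.04)],
                    phenotype_mode="continuous",
                    seed=1000 + seed,
                )
            )
            base = simulate_base_gwas(cohort, h2=0.3, seed=2000 + seed)
            ld = LDReference(cohort.dosages, cohort.variants)
            clumped = ld_clump(base, ld, ClumpParams(p_threshold=0.05))
            scores = build_score(clumped.rename(columns={"beta": "weight"}), cohort)
            result = associate_score(scores, cohort)
            positive += result.beta > 0
            significant += result.p < 0.05
        assert positive >= 0.95 * n_seeds
        assert significant >= 0.90 * n_seeds
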
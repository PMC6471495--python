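import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from racepop.diversity import (
    allele_freq,
    locus_diversity,
    matrix_diversity,
    population_diversity,
)
from racepop.io_genotypes import MISSING, GenotypeMatrix, Race, SamplePanel
from racepop.simulate import SimulationConfig, simulate_panel

from conftest import random_matrix


def oracle_locus_stats(calls: list[int]) -> dict[str, float]:
    """Direct-summation oracle: tally alleles one by one from dosage calls."""
    typed = [c for c in calls if c != MISSING]
    n = len(typed)
    alt = 0
    het = 0
    for c in typed:
        alt += c
        if c == 1:
            het += 1
    p = alt / (2 * n)
    q = 1 - p
    he = 2 * p * q
    shannon = 0.0
    for x in (p, q):
        if x > 0:
            shannon -= x * math.log(x)
    return {
        "n_typed": n,
        "p_alt": p,
        "maf": min(p, q),
        "ho": het / n,
        "he": he,
        "nei": (2 * n / (2 * n - 1)) * he,
        "shannon_i": shannon,
        "pic": 1 - (p**2 + q**2) - 2 * p**2 * q**2,
    }


class TestAlleleFreq:
    def test_all_ref(self):
        gm = GenotypeMatrix(
            ["a", "b"], ["l"], np.zeros((2, 1), np.int8), ["A"], ["G"]
        )
        assert allele_freq(gm, "l") == (0.0, 2)

    def test_three_genotypes_half(self):
        gm = GenotypeMatrix(
            ["a", "b", "c"],
            ["l"],
            np.array([[0], [1], [2]], np.int8),
            ["A"],
            ["G"],
        )
        p, n = allele_freq(gm, "l")
        assert p == 0.5 and n == 3

    def test_all_missing_flagged(self):
        gm = GenotypeMatrix(
            ["a"], ["l"], np.array([[MISSING]], np.int8), ["A"], ["G"]
        )
        p, n = allele_freq(gm, "l")
        assert n == 0 and math.isnan(p)

    def test_matches_brute_force(self, rng):
        gm = random_matrix(rng, 15, 40, missing_rate=0.2)
        for locus in gm.locus_ids:
            j = gm.locus_index([locus])[0]
            col = [int(x) for x in gm.dosage[:, j]]
            typed = [c for c in col if c != MISSING]
            if not typed:
                continue
            p, n = allele_freq(gm, locus)
            assert n == len(typed)
            assert p == pytest.approx(sum(typed) / (2 * len(typed)), abs=1e-15)


class TestLocusDiversity:
    def test_half_frequency_closed_form(self):
        gm = GenotypeMatrix(
            ["a", "b", "c", "d"],
            ["l"],
            np.array([[0], [1], [1], [2]], np.int8),
            ["A"],
            ["G"],
        )
        d = locus_diversity(gm, "l")
        assert d.he == pytest.approx(0.5)
        assert d.maf == pytest.approx(0.5)
        assert d.shannon_i == pytest.approx(math.log(2))
        assert d.pic == pytest.approx(0.375)

    def test_monomorphic(self):
        gm = GenotypeMatrix(
            ["a", "b"], ["l"], np.zeros((2, 1), np.int8), ["A"], ["G"]
        )
        d = locus_diversity(gm, "l")
        assert d.he == 0 and d.shannon_i == 0 and d.pic == 0

    def test_nei_small_n_correction(self):
        # p = 0.5 with n = 2 -> nei = (4/3) * 0.5
        gm = GenotypeMatrix(
            ["a", "b"], ["l"], np.array([[1], [1]], np.int8), ["A"], ["G"]
        )
        d = locus_diversity(gm, "l")
        assert d.nei == pytest.approx(4.0 / 3.0 * 0.5)

    def test_undersized_locus_rejected(self):
        gm = GenotypeMatrix(
            ["a", "b"],
            ["l"],
            np.array([[1], [MISSING]], np.int8),
            ["A"],
            ["G"],
        )
        with pytest.raises(ValueError, match="typed"):
            locus_diversity(gm, "l")


class TestOracleEquivalence:
    def test_random_matrices_match_oracle(self):
        # the per-locus statistics equal direct summation to 1e-12
        for seed in range(20):
            rng = np.random.default_rng(seed)
            gm = random_matrix(
                rng,
                int(rng.integers(3, 31)),
                int(rng.integers(5, 201)),
                missing_rate=0.15,
            )
            rows = {r.locus_id: r for r in matrix_diversity(gm)}
            for j, locus in enumerate(gm.locus_ids):
                col = [int(x) for x in gm.dosage[:, j]]
                typed = [c for c in col if c != MISSING]
                if len(typed) < 2:
                    assert locus not in rows
                    continue
                exp = oracle_locus_stats(col)
                got = rows[locus]
                for stat, val in exp.items():
                    assert getattr(got, stat) == pytest.approx(val, abs=1e-12), (
                        locus,
                        stat,
                    )


@given(
    dosages=st.lists(st.integers(min_value=0, max_value=2), min_size=2, max_size=40)
)
@settings(max_examples=200, deadline=None)
def test_invariants_hold(dosages):
    gm = GenotypeMatrix(
        [f"s{i}" for i in range(len(dosages))],
        ["l"],
        np.array([[d] for d in dosages], np.int8),
        ["A"],
        ["G"],
    )
    d = locus_diversity(gm, "l")
    assert 0 <= d.maf <= 0.5
    assert 0 <= d.ho <= 1
    assert 0 <= d.he <= 0.5
    assert d.pic <= d.he + 1e-15
    assert d.he <= d.shannon_i + 1e-15 or d.he == 0
    assert d.shannon_i <= math.log(2) + 1e-15
    assert d.nei >= d.he - 1e-15
    # invariance under allele relabeling (dosage 2 - d)
    flipped = GenotypeMatrix(
        gm.sample_ids,
        ["l"],
        2 - gm.dosage,
        ["G"],
        ["A"],
    )
    f = locus_diversity(flipped, "l")
    for stat in ("maf", "ho", "he", "nei", "shannon_i", "pic"):
        assert getattr(f, stat) == pytest.approx(getattr(d, stat), abs=1e-12)


class TestPopulationDiversity:
    def test_identical_populations_identical_rows(self, rng):
        gm = random_matrix(rng, 4, 20)
        gm.dosage[2:] = gm.dosage[:2]
        panel = SamplePanel(gm.sample_ids, [Race.M] * 4)
        grouping = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        rows = {r.population: r for r in population_diversity(gm, panel, grouping)}
        for stat in ("maf", "ho", "he", "nei", "shannon_i", "pic"):
            assert getattr(rows["A"], stat) == pytest.approx(getattr(rows["B"], stat))

    def test_hand_calculation(self):
        # 3 samples, 2 loci; locus1 dosages (0,1,1): p=1/3; locus2 (2,2,1): p=5/6
        gm = GenotypeMatrix(
            ["a", "b", "c"],
            ["l1", "l2"],
            np.array([[0, 2], [1, 2], [1, 1]], np.int8),
            ["A", "A"],
            ["G", "G"],
        )
        panel = SamplePanel(["a", "b", "c"], [Race.M] * 3)
        (row,) = population_diversity(gm, panel, {s: "P" for s in gm.sample_ids})
        he1 = 2 * (1 / 3) * (2 / 3)
        he2 = 2 * (5 / 6) * (1 / 6)
        assert row.he == pytest.approx((he1 + he2) / 2)
        assert row.ho == pytest.approx((2 / 3 + 1 / 3) / 2)
        assert row.maf == pytest.approx((1 / 3 + 1 / 6) / 2)

    def test_small_population_rejected(self, rng):
        gm = random_matrix(rng, 3, 5)
        panel = SamplePanel(gm.sample_ids, [Race.M] * 3)
        with pytest.raises(ValueError, match="lonely"):
            population_diversity(gm, panel, {"s0": "lonely", "s1": "P", "s2": "P"})

    def test_admixed_group_more_diverse(self):
        # mixture of two diverged sources has higher expected heterozygosity
        cfg = SimulationConfig(
            n_per_group={Race.M: 10, Race.G: 10, Race.GXM: 10},
            n_loci=2000,
            divergence_F=0.4,
            hybrid_q={Race.GXM: (0.5, 0.5)},
            seed=11,
        )
        gm, panel, _ = simulate_panel(cfg)
        rows = {r.population: r for r in population_diversity(gm, panel)}
        assert rows["GxM"].he > rows["M"].he
        assert rows["GxM"].he > rows["G"].he
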
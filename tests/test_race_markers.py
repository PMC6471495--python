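import numpy as np
import pytest

from racepop.io_genotypes import MISSING, GenotypeMatrix, Race, SamplePanel
from racepop.race_markers import (
    FAM_TAIL,
    VIC_TAIL,
    RaceSpecificLocus,
    build_kasp_assays,
    classify_race,
    find_race_specific_loci,
    parse_context_fasta,
)
from racepop.simulate import diagnostic_contexts, mimic_paper_panel


def _toy_panel():
    """2 M, 2 G, 2 WI, 2 GxM, 2 GxWI across 4 loci:

    l0: M-diagnostic (alt fixed in M, absent elsewhere, carried by GxM)
    l1: fixed same allele everywhere -> rejected at step 2
    l2: would be G-diagnostic but one call missing -> rejected at step 1
    l3: WI-diagnostic
    """
    sample_ids = ["m1", "m2", "g1", "g2", "w1", "w2", "gm1", "gm2", "gw1", "gw2"]
    races = [
        Race.M, Race.M, Race.G, Race.G, Race.WI, Race.WI,
        Race.GXM, Race.GXM, Race.GXWI, Race.GXWI,
    ]
    dosage = np.array(
        [
            # l0 l1 l2 l3
            [2, 2, 0, 0],  # m1
            [2, 2, 0, 0],  # m2
            [0, 2, 2, 0],  # g1
            [0, 2, 2, 0],  # g2
            [0, 2, 0, 2],  # w1
            [0, 2, MISSING, 2],  # w2  (l2 killed at step 1)
            [1, 2, 1, 0],  # gm1
            [1, 2, 1, 0],  # gm2
            [0, 2, 1, 1],  # gw1
            [0, 2, 1, 1],  # gw2
        ],
        dtype=np.int8,
    )
    gm = GenotypeMatrix(
        sample_ids,
        ["l0", "l1", "l2", "l3"],
        dosage,
        np.array(["A"] * 4),
        np.array(["G"] * 4),
    )
    return gm, SamplePanel(sample_ids, races)


class TestFindRaceSpecificLoci:
    def test_toy_panel(self):
        gm, panel = _toy_panel()
        found = find_race_specific_loci(gm, panel)
        assert [(m.locus_id, m.race, m.diagnostic_allele) for m in found] == [
            ("l0", Race.M, "alt"),
            ("l3", Race.WI, "alt"),
        ]
        assert found[0].hybrid_support == 2

    def test_same_allele_everywhere_rejected(self):
        gm, panel = _toy_panel()
        found = find_race_specific_loci(gm, panel)
        assert "l1" not in {m.locus_id for m in found}

    def test_missing_call_rejected_at_step1(self):
        gm, panel = _toy_panel()
        found = find_race_specific_loci(gm, panel)
        assert "l2" not in {m.locus_id for m in found}

    def test_sample_and_locus_order_invariant(self, rng):
        gm, panel, _ = mimic_paper_panel(
            0.3, seed=5, n_loci=300, n_diagnostic_per_race=2, hybrid_mode="f1"
        )
        base = find_race_specific_loci(gm, panel)
        sperm = [gm.sample_ids[i] for i in rng.permutation(gm.n_samples)]
        lperm = [gm.locus_ids[j] for j in rng.permutation(gm.n_loci)]
        shuffled = gm.subset_samples(sperm).subset_loci(lperm)
        found = find_race_specific_loci(shuffled, panel)
        assert {(m.locus_id, m.race, m.diagnostic_allele) for m in found} == {
            (m.locus_id, m.race, m.diagnostic_allele) for m in base
        }

    def test_recovers_planted_loci(self):
        gm, panel, truth = mimic_paper_panel(
            0.3, seed=9, n_loci=500, n_diagnostic_per_race=3, hybrid_mode="f1"
        )
        found = find_race_specific_loci(gm, panel)
        planted = {
            (l, race) for race, loci in truth.diagnostic_loci.items() for l, _ in loci
        }
        assert {(m.locus_id, m.race) for m in found} == planted

    def test_brute_force_recheck_of_predicates(self):
        gm, panel, _ = mimic_paper_panel(
            0.3, seed=12, n_loci=400, n_diagnostic_per_race=2, hybrid_mode="f1"
        )
        race_map = panel.race_map()
        for m in find_race_specific_loci(gm, panel):
            j = gm.locus_index([m.locus_id])[0]
            col = gm.dosage[:, j]
            labelled = [
                i for i, s in enumerate(gm.sample_ids)
                if race_map[s] is not Race.UNKNOWN
            ]
            assert all(col[i] != MISSING for i in labelled)  # step 1
            diag_dosage = 2 if m.diagnostic_allele == "alt" else 0
            for i, s in enumerate(gm.sample_ids):
                r = race_map[s]
                if r is m.race:
                    assert col[i] == diag_dosage  # fixed in own race
                elif r in (Race.M, Race.G, Race.WI):
                    assert col[i] == 2 - diag_dosage  # absent from other pure
            carriers = lambda idxs: sum(
                1 for i in idxs
                if (col[i] >= 1 if m.diagnostic_allele == "alt" else col[i] <= 1)
            )
            gxm = [i for i, s in enumerate(gm.sample_ids) if race_map[s] is Race.GXM]
            gxwi = [i for i, s in enumerate(gm.sample_ids) if race_map[s] is Race.GXWI]
            if m.race is Race.M:
                assert carriers(gxm) == len(gxm)
            elif m.race is Race.WI:
                assert carriers(gxwi) == len(gxwi)
            else:
                assert carriers(gxm) + carriers(gxwi) >= int(
                    np.ceil(11 * (len(gxm) + len(gxwi)) / 14)
                )

    def test_missing_pure_race_errors(self):
        gm, panel = _toy_panel()
        no_wi = SamplePanel(
            panel.sample_ids,
            [Race.G if r is Race.WI else r for r in panel.race_labels],
        )
        with pytest.raises(ValueError, match="WI"):
            find_race_specific_loci(gm, no_wi)


class TestKaspAssays:
    def _context(self):
        down = "TTAACCGGTT" * 5
        return {"L1": "ACGTACGTACGTACGTACGTACGT[A/G]" + down}

    def _locus(self):
        return RaceSpecificLocus("L1", Race.M, "alt", 7)

    def test_tails_verbatim(self):
        (assay,) = build_kasp_assays([self._locus()], self._context(), oligo_len=10)
        assert assay.fam_oligo.startswith("GAAGGTGACCAAGTTCATGCT")
        assert assay.vic_oligo.startswith("GAAGGTCGGAGTCAACGGATT")

    def test_three_prime_terminal_allele(self):
        (assay,) = build_kasp_assays([self._locus()], self._context(), oligo_len=10)
        assert assay.fam_oligo.endswith("A")
        assert assay.vic_oligo.endswith("G")
        # 3' stem = the 9 bases immediately 5' of the SNP, then the allele
        assert assay.fam_oligo[len(FAM_TAIL):] == "TACGTACGT" + "A"
        assert assay.vic_oligo[len(VIC_TAIL):] == "TACGTACGT" + "G"

    def test_oligos_differ_only_in_last_base(self):
        (assay,) = build_kasp_assays([self._locus()], self._context(), oligo_len=10)
        fam_core = assay.fam_oligo[len(FAM_TAIL):]
        vic_core = assay.vic_oligo[len(VIC_TAIL):]
        assert fam_core[:-1] == vic_core[:-1]
        assert fam_core[-1] != vic_core[-1]

    def test_common_primer_reverse_complement(self):
        (assay,) = build_kasp_assays(
            [self._locus()], self._context(), oligo_len=10, common_offset=4, common_len=6
        )
        # downstream = TTAACCGGTT..., offset 4 -> template CCGGTT -> revcomp AACCGG
        assert assay.common_primer == "AACCGG"

    def test_naming_per_race(self):
        loci = [
            RaceSpecificLocus("L1", Race.M, "alt", 7),
            RaceSpecificLocus("L2", Race.M, "alt", 7),
            RaceSpecificLocus("L3", Race.G, "alt", 11),
            RaceSpecificLocus("L4", Race.WI, "alt", 7),
        ]
        ctx = {k: self._context()["L1"] for k in ("L1", "L2", "L3", "L4")}
        names = [a.assay_name for a in build_kasp_assays(loci, ctx, oligo_len=10)]
        assert names == ["PaMsSNP1", "PaMsSNP2", "PaGsSNP1", "PaWIsSNP1"]

    def test_insufficient_flank_errors(self):
        ctx = {"L1": "ACG[A/G]TT"}
        with pytest.raises(ValueError, match="L1"):
            build_kasp_assays([self._locus()], ctx, oligo_len=10)

    def test_pcr_profile_recorded(self):
        (assay,) = build_kasp_assays([self._locus()], self._context(), oligo_len=10)
        assert "94C 15min" in assay.pcr_profile["hot_start"]
        assert "61C->58C" in assay.pcr_profile["touchdown"]
        assert "57C" in assay.pcr_profile["amplification"]

    def test_parse_context_fasta(self, tmp_path):
        fasta = tmp_path / "ctx.fa"
        fasta.write_text(">L1 extra stuff\nACGT[A/G]\nTTTT\n>L2\nGG[C/T]AA\n")
        ctx = parse_context_fasta(fasta)
        assert ctx == {"L1": "ACGT[A/G]TTTT", "L2": "GG[C/T]AA"}


class TestClassifyRace:
    def _markers(self):
        return [
            RaceSpecificLocus("lm", Race.M, "alt", 2),
            RaceSpecificLocus("lg", Race.G, "alt", 2),
            RaceSpecificLocus("lw", Race.WI, "alt", 2),
        ]

    def _matrix(self, rows):
        return GenotypeMatrix(
            [f"s{i}" for i in range(len(rows))],
            ["lm", "lg", "lw"],
            np.array(rows, dtype=np.int8),
            np.array(["A"] * 3),
            np.array(["G"] * 3),
        )

    def test_pure_m(self):
        gm = self._matrix([[2, 0, 0]])
        (call,) = classify_race(gm, self._markers())
        assert call.call == "M"
        assert call.detected_races == frozenset({Race.M})

    def test_f1_gxwi(self):
        gm = self._matrix([[0, 1, 1]])
        (call,) = classify_race(gm, self._markers())
        assert call.call == "GxWI"
        assert call.detected_races == frozenset({Race.G, Race.WI})

    def test_triple_carrier_ambiguous(self):
        gm = self._matrix([[1, 1, 1]])
        (call,) = classify_race(gm, self._markers())
        assert call.call == "AMBIGUOUS"

    def test_het_single_race_ambiguous(self):
        gm = self._matrix([[1, 0, 0]])
        (call,) = classify_race(gm, self._markers())
        assert call.call == "AMBIGUOUS"
        assert "homozygous" in call.reason

    def test_all_missing_ambiguous(self):
        gm = self._matrix([[MISSING, MISSING, MISSING]])
        (call,) = classify_race(gm, self._markers())
        assert call.call == "AMBIGUOUS"
        assert "missing" in call.reason

    def test_agreement_bounds(self):
        gm = self._matrix([[2, 0, 0]])
        with pytest.raises(ValueError):
            classify_race(gm, self._markers(), agreement=0.4)
        with pytest.raises(ValueError):
            classify_race(gm, self._markers(), agreement=1.2)

    def test_needs_two_races(self):
        gm = self._matrix([[2, 0, 0]])
        with pytest.raises(ValueError, match="2 races"):
            classify_race(gm, [RaceSpecificLocus("lm", Race.M, "alt", 2)])


class TestEndToEnd:
    def test_simulated_panel_all_true_classes(self):
        gm, panel, truth = mimic_paper_panel(
            0.3,
            seed=21,
            n_loci=400,
            n_diagnostic_per_race=3,
            hybrid_mode="f1",
            n_unknown=8,
        )
        markers = find_race_specific_loci(gm, panel)
        calls = {c.sample_id: c.call for c in classify_race(gm, markers)}
        for s in gm.sample_ids:
            r = panel.race_of(s)
            expected = "GxWI" if r in (Race.GXWI, Race.UNKNOWN) else r.value
            assert calls[s] == expected, (s, calls[s], expected)

    def test_kasp_from_discovered_markers(self):
        gm, panel, truth = mimic_paper_panel(
            0.3, seed=22, n_loci=300, n_diagnostic_per_race=2, hybrid_mode="f1"
        )
        markers = find_race_specific_loci(gm, panel)
        ctx = diagnostic_contexts(gm, truth, flank=60, seed=0)
        assays = build_kasp_assays(markers, ctx)
        assert len(assays) == len(markers)
        for a in assays:
            assert a.fam_oligo.startswith(FAM_TAIL)
            assert a.vic_oligo.startswith(VIC_TAIL)
            assert a.fam_oligo[-1] == a.fam_allele
            assert a.vic_oligo[-1] == a.vic_allele
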
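"""Scar assembly, oligo design, SOE joining, and genome surgery."""

import numpy as np
import pytest

from barseqkit.barcodes import generate_barcode
from barseqkit.constructs import (
    DEFAULT_LINKERS,
    FRT_SITE,
    LL_FORWARD,
    R1_LL_EXTENSION,
    RIGHT_FLANK,
    RL_SEQUENCE,
    SPACER_SEQUENCE,
    FlankTooShortError,
    GeneTarget,
    LinkerSet,
    SoeJoinError,
    apply_deletion,
    assemble_bar_scar,
    assemble_erm_bar_scar,
    codon_family_usage,
    design_oligos,
    flp_excise,
    revcomp,
    soe_join,
    verify_in_frame,
)

from conftest import make_gene


class TestLinkerConstants:
    def test_left_linker_is_revcomp_of_r1_extension(self):
        assert LL_FORWARD == revcomp(R1_LL_EXTENSION)
        assert LL_FORWARD == "ACGAGACGAGCTTCTTATATATGCTTCGCCAG"
        assert len(LL_FORWARD) == 32

    def test_right_flank_is_rl_prefix(self):
        assert RIGHT_FLANK == RL_SEQUENCE[:18]
        assert len(RL_SEQUENCE) == 33
        assert len(SPACER_SEQUENCE) == 18

    def test_frt_remnant_is_34_nt(self):
        assert len(FRT_SITE) == 34

    def test_erm_cassette_flanked_by_frt(self):
        cassette = DEFAULT_LINKERS.erm_cassette
        assert cassette.startswith(FRT_SITE) and cassette.endswith(FRT_SITE)


class TestScarAssembly:
    def test_bar_scar_is_138_bp_with_tiling_offsets(self, rng):
        for _ in range(20):
            scar = assemble_bar_scar(generate_barcode(rng))
            assert len(scar) == 138
            # components tile [0, 138) without gaps or overlaps
            intervals = sorted(scar.offsets.values())
            assert intervals[0][0] == 0 and intervals[-1][1] == 138
            assert all(
                intervals[i][1] == intervals[i + 1][0]
                for i in range(len(intervals) - 1)
            )

    def test_layout_and_barcode_placement(self, rng):
        bc = generate_barcode(rng)
        scar = assemble_bar_scar(bc)
        assert scar.seq[:3] == "ATG"
        assert scar.seq[69:87] == SPACER_SEQUENCE
        assert scar.seq[87:105] == bc.seq
        assert scar.seq[105:123] == RIGHT_FLANK
        assert scar.offsets["barcode"] == (87, 105)
        assert 87 % 3 == 0  # barcode occupies whole codons

    def test_no_trimer_aligned_stop_in_scar(self, rng):
        stops = {"TAA", "TAG", "TGA"}
        for _ in range(50):
            scar = assemble_bar_scar(generate_barcode(rng))
            assert all(
                scar.seq[i : i + 3] not in stops for i in range(0, 138, 3)
            )

    def test_invalid_barcode_rejected(self):
        with pytest.raises(ValueError, match="invalid barcode"):
            assemble_bar_scar("T" * 18)

    def test_erm_bar_length_arithmetic(self, rng):
        bc = generate_barcode(rng)
        bar = assemble_bar_scar(bc)
        erm = assemble_erm_bar_scar(bc)
        cassette = DEFAULT_LINKERS.erm_cassette
        assert len(erm) - len(bar) == len(cassette) - len(FRT_SITE)

    def test_flp_excision_round_trip(self, rng):
        """FLP-simulated excision of erm-bar equals bar for 100 barcodes."""
        for _ in range(100):
            bc = generate_barcode(rng)
            excised = flp_excise(assemble_erm_bar_scar(bc))
            direct = assemble_bar_scar(bc)
            assert excised.seq == direct.seq
            assert excised.offsets == direct.offsets
            assert excised.kind == "bar"

    def test_trailing_intervals_identical_relative_to_scar_end(self, rng):
        bc = generate_barcode(rng)
        bar, erm = assemble_bar_scar(bc), assemble_erm_bar_scar(bc)
        for name in ("spacer", "barcode", "RL"):
            ba, bb = bar.offsets[name]
            ea, eb = erm.offsets[name]
            assert (len(bar) - ba, len(bar) - bb) == (len(erm) - ea, len(erm) - eb)

    def test_flp_excise_requires_erm_bar(self, rng):
        with pytest.raises(ValueError):
            flp_excise(assemble_bar_scar(generate_barcode(rng)))


class TestDesignOligos:
    def test_anneal_arithmetic_matches_offsets(self, toy_genome):
        genome, target = toy_genome
        oset = design_oligos(genome, target)
        assert oset["F1"].anneal[0] == 3000
        assert oset["FO"].anneal[0] == 2500
        assert oset["R2"].anneal[1] == 5900
        assert oset["RO"].anneal[1] == 6400
        assert oset["R1_LL"].anneal == (4003 - 22, 4003)
        assert oset["F2_RL"].anneal == (4879, 4901)

    def test_tagged_oligos_carry_extensions(self, toy_genome):
        genome, target = toy_genome
        oset = design_oligos(genome, target)
        assert oset["R1_LL"].seq.startswith(R1_LL_EXTENSION)
        assert oset["F2_RL"].seq.startswith(RL_SEQUENCE)

    def test_check_product_in_bounds_for_900_nt_gene(self, toy_genome):
        genome, target = toy_genome
        oset = design_oligos(genome, target)
        assert 500 <= oset.check_product_length <= 876

    def test_short_flank_raises(self, rng):
        genome = {"chr1": make_gene(rng, 900) + "A" * 3000}
        target = GeneTarget("chr1", 0, 900, "+", "g")
        with pytest.raises(FlankTooShortError, match="upstream"):
            design_oligos(genome, target)

    def test_short_gene_falls_back_with_warning(self, rng):
        genome = {"chr1": "A" * 2000 + make_gene(rng, 300) + "A" * 2000}
        target = GeneTarget("chr1", 2000, 2300, "+", "tiny")
        with pytest.warns(UserWarning, match="internal span"):
            oset = design_oligos(genome, target)
        assert oset.check_product_length == 300 - 24

    def test_minus_strand_oligos_match_coding_orientation(self, toy_genome):
        genome, plus_target = toy_genome
        # Same gene presented on the minus strand of the flipped replicon.
        flipped = {"chr1": revcomp(genome["chr1"])}
        L = len(genome["chr1"])
        minus_target = GeneTarget(
            "chr1", L - plus_target.end, L - plus_target.start, "-", "geneX"
        )
        a = design_oligos(genome, plus_target)
        b = design_oligos(flipped, minus_target)
        for name in a.oligos:
            assert a[name].seq == b[name].seq
        assert b["F1"].anneal_strand == "-"


class TestSoeJoin:
    def test_simple_join(self):
        assert soe_join(["AAAC", "ACGG"], min_overlap=2) == "AAACGG"

    def test_no_overlap_errors_with_junction(self):
        with pytest.raises(SoeJoinError, match="junction 0/1"):
            soe_join(["AAAA", "CCCC"], min_overlap=2)

    def test_ambiguous_overlap_detected(self):
        with pytest.raises(SoeJoinError, match="ambiguous"):
            soe_join(["GAAAA", "AAAAG"], min_overlap=2)

    def test_three_fragment_mutagenic_assembly(self, rng, toy_genome):
        """US arm + marked middle + DS arm fuse via LL/RL homology into ~3 kb."""
        genome, target = toy_genome
        seq = genome["chr1"]
        bc = generate_barcode(rng)
        erm = assemble_erm_bar_scar(bc)
        middle = erm.seq[3:]  # the PCR'd middle fragment has no ATG
        us_arm = seq[target.start - 1000 : target.start + 3] + LL_FORWARD
        ds_arm = RL_SEQUENCE + seq[target.end - 21 : target.end + 1000]
        product = soe_join([us_arm, middle, ds_arm], min_overlap=20)
        expected = (
            seq[target.start - 1000 : target.start + 3]
            + middle
            + seq[target.end - 21 : target.end + 1000]
        )
        assert product == expected
        assert abs(len(product) - 3000) < len(erm)

    def test_reconstructs_randomly_fragmented_sequences(self):
        """Planted-overlap property: rejoining fragments recovers the original."""
        rng = np.random.default_rng(77)
        bases = "ACGT"
        for _ in range(200):
            n = int(rng.integers(150, 600))
            original = "".join(bases[i] for i in rng.integers(0, 4, size=n))
            n_frags = int(rng.integers(2, 5))
            cuts = sorted(rng.choice(np.arange(40, n - 40), size=n_frags - 1, replace=False))
            overlap = int(rng.integers(20, 35))
            frags = []
            prev = 0
            for cut in cuts:
                frags.append(original[prev : cut + overlap])
                prev = cut
            frags.append(original[prev:])
            try:
                assert soe_join(frags, min_overlap=18) == original
            except SoeJoinError:
                # Chance secondary overlap: legitimate ambiguity report.
                pass


class TestApplyDeletion:
    def test_length_arithmetic(self, rng, toy_genome):
        genome, target = toy_genome
        scar = assemble_bar_scar(generate_barcode(rng))
        mutant = apply_deletion(genome, target, scar)
        assert len(genome["chr1"]) - len(mutant["chr1"]) == 900 - 138 - 21
        # direct string surgery oracle
        seq = genome["chr1"]
        assert mutant["chr1"] == seq[:4003] + scar.seq[3:] + seq[4879:]

    def test_spacer_barcode_found_at_exactly_one_locus(self, rng, toy_genome):
        genome, target = toy_genome
        bc = generate_barcode(rng)
        scar = assemble_bar_scar(bc)
        mutant = apply_deletion(genome, target, scar)
        probe = SPACER_SEQUENCE + bc.seq
        assert mutant["chr1"].count(probe) == 1
        assert probe not in genome["chr1"]

    def test_minus_strand_inserts_reverse_complement(self, rng, toy_genome):
        genome, plus_target = toy_genome
        flipped = {"chr1": revcomp(genome["chr1"])}
        L = len(genome["chr1"])
        minus_target = GeneTarget(
            "chr1", L - plus_target.end, L - plus_target.start, "-", "geneX"
        )
        bc = generate_barcode(rng)
        scar = assemble_bar_scar(bc)
        mut_plus = apply_deletion(genome, plus_target, scar)
        mut_minus = apply_deletion(flipped, minus_target, scar)
        assert mut_minus["chr1"] == revcomp(mut_plus["chr1"])
        assert revcomp(SPACER_SEQUENCE + bc.seq) in mut_minus["chr1"]


class TestVerifyInFrame:
    def test_valid_deletion_passes_with_46_codons(self, rng, toy_genome):
        genome, target = toy_genome
        mutant = apply_deletion(genome, target, assemble_bar_scar(generate_barcode(rng)))
        report = verify_in_frame(mutant, target)
        assert report.passed, report.messages
        assert report.scar_codons == 46
        assert report.starts_with_atg and report.in_frame

    def test_minus_strand_deletion_passes(self, rng, toy_genome):
        genome, plus_target = toy_genome
        flipped = {"chr1": revcomp(genome["chr1"])}
        L = len(genome["chr1"])
        minus_target = GeneTarget(
            "chr1", L - plus_target.end, L - plus_target.start, "-", "geneX"
        )
        mutant = apply_deletion(
            flipped, minus_target, assemble_bar_scar(generate_barcode(rng))
        )
        assert verify_in_frame(mutant, minus_target).passed

    def test_forced_stop_barcode_reported_with_position(self, rng, toy_genome):
        genome, target = toy_genome
        scar = assemble_bar_scar(generate_barcode(rng))
        # force TAA into the barcode interval, bypassing validation
        broken_seq = scar.seq[:87] + "TAA" + scar.seq[90:]
        broken = type(scar)(seq=broken_seq, offsets=scar.offsets, kind="bar")
        mutant = apply_deletion(genome, target, broken)
        report = verify_in_frame(mutant, target)
        assert not report.passed
        assert 87 in report.stop_positions

    def test_truncated_scar_fails_frame_check(self, rng, toy_genome):
        genome, target = toy_genome
        scar = assemble_bar_scar(generate_barcode(rng))
        truncated = type(scar)(seq=scar.seq[:-34] + scar.seq[-33:], offsets=scar.offsets, kind="bar")
        mutant = apply_deletion(genome, target, truncated)
        report = verify_in_frame(mutant, target)
        assert not report.passed


class TestCodonFamilyUsage:
    def test_single_codon_family_is_one(self):
        cds = ["ATG" + "CGT" * 5 + "TAA"]
        assert codon_family_usage(cds, "CGT") == 1.0

    def test_mixed_arginine_family(self):
        cds = ["ATG" + "CGT" * 3 + "AGG" + "TAA"]
        assert codon_family_usage(cds, "AGG") == 0.25

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            codon_family_usage(["ATGTAA"], "TAA")

    def test_unframed_cds_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            codon_family_usage(["ATGC"], "CGT")

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError, match="no codons"):
            codon_family_usage(["ATGATG"], "CGT")
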
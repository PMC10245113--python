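import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdnakit import (
    CLASS_COLORS,
    BedRecord,
    FeatureClass,
    Genome,
    GenomeSequence,
    GenomicInterval,
    RdnaFeature,
    RdnaReference,
    append_chrR,
    emit_annotation_bed,
    mask_fasta,
    read_bed_records,
    read_feature_table,
    rotate_features,
    rotate_reference,
    swap_refgene_ids,
    write_bed_records,
)
from rdnakit.genome_build import write_feature_table


def one_chrom(seq):
    return Genome([GenomeSequence("chr1", seq)])


class TestMask:
    def test_hard_mask(self):
        out = mask_fasta(one_chrom("ACGTACGT"), [GenomicInterval.of("chr1", 2, 4)])
        assert out["chr1"].seq == "ACNNACGT"

    def test_soft_mask(self):
        out = mask_fasta(one_chrom("ACGTACGT"), [GenomicInterval.of("chr1", 2, 4)], mode="soft")
        assert out["chr1"].seq == "ACgtACGT"

    def test_n_count_conservation_and_untouched_bases(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        ivs = [GenomicInterval.of("chr1", 100, 400), GenomicInterval.of("chr1", 900, 950)]
        out = mask_fasta(one_chrom(seq), ivs)
        masked = out["chr1"].seq
        assert len(masked) == len(seq)
        assert masked.count("N") - seq.count("N") == 350
        # positions outside the intervals are bit-identical
        for i, (a, b) in enumerate(zip(seq, masked)):
            inside = 100 <= i < 400 or 900 <= i < 950
            assert (a == b) != inside or (inside and b == "N")

    def test_out_of_bounds_interval_names_itself(self):
        with pytest.raises(ValueError, match="chr1:5-100"):
            mask_fasta(one_chrom("ACGTACGT"), [GenomicInterval.of("chr1", 5, 100)])

    def test_bad_mode(self):
        with pytest.raises(ValueError, match="hard.*soft"):
            mask_fasta(one_chrom("ACGT"), [], mode="lower")


class TestRotation:
    def test_toy_example(self):
        assert rotate_reference("ABCDEFGHIJ", 7) == "HIJABCDEFG"

    def test_cut_at_length_is_identity(self):
        assert rotate_reference("ACGT", 4) == "ACGT"

    def test_out_of_range(self):
        for bad in (0, 5):
            with pytest.raises(ValueError):
                rotate_reference("ACGT", bad)

    def test_reference_scale_igs_block_first(self):
        """Cutting a 44,838-nt unit at 35,500 moves a 9,338-nt suffix to the
        front (the ~10 kb of IGS preceding the promoters); mouse: 45,306 cut
        at 36,000 gives 9,306."""
        for ref_len, cut, igs in ((44_838, 35_500, 9_338), (45_306, 36_000, 9_306)):
            rng = np.random.default_rng(ref_len)
            seq = "".join(rng.choice(list("ACGT"), ref_len))
            rotated = rotate_reference(seq, cut)
            assert len(rotated) == ref_len
            assert rotated[:igs] == seq[cut:]
            assert rotated[igs:] == seq[:cut]

    @settings(max_examples=60, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=200), st.data())
    def test_inverse_and_composition_conservation(self, seq, data):
        cut = data.draw(st.integers(1, len(seq)))
        rotated = rotate_reference(seq, cut)
        assert len(rotated) == len(seq)
        assert sorted(rotated) == sorted(seq)
        inverse_cut = len(seq) - cut or len(seq)  # identity is its own inverse
        assert rotate_reference(rotated, inverse_cut) == seq


class TestRotateFeatures:
    def test_shift_without_split(self):
        (f,) = rotate_features([RdnaFeature("x", FeatureClass.IGS, 0, 4)], 7, 10)
        assert (f.start, f.end) == (3, 7)

    def test_feature_starting_at_cut_maps_to_zero(self):
        (f,) = rotate_features([RdnaFeature("x", FeatureClass.IGS, 7, 9)], 7, 10)
        assert (f.start, f.end) == (0, 2)

    def test_straddling_feature_splits_with_length_conserved(self):
        out = rotate_features([RdnaFeature("x", FeatureClass.IGS, 5, 9)], 7, 10)
        assert [f.name for f in out] == ["x_p1", "x_p2"]
        assert sum(f.length for f in out) == 4
        assert (out[0].start, out[0].end) == (8, 10)  # original [5,7) -> end of unit
        assert (out[1].start, out[1].end) == (0, 2)  # original [7,9) -> front

    def test_exhaustive_modular_oracle_on_toy_unit(self):
        """Every (start, length, cut) on a 20-nt unit: rotated feature
        bases equal the original bases mapped through the rotation."""
        L = 20
        seq = "ABCDEFGHIJKLMNOPQRST"
        for cut in range(1, L + 1):
            rotated = rotate_reference(seq, cut)
            for start in range(L):
                for length in range(1, L - start + 1):
                    feats = rotate_features(
                        [RdnaFeature("f", FeatureClass.IGS, start, start + length)], cut, L
                    )
                    covered = sorted("".join(rotated[f.start : f.end] for f in feats))
                    assert covered == sorted(seq[start : start + length])
                    assert sum(f.length for f in feats) == length


class TestAppendChrR:
    def test_appended_last_and_sizes_updated(self):
        g = one_chrom("ACGT" * 100)
        custom = append_chrR(g, "GGGG" * 25, build_tag="toy-rDNA v1.0")
        assert custom.names[-1] == "chrR"
        assert custom.chrom_sizes["chrR"] == 100
        assert custom.total_length() == g.total_length() + 100
        assert custom.build_tag == "toy-rDNA v1.0"

    def test_chrR_sequence_bit_exact(self):
        rdna = RdnaReference("acc", "ACGTACGTAC", cut_pos=7)
        custom = append_chrR(one_chrom("TTTT"), rdna.rotated_seq())
        assert custom["chrR"].seq == rotate_reference("ACGTACGTAC", 7)

    def test_name_collision(self):
        custom = append_chrR(one_chrom("ACGT"), "GG")
        with pytest.raises(ValueError, match="chrR"):
            append_chrR(custom, "GG")


class TestSwapRefgeneIds:
    def test_mapping_and_passthrough(self, caplog):
        recs = [
            BedRecord("chr11", 0, 100, "NM_000518"),
            BedRecord("chr1", 5, 50, "NR_999999"),
        ]
        import logging

        with caplog.at_level(logging.WARNING, logger="rdnakit.genome_build"):
            out = swap_refgene_ids(recs, {"NM_000518": "HBB"})
        assert [r.name for r in out] == ["HBB", "NR_999999"]
        assert "NR_999999" in caplog.text

    def test_empty_map_is_identity(self):
        recs = [BedRecord("chr1", 0, 10, "NM_1")]
        assert [r.name for r in swap_refgene_ids(recs, {})] == ["NM_1"]


class TestAnnotationBed:
    def _custom(self, ref_len=1000):
        return append_chrR(one_chrom("A" * 100), "C" * ref_len)

    def test_class_colors_applied(self):
        feats = [
            RdnaFeature("18S", FeatureClass.MATURE_RRNA, 0, 100),
            RdnaFeature("47S_promoter", FeatureClass.PROMOTER, 100, 200),
            RdnaFeature("ITS1", FeatureClass.ITS, 200, 300),
            RdnaFeature("IGS", FeatureClass.IGS, 300, 900),
        ]
        recs = emit_annotation_bed(self._custom(), feats)
        by_name = {r.name: r for r in recs}
        assert by_name["18S"].item_rgb == "255,255,0"  # mature rRNA yellow
        assert by_name["47S_promoter"].item_rgb == "0,255,255"  # promoter cyan
        assert by_name["ITS1"].item_rgb == "0,0,255"  # transcribed spacer blue
        assert by_name["IGS"].item_rgb == "128,128,128"  # IGS gray
        assert all(r.chrom == "chrR" for r in recs)

    def test_refgene_records_pass_through(self):
        refgene = [BedRecord("chr1", 0, 50, "HBB", 0, "+")]
        recs = emit_annotation_bed(self._custom(), [], refgene)
        assert recs[0].name == "HBB" and recs[0].chrom == "chr1"

    def test_feature_beyond_chrR_is_error(self):
        with pytest.raises(ValueError, match="beyond"):
            emit_annotation_bed(self._custom(100), [RdnaFeature("x", FeatureClass.IGS, 0, 500)])

    def test_round_trip_via_bed_reader(self, tmp_path):
        feats = [RdnaFeature("18S", FeatureClass.MATURE_RRNA, 10, 110)]
        recs = emit_annotation_bed(self._custom(), feats)
        p = tmp_path / "ann.bed"
        write_bed_records(recs, p)
        (back,) = read_bed_records(p)
        assert (back.chrom, back.start, back.end, back.name, back.item_rgb) == (
            "chrR", 10, 110, "18S", "255,255,0",
        )


class TestFeatureTable:
    def test_round_trip(self, tmp_path):
        feats = [
            RdnaFeature("18S", FeatureClass.MATURE_RRNA, 3654, 5523),
            RdnaFeature("TTF1_site_1", FeatureClass.TTF1_SITE, 100, 120, "10,20,30"),
        ]
        p = tmp_path / "features.tsv"
        write_feature_table(feats, p)
        back = read_feature_table(p)
        assert back == feats

    def test_unknown_class_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("x\tnot_a_class\t0\t10\n")
        with pytest.raises(ValueError, match=":1.*not_a_class"):
            read_feature_table(p)


class TestRdnaReference:
    def test_cut_pos_validation(self):
        with pytest.raises(ValueError, match="cut_pos"):
            RdnaReference("acc", "ACGT", cut_pos=10)

    def test_rotated_features_land_in_browser_order(self):
        """With the cut inside the IGS, the rotated unit starts with IGS,
        then promoters, then the transcribed region."""
        seq = "A" * 1000
        feats = [
            RdnaFeature("transcribed", FeatureClass.MATURE_RRNA, 0, 300),
            RdnaFeature("IGS", FeatureClass.IGS, 300, 985),
            RdnaFeature("promoter", FeatureClass.PROMOTER, 985, 1000),
        ]
        rdna = RdnaReference("acc", seq, cut_pos=790, features=feats)
        rot = {f.name: f for f in rdna.rotated_features()}
        igs_tail = rot["IGS_p1"]
        assert igs_tail.start == 0 or rot["IGS_p2"].start == 0
        assert rot["promoter"].end < rot["transcribed"].start + 1000
        assert rot["promoter"].start < rot["transcribed"].start
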
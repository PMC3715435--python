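"""Cut-site geometry, end models and assay configuration validation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nhejoin.assay import (
    ISCEI,
    AmbiguousCutError,
    AssayConfig,
    ConfigError,
    CutSiteSpec,
    DsbEnd,
    Junction,
    MalformedInputError,
    UnsupportedOverhangError,
    apply_cut,
    builtin_assay,
    load_assay,
    religate,
    revcomp,
    validate_bases,
)

BASES = st.sampled_from("ACGT")
dna = lambda lo, hi: st.text(alphabet="ACGT", min_size=lo, max_size=hi)


class TestSequenceValidation:
    def test_uppercases_and_accepts_acgt(self):
        assert validate_bases("acgt") == "ACGT"

    @pytest.mark.parametrize("bad", ["", "ACGN", "ACG-T", "AC GT"])
    def test_rejects_empty_and_ambiguity_codes(self, bad):
        with pytest.raises(MalformedInputError):
            validate_bases(bad)

    def test_revcomp_is_an_involution(self):
        assert revcomp("ATAA") == "TTAT"
        assert revcomp(revcomp("GATTACA")) == "GATTACA"


class TestApplyCut:
    def test_iscei_yields_4nt_3prime_overhangs(self):
        duplex = "GGCCACGT" + ISCEI.recognition + "TTGCACGG"
        left, right = apply_cut(duplex, ISCEI)
        assert len(left.overhang) == 4 and len(right.overhang) == 4
        assert left.overhang == "ATAA"
        assert left.overhang_strand == "top" and right.overhang_strand == "bottom"
        # the two single-stranded windows are complementary images of the
        # same duplex segment
        assert left.overhang == revcomp(right.overhang)
        assert religate(left, right) == duplex

    def test_blunt_cutter_is_rejected(self):
        with pytest.raises(UnsupportedOverhangError):
            CutSiteSpec(name="blunt", recognition="GGATCC", top_cut=3, bottom_cut=3)

    def test_recognition_absent_or_repeated(self):
        with pytest.raises(AmbiguousCutError):
            apply_cut("ACGTACGTACGT", ISCEI)
        with pytest.raises(AmbiguousCutError):
            apply_cut(ISCEI.recognition + "TT" + ISCEI.recognition, ISCEI)

    def test_cut_religate_roundtrip_50_random_duplexes(self, rng):
        for _ in range(50):
            flank5 = "".join(rng.choice(list("ACGT"), size=rng.integers(6, 30)))
            flank3 = "".join(rng.choice(list("ACGT"), size=rng.integers(6, 30)))
            duplex = flank5 + ISCEI.recognition + flank3
            if duplex.count(ISCEI.recognition) != 1:
                continue
            left, right = apply_cut(duplex, ISCEI)
            assert religate(left, right) == duplex

    @settings(max_examples=60, derandomize=True)
    @given(flank5=dna(4, 20), flank3=dna(4, 20), top=st.integers(1, 10))
    def test_overhang_window_matches_cut_offsets(self, flank5, flank3, top):
        site = CutSiteSpec(name="syn", recognition="GCATCGATCGGATC",
                           top_cut=top, bottom_cut=top + 4)
        duplex = flank5 + site.recognition + flank3
        if duplex.count(site.recognition) != 1:
            return
        left, right = apply_cut(duplex, site)
        pos = duplex.find(site.recognition)
        assert left.overhang == duplex[pos + top: pos + top + 4]
        assert right.overhang == revcomp(left.overhang)
        assert religate(left, right) == duplex


class TestDsbEndGeometry:
    def test_left_end_overhang_must_be_on_top_strand(self):
        with pytest.raises(ConfigError):
            DsbEnd(side="left", duplex_top="ACGT", overhang="ATAA",
                   overhang_strand="bottom")

    def test_right_end_overhang_must_be_on_bottom_strand(self):
        with pytest.raises(ConfigError):
            DsbEnd(side="right", duplex_top="ACGT", overhang="TGTT",
                   overhang_strand="top")

    def test_virtual_top_is_pairing_image(self):
        end = DsbEnd(side="right", duplex_top="ACGT", overhang="TGTT",
                     overhang_strand="bottom")
        assert end.virtual_top == "AACA"


class TestAssayConfigs:
    def test_partial_assay_has_terminal_pairing(self, partial_assay):
        assert partial_assay.complementarity == "partial"
        # 1- and 2-nt perfect terminal pairing registers, as described for
        # the HO x I-SceI end combination
        assert partial_assay.pairing_registers == [1, 2]

    def test_noncomp_assay_pairs_in_no_register(self, noncomp_assay):
        assert noncomp_assay.complementarity == "none"
        assert noncomp_assay.pairing_registers == []

    def test_cis_assay_is_noncomplementary(self, cis_assay):
        assert cis_assay.complementarity == "none"
        assert cis_assay.system == "noncomp"

    def test_declared_system_must_match_geometry(self, partial_assay):
        text = (
            "name = noncomp\n"
            f"left.flank_top = {partial_assay.left_end.duplex_top}\n"
            "left.overhang = ATAA\n"
            "right.overhang_bottom = TGTT\n"
            f"right.flank_top = {partial_assay.right_end.duplex_top}\n"
            f"left_anchor = {partial_assay.left_anchor}\n"
            f"right_anchor = {partial_assay.right_anchor}\n"
        )
        with pytest.raises(ConfigError, match="pair"):
            load_assay(text)

    def test_wrong_overhang_length_rejected(self, partial_assay):
        text = (
            "name = partial\n"
            f"left.flank_top = {partial_assay.left_end.duplex_top}\n"
            "left.overhang = ATA\n"
            "right.overhang_bottom = TGTT\n"
            f"right.flank_top = {partial_assay.right_end.duplex_top}\n"
            f"left_anchor = {partial_assay.left_anchor}\n"
            f"right_anchor = {partial_assay.right_anchor}\n"
        )
        with pytest.raises(ConfigError, match="length"):
            load_assay(text)

    def test_anchor_must_sit_in_flank(self, partial_assay):
        with pytest.raises(ConfigError, match="anchor"):
            AssayConfig(
                name="partial",
                left_end=partial_assay.left_end,
                right_end=partial_assay.right_end,
                left_anchor="TTTTTTTT",
                right_anchor=partial_assay.right_anchor,
            )

    def test_builtin_overrides(self):
        cfg = builtin_assay("partial", max_deletion=30)
        assert cfg.max_deletion == 30


class TestJunctionValidation:
    def test_anchored_junction_accepted(self, partial_assay):
        top = partial_assay.left_top + partial_assay.right_top
        j = Junction(id="x", top=top, assay=partial_assay)
        assert j.top.startswith(partial_assay.left_anchor)

    def test_missing_anchor_rejected(self, partial_assay):
        with pytest.raises(MalformedInputError, match="anchor-missing"):
            Junction(id="x", top="ACGT" * 20, assay=partial_assay)
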
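"""Allele matching, flips, palindrome resolution, and the full pipeline."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrharmonize import (
    ActionCode,
    DropReason,
    HarmonizationConfig,
    HarmonizationError,
    ValidationError,
    SummaryDataset,
    VariantRecord,
    complement,
    flip,
    harmonize,
    is_palindromic,
    match_alleles,
    pairs_to_datasets,
    standardize_direction,
)

from conftest import eafs, nonpal_pairs, variant_records


class TestPrimitives:
    @pytest.mark.parametrize("a,b", [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")])
    def test_complement_is_watson_crick_and_involutive(self, a, b):
        assert complement(a) == b
        assert complement(complement(a)) == a

    @pytest.mark.parametrize(
        "ea,oa,expected",
        [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
         ("A", "C", False), ("A", "G", False), ("T", "G", False)],
    )
    def test_palindrome_detection(self, ea, oa, expected):
        assert is_palindromic(ea, oa) is expected

    def test_flip_matches_published_footnote_algebra(self):
        # beta times -1, eaf -> 1 - eaf, alleles swapped, se untouched
        rs1 = VariantRecord("rs1", "A", "C", -0.1, 0.04, 0.20)
        flipped = flip(rs1)
        assert flipped == VariantRecord("rs1", "C", "A", 0.1, 0.04, 0.80)
        rs2 = VariantRecord("rs2", "G", "T", -0.2, 0.03, 0.40)
        assert flip(rs2) == VariantRecord("rs2", "T", "G", 0.2, 0.03, 0.60)

    def test_flip_leaves_missing_eaf_missing(self):
        rec = VariantRecord("rs1", "A", "C", 0.3, 0.1, None)
        assert flip(rec).eaf is None

    @given(rec=variant_records())
    def test_flip_involution_and_eaf_conservation(self, rec):
        double = flip(flip(rec))
        assert double.allele_pair == rec.allele_pair
        assert double.beta == rec.beta and double.se == rec.se
        if rec.eaf is not None:
            assert rec.eaf + flip(rec).eaf == pytest.approx(1.0)
            assert double.eaf == pytest.approx(rec.eaf)


class TestStandardizeDirection:
    def test_table2_block(self, table2):
        exposure, _, _ = table2
        std = standardize_direction(exposure)
        assert [r.beta for r in std] == [0.1, 0.2, 0.2, 0.1, 0.18]
        assert std.get("rs1").allele_pair == ("C", "A")
        assert std.get("rs1").eaf == pytest.approx(0.80)
        assert std.get("rs2").allele_pair == ("T", "G")
        # already-positive records untouched
        assert std.get("rs4") == exposure.get("rs4")

    def test_idempotent(self, table2):
        std = standardize_direction(table2[0])
        assert standardize_direction(std).records == std.records

    def test_zero_beta_kept_with_warning(self):
        ds = SummaryDataset(
            [VariantRecord("rs1", "A", "C", 0.0, 0.1, 0.4)], role="exposure"
        )
        with pytest.warns(UserWarning, match="exactly 0"):
            out = standardize_direction(ds)
        assert out.get("rs1").beta == 0.0

    def test_refuses_outcome_dataset(self):
        ds = SummaryDataset([], role="outcome")
        with pytest.raises(ValidationError):
            standardize_direction(ds)


class TestMatchAlleles:
    def exp(self, ea, oa, eaf=0.3, beta=0.5):
        return VariantRecord("rs1", ea, oa, beta, 0.1, eaf)

    def out(self, ea, oa, eaf=0.3, beta=0.4):
        return VariantRecord("rs1", ea, oa, beta, 0.1, eaf)

    def test_identical_coding_is_noop(self):
        matched, action = match_alleles(self.exp("A", "C"), self.out("A", "C"))
        assert action.code is ActionCode.NONE
        assert matched == self.out("A", "C")

    def test_swapped_coding_flips_outcome(self):
        # the worked example's rs1: exposure C/A vs outcome A/C
        exposure = VariantRecord("rs1", "C", "A", 0.1, 0.04, 0.80)
        outcome = VariantRecord("rs1", "A", "C", -0.2, 0.04, 0.18)
        matched, action = match_alleles(exposure, outcome)
        assert action.code is ActionCode.FLIP_OUTCOME
        assert matched.allele_pair == ("C", "A")
        assert matched.beta == pytest.approx(0.2)
        assert matched.eaf == pytest.approx(0.82)

    def test_opposite_strand_same_order(self):
        matched, action = match_alleles(self.exp("A", "G"), self.out("T", "C"))
        assert action.code is ActionCode.STRAND_COMPLEMENT
        assert matched.allele_pair == ("A", "G")
        assert matched.beta == 0.4  # numbers untouched

    def test_opposite_strand_swapped_order(self):
        matched, action = match_alleles(self.exp("A", "G"), self.out("C", "T", eaf=0.7))
        assert action.code is ActionCode.STRAND_COMPLEMENT_AND_FLIP
        assert matched.allele_pair == ("A", "G")
        assert matched.beta == pytest.approx(-0.4)
        assert matched.eaf == pytest.approx(0.3)

    def test_strand_complement_can_be_disabled(self):
        config = HarmonizationConfig(allow_strand_complement=False)
        _, action = match_alleles(self.exp("A", "G"), self.out("T", "C"), config)
        assert action.drop_reason is DropReason.ALLELE_PAIR_MISMATCH

    def test_irreconcilable_pair_dropped(self):
        matched, action = match_alleles(self.exp("A", "C"), self.out("A", "G"))
        assert action.code is ActionCode.DROPPED
        assert action.drop_reason is DropReason.ALLELE_PAIR_MISMATCH

    # ---- palindromes ------------------------------------------------------

    def test_palindrome_discordant_eaf_flipped(self):
        # frequencies on opposite sides of 50% reveal opposite orientation
        matched, action = match_alleles(
            self.exp("A", "T", eaf=0.10), self.out("A", "T", eaf=0.88)
        )
        assert action.code is ActionCode.PALINDROME_RESOLVED_BY_EAF
        assert matched.eaf == pytest.approx(0.12)
        assert matched.beta == pytest.approx(-0.4)

    def test_palindrome_concordant_eaf_untouched(self):
        matched, action = match_alleles(
            self.exp("A", "T", eaf=0.10), self.out("A", "T", eaf=0.12)
        )
        assert action.code is ActionCode.NONE
        assert matched == self.out("A", "T", eaf=0.12)

    @given(exp_eaf=eafs, out_eaf=eafs)
    def test_palindrome_resolution_matches_enumeration_oracle(self, exp_eaf, out_eaf):
        """Independent oracle: enumerate both orientations and keep the one
        minimizing |eaf_exp - eaf_out| (when both EAFs are clearly away
        from 50%, that is the frequency-concordant orientation)."""
        config = HarmonizationConfig()
        window = config.palindrome_maf_window
        exposure = self.exp("C", "G", eaf=exp_eaf)
        outcome = self.out("C", "G", eaf=out_eaf)
        matched, action = match_alleles(exposure, outcome, config)
        ambiguous = (abs(exp_eaf - 0.5) <= window) or (abs(out_eaf - 0.5) <= window)
        if ambiguous:
            assert action.drop_reason is DropReason.PALINDROME_AMBIGUOUS
            return
        orientations = [outcome, outcome.with_(beta=-outcome.beta, eaf=1 - outcome.eaf)]
        oracle = min(orientations, key=lambda o: abs(exp_eaf - o.eaf))
        assert matched.beta == oracle.beta and matched.eaf == oracle.eaf

    def test_palindrome_inside_window_dropped(self):
        _, action = match_alleles(
            self.exp("A", "T", eaf=0.49), self.out("A", "T", eaf=0.51)
        )
        assert action.drop_reason is DropReason.PALINDROME_AMBIGUOUS

    def test_palindrome_missing_eaf_dropped_by_default(self):
        _, action = match_alleles(
            self.exp("A", "T", eaf=None), self.out("A", "T", eaf=0.2)
        )
        assert action.drop_reason is DropReason.MISSING_EAF_REQUIRED

    def test_palindrome_drop_all_policy(self):
        config = HarmonizationConfig(palindrome_policy="drop_all")
        _, action = match_alleles(
            self.exp("A", "T", eaf=0.10), self.out("A", "T", eaf=0.12), config
        )
        assert action.code is ActionCode.DROPPED

    def test_palindrome_never_strand_complemented(self):
        # symbols reversed could be either strand: must resolve by EAF,
        # not report a strand action
        matched, action = match_alleles(
            self.exp("A", "T", eaf=0.10), self.out("T", "A", eaf=0.85)
        )
        assert action.code is ActionCode.PALINDROME_RESOLVED_BY_EAF
        assert matched.allele_pair == ("A", "T")
        assert matched.eaf == pytest.approx(0.15)
        assert matched.beta == pytest.approx(-0.4)

    # ---- consistency oracle ----------------------------------------------

    @given(
        rec=variant_records(pair_strategy=nonpal_pairs, eaf_optional=False),
        corruption=st.sampled_from(["swap", "complement", "both"]),
    )
    def test_recovers_outcome_from_any_nonpalindromic_corruption(self, rec, corruption):
        """Simulate the other study reporting the same association under a
        different coding; matching must recover beta and EAF exactly."""
        exposure = rec.with_(beta=abs(rec.beta) + 0.1)
        corrupted = rec
        if corruption in ("swap", "both"):
            corrupted = flip(corrupted)
        if corruption in ("complement", "both"):
            corrupted = corrupted.with_(
                effect_allele=complement(corrupted.effect_allele),
                other_allele=complement(corrupted.other_allele),
            )
        matched, action = match_alleles(exposure, corrupted)
        assert not action.dropped
        assert matched.allele_pair == exposure.allele_pair
        assert matched.beta == pytest.approx(rec.beta, abs=1e-12)
        assert matched.eaf == pytest.approx(rec.eaf, abs=1e-12)


class TestHarmonizePipeline:
    def test_worked_example_final_block_exact(self, table2):
        pairs = harmonize(*table2)
        assert [p.variant_id for p in pairs] == ["rs1", "rs2", "rs5", "rs4"]
        actions = {p.variant_id: p.action.code for p in pairs}
        assert actions == {
            "rs1": ActionCode.FLIP_OUTCOME,
            "rs2": ActionCode.NONE,
            "rs5": ActionCode.NONE,
            "rs4": ActionCode.FLIP_OUTCOME,
        }
        expected = {
            "rs1": (("C", "A"), 0.1, 0.04, 0.80, ("C", "A"), 0.2, 0.04, 0.82),
            "rs2": (("T", "G"), 0.2, 0.03, 0.60, ("T", "G"), 0.4, 0.03, 0.58),
            "rs5": (("A", "G"), 0.18, 0.03, 0.58, ("A", "G"), 0.36, 0.03, 0.62),
            "rs4": (("G", "A"), 0.1, 0.04, 0.80, ("G", "A"), 0.2, 0.04, 0.82),
        }
        for p in pairs:
            e_pair, e_beta, e_se, e_eaf, o_pair, o_beta, o_se, o_eaf = expected[
                p.variant_id
            ]
            assert p.exposure.allele_pair == e_pair
            assert p.exposure.beta == pytest.approx(e_beta)
            assert p.exposure.se == e_se
            assert p.exposure.eaf == pytest.approx(e_eaf)
            assert p.outcome.allele_pair == o_pair
            assert p.outcome.beta == pytest.approx(o_beta)
            assert p.outcome.se == o_se
            assert p.outcome.eaf == pytest.approx(o_eaf)
        assert pairs[2].proxy_used == "rs5"

    def test_idempotent_on_own_output(self, table2):
        post_exp, post_out = pairs_to_datasets(harmonize(*table2))
        again = harmonize(post_exp, post_out)
        assert all(p.action.code is ActionCode.NONE for p in again)
        post_exp2, post_out2 = pairs_to_datasets(again)
        assert post_exp2.records == post_exp.records
        assert post_out2.records == post_out.records

    def test_surviving_pairs_share_coding_and_direction(self, table2):
        for p in harmonize(*table2):
            assert p.exposure.allele_pair == p.outcome.allele_pair
            assert p.exposure.beta >= 0

    def test_variant_missing_without_proxy_dropped(self, table2):
        exposure, outcome, _ = table2
        pairs = harmonize(exposure, outcome, proxies=None)
        dropped = {p.variant_id: p for p in pairs if p.action.dropped}
        assert set(dropped) == {"rs3"}
        assert (
            dropped["rs3"].action.drop_reason
            is DropReason.MISSING_IN_OUTCOME_NO_PROXY
        )
        assert dropped["rs3"].outcome is None

    def test_empty_inputs_and_total_loss_raise(self):
        empty_e = SummaryDataset([], role="exposure")
        empty_o = SummaryDataset([], role="outcome")
        with pytest.raises(HarmonizationError, match="empty"):
            harmonize(empty_e, empty_o)
        one_e = SummaryDataset(
            [VariantRecord("rs1", "A", "C", 0.1, 0.02, 0.3)], role="exposure"
        )
        one_o = SummaryDataset(
            [VariantRecord("rs1", "A", "G", 0.1, 0.02, 0.3)], role="outcome"
        )
        with pytest.raises(HarmonizationError, match="drop log"):
            harmonize(one_e, one_o)

    def test_config_window_bounds_enforced(self):
        with pytest.raises(ValidationError):
            HarmonizationConfig(palindrome_maf_window=0.6)
        with pytest.raises(ValidationError):
            HarmonizationConfig(palindrome_policy="banish")
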
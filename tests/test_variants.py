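"""Variant parsing/application and information-change arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from spliceinfo.infomodel import model_from_frequencies
from spliceinfo.scoring import score_site
from spliceinfo.synthetic import DONOR_FREQUENCIES, random_background
from spliceinfo.variants import (
    NaturalSite,
    SiteDelta,
    VariantRecord,
    analyze_variant,
    apply_variant,
    assess_concordance,
    cdna_to_genomic,
    classify_smc,
    fold_change,
    format_variant,
    invert_variant,
    parse_variant,
    position_spectrum,
    residual_strength,
)


EXON_TABLE = pd.DataFrame({"exon": [1, 2], "start": [1, 201], "end": [100, 300]})


class TestParsing:
    def test_substitution(self):
        v = parse_variant("chrT:100A>G")
        assert (v.seq_id, v.position, v.ref_allele, v.alt_allele) == ("chrT", 100, "A", "G")

    def test_g_prefix_accepted(self):
        assert parse_variant("chrT:g.100A>G").position == 100

    @pytest.mark.parametrize(
        "text", ["chrT:100A>G", "chrT:50_52del", "chrT:50_52delACG",
                 "chrT:100_101insACT", "chrT:50_52delinsAA"]
    )
    def test_format_parse_roundtrip(self, text):
        v = parse_variant(text)
        assert format_variant(parse_variant(format_variant(v))) == format_variant(v)

    def test_deletion_span(self):
        v = parse_variant("chrT:50_52del")
        assert v.span() == (50, 52)
        assert v.alt_allele == ""

    def test_insertion_flanks_must_be_adjacent(self):
        with pytest.raises(ValueError, match="adjacent"):
            parse_variant("chrT:100_102insA")

    def test_malformed_text_rejected_with_reason(self):
        with pytest.raises(ValueError, match="parse"):
            parse_variant("chrT:banana")

    def test_cdna_first_intronic_base_after_exon(self):
        # exon 1 spans genomic 1-100, so c.100+1 is genomic 101
        v = parse_variant("chrT:c.100+1G>A", exon_table=EXON_TABLE)
        assert v.position == 101
        assert v.notation_source == "cdna"

    def test_cdna_position_in_second_exon(self):
        # c.101 is the first base of exon 2 -> genomic 201
        assert cdna_to_genomic(EXON_TABLE, 101) == 201

    def test_ivs_notation(self):
        v = parse_variant("chrT:IVS1+1G>A", exon_table=EXON_TABLE)
        assert v.position == 101
        v = parse_variant("chrT:IVS1-2A>C", exon_table=EXON_TABLE)
        assert v.position == 199

    def test_cdna_without_exon_table_rejected(self):
        with pytest.raises(ValueError, match="exon table"):
            parse_variant("chrT:c.100+1G>A")


class TestApply:
    REF = "ACGTACGTACGTACGTACGT"

    def test_substitution_changes_exactly_one_base(self):
        v = VariantRecord("s", 5, "A", "G")
        applied = apply_variant(self.REF, v)
        assert len(applied.sequence) == len(self.REF)
        diffs = [i for i, (a, b) in enumerate(zip(self.REF, applied.sequence)) if a != b]
        assert diffs == [4]
        assert np.array_equal(applied.old_to_new, np.arange(len(self.REF) + 1))

    def test_three_nt_deletion_shifts_downstream_coordinates(self):
        v = parse_variant("s:5_7del")
        applied = apply_variant(self.REF, v)
        assert len(applied.sequence) == len(self.REF) - 3
        assert applied.map_coord(4) == 4
        assert applied.map_coord(5) == -1
        assert applied.map_coord(8) == 5

    def test_insertion_after_position(self):
        v = parse_variant("s:4_5insTTT")
        applied = apply_variant(self.REF, v)
        assert applied.sequence == self.REF[:4] + "TTT" + self.REF[4:]
        assert applied.map_coord(4) == 4
        assert applied.map_coord(5) == 8

    def test_composite_delins_matches_hand_built_string(self):
        ref = "AAACCCGGGTTTAAACCCGGGTTTAAACCCGGGTTTAAACCCGGGTTTAAACCCGGGTTT"
        v = parse_variant("s:10_12delinsAG")
        applied = apply_variant(ref, v)
        assert applied.sequence == ref[:9] + "AG" + ref[12:]
        assert len(applied.sequence) == 59

    def test_ref_mismatch_names_expected_and_observed(self):
        with pytest.raises(ValueError, match="expected 'T', observed 'A'"):
            apply_variant(self.REF, VariantRecord("s", 5, "T", "G"))

    def test_delete_then_reinsert_restores_reference(self):
        v = parse_variant("s:5_7del")
        applied = apply_variant(self.REF, v)
        inverse = invert_variant(self.REF, v)
        restored = apply_variant(applied.sequence, inverse)
        assert restored.sequence == self.REF

    def test_substitution_inverse_restores_reference(self):
        v = VariantRecord("s", 3, "G", "C")
        applied = apply_variant(self.REF, v)
        restored = apply_variant(applied.sequence, invert_variant(self.REF, v))
        assert restored.sequence == self.REF


class TestFoldChange:
    @pytest.mark.parametrize(
        "delta, fold",
        [(-7.0, 128.0), (0.0, 1.0), (-3.0, 8.0), (9.1, 548.7), (-3.5, 11.3)],
    )
    def test_printed_fold_values(self, delta, fold):
        assert float(fold_change(delta)) == pytest.approx(fold, rel=1e-2)

    def test_direction(self):
        assert fold_change(-2.0).direction == "reduction"
        assert fold_change(2.0).direction == "increase"
        assert fold_change(0.0).direction == "none"

    @given(st.floats(-10, 0), st.floats(-10, 0))
    def test_multiplicative_over_same_sign_changes(self, a, b):
        assert float(fold_change(a + b)) == pytest.approx(
            float(fold_change(a)) * float(fold_change(b)), rel=1e-9
        )


class TestResidualStrength:
    def test_worked_example(self):
        assert residual_strength(5.4, -2.6) == pytest.approx(67.5)

    def test_no_change_is_full_strength(self):
        assert residual_strength(8.0, 0.0) == pytest.approx(100.0)

    def test_half(self):
        assert residual_strength(5.0, -5.0) == pytest.approx(50.0)

    def test_undefined_for_nonpositive_initial(self):
        assert residual_strength(-1.0, 0.5) is None


class TestSmcBins:
    @pytest.mark.parametrize(
        "delta, label",
        [
            (-7.5, "deleterious"),
            (-7.0, "probably_deleterious"),
            (-5.0, "probably_deleterious"),
            (-4.0, "leaky"),
            (-2.0, "leaky"),
            (-1.0, "benign"),
            (-0.5, "benign"),
            (0.0, "benign"),
            (3.0, "benign"),
        ],
    )
    def test_bin_assignment(self, delta, label):
        assert classify_smc(delta) == label

    @given(st.floats(-50, 50, allow_nan=False))
    def test_partition_of_the_real_line(self, delta):
        assert classify_smc(delta) in (
            "deleterious", "probably_deleterious", "leaky", "benign"
        )


class TestAnalyzeVariant:
    def _planted_donor_sequence(self, models):
        """A ~8-bit donor (average natural strength) with GT core and a G at
        the last exonic base, planted in random background."""
        from spliceinfo.synthetic import design_site_sequence

        model = models["donor"]
        rng = np.random.default_rng(23)
        seq = list(random_background(200, rng))
        z = 100
        window = design_site_sequence(model, 8.0, pinned={-1: "G", 0: "G", 1: "T"})
        seq[z - 3 : z + 7] = list(window)
        return "".join(seq), z

    def test_weakened_natural_donor_is_leaky(self, models):
        """A donor losing ~3 bits stays above R_i,min: leaky, ~8-fold."""
        seq, z = self._planted_donor_sequence(models)
        model = models["donor"]
        # substitution at +5: consensus T -> G, a ~1.5-bit loss; use -1 G -> T
        ref = seq[z - 1]
        v = VariantRecord("s", z, ref, "T")  # offset -1, 1-based pos == z
        deltas = analyze_variant(
            seq, v, [model], [NaturalSite("donor", z)], r_i_min=1.6
        )
        nat = [d for d in deltas if d.is_natural][0]
        expected = model.weight("T", -1) - model.weight(ref, -1)
        assert nat.delta_ri == pytest.approx(expected, abs=1e-9)
        assert nat.category == "leaky"
        assert nat.min_fold_change == pytest.approx(2 ** abs(expected))

    def test_gt_disruption_abolishes_site(self, models):
        seq, z = self._planted_donor_sequence(models)
        v = VariantRecord("s", z + 1, "G", "T")  # offset 0
        deltas = analyze_variant(
            seq, v, [models["donor"]], [NaturalSite("donor", z)], r_i_min=1.6
        )
        nat = [d for d in deltas if d.is_natural][0]
        assert nat.category == "abolished"
        assert nat.smc_bin == "deleterious"
        assert nat.r_i_final < 1.6

    def test_identity_variant_changes_nothing(self, models):
        seq, z = self._planted_donor_sequence(models)
        v = VariantRecord("s", z + 1, "G", "G")
        deltas = analyze_variant(
            seq, v, [models["donor"]], [NaturalSite("donor", z)], r_i_min=1.6
        )
        assert all(d.delta_ri == pytest.approx(0.0) for d in deltas)
        nat = [d for d in deltas if d.is_natural][0]
        assert nat.category == "unchanged_above_min"
        assert float(fold_change(nat.delta_ri)) == 1.0

    def test_substitution_far_from_models_is_all_unchanged(self, models):
        seq, z = self._planted_donor_sequence(models)
        v = VariantRecord("s", 30, seq[29], "A" if seq[29] != "A" else "C")
        deltas = analyze_variant(
            seq, v, [models["donor"]], [NaturalSite("donor", z)], r_i_min=1.6
        )
        nat = [d for d in deltas if d.is_natural][0]
        assert abs(nat.delta_ri) < 1e-9

    def test_window_smaller_than_model_rejected(self, models):
        with pytest.raises(ValueError, match="window"):
            analyze_variant("A" * 100, VariantRecord("s", 50, "A", "C"),
                            [models["acceptor"]], window_nt=20)

    def test_deletion_rescored_across_junction(self, models):
        """Sites spanning a deletion are rescored on the mutated sequence."""
        seq, z = self._planted_donor_sequence(models)
        v = parse_variant(f"s:{z + 2}_{z + 4}del")  # removes +1..+3 of the donor
        deltas = analyze_variant(
            seq, v, [models["donor"]], [NaturalSite("donor", z)], r_i_min=1.6
        )
        nat = [d for d in deltas if d.is_natural][0]
        assert math.isfinite(nat.r_i_final)
        assert nat.delta_ri < 0

    def test_inverse_variant_restores_site_strengths(self, models):
        seq, z = self._planted_donor_sequence(models)
        v = VariantRecord("s", z + 1, "G", "T")
        applied = apply_variant(seq, v)
        restored = apply_variant(applied.sequence, invert_variant(seq, v))
        assert restored.sequence == seq
        assert score_site(models["donor"], restored.sequence, z).r_i == pytest.approx(
            score_site(models["donor"], seq, z).r_i
        )


class TestSiteDelta:
    def test_invariants(self):
        d = SiteDelta("donor", "donor", 10, "+", r_i_initial=9.6, r_i_final=6.6)
        assert d.delta_ri == pytest.approx(-3.0, abs=1e-9)
        assert d.min_fold_change == pytest.approx(8.0)
        assert d.residual_strength_pct == pytest.approx(100 * 6.6 / 9.6)


class TestPositionSpectrum:
    def test_counts_proportional_to_profile_give_r_one(self, models):
        from spliceinfo.infomodel import average_information

        model = models["donor"]
        profile, _ = average_information(model)
        rows = []
        for offset, info in zip(model.offsets, profile):
            rows.extend([{"offset": int(offset)}] * max(1, round(info * 50)))
        spectrum = position_spectrum(pd.DataFrame(rows), model)
        assert spectrum.correlation == pytest.approx(1.0, abs=0.02)

    def test_poisson_counts_with_profile_rate(self, models):
        from spliceinfo.infomodel import average_information

        model = models["donor"]
        profile, _ = average_information(model)
        rng = np.random.default_rng(41)
        offsets = rng.choice(model.offsets, size=500, p=profile / profile.sum())
        spectrum = position_spectrum(pd.DataFrame({"offset": offsets}), model)
        assert spectrum.correlation >= 0.8

    def test_too_few_positions_undefined(self, models):
        table = pd.DataFrame({"offset": [0, 0, 1]})
        assert position_spectrum(table, models["donor"]).correlation is None

    def test_offset_outside_window_rejected(self, models):
        with pytest.raises(ValueError, match="outside"):
            position_spectrum(pd.DataFrame({"offset": [99]}), models["donor"])


class TestConcordance:
    def test_criteria_a_through_e(self):
        records = [
            {"predicted": "abolished", "observed": "complete_loss"},
            {"predicted": "abolished", "observed": "residual_splicing",
             "rtpcr_heterozygote": True},
            {"predicted": "abolished", "observed": "residual_splicing"},
            {"predicted": "leaky", "observed": "residual_splicing"},
            {"predicted": "leaky", "observed": "cryptic_splicing",
             "stronger_cryptic_activated": True},
            {"predicted": "strengthened", "observed": "normal_splicing"},
            {"predicted": "cryptic", "observed": "cryptic_splicing",
             "predicted_top_isoform": True},
            {"predicted": "cryptic", "observed": "cryptic_splicing",
             "predicted_top_isoform": False},
            {"predicted": "regulatory", "observed": "aberrant_splicing",
             "binding_concordant": True},
        ]
        result = assess_concordance(records)
        labels = list(result.table["label"])
        assert labels == [
            "concordant", "concordant", "discordant", "concordant", "concordant",
            "concordant", "concordant", "partially_concordant", "concordant",
        ]
        # partial counts toward the overall percent, as in criterion d
        assert result.percent_concordant == pytest.approx(100 * 8 / 9)

    def test_uninformative_records_excluded_from_denominator(self):
        records = [
            {"predicted": "abolished", "observed": "complete_loss"},
            {"predicted": "abolished", "observed": None},
            {"predicted": "regulatory", "observed": "aberrant_splicing"},
        ]
        result = assess_concordance(records)
        assert result.n_informative == 1
        assert result.percent_concordant == pytest.approx(100.0)
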
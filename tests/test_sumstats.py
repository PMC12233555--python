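"""Summary-statistics I/O and two-sample harmonization."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cismr.sumstats import (
    AssociationRecord,
    PALINDROME_WINDOW,
    harmonize_pair,
    is_palindromic,
    read_sumstats,
    write_sumstats,
)


class TestRecordValidation:
    def test_rejects_identical_alleles(self, record):
        with pytest.raises(ValueError):
            record(ea="A", oa="A")

    def test_rejects_nonpositive_se(self, record):
        with pytest.raises(ValueError):
            record(se=0.0)

    def test_rejects_out_of_range_p(self, record):
        with pytest.raises(ValueError):
            record(pvalue=0.0)

    def test_binary_requires_case_count(self, record):
        with pytest.raises(ValueError):
            AssociationRecord(
                variant_id="v", chromosome="1", position=1, effect_allele="A",
                other_allele="G", eaf=0.5, beta=0.1, se=0.1, pvalue=0.5,
                n=100, n_cases=None, trait_type="binary",
            )


@pytest.mark.parametrize(
    "ea,oa,expected",
    [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
     ("A", "G", False), ("A", "C", False), ("T", "G", False), ("T", "C", False)],
)
def test_is_palindromic_over_all_pairs(ea, oa, expected):
    assert is_palindromic(ea, oa) is expected


def test_is_palindromic_rejects_non_acgt():
    with pytest.raises(ValueError):
        is_palindromic("A", "N")


class TestFileIO:
    def test_complete_rows_all_kept(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "variant_id\tchr\tpos\tea\toa\teaf\tbeta\tse\tp\tn\tn_cases\n"
            "rs1\t1\t100\ta\tg\t0.3\t0.1\t0.02\t1e-8\t1000\t\n"
            "rs2\t1\t200\tC\tT\t0.4\t-0.2\t0.05\t1e-4\t1000\t\n"
            "rs3\t2\t300\tG\tA\t0.5\t0.05\t0.01\t0.5\t1000\t\n"
        )
        records, report = read_sumstats(p)
        assert len(records) == 3 and report.n_skipped == 0
        assert records[0].effect_allele == "A"  # upper-cased

    def test_skip_reasons_counted(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "variant_id\tchr\tpos\tea\toa\teaf\tbeta\tse\tp\tn\tn_cases\n"
            "rs1\t1\t100\tA\tG\t0.3\t0.1\t0\t1e-8\t1000\t\n"  # se = 0
            "rs2\t1\t200\tC\tT\t0.4\t\t0.05\t1e-4\t1000\t\n"  # missing beta
            "rs3\t2\t300\tG\tA\t0.5\t0.1\t0.01\t1.5\t1000\t\n"  # p > 1
        )
        records, report = read_sumstats(p)
        assert records == []
        assert report.skipped == {
            "nonpositive_se": 1, "missing_beta_or_se": 1, "invalid_pvalue": 1,
        }

    def test_column_map_renames_source_headers(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "SNP\tCHR\tBP\tA1\tA2\tFRQ\tBETA\tSE\tP\tN\n"
            "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-8\t1000\n"
        )
        records, _ = read_sumstats(p, column_map={
            "SNP": "variant_id", "CHR": "chr", "BP": "pos", "A1": "ea",
            "A2": "oa", "FRQ": "eaf", "BETA": "beta", "SE": "se", "P": "p",
            "N": "n",
        })
        assert len(records) == 1 and records[0].variant_id == "rs1"

    def test_duplicate_variant_keeps_smallest_p(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "variant_id\tchr\tpos\tea\toa\teaf\tbeta\tse\tp\tn\tn_cases\n"
            "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-4\t1000\t\n"
            "rs1\t1\t100\tA\tG\t0.3\t0.2\t0.02\t1e-8\t1000\t\n"
        )
        records, report = read_sumstats(p)
        assert len(records) == 1 and records[0].beta == 0.2
        assert report.skipped["duplicate_variant_id"] == 1

    def test_round_trip_preserves_full_precision(self, tmp_path, record):
        originals = [
            record(variant_id="rs1", beta=0.123456789012345, se=1 / 3,
                   pvalue=2.5e-17, eaf=0.0521),
            record(variant_id="rs2", ea="T", oa="C", beta=-1e-5, se=0.5,
                   pvalue=1.0, n=50_000, n_cases=10_000),
        ]
        path = tmp_path / "rt.tsv"
        write_sumstats(originals, path)
        reread, report = read_sumstats(path)
        assert report.n_skipped == 0
        assert reread == originals


# palindromic window: open interval, both traits' frequencies
_W = PALINDROME_WINDOW


class TestHarmonization:
    def test_identical_alleles_pass_through(self, record):
        pair = harmonize_pair(record(beta=0.1), record(beta=0.2))
        assert pair.action_taken == "identical" and pair.outcome.beta == 0.2

    def test_swapped_alleles_negate_beta_and_complement_eaf(self, record):
        pair = harmonize_pair(
            record(beta=0.1), record(ea="G", oa="A", beta=0.2, eaf=0.3)
        )
        assert pair.action_taken == "allele_swap"
        assert pair.outcome.beta == -0.2
        assert pair.outcome.eaf == pytest.approx(0.7)
        assert pair.outcome.effect_allele == "A"

    def test_strand_flip_detected(self, record):
        # exposure A/G; outcome reported on the other strand as T/C
        pair = harmonize_pair(record(beta=0.1), record(ea="T", oa="C", beta=0.2))
        assert pair.action_taken == "strand_flip"
        assert pair.outcome.beta == 0.2
        assert pair.outcome.effect_allele == "A"

    def test_strand_flip_and_swap(self, record):
        pair = harmonize_pair(
            record(beta=0.1), record(ea="C", oa="T", beta=0.2, eaf=0.3)
        )
        assert pair.action_taken == "strand_flip_and_swap"
        assert pair.outcome.beta == -0.2
        assert pair.outcome.eaf == pytest.approx(0.7)

    def test_palindromic_mid_frequency_dropped(self, record):
        pair = harmonize_pair(
            record(ea="A", oa="T", eaf=0.50), record(ea="A", oa="T", eaf=0.50)
        )
        assert pair.dropped and pair.drop_reason == "palindromic_ambiguous"

    def test_palindromic_window_applies_to_either_trait(self, record):
        pair = harmonize_pair(
            record(ea="A", oa="T", eaf=0.30), record(ea="A", oa="T", eaf=0.45)
        )
        assert pair.dropped and pair.drop_reason == "palindromic_ambiguous"

    def test_palindromic_boundary_frequency_retained(self, record):
        # open interval: eaf exactly at the boundary is usable
        pair = harmonize_pair(
            record(ea="A", oa="T", eaf=0.42), record(ea="A", oa="T", eaf=0.42)
        )
        assert not pair.dropped

    def test_palindromic_missing_eaf_dropped(self, record):
        pair = harmonize_pair(
            record(ea="A", oa="T", eaf=0.3), record(ea="A", oa="T", eaf=None)
        )
        assert pair.dropped and pair.drop_reason == "palindromic_ambiguous"

    def test_palindromic_concordant_sides_kept_as_identical(self, record):
        pair = harmonize_pair(
            record(ea="A", oa="T", eaf=0.2, beta=0.1),
            record(ea="A", oa="T", eaf=0.25, beta=0.3),
        )
        assert pair.action_taken == "identical" and pair.outcome.beta == 0.3

    def test_palindromic_discordant_sides_treated_as_swap(self, record):
        pair = harmonize_pair(
            record(ea="A", oa="T", eaf=0.2, beta=0.1),
            record(ea="A", oa="T", eaf=0.8, beta=0.3),
        )
        assert pair.action_taken == "allele_swap"
        assert pair.outcome.beta == -0.3
        assert pair.outcome.eaf == pytest.approx(0.2)

    def test_incompatible_alleles_dropped(self, record):
        pair = harmonize_pair(record(ea="A", oa="G"), record(ea="A", oa="C"))
        assert pair.dropped and pair.drop_reason == "incompatible_alleles"

    def test_mismatched_variant_id_is_an_error(self, record):
        with pytest.raises(ValueError):
            harmonize_pair(record(variant_id="rs1"), record(variant_id="rs2"))


_alleles = st.sampled_from(["A", "C", "G", "T"])


@st.composite
def _harmonizable_pairs(draw):
    ea = draw(_alleles)
    oa = draw(_alleles.filter(lambda a: a != ea))
    eaf_e = draw(st.floats(0.01, 0.99))
    eaf_o = draw(st.floats(0.01, 0.99))
    orientation = draw(st.sampled_from(["identical", "swap", "flip", "flip_swap"]))
    return ea, oa, eaf_e, eaf_o, orientation


@given(_harmonizable_pairs(),
       st.floats(-1, 1).filter(lambda b: abs(b) > 1e-6),
       st.floats(-1, 1).filter(lambda b: abs(b) > 1e-6))
@settings(derandomize=True, max_examples=200)
def test_harmonization_involution_and_sign_identities(params, beta_e, beta_o):
    """Harmonizing an already-harmonized pair is a no-op; the outcome beta
    changes sign exactly when the action is a swap, and then eaf -> 1 - eaf."""
    from cismr.sumstats import COMPLEMENT

    ea, oa, eaf_e, eaf_o, orientation = params
    exp = AssociationRecord("v", "1", 1, ea, oa, eaf_e, beta_e, 0.1, 0.5, 1000)
    oea, ooa = ea, oa
    if orientation in ("swap", "flip_swap"):
        oea, ooa = ooa, oea
    if orientation in ("flip", "flip_swap"):
        oea, ooa = COMPLEMENT[oea], COMPLEMENT[ooa]
    out = AssociationRecord("v", "1", 1, oea, ooa, eaf_o, beta_o, 0.1, 0.5, 1000)

    pair = harmonize_pair(exp, out)
    if pair.dropped:
        assert pair.drop_reason in ("palindromic_ambiguous", "incompatible_alleles")
        return
    assert pair.outcome.effect_allele == exp.effect_allele
    assert pair.outcome.other_allele == exp.other_allele
    # sign identity
    sign_kept = pair.outcome.beta * beta_o > 0
    assert sign_kept == (pair.action_taken in ("identical", "strand_flip"))
    if not sign_kept:
        assert pair.outcome.eaf == pytest.approx(1.0 - eaf_o)
    # involution: a second pass changes nothing
    again = harmonize_pair(exp, pair.outcome)
    assert not again.dropped
    assert again.action_taken == "identical"
    assert again.outcome == pair.outcome
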
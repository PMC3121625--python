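import numpy as np
import pytest

from mitoskew import synthetic
from mitoskew.codon_code import (
    ALL_CODONS,
    CodonFamily,
    TRNAEntry,
    aa_composition,
    adaptation_test,
    anticodon_set_from_genome,
    classify_codon_strandedness,
    classify_pairing,
    codon_families,
    codon_usage,
    get_code,
    load_code,
    reverse_complement_rna,
    rhabdopleura_anticodon_set,
    usage_to_tsv,
    versatile_anticodon,
    versatile_anticodon_set,
)

from conftest import PTEROBRANCH_CODON_COUNTS, cds, make_genome, usage_from_counts

BUILTIN_CODES = ("vertebrate", "invertebrate", "echinoderm", "ascidian", "rhabdopleura")


class TestGeneticCodes:
    @pytest.mark.parametrize(
        "code_id, codon, aa",
        [
            ("vertebrate", "AGA", "*"), ("vertebrate", "AUA", "M"),
            ("invertebrate", "AGA", "S"), ("invertebrate", "AUA", "M"),
            ("echinoderm", "AAA", "N"), ("echinoderm", "AGG", "S"),
            ("ascidian", "AGA", "G"), ("ascidian", "AGG", "G"),
            ("rhabdopleura", "AUA", "I"), ("rhabdopleura", "AAA", "K"),
            ("rhabdopleura", "AGG", "K"), ("rhabdopleura", "AGA", "S"),
            ("rhabdopleura", "UGA", "W"),
        ],
    )
    def test_key_assignments(self, code_id, codon, aa):
        assert get_code(code_id).table[codon] == aa

    def test_numeric_lookup(self):
        assert get_code(2).id == "vertebrate"
        assert get_code("9").id == "echinoderm"

    def test_unknown_code_errors(self):
        with pytest.raises(KeyError):
            get_code("klingon")

    def test_load_code_text_format(self, tmp_path):
        code = get_code("rhabdopleura")
        lines = ["# test code"] + [f"{c}\t{code.table[c]}" for c in ALL_CODONS]
        lines.append("starts:AUG,GUG")
        path = tmp_path / "code.tsv"
        path.write_text("\n".join(lines) + "\n")
        loaded = load_code(path, label="reload")
        assert loaded.table == code.table
        assert loaded.start_codons == {"AUG", "GUG"}


class TestCodonFamilies:
    @pytest.mark.parametrize("code_id", BUILTIN_CODES)
    def test_families_partition_sense_codons(self, code_id):
        code = get_code(code_id)
        fams = codon_families(code)
        claimed = [c for f in fams for c in f.codons]
        assert sorted(claimed) == sorted(code.sense_codons)
        assert len(claimed) == len(set(claimed))

    def test_standard_metazoan_code_has_22_families(self):
        assert len(codon_families(get_code("invertebrate"))) == 22

    def test_rhabdopleura_has_23_families(self):
        fams = codon_families(get_code("rhabdopleura"))
        assert len(fams) == 23
        ile = next(f for f in fams if f.prefix == "AU" and f.amino_acid == "I")
        assert set(ile.codons) == {"AUU", "AUC", "AUA"} and ile.kind == "Y+A"
        agg = next(f for f in fams if f.prefix == "AG" and f.amino_acid == "K")
        assert agg.codons == ("AGG",)


class TestCodonUsage:
    def test_single_cds_two_codons(self):
        genome = make_genome("ATGTAA", [cds("ND1", 0, 6)])
        usage = codon_usage(genome, "rhabdopleura")
        assert usage["AUG"] == 1 and usage["UAA"] == 1
        assert usage.total == 2

    def test_incomplete_stop_tail_excluded(self):
        genome = make_genome("ATGAAAT", [cds("ND4", 0, 7)])
        usage = codon_usage(genome, "rhabdopleura")
        assert usage.total == 2
        assert usage.incomplete_tails == 1

    def test_internal_stop_warns_but_counts(self):
        genome = make_genome("ATGTAAATGTAA", [cds("ND1", 0, 12)])
        with pytest.warns(UserWarning, match="internal stop"):
            usage = codon_usage(genome, "rhabdopleura")
        assert usage["UAA"] == 2

    def test_totals_equal_floor_lengths(self):
        genome, _ = synthetic.generate_genome(synthetic.rhabdopleura_like(seed=8))
        usage = codon_usage(genome, "rhabdopleura")
        expected = sum(
            f.spliced_length // 3 for f in genome.features_of_kind("CDS"))
        assert usage.total == expected

    def test_no_cds_errors(self):
        with pytest.raises(ValueError):
            codon_usage(make_genome("ACGT"), "rhabdopleura")


class TestAAComposition:
    def test_two_codon_usage(self):
        usage = usage_from_counts(get_code("rhabdopleura"), {"AUG": 1, "AAA": 1})
        comp = aa_composition(usage)
        assert comp["M"] == pytest.approx(0.5)
        assert comp["K"] == pytest.approx(0.5)

    def test_stops_excluded_and_sums_to_one(self, rng):
        for _ in range(20):
            counts = {c: int(rng.integers(0, 50)) for c in ALL_CODONS}
            usage = usage_from_counts(get_code("invertebrate"), counts)
            if all(counts[c] == 0 for c in usage.code.sense_codons):
                continue
            comp = aa_composition(usage)
            assert sum(comp.values()) == pytest.approx(1.0, abs=1e-12)
            assert "*" not in comp

    def test_all_stop_usage_errors(self):
        usage = usage_from_counts(get_code("rhabdopleura"), {"UAA": 5})
        with pytest.raises(ValueError):
            aa_composition(usage)

    def test_gt_biased_genome_boosts_gt_amino_acids(self):
        biased, _ = synthetic.generate_genome(synthetic.rhabdopleura_like(seed=4))
        flat, _ = synthetic.generate_genome(synthetic.unbiased(seed=4))
        comp_b = aa_composition(codon_usage(biased, "rhabdopleura"))
        comp_f = aa_composition(codon_usage(flat, "invertebrate"))
        gt_share_b = sum(comp_b.get(aa, 0) for aa in "FGVW")
        gt_share_f = sum(comp_f.get(aa, 0) for aa in "FGVW")
        assert gt_share_b > gt_share_f


class TestStrandedness:
    @pytest.mark.parametrize("aa", ["F", "G", "V", "W"])
    def test_gt_exclusive(self, aa):
        assert classify_codon_strandedness(aa, get_code("rhabdopleura")) == "GT_exclusive"

    @pytest.mark.parametrize("aa", ["T", "P", "N", "H", "Q"])
    def test_ac_exclusive(self, aa):
        assert classify_codon_strandedness(aa, get_code("rhabdopleura")) == "AC_exclusive"

    def test_leu_mixed_by_enumeration(self):
        # UUR all GT-rich but CUC has only one G/U position -> mixed
        code = get_code("rhabdopleura")
        assert classify_codon_strandedness("L", code) == "mixed"

    def test_three_letter_names_accepted(self):
        assert classify_codon_strandedness("Phe", get_code("rhabdopleura")) == "GT_exclusive"

    def test_unencoded_amino_acid_errors(self):
        with pytest.raises(ValueError):
            classify_codon_strandedness("B", get_code("rhabdopleura"))

    @pytest.mark.parametrize("code_id", BUILTIN_CODES)
    def test_labels_cover_all_amino_acids(self, code_id):
        code = get_code(code_id)
        for aa in code.amino_acids:
            assert classify_codon_strandedness(aa, code) in (
                "GT_exclusive", "AC_exclusive", "mixed")


class TestVersatileAnticodon:
    def test_nny_family_gets_gnn(self):
        fam = CodonFamily("UU", "F", ("UUU", "UUC"), "NNY")
        assert versatile_anticodon(fam) == "GAA"

    def test_nnr_family_gets_unn(self):
        fam = CodonFamily("AA", "K", ("AAA", "AAG"), "NNR")
        assert versatile_anticodon(fam) == "UUU"

    def test_fourfold_family_gets_unn(self):
        fam = CodonFamily("GU", "V", ("GUU", "GUC", "GUA", "GUG"), "fourfold")
        assert versatile_anticodon(fam) == "UAC"

    def test_singleton_purine_family_extends_unn_rule(self):
        fam = CodonFamily("AU", "M", ("AUG",), "singleton")
        assert versatile_anticodon(fam) == "UAU"


class TestClassifyPairing:
    def test_pterobranch_set_has_three_deviations(self, pterobranch_usage):
        code = get_code("rhabdopleura")
        report = classify_pairing(rhabdopleura_anticodon_set(), code, pterobranch_usage)
        assert report.deviation_count == 3
        non_versatile = {
            (f.family.prefix, f.family.amino_acid): f.classification
            for f in report.families if f.classification != "versatile"
        }
        assert non_versatile == {
            ("AU", "M"): "adapted",   # anticodon CAU matches the start codon
            ("AA", "K"): "adapted",   # anticodon CUU matches the frequent AAG
            ("AG", "K"): "uncovered",  # reassigned AGG has no tRNA
        }

    def test_pterobranch_set_without_usage_still_three(self):
        code = get_code("rhabdopleura")
        report = classify_pairing(rhabdopleura_anticodon_set(), code, usage=None)
        assert report.deviation_count == 3

    def test_echinoderm_style_set(self):
        code = get_code("echinoderm")
        entries = []
        for fam in codon_families(code):
            if fam.prefix == "AG" and fam.amino_acid == "S":
                entries.append(TRNAEntry("S", "GCU", "trnS1"))
            else:
                entries.append(TRNAEntry(fam.amino_acid,
                                         versatile_anticodon(fam)))
        report = classify_pairing(entries, code)
        lys = next(f for f in report.families
                   if f.family.amino_acid == "K")
        assert lys.classification == "versatile"
        agn = next(f for f in report.families
                   if f.family.prefix == "AG" and f.family.amino_acid == "S")
        assert agn.classification == "versatile"
        assert "methylation" in agn.note
        assert report.deviation_count == 0

    @pytest.mark.parametrize("code_id", BUILTIN_CODES)
    def test_fully_versatile_set_has_zero_deviations(self, code_id):
        code = get_code(code_id)
        report = classify_pairing(versatile_anticodon_set(code), code)
        assert report.deviation_count == 0

    def test_unserved_trna_errors(self):
        code = get_code("rhabdopleura")
        bad = versatile_anticodon_set(code) + [TRNAEntry("K", "GGG", "bogus")]
        with pytest.raises(ValueError, match="serves no codon family"):
            classify_pairing(bad, code)

    def test_every_sense_codon_in_exactly_one_family(self):
        code = get_code("rhabdopleura")
        report = classify_pairing(rhabdopleura_anticodon_set(), code)
        seen = [c for f in report.families for c in f.family.codons]
        assert sorted(seen) == sorted(code.sense_codons)


class TestAdaptationTest:
    def test_phe_anticodon_matches_rare_codon(self, pterobranch_usage):
        code = get_code("rhabdopleura")
        results = adaptation_test(rhabdopleura_anticodon_set(), code, pterobranch_usage)
        phe = next(r for r in results if r.family.amino_acid == "F")
        # anticodon GAA complements UUC (count 35) while UUU has 554
        assert phe.anticodon == "GAA"
        assert phe.matches_most_frequent is False

    def test_unn_matches_dominant_nna(self):
        code = get_code("rhabdopleura")
        counts = {"AAA": 10, "AAG": 1}
        usage = usage_from_counts(code, counts)
        entries = [TRNAEntry("K", "UUU")]  # complement AAA
        results = adaptation_test(entries, code, usage)
        lys = next(r for r in results
                   if r.family.prefix == "AA" and r.family.amino_acid == "K")
        assert lys.matches_most_frequent is True

    def test_zero_usage_family_is_undefined(self):
        code = get_code("rhabdopleura")
        usage = usage_from_counts(code, {"UUU": 3})
        results = adaptation_test(versatile_anticodon_set(code), code, usage)
        val = next(r for r in results if r.family.amino_acid == "V")
        assert val.matches_most_frequent is None

    def test_random_usage_matches_brute_force_oracle(self, rng):
        code = get_code("invertebrate")
        entries = versatile_anticodon_set(code)
        for _ in range(10):
            counts = {c: int(rng.integers(0, 30)) for c in ALL_CODONS}
            usage = usage_from_counts(code, counts)
            results = adaptation_test(entries, code, usage)
            for r in results:
                fam_counts = {c: counts[c] for c in r.family.codons}
                if sum(fam_counts.values()) == 0 or r.anticodon is None:
                    assert r.matches_most_frequent is None
                    continue
                best = max(fam_counts.values())
                expected = reverse_complement_rna(r.anticodon)
                assert r.matches_most_frequent == (fam_counts[expected] == best)


class TestAnticodonPlumbing:
    def test_set_from_synthetic_genome_matches_builtin(self):
        genome, _ = synthetic.generate_genome(synthetic.rhabdopleura_like(seed=0))
        code = get_code("rhabdopleura")
        entries = anticodon_set_from_genome(genome, code)
        assert len(entries) == 22
        report = classify_pairing(entries, code, codon_usage(genome, code))
        assert report.deviation_count == 3

    def test_usage_tsv_has_64_rows_and_flags(self, pterobranch_usage):
        text = usage_to_tsv(pterobranch_usage, rhabdopleura_anticodon_set())
        lines = text.strip().splitlines()
        assert len(lines) == 65
        flagged = [l for l in lines if l.endswith("*")]
        assert len(flagged) == 22
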
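import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_matrix
from ssrkit.genotypes import (
    GenotypeError,
    GenotypeMatrix,
    GenotypeParseError,
    LocusOffset,
    ReferenceProfile,
    ReferenceProfilePanel,
    StandardizationError,
    decode_structure_input,
    normalize_name,
    read_genotype_table,
    standardize_alleles,
    write_pairs_csv,
    write_structure_input,
)

PAIRS = """accession,LocA,LocB
Acc1,130/134,128/128
Acc2,.,140/144
"""


class TestParsing:
    def test_pairs_csv_basic(self):
        gm = read_genotype_table(PAIRS)
        assert gm.accession_ids == ["Acc1", "Acc2"]
        assert gm.locus_ids == ["LocA", "LocB"]
        assert gm.call("Acc1", "LocA") == (130, 134)
        assert gm.call("Acc1", "LocB") == (128, 128)
        assert gm.call("Acc2", "LocA") is None
        assert gm.call("Acc2", "LocB") == (140, 144)
        assert int(gm.typed_mask.sum()) == 3

    def test_allele_order_normalized(self):
        gm = read_genotype_table("accession,L\nA,134/130\n")
        assert gm.call("A", "L") == (130, 134)

    def test_duplicate_accession_named_in_error(self):
        text = "accession,L\nSyrah,130/134\nSyrah,130/134\n"
        with pytest.raises(GenotypeError, match="Syrah"):
            read_genotype_table(text)

    def test_duplicate_locus_named_in_error(self):
        with pytest.raises(GenotypeError, match="LocA"):
            read_genotype_table("accession,LocA,LocA\nA,130/134,130/134\n")

    def test_non_integer_token_reports_position(self):
        with pytest.raises(GenotypeParseError, match="row 2.*LocA"):
            read_genotype_table("accession,LocA\nA,13x/134\n")

    def test_half_call_rejected(self):
        with pytest.raises(GenotypeParseError, match="half-call"):
            read_genotype_table("accession,LocA\nA,130\n")

    def test_two_column_dialect(self):
        text = "accession,LocA,LocA,LocB,LocB\nA,130,134,0,0\nB,128,128,140,144\n"
        gm = read_genotype_table(text, dialect="two_column_csv")
        assert gm.call("A", "LocA") == (130, 134)
        assert gm.call("A", "LocB") is None
        assert gm.call("B", "LocB") == (140, 144)

    def test_two_column_half_call(self):
        text = "accession,LocA,LocA\nA,130,0\n"
        with pytest.raises(GenotypeParseError, match="half-call"):
            read_genotype_table(text, dialect="two_column_csv")

    def test_tab_delimited_sniffed(self):
        gm = read_genotype_table("accession\tL\nA\t130/134\n")
        assert gm.call("A", "L") == (130, 134)

    def test_metadata_columns(self):
        gm = read_genotype_table(
            "accession,meta:name,L\nA1,Syrah,130/134\n"
        )
        assert gm.declared_name("A1") == "Syrah"


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pairs_csv_roundtrip(self, seed):
        gm = random_matrix(8, 4, seed, missing_rate=0.2)
        assert read_genotype_table(write_pairs_csv(gm)) == gm

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_pairs_roundtrip_property(self, seed):
        gm = random_matrix(5, 3, seed, missing_rate=0.3)
        assert read_genotype_table(write_pairs_csv(gm)) == gm


class TestStructureFormat:
    def test_single_call_two_rows(self):
        gm = GenotypeMatrix.from_calls(["A"], ["L"], [[(130, 134)]])
        text, recoding = write_structure_input(gm)
        lines = text.strip().splitlines()
        assert len(lines) == 3  # header + 2 allele rows
        codes = {lines[1].split("\t")[1], lines[2].split("\t")[1]}
        assert codes == {"1", "2"}
        assert recoding["L"] == {"130": 1, "134": 2}

    def test_missing_coded_minus9(self):
        gm = GenotypeMatrix.from_calls(["A"], ["L"], [[None]])
        text, _ = write_structure_input(gm)
        lines = text.strip().splitlines()
        assert lines[1].split("\t")[1] == "-9"
        assert lines[2].split("\t")[1] == "-9"

    def test_roundtrip_random(self):
        gm = random_matrix(5, 3, seed=42, missing_rate=0.2)
        gm.metadata.clear()  # structure text does not carry metadata
        text, recoding = write_structure_input(gm)
        assert decode_structure_input(text, recoding) == gm


def _panel(loci, profiles):
    return ReferenceProfilePanel(
        loci,
        [ReferenceProfile(name, prof, "test") for name, prof in profiles.items()],
    )


class TestStandardization:
    LOCI = ["L1", "L2"]

    def _gm(self, shift_l1=0):
        calls = [
            [(130 - shift_l1, 134 - shift_l1), (200, 202)],
            [(128 - shift_l1, 128 - shift_l1), (204, 204)],
        ]
        return GenotypeMatrix.from_calls(["A", "B"], self.LOCI, calls)

    def _ref_panel(self):
        return _panel(
            self.LOCI,
            {
                "VarA": {"L1": (130, 134), "L2": (200, 202)},
                "VarB": {"L1": (128, 128), "L2": (204, 204)},
            },
        )

    def test_identity_when_anchors_match(self):
        gm = self._gm()
        out, offsets = standardize_alleles(
            gm, self._ref_panel(), {"A": "VarA", "B": "VarB"}
        )
        assert out == gm
        assert all(o.offset == 0 for o in offsets.values())

    def test_systematic_shift_corrected(self):
        gm = self._gm(shift_l1=2)
        out, offsets = standardize_alleles(
            gm, self._ref_panel(), {"A": "VarA", "B": "VarB"}
        )
        assert offsets["L1"].offset == 2
        assert out.call("A", "L1") == (130, 134)
        assert out.call("B", "L1") == (128, 128)
        assert out.call("A", "L2") == (200, 202)  # untouched locus

    def test_idempotent(self):
        gm = self._gm(shift_l1=2)
        panel = self._ref_panel()
        anchors = {"A": "VarA", "B": "VarB"}
        once, _ = standardize_alleles(gm, panel, anchors)
        twice, offsets = standardize_alleles(once, panel, anchors)
        assert twice == once
        assert all(o.offset == 0 for o in offsets.values())

    def test_inconsistent_anchors_error(self):
        # anchors imply offsets {+2, +2, -6, -6} at L1 -> consistency 0.5
        gm = GenotypeMatrix.from_calls(
            ["A", "B"],
            ["L1"],
            [[(128, 132)], [(134, 134)]],
        )
        panel = _panel(
            ["L1"], {"VarA": {"L1": (130, 134)}, "VarB": {"L1": (128, 128)}}
        )
        with pytest.raises(StandardizationError, match="L1"):
            standardize_alleles(gm, panel, {"A": "VarA", "B": "VarB"})

    def test_unanchored_locus_warns_offset_zero(self):
        gm = self._gm()
        panel = _panel(["L1"], {"VarA": {"L1": (130, 134)}})
        with pytest.warns(UserWarning, match="L2"):
            _, offsets = standardize_alleles(gm, panel, {"A": "VarA"})
        assert offsets["L2"].offset == 0


class TestInvariants:
    def test_half_call_matrix_rejected(self):
        a1 = np.array([[130]])
        a2 = np.array([[-1]])
        with pytest.raises(GenotypeError, match="half-call"):
            GenotypeMatrix(["A"], ["L"], a1, a2)

    def test_nonpositive_allele_rejected(self):
        with pytest.raises(GenotypeError, match="positive"):
            GenotypeMatrix.from_calls(["A"], ["L"], [[(0, 130)]])

    def test_pair_order_insensitive_storage(self):
        gm1 = GenotypeMatrix(["A"], ["L"], np.array([[134]]), np.array([[130]]))
        assert gm1.call("A", "L") == (130, 134)


class TestNameNormalization:
    def test_case_accents_punctuation(self):
        assert normalize_name("Tempranillo  Tinto") == "tempranillo tinto"
        assert normalize_name("Müller-Thurgau") == "muller thurgau"

    def test_distinct_words_stay_distinct(self):
        assert normalize_name("Pedro Ximenez") != normalize_name("Pedro Gimenez")
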
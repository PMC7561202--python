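import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_matrix
from ssrkit import diversity
from ssrkit.genotypes import GenotypeError, GenotypeMatrix


def make_gm(calls, loci=None):
    n = len(calls)
    L = len(calls[0])
    loci = loci or [f"L{j}" for j in range(L)]
    return GenotypeMatrix.from_calls([f"A{i}" for i in range(n)], loci, calls)


class TestAlleleFrequencies:
    def test_two_hets(self):
        gm = make_gm([[(130, 134)], [(130, 134)]])
        ft = diversity.allele_frequencies(gm, "L0")
        assert ft.freqs == {130: 0.5, 134: 0.5}
        assert ft.n_typed == 2

    def test_hom_plus_het(self):
        gm = make_gm([[(130, 130)], [(130, 134)]])
        ft = diversity.allele_frequencies(gm, "L0")
        assert ft.freqs == {130: 0.75, 134: 0.25}

    def test_missing_excluded_from_denominator(self):
        gm = make_gm([[(130, 134)], [None]])
        ft = diversity.allele_frequencies(gm, "L0")
        assert ft.n_typed == 1
        assert ft.freqs == {130: 0.5, 134: 0.5}

    def test_all_missing(self):
        gm = make_gm([[None], [None]])
        ft = diversity.allele_frequencies(gm, "L0")
        assert ft.n_typed == 0 and ft.freqs == {}


class TestLocusSummary:
    def test_balanced_heterozygotes(self):
        # p = (0.5, 0.5), every call heterozygous
        gm = make_gm([[(130, 134)], [(130, 134)]])
        s = diversity.locus_summary(gm, "L0")
        assert s.ne == pytest.approx(2.0, abs=1e-9)
        assert s.he == pytest.approx(0.5, abs=1e-9)
        assert s.ho == pytest.approx(1.0, abs=1e-9)
        assert s.f == pytest.approx(-1.0, abs=1e-9)

    def test_monomorphic(self):
        gm = make_gm([[(130, 130)], [(130, 130)]])
        s = diversity.locus_summary(gm, "L0")
        assert (s.na, s.ne, s.ho, s.he) == (1, 1.0, 0.0, 0.0)
        assert s.f is None

    def test_unbiased_flag(self):
        gm = make_gm([[(130, 134)], [(130, 134)]])
        s = diversity.locus_summary(gm, "L0", unbiased=True)
        assert s.he == pytest.approx(0.5 * 4 / 3, abs=1e-12)

    def test_ne_le_na_equality_iff_equifrequent(self):
        gm = make_gm([[(130, 134)], [(130, 134)]])
        s = diversity.locus_summary(gm, "L0")
        assert s.ne == pytest.approx(s.na)
        gm2 = make_gm([[(130, 130)], [(130, 134)]])
        s2 = diversity.locus_summary(gm2, "L0")
        assert s2.ne < s2.na


class TestPic:
    def test_single_allele(self):
        gm = make_gm([[(130, 130)]])
        assert diversity.pic(diversity.allele_frequencies(gm, "L0")) == 0.0

    def test_two_equal_alleles(self):
        gm = make_gm([[(130, 134)], [(130, 134)]])
        # 1 - 0.5 - 2 * 0.25 * 0.25
        assert diversity.pic(
            diversity.allele_frequencies(gm, "L0")
        ) == pytest.approx(0.375, abs=1e-9)

    @given(
        counts=st.lists(st.integers(1, 20), min_size=1, max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_algebraic_identity(self, counts):
        # double-sum form == 1 - sum p^2 - (sum p^2)^2 + sum p^4
        p = np.array(counts, dtype=float)
        p /= p.sum()
        freqs = diversity.AlleleFrequencyTable(
            "x", {100 + 2 * i: float(v) for i, v in enumerate(p)}, 10
        )
        expected = 1 - (p**2).sum() - ((p**2).sum()) ** 2 + (p**4).sum()
        assert diversity.pic(freqs) == pytest.approx(expected, abs=1e-12)

    def test_pic_le_he(self):
        for seed in range(5):
            gm = random_matrix(30, 3, seed)
            for locus in gm.locus_ids:
                ft = diversity.allele_frequencies(gm, locus)
                s = diversity.locus_summary(gm, locus)
                assert diversity.pic(ft) <= s.he + 1e-12


class TestDiscriminatingPower:
    def test_all_same_pattern(self):
        gm = make_gm([[(130, 134)]] * 4)
        pt = diversity.pattern_frequencies(gm, "L0")
        assert diversity.discriminating_power(pt) == pytest.approx(0.0, abs=1e-12)

    def test_two_patterns_2_2(self):
        gm = make_gm([[(130, 134)], [(130, 134)], [(128, 128)], [(128, 128)]])
        pt = diversity.pattern_frequencies(gm, "L0")
        assert diversity.discriminating_power(pt) == pytest.approx(
            2.0 / 3.0, abs=1e-9
        )

    def test_four_distinct_patterns(self):
        gm = make_gm([[(130, 134)], [(128, 128)], [(140, 144)], [(150, 150)]])
        pt = diversity.pattern_frequencies(gm, "L0")
        assert diversity.discriminating_power(pt) == pytest.approx(1.0, abs=1e-9)

    def test_n_below_2_errors(self):
        gm = make_gm([[(130, 134)]])
        with pytest.raises(GenotypeError):
            diversity.discriminating_power(diversity.pattern_frequencies(gm, "L0"))

    def test_large_n_limit(self):
        # Dj -> 1 - sum p_i^2 as N -> inf
        reps = {(130, 134): 5000, (128, 128): 3000, (140, 144): 2000}
        calls = []
        for pat, k in reps.items():
            calls.extend([[pat]] * k)
        gm = make_gm(calls)
        pt = diversity.pattern_frequencies(gm, "L0")
        dj = diversity.discriminating_power(pt)
        p = np.array([0.5, 0.3, 0.2])
        assert dj == pytest.approx(1 - (p**2).sum(), abs=1e-3)


def simulate_hwe_locus(n, freqs, null_r, rng):
    """Draw n diploid calls under HWE with a null allele at frequency null_r."""
    alleles = list(freqs)
    p = np.array([freqs[a] for a in alleles]) * (1 - null_r)
    p = np.append(p, null_r)
    labels = alleles + [None]
    calls = []
    for _ in range(n):
        a = labels[rng.choice(len(labels), p=p / p.sum())]
        b = labels[rng.choice(len(labels), p=p / p.sum())]
        if a is None and b is None:
            calls.append([None])
        elif a is None:
            calls.append([(b, b)])
        elif b is None:
            calls.append([(a, a)])
        else:
            calls.append([(min(a, b), max(a, b))])
    return make_gm(calls)


class TestNullAlleleEM:
    FREQS = {100: 0.35, 104: 0.3, 108: 0.2, 112: 0.15}

    def test_no_nulls(self):
        rng = np.random.default_rng(7)
        gm = simulate_hwe_locus(500, self.FREQS, 0.0, rng)
        r = diversity.null_allele_frequency(gm, "L0")
        assert r < 0.02

    def test_recovers_r20(self):
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            gm = simulate_hwe_locus(500, self.FREQS, 0.20, rng)
            ests.append(diversity.null_allele_frequency(gm, "L0"))
        assert abs(float(np.mean(ests)) - 0.20) < 0.05

    def test_too_few_calls_returns_none(self):
        gm = make_gm([[(130, 134)]] * 5)
        with pytest.warns(UserWarning):
            assert diversity.null_allele_frequency(gm, "L0") is None

    def test_r_in_range(self):
        for seed in range(3):
            gm = random_matrix(50, 1, seed)
            r = diversity.null_allele_frequency(gm, gm.locus_ids[0])
            assert 0.0 <= r < 1.0


class TestPrivateRare:
    def _gm(self):
        return make_gm(
            [
                [(100, 102)],
                [(100, 100)],
                [(104, 104)],
                [(100, 102)],
            ]
        )

    def test_private_alleles(self):
        gm = self._gm()
        grouping = {"A0": "g1", "A1": "g1", "A2": "g2", "A3": "g1"}
        res = diversity.private_and_rare_alleles(gm, grouping)
        assert res.private["g2"] == [("L0", 104)]
        assert ("L0", 100) in res.private["g1"]  # only g1 carries 100

    def test_shared_alleles_not_private(self):
        gm = make_gm([[(100, 102)], [(100, 102)]])
        res = diversity.private_and_rare_alleles(gm, {"A0": "x", "A1": "y"})
        assert res.private == {"x": [], "y": []}

    def test_rare_strict_threshold(self):
        # 100 at freq 0.049 -> rare ; at 0.050 -> not rare
        def build(count_100, total):
            calls = [[(100, 100)]] * (count_100 // 2) + [
                [(200, 200)]
            ] * ((total - count_100 // 2))
            return make_gm(calls)

        # 49/1000 copies
        calls = [[(100, 200)]] * 49 + [[(200, 200)]] * 451
        gm = make_gm(calls)
        res = diversity.private_and_rare_alleles(
            gm, {a: "g" for a in gm.accession_ids}
        )
        assert ("L0", 100) in res.rare
        calls = [[(100, 200)]] * 50 + [[(200, 200)]] * 450
        gm = make_gm(calls)
        res = diversity.private_and_rare_alleles(
            gm, {a: "g" for a in gm.accession_ids}
        )
        assert ("L0", 100) not in res.rare

    def test_unlabeled_accession_errors(self):
        gm = self._gm()
        with pytest.raises(GenotypeError):
            diversity.private_and_rare_alleles(gm, {"A0": "g1"})

    def test_unknown_accession_errors(self):
        gm = self._gm()
        grouping = {a: "g" for a in gm.accession_ids}
        grouping["nope"] = "g"
        with pytest.raises(GenotypeError, match="nope"):
            diversity.private_and_rare_alleles(gm, grouping)


class TestCollectionSummary:
    def test_single_locus_totals(self):
        gm = make_gm([[(130, 134)], [(130, 134)]])
        cs = diversity.collection_summary(gm, full=False)
        s = diversity.locus_summary(gm, "L0")
        assert cs.total_na == s.na
        assert cs.total_ne == pytest.approx(s.ne)
        assert cs.means["na"] == s.na

    def test_two_loci_mean_and_total(self):
        gm = random_matrix(40, 2, seed=3, alleles=10)
        cs = diversity.collection_summary(gm, full=False)
        nas = [diversity.locus_summary(gm, l).na for l in gm.locus_ids]
        assert cs.total_na == sum(nas)
        assert cs.means["na"] == pytest.approx(np.mean(nas))
        assert cs.ses["na"] == pytest.approx(
            np.std(nas, ddof=1) / math.sqrt(2)
        )

    def test_f_excluded_when_undefined(self):
        gm = make_gm([[(130, 130), (100, 104)], [(130, 130), (100, 104)]])
        cs = diversity.collection_summary(gm, full=False)
        # L0 monomorphic (F undefined); mean F comes from L1 only
        assert cs.means["f"] == pytest.approx(
            diversity.locus_summary(gm, "L1").f
        )


class TestHweCalibration:
    def test_ho_matches_he_under_hwe(self):
        rng = np.random.default_rng(11)
        freqs = {100: 0.4, 104: 0.3, 108: 0.2, 112: 0.1}
        gm = simulate_hwe_locus(1000, freqs, 0.0, rng)
        s = diversity.locus_summary(gm, "L0")
        assert abs(s.ho - s.he) < 0.02
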
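"""Per-population status calls, polarity harmonization, SD/SP/SSP table."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svdiverge.io_formats import MISSING, SampleRecord
from svdiverge.sv_classify import (
    Category,
    PopulationStatus,
    Status,
    call_population_status,
    classify_interspecies_sv,
    frequency_spectrum,
    genotyping_summary,
    harmonize_polarity,
)

from conftest import make_matrix


def _samples(prefix, n, species):
    return [
        SampleRecord(f"{prefix}{i}", species, 10**9, 15.0, 0.95, False)
        for i in range(n)
    ]


def _status(sv_id, n_alleles, carriers, status, population="A"):
    return PopulationStatus(sv_id, population, n_alleles, carriers, status)


class TestPopulationStatus:
    def test_all_reference_genotypes_are_absent(self):
        m = make_matrix([[0], [0], [0], [0], [0]])
        (st_,) = call_population_status(m, _samples("S", 5, "A"), "A")
        assert st_.status is Status.ABSENT and st_.freq == 0.0

    def test_hand_counted_polymorphic_frequency(self):
        # genotypes (2,2,2,1,MISSING): 8 alleles genotyped, 7 carriers
        m = make_matrix([[2], [2], [2], [1], [MISSING]])
        (st_,) = call_population_status(m, _samples("S", 5, "A"), "A", min_alleles=8)
        assert st_.n_alleles_genotyped == 8
        assert st_.carrier_alleles == 7
        assert st_.freq == pytest.approx(0.875)
        assert st_.status is Status.POLYMORPHIC

    def test_too_few_alleles_is_unresolved(self):
        m = make_matrix([[1], [1], [0]])
        (st_,) = call_population_status(m, _samples("S", 3, "A"), "A", min_alleles=10)
        assert st_.status is Status.UNRESOLVED

    def test_empty_population_errors(self):
        m = make_matrix([[0], [0]])
        with pytest.raises(ValueError, match="population"):
            call_population_status(m, _samples("S", 2, "A"), "B")

    def test_excluded_samples_do_not_contribute(self):
        samples = _samples("S", 4, "A")
        samples[0] = SampleRecord("S0", "A", 10**9, 15.0, 0.95, excluded_by_pca=True)
        m = make_matrix([[2], [0], [0], [0]])
        (st_,) = call_population_status(m, samples, "A", min_alleles=2)
        assert st_.carrier_alleles == 0 and st_.status is Status.ABSENT

    def test_fixed_tolerance_allows_near_fixed(self):
        m = make_matrix([[2]] * 49 + [[1]])
        (strict,) = call_population_status(m, _samples("S", 50, "A"), "A")
        (tol,) = call_population_status(
            m, _samples("S", 50, "A"), "A", fixed_tolerance=0.02
        )
        assert strict.status is Status.POLYMORPHIC
        assert tol.status is Status.FIXED


class TestHarmonizePolarity:
    def test_expected_fixed_difference(self):
        a = _status("sv", 200, 0, Status.ABSENT, "A")
        b = _status("sv", 200, 0, Status.ABSENT, "B")
        assert harmonize_polarity(a, b) == (0.0, 1.0)

    def test_flip_arithmetic(self):
        a = _status("sv", 100, 30, Status.POLYMORPHIC, "A")
        b = _status("sv", 100, 60, Status.POLYMORPHIC, "B")
        p_a, p_b = harmonize_polarity(a, b)
        assert p_a == pytest.approx(0.3) and p_b == pytest.approx(0.4)

    def test_single_reference_passes_through(self):
        a = _status("sv", 100, 30, Status.POLYMORPHIC, "A")
        b = _status("sv", 100, 60, Status.POLYMORPHIC, "B")
        assert harmonize_polarity(a, b, single_reference=True) == (0.3, 0.6)

    def test_mismatched_ids_error(self):
        a = _status("sv1", 10, 0, Status.ABSENT)
        b = _status("sv2", 10, 0, Status.ABSENT, "B")
        with pytest.raises(ValueError, match="mismatch"):
            harmonize_polarity(a, b)


def _brute_force_category(st_a: Status, st_b_arrangement: Status) -> Category:
    """Independent enumeration of the decision table on harmonized statuses."""
    if Status.UNRESOLVED in (st_a, st_b_arrangement):
        return Category.UNRESOLVED
    n_poly = [st_a, st_b_arrangement].count(Status.POLYMORPHIC)
    if n_poly == 2:
        return Category.SSP
    if n_poly == 1:
        return Category.SP
    if st_a == st_b_arrangement:
        return Category.PRIVATE_OR_ARTIFACT
    return Category.SD


_STATUS_EXAMPLES = {
    Status.ABSENT: (200, 0),
    Status.POLYMORPHIC: (200, 100),
    Status.FIXED: (200, 200),
    Status.UNRESOLVED: (4, 2),
}


class TestClassification:
    def test_fixed_difference_is_sd(self):
        a = _status("sv", 200, 0, Status.ABSENT, "A")
        b = _status("sv", 200, 0, Status.ABSENT, "B")  # B lacks the A-arrangement
        c = classify_interspecies_sv(a, b)
        assert c.category is Category.SD
        assert (c.p_b_in_a, c.p_b_in_b) == (0.0, 1.0)

    def test_polymorphic_in_both_is_ssp(self):
        a = _status("sv", 200, 80, Status.POLYMORPHIC, "A")
        b = _status("sv", 200, 80, Status.POLYMORPHIC, "B")
        assert classify_interspecies_sv(a, b).category is Category.SSP

    def test_polymorphic_in_one_is_sp(self):
        a = _status("sv", 200, 0, Status.ABSENT, "A")
        b = _status("sv", 200, 140, Status.POLYMORPHIC, "B")
        assert classify_interspecies_sv(a, b).category is Category.SP

    def test_unsupported_by_both_is_private(self):
        a = _status("sv", 200, 0, Status.ABSENT, "A")
        b = _status("sv", 200, 200, Status.FIXED, "B")  # B fixed for A-arrangement
        c = classify_interspecies_sv(a, b)
        assert c.category is Category.PRIVATE_OR_ARTIFACT
        assert c.sub_label == "both_absent"

    def test_inverted_polarity_sd_is_flagged(self):
        a = _status("sv", 200, 200, Status.FIXED, "A")
        b = _status("sv", 200, 200, Status.FIXED, "B")
        c = classify_interspecies_sv(a, b)
        assert c.category is Category.SD and c.polarity_inverted

    def test_all_status_pairs_match_brute_force_enumeration(self):
        for st_a, st_b_arr in itertools.product(Status, Status):
            n_a, c_a = _STATUS_EXAMPLES[st_a]
            # construct the vs-ref-B call whose flip yields st_b_arr
            flip = {
                Status.ABSENT: Status.FIXED,
                Status.FIXED: Status.ABSENT,
            }.get(st_b_arr, st_b_arr)
            n_b, c_b = _STATUS_EXAMPLES[flip]
            a = _status("sv", n_a, c_a, st_a, "A")
            b = _status("sv", n_b, c_b, flip, "B")
            got = classify_interspecies_sv(a, b).category
            assert got is _brute_force_category(st_a, st_b_arr), (st_a, st_b_arr)

    def test_label_swap_symmetry(self):
        """Swapping population labels (with polarity flip) preserves SD/SP/SSP."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = 200
            c_a, c_b = int(rng.integers(0, n + 1)), int(rng.integers(0, n + 1))
            a = _status("sv", n, c_a, _status_of(c_a, n), "A")
            b = _status("sv", n, c_b, _status_of(c_b, n), "B")
            fwd = classify_interspecies_sv(a, b).category
            a2 = PopulationStatus("sv", "A", n, c_b, _status_of(c_b, n))
            b2 = PopulationStatus("sv", "B", n, c_a, _status_of(c_a, n))
            rev = classify_interspecies_sv(a2, b2).category
            assert fwd is rev


def _status_of(carriers, n):
    if carriers == 0:
        return Status.ABSENT
    if carriers == n:
        return Status.FIXED
    return Status.POLYMORPHIC


class TestSpectrumAndSummary:
    def test_empty_input_all_zero_histogram(self):
        frame = frequency_spectrum([])
        assert frame["count"].sum() == 0

    def test_tail_masses(self):
        statuses = [
            _status(f"sv{i}", 100, int(round(f * 100)), Status.POLYMORPHIC)
            for i, f in enumerate([0.05, 0.07, 0.95])
        ]
        frame = frequency_spectrum(statuses)
        tails = frame.attrs["tails"][("A", "ALL")]
        assert tails["n_low"] == 2 and tails["n_high"] == 1

    def test_histogram_matches_independent_counting_loop(self):
        rng = np.random.default_rng(5)
        n = 1000
        carriers = rng.integers(0, 201, size=n)
        statuses = [
            _status(f"sv{i}", 200, int(c), _status_of(int(c), 200))
            for i, c in enumerate(carriers)
        ]
        frame = frequency_spectrum(statuses, bin_width=0.05)
        # brute-force binning
        freqs = carriers / 200.0
        for _, row in frame.iterrows():
            lo, hi = row["bin_low"], row["bin_high"]
            if hi >= 1.0:
                expected = int(((freqs >= lo) & (freqs <= hi)).sum())
            else:
                expected = int(((freqs >= lo) & (freqs < hi)).sum())
            assert row["count"] == expected

    def test_partition_and_rate(self):
        statuses = [
            _status(f"sv{i}", 200, 100, Status.POLYMORPHIC) for i in range(8)
        ] + [_status(f"u{i}", 4, 2, Status.UNRESOLVED) for i in range(2)]
        frame = genotyping_summary(statuses)
        row = frame.iloc[0]
        assert (
            row["n_absent"] + row["n_polymorphic"] + row["n_fixed"] + row["n_unresolved"]
            == row["n_svs"]
        )
        assert row["genotyping_rate"] == pytest.approx(0.8)

    def test_zero_svs_no_division_error(self):
        frame = genotyping_summary([])
        assert frame.empty

    @settings(max_examples=30, deadline=None)
    @given(
        carriers=st.lists(st.integers(0, 20), min_size=1, max_size=50),
    )
    def test_status_counts_always_partition(self, carriers):
        statuses = [
            _status(f"sv{i}", 20, c, _status_of(c, 20)) for i, c in enumerate(carriers)
        ]
        frame = genotyping_summary(statuses)
        parts = frame[["n_absent", "n_polymorphic", "n_fixed", "n_unresolved"]].sum(axis=1)
        assert (parts == frame["n_svs"]).all()
        assert frame["n_svs"].sum() == len(carriers)
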
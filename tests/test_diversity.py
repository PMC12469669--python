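"""Diversity statistics: No, Ne, Ho, He, PIC, F, and the breed summary."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msatpop import (
    AlleleFrequencySpectrum,
    NoDataError,
    breed_inbreeding,
    dataset_from_rows,
    diversity_table,
    effective_allele_count,
    expected_heterozygosity,
    observed_allele_count,
    observed_heterozygosity,
    pic,
)
from msatpop.diversity import pic_class


def spectrum(freqs, n_genes=40):
    return AlleleFrequencySpectrum("P", "L", freqs, n_genes)


def random_spectrum(rng, max_alleles=8):
    k = rng.integers(2, max_alleles + 1)
    p = rng.dirichlet(np.ones(k))
    return spectrum({100 + 2 * i: float(x) for i, x in enumerate(p / p.sum())})


class TestAlleleCounts:
    @pytest.mark.parametrize(
        "freqs,expected",
        [({100: 0.75, 120: 0.25}, 2), ({100: 1.0}, 1),
         ({100 + i: 0.1 for i in range(10)}, 10)],
    )
    def test_observed(self, freqs, expected):
        assert observed_allele_count(spectrum(freqs)) == expected

    @pytest.mark.parametrize(
        "freqs,expected",
        [({100: 0.5, 120: 0.5}, 2.0), ({100: 0.75, 120: 0.25}, 1.6), ({100: 1.0}, 1.0)],
    )
    def test_effective(self, freqs, expected):
        assert effective_allele_count(spectrum(freqs)) == pytest.approx(expected)


class TestHeterozygosity:
    def test_observed_counting(self):
        ds = dataset_from_rows(
            ["L"],
            [("i1", "P", [(1, 2)]), ("i2", "P", [(1, 2)]), ("i3", "P", [(1, 2)]),
             ("i4", "P", [(1, 1)])],
        )
        assert observed_heterozygosity(ds, "P", "L") == 0.75

    def test_missing_excluded_from_denominator(self):
        ds = dataset_from_rows(
            ["L"], [("i1", "P", [(1, 2)]), ("i2", "P", [None]), ("i3", "P", [(1, 1)])]
        )
        assert observed_heterozygosity(ds, "P", "L") == 0.5

    def test_all_homozygous(self):
        ds = dataset_from_rows(["L"], [("i1", "P", [(1, 1)]), ("i2", "P", [(2, 2)])])
        assert observed_heterozygosity(ds, "P", "L") == 0.0

    def test_no_typed_individuals(self):
        ds = dataset_from_rows(["L"], [("i1", "P", [None]), ("i2", "Q", [(1, 1)])])
        with pytest.raises(NoDataError):
            observed_heterozygosity(ds, "P", "L")

    def test_expected_biased_symmetric(self):
        assert expected_heterozygosity(spectrum({1: 0.5, 2: 0.5}), unbiased=False) == 0.5

    def test_expected_unbiased_small_sample(self):
        he = expected_heterozygosity(spectrum({1: 0.5, 2: 0.5}, n_genes=20), unbiased=True)
        assert he == pytest.approx(20 / 19 * 0.5)

    def test_monomorphic_zero(self):
        assert expected_heterozygosity(spectrum({1: 1.0}), unbiased=False) == 0.0


class TestPic:
    @pytest.mark.parametrize(
        "freqs,expected",
        [({1: 0.5, 2: 0.5}, 0.375), ({1: 1.0}, 0.0),
         ({1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}, 0.703125)],
    )
    def test_hand_values(self, freqs, expected):
        assert pic(spectrum(freqs)) == pytest.approx(expected, abs=1e-12)

    def test_classification_bands(self):
        assert pic_class(0.6) == "high"
        assert pic_class(0.375) == "moderate"
        assert pic_class(0.1) == "low"


class TestInbreeding:
    def test_identity_when_equal(self):
        assert breed_inbreeding(0.5, 0.5) == 0.0

    def test_heterozygote_excess_negative(self):
        assert breed_inbreeding(0.72, 0.46) == pytest.approx(1 - 0.72 / 0.46)  # ~ -0.565

    def test_total_homozygosity(self):
        assert breed_inbreeding(0.0, 0.5) == 1.0

    def test_undefined_for_monomorphic(self):
        with pytest.raises(ValueError):
            breed_inbreeding(0.0, 0.0)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(seed=st.integers(0, 2**31 - 1))
def test_identities_on_random_spectra(seed):
    """PIC <= He <= 1 - 1/No and Ne <= No (equality iff equifrequent);
    PIC and He agree with brute-force double-loop oracles to 1e-12."""
    rng = np.random.default_rng(seed)
    spec = random_spectrum(rng)
    p = spec.frequencies()
    no = observed_allele_count(spec)
    ne = effective_allele_count(spec)
    he = expected_heterozygosity(spec, unbiased=False)
    pic_val = pic(spec)
    assert pic_val <= he + 1e-12
    assert he <= 1 - 1 / no + 1e-12
    assert 1 - 1e-12 <= ne <= no + 1e-12
    # brute-force oracles
    he_oracle = 1.0 - sum(x * x for x in p)
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * p[i] ** 2 * p[j] ** 2
    pic_oracle = he_oracle - cross
    assert he == pytest.approx(he_oracle, abs=1e-12)
    assert pic_val == pytest.approx(pic_oracle, abs=1e-12)


def test_ne_equals_no_iff_equifrequent():
    eq = spectrum({1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25})
    assert effective_allele_count(eq) == pytest.approx(4.0, abs=1e-12)
    uneq = spectrum({1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1})
    assert effective_allele_count(uneq) < 4.0


def test_statistics_invariant_under_relabeling(two_pop_dataset):
    """Relabeling alleles (order-preserving size shift) leaves Ho/He unchanged."""
    shifted = dataset_from_rows(
        ["LocA"],
        [
            (ind.id, ind.population,
             [None if (g := two_pop_dataset.calls[(ind.id, "LocA")]).is_missing
              else (g.allele_a + 50, g.allele_b + 50)])
            for ind in two_pop_dataset.individuals
        ],
    )
    for pop in ("P1", "P2"):
        assert observed_heterozygosity(shifted, pop, "LocA") == observed_heterozygosity(
            two_pop_dataset, pop, "LocA"
        )


class TestDiversityTable:
    def test_two_locus_mean_and_se(self):
        # Ho values 0.4 and 0.6 across two loci -> mean 0.5, SE 0.1
        rows = []
        for i in range(10):
            ga = (1, 2) if i < 4 else (1, 1)  # Ho = 0.4
            gb = (1, 2) if i < 6 else (1, 1)  # Ho = 0.6
            rows.append((f"i{i}", "P", [ga, gb]))
        _, summary = diversity_table(dataset_from_rows(["L1", "L2"], rows))
        row = summary.iloc[0]
        assert row["Ho_mean"] == pytest.approx(0.5)
        assert row["Ho_se"] == pytest.approx(0.1)
        assert row["loci_used"] == 2

    def test_single_locus_se_undefined(self):
        ds = dataset_from_rows(["L"], [("i1", "P", [(1, 2)]), ("i2", "P", [(1, 1)])])
        _, summary = diversity_table(ds)
        assert math.isnan(summary.iloc[0]["Ho_se"])

    def test_seven_breed_shape(self, default_sim):
        records, summary = diversity_table(default_sim)
        assert len(summary) == 7
        assert {"No_mean", "Ne_mean", "Ho_mean", "He_mean", "PIC_mean", "F_mean"} <= set(
            summary.columns
        )

    def test_f_averaging_conventions_differ_but_agree_in_sign(self, default_sim):
        _, a = diversity_table(default_sim, f_averaging="mean_of_ratios")
        _, b = diversity_table(default_sim, f_averaging="ratio_of_means")
        assert np.allclose(a["F_mean"], b["F_mean"], atol=0.15)
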
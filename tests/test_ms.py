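"""Charge-series deconvolution, peptide masses, cross-link ladders."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biophyskit.errors import (
    InvalidSequenceError,
    NoConsistentSeriesError,
    PreconditionError,
)
from biophyskit.ms_utils import (
    DSBU_BRIDGE,
    PROTON_MASS,
    PeakList,
    adduct_masses,
    complex_mass,
    deconvolute_charge_series,
    mz_to_neutral,
    peptide_average_mass,
)
from biophyskit.synthetic_data import synthetic_peaks

A7B_M = "LLLWKMGFFKRAKHPE"
A7B_SCRB = "KEFWGLHAKPRLKLMF"


class TestDeconvolution:
    def test_native_charge_series_of_a_21_7_kda_protein(self):
        """The printed triple 2178/2420/2722 must be assigned 10+/9+/8+
        and deconvolve to ~21,767 Da."""
        peaks = PeakList.from_pairs([(2178, 1.0), (2420, 1.0), (2722, 1.0)])
        res = deconvolute_charge_series(peaks, z_min=5, z_max=15)
        assert list(res.charges) == [10, 9, 8]
        assert res.neutral_mass == pytest.approx(21767.0, abs=10.0)

    @given(
        mass=st.floats(5e3, 2e5),
        z_lo=st.integers(1, 40),
        n_peaks=st.integers(3, 8),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_inverse_of_the_peak_generator(self, mass, z_lo, n_peaks):
        charges = range(z_lo, min(z_lo + n_peaks, 51))
        peaks = synthetic_peaks(mass, charges)
        res = deconvolute_charge_series(peaks, 1, 50)
        assert res.neutral_mass == pytest.approx(mass, rel=1e-9)
        assert set(res.charges) == set(charges)

    def test_integer_rounded_peaks_still_recover_within_0_1_percent(self):
        mass = 30000.0
        peaks = synthetic_peaks(mass, range(5, 13), mz_decimals=0)
        res = deconvolute_charge_series(peaks, 1, 50)
        assert res.neutral_mass == pytest.approx(mass, rel=1e-3)

    def test_intensity_weighting_of_the_mean(self):
        # put all weight on one peak: mass equals that peak's neutral mass
        peaks = PeakList.from_pairs([(2178, 1000.0), (2420, 0.0), (2722, 0.0)])
        res = deconvolute_charge_series(peaks, 5, 15)
        assert res.neutral_mass == pytest.approx(10 * (2178 - PROTON_MASS),
                                                 rel=1e-12)

    def test_single_peak_with_stated_charge(self):
        assert mz_to_neutral(2178.0, 1) == pytest.approx(2178.0 - 1.00728)

    def test_inconsistent_peaks_raise_no_series_signal(self):
        peaks = PeakList.from_pairs([(1000, 1.0), (1700, 1.0), (2900, 1.0)])
        with pytest.raises(NoConsistentSeriesError):
            deconvolute_charge_series(peaks, 1, 50)

    def test_preconditions(self):
        peaks = PeakList.from_pairs([(2178, 1.0), (2420, 1.0)])
        with pytest.raises(PreconditionError):
            deconvolute_charge_series(peaks, 10, 5)
        with pytest.raises(PreconditionError):
            deconvolute_charge_series(PeakList.from_pairs([(2178, 1.0)]), 1, 50)


class TestPeptideMass:
    def test_glycine(self):
        assert peptide_average_mass("G") == pytest.approx(75.07, abs=0.01)

    def test_integrin_peptide_against_residue_table_sum(self):
        assert peptide_average_mass(A7B_M) == pytest.approx(2001.5, abs=0.5)

    def test_agreement_with_independent_mass_library(self):
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        expected = pyteomics_mass.calculate_mass(sequence=A7B_M, average=True)
        assert peptide_average_mass(A7B_M) == pytest.approx(expected, abs=0.1)

    def test_acetylation_adds_42(self):
        free = peptide_average_mass(A7B_M)
        assert peptide_average_mass(A7B_M, n_term_mod="acetyl") - free == (
            pytest.approx(42.04, abs=0.01))

    def test_amidation_subtracts_one(self):
        free = peptide_average_mass(A7B_M)
        assert peptide_average_mass(A7B_M, c_term_mod="amide") - free == (
            pytest.approx(-0.985, abs=0.01))

    def test_scrambled_peptide_has_identical_mass(self):
        # same residue content, different order: mass must be identical
        assert peptide_average_mass(A7B_SCRB) == pytest.approx(
            peptide_average_mass(A7B_M), abs=1e-9)

    @given(st.permutations(list(A7B_M)))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_permutation_invariance(self, shuffled):
        assert peptide_average_mass("".join(shuffled)) == pytest.approx(
            peptide_average_mass(A7B_M), abs=1e-9)

    def test_unknown_letter_rejected(self):
        with pytest.raises(InvalidSequenceError):
            peptide_average_mass("GAVLX")
        with pytest.raises(InvalidSequenceError):
            peptide_average_mass("")


class TestCrosslinkArithmetic:
    def test_one_bridge_on_the_bare_protein(self):
        ladder = adduct_masses(21770.0, n_max=1)
        assert ladder.entries[1][1] == pytest.approx(21966.1, abs=0.5)

    def test_zero_adducts_is_identity(self):
        ladder = adduct_masses(21770.0, n_max=0)
        assert ladder.entries == [(0, 21770.0)]

    def test_five_bridges_land_in_the_observed_window(self):
        ladder = adduct_masses(21770.0, n_max=5)
        assert 22000.0 < ladder.entries[5][1] < 23000.0

    def test_ladder_spacing_is_exactly_the_bridge_mass(self):
        ladder = adduct_masses(21770.0, n_max=5, bridge_mass=196.1)
        diffs = np.diff(ladder.masses)
        assert np.allclose(diffs, 196.1, atol=1e-9)
        assert np.all(diffs > 0)

    def test_hydrolyzed_linkers_carry_an_extra_water_each(self):
        bridged = adduct_masses(21770.0, 3)
        hydro = adduct_masses(21770.0, 3, hydrolyzed=True)
        for (n, mb), (_, mh) in zip(bridged.entries, hydro.entries):
            assert mh - mb == pytest.approx(n * 18.0153, abs=1e-9)

    def test_protein_peptide_complex_mass(self):
        """Deconvolved protein + amidated 16-mer + one DSBU bridge must
        reproduce the 23,964 Da complex."""
        peptide = peptide_average_mass(A7B_M, c_term_mod="amide")
        total = complex_mass(21767.0, peptide, 1, DSBU_BRIDGE)
        assert total == pytest.approx(23964.0, abs=2.0)

    def test_complex_without_linker_is_a_simple_sum(self):
        assert complex_mass(21767.0, 2000.0, 0) == 23767.0

    def test_one_to_two_stoichiometry_window(self):
        """The bare 1:2 complex sits just below the observed 26.5-28 kDa
        signal window; with the extra linker decoration seen on the 1:1
        complex (2-5 additional DSBU) it spans the window."""
        peptide = peptide_average_mass(A7B_M, c_term_mod="amide")
        bare = complex_mass(21767.0, 2 * peptide, 2, DSBU_BRIDGE)
        decorated = adduct_masses(bare, n_max=5).masses
        assert bare < 26500.0
        assert np.any((decorated > 26500.0) & (decorated < 28000.0))

    def test_invalid_inputs(self):
        with pytest.raises(PreconditionError):
            adduct_masses(-1.0, 3)
        with pytest.raises(PreconditionError):
            complex_mass(0.0, 2000.0)
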
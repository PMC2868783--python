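"""Diprotic speciation, dimer mass balance, solubility and saturation ratio."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bilispec import (
    HIGH_PKA,
    LOW_PKA,
    NO_DIMER,
    DimerizationModel,
    IonizationConstants,
    SolubilityModel,
    ValidationError,
    dianion_saturation,
    fraction_table,
    monomer_composition_from_total,
    saturation_ratio,
    species_fractions,
    total_solubility,
)

pka_pairs = st.tuples(
    st.floats(2.0, 12.0, allow_nan=False), st.floats(2.0, 12.0, allow_nan=False)
)


class TestSpeciesFractions:
    @pytest.mark.parametrize(
        "ph, expected",
        [
            (5.0, (0.0656, 0.4137, 0.5208)),
            (4.0, (0.5847, 0.3689, 0.0464)),
        ],
    )
    def test_low_pka_reference_values(self, ph, expected, low_pka):
        fr = species_fractions(ph, low_pka)
        assert fr.as_tuple() == pytest.approx(expected, abs=5e-5)

    def test_diacid_and_monoanion_equal_at_first_pka(self):
        ks = IonizationConstants(4.0, 11.0)  # well-separated steps
        fr = species_fractions(4.0, ks)
        assert fr.fh2b == pytest.approx(fr.fhb, rel=1e-12)

    def test_acid_limit_is_pure_diacid(self, high_pka):
        fr = species_fractions(0.0, high_pka)
        assert fr.fh2b == pytest.approx(1.0, abs=1e-8)
        assert fr.fhb < 1e-8 and fr.fb < 1e-15

    def test_nonfinite_ph_rejected(self, high_pka):
        with pytest.raises(ValidationError):
            species_fractions(float("nan"), high_pka)

    @settings(max_examples=200, derandomize=True)
    @given(ph=st.floats(0.0, 14.0, allow_nan=False), pkas=pka_pairs)
    def test_fractions_sum_to_one_and_lie_in_unit_interval(self, ph, pkas):
        fr = species_fractions(ph, IonizationConstants(*pkas))
        assert sum(fr.as_tuple()) == pytest.approx(1.0, abs=1e-12)
        assert all(0.0 <= f <= 1.0 for f in fr.as_tuple())

    @settings(max_examples=100, derandomize=True)
    @given(
        ph=st.floats(0.5, 13.0, allow_nan=False),
        dph=st.floats(0.01, 1.0),
        pkas=pka_pairs,
    )
    def test_dianion_rises_and_diacid_falls_with_ph(self, ph, dph, pkas):
        ks = IonizationConstants(*pkas)
        lo, hi = species_fractions(ph, ks), species_fractions(ph + dph, ks)
        assert hi.fb > lo.fb
        assert hi.fh2b < lo.fh2b


class TestFractionTable:
    def test_matches_pointwise_computation(self, low_pka):
        grid = np.arange(4.0, 10.01, 0.5)
        table = fraction_table(grid, low_pka)
        assert len(table) == 13
        for _, row in table.iterrows():
            fr = species_fractions(row["pH"], low_pka)
            assert (row["fH2B"], row["fHB"], row["fB"]) == pytest.approx(
                fr.as_tuple(), rel=1e-14
            )

    def test_single_point_grid(self, high_pka):
        table = fraction_table([7.4], high_pka)
        assert len(table) == 1

    def test_high_pka_diacid_dominates_at_neutral_ph(self, high_pka):
        table = fraction_table(np.arange(4.0, 10.01, 0.5), high_pka)
        assert float(table.loc[table["pH"] == 6.0, "fH2B"].iloc[0]) > 0.99

    def test_unsorted_grid_rejected(self, high_pka):
        with pytest.raises(ValidationError):
            fraction_table([7.0, 6.0], high_pka)
        with pytest.raises(ValidationError):
            fraction_table([], high_pka)


class TestMonomerComposition:
    def test_no_dimer_reduces_to_fraction_split(self, high_pka):
        comp = monomer_composition_from_total(8.0, 7.4, high_pka, NO_DIMER)
        fr = species_fractions(7.4, high_pka)
        assert comp.ch2b == pytest.approx(8.0 * fr.fh2b, rel=1e-14)
        assert comp.chb == pytest.approx(8.0 * fr.fhb, rel=1e-14)
        assert comp.cb == pytest.approx(8.0 * fr.fb, rel=1e-14)
        assert comp.cdimer == 0.0

    def test_vesicle_anchor_composition(self, high_pka, dimer):
        # at pH 6.54 the dianion fraction is ~3e-4, so the dimer vanishes
        comp = monomer_composition_from_total(5.1, 6.54, high_pka, dimer)
        assert comp.ch2b == pytest.approx(4.968, abs=1e-3)
        assert comp.cdimer < 1e-6

    def test_forward_then_invert_recovers_composition(self, high_pka, dimer):
        # construct a composition with cb = 1 uM, then re-split its total
        ph = 9.0
        fr = species_fractions(ph, high_pka)
        cb = 1.0
        ch2b = cb * fr.fh2b / fr.fb
        chb = cb * fr.fhb / fr.fb
        cdim = dimer.kd * cb * cb
        assert cdim == pytest.approx(0.26)
        total = ch2b + chb + cb + 2 * cdim
        comp = monomer_composition_from_total(total, ph, high_pka, dimer)
        assert comp.cb == pytest.approx(cb, abs=1e-9)
        assert comp.ch2b == pytest.approx(ch2b, abs=1e-9)
        assert comp.cdimer == pytest.approx(cdim, abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(
        total=st.floats(1e-6, 100.0),
        ph=st.floats(4.0, 12.0),
        kd=st.floats(0.0, 2.0),
        pkas=pka_pairs,
    )
    def test_mass_balance_round_trip(self, total, ph, kd, pkas):
        comp = monomer_composition_from_total(
            total, ph, IonizationConstants(*pkas), DimerizationModel(kd)
        )
        assert comp.total_free == pytest.approx(total, abs=1e-9, rel=1e-9)
        assert min(comp.ch2b, comp.chb, comp.cb, comp.cdimer) >= 0.0

    def test_negative_total_rejected(self, high_pka):
        with pytest.raises(ValidationError):
            monomer_composition_from_total(-1.0, 7.0, high_pka)


class TestSolubility:
    @pytest.mark.parametrize(
        "ph, expected",
        [(7.40, 0.062), (7.83, 0.084), (8.05, 0.112), (8.2, 0.148)],
    )
    def test_partition_derived_solubilities(self, ph, expected):
        assert total_solubility(ph) == pytest.approx(expected, abs=5e-4)

    def test_acid_limit_is_diacid_solubility(self):
        assert total_solubility(4.0) == pytest.approx(0.051, abs=1e-4)

    def test_never_below_diacid_solubility(self):
        sol = SolubilityModel()
        for ph in np.linspace(0, 14, 57):
            assert total_solubility(ph, sol) > sol.s_h2b

    @pytest.mark.parametrize(
        "ph, expected",
        [
            (8.28, 0.051),           # exponent exactly zero
            (9.3, 0.051 * 10**2.04),
            (7.0, 0.051 * 10**-2.56),
        ],
    )
    def test_dianion_saturation(self, ph, expected):
        assert dianion_saturation(ph) == pytest.approx(expected, rel=1e-12)

    def test_saturation_ratio(self):
        ph = 7.8
        st_ = total_solubility(ph)
        assert saturation_ratio(st_, ph) == pytest.approx(1.0, rel=1e-12)
        assert saturation_ratio(0.0, ph) == 0.0
        # a 20.3 uM free pool at pH 7.0 is ~369-fold supersaturated
        assert saturation_ratio(20.3, 7.0) == pytest.approx(369.0, abs=1.0)
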
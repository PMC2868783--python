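"""Taurocholate micelle partition, apparent pKa shifts and the CD fit."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from bilispec import (
    BoundSpeciesFractions,
    EllipticityModel,
    MicelleDistribution,
    NumericalError,
    TcPartitionParams,
    ValidationError,
    apparent_pka,
    bound_species_fractions,
    fit_ellipticity,
    gen_tc_dataset,
    load_reference_table,
    log_partition,
    predict_tc_ellipticity,
    scale_ellipticity,
)

DIST = MicelleDistribution()


def formula_fractions(ph):
    """Independent arithmetic oracle for the bound-species fractions."""
    x = 10.0 ** (ph - 8.12)
    y = 10.0 ** (2 * ph - 16.56)
    t = 2.41 + 13.9 * x + 731.0 * y
    return 12.9 * x / t, 730.0 * y / t


class TestBoundSpeciesFractions:
    @pytest.mark.parametrize("ph", [7.23, 7.35, 8.13, 8.15, 9.12, 9.35, 11.60])
    def test_against_arithmetic_oracle(self, ph, high_pka):
        fr = bound_species_fractions(ph, DIST, high_pka)
        hb, b = formula_fractions(ph)
        assert fr.fs_hb == pytest.approx(hb, rel=1e-12)
        assert fr.fs_b == pytest.approx(b, rel=1e-12)

    def test_reference_row_at_ph_7_23(self, high_pka):
        fr = bound_species_fractions(7.23, DIST, high_pka)
        assert fr.fs_hb == pytest.approx(0.1661, abs=1e-4)
        assert fr.fs_b == pytest.approx(0.5794, abs=1e-4)

    def test_zero_ratios_bind_nothing(self, high_pka):
        fr = bound_species_fractions(7.0, MicelleDistribution(0, 0, 0), high_pka)
        assert fr.fs_h2b == fr.fs_hb == fr.fs_b == 0.0

    def test_bound_plus_free_fractions_sum_to_one(self, high_pka):
        for ph in np.linspace(5.0, 11.0, 13):
            fr = bound_species_fractions(ph, DIST, high_pka)
            x = 10.0 ** (ph - 8.12)
            y = 10.0 ** (2 * ph - 16.56)
            t = 2.41 + 13.9 * x + 731.0 * y
            free = (1 + x + y) / t
            assert fr.total_bound + free == pytest.approx(1.0, abs=1e-12)

    def test_dianion_rises_and_monoanion_eventually_falls(self, high_pka):
        grid = np.linspace(6.0, 11.5, 23)
        fs = [bound_species_fractions(ph, DIST, high_pka) for ph in grid]
        assert np.all(np.diff([f.fs_b for f in fs]) > 0)
        tail = [f.fs_hb for f in fs if f.fs_b > 0.5]
        assert np.all(np.diff(tail) < 0)


class TestApparentPka:
    @pytest.mark.parametrize(
        "pka_aq, ku, kd, expected",
        [
            (8.12, 1.41, 12.9, 7.16),
            (8.44, 12.9, 730.0, 6.69),
            (16.56, 1.41, 730.0, 13.85),
        ],
    )
    def test_reference_shifts(self, pka_aq, ku, kd, expected):
        assert apparent_pka(pka_aq, ku, kd) == pytest.approx(expected, abs=5e-3)

    def test_equal_uptake_leaves_pka_unshifted(self):
        assert apparent_pka(8.12, 5.0, 5.0) == 8.12

    def test_crossing_oracle(self, high_pka):
        # the pH where equal amounts are bound as HB- and B= is the
        # apparent second pKa
        f = lambda ph: (
            bound_species_fractions(ph, DIST, high_pka).fs_hb
            - bound_species_fractions(ph, DIST, high_pka).fs_b
        )
        crossing = brentq(f, 5.0, 9.0, xtol=1e-10)
        assert apparent_pka(8.44, DIST.k_hb, DIST.k_b) == pytest.approx(
            crossing, abs=1e-6
        )

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValidationError):
            apparent_pka(8.12, 0.0, 12.9)


class TestLogPartition:
    def test_acid_plateau(self):
        p = TcPartitionParams(log_po=2.5)
        assert log_partition(3.0, p) == pytest.approx(2.5, abs=1e-4)

    def test_half_step_at_first_apparent_pka(self):
        # 2*pH << B so the dianion term is negligible at pH = A
        p = TcPartitionParams(log_po=0.0, a=5.0, b=30.0)
        assert log_partition(5.0, p) == pytest.approx(-math.log10(2.0), abs=1e-6)

    def test_value_at_default_a(self):
        p = TcPartitionParams()
        expected = -math.log10(2.0 + 10.0 ** (2 * 7.36 - 14.08))
        assert log_partition(7.36, p) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_ph(self):
        p = TcPartitionParams()
        grid = np.linspace(4.0, 10.0, 25)
        vals = [log_partition(ph, p) for ph in grid]
        assert np.all(np.diff(vals) < 0)


class TestEllipticityModel:
    def test_linear_combination(self):
        m = EllipticityModel(a_star=-98.73, b_star=5.237)
        assert predict_tc_ellipticity(BoundSpeciesFractions(0, 0, 0), m) == 0.0
        assert predict_tc_ellipticity(BoundSpeciesFractions(0, 0, 1), m) == m.b_star
        val = predict_tc_ellipticity(BoundSpeciesFractions(0, 0.1661, 0.5790), m)
        assert val == pytest.approx(-13.36, abs=0.01)

    def test_fit_on_reference_table(self):
        df = load_reference_table()
        assert len(df) == 7
        fit = fit_ellipticity(list(zip(df["fs_hb"], df["fs_b"], df["theta_exp"])))
        assert fit.a_star == pytest.approx(-98.7, abs=0.05)
        assert fit.b_star == pytest.approx(5.24, abs=0.005)
        assert fit.sd == pytest.approx(1.1, abs=0.05)
        assert fit.r == pytest.approx(0.992, abs=5e-4)
        assert fit.stderr[0] == pytest.approx(5.6, abs=0.05)
        assert fit.stderr[1] == pytest.approx(0.54, abs=0.005)

    def test_noise_free_synthetic_recovery(self, high_pka):
        ds = gen_tc_dataset(-98.7, 5.24, np.linspace(6.5, 11.5, 7))
        pts = []
        for ph, theta in ds.rows():
            fr = bound_species_fractions(ph, DIST, high_pka)
            pts.append((fr.fs_hb, fr.fs_b, theta))
        fit = fit_ellipticity(pts)
        assert fit.a_star == pytest.approx(-98.7, rel=1e-10)
        assert fit.b_star == pytest.approx(5.24, rel=1e-10)
        assert fit.sd == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValidationError):
            fit_ellipticity([(0.1, 0.5, -5.0)])
        with pytest.raises(NumericalError):
            fit_ellipticity([(0.1, 0.5, -5.0)] * 3)  # single pH replicated


class TestScaleEllipticity:
    def test_concentration_rescaling(self):
        assert scale_ellipticity(-12.60, 4.6, 34.0) == pytest.approx(-93.1, abs=0.05)

    def test_identity_and_inverse(self):
        assert scale_ellipticity(5.0, 34.0, 34.0) == 5.0
        assert scale_ellipticity(
            scale_ellipticity(5.0, 4.6, 34.0), 34.0, 4.6
        ) == pytest.approx(5.0, rel=1e-12)

    def test_zero_reference_concentration_rejected(self):
        with pytest.raises(ValidationError):
            scale_ellipticity(5.0, 0.0, 34.0)
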
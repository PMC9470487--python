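"""Spectral IO, resampling and band-weighted optical properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from elytherm.spectra import (
    NIR,
    TOTAL,
    VIS,
    BandDefinition,
    Spectrum,
    SpectrumParseError,
    absorptivity_from_RT,
    band_energy_fraction,
    band_weighted_fraction,
    optics_to_frame,
    read_spectrum,
    resample_spectrum,
    summarize_optics,
)
from conftest import flat_spectrum, smooth_random_spectrum


def riemann_band_mean(I, F, X, band, step=1.0 / 64.0):
    """Independent fine-grid midpoint-Riemann oracle for ∫IFX/∫IF."""
    mids = np.arange(band.lo_nm + step / 2.0, band.hi_nm, step)
    iv = np.interp(mids, I.wavelengths_nm, I.values)
    fv = np.interp(mids, F.wavelengths_nm, F.values)
    xv = np.interp(mids, X.wavelengths_nm, X.values)
    return float(np.sum(iv * fv * xv) / np.sum(iv * fv))


# ---------------------------------------------------------------- IO


class TestReadSpectrum:
    def test_direct_read(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("400,10\n500,20\n")
        s = read_spectrum(p)
        assert len(s) == 2
        np.testing.assert_allclose(s.wavelengths_nm, [400, 500])
        np.testing.assert_allclose(s.values, [10, 20])

    def test_unsorted_rows_are_sorted(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("500,20\n400,10\n")
        s = read_spectrum(p)
        np.testing.assert_allclose(s.wavelengths_nm, [400, 500])
        np.testing.assert_allclose(s.values, [10, 20])

    def test_duplicate_wavelengths_collapsed_to_mean_with_flag(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("400,10\n400,30\n500,20\n")
        s = read_spectrum(p)
        np.testing.assert_allclose(s.wavelengths_nm, [400, 500])
        np.testing.assert_allclose(s.values, [20, 20])
        assert "duplicate_wavelengths_averaged" in s.qc_flags

    def test_header_and_delimiters(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("wavelength_nm\tvalue\n400\t10\n500\t20\n")
        s = read_spectrum(p)
        assert len(s) == 2

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(SpectrumParseError):
            read_spectrum(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("400,10\n500,oops\n")
        with pytest.raises(SpectrumParseError, match="line 2"):
            read_spectrum(p)

    def test_out_of_range_percent_is_flagged_not_clamped(self):
        s = Spectrum(np.array([400.0, 500.0]), np.array([105.0, 50.0]), kind="E")
        assert "values_outside_0_100" in s.qc_flags
        assert s.values[0] == 105.0


class TestResample:
    def test_identity_on_own_grid(self):
        s = Spectrum(np.array([400.0, 500.0, 600.0]), np.array([1.0, 5.0, 2.0]))
        out = resample_spectrum(s, s.wavelengths_nm)
        np.testing.assert_array_equal(out.values, s.values)

    def test_linear_midpoint(self):
        s = Spectrum(np.array([400.0, 500.0]), np.array([0.0, 100.0]))
        assert resample_spectrum(s, [450.0]).values[0] == pytest.approx(50.0)

    def test_no_extrapolation(self):
        s = Spectrum(np.array([400.0, 500.0]), np.array([0.0, 100.0]))
        with pytest.raises(ValueError, match="extrapolation"):
            resample_spectrum(s, [300.0, 450.0])


# ------------------------------------------- band-weighted fractions


class TestBandWeightedFraction:
    def test_weighted_mean_of_constant_is_the_constant(self):
        I = flat_spectrum(1.0, "I")
        F = flat_spectrum(100.0, "F")
        X = flat_spectrum(50.0, "E")
        for band in (VIS, NIR, TOTAL):
            assert band_weighted_fraction(I, F, X, band) == pytest.approx(50.0, abs=1e-12)

    def test_vis_share_of_flat_weight(self):
        """X = 100% on [400,700] falling to 0 by 701 nm, flat I and F: the
        TOTAL-band value is the VIS share of a flat 400-1700 weight
        (≈ 23.1%, with the 1-nm edge-ramp convention contributing half a
        nanometre); checked against the fine-grid oracle."""
        I = flat_spectrum(1.0, "I")
        F = flat_spectrum(100.0, "F")
        X = Spectrum(
            np.array([400.0, 700.0, 701.0, 1700.0]),
            np.array([100.0, 100.0, 0.0, 0.0]),
            kind="E",
        )
        got = band_weighted_fraction(I, F, X, TOTAL)
        assert got == pytest.approx(100.0 * 300.5 / 1300.0, abs=1e-9)
        assert got == pytest.approx(riemann_band_mean(I, F, X, TOTAL), abs=1e-6)

    def test_band_filter_restricts_the_weight(self):
        """With F an indicator of the NIR window, integrating over TOTAL
        equals integrating over NIR."""
        rng = np.random.default_rng(5)
        I = flat_spectrum(1.0, "I")
        # edge ramps kept inside [700, 1700] so the filter's support lies
        # entirely within the NIR band
        F_nir = Spectrum(
            np.array([350.0, 700.0, 701.0, 1699.0, 1700.0, 1750.0]),
            np.array([0.0, 0.0, 100.0, 100.0, 0.0, 0.0]),
            kind="F",
        )
        X = smooth_random_spectrum(rng)
        got_total = band_weighted_fraction(I, F_nir, X, TOTAL)
        got_nir = band_weighted_fraction(I, F_nir, X, NIR)
        assert got_total == pytest.approx(got_nir, abs=1e-9)

    def test_no_incident_energy_errors(self):
        I = flat_spectrum(0.0, "I")
        F = flat_spectrum(100.0, "F")
        X = flat_spectrum(50.0, "E")
        with pytest.raises(ValueError, match="no incident energy"):
            band_weighted_fraction(I, F, X, VIS)

    def test_oracle_equivalence_on_random_fixtures(self):
        """Implementation agrees with the independent fine-grid Riemann
        oracle to 1e-6 on 10 random smooth fixtures."""
        rng = np.random.default_rng(123)
        I = flat_spectrum(1.0, "I")
        for i in range(10):
            X = smooth_random_spectrum(rng)
            F = smooth_random_spectrum(rng, kind="F", base=60.0, amp=20.0)
            for band in (VIS, NIR, TOTAL):
                got = band_weighted_fraction(I, F, X, band)
                want = riemann_band_mean(I, F, X, band, step=1.0 / 64.0)
                assert got == pytest.approx(want, abs=1e-6), (i, band.name)

    def test_grid_refinement_convergence(self):
        """Halving the grid step moves any band value by < 0.01 pp."""
        rng = np.random.default_rng(7)
        I = flat_spectrum(1.0, "I")
        F = flat_spectrum(100.0, "F")
        for _ in range(5):
            X = smooth_random_spectrum(rng)
            for band in (VIS, NIR, TOTAL):
                v1 = band_weighted_fraction(I, F, X, band, step_nm=1.0)
                v2 = band_weighted_fraction(I, F, X, band, step_nm=0.5)
                assert abs(v1 - v2) < 0.01

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=hst.integers(0, 2**31 - 1))
    def test_weighted_mean_bounds(self, seed):
        """min X ≤ band value ≤ max X over the band, for random spectra."""
        rng = np.random.default_rng(seed)
        X = smooth_random_spectrum(rng)
        I = smooth_random_spectrum(rng, kind="I", base=40.0, amp=15.0)
        F = flat_spectrum(100.0, "F")
        for band in (VIS, NIR, TOTAL):
            v = band_weighted_fraction(I, F, X, band)
            in_band = (X.wavelengths_nm >= band.lo_nm) & (X.wavelengths_nm <= band.hi_nm)
            assert X.values[in_band].min() - 1e-9 <= v <= X.values[in_band].max() + 1e-9


class TestAbsorptivity:
    @pytest.mark.parametrize(
        "R,T,expected,flagged",
        [(20.0, 30.0, 50.0, False), (0.0, 0.0, 100.0, False), (60.0, 50.0, -10.0, True)],
    )
    def test_complement_and_flagging(self, R, T, expected, flagged):
        A, flags = absorptivity_from_RT(R, T)
        assert A == pytest.approx(expected)
        assert ("out_of_physical_range" in flags) == flagged

    def test_non_finite_errors(self):
        with pytest.raises(ValueError):
            absorptivity_from_RT(float("nan"), 10.0)


# ------------------------------------------------------- summaries


class TestSummarizeOptics:
    def test_constant_spectra(self):
        I = flat_spectrum(1.0, "I")
        F = {b.name: flat_spectrum(100.0, "F") for b in (VIS, NIR, TOTAL)}
        E = flat_spectrum(50.0, "E")
        S = flat_spectrum(10.0, "S")
        out = summarize_optics([("x", E, S)], I, F)
        assert len(out) == 3
        for s in out:
            assert s.reflectivity_R == pytest.approx(50.0, abs=1e-9)
            assert s.transmissivity_T == pytest.approx(10.0, abs=1e-9)
            assert s.absorptivity_A == pytest.approx(40.0, abs=1e-9)

    def test_energy_closure(self, cohort):
        out = summarize_optics(
            [(sid, *cohort.spectra[sid]) for sid in cohort.metadata.specimen_id],
            cohort.irradiance,
            cohort.filters,
        )
        for s in out:
            assert s.reflectivity_R + s.transmissivity_T + s.absorptivity_A == pytest.approx(
                100.0, abs=1e-9
            )

    def test_partition_mixture_identity(self):
        """With the same flat F everywhere, the TOTAL value is the
        ∫IF-weighted mean of the VIS and NIR values."""
        rng = np.random.default_rng(21)
        I = smooth_random_spectrum(rng, kind="I", base=40.0, amp=15.0)
        Fflat = flat_spectrum(100.0, "F")
        X = smooth_random_spectrum(rng)
        v_vis = band_weighted_fraction(I, Fflat, X, VIS)
        v_nir = band_weighted_fraction(I, Fflat, X, NIR)
        v_tot = band_weighted_fraction(I, Fflat, X, TOTAL)
        # flat F: trapezoid on the 1-nm grid is exact for the linear I
        grid_vis = np.arange(400.0, 700.5)
        grid_tot = np.arange(400.0, 1700.5)
        w = np.trapezoid(np.interp(grid_vis, I.wavelengths_nm, I.values), grid_vis) / np.trapezoid(
            np.interp(grid_tot, I.wavelengths_nm, I.values), grid_tot
        )
        assert v_tot == pytest.approx(w * v_vis + (1 - w) * v_nir, abs=1e-9)

    def test_metallic_family_is_nir_bright(self, cohort):
        """Broadband-metallic specimens reflect more in NIR than VIS and sit
        below the cohort's median absorptivity."""
        out = optics_to_frame(
            summarize_optics(
                [(sid, *cohort.spectra[sid]) for sid in cohort.metadata.specimen_id],
                cohort.irradiance,
                cohort.filters,
            )
        ).merge(cohort.metadata, on="specimen_id")
        tot = out[out.band == "TOTAL"]
        med = tot.absorptivity_A.median()
        metallic = out[out.family == "broadband_metallic"]
        for sid, grp in metallic.groupby("specimen_id"):
            r = grp.set_index("band").reflectivity_R
            assert r["NIR"] > r["VIS"]
            assert grp[grp.band == "TOTAL"].absorptivity_A.iloc[0] < med


def test_band_energy_fraction_flat_source():
    I = flat_spectrum(1.0, "I", lo=400.0, hi=1700.0)
    assert band_energy_fraction(I, VIS) == pytest.approx(100.0 * 300.0 / 1300.0, abs=1e-9)
    assert band_energy_fraction(I, VIS, denominator=VIS) == pytest.approx(100.0)
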
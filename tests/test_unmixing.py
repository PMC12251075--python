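"""Two-wavelength concentration recovery and its oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import flowspec as fs
from flowspec.errors import FlowSpecError

WLS = (424.0, 631.0)


def forward_intensities(dyes, conc, geometry):
    """Independent forward model through the scalar Beer-Lambert path."""
    return np.array(
        [
            fs.transmission(fs.absorbance(dyes, conc, geometry, wl))
            for wl in WLS
        ]
    )


class TestBuildCrossMatrix:
    def test_zero_cross_terms_give_diagonal(self, uncrossed_dyes, geometry):
        k = fs.build_cross_matrix(uncrossed_dyes, geometry, WLS)
        assert k.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert k.matrix[1, 0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diag(k.matrix) > 0)

    def test_identical_spectra_are_degenerate(self, geometry):
        spec = fs.make_dye_spectrum(500.0, 120.0, 0.01)
        d1 = fs.DyeDefinition("a", spec, 100.0)
        d2 = fs.DyeDefinition("b", spec, 100.0)
        with pytest.raises(FlowSpecError) as exc:
            fs.build_cross_matrix((d1, d2), geometry, WLS)
        assert exc.value.code == "degenerate_spectra"

    def test_entries_match_pointwise_spectrum_lookup(self, dyes, geometry):
        # Oracle: read eps straight off the stored spectrum arrays.
        k = fs.build_cross_matrix(dyes, geometry, WLS)
        for w, wl in enumerate(WLS):
            for d, dye in enumerate(dyes):
                grid = dye.spectrum.wavelengths
                eps = dye.spectrum.specific_absorptivity[grid == wl][0]
                assert k.matrix[w, d] == pytest.approx(
                    eps * geometry.path_length_mm, rel=1e-12
                )


class TestRecoverConcentrations:
    def test_blank_recovers_zero(self, dyes, geometry):
        k = fs.build_cross_matrix(dyes, geometry, WLS)
        np.testing.assert_allclose(
            fs.recover_concentrations([1.0, 1.0], k), [0.0, 0.0]
        )

    def test_round_trip_steady_state_mixture(self, dyes, geometry):
        # (C_TZ, C_EG) = (33.0, 4.17) ug/mL: the constant-flow steady-state
        # fractions (0.33, 0.167) times the stocks (100, 25).
        k = fs.build_cross_matrix(dyes, geometry, WLS)
        conc = np.array([33.0, 4.17])
        rec = fs.recover_concentrations(forward_intensities(dyes, conc, geometry), k)
        np.testing.assert_allclose(rec, conc, atol=1e-6)

    def test_matches_brute_force_grid_search(self, dyes, geometry):
        # Oracle: refined 2-D grid search over 0..C0 (2001 steps per axis)
        # minimizing the squared intensity residual; the closed-form solve
        # must agree within one grid step on random mixtures.
        from oracles import brute_force_unmix

        k = fs.build_cross_matrix(dyes, geometry, WLS)
        rng = np.random.default_rng(123)
        c_max = np.array([100.0, 25.0])  # (TZ, EG) stocks
        steps = c_max / 2000.0
        for _ in range(10):
            truth = rng.uniform([0, 0], c_max)
            i_meas = forward_intensities(dyes, truth, geometry)
            brute = brute_force_unmix(i_meas, k.matrix, c_max)
            solved = fs.recover_concentrations(i_meas, k)
            assert np.all(np.abs(solved - brute) <= steps + 1e-12)

    def test_zero_cross_equals_single_dye_calibration(self, uncrossed_dyes, geometry):
        # With a diagonal matrix, joint recovery must agree with inverting each
        # dye's own noiseless calibration curve.
        det = fs.DetectorConfig(relative_noise_sd=0.0)
        k = fs.build_cross_matrix(uncrossed_dyes, geometry, WLS)
        truth = np.array([41.0, 9.5])  # (TZ, EG)
        i_meas = forward_intensities(uncrossed_dyes, truth, geometry)
        joint = fs.recover_concentrations(i_meas, k)
        for j, dye in enumerate(uncrossed_dyes):
            pts = fs.generate_calibration_set(
                dye, np.linspace(0, dye.stock_concentration, 11), geometry, det
            )
            curve = fs.fit_calibration(pts, "single_exponential", dye_name=dye.name)
            assert curve.invert(float(i_meas[j])) == pytest.approx(joint[j], abs=1e-6)

    def test_noise_averaging_shrinks_error_as_sqrt_n(self, dyes, geometry):
        # Monte-Carlo: averaging n readouts shrinks recovery error ~ 1/sqrt(n).
        k = fs.build_cross_matrix(dyes, geometry, WLS)
        truth = np.array([30.0, 10.0])
        i_true = forward_intensities(dyes, truth, geometry)
        rng = np.random.default_rng(99)
        sd = 0.005

        def rms_error(n_avg, n_rep=400):
            errs = []
            for _ in range(n_rep):
                i_meas = np.mean(
                    i_true[None, :]
                    * (1 + sd * rng.standard_normal((n_avg, 2))),
                    axis=0,
                )
                rec = fs.recover_concentrations(
                    i_meas, k, stocks=[100.0, 25.0]
                )
                errs.append(rec - truth)
            return np.sqrt(np.mean(np.square(errs)))

        e1, e16 = rms_error(1), rms_error(16)
        assert e1 / e16 == pytest.approx(4.0, rel=0.25)

    @given(
        f_tz=st.floats(0.0, 1.0, allow_nan=False),
        f_eg=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_normalized_output_within_unit_interval(self, f_tz, f_eg):
        tz, eg = fs.default_dyes()
        geom = fs.FlowCellGeometry()
        k = fs.build_cross_matrix((tz, eg), geom, WLS)
        conc = np.array([f_tz * 100.0, f_eg * 25.0])
        rec = fs.recover_concentrations(forward_intensities((tz, eg), conc, geom), k)
        norm = rec / np.array([100.0, 25.0])
        assert np.all(norm >= 0.0) and np.all(norm <= 1.0 + 1e-9)

    def test_opaque_sample_rejected(self, dyes, geometry):
        k = fs.build_cross_matrix(dyes, geometry, WLS)
        with pytest.raises(FlowSpecError) as exc:
            fs.recover_concentrations([0.0, 0.5], k)
        assert exc.value.code == "opaque_sample"

    def test_inconsistent_intensities_rejected(self, dyes, geometry):
        # I631 too bright relative to I424 forces a large negative EG solution.
        k = fs.build_cross_matrix(dyes, geometry, WLS)
        conc = np.array([50.0, 10.0])
        i_meas = forward_intensities(dyes, conc, geometry)
        i_meas[1] *= 5.0
        with pytest.raises(FlowSpecError) as exc:
            fs.recover_concentrations(i_meas, k, stocks=[100.0, 25.0])
        assert exc.value.code == "inconsistent_intensities"

    def test_noise_allowance_widens_negative_floor(self, dyes, geometry):
        # A mildly over-unity blank reading (within 5 sigma of the detector
        # noise) is clipped to zero when the noise level is declared, but is a
        # violation under the strict stock-fraction floor alone.
        k = fs.build_cross_matrix(dyes, geometry, WLS)
        i_meas = np.array([1.0, 1.02])  # ~ -0.18 ug/mL EG, vs 0.125 strict floor
        with pytest.raises(FlowSpecError):
            fs.recover_concentrations(i_meas, k, stocks=[100.0, 25.0])
        rec = fs.recover_concentrations(
            i_meas, k, stocks=[100.0, 25.0], noise_sd=0.005
        )
        assert rec[1] == 0.0  # negative EG solution clipped
        assert rec[0] >= 0.0

    def test_vectorized_time_series(self, dyes, geometry):
        k = fs.build_cross_matrix(dyes, geometry, WLS)
        concs = np.array([[10.0, 5.0], [20.0, 2.0], [0.0, 0.0]]).T  # (2, T)
        i_series = np.stack(
            [forward_intensities(dyes, concs[:, t], geometry) for t in range(3)],
            axis=1,
        )
        rec = fs.recover_concentrations(i_series, k)
        np.testing.assert_allclose(rec, concs, atol=1e-9)
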
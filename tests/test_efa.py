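import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tangmorph as tm
from tangmorph.efa import coefficient_columns

from conftest import circle_points, ellipse_points, square_points


# ---------------------------------------------------------------------------
# Independent oracle: dense trapezoid-rule Fourier integration of the same
# arc-length-parametrized contour.  Kept deliberately naive.
# ---------------------------------------------------------------------------

def efa_trapezoid_oracle(points: np.ndarray, H: int, density: int = 400) -> np.ndarray:
    pts = np.vstack([points, points[:1]])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    T = t[-1]
    # dense grid including every polygon breakpoint, so the integrand is
    # smooth between grid nodes
    u = np.union1d(np.linspace(0.0, T, density * len(points) + 1), t)
    x = np.interp(u, t, pts[:, 0])
    y = np.interp(u, t, pts[:, 1])
    out = np.empty((H, 4))
    for n in range(1, H + 1):
        cos_u = np.cos(2 * np.pi * n * u / T)
        sin_u = np.sin(2 * np.pi * n * u / T)
        out[n - 1] = [
            (2.0 / T) * np.trapezoid(x * cos_u, u),
            (2.0 / T) * np.trapezoid(x * sin_u, u),
            (2.0 / T) * np.trapezoid(y * cos_u, u),
            (2.0 / T) * np.trapezoid(y * sin_u, u),
        ]
    return out


def random_star_polygon(rng, n_vertices=64):
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    angles += np.arange(n_vertices) * 1e-9  # guard against ties
    radii = rng.uniform(0.5, 1.5, n_vertices)
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])


# ---------------------------------------------------------------------------
# Forward transform
# ---------------------------------------------------------------------------

class TestForward:
    def test_circle_is_exactly_one_harmonic(self, circle_outline):
        coeffs = tm.efa_forward(circle_outline, H=8)
        np.testing.assert_allclose(
            coeffs.harmonics[0], [1.0, 0.0, 0.0, 1.0], atol=1e-4
        )
        assert np.abs(coeffs.harmonics[1:]).max() < 1e-9

    def test_ellipse_first_harmonic_dominates(self, ellipse_outline):
        """Arc-length traversal of an eccentric ellipse is not constant-speed,
        so a small tail of odd harmonics remains; the first harmonic still
        carries >99% of the power and all cross terms vanish."""
        coeffs = tm.efa_forward(ellipse_outline, H=11)
        a1, b1, c1, d1 = coeffs.harmonics[0]
        assert abs(b1) < 1e-9 and abs(c1) < 1e-9
        # frozen from the dense-integration oracle for the 2:1 ellipse
        assert a1 / d1 == pytest.approx(1.7040, abs=2e-3)
        sp = tm.spectrum(coeffs)
        assert sp.cumulative_fraction[0] > 0.99

    def test_square_matches_integration_oracle(self, square_outline):
        coeffs = tm.efa_forward(square_outline, H=8)
        oracle = efa_trapezoid_oracle(square_outline.points, 8)
        np.testing.assert_allclose(coeffs.harmonics, oracle, atol=1e-6)

    def test_random_polygons_match_integration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            pts = random_star_polygon(rng)
            coeffs = tm.efa_forward(tm.Outline("p", pts), H=11)
            oracle = efa_trapezoid_oracle(pts, 11)
            np.testing.assert_allclose(coeffs.harmonics, oracle, atol=1e-6)

    def test_offsets_equal_arc_length_centroid(self):
        pts = circle_points(256, r=1.0, center=(3.0, -2.0))
        coeffs = tm.efa_forward(tm.Outline("c", pts), H=3)
        assert coeffs.A0 == pytest.approx(3.0, abs=1e-6)
        assert coeffs.C0 == pytest.approx(-2.0, abs=1e-6)

    def test_harmonic_count_out_of_range(self, circle_outline):
        with pytest.raises(tm.ParameterError):
            tm.efa_forward(circle_outline, H=0)
        with pytest.raises(tm.ParameterError):
            tm.efa_forward(circle_outline, H=256)


# ---------------------------------------------------------------------------
# Inverse transform
# ---------------------------------------------------------------------------

class TestInverse:
    def test_circle_round_trip_pointwise(self, circle_outline):
        coeffs = tm.efa_forward(circle_outline, H=1)
        rec = tm.inverse_efa(coeffs, n_points=512)
        radii = np.hypot(rec.points[:, 0], rec.points[:, 1])
        np.testing.assert_allclose(radii, 1.0, atol=1e-4)

    def test_forward_of_inverse_preserves_the_shape(self):
        """forward∘inverse re-parametrizes by arc length, so coefficients of
        a non-constant-speed curve shift; the synthesized *geometry* must
        nevertheless be preserved."""
        from scipy.spatial import cKDTree

        rng = np.random.default_rng(3)
        harmonics = np.zeros((6, 4))
        harmonics[0] = [1.0, 0.0, 0.0, 1.0]
        harmonics[1:] = 1e-3 * rng.normal(size=(5, 4))
        coeffs = tm.EFACoefficients("c", 0.0, 0.0, harmonics)
        first = tm.inverse_efa(coeffs, n_points=4096)
        again = tm.inverse_efa(tm.efa_forward(first, H=6), n_points=4096)
        d, _ = cKDTree(first.points).query(again.points)
        assert d.max() < 1e-3

    def test_square_reconstruction_error_decreases_with_harmonics(self, square_outline):
        def rms_error(H):
            coeffs = tm.efa_forward(square_outline, H=H)
            rec = tm.inverse_efa(coeffs, n_points=2048)
            # nearest-vertex distance from reconstruction to the square
            d = np.abs(
                np.maximum(np.abs(rec.points[:, 0] - 0.5), np.abs(rec.points[:, 1] - 0.5))
                - 0.5
            )
            return np.sqrt(np.mean(d**2))

        errors = [rms_error(H) for H in (1, 3, 11, 25)]
        assert all(e1 > e2 for e1, e2 in zip(errors, errors[1:]))


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

class TestStandardize:
    @pytest.mark.parametrize("angle", [0.0, 0.5, -1.2])
    @pytest.mark.parametrize("scale", [1.0, 0.37, 12.0])
    def test_similarity_invariance(self, angle, scale):
        tool = tm.generate_tool(tm.ToolTruth(specimen_id="t", asymmetry=0.15, seed=5))
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = tm.Outline("t", scale * tool.points @ rot.T + np.array([7.0, -3.0]))
        ref = tm.standardized_coefficients(tool)
        got = tm.standardized_coefficients(moved)
        np.testing.assert_allclose(got.harmonics, ref.harmonics, atol=1e-6)

    def test_standardized_area_is_one(self, ellipse_outline):
        coeffs = tm.standardized_coefficients(ellipse_outline)
        rec = tm.inverse_efa(coeffs, n_points=2048)
        assert abs(rec.signed_area()) == pytest.approx(1.0, abs=1e-3)

    def test_circle_radius_after_standardization(self):
        pts = circle_points(512, r=2.0)
        coeffs = tm.standardized_coefficients(tm.Outline("c", pts))
        rec = tm.inverse_efa(coeffs, n_points=512)
        radii = np.hypot(rec.points[:, 0], rec.points[:, 1])
        np.testing.assert_allclose(radii, 1 / np.sqrt(np.pi), atol=1e-3)

    def test_elongation_retained_not_rohlf_rescaled(self, ellipse_outline):
        raw = tm.efa_forward(ellipse_outline, H=11)
        std = tm.standardize(raw, tm.measure_geometry(ellipse_outline).area)
        a1, _, _, d1 = std.harmonics[0]
        # ratio of the first-harmonic semi-axes survives standardization
        assert a1 / d1 == pytest.approx(raw.harmonics[0, 0] / raw.harmonics[0, 3], abs=1e-9)
        assert a1 / d1 > 1.5

    def test_circle_rotation_skipped_with_warning(self, circle_outline):
        raw = tm.efa_forward(circle_outline, H=5)
        with pytest.warns(UserWarning, match="circle"):
            std = tm.standardize(raw, tm.measure_geometry(circle_outline).area)
        assert std.normalization_state == tm.efa.FULL_NORMALIZATION

    def test_symmetric_outline_has_zero_cross_terms(self):
        tool = tm.generate_tool(
            tm.ToolTruth(specimen_id="s", asymmetry=0.0, noise_sd=0.0, seed=1)
        )
        std = tm.standardized_coefficients(tool)
        assert np.abs(std.harmonics[:, [1, 2]]).max() < 1e-6

    def test_mirroring_negates_cross_terms(self):
        tool = tm.generate_tool(tm.ToolTruth(specimen_id="a", asymmetry=0.25, seed=9))
        mirrored = tm.orient(
            tm.Outline("a", tool.points * np.array([1.0, -1.0])), "left"
        )
        ref = tm.standardized_coefficients(tool)
        got = tm.standardized_coefficients(mirrored)
        np.testing.assert_allclose(got.harmonics[:, [0, 3]], ref.harmonics[:, [0, 3]], atol=1e-6)
        np.testing.assert_allclose(got.harmonics[:, [1, 2]], -ref.harmonics[:, [1, 2]], atol=1e-6)

    def test_total_power_invariant_under_rotation_standardization(self):
        tool = tm.generate_tool(tm.ToolTruth(specimen_id="t", asymmetry=0.2, seed=4))
        raw = tm.efa_forward(tool, H=11)
        area = tm.measure_geometry(tool).area
        scaled_only = tm.EFACoefficients(
            "t", 0.0, 0.0, raw.harmonics / np.sqrt(area),
            normalization_state={"translated", "area_scaled"},
        )
        std = tm.standardize(raw, area)
        assert tm.spectrum(std).power.sum() == pytest.approx(
            tm.spectrum(scaled_only).power.sum(), rel=1e-9
        )

    def test_nonpositive_area_rejected(self, ellipse_outline):
        raw = tm.efa_forward(ellipse_outline, H=3)
        with pytest.raises(tm.ParameterError):
            tm.standardize(raw, 0.0)


# ---------------------------------------------------------------------------
# Spectrum and truncation
# ---------------------------------------------------------------------------

class TestSpectrum:
    def test_single_harmonic_power(self):
        coeffs = tm.EFACoefficients("x", 0.0, 0.0, np.array([[1.0, 0.0, 0.0, 1.0]]))
        sp = tm.spectrum(coeffs)
        assert sp.power[0] == pytest.approx(1.0)
        np.testing.assert_allclose(sp.cumulative_fraction, [1.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_cumulative_fraction_monotone_ending_at_one(self, seed):
        rng = np.random.default_rng(seed)
        coeffs = tm.EFACoefficients("r", 0.0, 0.0, rng.normal(size=(11, 4)))
        sp = tm.spectrum(coeffs)
        assert np.all(np.diff(sp.cumulative_fraction) >= -1e-15)
        assert sp.cumulative_fraction[-1] == pytest.approx(1.0, abs=1e-12)

    def test_zero_coefficients_rejected(self):
        coeffs = tm.EFACoefficients("z", 0.0, 0.0, np.zeros((3, 4)))
        with pytest.raises(tm.ParameterError):
            tm.spectrum(coeffs)

    def test_ellipses_need_one_harmonic(self):
        spectra = [
            tm.spectrum(tm.efa_forward(tm.Outline("e", ellipse_points(256, a, 1.0)), H=11))
            for a in (1.2, 1.5)
        ]
        assert tm.choose_harmonics(spectra, threshold=0.99) == 1

    def test_square_requirement_matches_brute_force_scan(self, square_outline, ellipse_outline):
        sq = tm.spectrum(tm.efa_forward(square_outline, H=11))
        ell = tm.spectrum(tm.efa_forward(ellipse_outline, H=11))
        brute = next(
            h + 1 for h in range(11) if sq.cumulative_fraction[h] >= 0.95
        )
        assert tm.choose_harmonics([ell, sq], threshold=0.95) == brute

    def test_unreachable_threshold_reports_error(self, square_outline):
        # spectrum computed well beyond the cap so the corner tail is visible
        sq = tm.spectrum(tm.efa_forward(square_outline, H=31))
        with pytest.raises(tm.ParameterError, match="unreachable"):
            tm.choose_harmonics([sq], threshold=0.9999999, max_h=11)


# ---------------------------------------------------------------------------
# Coefficient matrices and round trip
# ---------------------------------------------------------------------------

class TestCoefficientMatrix:
    def test_three_specimens_give_3x44(self, small_assemblage):
        outlines, _, _ = small_assemblage
        coeffs = [tm.standardized_coefficients(o, H=11) for o in outlines[:3]]
        matrix = tm.coefficient_matrix(coeffs)
        assert matrix.shape == (3, 44)
        assert list(matrix.columns) == coefficient_columns(11)

    def test_mixed_harmonic_count_rejected(self, ellipse_outline, square_outline):
        c1 = tm.standardized_coefficients(ellipse_outline, H=8)
        c2 = tm.standardized_coefficients(square_outline, H=11)
        with pytest.raises(tm.NormalizationError, match="harmonic"):
            tm.coefficient_matrix([c1, c2])

    def test_mixed_normalization_rejected(self, ellipse_outline):
        raw = tm.efa_forward(ellipse_outline, H=8)
        std = tm.standardized_coefficients(ellipse_outline, H=8)
        with pytest.raises(tm.NormalizationError, match="normalization"):
            tm.coefficient_matrix([raw, std])

    def test_single_specimen_matrix(self, ellipse_outline):
        matrix = tm.coefficient_matrix([tm.standardized_coefficients(ellipse_outline, H=5)])
        assert matrix.shape == (1, 20)

    def test_write_read_bit_exact(self, tmp_path, small_assemblage):
        outlines, _, _ = small_assemblage
        coeffs = [tm.standardized_coefficients(o) for o in outlines[:4]]
        path = tmp_path / "coeffs.csv"
        tm.write_coefficients(coeffs, path)
        back = tm.read_coefficients(path)
        for orig, rt in zip(coeffs, back):
            assert rt.specimen_id == orig.specimen_id
            assert rt.normalization_state == orig.normalization_state
            assert np.array_equal(rt.harmonics, orig.harmonics)
            assert rt.A0 == orig.A0 and rt.C0 == orig.C0
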
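"""Line-profile extraction, smoothing, edge detection and depth discretization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import stainkinetics as sk
from stainkinetics.profiles import (
    EdgeNotFoundError,
    EdgeUnresolvedError,
    ProfileTooShortError,
)

from conftest import true_boundary_offset_mm

VOXEL = 11.0


def make_image(pixels):
    return sk.SliceImage(pixels=np.asarray(pixels, float), voxel_size=VOXEL, time=0.0)


def make_profile(intensities, step_mm=VOXEL / 1000.0):
    vals = np.asarray(intensities, float)
    return sk.LineProfile(
        positions=np.arange(len(vals)) * step_mm, intensities=vals, width_px=1
    )


class TestExtractLineProfile:
    def test_uniform_image_gives_constant_profile(self):
        img = make_image(np.full((40, 60), 7.5))
        prof = sk.extract_line_profile(img, (3, 20), (55, 20), width_px=5)
        assert np.all(prof.intensities == 7.5)
        assert prof.step == pytest.approx(VOXEL / 1000.0)

    def test_width_one_equals_nearest_pixel_sampling(self):
        rng = np.random.default_rng(0)
        img = make_image(rng.uniform(0, 100, size=(30, 50)))
        prof = sk.extract_line_profile(img, (2, 11), (42, 11), width_px=1)
        assert np.array_equal(prof.intensities, img.pixels[11, 2:43])

    def test_column_gradient_matches_brute_force_band_average(self):
        # intensity = column index; for a horizontal ray each sample's band
        # lies in a single column, so the profile equals the column indices
        ny, nx = 21, 80
        img = make_image(np.tile(np.arange(nx, dtype=float), (ny, 1)))
        prof = sk.extract_line_profile(img, (5, 10), (70, 10), width_px=5)
        # independent oracle: enumerate the 5 pixels perpendicular to the ray
        for k, value in enumerate(prof.intensities):
            xs, ys = 5 + k, 10
            band = [img.pixels[ys + j, xs] for j in (-2, -1, 0, 1, 2)]
            assert value == pytest.approx(np.mean(band))
            assert value == pytest.approx(5 + k)

    def test_ray_leaving_image_bounds_rejected(self):
        img = make_image(np.zeros((20, 20)))
        with pytest.raises(ValueError, match="bounds"):
            sk.extract_line_profile(img, (1, 10), (30, 10))
        with pytest.raises(ValueError, match="bounds"):
            sk.extract_line_profile(img, (1, 1), (18, 1), width_px=5)

    def test_zero_length_and_even_width_rejected(self):
        img = make_image(np.zeros((20, 20)))
        with pytest.raises(ValueError, match="zero-length"):
            sk.extract_line_profile(img, (5, 5), (5, 5))
        with pytest.raises(ValueError, match="odd"):
            sk.extract_line_profile(img, (1, 5), (15, 5), width_px=4)


class TestGaussianSmooth:
    def test_constant_profile_is_fixed_point(self):
        prof = make_profile(np.full(100, 42.0))
        out = sk.gaussian_smooth(prof, sigma_px=3.0)
        assert np.allclose(out.intensities, 42.0, atol=1e-12)

    def test_impulse_response_is_normalized_kernel(self):
        n = 201
        vals = np.zeros(n)
        vals[100] = 1.0
        out = sk.gaussian_smooth(make_profile(vals), sigma_px=2.0)
        # normalized Gaussian truncated at +-4 sigma, centred on the impulse
        k = np.arange(n) - 100
        kernel = np.where(np.abs(k) <= 8, np.exp(-(k**2) / (2 * 2.0**2)), 0.0)
        kernel /= kernel.sum()
        assert np.allclose(out.intensities[92:109], kernel[92:109], atol=1e-12)
        assert out.intensities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_reflect_padding_conserves_mean(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1000, size=300)
        out = sk.gaussian_smooth(make_profile(vals), sigma_px=4.0)
        # direct summation oracle for the mean
        assert out.intensities.mean() == pytest.approx(vals.sum() / len(vals), abs=1e-9)

    def test_invalid_sigma_or_short_profile_rejected(self):
        prof = make_profile(np.arange(50.0))
        with pytest.raises(ValueError):
            sk.gaussian_smooth(prof, sigma_px=0.0)
        with pytest.raises(ValueError, match="kernel support"):
            sk.gaussian_smooth(make_profile(np.arange(5.0)), sigma_px=10.0)


def brute_force_edge(values, sigma_px, drop_fraction):
    """Independent re-statement of the three rules via direct summation."""
    n = len(values)
    radius = int(4 * sigma_px)
    k = np.arange(-radius, radius + 1)
    kernel = np.exp(-(k**2) / (2 * sigma_px**2))
    kernel /= kernel.sum()
    # half-sample symmetric reflection, matching the smoother's boundary rule
    padded = np.concatenate([values[:radius][::-1], values, values[-radius:][::-1]])
    sm = np.array([padded[i : i + 2 * radius + 1] @ kernel for i in range(n)])
    g = sm[1:] - sm[:-1]
    imax = int(np.argmax(g))
    assert g[imax] > 0
    for j in range(imax + 1, len(g)):
        if g[j] <= drop_fraction * g[imax]:
            return j
    raise AssertionError("unresolved")


class TestDetectEpicardialEdge:
    def test_flat_profile_has_no_edge(self):
        with pytest.raises(EdgeNotFoundError):
            sk.detect_epicardial_edge(make_profile(np.full(200, 5.0)))

    def test_decreasing_profile_has_no_edge(self):
        with pytest.raises(EdgeNotFoundError):
            sk.detect_epicardial_edge(make_profile(np.linspace(100, 0, 200)))

    def test_monotone_ramp_never_dropping_is_unresolved(self):
        # gradient is constant: it never falls below drop_fraction * max
        with pytest.raises(EdgeUnresolvedError):
            sk.detect_epicardial_edge(make_profile(np.linspace(0, 100, 200)), sigma_px=1.0)

    @pytest.mark.parametrize("sigma_px,drop", [(1.0, 0.25), (2.0, 0.1), (3.0, 0.5)])
    def test_logistic_ramp_matches_brute_force_rules(self, sigma_px, drop):
        x = np.arange(300, dtype=float)
        vals = 100.0 + 900.0 / (1 + np.exp(-(x - 150) / 4.0))
        result = sk.detect_epicardial_edge(make_profile(vals), sigma_px, drop)
        expected = brute_force_edge(vals, sigma_px, drop)
        assert abs(result.edge_index - expected) <= 2
        assert result.edge_index >= result.max_gradient_index

    def test_phantom_ray_edge_within_two_voxels_of_truth(
        self, noiseless_config, noiseless_stack, centre_ray
    ):
        cfg = noiseless_config
        start, end = centre_ray
        prof = sk.extract_line_profile(noiseless_stack[-1], start, end)
        edge = sk.detect_epicardial_edge(prof)
        true_mm = true_boundary_offset_mm(cfg, noiseless_stack[-1])
        assert abs(edge.edge_position - true_mm) <= 2 * cfg.voxel_mm

    def test_translation_equivariance(self):
        x = np.arange(400, dtype=float)
        vals = 50.0 + 500.0 / (1 + np.exp(-(x - 120) / 3.0))
        base = sk.detect_epicardial_edge(make_profile(vals))
        for shift in (7, 31):
            shifted = sk.detect_epicardial_edge(make_profile(np.concatenate([np.full(shift, vals[0]), vals[:-shift]])))
            assert shifted.edge_index == base.edge_index + shift

    @given(a=st.floats(0.1, 50), b=st.floats(-1000, 1000))
    def test_affine_intensity_invariance(self, a, b):
        # off-sample ramp centre avoids an exact two-way tie at the
        # gradient maximum, which rounding could break either way
        x = np.arange(300, dtype=float)
        vals = 100.0 + 900.0 / (1 + np.exp(-(x - 140.3) / 5.0))
        base = sk.detect_epicardial_edge(make_profile(vals))
        scaled = sk.detect_epicardial_edge(make_profile(a * vals + b))
        assert scaled.edge_index == base.edge_index
        assert scaled.max_gradient_index == base.max_gradient_index

    def test_noisy_phantom_rays_mostly_within_three_voxels(self, small_edge_config):
        # 2 % of the dynamic range as additive noise, 100 distinct seeds
        import dataclasses

        p = sk.ExactModelParams()
        dynamic = p.Imax_surface - small_edge_config.background_level
        hits = 0
        for seed in range(100):
            cfg = dataclasses.replace(
                small_edge_config, noise_sd=0.02 * dynamic, seed=seed
            )
            img = sk.render_slice(
                cfg, sk.phantom.exact_intensity_field(p, 58.0), 58.0, t_index=0
            )
            ny, nx = img.pixels.shape
            cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
            prof = sk.extract_line_profile(img, (0.0, cy), (cx, cy))
            edge = sk.detect_epicardial_edge(prof)
            true_mm = cx * cfg.voxel_mm - cfg.outer_radius
            if abs(edge.edge_position - true_mm) <= 3 * cfg.voxel_mm:
                hits += 1
        assert hits >= 95


class TestDiscretizeProfile:
    def _edge_at(self, prof, index):
        sm = sk.gaussian_smooth(prof, 1.0)
        return sk.EdgeResult(
            edge_index=index,
            edge_position=float(prof.positions[index]),
            max_gradient_index=index,
            smoothed=sm,
        )

    def test_constant_profile_gives_constant_segments(self):
        prof = make_profile(np.full(250, 3.25))
        segs = sk.discretize_profile(prof, self._edge_at(prof, 10))
        assert len(segs) == 20
        assert all(s.mean_intensity == pytest.approx(3.25) for s in segs)
        assert [s.depth for s in segs] == pytest.approx(np.arange(20) * 0.1)

    def test_linear_profile_matches_enumeration_oracle(self):
        step = VOXEL / 1000.0
        positions = np.arange(260) * step
        slope = 123.0
        prof = make_profile(slope * positions)
        edge = self._edge_at(prof, 15)
        segs = sk.discretize_profile(prof, edge)
        for k, seg in enumerate(segs):
            members = [
                slope * p
                for p in positions
                if k * 0.1 <= p - edge.edge_position < (k + 1) * 0.1
            ]
            assert seg.n_samples == len(members)
            assert seg.mean_intensity == pytest.approx(np.mean(members), rel=1e-12)

    def test_mass_conservation(self):
        rng = np.random.default_rng(2)
        prof = make_profile(rng.uniform(0, 1e4, size=300))
        edge = self._edge_at(prof, 7)
        segs = sk.discretize_profile(prof, edge)
        weighted = sum(s.mean_intensity * s.n_samples for s in segs) / sum(
            s.n_samples for s in segs
        )
        depth = prof.positions - edge.edge_position
        boundaries = np.arange(21) * 0.1
        covered = prof.intensities[(depth >= boundaries[0]) & (depth < boundaries[20])]
        assert weighted == pytest.approx(covered.mean(), rel=1e-12)

    def test_short_profile_error_reports_required_length(self):
        prof = make_profile(np.zeros(150))  # 1.65 mm long
        edge = self._edge_at(prof, 10)
        with pytest.raises(ProfileTooShortError, match="2.000 mm required"):
            sk.discretize_profile(prof, edge)
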
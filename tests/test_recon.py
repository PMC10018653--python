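"""FDK building blocks and 3D/4D reconstructions."""

import dataclasses
import math

import numpy as np
import pytest

import cbct4d as c
from cbct4d.recon import (angular_spacing, backproject, fdk3d, fdk4d,
                          max_angular_gap, preweight, ramp_filter, ramp_kernel,
                          short_scan_weights)
from cbct4d.projector import ProjectionSet, scan_schedule

SOFT = 0.02


def _small_geo(arc=200.0):
    return c.ScanGeometry(detector_cols=64, detector_rows=48,
                          pixel_pitch=6.0, arc_deg=arc)


def _cylinder(grid, mu=SOFT, radius=90.0):
    X, Y, Z = grid.meshgrid()
    vals = (mu * (X ** 2 + Y ** 2 <= radius ** 2)).astype(np.float32)
    return c.Volume(vals, grid.spacing, grid.origin)


def _scan(vol, geo, n_proj):
    protocol = c.Protocol("t", n_proj, 10.0, 16.1)
    v4 = c.Volume4D([vol] * 10, [k / 10 for k in range(10)])
    return c.simulate_scan(v4, geo, protocol)


class TestPreweight:
    def test_closed_form(self, geometry):
        ones = np.ones((geometry.detector_rows, geometry.detector_cols))
        w = preweight(ones, geometry)
        centre = w[geometry.detector_rows // 2 - 1,
                   geometry.detector_cols // 2 - 1]
        assert centre == pytest.approx(1.0, abs=1e-4)
        # weight at u = sdd (synthetic wide detector) is 1/sqrt(2)
        wide = c.ScanGeometry(detector_cols=3, detector_rows=1,
                              pixel_pitch=c.ScanGeometry().sdd, arc_deg=200)
        w = preweight(np.ones((1, 3)), wide)
        assert w[0, 0] == pytest.approx(1 / math.sqrt(2))
        assert w[0, 1] == 1.0

    def test_monotone_in_u(self, geometry):
        w = preweight(np.ones((geometry.detector_rows,
                               geometry.detector_cols)), geometry)
        row = w[geometry.detector_rows // 2]
        half = row[geometry.detector_cols // 2:]
        assert np.all(np.diff(half) <= 0)


class TestShortScanWeights:
    def test_conjugate_rays_sum_to_one(self, geometry):
        angles = np.linspace(0, 200, 2001)
        W = short_scan_weights(angles, geometry, 200.0, 0.0)
        u = (np.arange(geometry.detector_cols)
             - (geometry.detector_cols - 1) / 2) * geometry.pixel_pitch
        gamma = np.arctan(u / geometry.sdd)
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(3000):
            i = rng.integers(len(angles))
            j = rng.integers(len(u))
            b2 = angles[i] + 180.0 - 2.0 * math.degrees(gamma[j])
            if not 0.0 <= b2 <= 200.0:
                continue
            i2 = int(np.argmin(np.abs(angles - b2)))
            s = W[i, j] + W[i2, len(u) - 1 - j]
            assert s == pytest.approx(1.0, abs=0.05)
            checked += 1
        assert checked > 100

    def test_full_circle_weight_half(self, geometry):
        W = short_scan_weights(np.linspace(0, 360, 100), geometry, 360.0, 0.0)
        assert np.all(W == 0.5)

    def test_insufficient_arc_rejected(self, geometry):
        with pytest.raises(ValueError, match="insufficient"):
            short_scan_weights(np.linspace(0, 190, 10), geometry, 190.0, 0.0)


class TestRampFilter:
    def test_kernel_closed_form(self):
        du = 2.0
        h = ramp_kernel(8, du)
        m = len(h) // 2
        assert h[m] == pytest.approx(1.0 / (4 * du ** 2))
        assert h[m + 2] == 0.0 and h[m + 4] == 0.0
        for n in (1, 3):
            assert h[m + n] == pytest.approx(-1.0 / (math.pi * n * du) ** 2)
            assert h[m - n] == h[m + n]

    def test_constant_row_killed(self):
        # the truncated band-limited kernel leaves a ~0.3% DC residue
        row = np.full((1, 128), 3.7)
        out = ramp_filter(row, 1.0)
        assert np.all(np.abs(out[0, 20:-20]) < 5e-3 * np.abs(row).max())
        assert np.abs(out[0, 20:-20]).max() < 0.05 * np.abs(out).max()

    def test_impulse_returns_kernel(self):
        n = 64
        row = np.zeros((1, n))
        row[0, n // 2] = 1.0
        du = 1.5
        out = ramp_filter(row, du)
        taps = ramp_kernel(2 * n, du)
        m = len(taps) // 2
        expect = du * taps[m - n // 2: m + n - n // 2]
        np.testing.assert_allclose(out[0], expect, atol=1e-10)

    def test_centered_sphere_projection_symmetric(self, geometry):
        g = c.GridSpec.centered((41, 41, 41), (4.0,) * 3)
        X, Y, Z = g.meshgrid()
        vol = c.Volume((SOFT * (X**2 + Y**2 + Z**2 <= 70**2)).astype(np.float32),
                       g.spacing, g.origin)
        proj = c.forward_project(vol, geometry, 0.0)
        filt = ramp_filter(proj, geometry.pixel_pitch)
        mid = filt[geometry.detector_rows // 2 - 1]
        np.testing.assert_allclose(mid, mid[::-1], atol=1e-6 * np.abs(mid).max())


class TestBackproject:
    def test_no_projections_rejected(self, grid, geometry):
        with pytest.raises(ValueError):
            backproject(np.empty((0, 10, 10)), np.array([]), geometry, grid)

    def test_zero_projections_give_zero_volume(self, grid, geometry):
        filt = np.zeros((3, geometry.detector_rows, geometry.detector_cols))
        out = backproject(filt, np.array([0.0, 90.0, 180.0]), geometry, grid)
        assert not np.any(out.values)

    def test_single_projection_distance_weighting(self, geometry):
        """Uniform filtered image backprojects as (sid/U)^2 along the axis."""
        grid = c.GridSpec.centered((41, 41, 1), (4.0, 4.0, 4.0))
        filt = np.ones((1, geometry.detector_rows, geometry.detector_cols))
        out = backproject(filt, np.array([0.0]), geometry, grid)
        # angle 0: source at (+sid, 0, 0); U = sid - x
        xs = grid.axis_coords(0)
        expect = (geometry.sid / (geometry.sid - xs)) ** 2
        profile = out.values[:, 20, 0]
        np.testing.assert_allclose(profile, expect, rtol=1e-3)


class TestFdk3d:
    def test_static_phantom_roi_accuracy(self, static_bundle, rois, grid):
        rec = fdk3d(static_bundle["rapid"], grid)
        fg = rois.cnr_foreground.extract(rec.values).mean()
        assert fg == pytest.approx(SOFT, rel=0.05)

    def test_short_scan_matches_full_scan(self):
        geo200 = _small_geo(200.0)
        geo360 = _small_geo(360.0)
        grid = c.GridSpec.centered((40, 40, 8), (6.0,) * 3)
        vol = _cylinder(grid)
        r200 = fdk3d(_scan(vol, geo200, 180), grid)
        r360 = fdk3d(_scan(vol, geo360, 180), grid)
        ctr = (slice(17, 23), slice(17, 23), slice(3, 5))
        assert r200.values[ctr].mean() == pytest.approx(
            r360.values[ctr].mean(), rel=0.03
        )

    def test_rmse_decreases_with_projection_count(self):
        """View-sampling error shrinks with projection count until the
        deterministic discretization floor; no stochastic bumps."""
        geo = _small_geo()
        grid = c.GridSpec.centered((40, 40, 8), (6.0,) * 3)
        vol = _cylinder(grid)
        inner = (slice(8, 32), slice(8, 32), slice(2, 6))
        errs = []
        for n in (60, 120, 240, 480):
            rec = fdk3d(_scan(vol, geo, n), grid)
            errs.append(np.sqrt(np.mean(
                (rec.values[inner] - vol.values[inner]) ** 2)))
        for hi, lo in zip(errs, errs[1:]):
            assert lo <= hi * 1.005  # decreasing, ties only at the floor
        assert errs[-1] < errs[0]

    def test_linearity_in_projection_data(self):
        geo = _small_geo()
        grid = c.GridSpec.centered((24, 24, 6), (8.0,) * 3)
        vol = _cylinder(grid, radius=60.0)
        pset = _scan(vol, geo, 40)
        doubled = ProjectionSet(
            pset.images * 2.0, pset.angles_deg, pset.timestamps_s,
            pset.phase_fractions, pset.phase_bins, pset.geometry,
            pset.protocol, pset.n_phases,
        )
        r1 = fdk3d(pset, grid)
        r2 = fdk3d(doubled, grid)
        np.testing.assert_allclose(r2.values, 2.0 * r1.values, atol=1e-6)

    def test_moving_tumor_smears_in_3dfdk(self, moving_bundle, grid, phantom):
        """SI extent of the tumor in 3DFDK >= its extent in a single phase."""
        rec = fdk3d(moving_bundle["rapid"], grid)
        gt0 = moving_bundle["gt4d"][0]
        thresh = 0.5 * (phantom.config.mu_tumor + phantom.config.mu_lung)
        cx, cy, cz = np.round(
            grid.world_to_index(phantom.config.tumor_center)).astype(int)
        win = (slice(cx - 2, cx + 3), slice(cy - 2, cy + 3),
               slice(cz - 8, cz + 9))
        z_rec = np.nonzero((rec.values[win] > thresh).any(axis=(0, 1)))[0]
        z_gt = np.nonzero((gt0.values[win] > thresh).any(axis=(0, 1)))[0]
        assert len(z_rec) >= len(z_gt) > 0


class TestFdk4d:
    def test_zero_motion_phases_statistically_identical(self, static_phantom):
        """With no motion and evenly interleaved bins, every phase volume
        reconstructs the same anatomy from an equivalent angle set."""
        geo = c.pipeline.small_geometry()
        grid = c.pipeline.small_grid()
        g4 = c.generate_4dct(static_phantom, grid)
        T = 60.0 / 16.5
        pset = c.simulate_scan(g4, geo, c.Protocol("sync", 600, 60 * T, 16.5))
        assert pset.bin_counts().tolist() == [60] * 10
        v4 = fdk4d(pset, grid)
        base = v4[0].values.astype(np.float64)
        for v in v4.phases[1:]:
            rms = np.sqrt(np.mean((v.values - base) ** 2))
            assert rms < 0.05 * SOFT

    def test_phase_mean_matches_fdk3d_without_motion(self, static_bundle, grid):
        v4 = fdk4d(static_bundle["rapid"], grid)
        r3 = fdk3d(static_bundle["rapid"], grid)
        mean = np.mean([v.values for v in v4.phases], axis=0)
        rms = np.sqrt(np.mean((mean - r3.values) ** 2))
        assert rms < 0.05 * SOFT

    def test_empty_bin_reported(self, static_bundle, grid):
        pset = static_bundle["rapid"]
        mask = pset.phase_bins != 7
        orphaned = pset.subset(mask)
        with pytest.raises(ValueError, match="bin 7"):
            fdk4d(orphaned, grid)

    def test_rapid_bins_have_large_gaps(self, geometry):
        _, angles, _, bins = scan_schedule(geometry, c.RAPID)
        gaps = [max_angular_gap(angles[bins == b]) for b in range(10)]
        assert all(g > 30.0 for g in gaps)

    def test_conventional_bins_have_132_projections(self, geometry):
        _, _, _, bins = scan_schedule(geometry, c.CONVENTIONAL)
        assert np.bincount(bins, minlength=10).tolist() == [132] * 10


def test_angular_spacing_uniform_schedule():
    sp = angular_spacing(np.linspace(0, 200, 401))
    np.testing.assert_allclose(np.degrees(sp), 0.5, rtol=1e-9)
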
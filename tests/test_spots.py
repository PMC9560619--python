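"""Spot detection, morphometrics and rosette classification."""

import numpy as np
import pytest
from skimage import measure

from wpgap.domain import build_disk, build_rectangle
from wpgap.spots import (classify_rosette, label_spots, resample_to_raster,
                         threshold_mask)
from wpgap.synth import RosetteTemplate


def _flood_fill_count(mask):
    """Naive 8-connectivity component count (stack-based flood fill)."""
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    nx, ny = mask.shape
    for i in range(nx):
        for j in range(ny):
            if mask[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            x, y = a + da, b + db
                            if 0 <= x < nx and 0 <= y < ny \
                                    and mask[x, y] and not seen[x, y]:
                                seen[x, y] = True
                                stack.append((x, y))
    return count


class TestThresholdMask:
    def test_binary_field(self):
        f = np.zeros((10, 10))
        f[2:4, 2:4] = 10.0
        mask, degen = threshold_mask(f)
        assert not degen
        assert np.array_equal(mask, f == 10.0)

    def test_constant_field_flagged(self):
        mask, degen = threshold_mask(np.full((5, 5), 3.0))
        assert degen and not mask.any()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            threshold_mask(np.array([[np.nan, 1.0]]))


class TestLabelSpots:
    def test_two_disjoint_circles(self):
        dom = build_rectangle(Lx=5, Ly=5, n_x=128, n_y=128)
        X, Y = np.meshgrid(dom.x, dom.y, indexing="ij")
        f = np.where(np.hypot(X - 1.5, Y - 1.5) < 0.4, 10.0, 0.0) \
            + np.where(np.hypot(X - 3.5, Y - 3.5) < 0.4, 10.0, 0.0)
        ss = label_spots(f, dom)
        assert ss.count == 2
        # pixelated circles: ecc 0.25 is an axis ratio of 0.97
        assert ss.table["eccentricity"].max() < 0.3
        np.testing.assert_allclose(ss.table["r_eff"], 0.4, atol=0.05)

    def test_ellipse_effective_radius_is_semiaxis_mean(self):
        dom = build_rectangle(Lx=5, Ly=5, n_x=128, n_y=128)
        X, Y = np.meshgrid(dom.x, dom.y, indexing="ij")
        a, b = 0.8, 0.4   # semi-axes, um
        f = np.where(((X - 2.5) / a) ** 2 + ((Y - 2.5) / b) ** 2 < 1,
                     10.0, 0.0)
        ss = label_spots(f, dom)
        assert ss.count == 1
        px = 5 / 128
        assert ss.table["r_eff"].iloc[0] == pytest.approx((a + b) / 2,
                                                          abs=px)

    def test_empty_mask_gives_count_zero(self, disk64):
        ss = label_spots(np.full(disk64.shape, 2.0), disk64)
        assert ss.degenerate and ss.count == 0

    def test_labeling_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            mask = rng.random((24, 24)) < 0.3
            labels = measure.label(mask, connectivity=2)
            assert labels.max() == _flood_fill_count(mask)

    def test_polar_resampling_has_no_seam_artifact(self, disk128):
        # one spot straddling phi = 0 must remain a single component
        tpl = RosetteTemplate(n_spots=1, ring_radius=2.0, phase=0.0,
                              spot_sigma=0.3)
        ss = label_spots(100 * tpl.field(disk128), disk128)
        assert ss.count == 1
        assert ss.table["centroid_r"].iloc[0] == pytest.approx(2.0,
                                                               abs=0.15)
        assert abs(((ss.table["centroid_phi"].iloc[0] + np.pi)
                    % (2 * np.pi)) - np.pi) < 0.1

    def test_threshold_stability_for_separated_rosette(self, disk128):
        field = 100 * RosetteTemplate(n_spots=8,
                                      ring_radius=2.2).field(disk128)
        raster, inside, px, x0 = resample_to_raster(field, disk128)
        lo, hi = raster[inside].min(), raster[inside].max()
        base_thr = (lo + hi) / 2
        counts = []
        for shift in (-0.05, 0.0, 0.05):
            thr = base_thr + shift * (hi - lo)
            counts.append(measure.label((raster > thr) & inside,
                                        connectivity=2).max())
        assert max(counts) - min(counts) <= 1

    def test_rotation_invariant_count(self, disk128):
        for rot in (0.0, 0.21, 1.0):
            field = 100 * RosetteTemplate(n_spots=6, ring_radius=2.0,
                                          phase=rot).field(disk128)
            assert label_spots(field, disk128).count == 6


class TestClassifyRosette:
    def _spotset(self, field, dom):
        return label_spots(field, dom)

    def test_eight_equally_spaced_spots(self, disk128):
        ss = self._spotset(
            100 * RosetteTemplate(n_spots=8, ring_radius=2.0).field(disk128),
            disk128)
        assert classify_rosette(ss, ring_radius=2.0) == "rosette"

    def test_unbroken_annulus_is_ring(self, disk128):
        r = disk128.radius_grid()
        field = np.where(np.abs(r - 2.0) < 0.25, 10.0, 0.0)
        ss = self._spotset(field, disk128)
        assert classify_rosette(ss, ring_radius=2.0) == "ring"

    def test_scattered_spots_are_not_a_rosette(self, disk128):
        rng = np.random.default_rng(0)
        field = np.zeros(disk128.shape)
        rg, ag = disk128.radius_grid(), disk128.angle_grid()
        for rr, aa in zip(rng.uniform(0.3, 3.5, 8),
                          rng.uniform(0, 2 * np.pi, 8)):
            x0, y0 = rr * np.cos(aa), rr * np.sin(aa)
            x, y = rg * np.cos(ag), rg * np.sin(ag)
            field += 10 * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / 0.02)
        ss = self._spotset(field, disk128)
        assert classify_rosette(ss, ring_radius=2.0) == "spots-everywhere"

    def test_two_spots_are_none(self, disk128):
        ss = self._spotset(
            100 * RosetteTemplate(n_spots=2, ring_radius=2.0).field(disk128),
            disk128)
        assert classify_rosette(ss, ring_radius=2.0) == "none"

    def test_large_angular_gap_disqualifies(self, disk128):
        # 8 spot positions but only a 150-degree arc occupied
        field = np.zeros(disk128.shape)
        rg, ag = disk128.radius_grid(), disk128.angle_grid()
        x, y = rg * np.cos(ag), rg * np.sin(ag)
        for a in np.linspace(0, np.radians(150), 5):
            field += 10 * np.exp(
                -((x - 2 * np.cos(a)) ** 2 + (y - 2 * np.sin(a)) ** 2)
                / 0.02)
        ss = self._spotset(field, disk128)
        assert classify_rosette(ss, ring_radius=2.0) == "none"


class TestSpotSizeSweep:
    def test_radius_grows_diffusively_with_membrane_diffusivity(self, base):
        # doubling every diffusivity rescales space by sqrt(2), so the
        # spot radius must grow ~sqrt(2) per doubling of Du
        from wpgap.domain import build_rectangle
        from wpgap.spots import spot_size_sweep
        from wpgap.synth import InitSpec, noisy_initial_condition

        dom = build_rectangle(Lx=5.0, Ly=5.0, n_x=96, n_y=96)

        def make_ic(params, seed):
            return noisy_initial_condition(params, dom,
                                           InitSpec(rng_seed=seed))

        df = spot_size_sweep([0.02, 0.04, 0.08], base, dom, seeds=(0, 1),
                             make_ic=make_ic)
        radii = df["mean_radius"].to_numpy()
        assert np.all(np.diff(radii) > 0)
        ratios = radii[1:] / radii[:-1]
        assert np.all(np.abs(ratios - np.sqrt(2)) < 0.1 * np.sqrt(2))
        assert df["patterned"].all()
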
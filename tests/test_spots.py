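"""Cell geometry, spot detection and the Polarisation Index."""

import numpy as np
import pytest

from mrnapolar.spots import (
    CellGeometry,
    SpotSet,
    cell_geometry,
    cohort_pi_ratio,
    detect_spots,
    pi_ratio,
    polarisation_index,
    puncta_density,
    SpotDetector,
    PolarisationResult,
)
from mrnapolar.synthetic import SimCellSpec, gen_cell_with_spots, render_smfish_image


class TestCellGeometry:
    def test_disk_radius_of_gyration(self, disk_geometry):
        # analytic Rg of a disk of radius R is R/sqrt(2)
        assert disk_geometry.radius_of_gyration == pytest.approx(10 / np.sqrt(2), rel=0.02)
        assert disk_geometry.area == pytest.approx(np.pi * 100, rel=0.02)

    def test_square_radius_of_gyration(self):
        # Rg^2 = a^2/6 for a square of side a
        a, px = 8.0, 0.05
        mask = np.ones((int(a / px), int(a / px)), dtype=bool)
        geom = cell_geometry(mask, px)
        assert geom.radius_of_gyration == pytest.approx(a / np.sqrt(6), rel=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cell_geometry(np.zeros((5, 5), bool), 0.1)

    def test_single_pixel_mask_degenerate_for_pi(self):
        geom = cell_geometry(np.eye(1, dtype=bool), 0.1)
        assert geom.radius_of_gyration == 0
        with pytest.raises(ValueError, match="degenerate"):
            polarisation_index(SpotSet(points=[[0.05, 0.05]]), geom)


class TestPolarisationIndex:
    def test_spots_at_centroid_give_zero(self, disk_geometry):
        pts = np.tile(disk_geometry.centroid, (5, 1))
        res = polarisation_index(SpotSet(points=pts), disk_geometry)
        assert res.pi == pytest.approx(0.0, abs=1e-9)

    def test_rim_spots_give_sqrt2(self, disk_geometry):
        cx, cy = disk_geometry.centroid
        pts = np.tile([cx + 10.0, cy], (20, 1))
        res = polarisation_index(SpotSet(points=pts), disk_geometry)
        assert res.pi == pytest.approx(np.sqrt(2), rel=0.02)

    def test_uniform_spots_give_small_pi(self):
        geom, spots = gen_cell_with_spots(
            SimCellSpec(semi_axes=(10, 10), n_spots=10_000, polarization_kappa=0, seed=3)
        )
        assert polarisation_index(spots, geom).pi < 0.05

    def test_high_kappa_gives_large_pi(self):
        geom, spots = gen_cell_with_spots(
            SimCellSpec(semi_axes=(10, 10), n_spots=500, polarization_kappa=50, seed=4)
        )
        assert polarisation_index(spots, geom).pi > 0.8

    def test_mean_pi_increases_with_kappa(self):
        means = []
        for kappa in (0.0, 1.0, 5.0, 50.0):
            pis = []
            for seed in range(10):
                geom, spots = gen_cell_with_spots(
                    SimCellSpec(n_spots=150, polarization_kappa=kappa, seed=100 + seed)
                )
                pis.append(polarisation_index(spots, geom).pi)
            means.append(np.mean(pis))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_equivalent_radius_normaliser_on_disk(self, disk_geometry):
        # for a disk the equivalent radius is R itself, so rim spots give 1
        cx, cy = disk_geometry.centroid
        pts = np.tile([cx + 10.0, cy], (5, 1))
        res = polarisation_index(SpotSet(points=pts), disk_geometry, norm="equivalent-radius")
        assert res.pi == pytest.approx(1.0, rel=0.02)
        with pytest.raises(ValueError, match="normaliser"):
            polarisation_index(SpotSet(points=pts), disk_geometry, norm="bogus")

    def test_zero_spots_rejected(self, disk_geometry):
        with pytest.raises(ValueError, match="zero spots"):
            polarisation_index(SpotSet(points=np.empty((0, 2))), disk_geometry)

    def test_invariance_under_rigid_transforms(self):
        """PI is unchanged by translation, 90-degree rotation and isotropic
        scaling applied jointly to mask and spots."""
        geom, spots = gen_cell_with_spots(
            SimCellSpec(semi_axes=(15, 8), n_spots=200, polarization_kappa=3, seed=8)
        )
        base = polarisation_index(spots, geom).pi
        px = geom.pixel_size

        # translation by whole pixels
        shift_px = (7, 11)
        mask_t = np.pad(geom.mask, ((shift_px[1], 0), (shift_px[0], 0)))
        geom_t = cell_geometry(mask_t, px)
        pts_t = spots.points + np.array(shift_px) * px
        assert polarisation_index(SpotSet(points=pts_t), geom_t).pi == pytest.approx(
            base, abs=1e-6
        )

        # clockwise 90-degree rotation (exact on the raster): old pixel
        # (r, c) maps to (c, H-1-r), i.e. (x, y) -> (H_um - y, x)
        h_um = geom.mask.shape[0] * px
        mask_r = np.rot90(geom.mask, k=-1)
        geom_r = cell_geometry(mask_r, px)
        pts_r = np.column_stack([h_um - spots.points[:, 1], spots.points[:, 0]])
        assert polarisation_index(SpotSet(points=pts_r), geom_r).pi == pytest.approx(
            base, abs=1e-6
        )

        # isotropic scaling via pixel size
        geom_s = cell_geometry(geom.mask, px * 3)
        pts_s = spots.points * 3
        assert polarisation_index(SpotSet(points=pts_s), geom_s).pi == pytest.approx(
            base, abs=1e-6
        )


class TestDetectSpots:
    def _planted_cell(self, seed=5, n_spots=20, amplitude=1000, background=100):
        geom, spots = gen_cell_with_spots(
            SimCellSpec(semi_axes=(8, 8), pixel_size=0.1, n_spots=n_spots, seed=seed)
        )
        img = render_smfish_image(
            geom, spots, psf_sigma=0.2, amplitude=amplitude,
            background=background, noise="poisson", seed=seed,
        )
        return geom, spots, img

    @staticmethod
    def _match(truth, detected, tol_um):
        used = set()
        n = 0
        for t in truth:
            d = np.linalg.norm(detected - t, axis=1) if len(detected) else np.array([])
            order = np.argsort(d)
            for j in order:
                if j not in used and d[j] <= tol_um:
                    used.add(j)
                    n += 1
                    break
        return n

    def test_planted_spots_recovered_at_high_snr(self):
        recovered = 0
        for seed in (5, 6):
            geom, spots, img = self._planted_cell(seed=seed)
            det = detect_spots(img.pixels, img.pixel_size, psf_sigma=0.2, snr_min=5)
            matched = self._match(spots.points, det.points, tol_um=0.1)  # 1 px
            assert matched / len(det) >= 0.95  # precision
            recovered += int(matched >= 19)
        assert recovered == 2

    def test_blank_images_give_no_detections(self):
        rng = np.random.default_rng(13)
        fp = 0
        for _ in range(10):
            img = rng.normal(100, 5, size=(128, 128))
            det = detect_spots(img, 0.1, psf_sigma=0.2, snr_min=5)
            fp += len(det)
        assert fp == 0

    def test_noiseless_single_spot_at_true_position(self):
        geom = cell_geometry(np.ones((64, 64), bool), 0.1)
        spot = SpotSet(points=[[3.25, 3.25]])  # a pixel center
        img = render_smfish_image(geom, spot, psf_sigma=0.2, amplitude=500,
                                  background=10, noise=None)
        det = detect_spots(img.pixels, 0.1, psf_sigma=0.2, snr_min=5)
        assert len(det) == 1
        assert np.linalg.norm(det.points[0] - [3.25, 3.25]) <= 0.05  # 0.5 px

    def test_pi_from_detected_spots_matches_truth(self):
        geom, spots, img = self._planted_cell(seed=7, n_spots=40)
        det = detect_spots(img.pixels, img.pixel_size, psf_sigma=0.2, snr_min=5)
        pi_truth = polarisation_index(spots, geom).pi
        pi_det = polarisation_index(det, geom).pi
        assert abs(pi_det - pi_truth) < 0.05

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError, match="2D"):
            detect_spots(np.zeros((4, 4, 4)), 0.1, 0.2)

    def test_detector_transform_wrapper(self):
        geom, spots, img = self._planted_cell(seed=9, n_spots=10)
        det = SpotDetector(pixel_size=img.pixel_size, psf_sigma=0.2).fit().transform(img.pixels)
        assert isinstance(det, SpotSet) and len(det) > 0
        assert SpotDetector().get_params()["snr_min"] == 5.0


def _pi(v):
    return PolarisationResult(pi=v, n_spots=10, offset_vector=(0, 0))


class TestPiRatio:
    def test_simple_ratio(self):
        assert pi_ratio(_pi(0.6), _pi(0.3)) == pytest.approx(2.0)

    def test_identical_channels_give_unity(self, disk_geometry):
        geom, spots = gen_cell_with_spots(SimCellSpec(n_spots=50, seed=2))
        r = polarisation_index(spots, geom)
        assert pi_ratio(r, r) == 1.0

    def test_zero_control_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            pi_ratio(_pi(0.5), _pi(0.0))

    def test_cohort_excludes_zero_controls(self):
        mean, n_used, n_excl = cohort_pi_ratio(
            [_pi(0.6), _pi(0.4), _pi(0.9)], [_pi(0.3), _pi(0.0), _pi(0.3)]
        )
        assert n_used == 2 and n_excl == 1
        assert mean == pytest.approx((2.0 + 3.0) / 2)

    def test_polarized_target_over_uniform_control_exceeds_one(self):
        targets, controls = [], []
        for seed in range(8):
            g1, s1 = gen_cell_with_spots(
                SimCellSpec(n_spots=100, polarization_kappa=5, seed=seed)
            )
            g0, s0 = gen_cell_with_spots(
                SimCellSpec(n_spots=100, polarization_kappa=0, seed=1000 + seed)
            )
            targets.append(polarisation_index(s1, g1))
            controls.append(polarisation_index(s0, g0))
        mean, _, _ = cohort_pi_ratio(targets, controls)
        assert mean > 1.0


class TestPunctaDensity:
    def test_direct_value(self):
        assert puncta_density(50, 100.0) == pytest.approx(0.5)

    def test_zero_count(self):
        assert puncta_density(0, 10.0) == 0.0

    def test_doubling_area_halves_density(self):
        assert puncta_density(30, 60.0) == pytest.approx(puncta_density(30, 30.0) / 2)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            puncta_density(1, 0.0)
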
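"""Segmentation: ledger conventions, object counting, apoptotic detection."""

import numpy as np
import pytest

from spheroct import (
    OCTVolume,
    SegmentConfig,
    detect_apoptotic_bodies,
    generate_phantom,
    segment_nodules,
)
from spheroct.segment import slice_perimeter

from conftest import make_ball_volume, small_spec


def _disk_mask(rho: int) -> np.ndarray:
    n = 2 * rho + 9
    c = rho + 4
    zz, xx = np.mgrid[:n, :n]
    return (zz - c) ** 2 + (xx - c) ** 2 <= rho**2


def _brute_force_edge_count(mask: np.ndarray) -> int:
    padded = np.pad(mask.astype(np.int8), 1)
    return int(np.abs(np.diff(padded, axis=0)).sum()
               + np.abs(np.diff(padded, axis=1)).sum())


class TestLedgerConventions:
    def test_square_pixel_edge_ledger(self):
        vol = np.zeros((20, 20, 3))
        vol[5:15, 5:15, 1] = 1.0
        cfg = SegmentConfig(despeckle="none", perimeter_estimator="pixel_edge")
        nod = segment_nodules(OCTVolume(vol, (1, 1, 1)), cfg)
        assert len(nod.slice_ledger) == 1
        row = nod.slice_ledger.iloc[0]
        assert row["perimeter_um"] == pytest.approx(40.0)
        assert row["area_um2"] == pytest.approx(100.0)
        assert row["y_index"] == 1

    @pytest.mark.parametrize("rho", [10, 20])
    def test_digital_disk_area_and_perimeter_bounds(self, rho):
        mask = _disk_mask(rho)
        area = mask.sum()
        assert area == pytest.approx(np.pi * rho**2, rel=0.03)
        crofton = slice_perimeter(mask, (1.0, 1.0), "crofton")
        assert crofton == pytest.approx(2 * np.pi * rho, rel=0.10)
        # the pixel-edge estimator must agree exactly with brute-force
        # counting of exposed faces (its own convention)
        edge = slice_perimeter(mask, (1.0, 1.0), "pixel_edge")
        assert edge == _brute_force_edge_count(mask)

    def test_pixel_edge_anisotropic_pitch(self):
        # 1 x 1 px object with pitches (pz, px) = (2, 3): two faces of each
        # orientation -> perimeter 2*3 + 2*2 = 10
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        assert slice_perimeter(mask, (2.0, 3.0), "pixel_edge") == pytest.approx(10.0)

    def test_crofton_rejects_anisotropic_pitch(self):
        mask = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="isotropic"):
            slice_perimeter(mask, (1.0, 2.0), "crofton")


class TestNoduleSegmentation:
    def test_empty_volume_warns_and_returns_empty_ledger(self):
        vol = OCTVolume(np.zeros((10, 10, 10)), (1, 1, 1))
        with pytest.warns(UserWarning, match="no foreground"):
            nod = segment_nodules(vol)
        assert nod.n_objects == 0
        assert len(nod.slice_ledger) == 0

    def test_phantom_object_count_matches_truth(self):
        spec = small_spec(
            grid_shape=(80, 120, 120), voxel_pitch_um=(3, 3, 3),
            n_spheroids=5, radius_range_um=(25, 40), seed=11,
        )
        vol, _ = generate_phantom(spec)
        nod = segment_nodules(vol)
        assert nod.n_objects == 5

    def test_ledger_rows_cover_all_labeled_slices(self):
        vol, _ = generate_phantom(small_spec(seed=2))
        nod = segment_nodules(vol)
        labeled_ys = {int(y) for y in np.unique(np.nonzero(nod.labels)[2])}
        ledger_ys = set(nod.slice_ledger["y_index"].astype(int))
        assert labeled_ys == ledger_ys
        assert (nod.slice_ledger["area_um2"] > 0).all()
        assert (nod.slice_ledger["perimeter_um"] >= 0).all()


def _dumbbell_volume(separation_vox: float, body_r_vox: int = 6):
    shape = (48, 64, 48)
    zz, xx, yy = np.mgrid[: shape[0], : shape[1], : shape[2]]
    vol = np.full(shape, 0.05)
    nodule = (zz - 24) ** 2 + (xx - 32) ** 2 + (yy - 24) ** 2 <= 20**2
    vol[nodule] = 1.0
    for dx in (-separation_vox / 2, separation_vox / 2):
        body = (zz - 24) ** 2 + (xx - (32 + dx)) ** 2 + (yy - 24) ** 2 <= body_r_vox**2
        vol[body & nodule] = 3.0
    return OCTVolume(vol, (2.0, 2.0, 2.0))


class TestApoptoticDetection:
    def test_uniform_nodule_has_no_features(self):
        vol, _ = generate_phantom(small_spec(seed=1))
        nod = segment_nodules(vol)
        feats = detect_apoptotic_bodies(vol, nod)
        assert feats.n_features == 0

    def test_factor_must_be_positive(self):
        vol, _ = generate_phantom(small_spec(seed=1))
        nod = segment_nodules(vol)
        with pytest.raises(ValueError, match="factor"):
            detect_apoptotic_bodies(vol, nod, factor=0.0)

    def test_empty_nodules_warns(self):
        vol = OCTVolume(np.zeros((8, 8, 8)), (1, 1, 1))
        with pytest.warns(UserWarning):
            nod = segment_nodules(vol)
        with pytest.warns(UserWarning, match="empty apoptotic"):
            feats = detect_apoptotic_bodies(vol, nod)
        assert feats.n_features == 0

    def test_threshold_is_scale_invariant(self):
        vol, _ = generate_phantom(small_spec(seed=3, apoptotic_fraction=0.08))
        nod = segment_nodules(vol)
        feats = detect_apoptotic_bodies(vol, nod)
        for c in (1e-3, 250.0):
            scaled = OCTVolume(vol.intensity * c, vol.voxel_pitch_um, meta=vol.meta)
            nod_c = segment_nodules(scaled)
            feats_c = detect_apoptotic_bodies(scaled, nod_c)
            assert np.array_equal(feats_c.labels > 0, feats.labels > 0)

    @pytest.mark.parametrize("sep_factor", [2.0, 2.7, 3.4])
    def test_dumbbell_splits_into_two(self, sep_factor):
        vol = _dumbbell_volume(sep_factor * 6)
        nod = segment_nodules(vol, SegmentConfig(despeckle="none"))
        feats = detect_apoptotic_bodies(vol, nod, min_seed_separation_um=12.0)
        assert feats.n_features == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_feature_count_matches_constructed_truth(self, seed):
        # well-separated bright spheres inside one nodule: count must match
        rng = np.random.default_rng(seed)
        shape = (64, 64, 64)
        zz, xx, yy = np.mgrid[: shape[0], : shape[1], : shape[2]]
        center = np.array([32, 32, 32])
        nodule = ((zz - 32) ** 2 + (xx - 32) ** 2 + (yy - 32) ** 2) <= 26**2
        vol = np.full(shape, 0.05)
        vol[nodule] = 1.0
        body_r = 4
        centers: list[np.ndarray] = []
        while len(centers) < 6:
            cand = center + rng.uniform(-18, 18, size=3)
            if np.linalg.norm(cand - center) > 26 - body_r - 2:
                continue
            if all(np.linalg.norm(cand - c) >= 4 * body_r for c in centers):
                centers.append(cand)
        for c in centers:
            body = ((zz - c[0]) ** 2 + (xx - c[1]) ** 2 + (yy - c[2]) ** 2) <= body_r**2
            vol[body & nodule] = 3.0
        ovol = OCTVolume(vol, (2.0, 2.0, 2.0))
        nod = segment_nodules(ovol, SegmentConfig(despeckle="none"))
        feats = detect_apoptotic_bodies(ovol, nod)
        assert feats.n_features == 6

    def test_features_report_calibrated_volumes(self):
        vol, truth = generate_phantom(small_spec(seed=5, apoptotic_fraction=0.10))
        nod = segment_nodules(vol)
        feats = detect_apoptotic_bodies(vol, nod)
        assert feats.n_features > 0
        vox_vol = np.prod(vol.voxel_pitch_um)
        assert np.allclose(
            feats.features["volume_um3"], feats.features["voxels"] * vox_vol
        )
        lo, hi = feats.size_filter_voxels
        assert ((feats.features["voxels"] >= lo) & (feats.features["voxels"] <= hi)).all()
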
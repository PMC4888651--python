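"""SA:V ratio, disruption index, apoptotic density, normalization."""

import numpy as np
import pandas as pd
import pytest

from spheroct import (
    OCTVolume,
    SegmentConfig,
    UndefinedMetricError,
    apoptotic_density,
    disruption_index,
    global_sa_to_v,
    mask_sa_to_v,
    normalize_records,
    normalize_to_control,
    records_to_frame,
    segment_nodules,
)
from spheroct.metrics import MetricsRecord
from spheroct.segment import ApoptoticFeatureSet

from conftest import make_ball_volume


def _feature_set(volumes_um3, parent_volume_um3):
    rows = [
        {"feature_id": i + 1, "voxels": 1, "volume_um3": v,
         "centroid_z": 0.0, "centroid_x": 0.0, "centroid_y": 0.0,
         "mean_intensity": 1.0, "parent_nodule": 1}
        for i, v in enumerate(volumes_um3)
    ]
    features = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["feature_id", "voxels", "volume_um3", "centroid_z",
                 "centroid_x", "centroid_y", "mean_intensity", "parent_nodule"]
    )
    return ApoptoticFeatureSet(
        features, np.zeros((1, 1, 1), dtype=np.int32), 1.7, {}, (1, 10**6),
        parent_volume_um3,
    )


class TestGlobalSAV:
    def test_square_slice_under_pixel_edge_convention(self):
        vol = np.zeros((20, 20, 3))
        vol[5:15, 5:15, 1] = 1.0
        cfg = SegmentConfig(despeckle="none", perimeter_estimator="pixel_edge")
        nod = segment_nodules(OCTVolume(vol, (1, 1, 1)), cfg)
        assert global_sa_to_v(nod) == pytest.approx(0.4)

    def test_digital_ball_matches_stacked_circle_value(self):
        # stacked-circle convention: sum 2*pi*rho dz / sum pi*rho^2 dz = 3pi/4r
        r = 20
        vol, mask = make_ball_volume(r)
        nod = segment_nodules(vol)
        measured = global_sa_to_v(nod)
        assert measured == pytest.approx(3 * np.pi / (4 * r), rel=0.10)
        # independent oracle: continuous circle radii per slice
        c = r + 4
        surface = volume = 0.0
        for z in range(vol.shape[0]):
            rho2 = (r + 0.5) ** 2 - (z - c) ** 2
            if rho2 > 0:
                surface += 2 * np.pi * np.sqrt(rho2)
                volume += np.pi * rho2
        assert measured == pytest.approx(surface / volume, rel=0.10)
        # voxel-count volume check against the ledger's area sum
        ledger_vol = nod.slice_ledger["area_um2"].sum() * 1.0
        assert ledger_vol == pytest.approx(mask.sum(), rel=0.02)

    def test_splitting_increases_ratio(self):
        # one ball vs eight half-radius balls of equal total volume
        big = np.zeros((60, 60, 60), dtype=bool)
        zz, xx, yy = np.mgrid[:60, :60, :60]
        big |= (zz - 30) ** 2 + (xx - 30) ** 2 + (yy - 30) ** 2 <= 16**2
        split = np.zeros_like(big)
        for cz in (15, 45):
            for cx in (15, 45):
                for cy in (15, 45):
                    split |= (zz - cz) ** 2 + (xx - cx) ** 2 + (yy - cy) ** 2 <= 8**2
        assert mask_sa_to_v(split, (1, 1, 1)) > mask_sa_to_v(big, (1, 1, 1))

    def test_empty_ledger_is_undefined_not_zero(self):
        vol = OCTVolume(np.zeros((8, 8, 8)), (1, 1, 1))
        with pytest.warns(UserWarning):
            nod = segment_nodules(vol)
        with pytest.raises(UndefinedMetricError):
            global_sa_to_v(nod)

    def test_pitch_scaling_divides_ratio_exactly(self):
        _, mask = make_ball_volume(12)
        base = mask_sa_to_v(mask, (1.0, 1.0, 1.0))
        for c in (0.5, 4.0):
            scaled = mask_sa_to_v(mask, (c, c, c))
            assert scaled * c == pytest.approx(base, rel=1e-12)

    def test_global_ratio_is_sum_ratio_not_mean_of_ratios(self):
        # two objects of very different size: global ratio must equal
        # total-surface / total-volume, not the mean of per-object ratios
        zz, xx, yy = np.mgrid[:70, :70, :40]
        big = (zz - 35) ** 2 + (xx - 20) ** 2 + (yy - 20) ** 2 <= 15**2
        small = (zz - 35) ** 2 + (xx - 55) ** 2 + (yy - 20) ** 2 <= 5**2
        both = big | small
        vol = OCTVolume(both.astype(float), (1, 1, 1))
        nod = segment_nodules(vol, SegmentConfig(despeckle="none"))
        global_ratio = global_sa_to_v(nod)
        r_big = mask_sa_to_v(big, (1, 1, 1))
        r_small = mask_sa_to_v(small, (1, 1, 1))
        mean_of_ratios = 0.5 * (r_big + r_small)
        dy = 1.0
        led = nod.slice_ledger
        expected = led["perimeter_um"].sum() * dy / (led["area_um2"].sum() * dy)
        assert global_ratio == pytest.approx(expected, rel=1e-12)
        assert abs(global_ratio - mean_of_ratios) > 0.05 * global_ratio


class TestDisruptionIndex:
    def test_control_against_itself_is_exactly_zero(self):
        assert disruption_index(0.085, 0.085) == 0.0

    def test_arithmetic(self):
        assert disruption_index(0.26, 0.20) == pytest.approx(0.30)

    def test_requires_positive_control(self):
        with pytest.raises(ValueError):
            disruption_index(0.1, 0.0)


class TestApoptoticDensity:
    def test_empty_feature_set_is_zero(self):
        assert apoptotic_density(_feature_set([], 1e5)) == 0.0

    def test_arithmetic(self):
        fs = _feature_set([4000.0, 6000.0], 100000.0)
        assert apoptotic_density(fs) == pytest.approx(0.10)

    def test_zero_spheroid_volume_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            apoptotic_density(_feature_set([10.0], 0.0))

    def test_overflow_clipped_with_warning(self):
        fs = _feature_set([2e5], 1e5)
        with pytest.warns(UserWarning, match="clipping"):
            assert apoptotic_density(fs) == 1.0


class TestNormalization:
    def test_control_is_unity(self):
        assert normalize_to_control(0.02, 0.02) == 1.0

    def test_ratio(self):
        assert normalize_to_control(0.05, 0.02) == pytest.approx(2.5)

    def test_rank_order_preserved(self, rng):
        values = rng.uniform(0.01, 0.5, size=12)
        normed = np.array([normalize_to_control(v, 0.07) for v in values])
        assert np.array_equal(np.argsort(values), np.argsort(normed))

    def test_normalize_records_sets_control_to_baseline(self):
        recs = [
            MetricsRecord("w1", "NT", 0, sa_to_v=0.08, apoptotic_density=0.02),
            MetricsRecord("w2", "PDT", 0, sa_to_v=0.12, apoptotic_density=0.06),
        ]
        df = normalize_records(records_to_frame(recs))
        nt = df[df["treatment"] == "NT"].iloc[0]
        assert nt["disruption_index"] == 0.0
        assert nt["normalized_sa_to_v"] == 1.0
        assert nt["normalized_apoptotic_density"] == 1.0
        pdt = df[df["treatment"] == "PDT"].iloc[0]
        assert pdt["disruption_index"] == pytest.approx(0.5)
        assert pdt["normalized_apoptotic_density"] == pytest.approx(3.0)

    def test_missing_control_raises(self):
        recs = [MetricsRecord("w1", "PDT", 0, sa_to_v=0.1, apoptotic_density=0.0)]
        with pytest.raises(ValueError, match="control"):
            normalize_records(records_to_frame(recs))
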
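"""Treatment-response metrics: SA:V disruption index and apoptotic density.

Cell death by apoptosis or necrosis breaks cell-cell adhesion, so treated
spheroids shed material and fragment.  The global surface-area-to-volume
(SA:V) ratio captures this: per xz cross-section every segmented object
contributes its perimeter and enclosed area; surfaces are the summed
perimeters times the slice thickness, volumes the summed areas times the
slice thickness, and the global ratio is their quotient.  Normalizing to the
no-treatment control gives a unitless index; subtracting 1 shifts it so that
0 means "as intact as the control".

Apoptotic density is the summed volume of detected hyperscattering bodies
divided by the total segmented spheroid volume — a direct, label-free
read-out of programmed cell death.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segment import (
    ApoptoticFeatureSet,
    NoduleLabels,
    SegmentConfig,
    detect_apoptotic_bodies,
    segment_nodules,
    slice_ledger,
)
from .reconstruct import OCTVolume

__all__ = [
    "MetricsRecord",
    "UndefinedMetricError",
    "global_sa_to_v",
    "disruption_index",
    "normalized_sa_to_v",
    "apoptotic_density",
    "normalize_to_control",
    "mask_sa_to_v",
    "compute_well_record",
    "normalize_records",
    "records_to_frame",
]

METRICS_COLUMNS = [
    "well_id", "treatment", "day",
    "sa_to_v", "disruption_index", "normalized_sa_to_v",
    "apoptotic_density", "normalized_apoptotic_density",
    "n_objects", "n_apoptotic_features",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator is empty/zero — distinct from a zero value."""


@dataclass
class MetricsRecord:
    """Per-well metric row; normalized fields are filled against a control."""

    well_id: str
    treatment: str = ""
    day: float = 0.0
    sa_to_v: float = np.nan               # 1/um
    disruption_index: float = np.nan      # (sample/control) - 1, 0 = intact
    normalized_sa_to_v: float = np.nan    # sample/control, control = 1
    apoptotic_density: float = np.nan     # fraction of spheroid volume
    normalized_apoptotic_density: float = np.nan
    n_objects: int = 0
    n_apoptotic_features: int = 0
    extras: dict = field(default_factory=dict)


def global_sa_to_v(nodules: NoduleLabels) -> float:
    """Global surface-area-to-volume ratio (1/um) from the slice ledger.

    surface = sum(slice perimeters) x slice thickness,
    volume  = sum(slice areas) x slice thickness;
    the slice thickness (y pitch) cancels but is kept explicit so the two
    sums individually carry physical units.
    """
    ledger = nodules.slice_ledger
    if ledger is None or len(ledger) == 0:
        raise UndefinedMetricError("empty ledger: SA:V is undefined, not zero")
    dy = nodules.voxel_pitch_um[2]
    surface = float(ledger["perimeter_um"].sum()) * dy
    volume = float(ledger["area_um2"].sum()) * dy
    if volume <= 0:
        raise UndefinedMetricError("zero segmented volume")
    return surface / volume


def disruption_index(sample_ratio: float, control_ratio: float) -> float:
    """Control-normalized SA:V shifted so 0 means intact: s/c - 1."""
    if control_ratio <= 0:
        raise ValueError("control_ratio must be > 0")
    return sample_ratio / control_ratio - 1.0


def normalized_sa_to_v(sample_ratio: float, control_ratio: float) -> float:
    """Unsubtracted form of the disruption index (control = unity)."""
    return normalize_to_control(sample_ratio, control_ratio)


def apoptotic_density(features: ApoptoticFeatureSet) -> float:
    """Summed apoptotic feature volume over total spheroid volume."""
    if features.parent_nodule_volume_um3 <= 0:
        raise UndefinedMetricError("zero spheroid volume: density undefined")
    density = features.total_feature_volume_um3 / features.parent_nodule_volume_um3
    if density > 1.0:
        warnings.warn(
            f"apoptotic density {density:.3f} > 1 indicates a segmentation "
            "inconsistency; clipping to 1",
            stacklevel=2,
        )
        density = 1.0
    return density


def normalize_to_control(value: float, control_value: float) -> float:
    if control_value <= 0:
        raise ValueError("control value must be > 0")
    return value / control_value


def mask_sa_to_v(
    mask: np.ndarray,
    voxel_pitch_um: tuple[float, float, float],
    estimator: str = "crofton",
) -> float:
    """Ground-truth SA:V of a boolean mask under the same slice convention.

    Used by the phantom module so synthetic truth and measured metrics share
    one perimeter convention.
    """
    mask = np.asarray(mask)
    ledger = slice_ledger(mask.astype(np.int32), voxel_pitch_um, estimator)
    if len(ledger) == 0:
        raise UndefinedMetricError("empty mask")
    return float(ledger["perimeter_um"].sum() / ledger["area_um2"].sum())


def compute_well_record(
    volume: OCTVolume,
    well_id: str,
    treatment: str = "",
    day: float = 0.0,
    config: SegmentConfig | None = None,
    apoptotic_factor: float = 1.7,
    **detect_kwargs,
) -> MetricsRecord:
    """Run the full per-well analysis chain: segment, then both metrics.

    Degenerate wells (no detected foreground) yield a record with NaN
    metrics and ``n_objects == 0``; callers exclude them from group
    statistics rather than imputing values.
    """
    nodules = segment_nodules(volume, config)
    rec = MetricsRecord(well_id=well_id, treatment=treatment, day=day)
    rec.n_objects = nodules.n_objects
    if nodules.n_objects == 0:
        warnings.warn(f"well {well_id}: no foreground; metrics undefined", stacklevel=2)
        return rec
    rec.sa_to_v = global_sa_to_v(nodules)
    feats = detect_apoptotic_bodies(volume, nodules, factor=apoptotic_factor, **detect_kwargs)
    rec.apoptotic_density = apoptotic_density(feats)
    rec.n_apoptotic_features = feats.n_features
    return rec


def normalize_records(
    df: pd.DataFrame, control_treatment: str = "NT", per_day: bool = True
) -> pd.DataFrame:
    """Fill control-normalized columns against the mean no-treatment well.

    Per day (or globally when ``per_day=False``) the control level is the
    mean metric over wells whose treatment equals ``control_treatment``;
    each well's ratio to that level fills ``normalized_*`` and the
    subtracted ``disruption_index``.  A zero/absent control apoptotic
    density leaves ``normalized_apoptotic_density`` as NaN.
    """
    out = df.copy()
    days = sorted(out["day"].unique()) if per_day else [None]
    for day in days:
        sel = (out["day"] == day) if day is not None else np.ones(len(out), dtype=bool)
        ctrl = out[sel & (out["treatment"] == control_treatment)]
        if len(ctrl) == 0:
            raise ValueError(
                f"no control wells (treatment={control_treatment!r})"
                + (f" for day {day}" if day is not None else "")
            )
        c_sav = float(ctrl["sa_to_v"].mean())
        if not c_sav > 0:
            raise UndefinedMetricError("control SA:V is not positive")
        out.loc[sel, "normalized_sa_to_v"] = out.loc[sel, "sa_to_v"] / c_sav
        out.loc[sel, "disruption_index"] = out.loc[sel, "sa_to_v"] / c_sav - 1.0
        c_apop = float(ctrl["apoptotic_density"].mean())
        if c_apop > 0:
            out.loc[sel, "normalized_apoptotic_density"] = (
                out.loc[sel, "apoptotic_density"] / c_apop
            )
    return out


def records_to_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in METRICS_COLUMNS})
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)
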
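"""Synthetic OCT phantoms of 3-D tumor spheroid cultures.

The generator emulates the statistical structure the analysis chain assumes:
quasi-spherical nodules (400–700 um diameter by default) of elevated
backscatter in a dim medium, exponential depth attenuation, fully developed
speckle (unit-mean multiplicative exponential noise), treatment-induced
fragmentation (nodule material displaced into small detached fragments near
the parent), and hyperscattering apoptotic bodies (small bright spheres,
preferentially peripheral).  Every phantom carries exact ground-truth masks,
the true apoptotic volume fraction, and a ground-truth SA:V computed under
the same slice/perimeter convention as the metrics module, so parameter
recovery can be tested end to end.

A forward model (``simulate_raw_spectra``) converts a volume into raw
spectral interferograms whose FFT reconstruction recovers the axial
reflectivity profile, closing the loop with the reconstruct module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .reconstruct import AliasingError, OCTVolume, RawBScan
from . import metrics as _metrics

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PlacementError",
    "generate_phantom",
    "apply_fragmentation",
    "simulate_raw_spectra",
]

_SPECKLE_SEED_OFFSET = 24001  # decorrelates the speckle stream from placement


class PlacementError(RuntimeError):
    """Spheroids could not be placed without overlap."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic culture volume.

    Geometry defaults use a 4 um isotropic analysis grid large enough to
    hold nodules in the 400–700 um diameter range; the native instrument
    pitches are available in :mod:`spheroct.reconstruct` and every field is
    overridable.  Reflectivities are dimensionless linear backscatter
    levels; ``attenuation_coeff`` is the single-pass attenuation per
    micrometer applied as ``exp(-2 * mu * depth)``.
    """

    grid_shape: tuple[int, int, int] = (192, 256, 256)      # (z, x, y) voxels
    voxel_pitch_um: tuple[float, float, float] = (4.0, 4.0, 4.0)
    n_spheroids: int = 2
    radius_range_um: tuple[float, float] = (200.0, 350.0)
    base_reflectivity: float = 1.0
    background_reflectivity: float = 0.05
    fragmentation: float = 0.0
    apoptotic_fraction: float = 0.0
    apoptotic_gain: float = 3.0
    body_radius_range_um: tuple[float, float] = (5.0, 15.0)
    peripheral_bias: float = 2.0
    fragment_radius_range_um: tuple[float, float] = (6.0, 12.0)
    speckle: bool = True
    attenuation_coeff: float = 0.001                        # 1/um
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise ValueError("grid_shape: three positive integers required")
        if any(p <= 0 for p in self.voxel_pitch_um):
            raise ValueError("voxel_pitch_um: pitches must be > 0")
        if self.n_spheroids < 0:
            raise ValueError("n_spheroids: must be >= 0")
        if not 0.0 <= self.fragmentation <= 1.0:
            raise ValueError("fragmentation: must be in [0, 1]")
        if not 0.0 <= self.apoptotic_fraction <= 1.0:
            raise ValueError("apoptotic_fraction: must be in [0, 1]")
        if self.apoptotic_gain <= 0:
            raise ValueError("apoptotic_gain: must be > 0")
        if self.radius_range_um[0] > self.radius_range_um[1] or self.radius_range_um[0] <= 0:
            raise ValueError("radius_range_um: need 0 < min <= max")
        extent = [s * p for s, p in zip(self.grid_shape, self.voxel_pitch_um)]
        if self.n_spheroids and 2 * self.radius_range_um[0] > min(extent):
            raise ValueError(
                "radius_range_um: smallest spheroid does not fit in the grid"
            )
        if self.base_reflectivity <= 0 or self.background_reflectivity < 0:
            raise ValueError("reflectivities: base > 0 and background >= 0 required")
        if self.attenuation_coeff < 0:
            raise ValueError("attenuation_coeff: must be >= 0")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(s * p for s, p in zip(self.grid_shape, self.voxel_pitch_um))


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying a phantom volume."""

    nodule_mask: np.ndarray          # bool: intact nodule material
    fragment_labels: np.ndarray      # int: detached fragments (0 = none)
    apoptotic_mask: np.ndarray       # bool: hyperscattering body voxels
    true_apoptotic_fraction: float   # apoptotic voxels / foreground voxels
    true_sa_to_v: float              # per-convention ratio, 1/um (nan if empty)
    spheroids: list = field(default_factory=list)  # (center_um, radius_um, axis_scales)

    @property
    def foreground_mask(self) -> np.ndarray:
        return self.nodule_mask | (self.fragment_labels > 0)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[OCTVolume, PhantomTruth]:
    """Generate a phantom volume and its ground truth.

    Deterministic for a fixed spec (including seed).  Raises
    :class:`PlacementError` if non-overlapping placement fails after bounded
    retries.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    pitch = tuple(float(p) for p in spec.voxel_pitch_um)

    spheroids = _place_spheroids(rng, spec)
    nodule_mask = np.zeros(shape, dtype=bool)
    for center, radius, scales in spheroids:
        _paint_ellipsoid(nodule_mask, center, radius * scales, pitch, True)

    apop_mask = np.zeros(shape, dtype=bool)
    if spec.apoptotic_fraction > 0 and spheroids:
        for center, radius, scales in spheroids:
            _seed_bodies(rng, spec, apop_mask, nodule_mask, center, radius, scales, pitch)

    fragment_labels = np.zeros(shape, dtype=np.int32)
    if spec.fragmentation > 0 and spheroids:
        nodule_mask, fragment_labels, apop_mask = _fragment_masks(
            rng, spec, nodule_mask, apop_mask
        )

    truth = _finalize_truth(nodule_mask, fragment_labels, apop_mask, pitch, spheroids)
    volume = _render(spec, truth)
    return volume, truth


def _place_spheroids(rng: np.random.Generator, spec: PhantomSpec):
    """Non-overlapping random placement in physical coordinates."""
    extent = np.array(spec.extent_um)
    margin_um = 2.0 * max(spec.voxel_pitch_um)
    placed: list[tuple[np.ndarray, float, np.ndarray]] = []
    for i in range(spec.n_spheroids):
        ok = False
        for _ in range(300):
            radius = rng.uniform(*spec.radius_range_um)
            scales = rng.uniform(0.92, 1.08, size=3)
            pad = radius * scales.max() + margin_um
            if np.any(extent - 2 * pad <= 0):
                continue
            center = rng.uniform(pad, extent - pad)
            if all(
                np.linalg.norm(center - c) > radius * scales.max() + r * s.max() + margin_um
                for c, r, s in placed
            ):
                placed.append((center, radius, scales))
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place spheroid {i} without overlap after 300 retries"
            )
    return placed


def _paint_ellipsoid(mask, center_um, radii_um, pitch, value) -> np.ndarray:
    """Set voxels inside an axis-aligned ellipsoid; returns local bbox slices."""
    radii_um = np.broadcast_to(np.asarray(radii_um, dtype=float), (3,))
    lo = np.maximum(0, np.floor((center_um - radii_um) / pitch).astype(int))
    hi = np.minimum(mask.shape, np.ceil((center_um + radii_um) / pitch).astype(int) + 1)
    if np.any(hi <= lo):
        return None
    axes = [
        ((np.arange(lo[k], hi[k]) + 0.5) * pitch[k] - center_um[k]) / radii_um[k]
        for k in range(3)
    ]
    inside = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    ) <= 1.0
    region = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    mask[region] |= inside if value else False
    return region, inside


def _seed_bodies(rng, spec, apop_mask, nodule_mask, center, radius, scales, pitch):
    """Fill one spheroid with bright bodies until the target fraction is hit.

    The final body is trimmed (nearest-to-center voxels kept) so the realized
    apoptotic voxel count matches the target exactly up to quantization.
    """
    region = _spheroid_region(nodule_mask.shape, center, radius * scales, pitch)
    local_nodule = np.zeros(nodule_mask.shape, dtype=bool)
    res = _paint_ellipsoid(local_nodule, center, radius * scales, pitch, True)
    if res is None:
        return
    local_nodule &= nodule_mask
    nodule_vox = int(local_nodule.sum())
    target = int(round(spec.apoptotic_fraction * nodule_vox))
    count = int((apop_mask & local_nodule).sum())
    attempts = 0
    max_attempts = 200 + 50 * max(1, target)
    r_min, r_max = spec.body_radius_range_um
    exponent = 1.0 / (3.0 + spec.peripheral_bias)
    vox_vol = float(np.prod(pitch))
    while count < target and attempts < max_attempts:
        attempts += 1
        remaining = target - count
        r_b = rng.uniform(r_min, r_max)
        # shrink the body toward the remaining budget to limit overshoot
        r_need = (3.0 * remaining * vox_vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        r_b = min(r_b, max(r_need, r_min))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        u = rng.random() ** exponent
        c_b = center + direction * u * max(radius * scales.min() - r_b, 0.0)
        body = np.zeros(nodule_mask.shape, dtype=bool)
        if _paint_ellipsoid(body, c_b, r_b, pitch, True) is None:
            continue
        body &= local_nodule
        new = body & ~apop_mask
        n_new = int(new.sum())
        if n_new == 0:
            continue
        if n_new > remaining:
            # trim: keep the voxels nearest the body center
            coords = np.argwhere(new)
            d2 = (((coords + 0.5) * pitch - c_b) ** 2).sum(axis=1)
            keep = coords[np.argsort(d2, kind="stable")[:remaining]]
            new = np.zeros_like(new)
            new[tuple(keep.T)] = True
            n_new = remaining
        apop_mask |= new
        count += n_new
    if count < target and target > 0:
        warnings.warn(
            f"apoptotic seeding reached {count}/{target} voxels before the "
            "attempt cap",
            stacklevel=2,
        )
    _ = region


def _spheroid_region(shape, center_um, radii_um, pitch):
    radii_um = np.broadcast_to(np.asarray(radii_um, dtype=float), (3,))
    lo = np.maximum(0, np.floor((center_um - radii_um) / pitch).astype(int))
    hi = np.minimum(shape, np.ceil((center_um + radii_um) / pitch).astype(int) + 1)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

def _fragment_masks(rng, spec: PhantomSpec, nodule_mask, apop_mask, frag_labels0=None):
    """Displace a fraction of each nodule's voxels into detached fragments.

    Voxels are shed outermost-first (ascending distance transform), keeping
    the residual nodule compact; fragments are small spheres deposited in a
    dilation shell around the parent with one voxel of clearance so they
    stay detached.  Total foreground is conserved up to logged collisions.
    """
    frac = spec.fragmentation
    pitch = spec.voxel_pitch_um
    shape = nodule_mask.shape
    labels, n = ndimage.label(nodule_mask, structure=np.ones((3, 3, 3)))
    new_nodule = nodule_mask.copy()
    new_apop = apop_mask.copy()
    if frag_labels0 is None:
        frag_labels = np.zeros(shape, dtype=np.int32)
    else:
        frag_labels = frag_labels0.copy()
    occupied = nodule_mask | (frag_labels > 0)
    next_frag = int(frag_labels.max()) + 1
    r_lo, r_hi = spec.fragment_radius_range_um

    for comp_id in range(1, n + 1):
        comp = labels == comp_id
        nvox = int(comp.sum())
        n_remove = int(round(frac * nvox))
        if n_remove == 0:
            continue
        dist = ndimage.distance_transform_edt(comp, sampling=pitch)
        coords = np.argwhere(comp)
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], dist[comp]))
        shed = coords[order[:n_remove]]
        shed_idx = tuple(shed.T)
        new_nodule[shed_idx] = False
        new_apop[shed_idx] = False
        occupied[shed_idx] = False

        deposited = 0
        for dil in (4, 8, 14, 22, 32):
            if deposited >= n_remove:
                break
            shell = ndimage.binary_dilation(comp, iterations=dil) & ~comp
            free = shell & ~ndimage.binary_dilation(
                occupied, structure=np.ones((3, 3, 3))
            )
            cand = np.argwhere(free)
            if cand.size == 0:
                continue
            rng.shuffle(cand)
            for c_vox in cand:
                if deposited >= n_remove:
                    break
                if not free[tuple(c_vox)]:
                    continue
                c_um = (c_vox + 0.5) * np.asarray(pitch)
                r_f = rng.uniform(r_lo, r_hi)
                placed = _deposit_fragment(
                    occupied, frag_labels, shell, c_um, r_f, pitch,
                    n_remove - deposited, next_frag,
                )
                if placed:
                    deposited += placed
                    next_frag += 1
                    # block the used neighborhood; gaps are revisited at the
                    # next dilation level with the refreshed free mask
                    rad = int(np.ceil(r_f / min(pitch))) + 1
                    lo = np.maximum(0, c_vox - rad)
                    hi = np.minimum(shape, c_vox + rad + 2)
                    free[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = False
        if deposited < n_remove:
            lost = n_remove - deposited
            if lost > 0.01 * nvox:
                warnings.warn(
                    f"fragmentation collisions lost {lost} of {nvox} voxels "
                    f"({lost / nvox:.1%}) for nodule {comp_id}",
                    stacklevel=2,
                )
    return new_nodule, frag_labels, new_apop


def _deposit_fragment(occupied, frag_labels, shell, center_um, radius_um, pitch,
                      budget: int, label: int) -> int:
    """Carve one fragment sphere into free shell space; returns voxels placed.

    Keeps one voxel of clearance from anything occupied so fragments remain
    separate connected components; the sphere is trimmed to the remaining
    voxel budget (nearest-to-center first).
    """
    shape = occupied.shape
    radius = np.asarray([radius_um] * 3, dtype=float)
    lo = np.maximum(0, np.floor((center_um - radius) / pitch).astype(int) - 1)
    hi = np.minimum(shape, np.ceil((center_um + radius) / pitch).astype(int) + 2)
    if np.any(hi <= lo):
        return 0
    region = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    axes = [
        ((np.arange(lo[k], hi[k]) + 0.5) * pitch[k] - center_um[k]) / radius[k]
        for k in range(3)
    ]
    sphere = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    ) <= 1.0
    occ_local = occupied[region]
    clearance = ndimage.binary_dilation(occ_local, structure=np.ones((3, 3, 3)))
    allowed = sphere & shell[region] & ~clearance
    n_avail = int(allowed.sum())
    if n_avail == 0:
        return 0
    if n_avail > budget:
        coords = np.argwhere(allowed)
        centered = (coords + lo + 0.5) * np.asarray(pitch) - center_um
        d2 = (centered**2).sum(axis=1)
        keep = coords[np.argsort(d2, kind="stable")[:budget]]
        allowed = np.zeros_like(allowed)
        allowed[tuple(keep.T)] = True
        n_avail = budget
    occ_local = occupied[region]
    occ_local[allowed] = True
    occupied[region] = occ_local
    fl = frag_labels[region]
    fl[allowed] = label
    frag_labels[region] = fl
    return n_avail


def apply_fragmentation(
    volume: OCTVolume, truth: PhantomTruth, fragmentation: float
) -> tuple[OCTVolume, PhantomTruth]:
    """Fragment an existing phantom and re-render its intensity.

    ``fragmentation == 0`` returns bit-identical copies.  The speckle field
    is regenerated from the seed stored in the volume's render parameters,
    so the operation is deterministic and, at zero fragmentation, an exact
    identity.
    """
    if not 0.0 <= fragmentation <= 1.0:
        raise ValueError("fragmentation must be in [0, 1]")
    params = volume.meta.get("phantom_spec")
    if params is None:
        raise ValueError("volume lacks phantom provenance (meta['phantom_spec'])")
    spec = PhantomSpec(**{**params, "fragmentation": fragmentation})
    pitch = tuple(spec.voxel_pitch_um)
    if fragmentation == 0.0:
        new_truth = _finalize_truth(
            truth.nodule_mask.copy(), truth.fragment_labels.copy(),
            truth.apoptotic_mask.copy(), pitch, list(truth.spheroids),
        )
        return _render(spec, new_truth), new_truth
    rng = np.random.default_rng(spec.seed + 9173)
    nodule, frags, apop = _fragment_masks(
        rng, spec, truth.nodule_mask, truth.apoptotic_mask, truth.fragment_labels
    )
    new_truth = _finalize_truth(nodule, frags, apop, pitch, list(truth.spheroids))
    return _render(spec, new_truth), new_truth


# ---------------------------------------------------------------------------
# Rendering and truth finalization
# ---------------------------------------------------------------------------

def _finalize_truth(nodule_mask, fragment_labels, apop_mask, pitch, spheroids) -> PhantomTruth:
    foreground = nodule_mask | (fragment_labels > 0)
    fg = int(foreground.sum())
    frac = float(apop_mask.sum()) / fg if fg else 0.0
    if fg:
        sa_to_v = _metrics.mask_sa_to_v(foreground, pitch)
    else:
        sa_to_v = float("nan")
    return PhantomTruth(
        nodule_mask=nodule_mask,
        fragment_labels=fragment_labels,
        apoptotic_mask=apop_mask,
        true_apoptotic_fraction=frac,
        true_sa_to_v=sa_to_v,
        spheroids=spheroids,
    )


def _render(spec: PhantomSpec, truth: PhantomTruth) -> OCTVolume:
    shape = tuple(int(s) for s in spec.grid_shape)
    pitch = tuple(spec.voxel_pitch_um)
    refl = np.full(shape, spec.background_reflectivity, dtype=float)
    refl[truth.foreground_mask] = spec.base_reflectivity
    refl[truth.apoptotic_mask] = spec.base_reflectivity * spec.apoptotic_gain
    if spec.attenuation_coeff > 0:
        depth_um = (np.arange(shape[0]) + 0.5) * pitch[0]
        refl *= np.exp(-2.0 * spec.attenuation_coeff * depth_um)[:, None, None]
    speckle_seed = (int(spec.seed) + _SPECKLE_SEED_OFFSET) % (2**31)
    if spec.speckle:
        refl *= np.random.default_rng(speckle_seed).exponential(1.0, size=shape)
    meta = {
        "phantom_spec": asdict(spec),
        "speckle_seed": speckle_seed,
        "provenance": "synthetic phantom",
    }
    return OCTVolume(refl, pitch, log_scaled=False, meta=meta)


# ---------------------------------------------------------------------------
# Forward model: volume -> raw spectral interferograms
# ---------------------------------------------------------------------------

def simulate_raw_spectra(
    volume: OCTVolume, spectral_samples: int, dc_level: float = 1.0
) -> list[RawBScan]:
    """Emit raw spectra whose FFT reconstruction recovers the volume.

    For each A-scan with axial reflectivity profile ``a[z]``, the spectrum
    is ``S[m] = dc + sum_z a[z] * cos(2*pi*z*m/M)`` with ``M`` spectral
    samples — linear-in-wavenumber sampling with fringe frequency
    proportional to depth.  Requires ``M >= 2 * nz`` (Nyquist); otherwise an
    :class:`AliasingError` is raised.
    """
    nz, nx, ny = volume.shape
    m = int(spectral_samples)
    if m < 2 * nz:
        raise AliasingError(
            f"spectral_samples={m} aliases an axial extent of {nz} voxels; "
            f"need at least {2 * nz}"
        )
    z = np.arange(nz)
    k = np.arange(m)
    basis = np.cos(2.0 * np.pi * np.outer(z, k) / m)  # (nz, M)
    raws = []
    for y in range(ny):
        a = volume.intensity[:, :, y]             # (nz, nx)
        spectra = dc_level + a.T @ basis          # (nx, M)
        raws.append(
            RawBScan(spectra, lateral_pitch_um=volume.voxel_pitch_um[1], meta={"y": y})
        )
    return raws
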
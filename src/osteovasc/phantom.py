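"""Synthetic tibia phantoms with exact ground truth.

The generator emulates a barium-perfused mouse tibia as imaged by
high-resolution µCT: a cortical shell (hollow cylinder along ``z``), a
trabecular lattice of plates and rods inside the metaphyseal part of the
marrow cavity, a branching vascular tree of capsules entering the marrow,
optional blob-like contrast-agent leaks, and a final Gaussian blur plus
additive noise standing in for partial-volume effects and detector noise.

Intensity ordering is background < marrow < bone < vessel, mirroring a
barium-perfused specimen where the contrast agent is the brightest phase
and mineralized bone is intermediate.

Two independent seeds drive the randomness: ``geometry_seed`` fixes the
macro-geometry (trabecular placement, vessel tree, leaks) while ``seed``
drives only the additive noise field, so that the same specimen can be
"re-imaged" with fresh noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import Volume, write_volume

#: Study design: groups = {time point T1, T2} x {placebo P, bevacizumab B,
#: vatalanib V, combination C}, with the animal counts of the original
#: experiment (73 animals total).
DEFAULT_STUDY_DESIGN: dict[str, int] = {
    "T1P": 10, "T1B": 14, "T1V": 10, "T1C": 11,
    "T2P": 7, "T2B": 7, "T2V": 7, "T2C": 7,
}


class PhantomSizingError(ValueError):
    """Requested geometry does not fit inside the voxel grid."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic tibia volume.

    All physical lengths are in micrometres; the grid is isotropic with
    edge ``voxel_size_um``.
    """

    dims: tuple[int, int, int] = (128, 128, 128)
    voxel_size_um: float = 3.5
    cortex_outer_radius_um: float = 180.0
    cortex_thickness_um: float = 35.0
    trabecular_mix: float = 0.5      # fraction of trabecular volume from plates
    trabecular_fill: float = 0.15    # target Tb.BV/Mar.V in the metaphysis
    plate_thickness_um: float = 14.0
    rod_radius_um: float = 10.5
    metaphysis_fraction: float = 0.6
    vessel_root_radius_um: float = 30.0
    branching_levels: int = 6
    radius_decay: float = 0.7
    n_leaks: int = 3
    leak_radius_um: float = 25.0
    leak_offset_um: float = 0.0      # extra surface-to-center gap; >r detaches
    n_lesions: int = 0               # optional osteolytic carving, off by default
    lesion_radius_um: float = 50.0
    intensity_levels: tuple[float, float, float, float] = (20.0, 60.0, 140.0, 220.0)
    blur_sigma_vox: float = 0.8
    noise_sd: float = 8.0
    seed: int = 0
    geometry_seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 64 for d in self.dims):
            raise PhantomSizingError(f"dims must each be >= 64, got {self.dims}")
        for name in ("voxel_size_um", "cortex_outer_radius_um",
                     "cortex_thickness_um", "plate_thickness_um",
                     "rod_radius_um", "vessel_root_radius_um", "leak_radius_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.trabecular_mix <= 1.0:
            raise ValueError("trabecular_mix must be in [0, 1]")
        lv = self.intensity_levels
        if not (lv[0] < lv[1] < lv[2] < lv[3]):
            raise ValueError("intensity_levels must be strictly increasing")
        r_out_vox = self.cortex_outer_radius_um / self.voxel_size_um
        if 2 * (r_out_vox + 2) > min(self.dims[1], self.dims[2]):
            raise PhantomSizingError(
                f"cortex outer radius {self.cortex_outer_radius_um} um "
                f"({r_out_vox:.1f} vox) does not fit in dims {self.dims}"
            )
        if self.cortex_thickness_um >= self.cortex_outer_radius_um:
            raise PhantomSizingError("cortex thickness must be < outer radius")


@dataclass
class PhantomTruth:
    """Exact per-voxel ground truth of a generated phantom."""

    label_volume: np.ndarray          # 0 background, 1 bone, 2 vessel
    true_bvtv: float
    true_vvtv: float
    true_tb_bv_marv: float
    vessel_centerlines: list[tuple[np.ndarray, float]]  # (Nx3 points, radius um)
    compartment_masks: dict[str, np.ndarray]  # tv, marrow, cortical, trabecular
    leak_mask: np.ndarray
    marrow_intensity_mask: np.ndarray  # voxels rendered at marrow level


# ---------------------------------------------------------------------------
# rasterization helpers (bounding-box local, to keep painting cheap)

def _paint_sphere(mask: np.ndarray, center: np.ndarray, radius: float) -> None:
    lo = np.maximum(np.floor(center - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius + 2).astype(int), mask.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= radius ** 2


def _paint_capsule(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                   radius: float) -> None:
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius + 2).astype(int), mask.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij", sparse=True,
    )
    d = p1 - p0
    L2 = float(d @ d)
    vz, vy, vx = zz - p0[0], yy - p0[1], xx - p0[2]
    if L2 < 1e-12:
        t = 0.0
        d2 = vz ** 2 + vy ** 2 + vx ** 2
    else:
        t = np.clip((vz * d[0] + vy * d[1] + vx * d[2]) / L2, 0.0, 1.0)
        d2 = (vz - t * d[0]) ** 2 + (vy - t * d[1]) ** 2 + (vx - t * d[2]) ** 2
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= radius ** 2


def _paint_disc_plate(mask: np.ndarray, center: np.ndarray, normal: np.ndarray,
                      half_thickness: float, half_extent: float) -> None:
    """A disc-shaped plate: slab of given thickness, circular lateral extent."""
    r = half_extent + half_thickness
    lo = np.maximum(np.floor(center - r - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + r + 2).astype(int), mask.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij", sparse=True,
    )
    vz, vy, vx = zz - center[0], yy - center[1], xx - center[2]
    axial = vz * normal[0] + vy * normal[1] + vx * normal[2]
    rad2 = (vz ** 2 + vy ** 2 + vx ** 2) - axial ** 2
    sel = (np.abs(axial) <= half_thickness) & (rad2 <= half_extent ** 2)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= sel


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotate_about_random_azimuth(direction: np.ndarray, angle_rad: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Tilt `direction` by `angle_rad` around a random perpendicular axis."""
    d = direction / np.linalg.norm(direction)
    # perpendicular basis
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, a)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    phi = rng.uniform(0, 2 * np.pi)
    perp = np.cos(phi) * u + np.sin(phi) * v
    return np.cos(angle_rad) * d + np.sin(angle_rad) * perp


# ---------------------------------------------------------------------------

def _build_vessel_tree(spec: PhantomSpec, rng: np.random.Generator,
                       r_in_vox: float, center_yx: np.ndarray
                       ) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Recursive binary tree of capsule segments inside the marrow cylinder.

    Returns (p0, p1, radius_vox) per segment, ordered parent-before-child.
    Branch angles are uniform in [20, 60] degrees off the parent direction;
    the radius shrinks by ``radius_decay`` per level.
    """
    Z = spec.dims[0]
    vs = spec.voxel_size_um
    root_r = spec.vessel_root_radius_um / vs
    segments: list[tuple[np.ndarray, np.ndarray, float]] = []

    def clamp_inside(p: np.ndarray, r: float) -> np.ndarray:
        q = p.copy()
        q[0] = np.clip(q[0], 1.0, Z - 2.0)
        dyx = q[1:] - center_yx
        rad = np.linalg.norm(dyx)
        limit = r_in_vox - r - 1.0
        if rad > limit and rad > 1e-9:
            q[1:] = center_yx + dyx * (limit / rad)
        return q

    start = np.array([Z - 2.0, center_yx[0], center_yx[1]])
    d0 = np.array([-1.0, 0.0, 0.0])
    d0 = _rotate_about_random_azimuth(d0, np.deg2rad(rng.uniform(0, 10)), rng)
    base_len = 0.30 * Z

    def grow(p: np.ndarray, direction: np.ndarray, level: int) -> None:
        if level >= spec.branching_levels:
            return
        r = root_r * spec.radius_decay ** level
        length = base_len * 0.75 ** level
        p1 = clamp_inside(p + direction * length, r)
        segments.append((p.copy(), p1, r))
        for _ in range(2):
            ang = np.deg2rad(rng.uniform(20.0, 60.0))
            child_dir = _rotate_about_random_azimuth(direction, ang, rng)
            grow(p1, child_dir, level + 1)

    grow(clamp_inside(start, root_r), d0, 0)
    return segments


def generate_truth(spec: PhantomSpec) -> PhantomTruth:
    """Ground truth only (no intensity rendering); cheaper than a full
    phantom when only the exact masks or ratios are needed."""
    return _build_truth(spec)


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Generate one grayscale tibia phantom and its exact ground truth.

    Regenerating with the same spec is bit-identical.  The truth ratios are
    plain voxel-count ratios on the ground-truth masks, so the noiseless
    phantom thresholded at the midpoints between the intensity levels
    reproduces the truth labels exactly.
    """
    truth = _build_truth(spec)
    rng_noise = np.random.default_rng(spec.seed)
    lv = spec.intensity_levels
    labels = truth.label_volume
    img = np.full(spec.dims, lv[0], dtype=np.float32)
    img[truth.marrow_intensity_mask] = lv[1]
    img[labels == 1] = lv[2]
    img[labels == 2] = lv[3]
    if spec.blur_sigma_vox > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma_vox).astype(np.float32)
    if spec.noise_sd > 0:
        img = img + rng_noise.normal(0.0, spec.noise_sd, spec.dims).astype(np.float32)
    vol = Volume(img, voxel_size_um=spec.voxel_size_um,
                 provenance=f"phantom(geometry_seed={spec.geometry_seed}, "
                            f"seed={spec.seed})")
    return vol, truth


def _build_truth(spec: PhantomSpec) -> PhantomTruth:
    Z, Y, X = spec.dims
    vs = spec.voxel_size_um
    rng_geo = np.random.default_rng(spec.geometry_seed)

    r_out = spec.cortex_outer_radius_um / vs
    r_in = r_out - spec.cortex_thickness_um / vs
    cy, cx = (Y - 1) / 2.0, (X - 1) / 2.0
    yy, xx = np.ogrid[0:Y, 0:X]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    tv2d = r2 <= r_out ** 2
    in2d = r2 <= r_in ** 2
    shell2d = tv2d & ~in2d

    tv = np.broadcast_to(tv2d, (Z, Y, X)).copy()
    marrow = np.broadcast_to(in2d, (Z, Y, X)).copy()
    cortical = np.broadcast_to(shell2d, (Z, Y, X)).copy()

    # --- trabecular lattice (plates then rods) in the metaphyseal marrow ---
    z_meta = int(round(spec.metaphysis_fraction * Z))
    region = marrow.copy()
    region[z_meta:] = False
    region_count = int(region.sum())
    target = spec.trabecular_fill * region_count
    plate_target = spec.trabecular_mix * target

    trab = np.zeros_like(marrow)
    region_idx = np.argwhere(region)
    ht = spec.plate_thickness_um / vs / 2.0
    he = 4.0 * spec.plate_thickness_um / vs
    rod_r = spec.rod_radius_um / vs
    rod_len = 10.0 * rod_r

    def trab_count() -> int:
        return int(trab.sum())

    for _ in range(400):
        if trab_count() >= plate_target or len(region_idx) == 0:
            break
        c = region_idx[rng_geo.integers(len(region_idx))].astype(float)
        _paint_disc_plate(trab, c, _random_unit(rng_geo), ht, he)
        trab &= region
    for _ in range(600):
        if trab_count() >= target or len(region_idx) == 0:
            break
        c = region_idx[rng_geo.integers(len(region_idx))].astype(float)
        u = _random_unit(rng_geo)
        _paint_capsule(trab, c - u * rod_len / 2, c + u * rod_len / 2, rod_r)
        trab &= region

    # --- vascular tree ---
    segments = _build_vessel_tree(spec, rng_geo, r_in, np.array([cy, cx]))
    vessel = np.zeros_like(marrow)
    centerlines: list[tuple[np.ndarray, float]] = []
    for p0, p1, r in segments:
        _paint_capsule(vessel, p0, p1, r)
        n_pts = max(2, int(np.linalg.norm(p1 - p0)) + 1)
        pts = np.linspace(p0, p1, n_pts)
        centerlines.append((pts, 2 * r * vs))  # store caliber (diameter) in um
    vessel &= marrow

    # --- contrast-agent leaks: spheres seeded on the vessel surface ---
    leak = np.zeros_like(marrow)
    leak_r = spec.leak_radius_um / vs
    leak_off = spec.leak_offset_um / vs
    for _ in range(spec.n_leaks):
        p0, p1, r = segments[rng_geo.integers(len(segments))]
        t = rng_geo.uniform()
        point = p0 + t * (p1 - p0)
        w = _random_unit(rng_geo)
        axis = p1 - p0
        norm = np.linalg.norm(axis)
        if norm > 1e-9:  # offset perpendicular to the local vessel direction
            axis = axis / norm
            w = w - (w @ axis) * axis
            w = w / max(np.linalg.norm(w), 1e-9)
        center = point + w * (r + leak_off)
        _paint_sphere(leak, center, leak_r)
    leak &= marrow
    leak &= ~vessel

    # --- optional osteolytic carving of trabecular bone near vessels ---
    if spec.n_lesions > 0 and segments:
        for _ in range(spec.n_lesions):
            p0, p1, r = segments[rng_geo.integers(len(segments))]
            t = rng_geo.uniform()
            carve = np.zeros_like(trab)
            _paint_sphere(carve, p0 + t * (p1 - p0), spec.lesion_radius_um / vs)
            trab &= ~carve

    trab &= ~vessel  # vessels tunnel through the lattice
    leak &= ~trab    # leaked contrast fills marrow space, not bone
    bone = cortical | trab
    vessel_all = vessel | leak  # leaks share the vessel intensity

    labels = np.zeros(spec.dims, dtype=np.uint8)
    labels[bone] = 1
    labels[vessel_all] = 2
    marrow_bg = marrow & (labels == 0)

    tv_n = int(tv.sum())
    marv_n = int(marrow.sum())
    return PhantomTruth(
        label_volume=labels,
        true_bvtv=float(bone.sum()) / tv_n,
        true_vvtv=float(vessel.sum()) / tv_n,
        true_tb_bv_marv=float(trab.sum()) / marv_n,
        vessel_centerlines=centerlines,
        compartment_masks={
            "tv": tv, "marrow": marrow, "cortical": cortical, "trabecular": trab,
        },
        leak_mask=leak,
        marrow_intensity_mask=marrow_bg,
    )


def midpoint_threshold_labels(vol: Volume, intensity_levels: Iterable[float]
                              ) -> np.ndarray:
    """Oracle segmentation: threshold at midpoints between intensity levels.

    Bins below the marrow/bone midpoint map to background (0); the bone bin
    maps to 1 and the vessel bin to 2.  On a noiseless, unblurred phantom
    this reproduces the truth labels exactly.
    """
    lv = list(intensity_levels)
    m_bone = (lv[1] + lv[2]) / 2.0
    m_vessel = (lv[2] + lv[3]) / 2.0
    out = np.zeros(vol.data.shape, dtype=np.uint8)
    out[vol.data >= m_bone] = 1
    out[vol.data >= m_vessel] = 2
    return out


# ---------------------------------------------------------------------------
# ideal analytic solids used as morphometry oracles

def generate_ideal_shape(kind: str, size_vox: int,
                         thickness_or_radius_vox: float = 3.0) -> Volume:
    """Voxelize an analytic solid for use as a morphometry test input.

    kinds: ``plate`` (slab spanning the full lateral extent, thickness t,
    two-voxel axial margin), ``rod`` (capsule along z, radius r, length
    ``size_vox``), ``sphere`` (ball of radius r centered in a
    ``size_vox``-cube), ``torus`` (solid torus in a cube), ``menger``
    (level-k sponge, ``size_vox`` must be a power of 3, flush with the
    volume so box counts are exactly self-similar).
    """
    t = float(thickness_or_radius_vox)
    if kind == "plate":
        tz = int(round(t))
        shape = (tz + 4, size_vox, size_vox)
        out = np.zeros(shape, dtype=bool)
        out[2:2 + tz, :, :] = True
        return Volume(out)
    if kind == "rod":
        half = int(np.ceil(t)) + 3
        L = size_vox
        shape = (L + 2 * half, 2 * half + 1, 2 * half + 1)
        out = np.zeros(shape, dtype=bool)
        p0 = np.array([half, half, half], dtype=float)
        p1 = np.array([half + L, half, half], dtype=float)
        _paint_capsule(out, p0, p1, t)
        return Volume(out)
    if kind == "sphere":
        if 2 * t + 4 > size_vox:
            raise PhantomSizingError("sphere does not fit with 2-voxel margin")
        out = np.zeros((size_vox,) * 3, dtype=bool)
        c = np.full(3, (size_vox - 1) / 2.0)
        _paint_sphere(out, c, t)
        return Volume(out)
    if kind == "torus":
        R = size_vox / 2.0 - t - 3.0
        if R <= t:
            raise PhantomSizingError("torus does not fit with 2-voxel margin")
        c = (size_vox - 1) / 2.0
        zz, yy, xx = np.ogrid[0:size_vox, 0:size_vox, 0:size_vox]
        rho = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
        out = (rho - R) ** 2 + (zz - c) ** 2 <= t ** 2
        return Volume(out)
    if kind == "menger":
        level = int(round(np.log(size_vox) / np.log(3)))
        if 3 ** level != size_vox:
            raise PhantomSizingError("menger size must be a power of 3")
        out = np.ones((size_vox,) * 3, dtype=bool)
        for lv in range(level):
            step = size_vox // (3 ** (lv + 1))
            # a subcell is removed when >= 2 of its ternary digits are central
            mid = ((np.arange(size_vox) // step % 3) == 1).astype(np.int8)
            count = mid[:, None, None] + mid[None, :, None] + mid[None, None, :]
            out &= count < 2
        return Volume(out)
    raise ValueError(f"unknown shape kind: {kind}")


# ---------------------------------------------------------------------------
# study generation

_NUMERIC_EFFECT_FIELDS = {
    "trabecular_fill", "trabecular_mix", "vessel_root_radius_um",
    "plate_thickness_um", "rod_radius_um", "cortex_thickness_um",
    "radius_decay", "n_leaks", "noise_sd", "branching_levels",
}


@dataclass
class StudySample:
    sample_id: str
    group: str
    spec: PhantomSpec


def generate_study(design: dict[str, int] | None = None,
                   spec_base: PhantomSpec | None = None,
                   effect_map: dict[str, dict[str, float]] | None = None,
                   master_seed: int = 0,
                   jitter_cv: float = 0.08) -> list[StudySample]:
    """Lay out one phantom spec per animal of a grouped study design.

    ``effect_map`` maps group name -> {spec field: multiplier}; multipliers
    are applied on top of per-animal lognormal biological jitter
    (coefficient of variation ``jitter_cv``) on the trabecular fill and the
    vessel root radius.  Each animal's seeds derive deterministically from
    ``(master_seed, group, index)``.
    """
    design = dict(DEFAULT_STUDY_DESIGN) if design is None else dict(design)
    spec_base = PhantomSpec() if spec_base is None else spec_base
    effect_map = {} if effect_map is None else effect_map
    for g in effect_map:
        if g not in design:
            raise ValueError(f"effect_map group {g!r} not in study design")

    samples: list[StudySample] = []
    for gi, (group, n) in enumerate(sorted(design.items())):
        for i in range(n):
            ss = np.random.SeedSequence([master_seed, gi, i])
            geo_seed, noise_seed, jitter_seed = (
                int(s) % (2 ** 31) for s in ss.generate_state(3)
            )
            rng = np.random.default_rng(jitter_seed)
            sigma = np.sqrt(np.log(1 + jitter_cv ** 2))
            overrides: dict[str, object] = {
                "geometry_seed": geo_seed,
                "seed": noise_seed,
                "trabecular_fill": spec_base.trabecular_fill
                * float(rng.lognormal(-sigma ** 2 / 2, sigma)),
                "vessel_root_radius_um": spec_base.vessel_root_radius_um
                * float(rng.lognormal(-sigma ** 2 / 2, sigma)),
            }
            for fld, mult in effect_map.get(group, {}).items():
                if fld not in _NUMERIC_EFFECT_FIELDS:
                    raise ValueError(f"effect_map field {fld!r} not supported")
                base = overrides.get(fld, getattr(spec_base, fld))
                val = base * mult
                if isinstance(getattr(spec_base, fld), int):
                    val = int(round(val))
                overrides[fld] = val
            spec = replace(spec_base, **overrides)
            samples.append(StudySample(f"{group}-{i:02d}", group, spec))
    return samples


def study_manifest(samples: list[StudySample],
                   out_dir: str | None = None) -> pd.DataFrame:
    """Manifest table for a study; optionally materialize volumes to disk."""
    import os

    rows = []
    for s in samples:
        path = ""
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            path = os.path.join(out_dir, f"{s.sample_id}.tif")
            vol, _ = generate_phantom(s.spec)
            write_volume(vol, path)
        rows.append({"sample_id": s.sample_id, "group": s.group,
                     "path": path, "geometry_seed": s.spec.geometry_seed,
                     "seed": s.spec.seed})
    return pd.DataFrame(rows)
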
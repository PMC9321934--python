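"""Reference volumes: total volume, marrow cavity, trabecular/cortical split.

The total volume TV is everything inside the outer contour of the cortical
bone.  It is built slice-wise: on every ``keyslice_step``-th transverse
slice the filled 2D convex hull of the bone pixels is taken, and between
keyslices the hull shape is interpolated by linearly blending the signed
distance maps of the two bounding hulls (thresholded at zero) — a 2.5D
construction that follows the metaphyseal flare without letting a 3D hull
bridge the shaft curvature.

The marrow cavity is obtained by eroding the total volume until the
cortical shell is passed: walking inward from the TV boundary in
one-voxel depth rings, the cortex is the run of bone-majority rings; the
cavity starts at the first ring that is no longer mostly bone.  The
trabecular/cortical split is then a mask intersection: trabecular bone is
the bone inside the cavity, cortical bone the rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

logger = logging.getLogger(__name__)

_CROSS6 = ndimage.generate_binary_structure(3, 1)


class CompartmentError(ValueError):
    pass


@dataclass
class CompartmentSet:
    tv_mask: np.ndarray
    marrow_mask: np.ndarray
    cortical_mask: np.ndarray
    trabecular_mask: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        if (self.marrow_mask & ~self.tv_mask).any():
            raise CompartmentError("marrow must be contained in tv")
        if (self.cortical_mask & self.trabecular_mask).any():
            raise CompartmentError("cortical and trabecular must be disjoint")
        if (self.trabecular_mask & ~self.marrow_mask).any():
            raise CompartmentError("trabecular must be contained in marrow")


def _signed_distance_2d(mask: np.ndarray) -> np.ndarray:
    """Positive inside, negative outside, in pixels."""
    if not mask.any():
        return np.full(mask.shape, -np.inf, dtype=np.float32)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return (inside - outside).astype(np.float32)


def total_volume_envelope(bone_mask: np.ndarray, keyslice_step: int = 50
                          ) -> np.ndarray:
    """Total volume: per-keyslice convex hulls, shape-interpolated between.

    Keyslices are transverse (perpendicular to the long axis, i.e. fixed
    ``z``), taken every ``keyslice_step`` slices plus the last slice.
    Empty keyslices between non-empty ones are interpolated across with a
    warning.  On keyslices the result is exactly the filled hull and
    contains the bone.
    """
    if keyslice_step < 1:
        raise ValueError("keyslice_step must be >= 1")
    bone_mask = bone_mask.astype(bool)
    Z = bone_mask.shape[0]
    keys = sorted(set(range(0, Z, keyslice_step)) | {Z - 1})
    hulls: dict[int, np.ndarray] = {}
    for z in keys:
        sl = bone_mask[z]
        if sl.any():
            hulls[z] = morphology.convex_hull_image(sl)
    nonempty = sorted(hulls)
    if len(nonempty) < 2:
        raise CompartmentError("bone mask non-empty on fewer than 2 keyslices")
    if len(nonempty) < len(keys):
        first, last = nonempty[0], nonempty[-1]
        skipped = [z for z in keys if first < z < last and z not in hulls]
        if skipped:
            logger.warning("empty keyslices %s interpolated across", skipped)

    tv = np.zeros_like(bone_mask)
    sd_cache: dict[int, np.ndarray] = {}

    def sd(z: int) -> np.ndarray:
        if z not in sd_cache:
            sd_cache[z] = _signed_distance_2d(hulls[z])
        return sd_cache[z]

    for z0, z1 in zip(nonempty[:-1], nonempty[1:]):
        for z in range(z0, z1 + 1):
            if z in hulls:
                tv[z] = hulls[z]
                continue
            w = (z - z0) / (z1 - z0)
            tv[z] = (1 - w) * sd(z0) + w * sd(z1) >= 0
    return tv


def marrow_cavity(tv_mask: np.ndarray, bone_mask: np.ndarray,
                  bone_ring_fraction: float = 0.5) -> np.ndarray:
    """Marrow cavity: erode the TV until past the inner cortical contour.

    Per transverse slice, voxels are binned by their depth from the TV
    boundary (2D Euclidean distance).  The cortical shell shows up as the
    consecutive depth-one-voxel rings that are mostly bone (fraction above
    ``bone_ring_fraction``); the first ring that is no longer mostly bone
    straddles the true inner contour, so the cavity starts at that ring's
    mid-depth.  Small cortical perforations do not break the majority rule,
    so the cavity never leaks outside.  The final cavity is the largest
    6-connected 3D component of the per-slice result and includes the
    trabecular bone inside it.
    """
    tv_mask = tv_mask.astype(bool)
    bone_mask = bone_mask.astype(bool)
    if (bone_mask & ~tv_mask).any():
        n = int((bone_mask & ~tv_mask).sum())
        logger.warning("clipping %d bone voxels outside tv", n)
        bone_mask = bone_mask & tv_mask

    marrow = np.zeros_like(tv_mask)
    for z in range(tv_mask.shape[0]):
        tv2 = tv_mask[z]
        if not tv2.any():
            continue
        depth = ndimage.distance_transform_edt(tv2)
        max_d = int(np.ceil(depth.max()))
        bone2 = bone_mask[z]
        t = None
        prev_frac = 1.0
        for d in range(1, max_d + 1):
            ring = (depth > d - 1) & (depth <= d)
            n_ring = int(ring.sum())
            if n_ring == 0:
                break
            frac = int((ring & bone2).sum()) / n_ring
            if frac < bone_ring_fraction:
                # sub-voxel crossing of the 0.5 bone fraction between the
                # previous (mostly-bone) ring and this one
                t = (d - 1) + (prev_frac - bone_ring_fraction) \
                    / max(prev_frac - frac, 1e-9)
                break
            prev_frac = frac
        if t is not None:
            marrow[z] = depth > t
    if not marrow.any():
        raise CompartmentError("no marrow cavity found (solid bone?)")
    labels, n = ndimage.label(marrow, structure=_CROSS6)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        marrow = labels == (1 + int(np.argmax(sizes)))
    return marrow


def split_trabecular_cortical(bone_mask: np.ndarray, marrow_mask: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Trabecular = bone inside the cavity; cortical = the rest of the bone."""
    bone_mask = bone_mask.astype(bool)
    marrow_mask = marrow_mask.astype(bool)
    trabecular = bone_mask & marrow_mask
    cortical = bone_mask & ~marrow_mask
    return trabecular, cortical


def derive_compartments(bone_mask: np.ndarray, voxel_size_um: float,
                        keyslice_step: int = 50) -> CompartmentSet:
    """Full chain: TV envelope -> marrow cavity -> trabecular/cortical."""
    tv = total_volume_envelope(bone_mask, keyslice_step)
    marrow = marrow_cavity(tv, bone_mask)
    trab, cort = split_trabecular_cortical(bone_mask, marrow)
    return CompartmentSet(tv_mask=tv, marrow_mask=marrow, cortical_mask=cort,
                          trabecular_mask=trab, voxel_size_um=voxel_size_um)
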
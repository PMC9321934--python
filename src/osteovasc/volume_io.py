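"""Volume container and TIFF + sidecar I/O.

Volumes are 3D scalar grids in fixed ``(z, y, x)`` axis order, with ``z``
the anatomical long axis after preprocessing.  Voxels are isotropic; the
physical edge length in micrometres travels with the array in a YAML
sidecar so that every micrometre conversion downstream uses a single
number.  Label volumes use an 8-bit code table:

====  ==========
code  meaning
====  ==========
0     background
1     bone
2     vessel
3     cortical bone
4     trabecular bone
5     marrow
====  ==========
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace

import numpy as np
import tifffile
import yaml

logger = logging.getLogger(__name__)

#: default isotropic voxel edge (µm), matching the detector pixel size of
#: the synchrotron acquisitions this pipeline was designed around
DEFAULT_VOXEL_SIZE_UM = 3.5

# label codes
BACKGROUND, BONE, VESSEL = 0, 1, 2
CORTICAL, TRABECULAR, MARROW = 3, 4, 5


@dataclass
class Volume:
    """A 3D scalar grid with isotropic voxel size in micrometres."""

    data: np.ndarray
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("all dims must be >= 1")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um * 1e-3) ** 3

    def with_data(self, data: np.ndarray, provenance: str | None = None) -> "Volume":
        return replace(
            self, data=data,
            provenance=self.provenance if provenance is None else provenance,
        )


def _sidecar_path(path: str) -> str:
    base, _ = os.path.splitext(path)
    return base + ".yaml"


def write_volume(vol: Volume, path: str) -> None:
    """Write a volume as a multi-page TIFF plus a YAML sidecar.

    The sidecar records voxel size, axis order and provenance.  Writing is
    atomic with respect to partial TIFFs: the array is serialized to a
    temporary file which is renamed into place.
    """
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    tmp = path + ".part"
    try:
        tifffile.imwrite(tmp, vol.data, photometric="minisblack")
    except Exception:
        if os.path.exists(tmp):
            os.remove(tmp)
        raise
    os.replace(tmp, path)
    sidecar = {
        "voxel_size_um": float(vol.voxel_size_um),
        "axis_order": "zyx",
        "dtype": str(vol.data.dtype),
        "shape": [int(s) for s in vol.data.shape],
        "provenance": vol.provenance,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(sidecar, fh)


def read_volume(path: str) -> Volume:
    """Read a TIFF stack; voxel size comes from the YAML sidecar.

    A missing sidecar is tolerated: the voxel size falls back to
    3.5 µm with a logged warning, since that is the native resolution the
    pipeline's defaults are tuned for.
    """
    if not os.path.exists(path):
        raise IOError(f"no such volume: {path}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    voxel_size = DEFAULT_VOXEL_SIZE_UM
    provenance = ""
    sc = _sidecar_path(path)
    if os.path.exists(sc):
        with open(sc) as fh:
            meta = yaml.safe_load(fh) or {}
        voxel_size = float(meta.get("voxel_size_um", DEFAULT_VOXEL_SIZE_UM))
        provenance = meta.get("provenance", "")
    else:
        logger.warning(
            "no sidecar for %s; assuming voxel size %.2f um", path, DEFAULT_VOXEL_SIZE_UM
        )
    return Volume(data=data, voxel_size_um=voxel_size, provenance=provenance)
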
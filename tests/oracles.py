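"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity by a different route than the package:
local thickness by exhaustive maximal-sphere search, the Euler
characteristic from the cell counts of the cubical complex, and box
counts by direct enumeration.  They are deliberately slow and simple.
"""

import numpy as np


def brute_local_thickness(mask: np.ndarray) -> np.ndarray:
    """Exhaustive maximal-inscribed-sphere thickness map.

    Same sphere convention as the package (radius d-1/2 with d the
    distance to the nearest background voxel center, voxel membership
    |v-c| <= d) but computed by brute-force double loops over voxel
    pairs, with the distance-to-background itself found by scanning every
    background voxel.  Out-of-grid space counts as foreground.
    """
    mask = mask.astype(bool)
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    if len(bg) == 0:
        raise ValueError("no background: thickness unbounded")
    # distance to nearest background center, exhaustively
    d = np.empty(len(fg))
    for i, c in enumerate(fg):
        d[i] = np.sqrt(((bg - c) ** 2).sum(axis=1).min())
    th = np.zeros(mask.shape, dtype=float)
    for c, dc in zip(fg, d):
        cover = ((fg - c) ** 2).sum(axis=1) <= dc * dc + 1e-9
        val = 2 * (dc - 0.5)
        sel = fg[cover]
        cur = th[sel[:, 0], sel[:, 1], sel[:, 2]]
        th[sel[:, 0], sel[:, 1], sel[:, 2]] = np.maximum(cur, val)
    return th


def cubical_euler(mask: np.ndarray) -> int:
    """Euler characteristic of the union of closed unit cubes.

    chi = V - E + F - C over the grid cells touched by at least one
    foreground voxel; topologically this is the 26-connected foreground.
    """
    m = np.pad(mask.astype(bool), 1)

    def touched(axes):
        """Grid cells of codimension len(axes): a cell is in the complex if
        any incident voxel is foreground (OR over shifts along `axes`)."""
        out = m
        for ax in axes:
            out = out[tuple(slice(None) if a != ax else slice(1, None)
                            for a in range(3))] | \
                  out[tuple(slice(None) if a != ax else slice(None, -1)
                            for a in range(3))]
        return int(out.sum())

    c = int(m.sum())                      # 3-cells: voxels themselves
    f = sum(touched([ax]) for ax in range(3))
    e = sum(touched([a, b]) for a, b in ((0, 1), (0, 2), (1, 2)))
    v = touched([0, 1, 2])
    return v - e + f - c


def direct_box_counts(target: np.ndarray, sizes) -> list[int]:
    """Box occupancy by explicit python loops over the box grid."""
    counts = []
    pts = np.argwhere(target)
    for lam in sizes:
        boxes = {tuple(p // lam) for p in pts}
        counts.append(len(boxes))
    return counts
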
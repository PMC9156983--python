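"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they check: connected
components by explicit flood fill, erosion by per-voxel neighbor scanning.
"""

from collections import deque

import numpy as np

# All 26 neighbor offsets in 3-D.
OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]

OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def flood_fill_components(mask):
    """26-connected component voxel counts by breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    nz, ny, nx = mask.shape
    sizes = []
    for z, y, x in zip(*np.nonzero(mask)):
        if visited[z, y, x]:
            continue
        queue = deque([(z, y, x)])
        visited[z, y, x] = True
        size = 0
        while queue:
            cz, cy, cx = queue.popleft()
            size += 1
            for dz, dy, dx in OFFSETS_26:
                pz, py, px = cz + dz, cy + dy, cx + dx
                if 0 <= pz < nz and 0 <= py < ny and 0 <= px < nx:
                    if mask[pz, py, px] and not visited[pz, py, px]:
                        visited[pz, py, px] = True
                        queue.append((pz, py, px))
        sizes.append(size)
    return sorted(sizes)


def erode_once_6(mask):
    """One layer of 6-connected erosion; outside the array is background."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    nz, ny, nx = mask.shape
    for z, y, x in zip(*np.nonzero(mask)):
        keep = True
        for dz, dy, dx in OFFSETS_6:
            pz, py, px = z + dz, y + dy, x + dx
            if not (0 <= pz < nz and 0 <= py < ny and 0 <= px < nx) or not mask[pz, py, px]:
                keep = False
                break
        out[z, y, x] = keep
    return out


def draw_ellipse_2d(shape, center, semi_axes, angle_rad=0.0):
    """Boolean raster of a filled rotated ellipse (pixel-center rule)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dr = rr - center[0]
    dc = cc - center[1]
    u = np.cos(angle_rad) * dr + np.sin(angle_rad) * dc
    v = -np.sin(angle_rad) * dr + np.cos(angle_rad) * dc
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def solid_cylinder(shape, axis_len, radius, axis=0):
    """Boolean voxelization of a solid cylinder along ``axis``, centered on a
    voxel center (integer coordinates) to avoid worst-case digitization."""
    grids = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(float)
    others = [i for i in range(3) if i != axis]
    centers = [shape[i] // 2 for i in range(3)]
    r2 = (grids[others[0]] - centers[others[0]]) ** 2 + (
        grids[others[1]] - centers[others[1]]
    ) ** 2
    along = grids[axis]
    lo = (shape[axis] - axis_len) // 2
    return (r2 <= radius**2) & (along >= lo) & (along < lo + axis_len)
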
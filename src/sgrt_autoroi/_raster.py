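"""Orthographic coronal depth rasterization of triangle meshes.

The patient coordinate frame is x = patient-left positive, y = anterior
positive, z = superior positive, all in mm.  The projection is along the
anterior-posterior (y) axis onto the x-z (coronal) plane.  Images follow the
radiographic convention: row 0 is the most superior row, column 0 is the
most patient-right column.  The pixel with index (r, c) has its center at

    x = x0 + (c + 0.5) * spacing
    z = z_top - (r + 0.5) * spacing

where (x0, z_top) is the outer edge of pixel (0, 0).
"""

from __future__ import annotations

import numpy as np
from numba import njit

BACKGROUND_DEPTH = -1.0e30


@njit(cache=True)
def _depth_buffer(verts, faces, x0, z_top, spacing, n_rows, n_cols):  # pragma: no cover - numba
    depth = np.full((n_rows, n_cols), BACKGROUND_DEPTH)
    for k in range(faces.shape[0]):
        i0 = faces[k, 0]
        i1 = faces[k, 1]
        i2 = faces[k, 2]
        ax, ay, az = verts[i0, 0], verts[i0, 1], verts[i0, 2]
        bx, by, bz = verts[i1, 0], verts[i1, 1], verts[i1, 2]
        cx, cy, cz = verts[i2, 0], verts[i2, 1], verts[i2, 2]

        den = (bz - cz) * (ax - cx) + (cx - bx) * (az - cz)
        if abs(den) < 1e-12:
            continue

        min_x = min(ax, min(bx, cx))
        max_x = max(ax, max(bx, cx))
        min_z = min(az, min(bz, cz))
        max_z = max(az, max(bz, cz))

        c_lo = int(np.floor((min_x - x0) / spacing - 0.5))
        c_hi = int(np.ceil((max_x - x0) / spacing - 0.5))
        r_lo = int(np.floor((z_top - max_z) / spacing - 0.5))
        r_hi = int(np.ceil((z_top - min_z) / spacing - 0.5))
        if c_lo < 0:
            c_lo = 0
        if r_lo < 0:
            r_lo = 0
        if c_hi > n_cols - 1:
            c_hi = n_cols - 1
        if r_hi > n_rows - 1:
            r_hi = n_rows - 1

        for r in range(r_lo, r_hi + 1):
            z = z_top - (r + 0.5) * spacing
            for c in range(c_lo, c_hi + 1):
                x = x0 + (c + 0.5) * spacing
                l1 = ((bz - cz) * (x - cx) + (cx - bx) * (z - cz)) / den
                l2 = ((cz - az) * (x - cx) + (ax - cx) * (z - cz)) / den
                l3 = 1.0 - l1 - l2
                if l1 >= -1e-9 and l2 >= -1e-9 and l3 >= -1e-9:
                    y = l1 * ay + l2 * by + l3 * cy
                    if y > depth[r, c]:
                        depth[r, c] = y
    return depth


def project_depth(vertices: np.ndarray, faces: np.ndarray, x0: float,
                  z_top: float, spacing: float, n_rows: int, n_cols: int) -> np.ndarray:
    """Max-y (frontmost surface) depth buffer; BACKGROUND_DEPTH outside the silhouette."""
    verts = np.ascontiguousarray(vertices, dtype=np.float64)
    tris = np.ascontiguousarray(faces, dtype=np.int64)
    return _depth_buffer(verts, tris, float(x0), float(z_top), float(spacing),
                         int(n_rows), int(n_cols))
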
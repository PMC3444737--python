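"""Legacy-ASCII VTK output for point clouds with scalar/vector data.

Legacy POLYDATA files are human-diffable and readable by ParaView/VisIt;
they carry the node cloud as vertices with per-node fields such as the
transmembrane potential of a snapshot or the fiber vectors.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_vtk_points"]


def write_vtk_points(path, positions, scalars=None, vectors=None, title="efgmep"):
    """Write a legacy VTK POLYDATA point cloud.

    Parameters
    ----------
    positions : (N, d) array, d <= 3 (padded with zeros).
    scalars : dict name -> (N,) array, optional per-node scalar fields.
    vectors : dict name -> (N, 3) array, optional per-node vector fields.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    n = pos.shape[0]
    if pos.shape[1] < 3:
        pos = np.column_stack([pos, np.zeros((n, 3 - pos.shape[1]))])
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines.extend(" ".join(f"{v:.10g}" for v in row) for row in pos)
    lines.append(f"VERTICES {n} {2 * n}")
    lines.extend(f"1 {i}" for i in range(n))
    scalars = scalars or {}
    vectors = vectors or {}
    if scalars or vectors:
        lines.append(f"POINT_DATA {n}")
    for name, data in scalars.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{float(v):.10g}" for v in np.asarray(data))
    for name, data in vectors.items():
        arr = np.atleast_2d(np.asarray(data, dtype=float))
        if arr.shape[1] < 3:
            arr = np.column_stack([arr, np.zeros((n, 3 - arr.shape[1]))])
        lines.append(f"VECTORS {name} double")
        lines.extend(" ".join(f"{v:.10g}" for v in row) for row in arr)
    Path(path).write_text("\n".join(lines) + "\n")
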
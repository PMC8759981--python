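"""Plain-text field snapshots: legacy ASCII VTK structured points + PNG maps.

The writer emits the minimal legacy VTK a viewer (ParaView/VisIt) needs:
one ``STRUCTURED_POINTS`` dataset with cell data arrays ``temperature``
(degC, NaN on exterior cells) and ``tissue`` (label codes).  The matching
reader exists so rendered PNGs can be produced from snapshot files alone.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import LabelGrid
from .bioheat_solver import TemperatureField

__all__ = ["write_vtk", "read_vtk", "render_png"]


def write_vtk(path, field: TemperatureField) -> Path:
    grid = field.grid
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    h = grid.spacing
    lines = [
        "# vtk DataFile Version 3.0",
        f"cordcool temperature field t={field.time:.3f}s",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        # points grid: (nx+1, ny+1, 1) nodes so cells carry the data
        f"DIMENSIONS {grid.nx + 1} {grid.ny + 1} 1",
        f"ORIGIN {grid.origin[0]:.9g} {grid.origin[1]:.9g} 0",
        f"SPACING {h:.9g} {h:.9g} {h:.9g}",
        f"CELL_DATA {grid.nx * grid.ny}",
        "SCALARS temperature float 1",
        "LOOKUP_TABLE default",
    ]
    temp = np.asarray(field.values, dtype=float).ravel(order="C")
    lines.extend(" ".join(f"{v:.6f}" for v in temp[i:i + 9])
                 for i in range(0, len(temp), 9))
    lines.append("SCALARS tissue int 1")
    lines.append("LOOKUP_TABLE default")
    lab = grid.labels.ravel(order="C")
    lines.extend(" ".join(str(int(v)) for v in lab[i:i + 9])
                 for i in range(0, len(lab), 9))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk(path) -> TemperatureField:
    """Read a snapshot written by :func:`write_vtk`."""
    tokens_meta = {}
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    nx = ny = None
    origin = (0.0, 0.0)
    spacing = 1.0
    time = 0.0
    arrays: dict[str, np.ndarray] = {}
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("cordcool temperature field"):
            time = float(line.split("t=")[1].rstrip("s"))
        elif line.startswith("DIMENSIONS"):
            _, sx, sy, _ = line.split()
            nx, ny = int(sx) - 1, int(sy) - 1
        elif line.startswith("ORIGIN"):
            _, ox, oy, _ = line.split()
            origin = (float(ox), float(oy))
        elif line.startswith("SPACING"):
            spacing = float(line.split()[1])
        elif line.startswith("SCALARS"):
            name, dtype = line.split()[1:3]
            count = nx * ny
            vals: list[float] = []
            i += 2  # skip LOOKUP_TABLE
            while len(vals) < count:
                vals.extend(float(v) for v in lines[i].split())
                i += 1
            arrays[name] = np.asarray(vals).reshape(ny, nx)
            continue
        i += 1
    labels = arrays["tissue"].astype(np.uint8)
    grid = LabelGrid(nx=nx, ny=ny, spacing=spacing, origin=origin,
                     labels=labels)
    return TemperatureField(grid=grid, values=arrays["temperature"],
                            time=time)


def render_png(field: TemperatureField, path, *, vmin: float = 18.0,
               vmax: float = 38.0, dpi: int = 150) -> Path:
    """Render a temperature map with a fixed colour range so frames from
    different times are directly comparable."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = field.grid
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    extent_mm = [grid.origin[0] * 1e3,
                 (grid.origin[0] + grid.nx * grid.spacing) * 1e3,
                 grid.origin[1] * 1e3,
                 (grid.origin[1] + grid.ny * grid.spacing) * 1e3]
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(field.values, origin="lower", extent=extent_mm,
                   vmin=vmin, vmax=vmax, cmap="inferno")
    ax.contour(grid.labels, levels=np.arange(0.5, 11), colors="w",
               linewidths=0.3, extent=extent_mm, origin="lower")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(f"t = {field.time:.0f} s")
    fig.colorbar(im, ax=ax, label="temperature (degC)")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path
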
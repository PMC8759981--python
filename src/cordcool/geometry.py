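"""Parametric 2D axial anatomy and its raster representation.

The cross-section is assembled from geometric primitives (ellipses,
rectangles, a rounded-rectangle torso outline) painted back-to-front onto a
uniform square-cell raster: the torso and subcutaneous band first, then
viscera, vertebral bone, and finally the nested canal structures
(yellow ligament, epidural fat, dura, cerebrospinal fluid, spinal cord)
with the cooling catheter centred on the dorsal midline of the epidural
space.  Cell membership is decided by the cell *center*; later primitives
overwrite earlier ones, so every non-exterior cell ends up with exactly one
tissue label.

Axes: x is transverse (positive to the anatomical left), y is
antero-posterior with +y dorsal (towards the skin of the back, where the
catheter sits).  The cord ellipse is centred at the origin.  All lengths
are metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import ndimage

from .tissue_db import TISSUE_NAMES

__all__ = [
    "AnatomyParams",
    "LabelGrid",
    "Ellipse",
    "Rectangle",
    "RoundedRectangle",
    "ResolutionError",
    "ConstructionError",
    "EXTERIOR",
    "LABEL_CODES",
    "CODE_TO_NAME",
    "build_anatomy",
    "rasterize_primitive",
    "probe_index",
]

#: Raster code for cells outside the torso.
EXTERIOR = 0
#: tissue identifier -> raster code (1..10); 0 is exterior.
LABEL_CODES = {name: i + 1 for i, name in enumerate(TISSUE_NAMES)}
CODE_TO_NAME = {code: name for name, code in LABEL_CODES.items()}
CODE_TO_NAME[EXTERIOR] = "exterior"


class ResolutionError(ValueError):
    """Grid spacing too coarse to resolve a tissue layer."""


class ConstructionError(ValueError):
    """Anatomy primitives are inconsistent (overlap/out-of-domain/empty)."""


# ---------------------------------------------------------------------------
# primitives

@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]
    semiaxes: tuple[float, float]

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        a, b = self.semiaxes
        if a <= 0.0 or b <= 0.0:
            return np.zeros(np.broadcast(x, y).shape, dtype=bool)
        return ((x - self.center[0]) / a) ** 2 + ((y - self.center[1]) / b) ** 2 <= 1.0

    def bounds(self):
        (cx, cy), (a, b) = self.center, self.semiaxes
        return cx - a, cx + a, cy - b, cy + b


@dataclass(frozen=True)
class Rectangle:
    center: tuple[float, float]
    width: float
    height: float

    def contains(self, x, y):
        return (np.abs(x - self.center[0]) <= self.width / 2) & (
            np.abs(y - self.center[1]) <= self.height / 2)

    def bounds(self):
        cx, cy = self.center
        return (cx - self.width / 2, cx + self.width / 2,
                cy - self.height / 2, cy + self.height / 2)


@dataclass(frozen=True)
class RoundedRectangle:
    """Axis-aligned rectangle with quarter-ellipse (circular) corners."""

    center: tuple[float, float]
    width: float
    height: float
    corner_radius: float = 0.0

    def contains(self, x, y):
        hx, hy = self.width / 2, self.height / 2
        r = min(self.corner_radius, hx, hy)
        dx = np.maximum(np.abs(x - self.center[0]) - (hx - r), 0.0)
        dy = np.maximum(np.abs(y - self.center[1]) - (hy - r), 0.0)
        inside_box = (np.abs(x - self.center[0]) <= hx) & (
            np.abs(y - self.center[1]) <= hy)
        return inside_box & (dx ** 2 + dy ** 2 <= r ** 2 + 1e-300)

    def bounds(self):
        cx, cy = self.center
        return (cx - self.width / 2, cx + self.width / 2,
                cy - self.height / 2, cy + self.height / 2)


# ---------------------------------------------------------------------------
# anatomy parameters

@dataclass(frozen=True)
class AnatomyParams:
    """Dimensions of the parametric cross-section (metres).

    Defaults describe an adult thoracic level: a 10 x 8 mm elliptical cord
    inside a 2.5 mm cerebrospinal-fluid annulus, 1 mm dura, 3 mm epidural
    fat and a 4 mm ligament ring, all enclosed by vertebral bone, with the
    catheter (outer radius 1.5 mm, lumen radius 1.0 mm) on the dorsal
    epidural midline.  They are deliberate, tunable estimates: the governing
    dimensions a user may want to vary are the annulus thicknesses between
    catheter and cord.
    """

    domain_width: float = 0.300
    domain_height: float = 0.250
    cord_semiaxes: tuple[float, float] = (0.005, 0.004)
    csf_annulus_thickness: float = 0.0025
    dura_thickness: float = 0.001
    epidural_thickness: float = 0.003
    yellow_ligament_thickness: float = 0.004
    vertebral_body_semiaxes: tuple[float, float] = (0.022, 0.015)
    posterior_arch_thickness: float = 0.008
    subcutaneous_thickness: float = 0.010
    viscera_center: tuple[float, float] = (0.0, -0.060)
    viscera_semiaxes: tuple[float, float] = (0.100, 0.042)
    catheter_outer_radius: float = 0.0015
    catheter_lumen_radius: float = 0.0010
    catheter_dorsal_offset: float = 0.0015
    torso_margin: float = 0.002
    torso_corner_radius: float = 0.040

    # derived outer semi-axes of the nested canal ellipses -----------------
    @property
    def csf_outer(self) -> tuple[float, float]:
        a, b = self.cord_semiaxes
        t = self.csf_annulus_thickness
        return a + t, b + t

    @property
    def dura_outer(self) -> tuple[float, float]:
        a, b = self.csf_outer
        return a + self.dura_thickness, b + self.dura_thickness

    @property
    def epidural_outer(self) -> tuple[float, float]:
        a, b = self.dura_outer
        return a + self.epidural_thickness, b + self.epidural_thickness

    @property
    def ligament_outer(self) -> tuple[float, float]:
        a, b = self.epidural_outer
        t = self.yellow_ligament_thickness
        return a + t, b + t

    @property
    def arch_outer(self) -> tuple[float, float]:
        a, b = self.ligament_outer
        t = self.posterior_arch_thickness
        return a + t, b + t

    @property
    def catheter_center(self) -> tuple[float, float]:
        return (0.0, self.dura_outer[1] + self.catheter_dorsal_offset)

    def validate(self) -> None:
        lengths = {
            "domain_width": self.domain_width,
            "domain_height": self.domain_height,
            "cord_semiaxes[0]": self.cord_semiaxes[0],
            "cord_semiaxes[1]": self.cord_semiaxes[1],
            "csf_annulus_thickness": self.csf_annulus_thickness,
            "dura_thickness": self.dura_thickness,
            "epidural_thickness": self.epidural_thickness,
            "yellow_ligament_thickness": self.yellow_ligament_thickness,
            "vertebral_body_semiaxes[0]": self.vertebral_body_semiaxes[0],
            "vertebral_body_semiaxes[1]": self.vertebral_body_semiaxes[1],
            "posterior_arch_thickness": self.posterior_arch_thickness,
            "subcutaneous_thickness": self.subcutaneous_thickness,
            "catheter_outer_radius": self.catheter_outer_radius,
            "catheter_lumen_radius": self.catheter_lumen_radius,
            "catheter_dorsal_offset": self.catheter_dorsal_offset,
        }
        for name, value in lengths.items():
            if value <= 0:
                raise ConstructionError(f"{name} must be > 0 (got {value})")
        if self.catheter_lumen_radius >= self.catheter_outer_radius:
            raise ConstructionError(
                "catheter_lumen_radius must be smaller than "
                "catheter_outer_radius")
        if self.catheter_outer_radius > self.epidural_thickness:
            raise ConstructionError(
                "catheter does not fit: catheter_outer_radius "
                f"({self.catheter_outer_radius}) exceeds epidural_thickness "
                f"({self.epidural_thickness})")


# ---------------------------------------------------------------------------
# label grid

@dataclass
class LabelGrid:
    """Uniform square-cell raster of tissue labels.

    ``labels`` is a (ny, nx) uint8 array of codes (0 = exterior,
    1..10 = tissues, see :data:`LABEL_CODES`); ``lumen_mask`` flags the
    catheter-lumen cells on which the coolant boundary condition acts.
    ``origin`` is the lower-left *corner* of the domain; cell (iy, ix) has
    its center at ``origin + (ix + 0.5, iy + 0.5) * spacing``.
    """

    nx: int
    ny: int
    spacing: float
    origin: tuple[float, float]
    labels: np.ndarray
    lumen_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.shape != (self.ny, self.nx):
            raise ValueError("labels shape does not match (ny, nx)")
        if self.lumen_mask is None:
            self.lumen_mask = np.zeros((self.ny, self.nx), dtype=bool)

    @classmethod
    def empty(cls, nx: int, ny: int, spacing: float,
              origin: tuple[float, float] = (0.0, 0.0)) -> "LabelGrid":
        return cls(nx=nx, ny=ny, spacing=spacing, origin=origin,
                   labels=np.zeros((ny, nx), dtype=np.uint8))

    # -- coordinates -------------------------------------------------------
    @property
    def xc(self) -> np.ndarray:
        """x coordinates of cell centers, shape (nx,)."""
        return self.origin[0] + (np.arange(self.nx) + 0.5) * self.spacing

    @property
    def yc(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.ny) + 0.5) * self.spacing

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.xc, self.yc)

    @property
    def active(self) -> np.ndarray:
        return self.labels != EXTERIOR

    def skin_mask(self) -> np.ndarray:
        """Active cells with at least one 4-neighbour exterior cell."""
        ext = ~self.active
        pad = np.pad(ext, 1, constant_values=False)
        near_ext = (pad[:-2, 1:-1] | pad[2:, 1:-1]
                    | pad[1:-1, :-2] | pad[1:-1, 2:])
        return self.active & near_ext

    # -- lookup ------------------------------------------------------------
    def index_at(self, point: tuple[float, float]) -> tuple[int, int]:
        x, y = point
        ix = int(np.floor((x - self.origin[0]) / self.spacing))
        iy = int(np.floor((y - self.origin[1]) / self.spacing))
        if not (0 <= ix < self.nx and 0 <= iy < self.ny):
            raise IndexError(f"point {point} lies outside the domain")
        return iy, ix

    def label_name(self, iy: int, ix: int) -> str:
        return CODE_TO_NAME[int(self.labels[iy, ix])]

    def region_centroid(self, tissue: str) -> tuple[float, float]:
        mask = self.labels == LABEL_CODES[tissue]
        if not mask.any():
            raise ConstructionError(f"tissue {tissue!r} has no cells")
        iy, ix = np.nonzero(mask)
        return (float(self.xc[ix].mean()), float(self.yc[iy].mean()))

    def cord_center(self) -> tuple[int, int]:
        """Index of the canonical probe cell: the cord-region centroid."""
        return self.index_at(self.region_centroid("spinal_cord"))

    def area(self, tissue: str) -> float:
        """Rasterized area of a tissue class, m^2."""
        return float((self.labels == LABEL_CODES[tissue]).sum()) * self.spacing ** 2


# ---------------------------------------------------------------------------
# rasterization

def rasterize_primitive(shape, grid: LabelGrid, label: str,
                        *, check_domain: bool = True) -> LabelGrid:
    """Paint ``shape`` onto ``grid`` in-place (painter's order).

    Cells whose *centers* fall inside the shape receive ``label``; earlier
    labels underneath are overwritten.  Returns the grid for chaining.
    """
    if label not in LABEL_CODES:
        raise KeyError(f"unknown tissue label {label!r}")
    if check_domain:
        x0, x1, y0, y1 = shape.bounds()
        gx0, gy0 = grid.origin
        gx1 = gx0 + grid.nx * grid.spacing
        gy1 = gy0 + grid.ny * grid.spacing
        if x0 < gx0 - 1e-12 or x1 > gx1 + 1e-12 or y0 < gy0 - 1e-12 or y1 > gy1 + 1e-12:
            raise ConstructionError(
                f"shape {shape} extends outside the domain "
                f"[{gx0}, {gx1}] x [{gy0}, {gy1}]")
    X, Y = grid.center_mesh()
    grid.labels[shape.contains(X, Y)] = LABEL_CODES[label]
    return grid


def probe_index(grid: LabelGrid, point: tuple[float, float]) -> tuple[int, int]:
    """Cell index (iy, ix) of the cell containing ``point``.

    Raises ``IndexError`` when the point lies outside the domain.
    """
    return grid.index_at(point)


# ---------------------------------------------------------------------------
# anatomy builder

def build_anatomy(params: AnatomyParams | None = None,
                  spacing: float = 0.001) -> LabelGrid:
    """Rasterize the parametric anatomy onto a fresh grid.

    Enforces that every tissue annulus is at least one cell thick (the
    sub-millimetre catheter wall is exempt: when unresolved it is handled
    by the solver as a sub-grid interface resistance), paints all
    primitives back-to-front, places the catheter on the dorsal epidural
    midline, and verifies the structural invariants (all ten classes
    present, a single connected lumen, exterior bordered only by
    subcutaneous tissue).
    """
    p = params or AnatomyParams()
    p.validate()
    min_layer = min(p.csf_annulus_thickness, p.dura_thickness,
                    p.epidural_thickness, p.yellow_ligament_thickness,
                    p.posterior_arch_thickness, p.subcutaneous_thickness)
    if spacing > min_layer + 1e-12:
        raise ResolutionError(
            f"spacing {spacing} m cannot resolve the thinnest tissue layer "
            f"({min_layer} m); refine the grid or thicken the layer")

    nx = int(round(p.domain_width / spacing))
    ny = int(round(p.domain_height / spacing))
    grid = LabelGrid.empty(nx, ny, spacing,
                           origin=(-p.domain_width / 2, -p.domain_height / 2))

    torso_w = p.domain_width - 2 * p.torso_margin
    torso_h = p.domain_height - 2 * p.torso_margin
    torso = RoundedRectangle((0.0, 0.0), torso_w, torso_h,
                             p.torso_corner_radius)
    inner = RoundedRectangle(
        (0.0, 0.0),
        torso_w - 2 * p.subcutaneous_thickness,
        torso_h - 2 * p.subcutaneous_thickness,
        max(p.torso_corner_radius - p.subcutaneous_thickness, 0.0))

    rasterize_primitive(torso, grid, "subcutaneous_tissue")
    rasterize_primitive(inner, grid, "muscle")
    rasterize_primitive(Ellipse(p.viscera_center, p.viscera_semiaxes),
                        grid, "splanchnic_tissue")

    # vertebra: posterior arch ring around the canal plus the vertebral body
    # ventral to it (they overlap, forming one contiguous bone region)
    rasterize_primitive(Ellipse((0.0, 0.0), p.arch_outer), grid, "spine")
    vb_cy = -(p.ligament_outer[1] + p.vertebral_body_semiaxes[1] / 2)
    rasterize_primitive(Ellipse((0.0, vb_cy), p.vertebral_body_semiaxes),
                        grid, "spine")

    rasterize_primitive(Ellipse((0.0, 0.0), p.ligament_outer),
                        grid, "yellow_ligament")
    rasterize_primitive(Ellipse((0.0, 0.0), p.epidural_outer),
                        grid, "epidural_space")
    rasterize_primitive(Ellipse((0.0, 0.0), p.dura_outer), grid, "dura")
    rasterize_primitive(Ellipse((0.0, 0.0), p.csf_outer),
                        grid, "cerebrospinal_fluid")
    rasterize_primitive(Ellipse((0.0, 0.0), p.cord_semiaxes),
                        grid, "spinal_cord")

    # catheter on the dorsal epidural midline
    c = p.catheter_center
    r_out = Ellipse(c, (p.catheter_outer_radius, p.catheter_outer_radius))
    r_lum = Ellipse(c, (p.catheter_lumen_radius, p.catheter_lumen_radius))
    rasterize_primitive(r_out, grid, "catheter")
    X, Y = grid.center_mesh()
    lumen = r_lum.contains(X, Y)
    if not lumen.any():
        # grid too coarse to separate lumen from wall: every catheter cell
        # carries the coolant boundary
        lumen = grid.labels == LABEL_CODES["catheter"]
    grid.lumen_mask = lumen & (grid.labels == LABEL_CODES["catheter"])
    grid.meta["catheter_wall_thickness"] = (
        p.catheter_outer_radius - p.catheter_lumen_radius)
    grid.meta["catheter_center"] = c
    grid.meta["catheter_outer_radius"] = p.catheter_outer_radius
    grid.meta["catheter_lumen_radius"] = p.catheter_lumen_radius

    _check_invariants(grid)
    return grid


def _check_invariants(grid: LabelGrid) -> None:
    present = set(np.unique(grid.labels))
    missing = [name for name, code in LABEL_CODES.items()
               if code not in present]
    if missing:
        raise ConstructionError(
            f"tissue class(es) {missing} have no cells at spacing "
            f"{grid.spacing} m; refine the grid or adjust dimensions")
    if not grid.lumen_mask.any():
        raise ConstructionError("catheter lumen has no cells")
    _, n_comp = ndimage.label(grid.lumen_mask)
    if n_comp != 1:
        raise ConstructionError(
            f"catheter lumen fragments into {n_comp} components")
    # exterior must touch only subcutaneous tissue
    ext = grid.labels == EXTERIOR
    pad = np.pad(ext, 1, constant_values=False)
    near_ext = (pad[:-2, 1:-1] | pad[2:, 1:-1]
                | pad[1:-1, :-2] | pad[1:-1, 2:])
    bad = grid.active & near_ext & (
        grid.labels != LABEL_CODES["subcutaneous_tissue"])
    if bad.any():
        names = {CODE_TO_NAME[int(c)] for c in np.unique(grid.labels[bad])}
        raise ConstructionError(
            f"exterior borders non-subcutaneous tissue(s): {sorted(names)}")


def dorsal_midline_sequence(grid: LabelGrid) -> list[str]:
    """Tissue names encountered walking dorsally (+y) from the cord center,
    with consecutive duplicates collapsed.  Used to verify layer order."""
    iy0, ix = grid.cord_center()
    seq: list[str] = []
    for iy in range(iy0, grid.ny):
        name = grid.label_name(iy, ix)
        if not seq or seq[-1] != name:
            seq.append(name)
        if name == "exterior":
            break
    return seq
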
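"""Tissue templates and their rasterization.

A root cross-section is described at two levels:

* :class:`TissueTemplate` — the cellular anatomy in continuous coordinates
  (microns): cells with types, concentric layers, the xylem axis chain and the
  angular positions of the protoxylem poles.  Templates come from the built-in
  geometric generator (:func:`build_geometric_cross_section`) or from a
  segmented label image (:func:`load_labeled_section`).

* :class:`RasterGrid` — the template sampled on a 4-connected square lattice
  with an explicit cell-wall (apoplast) layer carved between cells.  Membrane
  faces live on lattice edges separating a cell-interior point from a wall
  point; each face carries the inward (wall → cell) unit normal and an
  orientation class relative to the root centre.

Orientation classes describe the direction a carrier on that face moves
material *into* the cell: ``inner`` faces import centripetally (the inward
normal points toward the centre), ``outer`` faces import centrifugally, and
``lateral-cw`` / ``lateral-ccw`` import clockwise / counter-clockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "CELL_TYPES",
    "STELE_TYPES",
    "STELE_INTERIOR_TYPES",
    "OUTER_LAYER_TYPES",
    "ORIENTATION_CLASSES",
    "WALL",
    "OUTSIDE",
    "InvalidTemplateError",
    "UnderResolutionError",
    "OrphanLabelError",
    "Cell",
    "TissueTemplate",
    "RasterGrid",
    "GeometrySpec",
    "build_geometric_cross_section",
    "load_labeled_section",
    "read_label_text",
    "write_label_text",
    "read_type_map",
    "write_type_map",
    "rasterize",
    "classify_faces",
]

CELL_TYPES = (
    "metaxylem",
    "protoxylem",
    "procambium",
    "phloem",
    "phloem-pole-procambium",
    "pericycle",
    "endodermis",
    "cortex",
    "epidermis",
)

#: cell types belonging to the stele (vascular cylinder incl. pericycle)
STELE_TYPES = (
    "metaxylem",
    "protoxylem",
    "procambium",
    "phloem",
    "phloem-pole-procambium",
    "pericycle",
)

#: stele cells within the pericycle ring
STELE_INTERIOR_TYPES = (
    "metaxylem",
    "protoxylem",
    "procambium",
    "phloem",
    "phloem-pole-procambium",
)

OUTER_LAYER_TYPES = ("endodermis", "cortex", "epidermis")

ORIENTATION_CLASSES = ("inner", "outer", "lateral-cw", "lateral-ccw")

# raster label sentinels
WALL = 0
OUTSIDE = -1


class InvalidTemplateError(ValueError):
    """The template violates an anatomical precondition."""


class UnderResolutionError(ValueError):
    """The grid spacing is too coarse to resolve every cell interior."""


class OrphanLabelError(KeyError):
    """A label image contains labels with no cell-type mapping."""

    def __init__(self, orphans: Sequence[int]):
        self.orphans = tuple(sorted(int(o) for o in orphans))
        super().__init__(f"labels with no cell-type mapping: {self.orphans}")


@dataclass(frozen=True)
class Cell:
    cell_id: int
    cell_type: str
    layer: str
    centroid: tuple[float, float]  # microns, template frame


@dataclass
class TissueTemplate:
    """Cellular anatomy of a cross-section in continuous coordinates."""

    cells: list[Cell]
    centre: tuple[float, float]
    xylem_axis: list[int]  # ordered cell ids, protoxylem -> ... -> protoxylem
    protoxylem_pole_angles: tuple[float, float]  # degrees, ccw from +x
    extent: float  # half-width (microns) of the square bounding box
    # exactly one of the two sources below is set
    assigner: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    label_image: np.ndarray | None = None
    pixel_size: float | None = None
    # cell-id mappings under mirror reflection (geometric templates only)
    mirror_x: dict[int, int] | None = None  # reflection about the xylem axis (y -> -y)
    mirror_y: dict[int, int] | None = None  # reflection about the phloem axis (x -> -x)
    name: str = "template"

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise InvalidTemplateError("duplicate cell ids")
        if any(i <= 0 for i in ids):
            raise InvalidTemplateError("cell ids must be positive integers")
        bad = {c.cell_type for c in self.cells} - set(CELL_TYPES)
        if bad:
            raise InvalidTemplateError(f"unknown cell types: {sorted(bad)}")

    @property
    def cell_by_id(self) -> dict[int, Cell]:
        return {c.cell_id: c for c in self.cells}

    @property
    def layers(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for c in self.cells:
            out.setdefault(c.layer, []).append(c.cell_id)
        return out

    def cells_of_type(self, *types: str) -> list[int]:
        return [c.cell_id for c in self.cells if c.cell_type in types]

    def raw_labels(self, dx: float) -> np.ndarray:
        """Sample the template on a symmetric square grid of spacing ``dx``.

        Returns an integer array with 0 = background (outside the section) and
        positive values = cell footprints (walls are carved later, by
        :func:`rasterize`).
        """
        n = 2 * int(math.ceil(self.extent / dx))
        coords = (np.arange(n) - (n - 1) / 2.0) * dx
        if self.assigner is not None:
            x = np.broadcast_to(coords[None, :], (n, n))
            y = np.broadcast_to(coords[:, None], (n, n))
            raw = self.assigner(x, y)
            return raw.astype(np.int32)
        assert self.label_image is not None and self.pixel_size is not None
        img = self.label_image
        # nearest-pixel resampling; template frame centred on image centre
        px = (coords + self.pixel_size * img.shape[1] / 2.0) / self.pixel_size
        py = (coords + self.pixel_size * img.shape[0] / 2.0) / self.pixel_size
        ix = np.clip(np.floor(px).astype(int), -1, img.shape[1])
        iy = np.clip(np.floor(py).astype(int), -1, img.shape[0])
        raw = np.zeros((n, n), dtype=np.int32)
        okx = (ix >= 0) & (ix < img.shape[1])
        oky = (iy >= 0) & (iy < img.shape[0])
        sub = img[np.clip(iy, 0, img.shape[0] - 1)[:, None],
                  np.clip(ix, 0, img.shape[1] - 1)[None, :]]
        raw = np.where(oky[:, None] & okx[None, :], sub, 0).astype(np.int32)
        return raw


@dataclass
class RasterGrid:
    """A rasterized template: label field, wall layer and membrane faces.

    ``labels``: ``OUTSIDE`` (-1) beyond the section, ``WALL`` (0) for
    apoplast points, positive cell id for cell-interior points.

    Faces are stored as flat parallel arrays.  ``face_axis`` is 0 for an
    x-edge (points ``(j,i)``–``(j,i+1)``) and 1 for a y-edge; ``face_edge``
    holds the ``(j, i)`` index of the edge's low point; ``face_cell_low`` is
    True when the cell-interior point is the low point of the edge.  The
    inward normal therefore points along -axis when the cell is the low point.
    """

    dx: float
    wall_thickness: float
    labels: np.ndarray
    centre_px: tuple[float, float]  # (row, col) position of the centre, px
    template: TissueTemplate
    # face arrays
    face_axis: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    face_edge: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    face_cell_low: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    face_cell_id: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    face_class: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def cell_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def wall_mask(self) -> np.ndarray:
        return self.labels == WALL

    @property
    def inside_mask(self) -> np.ndarray:
        return self.labels != OUTSIDE

    @property
    def cell_ids(self) -> np.ndarray:
        """Sorted array of cell ids present on the raster."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_faces(self) -> int:
        return self.face_axis.shape[0]

    def point_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates (microns) of every grid point."""
        ny, nx = self.labels.shape
        x = (np.arange(nx) - self.centre_px[1]) * self.dx
        y = (np.arange(ny) - self.centre_px[0]) * self.dx
        return np.broadcast_to(x[None, :], (ny, nx)), np.broadcast_to(y[:, None], (ny, nx))

    def face_normals(self) -> np.ndarray:
        """Inward (wall -> cell) unit normals, shape (n_faces, 2) as (nx, ny)."""
        n = np.zeros((self.n_faces, 2))
        sign = np.where(self.face_cell_low, -1.0, 1.0)
        n[self.face_axis == 0, 0] = sign[self.face_axis == 0]
        n[self.face_axis == 1, 1] = sign[self.face_axis == 1]
        return n

    def face_midpoints(self) -> np.ndarray:
        """Face midpoints (x, y) in microns, shape (n_faces, 2)."""
        j = self.face_edge[:, 0].astype(float)
        i = self.face_edge[:, 1].astype(float)
        i = i + np.where(self.face_axis == 0, 0.5, 0.0)
        j = j + np.where(self.face_axis == 1, 0.5, 0.0)
        x = (i - self.centre_px[1]) * self.dx
        y = (j - self.centre_px[0]) * self.dx
        return np.stack([x, y], axis=1)

    def face_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat indices of the (cell point, wall point) of every face."""
        ny, nx = self.labels.shape
        j, i = self.face_edge[:, 0], self.face_edge[:, 1]
        low = j * nx + i
        high = np.where(self.face_axis == 0, low + 1, low + nx)
        cell = np.where(self.face_cell_low, low, high)
        wall = np.where(self.face_cell_low, high, low)
        return cell, wall

    def cell_means(self, fld: np.ndarray) -> dict[int, float]:
        """Arithmetic mean of ``fld`` over each cell's interior points."""
        lab = self.labels
        m = lab > 0
        sums = np.bincount(lab[m], weights=fld[m])
        cnts = np.bincount(lab[m])
        out = {}
        for cid in self.cell_ids:
            out[int(cid)] = float(sums[cid] / cnts[cid])
        return out


# ---------------------------------------------------------------------------
# geometric generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometrySpec:
    """Parameters of the algorithmic ('geometric') cross-section.

    Defaults give a stele of ~50 um diameter inside a ~100 um section: a
    5-cell xylem axis spanning the stele along +x/-x, two phloem poles on the
    perpendicular axis, procambium filling the rest of the stele interior, a
    12-cell pericycle ring and endodermis / cortex / epidermis rings.  All
    radii are in microns.  ``wol`` replaces the stele interior by a smaller,
    all-protoxylem anatomy (receptor-mutant-like).
    """

    stele_interior_radius: float = 19.0
    ring_outer_radii: tuple[float, ...] = (25.0, 31.5, 40.5, 49.5)
    ring_names: tuple[str, ...] = ("pericycle", "endodermis", "cortex", "epidermis")
    ring_cell_counts: tuple[int, ...] = (12, 8, 8, 16)
    ring_offsets: tuple[float, ...] = (0.0, 0.0, 22.5, 0.0)  # degrees
    axis_n_cells: int = 5
    wol: bool = False
    scale: float = 1.0

    def scaled(self, s: float) -> "GeometrySpec":
        return replace(
            self,
            stele_interior_radius=self.stele_interior_radius * s,
            ring_outer_radii=tuple(r * s for r in self.ring_outer_radii),
            scale=self.scale * s,
        )


def _stele_seeds(spec: GeometrySpec) -> tuple[list[tuple[float, float]], list[str]]:
    """Voronoi seed points for the stele-interior cells."""
    R = spec.stele_interior_radius
    seeds: list[tuple[float, float]] = []
    types: list[str] = []
    n_ax = spec.axis_n_cells
    if n_ax < 3 or n_ax % 2 == 0:
        raise InvalidTemplateError("xylem axis needs an odd cell count >= 3")
    # xylem axis along x; protoxylem at the two margins
    xs = np.linspace(-0.8 * R, 0.8 * R, n_ax)
    for k, x in enumerate(xs):
        marginal = k == 0 or k == n_ax - 1
        seeds.append((float(x), 0.0))
        types.append("protoxylem" if (marginal or spec.wol) else "metaxylem")
    if spec.wol:
        # smaller, all-protoxylem interior: a ring of extra protoxylem cells
        r = 0.55 * R
        for ang in (45.0, 135.0, 225.0, 315.0):
            a = math.radians(ang)
            seeds.append((r * math.cos(a), r * math.sin(a)))
            types.append("protoxylem")
        return seeds, types
    # phloem poles perpendicular to the axis
    for sy in (1.0, -1.0):
        seeds.append((0.0, sy * 0.79 * R))
        types.append("phloem")
    # phloem-pole procambium flanking each pole
    rp = 0.79 * R
    for ang in (62.0, 118.0, 242.0, 298.0):
        a = math.radians(ang)
        seeds.append((rp * math.cos(a), rp * math.sin(a)))
        types.append("phloem-pole-procambium")
    # procambium between axis and phloem
    rq = 0.55 * R
    for ang in (30.0, 60.0, 120.0, 150.0, 210.0, 240.0, 300.0, 330.0):
        a = math.radians(ang)
        seeds.append((rq * math.cos(a), rq * math.sin(a)))
        types.append("procambium")
    for sy in (1.0, -1.0):
        seeds.append((0.0, sy * 0.42 * R))
        types.append("procambium")
    return seeds, types


def build_geometric_cross_section(spec: GeometrySpec | None = None) -> TissueTemplate:
    """Generate the algorithmic cross-section template.

    The returned template is mirror-symmetric about the xylem axis (x-axis)
    and the phloem axis (y-axis); the protoxylem poles sit at 0 and 180
    degrees and the phloem poles at 90 / 270 degrees.
    """
    spec = spec or GeometrySpec()
    if len(spec.ring_outer_radii) < 3:
        raise InvalidTemplateError("need at least 3 outer rings (endodermis, cortex, epidermis)")
    if len(spec.ring_outer_radii) != len(spec.ring_names) or len(spec.ring_names) != len(
        spec.ring_cell_counts
    ):
        raise InvalidTemplateError("ring radii / names / counts mismatch")
    if spec.axis_n_cells < 3:
        raise InvalidTemplateError("template has no xylem axis")
    if any(n % 2 for n in spec.ring_cell_counts):
        raise InvalidTemplateError("ring cell counts must be even (mirror symmetry)")

    seeds, seed_types = _stele_seeds(spec)
    seeds_arr = np.asarray(seeds)
    cells: list[Cell] = []
    next_id = 1
    stele_ids: list[int] = []
    for (sx, sy), t in zip(seeds, seed_types):
        cells.append(Cell(next_id, t, "stele-interior", (sx, sy)))
        stele_ids.append(next_id)
        next_id += 1

    # ring cells: annular sectors
    radii = (spec.stele_interior_radius,) + spec.ring_outer_radii
    ring_first_id: list[int] = []
    for k, (name, count, off) in enumerate(
        zip(spec.ring_names, spec.ring_cell_counts, spec.ring_offsets)
    ):
        ring_first_id.append(next_id)
        rmid = 0.5 * (radii[k] + radii[k + 1])
        for m in range(count):
            ang = math.radians(off + m * 360.0 / count)
            ctype = name if name in CELL_TYPES else "procambium"
            cells.append(Cell(next_id, ctype, name, (rmid * math.cos(ang), rmid * math.sin(ang))))
            next_id += 1

    R_out = spec.ring_outer_radii[-1]
    ring_counts = spec.ring_cell_counts
    ring_offsets = spec.ring_offsets

    def assigner(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        r = np.hypot(x, y)
        out = np.zeros(x.shape, dtype=np.int32)
        # stele interior: nearest seed
        inside = r < radii[0]
        if inside.any():
            xi = x[inside]
            yi = y[inside]
            d2 = (xi[:, None] - seeds_arr[None, :, 0]) ** 2 + (
                yi[:, None] - seeds_arr[None, :, 1]
            ) ** 2
            out[inside] = np.argmin(d2, axis=1) + 1
        # rings: sector by angle
        theta = np.degrees(np.arctan2(y, x))
        for k in range(len(ring_counts)):
            band = (r >= radii[k]) & (r < radii[k + 1])
            if not band.any():
                continue
            width = 360.0 / ring_counts[k]
            sector = np.floor(((theta[band] - ring_offsets[k]) / width) + 0.5).astype(int)
            sector %= ring_counts[k]
            out[band] = ring_first_id[k] + sector
        out[r >= R_out] = 0
        return out

    # mirror maps by reflecting centroids
    def _mirror_map(sx: float, sy: float) -> dict[int, int]:
        cents = np.array([c.centroid for c in cells])
        ids = [c.cell_id for c in cells]
        mapping: dict[int, int] = {}
        for c in cells:
            tx, ty = c.centroid[0] * sx, c.centroid[1] * sy
            d2 = (cents[:, 0] - tx) ** 2 + (cents[:, 1] - ty) ** 2
            k = int(np.argmin(d2))
            if d2[k] > 1e-6:
                raise InvalidTemplateError("template is not mirror-symmetric")
            mapping[c.cell_id] = ids[k]
        return mapping

    n_ax = spec.axis_n_cells
    tpl = TissueTemplate(
        cells=cells,
        centre=(0.0, 0.0),
        xylem_axis=list(range(1, n_ax + 1)),
        protoxylem_pole_angles=(0.0, 180.0),
        extent=R_out + 1.0,
        assigner=assigner,
        mirror_x=_mirror_map(1.0, -1.0),
        mirror_y=_mirror_map(-1.0, 1.0),
        name="geometric-wol" if spec.wol else "geometric",
    )
    # order the axis chain by x position
    tpl.xylem_axis.sort(key=lambda cid: tpl.cell_by_id[cid].centroid[0])
    return tpl


# ---------------------------------------------------------------------------
# label-image reader and plain-text formats
# ---------------------------------------------------------------------------


def read_label_text(path: str | Path) -> np.ndarray:
    """Read an integer label raster from whitespace-separated text."""
    return np.loadtxt(path, dtype=np.int32, ndmin=2)


def write_label_text(path: str | Path, labels: np.ndarray) -> None:
    np.savetxt(path, np.asarray(labels, dtype=int), fmt="%d")


def read_type_map(path: str | Path) -> dict[int, str]:
    """Read a ``label<TAB>cell_type`` sidecar file (0 = wall/background)."""
    out: dict[int, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        lab, ctype = line.split("\t")
        out[int(lab)] = ctype
    return out


def write_type_map(path: str | Path, type_map: Mapping[int, str]) -> None:
    lines = [f"{k}\t{v}" for k, v in sorted(type_map.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def load_labeled_section(
    label_image: np.ndarray | str | Path,
    type_map: Mapping[int, str] | str | Path,
    pixel_size: float = 1.0,
    centre: tuple[float, float] | None = None,
    xylem_axis: Sequence[int] = (),
    protoxylem_pole_angles: tuple[float, float] = (0.0, 180.0),
    name: str = "labeled-section",
) -> TissueTemplate:
    """Build a template from a segmented integer label image.

    ``label_image`` may be an array or a path to a whitespace-separated text
    raster; 0 marks wall/background.  ``type_map`` assigns a cell type to
    every positive label (array form or ``label<TAB>type`` file).  The centre
    defaults to the centroid of the stele-typed labels, in the template frame
    (origin at the image centre).
    """
    if not isinstance(label_image, np.ndarray):
        label_image = read_label_text(label_image)
    label_image = np.asarray(label_image, dtype=np.int32)
    if not isinstance(type_map, Mapping):
        type_map = read_type_map(type_map)
    present = np.unique(label_image)
    present = present[present > 0]
    orphans = [int(p) for p in present if int(p) not in type_map]
    if orphans:
        raise OrphanLabelError(orphans)

    ny, nx = label_image.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    # template frame: microns, origin at image centre, y increasing upward in
    # array order (consistent with the geometric assigner convention)
    fx = (xx - (nx - 1) / 2.0) * pixel_size
    fy = (yy - (ny - 1) / 2.0) * pixel_size
    cells = []
    layer_of = {
        t: ("stele-interior" if t in STELE_INTERIOR_TYPES else t) for t in CELL_TYPES
    }
    for lab in present:
        m = label_image == lab
        ctype = type_map[int(lab)]
        if ctype not in CELL_TYPES:
            raise InvalidTemplateError(f"unknown cell type {ctype!r} for label {int(lab)}")
        cells.append(
            Cell(int(lab), ctype, layer_of[ctype], (float(fx[m].mean()), float(fy[m].mean())))
        )
    if centre is None:
        stele = [c for c in cells if c.cell_type in STELE_TYPES]
        if stele:
            centre = (
                float(np.mean([c.centroid[0] for c in stele])),
                float(np.mean([c.centroid[1] for c in stele])),
            )
        else:
            centre = (0.0, 0.0)
    return TissueTemplate(
        cells=cells,
        centre=centre,
        xylem_axis=list(xylem_axis),
        protoxylem_pole_angles=protoxylem_pole_angles,
        extent=max(nx, ny) * pixel_size / 2.0,
        label_image=label_image,
        pixel_size=pixel_size,
        name=name,
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _square(r: int) -> np.ndarray:
    return np.ones((2 * r + 1, 2 * r + 1), dtype=bool)


def rasterize(template: TissueTemplate, dx: float, wall_thickness: float) -> RasterGrid:
    """Sample a template on a square lattice and carve the wall layer.

    Between two cells each cedes half the wall thickness; at the section
    boundary the full wall thickness is carved from the cell footprint, so
    the domain ends at the outer edge of the epidermal wall.  Deterministic:
    the same template and spacing give a bit-identical grid.
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    if wall_thickness < dx:
        raise ValueError("wall_thickness must be at least dx")
    raw = template.raw_labels(dx)
    ny, nx = raw.shape

    r_half = max(1, int(round(wall_thickness / (2.0 * dx))))
    r_full = max(1, int(round(wall_thickness / dx)))

    bg = raw <= 0
    near_bg = ndimage.binary_dilation(bg, structure=_square(r_full))
    # a cell point near a *different* cell within r_half becomes wall
    hi = np.where(raw > 0, raw, 0)
    lo = np.where(raw > 0, raw, np.iinfo(np.int32).max)
    near_diff = (ndimage.maximum_filter(hi, footprint=_square(r_half)) > raw) | (
        ndimage.minimum_filter(lo, footprint=_square(r_half)) < raw
    )
    interior = (raw > 0) & ~near_bg & ~near_diff
    labels = np.where(bg, OUTSIDE, np.where(interior, raw, WALL)).astype(np.int32)

    # exact mirror symmetry for geometric templates: force disagreeing points
    # to wall (ties at cell boundaries can otherwise flip asymmetrically)
    if template.mirror_x is not None:
        labels = _symmetrize(labels, template.mirror_x, axis=0)
    if template.mirror_y is not None:
        labels = _symmetrize(labels, template.mirror_y, axis=1)

    missing = sorted(
        set(c.cell_id for c in template.cells if _cell_in_raw(raw, c.cell_id))
        - set(np.unique(labels[labels > 0]).tolist())
    )
    if missing:
        raise UnderResolutionError(
            f"dx={dx} um leaves no interior for cells {missing}; use a finer grid"
        )

    # the raster is centred on the template frame; the root centre may be offset
    centre_px = (
        (ny - 1) / 2.0 + template.centre[1] / dx,
        (nx - 1) / 2.0 + template.centre[0] / dx,
    )

    grid = RasterGrid(
        dx=dx,
        wall_thickness=wall_thickness,
        labels=labels,
        centre_px=centre_px,
        template=template,
    )
    _build_faces(grid)
    classify_faces(grid)
    return grid


def _cell_in_raw(raw: np.ndarray, cid: int) -> bool:
    return bool((raw == cid).any())


def _symmetrize(labels: np.ndarray, mapping: dict[int, int], axis: int) -> np.ndarray:
    flipped = np.flip(labels, axis=axis)
    lut_size = int(labels.max()) + 1
    lut = np.arange(-1, lut_size, dtype=np.int32)
    for k, v in mapping.items():
        if k < lut_size:
            lut[k + 1] = v
    mirrored = lut[flipped + 1]
    out = labels.copy()
    both_cells = (labels > 0) & (mirrored > 0) & (labels != mirrored)
    out[both_cells] = WALL
    # a cell point whose mirror is wall also becomes wall
    out[(labels > 0) & (mirrored == WALL)] = WALL
    return out


def _build_faces(grid: RasterGrid) -> None:
    lab = grid.labels
    ax_list, edge_list, low_list, cid_list = [], [], [], []
    for axis in (0, 1):
        if axis == 0:
            a, b = lab[:, :-1], lab[:, 1:]
        else:
            a, b = lab[:-1, :], lab[1:, :]
        cell_low = (a > 0) & (b == WALL)
        cell_high = (a == WALL) & (b > 0)
        for mask, low in ((cell_low, True), (cell_high, False)):
            jj, ii = np.nonzero(mask)
            if jj.size == 0:
                continue
            ax_list.append(np.full(jj.size, axis))
            edge_list.append(np.stack([jj, ii], axis=1))
            low_list.append(np.full(jj.size, low, dtype=bool))
            cid_list.append((a if low else b)[jj, ii])
    if ax_list:
        grid.face_axis = np.concatenate(ax_list)
        grid.face_edge = np.concatenate(edge_list, axis=0)
        grid.face_cell_low = np.concatenate(low_list)
        grid.face_cell_id = np.concatenate(cid_list).astype(int)
    grid.face_class = np.zeros(grid.n_faces, dtype=np.int64)


def classify_faces(grid: RasterGrid, centre: tuple[float, float] | None = None) -> RasterGrid:
    """Assign an orientation class to every membrane face.

    Classes compare the inward normal with the radial (outward) and angular
    (counter-clockwise) unit vectors at the face midpoint; ties break toward
    the radial classes.  ``inner`` means the inward normal points toward the
    centre.
    """
    mids = grid.face_midpoints()
    if centre is not None:
        cx, cy = centre
        mids = mids - np.array([[cx, cy]])
    r = np.hypot(mids[:, 0], mids[:, 1])
    if grid.n_faces and np.any(r == 0):
        raise ValueError("a face lies exactly at the root centre")
    normals = grid.face_normals()
    with np.errstate(invalid="ignore"):
        rhat = mids / r[:, None]
    nr = normals[:, 0] * rhat[:, 0] + normals[:, 1] * rhat[:, 1]
    # theta-hat = (-y, x)/r
    nt = -normals[:, 0] * rhat[:, 1] + normals[:, 1] * rhat[:, 0]
    radial = np.abs(nr) >= np.abs(nt)
    cls = np.empty(grid.n_faces, dtype=np.int64)
    cls[radial & (nr < 0)] = ORIENTATION_CLASSES.index("inner")
    cls[radial & (nr >= 0)] = ORIENTATION_CLASSES.index("outer")
    cls[~radial & (nt < 0)] = ORIENTATION_CLASSES.index("lateral-cw")
    cls[~radial & (nt >= 0)] = ORIENTATION_CLASSES.index("lateral-ccw")
    grid.face_class = cls
    return grid
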
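"""Transporter placement maps, polarity variants and condition rewires.

A :class:`TransporterLayout` is a list of :class:`Placement` records: which
cells (by type or explicit id) carry which carrier on which membrane
orientation classes, at what fraction of the carrier-class permeability, and
under which regulation mode.  The default wild-type map transcribes the
experimentally observed localisations:

* importer (AUX1/LAX aggregate) — apolar on every stele cell, unregulated by
  default (auxin-up and restricted to the pericycle during lateral-root runs);
* PIN1 — procambium; the polar variant occupies only the lateral faces that
  export auxin toward the nearest xylem (protoxylem) pole, the apolar variant
  all faces;
* PIN3 — apolar on the xylem-axis cells, auxin-up-regulated;
* PIN7 — apolar in the procambium (a polar variant mirrors PIN1's
  orientation), plus a weaker apolar copy at the phloem poles;
* outer exporter — apolar and unregulated in endodermis, cortex, epidermis.

The receptor-mutant (*wol*) and cytokinin-treatment maps rewire PIN placement
directly (all three PINs apolar throughout the stele interior, transcribed
from imaging-based maps); hormone levels and response are left untouched.

Polar placements use the sentinel class ``"toward-xylem-pole"``: at binding
time it resolves, per cell, to the lateral orientation class whose export
direction points at the nearest protoxylem pole.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Sequence

import numpy as np
import yaml

from .geometry import (
    ORIENTATION_CLASSES,
    OUTER_LAYER_TYPES,
    STELE_TYPES,
    RasterGrid,
    TissueTemplate,
)
from .regulation import DEFAULT_MODES

__all__ = [
    "TRANSPORTER_KINDS",
    "EXPORTER_KINDS",
    "CONDITIONS",
    "Placement",
    "TransporterLayout",
    "wildtype_layout",
    "condition_layout",
    "bind_layout",
    "BoundLayout",
]

TRANSPORTER_KINDS = ("PIN1", "PIN3", "PIN7", "PIN7weak", "exporter_outer", "importer")
EXPORTER_KINDS = ("PIN1", "PIN3", "PIN7", "PIN7weak", "exporter_outer")
CONDITIONS = ("wildtype", "wol", "ck_treated", "pin1", "pin7", "importer_null", "lateral_root")

POLAR = "toward-xylem-pole"


@dataclass(frozen=True)
class Placement:
    transporter: str
    cell_types: tuple[str, ...] = ()
    cell_ids: tuple[int, ...] = ()
    classes: tuple[str, ...] | str = "all"  # "all", POLAR, or explicit classes
    strength: float = 1.0
    regulation: str | None = None  # None -> the kind's default mode

    def __post_init__(self) -> None:
        if self.transporter not in TRANSPORTER_KINDS:
            raise ValueError(f"unknown transporter kind {self.transporter!r}")
        if isinstance(self.classes, str):
            if self.classes not in ("all", POLAR):
                raise ValueError(f"bad classes spec {self.classes!r}")
        else:
            bad = set(self.classes) - set(ORIENTATION_CLASSES)
            if bad:
                raise ValueError(f"unknown orientation classes {sorted(bad)}")
        if self.strength < 0:
            raise ValueError("strength must be non-negative")


@dataclass
class TransporterLayout:
    placements: list[Placement]
    pin1_polarity: str = "polar"
    pin7_polarity: str = "apolar"
    pericycle_polarity: str = "apolar"  # PIN1/PIN7 polarity in pericycle (lateral-root runs)
    # importer map in the lateral-root context: expressed only in the pericycle
    # (auxin-regulated), or additionally static throughout the rest of the stele
    lateral_importer: str = "pericycle-only"  # or "stele-static"
    condition: str = "wildtype"

    def kinds_present(self) -> set[str]:
        return {p.transporter for p in self.placements}

    def without_kind(self, *kinds: str) -> "TransporterLayout":
        return replace(
            self, placements=[p for p in self.placements if p.transporter not in kinds]
        )

    # ---- serialization (structured text, round-trippable) ----
    def to_dict(self) -> dict:
        d = asdict(self)
        for p in d["placements"]:
            for k in ("cell_types", "cell_ids"):
                p[k] = list(p[k])
            if not isinstance(p["classes"], str):
                p["classes"] = list(p["classes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TransporterLayout":
        ps = []
        for p in d["placements"]:
            p = dict(p)
            p["cell_types"] = tuple(p.get("cell_types", ()))
            p["cell_ids"] = tuple(p.get("cell_ids", ()))
            c = p.get("classes", "all")
            p["classes"] = c if isinstance(c, str) else tuple(c)
            ps.append(Placement(**p))
        return cls(
            placements=ps,
            pin1_polarity=d.get("pin1_polarity", "polar"),
            pin7_polarity=d.get("pin7_polarity", "apolar"),
            pericycle_polarity=d.get("pericycle_polarity", "apolar"),
            lateral_importer=d.get("lateral_importer", "pericycle-only"),
            condition=d.get("condition", "wildtype"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TransporterLayout":
        return cls.from_dict(yaml.safe_load(text))


def wildtype_layout(
    pin1_polarity: str = "polar",
    pin7_polarity: str = "apolar",
    weak_pin7_strength: float = 0.5,
) -> TransporterLayout:
    """The wild-type transporter map (polarity variants selectable)."""
    for v in (pin1_polarity, pin7_polarity):
        if v not in ("polar", "apolar"):
            raise ValueError("polarity must be 'polar' or 'apolar'")
    # PIN1/PIN7 occupy the high-cytokinin-signalling domain: procambium and
    # pericycle (the flux decomposition of the polar/apolar variants relies on
    # PIN1-organized pericycle fluxes)
    pin17_types = ("procambium", "phloem-pole-procambium", "pericycle")
    placements = [
        Placement("importer", cell_types=STELE_TYPES, classes="all"),
        Placement(
            "PIN1",
            cell_types=pin17_types,
            classes=POLAR if pin1_polarity == "polar" else "all",
        ),
        Placement("PIN3", cell_types=("protoxylem", "metaxylem"), classes="all"),
        Placement(
            "PIN7",
            cell_types=pin17_types,
            classes=POLAR if pin7_polarity == "polar" else "all",
        ),
        Placement("PIN7weak", cell_types=("phloem",), classes="all", strength=weak_pin7_strength),
        Placement("exporter_outer", cell_types=OUTER_LAYER_TYPES, classes="all"),
    ]
    return TransporterLayout(
        placements=placements, pin1_polarity=pin1_polarity, pin7_polarity=pin7_polarity
    )


#: transcription of the imaging-based PIN maps used for the receptor mutant and
#: cytokinin treatment: all three PINs apolar throughout the stele interior.
_REWIRED_PIN_TYPES = (
    "protoxylem",
    "metaxylem",
    "procambium",
    "phloem-pole-procambium",
    "phloem",
    "pericycle",
)


def condition_layout(base: TransporterLayout, condition: str) -> TransporterLayout:
    """Rewire a wild-type layout for a mutant / treatment / context."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if condition == "wildtype":
        return replace(base, condition="wildtype")
    if condition == "pin1":
        return replace(base.without_kind("PIN1"), condition="pin1")
    if condition == "pin7":
        return replace(base.without_kind("PIN7", "PIN7weak"), condition="pin7")
    if condition == "importer_null":
        return replace(base.without_kind("importer"), condition="importer_null")
    if condition in ("wol", "ck_treated"):
        out = base.without_kind("PIN1", "PIN3", "PIN7", "PIN7weak")
        out.placements.extend(
            [
                Placement("PIN1", cell_types=_REWIRED_PIN_TYPES, classes="all"),
                Placement("PIN3", cell_types=_REWIRED_PIN_TYPES, classes="all"),
                Placement("PIN7", cell_types=_REWIRED_PIN_TYPES, classes="all"),
            ]
        )
        return replace(out, condition=condition)
    # lateral_root: drop PIN3, control PIN1/PIN7 polarity independently in the
    # pericycle, and switch the importer to auxin-up regulation restricted to
    # pericycle cells
    # only PIN1 and PIN7 remain in this context (PIN3 and the weak phloem PIN
    # are shoot-ward absent); the importer map is rebuilt below
    out = base.without_kind("PIN3", "PIN7weak", "importer", "PIN1", "PIN7")
    proc = ("procambium", "phloem-pole-procambium")
    peri_classes = POLAR if base.pericycle_polarity == "polar" else "all"
    if base.lateral_importer == "stele-static":
        out.placements.append(
            Placement(
                "importer",
                cell_types=tuple(t for t in STELE_TYPES if t != "pericycle"),
                classes="all",
                regulation="static",
            )
        )
    out.placements.extend(
        [
            Placement("importer", cell_types=("pericycle",), classes="all", regulation="auxin-up"),
            Placement("PIN1", cell_types=proc, classes=POLAR if base.pin1_polarity == "polar" else "all"),
            Placement("PIN7", cell_types=proc, classes=POLAR if base.pin7_polarity == "polar" else "all"),
            Placement("PIN1", cell_types=("pericycle",), classes=peri_classes),
            Placement("PIN7", cell_types=("pericycle",), classes=peri_classes),
        ]
    )
    return replace(out, condition="lateral_root")


# ---------------------------------------------------------------------------
# binding a layout to a rasterized template
# ---------------------------------------------------------------------------


@dataclass
class BoundLayout:
    """A layout resolved onto a grid's face set.

    ``strength``: (n_kinds, n_faces) placement strength per face (0 = absent);
    ``mode_code``: (n_kinds, n_cells) regulation-mode codes (0 static,
    1 auxin-up, 2 ck-up-auxin-down) per cell, indexed by compact cell index.
    """

    kinds: tuple[str, ...]
    strength: np.ndarray
    mode_code: np.ndarray
    cell_index: dict[int, int]  # cell id -> compact index
    layout: TransporterLayout

    def kind_index(self, kind: str) -> int:
        return self.kinds.index(kind)


_MODE_CODES = {"static": 0, "auxin-up": 1, "ck-up-auxin-down": 2}


def _signed_pole_distance(theta_deg: float, poles: Sequence[float]) -> float:
    """Signed angular distance (deg) to the nearest xylem pole, in (-180, 180]."""
    best = None
    for p in poles:
        d = (theta_deg - p + 180.0) % 360.0 - 180.0
        if best is None or abs(d) < abs(best):
            best = d
    return float(best)


def _polar_face_mask(grid: RasterGrid, cell_ids, tol_deg: float = 1.0) -> np.ndarray:
    """Faces of a polar placement: export toward the xylem axis.

    Stele-interior cells carry the carrier on every face whose export
    direction moves auxin away from the phloem poles and toward the xylem
    axis: the faces pointing at the axis line plus the lateral faces pointing
    at the nearest protoxylem pole (together they generate the
    four-quadrant flux circuit converging on the axis and flowing out
    through its poles).  Ring cells (e.g. the pericycle) carry it on the
    faces exporting toward the nearest protoxylem pole cell: lateral faces
    for most of the ring, the inner faces for a cell sitting at a pole
    (whose nearest pole cell lies radially inward), and both lateral
    directions at the phloem position, keeping the map mirror-symmetric.
    """
    tpl = grid.template
    poles = tpl.protoxylem_pole_angles
    normals = grid.face_normals()
    class_names = np.array(ORIENTATION_CLASSES)
    face_cls = class_names[grid.face_class]
    out = np.zeros(grid.n_faces, dtype=bool)
    for cid in cell_ids:
        cell = tpl.cell_by_id[cid]
        m = grid.face_cell_id == cid
        if not m.any():
            continue
        cx = cell.centroid[0] - tpl.centre[0]
        cy = cell.centroid[1] - tpl.centre[1]
        if cell.layer == "stele-interior":
            # faces whose export direction (-n_hat) decreases |y| ...
            sel = m & (normals[:, 1] * np.sign(cy) > 0)
            # ... plus lateral faces exporting toward the nearest pole
            theta = np.degrees(np.arctan2(cy, cx))
            s = _signed_pole_distance(theta, poles)
            if abs(s) >= tol_deg and abs(abs(s) - 90.0) >= tol_deg:
                lat = "lateral-ccw" if s > 0 else "lateral-cw"
                sel = sel | (m & (face_cls == lat))
            elif abs(abs(s) - 90.0) < tol_deg:
                sel = sel | (m & np.isin(face_cls, ("lateral-cw", "lateral-ccw")))
        else:
            theta = np.degrees(np.arctan2(cy, cx))
            s = _signed_pole_distance(theta, poles)
            if abs(s) < tol_deg:
                sel = m & (face_cls == "inner")
            elif abs(abs(s) - 90.0) < tol_deg:
                sel = m & np.isin(face_cls, ("lateral-cw", "lateral-ccw"))
            elif s > 0:  # nearest pole reached clockwise; export along -theta_hat
                sel = m & (face_cls == "lateral-ccw")
            else:
                sel = m & (face_cls == "lateral-cw")
        out |= sel
    return out


def bind_layout(layout: TransporterLayout, grid: RasterGrid) -> BoundLayout:
    tpl = grid.template
    ids = [int(c) for c in grid.cell_ids]
    cell_index = {cid: k for k, cid in enumerate(ids)}
    n_cells = len(ids)
    n_faces = grid.n_faces
    kinds = TRANSPORTER_KINDS
    strength = np.zeros((len(kinds), n_faces))
    mode_code = np.zeros((len(kinds), n_cells), dtype=np.int64)
    for k, kind in enumerate(kinds):
        mode_code[k, :] = _MODE_CODES[DEFAULT_MODES[kind]]

    cell_by_id = tpl.cell_by_id
    face_cid = grid.face_cell_id
    class_names = np.array(ORIENTATION_CLASSES)
    face_cls_name = class_names[grid.face_class]

    for p in layout.placements:
        k = kinds.index(p.transporter)
        sel_ids = set(p.cell_ids)
        if p.cell_types:
            sel_ids |= {cid for cid in ids if cell_by_id[cid].cell_type in p.cell_types}
        if not sel_ids:
            continue
        in_cells = np.isin(face_cid, sorted(sel_ids))
        if p.classes == "all":
            fmask = in_cells
        elif p.classes == POLAR:
            fmask = _polar_face_mask(grid, sorted(sel_ids))
        else:
            fmask = in_cells & np.isin(face_cls_name, list(p.classes))
        strength[k, fmask] = np.maximum(strength[k, fmask], p.strength)
        if p.regulation is not None:
            code = _MODE_CODES[p.regulation]
            for cid in sel_ids:
                if cid in cell_index:
                    mode_code[k, cell_index[cid]] = code
    return BoundLayout(
        kinds=kinds, strength=strength, mode_code=mode_code, cell_index=cell_index, layout=layout
    )
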
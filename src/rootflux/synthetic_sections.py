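"""Synthetic 'realistic-style' segmented sections.

The segmented confocal sections used for realistic-layout simulations are not
distributable, so the package ships synthetic stand-ins: label images produced
by sampling the geometric anatomy through a smooth deterministic warp, which
gives organically irregular, slightly asymmetric cell outlines at the same
tissue proportions (wild-type-like, and a smaller all-protoxylem-stele
receptor-mutant-like section).  The generator below reproduces the packaged
``data/synthetic_*_section.txt`` fixtures exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .geometry import (
    GeometrySpec,
    TissueTemplate,
    build_geometric_cross_section,
    write_label_text,
    write_type_map,
)

__all__ = ["synthetic_section", "write_synthetic_sections"]

PIXEL_SIZE = 1.5  # um per pixel of the packaged fixtures


def synthetic_section(kind: str = "wildtype", pixel_size: float = PIXEL_SIZE):
    """Return (label_image, type_map, meta) for a synthetic segmented section."""
    if kind == "wildtype":
        tpl = build_geometric_cross_section()
    elif kind == "wol":
        from .scenarios import _WOL_SPEC

        tpl = build_geometric_cross_section(_WOL_SPEC)
    else:
        raise ValueError(f"unknown section kind {kind!r}")
    n = 2 * int(np.ceil(tpl.extent / pixel_size))
    coords = (np.arange(n) - (n - 1) / 2.0) * pixel_size
    X = np.broadcast_to(coords[None, :], (n, n))
    Y = np.broadcast_to(coords[:, None], (n, n))
    # smooth deterministic warp: organic outlines, mild asymmetry
    Xw = X + 1.2 * np.sin(0.11 * Y + 1.0) + 0.6 * np.sin(0.23 * Y + 0.3)
    Yw = Y + 1.2 * np.sin(0.13 * X + 2.0) + 0.6 * np.sin(0.19 * X + 1.1)
    labels = tpl.assigner(Xw, Yw)
    type_map = {c.cell_id: c.cell_type for c in tpl.cells}
    meta = {
        "pixel_size": pixel_size,
        "xylem_axis": list(tpl.xylem_axis),
        "protoxylem_pole_angles": list(tpl.protoxylem_pole_angles),
    }
    return labels, type_map, meta


def write_synthetic_sections(outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for kind, stem in (("wildtype", "synthetic_wildtype_section"), ("wol", "synthetic_wol_section")):
        labels, type_map, meta = synthetic_section(kind)
        write_label_text(out / f"{stem}.txt", labels)
        write_type_map(out / f"{stem}.types.tsv", type_map)
        (out / f"{stem}.meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
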
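"""Templates, rasterization, face classification and label-image IO."""

from __future__ import annotations

import numpy as np
import pytest

from rootflux.geometry import (
    CELL_TYPES,
    ORIENTATION_CLASSES,
    OUTSIDE,
    WALL,
    GeometrySpec,
    OrphanLabelError,
    UnderResolutionError,
    build_geometric_cross_section,
    classify_faces,
    load_labeled_section,
    rasterize,
    read_label_text,
    read_type_map,
    write_label_text,
    write_type_map,
)
from rootflux.scenarios import build_template


class TestGeometricTemplate:
    def test_cell_types_valid(self, geometric_template):
        assert {c.cell_type for c in geometric_template.cells} <= set(CELL_TYPES)

    def test_xylem_axis_ordered_protoxylem_to_protoxylem(self, geometric_template):
        tpl = geometric_template
        axis = [tpl.cell_by_id[c] for c in tpl.xylem_axis]
        assert len(axis) == 5
        assert axis[0].cell_type == "protoxylem"
        assert axis[-1].cell_type == "protoxylem"
        assert all(c.cell_type == "metaxylem" for c in axis[1:-1])
        xs = [c.centroid[0] for c in axis]
        assert xs == sorted(xs) or xs == sorted(xs, reverse=True)
        # the axis lies on the pole-pole diameter (y = 0)
        assert max(abs(c.centroid[1]) for c in axis) < 1.0

    def test_ring_counts(self, geometric_template):
        layers = geometric_template.layers
        assert len(layers["pericycle"]) == 12
        assert len(layers["endodermis"]) == 8
        assert len(layers["cortex"]) == 8
        assert len(layers["epidermis"]) == 16

    def test_mirror_maps_are_type_preserving_involutions(self, geometric_template):
        tpl = geometric_template
        for mapping in (tpl.mirror_x, tpl.mirror_y):
            assert mapping is not None
            for a, b in mapping.items():
                assert mapping[b] == a
                assert tpl.cell_by_id[a].cell_type == tpl.cell_by_id[b].cell_type

    def test_wol_variant_all_protoxylem(self):
        tpl = build_template("geometric-wol")
        interior = [c for c in tpl.cells if c.layer == "stele-interior"]
        assert interior and all(c.cell_type == "protoxylem" for c in interior)

    def test_scaled_spec(self):
        spec = GeometrySpec().scaled(0.5)
        assert spec.stele_interior_radius == pytest.approx(9.5)
        assert spec.ring_outer_radii[-1] == pytest.approx(24.75)


class TestRasterize:
    def test_every_cell_present(self, mini_template, mini_grid):
        assert set(mini_grid.cell_ids) == {c.cell_id for c in mini_template.cells}

    def test_walls_separate_cells(self, mini_grid):
        lab = mini_grid.labels
        for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
            both = (a > 0) & (b > 0)
            assert not (a[both] != b[both]).any()

    def test_domain_ends_at_outer_wall(self, mini_grid):
        lab = mini_grid.labels
        border = np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
        assert (border == OUTSIDE).all()

    def test_faces_pair_cell_and_wall_points(self, mini_grid):
        cell_pts, wall_pts = mini_grid.face_points()
        flat = mini_grid.labels.ravel()
        assert (flat[cell_pts] > 0).all()
        assert (flat[wall_pts] == WALL).all()
        assert (flat[cell_pts] == mini_grid.face_cell_id).all()

    def test_cell_means_constant_field(self, mini_grid):
        fld = np.full(mini_grid.shape, 3.25)
        means = mini_grid.cell_means(fld)
        assert all(abs(v - 3.25) < 1e-12 for v in means.values())

    def test_deterministic(self, mini_template):
        g1 = rasterize(mini_template, dx=0.5, wall_thickness=1.0)
        g2 = rasterize(mini_template, dx=0.5, wall_thickness=1.0)
        assert (g1.labels == g2.labels).all()

    def test_under_resolution_raises(self, mini_template):
        with pytest.raises(UnderResolutionError):
            rasterize(mini_template, dx=3.0, wall_thickness=6.0)

    def test_mirror_symmetric_labels(self, geometric_template):
        grid = rasterize(geometric_template, dx=1.0, wall_thickness=2.0)
        lab = grid.labels
        flipped = np.flip(lab, axis=0)
        lut = np.arange(-1, lab.max() + 1)
        for k, v in geometric_template.mirror_x.items():
            lut[k + 1] = v
        assert (lut[flipped + 1] == lab).all()


class TestClassifyFaces:
    def test_all_faces_classified(self, mini_grid):
        assert mini_grid.face_class.shape == (mini_grid.n_faces,)
        assert set(np.unique(mini_grid.face_class)) <= set(range(len(ORIENTATION_CLASSES)))

    def test_lateral_counts_balance_per_ring(self, mini_template, mini_grid):
        cls = mini_grid.face_class
        cw = ORIENTATION_CLASSES.index("lateral-cw")
        ccw = ORIENTATION_CLASSES.index("lateral-ccw")
        for layer in ("pericycle", "endodermis", "cortex", "epidermis"):
            ids = mini_template.layers[layer]
            m = np.isin(mini_grid.face_cell_id, ids)
            assert (cls[m] == cw).sum() == (cls[m] == ccw).sum()

    def test_centred_convex_cell_is_all_inner(self, tiny_fixture):
        tpl, _ = tiny_fixture
        grid = rasterize(tpl, dx=0.5, wall_thickness=1.0)
        inner = ORIENTATION_CLASSES.index("inner")
        assert (grid.face_class == inner).all()

    def test_inner_normals_point_inward(self, mini_grid):
        inner = ORIENTATION_CLASSES.index("inner")
        mids = mini_grid.face_midpoints()
        normals = mini_grid.face_normals()
        dots = (mids * normals).sum(axis=1)
        assert (dots[mini_grid.face_class == inner] < 0).all()


class TestLabelIO:
    def test_roundtrip(self, tmp_path):
        labels = np.array([[0, 1, 1], [2, 2, 0]])
        tmap = {1: "procambium", 2: "pericycle"}
        write_label_text(tmp_path / "lab.txt", labels)
        write_type_map(tmp_path / "types.tsv", tmap)
        assert (read_label_text(tmp_path / "lab.txt") == labels).all()
        assert read_type_map(tmp_path / "types.tsv") == tmap

    def test_orphan_labels_raise(self):
        img = np.array([[1, 0, 2]])
        with pytest.raises(OrphanLabelError) as exc:
            load_labeled_section(img, {1: "procambium"})
        assert exc.value.orphans == (2,)

    def test_two_cell_fixture(self, two_cell_fixture):
        tpl, _ = two_cell_fixture
        assert len(tpl.cells) == 2
        grid = rasterize(tpl, dx=0.5, wall_thickness=1.0)
        assert set(grid.cell_ids) == {1, 2}

    def test_packaged_synthetic_sections_load(self):
        for name in ("synthetic-wt", "synthetic-wol"):
            tpl = build_template(name)
            assert tpl.cells
            assert tpl.xylem_axis
            rasterize(tpl, dx=1.0, wall_thickness=2.0)
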
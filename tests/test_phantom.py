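"""Phantom geometry, landmark placement, cohort fixture."""

import numpy as np
import pytest

import facefem.cohort as cohort
from facefem.mesh import MeshError
from facefem.phantom import GeometryParams, build_block_mesh, build_phantom


class TestPhantomInvariants:
    @pytest.mark.parametrize(
        "params",
        [
            GeometryParams(),
            GeometryParams(edge_length=8.0),
            GeometryParams(width=60.0, height=70.0, osteotomy_z=40.0,
                           cartilage_z=(45.0, 55.0), nose_z=50.0, cheek_z=50.0),
            GeometryParams(soft_thickness=20.0, bone_thickness=5.0,
                           cartilage_thickness=10.0),
        ],
    )
    def test_invariant_suite(self, params):
        """Region labelling, osteotomy separation and landmark placement
        hold over a grid of geometry parameters."""
        mesh, landmarks = build_phantom(params)
        mesh.validate()  # raises on violation
        landmarks.validate(mesh)
        # all four regions populated
        for region in ("skull_base", "maxilla_mobile", "cartilage", "soft_tissue"):
            assert mesh.region_mask(region).sum() > 0
        # mobile segment lies inferior to the osteotomy plane, anterior of y=0
        mob = mesh.nodes[mesh.region_nodes("maxilla_mobile")]
        assert mob[:, 2].max() < params.osteotomy_z
        base = mesh.nodes[mesh.region_nodes("skull_base")]
        assert base[:, 2].min() > params.osteotomy_z

    def test_midline_mirror_symmetry(self):
        """Mirroring x maps the mesh onto itself (node permutation)."""
        mesh, _ = build_phantom()
        mirrored = mesh.nodes * np.array([-1.0, 1.0, 1.0])
        # node sets coincide
        key = lambda arr: set(map(tuple, np.round(arr, 9)))
        assert key(mesh.nodes) == key(mirrored)
        # element (region, sorted-vertex-coordinates) multisets coincide
        def cells(nodes):
            out = set()
            for tet, rid in zip(mesh.tets, mesh.region_ids):
                pts = tuple(sorted(map(tuple, np.round(nodes[tet], 9))))
                out.add((int(rid), pts))
            return out

        assert cells(mesh.nodes) == cells(mirrored)

    def test_cartilage_inside_soft_layer(self, phantom_default):
        mesh, landmarks = phantom_default
        cart = mesh.nodes[mesh.region_nodes("cartilage")]
        p = GeometryParams()
        assert cart[:, 1].min() >= p.bone_thickness - 1e-9
        assert cart[:, 1].max() < p.depth  # never reaches the skin
        n_xyz = mesh.nodes[landmarks.indices["N"]]
        assert cart[:, 2].min() <= n_xyz[2] <= cart[:, 2].max()

    def test_landmarks_distinct_on_skin_and_symmetric(self, phantom_default):
        mesh, landmarks = phantom_default
        idx = landmarks.index_array()
        assert len(set(idx.tolist())) == 5
        skin_y = GeometryParams().depth
        assert np.allclose(mesh.nodes[idx, 1], skin_y)
        rc = mesh.nodes[landmarks.indices["RC"]]
        lc = mesh.nodes[landmarks.indices["LC"]]
        assert np.allclose(rc * [-1, 1, 1], lc)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(soft_thickness=-1.0),
            dict(width=0.0),
            dict(osteotomy_z=10.0),  # outside the bone plate span
            dict(osteotomy_z=79.0, cartilage_z=(45.0, 60.0)),
            dict(cartilage_thickness=20.0),  # thicker than the soft layer
        ],
    )
    def test_degenerate_parameters_raise(self, bad):
        with pytest.raises(MeshError):
            build_phantom(GeometryParams(**bad))

    def test_too_coarse_mesh_raises(self):
        with pytest.raises(MeshError, match="100"):
            build_phantom(GeometryParams(edge_length=40.0))

    def test_build_is_deterministic(self):
        m1, l1 = build_phantom(seed=3)
        m2, l2 = build_phantom(seed=3)
        assert np.array_equal(m1.nodes, m2.nodes)
        assert np.array_equal(m1.tets, m2.tets)
        assert l1.indices == l2.indices


class TestBlockMesh:
    def test_face_sets_and_volume(self):
        blk = build_block_mesh((10.0, 20.0, 30.0), 5.0)
        assert np.isclose(blk.volumes().sum(), 10 * 20 * 30)
        for tag, axis, val in (("x_min", 0, 0.0), ("y_max", 1, 20.0),
                               ("z_max", 2, 30.0)):
            assert np.allclose(blk.nodes[blk.node_sets[tag], axis], val)

    def test_unknown_region_raises(self):
        with pytest.raises(MeshError):
            build_block_mesh((10.0, 10.0, 10.0), 5.0, region="bone")


class TestCohortFixture:
    def test_table_shape_and_values(self):
        t = cohort.load_cohort_table()
        assert len(t) == 8
        assert list(t["patient"]) == [f"P{i}" for i in range(1, 9)]
        assert t["planned_maxillary_advancement_mm"].tolist() == [
            5, 4.5, 3.5, 4.5, 5.5, 4.5, 5.5, 4
        ]

    @pytest.mark.parametrize(
        "column,stat,rounding,expected",
        [
            ("planned_advancement", "mean", "1dp", 4.6),
            ("surgery_to_postop", "mean", "integer", 67),
            ("surgery_to_postop", "sd", "integer", 23),
            ("age", "mean", "none", 23.125),
            ("preop_to_surgery", "mean", "integer", 94),
        ],
    )
    def test_summaries(self, column, stat, rounding, expected):
        t = cohort.load_cohort_table()
        assert cohort.summarize_column(t, column, stat, rounding) == pytest.approx(
            expected
        )

    def test_errors(self):
        t = cohort.load_cohort_table()
        with pytest.raises(KeyError):
            cohort.summarize_column(t, "no_such_column")
        with pytest.raises(ValueError):
            cohort.summarize_column(t, "age", statistic="median")
        with pytest.raises(ValueError):
            cohort.summarize_column(t, "age", rounding="2dp")
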
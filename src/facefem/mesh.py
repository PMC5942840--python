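"""Labelled tetrahedral meshes for the layered midface phantom.

The mesh container is deliberately small: node coordinates in mm, tetrahedra
as 4-tuples of node indices, one region label per tetrahedron and a dict of
named boundary node sets.  Regions follow the anatomy of a Le Fort I model:
a fixed skull base, the osteotomised mobile maxillary segment, a nasal
cartilage inclusion and a homogeneous soft-tissue layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Region names in canonical order; region ids index into this tuple.
REGIONS = ("skull_base", "maxilla_mobile", "cartilage", "soft_tissue")

SKULL_BASE = 0
MAXILLA_MOBILE = 1
CARTILAGE = 2
SOFT_TISSUE = 3

#: Cephalometric landmark names in canonical order: pronasale (nose tip),
#: labrale superius (upper lip), labrale inferius (lower lip), right and
#: left cheek points.
LANDMARKS = ("N", "UL", "LL", "RC", "LC")


class MeshError(ValueError):
    """Raised for invalid mesh parameters or inconsistent meshes."""


@dataclass
class LabeledTetMesh:
    """Tetrahedral mesh with per-element region labels and named node sets.

    Attributes
    ----------
    nodes : (n_nodes, 3) float array
        Node coordinates in mm; x lateral, y anterior (advancement
        direction), z superior.
    tets : (n_tets, 4) int array
        Node indices of each tetrahedron, positively oriented.
    region_ids : (n_tets,) int array
        Index into :data:`REGIONS` per tetrahedron.
    node_sets : dict
        Named node index arrays (boundary faces per region, mobile-segment
        surface, skin surface...).
    """

    nodes: np.ndarray
    tets: np.ndarray
    region_ids: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    #: parent-cell id per tetrahedron for structured meshes (6 tets share a
    #: hexahedral cell); used for patch-averaged volumetric strain.  None
    #: for meshes of unknown provenance.
    patch_ids: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_tets(self) -> int:
        return int(self.tets.shape[0])

    def region_mask(self, name: str) -> np.ndarray:
        if name not in REGIONS:
            raise MeshError(f"unknown region {name!r}; expected one of {REGIONS}")
        return self.region_ids == REGIONS.index(name)

    def region_nodes(self, name: str) -> np.ndarray:
        """Sorted unique node indices touched by tetrahedra of a region."""
        return np.unique(self.tets[self.region_mask(name)])

    def volumes(self) -> np.ndarray:
        """Signed tetrahedron volumes (mm^3)."""
        p = self.nodes[self.tets]
        a, b, c = (p[:, i + 1] - p[:, 0] for i in range(3))
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def surface_nodes(self, region: str | None = None) -> np.ndarray:
        """Node indices on the boundary surface of the (sub)mesh.

        A face is on the surface if it belongs to exactly one tetrahedron of
        the selected element subset.
        """
        tets = self.tets if region is None else self.tets[self.region_mask(region)]
        faces = tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
        faces = np.sort(faces, axis=1)
        uniq, counts = np.unique(faces, axis=0, return_counts=True)
        return np.unique(uniq[counts == 1])

    def validate(self) -> None:
        """Check structural invariants; raise :class:`MeshError` on failure."""
        if self.tets.shape[1] != 4:
            raise MeshError("tets must have 4 nodes each")
        if self.region_ids.shape[0] != self.n_tets:
            raise MeshError("one region label per tetrahedron required")
        vols = self.volumes()
        if np.any(vols <= 0):
            raise MeshError(
                f"{int(np.sum(vols <= 0))} non-positive-volume tetrahedra"
            )
        base = set(self.region_nodes("skull_base").tolist())
        mobile = set(self.region_nodes("maxilla_mobile").tolist())
        if base & mobile:
            raise MeshError(
                "skull_base and maxilla_mobile share nodes: osteotomy gap missing"
            )
        soft = set(self.region_nodes("soft_tissue").tolist())
        if base and not (base & soft):
            raise MeshError("skull_base is not bonded to soft_tissue")
        if mobile and not (mobile & soft):
            raise MeshError("maxilla_mobile is not bonded to soft_tissue")


@dataclass
class LandmarkSet:
    """The five facial landmark probes on the outer skin surface."""

    indices: dict[str, int]

    def __post_init__(self) -> None:
        missing = [k for k in LANDMARKS if k not in self.indices]
        if missing:
            raise MeshError(f"missing landmarks: {missing}")

    def index_array(self) -> np.ndarray:
        return np.array([self.indices[k] for k in LANDMARKS], dtype=int)

    def coordinates(self, mesh: LabeledTetMesh) -> np.ndarray:
        return mesh.nodes[self.index_array()]

    def validate(self, mesh: LabeledTetMesh) -> None:
        idx = self.index_array()
        if len(set(idx.tolist())) != 5:
            raise MeshError("landmark node indices must be distinct")
        skin = set(mesh.surface_nodes("soft_tissue").tolist())
        if not set(idx.tolist()) <= skin:
            raise MeshError("landmarks must be soft-tissue surface nodes")
        xyz = mesh.nodes[idx]
        rc, lc = xyz[LANDMARKS.index("RC")], xyz[LANDMARKS.index("LC")]
        mirrored = rc * np.array([-1.0, 1.0, 1.0])
        if not np.allclose(mirrored, lc, atol=1e-9):
            raise MeshError("RC and LC must be mirror-symmetric about x = 0")
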
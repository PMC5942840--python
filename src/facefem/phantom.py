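"""Synthetic layered midface phantom.

The phantom is a rectangular layered block that reproduces the mechanical
structure a Le Fort I advancement acts on, without anatomical surface detail:

* a stiff posterior bone plate split by an osteotomy gap into a fixed
  *skull base* (superior) and a *mobile maxillary segment* (inferior),
* a near-incompressible homogeneous *soft-tissue* slab covering the bone
  anteriorly and wrapping below it (where the mandible would be),
* a *cartilage* inclusion embedded in the soft tissue behind the nose
  landmark,
* the five cephalometric probes N, UL, LL, RC, LC on the outer skin surface.

Coordinates: x lateral (midline at x = 0), y anterior (the advancement
direction), z superior; all lengths in mm.  Meshing is a structured
subdivision into 6 tetrahedra per hexahedral cell, mirrored about the
midline so the mesh is exactly symmetric in x.

The module also synthesises ground-truth "postoperative" landmark
displacements (a stand-in for postoperative CBCT measurements) by running
the forward solver at hidden true inputs and adding measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mesh import (
    CARTILAGE,
    LANDMARKS,
    MAXILLA_MOBILE,
    REGIONS,
    SKULL_BASE,
    SOFT_TISSUE,
    LabeledTetMesh,
    LandmarkSet,
    MeshError,
)

_VOID = -1

# 6-tet decomposition of a hexahedron around the v0-v6 diagonal, VTK corner
# numbering; all positively oriented.
_HEX_TO_TETS = np.array(
    [
        [0, 1, 2, 6],
        [0, 2, 3, 6],
        [0, 3, 7, 6],
        [0, 7, 4, 6],
        [0, 4, 5, 6],
        [0, 5, 1, 6],
    ]
)
# Corner permutation induced by mirroring x: (di,dj,dk) -> (1-di,dj,dk).
_MIRROR_CORNER = np.array([1, 0, 3, 2, 5, 4, 7, 6])
# Mirrored decomposition, orientation restored by swapping the last two nodes.
_HEX_TO_TETS_MIRROR = _MIRROR_CORNER[_HEX_TO_TETS][:, [0, 1, 3, 2]]


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of the layered block phantom (mm).

    Defaults give a midface-sized domain (80 x 25 x 80 mm) with a 10 mm
    bone plate, a 15 mm soft-tissue layer and an osteotomy at z = 45 mm.
    ``edge_length`` is the target element edge length (mesh density).
    """

    width: float = 80.0
    height: float = 80.0
    bone_thickness: float = 10.0
    soft_thickness: float = 20.0
    bone_z_min: float = 25.0
    # the gap interval (osteotomy_z +/- gap/2) spans whole cell layers at
    # the default and half-default edge lengths, so refining the mesh does
    # not change the carved gap
    osteotomy_z: float = 42.5
    osteotomy_gap: float = 5.0
    cartilage_halfwidth: float = 10.0
    cartilage_thickness: float = 10.0
    # septal/alar cartilage block bridging the osteotomy level up to the
    # nose landmark
    cartilage_z: tuple[float, float] = (40.0, 55.0)
    edge_length: float = 5.0
    # nominal landmark positions on the skin (snapped to the nearest node)
    nose_z: float = 50.0
    upper_lip_z: float = 30.0
    lower_lip_z: float = 15.0
    cheek_x: float = 20.0
    cheek_z: float = 55.0

    @property
    def depth(self) -> float:
        return self.bone_thickness + self.soft_thickness

    def validate(self) -> None:
        pos = {
            "width": self.width,
            "height": self.height,
            "bone_thickness": self.bone_thickness,
            "soft_thickness": self.soft_thickness,
            "edge_length": self.edge_length,
            "osteotomy_gap": self.osteotomy_gap,
        }
        for name, v in pos.items():
            if not v > 0:
                raise MeshError(f"{name} must be positive, got {v}")
        lo = self.osteotomy_z - self.osteotomy_gap / 2
        hi = self.osteotomy_z + self.osteotomy_gap / 2
        if not (self.bone_z_min < lo and hi < self.height):
            raise MeshError("osteotomy plane (and gap) must lie inside the bone plate")
        cz0, cz1 = self.cartilage_z
        if not (self.bone_z_min < cz0 < cz1 <= self.height):
            raise MeshError("cartilage box must lie within the bone-plate z-span")
        if self.cartilage_thickness >= self.soft_thickness:
            raise MeshError("cartilage must be strictly inside the soft-tissue layer")


def _axis_coords(length: float, h: float) -> np.ndarray:
    n = max(1, int(round(length / h)))
    return np.linspace(0.0, length, n + 1)


def _classify_cell(p: GeometryParams, xc, y0, y1, z0, z1) -> int:
    """Region id of a hex cell from its centre (void cells return -1)."""
    yc, zc = 0.5 * (y0 + y1), 0.5 * (z0 + z1)
    gap_lo = p.osteotomy_z - p.osteotomy_gap / 2
    gap_hi = p.osteotomy_z + p.osteotomy_gap / 2
    if yc < p.bone_thickness and zc > p.bone_z_min:
        # bone plate; carve the osteotomy gap out of any overlapping layer
        if z0 < gap_hi and z1 > gap_lo:
            return _VOID
        return MAXILLA_MOBILE if zc < p.osteotomy_z else SKULL_BASE
    cz0, cz1 = p.cartilage_z
    if (
        abs(xc) <= p.cartilage_halfwidth
        and p.bone_thickness <= yc <= p.bone_thickness + p.cartilage_thickness
        and y1 < p.depth  # cartilage must never reach the skin surface
        and cz0 <= zc <= cz1
    ):
        return CARTILAGE
    return SOFT_TISSUE


def _structured_tets(xs, ys, zs, classify, mirror_about: float | None = None):
    """Tets + labels for a tensor grid; cells classified by their centre.

    With ``mirror_about`` set, cells left of that x-plane use the mirrored
    hex decomposition so the tet set is closed under x-reflection.
    """
    nx, ny, nz = len(xs) - 1, len(ys) - 1, len(zs) - 1

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets, labels = [], []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                xc = 0.5 * (xs[i] + xs[i + 1])
                region = classify(xc, ys[j], ys[j + 1], zs[k], zs[k + 1])
                if region == _VOID:
                    continue
                # VTK hexahedron corner order
                c = [
                    nid(i, j, k),
                    nid(i + 1, j, k),
                    nid(i + 1, j + 1, k),
                    nid(i, j + 1, k),
                    nid(i, j, k + 1),
                    nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1),
                    nid(i, j + 1, k + 1),
                ]
                patt = _HEX_TO_TETS
                if mirror_about is not None and xc < mirror_about:
                    patt = _HEX_TO_TETS_MIRROR
                for t in patt:
                    tets.append([c[t[0]], c[t[1]], c[t[2]], c[t[3]]])
                    labels.append(region)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return nodes, np.array(tets, dtype=np.int64), np.array(labels, dtype=np.int64)


def _compress(nodes, tets):
    """Drop nodes not referenced by any tetrahedron."""
    used, inv = np.unique(tets, return_inverse=True)
    return nodes[used], inv.reshape(tets.shape).astype(np.int64)


def _coord_set(nodes, idx_pool, axis, value, tol=1e-9):
    sel = np.abs(nodes[idx_pool, axis] - value) < tol
    return np.asarray(idx_pool)[sel]


def build_phantom(
    params: GeometryParams | None = None, seed: int = 0
) -> tuple[LabeledTetMesh, LandmarkSet]:
    """Build the layered midface phantom mesh and its landmark set.

    Deterministic for fixed ``params`` (the structured mesh involves no
    randomness; ``seed`` is accepted for interface uniformity with the other
    generators and recorded only).
    """
    p = params or GeometryParams()
    p.validate()
    h = p.edge_length
    xs_half = _axis_coords(p.width / 2, h)
    xs = np.concatenate([-xs_half[::-1][:-1], xs_half])
    ys = _axis_coords(p.depth, h)
    # z is graded: half-size cells below the bone plate, where displacements
    # are small and the clamped bottom edge makes the solution steep
    zs_lo = _axis_coords(p.bone_z_min, h / 2)
    zs_hi = p.bone_z_min + _axis_coords(p.height - p.bone_z_min, h)
    zs = np.concatenate([zs_lo[:-1], zs_hi])

    nodes, tets, labels = _structured_tets(
        xs, ys, zs,
        lambda xc, y0, y1, z0, z1: _classify_cell(p, xc, y0, y1, z0, z1),
        mirror_about=0.0,
    )
    nodes, tets = _compress(nodes, tets)
    if nodes.shape[0] < 100:
        raise MeshError(
            f"mesh density too coarse: only {nodes.shape[0]} nodes (< 100); "
            "decrease edge_length"
        )
    mesh = LabeledTetMesh(
        nodes=nodes, tets=tets, region_ids=labels,
        patch_ids=np.arange(tets.shape[0]) // 6,  # 6 tets per parent hex
    )

    soft = mesh.region_nodes("soft_tissue")
    base = mesh.region_nodes("skull_base")
    sets = {
        "soft_y_min": _coord_set(nodes, soft, 1, 0.0),
        "soft_z_min": _coord_set(nodes, soft, 2, 0.0),
        "soft_z_max": _coord_set(nodes, soft, 2, p.height),
        "bone_y_min": _coord_set(nodes, base, 1, 0.0),
        "bone_z_max": _coord_set(nodes, base, 2, p.height),
        "mobile_surface": mesh.surface_nodes("maxilla_mobile"),
        "skin": _coord_set(nodes, soft, 1, p.depth),
    }
    for region in REGIONS:
        pool = mesh.region_nodes(region)
        if pool.size == 0:
            continue
        for axis, tag in ((1, "y"), (2, "z")):
            vals = nodes[pool, axis]
            sets[f"{region}_{tag}_min"] = _coord_set(nodes, pool, axis, vals.min())
            sets[f"{region}_{tag}_max"] = _coord_set(nodes, pool, axis, vals.max())
    mesh.node_sets = sets

    mesh.validate()
    landmarks = _place_landmarks(mesh, p)
    landmarks.validate(mesh)
    _check_cartilage_under_nose(mesh, landmarks, p)
    return mesh, landmarks


def _place_landmarks(mesh: LabeledTetMesh, p: GeometryParams) -> LandmarkSet:
    skin = mesh.node_sets["skin"]
    pts = mesh.nodes[skin]

    def snap(target):
        d = np.linalg.norm(pts - np.asarray(target), axis=1)
        return int(skin[int(np.argmin(d))])

    y = p.depth
    idx = {
        "N": snap((0.0, y, p.nose_z)),
        "UL": snap((0.0, y, p.upper_lip_z)),
        "LL": snap((0.0, y, p.lower_lip_z)),
        "RC": snap((+p.cheek_x, y, p.cheek_z)),
    }
    # left cheek = exact mirror of the snapped right cheek
    rc_xyz = mesh.nodes[idx["RC"]] * np.array([-1.0, 1.0, 1.0])
    idx["LC"] = snap(rc_xyz)
    return LandmarkSet(indices=idx)


def _check_cartilage_under_nose(mesh, landmarks, p) -> None:
    cart = mesh.region_nodes("cartilage")
    if cart.size == 0:
        raise MeshError("phantom has no cartilage elements; refine the mesh")
    cxyz = mesh.nodes[cart]
    if cxyz[:, 1].max() >= p.depth:  # must not reach the skin surface
        raise MeshError("cartilage touches the skin surface")
    n_xyz = mesh.nodes[landmarks.indices["N"]]
    in_x = cxyz[:, 0].min() <= n_xyz[0] <= cxyz[:, 0].max()
    in_z = cxyz[:, 2].min() <= n_xyz[2] <= cxyz[:, 2].max()
    if not (in_x and in_z):
        raise MeshError("cartilage inclusion is not located beneath landmark N")


def build_block_mesh(
    lengths: tuple[float, float, float],
    edge_length: float,
    region: str = "soft_tissue",
) -> LabeledTetMesh:
    """Single-region rectangular block with face node sets (test oracle mesh).

    Node sets ``x_min .. z_max`` name the six faces.  Used by the analytic
    verification cases (uniaxial extension, relaxation oracles).
    """
    if region not in REGIONS:
        raise MeshError(f"unknown region {region!r}")
    xs = _axis_coords(lengths[0], edge_length)
    ys = _axis_coords(lengths[1], edge_length)
    zs = _axis_coords(lengths[2], edge_length)
    rid = REGIONS.index(region)
    nodes, tets, labels = _structured_tets(xs, ys, zs, lambda *_: rid)
    mesh = LabeledTetMesh(
        nodes=nodes, tets=tets, region_ids=labels,
        patch_ids=np.arange(tets.shape[0]) // 6,
    )
    all_idx = np.arange(mesh.n_nodes)
    for axis, tag in ((0, "x"), (1, "y"), (2, "z")):
        mesh.node_sets[f"{tag}_min"] = _coord_set(nodes, all_idx, axis, 0.0)
        mesh.node_sets[f"{tag}_max"] = _coord_set(nodes, all_idx, axis, lengths[axis])
    return mesh


def refine(params: GeometryParams, factor: float = 2.0) -> GeometryParams:
    """Geometry with the target edge length divided by ``factor``."""
    return replace(params, edge_length=params.edge_length / factor)


def synthesize_truth(
    mesh: LabeledTetMesh,
    landmarks: LandmarkSet,
    true_inputs,
    noise_sd: float = 0.2,
    seed: int = 0,
    prony=None,
    time_grid=None,
    solver=None,
) -> np.ndarray:
    """Ground-truth "postoperative" landmark displacements (mm).

    Runs the viscoelastic forward solve at the hidden true inputs and adds
    zero-mean Gaussian measurement noise of standard deviation ``noise_sd``
    (mm) per landmark, standing in for segmentation and registration error
    of a postoperative CBCT measurement.  With ``noise_sd = 0`` the result
    is exactly the forward solve.  Reproducible given ``seed``.

    An existing :class:`~facefem.fem_core.ViscoelasticSolver` for ``mesh``
    can be passed via ``solver`` to reuse its precomputations.
    """
    from . import fem_core  # deferred: fem_core imports mesh types

    true_inputs.validate()
    if solver is None:
        solver = fem_core.ViscoelasticSolver(mesh)
    field = solver.solve(true_inputs, prony=prony, time_grid=time_grid)
    disp = fem_core.extract_landmarks(field, landmarks)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return disp
    rng = np.random.default_rng(seed)
    return disp + rng.normal(0.0, noise_sd, size=len(LANDMARKS))
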
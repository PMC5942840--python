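"""Quasi-static linear viscoelastic tetrahedral FEM.

Model
-----
Small-strain, quasi-static linear elasticity on linear tetrahedra.  Bone
(skull base and mobile maxillary segment) and nasal cartilage are purely
elastic; the facial soft tissue is linear viscoelastic with a two-term
Prony shear-relaxation series and *no volumetric relaxation* (the tissue is
treated as nearly incompressible, so relaxation acts on the deviatoric
response only):

    G(t) / G0 = 1 - s * sum_i g_i (1 - exp(-t / tau_i))

with weights ``g = (0.325, 0.3)`` and characteristic times
``tau = (1, 6) s`` by default (62.5 % total relaxation at unit scale), and
a dimensionless scale factor ``s`` that sweeps the relaxation between
30.5 % (s = 0.488) and 94.4 % (s = 1.512).

Near-incompressibility (``nu_soft`` up to 0.499) is handled with a B-bar
treatment: the volumetric strain of each soft-tissue element is replaced by
a node-averaged (volume-weighted) projection, which relieves the locking of
plain linear tetrahedra while leaving the deviatoric operator untouched.

Time integration uses the standard internal-variable exponential recurrence
(exact for strain varying linearly within a step): a linear ramp of the
prescribed advancement followed by a hold on a log-spaced grid, with the
end-of-hold field reported as the "postoperative" prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import LANDMARKS, REGIONS, LabeledTetMesh, LandmarkSet

__all__ = [
    "PronySeries",
    "InputVector",
    "BoundarySpec",
    "DisplacementField",
    "FEMError",
    "default_prony",
    "shear_relaxation",
    "relaxation_percent",
    "scale_for_relaxation",
    "table2_bounds",
    "INPUT_FIELDS",
    "MATERIAL_FIELDS",
    "default_boundary_spec",
    "default_time_grid",
    "ViscoelasticSolver",
    "solve_viscoelastic",
    "solve_elastic",
    "extract_landmarks",
]


class FEMError(RuntimeError):
    """Raised for ill-posed or non-convergent finite-element problems."""


# ---------------------------------------------------------------------------
# Prony series shear relaxation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PronySeries:
    """Normalised shear-relaxation series: weights g_i and times tau_i (s)."""

    g: tuple[float, ...] = (0.325, 0.3)
    tau: tuple[float, ...] = (1.0, 6.0)

    def __post_init__(self) -> None:
        if len(self.g) != len(self.tau):
            raise ValueError("g and tau must have the same length")
        if any(gi <= 0 for gi in self.g) or any(ti <= 0 for ti in self.tau):
            raise ValueError("Prony weights and times must be positive")
        if sum(self.g) >= 1.0:
            raise ValueError("sum of Prony weights must be < 1")

    @property
    def total(self) -> float:
        return float(sum(self.g))


def default_prony() -> PronySeries:
    """The two-term soft-tissue series (62.5 % total relaxation)."""
    return PronySeries()


def shear_relaxation(t, prony: PronySeries | None = None, scale: float = 1.0):
    """Normalised shear relaxation modulus G(t)/G0.

    ``G(t)/G0 = 1 - scale * sum_i g_i (1 - exp(-t/tau_i))``; monotone
    non-increasing in t with limit ``1 - scale * sum(g)``.
    """
    prony = prony or default_prony()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if scale * prony.total >= 1.0:
        raise ValueError("scale * sum(g) must be < 1 (long-time modulus > 0)")
    g = np.asarray(prony.g)
    tau = np.asarray(prony.tau)
    rel = np.sum(g * (1.0 - np.exp(-t[..., None] / tau)), axis=-1)
    out = 1.0 - scale * rel
    return float(out) if out.ndim == 0 else out


def relaxation_percent(scale: float, prony: PronySeries | None = None) -> float:
    """Long-time relaxation in percent, ``100 * scale * sum(g)``."""
    prony = prony or default_prony()
    return 100.0 * scale * prony.total


def scale_for_relaxation(percent: float, prony: PronySeries | None = None) -> float:
    """Scale factor producing a given long-time relaxation percentage."""
    prony = prony or default_prony()
    return percent / (100.0 * prony.total)


# ---------------------------------------------------------------------------
# Uncertain inputs
# ---------------------------------------------------------------------------

INPUT_FIELDS = (
    "E_bone",
    "nu_bone",
    "E_cart",
    "nu_cart",
    "E_soft",
    "nu_soft",
    "G_scale",
    "x_adv",
)

#: The four soft/cartilage material parameters that the optimisation stage
#: operates on (bone properties are screened out; advancement is not a
#: material property).
MATERIAL_FIELDS = ("E_cart", "E_soft", "nu_soft", "G_scale")


@dataclass(frozen=True)
class InputVector:
    """One realisation of the eight uncertain model inputs.

    Young's moduli in MPa, Poisson's ratios dimensionless, ``G_scale`` the
    Prony scaling factor, ``x_adv`` the prescribed anterior advancement of
    the mobile maxillary segment in mm.
    """

    E_bone: float = 10000.0
    nu_bone: float = 0.3
    E_cart: float = 2.75
    nu_cart: float = 0.32
    E_soft: float = 0.55
    nu_soft: float = 0.4745
    G_scale: float = 1.0
    x_adv: float = 4.6

    def validate(self, prony: PronySeries | None = None) -> None:
        prony = prony or default_prony()
        for name in ("E_bone", "E_cart", "E_soft"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("nu_bone", "nu_cart", "nu_soft"):
            nu = getattr(self, name)
            if not (0.0 <= nu < 0.5):
                raise ValueError(f"{name} must lie in [0, 0.5), got {nu}")
        if self.G_scale * prony.total >= 1.0:
            raise ValueError("G_scale * sum(g) must be < 1")
        if self.x_adv < 0:
            raise ValueError("x_adv must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in INPUT_FIELDS])

    def as_dict(self) -> dict[str, float]:
        return {f: float(getattr(self, f)) for f in INPUT_FIELDS}

    def replace(self, **kw) -> "InputVector":
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d) -> "InputVector":
        return cls(**{f: float(d[f]) for f in INPUT_FIELDS})


def table2_bounds(planned_advancement: float = 4.6) -> dict[str, tuple[float, float]]:
    """Literature min/max of the uncertain inputs.

    Bone, cartilage and soft-tissue elastic ranges; the Prony scale factor
    spanning 30.5-94.4 % relaxation; and the advancement uncertainty of
    +/- 2 mm around the planned value.
    """
    return {
        "E_bone": (5000.0, 15000.0),
        "nu_bone": (0.2, 0.4),
        "E_cart": (0.5, 5.0),
        "nu_cart": (0.26, 0.38),
        "E_soft": (0.1, 1.0),
        "nu_soft": (0.45, 0.499),
        "G_scale": (0.488, 1.512),
        "x_adv": (planned_advancement - 2.0, planned_advancement + 2.0),
    }


def midrange_inputs(bounds: dict[str, tuple[float, float]] | None = None) -> InputVector:
    """Input vector with every field at the midpoint of its range."""
    bounds = bounds or table2_bounds()
    return InputVector(**{k: 0.5 * (lo + hi) for k, (lo, hi) in bounds.items()})


# ---------------------------------------------------------------------------
# Boundary conditions and time protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundarySpec:
    """Fixed node sets (with constrained axes) and the prescribed advancement.

    ``fixed`` maps node-set names to axis tuples (0 = x, 1 = y, 2 = z).
    The prescribed set translates rigidly by ``direction * x_adv`` ramped
    linearly over ``ramp`` seconds, then held for ``hold`` seconds.
    """

    fixed: tuple[tuple[str, tuple[int, ...]], ...]
    prescribed_set: str = "mobile_surface"
    direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    prescribed_axes: tuple[int, ...] = (0, 1, 2)
    ramp: float = 1.0
    hold: float = 59.0

    @property
    def t_end(self) -> float:
        return self.ramp + self.hold


def default_boundary_spec() -> BoundarySpec:
    """Phantom boundary conditions.

    Soft tissue fixed on its posterior (y_min), superior (z_max) and
    inferior (z_min) faces; skull base fixed posteriorly (y_min) and
    superiorly (z_max); anterior translation prescribed on all surface
    nodes of the mobile maxillary segment.
    """
    axes = (0, 1, 2)
    return BoundarySpec(
        fixed=(
            ("soft_y_min", axes),
            ("soft_z_min", axes),
            ("soft_z_max", axes),
            ("bone_y_min", axes),
            ("bone_z_max", axes),
        ),
    )


def default_time_grid(
    ramp: float = 1.0,
    t_end: float = 60.0,
    n_ramp: int = 4,
    n_hold: int = 12,
    log_hold: bool = False,
) -> np.ndarray:
    """Solution times: linear ramp steps then hold steps to ``t_end``.

    The default holds to ``t_end = 10 * max(tau) = 60 s``, where the
    default series is within 1e-4 of its long-time modulus.  Hold steps are
    uniform by default (each unique step size shares one matrix
    factorisation, see :class:`ViscoelasticSolver`); ``log_hold=True``
    gives a log-spaced hold grid instead.
    """
    ramp_t = np.linspace(0.0, ramp, n_ramp + 1)
    if log_hold:
        hold_t = np.geomspace(ramp, t_end, n_hold + 1)[1:]
    else:
        hold_t = np.linspace(ramp, t_end, n_hold + 1)[1:]
    return np.concatenate([ramp_t, hold_t])


@dataclass
class DisplacementField:
    """Nodal displacement snapshots (mm) at stored solution times."""

    times: np.ndarray
    u: np.ndarray  # (n_times, n_nodes, 3)

    def final(self) -> np.ndarray:
        return self.u[-1]


def extract_landmarks(
    field_or_u, landmarks: LandmarkSet, component: int = 1, time_index: int = -1
) -> np.ndarray:
    """Signed displacement component at the five landmarks (mm).

    Default is the anterior (y) component at the final stored time, with
    the preoperative configuration as the zero baseline.
    """
    u = field_or_u.u[time_index] if isinstance(field_or_u, DisplacementField) else field_or_u
    idx = landmarks.index_array()
    if np.any(idx >= u.shape[0]):
        raise IndexError("landmark node index out of range")
    return np.asarray(u[idx, component], dtype=float)


# ---------------------------------------------------------------------------
# Element machinery
# ---------------------------------------------------------------------------

_M = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
# Deviatoric projector in Voigt notation (engineering shear):
# sigma_dev = 2G * PD6 @ eps
_PD6 = np.diag([1.0, 1.0, 1.0, 0.5, 0.5, 0.5]) - np.outer(_M, _M) / 3.0


def _element_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Shape-function gradients (E,4,3) and volumes (E,) of linear tets."""
    p = nodes[tets]  # (E,4,3)
    J = p[:, 1:] - p[:, :1]  # (E,3,3) rows = edge vectors
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    if np.any(vol <= 0):
        raise FEMError("mesh contains non-positively oriented tetrahedra")
    Jinv = np.linalg.inv(J)  # (E,3,3)
    # gradient of shape functions 1..3 are columns of J^-1 (d xi / d x)
    g123 = np.transpose(Jinv, (0, 2, 1))  # (E,3,3): g123[e,i] = grad N_{i+1}
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1), vol


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """Voigt strain-displacement matrices B (E,6,12), engineering shear."""
    E = grads.shape[0]
    B = np.zeros((E, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B


def _assemble(ke: np.ndarray, dofs: np.ndarray, ndof: int) -> sp.csr_matrix:
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()


def _lame(E: float, nu: float) -> tuple[float, float]:
    """(shear modulus G, bulk modulus kappa)."""
    return E / (2.0 * (1.0 + nu)), E / (3.0 * (1.0 - 2.0 * nu))


class ViscoelasticSolver:
    """Reusable solver for one labelled mesh.

    Precomputes element operators and region-wise unit stiffness blocks so
    repeated solves (designs of experiments) only rescale and refactorise.
    """

    def __init__(self, mesh: LabeledTetMesh, bc: BoundarySpec | None = None):
        mesh.validate()
        self.mesh = mesh
        self.bc = bc or default_boundary_spec()
        self.n_solves = 0
        nodes, tets = mesh.nodes, mesh.tets
        self.ndof = 3 * mesh.n_nodes
        grads, vol = _element_gradients(nodes, tets)
        self.vol = vol
        B = _b_matrices(grads)
        dofs = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)

        self._K_dev: dict[str, sp.csr_matrix] = {}
        self._K_vol: dict[str, sp.csr_matrix] = {}
        for region in REGIONS:
            m = mesh.region_mask(region)
            if not m.any():
                continue
            Br, dr, vr = B[m], dofs[m], vol[m]
            ke_dev = np.einsum("eia,ij,ejb->eab", Br, _PD6, Br) * vr[:, None, None]
            self._K_dev[region] = _assemble(ke_dev, dr, self.ndof)
            if region == "soft_tissue":
                patches = None if mesh.patch_ids is None else mesh.patch_ids[m]
                self._K_vol[region] = self._smoothed_vol_operator(
                    tets[m], Br, dr, vr, patches
                )
            else:
                bv = Br[:, :3, :].sum(axis=1)  # m^T B
                ke_vol = np.einsum("ea,eb->eab", bv, bv) * vr[:, None, None]
                self._K_vol[region] = _assemble(ke_vol, dr, self.ndof)

        # soft-tissue element data for the viscoelastic history update
        msoft = mesh.region_mask("soft_tissue")
        self._B_soft = self._big_b(B[msoft], dofs[msoft])
        self._vol_soft = vol[msoft]
        self._n_soft = int(msoft.sum())

    def _big_b(self, B: np.ndarray, dofs: np.ndarray) -> sp.csr_matrix:
        """Sparse (6E x ndof) operator: strains of all soft elements."""
        E = B.shape[0]
        rows = np.repeat(np.arange(6 * E), 12)
        cols = np.tile(dofs[:, None, :], (1, 6, 1)).ravel()
        return sp.coo_matrix(
            (B.ravel(), (rows, cols)), shape=(6 * E, self.ndof)
        ).tocsr()

    def _smoothed_vol_operator(
        self, tets, B, dofs, vol, patches=None
    ) -> sp.csr_matrix:
        """Averaged-volumetric-strain (B-bar) stiffness, unit bulk modulus.

        The volumetric strain is replaced by its volume-weighted average
        over an element patch and the volumetric energy integrated with
        patch volumes, relieving the volumetric locking of linear
        tetrahedra near nu = 0.5.  For structured meshes the patches are
        the parent hexahedral cells (classic mean-dilatation B-bar); for
        meshes without patch information the averaging falls back to
        nodal patches (node-based uniform strain), which is more
        diffusive.
        """
        E = tets.shape[0]
        bv = B[:, :3, :].sum(axis=1)  # (E,12): theta_e = bv . u_e
        rows = np.repeat(np.arange(E), 12)
        Gv = sp.coo_matrix((bv.ravel(), (rows, dofs.ravel())), shape=(E, self.ndof))
        if patches is not None:
            _, pid = np.unique(np.asarray(patches), return_inverse=True)
            P = sp.coo_matrix(
                (vol, (pid, np.arange(E))), shape=(pid.max() + 1, E)
            ).tocsr()
            vol_p = np.asarray(P.sum(axis=1)).ravel()
            Gp = (sp.diags(1.0 / vol_p) @ P @ Gv).tocsr()
            return (Gp.T @ sp.diags(vol_p) @ Gp).tocsr()
        # nodal fallback
        n_idx = tets.ravel()
        e_idx = np.repeat(np.arange(E), 4)
        w = np.repeat(vol / 4.0, 4)
        A = sp.coo_matrix((w, (n_idx, e_idx)), shape=(self.mesh.n_nodes, E)).tocsr()
        vol_n = np.asarray(A.sum(axis=1)).ravel()
        keep = vol_n > 0
        An = sp.diags(np.where(keep, 1.0 / np.where(keep, vol_n, 1.0), 0.0)) @ A
        Gn = (An @ Gv).tocsr()
        return (Gn.T @ sp.diags(vol_n) @ Gn).tocsr()

    # -- boundary conditions ------------------------------------------------

    def _dirichlet(self, inputs: InputVector, bc: BoundarySpec):
        sets = self.mesh.node_sets
        fixed: dict[int, float] = {}
        for name, axes in bc.fixed:
            if name not in sets:
                raise FEMError(f"unknown boundary node set {name!r}")
            for n in sets[name]:
                for ax in axes:
                    fixed[3 * int(n) + ax] = 0.0
        if bc.prescribed_set not in sets:
            raise FEMError(f"unknown prescribed node set {bc.prescribed_set!r}")
        presc_dofs, presc_vals = [], []
        d = np.asarray(bc.direction) * inputs.x_adv
        for n in sets[bc.prescribed_set]:
            for ax in bc.prescribed_axes:
                dof = 3 * int(n) + ax
                fixed.pop(dof, None)
                presc_dofs.append(dof)
                presc_vals.append(d[ax])
        fdofs = np.array(sorted(fixed), dtype=int)
        pdofs = np.array(presc_dofs, dtype=int)
        all_c = np.concatenate([fdofs, pdofs])
        vals = np.concatenate([np.zeros(len(fdofs)), np.array(presc_vals)])
        order = np.argsort(all_c)
        return all_c[order], vals[order]

    # -- solves -------------------------------------------------------------

    def _stiffness_parts(self, inputs: InputVector):
        """(K_base, K_soft_dev): full stiffness is K_base + f * K_soft_dev."""
        G_b, k_b = _lame(inputs.E_bone, inputs.nu_bone)
        G_c, k_c = _lame(inputs.E_cart, inputs.nu_cart)
        G_s, k_s = _lame(inputs.E_soft, inputs.nu_soft)
        K = sp.csr_matrix((self.ndof, self.ndof))
        for region, (G, k) in {
            "skull_base": (G_b, k_b),
            "maxilla_mobile": (G_b, k_b),
            "cartilage": (G_c, k_c),
        }.items():
            if region in self._K_dev:
                K = K + 2.0 * G * self._K_dev[region] + k * self._K_vol[region]
        K = K + k_s * self._K_vol["soft_tissue"]
        return K, (2.0 * G_s) * self._K_dev["soft_tissue"]

    def _stiffness(self, inputs: InputVector, soft_shear_factor: float):
        K_base, K_dev = self._stiffness_parts(inputs)
        return K_base + soft_shear_factor * K_dev

    def _solve_system(self, K, cdofs, cvals, rhs):
        free = np.setdiff1d(np.arange(self.ndof), cdofs, assume_unique=False)
        K = K.tocsc()
        u = np.zeros(self.ndof)
        u[cdofs] = cvals
        b = rhs[free] - K[free][:, cdofs] @ cvals
        try:
            lu = spla.splu(K[free][:, free])
        except RuntimeError as err:  # pragma: no cover - defensive
            raise FEMError(
                "singular stiffness system; a mesh region is insufficiently "
                f"constrained ({err})"
            ) from err
        u[free] = lu.solve(b)
        if not np.all(np.isfinite(u[free])):
            raise FEMError("solver produced non-finite displacements")
        return u

    def solve_elastic(
        self,
        inputs: InputVector,
        soft_shear_factor: float = 1.0,
        bc: BoundarySpec | None = None,
    ) -> DisplacementField:
        """Purely elastic solve (soft-tissue shear scaled by a factor).

        ``soft_shear_factor = 1`` is the instantaneous (unrelaxed) response;
        ``1 - G_scale * sum(g)`` is the long-time response.
        """
        inputs.validate()
        bc = bc or self.bc
        self.n_solves += 1
        K = self._stiffness(inputs, soft_shear_factor)
        cdofs, cvals = self._dirichlet(inputs, bc)
        u = self._solve_system(K, cdofs, cvals, np.zeros(self.ndof))
        return DisplacementField(times=np.array([bc.t_end]), u=u.reshape(1, -1, 3))

    def solve(
        self,
        inputs: InputVector,
        prony: PronySeries | None = None,
        bc: BoundarySpec | None = None,
        time_grid: np.ndarray | None = None,
        store: str = "all",
    ) -> DisplacementField:
        """Viscoelastic solve over the ramp-and-hold protocol.

        Returns the displacement field at every time-grid point
        (``store="all"``) or only the final one (``store="last"``).
        """
        prony = prony or default_prony()
        inputs.validate(prony)
        bc = bc or self.bc
        if time_grid is None:
            time_grid = default_time_grid(ramp=bc.ramp, t_end=bc.t_end)
        time_grid = np.asarray(time_grid, dtype=float)
        if time_grid[0] != 0.0 or np.any(np.diff(time_grid) <= 0):
            raise FEMError("time grid must start at 0 and increase strictly")
        if time_grid[-1] < bc.ramp:
            raise FEMError("time grid must cover the load ramp")
        self.n_solves += 1

        G_s0, _ = _lame(inputs.E_soft, inputs.nu_soft)
        g_hat = inputs.G_scale * np.asarray(prony.g)
        tau = np.asarray(prony.tau)
        Es = self._n_soft
        q = np.zeros((len(tau), Es, 6))  # stress-like internal variables
        pd_eps = np.zeros((Es, 6))

        cdofs, cvals_full = self._dirichlet(inputs, bc)
        free = np.setdiff1d(np.arange(self.ndof), cdofs, assume_unique=False)
        K_base, K_dev = self._stiffness_parts(inputs)
        K_base, K_dev = K_base.tocsc(), K_dev.tocsc()
        Kb_ff, Kb_fc = K_base[free][:, free], K_base[free][:, cdofs]
        Kd_ff, Kd_fc = K_dev[free][:, free], K_dev[free][:, cdofs]

        snaps = [np.zeros((self.mesh.n_nodes, 3))]
        u = np.zeros(self.ndof)
        lu_cache: dict[float, object] = {}
        for n in range(1, len(time_grid)):
            t, dt = time_grid[n], time_grid[n] - time_grid[n - 1]
            e = np.exp(-dt / tau)
            beta = (1.0 - e) * tau / dt
            factor = 1.0 - float(np.sum(g_hat * (1.0 - beta)))
            # history stress per soft element
            h = np.einsum("i,ies->es", e, q) - (
                2.0 * G_s0 * float(np.sum(g_hat * beta))
            ) * pd_eps
            f_hist = self._B_soft.T @ (self._vol_soft[:, None] * h).ravel()
            ramp_frac = min(t / bc.ramp, 1.0)
            uc = cvals_full * ramp_frac
            b = -f_hist[free] - (Kb_fc + factor * Kd_fc) @ uc
            key = round(factor, 12)
            lu = lu_cache.get(key)
            if lu is None:
                try:
                    lu = spla.splu((Kb_ff + factor * Kd_ff).tocsc())
                except RuntimeError as err:
                    raise FEMError(
                        "singular stiffness system; a mesh region is "
                        f"insufficiently constrained ({err})"
                    ) from err
                lu_cache[key] = lu
            u = np.zeros(self.ndof)
            u[cdofs] = uc
            u[free] = lu.solve(b)
            if not np.all(np.isfinite(u[free])):
                raise FEMError("solver produced non-finite displacements")
            eps = (self._B_soft @ u).reshape(Es, 6)
            pd_new = eps @ _PD6.T
            q = e[:, None, None] * q + (
                2.0 * G_s0 * g_hat * beta
            )[:, None, None] * (pd_new - pd_eps)[None]
            pd_eps = pd_new
            if store == "all" or n == len(time_grid) - 1:
                snaps.append(u.reshape(-1, 3).copy())
        times = time_grid if store == "all" else np.array([0.0, time_grid[-1]])
        return DisplacementField(times=times, u=np.stack(snaps))


def solve_viscoelastic(
    mesh: LabeledTetMesh,
    inputs: InputVector,
    bc: BoundarySpec | None = None,
    prony: PronySeries | None = None,
    time_grid: np.ndarray | None = None,
) -> DisplacementField:
    """One-shot viscoelastic solve (builds a solver; see ViscoelasticSolver)."""
    return ViscoelasticSolver(mesh, bc).solve(inputs, prony=prony, time_grid=time_grid)


def solve_elastic(
    mesh: LabeledTetMesh,
    inputs: InputVector,
    soft_shear_factor: float = 1.0,
    bc: BoundarySpec | None = None,
) -> DisplacementField:
    """One-shot elastic solve with a scaled soft-tissue shear modulus."""
    return ViscoelasticSolver(mesh, bc).solve_elastic(inputs, soft_shear_factor, bc)


def landmark_history_frame(field: DisplacementField, landmarks: LandmarkSet):
    """Landmark anterior-displacement time histories as a DataFrame."""
    import pandas as pd

    idx = landmarks.index_array()
    data = {"time_s": field.times}
    for k, name in enumerate(LANDMARKS):
        data[name] = field.u[:, idx[k], 1]
    return pd.DataFrame(data)
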
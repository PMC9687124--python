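"""Explicit-dynamics finite-element solver for two-finger palpation.

Central-difference (leapfrog) time integration on hexahedral meshes with
the three tissue models from :mod:`palpsim.materials`, rigid
hemispherical-capped fingers enforced by a frictionless node-to-surface
penalty, mass-proportional damping, and an energy ledger.

Element technology: total-Lagrangian hexahedra with one-point quadrature
and combined viscous + stiffness hourglass control (Flanagan–Belytschko
mode vectors).  The one-point path assembles deformation gradients and
nodal forces through a precomputed sparse gradient operator, so a time
step is a handful of sparse matvecs and batched 3x3 algebra.  Full 2x2x2
quadrature is available for verification runs via ``quadrature="full"``
(hourglass control is then unnecessary and switched off).

Units: mm, kg, ms — stress GPa, force kN (converted to N only at
reporting boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


from . import materials as mat
from .materials import MaterialCards, ViscoState, RibState
from .phantom import HexMesh, Part, _HEX_XI, compute_boundary_facets

__all__ = [
    "FingerPair",
    "ContactParams",
    "PalpationSchedule",
    "SimState",
    "Trajectory",
    "TrajectoryFrame",
    "SimulationError",
    "stable_timestep",
    "internal_forces",
    "contact_forces",
    "simulate_palpation",
    "crop_model",
    "export_trajectory_vtk",
]


class SimulationError(RuntimeError):
    """Solver instability or element inversion during a run."""


# ---------------------------------------------------------------------------
# Loading definitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FingerPair:
    """Two rigid hemispherical-capped fingertips indenting along -z.

    The pair is centred at plan position (x, y) with the finger axes
    vertical, tips ``spacing`` mm apart along x.  The indentation depth
    follows a linear ramp d(t) = depth * min(t / ramp_ms, 1).
    """

    x: float
    y: float
    tip_radius: float = 8.0
    spacing: float = 20.0
    depth: float = 15.0
    ramp_ms: float = 25.0
    shaft_length: float = 60.0

    def __post_init__(self) -> None:
        if self.tip_radius <= 0:
            raise ValueError("tip radius must be positive")
        if self.ramp_ms <= 0:
            raise ValueError("ramp duration must be positive")

    def depth_at(self, t: float) -> float:
        return self.depth * min(max(t, 0.0) / self.ramp_ms, 1.0)

    def speed_at(self, t: float) -> float:
        return self.depth / self.ramp_ms if 0.0 <= t < self.ramp_ms else 0.0

    def tip_centers(self, t: float, surface_z: float) -> np.ndarray:
        """Sphere-centre positions of both tips at time t (2, 3)."""
        zc = surface_z + self.tip_radius - self.depth_at(t)
        half = 0.5 * self.spacing
        return np.array([[self.x - half, self.y, zc], [self.x + half, self.y, zc]])


@dataclass(frozen=True)
class ContactParams:
    """Frictionless penalty contact: stiffness = scale * K_ref * h_elem."""

    penalty_scale: float = 0.3

    def __post_init__(self) -> None:
        if self.penalty_scale <= 0:
            raise ValueError("penalty scale must be positive")


@dataclass(frozen=True)
class PalpationSchedule:
    """Simulation duration and requested output time stamps (ms)."""

    duration_ms: float = 25.0
    output_stamps: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0)

    def __post_init__(self) -> None:
        st = tuple(float(s) for s in self.output_stamps)
        object.__setattr__(self, "output_stamps", st)
        if any(s < 0 or s > self.duration_ms + 1e-9 for s in st):
            raise ValueError("output stamps must lie within [0, duration]")
        if list(st) != sorted(st):
            raise ValueError("output stamps must be increasing")


# ---------------------------------------------------------------------------
# State and trajectory containers
# ---------------------------------------------------------------------------


@dataclass
class SimState:
    """Nodal kinematics plus per-element material state."""

    displacement: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    time: float
    defgrad: np.ndarray | None = None
    stress: np.ndarray | None = None  # (E, 3, 3) Cauchy stress
    visco: ViscoState | None = None
    rib: RibState | None = None
    rib_defgrad_prev: np.ndarray | None = None

    @classmethod
    def initial(cls, mesh: HexMesh) -> "SimState":
        n = mesh.n_nodes
        return cls(
            displacement=np.zeros((n, 3)),
            velocity=np.zeros((n, 3)),
            acceleration=np.zeros((n, 3)),
            time=0.0,
        )


@dataclass
class TrajectoryFrame:
    time: float
    displacements: np.ndarray
    element_stress: np.ndarray
    finger_force: float  # kN, magnitude of the total finger reaction


@dataclass
class Trajectory:
    frames: list[TrajectoryFrame]
    force_times: np.ndarray  # per-step times (ms)
    force_history: np.ndarray  # per-step |reaction| (kN)
    energy: dict[str, float]

    @property
    def peak_force_kN(self) -> float:
        return float(self.force_history.max(initial=0.0))

    @property
    def peak_force_N(self) -> float:
        return 1e3 * self.peak_force_kN

    def force_csv(self, path) -> None:
        """Force history as CSV (time ms, force N)."""
        arr = np.column_stack([self.force_times, 1e3 * self.force_history])
        np.savetxt(path, arr, delimiter=",", header="time_ms,force_N", comments="")


# ---------------------------------------------------------------------------
# Quadrature and hourglass constants
# ---------------------------------------------------------------------------

_GAUSS_1 = (np.zeros((1, 3)), np.array([8.0]))
_g = 1.0 / np.sqrt(3.0)
_GAUSS_8 = (_HEX_XI * _g, np.ones(8))

# Hourglass base vectors: products of natural coordinates at the 8 nodes.
_HG_BASE = np.stack(
    [
        _HEX_XI[:, 0] * _HEX_XI[:, 1],
        _HEX_XI[:, 1] * _HEX_XI[:, 2],
        _HEX_XI[:, 2] * _HEX_XI[:, 0],
        _HEX_XI[:, 0] * _HEX_XI[:, 1] * _HEX_XI[:, 2],
    ]
)  # (4, 8)


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi at natural point(s) xi: (n_pts, 8, 3)."""
    xi = np.atleast_2d(xi)
    out = np.empty((len(xi), 8, 3))
    for a in range(8):
        sa = _HEX_XI[a]
        out[:, a, 0] = sa[0] * (1 + xi[:, 1] * sa[1]) * (1 + xi[:, 2] * sa[2]) / 8.0
        out[:, a, 1] = sa[1] * (1 + xi[:, 0] * sa[0]) * (1 + xi[:, 2] * sa[2]) / 8.0
        out[:, a, 2] = sa[2] * (1 + xi[:, 0] * sa[0]) * (1 + xi[:, 1] * sa[1]) / 8.0
    return out


def _det3(a: np.ndarray) -> np.ndarray:
    return (
        a[..., 0, 0] * (a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1])
        - a[..., 0, 1] * (a[..., 1, 0] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 0])
        + a[..., 0, 2] * (a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0])
    )


def _inv3(a: np.ndarray, det: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    out[..., 0, 0] = a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1]
    out[..., 0, 1] = a[..., 0, 2] * a[..., 2, 1] - a[..., 0, 1] * a[..., 2, 2]
    out[..., 0, 2] = a[..., 0, 1] * a[..., 1, 2] - a[..., 0, 2] * a[..., 1, 1]
    out[..., 1, 0] = a[..., 1, 2] * a[..., 2, 0] - a[..., 1, 0] * a[..., 2, 2]
    out[..., 1, 1] = a[..., 0, 0] * a[..., 2, 2] - a[..., 0, 2] * a[..., 2, 0]
    out[..., 1, 2] = a[..., 0, 2] * a[..., 1, 0] - a[..., 0, 0] * a[..., 1, 2]
    out[..., 2, 0] = a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0]
    out[..., 2, 1] = a[..., 0, 1] * a[..., 2, 0] - a[..., 0, 0] * a[..., 2, 1]
    out[..., 2, 2] = a[..., 0, 0] * a[..., 1, 1] - a[..., 0, 1] * a[..., 1, 0]
    return out / det[..., None, None]


@njit(cache=True)
def _kernel_kinematics(
    conn,
    grads,
    u,
    v,
    gamma,
    hg_k,
    hg_c,
    part,
    fg,
    fk,
    fvisc,
    rib_map,
    rib_sigma,
    rib_ep,
    rib_fprev,
    rg,
    rk,
    rhard,
    rsy,
    F,
    J,
    Finv,
    sigma,
    f_hg,
):
    """Fused per-element loop: deformation gradients, flesh/rib stress,
    hourglass forces.  Liver elements are left for the caller.  Returns
    the index of an inverted element, or -1."""
    ne = conn.shape[0]
    fe = np.empty((3, 3))
    fd = np.empty((3, 3))
    tmp = np.empty((3, 3))
    for e in range(ne):
        for i in range(3):
            for jx in range(3):
                acc = 1.0 if i == jx else 0.0
                accd = 0.0
                for a in range(8):
                    nid = conn[e, a]
                    g = grads[e, a, jx]
                    acc += u[nid, i] * g
                    accd += v[nid, i] * g
                fe[i, jx] = acc
                fd[i, jx] = accd
                F[e, i, jx] = acc
        det = (
            fe[0, 0] * (fe[1, 1] * fe[2, 2] - fe[1, 2] * fe[2, 1])
            - fe[0, 1] * (fe[1, 0] * fe[2, 2] - fe[1, 2] * fe[2, 0])
            + fe[0, 2] * (fe[1, 0] * fe[2, 1] - fe[1, 1] * fe[2, 0])
        )
        if det <= 0.0:
            return e
        J[e] = det
        Finv[e, 0, 0] = (fe[1, 1] * fe[2, 2] - fe[1, 2] * fe[2, 1]) / det
        Finv[e, 0, 1] = (fe[0, 2] * fe[2, 1] - fe[0, 1] * fe[2, 2]) / det
        Finv[e, 0, 2] = (fe[0, 1] * fe[1, 2] - fe[0, 2] * fe[1, 1]) / det
        Finv[e, 1, 0] = (fe[1, 2] * fe[2, 0] - fe[1, 0] * fe[2, 2]) / det
        Finv[e, 1, 1] = (fe[0, 0] * fe[2, 2] - fe[0, 2] * fe[2, 0]) / det
        Finv[e, 1, 2] = (fe[0, 2] * fe[1, 0] - fe[0, 0] * fe[1, 2]) / det
        Finv[e, 2, 0] = (fe[1, 0] * fe[2, 1] - fe[1, 1] * fe[2, 0]) / det
        Finv[e, 2, 1] = (fe[0, 1] * fe[2, 0] - fe[0, 0] * fe[2, 1]) / det
        Finv[e, 2, 2] = (fe[0, 0] * fe[1, 1] - fe[0, 1] * fe[1, 0]) / det

        pcode = part[e]
        if pcode == 0:  # flesh: neo-Hookean + viscosity
            # D = sym(Fdot Finv)
            for i in range(3):
                for jx in range(3):
                    acc = 0.0
                    for kx in range(3):
                        acc += fd[i, kx] * Finv[e, kx, jx]
                    tmp[i, jx] = acc
            d00 = tmp[0, 0]
            d11 = tmp[1, 1]
            d22 = tmp[2, 2]
            d01 = 0.5 * (tmp[0, 1] + tmp[1, 0])
            d02 = 0.5 * (tmp[0, 2] + tmp[2, 0])
            d12 = 0.5 * (tmp[1, 2] + tmp[2, 1])
            jm23 = det ** (-2.0 / 3.0)
            b00 = fe[0, 0] ** 2 + fe[0, 1] ** 2 + fe[0, 2] ** 2
            b11 = fe[1, 0] ** 2 + fe[1, 1] ** 2 + fe[1, 2] ** 2
            b22 = fe[2, 0] ** 2 + fe[2, 1] ** 2 + fe[2, 2] ** 2
            b01 = fe[0, 0] * fe[1, 0] + fe[0, 1] * fe[1, 1] + fe[0, 2] * fe[1, 2]
            b02 = fe[0, 0] * fe[2, 0] + fe[0, 1] * fe[2, 1] + fe[0, 2] * fe[2, 2]
            b12 = fe[1, 0] * fe[2, 0] + fe[1, 1] * fe[2, 1] + fe[1, 2] * fe[2, 2]
            gj = fg * jm23 / det
            diag = gj * (b00 + b11 + b22) / 3.0 - fk * (det - 1.0) + fvisc * (d00 + d11 + d22) / 3.0
            sigma[e, 0, 0] = gj * b00 + fvisc * d00 - diag
            sigma[e, 1, 1] = gj * b11 + fvisc * d11 - diag
            sigma[e, 2, 2] = gj * b22 + fvisc * d22 - diag
            sigma[e, 0, 1] = sigma[e, 1, 0] = gj * b01 + fvisc * d01
            sigma[e, 0, 2] = sigma[e, 2, 0] = gj * b02 + fvisc * d02
            sigma[e, 1, 2] = sigma[e, 2, 1] = gj * b12 + fvisc * d12
        elif pcode == 1:  # rib: small-strain von Mises radial return
            r = rib_map[e]
            # strain increment from defgrad increment
            e00 = fe[0, 0] - rib_fprev[r, 0, 0]
            e11 = fe[1, 1] - rib_fprev[r, 1, 1]
            e22 = fe[2, 2] - rib_fprev[r, 2, 2]
            e01 = 0.5 * (fe[0, 1] - rib_fprev[r, 0, 1] + fe[1, 0] - rib_fprev[r, 1, 0])
            e02 = 0.5 * (fe[0, 2] - rib_fprev[r, 0, 2] + fe[2, 0] - rib_fprev[r, 2, 0])
            e12 = 0.5 * (fe[1, 2] - rib_fprev[r, 1, 2] + fe[2, 1] - rib_fprev[r, 2, 1])
            for i in range(3):
                for jx in range(3):
                    rib_fprev[r, i, jx] = fe[i, jx]
            tr = e00 + e11 + e22
            s00 = rib_sigma[r, 0, 0] + 2.0 * rg * (e00 - tr / 3.0) + rk * tr
            s11 = rib_sigma[r, 1, 1] + 2.0 * rg * (e11 - tr / 3.0) + rk * tr
            s22 = rib_sigma[r, 2, 2] + 2.0 * rg * (e22 - tr / 3.0) + rk * tr
            s01 = rib_sigma[r, 0, 1] + 2.0 * rg * e01
            s02 = rib_sigma[r, 0, 2] + 2.0 * rg * e02
            s12 = rib_sigma[r, 1, 2] + 2.0 * rg * e12
            p = (s00 + s11 + s22) / 3.0
            d0 = s00 - p
            d1 = s11 - p
            d2 = s22 - p
            seq = np.sqrt(1.5 * (d0 * d0 + d1 * d1 + d2 * d2 + 2.0 * (s01**2 + s02**2 + s12**2)))
            sy = rsy + rhard * rib_ep[r]
            if seq > sy:
                dgamma = (seq - sy) / (3.0 * rg + rhard)
                scale = 1.0 - 3.0 * rg * dgamma / seq
                d0 *= scale
                d1 *= scale
                d2 *= scale
                s01 *= scale
                s02 *= scale
                s12 *= scale
                s00 = d0 + p
                s11 = d1 + p
                s22 = d2 + p
                rib_ep[r] += dgamma
            rib_sigma[r, 0, 0] = s00
            rib_sigma[r, 1, 1] = s11
            rib_sigma[r, 2, 2] = s22
            rib_sigma[r, 0, 1] = rib_sigma[r, 1, 0] = s01
            rib_sigma[r, 0, 2] = rib_sigma[r, 2, 0] = s02
            rib_sigma[r, 1, 2] = rib_sigma[r, 2, 1] = s12
            for i in range(3):
                for jx in range(3):
                    sigma[e, i, jx] = rib_sigma[r, i, jx]

        # hourglass forces
        kk = hg_k[e]
        cc = hg_c[e]
        for h in range(4):
            for i in range(3):
                q = 0.0
                qd = 0.0
                for a in range(8):
                    ga = gamma[e, h, a]
                    nid = conn[e, a]
                    q += ga * u[nid, i]
                    qd += ga * v[nid, i]
                coef = kk * q + cc * qd
                for a in range(8):
                    f_hg[conn[e, a], i] -= gamma[e, h, a] * coef
    return -1


@njit(cache=True)
def _kernel_assemble(conn, grads, vols, sigma, J, Finv, f_int):
    """Internal nodal forces from element Cauchy stresses (one-point)."""
    ne = conn.shape[0]
    p = np.empty((3, 3))
    for e in range(ne):
        jw = J[e] * vols[e]
        for i in range(3):
            for jx in range(3):
                acc = 0.0
                for kx in range(3):
                    acc += sigma[e, i, kx] * Finv[e, jx, kx]
                p[i, jx] = acc * jw
        for a in range(8):
            nid = conn[e, a]
            for i in range(3):
                acc = 0.0
                for jx in range(3):
                    acc += p[i, jx] * grads[e, a, jx]
                f_int[nid, i] -= acc


def _ogden_cauchy_fast(fl: np.ndarray, jl: np.ndarray, params) -> np.ndarray:
    """Ogden Cauchy stress with the determinant precomputed (solver path).

    Same model as :func:`palpsim.materials.ogden_cauchy_stress`, minus the
    input validation and determinant recomputation.
    """
    bbar = (fl @ np.swapaxes(fl, -1, -2)) * jl[:, None, None] ** (-2.0 / 3.0)
    w, vv = np.linalg.eigh(bbar)
    lbar = np.sqrt(np.clip(w, 1e-30, None))
    beta = np.zeros_like(lbar)
    for mu, alpha in params.terms:
        la = lbar**alpha
        beta += mu * (la - np.mean(la, axis=-1, keepdims=True))
    dev = (vv * beta[:, None, :]) @ np.swapaxes(vv, -1, -2)
    sig = dev / jl[:, None, None]
    kj = params.bulk_modulus * (jl - 1.0)
    sig[:, 0, 0] += kj
    sig[:, 1, 1] += kj
    sig[:, 2, 2] += kj
    return sig


class FemModel:
    """Precomputed assembly data for one mesh + material card set."""

    def __init__(
        self,
        mesh: HexMesh,
        cards: MaterialCards,
        contact: ContactParams | None = None,
        quadrature: str = "one_point",
        hourglass_stiffness: float = 0.01,
        hourglass_viscosity: float = 0.1,
    ):
        if quadrature not in ("one_point", "full"):
            raise ValueError("quadrature must be 'one_point' or 'full'")
        self.mesh = mesh
        self.cards = cards
        self.contact_params = contact or ContactParams()
        self.quadrature = quadrature
        conn = mesh.elements
        ne = mesh.n_elements
        nn = mesh.n_nodes
        coords = mesh.node_coords
        xe = coords[conn]  # (E, 8, 3)

        pts, wts = _GAUSS_1 if quadrature == "one_point" else _GAUSS_8
        dn = _shape_gradients(pts)  # (gp, 8, 3)
        jac = np.einsum("eai,gaj->geij", xe, dn)
        detj = np.linalg.det(jac)
        if np.any(detj <= 0):
            raise ValueError("mesh contains an element with non-positive Jacobian")
        jinv = np.linalg.inv(jac)
        # reference gradients g_a = J^{-T} dN_a/dxi : (gp, E, 8, 3)
        self.grads = np.einsum("geji,gaj->geai", jinv, dn)
        self.gp_weights = wts[:, None] * detj  # (gp, E)
        self.volumes = self.gp_weights.sum(axis=0)  # (E,)
        self.char_length = self.volumes ** (1.0 / 3.0)

        self.part = mesh.part_label
        self.masks = {p: self.part == int(p) for p in (Part.FLESH, Part.RIB, Part.LIVER)}
        self.idx = {p: np.flatnonzero(m) for p, m in self.masks.items()}

        km = np.empty(ne)
        gm = np.empty(ne)
        rho = np.empty(ne)
        for p, card in (
            (Part.FLESH, cards.flesh),
            (Part.RIB, cards.rib),
            (Part.LIVER, (cards.liver_ogden, cards.liver_prony)),
        ):
            k, g, r = mat.elastic_moduli(card)
            km[self.masks[p]], gm[self.masks[p]], rho[self.masks[p]] = k, g, r
        self.bulk, self.shear, self.density = km, gm, rho
        self.wave_speed = np.sqrt((km + 4.0 * gm / 3.0) / rho)

        # lumped mass
        m = np.zeros(nn)
        np.add.at(m, conn.ravel(), np.repeat(rho * self.volumes / 8.0, 8))
        self.mass = m
        self.conn_flat = conn.ravel()

        self.fixed = np.zeros(nn, dtype=bool)
        self.fixed[mesh.fixed_node_set] = True
        self.boundary_nodes = np.unique(mesh.boundary_facets)
        self.surface_z = coords[:, 2].max()

        if quadrature == "one_point":
            g0 = np.ascontiguousarray(self.grads[0])  # (E, 8, 3)
            self.g0 = g0
            self.conn_c = np.ascontiguousarray(conn, dtype=np.int64)
            self.part_codes = np.ascontiguousarray(self.part, dtype=np.int64)
            rib_map = np.full(ne, -1, dtype=np.int64)
            rib_map[self.idx[Part.RIB]] = np.arange(len(self.idx[Part.RIB]))
            self.rib_map = rib_map

            # hourglass mode vectors (Flanagan–Belytschko corrected)
            hx = np.einsum("ha,eai->ehi", _HG_BASE, xe)  # (E, 4, 3)
            self.gamma = np.ascontiguousarray(
                _HG_BASE[None, :, :] - np.einsum("ehi,eai->eha", hx, g0)
            )  # (E, 4, 8)
            # stiffness scaled by the constrained modulus: hourglass modes of
            # nearly incompressible elements must resist on the same scale as
            # the volumetric response, or concentrated contact loads pour
            # energy into the zero-energy modes
            self.hg_k = hourglass_stiffness * (km + 4.0 * gm / 3.0) * self.char_length
            self.hg_c = (
                hourglass_viscosity * rho * self.wave_speed * self.volumes ** (2.0 / 3.0) / 4.0
            )
            if not HAVE_NUMBA:
                self._build_sparse_operators()

        kref = cards.flesh.bulk_modulus
        self.k_pen = self.contact_params.penalty_scale * kref * float(self.char_length.mean())

        # viscous correction of the explicit stability limit (flesh viscosity)
        eta = np.zeros(ne)
        eta[self.masks[Part.FLESH]] = cards.flesh.damping_coefficient * cards.flesh.shear_modulus
        xi = 2.0 * eta / (rho * self.wave_speed * self.char_length)
        self.critical_dt = float(
            np.min(self.char_length / self.wave_speed * (np.sqrt(1.0 + xi**2) - xi))
        )

    def _build_sparse_operators(self) -> None:
        """Sparse gradient/hourglass operators for the numpy fallback path.

        (B @ u.ravel()).reshape(E,3,3)[e,i,j] = sum_a g0[e,a,j] u[conn[e,a], i];
        B^T assembles nodal forces from first Piola–Kirchhoff stresses.
        """
        conn = self.mesh.elements
        ne, nn = self.mesh.n_elements, self.mesh.n_nodes
        g0 = self.g0
        gamma = self.gamma
        e_ix = np.arange(ne)
        ii = np.arange(3)
        jj = np.arange(3)
        rows = (
            e_ix[:, None, None, None] * 9
            + ii[None, None, :, None] * 3
            + jj[None, None, None, :]
        )  # (E, 8, 3, 3)
        rows = np.broadcast_to(rows, (ne, 8, 3, 3))
        cols = conn[:, :, None, None] * 3 + ii[None, None, :, None]
        cols = np.broadcast_to(cols, (ne, 8, 3, 3))
        vals = np.broadcast_to(g0[:, :, None, :], (ne, 8, 3, 3))
        self.B = sp.csr_matrix(
            (vals.ravel(), (rows.ravel(), cols.ravel())), shape=(9 * ne, 3 * nn)
        )
        self.BT = self.B.T.tocsr()

        hh = np.arange(4)
        rows = (
            e_ix[:, None, None, None] * 12
            + hh[None, None, :, None] * 3
            + ii[None, None, None, :]
        )
        rows = np.broadcast_to(rows, (ne, 8, 4, 3))
        cols = conn[:, :, None, None] * 3 + ii[None, None, None, :]
        cols = np.broadcast_to(cols, (ne, 8, 4, 3))
        vals = np.broadcast_to(np.swapaxes(gamma, 1, 2)[:, :, :, None], (ne, 8, 4, 3))
        self.H = sp.csr_matrix(
            (vals.ravel(), (rows.ravel(), cols.ravel())), shape=(12 * ne, 3 * nn)
        )
        self.HT = self.H.T.tocsr()

    # -- material state -----------------------------------------------------

    def initial_material_state(self):
        ngp = self.grads.shape[0]
        lead = () if self.quadrature == "one_point" else (ngp,)
        nl, nr = len(self.idx[Part.LIVER]), len(self.idx[Part.RIB])
        visco = ViscoState.zero(self.cards.liver_prony, (*lead, nl)) if nl else None
        rib = RibState.zero((*lead, nr)) if nr else None
        rib_f_prev = np.broadcast_to(np.eye(3), (*lead, nr, 3, 3)).copy() if nr else None
        return visco, rib, rib_f_prev

    # -- constitutive dispatch ----------------------------------------------

    def _element_stresses(self, f, fdot, dt, visco, rib, rib_f_prev):
        """Cauchy stress per quadrature point from part-wise models.

        ``f``/``fdot`` have shape (..., E, 3, 3); material states carry
        matching leading axes.  Returns (sigma, new material states).
        """
        j = _det3(f)
        if np.any(j <= 0):
            bad = int(np.argwhere(j <= 0)[-1][-1])
            raise SimulationError(f"element {bad} inverted (det F <= 0)")
        finv = _inv3(f, j)
        sigma = np.zeros_like(f)
        cards = self.cards

        li = self.idx[Part.FLESH]
        if len(li):
            ff, jf = f[..., li, :, :], j[..., li]
            d = fdot[..., li, :, :] @ finv[..., li, :, :]
            d = 0.5 * (d + np.swapaxes(d, -1, -2))
            b = ff @ np.swapaxes(ff, -1, -2)
            jm23 = jf ** (-2.0 / 3.0)
            trb = (b[..., 0, 0] + b[..., 1, 1] + b[..., 2, 2]) * jm23
            trd = d[..., 0, 0] + d[..., 1, 1] + d[..., 2, 2]
            gmod, kmod = cards.flesh.shear_modulus, cards.flesh.bulk_modulus
            visc = cards.flesh.damping_coefficient * gmod
            sig = (gmod * jm23 / jf)[..., None, None] * b + visc * d
            diag = gmod * trb / (3.0 * jf) - kmod * (jf - 1.0) + visc * trd / 3.0
            sig[..., 0, 0] -= diag
            sig[..., 1, 1] -= diag
            sig[..., 2, 2] -= diag
            sigma[..., li, :, :] = sig

        li = self.idx[Part.LIVER]
        new_visco = visco
        if len(li):
            fl = f[..., li, :, :]
            jl = j[..., li]
            sig_o = mat.ogden_cauchy_stress(fl, cards.liver_ogden)
            e_green = 0.5 * (np.swapaxes(fl, -1, -2) @ fl - np.eye(3))
            de = e_green - (visco.strain if visco is not None else 0.0)
            new_visco, s_over = mat.visco_overstress_update(visco, de, dt, cards.liver_prony)
            sig_v = fl @ s_over @ np.swapaxes(fl, -1, -2) / jl[..., None, None]
            sigma[..., li, :, :] = sig_o + sig_v

        li = self.idx[Part.RIB]
        new_rib, new_rib_f = rib, rib_f_prev
        if len(li):
            fr = f[..., li, :, :]
            dfr = fr - rib_f_prev
            deps = 0.5 * (dfr + np.swapaxes(dfr, -1, -2))
            sig_r, new_rib = mat.rib_plastic_update(deps, rib, cards.rib)
            sigma[..., li, :, :] = sig_r
            new_rib_f = fr

        # first Piola–Kirchhoff for the assembly
        p = j[..., None, None] * sigma @ np.swapaxes(finv, -1, -2)
        return sigma, p, (new_visco, new_rib, new_rib_f)

    # -- force evaluation ---------------------------------------------------

    def forces(self, u: np.ndarray, v: np.ndarray, dt: float, visco, rib, rib_f_prev):
        """Internal + hourglass nodal forces at displacement u, velocity v.

        Returns (f_int, f_hg, per-element Cauchy stress, new material
        states).  f_int is the force applied *to* the nodes by the
        element stresses (it opposes deformation).
        """
        ne = self.mesh.n_elements
        nn = self.mesh.n_nodes
        if self.quadrature == "one_point" and HAVE_NUMBA:
            cards = self.cards
            nr = len(self.idx[Part.RIB])
            if rib is not None:
                rib_sigma = np.ascontiguousarray(rib.sigma).copy()
                rib_ep = np.ascontiguousarray(rib.eq_plastic_strain).copy()
                rib_fp = np.ascontiguousarray(rib_f_prev).copy()
            else:
                rib_sigma = np.zeros((0, 3, 3))
                rib_ep = np.zeros(0)
                rib_fp = np.zeros((0, 3, 3))
            f = np.empty((ne, 3, 3))
            jdet = np.empty(ne)
            finv = np.empty((ne, 3, 3))
            sigma = np.zeros((ne, 3, 3))
            f_hg = np.zeros((nn, 3))
            bad = _kernel_kinematics(
                self.conn_c,
                self.g0,
                u,
                v,
                self.gamma,
                self.hg_k,
                self.hg_c,
                self.part_codes,
                cards.flesh.shear_modulus,
                cards.flesh.bulk_modulus,
                cards.flesh.damping_coefficient * cards.flesh.shear_modulus,
                self.rib_map,
                rib_sigma,
                rib_ep,
                rib_fp,
                cards.rib.shear_modulus,
                cards.rib.bulk_modulus,
                cards.rib.hardening_modulus,
                cards.rib.yield_stress,
                f,
                jdet,
                finv,
                sigma,
                f_hg,
            )
            if bad >= 0:
                raise SimulationError(f"element {bad} inverted (det F <= 0)")
            ll = self.idx[Part.LIVER]
            new_visco = visco
            if len(ll):
                fl = f[ll]
                jl = jdet[ll]
                sig_o = _ogden_cauchy_fast(fl, jl, cards.liver_ogden)
                e_green = 0.5 * (np.swapaxes(fl, -1, -2) @ fl - np.eye(3))
                de = e_green - (visco.strain if visco is not None else 0.0)
                new_visco, s_over = mat.visco_overstress_update(visco, de, dt, cards.liver_prony)
                sig_v = fl @ s_over @ np.swapaxes(fl, -1, -2) / jl[..., None, None]
                sigma[ll] = sig_o + sig_v
            f_int = np.zeros((nn, 3))
            _kernel_assemble(self.conn_c, self.g0, self.volumes, sigma, jdet, finv, f_int)
            new_rib = RibState(sigma=rib_sigma, eq_plastic_strain=rib_ep) if nr else rib
            new_ribf = rib_fp if nr else rib_f_prev
            return f_int, f_hg, sigma, (new_visco, new_rib, new_ribf)

        if self.quadrature == "one_point":
            f = (self.B @ u.ravel()).reshape(ne, 3, 3)
            f[:, 0, 0] += 1.0
            f[:, 1, 1] += 1.0
            f[:, 2, 2] += 1.0
            fdot = (self.B @ v.ravel()).reshape(ne, 3, 3)
            sigma, p, new_states = self._element_stresses(f, fdot, dt, visco, rib, rib_f_prev)
            f_int = (-(self.BT @ (p * self.volumes[:, None, None]).ravel())).reshape(-1, 3)

            q = (self.H @ u.ravel()).reshape(ne, 4, 3)
            qdot = (self.H @ v.ravel()).reshape(ne, 4, 3)
            qq = self.hg_k[:, None, None] * q + self.hg_c[:, None, None] * qdot
            f_hg = (-(self.HT @ qq.ravel())).reshape(-1, 3)
            return f_int, f_hg, sigma, new_states

        # full quadrature (verification path, no hourglass control)
        conn = self.mesh.elements
        ue, ve = u[conn], v[conn]
        grads = self.grads
        f = np.einsum("eai,geaj->geij", ue, grads)
        f[..., 0, 0] += 1.0
        f[..., 1, 1] += 1.0
        f[..., 2, 2] += 1.0
        fdot = np.einsum("eai,geaj->geij", ve, grads)
        sigma, p, new_states = self._element_stresses(f, fdot, dt, visco, rib, rib_f_prev)
        fe = -np.einsum("geij,geaj,ge->eai", p, grads, self.gp_weights)
        f_int = np.zeros_like(u)
        for c in range(3):
            f_int[:, c] = np.bincount(self.conn_flat, weights=fe[:, :, c].ravel(), minlength=len(u))
        sig_avg = np.einsum("ge...,ge->e...", sigma, self.gp_weights) / self.volumes[:, None, None]
        return f_int, np.zeros_like(u), sig_avg, new_states

    # -- contact ------------------------------------------------------------

    def contact(self, u: np.ndarray, fingers: FingerPair, t: float):
        """Penalty contact forces on boundary nodes.

        Returns (nodal force field (N, 3), finger reaction vector (3,),
        stored spring energy).  Reaction = minus the sum of nodal forces.
        """
        bn = self.boundary_nodes
        pos = self.mesh.node_coords[bn] + u[bn]
        centers = fingers.tip_centers(t, self.surface_z)
        f_nodes = np.zeros((len(u), 3))
        spring = 0.0
        for c in centers:
            rel = pos - c
            s = np.clip(rel[:, 2], 0.0, fingers.shaft_length)
            rel_seg = rel.copy()
            rel_seg[:, 2] -= s
            dist = np.linalg.norm(rel_seg, axis=1)
            pen = fingers.tip_radius - dist
            hit = pen > 0.0
            if not np.any(hit):
                continue
            d_safe = np.where(dist[hit] > 1e-12, dist[hit], 1.0)
            normal = rel_seg[hit] / d_safe[:, None]
            fmag = self.k_pen * pen[hit]
            np.add.at(f_nodes, bn[hit], fmag[:, None] * normal)
            spring += 0.5 * self.k_pen * float(np.sum(pen[hit] ** 2))
        reaction = -f_nodes.sum(axis=0)
        return f_nodes, reaction, spring


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def stable_timestep(mesh: HexMesh, cards: MaterialCards, safety: float = 0.9) -> float:
    """Courant-limited explicit time step (ms).

    dt = safety * min_e( h_e / c_e ), with h_e the element characteristic
    length V^(1/3) and c_e = sqrt((K + 4G/3) / rho) the dilatational wave
    speed of the element's material (instantaneous moduli for the liver).
    The integrator additionally applies the standard viscous-material
    correction factor sqrt(1 + xi^2) - xi on top of this bound.
    """
    if not 0.0 < safety <= 1.0:
        raise ValueError("safety fraction must be in (0, 1]")
    model = FemModel(mesh, cards)
    if np.any(model.density <= 0):
        raise ValueError("zero or negative density")
    return float(safety * np.min(model.char_length / model.wave_speed))


def internal_forces(
    mesh: HexMesh,
    state: SimState,
    cards: MaterialCards,
    dt: float = 1e-3,
    quadrature: str = "one_point",
) -> np.ndarray:
    """Nodal internal force field (incl. hourglass) for a given state.

    One-shot evaluation: builds the assembly data, evaluates element
    stresses from the state's displacements/velocities and returns the
    nodal forces the stresses apply to the nodes.
    """
    model = FemModel(mesh, cards, quadrature=quadrature)
    visco, rib, ribf = model.initial_material_state()
    if state.visco is not None:
        visco = state.visco
    if state.rib is not None:
        rib = state.rib
    if state.rib_defgrad_prev is not None:
        ribf = state.rib_defgrad_prev
    f_int, f_hg, sig, _ = model.forces(state.displacement, state.velocity, dt, visco, rib, ribf)
    state.stress = sig
    return f_int + f_hg


def contact_forces(
    mesh: HexMesh,
    fingers: FingerPair,
    params: ContactParams,
    state: SimState,
    cards: MaterialCards,
) -> tuple[np.ndarray, np.ndarray]:
    """Penalty contact nodal forces and the finger reaction (kN) at state.time."""
    model = FemModel(mesh, cards, contact=params)
    f, reaction, _ = model.contact(state.displacement, fingers, state.time)
    return f, reaction


def simulate_palpation(
    mesh: HexMesh,
    cards: MaterialCards,
    fingers: FingerPair,
    schedule: PalpationSchedule | None = None,
    contact: ContactParams | None = None,
    *,
    safety: float = 0.9,
    quadrature: str = "one_point",
    mass_scaling: float = 1.0,
    damping: float | None = None,
    hourglass_stiffness: float = 0.01,
    hourglass_viscosity: float = 0.1,
    progress: bool = False,
) -> Trajectory:
    """Run one palpation: prescribed finger ramp, leapfrog integration.

    ``damping`` is the mass-proportional damping rate alpha (1/ms),
    defaulting to the flesh card's damping coefficient.  ``mass_scaling``
    > 1 multiplies nodal masses by its square, enlarging the stable step
    by the same factor (off by default; inertial fidelity degrades).
    Aborts with :class:`SimulationError` on element inversion or kinetic
    energy exceeding 10x the external work.
    """
    schedule = schedule or PalpationSchedule()
    model = FemModel(
        mesh,
        cards,
        contact=contact,
        quadrature=quadrature,
        hourglass_stiffness=hourglass_stiffness,
        hourglass_viscosity=hourglass_viscosity,
    )
    alpha = cards.flesh.damping_coefficient if damping is None else damping
    dt0 = model.critical_dt * safety * mass_scaling
    n_steps = max(int(np.ceil(schedule.duration_ms / dt0)), 1)
    dt = schedule.duration_ms / n_steps
    stamp_steps = [int(round(s / dt)) for s in schedule.output_stamps]

    m = model.mass * mass_scaling**2
    minv = (1.0 / m)[:, None]
    mcol = m[:, None]
    u = np.zeros((mesh.n_nodes, 3))
    v = np.zeros_like(u)
    visco, rib, ribf = model.initial_material_state()

    frames: list[TrajectoryFrame] = []
    force_hist = np.zeros(n_steps + 1)
    times = np.arange(n_steps + 1) * dt
    w_fing = w_contact = e_int = e_hg = e_damp = 0.0
    spring = 0.0
    sigma = np.zeros((mesh.n_elements, 3, 3))

    if 0 in stamp_steps:
        frames.append(TrajectoryFrame(0.0, u.copy(), sigma.copy(), 0.0))

    for n in range(n_steps):
        t = n * dt
        f_int, f_hg, sigma, (visco, rib, ribf) = model.forces(u, v, dt, visco, rib, ribf)
        f_c, reaction, spring = model.contact(u, fingers, t)
        f_damp = -alpha * mcol * v
        a = (f_int + f_hg + f_c + f_damp) * minv
        a[model.fixed] = 0.0
        v_new = v + dt * a
        v_new[model.fixed] = 0.0
        vbar = 0.5 * (v + v_new)

        # energy ledger (discrete work increments with mid-step velocity)
        w_contact += float(np.sum(f_c * vbar)) * dt
        w_fing += float(np.sum(f_c[:, 2])) * (-fingers.speed_at(t)) * dt
        e_int += -float(np.sum(f_int * vbar)) * dt
        e_hg += -float(np.sum(f_hg * vbar)) * dt
        e_damp += -float(np.sum(f_damp * vbar)) * dt

        v = v_new
        u = u + dt * v
        force_hist[n + 1] = np.linalg.norm(reaction)

        if (n + 1) % 200 == 0 or n + 1 == n_steps:
            if not np.all(np.isfinite(u)):
                raise SimulationError(f"non-finite displacements at t = {t:.3f} ms")
            ke = 0.5 * float(np.sum(mcol * v**2))
            if w_fing > 1e-9 and ke > 10.0 * w_fing:
                raise SimulationError(
                    f"instability: kinetic energy {ke:.3e} exceeds 10x external work at t = {t:.3f} ms"
                )

        if (n + 1) in stamp_steps:
            frames.append(
                TrajectoryFrame((n + 1) * dt, u.copy(), sigma.copy(), float(np.linalg.norm(reaction)))
            )
        if progress and (n + 1) % max(n_steps // 10, 1) == 0:
            print(f"  t = {(n + 1) * dt:6.2f} ms  force = {1e3 * force_hist[n + 1]:8.2f} N")

    ke = 0.5 * float(np.sum(mcol * v**2))
    energy = {
        "external_work": w_fing,
        "contact_node_work": w_contact,
        "kinetic": ke,
        "internal": e_int,
        "hourglass": e_hg,
        "damping_dissipated": e_damp,
        "contact_spring": spring,
    }
    return Trajectory(frames=frames, force_times=times, force_history=force_hist, energy=energy)


def export_trajectory_vtk(mesh: HexMesh, trajectory: Trajectory, directory, prefix: str = "frame") -> list:
    """Write each trajectory frame as a legacy-VTK file with cell stress fields.

    Every frame gets the six Cauchy components plus the maximum principal
    stress as cell data; node coordinates are the deformed positions.
    Returns the written paths.
    """
    from pathlib import Path

    from .phantom import write_mesh

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    comps = [("sxx", 0, 0), ("syy", 1, 1), ("szz", 2, 2), ("sxy", 0, 1), ("syz", 1, 2), ("szx", 0, 2)]
    paths = []
    for k, frame in enumerate(trajectory.frames):
        deformed = mesh.copy()
        deformed.node_coords = mesh.node_coords + frame.displacements
        fields = {name: frame.element_stress[:, i, j] for name, i, j in comps}
        fields["sigma_max_principal"] = mat.max_principal_stress_field(frame.element_stress)
        path = directory / f"{prefix}_{k:03d}_t{frame.time:05.1f}ms.vtk"
        write_mesh(deformed, path, cell_data=fields)
        paths.append(path)
    return paths


def crop_model(mesh: HexMesh, box_min, box_max) -> HexMesh:
    """Reduced model: keep elements with centroid inside the box.

    Nodes are renumbered; nodes on newly exposed cut faces join the fixed
    set (the removed material is replaced by a rigid constraint, which is
    accurate when the cut is far from the loaded region).
    """
    lo, hi = np.asarray(box_min, float), np.asarray(box_max, float)
    cent = mesh.element_centroids()
    keep = np.all((cent >= lo) & (cent <= hi), axis=1)
    if not np.any(keep):
        raise ValueError("crop box contains no element centroids")
    keep_ids = np.flatnonzero(keep)
    elems_old = mesh.elements[keep_ids]
    used, inv = np.unique(elems_old, return_inverse=True)
    elements = inv.reshape(elems_old.shape)
    coords = mesh.node_coords[used]
    old_boundary_keys = {tuple(k) for k in np.sort(mesh.boundary_facets, axis=1)}
    boundary = compute_boundary_facets(elements)
    new_fixed_nodes = []
    for facet in boundary:
        old_facet = tuple(np.sort(used[facet]))
        if old_facet not in old_boundary_keys:
            new_fixed_nodes.extend(facet.tolist())
    old_fixed = np.zeros(mesh.n_nodes, dtype=bool)
    old_fixed[mesh.fixed_node_set] = True
    fixed = set(np.flatnonzero(old_fixed[used]).tolist()) | set(new_fixed_nodes)
    roi_old = set(mesh.roi_elements.tolist())
    roi_new = np.flatnonzero([int(e) in roi_old for e in keep_ids])
    out = HexMesh(
        node_coords=coords,
        elements=elements,
        part_label=mesh.part_label[keep_ids].copy(),
        boundary_facets=boundary,
        fixed_node_set=np.array(sorted(fixed), dtype=int),
        roi_elements=roi_new,
    )
    out.validate()
    return out
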
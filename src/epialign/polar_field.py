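"""Confined polar fluid with heterogeneous surface anchoring.

The tissue-scale cell polarity field ``p`` minimizes the rescaled free
energy on the two-cap domain (lengths in units of the characteristic
size R0)::

    F/F0 = int_O' dV' [ |p|^2 + (xi/R0)^2 f_D(p, grad p) ]
           + int_dO' dS' (lambda/R0) (p - p0)^2,

    f_D = (div p)^2 + K [p_hat x (curl p)]^2

with tangential preferred anchoring ``p0`` on the alpha (ExE) cap and
normal anchoring on the beta (VE) cap.  ``xi/R0`` is the relative
correlation length (distortion vs. restoring), ``lambda/R0`` the
relative anchoring length (surface vs. restoring), and ``K = k2/k0`` the
bend/splay ratio.  The energy scale ``F0 = a R0^3 / 2`` carries the bare
restoring coefficient and never enters the dimensionless problem.

Axisymmetric reduction
----------------------
By symmetry the field is in-plane, ``p = (p_x, 0, p_z)`` in cylindrical
coordinates (x = radius, z = axis), and all integrals carry the measure
``2 pi x dx dz``.  The curl of such a field is purely azimuthal, hence
perpendicular to ``p_hat``, so the bend density reduces *exactly* to
``K (dp_x/dz - dp_z/dx)^2`` — no unit-vector division remains and the
functional is a convex quadratic.  Minimization therefore amounts to one
Newton step (a single sparse SPD solve); the damped-Newton driver keeps
the general contract (monotone energy decrease, relative-residual
tolerance 1e-6) and records its iteration trace.

Regularity on the axis requires ``p_x = 0`` at x = 0, imposed as an
essential constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import CapGeometry, SliceMesh, generate_mesh

__all__ = [
    "MaterialParams",
    "AnchoringSpec",
    "FieldSolution",
    "DefectSet",
    "EnergyParts",
    "free_energy",
    "minimize",
    "global_order",
    "detect_defects",
    "defect_position",
    "phase_diagram",
]


@dataclass(frozen=True)
class MaterialParams:
    """Dimensionless material parameters of the polar fluid.

    xi_rel : correlation length over tissue size, xi/R0 (>= 0)
    lambda_rel : anchoring length over tissue size, lambda/R0 (>= 0)
    K : bend/splay elastic ratio k2/k0 (> 0), default 1e-2
    """

    xi_rel: float
    lambda_rel: float
    K: float = 1e-2

    def __post_init__(self):
        if self.xi_rel < 0 or self.lambda_rel < 0:
            raise ValueError("xi_rel and lambda_rel must be non-negative")
        if self.K <= 0:
            raise ValueError("K must be positive")


@dataclass(frozen=True)
class AnchoringSpec:
    """Preferred boundary field p0 per cap.

    Rules are ``"tangential"`` (meridional tangent) or ``"normal"``.
    Sign conventions (configurable): a positive tangential sign orients
    the tangent from the equator toward the cap apex — on the alpha cap
    this continues the proximally directed interior flow sourced by the
    VE-side normal anchoring, and it is the orientation that produces
    the observed total charge +1 with the defect displaced toward the
    ExE side.  A positive normal sign points into the tissue (the
    apico-basal direction at the VE boundary).
    """

    alpha_rule: str = "tangential"
    beta_rule: str = "normal"
    alpha_sign: float = 1.0
    beta_sign: float = 1.0
    p0_magnitude: float = 1.0

    def __post_init__(self):
        for rule in (self.alpha_rule, self.beta_rule):
            if rule not in ("tangential", "normal"):
                raise ValueError(f"unknown anchoring rule {rule!r}")

    def p0_at(self, points: np.ndarray, tags: np.ndarray,
              geom: CapGeometry) -> np.ndarray:
        """Evaluate p0 at boundary points (n, 2) tagged alpha/beta."""
        points = np.atleast_2d(points)
        out = np.empty_like(points, dtype=float)
        for mu, rule, sign, R, C in (
                ("alpha", self.alpha_rule, self.alpha_sign,
                 geom.R_alpha, geom.C_alpha),
                ("beta", self.beta_rule, self.beta_sign,
                 geom.R_beta, geom.C_beta)):
            m = tags == mu
            if not np.any(m):
                continue
            n_out = np.column_stack([points[m, 0], points[m, 1] - C]) / R
            n_out /= np.linalg.norm(n_out, axis=1, keepdims=True)
            if rule == "normal":
                vec = -n_out                      # + sign = inward
            else:                                 # + sign = equator -> apex
                vec = np.column_stack([-n_out[:, 1], n_out[:, 0]])
                if mu == "beta":                  # beta apex is distal
                    vec = -vec
            out[m] = sign * self.p0_magnitude * vec
        return out


UNIFORM_NORMAL = AnchoringSpec(alpha_rule="normal", beta_rule="normal")


@dataclass
class EnergyParts:
    bulk: float
    distortion: float
    surface: float

    @property
    def total(self) -> float:
        return self.bulk + self.distortion + self.surface


@dataclass
class FieldSolution:
    """Order-parameter field p on a slice mesh (units of R0, scale F0 = a R0^3/2)."""

    mesh: SliceMesh
    p: np.ndarray                      # (N, 2) nodal (p_x, p_z)
    params: MaterialParams
    anchoring: AnchoringSpec
    converged: bool = True
    residual: float = 0.0
    energy_trace: list = dc_field(default_factory=list)

    @property
    def free_energy(self) -> float:
        return free_energy(self, self.params, self.anchoring).total

    @property
    def P(self) -> float:
        return global_order(self)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.p, axis=1)

    def _triangulation(self, mirrored: bool = False):
        import matplotlib.tri as mtri
        nodes, tris = self.mesh.nodes, self.mesh.triangles
        if mirrored:
            off_axis = nodes[:, 0] > 1e-12
            idx_map = np.full(len(nodes), -1)
            idx_map[off_axis] = len(nodes) + np.arange(off_axis.sum())
            idx_map[~off_axis] = np.where(~off_axis)[0]
            m_nodes = nodes[off_axis] * np.array([-1.0, 1.0])
            all_nodes = np.vstack([nodes, m_nodes])
            m_tris = idx_map[tris][:, [0, 2, 1]]
            all_tris = np.vstack([tris, m_tris])
            return mtri.Triangulation(all_nodes[:, 0], all_nodes[:, 1], all_tris), off_axis
        return mtri.Triangulation(nodes[:, 0], nodes[:, 1], tris), None

    def interpolate(self, points: np.ndarray, mirrored: bool = False) -> np.ndarray:
        """Linear interpolation of (p_x, p_z) at (n, 2) slice points.

        With ``mirrored=True`` the field is evenly extended across the
        symmetry axis (p_x odd, p_z even), so loops around on-axis
        points can be evaluated.  Points outside the domain yield NaN.
        """
        import matplotlib.tri as mtri
        tri, off_axis = self._triangulation(mirrored)
        if mirrored:
            px = np.concatenate([self.p[:, 0], -self.p[off_axis, 0]])
            pz = np.concatenate([self.p[:, 1], self.p[off_axis, 1]])
        else:
            px, pz = self.p[:, 0], self.p[:, 1]
        points = np.atleast_2d(points)
        fx = mtri.LinearTriInterpolator(tri, px)
        fz = mtri.LinearTriInterpolator(tri, pz)
        vx = fx(points[:, 0], points[:, 1])
        vz = fz(points[:, 0], points[:, 1])
        return np.column_stack([np.ma.filled(vx, np.nan),
                                np.ma.filled(vz, np.nan)])

    def save(self, path) -> None:
        np.savez(path, nodes=self.mesh.nodes, triangles=self.mesh.triangles,
                 p=self.p, magnitude=self.magnitude(),
                 xi_rel=self.params.xi_rel, lambda_rel=self.params.lambda_rel,
                 K=self.params.K)


@dataclass
class DefectSet:
    """Topological defects of the slice field: (x, z, winding index)."""

    defects: list                       # list of (x, z, int)
    flagged: list = dc_field(default_factory=list)   # unresolvable candidates

    @property
    def total_charge(self) -> int:
        return int(sum(d[2] for d in self.defects))

    def __len__(self) -> int:
        return len(self.defects)


# ---------------------------------------------------------------------------
# finite-element forms

_QP_BARY = np.array([[2 / 3, 1 / 6, 1 / 6],
                     [1 / 6, 2 / 3, 1 / 6],
                     [1 / 6, 1 / 6, 2 / 3]])   # interior degree-2 rule
_QP_W = np.array([1 / 3, 1 / 3, 1 / 3])
_GP_1D = np.array([-1.0, 1.0]) / np.sqrt(3.0)  # 2-point Gauss on [-1, 1]


def _volume_forms(mesh: SliceMesh):
    """Sparse quadratic forms (mass M, splay Ddiv, bend Dcurl) with 2*pi*x measure.

    DOF layout: u = [p_x(nodes), p_z(nodes)], size 2N.
    """
    nodes, tris = mesh.nodes, mesh.triangles
    N = len(nodes)
    pts = nodes[tris]                                   # (T, 3, 2)
    v1 = pts[:, 1] - pts[:, 0]
    v2 = pts[:, 2] - pts[:, 0]
    det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]     # 2*area (CCW => > 0)
    area = 0.5 * det
    # P1 shape-function gradients (constant per element)
    gx = np.stack([(pts[:, 1, 1] - pts[:, 2, 1]) / det,
                   (pts[:, 2, 1] - pts[:, 0, 1]) / det,
                   (pts[:, 0, 1] - pts[:, 1, 1]) / det], axis=1)   # (T, 3)
    gz = np.stack([(pts[:, 2, 0] - pts[:, 1, 0]) / det,
                   (pts[:, 0, 0] - pts[:, 2, 0]) / det,
                   (pts[:, 1, 0] - pts[:, 0, 0]) / det], axis=1)

    T = len(tris)
    M_loc = np.zeros((T, 6, 6))
    Ddiv_loc = np.zeros((T, 6, 6))
    Dcurl_loc = np.zeros((T, 6, 6))
    # curl row: c . u_loc = dpx/dz - dpz/dx  (constant per element)
    c_row = np.concatenate([gz, -gx], axis=1)           # (T, 6)
    for q in range(3):
        lam = _QP_BARY[q]
        xq = pts[:, :, 0] @ lam                          # (T,)
        w = _QP_W[q] * area * 2.0 * np.pi * xq
        phi = np.broadcast_to(lam, (T, 3))
        zero = np.zeros((T, 3))
        # p_x, p_z value rows
        rx = np.concatenate([phi, zero], axis=1)
        rz = np.concatenate([zero, phi], axis=1)
        M_loc += w[:, None, None] * (rx[:, :, None] * rx[:, None, :]
                                     + rz[:, :, None] * rz[:, None, :])
        # divergence row: dpx/dx + p_x/x + dpz/dz
        d_row = np.concatenate([gx + phi / xq[:, None], gz], axis=1)
        Ddiv_loc += w[:, None, None] * d_row[:, :, None] * d_row[:, None, :]
        Dcurl_loc += w[:, None, None] * c_row[:, :, None] * c_row[:, None, :]

    dofs = np.concatenate([tris, tris + N], axis=1)      # (T, 6)
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()

    def asm(loc):
        A = sp.coo_matrix((loc.ravel(), (rows, cols)), shape=(2 * N, 2 * N))
        return A.tocsr()

    return asm(M_loc), asm(Ddiv_loc), asm(Dcurl_loc)


def _surface_forms(mesh: SliceMesh, anchoring: AnchoringSpec):
    """Surface quadratic form: int 2*pi*x (p - p0)^2 ds = u'Su - 2 s0'u + c0."""
    nodes = mesh.nodes
    N = len(nodes)
    e = mesh.boundary_edges
    a, b = nodes[e[:, 0]], nodes[e[:, 1]]
    length = np.linalg.norm(b - a, axis=1)
    E = len(e)
    S_loc = np.zeros((E, 4, 4))
    s0_loc = np.zeros((E, 4))
    c0 = 0.0
    for g in _GP_1D:
        t = 0.5 * (1 + g)
        phi = np.array([1 - t, t])
        pos = a + t * (b - a)                            # (E, 2)
        w = 0.5 * length * 2.0 * np.pi * pos[:, 0]
        p0 = anchoring.p0_at(pos, mesh.boundary_tags, mesh.geom)   # (E, 2)
        rx = np.concatenate([np.broadcast_to(phi, (E, 2)),
                             np.zeros((E, 2))], axis=1)
        rz = np.concatenate([np.zeros((E, 2)),
                             np.broadcast_to(phi, (E, 2))], axis=1)
        S_loc += w[:, None, None] * (rx[:, :, None] * rx[:, None, :]
                                     + rz[:, :, None] * rz[:, None, :])
        s0_loc += w[:, None] * (p0[:, 0:1] * rx + p0[:, 1:2] * rz)
        c0 += float(np.sum(w * np.sum(p0**2, axis=1)))

    dofs = np.column_stack([e, e + N])                   # (E, 4)
    rows = np.repeat(dofs, 4, axis=1).ravel()
    cols = np.tile(dofs, (1, 4)).ravel()
    S = sp.coo_matrix((S_loc.ravel(), (rows, cols)), shape=(2 * N, 2 * N)).tocsr()
    s0 = np.zeros(2 * N)
    np.add.at(s0, dofs.ravel(), s0_loc.ravel())
    return S, s0, c0


def _energy_from_forms(u, M, Ddiv, Dcurl, S, s0, c0, params) -> EnergyParts:
    bulk = float(u @ (M @ u))
    dist = params.xi_rel**2 * float(u @ (Ddiv @ u) + params.K * (u @ (Dcurl @ u)))
    surf = params.lambda_rel * float(u @ (S @ u) - 2.0 * (s0 @ u) + c0)
    return EnergyParts(bulk=bulk, distortion=dist, surface=surf)


def free_energy(field: FieldSolution,
                params: MaterialParams | None = None,
                anchoring: AnchoringSpec | None = None) -> EnergyParts:
    """Rescaled free energy F/F0 of a field, split into bulk, distortion, surface."""
    params = params or field.params
    anchoring = anchoring or field.anchoring
    M, Ddiv, Dcurl = _volume_forms(field.mesh)
    S, s0, c0 = _surface_forms(field.mesh, anchoring)
    u = field.p.T.reshape(-1)      # [px..., pz...] ordering via transpose
    u = np.concatenate([field.p[:, 0], field.p[:, 1]])
    return _energy_from_forms(u, M, Ddiv, Dcurl, S, s0, c0, params)


def minimize(geom: CapGeometry,
             params: MaterialParams,
             anchoring: AnchoringSpec | None = None,
             init: np.ndarray | None = None,
             resolution: float = 0.05,
             mesh: SliceMesh | None = None,
             rel_tol: float = 1e-6,
             max_iter: int = 30) -> FieldSolution:
    """Minimize the rescaled free energy on the two-cap domain.

    The geometry must be expressed in units of R0.  The discrete energy
    is quadratic (see module docstring), so the damped Newton iteration
    converges in a single step; the loop nevertheless verifies the
    relative residual and monotone energy decrease, and would damp if a
    step failed to lower the energy.

    Parameters
    ----------
    init : (N, 2) array, optional
        Initial nodal field; default is a weak radial field
        0.1 * (r - r_center) about the domain mid-height.
    """
    anchoring = anchoring or AnchoringSpec()
    if mesh is None:
        mesh = generate_mesh(geom, resolution)
    N = mesh.n_nodes
    M, Ddiv, Dcurl = _volume_forms(mesh)
    S, s0, c0 = _surface_forms(mesh, anchoring)
    A = (M + params.xi_rel**2 * (Ddiv + params.K * Dcurl)
         + params.lambda_rel * S).tocsr()
    b = params.lambda_rel * s0

    # essential constraint: p_x = 0 on the symmetry axis
    fixed = np.zeros(2 * N, dtype=bool)
    fixed[mesh.axis_nodes] = True
    free = ~fixed

    if init is None:
        z_tip, z_apex = mesh.geom.z_extent()
        center = np.array([0.0, 0.5 * (z_tip + z_apex)])
        init = 0.1 * (mesh.nodes - center)
    u = np.concatenate([init[:, 0], init[:, 1]]).astype(float)
    u[fixed] = 0.0

    A_ff = A[free][:, free].tocsc()
    solve = spla.factorized(A_ff)
    b_f = b[free]
    b_scale = max(np.linalg.norm(b_f), 1e-300)

    def energy(vec):
        return _energy_from_forms(vec, M, Ddiv, Dcurl, S, s0, c0, params).total

    trace = [energy(u)]
    residual = np.linalg.norm(b_f - A_ff @ u[free]) / b_scale
    converged = residual < rel_tol
    it = 0
    while not converged and it < max_iter:
        r = b_f - A_ff @ u[free]
        du = solve(r)
        step = 1.0
        E0 = trace[-1]
        for _ in range(40):                  # damped line search (never needed
            u_try = u.copy()                 # for the quadratic energy, kept as
            u_try[free] += step * du         # the solver contract)
            E1 = energy(u_try)
            if E1 <= E0 + 1e-12 * max(abs(E0), 1.0):
                break
            step *= 0.5
        u = u_try
        trace.append(E1)
        residual = np.linalg.norm(b_f - A_ff @ u[free]) / b_scale
        converged = residual < rel_tol
        it += 1

    p = np.column_stack([u[:N], u[N:]])
    return FieldSolution(mesh=mesh, p=p, params=params, anchoring=anchoring,
                         converged=bool(converged), residual=float(residual),
                         energy_trace=trace)


# ---------------------------------------------------------------------------
# derived quantities


def global_order(field: FieldSolution) -> float:
    """Global degree of order P = int |p| dV / V0 with cylindrical measure."""
    mesh = field.mesh
    pts = mesh.nodes[mesh.triangles]
    area = mesh.triangle_areas()
    p_tri = field.p[mesh.triangles]                     # (T, 3, 2)
    num = 0.0
    den = 0.0
    for q in range(3):
        lam = _QP_BARY[q]
        xq = pts[:, :, 0] @ lam
        w = _QP_W[q] * area * 2.0 * np.pi * xq
        pq = np.einsum("j,tjc->tc", lam, p_tri)
        num += np.sum(w * np.linalg.norm(pq, axis=1))
        den += np.sum(w)
    return float(num / den)


def _node_adjacency(mesh: SliceMesh):
    N = mesh.n_nodes
    pairs = set()
    for t in mesh.triangles:
        pairs.update([(t[0], t[1]), (t[1], t[2]), (t[2], t[0])])
    adj = [[] for _ in range(N)]
    for i, j in pairs:
        adj[i].append(j)
        adj[j].append(i)
    return adj


def _loop_winding(field: FieldSolution, center, rho, n_loop=128):
    """Winding number of p on a circle; None if the loop leaves the domain."""
    ang = np.linspace(0, 2 * np.pi, n_loop, endpoint=False)
    loop = np.asarray(center) + rho * np.column_stack([np.cos(ang), np.sin(ang)])
    pv = field.interpolate(loop, mirrored=True)
    if np.any(np.isnan(pv)) or np.any(np.linalg.norm(pv, axis=1) < 1e-300):
        return None
    d = np.arctan2(pv[:, 1], pv[:, 0])
    dd = np.diff(np.concatenate([d, d[:1]]))
    dd = (dd + np.pi) % (2 * np.pi) - np.pi
    return float(np.sum(dd) / (2 * np.pi))


def detect_defects(field: FieldSolution,
                   zero_threshold: float = 0.2,
                   loop_factor: float = 3.0,
                   n_loop: int = 128) -> DefectSet:
    """Locate interior zeros of |p| and their winding indices.

    The field lives on the half-plane slice, but a constant-azimuth
    plane through the axis is a full plane: the x < 0 half is the
    opposite-azimuth half-slice, where the field is the even mirror
    (p_x odd, p_z even).  Defects are therefore reported in full-plane
    coordinates — an on-axis zero appears once, while an off-axis zero
    (a defect ring in 3D) appears at +x and -x, so ``total_charge``
    is the plain sum of indices and matches the winding of the field
    along the whole tissue boundary.

    Candidates are nodal local minima of |p| below
    ``zero_threshold * max|p|``, at least two mesh resolutions away
    from the cap surface (zeros pinned on the boundary are anchoring
    artifacts, not interior defects).  Nearby candidates are clustered
    until each cluster can be enclosed by a loop of clearance
    ``loop_factor * resolution`` that overlaps no other cluster; the
    cluster's index is the winding number of p on that loop.
    Zero-winding clusters (regular field minima) are discarded;
    non-integer windings are reported as flagged.
    """
    mesh = field.mesh
    mag = field.magnitude()
    mmax = mag.max()
    if mmax <= 0:
        return DefectSet(defects=[])
    adj = _node_adjacency(mesh)
    bnodes = mesh.boundary_nodes()
    bpos = mesh.nodes[bnodes]
    bpos_full = np.vstack([bpos, bpos * np.array([-1.0, 1.0])])
    h = mesh.resolution
    rho0 = loop_factor * h

    cand = []
    for i in range(mesh.n_nodes):
        if mag[i] >= zero_threshold * mmax:
            continue
        if not all(mag[i] <= mag[j] + 1e-15 for j in adj[i]):
            continue
        d_bnd = np.min(np.linalg.norm(bpos - mesh.nodes[i], axis=1))
        if d_bnd < 2.0 * h:
            continue
        cand.append((mesh.nodes[i].copy(), mag[i]))
    if not cand:
        return DefectSet(defects=[])

    # full-plane candidate set: snap near-axis points, mirror the rest
    pts, mags = [], []
    for pos, m in cand:
        if pos[0] < 1.5 * h:
            pts.append(np.array([0.0, pos[1]]))
            mags.append(m)
        else:
            pts.append(pos)
            mags.append(m)
            pts.append(pos * np.array([-1.0, 1.0]))
            mags.append(m)
    pts = np.array(pts)
    mags = np.array(mags)

    # stage 1: per-candidate winding on a small loop; regular minima of a
    # nonvanishing field have winding 0 and drop out here
    flagged = []
    charged = []                           # (pos, mag, winding, rho)
    for pos, m in zip(pts, mags):
        w, rho_used = None, None
        for rho in (2.0 * h, 1.4 * h, 1.0 * h):
            w = _loop_winding(field, pos, rho, n_loop)
            if w is not None:
                rho_used = rho
                break
        if w is None:
            flagged.append((float(pos[0]), float(pos[1]), np.nan))
            continue
        if abs(w - round(w)) > 0.15:
            flagged.append((float(pos[0]), float(pos[1]), w))
        elif int(round(w)) != 0:
            charged.append((pos, m, int(round(w)), rho_used))
    if not charged:
        return DefectSet(defects=[], flagged=flagged)

    # stage 2: merge candidates whose loops overlap (they saw the same
    # zero, or an unresolved near-axis group) and re-measure each merged
    # cluster with one enclosing loop
    clusters = [[i] for i in range(len(charged))]

    def cluster_loop(c):
        """Centre, enclosed radius and measuring-loop radius of a cluster."""
        cpts = np.array([charged[i][0] for i in c])
        ctr = cpts.mean(axis=0)
        if cpts[:, 0].min() <= 0.0 <= cpts[:, 0].max():
            ctr[0] = 0.0
        r_enc = np.linalg.norm(cpts - ctr, axis=1).max() if len(c) > 1 else 0.0
        d_bnd = np.min(np.linalg.norm(bpos_full - ctr, axis=1))
        rho = min(max(r_enc + rho0, charged[c[0]][3]), 0.8 * d_bnd)
        return ctr, r_enc, rho

    # merge until no cluster's measuring loop contains or overlaps another
    changed = True
    while changed and len(clusters) > 1:
        changed = False
        geoms = [cluster_loop(c) for c in clusters]
        for a in range(len(clusters)):
            ctr_a, _, rho_a = geoms[a]
            for b in range(len(clusters)):
                if a == b:
                    continue
                inside = any(np.linalg.norm(charged[i][0] - ctr_a) < rho_a
                             for i in clusters[b])
                touching = (np.linalg.norm(ctr_a - geoms[b][0])
                            < rho_a + geoms[b][2])
                if inside or touching:
                    clusters[a] = clusters[a] + clusters[b]
                    del clusters[b]
                    changed = True
                    break
            if changed:
                break

    defects = []
    for c in clusters:
        cpts = np.array([charged[i][0] for i in c])
        cmag = np.array([charged[i][1] for i in c])
        spans_axis = cpts[:, 0].min() <= 0.0 <= cpts[:, 0].max()
        rep = cpts[np.argmin(cmag)]
        x0, z0 = (0.0, rep[1]) if spans_axis else (float(rep[0]), float(rep[1]))
        if len(c) == 1:
            defects.append((float(x0), float(z0), charged[c[0]][2]))
            continue
        ctr, r_enc, rho = cluster_loop(c)
        w = _loop_winding(field, ctr, rho, n_loop) if rho > r_enc + 0.4 * h else None
        if w is None:
            # enclosing loop does not fit; fall back on the deepest zero
            w = float(charged[c[np.argmin(cmag)]][2])
        wi = int(round(w))
        if abs(w - wi) > 0.15:
            flagged.append((float(x0), float(z0), w))
        elif wi != 0:
            defects.append((float(x0), float(z0), wi))
    return DefectSet(defects=defects, flagged=flagged)


def defect_position(field: FieldSolution,
                    geom: CapGeometry | None = None,
                    defect_set: DefectSet | None = None) -> float:
    """Relative axial defect position (z - L/2) / L.

    L is the axial tissue extent from the beta-cap apex (distal tip,
    position 0) to the alpha-cap apex; a positive value means the defect
    sits proximally of the mid-height, toward the alpha (ExE) cap.
    Requires exactly one detected defect.
    """
    geom = geom or field.mesh.geom
    ds = defect_set or detect_defects(field)
    if len(ds) != 1:
        raise ValueError(f"expected exactly one defect, found {len(ds)}: {ds}")
    z_def = ds.defects[0][1]
    z_tip, z_apex = geom.z_extent()
    L = z_apex - z_tip
    return float((z_def - z_tip - L / 2) / L)


def phase_diagram(geom: CapGeometry,
                  xi_grid,
                  lambda_grid,
                  anchoring: AnchoringSpec | None = None,
                  resolution: float = 0.05,
                  zero_threshold: float = 0.2) -> pd.DataFrame:
    """Global order and defect summary over a (xi_rel, lambda_rel) grid.

    One minimization per grid point on a shared mesh.  Returns a tidy
    frame with columns xi_rel, lambda_rel, P, free_energy, n_defects,
    total_charge, converged.
    """
    anchoring = anchoring or AnchoringSpec()
    mesh = generate_mesh(geom, resolution)
    rows = []
    for xi in np.asarray(xi_grid, dtype=float):
        for lam in np.asarray(lambda_grid, dtype=float):
            params = MaterialParams(xi_rel=float(xi), lambda_rel=float(lam))
            try:
                sol = minimize(geom, params, anchoring, mesh=mesh)
                ds = detect_defects(sol, zero_threshold=zero_threshold)
                rows.append({"xi_rel": xi, "lambda_rel": lam,
                             "P": sol.P, "free_energy": sol.free_energy,
                             "n_defects": len(ds),
                             "total_charge": ds.total_charge,
                             "converged": sol.converged})
            except Exception as exc:        # recorded, not fatal
                rows.append({"xi_rel": xi, "lambda_rel": lam,
                             "P": np.nan, "free_energy": np.nan,
                             "n_defects": -1, "total_charge": 0,
                             "converged": False, "error": str(exc)})
    return pd.DataFrame(rows)
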
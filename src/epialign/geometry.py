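"""Axisymmetric two-spherical-cap tissue geometry.

The tissue boundary is modeled as two spherical caps meeting at the
equator: cap ``alpha`` (the ExE-facing interface, polar angle
``theta in [0, pi/2]``) and cap ``beta`` (the VE-facing interface,
``theta in [pi/2, pi]``).  Each cap is a sphere of radius ``R_mu``
centred on the symmetry axis at ``(0, C_mu)``, so its polar-coordinate
profile about the origin is

    r(theta) = C_mu * cos(theta) + sqrt(R_mu**2 - C_mu**2 * sin(theta)**2)

equivalently, in curvature form with kappa = 1/R and gamma = 1/C,

    r(theta) = cos(theta)/gamma + sqrt(1/kappa**2 - sin(theta)**2/gamma**2).

The characteristic length ``R0 = (3*V0 / 4 pi)**(1/3)`` is derived from
the enclosed volume ``V0``; all field computations are carried out in
units of R0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CapGeometry",
    "BoundaryPointSet",
    "CapFitError",
    "cap_radius",
    "fit_caps",
    "enclosed_volume",
    "characteristic_length",
    "generate_mesh",
    "SliceMesh",
]


class CapFitError(RuntimeError):
    """Raised when the constrained cap fit cannot be completed."""


def _cap_radius_rc(theta, R, C):
    """Polar radius of a sphere of radius R centred at (0, C), about the origin."""
    theta = np.asarray(theta, dtype=float)
    rad = R * R - (C * np.sin(theta)) ** 2
    if np.any(rad < -1e-12 * max(R * R, 1.0)):
        raise ValueError("point not on cap: negative radicand in cap equation")
    return C * np.cos(theta) + np.sqrt(np.clip(rad, 0.0, None))


def cap_radius(theta, kappa, gamma):
    """Evaluate the cap profile r(theta; kappa, gamma).

    Parameters
    ----------
    theta : array_like
        Polar angle(s), radians.
    kappa : float
        Curvature 1/R of the cap (must be > 0).
    gamma : float
        Reciprocal centre offset 1/C.  ``gamma = inf`` encodes a sphere
        centred at the origin (C = 0).

    Returns
    -------
    ndarray or float
        Polar radius of the cap surface at ``theta``.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    C = 0.0 if np.isinf(gamma) else 1.0 / gamma
    return _cap_radius_rc(theta, 1.0 / kappa, C)


@dataclass(frozen=True)
class CapGeometry:
    """Two-cap axisymmetric tissue boundary in the (R, C) parameterization.

    The internal parameters are the cap radii and centre offsets; the
    curvature-form parameters ``kappa_mu = 1/R_mu`` and
    ``gamma_mu = 1/C_mu`` are exposed as properties (``gamma`` is
    infinite for a cap centred at the origin).
    """

    R_alpha: float
    C_alpha: float
    R_beta: float
    C_beta: float

    def __post_init__(self):
        if self.R_alpha <= 0 or self.R_beta <= 0:
            raise ValueError("cap radii must be positive")

    # curvature-form parameters
    @property
    def kappa_alpha(self) -> float:
        return 1.0 / self.R_alpha

    @property
    def kappa_beta(self) -> float:
        return 1.0 / self.R_beta

    @property
    def gamma_alpha(self) -> float:
        return np.inf if self.C_alpha == 0 else 1.0 / self.C_alpha

    @property
    def gamma_beta(self) -> float:
        return np.inf if self.C_beta == 0 else 1.0 / self.C_beta

    def radius(self, theta):
        """Boundary radius r(theta), piecewise over the two caps."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        out = np.empty_like(theta)
        a = theta <= np.pi / 2
        out[a] = _cap_radius_rc(theta[a], self.R_alpha, self.C_alpha)
        out[~a] = _cap_radius_rc(theta[~a], self.R_beta, self.C_beta)
        return out if out.size > 1 else float(out[0])

    @property
    def equator_mismatch(self) -> float:
        """|r_alpha(pi/2) - r_beta(pi/2)| — zero for a continuous boundary."""
        ra = _cap_radius_rc(np.pi / 2, self.R_alpha, self.C_alpha)
        rb = _cap_radius_rc(np.pi / 2, self.R_beta, self.C_beta)
        return abs(float(ra) - float(rb))

    @property
    def V0(self) -> float:
        return enclosed_volume(self)

    @property
    def R0(self) -> float:
        return characteristic_length(self)

    def scaled(self, s: float) -> "CapGeometry":
        """Geometry with all lengths multiplied by ``s``."""
        return CapGeometry(self.R_alpha * s, self.C_alpha * s,
                           self.R_beta * s, self.C_beta * s)

    def z_extent(self) -> tuple[float, float]:
        """(z_tip, z_apex): distal beta-cap apex and proximal alpha-cap apex."""
        z_apex = self.C_alpha + self.R_alpha          # theta = 0
        z_tip = self.C_beta - self.R_beta             # theta = pi
        return z_tip, z_apex

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "R_alpha": self.R_alpha, "C_alpha": self.C_alpha,
            "R_beta": self.R_beta, "C_beta": self.C_beta,
            "V0": self.V0, "R0": self.R0,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "CapGeometry":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["R_alpha"], d["C_alpha"], d["R_beta"], d["C_beta"])


@dataclass
class BoundaryPointSet:
    """Annotated boundary points of one cap, polar coordinates about the centroid."""

    mu: str                    # "alpha" | "beta"
    r: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.mu not in ("alpha", "beta"):
            raise ValueError("mu must be 'alpha' or 'beta'")
        if self.r.shape != self.theta.shape:
            raise ValueError("r and theta must have the same shape")
        if self.N < 3:
            raise ValueError("need at least 3 points per cap for fitting")
        lo, hi = (0.0, np.pi / 2) if self.mu == "alpha" else (np.pi / 2, np.pi)
        if np.any(self.theta < lo - 1e-9) or np.any(self.theta > hi + 1e-9):
            raise ValueError(f"theta outside the {self.mu}-cap domain [{lo}, {hi}]")

    @property
    def N(self) -> int:
        return self.r.size

    @classmethod
    def from_cartesian(cls, mu, x, z, centroid=(0.0, 0.0)) -> "BoundaryPointSet":
        """Build from (x, z) slice coordinates about a supplied centroid."""
        x = np.asarray(x, dtype=float) - centroid[0]
        z = np.asarray(z, dtype=float) - centroid[1]
        r = np.hypot(x, z)
        theta = np.arctan2(np.abs(x), z)   # polar angle from +z, x folded to >= 0
        return cls(mu, r, theta)


# ---------------------------------------------------------------------------
# fitting


def _initial_circle_fit(pts: BoundaryPointSet) -> tuple[float, float]:
    """Algebraic circle fit with centre constrained to the symmetry axis.

    On the axis the circle equation x^2 + (z - C)^2 = R^2 is linear in
    (C, t = R^2 - C^2):  r^2 = 2 z C + t.
    """
    z = pts.r * np.cos(pts.theta)
    A = np.column_stack([2 * z, np.ones_like(z)])
    sol, *_ = np.linalg.lstsq(A, pts.r**2, rcond=None)
    C, t = sol
    R2 = t + C * C
    if not np.isfinite(R2) or R2 <= 0:
        raise CapFitError("degenerate boundary points: algebraic circle fit failed")
    return float(np.sqrt(R2)), float(C)


def fit_caps(points_alpha: BoundaryPointSet,
             points_beta: BoundaryPointSet,
             constraint_tol: float = 1e-8) -> tuple[CapGeometry, dict]:
    """Fit the two-cap profile to boundary points under equator continuity.

    Minimizes the sum of squared radial residuals
    ``sum_i (r_i - r(theta_i; R_mu, C_mu))**2`` over both caps, subject to
    ``r_alpha(pi/2) = r_beta(pi/2)``.  The constraint is enforced by a
    penalty term whose weight is increased geometrically until the
    equator mismatch drops below ``constraint_tol`` relative to the
    equator radius.  Initial guesses come from independent algebraic
    circle fits per cap.

    Returns
    -------
    (CapGeometry, dict)
        The fitted geometry and diagnostics: ``h`` (final data cost),
        ``mismatch``, ``success``, ``n_iter``.
    """
    if points_alpha.mu != "alpha" or points_beta.mu != "beta":
        raise ValueError("point sets must be tagged alpha and beta respectively")

    Ra0, Ca0 = _initial_circle_fit(points_alpha)
    Rb0, Cb0 = _initial_circle_fit(points_beta)
    x0 = np.array([Ra0, Ca0, Rb0, Cb0])
    scale = float(np.mean(np.concatenate([points_alpha.r, points_beta.r])))
    if scale <= 0:
        raise CapFitError("boundary points collapse onto the centroid")

    def residuals(x, w):
        Ra, Ca, Rb, Cb = x
        res = []
        for (R, C, pts) in ((Ra, Ca, points_alpha), (Rb, Cb, points_beta)):
            rad = R * R - (C * np.sin(pts.theta)) ** 2
            bad = np.clip(-rad, 0.0, None)
            r_fit = C * np.cos(pts.theta) + np.sqrt(np.clip(rad, 0.0, None))
            res.append(pts.r - r_fit + 10.0 * np.sqrt(bad))
        ra = np.sqrt(max(Ra * Ra - Ca * Ca, 0.0))
        rb = np.sqrt(max(Rb * Rb - Cb * Cb, 0.0))
        res.append(np.array([w * (ra - rb)]))
        return np.concatenate(res)

    x = x0
    n_iter = 0
    sol = None
    for w in (1e2, 1e4, 1e6, 1e8, 1e10):
        sol = least_squares(residuals, x, args=(w,), method="lm",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
        x = sol.x
        n_iter += sol.nfev
        geom = CapGeometry(abs(x[0]), x[1], abs(x[2]), x[3])
        r_eq = _cap_radius_rc(np.pi / 2, geom.R_alpha, geom.C_alpha)
        if geom.equator_mismatch <= constraint_tol * max(r_eq, scale):
            break
    geom = CapGeometry(abs(x[0]), x[1], abs(x[2]), x[3])
    data_res = residuals(x, 0.0)[:-1]
    h = float(np.sum(data_res**2))
    r_eq = _cap_radius_rc(np.pi / 2, geom.R_alpha, geom.C_alpha)
    ok = geom.equator_mismatch <= constraint_tol * max(float(r_eq), scale)
    diag = {"h": h, "mismatch": geom.equator_mismatch,
            "success": bool(sol.success and ok), "n_iter": n_iter}
    if not sol.success:
        raise CapFitError(f"cap fit did not converge: {sol.message}")
    return geom, diag


# ---------------------------------------------------------------------------
# volume and characteristic length


def enclosed_volume(geom: CapGeometry, n_quad: int = 256) -> float:
    """Enclosed volume by solid-of-revolution integration of the cap profiles.

    V = (2*pi/3) * int_0^pi r(theta)^3 sin(theta) dtheta, evaluated with
    Gauss–Legendre quadrature on each cap separately (the profile is
    smooth per cap but only C0 at the equator).
    """
    xg, wg = np.polynomial.legendre.leggauss(n_quad)
    total = 0.0
    for lo, hi, R, C in ((0.0, np.pi / 2, geom.R_alpha, geom.C_alpha),
                         (np.pi / 2, np.pi, geom.R_beta, geom.C_beta)):
        th = 0.5 * (hi - lo) * xg + 0.5 * (hi + lo)
        w = 0.5 * (hi - lo) * wg
        r = _cap_radius_rc(th, R, C)
        total += np.sum(w * r**3 * np.sin(th))
    V = 2.0 * np.pi / 3.0 * total
    if V <= 0:
        raise ValueError("invalid geometry: non-positive enclosed volume")
    return float(V)


def characteristic_length(geom: CapGeometry) -> float:
    """R0 = (3 V0 / 4 pi)**(1/3)."""
    return float((3.0 * enclosed_volume(geom) / (4.0 * np.pi)) ** (1.0 / 3.0))


# ---------------------------------------------------------------------------
# meshing


@dataclass
class SliceMesh:
    """Triangulated constant-azimuth half-plane slice of the two-cap domain.

    Coordinates are (x, z) with x >= 0 the cylindrical radius and z the
    symmetry axis.  Boundary facets carry the identity of the cap they
    discretize; the axis segment (x = 0) is a symmetry line, not a
    physical boundary.
    """

    nodes: np.ndarray            # (N, 2) float
    triangles: np.ndarray        # (T, 3) int, CCW
    boundary_edges: np.ndarray   # (E, 2) int node pairs on the cap surface
    boundary_tags: np.ndarray    # (E,) '<U5': 'alpha' | 'beta'
    axis_nodes: np.ndarray       # (A,) int nodes with x = 0
    resolution: float
    geom: CapGeometry = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def triangle_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_edges.ravel())


def generate_mesh(geom: CapGeometry, resolution: float = 0.05) -> SliceMesh:
    """Structured triangulation of the half-plane slice in polar coordinates.

    Nodes sit on radial spokes theta_j = j*pi/n_t scaled to the local
    boundary radius; quads between consecutive rings are split into
    triangles, and the innermost ring fans from a single node at the
    origin.  ``resolution`` is the target edge length in the same units
    as the geometry (the field model uses units of R0).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    th_probe = np.linspace(0, np.pi, 181)
    r_probe = geom.radius(th_probe)
    r_mean = float(np.mean(r_probe))
    n_r = max(2, int(np.ceil(r_mean / resolution)))
    n_t = max(4, int(np.ceil(np.pi * r_mean / resolution)))
    if n_t % 2:
        n_t += 1                       # puts a node row exactly at the equator

    theta = np.linspace(0.0, np.pi, n_t + 1)
    r_b = geom.radius(theta)

    nodes = [np.array([0.0, 0.0])]
    index = np.zeros((n_r + 1, n_t + 1), dtype=int)   # index[i, j], i = radial ring
    for i in range(1, n_r + 1):
        frac = i / n_r
        r = frac * r_b
        x = r * np.sin(theta)
        z = r * np.cos(theta)
        for j in range(n_t + 1):
            index[i, j] = len(nodes)
            nodes.append(np.array([x[j], z[j]]))
    nodes = np.array(nodes)
    nodes[:, 0] = np.clip(nodes[:, 0], 0.0, None)     # guard tiny negative x

    tris = []
    for j in range(n_t):
        tris.append([0, index[1, j], index[1, j + 1]])
    for i in range(1, n_r):
        for j in range(n_t):
            a, b = index[i, j], index[i, j + 1]
            c, d = index[i + 1, j], index[i + 1, j + 1]
            tris.append([a, c, d])
            tris.append([a, d, b])
    tris = np.array(tris, dtype=int)

    # enforce CCW orientation
    p = nodes[tris]
    signed = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
              - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = signed < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]

    b_edges = np.array([[index[n_r, j], index[n_r, j + 1]] for j in range(n_t)])
    mid_theta = 0.5 * (theta[:-1] + theta[1:])
    b_tags = np.where(mid_theta < np.pi / 2, "alpha", "beta").astype("<U5")

    axis = np.concatenate([[0], index[1:, 0], index[1:, n_t]])
    return SliceMesh(nodes=nodes, triangles=tris, boundary_edges=b_edges,
                     boundary_tags=b_tags, axis_nodes=np.unique(axis),
                     resolution=resolution, geom=geom)
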
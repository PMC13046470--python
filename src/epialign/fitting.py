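"""Material-length inference from measured alignment fields.

The tissue's correlation length xi/R0 and anchoring length lambda/R0
are estimated by grid search: the averaged tissue shape is fitted with
the two-cap geometry, the polar-order model is minimized at each
parameter pair, and the model magnitude |p| is compared with the
experimental polarity magnitude p_exp = Lambda / Lambda_max at a set of
comparison points r_i via the cost

    C(xi/R0, lambda/R0) = sum_i [ p(r_i) - p_exp(r_i) ]^2 .

Comparison points lie in the intersection of the theoretical and
experimental shapes, farther than 0.05 from the symmetry axis and
farther than d (the mean s.d. of the averaged boundary) from any
boundary, excluding regions where the averaged experimental field has
poor statistics.  The nematic data carry no head-tail sign, so only
magnitudes enter the fit; directions are used afterwards for
validation through the alignment measure |cos(p, p_exp)| and through
projection profiles along standard horizontal and vertical paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import BoundaryPointSet, CapGeometry, fit_caps, generate_mesh
from .nematic import NematicMap
from .polar_field import (AnchoringSpec, FieldSolution, MaterialParams,
                          UNIFORM_NORMAL, defect_position, detect_defects,
                          minimize)

__all__ = [
    "ExperimentalPolarity",
    "ComparisonPointSet",
    "FitResult",
    "default_xi_grid",
    "default_lambda_grid",
    "fit_geometry_to_boundary",
    "experimental_polarity",
    "comparison_points",
    "fit_cost",
    "model_magnitude_surface",
    "fit_material_lengths",
    "alignment_validation",
    "path_projections",
    "compare_defect_positions",
]


def default_xi_grid() -> np.ndarray:
    """12 log-spaced xi/R0 values spanning both sides of the defect transition."""
    return np.geomspace(0.05, 1.0, 12)


def default_lambda_grid() -> np.ndarray:
    """16 log-spaced lambda/R0 values from weak to surface-dominated anchoring."""
    return np.geomspace(0.1, 20.0, 16)


@dataclass
class ExperimentalPolarity:
    """Measured polarity magnitude field in model (R0) units.

    ``grid`` are x-z points, ``p_exp = Lambda/Lambda_max`` in [0, 1],
    ``directors`` the in-plane unsigned alignment vectors (w_x, w_z)
    used only for validation, ``boundary`` the averaged tissue boundary
    and ``d`` its mean spread — all divided by the fitted R0.
    """

    grid: np.ndarray
    p_exp: np.ndarray
    directors: np.ndarray
    boundary: np.ndarray
    d: float
    geom: CapGeometry                 # fitted two-cap shape, R0 units (R0 = 1)
    lambda_max: float

    @property
    def P_exp(self) -> float:
        """Global experimental order: cylindrical-measure average of p_exp
        over the region enclosed by the averaged boundary."""
        inside = self._inside(self.grid)
        x = self.grid[inside, 0]
        return float(np.sum(x * self.p_exp[inside]) / np.sum(x))

    def _inside(self, pts) -> np.ndarray:
        from matplotlib.path import Path
        b = self.boundary
        closed = np.vstack([b, b[::-1] * [-1, 1]])
        return Path(closed).contains_points(np.atleast_2d(pts))


@dataclass
class ComparisonPointSet:
    """Grid points admitted to the fit, with the margins that defined them."""

    points: np.ndarray                # (N, 2) x-z, R0 units
    indices: np.ndarray               # rows of the experimental grid
    axis_margin: float
    d: float

    @property
    def N(self) -> int:
        return len(self.points)


@dataclass
class FitResult:
    """Cost surface over (xi/R0, lambda/R0) and the best-fit point."""

    surface: pd.DataFrame             # xi_rel, lambda_rel, C, P_model, ...
    best: MaterialParams
    best_solution: FieldSolution = field(repr=False, default=None)
    points: ComparisonPointSet = None

    @property
    def C_min(self) -> float:
        return float(self.surface["C"].min())

    @property
    def P_model(self) -> float:
        return float(self.best_solution.P)


# ---------------------------------------------------------------------------
# geometry from the averaged boundary


def fit_geometry_to_boundary(boundary: np.ndarray,
                             interface_z: float) -> tuple[CapGeometry, dict]:
    """Two-cap fit of an averaged boundary curve split at the interface height.

    Points with z above ``interface_z`` belong to the alpha (ExE) cap
    and the rest to the beta (VE) cap; within each cap the polar angle
    is remapped to the cap's nominal theta-domain for Eq.-style
    evaluation (the caps meet at the interface, which plays the role of
    the equator).
    """
    x, z = boundary[:, 0], boundary[:, 1]
    # recentre axially so the interface sits at the equator plane z = 0
    z0 = float(interface_z)
    r = np.hypot(x, z - z0)
    theta = np.arctan2(x, z - z0)
    is_alpha = z >= z0
    if is_alpha.sum() < 3 or (~is_alpha).sum() < 3:
        raise ValueError("interface height leaves fewer than 3 points per cap")
    pa = BoundaryPointSet("alpha", r[is_alpha],
                          np.clip(theta[is_alpha], 0, np.pi / 2))
    pb = BoundaryPointSet("beta", r[~is_alpha],
                          np.clip(theta[~is_alpha], np.pi / 2, np.pi))
    geom, diag = fit_caps(pa, pb)
    diag["z_offset"] = z0
    return geom, diag


def experimental_polarity(nmap: NematicMap,
                          lambda_max: float,
                          interface_z: float | None = None) -> ExperimentalPolarity:
    """Normalize a nematic map into model units (lengths in R0).

    Fits the two-cap geometry to the averaged boundary, rescales all
    coordinates by the fitted R0 (and recentres z at the interface
    height so the model and data share the equator plane), and sets
    p_exp = Lambda/lambda_max.
    """
    iz = nmap.interface_z if interface_z is None else interface_z
    if not np.isfinite(iz):
        raise ValueError("interface height unknown; supply interface_z")
    geom_n, diag = fit_geometry_to_boundary(nmap.boundary, iz)
    R0 = geom_n.R0
    geom = geom_n.scaled(1.0 / R0)
    shift = np.array([0.0, diag["z_offset"]])
    grid = (nmap.grid - shift) / R0
    boundary = (nmap.boundary - shift) / R0
    w = nmap.w
    directors = np.column_stack([w[:, 0], w[:, 2]])
    return ExperimentalPolarity(grid=grid, p_exp=nmap.Lambda / lambda_max,
                                directors=directors, boundary=boundary,
                                d=nmap.boundary_spread / R0, geom=geom,
                                lambda_max=lambda_max)


# ---------------------------------------------------------------------------
# comparison points and cost


def comparison_points(exp: ExperimentalPolarity,
                      geom: CapGeometry | None = None,
                      axis_margin: float = 0.05,
                      d: float | None = None) -> ComparisonPointSet:
    """Grid points in both shapes, away from the axis and the boundaries."""
    geom = geom or exp.geom
    d = exp.d if d is None else d
    pts = exp.grid
    x = pts[:, 0]
    r = np.hypot(pts[:, 0], pts[:, 1])
    theta = np.arctan2(np.abs(pts[:, 0]), pts[:, 1])
    in_model = r <= geom.radius(theta) - d
    in_exp = exp._inside(pts)
    if d > 0:
        bt = exp.boundary
        dd = np.min(np.linalg.norm(pts[:, None, :] - bt[None, :, :], axis=2),
                    axis=1)
        in_exp &= dd > d
    keep = (x > axis_margin) & in_model & in_exp
    if not keep.any():
        raise ValueError("no comparison points survive the margins")
    return ComparisonPointSet(points=pts[keep], indices=np.where(keep)[0],
                              axis_margin=axis_margin, d=d)


def fit_cost(p_model: np.ndarray, p_exp: np.ndarray) -> float:
    """Sum of squared magnitude differences at the comparison points."""
    pm = np.asarray(p_model, float)
    pe = np.asarray(p_exp, float)
    if pm.shape != pe.shape:
        raise ValueError("field samples must align")
    if np.any(np.isnan(pm)) or np.any(np.isnan(pe)):
        raise ValueError("field not evaluable at every comparison point")
    return float(np.sum((pm - pe) ** 2))


class _MeshSampler:
    """Barycentric sampler of nodal fields at fixed points (built once)."""

    def __init__(self, mesh, points):
        import matplotlib.tri as mtri
        tri = mtri.Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1],
                                 mesh.triangles)
        finder = tri.get_trifinder()
        pts = np.atleast_2d(points)
        t = finder(pts[:, 0], pts[:, 1])
        inside = t >= 0
        # nearest-node fallback for points that miss the mesh marginally
        self.fallback = ~inside
        nearest = np.argmin(
            np.linalg.norm(mesh.nodes[None, :, :] - pts[:, None, :], axis=2),
            axis=1)
        tt = np.where(inside, t, 0)
        tris = mesh.triangles[tt]
        a, b, c = (mesh.nodes[tris[:, i]] for i in range(3))
        det = ((b[:, 1] - c[:, 1]) * (a[:, 0] - c[:, 0])
               + (c[:, 0] - b[:, 0]) * (a[:, 1] - c[:, 1]))
        w1 = ((b[:, 1] - c[:, 1]) * (pts[:, 0] - c[:, 0])
              + (c[:, 0] - b[:, 0]) * (pts[:, 1] - c[:, 1])) / det
        w2 = ((c[:, 1] - a[:, 1]) * (pts[:, 0] - c[:, 0])
              + (a[:, 0] - c[:, 0]) * (pts[:, 1] - c[:, 1])) / det
        self.nodes = tris
        self.w = np.column_stack([w1, w2, 1 - w1 - w2])
        self.nearest = nearest

    def __call__(self, nodal: np.ndarray) -> np.ndarray:
        vals = np.einsum("pk,pk...->p...", self.w, nodal[self.nodes])
        if self.fallback.any():
            vals[self.fallback] = nodal[self.nearest[self.fallback]]
        return vals


def model_magnitude_surface(geom: CapGeometry,
                            points: np.ndarray,
                            xi_grid, lambda_grid,
                            K: float = 1e-2,
                            anchoring: AnchoringSpec | None = None,
                            resolution: float = 0.05):
    """Model |p| at fixed sample points for every (xi, lambda) pair.

    One energy minimization per grid point on a shared mesh; the
    magnitudes are read through a fixed barycentric interpolator, so
    repeated fits against different measured fields reuse the same
    surface.  Returns ``(records, magnitudes)`` where ``records`` is a
    list of dicts (xi_rel, lambda_rel, P_model, converged, solution)
    and ``magnitudes`` the matching (n_grid, n_points) array (NaN rows
    for failed solves).
    """
    anchoring = anchoring or AnchoringSpec()
    xi_grid = np.asarray(xi_grid, float)
    lambda_grid = np.asarray(lambda_grid, float)
    mesh = generate_mesh(geom, resolution)
    sampler = _MeshSampler(mesh, points)
    records, mags = [], []
    for xi in xi_grid:
        for lam in lambda_grid:
            params = MaterialParams(xi_rel=float(xi), lambda_rel=float(lam), K=K)
            try:
                sol = minimize(geom, params, anchoring, mesh=mesh)
                pm = np.linalg.norm(sampler(sol.p), axis=1)
                records.append({"xi_rel": float(xi), "lambda_rel": float(lam),
                                "P_model": sol.P, "converged": sol.converged,
                                "solution": sol})
                mags.append(pm)
            except Exception as exc:        # masked, not fatal
                records.append({"xi_rel": float(xi), "lambda_rel": float(lam),
                                "P_model": np.nan, "converged": False,
                                "solution": None, "error": str(exc)})
                mags.append(np.full(len(points), np.nan))
    return records, np.array(mags)


def fit_material_lengths(exp: ExperimentalPolarity,
                         xi_grid=None,
                         lambda_grid=None,
                         K: float = 1e-2,
                         anchoring: AnchoringSpec | None = None,
                         resolution: float = 0.05,
                         points: ComparisonPointSet | None = None,
                         surface_cache=None) -> FitResult:
    """Grid-search fit of (xi/R0, lambda/R0) to the measured magnitude field.

    The cost surface is bit-reproducible for a fixed grid and warm-start
    order; solve failures are masked with NaN cost.  Pass the output of
    :func:`model_magnitude_surface` as ``surface_cache`` to fit several
    measured fields against one set of solves.
    """
    xi_grid = default_xi_grid() if xi_grid is None else np.asarray(xi_grid, float)
    lambda_grid = (default_lambda_grid() if lambda_grid is None
                   else np.asarray(lambda_grid, float))
    pts = points or comparison_points(exp)
    pe = exp.p_exp[pts.indices]
    if surface_cache is None:
        surface_cache = model_magnitude_surface(
            exp.geom, pts.points, xi_grid, lambda_grid, K=K,
            anchoring=anchoring, resolution=resolution)
    records, mags = surface_cache

    rows = []
    best = None
    for rec, pm in zip(records, mags):
        row = {k: rec[k] for k in ("xi_rel", "lambda_rel", "P_model", "converged")}
        if np.any(np.isnan(pm)):
            row["C"] = np.nan
        else:
            row["C"] = fit_cost(pm, pe)
            if best is None or row["C"] < best[0]:
                best = (row["C"],
                        MaterialParams(rec["xi_rel"], rec["lambda_rel"], K),
                        rec["solution"])
        rows.append(row)
    if best is None:
        raise RuntimeError("every grid point failed to solve")
    surface = pd.DataFrame(rows)
    return FitResult(surface=surface, best=best[1], best_solution=best[2],
                     points=pts)


# ---------------------------------------------------------------------------
# validation


def alignment_validation(sol: FieldSolution,
                         exp: ExperimentalPolarity,
                         points: ComparisonPointSet | None = None):
    """Directional agreement |cos(p, p_exp)| at the comparison points.

    Both fields are reduced to their in-plane components; points where
    either vanishes are skipped and counted.  Returns (values, summary
    dict) with values in [0, 1].
    """
    pts = points or comparison_points(exp)
    pm = sol.interpolate(pts.points)
    pe = exp.directors[pts.indices]
    nm = np.linalg.norm(pm, axis=1)
    ne = np.linalg.norm(pe, axis=1)
    ok = (nm > 1e-12) & (ne > 1e-12) & ~np.isnan(nm) & ~np.isnan(ne)
    cosv = np.abs(np.sum(pm[ok] * pe[ok], axis=1)) / (nm[ok] * ne[ok])
    summary = {"mean_abs_cos": float(cosv.mean()) if ok.any() else np.nan,
               "n_used": int(ok.sum()), "n_skipped": int((~ok).sum())}
    return cosv, summary


def path_projections(sample_field,
                     boundary: np.ndarray,
                     n_samples: int = 60) -> dict:
    """Absolute axis projections of a field along six standard paths.

    ``sample_field`` maps (n, 2) x-z points to (n, 2) in-plane vectors.
    Three horizontal paths run at heights t/4, t/2 and 3t/4 above the
    distal tip (t = axial thickness of the boundary) and project on
    x-hat; three vertical paths at x = w/6, w/3 and 2w/3 (w = maximal
    half-width) project on z-hat.  Each profile is reported against the
    rescaled path coordinate in [0, 1] (0 at the axis / distal end).
    """
    z_min, z_max = boundary[:, 1].min(), boundary[:, 1].max()
    t = z_max - z_min
    w_emb = boundary[:, 0].max()
    from matplotlib.path import Path
    closed = np.vstack([boundary, boundary[::-1] * [-1, 1]])
    bpath = Path(closed)

    out = {}
    for frac in (0.25, 0.5, 0.75):
        z = z_min + frac * t
        xs = np.linspace(0, w_emb, 400)
        inside = bpath.contains_points(np.column_stack([xs, np.full_like(xs, z)]))
        if not inside.any():
            continue
        x_max = xs[inside].max()
        xq = np.linspace(0, x_max, n_samples)
        v = sample_field(np.column_stack([xq, np.full_like(xq, z)]))
        out[f"horizontal_t{frac:g}"] = (xq / max(x_max, 1e-12),
                                        np.abs(v[:, 0]))
    for frac in (1 / 6, 1 / 3, 2 / 3):
        x = frac * w_emb
        zs = np.linspace(z_min, z_max, 400)
        inside = bpath.contains_points(np.column_stack([np.full_like(zs, x), zs]))
        if not inside.any():
            continue
        z_lo, z_hi = zs[inside].min(), zs[inside].max()
        zq = np.linspace(z_lo, z_hi, n_samples)
        v = sample_field(np.column_stack([np.full_like(zq, x), zq]))
        out[f"vertical_w{frac:.2g}"] = ((zq - z_lo) / max(z_hi - z_lo, 1e-12),
                                        np.abs(v[:, 1]))
    return out


def compare_defect_positions(geom: CapGeometry,
                             params: MaterialParams,
                             anchoring: AnchoringSpec | None = None,
                             resolution: float = 0.05) -> pd.DataFrame:
    """Defect position: heterogeneous vs uniform anchoring, same geometry.

    Returns one row per anchoring with the relative axial position
    (z - L/2)/L; positive values lie toward the alpha (ExE) cap.
    """
    anchoring = anchoring or AnchoringSpec()
    mesh = generate_mesh(geom, resolution)
    rows = []
    for name, anc in (("heterogeneous", anchoring), ("uniform", UNIFORM_NORMAL)):
        sol = minimize(geom, params, anc, mesh=mesh)
        ds = detect_defects(sol)
        pos = defect_position(sol, geom, ds)
        rows.append({"anchoring": name, "relative_position": pos,
                     "n_defects": len(ds), "total_charge": ds.total_charge})
    return pd.DataFrame(rows)
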
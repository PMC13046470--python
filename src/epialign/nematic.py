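"""Elongation-weighted nematic order field over rotational slices.

The tissue is approximately rotationally symmetric about its
distal-proximal axis, so cell orientations are pooled over M = 36
rotational slices: the coordinate system is reoriented with z along the
axis and rescaled to unit tissue volume; each slice m is rotated into
the x-z plane, carrying the elongation axes v' = eta * v of the cells it
intersects, and at every grid point the weighted Landau-de Gennes
tensor (d = 3)

    Q(r) = (1/M) sum_m ||v''_m|| ( (d/(d-1)) v'' v''^T / ||v''||^2
                                   - I/(d-1) )

is accumulated (empty slices contribute zero but still count in the
1/M).  The principal eigenvector V(r) is the unsigned director, the
corresponding eigenvalue Lambda(r) the local alignment strength, and
w = Lambda * V the alignment vector.  The rotationally averaged tissue
boundary, the volume-averaged magnitude Lambda_avg and tensor-mean
cross-embryo averages follow the same slice construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .orientation import AxisFrame, LabelVolume, TissueMesh

__all__ = [
    "default_grid",
    "RotationalSliceSet",
    "StandardizedCells",
    "NematicMap",
    "reorient_and_normalize",
    "sample_slices",
    "q_tensor",
    "director_strength",
    "averaged_boundary",
    "average_nematic_magnitude",
    "cross_embryo_average",
    "build_nematic_map",
]


@dataclass
class RotationalSliceSet:
    """M equidistant rotational slices about the z axis."""

    M: int = 36

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("need at least one slice")
        self.theta_m = np.arange(self.M) * 2 * np.pi / self.M

    def rotation(self, m: int) -> np.ndarray:
        """Matrix mapping slice m onto the x-z plane (rotation by -theta_m)."""
        c, s = np.cos(self.theta_m[m]), np.sin(self.theta_m[m])
        return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])

    def plane_normal(self, m: int) -> np.ndarray:
        c, s = np.cos(self.theta_m[m]), np.sin(self.theta_m[m])
        return np.array([-s, c, 0.0])


@dataclass
class StandardizedCells:
    """Cells in the axis-aligned, unit-volume frame.

    ``scale`` converts frame lengths (um) to normalized lengths; the
    occupancy lookup maps normalized points back to voxel labels.
    """

    centers: np.ndarray              # (n, 3) normalized
    axes: np.ndarray                 # (n, 3) unit long axes, frame coords
    eta: np.ndarray                  # (n,)
    labels: np.ndarray               # (n,) volume labels
    scale: float                     # normalized units per um
    frame: AxisFrame
    volume_um3: float

    def occupancy(self, vol: LabelVolume):
        """Label lookup at normalized-coordinate points."""
        vox = vol.voxels
        shape = np.array(vox.shape)

        def lookup(points: np.ndarray) -> np.ndarray:
            pts = np.atleast_2d(points) / self.scale
            world = pts @ self.frame.rotation + self.frame.origin
            idx = np.round(world / vol.voxel_size).astype(int)
            ok = np.all((idx >= 0) & (idx < shape), axis=1)
            out = np.zeros(len(pts), dtype=vox.dtype)
            out[ok] = vox[tuple(idx[ok].T)]
            return out

        return lookup


def reorient_and_normalize(table, shapes, frame: AxisFrame,
                           tissue_volume: float) -> StandardizedCells:
    """Map cell centres and long axes into the unit-volume axis frame."""
    if tissue_volume <= 0:
        raise ValueError("tissue volume must be positive")
    scale = tissue_volume ** (-1.0 / 3.0)
    labels = np.array(sorted(shapes))
    centers = np.array([shapes[k].centroid for k in labels])
    axes = np.array([shapes[k].axes[0] for k in labels])
    eta = np.array([shapes[k].eta for k in labels])
    centers_n = frame.to_frame(centers) * scale
    axes_n = frame.vectors_to_frame(axes)
    axes_n /= np.linalg.norm(axes_n, axis=1, keepdims=True)
    return StandardizedCells(centers=centers_n, axes=axes_n, eta=eta,
                             labels=labels, scale=scale, frame=frame,
                             volume_um3=tissue_volume)


def sample_slices(cells: StandardizedCells,
                  slices: RotationalSliceSet,
                  vol: LabelVolume,
                  grid: np.ndarray) -> np.ndarray:
    """Weighted elongation axes v''_m at x-z grid points, per slice.

    ``grid`` is (n, 2) points (x, z) in normalized coordinates.  For
    slice m each grid point is rotated back into the tissue
    (r -> R^T r), the occupying cell is read from the label volume, and
    its elongation axis eta*v is rotated into the x-z plane.  Background
    points yield the zero vector.

    Returns (n, M, 3).
    """
    grid = np.atleast_2d(grid)
    n = len(grid)
    pts3 = np.column_stack([grid[:, 0], np.zeros(n), grid[:, 1]])
    lookup = cells.occupancy(vol)
    label_to_row = {int(k): i for i, k in enumerate(cells.labels)}
    out = np.zeros((n, slices.M, 3))
    for m in range(slices.M):
        R = slices.rotation(m)
        back = pts3 @ R                      # R^T applied to rows
        lab = lookup(back)
        for i, k in enumerate(lab):
            row = label_to_row.get(int(k))
            if row is None:
                continue
            v = cells.eta[row] * cells.axes[row]
            out[i, m] = R @ v
    return out


def q_tensor(samples: np.ndarray, M: int | None = None) -> np.ndarray:
    """Weighted Landau-de Gennes Q tensor from per-slice samples.

    ``samples`` is (M, 3) (or (n, M, 3)); zero-length samples are
    skipped but the average still divides by M.  Returns a symmetric
    traceless 3x3 tensor (or (n, 3, 3)).
    """
    s = np.asarray(samples, dtype=float)
    single = s.ndim == 2
    if single:
        s = s[None]
    n, M_eff, _ = s.shape
    M = M_eff if M is None else M
    norms = np.linalg.norm(s, axis=2)
    safe = np.where(norms < 1e-300, 1.0, norms)
    outer = np.einsum("nmi,nmj->nmij", s, s) / safe[..., None, None] ** 2
    eye = np.eye(3)
    contrib = norms[..., None, None] * (1.5 * outer - 0.5 * eye)
    contrib[norms < 1e-300] = 0.0
    Q = contrib.sum(axis=1) / M
    return Q[0] if single else Q


def director_strength(Q: np.ndarray, degeneracy_tol: float = 1e-9):
    """Principal eigenpair of Q: unsigned director V and strength Lambda.

    V is reported with the canonical hemisphere convention V_z >= 0
    (ties broken by V_x >= 0) and is NaN where the top eigenvalue is
    degenerate; Lambda is always returned.
    """
    Q = np.asarray(Q, dtype=float)
    single = Q.ndim == 2
    if single:
        Q = Q[None]
    vals, vecs = np.linalg.eigh(Q)
    lam = vals[:, -1]
    V = vecs[:, :, -1].copy()
    degen = (vals[:, -1] - vals[:, -2]) < degeneracy_tol
    flip = (V[:, 2] < 0) | ((V[:, 2] == 0) & (V[:, 0] < 0))
    V[flip] = -V[flip]
    V[degen] = np.nan
    if single:
        return V[0], float(lam[0])
    return V, lam


@dataclass
class NematicMap:
    """Gridded nematic alignment of one embryo (normalized coordinates)."""

    grid: np.ndarray                  # (n, 2) x-z points
    Q: np.ndarray                     # (n, 3, 3)
    V: np.ndarray                     # (n, 3) unsigned director (NaN if degenerate)
    Lambda: np.ndarray                # (n,)
    boundary: np.ndarray              # (n_ang, 2) averaged boundary curve (x, z)
    boundary_spread: float            # mean s.d. of per-slice boundary radii
    per_slice_boundaries: np.ndarray = field(repr=False, default=None)
    interface_z: float = np.nan

    @property
    def w(self) -> np.ndarray:
        return self.Lambda[:, None] * self.V

    def inside_boundary(self, points: np.ndarray) -> np.ndarray:
        """Mask of x-z points inside the averaged boundary (x folded)."""
        from matplotlib.path import Path
        b = self.boundary
        closed = np.vstack([b, b[::-1] * [-1, 1]])
        pts = np.atleast_2d(points)
        return Path(closed).contains_points(pts)

    def save(self, path) -> None:
        np.savez(path, grid=self.grid, Q=self.Q, V=self.V,
                 Lambda=self.Lambda, boundary=self.boundary,
                 boundary_spread=self.boundary_spread,
                 interface_z=self.interface_z)


def averaged_boundary(tissue: TissueMesh,
                      frame: AxisFrame,
                      scale: float,
                      slices: RotationalSliceSet,
                      n_angles: int = 90):
    """Rotationally averaged tissue boundary curve in the x-z half-plane.

    The tissue mesh is intersected with each slice plane; the section
    curves, folded to x >= 0, are resampled in polar angle about the
    origin and their radii averaged over slices.  Returns
    ``(curve (n_angles, 2), mean_sd, per_slice_radii (M, n_angles))``.
    """
    verts = frame.to_frame(tissue.mesh.vertices) * scale
    mesh_n = trimesh.Trimesh(vertices=verts, faces=tissue.mesh.faces,
                             process=False)
    psi_grid = np.linspace(0, np.pi, n_angles)
    radii = np.full((slices.M, n_angles), np.nan)
    for m in range(slices.M):
        lines = trimesh.intersections.mesh_plane(
            mesh_n, plane_normal=slices.plane_normal(m),
            plane_origin=np.zeros(3))
        if len(lines) == 0:
            continue
        pts = lines.reshape(-1, 3)
        R = slices.rotation(m)
        pq = pts @ R.T                      # into the x-z plane
        x = np.abs(pq[:, 0])
        z = pq[:, 2]
        rho = np.hypot(x, z)
        psi = np.arctan2(x, z)              # 0 at +z, pi at -z
        order = np.argsort(psi)
        psi_s, rho_s = psi[order], rho[order]
        # average duplicate angles, then interpolate
        radii[m] = np.interp(psi_grid, psi_s, rho_s,
                             left=rho_s[0], right=rho_s[-1])
    valid = ~np.isnan(radii).all(axis=1)
    if not valid.any():
        raise ValueError("no slice intersected the tissue mesh")
    mean_r = np.nanmean(radii[valid], axis=0)
    sd = float(np.nanmean(np.nanstd(radii[valid], axis=0)))
    curve = np.column_stack([mean_r * np.sin(psi_grid),
                             mean_r * np.cos(psi_grid)])
    return curve, sd, radii


def average_nematic_magnitude(nmap: NematicMap, lambda_max: float) -> float:
    """Volume-averaged normalized nematic magnitude Lambda_avg.

    Integrates Lambda over the region enclosed by the averaged boundary
    with the cylindrical measure (weight x) and normalizes by
    lambda_max times the enclosed volume, so a map with Lambda ==
    lambda_max everywhere gives 1.
    """
    if lambda_max <= 0:
        raise ValueError("lambda_max must be positive")
    inside = nmap.inside_boundary(nmap.grid) & (nmap.grid[:, 0] >= 0)
    if not inside.any():
        raise ValueError("no grid points inside the averaged boundary")
    x = nmap.grid[inside, 0]
    lam = nmap.Lambda[inside]
    return float(np.sum(lam * x) / (lambda_max * np.sum(x)))


def cross_embryo_average(maps: list[NematicMap]) -> NematicMap:
    """Tensor-mean nematic map of a cohort on a common grid.

    Q tensors are averaged across embryos before eigen-decomposition
    (never a mean of directors); the boundary is averaged over all
    embryos' slice curves.
    """
    if not maps:
        raise ValueError("empty cohort")
    g0 = maps[0].grid
    for m in maps[1:]:
        if m.grid.shape != g0.shape or not np.allclose(m.grid, g0):
            raise ValueError("nematic maps must share a common grid")
    Q = np.mean([m.Q for m in maps], axis=0)
    V, lam = director_strength(Q)
    all_radii = np.vstack([m.per_slice_boundaries for m in maps
                           if m.per_slice_boundaries is not None])
    psi_grid = np.linspace(0, np.pi, all_radii.shape[1])
    mean_r = np.nanmean(all_radii, axis=0)
    # d measures how much the embryos' averaged shapes differ from each
    # other (low-statistics margin), not the within-embryo slice
    # lumpiness of the cellular surface
    embryo_means = np.array([np.nanmean(m.per_slice_boundaries, axis=0)
                             for m in maps])
    if len(maps) > 1:
        sd = float(np.nanmean(np.nanstd(embryo_means, axis=0)))
    else:
        sd = maps[0].boundary_spread
    curve = np.column_stack([mean_r * np.sin(psi_grid),
                             mean_r * np.cos(psi_grid)])
    return NematicMap(grid=g0, Q=Q, V=V, Lambda=lam, boundary=curve,
                      boundary_spread=sd, per_slice_boundaries=all_radii,
                      interface_z=float(np.nanmean([m.interface_z
                                                    for m in maps])))


def default_grid(grid_n: int = 64,
                 x_max: float = 0.95,
                 z_min: float = -0.95,
                 z_max: float = 1.1) -> np.ndarray:
    """Fixed x-z grid in normalized coordinates, shared across a cohort.

    The window generously covers a unit-volume two-cap tissue (whose
    characteristic radius is (3/4pi)^(1/3) ~ 0.62), so embryo-to-embryo
    shape variation stays inside it.
    """
    gx = np.linspace(0.0, x_max, grid_n)
    gz = np.linspace(z_min, z_max, grid_n)
    X, Z = np.meshgrid(gx, gz)
    return np.column_stack([X.ravel(), Z.ravel()])


def build_nematic_map(vol: LabelVolume,
                      table, shapes, tissue: TissueMesh,
                      frame: AxisFrame,
                      M: int = 36,
                      grid_n: int = 64,
                      grid: np.ndarray | None = None) -> NematicMap:
    """Driver: standardized cells -> slice samples -> Q field -> map.

    Pass an explicit ``grid`` (e.g. :func:`default_grid`) when maps
    from several embryos will be averaged.
    """
    cells = reorient_and_normalize(table, shapes, frame,
                                   tissue_volume=float(abs(tissue.mesh.volume)))
    slices = RotationalSliceSet(M=M)
    curve, sd, radii = averaged_boundary(tissue, frame, cells.scale, slices)
    if grid is None:
        x_max = curve[:, 0].max()
        z_min, z_max = curve[:, 1].min(), curve[:, 1].max()
        pad = 0.02 * (z_max - z_min)
        gx = np.linspace(0.0, x_max + pad, grid_n)
        gz = np.linspace(z_min - pad, z_max + pad, grid_n)
        X, Z = np.meshgrid(gx, gz)
        grid = np.column_stack([X.ravel(), Z.ravel()])
    samples = sample_slices(cells, slices, vol, grid)
    Q = q_tensor(samples)
    V, lam = director_strength(Q)
    iz = frame.interface_height * cells.scale
    return NematicMap(grid=grid, Q=Q, V=V, Lambda=lam, boundary=curve,
                      boundary_spread=sd, per_slice_boundaries=radii,
                      interface_z=iz)
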
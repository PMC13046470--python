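"""Seed-deterministic synthetic embryos for pipeline validation.

Real segmented embryo volumes are not redistributable, so every stage of
the analysis is exercised on synthetic tissues that reproduce the
statistical structure the pipeline assumes: a two-spherical-cap domain
(default characteristic radius R0 ~ 25 um) packed with a few dozen
prolate ellipsoidal cells whose long axes follow a prescribed
orientation field — radial, boundary-anchored composite, or a solved
polar-order field — with von Mises–Fisher angular noise, and whose
shape anisotropy eta spans a configurable range.  Cells are rendered
into an isotropic label volume (anisotropic-Voronoi assignment, so
overlapping ellipsoids still produce disjoint labels) together with the
axis annotations a human would click: interface points on the cap
equator, the distal tip, and two transverse-edge points.

The generator is the study-condition definition, not a tuning knob:
defaults are 60 cells, eta in [0.2, 0.8], orientation concentration
kappa = 20, voxel 0.8 um.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import CapGeometry
from .orientation import AxisAnnotation, LabelVolume

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "default_geometry",
    "sample_cells",
    "rasterize",
    "make_annotations",
    "generate_embryo",
    "field_driven_cohort",
]


def default_geometry(scale_um: float = 23.0) -> CapGeometry:
    """Late-stage-like two-cap geometry scaled to physical micrometres.

    The unit-shape caps (R_alpha=1, C_alpha=0.2, R_beta=1.1, C_beta=0.5)
    satisfy equator continuity; ``scale_um`` multiplies all lengths and
    the default yields R0 ~ 24 um.
    """
    return CapGeometry(1.0, 0.2, 1.1, 0.5).scaled(scale_um)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic embryo."""

    geometry: CapGeometry = field(default_factory=default_geometry)
    n_cells: int = 60
    orientation_source: object = "radial"   # "radial" | "uniform" |
    #                                         "composite" | FieldSolution
    angular_noise_kappa: float = 20.0
    eta_range: tuple = (0.2, 0.8)
    voxel_size: float = 0.8
    fill_fraction: float = 0.9
    tiling: bool = True        # cells tile the tissue (epithelium-like)
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 2:
            raise ValueError("need at least two cells")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        lo, hi = self.eta_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("eta_range must satisfy 0 <= lo <= hi < 1")


@dataclass
class GroundTruth:
    """Per-cell generating parameters of a synthetic embryo."""

    centers: np.ndarray          # (n, 3) um
    orientations: np.ndarray     # (n, 3) unit long axes
    eta: np.ndarray              # (n,) target anisotropy
    semi_axes: np.ndarray        # (n, 3) um (a, b, b), prolate
    geometry: CapGeometry = None
    field_params: dict | None = None
    dropped_labels: list = field(default_factory=list)

    def save(self, path) -> None:
        d = {"centers": self.centers.tolist(),
             "orientations": self.orientations.tolist(),
             "eta": self.eta.tolist(),
             "semi_axes": self.semi_axes.tolist(),
             "geometry": self.geometry.to_dict() if self.geometry else None,
             "field_params": self.field_params,
             "dropped_labels": self.dropped_labels}
        with open(path, "w") as fh:
            json.dump(d, fh)


# ---------------------------------------------------------------------------
# orientation sources


def _radial_rule(centers, geom):
    v = centers.copy()
    n = np.linalg.norm(v, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return v / n


def _composite_rule(centers, geom):
    """Boundary-anchored composite: radial near the beta cap, tangential
    (meridional, equator -> apex) near the alpha cap, blended by polar angle."""
    out = np.empty_like(centers, dtype=float)
    r = np.linalg.norm(centers, axis=1)
    r[r == 0] = 1.0
    theta = np.arccos(np.clip(centers[:, 2] / r, -1, 1))
    radial = centers / r[:, None]
    # meridional tangent (toward +z pole), orthogonal to radial
    zhat = np.array([0.0, 0.0, 1.0])
    tang = zhat - radial * radial[:, 2:3]
    tn = np.linalg.norm(tang, axis=1, keepdims=True)
    tn[tn < 1e-12] = 1.0
    tang = tang / tn
    w = np.clip((theta - np.pi / 3) / (np.pi / 3), 0.0, 1.0)[:, None]
    v = (1 - w) * tang + w * radial
    vn = np.linalg.norm(v, axis=1, keepdims=True)
    vn[vn < 1e-12] = 1.0
    out[:] = v / vn
    return out


def _field_rule(centers, geom, sol):
    """Direction (and |p|) of a solved slice field at 3D points (um)."""
    R0 = geom.R0
    x = np.linalg.norm(centers[:, :2], axis=1) / R0
    z = centers[:, 2] / R0
    p = sol.interpolate(np.column_stack([x, z]))
    # nearest-inside fallback for points marginally outside the mesh hull
    bad = np.isnan(p).any(axis=1)
    if np.any(bad):
        shrink = np.column_stack([x[bad], z[bad]]) * 0.95
        p[bad] = sol.interpolate(shrink)
        p[np.isnan(p).any(axis=1)] = [0.0, 1.0]
    mag = np.linalg.norm(p, axis=1)
    safe = np.where(mag < 1e-12, 1.0, mag)
    phat = p / safe[:, None]
    # rotate in-plane (x, z) directions back to 3D around the z axis
    phi = np.arctan2(centers[:, 1], centers[:, 0])
    dirs = np.column_stack([phat[:, 0] * np.cos(phi),
                            phat[:, 0] * np.sin(phi),
                            phat[:, 1]])
    dirs[mag < 1e-12] = [0.0, 0.0, 1.0]
    return dirs, mag


def _orientation_field(spec: SyntheticSpec, centers, rng):
    src = spec.orientation_source
    mag = None
    if isinstance(src, str):
        if src == "radial":
            dirs = _radial_rule(centers, spec.geometry)
        elif src == "composite":
            dirs = _composite_rule(centers, spec.geometry)
        elif src == "uniform":
            v = rng.normal(size=centers.shape)
            dirs = v / np.linalg.norm(v, axis=1, keepdims=True)
        else:
            raise ValueError(f"unknown orientation source {src!r}")
    else:                                  # a FieldSolution
        dirs, mag = _field_rule(centers, spec.geometry, src)
    return dirs, mag


def _sample_vmf(mean_dirs: np.ndarray, kappa: float, rng) -> np.ndarray:
    """von Mises–Fisher draws on S^2 around per-row mean directions."""
    n = mean_dirs.shape[0]
    if np.isinf(kappa):
        return mean_dirs.copy()
    # Wood (1994) rejection-free inversion for d = 3
    u = rng.uniform(size=n)
    w = 1.0 + np.log(u + (1 - u) * np.exp(-2 * kappa)) / kappa
    phi = rng.uniform(0, 2 * np.pi, size=n)
    s = np.sqrt(np.clip(1 - w**2, 0, None))
    local = np.column_stack([s * np.cos(phi), s * np.sin(phi), w])
    # rotate local +z to each mean direction
    out = np.empty_like(mean_dirs)
    for i, mu in enumerate(mean_dirs):
        zhat = np.array([0.0, 0.0, 1.0])
        vperp = np.cross(zhat, mu)
        sn = np.linalg.norm(vperp)
        cs = float(np.dot(zhat, mu))
        if sn < 1e-12:
            R = np.eye(3) if cs > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -vperp[2], vperp[1]],
                           [vperp[2], 0, -vperp[0]],
                           [-vperp[1], vperp[0], 0]])
            R = np.eye(3) + vx + vx @ vx * ((1 - cs) / sn**2)
        out[i] = R @ local[i]
    return out


def eta_to_aspect(eta: float) -> float:
    """Prolate aspect ratio a/b realizing a target anisotropy.

    For a solid prolate ellipsoid (a, b, b) the inertia components are
    proportional to (2b^2, a^2 + b^2, a^2 + b^2), giving
    eta = 1 - sqrt(2 b^2 / (a^2 + b^2)); inverting yields
    (a/b)^2 = 2 / (1 - eta)^2 - 1.
    """
    if not 0 <= eta < 1:
        raise ValueError("eta must lie in [0, 1)")
    return float(np.sqrt(2.0 / (1.0 - eta) ** 2 - 1.0))


# ---------------------------------------------------------------------------
# cell placement and rendering


def sample_cells(spec: SyntheticSpec, rng=None):
    """Draw ellipsoidal cells filling the cap domain.

    Centres are placed by dart throwing with a minimum separation so the
    packing is quasi-uniform; each long axis is a vMF draw around the
    orientation source at the centre; prolate semi-axes are chosen so
    the solid-ellipsoid anisotropy hits a uniform draw from eta_range
    (or, for a field source, |p| rescaled into eta_range).

    Returns a GroundTruth record.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    geom = spec.geometry
    z_tip, z_apex = geom.z_extent()
    r_max = float(np.max(geom.radius(np.linspace(0, np.pi, 91))))

    cell_vol = spec.fill_fraction * geom.V0 / spec.n_cells
    r_cell = (3 * cell_vol / (4 * np.pi)) ** (1 / 3)
    min_sep = 1.35 * r_cell
    margin = 0.6 * r_cell

    theta_tab = np.linspace(0, np.pi, 361)
    r_tab = geom.radius(theta_tab)
    centers = []
    acc = np.empty((0, 3))
    attempts = 0
    max_attempts = 4000 * spec.n_cells
    while len(centers) < spec.n_cells and attempts < max_attempts:
        m = 512
        pts = rng.uniform([-r_max, -r_max, z_tip], [r_max, r_max, z_apex],
                          (m, 3))
        attempts += m
        r = np.linalg.norm(pts, axis=1)
        theta = np.arccos(np.clip(pts[:, 2] / np.maximum(r, 1e-12), -1, 1))
        inside = r <= np.interp(theta, theta_tab, r_tab) - margin
        for pt in pts[inside]:
            if len(centers) >= spec.n_cells:
                break
            if len(centers) and np.min(
                    np.linalg.norm(acc[:len(centers)] - pt, axis=1)) < min_sep:
                continue
            if len(centers) == len(acc):
                acc = np.vstack([acc, np.empty((64, 3))])
            acc[len(centers)] = pt
            centers.append(pt)
    if len(centers) < spec.n_cells:
        raise RuntimeError(
            f"packed only {len(centers)}/{spec.n_cells} cells; "
            "reduce n_cells or fill_fraction")
    centers = np.array(centers)

    mean_dirs, mag = _orientation_field(spec, centers, rng)
    dirs = _sample_vmf(mean_dirs, spec.angular_noise_kappa, rng)

    lo, hi = spec.eta_range
    if mag is None:
        eta = rng.uniform(lo, hi, size=spec.n_cells)
    else:
        # proportional to the local field magnitude so the pipeline's
        # normalized nematic strength reproduces |p| up to one scale
        eta = hi * mag / max(mag.max(), 1e-12)
    aspect = np.array([eta_to_aspect(e) for e in eta])
    b = (3 * cell_vol / (4 * np.pi * aspect)) ** (1 / 3)
    semi = np.column_stack([aspect * b, b, b])

    params = None
    if not isinstance(spec.orientation_source, str):
        p = spec.orientation_source.params
        params = {"xi_rel": p.xi_rel, "lambda_rel": p.lambda_rel, "K": p.K}
    return GroundTruth(centers=centers, orientations=dirs, eta=eta,
                       semi_axes=semi, geometry=geom, field_params=params)


def rasterize(truth: GroundTruth, spec: SyntheticSpec,
              tiling: bool | None = None,
              rotation: np.ndarray | None = None) -> LabelVolume:
    """Render cells into a label volume (anisotropic-Voronoi assignment).

    Every voxel centre is assigned to the cell whose normalized
    ellipsoidal quadratic form is smallest, guaranteeing disjoint labels
    for overlapping ellipsoids.  With ``tiling`` (the default) every
    in-domain voxel is claimed by its nearest cell, so the cells tile
    the tissue without background gaps — the structure membrane
    segmentation of an epithelium actually produces, and the reason the
    tissue surface is smooth at the cap boundary.  Without tiling only
    voxels with quadratic form < 1 (strictly inside an ellipsoid) are
    labelled.  Voxels outside the cap domain stay background; cells
    rendering to zero voxels are dropped and recorded on the
    GroundTruth.
    """
    geom = truth.geometry
    vs = spec.voxel_size
    tiling = spec.tiling if tiling is None else tiling
    z_tip, z_apex = geom.z_extent()
    r_max = float(np.max(geom.radius(np.linspace(0, np.pi, 91))))
    pad = 2 * vs
    if rotation is None:
        lo = np.array([-r_max - pad, -r_max - pad, z_tip - pad])
        hi = np.array([r_max + pad, r_max + pad, z_apex + pad])
    else:
        th = np.linspace(0, np.pi, 91)
        rb = geom.radius(th)
        phi = np.linspace(0, 2 * np.pi, 73)
        surf = np.stack([np.outer(rb * np.sin(th), np.cos(phi)),
                         np.outer(rb * np.sin(th), np.sin(phi)),
                         np.outer(rb * np.cos(th), np.ones_like(phi))],
                        axis=-1).reshape(-1, 3) @ rotation.T
        lo = surf.min(axis=0) - pad
        hi = surf.max(axis=0) + pad
    shape = np.ceil((hi - lo) / vs).astype(int)

    # voxel centre world coordinates: lo + (index + 0.5) * vs
    best_q = np.full(shape, np.inf, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.int32)
    n = len(truth.centers)
    grids = [lo[i] + (np.arange(shape[i]) + 0.5) * vs for i in range(3)]
    for k in range(n):
        c = truth.centers[k]
        a = truth.semi_axes[k]
        u = truth.orientations[k]
        # orthonormal triad with first axis along the orientation
        ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e2 = np.cross(u, ref)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(u, e2)
        R = np.vstack([u, e2, e3])          # rows: ellipsoid axes
        if tiling:
            i_lo, i_hi = np.zeros(3, int), shape
        else:
            ext = a.max()
            i_lo = np.clip(np.floor((c - ext - lo) / vs - 0.5).astype(int),
                           0, shape - 1)
            i_hi = np.clip(np.ceil((c + ext - lo) / vs + 0.5).astype(int),
                           1, shape)
        X, Y, Z = np.meshgrid(grids[0][i_lo[0]:i_hi[0]],
                              grids[1][i_lo[1]:i_hi[1]],
                              grids[2][i_lo[2]:i_hi[2]], indexing="ij")
        d = np.stack([X - c[0], Y - c[1], Z - c[2]], axis=-1)
        local = d @ R.T
        q = ((local[..., 0] / a[0]) ** 2
             + (local[..., 1] / a[1]) ** 2
             + (local[..., 2] / a[2]) ** 2).astype(np.float32)
        sl = (slice(i_lo[0], i_hi[0]), slice(i_lo[1], i_hi[1]),
              slice(i_lo[2], i_hi[2]))
        upd = q < best_q[sl] if tiling else (q < 1.0) & (q < best_q[sl])
        best_q[sl] = np.where(upd, q, best_q[sl])
        labels[sl] = np.where(upd, k + 1, labels[sl])

    # clip to the cap domain (in the unrotated tissue frame)
    idx = np.indices(shape)
    world = lo[:, None, None, None] + (idx + 0.5) * vs
    if rotation is not None:
        world = np.einsum("ji,j...->i...", rotation, world)
    r = np.sqrt((world**2).sum(axis=0))
    theta = np.arccos(np.clip(world[2] / np.maximum(r, 1e-12), -1, 1))
    inside = r <= geom.radius(theta.ravel()).reshape(shape)
    labels[~inside] = 0

    present = set(np.unique(labels)) - {0}
    truth.dropped_labels = [k + 1 for k in range(n) if (k + 1) not in present]
    vol = LabelVolume(voxels=labels, voxel_size=vs)
    vol._origin = lo                        # world offset used by rendering
    return vol


def make_annotations(spec: SyntheticSpec, rng=None,
                     jitter: float = 0.0,
                     n_interface: int = 8) -> AxisAnnotation:
    """Annotation points a human would click, with optional jitter (um).

    Interface points lie on the cap-equator circle, the tip at the
    beta-cap apex, and the two edge points straddle the equator at
    azimuth 0 (their mean fixes the 0-deg rotation plane).
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    geom = spec.geometry
    r_eq = float(geom.radius(np.pi / 2))
    phis = np.linspace(0, 2 * np.pi, n_interface, endpoint=False)
    interface = np.column_stack([r_eq * np.cos(phis),
                                 r_eq * np.sin(phis),
                                 np.zeros_like(phis)])
    z_tip, _ = geom.z_extent()
    tip = np.array([0.0, 0.0, z_tip])
    dz = 0.05 * r_eq
    edge = np.array([[r_eq, 0.0, dz], [r_eq, 0.0, -dz]])
    if jitter > 0:
        interface = interface + rng.normal(0, jitter, interface.shape)
        tip = tip + rng.normal(0, jitter, 3)
        edge = edge + rng.normal(0, jitter, edge.shape)
    return AxisAnnotation(interface_points=interface, tip_point=tip,
                          edge_points=edge)


def generate_embryo(spec: SyntheticSpec,
                    jitter: float = 0.0,
                    rotation: np.ndarray | None = None):
    """Full synthetic embryo: (LabelVolume, AxisAnnotation, GroundTruth).

    ``rotation`` applies a rigid 3x3 rotation to the whole embryo (cells,
    tissue domain and annotation points) before rasterization, for
    orientation-equivariance studies.  All coordinates (annotations,
    ground-truth centres) are expressed in the volume's physical frame,
    where array index i sits at i * voxel_size — the frame in which the
    quantification pipeline reports mesh coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    truth = sample_cells(spec, rng)
    ann = make_annotations(spec, rng, jitter=jitter)
    if rotation is not None:
        rotation = np.asarray(rotation, float)
        truth.centers = truth.centers @ rotation.T
        truth.orientations = truth.orientations @ rotation.T
        ann = AxisAnnotation(
            interface_points=ann.interface_points @ rotation.T,
            tip_point=rotation @ ann.tip_point,
            edge_points=ann.edge_points @ rotation.T)
    vol = rasterize(truth, spec, rotation=rotation)
    shift = -(vol._origin + 0.5 * spec.voxel_size)   # world -> volume frame
    truth.centers = truth.centers + shift
    truth.frame_offset = shift
    ann = AxisAnnotation(interface_points=ann.interface_points + shift,
                         tip_point=ann.tip_point + shift,
                         edge_points=ann.edge_points + shift)
    return vol, ann, truth


def field_driven_cohort(field_solution,
                        n_embryos: int,
                        template: SyntheticSpec,
                        shape_jitter: float = 0.0,
                        annotation_jitter: float = 0.0) -> list:
    """Cohort of embryos whose cell orientations follow a solved field.

    Cell long axes are sampled around the field direction at each cell
    centre and eta is |p| rescaled into the template's eta_range;
    ``shape_jitter`` applies relative log-normal jitter to the cap
    parameters per embryo.  Embryo k uses seed ``template.seed + k``.
    """
    out = []
    base = template.geometry
    for k in range(n_embryos):
        seed = template.seed + k
        rng = np.random.default_rng(seed)
        if shape_jitter > 0:
            f = np.exp(rng.normal(0, shape_jitter, size=2))
            geom = CapGeometry(base.R_alpha * f[0], base.C_alpha * f[0],
                               base.R_beta * f[1], base.C_beta * f[1])
            # restore equator continuity by rescaling the beta cap
            r_eq_a = geom.radius(np.pi / 2 - 1e-9)
            s = r_eq_a / CapGeometry(1, 0, geom.R_beta,
                                     geom.C_beta).radius(np.pi / 2 + 1e-9)
            geom = CapGeometry(geom.R_alpha, geom.C_alpha,
                               geom.R_beta * s, geom.C_beta * s)
        else:
            geom = base
        spec = replace(template, geometry=geom, seed=seed,
                       orientation_source=field_solution)
        out.append(generate_embryo(spec, jitter=annotation_jitter))
    return out
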
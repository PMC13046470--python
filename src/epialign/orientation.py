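"""Per-cell shape and orientation quantification from 3D label volumes.

A segmented tissue arrives as an integer label volume (0 = background)
with isotropic voxel size in micrometres.  Each cell is reconstructed as
a closed surface mesh; solid-body inertia analysis yields the principal
inertia components ``lambda1 <= lambda2 <= lambda3``, the shape
anisotropy ``eta = (lambda3 - sqrt(lambda1*lambda2)) / lambda3`` (0 for
a sphere, approaching 1 for a needle), and the cell's long axis — the
principal direction with the *smallest* inertia component.  Polarity is
this axis with its sign fixed outward: toward the local tissue-boundary
normal for boundary-touching cells, away from the tissue centroid for
interior cells.  The cell-to-boundary angle is the angle between
polarity and boundary normal folded to [0, 90] degrees, so 0 deg means
the cell stands perpendicular to the boundary surface (polarity along
the normal) and 90 deg means it lies parallel to it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import trimesh
from skimage import measure

__all__ = [
    "LabelVolume",
    "CellShape",
    "TissueMesh",
    "AxisAnnotation",
    "AxisFrame",
    "resample_isotropic",
    "extract_meshes",
    "inertia_analysis",
    "anisotropy",
    "boundary_normal",
    "polarity_vector",
    "boundary_angle",
    "neighbor_angles",
    "determine_axis",
    "quantify_cells",
]


@dataclass
class LabelVolume:
    """Integer-labelled 3D volume with isotropic voxel size (um)."""

    voxels: np.ndarray
    voxel_size: float
    boundary_labels: dict | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("label volume must be integer typed")
        if self.voxels.max() < 1:
            raise ValueError("label volume contains no cells")

    def labels(self) -> np.ndarray:
        lab = np.unique(self.voxels)
        return lab[lab > 0]

    @classmethod
    def from_tiff(cls, path, voxel_size: float) -> "LabelVolume":
        import tifffile
        return cls(np.asarray(tifffile.imread(path)), voxel_size)

    def to_tiff(self, path) -> None:
        import tifffile
        tifffile.imwrite(path, self.voxels)


@dataclass
class CellShape:
    """Mesh-derived descriptors of one segmented cell (lengths in um)."""

    label: int
    volume: float
    surface_area: float
    centroid: np.ndarray
    inertia: tuple                     # (lambda1, lambda2, lambda3), ascending
    axes: np.ndarray                   # rows = principal directions for inertia[i]
    eta: float
    touches_boundary: bool = False
    boundary_normal: np.ndarray | None = None
    polarity: np.ndarray | None = None


@dataclass
class TissueMesh:
    """Global tissue surface with per-vertex cell labels."""

    mesh: trimesh.Trimesh
    vertex_labels: np.ndarray
    centroid: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.centroid is None:
            self.centroid = np.asarray(self.mesh.center_mass, dtype=float)


@dataclass
class AxisAnnotation:
    """Manual annotation points defining the distal-proximal frame (um).

    interface_points : >= 6 points near the ExE/VE interface circle
    tip_point : one point at the distal tip
    edge_points : two points on the transverse edge fixing the 0-deg plane
    """

    interface_points: np.ndarray
    tip_point: np.ndarray
    edge_points: np.ndarray

    def __post_init__(self):
        self.interface_points = np.atleast_2d(np.asarray(self.interface_points, float))
        self.tip_point = np.asarray(self.tip_point, float)
        self.edge_points = np.atleast_2d(np.asarray(self.edge_points, float))
        if self.interface_points.shape[0] < 6:
            raise ValueError("need at least six interface points")
        if self.edge_points.shape[0] != 2:
            raise ValueError("need exactly two transverse-edge points")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"interface_points": self.interface_points.tolist(),
                       "tip_point": self.tip_point.tolist(),
                       "edge_points": self.edge_points.tolist()}, fh, indent=1)

    @classmethod
    def load(cls, path) -> "AxisAnnotation":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["interface_points"], d["tip_point"], d["edge_points"])


@dataclass
class AxisFrame:
    """Right-handed frame with z along the distal-proximal axis.

    ``rotation`` rows are the frame axes (x: 0-deg rotation plane,
    z: distal -> proximal); world points map to frame coordinates as
    ``rotation @ (point - origin)``.
    """

    origin: np.ndarray
    rotation: np.ndarray
    interface_plane: tuple             # (point_on_plane, unit_normal)

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.rotation.T

    def vectors_to_frame(self, vectors: np.ndarray) -> np.ndarray:
        return np.atleast_2d(vectors) @ self.rotation.T

    @property
    def interface_height(self) -> float:
        """Axial coordinate (frame z) of the interface-plane anchor point."""
        return float(self.to_frame(self.interface_plane[0])[0, 2])


# ---------------------------------------------------------------------------
# preprocessing


def resample_isotropic(raw: np.ndarray,
                       voxel_size_zyx,
                       bin_xy: int = 2,
                       labels: bool = False) -> tuple[np.ndarray, float]:
    """Channel-sum, 2x2x1 bin and isotropically rescale a raw stack.

    ``raw`` is (z, y, x) or (z, y, x, c); channels are summed first.
    In-plane binning averages ``bin_xy x bin_xy x 1`` blocks, then the
    volume is rescaled to cubic voxels whose edge is the smallest binned
    dimension.  With ``labels=True`` nearest-neighbour interpolation is
    used and no binning average is applied (labels are subsampled).

    Returns the resampled array and the isotropic voxel size.
    """
    vz, vy, vx = (float(v) for v in voxel_size_zyx)
    if min(vz, vy, vx) <= 0:
        raise ValueError("voxel dimensions must be positive")
    arr = np.asarray(raw)
    if arr.ndim == 4:
        arr = arr.sum(axis=-1)
    if arr.ndim != 3:
        raise ValueError("expected a 3D (or 3D multi-channel) array")
    if bin_xy > 1:
        ny = arr.shape[1] - arr.shape[1] % bin_xy
        nx = arr.shape[2] - arr.shape[2] % bin_xy
        a = arr[:, :ny, :nx]
        if labels:
            a = a[:, ::bin_xy, ::bin_xy]
        else:
            a = a.reshape(arr.shape[0], ny // bin_xy, bin_xy,
                          nx // bin_xy, bin_xy).mean(axis=(2, 4))
        arr = a
        vy, vx = vy * bin_xy, vx * bin_xy
    target = min(vz, vy, vx)
    zoom = (vz / target, vy / target, vx / target)
    if not np.allclose(zoom, 1.0):
        arr = ndi.zoom(arr, zoom, order=0 if labels else 1, grid_mode=True,
                       mode="grid-constant")
    return arr, target


# ---------------------------------------------------------------------------
# meshes and inertia


def _mesh_from_mask(mask: np.ndarray, voxel_size: float,
                    origin_voxel) -> trimesh.Trimesh:
    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = (verts - 1.0 + np.asarray(origin_voxel)) * voxel_size
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh.fix_normals()
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def extract_meshes(vol: LabelVolume,
                   min_voxels: int = 8) -> tuple[dict, TissueMesh]:
    """Per-cell surface meshes plus the labelled global tissue mesh.

    Marching cubes runs per label on its padded bounding box at the
    physical scale.  The tissue mesh keeps only the largest connected
    component and stores, per vertex, the label of the nearest cell
    voxel.  All meshes are repaired to consistent outward orientation
    (positive signed volume).
    """
    vox = vol.voxels
    cell_meshes: dict[int, trimesh.Trimesh] = {}
    slices = ndi.find_objects(vox)
    for lab in vol.labels():
        sl = slices[lab - 1]
        if sl is None:
            continue
        mask = vox[sl] == lab
        if mask.sum() < min_voxels:
            warnings.warn(f"label {lab}: fewer than {min_voxels} voxels, skipped")
            continue
        origin = [s.start for s in sl]
        cell_meshes[lab] = _mesh_from_mask(mask, vol.voxel_size, origin)

    tissue = _mesh_from_mask(vox > 0, vol.voxel_size, (0, 0, 0))
    parts = tissue.split(only_watertight=False)
    if len(parts) > 1:
        tissue = max(parts, key=lambda m: abs(m.volume))

    # nearest-label lookup for surface vertices
    bg = vox == 0
    _, idx = ndi.distance_transform_edt(bg, return_indices=True)
    near_label = vox[tuple(idx)]
    vidx = np.clip(np.round(tissue.vertices / vol.voxel_size).astype(int),
                   0, np.array(vox.shape) - 1)
    vertex_labels = near_label[tuple(vidx.T)]
    return cell_meshes, TissueMesh(mesh=tissue, vertex_labels=vertex_labels)


def inertia_analysis(mesh: trimesh.Trimesh):
    """Solid-body inertia spectrum and principal axes of a closed mesh.

    Returns ``(lambdas, axes, centroid, volume, area)`` with the inertia
    components sorted ascending and ``axes[i]`` the unit direction for
    ``lambdas[i]`` forming a right-handed triad.  The smallest component
    belongs to the cell's long geometric axis.
    """
    if not mesh.is_watertight:
        trimesh.repair.fill_holes(mesh)
        if not mesh.is_watertight:
            raise ValueError("mesh is not closed; inertia undefined")
    inertia = mesh.moment_inertia
    vals, vecs = np.linalg.eigh(inertia)
    order = np.argsort(vals)
    vals = vals[order]
    axes = vecs[:, order].T
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return (tuple(float(v) for v in vals), axes,
            np.asarray(mesh.center_mass, float),
            float(abs(mesh.volume)), float(mesh.area))


def anisotropy(lambda1: float, lambda2: float, lambda3: float) -> float:
    """Shape anisotropy eta = (lambda3 - sqrt(lambda1 lambda2)) / lambda3."""
    if not (0 < lambda1 <= lambda2 <= lambda3):
        raise ValueError("inertia components must be positive and ascending")
    return float((lambda3 - np.sqrt(lambda1 * lambda2)) / lambda3)


# ---------------------------------------------------------------------------
# polarity and angles


def boundary_normal(label: int, tissue: TissueMesh) -> np.ndarray | None:
    """Mean outward normal of the tissue surface patch of one cell.

    Vertex normals are averaged with dual-area weights: marching-cubes
    surfaces carry more vertices where the surface runs oblique to the
    voxel grid, and an unweighted vertex mean would therefore depend on
    the tissue's orientation relative to the grid.  Returns None when no
    tissue-surface vertex carries this label (an interior cell).
    """
    sel = tissue.vertex_labels == label
    if not np.any(sel):
        return None
    mesh = tissue.mesh
    if not hasattr(tissue, "_vertex_areas"):
        va = np.zeros(len(mesh.vertices))
        fa = mesh.area_faces / 3.0
        for i in range(3):
            np.add.at(va, mesh.faces[:, i], fa)
        tissue._vertex_areas = va
    w = tissue._vertex_areas[sel]
    n = (np.asarray(mesh.vertex_normals)[sel] * w[:, None]).sum(axis=0)
    norm = np.linalg.norm(n)
    if norm == 0:
        return None
    return n / norm


def polarity_vector(major_axis: np.ndarray,
                    cell_centroid: np.ndarray,
                    tissue_centroid: np.ndarray,
                    normal: np.ndarray | None = None) -> np.ndarray:
    """Sign-fix the cell's major axis into a polarity vector.

    Boundary cells (normal given): flipped when opposing the boundary
    normal.  Interior cells: flipped when pointing toward the tissue
    centroid.  An exactly perpendicular axis keeps its original sign.
    """
    v = np.asarray(major_axis, float)
    v = v / np.linalg.norm(v)
    ref = (np.asarray(normal, float) if normal is not None
           else np.asarray(cell_centroid, float) - np.asarray(tissue_centroid, float))
    d = float(np.dot(v, ref))
    if d < 0:
        return -v
    return v


def boundary_angle(polarity: np.ndarray, normal: np.ndarray) -> float:
    """Cell-to-boundary angle in degrees, folded to [0, 90].

    0 deg: polarity parallel to the surface normal (cell perpendicular
    to the boundary surface); 90 deg: cell lying parallel to it.
    """
    p = np.asarray(polarity, float)
    n = np.asarray(normal, float)
    np_, nn = np.linalg.norm(p), np.linalg.norm(n)
    if np_ == 0 or nn == 0:
        raise ValueError("zero vector has no direction")
    c = abs(float(np.dot(p, n)) / (np_ * nn))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def neighbor_angles(vol: LabelVolume,
                    axes: dict[int, np.ndarray],
                    min_overlap: float = 20.0) -> pd.DataFrame:
    """Angles between long axes of adjacent cells.

    Adjacency uses a one-voxel 26-connected dilation of each label; the
    overlap volume (um^3) is the dilated intersection with the
    neighbour, and pairs under ``min_overlap`` are dropped.  Each
    unordered pair appears once with the angle folded to [0, 90] deg.
    """
    vox = vol.voxels
    struct = np.ones((3, 3, 3), bool)
    voxvol = vol.voxel_size**3
    slices = ndi.find_objects(vox)
    rows = {}
    for lab in vol.labels():
        if lab not in axes:
            continue
        sl = slices[lab - 1]
        sl = tuple(slice(max(s.start - 1, 0), min(s.stop + 1, n))
                   for s, n in zip(sl, vox.shape))
        region = vol.voxels[sl]
        dil = ndi.binary_dilation(region == lab, structure=struct)
        over = region[dil & (region != lab) & (region > 0)]
        for other, count in zip(*np.unique(over, return_counts=True)):
            other = int(other)
            if other not in axes:
                continue
            key = (min(int(lab), other), max(int(lab), other))
            rows.setdefault(key, 0.0)
            rows[key] = max(rows[key], count * voxvol)
    out = []
    for (i, j), overlap in sorted(rows.items()):
        if overlap < min_overlap:
            continue
        c = abs(float(np.dot(axes[i], axes[j])))
        ang = float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
        out.append({"label_i": i, "label_j": j, "angle_deg": ang,
                    "overlap_um3": overlap})
    return pd.DataFrame(out, columns=["label_i", "label_j",
                                      "angle_deg", "overlap_um3"])


def determine_axis(ann: AxisAnnotation,
                   tissue_centroid: np.ndarray) -> AxisFrame:
    """Distal-proximal frame from annotation points.

    The rotation axis passes through the tissue centroid and the distal
    tip, oriented tip -> centroid (distal to proximal, frame +z).  The
    0-deg rotation plane contains the axis and the mean transverse-edge
    point (frame +x).  The least-squares plane through the interface
    points is retained for reporting the cap-split height.
    """
    c = np.asarray(tissue_centroid, float)
    axis = c - ann.tip_point
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("tip point coincides with the tissue centroid")
    ez = axis / norm
    edge = ann.edge_points.mean(axis=0) - c
    ex = edge - np.dot(edge, ez) * ez
    if np.linalg.norm(ex) < 1e-12:
        raise ValueError("transverse-edge points lie on the rotation axis")
    ex = ex / np.linalg.norm(ex)
    ey = np.cross(ez, ex)
    R = np.vstack([ex, ey, ez])

    pts = ann.interface_points
    p0 = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - p0)
    plane_normal = vt[-1]
    if np.dot(plane_normal, ez) < 0:
        plane_normal = -plane_normal
    return AxisFrame(origin=c, rotation=R, interface_plane=(p0, plane_normal))


# ---------------------------------------------------------------------------
# pipeline driver


def quantify_cells(vol: LabelVolume,
                   min_voxels: int = 8) -> tuple[pd.DataFrame, dict, TissueMesh]:
    """Full per-cell quantification of a label volume.

    Returns (table, cell_shapes, tissue_mesh); the table has one row per
    cell with volume, area, inertia spectrum, eta, polarity, boundary
    normal and boundary angle (NaN for interior cells).
    """
    meshes, tissue = extract_meshes(vol, min_voxels=min_voxels)
    rows = []
    shapes: dict[int, CellShape] = {}
    for lab, mesh in meshes.items():
        try:
            lam, axes, centroid, volume, area = inertia_analysis(mesh)
        except ValueError as exc:           # unrepairable sliver of a cell
            warnings.warn(f"label {lab}: {exc}; cell skipped")
            continue
        eta = anisotropy(*lam)
        normal = boundary_normal(lab, tissue)
        pol = polarity_vector(axes[0], centroid, tissue.centroid, normal)
        ang = boundary_angle(pol, normal) if normal is not None else np.nan
        shapes[lab] = CellShape(
            label=int(lab), volume=volume, surface_area=area, centroid=centroid,
            inertia=lam, axes=axes, eta=eta,
            touches_boundary=normal is not None,
            boundary_normal=normal, polarity=pol)
        rows.append({
            "label": int(lab), "volume_um3": volume, "area_um2": area,
            "centroid_x": centroid[0], "centroid_y": centroid[1],
            "centroid_z": centroid[2],
            "lambda1": lam[0], "lambda2": lam[1], "lambda3": lam[2],
            "eta": eta,
            "polarity_x": pol[0], "polarity_y": pol[1], "polarity_z": pol[2],
            "normal_x": normal[0] if normal is not None else np.nan,
            "normal_y": normal[1] if normal is not None else np.nan,
            "normal_z": normal[2] if normal is not None else np.nan,
            "boundary_flag": normal is not None,
            "boundary_angle_deg": ang,
        })
    return pd.DataFrame(rows), shapes, tissue
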
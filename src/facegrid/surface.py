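"""Surface reduction: accessible-surface points, residue depth, face
segmentation, and the flattening of each face into binned 2D property grids.

The accessible surface is a Shrake-Rupley point cloud: each heavy atom
contributes quasi-uniform test points on its probe-expanded sphere that are
not occluded by any neighbouring atom's expanded sphere. Residue depth is the
mean over a residue's heavy atoms of the minimum distance to that cloud;
residues shallower than ``depth_cutoff`` define the surface. The surface
atoms are partitioned into ``k`` faces by Lloyd's K-means started from the
six axis-extreme atoms (a deterministic, biased initialization), each face is
projected onto its least-squares (PCA) plane, and the projection is binned
into ``bin_size`` x ``bin_size`` boxes holding the mean property value of the
atoms in each box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io import PROPERTIES, Config, PropertiedStructure

logger = logging.getLogger(__name__)


@dataclass
class SurfaceModel:
    """Accessible-surface point cloud and the depths derived from it."""

    points: np.ndarray                       # (m, 3) surface points
    atom_depths: np.ndarray                  # (n,) min distance to cloud; NaN for H
    residue_depths: dict[tuple[str, str], float]
    surface_atoms: np.ndarray                # heavy-atom indices of surface residues


@dataclass
class FaceSegmentation:
    """Partition of the surface atoms into labelled faces."""

    labels: np.ndarray                       # per-surface-atom face id in 1..k
    centroids: np.ndarray                    # (k, 3)
    initialization: str                      # axis_extremes | axis_extremes_rotated45 | ...


@dataclass
class PlaneBasis:
    origin: np.ndarray                       # (3,) face centroid
    axes: np.ndarray                         # (2, 3) orthonormal in-plane axes


@dataclass
class FaceGrid:
    """One face's binned 2D property matrix plus bin -> atom back-mapping."""

    face_id: int
    property: str
    values: np.ndarray                       # (R, C) bin-averaged property values
    occupancy: np.ndarray                    # (R, C) bool
    bin_atoms: dict[tuple[int, int], list[int]]  # (row, col) -> global atom indices
    bin_size: float
    plane_basis: PlaneBasis

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# Accessible surface and depth


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (Fibonacci spiral)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5 ** 0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.clip(1 - z * z, 0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_surface_points(structure: PropertiedStructure,
                           probe_radius: float = 1.4,
                           n_sphere_points: int = 240) -> np.ndarray:
    """Shrake-Rupley accessible-surface point cloud over the heavy atoms.

    Each heavy atom's sphere of radius ``r_i + probe`` is sampled with
    ``n_sphere_points`` quasi-uniform points; points falling inside any other
    atom's expanded sphere are discarded. Fully buried atoms contribute none.
    """
    heavy = np.flatnonzero(structure.heavy_mask())
    if heavy.size == 0:
        raise ValueError("structure has no heavy atoms")
    xyz = structure.coords()[heavy]
    rad = structure.radii()[heavy] + probe_radius
    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(xyz)
    max_rad = rad.max()
    out: list[np.ndarray] = []
    for i in range(len(heavy)):
        pts = xyz[i] + rad[i] * unit
        neigh = tree.query_ball_point(xyz[i], rad[i] + max_rad)
        keep = np.ones(len(pts), dtype=bool)
        for j in neigh:
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - xyz[j], pts - xyz[j])
            keep &= d2 >= rad[j] ** 2 - 1e-9
        if keep.any():
            out.append(pts[keep])
    if not out:
        raise ValueError("no accessible surface points (fully occluded input?)")
    return np.vstack(out)


def residue_depth(structure: PropertiedStructure, points: np.ndarray,
                  depth_cutoff: float = 5.0) -> SurfaceModel:
    """Depths of atoms/residues from the surface cloud, and surface atoms.

    A residue contributes to the surface when the mean depth of its heavy
    atoms is below ``depth_cutoff``; all heavy atoms of such residues are the
    surface atoms used downstream.
    """
    if len(points) == 0:
        raise ValueError("empty surface point cloud")
    heavy = structure.heavy_mask()
    xyz = structure.coords()
    tree = cKDTree(points)
    atom_depths = np.full(len(structure), np.nan)
    atom_depths[heavy] = tree.query(xyz[heavy])[0]
    res_depths: dict[tuple[str, str], float] = {}
    surface: list[int] = []
    for key, idx in structure.residue_index.items():
        hidx = [i for i in idx if heavy[i]]
        if not hidx:
            continue
        d = float(np.mean(atom_depths[hidx]))
        res_depths[key] = d
        if d < depth_cutoff:
            surface.extend(hidx)
    return SurfaceModel(points=points, atom_depths=atom_depths,
                        residue_depths=res_depths,
                        surface_atoms=np.array(sorted(surface), dtype=int))


# ---------------------------------------------------------------------------
# Rigid orientation


def _heavy_centroid(structure: PropertiedStructure) -> np.ndarray:
    xyz = structure.coords()[structure.heavy_mask()]
    return xyz.mean(axis=0)


def orient_pca(structure: PropertiedStructure) -> PropertiedStructure:
    """Rotate so the heavy-atom principal axes align with x, y, z.

    Axes are ordered by decreasing variance; the centroid moves to the
    origin. The transform is rigid (det +1 rotation).
    """
    heavy = structure.heavy_mask()
    xyz = structure.coords()
    center = xyz[heavy].mean(axis=0)
    centered = xyz[heavy] - center
    cov = centered.T @ centered / max(len(centered) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] <= 1e-12 * max(evals[0], 1.0):
        raise ValueError("degenerate (collinear) atom cloud")
    if np.linalg.det(evecs) < 0:
        evecs[:, 2] = -evecs[:, 2]
    return structure.with_coords((xyz - center) @ evecs)


def rotation_matrix_xy(angle_x_deg: float, angle_y_deg: float) -> np.ndarray:
    ax, ay = np.radians([angle_x_deg, angle_y_deg])
    rx = np.array([[1, 0, 0],
                   [0, np.cos(ax), -np.sin(ax)],
                   [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)],
                   [0, 1, 0],
                   [-np.sin(ay), 0, np.cos(ay)]])
    return ry @ rx


def rotate_structure(structure: PropertiedStructure, angle_x_deg: float,
                     angle_y_deg: float) -> PropertiedStructure:
    """Right-handed rotation about x then y, about the heavy-atom centroid."""
    rot = rotation_matrix_xy(angle_x_deg, angle_y_deg)
    xyz = structure.coords()
    center = _heavy_centroid(structure)
    return structure.with_coords((xyz - center) @ rot.T + center)


# ---------------------------------------------------------------------------
# Face segmentation (biased K-means)


def biased_axis_extreme_seeds(coords: np.ndarray, k: int) -> np.ndarray:
    """Seed centroids at the atoms attaining max/min x, y, z (ties: lowest index)."""
    seeds = []
    for axis in range(3):
        seeds.append(int(np.argmax(coords[:, axis])))
        seeds.append(int(np.argmin(coords[:, axis])))
    if k > len(seeds):  # farthest-point extension beyond the six extremes
        chosen = list(dict.fromkeys(seeds))
        while len(chosen) < k:
            d = np.min(np.linalg.norm(coords[:, None, :] - coords[chosen][None], axis=2), axis=1)
            chosen.append(int(np.argmax(d)))
        return coords[chosen[:k]].copy()
    return coords[seeds[:k]].copy()


def biased_kmeans_faces(coords: np.ndarray, k: int = 6,
                        max_iter: int = 300,
                        initialization: str = "axis_extremes") -> FaceSegmentation:
    """Lloyd's K-means from the axis-extreme biased seeds.

    Deterministic: Euclidean metric, label-stability convergence, ties to the
    lowest face label, empty faces repaired by re-seeding with the point
    farthest from its centroid.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < k:
        raise ValueError(f"need at least {k} surface atoms, got {len(coords)}")
    if len(np.unique(coords, axis=0)) < k:
        raise ValueError("degenerate coordinates: fewer distinct points than faces")
    centroids = biased_axis_extreme_seeds(coords, k)
    labels = np.full(len(coords), -1)
    for _ in range(max_iter):
        d = np.linalg.norm(coords[:, None, :] - centroids[None], axis=2)
        new_labels = np.argmin(d, axis=1)  # argmin ties -> lowest label
        for face in range(k):
            if not np.any(new_labels == face):  # empty-cluster repair
                far = int(np.argmax(d[np.arange(len(coords)), new_labels]))
                new_labels[far] = face
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for face in range(k):
            centroids[face] = coords[labels == face].mean(axis=0)
    return FaceSegmentation(labels=labels + 1, centroids=centroids,
                            initialization=initialization)


# ---------------------------------------------------------------------------
# Projection and gridding


def project_face(face_coords: np.ndarray) -> tuple[np.ndarray, PlaneBasis]:
    """Project a face's atoms onto its least-squares (PCA) plane.

    Å units are preserved, so the projected extent is proportional to the
    cluster extent. Axis signs are fixed by making the skewness of each
    projected coordinate non-negative (determinism under reflection).
    """
    face_coords = np.asarray(face_coords, dtype=float)
    origin = face_coords.mean(axis=0)
    centered = face_coords - origin
    if len(face_coords) == 1:
        axes = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        return np.zeros((1, 2)), PlaneBasis(origin=origin, axes=axes)
    cov = centered.T @ centered
    _, evecs = np.linalg.eigh(cov)
    axes = evecs[:, ::-1][:, :2].T            # top-2 principal axes, rows
    xy = centered @ axes.T
    for j in range(2):                        # deterministic sign convention
        c = xy[:, j]
        skew = np.mean((c - c.mean()) ** 3)
        if skew < -1e-12:
            axes[j] = -axes[j]
            xy[:, j] = -xy[:, j]
    return xy, PlaneBasis(origin=origin, axes=axes)


def grid_face(face_xy: np.ndarray, atom_indices: Sequence[int],
              prop_values: np.ndarray, bin_size: float,
              face_id: int = 0, property_name: str = "",
              plane_basis: PlaneBasis | None = None) -> FaceGrid:
    """Bin a face's projected atoms into ``bin_size`` boxes of mean property.

    The grid spans [min, max] of the projected coordinates in half-open bins
    anchored at the min corner (the max coordinate falls in the last bin).
    Unoccupied bins hold 0; ``prop_values`` are per-atom and must be finite.
    """
    face_xy = np.asarray(face_xy, dtype=float)
    prop_values = np.asarray(prop_values, dtype=float)
    if np.isnan(prop_values).any():
        raise ValueError(f"property {property_name!r} absent on some face atoms")
    lo = face_xy.min(axis=0)
    extent = face_xy.max(axis=0) - lo
    nbins = np.maximum(np.ceil(extent / bin_size - 1e-9).astype(int), 1)
    idx = np.floor((face_xy - lo) / bin_size).astype(int)
    idx = np.minimum(idx, nbins - 1)
    values = np.zeros(tuple(nbins))
    counts = np.zeros(tuple(nbins))
    bin_atoms: dict[tuple[int, int], list[int]] = {}
    for (r, c), gidx, v in zip(idx, atom_indices, prop_values):
        values[r, c] += v
        counts[r, c] += 1
        bin_atoms.setdefault((int(r), int(c)), []).append(int(gidx))
    occupancy = counts > 0
    values[occupancy] /= counts[occupancy]
    return FaceGrid(face_id=face_id, property=property_name, values=values,
                    occupancy=occupancy, bin_atoms=bin_atoms, bin_size=bin_size,
                    plane_basis=plane_basis or PlaneBasis(np.zeros(3), np.eye(3)[:2]))


def property_grid_values(structure: PropertiedStructure, prop: str,
                         center_conservation: bool = True) -> np.ndarray:
    """Per-atom values used for gridding; conservation optionally centered.

    Grades are shifted to ``grade - 5`` so that 0 is neutral (empty bins hold
    0, which must not masquerade as a real signal).
    """
    vals = structure.property_values(prop)
    if prop == "conservation" and center_conservation:
        vals = vals - 5.0
    return vals


def build_face_grids(structure: PropertiedStructure, seg: FaceSegmentation,
                     surface_atoms: np.ndarray, properties: Sequence[str],
                     config: Config) -> dict[str, list[FaceGrid]]:
    """Project and grid every face for each requested property.

    Returns ``{property: [FaceGrid for face 1..k]}``; every face atom lands in
    exactly one bin of exactly one face.
    """
    xyz = structure.coords()
    k = int(seg.labels.max())
    prop_vals = {p: property_grid_values(structure, p, config.center_conservation)
                 for p in properties}
    grids: dict[str, list[FaceGrid]] = {p: [] for p in properties}
    for face in range(1, k + 1):
        members = surface_atoms[seg.labels == face]
        xy, basis = project_face(xyz[members])
        for p in properties:
            vals = prop_vals[p][members]
            if np.isnan(vals).any():
                missing = members[np.isnan(vals)][:5]
                raise ValueError(
                    f"property {p!r} absent on face {face} atoms "
                    f"(e.g. indices {missing.tolist()}) of {structure.label}")
            grids[p].append(grid_face(xy, members, vals, config.bin_size,
                                      face_id=face, property_name=p,
                                      plane_basis=basis))
    return grids


# ---------------------------------------------------------------------------
# Exports for inspection


def save_grid_txt(grid: FaceGrid, path: str | Path) -> None:
    header = f"face {grid.face_id} property {grid.property} bin_size {grid.bin_size}"
    np.savetxt(path, grid.values, header=header, fmt="%.6g")


def save_grid_image(grid: FaceGrid, path: str | Path) -> None:
    """Render a face grid to an image file (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    vmax = max(np.abs(grid.values).max(), 1e-12)
    im = ax.imshow(grid.values, cmap="coolwarm", vmin=-vmax, vmax=vmax)
    ax.set_title(f"face {grid.face_id} — {grid.property}")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def save_points_xyz(points: np.ndarray, path: str | Path, element: str = "He") -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(points)}\naccessible surface points\n")
        for p in points:
            fh.write(f"{element} {p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")
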
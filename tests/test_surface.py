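import numpy as np
import pytest

import facegrid as fg
from facegrid.io import AtomRecord, PropertiedStructure
from facegrid.surface import (PlaneBasis, biased_axis_extreme_seeds, grid_face,
                              project_face, property_grid_values)


def _structure_from_points(points, radius=1.6, residue_of=None, label="pts"):
    atoms = []
    for i, p in enumerate(points):
        res = residue_of(i) if residue_of else i + 1
        atoms.append(AtomRecord(serial=i + 1, atom_name=f"C{i % 9}",
                                residue_name="ALA", chain_id="A",
                                residue_seq=res, icode="",
                                x=float(p[0]), y=float(p[1]), z=float(p[2]),
                                element="C", radius=radius, charge=0.0))
    return PropertiedStructure(label, atoms)


def _fib_sphere(n):
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5 ** 0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(1 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


# ---------------------------------------------------------------------------
# Accessible surface points


def test_single_atom_full_sphere():
    st = _structure_from_points([[0, 0, 0]], radius=1.6)
    pts = fg.compute_surface_points(st, probe_radius=1.4, n_sphere_points=100)
    assert len(pts) == 100
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 3.0, atol=1e-12)


def test_two_distant_atoms_fully_exposed():
    st = _structure_from_points([[0, 0, 0], [100, 0, 0]])
    pts = fg.compute_surface_points(st, n_sphere_points=60)
    assert len(pts) == 120


def test_caged_atom_contributes_nothing():
    """An atom inside a tight icosahedral cage is fully occluded."""
    phi = (1 + 5 ** 0.5) / 2
    ico = np.array([[0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
                    [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
                    [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1]],
                   dtype=float)
    ico *= 3.0 / np.linalg.norm(ico[0])
    coords = np.vstack([[0.0, 0.0, 0.0], ico])
    st = _structure_from_points(coords, radius=1.6)
    pts = fg.compute_surface_points(st, probe_radius=1.4, n_sphere_points=200)
    # brute-force oracle: any point of the center atom's expanded sphere
    # within another atom's expanded sphere must have been dropped
    center_pts = pts[np.linalg.norm(pts, axis=1) < 3.0 + 1e-9]
    for p in center_pts:
        assert np.all(np.linalg.norm(p - ico, axis=1) >= 3.0 - 1e-9)
    # and in this geometry every center point is occluded
    assert len(center_pts) == 0


def test_no_heavy_atoms_errors():
    st = _structure_from_points([[0, 0, 0]])
    st.atoms[0].is_hydrogen = True
    with pytest.raises(ValueError):
        fg.compute_surface_points(st)


# ---------------------------------------------------------------------------
# Residue depth


def test_atom_on_surface_has_zero_depth():
    st = _structure_from_points([[0, 0, 0]])
    pts = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
    model = fg.residue_depth(st, pts)
    assert model.atom_depths[0] == 0.0
    assert len(model.surface_atoms) == 1  # single residue trivially surface


def test_concentric_shells_bury_inner_residues():
    """Residues on inner shells sit deeper than the 5 A cutoff.

    Shell spacing stays below the probe-accessible gap so no interior cavity
    surface forms and the only accessible surface is the outer shell's.
    """
    shells = [(2.0, 32, 1), (6.5, 128, 2), (11.0, 256, 3)]
    coords, res = [], []
    for radius, n, resid in shells:
        coords.append(_fib_sphere(n) * radius)
        res.extend([resid] * n)
    coords = np.vstack(coords)
    st = _structure_from_points(coords, radius=1.7,
                                residue_of=lambda i: res[i])
    pts = fg.compute_surface_points(st, n_sphere_points=120)
    model = fg.residue_depth(st, pts, depth_cutoff=5.0)
    depths = model.residue_depths
    assert depths[("A", "1")] > 5.0          # innermost excluded
    assert depths[("A", "3")] < 5.0          # outer shell is surface
    surface_res = {st.residue_of(i) for i in model.surface_atoms}
    assert ("A", "1") not in surface_res and ("A", "3") in surface_res


def test_depth_monotonic_under_distant_atom(blob):
    pts = fg.compute_surface_points(blob, n_sphere_points=60)
    base = fg.residue_depth(blob, pts)
    far = _structure_from_points([[500.0, 0, 0]])
    extra = fg.compute_surface_points(far, n_sphere_points=60)
    grown = fg.residue_depth(blob, np.vstack([pts, extra]))
    assert np.all(grown.atom_depths <= base.atom_depths + 1e-12)


# ---------------------------------------------------------------------------
# Rigid orientation


def test_orient_pca_aligns_and_preserves_distances():
    rng = np.random.default_rng(0)
    cloud = rng.normal(size=(80, 3)) * [8.0, 4.0, 2.0]
    st = _structure_from_points(cloud)
    aligned = fg.orient_pca(st)
    var = aligned.coords().var(axis=0)
    assert var[0] > var[1] > var[2]
    d0 = np.linalg.norm(cloud[:, None] - cloud[None], axis=2)
    c1 = aligned.coords()
    d1 = np.linalg.norm(c1[:, None] - c1[None], axis=2)
    np.testing.assert_allclose(d1, d0, atol=1e-9)
    np.testing.assert_allclose(c1.mean(axis=0), 0.0, atol=1e-9)


def test_orient_pca_rotation_invariant_spectrum():
    rng = np.random.default_rng(1)
    cloud = rng.normal(size=(60, 3)) * [8.0, 4.0, 2.0]
    st = fg.orient_pca(_structure_from_points(cloud))
    rot = fg.rotate_structure(_structure_from_points(cloud), 0.0, 30.0)
    st2 = fg.orient_pca(rot)
    np.testing.assert_allclose(st2.coords().var(axis=0),
                               st.coords().var(axis=0), rtol=1e-9)


def test_orient_pca_collinear_errors():
    st = _structure_from_points([[i, 0, 0] for i in range(5)])
    with pytest.raises(ValueError, match="collinear"):
        fg.orient_pca(st)


@pytest.mark.parametrize("angles", [(0, 0), (360, 360)])
def test_rotate_structure_identity(blob, angles):
    rot = fg.rotate_structure(blob, *angles)
    np.testing.assert_allclose(rot.coords(), blob.coords(), atol=1e-9)


def test_rotate_structure_y90_maps_x_to_minus_z():
    st = _structure_from_points([[1, 0, 0], [-1, 0, 0]])  # centroid at origin
    rot = fg.rotate_structure(st, 0.0, 90.0)
    np.testing.assert_allclose(rot.coords()[0], [0, 0, -1], atol=1e-12)


# ---------------------------------------------------------------------------
# Face segmentation


def test_biased_seeds_are_axis_extremes():
    rng = np.random.default_rng(2)
    coords = rng.normal(size=(50, 3)) * 10
    seeds = biased_axis_extreme_seeds(coords, 6)
    assert seeds[0, 0] == coords[:, 0].max()
    assert seeds[1, 0] == coords[:, 0].min()
    assert seeds[4, 2] == coords[:, 2].max()


def test_kmeans_six_blobs_against_sklearn():
    """Six tight blobs at the axis poles: one face per blob, matching sklearn."""
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(3)
    centers = np.array([[20, 0, 0], [-20, 0, 0], [0, 20, 0],
                        [0, -20, 0], [0, 0, 20], [0, 0, -20]], dtype=float)
    coords = np.vstack([c + rng.normal(0, 1.0, (15, 3)) for c in centers])
    seg = fg.biased_kmeans_faces(coords, k=6)
    labels = seg.labels.reshape(6, 15)
    assert all(len(set(row)) == 1 for row in labels)
    assert len({row[0] for row in labels}) == 6
    # brute-force nearest-centroid check at convergence
    d = np.linalg.norm(coords[:, None] - seg.centroids[None], axis=2)
    np.testing.assert_array_equal(np.argmin(d, axis=1) + 1, seg.labels)
    # sklearn from the same biased seeds converges to the same partition
    sk = KMeans(n_clusters=6, init=biased_axis_extreme_seeds(coords, 6),
                n_init=1, max_iter=300).fit(coords)
    for face in range(6):
        ours = set(np.flatnonzero(seg.labels == face + 1))
        theirs = set(np.flatnonzero(sk.labels_ == face))
        assert ours == theirs


def test_kmeans_k1_single_face(blob):
    seg = fg.biased_kmeans_faces(blob.coords(), k=1)
    assert set(seg.labels) == {1}


def test_kmeans_degenerate_input_errors():
    coords = np.zeros((10, 3))
    with pytest.raises(ValueError):
        fg.biased_kmeans_faces(coords, k=6)
    with pytest.raises(ValueError):
        fg.biased_kmeans_faces(np.zeros((3, 3)), k=6)  # fewer atoms than faces


def test_kmeans_partition_covers_all_atoms(blob):
    pts = fg.compute_surface_points(blob, n_sphere_points=60)
    model = fg.residue_depth(blob, pts)
    coords = blob.coords()[model.surface_atoms]
    seg = fg.biased_kmeans_faces(coords, k=6)
    assert len(seg.labels) == len(model.surface_atoms)
    sizes = np.bincount(seg.labels)[1:]
    assert sizes.sum() == len(model.surface_atoms)
    assert np.all(sizes > 0)


# ---------------------------------------------------------------------------
# Projection and gridding


def test_project_coplanar_face_preserves_distances():
    rng = np.random.default_rng(4)
    xy = rng.normal(size=(30, 2)) * 5
    coords = np.column_stack([xy, np.full(30, 3.0)])
    proj, basis = project_face(coords)
    d0 = np.linalg.norm(xy[:, None] - xy[None], axis=2)
    d1 = np.linalg.norm(proj[:, None] - proj[None], axis=2)
    np.testing.assert_allclose(d1, d0, atol=1e-9)


def test_project_hemispherical_cap_extent():
    r = 10.0
    pts = _fib_sphere(400) * r
    cap = pts[pts[:, 2] > 0]
    proj, _ = project_face(cap)
    radial = np.linalg.norm(proj, axis=1).max()
    assert r / 2 < radial <= r * 1.01  # PCA plane tilt from finite sampling


def test_project_translation_invariant():
    rng = np.random.default_rng(5)
    coords = rng.normal(size=(20, 3))
    p1, _ = project_face(coords)
    p2, _ = project_face(coords + [100.0, -50.0, 7.0])
    np.testing.assert_allclose(p1, p2, atol=1e-9)


def test_project_single_atom_face():
    proj, basis = project_face(np.array([[1.0, 2.0, 3.0]]))
    np.testing.assert_array_equal(proj, [[0.0, 0.0]])


def test_grid_face_adjacent_bins_and_mean():
    xy = np.array([[0.0, 0.0], [7.0, 0.0]])
    g = grid_face(xy, [10, 11], np.array([1.0, 0.0]), bin_size=5.0)
    assert g.values.shape == (2, 1)
    assert g.bin_atoms == {(0, 0): [10], (1, 0): [11]}
    g2 = grid_face(np.zeros((2, 2)), [0, 1], np.array([1.0, 0.0]), bin_size=5.0)
    assert g2.values[0, 0] == pytest.approx(0.5)


def test_grid_face_mass_conservation():
    rng = np.random.default_rng(6)
    xy = rng.uniform(-20, 20, size=(50, 2))
    vals = rng.normal(size=50)
    g = grid_face(xy, list(range(50)), vals, bin_size=5.0)
    total = sum(g.values[rc] * len(atoms) for rc, atoms in g.bin_atoms.items())
    assert total == pytest.approx(vals.sum())
    members = sorted(i for atoms in g.bin_atoms.values() for i in atoms)
    assert members == list(range(50))  # each atom in exactly one bin
    assert np.all(g.values[~g.occupancy] == 0)


def test_grid_face_missing_property_errors():
    with pytest.raises(ValueError, match="charge"):
        grid_face(np.zeros((2, 2)), [0, 1], np.array([1.0, np.nan]),
                  bin_size=5.0, property_name="charge")


def test_conservation_values_are_centered(blob):
    grades = {k: 9 for k in blob.residue_index}
    st = fg.apply_conservation(blob, grades)
    vals = property_grid_values(st, "conservation", center_conservation=True)
    np.testing.assert_array_equal(vals, 4.0)
    raw = property_grid_values(st, "conservation", center_conservation=False)
    np.testing.assert_array_equal(raw, 9.0)


def test_pipeline_translation_invariance(charged_pair):
    """Rigid translation leaves surface selection, faces and grids unchanged."""
    a = charged_pair[0]
    cfg = fg.Config()
    shifted = a.with_coords(a.coords() + [37.0, -11.0, 5.0])
    for st1, st2 in ((a, shifted),):
        p1 = fg.compute_surface_points(st1, n_sphere_points=60)
        p2 = fg.compute_surface_points(st2, n_sphere_points=60)
        m1 = fg.residue_depth(st1, p1)
        m2 = fg.residue_depth(st2, p2)
        np.testing.assert_array_equal(m1.surface_atoms, m2.surface_atoms)
        s1 = fg.biased_kmeans_faces(st1.coords()[m1.surface_atoms], 6)
        s2 = fg.biased_kmeans_faces(st2.coords()[m2.surface_atoms], 6)
        np.testing.assert_array_equal(s1.labels, s2.labels)
        g1 = fg.build_face_grids(st1, s1, m1.surface_atoms, ["charge"], cfg)
        g2 = fg.build_face_grids(st2, s2, m2.surface_atoms, ["charge"], cfg)
        for a_grid, b_grid in zip(g1["charge"], g2["charge"]):
            np.testing.assert_allclose(a_grid.values, b_grid.values, atol=1e-9)


def test_face_grids_partition_face_atoms(charge_prediction):
    """Every surface atom appears in exactly one bin of exactly one face."""
    for prepared in (charge_prediction.prepared_a, charge_prediction.prepared_b):
        for init in prepared.inits.values():
            seen = []
            for grid in init.grids["charge"]:
                for atoms in grid.bin_atoms.values():
                    seen.extend(atoms)
            assert sorted(seen) == sorted(prepared.surface.surface_atoms.tolist())
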
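"""Synthetic structure generation for end-to-end testing of the pipeline.

Generates toy "proteins" — pseudo-atoms grouped into contiguous residues on
the surface of a sphere, ellipsoid or two-lobed blob — poses two of them in
contact, engineers complementary +1/−1 charge patches on the true contact
interface (the proof-of-concept construction for a complex whose interaction
basis is known), and applies smooth low-frequency coordinate distortions at
a controlled Cα-equivalent RMSD to emulate homology-model uncertainty.

Everything is bit-reproducible from (spec, seed). Residues are written as
alanine so the hydrophobicity and conservation code paths run unmodified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (AtomRecord, PropertiedStructure, write_conservation, write_pdb,
                 write_pqr)
from .significance import true_interface

logger = logging.getLogger(__name__)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic blob protein."""

    n_residues: int = 64
    atoms_per_residue: int = 4
    shape: str = "sphere"            # sphere | ellipsoid | two_blob
    radius: float = 10.0             # Å
    patch_fraction: float = 0.15     # planted-patch size as residue fraction
    patch_contrast: float = 1.0      # planted property amplitude
    seed: int = 0
    jitter: float = 0.5              # Å, per-atom scatter around residue centers
    atom_radius: float = 1.7         # Å, pseudo-atom van der Waals radius

    def validate(self) -> "FixtureSpec":
        if not 0 < self.patch_fraction < 1:
            raise ValueError("patch_fraction must be in (0, 1)")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.shape not in ("sphere", "ellipsoid", "two_blob"):
            raise ValueError(f"unknown shape {self.shape!r}")
        return self


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5 ** 0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.clip(1 - z * z, 0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_blob_protein(spec: FixtureSpec, label: str = "blob", chain_id: str = "A",
                      center: tuple[float, float, float] = (0.0, 0.0, 0.0)
                      ) -> PropertiedStructure:
    """Pseudo-atoms quasi-uniform on the shape surface, in contiguous residues.

    Residue centers sit on a Fibonacci lattice over the surface; each
    residue's atoms scatter around its center with seeded Gaussian jitter, so
    residues are spatially contiguous. Charges default to 0, radii to
    ``spec.atom_radius``; deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    unit = _fibonacci_sphere(spec.n_residues)
    if spec.shape == "sphere":
        centers = unit * spec.radius
    elif spec.shape == "ellipsoid":
        centers = unit * (spec.radius * np.array([1.0, 0.8, 0.6]))
    else:  # two_blob: two offset spherical lobes
        half = spec.n_residues // 2
        lobe = spec.radius * 0.75
        c1 = _fibonacci_sphere(half) * lobe + [-0.6 * spec.radius, 0, 0]
        c2 = _fibonacci_sphere(spec.n_residues - half) * lobe + [0.6 * spec.radius, 0, 0]
        centers = np.vstack([c1, c2])
    atoms: list[AtomRecord] = []
    serial = 1
    for ri, c in enumerate(centers, start=1):
        for ai in range(spec.atoms_per_residue):
            pos = c + rng.normal(0.0, spec.jitter, 3) + np.asarray(center)
            atoms.append(AtomRecord(
                serial=serial, atom_name=f"C{ai + 1}", residue_name="ALA",
                chain_id=chain_id, residue_seq=ri, icode="",
                x=float(pos[0]), y=float(pos[1]), z=float(pos[2]),
                element="C", radius=spec.atom_radius, charge=0.0,
                is_hydrogen=False))
            serial += 1
    return PropertiedStructure(label, atoms)


def make_contact_pair(spec_a: FixtureSpec, spec_b: FixtureSpec | None = None,
                      gap: float = 1.0
                      ) -> tuple[PropertiedStructure, PropertiedStructure]:
    """Two blob proteins posed in contact along +x with surface gap ``gap`` Å.

    B is translated so that its minimum x coordinate sits ``gap`` beyond A's
    maximum, so the closest atom pair is roughly ``gap`` apart.
    """
    if spec_b is None:
        spec_b = FixtureSpec(**{**spec_a.__dict__, "seed": spec_a.seed + 10_000})
    a = make_blob_protein(spec_a, label="partner_a", chain_id="A")
    b = make_blob_protein(spec_b, label="partner_b", chain_id="B")
    shift = a.coords()[:, 0].max() + gap - b.coords()[:, 0].min()
    xyz_b = b.coords()
    xyz_b[:, 0] += shift
    return a, b.with_coords(xyz_b)


def engineer_charge_interface(struct_a: PropertiedStructure,
                              struct_b: PropertiedStructure,
                              contact_cutoff: float = 5.0
                              ) -> tuple[PropertiedStructure, PropertiedStructure,
                                         set[tuple[str, str]], set[tuple[str, str]]]:
    """Plant complementary charges on the true contact interface.

    Atoms of A within ``contact_cutoff`` of any B atom get charge +1, the
    matching atoms of B get −1, everything else 0 — the proof-of-concept
    construction for a complex whose binding is known to be charge-driven.
    Returns the modified structures and the ground-truth residue sets.
    """
    from scipy.spatial import cKDTree

    res_a, res_b = true_interface(struct_a, struct_b, contact_cutoff)
    if not res_a or not res_b:
        raise ValueError(f"no contacts within {contact_cutoff} Å; cannot "
                         "engineer an interface")
    out = []
    for s, t, sign in ((struct_a, struct_b, +1.0), (struct_b, struct_a, -1.0)):
        mod = s.copy()
        tree = cKDTree(t.coords()[t.heavy_mask()])
        d, _ = tree.query(mod.coords(), distance_upper_bound=contact_cutoff)
        for atom, di in zip(mod.atoms, d):
            atom.charge = sign if di < contact_cutoff else 0.0
        out.append(mod)
    return out[0], out[1], res_a, res_b


def perturb_structure(structure: PropertiedStructure, target_rmsd: float,
                      seed: int = 0, n_modes: int = 3) -> PropertiedStructure:
    """Smooth low-frequency distortion at an exact Cα-equivalent RMSD.

    The displacement field is a sum of ``n_modes`` seeded long-wavelength
    sinusoidal modes of the coordinates (wavelength twice the structure
    diameter), rescaled so the RMSD over the first atom of each residue —
    the Cα stand-in — equals ``target_rmsd``. Topology and residue
    identities are unchanged; ``target_rmsd=0`` returns an identical copy.
    """
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be >= 0")
    if target_rmsd == 0:
        return structure.copy()
    rng = np.random.default_rng(seed)
    xyz = structure.coords()
    centered = xyz - xyz.mean(axis=0)
    diameter = max(np.ptp(centered, axis=0).max(), 1e-6)
    wavelength = 2.0 * diameter
    disp = np.zeros_like(xyz)
    for _ in range(n_modes):
        k_dir = rng.normal(size=3)
        k_dir /= np.linalg.norm(k_dir)
        u_dir = rng.normal(size=3)
        u_dir /= np.linalg.norm(u_dir)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        phases = 2 * np.pi * (centered @ k_dir) / wavelength + phase
        disp += amp * np.sin(phases)[:, None] * u_dir
    first_atoms = np.array([idx[0] for idx in structure.residue_index.values()])
    rmsd0 = np.sqrt(np.mean(np.sum(disp[first_atoms] ** 2, axis=1)))
    if rmsd0 < 1e-12:
        raise ValueError("degenerate displacement field")
    disp *= target_rmsd / rmsd0
    return structure.with_coords(xyz + disp)


def write_fixture_files(structure: PropertiedStructure, directory: str | Path,
                        conservation: dict[tuple[str, str], int] | None = None
                        ) -> dict[str, Path]:
    """Write the standard PDB + PQR (+ conservation) files for a fixture."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "pdb": directory / f"{structure.label}.pdb",
        "pqr": directory / f"{structure.label}.pqr",
    }
    write_pdb(structure, paths["pdb"])
    write_pqr(structure, paths["pqr"])
    if conservation is not None:
        paths["consurf"] = directory / f"{structure.label}.grades.tsv"
        write_conservation(conservation, paths["consurf"])
    return paths


def patch_conservation_grades(structure: PropertiedStructure,
                              patch_residues: set[tuple[str, str]],
                              patch_grade: int = 9, background_grade: int = 5
                              ) -> dict[tuple[str, str], int]:
    """Grades with a conserved patch on the given residues, neutral elsewhere."""
    return {key: (patch_grade if key in patch_residues else background_grade)
            for key in structure.residue_index}
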
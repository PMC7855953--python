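"""Structure input/output and property annotation.

Reads the three input kinds of the pipeline — atomic coordinates (PDB),
per-atom charge/radius (PQR, as produced by PDB2PQR-style tools) and
per-residue evolutionary conservation grades (ConSurf-style tables) — and
merges them into a single :class:`PropertiedStructure` whose atoms carry
charge, hydrophobicity and conservation alongside their coordinates.

Hydrophobicity is assigned per residue from the Wimley-White *interfacial*
scale (water -> POPC bilayer interface transfer free energies, kcal/mol;
Wimley & White, Nat Struct Biol 1996). Negative values mark residues that
favour a hydrophobic environment. Charged side-chain forms are used for
Asp/Glu/Lys/Arg and neutral His.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

PROPERTIES = ("charge", "hydrophobicity", "conservation")

#: Wimley-White interfacial hydrophobicity scale, kcal/mol.
#: Charged forms for D/E/K/R; neutral His.
WIMLEY_WHITE_INTERFACE = {
    "ALA": 0.17, "ARG": 0.81, "ASN": 0.42, "ASP": 1.23, "CYS": -0.24,
    "GLN": 0.58, "GLU": 2.02, "GLY": 0.01, "HIS": 0.17, "ILE": -0.31,
    "LEU": -0.56, "LYS": 0.99, "MET": -0.23, "PHE": -1.13, "PRO": 0.45,
    "SER": 0.13, "THR": 0.14, "TRP": -1.85, "TYR": -0.94, "VAL": 0.07,
}

#: Fallback van der Waals radii (Å) by element, applied when no PQR is given.
DEFAULT_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS_FALLBACK = 1.70


class StructureError(ValueError):
    """Raised on malformed or empty structure inputs."""


@dataclass
class Config:
    """Pipeline parameters.

    All lengths in Å, angles in degrees. Defaults are the method's
    published operating point.
    """

    probe_radius: float = 1.4          # water probe radius for the accessible surface
    n_sphere_points: int = 240         # quasi-uniform test points per atom sphere
    depth_cutoff: float = 5.0          # residue depth below which a residue is "surface"
    bin_size: float = 5.0              # grid box edge for the 2D face grids
    k_faces: int = 6                   # number of K-means faces
    rotation_step_deg: int = 10        # in-plane rotation sampling of partner grids
    reinit_angles_deg: tuple[float, float] = (45.0, 45.0)  # x,y re-initialization rotation
    top_m: int = 10                    # hits used for init selection + consistency rule
    min_overlap_bins: int = 4          # minimum co-occupied cells for a scored lag
    n_shuffles: int = 1000             # permutation replicates for the extreme-value test
    interface_cutoff: float = 5.0      # heavy-atom distance defining a true interface residue
    rng_seed: int = 0
    use_pca_orientation: bool = False
    antibody_mode: bool = False
    property_order: tuple[str, ...] = ("charge", "conservation", "hydrophobicity")
    center_conservation: bool = True   # grid grade-5 instead of raw 1..9 grades
    p_value_plus_one: bool = False     # (k+1)/(n+1) small-sample correction
    pooled_evaluation: bool = False    # pool partners instead of macro-averaging

    def validate(self) -> "Config":
        if self.probe_radius <= 0 or self.depth_cutoff <= 0 or self.bin_size <= 0 \
                or self.interface_cutoff <= 0:
            raise ValueError("all lengths must be > 0")
        if 360 % self.rotation_step_deg != 0:
            raise ValueError("360 must be divisible by rotation_step_deg")
        if self.top_m < 1:
            raise ValueError("top_m must be >= 1")
        if self.k_faces < 1:
            raise ValueError("k_faces must be >= 1")
        unknown = set(self.property_order) - set(PROPERTIES)
        if unknown:
            raise ValueError(f"unknown properties in property_order: {sorted(unknown)}")
        return self


@dataclass
class AtomRecord:
    """One atom with coordinates and optional mapped surface properties.

    ``radius``/``charge`` come from a PQR file, ``hydrophobicity`` from the
    Wimley-White assignment and ``conservation`` from a ConSurf-style grade
    file; each is ``None`` until the corresponding source has been merged.
    """

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    icode: str
    x: float
    y: float
    z: float
    element: str = ""
    radius: float | None = None
    charge: float | None = None
    hydrophobicity: float | None = None
    conservation: int | None = None
    is_hydrogen: bool = False

    def residue_key(self) -> tuple[str, str]:
        """Author-numbering residue key; insertion code folded into the seq."""
        return (self.chain_id, f"{self.residue_seq}{self.icode}".strip())

    def validate(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise StructureError(f"non-finite coordinates on atom {self.serial}")
        if self.radius is not None and self.radius <= 0:
            raise StructureError(f"non-positive radius on atom {self.serial}")
        if self.conservation is not None and self.conservation not in range(1, 10):
            raise StructureError(
                f"conservation grade {self.conservation} outside 1..9 on atom {self.serial}")


class PropertiedStructure:
    """An ordered collection of :class:`AtomRecord` with a residue index.

    Atom order is stable across all operations; geometric transforms return
    new structures and never mutate in place.
    """

    def __init__(self, label: str, atoms: Sequence[AtomRecord]):
        self.label = label
        self.atoms: list[AtomRecord] = list(atoms)
        for a in self.atoms:
            a.validate()
        self.residue_index: dict[tuple[str, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            self.residue_index.setdefault(a.residue_key(), []).append(i)

    # -- array views -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def heavy_mask(self) -> np.ndarray:
        return np.array([not a.is_hydrogen for a in self.atoms], dtype=bool)

    def radii(self, default_table: Mapping[str, float] = DEFAULT_RADII) -> np.ndarray:
        out = np.empty(len(self.atoms))
        for i, a in enumerate(self.atoms):
            if a.radius is not None:
                out[i] = a.radius
            else:
                out[i] = default_table.get(a.element.upper(), DEFAULT_RADIUS_FALLBACK)
        return out

    def property_values(self, prop: str) -> np.ndarray:
        """Per-atom property array with NaN where the property is absent."""
        if prop not in PROPERTIES:
            raise ValueError(f"unknown property {prop!r}")
        vals = np.full(len(self.atoms), np.nan)
        for i, a in enumerate(self.atoms):
            v = getattr(a, prop)
            if v is not None:
                vals[i] = float(v)
        return vals

    def residue_of(self, index: int) -> tuple[str, str]:
        return self.atoms[index].residue_key()

    def with_coords(self, xyz: np.ndarray, label: str | None = None) -> "PropertiedStructure":
        """Copy with replaced coordinates (shape (n, 3)); properties carried over."""
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
                 for a, p in zip(self.atoms, xyz)]
        return PropertiedStructure(label or self.label, atoms)

    def copy(self) -> "PropertiedStructure":
        return PropertiedStructure(self.label, [replace(a) for a in self.atoms])


# ---------------------------------------------------------------------------
# Readers


_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def read_pdb(path: str | Path, chain_filter: Iterable[str] | None = None) -> PropertiedStructure:
    """Read ATOM records from a PDB file into a :class:`PropertiedStructure`.

    HETATM records, waters and alternate locations beyond the first are
    dropped. ``chain_filter`` restricts to the given chain ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    chains = set(chain_filter) if chain_filter is not None else None
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise StructureError(f"failed to parse PDB {path}: {exc}") from exc
    atoms: list[AtomRecord] = []
    if len(st) == 0:
        raise StructureError(f"no atoms in {path}")
    model = st[0]
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for res in chain:
            if res.het_flag != "A" or res.name in _WATER_NAMES:
                continue
            seen_names: set[str] = set()
            for atom in res:
                if atom.name in seen_names:  # altloc duplicates beyond the first
                    continue
                seen_names.add(atom.name)
                atoms.append(AtomRecord(
                    serial=atom.serial,
                    atom_name=atom.name,
                    residue_name=res.name,
                    chain_id=chain.name,
                    residue_seq=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                    element=atom.element.name,
                    is_hydrogen=atom.is_hydrogen(),
                ))
    if not atoms:
        raise StructureError(f"no atoms in {path} after filtering")
    return PropertiedStructure(path.stem, atoms)


def read_pqr(path: str | Path) -> PropertiedStructure:
    """Read a whitespace-tolerant PQR file (charge and radius follow z)."""
    path = Path(path)
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            tok = line.split()
            if len(tok) < 10:
                raise StructureError(
                    f"{path}:{lineno}: PQR line has {len(tok)} fields, "
                    "expected at least 10 (missing charge/radius?)")
            try:
                x, y, z, charge, radius = (float(t) for t in tok[-5:])
            except ValueError as exc:
                raise StructureError(f"{path}:{lineno}: bad numeric field: {exc}") from exc
            # ATOM serial name resname [chain] resseq x y z q r
            name, resname = tok[2], tok[3]
            if len(tok) == 11:
                chain_id, resid = tok[4], tok[5]
            else:
                chain_id, resid = "A", tok[4]
            seq, icode = _split_resid(resid, path, lineno)
            element = _element_from_name(name)
            atoms.append(AtomRecord(
                serial=int(tok[1]), atom_name=name, residue_name=resname,
                chain_id=chain_id, residue_seq=seq, icode=icode,
                x=x, y=y, z=z, element=element,
                radius=radius, charge=charge,
                is_hydrogen=element == "H",
            ))
    if not atoms:
        raise StructureError(f"no atoms in {path}")
    return PropertiedStructure(path.stem, atoms)


def _split_resid(resid: str, path: Path, lineno: int) -> tuple[int, str]:
    digits = resid
    icode = ""
    if digits and digits[-1].isalpha():
        digits, icode = digits[:-1], digits[-1]
    try:
        return int(digits), icode
    except ValueError as exc:
        raise StructureError(f"{path}:{lineno}: bad residue id {resid!r}") from exc


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else ""


def read_conservation(path: str | Path, chain_col: int = 0, seq_col: int = 1,
                      grade_col: int = 2) -> dict[tuple[str, str], int]:
    """Read a per-residue conservation grade table.

    Whitespace/tab separated, one residue per line; column indices are
    configurable for ConSurf-style layouts. Grades must be integers 1..9
    (1 = variable, 9 = conserved). Lines starting with '#' are skipped.
    """
    path = Path(path)
    grades: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            try:
                chain = tok[chain_col]
                resid = tok[seq_col]
                grade = int(tok[grade_col])
            except (IndexError, ValueError) as exc:
                raise StructureError(f"{path}:{lineno}: bad grade line: {exc}") from exc
            if grade not in range(1, 10):
                raise StructureError(f"{path}:{lineno}: grade {grade} outside 1..9")
            grades[(chain, resid)] = grade
    return grades


# ---------------------------------------------------------------------------
# Property assignment and merging


def assign_hydrophobicity(structure: PropertiedStructure,
                          table: Mapping[str, float] = WIMLEY_WHITE_INTERFACE
                          ) -> PropertiedStructure:
    """Assign each atom its residue's Wimley-White interfacial value.

    Unknown residue names get the neutral value 0 with a warning. Idempotent.
    """
    out = structure.copy()
    warned: set[str] = set()
    for a in out.atoms:
        if a.residue_name in table:
            a.hydrophobicity = table[a.residue_name]
        else:
            if a.residue_name not in warned:
                logger.warning("unknown residue %s: hydrophobicity set to 0", a.residue_name)
                warned.add(a.residue_name)
            a.hydrophobicity = 0.0
    return out


def apply_conservation(structure: PropertiedStructure,
                       grades: Mapping[tuple[str, str], int]) -> PropertiedStructure:
    """Annotate atoms with their residue's conservation grade (if listed)."""
    out = structure.copy()
    for a in out.atoms:
        a.conservation = grades.get(a.residue_key())
    return out


def merge_properties(base: PropertiedStructure,
                     pqr: PropertiedStructure | None = None,
                     conservation: Mapping[tuple[str, str], int] | None = None,
                     min_match: float = 0.9) -> PropertiedStructure:
    """Merge PQR charges/radii and conservation grades onto ``base``.

    PQR atoms are matched by (chain, residue, atom name). Heavy atoms of
    ``base`` must match at >= ``min_match`` or an alignment error is raised.
    PQR-only hydrogens are appended (they carry charge) flagged
    ``is_hydrogen``; base coordinates are never altered.
    """
    out = base.copy()
    if pqr is not None:
        lookup = {(a.residue_key(), a.atom_name): a for a in pqr.atoms}
        used: set[tuple[tuple[str, str], str]] = set()
        mismatches: list[str] = []
        n_heavy = n_matched = 0
        for a in out.atoms:
            key = (a.residue_key(), a.atom_name)
            src = lookup.get(key)
            if not a.is_hydrogen:
                n_heavy += 1
            if src is not None:
                a.charge = src.charge
                a.radius = src.radius
                used.add(key)
                if not a.is_hydrogen:
                    n_matched += 1
            else:
                mismatches.append(f"{a.chain_id}/{a.residue_seq}{a.icode}/{a.atom_name}")
        if n_heavy and n_matched / n_heavy < min_match:
            raise StructureError(
                f"PQR/PDB heavy-atom match {n_matched}/{n_heavy} below "
                f"{min_match:.0%}; first mismatches: {mismatches[:10]}")
        if mismatches:
            logger.info("%d base atoms had no PQR match", len(mismatches))
        extra = [replace(a) for a in pqr.atoms
                 if a.is_hydrogen and (a.residue_key(), a.atom_name) not in used]
        atoms = [replace(a) for a in out.atoms] + extra
        out = PropertiedStructure(out.label, atoms)
    if conservation is not None:
        out = apply_conservation(out, conservation)
    return out


# ---------------------------------------------------------------------------
# Writers


def write_pdb(structure: PropertiedStructure, path: str | Path,
              remarks: Sequence[str] = ()) -> None:
    """Write fixed-column v3.3 ATOM records (plus optional REMARK lines)."""
    with open(path, "w") as fh:
        for r in remarks:
            fh.write(f"REMARK 999 {r}\n")
        for i, a in enumerate(structure.atoms, 1):
            name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
            fh.write(
                f"ATOM  {i:5d} {name:<4.4s} {a.residue_name:<3.3s}"
                f" {a.chain_id[:1]}{a.residue_seq:4d}{a.icode:<1.1s}   "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2.2s}\n")
        fh.write("END\n")


def write_pqr(structure: PropertiedStructure, path: str | Path) -> None:
    with open(path, "w") as fh:
        radii = structure.radii()
        for i, a in enumerate(structure.atoms):
            q = a.charge if a.charge is not None else 0.0
            fh.write(
                f"ATOM  {i + 1:5d} {a.atom_name:<4.4s} {a.residue_name:<3.3s}"
                f" {a.chain_id[:1]} {a.residue_seq:4d}{a.icode:<1.1s}"
                f" {a.x:10.4f} {a.y:10.4f} {a.z:10.4f} {q:8.4f} {radii[i]:7.4f}\n")
        fh.write("END\n")


def write_conservation(grades: Mapping[tuple[str, str], int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# chain resid grade\n")
        for (chain, resid), grade in grades.items():
            fh.write(f"{chain}\t{resid}\t{grade}\n")


def write_residue_list(residues: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chain, resid in sorted(residues):
            fh.write(f"{chain}\t{resid}\n")
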
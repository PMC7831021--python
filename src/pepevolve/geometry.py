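"""Structure I/O and geometric primitives.

Everything downstream (site ranking, clustering, screening) is built on the
four operations defined here: Kabsch superposition, RMSD, center of mass and
Shrake-Rupley solvent-accessible surface area (SASA).

Coordinates are stored in angstroms throughout the package; nanometres appear
only at module boundaries that conventionally use them (the clustering cutoff,
AFM patch heights) and are converted on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Structure",
    "ResidueSelection",
    "SasaResult",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "kabsch_superpose",
    "coords_rmsd",
    "rmsd",
    "center_of_mass",
    "shrake_rupley_sasa",
    "sphere_points",
    "ATOMIC_MASSES",
    "VDW_RADII",
]

# Standard atomic masses (u), sufficient for protein heavy atoms plus the
# common hetero elements seen in PDB entries.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "NA": 22.990, "MG": 24.305, "K": 39.098, "CA": 40.078,
    "ZN": 65.38, "FE": 55.845, "MN": 54.938, "CU": 63.546,
}

# Bondi-style van der Waals radii (angstrom). Fixed published set; used for
# SASA. Metals are given ionic-ish fallbacks adequate for surface area work.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85,
    "I": 1.98, "NA": 2.27, "MG": 1.73, "K": 2.75, "CA": 2.31,
    "ZN": 1.39, "FE": 1.40, "MN": 1.40, "CU": 1.40,
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


class PDBParseError(ValueError):
    """Raised when a PDB coordinate line cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    """A single atom: identity plus a cartesian position in angstrom."""

    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    insertion_code: str = ""

    @property
    def residue_id(self) -> tuple[str, int, str]:
        """Residue identity: (chain, residue number, insertion code)."""
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def mass(self) -> float:
        try:
            return ATOMIC_MASSES[self.element.upper()]
        except KeyError:
            raise KeyError(
                f"no mass tabulated for element {self.element!r} "
                f"(atom {self.name} in {self.residue_name} "
                f"{self.chain_id}{self.residue_number})"
            ) from None


@dataclass
class Structure:
    """An ordered collection of atoms forming one model of a structure."""

    atoms: list[Atom]
    model_id: int = 1

    def __post_init__(self) -> None:
        for atom in self.atoms:
            if not np.all(np.isfinite(atom.position)):
                raise ValueError(f"non-finite position for atom {atom.name}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) float array, angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    def residue_ids(self) -> list[tuple[str, int, str]]:
        """Unique residue identities in atom order."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id)
        return list(seen)

    def atom_indices(self, selection: "ResidueSelection | None") -> np.ndarray:
        """Indices of atoms matched by *selection* (all atoms when None)."""
        if selection is None:
            return np.arange(len(self.atoms))
        return selection.resolve(self)

    def subset(self, indices: Iterable[int]) -> "Structure":
        return Structure([self.atoms[i] for i in indices], model_id=self.model_id)


@dataclass(frozen=True)
class ResidueSelection:
    """A set of residues on one chain, optionally restricted by atom class.

    ``atom_filter`` is one of ``"all"``, ``"backbone"`` (N, CA, C, O) or
    ``"heavy"`` (non-hydrogen).
    """

    chain_id: str
    residue_numbers: tuple[int, ...]
    atom_filter: str = "all"

    def __post_init__(self) -> None:
        if not self.residue_numbers:
            raise ValueError("empty residue selection")
        if self.atom_filter not in ("all", "backbone", "heavy"):
            raise ValueError(f"unknown atom filter {self.atom_filter!r}")
        object.__setattr__(
            self, "residue_numbers", tuple(dict.fromkeys(self.residue_numbers))
        )

    def _match(self, atom: Atom) -> bool:
        if atom.chain_id != self.chain_id:
            return False
        if atom.residue_number not in self.residue_numbers:
            return False
        if self.atom_filter == "backbone":
            return atom.name in BACKBONE_ATOMS
        if self.atom_filter == "heavy":
            return atom.element.upper() != "H"
        return True

    def resolve(self, structure: Structure) -> np.ndarray:
        """Atom indices in *structure* matched by this selection.

        Raises if any requested residue number is absent from the structure,
        so selection typos fail loudly instead of silently shrinking.
        """
        present = {
            a.residue_number for a in structure.atoms if a.chain_id == self.chain_id
        }
        missing = [r for r in self.residue_numbers if r not in present]
        if missing:
            raise ValueError(
                f"residues {missing} not found on chain {self.chain_id!r}"
            )
        idx = [i for i, a in enumerate(structure.atoms) if self._match(a)]
        if not idx:
            raise ValueError("selection matched no atoms")
        return np.asarray(idx, dtype=int)


@dataclass(frozen=True)
class SasaResult:
    """Shrake-Rupley output: per-atom, per-residue and total SASA (angstrom^2)."""

    per_atom: dict[int, float]
    per_residue: dict[tuple[str, int, str], float]
    total: float
    probe_radius: float
    n_sphere_points: int


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column dialect, MODEL/ENDMDL for multi-model files)
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    """Derive the element from a PDB atom name when column 77-78 is blank."""
    stripped = atom_name.strip()
    if not stripped:
        raise ValueError("empty atom name")
    # Names like "1HB / 2HG" start with a digit and are always hydrogens.
    if stripped[0].isdigit():
        return "H"
    two = stripped[:2].upper()
    # Two-letter elements only when the name occupies column 13 (4-char field
    # left-aligned into the element columns), which we approximate by the
    # common ion/halide names.
    if two in ("CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU", "SE") and len(stripped) <= 2:
        return two
    return stripped[0].upper()


def read_pdb(path: str | Path, include_hetatm: bool = False) -> list[Structure]:
    """Parse a fixed-column PDB file into one :class:`Structure` per model.

    HETATM records are skipped unless *include_hetatm* is set. Alternate
    location indicators other than blank/"A" are dropped. Insertion codes are
    preserved as part of residue identity.
    """
    path = Path(path)
    models: list[Structure] = []
    atoms: list[Atom] = []
    model_id = 1
    in_model_block = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record == "MODEL ":
                if in_model_block and atoms:
                    models.append(Structure(atoms, model_id=model_id))
                    atoms = []
                in_model_block = True
                try:
                    model_id = int(line[10:14])
                except ValueError:
                    model_id = len(models) + 1
            elif record == "ENDMDL":
                if not atoms:
                    raise PDBParseError(f"line {lineno}: empty model {model_id}")
                models.append(Structure(atoms, model_id=model_id))
                atoms = []
                in_model_block = False
            elif record == "ATOM  " or (record == "HETATM" and include_hetatm):
                altloc = line[16:17]
                if altloc not in (" ", "", "A"):
                    continue
                try:
                    name = line[12:16].strip()
                    residue_name = line[17:20].strip()
                    chain_id = line[21:22].strip() or " "
                    residue_number = int(line[22:26])
                    insertion_code = line[26:27].strip()
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except (ValueError, IndexError) as exc:
                    raise PDBParseError(
                        f"line {lineno}: malformed coordinate record: {line.rstrip()!r}"
                    ) from exc
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not element:
                    element = _infer_element(name)
                atoms.append(
                    Atom(
                        name=name,
                        element=element.upper(),
                        residue_number=residue_number,
                        residue_name=residue_name,
                        chain_id=chain_id,
                        position=np.array([x, y, z], dtype=float),
                        insertion_code=insertion_code,
                    )
                )
    if atoms:
        models.append(Structure(atoms, model_id=model_id))
    if not models:
        raise PDBParseError(f"{path}: no ATOM records found")
    return models


def write_pdb(models: Structure | Sequence[Structure], path: str | Path) -> None:
    """Write one or more models as a fixed-column PDB file."""
    if isinstance(models, Structure):
        models = [models]
    multi = len(models) > 1
    with open(path, "w") as fh:
        for structure in models:
            if multi:
                fh.write(f"MODEL     {structure.model_id:4d}\n")
            for i, a in enumerate(structure.atoms, start=1):
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                x, y, z = a.position
                fh.write(
                    f"ATOM  {i:5d} {name:<4s} {a.residue_name:<3s} "
                    f"{a.chain_id:1s}{a.residue_number:4d}{a.insertion_code or ' ':1s}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares superposition of *mobile* onto *target*.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits *target*. The rotation is
    always proper (determinant +1); the reflection branch of the SVD solution
    is corrected by the standard sign fix.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(
            f"point count mismatch: {mobile.shape} vs {target.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    mob_center = mobile.mean(axis=0)
    tgt_center = target.mean(axis=0)
    p = mobile - mob_center
    q = target - tgt_center
    if np.linalg.matrix_rank(p, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point set")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = tgt_center - rotation @ mob_center
    fitted = p @ rotation.T
    value = float(np.sqrt(np.mean(np.sum((fitted - q) ** 2, axis=1))))
    return rotation, translation, value


def coords_rmsd(a: np.ndarray, b: np.ndarray, fit: bool = True) -> float:
    """RMSD between two coordinate sets (angstrom); superposes first if *fit*."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if fit:
        return kabsch_superpose(a, b)[2]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd(
    frame_a: Structure,
    frame_b: Structure,
    selection: ResidueSelection | None = None,
    fit: bool = True,
) -> float:
    """RMSD (angstrom) between two frames over *selection*."""
    idx_a = frame_a.atom_indices(selection)
    idx_b = frame_b.atom_indices(selection)
    if len(idx_a) != len(idx_b):
        raise ValueError("selection resolves to different atom counts")
    return coords_rmsd(
        frame_a.coordinates[idx_a], frame_b.coordinates[idx_b], fit=fit
    )


def center_of_mass(
    structure: Structure,
    selection: ResidueSelection | None = None,
    weighted: bool = True,
) -> np.ndarray:
    """Mass-weighted center of the selected atoms (geometric centroid when
    ``weighted=False``)."""
    idx = structure.atom_indices(selection)
    coords = structure.coordinates[idx]
    if not weighted:
        return coords.mean(axis=0)
    masses = np.array([structure.atoms[i].mass for i in idx])
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral lattice).

    A fixed lattice (rather than random sampling) makes SASA reproducible
    bit-for-bit at fixed ``n``.
    """
    if n < 10:
        raise ValueError("need at least 10 sphere points")
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _vdw_radius(atom: Atom) -> float:
    try:
        return VDW_RADII[atom.element.upper()]
    except KeyError:
        raise KeyError(
            f"no van der Waals radius for element {atom.element!r} "
            f"(atom {atom.name} in {atom.residue_name} "
            f"{atom.chain_id}{atom.residue_number})"
        ) from None


def shrake_rupley_sasa(
    structure: Structure,
    selection: ResidueSelection | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Shrake-Rupley SASA of the selected atoms in the context of the whole
    structure.

    Each selected atom contributes the exposed fraction of a sphere of radius
    ``r_vdw + probe`` estimated over ``n_points`` lattice points; *all* atoms
    of the structure act as occluders, so a selection reports the area of
    those atoms as part of the full molecule, not in isolation.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    points = sphere_points(n_points)
    coords = structure.coordinates
    radii = np.array([_vdw_radius(a) for a in structure.atoms]) + probe_radius
    sel_idx = structure.atom_indices(selection)
    tree = cKDTree(coords)
    max_radius = radii.max()

    per_atom: dict[int, float] = {}
    per_residue: dict[tuple[str, int, str], float] = {}
    for i in sel_idx:
        r_i = radii[i]
        shell = coords[i] + r_i * points
        neighbours = tree.query_ball_point(coords[i], r_i + max_radius)
        neighbours = [j for j in neighbours if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((shell - coords[j]) ** 2, axis=1)
            exposed &= d2 > radii[j] ** 2
        area = 4.0 * np.pi * r_i**2 * exposed.sum() / n_points
        per_atom[int(i)] = float(area)
        rid = structure.atoms[i].residue_id
        per_residue[rid] = per_residue.get(rid, 0.0) + float(area)
    total = float(sum(per_atom.values()))
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        total=total,
        probe_radius=probe_radius,
        n_sphere_points=n_points,
    )
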
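"""Synthetic generators for every input the pipeline consumes.

Real inputs — a solved target structure, pocket-prediction tables, MD
ensembles of peptide/target complexes, AFM micrographs — require external
tools or instruments. The generators here produce structurally valid
stand-ins with planted, known ground truth (a site that ranks first
everywhere, blobs with known cluster membership, interfaces with planted
contacts, images with planted step heights), which is what makes the rest of
the package testable end to end.

These are simplified objects: backbone-only residues on smooth curves, ideal
Gaussian noise. They exercise the geometry and statistics of the methods,
not force-field realism.
"""

from __future__ import annotations

import numpy as np

from .geometry import Atom, ResidueSelection, Structure
from .site_ranking import RegionMap, SitePrediction

__all__ = [
    "THREE_LETTER",
    "make_residue_atoms",
    "chain_structure",
    "two_shell_structure",
    "synthetic_complex",
    "synthetic_site_predictions",
    "two_blob_ensemble",
    "drifting_complex_frames",
]

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# Idealized local offsets (angstrom) of backbone atoms around a residue
# center; chemically plausible spacing, not a force-field geometry.
_BACKBONE_OFFSETS = {
    "N": np.array([-1.2, 0.6, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.3, 0.5, 0.0]),
    "O": np.array([1.6, 1.7, 0.2]),
}


def make_residue_atoms(
    residue_name: str,
    residue_number: int,
    chain_id: str,
    center: np.ndarray,
    include_cb: bool = True,
) -> list[Atom]:
    """Backbone (+CB) atoms of one residue placed around *center*."""
    center = np.asarray(center, dtype=float)
    atoms = [
        Atom(
            name=name,
            element=name[0],
            residue_number=residue_number,
            residue_name=residue_name,
            chain_id=chain_id,
            position=center + offset,
        )
        for name, offset in _BACKBONE_OFFSETS.items()
    ]
    if include_cb and residue_name != "GLY":
        atoms.append(
            Atom(
                name="CB",
                element="C",
                residue_number=residue_number,
                residue_name=residue_name,
                chain_id=chain_id,
                position=center + np.array([-0.5, -1.4, 0.6]),
            )
        )
    return atoms


def chain_structure(
    sequence: str,
    chain_id: str = "A",
    start: np.ndarray | None = None,
    direction: np.ndarray | None = None,
    spacing: float = 3.8,
    first_residue: int = 1,
) -> Structure:
    """An extended chain: one residue every *spacing* angstrom along a line
    (the CA-CA virtual bond length of an extended backbone)."""
    start = np.zeros(3) if start is None else np.asarray(start, dtype=float)
    direction = (
        np.array([1.0, 0.0, 0.0]) if direction is None else np.asarray(direction, float)
    )
    direction = direction / np.linalg.norm(direction)
    atoms: list[Atom] = []
    for i, aa in enumerate(sequence):
        center = start + spacing * i * direction
        atoms.extend(
            make_residue_atoms(THREE_LETTER[aa], first_residue + i, chain_id, center)
        )
    return Structure(atoms)


def two_shell_structure(
    n_core: int = 8,
    n_surface: int = 12,
    core_radius: float = 3.0,
    surface_radius: float = 10.0,
    chain_id: str = "A",
    seed: int = 0,
) -> tuple[Structure, ResidueSelection, ResidueSelection]:
    """A globule with buried core residues and exposed surface residues.

    Returns the structure plus the core and surface residue selections; by
    construction the core selection has (much) smaller SASA than the surface
    one, which anchors burial-sensitivity tests.
    """
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    resnum = 1
    core_numbers, surface_numbers = [], []
    for shell_n, radius, bucket in (
        (n_core, core_radius, core_numbers),
        (n_surface, surface_radius, surface_numbers),
    ):
        for _ in range(shell_n):
            v = rng.normal(size=3)
            v = v / np.linalg.norm(v) * radius * (0.6 + 0.4 * rng.random())
            atoms.extend(make_residue_atoms("ALA", resnum, chain_id, v))
            bucket.append(resnum)
            resnum += 1
    structure = Structure(atoms)
    return (
        structure,
        ResidueSelection(chain_id, tuple(core_numbers)),
        ResidueSelection(chain_id, tuple(surface_numbers)),
    )


def synthetic_complex(
    target_sequence: str = "GASDEVRLYT",
    peptide_sequence: str = "CAAAAAAAAAAC",
    separation: float = 8.0,
    target_chain: str = "A",
    peptide_chain: str = "B",
) -> tuple[Structure, ResidueSelection, ResidueSelection]:
    """A two-chain complex: target chain along x, peptide chain parallel to
    it at *separation* angstrom in y. Returns (structure, target selection,
    peptide selection)."""
    target = chain_structure(target_sequence, chain_id=target_chain)
    peptide = chain_structure(
        peptide_sequence,
        chain_id=peptide_chain,
        start=np.array([0.0, separation, 0.0]),
    )
    structure = Structure(target.atoms + peptide.atoms)
    return (
        structure,
        ResidueSelection(target_chain, tuple(range(1, len(target_sequence) + 1))),
        ResidueSelection(peptide_chain, tuple(range(1, len(peptide_sequence) + 1))),
    )


def synthetic_site_predictions(
    region_map: RegionMap,
    n_poses: int = 12,
    n_sites_per_pose: int = 6,
    favored_region: str | None = None,
    seed: int = 0,
) -> list[SitePrediction]:
    """Ranked site predictions for *n_poses* poses drawn from the regions of
    *region_map*.

    When ``favored_region`` is given, a site from that region receives rank 1
    in every pose (the consensus winner is then known by construction); the
    remaining ranks are filled by regions sampled without replacement.
    """
    labels = sorted(region_map.regions)
    if favored_region is not None and favored_region not in region_map.regions:
        raise ValueError(f"favored region {favored_region!r} not in map")
    if n_sites_per_pose > len(labels):
        raise ValueError("more sites per pose than available regions")
    rng = np.random.default_rng(seed)
    predictions: list[SitePrediction] = []
    for pose_id in range(1, n_poses + 1):
        others = [l for l in labels if l != favored_region]
        order = list(rng.permutation(others))
        if favored_region is not None:
            order = [favored_region] + order
        for rank, label in enumerate(order[:n_sites_per_pose], start=1):
            residues = tuple(sorted(region_map.regions[label]))
            predictions.append(
                SitePrediction(
                    pose_id=pose_id,
                    rank=rank,
                    residues=ResidueSelection(region_map.chain_id, residues),
                    n_contacts=int(rng.integers(20, 120)),
                )
            )
    return predictions


def two_blob_ensemble(
    n_frames_per_blob: int = 20,
    n_atoms: int = 12,
    jitter: float = 0.05,
    separation: float = 20.0,
    seed: int = 0,
) -> np.ndarray:
    """Frames forming two tight conformational blobs far apart.

    Each blob is a reference conformation plus per-frame Gaussian jitter
    (angstrom); the blobs differ by an internal deformation of magnitude
    *separation* so no rigid-body fit can bring them close. Ground truth:
    exactly two clusters of ``n_frames_per_blob`` each at any cutoff between
    the intra- and inter-blob RMSD scales.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(scale=5.0, size=(n_atoms, 3))
    deformation = rng.normal(size=(n_atoms, 3))
    deformation -= deformation.mean(axis=0)
    deformation *= separation / np.sqrt(np.mean(np.sum(deformation**2, axis=1)))
    frames = []
    for blob_base in (base, base + deformation):
        for _ in range(n_frames_per_blob):
            frames.append(blob_base + rng.normal(scale=jitter, size=(n_atoms, 3)))
    return np.stack(frames)


def drifting_complex_frames(
    n_frames: int = 10,
    drift_start: int | None = None,
    drift_vector: np.ndarray | None = None,
    target_sequence: str = "GASDEVRLYT",
    peptide_sequence: str = "CAAAAAAAAAAC",
    separation: float = 8.0,
) -> tuple[list[Structure], ResidueSelection, ResidueSelection]:
    """A frame series of the synthetic complex in which the peptide chain
    rigidly translates by *drift_vector* from frame *drift_start* onward
    (no drift when ``drift_start`` is None). Ground truth for the COM-distance
    descriptor."""
    complex_structure, target_sel, peptide_sel = synthetic_complex(
        target_sequence=target_sequence,
        peptide_sequence=peptide_sequence,
        separation=separation,
    )
    drift_vector = (
        np.zeros(3) if drift_vector is None else np.asarray(drift_vector, float)
    )
    peptide_idx = set(complex_structure.atom_indices(peptide_sel).tolist())
    frames = []
    for k in range(n_frames):
        shift = (
            drift_vector
            if drift_start is not None and k >= drift_start
            else np.zeros(3)
        )
        atoms = [
            Atom(
                name=a.name,
                element=a.element,
                residue_number=a.residue_number,
                residue_name=a.residue_name,
                chain_id=a.chain_id,
                position=a.position + (shift if i in peptide_idx else 0.0),
                insertion_code=a.insertion_code,
            )
            for i, a in enumerate(complex_structure.atoms)
        ]
        frames.append(Structure(atoms, model_id=k + 1))
    return frames, target_sel, peptide_sel
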
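"""Greedy RMSD-neighborhood (Daura / gromos) clustering of conformational
ensembles and selection of the lowest-scoring cluster representative.

The algorithm: compute all pairwise RMSDs; repeatedly take the unassigned
frame with the most unassigned neighbours within the cutoff as a cluster
center, remove it and its neighbours, and continue until no frames remain.
Only clusters above a minimum size are considered when picking the scored
representative, so sparsely populated conformations never drive the design
loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import ResidueSelection, Structure, coords_rmsd

NM_PER_ANGSTROM = 0.1

__all__ = [
    "ConformationEnsemble",
    "ClusteringConfig",
    "Cluster",
    "pairwise_rmsd_matrix",
    "daura_cluster",
    "select_representative",
    "ensemble_from_structures",
    "read_coordinate_table",
    "write_clusters_json",
    "write_assignments_csv",
]


@dataclass
class ConformationEnsemble:
    """Frames of coordinates (angstrom) over a fixed atom selection."""

    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_times: np.ndarray | None = None  # ps
    selection: ResidueSelection | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in ensemble")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != len(self.frames):
                raise ValueError("frame_times length mismatch")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class ClusteringConfig:
    """Cutoff in nanometres (the conventional unit for this criterion);
    ``min_cluster_size`` of 11 implements the 'more than 10 structures'
    population filter."""

    cutoff: float = 0.105  # nm
    min_cluster_size: int = 11
    fit_before_rmsd: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass(frozen=True)
class Cluster:
    center_index: int
    member_indices: tuple[int, ...]
    size: int

    def __post_init__(self) -> None:
        if self.center_index not in self.member_indices:
            raise ValueError("center must be a member of its own cluster")
        if self.size != len(self.member_indices):
            raise ValueError("size does not match member count")


def pairwise_rmsd_matrix(
    ensemble: ConformationEnsemble, fit: bool = True
) -> np.ndarray:
    """Symmetric frame-by-frame RMSD matrix in nanometres (zero diagonal)."""
    n = len(ensemble)
    if n == 0:
        raise ValueError("empty ensemble")
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            value = coords_rmsd(ensemble.frames[i], ensemble.frames[j], fit=fit)
            matrix[i, j] = matrix[j, i] = value * NM_PER_ANGSTROM
    return matrix


def daura_cluster(
    ensemble: ConformationEnsemble,
    config: ClusteringConfig = ClusteringConfig(),
    rmsd_matrix: np.ndarray | None = None,
) -> list[Cluster]:
    """Greedy neighbour-count clustering.

    At each round the unassigned frame with the most unassigned neighbours
    within the cutoff seeds a cluster (ties broken toward the lowest frame
    index, giving deterministic output); it and its neighbours are removed.
    The returned clusters partition the frame set, in extraction order.
    """
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd_matrix(ensemble, fit=config.fit_before_rmsd)
    n = len(rmsd_matrix)
    within = rmsd_matrix <= config.cutoff
    np.fill_diagonal(within, False)

    unassigned = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while unassigned.any():
        counts = (within & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(within[center] & unassigned)
        member_set = tuple(sorted({center, *members.tolist()}))
        clusters.append(
            Cluster(
                center_index=center,
                member_indices=member_set,
                size=len(member_set),
            )
        )
        unassigned[list(member_set)] = False
    return clusters


def select_representative(
    clusters: Sequence[Cluster],
    ensemble: ConformationEnsemble,
    config: ClusteringConfig,
    scorer: Callable[[np.ndarray], float],
) -> tuple[int, float] | None:
    """Score the center of each sufficiently populated cluster and return the
    (frame index, score) of the minimum; ``None`` when no cluster survives
    the population filter."""
    surviving = [c for c in clusters if c.size >= config.min_cluster_size]
    if not surviving:
        return None
    scored = [
        (float(scorer(ensemble.frames[c.center_index])), c.center_index)
        for c in surviving
    ]
    score, index = min(scored)
    return index, score


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def ensemble_from_structures(
    models: Sequence[Structure],
    selection: ResidueSelection | None = None,
    frame_times: np.ndarray | None = None,
) -> ConformationEnsemble:
    """Build an ensemble from multi-model structures (e.g. read_pdb output),
    restricted to *selection*."""
    if not models:
        raise ValueError("no models supplied")
    frames = []
    n_atoms = None
    for m in models:
        idx = m.atom_indices(selection)
        if n_atoms is None:
            n_atoms = len(idx)
        elif len(idx) != n_atoms:
            raise ValueError("atom count differs between models")
        frames.append(m.coordinates[idx])
    return ConformationEnsemble(
        frames=np.stack(frames), frame_times=frame_times, selection=selection
    )


def read_coordinate_table(path: str | Path) -> ConformationEnsemble:
    """Read a plain coordinate table (columns frame, atom, x, y, z; angstrom;
    whitespace- or comma-separated)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"frame", "atom", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    frames = []
    for _, group in df.sort_values(["frame", "atom"]).groupby("frame", sort=True):
        frames.append(group[["x", "y", "z"]].to_numpy(dtype=float))
    counts = {f.shape[0] for f in frames}
    if len(counts) != 1:
        raise ValueError("atom count differs between frames")
    return ConformationEnsemble(frames=np.stack(frames))


def write_clusters_json(clusters: Sequence[Cluster], path: str | Path) -> None:
    payload = [
        {
            "center": c.center_index,
            "members": list(c.member_indices),
            "size": c.size,
        }
        for c in clusters
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def write_assignments_csv(
    clusters: Sequence[Cluster], n_frames: int, path: str | Path
) -> None:
    assignment = {}
    for cluster_id, c in enumerate(clusters):
        for m in c.member_indices:
            assignment[m] = cluster_id
    rows = [
        {"frame": i, "cluster": assignment[i], "is_center": any(
            c.center_index == i for c in clusters
        )}
        for i in range(n_frames)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
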
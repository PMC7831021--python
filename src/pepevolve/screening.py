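"""Post-design screening of candidate peptide binders.

Each candidate's complex trajectory is condensed into three descriptor
series — per-frame binding score, distance between the centers of mass of the
target site and of the peptide, and backbone RMSD of site + peptide relative
to the first frame — and checked against rejection rules: weak mean binding
(score above the -10 a.u. weak-binding threshold), drift away from the
target region, persistent contact of the anchor cysteines with the target
(the termini must stay free for DNA conjugation), and poor predicted water
solubility.

Contact detection is purely geometric: an h-bond is counted when a nitrogen
or oxygen of one side lies within the h-bond cutoff of a nitrogen or oxygen
of the other, a hydrophobic contact when two carbons fall within the
hydrophobic cutoff. This replaces interactive contact-diagram tools with a
documented, reproducible approximation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    ResidueSelection,
    Structure,
    center_of_mass,
    coords_rmsd,
)

NM_PER_ANGSTROM = 0.1

__all__ = [
    "DescriptorSeries",
    "ScreeningThresholds",
    "ContactReport",
    "RejectionReason",
    "ScreeningVerdict",
    "compute_descriptors",
    "detect_contacts",
    "apply_rejection_rules",
    "solubility",
    "CHARGED_RESIDUES",
    "HYDROPHOBIC_RESIDUES",
]

CHARGED_RESIDUES = frozenset("DEKRH")
HYDROPHOBIC_RESIDUES = frozenset("AVLIMFWYC")
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DescriptorSeries:
    """The three per-frame screening descriptors over a trajectory."""

    times: np.ndarray  # ps
    binding_score: np.ndarray  # a.u., lower = stronger
    com_distance: np.ndarray  # nm
    backbone_rmsd: np.ndarray  # nm, vs frame 0

    def __post_init__(self) -> None:
        arrays = {
            "times": np.asarray(self.times, dtype=float),
            "binding_score": np.asarray(self.binding_score, dtype=float),
            "com_distance": np.asarray(self.com_distance, dtype=float),
            "backbone_rmsd": np.asarray(self.backbone_rmsd, dtype=float),
        }
        lengths = {len(v) for v in arrays.values()}
        if len(lengths) != 1:
            raise ValueError("descriptor arrays must have equal length")
        if next(iter(lengths)) == 0:
            raise ValueError("empty descriptor series")
        if np.any(np.diff(arrays["times"]) <= 0) and len(arrays["times"]) > 1:
            raise ValueError("times must be strictly increasing")
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ps": self.times,
                "binding_score": self.binding_score,
                "com_distance_nm": self.com_distance,
                "backbone_rmsd_nm": self.backbone_rmsd,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ScreeningThresholds:
    """Rejection thresholds.

    ``weak_score_cutoff``: mean binding scores above this (-10 a.u. by
    convention) indicate weak binding. ``drift_distance``/``drift_fraction``
    quantify 'significantly shifted from the target region': rejection when
    the site-peptide COM distance exceeds ``drift_distance`` in more than
    ``drift_fraction`` of frames. The same persistence fraction governs
    anchor-Cys contacts.
    """

    weak_score_cutoff: float = -10.0  # a.u.
    drift_distance: float = 1.0  # nm
    drift_fraction: float = 0.5
    hbond_cutoff: float = 3.5  # angstrom
    hydrophobic_cutoff: float = 4.0  # angstrom

    def __post_init__(self) -> None:
        if not 0.0 <= self.drift_fraction <= 1.0:
            raise ValueError("drift_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ContactReport:
    """Residue-level contacts across an interface for one frame."""

    hbond_pairs: tuple[tuple[tuple[str, int], tuple[str, int], float], ...]
    hydrophobic_pairs: tuple[tuple[tuple[str, int], tuple[str, int], float], ...]

    def residues_in_contact(self, side: int = 0) -> set[tuple[str, int]]:
        """Residues of side *side* (0 = first selection) in any contact."""
        out: set[tuple[str, int]] = set()
        for pair in self.hbond_pairs + self.hydrophobic_pairs:
            out.add(pair[side])
        return out


class RejectionReason(str, Enum):
    # Enum order fixes the order of reasons in verdicts.
    weak_binding = "weak_binding"
    region_drift = "region_drift"
    anchor_contact = "anchor_contact"
    insoluble = "insoluble"


@dataclass(frozen=True)
class ScreeningVerdict:
    candidate_id: str
    passed: bool
    reasons: tuple[RejectionReason, ...]

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be equivalent to an empty reason list")

    def to_dict(self) -> dict:
        return {
            "candidate_id": self.candidate_id,
            "passed": self.passed,
            "reasons": [r.value for r in self.reasons],
        }


def compute_descriptors(
    frames: Sequence[Structure],
    site_selection: ResidueSelection,
    peptide_selection: ResidueSelection,
    scorer: Callable[[Structure], float],
    frame_times: np.ndarray | None = None,
) -> DescriptorSeries:
    """Evaluate the three descriptors on every frame of a complex trajectory.

    The backbone RMSD is computed over site + peptide backbones against frame
    0, after least-squares fitting.
    """
    if not frames:
        raise ValueError("no frames supplied")
    times = (
        np.asarray(frame_times, dtype=float)
        if frame_times is not None
        else np.arange(len(frames), dtype=float)
    )
    site_bb = ResidueSelection(
        site_selection.chain_id, site_selection.residue_numbers, "backbone"
    )
    pep_bb = ResidueSelection(
        peptide_selection.chain_id, peptide_selection.residue_numbers, "backbone"
    )

    def backbone_coords(frame: Structure) -> np.ndarray:
        idx = np.concatenate([frame.atom_indices(site_bb), frame.atom_indices(pep_bb)])
        return frame.coordinates[idx]

    ref_bb = backbone_coords(frames[0])
    scores, distances, rmsds = [], [], []
    for k, frame in enumerate(frames):
        try:
            scores.append(float(scorer(frame)))
        except Exception as exc:
            raise RuntimeError(f"scorer failed on frame {k}: {exc}") from exc
        site_com = center_of_mass(frame, site_selection)
        pep_com = center_of_mass(frame, peptide_selection)
        distances.append(np.linalg.norm(site_com - pep_com) * NM_PER_ANGSTROM)
        rmsds.append(coords_rmsd(backbone_coords(frame), ref_bb, fit=True) * NM_PER_ANGSTROM)
    return DescriptorSeries(
        times=times,
        binding_score=np.array(scores),
        com_distance=np.array(distances),
        backbone_rmsd=np.array(rmsds),
    )


def detect_contacts(
    frame: Structure,
    selection_a: ResidueSelection,
    selection_b: ResidueSelection,
    hbond_cutoff: float = 3.5,
    hydrophobic_cutoff: float = 4.0,
) -> ContactReport:
    """Distance-based interface contacts between two disjoint selections.

    Reported pairs are residue-level: each (residue_a, residue_b) pair appears
    once with the minimal qualifying atom distance.
    """
    idx_a = frame.atom_indices(selection_a)
    idx_b = frame.atom_indices(selection_b)
    if set(idx_a) & set(idx_b):
        raise ValueError("selections overlap")
    coords = frame.coordinates

    def residue_key(i: int) -> tuple[str, int]:
        a = frame.atoms[i]
        return (a.chain_id, a.residue_number)

    hbond: dict[tuple, float] = {}
    hydrophobic: dict[tuple, float] = {}
    for i in idx_a:
        ei = frame.atoms[i].element.upper()
        for j in idx_b:
            ej = frame.atoms[j].element.upper()
            d = float(np.linalg.norm(coords[i] - coords[j]))
            pair = (residue_key(i), residue_key(j))
            if ei in ("N", "O") and ej in ("N", "O") and d <= hbond_cutoff:
                if pair not in hbond or d < hbond[pair]:
                    hbond[pair] = d
            if ei == "C" and ej == "C" and d <= hydrophobic_cutoff:
                if pair not in hydrophobic or d < hydrophobic[pair]:
                    hydrophobic[pair] = d
    return ContactReport(
        hbond_pairs=tuple(
            (a, b, d) for (a, b), d in sorted(hbond.items())
        ),
        hydrophobic_pairs=tuple(
            (a, b, d) for (a, b), d in sorted(hydrophobic.items())
        ),
    )


def apply_rejection_rules(
    candidate_id: str,
    sequence: str,
    series: DescriptorSeries,
    contacts_over_frames: Sequence[ContactReport],
    anchor_residues: Sequence[tuple[str, int]],
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> ScreeningVerdict:
    """Aggregate the screening descriptors into a pass/reject verdict.

    *anchor_residues* identifies the peptide's anchor cysteines as
    (chain, residue_number) keys as they appear in contact reports; an anchor
    appearing in any contact pair in more than ``drift_fraction`` of frames
    triggers rejection, since the terminal Cys pair must remain free for
    DNA-conjugate chemistry.
    """
    reasons: list[RejectionReason] = []

    if float(np.mean(series.binding_score)) > thresholds.weak_score_cutoff:
        reasons.append(RejectionReason.weak_binding)

    drifted = np.asarray(series.com_distance) > thresholds.drift_distance
    if len(series) and drifted.mean() > thresholds.drift_fraction:
        reasons.append(RejectionReason.region_drift)

    anchor_set = set(anchor_residues)
    if contacts_over_frames:
        hits = [
            bool(anchor_set & report.residues_in_contact(side=1))
            for report in contacts_over_frames
        ]
        if np.mean(hits) > thresholds.drift_fraction:
            reasons.append(RejectionReason.anchor_contact)

    if solubility(sequence) != "good":
        reasons.append(RejectionReason.insoluble)

    reasons.sort(key=list(RejectionReason).index)
    return ScreeningVerdict(
        candidate_id=candidate_id,
        passed=not reasons,
        reasons=tuple(reasons),
    )


def solubility(sequence: str) -> str:
    """Predicted water solubility label, ``good`` or ``poor``.

    A deterministic composition heuristic standing in for proprietary web
    calculators: a peptide is 'good' when its charged-residue fraction
    (D, E, K, R, H) is at least 0.20 and its hydrophobic fraction
    (A, V, L, I, M, F, W, Y, C) is at most 0.60.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    unknown = set(seq) - VALID_RESIDUES
    if unknown:
        raise ValueError(f"unknown residue letters: {sorted(unknown)}")
    n = len(seq)
    charged = sum(aa in CHARGED_RESIDUES for aa in seq) / n
    hydrophobic = sum(aa in HYDROPHOBIC_RESIDUES for aa in seq) / n
    return "good" if charged >= 0.20 and hydrophobic <= 0.60 else "poor"


def write_verdicts_json(
    verdicts: Sequence[ScreeningVerdict], path: str | Path
) -> None:
    Path(path).write_text(
        json.dumps([v.to_dict() for v in verdicts], indent=2)
    )
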
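"""Consensus ranking of putative peptide-binding sites across target poses.

Pocket-mapping tools rank candidate binding sites independently within each
conformational pose of the target. To decide which surface region to design
against, the per-pose predictions are assigned to named regions of the
protein surface and pooled into a per-region consensus score: the mean, over
poses, of the best rank any site in that region attained in the pose. Lower
is better; a region that ranks first in every pose attains the minimum
possible score of 1.0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .geometry import ResidueSelection, Structure, SasaResult, shrake_rupley_sasa

UNASSIGNED = "unassigned"

__all__ = [
    "SitePrediction",
    "RegionMap",
    "ConsensusResult",
    "assign_region",
    "consensus_rank",
    "site_size",
    "read_predictions_csv",
    "write_predictions_csv",
    "read_region_map",
]


@dataclass(frozen=True)
class SitePrediction:
    """One predicted binding site: its pose, within-pose rank and residues."""

    pose_id: int
    rank: int
    residues: ResidueSelection
    n_contacts: int | None = None

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1 (1 = best)")


@dataclass(frozen=True)
class RegionMap:
    """Named surface regions as residue-number sets (one chain).

    Regions may overlap; labels must be unique (enforced by the mapping).
    """

    regions: dict[str, frozenset[int]]
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("region map is empty")
        frozen = {k: frozenset(v) for k, v in self.regions.items()}
        for label, residues in frozen.items():
            if not residues:
                raise ValueError(f"region {label!r} has no residues")
        object.__setattr__(self, "regions", frozen)


@dataclass(frozen=True)
class RegionScore:
    score: float
    best_rank_per_pose: tuple[float, ...]
    n_poses_observed: int


@dataclass(frozen=True)
class ConsensusResult:
    """Per-region consensus scores plus the best-first label ordering."""

    per_region: dict[str, RegionScore]
    ordering: tuple[str, ...]
    n_poses: int

    def to_dict(self) -> dict:
        return {
            "n_poses": self.n_poses,
            "ordering": list(self.ordering),
            "per_region": {
                label: {
                    "score": rs.score,
                    "best_rank_per_pose": list(rs.best_rank_per_pose),
                    "n_poses_observed": rs.n_poses_observed,
                }
                for label, rs in self.per_region.items()
            },
        }

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "region": label,
                "score": self.per_region[label].score,
                "n_poses_observed": self.per_region[label].n_poses_observed,
            }
            for label in self.ordering
        ]
        return pd.DataFrame(rows)


def assign_region(prediction: SitePrediction, region_map: RegionMap) -> str:
    """Label of the region sharing the most residues with the prediction.

    Ties go to the smaller (more specific) region, then lexicographic label;
    zero overlap with every region yields the sentinel label ``unassigned``.
    """
    site = set(prediction.residues.residue_numbers)
    best_label = UNASSIGNED
    best_key: tuple[int, int, str] | None = None
    for label, residues in region_map.regions.items():
        overlap = len(site & residues)
        if overlap == 0:
            continue
        key = (-overlap, len(residues), label)
        if best_key is None or key < best_key:
            best_key = key
            best_label = label
    return best_label


def consensus_rank(
    predictions: list[SitePrediction],
    region_map: RegionMap,
    reciprocal: bool = False,
) -> ConsensusResult:
    """Pool per-pose site rankings into a per-region consensus.

    For each region Z and pose i, ``r_Z(i)`` is the best (numerically
    smallest) rank among the sites assigned to Z in that pose; poses in which
    Z does not appear contribute a penalty rank of (number of sites in the
    pose) + 1, so absence is strictly worse than any observed rank. The
    default score is the mean of ``r_Z(i)`` over poses (lower = better); with
    ``reciprocal=True`` the score is N / sum(r_Z(i)) (higher = better). Both
    produce identical orderings.
    """
    if not predictions:
        raise ValueError("no predictions supplied")

    by_pose: dict[int, list[SitePrediction]] = {}
    for p in predictions:
        by_pose.setdefault(p.pose_id, []).append(p)
    for pose_id, pose_preds in by_pose.items():
        ranks = [p.rank for p in pose_preds]
        if len(set(ranks)) != len(ranks):
            raise ValueError(f"duplicate ranks in pose {pose_id}")

    pose_ids = sorted(by_pose)
    n_poses = len(pose_ids)
    labels = {assign_region(p, region_map) for p in predictions}

    per_region: dict[str, RegionScore] = {}
    for label in sorted(labels):
        best_ranks: list[float] = []
        observed = 0
        for pose_id in pose_ids:
            pose_preds = by_pose[pose_id]
            in_region = [
                p.rank for p in pose_preds if assign_region(p, region_map) == label
            ]
            if in_region:
                best_ranks.append(float(min(in_region)))
                observed += 1
            else:
                best_ranks.append(float(len(pose_preds) + 1))
        total = sum(best_ranks)
        score = n_poses / total if reciprocal else total / n_poses
        per_region[label] = RegionScore(
            score=score,
            best_rank_per_pose=tuple(best_ranks),
            n_poses_observed=observed,
        )

    # Ascending mean-best-rank regardless of the reported scale; ties broken
    # by more poses observed, then label.
    def sort_key(label: str) -> tuple[float, int, str]:
        rs = per_region[label]
        mean_rank = sum(rs.best_rank_per_pose) / n_poses
        return (mean_rank, -rs.n_poses_observed, label)

    ordering = tuple(sorted(per_region, key=sort_key))
    return ConsensusResult(per_region=per_region, ordering=ordering, n_poses=n_poses)


def site_size(
    prediction: SitePrediction,
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """SASA (angstrom^2) of the site's residues in the context of the full
    structure — the site-size criterion used to match site area to binder
    size."""
    result: SasaResult = shrake_rupley_sasa(
        structure,
        selection=prediction.residues,
        probe_radius=probe_radius,
        n_points=n_points,
    )
    return result.total


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_predictions_csv(path: str | Path) -> list[SitePrediction]:
    """Read site predictions from CSV with columns pose_id, rank, chain,
    residue_numbers (semicolon-joined), n_contacts (optional)."""
    df = pd.read_csv(path)
    required = {"pose_id", "rank", "chain", "residue_numbers"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    predictions = []
    for row in df.itertuples(index=False):
        residues = tuple(int(r) for r in str(row.residue_numbers).split(";"))
        n_contacts = (
            int(row.n_contacts)
            if "n_contacts" in df.columns and pd.notna(row.n_contacts)
            else None
        )
        predictions.append(
            SitePrediction(
                pose_id=int(row.pose_id),
                rank=int(row.rank),
                residues=ResidueSelection(str(row.chain), residues),
                n_contacts=n_contacts,
            )
        )
    return predictions


def write_predictions_csv(predictions: list[SitePrediction], path: str | Path) -> None:
    rows = [
        {
            "pose_id": p.pose_id,
            "rank": p.rank,
            "chain": p.residues.chain_id,
            "residue_numbers": ";".join(str(r) for r in p.residues.residue_numbers),
            "n_contacts": p.n_contacts,
        }
        for p in predictions
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_region_map(path: str | Path) -> RegionMap:
    """Read a region map from YAML or JSON: ``{chain: A, regions: {B: [34, ...]}}``
    or a bare ``{label: [residues]}`` mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if "regions" in data:
        chain = data.get("chain", "A")
        regions = data["regions"]
    else:
        chain = "A"
        regions = data
    return RegionMap(
        regions={str(k): frozenset(int(r) for r in v) for k, v in regions.items()},
        chain_id=str(chain),
    )
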
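"""Pluggable scoring backends for the design loop.

Physical docking scores are expensive and external; the machinery here makes
the evolution/clustering/screening pipeline exercisable end to end without
them:

* a synthetic per-position (optionally epistatically coupled) sequence
  fitness landscape with a known global optimum — the standard benchmark for
  checking that the Monte Carlo search actually finds what it should;
* a residue-level contact potential for scoring structures;
* an external-stub scorer that reads precomputed scores (e.g. real docking
  results) from a TSV keyed by sequence or frame, keeping any external
  docking tool at the data boundary.

All scorers return arbitrary units with lower = better.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .geometry import ResidueSelection, Structure

__all__ = [
    "SequenceLandscape",
    "ContactPotential",
    "landscape_score",
    "contact_score",
    "make_landscape",
    "external_stub_scorer",
    "make_scorer",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

MAX_ENUMERATION = 10**6


@dataclass(frozen=True)
class SequenceLandscape:
    """Per-position residue energies plus optional sparse pair couplings.

    ``weights[pos][aa]`` is the energy contribution of residue ``aa`` at
    position ``pos`` (0-based); ``couplings`` maps
    ``((pos_i, aa_i), (pos_j, aa_j))`` to an extra energy applied when both
    hold. ``fixed_positions`` (e.g. anchor cysteines) contribute nothing and
    are excluded from the searchable alphabet. The global optimum over the
    mutable space is computed at construction and stored.
    """

    weights: tuple[dict[str, float], ...]
    alphabet: tuple[str, ...]
    couplings: dict[tuple[tuple[int, str], tuple[int, str]], float] = field(
        default_factory=dict
    )
    fixed_positions: dict[int, str] = field(default_factory=dict)
    optimum_sequence: str = ""

    @property
    def length(self) -> int:
        return len(self.weights)

    def mutable_positions(self) -> list[int]:
        return [i for i in range(self.length) if i not in self.fixed_positions]


def landscape_score(sequence: str, landscape: SequenceLandscape) -> float:
    """E = sum of per-position weights plus active couplings; lower = better."""
    if len(sequence) != landscape.length:
        raise ValueError(
            f"sequence length {len(sequence)} != landscape length {landscape.length}"
        )
    total = 0.0
    for i, aa in enumerate(sequence):
        if i in landscape.fixed_positions:
            continue
        try:
            total += landscape.weights[i][aa]
        except KeyError:
            raise ValueError(f"residue {aa!r} not in landscape alphabet") from None
    for ((i, a), (j, b)), energy in landscape.couplings.items():
        if sequence[i] == a and sequence[j] == b:
            total += energy
    return total


def _enumerate_optimum(
    weights: Sequence[dict[str, float]],
    alphabet: Sequence[str],
    couplings: dict,
    fixed_positions: dict[int, str],
) -> str:
    positions = [i for i in range(len(weights)) if i not in fixed_positions]
    space = len(alphabet) ** len(positions)
    if space > MAX_ENUMERATION:
        raise ValueError(
            f"coupled landscape too large to verify by enumeration ({space} sequences)"
        )
    template = [fixed_positions.get(i, "") for i in range(len(weights))]
    best_seq, best_e = None, np.inf
    probe = SequenceLandscape(
        weights=tuple(weights),
        alphabet=tuple(alphabet),
        couplings=couplings,
        fixed_positions=dict(fixed_positions),
    )
    for combo in itertools.product(alphabet, repeat=len(positions)):
        seq_list = list(template)
        for pos, aa in zip(positions, combo):
            seq_list[pos] = aa
        seq = "".join(seq_list)
        e = landscape_score(seq, probe)
        if e < best_e or (e == best_e and best_seq is not None and seq < best_seq):
            best_seq, best_e = seq, e
    assert best_seq is not None
    return best_seq


def make_landscape(
    length: int,
    alphabet: Sequence[str] = tuple(aa for aa in AMINO_ACIDS if aa != "C"),
    seed: int = 0,
    ruggedness: float = 0.0,
    fixed_positions: dict[int, str] | None = None,
    weight_scale: float = 1.0,
    planted_gap: float | None = None,
) -> SequenceLandscape:
    """Random reproducible landscape with a recorded global optimum.

    ``ruggedness`` in [0, 1] controls the density of random pair couplings
    (0 = fully separable, in which case the optimum is the concatenation of
    per-position argmins). With couplings present the optimum is verified by
    exhaustive enumeration, so the searchable space must stay small.

    ``planted_gap`` plants an identifiable optimum: one uniformly chosen
    residue per mutable position is lowered to (position minimum -
    planted_gap). With i.i.d. normal weights alone, the gap between the best
    and second-best residue at a position is an order statistic that is often
    comparable to the lowest acceptance temperature, so the global optimum is
    not reliably distinguishable by any sampler in finite time; planting a
    gap well above the operating temperature makes the landscape a
    discriminating oracle for optimizer-recovery checks while leaving the
    rest of the landscape random.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= ruggedness <= 1.0:
        raise ValueError("ruggedness must lie in [0, 1]")
    fixed = dict(fixed_positions or {})
    rng = np.random.default_rng(seed)
    alphabet = tuple(alphabet)
    weights_list = []
    for i in range(length):
        w = {
            aa: float(v)
            for aa, v in zip(alphabet, rng.normal(0.0, weight_scale, len(alphabet)))
        }
        if planted_gap is not None and i not in fixed:
            chosen = alphabet[rng.integers(len(alphabet))]
            w[chosen] = min(w.values()) - float(planted_gap)
        weights_list.append(w)
    weights = tuple(weights_list)
    couplings: dict = {}
    if ruggedness > 0:
        positions = [i for i in range(length) if i not in fixed]
        n_pairs = int(round(ruggedness * len(positions)))
        for _ in range(n_pairs):
            i, j = sorted(rng.choice(positions, size=2, replace=False).tolist())
            a = alphabet[rng.integers(len(alphabet))]
            b = alphabet[rng.integers(len(alphabet))]
            couplings[((int(i), a), (int(j), b))] = float(
                rng.normal(0.0, weight_scale)
            )

    if couplings:
        optimum = _enumerate_optimum(weights, alphabet, couplings, fixed)
    else:
        chars = []
        for i in range(length):
            if i in fixed:
                chars.append(fixed[i])
            else:
                # deterministic argmin: lexicographically first on ties
                chars.append(min(alphabet, key=lambda aa: (weights[i][aa], aa)))
        optimum = "".join(chars)
    return SequenceLandscape(
        weights=weights,
        alphabet=alphabet,
        couplings=couplings,
        fixed_positions=fixed,
        optimum_sequence=optimum,
    )


@dataclass(frozen=True)
class ContactPotential:
    """Symmetric residue-pair energies (a.u.) applied when any heavy-atom
    pair of two residues is within the contact cutoff."""

    pair_energies: dict[tuple[str, str], float]
    contact_cutoff: float = 4.5  # angstrom

    def energy(self, res_a: str, res_b: str) -> float:
        key = (res_a, res_b) if res_a <= res_b else (res_b, res_a)
        return self.pair_energies.get(key, 0.0)

    @classmethod
    def from_table(
        cls, table: dict[tuple[str, str], float], contact_cutoff: float = 4.5
    ) -> "ContactPotential":
        symmetric: dict[tuple[str, str], float] = {}
        for (a, b), e in table.items():
            key = (a, b) if a <= b else (b, a)
            if key in symmetric and symmetric[key] != e:
                raise ValueError(f"asymmetric energies for pair {key}")
            symmetric[key] = float(e)
        return cls(pair_energies=symmetric, contact_cutoff=contact_cutoff)


def contact_score(
    structure: Structure,
    selection_a: ResidueSelection,
    selection_b: ResidueSelection,
    potential: ContactPotential,
) -> float:
    """Sum of pair energies over residue pairs across the interface with any
    heavy-atom distance within the cutoff."""
    idx_a = structure.atom_indices(selection_a)
    idx_b = structure.atom_indices(selection_b)
    if set(idx_a) & set(idx_b):
        raise ValueError("selections overlap")
    coords = structure.coordinates

    by_res_a: dict[tuple, list[int]] = {}
    for i in idx_a:
        if structure.atoms[i].element.upper() == "H":
            continue
        by_res_a.setdefault(structure.atoms[i].residue_id, []).append(i)
    by_res_b: dict[tuple, list[int]] = {}
    for j in idx_b:
        if structure.atoms[j].element.upper() == "H":
            continue
        by_res_b.setdefault(structure.atoms[j].residue_id, []).append(j)

    total = 0.0
    cutoff2 = potential.contact_cutoff**2
    for rid_a, atoms_a in by_res_a.items():
        name_a = next(
            structure.atoms[i].residue_name for i in atoms_a
        )
        for rid_b, atoms_b in by_res_b.items():
            name_b = next(structure.atoms[j].residue_name for j in atoms_b)
            d2 = np.min(
                np.sum(
                    (coords[atoms_a][:, None, :] - coords[atoms_b][None, :, :]) ** 2,
                    axis=2,
                )
            )
            if d2 <= cutoff2:
                total += potential.energy(name_a, name_b)
    return total


def external_stub_scorer(path: str | Path) -> Callable[[str], float]:
    """Scorer backed by a two-column TSV of key -> score (keys are sequences
    or frame identifiers). Unknown keys raise, so missing docking results are
    noticed rather than silently defaulted."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path} line {lineno}: expected 'key<TAB>score'")
            table[parts[0]] = float(parts[1])

    def score(key: str) -> float:
        try:
            return table[key]
        except KeyError:
            raise KeyError(f"no precomputed score for {key!r}") from None

    return score


def make_scorer(spec: dict) -> Callable:
    """Resolve a scorer spec dict ({'kind': ..., ...}) to a callable."""
    kind = spec.get("kind")
    if kind == "landscape":
        landscape = make_landscape(
            length=spec["length"],
            alphabet=tuple(spec.get("alphabet", tuple(aa for aa in AMINO_ACIDS if aa != "C"))),
            seed=int(spec.get("seed", 0)),
            ruggedness=float(spec.get("ruggedness", 0.0)),
            fixed_positions={int(k): v for k, v in spec.get("fixed_positions", {}).items()},
        )
        return lambda seq: landscape_score(seq, landscape)
    if kind == "contact_potential":
        raise ValueError(
            "contact_potential scorers need structural context; build one with "
            "contact_score and functools.partial"
        )
    if kind == "external_stub":
        return external_stub_scorer(spec["path"])
    raise ValueError(f"unknown scorer kind {kind!r}")
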
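"""Metropolis Monte Carlo evolution of cyclic peptide sequences.

A cyclic peptide (disulfide-bridged terminal cysteines, default length 12)
is evolved against a pluggable scoring function, lower score = stronger
predicted binding. Single-residue mutations are accepted with the Metropolis
probability

    P_acc = min[1, exp(-(E_new - E_old) / T_MC)]

where T_MC is a dimensionless acceptance temperature. Several replicas at
different T_MC run in parallel and exchange sequences by the standard
parallel-tempering criterion, so low-temperature chains can escape local
minima through the high-temperature ones.

Conformational sampling and physical scoring are abstracted behind the scorer
interface (see :mod:`pepevolve.surrogate_scoring`): any callable mapping a
sequence to a finite score can drive the evolution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeptideState",
    "EvolutionConfig",
    "AttemptRecord",
    "ExchangeRecord",
    "EvolutionTrajectory",
    "propose_mutation",
    "metropolis_accept",
    "attempt_exchange",
    "run_evolution",
    "select_candidates",
    "DEFAULT_ALPHABET",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# Cysteine is reserved for the two anchor positions so the single disulfide
# bridge that closes the cycle stays unique.
DEFAULT_ALPHABET = tuple(aa for aa in AMINO_ACIDS if aa != "C")

Scorer = Callable[[str], float]


@dataclass(frozen=True)
class PeptideState:
    """A cyclic peptide sequence under evolution.

    ``anchors`` are 1-based positions pinned to Cys (default the termini of a
    dodecapeptide); all other positions are mutable and never hold Cys.
    """

    sequence: str
    anchors: tuple[int, ...] = (1, 12)
    cyclic: bool = True
    score: float | None = None
    step_index: int = 0

    def __post_init__(self) -> None:
        for pos in self.anchors:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"anchor position {pos} outside sequence")
            if self.sequence[pos - 1] != "C":
                raise ValueError(f"anchor position {pos} must hold 'C'")
        for i, aa in enumerate(self.sequence, start=1):
            if aa == "C" and i not in self.anchors:
                raise ValueError(f"non-anchor Cys at position {i}")

    @property
    def mutable_positions(self) -> tuple[int, ...]:
        """0-based indices of mutable positions."""
        anchor_set = {a - 1 for a in self.anchors}
        return tuple(i for i in range(len(self.sequence)) if i not in anchor_set)

    @classmethod
    def polyalanine(cls, length: int = 12) -> "PeptideState":
        """The canonical starting binder: Cys1-polyalanine-Cys_n."""
        return cls(sequence="C" + "A" * (length - 2) + "C", anchors=(1, length))


@dataclass(frozen=True)
class EvolutionConfig:
    """Run parameters for the replica-exchange Metropolis evolution."""

    t_mc_values: tuple[float, ...] = (0.3, 0.6, 0.9)
    n_steps: int = 1000
    exchange_interval: int = 10
    mutable_alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    seed: int = 0

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.t_mc_values)
        if any(t <= 0 for t in ts):
            raise ValueError("t_mc_values must be strictly positive")
        if list(ts) != sorted(ts) or len(set(ts)) != len(ts):
            raise ValueError("t_mc_values must be strictly ascending")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.exchange_interval < 1:
            raise ValueError("exchange_interval must be >= 1")
        if not self.mutable_alphabet:
            raise ValueError("mutable alphabet is empty")
        object.__setattr__(self, "t_mc_values", ts)
        object.__setattr__(self, "mutable_alphabet", tuple(self.mutable_alphabet))


@dataclass(frozen=True)
class AttemptRecord:
    step: int
    sequence: str
    proposed_sequence: str
    e_old: float
    e_new: float
    accepted: bool


@dataclass(frozen=True)
class ExchangeRecord:
    step: int
    replica_pair: tuple[int, int]
    accepted: bool


@dataclass
class EvolutionTrajectory:
    """Complete bookkeeping of one evolution run: every mutation attempt per
    replica and every exchange attempt between replicas."""

    t_mc_values: tuple[float, ...]
    initial_states: list[PeptideState]
    replicas: list[list[AttemptRecord]]
    exchange_events: list[ExchangeRecord]
    final_states: list[PeptideState]

    def evaluated_sequences(self) -> dict[str, float]:
        """Every sequence with a known score, mapped to its best score."""
        best: dict[str, float] = {}

        def update(seq: str, score: float) -> None:
            if seq not in best or score < best[seq]:
                best[seq] = score

        for state in self.initial_states:
            if state.score is not None:
                update(state.sequence, state.score)
        for records in self.replicas:
            for rec in records:
                update(rec.sequence, rec.e_old)
                update(rec.proposed_sequence, rec.e_new)
        return best

    def acceptance_ratio(self, replica: int) -> float:
        records = self.replicas[replica]
        if not records:
            return float("nan")
        return sum(r.accepted for r in records) / len(records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, records in enumerate(self.replicas):
            for rec in records:
                rows.append(
                    {
                        "replica": i,
                        "t_mc": self.t_mc_values[i],
                        "step": rec.step,
                        "sequence": rec.sequence,
                        "proposed_sequence": rec.proposed_sequence,
                        "e_old": rec.e_old,
                        "e_new": rec.e_new,
                        "accepted": rec.accepted,
                    }
                )
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        best = self.evaluated_sequences()
        best_seq = min(best, key=lambda s: (best[s], s)) if best else None
        return {
            "n_replicas": len(self.replicas),
            "t_mc_values": list(self.t_mc_values),
            "n_steps": len(self.replicas[0]) if self.replicas else 0,
            "n_exchanges_attempted": len(self.exchange_events),
            "n_exchanges_accepted": sum(e.accepted for e in self.exchange_events),
            "acceptance_ratios": [
                self.acceptance_ratio(i) for i in range(len(self.replicas))
            ],
            "best_sequence": best_seq,
            "best_score": best[best_seq] if best_seq else None,
        }

    def write_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


# ---------------------------------------------------------------------------
# Elementary moves
# ---------------------------------------------------------------------------

def propose_mutation(
    state: PeptideState,
    rng: np.random.Generator,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
) -> str:
    """Mutate one uniformly chosen mutable position to a uniformly chosen
    different residue from *alphabet*; anchors are never touched."""
    positions = state.mutable_positions
    if not positions:
        raise ValueError("no mutable positions")
    pos = positions[rng.integers(len(positions))]
    current = state.sequence[pos]
    choices = [aa for aa in alphabet if aa != current]
    if not choices:
        raise ValueError("alphabet empty after excluding the current residue")
    new_aa = choices[rng.integers(len(choices))]
    return state.sequence[:pos] + new_aa + state.sequence[pos + 1 :]


def metropolis_accept(
    e_old: float, e_new: float, t_mc: float, rng: np.random.Generator
) -> bool:
    """Metropolis acceptance: probability min[1, exp(-(e_new - e_old)/t_mc)].

    Exactly one uniform variate is drawn per call, keeping replica random
    streams aligned regardless of the outcome.
    """
    if t_mc <= 0:
        raise ValueError("t_mc must be > 0")
    if not (math.isfinite(e_old) and math.isfinite(e_new)):
        raise ValueError("energies must be finite")
    u = rng.random()
    p_acc = min(1.0, math.exp(-(e_new - e_old) / t_mc))
    return u < p_acc


def attempt_exchange(
    t_i: float,
    t_j: float,
    e_i: float,
    e_j: float,
    rng: np.random.Generator,
) -> bool:
    """Parallel-tempering swap criterion for two replicas:
    accept with probability min[1, exp((1/T_i - 1/T_j)(E_i - E_j))]."""
    if t_i == t_j:
        raise ValueError("replica temperatures must differ")
    if not (math.isfinite(e_i) and math.isfinite(e_j)):
        raise ValueError("energies must be finite")
    u = rng.random()
    p_acc = min(1.0, math.exp((1.0 / t_i - 1.0 / t_j) * (e_i - e_j)))
    return u < p_acc


# ---------------------------------------------------------------------------
# The evolution loop
# ---------------------------------------------------------------------------

def run_evolution(
    initial: PeptideState,
    config: EvolutionConfig,
    scorer: Scorer,
) -> EvolutionTrajectory:
    """Run the replica-exchange Metropolis evolution.

    Every replica starts from *initial*, performs ``n_steps`` single-mutation
    attempts, and adjacent-temperature pairs attempt sequence swaps every
    ``exchange_interval`` steps (alternating even/odd pairings). The run is
    bit-reproducible given ``config.seed``: each replica draws from its own
    child stream of the master seed and exchanges from a dedicated stream.
    """
    n_rep = len(config.t_mc_values)
    seed_seq = np.random.SeedSequence(config.seed)
    children = seed_seq.spawn(n_rep + 1)
    replica_rngs = [np.random.default_rng(s) for s in children[:n_rep]]
    exchange_rng = np.random.default_rng(children[n_rep])

    def score_of(seq: str) -> float:
        value = float(scorer(seq))
        if not math.isfinite(value):
            raise ValueError(f"scorer returned non-finite value for {seq!r}")
        return value

    e0 = score_of(initial.sequence)
    states = [replace(initial, score=e0, step_index=0) for _ in range(n_rep)]
    initial_states = list(states)
    records: list[list[AttemptRecord]] = [[] for _ in range(n_rep)]
    exchanges: list[ExchangeRecord] = []

    for step in range(1, config.n_steps + 1):
        for r in range(n_rep):
            state = states[r]
            try:
                proposed = propose_mutation(
                    state, replica_rngs[r], config.mutable_alphabet
                )
                e_new = score_of(proposed)
            except ValueError as exc:
                raise RuntimeError(
                    f"evolution aborted at step {step}, replica {r}: {exc}"
                ) from exc
            e_old = state.score
            assert e_old is not None
            accepted = metropolis_accept(
                e_old, e_new, config.t_mc_values[r], replica_rngs[r]
            )
            records[r].append(
                AttemptRecord(
                    step=step,
                    sequence=state.sequence,
                    proposed_sequence=proposed,
                    e_old=e_old,
                    e_new=e_new,
                    accepted=accepted,
                )
            )
            if accepted:
                states[r] = replace(
                    state, sequence=proposed, score=e_new, step_index=step
                )

        if step % config.exchange_interval == 0 and n_rep > 1:
            phase = (step // config.exchange_interval) % 2
            for i in range(phase, n_rep - 1, 2):
                j = i + 1
                si, sj = states[i], states[j]
                assert si.score is not None and sj.score is not None
                accepted = attempt_exchange(
                    config.t_mc_values[i],
                    config.t_mc_values[j],
                    si.score,
                    sj.score,
                    exchange_rng,
                )
                exchanges.append(
                    ExchangeRecord(step=step, replica_pair=(i, j), accepted=accepted)
                )
                if accepted:
                    states[i], states[j] = (
                        replace(sj, step_index=step),
                        replace(si, step_index=step),
                    )

    return EvolutionTrajectory(
        t_mc_values=config.t_mc_values,
        initial_states=initial_states,
        replicas=records,
        exchange_events=exchanges,
        final_states=states,
    )


def select_candidates(
    trajectory: EvolutionTrajectory,
    k: int,
    solubility_filter: Callable[[str], bool] | None = None,
) -> list[tuple[str, float]]:
    """Top-*k* unique sequences from a trajectory by best attained score,
    after the solubility gate; deterministic (score, then lexicographic)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    best = trajectory.evaluated_sequences()
    survivors = [
        (seq, score)
        for seq, score in best.items()
        if solubility_filter is None or solubility_filter(seq)
    ]
    survivors.sort(key=lambda item: (item[1], item[0]))
    return survivors[:k]


def write_candidates_fasta(
    candidates: list[tuple[str, float]], path: str | Path, prefix: str = "pep"
) -> None:
    """Write selected candidates as FASTA, score annotated in the header."""
    with open(path, "w") as fh:
        for i, (seq, score) in enumerate(candidates, start=1):
            fh.write(f">{prefix}{i} score={score:.4f}\n{seq}\n")
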
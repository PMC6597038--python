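"""Synthetic targets and scripted movesets for tests and benchmarks.

Real design benchmarks and player move logs are external resources; this
module generates stand-ins with the same shapes: random valid secondary
structures with a controllable motif mix, a deterministic "teacher" that
solves a target with the canonical player strategies while logging every
move as a training example, and a tiered benchmark TSV writer.

The teacher's movesets are stereotyped by construction — each move's
base is a fixed function of the local motif (complement a mismatch,
guanine boosts, U-G super boosts, G-C closing pairs) — which gives
move-predictor training a learnable signal with a clean upper bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .core import (
    CANONICAL_PAIRS,
    COMPLEMENT,
    Move,
    PuzzleState,
    apply_moves,
    dotbracket_to_pairmap,
    find_motifs,
    locks_to_string,
    parse_locks,
)
from .folding import FoldingEngine, make_state, refold
from .policy import MoveRecord
from .core import encode_state

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StructureGenConfig:
    """Random-structure generator settings.

    Motif weights control which element is nested inside each stem;
    max_depth bounds nesting (depth 1 = a single stem-loop).  The
    minimum hairpin size of 3 is the physical constraint enforced by
    nearest-neighbor folding engines.
    """

    min_len: int = 12
    max_len: int = 40
    hairpin_weight: float = 1.0
    bulge_weight: float = 0.3
    internal_weight: float = 0.3
    multiloop_weight: float = 0.0
    min_hairpin: int = 3
    max_hairpin: int = 8
    min_stem: int = 3
    max_stem: int = 7
    max_depth: int = 2

    def __post_init__(self):
        if self.min_hairpin < 3:
            raise ValueError("minimum hairpin loop size is 3")
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        total = (self.hairpin_weight + self.bulge_weight
                 + self.internal_weight + self.multiloop_weight)
        if total <= 0:
            raise ValueError("at least one motif weight must be positive")
        # Smallest possible structure: one minimal stem-loop.
        if 2 * self.min_stem + self.min_hairpin > self.max_len:
            raise ValueError(
                "max_len too small for one minimal stem-loop "
                f"({2 * self.min_stem + self.min_hairpin})"
            )


def _unit(cfg: StructureGenConfig, rng: np.random.Generator,
          budget: int, depth: int) -> str:
    """One stem enclosing a randomly chosen interior, within ``budget``."""
    min_unit = 2 * cfg.min_stem + cfg.min_hairpin
    stem_max = min(cfg.max_stem, (budget - cfg.min_hairpin) // 2)
    s = int(rng.integers(cfg.min_stem, stem_max + 1))
    inner = budget - 2 * s

    kinds, weights = ["hairpin"], [cfg.hairpin_weight]
    if depth < cfg.max_depth:
        if inner >= min_unit + 1:
            kinds.append("bulge")
            weights.append(cfg.bulge_weight)
        if inner >= min_unit + 2:
            kinds.append("internal")
            weights.append(cfg.internal_weight)
        if inner >= 2 * min_unit + 3:
            kinds.append("multiloop")
            weights.append(cfg.multiloop_weight)
    weights = np.array(weights, dtype=float)
    if weights.sum() <= 0:
        kind = "hairpin"
    else:
        kind = kinds[int(rng.choice(len(kinds), p=weights / weights.sum()))]

    if kind == "hairpin":
        h = int(rng.integers(cfg.min_hairpin, min(cfg.max_hairpin, inner) + 1))
        body = "." * h
    elif kind == "bulge":
        b = int(rng.integers(1, min(3, inner - min_unit) + 1))
        child = _unit(cfg, rng, inner - b, depth + 1)
        body = "." * b + child if rng.random() < 0.5 else child + "." * b
    elif kind == "internal":
        # Bias toward the 2x2 loops the super-boost strategy targets.
        if inner >= min_unit + 4 and rng.random() < 0.5:
            m = n = 2
        else:
            m = int(rng.integers(1, min(3, inner - min_unit - 1) + 1))
            n = int(rng.integers(1, min(3, inner - min_unit - m) + 1))
        child = _unit(cfg, rng, inner - m - n, depth + 1)
        body = "." * m + child + "." * n
    else:  # multiloop with two branches
        sep = int(rng.integers(1, 3))
        if inner - 3 * sep < 2 * min_unit:
            sep = 1
        half = (inner - 3 * sep) // 2
        left = _unit(cfg, rng, half, depth + 1)
        right = _unit(cfg, rng, inner - 3 * sep - len(left), depth + 1)
        body = "." * sep + left + "." * sep + right + "." * sep
    return "(" * s + body + ")" * s


def random_structure(cfg: StructureGenConfig,
                     rng: np.random.Generator) -> str:
    """Draw a balanced, non-crossing dot-bracket structure.

    The generated length falls in [min_len, max_len]; generation retries
    until the budgeted recursion lands in range (an error after many
    retries signals infeasible constraints).
    """
    for _ in range(200):
        budget = int(rng.integers(cfg.min_len, cfg.max_len + 1))
        pad5 = int(rng.integers(0, 3))
        pad3 = int(rng.integers(0, 3))
        inner_budget = budget - pad5 - pad3
        if inner_budget < 2 * cfg.min_stem + cfg.min_hairpin:
            continue
        db = "." * pad5 + _unit(cfg, rng, inner_budget, 1) + "." * pad3
        if cfg.min_len <= len(db) <= cfg.max_len:
            dotbracket_to_pairmap(db)  # generator contract: always valid
            return db
    raise ValueError("structure generation failed; constraints infeasible")


# ---------------------------------------------------------------------------
# Scripted teacher


def teacher_moves(state: PuzzleState) -> list[Move]:
    """The stereotyped solving script for a target, in canonical order.

    1. complement mismatched target pairs (keep the lower-index base);
    2. U-G super boost in 2x2 internal loops;
    3. G boost at the first position of other internal-loop strands;
    4. G boost at the first position of hairpin loops;
    5. G-C closing pairs (G on the 5' side) at loop-flanking stem ends.

    Locked positions and no-op edits are skipped; moves are emitted in
    5'->3' motif order, one base change per move.
    """
    seq = list(state.sequence)
    moves: list[Move] = []

    def put(pos: int, base: str):
        if not state.locked[pos] and seq[pos] != base:
            moves.append(Move(pos, base))
            seq[pos] = base

    motifs = find_motifs(state.target_pm)
    stems = [m for m in motifs if m.kind == "stem"]
    for stem in sorted(stems, key=lambda m: m.positions[0]):
        pos = stem.positions
        half = len(pos) // 2
        for k in range(half):
            i, j = pos[k], pos[len(pos) - 1 - k]
            if seq[i] + seq[j] in CANONICAL_PAIRS:
                continue
            if not state.locked[j]:
                put(j, COMPLEMENT[seq[i]])
            elif not state.locked[i]:
                put(i, COMPLEMENT[seq[j]])
    loops = sorted(
        (m for m in motifs if m.kind in
         ("internal_loop", "bulge", "hairpin_loop")),
        key=lambda m: (m.positions[0] if m.positions else -1),
    )
    for loop in loops:
        if loop.kind == "internal_loop" and \
                tuple(len(s) for s in loop.strands) == (2, 2):
            for strand in loop.strands:
                for p, base in zip(strand, "UG"):
                    put(p, base)
        elif loop.kind in ("internal_loop", "bulge"):
            for strand in loop.strands:
                if strand:
                    put(strand[0], "G")
        elif loop.kind == "hairpin_loop" and loop.positions:
            put(loop.positions[0], "G")
    for loop in loops:
        for (i, j) in loop.closing:
            if {seq[i], seq[j]} == {"G", "C"}:
                continue
            if not state.locked[i] and not state.locked[j]:
                put(i, "G")
                put(j, "C")
    return moves


def teacher_playout(
    target: str,
    engine: FoldingEngine,
    locks: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Optional[str], list[MoveRecord]]:
    """Solve ``target`` with the scripted teacher, logging every move.

    Returns the solution sequence (None if the script fails to solve the
    target, which excludes it from dataset building) and one MoveRecord
    per move: the encoded state *before* the move plus the move labels.
    The script is deterministic; ``rng`` is accepted for interface
    symmetry but unused.
    """
    locked = parse_locks(locks, len(target))
    start = "A" * len(target)
    state = make_state(start, target, engine, locks=locks)
    records: list[MoveRecord] = []
    for move in teacher_moves(state):
        records.append(MoveRecord(encode_state(state), move.new_base,
                                  move.position))
        new_seq = apply_moves(state.sequence, [move], locked)
        state = refold(state, new_seq, engine)
    if not state.solved:
        logger.info("teacher failed to solve target %s", target)
        return None, records
    return state.sequence, records


def teacher_dataset(
    targets: list[str],
    engine: FoldingEngine,
) -> list[MoveRecord]:
    """Move records from every teacher-solvable target in ``targets``."""
    records: list[MoveRecord] = []
    for target in targets:
        solution, recs = teacher_playout(target, engine)
        if solution is not None:
            records.extend(recs)
    return records


# ---------------------------------------------------------------------------
# Benchmark files


#: Generation settings for the graded benchmark tiers: "easy" is single
#: hairpins and two-stem structures up to 40 nt; "medium" adds internal
#: loops and multiloops up to 80 nt and requires at least one of those
#: motifs to appear.
TIERS = {
    "easy": StructureGenConfig(
        min_len=12, max_len=40, hairpin_weight=1.0, bulge_weight=0.25,
        internal_weight=0.25, multiloop_weight=0.0, max_depth=2,
        min_stem=4, min_hairpin=4,
    ),
    "medium": StructureGenConfig(
        min_len=30, max_len=80, hairpin_weight=0.4, bulge_weight=0.3,
        internal_weight=0.5, multiloop_weight=0.4, max_depth=3,
        min_stem=4, min_hairpin=4,
    ),
}

_TIER_REQUIRED = {"easy": None, "medium": {"internal_loop", "multiloop"}}


def tier_structures(tier: str, n: int, rng: np.random.Generator) -> list[str]:
    """Draw ``n`` structures from a named tier's generator settings."""
    cfg = TIERS[tier]
    required = _TIER_REQUIRED[tier]
    out = []
    while len(out) < n:
        db = random_structure(cfg, rng)
        if required is not None:
            kinds = {m.kind for m in find_motifs(dotbracket_to_pairmap(db))}
            if not (kinds & required):
                continue
        out.append(db)
    return out


def make_benchmark(path, n: int = 20, tier: str = "easy",
                   rng: Optional[np.random.Generator] = None) -> Path:
    """Write an ``n``-row benchmark TSV: name, structure, lock string."""
    rng = rng if rng is not None else np.random.default_rng(0)
    path = Path(path)
    rows = []
    for k, db in enumerate(tier_structures(tier, n, rng)):
        locks = locks_to_string([False] * len(db))
        rows.append(f"{tier}_{k:03d}\t{db}\t{locks}")
    path.write_text("\n".join(rows) + "\n")
    return path
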
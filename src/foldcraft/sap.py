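"""Single-action playout (SAP): canonical player strategies for RNA design.

SAP applies six hand-coded strategies that experienced puzzle players use,
in a fixed order:

1. fix mismatches — make every target base pair Watson-Crick (A-U or G-C);
2. G-C end pairs — strengthen stem closing pairs that flank loops;
3. G internal-loop boost — guanine at the first position of each internal
   loop strand;
4. U-G-U-G super boost — U,G on both strands of a 2x2 internal loop
   (exploits the tandem G·U bonus of nearest-neighbor models);
5. G hairpin boost — guanine at the start of each hairpin loop;
6. flip pairs — reorient base pairs in target helices that are misfolded.

Each strategy proposes local candidate edits per motif; a candidate is
accepted only if, after refolding, the natural structure is strictly
closer to the target under the similarity metric, and reverted otherwise.
Sweeps over the strategy list repeat until nothing is accepted or the
sweep budget is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from difflib import SequenceMatcher
from typing import Iterator, Optional

import numpy as np

from .core import (
    CANONICAL_PAIRS,
    COMPLEMENT,
    Move,
    PuzzleState,
    StructureError,
    apply_moves,
    find_motifs,
)
from .folding import FoldingEngine, refold

STRATEGY_ORDER = (
    "fix_mismatches",
    "gc_end_pairs",
    "g_internal_loop_boost",
    "ugug_superboost",
    "g_hairpin_boost",
    "flip_pairs",
)


def similarity(db_a: str, db_b: str, mode: str = "ratio") -> float:
    """Closeness of two dot-bracket structures, in [0, 1].

    ``ratio`` (default) is the longest-contiguous-matching-block ratio
    2M/T of difflib's SequenceMatcher (autojunk disabled — structure
    strings have a 3-symbol alphabet, so the junk heuristic must not
    fire).  ``longest_block`` is the length of the single largest common
    block divided by the string length, the un-normalized variant.
    """
    if len(db_a) != len(db_b):
        raise StructureError(
            f"similarity requires equal lengths, got {len(db_a)} and {len(db_b)}"
        )
    if not db_a:
        return 1.0
    sm = SequenceMatcher(None, db_a, db_b, autojunk=False)
    if mode == "ratio":
        return sm.ratio()
    if mode == "longest_block":
        return sm.find_longest_match(0, len(db_a), 0, len(db_b)).size / len(db_a)
    raise ValueError(f"unknown similarity mode {mode!r}")


@dataclass(frozen=True)
class SapConfig:
    """SAP driver settings.

    max_sweeps bounds the number of passes over the strategy list;
    flip_attempts bounds the orientation patterns tried per misfolded
    helix (with >= 2^k attempts on a k-pair helix the search is
    exhaustive).  boost_hairpin_both_ends optionally also boosts the last
    hairpin-loop position.
    """

    max_sweeps: int = 5
    flip_attempts: int = 16
    similarity_mode: str = "ratio"
    boost_hairpin_both_ends: bool = False

    def __post_init__(self):
        if self.max_sweeps < 1 or self.flip_attempts < 1:
            raise ValueError("max_sweeps and flip_attempts must be positive")


@dataclass
class Candidate:
    """One motif-local proposal: alternative move lists, best one kept."""

    strategy: str
    variants: list[list[Move]]


@dataclass
class StrategyOutcome:
    """Result of one strategy pass over the whole puzzle."""

    strategy: str
    candidates: int
    #: the motif-local proposals considered (before accept/revert)
    proposed: list[Candidate]
    accepted_moves: list[Move]
    #: per accepted candidate: (moves applied together, similarity reached)
    accepted_steps: list[tuple[list[Move], float]]
    accepted: bool
    similarity_before: float
    similarity_after: float
    energy_before: float
    energy_after: float
    state: PuzzleState


@dataclass
class SapResult:
    state: PuzzleState
    solved: bool
    #: accepted steps: (strategy, moves applied together, similarity after)
    trace: list[tuple[str, list[Move], float]]
    sweeps: int
    outcomes: list[StrategyOutcome] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Candidate generators (pure: no folding, no acceptance)


def _target_stems(state: PuzzleState):
    return [m for m in find_motifs(state.target_pm) if m.kind == "stem"]


def _target_loops(state: PuzzleState, kinds):
    return [m for m in find_motifs(state.target_pm) if m.kind in kinds]


def _stem_pairs(stem) -> list[tuple[int, int]]:
    pos = stem.positions
    half = len(pos) // 2
    return [(pos[k], pos[len(pos) - 1 - k]) for k in range(half)]


def candidates_fix_mismatches(state: PuzzleState) -> list[Candidate]:
    """One candidate per target stem, complementing every mismatched pair.

    The lower-index base of a mismatch is kept and its partner set to the
    Watson-Crick complement (always yielding A-U or G-C); when the lower
    base is locked the unlocked partner is complemented instead, and
    fully locked pairs are skipped.  G-U already counts as paired.
    """
    out = []
    for stem in _target_stems(state):
        moves = []
        for i, j in _stem_pairs(stem):
            if state.sequence[i] + state.sequence[j] in CANONICAL_PAIRS:
                continue
            if not state.locked[j]:
                moves.append(Move(j, COMPLEMENT[state.sequence[i]]))
            elif not state.locked[i]:
                moves.append(Move(i, COMPLEMENT[state.sequence[j]]))
        moves = [m for m in moves if state.sequence[m.position] != m.new_base]
        if moves:
            out.append(Candidate("fix_mismatches", [moves]))
    return out


def candidates_gc_end_pairs(state: PuzzleState) -> list[Candidate]:
    """G-C at stem closing pairs adjacent to a loop.

    An "end pair" is any stem closing pair that flanks a hairpin,
    internal loop (incl. bulges) or multiloop.  Both orientations (G on
    the 5' or the 3' side) are offered; the driver keeps whichever
    refolds better.  Pairs already G-C, or locked to a non-G/C base,
    produce no candidate.
    """
    out = []
    seen = set()
    for loop in _target_loops(
        state, ("hairpin_loop", "internal_loop", "bulge", "multiloop")
    ):
        for (i, j) in loop.closing:
            if (i, j) in seen:
                continue
            seen.add((i, j))
            bi, bj = state.sequence[i], state.sequence[j]
            if {bi, bj} == {"G", "C"}:
                continue
            li, lj = state.locked[i], state.locked[j]
            variants = []
            if not li and not lj:
                variants = [[Move(i, "G"), Move(j, "C")],
                            [Move(i, "C"), Move(j, "G")]]
            elif li and not lj and bi in "GC":
                variants = [[Move(j, COMPLEMENT[bi])]]
            elif lj and not li and bj in "GC":
                variants = [[Move(i, COMPLEMENT[bj])]]
            variants = [
                [m for m in v if state.sequence[m.position] != m.new_base]
                for v in variants
            ]
            variants = [v for v in variants if v]
            if variants:
                out.append(Candidate("gc_end_pairs", variants))
    return out


def candidates_g_internal_loop_boost(state: PuzzleState) -> list[Candidate]:
    """Guanine at the first unpaired position (5'->3') of each internal-loop
    strand; a bulge boosts only its non-empty strand."""
    out = []
    for loop in _target_loops(state, ("internal_loop", "bulge")):
        moves = []
        for strand in loop.strands:
            if not strand:
                continue
            p = strand[0]
            if state.sequence[p] != "G" and not state.locked[p]:
                moves.append(Move(p, "G"))
        if moves:
            out.append(Candidate("g_internal_loop_boost", [moves]))
    return out


def candidates_ugug_superboost(state: PuzzleState) -> list[Candidate]:
    """U,G (5'->3') on both strands of every 2x2 internal loop."""
    out = []
    for loop in _target_loops(state, ("internal_loop",)):
        if tuple(len(s) for s in loop.strands) != (2, 2):
            continue
        moves = []
        for strand in loop.strands:
            for p, base in zip(strand, "UG"):
                if state.sequence[p] != base and not state.locked[p]:
                    moves.append(Move(p, base))
        if moves:
            out.append(Candidate("ugug_superboost", [moves]))
    return out


def candidates_g_hairpin_boost(
    state: PuzzleState, both_ends: bool = False
) -> list[Candidate]:
    """Guanine at the first position of each hairpin loop (optionally also
    the last, for the two-terminal variant)."""
    out = []
    for loop in _target_loops(state, ("hairpin_loop",)):
        if not loop.positions:
            continue
        targets = [loop.positions[0]]
        if both_ends and len(loop.positions) > 1:
            targets.append(loop.positions[-1])
        moves = [
            Move(p, "G")
            for p in targets
            if state.sequence[p] != "G" and not state.locked[p]
        ]
        if moves:
            out.append(Candidate("g_hairpin_boost", [moves]))
    return out


def misfolded_helices(state: PuzzleState):
    """Target stems whose pairs are not all present in the natural fold."""
    out = []
    for stem in _target_stems(state):
        pairs = _stem_pairs(stem)
        if any(state.natural_pm[i] != j for i, j in pairs):
            out.append(stem)
    return out


def candidates_flip_pairs(
    state: PuzzleState, attempts: int, rng: np.random.Generator
) -> list[Candidate]:
    """Random pair-orientation swaps within each misfolded target helix.

    An orientation pattern is a bitmask over the helix's pairs; bit set
    means the two bases of that pair are exchanged.  With ``attempts >=
    2^k`` all non-trivial patterns of a k-pair helix are enumerated
    (exhaustive search); otherwise ``attempts`` distinct patterns are
    sampled.  Locked or same-base pairs are never flipped.
    """
    out = []
    for stem in misfolded_helices(state):
        pairs = [
            (i, j)
            for i, j in _stem_pairs(stem)
            if not state.locked[i] and not state.locked[j]
            and state.sequence[i] != state.sequence[j]
        ]
        k = len(pairs)
        if k == 0:
            continue
        n_patterns = (1 << k) - 1  # non-zero masks
        if attempts >= n_patterns:
            masks = list(range(1, (1 << k)))
        else:
            masks = list(
                rng.choice(np.arange(1, 1 << k), size=attempts, replace=False)
            )
        variants = []
        for mask in masks:
            moves = []
            for b, (i, j) in enumerate(pairs):
                if (int(mask) >> b) & 1:
                    moves.append(Move(i, state.sequence[j]))
                    moves.append(Move(j, state.sequence[i]))
            variants.append(moves)
        out.append(Candidate("flip_pairs", variants))
    return out


def generate_candidates(
    state: PuzzleState,
    strategy: str,
    cfg: SapConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[Candidate]:
    if strategy == "fix_mismatches":
        return candidates_fix_mismatches(state)
    if strategy == "gc_end_pairs":
        return candidates_gc_end_pairs(state)
    if strategy == "g_internal_loop_boost":
        return candidates_g_internal_loop_boost(state)
    if strategy == "ugug_superboost":
        return candidates_ugug_superboost(state)
    if strategy == "g_hairpin_boost":
        return candidates_g_hairpin_boost(state, cfg.boost_hairpin_both_ends)
    if strategy == "flip_pairs":
        if rng is None:
            raise ValueError("flip_pairs requires a random generator")
        return candidates_flip_pairs(state, cfg.flip_attempts, rng)
    raise ValueError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# Acceptance driver


def _evaluate_candidate(
    state: PuzzleState,
    cand: Candidate,
    engine: FoldingEngine,
    mode: str,
) -> Optional[tuple[PuzzleState, list[Move], float]]:
    """Best strictly-improving variant of a candidate, or None."""
    sim0 = similarity(state.natural_db, state.target_db, mode)
    best = None
    for variant in cand.variants:
        moves = [m for m in variant if state.sequence[m.position] != m.new_base]
        if not moves:
            continue
        new_seq = apply_moves(state.sequence, moves, state.locked)
        new_state = refold(state, new_seq, engine)
        sim = similarity(new_state.natural_db, new_state.target_db, mode)
        if sim > sim0 and (best is None or sim > best[2]):
            best = (new_state, moves, sim)
    return best


def apply_strategy(
    state: PuzzleState,
    strategy: str,
    engine: FoldingEngine,
    cfg: Optional[SapConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> StrategyOutcome:
    """Run one strategy over all its motifs with local accept/revert."""
    cfg = cfg or SapConfig()
    sim_before = similarity(state.natural_db, state.target_db, cfg.similarity_mode)
    e_before = state.natural_energy
    cands = generate_candidates(state, strategy, cfg, rng)
    accepted: list[Move] = []
    steps: list[tuple[list[Move], float]] = []
    current = state
    for cand in cands:
        result = _evaluate_candidate(current, cand, engine, cfg.similarity_mode)
        if result is not None:
            current, moves, sim = result
            accepted.extend(moves)
            steps.append((moves, sim))
    sim_after = similarity(current.natural_db, current.target_db, cfg.similarity_mode)
    return StrategyOutcome(
        strategy=strategy,
        candidates=len(cands),
        proposed=cands,
        accepted_moves=accepted,
        accepted_steps=steps,
        accepted=bool(accepted),
        similarity_before=sim_before,
        similarity_after=sim_after,
        energy_before=e_before,
        energy_after=current.natural_energy,
        state=current,
    )


def fix_mismatches(state, engine, cfg=None):
    return apply_strategy(state, "fix_mismatches", engine, cfg)


def gc_end_pairs(state, engine, cfg=None):
    return apply_strategy(state, "gc_end_pairs", engine, cfg)


def g_internal_loop_boost(state, engine, cfg=None):
    return apply_strategy(state, "g_internal_loop_boost", engine, cfg)


def ugug_superboost(state, engine, cfg=None):
    return apply_strategy(state, "ugug_superboost", engine, cfg)


def g_hairpin_boost(state, engine, cfg=None):
    return apply_strategy(state, "g_hairpin_boost", engine, cfg)


def flip_pairs(state, engine, rng, cfg=None):
    return apply_strategy(state, "flip_pairs", engine, cfg, rng)


#: strategies whose similarity-neutral edits may be held provisionally
#: (the deterministic, motif-directed ones; random flips commit strictly).
_PROVISIONAL_OK = frozenset(STRATEGY_ORDER[:-1])

_TIE_EPS = 1e-12


def sap_solve(
    state: PuzzleState,
    engine: FoldingEngine,
    cfg: Optional[SapConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> SapResult:
    """Apply the strategies in canonical order until solved or stalled.

    A candidate edit *commits* only when it makes similarity(natural,
    target) strictly larger than at the last committed step, so the
    committed trace is strictly monotone.  Because early strategy edits
    (e.g. complementing a weak helix) often leave the fold unchanged
    until later edits stabilize it, similarity-*neutral* edits from the
    deterministic strategies are kept provisionally within a sweep: they
    become part of the next committing step, or are rolled back when the
    sweep ends without one.  Edits that lower similarity always revert
    immediately.  Sweeps stop when nothing commits, when the puzzle is
    solved, or at ``cfg.max_sweeps``.  Deterministic given (state, cfg,
    rng seed).
    """
    cfg = cfg or SapConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    mode = cfg.similarity_mode

    committed = state
    committed_sim = similarity(state.natural_db, state.target_db, mode)
    working = committed            # committed + provisional edits
    pending_moves: list[Move] = []
    trace: list[tuple[str, list[Move], float]] = []
    outcomes: list[StrategyOutcome] = []
    sweeps = 0

    while sweeps < cfg.max_sweeps and not committed.solved:
        sweeps += 1
        sweep_committed = False
        for strategy in STRATEGY_ORDER:
            cands = generate_candidates(working, strategy, cfg, rng)
            sim_before = similarity(working.natural_db, working.target_db, mode)
            e_before = working.natural_energy
            strategy_steps: list[tuple[list[Move], float]] = []
            strategy_moves: list[Move] = []
            for cand in cands:
                best = None  # (sim, -energy, state, moves)
                for variant in cand.variants:
                    moves = [
                        m for m in variant
                        if working.sequence[m.position] != m.new_base
                    ]
                    if not moves:
                        continue
                    new_seq = apply_moves(working.sequence, moves, working.locked)
                    cand_state = refold(working, new_seq, engine)
                    sim = similarity(
                        cand_state.natural_db, cand_state.target_db, mode
                    )
                    key = (sim, -cand_state.natural_energy)
                    if best is None or key > best[:2]:
                        best = (sim, -cand_state.natural_energy,
                                cand_state, moves)
                if best is None:
                    continue
                sim, _, cand_state, moves = best
                if sim > committed_sim + _TIE_EPS:
                    step_moves = pending_moves + moves
                    trace.append((strategy, step_moves, sim))
                    strategy_steps.append((step_moves, sim))
                    strategy_moves.extend(step_moves)
                    committed = cand_state
                    committed_sim = sim
                    working = cand_state
                    pending_moves = []
                    sweep_committed = True
                elif (
                    abs(sim - committed_sim) <= _TIE_EPS
                    and strategy in _PROVISIONAL_OK
                ):
                    working = cand_state
                    pending_moves = pending_moves + moves
                # else: worse — revert (drop cand_state)
                if committed.solved:
                    break
            outcomes.append(
                StrategyOutcome(
                    strategy=strategy,
                    candidates=len(cands),
                    proposed=cands,
                    accepted_moves=strategy_moves,
                    accepted_steps=strategy_steps,
                    accepted=bool(strategy_steps),
                    similarity_before=sim_before,
                    similarity_after=committed_sim,
                    energy_before=e_before,
                    energy_after=working.natural_energy,
                    state=working,
                )
            )
            if committed.solved:
                break
        # Roll back provisional edits that never led to an improvement.
        working = committed
        pending_moves = []
        if not sweep_committed:
            break
    return SapResult(
        state=committed,
        solved=committed.solved,
        trace=trace,
        sweeps=sweeps,
        outcomes=outcomes,
    )
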
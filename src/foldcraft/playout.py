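"""Policy-driven stochastic move playout and the two-stage solve pipeline.

Stage one samples moves from a move policy — any object mapping a puzzle
state to probability vectors over bases (A, U, G, C) and positions — for
at most 3x the puzzle length moves, refolding after each edit.  If the
puzzle is still unsolved, stage two hands the state to the single-action
playout of hand-coded player strategies (:mod:`foldcraft.sap`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, runtime_checkable

import numpy as np

from .core import BASES, Move, PuzzleState, apply_moves
from .folding import EngineConfig, FoldingEngine, make_state, refold
from .sap import SapConfig, sap_solve, similarity


@dataclass
class PolicyOutput:
    """Probabilities over the four bases and over sequence positions."""

    base_probs: np.ndarray      # (4,) over A, U, G, C
    location_probs: np.ndarray  # (L,)

    def __post_init__(self):
        self.base_probs = _renormalize(np.asarray(self.base_probs, dtype=float))
        self.location_probs = _renormalize(
            np.asarray(self.location_probs, dtype=float)
        )


def _renormalize(v: np.ndarray) -> np.ndarray:
    if np.any(v < 0):
        raise ValueError("probabilities must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("probability vector sums to zero")
    return v / total


@runtime_checkable
class MovePolicy(Protocol):
    """Contract for move predictors usable by the playout stage."""

    def predict(self, state: PuzzleState) -> PolicyOutput: ...


class BaselinePolicy:
    """Reference policy: attend to positions whose pairing is wrong.

    Location mass is uniform over positions where the natural pairing
    disagrees with the target (falling back to all unlocked positions
    when none disagree).  Base mass is the average, over those pending
    positions, of a uniform choice among the three bases different from
    the current one — so against a ground truth that changes the base,
    the expected top-1 hit rate of this base distribution is 1/3.
    """

    def predict(self, state: PuzzleState) -> PolicyOutput:
        L = state.length
        pending = [
            i
            for i in range(L)
            if state.natural_pm[i] != state.target_pm[i] and not state.locked[i]
        ]
        if not pending:
            pending = [i for i in range(L) if not state.locked[i]]
        if not pending:
            raise ValueError("no unlocked positions to act on")
        loc = np.zeros(L)
        loc[pending] = 1.0
        base = np.zeros(4)
        for i in pending:
            for b_idx, b in enumerate(BASES):
                if b != state.sequence[i]:
                    base[b_idx] += 1.0 / 3.0
        return PolicyOutput(base_probs=base, location_probs=loc)


@dataclass(frozen=True)
class PlayoutConfig:
    """Stochastic playout settings; budget = budget_multiplier x length."""

    budget_multiplier: int = 3
    skip_noop: bool = True

    def __post_init__(self):
        if self.budget_multiplier < 1:
            raise ValueError("budget_multiplier must be positive")


@dataclass
class TraceMove:
    """One applied move with its stage attribution."""

    stage: str  # "policy" | "sap"
    position: int
    new_base: str
    old_base: str
    similarity_after: float
    strategy: Optional[str] = None  # SAP strategy name, if stage == "sap"


@dataclass
class SolveResult:
    """Outcome of a design attempt.

    The trace replays deterministically: applying its moves in order to
    the start sequence yields ``state.sequence``.
    """

    solved: bool
    state: PuzzleState
    start_sequence: str
    trace: list[TraceMove]
    engine: dict
    seed: Optional[int]
    counters: dict = field(default_factory=dict)

    def replay_sequence(self) -> str:
        return apply_moves(
            self.start_sequence,
            [Move(t.position, t.new_base) for t in self.trace],
        )

    def to_dict(self) -> dict:
        return {
            "solved": self.solved,
            "sequence": self.state.sequence,
            "target": self.state.target_db,
            "natural": self.state.natural_db,
            "natural_energy": self.state.natural_energy,
            "start_sequence": self.start_sequence,
            "engine": self.engine,
            "seed": self.seed,
            "counters": self.counters,
            "trace": [
                {
                    "stage": t.stage,
                    "strategy": t.strategy,
                    "position": t.position,
                    "new_base": t.new_base,
                    "old_base": t.old_base,
                    "similarity_after": t.similarity_after,
                }
                for t in self.trace
            ],
        }


def stochastic_playout(
    state: PuzzleState,
    policy: MovePolicy,
    engine: FoldingEngine,
    cfg: Optional[PlayoutConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[PuzzleState, list[TraceMove]]:
    """Sample and apply at most ``budget_multiplier * L`` policy moves.

    Locked positions are masked out of the location distribution before
    renormalization; with ``skip_noop`` the current base is masked out of
    the base distribution at the sampled location, so every applied move
    changes the sequence.  Stops early when solved.
    """
    cfg = cfg or PlayoutConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    budget = cfg.budget_multiplier * state.length
    current = state
    trace: list[TraceMove] = []
    free = np.array([not l for l in current.locked], dtype=float)
    if not free.any():
        return current, trace
    for _ in range(budget):
        if current.solved:
            break
        out = policy.predict(current)
        if out.location_probs.shape[0] != current.length:
            raise ValueError(
                f"policy location vector length {out.location_probs.shape[0]} "
                f"!= puzzle length {current.length}"
            )
        loc_probs = out.location_probs * free
        if loc_probs.sum() <= 0:
            break
        loc_probs = loc_probs / loc_probs.sum()
        pos = int(rng.choice(current.length, p=loc_probs))
        base_probs = out.base_probs.copy()
        if cfg.skip_noop:
            base_probs[BASES.index(current.sequence[pos])] = 0.0
            if base_probs.sum() <= 0:
                base_probs = np.array(
                    [0.0 if b == current.sequence[pos] else 1.0 for b in BASES]
                )
        base_probs = base_probs / base_probs.sum()
        new_base = BASES[int(rng.choice(4, p=base_probs))]
        if new_base == current.sequence[pos]:
            continue  # no-op sampled with skip_noop off: consumes budget
        old_base = current.sequence[pos]
        new_seq = apply_moves(current.sequence, [Move(pos, new_base)], current.locked)
        current = refold(current, new_seq, engine)
        trace.append(
            TraceMove(
                stage="policy",
                position=pos,
                new_base=new_base,
                old_base=old_base,
                similarity_after=similarity(current.natural_db, current.target_db),
            )
        )
    return current, trace


def initial_sequence(target_db: str, locks: Optional[str] = None,
                     start_seq: Optional[str] = None) -> str:
    """Default puzzle start: all-adenine at unlocked positions.

    When a start sequence is supplied it is used verbatim; locked
    positions keep the start sequence's bases in either case.
    """
    if start_seq is not None:
        if len(start_seq) != len(target_db):
            raise ValueError("start sequence length != target length")
        return start_seq
    return "A" * len(target_db)


def solve(
    target_db: str,
    engine: Optional[FoldingEngine] = None,
    locks: Optional[str] = None,
    start_seq: Optional[str] = None,
    policy: Optional[MovePolicy] = None,
    playout_cfg: Optional[PlayoutConfig] = None,
    sap_cfg: Optional[SapConfig] = None,
    seed: Optional[int] = 0,
    use_sap: bool = True,
) -> SolveResult:
    """Two-stage solve: policy playout, then single-action playout.

    ``policy=None`` disables the first stage (SAP-only mode, the
    strategy-ablation configuration); ``use_sap=False`` disables the
    second (policy-only mode).
    """
    engine = engine or FoldingEngine(EngineConfig())
    rng = np.random.default_rng(seed)
    start = initial_sequence(target_db, locks, start_seq)
    state = make_state(start, target_db, engine, locks=locks)
    trace: list[TraceMove] = []

    if policy is not None and not state.solved:
        state, trace = stochastic_playout(state, policy, engine, playout_cfg, rng)

    sap_accepted = 0
    if use_sap and not state.solved:
        sap_result = sap_solve(state, engine, sap_cfg, rng)
        for strategy, moves, sim in sap_result.trace:
            for mv in moves:
                trace.append(
                    TraceMove(
                        stage="sap",
                        strategy=strategy,
                        position=mv.position,
                        new_base=mv.new_base,
                        old_base=state.sequence[mv.position],
                        similarity_after=sim,
                    )
                )
        sap_accepted = len(sap_result.trace)
        state = sap_result.state

    # old_base bookkeeping above used the pre-SAP sequence, which is wrong
    # when SAP edits one position twice; rebuild by replay for correctness.
    seq = start
    for t in trace:
        t.old_base = seq[t.position]
        seq = seq[: t.position] + t.new_base + seq[t.position + 1 :]

    return SolveResult(
        solved=state.solved,
        state=state,
        start_sequence=start,
        trace=trace,
        engine=engine.describe(),
        seed=seed,
        counters={
            "policy_moves": sum(1 for t in trace if t.stage == "policy"),
            "sap_moves": sum(1 for t in trace if t.stage == "sap"),
            "sap_accepted_steps": sap_accepted,
        },
    )
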
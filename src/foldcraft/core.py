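"""Core domain types for RNA secondary-structure design puzzles.

A design puzzle is a target secondary structure (dot-bracket) plus an
editable nucleotide sequence; the puzzle is solved when the minimum-free-
energy ("natural") structure of the sequence equals the target.  This
module holds the representations every other stage transforms: sequences,
dot-bracket strings, pairmaps, lock masks, structural motifs, and the
fixed numeric encoding of a puzzle state used by move-prediction models.

Conventions
-----------
* Bases are ordered ``A, U, G, C`` everywhere (one-hot columns, sampling).
* All coordinates are 0-based; a pairmap entry is the 0-based index of the
  partner, or -1 when unpaired.
* Lock masks are strings of ``x`` (locked) / ``o`` (free).
* Pseudoknots are rejected: dot-bracket input uses only ``. ( )``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

BASES = "AUGC"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Watson-Crick complement (used by the mismatch-fixing strategy, which
#: only ever writes A-U or G-C pairs).
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Pairs accepted as correctly formed in the folding model: Watson-Crick
#: plus the G-U wobble.
CANONICAL_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}

STRUCT_ENCODING = {".": 1, "(": 2, ")": 3}
LOCK_ENCODING = {False: 1, True: 2}


class StructureError(ValueError):
    """Invalid structure input; ``index`` locates the offending symbol."""

    def __init__(self, message: str, index: Optional[int] = None):
        super().__init__(message)
        self.index = index


def validate_sequence(seq: str) -> str:
    for i, b in enumerate(seq):
        if b not in _BASE_INDEX:
            raise StructureError(f"invalid base {b!r} at position {i}", index=i)
    return seq


def dotbracket_to_pairmap(db: str) -> list[int]:
    """Convert dot-bracket notation to a partner-index list.

    ``partner[i]`` is the 0-based index paired with ``i``, or -1 if
    position ``i`` is unpaired.  Raises :class:`StructureError` on
    unbalanced input or characters outside ``. ( )``.
    """
    partner = [-1] * len(db)
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(f"unmatched ')' at position {i}", index=i)
            j = stack.pop()
            partner[j] = i
            partner[i] = j
        elif c != ".":
            raise StructureError(f"invalid symbol {c!r} at position {i}", index=i)
    if stack:
        raise StructureError(f"unmatched '(' at position {stack[-1]}", index=stack[-1])
    return partner


def pairmap_to_dotbracket(pm: Sequence[int]) -> str:
    """Inverse of :func:`dotbracket_to_pairmap`.

    Validates the involution property (``partner[partner[i]] == i``) and
    rejects crossing (pseudoknotted) pairs.
    """
    L = len(pm)
    chars = []
    for i, j in enumerate(pm):
        if j == -1:
            chars.append(".")
            continue
        if not (0 <= j < L) or j == i:
            raise StructureError(f"partner index {j} out of range at {i}", index=i)
        if pm[j] != i:
            raise StructureError(
                f"involution violated: partner[{i}]={j} but partner[{j}]={pm[j]}",
                index=i,
            )
        chars.append("(" if i < j else ")")
    db = "".join(chars)
    # A stack re-parse detects crossing pairs.
    if dotbracket_to_pairmap(db) != list(pm):
        raise StructureError("pairmap contains crossing (pseudoknotted) pairs")
    return db


def parse_locks(locks: Optional[str], length: int) -> tuple[bool, ...]:
    """Parse an ``x``/``o`` lock string; ``None`` means all free."""
    if locks is None:
        return (False,) * length
    if len(locks) != length:
        raise StructureError(
            f"lock mask length {len(locks)} != sequence length {length}"
        )
    out = []
    for i, c in enumerate(locks):
        if c not in "xo":
            raise StructureError(f"invalid lock symbol {c!r} at position {i}", index=i)
        out.append(c == "x")
    return tuple(out)


def locks_to_string(locked: Sequence[bool]) -> str:
    return "".join("x" if l else "o" for l in locked)


class Move(NamedTuple):
    """A single-base edit: set ``position`` to ``new_base``."""

    position: int
    new_base: str


def apply_moves(sequence: str, moves: Iterable[Move],
                locked: Optional[Sequence[bool]] = None) -> str:
    """Apply moves to a sequence string, refusing edits at locked positions."""
    seq = list(sequence)
    for pos, base in moves:
        if not (0 <= pos < len(seq)):
            raise StructureError(f"move position {pos} out of range", index=pos)
        if base not in _BASE_INDEX:
            raise StructureError(f"move base {base!r} is not one of {BASES}")
        if locked is not None and locked[pos]:
            raise StructureError(f"position {pos} is locked", index=pos)
        seq[pos] = base
    return "".join(seq)


# ---------------------------------------------------------------------------
# Motifs


@dataclass(frozen=True)
class Motif:
    """A structural element of a secondary structure.

    kind
        One of ``stem``, ``hairpin_loop``, ``internal_loop``, ``bulge``,
        ``multiloop``, ``exterior``.
    positions
        The member positions: all paired positions for a stem, the
        unpaired positions for loops and the exterior.  Motifs partition
        ``range(L)``.
    closing
        The base pairs delimiting the motif.  For a stem these are its
        outermost and innermost pairs' span; for loops, the pair(s)
        adjacent to the loop, outermost first.
    strands
        For internal loops and bulges: the 5' and 3' unpaired runs, in
        that order (a bulge has one empty strand).  Empty otherwise.
    """

    kind: str
    positions: tuple[int, ...]
    closing: tuple[tuple[int, int], ...] = ()
    strands: tuple[tuple[int, ...], ...] = ()

    @property
    def size(self) -> int:
        return len(self.positions)


def find_motifs(pm: Sequence[int]) -> list[Motif]:
    """Decompose a pairmap into stems, loops and exterior positions.

    Stems are maximal runs of directly stacked pairs.  Each loop records
    its closing pair(s): a hairpin has one, an internal loop / bulge two,
    a multiloop one outer plus one per branch.  An ``m x n`` internal
    loop reports its strands so strategies can test sizes (e.g. 2x2).
    """
    L = len(pm)
    pairmap_to_dotbracket(pm)  # validates involution / crossing
    motifs: list[Motif] = []

    # Stems: start at a pair whose outside neighbours are not a stacked pair.
    for i in range(L):
        j = pm[i]
        if j <= i:
            continue
        outer_stacked = i > 0 and pm[i - 1] == j + 1
        if outer_stacked:
            continue
        run = [(i, j)]
        while pm[run[-1][0] + 1] == run[-1][1] - 1 and run[-1][0] + 1 < run[-1][1] - 1:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        positions = tuple(sorted(p for pair in run for p in pair))
        motifs.append(Motif("stem", positions, closing=(run[0], run[-1])))

    def interior(i: int, j: int):
        """Unpaired positions and branch pairs strictly inside pair (i, j)."""
        unpaired, branches = [], []
        k = i + 1
        while k < j:
            if pm[k] == -1:
                unpaired.append(k)
                k += 1
            else:
                branches.append((k, pm[k]))
                k = pm[k] + 1
        return unpaired, branches

    # Loops: every pair that does not directly stack onto a single inner pair
    # closes a loop.
    for i in range(L):
        j = pm[i]
        if j <= i:
            continue
        unpaired, branches = interior(i, j)
        if len(branches) == 1 and not unpaired:
            continue  # stacked pair, interior to a stem
        if not branches:
            motifs.append(Motif("hairpin_loop", tuple(unpaired), closing=((i, j),)))
        elif len(branches) == 1:
            (p, q) = branches[0]
            strand5 = tuple(range(i + 1, p))
            strand3 = tuple(range(q + 1, j))
            kind = "bulge" if (not strand5 or not strand3) else "internal_loop"
            motifs.append(
                Motif(kind, tuple(unpaired), closing=((i, j), (p, q)),
                      strands=(strand5, strand3))
            )
        else:
            motifs.append(
                Motif("multiloop", tuple(unpaired),
                      closing=((i, j), *branches))
            )

    # Exterior: top-level unpaired positions.
    exterior = []
    k = 0
    while k < L:
        if pm[k] == -1:
            exterior.append(k)
            k += 1
        else:
            k = pm[k] + 1
    if exterior or L == 0:
        if exterior:
            motifs.append(Motif("exterior", tuple(exterior)))
    return motifs


# ---------------------------------------------------------------------------
# Puzzle state


@dataclass(frozen=True)
class PuzzleState:
    """One snapshot of a design puzzle.

    ``natural_db``/``natural_energy`` must be the folding engine's output
    for ``sequence``; constructors in :mod:`foldcraft.folding` guarantee
    this.  ``target_energy`` is optional (the energy of the sequence
    evaluated on the target structure is undefined when the target pairs
    non-canonical bases).
    """

    sequence: str
    target_db: str
    natural_db: str
    natural_energy: float
    target_energy: Optional[float] = None
    locked: tuple[bool, ...] = ()

    target_pm: tuple[int, ...] = field(init=False)
    natural_pm: tuple[int, ...] = field(init=False)

    def __post_init__(self):
        validate_sequence(self.sequence)
        L = len(self.sequence)
        if len(self.target_db) != L or len(self.natural_db) != L:
            raise StructureError(
                f"length mismatch: sequence {L}, target {len(self.target_db)}, "
                f"natural {len(self.natural_db)}"
            )
        locked = self.locked if self.locked else (False,) * L
        if len(locked) != L:
            raise StructureError(f"lock mask length {len(locked)} != {L}")
        object.__setattr__(self, "locked", tuple(locked))
        object.__setattr__(
            self, "target_pm", tuple(dotbracket_to_pairmap(self.target_db))
        )
        object.__setattr__(
            self, "natural_pm", tuple(dotbracket_to_pairmap(self.natural_db))
        )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def solved(self) -> bool:
        return self.natural_db == self.target_db


# ---------------------------------------------------------------------------
# Feature encoding


@dataclass
class FeatureBlock:
    """Numeric encoding of a puzzle state.

    Field order and value conventions are fixed: one-hot sequence over
    (A, U, G, C); structure symbols ``.``/``(``/``)`` as 1/2/3; energies
    in kcal/mol as-is; pairmaps as 0-based partner indices (-1 unpaired);
    locks as 1 (free) / 2 (locked).  Copy/reset events in imported move
    logs mark affected one-hot rows as ``[1,1,1,1]``.
    """

    onehot: np.ndarray          # (L, 4) int
    natural_struct: np.ndarray  # (L,) int in {1,2,3}
    target_struct: np.ndarray   # (L,) int in {1,2,3}
    natural_energy: float
    target_energy: float        # NaN when absent
    natural_pm: np.ndarray      # (L,) int
    target_pm: np.ndarray       # (L,) int
    locks: np.ndarray           # (L,) int in {1,2}

    @property
    def length(self) -> int:
        return self.onehot.shape[0]

    def decode_sequence(self) -> str:
        """Recover the sequence from the one-hot block (reset rows -> 'A')."""
        out = []
        for row in self.onehot:
            idx = int(np.argmax(row))
            out.append(BASES[idx])
        return "".join(out)


def encode_onehot(seq: str) -> np.ndarray:
    validate_sequence(seq)
    out = np.zeros((len(seq), 4), dtype=int)
    for i, b in enumerate(seq):
        out[i, _BASE_INDEX[b]] = 1
    return out


def encode_structure(db: str) -> np.ndarray:
    try:
        return np.array([STRUCT_ENCODING[c] for c in db], dtype=int)
    except KeyError as e:
        raise StructureError(f"invalid structure symbol {e.args[0]!r}")


def encode_state(state: PuzzleState,
                 reset_positions: Iterable[int] = ()) -> FeatureBlock:
    """Encode a puzzle state into the fixed feature block.

    ``reset_positions`` marks positions affected by a copy/reset event in
    an imported move log; their one-hot rows become ``[1,1,1,1]``.
    """
    onehot = encode_onehot(state.sequence)
    for p in reset_positions:
        onehot[p, :] = 1
    te = state.target_energy if state.target_energy is not None else float("nan")
    return FeatureBlock(
        onehot=onehot,
        natural_struct=encode_structure(state.natural_db),
        target_struct=encode_structure(state.target_db),
        natural_energy=float(state.natural_energy),
        target_energy=float(te),
        natural_pm=np.array(state.natural_pm, dtype=int),
        target_pm=np.array(state.target_pm, dtype=int),
        locks=np.array([LOCK_ENCODING[l] for l in state.locked], dtype=int),
    )
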
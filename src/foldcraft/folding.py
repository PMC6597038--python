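"""Nearest-neighbor folding engine adapter.

The solver only needs two things from a thermodynamic model: the
minimum-free-energy (MFE) structure of a sequence, and the free energy of
a sequence on a given structure.  This module wraps the ViennaRNA
bindings behind that two-function contract so that a different engine
(e.g. a specific legacy binary via subprocess) can be swapped in for
exact-version studies.

The default parameter set is Turner1999-style, the model in which the
classic design benchmarks are known to be solvable and the default of the
game client the player strategies come from.  ViennaRNA holds the loaded
parameter table as process-global state; the adapter tracks which table
is loaded and reloads only on change, so mixing engines with different
parameter sets in one process is safe (if slow).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import StructureError, validate_sequence

try:
    import RNA
except ImportError:  # pragma: no cover - engine presence is environmental
    RNA = None

#: Parameter tables selectable by name.  "turner1999" approximates the
#: legacy engine used by the game client; "turner2004" is ViennaRNA's
#: modern default.
PARAMETER_SETS = ("turner1999", "turner2004")

_loaded_params: list[str] = ["turner2004"]  # ViennaRNA's startup default


@dataclass(frozen=True)
class EngineConfig:
    """Folding model settings, fixed for the lifetime of a solve.

    temperature is in degrees Celsius; dangles follows the ViennaRNA
    convention (2 = dangling ends on both sides, the library default).
    """

    parameter_set: str = "turner1999"
    temperature: float = 37.0
    dangles: int = 2

    def __post_init__(self):
        if self.parameter_set not in PARAMETER_SETS:
            raise ValueError(
                f"unknown parameter_set {self.parameter_set!r}; "
                f"choose from {PARAMETER_SETS}"
            )


class FoldingEngine:
    """MFE folding and structure-energy evaluation with a transparent cache."""

    def __init__(self, config: EngineConfig | None = None, cache: bool = True):
        if RNA is None:  # pragma: no cover
            raise RuntimeError(
                "ViennaRNA python bindings are required for folding "
                "(import RNA failed)"
            )
        self.config = config or EngineConfig()
        self._cache_enabled = cache
        self._fold_cache: dict[str, tuple[str, float]] = {}
        self._eval_cache: dict[tuple[str, str], float] = {}

    # -- engine plumbing ---------------------------------------------------

    def _ensure_params(self):
        want = self.config.parameter_set
        if _loaded_params[0] != want:
            if want == "turner1999":
                RNA.params_load_RNA_Turner1999()
            else:
                RNA.params_load_RNA_Turner2004()
            _loaded_params[0] = want

    def _compound(self, seq: str):
        self._ensure_params()
        md = RNA.md()
        md.temperature = self.config.temperature
        md.dangles = self.config.dangles
        return RNA.fold_compound(seq, md)

    # -- public contract ---------------------------------------------------

    def mfe_fold(self, seq: str) -> tuple[str, float]:
        """Return the MFE structure (dot-bracket) and its energy in kcal/mol."""
        validate_sequence(seq)
        if self._cache_enabled and seq in self._fold_cache:
            return self._fold_cache[seq]
        db, energy = self._compound(seq).mfe()
        result = (db, round(float(energy), 2))
        if self._cache_enabled:
            self._fold_cache[seq] = result
        return result

    def eval_energy(self, seq: str, db: str) -> float:
        """Free energy (kcal/mol) of ``seq`` folded on structure ``db``."""
        validate_sequence(seq)
        if len(db) != len(seq):
            raise StructureError(
                f"structure length {len(db)} != sequence length {len(seq)}"
            )
        key = (seq, db)
        if self._cache_enabled and key in self._eval_cache:
            return self._eval_cache[key]
        energy = round(float(self._compound(seq).eval_structure(db)), 2)
        if self._cache_enabled:
            self._eval_cache[key] = energy
        return energy

    def describe(self) -> dict:
        """Engine provenance recorded into every solve result."""
        return {
            "engine": "ViennaRNA",
            "version": RNA.__version__ if RNA is not None else None,
            "parameter_set": self.config.parameter_set,
            "temperature": self.config.temperature,
            "dangles": self.config.dangles,
        }


def make_state(sequence: str, target_db: str, engine: FoldingEngine,
               locks: str | None = None, evaluate_target_energy: bool = False):
    """Fold ``sequence`` and assemble a consistent :class:`PuzzleState`.

    Target-structure energy evaluation is optional: when the target pairs
    bases that are currently non-canonical the engine's value is not
    meaningful, so it is skipped unless requested.
    """
    from .core import PuzzleState, parse_locks

    natural_db, natural_energy = engine.mfe_fold(sequence)
    target_energy = None
    if evaluate_target_energy:
        target_energy = engine.eval_energy(sequence, target_db)
    return PuzzleState(
        sequence=sequence,
        target_db=target_db,
        natural_db=natural_db,
        natural_energy=natural_energy,
        target_energy=target_energy,
        locked=parse_locks(locks, len(sequence)),
    )


def refold(state, new_sequence: str, engine: FoldingEngine):
    """New state for an edited sequence; target, locks carried over."""
    from .core import PuzzleState

    natural_db, natural_energy = engine.mfe_fold(new_sequence)
    return PuzzleState(
        sequence=new_sequence,
        target_db=state.target_db,
        natural_db=natural_db,
        natural_energy=natural_energy,
        target_energy=state.target_energy,
        locked=state.locked,
    )
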
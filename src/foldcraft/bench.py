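"""Benchmark execution and reporting.

Runs the two-stage solver over a benchmark file of named targets (TSV:
name, dot-bracket, optional lock string), optionally repeating each
puzzle under several seeds, and collects a per-puzzle table plus the
aggregate solved count — the presentation used for design-benchmark
comparisons.  Ablation modes (policy-only, SAP-only) are selected by the
``policy`` / ``use_sap`` arguments.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .core import StructureError, dotbracket_to_pairmap, parse_locks
from .folding import EngineConfig, FoldingEngine
from .playout import MovePolicy, PlayoutConfig, solve
from .sap import SapConfig

logger = logging.getLogger(__name__)


def read_benchmark(path) -> list[tuple[str, str, Optional[str]]]:
    """Parse a benchmark TSV into (name, structure, locks) triples.

    Rows failing validation (unbalanced structure, bad lock string) are
    rejected with their file:line context; remaining rows are kept.
    """
    path = Path(path)
    out = []
    text = path.read_text().splitlines()
    if not any(line.strip() for line in text):
        logger.warning("benchmark file %s is empty", path)
        return out
    for lineno, line in enumerate(text, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        try:
            if len(parts) < 2:
                raise StructureError("expected name<TAB>structure[<TAB>locks]")
            name, db = parts[0], parts[1]
            locks = parts[2] if len(parts) > 2 and parts[2] else None
            dotbracket_to_pairmap(db)
            if locks is not None:
                parse_locks(locks, len(db))
            out.append((name, db, locks))
        except StructureError as exc:
            logger.warning("%s:%d: rejected row: %s", path, lineno, exc)
    return out


@dataclass
class BenchmarkReport:
    """Per-puzzle outcomes plus the aggregate solved count.

    ``rows`` has one entry per puzzle: name, length, solved flag (first
    seed), solved_runs out of runs, stage attribution of the solving
    run, accepted-move count, and wall time.  ``solved_count`` equals
    the sum of the per-puzzle solved flags.
    """

    rows: pd.DataFrame
    solved_count: int
    config: dict
    seeds: list[int]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "config": self.config,
                "seeds": self.seeds,
                "solved_count": self.solved_count,
                "rows": self.rows.to_dict(orient="records"),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "BenchmarkReport":
        if isinstance(source, (str, Path)) and Path(source).exists():
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        return cls(
            rows=pd.DataFrame(data["rows"]),
            solved_count=data["solved_count"],
            config=data["config"],
            seeds=list(data["seeds"]),
        )

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def run_benchmark(
    puzzles: Sequence[tuple[str, str, Optional[str]]],
    engine: Optional[FoldingEngine] = None,
    policy: Optional[MovePolicy] = None,
    use_sap: bool = True,
    playout_cfg: Optional[PlayoutConfig] = None,
    sap_cfg: Optional[SapConfig] = None,
    seeds: Sequence[int] = (0,),
) -> BenchmarkReport:
    """Solve every puzzle under each seed and tabulate the outcomes.

    The first seed defines the per-puzzle solved flag; additional seeds
    measure repeat-run consistency (solved_runs out of len(seeds)).
    Per-puzzle failures are recorded and the run continues.
    """
    if not puzzles:
        raise ValueError("run_benchmark requires at least one puzzle")
    engine = engine or FoldingEngine(EngineConfig())
    rows = []
    for name, target, locks in puzzles:
        solved_runs = 0
        first = None
        t0 = time.perf_counter()
        for seed in seeds:
            try:
                result = solve(
                    target,
                    engine=engine,
                    locks=locks,
                    policy=policy,
                    playout_cfg=playout_cfg,
                    sap_cfg=sap_cfg,
                    seed=seed,
                    use_sap=use_sap,
                )
            except Exception as exc:  # record, keep going
                logger.warning("puzzle %s failed under seed %s: %s",
                               name, seed, exc)
                continue
            if first is None:
                first = result
            solved_runs += int(result.solved)
        wall = time.perf_counter() - t0
        if first is None:
            rows.append({
                "name": name, "length": len(target), "solved": False,
                "solved_runs": 0, "runs": len(seeds), "stage": "error",
                "moves": 0, "wall_time_s": wall,
            })
            continue
        if first.solved:
            stage = "sap" if first.counters["sap_moves"] > 0 else "policy"
        else:
            stage = ""
        rows.append({
            "name": name,
            "length": len(target),
            "solved": bool(first.solved),
            "solved_runs": solved_runs,
            "runs": len(seeds),
            "stage": stage,
            "moves": len(first.trace),
            "wall_time_s": wall,
        })
    df = pd.DataFrame(rows)
    return BenchmarkReport(
        rows=df,
        solved_count=int(df["solved"].sum()),
        config={
            "engine": engine.describe(),
            "policy": type(policy).__name__ if policy is not None else None,
            "use_sap": use_sap,
            "playout": vars(playout_cfg) if playout_cfg else None,
            "sap": vars(sap_cfg) if sap_cfg else None,
        },
        seeds=list(seeds),
    )
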
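"""Move-predictor training and evaluation.

Two predictors are trained from logged design moves, imitating how
players edit puzzles: a *base predictor* for which nucleotide to write
and a *location predictor* for where to write it.  Each consumes the
fixed per-position encoding of the puzzle state (one-hot sequence,
structure symbols, pairmaps, energies, locks) padded to a maximum length
with a validity mask.

The base predictor additionally receives a location-marker channel
identifying the position being changed — during training and accuracy
evaluation it is set to the true move location, matching how base
accuracy is defined for logged moves; inside the playout policy wrapper
no location is available and the channel stays zero, so base and
location are sampled independently.

Networks are 1-D convolutions along the sequence (translation-equivariant,
like the visual patterns players recognize) built on :mod:`foldcraft._net`.
The default architecture is a reduced desk-scale schedule; the full-size
schedule (10 conv layers doubling 1..1024 channels, 4 dense layers,
sigmoid, dropout 0.1, minibatch 100, Adam) is expressible via
:class:`ArchConfig` for full-scale studies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import _net
from .core import (
    BASES,
    FeatureBlock,
    Move,
    PuzzleState,
    encode_state,
)
from .playout import PolicyOutput

logger = logging.getLogger(__name__)

LOG_COLUMNS = (
    "seq", "natural_db", "target_db", "natural_energy", "target_energy",
    "locks", "move_pos", "move_base",
)

#: Puzzle-length bins used for stratified accuracy reporting.
LENGTH_BINS = ((1, 50), (51, 100), (101, 150), (151, 400))


@dataclass
class MoveRecord:
    """One encoded training example: state features plus the move labels."""

    features: FeatureBlock
    label_base: str
    label_location: int

    def __post_init__(self):
        if self.label_base not in BASES:
            raise ValueError(f"label base {self.label_base!r} not in {BASES}")
        if not (0 <= self.label_location < self.features.length):
            raise ValueError(
                f"label location {self.label_location} outside puzzle "
                f"length {self.features.length}"
            )

    @property
    def length(self) -> int:
        return self.features.length


@dataclass(frozen=True)
class ArchConfig:
    """Network and training hyperparameters for both predictors.

    conv_channels / kernel / stride / pool describe the convolutional
    stack; fc_widths the dense head of the base predictor (the location
    predictor is fully convolutional).  max_length fixes the padded
    input size; puzzles longer than this cannot be encoded.  The
    use_* flags zero out feature groups for reduced-input ablations.
    """

    conv_channels: tuple[int, ...] = (8, 16)
    kernel: int = 5
    stride: int = 1
    pool: int = 1
    fc_widths: tuple[int, ...] = (48,)
    dropout: float = 0.1
    activation: str = "relu"
    minibatch: int = 50
    epochs: int = 12
    learning_rate: float = 3e-3
    optimizer: str = "adam"
    max_length: int = 64
    seed: int = 0
    use_sequence: bool = True
    use_dotbracket: bool = True
    use_pairmap: bool = True

    def __post_init__(self):
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if min(self.minibatch, self.kernel, self.stride,
               self.pool, self.max_length) < 1:
            raise ValueError("architecture sizes must be positive")
        if self.epochs < 0:  # 0 = untrained (random-initialized) predictors
            raise ValueError("epochs must be non-negative")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


#: The full-scale schedule from the original training runs (expressible,
#: but far beyond desk-scale CPU budgets).
FULL_SCALE_ARCH = ArchConfig(
    conv_channels=(1, 2, 4, 8, 16, 32, 64, 128, 256, 512, 1024),
    kernel=9,
    stride=2,
    fc_widths=(1024, 1024, 2048, 4096),
    dropout=0.1,
    activation="sigmoid",
    minibatch=100,
    epochs=50,
    max_length=400,
)

_N_STATE_CHANNELS = 12  # without the location marker


def record_channels(fb: FeatureBlock, arch: ArchConfig,
                    loc_marker: Optional[int] = None) -> np.ndarray:
    """Per-position channel matrix, zero-padded to ``arch.max_length``.

    Channels: one-hot sequence (4), structure symbols (2, scaled to
    [1/3, 1]), pairmaps (2, partner index scaled by max_length, -1 ->
    0), locks (1), validity mask (1), energies (2, broadcast, scaled by
    1/10 kcal/mol), plus an optional location-marker channel.
    """
    L, M = fb.length, arch.max_length
    if L > M:
        raise ValueError(f"puzzle length {L} exceeds model max_length {M}")
    n_ch = _N_STATE_CHANNELS + (1 if loc_marker is not None else 0)
    x = np.zeros((M, n_ch))
    if arch.use_sequence:
        x[:L, 0:4] = fb.onehot
    if arch.use_dotbracket:
        x[:L, 4] = fb.natural_struct / 3.0
        x[:L, 5] = fb.target_struct / 3.0
    if arch.use_pairmap:
        x[:L, 6] = (fb.natural_pm + 1) / M
        x[:L, 7] = (fb.target_pm + 1) / M
    x[:L, 8] = fb.locks - 1
    x[:L, 9] = 1.0  # validity mask
    x[:L, 10] = fb.natural_energy / 10.0
    te = fb.target_energy
    x[:L, 11] = 0.0 if np.isnan(te) else te / 10.0
    if loc_marker is not None:
        x[loc_marker, 12] = 1.0
    return x


# ---------------------------------------------------------------------------
# Move-log encoding


def encode_log_row(row) -> tuple[Optional[FeatureBlock], list[tuple[int, str]]]:
    """Encode one move-log row; returns (features, labelled moves).

    ``move_pos``/``move_base`` may carry several ';'-separated entries
    (simultaneous edits are treated as separate examples).  Copy/reset
    events (``move_base`` not a nucleotide, e.g. ``reset``) mark the
    affected one-hot rows as [1,1,1,1] and emit no labels.
    """
    locks = row["locks"] if isinstance(row.get("locks"), str) and row["locks"] else None
    te = row.get("target_energy")
    te = None if te is None or (isinstance(te, float) and np.isnan(te)) else float(te)
    state = PuzzleState(
        sequence=row["seq"],
        target_db=row["target_db"],
        natural_db=row["natural_db"],
        natural_energy=float(row["natural_energy"]),
        target_energy=te,
        locked=_parse_locks_field(locks, len(row["seq"])),
    )
    positions = [int(p) for p in str(row["move_pos"]).split(";") if p != ""]
    bases = [b for b in str(row["move_base"]).split(";") if b != ""]
    if bases and all(b in BASES for b in bases):
        if len(positions) != len(bases):
            raise ValueError("move_pos and move_base cardinality differ")
        fb = encode_state(state)
        return fb, list(zip(positions, bases))
    # copy / reset event
    fb = encode_state(state, reset_positions=positions)
    return fb, []


def _parse_locks_field(locks, length):
    from .core import parse_locks

    return parse_locks(locks, length)


def build_training_examples(move_log: pd.DataFrame) -> list[MoveRecord]:
    """Expand a tabular move log into per-move training records.

    Simultaneous multi-base edits become separate records sharing one
    feature block; copy/reset rows contribute no labels; malformed rows
    are skipped with a logged warning and final count.
    """
    missing = [c for c in ("seq", "natural_db", "target_db", "natural_energy",
                           "move_pos", "move_base") if c not in move_log.columns]
    if missing:
        raise ValueError(f"move log missing columns: {missing}")
    records: list[MoveRecord] = []
    skipped = 0
    for idx, row in move_log.iterrows():
        try:
            fb, labelled = encode_log_row(row)
        except Exception as exc:
            skipped += 1
            logger.warning("skipping malformed move-log row %s: %s", idx, exc)
            continue
        for pos, base in labelled:
            try:
                records.append(MoveRecord(fb, base, pos))
            except ValueError as exc:
                skipped += 1
                logger.warning("skipping malformed move-log row %s: %s", idx, exc)
    if skipped:
        logger.warning("move log: skipped %d malformed entries", skipped)
    return records


# ---------------------------------------------------------------------------
# Predictors


class _PredictorBase:
    def __init__(self, arch: ArchConfig, network: _net.Network,
                 history: list[float]):
        self.arch = arch
        self.network = network
        self.history = history  # mean training loss per epoch

    @property
    def max_length(self) -> int:
        return self.arch.max_length


class BasePredictor(_PredictorBase):
    """Predicts the nucleotide of the next move (4-way softmax)."""

    n_channels = _N_STATE_CHANNELS + 1  # with location marker

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.network.forward(x, train)

    def predict_proba(self, fb: FeatureBlock,
                      location: Optional[int] = None) -> np.ndarray:
        x = record_channels(fb, self.arch, loc_marker=location)[None]
        if location is None:
            x = np.concatenate([x, np.zeros((1, x.shape[1], 1))], axis=2)
        return _net.softmax(self.logits(x))[0]


class LocationPredictor(_PredictorBase):
    """Predicts the position of the next move (softmax over positions)."""

    n_channels = _N_STATE_CHANNELS

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = self.network.forward(x, train)[..., 0]  # (N, max_length)
        mask = x[:, :, 9]
        return out + (mask - 1.0) * 1e9  # padding positions -> -inf

    def predict_proba(self, fb: FeatureBlock) -> np.ndarray:
        x = record_channels(fb, self.arch)[None]
        return _net.softmax(self.logits(x))[0, : fb.length]


def _build_base_network(arch: ArchConfig, rng) -> _net.Network:
    layers = []
    in_ch = BasePredictor.n_channels
    length = arch.max_length
    for out_ch in arch.conv_channels:
        layers.append(_net.Conv1D(rng, in_ch, out_ch, arch.kernel, arch.stride))
        length = int(np.ceil(length / arch.stride))
        layers.append(_net.Activation(arch.activation))
        if arch.pool > 1:
            layers.append(_net.MeanPool1D(arch.pool))
            length = length // arch.pool
        in_ch = out_ch
    layers.append(_net.Flatten())
    width = length * in_ch
    for fc in arch.fc_widths:
        layers.append(_net.Dense(rng, width, fc))
        layers.append(_net.Activation(arch.activation))
        layers.append(_net.Dropout(rng, arch.dropout))
        width = fc
    layers.append(_net.Dense(rng, width, 4))
    return _net.Network(layers)


def _build_location_network(arch: ArchConfig, rng) -> _net.Network:
    # Fully convolutional, stride/pool-free: per-position score head.
    layers = []
    in_ch = LocationPredictor.n_channels
    for out_ch in arch.conv_channels:
        layers.append(_net.Conv1D(rng, in_ch, out_ch, arch.kernel, stride=1))
        layers.append(_net.Activation(arch.activation))
        layers.append(_net.Dropout(rng, arch.dropout))
        in_ch = out_ch
    layers.append(_net.Conv1D(rng, in_ch, 1, 1, stride=1))
    return _net.Network(layers)


def _train(network, X, y, arch, rng) -> list[float]:
    opt = _net.Adam(network.params, lr=arch.learning_rate)
    history = []
    n = X.shape[0]
    for _ in range(arch.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, arch.minibatch):
            idx = perm[start : start + arch.minibatch]
            logits = network.forward(X[idx], train=True)
            loss, grad = _net.softmax_xent(logits, y[idx])
            network.backward(grad)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def _train_location(predictor, X, y, arch, rng) -> list[float]:
    net = predictor.network
    opt = _net.Adam(net.params, lr=arch.learning_rate)
    history = []
    n = X.shape[0]
    for _ in range(arch.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, arch.minibatch):
            idx = perm[start : start + arch.minibatch]
            xb = X[idx]
            out = net.forward(xb, train=True)[..., 0]
            mask = xb[:, :, 9]
            logits = out + (mask - 1.0) * 1e9
            loss, grad = _net.softmax_xent(logits, y[idx])
            net.backward(grad[..., None])
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def train_move_predictor(
    records: Sequence[MoveRecord],
    arch: Optional[ArchConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[BasePredictor, LocationPredictor]:
    """Train the base/location predictor pair on encoded move records.

    One generator (from ``arch.seed`` unless given) drives weight init,
    shuffling and dropout, making training bit-reproducible.  Requires
    at least one full minibatch of records.
    """
    arch = arch or ArchConfig()
    if len(records) < arch.minibatch:
        raise ValueError(
            f"need at least one minibatch ({arch.minibatch} records) to "
            f"train, got {len(records)}"
        )
    rng = rng if rng is not None else np.random.default_rng(arch.seed)
    rng_base, rng_loc = rng.spawn(2)

    Xb = np.stack([
        record_channels(r.features, arch, loc_marker=r.label_location)
        for r in records
    ])
    yb = np.array([BASES.index(r.label_base) for r in records])
    Xl = np.stack([record_channels(r.features, arch) for r in records])
    yl = np.array([r.label_location for r in records])

    base = BasePredictor(arch, _build_base_network(arch, rng_base), [])
    base.history = _train(base.network, Xb, yb, arch, rng_base)
    loc = LocationPredictor(arch, _build_location_network(arch, rng_loc), [])
    loc.history = _train_location(loc, Xl, yl, arch, rng_loc)
    return base, loc


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class AccuracyReport:
    """Top-1 accuracies, overall and stratified.

    ``table`` mirrors the canonical layout: rows for all / paired /
    unpaired target status at the moved position, by puzzle-length bin,
    each with move counts and base/location hit counts.
    """

    base_accuracy: float
    location_accuracy: float
    table: pd.DataFrame


def _bin_label(L: int) -> str:
    for lo, hi in LENGTH_BINS:
        if lo <= L <= hi:
            return f"{lo}-{hi}"
    return f">{LENGTH_BINS[-1][1]}"


def evaluate_predictor(
    predictors: tuple[BasePredictor, LocationPredictor],
    records: Sequence[MoveRecord],
) -> AccuracyReport:
    """Stratified top-1 accuracy of the predictor pair on labelled moves.

    Base accuracy follows the logged-move protocol: the base predictor
    is shown the true move location via its marker channel.  Rows are
    stratified by puzzle length and by whether the moved position is
    paired in the target structure; bin counts sum to the "All" rows.
    """
    if not records:
        raise ValueError("cannot evaluate on an empty record set")
    base, loc = predictors
    arch = base.arch
    Xb = np.stack([
        record_channels(r.features, arch, loc_marker=r.label_location)
        for r in records
    ])
    Xl = np.stack([record_channels(r.features, loc.arch) for r in records])
    base_pred = np.argmax(base.logits(Xb), axis=1)
    loc_pred = np.argmax(loc.logits(Xl), axis=1)
    rows = []
    for k, r in enumerate(records):
        rows.append({
            "bin": _bin_label(r.length),
            "paired": "paired"
            if r.features.target_pm[r.label_location] != -1
            else "unpaired",
            "base_hit": int(base_pred[k] == BASES.index(r.label_base)),
            "loc_hit": int(loc_pred[k] == r.label_location),
        })
    df = pd.DataFrame(rows)

    def _agg(sub: pd.DataFrame) -> dict:
        return {
            "moves": len(sub),
            "location_hits": int(sub["loc_hit"].sum()),
            "location_accuracy": sub["loc_hit"].mean(),
            "base_hits": int(sub["base_hit"].sum()),
            "base_accuracy": sub["base_hit"].mean(),
        }

    bin_order = [f"{lo}-{hi}" for lo, hi in LENGTH_BINS]
    out_rows = []
    for group, sub in (
        ("all", df),
        ("paired", df[df["paired"] == "paired"]),
        ("unpaired", df[df["paired"] == "unpaired"]),
    ):
        for b in bin_order:
            part = sub[sub["bin"] == b]
            if len(part):
                out_rows.append({"group": group, "bin": b, **_agg(part)})
        if len(sub):
            out_rows.append({"group": group, "bin": "All", **_agg(sub)})
    table = pd.DataFrame(out_rows).set_index(["group", "bin"])
    return AccuracyReport(
        base_accuracy=float(df["base_hit"].mean()),
        location_accuracy=float(df["loc_hit"].mean()),
        table=table,
    )


# ---------------------------------------------------------------------------
# Policy wrapper & serialization


class NeuralPolicy:
    """Adapts a trained predictor pair to the playout MovePolicy contract.

    The base predictor runs without a location marker (base and location
    are sampled independently during playout); outputs renormalize to 1
    after the playout stage masks locked positions.
    """

    def __init__(self, base: BasePredictor, location: LocationPredictor):
        if base.arch.max_length != location.arch.max_length:
            raise ValueError("predictor pair disagrees on max_length")
        self.base = base
        self.location = location

    def predict(self, state: PuzzleState) -> PolicyOutput:
        if state.length > self.base.max_length:
            raise ValueError(
                f"puzzle length {state.length} exceeds trained "
                f"max_length {self.base.max_length}"
            )
        fb = encode_state(state)
        return PolicyOutput(
            base_probs=self.base.predict_proba(fb),
            location_probs=self.location.predict_proba(fb),
        )


def predictor_as_policy(base: BasePredictor,
                        location: LocationPredictor) -> NeuralPolicy:
    return NeuralPolicy(base, location)


def save_predictors(path, base: BasePredictor, location: LocationPredictor):
    """Serialize both networks plus the architecture config to ``.npz``."""
    payload = {
        f"base_{i}": w for i, w in enumerate(base.network.get_weights())
    }
    payload.update(
        {f"loc_{i}": w for i, w in enumerate(location.network.get_weights())}
    )
    meta = {
        "arch": asdict(base.arch),
        "base_history": base.history,
        "loc_history": location.history,
    }
    payload["meta"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_predictors(path) -> tuple[BasePredictor, LocationPredictor]:
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    arch_dict = meta["arch"]
    for key in ("conv_channels", "fc_widths"):
        arch_dict[key] = tuple(arch_dict[key])
    arch = ArchConfig(**arch_dict)
    rng = np.random.default_rng(0)  # shapes only; weights overwritten
    base = BasePredictor(arch, _build_base_network(arch, rng),
                         meta["base_history"])
    loc = LocationPredictor(arch, _build_location_network(arch, rng),
                            meta["loc_history"])
    base.network.set_weights(
        [data[f"base_{i}"] for i in range(len(base.network.get_weights()))]
    )
    loc.network.set_weights(
        [data[f"loc_{i}"] for i in range(len(loc.network.get_weights()))]
    )
    return base, loc
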
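# foldcraft

RNA secondary-structure design (inverse folding) with strategies learned
from human puzzle solvers.

Given a target secondary structure in dot-bracket notation, the task is
to find a nucleotide sequence whose predicted minimum-free-energy (MFE)
structure equals the target under a nearest-neighbor thermodynamic
model.  Expert players of RNA-design puzzle games consistently beat
classical algorithms at this; `foldcraft` packages the two ingredients
of that style of play for programmatic use:

1. **Stochastic move playout.**  A *move policy* maps the puzzle state
   to probability vectors over the four bases (A, U, G, C) and over
   sequence positions.  Moves are sampled and applied one at a time,
   refolding after each, for at most 3·L moves (L = puzzle length).
   Policies are pluggable: a built-in baseline that attends to
   incorrectly paired positions, or a trained move predictor that
   imitates logged design moves.
2. **Single-action playout (SAP).**  Six canonical player strategies
   applied in order: fix mismatched target pairs to Watson-Crick
   (A-U/G-C), place G-C at stem closing pairs flanking loops, a guanine
   boost at the first position of internal-loop strands, the U-G-U-G
   super boost in 2×2 internal loops, a guanine boost at the start of
   hairpin loops, and random reorientation of base pairs in misfolded
   helices.  An edit is kept only if the refolded structure moves
   strictly closer to the target, measured by the matching-block ratio
   (2M/T) of the two dot-bracket strings.

Folding and energy evaluation go through ViennaRNA, configured by
default for Turner1999-style nearest-neighbor parameters at 37 °C (the
model in which the classic design benchmarks are known solvable); the
engine and parameter set are injectable.

The package also contains the training side: encoding of puzzle states
into the fixed feature block (one-hot sequence; dot-bracket symbols as
1/2/3; pairmaps, where `pairmap[i]` is the partner index of position i
or −1; energies; lock flags), expansion of tabular move logs into
training records, a pair of small convolutional predictors (base and
location) with seeded, reproducible training, and stratified accuracy
reporting.  A fixtures module generates random valid target structures
with controllable motif mixes and a deterministic scripted "teacher"
whose movesets stand in for player data.

## Quick start

```python
from foldcraft import FoldingEngine, solve

engine = FoldingEngine()              # Turner1999-style, 37 °C
result = solve("((((....))))", engine=engine, policy=None, seed=0)
print(result.solved, result.state.sequence)
```

prints

```
True AAAGGAAACUUU
```

— SAP alone designs a sequence whose MFE structure is the 4-bp hairpin
`((((....))))`: three A-U pairs under a G-C closing pair with a
G-boosted loop, at −3.2 kcal/mol.  `result.trace` lists every accepted
move with its strategy and the similarity reached (1.0 = solved).

The same pipeline runs from the shell:

```bash
foldcraft solve --target "((((....))))" --policy none --seed 0
foldcraft make-fixtures --kind benchmark --tier medium -n 20 --out medium.tsv
foldcraft bench --benchmark medium.tsv --policy baseline --repeats 3
```

The `examples/` directory has one short narrative script per
capability: folding + encoding, SAP solving, move-predictor training,
and benchmark running.  For instance `examples/03_train_move_predictor.py`
trains the predictor pair on ~1,100 scripted-teacher moves and prints

```
held-out base accuracy:     0.978 (random baseline 1/3)
held-out location accuracy: 0.943 (uniform baseline 0.049)
```

— the teacher's moves are stereotyped by construction, so the
predictors recover them far above the random-guess rates.

Benchmark files are TSV (`name<TAB>structure<TAB>locks`, locks optional
`x`/`o` strings); any published structure list in that form can be run
through `foldcraft bench`.  Solved counts on external benchmarks depend
on the exact folding engine version and the trained policy, so they are
reported, not asserted.

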
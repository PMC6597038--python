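"""Fold a sequence, inspect its motifs, and encode the puzzle state.

Builds the worked 17-nt example: a 4-bp hairpin whose sequence folds at
-2.2 kcal/mol, encoded into the numeric feature block used by the move
predictors (one-hot bases, 1/2/3 structure symbols, pairmaps, locks).
"""

from foldcraft import (
    EngineConfig,
    FoldingEngine,
    dotbracket_to_pairmap,
    encode_state,
    find_motifs,
    make_state,
)

engine = FoldingEngine(EngineConfig(parameter_set="turner1999"))

sequence = "CCAGAAAAAAAAACUGG"
structure, energy = engine.mfe_fold(sequence)
print(f"sequence:  {sequence}")
print(f"MFE fold:  {structure}  ({energy} kcal/mol)")
# The minimum-free-energy ("natural") structure is the shape this
# sequence is predicted to adopt; a puzzle is solved when it equals
# the target structure.

pairmap = dotbracket_to_pairmap(structure)
print(f"pairmap:   {pairmap}")
# pairmap[i] is the 0-based index paired with i (-1 = unpaired):
# position 0 pairs with 16, so pairmap[0] == 16.

for motif in find_motifs(pairmap):
    print(f"motif:     {motif.kind:13s} positions {motif.positions}")

state = make_state(sequence, structure, engine,
                   locks="x" + "o" * 15 + "x")
block = encode_state(state)
print(f"one-hot row 0 (C): {block.onehot[0].tolist()}")
print(f"structure symbols: {block.natural_struct.tolist()}")
print(f"locks (1 free / 2 locked): {block.locks.tolist()}")
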
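"""Design a sequence for a target structure with SAP alone.

Starts from all-adenine and applies the six canonical player strategies
(fix mismatches, G-C end pairs, G boosts, U-G super boost, pair flips),
accepting edits only when the refolded structure moves closer to the
target.  The printed trace shows which strategy produced each accepted
move and the similarity reached.
"""

from foldcraft import FoldingEngine, solve

engine = FoldingEngine()
target = "((..((....))..))"  # two stems around a 2x2 internal loop

result = solve(target, engine=engine, policy=None, seed=0)

print(f"target:   {target}")
print(f"solved:   {result.solved}")
print(f"sequence: {result.state.sequence}")
print(f"natural:  {result.state.natural_db}")
print(f"energy:   {result.state.natural_energy} kcal/mol")
print("accepted moves (strategy, 1-based position, edit, similarity):")
for mv in result.trace:
    print(f"  {mv.strategy:22s} {mv.position + 1:3d}  "
          f"{mv.old_base}->{mv.new_base}  {mv.similarity_after:.3f}")
# similarity is the matching-block ratio of the natural vs target
# dot-bracket strings; 1.000 means the puzzle is solved.
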
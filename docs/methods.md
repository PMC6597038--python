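# Methods

## Problem and model

Inverse folding: given a target secondary structure (dot-bracket, no
pseudoknots), find a sequence over {A, U, G, C} whose minimum-free-
energy structure under a nearest-neighbor thermodynamic model equals
the target.  A puzzle state carries the sequence, the target structure,
the current MFE ("natural") structure and energy, and a lock mask of
positions that may not be edited.  All coordinates are 0-based
internally; the CLI displays 1-based positions.

Folding is delegated to ViennaRNA through a two-function adapter (MFE
fold; energy of a sequence on a fixed structure).  Defaults: Turner1999
parameter table, 37 °C, dangling-end treatment `dangles=2` (the library
default; the original game client's exact dangle convention is not
documented, so the adapter records whatever convention it ran with in
every result).  ViennaRNA holds the parameter table as process-global
state; the adapter tracks the loaded table and reloads on change, so
engines with different parameter sets can coexist.  Energies are
rounded to 0.01 kcal/mol (engine print precision) and compared at that
tolerance.  Evaluating the energy of a sequence *on the target*
structure is optional and skipped by default: when the target pairs
non-complementary bases the value is not meaningful.

## State encoding

The feature block fixes the encoding conventions: one-hot sequence with
column order A, U, G, C; dot-bracket symbols `.`/`(`/`)` as 1/2/3;
natural and target energies in kcal/mol as-is; natural and target
pairmaps as 0-based partner indices (−1 unpaired); locks as 1 (free) /
2 (locked).  Copy/reset events in imported move logs mark the affected
one-hot rows as [1,1,1,1] and contribute no labels.  The published
worked example of this encoding contains an internal inconsistency
(its target row has two more symbols than the 17-nt sequence, while its
target pairmap row has exactly 17 entries); this package requires all
fields of a state to share one length and reads the example at the
17-nt length implied by the pairmap row, i.e. with target
`(((((.......)))))`.

## Similarity

Closeness of two equal-length dot-bracket strings is the Ratcliff-
Obershelp matching-block ratio 2M/T as computed by Python's
`difflib.SequenceMatcher` with `autojunk=False` (the junk heuristic
must not fire on a 3-symbol alphabet).  It is symmetric, in [0, 1], and
1 exactly on identical strings.  A `longest_block` mode (largest single
common block over length) is available as a configuration switch for
studies of the un-normalized variant.

## Single-action playout

Strategy order: (1) fix mismatches, (2) G-C end pairs, (3) G internal-
loop boost, (4) U-G-U-G super boost, (5) G hairpin boost, (6) flip
pairs.  Motifs are parsed from the target structure: stems are maximal
runs of stacked pairs; a bulge is an internal loop with one empty
strand; an "end pair" is a stem closing pair adjacent to any loop
(hairpin, internal, bulge or multiloop).  Strategy details and tie-
breaks:

* Mismatch fixing keeps the lower-index base and writes the Watson-
  Crick complement at its partner (always yielding A-U or G-C); if the
  lower base is locked the unlocked partner is complemented; fully
  locked pairs are skipped.  G-U counts as correctly paired and is
  never "fixed".  Fixes are grouped per target stem.
* G-C end pairs try both orientations (G on the 5′ or 3′ side); the
  better-refolding one is kept, with lower free energy breaking
  similarity ties.
* The hairpin boost targets the first loop position; an option also
  boosts the last (the "each strand" reading of a single-stranded
  loop).
* Flip pairs enumerates orientation bitmasks over a misfolded helix's
  flippable pairs (both positions unlocked, different bases): all
  2^k − 1 non-trivial masks when the attempt budget covers them,
  otherwise that many distinct random masks.  This makes the search
  exactly exhaustive for small helices when attempts ≥ 2^k.

Acceptance: a candidate *commits* only if the refolded natural
structure is strictly closer to the target than at the last committed
step, so the committed-step similarity sequence is strictly
increasing.  Early edits frequently leave the fold unchanged — a
complemented all-A-U helix is often too weak to appear in the MFE
structure until a closing G-C or loop boost stabilizes it — so
similarity-*neutral* edits proposed by the deterministic strategies
(1-5) are held provisionally within a sweep: they are committed as part
of the next strictly-improving step, and rolled back when a sweep ends
without one.  Edits that lower similarity revert immediately, and the
random flip strategy only ever commits strictly.  A committed step is
attributed to the strategy that completed the improvement; enabling
edits held from earlier strategies are folded into that step's move
list.  Termination: at most `max_sweeps` (default 5) sweeps, stopping
early when a sweep commits nothing (provisional edits net to zero) or
when the natural structure equals the target.  Default flip budget: 16
attempts per helix.  Both defaults are desk-scale choices; the driver
is deterministic given (state, config, seed).

## Stochastic playout and the two-stage solver

A move policy returns non-negative base and location probability
vectors that are renormalized to sum to 1.  Playout samples a location
(locked positions masked, renormalized), then a base, independently —
the two predictors are separate and no conditioning of base on sampled
location is attempted.  By default the current base is masked out of
the base vector at the sampled location, so every applied move changes
the sequence; a toggle restores budget-consuming no-ops for fidelity
studies.  The move budget is 3×L; playout stops early when solved.
The solver runs playout first (if a policy is given), then SAP on the
resulting state, one way — SAP does not hand back to the policy.
Start sequences default to all-adenine, the conventional initial
puzzle state; locked positions keep the start sequence's bases.

The baseline policy spreads location mass uniformly over positions
whose natural pairing disagrees with the target (falling back to all
unlocked positions) and base mass uniformly over the three alternatives
to the current base, giving the analytic 1/3 top-1 rate against any
ground truth that changes the base.

## Move predictors

Two predictors imitate logged moves: a base predictor (4-way softmax)
and a location predictor (softmax over positions).  Inputs are
per-position channel matrices zero-padded to a fixed maximum length
(default 64; 84 in the recovery experiment to cover medium-tier
targets) with an explicit validity mask channel: one-hot sequence (4),
structure symbols scaled by 1/3 (2), partner indices scaled by the
maximum length (2), lock flag, mask, and the two energies scaled by
1/10 kcal/mol broadcast along the sequence.  The base predictor carries
one extra location-marker channel: during training and evaluation it
marks the true move location (base accuracy for a logged move is
defined given where the move was made), while the playout policy
wrapper leaves it zero, keeping base and location sampling independent.
Feature-group switches (sequence / dot-bracket / pairmap) support
reduced-input ablations.

The networks are 1-D convolutions along the sequence axis — the
location predictor fully convolutional with a per-position score head,
the base predictor a conv stack with a dense head — trained with
softmax cross-entropy and Adam in a self-contained numpy engine.  One
seeded generator drives initialization, shuffling and dropout, making
training bit-reproducible.  The default schedule is desk-scale: two
conv layers (8, 16 channels, kernel 5, stride 1), one dense layer of
48, dropout 0.1, ReLU, minibatch 50, 12 epochs, learning rate 3e-3.
The full-scale schedule of the original study (10 conv layers doubling
1→1024 channels, kernel 9, stride 2, four dense layers 1024/1024/2048/
4096, sigmoid, dropout 0.1, minibatch 100) is expressible in
`ArchConfig` but is a multi-GPU-days configuration and is not trained
here.  The original description gives a two-dimensional stride for a
sequence-axis convolution; this implementation strides along the
sequence axis only.  Model artifacts serialize the weights together
with the architecture config and training histories.

## Synthetic data

The structure generator composes stems (3-7 bp by default) around
hairpins (≥ 3 unpaired, the physical minimum), bulges (1-3 nt),
internal loops (1-3 nt per strand, biased toward the 2×2 loops the
super boost targets) and two-branch multiloops, with configurable motif
weights, nesting depth and length range; every draw is a valid
non-crossing structure.  Benchmark tiers define the study conditions:
*easy* = single hairpins and two-stem structures, L ≤ 40; *medium* =
structures containing internal loops or multiloops, L ≤ 80.  Tier
generators use stems ≥ 4 bp and hairpins ≥ 4 nt: benchmark targets
must be design-feasible, and 3-bp stems closed by triloops are
frequently unsolvable with A-U pairs plus a single G-C closing pair in
the Turner model — not "easy" by any reading.

The scripted teacher solves a target from all-A by applying, in 5′→3′
motif order: mismatch complements (per stem, outer to inner), U-G super
boosts, G loop boosts, G hairpin boosts, then G-C closing pairs (G on
the 5′ side).  Each move is logged with the encoded state before it.
The teacher is deterministic, emits one base change per record, and
never revisits a position back-and-forth, so its movesets are
stereotyped by construction — a clean learnable signal with a known
upper bound.  What passing the recovery test shows is that the training
pipeline can extract a stereotyped policy from logged moves; it does
not show that accuracies on *human* move logs would be comparable,
since real players mix strategies, explore, and use multi-move plans
that a per-move imitation target does not capture.

## Problem sizes and verification scale

The test suite runs at desk scale: property tests use 1,000 random
structures (round trips), exhaustive enumeration at L ≤ 12 (motif
parsing), 200 random states (SAP invariants), 50 easy + 30 medium
targets (SAP capability), ~2,300 teacher records from 210 targets
(policy recovery), and 5-20 seeds (consistency).  External structure
benchmarks and human move corpora are not bundled; the benchmark runner
accepts any conforming TSV, and solved counts on such lists are
reported, never asserted, because they additionally depend on the exact
folding-engine version and trained-policy quality.

## Known limitations

* Pseudoknots, multi-state (switch) targets, chemical modifications and
  sequence-composition constraints are out of scope.
* SAP encodes six strategies; motifs needing rarer idioms (e.g. zigzag
  stabilization) are not solvable by it.
* The similarity metric is string-local: structures that differ by a
  register shift can score high while sharing no pairs.
* Turner1999-compatibility approximates the legacy engine the player
  strategies were developed against; per-structure results can differ
  from the original engine's in edge cases.
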
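"""Train the base/location move predictors on scripted-teacher movesets.

A deterministic teacher solves synthetic targets with the canonical
strategies, logging each move as (encoded state, base, position).  Two
small convolutional predictors are trained on those records and scored
on held-out moves, then wrapped as a sampling policy for the playout
stage.  Expect held-out accuracies far above the random baselines
(1/3 for bases, 1/L for locations) because the teacher is stereotyped.
"""

import numpy as np

from foldcraft import (
    ArchConfig,
    FoldingEngine,
    evaluate_predictor,
    predictor_as_policy,
    solve,
    train_move_predictor,
)
from foldcraft.fixtures import teacher_dataset, tier_structures

engine = FoldingEngine()
rng = np.random.default_rng(11)

targets = tier_structures("easy", 120, rng)
records = teacher_dataset(targets, engine)
print(f"teacher movesets: {len(records)} records from {len(targets)} targets")

perm = np.random.default_rng(0).permutation(len(records))
split = int(0.8 * len(records))
train = [records[i] for i in perm[:split]]
held = [records[i] for i in perm[split:]]

base, location = train_move_predictor(train, ArchConfig(),
                                      np.random.default_rng(3))
report = evaluate_predictor((base, location), held)
mean_len = np.mean([r.length for r in held])
print(f"held-out base accuracy:     {report.base_accuracy:.3f} "
      f"(random baseline 1/3)")
print(f"held-out location accuracy: {report.location_accuracy:.3f} "
      f"(uniform baseline {1 / mean_len:.3f})")
print(report.table.round(3).to_string())

policy = predictor_as_policy(base, location)
result = solve("((((....))))", engine=engine, policy=policy, seed=1)
print(f"policy-guided solve of ((((....)))): solved={result.solved}, "
      f"{result.counters['policy_moves']} policy moves, "
      f"{result.counters['sap_moves']} SAP moves")
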
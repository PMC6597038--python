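"""Move-log encoding, predictor training, evaluation, policy wrapping."""

import numpy as np
import pandas as pd
import pytest

from foldcraft import (
    ArchConfig,
    BaselinePolicy,
    build_training_examples,
    evaluate_predictor,
    make_state,
    predictor_as_policy,
    solve,
    train_move_predictor,
)
from foldcraft.core import BASES
from foldcraft.fixtures import teacher_dataset, teacher_moves, tier_structures
from foldcraft.playout import PolicyOutput
from foldcraft.policy import (
    BasePredictor,
    LocationPredictor,
    load_predictors,
    save_predictors,
)

TINY_ARCH = ArchConfig(conv_channels=(4,), fc_widths=(16,), epochs=3,
                       minibatch=20, max_length=48)


def _log_row(seq="GGGGAAAACCCC", natural="((((....))))",
             target="((((....))))", pos="4", base="G", locks=""):
    return {
        "seq": seq, "natural_db": natural, "target_db": target,
        "natural_energy": -1.0, "target_energy": np.nan,
        "locks": locks, "move_pos": pos, "move_base": base,
    }


class TestBuildTrainingExamples:
    def test_simultaneous_mutation_yields_separate_records(self):
        log = pd.DataFrame([_log_row(pos="4;5", base="G;C")])
        records = build_training_examples(log)
        assert [(r.label_location, r.label_base) for r in records] == [
            (4, "G"), (5, "C")
        ]

    def test_reset_event_encodes_ones_and_no_label(self):
        from foldcraft.policy import encode_log_row

        fb, labelled = encode_log_row(_log_row(pos="2;3", base="reset"))
        assert labelled == []
        assert fb.onehot[2].tolist() == [1, 1, 1, 1]
        assert fb.onehot[3].tolist() == [1, 1, 1, 1]
        log = pd.DataFrame([_log_row(pos="2;3", base="reset")])
        assert build_training_examples(log) == []

    def test_empty_log_gives_empty_list(self):
        assert build_training_examples(pd.DataFrame(columns=[
            "seq", "natural_db", "target_db", "natural_energy",
            "move_pos", "move_base",
        ])) == []

    def test_malformed_rows_are_skipped_not_fatal(self, caplog):
        log = pd.DataFrame([
            _log_row(),
            _log_row(natural="((((....)))"),  # length mismatch
            _log_row(pos="99"),  # label out of range
        ])
        with caplog.at_level("WARNING"):
            records = build_training_examples(log)
        assert len(records) == 1
        assert "skipped 2" in caplog.text


@pytest.fixture(scope="module")
def teacher_records(engine):
    targets = tier_structures("easy", 40, np.random.default_rng(31))
    records = teacher_dataset(targets, engine)
    assert len(records) >= 200
    return records


class TestTraining:
    def test_insufficient_data_raises_with_minimum(self):
        with pytest.raises(ValueError, match="minibatch"):
            train_move_predictor([], TINY_ARCH)

    def test_untrained_predictor_outputs_near_uniform(self, teacher_records):
        arch = ArchConfig(conv_channels=(4,), fc_widths=(16,), epochs=0,
                          minibatch=20, max_length=48)
        bp, lp = train_move_predictor(teacher_records[:40], arch,
                                      np.random.default_rng(0))
        probs = bp.predict_proba(teacher_records[0].features)
        assert probs.max() < 0.6  # no class strongly preferred before training

    def test_training_is_seed_reproducible(self, teacher_records):
        runs = []
        for _ in range(2):
            bp, lp = train_move_predictor(
                teacher_records[:100], TINY_ARCH, np.random.default_rng(7)
            )
            rep = evaluate_predictor((bp, lp), teacher_records[100:160])
            runs.append((bp.history, lp.history,
                         rep.base_accuracy, rep.location_accuracy))
        assert runs[0] == runs[1]

    def test_training_loss_decreases(self, teacher_records):
        bp, lp = train_move_predictor(teacher_records[:200], TINY_ARCH,
                                      np.random.default_rng(1))
        assert bp.history[-1] < bp.history[0]
        assert lp.history[-1] < lp.history[0]


class TestEvaluation:
    def _stub_predictors(self, records):
        """Predictors that echo each record's own labels (perfect recall)."""
        arch = TINY_ARCH
        yb = np.array([BASES.index(r.label_base) for r in records])
        yl = np.array([r.label_location for r in records])

        class StubBase(BasePredictor):
            def __init__(self):
                self.arch = arch
                self.history = []

            def logits(self, x, train=False):
                return np.eye(4)[yb[: x.shape[0]]]

        class StubLoc(LocationPredictor):
            def __init__(self):
                self.arch = arch
                self.history = []

            def logits(self, x, train=False):
                return np.eye(arch.max_length)[yl[: x.shape[0]]]

        return StubBase(), StubLoc()

    def test_perfect_predictor_scores_one_everywhere(self, teacher_records):
        records = teacher_records[:150]
        report = evaluate_predictor(self._stub_predictors(records), records)
        assert report.base_accuracy == 1.0
        assert report.location_accuracy == 1.0
        assert (report.table["base_accuracy"] == 1.0).all()

    def test_bin_totals_sum_to_overall(self, teacher_records):
        records = teacher_records[:150]
        report = evaluate_predictor(self._stub_predictors(records), records)
        table = report.table
        for group in ("all", "paired", "unpaired"):
            if (group, "All") not in table.index:
                continue
            bins = table.loc[group].drop(index="All")
            assert bins["moves"].sum() == table.loc[(group, "All"), "moves"]
        assert table.loc[("all", "All"), "moves"] == len(records)
        paired_total = sum(
            table.loc[(g, "All"), "moves"]
            for g in ("paired", "unpaired")
            if (g, "All") in table.index
        )
        assert paired_total == len(records)

    def test_empty_record_set_rejected(self, teacher_records):
        with pytest.raises(ValueError):
            evaluate_predictor(self._stub_predictors(teacher_records), [])


class TestPolicyWrapper:
    def test_outputs_are_probability_vectors(self, engine, teacher_records):
        bp, lp = train_move_predictor(teacher_records[:100], TINY_ARCH,
                                      np.random.default_rng(2))
        policy = predictor_as_policy(bp, lp)
        state = make_state("A" * 12, "((((....))))", engine)
        out = policy.predict(state)
        assert out.base_probs.shape == (4,)
        assert out.location_probs.shape == (12,)
        assert out.base_probs.sum() == pytest.approx(1.0)
        assert out.location_probs.sum() == pytest.approx(1.0)
        # deterministic at inference
        again = policy.predict(state)
        assert np.array_equal(out.base_probs, again.base_probs)

    def test_length_beyond_trained_maximum_rejected(self, engine,
                                                    teacher_records):
        bp, lp = train_move_predictor(teacher_records[:100], TINY_ARCH,
                                      np.random.default_rng(2))
        policy = predictor_as_policy(bp, lp)
        long_target = "(" * 10 + "." * 40 + ")" * 10
        state = make_state("A" * 60, long_target, engine)
        with pytest.raises(ValueError, match="max_length"):
            policy.predict(state)

    def test_teacher_policy_beats_baseline_on_move_count(self, engine):
        """A perfect imitation of the scripted teacher solves toys in
        fewer playout moves than the baseline policy (median, 20 seeds)."""

        class TeacherPolicy:
            def predict(self, state):
                moves = teacher_moves(state)
                loc = np.zeros(state.length)
                base = np.zeros(4)
                if not moves:
                    loc[:] = 1.0
                    base[:] = 1.0
                else:
                    loc[moves[0].position] = 1.0
                    base[BASES.index(moves[0].new_base)] = 1.0
                return PolicyOutput(base, loc)

        target = "((((....))))..((((....))))"
        counts = {"teacher": [], "baseline": []}
        for seed in range(20):
            for name, pol in (("teacher", TeacherPolicy()),
                              ("baseline", BaselinePolicy())):
                r = solve(target, engine=engine, policy=pol,
                          use_sap=False, seed=seed)
                counts[name].append(
                    len(r.trace) if r.solved else 3 * len(target) + 1
                )
        assert np.median(counts["teacher"]) < np.median(counts["baseline"])


def test_predictor_serialization_roundtrip(tmp_path, teacher_records):
    bp, lp = train_move_predictor(teacher_records[:100], TINY_ARCH,
                                  np.random.default_rng(4))
    path = tmp_path / "model.npz"
    save_predictors(path, bp, lp)
    bp2, lp2 = load_predictors(path)
    fb = teacher_records[0].features
    assert np.allclose(bp.predict_proba(fb), bp2.predict_proba(fb))
    assert np.allclose(lp.predict_proba(fb), lp2.predict_proba(fb))
    assert bp2.arch == bp.arch
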
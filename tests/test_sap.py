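"""Single-action playout: similarity metric, strategies, driver."""

import numpy as np
import pytest

from foldcraft import PuzzleState, SapConfig, StructureError, make_state, sap_solve
from foldcraft.core import CANONICAL_PAIRS, Move, apply_moves, parse_locks
from foldcraft.sap import (
    apply_strategy,
    candidates_fix_mismatches,
    candidates_flip_pairs,
    candidates_g_hairpin_boost,
    candidates_g_internal_loop_boost,
    candidates_gc_end_pairs,
    candidates_ugug_superboost,
    misfolded_helices,
    similarity,
)

from conftest import random_structures


# ---------------------------------------------------------------------------
# Similarity


def block_match_ratio(a, b):
    """Independent recursive longest-common-block matcher (oracle).

    Finds the longest common contiguous block by brute force, recurses
    left and right of it, and returns 2M/T.
    """

    def longest_block(a, b):
        best = (0, 0, 0)  # (size, ai, bi)
        for i in range(len(a)):
            for j in range(len(b)):
                k = 0
                while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                    k += 1
                if k > best[0]:
                    best = (k, i, j)
        return best

    def matched(a, b):
        if not a or not b:
            return 0
        size, i, j = longest_block(a, b)
        if size == 0:
            return 0
        return size + matched(a[:i], b[:j]) + matched(a[i + size:], b[j + size:])

    total = len(a) + len(b)
    return 2.0 * matched(a, b) / total if total else 1.0


def test_similarity_identical_and_disjoint():
    assert similarity("((((....))))", "((((....))))") == 1.0
    assert similarity("((((", "))))") == 0.0


def test_similarity_matches_block_decomposition_oracle():
    pairs = [("(((...)))", "((.....))")]
    structs = random_structures(30, seed=9, min_len=10, max_len=40)
    rng = np.random.default_rng(2)
    for _ in range(30):
        a, b = rng.choice(len(structs), 2)
        if len(structs[a]) == len(structs[b]):
            pairs.append((structs[a], structs[b]))
    # also same-length perturbed pairs
    for db in structs[:10]:
        flipped = db.replace("(", ".", 2)
        pairs.append((db, flipped))
    for a, b in pairs:
        assert similarity(a, b) == pytest.approx(block_match_ratio(a, b))
        assert similarity(a, b) == similarity(b, a)  # symmetric


def test_similarity_rejects_length_mismatch():
    with pytest.raises(StructureError):
        similarity("...", "....")


# ---------------------------------------------------------------------------
# Strategy proposals (pure candidate generation)


def _state(seq, target, natural=None, locks=None, energy=0.0):
    return PuzzleState(
        sequence=seq,
        target_db=target,
        natural_db=natural if natural is not None else "." * len(seq),
        natural_energy=energy,
        locked=parse_locks(locks, len(seq)),
    )


class TestFixMismatches:
    def test_keeps_lower_index_base(self):
        cands = candidates_fix_mismatches(_state("CAAAAA", "(....)"))
        assert [c.variants for c in cands] == [[[Move(5, "G")]]]

    def test_complementary_pair_untouched(self):
        assert candidates_fix_mismatches(_state("GAAAAC", "(....)")) == []

    def test_c_opposite_a_becomes_u(self):
        # mismatched C paired against a kept A is switched to U
        cands = candidates_fix_mismatches(_state("ACCCC", "(...)"))
        assert cands[0].variants == [[Move(4, "U")]]

    def test_gu_wobble_counts_as_paired(self):
        assert candidates_fix_mismatches(_state("GAAAAU", "(....)")) == []

    def test_locked_lower_base_complements_partner(self):
        cands = candidates_fix_mismatches(
            _state("CAAAAA", "(....)", locks="xooooo")
        )
        assert cands[0].variants == [[Move(5, "G")]]
        # partner locked instead: mutate the lower index
        cands = candidates_fix_mismatches(
            _state("AAAAAC", "(....)", locks="ooooox")
        )
        assert cands[0].variants == [[Move(0, "G")]]
        # both locked: skip
        assert candidates_fix_mismatches(
            _state("CAAAAA", "(....)", locks="xoooox")
        ) == []

    def test_full_pass_leaves_only_watson_crick_pairs(self):
        for db in random_structures(40, seed=5):
            rng = np.random.default_rng(len(db))
            seq = "".join(rng.choice(list("AUGC"), size=len(db)))
            state = _state(seq, db)
            moves = [
                m for c in candidates_fix_mismatches(state) for m in c.variants[0]
            ]
            fixed = apply_moves(seq, moves)
            for i, j in enumerate(state.target_pm):
                if j > i:
                    assert fixed[i] + fixed[j] in CANONICAL_PAIRS
                    if seq[i] + seq[j] not in CANONICAL_PAIRS:
                        # repaired pairs are strictly Watson-Crick
                        assert fixed[i] + fixed[j] in {"AU", "UA", "GC", "CG"}


class TestGcEndPairs:
    def test_both_orientations_offered(self):
        cands = candidates_gc_end_pairs(_state("AUAAGAAAUUAU", "((((....))))"))
        inner = next(
            c for c in cands if {m.position for v in c.variants for m in v} <= {3, 8}
        )
        assert [[(m.position, m.new_base) for m in v] for v in inner.variants] == [
            [(3, "G"), (8, "C")],
            [(3, "C"), (8, "G")],
        ]

    def test_gc_closing_lowers_energy(self, engine):
        # evaluate the same hairpin with A-U vs G-C closing pair
        db = "((((....))))"
        au = engine.eval_energy("AUAAGAAAUUAU", db)
        gc = engine.eval_energy("AUAGGAAACUAU", db)
        assert gc < au

    def test_already_gc_no_candidate(self):
        state = _state("AUAGGAAACUAU", "((((....))))")
        positions = {
            m.position
            for c in candidates_gc_end_pairs(state)
            for v in c.variants
            for m in v
        }
        assert 3 not in positions and 8 not in positions

    def test_locked_pair_no_candidate(self):
        state = _state("AAAAGAAACAAA", "((((....))))", locks="oooxooooxooo")
        positions = {
            m.position
            for c in candidates_gc_end_pairs(state)
            for v in c.variants
            for m in v
        }
        assert 3 not in positions and 8 not in positions


class TestBoosts:
    def test_g_internal_loop_boost_first_of_each_strand(self):
        state = _state("A" * 16, "((..((....))..))")
        cands = candidates_g_internal_loop_boost(state)
        assert [c.variants for c in cands] == [[[Move(2, "G"), Move(12, "G")]]]

    def test_g_internal_loop_boost_skips_existing_g(self):
        seq = "AA" + "G" + "A" * 9 + "G" + "AAA"
        state = _state(seq, "((..((....))..))")
        assert candidates_g_internal_loop_boost(state) == []

    def test_bulge_boosts_only_nonempty_strand(self):
        db = "((..((....))))"
        state = _state("A" * 14, db)
        cands = candidates_g_internal_loop_boost(state)
        assert [c.variants for c in cands] == [[[Move(2, "G")]]]

    def test_ugug_superboost_on_2x2_loop(self):
        state = _state("A" * 16, "((..((....))..))")
        cands = candidates_ugug_superboost(state)
        assert cands[0].variants == [
            [Move(2, "U"), Move(3, "G"), Move(12, "U"), Move(13, "G")]
        ]

    def test_ugug_ignores_other_loop_sizes(self):
        assert candidates_ugug_superboost(
            _state("A" * 14, "((.((....)).))")  # 1x1 loop
        ) == []

    def test_ugug_noop_when_already_set(self):
        seq = "AA" + "UG" + "A" * 8 + "UG" + "AA"
        assert candidates_ugug_superboost(
            _state(seq, "((..((....))..))")
        ) == []

    def test_g_hairpin_boost_first_loop_position(self):
        cands = candidates_g_hairpin_boost(_state("A" * 12, "((((....))))"))
        assert cands[0].variants == [[Move(4, "G")]]

    def test_g_hairpin_boost_triloop(self):
        cands = candidates_g_hairpin_boost(_state("A" * 11, "((((...))))"))
        assert cands[0].variants == [[Move(4, "G")]]

    def test_g_hairpin_boost_skips_existing_g(self):
        assert candidates_g_hairpin_boost(
            _state("AAAAGAAAAAAA", "((((....))))")
        ) == []

    def test_g_hairpin_boost_both_ends_option(self):
        cands = candidates_g_hairpin_boost(
            _state("A" * 12, "((((....))))"), both_ends=True
        )
        assert cands[0].variants == [[Move(4, "G"), Move(7, "G")]]


class TestFlipPairs:
    def _misfolded(self, engine):
        # four flippable A-U pairs too weak to fold: natural != target
        seq = "AUAUAAAAAUAU"
        state = make_state(seq, "((((....))))", engine)
        assert not state.solved
        return state

    def test_correct_state_has_no_candidates(self, engine):
        state = make_state("GGGGAAAACCCC", "((((....))))", engine)
        assert misfolded_helices(state) == []

    def test_seeded_flip_sequence_is_deterministic(self, engine):
        state = self._misfolded(engine)
        a = candidates_flip_pairs(state, 3, np.random.default_rng(4))
        b = candidates_flip_pairs(state, 3, np.random.default_rng(4))
        assert [c.variants for c in a] == [c.variants for c in b]

    def test_exhaustive_attempts_enumerate_all_orientations(self, engine):
        state = self._misfolded(engine)
        cands = candidates_flip_pairs(state, 16, np.random.default_rng(0))
        assert len(cands) == 1
        assert len(cands[0].variants) == 2 ** 4 - 1

    def test_flip_matches_exhaustive_orientation_oracle(self, engine):
        """With attempts >= 2^k the strategy finds the oracle's best
        orientation; with fewer it never beats the oracle."""
        rng = np.random.default_rng(77)
        checked = 0
        for _ in range(40):
            target = "((((....))))" if checked % 2 else "(((.....)))"
            pm = [-1] * len(target)
            from foldcraft.core import dotbracket_to_pairmap
            pm = dotbracket_to_pairmap(target)
            pairs = [(i, j) for i, j in enumerate(pm) if j > i]
            seq = list(rng.choice(list("AUGC"), size=len(target)))
            for i, j in pairs:
                bases = ["GC", "CG", "AU", "UA"][int(rng.integers(4))]
                seq[i], seq[j] = bases[0], bases[1]
            state = make_state("".join(seq), target, engine)
            if state.solved or not misfolded_helices(state):
                continue
            checked += 1
            k = len(pairs)
            # oracle: evaluate every orientation mask exhaustively
            best_oracle = similarity(state.natural_db, state.target_db)
            for mask in range(1, 1 << k):
                s = list(state.sequence)
                for b, (i, j) in enumerate(pairs):
                    if (mask >> b) & 1:
                        s[i], s[j] = s[j], s[i]
                folded = engine.mfe_fold("".join(s))[0]
                best_oracle = max(
                    best_oracle, similarity(folded, state.target_db)
                )
            for attempts in (2, 1 << k):
                out = apply_strategy(
                    state, "flip_pairs", engine,
                    SapConfig(flip_attempts=attempts),
                    np.random.default_rng(5),
                )
                got = similarity(out.state.natural_db, out.state.target_db)
                assert got <= best_oracle + 1e-12
                if attempts >= 1 << k:
                    assert got == pytest.approx(best_oracle)
        assert checked >= 5


# ---------------------------------------------------------------------------
# Driver


def test_sap_solves_simple_hairpin_from_all_a(engine):
    result = sap_solve(
        make_state("A" * 12, "((((....))))", engine),
        engine,
        rng=np.random.default_rng(0),
    )
    assert result.solved
    assert result.sweeps == 1


def test_sap_on_solved_input_is_a_noop(engine):
    result = sap_solve(make_state("GGGGAAAACCCC", "((((....))))", engine), engine)
    assert result.solved and result.trace == []


def test_sap_all_locked_unsolved_does_nothing(engine):
    state = make_state("A" * 12, "((((....))))", engine, locks="x" * 12)
    result = sap_solve(state, engine)
    assert not result.solved and result.trace == []
    assert result.state.sequence == "A" * 12


def test_sap_trace_similarity_strictly_increases(engine):
    for db in random_structures(20, seed=13, min_len=12, max_len=40):
        state = make_state("A" * len(db), db, engine)
        result = sap_solve(state, engine, rng=np.random.default_rng(1))
        sims = [sim for _, _, sim in result.trace]
        assert all(b > a for a, b in zip(sims, sims[1:]))


def test_sap_never_mutates_locked_positions(engine):
    rng = np.random.default_rng(3)
    for db in random_structures(20, seed=17, min_len=12, max_len=40):
        locks = "".join(rng.choice(["x", "o"], size=len(db), p=[0.2, 0.8]))
        state = make_state("A" * len(db), db, engine, locks=locks)
        result = sap_solve(state, engine, rng=np.random.default_rng(2))
        for _, moves, _ in result.trace:
            for mv in moves:
                assert locks[mv.position] == "o"
        # locked bases unchanged in the final sequence
        for i, c in enumerate(locks):
            if c == "x":
                assert result.state.sequence[i] == "A"


def test_sap_solve_is_deterministic(engine):
    state = make_state("A" * 22, "(((((((.....)))..))))." , engine)
    a = sap_solve(state, engine, rng=np.random.default_rng(9))
    b = sap_solve(state, engine, rng=np.random.default_rng(9))
    assert a.trace == b.trace
    assert a.state.sequence == b.state.sequence
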
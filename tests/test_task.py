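"""Grid geometry, templates, quadruplet realisation and schedules."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rotgen.task import (
    ANCHORS,
    EXPERIMENT_IDS,
    ROTATIONS,
    Transformation,
    build_mapping_block,
    build_schedule,
    canonical_templates,
    enumerate_quadruplets,
    pattern_of,
    realise_quadruplet,
    rotate_template,
    schedule_to_frame,
    trial_from_row,
    unsigned_pattern,
)

ALL_TRIALS = [
    t for far in (False, True)
    for t in enumerate_quadruplets(ROTATIONS, far_transfer=far)
]


class TestTemplates:
    def test_canonical_template_vectors(self):
        t0, t1, t2 = canonical_templates()
        assert t0.vectors == ((1, 0), (0, 1), (-1, 0))        # E, N, W
        assert t1.vectors == ((1, 1), (-1, 0), (1, -1))       # NE, W, SE
        assert t2.vectors == ((0, 1), (1, -1), (0, 1))        # N, SE, N

    def test_templates_tile_a_unit_square(self):
        for tpl in canonical_templates():
            offs = tpl.offsets()
            assert len(set(offs)) == 4
            si = sorted({o[0] for o in offs})
            sj = sorted({o[1] for o in offs})
            assert si[1] - si[0] == 1 and sj[1] - sj[0] == 1

    def test_quarter_turn_rotation_examples(self):
        t0, t1, _ = canonical_templates()
        assert rotate_template(t1, 90).compass == ("NW", "S", "NE")
        assert rotate_template(t1, 0) == t1
        assert rotate_template(t0, 180).compass == ("W", "S", "E")

    def test_rotation_must_be_quarter_turn(self):
        with pytest.raises(ValueError):
            rotate_template(canonical_templates()[0], 45)

    def test_twelve_rotated_templates_pairwise_distinct(self):
        seqs = {
            rotate_template(tpl, rot).vectors
            for tpl in canonical_templates()
            for rot in ROTATIONS
        }
        assert len(seqs) == 12  # 2D template matching is unambiguous


class TestRealisation:
    def test_canonical_walk_from_origin(self):
        trial = realise_quadruplet(0, Transformation(0), (0, 0))
        assert trial.positions == ((0, 0), (1, 0), (1, 1), (0, 1))

    def test_rotated_walk_starts_inside_the_square(self):
        trial = realise_quadruplet(0, Transformation(90), (0, 0))
        assert trial.positions == ((1, 0), (1, 1), (0, 1), (0, 0))

    def test_outer_anchor_rejected(self):
        with pytest.raises(ValueError):
            realise_quadruplet(1, Transformation(0), (3, 3))

    def test_every_quadruplet_occupies_its_anchor_square(self):
        for trial in ALL_TRIALS:
            a = trial.anchor
            square = {(a[0], a[1]), (a[0] + 1, a[1]),
                      (a[0], a[1] + 1), (a[0] + 1, a[1] + 1)}
            assert set(trial.positions) == square
            diffs = tuple(
                (q[0] - p[0], q[1] - p[1])
                for p, q in zip(trial.positions[:-1], trial.positions[1:])
            )
            expected = rotate_template(
                canonical_templates()[trial.category],
                trial.transformation.rotation).vectors
            assert diffs == expected

    def test_enumeration_counts(self):
        assert len(enumerate_quadruplets((0,))) == 27
        assert len(enumerate_quadruplets((0, 90))) == 54
        with pytest.raises(ValueError):
            enumerate_quadruplets(())


class TestPatterns:
    def test_signed_pattern_examples(self):
        cat1 = realise_quadruplet(1, Transformation(0), (0, 0))
        assert pattern_of(cat1, "i", signed=True) == "ABAB"
        cat0 = realise_quadruplet(0, Transformation(0), (0, 0))
        assert pattern_of(cat0, "j", signed=True) == "AABB"

    def test_unsigned_identifies_level_swap(self):
        assert unsigned_pattern("BABA") == unsigned_pattern("ABAB")
        assert unsigned_pattern("ABBA") == "ABBA"

    @given(st.lists(st.sampled_from("AB"), min_size=4, max_size=4))
    @settings(derandomize=True, max_examples=30)
    def test_unsigned_is_idempotent_and_swap_invariant(self, letters):
        token = "".join(letters)
        swap = token.translate(str.maketrans("AB", "BA"))
        assert unsigned_pattern(token) == unsigned_pattern(swap)
        assert unsigned_pattern(unsigned_pattern(token)) == unsigned_pattern(token)

    def test_only_six_signed_three_unsigned_patterns_realisable(self):
        for dim in "ij":
            signed = {pattern_of(t, dim, signed=True) for t in ALL_TRIALS}
            unsigned = {pattern_of(t, dim, signed=False) for t in ALL_TRIALS}
            assert len(signed) == 6
            assert len(unsigned) == 3


# expected (day, task, n_trials) sequences, one row per schedule-table row
_EXP1_ROWS = [(1, "quadruplet", 120), (1, "quadruplet", 105), (1, "quadruplet", 105)]
_MAPPING_D1 = [(1, "mapping", 48)] * 5 + [(1, "mapping", 96)]
_EXP23_ROWS = (
    [(1, "quadruplet", 60)] + _MAPPING_D1
    + [(2, "quadruplet", 60)] + [(2, "mapping", 48)] * 3
    + [(2, "quadruplet", 30), (2, "quadruplet", 30), (2, "mapping", 48),
       (2, "quadruplet", 60), (2, "mapping", 48),
       (2, "quadruplet", 90), (2, "quadruplet", 90)]
)
_EXP4_ROWS = (
    [(1, "filler", 60)] + _MAPPING_D1
    + [(2, "filler", 60)] + [(2, "mapping", 48)] * 3
    + [(2, "quadruplet", 60), (2, "mapping", 48),
       (2, "quadruplet", 60), (2, "mapping", 48),
       (2, "quadruplet", 90), (2, "quadruplet", 90)]
)
_EXPECTED_ROWS = {
    "1": _EXP1_ROWS, "2": _EXP23_ROWS, "3": _EXP23_ROWS, "4": _EXP4_ROWS,
}


class TestSchedules:
    @pytest.mark.parametrize("experiment_id", EXPERIMENT_IDS)
    @pytest.mark.parametrize("seed", [0, 7])
    def test_phase_rows_match_schedule_tables(self, experiment_id, seed):
        schedule = build_schedule(experiment_id, seed)
        rows = [(ph.day, ph.task, ph.n_trials) for ph in schedule.phases]
        assert rows == _EXPECTED_ROWS[experiment_id[0]]
        for ph in schedule.phases:
            assert len(ph.trials) == ph.n_trials

    def test_session_totals(self):
        assert build_schedule("1a", 3).day_total(1) == 330
        s2 = build_schedule("2a", 3)
        assert s2.day_total(1) == 396
        assert s2.day_total(2) == 600

    def test_unknown_experiment_rejected(self):
        with pytest.raises(ValueError):
            build_schedule("5a", 0)

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_categorisation_blocks_balanced(self, seed):
        schedule = build_schedule("2a", seed)
        trials = schedule.quadruplet_trials
        for _, block in itertools.groupby(trials, key=lambda t: t.block_index):
            cats = [t.category for t in block]
            assert len(cats) == 30
            assert all(cats.count(c) == 10 for c in range(3))

    def test_mixed_phase_transformation_balance(self):
        schedule = build_schedule("1a", 5)
        transfer = [t for t in schedule.quadruplet_trials if not t.feedback]
        assert len(transfer) == 105
        counts = {}
        for t in transfer:
            counts[t.transformation] = counts.get(t.transformation, 0) + 1
        assert sorted(counts.values()) == [15] * 7
        # training halves of the mixed blocks carry feedback
        train = [t for t in schedule.quadruplet_trials
                 if t.feedback and t.block_index >= 4]
        assert len(train) == 105

    def test_mixed_rotation_training_balanced(self):
        schedule = build_schedule("2a", 11)
        train = [t for t in schedule.quadruplet_trials
                 if t.phase in ("pretraining", "training")]
        rots = [t.transformation.rotation for t in train]
        assert rots.count(0) == rots.count(90) == len(train) // 2

    def test_exp3_pretraining_canonical_only(self):
        schedule = build_schedule("3b", 2)
        pre = [t for t in schedule.quadruplet_trials if t.phase == "pretraining"]
        assert pre and all(t.transformation.rotation == 0 for t in pre)
        assert schedule.trained_rotations == (0, 90)

    def test_filler_blocks_balanced(self):
        schedule = build_schedule("4a", 4)
        filler_phases = [ph for ph in schedule.phases if ph.task == "filler"]
        assert [ph.n_trials for ph in filler_phases] == [60, 60]
        for ph in filler_phases:
            for k in range(0, 60, 30):
                cats = [t.category for t in ph.trials[k:k + 30]]
                assert all(cats.count(c) == 10 for c in range(3))


class TestMappingBlocks:
    def test_every_cell_three_times(self):
        rng = np.random.default_rng(0)
        for restriction in ("both", "i_only", "j_only"):
            block = build_mapping_block(restriction, rng)
            assert len(block) == 48
            counts = {}
            for t in block:
                counts[t.target_cell] = counts.get(t.target_cell, 0) + 1
            assert sorted(counts.values()) == [3] * 16

    def test_restricted_runs_vary_one_dimension(self):
        block = build_mapping_block("i_only", np.random.default_rng(1))
        for run_start in range(0, 48, 12):
            run = block[run_start:run_start + 12]
            assert len({t.target_cell[1] for t in run}) == 1  # j fixed
            assert len({t.target_cell[0] for t in run}) == 4

    def test_seeds_permute_the_same_multiset(self):
        b1 = build_mapping_block("both", np.random.default_rng(1))
        b2 = build_mapping_block("both", np.random.default_rng(2))
        assert sorted(t.target_cell for t in b1) == sorted(t.target_cell for t in b2)
        assert [t.target_cell for t in b1] != [t.target_cell for t in b2]


class TestExport:
    def test_schedule_frame_roundtrip(self, exp1a_schedule):
        frame = schedule_to_frame(exp1a_schedule)
        trials = exp1a_schedule.quadruplet_trials
        assert len(frame) == len(trials)
        rebuilt = [trial_from_row(row) for _, row in frame.iterrows()]
        assert rebuilt == trials
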
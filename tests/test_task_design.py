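"""Task schedules: canonical structure, labelling, sampling distributions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from frogpan.task_design import (
    DEFAULT_MAX_STEP,
    LABELS,
    BlockSchedule,
    GenerationError,
    ScheduleError,
    SegmentSpec,
    canonical_schedule,
    label_trials,
    sample_targets,
    _draw_segment,
)


class TestCanonicalSchedules:
    def test_block_lengths(self):
        for kind in ("gradual", "abrupt"):
            assert canonical_schedule(kind).total_trials == 100

    def test_gradual_mean_path(self):
        means = [s.mean for s in canonical_schedule("gradual").segments]
        assert means == [25, 30, 35, 30, 25, 20, 15, 20, 25]
        assert [s.n_trials for s in canonical_schedule("gradual").segments] == [
            20, 10, 10, 10, 10, 10, 10, 10, 10,
        ]

    def test_gradual_second_segment(self):
        seg = canonical_schedule("gradual").segments[1]
        assert seg == SegmentSpec(mean=30, sd=1.7, n_trials=10, trend="gradually_increase")

    def test_abrupt_block_partition(self):
        sched = canonical_schedule("abrupt")
        assert len(sched.segments) == 9
        # each abrupt segment is a single trial at the new mean
        abrupt = [s for s in sched.segments if s.is_abrupt]
        assert [s.mean for s in abrupt] == [35, 25, 15, 25]
        assert all(s.n_trials == 1 for s in abrupt)

    def test_all_sds_fixed(self):
        for kind in ("gradual", "abrupt"):
            assert {s.sd for s in canonical_schedule(kind).segments} == {1.7}

    def test_unknown_block_kind(self):
        with pytest.raises(ScheduleError):
            canonical_schedule("practice")

    def test_idempotent(self):
        assert canonical_schedule("gradual") == canonical_schedule("gradual")


class TestLabels:
    def test_abrupt_positions_one_based(self):
        labels = label_trials(canonical_schedule("abrupt"))
        positions = [i + 1 for i, l in enumerate(labels) if l == "abruptly_changed"]
        assert positions == [30, 50, 70, 90]

    def test_gradual_positions_one_based(self):
        labels = label_trials(canonical_schedule("gradual"))
        pos = {i + 1 for i, l in enumerate(labels) if l == "gradually_changed"}
        expected = set()
        for lo in (21, 41, 61, 81):
            expected |= set(range(lo, lo + 10))
        assert pos == expected
        assert labels[4] == "fluct_gradual"  # trial 5 is a fluctuation trial

    def test_label_partition_counts(self):
        g = label_trials(canonical_schedule("gradual"))
        a = label_trials(canonical_schedule("abrupt"))
        assert g.count("fluct_gradual") == 60 and g.count("gradually_changed") == 40
        assert a.count("fluct_abrupt") == 96 and a.count("abruptly_changed") == 4
        assert set(g) | set(a) <= set(LABELS)


class TestSampling:
    def test_determinism(self):
        a = sample_targets(canonical_schedule("gradual"), seed=5)
        b = sample_targets(canonical_schedule("gradual"), seed=5)
        assert np.array_equal(a.targets, b.targets) and a.labels == b.labels

    def test_range_and_resolution(self):
        seq = sample_targets(canonical_schedule("abrupt"), seed=5)
        assert seq.targets.min() >= 0 and seq.targets.max() <= 50
        assert np.allclose(seq.targets, np.round(seq.targets, 1))

    def test_gradual_max_step_enforced(self):
        for seed in range(20):
            seq = sample_targets(canonical_schedule("gradual"), seed=seed)
            assert np.max(np.abs(np.diff(seq.targets))) <= DEFAULT_MAX_STEP

    def test_abrupt_jump_magnitude(self):
        # mean gap at the 30th trial is ~10 target units across seeds
        gaps = [
            abs(
                sample_targets(canonical_schedule("abrupt"), seed=s).targets[29]
                - sample_targets(canonical_schedule("abrupt"), seed=s).targets[28]
            )
            for s in range(40)
        ]
        assert 8.5 < np.mean(gaps) < 11.5

    def test_abrupt_segment_mean(self):
        # trials 31-49 track the new mean of 35
        vals = np.concatenate(
            [
                sample_targets(canonical_schedule("abrupt"), seed=s).targets[30:49]
                for s in range(30)
            ]
        )
        assert abs(vals.mean() - 35) < 3 * 1.7 / np.sqrt(len(vals)) + 0.05

    def test_trend_segments_mostly_monotone(self):
        seq = sample_targets(canonical_schedule("gradual"), seed=11)
        rising = seq.targets[20:30]  # trials 21-30, fluctuating upward trend
        rho = stats.spearmanr(np.arange(10), rising).statistic
        assert rho > 0.5

    def test_segment_marginal_distribution(self):
        # raw per-segment draws are the clipped/rounded Gaussian (KS, pooled
        # over seeds, before trend reordering)
        seg = SegmentSpec(mean=35, sd=1.7, n_trials=10, trend="randomly_fluctuate")
        draws = np.concatenate(
            [_draw_segment(np.random.default_rng(s), seg) for s in range(100)]
        )
        assert stats.kstest(draws, stats.norm(35, 1.7).cdf).pvalue > 0.01

    def test_unsatisfiable_constraint_raises(self):
        sched = BlockSchedule(
            "gradual",
            (
                SegmentSpec(5, 0.5, 5, "randomly_fluctuate"),
                SegmentSpec(45, 0.5, 5, "randomly_fluctuate"),
            ),
        )
        with pytest.raises(GenerationError):
            sample_targets(sched, seed=0, max_step=2.0)

    def test_bad_max_step(self):
        with pytest.raises(ScheduleError):
            sample_targets(canonical_schedule("gradual"), seed=0, max_step=-1)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mean=25, sd=0, n_trials=10, trend="randomly_fluctuate"),
            dict(mean=-1, sd=1.7, n_trials=10, trend="randomly_fluctuate"),
            dict(mean=25, sd=1.7, n_trials=0, trend="randomly_fluctuate"),
            dict(mean=25, sd=1.7, n_trials=10, trend="sideways"),
        ],
    )
    def test_invalid_segments(self, kwargs):
        with pytest.raises(ScheduleError):
            SegmentSpec(**kwargs)


@given(st.integers(min_value=0, max_value=10_000))
def test_sequences_reproducible_for_any_seed(seed):
    sched = canonical_schedule("abrupt")
    a = sample_targets(sched, seed=seed)
    b = sample_targets(sched, seed=seed)
    assert np.array_equal(a.targets, b.targets)
    assert len(a) == 100
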
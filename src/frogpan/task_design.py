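"""Two-block changepoint estimation task: schedules, target sampling, labels.

The task presents a stream of target values on a 0-50 estimation bar.  Targets
are Gaussian draws whose mean either drifts in 5-unit steps every ten trials
(the *gradual* block) or jumps by 10 units every twenty trials (the *abrupt*
block); the SD is fixed at 1.7 in both blocks.  Each 100-trial block is
described as an ordered list of :class:`SegmentSpec` and realized into a
:class:`TaskSequence` of per-trial targets and condition labels.

Trial indices in labels and docstrings are 1-based (``abrupt trials are the
30th, 50th, 70th and 90th``); arrays are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trend",
    "SegmentSpec",
    "BlockSchedule",
    "TaskSequence",
    "ScheduleError",
    "GenerationError",
    "canonical_schedule",
    "sample_targets",
    "label_trials",
    "LABELS",
    "BASELINE_LABEL",
    "TARGET_MIN",
    "TARGET_MAX",
    "DEFAULT_MAX_STEP",
]

TARGET_MIN = 0.0
TARGET_MAX = 50.0

#: condition labels, baseline first (reference level of every condition factor)
LABELS = ("fluct_gradual", "gradually_changed", "fluct_abrupt", "abruptly_changed")
BASELINE_LABEL = LABELS[0]

#: largest trial-to-trial target jump allowed inside the gradual block.  The
#: abrupt block's engineered jumps are ~10 units; 6 keeps every gradual-block
#: delta well below that while remaining feasible under adjacent N(mu, 1.7),
#: N(mu +/- 5, 1.7) segments.
DEFAULT_MAX_STEP = 6.0

_TRENDS = (
    "randomly_fluctuate",
    "gradually_increase",
    "gradually_decrease",
    "abruptly_increase",
    "abruptly_decrease",
)

#: jitter SD applied after sorting a trend segment, in target units
_TREND_JITTER_SD = 0.5

_MAX_SEGMENT_ATTEMPTS = 1000


class ScheduleError(ValueError):
    """Invalid block kind or malformed schedule."""


class GenerationError(RuntimeError):
    """Target sampling could not satisfy the smoothness constraint."""


Trend = str


@dataclass(frozen=True)
class SegmentSpec:
    """A run of trials drawn from one Gaussian with one trend tag."""

    mean: float
    sd: float
    n_trials: int
    trend: Trend

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ScheduleError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.sd <= 0:
            raise ScheduleError(f"sd must be > 0, got {self.sd}")
        if not (TARGET_MIN <= self.mean <= TARGET_MAX):
            raise ScheduleError(f"mean {self.mean} outside [{TARGET_MIN}, {TARGET_MAX}]")
        if self.trend not in _TRENDS:
            raise ScheduleError(f"unknown trend {self.trend!r}")

    @property
    def is_abrupt(self) -> bool:
        return self.trend.startswith("abruptly")

    @property
    def is_gradual_trend(self) -> bool:
        return self.trend.startswith("gradually")


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered segments making up one experimental block."""

    block_kind: str
    segments: tuple[SegmentSpec, ...]

    def __post_init__(self) -> None:
        if self.block_kind not in ("gradual", "abrupt"):
            raise ScheduleError(f"unknown block_kind {self.block_kind!r}")
        if not self.segments:
            raise ScheduleError("schedule needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_trials(self) -> int:
        return sum(s.n_trials for s in self.segments)


@dataclass(frozen=True)
class TaskSequence:
    """One realized block: per-trial targets and condition labels."""

    targets: np.ndarray
    labels: tuple[str, ...]
    block_kind: str
    seed: int | None = None

    def __post_init__(self) -> None:
        targets = np.asarray(self.targets, dtype=float)
        object.__setattr__(self, "targets", targets)
        if len(targets) != len(self.labels):
            raise ScheduleError("targets and labels length mismatch")
        if targets.min() < TARGET_MIN or targets.max() > TARGET_MAX:
            raise ScheduleError("targets outside the estimation bar range")

    def __len__(self) -> int:
        return len(self.labels)


# -- canonical schedules ----------------------------------------------------

_SD = 1.7

_GRADUAL_ROWS = (
    (25, 20, "randomly_fluctuate"),
    (30, 10, "gradually_increase"),
    (35, 10, "randomly_fluctuate"),
    (30, 10, "gradually_decrease"),
    (25, 10, "randomly_fluctuate"),
    (20, 10, "gradually_decrease"),
    (15, 10, "randomly_fluctuate"),
    (20, 10, "gradually_increase"),
    (25, 10, "randomly_fluctuate"),
)

# abrupt rows split each single abrupt trial from its following fluctuation run
_ABRUPT_ROWS = (
    (25, 29, "randomly_fluctuate"),
    (35, 1, "abruptly_increase"),
    (35, 19, "randomly_fluctuate"),
    (25, 1, "abruptly_decrease"),
    (25, 19, "randomly_fluctuate"),
    (15, 1, "abruptly_decrease"),
    (15, 19, "randomly_fluctuate"),
    (25, 1, "abruptly_increase"),
    (25, 10, "randomly_fluctuate"),
)


def canonical_schedule(block_kind: str) -> BlockSchedule:
    """Return the canonical 100-trial schedule for one block kind.

    The gradual block's mean path is 25 (x20), 30, 35, 30, 25, 20, 15, 20, 25
    in ten-trial runs; the abrupt block's is 25 (x30), 35 (x20), 25 (x20),
    15 (x20), 25 (x10) with the mean jumping on trials 30, 50, 70 and 90.
    Deterministic; raises :class:`ScheduleError` for unknown kinds.
    """
    if block_kind == "gradual":
        rows = _GRADUAL_ROWS
    elif block_kind == "abrupt":
        rows = _ABRUPT_ROWS
    else:
        raise ScheduleError(f"unknown block_kind {block_kind!r}")
    segments = tuple(SegmentSpec(mean=m, sd=_SD, n_trials=n, trend=t) for m, n, t in rows)
    return BlockSchedule(block_kind=block_kind, segments=segments)


# -- labelling --------------------------------------------------------------


def label_trials(schedule: BlockSchedule) -> tuple[str, ...]:
    """One condition label per trial, derived from segment trend tags.

    Abrupt labels land only on the first trial of an ``abruptly_*`` segment
    (canonical abrupt segments holding a single trial); ``gradually_*``
    segments are labelled gradually_changed throughout; everything else is the
    block's fluctuation baseline.
    """
    fluct = "fluct_gradual" if schedule.block_kind == "gradual" else "fluct_abrupt"
    labels: list[str] = []
    for seg in schedule.segments:
        if seg.is_abrupt:
            labels.append("abruptly_changed")
            labels.extend([fluct] * (seg.n_trials - 1))
        elif seg.is_gradual_trend:
            labels.extend(["gradually_changed"] * seg.n_trials)
        else:
            labels.extend([fluct] * seg.n_trials)
    return tuple(labels)


# -- target sampling --------------------------------------------------------


def _draw_segment(rng: np.random.Generator, seg: SegmentSpec) -> np.ndarray:
    """Raw i.i.d. Gaussian draws for one segment, clipped and rounded.

    This is the marginal distribution before any trend reordering; kept
    separate so its distributional behaviour is directly testable.
    """
    vals = rng.normal(seg.mean, seg.sd, size=seg.n_trials)
    return np.round(np.clip(vals, TARGET_MIN, TARGET_MAX), 1)


def _apply_trend(rng: np.random.Generator, seg: SegmentSpec, vals: np.ndarray) -> np.ndarray:
    """Reorder a trend segment monotonically, then jitter.

    Sorting the i.i.d. draws ascending/descending realizes the qualitative
    "fluctuating upward (downward) trend" without materially changing the
    segment's marginal mean; the small Gaussian jitter keeps the path from
    being exactly monotone.
    """
    if seg.trend == "gradually_increase":
        vals = np.sort(vals)
    elif seg.trend == "gradually_decrease":
        vals = np.sort(vals)[::-1]
    else:
        return vals
    vals = vals + rng.normal(0.0, _TREND_JITTER_SD, size=len(vals))
    return np.round(np.clip(vals, TARGET_MIN, TARGET_MAX), 1)


def sample_targets(
    schedule: BlockSchedule,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    max_step: float = DEFAULT_MAX_STEP,
) -> TaskSequence:
    """Realize a schedule into a reproducible target sequence.

    Within the gradual block, consecutive targets are constrained to differ by
    at most ``max_step`` (reject-and-resample per segment); the abrupt block's
    changepoint transitions are deliberately unconstrained so the engineered
    ~10-unit jumps survive.  Raises :class:`GenerationError` if a segment
    cannot satisfy the constraint within a bounded number of attempts.
    """
    if max_step <= 0:
        raise ScheduleError(f"max_step must be > 0, got {max_step}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    constrain = schedule.block_kind == "gradual"

    out: list[np.ndarray] = []
    prev_last: float | None = None
    for i, seg in enumerate(schedule.segments):
        for _ in range(_MAX_SEGMENT_ATTEMPTS):
            vals = _apply_trend(rng, seg, _draw_segment(rng, seg))
            if not constrain:
                break
            deltas_ok = len(vals) < 2 or np.max(np.abs(np.diff(vals))) <= max_step
            boundary_ok = prev_last is None or abs(vals[0] - prev_last) <= max_step
            if deltas_ok and boundary_ok:
                break
        else:
            raise GenerationError(
                f"segment {i} (mean {seg.mean}, trend {seg.trend}) could not "
                f"satisfy max_step={max_step} after {_MAX_SEGMENT_ATTEMPTS} attempts"
            )
        out.append(vals)
        prev_last = float(vals[-1])

    targets = np.concatenate(out)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return TaskSequence(
        targets=targets,
        labels=label_trials(schedule),
        block_kind=schedule.block_kind,
        seed=seed_val,
    )
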
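"""Generative cohorts of surprise-gated delta-rule agents.

Each agent tracks the target with a delta rule: after seeing trial *t*'s
target it moves its estimate by an amount whose magnitude is a function
``m(|PE|)`` of the absolute prediction error and whose direction is the sign
of the PE, plus Gaussian update noise.  Two mean functions are supported:

``linear_by_condition``
    ``m(|PE|) = intercept_c + lr_c * |PE|`` with condition-specific composites
    (the condition-wise mixed-model estimates serve as defaults), the
    frog-in-the-pan pattern entering through the abrupt condition's larger
    intercept and learning rate.

``segmented``
    ``m(|PE|) = b0 + b1*|PE| + delta*max(0, |PE| - psi)`` — a broken line in
    absolute PE whose slope jumps by ``delta`` once the PE exceeds the
    surprise breakpoint ``psi``.

A minority of trials (probability ``p_no_update``) carry no update at all,
mimicking participants who stick to their previous estimate.  Reaction times
in the secondary letter task are condition-mean based with agent-level random
intercepts and an occasional exponential lapse tail that exercises the
3-second exclusion rule downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task_design import (
    LABELS,
    TARGET_MAX,
    TARGET_MIN,
    TaskSequence,
    canonical_schedule,
    sample_targets,
)

__all__ = [
    "UpdateRuleParams",
    "RTParams",
    "CohortSpec",
    "COHORT_COLUMNS",
    "simulate_agent",
    "simulate_cohort",
    "SimulationError",
]

#: canonical column order of the cohort table CSV schema
COHORT_COLUMNS = [
    "participant_id",
    "block",
    "order",
    "trial",
    "condition",
    "target",
    "estimate",
    "pe",
    "update",
    "rt",
    "letter",
    "response",
]

ESTIMATE_INIT = 25.0  # bar midpoint; equals the first segment mean

_LINEAR_INTERCEPTS = {
    "fluct_gradual": 1.017,
    "gradually_changed": 1.039,
    "fluct_abrupt": 0.756,
    "abruptly_changed": 2.548,
}
_LINEAR_LRS = {
    "fluct_gradual": 0.528,
    "gradually_changed": 0.533,
    "fluct_abrupt": 0.595,
    "abruptly_changed": 0.693,
}


class SimulationError(ValueError):
    """Incompatible task/parameter combination."""


@dataclass(frozen=True)
class UpdateRuleParams:
    """Parameters of the generative update rule.

    ``update_noise_sd`` (1.5 target units) and ``p_no_update`` (0.05) are
    calibration choices, not fitted quantities; see docs/methods.md.
    """

    mode: str = "linear_by_condition"
    intercept_by_condition: dict[str, float] = field(
        default_factory=lambda: dict(_LINEAR_INTERCEPTS)
    )
    lr_by_condition: dict[str, float] = field(default_factory=lambda: dict(_LINEAR_LRS))
    beta0: float = 0.916
    beta1: float = 0.536
    delta: float = 0.536
    psi: float = 5.337
    update_noise_sd: float = 1.5
    p_no_update: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("linear_by_condition", "segmented"):
            raise SimulationError(f"unknown update-rule mode {self.mode!r}")
        if self.psi <= 0:
            raise SimulationError("psi must be > 0")
        if self.update_noise_sd < 0:
            raise SimulationError("update_noise_sd must be >= 0")
        if not 0.0 <= self.p_no_update < 1.0:
            raise SimulationError("p_no_update must be in [0, 1)")
        for lbl in LABELS:
            if lbl not in self.intercept_by_condition or lbl not in self.lr_by_condition:
                raise SimulationError(f"missing condition {lbl!r} in linear parameters")
        for lbl, lr in self.lr_by_condition.items():
            if not 0.0 <= lr <= 1.5:
                raise SimulationError(f"learning rate for {lbl!r} outside [0, 1.5]")

    @classmethod
    def linear_defaults(cls) -> "UpdateRuleParams":
        return cls(mode="linear_by_condition")

    @classmethod
    def segmented_defaults(cls) -> "UpdateRuleParams":
        return cls(mode="segmented")

    def zero_noise(self) -> "UpdateRuleParams":
        """Noise-free variant used for identifiability checks."""
        return replace(self, update_noise_sd=0.0, p_no_update=0.0)

    def mean_update(self, abs_pe, condition=None):
        """Mean update magnitude ``m(|PE|)`` (floored at zero).

        ``condition`` is required in linear mode (scalar label or array of
        labels aligned with ``abs_pe``).
        """
        abs_pe = np.asarray(abs_pe, dtype=float)
        if self.mode == "segmented":
            m = self.beta0 + self.beta1 * abs_pe + self.delta * np.maximum(
                0.0, abs_pe - self.psi
            )
        else:
            if condition is None:
                raise SimulationError("linear mode needs a condition label")
            cond = np.broadcast_to(np.asarray(condition, dtype=object), abs_pe.shape)
            icpt = np.vectorize(self.intercept_by_condition.__getitem__)(cond)
            lr = np.vectorize(self.lr_by_condition.__getitem__)(cond)
            m = icpt + lr * abs_pe
        return np.maximum(m, 0.0)


@dataclass(frozen=True)
class RTParams:
    """Condition-mean reaction-time model for the letter task (seconds)."""

    mean_by_condition: dict[str, float] = field(
        default_factory=lambda: {
            "fluct_gradual": 0.883,
            "gradually_changed": 0.85,
            "fluct_abrupt": 0.855,
            "abruptly_changed": 1.105,
        }
    )
    rt_noise_sd: float = 0.35
    participant_rt_sd: float = 0.15
    p_lapse: float = 0.02
    lapse_mean: float = 2.0
    rt_floor: float = 0.15

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.mean_by_condition.values()):
            raise SimulationError("RT condition means must be > 0")
        if self.rt_noise_sd < 0 or self.participant_rt_sd < 0:
            raise SimulationError("RT noise sds must be >= 0")
        if not 0.0 <= self.p_lapse < 1.0:
            raise SimulationError("p_lapse must be in [0, 1)")

    def zero_noise(self) -> "RTParams":
        return replace(self, rt_noise_sd=0.0, participant_rt_sd=0.0, p_lapse=0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, seed and between-agent heterogeneity."""

    n_agents: int = 109
    seed: int | None = None
    participant_lr_sd: float = 0.1
    participant_intercept_sd: float = 0.3
    counterbalance: bool = True

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise SimulationError("n_agents must be >= 1")
        if self.participant_lr_sd < 0 or self.participant_intercept_sd < 0:
            raise SimulationError("random-effect sds must be >= 0")


@dataclass(frozen=True)
class AgentEffects:
    """Per-agent random-effect realizations (zero by default)."""

    intercept: float = 0.0
    slope: float = 0.0
    rt: float = 0.0


# -- core simulation --------------------------------------------------------


def _simulate_block(
    task: TaskSequence,
    up: UpdateRuleParams,
    rp: RTParams,
    eff_int: np.ndarray,
    eff_slope: np.ndarray,
    eff_rt: np.ndarray,
    rng: np.random.Generator,
):
    """Simulate all agents through one block; returns (T, n) arrays.

    Vectorized over agents; the trial loop is unavoidable because each
    estimate feeds the next trial's prediction error.
    """
    n = len(eff_int)
    T = len(task)
    targets = task.targets
    labels = list(task.labels)
    label_idx = np.array([LABELS.index(l) for l in labels])

    lin_icpt = np.array([up.intercept_by_condition[l] for l in LABELS])
    lin_lr = np.array([up.lr_by_condition[l] for l in LABELS])
    rt_mean = np.array([rp.mean_by_condition[l] for l in LABELS])

    est = np.empty((T, n))
    pe = np.empty((T, n))
    upd = np.full((T, n), np.nan)
    rt = np.empty((T, n))
    letters = rng.integers(0, 2, size=(T, n))  # 0 = L, 1 = R

    cur = np.full(n, ESTIMATE_INIT)
    for t in range(T):
        est[t] = cur
        e = targets[t] - cur
        pe[t] = e
        ci = label_idx[t]

        # reaction time for this trial
        r = rt_mean[ci] + eff_rt + rng.normal(0.0, rp.rt_noise_sd, size=n)
        lapse = rng.random(n) < rp.p_lapse
        if lapse.any():
            r = r + np.where(lapse, rng.exponential(rp.lapse_mean, size=n), 0.0)
        rt[t] = np.maximum(r, rp.rt_floor)

        if t == T - 1:
            break  # the last feedback has no following estimate

        abs_e = np.abs(e)
        if up.mode == "segmented":
            m = (
                (up.beta0 + eff_int)
                + (up.beta1 + eff_slope) * abs_e
                + up.delta * np.maximum(0.0, abs_e - up.psi)
            )
        else:
            m = (lin_icpt[ci] + eff_int) + (lin_lr[ci] + eff_slope) * abs_e
        m = np.maximum(m, 0.0)
        step = np.sign(e) * m
        if up.update_noise_sd > 0:
            step = step + rng.normal(0.0, up.update_noise_sd, size=n)
        if up.p_no_update > 0:
            step = np.where(rng.random(n) < up.p_no_update, 0.0, step)
        nxt = np.clip(cur + step, TARGET_MIN, TARGET_MAX)
        upd[t] = nxt - cur  # exact telescoping even after clipping
        cur = nxt

    return est, pe, upd, rt, letters


def _block_frame(task, est, pe, upd, rt, letters, agent_ids, orders):
    """Assemble long-format rows for one block across agents."""
    T, n = est.shape
    frames = []
    letter_map = np.array(["L", "R"])
    response_map = np.array(["left", "right"])
    for j in range(n):
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": agent_ids[j],
                    "block": task.block_kind,
                    "order": orders[j],
                    "trial": np.arange(1, T + 1),
                    "condition": list(task.labels),
                    "target": task.targets,
                    "estimate": est[:, j],
                    "pe": pe[:, j],
                    "update": upd[:, j],
                    "rt": rt[:, j],
                    "letter": letter_map[letters[:, j]],
                    "response": response_map[letters[:, j]],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_agent(
    task: TaskSequence,
    update_params: UpdateRuleParams | None = None,
    rt_params: RTParams | None = None,
    agent_effects: AgentEffects | None = None,
    seed: int | np.random.Generator | None = None,
    participant_id: int = 1,
) -> pd.DataFrame:
    """Simulate a single agent through one block; returns trial-record rows.

    The returned frame follows the cohort CSV schema (one row per trial;
    ``update`` is NaN on the last trial, which has no following estimate).
    """
    up = update_params or UpdateRuleParams()
    rp = rt_params or RTParams()
    eff = agent_effects or AgentEffects()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    est, pe, upd, rt, letters = _simulate_block(
        task,
        up,
        rp,
        np.array([eff.intercept]),
        np.array([eff.slope]),
        np.array([eff.rt]),
        rng,
    )
    return _block_frame(task, est, pe, upd, rt, letters, [participant_id], [1])[
        COHORT_COLUMNS
    ]


def simulate_cohort(
    spec: CohortSpec | None = None,
    update_params: UpdateRuleParams | None = None,
    rt_params: RTParams | None = None,
    schedules: dict | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a full cohort over both canonical blocks.

    All agents see the same realized target sequences (as in the original
    task, where the pseudo-random streams were fixed); between-agent
    variability comes from random effects, update noise, non-updating trials,
    lapses and letter draws.  With ``counterbalance`` half the agents (even
    participant ids) complete the abrupt block first; block order affects only
    the ``order`` column because each block starts from a fresh midpoint
    estimate.

    Deterministic given ``seed`` (falling back to ``spec.seed``).
    """
    spec = spec or CohortSpec()
    up = update_params or UpdateRuleParams()
    rp = rt_params or RTParams()
    if seed is None:
        seed = spec.seed
    ss = np.random.SeedSequence(seed)
    s_targets, s_effects, s_sim = ss.spawn(3)

    if schedules is None:
        schedules = {
            "gradual": canonical_schedule("gradual"),
            "abrupt": canonical_schedule("abrupt"),
        }
    rng_t = np.random.default_rng(s_targets)
    tasks = {kind: sample_targets(sched, seed=rng_t) for kind, sched in schedules.items()}

    n = spec.n_agents
    rng_e = np.random.default_rng(s_effects)
    eff_int = rng_e.normal(0.0, spec.participant_intercept_sd, size=n)
    eff_slope = rng_e.normal(0.0, spec.participant_lr_sd, size=n)
    eff_rt = rng_e.normal(0.0, rp.participant_rt_sd, size=n)

    agent_ids = np.arange(1, n + 1)
    if spec.counterbalance:
        abrupt_first = agent_ids % 2 == 0
    else:
        abrupt_first = np.zeros(n, dtype=bool)

    rng_s = np.random.default_rng(s_sim)
    frames = []
    for kind in sorted(tasks):  # fixed iteration order for determinism
        task = tasks[kind]
        est, pe, upd, rt, letters = _simulate_block(
            task, up, rp, eff_int, eff_slope, eff_rt, rng_s
        )
        if kind == "abrupt":
            orders = np.where(abrupt_first, 1, 2)
        else:
            orders = np.where(abrupt_first, 2, 1)
        frames.append(_block_frame(task, est, pe, upd, rt, letters, agent_ids, orders))

    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["participant_id", "order", "trial"], kind="stable")
    return df.reset_index(drop=True)[COHORT_COLUMNS]
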
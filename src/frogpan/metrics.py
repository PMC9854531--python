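"""Trial-level quantities and the analysis table.

Turns raw trial tables (simulated or externally supplied in the cohort CSV
schema) into the table the inference battery consumes: signed and absolute
prediction errors and updates, the PE-aligned update used as the regression
response, empirical learning rates, baseline-referenced condition coding and
the 3-second reaction-time exclusion.

Row alignment: row *t* carries ``pe_t`` (from trial *t*'s target and
estimate) together with the update made in response to it,
``update_t = estimate_{t+1} - estimate_t``.  The last trial of a block has no
paired update and is dropped from update models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .task_design import BASELINE_LABEL, LABELS

__all__ = [
    "EPSILON_PE",
    "RT_EXCLUSION_SECONDS",
    "DUMMY_COLUMNS",
    "compute_prediction_error",
    "compute_update",
    "empirical_learning_rate",
    "exclude_rts",
    "code_conditions",
    "decode_conditions",
    "add_pe_update",
    "build_analysis_table",
    "condition_summary",
    "DataError",
]

#: |PE| below this is treated as zero when forming empirical learning rates
EPSILON_PE = 1e-9

#: reaction times strictly greater than this many seconds are excluded
RT_EXCLUSION_SECONDS = 3.0

DUMMY_COLUMNS = [f"d_{lbl}" for lbl in LABELS if lbl != BASELINE_LABEL]


class DataError(ValueError):
    """Malformed trial data (negative RTs, unknown labels, ...)."""


def compute_prediction_error(target, estimate):
    """Signed prediction error: target minus current estimate (exact)."""
    return np.asarray(target, dtype=float) - np.asarray(estimate, dtype=float)


def compute_update(estimate_next, estimate_now):
    """Signed update: next estimate minus current estimate (exact)."""
    return np.asarray(estimate_next, dtype=float) - np.asarray(estimate_now, dtype=float)


def empirical_learning_rate(update, pe):
    """Per-trial ratio update/PE, NaN wherever |PE| < ``EPSILON_PE``.

    Undefined values are NaN by construction (a value, not an error) and are
    excluded from any rate summary.
    """
    update = np.asarray(update, dtype=float)
    pe = np.asarray(pe, dtype=float)
    out = np.full(np.broadcast(update, pe).shape, np.nan)
    ok = np.abs(pe) >= EPSILON_PE
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(update, pe, out=out, where=ok)
    return out


def exclude_rts(table: pd.DataFrame, limit: float = RT_EXCLUSION_SECONDS) -> pd.DataFrame:
    """Flag reaction times for the strict >3 s exclusion.

    Adds a boolean ``rt_included`` column; exactly 3.0 s stays included.
    Raises :class:`DataError` on negative RTs.
    """
    rt = table["rt"].to_numpy(dtype=float)
    if np.any(rt < 0):
        raise DataError("negative reaction times in table")
    out = table.copy()
    out["rt_included"] = rt <= limit
    return out


def code_conditions(table: pd.DataFrame) -> pd.DataFrame:
    """Baseline-referenced condition factor plus dummy columns.

    The reference level is the gradual block's fluctuation condition; dummies
    ``d_gradually_changed``, ``d_fluct_abrupt``, ``d_abruptly_changed`` code
    the other three levels.  Raises :class:`DataError` on unknown labels.
    """
    cond = table["condition"]
    unknown = set(cond.unique()) - set(LABELS)
    if unknown:
        raise DataError(f"unknown condition labels: {sorted(unknown)}")
    out = table.copy()
    out["condition"] = pd.Categorical(cond, categories=list(LABELS))
    for lbl in LABELS:
        if lbl != BASELINE_LABEL:
            out[f"d_{lbl}"] = (cond == lbl).astype(np.int8)
    return out


def decode_conditions(table: pd.DataFrame) -> pd.Series:
    """Invert :func:`code_conditions`: recover labels from dummy columns."""
    labels = np.full(len(table), BASELINE_LABEL, dtype=object)
    for lbl in LABELS:
        if lbl != BASELINE_LABEL:
            labels[table[f"d_{lbl}"].to_numpy() == 1] = lbl
    return pd.Series(labels, index=table.index, name="condition")


def add_pe_update(table: pd.DataFrame) -> pd.DataFrame:
    """(Re)derive pe and update columns from stored targets and estimates.

    Useful for externally supplied tables that carry only targets and
    estimates.  Updates are aligned so that row *t* holds the update made in
    response to row *t*'s PE; the last row of each participant-block gets NaN.
    """
    out = table.copy()
    out["pe"] = compute_prediction_error(out["target"], out["estimate"])
    nxt = out.groupby(["participant_id", "block"], sort=False)["estimate"].shift(-1)
    out["update"] = compute_update(nxt, out["estimate"])
    return out


def build_analysis_table(table: pd.DataFrame) -> pd.DataFrame:
    """Full analysis table from a cohort table.

    Adds absolute transforms, the PE-aligned response ``dir_update``
    (sign(PE) * update; equal to |update| whenever the update goes in the
    direction of the PE), the empirical learning rate, the non-updating flag
    (update exactly zero), condition dummies and the RT inclusion flag.
    """
    out = code_conditions(exclude_rts(table))
    pe = out["pe"].to_numpy(dtype=float)
    upd = out["update"].to_numpy(dtype=float)
    out["abs_pe"] = np.abs(pe)
    out["abs_update"] = np.abs(upd)
    out["dir_update"] = np.sign(pe) * upd
    out["empirical_lr"] = empirical_learning_rate(upd, pe)
    out["is_nonupdating"] = (upd == 0.0) & ~np.isnan(upd)
    return out


def condition_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Descriptive means and SDs by condition (absolute PE/update, RT).

    The RT column respects the 3 s exclusion; PE/update summaries use every
    trial with a defined update (non-updating trials included).
    """
    if "abs_pe" not in table.columns:
        table = build_analysis_table(table)
    rows = []
    for lbl in LABELS:
        sub = table[table["condition"] == lbl]
        upd = sub["abs_update"].dropna()
        rt = sub.loc[sub["rt_included"], "rt"]
        rows.append(
            {
                "condition": lbl,
                "n_trials": len(sub),
                "abs_pe_mean": sub["abs_pe"].mean(),
                "abs_pe_sd": sub["abs_pe"].std(),
                "abs_update_mean": upd.mean(),
                "abs_update_sd": upd.std(),
                "rt_mean": rt.mean(),
                "rt_sd": rt.std(),
                "n_rt_excluded": int((~sub["rt_included"]).sum()),
            }
        )
    return pd.DataFrame(rows)
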
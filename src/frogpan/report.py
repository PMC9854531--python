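"""Plain-text / markdown rendering of descriptives and fit results.

Mirrors the layout of the study's summary tables: condition-wise
descriptives, the condition x PE mixed model, the quadratic probe, the
segmented breakpoint model, the threshold logistic and the RT model.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["render_descriptives", "render_fit", "render_report"]


def _fmt(df: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    """Render a DataFrame as a GitHub-style markdown table."""
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: floatfmt.format(v))
    cells = [[""] + [str(c) for c in out.columns]]
    for idx, row in out.iterrows():
        cells.append([str(idx)] + [str(v) for v in row])
    widths = [max(len(r[j]) for r in cells) for j in range(len(cells[0]))]
    def line(row):
        return "| " + " | ".join(v.ljust(w) for v, w in zip(row, widths)) + " |"
    sep = "|" + "|".join("-" * (w + 2) for w in widths) + "|"
    return "\n".join([line(cells[0]), sep] + [line(r) for r in cells[1:]])


def render_descriptives(summary: pd.DataFrame) -> str:
    lines = ["## Descriptives by condition", ""]
    lines.append(_fmt(summary.set_index("condition")))
    return "\n".join(lines) + "\n"


def render_fit(name: str, model) -> str:
    """Markdown section for one fitted model."""
    lines = [f"## {name}", ""]
    lines.append(_fmt(model.summary_frame()))
    extra = []
    if hasattr(model, "composite_lr_"):
        comp = pd.DataFrame(
            {k: {"learning rate": v[0], "se": v[1]} for k, v in model.composite_lr_.items()}
        ).T
        extra.append("\nComposite learning rates:\n\n" + _fmt(comp))
    if hasattr(model, "psi_"):
        lo, hi = model.psi_ci_
        extra.append(
            f"\nBreakpoint psi = {model.psi_:.3f} (95% CI {lo:.3f} - {hi:.3f}); "
            f"slope increases by {model.delta_:.3f} above it."
        )
    if getattr(model, "separation_flag_", False):
        extra.append(
            "\nNote: at least one condition cell is empty or pure; the "
            "corresponding odds ratio is not stably estimable "
            "(quasi-separation)."
        )
    if hasattr(model, "random_intercept_var_"):
        extra.append(
            f"\nParticipant random-intercept variance: "
            f"{model.random_intercept_var_:.4f}; residual variance: "
            f"{model.resid_var_:.4f}; n = {model.n_obs_}."
        )
    return "\n".join(lines + extra) + "\n"


def render_report(sections: dict[str, str]) -> str:
    """Join pre-rendered sections under a title."""
    parts = ["# frogpan analysis report", ""]
    for _, text in sections.items():
        parts.append(text)
        parts.append("")
    return "\n".join(parts)
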
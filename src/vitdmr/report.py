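"""Human-readable rendering of the pipeline's result tables.

Formatting rules: estimates to 3 decimals, F to 2 decimals, p-values in
scientific notation below 0.001, rounding half away from zero. Every
rendered number is recoverable unrounded from the corresponding
machine-readable table.
"""

from __future__ import annotations

import math

import pandas as pd


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (so 0.0785 -> 0.079 at 3 dp)."""
    if not math.isfinite(x):
        return x
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def fmt_estimate(x: float, ndigits: int = 3) -> str:
    return f"{round_half_away(x, ndigits):.{ndigits}f}"


def fmt_p(p: float) -> str:
    if not math.isfinite(p):
        return "NA"
    if p < 0.001:
        return f"{p:.3E}"
    return fmt_estimate(p, 3)


def _descriptive_decimals(magnitude: float) -> int:
    """Clinical-table convention: more decimals for small-magnitude values
    (BMD to 3, serum Ca to 2, hormone levels to 1)."""
    m = abs(magnitude)
    if m >= 5:
        return 1
    if m >= 1:
        return 2
    return 3


def render_descriptives(summary: pd.DataFrame) -> str:
    """Table-1-style block: 'mean +/- SD' or 'median (Q1-Q3)' per variable."""
    lines = ["Characteristics\tValue\tMinimum\tMaximum"]
    for _, row in summary.iterrows():
        nd = _descriptive_decimals(row["median"])
        if row["branch"] == "mean_sd":
            value = f"{fmt_estimate(row['mean'], nd)} ± {fmt_estimate(row['sd'], nd)}"
        else:
            value = (
                f"{fmt_estimate(row['median'], nd)} "
                f"({fmt_estimate(row['q1'], nd)}–{fmt_estimate(row['q3'], nd)})"
            )
        lines.append(
            f"{row['variable']}\t{value}\t{fmt_estimate(row['min'], nd)}\t{fmt_estimate(row['max'], nd)}"
        )
    return "\n".join(lines)


def render_exclusion_report(report) -> str:
    return (
        f"Enrolled: {report.n_enrolled}\n"
        f"Excluded (disease/medication): {report.n_excluded_stage1} ({report.pct_stage1}%)\n"
        f"Excluded (abnormal labs): {report.n_excluded_stage2} ({report.pct_stage2}%)\n"
        f"Analysed: {report.n_final}"
    )


def render_observational(table: pd.DataFrame) -> str:
    lines = ["Outcome\tCrude beta\tCrude P\tAdjusted beta\tAdjusted P\tFDR P"]
    for _, r in table.iterrows():
        lines.append(
            "\t".join(
                [
                    str(r["outcome"]),
                    fmt_estimate(r["beta_crude"]),
                    fmt_p(r["p_crude"]),
                    fmt_estimate(r["beta_adjusted"]),
                    fmt_p(r["p_adjusted"]),
                    fmt_p(r["p_adjusted_fdr"]),
                ]
            )
        )
    return "\n".join(lines)


def render_instrument_strength(battery: pd.DataFrame) -> str:
    """Diagnostics per model (first outcome row; identical across outcomes)."""
    lines = ["Model\tR2\tF\tRelative bias\tWeak"]
    seen = set()
    for _, r in battery.iterrows():
        if r["model"] in seen:
            continue
        seen.add(r["model"])
        lines.append(
            "\t".join(
                [
                    str(r["model"]),
                    fmt_estimate(r["first_stage_r2"]),
                    fmt_estimate(r["f_analytic"], 2),
                    fmt_estimate(r["relative_bias"]),
                    "yes" if r["weak_instrument"] else "no",
                ]
            )
        )
    return "\n".join(lines)


def render_mr(battery: pd.DataFrame) -> str:
    if len(battery) == 0:
        return "Outcome\tModel\tBeta\tSE\tP\tHausman P (FDR)"
    lines = ["Outcome\tModel\tBeta\tSE\tP\tHausman P (FDR)"]
    for _, r in battery.iterrows():
        lines.append(
            "\t".join(
                [
                    str(r["outcome"]),
                    str(r["model"]),
                    fmt_estimate(r["beta"]),
                    fmt_estimate(r["se"]),
                    fmt_p(r["p"]),
                    fmt_p(r["hausman_p_fdr"]),
                ]
            )
        )
    return "\n".join(lines)
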
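"""Rendering of result tables.

Reproduces the published table layouts: pairing-type RT means (baseline vs
posttraining, test statistic, p, effect size) and the adherence/symptom
outcome table.  Numbers follow the source precision: RT means and SDs to
integer milliseconds, effect sizes to two decimals, percentages to integer
percent.
"""

from __future__ import annotations

import io

import pandas as pd

from .errors import InvalidInputError
from .outcomes import PHQ9_BANDS, OutcomeReport
from .rt import PairingMeansTable

_BAND_RANGES = {
    "minimal": "0-4",
    "mild": "5-9",
    "moderate": "10-14",
    "moderately-severe": "15-19",
    "severe": "20-27",
}


def fmt_ms(x: float) -> str:
    return f"{x:.0f}"


def fmt_d(x: float) -> str:
    return f"{x:.2f}"


def fmt_pct(x: float) -> str:
    return f"{x:.0f}%"


def render_pairing_table(table: PairingMeansTable, fmt: str = "markdown") -> str:
    """Render the pairing-type RT summary (baseline vs posttraining)."""
    rows = []
    for _, r in table.table.iterrows():
        rows.append(
            {
                "Stimuli pairing": r["pairing_type"],
                "Baseline mean reaction time, ms (SD)": f"{fmt_ms(r['baseline_mean'])} ({fmt_ms(r['baseline_sd'])})",
                "Posttraining mean reaction time, ms (SD)": f"{fmt_ms(r['posttraining_mean'])} ({fmt_ms(r['posttraining_sd'])})",
                "Reduction, ms": fmt_ms(r["reduction_ms"]),
                "Test statistic": f"{r['t']:.2f}",
                "P value": f"{r['p']:.3f}",
                "Cohen d": fmt_d(r["cohen_d"]),
            }
        )
    return _emit(pd.DataFrame(rows), fmt)


def render_outcome_report(report: OutcomeReport, fmt: str = "markdown") -> str:
    """Render the adherence-change and depressive-symptom outcome table."""
    if report.n < 1:
        raise InvalidInputError("empty outcome report")
    rows = [
        {
            "Characteristic": "Adherence rate <=75%, n (%)",
            "Baseline": _n_pct(report.adherence_pre_counts["low"], report.n),
            "Posttraining": _n_pct(report.adherence_post_counts["low"], report.n),
            "Test statistic": f"{report.chi2:.1f}",
            "P value": f"{report.chi2_p:.3f}",
            "Effect size": f"phi={fmt_d(report.phi)}",
        },
        {
            "Characteristic": "Adherence rate >75%, n (%)",
            "Baseline": _n_pct(report.adherence_pre_counts["moderate/high"], report.n),
            "Posttraining": _n_pct(report.adherence_post_counts["moderate/high"], report.n),
            "Test statistic": "",
            "P value": "",
            "Effect size": "",
        },
        {
            "Characteristic": "Depressive symptoms, mean (SD)",
            "Baseline": f"{report.phq9_pre_mean:.1f} ({report.phq9_pre_sd:.1f})",
            "Posttraining": f"{report.phq9_post_mean:.1f} ({report.phq9_post_sd:.1f})",
            "Test statistic": f"t={report.t:.2f}",
            "P value": f"{report.p:.3f}",
            "Effect size": f"d={fmt_d(report.cohen_d)}; reduction {fmt_pct(report.percent_reduction)}",
        },
    ]
    for band in PHQ9_BANDS:
        rows.append(
            {
                "Characteristic": f"Severity {band} ({_BAND_RANGES[band]}), n (%)",
                "Baseline": _n_pct(report.severity_pre_counts[band], report.n),
                "Posttraining": _n_pct(report.severity_post_counts[band], report.n),
                "Test statistic": "",
                "P value": "",
                "Effect size": "",
            }
        )
    return _emit(pd.DataFrame(rows), fmt)


def _n_pct(count: int, n: int) -> str:
    return f"{count} ({100.0 * count / n:.0f})"


def _emit(df: pd.DataFrame, fmt: str) -> str:
    if fmt == "csv":
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()
    if fmt == "markdown":
        # plain pipe table, no tabulate dependency
        cols = list(df.columns)
        lines = ["| " + " | ".join(cols) + " |", "|" + "|".join(["---"] * len(cols)) + "|"]
        for _, row in df.iterrows():
            lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
        return "\n".join(lines) + "\n"
    raise InvalidInputError(f"unknown report format {fmt!r}")
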
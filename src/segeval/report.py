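"""Human-readable rendering of cohort metrics and study reports.

Emits Markdown and CSV tables laid out like the standard clinical
reporting format: a per-patient metric table with mean ± SD rows, a
per-clinician score-distribution table with mean-score and pooled-%
columns, and a Turing-test positive/negative table with the mean
positive rate.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from .clinical import ScoreSummary, StudyReport, TuringSummary
from .metrics import CohortSummary, PairMetrics, round_half_up


def _fmt(x: float, nd: int = 2) -> str:
    return f"{round_half_up(float(x), nd):.{nd}f}"


def render_cohort_markdown(
    per_patient: list[PairMetrics], summary: CohortSummary
) -> str:
    lines = ["| Patient | DSC | 95HD (mm) |", "|---|---|---|"]
    for m in per_patient:
        lines.append(f"| {m.patient_id} | {_fmt(m.dsc)} | {_fmt(m.hd95_mm)} |")
    lines.append(
        f"| Mean ± SD | {_fmt(summary.mean_dsc)} ± {_fmt(summary.sd_dsc)} "
        f"| {_fmt(summary.mean_hd95)} ± {_fmt(summary.sd_hd95)} |"
    )
    return "\n".join(lines)


def render_score_markdown(summaries: dict[str, ScoreSummary]) -> str:
    """Score-distribution table per session, clinicians as columns."""
    out = []
    for session, s in summaries.items():
        clinicians = sorted(s.per_clinician)
        header = ["Score"] + [
            f"{c} {arm}" for c in clinicians for arm in ("AI", "GT")
        ] + ["Pooled AI n (%)", "Pooled GT n (%)"]
        lines = [f"### Session {session}", "| " + " | ".join(header) + " |",
                 "|" + "---|" * len(header)]
        for score in range(4):
            row = [str(score)]
            for c in clinicians:
                for arm in ("AI", "GT"):
                    cell = s.per_clinician[c].get(arm)
                    row.append(str(cell["counts"][score]) if cell else "–")
            for arm in ("AI", "GT"):
                row.append(
                    f"{s.pooled_counts[arm][score]} "
                    f"({_fmt(s.pooled_percent[arm][score], 1)})"
                )
            lines.append("| " + " | ".join(row) + " |")
        row = ["Mean score"]
        for c in clinicians:
            for arm in ("AI", "GT"):
                cell = s.per_clinician[c].get(arm)
                row.append(_fmt(cell["mean"]) if cell else "–")
        row += [_fmt(s.overall_mean["AI"]), _fmt(s.overall_mean["GT"])]
        lines.append("| " + " | ".join(row) + " |")
        out.append("\n".join(lines))
    return "\n\n".join(out)


def render_turing_markdown(summaries: dict[str, TuringSummary]) -> str:
    out = []
    for session, s in summaries.items():
        clinicians = sorted(s.per_clinician)
        header = ["Session " + session] + clinicians + ["Mean positive rate"]
        lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
        pos = ["Positive"] + [
            str(s.per_clinician[c]["positive"]) for c in clinicians
        ] + [f"{_fmt(100 * s.mean_positive_rate, 1)}%"]
        neg = ["Negative"] + [
            str(s.per_clinician[c]["n"] - s.per_clinician[c]["positive"])
            for c in clinicians
        ] + [""]
        lines += ["| " + " | ".join(pos) + " |", "| " + " | ".join(neg) + " |"]
        lines.append(
            f"\nIntelligence criterion (every clinician ≥ "
            f"{100 * s.criterion:.0f}%): "
            + ("passed" if s.verdict_all_clinicians else "failed")
        )
        out.append("\n".join(lines))
    return "\n\n".join(out)


def render_report_markdown(report: StudyReport) -> str:
    parts = []
    if report.scoring:
        parts.append("## Clinicians' scoring\n\n" + render_score_markdown(report.scoring))
    if report.turing:
        parts.append("## Turing test\n\n" + render_turing_markdown(report.turing))
    if report.kappa:
        lines = ["## Two-session consistency (Cohen's kappa)",
                 "| Clinician | kappa | n | acceptable (≥ 0.2) |", "|---|---|---|---|"]
        for c, v in report.kappa.items():
            k = "undefined" if v["kappa"] is None else _fmt(v["kappa"], 3)
            lines.append(f"| {c} | {k} | {v['n']} | {v['acceptable']} |")
        parts.append("\n".join(lines))
    if report.mcnemar:
        lines = ["## Turing-test session consistency (McNemar)",
                 "| Clinician | p | discordant | method |", "|---|---|---|---|"]
        for c, v in report.mcnemar.items():
            p = "–" if v.get("p") is None else _fmt(v["p"], 3)
            lines.append(f"| {c} | {p} | {v.get('discordant')} | {v.get('method')} |")
        parts.append("\n".join(lines))
    return "\n\n".join(parts) if parts else "(empty study)"


def cohort_to_csv(per_patient: list[PairMetrics], summary: CohortSummary) -> str:
    buf = StringIO()
    df = pd.DataFrame([m.to_dict() for m in per_patient])
    df.to_csv(buf, index=False)
    buf.write(
        f"# mean_dsc={_fmt(summary.mean_dsc)} sd_dsc={_fmt(summary.sd_dsc)} "
        f"mean_hd95={_fmt(summary.mean_hd95)} sd_hd95={_fmt(summary.sd_hd95)}\n"
    )
    return buf.getvalue()
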
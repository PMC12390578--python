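"""Markdown rendering of an analysis: classification, RMSE, CI, and
closest-match tables. Every number in the report is taken from the computed
result objects — the renderer performs no computation of its own — and the
output is deterministic, so regenerating from the same results is
byte-identical.
"""

from __future__ import annotations

from typing import Sequence

from .concordance import ConcordanceResult
from .pipeline import AnalysisResult


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def render_report(
    analysis: AnalysisResult, concordances: Sequence[ConcordanceResult]
) -> str:
    lines: list[str] = ["# Bioassay and field-trial concordance report", ""]

    lines += ["## Field-trial 12 h mortality", ""]
    lines += [
        "| strain | product | mean 12 h % | SE | cages | Abbott applied | raw mean % |",
        "|---|---|---|---|---|---|---|",
    ]
    for s in analysis.field_summaries:
        lines.append(
            f"| {s.strain} | {s.product} | {_fmt(s.mean_12h_pct)} | {_fmt(s.se_pct)} | "
            f"{s.n_cages} | {'yes' if s.abbott_applied else 'no'} | {_fmt(s.raw_mean_12h_pct)} |"
        )
    lines.append("")

    lines += ["## Resistance classification (CDC bands at the diagnostic time)", ""]
    lines += [
        "| strain | reference | chemical | grade | diagnostic time (min) | mortality % | class |",
        "|---|---|---|---|---|---|---|",
    ]
    for d in analysis.diagnostics:
        grade = d.treatment.grade.value + (" (flagged)" if d.formulated_flag else "")
        lines.append(
            f"| {d.strain} | {d.reference_strain} | {d.treatment.name} | {grade} | "
            f"{d.diagnostic_time} | {_fmt(d.mortality_at_dt)} | {d.classification.value} |"
        )
    lines.append("")

    lines += ["## Concordance with field performance", ""]
    lines += [
        "| strain | comparison | field mean % | RMSE a | RMSE b | boot mean diff | 95% CI | significant |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for c in concordances:
        lines.append(
            f"| {c.strain} | {c.diff_label} | {_fmt(c.field_mean_pct)} | {_fmt(c.rmse_a)} | "
            f"{_fmt(c.rmse_b)} | {_fmt(c.boot_mean_diff)} | ({_fmt(c.ci_low)}, {_fmt(c.ci_high)}) | "
            f"{'yes' if c.significant else 'no'} |"
        )
    lines.append("")

    lines += ["## Closest bioassay match to field mortality", ""]
    lines += [
        "| strain | arm | closest time (min) | bioassay mortality % |",
        "|---|---|---|---|",
    ]
    for c in concordances:
        lines.append(
            f"| {c.strain} | {c.label_a} | {c.closest_time_a} | {_fmt(c.closest_mortality_a)} |"
        )
        lines.append(
            f"| {c.strain} | {c.label_b} | {c.closest_time_b} | {_fmt(c.closest_mortality_b)} |"
        )
    lines.append("")
    return "\n".join(lines)
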
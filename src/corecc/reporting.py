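"""Report rendering: structured JSON (full precision), CSV and text summary.

The CSV mirrors the case-study table layout (one row per tree node: path,
surplus ratio to 2 decimals, carrying state, degree as a whole percent);
the JSON document carries full-precision values for machine consumption;
the text summary names the most binding (lowest-ratio) indicator in each
dimension.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

from .assessment import AssessmentReport


def report_records(report: AssessmentReport) -> list[dict]:
    """Full-precision records, one per tree node."""
    return [
        {
            "path": n.path,
            "name": n.name,
            "level": n.level,
            "surplus_ratio": n.result.d,
            "state": n.result.state.value,
            "degree_percent": n.result.degree,
        }
        for n in report.nodes
    ]


def write_json(report: AssessmentReport, path: str | Path) -> None:
    doc = {
        "source": report.source,
        "timestamp": report.timestamp,
        "warning_width": report.warning_width,
        "nodes": report_records(report),
    }
    with Path(path).open("w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def write_csv(report: AssessmentReport, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "name", "level", "surplus_ratio", "state", "degree_percent"])
        for n in report.nodes:
            w.writerow(
                [
                    n.path,
                    n.name,
                    n.level,
                    f"{n.result.d:.2f}",
                    n.result.state.value,
                    f"{round(n.result.degree):d}",
                ]
            )


def text_summary(report: AssessmentReport) -> str:
    """Human-readable summary naming the binding indicator per dimension."""
    lines = []
    overall = report.overall
    lines.append(
        f"Overall carrying state: {overall.state.value} "
        f"(surplus ratio {overall.d:+.2f}, degree {round(overall.degree)}%)"
    )
    dims = [n for n in report.nodes if n.level == "dimension"]
    indicators = [n for n in report.nodes if n.level == "indicator"]
    for dim in dims:
        members = [i for i in indicators if i.path.startswith(dim.path + "/")]
        binding = min(members, key=lambda n: n.result.d)
        lines.append(
            f"  {dim.name}: {dim.result.state.value} "
            f"({dim.result.d:+.2f}, {round(dim.result.degree)}%); "
            f"binding indicator: {binding.name} ({binding.result.d:+.2f})"
        )
    return "\n".join(lines)


def render_report(
    report: AssessmentReport,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("structured", "csv", "text"),
    stem: str = "report",
) -> list[Path]:
    """Write the report in the requested formats; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if "structured" in formats:
        p = out / f"{stem}.json"
        write_json(report, p)
        written.append(p)
    if "csv" in formats:
        p = out / f"{stem}.csv"
        write_csv(report, p)
        written.append(p)
    if "text" in formats:
        p = out / f"{stem}.txt"
        p.write_text(text_summary(report) + "\n")
        written.append(p)
    return written
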
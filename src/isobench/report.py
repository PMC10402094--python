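"""Consolidated metric reports and their rendering.

A Report is a named block of metric values for one submission. Undefined
ratios are carried as NA *with a reason code* rather than silent zeros,
so downstream averaging has to confront them explicitly. JSON output
retains full precision; TSV/HTML render numbers at 4 significant digits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence, Union

import pandas as pd

PathLike = Union[str, Path]

_FORMATS = ("tsv", "json", "html")


@dataclass
class Report:
    """Metric block for one submission, plus configuration echo."""

    name: str
    metrics: dict[str, Any] = field(default_factory=dict)
    na_reasons: dict[str, str] = field(default_factory=dict)
    config: dict[str, Any] = field(default_factory=dict)

    def set(self, key: str, value: Any, na_reason: str = "") -> None:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            self.metrics[key] = None
            self.na_reasons[key] = na_reason or "undefined"
        else:
            self.metrics[key] = value

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "metrics": self.metrics,
            "na_reasons": self.na_reasons,
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Report":
        return cls(
            name=d["name"],
            metrics=dict(d.get("metrics", {})),
            na_reasons=dict(d.get("na_reasons", {})),
            config=dict(d.get("config", {})),
        )


def _cell(report: Report, key: str) -> str:
    v = report.metrics.get(key)
    if v is None:
        return f"NA({report.na_reasons.get(key, 'undefined')})"
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def reports_frame(reports: Sequence[Report]) -> pd.DataFrame:
    """One row per report, stable column order (first-seen metric order)."""
    keys: list[str] = []
    for r in reports:
        for k in r.metrics:
            if k not in keys:
                keys.append(k)
    rows = [
        {"submission": r.name, **{k: _cell(r, k) for k in keys}} for r in reports
    ]
    return pd.DataFrame(rows)


def render_report(
    reports: Sequence[Report], path: PathLike, format: str = "json"
) -> Path:
    """Write one or more reports to TSV, JSON or a minimal HTML table."""
    if not reports:
        raise ValueError("need at least one report")
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    path = Path(path)
    if format == "json":
        payload = [r.to_dict() for r in reports]
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        reports_frame(reports).to_csv(path, sep="\t", index=False)
    else:
        html = reports_frame(reports).to_html(index=False)
        path.write_text(html)
    return path


def load_reports(path: PathLike) -> list[Report]:
    payload = json.loads(Path(path).read_text())
    return [Report.from_dict(d) for d in payload]
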
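"""Assessment file I/O, report serialization and assessment comparison.

Assessments travel as CSV (columns ``parameter_id,value,fish_index,unit``;
the literal ``NA`` marks a value that does not apply) or as JSON. Reports
serialize losslessly to JSON and embed a checksum of the configuration that
produced them, so two reports are only ever compared when they came from
the same model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .registry import ModelConfig, config_checksum
from .scoring import (
    NA,
    Assessment,
    Measurement,
    ModuleGradeResult,
    ScoredParameter,
    assess,
)
from .derived import round_half_up

__all__ = [
    "AssessmentReport",
    "ComparisonReport",
    "read_assessment",
    "write_assessment",
    "build_report",
    "report_to_json",
    "report_from_json",
    "compare_assessments",
    "format_report_table",
]

_META_KEYS = ("farm_id", "location", "system", "species", "purpose", "timestamp")


def read_assessment(
    path: Union[str, Path],
    fmt: Optional[str] = None,
    cfg: Optional[ModelConfig] = None,
    metadata: Optional[dict] = None,
) -> Assessment:
    """Read an assessment from CSV or JSON.

    ``NA`` strings map to the missing marker. When a config is given every
    parameter id is checked against it and numeric/ordinal value kinds are
    validated; a declared unit must match the config's unit for that
    parameter.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        data = json.loads(path.read_text(encoding="utf-8"))
        meta = {k: data.get(k, "") for k in _META_KEYS}
        rows = data["measurements"]
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"parameter_id", "value"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"{path}: CSV must have columns {sorted(required)} "
                f"(got {list(df.columns)})"
            )
        meta = dict(metadata or {})
        rows = df.to_dict("records")

    measurements = []
    for row in rows:
        pid = str(row["parameter_id"]).strip()
        if not pid:
            continue
        raw = row.get("value", "")
        fish = row.get("fish_index", None)
        fish_index = int(fish) if fish not in (None, "", "NA") else None
        unit = str(row.get("unit", "") or "").strip()
        value = _parse_value(raw)
        if cfg is not None:
            p = cfg.parameter(pid)  # raises KeyError on unknown id
            if unit and p.unit and unit != p.unit:
                raise ValueError(
                    f"parameter '{pid}': unit mismatch "
                    f"(file says '{unit}', config says '{p.unit}')"
                )
        measurements.append(Measurement(pid, value, fish_index))
    meta = {k: str((metadata or {}).get(k, meta.get(k, ""))) for k in _META_KEYS}
    return Assessment(measurements=measurements, **meta)


def _parse_value(raw):
    if raw is None:
        return NA
    if isinstance(raw, (int, float)):
        return raw
    s = str(raw).strip()
    if s in ("", "NA", "na", "NaN"):
        return NA
    try:
        f = float(s)
    except ValueError:
        return s  # ordinal label
    return int(f) if f.is_integer() and "." not in s and "e" not in s.lower() else f


def write_assessment(a: Assessment, path: Union[str, Path], fmt: Optional[str] = None,
                     cfg: Optional[ModelConfig] = None) -> None:
    """Write an assessment to CSV or JSON (inverse of :func:`read_assessment`)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        doc = {k: getattr(a, k) for k in _META_KEYS}
        doc["measurements"] = [
            {
                "parameter_id": m.parameter_id,
                "value": "NA" if m.is_na else m.value,
                "fish_index": m.fish_index,
            }
            for m in a.measurements
        ]
        path.write_text(json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8")
        return
    lines = ["parameter_id,value,fish_index,unit"]
    for m in a.measurements:
        v = "NA" if m.is_na else m.value
        fish = "" if m.fish_index is None else m.fish_index
        unit = ""
        if cfg is not None:
            try:
                unit = cfg.parameter(m.parameter_id).unit
            except KeyError:
                unit = ""
        lines.append(f"{m.parameter_id},{v},{fish},{unit}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Reports


@dataclass
class AssessmentReport:
    """Serializable result of one assessment run."""

    farm_id: str
    location: str
    system: str
    species: str
    purpose: str
    timestamp: str
    config_checksum: str
    engine_version: str
    results: list[ModuleGradeResult]
    warnings: list[str] = field(default_factory=list)

    def module(self, module_id: str) -> ModuleGradeResult:
        for r in self.results:
            if r.module_id == module_id:
                return r
        raise KeyError(f"no grade for module '{module_id}'")

    def grades_2dp(self) -> dict[str, float]:
        return {r.module_id: r.grade_2dp for r in self.results}


def build_report(a: Assessment, cfg: ModelConfig) -> AssessmentReport:
    """Run the engine on an assessment and wrap the outcome in a report."""
    from . import __version__

    import warnings as _w

    caught: list[str] = []
    with _w.catch_warnings(record=True) as rec:
        _w.simplefilter("always")
        results = assess(a, cfg)
    caught = [str(r.message) for r in rec]
    graded = {r.module_id for r in results}
    for mod in cfg.modules:
        if mod.id not in graded:
            caught.append(f"module '{mod.id}': no measured parameters; omitted")
    return AssessmentReport(
        farm_id=a.farm_id,
        location=a.location,
        system=a.system,
        species=a.species,
        purpose=a.purpose,
        timestamp=a.timestamp,
        config_checksum=config_checksum(cfg),
        engine_version=__version__,
        results=results,
        warnings=caught,
    )


def report_to_json(report: AssessmentReport) -> str:
    doc = asdict(report)
    return json.dumps(doc, indent=1, sort_keys=True)


def report_from_json(text: str) -> AssessmentReport:
    doc = json.loads(text)
    results = [
        ModuleGradeResult(
            module_id=r["module_id"],
            grade=r["grade"],
            category=r["category"],
            scored=[ScoredParameter(**s) for s in r["scored"]],
            n_missing=r["n_missing"],
        )
        for r in doc.pop("results")
    ]
    return AssessmentReport(results=results, **doc)


def format_report_table(report: AssessmentReport) -> str:
    """Human-readable grade table."""
    lines = []
    head = ", ".join(
        f"{k}={getattr(report, k)}"
        for k in ("farm_id", "location", "system", "species")
        if getattr(report, k)
    )
    if head:
        lines.append(head)
    lines.append(f"{'module':<8}{'grade':>8}  category")
    for r in report.results:
        lines.append(f"{r.module_id:<8}{r.grade_2dp:>8.2f}  {r.category}")
    for w in report.warnings:
        lines.append(f"! {w}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Comparison


@dataclass
class ComparisonReport:
    """Per-module grade deltas between two runs of the same model config."""

    earlier: str
    later: str
    deltas: dict[str, float]  # later grade - earlier grade, per module
    changed_parameters: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def compare_assessments(
    earlier: AssessmentReport, later: AssessmentReport
) -> ComparisonReport:
    """Grade deltas (later - earlier) for modules present in both reports.

    Refuses to compare reports produced under different configurations —
    a delta across differing interval tables would be meaningless.
    """
    if earlier.config_checksum != later.config_checksum:
        raise ValueError(
            "reports were produced with different model configurations; "
            "refusing to compare"
        )
    deltas = {}
    for r in later.results:
        try:
            prev = earlier.module(r.module_id)
        except KeyError:
            continue
        deltas[r.module_id] = round_half_up(r.grade - prev.grade, 10)
    earlier_iv = {
        s.parameter_id: s.interval_index for r in earlier.results for s in r.scored
    }
    changed = sorted(
        s.parameter_id
        for r in later.results
        for s in r.scored
        if s.parameter_id in earlier_iv and earlier_iv[s.parameter_id] != s.interval_index
    )
    return ComparisonReport(
        earlier=earlier.farm_id or earlier.timestamp,
        later=later.farm_id or later.timestamp,
        deltas=deltas,
        changed_parameters=changed,
    )
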
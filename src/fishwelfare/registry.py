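"""Scoring-model registry: modules, parameters, intervals and weights.

The welfare model is a configurable registry of five modules — farm
management (M), water quality (W), fish group behaviour (FG), fish external
appearance (FE) and fish internal appearance (FI) — each holding parameters
whose observed state falls into one of an ordered list of intervals. Every
interval carries a parameter score ``PS`` in [-1, 0] (0 = no or positive
influence on welfare, -1 = negative influence) and a score weight ``SW`` in
1..5 encoding the severity (intensity/duration/frequency) of the stressor
the interval represents. Every parameter carries a parameter weight ``PW``
in 1..5 for its relative welfare relevance. The module-level exponents
``SWE`` and ``PWE`` feed the grade equation in :mod:`fishwelfare.scoring`.

Configurations are plain YAML/JSON documents validated against the pydantic
models below; :func:`config_json_schema` publishes the machine-readable
schema.
"""

from __future__ import annotations

import hashlib
import json
import math
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ModuleDef",
    "IntervalDef",
    "ParameterDef",
    "ModelConfig",
    "RegulatoryOverride",
    "ConfigError",
    "load_model_config",
    "write_model_config",
    "default_model_config",
    "resolve_interval",
    "apply_overrides",
    "config_json_schema",
    "config_checksum",
    "MODULE_IDS",
]

MODULE_IDS = ("M", "W", "FG", "FE", "FI")

#: Exponent shared by the score and parameter weights in the grade equation,
#: calibrated against datasets with known welfare impact.
DEFAULT_EXPONENT = 1.7


class ConfigError(ValueError):
    """A model configuration violated a structural invariant."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ModuleDef(_Model):
    """One of the five assessment modules and its grade-equation exponents.

    ``score_weight_exponent`` (SWE) is 0 for module M: management intervals
    influence the fish mostly indirectly, so a dynamic score weight is not
    needed there and every SW collapses to 1.
    """

    id: Literal["M", "W", "FG", "FE", "FI"]
    name: str
    score_weight_exponent: float = Field(ge=0.0)
    parameter_weight_exponent: float = Field(ge=0.0)
    typical_interval_count: int = Field(gt=0)


class IntervalDef(_Model):
    """A single observable state of a parameter with its score and severity.

    Numeric intervals use the half-open ``[low, high)`` convention
    (lower-inclusive) so that printed thresholds such as "10-16 °C" assign
    deterministically; open outer ranges use +/-inf sentinels. Index 0 is
    always the optimal interval (PS=0, SW=1). For numeric parameters the
    index orders severity, not position on the number line: both "too low"
    and "too high" ranges may map to higher indices.
    """

    index: int = Field(ge=0)
    kind: Literal["numeric", "ordinal"]
    numeric_bounds: Optional[tuple[float, float]] = None
    ordinal_label: Optional[str] = None
    parameter_score: float = Field(ge=-1.0, le=0.0)
    score_weight: int = Field(ge=1, le=5)

    @model_validator(mode="after")
    def _check_kind(self) -> "IntervalDef":
        if self.kind == "numeric":
            if self.numeric_bounds is None or self.ordinal_label is not None:
                raise ValueError(
                    f"interval {self.index}: numeric kind requires numeric_bounds "
                    "and no ordinal_label"
                )
            low, high = self.numeric_bounds
            if not low < high:
                raise ValueError(
                    f"interval {self.index}: bounds must satisfy low < high, "
                    f"got [{low}, {high})"
                )
        else:
            if self.ordinal_label is None or self.numeric_bounds is not None:
                raise ValueError(
                    f"interval {self.index}: ordinal kind requires ordinal_label "
                    "and no numeric_bounds"
                )
        if self.index == 0 and (self.parameter_score != 0.0 or self.score_weight != 1):
            raise ValueError(
                "interval 0 is the optimal interval and must have "
                "parameter_score=0 and score_weight=1"
            )
        return self


class ParameterDef(_Model):
    """A welfare parameter: its module, unit, intervals and weight."""

    id: str
    name: str
    module_id: Literal["M", "W", "FG", "FE", "FI"]
    unit: str = ""
    value_kind: Literal["numeric", "ordinal"]
    intervals: list[IntervalDef]
    parameter_weight: int = Field(default=3, ge=1, le=5)
    per_fish: bool = False
    applicability: dict[str, list[str]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_intervals(self) -> "ParameterDef":
        iv = self.intervals
        if len(iv) < 2:
            raise ValueError(f"parameter '{self.id}': needs at least 2 intervals")
        if [i.index for i in iv] != list(range(len(iv))):
            raise ValueError(
                f"parameter '{self.id}': interval indices must be 0..{len(iv) - 1} in order"
            )
        kinds = {i.kind for i in iv}
        if kinds != {self.value_kind}:
            raise ValueError(
                f"parameter '{self.id}': interval kinds {kinds} do not match "
                f"value_kind '{self.value_kind}'"
            )
        for a, b in zip(iv, iv[1:]):
            if b.parameter_score > a.parameter_score:
                raise ValueError(
                    f"parameter '{self.id}': parameter_score must be non-increasing "
                    f"with severity (interval {b.index})"
                )
            if b.score_weight < a.score_weight:
                raise ValueError(
                    f"parameter '{self.id}': score_weight must be non-decreasing "
                    f"with severity (interval {b.index})"
                )
        if self.value_kind == "numeric":
            self._check_numeric_coverage()
        else:
            labels = [i.ordinal_label for i in iv]
            if len(set(labels)) != len(labels):
                raise ValueError(f"parameter '{self.id}': duplicate ordinal labels")
        return self

    def _check_numeric_coverage(self) -> None:
        ranges = sorted((i.numeric_bounds for i in self.intervals), key=lambda r: r[0])
        for (lo1, hi1), (lo2, hi2) in zip(ranges, ranges[1:]):
            if lo2 < hi1:
                raise ValueError(
                    f"parameter '{self.id}': overlapping numeric intervals "
                    f"[{lo1}, {hi1}) and [{lo2}, {hi2})"
                )
            if lo2 > hi1:
                raise ValueError(
                    f"parameter '{self.id}': gap in numeric coverage between "
                    f"{hi1} and {lo2}"
                )

    @property
    def measurable_range(self) -> tuple[float, float]:
        """Declared measurable range: union of the numeric interval bounds."""
        if self.value_kind != "numeric":
            raise ValueError(f"parameter '{self.id}' is ordinal")
        lows = [i.numeric_bounds[0] for i in self.intervals]
        highs = [i.numeric_bounds[1] for i in self.intervals]
        return min(lows), max(highs)


class RegulatoryOverride(_Model):
    """Replacement intervals for a parameter, e.g. to match local law."""

    parameter_id: str
    intervals: list[IntervalDef]
    jurisdiction: str
    rationale: str = ""


class ModelConfig(_Model):
    """The full scoring registry for one purpose/species/system context."""

    schema_version: int = 1
    provenance: str = ""
    modules: list[ModuleDef]
    parameters: list[ParameterDef]

    @model_validator(mode="after")
    def _check_refs(self) -> "ModelConfig":
        mids = [m.id for m in self.modules]
        if len(set(mids)) != len(mids):
            raise ValueError("duplicate module ids")
        pids = [p.id for p in self.parameters]
        if len(set(pids)) != len(pids):
            dupes = sorted({p for p in pids if pids.count(p) > 1})
            raise ValueError(f"duplicate parameter ids: {dupes}")
        known = set(mids)
        for p in self.parameters:
            if p.module_id not in known:
                raise ValueError(
                    f"parameter '{p.id}' references unknown module '{p.module_id}'"
                )
        return self

    def module(self, module_id: str) -> ModuleDef:
        for m in self.modules:
            if m.id == module_id:
                return m
        raise KeyError(f"unknown module '{module_id}'")

    def parameter(self, parameter_id: str) -> ParameterDef:
        p = self._by_id().get(parameter_id)
        if p is None:
            raise KeyError(f"unknown parameter '{parameter_id}'")
        return p

    def _by_id(self) -> dict[str, ParameterDef]:
        return {p.id: p for p in self.parameters}

    def module_parameters(self, module_id: str) -> list[ParameterDef]:
        return [p for p in self.parameters if p.module_id == module_id]


# ---------------------------------------------------------------------------
# I/O


def _infinity_safe_dump(obj: dict) -> dict:
    return obj


def load_model_config(
    source: Union[str, Path], fmt: Optional[str] = None
) -> ModelConfig:
    """Load and validate a model configuration from YAML or JSON.

    ``source`` may be a path or a literal document string; ``fmt`` is
    inferred from the file suffix when omitted (YAML parses JSON too).
    Raises :class:`ConfigError` naming the offending field on violation.
    """
    text, fmt = _read_source(source, fmt)
    try:
        if fmt == "json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"could not parse config as {fmt}: {exc}") from exc
    return validate_config_dict(data)


def validate_config_dict(data: dict) -> ModelConfig:
    """Validate an already-parsed config mapping into a :class:`ModelConfig`."""
    try:
        return ModelConfig.model_validate(_decode_bounds(data))
    except Exception as exc:  # pydantic ValidationError carries field paths
        raise ConfigError(str(exc)) from exc


def _looks_like_path(s: str) -> bool:
    if "\n" in s or len(s) > 1024:
        return False
    try:
        return Path(s).exists()
    except OSError:
        return False


def _read_source(source: Union[str, Path], fmt: Optional[str]) -> tuple[str, str]:
    if isinstance(source, Path) or (
        isinstance(source, str) and _looks_like_path(source)
    ):
        path = Path(source)
        if fmt is None:
            fmt = "json" if path.suffix.lower() == ".json" else "yaml"
        return path.read_text(encoding="utf-8"), fmt
    return str(source), fmt or "yaml"


def _encode_bounds(data: dict) -> dict:
    """Replace non-finite floats by string sentinels for JSON/YAML safety."""

    def enc(x):
        if isinstance(x, float) and math.isinf(x):
            return "inf" if x > 0 else "-inf"
        if isinstance(x, dict):
            return {k: enc(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [enc(v) for v in x]
        return x

    return enc(data)


def _decode_bounds(data):
    def dec(x):
        if isinstance(x, str) and x in ("inf", "-inf", ".inf", "-.inf"):
            return float(x.replace(".", ""))
        if isinstance(x, dict):
            return {k: dec(v) for k, v in x.items()}
        if isinstance(x, list):
            return [dec(v) for v in x]
        return x

    return dec(data)


def write_model_config(cfg: ModelConfig, path: Union[str, Path], fmt: Optional[str] = None) -> None:
    """Serialize a configuration to YAML (default) or JSON."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "yaml"
    data = _encode_bounds(cfg.model_dump(mode="json"))
    if fmt == "json":
        path.write_text(json.dumps(data, indent=1, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def default_model_config() -> ModelConfig:
    """The shipped default 80-parameter configuration (5 modules)."""
    ref = resources.files("fishwelfare.data").joinpath("default_config.yaml")
    return load_model_config(ref.read_text(encoding="utf-8"), "yaml")


def config_json_schema() -> dict:
    """JSON schema for configuration documents."""
    return ModelConfig.model_json_schema()


def config_checksum(cfg: ModelConfig) -> str:
    """Stable sha256 over the canonical JSON dump; embedded in reports."""
    blob = json.dumps(
        _encode_bounds(cfg.model_dump(mode="json")), sort_keys=True, separators=(",", ":")
    )
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()


# ---------------------------------------------------------------------------
# Interval resolution


def resolve_interval(param: ParameterDef, value) -> IntervalDef:
    """Map a measured value onto the unique interval containing it.

    Numeric values use the lower-inclusive ``[low, high)`` rule; ordinal
    values match by integer interval index or by exact label. A value
    outside all intervals is a config/measurement mismatch and raises
    ``ValueError`` — it is never a silent missing value.
    """
    if param.value_kind == "numeric":
        try:
            v = float(value)
        except (TypeError, ValueError):
            raise ValueError(
                f"parameter '{param.id}': numeric value expected, got {value!r}"
            ) from None
        if not math.isfinite(v):
            raise ValueError(f"parameter '{param.id}': value must be finite")
        for iv in param.intervals:
            low, high = iv.numeric_bounds
            if low <= v < high:
                return iv
        lo, hi = param.measurable_range
        raise ValueError(
            f"parameter '{param.id}': value {v} outside measurable range [{lo}, {hi})"
        )
    # ordinal
    if isinstance(value, bool):
        raise ValueError(f"parameter '{param.id}': boolean is not an interval index")
    if isinstance(value, (int, float)) and float(value).is_integer():
        idx = int(value)
        if 0 <= idx < len(param.intervals):
            return param.intervals[idx]
        raise ValueError(
            f"parameter '{param.id}': interval index {idx} out of range "
            f"0..{len(param.intervals) - 1}"
        )
    if isinstance(value, str):
        for iv in param.intervals:
            if iv.ordinal_label == value:
                return iv
        raise ValueError(f"parameter '{param.id}': unknown ordinal label {value!r}")
    raise ValueError(f"parameter '{param.id}': cannot interpret value {value!r}")


# ---------------------------------------------------------------------------
# Regulatory overrides


def apply_overrides(
    cfg: ModelConfig, overrides: list[RegulatoryOverride]
) -> ModelConfig:
    """Return a new config with override intervals substituted.

    The input config is untouched; provenance records each jurisdiction.
    Idempotent: applying the same override twice yields an identical config
    apart from the provenance note, which is de-duplicated.
    """
    data = cfg.model_dump()
    by_id = {p["id"]: p for p in data["parameters"]}
    notes = []
    for ov in overrides:
        if ov.parameter_id not in by_id:
            raise ConfigError(f"override targets unknown parameter '{ov.parameter_id}'")
        by_id[ov.parameter_id]["intervals"] = [iv.model_dump() for iv in ov.intervals]
        notes.append(f"override[{ov.jurisdiction}]: {ov.parameter_id}")
    for note in notes:
        if note not in data["provenance"]:
            data["provenance"] = (data["provenance"] + "; " + note).strip("; ")
    return validate_config_dict(data)
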
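"""Packaged farm validation fixtures and a synthetic-assessment generator.

Six real farm visits (indoor/outdoor, RAS/FTS, rainbow trout/pikeperch)
ship as CSV fixtures: water-quality parameters as measured values, all
other modules as observed interval indices, with ``NA`` where a parameter
does not apply (e.g. predator protection indoors, ambient light outdoors).

:func:`generate_assessment` draws synthetic assessments against any config
for property testing: severity profiles place every parameter in the
optimal interval, the worst interval, a mixed pattern, or uniformly random
intervals, with an optional missing-data fraction. Numeric values are drawn
uniformly inside the chosen interval's bounds (clipped at the outermost
finite limits) so interval resolution round-trips to the drawn interval.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import numpy as np

from .io import read_assessment
from .registry import ModelConfig
from .scoring import NA, Assessment, Measurement

__all__ = ["FixtureSpec", "load_farm_fixture", "farm_metadata", "generate_assessment"]

N_FARMS = 6


def farm_metadata(farm_id: int) -> dict:
    """Location/system/species/purpose and morphometrics for one farm."""
    if not 1 <= farm_id <= N_FARMS:
        raise ValueError(f"farm_id must be 1..{N_FARMS}, got {farm_id}")
    ref = resources.files("fishwelfare.data").joinpath("farms/metadata.json")
    return json.loads(ref.read_text(encoding="utf-8"))[str(farm_id)]


def load_farm_fixture(farm_id: int, cfg: ModelConfig | None = None) -> Assessment:
    """Load one of the six packaged farm assessments."""
    meta = farm_metadata(farm_id)
    ref = resources.files("fishwelfare.data").joinpath(f"farms/farm{farm_id}.csv")
    with resources.as_file(ref) as path:
        return read_assessment(
            path,
            fmt="csv",
            cfg=cfg,
            metadata={
                "farm_id": str(farm_id),
                "location": meta["location"],
                "system": meta["system"],
                "species": meta["species"],
                "purpose": meta["purpose"],
            },
        )


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic assessment; same seed + spec => same output."""

    seed: int
    modules: tuple[str, ...] = ("M", "W", "FG", "FE", "FI")
    severity: Literal["optimal", "mixed", "worst", "random"] = "random"
    n_fish: int = 5
    missing_fraction: float = 0.0

    def __post_init__(self):
        if not 1 <= self.n_fish <= 10:
            raise ValueError("n_fish must be in 1..10")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")


def generate_assessment(cfg: ModelConfig, spec: FixtureSpec) -> Assessment:
    """Draw a deterministic synthetic assessment against a config."""
    rng = np.random.default_rng(spec.seed)
    measurements: list[Measurement] = []
    for p in cfg.parameters:
        if p.module_id not in spec.modules:
            continue
        fish_indices = range(1, spec.n_fish + 1) if p.per_fish else [None]
        for fish in fish_indices:
            if spec.missing_fraction and rng.random() < spec.missing_fraction:
                measurements.append(Measurement(p.id, NA, fish))
                continue
            idx = _choose_index(p, spec.severity, rng)
            value = _value_in_interval(p, idx, rng)
            measurements.append(Measurement(p.id, value, fish))
    return Assessment(
        farm_id=f"synthetic-{spec.seed}",
        purpose="synthetic",
        measurements=measurements,
    )


def _choose_index(p, severity: str, rng) -> int:
    n = len(p.intervals)
    if severity == "optimal":
        return 0
    if severity == "worst":
        return min(range(n), key=lambda i: (p.intervals[i].parameter_score, i))
    if severity == "mixed":
        return int(rng.integers(0, min(2, n)))  # optimal or first degraded
    return int(rng.integers(0, n))


def _value_in_interval(p, idx: int, rng):
    iv = p.intervals[idx]
    if p.value_kind == "ordinal":
        return idx
    low, high = iv.numeric_bounds
    # clip open outer ranges at a finite width so sampling stays bounded
    if math.isinf(low):
        low = high - max(1.0, abs(high))
    if math.isinf(high):
        high = low + max(1.0, abs(low))
    return float(low + (high - low) * rng.random())
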
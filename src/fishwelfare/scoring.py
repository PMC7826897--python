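"""The grade engine: measurements -> parameter scores -> module grades.

Each measured parameter resolves to an interval carrying a parameter score
``PS`` in [-1, 0] and a score weight ``SW`` in 1..5; the parameter itself
carries a relevance weight ``PW`` in 1..5. A module's grade is

    MG = 1 + sum_i PS_i * SW_i**SWE * PW_i**PWE
           / sum_i SW_i**SWE * PW_i**PWE

over the parameters actually measured (missing parameters drop out of the
numerator *and* denominator, so partial assessments stay valid). The
exponents SWE = PWE = 1.7 were calibrated so datasets with known welfare
impact land in the intended grade category; module M (farm management)
uses SWE = 0 because its intervals act on the fish only indirectly.

The denominator applies the exponents too — a weighted mean of PS with
weights SW**SWE * PW**PWE. This is the only normalisation under which the
grade is guaranteed to stay in [0, 1] (an exponent-free denominator can be
driven far below 0 by a single severe parameter), with MG = 1 exactly when
every score is 0 and MG = 0 when every score is -1.

Grades map to semantic categories: [0, 0.25) critical, [0.25, 0.5) poor,
[0.5, 0.75) acceptable, [0.75, 1] good; categorisation always uses the
unrounded grade.

Parameters of the fish-appearance modules are sampled on several individual
fish (3-10 recommended; fewer than 3 yields unreliable results) and the
per-fish scores are averaged arithmetically before grading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Literal, Optional, Sequence, Union

from .registry import ModelConfig, ModuleDef, ParameterDef, resolve_interval

__all__ = [
    "NA",
    "Measurement",
    "Assessment",
    "ScoredParameter",
    "ModuleGradeResult",
    "CATEGORY_BOUNDS",
    "score_measurement",
    "average_fish_scores",
    "module_grade",
    "categorize",
    "assess",
    "calibrate_exponents",
    "make_boundary_dataset",
    "FewFishWarning",
]


class _NAType:
    """Singleton marker for 'not available': parameter does not apply here."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "NA"

    def __bool__(self):
        return False


NA = _NAType()


class FewFishWarning(UserWarning):
    """Fewer than three fish sampled for a per-fish parameter."""


@dataclass(frozen=True)
class Measurement:
    """One observed value: numeric, ordinal interval index/label, or NA."""

    parameter_id: str
    value: Union[float, int, str, _NAType]
    fish_index: Optional[int] = None

    @property
    def is_na(self) -> bool:
        return isinstance(self.value, _NAType)


@dataclass
class Assessment:
    """One farm visit: metadata plus the measurement list."""

    location: str = ""
    system: str = ""
    species: str = ""
    purpose: str = ""
    farm_id: str = ""
    timestamp: str = ""
    measurements: list[Measurement] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for m in self.measurements:
            key = (m.parameter_id, m.fish_index)
            if key in seen:
                raise ValueError(
                    f"duplicate measurement for parameter '{m.parameter_id}'"
                    + (f" fish {m.fish_index}" if m.fish_index is not None else "")
                )
            seen.add(key)


@dataclass(frozen=True)
class ScoredParameter:
    """Effective (possibly fish-averaged) PS/SW plus the parameter's PW."""

    parameter_id: str
    effective_ps: float
    effective_sw: float
    pw: int
    n_fish_averaged: int = 1
    interval_index: Optional[int] = None

    def __post_init__(self):
        if not -1.0 <= self.effective_ps <= 0.0:
            raise ValueError(f"effective_ps {self.effective_ps} outside [-1, 0]")
        if self.effective_sw < 1.0:
            raise ValueError("effective_sw must be >= 1")
        if not 1 <= self.pw <= 5:
            raise ValueError("pw must be in 1..5")
        if self.n_fish_averaged < 1:
            raise ValueError("n_fish_averaged must be >= 1")


CATEGORY_BOUNDS = (
    (0.25, "critical"),
    (0.50, "poor"),
    (0.75, "acceptable"),
)

Category = Literal["critical", "poor", "acceptable", "good"]


@dataclass
class ModuleGradeResult:
    module_id: str
    grade: float
    category: str
    scored: list[ScoredParameter]
    n_missing: int

    @property
    def grade_2dp(self) -> float:
        """Reporting precision (half-up, 2 decimals); category stays unrounded."""
        from .derived import round_half_up

        return round_half_up(self.grade, 2)


def score_measurement(
    m: Measurement, p: ParameterDef, cfg: ModelConfig
) -> Optional[ScoredParameter]:
    """Resolve one measurement to (PS, SW, PW); ``None`` when the value is NA.

    NA excludes the parameter from both numerator and denominator of the
    module grade. Any non-NA value that matches no interval raises — a
    config/measurement mismatch must never pass silently as missing data.
    """
    cfg.parameter(p.id)  # raises KeyError when absent from the config
    if m.parameter_id != p.id:
        raise ValueError(
            f"measurement for '{m.parameter_id}' scored against parameter '{p.id}'"
        )
    if m.is_na:
        return None
    iv = resolve_interval(p, m.value)
    return ScoredParameter(
        parameter_id=p.id,
        effective_ps=iv.parameter_score,
        effective_sw=float(iv.score_weight),
        pw=p.parameter_weight,
        n_fish_averaged=1,
        interval_index=iv.index,
    )


def average_fish_scores(scored: Sequence[ScoredParameter]) -> ScoredParameter:
    """Arithmetic mean of per-fish PS and SW for one parameter.

    The averaged score weight may be non-integer; it is used as-is in both
    numerator and denominator of the grade. Warns when fewer than three
    fish were sampled.
    """
    if not scored:
        raise ValueError("cannot average an empty score list")
    ids = {s.parameter_id for s in scored}
    if len(ids) != 1:
        raise ValueError(f"scores mix parameters: {sorted(ids)}")
    n = len(scored)
    if n > 10:
        raise ValueError("more than 10 fish per parameter is not supported")
    if n < 3:
        warnings.warn(
            f"parameter '{scored[0].parameter_id}': only {n} fish sampled; "
            "fewer than three fish will yield unreliable results",
            FewFishWarning,
            stacklevel=2,
        )
    idx = {s.interval_index for s in scored}
    return ScoredParameter(
        parameter_id=scored[0].parameter_id,
        effective_ps=sum(s.effective_ps for s in scored) / n,
        effective_sw=sum(s.effective_sw for s in scored) / n,
        pw=scored[0].pw,
        n_fish_averaged=n,
        interval_index=idx.pop() if len(idx) == 1 else None,
    )


def _grade(scored: Sequence[ScoredParameter], swe: float, pwe: float) -> float:
    num = sum(s.effective_ps * s.effective_sw**swe * s.pw**pwe for s in scored)
    den = sum(s.effective_sw**swe * s.pw**pwe for s in scored)
    return 1.0 + num / den


def categorize(grade: float) -> str:
    """Semantic welfare category for a grade in [0, 1]."""
    if not 0.0 <= grade <= 1.0:
        raise ValueError(f"grade {grade} outside [0, 1]")
    for upper, name in CATEGORY_BOUNDS:
        if grade < upper:
            return name
    return "good"


def module_grade(
    scored: Sequence[ScoredParameter], mod: ModuleDef, n_missing: int = 0
) -> ModuleGradeResult:
    """Grade one module from its non-missing scored parameters."""
    scored = list(scored)
    if not scored:
        raise ValueError(f"module '{mod.id}': no measured parameters to grade")
    g = _grade(scored, mod.score_weight_exponent, mod.parameter_weight_exponent)
    # guard against float round-off at the exact boundaries
    g = min(1.0, max(0.0, g))
    return ModuleGradeResult(
        module_id=mod.id,
        grade=g,
        category=categorize(g),
        scored=scored,
        n_missing=n_missing,
    )


def assess(a: Assessment, cfg: ModelConfig) -> list[ModuleGradeResult]:
    """Run a full assessment: per-fish averaging, then one grade per module.

    Modules without any measured parameter are omitted (absence of evidence
    is not good welfare); parameters never measured at all simply do not
    contribute.
    """
    by_param: dict[str, list[Measurement]] = {}
    for m in a.measurements:
        cfg.parameter(m.parameter_id)  # raises on unknown id
        by_param.setdefault(m.parameter_id, []).append(m)

    per_module: dict[str, list[ScoredParameter]] = {mod.id: [] for mod in cfg.modules}
    missing: dict[str, int] = {mod.id: 0 for mod in cfg.modules}
    for pid, ms in by_param.items():
        p = cfg.parameter(pid)
        scored = [score_measurement(m, p, cfg) for m in ms]
        scored = [s for s in scored if s is not None]
        if not scored:
            missing[p.module_id] += 1
            continue
        if len(scored) == 1:
            per_module[p.module_id].append(scored[0])
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FewFishWarning)
                per_module[p.module_id].append(average_fish_scores(scored))

    results = []
    for mod in cfg.modules:
        if not per_module[mod.id]:
            continue
        results.append(
            module_grade(per_module[mod.id], mod, n_missing=missing[mod.id])
        )
    return results


# ---------------------------------------------------------------------------
# Exponent calibration


def calibrate_exponents(
    boundary_datasets: Sequence[tuple[Sequence[ScoredParameter], str]],
    grid: Sequence[float],
) -> float:
    """Grid-search the shared exponent (SWE = PWE) against labelled datasets.

    Each dataset pairs a scored parameter set with the welfare category it
    is known to represent (e.g. optimal vs. lethal conditions). The winner
    minimises category misclassifications; ties break toward the smallest
    exponent, preferring the least aggressive transformation.
    """
    if not boundary_datasets or not len(grid):
        raise ValueError("calibration needs at least one dataset and one grid point")
    best_e, best_err = None, None
    for e in sorted(grid):
        err = 0
        for scored, target in boundary_datasets:
            g = min(1.0, max(0.0, _grade(scored, e, e)))
            if categorize(g) != target:
                err += 1
        if best_err is None or err < best_err:
            best_e, best_err = e, err
    return best_e


def make_boundary_dataset(
    boundary_grade: float, at_exponent: float, target_category: str
) -> tuple[list[ScoredParameter], str]:
    """Invert the grade equation to build a calibration dataset.

    Constructs a two-parameter scored set — one optimal (PS 0, weights 1)
    and one degraded with maximal weights (SW = PW = 5) — whose grade
    crosses ``boundary_grade`` exactly at ``at_exponent``. Because the
    grade is strictly decreasing in the exponent for this shape, exponents
    above ``at_exponent`` land below the boundary and vice versa, so a pair
    of such sets brackets a unique correct grid point.
    """
    u = 25.0  # SW * PW of the degraded parameter
    f = u**at_exponent / (1.0 + u**at_exponent)
    ps = (boundary_grade - 1.0) / f
    if not -1.0 <= ps <= 0.0:
        raise ValueError("boundary not reachable with this construction")
    scored = [
        ScoredParameter("optimal", 0.0, 1.0, 1),
        ScoredParameter("degraded", ps, 5.0, 5),
    ]
    return scored, target_category
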
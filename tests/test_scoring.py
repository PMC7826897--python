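"""Grade-engine behaviour: equation, averaging, categories, calibration.

The engine is checked against an independently coded direct summation of
the grade equation on randomized scored sets, plus the analytic boundary
cases (all-optimal -> 1, all-worst -> 0) and structural invariants
(normalisation, monotone degradation, module-M score-weight invariance).
"""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fishwelfare import (
    NA,
    Assessment,
    FewFishWarning,
    Measurement,
    ScoredParameter,
    assess,
    average_fish_scores,
    calibrate_exponents,
    categorize,
    make_boundary_dataset,
    module_grade,
    score_measurement,
)
from fishwelfare.registry import ModuleDef

GENERIC = ModuleDef(
    id="W", name="generic", score_weight_exponent=1.7,
    parameter_weight_exponent=1.7, typical_interval_count=4,
)
MGMT = ModuleDef(
    id="M", name="management", score_weight_exponent=0.0,
    parameter_weight_exponent=1.7, typical_interval_count=3,
)


def oracle_grade(scored, swe, pwe):
    """Independent direct summation of the grade equation (numpy route)."""
    ps = np.array([s.effective_ps for s in scored], dtype=float)
    sw = np.array([s.effective_sw for s in scored], dtype=float)
    pw = np.array([s.pw for s in scored], dtype=float)
    w = np.power(sw, swe) * np.power(pw, pwe)
    return 1.0 + float(np.dot(ps, w) / np.sum(w))


def random_scored(rng, n):
    return [
        ScoredParameter(
            parameter_id=f"p{i}",
            effective_ps=-float(rng.random()),
            effective_sw=1.0 + 4.0 * float(rng.random()),
            pw=int(rng.integers(1, 6)),
        )
        for i in range(n)
    ]


def test_engine_matches_oracle_on_500_random_sets():
    rng = np.random.default_rng(145)
    for _ in range(500):
        scored = random_scored(rng, int(rng.integers(1, 25)))
        got = module_grade(scored, GENERIC).grade
        want = oracle_grade(scored, 1.7, 1.7)
        assert got == pytest.approx(want, rel=1e-12, abs=1e-12)
        assert 0.0 <= got <= 1.0


def test_all_optimal_grade_is_exactly_one():
    scored = [ScoredParameter(f"p{i}", 0.0, 1.0, 3) for i in range(10)]
    res = module_grade(scored, GENERIC)
    assert res.grade == 1.0 and res.category == "good"


def test_all_worst_grade_is_exactly_zero():
    rng = np.random.default_rng(3)
    scored = [
        ScoredParameter(f"p{i}", -1.0, float(rng.integers(1, 6)), int(rng.integers(1, 6)))
        for i in range(12)
    ]
    res = module_grade(scored, GENERIC)
    assert res.grade == 0.0 and res.category == "critical"


def test_grade_one_iff_all_scores_zero():
    scored = [ScoredParameter("a", 0.0, 1.0, 3), ScoredParameter("b", -0.01, 5.0, 1)]
    assert module_grade(scored, GENERIC).grade < 1.0


def test_duplication_invariance():
    rng = np.random.default_rng(9)
    for _ in range(50):
        scored = random_scored(rng, int(rng.integers(1, 10)))
        g1 = module_grade(scored, GENERIC).grade
        g2 = module_grade(scored + scored, GENERIC).grade
        assert g2 == pytest.approx(g1, rel=1e-12)


def test_removing_parameter_at_current_grade_is_neutral():
    """A parameter whose 1 + PS equals MG contributes its own mean."""
    scored = [
        ScoredParameter("a", -0.4, 2.0, 3),
        ScoredParameter("b", -0.1, 1.0, 2),
    ]
    g = module_grade(scored, GENERIC).grade
    neutral = ScoredParameter("c", g - 1.0, 3.0, 4)
    g2 = module_grade(scored + [neutral], GENERIC).grade
    assert g2 == pytest.approx(g, rel=1e-12)


def test_monotone_degradation_200_perturbations():
    """Strictly lowering one parameter's PS strictly lowers the grade."""
    rng = np.random.default_rng(77)
    for _ in range(200):
        scored = random_scored(rng, int(rng.integers(2, 15)))
        i = int(rng.integers(len(scored)))
        s = scored[i]
        if s.effective_ps <= -0.99:
            continue
        headroom = s.effective_ps + 1.0  # distance to the worst score
        drop = float(rng.uniform(0.1, 0.9)) * headroom
        worse = ScoredParameter(
            s.parameter_id,
            effective_ps=s.effective_ps - drop,
            effective_sw=s.effective_sw,
            pw=s.pw,
        )
        perturbed = scored[:i] + [worse] + scored[i + 1:]
        assert module_grade(perturbed, GENERIC).grade < module_grade(scored, GENERIC).grade


def test_module_m_ignores_score_weights():
    rng = np.random.default_rng(11)
    for _ in range(30):
        scored = random_scored(rng, 8)
        reweighted = [
            ScoredParameter(s.parameter_id, s.effective_ps, float(rng.integers(1, 6)), s.pw)
            for s in scored
        ]
        g1 = module_grade(scored, MGMT).grade
        g2 = module_grade(reweighted, MGMT).grade
        assert g2 == pytest.approx(g1, rel=1e-12)


def test_empty_module_raises():
    with pytest.raises(ValueError):
        module_grade([], GENERIC)


@pytest.mark.parametrize(
    "grade,category",
    [
        (0.0, "critical"), (0.2499, "critical"),
        (0.25, "poor"), (0.31, "poor"), (0.4999, "poor"),
        (0.5, "acceptable"), (0.7499, "acceptable"),
        (0.75, "good"), (1.0, "good"),
    ],
)
def test_categorize_brackets(grade, category):
    assert categorize(grade) == category


def test_categorize_out_of_range():
    with pytest.raises(ValueError):
        categorize(1.01)
    with pytest.raises(ValueError):
        categorize(-0.01)


# ---------------------------------------------------------------------------
# scoring measurements & fish averaging


def test_score_measurement_composition(cfg):
    """score_measurement == resolve_interval + weight lookup, independently."""
    from fishwelfare import resolve_interval

    rng = np.random.default_rng(5)
    numeric = [p for p in cfg.parameters if p.value_kind == "numeric"]
    for _ in range(100):
        p = numeric[rng.integers(len(numeric))]
        lo, hi = p.measurable_range
        v = float(rng.uniform(max(lo, -100), min(hi, 1000)))
        s = score_measurement(Measurement(p.id, v), p, cfg)
        iv = resolve_interval(p, v)
        assert (s.effective_ps, s.effective_sw, s.pw) == (
            iv.parameter_score, float(iv.score_weight), p.parameter_weight)


def test_score_na_returns_missing_marker(cfg):
    p = cfg.parameter("predator_protection")
    assert score_measurement(Measurement(p.id, NA), p, cfg) is None


def test_score_interval_zero_has_ps0_sw1(cfg):
    p = cfg.parameter("heart")
    s = score_measurement(Measurement("heart", 0), p, cfg)
    assert s.effective_ps == 0.0 and s.effective_sw == 1.0


def test_average_identical_scores():
    scored = [ScoredParameter("gills", -0.5, 3.0, 4)] * 5
    avg = average_fish_scores(scored)
    assert avg.effective_ps == -0.5 and avg.effective_sw == 3.0
    assert avg.n_fish_averaged == 5


def test_average_is_arithmetic_mean():
    scored = [ScoredParameter("gills", 0.0, 1.0, 4), ScoredParameter("gills", -1.0, 5.0, 4)]
    with pytest.warns(FewFishWarning):
        avg = average_fish_scores(scored)
    assert avg.effective_ps == -0.5 and avg.effective_sw == 3.0


def test_average_matches_independent_mean():
    rng = np.random.default_rng(21)
    for _ in range(50):
        n = int(rng.integers(3, 11))
        scored = [
            ScoredParameter("p", -float(rng.random()), 1.0 + 4 * float(rng.random()), 2)
            for _ in range(n)
        ]
        avg = average_fish_scores(scored)
        assert avg.effective_ps == pytest.approx(
            float(np.mean([s.effective_ps for s in scored])), rel=1e-12)
        assert avg.effective_sw == pytest.approx(
            float(np.mean([s.effective_sw for s in scored])), rel=1e-12)


def test_average_rejects_mixed_parameters_and_empty():
    with pytest.raises(ValueError):
        average_fish_scores([])
    with pytest.raises(ValueError):
        average_fish_scores(
            [ScoredParameter("a", 0.0, 1.0, 3), ScoredParameter("b", 0.0, 1.0, 3)]
        )


def test_few_fish_warning_below_three():
    with pytest.warns(FewFishWarning):
        average_fish_scores([ScoredParameter("a", 0.0, 1.0, 3)] * 2)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        average_fish_scores([ScoredParameter("a", 0.0, 1.0, 3)] * 3)


# ---------------------------------------------------------------------------
# assess()


def test_assess_single_module_only(cfg):
    a = Assessment(measurements=[Measurement("oxygen", 9.0), Measurement("ph", 7.2)])
    results = assess(a, cfg)
    assert [r.module_id for r in results] == ["W"]


def test_assess_averages_per_fish(cfg):
    ms = [Measurement("gills", i % 2, fish_index=i + 1) for i in range(4)]
    a = Assessment(measurements=ms)
    (res,) = assess(a, cfg)
    (s,) = res.scored
    assert s.n_fish_averaged == 4
    assert s.effective_ps == pytest.approx(
        (2 * 0.0 + 2 * cfg.parameter("gills").intervals[1].parameter_score) / 4)


def test_assess_rejects_unknown_parameter(cfg):
    with pytest.raises(KeyError):
        assess(Assessment(measurements=[Measurement("bogus", 1)]), cfg)


def test_assessment_rejects_duplicates():
    with pytest.raises(ValueError, match="duplicate"):
        Assessment(measurements=[Measurement("oxygen", 9.0), Measurement("oxygen", 8.0)])


def test_assess_all_na_module_omitted(cfg):
    a = Assessment(
        measurements=[Measurement("oxygen", NA), Measurement("heart", 0)]
    )
    results = assess(a, cfg)
    assert [r.module_id for r in results] == ["FI"]


# ---------------------------------------------------------------------------
# calibration harness


GRID = [round(1.0 + 0.1 * k, 1) for k in range(16)]  # 1.0 .. 2.5


def test_calibration_recovers_target_exponent():
    """Boundary sets built by inverting the equation single out 1.7."""
    datasets = [
        make_boundary_dataset(0.75, 1.65, "acceptable"),
        make_boundary_dataset(0.25, 1.75, "poor"),
    ]
    assert calibrate_exponents(datasets, GRID) == 1.7


def test_calibration_tie_breaks_to_smallest():
    dataset = ([ScoredParameter("p", 0.0, 1.0, 3)], "good")  # satisfied everywhere
    assert calibrate_exponents([dataset], GRID) == 1.0


def test_calibration_order_independent():
    datasets = [
        make_boundary_dataset(0.75, 1.65, "acceptable"),
        make_boundary_dataset(0.25, 1.75, "poor"),
    ]
    shuffled = list(reversed(GRID))
    assert calibrate_exponents(datasets, shuffled) == calibrate_exponents(datasets, GRID)


def test_calibration_empty_inputs_rejected():
    with pytest.raises(ValueError):
        calibrate_exponents([], GRID)
    with pytest.raises(ValueError):
        calibrate_exponents([([ScoredParameter("p", 0.0, 1.0, 3)], "good")], [])
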
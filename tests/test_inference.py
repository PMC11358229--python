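"""Credible-interval decisions, delta_t effect sizes, report assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emosearch.inference import (
    InferenceReport,
    build_report,
    ci_overlap_decision,
    delta_t,
)


def test_disjoint_intervals_credibly_different():
    r = ci_overlap_decision((1, 2), (3, 4))
    assert r.decision == "credibly_different" and not r.overlap


def test_first_grade_sensitivity_intervals_do_not_overlap():
    # posterior intervals for angry vs happy sensitivity in the youngest group
    r = ci_overlap_decision((2.60, 3.15), (2.29, 2.58))
    assert r.decision == "credibly_different"


def test_shared_endpoint_counts_as_overlap():
    r = ci_overlap_decision((1, 3), (3, 4))
    assert r.decision == "not_distinguished" and r.overlap


def test_overlap_symmetric():
    a, b = (0.2, 1.1), (0.9, 2.0)
    assert ci_overlap_decision(a, b).overlap == ci_overlap_decision(b, a).overlap


def test_unordered_interval_rejected():
    with pytest.raises(ValueError):
        ci_overlap_decision((2, 1), (0, 1))


def test_delta_t_identical_draws_zero(rng):
    a = rng.normal(size=4000)
    sd = np.abs(rng.normal(1, 0.1, size=4000))
    res = delta_t(a, a, [sd])
    assert res["median"] == 0.0
    assert res["ci_low"] == res["ci_high"] == 0.0


def test_delta_t_scale_invariant(rng):
    a = rng.normal(2.0, 0.1, size=4000)
    b = rng.normal(1.5, 0.1, size=4000)
    sd = np.abs(rng.normal(0.8, 0.05, size=4000))
    r1 = delta_t(a, b, [sd])
    r10 = delta_t(10 * a, 10 * b, [10 * sd])
    assert r10["median"] == pytest.approx(r1["median"], rel=1e-12)
    assert r10["ci_low"] == pytest.approx(r1["ci_low"], rel=1e-12)


def test_delta_t_recovers_known_standardized_difference(rng):
    # posterior draws around means 0.5 apart with unit total SD
    n = 20_000
    a = rng.normal(0.5, 0.02, size=n)
    b = rng.normal(0.0, 0.02, size=n)
    sd = np.abs(rng.normal(1.0, 0.02, size=n))
    res = delta_t(a, b, [sd])
    assert res["ci_low"] < 0.5 < res["ci_high"]
    assert res["median"] == pytest.approx(0.5, abs=0.02)


@settings(max_examples=40, deadline=None)
@given(shift=st.floats(-2, 2))
def test_delta_t_sign_matches_mean_difference(shift):
    rng = np.random.default_rng(0)
    a = rng.normal(shift, 0.01, size=500)
    b = rng.normal(0.0, 0.01, size=500)
    sd = np.full(500, 0.7)
    res = delta_t(a, b, [sd])
    if abs(shift) > 0.05:
        assert np.sign(res["median"]) == np.sign(shift)


def test_delta_t_validation(rng):
    a = rng.normal(size=100)
    with pytest.raises(ValueError):
        delta_t(a, a[:50], [np.ones(100)])
    with pytest.raises(ValueError):
        delta_t(a, a, [])
    with pytest.raises(ValueError):
        delta_t(a, a, [np.zeros(100)])
    with pytest.raises(ValueError):
        delta_t(a, a, [-np.ones(100)])


class _FakePosterior:
    def __init__(self, summary, max_rhat=1.0):
        self.summary = summary
        self.max_rhat = max_rhat


def _fake_posteriors(max_rhat=1.0):
    import pandas as pd

    rt_rows = [
        dict(group=g, condition=c, parameter=p, median=1.0, ci_low=0.8, ci_high=1.2, rhat=1.0)
        for g in ("I", "V", "IX")
        for c in ("angry_target", "happy_target", "target_absent")
        for p in ("mu", "sigma", "tau")
    ]
    sdt_rows = [
        dict(group=g, emotion=e, parameter="d", median=2.5, ci_low=2.2, ci_high=2.8, rhat=1.0)
        for g in ("I", "V", "IX")
        for e in ("angry", "happy")
    ]
    return (
        _FakePosterior(pd.DataFrame(rt_rows), max_rhat),
        _FakePosterior(pd.DataFrame(sdt_rows), max_rhat),
    )


def test_report_cell_counts_match_design():
    exg, sdt = _fake_posteriors()
    rep = build_report(exg, sdt, [ci_overlap_decision((1, 2), (3, 4), label="x")])
    assert len(rep.rt_cells) == 27
    assert len(rep.sdt_cells) == 6
    assert len(rep.comparisons) == 1


def test_report_round_trips_through_json(tmp_path):
    exg, sdt = _fake_posteriors()
    rep = build_report(exg, sdt, [])
    path = tmp_path / "report.json"
    rep.to_json(path)
    back = InferenceReport.from_json(path)
    assert back.rt_cells == rep.rt_cells
    assert back.sdt_cells == rep.sdt_cells


def test_report_missing_cell_named():
    exg, sdt = _fake_posteriors()
    exg.summary = exg.summary.iloc[1:]
    with pytest.raises(ValueError, match="angry_target"):
        build_report(exg, sdt, [])


def test_report_refuses_unconverged_posteriors():
    exg, sdt = _fake_posteriors(max_rhat=1.2)
    with pytest.raises(RuntimeError, match="R-hat"):
        build_report(exg, sdt, [])
    rep = build_report(exg, sdt, [], allow_unconverged=True)
    assert rep.diagnostics["max_rhat"] == 1.2
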
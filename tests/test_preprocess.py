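"""Tukey fence filtering and the reduction to signal-detection counts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import emosearch as es
from emosearch.preprocess import TukeyOutlierFilter, to_sdt_counts, tukey_filter


def test_planted_outlier_removed_exactly():
    # Q1=2, Q3=4 under linear interpolation, IQR=2, fences (-1, 7)
    keep, report = tukey_filter([1, 2, 3, 4, 100])
    np.testing.assert_array_equal(keep, [True, True, True, True, False])
    assert report.n_removed == 1
    assert report.fences["all"] == (-1.0, 7.0)


def test_all_equal_values_kept():
    keep, report = tukey_filter([2.2] * 10)
    assert keep.all()
    assert report.fences["all"] == (2.2, 2.2)


def test_values_exactly_on_fence_kept():
    # data [0..4]: Q1=1, Q3=3, fences (-2, 6); 6 itself must survive
    keep, _ = tukey_filter([0, 1, 2, 3, 4, 6])
    assert keep[-1]


def test_gaussian_removal_rate_matches_normal_tail():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(100_000)
    _, report = tukey_filter(x)
    # closed form: fences at +-(q75 + 1.5 IQR) = +-2.6980 SD -> two-tail mass
    q = stats.norm.ppf(0.75)
    p = 2 * stats.norm.sf(q + 1.5 * (2 * q))
    se = np.sqrt(p * (1 - p) / len(x))
    assert abs(report.fraction_removed - p) < 3 * se


def test_requires_at_least_four_values():
    with pytest.raises(ValueError):
        tukey_filter([1.0, 2.0, 3.0])


def test_refiltering_with_original_fences_is_stable():
    """Re-estimated fences move inward after removal (the rule is not
    strictly idempotent), but the original fences keep every survivor,
    and a second pass removes at most the nominal normal-tail fraction."""
    rng = np.random.default_rng(1)
    x = np.concatenate([rng.normal(2, 0.3, 500), [15.0, 20.0]])
    keep, r1 = tukey_filter(x)
    lo, hi = r1.fences["all"]
    survivors = x[keep]
    assert ((survivors >= lo) & (survivors <= hi)).all()
    keep2, r2 = tukey_filter(survivors)
    assert r2.fraction_removed <= 0.02


@settings(max_examples=40, deadline=None)
@given(offset=st.floats(-100, 100))
def test_fences_translation_equivariant(offset):
    x = np.array([1.0, 2.0, 2.5, 3.0, 4.0, 9.0])
    _, r0 = tukey_filter(x)
    _, r1 = tukey_filter(x + offset)
    lo0, hi0 = r0.fences["all"]
    lo1, hi1 = r1.fences["all"]
    assert lo1 == pytest.approx(lo0 + offset, abs=1e-9)
    assert hi1 == pytest.approx(hi0 + offset, abs=1e-9)


def test_transformer_scopes_and_report(small_trials):
    for scope in ("cell", "participant", "global"):
        f = TukeyOutlierFilter(scope=scope)
        out = f.fit_transform(small_trials)
        assert len(out) == f.report_.n_total - f.report_.n_removed
        assert 0 <= f.report_.fraction_removed < 0.2
    with pytest.raises(ValueError):
        TukeyOutlierFilter(scope="block").fit(small_trials)


def _toy_trials():
    rows = []
    # 4 angry-present (3 "different"), 4 happy-present (4 "different"),
    # 8 absent (1 "different")
    for i, resp in enumerate(["different"] * 3 + ["same"]):
        rows.append(("p1", "I", "angry_target", resp))
    for i in range(4):
        rows.append(("p1", "I", "happy_target", "different"))
    for i, resp in enumerate(["different"] + ["same"] * 7):
        rows.append(("p1", "I", "target_absent", resp))
    df = pd.DataFrame(rows, columns=["participant_id", "group", "condition", "response"])
    df["rt"] = 1.0
    return df


def test_sdt_counts_by_enumeration():
    counts = to_sdt_counts(_toy_trials())
    angry = counts[counts.emotion == "angry"].iloc[0]
    happy = counts[counts.emotion == "happy"].iloc[0]
    assert (angry.n_hits, angry.n_signal) == (3, 4)
    assert (happy.n_hits, happy.n_signal) == (4, 4)
    assert (angry.n_false_alarms, angry.n_noise) == (1, 8)
    # shared target-absent trials: identical noise counts in both rows
    assert (happy.n_false_alarms, happy.n_noise) == (1, 8)


def test_sdt_counts_degenerate_responders(small_trials):
    allsame = small_trials.assign(response="same")
    c = to_sdt_counts(allsame)
    assert (c.n_hits == 0).all() and (c.n_false_alarms == 0).all()

    perfect = small_trials.assign(
        response=np.where(small_trials.target_present, "different", "same")
    )
    c = to_sdt_counts(perfect)
    assert (c.n_hits == c.n_signal).all() and (c.n_false_alarms == 0).all()


def test_sdt_counts_sum_to_design(small_trials, one_group_config):
    c = to_sdt_counts(small_trials)
    n = one_group_config.n_participants_per_group
    per_emotion = one_group_config.n_trials_per_participant // 4
    assert c.groupby("emotion")["n_signal"].sum().eq(n * per_emotion).all()


def test_sdt_counts_requires_absent_trials(small_trials):
    with pytest.raises(ValueError):
        to_sdt_counts(small_trials[small_trials.condition != "target_absent"])
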
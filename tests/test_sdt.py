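"""Signal-detection point estimates and the hierarchical model."""

import numpy as np
import pytest

import emosearch as es
from emosearch.preprocess import to_sdt_counts
from emosearch.sdt import collapse_and_refit, dprime_point


def test_dprime_known_quantiles():
    assert dprime_point(0.97725, 0.5) == pytest.approx(2.0, abs=1e-4)
    assert dprime_point(0.69146, 0.30854) == pytest.approx(1.0, abs=1e-4)
    assert dprime_point(0.42, 0.42) == 0.0


def test_dprime_edge_rates_corrected_or_rejected():
    with pytest.raises(ValueError):
        dprime_point(1.0, 0.1)
    with pytest.raises(ValueError):
        dprime_point(1.2, 0.1)
    val = dprime_point(1.0, 0.0, n_signal=24, n_noise=48)
    # 1/(2N) correction on both rates
    from scipy.special import ndtri

    assert val == pytest.approx(ndtri(1 - 1 / 48) - ndtri(1 / 96))


@pytest.fixture(scope="module")
def fitted(small_trials_module, light_fit_config_module):
    counts = to_sdt_counts(small_trials_module)
    return es.fit_hierarchical_sdt(counts, config=light_fit_config_module, random_state=0), counts


@pytest.fixture(scope="module")
def small_trials_module():
    cfg = es.SimulationConfig(
        n_participants_per_group=15,
        n_trials_per_participant=96,
        group_labels=("I",),
        exgauss_truth={k: v for k, v in es.DEFAULT_EXGAUSS_TRUTH.items() if k[0] == "I"},
        sdt_truth={k: v for k, v in es.DEFAULT_SDT_TRUTH.items() if k[0] == "I"},
        rng_seed=42,
    )
    return es.generate_behavioral_dataset(cfg)


@pytest.fixture(scope="module")
def light_fit_config_module():
    from emosearch.mcmc import FitConfig

    return FitConfig(n_iter=1200, n_warmup=500, theta_refresh=3)


def test_fit_recovers_sensitivity_ordering(fitted):
    post, _ = fitted
    assert post.median("I", "angry", "d") > post.median("I", "happy", "d")
    lo, hi = post.ci("I", "angry", "d")
    assert lo < 2.87 < hi or abs(post.median("I", "angry", "d") - 2.87) < 0.5


def test_posterior_rates_match_empirical_pooled_rates(fitted):
    post, counts = fitted
    from scipy.special import ndtr

    for emo in ("angry", "happy"):
        c = counts[counts.emotion == emo]
        emp_hit = c.n_hits.sum() / c.n_signal.sum()
        d = post.median("I", emo, "d")
        cc = post.median("I", emo, "c")
        model_hit = ndtr(d / 2 - cc)
        assert model_hit == pytest.approx(emp_hit, abs=0.05)
    emp_fa = counts[counts.emotion == "angry"].n_false_alarms.sum() / counts[
        counts.emotion == "angry"
    ].n_noise.sum()
    d = post.median("I", "angry", "d")
    cc = post.median("I", "angry", "c")
    assert ndtr(-d / 2 - cc) == pytest.approx(emp_fa, abs=0.05)


def test_participant_estimates_shrink_toward_group_mean(fitted):
    post, counts = fitted
    from scipy.special import ndtri

    group_d = post.median("I", "angry", "d")
    part = post.participant_summary.set_index("participant_id")
    c = counts[counts.emotion == "angry"].set_index("participant_id")
    inside = 0
    total = 0
    for pid, row in c.iterrows():
        hr = np.clip(row.n_hits / row.n_signal, 1 / (2 * row.n_signal), 1 - 1 / (2 * row.n_signal))
        fr = np.clip(
            row.n_false_alarms / row.n_noise, 1 / (2 * row.n_noise), 1 - 1 / (2 * row.n_noise)
        )
        emp = ndtri(hr) - ndtri(fr)
        fit_d = part.loc[pid, "d_angry"]
        lo, hi = sorted((emp, group_d))
        total += 1
        inside += lo - 0.15 <= fit_d <= hi + 0.15
    assert inside / total >= 0.8


def test_label_swap_equivariance(fitted, light_fit_config_module):
    post, counts = fitted
    swapped = counts.copy()
    swapped["emotion"] = swapped["emotion"].map({"angry": "happy", "happy": "angry"})
    post2 = es.fit_hierarchical_sdt(
        swapped, config=light_fit_config_module, random_state=0
    )
    for emo_a, emo_b in (("angry", "happy"), ("happy", "angry")):
        assert post2.median("I", emo_a, "d") == pytest.approx(
            post.median("I", emo_b, "d"), abs=0.08
        )


def test_count_table_validation(fitted):
    _, counts = fitted
    bad = counts.copy()
    bad.loc[bad.index[0], "n_hits"] = bad.loc[bad.index[0], "n_signal"] + 1
    with pytest.raises(ValueError):
        es.HierarchicalSDTModel().fit(bad)
    zero = counts.copy()
    zero["n_hits"] = 0
    zero["n_false_alarms"] = 0
    with pytest.raises(ValueError):
        es.HierarchicalSDTModel().fit(zero)


def test_collapse_and_refit_merges_groups(light_fit_config_module):
    cfg = es.SimulationConfig(
        n_participants_per_group=10, n_trials_per_participant=96, rng_seed=9
    )
    counts = to_sdt_counts(es.generate_behavioral_dataset(cfg))
    post = collapse_and_refit(
        counts, ["V", "IX"], config=light_fit_config_module, random_state=1
    )
    groups = set(post.summary.group)
    assert groups == {"I", "V+IX"}
    # pooled group keeps a sensible sensitivity estimate (truth 2.9-3.1 angry)
    assert 2.0 < post.median("V+IX", "angry", "d") < 4.0


def test_collapse_rejects_bad_merges(fitted):
    _, counts = fitted
    with pytest.raises(ValueError):
        collapse_and_refit(counts, ["I", "I"])
    with pytest.raises(ValueError):
        collapse_and_refit(counts, ["I", "nope"])
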
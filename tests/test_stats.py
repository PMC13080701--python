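"""Outlier gating, OLS/ANCOVA, bootstrap tests and multiplicity control."""

import numpy as np
import pandas as pd
import pytest

from hepkit.stats import (
    ModelSpec,
    bonferroni_gate,
    bootstrap_test,
    exclude_outliers,
    fit_ols,
    paired_symptom_test,
)


# ---------------------------------------------------------------------------
# outlier exclusion
# ---------------------------------------------------------------------------

def test_outlier_removed_when_z_exceeds_three():
    v = np.concatenate([np.random.default_rng(0).normal(0, 0.1, 30), [50.0]])
    kept, excluded = exclude_outliers(v, ids=list(range(31)))
    assert excluded == [30]
    assert kept.size == 30


def test_all_equal_values_exclude_nothing():
    kept, excluded = exclude_outliers(np.full(10, 3.3))
    assert kept.size == 10 and excluded == []


def test_outliers_match_brute_force_on_random_instances():
    rng = np.random.default_rng(1)
    for _ in range(100):
        v = rng.normal(0, 1, size=rng.integers(3, 50))
        if rng.random() < 0.5:
            v[rng.integers(v.size)] += rng.choice([-1, 1]) * 20
        kept, excluded = exclude_outliers(v)
        mu, sd = v.mean(), v.std(ddof=1)
        brute = [i for i in range(v.size) if abs(v[i] - mu) > 3 * sd]
        assert excluded == brute


def test_gaussian_tail_mass_near_quarter_percent():
    v = np.random.default_rng(2).normal(0, 1, size=20000)
    _, excluded = exclude_outliers(v)
    frac = len(excluded) / v.size
    assert 0.0005 < frac < 0.006  # ~0.27% two-sided beyond 3 SD


def test_too_few_values_raise():
    with pytest.raises(ValueError):
        exclude_outliers(np.array([1.0, 2.0]))


# ---------------------------------------------------------------------------
# OLS / ANCOVA
# ---------------------------------------------------------------------------

def _cohort_frame(n=20, effect=3.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for etype in ("FS", "ES"):
        for semio in ("motile", "non_motile"):
            mean = effect * (1 if semio == "non_motile" else -1) * (etype == "FS")
            for _ in range(n):
                rows.append(
                    {
                        "event_type": etype,
                        "semiology": semio,
                        "hep_change_uv": rng.normal(mean, 1.0),
                        "hr_change_bpm": rng.normal(0, 3.0),
                    }
                )
    return pd.DataFrame(rows)


def test_zero_outcome_gives_zero_f():
    data = _cohort_frame(5, effect=0.0)
    data["hep_change_uv"] = 0.0
    fit = fit_ols(data, ModelSpec())
    f, p = fit.term_f("semiology")
    assert f == 0.0 and p == 1.0


def test_semiology_effect_detected_in_fs_not_es():
    data = _cohort_frame(15, effect=3.0, seed=3)
    spec = ModelSpec(fixed_factors=("semiology",), strata=("semiology",))
    f_fs, p_fs = fit_ols(data[data.event_type == "FS"], spec).term_f("semiology")
    f_es, p_es = fit_ols(data[data.event_type == "ES"], spec).term_f("semiology")
    assert p_fs < 0.001
    assert p_es > 0.01
    assert f_fs > f_es


def test_duplicate_coded_factor_raises_rank_error():
    data = _cohort_frame(5)
    data["semiology2"] = data["semiology"]
    spec = ModelSpec(fixed_factors=("semiology", "semiology2"), strata=())
    with pytest.raises(ValueError, match="rank"):
        fit_ols(data, spec)


def test_single_level_factor_raises():
    data = _cohort_frame(5)
    data["semiology"] = "motile"
    with pytest.raises(ValueError, match="levels"):
        fit_ols(data, ModelSpec())


# ---------------------------------------------------------------------------
# bootstrap tests
# ---------------------------------------------------------------------------

def test_one_sample_on_zeros_has_p_near_one():
    res = bootstrap_test(np.zeros(20), kind="one_sample", seed=0)
    assert res.p_empirical > 0.99
    assert not res.significant


def test_bootstrap_seeded_determinism():
    v = np.random.default_rng(5).normal(0.5, 1, 25)
    a = bootstrap_test(v, kind="one_sample", seed=11)
    b = bootstrap_test(v, kind="one_sample", seed=11)
    assert a.p_empirical == b.p_empirical and a.statistic == b.statistic


def test_classical_and_bootstrap_p_agree_on_large_gaussian_samples():
    rng = np.random.default_rng(6)
    for _ in range(5):
        a = rng.normal(0.15, 1, 150)
        b = rng.normal(0.0, 1, 150)
        res = bootstrap_test(
            np.concatenate([a, b]), kind="two_sample",
            group=np.array([0] * 150 + [1] * 150), seed=2,
        )
        assert abs(res.p_classical - res.p_empirical) < 0.02


def test_two_sample_power_for_large_separation():
    rng = np.random.default_rng(7)
    hits = 0
    for i in range(20):
        a = rng.normal(0.0, 1, 25)
        b = rng.normal(1.5, 1, 25)
        res = bootstrap_test(
            np.concatenate([a, b]), kind="two_sample",
            group=np.array([0] * 25 + [1] * 25), seed=i,
        )
        hits += res.significant
    assert hits == 20  # analytic power of the t-test here is > 0.999


def test_empirical_p_has_plus_one_smoothing():
    v = np.random.default_rng(8).normal(5.0, 0.5, 30)  # overwhelming effect
    res = bootstrap_test(v, kind="one_sample", n_resamples=500, seed=0)
    assert res.p_empirical == pytest.approx(1 / 501)


def test_one_sample_requires_two_values():
    with pytest.raises(ValueError):
        bootstrap_test(np.array([1.0]), kind="one_sample")


def test_ols_f_bootstrap_reports_mean_f_and_empirical_p():
    data = _cohort_frame(12, effect=3.0, seed=9)
    spec = ModelSpec(fixed_factors=("semiology",), strata=("semiology",))
    res = bootstrap_test(
        kind="ols_F", summaries=data[data.event_type == "FS"], model=spec,
        term="semiology", n_resamples=200, seed=1,
    )
    assert res.p_empirical < 0.01
    assert res.boot_mean_stat > 10.0
    null = bootstrap_test(
        kind="ols_F", summaries=data[data.event_type == "ES"], model=spec,
        term="semiology", n_resamples=200, seed=1,
    )
    assert null.p_empirical > 0.05


# ---------------------------------------------------------------------------
# paired tests and multiplicity
# ---------------------------------------------------------------------------

def test_paired_identical_conditions_gives_t_zero_p_one():
    v = np.random.default_rng(10).normal(0, 1, 12)
    res = paired_symptom_test(v, v)
    assert res.statistic == 0.0 and res.p_classical == 1.0 and not res.significant


def test_paired_constant_shift_is_degenerate_but_significant():
    base = np.random.default_rng(11).normal(0, 1, 10)
    res = paired_symptom_test(base + 2.0, base)
    assert res.degenerate and res.significant


def test_paired_power_for_two_microvolt_shift():
    rng = np.random.default_rng(12)
    base = rng.normal(4.0, 1.0, 19)
    pre = base + 2.0 + rng.normal(0, 1.0, 19)
    res = paired_symptom_test(pre, base, alpha=0.05 / 6)
    assert res.significant and res.statistic > 0


def test_paired_length_mismatch_raises():
    with pytest.raises(ValueError):
        paired_symptom_test(np.zeros(3), np.zeros(4))


def test_bonferroni_adjusted_alphas():
    v = np.random.default_rng(13).normal(1.0, 1.0, 30)
    res = [bootstrap_test(v, kind="one_sample", seed=0)]
    assert bonferroni_gate(res, 4)[0].alpha == pytest.approx(0.0125)
    assert bonferroni_gate(res, 6)[0].alpha == pytest.approx(0.05 / 6, abs=1e-6)
    assert bonferroni_gate(res, 1, base_alpha=0.05)[0].alpha == 0.05
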
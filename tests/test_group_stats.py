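import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from fdlquant.group_stats import (
    TTEST_PAIRS,
    ancova,
    pairwise_ttests,
    parse_apoe_e4_count,
    shapiro_gate,
    spearman,
)
from fdlquant.image_io import GROUP_ORDER
from fdlquant.synthetic_data import generate_case_covariates

# ---------------------------------------------------------------------------
# independent oracles


def brute_force_midranks(x):
    """Midranks by direct definition: mean of 1-based sorted positions."""
    x = list(x)
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_force_rho(x, y):
    rx, ry = brute_force_midranks(x), brute_force_midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


# ---------------------------------------------------------------------------
# Shapiro-Wilk gate


def test_shapiro_passes_normal_draws_in_most_seeds():
    passes = 0
    for seed in range(100):
        vals = np.random.default_rng(seed).normal(2.0, 0.3, size=20)
        if shapiro_gate(vals).p_value >= 0.05:
            passes += 1
    assert passes >= 90


def test_shapiro_rejects_bimodal_binary():
    vals = np.array([0.0] * 20 + [1.0] * 20)
    assert shapiro_gate(vals).p_value < 0.05


def test_shapiro_degenerate_inputs():
    with pytest.raises(ValueError):
        shapiro_gate([1.0, 2.0])
    with pytest.raises(ValueError):
        shapiro_gate([3.0] * 10)


# ---------------------------------------------------------------------------
# pairwise t-tests


def four_groups(**overrides):
    groups = {
        "early-MFG": [2.13, 2.59, 2.92],
        "early-aHPC": [1.07, 1.4, 1.7],
        "late-MFG": [1.22, 1.5, 1.81],
        "late-aHPC": [1.00, 1.24, 1.55],
    }
    groups.update(overrides)
    return groups


def test_identical_groups_give_t0_p1():
    same = [1.0, 2.0, 3.0]
    res = pairwise_ttests({g: same for g in GROUP_ORDER})
    for r in res:
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)


def test_t_statistic_matches_closed_form_on_fixture():
    a, b = [2.13, 2.59, 2.92], [1.00, 1.24, 1.55]
    res = pairwise_ttests(four_groups(**{"early-MFG": a, "late-aHPC": b}))
    r = next(t for t in res if t.groups == ("early-MFG", "late-aHPC"))
    # pooled-variance two-sample t, written out
    ma, mb = np.mean(a), np.mean(b)
    sp2 = (sum((v - ma) ** 2 for v in a) + sum((v - mb) ** 2 for v in b)) / 4
    t_manual = (ma - mb) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
    assert r.statistic == pytest.approx(t_manual, rel=1e-12)
    assert r.p_value == pytest.approx(
        2 * scipy.stats.t.sf(abs(t_manual), df=4), rel=1e-12
    )
    # closed form puts this fixture at p = 0.01003: clearly significant
    assert r.p_value < 0.05


def test_exactly_the_six_listed_pairs_in_order():
    res = pairwise_ttests(four_groups())
    assert [r.groups for r in res] == list(TTEST_PAIRS)
    assert len(res) == 6


def test_holm_adjustment_never_decreases_p():
    raw = pairwise_ttests(four_groups())
    adj = pairwise_ttests(four_groups(), holm=True)
    for r, a in zip(raw, adj):
        assert a.p_value >= r.p_value - 1e-15
        assert a.p_value <= 1.0


def test_too_small_group_rejected():
    with pytest.raises(ValueError, match="fewer than 2"):
        pairwise_ttests(four_groups(**{"late-MFG": [1.5]}))


# ---------------------------------------------------------------------------
# ANCOVA


def null_cases(seed, n_per_group=5, group_effects=(2.59, 1.28, 1.43, 1.24)):
    rng = np.random.default_rng(seed)
    rows = []
    for g, mu in zip(GROUP_ORDER, group_effects):
        stage, region = g.split("-", 1)
        for i in range(n_per_group):
            rows.append(
                {"case_id": f"{g}-{i}", "stage": stage, "region": region,
                 "mean_score": mu + rng.normal(0, 0.25)}
            )
    df = pd.DataFrame(rows)
    cov = generate_case_covariates(df["case_id"].tolist(), seed=seed + 1)
    return df.merge(cov, on="case_id")


def test_parse_apoe_variants():
    assert parse_apoe_e4_count("ε3–ε3") == 0
    assert parse_apoe_e4_count("ε3–ε4") == 1
    assert parse_apoe_e4_count("e4/e4") == 2
    assert math.isnan(parse_apoe_e4_count("-"))
    assert math.isnan(parse_apoe_e4_count(None))
    with pytest.raises(ValueError):
        parse_apoe_e4_count("ε3")


def test_constant_covariate_flagged_inestimable():
    df = null_cases(0)
    df["age"] = 70
    res = ancova(df)
    assert math.isnan(res.covariates["age"].p_value)
    assert "inestimable" in res.covariates["age"].note
    assert not math.isnan(res.covariates["final_mmse"].p_value)


def test_missing_apoe_dropped_listwise_with_ids():
    df = null_cases(1)
    df.loc[df.index[:2], "apoe"] = "-"
    res = ancova(df)
    assert len(res.dropped_cases) == 2
    assert res.n_used == len(df) - 2


def test_null_covariates_rarely_significant():
    hits = total = 0
    for seed in range(40):
        res = ancova(null_cases(seed))
        for key in ("age", "final_mmse", "apoe"):
            total += 1
            hits += res.covariates[key].p_value < 0.05
    assert hits / total <= 0.15  # ~5% expected under the null


def test_planted_age_slope_recovered():
    df = null_cases(7, n_per_group=8)
    df["mean_score"] = df["mean_score"] + 0.04 * (df["age"] - df["age"].mean())
    res = ancova(df)
    assert res.covariates["age"].p_value < 0.05


def test_group_factor_detected():
    res = ancova(null_cases(3))
    assert res.factors["stage"].p_value < 0.05 or res.factors["region"].p_value < 0.05


def test_onehot_apoe_coding_runs():
    res = ancova(null_cases(11), apoe_coding="onehot")
    assert 0 <= res.covariates["apoe"].p_value <= 1


# ---------------------------------------------------------------------------
# Spearman


def test_perfect_antimonotone_rho_is_exactly_minus_one():
    x = np.array([0.9, 0.3, 0.5, 0.7, 0.1])
    res = spearman(x, 1 - x)
    assert res.statistic == -1.0
    # exact permutation p: only the 2 extreme orderings of 5! reach |rho|=1
    assert res.p_value == pytest.approx(2 / math.factorial(5), rel=1e-12)


def test_exact_p_small_n_closed_form():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = spearman(x, -x)
    assert res.p_value == pytest.approx(2 / 24, rel=1e-12)


def test_ties_with_complement_still_minus_one():
    r = np.array([0.2, 0.2, 0.6, 0.8, 0.8, 0.5])
    res = spearman(r, 1 - r)
    assert res.statistic == -1.0
    assert brute_force_rho(r, 1 - r) == pytest.approx(-1.0, abs=1e-12)


def test_rho_matches_brute_force_and_scipy_with_ties(rng):
    for n in (5, 8, 12):
        for _ in range(10):
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho = spearman(x, y).statistic
            assert rho == pytest.approx(brute_force_rho(x, y), abs=1e-12)
            assert rho == pytest.approx(scipy.stats.spearmanr(x, y).statistic, abs=1e-12)


def test_independent_pairs_have_near_zero_rho(rng):
    x, y = rng.random(1000), rng.random(1000)
    res = spearman(x, y)
    assert abs(res.statistic) < 0.1
    assert res.p_value > 1e-6  # nothing spuriously extreme


def test_asymptotic_p_matches_t_reference():
    x = np.arange(20.0)
    y = x + np.sin(x) * 6
    res = spearman(x, y)
    ref = scipy.stats.spearmanr(x, y)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def test_spearman_complement_identity_exhaustive_small_n():
    """Spearman(R, 1-R) = -1 for every R arrangement with >= 2 distinct values."""
    for vals in itertools.product([0.1, 0.5, 0.9], repeat=4):
        r = np.array(vals)
        if np.unique(r).size < 2:
            continue
        assert spearman(r, 1 - r).statistic == -1.0


def test_spearman_degenerate_inputs():
    with pytest.raises(ValueError):
        spearman([1, 2], [2, 1])
    with pytest.raises(ValueError):
        spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_type_one_error_near_alpha():
    """t-test path holds its nominal 5% size under a null simulation."""
    rejections = 0
    reps = 2000
    for seed in range(reps):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 5), rng.normal(0, 1, 5)
        _, p = scipy.stats.ttest_ind(a, b, equal_var=True)
        rejections += p < 0.05
    rate = rejections / reps
    # Monte-Carlo band: 3 * sqrt(.05*.95/2000) ~ 0.0146
    assert 0.035 <= rate <= 0.065
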
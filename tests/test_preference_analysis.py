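import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hetmate import (
    PreferenceTrial,
    association_proportions,
    attach_heterozygosity,
    read_trials_csv,
    repeatability_anova,
    repeatability_bootstrap_se,
    similarity_preference_test,
    write_trials_csv,
)


def _trial(tid, durations, focal="f1", stims=None, group="A"):
    stims = stims or [f"s{k}" for k in range(6)]
    return PreferenceTrial(tid, focal, "F", group, tuple(stims), tuple(durations))


def test_trial_validation():
    with pytest.raises(ValueError, match="six|6"):
        PreferenceTrial("t", "f", "F", "A", ("a",) * 5, (1.0,) * 5)
    with pytest.raises(ValueError, match="non-negative"):
        _trial("t", (1, 2, 3, -1, 0, 0))


def test_association_proportions_examples():
    trials = [
        _trial("t1", (600, 0, 0, 0, 0, 0)),
        _trial("t2", (0, 0, 0, 0, 0, 0)),
        _trial("t3", (30, 10, 10, 0, 0, 0)),
    ]
    obs, excl = association_proportions(trials)
    assert list(excl["trial_id"]) == ["t2"]
    p1 = obs[obs.trial_id == "t1"]["proportion"].to_numpy()
    np.testing.assert_allclose(p1, [1, 0, 0, 0, 0, 0])
    p3 = obs[obs.trial_id == "t3"]["proportion"].to_numpy()
    np.testing.assert_allclose(p3, [0.6, 0.2, 0.2, 0, 0, 0])
    # bookkeeping: per-trial sums are 1 and counts add up
    sums = obs.groupby("trial_id")["proportion"].sum()
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)
    assert len(excl) + obs["trial_id"].nunique() == len(trials)


def test_trials_csv_round_trip(tmp_path):
    trials = [_trial("t1", (10, 20, 0, 5, 5, 0)), _trial("t2", (1, 1, 1, 1, 1, 1))]
    path = tmp_path / "trials.csv"
    write_trials_csv(trials, path)
    again = read_trials_csv(path)
    assert again == trials


# -- repeatability -----------------------------------------------------------


def icc1_oracle_balanced(groups):
    """Independent balanced-design ICC(1) route via the one-way F statistic."""
    k = len(next(iter(groups.values())))
    F = stats.f_oneway(*groups.values()).statistic
    return (F - 1.0) / (F + k - 1.0)


def test_repeatability_hand_fixture():
    res = repeatability_anova({"a": (0, 1), "b": (1, 2), "c": (2, 3)})
    assert res.ms_among == pytest.approx(2.0, abs=1e-12)
    assert res.ms_within == pytest.approx(0.5, abs=1e-12)
    assert res.n0 == pytest.approx(2.0, abs=1e-12)
    assert res.r == pytest.approx(0.6, abs=1e-12)


def test_repeatability_extremes():
    perfect = repeatability_anova({"a": (1.0, 1.0), "b": (2.0, 2.0), "c": (5.0, 5.0)})
    assert perfect.r == pytest.approx(1.0)
    noise = repeatability_anova({"a": (0.0, 2.0), "b": (1.0, 1.0), "c": (0.5, 1.5)})
    assert noise.r <= 0.0 and noise.negative


def test_repeatability_errors():
    with pytest.raises(ValueError, match="2 groups"):
        repeatability_anova({"a": (1, 2)})
    with pytest.raises(ValueError, match="singleton"):
        repeatability_anova({"a": (1,), "b": (2,)})


def test_repeatability_matches_independent_icc_oracle():
    rng = np.random.default_rng(55)
    for _ in range(100):
        g = int(rng.integers(3, 10))
        k = int(rng.integers(2, 6))
        groups = {
            j: rng.normal(rng.normal(0, 1), 1, size=k) for j in range(g)
        }
        ours = repeatability_anova(groups).r
        assert ours == pytest.approx(icc1_oracle_balanced(groups), abs=1e-10)


def test_repeatability_bootstrap_se_reasonable():
    rng = np.random.default_rng(56)
    groups = {j: rng.normal(j * 0.2, 1.0, size=3) for j in range(30)}
    se = repeatability_bootstrap_se(groups, n_boot=200, seed=1)
    assert 0.0 < se < 1.0


# -- similarity preference test ---------------------------------------------


def _obs_frame(P, het_f, het_s):
    rows = []
    for t in range(P.shape[0]):
        for s in range(6):
            rows.append({"trial_id": f"t{t}", "slot": s + 1,
                         "proportion": P[t, s],
                         "het_focal": het_f[t], "het_stimulus": het_s[t, s]})
    return pd.DataFrame(rows)


def test_similarity_maximal_concordance():
    """Proportions strictly decreasing in |het difference| -> tiny p."""
    rng = np.random.default_rng(66)
    T = 20
    het_f = rng.uniform(0.3, 0.9, T)
    het_s = rng.uniform(0.0, 1.0, (T, 6))
    P = np.empty((T, 6))
    for t in range(T):
        order = np.argsort(np.abs(het_f[t] - het_s[t]))
        weights = np.array([0.4, 0.25, 0.15, 0.1, 0.07, 0.03])
        P[t, order] = weights
    res = similarity_preference_test(_obs_frame(P, het_f, het_s), n_perm=10_000, seed=0)
    assert res.p_value <= 0.001
    assert res.observed > 0


def test_similarity_invariant_to_het_shift():
    rng = np.random.default_rng(67)
    T = 12
    het_f = rng.uniform(0, 1, T)
    het_s = rng.uniform(0, 1, (T, 6))
    P = rng.dirichlet(np.ones(6), T)
    a = similarity_preference_test(_obs_frame(P, het_f, het_s), n_perm=200, seed=3)
    b = similarity_preference_test(
        _obs_frame(P, het_f + 5.0, het_s + 5.0), n_perm=200, seed=3
    )
    assert a.observed == pytest.approx(b.observed, abs=1e-12)
    assert a.p_value == b.p_value


def test_similarity_requires_trials_and_variance():
    rng = np.random.default_rng(68)
    P = rng.dirichlet(np.ones(6), 5)
    with pytest.raises(ValueError, match="10 trials"):
        similarity_preference_test(
            _obs_frame(P, rng.uniform(0, 1, 5), rng.uniform(0, 1, (5, 6))),
            n_perm=10, seed=0,
        )
    P = rng.dirichlet(np.ones(6), 12)
    flat = _obs_frame(P, np.full(12, 0.5), np.full((12, 6), 0.5))
    with pytest.raises(ValueError, match="variance"):
        similarity_preference_test(flat, n_perm=10, seed=0)


def test_similarity_reproducible():
    rng = np.random.default_rng(69)
    frame = _obs_frame(rng.dirichlet(np.ones(6), 15),
                       rng.uniform(0, 1, 15), rng.uniform(0, 1, (15, 6)))
    a = similarity_preference_test(frame, n_perm=300, seed=9)
    b = similarity_preference_test(frame, n_perm=300, seed=9)
    assert (a.p_value, a.null_q025, a.null_q975) == (b.p_value, b.null_q025, b.null_q975)


def test_attach_heterozygosity_joins():
    obs = pd.DataFrame({"focal_id": ["a"], "stimulus_id": ["b"]})
    out = attach_heterozygosity(obs, {"a": 0.7, "b": 0.2})
    assert out.loc[0, "het_focal"] == 0.7 and out.loc[0, "het_stimulus"] == 0.2
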
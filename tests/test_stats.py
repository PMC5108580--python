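"""Statistical toolkit: oracles, invariances, multiplicity control."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_hyp
from scipy import stats as sps

from dceradiomics import phantom as ph
from dceradiomics import stats as st


def exact_mw_p_by_enumeration(x, y):
    """Two-sided exact Mann-Whitney p by full labeling enumeration (no ties)."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = sps.rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - nx * (nx + 1) / 2

    u_obs = u_of(range(nx))
    mean_u = nx * (n - nx) / 2
    dev = abs(u_obs - mean_u)
    count = total = 0
    for idx in itertools.combinations(range(n), nx):
        total += 1
        if abs(u_of(idx) - mean_u) >= dev - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_worked_example_exact(self):
        res = st.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res["u"] == 0.0
        assert res["p_two_sided"] == pytest.approx(0.1, abs=1e-12)
        assert res["method"] == "exact"

    def test_identical_samples_p_one(self):
        assert st.mann_whitney([2, 2, 2], [2, 2, 2])["p_two_sided"] == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            nx = int(rng.integers(2, 8))
            ny = int(rng.integers(2, 8))
            if nx * ny > 64:
                continue
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            res = st.mann_whitney(x, y)
            assert res["method"] == "exact"
            assert res["p_two_sided"] == pytest.approx(
                exact_mw_p_by_enumeration(x, y), abs=1e-12
            )

    def test_large_or_tied_samples_use_normal_approx(self, rng):
        x = rng.integers(0, 4, size=30).astype(float)
        y = rng.integers(0, 4, size=30).astype(float)
        res = st.mann_whitney(x, y)
        assert res["method"] == "normal"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res["p_two_sided"] == pytest.approx(ref.pvalue, abs=1e-12)

    @given(st_hyp.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=12), r.normal(size=9)
        p1 = st.mann_whitney(x, y)["p_two_sided"]
        p2 = st.mann_whitney(np.exp(x), np.exp(y))["p_two_sided"]
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestEmpiricalAuc:
    def test_perfect_separation(self):
        res = st.empirical_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert res.auc == 1.0

    def test_null_shuffle_near_half(self, rng):
        scores = rng.normal(size=1000)
        labels = rng.random(1000) > 0.5
        assert abs(st.empirical_auc(scores, labels).auc - 0.5) < 0.05

    def test_matches_brute_force_double_loop(self, rng):
        scores = rng.integers(0, 6, size=40).astype(float)  # ties included
        labels = rng.random(40) > 0.6
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        pos, neg = scores[labels], scores[~labels]
        brute = np.mean([
            1.0 if p > q else (0.5 if p == q else 0.0)
            for p in pos for q in neg
        ])
        assert st.empirical_auc(scores, labels).auc == pytest.approx(brute, abs=1e-12)

    def test_complement_identity(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) > 0.4
        a1 = st.empirical_auc(scores, labels).auc
        a2 = st.empirical_auc(-scores, labels).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            st.empirical_auc([1.0, 2.0], [1, 1])


class TestKendallTauB:
    def test_perfect_concordance_and_reversal(self):
        x = np.arange(1.0, 6.0)
        assert st.kendall_tau_b(x, x).tau_b == pytest.approx(1.0)
        assert st.kendall_tau_b(x[::-1], x).tau_b == pytest.approx(-1.0)

    def test_counts_match_python_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 25))
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(1, 6, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            res = st.kendall_tau_b(x, y)
            c = d = tx = ty = txy = 0
            for i in range(n):
                for j in range(i + 1, n):
                    sx = np.sign(x[i] - x[j])
                    sy = np.sign(y[i] - y[j])
                    if sx == 0 and sy == 0:
                        txy += 1
                    elif sx == 0:
                        tx += 1
                    elif sy == 0:
                        ty += 1
                    elif sx == sy:
                        c += 1
                    else:
                        d += 1
            assert (res.concordant, res.discordant) == (c, d)
            assert (res.ties_x, res.ties_y, res.ties_xy) == (tx, ty, txy)

    @given(st_hyp.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_scipy_tau_and_p(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(10, 60))
        x = r.normal(size=n)
        y = r.integers(1, 6, size=n).astype(float)
        if np.all(y == y[0]):
            y[0] += 1
        res = st.kendall_tau_b(x, y)
        ref = sps.kendalltau(x, y, variant="b", method="asymptotic")
        assert res.tau_b == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_symmetry_and_sign_flip(self, rng):
        x = rng.normal(size=30)
        y = rng.integers(1, 6, size=30).astype(float)
        assert st.kendall_tau_b(x, y).tau_b == pytest.approx(
            st.kendall_tau_b(y, x).tau_b
        )
        assert st.kendall_tau_b(-x, y).tau_b == pytest.approx(
            -st.kendall_tau_b(x, y).tau_b
        )

    def test_constant_argument_rejected(self):
        with pytest.raises(ValueError, match="no variation"):
            st.kendall_tau_b([1, 1, 1, 1], [1, 2, 3, 4])


class TestHolm:
    def test_three_test_thresholds(self):
        t = st.holm_thresholds(3, 0.05)
        assert np.round(t, 4).tolist() == [0.0167, 0.025, 0.05]

    def test_single_test_threshold_is_alpha(self):
        assert st.holm_thresholds(1, 0.05).tolist() == [0.05]

    def test_step_down_stops_chain(self):
        # 0.001 rejected at 0.0167; 0.08 > 0.025 stops; 0.23 not tested
        reject = st.holm_decide([0.001, 0.23, 0.08], 0.05)
        assert reject.tolist() == [True, False, False]

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(int(rng.integers(1, 12)))
            ours = st.holm_decide(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="holm")[0]
            assert np.array_equal(ours, ref)

    def test_between_bonferroni_and_unadjusted(self, rng):
        p = rng.random(10) * 0.2
        holm = st.holm_decide(p, 0.05)
        bonf = p <= 0.05 / 10
        raw = p <= 0.05
        assert (bonf <= holm).all()  # Holm rejects a superset of Bonferroni
        assert (holm <= raw).all()  # ... and a subset of unadjusted


class TestSizeStrata:
    @pytest.mark.parametrize(
        "diameter,stratum",
        [(17.6, "T1"), (20.0, "T1"), (20.000001, "T2"), (50.0, "T2"), (51.0, "T3")],
    )
    def test_boundaries(self, diameter, stratum):
        assert st.size_strata([diameter])[0] == stratum

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            st.size_strata([10.0, 0.0])


class TestAssociationReport:
    def test_shape_contract(self):
        cohort = ph.make_cohort(60, rng_seed=0)
        features = ["effective_diameter_mm", "irregularity", "entropy"]
        rep = st.association_report(cohort, features)
        assert len(rep["group_tests"]) == 4 * 3
        assert set(rep["group_tests"]["task"]) == {"ER", "PR", "HER2", "TN"}
        assert "empirical" in rep["meta"]["roc_method"]

    def test_programmed_entropy_trend_detected(self):
        cohort = ph.make_cohort(
            91, effects={"entropy": {"subtype": 0.5}}, rng_seed=3
        )
        rep = st.association_report(cohort, ["entropy"])
        row = rep["trends"].query("feature == 'entropy' and stratum == 'all'")
        assert row["p_value"].iloc[0] < 0.05
        assert row["tau_b"].iloc[0] > 0

    def test_small_stratum_skipped_with_warning(self, caplog):
        cohort = ph.make_cohort(30, rng_seed=1)
        cohort["effective_diameter_mm"] = 10.0  # all T1
        with caplog.at_level("WARNING"):
            rep = st.association_report(cohort, ["entropy"])
        assert "skipped" in caplog.text
        assert set(rep["trends"]["stratum"]) == {"all", "T1"}
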
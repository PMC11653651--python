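import itertools

import numpy as np
import pandas as pd
import pytest

from mirlame.errors import ValidationError
from mirlame.expression import rpm_normalize
from mirlame.patterns import (FuzzyCMeans, FuzzyCMeansResults, TrendCall,
                              assign_pattern, build_timecourse, call_trend,
                              classify_temporal_patterns, select_signatures,
                              standardize_profiles)
from mirlame.simulate import (PATTERN_CATEGORIES, PlantedPattern,
                              default_longitudinal_config,
                              simulate_recovery_cohort)


def naive_fcm(x, u, m, tol, max_iter):
    """Plain-loop FCM oracle: same alternating updates, no vectorized tricks."""
    n, c = u.shape
    centroids = np.zeros((c, x.shape[1]))
    prev = None
    objective = None
    for _ in range(max_iter):
        for k in range(c):
            num = np.zeros(x.shape[1])
            den = 0.0
            for i in range(n):
                num += (u[i, k] ** m) * x[i]
                den += u[i, k] ** m
            centroids[k] = num / den
        d2 = np.zeros((n, c))
        for i in range(n):
            for k in range(c):
                d2[i, k] = np.sum((x[i] - centroids[k]) ** 2)
        for i in range(n):
            if (d2[i] <= 1e-300).any():
                z = d2[i] <= 1e-300
                u[i] = z / z.sum()
            else:
                w = d2[i] ** (-1.0 / (m - 1.0))
                u[i] = w / w.sum()
        objective = sum((u[i, k] ** m) * d2[i, k]
                        for i in range(n) for k in range(c))
        if prev is not None and np.max(np.abs(centroids - prev)) < tol:
            break
        prev = centroids.copy()
    return centroids, u, objective


class TestTimecourse:
    def make(self, values_by_week, recovery="RE"):
        samples, weeks = [], []
        cols = {}
        for w, vals in values_by_week.items():
            for i, v in enumerate(vals):
                sid = f"{w}_{i}"
                samples.append(sid)
                weeks.append(w)
                cols[sid] = [v]
        rpm = pd.DataFrame(cols, index=["m0"])
        meta = pd.DataFrame({
            "sample_id": samples, "animal_id": samples,
            "phenotype": "DD", "week": weeks,
            "gait_score": pd.array([1] * len(samples), dtype="Int64"),
            "recovery": recovery})
        return rpm, meta

    def test_single_sample_per_week_equals_that_sample(self):
        rpm, meta = self.make({"W0": [3.0], "W1": [5.0], "W2": [7.0]})
        tc = build_timecourse(rpm, meta, "DD", "RE")
        assert tc.loc["m0"].tolist() == [3.0, 5.0, 7.0]

    def test_duplicated_samples_do_not_change_the_mean(self):
        rpm, meta = self.make({"W0": [3.0, 3.0], "W1": [5.0, 5.0],
                               "W2": [7.0, 7.0]})
        tc = build_timecourse(rpm, meta, "DD", "RE")
        assert tc.loc["m0"].tolist() == [3.0, 5.0, 7.0]

    def test_missing_week_rejected(self):
        rpm, meta = self.make({"W0": [3.0], "W1": [5.0], "W2": [7.0]})
        with pytest.raises(ValidationError):
            build_timecourse(rpm, meta, "DD", "UNR")

    def test_matches_generator_group_means(self, longitudinal_sim):
        rpm = rpm_normalize(longitudinal_sim.counts)
        tc = build_timecourse(rpm, longitudinal_sim.metadata, "DD", "UNR")
        # planted U-D pattern: rises then falls
        profile = tc.loc["bta-mir-s0060"]
        assert profile["W1"] > 2 * profile["W0"]
        assert profile["W2"] < profile["W1"] / 2


class TestStandardize:
    def test_closed_form_z_score(self):
        tc = pd.DataFrame([[2.0, 4.0, 6.0]], index=["m0"],
                          columns=["W0", "W1", "W2"])
        z, excluded = standardize_profiles(tc)
        assert np.allclose(z.loc["m0"], [-1.2247, 0.0, 1.2247], atol=1e-4)
        assert len(excluded) == 0

    def test_constant_profile_excluded(self):
        tc = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]],
                          index=["flat", "rising"], columns=["W0", "W1", "W2"])
        z, excluded = standardize_profiles(tc)
        assert list(excluded) == ["flat"]
        assert list(z.index) == ["rising"]

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        tc = pd.DataFrame(rng.normal(size=(20, 3)))
        z, _ = standardize_profiles(tc)
        assert np.abs(z.mean(axis=1)).max() < 1e-9
        assert np.abs(z.std(axis=1, ddof=0) - 1).max() < 1e-9


class TestFuzzyCMeans:
    def two_blobs(self, seed=0, n=5, spread=0.05):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(np.vstack([
            rng.normal([-1, 0, 1], spread, size=(n, 3)),
            rng.normal([1, 0, -1], spread, size=(n, 3))]))

    def test_separated_blobs_get_confident_memberships(self):
        res = FuzzyCMeans(self.two_blobs(), n_clusters=2, seed=1).fit()
        assert res.memberships.to_numpy().max(axis=1).min() > 0.95

    def test_matches_plain_loop_oracle(self):
        x = self.two_blobs(seed=2, n=3).to_numpy()  # N=6, T=3
        rng = np.random.default_rng(5)
        u0 = rng.random((6, 2))
        u0 /= u0.sum(axis=1, keepdims=True)
        model = FuzzyCMeans(pd.DataFrame(x), n_clusters=2, tol=1e-9)
        res = model.fit(init_memberships=u0.copy())
        _, _, obj = naive_fcm(x, u0.copy(), 2.0, 1e-9, 1000)
        assert res.objective == pytest.approx(obj, abs=1e-6)

    def test_membership_rows_sum_to_one(self):
        res = FuzzyCMeans(self.two_blobs(seed=3), n_clusters=3, seed=2).fit()
        assert np.allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_objective_nonincreasing(self):
        res = FuzzyCMeans(self.two_blobs(seed=4, spread=0.5),
                          n_clusters=2, seed=3).fit()
        path = np.array(res.objective_path)
        assert (np.diff(path) <= 1e-9).all()

    def test_same_partition_same_objective_across_seeds(self):
        data = self.two_blobs(seed=5)
        r1 = FuzzyCMeans(data, n_clusters=2, seed=10).fit()
        r2 = FuzzyCMeans(data, n_clusters=2, seed=99).fit()
        assert r1.objective == pytest.approx(r2.objective, abs=1e-6)

    def test_seed_determinism(self):
        data = self.two_blobs(seed=6)
        r1 = FuzzyCMeans(data, n_clusters=2, seed=7).fit()
        r2 = FuzzyCMeans(data, n_clusters=2, seed=7).fit()
        pd.testing.assert_frame_equal(r1.memberships, r2.memberships)

    def test_equidistant_point_splits_membership(self):
        x = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0],
                          [0.5, 0.5]])
        u0 = np.array([[1, 0], [1, 0], [0, 1], [0, 1], [0.5, 0.5]], dtype=float)
        res = FuzzyCMeans(x, n_clusters=2, tol=1e-12).fit(init_memberships=u0)
        assert np.allclose(res.memberships.iloc[4], [0.5, 0.5], atol=1e-9)

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValidationError):
            FuzzyCMeans(self.two_blobs(), n_clusters=10)


class TestSignatures:
    def make_results(self, memberships):
        m = pd.DataFrame(memberships)
        model = FuzzyCMeans(pd.DataFrame(np.zeros((m.shape[0] + m.shape[1], 2))),
                            n_clusters=m.shape[1])
        return FuzzyCMeansResults(model=model, centroids=pd.DataFrame(),
                                  memberships=m, objective=0.0,
                                  objective_path=(0.0,), n_iter=1)

    def test_strict_threshold(self):
        res = self.make_results({0: [0.71, 0.70], 1: [0.29, 0.30]})
        sig = select_signatures(res)
        assert sig[0] == {0} and sig[1] == set()

    def test_threshold_one_gives_empty_sets(self):
        res = self.make_results({0: [0.8, 0.6], 1: [0.2, 0.4]})
        sig = select_signatures(res, threshold=1.0)
        assert all(not s for s in sig.values())

    def test_invariant_to_cluster_relabeling(self):
        mem = {0: [0.9, 0.1, 0.5], 1: [0.1, 0.9, 0.5]}
        res = self.make_results(mem)
        swapped = self.make_results({0: mem[1], 1: mem[0]})
        sets1 = {frozenset(s) for s in select_signatures(res).values()}
        sets2 = {frozenset(s) for s in select_signatures(swapped).values()}
        assert sets1 == sets2


class TestTrends:
    @pytest.mark.parametrize("lfc,fdr,expected", [
        (1.5, 0.01, "U"),
        (-1.2, 0.20, "N"),
        (-1.2, 0.01, "D"),
        (0.9, 0.001, "N"),
    ])
    def test_trend_rule(self, lfc, fdr, expected):
        call = call_trend(lfc, fdr, ("W0", "W1"))
        assert call.call == expected

    def test_pattern_concatenation(self):
        t1 = call_trend(1.5, 0.01, ("W0", "W1"))
        t2 = call_trend(-1.5, 0.01, ("W1", "W2"))
        assert assign_pattern(t1, t2) == "U-D"

    def test_nonconsecutive_intervals_rejected(self):
        t1 = TrendCall(("W0", "W1"), "N", 0.0, 1.0)
        t2 = TrendCall(("W0", "W2"), "N", 0.0, 1.0)
        with pytest.raises(ValidationError):
            assign_pattern(t1, t2)

    def test_enumeration_yields_exactly_nine_patterns(self):
        patterns = set()
        for c1, c2 in itertools.product("UND", repeat=2):
            t1 = TrendCall(("W0", "W1"), c1, 0.0, 1.0)
            t2 = TrendCall(("W1", "W2"), c2, 0.0, 1.0)
            patterns.add(assign_pattern(t1, t2))
        assert patterns == set(PATTERN_CATEGORIES)
        assert len(patterns) == 9

    def test_planted_patterns_recovered_across_seeds(self):
        plants = [PlantedPattern("bta-mir-s0040", "DD", "UNR", "U-D"),
                  PlantedPattern("bta-mir-s0041", "DD", "UNR", "N-U")]
        correct = total = 0
        for seed in range(5):
            cfg = default_longitudinal_config(
                seed=seed, n_mirnas=80, group_sizes={"DD": 24},
                planted_patterns=plants)
            sim = simulate_recovery_cohort(cfg)
            table = classify_temporal_patterns(sim.counts, sim.metadata,
                                               "DD", "UNR")
            for p in plants:
                total += 1
                correct += table.loc[p.mirna_id, "pattern"] == p.pattern
        assert correct / total >= 0.8

    def test_pattern_values_stay_in_taxonomy(self, longitudinal_sim):
        table = classify_temporal_patterns(
            longitudinal_sim.counts, longitudinal_sim.metadata, "DD", "RE")
        assert set(table["pattern"]) <= set(PATTERN_CATEGORIES)
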
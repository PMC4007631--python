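"""Promoter shift test, BH FDR, two-tier calls and sample clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as ss

import medipdiff as md
from medipdiff import promoters


class TestShiftTest:
    def test_exact_small_sample(self):
        p, direction = promoters.promoter_shift_test([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3)
        assert direction == "hypo"

    def test_pool_containing_member_matches_disjoint_formulation(self):
        # ranking {1,2} within {1,2,3,4} == two-sample test vs {3,4}
        p, _ = promoters.promoter_shift_test(
            [1.0, 2.0], [1.0, 2.0, 3.0, 4.0], pool_contains_member=True
        )
        assert p == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_scipy_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(2, 8))
        y = rng.normal(size=rng.integers(3, 8))
        p, _ = promoters.promoter_shift_test(x, y)
        ref = ss.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_values_matching_background_give_large_p(self):
        background = np.linspace(-3, 3, 200)
        x = np.quantile(background, [0.3, 0.5, 0.7])
        p, _ = promoters.promoter_shift_test(x, background)
        assert p > 0.5

    def test_extreme_promoter_far_tail(self):
        background = np.random.default_rng(0).normal(size=100)
        x = background.max() + np.arange(1.0, 6.0)
        p, direction = promoters.promoter_shift_test(x, background)
        assert direction == "hyper"
        assert p < 1e-3
        # agrees with the scipy asymptotic continuity-corrected test
        ref = ss.mannwhitneyu(x, background, alternative="two-sided",
                              method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_single_probe_promoter_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            promoters.promoter_shift_test([1.0], [2.0, 3.0])

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=260)
        codes = np.repeat(np.arange(20), 13)
        p_vec, hyper = promoters.shift_tests(t, codes, 20)
        for g in (0, 7, 19):
            member = t[codes == g]
            p_ref, d_ref = promoters.promoter_shift_test(
                member, t, pool_contains_member=True
            )
            assert p_vec[g] == pytest.approx(p_ref, rel=1e-9)
            assert ("hyper" if hyper[g] else "hypo") == d_ref


class TestBhFdr:
    def test_hand_examples(self):
        assert promoters.bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)
        np.testing.assert_allclose(
            promoters.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])),
            [0.04, 0.04, 0.04, 0.04],
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            promoters.bh_fdr(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            promoters.bh_fdr(np.array([1.5]))

    @given(st.integers(0, 500))
    def test_matches_step_up_oracle_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-12, 1, rng.integers(1, 40))
        q = promoters.bh_fdr(p)
        # independent hand step-up
        m = len(p)
        order = np.argsort(p)
        adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        np.testing.assert_allclose(q, expected, rtol=1e-10)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCallPromoters:
    def _toy_calls(self, q_target):
        """Build probe stats for one promoter embedded in a null background."""
        rng = np.random.default_rng(0)
        n_bg = 300
        rows = []
        for i in range(n_bg):
            rows.append((f"bg{i:03d}_{0:02d}", f"bg{i:03d}", rng.normal(), 0.5, rng.normal(0, 0.05)))
            rows.append((f"bg{i:03d}_{1:02d}", f"bg{i:03d}", rng.normal(), 0.5, rng.normal(0, 0.05)))
        df = pd.DataFrame(rows, columns=["probe_id", "promoter_id", "t_mod", "p", "beta"])
        return df.set_index("probe_id")

    def test_conjunction_of_criteria(self):
        df = self._toy_calls(None)
        # promoter with a DM probe and strongly shifted statistics
        extra = pd.DataFrame(
            {
                "promoter_id": ["hit"] * 8 + ["shift_only"] * 8,
                "t_mod": list(np.arange(8.0, 16.0)) * 2,
                "p": [0.001] + [0.3] * 7 + [0.3] * 8,
                "beta": [0.5] + [0.1] * 15,
            },
            index=pd.Index([f"x{i}" for i in range(16)], name="probe_id"),
        )
        calls = promoters.call_promoters(pd.concat([df, extra]))
        assert bool(calls.loc["hit", "called_default"])
        # no DM probe -> not called however small q
        assert not bool(calls.loc["shift_only", "called_default"])
        assert calls.loc["shift_only", "q"] < 0.001

    def test_q_threshold_gates_default_call(self):
        df = self._toy_calls(None)
        extra = pd.DataFrame(
            {
                "promoter_id": ["weak"] * 2,
                "t_mod": [1.0, 1.2],
                "p": [0.001, 0.5],
                "beta": [0.5, 0.0],
            },
            index=pd.Index(["w0", "w1"], name="probe_id"),
        )
        calls = promoters.call_promoters(pd.concat([df, extra]))
        assert bool(calls.loc["weak", "has_dm_probe"])
        assert calls.loc["weak", "q"] > 0.20
        assert not bool(calls.loc["weak", "called_default"])

    def test_single_probe_promoters_skipped(self):
        df = self._toy_calls(None)
        lone = pd.DataFrame(
            {"promoter_id": ["lone"], "t_mod": [5.0], "p": [0.001], "beta": [0.5]},
            index=pd.Index(["l0"], name="probe_id"),
        )
        calls = promoters.call_promoters(pd.concat([df, lone]))
        assert "lone" not in calls.index


class TestRepresentativeProbe:
    def test_argmin_and_tie_rules(self):
        df = pd.DataFrame(
            {
                "promoter_id": ["P"] * 3 + ["Q"] * 2 + ["R"],
                "p": [0.5, 0.01, 0.2, 0.01, 0.01, 0.9],
                "beta": [0.1, 0.2, 0.3, 0.3, -0.6, 0.0],
            },
            index=pd.Index(["a", "b", "c", "d", "e", "f"], name="probe_id"),
        )
        rep = promoters.representative_probe(df)
        assert rep["P"] == "b"       # smallest p
        assert rep["Q"] == "e"       # tie on p -> larger |beta|
        assert rep["R"] == "f"       # single probe

    def test_lexicographic_final_tie_break(self):
        df = pd.DataFrame(
            {"promoter_id": ["P", "P"], "p": [0.01, 0.01], "beta": [0.3, -0.3]},
            index=pd.Index(["z", "a"], name="probe_id"),
        )
        assert promoters.representative_probe(df)["P"] == "a"


class TestClusterSamples:
    def test_identical_columns_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        df = pd.DataFrame({
            "s1": base, "s2": base, "s3": rng.normal(size=20),
            "s4": rng.normal(size=20),
        })
        Z, order = md.cluster_samples(df)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-7)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_anticorrelated_distance_two(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": -x})
        corr = df.corr().iloc[0, 1]
        assert 1 - corr == pytest.approx(2.0)

    def test_matches_lance_williams_oracle(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        Z, _ = md.cluster_samples(df)
        d = 1 - df.corr().to_numpy()

        # naive Ward agglomeration via the Lance-Williams recurrence
        clusters = {i: [i] for i in range(4)}
        dist = {frozenset((i, j)): d[i, j] for i in range(4) for j in range(i + 1, 4)}
        merges = []
        next_id = 4
        while len(clusters) > 1:
            pair = min(dist, key=lambda k: (dist[k], sorted(k)))
            s, t = sorted(pair)
            h = dist[pair]
            merges.append((s, t, h))
            rest = [c for c in clusters if c not in (s, t)]
            new = {}
            for v in rest:
                nv, ns, nt = len(clusters[v]), len(clusters[s]), len(clusters[t])
                T = nv + ns + nt
                new[v] = np.sqrt(
                    (nv + ns) / T * dist[frozenset((v, s))] ** 2
                    + (nv + nt) / T * dist[frozenset((v, t))] ** 2
                    - nv / T * h**2
                )
            clusters[next_id] = clusters.pop(s) + clusters.pop(t)
            dist = {k: v for k, v in dist.items() if not (k & {s, t})}
            for v, dd in new.items():
                dist[frozenset((v, next_id))] = dd
            next_id += 1

        for row, (s, t, h) in zip(Z, merges):
            assert {int(row[0]), int(row[1])} == {s, t}
            assert row[2] == pytest.approx(h, rel=1e-9)

    def test_constant_column_gets_max_distance(self):
        df = pd.DataFrame({"a": np.arange(5.0), "b": np.arange(5.0),
                           "c": np.ones(5)})
        Z, order = md.cluster_samples(df)
        assert len(order) == 3  # runs despite the undefined correlation
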
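"""Log ratios, quantile normalization, MvA QC and replicate averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import medipdiff as md
from medipdiff.normalize import MethylationMatrix


def matrix(values, columns=None):
    arr = np.asarray(values, dtype=float)
    columns = columns or [f"a{i}" for i in range(arr.shape[1])]
    return MethylationMatrix(pd.DataFrame(arr, columns=columns), "raw")


class TestLogRatios:
    def test_hand_values(self):
        bound = pd.DataFrame({"a": [4.0, 2.0]})
        input_ = pd.DataFrame({"a": [2.0, 2.0]})
        mm = md.compute_log_ratios(bound, input_)
        np.testing.assert_allclose(mm.values["a"], [1.0, 0.0])

    def test_matches_brute_force_and_missingness(self):
        rng = np.random.default_rng(0)
        b = rng.lognormal(8, 1, (50, 4))
        i = rng.lognormal(8, 1, (50, 4))
        b[3, 2] = -1.0
        mm = md.compute_log_ratios(pd.DataFrame(b), pd.DataFrame(i))
        expected = np.log2(b) - np.log2(np.abs(i))
        mask = b > 0
        np.testing.assert_allclose(mm.values.to_numpy()[mask], expected[mask])
        assert np.isnan(mm.values.to_numpy()[3, 2])


class TestQuantileNormalize:
    def test_hand_example(self):
        out = md.quantile_normalize(matrix([[1, 2], [3, 4]]))
        np.testing.assert_allclose(out.values.to_numpy(), [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_fixed_point(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 3))
        out = md.quantile_normalize(matrix(x))
        np.testing.assert_allclose(out.values.to_numpy(), x)

    def test_ties_get_mean_of_spanned_reference(self):
        out = md.quantile_normalize(matrix([[1, 10], [1, 20], [5, 30]]))
        # reference = mean of sorted columns = (5.5, 10.5, 17.5)
        col0 = out.values.iloc[:, 0].to_numpy()
        np.testing.assert_allclose(col0, [8.0, 8.0, 17.5])

    def test_missing_values_stay_missing(self):
        x = np.array([[1.0, 2.0], [np.nan, 4.0], [3.0, 6.0]])
        out = md.quantile_normalize(matrix(x))
        assert np.isnan(out.values.to_numpy()[1, 0])
        assert np.isfinite(out.values.to_numpy()[[0, 2], 0]).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            md.quantile_normalize(matrix(np.array([[1.0], [2.0]])))
        x = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError, match="fewer than 2"):
            md.quantile_normalize(matrix(x))

    @given(st.integers(0, 1000))
    def test_idempotent_and_columns_share_sorted_values(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(rng.integers(5, 30), rng.integers(2, 6)))
        once = md.quantile_normalize(matrix(x))
        twice = md.quantile_normalize(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12
        )
        sorted_cols = np.sort(once.values.to_numpy(), axis=0)
        np.testing.assert_allclose(
            sorted_cols, sorted_cols[:, [0]] * np.ones_like(sorted_cols), atol=1e-9
        )
        assert np.allclose(once.values.mean(0), once.values.mean(0).iloc[0])


class TestMaQc:
    def test_equal_channels_zero_m(self):
        b = pd.DataFrame({"a": np.full(100, 50.0)})
        qc = md.ma_qc(b, b)
        assert qc.loc[0, "median_M"] == pytest.approx(0.0)

    def test_doubled_bound_gives_m_one(self):
        rng = np.random.default_rng(1)
        i = pd.DataFrame({"a": rng.lognormal(8, 1, 200)})
        qc = md.ma_qc(2 * i, i)
        assert qc.loc[0, "median_M"] == pytest.approx(1.0)

    def test_dye_bias_slope_monotone_in_amplitude(self):
        slopes = []
        for amp in (0.0, 0.2, 0.5):
            cfg = md.SimulationConfig(n_promoters=80, n_mirnas=4, n_case=2,
                                      n_control=2, seed=9, dye_bias_amplitude=amp)
            layout = md.generate_genome_layout(cfg)
            truth = md.simulate_truth(layout, cfg)
            bound, input_, sheet = md.simulate_arrays(layout, truth, cfg)
            qc = md.ma_qc(bound, input_)
            slopes.append(qc["slope_MA"].abs().mean())
        assert slopes[0] < slopes[1] < slopes[2]


class TestAverageReplicates:
    def test_mean_and_missing_handling(self):
        sheet = pd.DataFrame({
            "array_id": ["a1", "a2", "a3"], "individual_id": ["i1"] * 3,
            "replicate": [1, 2, 3], "group": ["case"] * 3,
        })
        mm = matrix(np.array([[0.2, 0.4, 0.6], [0.2, np.nan, 0.6]]),
                    columns=["a1", "a2", "a3"])
        avg = md.average_replicates(mm, sheet)
        np.testing.assert_allclose(avg.values["i1"], [0.4, 0.4])

    def test_one_column_per_individual(self, small_data):
        avg = small_data["avg"]
        assert avg.values.shape[1] == 40
        assert avg.stage == "individual-averaged"

    def test_commutes_with_replicate_permutation(self, small_data):
        sheet = small_data["sheet"]
        mm = small_data["mm"]
        shuffled = sheet.sample(frac=1, random_state=3)
        a = md.average_replicates(mm, sheet)
        b = md.average_replicates(mm, shuffled)
        pd.testing.assert_frame_equal(a.values, b.values[a.values.columns])


class TestVarianceExplained:
    def _cohort(self, individual_sd, replicate_sd, seed=21):
        cfg = md.SimulationConfig(
            n_promoters=100, n_mirnas=5, n_case=5, n_control=5, seed=seed,
            individual_sd=individual_sd, replicate_sd=replicate_sd,
        )
        layout = md.generate_genome_layout(cfg)
        truth = md.simulate_truth(layout, cfg)
        bound, input_, sheet = md.simulate_arrays(layout, truth, cfg)
        return md.compute_log_ratios(bound, input_), sheet

    def test_no_replicate_noise_gives_one(self):
        mm, sheet = self._cohort(0.3, 0.0)
        assert md.replicate_variance_explained(mm, sheet) == pytest.approx(1.0)

    def test_no_individual_variation_gives_near_zero(self):
        mm, sheet = self._cohort(0.0, 0.3)
        # use all probes: restricting to the most variable ones would add
        # selection bias to the variance-component estimate under the null
        got = md.replicate_variance_explained(mm, sheet, top_k=mm.n_probes)
        assert got < 0.05

    def test_matches_hand_anova_on_toy(self):
        # 3 individuals x 2 replicates, one probe
        sheet = pd.DataFrame({
            "array_id": list("abcdef"), "individual_id": ["i1", "i1", "i2", "i2", "i3", "i3"],
            "replicate": [1, 2] * 3, "group": ["case"] * 6,
        })
        row = np.array([[1.0, 2.0, 4.0, 5.0, 9.0, 10.0]])
        mm = matrix(row, columns=list("abcdef"))
        got = md.replicate_variance_explained(mm, sheet, top_k=1)
        # hand decomposition: group means 1.5/4.5/9.5, grand 5.1(6)
        msb = 2 * ((1.5 - 31 / 6) ** 2 + (4.5 - 31 / 6) ** 2 + (9.5 - 31 / 6) ** 2) / 2
        msw = (0.5 * 3) / 3  # SSW = 0.5 per individual, df = 6 - 3
        sigma_b2 = (msb - msw) / 2
        assert got == pytest.approx(sigma_b2 / (sigma_b2 + msw))

    def test_top_k_capped_with_warning(self, small_data):
        mm, sheet = small_data["mm"], small_data["sheet"]
        got = md.replicate_variance_explained(mm, sheet, top_k=10**6)
        assert 0 <= got <= 1
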
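import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import mirtempo as mt
from mirtempo.prep import CountFormatError, NormFactors

from _oracles import tmm_factors_bruteforce


class TestReadWrite:
    def test_round_trip_is_identity(self, toy_counts, tmp_path):
        path = tmp_path / "counts.tsv"
        mt.prep.write_count_table(toy_counts, path)
        back = mt.read_count_table(path)
        pd.testing.assert_frame_equal(
            back, toy_counts.astype(np.int64), check_names=False
        )

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("feature_id\ts1\ts2\nmiR-a\t4\t-3\n")
        with pytest.raises(CountFormatError, match="negative"):
            mt.read_count_table(path)

    def test_duplicate_feature_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("feature_id\ts1\nmiR-21a-5p\t4\nmiR-21a-5p\t2\n")
        with pytest.raises(CountFormatError, match="duplicate"):
            mt.read_count_table(path)

    def test_ragged_rows_rejected(self, tmp_path):
        path = tmp_path / "ragged.tsv"
        path.write_text("feature_id\ts1\ts2\nmiR-a\t4\t3\nmiR-b\t1\n")
        with pytest.raises(CountFormatError):
            mt.read_count_table(path)

    def test_non_integer_count_rejected(self, tmp_path):
        path = tmp_path / "float.tsv"
        path.write_text("feature_id\ts1\ts2\nmiR-a\t4.5\t3\n")
        with pytest.raises(CountFormatError, match="non-integer"):
            mt.read_count_table(path)


class TestCpm:
    def test_million_read_sample_gives_cpm_equal_counts(self):
        counts = pd.DataFrame({"s1": [999_990, 10]}, index=["miR-a", "miR-b"])
        cpm = mt.compute_cpm(counts)
        pd.testing.assert_frame_equal(cpm, counts.astype(float), check_dtype=False)

    def test_cpm_columns_sum_to_one_million(self, toy_counts):
        cpm = mt.compute_cpm(toy_counts)
        assert np.allclose(cpm.sum(axis=0), 1e6)

    def test_doubling_a_factor_halves_that_samples_cpm(self, toy_counts):
        base = NormFactors.unit(toy_counts)
        doubled = NormFactors(
            lib_size=base.lib_size,
            factor=base.factor * pd.Series(
                [2.0, 1.0, 1.0, 1.0], index=toy_counts.columns
            ),
        )
        a = mt.compute_cpm(toy_counts, base)
        b = mt.compute_cpm(toy_counts, doubled)
        assert np.allclose(b.iloc[:, 0], a.iloc[:, 0] / 2)
        assert np.allclose(b.iloc[:, 1:], a.iloc[:, 1:])

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [3], "s2": [0]}, index=["miR-a"])
        with pytest.raises(ValueError, match="library"):
            mt.compute_cpm(counts)


class TestFilter:
    def _with_filler(self, rows, lib=100_000):
        """Matrix with the given feature rows plus a filler reaching the library size."""
        df = pd.DataFrame(rows).T
        df.columns = [f"s{j}" for j in range(df.shape[1])]
        filler = lib - df.sum(axis=0)
        df.loc["filler"] = filler
        return df

    def test_hand_computed_cpm_boundary(self):
        # libraries of 1e5: counts of 1 are CPM 10 > 4; three such samples keep
        # a feature, two do not
        counts = self._with_filler({
            "keep": [1, 1, 1, 0, 0, 0],
            "drop": [1, 1, 0, 0, 0, 0],
        })
        kept = mt.filter_low_expression(counts, min_cpm=4, min_samples=3)
        assert "keep" in kept.index and "drop" not in kept.index

    def test_all_zero_feature_removed(self):
        counts = self._with_filler({"zero": [0, 0, 0, 0, 0, 0], "ok": [9, 9, 9, 9, 9, 9]})
        kept = mt.filter_low_expression(counts)
        assert "zero" not in kept.index and "ok" in kept.index

    def test_cpm_five_in_three_samples_retained(self):
        counts = self._with_filler({"f": [5, 5, 5, 0, 0, 0]}, lib=1_000_000)
        assert "f" in mt.filter_low_expression(counts).index

    def test_min_samples_beyond_data_rejected(self, toy_counts):
        with pytest.raises(ValueError, match="min_samples"):
            mt.filter_low_expression(toy_counts, min_samples=10)

    @given(
        arrays(np.int64, (8, 6), elements=st.integers(0, 500)).filter(
            lambda a: (a.sum(axis=0) > 0).all()
        )
    )
    def test_filtering_is_idempotent(self, values):
        counts = pd.DataFrame(
            values,
            index=[f"f{i}" for i in range(8)],
            columns=[f"s{j}" for j in range(6)],
        )
        once = mt.filter_low_expression(counts, min_samples=2)
        twice = mt.filter_low_expression(once, min_samples=2) if not once.empty else once
        pd.testing.assert_frame_equal(once, twice)


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        col = pd.Series([10, 40, 3, 90, 17], index=[f"f{i}" for i in range(5)])
        counts = pd.DataFrame({f"s{j}": col for j in range(4)})
        fac = mt.tmm_factors(counts)
        assert np.allclose(fac.factor, 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        a = pd.Series([10, 40, 3, 90, 17, 55], index=[f"f{i}" for i in range(6)])
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        fac = mt.tmm_factors(counts)
        assert np.allclose(fac.factor, 1.0)

    def test_matches_bruteforce_formula_with_abundance_outlier(self):
        rng = np.random.default_rng(12)
        counts = pd.DataFrame(
            rng.poisson(60, size=(20, 5)),
            index=[f"f{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(5)],
        )
        counts.iloc[0, 2] = counts.iloc[:, 2].sum()  # ~50% of that sample
        fac = mt.tmm_factors(counts)
        oracle = tmm_factors_bruteforce(counts)
        assert np.max(np.abs(fac.factor.to_numpy() - oracle)) < 1e-10

    def test_invariant_to_integer_scaling_of_one_sample(self):
        rng = np.random.default_rng(13)
        counts = pd.DataFrame(
            rng.poisson(30, size=(15, 4)),
            index=[f"f{i}" for i in range(15)],
            columns=[f"s{j}" for j in range(4)],
        )
        scaled = counts.copy()
        scaled["s1"] = scaled["s1"] * 3
        # M-values, A-values and trim ranks are unchanged; only the precision
        # weights shift (they reflect the tripled counting depth), so the
        # factors agree closely but not exactly
        assert np.allclose(
            mt.tmm_factors(counts).factor, mt.tmm_factors(scaled).factor, atol=1e-2
        )

    def test_factors_have_unit_geometric_mean(self, sim_small):
        counts, _, _ = sim_small
        fac = mt.tmm_factors(mt.filter_low_expression(counts))
        assert abs(np.exp(np.mean(np.log(fac.factor))) - 1) < 1e-12

    def test_disjoint_support_rejected(self):
        counts = pd.DataFrame(
            {"a": [5, 5, 0, 0], "b": [4, 6, 0, 0], "c": [0, 0, 7, 3]},
            index=[f"f{i}" for i in range(4)],
        )
        with pytest.raises(ValueError, match="no nonzero"):
            mt.tmm_factors(counts)


class TestPcaQc:
    def test_duplicated_sample_gets_identical_coordinates(self, toy_counts):
        counts = toy_counts.copy()
        counts["s0_dup"] = counts["s0"]
        scores, _ = mt.pca_qc(mt.compute_cpm(counts))
        assert np.allclose(scores.loc["s0"], scores.loc["s0_dup"], atol=1e-8)

    def test_variance_fractions_non_increasing_and_bounded(self, sim_small):
        counts, design, _ = sim_small
        cpm = mt.compute_cpm(mt.filter_low_expression(counts))
        _, var_frac = mt.pca_qc(cpm, design)
        assert np.all(np.diff(var_frac) <= 1e-12)
        assert var_frac.sum() <= 1 + 1e-9

    def test_groups_separate_under_strong_effects(self):
        cfg = mt.SimConfig(
            n_features=300,
            lib_size_mean=2e5,
            effect_log2fc=2.0,
            module_fractions={"up-up": 0.1, "down-down": 0.1},
            dispersion=0.05,
            seed=21,
        )
        counts, design, _ = mt.simulate_experiment(cfg)
        cpm = mt.compute_cpm(mt.filter_low_expression(counts))
        scores, _ = mt.pca_qc(cpm, design)
        xy = scores[["PC1", "PC2"]].to_numpy()
        labels = (design["condition"] + design["timepoint"].astype(str)).to_numpy()
        within, between = [], []
        for i in range(len(xy)):
            for j in range(i + 1, len(xy)):
                d = np.linalg.norm(xy[i] - xy[j])
                (within if labels[i] == labels[j] else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_too_few_features_or_samples_rejected(self):
        one_feature = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}, index=["f0"])
        with pytest.raises(ValueError, match="two features"):
            mt.pca_qc(one_feature)
        two_samples = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match="three samples"):
            mt.pca_qc(two_samples)
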
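import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import gammaln

import mirtempo as mt
from mirtempo.diffexp import Dispersion, _exact_pvalues, bh_adjust
from mirtempo.prep import NormFactors

from _oracles import binomial_two_sided, exact_pvalue_bruteforce


def _equal_lib_factors(samples, lib=1e6):
    return NormFactors(
        lib_size=pd.Series(lib, index=samples),
        factor=pd.Series(1.0, index=samples),
    )


class TestBhAdjust:
    def test_printed_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_all_ones_stay_ones(self):
        assert np.allclose(bh_adjust([1.0] * 5), 1.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_q_at_least_p_and_order_preserved(self, pvals):
        q = bh_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all(q <= 1 + 1e-12)
        # q is non-decreasing in p order
        order = np.argsort(pvals, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestExactTest:
    @pytest.mark.parametrize("phi", [0.0, 0.2])
    def test_matches_bruteforce_enumeration_small_totals(self, phi):
        """Full-enumeration oracle agreement at totals <= 30, 3 vs 3 samples."""
        rng = np.random.default_rng(17)
        for _ in range(60):
            a = rng.integers(0, 6, 3)
            b = rng.integers(0, 6, 3)
            if a.sum() + b.sum() == 0:
                continue
            p_pkg = _exact_pvalues(
                np.array([a.sum()]), np.array([b.sum()]), 3, 3, phi
            )[0]
            p_ref = exact_pvalue_bruteforce(a, b, phi)
            assert abs(p_pkg - p_ref) < 1e-9

    def test_poisson_limit_equals_binomial_enumeration(self):
        """phi=0, equal libraries: conditional law is Binomial(t, n_a/(n_a+n_b))."""
        a, b = [2, 3], [8, 9]
        p_pkg = _exact_pvalues(np.array([5]), np.array([17]), 2, 2, 0.0)[0]
        assert abs(p_pkg - binomial_two_sided(a, b)) < 1e-12

    def test_mode_split_has_pvalue_one(self):
        # equal group sizes, split at the conditional mode
        p = _exact_pvalues(np.array([15]), np.array([15]), 3, 3, 0.1)[0]
        assert p == pytest.approx(1.0)

    def test_zero_total_feature_defined_not_error(self):
        samples = [f"s{j}" for j in range(6)]
        counts = pd.DataFrame(
            [[0] * 6, [50, 60, 40, 55, 45, 52]],
            index=["empty", "busy"],
            columns=samples,
        )
        de = mt.nb_exact_test(
            counts, samples[:3], samples[3:], 0.1, _equal_lib_factors(samples)
        )
        assert de.loc["empty", "pvalue"] == 1.0
        assert de.loc["empty", "log2fc"] == 0.0

    def test_group_swap_negates_log2fc_and_keeps_p(self, sim_small):
        counts, design, _ = sim_small
        filtered = mt.filter_low_expression(counts)
        factors = mt.tmm_factors(filtered)
        g3 = list(design.index[(design.condition == "activated") & (design.timepoint == 3)])
        nt = list(design.index[design.condition == "NT"])
        fwd = mt.nb_exact_test(filtered, nt, g3, 0.1, factors)
        rev = mt.nb_exact_test(filtered, g3, nt, 0.1, factors)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_p_never_increases_moving_away_from_mode(self):
        t = 40
        s = np.arange(t + 1)
        p = _exact_pvalues(s, t - s, 3, 3, 0.2)
        mode = int(np.argmax(p))
        assert np.all(np.diff(p[: mode + 1]) >= -1e-12)
        assert np.all(np.diff(p[mode:]) <= 1e-12)

    def test_empty_group_rejected(self, toy_counts):
        with pytest.raises(ValueError, match="at least one sample"):
            mt.nb_exact_test(toy_counts, [], list(toy_counts.columns), 0.1)


class TestDems:
    @pytest.mark.parametrize(
        "q,lfc,expected",
        [
            (0.04, 0.5, "up"),  # passes both gates
            (0.2, 2.0, None),  # fails the FDR gate
            (0.001, 0.2, None),  # fails the fold-change gate
            (0.05, -0.34, "down"),  # inclusive FDR boundary, strict FC gate
        ],
    )
    def test_gates_and_direction(self, q, lfc, expected):
        de = pd.DataFrame(
            {"log2fc": [lfc], "avg_log2cpm": [5.0], "pvalue": [q / 2], "qvalue": [q]},
            index=["miR-x-5p"],
        )
        calls = mt.call_dems(de)
        if expected is None:
            assert calls.empty
        else:
            assert list(calls["direction"]) == [expected]


class TestDispersion:
    def test_recovers_simulating_value(self):
        """3 vs 3 triplicate-style design at phi=0.1, 2000 features."""
        cfg = mt.SimConfig(
            n_features=2000,
            groups=(("NT", 0, 3), ("activated", 3, 3)),
            module_fractions={},
            dispersion=0.1,
            seed=31,
        )
        counts, design, _ = mt.simulate_experiment(cfg)
        filtered = mt.filter_low_expression(counts)
        groups = [list(design.index[:3]), list(design.index[3:])]
        est = mt.estimate_common_dispersion(filtered, groups, mt.tmm_factors(filtered))
        assert 0.08 <= est.common <= 0.12

    def test_poisson_data_estimates_near_zero(self):
        cfg = mt.SimConfig(
            n_features=800,
            groups=(("NT", 0, 3), ("activated", 3, 3)),
            module_fractions={},
            dispersion=0.0,
            lib_size_mean=2e5,
            seed=32,
        )
        counts, design, _ = mt.simulate_experiment(cfg)
        filtered = mt.filter_low_expression(counts)
        groups = [list(design.index[:3]), list(design.index[3:])]
        est = mt.estimate_common_dispersion(filtered, groups)
        assert est.common < 0.01

    def test_grid_plus_golden_matches_fine_grid_argmax(self):
        """Optimizer oracle: exhaustive 4000-point grid on a 50-feature fixture."""
        rng = np.random.default_rng(33)
        mu = rng.uniform(20, 200, 50)
        lam = rng.gamma(1 / 0.15, 0.15 * mu[:, None], size=(50, 6))
        counts = pd.DataFrame(
            rng.poisson(lam),
            index=[f"f{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(6)],
        )
        totals = counts.sum(axis=0)
        counts.iloc[0] += (totals.max() - totals).to_numpy()  # equal libraries
        groups = [list(counts.columns[:3]), list(counts.columns[3:])]
        est = mt.estimate_common_dispersion(counts, groups, NormFactors.unit(counts))

        def cond_ll(phi):
            total = 0.0
            for g in groups:
                y = counts[g].to_numpy(dtype=float)
                # pseudo-counts equal raw counts here (factors put aside for the oracle)
                r = 1.0 / phi
                n = y.shape[1]
                total += np.sum(
                    gammaln(y + r).sum(axis=1)
                    - n * gammaln(r)
                    + gammaln(n * r)
                    - gammaln(y.sum(axis=1) + n * r)
                )
            return total

        fine = np.logspace(-6, 1, 4000)
        ll = [cond_ll(p) for p in fine]
        best = fine[int(np.argmax(ll))]
        # within the coarse-grid resolution (~0.24 decades)
        assert abs(np.log10(est.common) - np.log10(best)) < 0.25

    def test_all_zero_matrix_rejected(self):
        counts = pd.DataFrame(
            np.zeros((3, 4), dtype=int),
            index=list("abc"),
            columns=[f"s{j}" for j in range(4)],
        )
        with pytest.raises(ValueError):
            mt.estimate_common_dispersion(counts, [[f"s{j}" for j in range(4)]])

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            Dispersion(common=-0.5)


class TestTagwiseDispersion:
    def test_shrunk_estimates_cluster_around_common(self):
        cfg = mt.SimConfig(
            n_features=300,
            groups=(("NT", 0, 3), ("activated", 3, 3)),
            module_fractions={},
            dispersion=0.1,
            lib_size_mean=2e5,
            seed=34,
        )
        counts, design, _ = mt.simulate_experiment(cfg)
        filtered = mt.filter_low_expression(counts)
        groups = [list(design.index[:3]), list(design.index[3:])]
        est = mt.diffexp.estimate_tagwise_dispersion(filtered, groups)
        assert est.per_feature is not None
        assert len(est.per_feature) == len(filtered)
        assert (est.per_feature > 0).all()
        # shrinkage keeps the bulk of per-feature values near the common one
        log_ratio = np.log10(est.per_feature / est.common)
        assert np.median(np.abs(log_ratio)) < 1.0
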
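import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plastiscan.stats import (
    chance_proportion,
    fraction_exceeding,
    log_ratio_trait,
    overlap_randomization,
    proportion_chisq,
    pst_bootstrap,
    pst_statistic,
    pst_table,
)


def exact_overlap_null(a_calls: dict, n_up: int, n_down: int, universe: list):
    """Enumerate every assignment of B's up/down calls to distinct genes and
    return the exact distribution of the direction-matched overlap count."""
    counts = []
    for sig_genes in itertools.permutations(universe, n_up + n_down):
        ups, downs = sig_genes[:n_up], sig_genes[n_up:]
        c = sum(1 for g in ups if a_calls.get(g) == "up")
        c += sum(1 for g in downs if a_calls.get(g) == "down")
        counts.append(c)
    return np.array(counts)


def _series(mapping):
    return pd.Series(mapping)


class TestOverlapRandomization:
    def test_matches_exhaustive_enumeration(self):
        universe = ["g1", "g2", "g3"]
        a = _series({"g1": "up", "g2": "down", "g3": "ns"})
        b = _series({"g1": "up", "g2": "ns", "g3": "ns"})
        exact = exact_overlap_null({"g1": "up", "g2": "down"}, 1, 0, universe)
        # observed overlap is 1; exact P(overlap >= 1) = 1/3
        p_exact = (exact >= 1).mean()
        assert p_exact == pytest.approx(1 / 3)
        rr = overlap_randomization(a, b, universe, n_permutations=10_000, seed=0)
        assert rr.observed_overlap == 1
        assert abs(rr.p_value - p_exact) < 0.02
        assert abs(rr.expected_overlap - exact.mean()) < 0.02

    def test_matches_enumeration_larger_universe(self):
        universe = [f"g{i}" for i in range(8)]
        a_map = {"g0": "up", "g1": "up", "g2": "down", "g3": "down"}
        a = _series({g: a_map.get(g, "ns") for g in universe})
        b = _series(
            {g: c for g, c in zip(universe, ["up", "down", "up", "ns", "ns", "ns", "ns", "ns"])}
        )
        exact = exact_overlap_null(a_map, 2, 1, universe)
        observed = 1 + 0 + 0  # g0 up matches; g1 down vs up no; g2 up vs down no
        rr = overlap_randomization(a, b, universe, n_permutations=10_000, seed=1)
        assert rr.observed_overlap == observed
        assert abs(rr.p_value - (1 + (exact >= observed).sum()) / (len(exact) + 1)) < 0.02
        assert abs(rr.expected_overlap - exact.mean()) < 0.05

    def test_all_ns_partner_gives_p_one(self):
        universe = ["g1", "g2", "g3"]
        a = _series({"g1": "up", "g2": "down", "g3": "ns"})
        b = _series({g: "ns" for g in universe})
        rr = overlap_randomization(a, b, universe, n_permutations=100, seed=0)
        assert rr.observed_overlap == 0 and rr.p_value == 1.0

    def test_identical_saturated_sets_give_p_one(self):
        universe = ["g1", "g2"]
        a = _series({"g1": "up", "g2": "up"})
        rr = overlap_randomization(a, a, universe, n_permutations=50, seed=0)
        assert rr.observed_overlap == 2 and rr.p_value == 1.0

    def test_universe_smaller_than_significant_set_rejected(self):
        a = _series({"g1": "up"})
        b = _series({"g1": "up", "g2": "up"})
        with pytest.raises(ValueError, match="universe"):
            overlap_randomization(a, b, ["g1"], n_permutations=10)

    def test_super_uniform_under_independent_nulls(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(200)]
        pvals = []
        for k in range(200):
            a = _series(
                {g: rng.choice(["up", "down", "ns"], p=[0.1, 0.1, 0.8]) for g in universe}
            )
            b = _series(
                {g: rng.choice(["up", "down", "ns"], p=[0.1, 0.1, 0.8]) for g in universe}
            )
            rr = overlap_randomization(a, b, universe, n_permutations=200, seed=k)
            pvals.append(rr.p_value)
        pvals = np.array(pvals)
        for alpha in (0.05, 0.1, 0.25):
            frac = (pvals <= alpha).mean()
            se = np.sqrt(alpha * (1 - alpha) / len(pvals))
            assert frac <= alpha + 3 * se


class TestProportionChisq:
    def test_null_equality_gives_zero(self):
        out = proportion_chisq(30, 100, 0.3)
        assert out.chi2 == 0.0 and out.p_value == 1.0

    def test_hand_computed_statistic(self):
        out = proportion_chisq(50, 100, 0.25, continuity=False)
        assert out.chi2 == pytest.approx(33.33, abs=0.005)
        assert out.df == 1

    def test_monotone_in_deviation(self):
        stats_seq = [proportion_chisq(x, 100, 0.25).chi2 for x in (30, 40, 50, 60)]
        assert stats_seq == sorted(stats_seq)

    def test_continuity_correction_shrinks_statistic(self):
        plain = proportion_chisq(50, 100, 0.25).chi2
        corrected = proportion_chisq(50, 100, 0.25, continuity=True).chi2
        assert corrected < plain

    @pytest.mark.parametrize("p0", [0.0, 1.0])
    def test_degenerate_null_rejected(self, p0):
        with pytest.raises(ValueError):
            proportion_chisq(5, 10, p0)


class TestChanceProportion:
    def test_product_of_marginals(self):
        rng = np.random.default_rng(4)
        n = 2000
        frame = pd.DataFrame(
            {
                "c1": rng.choice(["up", "ns"], size=n, p=[0.1, 0.9]),
                "c2": rng.choice(["up", "ns"], size=n, p=[0.1, 0.9]),
            }
        )
        rule = lambda f: (f["c1"] == "up") & (f["c2"] == "up")
        p0, se = chance_proportion(frame, rule, n_permutations=300, seed=0)
        marg = (frame["c1"] == "up").mean() * (frame["c2"] == "up").mean()
        assert abs(p0 - marg) < 4 * se + 1e-4

    def test_impossible_condition_gives_zero(self):
        frame = pd.DataFrame({"c1": ["up", "ns"] * 10})
        rule = lambda f: f["c1"] == "sideways"
        p0, _ = chance_proportion(frame, rule, n_permutations=20, seed=0)
        assert p0 == 0.0

    def test_monte_carlo_se_scaling(self):
        # quadrupling the permutation count halves the reported SE
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            {
                "c1": rng.choice(["up", "ns"], size=300, p=[0.3, 0.7]),
                "c2": rng.choice(["up", "ns"], size=300, p=[0.3, 0.7]),
            }
        )
        rule = lambda f: (f["c1"] == "up") & (f["c2"] == "up")
        reps = 25
        se_small = [chance_proportion(frame, rule, 16, seed=i)[1] for i in range(reps)]
        se_big = [chance_proportion(frame, rule, 64, seed=1000 + i)[1] for i in range(reps)]
        ratio = np.mean(se_small) / np.mean(se_big)
        assert 1.5 < ratio < 2.7


class TestPst:
    def test_equal_variance_components_third(self):
        # two populations with means 0 and 2 -> s2_between = 2;
        # within-population sample variance = 2 as well
        a = np.array([-np.sqrt(2), 0.0, np.sqrt(2)])
        vals = np.concatenate([a, a + 2.0])
        labels = ["p1"] * 3 + ["p2"] * 3
        out = pst_statistic(vals, labels, c_over_h2=1.0)
        assert out.sigma2_between == pytest.approx(out.sigma2_within)
        assert out.pst == pytest.approx(1 / 3)

    def test_identical_means_zero(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = ["p1"] * 3 + ["p2"] * 3
        assert pst_statistic(vals, labels).pst == 0.0

    def test_zero_within_variance_one(self):
        vals = np.array([1.0, 1.0, 2.0, 2.0])
        labels = ["p1", "p1", "p2", "p2"]
        assert pst_statistic(vals, labels).pst == 1.0

    def test_degenerate_flagged(self):
        vals = np.ones(6)
        labels = ["p1"] * 3 + ["p2"] * 3
        with pytest.warns(UserWarning, match="undefined"):
            out = pst_statistic(vals, labels)
        assert np.isnan(out.pst)

    @settings(max_examples=50, derandomize=True)
    @given(
        shift=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    def test_location_scale_invariance(self, shift, scale):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=12)
        vals[6:] += 1.5
        labels = ["p1"] * 6 + ["p2"] * 6
        base = pst_statistic(vals, labels).pst
        moved = pst_statistic(vals * scale + shift, labels).pst
        assert moved == pytest.approx(base, rel=1e-9)

    def test_pst_table_matches_scalar(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.normal(size=(5, 3)), index=list("abcde"))
        b = pd.DataFrame(rng.normal(loc=1.0, size=(5, 3)), index=list("abcde"))
        tab = pst_table({"p1": a, "p2": b})
        for g in "abcde":
            vals = np.concatenate([a.loc[g], b.loc[g]])
            labels = ["p1"] * 3 + ["p2"] * 3
            assert tab.loc[g, "pst"] == pytest.approx(pst_statistic(vals, labels).pst)


class TestPstBootstrap:
    def test_ci_shrinks_with_separated_populations(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0, 0.01, 200), rng.normal(5, 0.01, 200)])
        labels = ["p1"] * 200 + ["p2"] * 200
        out = pst_bootstrap(vals, labels, reps=200, seed=0)
        assert out.ci_high - out.ci_low < 0.01
        assert out.pst > 0.99

    def test_point_estimate_inside_ci(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 1, 8), rng.normal(1, 1, 8)])
        labels = ["p1"] * 8 + ["p2"] * 8
        out = pst_bootstrap(vals, labels, reps=200, seed=1)
        assert out.ci_low <= out.pst <= out.ci_high

    def test_seeded_runs_identical(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(0, 1, 6), rng.normal(1, 1, 6)])
        labels = ["p1"] * 6 + ["p2"] * 6
        a = pst_bootstrap(vals, labels, reps=150, seed=7)
        b = pst_bootstrap(vals, labels, reps=150, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            pst_bootstrap([1.0, 2.0, 3.0, 4.0], ["p1", "p1", "p2", "p2"], reps=10)


class TestFractionExceeding:
    def test_saturated_pst(self):
        fst = np.linspace(0, 0.9, 100)
        assert fraction_exceeding(np.ones(5), fst, alpha=0.05) == 1.0

    def test_calibrated_when_pst_drawn_from_fst(self):
        rng = np.random.default_rng(5)
        fst = rng.beta(0.8, 3.0, 10_000)
        pst = rng.choice(fst, size=10_000, replace=True)
        frac = fraction_exceeding(pst, fst, alpha=0.05)
        assert abs(frac - 0.05) < 0.01

    def test_empty_gene_set_flagged(self):
        with pytest.warns(UserWarning, match="empty gene set"):
            out = fraction_exceeding(np.array([]), np.array([0.1, 0.2]))
        assert np.isnan(out)

    def test_empty_fst_rejected(self):
        with pytest.raises(ValueError):
            fraction_exceeding(np.array([0.5]), np.array([]))


class TestLogRatioTrait:
    def test_paired_ratio_columns(self, sim_small):
        from plastiscan.contrasts import prepare_experiment
        from plastiscan.de import normalized_counts

        zinc = prepare_experiment(sim_small["zinc"], sim_small["sheet"], "zinc_expt")
        norm = normalized_counts(zinc.cm, zinc.size_factors)
        tab = log_ratio_trait(norm, zinc.sheet, "Mine-W", "zinc")
        assert set(tab.columns) == {"i1", "i2", "i3"}
        assert len(tab) == zinc.cm.shape[0]
        assert np.isfinite(tab.to_numpy()).all()
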
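"""Bipolarity testing and pCSM calling."""

import numpy as np
import pytest

from methdissect.betamix import (assign_subsets, bipolarity_pvalue,
                                 fit_beta_mixture, shrink_levels)
from methdissect.betamix import test_bipolarity as lrt_pvalue
from methdissect.pcsm import (call_pcsm, cluster_patterns_bulk, is_candidate,
                              segment_seed, subset_diff_stats, unit_levels)
from methdissect.io_segments import SegmentKey

from conftest import profile_from_counts


class TestCandidateGate:
    @pytest.mark.parametrize("counts,expected", [
        ({"1111": 1, "0000": 1, "1010": 8}, True),
        ({"1110": 5, "0000": 5}, False),
        ({"1111": 10}, False),
    ])
    def test_requires_both_extreme_patterns(self, counts, expected):
        assert is_candidate(profile_from_counts(counts)) is expected

    def test_only_candidates_are_tested(self):
        profiles = [profile_from_counts({"1110": 6, "0001": 6}),
                    profile_from_counts({"1111": 6, "0000": 6},
                                        pos=(200, 210, 220, 230))]
        calls = call_pcsm(profiles, seed=1)
        by_pos = {c.key.pos[0]: c for c in calls}
        assert by_pos[100].p_raw == 1.0 and by_pos[100].p_adj == 1.0
        assert by_pos[200].p_raw < 1.0


class TestUnitLevels:
    def test_quarter_grid(self):
        p = profile_from_counts({"1101": 1, "0000": 1, "1111": 1})
        assert sorted(unit_levels(p)) == [0.0, 0.75, 1.0]

    def test_length_matches_units(self):
        p = profile_from_counts({"1010": 7, "0000": 3})
        assert len(unit_levels(p)) == 10


class TestBetaMixtureFit:
    def test_separated_components_recovered(self, rng):
        levels = np.concatenate([rng.beta(20, 1, 10), rng.beta(1, 20, 10)])
        fit = fit_beta_mixture(levels, seed=1)
        lo, hi = fit.component_means
        assert lo < 0.5 < hi
        assert hi - lo > 0.8
        # agrees with an independent direct likelihood maximization
        from scipy.optimize import minimize
        from scipy.stats import beta as beta_dist
        x = shrink_levels(levels)

        def nll(theta):
            w = 1 / (1 + np.exp(-theta[0]))
            a1, b1, a2, b2 = np.exp(theta[1:])
            f = (w * beta_dist.pdf(x, a1, b1)
                 + (1 - w) * beta_dist.pdf(x, a2, b2))
            return -np.log(np.maximum(f, 1e-300)).sum()

        best = min(
            minimize(nll, t0, method="Nelder-Mead",
                     options={"maxiter": 4000, "fatol": 1e-10}).fun
            for t0 in ([0.0, np.log(20), 0.0, 0.0, np.log(20)],
                       [0.0, 0.0, np.log(20), np.log(20), 0.0])
        )
        # the constrained MoM-EM likelihood must be close to (and of course
        # not above) the unconstrained optimum
        assert fit.ll2 <= -best + 1e-6
        assert fit.ll2 > -best - 0.1 * abs(best) - 2.0

    def test_degenerate_constant_levels_not_significant(self):
        fit = fit_beta_mixture(np.full(20, 0.5), seed=0)
        assert fit.lrt == pytest.approx(0.0, abs=1e-9)
        assert lrt_pvalue(fit) == 1.0

    def test_mirror_symmetry(self, rng):
        levels = rng.beta(2, 6, 24)
        f1 = fit_beta_mixture(levels, seed=3)
        f2 = fit_beta_mixture(1.0 - levels, seed=3)
        m1 = np.sort(f1.component_means)
        m2 = np.sort(1.0 - f2.component_means)
        assert np.allclose(m1, m2, atol=5e-2)

    def test_ll2_never_below_ll1(self, rng):
        for i in range(20):
            levels = rng.beta(0.5 + i / 10, 2.0, 15)
            fit = fit_beta_mixture(levels, seed=i)
            assert fit.ll2 >= fit.ll1

    def test_responsibility_rows_sum_to_one(self, rng):
        fit = fit_beta_mixture(rng.beta(2, 2, 30), seed=0)
        assert np.allclose(fit.responsibilities.sum(axis=1), 1.0)


class TestBipolarityPvalue:
    def test_lrt_zero_gives_p_one(self):
        p, fit = bipolarity_pvalue(np.full(15, 0.5), seed=0)
        assert p == 1.0

    def test_well_separated_chi2_p_tiny(self, rng):
        levels = np.concatenate([rng.beta(20, 1, 10), rng.beta(1, 20, 10)])
        fit = fit_beta_mixture(levels, seed=1)
        assert lrt_pvalue(fit, method="chi2") < 1e-6

    def test_well_separated_bootstrap_p_at_floor(self, rng):
        levels = np.concatenate([rng.beta(20, 1, 10), rng.beta(1, 20, 10)])
        x = rng.binomial(4, levels) / 4
        p, _ = bipolarity_pvalue(x, seed=1, discretize=4)
        assert p <= 1.0 / 201 + 1e-12

    def test_p_in_unit_interval(self, rng):
        for i in range(10):
            p, _ = bipolarity_pvalue(rng.beta(1, 3, 12), seed=i)
            assert 0.0 < p <= 1.0

    def test_subset_orientation_invariant(self, rng):
        levels = np.concatenate([rng.beta(8, 2, 12), rng.beta(2, 8, 12)])
        fit = fit_beta_mixture(levels, seed=2)
        _, _, mu_lo, mu_hi, diff = assign_subsets(fit, levels)
        assert mu_lo <= mu_hi and diff == pytest.approx(mu_hi - mu_lo)


class TestCallPcsm:
    def _mixed_profiles(self, rng, n_bipolar=12, n_uni=30):
        profiles = []
        pos0 = 100
        for i in range(n_bipolar):
            lv = np.concatenate([rng.beta(20, 1, 10), rng.beta(1, 20, 10)])
            pats = ["".join(str(b) for b in rng.binomial(1, l, 4)) for l in lv]
            counts = {}
            for p in pats:
                counts[p] = counts.get(p, 0) + 1
            profiles.append(profile_from_counts(
                counts, pos=(pos0, pos0 + 10, pos0 + 20, pos0 + 30)))
            pos0 += 200
        for i in range(n_uni):
            lv = rng.beta(5, 5, 20)
            pats = ["".join(str(b) for b in rng.binomial(1, l, 4)) for l in lv]
            counts = {}
            for p in pats:
                counts[p] = counts.get(p, 0) + 1
            profiles.append(profile_from_counts(
                counts, pos=(pos0, pos0 + 10, pos0 + 20, pos0 + 30)))
            pos0 += 200
        return profiles

    def test_effect_floor_and_alpha_enforced(self, rng):
        profiles = self._mixed_profiles(rng)
        calls = call_pcsm(profiles, alpha=0.05, min_diff=0.30, seed=5)
        for c in calls:
            if c.is_pcsm:
                assert c.diff > 0.30 and c.p_adj < 0.05
            assert 0.0 <= c.mu_hypo <= c.mu_hyper <= 1.0
            assert c.p_adj >= c.p_raw - 1e-12

    def test_diff_above_threshold_but_large_p_rejected(self):
        # perfectly bipolar split of four units: large effect, weak evidence;
        # a strict alpha must veto the call despite diff = 1
        p = profile_from_counts({"1111": 2, "0000": 2})
        (c,) = call_pcsm([p], seed=0, alpha=0.01)
        assert c.diff == 1.0 and c.p_adj > 0.01 and not c.is_pcsm

    def test_bh_independent_of_input_order(self, rng):
        profiles = self._mixed_profiles(rng, n_bipolar=6, n_uni=10)
        calls_a = call_pcsm(profiles, seed=9)
        calls_b = call_pcsm(profiles[::-1], seed=9)
        pa = {str(c.key): c.p_adj for c in calls_a}
        pb = {str(c.key): c.p_adj for c in calls_b}
        assert pa == pb

    def test_bh_matches_manual_computation(self, rng):
        profiles = self._mixed_profiles(rng, n_bipolar=5, n_uni=8)
        calls = call_pcsm(profiles, seed=4)
        cand = [c for c in calls
                if str(c.key) in {str(p.key) for p in profiles if is_candidate(p)}]
        m = len(cand)
        order = np.argsort([c.p_raw for c in cand], kind="stable")
        praw = np.array([c.p_raw for c in cand])[order]
        padj_expected = np.minimum.accumulate((praw * m / np.arange(1, m + 1))[::-1])[::-1]
        padj_got = np.array([c.p_adj for c in cand])[order]
        assert np.allclose(padj_got, np.minimum(padj_expected, 1.0))


class TestBulkClustering:
    def test_perfectly_separated_patterns(self):
        p = profile_from_counts({"1111": 5, "0000": 5}, mode="bulk")
        labels = cluster_patterns_bulk(p, seed=0, n_sweeps=150, burn_in=30)
        lv = unit_levels(p)
        groups = {tuple(np.sort(lv[labels == c])) for c in np.unique(labels)}
        assert groups == {(0.0,) * 5, (1.0,) * 5}

    def test_bulk_call_diff_one(self):
        p = profile_from_counts({"1111": 5, "0000": 5}, mode="bulk")
        (c,) = call_pcsm([p], mode="bulk", seed=0, gibbs_sweeps=150,
                         gibbs_burn_in=30)
        assert c.diff == 1.0

    def test_planted_bulk_mixture_called_in_most_runs(self, rng):
        # 60/40 fully methylated vs unmethylated reads, n=20
        hits = 0
        runs = 100
        for s in range(runs):
            p = profile_from_counts({"1111": 12, "0000": 8}, mode="bulk")
            labels = cluster_patterns_bulk(p, seed=s, n_sweeps=120, burn_in=30)
            lv = unit_levels(p)
            means = [lv[labels == c].mean() for c in np.unique(labels)]
            if max(means) - min(means) >= 0.99:
                hits += 1
        assert hits >= 95

    def test_non_candidate_never_clustered(self):
        p = profile_from_counts({"0101": 10}, mode="bulk")
        (c,) = call_pcsm([p], mode="bulk", seed=0)
        assert c.p_raw == 1.0 and not c.is_pcsm


class TestSubsetDiffStats:
    def test_homogeneous_fully_methylated(self):
        p = profile_from_counts({"1111": 12})
        calls = call_pcsm([p], seed=0)
        stats = subset_diff_stats(calls)
        assert stats.loc[0, "mean_level"] == 1.0
        assert stats.loc[0, "diff"] == 0.0

    def test_bipolar_half_half(self):
        p = profile_from_counts({"1111": 5, "0000": 5})
        stats = subset_diff_stats(call_pcsm([p], seed=0))
        assert stats.loc[0, "mean_level"] == pytest.approx(0.5)
        assert stats.loc[0, "diff"] == pytest.approx(1.0)

    def test_matches_brute_force_recomputation(self, rng):
        profiles = []
        pos0 = 100
        for _ in range(10):
            lv = rng.beta(2, 2, 14)
            pats = ["".join(str(b) for b in rng.binomial(1, l, 4)) for l in lv]
            counts = {}
            for p in pats:
                counts[p] = counts.get(p, 0) + 1
            profiles.append(profile_from_counts(
                counts, pos=(pos0, pos0 + 10, pos0 + 20, pos0 + 30)))
            pos0 += 200
        calls = call_pcsm(profiles, seed=2)
        stats = subset_diff_stats(calls).set_index("segment")
        for c in calls:
            n_lo, n_hi = len(c.hypo_units), len(c.hyper_units)
            mean = (c.mu_hypo * n_lo + c.mu_hyper * n_hi) / (n_lo + n_hi)
            row = stats.loc[str(c.key)]
            assert row["mean_level"] == pytest.approx(mean)
            assert row["diff"] == pytest.approx(
                0.0 if n_lo == 0 or n_hi == 0 else c.mu_hyper - c.mu_hypo)


def test_segment_seed_stable_and_in_range():
    k = SegmentKey("chr3", (5, 10, 15, 20))
    assert segment_seed(k, 7) == segment_seed(k, 7)
    assert 0 <= segment_seed(k, 7) < 2 ** 31
    assert segment_seed(k, 7) != segment_seed(k, 8)
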
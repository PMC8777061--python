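import itertools

import numpy as np
import pandas as pd
import pytest

from gmqn.errors import ValidationError
from gmqn.evalsuite import (
    adjacent_pair_difference,
    case_control_consistency,
    covariate_correlation,
    replicate_variance,
    select_adjacent_pairs,
    select_random_pairs,
)
from gmqn.simulate import SimulationConfig, simulate_dataset


class TestReplicateVariance:
    def test_identical_replicates_have_zero_variance(self):
        beta = pd.DataFrame(
            {"a": [0.3, 0.8], "b": [0.3, 0.8], "c": [0.3, 0.8]}, index=["cg0", "cg1"]
        )
        res = replicate_variance(beta, [0, 0, 0])
        assert res.mean_variance == pytest.approx(0.0, abs=1e-16)

    def test_hand_computed_two_sample_variance(self):
        # var({0.2, 0.4}) with n-1 denominator = 0.02
        beta = pd.DataFrame({"a": [0.2], "b": [0.4]}, index=["cg0"])
        res = replicate_variance(beta, [0, 0])
        assert res.per_probe["cg0"] == pytest.approx(0.02)

    def test_singleton_groups_excluded(self):
        beta = pd.DataFrame(
            {"a": [0.2], "b": [0.4], "c": [0.9]}, index=["cg0"]
        )
        res = replicate_variance(beta, [0, 0, 1])
        assert res.n_groups == 1 and res.n_excluded_groups == 1
        assert res.per_probe["cg0"] == pytest.approx(0.02)
        with pytest.raises(ValidationError):
            replicate_variance(beta, [0, 1, 2])


class TestCaseControl:
    @staticmethod
    def _matrix(rng, n_probes=400, n_per_group=12, n_diff=20, delta=0.2):
        base = rng.uniform(0.2, 0.8, n_probes)
        beta = np.clip(
            base[:, None] + rng.normal(0, 0.02, (n_probes, 2 * n_per_group)), 0, 1
        )
        beta[:n_diff, :n_per_group] = np.clip(beta[:n_diff, :n_per_group] + delta, 0, 1)
        cols = [f"S{i}" for i in range(2 * n_per_group)]
        labels = ["case"] * n_per_group + ["control"] * n_per_group
        return (
            pd.DataFrame(beta, index=[f"cg{i}" for i in range(n_probes)], columns=cols),
            pd.Series(labels, index=cols),
        )

    def test_identical_train_and_test_sets_give_auc_one(self, rng):
        beta, labels = self._matrix(rng)
        cols = list(beta.columns)
        res = case_control_consistency(beta, labels, split=(cols, cols))
        assert res.auc == 1.0
        assert res.n_gold_positive > 0

    def test_auc_matches_pairwise_comparison_oracle(self, rng):
        beta, labels = self._matrix(rng, n_probes=200, n_diff=15)
        res = case_control_consistency(beta, labels, seed=11)
        # recompute gold/scores exactly as documented, then brute-force AUC
        from scipy import stats
        from statsmodels.stats.multitest import multipletests

        train, test = res.train_samples, res.test_samples

        def pvals(cols):
            case = [c for c in cols if labels[c] == "case"]
            ctrl = [c for c in cols if labels[c] == "control"]
            return stats.ttest_ind(
                beta[case], beta[ctrl], axis=1, equal_var=False
            ).pvalue

        gold = multipletests(pvals(train), alpha=0.05, method="fdr_bh")[0]
        score = -np.log10(np.maximum(pvals(test), 1e-300))
        pos, neg = score[gold], score[~gold]
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p, n in itertools.product(pos, neg)
        )
        assert res.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_degenerate_designs_rejected(self, rng):
        beta, labels = self._matrix(rng, n_per_group=3)
        with pytest.raises(ValidationError):
            case_control_consistency(beta, labels)


class TestCovariate:
    def test_exactly_linear_probe_has_r_one(self):
        cov = np.linspace(20, 80, 12)
        beta = pd.DataFrame(
            {"probe": 0.2 + 0.005 * cov}, index=[f"S{i}" for i in range(12)]
        ).T
        res = covariate_correlation(beta, cov)
        assert res.r["probe"] == pytest.approx(1.0)
        assert res.counts[0.7] == 1

    def test_null_probes_rarely_exceed_point_three(self, rng):
        n = 100
        cov = rng.uniform(0, 1, n)
        beta = pd.DataFrame(
            rng.uniform(0, 1, (500, n)), columns=[f"S{i}" for i in range(n)]
        )
        res = covariate_correlation(beta, cov)
        assert float((res.r.abs() >= 0.3).mean()) < 0.02

    def test_zero_variance_probe_excluded_from_counts(self):
        cov = np.arange(12, dtype=float)
        beta = pd.DataFrame(
            [np.full(12, 0.5), 0.01 * cov + 0.2], columns=[f"S{i}" for i in range(12)]
        )
        res = covariate_correlation(beta, cov)
        assert res.n_excluded == 1
        assert res.counts[0.7] == 1


class TestAdjacentPairs:
    def test_self_pairs_have_zero_difference(self):
        beta = pd.DataFrame({"s": [0.1, 0.9]}, index=["cg0", "cg1"])
        res = adjacent_pair_difference(beta, [("cg0", "cg0")], [("cg0", "cg1")])
        assert res.adjacent_mean == 0.0
        assert res.random_mean == pytest.approx(0.8)
        assert res.ratio == 0.0

    def test_pair_with_unknown_probe_skipped_and_counted(self):
        beta = pd.DataFrame({"s": [0.1, 0.9]}, index=["cg0", "cg1"])
        res = adjacent_pair_difference(
            beta, [("cg0", "cg1"), ("cg0", "cgMISSING")], [("cg0", "cg1")]
        )
        assert res.n_skipped_pairs == 1

    def test_random_pairs_match_analytic_mixture_difference(self):
        """Noiseless independent beta draws vs quadrature E|X - Y|."""
        cfg = SimulationConfig(
            n_samples=1, seed=9, background_sd=0.0, type2_bias=0.0,
            n_probes_type1_red=3000, n_probes_type1_green=3000, n_probes_type2=0,
        )
        samples, ann, truth = simulate_dataset(cfg)
        beta = truth.true_beta
        pairs = select_random_pairs(ann, 3000, seed=1)
        res = adjacent_pair_difference(beta, pairs, pairs)
        # analytic: E|X-Y| for the generating mixture, by quadrature
        from scipy.stats import beta as beta_dist

        grid = np.linspace(1e-6, 1 - 1e-6, 2001)
        pdf = sum(
            w * beta_dist.pdf(grid, a, b)
            for w, (a, b) in zip(cfg.beta_weights, cfg.beta_shapes)
        )
        pdf /= np.trapezoid(pdf, grid)
        diff = np.abs(grid[:, None] - grid[None, :])
        joint = pdf[:, None] * pdf[None, :]
        expected = float(
            np.trapezoid(np.trapezoid(diff * joint, grid, axis=1), grid)
        )
        assert res.random_mean == pytest.approx(expected, rel=0.05)


class TestSelectAdjacentPairs:
    def test_strict_distance_threshold(self, tiny_annotation):
        pairs = select_adjacent_pairs(tiny_annotation, max_distance=10)
        assert pairs == [("cgA", "cgB")]  # 100 vs 105 pairs; 500 vs 1500 does not
        ann = tiny_annotation.copy()
        ann.loc["cgB", "position"] = 110
        assert select_adjacent_pairs(ann, max_distance=10) == []

    def test_matches_brute_force_enumeration(self, rng):
        n = 20
        ann = pd.DataFrame(
            {
                "chromosome": rng.choice(["chr1", "chr2"], n),
                "position": rng.integers(0, 60, n),
            },
            index=pd.Index([f"cg{i:02d}" for i in range(n)], name="probe_id"),
        )
        got = select_adjacent_pairs(ann, max_distance=10)
        # oracle: enumerate candidates, take greedily in leftmost order
        used, expected = set(), []
        ordered = ann.sort_values(["chromosome", "position"], kind="stable")
        cands = [
            (a, b)
            for (a, ra), (b, rb) in itertools.combinations(ordered.iterrows(), 2)
            if ra["chromosome"] == rb["chromosome"]
            and abs(int(ra["position"]) - int(rb["position"])) < 10
        ]
        for a, b in cands:
            if a not in used and b not in used:
                expected.append((a, b))
                used.update((a, b))
        assert sorted(got) == sorted(expected)
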
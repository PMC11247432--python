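"""Metrics: accuracy/kappa, KS/KL similarity, Wilcoxon, repeated runs."""

import itertools

import numpy as np
import pytest

from eeggan import (
    EEGEpochs,
    accuracy_and_kappa,
    kl_divergence,
    ks_similarity,
    repeated_runs,
    similarity_report,
    wilcoxon_signed_rank,
)


class TestAccuracyKappa:
    def test_perfect_agreement(self):
        y = np.array([0, 1, 2, 3, 0, 1])
        assert accuracy_and_kappa(y, y, 4) == (1.0, 1.0)

    def test_contingency_hand_value(self):
        """Table [[30,10],[10,50]]: acc 0.8, p_e 0.52, kappa 0.28/0.48."""
        true = np.array([0] * 40 + [1] * 60)
        pred = np.concatenate([
            np.zeros(30), np.ones(10),  # true 0
            np.zeros(10), np.ones(50),  # true 1
        ]).astype(int)
        acc, kappa = accuracy_and_kappa(pred, true, 2)
        assert np.isclose(acc, 0.8)
        assert np.isclose(kappa, (0.8 - 0.52) / 0.48)

    def test_random_predictions_near_zero_kappa(self, rng):
        true = np.repeat(np.arange(4), 500)
        pred = rng.integers(0, 4, size=2000)
        _, kappa = accuracy_and_kappa(pred, true, 4)
        assert abs(kappa) < 0.05

    def test_degenerate_agreement_warns(self, caplog):
        y = np.zeros(5, dtype=int)
        with caplog.at_level("WARNING", logger="eeggan"):
            acc, kappa = accuracy_and_kappa(y, y, 2)
        assert acc == 1.0 and kappa == 0.0


class TestKsSimilarity:
    def test_identical_samples(self, rng):
        x = rng.normal(size=500)
        assert ks_similarity(x, x) == 1.0

    def test_disjoint_supports(self, rng):
        assert ks_similarity(rng.uniform(0, 1, 100), rng.uniform(5, 6, 100)) == 0.0

    def test_matches_brute_force_cdf_oracle(self, rng):
        a = rng.normal(size=37)
        b = rng.normal(loc=0.7, size=53)
        # brute force: evaluate both empirical CDFs at every pooled point
        pooled = np.concatenate([a, b])
        d = max(
            abs((a <= v).mean() - (b <= v).mean()) for v in pooled
        )
        assert np.isclose(ks_similarity(a, b), 1.0 - d)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=40), rng.normal(loc=1, size=60)
        assert np.isclose(ks_similarity(a, b), ks_similarity(b, a))


class TestKlDivergence:
    def test_identical_within_smoothing(self, rng):
        x = rng.normal(size=1000)
        assert kl_divergence(x, x) < 1e-9

    def test_nonnegative_property_sweep(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = r.normal(loc=r.uniform(-1, 1), size=200)
            b = r.normal(loc=r.uniform(-1, 1), scale=r.uniform(0.5, 2), size=200)
            assert kl_divergence(a, b) >= 0.0

    def test_three_bin_hand_value(self):
        # counts (2,1,1) vs (1,1,2) on 3 equal bins of [0, 1):
        # p=(.5,.25,.25), q=(.25,.25,.5) -> KL = .5 ln2 - .25 ln2
        real = [0.1, 0.2, 0.5, 0.99]
        gen = [0.1, 0.5, 0.8, 0.99]
        expected = 0.5 * np.log(2) - 0.25 * np.log(2)
        assert np.isclose(kl_divergence(real, gen, n_bins=3), expected, atol=1e-6)

    def test_asymmetric_in_general(self, rng):
        a = rng.normal(size=500)
        b = rng.normal(scale=3.0, size=500)
        assert not np.isclose(kl_divergence(a, b), kl_divergence(b, a))


class TestSimilarityReport:
    def test_identical_epochs_score_one(self, rng):
        ep = EEGEpochs(rng.normal(size=(8, 2, 50)), np.array([0, 1] * 4),
                       250.0, ["a", "b"], 2)
        rep = similarity_report(ep, ep)
        assert rep.ks_score == 1.0 and rep.ks_d == 0.0
        assert rep.kl_divergence < 1e-9

    def test_shifted_distribution_scores_lower(self, rng):
        ep = EEGEpochs(rng.normal(size=(8, 2, 50)), np.array([0, 1] * 4),
                       250.0, ["a", "b"], 2)
        shifted = EEGEpochs(ep.data + 2.0, ep.labels, ep.fs, ep.channel_names, 2)
        rep = similarity_report(ep, shifted)
        assert rep.ks_score < 0.5
        assert rep.kl_divergence > 0.5


class TestWilcoxon:
    def test_identical_pairs(self, caplog):
        with caplog.at_level("WARNING", logger="eeggan"):
            p = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_six_positive_differences_one_sided(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a - np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        assert np.isclose(wilcoxon_signed_rank(a, b, alternative="greater"), 1 / 64)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exact_enumeration(self, seed):
        """Exact p for r<=10 equals brute-force enumeration of sign patterns."""
        r = np.random.default_rng(seed)
        n = 8
        diffs = np.round(r.normal(size=n), 3)
        while (diffs == 0).any() or len(set(np.abs(diffs))) < n:
            diffs = np.round(r.normal(size=n), 3)
        a = np.zeros(n) + diffs
        b = np.zeros(n)
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        w_plus = ranks[diffs > 0].sum()
        # null: every sign pattern equally likely
        stats = [
            sum(rk for rk, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)
        ]
        stats = np.array(stats)
        p_greater = (stats >= w_plus).mean()
        assert np.isclose(
            wilcoxon_signed_rank(a, b, alternative="greater"), p_greater, atol=1e-12
        )


class TestRepeatedRuns:
    def test_single_run_best_equals_mean(self):
        summary = repeated_runs(lambda s: {"accuracy": 0.8, "kappa": 0.6}, [1])
        assert summary.best_accuracy == summary.mean_accuracy == 0.8

    def test_deterministic_given_seed_list(self):
        fn = lambda s: {"accuracy": (s * 37 % 11) / 11, "kappa": 0.0}
        a = repeated_runs(fn, [1, 2, 3])
        b = repeated_runs(fn, [1, 2, 3])
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_best_at_least_mean(self, rng):
        fn = lambda s: {"accuracy": float(np.random.default_rng(s).random()),
                        "kappa": 0.0}
        summary = repeated_runs(fn, list(range(10)))
        assert summary.best_accuracy >= summary.mean_accuracy
        assert summary.best_kappa >= summary.mean_kappa

    def test_failed_run_excluded_and_reported(self, caplog):
        def fn(s):
            if s == 2:
                raise RuntimeError("boom")
            return {"accuracy": 0.5, "kappa": 0.1}

        with caplog.at_level("ERROR", logger="eeggan"):
            summary = repeated_runs(fn, [1, 2, 3])
        assert summary.failed_seeds == [2]
        assert len(summary.accuracies) == 2
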
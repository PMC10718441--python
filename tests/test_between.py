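"""Between-scales histograms, binomial tails and significance profiles."""
import math

import numpy as np
import pytest
from scipy import stats

from scalestats import (
    BetweenConfig,
    balanced_subsample,
    binomial_tail_test,
    empirical_bin_probabilities,
    fit_lognormal,
    interval_histogram,
    lognorm_bin_probabilities,
    sample_lognorm_scales,
    significance_profile,
)
from scalestats.between import bin_centers_for
from scalestats.corpus import Corpus
from scalestats.nulls import Layout, LognormParams
from scalestats.errors import DomainError
from tests.test_corpus_io import make_record


class TestBalancedSubsample:
    def make_corpus(self, sizes):
        records = []
        for s, n in enumerate(sizes):
            for j in range(n):
                records.append(
                    make_record(
                        scale_id=f"s{s}_{j}",
                        society_id=f"soc{s}",
                        notes=(0.0, 200.0, 700.0, 1200.0),
                    )
                )
        return Corpus(records=records)

    def test_cap_enforced(self):
        corpus = self.make_corpus([12])
        sub = balanced_subsample(corpus, 5, seed=0)
        assert len(sub) == 5

    def test_small_societies_kept_whole(self):
        corpus = self.make_corpus([3])
        assert len(balanced_subsample(corpus, 5, seed=0)) == 3

    def test_count_arithmetic(self):
        corpus = self.make_corpus([10] * 30)
        assert len(balanced_subsample(corpus, 5, seed=1)) == 150

    def test_cap_respected_across_resamples(self, default_corpus):
        for seed in range(10):
            sub = balanced_subsample(default_corpus, 3, seed=seed)
            assert max(len(v) for v in sub.society_index.values()) <= 3


class TestIntervalHistogram:
    def test_bin_edges_centered(self):
        centers, counts = interval_histogram([1200.0, 1200.0, 700.0], 30.0, (0, 2700))
        assert counts[np.where(centers == 1200.0)[0][0]] == 2
        # 700 lies in [675, 705) whose center is 690
        assert counts[np.where(centers == 690.0)[0][0]] == 1
        assert counts.sum() == 3

    def test_empty_values(self):
        _, counts = interval_histogram([], 30.0, (0, 2700))
        assert counts.sum() == 0

    def test_total_conserved(self, rng):
        values = rng.uniform(20, 2600, 500)
        _, counts = interval_histogram(values, 30.0, (0, 2700))
        assert counts.sum() == 500


class TestLognormBinProbabilities:
    def test_whole_axis_sums_to_one(self):
        params = LognormParams(mu=np.log(600.0), sigma=0.5)
        p = lognorm_bin_probabilities(params, np.array([50_000.0]), 100_000.0)
        assert p[0] == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_cross_check(self, rng):
        params = LognormParams(mu=np.log(600.0), sigma=0.5)
        p = lognorm_bin_probabilities(params, np.array([600.0]), 30.0)[0]
        draws = rng.lognormal(params.mu, params.sigma, 1_000_000)
        hits = np.mean((draws >= 585.0) & (draws < 615.0))
        se = np.sqrt(p * (1 - p) / 1_000_000)
        assert abs(hits - p) < 4 * se

    def test_degenerate_sigma_rejected(self):
        with pytest.raises(DomainError):
            lognorm_bin_probabilities(
                LognormParams(mu=6.0, sigma=0.0), np.array([600.0]), 30.0
            )

    def test_probabilities_sum_over_range(self):
        params = LognormParams(mu=np.log(700.0), sigma=0.6)
        centers = bin_centers_for(30.0, (0.0, 2700.0))
        p = lognorm_bin_probabilities(params, centers, 30.0)
        expected = stats.norm.cdf((np.log(2715.0) - params.mu) / params.sigma)
        assert p.sum() == pytest.approx(expected, abs=1e-9)


class TestBinomialTail:
    @pytest.mark.parametrize(
        "k,n,p,expected,direction",
        [
            (10, 10, 0.5, 0.5**10, "more"),
            (0, 5, 0.2, 0.8**5, "less"),
            (5, 5, 1.0, 1.0, "less"),
        ],
    )
    def test_closed_forms(self, k, n, p, expected, direction):
        q, d = binomial_tail_test(k, n, p)
        assert q == pytest.approx(expected, abs=1e-12)
        assert d == direction

    def test_matches_exhaustive_pmf_summation(self):
        for n in range(1, 13):
            for p in np.arange(0.1, 0.95, 0.1):
                pmf = np.array(
                    [
                        math.comb(n, j) * p**j * (1 - p) ** (n - j)
                        for j in range(n + 1)
                    ]
                )
                for k in range(n + 1):
                    q, d = binomial_tail_test(k, n, p)
                    if k / n > p:
                        assert d == "more"
                        assert q == pytest.approx(pmf[k:].sum(), abs=1e-10)
                    else:
                        assert d == "less"
                        assert q == pytest.approx(pmf[: k + 1].sum(), abs=1e-10)

    def test_tails_sum_to_one_plus_pmf(self):
        k, n, p = 4, 11, 0.3
        upper = stats.binom.sf(k - 1, n, p)
        lower = stats.binom.cdf(k, n, p)
        assert upper + lower == pytest.approx(1 + stats.binom.pmf(k, n, p))


class TestEmpiricalProbabilities:
    def test_shuffle_identity_on_equidistant_corpus(self):
        records = [
            make_record(scale_id=f"e{i}", society_id=f"soc{i}",
                        notes=tuple(np.arange(6) * 240.0))
            for i in range(10)
        ]
        corpus = Corpus(records=records)
        centers = bin_centers_for(30.0, (0.0, 1300.0))
        p = empirical_bin_probabilities(
            "shuffle", corpus, centers, 30.0, (0.0, 1300.0), n_sets=5, seed=0
        )
        _, counts = interval_histogram(corpus.all_notes(), 30.0, (0.0, 1300.0))
        assert np.allclose(p, counts / counts.sum())

    def test_probabilities_sum_to_one(self, measured_corpus):
        centers = bin_centers_for(30.0, (0.0, 4000.0))
        p = empirical_bin_probabilities(
            "resample", measured_corpus, centers, 30.0, (0.0, 4000.0),
            n_sets=20, seed=1,
        )
        assert p.sum() == pytest.approx(1.0, abs=0.01)


class TestSignificanceProfile:
    def test_lognorm_self_consistency(self):
        # a corpus drawn from a lognormal should produce no significant bins
        params = LognormParams(mu=np.log(700.0), sigma=0.55)
        hits = 0
        for seed in range(5):
            corpus = sample_lognorm_scales(params, Layout(tuple([6] * 150)), seed=seed)
            prof = significance_profile(
                corpus,
                "lognorm",
                BetweenConfig(n_resamples=50, n_bootstrap=50),
                seed=seed,
            )
            hits += prof.significant().size > 0
        assert hits <= 1

    def test_directions_follow_proportions(self, measured_corpus):
        prof = significance_profile(
            measured_corpus,
            "lognorm",
            BetweenConfig(n_resamples=50, n_bootstrap=50),
            seed=3,
        )
        assert prof.k.sum() == prof.n
        obs = prof.k / prof.n
        more = prof.direction == "more"
        assert np.all(obs[more] > prof.p[more])
        assert np.all(obs[~more] <= prof.p[~more])
        assert np.all((prof.q_tail >= 0) & (prof.q_tail <= 1))

    def test_shuffle_model_runs(self, measured_corpus):
        prof = significance_profile(
            measured_corpus,
            "shuffle",
            BetweenConfig(n_resamples=30, n_model_sets=100, n_bootstrap=30),
            seed=4,
        )
        assert prof.model == "shuffle"
        assert prof.alpha_bonferroni == pytest.approx(0.05 / prof.bin_centers.size)
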
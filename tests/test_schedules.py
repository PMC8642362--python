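"""Schedule generators: Poisson draws, PG walks, random sampling, gap stats, I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st_h
from scipy import stats

from nusclust import (
    GapModulation,
    Grid,
    Schedule,
    draw_poisson,
    ensemble_stats,
    gap_sizes,
    generate_poisson_gap,
    generate_poisson_gap_2d,
    generate_random,
    make_schedule,
    read_schedule,
    reciprocal_quarter_sine_weights,
    write_schedule,
)
from nusclust.schedules import SCHEMES, ScheduleError


class TestDrawPoisson:
    def test_zero_rate_is_degenerate_at_zero(self):
        rng = np.random.default_rng(0)
        assert all(draw_poisson(0.0, rng) == 0 for _ in range(100))

    def test_negative_rate_rejected(self):
        with pytest.raises(ScheduleError):
            draw_poisson(-1.0, np.random.default_rng(0))

    def test_pmf_at_zero_for_unit_rate(self):
        # Pr(X=0) = exp(-1); Monte-Carlo check within 3 binomial sigma
        rng = np.random.default_rng(1)
        n = 30_000
        draws = np.array([draw_poisson(1.0, rng) for _ in range(n)])
        p0 = np.mean(draws == 0)
        target = np.exp(-1.0)
        sigma = np.sqrt(target * (1 - target) / n)
        assert abs(p0 - target) < 3 * sigma

    def test_mean_and_variance_equal_rate(self):
        rng = np.random.default_rng(2)
        lam, n = 4.0, 30_000
        draws = np.array([draw_poisson(lam, rng) for _ in range(n)])
        sigma_mean = np.sqrt(lam / n)
        # var of the sample variance of a Poisson: (lam + 2*lam^2)/n
        sigma_var = np.sqrt((lam + 2 * lam**2) / n)
        assert abs(draws.mean() - lam) < 3 * sigma_mean
        assert abs(draws.var() - lam) < 3 * sigma_var


class TestPoissonGap:
    @pytest.mark.parametrize("kind", ["none", "quarter_sine", "half_sine", "exponential"])
    @pytest.mark.parametrize("m", [1, 13, 64, 200, 256])
    def test_invariants(self, grid256, kind, m):
        s = generate_poisson_gap(grid256, m, kind, seed=7)
        assert s.m == m
        assert s.indices[0] == 0
        assert len(set(s.indices)) == m
        assert list(s.indices) == sorted(s.indices)
        assert s.indices[-1] <= 255

    def test_deterministic_given_seed(self, grid256):
        a = generate_poisson_gap(grid256, 64, "quarter_sine", seed=123)
        b = generate_poisson_gap(grid256, 64, "quarter_sine", seed=123)
        c = generate_poisson_gap(grid256, 64, "quarter_sine", seed=124)
        assert a.indices == b.indices
        assert a.indices != c.indices

    def test_full_sampling_has_zero_gaps(self, grid256):
        s = generate_poisson_gap(grid256, 256, "half_sine", seed=0)
        assert s.indices == tuple(range(256))
        assert np.all(gap_sizes(s) == 0)

    def test_m_out_of_range(self, grid256):
        with pytest.raises(ScheduleError):
            generate_poisson_gap(grid256, 257, "none", seed=0)
        with pytest.raises(ScheduleError):
            generate_poisson_gap(grid256, 0, "none", seed=0)

    def test_pooled_gaps_follow_poisson_shape(self, grid256):
        # Unmodulated PG gaps pooled over an ensemble fit Pois(lam_hat) by
        # chi-square GOF.  500 schedules: enough power for the shape while
        # the exact-m conditioning bias (variance deficit ~1/(m-1)) stays
        # below detection.
        ens = [generate_poisson_gap(grid256, 64, "none", seed=s) for s in range(500)]
        counts = ensemble_stats(ens).histogram.counts
        lam_hat = (np.arange(counts.size) * counts).sum() / counts.sum()
        k = min(16, counts.size)
        obs = counts[:k]
        pmf = stats.poisson.pmf(np.arange(k), lam_hat)
        expected = pmf / pmf.sum() * obs.sum()
        chi2 = ((obs - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, k - 2)  # one df lost to the fitted mean
        assert p > 0.01

    def test_mean_gap_matches_sampling_level(self, grid256):
        # E[gap] = (n-m)/m for unmodulated PG
        gaps = np.concatenate(
            [gap_sizes(generate_poisson_gap(grid256, 64, "none", seed=s)) for s in range(100)]
        )
        assert abs(gaps.mean() - 3.0) < 0.1

    def test_high_sampling_levels_match_random_gap_distribution(self, grid256):
        # Above ~50% sampling PG and unweighted random gap distributions are
        # indistinguishable (KS < 0.05 on 25-schedule pooled histograms).
        for m in (192, 224):
            pg = ensemble_stats(
                [generate_poisson_gap(grid256, m, "none", seed=s) for s in range(25)]
            ).histogram.counts.astype(float)
            rnd = ensemble_stats(
                [generate_random(grid256, m, seed=s) for s in range(25)]
            ).histogram.counts.astype(float)
            size = max(pg.size, rnd.size)
            cdf_pg = np.pad(pg, (0, size - pg.size)).cumsum() / pg.sum()
            cdf_rnd = np.pad(rnd, (0, size - rnd.size)).cumsum() / rnd.sum()
            assert np.abs(cdf_pg - cdf_rnd).max() < 0.05


class TestRandom:
    def test_full_grid_regardless_of_weights(self, grid256):
        w = reciprocal_quarter_sine_weights(256)
        s = generate_random(grid256, 256, weights=w, seed=0)
        assert s.indices == tuple(range(256))

    def test_uniform_density_is_flat(self, grid256):
        n_seeds = 3000
        counts = ensemble_stats(
            [generate_random(grid256, 64, seed=s) for s in range(n_seeds)]
        ).selection_counts
        p = 63 / 255  # index 0 forced; others uniform
        sigma = np.sqrt(p * (1 - p) * n_seeds)
        z = (counts[1:] - p * n_seeds) / sigma
        assert counts[0] == n_seeds
        # family-wise bound over 255 bins plus an aggregate chi-square check
        assert np.abs(z).max() < 5.5
        assert stats.chi2.sf((z**2).sum(), 255) > 1e-4

    def test_insufficient_positive_weights(self, grid256):
        w = np.zeros(256)
        w[1:5] = 1.0
        with pytest.raises(ScheduleError, match="positive weights"):
            generate_random(grid256, 10, weights=w, seed=0)

    def test_invalid_weights(self, grid256):
        w = np.ones(256)
        w[3] = -1.0
        with pytest.raises(ScheduleError):
            generate_random(grid256, 10, weights=w, seed=0)
        with pytest.raises(ScheduleError):
            generate_random(grid256, 10, weights=np.ones(100), seed=0)


class TestGapsAndEnsembles:
    def test_gap_sizes_examples(self):
        g = Grid((8,))
        assert list(gap_sizes(Schedule(g, (0, 1, 2, 3)))) == [0, 0, 0]
        assert list(gap_sizes(Schedule(g, (0, 4, 5)))) == [3, 0]
        assert np.all(gap_sizes(Schedule(g, tuple(range(8)))) == 0)

    def test_gap_sizes_rejects_2d(self):
        s = Schedule(Grid((4, 4)), ((0, 0), (1, 2)))
        with pytest.raises(ScheduleError):
            gap_sizes(s)

    def test_single_full_schedule_stats(self):
        g = Grid((16,))
        stats_ = ensemble_stats([Schedule(g, tuple(range(16)))])
        assert stats_.histogram.counts[0] == 15
        assert stats_.histogram.counts.sum() == 15
        assert np.all(stats_.selection_counts == 1)

    def test_zeroth_increment_always_selected(self, grid256):
        ens = [make_schedule(sch, grid256, 32, seed=s) for sch in SCHEMES for s in range(5)]
        counts = ensemble_stats(ens).selection_counts
        assert counts[0] == len(ens)

    def test_mixed_grids_rejected(self):
        a = Schedule(Grid((8,)), (0, 1))
        b = Schedule(Grid((16,)), (0, 1))
        with pytest.raises(ScheduleError):
            ensemble_stats([a, b])
        with pytest.raises(ScheduleError):
            ensemble_stats([])


class TestScheduleIO:
    def test_roundtrip(self):
        g = Grid((8,))
        s = Schedule(g, (0, 4, 5))
        text = write_schedule(s)
        assert text == "0\n4\n5\n"
        assert read_schedule(text, g).indices == (0, 4, 5)

    def test_read_normalizes_order(self):
        assert read_schedule("5\n0\n4\n", Grid((8,))).indices == (0, 4, 5)

    def test_read_errors_name_line(self):
        g = Grid((8,))
        with pytest.raises(ScheduleError, match="line 2"):
            read_schedule("0\n0\n4\n", g)
        with pytest.raises(ScheduleError, match="line 3"):
            read_schedule("0\n4\n9\n", g)
        with pytest.raises(ScheduleError, match="line 1"):
            read_schedule("0 1\n", g)

    def test_2d_roundtrip(self):
        g = Grid((4, 6))
        s = Schedule(g, ((0, 0), (1, 3), (3, 5)))
        text = write_schedule(s)
        assert read_schedule(text, g).indices == s.indices


class TestPoissonGap2D:
    def test_full_grid(self):
        g = Grid((4, 5))
        s = generate_poisson_gap_2d(g, 20, "none", seed=0)
        assert len(s.indices) == 20
        assert len(set(s.indices)) == 20

    def test_unique_and_origin_included(self):
        g = Grid((55, 75))
        for seed in range(3):
            s = generate_poisson_gap_2d(g, 300, "quarter_sine", seed=seed)
            assert s.m == 300
            assert len(set(s.indices)) == 300
            assert (0, 0) in s.indices

    def test_density_decays_along_antidiagonals(self):
        g = Grid((55, 75))
        full_mean = np.mean([i + j for i in range(55) for j in range(75)])
        sampled = [
            np.mean([i + j for i, j in generate_poisson_gap_2d(g, 300, "quarter_sine", s).indices])
            for s in range(10)
        ]
        assert np.mean(sampled) < full_mean

    def test_m_out_of_range(self):
        with pytest.raises(ScheduleError):
            generate_poisson_gap_2d(Grid((4, 4)), 17, "none", seed=0)


class TestModulation:
    def test_profiles_in_unit_interval(self):
        for kind in ("none", "quarter_sine", "half_sine", "exponential"):
            f = GapModulation(kind).profile(255)
            assert np.all(f > 0) and np.all(f <= 1)

    def test_none_is_identity(self):
        assert np.all(GapModulation("none").profile(10) == 1.0)

    def test_exponential_density_decays(self, grid256):
        # exponential gap growth -> decaying sampling density
        counts = ensemble_stats(
            [generate_poisson_gap(grid256, 64, "exponential", seed=s) for s in range(200)]
        ).selection_counts
        assert counts[1:40].mean() > 2 * counts[200:].mean()

    def test_unknown_kind(self):
        with pytest.raises(ScheduleError):
            GapModulation("sawtooth")


@given(
    n=st_h.integers(min_value=4, max_value=64),
    frac=st_h.floats(min_value=0.1, max_value=1.0),
    scheme=st_h.sampled_from(SCHEMES),
    seed=st_h.integers(min_value=0, max_value=2**20),
)
def test_any_generated_schedule_satisfies_invariants(n, frac, scheme, seed):
    """Every generator, any parameters: 0 included, unique, exactly m points."""
    m = max(1, int(round(frac * n)))
    s = make_schedule(scheme, Grid((n,)), m, seed)
    assert s.m == m
    assert s.indices[0] == 0
    assert len(set(s.indices)) == m
    assert all(0 <= i < n for i in s.indices)
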
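import numpy as np
import pytest
from scipy import stats as sps

import recsim as rs
from recsim.meiosis import InterferenceFallbackWarning

from conftest import degenerate_count_dist


class TestCountDistribution:
    def test_renormalized_defaults(self):
        d = rs.renormalize_count_dist((0.16, 0.30, 0.23, 0.15))
        np.testing.assert_allclose(
            d.p, np.array([0.16, 0.30, 0.23, 0.15]) / 0.84)
        # frozen: (0.30 + 2*0.23 + 3*0.15) / 0.84
        assert d.mean == pytest.approx(1.4404761904761905, abs=1e-12)

    def test_degenerate_and_identity_cases(self):
        assert rs.renormalize_count_dist((1, 0, 0, 0)).mean == 0.0
        d = rs.renormalize_count_dist((0.25, 0.25, 0.25, 0.25))
        np.testing.assert_allclose(d.p, [0.25] * 4)

    @pytest.mark.parametrize("raw", [(0, 0, 0, 0), (-0.1, 0.5, 0.3, 0.1),
                                     (0.5, 0.5, 0.5, 0.5)])
    def test_invalid_raw_rejected(self, raw):
        with pytest.raises(ValueError):
            rs.renormalize_count_dist(raw)

    def test_degenerate_sampler(self):
        d = degenerate_count_dist(2)
        rng = np.random.default_rng(0)
        assert all(rs.sample_crossover_count(d, rng) == 2 for _ in range(100))

    def test_empirical_frequencies_recover_parameters(self):
        d = rs.CrossoverCountDistribution.from_raw()
        rng = np.random.default_rng(123)
        draws = d.sample(rng, size=100_000)
        # frozen oracle: 0.30 / 0.84 = 0.357142...
        assert np.mean(draws == 1) == pytest.approx(0.30 / 0.84, abs=0.005)
        assert draws.mean() == pytest.approx(d.mean, abs=0.01)


class TestCrossoverPositions:
    def test_zero_count_gives_empty(self, toy_params):
        rng = np.random.default_rng(0)
        pos = rs.sample_crossover_positions("1", toy_params.rec_map, 0,
                                            10_000_000, rng)
        assert pos.size == 0

    def test_min_separation_always_respected(self, toy_params):
        rng = np.random.default_rng(1)
        for _ in range(2000):
            pos = rs.sample_crossover_positions("1", toy_params.rec_map, 2,
                                                10_000_000, rng)
            assert pos[1] - pos[0] >= 10_000_000
            assert 0 <= pos[0] and pos[1] < 100_000_000

    def test_impossible_separation_falls_back_with_warning(self):
        g = rs.build_genome([("1", 25_000_000)])
        grid = rs.make_window_grid(g, 1_000_000)
        m = rs.RecombinationMap(grid, {"1": np.ones(25)})
        rng = np.random.default_rng(2)
        with pytest.warns(InterferenceFallbackWarning):
            pos = rs.sample_crossover_positions("1", m, 3, 10_000_000, rng,
                                                max_resample=50)
        assert pos.size == 3  # count never altered by rejection

    def test_marginal_matches_window_probabilities(self):
        # chi-square GOF on a 10-window toy map, alpha = 0.001
        g = rs.build_genome([("1", 10_000)])
        grid = rs.make_window_grid(g, 1_000)
        rng0 = np.random.default_rng(10)
        rates = rng0.gamma(1.0, 1.0, 10) + 0.05
        m = rs.RecombinationMap(grid, {"1": rates})
        rng = np.random.default_rng(11)
        pos = np.concatenate([
            rs.sample_crossover_positions("1", m, 1, 0, rng)
            for _ in range(100_000)])
        counts = np.histogram(pos, bins=np.arange(0, 11_000, 1000))[0]
        chi2 = sps.chisquare(counts, 100_000 * m.probs["1"])
        assert chi2.pvalue > 0.001


class TestGameteFormation:
    def test_homozygous_parent_yields_pure_gamete(self, toy_params):
        parent = rs.Individual.founder(toy_params.genome, 7)
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = rs.form_gamete(parent, toy_params, rng)
            assert g.n_junctions() == 0
            assert all(segs[0][2] == 7 for segs in g.segments.values())

    def test_f1_two_crossovers_alternate_strands(self, toy_genome):
        params = rs.MeiosisParams(
            count_dist=degenerate_count_dist(2),
            rec_map=rs.RecombinationMap(
                rs.make_window_grid(toy_genome, 1_000_000),
                {c: np.ones(rs.make_window_grid(toy_genome, 1_000_000)
                            .n_windows(c)) for c in toy_genome.ids}),
            min_separation=0,
        )
        f1 = rs.Individual(rs.Haplotype.pure(toy_genome, 0),
                           rs.Haplotype.pure(toy_genome, 1))
        rng = np.random.default_rng(5)
        patterns = set()
        for _ in range(200):
            g = rs.form_gamete(f1, params, rng)
            labels = tuple(s[2] for s in g.segments["1"])
            assert labels in {(0, 1, 0), (1, 0, 1)}
            assert g.n_junctions("1") == 2
            patterns.add(labels)
        assert patterns == {(0, 1, 0), (1, 0, 1)}  # both orderings occur

    def test_f1_mean_junctions_matches_count_distribution(self, maize_params):
        # 10 chromosomes x mean 1.4405 crossovers => ~14.4 junctions/gamete
        genome = maize_params.genome
        f1 = rs.Individual(rs.Haplotype.pure(genome, 0),
                           rs.Haplotype.pure(genome, 1))
        rng = np.random.default_rng(8)
        n = 3000
        counts = np.array([rs.form_gamete(f1, maize_params, rng).n_junctions()
                           for _ in range(n)])
        expected = len(genome) * maize_params.count_dist.mean
        se = counts.std(ddof=1) / np.sqrt(n)
        assert abs(counts.mean() - expected) < 3 * se

    def test_junction_survival_is_one_half(self, toy_genome):
        """A parental junction survives transmission with prob 1/2 when no
        crossover falls near it — exhaustive strand enumeration gives
        {carries, lacks}, each from one of the two equally likely strands."""
        x = 40_000_000
        hap1 = rs.Haplotype(toy_genome, {
            "1": [(0.0, x, 0), (x, 100_000_000.0, 1)],
            "2": [(0.0, 60_000_000.0, 0)]})
        hap2 = rs.Haplotype.pure(toy_genome, 0)
        parent = rs.Individual(hap1, hap2)
        grid = rs.make_window_grid(toy_genome, 1_000_000)
        params = rs.MeiosisParams(
            count_dist=degenerate_count_dist(0),  # no new crossovers
            rec_map=rs.RecombinationMap(
                grid, {c: np.ones(grid.n_windows(c)) for c in toy_genome.ids}))
        rng = np.random.default_rng(9)
        n = 4000
        carried = sum(rs.form_gamete(parent, params, rng).n_junctions("1") == 1
                      for _ in range(n))
        # binomial(n, 1/2): 3-sigma band
        assert abs(carried / n - 0.5) < 3 * 0.5 / np.sqrt(n)


class TestMergeInvisibleJunctions:
    def test_adjacent_same_label_fused(self):
        g = rs.build_genome([("1", 30)])
        h = rs.Haplotype(g, {"1": [(0, 10, 0), (10, 20, 0), (20, 30, 1)]})
        assert h.segments["1"] == [(0, 20, 0), (20, 30, 1)]

    def test_idempotent(self):
        g = rs.build_genome([("1", 30)])
        h = rs.Haplotype(g, {"1": [(0, 20, 0), (20, 30, 1)]})
        assert rs.merge_invisible_junctions(h).segments == h.segments

    def test_all_same_label_collapses_to_one_segment(self):
        g = rs.build_genome([("1", 30)])
        h = rs.Haplotype(g, {"1": [(0, 10, 5), (10, 20, 5), (20, 30, 5)]})
        assert h.segments["1"] == [(0, 30, 5)]
        assert h.n_junctions() == 0
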
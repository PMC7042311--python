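"""Tissue growth, sampling, sequencing noise, and lineage bookkeeping."""

import numpy as np
import pytest
from scipy.stats import chisquare, poisson

from mutdist.distances import build_histogram
from mutdist.simulate import (
    SeqConfig,
    SimConfig,
    BulkSample,
    clonal_profile,
    ground_truth_distances,
    sequencing_noise,
    simulate_tissue,
    take_samples,
    true_sample_profile,
)


class TestSimulateTissue:
    @pytest.mark.parametrize("death", ["explicit", "effective"])
    def test_no_death_gives_exact_division_count(self, death):
        tissue = simulate_tissue(
            SimConfig(muL=1.0, beta=1.0, target_cells=8, death=death, seed=1)
        )
        assert tissue.n_branching_divisions == 7
        assert tissue.n_nonbranching_divisions == 0
        assert tissue.n_cells == 8

    def test_zero_mutation_rate_gives_identical_genotypes(self):
        tissue = simulate_tissue(SimConfig(muL=0.0, beta=0.9, target_cells=50, seed=2))
        root_set = tissue.mutation_set(0)
        for cell in tissue.alive:
            assert tissue.mutation_set(cell) == root_set

    def test_seed_reproducibility(self):
        cfg = SimConfig(muL=2.0, beta=0.8, target_cells=300, seed=11)
        t1 = simulate_tissue(cfg)
        t2 = simulate_tissue(cfg)
        np.testing.assert_array_equal(t1.parent, t2.parent)
        np.testing.assert_array_equal(t1.n_new, t2.n_new)
        np.testing.assert_array_equal(t1.alive, t2.alive)

    def test_effective_mode_mutation_burden_scales_with_depth(self):
        # expected mutations per cell ~ muL x root-to-cell divisions
        tissue = simulate_tissue(
            SimConfig(muL=4.0, beta=1.0, target_cells=2000, death="effective", seed=5)
        )
        cells = tissue.alive[:200]
        ratios = [
            len(tissue.mutation_set(c)) / (4.0 * (len(tissue.lineage_path(c)) - 1))
            for c in cells
        ]
        assert 0.9 < np.mean(ratios) < 1.1

    def test_spatial_growth_produces_contiguous_population(self):
        tissue = simulate_tissue(
            SimConfig(muL=1.0, beta=0.9, target_cells=400, mode="spatial-2D", seed=3)
        )
        assert tissue.n_cells == 400
        pos = {tuple(tissue.positions[c]) for c in tissue.alive}
        assert len(pos) == 400
        # every cell has at least one occupied neighbour (single cluster)
        for x, y in pos:
            assert any(
                (x + dx, y + dy) in pos for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1))
            )

    def test_spatial_grid_too_small_raises(self):
        with pytest.raises(ValueError):
            simulate_tissue(
                SimConfig(muL=1.0, beta=1.0, target_cells=400, mode="spatial-2D",
                          grid_side=10, seed=1)
            )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(target_cells=1)
        with pytest.raises(ValueError):
            SimConfig(beta=0.0)
        with pytest.raises(ValueError):
            SimConfig(mode="spatial-5D")
        with pytest.raises(ValueError):
            SimConfig(death="sometimes")

    def test_sibling_distances_poisson_at_full_survival(self):
        # at beta = 1 every sibling branch spans >= 1 division whose
        # mutation count mixes Poisson(i muL) over the division count;
        # with a fully sampled small tissue every branch is one division
        tissue = simulate_tissue(SimConfig(muL=6.0, beta=1.0, target_cells=300, seed=9))
        samples = take_samples(tissue, 300, 1, rng=np.random.default_rng(1))
        hist = ground_truth_distances(tissue, samples, include_terminal=True)
        ys, cs = hist.as_arrays()
        n = cs.sum()
        kmax = int(ys.max())
        expected = poisson.pmf(np.arange(kmax + 1), 6.0) * n
        observed = np.zeros(kmax + 1)
        observed[ys] = cs
        # pool tails so expected counts stay reasonable
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        exp *= obs.sum() / exp.sum()
        assert chisquare(obs, exp).pvalue > 0.01


class TestSampling:
    def test_single_cell_profiles_are_true_genotypes(self, small_tissue):
        samples = take_samples(small_tissue, 10, 1, rng=np.random.default_rng(0))
        for s in samples:
            assert true_sample_profile(small_tissue, s).mutations == small_tissue.mutation_set(
                s.cells[0]
            )

    def test_whole_tissue_sample_profile_is_population_mrca(self, small_tissue):
        sample = take_samples(
            small_tissue, 1, small_tissue.n_cells, rng=np.random.default_rng(0)
        )[0]
        profile = true_sample_profile(small_tissue, sample)
        mrca = small_tissue.mrca(list(small_tissue.alive))
        assert profile.mutations == small_tissue.mutation_set(mrca)
        # clonal mutations are carried by every sampled cell
        for cell in sample.cells[:50]:
            assert profile.mutations <= small_tissue.mutation_set(cell)

    def test_sample_fractions_are_carrier_fractions(self, small_tissue):
        sample = take_samples(small_tissue, 1, 40, rng=np.random.default_rng(4))[0]
        muts = sorted(sample.fractions)[:30]
        for m in muts:
            carriers = sum(
                1 for c in sample.cells if m in small_tissue.mutation_set(c)
            )
            assert sample.fractions[m] == pytest.approx(carriers / len(sample.cells))

    def test_infeasible_request_rejected(self, small_tissue):
        with pytest.raises(ValueError):
            take_samples(small_tissue, 10, small_tissue.n_cells)

    def test_spatial_samples_are_contiguous_patches(self):
        tissue = simulate_tissue(
            SimConfig(muL=1.0, beta=0.95, target_cells=600, mode="spatial-2D", seed=4)
        )
        samples = take_samples(tissue, 5, 20, rng=np.random.default_rng(0))
        for s in samples:
            pts = {tuple(tissue.positions[c]) for c in s.cells}
            assert len(pts) == 20
            # contiguity: breadth-first flood from one point covers the patch
            seen = {next(iter(pts))}
            frontier = list(seen)
            while frontier:
                x, y = frontier.pop()
                for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    q = (x + dx, y + dy)
                    if q in pts and q not in seen:
                        seen.add(q)
                        frontier.append(q)
            assert seen == pts

    def test_maximal_distance_centres_spread(self):
        tissue = simulate_tissue(
            SimConfig(muL=1.0, beta=0.95, target_cells=600, mode="spatial-2D", seed=4)
        )
        far = take_samples(tissue, 6, 5, "maximal-distance", np.random.default_rng(1))
        locs = np.array([s.location for s in far])
        dists = [np.linalg.norm(a - b) for i, a in enumerate(locs) for b in locs[i + 1:]]
        assert min(dists) > 3  # centres are not adjacent


class TestSequencingNoise:
    def _sample_with_fractions(self, fractions):
        return BulkSample("S0", cells=(0,), fractions=fractions)

    def test_clonal_mutation_moments(self, rng):
        sample = self._sample_with_fractions({m: 1.0 for m in range(20_000)})
        table = sequencing_noise(sample, SeqConfig(mean_depth=100), rng)
        assert table["depth"].mean() == pytest.approx(100, rel=0.02)
        assert table["vaf"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_diploid_halves_expected_vaf(self, rng):
        sample = self._sample_with_fractions({m: 1.0 for m in range(20_000)})
        table = sequencing_noise(sample, SeqConfig(mean_depth=100, diploid=True), rng)
        assert table["vaf"].mean() == pytest.approx(0.5, rel=0.02)

    def test_absent_mutation_never_read(self, rng):
        sample = self._sample_with_fractions({m: 0.0 for m in range(5000)})
        table = sequencing_noise(sample, SeqConfig(mean_depth=100), rng)
        assert (table["alt_reads"] == 0).all()

    def test_alt_reads_match_poisson_binomial_mixture(self, rng):
        # depth ~ Poisson(Z), alt | depth ~ Binomial(depth, f): the alt-read
        # marginal is Poisson(Z f) by thinning — the independent oracle
        f, Z, n = 0.37, 30.0, 40_000
        sample = self._sample_with_fractions({m: f for m in range(n)})
        table = sequencing_noise(sample, SeqConfig(mean_depth=Z), rng)
        alt = table["alt_reads"].to_numpy()
        kmax = int(alt.max())
        expected = poisson.pmf(np.arange(kmax + 1), Z * f) * n
        observed = np.bincount(alt, minlength=kmax + 1)
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        exp *= obs.sum() / exp.sum()
        assert chisquare(obs, exp).pvalue > 0.01

    def test_zero_depth_rows_have_missing_vaf(self):
        rng = np.random.default_rng(0)
        sample = self._sample_with_fractions({m: 1.0 for m in range(3000)})
        table = sequencing_noise(sample, SeqConfig(mean_depth=1), rng)
        zero = table[table["depth"] == 0]
        assert len(zero) > 0 and zero["vaf"].isna().all()


class TestClonalProfile:
    def test_threshold_separates_clonal_from_subclonal(self, rng):
        sample = BulkSample("S1", cells=(0,), fractions={1: 1.0, 2: 0.02})
        table = sequencing_noise(sample, SeqConfig(mean_depth=500), rng)
        profile = clonal_profile(table, SeqConfig(clonal_vaf_threshold=0.3))
        assert profile.mutations == {1}

    def test_zero_threshold_retains_all_detected(self, rng):
        sample = BulkSample("S1", cells=(0,), fractions={1: 1.0, 2: 0.5, 3: 0.2})
        table = sequencing_noise(sample, SeqConfig(mean_depth=500), rng)
        profile = clonal_profile(table, SeqConfig(clonal_vaf_threshold=0.0))
        assert profile.mutations == {1, 2, 3}

    def test_noiseless_pipeline_recovers_true_mrca_profiles(self, small_tissue):
        # deep sequencing + moderate threshold reproduces the lineage truth
        rng = np.random.default_rng(8)
        samples = take_samples(small_tissue, 6, 25, rng=rng)
        seq = SeqConfig(mean_depth=1000, clonal_vaf_threshold=0.85)
        for s in samples:
            called = clonal_profile(sequencing_noise(s, seq, rng), seq)
            truth = true_sample_profile(small_tissue, s)
            # every true clonal mutation has fraction 1.0 and is retained
            assert truth.mutations <= called.mutations

    def test_empty_table_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            clonal_profile(pd.DataFrame(), SeqConfig())


class TestGroundTruthDistances:
    def test_sister_clades_give_branch_distances(self):
        tissue = simulate_tissue(SimConfig(muL=3.0, beta=1.0, target_cells=64, seed=21))
        samples = take_samples(tissue, 6, 1, rng=np.random.default_rng(2))
        hist = ground_truth_distances(tissue, samples, include_terminal=True)
        profiles = [true_sample_profile(tissue, s) for s in samples]
        assert hist == build_histogram(profiles, include_terminal=True)

    def test_foreign_cells_rejected(self, small_tissue):
        bogus = BulkSample("X", cells=(10**9,), fractions={})
        with pytest.raises(ValueError):
            ground_truth_distances(small_tissue, [bogus])
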
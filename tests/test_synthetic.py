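import numpy as np
import pytest

from imputebench import (
    ArrayContent,
    ImputerConfig,
    SimConfig,
    build_accuracy_table,
    inject_misplacement,
    inject_switch_errors,
    ls_impute,
    noisy_impute,
    simulate_population,
)
from imputebench.metrics import concordance_rate, pearson
from imputebench.synthetic import (
    chrom_bounds_of,
    drawn_frequencies,
    haplotypes_for_samples,
    ls_posteriors,
)


class TestSimulator:
    def test_bit_reproducible_under_fixed_seed(self):
        cfg = SimConfig(n_samples=20, n_markers=100, n_haplotypes_founder=30,
                        mosaic_generations=10, n_haplotypes_pool=60, seed=5)
        a = simulate_population(cfg)
        b = simulate_population(cfg)
        np.testing.assert_array_equal(a[0].genotypes, b[0].genotypes)
        np.testing.assert_array_equal(a[2], b[2])
        assert a[1].table.equals(b[1].table)

    def test_genotypes_are_haplotype_sums(self, small_sim):
        panel, _, haps = small_sim
        np.testing.assert_array_equal(
            panel.genotypes, (haps[0::2] + haps[1::2]).T
        )

    def test_no_recombination_copies_whole_founder_chromosomes(self):
        cfg = SimConfig(n_samples=15, n_markers=80, n_haplotypes_founder=25,
                        mosaic_generations=1, n_haplotypes_pool=25,
                        recomb_rate_per_bp=0.0, seed=3)
        panel, mmap, haps = simulate_population(cfg)
        founders = (
            np.random.default_rng(np.random.SeedSequence([3, 2]))
            .random((25, 80)) < drawn_frequencies(cfg)
        ).astype(np.int8)
        chroms = mmap.chrom_of(panel.markers)
        for start, stop in chrom_bounds_of(chroms):
            for hap in haps:
                block = hap[start:stop]
                assert any(np.array_equal(block, f[start:stop]) for f in founders)

    def test_sample_frequencies_track_drawn_spectrum(self):
        cfg = SimConfig(n_samples=150, n_markers=800, seed=13)
        panel, _, _ = simulate_population(cfg)
        drawn = drawn_frequencies(cfg)
        realized = panel.allele_freq()
        # founder binomial noise + drift through the mosaic generations
        var = drawn * (1 - drawn) * (
            1 / cfg.n_haplotypes_founder + cfg.mosaic_generations / cfg.n_haplotypes_pool
        )
        within = np.abs(realized - drawn) <= 3 * np.sqrt(var)
        assert within.mean() > 0.95
        assert pearson(drawn, realized) > 0.8

    def test_ld_decays_with_distance(self, small_sim):
        panel, mmap, haps = small_sim
        pos = mmap.pos_of(panel.markers)
        chroms = mmap.chrom_of(panel.markers)
        h = haps.astype(float)
        rng = np.random.default_rng(0)
        near, far = [], []
        for _ in range(1000):
            i = int(rng.integers(0, panel.n_markers - 1))
            j = i + 1
            if chroms[i] == chroms[j]:
                r = pearson(h[:, i], h[:, j])
                if np.isfinite(r):
                    near.append(r * r)
            k = int(rng.integers(0, panel.n_markers))
            far_candidates = np.nonzero(
                (chroms == chroms[k]) & (np.abs(pos - pos[k]) > 500_000)
            )[0]
            if len(far_candidates):
                j2 = int(rng.choice(far_candidates))
                r = pearson(h[:, k], h[:, j2])
                if np.isfinite(r):
                    far.append(r * r)
        assert np.mean(near) > 2 * np.mean(far)


class TestLsImputer:
    def test_posteriors_normalised_everywhere(self, small_sim):
        panel, mmap, haps = small_sim
        ref = haps[:40]
        obs = haps[41].copy()
        obs[::3] = -1  # untyped sites
        gamma = ls_posteriors(ref, obs, mmap.chrom_of(panel.markers), mmap.pos_of(panel.markers))
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_self_imputation_recovers_reference_sample(self, small_sim):
        panel, mmap, haps = small_sim
        ref_ids = list(panel.samples[:30])
        ref_h = haplotypes_for_samples(haps, panel.samples, ref_ids)
        # target = a sample that is itself in the reference panel
        tgt_ids = [panel.samples[0]]
        tgt_h = haplotypes_for_samples(haps, panel.samples, tgt_ids)
        sparse = ArrayContent("sp", frozenset(panel.markers[::5]))
        cfg = ImputerConfig(eps=1e-4, rho_per_bp=1e-4)  # sticky copying: exact template exists
        res = ls_impute(ref_h, tgt_h, panel.markers, mmap, sparse, cfg, tgt_ids)
        truth = panel.subset_samples(tgt_ids).subset_markers(res.markers)
        match = (res.best_guess[:, 0] == truth.genotypes[:, 0]).mean()
        assert match > 0.97

    def test_accuracy_increases_with_reference_size(self, small_sim):
        panel, mmap, haps = small_sim
        tgt_ids = list(panel.samples[50:])
        tgt_h = haplotypes_for_samples(haps, panel.samples, tgt_ids)
        truth = panel.subset_samples(tgt_ids)
        sparse = ArrayContent("sp", frozenset(panel.markers[::8]))
        means = []
        for n_ref in (6, 15, 30, 50):
            ref_h = haplotypes_for_samples(haps, panel.samples, panel.samples[:n_ref])
            res = ls_impute(ref_h, tgt_h, panel.markers, mmap, sparse,
                            ImputerConfig(), tgt_ids)
            table = build_accuracy_table(truth, res)
            means.append(np.nanmean(table["r2_dose"]))
        assert means == sorted(means)

    def test_too_small_reference_rejected(self, small_sim):
        panel, mmap, haps = small_sim
        sparse = ArrayContent("sp", frozenset(panel.markers[::5]))
        with pytest.raises(ValueError, match="reference"):
            ls_impute(haps[:1], haps[2:4], panel.markers, mmap, sparse)


class TestNoisyImputer:
    def test_zero_error_is_perfect(self, small_sim):
        panel, _, _ = small_sim
        res = noisy_impute(panel, ImputerConfig(mode="noise", noise_e=0.0), seed=1)
        np.testing.assert_array_equal(res.best_guess, panel.genotypes)

    @pytest.mark.parametrize("e", [0.1, 2 / 3])
    def test_concordance_matches_error_rate(self, small_sim, e):
        panel, _, _ = small_sim
        res = noisy_impute(panel, ImputerConfig(mode="noise", noise_e=e), seed=2)
        cr = np.mean(
            [concordance_rate(g, b) for g, b in zip(panel.genotypes, res.best_guess)]
        )
        n = panel.genotypes.size
        assert abs(cr - (1 - e)) < 3 * np.sqrt(e * (1 - e) / n)

    def test_dosages_follow_best_guess(self, small_sim):
        panel, _, _ = small_sim
        res = noisy_impute(panel, ImputerConfig(mode="noise", noise_e=0.05,
                                                noise_jitter_sd=0.1), seed=3)
        assert res.dosages.min() >= 0 and res.dosages.max() <= 2
        assert np.abs(res.dosages - res.best_guess).mean() < 0.2


class TestCorruptionFixtures:
    def test_zero_blocks_leaves_map_unchanged(self, small_sim):
        _, mmap, _ = small_sim
        out, moved = inject_misplacement(mmap, 0, 5, seed=1)
        assert moved == []
        assert out.table.equals(mmap.table)

    def test_blocks_moved_far_and_compact(self, small_sim):
        _, mmap, _ = small_sim
        out, moved = inject_misplacement(mmap, 3, 5, seed=2, min_shift_bp=400_000)
        assert len(moved) == 15
        for i in range(0, 15, 5):
            block = moved[i:i + 5]
            old_c = mmap.chrom_of(block)
            new_c = out.chrom_of(block)
            new_p = out.pos_of(block)
            assert len(set(new_c)) == 1
            if new_c[0] == old_c[0]:
                old_mid = np.median(mmap.pos_of(block))
                assert abs(np.median(new_p) - old_mid) >= 300_000
            spacing = np.median(np.diff(np.sort(mmap.pos_of(mmap.marker_ids))))
            assert new_p.max() - new_p.min() <= 5 * 20 * spacing
        untouched = [m for m in mmap.marker_ids if m not in set(moved)]
        assert out.table.loc[untouched].equals(mmap.table.loc[untouched])

    def test_switch_errors_preserve_genotypes(self, small_sim):
        panel, mmap, haps = small_sim
        chroms = mmap.chrom_of(panel.markers)
        out = inject_switch_errors(haps, chroms, 0.05, seed=4)
        assert not np.array_equal(out, haps)
        np.testing.assert_array_equal(
            out[0::2] + out[1::2], haps[0::2] + haps[1::2]
        )

    def test_switch_errors_zero_rate_noop(self, small_sim):
        panel, mmap, haps = small_sim
        out = inject_switch_errors(haps, mmap.chrom_of(panel.markers), 0.0, seed=4)
        np.testing.assert_array_equal(out, haps)
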
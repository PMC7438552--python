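"""Tests for the synthetic bulked-segregant experiment generator."""

import math

import numpy as np
import pytest
from scipy import stats

from bseseq.popsim import (
    SimConfig,
    draw_ems_alleles,
    generate_ems_sites,
    haldane,
    sample_reads,
    select_bulks,
    simulate_experiment,
    simulate_f2_individual,
    simulate_population,
    write_simulation,
)
from bseseq.candidate_filter import is_ems_transition

RNG = lambda seed=0: np.random.default_rng(seed)


class TestHaldane:
    def test_closed_form_at_50mb(self):
        # 50 Mb at 1 cM/Mb = 0.5 Morgans -> r = (1 - e^-1)/2
        assert haldane(0.5) == pytest.approx((1 - math.exp(-1)) / 2)

    def test_limits(self):
        assert haldane(0.0) == 0.0
        assert haldane(100.0) == pytest.approx(0.5)


class TestMeiosis:
    def test_single_marker_segregates_1_2_1(self):
        rng = RNG(42)
        counts = np.zeros(3)
        draws = np.array(
            [simulate_f2_individual([1_000], 1.0, rng)[0] for _ in range(10_000)]
        )
        for g in range(3):
            counts[g] = np.sum(draws == g)
        p = stats.chisquare(counts, f_exp=[2500, 5000, 2500]).pvalue
        assert p > 0.001

    def test_zero_distance_markers_co_inherited(self):
        rng = RNG(0)
        geno = simulate_population([1_000, 1_000 + 0], 1.0, 2_000, rng)
        assert np.array_equal(geno[:, 0], geno[:, 1])

    def test_recombination_matches_haldane_at_50mb(self):
        rng = RNG(7)
        n = 10_000
        from bseseq.popsim import _draw_gametes

        gametes = _draw_gametes(np.array([1, 50_000_001]), 1.0, n, rng)
        observed_r = np.mean(gametes[:, 0] != gametes[:, 1])
        expected_r = (1 - math.exp(-1)) / 2  # ~0.3161
        se = math.sqrt(expected_r * (1 - expected_r) / n)
        assert abs(observed_r - expected_r) < 4 * se

    def test_population_alt_frequency_near_half(self):
        rng = RNG(3)
        geno = simulate_population(np.arange(1, 51) * 1_000_000, 1.0, 2_000, rng)
        af = geno.mean(axis=0) / 2
        se = math.sqrt(0.25 / (2 * 2_000))
        assert np.all(np.abs(af - 0.5) < 5 * se)

    def test_inbred_population_has_no_heterozygotes(self):
        rng = RNG(1)
        geno = simulate_population(np.arange(1, 11) * 1_000_000, 1.0, 500, rng, inbred=True)
        assert set(np.unique(geno)) <= {0, 2}


class TestSelectBulks:
    def _population(self, seed=5, n=431):
        rng = RNG(seed)
        positions = np.arange(1, 101) * 1_000_000
        geno = simulate_population(positions, 1.0, n, rng)
        return geno, rng

    def test_f2_bulk_frequencies_at_causal(self):
        geno, rng = self._population()
        wild, mutant = select_bulks(geno, 50, "f2_recessive", 30, rng)
        m_af = geno[mutant, 50].mean() / 2
        w_af = geno[wild, 50].mean() / 2
        assert m_af == 1.0
        # wild bulk drawn from AA:Aa = 1:2 -> expectation 1/3
        assert abs(w_af - 1 / 3) < 0.15

    def test_homozygous_selection_wild_af_zero(self):
        geno, rng = self._population()
        wild, _ = select_bulks(geno, 50, "f2_recessive", 30, rng,
                               wild_bulk_selection="homozygous")
        assert geno[wild, 50].mean() == 0.0

    def test_insufficient_population_raises(self):
        geno, rng = self._population(n=40)  # ~10 aa homozygotes expected
        with pytest.raises(ValueError, match="larger population"):
            select_bulks(geno, 50, "f2_recessive", 30, rng)


class TestSampleReads:
    def test_fixed_allele_no_error(self):
        ref, alt = sample_reads(np.ones(100), 70, 0.0, RNG(0))
        assert np.all(ref == 0)

    def test_error_rate_recovered_at_af_zero(self):
        ref, alt = sample_reads(np.zeros(100_000), 70, 0.01, RNG(1))
        observed = alt.sum() / (alt.sum() + ref.sum())
        assert observed == pytest.approx(0.01, rel=0.1)

    def test_large_depth_limit_recovers_af(self):
        ref, alt = sample_reads(np.full(10_000, 1 / 3), 70, 0.0, RNG(2))
        assert alt.sum() / (alt.sum() + ref.sum()) == pytest.approx(1 / 3, abs=0.01)

    def test_invalid_af_rejected(self):
        with pytest.raises(ValueError):
            sample_reads(1.5, 70, 0.0, RNG(0))


class TestEmsSites:
    def test_pure_spectrum_all_transitions(self):
        seq = "ACGT" * 500
        sites = generate_ems_sites(seq, 200, ems_spectrum=1.0, rng=RNG(0))
        assert all(is_ems_transition(ref, alt) for _, ref, alt in sites)

    def test_default_spectrum_over_99_percent(self):
        rng = RNG(11)
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        sites = generate_ems_sites(seq, 10_000, rng=RNG(12))
        frac = np.mean([is_ems_transition(r, a) for _, r, a in sites])
        assert frac >= 0.99

    def test_positions_unique_and_in_range(self):
        seq = "ACGT" * 100
        sites = generate_ems_sites(seq, 150, ems_spectrum=0.5, rng=RNG(3))
        positions = [p for p, _, _ in sites]
        assert len(set(positions)) == len(positions) == 150
        assert all(1 <= p <= len(seq) for p in positions)
        for p, ref, _ in sites:
            assert seq[p - 1] == ref

    def test_no_cg_available_raises(self):
        with pytest.raises(ValueError, match="C/G"):
            generate_ems_sites("A" * 100, 10, ems_spectrum=1.0, rng=RNG(0))

    def test_too_many_sites_raises(self):
        with pytest.raises(ValueError):
            generate_ems_sites("ACGT", 10, rng=RNG(0))

    def test_draw_ems_alleles_never_yields_identical_pair(self):
        ref, alt = draw_ems_alleles(5_000, 0.5, RNG(4))
        assert np.all(ref != alt)


SMALL = dict(
    chrom_length_bp=50_000_000, n_markers=200, population_size=200, rng_seed=9
)


class TestExperiment:
    def test_causal_truth_frequencies(self):
        _, truth = simulate_experiment(SimConfig(**SMALL))
        frame = truth.to_frame()
        causal = frame[frame.is_causal]
        assert len(causal) == 1
        assert causal.true_mutant_af.iloc[0] == 1.0
        assert is_ems_transition(truth.causal_key[2], truth.causal_key[3])

    def test_truth_af_equals_mean_genotype_dosage(self):
        _, truth = simulate_experiment(SimConfig(**SMALL))
        expected = truth.genotypes[truth.wild_members].mean(axis=0) / 2
        assert np.allclose(truth.true_wild_af, expected)

    def test_linked_markers_share_causal_geometry(self):
        """True mutant-bulk AF decays from 1 with distance from the causal
        site, approaching the Haldane selection-conditioned expectation 1 - r;
        markers on an unlinked chromosome sit at 1/2."""
        reps = []
        for seed in range(30):
            cfg = SimConfig(n_chromosomes=2, chrom_length_bp=200_000_000,
                            n_markers=300, population_size=300, rng_seed=seed)
            _, truth = simulate_experiment(cfg)
            on_causal = truth.chroms == truth.causal_key[0]
            d = np.abs(truth.positions - truth.causal_key[1])
            near = truth.true_mutant_af[on_causal & (d < 5_000_000)].mean()
            mid = truth.true_mutant_af[on_causal & (d > 20_000_000) & (d < 60_000_000)].mean()
            far = truth.true_mutant_af[on_causal & (d > 80_000_000)].mean()
            unlinked = truth.true_mutant_af[~on_causal].mean()
            reps.append((near, mid, far, unlinked))
        near, mid, far, unlinked = np.mean(reps, axis=0)
        assert near > mid > far > unlinked
        # >80 Mb at 1 cM/Mb: r in [0.40, 0.49], so 1 - r averages ~0.55-0.60
        assert 0.5 < far < 0.65
        assert unlinked == pytest.approx(0.5, abs=0.03)

    def test_marker_count(self):
        variants, _ = simulate_experiment(SimConfig(**SMALL))
        # configured markers plus the inserted causal site (unless it collides)
        assert len(variants) in (200, 201)

    def test_write_simulation_deterministic(self, tmp_path):
        cfg = SimConfig(**SMALL)
        p1 = write_simulation(cfg, tmp_path / "a")
        p2 = write_simulation(cfg, tmp_path / "b")
        for key in ("vcf", "truth", "config"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_written_vcf_parses_back(self, tmp_path):
        from bseseq.variant_io import read_bulk_vcf

        cfg = SimConfig(**SMALL)
        paths = write_simulation(cfg, tmp_path)
        variants, _ = simulate_experiment(cfg)
        back = read_bulk_vcf(paths["vcf"], "wild_bulk", "mutant_bulk")
        assert len(back) == len(variants)
        assert [(v.wild, v.mutant) for v in back] == [(v.wild, v.mutant) for v in variants]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(bulk_size=0)
        with pytest.raises(ValueError):
            SimConfig(sequencing_error_rate=0.7)
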
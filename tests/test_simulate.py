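"""Simulator contracts: determinism, designed-panel recovery, mosaic
statistics, and recovery scoring."""

import numpy as np
import pytest

from laikit.caller import UNCALLED, AncestrySegment
from laikit.panel import ConfigurationError, screen_specific_snps
from laikit.simulate import (SimulationConfig, TruthTracts, evaluate_recovery,
                             simulate_admixed, simulate_reference)

from conftest import panel_rows, segments_to_paint


def small_config(**kw):
    base = dict(chrom_length=2_000_000, ref_sizes=30, n_admixed=5,
                snp_density=1e-4, seed=7)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ConfigurationError):
            small_config(proportions=(0.5, 0.4))
        with pytest.raises(ConfigurationError):
            small_config(generations=0)
        with pytest.raises(ConfigurationError):
            small_config(epsilon=1.0)
        with pytest.raises(ConfigurationError):
            small_config(snp_density=(1e-4,))
        with pytest.raises(ConfigurationError):
            small_config(populations=("ONLY",), proportions=(1.0,),
                         snp_density=1e-4)

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("chrom_length: 500000\nseed: 3\n"
                        "populations: [AFR, EUR]\nproportions: [0.6, 0.4]\n")
        cfg = SimulationConfig.from_yaml(path)
        assert cfg.chrom_length == 500000 and cfg.proportions == (0.6, 0.4)


class TestSimulateReference:
    def test_deterministic_for_fixed_seed(self):
        c1, p1 = simulate_reference(small_config())
        c2, p2 = simulate_reference(small_config())
        assert p1 == p2
        assert np.array_equal(c1.genotypes, c2.genotypes)
        assert c1.sample_ids == c2.sample_ids

    def test_snp_count_matches_density_expectation(self):
        # density 1e-4 on 1 Mb -> ~100 SNPs per population (Poisson, 4 SD)
        cfg = small_config(chrom_length=1_000_000, seed=123)
        _, panel = simulate_reference(cfg)
        for mk in panel.M_k():
            assert abs(mk - 100) < 4 * np.sqrt(100)

    def test_specific_alleles_absent_elsewhere_when_clean(self):
        cohort, panel = simulate_reference(small_config(epsilon=0.0))
        alt_c = cohort.alt_counts()
        off_target = alt_c.copy()
        off_target[np.arange(panel.M), panel.pop_index] = 0
        assert off_target.sum() == 0

    def test_epsilon_plants_hidden_alleles(self):
        cohort, panel = simulate_reference(
            small_config(epsilon=0.5, ref_sizes=500, seed=5))
        alt_c = cohort.alt_counts()
        off_target = alt_c.copy()
        off_target[np.arange(panel.M), panel.pop_index] = 0
        assert off_target.sum() > 0       # some hidden copies were sampled
        assert (panel.hidden_pop >= 0).mean() == pytest.approx(0.5, abs=0.1)

    def test_screen_recovers_designed_panel(self):
        """With no misclassification, screening at min_copies=1 returns
        exactly the designed SNPs with >=1 sampled copy that stay minor in
        their population's sample."""
        cohort, designed = simulate_reference(small_config(seed=42))
        panel = screen_specific_snps(cohort, min_copies=1)
        alt_c = cohort.alt_counts()
        realized = alt_c[np.arange(designed.M), designed.pop_index]
        sizes = 2 * cohort.pop_sizes[designed.pop_index]
        eligible = (realized >= 1) & (realized / sizes <= 0.5)
        expected = {(str(c), int(p)) for c, p in
                    zip(designed.chrom[eligible], designed.pos[eligible])}
        assert panel.key_set() == expected

    def test_zero_snp_population_raises(self):
        with pytest.raises(ConfigurationError, match="zero specific SNPs"):
            simulate_reference(small_config(chrom_length=1000,
                                            snp_density=1e-6))


class TestSimulateAdmixed:
    def test_deterministic_for_fixed_seed(self):
        cfg = small_config()
        _, panel = simulate_reference(cfg)
        pm1, t1 = simulate_admixed(cfg, panel)
        pm2, t2 = simulate_admixed(cfg, panel)
        assert np.array_equal(pm1.X, pm2.X)
        for key in t1.tracts:
            assert np.array_equal(t1.tracts[key][0], t2.tracts[key][0])
            assert np.array_equal(t1.tracts[key][1], t2.tracts[key][1])

    def test_single_ancestry_degenerate_mixture(self):
        cfg = small_config(proportions=(1.0, 0.0))
        _, panel = simulate_reference(cfg)
        pm, truth = simulate_admixed(cfg, panel)
        for bounds, labels in truth.tracts.values():
            assert set(labels) == {"POP1"}
        # no POP2-specific allele can appear on a pure POP1 background
        assert pm.X[:, :, panel.theta(1)].sum() == 0

    def test_breakpoint_count_matches_poisson_mean(self):
        # g=10, L=250 Mb, r=1e-8 -> mean 25 breakpoints per haplotype
        cfg = SimulationConfig(chrom_length=250_000_000, ref_sizes=2,
                               n_admixed=100, snp_density=2e-6,
                               generations=10, seed=9)
        _, panel = simulate_reference(cfg)
        _, truth = simulate_admixed(cfg, panel)
        counts = [len(bounds) - 2 for bounds, _ in truth.tracts.values()]
        mean = np.mean(counts)
        se = np.sqrt(25 / len(counts))
        assert abs(mean - 25) < 4 * se

    def test_truth_tracts_tile_chromosome(self):
        cfg = small_config(generations=50)
        _, panel = simulate_reference(cfg)
        _, truth = simulate_admixed(cfg, panel)
        for bounds, labels in truth.tracts.values():
            assert bounds[0] == 0 and bounds[-1] == cfg.chrom_length
            assert (np.diff(bounds) > 0).all()
            assert len(labels) == len(bounds) - 1


def truth_of(tracts, length=1000, chrom="1"):
    return TruthTracts(chrom=chrom, chrom_length=length, tracts={
        key: (np.array(bounds), np.array(labels, dtype=object))
        for key, (bounds, labels) in tracts.items()})


def segs(key, triples, chrom="1"):
    return [AncestrySegment(chrom, s, e, key[0], key[1], l)
            for s, e, l in triples]


class TestEvaluateRecovery:
    def test_identical_segments_score_perfect(self):
        truth = truth_of({("S", 1): ([0, 400, 1000], ["AFR", "EUR"])})
        segments = segs(("S", 1), [(0, 400, "AFR"), (400, 1000, "EUR")])
        rec = evaluate_recovery(segments, truth)
        assert (rec.correct, rec.wrong, rec.uncalled) == (1.0, 0.0, 0.0)

    def test_everything_uncalled(self):
        truth = truth_of({("S", 1): ([0, 1000], ["AFR"])})
        rec = evaluate_recovery(segs(("S", 1), [(0, 1000, UNCALLED)]), truth)
        assert (rec.correct, rec.wrong, rec.uncalled) == (0.0, 0.0, 1.0)

    def test_half_correct_half_uncalled(self):
        truth = truth_of({("S", 1): ([0, 1000], ["AFR"])})
        rec = evaluate_recovery(
            segs(("S", 1), [(0, 500, "AFR"), (500, 1000, UNCALLED)]), truth)
        assert (rec.correct, rec.wrong, rec.uncalled) == (0.5, 0.0, 0.5)

    def test_fractions_conserve_and_match_paint_oracle(self, rng):
        length = 500
        labels = np.array(["A", "B", UNCALLED], dtype=object)
        truth_cuts = np.sort(rng.choice(np.arange(1, length), 4, replace=False))
        truth_labels = [str(labels[rng.integers(0, 2)]) for _ in range(5)]
        truth = truth_of({("S", 1): ([0, *truth_cuts, length], truth_labels)},
                         length=length)
        seg_cuts = np.sort(rng.choice(np.arange(1, length), 6, replace=False))
        seg_bounds = [0, *seg_cuts, length]
        triples = [(seg_bounds[i], seg_bounds[i + 1],
                    str(labels[rng.integers(0, 3)])) for i in range(7)]
        segments = segs(("S", 1), triples)
        rec = evaluate_recovery(segments, truth)
        assert rec.correct + rec.wrong + rec.uncalled == pytest.approx(1.0)
        # per-bp oracle
        called = segments_to_paint(segments, length)
        true_paint = segments_to_paint(
            truth.to_segments(), length)
        unc = called == UNCALLED
        correct = (~unc) & (called == true_paint)
        assert rec.correct == pytest.approx(correct.mean())
        assert rec.uncalled == pytest.approx(unc.mean())

    def test_mismatched_haplotypes_rejected(self):
        truth = truth_of({("S", 1): ([0, 1000], ["AFR"])})
        with pytest.raises(ValueError, match="haplotype sets"):
            evaluate_recovery(segs(("T", 1), [(0, 1000, "AFR")]), truth)
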
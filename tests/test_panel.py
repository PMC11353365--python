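"""Screening rules, panel invariants, and panel TSV round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from laikit.panel import (ConfigurationError, PanelFormatError, ReferenceCohort,
                          SNPPanel, read_panel, screen_specific_snps,
                          write_panel)

from conftest import make_cohort, make_panel, panel_rows, screen_oracle

POPS3 = ["AFR", "EUR", "EAS"]


def cohort_from_counts(count_rows, pop_sizes=(50, 50, 50)):
    snps = [{"chrom": "1", "pos": 100 * (i + 1), "alt_copies": row}
            for i, row in enumerate(count_rows)]
    return make_cohort(POPS3, pop_sizes, snps)


class TestScreeningRule:
    @pytest.mark.parametrize("copies,retained", [
        ((5, 0, 0), True),    # meets the 5-copy threshold, private to pop 1
        ((4, 0, 0), False),   # below copy threshold
        ((5, 1, 0), False),   # allele leaks into a second population
    ])
    def test_copy_threshold_and_privacy(self, copies, retained):
        panel = screen_specific_snps(cohort_from_counts([copies]), min_copies=5)
        assert panel.M == (1 if retained else 0)
        if retained:
            assert panel.populations[panel.pop_index[0]] == "AFR"
            assert panel.maf[0] == pytest.approx(5 / 100)
            assert panel.count[0] == 5

    def test_ref_allele_can_be_specific(self):
        # ALT fixed in two populations, segregating in the third: the REF
        # allele is private to the third population.
        cohort = cohort_from_counts([(100, 100, 94)])
        panel = screen_specific_snps(cohort, min_copies=5)
        assert panel.M == 1
        assert panel.allele[0] == cohort.ref[0]
        assert panel.populations[panel.pop_index[0]] == "EAS"
        assert panel.maf[0] == pytest.approx(6 / 100)

    def test_majority_allele_not_specific(self):
        # private allele at frequency > 0.5 in its own population is not the
        # minor allele there, hence not retained
        panel = screen_specific_snps(cohort_from_counts([(60, 0, 0)]),
                                     min_copies=5)
        assert panel.M == 0

    def test_frequency_exactly_half_allowed(self):
        panel = screen_specific_snps(cohort_from_counts([(50, 0, 0)]),
                                     min_copies=5)
        assert panel.M == 1 and panel.maf[0] == 0.5

    def test_errors(self):
        with pytest.raises(ConfigurationError):
            screen_specific_snps(
                make_cohort(["AFR"], [10],
                            [{"chrom": "1", "pos": 1, "alt_copies": (2,)}]))
        with pytest.raises(ConfigurationError):
            screen_specific_snps(
                make_cohort(POPS3, [10, 10, 0],
                            [{"chrom": "1", "pos": 1,
                              "alt_copies": (2, 0, 0)}]))
        with pytest.raises(ValueError):
            screen_specific_snps(cohort_from_counts([(5, 0, 0)]), min_copies=0)


class TestScreeningProperties:
    def test_oracle_equivalence_random_cohort(self, rng):
        for _ in range(5):
            n = int(rng.integers(50, 300))
            counts = np.stack([rng.integers(0, 2 * s + 1, size=n)
                               for s in (20, 30, 25)], axis=1)
            counts[rng.random(n) < 0.4] = 0          # many monomorphic SNPs
            pos = np.sort(rng.choice(np.arange(1, 10**6), n, replace=False))
            snps = [{"chrom": "1", "pos": int(p), "alt_copies": tuple(c)}
                    for p, c in zip(pos, counts)]
            cohort = make_cohort(POPS3, (20, 30, 25), snps)
            panel = screen_specific_snps(cohort, min_copies=3)
            assert panel_rows(panel) == screen_oracle(cohort, 3)

    @given(counts=st.lists(
        st.tuples(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)),
        min_size=1, max_size=12),
        min_copies=st.integers(1, 6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_oracle_equivalence_property(self, counts, min_copies):
        cohort = cohort_from_counts(counts, pop_sizes=(10, 10, 10))
        panel = screen_specific_snps(cohort, min_copies=min_copies)
        assert panel_rows(panel) == screen_oracle(cohort, min_copies)

    def test_partition_and_monotonicity(self, rng):
        counts = np.zeros((200, 3), dtype=int)
        k = rng.integers(0, 3, size=200)
        counts[np.arange(200), k] = rng.integers(0, 40, size=200)
        cohort = cohort_from_counts([tuple(c) for c in counts],
                                    pop_sizes=(40, 40, 40))
        sizes = []
        for mc in (1, 3, 5, 10):
            panel = screen_specific_snps(cohort, min_copies=mc)
            assert panel.M_k().sum() == panel.M            # theta partition
            covered = np.zeros(panel.M, dtype=int)
            for kk in range(panel.K):
                covered[panel.theta(kk)] += 1
            assert (covered == 1).all()
            sizes.append(panel.M)
        assert sizes == sorted(sizes, reverse=True)        # monotone in copies

    def test_idempotence(self, rng):
        counts = [(7, 0, 0), (0, 9, 0), (0, 0, 12), (3, 3, 0), (0, 0, 2)]
        cohort = cohort_from_counts(counts)
        panel = screen_specific_snps(cohort, min_copies=5)
        keys = panel.key_set()
        mask = np.array([(c, int(p)) in keys
                         for c, p in zip(cohort.chrom, cohort.pos)])
        again = screen_specific_snps(cohort.restrict_to(mask), min_copies=5)
        assert again == panel


class TestPanelIO:
    def roundtrip(self, panel, tmp_path):
        path = tmp_path / "panel.tsv"
        write_panel(panel, path)
        return read_panel(path)

    def test_roundtrip_identity(self, tmp_path):
        panel = make_panel(POPS3, [
            ("1", 100, "AFR", "G", 0.05, 5),
            ("1", 250, "EUR", "T", 0.123456789, 12),
            ("2", 50, "EAS", "A", 0.5, 50),
        ])
        assert self.roundtrip(panel, tmp_path) == panel

    def test_empty_panel_roundtrip(self, tmp_path):
        panel = make_panel(POPS3, [])
        back = self.roundtrip(panel, tmp_path)
        assert back == panel and back.populations == POPS3

    def test_duplicate_position_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_panel(make_panel(POPS3, [("1", 100, "AFR", "G", 0.05, 5)]), path)
        with open(path, "a") as fh:
            fh.write("1\t100\tEUR\tT\t0.1\t7\n")
        with pytest.raises(PanelFormatError, match="line 4"):
            read_panel(path)

    def test_unsorted_position_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        with open(path, "w") as fh:
            fh.write("#populations=AFR,EUR\n")
            fh.write("chrom\tpos\tspecific_pop\tspecific_allele\tmaf\tcount\n")
            fh.write("1\t500\tAFR\tG\t0.1\t5\n")
            fh.write("1\t100\tEUR\tT\t0.1\t5\n")
        with pytest.raises(PanelFormatError, match="line 4"):
            read_panel(path)

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tspecific_pop\tspecific_allele\tmaf\tcount\n")
            fh.write("1\tnot_an_int\tAFR\tG\t0.1\t5\n")
        with pytest.raises(PanelFormatError, match="line 2"):
            read_panel(path)

    def test_constructor_rejects_duplicates(self):
        with pytest.raises(PanelFormatError):
            make_panel(POPS3, [("1", 100, "AFR", "G", 0.05, 5),
                               ("1", 100, "EUR", "T", 0.1, 6)])
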
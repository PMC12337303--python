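"""Generator correctness: locus construction, gel selection, read emission
with ground truth, and the count/protein table simulators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prernaseq.diffstats import diff_test
from prernaseq.simulate import (
    SimConfig,
    SpeciesSpec,
    default_protein_design,
    make_locus,
    revcomp,
    simulate_count_table,
    simulate_homolog,
    simulate_protein_table,
    simulate_reads,
    size_select,
)


class TestLocus:
    def test_geometry(self):
        locus = make_locus(seed=1, upstream_len=100, mature_len=157, downstream_len=500)
        assert len(locus.seq) == 757
        assert locus.mature_start == 100
        assert locus.mature_end == 257

    def test_seed_determinism_and_divergence(self):
        a = make_locus(1)
        b = make_locus(1)
        c = make_locus(2)
        assert a.seq == b.seq
        assert a.seq != c.seq

    @pytest.mark.parametrize("kwargs", [
        {"upstream_len": 0}, {"mature_len": -3}, {"downstream_len": 0},
    ])
    def test_nonpositive_lengths_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_locus(1, **{"upstream_len": 100, "mature_len": 157,
                             "downstream_len": 500, **kwargs})


class TestSizeSelect:
    @staticmethod
    def _mix(lengths):
        n = len(lengths)
        return [SpeciesSpec(f"s{L}", L - 1, 1.0 / n) for L in lengths]

    def test_hard_window_thresholds(self):
        kept = size_select(self._mix([150, 159, 300, 450]), (155, 400), "hard")
        assert sorted(s.length_nt for s in kept) == [159, 300]
        assert sum(s.relative_abundance for s in kept) == pytest.approx(1.0)

    def test_hard_window_identity(self):
        kept = size_select(self._mix([200]), (160, 400), "hard")
        assert kept[0].relative_abundance == pytest.approx(1.0)

    def test_smeared_retains_midpoint_more_than_boundary(self):
        mid, edge = self._mix([280, 160])
        kept = size_select([mid, edge], (160, 400), "smeared")
        by_len = {s.length_nt: s.relative_abundance for s in kept}
        assert by_len[280] > by_len[160]

    def test_empty_survivor_set_is_an_error(self):
        with pytest.raises(ValueError, match="no species"):
            size_select(self._mix([100, 120]), (160, 400), "hard")

    def test_abundance_conservation(self):
        kept = size_select(self._mix([150, 170, 200, 390, 410]), (160, 400), "smeared")
        assert sum(s.relative_abundance for s in kept) == pytest.approx(1.0)


class TestSimulateReads:
    def test_zero_error_payload_is_revcomp_window(self, locus):
        t = locus.mature_start + 158
        sp = [SpeciesSpec("pre159", 158, 1.0)]
        reads, _ = simulate_reads(locus, sp, SimConfig(n_reads=10, error_rate=0.0, seed=1))
        expected = revcomp(locus.seq[t - 79 : t + 1])
        assert all(r.seq[16:] == expected for r in reads)

    def test_anchor_at_read_positions_13_to_15(self, locus, species):
        reads, _ = simulate_reads(locus, species, SimConfig(n_reads=200, seed=2))
        assert all(r.seq[13:16] == "ATG" for r in reads)

    def test_species_sampling_within_binomial_interval(self, locus):
        sp = [SpeciesSpec("a", 158, 0.5), SpeciesSpec("b", 271, 0.5)]
        _, truth = simulate_reads(locus, sp, SimConfig(n_reads=1000, seed=7))
        mols = truth.drop_duplicates("molecule_id")
        n = len(mols)
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n, 0.5)
        count_a = (mols["species"] == "a").sum()
        assert lo <= count_a <= hi

    def test_reads_fully_explained_by_ground_truth(self, clean_sim, locus):
        """Zero-error payloads must be reconstructable from (terminus,
        read_len, locus) alone."""
        reads, truth = clean_sim
        terminus = dict(zip(truth.read_id, truth.terminus))
        for r in reads[:500]:
            t = terminus[r.read_id]
            assert r.seq[16:] == revcomp(locus.seq[t - 79 : t + 1])

    def test_ground_truth_one_record_per_read(self, clean_sim):
        reads, truth = clean_sim
        assert len(truth) == len(reads)
        assert truth.read_id.is_unique

    def test_seed_determinism(self, locus, species):
        cfg = SimConfig(n_reads=300, error_rate=0.02, seed=9)
        r1, t1 = simulate_reads(locus, species, cfg)
        r2, t2 = simulate_reads(locus, species, cfg)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1, t2)

    def test_mod_positions_raise_mismatch_rate(self, locus):
        t = locus.mature_start + 158
        sp = [SpeciesSpec("pre159", 158, 1.0)]
        mod = frozenset({t - 40})
        cfg = SimConfig(n_reads=500, error_rate=0.0, mod_positions=mod, seed=3)
        reads, _ = simulate_reads(locus, sp, cfg)
        clean = revcomp(locus.seq[t - 79 : t + 1])
        # payload index 40 maps to locus position t - 40
        mismatches = sum(r.seq[16:][40] != clean[40] for r in reads)
        assert 0.2 < mismatches / len(reads) < 0.4


class TestCountTable:
    def test_null_p_values_roughly_uniform(self):
        table = simulate_count_table(n_features=1000, n_nuclear=0, n_pre=0, seed=7)
        res = diff_test(table)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_planted_lfc_recovered(self):
        effects = np.zeros(200)
        effects[0] = -3.0
        table = simulate_count_table(
            n_features=200, n_nuclear=0, n_pre=0, effects=effects, seed=3
        )
        assert diff_test(table)["log2FC"].iloc[0] == pytest.approx(-3.0, abs=0.5)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            simulate_count_table(replicates=1)
        with pytest.raises(ValueError):
            simulate_count_table(dispersion=0.0)

    def test_determinism(self):
        a = simulate_count_table(n_features=50, seed=4)
        b = simulate_count_table(n_features=50, seed=4)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestProteinTable:
    def test_determinism(self):
        a = simulate_protein_table(seed=11)
        b = simulate_protein_table(seed=11)
        pd.testing.assert_frame_equal(a.intensities, b.intensities)

    def test_default_design_category_sizes(self):
        design = default_protein_design(0)
        sizes = design.groupby("category").size()
        assert sizes["RP"] == 47 and sizes["initiation"] == 29
        assert sizes["elongation"] == 8 and sizes["RBP"] == 16 and sizes["RBF"] == 36
        assert (design.loc[design.category == "RBF", "release_site"] == "nucleus").sum() == 9

    def test_shifted_category_flagged_in_every_pairwise_test(self):
        """A -1 shift on one 47-member category against three null ones must
        be detected at alpha = 0.01 in each pairwise Welch test."""
        from prernaseq.diffstats import category_stats, volcano_classify

        rows = [
            (f"{cat}{i}", cat, -1.0 if cat == "RP" else 0.0, None, None, False)
            for cat in ("RP", "A", "B", "C")
            for i in range(47)
        ]
        design = pd.DataFrame(
            rows, columns=["protein", "category", "true_shift",
                           "release_site", "interaction", "moonlighting"],
        ).set_index("protein")
        for seed in range(5):
            pt = simulate_protein_table(design, seed=seed)
            lfc = volcano_classify(pt)["log2FC"]
            res = category_stats(lfc, pt.protein_meta["category"],
                                 pairs=[("RP", "A"), ("RP", "B"), ("RP", "C")])
            assert (res["pairwise"]["p"] < 0.01).all()


class TestHomolog:
    def test_mature_region_more_conserved(self, locus):
        hom = simulate_homolog(locus, seed=2)
        mature = locus.seq[locus.mature_start : locus.mature_end]
        # crude identity proxy: shared 15-mers are common for the mature
        # interval, rare for the spacer
        def shared_kmers(ref_seg):
            return sum(ref_seg[i : i + 15] in hom for i in range(0, len(ref_seg) - 15, 5))

        spacer = locus.seq[locus.mature_end : locus.mature_end + locus.mature_len]
        assert shared_kmers(mature) > shared_kmers(spacer)

    def test_determinism(self, locus):
        assert simulate_homolog(locus, seed=3) == simulate_homolog(locus, seed=3)
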
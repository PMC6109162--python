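"""Reynolds FST, PBS closed forms, window scan, peaks and gene assignment."""

import math

import numpy as np
import pandas as pd
import pytest

from andescan import pbs
from andescan.core_io import GeneAnnotation, allele_counts
from andescan.synthetic import GeneratorConfig, SweepSpec, \
    generate_neutral_genotypes, inject_sweep
from conftest import make_gm, make_samples


def reynolds_scalar(d1, c1, d2, c2):
    """Straight-line hand transcription of the biallelic Reynolds (1983)
    estimator, kept independent of the vectorized implementation."""
    p1, p2 = d1 / c1, d2 / c2
    n1, n2 = c1 / 2, c2 / 2
    a1 = 2 * p1 * (1 - p1)
    a2 = 2 * p2 * (1 - p2)
    het = n1 * a1 + n2 * a2
    denom = 4 * n1 * n2 * (n1 + n2 - 1)
    a = (p1 - p2) ** 2 - (n1 + n2) * het / denom
    b = het * (4 * n1 * n2 - n1 - n2) / denom
    return a / (a + b) if a + b > 0 else 0.0


class TestReynoldsFst:
    def test_identical_frequencies_clamp_to_zero(self):
        f = pbs.reynolds_fst(50, 100, 50, 100)
        assert f <= 0.0
        assert pbs.branch_transform(f) == 0.0

    def test_fixed_difference_is_one(self):
        assert pbs.reynolds_fst(100, 100, 0, 100) == pytest.approx(1.0)

    def test_half_vs_quarter_hand_value(self):
        # p1=0.5, p2=0.25, 50 diploids each, evaluated by hand:
        # het = 50*0.5 + 50*0.375 = 43.75, denom = 4*2500*99 = 990000
        # a = 0.0625 - 100*43.75/990000, b = 43.75*9900/990000 = 0.4375
        a = 0.0625 - 4375 / 990000
        expected = a / (a + 0.4375)
        assert pbs.reynolds_fst(50, 100, 25, 100) == pytest.approx(
            expected, abs=1e-15)

    def test_small_samples_are_missing(self):
        assert np.isnan(pbs.reynolds_fst(1, 1, 5, 10))

    def test_matches_scalar_oracle_on_random_counts(self):
        rng = np.random.default_rng(5)
        c1 = rng.integers(4, 200, 100)
        c2 = rng.integers(4, 200, 100)
        d1 = rng.integers(0, c1 + 1)
        d2 = rng.integers(0, c2 + 1)
        vec = pbs.reynolds_fst(d1, c1, d2, c2)
        for i in range(100):
            assert vec[i] == pytest.approx(
                reynolds_scalar(d1[i], c1[i], d2[i], c2[i]), abs=1e-12)


class TestPbsSnp:
    def test_symmetric_drift_closed_form(self):
        assert pbs.pbs_snp(0.5, 0.5, 0.0) == pytest.approx(-math.log(0.5),
                                                           abs=1e-12)

    def test_no_drift_is_zero(self):
        assert pbs.pbs_snp(0.0, 0.0, 0.0) == 0.0

    def test_outgroup_drift_gives_negative_pbs(self):
        expected = (2 * -math.log(0.9) - (-math.log(0.6))) / 2
        got = pbs.pbs_snp(0.1, 0.1, 0.4)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got < 0

    def test_missing_fst_propagates(self):
        assert np.isnan(pbs.pbs_snp(np.nan, 0.1, 0.1))

    def test_fst_one_stays_finite(self):
        assert np.isfinite(pbs.pbs_snp(1.0, 1.0, 0.0))


class TestPbsScan:
    def test_equals_straight_line_recomputation(self, bn_dataset):
        gm, st = bn_dataset
        table = pbs.pbs_scan(gm, st)
        counts = {g: allele_counts(gm, st, g)
                  for g in ("Andean", "Amazonian", "Mesoamerican")}
        for i in range(gm.n_variants):
            f_am = reynolds_scalar(counts["Andean"][0][i],
                                   counts["Andean"][1][i],
                                   counts["Mesoamerican"][0][i],
                                   counts["Mesoamerican"][1][i])
            f_aa = reynolds_scalar(counts["Andean"][0][i],
                                   counts["Andean"][1][i],
                                   counts["Amazonian"][0][i],
                                   counts["Amazonian"][1][i])
            f_ma = reynolds_scalar(counts["Mesoamerican"][0][i],
                                   counts["Mesoamerican"][1][i],
                                   counts["Amazonian"][0][i],
                                   counts["Amazonian"][1][i])
            t = [-math.log(1 - min(max(f, 0.0), 1 - 1e-9))
                 for f in (f_am, f_aa, f_ma)]
            expected = (t[0] + t[1] - t[2]) / 2
            assert table["pbs"].iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_group_label_swap_permutes_branches(self, bn_dataset):
        gm, st = bn_dataset
        swapped = st.frame.copy()
        swapped["group"] = swapped["group"].map(
            {"Andean": "Amazonian", "Amazonian": "Andean",
             "Mesoamerican": "Mesoamerican"})
        from andescan.core_io import SampleTable
        t1 = pbs.pbs_scan(gm, st)
        t2 = pbs.pbs_scan(gm, SampleTable(swapped))
        np.testing.assert_allclose(t2["fst_and_meso"], t1["fst_meso_amaz"],
                                   atol=1e-12)
        np.testing.assert_allclose(t2["fst_and_amaz"], t1["fst_and_amaz"],
                                   atol=1e-12)
        np.testing.assert_allclose(t2["fst_meso_amaz"], t1["fst_and_meso"],
                                   atol=1e-12)

    def test_polarization_invariance(self, bn_dataset):
        gm, st = bn_dataset
        flipped = gm.dosages.copy()
        called = flipped != -1
        flipped[called] = 2 - flipped[called]
        from andescan.core_io import GenotypeMatrix
        gm2 = GenotypeMatrix(gm.variants, flipped, gm.sample_ids)
        np.testing.assert_allclose(pbs.pbs_scan(gm2, st)["pbs"],
                                   pbs.pbs_scan(gm, st)["pbs"], atol=1e-12)


class TestWindowScan:
    @staticmethod
    def _snp_table(values, chrom="1"):
        n = len(values)
        return pd.DataFrame({
            "snp": [f"s{i}" for i in range(n)],
            "chrom": np.full(n, chrom, dtype=object),
            "pos": 1000 * np.arange(1, n + 1), "pbs": values})

    def test_window_count_arithmetic(self):
        w = pbs.window_scan(self._snp_table(np.zeros(100)))
        assert len(w) == 17  # (100 - 20) / 5 + 1

    def test_constant_values_give_constant_means(self):
        w = pbs.window_scan(self._snp_table(np.full(60, 0.3)))
        assert np.allclose(w["mean_pbs"], 0.3)

    def test_matches_brute_force_on_random_vector(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=1000)
        w = pbs.window_scan(self._snp_table(vals))
        brute = [vals[s:s + 20].sum() / 20 for s in range(0, 981, 5)]
        assert len(w) == len(brute)
        assert np.max(np.abs(w["mean_pbs"].to_numpy() - brute)) < 1e-12

    def test_windows_never_span_chromosomes(self):
        t1 = self._snp_table(np.zeros(30), chrom="1")
        t2 = self._snp_table(np.ones(15), chrom="2")
        both = pd.concat([t1, t2], ignore_index=True)
        w = pbs.window_scan(both)
        assert set(w["chrom"]) == {"1"}
        assert len(w) == 3

    def test_short_chromosome_yields_no_windows(self):
        w = pbs.window_scan(self._snp_table(np.zeros(19)))
        assert len(w) == 0


class TestCallPeaks:
    def test_outlier_fraction_matches_percentile_definition(self):
        rng = np.random.default_rng(3)
        snp_table = TestWindowScan._snp_table(rng.normal(size=5020))
        w = pbs.window_scan(snp_table)
        thresh = np.percentile(w["mean_pbs"], 99.5)
        n_out = int((w["mean_pbs"] > thresh).sum())
        assert abs(n_out / len(w) - 0.005) < 0.002

    def test_injected_extreme_sweep_is_peak_top_snp(self, bn_dataset):
        gm, st = bn_dataset
        swept = inject_sweep(gm, st, SweepSpec(500, andean_freq=1.0,
                                               lowland_freq=0.0), seed=1)
        table = pbs.pbs_scan(swept, st)
        # brute-force: target carries the maximum per-SNP PBS
        assert int(np.nanargmax(table["pbs"])) == 500
        w = pbs.window_scan(table)
        peaks = pbs.call_peaks(w, table, (99.5,))
        hit = peaks[(peaks["first_idx"] <= 500) & (peaks["last_idx"] >= 500)]
        assert len(hit) == 1
        assert hit["top_snp"].iloc[0] == gm.variants.id[500]
        span = table["pbs"].iloc[int(hit["first_idx"].iloc[0]):
                                 int(hit["last_idx"].iloc[0]) + 1]
        assert hit["top_pbs"].iloc[0] == pytest.approx(np.nanmax(span))

    def test_adjacent_outlier_windows_merge(self):
        snp_table = TestWindowScan._snp_table(np.zeros(3000))
        snp_table.loc[1500:1530, "pbs"] = 5.0
        w = pbs.window_scan(snp_table)
        peaks = pbs.call_peaks(w, snp_table, (99.5,))
        assert len(peaks) == 1  # one merged run, not several windows


class TestAssignNearestGene:
    ANNOT = GeneAnnotation(pd.DataFrame({
        "chrom": ["1", "1", "2"],
        "start": [1000, 5001, 100],
        "end": [2000, 6000, 200],
        "name": ["A", "B", "C"]}))

    def test_inside_gene(self):
        assert pbs.assign_nearest_gene("1", 1500, self.ANNOT) == ("A", 0.0)

    def test_nearest_by_distance(self):
        # 1-based 2101 -> base 2100: 101 bp right of A's last base (1999)
        gene, d = pbs.assign_nearest_gene("1", 2101, self.ANNOT)
        assert (gene, d) == ("A", 101.0)

    def test_equidistant_tie_breaks_to_smaller_start(self):
        # base 3500 is 1501 from both A (last base 1999) and B (start 5001)
        gene, d = pbs.assign_nearest_gene("1", 3501, self.ANNOT)
        assert (gene, d) == ("A", 1501.0)

    def test_chromosome_without_genes(self):
        gene, d = pbs.assign_nearest_gene("9", 100, self.ANNOT)
        assert gene == "none" and np.isinf(d)
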
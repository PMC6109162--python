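"""Synthetic genotype/haplotype generators and fixture round-trips."""

import numpy as np
import pytest
from scipy.stats import binomtest

from andescan import pbs
from andescan.core_io import group_frequencies, read_vcf, read_sample_table
from andescan.neutral_null import demographic_model
from andescan.synthetic import (GeneratorConfig, SweepSpec, _bn_draw,
                                branch_drift, generate_haplotypes,
                                generate_neutral_genotypes,
                                haplotypes_to_genotypes, inject_sweep,
                                make_gene_annotation, write_fixture)
from andescan.haplostats import ehh_at, ehh_curve


class TestGeneratorConfig:
    def test_default_sizes_match_study_groups(self):
        sizes = GeneratorConfig().group_sizes()
        assert sizes == {"Andean": 63, "Amazonian": 106, "Mesoamerican": 153}

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError, match="window"):
            GeneratorConfig(n_snps=10)


class TestBranchDrift:
    def test_no_drift_returns_parent_frequencies(self):
        p = np.array([0.2, 0.5, 0.9])
        assert np.array_equal(_bn_draw(p, 0.0, np.random.default_rng(0)), p)

    def test_constant_model_branch_f_values(self):
        f = branch_drift(demographic_model("constant"))
        # terminal sister branches: 480 gen at Ne 7000
        assert f["Andean"] == pytest.approx(1 - np.exp(-480 / 14000))
        assert f["Amazonian"] == f["Andean"]
        assert f["Mesoamerican"] == pytest.approx(1 - np.exp(-600 / 14000))
        assert 0 < f["internal"] < f["Andean"]

    def test_bottleneck_increases_amazonian_drift(self):
        f_const = branch_drift(demographic_model("constant"))
        f_bn = branch_drift(demographic_model("bottleneck"))
        assert f_bn["Amazonian"] > f_const["Amazonian"]


class TestGenerateNeutralGenotypes:
    def test_same_seed_reproduces_exactly(self):
        cfg = GeneratorConfig(n_snps=100, seed=5)
        gm1, _ = generate_neutral_genotypes(cfg)
        gm2, _ = generate_neutral_genotypes(cfg)
        assert np.array_equal(gm1.dosages, gm2.dosages)

    def test_sister_groups_are_closer_than_outgroup(self):
        # drift topology ((Andean, Amazonian), Mesoamerican): mean FST
        # between sisters must fall below mean FST to the outgroup
        cfg = GeneratorConfig(n_snps=5000, seed=6)
        gm, st = generate_neutral_genotypes(cfg)
        table = pbs.pbs_scan(gm, st)
        assert (table["fst_and_amaz"].mean()
                < table["fst_and_meso"].mean())
        assert (table["fst_and_amaz"].mean()
                < table["fst_meso_amaz"].mean())

    def test_coalescent_backend_passes_polymorphism_filter(self):
        from andescan.core_io import filter_polymorphic
        cfg = GeneratorConfig(n_snps=60, seed=7, backend="coalescent")
        gm, st = generate_neutral_genotypes(cfg)
        assert filter_polymorphic(gm, st).n_variants == 60

    def test_realized_frequencies_track_generating_frequencies(self):
        # aggregated over many SNPs the realized Andean frequency is an
        # unbiased estimate of the Balding-Nichols group frequency
        from andescan.synthetic import _variant_table, group_frequencies_bn
        cfg = GeneratorConfig(n_snps=3000, seed=8)
        gm, st = generate_neutral_genotypes(cfg)
        realized = group_frequencies(gm, st)["Andean"].to_numpy()
        # replay the generator's stream to recover the latent frequencies
        rng = np.random.default_rng(cfg.seed)
        _variant_table(cfg, rng)
        latent = group_frequencies_bn(cfg, rng)["Andean"]
        resid = realized - latent
        se = resid.std() / np.sqrt(len(resid))
        assert abs(resid.mean()) < 3 * se


class TestInjectSweep:
    def test_realized_andean_frequency_within_binomial_error(self, bn_dataset):
        gm, st = bn_dataset
        swept = inject_sweep(gm, st, SweepSpec(100, 0.40, 0.05), seed=3)
        count = int(swept.dosages[100, st.group_indices("Andean")].sum())
        assert binomtest(count, 126, 0.40).pvalue > 0.001

    def test_other_snps_untouched(self, bn_dataset):
        gm, st = bn_dataset
        swept = inject_sweep(gm, st, SweepSpec(100), seed=3)
        mask = np.ones(gm.n_variants, dtype=bool)
        mask[100] = False
        assert np.array_equal(swept.dosages[mask], gm.dosages[mask])

    def test_full_contrast_makes_target_the_global_maximum(self, bn_dataset):
        gm, st = bn_dataset
        swept = inject_sweep(gm, st, SweepSpec(100, 1.0, 0.0), seed=4)
        table = pbs.pbs_scan(swept, st)
        assert int(np.nanargmax(table["pbs"].to_numpy())) == 100

    def test_equal_frequencies_look_neutral(self, bn_dataset):
        gm, st = bn_dataset
        swept = inject_sweep(gm, st, SweepSpec(100, 0.3, 0.3), seed=5)
        freqs = group_frequencies(swept, st).iloc[100]
        assert np.all(np.abs(freqs - 0.3) < 0.15)

    def test_out_of_range_target_rejected(self, bn_dataset):
        gm, st = bn_dataset
        with pytest.raises(ValueError, match="target"):
            inject_sweep(gm, st, SweepSpec(10 ** 6), seed=0)


class TestGenerateHaplotypes:
    def test_deterministic_and_shapes(self):
        cfg = GeneratorConfig(n_snps=50, seed=9)
        h1 = generate_haplotypes(cfg)
        h2 = generate_haplotypes(cfg)
        assert h1["Andean"].n_haplotypes == 126
        assert h1["Mesoamerican"].n_haplotypes == 306
        assert np.array_equal(h1["Andean"].haplotypes,
                              h2["Andean"].haplotypes)

    def test_neutral_ehh_decays_toward_background(self):
        cfg = GeneratorConfig(n_snps=200, seed=10)
        h = generate_haplotypes(cfg)["Andean"]
        freqs = h.derived_freq()
        core = int(np.argmin(np.abs(freqs - 0.5)))
        curve = ehh_curve(h, core, 1, cutoff=0.0, max_gap=10 ** 9)
        side = curve.ehh_right if len(curve.ehh_right) > 10 else curve.ehh_left
        assert side[min(len(side) - 1, 40)] < 0.5

    def test_full_sweep_carriers_identical_over_core(self):
        cfg = GeneratorConfig(n_snps=41, seed=11, snp_spacing_bp=1000)
        spec = SweepSpec(20, andean_freq=1.0, lowland_freq=0.0,
                         core_length_bp=30_000)
        and_h = generate_haplotypes(cfg, spec, core_flip_rate=0.0)["Andean"]
        pos = and_h.positions
        half = spec.core_length_bp // 2
        inside = np.flatnonzero(np.abs(pos - pos[20]) <= half)
        # every carrier shares the founder: EHH = 1 across the whole core
        assert ehh_at(and_h, 20, 1, int(inside[0])) == 1.0
        assert ehh_at(and_h, 20, 1, int(inside[-1])) == 1.0

    def test_oversized_core_rejected(self):
        cfg = GeneratorConfig(n_snps=30, seed=12, snp_spacing_bp=100)
        with pytest.raises(ValueError, match="core"):
            generate_haplotypes(cfg, SweepSpec(
                15, core_length_bp=10 ** 9), core_flip_rate=0.0)

    def test_sweep_raises_xpehh_at_target_across_seeds(self):
        # directional check: the raw Andean-vs-lowland log-ratio of iHH at
        # the target is positive in (almost) every replicate
        from andescan.haplostats import _site_ihh
        wins = 0
        for seed in range(20):
            cfg = GeneratorConfig(n_snps=120, seed=40 + seed)
            haps = generate_haplotypes(cfg, SweepSpec(60))
            ihh_t = _site_ihh(haps["Andean"], 60, None, 0.05, 200_000)[0]
            ihh_r = _site_ihh(haps["Amazonian"], 60, None, 0.05, 200_000)[0]
            wins += int(np.log(ihh_t / ihh_r) > 0)
        assert wins >= 15

    def test_carrier_fraction_matches_spec_frequency(self):
        cfg = GeneratorConfig(n_snps=50, seed=13)
        haps = generate_haplotypes(
            cfg, SweepSpec(25, 0.40, 0.05, core_length_bp=50_000))
        and_freq = haps["Andean"].derived_freq()[25]
        assert and_freq == pytest.approx(round(0.40 * 126) / 126)
        low_freq = haps["Mesoamerican"].derived_freq()[25]
        assert low_freq == pytest.approx(round(0.05 * 306) / 306)


class TestFixtureRoundTrip:
    def test_files_readable_and_vcf_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(n_snps=40, seed=14)
        haps = generate_haplotypes(cfg)
        gm, st, phased = haplotypes_to_genotypes(haps, cfg)
        genes = make_gene_annotation(gm, every=20, span_snps=5,
                                     sweep_index=20)
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        p1 = write_fixture(d1, cfg, gm, st, genes, phased=phased)
        p2 = write_fixture(d2, cfg, gm, st, genes, phased=phased)
        assert (d1 / "genotypes.vcf").read_bytes() == \
            (d2 / "genotypes.vcf").read_bytes()
        back = read_vcf(p1["vcf"])
        assert np.array_equal(back.dosages, gm.dosages)
        st_back = read_sample_table(p1["samples"])
        assert st_back.group_counts() == st.group_counts()

    def test_gene_over_sweep_target_is_assigned(self, tmp_path):
        cfg = GeneratorConfig(n_snps=40, seed=15)
        gm, st = generate_neutral_genotypes(cfg)
        genes = make_gene_annotation(gm, sweep_index=20, sweep_gene="SWP")
        gene, dist = pbs.assign_nearest_gene(
            gm.variants.chrom[20], int(gm.variants.pos[20]), genes)
        assert gene == "SWP" and dist == 0.0
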
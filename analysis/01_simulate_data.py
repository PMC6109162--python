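#!/usr/bin/env python
"""Simulate the study fixture: three-group SNP-array genotypes with an
Andean-branch sweep at the reported frequency contrast (0.40 vs 0.05).

Writes a phased VCF, sample table, gene BED and manifest under
results/fixture/, plus a genotype-view fixture with the frequency-level
sweep injection used by the PBS/bootstrap stages.
"""

from pathlib import Path

import numpy as np

from andescan.core_io import group_frequencies
from andescan.synthetic import (GeneratorConfig, SweepSpec,
                                generate_haplotypes,
                                generate_neutral_genotypes,
                                haplotypes_to_genotypes, inject_sweep,
                                make_gene_annotation, write_fixture)

SEED = 20180824
N_SNPS = 2000
TARGET = 1000

out = Path("results/fixture")
cfg = GeneratorConfig(n_snps=N_SNPS, seed=SEED)
spec = SweepSpec(TARGET, andean_freq=0.40, lowland_freq=0.05)

# haplotype view: shared-core sweep for the EHH-family statistics
haps = generate_haplotypes(cfg, spec)
gm_h, st, phased = haplotypes_to_genotypes(haps, cfg)
genes = make_gene_annotation(gm_h, sweep_index=TARGET)
paths = write_fixture(out, cfg, gm_h, st, genes, phased=phased)

# genotype view: frequency-level injection for PBS / bootstrap / IDW
gm, st2 = generate_neutral_genotypes(cfg)
gm = inject_sweep(gm, st2, spec, seed=SEED + 1)
write_fixture(out / "genotype_view", cfg, gm, st2, genes)

freqs = group_frequencies(gm, st2).iloc[TARGET]
print(f"fixture written to {out}")
print(f"samples per group: {st.group_counts()}")
print(f"target SNP {gm.variants.id[TARGET]} derived frequencies: "
      + ", ".join(f"{g}={freqs[g]:.3f}" for g in freqs.index))
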
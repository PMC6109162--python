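#!/usr/bin/env python
"""EHH-family statistics on the phased fixture: Andean iHS (bin-standardized)
and XP-EHH of Andeans against each lowland group, with empirical p-values.

Reads the phased VCF from results/fixture/ and writes TSVs under
results/haplostats/.
"""

from pathlib import Path

import numpy as np

from andescan.core_io import read_phased_haplotypes, read_sample_table
from andescan.haplostats import ihs_scores, standardize_ihs, xpehh_pvalue, xpehh_scores
from andescan.pipeline import _split_haplotypes

TARGET = "snp001000"

fix = Path("results/fixture")
out = Path("results/haplostats")
out.mkdir(parents=True, exist_ok=True)

gm, phased = read_phased_haplotypes(fix / "genotypes.vcf")
st = read_sample_table(fix / "samples.tsv")
haps = _split_haplotypes(gm, st, phased)
ti = int(np.flatnonzero(gm.variants.id == TARGET)[0])

for ref in ("Mesoamerican", "Amazonian"):
    sc = xpehh_pvalue(xpehh_scores(haps["Andean"], haps[ref]))
    sc.to_csv(out / f"xpehh_andean_vs_{ref.lower()}.tsv", sep="\t",
              index=False)
    row = sc[sc["snp_index"] == ti].iloc[0]
    print(f"XP-EHH Andean vs {ref} at {TARGET}: "
          f"std score {row['xpehh_std']:.3f}, p = {row['pvalue']:.4f}")

ihs = standardize_ihs(ihs_scores(haps["Andean"]))
ihs.to_csv(out / "ihs_andean.tsv", sep="\t", index=False)
z = ihs["ihs_std"].dropna()
print(f"Andean iHS: {len(z)} scored SNPs, mean {z.mean():.3f}, "
      f"sd {z.std():.3f} (bin-standardized, approximately Gaussian)")
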
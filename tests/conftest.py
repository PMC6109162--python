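import numpy as np
import pandas as pd
import pytest

from andescan.core_io import GenotypeMatrix, SampleTable, VariantTable
from andescan.synthetic import GeneratorConfig, generate_neutral_genotypes


def make_variants(n, chrom="1", start=1000, spacing=1000):
    pos = start + spacing * np.arange(n)
    return VariantTable(
        np.full(n, chrom, dtype=object), pos,
        np.array([f"s{i}" for i in range(n)], dtype=object),
        np.full(n, "A", dtype=object), np.full(n, "G", dtype=object))


def make_samples(n_per_group=2):
    rows = []
    for g, lat, lon, alt in (("Andean", -16.0, -68.0, 4100.0),
                             ("Amazonian", -5.0, -63.0, 120.0),
                             ("Mesoamerican", 18.0, -95.0, 1500.0)):
        for i in range(n_per_group):
            rows.append({"sample_id": f"{g[:3]}{i}", "population": g + "_pop",
                         "group": g, "latitude": lat, "longitude": lon,
                         "altitude_m": alt})
    return SampleTable(pd.DataFrame(rows))


def make_gm(dosage_rows, sample_table):
    dos = np.asarray(dosage_rows, dtype=np.int8)
    return GenotypeMatrix(make_variants(dos.shape[0]), dos,
                          list(sample_table.frame["sample_id"]))


@pytest.fixture(scope="session")
def bn_dataset():
    """1,000-SNP neutral Balding-Nichols dataset at the study sample sizes."""
    cfg = GeneratorConfig(n_snps=1000, seed=42)
    gm, st = generate_neutral_genotypes(cfg)
    return gm, st
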
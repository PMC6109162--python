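"""Data model and readers for the three-group SNP selection scan.

Genotypes are stored as derived-allele dosages (0/1/2, -1 for missing) over
variants x samples.  Samples belong to named populations which are in turn
assigned to one of three continental groups: the high-altitude test group
(Andean) and two lowland groups (Amazonian, Mesoamerican).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("Andean", "Amazonian", "Mesoamerican")
MISSING = -1


@dataclass
class VariantTable:
    """Per-SNP metadata: location, identifier and allele polarization.

    ``ancestral_allele``/``derived_allele`` hold single bases; a SNP whose
    polarization is unknown carries ``"N"`` in both and is excluded from
    statistics that need ancestral/derived labels (iHS) but not from PBS.
    """

    chrom: np.ndarray          # str array
    pos: np.ndarray            # 1-based int positions
    id: np.ndarray             # unique SNP ids
    ancestral_allele: np.ndarray
    derived_allele: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.id = np.asarray(self.id, dtype=object)
        self.ancestral_allele = np.asarray(self.ancestral_allele, dtype=object)
        self.derived_allele = np.asarray(self.derived_allele, dtype=object)
        if len(set(self.id)) != len(self.id):
            raise ValueError("SNP ids must be unique")
        polarized = self.ancestral_allele != "N"
        if np.any((self.ancestral_allele == self.derived_allele) & polarized):
            raise ValueError("ancestral and derived alleles must differ")
        for ch in pd.unique(self.chrom):
            p = self.pos[self.chrom == ch]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"positions must be strictly increasing on {ch}")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def is_polarized(self) -> np.ndarray:
        return np.asarray(self.ancestral_allele != "N")

    def take(self, idx: np.ndarray) -> "VariantTable":
        return VariantTable(self.chrom[idx], self.pos[idx], self.id[idx],
                            self.ancestral_allele[idx],
                            self.derived_allele[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "pos": self.pos, "id": self.id,
            "ancestral": self.ancestral_allele,
            "derived": self.derived_allele,
        })


@dataclass
class GenotypeMatrix:
    """Derived-allele dosages (variants x samples), -1 = missing."""

    variants: VariantTable
    dosages: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (variants x samples)")
        if self.dosages.shape[0] != len(self.variants):
            raise ValueError("dosage rows must match variant count")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")
        if self.sample_ids and len(self.sample_ids) != self.dosages.shape[1]:
            raise ValueError("sample_ids length must match dosage columns")

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.variants.take(idx), self.dosages[idx],
                              self.sample_ids)


@dataclass
class SampleTable:
    """Sample -> population -> group assignment with geography."""

    frame: pd.DataFrame  # sample_id, population, group, latitude, longitude, altitude_m

    REQUIRED = ("sample_id", "population", "group",
                "latitude", "longitude", "altitude_m")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        if len(self.frame) == 0:
            raise ValueError("sample table is empty")
        dup = self.frame["sample_id"].duplicated()
        if dup.any():
            raise ValueError(
                "duplicated sample ids: "
                + ", ".join(self.frame.loc[dup, "sample_id"].astype(str)))
        bad = ~self.frame["group"].isin(GROUPS)
        if bad.any():
            rows = self.frame.loc[bad, ["sample_id", "group"]]
            raise ValueError(f"unknown group labels:\n{rows.to_string()}")
        if (self.frame["altitude_m"].dropna() < 0).any():
            raise ValueError("altitude_m must be >= 0")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def group_indices(self, group: str) -> np.ndarray:
        """Column indices (sample order) of the samples in ``group``."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return np.flatnonzero((self.frame["group"] == group).to_numpy())

    def population_indices(self, population: str) -> np.ndarray:
        return np.flatnonzero(
            (self.frame["population"] == population).to_numpy())

    def group_counts(self) -> dict[str, int]:
        return {g: int((self.frame["group"] == g).sum()) for g in GROUPS}

    def populations_in_group(self, group: str) -> list[str]:
        sub = self.frame[self.frame["group"] == group]
        return list(dict.fromkeys(sub["population"]))


@dataclass
class GeneAnnotation:
    """Gene intervals, half-open 0-based as in BED, sorted by (chrom, start)."""

    frame: pd.DataFrame  # chrom, start, end, name

    def __post_init__(self) -> None:
        f = self.frame
        if (f["start"] >= f["end"]).any():
            raise ValueError("gene intervals need start < end")
        self.frame = f.sort_values(["chrom", "start"],
                                   kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers / writers

def read_vcf(path, ancestral_table: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into derived-allele dosages.

    Polarization uses the ``AA`` INFO tag, overridden per SNP by
    ``ancestral_table`` (columns ``id``, ``ancestral``) when given.  When the
    ancestral allele equals ALT the dosage is folded (2 - ALT count).  SNPs
    with no ancestral assignment keep REF->ALT orientation but are marked
    unpolarized (``"N"`` alleles).  Multi-allelic records are skipped with a
    warning.
    """
    from cyvcf2 import VCF

    override = {}
    if ancestral_table is not None:
        override = dict(zip(ancestral_table["id"], ancestral_table["ancestral"]))

    chroms, poss, ids, ancs, ders, rows = [], [], [], [], [], []
    vcf = VCF(str(path), gts012=True)
    try:
        samples = list(vcf.samples)
        for rec in vcf:
            if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
                logger.warning("skipping non-biallelic-SNP record at %s:%d",
                               rec.CHROM, rec.POS)
                continue
            ref, alt = rec.REF, rec.ALT[0]
            snp_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
            aa = override.get(snp_id, rec.INFO.get("AA"))
            if isinstance(aa, str):
                aa = aa.upper()
            # gts012: 0/1/2 = ALT dosage, 3 = missing
            alt_dose = np.asarray(rec.gt_types, dtype=np.int8)
            miss = alt_dose == 3
            if aa == ref:
                anc, der, dose = ref, alt, alt_dose
            elif aa == alt:
                anc, der, dose = alt, ref, 2 - alt_dose
            else:
                if aa is not None:
                    logger.warning(
                        "AA=%s matches neither allele at %s; left unpolarized",
                        aa, snp_id)
                anc, der, dose = "N", "N", alt_dose
            dose = dose.copy()
            dose[miss] = MISSING
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            ids.append(snp_id)
            ancs.append(anc)
            ders.append(der)
            rows.append(dose)
    finally:
        vcf.close()
    vt = VariantTable(np.array(chroms, dtype=object), np.array(poss),
                      np.array(ids, dtype=object),
                      np.array(ancs, dtype=object),
                      np.array(ders, dtype=object))
    dosages = (np.vstack(rows) if rows
               else np.empty((0, len(samples)), dtype=np.int8))
    return GenotypeMatrix(vt, dosages, samples)


def write_vcf(path, gm: GenotypeMatrix, phased: np.ndarray | None = None) -> None:
    """Write a GenotypeMatrix as VCF v4.2 with the AA INFO tag.

    ``phased`` (optional) carries haplotype alleles (variants x 2*samples);
    when given, genotypes are written phased (``a|b``) so the file round-trips
    through haplotype readers.  Derived alleles are written as ALT.
    """
    vt = gm.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,'
                 'Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for ch in dict.fromkeys(vt.chrom):
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for i in range(gm.n_variants):
            anc = vt.ancestral_allele[i]
            der = vt.derived_allele[i]
            ref, alt = (anc, der) if anc != "N" else ("A", "G")
            info = f"AA={anc}" if anc != "N" else "."
            if phased is not None:
                gts = [f"{phased[i, 2 * j]}|{phased[i, 2 * j + 1]}"
                       for j in range(gm.n_samples)]
            else:
                codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [codes[int(d)] for d in gm.dosages[i]]
            fh.write(f"{vt.chrom[i]}\t{vt.pos[i]}\t{vt.id[i]}\t{ref}\t{alt}"
                     f"\t.\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n")


def read_phased_haplotypes(path, ancestral_table: pd.DataFrame | None = None
                           ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Read a phased VCF into (GenotypeMatrix, haplotype allele matrix).

    The second return value is a (variants x 2*samples) 0/1 matrix of
    derived-allele indicators with sample j's haplotypes in columns 2j and
    2j+1.  Records with unphased or missing genotypes raise, since the
    haplotype statistics require fully phased input.
    """
    from cyvcf2 import VCF

    gm = read_vcf(path, ancestral_table=ancestral_table)
    # re-walk records for phase information
    vcf = VCF(str(path))
    kept = set(gm.variants.id)
    by_id = {gm.variants.id[i]: i for i in range(len(gm.variants))}
    hap = np.zeros((gm.n_variants, 2 * gm.n_samples), dtype=np.uint8)
    try:
        for rec in vcf:
            snp_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
            if snp_id not in kept:
                continue
            i = by_id[snp_id]
            alt_is_derived = gm.variants.derived_allele[i] != rec.REF
            for j, gt in enumerate(rec.genotypes):
                a, b, phased = gt[0], gt[1], gt[-1]
                if a < 0 or b < 0 or not phased:
                    raise ValueError(
                        f"unphased or missing genotype at {snp_id}, "
                        f"sample {j}: haplotype statistics need phased data")
                if not alt_is_derived:
                    a, b = 1 - a, 1 - b
                hap[i, 2 * j] = a
                hap[i, 2 * j + 1] = b
    finally:
        vcf.close()
    return gm, hap


def read_sample_table(path) -> SampleTable:
    frame = pd.read_csv(path, sep="\t")
    return SampleTable(frame)


def write_sample_table(path, st: SampleTable) -> None:
    st.frame.to_csv(path, sep="\t", index=False)


def read_bed(path) -> GeneAnnotation:
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["chrom", "start", "end", "name"],
                        dtype={"chrom": str})
    return GeneAnnotation(frame)


def write_bed(path, ga: GeneAnnotation) -> None:
    ga.frame.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# filters and counts

def allele_counts(gm: GenotypeMatrix, st: SampleTable,
                  group: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (derived-allele count, called chromosome count) for a group.

    Missing genotypes shrink the chromosome count SNP-wise; a SNP with all
    genotypes missing yields (0, 0).
    """
    idx = st.group_indices(group)
    if idx.size == 0:
        raise ValueError(f"group {group!r} has no samples")
    sub = gm.dosages[:, idx]
    called = sub != MISSING
    derived = np.where(called, sub, 0).sum(axis=1).astype(np.int64)
    chroms = 2 * called.sum(axis=1).astype(np.int64)
    return derived, chroms


def group_frequencies(gm: GenotypeMatrix, st: SampleTable) -> pd.DataFrame:
    """Pooled derived-allele frequency per group (NaN where uncalled)."""
    out = {}
    for g in GROUPS:
        d, n = allele_counts(gm, st, g)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[g] = np.where(n > 0, d / np.maximum(n, 1), np.nan)
    return pd.DataFrame(out)


def filter_polymorphic(gm: GenotypeMatrix, st: SampleTable,
                       min_groups: int = 2) -> GenotypeMatrix:
    """Keep SNPs segregating (0 < derived freq < 1) in >= ``min_groups`` groups."""
    n_seg = np.zeros(gm.n_variants, dtype=int)
    for g in GROUPS:
        d, n = allele_counts(gm, st, g)
        n_seg += (d > 0) & (d < n)
    keep = np.flatnonzero(n_seg >= min_groups)
    if len(keep) < gm.n_variants:
        logger.info("polymorphism filter: kept %d of %d SNPs",
                    len(keep), gm.n_variants)
    return gm.take_variants(keep)
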
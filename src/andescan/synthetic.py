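"""Synthetic three-group genotype and haplotype fixtures.

Emulates the structure the selection scan assumes: 63 Andean highlanders and
two lowland groups (106 Amazonian, 153 Mesoamerican) genotyped at
SNP-array-like common variants, with hierarchical drift on the
((Andean, Amazonian), Mesoamerican) topology and an optional Andean-specific
sweep (derived frequency ~0.40 in Andeans vs ~0.05 in both lowland groups,
the magnitude of the reported candidate loci) carrying an extended shared
core haplotype.

Two genotype backends share one interface:

* ``balding_nichols`` (fast default) — ancestral frequency drawn from a
  Beta(0.8, 0.8) spectrum truncated to [0.05, 0.95] (mimicking array
  ascertainment for common SNPs), then per-branch drift with
  ``F = 1 - exp(-t / 2 Ne)`` integrated along each branch of the chosen
  demographic model;
* ``coalescent`` — per-SNP genealogy + single mutation from the native
  structured-coalescent simulator, with the scan's polymorphism filter
  applied at generation time (so fixtures are distributed exactly as the
  simulation null).

Haplotypes are built by mosaic copying from a founder panel (geometric block
lengths), which produces background LD that decays with distance; sweep
carriers share one founder haplotype over the core length with sparse
mutations.  This deliberately does not model recombination genealogically —
it is sufficient to give the EHH statistics the directional structure a hard
sweep creates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_io import (GROUPS, GeneAnnotation, GenotypeMatrix, SampleTable,
                      VariantTable, write_bed, write_sample_table, write_vcf)
from .haplostats import HaplotypeSet
from .neutral_null import (DemographicModel, demographic_model,
                           mutation_node, sample_coalescent_tree)

# population name -> (group, latitude, longitude, altitude_m, n_samples)
# geography loosely follows Andean altiplano, Amazon basin and Mesoamerica;
# sub-population sizes sum to the 63/106/153 group totals.
DEFAULT_POPULATIONS = {
    "Aymara":    ("Andean", -16.5, -68.2, 4100.0, 35),
    "Quechua":   ("Andean", -13.5, -71.9, 4300.0, 28),
    "Karitiana": ("Amazonian", -9.9, -63.3, 150.0, 30),
    "Surui":     ("Amazonian", -11.0, -61.0, 200.0, 26),
    "Ticuna":    ("Amazonian", -4.0, -70.0, 90.0, 28),
    "Piapoco":   ("Amazonian", 3.8, -68.0, 110.0, 22),
    "Maya":      ("Mesoamerican", 20.7, -89.6, 20.0, 44),
    "Mixe":      ("Mesoamerican", 17.0, -96.0, 1700.0, 30),
    "Mixtec":    ("Mesoamerican", 17.3, -97.7, 1900.0, 33),
    "Kaqchikel": ("Mesoamerican", 14.6, -90.7, 2100.0, 26),
    "Tepehuano": ("Mesoamerican", 23.3, -104.9, 2200.0, 20),
}


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic fixtures."""

    n_snps: int = 5000
    populations: dict = field(
        default_factory=lambda: dict(DEFAULT_POPULATIONS))
    model: str = "constant"            # demographic preset label
    backend: str = "balding_nichols"   # or "coalescent"
    spectrum_beta: tuple[float, float] = (0.8, 0.8)
    spectrum_bounds: tuple[float, float] = (0.05, 0.95)
    snp_spacing_bp: int = 5000
    chrom: str = "1"
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 20:
            raise ValueError("n_snps must cover at least one 20-SNP window")
        sizes = self.group_sizes()
        if any(v < 1 for v in sizes.values()):
            raise ValueError("every group needs at least one sample")

    def group_sizes(self) -> dict[str, int]:
        out = {g: 0 for g in GROUPS}
        for _, (group, _, _, _, n) in self.populations.items():
            out[group] += n
        return out

    def demographic(self) -> DemographicModel:
        return demographic_model(self.model)


@dataclass
class SweepSpec:
    """An injected Andean-branch selected locus."""

    target_index: int
    andean_freq: float = 0.40
    lowland_freq: float = 0.05
    core_length_bp: int = 300_000

    def __post_init__(self) -> None:
        for f in (self.andean_freq, self.lowland_freq):
            if not 0.0 <= f <= 1.0:
                raise ValueError("sweep frequencies must lie in [0, 1]")


# ---------------------------------------------------------------------------
# branch drift parameters

def branch_drift(model: DemographicModel) -> dict[str, float]:
    """Per-branch Balding-Nichols F = 1 - exp(-t / 2 Ne(t) integrated).

    Branches: terminal Andean and Amazonian (present to the sister split),
    terminal Mesoamerican (present to the root split), and the internal
    Andean+Amazonian ancestor (sister split to root split, taking the
    post-split Ne of the merged lineage).
    """
    t_sister = model.merges[0][0]
    t_root = model.merges[1][0]

    def integral(pop: str, lo: float, hi: float) -> float:
        total = 0.0
        t = lo
        while t < hi - 1e-9:
            ne = model.ne_at(pop, t)
            nxt = hi
            for start, _ in model.populations[pop]:
                if t < start < nxt:
                    nxt = start
            total += (nxt - t) / (2.0 * ne)
            t = nxt
        return total

    f = {
        "Andean": 1.0 - np.exp(-integral("Andean", 0.0, t_sister)),
        "Amazonian": 1.0 - np.exp(-integral("Amazonian", 0.0, t_sister)),
        "Mesoamerican": 1.0 - np.exp(-integral("Mesoamerican", 0.0, t_root)),
        "internal": 1.0 - np.exp(-integral("Andean", t_sister, t_root)),
    }
    for name, val in f.items():
        if not 0.0 <= val < 1.0:
            raise ValueError(f"infeasible drift F={val} on branch {name}")
    return f


def _bn_draw(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols daughter frequencies Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    if f < 1e-12:
        return p.copy()
    lam = (1.0 - f) / f
    return rng.beta(np.maximum(p * lam, 1e-12),
                    np.maximum((1.0 - p) * lam, 1e-12))


def _sample_table(cfg: GeneratorConfig) -> SampleTable:
    rows = []
    for pop, (group, lat, lon, alt, n) in cfg.populations.items():
        for i in range(n):
            rows.append({"sample_id": f"{pop}_{i:03d}", "population": pop,
                         "group": group, "latitude": lat, "longitude": lon,
                         "altitude_m": alt})
    return SampleTable(pd.DataFrame(rows))


def _variant_table(cfg: GeneratorConfig, rng: np.random.Generator) -> VariantTable:
    pos = np.cumsum(rng.integers(1, 2 * cfg.snp_spacing_bp,
                                 size=cfg.n_snps)) + 10_000
    bases = np.array(list("ACGT"), dtype=object)
    anc_idx = rng.integers(0, 4, size=cfg.n_snps)
    der_idx = (anc_idx + rng.integers(1, 4, size=cfg.n_snps)) % 4
    return VariantTable(
        np.full(cfg.n_snps, cfg.chrom, dtype=object), pos,
        np.array([f"snp{i:06d}" for i in range(cfg.n_snps)], dtype=object),
        bases[anc_idx], bases[der_idx])


def group_frequencies_bn(cfg: GeneratorConfig,
                         rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Hierarchical Balding-Nichols group frequencies for every SNP."""
    a, b = cfg.spectrum_beta
    lo, hi = cfg.spectrum_bounds
    p0 = lo + (hi - lo) * rng.beta(a, b, size=cfg.n_snps)
    f = branch_drift(cfg.demographic())
    p_anc = _bn_draw(p0, f["internal"], rng)
    return {
        "Andean": _bn_draw(p_anc, f["Andean"], rng),
        "Amazonian": _bn_draw(p_anc, f["Amazonian"], rng),
        "Mesoamerican": _bn_draw(p0, f["Mesoamerican"], rng),
    }


def _genotypes_from_freqs(freqs: dict[str, np.ndarray], st: SampleTable,
                          rng: np.random.Generator) -> np.ndarray:
    n_snps = len(next(iter(freqs.values())))
    dos = np.zeros((n_snps, len(st)), dtype=np.int8)
    for g in GROUPS:
        idx = st.group_indices(g)
        dos[:, idx] = rng.binomial(
            2, freqs[g][:, None], size=(n_snps, len(idx))).astype(np.int8)
    return dos


def _coalescent_dosages(cfg: GeneratorConfig, st: SampleTable,
                        rng: np.random.Generator) -> np.ndarray:
    """One filtered genealogy + mutation per SNP; haploids paired randomly
    within their population into diploids."""
    model = cfg.demographic()
    sizes = cfg.group_sizes()
    hap_sizes = {g: 2 * sizes[g] for g in GROUPS}
    size_arr = np.array([hap_sizes[g] for g in GROUPS])
    dos = np.zeros((cfg.n_snps, len(st)), dtype=np.int8)
    col_of_group = {g: st.group_indices(g) for g in GROUPS}
    for s in range(cfg.n_snps):
        while True:
            tree = sample_coalescent_tree(model, hap_sizes, rng)
            node = mutation_node(tree, rng)
            leaves = tree.leaves_below(node)
            counts = np.bincount(tree.leaf_pop[leaves],
                                 minlength=len(GROUPS))
            seg = (counts > 0) & (counts < size_arr)
            if seg.sum() >= 2:
                break
        carrier = np.zeros(tree.n_leaves, dtype=np.int8)
        carrier[leaves] = 1
        offset = 0
        for gi, g in enumerate(GROUPS):
            k = hap_sizes[g]
            dose = carrier[offset:offset + k]
            dos[s, col_of_group[g]] = dose[0::2] + dose[1::2]
            offset += k
    return dos


def generate_neutral_genotypes(cfg: GeneratorConfig) -> tuple[GenotypeMatrix,
                                                              SampleTable]:
    """Neutral three-group genotypes under the configured backend."""
    rng = np.random.default_rng(cfg.seed)
    st = _sample_table(cfg)
    vt = _variant_table(cfg, rng)
    if cfg.backend == "balding_nichols":
        freqs = group_frequencies_bn(cfg, rng)
        dos = _genotypes_from_freqs(freqs, st, rng)
    elif cfg.backend == "coalescent":
        dos = _coalescent_dosages(cfg, st, rng)
    else:
        raise ValueError(f"unknown backend {cfg.backend!r}")
    if cfg.missing_rate > 0:
        miss = rng.random(dos.shape) < cfg.missing_rate
        dos[miss] = -1
    return GenotypeMatrix(vt, dos, list(st.frame["sample_id"])), st


def inject_sweep(gm: GenotypeMatrix, st: SampleTable, spec: SweepSpec,
                 seed: int = 0) -> GenotypeMatrix:
    """Redraw the target SNP's genotypes at the sweep frequencies.

    Andean samples are drawn binomially at ``andean_freq``, both lowland
    groups at ``lowland_freq``; every other SNP is untouched.
    """
    if not 0 <= spec.target_index < gm.n_variants:
        raise ValueError("sweep target outside the SNP range")
    rng = np.random.default_rng(seed)
    dos = gm.dosages.copy()
    for g in GROUPS:
        freq = spec.andean_freq if g == "Andean" else spec.lowland_freq
        idx = st.group_indices(g)
        dos[spec.target_index, idx] = rng.binomial(
            2, freq, size=len(idx)).astype(np.int8)
    return GenotypeMatrix(gm.variants, dos, gm.sample_ids)


# ---------------------------------------------------------------------------
# haplotypes

def _mosaic_panel(n_hap: int, freqs: np.ndarray, panel_size: int,
                  switch_prob: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Mosaic-copying haplotypes: LD from shared panel blocks.

    A founder panel is drawn per SNP at the group frequencies; each output
    haplotype copies one panel member and switches to a random member with
    probability ``switch_prob`` per SNP step (geometric block lengths).
    """
    n_snps = len(freqs)
    panel = (rng.random((panel_size, n_snps)) < freqs).astype(np.uint8)
    donors = np.empty((n_hap, n_snps), dtype=np.int64)
    donors[:, 0] = rng.integers(panel_size, size=n_hap)
    switches = rng.random((n_hap, n_snps)) < switch_prob
    new_donor = rng.integers(panel_size, size=(n_hap, n_snps))
    for j in range(1, n_snps):
        donors[:, j] = np.where(switches[:, j], new_donor[:, j],
                                donors[:, j - 1])
    return panel[donors, np.arange(n_snps)]


def generate_haplotypes(cfg: GeneratorConfig, spec: SweepSpec | None = None,
                        panel_size: int = 24,
                        mean_block_snps: float = 15.0,
                        core_flip_rate: float = 0.002) -> dict[str, HaplotypeSet]:
    """Phased haplotypes per group, optionally with an Andean sweep core.

    Neutral background: mosaic copying from a per-group founder panel with
    geometric block lengths (mean ``mean_block_snps`` SNPs), so haplotype
    homozygosity decays with distance.  With a sweep, a fraction
    ``andean_freq`` of Andean haplotypes shares a single founder haplotype
    (derived at the target) across the core window, with sparse mutations;
    lowland carriers at ``lowland_freq`` get the derived allele without an
    extended core.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    vt_rng = np.random.default_rng(cfg.seed)
    positions = _variant_table(cfg, vt_rng).pos
    freqs = group_frequencies_bn(cfg, np.random.default_rng(cfg.seed + 2))
    switch_prob = 1.0 / mean_block_snps
    sizes = cfg.group_sizes()

    if spec is not None:
        if spec.core_length_bp > positions[-1] - positions[0]:
            raise ValueError("sweep core longer than the simulated region")
        half = spec.core_length_bp // 2
        tpos = positions[spec.target_index]
        core_mask = (positions >= tpos - half) & (positions <= tpos + half)

    out = {}
    for g in GROUPS:
        n_hap = 2 * sizes[g]
        hap = _mosaic_panel(n_hap, freqs[g], panel_size, switch_prob, rng)
        if spec is not None:
            target_freq = (spec.andean_freq if g == "Andean"
                           else spec.lowland_freq)
            n_car = int(round(target_freq * n_hap))
            carriers = rng.choice(n_hap, size=n_car, replace=False)
            hap[:, spec.target_index] = 0
            hap[carriers, spec.target_index] = 1
            if g == "Andean" and n_car > 0:
                founder = (rng.random(int(core_mask.sum()))
                           < freqs[g][core_mask]).astype(np.uint8)
                for c in carriers:
                    copy = founder.copy()
                    # sparse flips stand in for recombination leakage into
                    # the core; de-novo mutations would not be array SNPs
                    mut = rng.random(len(copy)) < core_flip_rate
                    copy[mut] ^= 1
                    hap[c, core_mask] = copy
                hap[carriers, spec.target_index] = 1
        out[g] = HaplotypeSet(hap, positions, label=g)
    return out


def haplotypes_to_genotypes(haps: dict[str, HaplotypeSet],
                            cfg: GeneratorConfig) -> tuple[GenotypeMatrix,
                                                           SampleTable,
                                                           np.ndarray]:
    """Pair consecutive haplotypes into diploids; also returns the phased
    allele matrix (variants x 2*samples) ordered to match the samples."""
    st = _sample_table(cfg)
    vt = _variant_table(cfg, np.random.default_rng(cfg.seed))
    cols = []
    for g in GROUPS:
        cols.append(haps[g].haplotypes.T)  # snps x haplotypes
    phased = np.hstack(cols)
    # sample table lists populations grouped within groups in GROUPS order?
    # _sample_table preserves cfg.populations order; rebuild in group order
    order = np.concatenate([st.group_indices(g) for g in GROUPS])
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    phased_cols = np.empty_like(phased)
    for new_col, sample_col in enumerate(order):
        phased_cols[:, 2 * sample_col] = phased[:, 2 * new_col]
        phased_cols[:, 2 * sample_col + 1] = phased[:, 2 * new_col + 1]
    dos = (phased_cols[:, 0::2] + phased_cols[:, 1::2]).astype(np.int8)
    return GenotypeMatrix(vt, dos, list(st.frame["sample_id"])), st, phased_cols


def make_gene_annotation(gm: GenotypeMatrix, every: int = 200,
                         span_snps: int = 10,
                         sweep_index: int | None = None,
                         sweep_gene: str = "SWEPT1") -> GeneAnnotation:
    """Evenly spaced synthetic genes, plus one covering the sweep target."""
    vt = gm.variants
    rows = []
    k = 0
    for start in range(0, gm.n_variants - span_snps, every):
        rows.append({"chrom": str(vt.chrom[start]),
                     "start": int(vt.pos[start]) - 1,
                     "end": int(vt.pos[start + span_snps]),
                     "name": f"GENE{k:03d}"})
        k += 1
    if sweep_index is not None:
        rows.append({"chrom": str(vt.chrom[sweep_index]),
                     "start": int(vt.pos[sweep_index]) - 500,
                     "end": int(vt.pos[sweep_index]) + 500,
                     "name": sweep_gene})
    return GeneAnnotation(pd.DataFrame(rows))


def write_fixture(out_dir, cfg: GeneratorConfig, gm: GenotypeMatrix,
                  st: SampleTable, genes: GeneAnnotation | None = None,
                  phased: np.ndarray | None = None) -> dict[str, str]:
    """Emit VCF + sample TSV (+ genes BED) and a YAML manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": str(out / "genotypes.vcf"),
             "samples": str(out / "samples.tsv"),
             "manifest": str(out / "manifest.yaml")}
    write_vcf(paths["vcf"], gm, phased=phased)
    write_sample_table(paths["samples"], st)
    if genes is not None:
        paths["genes"] = str(out / "genes.bed")
        write_bed(paths["genes"], genes)
    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(cfg).items()
                           if k != "populations"},
                "group_sizes": cfg.group_sizes(),
                "seed": cfg.seed, "files": paths}
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths
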
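"""End-to-end selection scan: filter -> PBS -> peaks -> null -> haplotypes
-> bootstrap -> IDW, with a reproducibility manifest.

A single master seed drives every stochastic stage through per-stage seeds
derived by stable hashing of the stage name, so independent streams stay
independent while the whole run is reproducible byte for byte.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_io, freq_geo, haplostats, neutral_null, pbs, synthetic
from .core_io import GROUPS

logger = logging.getLogger(__name__)

LOWLAND_GROUPS = ("Mesoamerican", "Amazonian")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class ScanConfig:
    """Resolved parameters of a full scan; defaults follow the published
    analysis (20-SNP windows stepping by 5, 99.5/99.9 empirical percentile
    tiers, 10,000 coalescent and bootstrap replicates)."""

    vcf: str | None = None
    samples: str | None = None
    genes: str | None = None
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    sweep: dict | None = None                      # SweepSpec overrides
    window: int = 20
    step: int = 5
    percentiles: tuple[float, float] = (99.5, 99.9)
    models: tuple[str, ...] = neutral_null.MODEL_LABELS
    n_reps: int = 10_000
    ehh_cutoff: float = haplostats.EHH_CUTOFF
    max_gap: int = haplostats.MAX_GAP
    n_boot: int = 10_000
    grid_lat: tuple[float, float, int] = (-30.0, 25.0, 23)
    grid_lon: tuple[float, float, int] = (-110.0, -55.0, 23)
    idw_power: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def _write_tsv(path: Path, frame: pd.DataFrame, provenance: dict) -> None:
    with open(path, "w") as fh:
        for k in sorted(provenance):
            fh.write(f"# {k}: {provenance[k]}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _load_or_generate(cfg: ScanConfig):
    """Return (gm, st, genes, haplotypes-by-group or None)."""
    if cfg.vcf is not None:
        gm, phased = core_io.read_phased_haplotypes(cfg.vcf)
        st = core_io.read_sample_table(cfg.samples)
        genes = core_io.read_bed(cfg.genes) if cfg.genes else None
        return gm, st, genes, _split_haplotypes(gm, st, phased)
    # synthetic mode: the configured sweep locus is realised twice — as a
    # frequency-level injection in the genotype fixture (PBS, bootstrap,
    # IDW) and as a shared-core haplotype fixture (EHH-family statistics)
    gen_cfg = synthetic.GeneratorConfig(
        seed=stage_seed(cfg.seed, "generate"), **cfg.generator)
    spec = synthetic.SweepSpec(**cfg.sweep) if cfg.sweep else None
    gm, st = synthetic.generate_neutral_genotypes(gen_cfg)
    if spec is not None:
        gm = synthetic.inject_sweep(gm, st, spec,
                                    seed=stage_seed(cfg.seed, "sweep"))
    genes = synthetic.make_gene_annotation(
        gm, sweep_index=spec.target_index if spec else None)
    haps = synthetic.generate_haplotypes(gen_cfg, spec)
    return gm, st, genes, haps


def _split_haplotypes(gm, st, phased) -> dict[str, haplostats.HaplotypeSet]:
    out = {}
    unpolarized = ~gm.variants.is_polarized
    for g in GROUPS:
        cols = []
        for j in st.group_indices(g):
            cols.extend((2 * j, 2 * j + 1))
        hap = phased[:, cols].T
        out[g] = haplostats.HaplotypeSet(hap, gm.variants.pos, label=g)
    if unpolarized.any():
        logger.info("%d SNPs lack ancestral polarization; they stay in PBS "
                    "and XP-EHH but are dropped from iHS",
                    int(unpolarized.sum()))
    return out


def run_full_scan(cfg: ScanConfig, out_dir) -> dict:
    """Execute the whole scan; returns a dict of output paths and key frames.

    Any stage failure propagates with the stage name; outputs written so
    far are left in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"seed": cfg.seed}
    results: dict = {"out_dir": str(out)}

    stage = "load"
    try:
        gm, st, genes, haps = _load_or_generate(cfg)
        stage = "filter"
        orig_index = {v: i for i, v in enumerate(gm.variants.id)}
        gm = core_io.filter_polymorphic(gm, st)
        kept_cols = np.array([orig_index[v] for v in gm.variants.id])
        haps = {g: hs.take_snps(kept_cols) for g, hs in haps.items()}
        keep = {v: i for i, v in enumerate(gm.variants.id)}

        stage = "pbs_scan"
        snp_table = pbs.pbs_scan(gm, st)
        _write_tsv(out / "pbs_per_snp.tsv", snp_table, prov)
        windows = pbs.window_scan(snp_table, cfg.window, cfg.step)
        _write_tsv(out / "pbs_windows.tsv", windows, prov)

        stage = "peaks"
        peaks = pbs.call_peaks(windows, snp_table, cfg.percentiles, genes)
        _write_tsv(out / "pbs_peaks.tsv", peaks, prov)
        top = peaks.drop_duplicates("top_snp") if len(peaks) else peaks
        results["peaks"] = peaks

        stage = "neutral_null"
        sizes = st.group_counts()
        hap_sizes = {g: 2 * n for g, n in sizes.items()}
        null_p: dict[str, np.ndarray] = {}
        for label in cfg.models:
            model = neutral_null.demographic_model(label)
            null = neutral_null.simulate_pbs_null(
                model, hap_sizes, n_reps=cfg.n_reps,
                seed=stage_seed(cfg.seed, f"null_{label}"))
            np.savetxt(out / f"null_pbs_{label}.tsv", null.values,
                       header=f"model={label} seed={null.seed} "
                              f"reps={null.n_reps} redraws={null.redraws}")
            if len(top):
                null_p[label] = neutral_null.empirical_pvalue(
                    top["top_pbs"].to_numpy(), null)
        results["null_p"] = null_p

        stage = "haplostats"
        xp = {}
        for ref in LOWLAND_GROUPS:
            sc = haplostats.xpehh_scores(haps["Andean"], haps[ref],
                                         cfg.ehh_cutoff, cfg.max_gap)
            sc = haplostats.xpehh_pvalue(sc)
            xp[ref] = sc.set_index("snp_index")
            _write_tsv(out / f"xpehh_andean_vs_{ref.lower()}.tsv", sc, prov)
        polarized = gm.variants.is_polarized
        ihs_raw = haplostats.ihs_scores(
            haps["Andean"], cutoff=cfg.ehh_cutoff, max_gap=cfg.max_gap)
        ihs_raw = ihs_raw[polarized[ihs_raw["snp_index"].to_numpy()]]
        ihs = haplostats.standardize_ihs(ihs_raw)
        _write_tsv(out / "ihs_andean.tsv", ihs, prov)
        results["xpehh"] = xp

        stage = "freq_geo"
        boot_rows, cand_rows, freq_cols = [], [], {}
        lat = np.linspace(*cfg.grid_lat)
        lon = np.linspace(*cfg.grid_lon)
        for rank, (_, pk) in enumerate(top.iterrows()):
            snp_id = pk["top_snp"]
            i = keep[snp_id]
            row = {
                "snp": snp_id,
                "ancestral": gm.variants.ancestral_allele[i],
                "derived": gm.variants.derived_allele[i],
                "gene": pk.get("gene", "none"),
                "pos": int(pk["top_pos"]),
                "pbs": float(pk["top_pbs"]),
            }
            for ref in LOWLAND_GROUPS:
                if i in xp[ref].index:
                    row[f"xpehh_vs_{ref.lower()}"] = float(
                        xp[ref].loc[i, "xpehh_std"])
                    row[f"xpehh_p_vs_{ref.lower()}"] = float(
                        xp[ref].loc[i, "pvalue"])
                else:
                    row[f"xpehh_vs_{ref.lower()}"] = np.nan
                    row[f"xpehh_p_vs_{ref.lower()}"] = np.nan
            for label in cfg.models:
                row[f"sim_p_{label}"] = float(null_p[label][rank])
            cand_rows.append(row)

            col = {}
            for g in GROUPS:
                col[g] = freq_geo.group_weighted_frequency(gm, st, g, i)
            freq_cols[snp_id] = col
            for g in LOWLAND_GROUPS:
                br = freq_geo.bootstrap_group_ci(
                    gm, st, i, g, n_boot=cfg.n_boot,
                    seed=stage_seed(cfg.seed, f"boot_{snp_id}_{g}"))
                boot_rows.append(asdict(br))
            surf = freq_geo.snp_surface(gm, st, i, lat, lon,
                                        power=cfg.idw_power)
            _write_tsv(out / f"idw_{snp_id}.tsv", surf.to_frame(), prov)

        candidates = pd.DataFrame(cand_rows)
        _write_tsv(out / "candidates.tsv", candidates, prov)
        freq_table = pd.DataFrame(freq_cols)
        freq_table.insert(0, "group", freq_table.index)
        _write_tsv(out / "group_frequencies.tsv",
                   freq_table.reset_index(drop=True), prov)
        if boot_rows:
            _write_tsv(out / "bootstrap_ci.tsv", pd.DataFrame(boot_rows),
                       prov)
        results["candidates"] = candidates

        stage = "manifest"
        manifest = {
            "config": cfg.to_dict(),
            "stage_seeds": {s: stage_seed(cfg.seed, s)
                            for s in ("generate",
                                      *(f"null_{m}" for m in cfg.models))},
            "n_snps_after_filter": int(gm.n_variants),
            "n_windows": int(len(windows)),
            "n_peaks": int(len(peaks)),
        }
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"full scan failed at stage {stage!r}: {exc}") from exc
    return results
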
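"""Population Branch Statistic scan.

PBS isolates allele-frequency change on the branch leading to a focal
population of a three-population tree.  With ((Andean, Amazonian),
Mesoamerican) topology, pairwise FST values are transformed into additive
branch distances ``T = -log(1 - FST)`` and the Andean branch length is

    PBS = (T_and_meso + T_and_amaz - T_meso_amaz) / 2.

Large PBS marks SNPs whose frequencies moved specifically in the highland
group.  FST defaults to the Reynolds et al. (1983) moment estimator computed
on group-pooled allele counts; Hudson and Weir-Cockerham estimators are
available behind a flag.  Window means (20 SNPs, step 5) are ranked against
the empirical 99.5th/99.9th percentiles and outlier windows are merged into
peaks, each carrying its top per-SNP-PBS SNP and nearest gene.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core_io import GROUPS, GeneAnnotation, GenotypeMatrix, SampleTable, allele_counts

logger = logging.getLogger(__name__)

FST_CAP = 1.0 - 1e-9  # keeps -log(1 - FST) finite at fixed differences

_PAIRS = (("Andean", "Mesoamerican"), ("Andean", "Amazonian"),
          ("Mesoamerican", "Amazonian"))


def reynolds_fst(d1, c1, d2, c2):
    """Reynolds et al. (1983) coancestry estimator for a biallelic SNP.

    Parameters are derived-allele counts ``d`` and called chromosome counts
    ``c`` per population (arrays broadcast).  Returns the raw estimate
    a / (a + b), which may be negative; NaN where either ``c`` < 2.

    For sample frequencies ``p_i`` and diploid sample sizes ``n_i = c_i/2``,
    with ``alpha_i = 2 p_i (1 - p_i)``:

        a = (p1 - p2)^2 - (n1+n2)(n1 a1 + n2 a2) / (4 n1 n2 (n1+n2-1))
        b = (n1 a1 + n2 a2)(4 n1 n2 - n1 - n2) / (4 n1 n2 (n1+n2-1))

    ``a`` is exactly unbiased for zero when both samples share one source
    population, and a/(a+b) -> 1 at a fixed difference.
    """
    d1, c1, d2, c2 = (np.asarray(x, dtype=float) for x in (d1, c1, d2, c2))
    valid = (c1 >= 2) & (c2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = d1 / c1
        p2 = d2 / c2
        n1, n2 = c1 / 2.0, c2 / 2.0
        a1 = 2.0 * p1 * (1.0 - p1)
        a2 = 2.0 * p2 * (1.0 - p2)
        het = n1 * a1 + n2 * a2
        denom = 4.0 * n1 * n2 * (n1 + n2 - 1.0)
        a = (p1 - p2) ** 2 - (n1 + n2) * het / denom
        b = het * (4.0 * n1 * n2 - n1 - n2) / denom
        fst = np.where(a + b > 0, a / np.where(a + b > 0, a + b, 1.0), 0.0)
    return np.where(valid, fst, np.nan)


def hudson_fst(d1, c1, d2, c2):
    """Hudson estimator (Bhatia et al. 2013 form); alternative to Reynolds."""
    d1, c1, d2, c2 = (np.asarray(x, dtype=float) for x in (d1, c1, d2, c2))
    valid = (c1 >= 2) & (c2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = d1 / c1, d2 / c2
        num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (c1 - 1)
               - p2 * (1 - p2) / (c2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.where(valid, fst, np.nan)


def wc_fst(d1, c1, d2, c2):
    """Weir & Cockerham (1984) theta for two populations, biallelic."""
    d1, c1, d2, c2 = (np.asarray(x, dtype=float) for x in (d1, c1, d2, c2))
    valid = (c1 >= 2) & (c2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        n1, n2 = c1 / 2.0, c2 / 2.0
        p1, p2 = d1 / c1, d2 / c2
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        # heterozygote frequency approximated from HWE on pooled counts
        hbar = (n1 * 2 * p1 * (1 - p1) + n2 * 2 * p2 * (1 - p2)) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        tot = a + b + c
        fst = np.where(tot > 0, a / np.where(tot > 0, tot, 1.0), 0.0)
    return np.where(valid, fst, np.nan)


_ESTIMATORS = {"reynolds": reynolds_fst, "hudson": hudson_fst,
               "weir-cockerham": wc_fst}


def branch_transform(fst):
    """T = -log(1 - FST), with FST clamped to [0, 1 - 1e-9] first."""
    fst = np.clip(np.asarray(fst, dtype=float), 0.0, FST_CAP)
    return -np.log1p(-fst)


def pbs_from_fst(fst_and_meso, fst_and_amaz, fst_meso_amaz):
    """Andean branch length from the three pairwise FST values.

    Negative PBS is retained as-is (no clamping of the statistic itself);
    a missing FST propagates to a missing PBS.
    """
    t1 = branch_transform(fst_and_meso)
    t2 = branch_transform(fst_and_amaz)
    t3 = branch_transform(fst_meso_amaz)
    return t1, t2, t3, (t1 + t2 - t3) / 2.0


def pbs_snp(fst_and_meso, fst_and_amaz, fst_meso_amaz) -> float:
    """Scalar convenience wrapper: the Andean PBS for one FST triplet."""
    return float(pbs_from_fst(fst_and_meso, fst_and_amaz, fst_meso_amaz)[3])


def pbs_scan(gm: GenotypeMatrix, st: SampleTable,
             estimator: str = "reynolds") -> pd.DataFrame:
    """Per-SNP pairwise FSTs, branch transforms and Andean PBS.

    Returns one row per SNP: snp, chrom, pos, the three raw FST estimates,
    the three T transforms and the PBS value (NaN where any FST is missing).
    """
    est = _ESTIMATORS[estimator]
    counts = {g: allele_counts(gm, st, g) for g in GROUPS}
    fst = {}
    for g1, g2 in _PAIRS:
        d1, c1 = counts[g1]
        d2, c2 = counts[g2]
        fst[(g1, g2)] = est(d1, c1, d2, c2)
    t1, t2, t3, pbs = pbs_from_fst(fst[_PAIRS[0]], fst[_PAIRS[1]],
                                   fst[_PAIRS[2]])
    vt = gm.variants
    return pd.DataFrame({
        "snp": vt.id, "chrom": vt.chrom, "pos": vt.pos,
        "fst_and_meso": fst[_PAIRS[0]], "fst_and_amaz": fst[_PAIRS[1]],
        "fst_meso_amaz": fst[_PAIRS[2]],
        "t_and_meso": t1, "t_and_amaz": t2, "t_meso_amaz": t3,
        "pbs": pbs,
    })


def window_scan(snp_table: pd.DataFrame, window: int = 20,
                step: int = 5) -> pd.DataFrame:
    """Sliding-window mean PBS; windows never span chromosomes.

    Windows hold exactly ``window`` SNPs and advance by ``step`` SNPs;
    the trailing remainder shorter than ``window`` is dropped.  Returns
    chrom, first/last global SNP index, first/last SNP id, mean_pbs.
    """
    rows = []
    pbs = snp_table["pbs"].to_numpy(dtype=float)
    chroms = snp_table["chrom"].to_numpy()
    ids = snp_table["snp"].to_numpy()
    offset = 0
    for ch in dict.fromkeys(chroms):
        mask = chroms == ch
        n = int(mask.sum())
        vals = pbs[offset:offset + n]
        if n < window:
            logger.warning("chromosome %s has %d SNPs (< window %d); "
                           "no windows emitted", ch, n, window)
        csum = np.concatenate(([0.0], np.cumsum(vals)))
        for start in range(0, n - window + 1, step):
            stop = start + window
            rows.append({
                "chrom": ch,
                "first_idx": offset + start,
                "last_idx": offset + stop - 1,
                "first_snp": ids[offset + start],
                "last_snp": ids[offset + stop - 1],
                "mean_pbs": (csum[stop] - csum[start]) / window,
            })
        offset += n
    return pd.DataFrame(rows, columns=["chrom", "first_idx", "last_idx",
                                       "first_snp", "last_snp", "mean_pbs"])


def call_peaks(windows: pd.DataFrame, snp_table: pd.DataFrame,
               percentiles: tuple[float, ...] = (99.5, 99.9),
               annotation: GeneAnnotation | None = None) -> pd.DataFrame:
    """Merge outlier windows into peaks at each empirical percentile tier.

    Thresholds are linear-interpolation percentiles of the window means over
    the whole scan.  Outlier windows on the same chromosome whose SNP spans
    overlap or touch are merged; each peak reports the SNP with the maximum
    per-SNP PBS in its span and, when an annotation is given, that SNP's
    nearest gene.
    """
    if len(windows) < 200:
        logger.warning("only %d windows; upper empirical percentiles are "
                       "poorly resolved", len(windows))
    means = windows["mean_pbs"].to_numpy(dtype=float)
    pbs = snp_table["pbs"].to_numpy(dtype=float)
    peaks = []
    for tier in percentiles:
        thresh = float(np.percentile(means, tier)) if len(means) else np.inf
        out = windows[means > thresh]
        for ch, sub in out.groupby("chrom", sort=False):
            sub = sub.sort_values("first_idx")
            cur_first, cur_last = None, None
            spans = []
            for first, last in zip(sub["first_idx"], sub["last_idx"]):
                if cur_first is None:
                    cur_first, cur_last = first, last
                elif first <= cur_last + 1:
                    cur_last = max(cur_last, last)
                else:
                    spans.append((cur_first, cur_last))
                    cur_first, cur_last = first, last
            if cur_first is not None:
                spans.append((cur_first, cur_last))
            for first, last in spans:
                span_pbs = pbs[first:last + 1]
                top_rel = int(np.nanargmax(span_pbs))
                top = first + top_rel
                peaks.append({
                    "tier": tier, "chrom": ch,
                    "first_idx": int(first), "last_idx": int(last),
                    "threshold": thresh,
                    "top_snp": snp_table["snp"].iloc[top],
                    "top_pos": int(snp_table["pos"].iloc[top]),
                    "top_pbs": float(span_pbs[top_rel]),
                })
    peak_df = pd.DataFrame(peaks, columns=["tier", "chrom", "first_idx",
                                           "last_idx", "threshold",
                                           "top_snp", "top_pos", "top_pbs"])
    if annotation is not None and len(peak_df):
        genes, dists = [], []
        for _, row in peak_df.iterrows():
            g, d = assign_nearest_gene(row["chrom"], row["top_pos"],
                                       annotation)
            genes.append(g)
            dists.append(d)
        peak_df["gene"] = genes
        peak_df["gene_distance"] = dists
    return peak_df


def assign_nearest_gene(chrom: str, pos: int,
                        annotation: GeneAnnotation) -> tuple[str, float]:
    """Gene containing the SNP, else the nearest; ties -> smaller start.

    ``pos`` is 1-based; intervals are half-open 0-based, so the SNP occupies
    base [pos-1, pos).  Returns ("none", inf) when the chromosome has no
    genes.
    """
    genes = annotation.frame[annotation.frame["chrom"] == str(chrom)]
    if len(genes) == 0:
        return "none", float("inf")
    base = pos - 1
    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    inside = (starts <= base) & (base < ends)
    if inside.any():
        i = int(np.flatnonzero(inside)[0])  # smallest start (sorted)
        return str(genes["name"].iloc[i]), 0.0
    # distance to the closer boundary of each interval
    dist = np.where(base < starts, starts - base, base - (ends - 1))
    best = dist.min()
    i = int(np.flatnonzero(dist == best)[0])  # sorted by start -> tie rule
    return str(genes["name"].iloc[i]), float(best)
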
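"""EHH-family haplotype statistics: EHH, iHS and XP-EHH.

All three statistics quantify the decay of haplotype homozygosity around a
core SNP.  EHH at distance x is the probability that two randomly chosen
chromosomes carrying the core allele are identical over the stretch from the
core to x; a hard sweep drags a long shared haplotype to high frequency, so
EHH decays slowly around selected alleles.

* iHS (within one population) compares the integrated EHH (iHH, area under
  the decay curve over physical distance) of the ancestral vs the derived
  core allele, ``ln(iHH_A / iHH_D)``, standardized within derived-allele
  frequency bins; it is most powerful for incomplete sweeps.
* XP-EHH compares allele-agnostic iHH between a test and a reference
  population, ``ln(iHH_test / iHH_ref)``, standardized genome-wide; positive
  scores mean extended homozygosity in the test population and the statistic
  is most powerful for sweeps at or near fixation.

Integration truncates where EHH drops below a cutoff (default 0.05) and at
inter-SNP gaps larger than ``max_gap`` (default 200 kb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

EHH_CUTOFF = 0.05
MAX_GAP = 200_000


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes (rows) x SNPs (columns) on one chromosome.

    0 = ancestral, 1 = derived; ``positions`` are physical bp, strictly
    increasing.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] < 2:
            raise ValueError("need a 2-D matrix with >= 2 haplotypes")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("positions must match SNP columns")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def derived_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def take_snps(self, idx) -> "HaplotypeSet":
        idx = np.asarray(idx)
        return HaplotypeSet(self.haplotypes[:, idx], self.positions[idx],
                            self.label)


def _homozygosity(codes: np.ndarray) -> float:
    """Sum_i C(c_i,2) / C(n,2) over the partition encoded by ``codes``."""
    n = len(codes)
    counts = np.bincount(codes)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh_at(hs: HaplotypeSet, core: int, core_allele: int, flank: int) -> float:
    """EHH of ``core_allele`` carriers over the span core..flank inclusive.

    Partition the carriers by identity of the haplotype stretch between the
    core and the flank SNP; EHH is the probability a random carrier pair
    falls in one class.  NaN (logged) with fewer than two carriers.
    """
    carriers = hs.haplotypes[:, core] == core_allele
    n = int(carriers.sum())
    if n < 2:
        logger.warning("fewer than 2 carriers of allele %d at column %d",
                       core_allele, core)
        return float("nan")
    lo, hi = min(core, flank), max(core, flank)
    seg = hs.haplotypes[carriers, lo:hi + 1]
    _, codes = np.unique(seg, axis=0, return_inverse=True)
    return _homozygosity(codes)


@dataclass
class EHHCurve:
    """One-sided-pair EHH decay around a core SNP.

    Index 0 of each side is the core itself; ``ehh_left``/``ehh_right`` run
    outward.  ``censored`` flags a side that never decayed below the cutoff
    before running out of data (or hitting a gap).
    """

    core: int
    core_allele: int | None          # None = allele-agnostic (all haplotypes)
    pos_left: np.ndarray             # descending positions, core first
    ehh_left: np.ndarray
    pos_right: np.ndarray            # ascending positions, core first
    ehh_right: np.ndarray
    censored: bool


def _decay_side(hap: np.ndarray, positions: np.ndarray, core: int,
                step: int, cutoff: float, max_gap: int,
                start_codes: np.ndarray) -> tuple[list, list, bool]:
    """Walk outward from the core refining the identity partition.

    Returns positions, EHH values (starting at the core) and whether the
    side ended censored (never dropped below ``cutoff``).
    """
    n = hap.shape[0]
    codes = start_codes
    pos_out = [int(positions[core])]
    ehh_out = [_homozygosity(codes)]
    col = core
    while True:
        nxt = col + step
        if nxt < 0 or nxt >= hap.shape[1]:
            return pos_out, ehh_out, ehh_out[-1] >= cutoff
        if abs(int(positions[nxt]) - int(positions[col])) > max_gap:
            logger.debug("gap > %d bp at column %d; side truncated",
                         max_gap, col)
            return pos_out, ehh_out, ehh_out[-1] >= cutoff
        codes = np.unique(codes * 2 + hap[:, nxt], return_inverse=True)[1]
        ehh = _homozygosity(codes)
        pos_out.append(int(positions[nxt]))
        ehh_out.append(ehh)
        if ehh < cutoff:
            return pos_out, ehh_out, False
        if ehh == 0.0:
            return pos_out, ehh_out, False
        col = nxt


def ehh_curve(hs: HaplotypeSet, core: int, core_allele: int | None,
              cutoff: float = EHH_CUTOFF, max_gap: int = MAX_GAP) -> EHHCurve | None:
    """Bidirectional EHH decay curve for one core SNP.

    ``core_allele`` 0/1 restricts to carriers (EHH(core) = 1); ``None``
    uses all haplotypes with the core column itself in the identity check
    (the XP-EHH convention, EHH(core) = core-site homozygosity).  Returns
    None when fewer than two chromosomes qualify.
    """
    if core_allele is None:
        hap = hs.haplotypes
        start = hap[:, core].astype(np.int64)
    else:
        mask = hs.haplotypes[:, core] == core_allele
        if int(mask.sum()) < 2:
            return None
        hap = hs.haplotypes[mask]
        start = np.zeros(hap.shape[0], dtype=np.int64)
    pl, el, cl = _decay_side(hap, hs.positions, core, -1, cutoff, max_gap, start)
    pr, er, cr = _decay_side(hap, hs.positions, core, +1, cutoff, max_gap, start)
    return EHHCurve(core, core_allele,
                    np.array(pl), np.array(el),
                    np.array(pr), np.array(er),
                    censored=bool(cl or cr))


def ihh(curve: EHHCurve, cutoff: float = EHH_CUTOFF) -> tuple[float, bool]:
    """Integrated EHH: trapezoids over bp, both sides of the core summed.

    Each side contributes up to and including the first point where EHH
    dropped below ``cutoff`` (the curve is already truncated there); a side
    that never dropped is integrated to its end and flagged censored.
    """
    total = 0.0
    for pos, vals in ((curve.pos_left, curve.ehh_left),
                      (curve.pos_right, curve.ehh_right)):
        if len(pos) > 1:
            d = np.abs(np.diff(pos.astype(float)))
            total += float(np.sum(d * (vals[1:] + vals[:-1]) / 2.0))
    return total, curve.censored


def _site_ihh(hs: HaplotypeSet, core: int, core_allele: int | None,
              cutoff: float, max_gap: int) -> tuple[float, bool] | None:
    curve = ehh_curve(hs, core, core_allele, cutoff, max_gap)
    if curve is None:
        return None
    return ihh(curve, cutoff)


def ihs_scores(hs: HaplotypeSet, min_maf: float = 0.05,
               cutoff: float = EHH_CUTOFF, max_gap: int = MAX_GAP) -> pd.DataFrame:
    """Unstandardized iHS per SNP: ln(iHH_ancestral / iHH_derived).

    SNPs below the minor-allele-frequency floor, with < 2 carriers of either
    allele, or with a zero iHH are skipped with a reason column in the log.
    """
    rows = []
    freqs = hs.derived_freq()
    for snp in range(hs.n_snps):
        p = freqs[snp]
        if min(p, 1 - p) < min_maf:
            continue
        res_a = _site_ihh(hs, snp, 0, cutoff, max_gap)
        res_d = _site_ihh(hs, snp, 1, cutoff, max_gap)
        if res_a is None or res_d is None:
            logger.debug("SNP %d skipped: <2 carriers of one allele", snp)
            continue
        ihh_a, cens_a = res_a
        ihh_d, cens_d = res_d
        if ihh_a <= 0 or ihh_d <= 0:
            logger.debug("SNP %d skipped: zero iHH", snp)
            continue
        rows.append({"snp_index": snp, "pos": int(hs.positions[snp]),
                     "derived_freq": float(p),
                     "ihh_ancestral": ihh_a, "ihh_derived": ihh_d,
                     "ihs_raw": float(np.log(ihh_a / ihh_d)),
                     "censored": bool(cens_a or cens_d)})
    return pd.DataFrame(rows, columns=["snp_index", "pos", "derived_freq",
                                       "ihh_ancestral", "ihh_derived",
                                       "ihs_raw", "censored"])


def standardize_ihs(records: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Standardize raw iHS within equal-width derived-frequency bins.

    Within each bin the mean is subtracted and the standard deviation
    divided out, so extreme standardized scores mark unusually long
    haplotypes relative to SNPs of comparable frequency.  Bins with fewer
    than two records get NaN.
    """
    out = records.copy()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = np.clip(np.digitize(out["derived_freq"], edges) - 1, 0, n_bins - 1)
    out["freq_bin"] = bins
    std = np.full(len(out), np.nan)
    for b in np.unique(bins):
        m = bins == b
        vals = out.loc[m, "ihs_raw"].to_numpy()
        if len(vals) >= 2 and np.std(vals) > 0:
            std[m] = (vals - vals.mean()) / vals.std()
    out["ihs_std"] = std
    return out


def xpehh_scores(hs_test: HaplotypeSet, hs_ref: HaplotypeSet,
                 cutoff: float = EHH_CUTOFF, max_gap: int = MAX_GAP) -> pd.DataFrame:
    """XP-EHH per shared SNP: ln(iHH_test / iHH_ref), standardized genome-wide.

    iHH here is allele-agnostic (all haplotypes, core column included in the
    identity check) per population.  Positive standardized scores indicate
    extended homozygosity in the test population.
    """
    if hs_test.n_snps != hs_ref.n_snps or np.any(
            hs_test.positions != hs_ref.positions):
        raise ValueError("test and reference sets must share SNP positions")
    rows = []
    for snp in range(hs_test.n_snps):
        res_t = _site_ihh(hs_test, snp, None, cutoff, max_gap)
        res_r = _site_ihh(hs_ref, snp, None, cutoff, max_gap)
        ihh_t, cens_t = res_t
        ihh_r, cens_r = res_r
        if ihh_t <= 0 or ihh_r <= 0:
            logger.debug("SNP %d skipped: zero iHH", snp)
            continue
        rows.append({"snp_index": snp, "pos": int(hs_test.positions[snp]),
                     "ihh_test": ihh_t, "ihh_ref": ihh_r,
                     "xpehh_raw": float(np.log(ihh_t / ihh_r)),
                     "censored": bool(cens_t or cens_r)})
    df = pd.DataFrame(rows, columns=["snp_index", "pos", "ihh_test",
                                     "ihh_ref", "xpehh_raw", "censored"])
    if len(df) >= 2 and df["xpehh_raw"].std() > 0:
        df["xpehh_std"] = ((df["xpehh_raw"] - df["xpehh_raw"].mean())
                           / df["xpehh_raw"].std())
    else:
        df["xpehh_std"] = np.nan
    return df


def xpehh_pvalue(scores: pd.DataFrame, method: str = "empirical",
                 column: str = "xpehh_std") -> pd.DataFrame:
    """One-sided significance of XP-EHH scores.

    ``empirical`` (default): rank p = (1 + #{other scores > s}) / (N + 1)
    within the scan itself, so the top-ranked of 9,999 SNPs gets 1e-4;
    ``normal``: upper-tail 1 - Phi(s) of the standardized score.
    """
    out = scores.copy()
    s = out[column].to_numpy(dtype=float)
    if method == "empirical":
        order = np.sort(s)
        n_gt = len(s) - np.searchsorted(order, s, side="right")
        out["pvalue"] = (1.0 + n_gt) / (len(s) + 1.0)
    elif method == "normal":
        out["pvalue"] = norm.sf(s)
    else:
        raise ValueError("method must be 'empirical' or 'normal'")
    return out
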
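"""Heterozygosity scans, X/Y SNP pattern classification, and between-
species site classes.

In a male carrying a non-recombining X-Y pair, every X-Y nucleotide
difference appears as a heterozygous call, so sliding-window
heterozygosity in males (but not females) traces X-Y divergence.  The
pattern rules stratify sites by role groups:

* X-specific: other-species females homozygous for allele a, focal
  females homozygous for a different allele b, focal males heterozygous;
* Y-specific: both female groups homozygous for the same allele, focal
  males heterozygous;
* shared: focal males and females homozygous for allele b, other-species
  females homozygous for a different allele a.

Between-species classes use females only: a fixed difference means the
two female groups are homozygous for different alleles; a species is
polymorphic at a site when at least one of its females is heterozygous
or carries a different homozygote than the rest.  All rules quantify
over complete, non-missing genotypes; any missingness makes a site
unclassified rather than relaxing the quorum.  Depth masks use strict
inequalities: with bounds (lo, hi), a position is usable iff
``lo <= depth <= hi`` in every required sample (preset ``strict`` =
(20, 200), ``loose`` = (10, 500)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import HET, HOM_ALT, HOM_REF, MISSING, CoverageTrack, GenotypeMatrix
from .stats_core import GradientFit, grubbs_test, logistic_fit

log = logging.getLogger("neosexscan")

__all__ = [
    "SiteMask",
    "MASK_PRESETS",
    "build_site_mask",
    "genome_snp_rate",
    "het_windows",
    "chromosome_het_summary",
    "classify_xy_snps",
    "classify_species_sites",
    "species_site_windows",
    "fusion_gradient",
    "chromosome_outlier_tests",
]

MASK_PRESETS: dict[str, tuple[float, float]] = {
    "strict": (20.0, 200.0),
    "loose": (10.0, 500.0),
}


@dataclass
class SiteMask:
    """Per-chromosome usable flags at the coverage track's bin resolution."""

    usable: dict[str, np.ndarray]  # bool per bin
    bin_size: int
    lo: float
    hi: float

    def usable_at(self, chrom: str, positions) -> np.ndarray:
        pos = np.asarray(positions, dtype=np.int64)
        arr = self.usable.get(chrom)
        if arr is None:
            return np.zeros(pos.size, dtype=bool)
        idx = (pos - 1) // self.bin_size
        ok = (idx >= 0) & (idx < arr.size)
        out = np.zeros(pos.size, dtype=bool)
        out[ok] = arr[idx[ok]]
        return out

    def usable_count(self, chrom: str, start: int, end: int) -> int:
        """Number of usable positions in the 1-based inclusive interval."""
        arr = self.usable.get(chrom)
        if arr is None or end < start:
            return 0
        b = self.bin_size
        total = 0
        i0 = (start - 1) // b
        i1 = min((end - 1) // b, arr.size - 1)
        for i in range(i0, i1 + 1):
            if arr[i]:
                lo = max(start, i * b + 1)
                hi = min(end, (i + 1) * b)
                total += hi - lo + 1
        return total

    def usable_counts_per_window(self, chrom: str, starts: np.ndarray,
                                 window: int, length: int) -> np.ndarray:
        arr = self.usable.get(chrom)
        if arr is None:
            return np.zeros(len(starts), dtype=np.int64)
        b = self.bin_size
        csum = np.concatenate([[0], np.cumsum(arr.astype(np.int64))])
        i0 = (np.asarray(starts) - 1) // b
        ends = np.minimum(np.asarray(starts) + window - 1, length)
        i1 = np.minimum((ends - 1) // b + 1, arr.size)
        return (csum[i1] - csum[i0]) * b  # bin-resolution approximation

    def chrom_usable_total(self, chrom: str) -> int:
        arr = self.usable.get(chrom)
        return 0 if arr is None else int(arr.sum()) * self.bin_size


def build_site_mask(tracks: list[CoverageTrack], lo: float, hi: float) -> SiteMask:
    """Usable iff every track's depth satisfies ``lo <= depth <= hi``.

    Tracks must be raw (unnormalized) depth with a common bin size.
    Tightening the bounds can only shrink the usable set.
    """
    if lo >= hi:
        raise ValueError(f"mask bounds require lo < hi, got ({lo}, {hi})")
    if not tracks:
        raise ValueError("at least one coverage track required")
    bins = {t.bin_size for t in tracks}
    if len(bins) != 1:
        raise ValueError("tracks must share a bin size")
    if any(t.normalized for t in tracks):
        raise ValueError("mask bounds apply to raw depth, not normalized tracks")
    usable: dict[str, np.ndarray] = {}
    for chrom in tracks[0].chroms:
        ok = None
        for t in tracks:
            a = np.asarray(t.depth[chrom], dtype=float)
            this = (a >= lo) & (a <= hi)
            ok = this if ok is None else (ok & this)
        usable[chrom] = ok
    return SiteMask(usable=usable, bin_size=tracks[0].bin_size, lo=lo, hi=hi)


def _mask_or_all(matrix: GenotypeMatrix, mask: SiteMask | None,
                 chrom: str, positions: np.ndarray) -> np.ndarray:
    if mask is None:
        return np.ones(positions.size, dtype=bool)
    return mask.usable_at(chrom, positions)


# ---------------------------------------------------------------------------
# Rates and windows
# ---------------------------------------------------------------------------

def genome_snp_rate(matrix: GenotypeMatrix, sample_id: str, mask: SiteMask,
                    ) -> float:
    """Substitution rate vs the reference: homozygous-alt SNPs count one,
    heterozygous SNPs one half, over all usable positions."""
    si = matrix.sample_index(sample_id)
    num = 0.0
    denom = 0
    for chrom in mask.usable:
        on = matrix.sites_on(chrom)
        pos = matrix.pos[on]
        ok = mask.usable_at(chrom, pos)
        g = matrix.gt[on, si][ok]
        num += float((g == HOM_ALT).sum()) + 0.5 * float((g == HET).sum())
        denom += mask.chrom_usable_total(chrom)
    if denom == 0:
        return float("nan")
    return num / denom


def het_windows(matrix: GenotypeMatrix, sample_id: str,
                mask: SiteMask | None, chrom_lengths: dict[str, int],
                window: int = 500_000, step: int = 100_000) -> pd.DataFrame:
    """Sliding-window proportion of heterozygous sites among usable
    positions.  Windows with zero usable positions are NaN-flagged."""
    from .coverage_analysis import window_starts

    si = matrix.sample_index(sample_id)
    rows = []
    for chrom, length in chrom_lengths.items():
        starts, partial = window_starts(length, window, step)
        ends = np.minimum(starts + window - 1, length)
        on = matrix.sites_on(chrom)
        pos = matrix.pos[on]
        g = matrix.gt[on, si]
        ok = _mask_or_all(matrix, mask, chrom, pos)
        het_pos = np.sort(pos[ok & (g == HET)])
        n_het = (np.searchsorted(het_pos, ends, side="right")
                 - np.searchsorted(het_pos, starts, side="left"))
        if mask is None:
            usable = (ends - starts + 1).astype(np.int64)
        else:
            usable = mask.usable_counts_per_window(chrom, starts, window, length)
        with np.errstate(invalid="ignore", divide="ignore"):
            value = np.where(usable > 0, n_het / np.maximum(usable, 1), np.nan)
        for s, e, v, u in zip(starts, ends, value, usable):
            rows.append((chrom, int(s), int(e), float(v), int(u), partial))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value",
                                       "n_informative", "partial"])


def chromosome_het_summary(matrix: GenotypeMatrix, sample_id: str,
                           mask: SiteMask | None,
                           chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Per-chromosome proportion of heterozygous sites among usable
    positions (the chromosome-level aggregate behind the outlier test)."""
    si = matrix.sample_index(sample_id)
    rows = []
    for chrom, length in chrom_lengths.items():
        on = matrix.sites_on(chrom)
        pos = matrix.pos[on]
        ok = _mask_or_all(matrix, mask, chrom, pos)
        n_het = int(((matrix.gt[on, si] == HET) & ok).sum())
        usable = length if mask is None else mask.chrom_usable_total(chrom)
        rows.append((chrom, n_het / usable if usable else float("nan"),
                     n_het, usable))
    return pd.DataFrame(rows, columns=["chrom", "value", "n_het", "n_usable"])


def chromosome_outlier_tests(values: pd.Series, candidates: list[str],
                             autosomes: list[str], alpha: float = 0.05,
                             ) -> pd.DataFrame:
    """Grubbs test of each candidate chromosome against the autosomes.

    Each candidate is tested in the set {autosomes + candidate}, as the
    single-outlier test requires."""
    rows = []
    ref = values.reindex(autosomes).dropna()
    if len(ref) < 4:
        raise ValueError("need >= 4 autosome values")
    for cand in candidates:
        if cand not in values.index or not np.isfinite(values[cand]):
            rows.append((cand, float("nan"), float("nan"), False, "high"))
            continue
        vals = np.concatenate([ref.to_numpy(), [values[cand]]])
        G, p = grubbs_test(vals, len(vals) - 1)
        direction = "high" if values[cand] > ref.mean() else "low"
        rows.append((cand, G, p, p < alpha, direction))
    return pd.DataFrame(rows, columns=["candidate", "G", "p",
                                       "significant", "direction"])


# ---------------------------------------------------------------------------
# Pattern classification
# ---------------------------------------------------------------------------

def _all_eq(g: np.ndarray, code: int) -> np.ndarray:
    return (g == code).all(axis=1)


def classify_xy_snps(matrix: GenotypeMatrix, roles: dict[str, list[str]],
                     mask: SiteMask | None = None) -> pd.DataFrame:
    """Label every site X_specific / Y_specific / shared / unclassified.

    ``roles`` maps 'focal_males', 'focal_females' and 'other_females' to
    sample ids.  Sites with any missing role genotype, or failing the
    mask, are unclassified (exactly one label per site, so the four
    categories always partition the input)."""
    fm = [matrix.sample_index(s) for s in roles["focal_males"]]
    ff = [matrix.sample_index(s) for s in roles["focal_females"]]
    of = [matrix.sample_index(s) for s in roles["other_females"]]
    g_fm, g_ff, g_of = matrix.gt[:, fm], matrix.gt[:, ff], matrix.gt[:, of]

    complete = ((g_fm != MISSING).all(1) & (g_ff != MISSING).all(1)
                & (g_of != MISSING).all(1))
    if mask is not None:
        ok = np.zeros(matrix.n_sites, dtype=bool)
        for chrom in np.unique(matrix.chrom):
            on = matrix.sites_on(chrom)
            ok[on] = mask.usable_at(chrom, matrix.pos[on])
        complete &= ok

    fm_het = _all_eq(g_fm, HET)
    ff_rr, ff_aa = _all_eq(g_ff, HOM_REF), _all_eq(g_ff, HOM_ALT)
    of_rr, of_aa = _all_eq(g_of, HOM_REF), _all_eq(g_of, HOM_ALT)
    fm_rr, fm_aa = _all_eq(g_fm, HOM_REF), _all_eq(g_fm, HOM_ALT)

    x_spec = fm_het & ((of_rr & ff_aa) | (of_aa & ff_rr))
    y_spec = fm_het & ((of_rr & ff_rr) | (of_aa & ff_aa))
    shared = ((fm_aa & ff_aa & of_rr) | (fm_rr & ff_rr & of_aa))

    category = np.full(matrix.n_sites, "unclassified", dtype=object)
    category[complete & x_spec] = "X_specific"
    category[complete & y_spec] = "Y_specific"
    category[complete & shared] = "shared"
    return pd.DataFrame({"chrom": matrix.chrom, "pos": matrix.pos,
                         "category": category, "eligible": complete})


def classify_species_sites(matrix: GenotypeMatrix, females_a: list[str],
                           females_b: list[str],
                           mask: SiteMask | None = None) -> pd.DataFrame:
    """Fixed-difference and within-species polymorphism flags per site,
    from the two species' females.

    A fixed difference requires all A females homozygous for one allele
    and all B females homozygous for the other; a species is polymorphic
    when at least one of its females is heterozygous or carries a
    different homozygote.  Any missing genotype makes the site
    ineligible (no flags)."""
    ga = matrix.gt[:, [matrix.sample_index(s) for s in females_a]]
    gb = matrix.gt[:, [matrix.sample_index(s) for s in females_b]]
    complete = (ga != MISSING).all(1) & (gb != MISSING).all(1)
    if mask is not None:
        ok = np.zeros(matrix.n_sites, dtype=bool)
        for chrom in np.unique(matrix.chrom):
            on = matrix.sites_on(chrom)
            ok[on] = mask.usable_at(chrom, matrix.pos[on])
        complete &= ok

    def hom_uniform(g: np.ndarray) -> np.ndarray:
        return _all_eq(g, HOM_REF) | _all_eq(g, HOM_ALT)

    poly_a = complete & ~hom_uniform(ga)
    poly_b = complete & ~hom_uniform(gb)
    fixed = (complete
             & ((_all_eq(ga, HOM_REF) & _all_eq(gb, HOM_ALT))
                | (_all_eq(ga, HOM_ALT) & _all_eq(gb, HOM_REF))))
    return pd.DataFrame({"chrom": matrix.chrom, "pos": matrix.pos,
                         "fixed_diff": fixed, "polymorphic_a": poly_a,
                         "polymorphic_b": poly_b, "eligible": complete})


def species_site_windows(classes: pd.DataFrame, flag: str,
                         mask: SiteMask | None,
                         chrom_lengths: dict[str, int],
                         autosomes: list[str],
                         window: int = 500_000, step: int = 100_000,
                         ) -> pd.DataFrame:
    """Sliding-window proportion of flagged sites, expressed relative to
    the autosomal mean proportion (values of 1 mean 'autosome-like')."""
    from .coverage_analysis import window_starts

    # autosomal mean proportion
    auto_n = auto_d = 0.0
    for chrom in autosomes:
        sub = classes[classes["chrom"] == chrom]
        auto_n += float(sub[flag].sum())
        auto_d += (mask.chrom_usable_total(chrom) if mask is not None
                   else chrom_lengths[chrom])
    auto_rate = auto_n / auto_d if auto_d else float("nan")

    rows = []
    for chrom, length in chrom_lengths.items():
        sub = classes[classes["chrom"] == chrom]
        flagged = np.sort(sub.loc[sub[flag], "pos"].to_numpy())
        starts, partial = window_starts(length, window, step)
        ends = np.minimum(starts + window - 1, length)
        n_flag = (np.searchsorted(flagged, ends, side="right")
                  - np.searchsorted(flagged, starts, side="left"))
        if mask is None:
            usable = (ends - starts + 1).astype(np.int64)
        else:
            usable = mask.usable_counts_per_window(chrom, starts, window, length)
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.where(usable > 0, n_flag / np.maximum(usable, 1), np.nan)
        rel = prop / auto_rate if auto_rate and np.isfinite(auto_rate) else prop * np.nan
        for s, e, v, u in zip(starts, ends, rel, usable):
            rows.append((chrom, int(s), int(e), float(v), int(u), partial))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value",
                                       "n_informative", "partial"])


# ---------------------------------------------------------------------------
# Fusion-distance gradient
# ---------------------------------------------------------------------------

def fusion_gradient(het_positions, fusion_end: int, chrom_length: int,
                    chrom: str | None = None, mask: SiteMask | None = None,
                    bin: int = 1000) -> GradientFit:
    """Binomial regression of per-bin heterozygosity on distance from the
    fusion end.

    The chromosome is partitioned into right-open bins of ``bin`` bp;
    successes are heterozygous sites per bin, totals are usable
    positions (all positions without a mask), and the covariate is the
    bin midpoint's distance from the fusion end.  A negative slope means
    heterozygosity declines away from the fusion."""
    het = np.sort(np.asarray(het_positions, dtype=np.int64))
    edges = np.arange(1, chrom_length + bin, bin, dtype=np.int64)
    edges[-1] = max(edges[-1], chrom_length + 1)
    n_bins = edges.size - 1
    succ = np.diff(np.searchsorted(het, edges, side="left")).astype(float)
    if mask is None:
        totals = np.diff(edges).astype(float)
    else:
        totals = np.array(
            [mask.usable_count(chrom, int(edges[i]), int(edges[i + 1] - 1))
             for i in range(n_bins)], dtype=float)
    mid = (edges[:-1] + (edges[1:] - 1)) / 2.0
    dist = np.abs(mid - fusion_end)
    if int((totals > 0).sum()) < 2:
        raise ValueError("fusion_gradient needs >= 2 non-empty bins")
    succ = np.minimum(succ, totals)  # guard against mask/bin mismatches
    return logistic_fit(succ, totals, dist)
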
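"""Y-degeneration detection from sex-differential read depth.

A hemizygous (Y-deleted) region shows up as halved male depth: after
normalizing each sample's depth by its library size, chromosome-level
means are compared by Grubbs' outlier test (candidate sex chromosome
against the autosomes), and a sliding-window scan of male-minus-female
normalized depth localizes the deleted span.  Positions with zero depth
are excluded from all means, since repeat-masked spans would otherwise
bias them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack
from .stats_core import grubbs_test

log = logging.getLogger("neosexscan")

__all__ = [
    "normalize_coverage",
    "chromosome_mean_coverage",
    "window_starts",
    "sex_coverage_windows",
    "detect_degeneration",
    "DegenerationReport",
]


def normalize_coverage(track: CoverageTrack) -> CoverageTrack:
    """Divide every depth value by the sample's library size."""
    if track.library_size is None or track.library_size <= 0:
        raise ValueError(f"library_size must be > 0 for {track.sample_id}")
    depth = {c: np.asarray(a, dtype=float) / track.library_size
             for c, a in track.depth.items()}
    return CoverageTrack(sample_id=track.sample_id, depth=depth,
                         bin_size=track.bin_size,
                         library_size=track.library_size, normalized=True)


def chromosome_mean_coverage(track: CoverageTrack,
                             covered_only: bool = True) -> pd.DataFrame:
    """Per-chromosome mean depth.

    With ``covered_only`` (the default) the mean is taken over positions
    with depth > 0; chromosomes with no covered position get
    ``n_positions = 0`` and a NaN mean.  ``covered_only=False`` averages
    over the full chromosome length instead (both conventions are
    reported by the pipeline since the exclusion stage for repeat masks
    is not uniquely determined).
    """
    rows = []
    for chrom, arr in track.depth.items():
        a = np.asarray(arr, dtype=float)
        if covered_only:
            cov = a[a > 0]
            mean = float(cov.mean()) if cov.size else float("nan")
            n_pos = int(cov.size * track.bin_size)
        else:
            mean = float(a.mean()) if a.size else float("nan")
            n_pos = int(a.size * track.bin_size)
        rows.append((chrom, mean, n_pos))
    return pd.DataFrame(rows, columns=["chrom", "mean", "n_positions"])


def window_starts(length: int, window: int, step: int) -> tuple[np.ndarray, bool]:
    """1-based start coordinates of sliding windows over a chromosome.

    Only windows that fit entirely are emitted; when the window exceeds
    the chromosome, a single truncated window starting at 1 is returned
    with a partial flag.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if window > length:
        return np.array([1], dtype=np.int64), True
    n = (length - window) // step + 1
    return 1 + step * np.arange(n, dtype=np.int64), False


def _window_means(arr: np.ndarray, bin_size: int, starts: np.ndarray,
                  window: int, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean over covered (depth > 0) bins per window, plus covered-bin
    counts; bins are attributed to windows by their start coordinate."""
    a = np.asarray(arr, dtype=float)
    covered = a > 0
    csum = np.concatenate([[0.0], np.cumsum(a * covered)])
    ccnt = np.concatenate([[0], np.cumsum(covered)])
    # bin index range [i0, i1) for window [start, start+window-1]
    i0 = (starts - 1) // bin_size
    ends = np.minimum(starts + window - 1, length)
    i1 = np.minimum((ends - 1) // bin_size + 1, a.size)
    tot = csum[i1] - csum[i0]
    cnt = ccnt[i1] - ccnt[i0]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return mean, cnt


def sex_coverage_windows(male: CoverageTrack, female: CoverageTrack,
                         window: int = 500_000, step: int = 100_000,
                         chroms: list[str] | None = None) -> pd.DataFrame:
    """Sliding windows of male minus female normalized mean depth.

    Both tracks must be normalized and binned identically.  Per window
    the mean is taken over covered positions of the respective sample;
    windows where either sample has no covered position are flagged
    unusable (NaN value).
    """
    if not (male.normalized and female.normalized):
        raise ValueError("tracks must be normalized (see normalize_coverage)")
    if male.bin_size != female.bin_size:
        raise ValueError("tracks must share a bin size")
    rows = []
    for chrom in chroms or male.chroms:
        if chrom not in female.depth:
            raise ValueError(f"chromosome {chrom} missing from female track")
        length = max(male.chrom_length(chrom), female.chrom_length(chrom))
        starts, partial = window_starts(length, window, step)
        m_mean, m_cnt = _window_means(male.depth[chrom], male.bin_size,
                                      starts, window, length)
        f_mean, f_cnt = _window_means(female.depth[chrom], female.bin_size,
                                      starts, window, length)
        value = m_mean - f_mean
        usable = (m_cnt > 0) & (f_cnt > 0)
        ends = np.minimum(starts + window - 1, length)
        for s, e, v, u, nm, nf in zip(starts, ends, value, usable, m_cnt, f_cnt):
            rows.append((chrom, int(s), int(e),
                         float(v) if u else float("nan"),
                         int(min(nm, nf) * male.bin_size), bool(u), partial))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value",
                                       "n_informative", "usable", "partial"])


@dataclass
class DegenerationReport:
    """Per-candidate decision across sexes."""

    candidate: str
    degenerate: bool       # male-significant and female-nonsignificant
    male_p: dict[str, float]
    female_p: dict[str, float]


def detect_degeneration(summaries: pd.DataFrame, candidates: list[str],
                        autosomes: list[str], alpha: float = 0.05,
                        ) -> tuple[pd.DataFrame, dict[str, DegenerationReport]]:
    """Grubbs test of each candidate chromosome's mean depth per sample.

    ``summaries`` has columns (sample_id, sex, chrom, mean); each
    candidate is tested against {autosomes + candidate}.  A candidate is
    flagged degenerate when it is a significant low outlier in every
    male and in no female.  At least 4 reference chromosomes are
    required (the test is undefined below that).
    """
    if len(autosomes) < 4:
        raise ValueError("need >= 4 autosomes for the outlier test")
    rows = []
    reports: dict[str, DegenerationReport] = {}
    for cand in candidates:
        male_p: dict[str, float] = {}
        female_p: dict[str, float] = {}
        male_sig_low: list[bool] = []
        female_sig_low: list[bool] = []
        for (sid, sex), sub in summaries.groupby(["sample_id", "sex"]):
            means = sub.set_index("chrom")["mean"]
            ref = means.reindex(autosomes).dropna()
            if cand not in means.index or len(ref) < 4:
                continue
            vals = np.concatenate([ref.to_numpy(), [means[cand]]])
            G, p = grubbs_test(vals, len(vals) - 1)
            sig_low = bool(p < alpha and means[cand] < ref.mean())
            rows.append((cand, sid, sex, G, p, sig_low))
            if sex == "male":
                male_p[sid] = p
                male_sig_low.append(sig_low)
            else:
                female_p[sid] = p
                female_sig_low.append(sig_low)
        male_sig = bool(male_sig_low) and all(male_sig_low)
        female_ns = not any(female_sig_low)
        reports[cand] = DegenerationReport(candidate=cand,
                                           degenerate=male_sig and female_ns,
                                           male_p=male_p, female_p=female_p)
    frame = pd.DataFrame(rows, columns=["candidate", "sample_id", "sex",
                                        "G", "p", "significant_low"])
    return frame, reports
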
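"""Codon-level divergence: Nei-Gojobori Ka/Ks and a counting two-ratio test.

The X-Y allelic comparison works on *virtual haplotypes*: a diploid
individual's heterozygous SNPs are randomly phased onto one of two copies
of each coding sequence, so the pair of haplotypes carries the X-Y
differences without requiring physical phasing.  Lineage-specific rates
use one haploid consensus per taxon and a parsimony assignment of
substitutions to the focal or background branches against an outgroup
(two-ratio, method "NG86-two-ratio"): at each codon where exactly one
taxon differs, the change is placed on that taxon's branch, with changes
on the outgroup's own branch pooled into the background.

Site opportunities follow Nei & Gojobori's (1986) counting scheme: each
codon position contributes the fraction of its three single-nucleotide
changes that are synonymous (changes to stop codons count as
nonsynonymous).  Codons differing at several positions are resolved by
averaging observed Nd/Sd over all orderings of single-step pathways,
excluding pathways that pass through a stop codon; distances are
Jukes-Cantor corrected.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io_formats import (
    HET, HOM_ALT, HOM_REF, MISSING, CodingGeneModel, GenotypeMatrix, revcomp,
)

log = logging.getLogger("neosexscan")

__all__ = [
    "KaKsResult",
    "BranchOmega",
    "HaplotypePair",
    "codon_site_counts",
    "pathway_counts",
    "ng86_kaks",
    "build_virtual_haplotypes",
    "consensus_haploid",
    "branch_specific_omega",
    "pooled_branch_omega",
    "annotate_snp_effect",
    "annotate_snp_effects_bulk",
    "nonsyn_fraction_by_category",
]

_BASES = "ACGT"


def _standard_code() -> tuple[dict[str, str], frozenset[str]]:
    from Bio.Data.CodonTable import standard_dna_table as tbl

    table = dict(tbl.forward_table)
    stops = frozenset(tbl.stop_codons)
    return table, stops


CODON_TO_AA, STOP_CODONS = _standard_code()
SENSE_CODONS = tuple(sorted(CODON_TO_AA))


def _is_sense(codon: str) -> bool:
    return codon in CODON_TO_AA


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Position j contributes ``(# synonymous single-base changes)/3``
    synonymous sites; changes creating a stop codon are nonsynonymous.
    The two counts always sum to 3.
    """
    if not _is_sense(codon):
        raise ValueError(f"not a sense codon: {codon!r}")
    s = 0.0
    for j in range(3):
        for b in _BASES:
            if b == codon[j]:
                continue
            alt = codon[:j] + b + codon[j + 1:]
            if _is_sense(alt) and CODON_TO_AA[alt] == CODON_TO_AA[codon]:
                s += 1.0 / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) differences between
    two sense codons.

    Averages over all orderings of the single-nucleotide steps from c1 to
    c2; orderings passing through a stop codon are excluded.  If every
    ordering is blocked by a stop (possible only for triple differences),
    the average falls back to all orderings, counting steps into or out
    of a stop as nonsynonymous.
    """
    if not (_is_sense(c1) and _is_sense(c2)):
        raise ValueError("pathway_counts requires sense codons")
    diffs = [j for j in range(3) if c1[j] != c2[j]]
    if not diffs:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool):
        nd = sd = 0.0
        cur = c1
        for j in order:
            nxt = cur[:j] + c2[j] + cur[j + 1:]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                if not allow_stops:
                    return None
                nd += 1.0
            elif CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return nd, sd

    paths = [walk(o, allow_stops=False) for o in itertools.permutations(diffs)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [walk(o, allow_stops=True) for o in itertools.permutations(diffs)]
    nd = sum(p[0] for p in valid) / len(valid)
    sd = sum(p[1] for p in valid) / len(valid)
    return nd, sd


def _jukes_cantor(p: float) -> float:
    """JC69 distance -3/4 ln(1 - 4p/3); nan when the correction diverges."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class KaKsResult:
    """Pairwise Nei-Gojobori result for one coding sequence pair."""

    ka: float
    ks: float
    ka_ks: float          # nan when undefined (Ks = 0 or correction diverges)
    nd: float
    sd: float
    n_sites: float        # nonsynonymous opportunities (pairwise mean)
    s_sites: float        # synonymous opportunities (pairwise mean)
    n_codons_used: int
    n_codons_skipped: int
    defined: bool


def _codon_iter(seq: str):
    for i in range(0, len(seq), 3):
        yield seq[i:i + 3]


def ng86_kaks(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks between two aligned coding sequences.

    Codon pairs containing an ambiguous base or a stop codon are skipped
    and counted.  Proportions are Jukes-Cantor corrected; the result is
    symmetric in its arguments.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be equal length")
    if len(a) % 3 != 0:
        raise ValueError("length must be divisible by 3")
    nd = sd = 0.0
    s_a = n_a = s_b = n_b = 0.0
    used = skipped = 0
    for ca, cb in zip(_codon_iter(a), _codon_iter(b)):
        if not (_is_sense(ca) and _is_sense(cb)):
            skipped += 1
            continue
        used += 1
        sa, na = codon_site_counts(ca)
        sb, nb = codon_site_counts(cb)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        d_n, d_s = pathway_counts(ca, cb)
        nd += d_n
        sd += d_s
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    if used == 0:
        return KaKsResult(float("nan"), float("nan"), float("nan"), 0.0, 0.0,
                          0.0, 0.0, 0, skipped, defined=False)
    ka = _jukes_cantor(nd / n_sites) if n_sites > 0 else float("nan")
    ks = _jukes_cantor(sd / s_sites) if s_sites > 0 else float("nan")
    if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
        ratio, defined = float("nan"), False
    else:
        ratio, defined = ka / ks, True
    return KaKsResult(ka=ka, ks=ks, ka_ks=ratio, nd=nd, sd=sd,
                      n_sites=n_sites, s_sites=s_sites,
                      n_codons_used=used, n_codons_skipped=skipped,
                      defined=defined)


# ---------------------------------------------------------------------------
# Haplotype construction from diploid genotypes
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePair:
    gene_id: str
    hap1: str
    hap2: str
    seed: int
    n_het_sites: int
    n_hom_sites: int


class GeneExcluded(Exception):
    """Raised when a gene cannot be used (indel overlap, allele mismatch)."""


def _gene_variants(matrix: GenotypeMatrix, sample_idx: int, gene: CodingGeneModel):
    """Yield (cds_index, ref_base, alt_base, gt_code) for the sample's
    variants inside the gene CDS, in translation-strand orientation."""
    on_chrom = matrix.sites_on(gene.chrom)
    idx = np.flatnonzero(on_chrom)
    lo, hi = gene.span
    idx = idx[(matrix.pos[idx] >= lo) & (matrix.pos[idx] <= hi)]
    for i in idx:
        ci = gene.cds_index_of(int(matrix.pos[i]))
        if ci is None:
            continue
        g = int(matrix.gt[i, sample_idx])
        if g in (HOM_REF, MISSING):
            continue
        ref, alt = str(matrix.ref[i]), str(matrix.alt[i])
        if gene.strand == "-":
            ref, alt = revcomp(ref), revcomp(alt)
        yield ci, ref, alt, g


def _check_gene_usable(matrix: GenotypeMatrix, gene: CodingGeneModel) -> None:
    ind = matrix.indel_positions.get(gene.chrom)
    if ind is not None and ind.size:
        lo, hi = gene.span
        if ((ind >= lo) & (ind <= hi)).any():
            raise GeneExcluded(f"gene {gene.gene_id} overlaps an indel call")


def build_virtual_haplotypes(matrix: GenotypeMatrix, sample_id: str,
                             gene: CodingGeneModel, seed: int) -> HaplotypePair:
    """Phase one individual's genotypes in a gene onto two virtual CDS copies.

    Homozygous-alt sites are substituted into both copies; each
    heterozygous site's alt allele is assigned to copy 1 or copy 2 with
    probability 1/2, independently per site, deterministically under the
    seed.  Genes overlapping indel calls, or with an allele that does not
    match the reference CDS base, are excluded.
    """
    _check_gene_usable(matrix, gene)
    rng = np.random.default_rng(seed)
    si = matrix.sample_index(sample_id)
    h1 = list(gene.cds_seq)
    h2 = list(gene.cds_seq)
    n_het = n_hom = 0
    for ci, ref, alt, g in _gene_variants(matrix, si, gene):
        if h1[ci].upper() != ref.upper():
            raise GeneExcluded(
                f"gene {gene.gene_id}: ref allele {ref!r} does not match CDS "
                f"base {h1[ci]!r} at codon-frame index {ci}")
        if g == HOM_ALT:
            h1[ci] = alt
            h2[ci] = alt
            n_hom += 1
        elif g == HET:
            if rng.integers(2) == 0:
                h1[ci] = alt
            else:
                h2[ci] = alt
            n_het += 1
    return HaplotypePair(gene_id=gene.gene_id, hap1="".join(h1), hap2="".join(h2),
                         seed=seed, n_het_sites=n_het, n_hom_sites=n_hom)


def consensus_haploid(matrix: GenotypeMatrix, sample_id: str,
                      gene: CodingGeneModel, seed: int) -> str:
    """One haploid CDS from a diploid individual: hom calls applied,
    het calls resolved by a fair coin under the seed."""
    _check_gene_usable(matrix, gene)
    rng = np.random.default_rng(seed)
    si = matrix.sample_index(sample_id)
    seq = list(gene.cds_seq)
    for ci, ref, alt, g in _gene_variants(matrix, si, gene):
        if seq[ci].upper() != ref.upper():
            raise GeneExcluded(
                f"gene {gene.gene_id}: ref allele mismatch at index {ci}")
        if g == HOM_ALT or (g == HET and rng.integers(2) == 0):
            seq[ci] = alt
    return "".join(seq)


# ---------------------------------------------------------------------------
# Two-ratio branch-specific omega
# ---------------------------------------------------------------------------

@dataclass
class BranchOmega:
    """Counting two-ratio result: focal-branch vs background rates."""

    omega_focal: float       # omega_1
    omega_background: float  # omega_0
    nd_focal: float
    sd_focal: float
    nd_background: float
    sd_background: float
    n_sites: float
    s_sites: float
    n_codons_used: int
    n_codons_excluded: int   # three-allele / conflicting-pattern codons
    focal_defined: bool
    background_defined: bool
    method: str = "NG86-two-ratio"


def branch_specific_omega(focal_cds: str, sister_cds: str,
                          outgroup_cds: str) -> BranchOmega:
    """Assign substitutions to the focal or background branch by parsimony.

    Per codon: if exactly one sequence differs from the other two, the
    agreeing pair defines the ancestral codon and the change is placed on
    the odd sequence's branch -- the focal branch when the focal sequence
    is odd, the background otherwise (sister-specific and outgroup/
    ancestral changes are pooled as background).  Codons where all three
    sequences differ are excluded and counted.  Site opportunities come
    from the inferred ancestral codons.
    """
    seqs = [focal_cds.upper(), sister_cds.upper(), outgroup_cds.upper()]
    if len({len(s) for s in seqs}) != 1 or len(seqs[0]) % 3 != 0:
        raise ValueError("three equal-length in-frame sequences required")
    nd_f = sd_f = nd_b = sd_b = 0.0
    s_sites = n_sites = 0.0
    used = excluded = 0
    for cf, cs, co in zip(*[_codon_iter(s) for s in seqs]):
        if not (_is_sense(cf) and _is_sense(cs) and _is_sense(co)):
            excluded += 1
            continue
        if cf == cs == co:
            anc = cf
            used += 1
        elif cf == cs:          # outgroup odd: ancestral-branch change
            anc = cf
            d_n, d_s = pathway_counts(anc, co)
            nd_b += d_n
            sd_b += d_s
            used += 1
        elif cf == co:          # sister odd: background
            anc = cf
            d_n, d_s = pathway_counts(anc, cs)
            nd_b += d_n
            sd_b += d_s
            used += 1
        elif cs == co:          # focal odd: focal branch
            anc = cs
            d_n, d_s = pathway_counts(anc, cf)
            nd_f += d_n
            sd_f += d_s
            used += 1
        else:                   # all three distinct: conflicting pattern
            excluded += 1
            continue
        sa, na = codon_site_counts(anc)
        s_sites += sa
        n_sites += na

    def _omega(nd: float, sd: float) -> tuple[float, bool]:
        if sd <= 0 or s_sites <= 0 or n_sites <= 0:
            return float("nan"), False
        return (nd / n_sites) / (sd / s_sites), True

    w1, d1 = _omega(nd_f, sd_f)
    w0, d0 = _omega(nd_b, sd_b)
    return BranchOmega(omega_focal=w1, omega_background=w0,
                       nd_focal=nd_f, sd_focal=sd_f,
                       nd_background=nd_b, sd_background=sd_b,
                       n_sites=n_sites, s_sites=s_sites,
                       n_codons_used=used, n_codons_excluded=excluded,
                       focal_defined=d1, background_defined=d0)


def pooled_branch_omega(results: list[BranchOmega]) -> tuple[float, float]:
    """Aggregate (omega_1, omega_0) by pooling counts across genes.

    Pooling sums Nd, Sd and site opportunities before forming the rate
    ratio, which keeps the aggregate defined even when individual genes
    have no synonymous changes on a branch.
    """
    nd_f = sum(r.nd_focal for r in results)
    sd_f = sum(r.sd_focal for r in results)
    nd_b = sum(r.nd_background for r in results)
    sd_b = sum(r.sd_background for r in results)
    n = sum(r.n_sites for r in results)
    s = sum(r.s_sites for r in results)
    w1 = (nd_f / n) / (sd_f / s) if sd_f > 0 and n > 0 else float("nan")
    w0 = (nd_b / n) / (sd_b / s) if sd_b > 0 and n > 0 else float("nan")
    return w1, w0


# ---------------------------------------------------------------------------
# Per-SNP effect annotation
# ---------------------------------------------------------------------------

def annotate_snp_effect(chrom: str, pos: int, ref: str, alt: str,
                        genes: list[CodingGeneModel]) -> str:
    """Classify a biallelic SNV as noncoding / synonymous / nonsynonymous.

    The alt allele is substituted into the codon of every CDS containing
    the site (strand-aware); sites in overlapping genes with conflicting
    effects are 'ambiguous'.  A change into or out of a stop codon is
    nonsynonymous.
    """
    effects = set()
    for gene in genes:
        ci = gene.cds_index_of(pos) if gene.chrom == chrom else None
        if ci is None:
            continue
        r, a = (ref, alt) if gene.strand == "+" else (revcomp(ref), revcomp(alt))
        codon_start = (ci // 3) * 3
        codon = gene.cds_seq[codon_start:codon_start + 3].upper()
        off = ci - codon_start
        if codon[off] != r.upper():
            log.warning("ref mismatch at %s:%d in %s; site skipped",
                        chrom, pos, gene.gene_id)
            continue
        mutant = codon[:off] + a.upper() + codon[off + 1:]
        if not _is_sense(codon) or not _is_sense(mutant):
            effects.add("nonsynonymous")
        elif CODON_TO_AA[codon] == CODON_TO_AA[mutant]:
            effects.add("synonymous")
        else:
            effects.add("nonsynonymous")
    if not effects:
        return "noncoding"
    if len(effects) > 1:
        return "ambiguous"
    return effects.pop()


def annotate_snp_effects_bulk(matrix: GenotypeMatrix,
                              genes: list[CodingGeneModel]) -> list[str]:
    """Vector of ``annotate_snp_effect`` results for every matrix site.

    Uses a per-chromosome interval index over gene spans so only genes
    that can overlap a site are inspected; results are identical to
    calling ``annotate_snp_effect`` per site."""
    import bisect

    by_chrom: dict[str, list[CodingGeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index: dict[str, tuple[list[int], list[int], list[CodingGeneModel]]] = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: g.span[0])
        starts = [g.span[0] for g in gs]
        # running maximum of span ends lets the back-scan stop early even
        # when spans overlap arbitrarily
        prefix_max_end: list[int] = []
        m = 0
        for g in gs:
            m = max(m, g.span[1])
            prefix_max_end.append(m)
        index[chrom] = (starts, prefix_max_end, gs)

    out = []
    for i in range(matrix.n_sites):
        chrom = matrix.chrom[i]
        if chrom not in index:
            out.append("noncoding")
            continue
        starts, pmax, gs = index[chrom]
        pos = int(matrix.pos[i])
        j = bisect.bisect_right(starts, pos) - 1
        cands = []
        while j >= 0 and pmax[j] >= pos:
            if gs[j].span[1] >= pos:
                cands.append(gs[j])
            j -= 1
        if not cands:
            out.append("noncoding")
            continue
        out.append(annotate_snp_effect(chrom, pos, str(matrix.ref[i]),
                                       str(matrix.alt[i]), cands))
    return out


def nonsyn_fraction_by_category(categories, effects) -> dict[str, float]:
    """Per-category proportion of nonsynonymous SNPs among coding SNPs.

    ``categories`` and ``effects`` are aligned per-site sequences; sites
    with effect 'noncoding' or 'ambiguous' are ignored.  Categories with
    no coding SNPs get nan (undefined-flagged).
    """
    counts: dict[str, list[int]] = {}
    for cat, eff in zip(categories, effects):
        if eff not in ("synonymous", "nonsynonymous"):
            continue
        c = counts.setdefault(cat, [0, 0])
        if eff == "nonsynonymous":
            c[0] += 1
        else:
            c[1] += 1
    out = {}
    for cat, (n_non, n_syn) in counts.items():
        tot = n_non + n_syn
        out[cat] = n_non / tot if tot else float("nan")
    return out
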
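"""Synthetic genomes, genotypes, depth tracks, gene models and expression
matrices with known truth.

The generator emulates the structure of a two-species resequencing study
of a young Y-autosome fusion:

* two species ("focal" and "sister") separated by fixed differences and
  carrying within-species polymorphism, plus one diverged outgroup;
* an ancestral sex chromosome with a non-recombining span where X-Y
  divergent sites make males of both species heterozygous, and a deleted
  (hemizygous) span where male read depth is halved and males are called
  homozygous for the X allele;
* a neo-sex chromosome (in the focal species only) whose X-Y
  heterozygosity declines with distance from the fusion end,
  ``p(d) = p_max * exp(-d / scale)`` by default;
* coding genes whose neo-Y (and neo-X) mutations are accepted or
  rejected to achieve a target dN/dS under Nei-Gojobori opportunity
  counting;
* per-sample binned depth tracks and a probe-level expression matrix
  with planted sex-, species- and tissue-biased genes.

Default sample counts follow the study design the pipeline targets:
five focal males, five focal females, one sister male, five sister
females and one outgroup female.  Every emitted variant site carries
exactly one truth label.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codonevol
from .io_formats import (
    HET, HOM_ALT, HOM_REF, CodingGeneModel, CoverageTrack, GenotypeMatrix,
    SampleSheet, revcomp, write_coverage, write_genotypes,
)

log = logging.getLogger("neosexscan")

__all__ = [
    "SimulationConfig",
    "TruthTables",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_genotypes",
    "simulate_sex_coverage",
    "simulate_coding_divergence",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Tunable truth of the synthetic study.  Rates are per bp."""

    # chromosome plan
    n_autosomes: int = 10
    autosome_length: int = 2_000_000
    neo_chrom: str = "chrNeo"
    neo_chrom_length: int = 10_000_000
    anc_chrom: str = "chrAnc"
    anc_chrom_length: int = 4_000_000

    # ancestral sex chromosome
    anc_nonrecomb_span: tuple[int, int] = (1, 3_000_000)
    anc_deleted_span: tuple[int, int] = (500_000, 2_000_000)
    male_depth_factor: float = 0.5
    anc_xy_het_rate: float = 0.004

    # neo-sex chromosome (focal species only)
    fusion_end: int = 1
    neo_het_p_max: float = 0.01
    neo_het_decay_scale: float = 5_000_000.0
    neo_decay_form: str = "exponential"  # or "logistic"
    neo_y_coding_omega: float = 0.5
    neo_x_coding_omega: float = 0.2
    neo_y_site_fraction: float = 0.5     # share of X-Y sites that are Y-specific

    # species parameters
    fixed_diff_rate: float = 0.002
    polymorphism_rate: float = 0.002
    outgroup_divergence_rate: float = 0.02
    # focal-species polymorphism on the neo-sex chromosome is reduced
    # (recombination suppression around the fusion lowers diversity)
    neo_polymorphism_factor: float = 0.5

    # samples
    n_focal_males: int = 5
    n_focal_females: int = 5
    n_sister_males: int = 1
    n_sister_females: int = 5
    n_outgroup_females: int = 1

    # depth model
    depth_mean: float = 50.0
    coverage_bin: int = 1000
    sample_scale_jitter: float = 0.15

    # genes
    n_genes: int = 100
    cds_codons_range: tuple[int, int] = (100, 400)

    # expression
    n_expression_replicates: int = 4
    expr_bias_rate_autosome: float = 0.05
    expr_bias_rate_sex_chrom: float = 0.15
    expr_species_bias_rate: float = 0.05
    expr_bias_effect: float = 1.0        # log2 units
    expr_noise_sd: float = 0.25
    expr_base_log2: float = 8.0
    expr_base_sd: float = 2.0            # between-gene spread of base level
    expr_error_log2: float = 4.0         # background/error signal level
    tissue_specific_rate: float = 0.05   # per sex-specific tissue class
    # Neo-Y regulatory decay: each upstream X-Y divergent site silences the
    # Y copy's regulation independently with this probability; a silenced Y
    # copy halves the male dose (a 1 log2 female bias).
    cis_silencing_per_het: float = 0.01

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("anc_xy_het_rate", "neo_het_p_max", "fixed_diff_rate",
                     "polymorphism_rate", "outgroup_divergence_rate",
                     "male_depth_factor", "neo_y_site_fraction",
                     "neo_polymorphism_factor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        s, e = self.anc_nonrecomb_span
        ds, de = self.anc_deleted_span
        if not (1 <= s <= e <= self.anc_chrom_length):
            raise ValueError("anc_nonrecomb_span outside chromosome")
        if not (s <= ds <= de <= e):
            raise ValueError("anc_deleted_span must lie inside anc_nonrecomb_span")
        if self.neo_decay_form not in ("exponential", "logistic"):
            raise ValueError("neo_decay_form must be exponential|logistic")

    def chrom_plan(self) -> dict[str, int]:
        plan = {f"chrA{i + 1:02d}": self.autosome_length
                for i in range(self.n_autosomes)}
        plan[self.neo_chrom] = self.neo_chrom_length
        plan[self.anc_chrom] = self.anc_chrom_length
        return plan

    def sample_sheet(self) -> SampleSheet:
        rows = []
        for i in range(self.n_focal_males):
            rows.append((f"FM{i + 1}", "focal", "male"))
        for i in range(self.n_focal_females):
            rows.append((f"FF{i + 1}", "focal", "female"))
        for i in range(self.n_sister_males):
            rows.append((f"SM{i + 1}", "sister", "male"))
        for i in range(self.n_sister_females):
            rows.append((f"SF{i + 1}", "sister", "female"))
        for i in range(self.n_outgroup_females):
            rows.append((f"OF{i + 1}", "outgroup", "female"))
        return SampleSheet(pd.DataFrame(rows, columns=["sample_id", "species", "sex"]))

    def roles(self) -> dict[str, list[str]]:
        sheet = self.sample_sheet()
        return {
            "focal_males": sheet.select("focal", "male"),
            "focal_females": sheet.select("focal", "female"),
            "other_females": sheet.select("sister", "female"),
        }

    def decay_probability(self, distance) -> np.ndarray:
        """X-Y heterozygosity probability at distance d from the fusion."""
        d = np.asarray(distance, dtype=float)
        s = self.neo_het_decay_scale
        if self.neo_decay_form == "exponential":
            return self.neo_het_p_max * np.exp(-d / s)
        return self.neo_het_p_max / (1.0 + np.exp((d - s) / (0.2 * s)))


@dataclass
class TruthTables:
    """Ground truth emitted with every simulated dataset.

    ``sites`` has one row per variant site with a unique ``category``
    label plus female-visible species flags (computed from the sampled
    female genotypes, since the fixed/polymorphic rules quantify over the
    five sampled females of each species).
    """

    sites: pd.DataFrame   # chrom,pos,category,true_fixed_diff,true_poly_focal,true_poly_sister
    genes: pd.DataFrame   # gene_id,chrom,start,end,strand,sex_bias,species_bias,tissue_class
    deleted_span: tuple[str, int, int]

    def write(self, out_dir: str) -> None:
        self.sites.to_csv(os.path.join(out_dir, "truth_sites.tsv"),
                          sep="\t", index=False)
        self.genes.to_csv(os.path.join(out_dir, "truth_genes.tsv"),
                          sep="\t", index=False)


@dataclass
class SimulatedDataset:
    """Paths and in-memory handles for one simulated study."""

    config: SimulationConfig
    sample_sheet: SampleSheet
    matrix: GenotypeMatrix
    gene_models: list[CodingGeneModel]
    coverage: dict[str, CoverageTrack]
    truth: TruthTables
    paths: dict[str, str] = field(default_factory=dict)
    expression: dict[str, pd.DataFrame] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _random_reference(plan: dict[str, int], rng) -> dict[str, np.ndarray]:
    return {c: _BASES[rng.integers(0, 4, size=ln)] for c, ln in plan.items()}


def _random_cds(n_codons: int, rng) -> str:
    """ATG + random sense codons + one stop codon."""
    sense = [c for c in codonevol.SENSE_CODONS if c != "ATG"]
    body = rng.choice(len(sense), size=n_codons - 2)
    stop = sorted(codonevol.STOP_CODONS)[rng.integers(3)]
    return "ATG" + "".join(sense[i] for i in body) + stop


def _place_genes(cfg: SimulationConfig, plan: dict[str, int], rng
                 ) -> list[CodingGeneModel]:
    """Place non-overlapping single-CDS genes proportionally to length."""
    if cfg.n_genes == 0:
        return []
    chroms = list(plan)
    lengths = np.array([plan[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    genes: list[CodingGeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    lo_c, hi_c = cfg.cds_codons_range
    attempts = 0
    while len(genes) < cfg.n_genes:
        attempts += 1
        if attempts > cfg.n_genes * 50:
            raise ValueError("could not place genes; chromosome plan too small")
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        n_codons = int(rng.integers(lo_c, hi_c + 1))
        glen = 3 * n_codons
        if glen >= plan[chrom] - 2:
            raise ValueError(f"gene of {glen} bp exceeds {chrom}")
        start = int(rng.integers(1, plan[chrom] - glen))
        end = start + glen - 1
        if any(not (end < s or start > e) for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.7 else "-"
        seq = _random_cds(n_codons, rng)
        genes.append(CodingGeneModel(
            gene_id=f"gene{len(genes) + 1:04d}", chrom=chrom,
            cds_intervals=[(start, end)], strand=strand, cds_seq=seq))
    genes.sort(key=lambda g: (g.chrom, g.span[0]))
    return genes


def _patch_reference(ref: dict[str, np.ndarray],
                     genes: list[CodingGeneModel]) -> None:
    for g in genes:
        s, e = g.span
        seq = g.cds_seq if g.strand == "+" else revcomp(g.cds_seq)
        ref[g.chrom][s - 1:e] = np.frombuffer(seq.encode(), dtype=np.uint8)


def _unique_positions(length: int, count: int, rng) -> np.ndarray:
    """`count` distinct 1-based positions, uniform on [1, length]."""
    if count <= 0:
        return np.empty(0, dtype=np.int64)
    draw = int(count * 1.05) + 10
    pos = np.unique(rng.integers(1, length + 1, size=draw))
    rng.shuffle(pos)
    return np.sort(pos[:count]).astype(np.int64)


def _sfs_counts(n_chrom: int, size: int, rng) -> np.ndarray:
    """Derived-allele copy counts from a neutral-like SFS, P(i) ~ 1/i."""
    i = np.arange(1, n_chrom)
    w = 1.0 / i
    return rng.choice(i, size=size, p=w / w.sum())


def _choose_calibrated_change(gene: CodingGeneModel, omega: float, rng
                              ) -> tuple[int, str, str]:
    """(genomic position, ref base, alt base) for one coding mutation.

    Candidate single-base changes are drawn uniformly over the gene's
    codons (the terminal stop excluded); changes creating a stop are
    rejected, synonymous changes always accepted, nonsynonymous accepted
    with probability ``omega`` -- the classical acceptance-rejection
    scheme whose expected Nd/Sd ratio matches ``omega`` under
    Nei-Gojobori opportunity counting.
    """
    seq = gene.cds_seq
    n_codons = len(seq) // 3 - 1  # exclude terminal stop codon
    gpos = gene.genomic_positions()
    for _ in range(10_000):
        ci = int(rng.integers(0, n_codons))
        off = int(rng.integers(0, 3))
        idx = 3 * ci + off
        codon = seq[3 * ci:3 * ci + 3]
        ref = codon[off]
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        mutant = codon[:off] + alt + codon[off + 1:]
        if mutant in codonevol.STOP_CODONS:
            continue
        syn = codonevol.CODON_TO_AA[mutant] == codonevol.CODON_TO_AA[codon]
        if not syn and rng.random() >= omega:
            continue
        g = int(gpos[idx])
        if gene.strand == "-":
            return g, revcomp(ref), revcomp(alt)
        return g, ref, alt
    raise RuntimeError(f"no acceptable mutation found in {gene.gene_id}")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _collides_with_xy_pattern(row: np.ndarray, fm: list[int],
                              ff: list[int]) -> bool:
    """True when a focal polymorphic draw exactly replicates an X-, Y- or
    shared-type genotype pattern (other-species females are homozygous
    reference at such sites, so only these cases can collide)."""
    g_fm, g_ff = row[fm], row[ff]
    fm_het = bool((g_fm == HET).all())
    ff_uniform_hom = bool((g_ff == HOM_REF).all() or (g_ff == HOM_ALT).all())
    if fm_het and ff_uniform_hom:
        return True  # X- or Y-type pattern
    return bool((g_fm == HOM_ALT).all() and (g_ff == HOM_ALT).all())


def simulate_genotypes(cfg: SimulationConfig, rng=None,
                       genes: list[CodingGeneModel] | None = None,
                       ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw all variant sites and diploid genotypes; returns the matrix
    and the per-site truth table."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genes = genes or []
    sheet = cfg.sample_sheet()
    samples = sheet.sample_ids
    idx = {s: i for i, s in enumerate(samples)}
    fm = [idx[s] for s in sheet.select("focal", "male")]
    ff = [idx[s] for s in sheet.select("focal", "female")]
    sm = [idx[s] for s in sheet.select("sister", "male")]
    sf = [idx[s] for s in sheet.select("sister", "female")]
    og = [idx[s] for s in sheet.select("outgroup")]
    focal = fm + ff
    sister = sm + sf
    n_samples = len(samples)
    plan = cfg.chrom_plan()
    genes_by_chrom: dict[str, list[CodingGeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    records: dict[tuple[str, int], dict] = {}

    def add_site(chrom: str, pos: int, category: str, gt_row: np.ndarray,
                 ref: str | None = None, alt: str | None = None) -> None:
        key = (chrom, int(pos))
        if key in records:  # collisions between categories: first wins
            return
        records[key] = {"category": category, "gt": gt_row, "ref": ref, "alt": alt}

    def blank() -> np.ndarray:
        return np.full(n_samples, HOM_REF, dtype=np.int8)

    ds, de = cfg.anc_deleted_span
    nrs, nre = cfg.anc_nonrecomb_span

    for chrom, length in plan.items():
        is_neo = chrom == cfg.neo_chrom
        is_anc = chrom == cfg.anc_chrom
        # --- fixed differences between species (labelled "shared" on the
        # neo-sex chromosome, where they are X-Y-shared derived alleles)
        n_fd = rng.binomial(length, cfg.fixed_diff_rate)
        for p in _unique_positions(length, n_fd, rng):
            row = blank()
            row[focal] = HOM_ALT
            add_site(chrom, p, "shared" if is_neo else "fixed_diff", row)
        # --- within-species polymorphism
        for species_name, members, label in (
            ("focal", focal, "polymorphic_focal"),
            ("sister", sister, "polymorphic_sister"),
        ):
            n_chrom = 2 * len(members)
            if n_chrom < 2:
                continue
            rate = cfg.polymorphism_rate
            if is_neo and species_name == "focal":
                rate *= cfg.neo_polymorphism_factor
            n_poly = rng.binomial(length, rate)
            if n_poly == 0:
                continue
            pos = _unique_positions(length, n_poly, rng)
            counts = _sfs_counts(n_chrom, pos.size, rng)
            for p, k in zip(pos, counts):
                # Redraw carrier assignments that replicate an X/Y pattern
                # exactly (all focal males het with uniform-homozygous
                # females, or a shared-type fixation) so every site keeps
                # a single unambiguous truth label.
                for _ in range(200):
                    carriers = rng.permutation(n_chrom)[:k]
                    per_ind = np.bincount(carriers // 2, minlength=len(members))
                    row = blank()
                    for m, c in zip(members, per_ind):
                        row[m] = (HOM_REF, HET, HOM_ALT)[int(c)]
                    if species_name != "focal":
                        break
                    if not _collides_with_xy_pattern(row, fm, ff):
                        break
                else:
                    continue  # pattern unavoidable; drop the site
                add_site(chrom, p, label, row)
        # --- outgroup divergence
        n_og = rng.binomial(length, cfg.outgroup_divergence_rate)
        for p in _unique_positions(length, n_og, rng):
            row = blank()
            row[og] = HOM_ALT
            add_site(chrom, p, "outgroup_divergent", row)
        # --- X-Y divergent sites
        if is_neo and cfg.neo_het_p_max > 0:
            # Inhomogeneous density p(d); exact for the exponential form,
            # thinning against p_max otherwise.
            if cfg.neo_decay_form == "exponential":
                s = cfg.neo_het_decay_scale
                mean_n = cfg.neo_het_p_max * s * (1.0 - math.exp(-length / s))
                n_xy = rng.poisson(mean_n)
                u = rng.random(n_xy)
                d = -s * np.log1p(-u * (1.0 - math.exp(-length / s)))
            else:
                cand = rng.binomial(length, cfg.neo_het_p_max)
                d_all = rng.integers(0, length, size=cand).astype(float)
                keep = rng.random(cand) < (cfg.decay_probability(d_all)
                                           / cfg.neo_het_p_max)
                d = d_all[keep]
            if cfg.fusion_end <= 1:
                pos_xy = np.clip(np.floor(d).astype(np.int64) + 1, 1, length)
            else:
                pos_xy = np.clip(cfg.fusion_end - np.floor(d).astype(np.int64),
                                 1, length)
            is_y = rng.random(pos_xy.size) < cfg.neo_y_site_fraction
            for p, y_specific in zip(pos_xy, is_y):
                ref = alt = None
                p = int(p)
                host = next((g for g in genes_by_chrom.get(chrom, [])
                             if g.cds_index_of(p) is not None), None)
                if host is not None:
                    omega = (cfg.neo_y_coding_omega if y_specific
                             else cfg.neo_x_coding_omega)
                    p, ref, alt = _choose_calibrated_change(host, omega, rng)
                row = blank()
                row[fm] = HET
                if not y_specific:
                    row[ff] = HOM_ALT
                add_site(chrom, p, "Y_specific" if y_specific else "X_specific",
                         row, ref, alt)
        if is_anc and cfg.anc_xy_het_rate > 0:
            # X-Y divergent sites in the non-recombining, non-deleted span:
            # males of both species are heterozygous there.
            segs = [(nrs, ds - 1), (de + 1, nre)]
            for a, b in segs:
                span = b - a + 1
                if span <= 0:
                    continue
                n_axy = rng.binomial(span, cfg.anc_xy_het_rate)
                for p in _unique_positions(span, n_axy, rng) + (a - 1):
                    row = blank()
                    row[fm] = HET
                    row[sm] = HET
                    add_site(chrom, p, "Y_specific", row)

    # ---- assemble, sorted by (chrom, pos)
    order = sorted(records)
    chroms = np.array([k[0] for k in order], dtype=object)
    pos = np.array([k[1] for k in order], dtype=np.int64)
    gt = (np.vstack([records[k]["gt"] for k in order])
          if order else np.empty((0, n_samples), np.int8))
    refs = np.array([records[k]["ref"] or "" for k in order], dtype=object)
    alts = np.array([records[k]["alt"] or "" for k in order], dtype=object)

    # depth per call: halved for males over the deleted span
    scales = 1.0 + cfg.sample_scale_jitter * (rng.random(n_samples) * 2 - 1)
    male_idx = np.zeros(n_samples, dtype=bool)
    male_idx[fm] = True
    male_idx[sm] = True
    mean = np.tile(cfg.depth_mean * scales, (len(order), 1))
    in_del = (chroms == cfg.anc_chrom) & (pos >= ds) & (pos <= de)
    mean[np.ix_(in_del, male_idx)] *= cfg.male_depth_factor
    depth = rng.poisson(mean).astype(np.int32)

    # female-visible species flags (the fixed/polymorphic rules quantify
    # over the sampled females only)
    def _flags(row: np.ndarray) -> tuple[bool, bool, bool]:
        a, b = row[ff], row[sf]
        polyA = bool((a == HET).any() or (len(a) and a.min() != a.max()))
        polyB = bool((b == HET).any() or (len(b) and b.min() != b.max()))
        fixed = bool(len(a) and len(b) and not polyA and not polyB
                     and a[0] != b[0] and HET not in (a[0], b[0]))
        return fixed, polyA, polyB

    truth_rows = []
    for k, c, p in zip(order, chroms, pos):
        fixed, pa, pb = _flags(records[k]["gt"])
        truth_rows.append((c, int(p), records[k]["category"], fixed, pa, pb))
    truth = pd.DataFrame(truth_rows, columns=[
        "chrom", "pos", "category", "true_fixed_diff",
        "true_poly_focal", "true_poly_sister"])

    matrix = GenotypeMatrix(chrom=chroms, pos=pos, ref=refs, alt=alts,
                            gt=gt.astype(np.int8), depth=depth,
                            samples=samples)
    return matrix, truth


def _fill_alleles(matrix: GenotypeMatrix, ref: dict[str, np.ndarray],
                  rng) -> None:
    """Assign ref alleles from the reference and random distinct alts for
    sites whose alleles were not fixed by coding-mutation calibration."""
    for i in range(matrix.n_sites):
        base = chr(ref[matrix.chrom[i]][matrix.pos[i] - 1])
        if matrix.ref[i]:
            continue
        matrix.ref[i] = base
        others = [b for b in "ACGT" if b != base]
        matrix.alt[i] = others[int(rng.integers(3))]


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def simulate_sex_coverage(cfg: SimulationConfig, rng=None,
                          ) -> dict[str, CoverageTrack]:
    """Binned depth tracks for every sample; male depth over the deleted
    span of the ancestral sex chromosome is scaled by the depth factor."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sheet = cfg.sample_sheet()
    plan = cfg.chrom_plan()
    b = cfg.coverage_bin
    ds, de = cfg.anc_deleted_span
    tracks: dict[str, CoverageTrack] = {}
    for _, rec in sheet.frame.iterrows():
        scale = 1.0 + cfg.sample_scale_jitter * (rng.random() * 2 - 1)
        depth: dict[str, np.ndarray] = {}
        for chrom, length in plan.items():
            n_bins = (length + b - 1) // b
            mean = np.full(n_bins, cfg.depth_mean * scale)
            if chrom == cfg.anc_chrom and rec["sex"] == "male":
                starts = np.arange(n_bins, dtype=np.int64) * b + 1
                hit = (starts <= de) & (starts + b - 1 >= ds)
                mean[hit] *= cfg.male_depth_factor
            depth[chrom] = rng.poisson(mean).astype(float)
        tracks[rec["sample_id"]] = CoverageTrack(
            sample_id=rec["sample_id"], depth=depth, bin_size=b)
    return tracks


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _simulate_expression(cfg: SimulationConfig, genes: list[CodingGeneModel],
                         matrix: GenotypeMatrix, truth_sites: pd.DataFrame,
                         rng) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Probe x array raw-signal matrix plus per-gene truth labels."""
    sheet = cfg.sample_sheet()
    arrays = []
    for species in ("focal", "sister"):
        for sex in ("male", "female"):
            for tissue in ("brain", "gonad"):
                for r in range(cfg.n_expression_replicates):
                    arrays.append((f"{species[:1].upper()}{sex[:1].upper()}"
                                   f"{tissue[:2]}{r + 1}", species, sex, tissue))
    array_map = pd.DataFrame(arrays, columns=["array_id", "species", "sex", "tissue"])

    sex_chroms = {cfg.neo_chrom, cfg.anc_chrom}
    # upstream X-Y het counts (10 kb, strand-aware) for cis coupling
    het_mask = truth_sites["category"].isin(["X_specific", "Y_specific"])
    het_sites = truth_sites[het_mask]
    up_counts = {}
    for g in genes:
        sub = het_sites[het_sites["chrom"] == g.chrom]
        if g.strand == "+":
            lo, hi = g.tss - 10_000, g.tss - 1
        else:
            lo, hi = g.tss + 1, g.tss + 10_000
        up_counts[g.gene_id] = int(((sub["pos"] >= lo) & (sub["pos"] <= hi)).sum())

    gene_rows = []
    signal_log2 = {}
    for g in genes:
        bias_rate = (cfg.expr_bias_rate_sex_chrom if g.chrom in sex_chroms
                     else cfg.expr_bias_rate_autosome)
        sex_bias = "none"
        if rng.random() < bias_rate:
            sex_bias = "male" if rng.random() < 0.5 else "female"
        species_bias = bool(rng.random() < cfg.expr_species_bias_rate)
        tissue_class = "none"
        u = rng.random()
        if u < cfg.tissue_specific_rate:
            tissue_class = "testis"
        elif u < 2 * cfg.tissue_specific_rate:
            tissue_class = "ovary"
        base = cfg.expr_base_log2 + rng.normal(0, cfg.expr_base_sd)
        # signed sex effect in log2 units, positive = female-biased
        signed = 0.0
        if sex_bias == "female":
            signed += cfg.expr_bias_effect
        elif sex_bias == "male":
            signed -= cfg.expr_bias_effect
        if g.chrom == cfg.neo_chrom:
            p_silenced = 1.0 - (1.0 - cfg.cis_silencing_per_het) ** up_counts[g.gene_id]
            if rng.random() < p_silenced:
                # Y copy silenced: males keep one dose, a 1 log2 female bias
                signed += 1.0
        sex_bias = ("none" if signed == 0.0
                    else "female" if signed > 0 else "male")
        effect = abs(signed)
        vals = np.empty(len(array_map))
        for j, arr in array_map.iterrows():
            v = base
            if tissue_class == "testis" and not (arr["sex"] == "male"
                                                 and arr["tissue"] == "gonad"):
                v = cfg.expr_error_log2
            elif tissue_class == "ovary" and not (arr["sex"] == "female"
                                                  and arr["tissue"] == "gonad"):
                v = cfg.expr_error_log2
            if arr["tissue"] == "brain" and sex_bias != "none":
                half = effect / 2.0
                v += half if arr["sex"] == sex_bias else -half
            if arr["tissue"] == "brain" and species_bias:
                v += cfg.expr_bias_effect / 2.0 * (1 if arr["species"] == "focal"
                                                   else -1)
            vals[j] = v
        signal_log2[g.gene_id] = vals
        gene_rows.append((g.gene_id, g.chrom, g.span[0], g.span[1], g.strand,
                          sex_bias, species_bias, tissue_class,
                          up_counts[g.gene_id], effect))
    gene_truth = pd.DataFrame(gene_rows, columns=[
        "gene_id", "chrom", "start", "end", "strand", "sex_bias",
        "species_bias", "tissue_class", "upstream_het_10kb", "sex_effect_log2"])

    # two probes per gene, lognormal noise, per-array scale factors
    probe_rows, probe_ids = [], []
    array_scale = 2.0 ** rng.uniform(-0.5, 0.5, size=len(array_map))
    data = []
    for g in genes:
        for k in range(2):
            pid = f"{g.gene_id}_p{k + 1}"
            probe_ids.append(pid)
            probe_rows.append((pid, g.gene_id, g.chrom, g.tss, g.strand))
            noise = rng.normal(0, cfg.expr_noise_sd, size=len(array_map))
            offset = rng.normal(0, 0.3)
            data.append(2.0 ** (signal_log2[g.gene_id] + offset + noise)
                        * array_scale)
    signals = pd.DataFrame(np.vstack(data) if data else np.empty((0, len(array_map))),
                           index=probe_ids, columns=array_map["array_id"])
    probe_map = pd.DataFrame(probe_rows, columns=["probe_id", "gene_id",
                                                  "chrom", "tss", "strand"])
    return ({"signals": signals, "probe_map": probe_map,
             "array_map": array_map}, gene_truth)


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def _write_fasta(ref: dict[str, np.ndarray], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, arr in ref.items():
            fh.write(f">{chrom}\n")
            s = arr.tobytes().decode()
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def _write_gff(genes: list[CodingGeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(f"{g.chrom}\tneosexscan\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            fh.write(f"{g.chrom}\tneosexscan\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}.t1;Parent={g.gene_id}\n")
            for i, (cs, ce) in enumerate(g.cds_intervals):
                fh.write(f"{g.chrom}\tneosexscan\tCDS\t{cs}\t{ce}\t.\t{g.strand}"
                         f"\t0\tID={g.gene_id}.cds{i + 1};Parent={g.gene_id}.t1\n")


def simulate_dataset(cfg: SimulationConfig, out_dir: str | None = None
                     ) -> SimulatedDataset:
    """Generate a complete synthetic study.

    With ``out_dir`` set, writes reference FASTA, VCF, per-sample
    bedGraph coverage, GFF3, expression TSVs, the sample sheet and truth
    tables in the formats the pipeline's readers accept; the same seed
    yields byte-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    plan = cfg.chrom_plan()
    ref = _random_reference(plan, rng)
    genes = _place_genes(cfg, plan, rng)
    _patch_reference(ref, genes)
    matrix, truth_sites = simulate_genotypes(cfg, rng, genes)
    _fill_alleles(matrix, ref, rng)
    tracks = simulate_sex_coverage(cfg, rng)
    expression, gene_truth = _simulate_expression(cfg, genes, matrix,
                                                  truth_sites, rng)
    truth = TruthTables(sites=truth_sites, genes=gene_truth,
                        deleted_span=(cfg.anc_chrom, *cfg.anc_deleted_span))
    sheet = cfg.sample_sheet()
    ds = SimulatedDataset(config=cfg, sample_sheet=sheet, matrix=matrix,
                          gene_models=genes, coverage=tracks, truth=truth,
                          expression=expression)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "fasta": os.path.join(out_dir, "reference.fa"),
            "vcf": os.path.join(out_dir, "genotypes.vcf"),
            "gff": os.path.join(out_dir, "genes.gff3"),
            "samples": os.path.join(out_dir, "samples.tsv"),
            "expression": os.path.join(out_dir, "expression.tsv"),
            "probe_map": os.path.join(out_dir, "probe_map.tsv"),
            "array_map": os.path.join(out_dir, "array_map.tsv"),
        }
        _write_fasta(ref, paths["fasta"])
        _write_gff(genes, paths["gff"])
        write_genotypes(matrix, paths["vcf"], contig_lengths=plan)
        sheet.to_tsv(paths["samples"])
        cov_dir = os.path.join(out_dir, "coverage")
        os.makedirs(cov_dir, exist_ok=True)
        for sid, tr in tracks.items():
            p = os.path.join(cov_dir, f"{sid}.bedgraph")
            write_coverage(tr, p)
            paths[f"coverage:{sid}"] = p
        expression["signals"].rename_axis("probe_id").to_csv(
            paths["expression"], sep="\t")
        expression["probe_map"].to_csv(paths["probe_map"], sep="\t", index=False)
        expression["array_map"].to_csv(paths["array_map"], sep="\t", index=False)
        truth.write(out_dir)
        ds.paths = paths
    return ds


# ---------------------------------------------------------------------------
# Coding-sequence trio simulation
# ---------------------------------------------------------------------------

def _stochastic_round(x: float, rng) -> int:
    base = math.floor(x)
    return base + (1 if rng.random() < (x - base) else 0)


def _apply_class_change(seq: list[str], codon_idx: int, want_syn: bool, rng
                        ) -> bool:
    """Try to apply one substitution of the requested class at a codon.
    Returns False when the codon offers no change of that class."""
    codon = "".join(seq[3 * codon_idx:3 * codon_idx + 3])
    options = []
    for off in range(3):
        for b in "ACGT":
            if b == codon[off]:
                continue
            mut = codon[:off] + b + codon[off + 1:]
            if mut in codonevol.STOP_CODONS:
                continue
            syn = codonevol.CODON_TO_AA[mut] == codonevol.CODON_TO_AA[codon]
            if syn == want_syn:
                options.append((off, b))
    if not options:
        return False
    off, b = options[int(rng.integers(len(options)))]
    seq[3 * codon_idx + off] = b
    return True


def simulate_coding_divergence(cds: str, omega_focal: float,
                               omega_background: float,
                               ks_focal: float = 0.025,
                               ks_background: float = 0.025,
                               ks_outgroup: float = 0.05,
                               seed: int | np.random.Generator = 0,
                               ) -> tuple[str, str, str, dict[str, tuple[int, int]]]:
    """Evolve three aligned CDS (focal, sister, outgroup) from one root.

    Substitution counts per branch are ``ks * S`` synonymous and
    ``omega * ks * N`` nonsynonymous changes (stochastic rounding keeps
    the expectations exact), placed on distinct codons so the counting
    estimators see each change unambiguously; no stop codons are
    introduced.  Returns the three sequences plus the true per-branch
    (nonsynonymous, synonymous) counts.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    n_codons = len(cds) // 3
    targets = [i for i in range(n_codons)
               if cds[3 * i:3 * i + 3] in codonevol.CODON_TO_AA]
    s_sites = sum(codonevol.codon_site_counts(cds[3 * i:3 * i + 3])[0]
                  for i in targets)
    n_sites = 3.0 * len(targets) - s_sites

    branch_spec = {
        "focal": (ks_focal, omega_focal),
        "sister": (ks_background, omega_background),
        "outgroup": (ks_outgroup, omega_background),
    }
    wanted: list[tuple[str, bool]] = []
    true_counts = {}
    for name, (ks, om) in branch_spec.items():
        n_s = _stochastic_round(ks * s_sites, rng)
        n_n = _stochastic_round(om * ks * n_sites, rng)
        true_counts[name] = (n_n, n_s)
        wanted += [(name, True)] * n_s + [(name, False)] * n_n
    if len(wanted) > len(targets):
        raise ValueError("requested substitution count exceeds available codons")

    seqs = {name: list(cds) for name in branch_spec}
    free = list(rng.permutation(targets))
    applied = {name: [0, 0] for name in branch_spec}  # [nonsyn, syn]
    for name, want_syn in wanted:
        while free:
            ci = int(free.pop())
            if _apply_class_change(seqs[name], ci, want_syn, rng):
                applied[name][0 if not want_syn else 1] += 1
                break
        else:
            raise ValueError("ran out of codons able to host the requested class")
    truth = {name: (applied[name][0], applied[name][1]) for name in branch_spec}
    return ("".join(seqs["focal"]), "".join(seqs["sister"]),
            "".join(seqs["outgroup"]), truth)
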
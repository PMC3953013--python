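"""Readers and writers for the standard formats the pipeline touches.

Coordinates are 1-based inclusive internally (the VCF/GFF convention);
BED and bedGraph output is 0-based half-open.  Only biallelic SNVs are
retained in the genotype matrix: indel and multiallelic records are
dropped and counted, and indel positions are remembered so that coding
genes overlapping them can be excluded downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("neosexscan")

__all__ = [
    "SampleSheet",
    "GenotypeMatrix",
    "CoverageTrack",
    "AssemblyLayout",
    "CodingGeneModel",
    "read_sample_sheet",
    "read_genotypes",
    "write_genotypes",
    "read_coverage",
    "write_coverage",
    "read_gene_models",
    "apply_assembly_layout",
    "write_windows",
]

# Genotype codes in GenotypeMatrix.gt
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Sample metadata: one row per sample with species and sex labels."""

    frame: pd.DataFrame  # columns: sample_id, species, sex

    def __post_init__(self) -> None:
        required = {"sample_id", "species", "sex"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")
        bad_sex = set(self.frame["sex"]) - {"male", "female"}
        if bad_sex:
            raise ValueError(f"sex labels must be male/female, got {sorted(bad_sex)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def select(self, species: str | None = None, sex: str | None = None) -> list[str]:
        f = self.frame
        if species is not None:
            f = f[f["species"] == species]
        if sex is not None:
            f = f[f["sex"] == sex]
        return list(f["sample_id"])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(frame)


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic diploid SNV calls, site x sample, with per-call depth.

    ``gt`` uses codes 0=hom_ref, 1=het, 2=hom_alt, -1=missing.  Positions
    are strictly increasing within each chromosome; missing calls are
    explicit and never imputed.
    """

    chrom: np.ndarray       # str, per site
    pos: np.ndarray         # int64, 1-based
    ref: np.ndarray         # str
    alt: np.ndarray         # str
    gt: np.ndarray          # int8, sites x samples
    depth: np.ndarray       # int32, sites x samples
    samples: list[str]
    n_excluded_indels: int = 0
    n_excluded_multiallelic: int = 0
    indel_positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gt.shape != (self.pos.size, len(self.samples)):
            raise ValueError("gt shape does not match sites x samples")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def sites_on(self, chrom: str) -> np.ndarray:
        """Boolean site selector for one chromosome."""
        return self.chrom == chrom

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chrom=self.chrom[mask], pos=self.pos[mask],
            ref=self.ref[mask], alt=self.alt[mask],
            gt=self.gt[mask], depth=self.depth[mask],
            samples=list(self.samples),
            n_excluded_indels=self.n_excluded_indels,
            n_excluded_multiallelic=self.n_excluded_multiallelic,
            indel_positions=dict(self.indel_positions),
        )


def read_genotypes(vcf_path, sample_sheet: SampleSheet) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix, keeping biallelic SNVs only.

    Indel and multiallelic records are dropped and counted; indel
    positions are recorded per chromosome.  All sheet samples must be
    present in the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    vcf_samples = list(vcf.samples)
    for sid in sample_sheet.sample_ids:
        if sid not in vcf_samples:
            raise ValueError(f"sample {sid!r} from sheet missing in VCF header")
    order = [vcf_samples.index(s) for s in sample_sheet.sample_ids]

    chroms, poss, refs, alts = [], [], [], []
    gts, dps = [], []
    n_indel = n_multi = 0
    indel_pos: dict[str, list[int]] = {}
    for i, v in enumerate(vcf):
        try:
            if len(v.ALT) != 1:
                n_multi += 1
                continue
            if v.is_indel or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                n_indel += 1
                indel_pos.setdefault(v.CHROM, []).append(v.POS)
                continue
            # gts012: 0=hom_ref 1=het 2=hom_alt 3=unknown
            g = np.asarray(v.gt_types, dtype=np.int8)[order]
            g[g == 3] = MISSING
            dp = v.format("DP")
            if dp is None:
                d = np.zeros(len(order), dtype=np.int32)
            else:
                d = np.asarray(dp, dtype=np.int32).reshape(-1)[order]
                d[d < 0] = 0
            chroms.append(v.CHROM)
            poss.append(v.POS)
            refs.append(v.REF)
            alts.append(v.ALT[0])
            gts.append(g)
            dps.append(d)
        except Exception as exc:
            raise ValueError(f"malformed VCF record at line ~{i + 1}: {exc}") from exc

    n = len(poss)
    if n_indel:
        log.info("%d indel record(s) excluded", n_indel)
    if n_multi:
        log.info("%d multiallelic record(s) excluded", n_multi)
    return GenotypeMatrix(
        chrom=np.asarray(chroms, dtype=object) if n else np.empty(0, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object) if n else np.empty(0, dtype=object),
        alt=np.asarray(alts, dtype=object) if n else np.empty(0, dtype=object),
        gt=np.vstack(gts).astype(np.int8) if n else np.empty((0, len(order)), np.int8),
        depth=np.vstack(dps).astype(np.int32) if n else np.empty((0, len(order)), np.int32),
        samples=sample_sheet.sample_ids,
        n_excluded_indels=n_indel,
        n_excluded_multiallelic=n_multi,
        indel_positions={c: np.asarray(p, dtype=np.int64) for c, p in indel_pos.items()},
    )


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_genotypes(matrix: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write the matrix as an uncompressed VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=neosexscan\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in dict.fromkeys(matrix.chrom.tolist()):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for i in range(matrix.n_sites):
            cells = [
                f"{_GT_STR[int(matrix.gt[i, j])]}:{int(matrix.depth[i, j])}"
                for j in range(len(matrix.samples))
            ]
            fh.write(
                f"{matrix.chrom[i]}\t{matrix.pos[i]}\t.\t{matrix.ref[i]}\t"
                f"{matrix.alt[i]}\t.\tPASS\t.\tGT:DP\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Per-sample read depth along each chromosome.

    ``depth[chrom]`` holds one value per bin of ``bin_size`` bp
    (``bin_size=1`` means per-position).  Zero marks uncovered or
    repeat-masked spans.  ``library_size`` is the sample's total mapped
    yield used for between-sample normalization.
    """

    sample_id: str
    depth: dict[str, np.ndarray]
    bin_size: int = 1
    library_size: float | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        for c, arr in self.depth.items():
            if (np.asarray(arr) < 0).any():
                raise ValueError(f"negative depth on {c}")
        if self.library_size is None:
            self.library_size = float(
                sum(np.asarray(a, dtype=float).sum() for a in self.depth.values())
                * self.bin_size
            )

    @property
    def chroms(self) -> list[str]:
        return list(self.depth)

    def chrom_length(self, chrom: str) -> int:
        return int(len(self.depth[chrom]) * self.bin_size)


def read_coverage(path, sample_id: str | None = None,
                  library_size: float | None = None) -> CoverageTrack:
    """Read a bedGraph depth track (chrom, start0, end0, depth).

    The bin size is inferred from the interval spans, which must be
    constant apart from a possibly shorter final bin per chromosome.
    """
    import os

    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "depth"],
                     dtype={"chrom": str})
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(str(path)))[0]
    spans = (df["end"] - df["start"]).to_numpy()
    if (spans <= 0).any():
        raise ValueError("bedGraph intervals must have positive span")
    bin_size = int(spans.max())
    depth: dict[str, np.ndarray] = {}
    for c, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        if not (np.diff(starts) == bin_size).all():
            raise ValueError(f"non-uniform bins on {c}")
        depth[c] = sub["depth"].to_numpy(dtype=float)
    return CoverageTrack(sample_id=sample_id, depth=depth, bin_size=bin_size,
                         library_size=library_size)


def write_coverage(track: CoverageTrack, path) -> None:
    """Write a coverage track as bedGraph (0-based half-open bins)."""
    with open(path, "w") as fh:
        for c, arr in track.depth.items():
            b = track.bin_size
            for i, d in enumerate(np.asarray(arr)):
                val = int(d) if float(d).is_integer() else float(d)
                fh.write(f"{c}\t{i * b}\t{(i + 1) * b}\t{val}\n")


# ---------------------------------------------------------------------------
# Assembly layout (supercontig reordering)
# ---------------------------------------------------------------------------

@dataclass
class AssemblyLayout:
    """Ordered assembly blocks with per-block orientation.

    An inverted block maps position p to ``start + end - p``, mirroring
    the block in place; forward blocks are identity.  Blocks must not
    overlap within a chromosome.
    """

    blocks: pd.DataFrame  # columns: chrom, start, end, orientation

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "orientation"}
        if required - set(self.blocks.columns):
            raise ValueError(f"layout needs columns {sorted(required)}")
        bad = set(self.blocks["orientation"]) - {"forward", "inverted"}
        if bad:
            raise ValueError(f"unknown orientation labels: {sorted(bad)}")
        for c, sub in self.blocks.groupby("chrom"):
            s = sub.sort_values("start")
            if (s["end"].to_numpy()[:-1] >= s["start"].to_numpy()[1:]).any():
                raise ValueError(f"overlapping blocks on {c}")

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.blocks[self.blocks["chrom"] == chrom]


def apply_assembly_layout(chrom: str, positions, layout: AssemblyLayout
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Remap positions through the assembly layout of one chromosome.

    Returns ``(remapped, placed)``: positions outside every block keep
    their original coordinate but are flagged unplaced so scans can
    exclude them.
    """
    pos = np.asarray(positions, dtype=np.int64)
    out = pos.copy()
    placed = np.zeros(pos.size, dtype=bool)
    for _, blk in layout.for_chrom(chrom).iterrows():
        inside = (pos >= blk["start"]) & (pos <= blk["end"])
        placed |= inside
        if blk["orientation"] == "inverted":
            out[inside] = int(blk["start"]) + int(blk["end"]) - pos[inside]
    n_out = int((~placed).sum())
    if n_out:
        log.warning("%d position(s) on %s fall outside all layout blocks", n_out, chrom)
    return out, placed


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CodingGeneModel:
    """A protein-coding gene: ordered CDS intervals plus the spliced CDS.

    CDS intervals are 1-based inclusive in genomic order; the spliced
    sequence is in translation order (minus-strand genes are
    reverse-complemented).  A terminal stop codon, if annotated, is part
    of the sequence; codon-level analyses skip stop codons pairwise.
    """

    gene_id: str
    chrom: str
    cds_intervals: list[tuple[int, int]]
    strand: str
    cds_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be +/- for {self.gene_id}")
        if len(self.cds_seq) % 3 != 0:
            raise ValueError(f"CDS length not divisible by 3 for {self.gene_id}")

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    @property
    def tss(self) -> int:
        """Transcription/translation start position (strand-aware)."""
        return self.span[0] if self.strand == "+" else self.span[1]

    def genomic_positions(self) -> np.ndarray:
        """Genomic position of each CDS base, in translation order."""
        parts = [np.arange(s, e + 1, dtype=np.int64) for s, e in self.cds_intervals]
        gpos = np.concatenate(parts)
        return gpos[::-1] if self.strand == "-" else gpos

    def cds_index_of(self, genomic_pos: int) -> int | None:
        """Translation-order index of a genomic position, or None."""
        offset = 0
        total = len(self.cds_seq)
        for s, e in self.cds_intervals:
            if s <= genomic_pos <= e:
                fwd = offset + (genomic_pos - s)
                return fwd if self.strand == "+" else total - 1 - fwd
            offset += e - s + 1
        return None

    def overlaps(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.cds_index_of(pos) is not None


def _validate_orf(gene_id: str, seq: str) -> str | None:
    """Return a rejection reason for a broken model, or None if valid."""
    from Bio.Data.CodonTable import standard_dna_table as tbl

    if len(seq) % 3 != 0:
        return "length not divisible by 3"
    if len(seq) < 6:
        return "too short"
    if seq[:3].upper() != "ATG":
        return "no start codon"
    internal = [seq[i:i + 3].upper() for i in range(3, len(seq) - 3, 3)]
    if any(c in tbl.stop_codons for c in internal):
        return "internal stop codon"
    return None


def read_gene_models(gff_path, fasta_path) -> list[CodingGeneModel]:
    """Read gene models from GFF3 + FASTA; broken ORFs skipped with warning."""
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(str(gff_path), dbfn=":memory:",
                            merge_strategy="create_unique", keep_order=True)
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    genes: list[CodingGeneModel] = []
    for gene in db.features_of_type("gene"):
        cds = sorted(db.children(gene, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            continue
        if gene.seqid not in fasta:
            raise ValueError(f"GFF seqid {gene.seqid!r} not in FASTA")
        strand = gene.strand
        intervals = [(f.start, f.end) for f in cds]
        pieces = [str(fasta[gene.seqid][s - 1:e]) for s, e in intervals]
        seq = "".join(pieces)
        if strand == "-":
            seq = revcomp(seq)
        reason = _validate_orf(gene.id, seq)
        if reason is not None:
            warnings.warn(f"gene {gene.id} skipped: {reason}", stacklevel=2)
            continue
        genes.append(CodingGeneModel(gene_id=gene.id, chrom=gene.seqid,
                                     cds_intervals=intervals, strand=strand,
                                     cds_seq=seq))
    return genes


# ---------------------------------------------------------------------------
# Window output
# ---------------------------------------------------------------------------

def write_windows(stats: pd.DataFrame, bed_path) -> None:
    """Write window statistics as BED (0-based half-open): chrom, start,
    end, value, plus any remaining columns after those four."""
    df = stats.copy()
    for col in ("chrom", "start", "end", "value"):
        if col not in df.columns:
            raise ValueError(f"window frame missing column {col!r}")
    df["start"] = df["start"].astype(np.int64) - 1  # 1-based -> 0-based
    cols = ["chrom", "start", "end", "value"] + [
        c for c in df.columns if c not in ("chrom", "start", "end", "value")
    ]
    df[cols].to_csv(bed_path, sep="\t", header=False, index=False)


def read_windows(bed_path, extra_columns: list[str] | None = None) -> pd.DataFrame:
    names = ["chrom", "start", "end", "value"] + (extra_columns or [])
    df = pd.read_csv(bed_path, sep="\t", header=None, names=names,
                     dtype={"chrom": str})
    df["start"] = df["start"].astype(np.int64) + 1  # back to 1-based
    return df
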
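"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
Externally everything follows the formats themselves: VCF and GFF3 are
1-based inclusive, BED is 0-based half-open.  Internally all interval
arithmetic uses 0-based half-open coordinates; :class:`RegionMask` stores
them directly and :class:`GenomeAnnotation` converts on load.  Variant
positions (:attr:`VariantTable.pos`) stay 1-based because they are only
ever compared point-wise, never sliced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

__all__ = [
    "VariantTable",
    "Gene",
    "CdsSegment",
    "GenomeAnnotation",
    "RegionMask",
    "read_vcf",
    "write_vcf",
    "read_gff3",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
]


class VcfFormatError(ValueError):
    """Raised for VCF files the pipeline cannot safely interpret."""


@dataclass
class VariantTable:
    """Per-site, per-sample allele read counts and genotype dosages.

    All per-sample arrays are ``(n_sites, n_samples)`` float arrays with
    ``NaN`` marking a missing observation.  Genotypes are alt-allele
    dosages (0/1/2 for diploids; mitochondrial calls from haploid-style
    callers come through as 0 or 2).  ``alt_count`` aggregates reads over
    all alternate alleles of the record.
    """

    contig: np.ndarray          # (n_sites,) str
    pos: np.ndarray             # (n_sites,) int, 1-based
    ref: np.ndarray             # (n_sites,) str
    alt: list                   # list of tuples of alt allele strings
    samples: list               # sample ids, file order
    ref_count: np.ndarray       # (n_sites, n_samples) float, NaN = missing
    alt_count: np.ndarray
    total_depth: np.ndarray
    genotype: np.ndarray        # alt dosage, NaN = missing call

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def is_multiallelic(self) -> np.ndarray:
        return np.array([len(a) > 1 for a in self.alt], dtype=bool)

    def site_ids(self) -> list:
        return [f"{c}:{p}" for c, p in zip(self.contig, self.pos)]

    def subset_sites(self, keep: np.ndarray) -> "VariantTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return VariantTable(
            contig=self.contig[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=[self.alt[i] for i in idx],
            samples=list(self.samples),
            ref_count=self.ref_count[idx],
            alt_count=self.alt_count[idx],
            total_depth=self.total_depth[idx],
            genotype=self.genotype[idx],
        )

    def copy(self) -> "VariantTable":
        return replace(
            self,
            contig=self.contig.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=[tuple(a) for a in self.alt],
            samples=list(self.samples),
            ref_count=self.ref_count.copy(),
            alt_count=self.alt_count.copy(),
            total_depth=self.total_depth.copy(),
            genotype=self.genotype.copy(),
        )

    def equals(self, other: "VariantTable") -> bool:
        return (
            list(self.contig) == list(other.contig)
            and list(self.pos) == list(other.pos)
            and list(self.ref) == list(other.ref)
            and [tuple(a) for a in self.alt] == [tuple(a) for a in other.alt]
            and self.samples == other.samples
            and _nan_equal(self.ref_count, other.ref_count)
            and _nan_equal(self.alt_count, other.alt_count)
            and _nan_equal(self.total_depth, other.total_depth)
            and _nan_equal(self.genotype, other.genotype)
        )


def _nan_equal(a: np.ndarray, b: np.ndarray) -> bool:
    return a.shape == b.shape and bool(
        np.all((np.isnan(a) & np.isnan(b)) | (a == b))
    )


@dataclass(frozen=True)
class Gene:
    gene_id: str
    contig: str
    start: int  # 0-based half-open internally
    end: int
    strand: str


@dataclass(frozen=True)
class CdsSegment:
    gene_id: str
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    phase: int


@dataclass
class GenomeAnnotation:
    """Gene models with interval indexes for overlap queries.

    Intervals are 0-based half-open internally; :func:`read_gff3`
    converts from the GFF3 1-based inclusive convention.  Introns are
    the gaps between consecutive exons of one transcript.
    """

    genes: dict = field(default_factory=dict)          # gene_id -> Gene
    cds: dict = field(default_factory=dict)            # gene_id -> [CdsSegment]
    introns: dict = field(default_factory=dict)        # gene_id -> [(start, end)]
    _tree: dict = field(default_factory=dict)          # contig -> IntervalTree

    def add_gene(self, gene: Gene) -> None:
        self.genes[gene.gene_id] = gene
        self._tree.setdefault(gene.contig, IntervalTree()).addi(
            gene.start, gene.end, gene.gene_id
        )

    def n_genes(self) -> int:
        return len(self.genes)

    def genes_overlapping(self, contig: str, start: int, end: int) -> list:
        """Gene ids whose span intersects ``[start, end)`` (0-based)."""
        tree = self._tree.get(contig)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end))

    def gene_at(self, contig: str, pos1: int):
        """Gene containing a 1-based position, or ``None``."""
        hits = self.genes_overlapping(contig, pos1 - 1, pos1)
        return self.genes[hits[0]] if hits else None


@dataclass
class RegionMask:
    """Labelled genomic intervals, 0-based half-open, kept normalized."""

    intervals: dict = field(default_factory=dict)  # label -> {contig: [(s, e)]}

    def add(self, label: str, contig: str, start: int, end: int) -> None:
        if end <= start:
            raise ValueError(f"empty interval [{start}, {end})")
        per = self.intervals.setdefault(label, {})
        per.setdefault(contig, []).append((start, end))
        per[contig] = _merge_intervals(per[contig])

    def labels(self) -> list:
        return sorted(self.intervals)

    def iter_intervals(self) -> Iterable[tuple]:
        for label in sorted(self.intervals):
            for contig in sorted(self.intervals[label]):
                for s, e in self.intervals[label][contig]:
                    yield label, contig, s, e

    def contains(self, contig: str, pos1: int):
        """Label covering a 1-based position, or ``None`` (first by label order)."""
        p0 = pos1 - 1
        for label in sorted(self.intervals):
            for s, e in self.intervals[label].get(contig, ()):
                if s <= p0 < e:
                    return label
        return None

    def total_bp(self, label=None) -> int:
        return sum(
            e - s
            for lab, _c, s, e in self.iter_intervals()
            if label is None or lab == label
        )

    def merged(self, other: "RegionMask") -> "RegionMask":
        out = RegionMask()
        for m in (self, other):
            for label, contig, s, e in m.iter_intervals():
                out.add(label, contig, s, e)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionMask):
            return NotImplemented
        return list(self.iter_intervals()) == list(other.iter_intervals())


def _merge_intervals(ivs: Sequence[tuple]) -> list:
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(v) for v in out]


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path) -> VariantTable:
    """Read a VCF 4.x with per-sample GT, AD and DP into a :class:`VariantTable`.

    Multi-allelic records are retained (flag them with
    :meth:`VariantTable.is_multiallelic`); the biallelic filter removes
    them later so that filter counts stay auditable.  A sample whose AD
    is missing at a site gets missing counts, never zeros.
    """
    vf = pysam.VariantFile(str(path))
    fmts = vf.header.formats.keys()
    for needed in ("AD", "DP", "GT"):
        if needed not in fmts:
            raise VcfFormatError(
                f"{path}: FORMAT field {needed} is not declared in the header"
            )
    samples = list(vf.header.samples)
    contigs, poss, refs, alts = [], [], [], []
    rcs, acs, dps, gts = [], [], [], []
    for rec in vf:
        alt_alleles = tuple(a for a in (rec.alts or ()) if a is not None)
        contigs.append(rec.contig)
        poss.append(rec.pos)
        refs.append(rec.ref)
        alts.append(alt_alleles)
        rc = np.full(len(samples), np.nan)
        ac = np.full(len(samples), np.nan)
        dp = np.full(len(samples), np.nan)
        gt = np.full(len(samples), np.nan)
        for j, s in enumerate(samples):
            call = rec.samples[s]
            ad = call.get("AD")
            if ad is not None and ad[0] is not None:
                rc[j] = ad[0]
                ac[j] = sum(x for x in ad[1:] if x is not None)
            d = call.get("DP")
            if d is not None:
                dp[j] = d
            elif ad is not None and ad[0] is not None:
                raise VcfFormatError(
                    f"{path}: record {rec.contig}:{rec.pos} sample {s} has AD but no DP"
                )
            alleles = call.get("GT")
            if alleles is not None and all(a is not None for a in alleles):
                gt[j] = sum(1 for a in alleles if a > 0) * (2 // len(alleles))
        rcs.append(rc)
        acs.append(ac)
        dps.append(dp)
        gts.append(gt)
    vf.close()
    return VariantTable(
        contig=np.array(contigs, dtype=object),
        pos=np.array(poss, dtype=int),
        ref=np.array(refs, dtype=object),
        alt=alts,
        samples=samples,
        ref_count=np.array(rcs) if rcs else np.empty((0, len(samples))),
        alt_count=np.array(acs) if acs else np.empty((0, len(samples))),
        total_depth=np.array(dps) if dps else np.empty((0, len(samples))),
        genotype=np.array(gts) if gts else np.empty((0, len(samples))),
    )


def write_vcf(table: VariantTable, path) -> None:
    """Write a :class:`VariantTable` as uncompressed VCF 4.2.

    The table's aggregated alt read count goes into the first ALT slot of
    AD, so ``read_vcf(write_vcf(t))`` reproduces ``t`` exactly; per-alt AD
    detail of foreign multi-allelic files is not preserved.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig in dict.fromkeys(table.contig):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for i in range(table.n_sites):
            alt = ",".join(table.alt[i]) if table.alt[i] else "."
            n_alt = max(len(table.alt[i]), 1)
            cols = [
                str(table.contig[i]),
                str(table.pos[i]),
                ".",
                str(table.ref[i]),
                alt,
                ".",
                "PASS",
                ".",
                "GT:AD:DP",
            ]
            for j in range(table.n_samples):
                gt = table.genotype[i, j]
                if np.isnan(gt):
                    gt_s = "./."
                else:
                    gt_s = {0: "0/0", 1: "0/1", 2: "1/1"}[int(gt)]
                if np.isnan(table.ref_count[i, j]):
                    ad_s = "."
                else:
                    ad = [int(table.ref_count[i, j]), int(table.alt_count[i, j])]
                    ad += [0] * (n_alt - 1)
                    ad_s = ",".join(map(str, ad))
                dp = table.total_depth[i, j]
                dp_s = "." if np.isnan(dp) else str(int(dp))
                cols.append(f"{gt_s}:{ad_s}:{dp_s}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path) -> GenomeAnnotation:
    """Parse GFF3 gene/mRNA/exon/CDS features via gffutils.

    Introns are computed as gaps between consecutive exons of each
    transcript and attributed to the parent gene.  A CDS without a
    resolvable parent gene is skipped with a warning; start > end is an
    error.
    """
    import gffutils

    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 5 and int(parts[3]) > int(parts[4]):
                raise ValueError(f"{path}:{ln}: start > end")

    ann = GenomeAnnotation()
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except (ValueError, gffutils.exceptions.EmptyInputError):
        return ann  # empty file

    for g in db.features_of_type("gene"):
        ann.add_gene(Gene(g.id, g.seqid, g.start - 1, g.end, g.strand))

    def parent_gene(feature):
        node = feature
        seen = set()
        while True:
            parents = list(db.parents(node, level=1))
            if not parents:
                return node.id if node.featuretype == "gene" else None
            node = parents[0]
            if node.id in seen:
                return None
            seen.add(node.id)
            if node.featuretype == "gene":
                return node.id

    for c in db.features_of_type("CDS"):
        gid = parent_gene(c)
        if gid is None or gid not in ann.genes:
            warnings.warn(f"CDS at {c.seqid}:{c.start} has no parent gene; skipped")
            continue
        phase = int(c.frame) if c.frame not in (None, ".") else 0
        ann.cds.setdefault(gid, []).append(
            CdsSegment(gid, c.seqid, c.start - 1, c.end, c.strand, phase)
        )
    for segs in ann.cds.values():
        segs.sort(key=lambda s: s.start)

    for t in db.features_of_type(("mRNA", "transcript")):
        gid = parent_gene(t)
        if gid is None:
            continue
        exons = sorted(
            db.children(t, featuretype="exon", level=1), key=lambda e: e.start
        )
        for a, b in zip(exons, exons[1:]):
            if b.start - 1 > a.end:  # non-empty gap, 0-based [a.end, b.start-1)
                ann.introns.setdefault(gid, []).append((a.end, b.start - 1))
    for ivs in ann.introns.values():
        ivs.sort()
    return ann


# ---------------------------------------------------------------------------
# FASTA / BED


def read_fasta(path) -> dict:
    """Read FASTA into an ordered ``{name: SEQUENCE}`` map, upper-cased."""
    seqs: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate contig name {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_bed(path, label: str = "user") -> RegionMask:
    """Read a BED file (0-based half-open) into a :class:`RegionMask`.

    A 4th column, when present, is used as the interval label.
    """
    mask = RegionMask()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            lab = parts[3] if len(parts) > 3 else label
            mask.add(lab, parts[0], int(parts[1]), int(parts[2]))
    return mask


def write_bed(mask: RegionMask, path) -> None:
    with open(path, "w") as fh:
        for label, contig, s, e in mask.iter_intervals():
            fh.write(f"{contig}\t{s}\t{e}\t{label}\n")
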
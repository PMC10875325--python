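"""Mitochondrial C-to-U RNA-editing detection from replicate RNA-seq calls.

Editing appears in RNA-seq as a C→T mismatch on the transcribed strand
(G→A in genome coordinates for genes on the minus strand).  Candidate
sites must be variant-called in every biological replicate of a
condition, absent from matched WGS calls (which would mark a genomic
SNP), and located inside an annotated gene so the transcribed strand is
known.  Each retained site carries per-replicate editing efficiencies
(edited reads / covering reads), its feature class, and — for CDS sites
— the codon position on spliced coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence
import warnings

import numpy as np
import pandas as pd

from .io_formats import GenomeAnnotation, VariantTable

__all__ = [
    "EditingSite",
    "call_editing_sites",
    "editing_efficiency",
    "compare_conditions",
    "codon_position",
]


@dataclass
class EditingSite:
    contig: str
    pos: int  # 1-based
    strand: str
    gene_id: str
    feature: str  # CDS | intron | other
    codon_pos: Optional[int]  # 1..3 for CDS sites
    efficiencies: list = field(default_factory=list)  # per replicate
    quantifiable: bool = True

    @property
    def mean_efficiency(self) -> float:
        return float(np.mean(self.efficiencies)) if self.quantifiable else np.nan


def _site_key(table: VariantTable, i: int) -> tuple:
    alt = table.alt[i][0] if table.alt[i] else "."
    return (str(table.contig[i]), int(table.pos[i]), str(table.ref[i]), alt)


def _feature_of(annotation: GenomeAnnotation, gene_id: str, pos1: int) -> str:
    p0 = pos1 - 1
    for seg in annotation.cds.get(gene_id, ()):
        if seg.start <= p0 < seg.end:
            return "CDS"
    for s, e in annotation.introns.get(gene_id, ()):
        if s <= p0 < e:
            return "intron"
    return "other"


def call_editing_sites(
    rna_tables: Sequence[VariantTable],
    wgs_table: VariantTable,
    annotation: GenomeAnnotation,
    n_replicates: int = 3,
) -> list:
    """Consensus C-to-U calling across biological replicates.

    Keeps sites that are (1) called in all replicates, (2) not present
    in the WGS calls at the same position, (3) a C→T change for
    plus-strand host genes or G→A for minus-strand genes, and (4) inside
    an annotated gene.  Returns :class:`EditingSite` objects with
    per-replicate efficiencies (NaN-flagged when a replicate has no
    coverage).
    """
    if len(rna_tables) != n_replicates:
        raise ValueError(
            f"expected {n_replicates} replicate tables, got {len(rna_tables)}"
        )
    keysets = []
    index = []
    for t in rna_tables:
        d = {_site_key(t, i): i for i in range(t.n_sites)}
        keysets.append(set(d))
        index.append(d)
    shared = set.intersection(*keysets) if keysets else set()
    wgs_pos = {(str(wgs_table.contig[i]), int(wgs_table.pos[i]))
               for i in range(wgs_table.n_sites)}
    sites = []
    for key in sorted(shared, key=lambda k: (k[0], k[1])):
        contig, pos, ref, alt = key
        if (contig, pos) in wgs_pos:
            continue
        gene = annotation.gene_at(contig, pos)
        if gene is None:
            continue
        if gene.strand == "+" and (ref, alt) != ("C", "T"):
            continue
        if gene.strand == "-" and (ref, alt) != ("G", "A"):
            continue
        effs = []
        quantifiable = True
        for t, d in zip(rna_tables, index):
            i = d[key]
            dp = float(np.nansum(t.ref_count[i]) + np.nansum(t.alt_count[i]))
            edited = float(np.nansum(t.alt_count[i]))
            if dp <= 0:
                effs.append(np.nan)
                quantifiable = False
            else:
                effs.append(edited / dp)
        feature = _feature_of(annotation, gene.gene_id, pos)
        cp = (
            codon_position(contig, pos, gene.gene_id, annotation)
            if feature == "CDS"
            else None
        )
        sites.append(
            EditingSite(
                contig=contig,
                pos=pos,
                strand=gene.strand,
                gene_id=gene.gene_id,
                feature=feature,
                codon_pos=cp,
                efficiencies=effs,
                quantifiable=quantifiable,
            )
        )
    return sites


def editing_efficiency(edited_counts, total_counts):
    """Per-replicate edited fractions and their unweighted mean.

    Raises if any replicate has zero coverage (the site is then not
    quantifiable and should be flagged by the caller).
    """
    e = np.asarray(edited_counts, dtype=float)
    t = np.asarray(total_counts, dtype=float)
    if np.any(t <= 0):
        raise ValueError("zero coverage in a replicate; site not quantifiable")
    frac = e / t
    return frac, float(frac.mean())


def compare_conditions(
    wt_sites: Sequence[EditingSite],
    mut_sites: Sequence[EditingSite],
    min_abs_diff: float = 0.10,
) -> pd.DataFrame:
    """Differential editing between conditions by mean-efficiency shift.

    Sites are matched by (contig, pos); only sites quantifiable in both
    conditions are compared.  ``difference`` = mean(mut) − mean(wt);
    ``flagged`` when |difference| ≥ ``min_abs_diff``, with the direction
    of change recorded.
    """
    wt = {(s.contig, s.pos): s for s in wt_sites if s.quantifiable}
    mut = {(s.contig, s.pos): s for s in mut_sites if s.quantifiable}
    shared = sorted(set(wt) & set(mut))
    if not shared:
        warnings.warn("no shared quantifiable editing sites between conditions")
    rows = []
    for key in shared:
        w, m = wt[key], mut[key]
        diff = m.mean_efficiency - w.mean_efficiency
        rows.append(
            {
                "contig": key[0],
                "pos": key[1],
                "gene": w.gene_id,
                "feature": w.feature,
                "codon_pos": w.codon_pos,
                "wt_mean": w.mean_efficiency,
                "mut_mean": m.mean_efficiency,
                "difference": diff,
                "flagged": bool(abs(diff) >= min_abs_diff),
                "direction": "up" if diff > 0 else ("down" if diff < 0 else "none"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "gene", "feature", "codon_pos",
            "wt_mean", "mut_mean", "difference", "flagged", "direction",
        ],
    )


def codon_position(
    contig: str, pos1: int, gene_id: str, annotation: GenomeAnnotation
) -> int:
    """Codon position (1, 2 or 3) of a genomic site on spliced CDS
    coordinates, strand-aware.

    CDS segments are concatenated in transcription order (reverse genomic
    order for minus-strand genes); the first segment's phase shifts the
    reading frame.  A phase annotation inconsistent between consecutive
    segments is an error.
    """
    segs = annotation.cds.get(gene_id)
    if not segs:
        raise ValueError(f"gene {gene_id} has no CDS")
    strand = segs[0].strand
    ordered = sorted(segs, key=lambda s: s.start, reverse=(strand == "-"))
    # validate phase consistency across the spliced transcript
    cum = 0
    for seg in ordered:
        expected_phase = (3 - cum % 3) % 3 if cum else ordered[0].phase
        if seg.phase != expected_phase:
            raise ValueError(
                f"gene {gene_id}: CDS phase {seg.phase} inconsistent with "
                f"spliced position (expected {expected_phase})"
            )
        cum += seg.end - seg.start
    p0 = pos1 - 1
    offset = ordered[0].phase  # bases to skip before the first full codon
    cum = 0
    for seg in ordered:
        if seg.start <= p0 < seg.end:
            within = (p0 - seg.start) if strand == "+" else (seg.end - 1 - p0)
            idx = cum + within - offset
            if idx < 0:
                raise ValueError("site falls in the phase overhang before codon 1")
            return idx % 3 + 1
        cum += seg.end - seg.start
    raise ValueError(f"position {contig}:{pos1} not inside CDS of {gene_id}")
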
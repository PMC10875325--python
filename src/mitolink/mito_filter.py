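"""Strict filter cascade for mitochondrial variant calls.

Organelle variant calls are prone to false positives from repeated
tracts within the mitochondrial genome and from numts — mitochondrial
insertions in the nuclear (or plastid) genome that cross-map reads.  The
cascade removes: non-biallelic sites, sites with excess missing calls,
sites with anomalously high depth (multi-copy signature), per-sample
observations supported by too few reads, and sites inside repeat or
cross-genome homology masks.  Every removal is recorded in an auditable
ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import RegionMask, VariantTable

__all__ = [
    "FilterReport",
    "filter_biallelic_missing",
    "filter_depth",
    "find_self_repeats",
    "find_cross_homology",
    "apply_region_mask",
    "run_filter_cascade",
]

REASONS = (
    "non_biallelic",
    "missing_gt",
    "high_depth",
    "low_reads_all",
    "repeat_region",
    "cross_homology",
)


@dataclass
class FilterReport:
    """Kept/removed ledger for one filter stage (or a whole cascade)."""

    kept: VariantTable
    removed_reasons: dict = field(default_factory=dict)  # site id -> [reasons]
    counts: dict = field(default_factory=dict)           # first-cause reason -> n

    @property
    def n_input(self) -> int:
        return self.kept.n_sites + len(self.removed_reasons)

    def record(self, site_id: str, reason: str) -> None:
        if reason not in REASONS:
            raise ValueError(f"unknown removal reason {reason!r}")
        first = site_id not in self.removed_reasons
        self.removed_reasons.setdefault(site_id, []).append(reason)
        if first:
            self.counts[reason] = self.counts.get(reason, 0) + 1

    def chain(self, later: "FilterReport") -> "FilterReport":
        """Compose with a report produced from this report's kept table."""
        out = FilterReport(kept=later.kept)
        out.removed_reasons = {k: list(v) for k, v in self.removed_reasons.items()}
        out.counts = dict(self.counts)
        for sid, reasons in later.removed_reasons.items():
            for r in reasons:
                out.record(sid, r)
        return out


def filter_biallelic_missing(
    variants: VariantTable, max_missing: float = 0.40
) -> FilterReport:
    """Keep biallelic sites with a missing-call fraction ≤ ``max_missing``.

    The boundary is inclusive: exactly 40% missing is retained.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must lie in [0, 1]")
    report = FilterReport(kept=variants)
    keep = np.ones(variants.n_sites, dtype=bool)
    multi = variants.is_multiallelic()
    miss_frac = np.isnan(variants.genotype).mean(axis=1)
    ids = variants.site_ids()
    for i in range(variants.n_sites):
        if multi[i]:
            keep[i] = False
            report.record(ids[i], "non_biallelic")
        if miss_frac[i] > max_missing:
            keep[i] = False
            report.record(ids[i], "missing_gt")
    report.kept = variants.subset_sites(keep)
    return report


def filter_depth(
    variants: VariantTable,
    depth_factor: float = 1.5,
    min_reads: int = 4,
    genome_mean_depth: Optional[float] = None,
    max_missing: float = 0.40,
) -> FilterReport:
    """Depth-based site removal and per-observation read floor.

    The genome-wide mean depth is the mean over sites of the per-site
    mean sample depth unless a precomputed ``genome_mean_depth`` is
    supplied.  Sites whose per-site mean depth exceeds ``depth_factor``
    times the genome mean are removed (multi-copy signature).  Individual
    observations with fewer than ``min_reads`` supporting reads are set
    missing — not zero — and the missingness filter is re-applied, so a
    site can fall to ``missing_gt`` here.
    """
    if variants.n_sites and not np.any(np.nan_to_num(variants.total_depth) > 0):
        raise ValueError("all-zero depth table")
    report = FilterReport(kept=variants)
    if variants.n_sites == 0:
        return report
    site_mean = np.nanmean(
        np.where(np.isnan(variants.total_depth), np.nan, variants.total_depth), axis=1
    )
    mean_depth = float(np.nanmean(site_mean)) if genome_mean_depth is None else genome_mean_depth
    ids = variants.site_ids()
    keep = np.ones(variants.n_sites, dtype=bool)
    for i in range(variants.n_sites):
        if site_mean[i] > depth_factor * mean_depth:
            keep[i] = False
            report.record(ids[i], "high_depth")

    out = variants.subset_sites(keep).copy()
    low = np.nan_to_num(out.total_depth, nan=-1.0) < min_reads
    out.ref_count[low] = np.nan
    out.alt_count[low] = np.nan
    out.total_depth[low] = np.nan
    out.genotype[low] = np.nan

    miss_frac = np.isnan(out.genotype).mean(axis=1) if out.n_samples else np.zeros(out.n_sites)
    keep2 = np.ones(out.n_sites, dtype=bool)
    ids2 = out.site_ids()
    for i in range(out.n_sites):
        if miss_frac[i] > max_missing:
            keep2[i] = False
            report.record(ids2[i], "low_reads_all")
    report.kept = out.subset_sites(keep2)
    return report


def _kmer_spans(
    seq: str, k: int, other: Optional[str] = None
) -> list:
    """0-based spans of k-mers of ``seq`` repeated in ``seq`` (or shared
    with ``other``), considering both strands.

    The union of the spans of all duplicated k-mers equals the union of
    all maximal exact repeats of length ≥ k, which is exactly the region
    a length-threshold repeat filter must mask.
    """
    n = len(seq)
    if n < k:
        return []
    spans = []
    if other is None:
        first: dict = {}
        dup_starts = []
        for i in range(n - k + 1):
            w = seq[i : i + k]
            if w in first:
                dup_starts.append(i)
                j = first[w]
                if j is not None:
                    dup_starts.append(j)
                    first[w] = None  # already reported
            else:
                first[w] = i
        # reverse-complement self matches (palindromic duplications)
        rc = _revcomp(seq)
        fwd = {}
        for i in range(n - k + 1):
            fwd.setdefault(seq[i : i + k], []).append(i)
        for i in range(n - k + 1):
            w = rc[i : i + k]
            if w in fwd:
                orig = n - k - i  # position of this window on the forward strand
                for j in fwd[w]:
                    if j != orig or w == _revcomp(w):
                        dup_starts.append(j)
                        dup_starts.append(orig)
        for i in sorted(set(dup_starts)):
            spans.append((i, i + k))
    else:
        words = set()
        for i in range(len(other) - k + 1):
            words.add(other[i : i + k])
        rc_other = _revcomp(other)
        for i in range(len(rc_other) - k + 1):
            words.add(rc_other[i : i + k])
        for i in range(n - k + 1):
            if seq[i : i + k] in words:
                spans.append((i, i + k))
    return spans


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def find_self_repeats(mito_fasta: dict, min_len: int = 100) -> RegionMask:
    """Mask all exact repeated tracts of length ≥ ``min_len`` (both strands).

    Every copy of a repeat is masked.  ``min_len`` below 20 is rejected:
    short k-mers recur by chance and would mask essentially everything.
    """
    if min_len < 20:
        raise ValueError("min_len < 20 would mask the whole genome")
    mask = RegionMask()
    names = list(mito_fasta)
    for name in names:
        for s, e in _kmer_spans(mito_fasta[name], min_len):
            mask.add("self_repeat", name, s, e)
    # tracts shared between different mito contigs
    for a in range(len(names)):
        for b in range(len(names)):
            if a == b:
                continue
            for s, e in _kmer_spans(mito_fasta[names[a]], min_len, mito_fasta[names[b]]):
                mask.add("self_repeat", names[a], s, e)
    return mask


def find_cross_homology(
    mito_fasta: dict, other_fasta: dict, min_len: int = 100,
    label: str = "cross_homology",
) -> RegionMask:
    """Mito-coordinate mask of exact tracts ≥ ``min_len`` shared with
    another genome (numt / plastid-transfer candidates), both strands."""
    if min_len < 20:
        raise ValueError("min_len < 20 would mask the whole genome")
    mask = RegionMask()
    other = "".join(other_fasta.values())
    if not other:
        return mask
    for name, seq in mito_fasta.items():
        for s, e in _kmer_spans(seq, min_len, other):
            mask.add(label, name, s, e)
    return mask


def apply_region_mask(variants: VariantTable, masks: RegionMask) -> FilterReport:
    """Remove sites whose position lies inside any mask interval."""
    report = FilterReport(kept=variants)
    keep = np.ones(variants.n_sites, dtype=bool)
    ids = variants.site_ids()
    label_to_reason = {
        "self_repeat": "repeat_region",
        "cross_homology": "cross_homology",
        "user": "repeat_region",
    }
    for i in range(variants.n_sites):
        label = masks.contains(str(variants.contig[i]), int(variants.pos[i]))
        if label is not None:
            keep[i] = False
            report.record(ids[i], label_to_reason.get(label, "repeat_region"))
    report.kept = variants.subset_sites(keep)
    return report


def run_filter_cascade(
    variants: VariantTable,
    masks: Optional[RegionMask] = None,
    max_missing: float = 0.40,
    depth_factor: float = 1.5,
    min_reads: int = 4,
    genome_mean_depth: Optional[float] = None,
) -> FilterReport:
    """Full cascade in the fixed order: biallelic/missing → depth → masks."""
    r1 = filter_biallelic_missing(variants, max_missing=max_missing)
    r2 = filter_depth(
        r1.kept,
        depth_factor=depth_factor,
        min_reads=min_reads,
        genome_mean_depth=genome_mean_depth,
        max_missing=max_missing,
    )
    report = r1.chain(r2)
    if masks is not None:
        r3 = apply_region_mask(report.kept, masks)
        report = report.chain(r3)
    return report
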
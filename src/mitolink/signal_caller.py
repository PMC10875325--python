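"""Association signals: clustering, gene assignment, summaries, enrichment.

A "signal" is a cluster of nuclear SNPs whose -log10(P) exceeds the
genome-wide threshold (default 6, strictly greater-than), spanned by its
left- and right-most member SNPs.  Nearby above-threshold runs separated
by at most ``max_gap_bp`` merge into one signal.  Genes whose span
overlaps a signal interval are attached, and per-dataset summaries count
de-duplicated associated genes against the annotated-gene universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomeAnnotation

__all__ = [
    "Signal",
    "call_signals",
    "assign_genes",
    "summarize",
    "term_enrichment",
    "manhattan_plot",
]


@dataclass
class Signal:
    phenotype_id: str
    contig: str
    start: int  # 1-based inclusive span over member SNPs
    end: int
    members: list  # [(pos, p)]
    lead_pos: int
    lead_p: float
    max_neglog10p: float
    genes: list = field(default_factory=list)
    lead_gene: str = ""


def call_signals(
    results: pd.DataFrame,
    threshold_neglog10p: float = 6.0,
    max_gap_bp: int = 1_000_000,
    phenotype_id: str = "",
) -> list:
    """Cluster above-threshold SNPs into signals.

    Only SNPs with -log10(p) strictly above the threshold are members.
    Consecutive members on one contig merge while the gap between them is
    at most ``max_gap_bp``.  The lead SNP has minimal p (ties broken by
    smaller position).
    """
    hits = results.loc[
        results["neglog10p"].notna()
        & (results["neglog10p"] > threshold_neglog10p)
    ].sort_values(["contig", "pos"], kind="mergesort")
    signals: list = []
    for contig, grp in hits.groupby("contig", sort=True):
        pos = grp["pos"].to_numpy(dtype=int)
        pv = grp["p"].to_numpy(dtype=float)
        nl = grp["neglog10p"].to_numpy(dtype=float)
        start_idx = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > max_gap_bp:
                mp = pos[start_idx:i]
                mv = pv[start_idx:i]
                lead = int(np.lexsort((mp, mv))[0])
                signals.append(
                    Signal(
                        phenotype_id=phenotype_id,
                        contig=str(contig),
                        start=int(mp[0]),
                        end=int(mp[-1]),
                        members=list(zip(mp.tolist(), mv.tolist())),
                        lead_pos=int(mp[lead]),
                        lead_p=float(mv[lead]),
                        max_neglog10p=float(nl[start_idx:i].max()),
                    )
                )
                start_idx = i
    return signals


def assign_genes(signals: Sequence[Signal], annotation: GenomeAnnotation) -> list:
    """Attach genes whose [start, end] span intersects each signal interval.

    Intersection is on 1-based inclusive coordinates (a gene starting one
    base past the signal end is not attached).  The gene hosting the lead
    SNP, when any, is flagged as the primary candidate.
    """
    known_contigs = {g.contig for g in annotation.genes.values()}
    for sig in signals:
        if sig.contig not in known_contigs:
            warnings.warn(f"contig {sig.contig} absent from annotation")
            sig.genes = []
            continue
        # signal [start, end] 1-based inclusive -> 0-based half-open
        sig.genes = annotation.genes_overlapping(sig.contig, sig.start - 1, sig.end)
        host = annotation.gene_at(sig.contig, sig.lead_pos)
        sig.lead_gene = host.gene_id if host is not None else ""
    return list(signals)


def summarize(signals_per_dataset: Mapping[str, Sequence[Signal]],
              annotation: GenomeAnnotation) -> pd.DataFrame:
    """Per-dataset signal/gene counts and gene percentage.

    ``percentage`` is 100 × (de-duplicated associated genes) / (annotated
    genes).
    """
    n_annotated = annotation.n_genes()
    if n_annotated == 0:
        raise ValueError("annotation contains no genes")
    rows = []
    for name, signals in signals_per_dataset.items():
        genes = sorted({g for s in signals for g in s.genes})
        rows.append(
            {
                "dataset": name,
                "n_signals": len(signals),
                "n_genes": len(genes),
                "percentage": 100.0 * len(genes) / n_annotated,
            }
        )
    return pd.DataFrame(rows)


def term_enrichment(
    target_genes: Iterable[str],
    gene2term: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric term enrichment with BH correction.

    For each term with members in the universe: p = P(X ≥ k) where X is
    hypergeometric(M = universe size, K = term size, N = target size) and
    k the overlap.  Terms with no universe member are skipped.
    """
    universe = set(universe)
    target = set(target_genes)
    if not target <= universe:
        raise ValueError("target genes must be a subset of the universe")
    term_members: dict = {}
    for gene, terms in gene2term.items():
        if gene not in universe:
            continue
        for t in terms:
            term_members.setdefault(t, set()).add(gene)
    M, N = len(universe), len(target)
    rows = []
    for term, members in sorted(term_members.items()):
        K = len(members)
        k = len(members & target)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        expected = K * N / M
        rows.append(
            {
                "term": term,
                "overlap": k,
                "term_size": K,
                "fold": (k / expected) if expected > 0 else np.nan,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q"] = []
    return df


def manhattan_plot(
    results: pd.DataFrame,
    signals: Sequence[Signal] = (),
    out_path=None,
    threshold_neglog10p: float = 6.0,
):
    """Manhattan plot: per-contig colored -log10(p) with threshold line
    and diamond markers on signal lead SNPs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if results.empty:
        raise ValueError("empty association table")
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, (contig, grp) in enumerate(
        results.sort_values(["contig", "pos"]).groupby("contig", sort=True)
    ):
        x = grp["pos"].to_numpy() + offset
        ax.scatter(
            x, grp["neglog10p"], s=4, color=f"C{i % 10}", rasterized=True
        )
        ticks.append(x.mean())
        labels.append(str(contig))
        contig_span = int(grp["pos"].max())
        for sig in signals:
            if sig.contig == str(contig):
                ax.scatter(
                    [sig.lead_pos + offset],
                    [-np.log10(sig.lead_p)],
                    marker="D",
                    s=30,
                    color="black",
                    zorder=3,
                )
        offset += contig_span + 1
    ax.axhline(threshold_neglog10p, linestyle="--", color="grey")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("position")
    ax.set_ylabel(r"$-\log_{10}(P)$")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
        return out_path
    return fig


def signals_to_frame(signals: Sequence[Signal]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "phenotype": s.phenotype_id,
                "contig": s.contig,
                "start": s.start,
                "end": s.end,
                "n_members": len(s.members),
                "lead_pos": s.lead_pos,
                "lead_p": s.lead_p,
                "max_neglog10p": s.max_neglog10p,
                "genes": ",".join(s.genes),
                "lead_gene": s.lead_gene,
            }
            for s in signals
        ]
    )
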
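"""Nucleotide diversity, diversity contrasts, consensus CDS, NG86 Ka/Ks.

Windowed π follows the vcftools ``--window-pi`` semantics: per-site
π = 2·c0·c1 / (n·(n−1)) over non-missing allele copies, summed within a
sliding window and divided by the window length in base pairs, so
monomorphic positions dilute but never add.  Gene-level contrasts
(associated vs background genes) use a two-sided Wilcoxon rank-sum test.
Ka/Ks between a population consensus CDS and an outgroup CDS uses the
Nei–Gojobori (1986) counting estimator with Jukes–Cantor correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeAnnotation, VariantTable

__all__ = [
    "windowed_pi",
    "gene_diversity_contrast",
    "consensus_sequence",
    "kaks_ng86",
    "KaKsResult",
]

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_NT = "ACGT"


def site_pi(variants: VariantTable) -> pd.DataFrame:
    """Per-site nucleotide diversity from diploid genotype dosages.

    Each non-missing diploid genotype contributes two allele copies;
    π_site = 2·c0·c1 / (n·(n−1)).
    """
    g = variants.genotype  # (sites, samples) alt dosage
    obs = ~np.isnan(g)
    n = 2 * obs.sum(axis=1).astype(float)
    c1 = np.nansum(g, axis=1)
    c0 = n - c1
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(n > 1, 2.0 * c0 * c1 / (n * (n - 1.0)), 0.0)
    return pd.DataFrame(
        {"contig": variants.contig, "pos": variants.pos, "pi": pi}
    )


def windowed_pi(
    variants: VariantTable,
    window: int = 100_000,
    step: int = 10_000,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Sliding-window π track (vcftools ``--window-pi`` semantics).

    Windows start at 1, 1+step, … and span ``window`` bp (terminal
    windows truncated at the contig end); window π is the sum of site π
    divided by the window length in bp.
    """
    if step > window:
        raise ValueError("step must not exceed window")
    persite = site_pi(variants)
    rows = []
    for contig, grp in persite.groupby("contig", sort=True):
        length = (
            int(contig_lengths[contig])
            if contig_lengths and contig in contig_lengths
            else int(grp["pos"].max())
        )
        pos = grp["pos"].to_numpy(dtype=int)
        pv = grp["pi"].to_numpy(dtype=float)
        start = 1
        while start <= length:
            end = min(start + window - 1, length)
            in_win = (pos >= start) & (pos <= end)
            rows.append(
                {
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "n_sites": int(in_win.sum()),
                    "pi": float(pv[in_win].sum()) / (end - start + 1),
                }
            )
            if end == length:
                break
            start += step
    return pd.DataFrame(rows)


def gene_diversity_contrast(
    pi_values: pd.DataFrame,
    target_genes: Sequence[str],
    background_genes: Sequence[str],
    annotation: Optional[GenomeAnnotation] = None,
    mode: str = "window",
):
    """Target-vs-background gene diversity with a rank-sum test.

    ``mode='window'`` maps each gene to the mean π of the windows
    overlapping its span (``pi_values`` is a window track);
    ``mode='site'`` averages site π inside the gene span (``pi_values``
    from :func:`site_pi`).  Returns per-group summaries (median and
    quartiles, as in a boxplot) and the two-sided Wilcoxon rank-sum p
    (exact for combined n ≤ 30 without ties, normal approximation with
    tie correction otherwise).
    """
    if annotation is None:
        raise ValueError("annotation required to map genes to windows")

    def gene_pi(gene_id: str):
        g = annotation.genes[gene_id]
        if mode == "window":
            sel = pi_values.loc[
                (pi_values["contig"] == g.contig)
                & (pi_values["start"] <= g.end)       # window start 1-based
                & (pi_values["end"] >= g.start + 1)
            ]
        elif mode == "site":
            sel = pi_values.loc[
                (pi_values["contig"] == g.contig)
                & (pi_values["pos"] >= g.start + 1)
                & (pi_values["pos"] <= g.end)
            ]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return float(sel["pi"].mean()) if len(sel) else np.nan

    tv = np.array([gene_pi(g) for g in target_genes], dtype=float)
    bv = np.array([gene_pi(g) for g in background_genes], dtype=float)
    tv, bv = tv[~np.isnan(tv)], bv[~np.isnan(bv)]
    if len(tv) < 3 or len(bv) < 3:
        raise ValueError("each group needs at least 3 genes with diversity values")
    n_comb = len(tv) + len(bv)
    has_ties = len(np.unique(np.concatenate([tv, bv]))) < n_comb
    method = "exact" if (n_comb <= 30 and not has_ties) else "asymptotic"
    test = stats.mannwhitneyu(tv, bv, alternative="two-sided", method=method)

    def summary(v):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return {"n": len(v), "median": med, "q1": q1, "q3": q3, "mean": v.mean()}

    return {
        "target": summary(tv),
        "background": summary(bv),
        "target_values": tv,
        "background_values": bv,
        "statistic": float(test.statistic),
        "p_value": float(test.pvalue),
    }


def consensus_sequence(
    reference_cds: str, variants: VariantTable, warn=None
) -> str:
    """Replace each variant site with the majority allele across samples.

    Variant positions are 1-based within the CDS coordinate frame.  The
    majority is over non-missing genotype dosages (2·count(ref allele)
    vs alt copies); ties keep the reference.  Length-changing alleles
    are skipped (with a warning callback when provided).
    """
    seq = list(reference_cds.upper())
    for i in range(variants.n_sites):
        pos = int(variants.pos[i])
        if not 1 <= pos <= len(seq):
            continue
        alts = variants.alt[i]
        ref = str(variants.ref[i])
        if len(ref) != 1 or any(len(a) != 1 for a in alts):
            if warn:
                warn(f"indel at CDS position {pos} skipped")
            continue
        g = variants.genotype[i]
        g = g[~np.isnan(g)]
        if g.size == 0:
            continue
        alt_copies = float(g.sum())
        ref_copies = 2.0 * g.size - alt_copies
        if alt_copies > ref_copies:
            seq[pos - 1] = alts[0]
    return "".join(seq)


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: Optional[float]  # None when Ks == 0
    nd: float
    sd: float
    n_sites: float
    s_sites: float

    @property
    def undefined_ratio(self) -> bool:
        return self.ratio is None


def _syn_fraction(codon: str) -> tuple:
    """(nonsyn_sites, syn_sites) for one codon: at each position the
    fraction of the three possible changes that preserve the amino acid.
    Changes to stop codons count as nonsynonymous."""
    aa = CODON_TABLE[codon]
    s = 0.0
    for i in range(3):
        syn = 0
        for b in _NT:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if CODON_TABLE[mut] == aa and CODON_TABLE[mut] != "*":
                syn += 1
        s += syn / 3.0
    return 3.0 - s, s


def _pathway_counts(ca: str, cb: str) -> tuple:
    """(Nd, Sd) between two codons, averaged over all substitution
    pathways that avoid intermediate stop codons (standard NG86)."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = ca
        nd = sd = 0
        ok = True
        for i in order:
            nxt = cur[:i] + cb[i] + cur[i + 1 :]
            if CODON_TABLE[nxt] == "*" and nxt != cb:
                ok = False
                break
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((nd, sd))
    if not paths:  # all pathways hit a stop: fall back to unrestricted paths
        for order in permutations(diff):
            cur = ca
            nd = sd = 0
            for i in order:
                nxt = cur[:i] + cb[i] + cur[i + 1 :]
                if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((nd, sd))
    nd = float(np.mean([p[0] for p in paths]))
    sd = float(np.mean([p[1] for p in paths]))
    return nd, sd


def _jukes_cantor(p: float) -> float:
    """Jukes–Cantor distance where valid; raw proportion otherwise.

    The correction diverges at p = 3/4 (more observed differences than a
    random pair of sequences); such saturated proportions are returned
    uncorrected, which only arises on very short or very divergent
    alignments.
    """
    if p >= 0.75:
        return float(p)
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def kaks_ng86(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks between two aligned in-frame CDSs.

    Synonymous/nonsynonymous site counts are averaged over the two
    sequences; substitutions in multi-hit codons average over all
    stop-free pathways; pS and pN receive the Jukes–Cantor correction.
    The ratio is flagged undefined when Ks = 0.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    if len(a) % 3:
        raise ValueError("length not divisible by 3")
    if "-" in a or "-" in b:
        raise ValueError("gapped alignment not supported")
    n_sites = s_sites = 0.0
    nd = sd = 0.0
    n_codons = len(a) // 3
    for i in range(n_codons):
        ca, cb = a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3]
        if CODON_TABLE.get(ca) is None or CODON_TABLE.get(cb) is None:
            raise ValueError(f"non-ACGT codon at index {i}")
        is_terminal = i == n_codons - 1
        if (CODON_TABLE[ca] == "*" or CODON_TABLE[cb] == "*") and not is_terminal:
            raise ValueError(f"internal stop codon at index {i}")
        if CODON_TABLE[ca] == "*" or CODON_TABLE[cb] == "*":
            continue  # terminal stop excluded from counting
        na, sa = _syn_fraction(ca)
        nb, sb = _syn_fraction(cb)
        n_sites += (na + nb) / 2.0
        s_sites += (sa + sb) / 2.0
        d_n, d_s = _pathway_counts(ca, cb)
        nd += d_n
        sd += d_s
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    ka = _jukes_cantor(pn) if pn > 0 else 0.0
    ks = _jukes_cantor(ps) if ps > 0 else 0.0
    ratio = (ka / ks) if ks > 0 else None
    return KaKsResult(
        ka=float(ka), ks=float(ks), ratio=ratio,
        nd=nd, sd=sd, n_sites=n_sites, s_sites=s_sites,
    )
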
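"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate the study design end to end: a subdivided
population whose nuclear SNPs carry Balding–Nichols stratification and
kinship signal, mitochondrial variants whose per-individual
reference-allele fraction is shifted by a causal nuclear genotype on top
of a polygenic background, binomial read sampling at a stated depth,
mitochondrial genomes with planted exact repeats and numt-shared tracts,
and replicate RNA-editing count data with the decoy classes the caller
must reject.  Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import RegionMask, VariantTable

__all__ = [
    "SimulationConfig",
    "simulate_population",
    "simulate_mito_fractions",
    "simulate_read_counts",
    "simulate_mito_genome",
    "simulate_editing_data",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a structured cohort of 300 individuals from 3
    subpopulations at F_ST = 0.3, genotyped at 5,000 common nuclear SNPs,
    with mitochondrial read fractions centred at 0.5 and sequenced at a
    mean depth of 100×.  ``beta`` is the shift in reference-allele
    fraction per copy of the causal allele; ``heritability_background``
    is the share of latent phenotype variance carried by kinship.
    """

    n_individuals: int = 300
    n_subpops: int = 3
    fst: float = 0.3
    n_nuclear_snps: int = 5000
    maf_range: tuple = (0.05, 0.5)
    causal_snp_index: Optional[int] = None
    beta: float = 0.2
    mu: float = 0.5
    heritability_background: float = 0.4
    noise_sd: float = 0.05
    mean_depth: float = 100.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5 or (0 < lo <= hi <= 0.5)):
            raise ValueError("maf_range bounds must lie in (0, 0.5]")
        if self.n_subpops > self.n_individuals:
            raise ValueError("more subpopulations than individuals")
        if not 0 <= self.heritability_background < 1:
            raise ValueError("heritability_background must be in [0, 1)")


def simulate_population(config: SimulationConfig):
    """Draw diploid nuclear genotypes for a subdivided population.

    Ancestral frequencies are uniform on ``maf_range``; subpopulation
    frequencies follow the Balding–Nichols beta distribution with
    parameter ``fst``; genotypes are Binomial(2, p_subpop).  Returns a
    nuclear :class:`VariantTable` (dosage-only; read counts missing) and
    the per-individual subpopulation labels.
    """
    rng = np.random.default_rng(config.seed)
    n, m, k = config.n_individuals, config.n_nuclear_snps, config.n_subpops
    p_anc = rng.uniform(*config.maf_range, size=m)
    if config.fst > 0:
        a = p_anc * (1 - config.fst) / config.fst
        b = (1 - p_anc) * (1 - config.fst) / config.fst
        p_sub = rng.beta(a, b, size=(k, m))
    else:
        p_sub = np.broadcast_to(p_anc, (k, m)).copy()
    p_sub = np.clip(p_sub, 1e-6, 1 - 1e-6)
    labels = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    geno = rng.binomial(2, p_sub[labels, :]).astype(float)  # (n, m) alt dosage
    if config.missing_rate > 0:
        miss = rng.random(size=geno.shape) < config.missing_rate
        geno[miss] = np.nan

    # SNPs spread along one synthetic nuclear chromosome, strictly increasing
    positions = np.cumsum(rng.integers(1, 10_000, size=m)) + 1
    samples = [f"S{i:04d}" for i in range(n)]
    nan = np.full((m, n), np.nan)
    table = VariantTable(
        contig=np.array(["chr1"] * m, dtype=object),
        pos=positions,
        ref=np.array(["A"] * m, dtype=object),
        alt=[("G",)] * m,
        samples=samples,
        ref_count=nan.copy(),
        alt_count=nan.copy(),
        total_depth=nan.copy(),
        genotype=geno.T,
    )
    return table, labels


def ibs_kinship_from_dosage(geno: np.ndarray) -> np.ndarray:
    """IBS kinship K_ij = 1 - mean_s |g_is - g_js| / 2 (mean-imputed).

    ``geno`` is (n_individuals, n_snps).  Integer-valued matrices use an
    indicator-matmul identity; otherwise falls back to chunked pairwise
    differences.
    """
    g = np.asarray(geno, dtype=float)
    if np.isnan(g).any():
        col_mean = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g = g.copy()
        g[idx] = np.take(col_mean, idx[1])
    n, m = g.shape
    if np.all(g == np.round(g)):
        ind = [(g == v).astype(float) for v in (0.0, 1.0, 2.0)]
        d = np.zeros((n, n))
        for u in range(3):
            for v in range(3):
                w = abs(u - v)
                if w:
                    d += w * (ind[u] @ ind[v].T)
    else:
        d = np.zeros((n, n))
        for s in range(0, m, 256):
            blk = g[:, s : s + 256]
            d += np.abs(blk[:, None, :] - blk[None, :, :]).sum(axis=2)
    K = 1.0 - d / (2.0 * m)
    return (K + K.T) / 2.0


def simulate_mito_fractions(
    genotypes: np.ndarray,
    config: SimulationConfig,
    n_variants: int = 1,
    kinship: Optional[np.ndarray] = None,
):
    """True per-individual reference-allele fractions for mito variants.

    fraction = clip(mu + beta * g_causal + polygenic + noise, 0, 1).  The
    polygenic term has covariance proportional to the cohort's realized
    IBS kinship, scaled so that it contributes ``heritability_background``
    of the latent (pre-read-sampling) variance; the residual is
    N(0, noise_sd^2).  Variants without a causal SNP use beta = 0.

    Returns an ``(n_variants, n_individuals)`` array.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    g = np.asarray(genotypes, dtype=float)
    n = g.shape[0]
    hb = config.heritability_background
    fractions = np.empty((n_variants, n))
    if hb > 0:
        K = ibs_kinship_from_dosage(g) if kinship is None else kinship
        w, U = np.linalg.eigh(K)
        w = np.clip(w, 0.0, None)
        # scale K so its average diagonal is 1: polygenic var == sigma_g^2
        scale = np.mean(np.diag(K))
        L = U * np.sqrt(w / scale)
        sigma_g = config.noise_sd * np.sqrt(hb / (1 - hb))
    for v in range(n_variants):
        y = np.full(n, config.mu)
        if config.causal_snp_index is not None and v == 0 and config.beta != 0:
            gc = g[:, config.causal_snp_index].copy()
            if np.isnan(gc).any():
                gc[np.isnan(gc)] = np.nanmean(gc)
            y = y + config.beta * (gc - gc.mean())
        if hb > 0:
            y = y + sigma_g * (L @ rng.standard_normal(n))
        y = y + config.noise_sd * rng.standard_normal(n)
        fractions[v] = np.clip(y, 0.0, 1.0)
    return fractions


def simulate_read_counts(
    fractions: np.ndarray,
    mean_depth: float,
    seed: int,
    contig: str = "chrM",
    positions: Optional[Sequence[int]] = None,
    samples: Optional[Sequence[str]] = None,
) -> VariantTable:
    """Binomial read sampling of mitochondrial fractions.

    Per-sample depth ~ Poisson(mean_depth); ref reads ~ Binomial(depth,
    fraction).  Zero-depth observations are missing.  Genotype calls are
    0/0 when the site reads pure reference, 1/1 when pure alternate,
    0/1 otherwise (heteroplasmic) — the diploid-style coding organelle
    variant callers emit.
    """
    fr = np.atleast_2d(np.asarray(fractions, dtype=float))
    if np.any((fr < 0) | (fr > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    n_var, n = fr.shape
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    depth = rng.poisson(mean_depth, size=fr.shape).astype(float)
    ref = rng.binomial(depth.astype(int), fr).astype(float)
    alt = depth - ref
    covered = depth > 0
    ref[~covered] = np.nan
    alt[~covered] = np.nan
    depth_out = depth.copy()
    gt = np.full(fr.shape, np.nan)
    with np.errstate(invalid="ignore"):
        frac_obs = ref / depth
    gt[covered & (frac_obs == 1.0)] = 0.0
    gt[covered & (frac_obs == 0.0)] = 2.0
    gt[covered & (frac_obs > 0) & (frac_obs < 1)] = 1.0
    if positions is None:
        positions = np.arange(1, n_var + 1) * 500
    if samples is None:
        samples = [f"S{i:04d}" for i in range(n)]
    return VariantTable(
        contig=np.array([contig] * n_var, dtype=object),
        pos=np.asarray(positions, dtype=int),
        ref=np.array(["C"] * n_var, dtype=object),
        alt=[("T",)] * n_var,
        samples=list(samples),
        ref_count=ref,
        alt_count=alt,
        total_depth=depth_out,
        genotype=gt,
    )


_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def simulate_mito_genome(
    length: int,
    planted_repeats: Sequence[tuple] = (),
    planted_numt: Optional[tuple] = None,
    nuclear_length: int = 20_000,
    seed: int = 0,
    mito_name: str = "chrM",
    nuclear_name: str = "chr1",
):
    """Random mito genome with exact duplicate tracts and a numt decoy.

    ``planted_repeats`` is a list of ``(src_start, dst_start, length)``
    0-based tuples: the tract at ``src_start`` is copied to ``dst_start``
    within the mito genome.  ``planted_numt`` is ``(mito_start, length)``:
    that tract is copied into a random nuclear decoy contig.  Returns
    ``(mito_seq_dict, nuclear_seq_dict, truth_mask)`` where the truth
    mask covers every planted copy in mito coordinates
    (labels ``self_repeat`` / ``cross_homology``).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    seq = rng.choice(_BASES, size=length)
    truth = RegionMask()
    claimed: list = []

    def claim(s, e):
        for cs, ce in claimed:
            if s < ce and cs < e:
                raise ValueError("overlapping planted tracts")
        claimed.append((s, e))

    def break_flank(arr, i, other_base):
        # force a mismatch so the planted tract is maximal by construction
        if 0 <= i < len(arr) and arr[i] == other_base:
            arr[i] = _BASES[(np.flatnonzero(_BASES == other_base)[0] + 1) % 4]

    for src, dst, ln in planted_repeats:
        if ln < 1 or src + ln > length or dst + ln > length:
            raise ValueError("planted repeat outside genome")
        claim(src, src + ln)
        claim(dst, dst + ln)
        seq[dst : dst + ln] = seq[src : src + ln]
        break_flank(seq, dst - 1, seq[src - 1] if src > 0 else "")
        break_flank(seq, dst + ln, seq[src + ln] if src + ln < length else "")
        truth.add("self_repeat", mito_name, src, src + ln)
        truth.add("self_repeat", mito_name, dst, dst + ln)

    nuc = rng.choice(_BASES, size=nuclear_length)
    if planted_numt is not None:
        ms, ln = planted_numt
        if ms + ln > length or ln > nuclear_length:
            raise ValueError("planted numt outside genome")
        claim(ms, ms + ln)
        ins = (nuclear_length - ln) // 2
        nuc[ins : ins + ln] = seq[ms : ms + ln]
        break_flank(nuc, ins - 1, seq[ms - 1] if ms > 0 else "")
        break_flank(nuc, ins + ln, seq[ms + ln] if ms + ln < length else "")
        truth.add("cross_homology", mito_name, ms, ms + ln)

    return (
        {mito_name: "".join(seq)},
        {nuclear_name: "".join(nuc)},
        truth,
    )


@dataclass
class EditingTruth:
    """Planted editing sites and decoys with expected caller behaviour."""

    sites: list = field(default_factory=list)        # recoverable (contig, pos)
    decoys: list = field(default_factory=list)       # (contig, pos, reason)
    efficiencies: dict = field(default_factory=dict) # (contig, pos) -> per-condition


def simulate_editing_data(
    sites: Sequence[tuple],
    wt_efficiency,
    mut_efficiency=None,
    n_replicates: int = 3,
    depth: int = 50,
    seed: int = 0,
    contig: str = "chrM",
    decoys: bool = True,
):
    """Replicate RNA-seq variant tables for C-to-U editing analysis.

    ``sites`` is a list of ``(pos, strand)`` planted editing sites: the
    genomic change is C→T for ``+`` host genes and G→A for ``-``.
    Efficiencies may be scalars or per-site sequences.  Edited read
    counts are Binomial(depth, efficiency) per replicate.  When
    ``decoys`` is set, three non-recoverable classes are appended after
    the last planted site: a genomic SNP also present in WGS, a
    non-C-to-U change (A→G), and a site variant-called in only
    ``n_replicates - 1`` replicates.

    Returns ``(wt_tables, mut_tables, wgs_table, truth)``; ``mut_tables``
    is ``None`` when ``mut_efficiency`` is ``None``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    wt_eff = np.broadcast_to(np.asarray(wt_efficiency, dtype=float), (len(sites),))
    truth = EditingTruth()

    rows = []  # (pos, ref, alt, kind)
    for (pos, strand), e in zip(sites, wt_eff):
        ref, alt = ("C", "T") if strand == "+" else ("G", "A")
        rows.append((pos, ref, alt, "edit"))
        truth.sites.append((contig, pos))
        truth.efficiencies[(contig, pos)] = {"wt": float(e)}
    if mut_efficiency is not None:
        mut_eff = np.broadcast_to(
            np.asarray(mut_efficiency, dtype=float), (len(sites),)
        )
        for (pos, _), e in zip(sites, mut_eff):
            truth.efficiencies[(contig, pos)]["mut"] = float(e)

    wgs_rows = []
    if decoys:
        base = max(p for p, _ in sites) + 40
        wgs_rows.append((base, "C", "T"))
        rows.append((base, "C", "T", "in_wgs"))
        truth.decoys.append((contig, base, "in_wgs"))
        rows.append((base + 10, "A", "G", "wrong_change"))
        truth.decoys.append((contig, base + 10, "wrong_change"))
        rows.append((base + 20, "C", "T", "partial_replicates"))
        truth.decoys.append((contig, base + 20, "partial_replicates"))

    def build_tables(effs):
        tables = []
        for r in range(n_replicates):
            keep, rc, ac, dp, gt = [], [], [], [], []
            for k, (pos, ref, alt, kind) in enumerate(rows):
                if kind == "partial_replicates" and r == n_replicates - 1:
                    continue
                if kind == "edit":
                    e = effs[k]
                elif kind == "in_wgs":
                    e = 1.0
                else:
                    e = 0.5
                edited = rng.binomial(depth, e)
                keep.append((pos, ref, alt))
                rc.append(depth - edited)
                ac.append(edited)
                dp.append(depth)
                gt.append(1.0 if 0 < edited < depth else (2.0 if edited == depth else 0.0))
            tables.append(
                VariantTable(
                    contig=np.array([contig] * len(keep), dtype=object),
                    pos=np.array([p for p, _, _ in keep], dtype=int),
                    ref=np.array([r_ for _, r_, _ in keep], dtype=object),
                    alt=[(a,) for _, _, a in keep],
                    samples=["rna"],
                    ref_count=np.array(rc, dtype=float)[:, None],
                    alt_count=np.array(ac, dtype=float)[:, None],
                    total_depth=np.array(dp, dtype=float)[:, None],
                    genotype=np.array(gt, dtype=float)[:, None],
                )
            )
        return tables

    wt_tables = build_tables(list(wt_eff) + [None] * (len(rows) - len(sites)))
    mut_tables = None
    if mut_efficiency is not None:
        mut_tables = build_tables(list(mut_eff) + [None] * (len(rows) - len(sites)))

    wgs = VariantTable(
        contig=np.array([contig] * len(wgs_rows), dtype=object),
        pos=np.array([p for p, _, _ in wgs_rows], dtype=int),
        ref=np.array([r_ for _, r_, _ in wgs_rows], dtype=object),
        alt=[(a,) for _, _, a in wgs_rows],
        samples=["wgs"],
        ref_count=np.full((len(wgs_rows), 1), 10.0),
        alt_count=np.full((len(wgs_rows), 1), 10.0),
        total_depth=np.full((len(wgs_rows), 1), 20.0),
        genotype=np.full((len(wgs_rows), 1), 1.0),
    )
    return wt_tables, mut_tables, wgs, truth
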
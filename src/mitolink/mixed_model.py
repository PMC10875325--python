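"""Kinship mixed-model association engine (EMMA variance components,
EMMAX-style single-rotation genome scan).

The model for one mito phenotype y over n individuals is

    y = X beta + u + e,   u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

with K a kinship matrix absorbing population stratification and hidden
relatedness.  Variance components are estimated once per phenotype by
REML, profiling in delta = sigma_e^2 / sigma_g^2 through a single
eigendecomposition of S K S (S the projection orthogonal to X); every
nuclear SNP is then tested by generalized least squares with the null
covariance held fixed — the EMMAX approximation.  P-values come from a
two-sided t test with n - q - 1 degrees of freedom, with the residual
scale re-estimated per SNP on the rotated data, so the K = I case
reduces exactly to ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import VariantTable
from .phenotype import PhenotypeMatrix
from .synthetic_data import ibs_kinship_from_dosage

__all__ = [
    "KinshipMatrix",
    "VarianceComponents",
    "filter_nuclear_snps",
    "compute_kinship",
    "estimate_variance_components",
    "gls_scan",
    "run_gwas",
]


@dataclass
class KinshipMatrix:
    values: np.ndarray
    samples: list
    method: str = "ibs"

    def subset(self, idx: np.ndarray) -> "KinshipMatrix":
        return KinshipMatrix(
            values=self.values[np.ix_(idx, idx)],
            samples=[self.samples[i] for i in np.flatnonzero(np.asarray(idx))]
            if np.asarray(idx).dtype == bool
            else [self.samples[i] for i in idx],
            method=self.method,
        )


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    delta: float
    reml_loglik: float
    boundary: bool = False


def genotype_dosage_matrix(variants: VariantTable) -> np.ndarray:
    """(n_individuals, n_snps) alt-dosage matrix with NaN for missing."""
    return variants.genotype.T.astype(float)


def snp_maf(dosage: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per SNP from 0/1/2 dosages (NaN-aware)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(dosage, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_nuclear_snps(
    variants: VariantTable, max_missing: float = 0.40, min_maf: float = 0.05
) -> VariantTable:
    """Drop nuclear SNPs with missingness > ``max_missing`` or MAF < ``min_maf``."""
    dosage = genotype_dosage_matrix(variants)
    miss = np.isnan(dosage).mean(axis=0)
    maf = snp_maf(dosage)
    keep = (miss <= max_missing) & (maf >= min_maf) & ~np.isnan(maf)
    if not np.any(keep):
        raise ValueError(
            f"no SNP survives filtering ({variants.n_sites} in, "
            f"{int((miss > max_missing).sum())} over-missing, "
            f"{int((maf < min_maf).sum())} low-MAF)"
        )
    return variants.subset_sites(keep)


def mean_impute(dosage: np.ndarray) -> np.ndarray:
    """Per-SNP mean imputation of missing dosages (columns all-NaN → 0)."""
    g = np.array(dosage, dtype=float)
    if np.isnan(g).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(g, axis=0)
        mu = np.nan_to_num(mu)
        idx = np.where(np.isnan(g))
        g[idx] = mu[idx[1]]
    return g


def compute_kinship(variants: VariantTable, method: str = "ibs") -> KinshipMatrix:
    """Kinship from filtered nuclear genotypes.

    ``ibs`` (default): K_ij = 1 - mean_s |g_is - g_js| / 2, entries in
    [0, 1].  ``centered``: the standardized genomic relationship matrix
    Z Z' / m with Z the per-SNP standardized dosages.  Either way the
    matrix is symmetrized and, if a tiny negative eigenvalue remains,
    clipped to positive semidefinite.
    """
    dosage = genotype_dosage_matrix(variants)
    if dosage.shape[1] < 2:
        raise ValueError("need at least 2 SNPs for kinship")
    g = mean_impute(dosage)
    if method == "ibs":
        K = ibs_kinship_from_dosage(g)
    elif method == "centered":
        p = g.mean(axis=0) / 2.0
        sd = np.sqrt(2.0 * p * (1.0 - p))
        sd[sd == 0] = 1.0
        Z = (g - 2.0 * p) / sd
        K = Z @ Z.T / Z.shape[1]
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    K = (K + K.T) / 2.0
    wmin = np.linalg.eigvalsh(K)[0]
    if wmin < 0:
        if wmin < -1e-8:
            w, U = np.linalg.eigh(K)
            K = (U * np.clip(w, 0.0, None)) @ U.T
        else:
            K = K + (-wmin) * np.eye(K.shape[0])
    return KinshipMatrix(values=K, samples=list(variants.samples), method=method)


def _reml_spectrum(y: np.ndarray, X: np.ndarray, K: np.ndarray):
    """Eigen-system of S K S restricted to the column space orthogonal to X."""
    n, q = X.shape
    Q, _ = np.linalg.qr(X)
    S = np.eye(n) - Q @ Q.T
    w, U = np.linalg.eigh(S @ K @ S)
    # keep the n - q largest eigenvalues (the rest are the null space of S)
    order = np.argsort(w)[::-1][: n - q]
    lam = np.clip(w[order], 0.0, None)
    eta = U[:, order].T @ y
    return lam, eta


def reml_loglik(delta: float, lam: np.ndarray, eta: np.ndarray) -> float:
    """Profiled REML log-likelihood at delta (EMMA spectral form)."""
    nq = len(lam)
    denom = lam + delta
    ss = np.sum(eta**2 / denom)
    return 0.5 * (
        nq * np.log(nq / (2 * np.pi)) - nq - nq * np.log(ss) - np.sum(np.log(denom))
    )


def estimate_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    grid_points: int = 100,
    log10_bounds: tuple = (-5.0, 5.0),
) -> VarianceComponents:
    """REML variance components by spectral profile likelihood in delta.

    One eigendecomposition of the projected kinship; the profile is
    evaluated on a log10-delta grid and refined locally with bounded
    scalar minimization.  An optimum at a grid boundary is flagged
    (sigma_g^2 ≈ 0 corresponds to the upper boundary).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    keep = ~np.isnan(y)
    y, X, K = y[keep], X[keep], K[np.ix_(keep, keep)]
    n, q = X.shape
    if n <= q:
        raise ValueError("more covariates than samples")
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    wmin = np.linalg.eigvalsh(K)[0]
    if wmin < -1e-8:
        raise ValueError("kinship matrix is not positive semidefinite")
    lam, eta = _reml_spectrum(y, X, K)
    grid = np.logspace(log10_bounds[0], log10_bounds[1], grid_points)
    ll = np.array([reml_loglik(d, lam, eta) for d in grid])
    best = int(np.argmax(ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_points - 1)]
    res = optimize.minimize_scalar(
        lambda t: -reml_loglik(10.0**t, lam, eta),
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    delta = float(10.0**res.x)
    loglik = float(reml_loglik(delta, lam, eta))
    boundary = best in (0, grid_points - 1)
    sigma_g2 = float(np.sum(eta**2 / (lam + delta)) / (n - q))
    sigma_e2 = float(delta * sigma_g2)
    return VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        delta=delta,
        reml_loglik=loglik,
        boundary=boundary,
    )


def _rotation(K: np.ndarray, vc: VarianceComponents) -> np.ndarray:
    """Sigma^{-1/2} for Sigma = sigma_g^2 K + sigma_e^2 I."""
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    d = vc.sigma_g2 * w + vc.sigma_e2
    if np.any(d <= 0):
        raise ValueError("degenerate covariance; cannot rotate")
    return (U / np.sqrt(d)) @ U.T


def gls_scan(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    vc: VarianceComponents,
    genotypes: VariantTable,
) -> pd.DataFrame:
    """Per-SNP association tests with the null covariance held fixed.

    Rotates y, X and all genotype columns once by Sigma^{-1/2}; each SNP
    is then an ordinary regression on the rotated data (slope, standard
    error, t with n - q - 1 df, two-sided p).  SNPs with zero variance
    after mean imputation are recorded as skipped.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    keep = ~np.isnan(y)
    dosage = genotype_dosage_matrix(genotypes)[keep]
    y, X, K = y[keep], X[keep], K[np.ix_(keep, keep)]
    n, q = X.shape
    G = mean_impute(dosage)
    R = _rotation(K, vc)
    yr = R @ y
    Xr = R @ X
    Gr = R @ G
    Qx, _ = np.linalg.qr(Xr)
    y_res = yr - Qx @ (Qx.T @ yr)
    G_res = Gr - Qx @ (Qx.T @ Gr)
    gss = np.einsum("ij,ij->j", G_res, G_res)
    gy = G_res.T @ y_res
    yss = float(y_res @ y_res)
    df = n - q - 1
    ok = gss > 1e-12
    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    tstat = np.full(G.shape[1], np.nan)
    pval = np.full(G.shape[1], np.nan)
    beta[ok] = gy[ok] / gss[ok]
    rss = np.maximum(yss - beta[ok] ** 2 * gss[ok], 0.0)
    sigma2 = rss / df
    se[ok] = np.sqrt(sigma2 / gss[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat[ok] = beta[ok] / se[ok]
    pval[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    maf = snp_maf(dosage)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(pval)
    out = pd.DataFrame(
        {
            "contig": genotypes.contig,
            "pos": genotypes.pos,
            "beta": beta,
            "se": se,
            "t": tstat,
            "p": np.where(ok, pval, np.nan),
            "neglog10p": np.where(ok, neglog, np.nan),
            "n": n,
            "maf": maf,
            "skipped": ~ok,
        }
    )
    return out


def run_gwas(
    phenotypes: PhenotypeMatrix,
    genotypes: VariantTable,
    kinship: KinshipMatrix,
    covariates: Optional[np.ndarray] = None,
    min_samples: int = 30,
) -> dict:
    """Mixed-model scan of every mito phenotype against all nuclear SNPs.

    Returns ``{variant_id: (AssociationResult DataFrame, VarianceComponents)}``.
    Phenotypes with fewer than ``min_samples`` non-missing values, or that
    are constant, are skipped with a warning rather than aborting the run.
    """
    if phenotypes.samples != list(genotypes.samples):
        common = [s for s in phenotypes.samples if s in genotypes.samples]
        if len(common) < min_samples:
            raise ValueError("phenotype and genotype samples do not align")
        phenotypes = PhenotypeMatrix(
            values=phenotypes.values[common], binary=phenotypes.binary
        )
        gidx = [genotypes.samples.index(s) for s in common]
        genotypes = VariantTable(
            contig=genotypes.contig,
            pos=genotypes.pos,
            ref=genotypes.ref,
            alt=genotypes.alt,
            samples=common,
            ref_count=genotypes.ref_count[:, gidx],
            alt_count=genotypes.alt_count[:, gidx],
            total_depth=genotypes.total_depth[:, gidx],
            genotype=genotypes.genotype[:, gidx],
        )
        kidx = [kinship.samples.index(s) for s in common]
        kinship = kinship.subset(np.array(kidx))
    n = len(phenotypes.samples)
    X = np.ones((n, 1))
    results = {}
    for vid in phenotypes.variant_ids:
        y = phenotypes.row(vid)
        n_obs = int(np.sum(~np.isnan(y)))
        if n_obs < min_samples:
            warnings.warn(f"phenotype {vid}: only {n_obs} observations; skipped")
            continue
        try:
            vc = estimate_variance_components(y, X, kinship.values)
            table = gls_scan(y, X, kinship.values, vc, genotypes)
        except ValueError as exc:
            warnings.warn(f"phenotype {vid}: {exc}; skipped")
            continue
        results[vid] = (table, vc)
    return results
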
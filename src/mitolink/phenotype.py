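"""Heteroplasmy phenotypes: reference-allele fractions per mito variant.

Each mitochondrial variant becomes one quantitative "phenotype": the
per-individual fraction of reads supporting the reference allele.  A
binarized companion (0 below 0.05, 1 above 0.95, missing in between)
supports the binary-trait re-analysis, and variants are classified by
their heteroplasmy pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import VariantTable

__all__ = [
    "PhenotypeMatrix",
    "ref_allele_fraction",
    "build_phenotype_matrix",
    "binarize",
    "classify_heteroplasmy",
]


@dataclass
class PhenotypeMatrix:
    """Mito-variant × individual matrix of reference-allele fractions.

    Rows are keyed ``contig:pos``; entries lie in [0, 1] or are NaN.
    ``binary`` marks whether entries are the thresholded 0/1 companion.
    """

    values: pd.DataFrame  # index: variant id, columns: sample ids
    binary: bool = False

    @property
    def variant_ids(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def row(self, variant_id: str) -> np.ndarray:
        return self.values.loc[variant_id].to_numpy(dtype=float)

    def to_tsv(self, path, transpose: bool = False) -> None:
        df = self.values.T if transpose else self.values
        df.to_csv(path, sep="\t", na_rep="NA", index_label="id")

    @classmethod
    def from_tsv(cls, path, binary: bool = False) -> "PhenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        # accept the transposed layout (samples as rows) by checking keys
        if df.index.size and all(":" in str(c) for c in df.columns) and not all(
            ":" in str(i) for i in df.index
        ):
            df = df.T
        return cls(values=df.astype(float), binary=binary)


def ref_allele_fraction(ref_count, total_count):
    """ref_count / total_count, or NaN when no reads cover the site.

    Works element-wise on arrays; NaN inputs propagate (a masked
    observation stays missing).
    """
    rc = np.asarray(ref_count, dtype=float)
    tc = np.asarray(total_count, dtype=float)
    valid = ~(np.isnan(rc) | np.isnan(tc))
    if np.any(rc[valid] > tc[valid]):
        raise ValueError("ref_count exceeds total_count")
    if np.any(rc[valid] < 0):
        raise ValueError("negative read count")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(tc > 0, rc / tc, np.nan)
    if np.ndim(ref_count) == 0:
        return float(out) if not np.isnan(out) else np.nan
    return out


def build_phenotype_matrix(variants: VariantTable) -> PhenotypeMatrix:
    """One phenotype row per filtered mito variant.

    Entries are ``ref_count / total_depth`` per sample; observations with
    zero or masked depth are NaN.
    """
    ids = variants.site_ids()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant keys")
    frac = ref_allele_fraction(variants.ref_count, variants.total_depth)
    df = pd.DataFrame(frac, index=ids, columns=variants.samples)
    return PhenotypeMatrix(values=df, binary=False)


def binarize(
    matrix: PhenotypeMatrix, low: float = 0.05, high: float = 0.95
) -> PhenotypeMatrix:
    """Threshold fractions to a binary trait: < low → 0, > high → 1.

    Intermediate heteroplasmy (and missing entries) become missing; both
    inequalities are strict, so a value exactly at a threshold is dropped.
    """
    if low >= high:
        raise ValueError("low threshold must be below high threshold")
    v = matrix.values.to_numpy(dtype=float)
    out = np.full_like(v, np.nan)
    out[v < low] = 0.0
    out[v > high] = 1.0
    return PhenotypeMatrix(
        values=pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        binary=True,
    )


def classify_heteroplasmy(
    matrix: PhenotypeMatrix, low: float = 0.05, high: float = 0.95
) -> dict:
    """Classify each variant's heteroplasmy pattern.

    - ``homoplasmic_both_alleles``: some sample is reference-homoplasmic
      (fraction > high) and some sample is alt-homoplasmic (< low).
    - ``exclusively_heteroplasmic_alt``: the alternative allele appears
      (some fraction < high) but never at homoplasmic level (no fraction
      < low) — the pattern where an alt allele exists only within
      heteroplasmic individuals.
    - ``monomorphic``: no sample shows the alternative allele below the
      ``high`` threshold.
    """
    labels = {}
    for vid in matrix.variant_ids:
        row = matrix.row(vid)
        row = row[~np.isnan(row)]
        has_alt_homo = bool(np.any(row < low))
        has_ref_homo = bool(np.any(row > high))
        has_alt = bool(np.any(row < high))
        if has_alt_homo and has_ref_homo:
            labels[vid] = "homoplasmic_both_alleles"
        elif has_alt and not has_alt_homo:
            labels[vid] = "exclusively_heteroplasmic_alt"
        elif not has_alt:
            labels[vid] = "monomorphic"
        else:
            # only alt-homoplasmic individuals: alt fixed where present
            labels[vid] = "monomorphic"
        if not len(row):
            labels[vid] = "monomorphic"
    return labels
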
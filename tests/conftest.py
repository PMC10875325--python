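import numpy as np
import pytest

from mitolink.io_formats import VariantTable


def make_table(
    pos,
    ref_count,
    alt_count,
    total_depth=None,
    genotype=None,
    contig="chrM",
    ref="C",
    alt=("T",),
    samples=None,
):
    """Small helper to build a VariantTable from plain lists.

    ``ref_count``/``alt_count`` are (n_sites, n_samples) nested lists;
    None entries become missing.
    """
    rc = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in ref_count]
    )
    ac = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in alt_count]
    )
    dp = rc + ac if total_depth is None else np.array(
        [[np.nan if v is None else float(v) for v in row] for row in total_depth]
    )
    if genotype is None:
        gt = np.where(np.isnan(rc), np.nan, np.where(ac > 0, np.where(rc > 0, 1.0, 2.0), 0.0))
    else:
        gt = np.array(
            [[np.nan if v is None else float(v) for v in row] for row in genotype]
        )
    n_sites, n_samples = rc.shape
    if samples is None:
        samples = [f"S{i}" for i in range(n_samples)]
    if isinstance(ref, str):
        ref = [ref] * n_sites
    if isinstance(alt, tuple):
        alt = [alt] * n_sites
    if isinstance(contig, str):
        contig = [contig] * n_sites
    return VariantTable(
        contig=np.array(contig, dtype=object),
        pos=np.array(pos, dtype=int),
        ref=np.array(ref, dtype=object),
        alt=list(alt),
        samples=list(samples),
        ref_count=rc,
        alt_count=ac,
        total_depth=dp,
        genotype=gt,
    )


@pytest.fixture
def toy_gff(tmp_path):
    """Three genes on two contigs; one with a spliced CDS."""
    path = tmp_path / "toy.gff3"
    path.write_text(
        "##gff-version 3\n"
        "chr1\ttest\tgene\t100\t500\t.\t+\t.\tID=geneA\n"
        "chr1\ttest\tmRNA\t100\t500\t.\t+\t.\tID=mA;Parent=geneA\n"
        "chr1\ttest\texon\t100\t200\t.\t+\t.\tID=eA1;Parent=mA\n"
        "chr1\ttest\texon\t300\t500\t.\t+\t.\tID=eA2;Parent=mA\n"
        "chr1\ttest\tCDS\t100\t200\t.\t+\t0\tID=cA1;Parent=mA\n"
        "chr1\ttest\tCDS\t300\t500\t.\t+\t1\tID=cA2;Parent=mA\n"
        "chr1\ttest\tgene\t1500\t3000\t.\t-\t.\tID=geneB\n"
        "chr1\ttest\tmRNA\t1500\t3000\t.\t-\t.\tID=mB;Parent=geneB\n"
        "chr1\ttest\texon\t1500\t3000\t.\t-\t.\tID=eB1;Parent=mB\n"
        "chr1\ttest\tCDS\t1500\t3000\t.\t-\t0\tID=cB1;Parent=mB\n"
        "chr2\ttest\tgene\t10\t90\t.\t+\t.\tID=geneC\n"
    )
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
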
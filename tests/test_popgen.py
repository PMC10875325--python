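from itertools import permutations

import numpy as np
import pytest

from mitolink import io_formats as io, popgen

from conftest import make_table


def geno_table(positions, dosages, contig="chr1"):
    g = np.asarray(dosages, dtype=float)
    n_sites, n = g.shape
    return make_table(
        positions,
        [[0] * n] * n_sites,
        [[0] * n] * n_sites,
        total_depth=[[10] * n] * n_sites,
        genotype=[[None if np.isnan(v) else v for v in row] for row in g],
        contig=contig,
        ref="A",
    )


def pairwise_pi_oracle(dosages):
    """Mean per-site pairwise difference over allele copies, enumerating
    every pair of copies explicitly (independent of the estimator)."""
    out = []
    for row in np.asarray(dosages, dtype=float):
        copies = []
        for g in row:
            if not np.isnan(g):
                copies += [1] * int(g) + [0] * (2 - int(g))
        n = len(copies)
        diffs = sum(
            copies[i] != copies[j] for i in range(n) for j in range(i + 1, n)
        )
        out.append(diffs / (n * (n - 1) / 2) if n > 1 else 0.0)
    return np.array(out)


class TestWindowedPi:
    def test_empty_window_pi_zero(self):
        t = geno_table([5], [[0, 0, 0, 0]])
        track = popgen.windowed_pi(t, window=100, step=100, contig_lengths={"chr1": 300})
        assert track.loc[1, "pi"] == 0.0 and track.loc[2, "pi"] == 0.0

    def test_worked_four_copy_example(self):
        # one site, 4 haploid copies split 2/2: site pi = 2*2*2/(4*3) = 2/3
        # (4 of the 6 copy pairs differ), spread over a 100 bp window
        t = geno_table([50], [[0, 2]])  # two diploids: 2 ref copies + 2 alt copies
        track = popgen.windowed_pi(t, window=100, step=100, contig_lengths={"chr1": 100})
        assert track.loc[0, "pi"] == pytest.approx((2 / 3) / 100, abs=1e-15)

    def test_matches_pairwise_difference_oracle(self, rng):
        dosages = rng.integers(0, 3, size=(10, 6)).astype(float)
        dosages[rng.random(dosages.shape) < 0.15] = np.nan
        pos = np.sort(rng.choice(np.arange(1, 90), size=10, replace=False))
        t = geno_table(pos.tolist(), dosages)
        track = popgen.windowed_pi(t, window=100, step=100, contig_lengths={"chr1": 100})
        expect = pairwise_pi_oracle(dosages).sum() / 100
        assert track.loc[0, "pi"] == pytest.approx(expect, abs=1e-12)

    def test_invariant_to_record_order_and_sample_relabel(self, rng):
        dosages = rng.integers(0, 3, size=(8, 5)).astype(float)
        pos = np.sort(rng.choice(np.arange(1, 500), size=8, replace=False))
        t1 = geno_table(pos.tolist(), dosages)
        perm = rng.permutation(8)
        t2 = geno_table(pos[perm].tolist(), dosages[perm])
        shuffled_samples = dosages[:, rng.permutation(5)]
        t3 = geno_table(pos.tolist(), shuffled_samples)
        kw = dict(window=200, step=100, contig_lengths={"chr1": 500})
        a = popgen.windowed_pi(t1, **kw)
        assert np.allclose(a["pi"], popgen.windowed_pi(t2, **kw)["pi"])
        assert np.allclose(a["pi"], popgen.windowed_pi(t3, **kw)["pi"])

    def test_step_larger_than_window_rejected(self):
        t = geno_table([5], [[1, 1]])
        with pytest.raises(ValueError):
            popgen.windowed_pi(t, window=10, step=20)


class TestDiversityContrast:
    def _annotation(self, spans):
        ann = io.GenomeAnnotation()
        for i, (s, e) in enumerate(spans):
            ann.add_gene(io.Gene(f"g{i}", "chr1", s, e, "+"))
        return ann

    def _site_frame(self, pos, pi):
        import pandas as pd

        return pd.DataFrame({"contig": ["chr1"] * len(pos), "pos": pos, "pi": pi})

    def test_identical_groups_p_near_one(self):
        ann = self._annotation([(i * 100, i * 100 + 50) for i in range(6)])
        pis = self._site_frame(
            [i * 100 + 10 for i in range(6)], [0.01, 0.02, 0.03, 0.01, 0.02, 0.03]
        )
        out = popgen.gene_diversity_contrast(
            pis, ["g0", "g1", "g2"], ["g3", "g4", "g5"], annotation=ann, mode="site"
        )
        assert out["p_value"] >= 0.99

    def test_exact_rank_sum_textbook_value(self):
        ann = self._annotation([(i * 100, i * 100 + 50) for i in range(6)])
        pis = self._site_frame([i * 100 + 10 for i in range(6)], [1, 2, 3, 4, 5, 6])
        out = popgen.gene_diversity_contrast(
            pis, ["g0", "g1", "g2"], ["g3", "g4", "g5"], annotation=ann, mode="site"
        )
        assert out["p_value"] == pytest.approx(0.1, abs=1e-12)

    def test_exact_p_matches_exhaustive_permutation_oracle(self):
        target = [1.0, 2.0, 3.0]
        background = [4.0, 5.0, 6.0]
        pooled = target + background
        obs = sum(target)
        count = 0
        total = 0
        from itertools import combinations

        sums = [sum(c) for c in combinations(pooled, 3)]
        mean_sum = np.mean(sums)
        for s in sums:
            total += 1
            if abs(s - mean_sum) >= abs(obs - mean_sum) - 1e-12:
                count += 1
        assert count / total == pytest.approx(0.1)

    def test_planted_elevation_detected(self):
        rng = np.random.default_rng(30)
        detected = 0
        n_rep = 10
        n_genes = 550
        for _ in range(n_rep):
            spans = [(i * 100, i * 100 + 50) for i in range(n_genes)]
            ann = self._annotation(spans)
            base = rng.gamma(2.0, 0.005, size=n_genes)
            base[:50] *= 2.0  # targets at doubled diversity
            pis = self._site_frame([i * 100 + 10 for i in range(n_genes)], base)
            out = popgen.gene_diversity_contrast(
                pis,
                [f"g{i}" for i in range(50)],
                [f"g{i}" for i in range(50, n_genes)],
                annotation=ann,
                mode="site",
            )
            detected += out["p_value"] < 0.01
        assert detected >= 9

    def test_small_group_rejected(self):
        ann = self._annotation([(0, 10), (20, 30), (40, 50), (60, 70)])
        pis = self._site_frame([5, 25, 45, 65], [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError):
            popgen.gene_diversity_contrast(
                pis, ["g0"], ["g1", "g2", "g3"], annotation=ann, mode="site"
            )


class TestConsensus:
    def test_no_variants_identity(self):
        import numpy as _np
        from mitolink.io_formats import VariantTable

        t = VariantTable(
            contig=_np.array([], dtype=object), pos=_np.array([], dtype=int),
            ref=_np.array([], dtype=object), alt=[], samples=["S0", "S1"],
            ref_count=_np.empty((0, 2)), alt_count=_np.empty((0, 2)),
            total_depth=_np.empty((0, 2)), genotype=_np.empty((0, 2)),
        )
        assert popgen.consensus_sequence("ACGTAC", t) == "ACGTAC"

    def test_majority_alt_substituted(self):
        # 9 of 10 samples homozygous alt at CDS position 3
        g = [[2.0] * 9 + [0.0]]
        t = make_table([3], [[0] * 10], [[0] * 10], total_depth=[[9] * 10],
                       genotype=g, contig="cds", ref="G", alt=[("T",)])
        assert popgen.consensus_sequence("ACGTAC", t) == "ACTTAC"

    def test_fifty_fifty_tie_keeps_reference(self):
        g = [[2.0, 0.0]]
        t = make_table([3], [[0, 0]], [[0, 0]], total_depth=[[9, 9]],
                       genotype=g, contig="cds", ref="G", alt=[("T",)])
        assert popgen.consensus_sequence("ACGTAC", t) == "ACGTAC"

    def test_indel_skipped_with_warning(self):
        t = make_table([3], [[0]], [[0]], total_depth=[[9]],
                       genotype=[[2.0]], contig="cds", ref="G", alt=[("GTT",)])
        messages = []
        out = popgen.consensus_sequence("ACGTAC", t, warn=messages.append)
        assert out == "ACGTAC" and messages


def ng86_pathway_oracle(ca, cb):
    """Exhaustive pathway enumeration written independently: walk every
    permutation of differing positions, drop stop-containing paths."""
    table = popgen.CODON_TABLE
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    results = []
    for order in permutations(diffs):
        steps = []
        cur = ca
        valid = True
        for i in order:
            nxt = cur[:i] + cb[i] + cur[i + 1:]
            if table[nxt] == "*" and nxt != cb:
                valid = False
                break
            steps.append((table[cur], table[nxt]))
            cur = nxt
        if valid:
            nd = sum(a != b for a, b in steps)
            results.append((nd, len(steps) - nd))
    if not results:
        return None
    return (
        float(np.mean([r[0] for r in results])),
        float(np.mean([r[1] for r in results])),
    )


class TestKaKs:
    def test_identical_sequences_zero(self):
        res = popgen.kaks_ng86("ATGAAATTT", "ATGAAATTT")
        assert res.ka == 0.0 and res.ks == 0.0 and res.ratio is None

    def test_synonymous_phe_change(self):
        res = popgen.kaks_ng86("TTT", "TTC")
        assert res.sd == 1.0 and res.nd == 0.0
        assert res.ks > 0 and res.ka == 0.0

    def test_site_counts_sum_to_three_per_codon(self, rng):
        codons = [c for c in popgen.CODON_TABLE if popgen.CODON_TABLE[c] != "*"]
        for c in codons:
            n, s = popgen._syn_fraction(c)
            assert n + s == pytest.approx(3.0)

    def test_random_codon_pairs_match_pathway_oracle(self, rng):
        codons = [c for c in popgen.CODON_TABLE if popgen.CODON_TABLE[c] != "*"]
        checked = 0
        while checked < 100:
            ca, cb = rng.choice(codons, size=2)
            expect = ng86_pathway_oracle(ca, cb)
            if expect is None:
                continue
            res = popgen.kaks_ng86(ca, cb)
            assert (res.nd, res.sd) == pytest.approx(expect)
            checked += 1

    def test_symmetry(self, rng):
        codons = [c for c in popgen.CODON_TABLE if popgen.CODON_TABLE[c] != "*"]
        for _ in range(20):
            a = "".join(rng.choice(codons, size=5))
            b = "".join(rng.choice(codons, size=5))
            ra = popgen.kaks_ng86(a, b)
            rb = popgen.kaks_ng86(b, a)
            assert ra.ka == pytest.approx(rb.ka)
            assert ra.ks == pytest.approx(rb.ks)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            popgen.kaks_ng86("ATGTAAAAA", "ATGAAAAAA")

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError):
            popgen.kaks_ng86("ATGA", "ATGA")
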
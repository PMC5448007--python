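"""IBS/MDS, Weir-Cockerham F_ST (with an independent per-locus oracle)
and Spearman correlation."""

import numpy as np
import pytest

from isopop import (GenotypeMatrix, MarkerMap, ibs_matrix, mds,
                    pairwise_fst, spearman)
from isopop.structure import _theta


def _gm(dos, pops=None):
    dos = np.asarray(dos, dtype=np.int8)
    n, m = dos.shape
    mmap = MarkerMap(
        np.array(["1"] * m, dtype=object),
        np.array([f"m{i}" for i in range(m)], dtype=object),
        np.arange(1, m + 1) * 10_000, np.arange(1, m + 1) * 0.01)
    return GenotypeMatrix(dos, np.array([f"s{i}" for i in range(n)],
                                        dtype=object), mmap, pops)


class TestIbs:
    def test_hand_counted_fixture(self):
        dos = np.array([
            [0, 1, 2, 1],
            [0, 2, 2, 0],
            [2, 1, 0, 1],
        ])
        sim = ibs_matrix(_gm(dos))
        # s0~s1: shared alleles 2,1,2,1 -> 6/8
        assert sim[0, 1] == pytest.approx(6 / 8)
        # s0~s2: 0,2,0,2 -> 4/8
        assert sim[0, 2] == pytest.approx(4 / 8)
        # s1~s2: 0,1,0,1 -> 2/8
        assert sim[1, 2] == pytest.approx(2 / 8)

    def test_duplicate_is_one_and_opposite_is_zero(self):
        dos = np.array([[0, 0, 0], [0, 0, 0], [2, 2, 2]])
        sim = ibs_matrix(_gm(dos))
        assert sim[0, 1] == 1.0
        assert sim[0, 2] == 0.0

    def test_no_overlap_pair_rejected(self):
        dos = np.array([[0, -1], [-1, 2]])
        with pytest.raises(ValueError, match="no.*markers"):
            ibs_matrix(_gm(dos))


class TestMds:
    def test_collinear_points_recovered_exactly(self):
        """Four points on a line: classical scaling must reproduce the
        inter-point distances on dimension 1 to 1e-9."""
        x = np.array([0.0, 0.1, 0.25, 0.4])
        dist = np.abs(x[:, None] - x[None, :])
        res = mds(1.0 - dist, k=2)
        d1 = np.abs(res.coordinates[:, 0][:, None]
                    - res.coordinates[:, 0][None, :])
        assert np.allclose(d1, dist, atol=1e-9)

    def test_identical_samples_map_to_origin(self):
        res = mds(np.ones((5, 5)), k=2)
        assert np.allclose(res.coordinates, 0.0, atol=1e-9)

    def test_two_simulated_clusters_separate_on_dim1(self, isolate_sim,
                                                     outbred_sim):
        iso_panel, _ = isolate_sim
        # use two synthetic populations drawn from different founder pools
        rng = np.random.default_rng(5)
        pa = rng.uniform(0.1, 0.9, 800)
        pb = np.clip(pa + rng.normal(0, 0.12, 800), 0.05, 0.95)
        da = rng.binomial(2, pa, (15, 800)).astype(np.int8)
        db = rng.binomial(2, pb, (15, 800)).astype(np.int8)
        g = _gm(np.vstack([da, db]))
        res = mds(ibs_matrix(g), k=2)
        c1 = res.coordinates[:, 0]
        assert max(c1[:15]) < min(c1[15:]) or min(c1[:15]) > max(c1[15:])

    def test_k_exceeding_samples_rejected(self):
        with pytest.raises(ValueError):
            mds(np.eye(3), k=3)


def _wc_locus_oracle(counts_a, counts_b):
    """Independent scalar Weir-Cockerham (1984) a,b,c for one locus.

    ``counts_x`` = (n_hom_ref, n_het, n_hom_alt) in population x.  Written
    directly from the published component formulas, scalar arithmetic only.
    """
    import math
    r = 2
    comps = []
    ns, ps, hs = [], [], []
    for c in (counts_a, counts_b):
        n = sum(c)
        p = (2 * c[2] + c[1]) / (2 * n)
        h = c[1] / n
        ns.append(n)
        ps.append(p)
        hs.append(h)
    nbar = sum(ns) / r
    nc = (sum(ns) - sum(n * n for n in ns) / sum(ns)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / sum(ns)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / sum(ns)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestFst:
    def _oracle_theta(self, dos, labels):
        num = den = 0.0
        for j in range(dos.shape[1]):
            counts = []
            for pop in sorted(set(labels)):
                col = dos[np.asarray(labels) == pop, j]
                counts.append((int((col == 0).sum()), int((col == 1).sum()),
                               int((col == 2).sum())))
            ps = [(2 * c[2] + c[1]) / (2 * sum(c)) for c in counts]
            pooled = sum(2 * c[2] + c[1] for c in counts) / \
                (2 * sum(sum(c) for c in counts))
            if pooled in (0.0, 1.0):
                continue
            a, b, c = _wc_locus_oracle(*counts)
            num += a
            den += a + b + c
        return num / den

    def test_matches_per_locus_oracle_to_1e12(self):
        rng = np.random.default_rng(6)
        for trial in range(5):
            na, nb = rng.integers(4, 12, 2)
            m = 40
            pa = rng.uniform(0.1, 0.9, m)
            pb = np.clip(pa + rng.normal(0, 0.15, m), 0.05, 0.95)
            dos = np.vstack([
                rng.binomial(2, pa, (na, m)),
                rng.binomial(2, pb, (nb, m)),
            ]).astype(np.int8)
            labels = np.array(["A"] * na + ["B"] * nb, dtype=object)
            g = _gm(dos, labels)
            res = pairwise_fst(g, n_perm=5, ci_boot_loci=5, seed=trial)
            oracle = self._oracle_theta(dos, labels)
            assert res.fst.loc["A", "B"] == pytest.approx(oracle,
                                                          abs=1e-12)

    def test_fixed_difference_gives_one(self):
        dos = np.vstack([np.zeros((6, 50)), np.full((6, 50), 2)])
        g = _gm(dos, np.array(["A"] * 6 + ["B"] * 6, dtype=object))
        res = pairwise_fst(g, n_perm=5, ci_boot_loci=5, seed=0)
        assert res.fst.loc["A", "B"] == pytest.approx(1.0)

    def test_random_split_near_zero(self):
        rng = np.random.default_rng(7)
        dos = rng.binomial(2, rng.uniform(0.2, 0.8, 800),
                           (60, 800)).astype(np.int8)
        labels = np.array(["A"] * 30 + ["B"] * 30, dtype=object)
        g = _gm(dos, labels)
        res = pairwise_fst(g, n_perm=20, ci_boot_loci=20, seed=1)
        assert abs(res.fst.loc["A", "B"]) < 0.01
        assert res.p_value.loc["A", "B"] > 0.05

    def test_increases_with_divergence_time(self):
        """Longer isolation -> larger F_ST (two gene-dropping populations
        splitting from shared founder frequencies)."""
        from isopop import DemographyConfig, Epoch, make_marker_map, \
            simulate_gene_dropping
        mmap = make_marker_map([50.0], 1200, seed=9)
        rng = np.random.default_rng(9)
        freqs = rng.uniform(0.2, 0.8, len(mmap))
        means = []
        for gens in (3, 25):
            vals = []
            for seed in range(3):
                panels = []
                for pop, s in (("A", 100 + seed), ("B", 200 + seed)):
                    p, _ = simulate_gene_dropping(
                        DemographyConfig(60, [Epoch(gens, 60)]), mmap,
                        founder_freqs=freqs, n_sample=20,
                        population_label=pop, seed=s)
                    panels.append(p.to_genotypes())
                dos = np.vstack([pp.dosages for pp in panels])
                labels = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
                g = GenotypeMatrix(dos, np.array(
                    [f"x{i}" for i in range(40)], dtype=object),
                    mmap, labels)
                vals.append(_theta(g.dosages,
                                   [np.arange(20), np.arange(20, 40)]))
            means.append(np.mean(vals))
        assert means[1] > means[0] > 0

    def test_monomorphic_only_rejected(self):
        dos = np.zeros((8, 10))
        g = _gm(dos, np.array(["A"] * 4 + ["B"] * 4, dtype=object))
        with pytest.raises(ValueError, match="monomorphic"):
            pairwise_fst(g, n_perm=2, ci_boot_loci=2, seed=0)


class TestSpearman:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        rho, p = spearman(x, x, n_perm=200, seed=0)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, -x, n_perm=200, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_fixture_with_tie(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [10.0, 20.0, 20.0, 30.0]
        # ranks y = 1, 2.5, 2.5, 4; hand Pearson of ranks = 0.9487
        rho, _ = spearman(x, y, n_perm=100, seed=0)
        assert rho == pytest.approx(0.94868329, abs=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [5, 5, 5], n_perm=10)
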
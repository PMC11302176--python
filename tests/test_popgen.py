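"""Consensus building, variant calling, PCA and pairwise SNP distances."""

from __future__ import annotations

import shutil
import subprocess

import numpy as np
import pytest

from ltrpop.io import read_vcf, write_vcf
from ltrpop.models import VariantTable
from ltrpop.popgen import (
    build_consensus,
    call_variants,
    pairwise_snp_distance,
    run_pca,
)
from ltrpop.simulate import random_dna


@pytest.fixture(scope="module")
def consensus_300():
    return random_dna(np.random.default_rng(55), 300)


class TestBuildConsensus:
    def test_identical_copies_reproduce_the_copy(self, consensus_300):
        copies = {f"c{i}": consensus_300 for i in range(30)}
        assert build_consensus(copies, sample_n=30, seed=0) == consensus_300

    def test_column_majority(self, consensus_300):
        pos = 120
        base = consensus_300[pos]
        other = "G" if base != "G" else "A"
        copies = {}
        for i in range(30):
            s = list(consensus_300)
            if i < 10:
                s[pos] = other if base != other else base
            copies[f"c{i}"] = "".join(s)
        cons = build_consensus(copies, sample_n=30, seed=0)
        assert cons[pos] == base  # 20 majority beats 10 minority

    def test_seeded_sampling_is_deterministic(self, consensus_300):
        rng = np.random.default_rng(1)
        copies = {f"c{i}": random_dna(rng, 300) for i in range(50)}
        assert build_consensus(copies, seed=3) == build_consensus(copies, seed=3)

    def test_fewer_than_two_copies_rejected(self, consensus_300):
        with pytest.raises(ValueError):
            build_consensus({"only": consensus_300})


class TestCallVariants:
    def test_half_frequency_site(self, consensus_300):
        copies = {}
        for i in range(10):
            s = list(consensus_300)
            if i < 5:
                s[100] = "G" if s[100] != "G" else "A"
            copies[f"c{i}"] = "".join(s)
        table = call_variants(copies, consensus_300)
        assert list(table.positions) == [100]
        g = table.genotypes[:, 0]
        assert (g == 1).sum() == 5 and (g == 0).sum() == 5

    def test_singleton_below_maf_dropped(self, consensus_300):
        """One carrier among 200 copies (frequency 0.005) is below the 1%
        minor-allele threshold."""
        copies = {f"c{i}": consensus_300 for i in range(199)}
        s = list(consensus_300)
        s[50] = "T" if s[50] != "T" else "C"
        copies["carrier"] = "".join(s)
        table = call_variants(copies, consensus_300)
        assert table.n_sites == 0

    def test_two_percent_frequency_retained(self, consensus_300):
        copies = {f"c{i}": consensus_300 for i in range(196)}
        for i in range(4):
            s = list(consensus_300)
            s[50] = "T" if s[50] != "T" else "C"
            copies[f"alt{i}"] = "".join(s)
        table = call_variants(copies, consensus_300)
        assert list(table.positions) == [50]

    def test_insertion_creates_no_site(self, consensus_300):
        rng = np.random.default_rng(10)
        copies = {}
        for i in range(10):
            s = list(consensus_300)
            if i < 5:
                s[100] = "G" if s[100] != "G" else "A"
            seq = "".join(s)
            if i == 0:  # 50 bp insertion in one copy
                seq = seq[:150] + random_dna(rng, 50) + seq[150:]
            copies[f"c{i}"] = seq
        table = call_variants(copies, consensus_300)
        assert list(table.positions) == [100]

    def test_deletion_is_missing_data(self, consensus_300):
        copies = {}
        for i in range(10):
            s = list(consensus_300)
            if i < 5:
                s[100] = "G" if s[100] != "G" else "A"
            seq = "".join(s)
            if i == 0:
                seq = seq[:95] + seq[110:]  # deletion spanning site 100
            copies[f"c{i}"] = seq
        table = call_variants(copies, consensus_300)
        assert list(table.positions) == [100]
        assert table.genotypes[list(copies).index("c0"), 0] == VariantTable.MISSING

    def test_poorly_aligning_copy_dropped(self, consensus_300, caplog):
        rng = np.random.default_rng(12)
        copies = {f"c{i}": consensus_300 for i in range(3)}
        copies["junk"] = random_dna(rng, 300)
        s = list(consensus_300)
        s[10] = "A" if s[10] != "A" else "C"
        copies["c1"] = "".join(s)
        with caplog.at_level("WARNING"):
            table = call_variants(copies, consensus_300)
        assert "junk" not in table.copy_ids

    def test_site_bounds_hold(self, family_population):
        family_population["table"].validate_site_bounds()


class TestPCA:
    def _two_subfamilies(self, consensus_300, rng, n_per=20, n_sites=20):
        sites = rng.choice(300, size=n_sites, replace=False)
        copies = {}
        for i in range(2 * n_per):
            s = list(consensus_300)
            if i >= n_per:
                for p in sites:
                    s[p] = "A" if s[p] != "A" else "G"
            # private noise so copies are not identical
            p = int(rng.integers(300))
            s[p] = "T" if s[p] != "T" else "C"
            copies[f"c{i:02d}"] = "".join(s)
        return copies

    def test_pc1_separates_two_subfamilies(self, consensus_300):
        """Two subfamilies differing at 20 fixed sites separate on PC1
        with perfect cluster purity."""
        rng = np.random.default_rng(13)
        copies = self._two_subfamilies(consensus_300, rng)
        table = call_variants(copies, consensus_300)
        pca = run_pca(table)
        pc1 = pca.coordinates[:, 0]
        labels = np.array([int(c[1:]) >= 20 for c in pca.copy_ids])
        side = pc1 > np.median(pc1)
        purity = max((side == labels).mean(), (side != labels).mean())
        assert purity == 1.0

    def test_identical_copies_are_degenerate(self, consensus_300):
        copies = {f"c{i}": consensus_300 for i in range(5)}
        with pytest.raises(ValueError):
            table = call_variants(copies, consensus_300)
            run_pca(table)

    def test_variance_accounting(self, family_population):
        table = family_population["table"]
        pca = run_pca(table)
        assert np.all(np.diff(pca.explained_variance) <= 1e-9)
        X = table.genotypes.astype(float)
        X[X == VariantTable.MISSING] = np.nan
        col_mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = col_mean[idx[1]]
        total = X.var(axis=0, ddof=1).sum()
        assert pca.explained_variance.sum() <= total + 1e-9

    def test_subfamily_recovery_on_simulated_family(self, family_population):
        """k-means on PC1/2 recovers the implanted subfamilies (purity >=
        0.9) for the simulated family population."""
        from sklearn.cluster import KMeans

        table = family_population["table"]
        pca = run_pca(table)
        subs = family_population["subfamilies"]
        y = np.array([subs[i] for i in pca.copy_ids])
        k = len(set(y))
        km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(
            pca.coordinates[:, :2]
        )
        purity = (
            sum(
                np.bincount(
                    np.unique(y[km.labels_ == c], return_inverse=True)[1]
                ).max()
                for c in range(k)
                if (km.labels_ == c).any()
            )
            / y.size
        )
        assert purity >= 0.9


class TestPairwiseDistance:
    def _table(self, genotypes):
        g = np.asarray(genotypes, dtype=np.int8)
        return VariantTable(
            consensus_id="t",
            positions=np.arange(g.shape[1]),
            ref_alleles=["A"] * g.shape[1],
            alt_alleles=[["G"]] * g.shape[1],
            genotypes=g,
            copy_ids=[f"c{i}" for i in range(g.shape[0])],
            maf=0.0,
            missing_cutoff=1.0,
        )

    def test_self_distance_zero_and_counts(self):
        t = self._table([[0, 0, 0, 1, 1], [0, 1, 1, 0, 1], [0, 0, 0, 1, 1]])
        d = pairwise_snp_distance(t)
        assert d[0, 0] == 0
        assert d[0, 1] == 3 and d[1, 0] == 3
        assert d[0, 2] == 0

    def test_missing_pairs_do_not_count(self):
        t = self._table([[0, -1, 1], [1, 1, -1]])
        d = pairwise_snp_distance(t)
        assert d[0, 1] == 1  # only site 0 is comparable and differs

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_agrees_with_ape_dist_gene(self, tmp_path):
        """Independent oracle: ape::dist.gene pairwise difference counts."""
        rng = np.random.default_rng(21)
        g = rng.integers(0, 2, size=(8, 40)).astype(np.int8)
        t = self._table(g)
        ours = pairwise_snp_distance(t)
        csv = tmp_path / "geno.csv"
        np.savetxt(csv, g, fmt="%d", delimiter=",")
        script = tmp_path / "dist.R"
        script.write_text(
            f'g <- as.matrix(read.csv("{csv}", header=FALSE));\n'
            "d <- ape::dist.gene(g, method='pairwise');\n"
            "cat(as.vector(as.matrix(d)))\n"
        )
        res = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True,
            text=True,
            check=True,
        )
        theirs = np.array(res.stdout.split(), dtype=float).reshape(8, 8)
        assert np.array_equal(ours, theirs)


def test_vcf_round_trip_is_identity(tmp_path, consensus_300):
    copies = {}
    rng = np.random.default_rng(17)
    for i in range(20):
        s = list(consensus_300)
        if i % 3 == 0:
            s[30] = "A" if s[30] != "A" else "G"
        if i % 4 == 0:
            s[60] = "C" if s[60] != "C" else "T"
        seq = "".join(s)
        if i == 5:
            seq = seq[:25] + seq[40:]  # deletion -> missing calls
        copies[f"c{i:02d}"] = seq
    table = call_variants(copies, consensus_300)
    assert table.n_sites >= 2
    path = tmp_path / "v.vcf"
    write_vcf(path, table, len(consensus_300))
    back = read_vcf(path)
    assert back.consensus_id == table.consensus_id
    assert list(back.positions) == list(table.positions)
    assert back.ref_alleles == table.ref_alleles
    assert back.alt_alleles == table.alt_alleles
    assert back.copy_ids == table.copy_ids
    assert np.array_equal(back.genotypes, table.genotypes)
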
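"""Midpoint positional metric, Mantel permutation test, region/age filter."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltrpop.models import CentromereDefinition, FullLengthCopy, GenomicInterval
from ltrpop.spatial import (
    filter_region_age,
    mantel_statistic,
    mantel_test,
    positional_difference,
    positional_distance_matrix,
)

MB = 1_000_000


@pytest.fixture()
def cen200():
    return CentromereDefinition("chr1", 150 * MB, 250 * MB, midpoint=200 * MB)


class TestPositionalDifference:
    def test_opposite_sides_of_midpoint(self, cen200):
        """Copies at 180 and 210 Mb around a 200 Mb midpoint differ by 10 Mb."""
        assert positional_difference(180 * MB, 210 * MB, cen200) == pytest.approx(10.0)

    def test_equidistant_copies_have_zero_difference(self):
        """245 and 255 Mb are both 5 Mb from a 250 Mb midpoint."""
        cen = CentromereDefinition("chr1", 200 * MB, 300 * MB, midpoint=250 * MB)
        assert abs(245 * MB - cen.midpoint) / MB == pytest.approx(5.0)
        assert positional_difference(245 * MB, 255 * MB, cen) == pytest.approx(0.0)

    def test_identical_positions(self, cen200):
        assert positional_difference(3 * MB, 3 * MB, cen200) == 0.0

    def test_chromosome_mismatch_rejected(self, cen200):
        with pytest.raises(ValueError):
            positional_difference(1.0, 2.0, cen200, chrom_i="chr2")

    @given(st.lists(st.floats(0, 5e8), min_size=3, max_size=3))
    @settings(max_examples=200, deadline=None)
    def test_pseudometric_properties(self, positions):
        cen = CentromereDefinition("chr1", 150 * MB, 250 * MB, midpoint=200 * MB)
        a, b, c = positions
        dab = positional_difference(a, b, cen)
        dba = positional_difference(b, a, cen)
        dac = positional_difference(a, c, cen)
        dcb = positional_difference(c, b, cen)
        assert dab == dba
        assert dab <= dac + dcb + 1e-9

    def test_matrix_agrees_with_scalar(self, cen200):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 400 * MB, size=6)
        m = positional_distance_matrix(pos, cen200)
        for i in range(6):
            for j in range(6):
                assert m[i, j] == pytest.approx(
                    positional_difference(pos[i], pos[j], cen200)
                )


def _random_distance_matrix(rng, n):
    m = rng.random((n, n))
    m = m + m.T
    np.fill_diagonal(m, 0)
    return m


class TestMantel:
    def test_identical_matrices_give_statistic_one(self):
        rng = np.random.default_rng(1)
        m = _random_distance_matrix(rng, 10)
        res = mantel_test(m, m.copy(), permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_small_matrix_p_matches_exhaustive_enumeration(self):
        """On a 4x4 problem the permutation p is within Monte-Carlo error
        of the exact p over all 24 row/column permutations."""
        rng = np.random.default_rng(7)
        g = _random_distance_matrix(rng, 4)
        p_mat = _random_distance_matrix(rng, 4)
        r_obs = mantel_statistic(g, p_mat)
        stats = []
        for perm in itertools.permutations(range(4)):
            idx = np.array(perm)
            stats.append(mantel_statistic(g, p_mat[np.ix_(idx, idx)]))
        p_exact = np.mean([s >= r_obs - 1e-12 for s in stats])
        res = mantel_test(g, p_mat, permutations=9999, seed=11)
        mc_err = 3 * np.sqrt(p_exact * (1 - p_exact) / 9999) + 1e-4
        assert abs(res.p_value - p_exact) <= mc_err

    def test_null_type_one_error_is_nominal(self):
        """Independent random matrices (n=30): rejection rate at alpha=0.05
        over 500 replicates within binomial error of 0.05."""
        rng = np.random.default_rng(19)
        rejections = 0
        for rep in range(500):
            g = _random_distance_matrix(rng, 30)
            p_mat = _random_distance_matrix(rng, 30)
            res = mantel_test(g, p_mat, permutations=199, seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        # 3 sigma around 25 of 500
        assert abs(rejections - 25) <= 3 * np.sqrt(500 * 0.05 * 0.95)

    def test_seeded_reproducibility_and_relabeling_invariance(self):
        rng = np.random.default_rng(23)
        g = _random_distance_matrix(rng, 15)
        p_mat = _random_distance_matrix(rng, 15)
        r1 = mantel_test(g, p_mat, permutations=499, seed=5)
        r2 = mantel_test(g, p_mat, permutations=499, seed=5)
        assert (r1.statistic, r1.p_value) == (r2.statistic, r2.p_value)
        order = rng.permutation(15)
        r3 = mantel_test(
            g[np.ix_(order, order)], p_mat[np.ix_(order, order)],
            permutations=499, seed=5,
        )
        assert r3.statistic == pytest.approx(r1.statistic)

    def test_missing_entries_dropped_pairwise(self):
        rng = np.random.default_rng(29)
        g = _random_distance_matrix(rng, 12)
        p_mat = g + 0.01 * _random_distance_matrix(rng, 12)
        g_nan = g.copy()
        g_nan[0, 1] = g_nan[1, 0] = np.nan
        res = mantel_test(g_nan, p_mat, permutations=99, seed=1)
        assert res.statistic > 0.9

    def test_degenerate_zero_variance_rejected(self):
        g = np.zeros((5, 5))
        p_mat = _random_distance_matrix(np.random.default_rng(0), 5)
        with pytest.raises(ValueError):
            mantel_test(g, p_mat, permutations=99)

    def test_gradient_population_shows_positive_association(self, family_population):
        """Simulated age-position gradient: positive Mantel statistic at
        p <= 0.01; shuffling positions destroys the signal."""
        dist = family_population["distances"].astype(float)
        table = family_population["table"]
        cen = family_population["centromere"]
        positions = [family_population["positions"][i] for i in table.copy_ids]
        pos_m = positional_distance_matrix(positions, cen)
        res = mantel_test(dist, pos_m, permutations=999, seed=3)
        assert res.statistic > 0
        assert res.p_value <= 0.01
        # shuffled positions: p > 0.05 in >= 90% of 100 replicates
        rng = np.random.default_rng(4)
        nonsig = 0
        for _ in range(100):
            order = rng.permutation(len(positions))
            shuffled = positional_distance_matrix(
                np.asarray(positions)[order], cen
            )
            r = mantel_test(dist, shuffled, permutations=199,
                            seed=int(rng.integers(2**31)))
            nonsig += r.p_value > 0.05
        assert nonsig >= 90


class TestFilterRegionAge:
    def _copy_at(self, mb):
        s = int(mb * MB)
        return FullLengthCopy(
            id=f"c{mb}",
            family="F",
            interval=GenomicInterval("chr4", s - 1000, s + 1000),
            ltr5=GenomicInterval("chr4", s - 1000, s - 500),
            ltr3=GenomicInterval("chr4", s + 500, s + 1000),
        )

    def test_neocentromere_bounds(self):
        """Region 281.1-284 Mb, age <= 100,000 y: inside/young retained,
        old or outside excluded."""
        region = GenomicInterval("chr4", int(281.1 * MB), 284 * MB)
        pairs = [
            (self._copy_at(282), 50_000.0),
            (self._copy_at(282.5), 150_000.0),
            (self._copy_at(280), 50_000.0),
        ]
        kept = filter_region_age(pairs, region, max_age=100_000)
        assert [c.id for c, _ in kept] == ["c282"]

    def test_wrong_chromosome_excluded(self):
        region = GenomicInterval("chr5", int(281.1 * MB), 284 * MB)
        kept = filter_region_age([(self._copy_at(282), 1.0)], region, 1e5)
        assert kept == []
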
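"""Hot-spot calling (vs a brute-force oracle), peak classification,
family normalisation and consensus-coordinate projection."""

from __future__ import annotations

import numpy as np
import pytest

from ltrpop.align import local_align
from ltrpop.chipseq import (
    classify_peak,
    compile_profile,
    detect_hotspots,
    family_enrichment,
    project_coverage,
    region_average,
)
from ltrpop.models import (
    CoverageTrack,
    FullLengthCopy,
    GenomicInterval,
    revcomp,
)
from ltrpop.simulate import random_dna


def _track(label, arr):
    return CoverageTrack(label=label, depth={"chr1": np.asarray(arr, dtype=np.int64)})


def _iv(s, e):
    return GenomicInterval("chr1", s, e)


class TestRegionAverage:
    def test_uniform_depth(self):
        t = _track("x", np.full(1000, 7))
        assert region_average(t, [_iv(100, 300)]) == 7.0

    def test_mean_over_disjoint_regions(self):
        arr = np.zeros(1000)
        arr[0:100] = 10
        arr[500:600] = 20
        t = _track("x", arr)
        assert region_average(t, [_iv(0, 100), _iv(500, 600)]) == 15.0

    def test_overlapping_regions_counted_once(self):
        arr = np.zeros(1000)
        arr[0:100] = 10
        t = _track("x", arr)
        assert region_average(t, [_iv(0, 100), _iv(50, 100)]) == 10.0

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValueError):
            region_average(_track("x", np.ones(10)), [])


def brute_force_peaks(exp, controls, regions, min_len, fold):
    """Per-base reimplementation of the hot-spot rule."""
    baseline = region_average(exp, regions)
    out = []
    for chrom, depth in exp.depth.items():
        in_region = np.zeros(depth.size, dtype=bool)
        for r in regions:
            if r.chrom == chrom:
                in_region[r.start : r.end] = True
        ctrl = sum(c.depth[chrom] for c in controls)
        run = []
        for i in range(depth.size + 1):
            ok = (
                i < depth.size
                and in_region[i]
                and depth[i] >= fold * baseline
                and depth[i] >= fold * ctrl[i]
            )
            if ok:
                run.append(i)
            elif run:
                if len(run) >= min_len:
                    out.append((chrom, run[0], run[-1] + 1))
                run = []
    return out


class TestDetectHotspots:
    def _fixture(self, seed=0):
        rng = np.random.default_rng(seed)
        depth = rng.poisson(5, size=8000)
        for s, ln in zip((1000, 2500, 5000, 6900), (130, 90, 210, 101)):
            depth[s : s + ln] = 80
        exp = _track("exp", depth)
        ctrls = [
            _track("c1", rng.poisson(2, size=8000)),
            _track("c2", rng.poisson(2, size=8000)),
        ]
        regions = [_iv(500, 7500)]
        return exp, ctrls, regions

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_boundaries_equal_brute_force_oracle(self, seed):
        exp, ctrls, regions = self._fixture(seed)
        peaks = detect_hotspots(exp, ctrls, regions, min_len=100, fold=5)
        expected = brute_force_peaks(exp, ctrls, regions, 100, 5)
        got = [(p.interval.chrom, p.interval.start, p.interval.end) for p in peaks]
        assert got == expected
        assert expected, "oracle found no peaks; fixture is vacuous"

    def test_qualifying_run_of_90_bp_is_not_a_peak(self):
        arr = np.full(10_000, 10)
        arr[4000:4090] = 60
        exp = _track("exp", arr)
        ctrls = [_track("c", np.full(10_000, 6)), _track("m", np.full(10_000, 6))]
        assert detect_hotspots(exp, ctrls, [_iv(0, 10_000)]) == []

    def test_120_bp_run_is_exactly_one_peak_with_exact_bounds(self):
        arr = np.full(10_000, 10)
        arr[4000:4120] = 60
        exp = _track("exp", arr)
        ctrls = [_track("c", np.full(10_000, 6)), _track("m", np.full(10_000, 6))]
        peaks = detect_hotspots(exp, ctrls, [_iv(0, 10_000)])
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.interval.start, p.interval.end) == (4000, 4120)
        assert p.mean_exp == 60.0
        assert p.control_sum_max == 12.0

    def test_flat_track_yields_nothing(self):
        exp = _track("exp", np.full(5000, 10))
        ctrls = [_track("c", np.full(5000, 10))]
        assert detect_hotspots(exp, ctrls, [_iv(0, 5000)]) == []

    def test_zero_baseline_is_an_error(self):
        exp = _track("exp", np.zeros(5000))
        with pytest.raises(ValueError):
            detect_hotspots(exp, [], [_iv(0, 5000)])

    def test_max_len_option_drops_long_runs(self):
        arr = np.full(10_000, 10)
        arr[4000:4500] = 200
        exp = _track("exp", arr)
        ctrls = [_track("c", np.full(10_000, 6))]
        assert detect_hotspots(exp, ctrls, [_iv(0, 10_000)], max_len=300) == []


class TestClassifyPeak:
    @pytest.fixture(scope="class")
    @staticmethod
    def library():
        rng = np.random.default_rng(31)
        return {
            "RLG_Cereba": random_dna(rng, 3000),
            "RLG_Quinta": random_dna(rng, 2000),
        }

    def test_exact_fragment_classifies_with_identity_one(self, library):
        peak = library["RLG_Cereba"][500:600]
        fam, ident = classify_peak(peak, library)
        assert fam == "RLG_Cereba" and ident == 1.0

    def test_reverse_complement_fragment_classifies(self, library):
        peak = revcomp(library["RLG_Quinta"][100:250])
        fam, _ = classify_peak(peak, library)
        assert fam == "RLG_Quinta"

    def test_low_identity_fragment_unclassified(self, library):
        """~65% identity over 95 bp misses the 70% identity threshold."""
        frag = list(library["RLG_Cereba"][500:595])
        for i in range(0, 95, 3):  # every third base mismatched
            frag[i] = "A" if frag[i] != "A" else "C"
        fam, ident = classify_peak("".join(frag), library)
        assert fam is None and ident is None

    def test_random_sequence_unclassified(self, library):
        rng = np.random.default_rng(32)
        fam, _ = classify_peak(random_dna(rng, 150), library)
        assert fam is None

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            classify_peak("ACGT" * 30, {})


class TestFamilyEnrichment:
    def test_peaks_per_mb(self):
        assert family_enrichment({"X": 10}, {"X": 1_000_000}) == {"X": 10.0}

    def test_doubling_bp_halves_density(self):
        one = family_enrichment({"X": 10}, {"X": 1_000_000})["X"]
        two = family_enrichment({"X": 10}, {"X": 2_000_000})["X"]
        assert two == one / 2

    def test_zero_bp_family_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            out = family_enrichment({"X": 10, "Y": 1}, {"X": 1_000_000, "Y": 0})
        assert "Y" not in out and "X" in out


def _make_copy(chrom="chr1", start=100, length=300, strand="+"):
    return FullLengthCopy(
        id="p1",
        family="F",
        interval=GenomicInterval(chrom, start, start + length, strand),
        ltr5=GenomicInterval(chrom, start, start + 50, strand)
        if strand == "+"
        else GenomicInterval(chrom, start + length - 50, start + length, strand),
        ltr3=GenomicInterval(chrom, start + length - 50, start + length, strand)
        if strand == "+"
        else GenomicInterval(chrom, start, start + 50, strand),
    )


class TestProjection:
    def setup_method(self):
        rng = np.random.default_rng(41)
        self.consensus = random_dna(rng, 300)
        self.rng = rng

    def _genome_track(self, copy_seq, start=100, depth_val=10):
        genome = random_dna(self.rng, start) + copy_seq + random_dna(self.rng, 100)
        track = _track("exp", np.full(len(genome), depth_val))
        return genome, track

    def test_identical_copy_uniform_depth(self):
        copy = _make_copy(length=300)
        _, track = self._genome_track(self.consensus)
        aln = local_align(self.consensus, self.consensus)
        prof = project_coverage(copy, aln, track, 300)
        assert np.array_equal(prof, np.full(300, 10.0))

    def test_insertion_depth_is_discarded(self):
        """A 50 bp insertion at uniform depth 10: total projected depth is
        10 * (copy length - 50)."""
        copy_seq = self.consensus[:150] + random_dna(self.rng, 50) + self.consensus[150:]
        copy = _make_copy(length=len(copy_seq))
        _, track = self._genome_track(copy_seq)
        aln = local_align(copy_seq, self.consensus, gap_open=50, gap_extend=0.1)
        prof = project_coverage(copy, aln, track, 300)
        assert prof.sum() == 10.0 * (len(copy_seq) - 50)

    def test_deleted_consensus_columns_get_nothing(self):
        copy_seq = self.consensus[:200] + self.consensus[250:]
        copy = _make_copy(length=len(copy_seq))
        _, track = self._genome_track(copy_seq)
        aln = local_align(copy_seq, self.consensus, gap_open=50, gap_extend=0.1)
        prof = project_coverage(copy, aln, track, 300)
        # exactly 50 consensus columns receive nothing (gap placement at
        # chance-matching edges may shift by a base or two)
        assert (prof == 0).sum() == 50
        assert (prof[202:248] == 0).all()
        assert prof.sum() == 10.0 * len(copy_seq)

    def test_minus_strand_projected_in_consensus_orientation(self):
        """Depth over a minus-strand copy lands on the consensus 5'->3'."""
        copy = _make_copy(length=300, strand="-")
        genome_seq = revcomp(self.consensus)  # genome carries the rc
        _, track = self._genome_track(genome_seq)
        # gradient depth so orientation errors are visible
        track.depth["chr1"][:] = 0
        track.depth["chr1"][100:400] = np.arange(300)
        aln = local_align(self.consensus, self.consensus)
        prof = project_coverage(copy, aln, track, 300)
        assert np.array_equal(prof, np.arange(300)[::-1])

    def test_chromosome_mismatch_is_an_error(self):
        copy = _make_copy(chrom="chr2")
        track = _track("exp", np.full(1000, 5))
        aln = local_align(self.consensus, self.consensus)
        with pytest.raises(ValueError):
            project_coverage(copy, aln, track, 300)

    def test_depth_conservation_invariant(self):
        """Summed projected depth equals genomic depth over the copy minus
        the depth over insertion bases, on a random track."""
        copy_seq = self.consensus[:100] + random_dna(self.rng, 30) + self.consensus[100:]
        copy = _make_copy(length=len(copy_seq))
        genome, _ = self._genome_track(copy_seq)
        track = _track("exp", self.rng.poisson(8, size=len(genome) + 200))
        aln = local_align(copy_seq, self.consensus, gap_open=50, gap_extend=0.1)
        prof = project_coverage(copy, aln, track, 300)
        s, e = copy.interval.start, copy.interval.end
        total = track.depth["chr1"][s:e].sum()
        ins = track.depth["chr1"][s + 100 : s + 130].sum()
        assert prof.sum() == total - ins


class TestCompileProfile:
    def test_single_copy_profile_is_its_projection(self):
        proj = np.arange(10.0)
        profiles, _ = compile_profile({"CENH3": [proj]}, "F")
        assert np.array_equal(profiles["CENH3"].depth, proj)
        assert profiles["CENH3"].copy_count == 1

    def test_sums_are_additive_and_ratio_uses_pseudocount(self):
        a, b = np.full(5, 3.0), np.full(5, 7.0)
        mock = np.full(5, 4.0)
        profiles, ratio = compile_profile(
            {"CENH3": [a, b], "CENH3_mock": [mock]}, "F", mock_experiment="CENH3_mock"
        )
        assert np.array_equal(profiles["CENH3"].depth, a + b)
        assert np.allclose(ratio, (a + b) / (mock + 1.0))

    def test_empty_projections_rejected(self):
        with pytest.raises(ValueError):
            compile_profile({"CENH3": []}, "F")
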
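"""CENH3 hot-spot detection and consensus-coordinate coverage projection.

Hot spots are maximal runs of bases, inside the supplied regions, where
the experimental depth is at least ``fold`` times the region-average
baseline AND at least ``fold`` times the per-base sum of all control and
mock tracks; runs shorter than ``min_len`` bp are discarded.  The
baseline is computed once per region set (centromeres and the control
chromosome arm are screened with their own averages).

Peaks are assigned to a TE family when their best local alignment
against a family library reaches >= 90 bp and >= 70% identity.  Family
peak counts can be normalised to annotated family bp (peaks per Mb).

For consensus profiles, the per-base genomic depth over each annotated
copy is transferred through the copy-to-consensus alignment: copy bases
in insertions contribute nothing, deleted consensus columns receive
nothing, and minus-strand copies are projected in consensus orientation.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .align import GAP, PairwiseAlignment, local_align
from .models import (
    ConsensusCoverageProfile,
    CoverageTrack,
    FullLengthCopy,
    GenomicInterval,
    HotspotPeak,
    revcomp,
)

logger = logging.getLogger(__name__)


def _region_mask(
    track: CoverageTrack, regions: Sequence[GenomicInterval]
) -> dict[str, np.ndarray]:
    masks: dict[str, np.ndarray] = {}
    for r in regions:
        if r.chrom not in track.depth:
            raise ValueError(f"region chromosome {r.chrom} not in track")
        arr = track.depth[r.chrom]
        if r.end > arr.size:
            raise ValueError(f"region {r} outside track bounds")
        masks.setdefault(r.chrom, np.zeros(arr.size, dtype=bool))[r.start : r.end] = True
    return masks


def region_average(
    track: CoverageTrack, regions: Sequence[GenomicInterval]
) -> float:
    """Mean depth over the union of regions (each base counted once)."""
    if not regions:
        raise ValueError("empty region set")
    masks = _region_mask(track, regions)
    total = sum(track.depth[c][m].sum() for c, m in masks.items())
    n = sum(int(m.sum()) for m in masks.values())
    return float(total) / n


def detect_hotspots(
    exp: CoverageTrack,
    controls: Sequence[CoverageTrack],
    regions: Sequence[GenomicInterval],
    min_len: int = 100,
    fold: float = 5.0,
    max_len: Optional[int] = None,
) -> list[HotspotPeak]:
    """Maximal qualifying runs of enriched bases within the regions.

    A base qualifies when ``exp >= fold * baseline`` and
    ``exp >= fold * sum(controls)`` at that base; runs of at least
    ``min_len`` qualifying bases become peaks.  ``max_len`` optionally
    discards longer runs.
    """
    baseline = region_average(exp, regions)
    if baseline <= 0:
        raise ValueError("degenerate track: zero baseline coverage")
    masks = _region_mask(exp, regions)
    peaks: list[HotspotPeak] = []
    for chrom, mask in masks.items():
        depth = exp.depth[chrom].astype(np.float64)
        ctrl_sum = np.zeros_like(depth)
        for c in controls:
            if chrom not in c.depth:
                raise ValueError(f"control {c.label} missing chromosome {chrom}")
            ctrl_sum += c.depth[chrom]
        ok = (depth >= fold * baseline) & (depth >= fold * ctrl_sum) & mask
        # maximal runs of True
        padded = np.diff(np.r_[0, ok.view(np.int8), 0])
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        for s, e in zip(starts, ends):
            if e - s < min_len or (max_len is not None and e - s > max_len):
                continue
            seg = depth[s:e]
            peaks.append(
                HotspotPeak(
                    interval=GenomicInterval(chrom, int(s), int(e)),
                    mean_exp=float(seg.mean()),
                    baseline=baseline,
                    fold_over_baseline=float(seg.mean() / baseline),
                    control_sum_max=float(ctrl_sum[s:e].max()),
                )
            )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


def classify_peak(
    peak_seq: str,
    te_library: dict[str, str],
    min_len: int = 90,
    min_identity: float = 0.70,
) -> tuple[Optional[str], Optional[float]]:
    """Best TE-family assignment of a peak sequence, or (None, None).

    A family qualifies when its best local alignment with the peak spans
    at least ``min_len`` columns at >= ``min_identity`` identity; ties go
    to the higher identity, then the alphabetically first family.
    """
    if not te_library:
        raise ValueError("empty TE library")
    best: Optional[tuple[float, str]] = None
    for name in sorted(te_library):
        seq = te_library[name]
        for query in (peak_seq, revcomp(peak_seq)):  # both strands, as blastn would
            try:
                aln = local_align(query, seq, method="dp")
            except ValueError:
                continue
            if aln.n_columns >= min_len and aln.identity >= min_identity:
                if best is None or aln.identity > best[0]:
                    best = (aln.identity, name)
    if best is None:
        return None, None
    return best[1], best[0]


def family_enrichment(
    peak_counts: dict[str, int], family_genomic_bp: dict[str, int]
) -> dict[str, float]:
    """Peaks per Mb of annotated family sequence."""
    out: dict[str, float] = {}
    for fam, count in peak_counts.items():
        bp = family_genomic_bp.get(fam, 0)
        if bp <= 0:
            logger.warning("family %s has no annotated bp; excluded", fam)
            continue
        out[fam] = count / (bp / 1e6)
    return out


def project_coverage(
    copy: FullLengthCopy,
    aln: PairwiseAlignment,
    track: CoverageTrack,
    consensus_length: int,
) -> np.ndarray:
    """Transfer per-base genomic depth onto consensus coordinates.

    ``aln`` aligns the copy's element sequence (5'->3' orientation, row
    a) to the family consensus (row b).  Depth at copy bases inside
    insertions is discarded; deleted consensus columns get nothing.
    """
    if copy.interval.chrom not in track.depth:
        raise ValueError(
            f"track {track.label} has no chromosome {copy.interval.chrom}"
        )
    genomic = track.depth[copy.interval.chrom][
        copy.interval.start : copy.interval.end
    ].astype(np.float64)
    if copy.strand == "-":
        genomic = genomic[::-1]  # index 0 = element 5' end
    profile = np.zeros(consensus_length, dtype=np.float64)
    pos_copy = aln.start_a
    pos_cons = aln.start_b
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if y == GAP:  # copy insertion: depth discarded
            pos_copy += 1
            continue
        if x == GAP:  # deletion in copy: consensus column gets nothing
            pos_cons += 1
            continue
        profile[pos_cons] += genomic[pos_copy]
        pos_copy += 1
        pos_cons += 1
    return profile


def compile_profile(
    projections: dict[str, list[np.ndarray]],
    family: str,
    mock_experiment: Optional[str] = None,
    pseudocount: float = 1.0,
) -> tuple[dict[str, ConsensusCoverageProfile], Optional[np.ndarray]]:
    """Sum per-copy projections per experiment; optionally a ratio profile.

    ``projections`` maps experiment label -> list of per-copy consensus
    profiles.  If ``mock_experiment`` is given, the ratio profile divides
    the first non-mock experiment by the mock plus a pseudocount.
    """
    if not projections or all(not v for v in projections.values()):
        raise ValueError("no projections")
    profiles: dict[str, ConsensusCoverageProfile] = {}
    for exp_label, arrs in projections.items():
        if not arrs:
            continue
        total = np.sum(arrs, axis=0)
        profiles[exp_label] = ConsensusCoverageProfile(
            family=family, experiment=exp_label, depth=total, copy_count=len(arrs)
        )
    ratio = None
    if mock_experiment is not None and mock_experiment in profiles:
        exp_labels = [l for l in profiles if l != mock_experiment]
        if exp_labels:
            ratio = profiles[exp_labels[0]].depth / (
                profiles[mock_experiment].depth + pseudocount
            )
    return profiles, ratio
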
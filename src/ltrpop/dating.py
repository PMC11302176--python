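"""Insertion dating from the divergence of a copy's two LTRs.

At insertion the 5' and 3' LTRs of a retrotransposon are identical; the
substitutions they accumulate afterwards are a molecular clock.  The two
LTRs are aligned locally (match +5, mismatch -4, gap open 10, gap extend
0.5), transitions (A<->G, C<->T) and transversions are counted over
ungapped columns, the proportions are corrected with the Kimura
two-parameter distance

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)),

and the age follows as T = d / (2 r) with a substitution rate r of
1.3e-8 substitutions per site per year for intergenic grass DNA (the
factor 2 because both LTRs diverge from their common initial state).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .align import PairwiseAlignment, local_align
from .models import AgeEstimate

GRASS_INTERGENIC_RATE = 1.3e-8  # substitutions / site / year

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = set("ACGT")


class SaturationError(ValueError):
    """Divergence too high for the two-parameter correction (log of <= 0)."""


def align_ltr_pair(
    ltr5: str,
    ltr3: str,
    match: float = 5,
    mismatch: float = -4,
    gap_open: float = 10,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Local alignment of a copy's two LTRs (Water-style affine scoring)."""
    if not ltr5 or not ltr3:
        raise ValueError("empty LTR sequence")
    return local_align(ltr5, ltr3, match, mismatch, gap_open, gap_extend)


def count_site_patterns(aln: PairwiseAlignment) -> tuple[int, int, int]:
    """(ungapped_sites, transitions, transversions) over alignment columns.

    Columns with a gap or an ambiguity code in either row are excluded.
    """
    sites = transitions = transversions = 0
    for x, y in zip(aln.aligned_a.upper(), aln.aligned_b.upper()):
        if x not in _BASES or y not in _BASES:
            continue
        sites += 1
        if x != y:
            if (x, y) in _TRANSITIONS:
                transitions += 1
            else:
                transversions += 1
    return sites, transitions, transversions


def k2p_distance(ungapped_sites: int, transitions: int, transversions: int) -> float:
    """Kimura two-parameter distance from site-pattern counts.

    Raises
    ------
    SaturationError
        If the observed proportions are outside the model's domain
        (1 - 2P - Q <= 0 or 1 - 2Q <= 0).
    """
    if ungapped_sites <= 0:
        raise ValueError("no ungapped sites")
    if transitions + transversions > ungapped_sites:
        raise ValueError("more differences than sites")
    p = transitions / ungapped_sites
    q = transversions / ungapped_sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"site patterns saturated (P={p:.3f}, Q={q:.3f})"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def date_insertion(distance: float, rate: float = GRASS_INTERGENIC_RATE) -> float:
    """Insertion age in years: T = d / (2 r)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return distance / (2.0 * rate)


def estimate_age(
    copy_id: str,
    ltr5: str,
    ltr3: str,
    rate: float = GRASS_INTERGENIC_RATE,
    min_ltr_coverage: float = 0.5,
    gap_open: float = 10,
    gap_extend: float = 0.5,
) -> AgeEstimate:
    """Full dating chain for one copy: align, count, correct, date.

    Copies whose LTR alignment covers less than ``min_ltr_coverage`` of the
    shorter LTR are rejected (partial alignments date a fragment, not the
    insertion).
    """
    aln = align_ltr_pair(ltr5, ltr3, gap_open=gap_open, gap_extend=gap_extend)
    aligned_bases = len(aln.aligned_a.replace("-", ""))
    if aligned_bases < min_ltr_coverage * min(len(ltr5), len(ltr3)):
        raise ValueError(
            f"{copy_id}: LTR alignment covers only "
            f"{aligned_bases}/{min(len(ltr5), len(ltr3))} bp"
        )
    sites, ts, tv = count_site_patterns(aln)
    d = k2p_distance(sites, ts, tv)
    return AgeEstimate(
        copy_id=copy_id,
        ungapped_sites=sites,
        transitions=ts,
        transversions=tv,
        distance=d,
        age=date_insertion(d, rate),
        rate=rate,
    )


def date_copies(
    copies_ltrs: Iterable[tuple[str, str, str]],
    rate: float = GRASS_INTERGENIC_RATE,
    min_ltr_coverage: float = 0.5,
) -> tuple[list[AgeEstimate], list[str]]:
    """Date many copies given (copy_id, ltr5_seq, ltr3_seq) triples.

    Returns the estimates and the ids of copies that could not be dated
    (saturated or insufficient alignment coverage).
    """
    estimates: list[AgeEstimate] = []
    failed: list[str] = []
    for copy_id, ltr5, ltr3 in copies_ltrs:
        try:
            estimates.append(
                estimate_age(copy_id, ltr5, ltr3, rate, min_ltr_coverage)
            )
        except (SaturationError, ValueError):
            failed.append(copy_id)
    return estimates, failed


def age_percentile_filter(
    ages: Sequence[float], percentile: float = 99.0
) -> np.ndarray:
    """Retain ages at or below the given empirical percentile.

    Used when displaying age distributions so that a handful of ancient
    (or saturated) outliers do not dominate the axis.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("no ages given")
    cutoff = np.percentile(ages, percentile)
    return ages[ages <= cutoff]
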
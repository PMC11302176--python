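"""Full-length retrotransposon discovery by paired-LTR scanning.

A full-length LTR retrotransposon is two similar LTRs in the same
orientation at roughly the distance expected from the family consensus,
with the family's internal coding region between them.  Discovery runs in
three stages:

1. LTR hit search — seed k-mer matches of the family LTR consensus (both
   orientations) are clustered into candidate loci and each candidate is
   verified by infix alignment (edlib) against identity and coverage
   thresholds.
2. Pairing — two same-strand hits whose span (5' LTR start to 3' LTR end)
   falls inside one of the family's size windows delimit a candidate
   element.  The span check is the operational "expected distance" rule.
3. CDS screen — the inter-LTR region must align to the family internal
   consensus; this discards LTR pairs found at the right distance by
   chance (host sequence or unrelated elements between them).

Overlapping candidates are resolved greedily by combined LTR alignment
score (ties to the leftmost start), so output is deterministic.  Copies
are then annotated with their flanking target-site duplications (TSDs);
recombinant or rearranged copies are removed by the TSD mismatch filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np

from .align import _kmer_codes, _encode
from .models import FamilyModel, FullLengthCopy, GenomicInterval, TSD_UNDEFINED, revcomp

logger = logging.getLogger(__name__)

_SEED_K = 16
_MIN_SEEDS = 3
_CLUSTER_TOL = 40  # bp; diagonal clustering tolerance (absorbs small indels)
_VERIFY_MARGIN = 100  # bp of slack around a candidate locus


@dataclass
class LTRHit:
    """One verified LTR consensus hit on the genome."""

    chrom: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float
    score: float  # matched bases estimate: len * identity


def _seed_candidate_starts(
    genome_kmers: np.ndarray, query: str, k: int = _SEED_K
) -> list[int]:
    """Candidate query-start positions from clustered seed diagonals."""
    q_codes = _kmer_codes(_encode(query), k)
    offsets: dict[int, int] = {}
    for off, code in enumerate(q_codes.tolist()):
        if code >= 0 and code not in offsets:
            offsets[code] = off
    mask = np.isin(genome_kmers, np.fromiter(offsets.keys(), dtype=np.int64))
    positions = np.flatnonzero(mask)
    diags = np.array(
        [p - offsets[int(genome_kmers[p])] for p in positions], dtype=np.int64
    )
    diags = np.sort(diags[diags >= 0])
    candidates: list[int] = []
    i = 0
    while i < diags.size:
        j = i
        while j + 1 < diags.size and diags[j + 1] - diags[j] <= _CLUSTER_TOL:
            j += 1
        if j - i + 1 >= _MIN_SEEDS:
            candidates.append(int(np.median(diags[i : j + 1])))
        i = j + 1
    return candidates


_POLISH_WINDOW = 30  # bp of terminal consensus used to polish hit boundaries
_POLISH_SHIFT = 6


def _polish_boundary(
    genome_seq: str, pos: int, ref_block: str, is_start: bool
) -> int:
    """Snap a hit boundary to the offset best matching the consensus end.

    Edit-distance endpoints wobble by a few bases when terminal bases are
    mutated or chance-match the flank; an ungapped comparison of the
    terminal consensus block at small shifts recovers the exact boundary.
    """
    w = len(ref_block)
    best_pos, best_m = pos, -1
    for d in sorted(range(-_POLISH_SHIFT, _POLISH_SHIFT + 1), key=lambda x: (abs(x), x)):
        p = pos + d
        s = p if is_start else p - w
        if s < 0 or s + w > len(genome_seq):
            continue
        m = sum(a == b for a, b in zip(genome_seq[s : s + w], ref_block))
        if m > best_m:
            best_m, best_pos = m, p
    return best_pos


def _verify_hit(
    chrom: str,
    genome_seq: str,
    cand_start: int,
    query: str,
    strand: str,
    min_identity: float,
    min_coverage: float,
) -> Optional[LTRHit]:
    L = len(query)
    lo = max(0, cand_start - _VERIFY_MARGIN)
    hi = min(len(genome_seq), cand_start + L + _VERIFY_MARGIN)
    window = genome_seq[lo:hi]
    res = edlib.align(query, window, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    identity = 1.0 - res["editDistance"] / L
    s, e = res["locations"][0]
    span = e + 1 - s
    coverage = min(span / L, 1.0)
    if identity < min_identity or coverage < min_coverage:
        return None
    start = _polish_boundary(genome_seq, lo + s, query[:_POLISH_WINDOW], True)
    end = _polish_boundary(genome_seq, lo + e + 1, query[-_POLISH_WINDOW:], False)
    if end - start < min_coverage * L:
        return None
    return LTRHit(
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        identity=identity,
        coverage=coverage,
        score=L * identity,
    )


def _dedupe_hits(hits: list[LTRHit]) -> list[LTRHit]:
    hits = sorted(hits, key=lambda h: (h.start, -h.score))
    out: list[LTRHit] = []
    for h in hits:
        if out and h.start < out[-1].end - (out[-1].end - out[-1].start) // 2:
            if h.score > out[-1].score:
                out[-1] = h
            continue
        out.append(h)
    return out


def find_ltr_hits(
    genome: dict[str, str],
    family: FamilyModel,
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
) -> list[LTRHit]:
    """All verified hits of the family LTR consensus, both strands."""
    hits: list[LTRHit] = []
    for chrom, seq in genome.items():
        genome_kmers = _kmer_codes(_encode(seq), _SEED_K)
        for strand, query in (
            ("+", family.ltr_consensus),
            ("-", revcomp(family.ltr_consensus)),
        ):
            for cand in _seed_candidate_starts(genome_kmers, query):
                hit = _verify_hit(
                    chrom, seq, cand, query, strand, min_identity, min_coverage
                )
                if hit is not None:
                    hits.append(hit)
    per_strand: list[LTRHit] = []
    for strand in "+-":
        per_strand.extend(_dedupe_hits([h for h in hits if h.strand == strand]))
    return sorted(per_strand, key=lambda h: (h.chrom, h.start))


def _cds_validates(
    genome_seq: str,
    inner_start: int,
    inner_end: int,
    family: FamilyModel,
    strand: str,
    min_identity: float,
) -> bool:
    """Screen the inter-LTR region against the internal consensus."""
    if inner_end <= inner_start:
        return False
    region = genome_seq[inner_start:inner_end]
    query = family.internal_consensus if strand == "+" else revcomp(
        family.internal_consensus
    )
    # seed-count quick reject: unrelated sequence shares essentially no
    # 16-mers with a multi-kb consensus
    region_kmers = set(_kmer_codes(_encode(region), _SEED_K).tolist())
    query_kmers = _kmer_codes(_encode(query), _SEED_K)
    shared = np.isin(query_kmers, np.fromiter(region_kmers, dtype=np.int64)).sum()
    if shared < 5:
        return False
    res = edlib.align(query, region, mode="HW", task="distance")
    if res["editDistance"] < 0:
        return False
    return 1.0 - res["editDistance"] / len(query) >= min_identity


def find_full_length_copies(
    genome: dict[str, str],
    family: FamilyModel,
    min_ltr_identity: float = 0.8,
    min_ltr_coverage: float = 0.8,
    cds_min_identity: float = 0.70,
) -> list[FullLengthCopy]:
    """Identify full-length copies of one family in a genome.

    Returns copies sorted by position, with ``cds_validated`` True for all
    of them (candidates failing the CDS screen are excluded) and TSD
    fields populated from the flanking sequence.
    """
    if not genome or all(not s for s in genome.values()):
        raise ValueError("empty genome")
    hits = find_ltr_hits(genome, family, min_ltr_identity, min_ltr_coverage)

    candidates: list[tuple[float, int, FullLengthCopy]] = []
    by_chrom_strand: dict[tuple[str, str], list[LTRHit]] = {}
    for h in hits:
        by_chrom_strand.setdefault((h.chrom, h.strand), []).append(h)

    for (chrom, strand), group in by_chrom_strand.items():
        group.sort(key=lambda h: h.start)
        seq = genome[chrom]
        max_window = max(hi for _, hi in family.size_windows)
        for i, first in enumerate(group):
            for second in group[i + 1 :]:
                span = second.end - first.start
                if span > max_window:
                    break
                if not family.in_window(span):
                    continue
                if not _cds_validates(
                    seq, first.end, second.start, family, strand, cds_min_identity
                ):
                    continue
                interval = GenomicInterval(chrom, first.start, second.end, strand)
                left = GenomicInterval(chrom, first.start, first.end, strand)
                right = GenomicInterval(chrom, second.start, second.end, strand)
                ltr5, ltr3 = (left, right) if strand == "+" else (right, left)
                copy = FullLengthCopy(
                    id="",  # assigned after overlap resolution
                    family=family.name,
                    interval=interval,
                    ltr5=ltr5,
                    ltr3=ltr3,
                    cds_validated=True,
                )
                candidates.append((first.score + second.score, interval.start, copy))

    # greedy overlap resolution: best combined LTR score first, leftmost ties
    candidates.sort(key=lambda t: (-t[0], t[1]))
    accepted: list[FullLengthCopy] = []
    for _, _, copy in candidates:
        iv = copy.interval
        if any(
            iv.chrom == c.interval.chrom
            and iv.start < c.interval.end
            and c.interval.start < iv.end
            for c in accepted
        ):
            continue
        accepted.append(copy)
    accepted.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    for idx, copy in enumerate(accepted, start=1):
        copy.id = f"{family.name}_{idx:04d}"
        tsd5, tsd3, mm = extract_tsd(copy, genome, family.tsd_length)
        copy.tsd5, copy.tsd3, copy.tsd_mismatches = tsd5, tsd3, mm
        assert family.in_window(copy.interval.length), "size window violated"
    logger.info(
        "%s: %d LTR hits -> %d candidates -> %d accepted copies",
        family.name,
        len(hits),
        len(candidates),
        len(accepted),
    )
    return accepted


def extract_tsd(
    copy: FullLengthCopy, genome: dict[str, str], tsd_length: Optional[int] = None
) -> tuple[str, str, int]:
    """Flanking TSD pair and their Hamming distance.

    Flanks are read on the forward genomic strand regardless of element
    strand: ``tsd5`` immediately left of the element, ``tsd3`` immediately
    right.  A flank truncated by the contig edge yields the sentinel
    :data:`ltrpop.models.TSD_UNDEFINED` mismatch count.
    """
    t = tsd_length if tsd_length is not None else max(len(copy.tsd5), 5)
    seq = genome[copy.interval.chrom]
    start, end = copy.interval.start, copy.interval.end
    if start - t < 0 or end + t > len(seq):
        return "", "", TSD_UNDEFINED
    tsd5 = seq[start - t : start]
    tsd3 = seq[end : end + t]
    mismatches = sum(a != b for a, b in zip(tsd5, tsd3))
    return tsd5, tsd3, mismatches


def filter_by_tsd(
    copies: Sequence[FullLengthCopy], max_mismatch: int = 1
) -> list[FullLengthCopy]:
    """Retain copies whose TSD pair differs at most ``max_mismatch`` bases.

    Copies with an undefined TSD (contig-edge truncation) are removed:
    their recombination status cannot be confirmed.
    """
    return [
        c
        for c in copies
        if c.tsd_mismatches != TSD_UNDEFINED and c.tsd_mismatches <= max_mismatch
    ]


def evaluate_discovery(
    found: Sequence[FullLengthCopy],
    truth_intervals: Sequence[GenomicInterval],
    tolerance: int = 5,
) -> tuple[float, float]:
    """(recall, precision) of found copies against truth coordinates.

    A found copy matches a truth interval if both boundaries agree within
    ``tolerance`` bp; each truth interval may be matched once.
    """
    unmatched = list(truth_intervals)
    tp = 0
    for c in found:
        for t in unmatched:
            if (
                c.interval.chrom == t.chrom
                and abs(c.interval.start - t.start) <= tolerance
                and abs(c.interval.end - t.end) <= tolerance
            ):
                unmatched.remove(t)
                tp += 1
                break
    recall = tp / len(truth_intervals) if truth_intervals else 1.0
    precision = tp / len(found) if found else 1.0
    return recall, precision
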
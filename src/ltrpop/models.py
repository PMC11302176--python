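"""Shared domain types for the centromeric retrotransposon pipeline.

Coordinates are 0-based half-open throughout the library; GFF3/VCF emit
1-based inclusive positions at the I/O boundary (see :mod:`ltrpop.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

DNA_ALPHABET = "ACGT"

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class FamilyModel:
    """A retrotransposon family: consensus sequences plus discovery windows.

    Parameters
    ----------
    name:
        Family label, e.g. ``RLG_Cereba``.
    ltr_consensus:
        Consensus of the long terminal repeat.
    internal_consensus:
        Consensus of the internal (inter-LTR) region.
    size_windows:
        Accepted full-length element sizes, measured from the start of the
        5' LTR to the end of the 3' LTR, as ``(min_bp, max_bp)`` pairs.
    tsd_length:
        Target-site duplication length in bp (5 for Gypsy elements).
    """

    name: str
    ltr_consensus: str
    internal_consensus: str
    size_windows: list[tuple[int, int]]
    tsd_length: int = 5

    def __post_init__(self) -> None:
        if not self.size_windows:
            raise ValueError(f"family {self.name}: size_windows empty")
        for lo, hi in self.size_windows:
            if not lo < hi:
                raise ValueError(
                    f"family {self.name}: malformed size window ({lo}, {hi})"
                )
        for label, seq in (
            ("ltr_consensus", self.ltr_consensus),
            ("internal_consensus", self.internal_consensus),
        ):
            if not seq or set(seq.upper()) - set("ACGTN"):
                raise ValueError(f"family {self.name}: {label} not DNA over ACGTN")
        if self.tsd_length < 2:
            raise ValueError(f"family {self.name}: tsd_length < 2")

    @property
    def element_consensus(self) -> str:
        """Full-length element consensus: LTR + internal + LTR."""
        return self.ltr_consensus + self.internal_consensus + self.ltr_consensus

    def in_window(self, length: int) -> bool:
        return any(lo <= length <= hi for lo, hi in self.size_windows)


# sentinel for a TSD that cannot be evaluated (contig edge)
TSD_UNDEFINED = -1


@dataclass
class FullLengthCopy:
    """One annotated full-length element copy in genomic coordinates."""

    id: str
    family: str
    interval: GenomicInterval
    ltr5: GenomicInterval
    ltr3: GenomicInterval
    tsd5: str = ""
    tsd3: str = ""
    tsd_mismatches: int = TSD_UNDEFINED
    cds_validated: bool = False

    def __post_init__(self) -> None:
        for ltr in (self.ltr5, self.ltr3):
            if not self.interval.contains(ltr):
                raise ValueError(f"copy {self.id}: LTR outside element interval")
            if ltr.strand != self.interval.strand:
                raise ValueError(f"copy {self.id}: LTR strand mismatch")
        if not (self.ltr5.end <= self.ltr3.start or self.ltr3.end <= self.ltr5.start):
            raise ValueError(f"copy {self.id}: overlapping LTRs")

    @property
    def strand(self) -> str:
        return self.interval.strand

    def element_sequence(self, genome: dict[str, str]) -> str:
        """Element sequence in 5'->3' element orientation."""
        seq = genome[self.interval.chrom][self.interval.start : self.interval.end]
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class AgeEstimate:
    """Insertion age derived from the divergence of a copy's two LTRs."""

    copy_id: str
    ungapped_sites: int
    transitions: int
    transversions: int
    distance: float
    age: float
    rate: float

    def __post_init__(self) -> None:
        if self.transitions + self.transversions > self.ungapped_sites:
            raise ValueError("more differences than ungapped sites")
        if self.distance < 0 or self.age < 0:
            raise ValueError("negative distance or age")


@dataclass
class VariantTable:
    """Copies x consensus-position variant matrix.

    ``genotypes[i, j]`` is the allele index of copy ``i`` at site ``j``:
    0 = reference (consensus) allele, 1.. = alternate alleles in ``alts``
    order, :data:`MISSING` (-1) = missing (deleted or unaligned).
    """

    consensus_id: str
    positions: np.ndarray  # consensus positions, 0-based, strictly increasing
    ref_alleles: list[str]
    alt_alleles: list[list[str]]
    genotypes: np.ndarray  # int8/int16, copies x sites
    copy_ids: list[str]
    maf: float = 0.01
    missing_cutoff: float = 0.90

    MISSING = -1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes)
        n, s = self.genotypes.shape
        if n != len(self.copy_ids) or s != len(self.positions):
            raise ValueError("genotype matrix shape mismatch")
        if s and np.any(np.diff(self.positions) <= 0):
            raise ValueError("site positions not strictly increasing")

    @property
    def n_copies(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def validate_site_bounds(self) -> None:
        """Assert the MAF and missingness bounds hold for every site."""
        g = self.genotypes
        for j in range(self.n_sites):
            col = g[:, j]
            obs = col[col != self.MISSING]
            miss_frac = 1 - obs.size / col.size
            if miss_frac > self.missing_cutoff:
                raise AssertionError(f"site {j}: missing fraction {miss_frac:.3f}")
            if obs.size == 0:
                raise AssertionError(f"site {j}: all missing")
            counts = np.bincount(obs)
            maf = 1 - counts.max() / obs.size
            if maf + 1e-12 < self.maf:
                raise AssertionError(f"site {j}: MAF {maf:.4f} < {self.maf}")


@dataclass
class PCAResult:
    """PCA of the numeric-encoded variant matrix."""

    coordinates: np.ndarray  # copies x components
    explained_variance: np.ndarray  # per component
    component_loadings: np.ndarray  # sites x components
    copy_ids: list[str] = field(default_factory=list)


@dataclass
class CoverageTrack:
    """Per-base read depth, one integer array per chromosome."""

    label: str
    depth: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.depth.items():
            arr = np.asarray(arr)
            if arr.ndim != 1 or (arr.size and arr.min() < 0):
                raise ValueError(f"{self.label}/{chrom}: invalid depth array")
            self.depth[chrom] = arr


@dataclass
class HotspotPeak:
    """A CENH3-enriched segment with its baseline statistics."""

    interval: GenomicInterval
    mean_exp: float
    baseline: float
    fold_over_baseline: float
    control_sum_max: float
    family: Optional[str] = None
    identity: Optional[float] = None


@dataclass
class ConsensusCoverageProfile:
    """Per-position depth summed over copies, in consensus coordinates."""

    family: str
    experiment: str
    depth: np.ndarray
    copy_count: int


@dataclass
class CentromereDefinition:
    """Centromere boundaries and midpoint on one chromosome."""

    chrom: str
    start: int
    end: int
    midpoint: Optional[float] = None

    def __post_init__(self) -> None:
        if self.midpoint is None:
            self.midpoint = 0.5 * (self.start + self.end)
        if not (self.start < self.midpoint < self.end):
            raise ValueError("midpoint outside centromere bounds")


@dataclass
class MantelResult:
    """Permutation test of association between two distance matrices."""

    statistic: float
    p_value: float
    permutations: int
    method: str = "spearman"

    def __post_init__(self) -> None:
        if not -1 - 1e-9 <= self.statistic <= 1 + 1e-9:
            raise ValueError("statistic outside [-1, 1]")
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value outside (0, 1]")
        if self.p_value < 1.0 / (self.permutations + 1) - 1e-15:
            raise ValueError("p-value below permutation resolution")
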
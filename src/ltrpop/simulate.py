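"""Synthetic genomes with implanted retrotransposons and known ground truth.

The generator emulates the structure of a centromeric chromosome region
populated by two Gypsy retrotransposon families: full-length copies with
5-bp target-site duplications (TSDs), per-copy LTR divergence consistent
with an assigned insertion age under a molecular clock, subfamily SNP
haplotypes, decoy solo LTRs / truncated copies / recombinants with broken
TSDs, and CENH3 ChIP coverage tracks with enrichment confined to LTR
segments.

Mutation model
--------------
Each family has a present-day element consensus.  Copies descend from a
single master lineage: a copy of age ``a`` inherits every master-lineage
mutation event whose time is younger than ``a`` (these are shared,
age-ordered differences from the consensus), and additionally acquires
private per-site substitutions with probability ``rate * a`` in each LTR
and in the internal region independently.  Master mutations in the LTR are
mirrored into both LTRs, so the divergence *between* a copy's two LTRs
comes from private mutations only and has expectation ``2 * rate * a`` per
site — the quantity the dating module estimates.  The shared master
history additionally makes copies of similar age genetically similar,
which is the structure behind the age-versus-position association tested
by the spatial module.

Transitions are drawn with probability ``ts_tv_ratio / (ts_tv_ratio + 1)``
per substitution event; transversions pick either alternative equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .models import (
    CentromereDefinition,
    CoverageTrack,
    FamilyModel,
    GenomicInterval,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

MIN_IMPLANT_GAP = 60  # bp of host sequence kept between implants


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic chromosome."""

    genome_length: int = 5_000_000
    chrom: str = "chr1"
    centromere_start: int = 1_500_000
    centromere_end: int = 3_500_000
    families: Optional[list[FamilyModel]] = None
    copies_per_family: int = 100
    subfamily_count: int = 3
    subfamily_diagnostic_sites: int = 20
    age_range: tuple[float, float] = (10_000.0, 2_500_000.0)
    substitution_rate: float = 1.3e-8
    ts_tv_ratio: float = 2.0
    age_position_gradient: bool = True
    decoy_solo_ltrs: int = 5
    decoy_truncated: int = 5
    decoy_recombinant: int = 5
    tsd_length: int = 5
    chip_enrichment_fold: float = 30.0
    chip_background_mean: float = 10.0
    chip_segment_length: int = 150
    chip_target_family: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        cen_len = self.centromere_end - self.centromere_start
        if not 0 < cen_len < self.genome_length:
            raise ValueError("genome_length > centromere length > 0 violated")
        if not 0 <= self.centromere_start < self.centromere_end <= self.genome_length:
            raise ValueError("centromere outside genome bounds")
        if self.age_range[0] < 0 or self.age_range[0] > self.age_range[1]:
            raise ValueError("invalid age_range")
        if self.substitution_rate <= 0:
            raise ValueError("substitution rate must be positive")
        if self.tsd_length < 2:
            raise ValueError("tsd_length must be >= 2")
        if self.chip_enrichment_fold < 1:
            raise ValueError("chip_enrichment_fold must be >= 1")

    def resolved_families(self, rng: np.random.Generator) -> list[FamilyModel]:
        return self.families if self.families is not None else default_families(rng)


@dataclass
class TruthCopy:
    """Ground truth for one implanted element (or decoy)."""

    id: str
    family: str
    interval: GenomicInterval
    ltr5: Optional[GenomicInterval]
    ltr3: Optional[GenomicInterval]
    tsd5: str
    tsd3: str
    true_age: float
    subfamily: Optional[str]
    is_decoy: bool
    decoy_type: Optional[str] = None  # solo_ltr | truncated | recombinant_tsd
    sequence: str = ""  # implanted sequence in genomic (forward) orientation


@dataclass
class TruthSet:
    """Everything the generator implanted, with true parameters."""

    copies: list[TruthCopy]
    enrichment_segments: list[tuple[str, int, int, float]]  # chrom, start, end, fold
    centromere: CentromereDefinition
    families: list[FamilyModel] = field(default_factory=list)

    def non_decoys(self, family: Optional[str] = None) -> list[TruthCopy]:
        return [
            c
            for c in self.copies
            if not c.is_decoy and (family is None or c.family == family)
        ]

    def decoys(self, decoy_type: Optional[str] = None) -> list[TruthCopy]:
        return [
            c
            for c in self.copies
            if c.is_decoy and (decoy_type is None or c.decoy_type == decoy_type)
        ]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def default_families(rng: np.random.Generator) -> list[FamilyModel]:
    """Two families mirroring the structure of RLG_Cereba and RLG_Quinta.

    The Cereba analogue is a 7,850 bp element (1,000 bp LTRs) selected in
    a 7,700-8,000 bp window; the Quinta analogue is a 4,400 bp element
    (550 bp LTRs) with the two size windows of that family.
    """
    return [
        FamilyModel(
            name="RLG_Cereba_syn",
            ltr_consensus=random_dna(rng, 1000),
            internal_consensus=random_dna(rng, 5850),
            size_windows=[(7700, 8000)],
            tsd_length=5,
        ),
        FamilyModel(
            name="RLG_Quinta_syn",
            ltr_consensus=random_dna(rng, 550),
            internal_consensus=random_dna(rng, 3300),
            size_windows=[(4300, 4500), (4700, 4800)],
            tsd_length=5,
        ),
    ]


def _substitute(base: str, ts_tv_ratio: float, rng: np.random.Generator) -> str:
    if rng.random() < ts_tv_ratio / (ts_tv_ratio + 1.0):
        return _TRANSITION[base]
    return _TRANSVERSIONS[base][rng.integers(2)]


def mutate_sequence(
    seq: str, per_site_prob: float, ts_tv_ratio: float, rng: np.random.Generator
) -> str:
    """Apply independent per-site substitutions with the given probability."""
    if per_site_prob <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < per_site_prob)
    for i in hits:
        arr[i] = _substitute(arr[i], ts_tv_ratio, rng)
    return "".join(arr)


def mutate_ltr_pair(
    ltr_consensus: str,
    age: float,
    rate: float,
    ts_tv_ratio: float,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Two independently mutated LTR copies; expected pairwise divergence
    approaches ``2 * rate * age`` per site."""
    p = rate * age
    return (
        mutate_sequence(ltr_consensus, p, ts_tv_ratio, rng),
        mutate_sequence(ltr_consensus, p, ts_tv_ratio, rng),
    )


@dataclass
class _MasterHistory:
    """Time-ordered shared mutation events for one family."""

    ltr_events: list[tuple[float, int, str]]  # (age of event, position, base)
    internal_events: list[tuple[float, int, str]]

    def sequences_at(self, age: float, family: FamilyModel) -> tuple[str, str]:
        ltr = list(family.ltr_consensus)
        for t, pos, base in self.ltr_events:
            if t < age:
                ltr[pos] = base
        internal = list(family.internal_consensus)
        for t, pos, base in self.internal_events:
            if t < age:
                internal[pos] = base
        return "".join(ltr), "".join(internal)


def _build_master_history(
    family: FamilyModel, config: SimulationConfig, rng: np.random.Generator
) -> _MasterHistory:
    age_max = config.age_range[1]

    def events(seq: str) -> list[tuple[float, int, str]]:
        n = rng.poisson(len(seq) * config.substitution_rate * age_max)
        out = []
        for _ in range(n):
            pos = int(rng.integers(len(seq)))
            out.append(
                (
                    float(rng.uniform(0, age_max)),
                    pos,
                    _substitute(seq[pos], config.ts_tv_ratio, rng),
                )
            )
        return sorted(out, reverse=True)  # oldest applied first

    return _MasterHistory(events(family.ltr_consensus), events(family.internal_consensus))


def _subfamily_haplotypes(
    family: FamilyModel, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, list[tuple[int, str]]]:
    """Diagnostic substitutions in the internal region, per subfamily."""
    k = config.subfamily_count
    n_sites = k * config.subfamily_diagnostic_sites
    positions = rng.choice(len(family.internal_consensus), size=n_sites, replace=False)
    haplotypes: dict[str, list[tuple[int, str]]] = {}
    for s in range(k):
        label = f"{family.name}_sub{s + 1}"
        block = positions[
            s * config.subfamily_diagnostic_sites : (s + 1)
            * config.subfamily_diagnostic_sites
        ]
        haplotypes[label] = [
            (int(p), _substitute(family.internal_consensus[p], config.ts_tv_ratio, rng))
            for p in block
        ]
    return haplotypes


@dataclass
class _Implant:
    family: FamilyModel
    kind: str  # full | solo_ltr | truncated | recombinant_tsd
    region: str  # centromere | arm
    sequence: str = ""  # element-oriented, filled later
    age: float = 0.0
    subfamily: Optional[str] = None
    strand: str = "+"
    ltr_len: int = 0  # LTR length within sequence (0 if absent)
    has_ltr3: bool = False


def _allocate(
    items: list[_Implant],
    region_start: int,
    region_end: int,
    tsd_len: int,
    rng: np.random.Generator,
) -> list[int]:
    """Non-overlapping start positions for implants within one region."""
    if not items:
        return []
    lengths = [len(it.sequence) for it in items]
    occupied = sum(lengths) + len(items) * (MIN_IMPLANT_GAP + 2 * tsd_len)
    free = (region_end - region_start) - occupied
    if free <= 0:
        raise ValueError(
            f"implant overflow: {sum(lengths)} bp of implants do not fit in "
            f"region [{region_start}, {region_end})"
        )
    cuts = np.sort(rng.uniform(0, free, size=len(items)))
    starts = []
    offset = region_start
    for cut_prev, cut, it in zip(np.r_[0.0, cuts[:-1]], cuts, items):
        offset += int(cut - cut_prev) + MIN_IMPLANT_GAP // 2 + tsd_len
        starts.append(offset)
        offset += len(it.sequence) + tsd_len + MIN_IMPLANT_GAP // 2
    return starts


def _age_for_position(
    pos: float, config: SimulationConfig, rng: np.random.Generator
) -> float:
    lo, hi = config.age_range
    if not config.age_position_gradient:
        return float(rng.uniform(lo, hi))
    mid = 0.5 * (config.centromere_start + config.centromere_end)
    max_dist = 0.5 * (config.centromere_end - config.centromere_start)
    u = min(abs(pos - mid) / max_dist, 1.0)
    age = (lo + (hi - lo) * u) * rng.normal(1.0, 0.08)
    return float(np.clip(age, lo, hi))


def generate_truth_set(
    config: SimulationConfig,
) -> tuple[dict[str, str], TruthSet]:
    """Build the genome and its ground truth. Deterministic for fixed seed."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 0])))
    families = config.resolved_families(rng)
    rate = config.substitution_rate

    masters = {f.name: _build_master_history(f, config, rng) for f in families}
    haplotypes = {f.name: _subfamily_haplotypes(f, config, rng) for f in families}

    # plan implants
    cen_items: list[_Implant] = []
    arm_items: list[_Implant] = []
    for fam in families:
        for _ in range(config.copies_per_family):
            cen_items.append(_Implant(fam, "full", "centromere"))
        for _ in range(config.decoy_recombinant):
            cen_items.append(_Implant(fam, "recombinant_tsd", "centromere"))
        for _ in range(config.decoy_solo_ltrs):
            arm_items.append(_Implant(fam, "solo_ltr", "arm"))
        for _ in range(config.decoy_truncated):
            arm_items.append(_Implant(fam, "truncated", "arm"))
    rng.shuffle(cen_items)
    rng.shuffle(arm_items)

    # provisional positions need sequence lengths; ages need positions.
    # Pass 1: assign placeholder lengths from family geometry.
    def nominal_length(it: _Implant) -> int:
        L_ltr = len(it.family.ltr_consensus)
        L_int = len(it.family.internal_consensus)
        if it.kind == "solo_ltr":
            return L_ltr
        if it.kind == "truncated":
            return L_ltr + int(0.6 * L_int)
        return 2 * L_ltr + L_int

    for it in cen_items + arm_items:
        it.sequence = "N" * nominal_length(it)

    cen_starts = _allocate(
        cen_items, config.centromere_start, config.centromere_end, config.tsd_length, rng
    )
    # arms: split decoys between the two chromosome arms
    left = [it for i, it in enumerate(arm_items) if i % 2 == 0]
    right = [it for i, it in enumerate(arm_items) if i % 2 == 1]
    left_starts = _allocate(left, 0, config.centromere_start, config.tsd_length, rng)
    right_starts = _allocate(
        right, config.centromere_end, config.genome_length, config.tsd_length, rng
    )
    placed = (
        list(zip(cen_items, cen_starts))
        + list(zip(left, left_starts))
        + list(zip(right, right_starts))
    )

    # Pass 2: realize sequences (ages depend on placement for the gradient)
    subfamily_labels = {f.name: sorted(haplotypes[f.name]) for f in families}
    for it, start in placed:
        fam = it.family
        mid = start + len(it.sequence) / 2
        it.age = _age_for_position(mid, config, rng)
        it.strand = "+" if rng.random() < 0.5 else "-"
        if it.kind in ("full", "recombinant_tsd"):
            labels = subfamily_labels[fam.name]
            if config.age_position_gradient:
                # subfamilies were active in different eras
                lo, hi = config.age_range
                idx = min(
                    int((it.age - lo) / max(hi - lo, 1) * len(labels)), len(labels) - 1
                )
                it.subfamily = labels[idx]
            else:
                it.subfamily = labels[int(rng.integers(len(labels)))]
        master_ltr, master_int = masters[fam.name].sequences_at(it.age, fam)
        if it.subfamily:
            internal = list(master_int)
            for pos, base in haplotypes[fam.name][it.subfamily]:
                internal[pos] = base
            master_int = "".join(internal)
        p = rate * it.age
        ltr_a = mutate_sequence(master_ltr, p, config.ts_tv_ratio, rng)
        it.ltr_len = len(fam.ltr_consensus)
        if it.kind == "solo_ltr":
            it.sequence = ltr_a
            it.has_ltr3 = False
        elif it.kind == "truncated":
            internal = mutate_sequence(master_int, p, config.ts_tv_ratio, rng)
            it.sequence = ltr_a + internal[: int(0.6 * len(internal))]
            it.has_ltr3 = False
        else:
            ltr_b = mutate_sequence(master_ltr, p, config.ts_tv_ratio, rng)
            internal = mutate_sequence(master_int, p, config.ts_tv_ratio, rng)
            it.sequence = ltr_a + internal + ltr_b
            it.has_ltr3 = True

    # genome assembly
    genome_arr = rng.choice(_BASES, size=config.genome_length)
    copies: list[TruthCopy] = []
    enrichment: list[tuple[str, int, int, float]] = []
    target_family = config.chip_target_family or families[0].name
    counter = 0
    for it, start in sorted(placed, key=lambda x: x[1]):
        counter += 1
        end = start + len(it.sequence)
        tsd = random_dna(rng, config.tsd_length)
        tsd5, tsd3 = tsd, tsd
        if it.kind == "recombinant_tsd":
            # break the 3' TSD at >= 2 positions
            broken = list(tsd)
            for pos in rng.choice(config.tsd_length, size=2, replace=False):
                broken[pos] = _substitute(broken[pos], 1.0, rng)
            tsd3 = "".join(broken)
        genomic_seq = it.sequence if it.strand == "+" else revcomp(it.sequence)
        genome_arr[start - config.tsd_length : start] = np.frombuffer(
            tsd5.encode(), dtype=np.uint8
        )
        genome_arr[start:end] = np.frombuffer(genomic_seq.encode(), dtype=np.uint8)
        genome_arr[end : end + config.tsd_length] = np.frombuffer(
            tsd3.encode(), dtype=np.uint8
        )

        L = it.ltr_len
        ltr5 = ltr3 = None
        if it.kind == "solo_ltr":
            ltr5 = GenomicInterval(config.chrom, start, end, it.strand)
        else:
            if it.strand == "+":
                ltr5 = GenomicInterval(config.chrom, start, start + L, "+")
                if it.has_ltr3:
                    ltr3 = GenomicInterval(config.chrom, end - L, end, "+")
            else:
                ltr5 = GenomicInterval(config.chrom, end - L, end, "-")
                if it.has_ltr3:
                    ltr3 = GenomicInterval(config.chrom, start, start + L, "-")
        is_decoy = it.kind != "full"
        copies.append(
            TruthCopy(
                id=f"truth_{counter:04d}",
                family=it.family.name,
                interval=GenomicInterval(config.chrom, start, end, it.strand),
                ltr5=ltr5,
                ltr3=ltr3,
                tsd5=tsd5,
                tsd3=tsd3,
                true_age=it.age,
                subfamily=it.subfamily,
                is_decoy=is_decoy,
                decoy_type=None if not is_decoy else it.kind,
                sequence=genomic_seq,
            )
        )
        if it.kind == "full" and it.family.name == target_family:
            # CENH3 enrichment segment centred in the element's 5' LTR
            off = (L - config.chip_segment_length) // 2
            if off >= 0:
                if it.strand == "+":
                    seg = (start + off, start + off + config.chip_segment_length)
                else:
                    seg = (end - off - config.chip_segment_length, end - off)
                enrichment.append(
                    (config.chrom, seg[0], seg[1], config.chip_enrichment_fold)
                )

    genome = {config.chrom: genome_arr.tobytes().decode()}
    truth = TruthSet(
        copies=copies,
        enrichment_segments=enrichment,
        centromere=CentromereDefinition(
            config.chrom, config.centromere_start, config.centromere_end
        ),
        families=families,
    )
    return genome, truth


def generate_chip_tracks(
    genome: dict[str, str], truth: TruthSet, config: SimulationConfig
) -> dict[str, CoverageTrack]:
    """Experimental, control and mock coverage tracks (integer, Poisson).

    The experimental track is elevated by ``chip_enrichment_fold`` inside
    the truth's enrichment segments; control and mock are background-only.
    """
    if config.chip_enrichment_fold < 1:
        raise ValueError("chip_enrichment_fold must be >= 1")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 1])))
    mean = config.chip_background_mean
    tracks: dict[str, CoverageTrack] = {}
    for label in ("CENH3", "control_input", "CENH3_mock"):
        depth = {}
        for chrom, seq in genome.items():
            arr = rng.poisson(mean, size=len(seq))
            if label == "CENH3":
                for c, s, e, fold in truth.enrichment_segments:
                    if c == chrom:
                        arr[s:e] = rng.poisson(mean * fold, size=e - s)
            depth[chrom] = arr.astype(np.int64)
        tracks[label] = CoverageTrack(label=label, depth=depth)
    return tracks
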
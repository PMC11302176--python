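"""End-to-end orchestration: simulate -> discover -> date -> popgen ->
ChIP hot spots -> spatial association, with artifacts and a run manifest.

Every stage is a thin call into the corresponding module; the pipeline
adds bookkeeping (per-stage counts, file outputs, seeds and thresholds
in one auditable place) and halts with the stage name on failure.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .models import (
    CentromereDefinition,
    FullLengthCopy,
    GenomicInterval,
    revcomp,
)
from .simulate import SimulationConfig, TruthSet, generate_chip_tracks, generate_truth_set
from . import chipseq, dating, discovery, io, popgen, spatial

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, at their standard defaults."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_ltr_identity: float = 0.8
    min_ltr_coverage: float = 0.8
    cds_min_identity: float = 0.70
    tsd_max_mismatch: int = 1
    rate: float = 1.3e-8
    maf: float = 0.01
    missing_cutoff: float = 0.90
    consensus_sample: int = 30
    hotspot_min_len: int = 100
    hotspot_fold: float = 5.0
    hotspot_max_len: Optional[int] = None
    classify_min_len: int = 90
    classify_min_identity: float = 0.70
    mantel_permutations: int = 9999
    age_display_percentile: float = 99.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("min_ltr_identity", 0, 1),
            ("min_ltr_coverage", 0, 1),
            ("cds_min_identity", 0, 1),
            ("maf", 0, 0.5),
            ("missing_cutoff", 0, 1),
            ("classify_min_identity", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.rate <= 0 or self.hotspot_fold < 1 or self.mantel_permutations < 1:
            raise ValueError("invalid threshold configuration")

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["families"] = (
            None
            if self.simulation.families is None
            else [f.name for f in self.simulation.families]
        )
        return {"version": __version__, "config": d}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage


def element_sequences(
    copies: list[FullLengthCopy], genome: dict[str, str]
) -> dict[str, str]:
    """Element sequences in 5'->3' orientation, keyed by copy id."""
    return {c.id: c.element_sequence(genome) for c in copies}


def run_pipeline(config: PipelineConfig, outdir: Optional[str] = None) -> dict:
    """Run the full analysis on a synthetic genome; return a report dict.

    The report holds in-memory results per stage plus ``counts`` (the
    stage funnel) and ``manifest``.  With ``outdir`` set, all artifacts
    (FASTA/GFF3/BED/bedGraph/VCF/TSV and the manifest) are written there.
    """
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"counts": {}, "manifest": config.manifest()}
    counts = report["counts"]

    def stage(name):
        logger.info("stage: %s", name)

    # ------------------------------------------------ simulate
    try:
        stage("simulate")
        genome, truth = generate_truth_set(config.simulation)
        tracks = generate_chip_tracks(genome, truth, config.simulation)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e
    report.update(genome=genome, truth=truth, tracks=tracks)
    counts["implanted_non_decoys"] = len(truth.non_decoys())
    counts["implanted_decoys"] = len(truth.decoys())
    if out:
        io.write_fasta(out / "genome.fa", genome)
        io.write_truth_gff3(out / "truth.gff3", truth)
        io.truth_table(truth).to_csv(out / "truth.tsv", sep="\t", index=False)
        for label, tr in tracks.items():
            io.write_bedgraph(out / f"track_{label}.bedgraph", tr)

    # ------------------------------------------------ discover + TSD filter
    try:
        stage("discover")
        found: dict[str, list[FullLengthCopy]] = {}
        filtered: dict[str, list[FullLengthCopy]] = {}
        for fam in truth.families:
            copies = discovery.find_full_length_copies(
                genome,
                fam,
                config.min_ltr_identity,
                config.min_ltr_coverage,
                config.cds_min_identity,
            )
            found[fam.name] = copies
            filtered[fam.name] = discovery.filter_by_tsd(
                copies, config.tsd_max_mismatch
            )
            counts[f"found_{fam.name}"] = len(copies)
            counts[f"tsd_passed_{fam.name}"] = len(filtered[fam.name])
    except Exception as e:  # noqa: BLE001
        raise StageError("discover", e) from e
    report.update(found=found, filtered=filtered)
    if out:
        all_found = [c for v in found.values() for c in v]
        io.write_copies_gff3(out / "copies.gff3", all_found)
        io.write_bed(
            out / "copies.bed",
            [c.interval for c in all_found],
            [c.id for c in all_found],
        )

    # ------------------------------------------------ date
    try:
        stage("date")
        ages: dict[str, list] = {}
        for fam in truth.families:
            triples = []
            for c in filtered[fam.name]:
                elem = c.element_sequence(genome)
                L = len(fam.ltr_consensus)
                triples.append((c.id, elem[:L], elem[-L:]))
            estimates, failed = dating.date_copies(triples, rate=config.rate)
            ages[fam.name] = estimates
            counts[f"dated_{fam.name}"] = len(estimates)
            counts[f"dating_failed_{fam.name}"] = len(failed)
    except Exception as e:  # noqa: BLE001
        raise StageError("date", e) from e
    report["ages"] = ages
    if out:
        rows = [
            dataclasses.asdict(est) for fam in ages for est in ages[fam]
        ]
        pd.DataFrame(rows).to_csv(out / "ages.tsv", sep="\t", index=False)

    # ------------------------------------------------ popgen
    try:
        stage("popgen")
        tables = {}
        pcas = {}
        consensi = {}
        distances = {}
        for fam in truth.families:
            seqs = element_sequences(filtered[fam.name], genome)
            if len(seqs) < 2:
                continue
            cons = popgen.build_consensus(
                seqs, sample_n=config.consensus_sample, seed=config.seed
            )
            consensi[fam.name] = cons
            table = popgen.call_variants(
                seqs,
                cons,
                maf=config.maf,
                missing_cutoff=config.missing_cutoff,
                consensus_id=f"{fam.name}_consensus",
            )
            tables[fam.name] = table
            counts[f"sites_{fam.name}"] = table.n_sites
            pcas[fam.name] = popgen.run_pca(table)
            distances[fam.name] = popgen.pairwise_snp_distance(table)
            if out:
                io.write_vcf(out / f"variants_{fam.name}.vcf", table, len(cons))
                coords = pcas[fam.name].coordinates
                pd.DataFrame(
                    coords,
                    index=table.copy_ids,
                    columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
                ).to_csv(out / f"pca_{fam.name}.tsv", sep="\t")
                io.write_distance_matrix(
                    out / f"snp_distance_{fam.name}.tsv",
                    distances[fam.name],
                    table.copy_ids,
                )
    except Exception as e:  # noqa: BLE001
        raise StageError("popgen", e) from e
    report.update(tables=tables, pcas=pcas, consensi=consensi, distances=distances)

    # ------------------------------------------------ ChIP hot spots
    try:
        stage("chip")
        cen = truth.centromere
        cen_regions = [GenomicInterval(cen.chrom, cen.start, cen.end)]
        exp = tracks["CENH3"]
        controls = [tracks[k] for k in tracks if k != "CENH3"]
        peaks = chipseq.detect_hotspots(
            exp,
            controls,
            cen_regions,
            min_len=config.hotspot_min_len,
            fold=config.hotspot_fold,
            max_len=config.hotspot_max_len,
        )
        # control screen on the left chromosome arm, with its own baseline
        arm_regions = [GenomicInterval(cen.chrom, 0, cen.start)]
        arm_peaks = chipseq.detect_hotspots(
            exp,
            controls,
            arm_regions,
            min_len=config.hotspot_min_len,
            fold=config.hotspot_fold,
            max_len=config.hotspot_max_len,
        )
        library = {f.name: f.element_consensus for f in truth.families}
        fam_counts: dict[str, int] = {}
        for p in peaks:
            seq = genome[p.interval.chrom][p.interval.start : p.interval.end]
            fam, ident = chipseq.classify_peak(
                seq, library, config.classify_min_len, config.classify_min_identity
            )
            p.family, p.identity = fam, ident
            if fam:
                fam_counts[fam] = fam_counts.get(fam, 0) + 1
        fam_bp = {
            f.name: sum(c.interval.length for c in filtered[f.name])
            for f in truth.families
        }
        enrichment = chipseq.family_enrichment(fam_counts, fam_bp)
        counts["hotspots_centromere"] = len(peaks)
        counts["hotspots_control_arm"] = len(arm_peaks)
        counts["hotspots_classified"] = sum(1 for p in peaks if p.family)

        # consensus coverage profiles for the CENH3 target family
        target = config.simulation.chip_target_family or truth.families[0].name
        projections: dict[str, list[np.ndarray]] = {"CENH3": [], "CENH3_mock": []}
        cons = consensi.get(target)
        if cons:
            for c in filtered[target]:
                aln = popgen.align_copy_to_consensus(c.element_sequence(genome), cons)
                for label in projections:
                    projections[label].append(
                        chipseq.project_coverage(c, aln, tracks[label], len(cons))
                    )
            profiles, ratio = chipseq.compile_profile(
                projections, target, mock_experiment="CENH3_mock"
            )
        else:
            profiles, ratio = {}, None
    except Exception as e:  # noqa: BLE001
        raise StageError("chip", e) from e
    report.update(
        peaks=peaks,
        arm_peaks=arm_peaks,
        family_enrichment=enrichment,
        profiles=profiles,
        profile_ratio=ratio,
    )
    if out:
        io.write_bed(
            out / "hotspots.bed",
            [p.interval for p in peaks],
            [p.family or "unclassified" for p in peaks],
        )
        pd.DataFrame(
            [
                {
                    "chrom": p.interval.chrom,
                    "start": p.interval.start,
                    "end": p.interval.end,
                    "mean_exp": p.mean_exp,
                    "fold": p.fold_over_baseline,
                    "family": p.family or "",
                    "identity": p.identity if p.identity is not None else "",
                }
                for p in peaks
            ]
        ).to_csv(out / "hotspots.tsv", sep="\t", index=False)
        if profiles:
            df = pd.DataFrame(
                {label: prof.depth for label, prof in profiles.items()}
            )
            if ratio is not None:
                df["ratio"] = ratio
            df.index.name = "consensus_pos"
            df.to_csv(out / f"profile_{target}.tsv", sep="\t")

    # ------------------------------------------------ spatial association
    try:
        stage("mantel")
        mantel_results = {}
        for fam in truth.families:
            if fam.name not in tables:
                continue
            table = tables[fam.name]
            id2copy = {c.id: c for c in filtered[fam.name]}
            positions = [id2copy[i].interval.midpoint for i in table.copy_ids]
            pos_matrix = spatial.positional_distance_matrix(positions, cen)
            mantel_results[fam.name] = spatial.mantel_test(
                distances[fam.name].astype(float),
                pos_matrix,
                permutations=config.mantel_permutations,
                seed=config.seed,
            )
            counts[f"mantel_n_{fam.name}"] = table.n_copies
    except Exception as e:  # noqa: BLE001
        raise StageError("mantel", e) from e
    report["mantel"] = mantel_results
    if out:
        pd.DataFrame(
            [
                {
                    "family": fam,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "permutations": r.permutations,
                    "method": r.method,
                }
                for fam, r in mantel_results.items()
            ]
        ).to_csv(out / "mantel.tsv", sep="\t", index=False)
        io.write_manifest(out / "manifest.json", {**report["manifest"], "counts": counts})

    return report
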
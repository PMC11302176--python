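"""Readers and writers for the pipeline's standard formats.

Internal coordinates are 0-based half-open everywhere; GFF3 and VCF are
emitted/parsed 1-based inclusive, BED and bedGraph 0-based half-open,
per each format's own convention.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    CoverageTrack,
    FamilyModel,
    FullLengthCopy,
    GenomicInterval,
    VariantTable,
)
from .simulate import TruthCopy, TruthSet

PathLike = Union[str, Path]


# --------------------------------------------------------------- FASTA

def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: PathLike, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------- GFF3

def _gff_attrs(pairs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs.items() if v != "")


def write_copies_gff3(path: PathLike, copies: Sequence[FullLengthCopy]) -> None:
    """Annotated full-length copies as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in copies:
            attrs = {
                "ID": c.id,
                "family": c.family,
                "ltr5": f"{c.ltr5.start + 1}-{c.ltr5.end}",
                "ltr3": f"{c.ltr3.start + 1}-{c.ltr3.end}",
                "tsd5": c.tsd5,
                "tsd3": c.tsd3,
                "tsd_mismatches": str(c.tsd_mismatches),
                "cds_validated": str(int(c.cds_validated)),
            }
            fh.write(
                "\t".join(
                    [
                        c.interval.chrom,
                        "ltrpop",
                        "LTR_retrotransposon",
                        str(c.interval.start + 1),
                        str(c.interval.end),
                        ".",
                        c.interval.strand,
                        ".",
                        _gff_attrs(attrs),
                    ]
                )
                + "\n"
            )


def read_copies_gff3(path: PathLike) -> list[FullLengthCopy]:
    copies: list[FullLengthCopy] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, _, start, end, _, strand, _, attr_s = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in attr_s.split(";") if "=" in kv)
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)

            def parse_range(s: str) -> GenomicInterval:
                a, b = s.split("-")
                return GenomicInterval(chrom, int(a) - 1, int(b), strand)

            copies.append(
                FullLengthCopy(
                    id=attrs["ID"],
                    family=attrs["family"],
                    interval=iv,
                    ltr5=parse_range(attrs["ltr5"]),
                    ltr3=parse_range(attrs["ltr3"]),
                    tsd5=attrs.get("tsd5", ""),
                    tsd3=attrs.get("tsd3", ""),
                    tsd_mismatches=int(attrs.get("tsd_mismatches", -1)),
                    cds_validated=bool(int(attrs.get("cds_validated", 0))),
                )
            )
    return copies


def write_truth_gff3(path: PathLike, truth: TruthSet) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in truth.copies:
            attrs = {
                "ID": c.id,
                "family": c.family,
                "true_age": f"{c.true_age:.1f}",
                "subfamily": c.subfamily or "",
                "tsd5": c.tsd5,
                "tsd3": c.tsd3,
                "is_decoy": str(int(c.is_decoy)),
                "decoy_type": c.decoy_type or "",
            }
            fh.write(
                "\t".join(
                    [
                        c.interval.chrom,
                        "ltrpop_sim",
                        "LTR_retrotransposon",
                        str(c.interval.start + 1),
                        str(c.interval.end),
                        ".",
                        c.interval.strand,
                        ".",
                        _gff_attrs(attrs),
                    ]
                )
                + "\n"
            )


def truth_table(truth: TruthSet) -> pd.DataFrame:
    rows = []
    for c in truth.copies:
        rows.append(
            {
                "id": c.id,
                "family": c.family,
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "strand": c.interval.strand,
                "true_age": c.true_age,
                "subfamily": c.subfamily or "",
                "is_decoy": int(c.is_decoy),
                "decoy_type": c.decoy_type or "",
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------- BED / bedGraph

def write_bed(path: PathLike, intervals: Sequence[GenomicInterval],
              names: Optional[Sequence[str]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region_{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bed(path: PathLike) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split()
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bedgraph(path: PathLike, track: CoverageTrack) -> None:
    """4-column bedGraph with run-length compressed intervals."""
    with open(path, "w") as fh:
        for chrom in sorted(track.depth):
            arr = track.depth[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.r_[0, change]
            ends = np.r_[change, arr.size]
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]}\n")


def read_bedgraph(
    path: PathLike, label: str, chrom_lengths: Optional[dict[str, int]] = None
) -> CoverageTrack:
    segments: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split()[:4]
            segments.setdefault(chrom, []).append((int(s), int(e), float(v)))
    depth: dict[str, np.ndarray] = {}
    for chrom, segs in segments.items():
        length = (
            chrom_lengths[chrom] if chrom_lengths else max(e for _, e, _ in segs)
        )
        arr = np.zeros(length, dtype=np.int64)
        for s, e, v in segs:
            arr[s:e] = int(round(v))
        depth[chrom] = arr
    return CoverageTrack(label=label, depth=depth)


# --------------------------------------------------------------- VCF

def write_vcf(path: PathLike, table: VariantTable, contig_length: int) -> None:
    """VCF 4.2 with the consensus as the contig and haploid genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={table.consensus_id},length={contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.copy_ids)
            + "\n"
        )
        for j in range(table.n_sites):
            alts = ",".join(table.alt_alleles[j]) or "."
            calls = [
                "." if g == VariantTable.MISSING else str(int(g))
                for g in table.genotypes[:, j]
            ]
            fh.write(
                "\t".join(
                    [
                        table.consensus_id,
                        str(int(table.positions[j]) + 1),
                        f"site{j + 1}",
                        table.ref_alleles[j],
                        alts,
                        ".",
                        "PASS",
                        ".",
                        "GT",
                    ]
                    + calls
                )
                + "\n"
            )


def read_vcf(path: PathLike, maf: float = 0.01, missing_cutoff: float = 0.90) -> VariantTable:
    """Parse a haploid single-contig VCF back into a VariantTable."""
    import pysam

    vf = pysam.VariantFile(str(path))
    copy_ids = list(vf.header.samples)
    positions: list[int] = []
    refs: list[str] = []
    alts: list[list[str]] = []
    rows: list[np.ndarray] = []
    consensus_id = None
    for rec in vf:
        consensus_id = rec.chrom
        positions.append(rec.pos - 1)
        refs.append(rec.ref)
        alts.append(list(rec.alts) if rec.alts else [])
        col = np.full(len(copy_ids), VariantTable.MISSING, dtype=np.int8)
        for i, sample in enumerate(copy_ids):
            gt = rec.samples[sample].get("GT")
            if gt and gt[0] is not None:
                col[i] = gt[0]
        rows.append(col)
    vf.close()
    genotypes = (
        np.stack(rows, axis=1) if rows else np.zeros((len(copy_ids), 0), dtype=np.int8)
    )
    return VariantTable(
        consensus_id=consensus_id or "consensus",
        positions=np.array(positions, dtype=np.int64),
        ref_alleles=refs,
        alt_alleles=alts,
        genotypes=genotypes,
        copy_ids=copy_ids,
        maf=maf,
        missing_cutoff=missing_cutoff,
    )


# --------------------------------------------------------------- TSV

def write_distance_matrix(path: PathLike, matrix: np.ndarray, ids: Sequence[str]) -> None:
    pd.DataFrame(matrix, index=list(ids), columns=list(ids)).to_csv(path, sep="\t")


def read_distance_matrix(path: PathLike) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_manifest(path: PathLike, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# --------------------------------------------------------------- family library

def load_family_library(fasta_path: PathLike, config_path: PathLike) -> list[FamilyModel]:
    """Validated family models from a consensus FASTA plus a YAML config.

    The config maps family names to the FASTA ids of their LTR and
    internal consensus and the size windows::

        families:
          RLG_Cereba:
            ltr: RLG_Cereba_LTR
            internal: RLG_Cereba_INT
            size_windows: [[7700, 8000]]
            tsd_length: 5
    """
    seqs = read_fasta(fasta_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not cfg or "families" not in cfg:
        raise ValueError("family config lacks a 'families' section")
    models: list[FamilyModel] = []
    for name, spec in cfg["families"].items():
        for key in ("ltr", "internal"):
            if spec.get(key) not in seqs:
                raise ValueError(
                    f"family {name}: FASTA id {spec.get(key)!r} ({key}) not found"
                )
        windows = [tuple(w) for w in spec["size_windows"]]
        models.append(
            FamilyModel(
                name=name,
                ltr_consensus=seqs[spec["ltr"]],
                internal_consensus=seqs[spec["internal"]],
                size_windows=windows,
                tsd_length=int(spec.get("tsd_length", 5)),
            )
        )
    return models
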
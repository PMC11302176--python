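"""Build the synthetic study: a 5 Mb chromosome with a 2 Mb centromere,
100 implanted copies of each of two retrotransposon families (Cereba- and
Quinta-like geometry), subfamily haplotypes, an age-position gradient,
decoy solo LTRs / truncated copies / TSD-broken recombinants, and CENH3
ChIP coverage tracks with LTR-confined enrichment.

Writes genome.fa, truth.gff3/tsv, families.fa/yaml, centromere.bed and
the three bedGraph tracks under results/.
"""

import argparse
from pathlib import Path

import yaml

from ltrpop import io
from ltrpop.models import GenomicInterval
from ltrpop.simulate import SimulationConfig, generate_chip_tracks, generate_truth_set


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--copies-per-family", type=int, default=100)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed, copies_per_family=args.copies_per_family)
    genome, truth = generate_truth_set(cfg)
    tracks = generate_chip_tracks(genome, truth, cfg)

    out = args.results
    out.mkdir(parents=True, exist_ok=True)
    io.write_fasta(out / "genome.fa", genome)
    io.write_truth_gff3(out / "truth.gff3", truth)
    io.truth_table(truth).to_csv(out / "truth.tsv", sep="\t", index=False)
    cen = truth.centromere
    io.write_bed(out / "centromere.bed",
                 [GenomicInterval(cen.chrom, cen.start, cen.end)], ["centromere"])
    for label, tr in tracks.items():
        io.write_bedgraph(out / f"track_{label}.bedgraph", tr)

    fam_seqs, fam_cfg = {}, {"families": {}}
    for f in truth.families:
        fam_seqs[f"{f.name}_LTR"] = f.ltr_consensus
        fam_seqs[f"{f.name}_INT"] = f.internal_consensus
        fam_cfg["families"][f.name] = {
            "ltr": f"{f.name}_LTR",
            "internal": f"{f.name}_INT",
            "size_windows": [list(w) for w in f.size_windows],
            "tsd_length": f.tsd_length,
        }
    io.write_fasta(out / "families.fa", fam_seqs)
    (out / "families.yaml").write_text(yaml.safe_dump(fam_cfg))

    n = len(truth.non_decoys())
    print(f"genome: {sum(len(s) for s in genome.values()):,} bp, seed {args.seed}")
    print(f"implanted {n} genuine copies and {len(truth.decoys())} decoys")
    print(f"enrichment segments (CENH3): {len(truth.enrichment_segments)}")
    print(f"artifacts under {out}/")


if __name__ == "__main__":
    main()
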
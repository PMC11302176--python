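# ltrpop

Population analysis of centromere-specific LTR retrotransposons.

Functional centromeres of Triticeae grasses are built largely from two
*Gypsy* retrotransposon families (the Cereba and Quinta type), whose
copies are bound by the centromeric histone variant CENH3 and whose
insertion history records how centromeres move. `ltrpop` implements the
full analysis chain for such element populations, aimed at researchers
studying transposable elements and centromere biology:

1. **Discovery** — full-length copies found as paired same-orientation
   LTR consensus hits whose span falls in a family size window
   (7,700–8,000 bp Cereba-type; 4,300–4,500 / 4,700–4,800 bp
   Quinta-type), validated by the internal coding sequence, and filtered
   by target-site duplication (TSD) concordance (max 1 mismatch in 5 bp)
   to exclude recombinant copies.
2. **Insertion dating** — the two LTRs of a copy are aligned (Water
   scoring: gap open 10, extend 0.5), transitions P and transversions Q
   are counted, corrected with the Kimura two-parameter distance
   `d = -1/2 ln((1-2P-Q)·sqrt(1-2Q))`, and dated as `T = d/(2r)` with
   `r = 1.3e-8` substitutions·site⁻¹·yr⁻¹.
3. **Population structure** — copies aligned to a 30-copy majority
   consensus (gap open 50, extend 0.1); variants at minor-allele
   frequency ≥ 1% (insertions ignored, deletions missing, 90% per-site
   missing cutoff) written as VCF, then PCA and pairwise SNP counts.
4. **CENH3 hot spots** — segments of ≥ 100 bp at ≥ 5× the region-average
   CENH3 coverage *and* ≥ 5× the summed control/mock coverage;
   classification to TE families at ≥ 90 bp / ≥ 70% identity;
   normalisation to peaks per Mb of family sequence; per-copy coverage
   projected onto the family consensus (insertions omitted).
5. **Spatial association** — Mantel test (Spearman, 9,999 permutations)
   between pairwise SNP counts and the positional difference
   `| |p_i - m| - |p_j - m| |` relative to the centromere midpoint `m`.

Because these analyses can only be validated where the truth is known,
the package includes a synthetic-genome generator that implants element
copies with known ages, subfamilies, TSDs, decoys and ChIP enrichment —
every stage is tested end-to-end against that ground truth.

## Worked example

The analysis is a chain of numbered scripts over the library (each can
be re-run independently; all state lives in `results/`):

```
python analysis/01_simulate_genome.py --seed 1 --copies-per-family 60
python analysis/02_discover_copies.py
python analysis/03_date_insertions.py
python analysis/04_population_structure.py
python analysis/05_cenh3_hotspots.py
python analysis/06_spatial_association.py
```

Output (seed 1):

```
genome: 5,000,000 bp, seed 1
implanted 120 genuine copies and 30 decoys
RLG_Cereba_syn: 65 full-length copies found (recall 1.000, precision 1.000); 60 pass the TSD filter
RLG_Quinta_syn: 65 full-length copies found (recall 1.000, precision 1.000); 60 pass the TSD filter
dated 120 copies (0 failed)
estimated age vs distance from midpoint: Spearman rho=0.945 (p=5.6e-59)
RLG_Cereba_syn: 60 copies x 5004 sites; PC1/PC2 explain 35%/15% of variance
RLG_Cereba_syn: k-means on PC1/2 recovers 3 subfamilies with purity 1.00
60 CENH3 hot spots in the centromere (mean size 150 bp); 60 classified to a TE family
RLG_Cereba_syn: CENH3/mock ratio peaks at consensus position 496 (5' LTR spans 0-1000), max ratio 33.6
RLG_Cereba_syn: Mantel r = 0.570, p = 0.0001 (9999 permutations); regression slope 316.7 SNPs/Mb
```

Reading this: each of the 65 per-family calls includes the 5 implanted
recombinant decoys, which the TSD filter then removes (60 remain —
exactly the genuine copies). Estimated ages reproduce the implanted
age-position gradient (older copies away from the midpoint). PCA
separates the three implanted subfamilies perfectly. All ChIP hot spots
fall in element LTRs and classify to the target family, and the
consensus-projected CENH3/mock ratio localises the binding region inside
the LTR. The Mantel test detects the positive association between
genetic and midpoint-relative physical distance at the permutation
floor (p = 1/10,000).

The same stages are available as a CLI (`ltrpop simulate|discover|date|
popgen|chip|mantel|run`) for use on external FASTA/GFF3/bedGraph inputs.

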
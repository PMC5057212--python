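# riboheat

Joint analysis of ribosome profiling (Ribo-Seq) and RNA-Seq for the plant
heat-stress response, as a tested, reusable Python library. It covers the
downstream computational steps of a two-condition (control vs prolonged
heat), two-replicate experiment on *Arabidopsis thaliana*-style data:

- **Quantification** — gene-level counting in transcript space (midpoint
  rule), rpm/rpkm normalisation, and a spike-in-based detection limit
  (least-squares fit of log observed rpkm vs log concentration over the
  upper ladder, walk-down to the lowest rung still on the line).
- **Differential regulation classes** — negative-binomial testing (DESeq
  lineage: median-of-ratios size factors, `var = μ + αμ²` with a
  cross-gene mean-dispersion trend, Wald test on log₂ fold change),
  Benjamini–Hochberg at FDR 0.1, then each gene is classed
  `both_up/down` (transcription and translation move together),
  `mrna_only_*` (transcript changes, footprints do not),
  `rpf_only_*` (purely translational), `discordant`, `unchanged` or
  `below_detection`.
- **RNA structure** — 39-nt sliding-window folding-energy profiles around
  start codons (energy assigned to the window centre; position 0 = first
  nucleotide of the ATG), group metaprofiles, and a Mann–Whitney
  comparison of per-gene mean energy over the 100 nt upstream of the
  start. Folding is an exact weighted pair-maximisation dynamic program
  (G-C=3, A-U=2, G-U=1, hairpin ≥ 3; reported negated, more negative =
  more stable) with an adapter seam for an external thermodynamic folder.
- **G-quadruplexes** — grammar scanner for G₂N₁₋₇G₂N₁₋₇G₂N₁₋₇G₂ (and the
  G3/G4 tiers), region stratification by hit start, footprint
  metaprofiles over 200 nt upstream / 250 nt downstream of each hit's
  first base with a Wilcoxon signed-rank condition comparison, fold-change
  association, and the 3′UTR half-reads check.
- **Alternative ORFs** — half-transcript symmetry screening (robust z on
  the first-half read fraction), single change-point localisation on
  coverage (two-segment least squares), in-frame ATG search near the
  change-point, translation to the stop with charged-residue fractions,
  and an AGAAnnTTCT heat-shock promoter-element scan.
- **Plastid stoichiometry** — protein production as footprint rpkm over
  the CDS (optionally per-operon-mRNA-normalised translational
  efficiency), audit of subunit production ratios against declared
  complex stoichiometries, disproportionality flagging under stress, and
  Spearman correlation against an external abundance table.
- **Synthetic data** — a first-class generator that plants every one of
  the above signals with known ground truth: regulation classes,
  A/U-rich low-structure 5′UTRs, quadruplex motifs with rejection-sampled
  negative backgrounds, an alternative-ORF gene (footprint step at CDS
  position 2195, 88-codon internal ORF), a 2-rpkm spike-in detection
  floor, and a 3:1:1:1 plastid operon.

## Worked example

`examples/` holds one short script per capability. For instance,
discovering the planted alternative ORF from simulated stress footprints
(`python examples/alternative_orf.py`):

```
11 asymmetry outliers in heat RPF (genes with planted 5'UTR quadruplex
footprint gains near the start codon also surface here); the strongest,
second-half-shifted one:
gene_id  first_fraction   robust_z   direction
  g0079        0.149555 -19.788658 second_half
  g0081        0.695029  10.923435  first_half
  g0100        0.670213   9.526210  first_half

g0079: footprint step at CDS position 2209 (ratio 12.0); planted at 2195
in-frame ATG at 2196; peptide 88 aa, 40% K+R vs 8% D+E
heat-shock element (AGAAnnTTCT) in the upstream kb at: [700]
```

Reading: gene g0079 puts only 15% of its stress footprints in the first
half of its CDS (robust z ≈ −20 against the cohort), the coverage step is
localised ~14 nt downstream of the planted position (read-length
smearing), the first in-frame ATG after it opens an 88-amino-acid ORF
rich in positively charged residues, and the upstream kilobase carries a
heat-shock factor binding element — together the signature of a
heat-induced alternative transcript/ORF.

The same pattern holds for the other scripts: `differential_classes.py`
prints the planted-vs-called class confusion matrix (≈94% recovery at a
4-fold effect and depth 500), `detection_limit.py` recovers thresholds
near the planted 2-rpkm floor, `quadruplex_scan.py` shows the stress
footprint elevation over 5′UTR quadruplexes (signed-rank p ≈ 1e-12), and
`plastid_stoichiometry.py` recovers 3:1:1:1 operon ratios within a few
percent and flags the subunit whose production was halved under heat.

## Command line

A thin CLI mirrors the library:

```
riboheat simulate --out ds --seed 1 --n-genes 300
riboheat count --annotation ds/annotation.gff3 --fasta ds/transcripts.fasta \
    --reads ds/reads_RNA_control_1.tsv ... --out counts.tsv
riboheat diffexpr --counts-mrna mrna.tsv --counts-rpf rpf.tsv --fdr 0.1 --out de.tsv
riboheat demo --out demo_out --seed 1      # full pipeline + summary.md
```

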
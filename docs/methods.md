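# Methods

This note documents the models and procedures `riboheat` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and counting

All internal coordinates are 0-based half-open in transcript (sense
strand) space; GFF3 (1-based closed) and bedGraph (0-based half-open)
are converted only at the I/O boundary. One transcript — the longest
annotated mRNA — represents each gene.

A read belongs to a region (5′UTR / CDS / 3′UTR) iff its midpoint,
`pos + length // 2`, falls inside the region's interval. Midpoint
assignment counts each read at most once, so region counts partition the
full-transcript count; boundary-straddling reads go to whichever side
holds the midpoint. No P-site offsetting is applied: the analyses here
operate at window scales (≥ 39 nt) where a fixed per-read offset cancels.

rpm = count / total·10⁶; rpkm = rpm / (length in kb). Spike-ins do not
map to the transcriptome and are excluded from gene denominators; their
own rpkm uses the gene-mapped total plus the spike-in reads.

## Spike-in detection limit

A least-squares line is fitted to log(observed rpkm) vs log(known
concentration) over the upper half of the ladder, where detection is
assumed linear. Walking down the ladder, the threshold is the observed
rpkm of the lowest rung whose residual stays within 2 × the fit's
residual SD; rungs below the detection floor drop out of the line by
multiple folds and are excluded robustly. Two estimator details matter
at ladder sizes of ~11 rungs: the residual SD is computed with a
degrees-of-freedom correction, and it is floored at 0.18 log-units
(~20%) — with only five high rungs the raw SD estimate can collapse far
below typical spike-in library variation, and a rung should not be
called off the line for departing by less than that. The walk-down
evaluates the whole ladder ("lowest rung within tolerance") rather than
stopping at the first violation, so a single noisy mid-rung cannot
truncate it. Genes whose rpkm is below the threshold in every sample
are flagged not reliably detected and excluded from differential
testing.

## Negative-binomial differential test

Counts are modelled as NB with variance `μ + αμ²`. Library sizes are
median-of-ratios size factors (geometric-mean reference, factors
rescaled to geometric mean 1). Fold changes are log₂ of normalized
condition means with a 0.5 pseudocount.

Dispersion: the per-gene pooled within-condition method-of-moments
estimate has only two residual degrees of freedom in a 2 × 2 design; a
Wald test built on it is severely anti-conservative (measured ~19% at
nominal 5% in the suite's simulations). The working dispersion is
therefore a cross-gene trend, `α(μ) = a₀ + a₁/μ`, fitted by least
squares to the per-gene moment estimates and floored at `α_floor =
10⁻⁸` — the same information-sharing idea the DESeq family uses. With
the trend dispersion, the Wald z statistic with a delta-method standard
error on the log₂ fold change is calibrated across the depths and
dispersions the acceptance test sweeps (type-I rate ~0.05). The trend
assumes most genes share a smooth mean-dispersion relationship; with
strong per-gene dispersion heterogeneity the test would under- or
over-cover for outlier genes (no per-gene shrinkage compromise is
attempted).

Classification at FDR `q` (default 0.1, BH within each assay): both
assays significant and co-directional → `both_*`; one assay → `mrna_only_*`
or `rpf_only_*`; both significant with opposite signs → `discordant`;
otherwise `unchanged`; genes failing detection → `below_detection`.

## Folding-energy profiles

The folding primitive maximises summed pair weights (G-C = 3, A-U = 2,
G-U = 1) over nested structures with a minimum hairpin loop of 3
unpaired nucleotides — an exactly solvable O(n³) dynamic program,
verified against exhaustive enumeration in the tests, not a
thermodynamic nearest-neighbour model. Group conclusions rest on
relative pair-richness contrasts, which this preserves; absolute
energies are in arbitrary units (negated pair score; more negative =
more stable). `fold_mfe(backend=...)` is the seam for substituting an
external thermodynamic folder, and profile outputs carry the backend
name. T is read as U.

Profiles fold a 39-nt window per centre position, assign the energy to
the centre, and span −150..+150 around the start codon by default
(window centres whose window crosses a transcript end are undefined).
The group statistic is the per-gene mean energy over [−100, 0); groups
are compared by a two-sided two-sample Mann–Whitney U (skipped below 3
genes per group).

## G-quadruplex scanning

The grammar is four G-runs of length ≥ tier (G2/G3/G4) separated by
1–7 nt loops. Matching is run-based: a maximal run of at least
tier-many Gs satisfies one run requirement and anchors at its first
position; loops are gaps between chosen runs (chains may skip over
intervening runs when the direct gap is ≤ 7). Each anchor yields at
most one hit, chosen lazily (nearest next run, with backtracking), so
counts are per-locus; `all_matches=True` enumerates every valid chain.
Run-based matching makes tier containment exact: a G4 anchor is always
a G3 and a G2 anchor. A hit's region is the region containing its first
base.

### Flank metaprofiles

For genes with a hit in a region class, per-position values over
[−200, +250) around the hit's first base are footprint rpm divided by
mRNA rpm (pseudocount 1 read, rpm-scaled), averaged per gene over its
hits, then averaged over genes with equal weight. Conditions are
compared by a two-sided Wilcoxon signed-rank test on the 450 paired
per-position values (all-zero differences → p = 1).

Four estimator choices make this paired test usable at small cohort
sizes (tens of genes), where the naive construction is grossly
anti-conservative under the null:

1. **5′-assigned footprint density**, not read-span coverage, is the
   per-position signal. Span coverage smears each read over ~30
   positions and autocorrelates the "independent" pairs (measured lag-1
   autocorrelation ≈ 0.96); single-position assignment is the
   ribosome-profiling convention and keeps positions independent.
2. **A condition-pooled mRNA denominator**, smoothed with a 31-nt
   running mean: one shared denominator divides both condition curves
   identically, so its sampling noise cancels exactly in their
   contrast. (mRNA coverage is locally smooth at read-length scale, so
   the smoothing loses no structure.)
3. **Per-gene baseline normalisation**: each gene's curve is divided by
   its own footprint/mRNA ratio over the transcript *excluding* the
   flank window, per condition. This removes the gene-level counting
   noise (NB dispersion) that is otherwise shared by all 450 positions
   of a gene — the dominant violation of pair independence in small
   cohorts — without letting a real elevation inside the window deflate
   its own baseline. Raw curves are available with
   `gene_normalize=False`.
4. The residual miscalibration scales as (test positions)/(baseline
   positions), so studies of positional footprint gain are best run on
   genes whose transcripts are long relative to the 450-nt window; the
   acceptance simulations use hosts with 6–7 kb CDSs, at which the
   null is calibrated (no-effect runs significant at the nominal rate)
   while planted elevations are detected at p ≪ 0.01.

Denominators use totals restricted to the compartment under study
(nuclear-mapped reads), since plastid footprint share shifts under heat
and would otherwise masquerade as a global nuclear effect. Both
per-position and cumulative-sum curves are emitted; tests run on
per-position values.

### Association and half-reads checks

Genes with a 5′UTR G2 hit are split by their footprint regulation
(significantly up vs unchanged/down at the chosen FDR) and the CDS
footprint log₂ fold-change distributions compared by Mann–Whitney. The
3′UTR check pairs each hit gene's first-half mRNA fraction between
conditions (Wilcoxon signed-rank); genes under the `min_reads` floor
(default 32, at which a ±0.25 departure from symmetry is binomially
detectable at p < 0.01) are excluded.

## Alternative-ORF discovery

The half-transcript symmetry statistic splits each CDS at
`floor(len/2)` (first half shorter on odd lengths). Outliers are genes
whose first-half fraction has robust z (median/1.4826·MAD, SD fallback)
beyond 4. The change-point is the split maximising the two-segment
least-squares gain on per-position coverage (equivalently maximal CUSUM
deviation); a step ratio within [1/1.5, 1.5] is flagged `no_step`.
Because coverage ramps over a read length at a true step, the estimate
sits ~10–15 nt downstream of the true 5′-density step; the in-frame ATG
search window of [−30, +60] around the change-point absorbs this. The
peptide is translated from that ATG to the first in-frame stop
(standard code) and its length counts the residues after the initiator
Met — an ATG immediately followed by a stop encodes length 0. Charged
fractions (K+R, D+E) are reported without a background test.

The promoter scan matches a consensus (default the plant heat-shock
element AGAAnnTTCT, N = wildcard) on both strands with an optional
mismatch budget. This consensus is its own reverse complement, so exact
occurrences report one row per strand. De-novo motif discovery is not
reimplemented; the UTR footprint-gain selector (rpm fold change ≥ 2 and
≥ 10 stress-condition reads in the UTR, over a caller-supplied candidate
universe) exports FASTA plus a YAML sidecar recording the downstream
MEME parameters (width 6–20, ≤ 10 motifs, zero-or-one site per
sequence).

## Plastid protein production and stoichiometry

Production is the average footprint density over the CDS (footprint
rpkm), treating each footprint as one protein equivalent — an upper
bound that ignores drop-off and degradation. A second mode divides by
mRNA rpkm (+0.5 rpkm pseudocount) as a translational-efficiency
variant; for polycistronic operons the mRNA rpkm is per-operon and
shared across its ORFs, so within-operon production ratios reflect
footprints only. Both columns are always emitted because the two
definitions coexist in practice; `rpf_rpkm` is the headline default.

The audit normalises subunit production to the lowest-stoichiometry
subunit, reports Spearman ρ between production and declared
stoichiometry per condition (ties in the declared integers bound ρ away
from 1 even for perfect data — exact proportionality with identical tie
structure still gives ρ = 1), and flags a complex disproportionate when
its subunit heat/control fold changes span more than 1.75-fold
(max/min). The threshold sits deliberately below a strict 2 so that a
subunit whose production halves — the canonical disproportionate
response — is flagged despite counting noise, while remaining far above
the ~10% spread of proportional complexes.

## The synthetic-data generator

The generator emulates the targeted study design: 2 conditions × 2
replicates × 2 assays, gene counts NB(μ, α) with α = 0.05 by default
(a typical bulk RNA-seq overdispersion; the underlying study gives no
replicate-variability number, so this is a free parameter), per-gene
baseline means lognormal around `depth` (default 200 reads/gene, σ =
0.5), per-sample library factors uniform in [0.8, 1.25], and read
lengths uniform 25–35 nt for both assays (gel-selected fragment range).
Regulation classes plant ±`lfc_effect` on the mRNA assay, the RPF
assay, or both; `rpf_lfc` in the ground truth is the *total* footprint
change (transcriptional × translational-efficiency components
combined). Read 5′ positions are multinomial over the transcript,
uniform except for three planted stress-RPF signals, all *net-positive*
(extra footprints over the planted window; baseline density elsewhere
preserved — a zero-sum redistribution would depress every non-window
position and invert flank comparisons):

- a step increase (default 12×) downstream of CDS position 2195 in the
  alternative-ORF gene, which is built with a first in-frame ATG at the
  change-point, an 88-codon ORF with ~40% K+R, a stop, a cleared ATG
  window upstream, and a planted AGAACGTTCT element at position 700 of
  its upstream kilobase;
- a 3× elevation over [−25, +75) around each planted UTR G2 quadruplex
  (motifs inserted into rejection-sampled match-free regions, with a
  whole-transcript recheck so boundary-spanning chains cannot leak into
  cleaned regions of background genes);
- plastid footprint densities proportional to declared complex
  stoichiometry (default one ATP-synthase-like complex with a 3:1:1:1
  operon and a second 1:1 operon), scaled 0.7× under heat with one
  subunit (atpE) additionally halved.

Plastid counts use near-Poisson dispersion (α = 10⁻³): the plastid
fraction is deeply sequenced and pooled over many plastids per cell, so
subunit ratios are technical-noise limited; mean-level biological
dispersion would cap ratio accuracy at ~20% regardless of depth and
contradict the stoichiometry-recovery behaviour the module targets.
Plastid singleton ORFs (default 54, lognormal density spread σ = 1)
stand in for the remaining chloroplast proteome in the abundance
correlation; the synthetic abundance table multiplies production by
lognormal noise with SD = 0.85 × sd(log production), a constant
calibrated once against the generator so that the production–abundance
Spearman ρ realises ≈ 0.75 at n = 60 — the concordance magnitude this
production proxy is expected to show against an orthogonal abundance
measurement.

Spike-ins (RNA samples only) form a 2-fold ladder (2⁻⁴…2⁶ units, one
unit ≡ 1 rpkm in expectation), with a planted 2-rpkm detection floor:
below it, expected rpkm falls as conc·(conc/floor)². Spike length
(150 kb) and a 12% technical CV are chosen so the ladder occupies a
realistic ~2% of a desk-scale library while the floor rung still
carries enough reads to be measurable; the floor-recovery mathematics
is scale-free.

What the generator does **not** emulate: genome space (introns,
splicing, multi-isoform genes, alignment ambiguity), sequencing errors
and adapter artifacts, positional biases (ramp effects, codon-level
pausing, periodicity), partial transcript degradation, and any coupling
between structure and expression beyond the planted compositions.
Passing tests therefore demonstrate that the estimators recover planted
effects under idealised noise of realistic magnitude — not that they
are robust to every artifact of real libraries.

## Problem sizes and determinism

Simulation sizes used by the tests and acceptance script (hundreds of
genes, depths of a few hundred reads per gene, tens of replicate runs)
were chosen as the smallest at which each planted effect is
comfortably identifiable by its estimator; all stochastic steps run
through seeded NumPy generators (distinct named substreams per stage),
and a fixed configuration reproduces byte-identical datasets and
reports.

## Known limitations

- The Wald/trend-dispersion test assumes a shared mean-dispersion
  trend; no outlier-robust or per-gene-shrinkage variant is provided.
- The folding model ranks pair-richness, not free energy; absolute
  values are not comparable to thermodynamic folders.
- Per-locus quadruplex counting reports one hit per anchoring G-run;
  overlapping alternative decompositions are available only via
  `all_matches`.
- The change-point model is single-step (binary segmentation depth 1).
- The flank-metaprofile signed-rank test treats positions as exchangeable
  pairs; its calibration degrades when transcripts are short relative to
  the 450-nt window (see above).
- The 2×2 design is the minimum the testing supports; power figures in
  the test suite do not transfer to other designs.
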
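"""Discover the planted alternative ORF from footprint coverage.

Pipeline: half-transcript symmetry screen flags the asymmetric gene ->
change-point localises the footprint step in its CDS -> the first
in-frame ATG near the step starts the alternative ORF -> translation to
the stop characterises the peptide. A heat-shock promoter element is
then searched in the 1-kb upstream region.
"""

from riboheat import orf, quantify
from riboheat.pipeline import pooled_coverage
from riboheat.simulate import (
    SimulationConfig, generate_transcriptome, simulate_counts_and_coverage,
)

cfg = SimulationConfig(seed=6, n_genes=200, depth=400.0)
models, truth = generate_transcriptome(cfg)
samples, _ = simulate_counts_and_coverage(models, truth, cfg)

rpf_heat = [s for s in samples if s.assay == "RPF" and s.condition == "heat"]
sym = quantify.half_symmetry(rpf_heat, models)
outliers = orf.asymmetry_outliers(sym).sort_values(
    "robust_z", key=lambda z: z.abs(), ascending=False
)
print(f"{len(outliers)} asymmetry outliers in heat RPF "
      "(genes with planted 5'UTR quadruplex footprint gains near the start "
      "codon also surface here); the strongest, second-half-shifted one:")
print(outliers.head(3)[["gene_id", "first_fraction", "robust_z", "direction"]]
      .to_string(index=False))

model_map = {m.gene_id: m for m in models}
cov, _ = pooled_coverage(samples, models, "RPF", "heat")
gid = outliers.iloc[0]["gene_id"]
m = model_map[gid]
cp = orf.find_changepoint(cov[m.transcript_id], region=m.cds)
call = orf.call_alt_orf(m, cp.position, step_ratio=cp.step_ratio)
print(f"\n{gid}: footprint step at CDS position {cp.position} "
      f"(ratio {cp.step_ratio:.1f}); planted at {truth.altorf['changepoint_cds']}")
print(f"in-frame ATG at {call.alt_start}; peptide {call.peptide_length} aa, "
      f"{call.positive_fraction:.0%} K+R vs {call.negative_fraction:.0%} D+E")

matches = orf.promoter_element_scan(m.upstream_region)
print(f"heat-shock element (AGAAnnTTCT) in the upstream kb at: "
      f"{sorted(set(matches['position']))}")
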
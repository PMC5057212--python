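"""Plastid protein production from footprint density and the complex
stoichiometry audit.

Production is estimated as footprint rpkm over each CDS (each footprint
taken as one protein made). The planted operon has 3:1:1:1 subunit
densities; under heat one subunit's production is additionally halved
and should be flagged disproportionate. A synthetic mass-spec-style
abundance table is compared by Spearman correlation.
"""

from riboheat import plastid, quantify
from riboheat.simulate import (
    SimulationConfig, generate_transcriptome, simulate_counts_and_coverage,
    simulate_abundance,
)

cfg = SimulationConfig(seed=7, n_genes=100, depth=300.0, plastid_depth=1700.0)
models, truth = generate_transcriptome(cfg)
samples, _ = simulate_counts_and_coverage(models, truth, cfg)

rpf = [s for s in samples if s.assay == "RPF"]
rna = [s for s in samples if s.assay == "RNA"]
cm_rpf = quantify.build_count_matrix(rpf, models, region="CDS")
cm_rna = quantify.build_count_matrix(rna, models, region="CDS")
prod = {
    cond: plastid.protein_production(
        cm_rpf, models, rna_counts=cm_rna,
        samples=[s.sample_id for s in rpf if s.condition == cond],
    )["production"]
    for cond in ("control", "heat")
}
rep = plastid.stoichiometry_audit(prod, truth.complexes)[0]
cols = ["stoichiometry", "expected_ratio", "ratio_control", "ratio_heat", "fold_change"]
print(rep.table[cols].round(2))
print(f"concordance (Spearman rho): {rep.concordance}")
print(f"disproportionate under heat: {rep.disproportionate}, "
      f"flagged: {rep.flagged_subunits}")

abundance = simulate_abundance(prod["control"], cfg)
out = plastid.abundance_correlation(prod["control"], abundance)
print(f"\nproduction vs abundance Spearman rho = {out['rho']:.3f} "
      f"over {out['n']} plastid proteins")
print("-> control ratios track the assembled stoichiometry; the heat "
      "column shows the planted disproportionate subunit")
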
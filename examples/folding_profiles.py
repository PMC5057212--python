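"""Folding-energy metaprofiles around start codons for gene groups.

The generator draws A/U-rich 5'UTRs for the translationally upregulated
group, mimicking selection for low secondary-structure propensity
upstream of the start codon. A 39-nt sliding window is folded with the
built-in pair-maximisation model; the group contrast tests the per-gene
mean energy over the 100 nt upstream of the start.
"""

from riboheat import structure
from riboheat.simulate import SimulationConfig, generate_transcriptome

cfg = SimulationConfig(
    seed=4, n_genes=80, altorf_gene=False,
    n_per_class={"rpf_only_up": 40, "null": 40},
    n_quadruplex_genes={}, n_plastid_singletons=0,
)
models, truth = generate_transcriptome(cfg)
model_map = {m.gene_id: m for m in models}
groups = {
    "translational_up": truth.low_structure_genes,
    "background": [g for g, c in truth.classes.items() if c == "null"],
}
profiles = {
    g: structure.window_mfe_profile(model_map[g], span=(-100, 20))
    for gs in groups.values() for g in gs
}
metas, report = structure.group_metaprofile(profiles, groups)
for name, meta in metas.items():
    upstream = meta.mean[meta.mean.index < 0]
    print(f"{name}: mean energy over [-100, 0) = {upstream.mean():.2f} "
          f"(n = {int(meta.n.max())} genes)")
print(report.to_string(index=False))
print("-> higher (less negative) energy upstream of the start codon means "
      "less stable structure; the planted contrast is recovered by the "
      "Mann-Whitney comparison")
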
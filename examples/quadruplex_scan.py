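"""Scan transcripts for G-quadruplex grammar hits and build the stress
footprint metaprofile around 5'UTR hits.

The grammar (tiers G2/G3/G4) is four G-runs separated by 1-7 nt loops.
Under simulated heat stress, extra ribosome footprints are planted over
the 5'UTR quadruplex windows; the metaprofile compares per-position
footprint/mRNA values between conditions with a Wilcoxon signed-rank test.
"""

import numpy as np

from riboheat import quadruplex as quad
from riboheat.pipeline import pooled_coverage
from riboheat.simulate import (
    SimulationConfig, generate_transcriptome, simulate_counts_and_coverage,
)

cfg = SimulationConfig(
    seed=5, n_genes=150, depth=600.0, altorf_gene=False,
    n_per_class={"null": 150}, n_quadruplex_genes={"UTR5": 30},
    utr5_len=(300, 400), cds_len=(6000, 7200), utr3_len=(300, 400),
    n_plastid_singletons=0,
)
models, truth = generate_transcriptome(cfg)
samples, _ = simulate_counts_and_coverage(models, truth, cfg)

hits = [h for m in models for h in quad.scan_quadruplexes(m, tiers=("G2", "G3"))]
table = quad.hits_table(hits)
print(table.groupby(["tier", "region"]).size().to_string())

rpf = {c: pooled_coverage(samples, models, "RPF", c, total_over="nuclear",
                          mode="density") for c in ("control", "heat")}
rna = {c: pooled_coverage(samples, models, "RNA", c, total_over="nuclear",
                          mode="density") for c in ("control", "heat")}
planted, seen = [], set()
for h in hits:
    if h.tier == "G2" and h.region == "UTR5" and h.gene_id in truth.quadruplexes \
            and h.gene_id not in seen:
        planted.append(h)
        seen.add(h.gene_id)
mp = quad.flank_metaprofile(
    planted, models,
    {c: rpf[c][0] for c in rpf}, {c: rna[c][0] for c in rna},
    {c: rpf[c][1] for c in rpf}, {c: rna[c][1] for c in rna},
)
window = slice(quad.FLANK_UP - 25, quad.FLANK_UP + 75)
print(f"\n5'UTR G2 metaprofile over {mp.n_genes} genes:")
print(f"  mean value over the quadruplex window: "
      f"heat {np.nanmean(mp.mean_heat[window]):.2f} vs "
      f"control {np.nanmean(mp.mean_control[window]):.2f}")
print(f"  signed-rank p = {mp.pvalue:.2e}")
print("-> footprint accumulation over the quadruplex under heat, absent "
      "from the control curve")
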
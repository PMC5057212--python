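"""End-to-end orchestration over a simulated dataset: simulate -> count ->
differential classes -> structure -> quadruplex -> alt-ORF -> plastid,
with a markdown summary and a run manifest. Every stage is also
independently invocable through the library or the CLI.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import diffexpr, io as rio, orf, plastid as plastid_mod, quadruplex as quad
from . import quantify, structure
from .models import SampleReads, TranscriptModel
from .simulate import (
    GroundTruth, SimulationConfig, generate_transcriptome,
    simulate_abundance, simulate_counts_and_coverage, write_dataset,
)

__version__ = "0.1.0"


def pooled_coverage(
    samples: Sequence[SampleReads],
    models: Sequence[TranscriptModel],
    assay: str,
    condition: str,
    total_over: Optional[str] = None,
    mode: str = "coverage",
):
    """Replicate-pooled coverage and total mapped reads for one assay/condition.

    ``total_over="nuclear"`` (or ``"plastid"``) restricts the reported
    total to reads on that compartment's transcripts, which is the right
    denominator for within-compartment rpm comparisons across conditions.
    ``mode="density"`` builds 5'-end density tracks instead of full-span
    coverage.
    """
    sel = [s for s in samples if s.assay == assay and s.condition == condition]
    rec = pd.concat([s.records for s in sel], ignore_index=True)
    pooled = SampleReads(
        sample_id=f"{assay}_{condition}_pooled", assay=assay, condition=condition,
        records=rec,
    )
    if total_over is None:
        total = float(len(rec))
    else:
        tids = {m.transcript_id for m in models if m.compartment == total_over}
        total = float(rec["transcript_id"].isin(tids).sum())
    build = rio.density_from_reads if mode == "density" else rio.coverage_from_reads
    return build(pooled, models), total


@dataclass
class DemoResult:
    config: SimulationConfig
    truth: GroundTruth
    models: list[TranscriptModel]
    detection: pd.DataFrame
    change_records: pd.DataFrame
    confusion: pd.DataFrame
    class_recovery: float
    structure_report: pd.DataFrame
    quad_metaprofile: quad.FlankMetaprofile
    quad_association: dict
    altorf_call: Optional[orf.AltOrfCall]
    altorf_changepoint: Optional[orf.ChangePoint]
    stoichiometry: list[plastid_mod.StoichiometryReport]
    abundance_rho: float
    outdir: Optional[Path] = None


def _confusion(truth: GroundTruth, records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Planted-vs-recovered class table; null genes count as recovered when
    called unchanged. Only nuclear (classed) genes participate."""
    planted = pd.Series(truth.classes)
    called = records["class"].reindex(planted.index).fillna("missing")
    expected = planted.replace({"null": "unchanged"})
    table = pd.crosstab(planted, called, rownames=["planted"], colnames=["called"])
    recovery = float((called == expected).mean())
    return table, recovery


def run_demo(
    config: SimulationConfig,
    outdir: Optional[str | Path] = None,
    structure_span: tuple[int, int] = (-120, 30),
    structure_group_size: int = 50,
) -> DemoResult:
    """Run every stage on one simulated dataset with planted ground truth.

    Writes stage outputs, ``summary.md`` and ``manifest.json`` under
    ``outdir`` when given. The summary is deterministic for a fixed
    config; the manifest additionally carries timestamps and file hashes.
    """
    models, truth = generate_transcriptome(config)
    samples, spike_table = simulate_counts_and_coverage(models, truth, config)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_dataset(out / "dataset", models, truth, samples, spike_table, config)

    # --- counting and detection limit
    rna = [s for s in samples if s.assay == "RNA"]
    rpf = [s for s in samples if s.assay == "RPF"]
    cm_rna = quantify.build_count_matrix(rna, models, region="CDS")
    cm_rpf = quantify.build_count_matrix(rpf, models, region="CDS")
    spike_rpkm = quantify.spikein_rpkm(spike_table, cm_rna.totals)
    detection = quantify.detection_limit(spike_rpkm)
    thresholds = detection.set_index("sample")["threshold_rpkm"]
    rpkm_rna = quantify.normalize(cm_rna, "rpkm")
    det_ok = thresholds.dropna()
    detected = (
        (rpkm_rna[det_ok.index] >= det_ok).any(axis=1)
        if len(det_ok) else pd.Series(True, index=rpkm_rna.index)
    )

    # --- differential classes (nuclear genes only)
    nuclear_ids = [m.gene_id for m in models if m.compartment == "nuclear"]
    conds = [s.condition for s in rna]
    res_m = diffexpr.nb_test(
        cm_rna.counts.loc[nuclear_ids], diffexpr.size_factors(cm_rna.counts.loc[nuclear_ids]),
        conds,
    )
    conds_r = [s.condition for s in rpf]
    res_r = diffexpr.nb_test(
        cm_rpf.counts.loc[nuclear_ids], diffexpr.size_factors(cm_rpf.counts.loc[nuclear_ids]),
        conds_r,
    )
    records = diffexpr.classify_genes(
        res_m, res_r, fdr=0.1, detected=detected.reindex(nuclear_ids)
    )
    confusion, recovery = _confusion(truth, records)

    # --- structure metaprofiles
    model_map = {m.gene_id: m for m in models}
    up_genes = truth.low_structure_genes[:structure_group_size]
    background = [
        g for g, c in truth.classes.items()
        if c == "null" and (not truth.altorf or g != truth.altorf["gene_id"])
    ][:structure_group_size]
    profiles = {
        g: structure.window_mfe_profile(model_map[g], span=structure_span)
        for g in up_genes + background
    }
    _, structure_report = structure.group_metaprofile(
        profiles, {"translational_up": up_genes, "background": background}
    )

    # --- quadruplex
    hits = [
        h for m in models if m.compartment == "nuclear"
        for h in quad.scan_quadruplexes(m, tiers=(config.quadruplex_tier,))
    ]
    rpf_cov = {
        c: pooled_coverage(samples, models, "RPF", c, total_over="nuclear")
        for c in ("control", "heat")
    }
    rna_cov = {
        c: pooled_coverage(samples, models, "RNA", c, total_over="nuclear")
        for c in ("control", "heat")
    }
    rpf_den = {
        c: pooled_coverage(samples, models, "RPF", c, total_over="nuclear",
                           mode="density")
        for c in ("control", "heat")
    }
    rna_den = {
        c: pooled_coverage(samples, models, "RNA", c, total_over="nuclear",
                           mode="density")
        for c in ("control", "heat")
    }
    planted_utr5 = {
        g for g, qs in truth.quadruplexes.items() if any(q["region"] == "UTR5" for q in qs)
    }
    metaprofile = quad.flank_metaprofile(
        [h for h in hits if h.region == "UTR5" and h.gene_id in planted_utr5],
        models,
        {c: rpf_den[c][0] for c in rpf_den},
        {c: rna_den[c][0] for c in rna_den},
        {c: rpf_den[c][1] for c in rpf_den},
        {c: rna_den[c][1] for c in rna_den},
    )
    association = quad.quadruplex_fold_change_association(hits, records)

    # --- alternative ORF
    altorf_call = None
    altorf_cp = None
    if truth.altorf:
        gid = truth.altorf["gene_id"]
        m = model_map[gid]
        cov = rpf_cov["heat"][0][m.transcript_id]
        altorf_cp = orf.find_changepoint(cov, region=m.cds)
        altorf_call = orf.call_alt_orf(
            m, altorf_cp.position, step_ratio=altorf_cp.step_ratio, condition="heat"
        )

    # --- plastid stoichiometry
    control_rpf = [s.sample_id for s in rpf if s.condition == "control"]
    heat_rpf = [s.sample_id for s in rpf if s.condition == "heat"]
    prod = {
        cond: plastid_mod.protein_production(
            cm_rpf, models, rna_counts=cm_rna, samples=cols
        )["production"]
        for cond, cols in (("control", control_rpf), ("heat", heat_rpf))
    }
    stoich = plastid_mod.stoichiometry_audit(prod, truth.complexes)
    abundance = simulate_abundance(prod["control"], config)
    abund = plastid_mod.abundance_correlation(prod["control"], abundance)

    result = DemoResult(
        config=config, truth=truth, models=models, detection=detection,
        change_records=records, confusion=confusion, class_recovery=recovery,
        structure_report=structure_report, quad_metaprofile=metaprofile,
        quad_association=association, altorf_call=altorf_call,
        altorf_changepoint=altorf_cp, stoichiometry=stoich,
        abundance_rho=abund["rho"], outdir=out,
    )
    if out is not None:
        _write_outputs(result, out)
    return result


def _write_outputs(r: DemoResult, out: Path) -> None:
    r.detection.to_csv(out / "detection_limit.tsv", sep="\t", index=False)
    r.change_records.to_csv(out / "diffexpr.tsv", sep="\t")
    r.confusion.to_csv(out / "class_confusion.tsv", sep="\t")
    r.structure_report.to_csv(out / "structure_test.tsv", sep="\t", index=False)
    r.quad_metaprofile.to_frame().to_csv(out / "quadruplex_metaprofile.tsv", sep="\t", index=False)
    lines = ["# riboheat demo summary", ""]
    lines += ["## Regulation classes (planted vs called)", "",
              r.confusion.to_markdown(), "",
              f"Planted-class recovery: {r.class_recovery:.1%}", ""]
    det = r.detection
    lines += ["## Spike-in detection limit (rpkm per RNA sample)", "",
              det.to_markdown(index=False), ""]
    lines += ["## Start-codon folding-energy contrast", "",
              r.structure_report.to_markdown(index=False), ""]
    mp = r.quad_metaprofile
    lines += ["## 5'UTR quadruplex RPF metaprofile", "",
              f"n genes: {mp.n_genes}; heat-vs-control signed-rank p: {mp.pvalue:.3g}", ""]
    if r.altorf_call is not None:
        c = r.altorf_call
        lines += ["## Alternative ORF", "",
                  f"gene {c.gene_id}: change-point at CDS position "
                  f"{r.altorf_changepoint.position} (step ratio "
                  f"{r.altorf_changepoint.step_ratio:.1f}); in-frame ATG at "
                  f"{c.alt_start}; peptide {c.peptide_length} aa "
                  f"({c.positive_fraction:.0%} K+R)", ""]
    lines += ["## Plastid complex stoichiometry", ""]
    for rep in r.stoichiometry:
        if rep.skipped:
            lines += [f"- {rep.complex_name}: skipped ({rep.reason})"]
        else:
            lines += [f"### {rep.complex_name}", "", rep.table.to_markdown(), "",
                      f"Spearman rho by condition: " +
                      ", ".join(f"{k}={v:.3f}" for k, v in rep.concordance.items()),
                      f"Disproportionate under heat: {rep.disproportionate} "
                      f"{rep.flagged_subunits}", ""]
    lines += [f"Production vs synthetic abundance Spearman rho: {r.abundance_rho:.3f}", ""]
    (out / "summary.md").write_text("\n".join(lines))
    _write_manifest(out, r)


def _write_manifest(out: Path, r: DemoResult) -> None:
    hashes = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            hashes[str(p.relative_to(out))] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "command": "demo",
        "seed": r.config.seed,
        "parameters": {
            "n_genes": r.config.n_genes, "depth": r.config.depth,
            "lfc_effect": r.config.lfc_effect, "dispersion": r.config.dispersion,
        },
        "artifact_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "file_sha256": hashes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
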
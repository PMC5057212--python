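"""G-quadruplex grammar scanning and footprint-coverage analysis around hits.

The grammar is four guanine runs separated by 1-7 nt loops: tier G2 is
G2 N1-7 G2 N1-7 G2 N1-7 G2, and analogously for G3 and G4. Matching is
run-based: a maximal run of >= tier-many Gs satisfies the run requirement
and anchors a hit at the run's first position; loops are the gaps between
consecutive chosen runs. Each anchor yields at most one hit, chosen
lazily (nearest next run first, with backtracking), which makes hit
counts per-locus rather than combinatorial and gives exact tier
containment: every G4 hit anchors a G3 and a G2 hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .models import CoverageTrack, TranscriptModel

TIERS = {"G2": 2, "G3": 3, "G4": 4}
MAX_LOOP = 7
FLANK_UP = 200
FLANK_DOWN = 250
#: running-mean width for the mRNA denominator; reads span 25-35 nt so
#: true mRNA coverage is locally smooth, and smoothing removes the
#: depth-dependent small-count bias of the per-position ratio
RNA_SMOOTH_NT = 31


@dataclass(frozen=True)
class QuadruplexHit:
    gene_id: str
    tier: str
    region: Optional[str]  # region containing the first base, None if outside annotation
    start: int  # transcript coordinate of the first G of the first run
    end: int    # past-the-end of the last run
    sequence: str


def g_runs(sequence: str) -> list[tuple[int, int]]:
    """Maximal runs of G as (start, end) half-open intervals."""
    runs = []
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8) == ord("G")
    if not arr.any():
        return runs
    padded = np.concatenate([[False], arr, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _chain_from(runs: list[tuple[int, int]], idx: int, needed: int) -> Optional[int]:
    """Lazily extend a chain of runs from ``runs[idx]``; returns last run index."""
    if needed == 0:
        return idx
    s, e = runs[idx]
    for nxt in range(idx + 1, len(runs)):
        gap = runs[nxt][0] - e
        if gap > MAX_LOOP:
            break
        if gap >= 1:
            found = _chain_from(runs, nxt, needed - 1)
            if found is not None:
                return found
    return None


def scan_quadruplexes(
    model_or_seq: TranscriptModel | str,
    tiers: Sequence[str] = ("G2", "G3", "G4"),
    all_matches: bool = False,
) -> list[QuadruplexHit]:
    """All per-anchor quadruplex hits of the requested tiers.

    Tiers are scanned independently. With ``all_matches`` every valid
    run-quadruple is reported instead of one lazy hit per anchor.
    """
    if isinstance(model_or_seq, TranscriptModel):
        seq = model_or_seq.sequence.upper().replace("U", "T")
        gene_id = model_or_seq.gene_id
        region_of = model_or_seq.region_of
    else:
        seq = model_or_seq.upper().replace("U", "T")
        gene_id = ""
        region_of = lambda pos: None  # noqa: E731
    hits: list[QuadruplexHit] = []
    runs_all = g_runs(seq)
    for tier in tiers:
        k = TIERS[tier]
        runs = [r for r in runs_all if r[1] - r[0] >= k]
        if all_matches:
            hits.extend(_all_matches(seq, gene_id, region_of, tier, runs))
            continue
        for idx, (s, e) in enumerate(runs):
            last = _chain_from(runs, idx, 3)
            if last is not None:
                end = runs[last][1]
                hits.append(
                    QuadruplexHit(
                        gene_id=gene_id,
                        tier=tier,
                        region=region_of(s),
                        start=s,
                        end=end,
                        sequence=seq[s:end],
                    )
                )
    return hits


def _all_matches(seq, gene_id, region_of, tier, runs) -> list[QuadruplexHit]:
    out = []

    def extend(idx: int, needed: int, first: int):
        if needed == 0:
            end = runs[idx][1]
            out.append(
                QuadruplexHit(gene_id, tier, region_of(runs[first][0]),
                              runs[first][0], end, seq[runs[first][0]: end])
            )
            return
        e = runs[idx][1]
        for nxt in range(idx + 1, len(runs)):
            gap = runs[nxt][0] - e
            if gap > MAX_LOOP:
                break
            if gap >= 1:
                extend(nxt, needed - 1, first)

    for i in range(len(runs)):
        extend(i, 3, i)
    return out


def hits_table(hits: Sequence[QuadruplexHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [h.__dict__ for h in hits],
        columns=["gene_id", "tier", "region", "start", "end", "sequence"],
    )


def write_hits_bed(hits: Sequence[QuadruplexHit], path, transcript_of: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            name = f"{h.tier}:{h.region or 'NA'}"
            fh.write(f"{transcript_of.get(h.gene_id, h.gene_id)}\t{h.start}\t{h.end}\t{name}\n")


# ---------------------------------------------------------------------------
# Flanking coverage metaprofiles


@dataclass
class FlankMetaprofile:
    """Per-position RPF/mRNA metaprofile over [-200, +250) around hit starts."""

    positions: np.ndarray
    mean_control: np.ndarray
    mean_heat: np.ndarray
    cumulative_control: np.ndarray
    cumulative_heat: np.ndarray
    n_genes: int
    pvalue: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "mean_control": self.mean_control,
                "mean_heat": self.mean_heat,
                "cumulative_control": self.cumulative_control,
                "cumulative_heat": self.cumulative_heat,
            }
        )


def _shared_rna_rpm(
    tids: set[str],
    rna_cov_by_cond: Mapping[str, Mapping[str, CoverageTrack]],
    rna_totals: Mapping[str, float],
) -> dict[str, np.ndarray]:
    """Condition-pooled, smoothed mRNA rpm per transcript.

    A single shared denominator means its sampling noise divides both
    condition curves identically and cancels exactly in their contrast.
    """
    out = {}
    for tid in tids:
        tracks = []
        for cond, covs in rna_cov_by_cond.items():
            if tid in covs:
                scale = 1e6 / max(rna_totals[cond], 1.0)
                tracks.append(covs[tid].depth.astype(float) * scale)
        if tracks:
            pooled = np.mean(tracks, axis=0)
            out[tid] = uniform_filter1d(pooled, RNA_SMOOTH_NT, mode="nearest")
    return out


def _gene_flank_values(
    hits: Sequence[QuadruplexHit],
    transcript_of: Mapping[str, str],
    rpf_cov: Mapping[str, CoverageTrack],
    rna_rpm: Mapping[str, np.ndarray],
    rpf_total: float,
    pseudo_rpm: float,
    gene_normalize: bool,
) -> dict[str, np.ndarray]:
    """Per gene: position-wise RPF rpm / max(shared RNA rpm, pseudocount),
    hits averaged. With ``gene_normalize`` each gene's curve is divided by
    the gene's baseline RPF/RNA ratio in that condition, computed over the
    transcript excluding the flank window itself: this removes the
    gene-level count noise shared across all flank positions (which
    dominates the condition contrast in small cohorts) without letting a
    real elevation inside the window deflate its own baseline."""
    span = FLANK_UP + FLANK_DOWN
    per_gene: dict[str, list[np.ndarray]] = {}
    for h in hits:
        tid = transcript_of[h.gene_id]
        if tid not in rpf_cov or tid not in rna_rpm:
            continue
        rpf = rpf_cov[tid].depth.astype(float) * 1e6 / max(rpf_total, 1.0)
        rna = rna_rpm[tid]
        vals = np.full(span, np.nan)
        lo = h.start - FLANK_UP
        for i in range(span):
            p = lo + i
            if 0 <= p < len(rpf):
                vals[i] = rpf[p] / max(rna[p], pseudo_rpm)
        if gene_normalize:
            baseline = np.ones(len(rpf), dtype=bool)
            baseline[max(lo, 0): min(h.start + FLANK_DOWN, len(rpf))] = False
            if baseline.sum() < 50:  # short transcript: fall back to all
                baseline[:] = True
            gene_ratio = rpf[baseline].mean() / max(rna[baseline].mean(), pseudo_rpm)
            if gene_ratio > 0:
                vals = vals / gene_ratio
        per_gene.setdefault(h.gene_id, []).append(vals)
    out = {}
    for g, v in per_gene.items():
        if len(v) == 1:
            out[g] = v[0]
        else:
            stacked = np.stack(v)
            ok = np.isfinite(stacked)
            sums = np.where(ok, stacked, 0.0).sum(axis=0)
            ns = ok.sum(axis=0)
            out[g] = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    return out


def flank_metaprofile(
    hits: Sequence[QuadruplexHit],
    models: Sequence[TranscriptModel],
    rpf_cov_by_cond: Mapping[str, Mapping[str, CoverageTrack]],
    rna_cov_by_cond: Mapping[str, Mapping[str, CoverageTrack]],
    rpf_totals: Mapping[str, float],
    rna_totals: Optional[Mapping[str, float]] = None,
    pseudocount: float = 1.0,
    gene_normalize: bool = True,
) -> FlankMetaprofile:
    """Equal-gene-weight RPF/mRNA metaprofile around quadruplex starts.

    For each hit gene and each position in [-200, +250) relative to the
    hit's first base: RPF coverage in rpm divided by the mRNA rpm at that
    position (floored at ``pseudocount`` reads, rpm-scaled). Totals should
    be restricted to the transcript set under study (e.g. nuclear-mapped
    reads) so compartment-level depth shifts between conditions cancel;
    when ``rna_totals`` is omitted the RPF totals are reused. Genes with
    several hits contribute the average of their hits; positions outside
    the transcript are excluded from that gene's contribution. Conditions
    (keys ``"control"``/``"heat"`` of the coverage mappings) are compared
    by a two-sided Wilcoxon signed-rank test on the 450 paired per-position
    metaprofile values; all-zero differences give p = 1 by convention.

    By default each gene's curve is scaled by its own transcript-wide
    RPF/RNA ratio per condition (``gene_normalize``): without this, the
    gene-level counting noise shared by all positions of a gene dominates
    the paired contrast in small cohorts and the signed-rank test is
    anti-conservative under the null. Disable to inspect raw ratio curves.
    """
    positions = np.arange(-FLANK_UP, FLANK_DOWN)
    if len(hits) == 0:
        empty = np.full(len(positions), np.nan)
        return FlankMetaprofile(positions, empty, empty, empty, empty, 0, np.nan)
    if rna_totals is None:
        rna_totals = rpf_totals
    transcript_of = {m.gene_id: m.transcript_id for m in models}
    rna_rpm = _shared_rna_rpm(
        {transcript_of[h.gene_id] for h in hits if h.gene_id in transcript_of},
        rna_cov_by_cond, rna_totals,
    )
    pseudo_rpm = pseudocount * 1e6 / max(float(np.mean(list(rna_totals.values()))), 1.0)
    curves = {}
    genes: set[str] = set()
    for cond in ("control", "heat"):
        vals = _gene_flank_values(
            hits, transcript_of, rpf_cov_by_cond[cond], rna_rpm,
            rpf_totals[cond], pseudo_rpm, gene_normalize,
        )
        genes |= set(vals)
        if vals:
            stacked = np.stack(list(vals.values()))
            ok = np.isfinite(stacked)
            ns = ok.sum(axis=0)
            curves[cond] = np.where(
                ns > 0, np.where(ok, stacked, 0.0).sum(axis=0) / np.maximum(ns, 1), np.nan
            )
        else:
            curves[cond] = np.full(len(positions), np.nan)
    diffs = curves["heat"] - curves["control"]
    finite = np.isfinite(diffs)
    if finite.sum() == 0 or np.allclose(diffs[finite], 0.0):
        pvalue = 1.0
    else:
        pvalue = float(
            stats.wilcoxon(
                curves["heat"][finite], curves["control"][finite],
                zero_method="wilcox", alternative="two-sided",
            ).pvalue
        )

    def cum(x):
        c = np.where(np.isfinite(x), x, 0.0)
        return np.cumsum(c)

    return FlankMetaprofile(
        positions=positions,
        mean_control=curves["control"],
        mean_heat=curves["heat"],
        cumulative_control=cum(curves["control"]),
        cumulative_heat=cum(curves["heat"]),
        n_genes=len(genes),
        pvalue=pvalue,
    )


# ---------------------------------------------------------------------------
# Fold-change association and 3'UTR half-reads check


def quadruplex_fold_change_association(
    hits: Sequence[QuadruplexHit],
    change_records: pd.DataFrame,
    tier: str = "G2",
    region: str = "UTR5",
    fdr: float = 0.1,
) -> dict:
    """Compare CDS RPF fold changes of quadruplex genes that are
    translationally up vs unchanged/down.

    Genes with >= 1 hit of ``tier`` in ``region`` are split by their
    regulation record: significantly up in RPF (adjusted p <= fdr and
    positive fold change) vs everything else. Reports group sizes, the
    log2FC distributions and a two-sided Mann-Whitney p (skipped when a
    group is empty).
    """
    carriers = sorted(
        {h.gene_id for h in hits if h.tier == tier and h.region == region}
    )
    carriers = [g for g in carriers if g in change_records.index]
    rec = change_records.loc[carriers]
    sig_up = (rec["padj_rpf"] <= fdr) & (rec["log2fc_rpf"] > 0)
    up = rec.loc[sig_up, "log2fc_rpf"]
    rest = rec.loc[~sig_up, "log2fc_rpf"]
    out = {
        "tier": tier,
        "region": region,
        "n_up": int(len(up)),
        "n_rest": int(len(rest)),
        "up_genes": list(up.index),
        "rest_genes": list(rest.index),
        "log2fc_up": up,
        "log2fc_rest": rest,
        "pvalue": np.nan,
    }
    if len(up) and len(rest):
        out["pvalue"] = float(
            stats.mannwhitneyu(up, rest, alternative="two-sided").pvalue
        )
    return out


def utr3_half_reads_check(
    hits: Sequence[QuadruplexHit],
    symmetry_by_cond: Mapping[str, pd.DataFrame],
    tier: str = "G2",
) -> dict:
    """Paired first-half mRNA fractions (control vs heat) for genes with a
    3'UTR quadruplex; Wilcoxon signed-rank on the paired fractions.

    ``symmetry_by_cond`` maps condition -> half_symmetry table for the
    mRNA assay (genes below min_reads are already excluded there).
    """
    carriers = sorted({h.gene_id for h in hits if h.tier == tier and h.region == "UTR3"})
    ctl = symmetry_by_cond["control"].set_index("gene_id")["first_fraction"]
    heat = symmetry_by_cond["heat"].set_index("gene_id")["first_fraction"]
    shared = [g for g in carriers if g in ctl.index and g in heat.index]
    a = ctl.loc[shared].to_numpy()
    b = heat.loc[shared].to_numpy()
    table = pd.DataFrame(
        {"gene_id": shared, "first_fraction_control": a, "first_fraction_heat": b}
    )
    if len(shared) == 0 or np.allclose(a, b):
        return {"table": table, "pvalue": 1.0 if len(shared) else np.nan, "n": len(shared)}
    p = float(stats.wilcoxon(b, a, zero_method="wilcox", alternative="two-sided").pvalue)
    return {"table": table, "pvalue": p, "n": len(shared)}
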
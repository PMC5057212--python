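"""Alternative-transcript/ORF detection from footprint asymmetry and
coverage change-points, peptide characterisation, heat-shock promoter
element scanning, and selection of UTR footprint-gain genes for motif
export.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from .io import write_fasta
from .models import CoverageTrack, TranscriptModel

POSITIVE_AA = set("KR")
NEGATIVE_AA = set("DE")

#: heat-shock element consensus recognised by plant heat shock factors
HSE_CONSENSUS = "AGAANNTTCT"

#: MEME parameters recorded alongside every motif-export (discovery itself
#: is performed externally)
MEME_PARAMETERS = {
    "tool": "MEME",
    "min_width": 6,
    "max_width": 20,
    "max_motifs": 10,
    "site_distribution": "zero_or_one_per_sequence",
}


# ---------------------------------------------------------------------------
# Asymmetry outliers


def asymmetry_outliers(
    symmetry: pd.DataFrame, threshold: float = 4.0
) -> pd.DataFrame:
    """Flag genes whose first-half read fraction is a robust outlier.

    Requires >= 20 symmetry records. The robust z is
    (fraction - median) / (1.4826 * MAD); falls back to the SD when the
    MAD is 0, and reports no outliers when both are 0. Returns the flagged
    rows with ``robust_z`` and ``direction`` (``second_half`` for z < 0).
    """
    if len(symmetry) < 20:
        raise ValueError("need >= 20 genes for outlier screening")
    frac = symmetry["first_fraction"].to_numpy(dtype=float)
    med = np.median(frac)
    mad = np.median(np.abs(frac - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = frac.std(ddof=0)
    if scale == 0:
        return symmetry.iloc[0:0].assign(robust_z=[], direction=[])
    z = (frac - med) / scale
    out = symmetry.loc[np.abs(z) > threshold].copy()
    out["robust_z"] = z[np.abs(z) > threshold]
    out["direction"] = np.where(out["robust_z"] < 0, "second_half", "first_half")
    return out


# ---------------------------------------------------------------------------
# Change-point


@dataclass
class ChangePoint:
    position: int  # region-local coordinate of the first position after the step
    step_ratio: float
    no_step: bool
    gain: float


def find_changepoint(
    coverage: CoverageTrack | np.ndarray,
    region: Optional[tuple[int, int]] = None,
    eps: float = 1e-9,
    min_ratio: float = 1.5,
) -> ChangePoint:
    """Single change-point by two-segment least squares on per-position depth.

    Scans all splits t of the (region-restricted) coverage vector and
    keeps the one maximising the reduction in squared error of a
    two-constant-segment fit (equivalently the maximal CUSUM deviation).
    ``step_ratio`` is mean(after) / max(mean(before), eps); ratios within
    [1/min_ratio, min_ratio] are flagged ``no_step`` (flat coverage).
    Positions are local to the region.
    """
    x = coverage.depth if isinstance(coverage, CoverageTrack) else np.asarray(coverage)
    if region is not None:
        x = x[region[0]: region[1]]
    x = x.astype(float)
    n = len(x)
    if n < 200:
        raise ValueError("region length must be >= 200")
    if x.sum() <= 0:
        raise ValueError("total coverage must be > 0")
    csum = np.cumsum(x)
    t = np.arange(1, n)
    mean_before = csum[:-1] / t
    mean_after = (csum[-1] - csum[:-1]) / (n - t)
    # SSE gain of splitting at t relative to a single constant segment
    total_mean = csum[-1] / n
    gain = t * (mean_before - total_mean) ** 2 + (n - t) * (mean_after - total_mean) ** 2
    best = int(np.argmax(gain)) + 1
    ratio = float(mean_after[best - 1] / max(mean_before[best - 1], eps))
    no_step = (1.0 / min_ratio) < ratio < min_ratio
    return ChangePoint(
        position=best, step_ratio=ratio, no_step=bool(no_step), gain=float(gain[best - 1])
    )


# ---------------------------------------------------------------------------
# Alternative ORF calling


@dataclass
class AltOrfCall:
    gene_id: str
    changepoint: int  # CDS-local position
    alt_start: Optional[int]  # CDS-local in-frame ATG position
    peptide: str
    peptide_length: int
    positive_fraction: float
    negative_fraction: float
    step_ratio: float
    condition: str
    accepted: bool
    reason: str = ""


def call_alt_orf(
    model: TranscriptModel,
    changepoint: int,
    step_ratio: float = np.nan,
    condition: str = "heat",
    search_slack: tuple[int, int] = (-30, 60),
) -> AltOrfCall:
    """Call an internal in-frame ORF near a coverage change-point.

    ``changepoint`` is CDS-local. The first ATG at an in-frame CDS
    position within [changepoint + slack_lo, changepoint + slack_hi] is
    taken as the alternative start; translation runs to the first in-frame
    stop (standard code). The reported peptide counts the residues encoded
    after the initiator Met (so ATG immediately followed by a stop gives
    length 0). Without a stop before the CDS end the peptide runs to the
    CDS end and the call is annotated accordingly. No in-frame ATG in the
    window rejects the call with a reason.
    """
    cds = model.region_seq("CDS")
    if not (0 <= changepoint < len(cds)):
        return AltOrfCall(model.gene_id, changepoint, None, "", 0, 0.0, 0.0,
                          step_ratio, condition, False, "change-point outside CDS")
    lo = max(changepoint + search_slack[0], 0)
    hi = min(changepoint + search_slack[1], len(cds) - 3)
    alt_start = None
    for pos in range(lo, hi + 1):
        if pos % 3 == 0 and cds[pos: pos + 3] == "ATG":
            alt_start = pos
            break
    if alt_start is None:
        return AltOrfCall(model.gene_id, changepoint, None, "", 0, 0.0, 0.0,
                          step_ratio, condition, False,
                          "no in-frame ATG within search window")
    tail = cds[alt_start + 3:]  # residues after the initiator Met
    tail = tail[: len(tail) - len(tail) % 3]
    aa = str(Seq(tail).translate())
    reason = ""
    if "*" in aa:
        peptide = aa[: aa.index("*")]
    else:
        peptide = aa
        reason = "no in-frame stop before CDS end"
    npos = sum(1 for c in peptide if c in POSITIVE_AA)
    nneg = sum(1 for c in peptide if c in NEGATIVE_AA)
    denom = max(len(peptide), 1)
    return AltOrfCall(
        gene_id=model.gene_id,
        changepoint=changepoint,
        alt_start=alt_start,
        peptide=peptide,
        peptide_length=len(peptide),
        positive_fraction=npos / denom,
        negative_fraction=nneg / denom,
        step_ratio=step_ratio,
        condition=condition,
        accepted=True,
        reason=reason,
    )


# ---------------------------------------------------------------------------
# Promoter element scan


_COMP = str.maketrans("ACGTN", "TGCAN")


def _matches_at(seq: str, pos: int, consensus: str, max_mismatch: int) -> bool:
    mm = 0
    for i, c in enumerate(consensus):
        if c == "N":
            continue
        if seq[pos + i] != c:
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def promoter_element_scan(
    sequence: str,
    element: str = HSE_CONSENSUS,
    max_mismatch: int = 0,
) -> pd.DataFrame:
    """All matches of a consensus element on both strands.

    ``N`` in the consensus is a wildcard; up to ``max_mismatch``
    mismatches are allowed at non-wildcard positions. Minus-strand matches
    are positions where the reverse complement of the element occurs; the
    reported position is on the given (plus) sequence. Note the default
    heat-shock element consensus is its own reverse complement, so every
    exact occurrence reports one row per strand. Columns: position,
    strand, matched.
    """
    seq = sequence.upper()
    element = element.upper()
    rc = element.translate(_COMP)[::-1]
    k = len(element)
    rows = []
    for pos in range(len(seq) - k + 1):
        if _matches_at(seq, pos, element, max_mismatch):
            rows.append({"position": pos, "strand": "+", "matched": seq[pos: pos + k]})
        if _matches_at(seq, pos, rc, max_mismatch):
            rows.append({"position": pos, "strand": "-", "matched": seq[pos: pos + k]})
    return pd.DataFrame(rows, columns=["position", "strand", "matched"])


def write_promoter_bed(matches: pd.DataFrame, gene_id: str, path) -> None:
    with open(path, "w") as fh:
        for _, r in matches.iterrows():
            fh.write(
                f"{gene_id}\t{r['position']}\t{r['position'] + len(r['matched'])}"
                f"\tHSE\t0\t{r['strand']}\n"
            )


# ---------------------------------------------------------------------------
# UTR footprint-gain gene selection (motif-discovery input preparation)


def select_utr_rpf_gain_genes(
    rpf_counts_by_cond: Mapping[str, pd.Series],
    rpf_totals_by_cond: Mapping[str, float],
    models: Sequence[TranscriptModel],
    candidate_genes: Sequence[str],
    region: str = "UTR5",
    fold_threshold: float = 2.0,
    min_reads: int = 10,
    pseudocount: float = 1.0,
    fasta_path: Optional[str | Path] = None,
    metadata_path: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Genes (among translational-up candidates) gaining UTR footprints
    under heat, with their UTR sequences exported for motif discovery.

    Selection: UTR RPF rpm fold change (heat / control, ``pseudocount``
    added to both rpm values) >= ``fold_threshold`` and heat UTR raw count
    >= ``min_reads``. Genes without an annotated UTR of the requested
    class are skipped. The export records the downstream MEME parameters
    in a YAML sidecar.
    """
    model_map = {m.gene_id: m for m in models}
    ctl, heat = rpf_counts_by_cond["control"], rpf_counts_by_cond["heat"]
    rows = []
    for gid in candidate_genes:
        m = model_map.get(gid)
        if m is None:
            continue
        lo, hi = m.region(region)
        if hi <= lo:
            continue
        c = float(ctl.get(gid, 0))
        h = float(heat.get(gid, 0))
        rpm_c = c * 1e6 / max(rpf_totals_by_cond["control"], 1.0) + pseudocount
        rpm_h = h * 1e6 / max(rpf_totals_by_cond["heat"], 1.0) + pseudocount
        fc = rpm_h / rpm_c
        if fc >= fold_threshold and h >= min_reads:
            rows.append(
                {"gene_id": gid, "region": region, "control_count": c,
                 "heat_count": h, "rpm_fold_change": fc}
            )
    selected = pd.DataFrame(
        rows, columns=["gene_id", "region", "control_count", "heat_count", "rpm_fold_change"]
    )
    if fasta_path is not None and len(selected):
        seqs = {g: model_map[g].region_seq(region) for g in selected["gene_id"]}
        write_fasta(seqs, fasta_path)
        if metadata_path is not None:
            Path(metadata_path).write_text(
                yaml.safe_dump(
                    {"region": region, "n_sequences": len(seqs),
                     "fold_threshold": fold_threshold, "min_reads": min_reads,
                     "meme": MEME_PARAMETERS},
                    sort_keys=False,
                )
            )
    return selected
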
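"""Gene-level counting, rpm/rpkm normalisation, spike-in detection limits
and the half-transcript symmetry statistic.

A read belongs to a region iff its midpoint, ``pos + length // 2``, falls
inside the region's half-open interval. Midpoint assignment counts every
read at most once, so region counts partition the full-transcript counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import SampleReads, TranscriptModel

#: binomial detectability rationale: with >= 32 reads a first-half fraction
#: deviating by 0.25 from 0.5 reaches p < 0.01
DEFAULT_MIN_READS = 32


@dataclass
class CountMatrix:
    """Gene x sample raw counts plus the metadata normalisation needs.

    ``totals`` are per-sample total mapped reads (all reads in the sample,
    not only those falling in the counted region); ``lengths`` is the
    counted feature length per gene in nt.
    """

    counts: pd.DataFrame
    totals: pd.Series
    lengths: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.totals = self.totals.reindex(self.counts.columns)
        self.lengths = self.lengths.reindex(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)


def _midpoints(records: pd.DataFrame) -> np.ndarray:
    return records["pos"].to_numpy() + records["length"].to_numpy() // 2


def count_reads(
    reads: SampleReads,
    models: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
    region: str = "CDS",
) -> pd.Series:
    """One CountMatrix column: reads per gene whose midpoint lies in ``region``.

    ``region`` is one of ``CDS``, ``UTR5``, ``UTR3`` or ``full``. Empty
    input yields an all-zero column.
    """
    if not isinstance(models, Mapping):
        models = {m.transcript_id: m for m in models}
    gene_of = {tid: m.gene_id for tid, m in models.items()}
    bounds = {tid: m.region(region) for tid, m in models.items()}
    rec = reads.records
    counts = pd.Series(0, index=sorted({m.gene_id for m in models.values()}), dtype=np.int64)
    if len(rec) == 0:
        counts.name = reads.sample_id
        return counts
    mids = _midpoints(rec)
    tids = rec["transcript_id"].to_numpy()
    lo = np.array([bounds.get(t, (0, 0))[0] for t in tids])
    hi = np.array([bounds.get(t, (0, 0))[1] for t in tids])
    known = np.array([t in bounds for t in tids])
    in_region = known & (mids >= lo) & (mids < hi)
    hits = pd.Series(tids[in_region]).map(gene_of).value_counts()
    counts.loc[hits.index] += hits.astype(np.int64)
    counts.name = reads.sample_id
    return counts


def build_count_matrix(
    samples: Sequence[SampleReads],
    models: Sequence[TranscriptModel],
    region: str = "CDS",
) -> CountMatrix:
    """Count all samples over one region; totals are per-sample mapped reads."""
    cols = [count_reads(s, models, region) for s in samples]
    counts = pd.concat(cols, axis=1)
    totals = pd.Series({s.sample_id: s.total_reads for s in samples})
    lengths = pd.Series(
        {m.gene_id: m.region(region)[1] - m.region(region)[0] for m in models}
    )
    return CountMatrix(counts=counts, totals=totals, lengths=lengths.reindex(counts.index))


def normalize(cm: CountMatrix, mode: str = "rpkm") -> pd.DataFrame:
    """rpm = count / total * 1e6; rpkm = count / (length_kb * total_millions)."""
    if (cm.totals <= 0).any():
        bad = cm.totals.index[cm.totals <= 0].tolist()
        raise ValueError(f"zero total mapped reads for sample(s) {bad}")
    rpm = cm.counts / cm.totals.to_numpy()[None, :] * 1e6
    if mode == "rpm":
        return rpm
    if mode == "rpkm":
        return rpm.div(cm.lengths.to_numpy()[:, None] / 1e3, axis=0)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Spike-in detection limit


def spikein_rpkm(spike_table: pd.DataFrame, gene_totals: pd.Series) -> pd.DataFrame:
    """Observed rpkm of each spike-in in each RNA sample.

    Spike-in reads do not map to the transcriptome, so they are excluded
    from the gene totals; for spike-in normalisation the denominator is the
    sample's gene-mapped total plus its spike-in reads.

    ``spike_table`` columns: spikein_id, concentration, length, then one
    count column per RNA sample.
    """
    count_cols = [c for c in spike_table.columns if c in gene_totals.index]
    counts = spike_table[count_cols].to_numpy(dtype=float)
    denom = gene_totals[count_cols].to_numpy() + counts.sum(axis=0)
    rpkm = counts / (spike_table["length"].to_numpy()[:, None] / 1e3) / (denom[None, :] / 1e6)
    out = spike_table[["spikein_id", "concentration"]].copy()
    for j, c in enumerate(count_cols):
        out[c] = rpkm[:, j]
    return out


#: lower bound on the fit's residual-SD estimate, in log units (~20%):
#: with only a handful of high rungs the SD estimate can collapse well
#: below typical spike-in library variation, and a rung should not be
#: called off the linear range for departing less than that
MIN_RESID_SD = 0.18


def detection_limit(
    spike_rpkm: pd.DataFrame,
    tolerance_sd: float = 2.0,
) -> pd.DataFrame:
    """Per-sample detection threshold from the spike-in ladder.

    A least-squares line is fitted to log(observed rpkm) vs log(known
    concentration) over the upper half of the ladder, where detection is
    assumed linear. Walking down the ladder, the threshold is the observed
    rpkm of the lowest spike-in whose residual from that line stays within
    ``tolerance_sd`` times the fit's residual SD. Genes with rpkm below the
    threshold in every sample should be treated as not reliably detected.

    Requires >= 4 spike-ins spanning >= 2 orders of magnitude. A sample
    whose spike-ins are all zero gets an undefined (NaN) threshold and is
    flagged.
    """
    conc = spike_rpkm["concentration"].to_numpy(dtype=float)
    if len(conc) < 4:
        raise ValueError("need >= 4 spike-ins")
    if conc.max() / conc.min() < 100:
        raise ValueError("spike-in ladder must span >= 2 orders of magnitude")
    order = np.argsort(conc)[::-1]  # high to low
    sample_cols = [
        c for c in spike_rpkm.columns if c not in ("spikein_id", "concentration")
    ]
    rows = []
    for col in sample_cols:
        obs = spike_rpkm[col].to_numpy(dtype=float)[order]
        known = conc[order]
        if (obs <= 0).all():
            rows.append({"sample": col, "threshold_rpkm": np.nan, "flag": "all_zero"})
            continue
        upper = slice(0, max(len(known) // 2, 2))
        x, y = np.log(known[upper]), np.log(np.maximum(obs[upper], 1e-12))
        slope, intercept = np.polyfit(x, y, 1)
        dof = max(len(y) - 2, 1)
        resid_sd = float(
            np.sqrt(np.sum((y - (slope * x + intercept)) ** 2) / dof)
        )
        tol = tolerance_sd * max(resid_sd, MIN_RESID_SD)
        # walk down the full ladder; the lowest rung still on the fitted
        # line (within tolerance) sets the threshold
        threshold = obs[0]
        for known_i, obs_i in zip(known, obs):
            if obs_i <= 0:
                continue
            resid = np.log(obs_i) - (slope * np.log(known_i) + intercept)
            if abs(resid) <= tol:
                threshold = obs_i
        rows.append(
            {
                "sample": col,
                "threshold_rpkm": float(threshold),
                "flag": "ok",
                "fit_slope": float(slope),
                "tolerance": float(tol),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Half-transcript symmetry


def half_symmetry(
    samples: Sequence[SampleReads] | SampleReads,
    models: Sequence[TranscriptModel],
    assay: Optional[str] = None,
    min_reads: int = DEFAULT_MIN_READS,
) -> pd.DataFrame:
    """First- vs second-half CDS read counts per gene.

    The CDS splits at ``floor(len / 2)`` (first half is the shorter side on
    odd lengths); reads are assigned by the midpoint rule. Genes with fewer
    than ``min_reads`` reads in the CDS are excluded. When several samples
    are given their reads are pooled (they should share assay/condition).
    Columns: gene_id, assay, first_half, second_half, first_fraction, total.
    """
    if isinstance(samples, SampleReads):
        samples = [samples]
    if assay is None:
        assay = samples[0].assay
    model_map = {m.transcript_id: m for m in models}
    rec = pd.concat([s.records for s in samples], ignore_index=True)
    rec = rec[rec["transcript_id"].isin(model_map.keys())]
    mids = _midpoints(rec)
    tids = rec["transcript_id"].to_numpy()
    cds_lo = np.array([model_map[t].cds[0] for t in tids])
    cds_hi = np.array([model_map[t].cds[1] for t in tids])
    split = cds_lo + (cds_hi - cds_lo) // 2
    in_cds = (mids >= cds_lo) & (mids < cds_hi)
    first = pd.Series(tids[in_cds & (mids < split)]).value_counts()
    second = pd.Series(tids[in_cds & (mids >= split)]).value_counts()
    rows = []
    for tid, m in model_map.items():
        f = int(first.get(tid, 0))
        s = int(second.get(tid, 0))
        tot = f + s
        if tot < min_reads:
            continue
        rows.append(
            {
                "gene_id": m.gene_id,
                "assay": assay,
                "first_half": f,
                "second_half": s,
                "total": tot,
                "first_fraction": f / tot,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "assay", "first_half", "second_half", "total", "first_fraction"]
    )
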
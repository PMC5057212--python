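"""Reading and writing the external formats the pipeline touches.

Internal convention is 0-based half-open transcript coordinates; GFF3 is
converted from/to 1-based closed intervals and bedGraph is written 0-based
half-open, both at this boundary only.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import CoverageTrack, ModelError, SampleReads, TranscriptModel

logger = logging.getLogger(__name__)

READ_COLUMNS = ["transcript_id", "pos", "length"]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3 (transcript-space: seqid column == transcript id)

_GFF_COLS = (
    "seqid source type start end score strand phase attributes".split()
)


def _fmt_attrs(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attrs(field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key] = value
    return out


def write_annotation(
    models: Sequence[TranscriptModel],
    gff3_path: str | Path,
    fasta_path: str | Path,
    upstream_fasta_path: str | Path | None = None,
) -> None:
    """Write transcript models as transcript-space GFF3 + FASTA.

    GFF3 intervals are 1-based closed per the standard. Compartment and
    operon annotations travel as gene attributes. Upstream (promoter)
    sequences, when present, go to a separate FASTA keyed by gene id.
    """
    lines = ["##gff-version 3"]
    for m in models:
        gene_attrs = {"ID": m.gene_id, "compartment": m.compartment}
        if m.operon_id:
            gene_attrs["operon_id"] = m.operon_id
        rows = [
            ("gene", 0, m.length, gene_attrs),
            ("mRNA", 0, m.length, {"ID": m.transcript_id, "Parent": m.gene_id}),
        ]
        if m.utr5[1] > m.utr5[0]:
            rows.append(
                ("five_prime_UTR", m.utr5[0], m.utr5[1], {"Parent": m.transcript_id})
            )
        rows.append(("CDS", m.cds[0], m.cds[1], {"Parent": m.transcript_id}))
        if m.utr3[1] > m.utr3[0]:
            rows.append(
                ("three_prime_UTR", m.utr3[0], m.utr3[1], {"Parent": m.transcript_id})
            )
        for ftype, lo, hi, attrs in rows:
            # half-open [lo, hi) -> 1-based closed [lo+1, hi]
            lines.append(
                "\t".join(
                    [
                        m.transcript_id,
                        "riboheat",
                        ftype,
                        str(lo + 1),
                        str(hi),
                        ".",
                        "+",
                        "0" if ftype == "CDS" else ".",
                        _fmt_attrs(attrs),
                    ]
                )
            )
    Path(gff3_path).write_text("\n".join(lines) + "\n")
    write_fasta({m.transcript_id: m.sequence for m in models}, fasta_path)
    if upstream_fasta_path is not None:
        ups = {m.gene_id: m.upstream_region for m in models if m.upstream_region}
        if ups:
            write_fasta(ups, upstream_fasta_path)


def read_annotation(
    gff3_path: str | Path,
    fasta_path: str | Path,
    upstream_fasta_path: str | Path | None = None,
) -> list[TranscriptModel]:
    """Load transcript models from GFF3 + FASTA.

    Per gene, the longest annotated mRNA is kept. Genes whose features
    violate the model invariants (e.g. CDS not divisible by 3) are skipped
    with a logged reason; a feature referencing a missing FASTA sequence is
    a hard error.
    """
    sequences = read_fasta(fasta_path)
    upstream = read_fasta(upstream_fasta_path) if upstream_fasta_path else {}

    genes: dict[str, dict] = {}
    mrnas: dict[str, dict] = {}
    for raw in Path(gff3_path).read_text().splitlines():
        if not raw or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) != 9:
            continue
        row = dict(zip(_GFF_COLS, fields))
        attrs = _parse_attrs(row["attributes"])
        lo, hi = int(row["start"]) - 1, int(row["end"])  # to half-open
        ftype = row["type"]
        if ftype == "gene":
            genes[attrs["ID"]] = {
                "compartment": attrs.get("compartment", "nuclear"),
                "operon_id": attrs.get("operon_id") or None,
            }
        elif ftype == "mRNA":
            mrnas[attrs["ID"]] = {
                "gene": attrs["Parent"],
                "seqid": row["seqid"],
                "length": hi - lo,
                "features": {},
            }
        elif ftype in ("five_prime_UTR", "CDS", "three_prime_UTR"):
            parent = attrs["Parent"]
            mrnas.setdefault(
                parent, {"gene": None, "seqid": row["seqid"], "length": None, "features": {}}
            )
            mrnas[parent]["features"][ftype] = (lo, hi)

    # longest mRNA per gene
    chosen: dict[str, str] = {}
    for tid, info in mrnas.items():
        gid = info["gene"]
        if gid is None:
            continue
        length = info["length"]
        if gid not in chosen or length > mrnas[chosen[gid]]["length"]:
            chosen[gid] = tid

    out: list[TranscriptModel] = []
    for gid, tid in sorted(chosen.items()):
        info = mrnas[tid]
        if info["seqid"] not in sequences:
            raise KeyError(f"no sequence for transcript {info['seqid']!r} in FASTA")
        seq = sequences[info["seqid"]]
        feats = info["features"]
        if "CDS" not in feats:
            logger.warning("skipping %s: no CDS feature", gid)
            continue
        cds = feats["CDS"]
        utr5 = feats.get("five_prime_UTR", (0, cds[0]))
        utr3 = feats.get("three_prime_UTR", (cds[1], len(seq)))
        meta = genes.get(gid, {"compartment": "nuclear", "operon_id": None})
        try:
            out.append(
                TranscriptModel(
                    gene_id=gid,
                    transcript_id=tid,
                    sequence=seq,
                    utr5=utr5,
                    cds=cds,
                    utr3=utr3,
                    compartment=meta["compartment"],
                    operon_id=meta["operon_id"],
                    upstream_region=upstream.get(gid),
                )
            )
        except ModelError as exc:
            logger.warning("skipping %s: %s", gid, exc)
    return out


# ---------------------------------------------------------------------------
# Reads TSV

def write_reads(reads: SampleReads, path: str | Path) -> None:
    df = reads.records[READ_COLUMNS].rename(
        columns={"pos": "five_prime_pos_0based", "length": "read_length"}
    )
    df.to_csv(path, sep="\t", index=False)


def read_reads(
    path: str | Path, sample_id: str, assay: str, condition: str
) -> SampleReads:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(
        columns={"five_prime_pos_0based": "pos", "read_length": "length"}
    )
    return SampleReads(sample_id=sample_id, assay=assay, condition=condition, records=df)


# ---------------------------------------------------------------------------
# Coverage

def coverage_from_reads(
    reads: SampleReads,
    models: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
) -> dict[str, CoverageTrack]:
    """Per-position depth: position p counts reads with p in [pos, pos+length).

    Reads overhanging the transcript 3' end are clipped at the boundary so
    the depth vector length always equals the transcript length. Records
    naming an unknown transcript are skipped (counted and logged).
    """
    if not isinstance(models, Mapping):
        models = {m.transcript_id: m for m in models}
    tracks = {
        tid: np.zeros(m.length, dtype=np.int64) for tid, m in models.items()
    }
    rec = reads.records
    known = rec["transcript_id"].isin(models.keys()).to_numpy()
    n_skipped = int((~known).sum())
    if n_skipped:
        logger.warning(
            "%s: skipped %d reads on unknown transcripts", reads.sample_id, n_skipped
        )
    for tid, grp in rec[known].groupby("transcript_id", sort=False):
        depth = tracks[tid]
        n = len(depth)
        starts = np.clip(grp["pos"].to_numpy(), 0, n)
        ends = np.clip(grp["pos"].to_numpy() + grp["length"].to_numpy(), 0, n)
        # difference-array accumulation
        diff = np.zeros(n + 1, dtype=np.int64)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
        depth += np.cumsum(diff[:-1])
    return {tid: CoverageTrack(tid, d) for tid, d in tracks.items()}


def density_from_reads(
    reads: SampleReads,
    models: Sequence[TranscriptModel] | Mapping[str, TranscriptModel],
) -> dict[str, CoverageTrack]:
    """Per-position 5'-end read counts (one position per read).

    Single-position assignment keeps positional signals sharp and
    statistically independent across positions, which full-span coverage
    does not; it is the conventional per-position quantity in ribosome
    profiling.
    """
    if not isinstance(models, Mapping):
        models = {m.transcript_id: m for m in models}
    tracks = {tid: np.zeros(m.length, dtype=np.int64) for tid, m in models.items()}
    rec = reads.records
    known = rec["transcript_id"].isin(models.keys()).to_numpy()
    for tid, grp in rec[known].groupby("transcript_id", sort=False):
        np.add.at(tracks[tid], np.clip(grp["pos"].to_numpy(), 0, len(tracks[tid]) - 1), 1)
    return {tid: CoverageTrack(tid, d) for tid, d in tracks.items()}


def write_bedgraph(tracks: Mapping[str, CoverageTrack], path: str | Path) -> None:
    """Run-length-encoded bedGraph (0-based half-open) on transcript coords."""
    with open(path, "w") as fh:
        for tid in sorted(tracks):
            depth = tracks[tid].depth
            if len(depth) == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(depth)]])
            for s, e in zip(starts, ends):
                fh.write(f"{tid}\t{s}\t{e}\t{int(depth[s])}\n")


def read_bedgraph(path: str | Path, lengths: Mapping[str, int]) -> dict[str, CoverageTrack]:
    tracks = {tid: np.zeros(n, dtype=np.int64) for tid, n in lengths.items()}
    for raw in Path(path).read_text().splitlines():
        if not raw or raw.startswith(("track", "#")):
            continue
        tid, s, e, v = raw.split("\t")
        if tid in tracks:
            tracks[tid][int(s): int(e)] = int(v)
    return {tid: CoverageTrack(tid, d) for tid, d in tracks.items()}
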
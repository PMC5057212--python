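"""Core in-memory containers shared across the pipeline.

All coordinates are 0-based half-open in transcript space (sense strand).
External formats (GFF3: 1-based closed; bedGraph: 0-based half-open) are
converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

Interval = tuple[int, int]

VALID_COMPARTMENTS = ("nuclear", "plastid")
VALID_ASSAYS = ("RNA", "RPF")
VALID_CONDITIONS = ("control", "heat")
REGIONS = ("UTR5", "CDS", "UTR3")


class ModelError(ValueError):
    """Raised when a transcript model violates its structural invariants."""


@dataclass(frozen=True)
class TranscriptModel:
    """One gene's representative (longest) transcript.

    Parameters
    ----------
    gene_id, transcript_id
        Stable identifiers; one transcript per gene in this pipeline.
    sequence
        DNA alphabet (ACGT); folding routines treat T as U.
    utr5, cds, utr3
        Half-open 0-based intervals in transcript coordinates. They must
        tile the transcript: ``utr5.end == cds.start`` and
        ``cds.end == utr3.start``; the CDS length must be divisible by 3.
    compartment
        ``"nuclear"`` or ``"plastid"``.
    operon_id
        Groups plastid ORFs transcribed as one polycistronic unit.
    upstream_region
        Optional promoter-proximal genomic sequence (<= 1 kb) upstream of
        the transcription start, used for promoter-element scanning.
    """

    gene_id: str
    transcript_id: str
    sequence: str
    utr5: Interval
    cds: Interval
    utr3: Interval
    compartment: str = "nuclear"
    operon_id: Optional[str] = None
    upstream_region: Optional[str] = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if self.utr5[0] != 0 or self.utr5[1] != self.cds[0]:
            raise ModelError(f"{self.gene_id}: utr5 must run from 0 to cds.start")
        if self.cds[1] != self.utr3[0]:
            raise ModelError(f"{self.gene_id}: cds.end must equal utr3.start")
        if self.utr3[1] != n:
            raise ModelError(f"{self.gene_id}: utr3 must end at transcript end ({n})")
        if (self.cds[1] - self.cds[0]) % 3 != 0:
            raise ModelError(f"{self.gene_id}: CDS length not divisible by 3")
        if self.cds[1] <= self.cds[0]:
            raise ModelError(f"{self.gene_id}: empty CDS")
        if self.compartment not in VALID_COMPARTMENTS:
            raise ModelError(f"{self.gene_id}: unknown compartment {self.compartment!r}")
        if self.upstream_region is not None and len(self.upstream_region) > 1000:
            raise ModelError(f"{self.gene_id}: upstream region exceeds 1 kb")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        return self.cds[1] - self.cds[0]

    @property
    def start_codon_pos(self) -> int:
        """Transcript position of the first nucleotide of the start codon."""
        return self.cds[0]

    def region(self, name: str) -> Interval:
        if name == "UTR5":
            return self.utr5
        if name == "CDS":
            return self.cds
        if name == "UTR3":
            return self.utr3
        if name == "full":
            return (0, self.length)
        raise KeyError(name)

    def region_of(self, pos: int) -> Optional[str]:
        """Region name containing transcript position ``pos`` (None if outside)."""
        for name in REGIONS:
            lo, hi = self.region(name)
            if lo <= pos < hi:
                return name
        return None

    def region_seq(self, name: str) -> str:
        lo, hi = self.region(name)
        return self.sequence[lo:hi]


@dataclass
class SampleReads:
    """Transcript-space read records for one sequencing sample.

    ``records`` columns: ``transcript_id`` (str), ``pos`` (0-based 5' end),
    ``length`` (nt, > 0). Reads may overhang the 3' transcript end; coverage
    computation clips them at the boundary.
    """

    sample_id: str
    assay: str
    condition: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.assay not in VALID_ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.condition not in VALID_CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        required = {"transcript_id", "pos", "length"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"reads table missing columns {sorted(missing)}")

    @property
    def total_reads(self) -> int:
        return int(len(self.records))


@dataclass
class CoverageTrack:
    """Per-position read depth for one transcript (length == transcript length)."""

    transcript_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be 1-D")
        if (self.depth < 0).any():
            raise ValueError("negative depth")
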
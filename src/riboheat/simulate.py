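"""Synthetic two-condition, two-replicate RNA-Seq/Ribo-Seq datasets with
planted ground truth for every downstream stage.

The generator emulates the study design the pipeline targets: control and
heat conditions, two biological replicates each, with both a total-RNA
assay and a ribosome-footprint (RPF) assay per sample. Gene-level counts
are negative binomial (``var = mu + alpha mu^2``); condition effects are
planted per regulation class (transcriptional fold change on the RNA
assay, transcriptional x translational-efficiency fold change on the RPF
assay). Read 5' positions are multinomial over the transcript, uniform
except for three planted coverage signals: a step increase downstream of
a change-point in the alternative-ORF gene's stress RPF sample, an
elevation over planted UTR G-quadruplex windows in the stress RPF
samples, and plastid subunit footprint densities proportional to declared
complex stoichiometry. Spike-ins with a known 2-fold concentration ladder
and a planted detection floor are added to the RNA samples only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import SampleReads, TranscriptModel
from .plastid import ComplexDefinition, write_complex_definitions
from .quadruplex import TIERS, scan_quadruplexes
from . import io as rio

DE_CLASSES = (
    "both_up", "both_down", "mrna_only_up", "mrna_only_down",
    "rpf_only_up", "rpf_only_down", "null",
)

SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
KR_CODONS = ("AAA", "AAG", "CGT", "CGC", "CGA", "CGG", "AGA", "AGG")

#: consensus heat-shock element planted in the alt-ORF gene's promoter
PLANTED_HSE = "AGAACGTTCT"


def default_plastid_complexes() -> list[ComplexDefinition]:
    """An ATP-synthase-like complex split over two operons, with a 3:1:1:1
    stoichiometry in the first operon (synthetic study conditions, not the
    organism's literature values)."""
    return [
        ComplexDefinition(
            name="ATP_synthase_like",
            subunits=(
                ("atpA", 3, "operon1"),
                ("atpE", 1, "operon1"),
                ("atpI", 1, "operon1"),
                ("atpH", 1, "operon1"),
                ("atpB", 1, "operon2"),
                ("atpF", 1, "operon2"),
            ),
        )
    ]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset. See docs/methods.md for
    the rationale behind each default."""

    seed: int = 0
    n_genes: int = 300
    utr5_len: tuple[int, int] = (140, 300)
    cds_len: tuple[int, int] = (300, 1500)
    utr3_len: tuple[int, int] = (100, 300)
    n_per_class: Optional[dict[str, int]] = None  # default: n_genes/15 per DE class
    lfc_effect: float = 1.0
    dispersion: float = 0.05
    depth: float = 200.0
    gene_mean_sigma: float = 0.5
    n_quadruplex_genes: Optional[dict[str, int]] = None  # default: scaled to null size
    quadruplex_tier: str = "G2"
    quadruplex_host_classes: tuple[str, ...] = ("null",)
    quadruplex_rpf_boost: float = 3.0
    quadruplex_boost_flank: tuple[int, int] = (-25, 75)
    altorf_gene: bool = True
    altorf_changepoint: int = 2195  # CDS-local
    altorf_cds_len: int = 2802
    altorf_peptide_len: int = 88
    altorf_positive_fraction: float = 0.4
    altorf_step_ratio: float = 12.0
    altorf_expression_factor: float = 4.0  # highly expressed, no fold change
    spikein_concentrations: tuple[float, ...] = tuple(
        float(2.0**k) for k in range(-4, 7)
    )
    spikein_floor: float = 2.0
    spikein_length: int = 150_000
    spikein_tech_cv: float = 0.12  # library-prep variability on spike counts
    plastid_complexes: list[ComplexDefinition] = field(
        default_factory=default_plastid_complexes
    )
    plastid_depth: float = 2000.0  # RPF reads per unit stoichiometry per sample
    plastid_cds_len: int = 600
    plastid_utr_len: int = 30
    plastid_rna_depth: float = 1500.0  # per-operon mRNA reads per subunit
    plastid_dispersion: float = 1e-3  # deep pooled fraction: near-Poisson
    n_plastid_singletons: int = 54  # plastid ORFs outside the declared complexes
    plastid_density_sigma: float = 1.0  # lognormal spread of singleton densities
    plastid_heat_scale: float = 0.7
    plastid_disproportionate_subunit: Optional[str] = "atpE"
    plastid_disproportionate_factor: float = 0.5
    library_size_jitter: tuple[float, float] = (0.8, 1.25)
    read_length: tuple[int, int] = (25, 35)
    abundance_noise_factor: float = 0.85  # x sd(log production), see docs
    max_rejection: int = 10_000

    def __post_init__(self) -> None:
        if self.n_per_class is None:
            per = max(self.n_genes // 15, 1)
            base = {c: per for c in DE_CLASSES if c != "null"}
            base["null"] = self.n_genes - sum(base.values())
            self.n_per_class = base
        if self.n_quadruplex_genes is None:
            budget = max(self.n_per_class.get("null", 0) - int(self.altorf_gene), 0)
            q = min(30, budget // 2)
            self.n_quadruplex_genes = {"UTR5": q, "UTR3": q} if q else {}
        missing = set(DE_CLASSES) - set(self.n_per_class)
        if missing:
            for c in missing:
                self.n_per_class[c] = 0
        if any(v < 0 for v in self.n_per_class.values()):
            raise ValueError("class sizes must be >= 0")
        if sum(self.n_per_class.values()) != self.n_genes:
            raise ValueError(
                f"class sizes sum to {sum(self.n_per_class.values())}, "
                f"expected n_genes={self.n_genes}"
            )
        if self.lfc_effect <= 0:
            raise ValueError("lfc_effect must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.altorf_gene:
            needed = self.altorf_changepoint + 60 + 3 * (self.altorf_peptide_len + 2)
            if self.altorf_cds_len < needed:
                raise ValueError(
                    "infeasible config: alt-ORF CDS too short for the planted "
                    f"change-point and peptide (need >= {needed} nt)"
                )
            if self.n_per_class.get("null", 0) < 1:
                raise ValueError("alt-ORF gene requires at least one null-class gene")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["plastid_complexes"] = [
            {"name": c["name"], "subunits": [list(s) for s in c["subunits"]]}
            for c in d["plastid_complexes"]
        ]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class GroundTruth:
    """Planted features, recoverable by every downstream module."""

    classes: dict[str, str]
    mrna_lfc: dict[str, float]
    rpf_lfc: dict[str, float]
    quadruplexes: dict[str, list[dict]]
    altorf: Optional[dict]
    spikein_floor: float
    complexes: list[ComplexDefinition]
    low_structure_genes: list[str]

    def to_json(self, path: str | Path) -> None:
        d = {
            "classes": self.classes,
            "mrna_lfc": self.mrna_lfc,
            "rpf_lfc": self.rpf_lfc,
            "quadruplexes": self.quadruplexes,
            "altorf": self.altorf,
            "spikein_floor": self.spikein_floor,
            "complexes": [
                {"name": c.name, "subunits": [list(s) for s in c.subunits]}
                for c in self.complexes
            ],
            "low_structure_genes": self.low_structure_genes,
        }
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["complexes"] = [
            ComplexDefinition(c["name"], tuple(tuple(s) for s in c["subunits"]))
            for c in d["complexes"]
        ]
        return cls(**d)


# ---------------------------------------------------------------------------
# Sequence generation helpers


def _random_seq(rng: np.random.Generator, n: int, probs=None) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))

AU_RICH = np.array([0.4, 0.1, 0.1, 0.4])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(SENSE_CODONS, size=n_codons - 2))
    return "ATG" + body + "TAA"


def _region_quadruplex_free(
    rng: np.random.Generator, make, tier: str, cap: int
) -> str:
    """Rejection-sample ``make(rng)`` until it has no hit of ``tier``."""
    for _ in range(cap):
        seq = make(rng)
        if not scan_quadruplexes(seq, tiers=(tier,)):
            return seq
    raise RuntimeError(
        f"rejection sampling failed to produce a {tier}-free sequence in {cap} tries"
    )


def _quadruplex_motif(rng: np.random.Generator, tier: str) -> str:
    run = "G" * TIERS[tier]
    loops = ["".join(rng.choice(list("ACT"), size=rng.integers(1, 4))) for _ in range(3)]
    return run + loops[0] + run + loops[1] + run + loops[2] + run


def _altorf_cds(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[str, int]:
    """CDS with an internal in-frame ORF: first in-frame ATG at/after the
    change-point, exactly ``altorf_peptide_len`` codons, then a stop."""
    n_codons = cfg.altorf_cds_len // 3
    codons = list(rng.choice(SENSE_CODONS, size=n_codons))
    codons[0] = "ATG"
    codons[-1] = "TAA"
    cp = cfg.altorf_changepoint
    alt_start = cp if cp % 3 == 0 else cp + (3 - cp % 3)
    ai = alt_start // 3
    # initiator Met, then peptide_len coding codons, then the stop
    stop_i = ai + cfg.altorf_peptide_len + 1
    # clear competing ATGs in the search window upstream of the planted start
    for i in range((cp - 30) // 3, ai):
        if 0 <= i < n_codons and codons[i] == "ATG":
            codons[i] = "GCT"
    codons[ai] = "ATG"
    # peptide body with the configured positively-charged fraction
    n_body = cfg.altorf_peptide_len
    n_kr = int(round(cfg.altorf_positive_fraction * cfg.altorf_peptide_len))
    body = [rng.choice(KR_CODONS) for _ in range(n_kr)]
    neutral = [c for c in SENSE_CODONS if c not in KR_CODONS]
    body += [rng.choice(neutral) for _ in range(n_body - n_kr)]
    rng.shuffle(body)
    codons[ai + 1: stop_i] = body
    codons[stop_i] = "TAA"
    # no stray stops between the alt start and its stop (sense codons only)
    return "".join(codons), alt_start


# ---------------------------------------------------------------------------
# Transcriptome generation


def generate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[TranscriptModel], GroundTruth]:
    """Build the toy transcriptome and its planted ground truth.

    Deterministic under a fixed seed. Background (non-quadruplex) genes
    are rejection-sampled so the planted tier has no match in any region
    where planting was requested; quadruplex genes carry >= 1 inserted
    motif in their assigned region. Translationally upregulated
    (``rpf_only_up``) genes draw an A/U-rich 5'UTR (the low-structure
    group); all other UTRs are uniform-composition.
    """
    rng = np.random.default_rng([config.seed, 0])
    n5 = dict(config.n_per_class)
    gene_classes: list[tuple[str, str]] = []
    i = 1
    for cls in DE_CLASSES:
        for _ in range(n5.get(cls, 0)):
            gene_classes.append((f"g{i:04d}", cls))
            i += 1
    classes = dict(gene_classes)

    tier = config.quadruplex_tier
    planted_regions = [r for r, n in config.n_quadruplex_genes.items() if n > 0]

    altorf_gid = None
    if config.altorf_gene:
        altorf_gid = next(g for g, c in gene_classes if c == "null")

    host_pool = [
        g for g, c in gene_classes
        if c in config.quadruplex_host_classes and g != altorf_gid
    ]
    hosts: dict[str, list[str]] = {}
    cursor = 0
    for region in planted_regions:
        n = config.n_quadruplex_genes[region]
        if cursor + n > len(host_pool):
            raise ValueError(
                "infeasible config: not enough host-class genes for the "
                "requested quadruplex planting"
            )
        hosts[region] = host_pool[cursor: cursor + n]
        cursor += n
    host_of: dict[str, str] = {
        g: region for region, gs in hosts.items() for g in gs
    }

    low_structure = [g for g, c in gene_classes if c == "rpf_only_up"]
    low_structure_set = set(low_structure)

    models: list[TranscriptModel] = []
    truth_quads: dict[str, list[dict]] = {}
    altorf_truth = None

    for gid, cls in gene_classes:
        L5 = int(rng.integers(config.utr5_len[0], config.utr5_len[1] + 1))
        L3 = int(rng.integers(config.utr3_len[0], config.utr3_len[1] + 1))
        if gid == altorf_gid:
            cds, alt_start = _altorf_cds(rng, config)
        else:
            n_codons = int(rng.integers(config.cds_len[0] // 3, config.cds_len[1] // 3 + 1))
            cds = _random_cds(rng, n_codons)

        utr_probs = AU_RICH if gid in low_structure_set else None

        def make_utr(length, probs):
            return lambda r: _random_seq(r, length, probs)

        region_seqs = {}
        for region, length, probs in (
            ("UTR5", L5, utr_probs), ("UTR3", L3, None)
        ):
            if region in planted_regions:
                region_seqs[region] = _region_quadruplex_free(
                    rng, make_utr(length, probs), tier, config.max_rejection
                )
            else:
                region_seqs[region] = _random_seq(rng, length, probs)
        if "CDS" in planted_regions and gid not in host_of:
            # background CDS must also be match-free when CDS planting is on
            n_cod = len(cds) // 3
            cds = _region_quadruplex_free(
                rng, lambda r: _random_cds(r, n_cod), tier, config.max_rejection
            ) if gid != altorf_gid else cds

        if gid in host_of:
            region = host_of[gid]
            motif = _quadruplex_motif(rng, tier)
            target = region_seqs[region] if region != "CDS" else cds
            if len(target) < len(motif) + 4:
                raise ValueError(f"infeasible config: {region} too short for motif")
            pos = int(rng.integers(1, len(target) - len(motif) - 1))
            planted = target[:pos] + motif + target[pos + len(motif):]
            # keep motif runs maximal: non-G flanks
            planted = (
                planted[: pos - 1]
                + ("A" if planted[pos - 1] == "G" else planted[pos - 1])
                + planted[pos: pos + len(motif)]
                + ("A" if planted[pos + len(motif)] == "G" else planted[pos + len(motif)])
                + planted[pos + len(motif) + 1:]
            )
            if region == "CDS":
                cds = planted
            else:
                region_seqs[region] = planted

        # a hit can straddle a region boundary even when each region is
        # clean in isolation: recheck the assembled transcript and resample
        # the offending background region until no hit starts there
        if gid != altorf_gid:
            for _ in range(config.max_rejection):
                seq_try = region_seqs["UTR5"] + cds + region_seqs["UTR3"]
                bounds = {
                    "UTR5": (0, L5),
                    "CDS": (L5, L5 + len(cds)),
                    "UTR3": (L5 + len(cds), len(seq_try)),
                }
                bad = None
                for h in scan_quadruplexes(seq_try, tiers=(tier,)):
                    for region in planted_regions:
                        lo, hi = bounds[region]
                        if lo <= h.start < hi and host_of.get(gid) != region:
                            bad = region
                            break
                    if bad:
                        break
                if bad is None:
                    break
                probs = AU_RICH if (gid in low_structure_set and bad == "UTR5") else None
                if bad == "CDS":
                    cds = _random_cds(rng, len(cds) // 3)
                else:
                    region_seqs[bad] = _random_seq(rng, len(region_seqs[bad]), probs)
            else:
                raise RuntimeError("could not clear boundary quadruplex hits")

        seq = region_seqs["UTR5"] + cds + region_seqs["UTR3"]
        upstream = None
        if gid == altorf_gid:
            up = _random_seq(rng, 1000)
            upstream = up[:700] + PLANTED_HSE + up[700 + len(PLANTED_HSE):]
        model = TranscriptModel(
            gene_id=gid,
            transcript_id=f"{gid}.1",
            sequence=seq,
            utr5=(0, L5),
            cds=(L5, L5 + len(cds)),
            utr3=(L5 + len(cds), len(seq)),
            upstream_region=upstream,
        )
        models.append(model)

        if gid in host_of:
            region = host_of[gid]
            found = [
                h for h in scan_quadruplexes(model, tiers=(tier,)) if h.region == region
            ]
            assert found, "planted motif must be recoverable by the scanner"
            truth_quads[gid] = [
                {"tier": h.tier, "region": h.region, "start": h.start, "end": h.end}
                for h in found
            ]
        if gid == altorf_gid:
            altorf_truth = {
                "gene_id": gid,
                "changepoint_cds": config.altorf_changepoint,
                "alt_start_cds": alt_start,
                "peptide_length": config.altorf_peptide_len,
                "changepoint_tx": L5 + config.altorf_changepoint,
            }

    # plastid genes: declared complex subunits plus free-standing ORFs
    def _plastid_model(gene_id: str, operon: Optional[str]) -> TranscriptModel:
        Lu = config.plastid_utr_len
        cds = _random_cds(rng, config.plastid_cds_len // 3)
        seq = _random_seq(rng, Lu) + cds + _random_seq(rng, Lu)
        return TranscriptModel(
            gene_id=gene_id,
            transcript_id=f"{gene_id}.1",
            sequence=seq,
            utr5=(0, Lu),
            cds=(Lu, Lu + len(cds)),
            utr3=(Lu + len(cds), len(seq)),
            compartment="plastid",
            operon_id=operon,
        )

    for cx in config.plastid_complexes:
        for gene_id, stoich, operon in cx.subunits:
            models.append(_plastid_model(gene_id, operon))
    for j in range(config.n_plastid_singletons):
        models.append(_plastid_model(f"pt{j + 1:03d}", None))

    mrna_lfc, rpf_lfc = {}, {}
    e = config.lfc_effect
    effect = {
        "both_up": (e, e), "both_down": (-e, -e),
        "mrna_only_up": (e, 0.0), "mrna_only_down": (-e, 0.0),
        "rpf_only_up": (0.0, e), "rpf_only_down": (0.0, -e),
        "null": (0.0, 0.0),
    }
    for gid, cls in gene_classes:
        mrna_lfc[gid], rpf_lfc[gid] = effect[cls]

    truth = GroundTruth(
        classes=classes,
        mrna_lfc=mrna_lfc,
        rpf_lfc=rpf_lfc,
        quadruplexes=truth_quads,
        altorf=altorf_truth,
        spikein_floor=config.spikein_floor,
        complexes=list(config.plastid_complexes),
        low_structure_genes=low_structure,
    )
    return models, truth


# ---------------------------------------------------------------------------
# Count and coverage simulation


def _nb_draw(rng: np.random.Generator, mean: float, alpha: float) -> int:
    if mean <= 0:
        return 0
    if alpha < 1e-6:
        return int(rng.poisson(mean))
    r = 1.0 / alpha
    return int(rng.negative_binomial(r, r / (r + mean)))


def _position_weights(
    model: TranscriptModel,
    truth: GroundTruth,
    config: SimulationConfig,
    assay: str,
    condition: str,
) -> Optional[np.ndarray]:
    """None means uniform. Planted coverage signals apply to stress RPF only."""
    if assay != "RPF" or condition != "heat":
        return None
    w = None
    if truth.altorf and truth.altorf["gene_id"] == model.gene_id:
        w = np.ones(model.length)
        w[model.cds[0] + truth.altorf["changepoint_cds"]:] *= config.altorf_step_ratio
    if model.gene_id in truth.quadruplexes and config.quadruplex_rpf_boost != 1.0:
        if w is None:
            w = np.ones(model.length)
        for q in truth.quadruplexes[model.gene_id]:
            lo = max(q["start"] + config.quadruplex_boost_flank[0], 0)
            hi = min(q["start"] + config.quadruplex_boost_flank[1], model.length)
            w[lo:hi] *= config.quadruplex_rpf_boost
    return w


def simulate_counts_and_coverage(
    models: Sequence[TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[list[SampleReads], pd.DataFrame]:
    """Simulate the 2 conditions x 2 replicates x 2 assays read samples
    plus the spike-in truth table.

    Returns 8 ``SampleReads`` (RNA/RPF x control/heat x replicates 1-2)
    and the spike-in table (spikein_id, concentration, length, one count
    column per RNA sample). Zero depth yields empty but well-formed
    samples.
    """
    rng = np.random.default_rng([config.seed, 1])
    nuclear = [m for m in models if m.compartment == "nuclear"]
    plastid = [m for m in models if m.compartment == "plastid"]
    stoich_of = {
        s[0]: s[1] for cx in truth.complexes for s in cx.subunits
    }
    operon_of = {m.gene_id: m.operon_id for m in plastid}

    base_mean = {
        m.gene_id: config.depth * rng.lognormal(0.0, config.gene_mean_sigma)
        for m in nuclear
    }
    if truth.altorf:
        base_mean[truth.altorf["gene_id"]] *= config.altorf_expression_factor
    # plastid ORFs outside the declared complexes: broad density spread
    singleton_density = {
        m.gene_id: float(rng.lognormal(0.0, config.plastid_density_sigma))
        for m in plastid
        if m.gene_id not in stoich_of
    }
    sample_plan = [
        (assay, cond, rep)
        for assay in ("RNA", "RPF")
        for cond in ("control", "heat")
        for rep in (1, 2)
    ]
    lib_factor = {
        f"{a}_{c}_{r}": float(rng.uniform(*config.library_size_jitter))
        for a, c, r in sample_plan
    }

    samples: list[SampleReads] = []
    spike_counts: dict[str, np.ndarray] = {}
    conc = np.asarray(config.spikein_concentrations, dtype=float)

    for assay, cond, rep in sample_plan:
        sid = f"{assay}_{cond}_{rep}"
        f = lib_factor[sid]
        tids, poss, lens = [], [], []
        for m in models:
            alpha = config.dispersion
            if m.compartment == "plastid":
                alpha = config.plastid_dispersion
                if assay == "RPF":
                    mean = config.plastid_depth * stoich_of.get(
                        m.gene_id, singleton_density.get(m.gene_id, 1.0)
                    )
                    if cond == "heat":
                        mean *= config.plastid_heat_scale
                        if m.gene_id == config.plastid_disproportionate_subunit:
                            mean *= config.plastid_disproportionate_factor
                else:
                    mean = config.plastid_rna_depth
            else:
                mean = base_mean[m.gene_id]
                if cond == "heat":
                    # rpf_lfc is the total footprint change (transcriptional
                    # x translational-efficiency components combined)
                    lfc = (
                        truth.rpf_lfc[m.gene_id] if assay == "RPF"
                        else truth.mrna_lfc[m.gene_id]
                    )
                    mean = mean * 2.0**lfc
            w = _position_weights(m, truth, config, assay, cond)
            if w is not None:
                # planted elevations add footprints: positions outside the
                # boosted windows keep their baseline expected density
                mean = mean * w.sum() / len(w)
            k = _nb_draw(rng, mean * f, alpha)
            if k == 0:
                continue
            if w is None:
                pos = rng.integers(0, m.length, size=k)
            else:
                pos = rng.choice(m.length, size=k, p=w / w.sum())
            tids.append(np.repeat(m.transcript_id, k))
            poss.append(pos)
            lens.append(
                rng.integers(config.read_length[0], config.read_length[1] + 1, size=k)
            )
        records = pd.DataFrame(
            {
                "transcript_id": np.concatenate(tids) if tids else np.array([], dtype=object),
                "pos": np.concatenate(poss) if poss else np.array([], dtype=np.int64),
                "length": np.concatenate(lens) if lens else np.array([], dtype=np.int64),
            }
        )
        samples.append(
            SampleReads(sample_id=sid, assay=assay, condition=cond, records=records)
        )
        if assay == "RNA":
            total = len(records)
            # below the planted floor detection drops out steeply
            expected_rpkm = np.where(
                conc >= config.spikein_floor,
                conc,
                conc * (conc / config.spikein_floor) ** 2,
            )
            expected_counts = (
                expected_rpkm * (config.spikein_length / 1e3) * (total / 1e6)
            )
            if config.spikein_tech_cv > 0:
                sigma = np.sqrt(np.log1p(config.spikein_tech_cv**2))
                expected_counts = expected_counts * rng.lognormal(
                    -(sigma**2) / 2, sigma, size=len(expected_counts)
                )
            spike_counts[sid] = rng.poisson(expected_counts)

    spike_table = pd.DataFrame(
        {
            "spikein_id": [f"spike{i:02d}" for i in range(len(conc))],
            "concentration": conc,
            "length": config.spikein_length,
        }
    )
    for sid, counts in spike_counts.items():
        spike_table[sid] = counts
    return samples, spike_table


def simulate_abundance(
    production: pd.Series, config: SimulationConfig, seed_stream: int = 2
) -> pd.Series:
    """Synthetic external protein-abundance table: production with
    multiplicative log-noise at ``abundance_noise_factor`` times the
    spread of log production (calibrated to the concordance magnitude the
    production proxy is expected to show against an orthogonal abundance
    measurement; see docs/methods.md)."""
    rng = np.random.default_rng([config.seed, seed_stream])
    logp = np.log(np.maximum(production.to_numpy(dtype=float), 1e-12))
    sd = float(np.std(logp)) * config.abundance_noise_factor
    noise = rng.normal(0.0, sd, size=len(logp))
    return pd.Series(np.exp(logp + noise), index=production.index, name="abundance")


# ---------------------------------------------------------------------------
# Dataset writing


def write_dataset(
    outdir: str | Path,
    models: Sequence[TranscriptModel],
    truth: GroundTruth,
    samples: Sequence[SampleReads],
    spike_table: pd.DataFrame,
    config: SimulationConfig,
) -> None:
    """Write the complete dataset: FASTA, GFF3, per-sample reads TSVs,
    spike-in truth TSV, complex definitions TSV, ground-truth JSON and the
    config YAML. Byte-identical across reruns with the same config."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rio.write_annotation(
        models, out / "annotation.gff3", out / "transcripts.fasta",
        out / "upstream.fasta",
    )
    for s in samples:
        rio.write_reads(s, out / f"reads_{s.sample_id}.tsv")
    spike_table.to_csv(out / "spikeins.tsv", sep="\t", index=False)
    write_complex_definitions(config.plastid_complexes, out / "complexes.tsv")
    truth.to_json(out / "ground_truth.json")
    config.to_yaml(out / "config.yaml")
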
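"""Protein-production estimates from ribosome-footprint density and
stoichiometry auditing of plastid multiprotein complexes.

The production proxy assumes each footprint corresponds to a ribosome
completing a protein: production = average footprint density over the CDS
(RPF rpkm). A translational-efficiency variant divides by mRNA rpkm; for
polycistronic operons the mRNA rpkm is computed per operon and shared by
its ORFs, so within-operon production ratios are unaffected by the shared
transcript level. Both columns are always emitted; ``mode`` selects the
headline one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import TranscriptModel
from .quantify import CountMatrix, normalize

TE_PSEUDOCOUNT_RPKM = 0.5


@dataclass(frozen=True)
class ComplexDefinition:
    """A protein complex: (gene_id, integer stoichiometry, operon id) per subunit."""

    name: str
    subunits: tuple[tuple[str, int, Optional[str]], ...]

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.subunits]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.name}: duplicate subunits")
        if any(s[1] < 1 for s in self.subunits):
            raise ValueError(f"{self.name}: stoichiometries must be >= 1")


def read_complex_definitions(path) -> list[ComplexDefinition]:
    """TSV columns: complex, gene_id, stoichiometry, operon (empty allowed)."""
    df = pd.read_csv(path, sep="\t", dtype={"operon": str})
    out = []
    for name, grp in df.groupby("complex", sort=False):
        subunits = tuple(
            (r["gene_id"], int(r["stoichiometry"]),
             r["operon"] if isinstance(r.get("operon"), str) and r["operon"] else None)
            for _, r in grp.iterrows()
        )
        out.append(ComplexDefinition(name=name, subunits=subunits))
    return out


def write_complex_definitions(complexes: Sequence[ComplexDefinition], path) -> None:
    rows = [
        {"complex": c.name, "gene_id": g, "stoichiometry": s, "operon": o or ""}
        for c in complexes for g, s, o in c.subunits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def protein_production(
    rpf_counts: CountMatrix,
    models: Sequence[TranscriptModel],
    rna_counts: Optional[CountMatrix] = None,
    mode: str = "rpf_rpkm",
    samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-gene protein-production values for plastid genes.

    ``rpf_rpkm``: footprint rpkm over the CDS, averaged over the selected
    samples. ``te``: that value divided by mRNA rpkm (+0.5 rpkm
    pseudocount), with operon genes sharing a per-operon mRNA rpkm. Both
    are emitted as columns ``rpf_rpkm`` and ``te``; ``production`` repeats
    the headline mode. te values resting on zero mRNA are flagged in
    ``te_unstable``.
    """
    plastid = [m for m in models if m.compartment == "plastid"]
    if not plastid:
        raise ValueError("no plastid genes flagged in the models")
    gids = [m.gene_id for m in plastid]
    cols = list(samples) if samples is not None else rpf_counts.samples
    rpf_rpkm = normalize(rpf_counts, "rpkm").loc[gids, cols].mean(axis=1)
    out = pd.DataFrame({"rpf_rpkm": rpf_rpkm})
    out["operon_id"] = [m.operon_id for m in plastid]
    if rna_counts is not None:
        rna_cols = [c for c in rna_counts.samples if samples is None or c in samples]
        if not rna_cols:
            rna_cols = rna_counts.samples
        mrna = normalize(rna_counts, "rpkm").loc[gids, rna_cols].mean(axis=1)
        operon_mrna = mrna.copy()
        for op, grp in out.groupby("operon_id", dropna=True).groups.items():
            operon_mrna.loc[grp] = mrna.loc[grp].mean()
        out["mrna_rpkm"] = operon_mrna
        out["te"] = out["rpf_rpkm"] / (operon_mrna + TE_PSEUDOCOUNT_RPKM)
        out["te_unstable"] = operon_mrna <= 0
    else:
        out["mrna_rpkm"] = np.nan
        out["te"] = np.nan
        out["te_unstable"] = True
    if mode not in ("rpf_rpkm", "te"):
        raise ValueError(f"unknown mode {mode!r}")
    out["production"] = out[mode]
    return out


@dataclass
class StoichiometryReport:
    complex_name: str
    table: pd.DataFrame  # per subunit: production per condition, ratios, expected
    concordance: dict[str, float]  # condition -> Spearman rho
    fold_changes: pd.Series  # heat / control per subunit
    disproportionate: bool
    flagged_subunits: list[str]
    skipped: bool = False
    reason: str = ""


def stoichiometry_audit(
    production_by_cond: Mapping[str, pd.Series],
    complexes: Sequence[ComplexDefinition],
    disproportion_fold: float = 1.75,
) -> list[StoichiometryReport]:
    """Audit each complex: do subunit production values track stoichiometry?

    Per complex and condition: production ratios normalized to the
    lowest-stoichiometry subunit, expected integer ratios, and Spearman
    rho between production and stoichiometry. Per-subunit heat/control
    fold changes; a complex whose subunit fold changes span more than
    ``disproportion_fold`` (max/min) is flagged disproportionate, with the
    subunits below max_fc / disproportion_fold named. The default sits
    below a strict 2-fold so that a subunit whose production halves — the
    canonical disproportionate response — is flagged despite counting
    noise, while remaining far above the ~10% spread proportional
    complexes show. Complexes with fewer than 2 quantified subunits are
    skipped with a reason.
    """
    reports = []
    for cx in complexes:
        gids = [s[0] for s in cx.subunits]
        stoich = pd.Series({s[0]: s[1] for s in cx.subunits})
        prod = {
            cond: vals.reindex(gids) for cond, vals in production_by_cond.items()
        }
        quantified = [
            g for g in gids
            if all(np.isfinite(p.get(g, np.nan)) and p.get(g, 0) > 0 for p in prod.values())
        ]
        if len(quantified) < 2:
            reports.append(
                StoichiometryReport(cx.name, pd.DataFrame(), {}, pd.Series(dtype=float),
                                    False, [], skipped=True,
                                    reason=f"only {len(quantified)} quantified subunits")
            )
            continue
        ref = stoich.loc[quantified].idxmin()
        table = pd.DataFrame({"stoichiometry": stoich.loc[quantified]})
        table["expected_ratio"] = stoich.loc[quantified] / stoich.loc[ref]
        concordance = {}
        for cond, vals in prod.items():
            v = vals.loc[quantified]
            table[f"production_{cond}"] = v
            table[f"ratio_{cond}"] = v / v.loc[ref]
            rho = stats.spearmanr(v.to_numpy(), stoich.loc[quantified].to_numpy()).statistic
            concordance[cond] = float(rho)
        if {"control", "heat"} <= set(prod):
            fc = prod["heat"].loc[quantified] / prod["control"].loc[quantified]
        else:
            fc = pd.Series(np.nan, index=quantified)
        fc_ok = fc.dropna()
        dispro = bool(len(fc_ok) >= 2 and fc_ok.max() / fc_ok.min() > disproportion_fold)
        flagged = (
            list(fc_ok.index[fc_ok < fc_ok.max() / disproportion_fold]) if dispro else []
        )
        table["fold_change"] = fc
        reports.append(
            StoichiometryReport(cx.name, table, concordance, fc, dispro, flagged)
        )
    return reports


def abundance_correlation(
    production: pd.Series, abundance: pd.Series, min_n: int = 5
) -> dict:
    """Spearman rho between footprint-based production and an external
    abundance table over the shared gene set; pairs table emitted.
    """
    shared = production.index.intersection(abundance.index)
    pairs = pd.DataFrame(
        {"production": production.loc[shared], "abundance": abundance.loc[shared]}
    )
    result = {"n": int(len(shared)), "pairs": pairs, "rho": np.nan, "low_n": False}
    if len(shared) >= 2:
        result["rho"] = float(
            stats.spearmanr(pairs["production"], pairs["abundance"]).statistic
        )
    if len(shared) < min_n:
        result["low_n"] = True
    return result
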
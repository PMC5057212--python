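"""Grammar scanner vs exhaustive run-quadruple enumeration, metaprofile
mechanics and the association/half-reads reports."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riboheat import quadruplex as quad
from riboheat.models import CoverageTrack, TranscriptModel


def oracle_anchor_map(seq: str, k: int) -> dict[int, set[int]]:
    """Exhaustive enumeration: for every quadruple of G-runs (length >= k)
    with all inter-run gaps in 1..7, record anchor -> possible ends."""
    runs = []
    i = 0
    while i < len(seq):
        if seq[i] == "G":
            j = i
            while j < len(seq) and seq[j] == "G":
                j += 1
            if j - i >= k:
                runs.append((i, j))
            i = j
        else:
            i += 1
    anchors: dict[int, set[int]] = {}
    for combo in itertools.combinations(range(len(runs)), 4):
        ok = all(
            1 <= runs[combo[t + 1]][0] - runs[combo[t]][1] <= 7 for t in range(3)
        )
        if ok:
            anchors.setdefault(runs[combo[0]][0], set()).add(runs[combo[3]][1])
    return anchors


class TestScanner:
    def test_minimal_g2_single_hit(self):
        hits = quad.scan_quadruplexes("GGAGGAGGAGG", tiers=("G2",))
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.sequence) == (0, 11, "GGAGGAGGAGG")

    def test_g3_also_matches_g2(self):
        hits = quad.scan_quadruplexes("GGGAGGGAGGGAGGG", tiers=("G2", "G3"))
        tiers = {h.tier for h in hits}
        assert "G3" in tiers and "G2" in tiers
        g3 = [h for h in hits if h.tier == "G3"]
        assert len(g3) == 1 and g3[0].start == 0

    def test_loop_longer_than_seven_rejected(self):
        assert quad.scan_quadruplexes("GG" + "A" * 8 + "GGAGGAGG", tiers=("G2",)) == []
        assert quad.scan_quadruplexes("GG" + "A" * 7 + "GGAGGAGG", tiers=("G2",)) != []

    def test_no_g4_in_plain_g2_repeat(self):
        assert quad.scan_quadruplexes("GGAGGAGGAGG", tiers=("G4",)) == []

    def test_region_assignment_by_start(self):
        seq = "GGAGGAGGAGG" + "A" * 19 + "ATG" + "A" * 27 + "TAAAAA"
        m = TranscriptModel(
            gene_id="g", transcript_id="g.1", sequence=seq,
            utr5=(0, 30), cds=(30, 63), utr3=(63, len(seq)),
        )
        hits = quad.scan_quadruplexes(m, tiers=("G2",))
        assert hits[0].region == "UTR5"

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet="GGGACT", min_size=0, max_size=120))
    def test_equals_exhaustive_enumeration(self, seq):
        """Scanner anchors equal the exhaustive enumeration for every tier,
        and each reported hit is one of the valid chains from its anchor."""
        for tier, k in (("G2", 2), ("G3", 3), ("G4", 4)):
            oracle = oracle_anchor_map(seq, k)
            hits = quad.scan_quadruplexes(seq, tiers=(tier,))
            assert {h.start for h in hits} == set(oracle)
            for h in hits:
                assert h.end in oracle[h.start]

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.text(alphabet="GGACT", min_size=0, max_size=150))
    def test_tier_containment(self, seq):
        """Every G4 anchor is a G3 anchor; every G3 anchor is a G2 anchor."""
        a = {
            t: {h.start for h in quad.scan_quadruplexes(seq, tiers=(t,))}
            for t in ("G2", "G3", "G4")
        }
        assert a["G4"] <= a["G3"] <= a["G2"]

    def test_all_matches_mode_superset(self):
        seq = "GGAGGAGGAGGAGG"
        lazy = quad.scan_quadruplexes(seq, tiers=("G2",))
        full = quad.scan_quadruplexes(seq, tiers=("G2",), all_matches=True)
        assert {(h.start, h.end) for h in lazy} <= {(h.start, h.end) for h in full}
        assert len(full) >= len(lazy)


def _uniform_setup(rpf_depth, rna_depth, n_genes=1, length=800, hit_start=300):
    models, hits, rpf, rna = [], [], {}, {}
    for i in range(n_genes):
        g = f"g{i}"
        m = TranscriptModel(
            gene_id=g, transcript_id=f"{g}.1", sequence="A" * length,
            utr5=(0, 350), cds=(350, 650), utr3=(650, length),
        )
        models.append(m)
        hits.append(quad.QuadruplexHit(g, "G2", "UTR5", hit_start, hit_start + 11, ""))
        rpf[f"{g}.1"] = CoverageTrack(f"{g}.1", np.full(length, rpf_depth))
        rna[f"{g}.1"] = CoverageTrack(f"{g}.1", np.full(length, rna_depth))
    return models, hits, rpf, rna


class TestFlankMetaprofile:
    def test_identical_conditions_p_one(self):
        models, hits, rpf, rna = _uniform_setup(10, 5)
        mp = quad.flank_metaprofile(
            hits, models,
            {"control": rpf, "heat": rpf},
            {"control": rna, "heat": rna},
            {"control": 1e6, "heat": 1e6},
        )
        assert mp.pvalue == 1.0

    def test_constant_ratio_flat_profile(self):
        """Uniform RPF 10 over RNA 5 gives a flat curve at 2x rpm scale."""
        models, hits, rpf, rna = _uniform_setup(10, 5)
        mp = quad.flank_metaprofile(
            hits, models, {"control": rpf, "heat": rpf},
            {"control": rna, "heat": rna}, {"control": 1e6, "heat": 1e6},
            gene_normalize=False,
        )
        expected = (10 * 1e6 / 1e6) / 5
        assert np.allclose(mp.mean_control, expected)
        assert mp.n_genes == 1

    def test_duplicated_gene_set_idempotent(self):
        """Equal gene weighting: duplicating every hit leaves the curve."""
        models, hits, rpf, rna = _uniform_setup(8, 4, n_genes=3)
        args = (
            {"control": rpf, "heat": rpf}, {"control": rna, "heat": rna},
            {"control": 1e6, "heat": 1e6},
        )
        single = quad.flank_metaprofile(hits, models, *args)
        doubled = quad.flank_metaprofile(hits + hits, models, *args)
        np.testing.assert_allclose(single.mean_control, doubled.mean_control)

    def test_positions_outside_transcript_excluded(self):
        models, hits, rpf, rna = _uniform_setup(10, 5, hit_start=50)
        mp = quad.flank_metaprofile(
            hits, models, {"control": rpf, "heat": rpf},
            {"control": rna, "heat": rna}, {"control": 1e6, "heat": 1e6},
        )
        assert np.isnan(mp.mean_control[0])  # position -200 < transcript start
        assert np.isfinite(mp.mean_control[200])

    def test_empty_hit_set(self):
        mp = quad.flank_metaprofile(
            [], [], {"control": {}, "heat": {}}, {"control": {}, "heat": {}},
            {"control": 1.0, "heat": 1.0},
        )
        assert mp.n_genes == 0 and np.isnan(mp.pvalue)


class TestAssociation:
    def _records(self, rows):
        df = pd.DataFrame(
            rows, columns=["log2fc_rpf", "padj_rpf"],
            index=[f"g{i}" for i in range(len(rows))],
        )
        return df

    def _hits(self, genes, region="UTR5"):
        return [quad.QuadruplexHit(g, "G2", region, 0, 11, "") for g in genes]

    def test_planted_up_genes_captured(self):
        rec = self._records([(2.0, 0.01), (1.5, 0.02), (0.0, 0.9), (-1.0, 0.5)])
        out = quad.quadruplex_fold_change_association(self._hits(rec.index), rec)
        assert set(out["up_genes"]) == {"g0", "g1"}
        assert set(out["rest_genes"]) == {"g2", "g3"}

    def test_no_quadruplex_genes(self):
        rec = self._records([(2.0, 0.01)])
        out = quad.quadruplex_fold_change_association([], rec)
        assert out["n_up"] == 0 and out["n_rest"] == 0 and np.isnan(out["pvalue"])

    def test_identical_distributions_nonsignificant(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(1.0, 0.2, 40)
        rows = [(v, 0.01 if i < 20 else 0.01) for i, v in enumerate(vals)]
        rec = self._records(rows)
        # force the split by padj: half up (sig, positive), half sig but negative
        rec.iloc[20:, 0] = -rec.iloc[20:, 0]
        out = quad.quadruplex_fold_change_association(self._hits(rec.index), rec)
        assert out["n_up"] == 20 and out["n_rest"] == 20


class TestUtr3HalfReads:
    def _sym(self, genes, fracs):
        return pd.DataFrame(
            {"gene_id": genes, "assay": "RNA", "first_fraction": fracs}
        )

    def test_identical_conditions(self):
        genes = [f"g{i}" for i in range(10)]
        hits = [quad.QuadruplexHit(g, "G2", "UTR3", 0, 11, "") for g in genes]
        sym = self._sym(genes, np.linspace(0.4, 0.6, 10))
        out = quad.utr3_half_reads_check(hits, {"control": sym, "heat": sym})
        assert out["pvalue"] == 1.0 and out["n"] == 10

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(50)]
        hits = [quad.QuadruplexHit(g, "G2", "UTR3", 0, 11, "") for g in genes]
        ctl = self._sym(genes, np.clip(rng.normal(0.5, 0.03, 50), 0, 1))
        heat = self._sym(genes, np.clip(rng.normal(0.42, 0.03, 50), 0, 1))
        out = quad.utr3_half_reads_check(hits, {"control": ctl, "heat": heat})
        assert out["pvalue"] < 0.05
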
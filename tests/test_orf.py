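"""Asymmetry screening, change-point localisation, alternative-ORF calls,
promoter-element scanning and UTR footprint-gain selection."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from riboheat import orf
from riboheat.models import TranscriptModel


def sym_table(fracs):
    return pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(len(fracs))], "assay": "RPF",
         "first_half": 0, "second_half": 0, "total": 100,
         "first_fraction": fracs}
    )


class TestAsymmetryOutliers:
    def test_single_extreme_gene_flagged(self):
        rng = np.random.default_rng(0)
        fracs = list(np.clip(rng.normal(0.5, 0.02, 30), 0, 1)) + [0.05]
        out = orf.asymmetry_outliers(sym_table(fracs))
        assert list(out["gene_id"]) == ["g30"]
        assert out.iloc[0]["direction"] == "second_half"

    def test_requires_twenty_genes(self):
        with pytest.raises(ValueError):
            orf.asymmetry_outliers(sym_table([0.5] * 10))

    def test_zero_mad_falls_back_to_sd(self):
        fracs = [0.5] * 25 + [0.9]
        out = orf.asymmetry_outliers(sym_table(fracs))
        assert "g25" in list(out["gene_id"])

    def test_all_identical_no_outliers(self):
        out = orf.asymmetry_outliers(sym_table([0.5] * 25))
        assert len(out) == 0

    def test_specificity_without_planted_asymmetry(self):
        """Binomial-only cohorts rarely produce |z| > 4 flags."""
        runs_with_flags = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            fracs = rng.binomial(200, 0.5, size=60) / 200
            if len(orf.asymmetry_outliers(sym_table(fracs))) > 0:
                runs_with_flags += 1
        assert runs_with_flags <= 3


class TestChangepoint:
    def test_planted_step_localised(self):
        """A 2 -> 20 step at position 2195 with Poisson noise is recovered
        within +/- 15 nt."""
        errs = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.poisson(2, 2195), rng.poisson(20, 605)])
            cp = orf.find_changepoint(x)
            errs.append(abs(cp.position - 2195))
            assert not cp.no_step
            assert cp.step_ratio == pytest.approx(10.0, rel=0.3)
        assert np.median(errs) <= 15

    def test_flat_coverage_flagged_no_step(self):
        cp = orf.find_changepoint(np.full(500, 7.0))
        assert cp.no_step
        assert cp.step_ratio == pytest.approx(1.0, abs=0.05)

    def test_step_near_edge(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.poisson(2, 10), rng.poisson(40, 2790)])
        cp = orf.find_changepoint(x)
        assert abs(cp.position - 10) <= 15

    def test_short_region_rejected(self):
        with pytest.raises(ValueError):
            orf.find_changepoint(np.ones(100))

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            orf.find_changepoint(np.zeros(300))


def _model_with_cds(cds: str, utr5: int = 20, utr3: int = 20) -> TranscriptModel:
    seq = "A" * utr5 + cds + "C" * utr3
    return TranscriptModel(
        gene_id="g1", transcript_id="g1.1", sequence=seq,
        utr5=(0, utr5), cds=(utr5, utr5 + len(cds)),
        utr3=(utr5 + len(cds), len(seq)),
    )


class TestCallAltOrf:
    def test_planted_orf_translated_to_planted_stop(self, small_transcriptome):
        """On the generator's planted gene the call reproduces the planted
        peptide exactly, as verified by independent re-translation."""
        models, truth = small_transcriptome
        alt = truth.altorf
        m = {x.gene_id: x for x in models}[alt["gene_id"]]
        call = orf.call_alt_orf(m, alt["changepoint_cds"])
        assert call.accepted
        assert call.alt_start == alt["alt_start_cds"]
        assert call.peptide_length == alt["peptide_length"] == 88
        cds = m.region_seq("CDS")
        independent = str(
            Seq(cds[call.alt_start + 3: call.alt_start + 3 + 3 * (88 + 1)]).translate()
        )
        assert independent == call.peptide + "*"
        recount = sum(1 for c in call.peptide if c in "KR") / len(call.peptide)
        assert call.positive_fraction == pytest.approx(recount)

    def test_immediate_stop_zero_length(self):
        cds = "ATG" + "AAA" * 30 + "ATGTAA" + "AAA" * 10 + "TAA"
        m = _model_with_cds(cds)
        call = orf.call_alt_orf(m, 93, search_slack=(0, 6))
        assert call.accepted and call.peptide_length == 0

    def test_no_atg_in_window_rejected(self):
        cds = "ATG" + "AAA" * 40 + "TAA"
        call = orf.call_alt_orf(_model_with_cds(cds), 60)
        assert not call.accepted and "no in-frame ATG" in call.reason

    def test_no_stop_runs_to_cds_end(self):
        cds = "ATG" + "AAA" * 10 + "ATG" + "AAA" * 10 + "TGG"
        call = orf.call_alt_orf(_model_with_cds(cds), 33, search_slack=(0, 3))
        assert call.accepted and "no in-frame stop" in call.reason
        assert call.peptide_length == 11

    def test_changepoint_outside_cds_rejected(self):
        call = orf.call_alt_orf(_model_with_cds("ATG" + "AAA" * 10 + "TAA"), 500)
        assert not call.accepted


def brute_force_element_scan(seq, element, max_mm=0):
    comp = str.maketrans("ACGTN", "TGCAN")
    out = []
    for pattern, strand in ((element, "+"), (element.translate(comp)[::-1], "-")):
        for i in range(len(seq) - len(pattern) + 1):
            mm = sum(
                1 for a, b in zip(seq[i: i + len(pattern)], pattern)
                if b != "N" and a != b
            )
            if mm <= max_mm:
                out.append((i, strand))
    return sorted(out)


class TestPromoterScan:
    def test_exact_consensus_found_both_strands(self):
        """AGAAnnTTCT is its own reverse-complement consensus, so an exact
        occurrence is a hit on both strands at the same position."""
        seq = "T" * 100 + "AGAACGTTCT" + "T" * 100
        out = orf.promoter_element_scan(seq)
        assert list(out["position"]) == [100, 100]
        assert set(out["strand"]) == {"+", "-"}

    def test_reverse_complement_reported_minus(self):
        """An element with fixed (asymmetric) wildcard bases embedded as its
        reverse complement is reported on the minus strand."""
        elem = "AGAAGGTTCT"
        rc = str(Seq(elem).reverse_complement())
        seq = "T" * 50 + rc + "T" * 50
        out = orf.promoter_element_scan(seq, element=elem.replace("GG", "GG"))
        minus = out[out["strand"] == "-"]
        assert 50 in list(minus["position"])

    def test_equals_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 300))
            got = sorted(
                (int(r["position"]), r["strand"])
                for _, r in orf.promoter_element_scan(seq, max_mismatch=1).iterrows()
            )
            assert got == brute_force_element_scan(seq, orf.HSE_CONSENSUS, 1)

    def test_null_match_rate_matches_analytics(self):
        """Random 1-kb sequence: ~2 * 991 / 4^8 expected matches; observed
        mean over seeded sequences within 3 SD."""
        rng = np.random.default_rng(4)
        n_seqs = 1500
        lam = 2 * 991 * 0.25**8
        counts = [
            len(orf.promoter_element_scan("".join(rng.choice(list("ACGT"), 1000))))
            for _ in range(n_seqs)
        ]
        assert abs(np.mean(counts) - lam) < 3 * np.sqrt(lam / n_seqs)

    def test_planted_hse_in_simulated_promoter(self, small_transcriptome):
        models, truth = small_transcriptome
        m = {x.gene_id: x for x in models}[truth.altorf["gene_id"]]
        out = orf.promoter_element_scan(m.upstream_region)
        assert 700 in list(out["position"])


class TestUtrGainSelection:
    def _setup(self):
        ms = []
        for i in range(6):
            g = f"g{i}"
            ms.append(TranscriptModel(
                gene_id=g, transcript_id=f"{g}.1", sequence="ACGT" * 60,
                utr5=(0, 60), cds=(60, 180), utr3=(180, 240),
            ))
        return ms

    def test_planted_gains_selected(self, tmp_path):
        ms = self._setup()
        ctl = pd.Series({f"g{i}": 10 for i in range(6)})
        heat = ctl.copy()
        heat[["g1", "g3"]] = 100
        out = orf.select_utr_rpf_gain_genes(
            {"control": ctl, "heat": heat}, {"control": 1e6, "heat": 1e6},
            ms, candidate_genes=[f"g{i}" for i in range(6)],
            fasta_path=tmp_path / "utr.fa", metadata_path=tmp_path / "meta.yaml",
        )
        assert sorted(out["gene_id"]) == ["g1", "g3"]
        assert (tmp_path / "utr.fa").exists()
        assert "MEME" in (tmp_path / "meta.yaml").read_text()

    def test_zero_reads_empty(self):
        ms = self._setup()
        zero = pd.Series(0, index=[m.gene_id for m in ms])
        out = orf.select_utr_rpf_gain_genes(
            {"control": zero, "heat": zero}, {"control": 1e6, "heat": 1e6},
            ms, candidate_genes=[m.gene_id for m in ms],
        )
        assert len(out) == 0

    def test_unit_threshold_passes_all_with_min_reads(self):
        ms = self._setup()
        ctl = pd.Series({f"g{i}": 20 for i in range(6)})
        out = orf.select_utr_rpf_gain_genes(
            {"control": ctl, "heat": ctl}, {"control": 1e6, "heat": 1e6},
            ms, candidate_genes=[f"g{i}" for i in range(6)], fold_threshold=1.0,
        )
        assert len(out) == 6
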
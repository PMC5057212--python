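"""Counting rules, normalisation units, spike-in detection limits and the
half-transcript symmetry statistic."""

import numpy as np
import pandas as pd
import pytest

from riboheat import quantify
from riboheat.models import SampleReads, TranscriptModel


def model(gene="g1", utr5=30, cds=300, utr3=30):
    n = utr5 + cds + utr3
    return TranscriptModel(
        gene_id=gene, transcript_id=f"{gene}.1", sequence="A" * n,
        utr5=(0, utr5), cds=(utr5, utr5 + cds), utr3=(utr5 + cds, n),
    )


def reads(rows, assay="RPF", condition="heat"):
    return SampleReads(
        sample_id=f"{assay}_{condition}_1", assay=assay, condition=condition,
        records=pd.DataFrame(rows, columns=["transcript_id", "pos", "length"]),
    )


class TestCounting:
    def test_midpoint_in_region(self):
        m = model(utr5=0, cds=300, utr3=30)
        col = quantify.count_reads(reads([("g1.1", 10, 30)]), [m], "CDS")
        assert col["g1"] == 1

    def test_boundary_read_assigned_once(self):
        """A read straddling the UTR5/CDS boundary counts only where its
        midpoint falls."""
        m = model(utr5=30, cds=300, utr3=30)
        r = reads([("g1.1", 20, 30)])  # midpoint 35: CDS
        assert quantify.count_reads(r, [m], "CDS")["g1"] == 1
        assert quantify.count_reads(r, [m], "UTR5")["g1"] == 0
        r2 = reads([("g1.1", 10, 30)])  # midpoint 25: UTR5
        assert quantify.count_reads(r2, [m], "CDS")["g1"] == 0
        assert quantify.count_reads(r2, [m], "UTR5")["g1"] == 1

    def test_partition_consistency_against_brute_force(self):
        """UTR5+CDS+UTR3 counts equal full counts, and each matches an
        explicit per-read re-scan."""
        rng = np.random.default_rng(11)
        ms = [model("g1"), model("g2", utr5=50, cds=600, utr3=80)]
        lens = {m.transcript_id: m.length for m in ms}
        rows = []
        for tid, L in lens.items():
            pos = rng.integers(0, L, 500)
            rl = rng.integers(25, 36, 500)
            rows += [(tid, int(p), int(l)) for p, l in zip(pos, rl)]
        r = reads(rows)
        by_region = {
            reg: quantify.count_reads(r, ms, reg)
            for reg in ("UTR5", "CDS", "UTR3", "full")
        }
        model_map = {m.transcript_id: m for m in ms}
        brute = {reg: {"g1": 0, "g2": 0} for reg in ("UTR5", "CDS", "UTR3", "full")}
        for tid, p, l in rows:
            m = model_map[tid]
            mid = p + l // 2
            for reg in brute:
                lo, hi = m.region(reg)
                if lo <= mid < hi:
                    brute[reg][m.gene_id] += 1
        for reg, col in by_region.items():
            assert col.to_dict() == brute[reg]
        total = by_region["UTR5"] + by_region["CDS"] + by_region["UTR3"]
        pd.testing.assert_series_equal(total, by_region["full"], check_names=False)


class TestNormalize:
    def _cm(self, counts, totals, lengths):
        return quantify.CountMatrix(
            counts=pd.DataFrame(counts), totals=pd.Series(totals),
            lengths=pd.Series(lengths),
        )

    def test_unit_definitions(self):
        cm = self._cm({"s1": {"g": 50}}, {"s1": 10**6}, {"g": 1000})
        assert quantify.normalize(cm, "rpm").loc["g", "s1"] == pytest.approx(50)
        assert quantify.normalize(cm, "rpkm").loc["g", "s1"] == pytest.approx(50)

    def test_scale_invariance(self):
        cm1 = self._cm({"s1": {"g": 50, "h": 10}}, {"s1": 1000}, {"g": 500, "h": 2000})
        cm2 = self._cm({"s1": {"g": 100, "h": 20}}, {"s1": 2000}, {"g": 500, "h": 2000})
        pd.testing.assert_frame_equal(
            quantify.normalize(cm1, "rpm"), quantify.normalize(cm2, "rpm")
        )

    def test_rpm_column_sum_oracle(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, (20, 3)), columns=list("abc"))
        totals = pd.Series({"a": 5000, "b": 7000, "c": 9000})
        cm = self._cm(counts, totals, pd.Series(1000, index=counts.index))
        rpm = quantify.normalize(cm, "rpm")
        expected = counts.sum() / totals * 1e6
        pd.testing.assert_series_equal(rpm.sum(), expected)

    def test_zero_total_is_error(self):
        cm = self._cm({"s1": {"g": 0}}, {"s1": 0}, {"g": 1000})
        with pytest.raises(ValueError, match="s1"):
            quantify.normalize(cm)


class TestDetectionLimit:
    def _table(self, conc, obs):
        df = pd.DataFrame({
            "spikein_id": [f"s{i}" for i in range(len(conc))],
            "concentration": conc,
        })
        df["RNA_control_1"] = obs
        return df

    def test_perfect_ladder_reaches_bottom(self):
        conc = [2.0**k for k in range(-2, 8)]
        out = quantify.detection_limit(self._table(conc, conc))
        assert out.loc[0, "threshold_rpkm"] == pytest.approx(min(conc))
        assert out.loc[0, "flag"] == "ok"

    def test_all_zero_sample_flagged(self):
        conc = [2.0**k for k in range(-2, 8)]
        df = self._table(conc, conc)
        df["RNA_heat_1"] = 0.0
        out = quantify.detection_limit(df).set_index("sample")
        assert out.loc["RNA_heat_1", "flag"] == "all_zero"
        assert np.isnan(out.loc["RNA_heat_1", "threshold_rpkm"])
        assert out.loc["RNA_control_1", "flag"] == "ok"

    def test_planted_floor_recovered_within_one_step(self):
        """Over seeded noisy ladders with dropout below a planted floor the
        median recovered threshold error is at most one 2-fold step."""
        conc = np.array([2.0**k for k in range(-4, 7)])
        floor = 2.0
        errors = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            expected = np.where(conc >= floor, conc, conc * (conc / floor) ** 2)
            scale = 40.0  # counts per rpkm
            obs = rng.poisson(expected * scale) / scale
            out = quantify.detection_limit(self._table(conc, obs))
            thr = out.loc[0, "threshold_rpkm"]
            errors.append(abs(np.log2(max(thr, 1e-6)) - np.log2(floor)))
        assert np.median(errors) <= 1.0

    def test_short_ladder_rejected(self):
        with pytest.raises(ValueError):
            quantify.detection_limit(self._table([1, 2, 4], [1, 2, 4]))


class TestHalfSymmetry:
    def test_uniform_reads_near_half(self):
        rng = np.random.default_rng(2)
        m = model(utr5=0, cds=300, utr3=0)
        rows = [("g1.1", int(p), 1) for p in rng.integers(0, 300, 400)]
        out = quantify.half_symmetry(reads(rows), [m], min_reads=32)
        frac = out.loc[0, "first_fraction"]
        # binomial(400, .5) 4-sigma band
        assert abs(frac - 0.5) < 4 * 0.5 / np.sqrt(400)

    def test_all_reads_first_half(self):
        m = model(utr5=0, cds=300, utr3=0)
        rows = [("g1.1", 0, 1)] * 40
        out = quantify.half_symmetry(reads(rows), [m])
        assert out.loc[0, "first_fraction"] == 1.0

    def test_odd_cds_first_half_shorter(self):
        """On a CDS of odd half-split the boundary read falls second-half."""
        m = TranscriptModel(
            gene_id="g1", transcript_id="g1.1", sequence="A" * 9,
            utr5=(0, 0), cds=(0, 9), utr3=(9, 9),
        )
        rows = [("g1.1", 4, 1)] * 40  # midpoint 4 == floor(9/2): second half
        out = quantify.half_symmetry(reads(rows), [m], min_reads=10)
        assert out.loc[0, "second_half"] == 40

    def test_low_coverage_genes_excluded(self):
        m = model(utr5=0, cds=300, utr3=0)
        out = quantify.half_symmetry(reads([("g1.1", 0, 1)] * 10), [m], min_reads=32)
        assert len(out) == 0
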
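"""Stage 1: eRNA filtering, activation calls, CNV enrichment, methylation."""

import numpy as np
import pandas as pd
import pytest

from secircuit import io as gio
from secircuit.activation import (
    call_activated_ses,
    call_differential_methylation,
    cnv_enrichment,
    filter_erna,
)


def _matrix(values, n_cancer, prefix="f"):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    cols = [f"C{i}" for i in range(n_cancer)] + [f"N{i}" for i in range(n - n_cancer)]
    labels = {c: ("cancer" if c.startswith("C") else "normal") for c in cols}
    df = pd.DataFrame(values, index=[f"{prefix}{i}" for i in range(values.shape[0])], columns=cols)
    return gio.LabeledMatrix(df, labels)


class TestFilterErna:
    def test_zero_fraction_boundary(self):
        n = 100
        row_71 = np.r_[np.zeros(71), np.ones(29)]
        row_70 = np.r_[np.zeros(70), np.ones(30)]
        m = _matrix([row_71, row_70], 50)
        out = filter_erna(m)
        assert out.row_ids == ["f1"]
        assert out.removed_rows == ["f0"]

    def test_counts_match_brute_force(self, rng):
        vals = rng.random(size=(60, 40))
        vals[rng.random(size=vals.shape) < 0.6] = 0.0
        m = _matrix(vals, 20)
        out = filter_erna(m)
        expected = [
            f"f{i}" for i in range(60) if (vals[i] == 0).mean() <= 0.7
        ]
        assert out.row_ids == expected

    def test_nan_not_counted_as_zero(self):
        row = np.r_[np.full(71, np.nan), np.ones(29)]
        m = _matrix([row], 50)
        assert filter_erna(m).row_ids == ["f0"]


class TestCallActivatedSes:
    def _setup(self, rng, shift):
        ses = [
            gio.GenomicInterval("chr1", 0, 1000, "SE_A"),
            gio.GenomicInterval("chr1", 2000, 3000, "SE_B"),
        ]
        loci = [
            gio.GenomicInterval("chr1", 100, 200, "e1"),
            gio.GenomicInterval("chr1", 300, 400, "e2"),
            gio.GenomicInterval("chr1", 2100, 2200, "e3"),
        ]
        base = rng.normal(3, 1, size=(3, 100))
        base[:2, :50] += shift  # SE_A eRNAs up in cancer
        return ses, loci, _matrix(2.0 ** base, 50, prefix="ignored"), base

    def test_planted_shift_recovered(self, rng):
        ses, loci, m, _ = self._setup(rng, 1.5)
        m.values.index = ["e1", "e2", "e3"]
        calls, activated = call_activated_ses(m, loci, ses)
        assert activated == ["SE_A"]
        up = {c.erna_id for c in calls if c.up_regulated}
        assert up == {"e1", "e2"}

    def test_up_flag_matches_q_threshold(self, rng):
        ses, loci, m, _ = self._setup(rng, 0.8)
        m.values.index = ["e1", "e2", "e3"]
        calls, _ = call_activated_ses(m, loci, ses, q_thresh=0.05)
        for c in calls:
            assert c.up_regulated == (c.summary.q_value < 0.05)
            assert c.summary.q_value >= c.summary.p_value - 1e-12

    def test_unmapped_erna_dropped(self, rng):
        ses, loci, m, _ = self._setup(rng, 1.5)
        loci[2] = gio.GenomicInterval("chr1", 5000, 5100, "e3")  # outside any SE
        m.values.index = ["e1", "e2", "e3"]
        calls, _ = call_activated_ses(m, loci, ses)
        assert {c.erna_id for c in calls} == {"e1", "e2"}

    def test_invariant_under_sample_permutation(self, rng):
        ses, loci, m, _ = self._setup(rng, 1.2)
        m.values.index = ["e1", "e2", "e3"]
        _, act1 = call_activated_ses(m, loci, ses)
        perm = rng.permutation(m.values.columns)
        m2 = gio.LabeledMatrix(m.values[perm], m.sample_labels)
        _, act2 = call_activated_ses(m2, loci, ses)
        assert act1 == act2


class TestCnvEnrichment:
    def _regions(self, n, offset=0, name="R"):
        return [gio.GenomicInterval("chr1", offset + i * 1000, offset + i * 1000 + 500, f"{name}{i}") for i in range(n)]

    def test_planted_amplification_enriched(self):
        ses = self._regions(20, name="SE")
        rand = self._regions(20, offset=100_000, name="RND")
        seg = pd.DataFrame(
            {
                "sample": ["s1"] * 15,
                "chrom": ["chr1"] * 15,
                "start": [i * 1000 for i in range(15)],
                "end": [i * 1000 + 400 for i in range(15)],
                "log2_ratio": [1.5] * 15,
            }
        )
        res = cnv_enrichment(seg, ses, rand)
        assert res.amp_odds_ratio > 10 and res.amp_p < 0.01

    def test_identical_profiles_odds_near_one(self):
        ses = self._regions(10, name="SE")
        rand = self._regions(10, offset=100_000, name="RND")
        rows = []
        for regions in (ses, rand):
            for r in regions[:5]:
                rows.append(("s1", "chr1", r.start, r.end, 1.2))
        seg = pd.DataFrame(rows, columns=gio.SEG_COLUMNS)
        res = cnv_enrichment(seg, ses, rand)
        assert res.amp_odds_ratio == pytest.approx(1.0)

    def test_classification_cut_is_strict(self):
        ses = self._regions(5, name="SE")
        rand = self._regions(5, offset=100_000, name="RND")
        seg = pd.DataFrame([("s1", "chr1", 0, 400, 0.8)], columns=gio.SEG_COLUMNS)
        res = cnv_enrichment(seg, ses, rand, log2_cut=0.8)
        assert res.n_amp_segments == 0 and res.degenerate

    def test_no_segments_flagged(self):
        ses = self._regions(5, name="SE")
        rand = self._regions(5, offset=100_000, name="RND")
        seg = pd.DataFrame([("s1", "chr1", 0, 400, 0.1)], columns=gio.SEG_COLUMNS)
        res = cnv_enrichment(seg, ses, rand)
        assert res.degenerate and np.isnan(res.amp_odds_ratio)


class TestDifferentialMethylation:
    def _setup(self, rng, delta):
        ses = [gio.GenomicInterval("chr1", 0, 1000, "SE_A")]
        loci = [
            gio.GenomicInterval("chr1", 10, 11, "cg1"),
            gio.GenomicInterval("chr1", 20, 21, "cg2"),
        ]
        beta = np.empty((2, 100))
        beta[0, :50] = rng.beta((0.55 + delta) * 30, (0.45 - delta) * 30, 50)
        beta[0, 50:] = rng.beta(0.55 * 30, 0.45 * 30, 50)
        beta[1] = rng.beta(0.55 * 30, 0.45 * 30, 100)
        m = _matrix(beta, 50)
        m.values.index = ["cg1", "cg2"]
        return ses, loci, m

    def test_planted_hypomethylation_called(self, rng):
        ses, loci, m = self._setup(rng, -0.30)
        calls = call_differential_methylation(m, loci, ses)
        by_id = {c.cpg_id: c for c in calls}
        assert by_id["cg1"].direction == "hypo"
        assert by_id["cg2"].direction == "none"

    def test_hypo_and_hyper_sets_disjoint(self, rng):
        ses, loci, m = self._setup(rng, 0.25)
        calls = call_differential_methylation(m, loci, ses)
        hypo = {c.cpg_id for c in calls if c.direction == "hypo"}
        hyper = {c.cpg_id for c in calls if c.direction == "hyper"}
        assert hypo.isdisjoint(hyper)
        assert "cg1" in hyper
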
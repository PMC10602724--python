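"""Stage 2: contact support, enhanced scores and gene assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from secircuit import io as gio
from secircuit.assignment import (
    EnhancedScore,
    assign_genes,
    compute_es_threshold,
    contact_supported_pairs,
    enhanced_score_value,
    filter_genes,
    gene_expression_tests,
    score_candidates,
)
from secircuit.stats import MIResult


def _score(se="SE1", erna="e1", gene="g1", nmi=0.1, p=1e-5, q=1e-5, lfc=1.0):
    es = enhanced_score_value(nmi, lfc, p, q)
    mi = MIResult(nmi, nmi, 0, 0, 1, p, 100, 0)
    return EnhancedScore(se, erna, gene, mi, p, q, 2.0**lfc, lfc, es)


class TestContactSupport:
    def _fixtures(self):
        ses = [gio.GenomicInterval("chr1", 0, 4000, "SE1")]
        tss = [gio.GenomicInterval("chr2", 50_000, 50_001, "g1", "+")]
        return ses, tss

    def test_direct_support(self):
        ses, tss = self._fixtures()
        contact = (
            gio.GenomicInterval("chr1", 1000, 2000, "c"),
            gio.GenomicInterval("chr2", 49_000, 49_500, "c"),
        )
        assert contact_supported_pairs(ses, tss, [contact]) == {("SE1", "g1")}

    def test_orientation_agnostic(self):
        ses, tss = self._fixtures()
        contact = (
            gio.GenomicInterval("chr2", 49_000, 49_500, "c"),
            gio.GenomicInterval("chr1", 1000, 2000, "c"),
        )
        assert contact_supported_pairs(ses, tss, [contact]) == {("SE1", "g1")}

    def test_window_boundary_excluded(self):
        ses, tss = self._fixtures()
        # anchor entirely beyond TSS + 3000 (promoter end is 53_001 half-open)
        contact = (
            gio.GenomicInterval("chr1", 1000, 2000, "c"),
            gio.GenomicInterval("chr2", 53_001, 53_500, "c"),
        )
        assert contact_supported_pairs(ses, tss, [contact]) == set()

    def test_matches_quadratic_oracle(self, rng):
        ses = [gio.GenomicInterval("chr1", i * 5000, i * 5000 + 2000, f"SE{i}") for i in range(10)]
        tss = [gio.GenomicInterval("chr1", 60_000 + i * 8000, 60_001 + i * 8000, f"g{i}", "+") for i in range(10)]
        contacts = []
        for _ in range(60):
            a = int(rng.integers(0, 140_000))
            b = int(rng.integers(0, 140_000))
            contacts.append(
                (gio.GenomicInterval("chr1", a, a + 800, "c"), gio.GenomicInterval("chr1", b, b + 800, "c"))
            )
        got = contact_supported_pairs(ses, tss, contacts)
        proms = {t.name: gio.promoter_window(t, 3000) for t in tss}
        expected = set()
        for a, b in contacts:
            for x, y in ((a, b), (b, a)):
                for se in ses:
                    for t in tss:
                        if gio.intervals_overlap(se, x) and gio.intervals_overlap(proms[t.name], y):
                            expected.add((se.name, t.name))
        assert got == expected


class TestEnhancedScore:
    def test_stated_arithmetic_example(self):
        # nmi=0.2, FC=2 (log2FC=1), P=q=1e-5 -> 0.2 / Phi(1e-5)^2 ~ 0.800
        es = enhanced_score_value(0.2, 1.0, 1e-5, 1e-5)
        assert es == pytest.approx(0.2 / norm.cdf(1e-5) ** 2, rel=1e-12)
        assert es == pytest.approx(0.800, abs=1e-3)

    def test_zero_nmi_zero_score(self):
        assert enhanced_score_value(0.0, 2.0, 1e-5, 1e-5) == 0.0

    def test_monotone_in_nmi_and_fc(self):
        base = enhanced_score_value(0.2, 1.0, 1e-5, 1e-5)
        assert enhanced_score_value(0.3, 1.0, 1e-5, 1e-5) > base
        assert enhanced_score_value(0.2, 1.5, 1e-5, 1e-5) > base

    def test_fc_floor_on_zero_normal_mean(self):
        cols = [f"C{i}" for i in range(10)] + [f"N{i}" for i in range(10)]
        labels = {c: ("cancer" if c.startswith("C") else "normal") for c in cols}
        vals = np.r_[np.full(10, 4.0), np.zeros(10)][None, :]
        m = gio.LabeledMatrix(pd.DataFrame(vals, index=["g"], columns=cols), labels)
        t = gene_expression_tests(m)
        assert bool(t.loc["g", "fc_floored"])
        assert np.isfinite(t.loc["g", "log2_fc"])


class TestAssignGenes:
    def test_boundary_es_assigned(self):
        s = _score(nmi=0.2, lfc=1.0)
        s.es = 0.0051
        assert len(assign_genes([s])) == 1
        s.es = 0.005
        assert len(assign_genes([s])) == 0

    def test_p_gate_blocks_high_es(self):
        s = _score(p=1e-3)
        s.es = 0.02
        assert assign_genes([s]) == []

    def test_matches_brute_force_filter(self, rng):
        scores = []
        for i in range(200):
            scores.append(
                _score(
                    se=f"SE{i % 7}", erna=f"e{i}", gene=f"g{i % 31}",
                    nmi=float(rng.random() * 0.4),
                    p=float(10 ** rng.uniform(-8, -1)),
                    q=float(10 ** rng.uniform(-8, -1)),
                    lfc=float(rng.uniform(-1, 3)),
                )
            )
        links = assign_genes(scores)
        expected = {
            (s.se_id, s.gene_id)
            for s in scores
            if s.p_mi < 1e-4 and s.q_up < 1e-4 and s.es > 0.005
        }
        assert {(l.se_id, l.gene_id) for l in links} == expected
        for l in links:
            best = max(s.es for s in scores if (s.se_id, s.gene_id) == (l.se_id, l.gene_id)
                       and s.p_mi < 1e-4 and s.q_up < 1e-4 and s.es > 0.005)
            assert l.best_es == best

    def test_tf_flagging(self):
        s = _score(gene="TF9", nmi=0.3)
        (link,) = assign_genes([s], tf_ids={"TF9"})
        assert link.is_tf


class TestEsThreshold:
    def test_stated_arithmetic(self):
        scores = [_score(nmi=0.1, lfc=0.0125) for _ in range(12)]
        thr = compute_es_threshold(scores)
        assert thr == pytest.approx((0.1 * 0.0125) / norm.cdf(1e-4) ** 2, rel=1e-12)
        assert thr == pytest.approx(0.005, abs=2e-4)

    def test_scales_linearly_with_mean_nmi(self):
        s1 = [_score(nmi=0.1, lfc=1.0) for _ in range(12)]
        s2 = [_score(nmi=0.2, lfc=1.0) for _ in range(12)]
        assert compute_es_threshold(s2) == pytest.approx(2 * compute_es_threshold(s1))

    def test_requires_ten_pairs(self):
        with pytest.raises(ValueError):
            compute_es_threshold([_score()] * 5)


class TestScoreCandidates:
    def test_deterministic_and_order_independent(self, rng):
        cols = [f"C{i}" for i in range(30)] + [f"N{i}" for i in range(30)]
        labels = {c: ("cancer" if c.startswith("C") else "normal") for c in cols}
        erna_vals = rng.lognormal(1, 1, size=(2, 60))
        gene_vals = rng.lognormal(2, 1, size=(2, 60))
        erna = gio.LabeledMatrix(pd.DataFrame(erna_vals, index=["e1", "e2"], columns=cols), labels)
        genes = gio.LabeledMatrix(pd.DataFrame(gene_vals, index=["g1", "g2"], columns=cols), labels)
        mapping = {"SE1": ["e1", "e2"]}
        pairs_fwd = {("SE1", "g1"), ("SE1", "g2")}
        s1 = score_candidates(erna, genes, pairs_fwd, mapping, n_perm=200, seed=3)
        s2 = score_candidates(erna, genes, pairs_fwd, mapping, n_perm=200, seed=3)
        key = lambda s: (s.erna_id, s.gene_id)
        assert sorted([(key(x), x.es) for x in s1]) == sorted([(key(x), x.es) for x in s2])

    def test_gene_filter_threshold(self):
        cols = [f"C{i}" for i in range(5)] + [f"N{i}" for i in range(5)]
        labels = {c: ("cancer" if c.startswith("C") else "normal") for c in cols}
        vals = np.array([[0, 0, 0, 1, 1, 1, 1, 1, 1, 1], [0, 0, 0, 0, 1, 1, 1, 1, 1, 1]], dtype=float)
        m = gio.LabeledMatrix(pd.DataFrame(vals, index=["keep", "drop"], columns=cols), labels)
        assert filter_genes(m).row_ids == ["keep"]  # 70% expressed kept, 60% dropped
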
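"""Stage 3: master TF ranking and core regulatory circuitry detection.

Master TFs are SE-assigned TF genes ranked by the master score

    MS = lambda * expression_ratio,      lambda = mu_c * log2FC,

where mu_c is the trimmed-low-tail mean expression in cancer, log2FC the
trimmed cancer/normal fold change, and the expression ratio the fraction
of cancer samples whose expression exceeds max(1 FPKM, mu_c).  The top
15% by MS form the master set.  A master TF joins the core transcriptional
regulatory circuitry (CRC) when its binding motif occurs validly (>= 5
hits at p < 1e-4) inside its own SE regions — an autoregulatory loop —
and directed cross-edges between CRC TFs complete the interconnected
circuitry graph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import FastaStore, GenomicInterval, LabeledMatrix, PWM
from .motif import MotifHit, ScoredPWM, scan_regions
from .stats import bh_adjust, derive_seed, mi_permutation_p

logger = logging.getLogger(__name__)

__all__ = [
    "MasterScore",
    "CircuitryGraph",
    "master_score",
    "expression_ratio",
    "detect_crc",
    "downstream_genes",
]

FC_FLOOR = 1e-6


@dataclass
class MasterScore:
    tf_id: str
    mu_c: float
    mu_n: float
    log2_fc: float
    lam: float
    expression_ratio: float
    ms: float
    rank_percentile: float = math.nan
    fc_floored: bool = False


@dataclass
class CircuitryGraph:
    """Directed motif-binding graph restricted to self-looped master TFs."""

    nodes: list[str]
    edges: list[tuple[str, str]]  # tf_a -> tf_b: a's motif valid in b's SEs
    self_loops: list[str]
    hit_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "edges": [list(e) for e in self.edges],
            "self_loops": self.self_loops,
            "hit_counts": {f"{a}->{b}": c for (a, b), c in sorted(self.hit_counts.items())},
        }


def expression_ratio(cancer_values: np.ndarray, mu_c: float, fpkm_floor: float = 1.0) -> float:
    """Fraction of cancer samples with expression above max(fpkm_floor, mu_c)."""
    thr = max(fpkm_floor, mu_c)
    v = np.asarray(cancer_values, dtype=float)
    v = v[np.isfinite(v)]
    return float((v > thr).mean()) if v.size else 0.0


def master_score(
    tf_expr: LabeledMatrix,
    trim: float = 0.3,
    top_frac: float = 0.15,
) -> tuple[list[MasterScore], list[str]]:
    """Master scores for all provided TFs and the top-fraction master set.

    The master set is the top ``ceil(top_frac * n)`` TFs by MS, with ties
    broken by lambda and then lexicographic id.
    """
    from .stats import trimmed_group_test

    cancer = tf_expr.cancer.to_numpy(dtype=float)
    normal = tf_expr.normal.to_numpy(dtype=float)
    out = []
    for i, tf in enumerate(tf_expr.row_ids):
        s = trimmed_group_test(cancer[i], normal[i], trim, "greater")
        floored = s.mu_n <= 0.0
        fc = max(s.mu_c, FC_FLOOR) / max(s.mu_n, FC_FLOOR)
        lfc = math.log2(fc)
        lam = s.mu_c * lfc
        ratio = expression_ratio(cancer[i], s.mu_c)
        out.append(MasterScore(tf, s.mu_c, s.mu_n, lfc, lam, ratio, lam * ratio, fc_floored=floored))
    order = sorted(out, key=lambda m: (-m.ms, -m.lam, m.tf_id))
    n = len(order)
    for rank, m in enumerate(order):
        m.rank_percentile = 100.0 * (1.0 - rank / n)
    k = min(n, int(math.ceil(top_frac * n)))
    masters = [m.tf_id for m in order[:k]]
    return order, masters


def detect_crc(
    master_tfs: list[str],
    tf_se_regions: dict[str, list[GenomicInterval]],
    pwms: dict[str, PWM],
    genome: FastaStore,
    background: np.ndarray | None = None,
    min_occurrences: int = 5,
    p_thresh: float = 1e-4,
) -> tuple[CircuitryGraph, list[MotifHit]]:
    """The CRC graph: self-looped master TFs plus their cross-regulation edges.

    A TF joins the CRC iff its PWM has at least ``min_occurrences`` hits
    (p < ``p_thresh``, both strands, overlaps counted individually) in
    the union of its own SE sequences.  Directed cross-edges require the
    same hit count in the target TF's SEs; the returned graph is
    restricted to self-looped nodes.  Membership is independent of the
    order TFs are processed.
    """
    scored: dict[str, ScoredPWM] = {}
    usable = []
    for tf in sorted(master_tfs):
        if tf not in pwms:
            logger.warning("master TF %s has no PWM; excluded from CRC detection", tf)
            continue
        if not tf_se_regions.get(tf):
            logger.warning("master TF %s has no assigned SE; excluded", tf)
            continue
        scored[tf] = ScoredPWM(pwms[tf], background)
        usable.append(tf)
    all_hits: list[MotifHit] = []
    counts: dict[tuple[str, str], int] = {}
    for a in usable:
        for b in usable:
            hits = scan_regions(genome, tf_se_regions[b], scored[a], p_thresh)
            counts[(a, b)] = len(hits)
            all_hits.extend(hits)
    self_looped = sorted(tf for tf in usable if counts.get((tf, tf), 0) >= min_occurrences)
    node_set = set(self_looped)
    edges = [
        (a, b)
        for (a, b), c in sorted(counts.items())
        if c >= min_occurrences and a in node_set and b in node_set
    ]
    graph = CircuitryGraph(self_looped, edges, self_looped, counts)
    return graph, all_hits


def downstream_genes(
    crc_tfs: list[str],
    expr: LabeledMatrix,
    gene_se_regions: dict[str, list[GenomicInterval]],
    promoters: dict[str, GenomicInterval],
    genome: FastaStore,
    pwms: dict[str, PWM],
    background: np.ndarray | None = None,
    de_q: float = 0.01,
    mi_q: float = 0.01,
    min_occurrences: int = 5,
    p_thresh: float = 1e-4,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Downstream genes perturbed by CRC TFs, with binding class.

    Differentially expressed genes (two-sided Mann-Whitney across all
    samples, BH q < 0.01) are scanned for each CRC TF's motif in their
    linked SE regions and promoters; candidates with >= 5 valid hits are
    confirmed when the TF-gene expression MI permutation p-value (BH
    within TF) is < 0.01.  Binding class is ``SE``, ``promoter`` or
    ``both``.
    """
    cancer = expr.cancer.to_numpy(dtype=float)
    normal = expr.normal.to_numpy(dtype=float)
    de_p = []
    for i in range(len(expr.row_ids)):
        c, n = cancer[i], normal[i]
        if np.ptp(np.concatenate([c, n])) == 0.0:
            de_p.append(1.0)
        else:
            de_p.append(float(sps.mannwhitneyu(c, n, alternative="two-sided", method="asymptotic").pvalue))
    de_qv = bh_adjust(de_p)
    de_genes = [g for g, q in zip(expr.row_ids, de_qv) if q < de_q and g not in crc_tfs]
    logger.info("downstream_genes: %d DE genes at q < %g", len(de_genes), de_q)

    rows = []
    gene_cancer = expr.cancer
    for tf in sorted(crc_tfs):
        if tf not in pwms:
            logger.warning("CRC TF %s has no PWM; skipped in downstream scan", tf)
            continue
        spwm = ScoredPWM(pwms[tf], background)
        tf_vals = gene_cancer.loc[tf].to_numpy(dtype=float)
        candidates = []
        for g in de_genes:
            n_se_hits = len(scan_regions(genome, gene_se_regions.get(g, []), spwm, p_thresh))
            prom = promoters.get(g)
            n_prom_hits = len(scan_regions(genome, [prom], spwm, p_thresh)) if prom else 0
            se_bound = n_se_hits >= min_occurrences
            prom_bound = n_prom_hits >= min_occurrences
            if se_bound or prom_bound:
                candidates.append((g, n_se_hits, n_prom_hits, se_bound, prom_bound))
        mi_ps = []
        for g, *_ in candidates:
            gvals = gene_cancer.loc[g].to_numpy(dtype=float)
            mi = mi_permutation_p(tf_vals, gvals, n_perm=n_perm, seed=derive_seed(seed, "down", tf, g))
            mi_ps.append(mi.p_value)
        mi_qv = bh_adjust(mi_ps)
        for (g, n_se, n_prom, se_b, prom_b), p, q in zip(candidates, mi_ps, mi_qv):
            if q < mi_q:
                cls = "both" if (se_b and prom_b) else ("SE" if se_b else "promoter")
                rows.append((tf, g, cls, n_se, n_prom, p, q))
    return pd.DataFrame(
        rows,
        columns=["crc_tf", "gene_id", "binding_class", "se_hits", "promoter_hits", "mi_p", "mi_q"],
    )
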
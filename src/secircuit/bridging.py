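"""Stage 4: CRC-TF/partner-TF pairs (CTPs) bridging SE-promoter loops.

Partner TFs for each CRC TF must (1) share a protein-protein interaction
recorded in at least two source datasets, (2) have cancer expression
ratio above 0.3, (3) show at least five valid motif hits in the SE or
promoter regions of SE-assigned genes, and (4) be significantly
associated (MI permutation p < 0.01) with at least one SE-assigned gene.

A pair *bridges* an assigned SE-gene link when the raw Spearman
correlation between the SE's eRNA transcription and the gene's expression
across cancer samples is significant (Pr < 0.05) but vanishes after
jointly conditioning on the pair's expression (Pp > 0.05).  Flagged CTPs
are validated with a stratified-permutation conditional-independence
test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import FastaStore, GenomicInterval, LabeledMatrix, PWM
from .motif import ScoredPWM, scan_regions
from .stats import (
    PartialCorrelationResult,
    conditional_independence_test,
    derive_seed,
    mi_permutation_p,
    partial_spearman,
)
from .circuitry import expression_ratio

logger = logging.getLogger(__name__)

__all__ = [
    "PartnerCandidate",
    "BridgeResult",
    "partner_candidates",
    "bridge_test",
    "ci_validate",
    "summarize_ctps",
]


@dataclass
class PartnerCandidate:
    crc_tf: str
    partner_tf: str
    ppi_support: int
    expression_ratio: float
    motif_support: int
    mi_p: float
    mi_gene: str


@dataclass
class BridgeResult:
    se_id: str
    erna_id: str
    gene_id: str
    crc_tf: str
    partner_tf: str
    pc: PartialCorrelationResult
    is_ctp: bool
    ci_p: float = float("nan")
    ci_confirmed: bool = False


def partner_candidates(
    crc_tfs: list[str],
    ppi_edges: pd.DataFrame,
    expr: LabeledMatrix,
    assigned_gene_ids: list[str],
    assigned_regions: list[GenomicInterval],
    pwms: dict[str, PWM],
    genome: FastaStore,
    tf_ids: list[str],
    background: np.ndarray | None = None,
    ratio_min: float = 0.3,
    motif_min: int = 5,
    mi_p_thresh: float = 0.01,
    motif_p: float = 1e-4,
    trim: float = 0.3,
    n_perm: int = 1000,
    seed: int = 0,
    max_mi_tries: int = 25,
) -> list[PartnerCandidate]:
    """Apply the four partner gates in order and return surviving pairs.

    ``assigned_regions`` is the union of SE regions and promoter windows
    of SE-assigned genes; gate (4) passes when the partner associates
    with at least one SE-assigned gene, tried in decreasing rank-
    correlation order (capped) so the check is deterministic and cheap.
    The surviving set does not depend on gate application order since the
    gates are independent predicates.
    """
    from .stats import trimmed_group_test

    crc_set = set(crc_tfs)
    tf_set = set(tf_ids)
    # gate 1: PPI with a CRC TF in >= 2 source datasets
    support: dict[tuple[str, str], set[str]] = {}
    for r in ppi_edges.itertuples():
        a, b, ds = str(r.tf_a), str(r.tf_b), str(r.dataset)
        for crc, other in ((a, b), (b, a)):
            if crc in crc_set and other != crc and other in tf_set:
                support.setdefault((crc, other), set()).add(ds)
    pairs = {k: v for k, v in support.items() if len(v) >= 2}

    cancer = expr.cancer
    assigned_in_expr = [g for g in assigned_gene_ids if g in expr.values.index]
    gene_mat = cancer.loc[assigned_in_expr].to_numpy(dtype=float) if assigned_in_expr else np.empty((0, 0))
    out = []
    for (crc, partner) in sorted(pairs):
        if partner not in expr.values.index:
            logger.warning("partner TF %s absent from expression matrix; dropped", partner)
            continue
        pvals_c = cancer.loc[partner].to_numpy(dtype=float)
        normal = expr.normal.loc[partner].to_numpy(dtype=float)
        s = trimmed_group_test(pvals_c, normal, trim, "greater")
        ratio = expression_ratio(pvals_c, s.mu_c)
        if ratio <= ratio_min:
            continue
        if partner not in pwms:
            logger.warning("partner TF %s has no PWM; dropped", partner)
            continue
        spwm = ScoredPWM(pwms[partner], background)
        n_hits = len(scan_regions(genome, assigned_regions, spwm, motif_p))
        if n_hits < motif_min:
            continue
        if not assigned_in_expr:
            continue
        # gate 4: strongest rank-correlated assigned genes first
        pr = rankdata(pvals_c)
        rho = np.array([
            abs(np.corrcoef(pr, rankdata(gene_mat[i]))[0, 1]) for i in range(len(assigned_in_expr))
        ])
        order = np.argsort(-rho, kind="stable")[:max_mi_tries]
        best_p, best_gene = 1.0, ""
        for i in order:
            g = assigned_in_expr[int(i)]
            mi = mi_permutation_p(
                pvals_c, gene_mat[int(i)], n_perm=n_perm, seed=derive_seed(seed, "partner", partner, g)
            )
            if mi.p_value < best_p:
                best_p, best_gene = mi.p_value, g
            if mi.p_value < mi_p_thresh:
                break
        if best_p >= mi_p_thresh:
            continue
        out.append(
            PartnerCandidate(crc, partner, len(pairs[(crc, partner)]), ratio, n_hits, best_p, best_gene)
        )
    return out


def bridge_test(
    erna_values,
    gene_values,
    tf_a_values,
    tf_b_values,
    se_id: str = ".",
    erna_id: str = ".",
    gene_id: str = ".",
    crc_tf: str = ".",
    partner_tf: str = ".",
    alpha_raw: float = 0.05,
    alpha_partial: float = 0.05,
) -> BridgeResult:
    """Does the TF pair statistically bridge the SE-gene correlation?

    ``is_ctp`` is exactly the conjunction Pr < alpha_raw and
    Pp > alpha_partial, with Pp from the second-order (joint) partial
    Spearman correlation; degenerate conditioning never flags a CTP.
    """
    pc = partial_spearman(erna_values, gene_values, [tf_a_values, tf_b_values])
    is_ctp = (not pc.degenerate) and pc.p_raw < alpha_raw and pc.p_partial > alpha_partial
    return BridgeResult(se_id, erna_id, gene_id, crc_tf, partner_tf, pc, bool(is_ctp))


def ci_validate(
    bridge_results: list[BridgeResult],
    value_lookup,
    n_perm: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Conditional-independence validation of flagged CTPs.

    ``value_lookup(result)`` must return ``(erna, gene, tf_a, tf_b)``
    value vectors.  A CTP is confirmed when the permutation CMI test does
    *not* reject SE-gene independence given the TF pair (p >= alpha).
    Returns the confirmed fraction (NaN when no CTP was flagged).
    """
    flagged = [r for r in bridge_results if r.is_ctp]
    for r in flagged:
        ev, gv, av, bv = value_lookup(r)
        r.ci_p = conditional_independence_test(
            ev, gv, [av, bv], n_perm=n_perm,
            seed=derive_seed(seed, "ci", r.erna_id, r.gene_id, r.crc_tf, r.partner_tf),
        )
        r.ci_confirmed = bool(r.ci_p >= alpha)
    if not flagged:
        return float("nan")
    return float(np.mean([r.ci_confirmed for r in flagged]))


def summarize_ctps(bridge_results: list[BridgeResult]) -> dict:
    """Distinct bridging pairs, per-gene CTP counts and their mean.

    The mean counts, per regulated gene, how many distinct
    (CRC TF, partner TF) pairs bridge at least one of its SE links;
    ``mean_ctps_per_gene`` is None when nothing was bridged.
    """
    flagged = [r for r in bridge_results if r.is_ctp]
    pair_links: dict[tuple[str, str], int] = {}
    gene_pairs: dict[str, set[tuple[str, str]]] = {}
    for r in flagged:
        pair = (r.crc_tf, r.partner_tf)
        pair_links[pair] = pair_links.get(pair, 0) + 1
        gene_pairs.setdefault(r.gene_id, set()).add(pair)
    pair_table = pd.DataFrame(
        [(a, b, c) for (a, b), c in sorted(pair_links.items())],
        columns=["crc_tf", "partner_tf", "n_bridged_links"],
    )
    gene_counts = pd.DataFrame(
        [(g, len(ps)) for g, ps in sorted(gene_pairs.items())],
        columns=["gene_id", "n_ctps"],
    )
    mean = float(gene_counts["n_ctps"].mean()) if len(gene_counts) else None
    return {
        "pair_table": pair_table,
        "gene_counts": gene_counts,
        "n_ctps": len(pair_table),
        "n_regulated_genes": len(gene_counts),
        "mean_ctps_per_gene": mean,
    }
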
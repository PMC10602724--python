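"""Stage 1: call activated super-enhancers from eRNA transcription.

An SE is *activated* when at least one of its component eRNAs is
significantly up-regulated in cancer: the mean transcription of the 30%
of cancer samples with the lowest levels is tested against the matching
normal low tail (one-sided Mann-Whitney U), with BH adjustment across all
tested eRNAs and a q < 0.05 call threshold.  The activated set is then
characterized by CNV amplification/deletion enrichment against
length-matched random regions and by differential CpG methylation inside
the SE regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomicInterval, LabeledMatrix, assign_containing, overlap_any
from .stats import TrimmedGroupSummary, bh_adjust, fisher_enrichment, trimmed_group_test

logger = logging.getLogger(__name__)

__all__ = [
    "ActivationCall",
    "MethylationCall",
    "CNVEnrichment",
    "filter_erna",
    "call_activated_ses",
    "cnv_enrichment",
    "call_differential_methylation",
]


@dataclass
class ActivationCall:
    erna_id: str
    se_id: str
    summary: TrimmedGroupSummary
    up_regulated: bool


@dataclass
class MethylationCall:
    cpg_id: str
    se_id: str
    direction: str  # hypo / hyper / none
    summary_hypo: TrimmedGroupSummary
    summary_hyper: TrimmedGroupSummary


@dataclass
class CNVEnrichment:
    amp_odds_ratio: float
    amp_p: float
    del_odds_ratio: float
    del_p: float
    n_amp_segments: int
    n_del_segments: int
    degenerate: bool = False


def filter_erna(matrix: LabeledMatrix, max_zero_fraction: float = 0.7) -> LabeledMatrix:
    """Drop eRNAs not transcribed (RPKM = 0) in more than 70% of samples.

    The comparison is strict (> 70% removed, exactly 70% retained); NaN
    entries do not count as zeros.  Removed row ids are retained on the
    returned matrix (``removed_rows``) and logged.
    """
    vals = matrix.values.to_numpy(dtype=float)
    zero_frac = (vals == 0.0).sum(axis=1) / vals.shape[1]
    keep = zero_frac <= max_zero_fraction
    removed = [r for r, k in zip(matrix.row_ids, keep) if not k]
    if removed:
        logger.info("filter_erna: removed %d/%d rows", len(removed), len(keep))
    out = matrix.subset_rows([r for r, k in zip(matrix.row_ids, keep) if k])
    out.removed_rows = removed
    return out


def call_activated_ses(
    erna: LabeledMatrix,
    erna_loci: list[GenomicInterval],
    se_regions: list[GenomicInterval],
    trim: float = 0.3,
    q_thresh: float = 0.05,
) -> tuple[list[ActivationCall], list[str]]:
    """Per-eRNA trimmed tests, BH across eRNAs, and the activated SE set.

    eRNA loci must each be contained in exactly one SE region; others are
    dropped with a warning.  Returns ``(calls, activated_se_ids)`` with
    the activated ids in SE input order.
    """
    loci_by_id = {iv.name: iv for iv in erna_loci}
    present = [r for r in erna.row_ids if r in loci_by_id]
    containers = assign_containing([loci_by_id[r] for r in present], se_regions)
    se_of: dict[str, str] = {}
    for rid, se_id in zip(present, containers):
        if se_id is None:
            logger.warning("eRNA %s not contained in exactly one SE; dropped", rid)
        else:
            se_of[rid] = se_id
    tested = [r for r in erna.row_ids if r in se_of]
    cancer = erna.cancer.to_numpy(dtype=float)
    normal = erna.normal.to_numpy(dtype=float)
    row_index = {r: i for i, r in enumerate(erna.row_ids)}
    summaries = [
        trimmed_group_test(cancer[row_index[r]], normal[row_index[r]], trim, "greater")
        for r in tested
    ]
    qvals = bh_adjust([s.p_value for s in summaries])
    calls = []
    for r, s, q in zip(tested, summaries, qvals):
        s.q_value = float(q)
        calls.append(ActivationCall(r, se_of[r], s, bool(q < q_thresh)))
    up_ses = {c.se_id for c in calls if c.up_regulated}
    activated = [se.name for se in se_regions if se.name in up_ses]
    return calls, activated


def _classify_segments(segments: pd.DataFrame, log2_cut: float):
    amp = segments[segments["log2_ratio"] > log2_cut]
    dele = segments[segments["log2_ratio"] < -log2_cut]
    return amp, dele


def _seg_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), name=str(r.sample))
        for r in df.itertuples()
    ]


def cnv_enrichment(
    segments: pd.DataFrame,
    se_regions: list[GenomicInterval],
    random_regions: list[GenomicInterval],
    log2_cut: float = 0.8,
) -> CNVEnrichment:
    """Fisher enrichment of amplified/deleted segments in SEs vs random regions.

    A region counts as hit when it overlaps (>= 1 bp) at least one
    qualifying segment from any sample.  Returns flagged NaN odds ratios
    when no segment survives classification.
    """
    amp, dele = _classify_segments(segments, log2_cut)
    result = {}
    degenerate = False
    for key, seg_df in (("amp", amp), ("del", dele)):
        if seg_df.empty:
            result[key] = (float("nan"), float("nan"))
            degenerate = True
            continue
        ivs = _seg_intervals(seg_df)
        se_hits = int(overlap_any(se_regions, ivs).sum())
        bg_hits = int(overlap_any(random_regions, ivs).sum())
        result[key] = fisher_enrichment(se_hits, len(se_regions), bg_hits, len(random_regions))
    return CNVEnrichment(
        amp_odds_ratio=result["amp"][0],
        amp_p=result["amp"][1],
        del_odds_ratio=result["del"][0],
        del_p=result["del"][1],
        n_amp_segments=len(amp),
        n_del_segments=len(dele),
        degenerate=degenerate,
    )


def call_differential_methylation(
    beta: LabeledMatrix,
    cpg_loci: list[GenomicInterval],
    se_regions: list[GenomicInterval],
    trim: float = 0.3,
    q_thresh: float = 0.05,
) -> list[MethylationCall]:
    """Two one-sided trimmed tests per CpG inside SE regions.

    The ``less`` direction (cancer low-tail mean below normal) labels
    hypomethylated CpGs; ``greater`` labels hypermethylated ones.  Each
    direction is BH-adjusted separately and called at q < 0.05; a CpG can
    never be called in both directions.
    """
    loci_by_id = {iv.name: iv for iv in cpg_loci}
    present = [r for r in beta.row_ids if r in loci_by_id]
    containers = assign_containing([loci_by_id[r] for r in present], se_regions)
    mapped = [(r, se) for r, se in zip(present, containers) if se is not None]
    cancer = beta.cancer.to_numpy(dtype=float)
    normal = beta.normal.to_numpy(dtype=float)
    row_index = {r: i for i, r in enumerate(beta.row_ids)}
    s_hypo = [trimmed_group_test(cancer[row_index[r]], normal[row_index[r]], trim, "less") for r, _ in mapped]
    s_hyper = [trimmed_group_test(cancer[row_index[r]], normal[row_index[r]], trim, "greater") for r, _ in mapped]
    q_hypo = bh_adjust([s.p_value for s in s_hypo])
    q_hyper = bh_adjust([s.p_value for s in s_hyper])
    calls = []
    for (r, se_id), sh, so, qh, qo in zip(mapped, s_hypo, s_hyper, q_hypo, q_hyper):
        sh.q_value = float(qh)
        so.q_value = float(qo)
        hypo = qh < q_thresh
        hyper = qo < q_thresh
        assert not (hypo and hyper), f"CpG {r} significant in both directions"
        direction = "hypo" if hypo else ("hyper" if hyper else "none")
        calls.append(MethylationCall(r, se_id, direction, sh, so))
    return calls
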
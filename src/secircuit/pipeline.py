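"""End-to-end orchestration of the four pipeline stages.

``run`` executes activation calling, SE-gene assignment, circuitry
detection and CTP bridging from a structured config, writing every
intermediate table plus a machine-readable manifest into a run
directory.  All randomness flows from the single config seed through
stable per-entity sub-seeds, so re-running an identical config
reproduces every output byte for byte.  ``evaluate`` scores a run
against the synthetic generator's ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import roc_auc_score

from . import activation as act
from . import assignment as asg
from . import bridging as brg
from . import circuitry as crc
from . import io as gio
from .simulate import GroundTruth, sample_random_regions
from .stats import derive_seed

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run", "evaluate"]

BUNDLE_FILES = {
    "erna_rpkm": "erna_rpkm.tsv",
    "erna_loci": "erna_loci.bed",
    "gene_fpkm": "gene_fpkm.tsv",
    "gene_tss": "gene_tss.bed",
    "sample_labels": "sample_labels.tsv",
    "se_regions": "se_regions.bed",
    "cnv_segments": "cnv_segments.seg",
    "methylation_beta": "methylation_beta.tsv",
    "cpg_loci": "cpg_loci.bed",
    "contacts": "contacts.bedpe",
    "genome_fasta": "genome.fa",
    "motifs": "motifs.jaspar",
    "tf_list": "tf_list.tsv",
    "ppi_edges": "ppi_edges.tsv",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input paths plus every threshold the method uses.

    Threshold defaults are the published operating points: 30% trim,
    activation q < 0.05, CNV log2 cut 0.8, TSS +/- 3 kb promoters,
    eS > 0.005 with P and q gates at 1e-4, motif p < 1e-4 with >= 5
    occurrences, top 15% master TFs, partner expression ratio > 0.3,
    and Pr < 0.05 / Pp > 0.05 for CTP bridging.
    """

    inputs: dict[str, str] = field(default_factory=dict)
    trim_fraction: float = 0.3
    q_activation: float = 0.05
    log2_cnv: float = 0.8
    promoter_halfwidth: int = 3000
    es_threshold: float = 0.005
    mi_gate: float = 1e-4
    q_gate: float = 1e-4
    de_q: float = 0.01
    downstream_mi_q: float = 0.01
    motif_p: float = 1e-4
    motif_min: int = 5
    top_tf_frac: float = 0.15
    ratio_min: float = 0.3
    partner_mi_p: float = 0.01
    alpha_raw: float = 0.05
    alpha_partial: float = 0.05
    n_perm: int = 1000
    ci_n_perm: int = 500
    seed: int = 7

    @classmethod
    def from_bundle(cls, bundle_dir, **overrides) -> "PipelineConfig":
        bundle_dir = Path(bundle_dir)
        inputs = {k: str(bundle_dir / v) for k, v in BUNDLE_FILES.items()}
        return cls(inputs=inputs, **overrides)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        inputs = data.pop("inputs", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(inputs=inputs, **data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def validate(self) -> None:
        missing = [k for k in BUNDLE_FILES if k not in self.inputs]
        if missing:
            raise ValueError(f"missing input paths: {missing}")
        absent = [p for p in self.inputs.values() if not Path(p).exists()]
        if absent:
            raise FileNotFoundError(f"input files not found: {absent}")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def run(config: PipelineConfig, run_dir) -> Path:
    """Execute stages 1-4 and write all outputs into ``run_dir``."""
    config.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("secircuit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    config.to_yaml(run_dir / "config.yaml")
    counts: dict[str, int] = {}
    stage = "load"
    try:
        inp = config.inputs
        genome = gio.read_fasta(inp["genome_fasta"])
        background = genome.mono_frequencies()
        se_regions = gio.read_bed(inp["se_regions"])
        se_by_id = {s.name: s for s in se_regions}
        erna_loci = gio.read_bed(inp["erna_loci"])
        erna = gio.read_matrix(inp["erna_rpkm"], inp["sample_labels"])
        genes = gio.read_matrix(inp["gene_fpkm"], inp["sample_labels"])
        tss = gio.read_bed(inp["gene_tss"])
        tf_table = pd.read_csv(inp["tf_list"], sep="\t").astype(str)
        tf_ids = tf_table["tf_id"].tolist()
        pwm_of_tf = dict(zip(tf_table["tf_id"], tf_table.get("pwm_id", tf_table["tf_id"])))
        pwms_list = gio.read_jaspar(inp["motifs"], background=background)
        pwm_by_id = {p.motif_id: p for p in pwms_list}
        tf_pwms = {tf: pwm_by_id[mid] for tf, mid in pwm_of_tf.items() if mid in pwm_by_id}
        contacts = gio.read_bedpe(inp["contacts"])
        seg = gio.read_seg(inp["cnv_segments"])
        beta = gio.read_matrix(inp["methylation_beta"], inp["sample_labels"])
        cpg_loci = gio.read_bed(inp["cpg_loci"])
        ppi = gio.read_ppi(inp["ppi_edges"])

        # ------------------------------------------------------------------
        stage = "activation"
        erna_f = act.filter_erna(erna)
        calls, activated_ids = act.call_activated_ses(
            erna_f, erna_loci, se_regions, config.trim_fraction, config.q_activation
        )
        counts["ernas_tested"] = len(calls)
        counts["up_regulated_ernas"] = sum(c.up_regulated for c in calls)
        counts["activated_ses"] = len(activated_ids)
        _write_tsv(
            pd.DataFrame(
                [
                    (c.erna_id, c.se_id, c.summary.mu_c, c.summary.mu_n, c.summary.p_value,
                     c.summary.q_value, c.up_regulated)
                    for c in calls
                ],
                columns=["erna_id", "se_id", "mu_c", "mu_n", "p", "q", "up_regulated"],
            ),
            run_dir / "activation_calls.tsv",
        )
        activated_regions = [se_by_id[i] for i in activated_ids]
        gio.write_bed(activated_regions, run_dir / "activated_ses.bed")

        rand_regions = sample_random_regions(
            genome,
            n=max(len(activated_regions), 1),
            length_source=se_regions,
            exclude=se_regions,
            seed=derive_seed(config.seed, "random-regions"),
        )
        cnv = act.cnv_enrichment(seg, activated_regions or se_regions, rand_regions, config.log2_cnv)
        with open(run_dir / "cnv_enrichment.json", "w") as fh:
            json.dump(dataclasses.asdict(cnv), fh, indent=2, sort_keys=True)

        meth_calls = act.call_differential_methylation(
            beta, cpg_loci, activated_regions or se_regions, config.trim_fraction, config.q_activation
        )
        counts["hypo_cpgs"] = sum(c.direction == "hypo" for c in meth_calls)
        counts["hyper_cpgs"] = sum(c.direction == "hyper" for c in meth_calls)
        _write_tsv(
            pd.DataFrame(
                [
                    (c.cpg_id, c.se_id, c.direction, c.summary_hypo.p_value, c.summary_hypo.q_value,
                     c.summary_hyper.p_value, c.summary_hyper.q_value)
                    for c in meth_calls
                ],
                columns=["cpg_id", "se_id", "direction", "p_hypo", "q_hypo", "p_hyper", "q_hyper"],
            ),
            run_dir / "methylation_calls.tsv",
        )

        # ------------------------------------------------------------------
        stage = "assignment"
        genes_f = asg.filter_genes(genes)
        chrom_len = {c: genome.chrom_length(c) for c in genome.chrom_names}
        tss_f = [t for t in tss if t.name in set(genes_f.row_ids)]
        pairs = asg.contact_supported_pairs(
            activated_regions, tss_f, contacts, config.promoter_halfwidth
        )
        erna_of_se: dict[str, list[str]] = {}
        for c in calls:
            erna_of_se.setdefault(c.se_id, []).append(c.erna_id)
        gene_tests = asg.gene_expression_tests(genes_f, config.trim_fraction)
        scores = asg.score_candidates(
            erna_f, genes_f, pairs, erna_of_se, config.trim_fraction,
            config.n_perm, config.seed, gene_tests,
        )
        counts["candidate_pairs"] = len(pairs)
        counts["scored_combinations"] = len(scores)
        links = asg.assign_genes(
            scores, config.es_threshold, config.mi_gate, config.q_gate, set(tf_ids)
        )
        counts["assigned_genes"] = len({l.gene_id for l in links})
        counts["assigned_links"] = len(links)
        es_data_threshold = (
            asg.compute_es_threshold(scores, config.mi_gate) if len(scores) >= 10 else float("nan")
        )
        _write_tsv(
            pd.DataFrame(
                [
                    (s.se_id, s.erna_id, s.gene_id, s.mi.mi, s.mi.nmi, s.p_mi, s.q_up,
                     s.fc, s.log2_fc, s.es)
                    for s in scores
                ],
                columns=["se_id", "erna_id", "gene_id", "mi_bits", "nmi", "p_mi", "q_up",
                         "fc", "log2_fc", "es"],
            ),
            run_dir / "se_gene_scores.tsv",
        )
        _write_tsv(
            pd.DataFrame(
                [
                    (l.se_id, l.gene_id, l.best_es, l.best_erna, ",".join(l.supporting_ernas), l.is_tf)
                    for l in links
                ],
                columns=["se_id", "gene_id", "best_es", "best_erna", "supporting_ernas", "is_tf"],
            ),
            run_dir / "se_assigned_genes.tsv",
        )
        prom_by_gene = {
            t.name: gio.promoter_window(t, config.promoter_halfwidth, chrom_len.get(t.chrom))
            for t in tss
        }
        gio.write_bedpe(
            [
                (dataclasses.replace(se_by_id[l.se_id], name=f"{l.se_id}|{l.gene_id}"),
                 dataclasses.replace(prom_by_gene[l.gene_id], name=f"{l.se_id}|{l.gene_id}"))
                for l in links
                if l.gene_id in prom_by_gene
            ],
            run_dir / "links.bedpe",
        )

        # ------------------------------------------------------------------
        stage = "circuitry"
        assigned_tf_links = [l for l in links if l.is_tf]
        assigned_tf_ids = sorted({l.gene_id for l in assigned_tf_links})
        counts["assigned_tfs"] = len(assigned_tf_ids)
        tf_se_regions: dict[str, list[gio.GenomicInterval]] = {}
        for l in assigned_tf_links:
            tf_se_regions.setdefault(l.gene_id, []).append(se_by_id[l.se_id])
        if assigned_tf_ids:
            ms_list, master_ids = crc.master_score(
                genes_f.subset_rows(assigned_tf_ids), config.trim_fraction, config.top_tf_frac
            )
        else:
            ms_list, master_ids = [], []
        counts["master_tfs"] = len(master_ids)
        _write_tsv(
            pd.DataFrame(
                [
                    (m.tf_id, m.mu_c, m.mu_n, m.log2_fc, m.lam, m.expression_ratio, m.ms,
                     m.rank_percentile, m.tf_id in master_ids)
                    for m in ms_list
                ],
                columns=["tf_id", "mu_c", "mu_n", "log2_fc", "lambda", "expression_ratio",
                         "ms", "rank_percentile", "is_master"],
            ),
            run_dir / "master_scores.tsv",
        )
        graph, hits = crc.detect_crc(
            master_ids, tf_se_regions, tf_pwms, genome, background,
            config.motif_min, config.motif_p,
        )
        counts["crc_tfs"] = len(graph.nodes)
        with open(run_dir / "crc_graph.json", "w") as fh:
            json.dump(graph.to_dict(), fh, indent=2, sort_keys=True)
        gio.write_bed(
            [h.interval for h in hits],
            run_dir / "motif_hits.bed",
            scores=[-np.log10(max(h.p_value, 1e-300)) for h in hits],
        )

        gene_se_regions: dict[str, list[gio.GenomicInterval]] = {}
        for l in links:
            gene_se_regions.setdefault(l.gene_id, []).append(se_by_id[l.se_id])
        downstream = crc.downstream_genes(
            graph.nodes, genes_f, gene_se_regions, prom_by_gene, genome, tf_pwms,
            background, config.de_q, config.downstream_mi_q, config.motif_min,
            config.motif_p, config.n_perm, derive_seed(config.seed, "downstream"),
        )
        counts["downstream_targets"] = len(downstream)
        _write_tsv(downstream, run_dir / "downstream_targets.tsv")

        # ------------------------------------------------------------------
        stage = "bridging"
        assigned_gene_ids = sorted({l.gene_id for l in links if not l.is_tf})
        assigned_regions = [se_by_id[i] for i in sorted({l.se_id for l in links})]
        assigned_regions += [prom_by_gene[g] for g in assigned_gene_ids if g in prom_by_gene]
        cands = brg.partner_candidates(
            graph.nodes, ppi, genes_f, assigned_gene_ids, assigned_regions,
            tf_pwms, genome, tf_ids, background, config.ratio_min, config.motif_min,
            config.partner_mi_p, config.motif_p, config.trim_fraction,
            config.n_perm, derive_seed(config.seed, "partner"),
        )
        counts["partner_pairs"] = len(cands)
        _write_tsv(
            pd.DataFrame(
                [
                    (c.crc_tf, c.partner_tf, c.ppi_support, c.expression_ratio,
                     c.motif_support, c.mi_p, c.mi_gene)
                    for c in cands
                ],
                columns=["crc_tf", "partner_tf", "ppi_support", "expression_ratio",
                         "motif_support", "mi_p", "mi_gene"],
            ),
            run_dir / "partner_candidates.tsv",
        )

        erna_cancer = erna_f.cancer
        gene_cancer = genes_f.cancer
        results = []
        # every supporting eRNA of a link is tested; a (link, pair) combo
        # bridges when any of its eRNAs does, mirroring the >= 1-eRNA rule
        # used for SE activation
        for l in links:
            if l.is_tf or l.gene_id not in gene_cancer.index:
                continue
            gv = gene_cancer.loc[l.gene_id].to_numpy(dtype=float)
            for erna_id in l.supporting_ernas:
                ev = erna_cancer.loc[erna_id].to_numpy(dtype=float)
                for c in cands:
                    if c.crc_tf not in gene_cancer.index or c.partner_tf not in gene_cancer.index:
                        continue
                    av = gene_cancer.loc[c.crc_tf].to_numpy(dtype=float)
                    bv = gene_cancer.loc[c.partner_tf].to_numpy(dtype=float)
                    results.append(
                        brg.bridge_test(
                            ev, gv, av, bv, l.se_id, erna_id, l.gene_id,
                            c.crc_tf, c.partner_tf, config.alpha_raw, config.alpha_partial,
                        )
                    )
        counts["bridge_tests"] = len(results)
        counts["ctp_links"] = sum(r.is_ctp for r in results)

        def lookup(r: brg.BridgeResult):
            return (
                erna_cancer.loc[r.erna_id].to_numpy(dtype=float),
                gene_cancer.loc[r.gene_id].to_numpy(dtype=float),
                gene_cancer.loc[r.crc_tf].to_numpy(dtype=float),
                gene_cancer.loc[r.partner_tf].to_numpy(dtype=float),
            )

        confirmed_frac = brg.ci_validate(
            results, lookup, config.ci_n_perm, derive_seed(config.seed, "ci")
        )
        _write_tsv(
            pd.DataFrame(
                [
                    (r.se_id, r.erna_id, r.gene_id, r.crc_tf, r.partner_tf,
                     r.pc.rho_raw, r.pc.p_raw, r.pc.rho_partial, r.pc.p_partial,
                     r.pc.degenerate, r.is_ctp, r.ci_p, r.ci_confirmed)
                    for r in results
                ],
                columns=["se_id", "erna_id", "gene_id", "crc_tf", "partner_tf",
                         "rho_raw", "p_raw", "rho_partial", "p_partial", "degenerate",
                         "is_ctp", "ci_p", "ci_confirmed"],
            ),
            run_dir / "ctp_bridges.tsv",
        )
        summary = brg.summarize_ctps(results)
        counts["ctps"] = summary["n_ctps"]
        with open(run_dir / "ctp_summary.json", "w") as fh:
            json.dump(
                {
                    "n_ctps": summary["n_ctps"],
                    "n_regulated_genes": summary["n_regulated_genes"],
                    "mean_ctps_per_gene": summary["mean_ctps_per_gene"],
                    "ci_confirmed_fraction": None if np.isnan(confirmed_frac) else confirmed_frac,
                    "pairs": summary["pair_table"].to_dict(orient="records"),
                    "gene_counts": summary["gene_counts"].to_dict(orient="records"),
                },
                fh, indent=2, sort_keys=True,
            )

        manifest = {
            "seed": config.seed,
            "thresholds": {
                k: v for k, v in dataclasses.asdict(config).items() if k != "inputs"
            },
            "counts": counts,
            "es_data_driven_threshold": None if np.isnan(es_data_threshold) else es_data_threshold,
            "outputs": sorted(p.name for p in run_dir.iterdir() if p.name != "run.log"),
        }
        with open(run_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return run_dir
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, str(exc)) from exc
    finally:
        root.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# evaluation against ground truth
# ---------------------------------------------------------------------------


def evaluate(run_dir, truth_dir, out_path=None) -> dict:
    """Recovery metrics of a run against the generator's planted truth.

    Reports activated-SE sensitivity and observed FDR, AUROC of the
    enhanced score over contact-supported candidates, CRC TF set
    equality/Jaccard, CTP sensitivity on mediated triples and false-flag
    rate on unmediated controls, and the CI-confirmed fraction.
    """
    run_dir = Path(run_dir)
    truth = GroundTruth.read(truth_dir)
    called = {iv.name for iv in gio.read_bed(run_dir / "activated_ses.bed")}
    true_act = set(truth.activated_se_ids)
    sens = len(called & true_act) / len(true_act) if true_act else float("nan")
    fdr = len(called - true_act) / len(called) if called else 0.0

    scores = pd.read_csv(run_dir / "se_gene_scores.tsv", sep="\t")
    true_links = {(r.se_id, r.gene_id) for r in truth.se_gene_links.itertuples()}
    auroc = float("nan")
    if len(scores):
        best = scores.groupby(["se_id", "gene_id"])["es"].max().reset_index()
        y = np.array([(r.se_id, r.gene_id) in true_links for r in best.itertuples()])
        if 0 < y.sum() < len(y):
            auroc = float(roc_auc_score(y, best["es"].to_numpy()))

    with open(run_dir / "crc_graph.json") as fh:
        graph = json.load(fh)
    crc_called = set(graph["nodes"])
    crc_true = set(truth.crc_tf_ids)
    union = crc_called | crc_true
    jaccard = len(crc_called & crc_true) / len(union) if union else 1.0

    bridges = pd.read_csv(run_dir / "ctp_bridges.tsv", sep="\t")
    key_cols = ["se_id", "gene_id", "crc_tf", "partner_tf"]
    flagged = (
        {tuple(r) for r in bridges.loc[bridges["is_ctp"], key_cols].itertuples(index=False)}
        if len(bridges)
        else set()
    )
    trip = truth.ctp_triples
    med = trip[trip["mediated"]] if len(trip) else trip
    ctl = trip[~trip["mediated"]] if len(trip) else trip
    med_keys = {tuple(r) for r in med[key_cols].itertuples(index=False)} if len(med) else set()
    ctl_keys = {tuple(r) for r in ctl[key_cols].itertuples(index=False)} if len(ctl) else set()
    ctp_sens = len(med_keys & flagged) / len(med_keys) if med_keys else float("nan")
    ctp_ffr = len(ctl_keys & flagged) / len(ctl_keys) if ctl_keys else float("nan")

    with open(run_dir / "ctp_summary.json") as fh:
        summary = json.load(fh)

    metrics = {
        "activated_se_sensitivity": sens,
        "activated_se_fdr": fdr,
        "n_activated_called": len(called),
        "se_gene_auroc": auroc,
        "crc_set_equal": bool(crc_called == crc_true),
        "crc_jaccard": jaccard,
        "crc_called": sorted(crc_called),
        "ctp_sensitivity": ctp_sens,
        "ctp_false_flag_rate": ctp_ffr,
        "ci_confirmed_fraction": summary.get("ci_confirmed_fraction"),
        "mean_ctps_per_gene": summary.get("mean_ctps_per_gene"),
    }
    if out_path is not None:
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        with open(out_path, "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True, default=_default)
    return metrics
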
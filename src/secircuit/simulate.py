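"""Synthetic multi-omics cohort generator with planted ground truth.

Emulates the statistical structure the pipeline assumes in real tumor
cohorts, at desk scale:

* a synthetic genome with super-enhancer (SE) blocks on one chromosome and
  gene/TF loci on another;
* eRNA transcription (RPKM) driven by a latent per-sample SE-activity
  variable; a planted subset of SEs gains an ``activation_shift`` log2
  mean in cancer samples;
* gene expression (FPKM) where linked genes draw from the latent activity
  of an activated SE (rank correlation ~ ``link_strength``), plus
  sparsity from a detection limit;
* hypomethylated CpGs and preferentially amplified CNV segments inside
  activated SEs;
* JASPAR PWMs for every TF, with each planted CRC TF's consensus embedded
  at least five times in its own SE (and in partner SEs along a regulatory
  cycle), while decoy TFs carry at most two copies;
* CRC-TF/partner-TF pairs whose joint expression *mediates* an SE-to-gene
  correlation (so conditioning on the pair removes it), alongside control
  triples whose SE-gene correlation is direct;
* PPI edges supporting every true pair in at least two synthetic source
  datasets, with single-dataset decoys.

Everything is driven by one integer seed; the same config always produces
a byte-identical file bundle.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .stats import derive_seed

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort", "sample_random_regions"]

# geometry constants (bp)
SE_LENGTH = 4000
SE_SPACING = 10000
ERNA_LENGTH = 300
GENE_SLOT = 8000
RPKM_LIMIT = 0.5  # detection limit: values below become exact zeros
FPKM_LIMIT = 0.25
PPI_DATASETS = ("synthA", "synthB", "synthC")


@dataclass
class CohortConfig:
    """Generator settings; defaults are the package's reference conditions."""

    n_cancer: int = 50
    n_normal: int = 50
    n_se: int = 200
    frac_activated: float = 0.2
    activation_shift: float = 1.5
    n_genes: int = 1000
    frac_linked: float = 0.15
    link_strength: float = 0.7
    n_tfs: int = 30
    n_crc_tfs: int = 5
    motif_length: int = 10
    n_ctp_triples: int = 40
    noise_sd: float = 0.5
    seed: int = 7

    def validate(self) -> None:
        for name in ("n_cancer", "n_normal", "n_se", "n_genes", "n_tfs", "n_crc_tfs", "motif_length", "n_ctp_triples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_activated", "frac_linked"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if not (0.0 <= self.link_strength < 1.0):
            raise ValueError("link_strength must be in [0, 1)")
        if self.motif_length > SE_LENGTH:
            raise ValueError("motif_length exceeds the SE length; nothing can be planted")
        if self.n_crc_tfs > self.n_tfs:
            raise ValueError("n_crc_tfs cannot exceed n_tfs")
        if self.n_crc_tfs > math.ceil(0.15 * self.n_tfs):
            logging.getLogger(__name__).warning(
                "n_crc_tfs=%d exceeds the top-15%% master slots for n_tfs=%d; "
                "planted CRC TFs will not all be recoverable",
                self.n_crc_tfs, self.n_tfs,
            )


@dataclass
class GroundTruth:
    """Planted truth tables; every id resolves to a generated entity."""

    activated_se_ids: list[str]
    se_gene_links: pd.DataFrame  # se_id, gene_id, kind
    master_tf_ids: list[str]
    crc_tf_ids: list[str]
    crc_edges: pd.DataFrame  # tf_a, tf_b
    ctp_triples: pd.DataFrame  # se_id, gene_id, crc_tf, partner_tf, mediated
    hypo_cpg_ids: list[str]
    amplified_segment_ids: list[str]

    def write(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("activated_se_ids", "master_tf_ids", "crc_tf_ids", "hypo_cpg_ids", "amplified_segment_ids"):
            pd.Series(getattr(self, name), name="id").to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
        self.se_gene_links.to_csv(out_dir / "se_gene_links.tsv", sep="\t", index=False)
        self.crc_edges.to_csv(out_dir / "crc_edges.tsv", sep="\t", index=False)
        self.ctp_triples.to_csv(out_dir / "ctp_triples.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, truth_dir) -> "GroundTruth":
        truth_dir = Path(truth_dir)

        def ids(name):
            df = pd.read_csv(truth_dir / f"{name}.tsv", sep="\t")
            return [] if df.empty else df["id"].astype(str).tolist()

        return cls(
            activated_se_ids=ids("activated_se_ids"),
            se_gene_links=pd.read_csv(truth_dir / "se_gene_links.tsv", sep="\t"),
            master_tf_ids=ids("master_tf_ids"),
            crc_tf_ids=ids("crc_tf_ids"),
            crc_edges=pd.read_csv(truth_dir / "crc_edges.tsv", sep="\t"),
            ctp_triples=pd.read_csv(truth_dir / "ctp_triples.tsv", sep="\t"),
            hypo_cpg_ids=ids("hypo_cpg_ids"),
            amplified_segment_ids=ids("amplified_segment_ids"),
        )


# ---------------------------------------------------------------------------
# random region sampling
# ---------------------------------------------------------------------------


def sample_random_regions(
    genome: gio.FastaStore,
    n: int,
    length_source,
    exclude,
    seed: int = 0,
    max_tries_per_region: int = 200,
) -> list[gio.GenomicInterval]:
    """Length-matched random regions avoiding an exclusion set.

    Lengths are resampled (with replacement) from ``length_source``;
    placements are uniform over valid positions, seeded, and rejected when
    they overlap ``exclude`` or run off a chromosome.  Raises after a
    bounded number of retries, reporting how many regions were achieved.
    """
    rng = np.random.default_rng(seed)
    lengths = [iv.length for iv in length_source]
    if not lengths:
        raise ValueError("length_source is empty")
    chroms = genome.chrom_names
    chrom_len = np.array([genome.chrom_length(c) for c in chroms], dtype=float)
    weights = chrom_len / chrom_len.sum()
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in exclude:
        excl_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: list[gio.GenomicInterval] = []
    for i in range(n):
        length = int(lengths[rng.integers(0, len(lengths))])
        placed = False
        for _ in range(max_tries_per_region):
            ci = int(rng.choice(len(chroms), p=weights))
            chrom = chroms[ci]
            max_start = genome.chrom_length(chrom) - length
            if max_start < 0:
                continue
            start = int(rng.integers(0, max_start + 1))
            end = start + length
            hits = excl_by_chrom.get(chrom, [])
            if any(start < e and s < end for s, e in hits):
                continue
            out.append(gio.GenomicInterval(chrom, start, end, name=f"RAND{i:05d}"))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place region {i} after {max_tries_per_region} tries "
                f"(achieved {len(out)} of {n})"
            )
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _random_sequence(rng, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _embed(seq: np.ndarray, offset: int, word_codes: np.ndarray) -> None:
    seq[offset : offset + word_codes.size] = word_codes


def _codes(word: str) -> np.ndarray:
    lut = {b: i for i, b in enumerate(gio.ALPHABET)}
    return np.array([lut[c] for c in word], dtype=np.int8)


def _decode(seq: np.ndarray) -> str:
    return "".join(gio.ALPHABET[c] for c in seq)


def _log2_to_abundance(log2_vals: np.ndarray, limit: float) -> np.ndarray:
    v = np.power(2.0, log2_vals)
    v[v < limit] = 0.0
    return np.round(v, 6)


def generate_cohort(config: CohortConfig, out_dir) -> tuple[Path, GroundTruth]:
    """Write the full synthetic bundle and its ground truth to ``out_dir``.

    Returns ``(out_dir, GroundTruth)``.  The bundle contains exactly the
    formats the pipeline reads plus a ``manifest.json`` listing every file
    and a ``ground_truth/`` directory of TSV truth tables.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    n_c, n_n = config.n_cancer, config.n_normal
    samples = [f"C{i + 1:03d}" for i in range(n_c)] + [f"N{i + 1:03d}" for i in range(n_n)]
    labels = {s: ("cancer" if s.startswith("C") else "normal") for s in samples}
    is_cancer = np.array([1.0] * n_c + [0.0] * n_n)

    # --- entities -----------------------------------------------------------
    se_ids = [f"SE{i + 1:04d}" for i in range(config.n_se)]
    n_act = max(1, int(round(config.frac_activated * config.n_se))) if config.frac_activated > 0 else 0
    rng_layout = np.random.default_rng(derive_seed(seed, "layout"))
    act_idx = np.sort(rng_layout.choice(config.n_se, size=n_act, replace=False)) if n_act else np.array([], dtype=int)
    activated = np.zeros(config.n_se, dtype=bool)
    activated[act_idx] = True

    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    tf_ids = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]
    crc_tfs = tf_ids[: config.n_crc_tfs]

    # SE geometry on chrSE, gene slots on chrG
    se_regions = [
        gio.GenomicInterval("chrSE", i * SE_SPACING + 1000, i * SE_SPACING + 1000 + SE_LENGTH, se_ids[i])
        for i in range(config.n_se)
    ]
    chr_se_len = config.n_se * SE_SPACING + 2000
    all_feature_ids = gene_ids + tf_ids
    tss = []
    for i, gid in enumerate(all_feature_ids):
        pos = i * GENE_SLOT + GENE_SLOT // 2
        tss.append(gio.GenomicInterval("chrG", pos, pos + 1, gid, "+"))
    chr_g_len = len(all_feature_ids) * GENE_SLOT + 2000

    # eRNAs: 3-8 per SE, inside the SE
    erna_ids, erna_regions, erna_se = [], [], []
    for i, se in enumerate(se_regions):
        k = int(rng_layout.integers(3, 9))
        for j in range(k):
            start = se.start + 200 + j * 450
            eid = f"E{se_ids[i]}_{j + 1}"
            erna_ids.append(eid)
            erna_regions.append(gio.GenomicInterval("chrSE", start, start + ERNA_LENGTH, eid))
            erna_se.append(i)
    erna_se = np.array(erna_se)

    # --- latent SE activity and eRNA transcription --------------------------
    rng_expr = np.random.default_rng(derive_seed(seed, "expression"))
    delta = rng_expr.normal(0.0, 1.0, size=(config.n_se, len(samples)))
    activity = delta + config.activation_shift * activated[:, None] * is_cancer[None, :]

    erna_base = rng_expr.normal(-1.0, 1.5, size=len(erna_ids))
    erna_log2 = (
        erna_base[:, None]
        + activity[erna_se, :]
        + rng_expr.normal(0.0, config.noise_sd, size=(len(erna_ids), len(samples)))
    )
    erna_rpkm = _log2_to_abundance(erna_log2, RPKM_LIMIT)

    # --- SE-gene link plan ---------------------------------------------------
    n_linked = int(round(config.frac_linked * config.n_genes))
    n_mediated = min(config.n_ctp_triples, n_linked)
    n_control = min(config.n_ctp_triples, max(0, n_linked - n_mediated))
    n_plain = n_linked - n_mediated - n_control
    linked_genes = gene_ids[:n_linked]
    mediated_genes = linked_genes[:n_mediated]
    control_genes = linked_genes[n_mediated : n_mediated + n_control]
    plain_genes = linked_genes[n_mediated + n_control :]

    # TF-pair plan: each pair is one CRC TF plus a dedicated partner TF, and
    # is driven by the CRC TF's own SE
    n_partners = min(config.n_tfs - config.n_crc_tfs, max(2, int(math.ceil(config.n_ctp_triples / 5)))) if n_mediated else 0
    partner_tfs = tf_ids[config.n_crc_tfs : config.n_crc_tfs + n_partners]
    pairs = [(crc_tfs[k % len(crc_tfs)], partner_tfs[k]) for k in range(n_partners)]

    # each TF's own SE: a distinct activated SE when possible
    own_se: dict[str, int] = {}
    act_list = list(act_idx) if n_act else list(range(config.n_se))
    for i, tf in enumerate(tf_ids):
        own_se[tf] = act_list[i % len(act_list)]
    # partners share the driver SE of their pair's CRC TF
    pair_se = {}
    for crc, partner in pairs:
        pair_se[(crc, partner)] = own_se[crc]
        own_se[partner] = own_se[crc]

    driver_ses = {own_se[crc] for crc in crc_tfs}
    non_driver_act = [i for i in act_list if i not in driver_ses] or act_list

    links = []  # (se_idx, gene_id, kind)
    for j, g in enumerate(plain_genes):
        links.append((act_list[j % len(act_list)], g, "plain"))
    for j, g in enumerate(control_genes):
        links.append((non_driver_act[j % len(non_driver_act)], g, "control"))
    med_pair = [pairs[j % len(pairs)] for j in range(n_mediated)] if pairs else []
    for j, g in enumerate(mediated_genes):
        links.append((pair_se[med_pair[j]], g, "mediated"))
    for tf in tf_ids:
        links.append((own_se[tf], tf, "tf"))

    # --- TF expression --------------------------------------------------------
    ls = config.link_strength
    shift = config.activation_shift
    # CRC and partner TFs are driven by the transcription of their driver
    # SE's dominant (highest-base) eRNA, standardized within groups, so
    # that conditioning on the TF pair blocks the eRNA-to-gene path of
    # mediated triples; the dominant eRNA is the one least affected by the
    # detection limit, keeping the mediation path observable.  Other TFs
    # follow the latent SE activity directly.
    dominant_erna_of_se: dict[int, int] = {}
    for k, s_i in enumerate(erna_se):
        s_i = int(s_i)
        if s_i not in dominant_erna_of_se or erna_base[k] > erna_base[dominant_erna_of_se[s_i]]:
            dominant_erna_of_se[s_i] = k

    def _group_z(v: np.ndarray) -> np.ndarray:
        within_sd = math.sqrt(0.5 * (v[is_cancer > 0].var() + v[is_cancer == 0].var()))
        return (v - v[is_cancer == 0].mean()) / (within_sd + 1e-12)

    tf_log2 = {}
    for tf in tf_ids:
        se_i = own_se[tf]
        if tf in crc_tfs:
            base, a, offset = 5.5, max(ls, 0.95 if ls > 0 else 0.0), shift
        elif tf in partner_tfs:
            base, a, offset = 3.0, max(ls, 0.95 if ls > 0 else 0.0), shift * 0.7
        else:
            base, a, offset = 3.0, ls, shift * 0.7
        noise = math.sqrt(max(1.0 - a * a, 0.05))
        if tf in crc_tfs or tf in partner_tfs:
            driver = _group_z(erna_log2[dominant_erna_of_se[se_i]])
        else:
            driver = activity[se_i]
        tf_log2[tf] = (
            base
            + a * driver
            + offset * is_cancer
            + rng_expr.normal(0.0, noise, size=len(samples))
        )

    # --- gene expression ------------------------------------------------------
    gene_log2 = {}
    gene_base = rng_expr.normal(3.0, 1.5, size=config.n_genes)
    link_se = {g: s for s, g, _ in links}
    kind_of = {g: k for _, g, k in links}
    pair_of_mediated = dict(zip(mediated_genes, med_pair))
    noise_g = math.sqrt(max(1.0 - ls * ls, 0.05))
    # a slice of unlinked genes are cancer-DE for reasons unrelated to SEs
    n_decoy_de = int(0.1 * config.n_genes)
    decoy_de_offsets = rng_expr.normal(0.0, 1.5, size=n_decoy_de)
    for i, g in enumerate(gene_ids):
        base = gene_base[i]
        eps = rng_expr.normal(0.0, 1.0, size=len(samples))
        kind = kind_of.get(g)
        if kind in ("plain", "control"):
            se_i = link_se[g]
            vals = base + ls * activity[se_i] + shift * is_cancer + noise_g * eps
        elif kind == "mediated":
            crc, partner = pair_of_mediated[g]
            s = tf_log2[crc] + tf_log2[partner]
            # affine in the TF sum: center on the normal group and scale by
            # the within-group SD, so the gene inherits the TFs' cancer
            # upregulation while the within-cancer correlation stays at
            # ~ link_strength (a pooled-SD scaling would dilute it)
            within_sd = math.sqrt(
                0.5 * (s[is_cancer > 0].var() + s[is_cancer == 0].var())
            )
            s_std = (s - s[is_cancer == 0].mean()) / (within_sd + 1e-12)
            vals = base + ls * s_std + shift * is_cancer + noise_g * eps
        else:
            vals = base + eps
            if i >= config.n_genes - n_decoy_de:
                vals = vals + decoy_de_offsets[i - (config.n_genes - n_decoy_de)] * is_cancer
        gene_log2[g] = vals
    for tf in tf_ids:
        gene_log2[tf] = tf_log2[tf]
    fpkm = pd.DataFrame(
        {s: [gene_log2[g][k] for g in all_feature_ids] for k, s in enumerate(samples)},
        index=all_feature_ids,
    )
    fpkm_values = _log2_to_abundance(fpkm.to_numpy(), FPKM_LIMIT)
    fpkm = pd.DataFrame(fpkm_values, index=all_feature_ids, columns=samples)

    # --- methylation ----------------------------------------------------------
    rng_meth = np.random.default_rng(derive_seed(seed, "methylation"))
    cpg_regions, cpg_ids, hypo_ids = [], [], []
    beta_rows = []
    conc = 30.0
    for i, se in enumerate(se_regions):
        for j in range(2):
            cid = f"cg_{se_ids[i]}_{j + 1}"
            pos = se.start + 50 + j * 120
            cpg_ids.append(cid)
            cpg_regions.append(gio.GenomicInterval("chrSE", pos, pos + 1, cid))
            hypo = activated[i] and j == 0 and config.activation_shift > 0
            if hypo:
                hypo_ids.append(cid)
                mu_c, mu_n = 0.35, 0.65
            else:
                mu_c = mu_n = 0.55
            row = np.empty(len(samples))
            row[: n_c] = rng_meth.beta(mu_c * conc, (1 - mu_c) * conc, size=n_c)
            row[n_c:] = rng_meth.beta(mu_n * conc, (1 - mu_n) * conc, size=n_n)
            beta_rows.append(np.round(row, 6))
    beta = pd.DataFrame(beta_rows, index=cpg_ids, columns=samples)

    # --- CNV segments ---------------------------------------------------------
    rng_cnv = np.random.default_rng(derive_seed(seed, "cnv"))
    seg_rows = []
    amplified_ids = []
    for s in samples:
        cancer = labels[s] == "cancer"
        if cancer and n_act:
            for i in act_idx:
                if rng_cnv.random() < 0.35:
                    se = se_regions[i]
                    start = max(0, se.start - 500)
                    end = min(chr_se_len, se.end + 500)
                    lr = float(rng_cnv.normal(1.2, 0.2))
                    seg_rows.append((s, "chrSE", start, end, round(lr, 4)))
                    amplified_ids.append(f"{s}:chrSE:{start}-{end}")
        for _ in range(5):  # neutral background segments
            start = int(rng_cnv.integers(0, chr_se_len - 3000))
            seg_rows.append((s, "chrSE", start, start + 3000, round(float(rng_cnv.normal(0.0, 0.1)), 4)))
        if cancer:
            for _ in range(2):  # deletions placed without SE preference
                start = int(rng_cnv.integers(0, chr_se_len - 2000))
                seg_rows.append((s, "chrSE", start, start + 2000, round(float(rng_cnv.normal(-1.2, 0.2)), 4)))
    seg = pd.DataFrame(seg_rows, columns=gio.SEG_COLUMNS)

    # --- genome, PWMs and motif planting -------------------------------------
    rng_seq = np.random.default_rng(derive_seed(seed, "genome"))
    chr_se = _random_sequence(rng_seq, chr_se_len)
    chr_g = _random_sequence(rng_seq, chr_g_len)

    consensus = {}
    pwm_counts = {}
    for tf in tf_ids:
        word = _decode(_random_sequence(rng_seq, config.motif_length))
        consensus[tf] = word
        counts = np.full((4, config.motif_length), 5, dtype=int)
        for j, b in enumerate(word):
            counts[gio.ALPHABET.index(b), j] = 85
        pwm_counts[f"M_{tf}"] = counts

    def mutate(word: str) -> str:
        n_mut = max(1, int(round(0.1 * len(word))))
        pos = rng_seq.choice(len(word), size=n_mut, replace=False)
        w = list(word)
        for p in pos:
            w[p] = gio.ALPHABET[(gio.ALPHABET.index(w[p]) + 1 + int(rng_seq.integers(0, 3))) % 4]
        return "".join(w)

    def plant_in_se(se_i: int, word: str, n_exact: int, n_mut: int, lane: int) -> None:
        # lanes keep different TFs' plantings at disjoint offsets
        se = se_regions[se_i]
        step = config.motif_length + 5
        base_off = 20 + lane * (step * 8)
        k = 0
        for _ in range(n_exact):
            _embed(chr_se, se.start + base_off + k * step, _codes(word))
            k += 1
        for _ in range(n_mut):
            _embed(chr_se, se.start + base_off + k * step, _codes(mutate(word)))
            k += 1

    def plant_in_promoter(gene_id: str, word: str, n_copies: int, lane: int) -> None:
        t = tss[all_feature_ids.index(gene_id)]
        step = config.motif_length + 5
        start = max(0, t.start - 2800) + lane * (step * 6)
        for k in range(n_copies):
            _embed(chr_g, start + k * step, _codes(word))

    crc_edges_rows = []
    for idx, tf in enumerate(crc_tfs):
        plant_in_se(own_se[tf], consensus[tf], 5, 1, lane=0)
        crc_edges_rows.append((tf, tf))
        if len(crc_tfs) > 1:
            target = crc_tfs[(idx + 1) % len(crc_tfs)]
            plant_in_se(own_se[target], consensus[tf], 5, 0, lane=1)
            crc_edges_rows.append((tf, target))
    for tf in tf_ids[config.n_crc_tfs :]:
        if tf in partner_tfs:
            continue
        plant_in_se(own_se[tf], consensus[tf], 2, 0, lane=2)  # decoys: below threshold
    for lane_k, (crc, partner) in enumerate(pairs):
        plant_in_se(pair_se[(crc, partner)], consensus[partner], 6, 0, lane=3)
        p_genes = [g for g in mediated_genes if pair_of_mediated[g] == (crc, partner)]
        if p_genes:
            plant_in_promoter(p_genes[0], consensus[partner], 5, lane=0)
        for g in p_genes[:2]:
            plant_in_promoter(g, consensus[crc], 5, lane=1)

    genome_seqs = {"chrSE": _decode(chr_se), "chrG": _decode(chr_g)}

    # --- contacts -------------------------------------------------------------
    rng_ct = np.random.default_rng(derive_seed(seed, "contacts"))
    contact_pairs = []
    seen = set()
    for se_i, g, _kind in links:
        se = se_regions[se_i]
        t = tss[all_feature_ids.index(g)]
        a = gio.GenomicInterval("chrSE", se.start + 1500, se.start + 2500, f"{se.name}|{g}")
        b = gio.GenomicInterval("chrG", max(0, t.start - 100), t.start + 100, f"{se.name}|{g}")
        contact_pairs.append((a, b))
        seen.add((se_i, g))
    unlinked = [g for g in gene_ids if g not in link_se]
    n_decoys = len(contact_pairs)
    tries = 0
    while len(contact_pairs) < 2 * n_decoys and tries < 20 * n_decoys and unlinked:
        tries += 1
        se_i = int(rng_ct.integers(0, config.n_se))
        g = unlinked[int(rng_ct.integers(0, len(unlinked)))]
        if (se_i, g) in seen:
            continue
        seen.add((se_i, g))
        se = se_regions[se_i]
        t = tss[all_feature_ids.index(g)]
        a = gio.GenomicInterval("chrSE", se.start + 1500, se.start + 2500, f"{se.name}|{g}")
        b = gio.GenomicInterval("chrG", max(0, t.start - 100), t.start + 100, f"{se.name}|{g}")
        contact_pairs.append((a, b))

    # --- PPIs -----------------------------------------------------------------
    rng_ppi = np.random.default_rng(derive_seed(seed, "ppi"))
    ppi_rows = []
    for crc, partner in pairs:
        k = 2 + int(rng_ppi.integers(0, 2))  # 2 or 3 datasets
        for ds in rng_ppi.choice(PPI_DATASETS, size=k, replace=False):
            ppi_rows.append((crc, partner, str(ds)))
    true_pairs = {frozenset(p) for p in pairs}
    n_ppi_decoys = 0
    while n_ppi_decoys < config.n_tfs and len(tf_ids) > 1:
        a, b = rng_ppi.choice(tf_ids, size=2, replace=False)
        if frozenset((a, b)) in true_pairs:
            continue
        ppi_rows.append((str(a), str(b), str(rng_ppi.choice(PPI_DATASETS))))
        n_ppi_decoys += 1
    ppi = pd.DataFrame(ppi_rows, columns=gio.PPI_COLUMNS)

    # --- write the bundle -----------------------------------------------------
    files = {}

    def emit(name, writer):
        path = out_dir / name
        writer(path)
        files[name] = name

    emit("genome.fa", lambda p: gio.write_fasta(genome_seqs, p))
    emit("se_regions.bed", lambda p: gio.write_bed(se_regions, p))
    emit("erna_loci.bed", lambda p: gio.write_bed(erna_regions, p))
    emit("gene_tss.bed", lambda p: gio.write_bed(tss, p))
    emit("cpg_loci.bed", lambda p: gio.write_bed(cpg_regions, p))
    emit("sample_labels.tsv", lambda p: gio.write_labels(labels, p))
    erna_df = pd.DataFrame(erna_rpkm, index=erna_ids, columns=samples)
    emit("erna_rpkm.tsv", lambda p: gio.write_matrix(gio.LabeledMatrix(erna_df, labels), p))
    emit("gene_fpkm.tsv", lambda p: gio.write_matrix(gio.LabeledMatrix(fpkm, labels), p))
    emit("methylation_beta.tsv", lambda p: gio.write_matrix(gio.LabeledMatrix(beta, labels), p))
    emit("cnv_segments.seg", lambda p: gio.write_seg(seg, p))
    emit("contacts.bedpe", lambda p: gio.write_bedpe(contact_pairs, p))
    emit("motifs.jaspar", lambda p: gio.write_jaspar(pwm_counts, p))
    emit("tf_list.tsv", lambda p: pd.DataFrame({"tf_id": tf_ids, "pwm_id": [f"M_{t}" for t in tf_ids]}).to_csv(p, sep="\t", index=False))
    emit("ppi_edges.tsv", lambda p: gio.write_ppi(ppi, p))

    links_df = pd.DataFrame(
        [(se_ids[s], g, k) for s, g, k in links], columns=["se_id", "gene_id", "kind"]
    )
    ctp_rows = []
    for j, g in enumerate(mediated_genes):
        crc, partner = med_pair[j]
        ctp_rows.append((se_ids[pair_se[(crc, partner)]], g, crc, partner, True))
    for j, g in enumerate(control_genes):
        crc, partner = pairs[j % len(pairs)] if pairs else (None, None)
        if crc is None:
            continue
        ctp_rows.append((se_ids[link_se[g]], g, crc, partner, False))
    truth = GroundTruth(
        activated_se_ids=[se_ids[i] for i in act_idx],
        se_gene_links=links_df,
        master_tf_ids=list(crc_tfs),
        crc_tf_ids=list(crc_tfs),
        crc_edges=pd.DataFrame(crc_edges_rows, columns=["tf_a", "tf_b"]),
        ctp_triples=pd.DataFrame(
            ctp_rows, columns=["se_id", "gene_id", "crc_tf", "partner_tf", "mediated"]
        ),
        hypo_cpg_ids=hypo_ids,
        amplified_segment_ids=amplified_ids,
    )
    truth.write(out_dir / "ground_truth")

    manifest = {
        "config": asdict(config),
        "files": sorted(files),
        "ground_truth_dir": "ground_truth",
        "counts": {
            "samples": len(samples),
            "ses": config.n_se,
            "activated_ses": int(n_act),
            "ernas": len(erna_ids),
            "genes": config.n_genes,
            "tfs": config.n_tfs,
            "crc_tfs": config.n_crc_tfs,
            "linked_genes": n_linked,
            "mediated_triples": int((truth.ctp_triples["mediated"] == True).sum()) if len(truth.ctp_triples) else 0,  # noqa: E712
            "control_triples": int((truth.ctp_triples["mediated"] == False).sum()) if len(truth.ctp_triples) else 0,  # noqa: E712
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out_dir, truth
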
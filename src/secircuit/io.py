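"""Readers and writers for the standard genomic formats the pipeline touches.

Supported formats: BED3-6, BEDPE, FASTA, JASPAR PWM text, SEG-like CNV
tables, TSV expression/methylation matrices with a sample-label sidecar,
and TSV protein-protein interaction edge lists.  Gzip input is handled
transparently (by ``.gz`` suffix).

Coordinate convention is 0-based half-open everywhere; ``to_zero_based``
converts 1-based inclusive coordinates at the boundary.  Readers reject
malformed records with the offending line number rather than repairing
them silently.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

__all__ = [
    "GenomicInterval",
    "LabeledMatrix",
    "PWM",
    "FastaStore",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "read_jaspar",
    "write_jaspar",
    "read_seg",
    "write_seg",
    "read_fasta",
    "write_fasta",
    "read_ppi",
    "write_ppi",
    "to_zero_based",
    "intervals_overlap",
    "overlap_any",
    "assign_containing",
    "promoter_window",
    "reverse_complement",
]

ALPHABET = "ACGT"


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def to_zero_based(chrom: str, start_1based: int, end_inclusive: int, **kw) -> GenomicInterval:
    """Convert 1-based inclusive coordinates to the half-open convention."""
    return GenomicInterval(chrom, start_1based - 1, end_inclusive, **kw)


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_any(queries, targets) -> np.ndarray:
    """Boolean vector: does each query overlap >= 1 bp of any target?

    Brute force grouped by chromosome; adequate at the region counts this
    pipeline works with.
    """
    queries = list(queries)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
    out = np.zeros(len(queries), dtype=bool)
    arr = {c: (np.array([s for s, _ in v]), np.array([e for _, e in v])) for c, v in by_chrom.items()}
    for i, q in enumerate(queries):
        if q.chrom not in arr:
            continue
        s, e = arr[q.chrom]
        out[i] = bool(np.any((q.start < e) & (s < q.end)))
    return out


def assign_containing(queries, containers) -> list[str | None]:
    """For each query, the name of the container that fully contains it.

    Returns ``None`` where no container (or more than one) contains the
    query; ambiguity is treated as unmapped.
    """
    out: list[str | None] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for c in containers:
        by_chrom.setdefault(c.chrom, []).append(c)
    for q in queries:
        hits = [
            c.name
            for c in by_chrom.get(q.chrom, [])
            if c.start <= q.start and q.end <= c.end
        ]
        out.append(hits[0] if len(hits) == 1 else None)
    return out


def promoter_window(
    tss: GenomicInterval, halfwidth: int = 3000, chrom_length: int | None = None
) -> GenomicInterval:
    """Promoter = TSS +/- ``halfwidth``, strand-aware, clipped to the chromosome.

    The TSS position is ``start`` for ``+``/unstranded records and
    ``end - 1`` for ``-`` strand records.
    """
    pos = tss.start if tss.strand in ("+", ".") else tss.end - 1
    start = max(0, pos - halfwidth)
    end = pos + halfwidth + 1
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(tss.chrom, start, end, name=tss.name, strand=tss.strand)


# ---------------------------------------------------------------------------
# BED / BEDPE
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has < 3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, name, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals, path, scores=None) -> None:
    with _open(path, "wt") as fh:
        for i, iv in enumerate(intervals):
            score = "0" if scores is None else f"{scores[i]:.6g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def read_bedpe(path) -> list[tuple[GenomicInterval, GenomicInterval]]:
    out = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: BEDPE line has < 6 columns")
            name = f[6] if len(f) > 6 else "."
            try:
                a = GenomicInterval(f[0], int(f[1]), int(f[2]), name)
                b = GenomicInterval(f[3], int(f[4]), int(f[5]), name)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append((a, b))
    return out


def write_bedpe(pairs, path) -> None:
    with _open(path, "wt") as fh:
        for a, b in pairs:
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t{a.name}\n"
            )


# ---------------------------------------------------------------------------
# labeled matrices
# ---------------------------------------------------------------------------


@dataclass
class LabeledMatrix:
    """A feature x sample matrix with cancer/normal sample labels.

    Values are floats; missing entries are NaN and are distinct from zero
    (sparsity filters count zeros, not missing).
    """

    values: pd.DataFrame
    sample_labels: dict[str, str]
    removed_rows: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate row ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = [c for c in self.values.columns if c not in self.sample_labels]
        if missing:
            raise ValueError(f"samples without labels: {missing[:5]}")
        bad = {v for v in self.sample_labels.values()} - {"cancer", "normal"}
        if bad:
            raise ValueError(f"unknown sample classes: {sorted(bad)}")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)

    def columns_of(self, label: str) -> list[str]:
        return [c for c in self.values.columns if self.sample_labels[c] == label]

    @property
    def cancer(self) -> pd.DataFrame:
        return self.values[self.columns_of("cancer")]

    @property
    def normal(self) -> pd.DataFrame:
        return self.values[self.columns_of("normal")]

    def row(self, row_id: str) -> np.ndarray:
        return self.values.loc[row_id].to_numpy(dtype=float)

    def subset_rows(self, row_ids) -> "LabeledMatrix":
        return replace(self, values=self.values.loc[list(row_ids)], removed_rows=[])


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"], dtype=str)
    return dict(zip(df["sample"], df["label"]))


def write_labels(labels: dict[str, str], path) -> None:
    with _open(path, "wt") as fh:
        for s, lab in labels.items():
            fh.write(f"{s}\t{lab}\n")


def read_matrix(path, label_path) -> LabeledMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    labels = read_labels(label_path)
    return LabeledMatrix(df.astype(float), labels)


def write_matrix(matrix: LabeledMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# JASPAR PWMs
# ---------------------------------------------------------------------------


@dataclass
class PWM:
    """Position weight matrix over ACGT with a background model.

    ``probs`` is a 4 x L array of per-position base probabilities built
    from counts with a background-weighted pseudocount; columns sum to one.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.1
    consensus: str = ""

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 4:
            raise ValueError(f"{self.motif_id}: PWM must be 4 x L with L >= 4")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: PWM columns must sum to 1")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("background must sum to 1")
        if not self.consensus:
            self.consensus = "".join(ALPHABET[i] for i in self.probs.argmax(axis=0))

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def from_counts(cls, motif_id, counts, background=None, pseudocount: float = 0.1) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4:
            raise ValueError(f"{motif_id}: counts must have 4 rows (ACGT)")
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        col = counts.sum(axis=0)
        probs = (counts + pseudocount * background[:, None]) / (col + pseudocount)
        return cls(motif_id, probs, background, pseudocount)


def read_jaspar(path, background=None, pseudocount: float = 0.1) -> list[PWM]:
    with _open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
        out = []
        for m in records:
            counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
            mid = m.matrix_id or m.name
            out.append(PWM.from_counts(mid, counts, background, pseudocount))
    return out


def write_jaspar(pwm_counts: dict[str, np.ndarray], path) -> None:
    """Write integer count matrices in JASPAR 2016 text format."""
    with _open(path, "wt") as fh:
        for mid, counts in pwm_counts.items():
            counts = np.asarray(counts)
            fh.write(f">{mid}\t{mid}\n")
            for i, base in enumerate(ALPHABET):
                row = " ".join(f"{int(v):6d}" for v in counts[i])
                fh.write(f"{base}  [{row} ]\n")


# ---------------------------------------------------------------------------
# SEG-like CNV tables
# ---------------------------------------------------------------------------

SEG_COLUMNS = ["sample", "chrom", "start", "end", "log2_ratio"]


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SEG file missing columns: {missing}")
    df = df[SEG_COLUMNS].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"SEG row {bad}: start >= end")
    return df


def write_seg(df: pd.DataFrame, path) -> None:
    df[SEG_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


class FastaStore:
    """In-memory genome with subsequence extraction by half-open interval."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {str(k): str(v).upper() for k, v in sequences.items()}

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, interval: GenomicInterval) -> str:
        if interval.chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        seq = self._seqs[interval.chrom]
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {len(seq)}"
            )
        return seq[interval.start : interval.end]

    def mono_frequencies(self) -> np.ndarray:
        """Genome-wide mononucleotide frequencies over ACGT (N ignored)."""
        counts = np.zeros(4)
        for seq in self._seqs.values():
            for i, b in enumerate(ALPHABET):
                counts[i] += seq.count(b)
        total = counts.sum()
        return counts / total if total > 0 else np.full(4, 0.25)


_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def read_fasta(path) -> FastaStore:
    with _open(path) as fh:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    for name, seq in seqs.items():
        bad = set(seq.upper()) - set(ALPHABET + "N")
        if bad:
            raise ValueError(f"{name}: invalid characters {sorted(bad)}")
    return FastaStore(seqs)


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with _open(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PPI edges
# ---------------------------------------------------------------------------

PPI_COLUMNS = ["tf_a", "tf_b", "dataset"]


def read_ppi(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PPI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PPI file missing columns: {missing}")
    return df[PPI_COLUMNS].astype(str)


def write_ppi(df: pd.DataFrame, path) -> None:
    df[PPI_COLUMNS].to_csv(path, sep="\t", index=False)
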
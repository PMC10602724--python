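"""PWM motif scanning with exact p-values.

Scores every position of a sequence (both strands) against a position
weight matrix using log-odds in bits relative to a mononucleotide
background, and attaches to every score an *exact* p-value: the
probability, under the background model, that a random word of motif
length scores at least as high.  The null score distribution is computed
by dynamic programming over the per-position score distributions after
quantizing scores to a fixed step (default 0.005 bits), so the p < 1e-4
hit threshold is deterministic rather than estimated by shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ALPHABET, FastaStore, GenomicInterval, PWM

__all__ = ["MotifHit", "ScoredPWM", "scan_pwm", "scan_regions", "count_hits"]

QUANT_STEP = 0.005  # bits; quantization step of the score grid

_CODE = {b: i for i, b in enumerate(ALPHABET)}


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else (N) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int64)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


@dataclass(frozen=True)
class MotifHit:
    """A significant motif occurrence."""

    pwm_id: str
    interval: GenomicInterval
    strand: str
    score: float  # log-odds, bits
    p_value: float


class ScoredPWM:
    """A PWM prepared for scanning: quantized log-odds and exact null tail.

    The integer score of word ``w`` is ``sum_j round(log2(p[j, w_j] /
    bg[w_j]) / step)``; ``pvalue(s)`` returns the exact background
    probability of a word scoring ``>= s`` on the same integer grid.
    """

    def __init__(self, pwm: PWM, background: np.ndarray | None = None, step: float = QUANT_STEP):
        self.pwm = pwm
        self.step = float(step)
        bg = pwm.background if background is None else np.asarray(background, dtype=float)
        if np.any(bg <= 0):
            raise ValueError("background frequencies must be positive")
        self.background = bg / bg.sum()
        logodds = np.log2(pwm.probs / self.background[:, None])  # (4, L)
        self.int_scores = np.rint(logodds / self.step).astype(np.int64).T  # (L, 4)
        self._build_null()

    @property
    def length(self) -> int:
        return self.int_scores.shape[0]

    def _build_null(self) -> None:
        mins = self.int_scores.min(axis=1)
        spans = self.int_scores.max(axis=1) - mins
        self._min_total = int(mins.sum())
        size = int(spans.sum()) + 1
        dist = np.zeros(size)
        dist[0] = 1.0
        width = 1
        for j in range(self.length):
            new = np.zeros(size)
            offs = self.int_scores[j] - mins[j]
            for b in range(4):
                o = int(offs[b])
                new[o : o + width] += dist[:width] * self.background[b]
            dist = new
            width += int(spans[j])
        # tail[k] = P(total shifted score >= k)
        self._tail = np.cumsum(dist[::-1])[::-1]
        self._dist = dist

    @property
    def null_distribution(self) -> np.ndarray:
        """Exact probability mass over the shifted integer score grid."""
        return self._dist

    def pvalue(self, int_score: int | np.ndarray):
        """Exact p-value(s) for integer score(s) on this PWM's grid."""
        idx = np.asarray(int_score) - self._min_total
        idx = np.clip(idx, 0, self._tail.size - 1)
        p = self._tail[idx]
        return float(p) if np.isscalar(int_score) or np.ndim(int_score) == 0 else p

    def score_word(self, word: str) -> int:
        codes = encode_sequence(word)
        if codes.size != self.length or (codes == 4).any():
            raise ValueError("word must be ACGT of motif length")
        return int(self.int_scores[np.arange(self.length), codes].sum())


def _window_scores(codes: np.ndarray, int_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores of all windows plus a validity mask (no N)."""
    L = int_scores.shape[0]
    n_win = codes.size - L + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    safe = np.where(codes == 4, 0, codes)
    total = np.zeros(n_win, dtype=np.int64)
    invalid = np.zeros(n_win, dtype=bool)
    for j in range(L):
        col = safe[j : j + n_win]
        total += int_scores[j][col]
        invalid |= codes[j : j + n_win] == 4
    return total, ~invalid


def scan_pwm(
    sequence: str,
    pwm: PWM | ScoredPWM,
    p_thresh: float = 1e-4,
    background: np.ndarray | None = None,
    chrom: str = ".",
    offset: int = 0,
) -> list[MotifHit]:
    """All positions on both strands where the PWM scores with p < p_thresh.

    Windows containing N are skipped.  Overlapping hits are reported
    individually; reverse-strand hits are reported on forward-strand
    coordinates.  Returns an empty list when the motif is longer than the
    sequence.
    """
    spwm = pwm if isinstance(pwm, ScoredPWM) else ScoredPWM(pwm, background)
    codes = encode_sequence(sequence)
    L = spwm.length
    hits: list[MotifHit] = []
    rc_scores = spwm.int_scores[::-1, ::-1]  # motif on the minus strand
    for strand, mat in (("+", spwm.int_scores), ("-", rc_scores)):
        scores, valid = _window_scores(codes, mat)
        if scores.size == 0:
            continue
        pvals = spwm.pvalue(scores)
        sel = np.nonzero(valid & (pvals < p_thresh))[0]
        for i in sel:
            iv = GenomicInterval(chrom, offset + int(i), offset + int(i) + L, spwm.pwm.motif_id)
            hits.append(MotifHit(spwm.pwm.motif_id, iv, strand, float(scores[i] * spwm.step), float(pvals[i])))
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def scan_regions(
    genome: FastaStore,
    regions,
    pwm: PWM | ScoredPWM,
    p_thresh: float = 1e-4,
    background: np.ndarray | None = None,
) -> list[MotifHit]:
    """Scan a PWM over a list of genomic regions, in genomic coordinates."""
    spwm = pwm if isinstance(pwm, ScoredPWM) else ScoredPWM(pwm, background)
    hits: list[MotifHit] = []
    for region in regions:
        seq = genome.fetch(region)
        hits.extend(
            scan_pwm(seq, spwm, p_thresh, chrom=region.chrom, offset=region.start)
        )
    return hits


def count_hits(
    genome: FastaStore,
    regions,
    pwm: PWM | ScoredPWM,
    p_thresh: float = 1e-4,
    background: np.ndarray | None = None,
) -> int:
    return len(scan_regions(genome, regions, pwm, p_thresh, background))
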
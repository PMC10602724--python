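"""Statistical primitives for the super-enhancer circuitry pipeline.

This module collects the rank-based and information-theoretic machinery the
pipeline is built on:

* a one-sided Mann-Whitney U test on the low-expression tails of two sample
  groups (``trimmed_group_test``), used for eRNA activation, differential
  expression and differential methylation calls;
* Benjamini-Hochberg FDR adjustment (``bh_adjust``);
* Fisher's exact enrichment on 2x2 region-overlap tables
  (``fisher_enrichment``);
* plug-in mutual information on equal-frequency-discretized vectors with a
  permutation Fisher-Z p-value (``mutual_information``,
  ``mi_permutation_p``);
* first- and second-order Spearman partial correlation
  (``partial_spearman``);
* a stratified-permutation conditional-independence test based on
  conditional mutual information (``conditional_independence_test``).

All stochastic routines take an explicit integer seed and are reproducible
bit-for-bit on a fixed platform.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TrimmedGroupSummary",
    "MIResult",
    "PartialCorrelationResult",
    "trimmed_group_test",
    "bh_adjust",
    "fisher_enrichment",
    "mutual_information",
    "mi_permutation_p",
    "partial_spearman",
    "conditional_independence_test",
    "default_n_bins",
    "equal_frequency_bins",
    "derive_seed",
]


def derive_seed(seed: int, *tokens: object) -> int:
    """Derive a stable sub-seed from a global seed and entity identifiers.

    Uses CRC32 over the token string so the result does not depend on
    Python's per-process hash randomization or on iteration order.
    """
    h = zlib.crc32("|".join(str(t) for t in tokens).encode("utf-8"))
    return (int(seed) ^ h) % (2**31 - 1)


# ---------------------------------------------------------------------------
# trimmed one-sided Mann-Whitney U test
# ---------------------------------------------------------------------------


@dataclass
class TrimmedGroupSummary:
    """Result of the trimmed-low-tail one-sided Mann-Whitney U test.

    ``mu_c`` / ``mu_n`` are means over the *selected* (trimmed) cancer and
    normal subsets only.  ``q_value`` is NaN until BH adjustment is applied
    by the caller across a family of tests.
    """

    mu_c: float
    mu_n: float
    trim_fraction: float
    alternative: str
    p_value: float
    q_value: float = math.nan
    degenerate: bool = False


def _trim_low(values: np.ndarray, trim_fraction: float) -> np.ndarray:
    """Lowest ``floor(trim_fraction * n)`` finite values (at least one).

    Ties at the boundary are broken by stable sort order, so the selection
    is deterministic for a fixed input ordering.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values to trim")
    k = max(1, int(math.floor(trim_fraction * v.size)))
    order = np.argsort(v, kind="stable")
    return v[order[:k]]


def trimmed_group_test(
    cancer_values,
    normal_values,
    trim_fraction: float = 0.3,
    alternative: str = "greater",
) -> TrimmedGroupSummary:
    """One-sided Mann-Whitney U test between trimmed low tails of two groups.

    Selects the ``floor(trim_fraction * n)`` lowest values of each group
    (minimum one value) and compares the cancer subset against the normal
    subset with a one-sided Mann-Whitney U test (normal approximation with
    tie correction).  ``alternative='greater'`` tests whether the cancer
    low tail sits above the normal low tail.

    Degenerate inputs (all selected values identical across both subsets)
    yield a flagged result with ``p_value = 1`` rather than raising, so
    genome-scale loops never abort.
    """
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less', got {alternative!r}")
    if not (0.0 < trim_fraction <= 1.0):
        raise ValueError(f"trim_fraction must be in (0, 1], got {trim_fraction}")
    c = _trim_low(cancer_values, trim_fraction)
    n = _trim_low(normal_values, trim_fraction)
    mu_c = float(np.mean(c))
    mu_n = float(np.mean(n))
    pooled = np.concatenate([c, n])
    if np.ptp(pooled) == 0.0:
        return TrimmedGroupSummary(mu_c, mu_n, trim_fraction, alternative, 1.0, degenerate=True)
    res = sps.mannwhitneyu(c, n, alternative=alternative, method="asymptotic")
    p = float(min(1.0, res.pvalue))
    if not math.isfinite(p):  # pragma: no cover - scipy guards this already
        return TrimmedGroupSummary(mu_c, mu_n, trim_fraction, alternative, 1.0, degenerate=True)
    return TrimmedGroupSummary(mu_c, mu_n, trim_fraction, alternative, p)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserved.

    NaN entries propagate as NaN; the remaining entries are adjusted as a
    family of their own (NaNs neither count toward ``m`` nor perturb
    neighbours).
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        valid = p[mask]
        if valid.min() < 0 or valid.max() > 1:
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(valid, method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Fisher's exact enrichment
# ---------------------------------------------------------------------------


def fisher_enrichment(
    in_set_hits: int, in_set_total: int, bg_hits: int, bg_total: int
) -> tuple[float, float]:
    """One-sided Fisher's exact enrichment of hits in a set vs background.

    The 2x2 table is ``[[hits_in, misses_in], [hits_bg, misses_bg]]``.
    Returns ``(odds_ratio, p_value)`` where the odds ratio is the
    cross-product ratio, with a Haldane 0.5 correction applied only when a
    cell is zero, and the p-value is the one-sided (enrichment) exact tail.
    """
    for name, (h, t) in {
        "in_set": (in_set_hits, in_set_total),
        "background": (bg_hits, bg_total),
    }.items():
        if t <= 0:
            raise ValueError(f"{name} margin total must be positive, got {t}")
        if h < 0 or h > t:
            raise ValueError(f"{name} hits must satisfy 0 <= hits <= total ({h}/{t})")
    a, b = in_set_hits, in_set_total - in_set_hits
    c, d = bg_hits, bg_total - bg_hits
    if 0 in (a, b, c, d):
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    odds_ratio = (aa * dd) / (bb * cc)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds_ratio), float(p)


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------


def default_n_bins(n: int) -> int:
    """Default bin count ``floor(sqrt(n / 5))`` clamped to [2, 10]."""
    return int(min(10, max(2, math.floor(math.sqrt(n / 5)))))


def equal_frequency_bins(x, n_bins: int) -> np.ndarray:
    """Equal-frequency (quantile) bin indices in ``[0, n_bins)``.

    Ties are split deterministically by stable sort order, so identical
    inputs always produce identical binnings.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    ranks = np.empty(n, dtype=np.int64)
    ranks[np.argsort(x, kind="stable")] = np.arange(n)
    return (ranks * n_bins) // n


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _mi_from_joint(joint: np.ndarray) -> float:
    """Plug-in MI (bits) by direct double sum over a contingency table."""
    n = joint.sum()
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log2(pxy / (px * py))
    return float(np.nansum(terms))


def mutual_information(x, y, n_bins: int | None = None) -> tuple[float, float]:
    """Plug-in mutual information (bits) and normalized MI of two vectors.

    Both vectors are discretized by equal-frequency binning into ``n_bins``
    bins; MI is the base-2 plug-in estimate over the joint histogram and
    ``nmi = MI / sqrt(H(X) * H(Y))`` (0 when either marginal entropy is 0).
    Constant vectors yield ``(0, 0)`` with a logged warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if n_bins is None:
        n_bins = default_n_bins(x.size)
    if x.size < 3 * n_bins:
        raise ValueError(f"need at least 3*n_bins={3 * n_bins} samples, got {x.size}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        logger.warning("mutual_information: constant input vector, returning MI=0")
        return 0.0, 0.0
    bx = equal_frequency_bins(x, n_bins)
    by = equal_frequency_bins(y, n_bins)
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).reshape(n_bins, n_bins)
    mi = _mi_from_joint(joint.astype(float))
    hx = _entropy(joint.sum(axis=1) / x.size)
    hy = _entropy(joint.sum(axis=0) / x.size)
    if hx <= 0.0 or hy <= 0.0:
        return max(mi, 0.0), 0.0
    nmi = mi / math.sqrt(hx * hy)
    return max(mi, 0.0), float(min(max(nmi, 0.0), 1.0))


@dataclass
class MIResult:
    """Mutual information with a permutation Fisher-Z p-value.

    ``z_obs`` is the Fisher-Z (atanh) transform of the observed normalized
    MI; ``z_perm_mean``/``z_perm_sd`` are the mean and SD of the transforms
    of the permuted normalized MIs; the p-value is the two-sided normal
    tail ``2 * Phi(-|Z - z'| / sigma_z)``.
    """

    mi: float
    nmi: float
    z_obs: float
    z_perm_mean: float
    z_perm_sd: float
    p_value: float
    n_perm: int
    seed: int
    degenerate: bool = False


_ATANH_CLAMP = 1.0 - 1e-9


def _perm_nmi(bx: np.ndarray, by: np.ndarray, n_bins: int, n_perm: int, rng) -> np.ndarray:
    """Normalized MI for ``n_perm`` random permutations of ``by``, vectorized.

    Permutation preserves both marginals, so the marginal entropies are
    computed once.
    """
    n = bx.size
    B = n_bins
    perm = rng.permuted(np.tile(by, (n_perm, 1)), axis=1)
    codes = bx[None, :] * B + perm + (np.arange(n_perm)[:, None] * (B * B))
    counts = np.bincount(codes.ravel(), minlength=n_perm * B * B).reshape(n_perm, B, B)
    pxy = counts / n
    px = np.bincount(bx, minlength=B) / n
    py = np.bincount(by, minlength=B) / n
    denom = px[None, :, None] * py[None, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log2(pxy / denom)
    mi = np.nansum(terms, axis=(1, 2))
    hx, hy = _entropy(px), _entropy(py)
    if hx <= 0 or hy <= 0:
        return np.zeros(n_perm)
    return np.clip(mi, 0.0, None) / math.sqrt(hx * hy)


def mi_permutation_p(
    x, y, n_perm: int = 1000, seed: int = 0, n_bins: int | None = None
) -> MIResult:
    """Permutation Fisher-Z significance of the normalized mutual information.

    Shuffles ``y`` ``n_perm`` times (seeded), Fisher-Z transforms the
    observed and permuted normalized MIs, and converts the standardized
    observed transform into a two-sided normal p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if n_bins is None:
        n_bins = default_n_bins(x.size)
    mi, nmi = mutual_information(x, y, n_bins)
    z_obs = float(np.arctanh(min(nmi, _ATANH_CLAMP)))
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return MIResult(mi, nmi, z_obs, z_obs, 0.0, 1.0, n_perm, seed, degenerate=True)
    bx = equal_frequency_bins(x, n_bins)
    by = equal_frequency_bins(y, n_bins)
    rng = np.random.default_rng(seed)
    nmi_perm = _perm_nmi(bx, by, n_bins, n_perm, rng)
    z_perm = np.arctanh(np.clip(nmi_perm, 0.0, _ATANH_CLAMP))
    z_mean = float(z_perm.mean())
    z_sd = float(z_perm.std(ddof=1))
    if z_sd == 0.0:
        p = 1.0 if z_obs <= z_mean else 1.0 / (n_perm + 1)
        return MIResult(mi, nmi, z_obs, z_mean, 0.0, p, n_perm, seed, degenerate=True)
    p = float(2.0 * sps.norm.sf(abs(z_obs - z_mean) / z_sd))
    return MIResult(mi, nmi, z_obs, z_mean, z_sd, min(p, 1.0), n_perm, seed)


# ---------------------------------------------------------------------------
# partial Spearman correlation
# ---------------------------------------------------------------------------


@dataclass
class PartialCorrelationResult:
    """Raw and partial Spearman correlation of an SE-gene pair.

    ``rho_partial`` removes the rank-scale linear effect of one or two
    conditioning TF expression vectors; ``conditioning_arity`` records how
    many.  Degenerate conditioning (a conditioner perfectly rank-correlated
    with either variable) is flagged and reported as ``rho_partial = 0``.
    """

    rho_raw: float
    p_raw: float
    rho_partial: float
    p_partial: float
    conditioning_arity: int
    degenerate: bool = False
    first_order: dict = field(default_factory=dict)


def _rho_p(rho: float, n: int, n_cond: int) -> float:
    """Two-sided t-approximation p-value for a (partial) correlation."""
    df = n - 2 - n_cond
    if df <= 0:
        return 1.0
    r = min(max(rho, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


def _partial1(rxy: float, rxz: float, ryz: float) -> float:
    denom = math.sqrt((1.0 - rxz * rxz) * (1.0 - ryz * ryz))
    return (rxy - rxz * ryz) / denom


_DEGEN_TOL = 1.0 - 1e-12


def partial_spearman(se, g, conditioners) -> PartialCorrelationResult:
    """Spearman correlation of ``se`` and ``g`` partialled on 1-2 conditioners.

    The raw Spearman rho and its asymptotic t p-value come first; the
    first-order partial correlation uses the classical recursion on the
    rank-correlation matrix, and two conditioners are handled by one more
    recursion step (joint, order-invariant).  Degrees of freedom for the
    partial p-value are reduced by the conditioning arity.
    """
    se = np.asarray(se, dtype=float)
    g = np.asarray(g, dtype=float)
    conds = [np.asarray(c, dtype=float) for c in conditioners]
    if not (1 <= len(conds) <= 2):
        raise ValueError("need 1 or 2 conditioners")
    n = se.size
    if n < 8 or g.size != n or any(c.size != n for c in conds):
        raise ValueError("vectors must share a length of at least 8")
    for c in conds:
        if np.ptp(c) == 0.0:
            raise ValueError("conditioners must be non-constant")
    ranks = np.vstack([sps.rankdata(v) for v in [se, g, *conds]])
    R = np.corrcoef(ranks)
    rho_raw = float(R[0, 1])
    p_raw = _rho_p(rho_raw, n, 0)
    k = len(conds)

    def result(rho_partial: float, degenerate: bool, first_order: dict) -> PartialCorrelationResult:
        p_partial = 1.0 if degenerate else _rho_p(rho_partial, n, k)
        return PartialCorrelationResult(
            rho_raw, p_raw, rho_partial, p_partial, k, degenerate, first_order
        )

    # first-order partials given the first conditioner (index 2)
    if abs(R[0, 2]) >= _DEGEN_TOL or abs(R[1, 2]) >= _DEGEN_TOL:
        return result(0.0, True, {})
    r01_2 = _partial1(R[0, 1], R[0, 2], R[1, 2])
    if k == 1:
        return result(float(r01_2), False, {"rho_se_g_given_c1": float(r01_2)})
    if abs(R[0, 3]) >= _DEGEN_TOL or abs(R[1, 3]) >= _DEGEN_TOL or abs(R[2, 3]) >= _DEGEN_TOL:
        return result(0.0, True, {})
    r01_3 = _partial1(R[0, 1], R[0, 3], R[1, 3])
    r03_2 = _partial1(R[0, 3], R[0, 2], R[2, 3])
    r13_2 = _partial1(R[1, 3], R[1, 2], R[2, 3])
    if abs(r03_2) >= _DEGEN_TOL or abs(r13_2) >= _DEGEN_TOL:
        return result(0.0, True, {})
    r01_23 = _partial1(r01_2, r03_2, r13_2)
    first = {"rho_se_g_given_c1": float(r01_2), "rho_se_g_given_c2": float(r01_3)}
    return result(float(r01_23), False, first)


# ---------------------------------------------------------------------------
# conditional independence test
# ---------------------------------------------------------------------------


def _cmi_from_joint(joint: np.ndarray) -> float:
    """I(X;Y|Z) in bits by direct triple sum over an (X, Y, Z) table."""
    n = joint.sum()
    p = joint / n
    pz = p.sum(axis=(0, 1))
    pxz = p.sum(axis=1)
    pyz = p.sum(axis=0)
    total = 0.0
    nx, ny, nz = p.shape
    for z in range(nz):
        if pz[z] <= 0:
            continue
        for i in range(nx):
            for j in range(ny):
                pxyz = p[i, j, z]
                if pxyz > 0:
                    total += pxyz * math.log2(pz[z] * pxyz / (pxz[i, z] * pyz[j, z]))
    return float(total)


def conditional_independence_test(
    se,
    g,
    conditioners,
    n_perm: int = 500,
    seed: int = 0,
    n_bins: int | None = None,
) -> float:
    """Permutation test of ``SE independent of G given the conditioners``.

    All vectors are equal-frequency discretized; the statistic is the
    conditional mutual information I(SE; G | TF) and the null is built by
    permuting the discretized ``g`` *within strata* of the (joint)
    discretized conditioners.  Strata smaller than two samples are dropped
    with a logged warning.  Returns ``(1 + #{CMI_perm >= CMI_obs}) /
    (n_perm + 1)``.
    """
    se = np.asarray(se, dtype=float)
    g = np.asarray(g, dtype=float)
    conds = [np.asarray(c, dtype=float) for c in conditioners]
    if not (1 <= len(conds) <= 2):
        raise ValueError("need 1 or 2 conditioners")
    n = se.size
    if n_bins is None:
        n_bins = default_n_bins(n)
    B = n_bins
    bx = equal_frequency_bins(se, B)
    by = equal_frequency_bins(g, B)
    bz = equal_frequency_bins(conds[0], B)
    if len(conds) == 2:
        bz = bz * B + equal_frequency_bins(conds[1], B)
    # relabel strata compactly and drop singletons
    uniq, bz = np.unique(bz, return_inverse=True)
    sizes = np.bincount(bz)
    keep = sizes[bz] >= 2
    if not keep.all():
        logger.warning(
            "conditional_independence_test: dropping %d samples in strata of size < 2",
            int((~keep).sum()),
        )
    bx, by, bz = bx[keep], by[keep], bz[keep]
    _, bz = np.unique(bz, return_inverse=True)
    nz = bz.max() + 1 if bz.size else 0
    if bz.size < 4 or nz == 0:
        return 1.0
    m = bx.size

    def joint(by_arr: np.ndarray) -> np.ndarray:
        codes = (bx * B + by_arr) * nz + bz
        return np.bincount(codes, minlength=B * B * nz).reshape(B, B, nz).astype(float)

    cmi_obs = _cmi_from_joint(joint(by))
    rng = np.random.default_rng(seed)
    # permutation matrix: shuffle g-bins within each stratum, all perms at once
    perms = np.tile(by, (n_perm, 1))
    for z in range(nz):
        idx = np.nonzero(bz == z)[0]
        block = rng.permuted(np.tile(by[idx], (n_perm, 1)), axis=1)
        perms[:, idx] = block
    # vectorized CMI over permutations
    codes = (bx[None, :] * B + perms) * nz + bz[None, :]
    codes = codes + np.arange(n_perm)[:, None] * (B * B * nz)
    counts = np.bincount(codes.ravel(), minlength=n_perm * B * B * nz)
    counts = counts.reshape(n_perm, B, B, nz).astype(float)
    p = counts / m
    pz = p.sum(axis=(1, 2))  # (n_perm, nz)
    pxz = p.sum(axis=2)  # (n_perm, B, nz)
    pyz = p.sum(axis=1)  # (n_perm, B, nz)
    denom = pxz[:, :, None, :] * pyz[:, None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(pz[:, None, None, :] * p / denom)
    cmi_perm = np.nansum(terms, axis=(1, 2, 3))
    n_ge = int((cmi_perm >= cmi_obs - 1e-12).sum())
    return float((1 + n_ge) / (n_perm + 1))
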
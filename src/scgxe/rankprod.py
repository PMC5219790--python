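"""Rank-product statistics for reproducible differential and heterogeneous expression.

The statistic per gene g is the product of its per-library ranks,
``RP_g = prod_l r_{g,l}``, where within each sequencing library the genes are
ranked by a summary statistic (the cross-subtype mean shift mu for "global"
differential expression, or the mean absolute deviation MAD of the per-subtype
shifts for "heterogeneous" / context-specific expression).  Under the null the
k ranks of a gene are independent and uniform on {1..n}, so a small rank
product certifies reproducibly extreme behaviour across libraries.

The null tail P(RP <= rp) is computed exactly by counting lattice points under
the hyperbola ``prod r_l <= rp`` whenever the lattice is small enough to
enumerate, and otherwise bracketed by guaranteed lower/upper envelopes derived
from the coupling ``n*U < ceil(n*U) <= n*U + 1`` (U uniform on (0,1]).  The
reported p-value is the geometric mean of the two envelopes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, getcontext
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SubtypeDelta",
    "SummaryStat",
    "RankProductResult",
    "subtype_deltas",
    "mu_mad",
    "rank_within_library",
    "rank_product",
    "rp_exact",
    "rp_pvalue_bounds",
    "rp_continuous_bounds",
    "geometric_mean_p",
    "qvalues",
    "rank_product_test",
]

# Lattices up to this many points are counted exactly inside rp_pvalue_bounds.
EXACT_LATTICE_BUDGET = 100_000_000


# ---------------------------------------------------------------------------
# null-distribution machinery
# ---------------------------------------------------------------------------

def _floor_values(m: int) -> np.ndarray:
    """Ascending array of the distinct values of m // d over d >= 1."""
    vals = []
    d = 1
    while d <= m:
        v = m // d
        vals.append(v)
        d = m // v + 1
    return np.array(vals[::-1], dtype=np.int64)


def rp_exact(rp: float, n: int, k: int, op_budget: float = 2e9) -> float:
    """Exact null probability P(RP <= rp) for k uniform ranks on {1..n}.

    Counts the k-tuples with product <= floor(rp) by dynamic programming over
    the distinct values of floor(rp / m); cost grows like k * n * sqrt(rp).

    Raises ``ValueError`` if the requested case exceeds ``op_budget``
    elementary operations or risks integer overflow.
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    m = math.floor(rp)
    if m < 1:
        return 0.0
    nk = n ** k  # exact Python int
    if m >= nk:
        return 1.0
    if k == 1:
        return min(m, n) / n
    # crude overflow guard: N_k(m) <= m * (ln n + 1)^(k-1)
    if m * (math.log(n) + 1.0) ** (k - 1) > 8e18:
        raise ValueError("exact rank-product count would overflow int64")
    values = _floor_values(m)
    ops = (k - 1) * min(n, m) * len(values)
    if ops > op_budget:
        raise ValueError(
            f"exact rank-product tail at rp={rp}, n={n}, k={k} exceeds the "
            f"compute budget ({ops:.2g} > {op_budget:.2g} operations)"
        )
    counts = np.minimum(values, n).astype(np.int64)
    rmax = min(n, m)
    for _ in range(k - 1):
        new = np.zeros(len(values), dtype=np.int64)
        for r in range(1, rmax + 1):
            w = values // r
            nz = w >= 1
            if not nz.any():
                break
            idx = np.searchsorted(values, w[nz])
            new[nz] += counts[idx]
        counts = new
    total = int(counts[-1])
    if nk < 2 ** 62:
        return total / nk
    return float(math.exp(math.log(total) - k * math.log(n)))


def _upper_envelope(log_rp: float, n: int, k: int) -> float:
    """P(prod n*U_l <= rp): closed form, a guaranteed upper bound."""
    s = k * math.log(n) - log_rp  # -ln x >= 0
    if s <= 0:
        return 1.0
    term = 1.0
    acc = 1.0
    for j in range(1, k):
        term *= s / j
        acc += term
    return min(1.0, math.exp(-s) * acc)


def _alternating_inner(s: float, k: int) -> float:
    """A(s) = sum_{i<k} (-1)^(k-1-i) s^i / i!  (from int e^w w^(k-1) dw)."""
    acc = 0.0
    term = 1.0  # s^i / i!
    sign = (-1) ** (k - 1)
    for i in range(k):
        acc += sign * term
        term *= s / (i + 1)
        sign = -sign
    return acc


def _lower_envelope_float(log_rp: float, n: int, k: int) -> tuple[float, float]:
    """P(prod (n*U_l + 1) <= rp) and the largest term magnitude met on the way."""
    logn = math.log(n)
    big_l = math.log(n + 1.0)
    x = math.exp(log_rp - k * logn)  # rp / n^k
    sign_b = (-1) ** (k - 1)
    acc = 0.0
    maxmag = 0.0
    for j in range(k + 1):
        s_j = log_rp - j * big_l
        if s_j <= 0:
            break
        comb = math.comb(k, j)
        scaled_pow = math.exp(j * big_l - k * logn)  # (n+1)^j / n^k
        term = ((-1) ** j) * comb * (x * _alternating_inner(s_j, k) - sign_b * scaled_pow)
        acc += term
        maxmag = max(maxmag, abs(term))
    return acc, maxmag


def _lower_envelope_decimal(log_rp: float, n: int, k: int) -> float:
    """High-precision evaluation of the alternating lower-envelope sum."""
    getcontext().prec = 60
    t = Decimal(log_rp)
    logn = Decimal(n).ln()
    big_l = Decimal(n + 1).ln()
    x = (t - k * logn).exp()
    sign_b = Decimal((-1) ** (k - 1))
    acc = Decimal(0)
    for j in range(k + 1):
        s_j = t - j * big_l
        if s_j <= 0:
            break
        # inner alternating sum A(s_j)
        inner = Decimal(0)
        term = Decimal(1)
        sign = Decimal((-1) ** (k - 1))
        for i in range(k):
            inner += sign * term
            term *= s_j / (i + 1)
            sign = -sign
        scaled_pow = (j * big_l - k * logn).exp()
        acc += Decimal((-1) ** j) * math.comb(k, j) * (x * inner - sign_b * scaled_pow)
    return float(acc)


def rp_continuous_bounds(rp: float, n: int, k: int) -> tuple[float, float]:
    """Guaranteed (lower, upper) envelopes on P(RP <= rp) in closed form.

    Couples the discrete rank r = ceil(n*U) with the continuous n*U so that
    ``n*U <= r <= n*U + 1`` pointwise; the product-of-uniforms tails on either
    side of the squeeze are exact integrals, hence guaranteed bounds for any
    (n, k, rp), including non-integer rp from tied average ranks.
    """
    if rp < 1:
        return 0.0, 0.0
    log_rp = math.log(rp)
    if log_rp >= k * math.log(n):
        return 1.0, 1.0
    upper = _upper_envelope(log_rp, n, k)
    lower, maxmag = _lower_envelope_float(log_rp, n, k)
    if maxmag > 0 and (lower <= 0 or maxmag / max(abs(lower), 1e-300) > 1e8):
        lower = _lower_envelope_decimal(log_rp, n, k)
    lower = min(max(lower, 0.0), upper)
    return lower, upper


def rp_pvalue_bounds(
    rp: float,
    n: int,
    k: int,
    exact_lattice_budget: int = EXACT_LATTICE_BUDGET,
) -> tuple[float, float]:
    """Bracket the exact null tail P(RP <= rp); bounds coincide when exact.

    For a single library the closed form ``floor(rp)/n`` is returned on both
    sides.  When ``n**k`` is small enough the exact lattice count is used
    (both bounds equal the exact tail); otherwise the continuous envelopes of
    :func:`rp_continuous_bounds` are returned.
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    if rp < 1 - 1e-12 or math.log(max(rp, 1.0)) > k * math.log(n) + 1e-9:
        raise ValueError(f"rank product {rp} outside [1, n^k] for n={n}, k={k}")
    if k == 1:
        p = min(math.floor(rp), n) / n
        return p, p
    if n ** k <= exact_lattice_budget:
        p = rp_exact(rp, n, k)
        return p, p
    return rp_continuous_bounds(rp, n, k)


def geometric_mean_p(p_lower: float, p_upper: float) -> float:
    """Geometric mean of the bracketing p-values, the reported significance."""
    if not (0 <= p_lower <= p_upper <= 1 + 1e-12):
        raise ValueError("require 0 <= p_lower <= p_upper <= 1")
    if p_lower == 0:
        warnings.warn("p_lower is 0; falling back to the upper bound alone")
        return min(p_upper, 1.0)
    return min(math.sqrt(p_lower * p_upper), 1.0)


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def qvalues(pvals: Sequence[float], lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values with the smoother estimate of pi0.

    pi0 is estimated from #{p > lambda} / (m (1 - lambda)) over a lambda grid
    (0.05 .. 0.95), smoothed with a cubic fit and read off at the grid top,
    clamped to (0, 1].  With fewer than 100 p-values pi0 falls back to 1
    (plain Benjamini-Hochberg) with a warning.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if m < 100:
        warnings.warn("fewer than 100 p-values; using pi0 = 1 (BH)")
        pi0 = 1.0
    else:
        pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
        coef = np.polyfit(lambdas, pi0_l, 3)
        pi0 = float(np.polyval(coef, lambdas.max()))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * ranked * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# summary statistics (mu / MAD over subtype shifts)
# ---------------------------------------------------------------------------

@dataclass
class SubtypeDelta:
    """Per (gene, library, subtype) change in mean log2(TPM+1) between contrast levels."""

    d: np.ndarray                 # genes x libraries x subtypes, NaN where masked
    genes: list
    libraries: list
    subtypes: list
    contrast: tuple               # (column, (level1, level2)); d = mean(level2) - mean(level1)
    n_cells: np.ndarray           # libraries x subtypes x 2 cell counts
    mask: np.ndarray              # libraries x subtypes; True where usable


@dataclass
class SummaryStat:
    mu: np.ndarray                # genes x libraries
    mad: np.ndarray               # genes x libraries
    n_subtypes: np.ndarray        # libraries; unmasked subtype count
    genes: list
    libraries: list


@dataclass
class RankProductResult:
    """Tables of per-direction rank-product tests and a per-gene summary."""

    table: pd.DataFrame           # rows: gene x test x direction
    summary: pd.DataFrame         # rows: gene x test; two-sided p, q, significance
    n_genes: int
    libraries: list


def subtype_deltas(
    log_expr: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, tuple] = ("genotype", ("WT", "KO")),
    subtype_col: str = "state",
    library_col: str = "chip",
    min_cells: int = 3,
) -> SubtypeDelta:
    """Per-library, per-subtype mean shifts d between the two contrast levels.

    ``log_expr`` is genes x cells (columns = cell ids matching ``meta`` index)
    on the log2(TPM+1) scale.  Entries with fewer than ``min_cells`` cells on
    either contrast level are masked (NaN).  Libraries missing a contrast
    level entirely are excluded with a warning.
    """
    col, (lv1, lv2) = contrast
    meta = meta.loc[list(log_expr.columns)]
    libraries = sorted(meta[library_col].unique().tolist())
    subtypes = sorted(meta[subtype_col].dropna().unique().tolist())
    if not subtypes:
        raise ValueError("no subtypes present in metadata")
    values = log_expr.to_numpy()
    keep_libs = []
    for lib in libraries:
        lm = meta[library_col] == lib
        if (lm & (meta[col] == lv1)).any() and (lm & (meta[col] == lv2)).any():
            keep_libs.append(lib)
        else:
            warnings.warn(f"library {lib!r} lacks contrast level {lv1!r} or {lv2!r}; excluded")
    if not keep_libs:
        raise ValueError("no library carries both contrast levels")
    G = values.shape[0]
    L, S = len(keep_libs), len(subtypes)
    d = np.full((G, L, S), np.nan)
    n_cells = np.zeros((L, S, 2), dtype=int)
    mask = np.zeros((L, S), dtype=bool)
    col_vals = meta[col].to_numpy()
    lib_vals = meta[library_col].to_numpy()
    sub_vals = meta[subtype_col].to_numpy()
    for li, lib in enumerate(keep_libs):
        for si, sub in enumerate(subtypes):
            base = (lib_vals == lib) & (sub_vals == sub)
            g1 = base & (col_vals == lv1)
            g2 = base & (col_vals == lv2)
            n1, n2 = int(g1.sum()), int(g2.sum())
            n_cells[li, si] = (n1, n2)
            if n1 >= min_cells and n2 >= min_cells:
                d[:, li, si] = values[:, g2].mean(axis=1) - values[:, g1].mean(axis=1)
                mask[li, si] = True
    return SubtypeDelta(
        d=d,
        genes=list(log_expr.index),
        libraries=keep_libs,
        subtypes=subtypes,
        contrast=contrast,
        n_cells=n_cells,
        mask=mask,
    )


def mu_mad(delta: SubtypeDelta) -> SummaryStat:
    """mu = mean of the subtype shifts; MAD = mean absolute deviation about mu.

    Both are taken over the unmasked subtypes of each (gene, library); a
    (gene, library) with no usable subtype stays NaN.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mu = np.nanmean(delta.d, axis=2)
        mad = np.nanmean(np.abs(delta.d - mu[:, :, None]), axis=2)
    n_subtypes = delta.mask.sum(axis=1)
    return SummaryStat(mu=mu, mad=mad, n_subtypes=n_subtypes,
                       genes=delta.genes, libraries=delta.libraries)


def rank_within_library(stat: np.ndarray, direction: str = "up") -> np.ndarray:
    """Ranks per library column; 1 = most extreme in ``direction``, ties averaged.

    Masked (NaN) entries receive the least-extreme rank n so that every
    library ranks the same n genes.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    stat = np.asarray(stat, dtype=float)
    G, L = stat.shape
    ranks = np.full((G, L), float(G))
    for li in range(L):
        colv = stat[:, li]
        ok = np.isfinite(colv)
        vals = colv[ok]
        if direction == "up":
            ranks[ok, li] = rankdata(-vals, method="average")
        else:
            ranks[ok, li] = rankdata(vals, method="average")
    return ranks


def rank_product(ranks: np.ndarray) -> np.ndarray:
    """RP per gene: the product of its per-library ranks."""
    ranks = np.asarray(ranks, dtype=float)
    if ranks.ndim == 1:
        ranks = ranks[:, None]
    return np.exp(np.log(ranks).sum(axis=1))


def _pvalues_for(rp: np.ndarray, n: int, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pl = np.empty(rp.size)
    pu = np.empty(rp.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, r in enumerate(rp):
            lo, hi = rp_pvalue_bounds(min(r, float(n) ** k), n, k)
            pl[i], pu[i] = lo, hi
        p = np.array([geometric_mean_p(lo, hi) for lo, hi in zip(pl, pu)])
    return pl, pu, np.maximum(p, 1e-300)


def rank_product_test(
    log_expr: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, tuple] = ("genotype", ("WT", "KO")),
    subtype_col: str = "state",
    library_col: str = "chip",
    min_cells: int = 3,
    fdr: float = 0.05,
) -> RankProductResult:
    """Full mu and MAD rank-product testing with q-values.

    Each test (mu for a global shift, MAD for subtype-specific heterogeneity)
    is run in both directions; the per-gene headline p-value is
    ``min(p_up, p_down) * 2`` capped at 1, with Storey q-values and a 5% FDR
    significance flag per test.
    """
    delta = subtype_deltas(log_expr, meta, contrast, subtype_col, library_col, min_cells)
    stats = mu_mad(delta)
    n = len(stats.genes)
    k = len(stats.libraries)
    rows = []
    summaries = []
    for test, stat in (("mu", stats.mu), ("mad", stats.mad)):
        per_dir_p = {}
        for direction in ("up", "down"):
            ranks = rank_within_library(stat, direction)
            rp = rank_product(ranks)
            pl, pu, p = _pvalues_for(rp, n, k)
            per_dir_p[direction] = p
            frame = pd.DataFrame(
                {
                    "gene_id": stats.genes,
                    "test": test,
                    "contrast": f"{delta.contrast[0]}:{delta.contrast[1][1]}-vs-{delta.contrast[1][0]}",
                    "direction": direction,
                    "rank_product": rp,
                    "p_lower": pl,
                    "p_upper": pu,
                    "p": p,
                }
            )
            for li, lib in enumerate(stats.libraries):
                frame[f"rank_{lib}"] = ranks[:, li]
            rows.append(frame)
        p2 = np.minimum(np.minimum(per_dir_p["up"], per_dir_p["down"]) * 2, 1.0)
        q = qvalues(p2)
        summaries.append(
            pd.DataFrame(
                {
                    "gene_id": stats.genes,
                    "test": test,
                    "p_two_sided": p2,
                    "neg_log10_p": -np.log10(p2),
                    "q": q,
                    "global_significant": q <= fdr,
                }
            )
        )
    return RankProductResult(
        table=pd.concat(rows, ignore_index=True),
        summary=pd.concat(summaries, ignore_index=True),
        n_genes=n,
        libraries=stats.libraries,
    )
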
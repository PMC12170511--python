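"""Two-group differential expression on log-normalized spot expression.

The test is the Mann-Whitney / Wilcoxon rank-sum with average ranks for ties
and a tie-corrected normal approximation (0.5 continuity correction), the
convention most single-cell toolkits default to.  Effect size is the Seurat
convention: log2 of de-logged group means with a pseudocount.  Multiple
testing is Benjamini-Hochberg over the genes actually tested; a gene is
tested only if its detection fraction reaches ``min_pct`` in at least one
group.  A gene is flagged significant when q < alpha, |log2FC| >= lfc_min and
the detection floor is met.

All three primitives (rank-sum p, BH step-up, KS in :mod:`hexniche.depth`)
are implemented here from their definitions; library equivalents serve as
independent oracles in the test suite only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .niche import Contrast
from .preprocess import NormalizedMatrix

__all__ = [
    "DEConfig",
    "rank_sum_test",
    "bh_adjust",
    "log2_fold_change",
    "de_analysis",
    "screen_with_hvg",
    "compare_gene_sets",
    "GeneSetComparison",
]

MIN_GROUP_SIZE = 3
# exact permutation p-value when the number of group assignments is enumerable
EXACT_MAX_ASSIGNMENTS = 20_000


@dataclass
class DEConfig:
    min_pct: float = 0.10
    lfc_min: float = 0.25
    alpha: float = 0.05
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.min_pct <= 1):
            raise ValueError("min_pct must be in [0, 1]")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------


def _rank_sum_bulk(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Mann-Whitney over rows: x (G, n1) vs y (G, n2).

    Returns (U of the first sample, two-sided p from the tie-corrected normal
    approximation with 0.5 continuity correction).  Rows that are entirely
    tied get p = 1.
    """
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    g, n1 = x.shape
    n2 = y.shape[1]
    pooled = np.concatenate([x, y], axis=1)
    n = n1 + n2
    # average ranks from one argsort: runs of equal sorted values share the
    # mean of their 1-based rank range
    order = np.argsort(pooled, axis=1, kind="stable")
    s = np.take_along_axis(pooled, order, axis=1)
    starts = np.ones((g, n), dtype=bool)
    starts[:, 1:] = s[:, 1:] != s[:, :-1]
    flat_idx = np.flatnonzero(starts.ravel())
    run_id = np.cumsum(starts.ravel()) - 1
    lengths = np.bincount(run_id)  # length of each tie run, all rows concatenated
    avg_rank = (flat_idx % n) + (lengths + 1) / 2.0
    ranks_sorted = avg_rank[run_id].reshape(g, n)
    r1 = np.where(order < n1, ranks_sorted, 0.0).sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    tie_sum = np.bincount(flat_idx // n, weights=lengths.astype(float) ** 3 - lengths,
                          minlength=g)

    return u, _p_from_u(u, n1, n2, tie_sum)


def _p_from_u(u: np.ndarray, n1: int, n2: int, tie_sum: np.ndarray) -> np.ndarray:
    """Two-sided p from the tie-corrected normal approximation of U."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
    p = np.ones(u.shape[0])
    ok = var > 0
    diff = u[ok] - mu
    z = (np.abs(diff) - 0.5).clip(min=0.0) / np.sqrt(var[ok])
    p[ok] = np.minimum(2.0 * scipy.stats.norm.sf(z), 1.0)
    return np.maximum(p, np.finfo(float).tiny)


def _rank_sum_sparse(sub1: sp.csr_matrix, sub2: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Mann-Whitney for non-negative sparse data.

    Algebraically identical to :func:`_rank_sum_bulk`: the implicit zeros of
    each row form one tie run occupying ranks 1..z, so only the stored
    nonzeros need sorting.
    """
    g, n1 = sub1.shape
    n2 = sub2.shape[1]
    n = n1 + n2
    pooled = sp.hstack([sub1.tocsr(), sub2.tocsr()]).tocsr()
    pooled.eliminate_zeros()
    vals = pooled.data
    if vals.size and vals.min() <= 0:
        raise ValueError("sparse rank-sum requires strictly positive stored values")
    nnz = np.diff(pooled.indptr)
    rows = np.repeat(np.arange(g), nnz)
    in_g1 = pooled.indices < n1
    if np.issubdtype(vals.dtype, np.integer):
        # composite integer key sorts with radix in O(M)
        vmax = int(vals.max()) + 1 if vals.size else 1
        order = np.argsort(rows * vmax + vals, kind="stable")
    else:
        vals = vals.astype(np.float64)
        order = np.lexsort((vals, rows))
    v_s, rows_s, g1_s = vals[order], rows[order], in_g1[order]
    m = vals.size
    starts = np.ones(m, dtype=bool)
    if m > 1:
        starts[1:] = (rows_s[1:] != rows_s[:-1]) | (v_s[1:] != v_s[:-1])
    run_id = np.cumsum(starts) - 1
    lengths = np.bincount(run_id) if m else np.zeros(0, dtype=int)
    start_idx = np.flatnonzero(starts)
    z = (n - nnz).astype(float)  # zeros per row, ranked 1..z with average (z+1)/2
    pos_in_row = start_idx - pooled.indptr[rows_s[start_idx]]
    avg_rank_run = z[rows_s[start_idx]] + pos_in_row + (lengths + 1) / 2.0
    rank_item = avg_rank_run[run_id] if m else np.zeros(0)
    r1_nonzero = np.bincount(rows_s[g1_s], weights=rank_item[g1_s], minlength=g)
    nnz1 = np.bincount(rows[in_g1], minlength=g)
    r1 = (n1 - nnz1) * (z + 1) / 2.0 + r1_nonzero
    u = r1 - n1 * (n1 + 1) / 2.0
    tie_sum = (
        np.bincount(rows_s[start_idx], weights=lengths.astype(float) ** 3 - lengths, minlength=g)
        + z**3
        - z
    )
    return u, _p_from_u(u, n1, n2, tie_sum)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Mann-Whitney U of *x* and a two-sided p-value.

    Both samples need at least three observations.  Average ranks for ties.
    For small samples (at most ``EXACT_MAX_ASSIGNMENTS`` group assignments)
    the p-value is the exact permutation tail, which handles arbitrary tie
    structure; larger samples use the tie-corrected normal approximation
    with 0.5 continuity correction.  p is clamped to (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < MIN_GROUP_SIZE or n2 < MIN_GROUP_SIZE:
        raise ValueError(f"each group needs >= {MIN_GROUP_SIZE} observations")
    u, p = _rank_sum_bulk(x[None, :], y[None, :])
    u0 = float(u[0])
    if math.comb(n1 + n2, n1) <= EXACT_MAX_ASSIGNMENTS:
        return u0, _exact_permutation_p(x, y, u0)
    return u0, float(p[0])


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p: share of group assignments at least as extreme in U."""
    n1, n2 = x.size, y.size
    ranks = scipy.stats.rankdata(np.concatenate([x, y]))
    idx = np.array(list(itertools.combinations(range(n1 + n2), n1)))
    u_all = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    p = float(np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - 1e-12))
    return max(p, float(np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; order-preserving.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D p-value vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------


def _group_mean_expm1(nm: NormalizedMatrix, cols: np.ndarray) -> np.ndarray:
    sub = nm.matrix[:, cols]
    sub = sub.copy()
    sub.data = np.expm1(sub.data)
    return np.asarray(sub.mean(axis=1)).ravel()


def log2_fold_change(nm: NormalizedMatrix, gene, group1, group2, pseudocount: float = 1.0) -> float:
    """log2[(mean de-logged expression in group1 + pc) / (same in group2 + pc)]."""
    if len(group1) == 0 or len(group2) == 0:
        raise ValueError("empty group")
    gi = nm.gene_index([gene])[0]
    c1 = nm.spot_index(group1)
    c2 = nm.spot_index(group2)
    row = nm.matrix[[gi], :]
    m1 = _group_mean_expm1(NormalizedMatrix([gene], nm.spots, row, nm.scale_factor), c1)[0]
    m2 = _group_mean_expm1(NormalizedMatrix([gene], nm.spots, row, nm.scale_factor), c2)[0]
    return float(np.log2((m1 + pseudocount) / (m2 + pseudocount)))


# ---------------------------------------------------------------------------
# full contrast analysis
# ---------------------------------------------------------------------------


def de_analysis(nm: NormalizedMatrix, contrast: Contrast, cfg: DEConfig | None = None,
                genes=None) -> pd.DataFrame:
    """Differential expression for one contrast.

    Returns a DataFrame indexed by gene with columns log2fc, p, q,
    pct_group1, pct_group2, tested, significant.  Genes below ``min_pct``
    detection in both groups are skipped before testing (p and q are NaN);
    BH runs over tested genes only.
    """
    cfg = cfg or DEConfig()
    if set(contrast.group1) & set(contrast.group2):
        raise ValueError("contrast groups overlap")
    if len(contrast.group1) < MIN_GROUP_SIZE or len(contrast.group2) < MIN_GROUP_SIZE:
        raise ValueError(f"each contrast group needs >= {MIN_GROUP_SIZE} spots")
    c1 = nm.spot_index(contrast.group1)
    c2 = nm.spot_index(contrast.group2)
    if genes is None:
        rows = np.arange(len(nm.genes))
        gene_names = list(nm.genes)
    else:
        rows = nm.gene_index(genes)
        gene_names = list(genes)

    sub1 = nm.matrix[rows][:, c1]
    sub2 = nm.matrix[rows][:, c2]
    pct1 = np.asarray((sub1 > 0).sum(axis=1)).ravel() / len(c1)
    pct2 = np.asarray((sub2 > 0).sum(axis=1)).ravel() / len(c2)

    e1 = sub1.copy()
    e1.data = np.expm1(e1.data)
    e2 = sub2.copy()
    e2.data = np.expm1(e2.data)
    m1 = np.asarray(e1.mean(axis=1)).ravel()
    m2 = np.asarray(e2.mean(axis=1)).ravel()
    lfc = np.log2((m1 + cfg.pseudocount) / (m2 + cfg.pseudocount))

    tested = np.maximum(pct1, pct2) >= cfg.min_pct
    p = np.full(len(rows), np.nan)
    q = np.full(len(rows), np.nan)
    if tested.any():
        # rank on the cached ordinal codes: same ranks/ties, integer-fast sort
        cm = nm.rank_codes()
        code1 = cm[rows][:, c1][tested]
        code2 = cm[rows][:, c2][tested]
        _, p_tested = _rank_sum_sparse(code1, code2)
        p[tested] = p_tested
        q[tested] = bh_adjust(p_tested)

    significant = tested & (q < cfg.alpha) & (np.abs(lfc) >= cfg.lfc_min)
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "p": p,
            "q": q,
            "pct_group1": pct1,
            "pct_group2": pct2,
            "tested": tested,
            "significant": significant,
        },
        index=pd.Index(gene_names, name="gene"),
    )


def significant_genes(table: pd.DataFrame) -> set:
    return set(table.index[table["significant"]])


def screen_with_hvg(de_genes: set, hvg, mode: str = "intersection") -> set:
    """Combine a DE gene set with the highly-variable gene list.

    ``intersection`` (default) keeps DE genes that are also highly variable;
    ``union`` keeps both sets.
    """
    hvg_set = set(hvg)
    de_genes = set(de_genes)
    if mode == "intersection":
        return de_genes & hvg_set
    if mode == "union":
        return de_genes | hvg_set
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class GeneSetComparison:
    unique_to_a: set
    shared: set
    unique_to_b: set

    @property
    def counts(self) -> dict:
        na, ns, nb = len(self.unique_to_a), len(self.shared), len(self.unique_to_b)
        total_a = na + ns
        total_b = nb + ns
        return {
            "unique_to_a": na,
            "shared": ns,
            "unique_to_b": nb,
            "n_a": total_a,
            "n_b": total_b,
            "frac_a_unique": na / total_a if total_a else 0.0,
            "frac_b_unique": nb / total_b if total_b else 0.0,
        }

    def to_dict(self) -> dict:
        return {
            "unique_to_a": sorted(self.unique_to_a),
            "shared": sorted(self.shared),
            "unique_to_b": sorted(self.unique_to_b),
            "counts": self.counts,
        }


def compare_gene_sets(set_a, set_b) -> GeneSetComparison:
    """Partition two gene sets into unique/shared/unique with counts."""
    a, b = set(set_a), set(set_b)
    return GeneSetComparison(a - b, a & b, b - a)
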
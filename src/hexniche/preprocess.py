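"""Normalization, highly-variable-gene selection, and detection rates.

Normalization is deterministic log-CP10K: each count is scaled to the spot's
library size, multiplied by ``scale_factor`` (default 1e4), and log1p
transformed with natural log.  The immune-score threshold downstream is
interpreted on this scale.

HVG selection follows the classic binned-dispersion recipe: per gene, the mean
and dispersion (variance / mean) of log-normalized expression are computed;
genes are split into 20 equal-occupancy mean bins and dispersion is z-scored
within each bin; genes are ranked by the standardized dispersion, ties broken
lexicographically by symbol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .spatial_io import CountMatrix

__all__ = ["NormalizedMatrix", "normalize", "select_hvg", "detection_rates"]

logger = logging.getLogger(__name__)

N_HVG_BINS = 20


@dataclass
class NormalizedMatrix:
    """Log-normalized expression; zero wherever the raw count is zero."""

    genes: list
    spots: list
    matrix: sp.csr_matrix  # genes x spots, float
    scale_factor: float
    _rank_codes: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def rank_codes(self) -> sp.csr_matrix:
        """Order-preserving integer recoding of the expression values.

        Same sparsity structure as ``matrix`` with data replaced by dense
        integer codes >= 1 (implicit zeros rank below every stored value).
        Rank-based statistics only need this ordinal view, which sorts much
        faster than floats; computed once and cached.
        """
        if self._rank_codes is None:
            data = self.matrix.data
            _, inv = np.unique(data, return_inverse=True)
            codes = self.matrix.copy()
            codes.data = (inv + 1).astype(np.int64)
            self._rank_codes = codes
        return self._rank_codes

    def spot_index(self, spot_ids) -> np.ndarray:
        idx = pd.Index(self.spots).get_indexer(list(spot_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(spot_ids, idx) if i < 0][:5]
            raise KeyError(f"unknown spot ids: {missing}")
        return idx

    def gene_index(self, gene_symbols) -> np.ndarray:
        idx = pd.Index(self.genes).get_indexer(list(gene_symbols))
        if (idx < 0).any():
            missing = [g for g, i in zip(gene_symbols, idx) if i < 0][:5]
            raise KeyError(f"unknown genes: {missing}")
        return idx


def normalize(m: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Log-CP10K: value = ln(1 + count * scale_factor / spot_total).

    Raises if any spot has zero total count (those spots cannot be placed on
    the common scale); the error lists the offending spot ids.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = m.spot_totals().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        ids = [m.spots[i] for i in zero[:10]]
        raise ValueError(f"{zero.size} spot(s) with zero total count, e.g. {ids}")
    x = m.matrix.tocsc().astype(float)
    # scale each column (spot) by scale_factor / total, then log1p on nonzeros
    x = x @ sp.diags(scale_factor / totals)
    x.data = np.log1p(x.data)
    x = x.tocsr()
    x.eliminate_zeros()  # explicit zeros in the input must stay implicit
    return NormalizedMatrix(list(m.genes), list(m.spots), x, float(scale_factor))


def _mean_var(matrix: sp.spmatrix) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise mean and (population) variance of a sparse matrix."""
    n = matrix.shape[1]
    mean = np.asarray(matrix.mean(axis=1)).ravel()
    sq = matrix.copy()
    sq.data = sq.data**2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = np.maximum(ex2 - mean**2, 0.0)
    return mean, var


def select_hvg(m: CountMatrix, n: int = 3000, scale_factor: float = 1e4) -> list:
    """Rank genes by binned standardized dispersion; return the top *n* symbols.

    Dispersion is variance/mean of log-normalized expression (0 for silent or
    constant genes).  If *n* exceeds the gene count, all genes are returned
    with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    nm = normalize(m, scale_factor=scale_factor)
    mean, var = _mean_var(nm.matrix)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    df = pd.DataFrame({"gene": nm.genes, "mean": mean, "disp": disp})
    # equal-occupancy mean bins: 20 once the matrix has >= 100 genes, fewer on
    # tiny matrices so every bin keeps >= 5 genes and the within-bin z-score
    # stays well conditioned
    n_bins = min(N_HVG_BINS, max(1, len(df) // 5))
    df["bin"] = pd.qcut(df["mean"].rank(method="first"), q=n_bins, labels=False)
    z = np.zeros(len(df))
    for _, idx in df.groupby("bin").groups.items():
        vals = df.loc[idx, "disp"].to_numpy()
        sd = vals.std()
        if sd > 0:
            z[df.index.get_indexer(idx)] = (vals - vals.mean()) / sd
    df["z"] = z
    df = df.sort_values(["z", "gene"], ascending=[False, True], kind="mergesort")
    if n > len(df):
        logger.warning("requested %d HVGs but matrix has only %d genes", n, len(df))
        n = len(df)
    return df["gene"].head(n).tolist()


def detection_rates(m: CountMatrix, spots=None) -> pd.DataFrame:
    """Per-gene detection over a spot subset: n_spots_detected and pct_detected.

    A gene is detected in a spot when its count is > 0.  *spots* defaults to
    all spots of the matrix; an empty subset is an error.
    """
    if spots is None:
        sub = m.matrix
        n_spots = len(m.spots)
    else:
        spots = list(spots)
        if len(spots) == 0:
            raise ValueError("empty spot subset")
        idx = pd.Index(m.spots).get_indexer(spots)
        if (idx < 0).any():
            missing = [s for s, i in zip(spots, idx) if i < 0][:5]
            raise KeyError(f"unknown spot ids: {missing}")
        sub = m.matrix[:, idx]
        n_spots = len(spots)
    det = np.asarray((sub > 0).sum(axis=1)).ravel().astype(int)
    return pd.DataFrame(
        {"n_spots_detected": det, "pct_detected": det / n_spots}, index=pd.Index(m.genes, name="gene")
    )
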
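"""Compositional analysis: centered log-ratio transform and PERMANOVA.

Cell-type composition tables live on the simplex, so Euclidean statistics are
applied after the centered log-ratio (CLR) transform: zeros are replaced by a
small epsilon, rows re-closed to 1, and each row is log-transformed and
centered by its own log-mean (equivalently, divided by its geometric mean).

PERMANOVA partitions the Gower-centered squared Euclidean distance matrix
among the terms of a crossed two-factor design (A, B, A×B, residual) with
sequential (Type I) sums of squares — the default behaviour of vegan's
``adonis2`` — and assesses each term's pseudo-F by permuting raw observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["CompositionTable", "PermanovaResult", "clr_transform", "permanova"]


@dataclass
class CompositionTable:
    """Per-observation category proportions plus categorical covariates.

    ``proportions`` rows are non-negative and sum to 1 (tolerance 1e-6);
    ``factors`` shares the row index and holds categorical covariates such as
    sequencing depth and tissue region.
    """

    proportions: pd.DataFrame
    factors: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.proportions.to_numpy(dtype=float)
        if (p < 0).any():
            raise ValueError("negative proportion in composition table")
        sums = p.sum(axis=1)
        if np.any(np.abs(sums - 1) > 1e-6):
            bad = self.proportions.index[np.abs(sums - 1) > 1e-6][:5].tolist()
            raise ValueError(f"rows not on the simplex (sum != 1): {bad}")
        if not self.factors.index.equals(self.proportions.index):
            raise ValueError("factors and proportions must share the same row index")

    @classmethod
    def from_csv(cls, path, categories: list[str] | None = None,
                 factor_cols: list[str] | None = None) -> "CompositionTable":
        df = pd.read_csv(path, index_col=0)
        if categories is None:
            numeric = df.select_dtypes(include=[np.number]).columns.tolist()
            categories = numeric
        if factor_cols is None:
            factor_cols = [c for c in df.columns if c not in categories]
        return cls(df[categories], df[factor_cols])

    def to_csv(self, path) -> None:
        pd.concat([self.proportions, self.factors], axis=1).to_csv(path)


def clr_transform(table, epsilon: float = 1e-6) -> pd.DataFrame:
    """Centered log-ratio transform of composition rows.

    Zeros are replaced by *epsilon* and the row re-closed before taking logs;
    each output row sums to zero.
    """
    if isinstance(table, CompositionTable):
        props = table.proportions
    else:
        props = pd.DataFrame(table)
    x = props.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative proportion")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    x = np.where(x == 0, epsilon, x)
    x = x / x.sum(axis=1, keepdims=True)
    logs = np.log(x)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=props.index, columns=props.columns)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # index term; columns sum_sq, df, pseudo_F, p_value
    total_ss: float
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        out = {
            term: {
                "sum_sq": float(row["sum_sq"]),
                "df": int(row["df"]),
                "pseudo_F": (None if np.isnan(row["pseudo_F"]) else float(row["pseudo_F"])),
                "p_value": (None if np.isnan(row["p_value"]) else float(row["p_value"])),
            }
            for term, row in self.table.iterrows()
        }
        out["total_ss"] = self.total_ss
        out["n_permutations"] = self.n_permutations
        out["seed"] = self.seed
        return out


def _dummies(levels: pd.Series) -> np.ndarray:
    cats = pd.Categorical(levels)
    return np.eye(len(cats.categories))[cats.codes]


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def permanova(data, factor_a, factor_b=None, n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA on Euclidean distances of *data*.

    *data* is an observations × variables real matrix (typically CLR-
    transformed compositions).  With one factor the partition is A + residual;
    with two factors it is the sequential A, B, A×B, residual decomposition on
    the Gower-centered distance matrix.  p-values are
    (1 + #{F_perm >= F_obs}) / (n_perm + 1) under permutation of the raw
    observations.
    """
    x = np.asarray(pd.DataFrame(data).to_numpy(dtype=float))
    n = x.shape[0]
    fa = pd.Series(list(factor_a)).astype(str)
    if len(fa) != n:
        raise ValueError("factor_a length mismatch")
    if fa.nunique() < 2:
        raise ValueError("factor_a needs >= 2 levels")
    fb = None
    if factor_b is not None:
        fb = pd.Series(list(factor_b)).astype(str)
        if len(fb) != n:
            raise ValueError("factor_b length mismatch")
        if fb.nunique() < 2:
            raise ValueError("factor_b needs >= 2 levels")
        cells = pd.crosstab(fa, fb)
        if (cells.to_numpy() == 0).any():
            raise ValueError("empty design cell: factors are confounded")
        if (cells.to_numpy() < 2).any():
            raise ValueError("each design cell needs >= 2 observations")

    # Gower-centered matrix from squared Euclidean distances
    d2 = squareform(pdist(x, metric="euclidean")) ** 2
    a = -0.5 * d2
    c = np.eye(n) - np.ones((n, n)) / n
    g = c @ a @ c
    total_ss = float(np.trace(g))

    ones = np.ones((n, 1))
    da = _dummies(fa)
    hats = [_hat(ones)]
    if fb is None:
        hats.append(_hat(np.hstack([ones, da])))
        terms = ["factor_a"]
        dfs = [fa.nunique() - 1]
        df_res = n - fa.nunique()
    else:
        db = _dummies(fb)
        inter = (da[:, :, None] * db[:, None, :]).reshape(n, -1)
        hats.append(_hat(np.hstack([ones, da])))
        hats.append(_hat(np.hstack([ones, da, db])))
        hats.append(_hat(np.hstack([ones, da, db, inter])))
        terms = ["factor_a", "factor_b", "interaction"]
        dfs = [
            fa.nunique() - 1,
            fb.nunique() - 1,
            (fa.nunique() - 1) * (fb.nunique() - 1),
        ]
        df_res = n - fa.nunique() * fb.nunique()
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    h_full = hats[-1]

    def _partition(gm: np.ndarray) -> tuple[np.ndarray, float]:
        fits = np.array([float(np.sum(h * gm.T)) for h in hats])  # tr(H G)
        ss_terms = np.diff(fits)
        ss_res = float(np.trace(gm)) - float(np.sum(h_full * gm.T))
        return ss_terms, ss_res

    ss_terms, ss_res = _partition(g)
    ms_res = ss_res / df_res
    f_obs = np.array([ss / df / ms_res for ss, df in zip(ss_terms, dfs)])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = _partition(gp)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_p = np.array([ss / df / (ss_res_p / df_res) for ss, df in zip(ss_p, dfs)])
        exceed += f_p >= f_obs
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    rows = [
        {"term": t, "sum_sq": float(ss), "df": int(df), "pseudo_F": float(f), "p_value": float(p)}
        for t, ss, df, f, p in zip(terms, ss_terms, dfs, f_obs, pvals)
    ]
    rows.append({"term": "residual", "sum_sq": ss_res, "df": df_res,
                 "pseudo_F": np.nan, "p_value": np.nan})
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table=table, total_ss=total_ss, n_permutations=n_perm, seed=seed)
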
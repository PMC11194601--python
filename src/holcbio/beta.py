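"""Beta diversity: presence-absence matrices, Jaccard distances, PERMANOVA.

Builds neighborhood-by-species presence matrices, computes Jaccard
dissimilarities (0 = identical assemblages, 1 = disjoint), and partitions
squared dissimilarities by sequential (Type-I) model terms — city first,
then HOLC grade — with permutation p-values, following the adonis-style
algorithm: Gower-center the squared distance matrix and take hat-matrix
traces per term. Pairwise grade comparisons run within each city with a
Benjamini-Hochberg correction across the six grade pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .ingest import GRADES


# ---------------------------------------------------------------------------
# Community and distance matrices
# ---------------------------------------------------------------------------


def build_presence_matrix(
    records: pd.DataFrame,
    neighborhoods: pd.DataFrame | None = None,
    subset: str = "all",
) -> tuple[pd.DataFrame, int]:
    """Neighborhood x species 0/1 matrix under a subset.

    Returns (matrix, n_dropped_rows); neighborhoods with no species under
    the subset are excluded.
    """
    if records.empty:
        raise ValueError("empty record set")
    if subset == "all":
        sub = records
    elif subset == "native":
        sub = records[records["native"] == "native"]
    elif subset == "nonnative":
        sub = records[records["native"] == "introduced"]
    else:
        raise ValueError(f"unknown subset {subset!r}")
    col = "species" if "species" in sub.columns else "scientific_name"
    mat = pd.crosstab(sub["neighborhood_id"], sub[col]).astype(bool).astype(np.int8)
    n_candidate = (
        len(neighborhoods) if neighborhoods is not None
        else records["neighborhood_id"].nunique()
    )
    n_dropped = n_candidate - len(mat)
    return mat, int(n_dropped)


def jaccard_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard dissimilarity d = 1 - |A∩B| / |A∪B| over species sets."""
    values = matrix.to_numpy(bool)
    if (values.sum(axis=1) == 0).any():
        raise ValueError("all-zero rows must be excluded before distances")
    d = squareform(pdist(values, metric="jaccard"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    """Sequential-SS PERMANOVA table plus permutation metadata."""

    table: pd.DataFrame  # term, df, SS, R2, F, p
    n_permutations: int
    seed: int | None
    permutation_scheme: str = "free"

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]


def _hat(X: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of X."""
    Q, R = np.linalg.qr(X)
    rank = int((np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max())).sum())
    Q = Q[:, :rank]
    return Q @ Q.T


def _dummies(factor: np.ndarray) -> np.ndarray:
    levels = pd.unique(factor)
    return (factor[:, None] == levels[None, :]).astype(float)


def _gower_center(d: np.ndarray) -> np.ndarray:
    A = -0.5 * d**2
    n = d.shape[0]
    C = np.eye(n) - np.ones((n, n)) / n
    return C @ A @ C


def permanova(
    dist: pd.DataFrame,
    factors: pd.DataFrame,
    terms: tuple[str, ...] = ("city", "holc_grade"),
    n_perm: int = 10_000,
    seed: int | None = None,
    exact: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential (Type-I) terms.

    ``dist`` is a square symmetric dissimilarity matrix; ``factors`` holds
    one column per term, aligned with the rows of ``dist``. Pseudo-F per
    term is (SS_term/df_term)/(SS_res/df_res); p-values come from free
    permutation of rows/columns of ``dist`` with the "+1 include the
    observed" convention, or from exhaustive enumeration when
    ``exact=True`` (n <= 8).
    """
    d = dist.to_numpy(float)
    n = d.shape[0]
    if d.shape[1] != n or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    for t in terms:
        if factors[t].nunique() < 2:
            raise ConfigurationError(f"term {t!r} has fewer than 2 levels")
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")

    G = _gower_center(d)
    SS_total = float(np.trace(G))

    # sequential projectors: intercept, then each term added in order
    X = np.ones((n, 1))
    H_prev = _hat(X)
    M_terms = []
    dfs = []
    rank_prev = 1
    for t in terms:
        X = np.hstack([X, _dummies(factors[t].to_numpy())])
        H = _hat(X)
        M_terms.append(H - H_prev)
        rank = int(round(np.trace(H)))
        dfs.append(rank - rank_prev)
        H_prev, rank_prev = H, rank
    M_res = np.eye(n) - H_prev
    df_res = n - rank_prev
    if df_res < 1:
        raise ConfigurationError("not enough residual degrees of freedom")

    def stats(Gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(M * Gmat)) for M in M_terms])
        ss_res = float(np.sum(M_res * Gmat))
        return ss, ss_res

    ss_obs, ss_res_obs = stats(G)
    F_obs = (ss_obs / np.array(dfs)) / (ss_res_obs / df_res)

    if exact:
        if n > 8:
            raise ConfigurationError("exhaustive enumeration limited to n <= 8")
        count_ge = np.zeros(len(terms))
        total = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            Gp = G[np.ix_(p, p)]
            ss, ss_res = stats(Gp)
            Fp = (ss / np.array(dfs)) / (ss_res / df_res)
            count_ge += Fp >= F_obs - 1e-12
            total += 1
        pvals = count_ge / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count_ge = np.zeros(len(terms))
        block = max(1, min(n_perm, 2_000_000 // (n * n)))
        done = 0
        while done < n_perm:
            b = min(block, n_perm - done)
            perms = np.argsort(rng.random((b, n)), axis=1)
            Gp = G[perms[:, :, None], perms[:, None, :]]
            ss = np.stack([np.einsum("ij,bij->b", M, Gp) for M in M_terms])
            ss_res = np.einsum("ij,bij->b", M_res, Gp)
            Fp = (ss / np.array(dfs)[:, None]) / (ss_res / df_res)[None, :]
            count_ge += (Fp >= F_obs[:, None] - 1e-12).sum(axis=1)
            done += b
        pvals = (1.0 + count_ge) / (1.0 + n_perm)
        n_used = n_perm

    rows = []
    for i, t in enumerate(terms):
        rows.append(
            {
                "term": t,
                "df": dfs[i],
                "SS": ss_obs[i],
                "R2": ss_obs[i] / SS_total,
                "F": F_obs[i],
                "p": pvals[i],
            }
        )
    rows.append(
        {"term": "Residual", "df": df_res, "SS": ss_res_obs,
         "R2": ss_res_obs / SS_total, "F": np.nan, "p": np.nan}
    )
    rows.append(
        {"term": "Total", "df": n - 1, "SS": SS_total, "R2": 1.0,
         "F": np.nan, "p": np.nan}
    )
    table = pd.DataFrame(rows)
    if not math.isclose(
        ss_obs.sum() + ss_res_obs, SS_total, rel_tol=1e-8, abs_tol=1e-10
    ):
        raise AssertionError("sum-of-squares partition failed to close")
    return PermanovaResult(
        table=table, n_permutations=n_used, seed=seed,
        permutation_scheme="exact" if exact else "free",
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pairwise_permanova(
    dist: pd.DataFrame,
    meta: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-city pairwise grade PERMANOVAs with BH correction within city.

    ``meta`` is indexed like ``dist`` (or has a ``neighborhood_id`` column)
    with ``city`` and ``holc_grade`` columns. A pair with fewer than two
    neighborhoods in either grade is reported as untestable (no p-value).
    """
    if "neighborhood_id" in meta.columns:
        meta = meta.set_index("neighborhood_id")
    meta = meta.loc[dist.index]
    rows = []
    rng = np.random.default_rng(seed)
    for city in sorted(meta["city"].unique()):
        city_rows = []
        for a, b in itertools.combinations(GRADES, 2):
            ids = meta.index[
                (meta["city"] == city) & (meta["holc_grade"].isin([a, b]))
            ]
            grades_here = meta.loc[ids, "holc_grade"]
            if (grades_here == a).sum() < 2 or (grades_here == b).sum() < 2:
                city_rows.append(
                    {"city": city, "pair": f"{a}-{b}", "F": np.nan,
                     "p": np.nan, "testable": False}
                )
                continue
            sub_d = dist.loc[ids, ids]
            sub_f = meta.loc[ids, ["holc_grade"]]
            res = permanova(
                sub_d, sub_f, terms=("holc_grade",), n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
            )
            row = res.term("holc_grade")
            city_rows.append(
                {"city": city, "pair": f"{a}-{b}", "F": row["F"],
                 "p": row["p"], "testable": True}
            )
        testable = [r for r in city_rows if r["testable"]]
        if testable:
            adj = bh_adjust([r["p"] for r in testable])
            for r, q in zip(testable, adj):
                r["p_adjusted"] = q
                r["stars"] = _stars(q)
        for r in city_rows:
            r.setdefault("p_adjusted", np.nan)
            r.setdefault("stars", "")
        rows.extend(city_rows)
    return pd.DataFrame(rows)
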
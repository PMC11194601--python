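"""Accumulated species richness (collector's curves) and grade comparisons.

A stratum's curve tracks the cumulative number of unique species as its
observations accrue: a record of an already-seen species adds to the
observation count but not to richness. Curves are compared against a
reference grade by the number of observations each stratum needs to reach
the reference's maximum observed richness (the delta statistic), and a
closed-form hypergeometric rarefaction expectation serves as the analytic
oracle for permutation-averaged curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass
class AccumulationCurve:
    """Accumulated unique-species count ``S`` at observation counts 1..n."""

    label: str
    S: np.ndarray  # S[k-1] = unique species among the first k records
    order: str  # "chronological" or "permuted(seed)"

    def __len__(self) -> int:
        return len(self.S)

    @property
    def final_richness(self) -> int:
        return int(self.S[-1]) if len(self.S) else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stratum": self.label, "k": np.arange(1, len(self.S) + 1), "S_k": self.S}
        )


def accumulate(
    records: pd.DataFrame,
    order: str = "chronological",
    seed: int | None = None,
    label: str = "",
) -> AccumulationCurve:
    """Accumulation curve for one stratum's records.

    Chronological order sorts by ``observed_on`` with ties broken by record
    id; ``order="permuted"`` shuffles uniformly with the given seed. An empty
    stratum yields an empty curve.
    """
    if records.empty:
        return AccumulationCurve(label=label, S=np.array([], dtype=int), order=order)
    col = "species" if "species" in records.columns else "scientific_name"
    if records[col].isna().any():
        raise ValueError("every record must have a species name")
    if order == "chronological":
        df = records.sort_values(
            ["observed_on", "record_id" if "record_id" in records.columns else "id"],
            kind="mergesort",
        )
        order_used = "chronological"
    elif order == "permuted":
        rng = np.random.default_rng(seed)
        df = records.iloc[rng.permutation(len(records))]
        order_used = f"permuted({seed})"
    else:
        raise ValueError(f"unknown order {order!r}")
    new = ~df[col].duplicated().to_numpy()
    return AccumulationCurve(label=label, S=np.cumsum(new), order=order_used)


def observations_to_reach(curve: AccumulationCurve, target_richness: int):
    """Smallest observation count at which the curve reaches ``target_richness``.

    Returns ``None`` ("unreached") when the stratum never accumulates that
    many species.
    """
    if target_richness < 1:
        raise ValueError("target richness must be >= 1")
    if len(curve) == 0 or curve.S[-1] < target_richness:
        return None
    return int(np.searchsorted(curve.S, target_richness, side="left")) + 1


def compare_to_reference(
    curves: dict[str, AccumulationCurve], reference: str = "A"
) -> pd.DataFrame:
    """Observations needed per stratum to reach the reference's final richness.

    Delta = obs(stratum) - obs(reference); NaN when the stratum never reaches
    the reference richness.
    """
    if reference not in curves:
        raise KeyError(f"reference stratum {reference!r} not among curves")
    s_star = curves[reference].final_richness
    ref_obs = observations_to_reach(curves[reference], s_star) if s_star else None
    rows = []
    for label in sorted(curves):
        obs = observations_to_reach(curves[label], s_star) if s_star else None
        rows.append(
            {
                "stratum": label,
                "S_star": s_star,
                "obs_to_reach": obs if obs is not None else np.nan,
                "delta": (obs - ref_obs)
                if (obs is not None and ref_obs is not None)
                else np.nan,
                "reached": obs is not None,
            }
        )
    return pd.DataFrame(rows)


def expected_rarefaction(species_counts, k: int) -> float:
    """Expected richness in a uniform subsample of ``k`` records, no replacement.

    E[S_k] = sum_s 1 - C(N - n_s, k) / C(N, k) over species with n_s records.
    """
    counts = np.asarray(
        list(species_counts.values())
        if isinstance(species_counts, dict)
        else species_counts,
        dtype=int,
    )
    if (counts < 1).any():
        raise ValueError("species counts must be positive")
    N = int(counts.sum())
    if k > N:
        raise ValueError(f"subsample size {k} exceeds total records {N}")
    if k < 0:
        raise ValueError("subsample size must be non-negative")

    def log_comb(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    keep = counts <= N - k  # species that can be entirely missed
    p_miss = np.zeros(len(counts))
    if keep.any():
        p_miss[keep] = np.exp(log_comb(N - counts[keep], k) - log_comb(N, k))
    return float(np.sum(1.0 - p_miss))


def curves_by(
    records: pd.DataFrame,
    neighborhoods: pd.DataFrame,
    by: tuple[str, ...] = ("holc_grade",),
    order: str = "chronological",
    seed: int | None = None,
) -> dict[str, AccumulationCurve]:
    """One curve per stratum, strata defined by neighborhood attributes.

    ``by`` may combine ``holc_grade``, ``city`` and the record column
    ``clade``; stratum labels join the values with "/".
    """
    meta = neighborhoods.set_index("neighborhood_id")
    df = records.copy()
    for colname in by:
        if colname == "clade":
            continue
        df[colname] = df["neighborhood_id"].map(meta[colname])
    keys = [df[c] for c in by]
    labels = keys[0].astype(str)
    for k in keys[1:]:
        labels = labels + "/" + k.astype(str)
    out = {}
    for label, grp in df.groupby(labels.to_numpy()):
        out[str(label)] = accumulate(grp, order=order, seed=seed, label=str(label))
    return out
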
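"""Cohort recurrence summaries and RPPA-style statistics.

Covers the statistics used downstream of fusion discovery: per-group
recurrence percentages over a presence/absence cohort table, an exact
two-sided Mann-Whitney-Wilcoxon test for small replicate groups,
same-direction concordance between two differential comparisons, and
hypergeometric pathway enrichment.

No multiple-testing correction is applied by default (the screen is an
uncorrected p<0.05 one); a Benjamini-Hochberg option exists and logs a
warning when left off for large panels.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EXACT_ENUMERATION_LIMIT = 12  # complete labeling enumeration up to this many observations


@dataclass
class ProteinMatrix:
    """Antibody-level protein quantification across replicated conditions.

    ``values``: antibodies x samples; ``conditions``: sample -> condition
    label; ``antibody_to_protein``: one protein may carry several
    antibodies.
    """

    values: pd.DataFrame
    conditions: pd.Series
    antibody_to_protein: Mapping[str, str]

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("protein levels must be finite")
        counts = self.conditions.value_counts()
        if (counts < 2).any():
            raise ValueError("every condition needs at least 2 replicates")

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions.get(s) == condition]


@dataclass(frozen=True)
class DifferentialResult:
    protein: str
    direction: str | None  # 'up'/'down' in the case condition; None when medians tie
    p_value: float
    significant: bool


def recurrence_summary(
    presence: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-fusion, per-group positive counts and percentages.

    ``presence`` is fusions x samples (truthy = positive); ``groups``
    maps each sample to its cohort group. Percentages are rounded to the
    nearest integer with one decimal retained in a secondary column; an
    empty group reports NA.
    """
    missing = [s for s in presence.columns if s not in groups]
    if missing:
        raise ValueError(f"samples without group assignment: {missing}")
    group_names = sorted(set(groups.values()))
    rows = []
    for fusion in presence.index:
        for group in group_names:
            samples = [s for s in presence.columns if groups[s] == group]
            total = len(samples)
            if total == 0:
                rows.append(
                    {
                        "fusion": fusion,
                        "group": group,
                        "positives": 0,
                        "total": 0,
                        "percent": pd.NA,
                        "percent_1dp": pd.NA,
                    }
                )
                continue
            positives = int(presence.loc[fusion, samples].astype(bool).sum())
            pct = 100.0 * positives / total
            rows.append(
                {
                    "fusion": fusion,
                    "group": group,
                    "positives": positives,
                    "total": total,
                    "percent": int(round(pct)),
                    "percent_1dp": round(pct, 1),
                }
            )
    return pd.DataFrame(
        rows, columns=["fusion", "group", "positives", "total", "percent", "percent_1dp"]
    )


def _u_statistic(ranks_x: np.ndarray, n_x: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2.0)


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p-value.

    For up to 12 total observations the null distribution of the U
    statistic (mid-ranks under ties) is obtained by complete enumeration
    of all C(n+m, n) group labelings; beyond that a normal approximation
    with tie correction and continuity correction is used. The two-sided
    p is 2 x min(lower tail, upper tail), capped at 1. Triplicate groups
    can never reach p < 0.1 exactly; callers screening at alpha = 0.05
    are warned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 2 or m < 2:
        raise ValueError("both groups need at least 2 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n], n)
    total = n + m
    if total <= EXACT_ENUMERATION_LIMIT:
        smallest = 2.0 / math.comb(total, n)
        if smallest > 0.05:
            warnings.warn(
                f"groups of {n} vs {m}: smallest attainable exact two-sided p is "
                f"{smallest:.3g}; a p < 0.05 screen cannot succeed",
                stacklevel=2,
            )
        us = []
        for idx in combinations(range(total), n):
            us.append(_u_statistic(ranks[list(idx)], n))
        us = np.asarray(us)
        count = len(us)
        lower = np.sum(us <= u_obs) / count
        upper = np.sum(us >= u_obs) / count
        return float(min(1.0, 2.0 * min(lower, upper)))
    # normal approximation with tie + continuity correction
    mu = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (total * (total - 1))
    sigma2 = n * m / 12.0 * ((total + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def rppa_differential(
    matrix: ProteinMatrix, case: str, control: str, alpha: float = 0.05
) -> dict[str, DifferentialResult]:
    """Antibody-level rank-sum tests collapsed to protein level.

    Each antibody is tested case-vs-control with the exact MWW test;
    antibody results collapse to their protein by minimum p-value, with
    direction taken from that antibody ('up' = higher median in the case
    condition).
    """
    case_samples = matrix.samples_of(case)
    ctrl_samples = matrix.samples_of(control)
    if not case_samples or not ctrl_samples:
        raise ValueError(f"conditions {case!r}/{control!r} not found in matrix")
    best: dict[str, tuple[float, str | None]] = {}
    for antibody in matrix.values.index:
        protein = matrix.antibody_to_protein.get(antibody, antibody)
        xs = matrix.values.loc[antibody, case_samples].to_numpy(dtype=float)
        ys = matrix.values.loc[antibody, ctrl_samples].to_numpy(dtype=float)
        p = mann_whitney_exact(xs, ys)
        med_diff = float(np.median(xs) - np.median(ys))
        direction = None if med_diff == 0 else ("up" if med_diff > 0 else "down")
        if protein not in best or p < best[protein][0]:
            best[protein] = (p, direction)
    return {
        protein: DifferentialResult(
            protein=protein, direction=direction, p_value=p, significant=p < alpha
        )
        for protein, (p, direction) in best.items()
    }


def concordant_overlap(
    diff_a: Mapping[str, DifferentialResult],
    diff_b: Mapping[str, DifferentialResult],
    alpha: float = 0.05,
) -> list[str]:
    """Proteins significant in both comparisons with the same direction.

    The concordance screen behind 'altered in the same manner in both
    patient tissue and transfected cells'. Deterministically ordered by
    protein id.
    """
    shared = set(diff_a) & set(diff_b)
    out = []
    for protein in sorted(shared):
        a, b = diff_a[protein], diff_b[protein]
        if (
            a.p_value < alpha
            and b.p_value < alpha
            and a.direction is not None
            and a.direction == b.direction
        ):
            out.append(protein)
    return out


def hypergeometric_enrichment(
    universe_size: int, pathway_size: int, selected: int, selected_in_pathway: int
) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    Probability of drawing at least ``selected_in_pathway`` pathway
    members when ``selected`` proteins are drawn from a universe of
    ``universe_size`` containing ``pathway_size`` pathway members.
    """
    n_, k_, n_sel, k_sel = universe_size, pathway_size, selected, selected_in_pathway
    if not (0 <= k_sel <= min(k_, n_sel) <= n_):
        raise ValueError(
            f"inconsistent counts N={n_}, K={k_}, n={n_sel}, k={k_sel}"
        )
    if n_sel > n_ or k_ > n_:
        raise ValueError("selection or pathway larger than the universe")
    if k_sel == 0:
        return 1.0
    return float(stats.hypergeom.sf(k_sel - 1, n_, k_, n_sel))


def enrichment_inversions(
    universe_size: int = 130,
    selected: int = 17,
    target_p: float = 0.0205,
    decimals: int = 4,
) -> pd.DataFrame:
    """Enumerate (pathway_size, hits) pairs whose upper-tail p rounds to a target.

    A documented exploration utility: when a printed enrichment p-value
    arrives without its underlying pathway counts, this enumerates every
    (K, k) consistent with it at the given rounding.
    """
    rows = []
    for k_path in range(1, universe_size + 1):
        for hits in range(1, min(k_path, selected) + 1):
            p = hypergeometric_enrichment(universe_size, k_path, selected, hits)
            if round(p, decimals) == round(target_p, decimals):
                rows.append({"pathway_size": k_path, "hits": hits, "p_value": p})
    return pd.DataFrame(rows, columns=["pathway_size", "hits", "p_value"])


def benjamini_hochberg(p_values: Mapping[str, float]) -> dict[str, float]:
    """Optional BH-adjusted q-values (off by default in the screens above)."""
    items = sorted(p_values.items(), key=lambda kv: kv[1])
    m = len(items)
    out: dict[str, float] = {}
    prev = 1.0
    for rank, (key, p) in reversed(list(enumerate(items, start=1))):
        q = min(prev, p * m / rank)
        out[key] = q
        prev = q
    return out
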
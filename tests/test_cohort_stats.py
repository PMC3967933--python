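"""Recurrence arithmetic, exact rank-sum and hypergeometric tests, concordance."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fusioncall.cohort_stats import (
    DifferentialResult,
    benjamini_hochberg,
    concordant_overlap,
    enrichment_inversions,
    hypergeometric_enrichment,
    mann_whitney_exact,
    recurrence_summary,
    rppa_differential,
)
from fusioncall.synthetic_data import make_protein_matrix


def _presence(n_pos, n_total, group="cancer"):
    samples = [f"s{i}" for i in range(n_total)]
    presence = pd.DataFrame(
        [[1] * n_pos + [0] * (n_total - n_pos)], index=["fus"], columns=samples
    )
    return presence, {s: group for s in samples}


class TestRecurrence:
    @pytest.mark.parametrize(
        "pos,total,expected", [(12, 60, 20), (5, 28, 18), (2, 28, 7), (0, 10, 0)]
    )
    def test_percentages(self, pos, total, expected):
        presence, groups = _presence(pos, total)
        out = recurrence_summary(presence, groups)
        assert out.loc[0, "percent"] == expected
        assert out.loc[0, "positives"] == pos and out.loc[0, "total"] == total

    def test_one_decimal_column(self):
        presence, groups = _presence(5, 28)
        out = recurrence_summary(presence, groups)
        assert out.loc[0, "percent_1dp"] == pytest.approx(17.9)

    def test_positive_and_negative_fractions_sum_to_one(self):
        presence, groups = _presence(7, 30)
        out = recurrence_summary(presence, groups)
        frac_pos = out.loc[0, "positives"] / out.loc[0, "total"]
        assert frac_pos + (1 - frac_pos) == pytest.approx(1.0)

    def test_unassigned_sample_errors(self):
        presence, groups = _presence(1, 4)
        del groups["s0"]
        with pytest.raises(ValueError, match="without group"):
            recurrence_summary(presence, groups)

    def test_multiple_groups(self):
        samples = [f"c{i}" for i in range(28)] + [f"o{i}" for i in range(10)]
        presence = pd.DataFrame(
            [[1] * 5 + [0] * 23 + [0] * 10], index=["fus"], columns=samples
        )
        groups = {s: ("cancer" if s.startswith("c") else "normal_ovary") for s in samples}
        out = recurrence_summary(presence, groups).set_index("group")
        assert out.loc["cancer", "percent"] == 18
        assert out.loc["normal_ovary", "percent"] == 0


def _oracle_mww(x, y):
    """Independent enumeration oracle using the pair-count U definition."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = 0.0
        for a in xs:
            for b in ys:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    obs = u_of(tuple(range(n)))
    us = [u_of(idx) for idx in itertools.combinations(range(len(pooled)), n)]
    lower = sum(1 for u in us if u <= obs) / len(us)
    upper = sum(1 for u in us if u >= obs) / len(us)
    return min(1.0, 2.0 * min(lower, upper))


class TestMannWhitney:
    def test_fully_separated_triplets(self):
        # 2 of the C(6,3)=20 labelings are as extreme: p = 0.1
        assert mann_whitney_exact([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_give_one(self):
        assert mann_whitney_exact([1, 2, 2, 3], [1, 2, 2, 3]) == pytest.approx(1.0)

    def test_constant_data_gives_one(self):
        assert mann_whitney_exact([5, 5, 5], [5, 5, 5]) == 1.0

    def test_symmetric_in_groups(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=4), rng.normal(size=5)
        assert mann_whitney_exact(x, y) == pytest.approx(mann_whitney_exact(y, x))

    def test_triplicates_warn_that_alpha_is_unreachable(self):
        with pytest.warns(UserWarning, match="smallest attainable"):
            mann_whitney_exact([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])

    @pytest.mark.parametrize("sizes", [(3, 3), (4, 4), (3, 5)])
    def test_matches_enumeration_oracle_with_ties(self, sizes):
        rng = np.random.default_rng(1)
        n, m = sizes
        for _ in range(40):
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, m).astype(float)
            if np.all(np.concatenate([x, y]) == x[0]):
                continue
            assert mann_whitney_exact(x, y) == pytest.approx(_oracle_mww(x, y))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            x = rng.normal(size=5)
            y = rng.normal(size=4)
            expected = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert mann_whitney_exact(x, y) == pytest.approx(expected)

    def test_large_sample_branch_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=9)
        y = rng.normal(size=8)
        expected = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        assert mann_whitney_exact(x, y) == pytest.approx(expected, rel=1e-9)

    def test_too_small_groups_error(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([1.0], [2.0, 3.0])


def _oracle_hypergeom(N, K, n, k):
    """Draw-enumeration oracle: fraction of n-subsets with >= k pathway hits."""
    pathway = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(pathway & set(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_worked_example(self):
        # 66 of the C(10,5)=252 draws contain >= 3 of the 4 pathway members
        assert hypergeometric_enrichment(10, 4, 5, 3) == pytest.approx(66 / 252)

    def test_k_zero_gives_one(self):
        assert hypergeometric_enrichment(130, 20, 17, 0) == 1.0

    def test_matches_draw_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            N = int(rng.integers(5, 21))
            n = int(rng.integers(2, min(8, N) + 1))
            K = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeometric_enrichment(N, K, n, k) == pytest.approx(
                _oracle_hypergeom(N, K, n, k)
            )

    def test_monotone_nonincreasing_in_k(self):
        ps = [hypergeometric_enrichment(130, 25, 17, k) for k in range(0, 10)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(10, 4, 5, 6)

    def test_inversion_utility_recovers_known_counts(self):
        p = hypergeometric_enrichment(130, 25, 17, 8)
        df = enrichment_inversions(130, 17, target_p=p, decimals=6)
        assert ((df.pathway_size == 25) & (df.hits == 8)).any()


def _diff(protein, direction, p):
    return DifferentialResult(protein, direction, p, p < 0.05)


class TestConcordance:
    def test_same_direction_significant_included(self):
        a = {"P1": _diff("P1", "up", 0.01)}
        b = {"P1": _diff("P1", "up", 0.03)}
        assert concordant_overlap(a, b) == ["P1"]

    def test_opposite_direction_excluded(self):
        a = {"P1": _diff("P1", "up", 0.01)}
        b = {"P1": _diff("P1", "down", 0.03)}
        assert concordant_overlap(a, b) == []

    def test_nonsignificant_excluded(self):
        a = {"P1": _diff("P1", "up", 0.2)}
        b = {"P1": _diff("P1", "up", 0.01)}
        assert concordant_overlap(a, b) == []

    def test_self_overlap_equals_significant_set(self):
        d = {
            "P1": _diff("P1", "up", 0.01),
            "P2": _diff("P2", "down", 0.2),
            "P3": _diff("P3", "down", 0.04),
        }
        assert concordant_overlap(d, d) == ["P1", "P3"]

    def test_planted_concordant_proteins_recovered(self):
        a, b, planted = make_protein_matrix(seed=0)
        da = rppa_differential(a, "S5", "S19")
        db = rppa_differential(b, "shortWDFY2", "wtWDFY2")
        assert concordant_overlap(da, db) == planted


def test_antibody_collapse_uses_minimum_p():
    values = pd.DataFrame(
        {
            "c1": [10.0, 10.0],
            "c2": [11.0, 10.1],
            "c3": [12.0, 9.9],
            "c4": [13.0, 10.2],
            "k1": [1.0, 1.0],
            "k2": [2.0, 1.1],
            "k3": [3.0, 0.9],
            "k4": [4.0, 1.2],
        },
        index=["ab1", "ab2"],
    )
    conditions = pd.Series(
        ["case"] * 4 + ["ctrl"] * 4, index=values.columns
    )
    from fusioncall.cohort_stats import ProteinMatrix

    matrix = ProteinMatrix(values, conditions, {"ab1": "P1", "ab2": "P1"})
    res = rppa_differential(matrix, "case", "ctrl")
    assert set(res) == {"P1"}
    # ab1 fully separates (p = 2/70); ab2 does not
    assert res["P1"].p_value == pytest.approx(2 / 70)
    assert res["P1"].direction == "up"


def test_benjamini_hochberg_monotone():
    ps = {"a": 0.001, "b": 0.01, "c": 0.04, "d": 0.8}
    qs = benjamini_hochberg(ps)
    ordered = [qs[k] for k in sorted(ps, key=ps.get)]
    assert ordered == sorted(ordered)
    assert qs["a"] == pytest.approx(0.004)
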
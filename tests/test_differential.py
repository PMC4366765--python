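"""Fold change, ANOVA/post hocs against independent oracles, cascade rules."""

import math

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy import stats

from spectracount.differential import (
    FilterCriteria,
    anova_oneway,
    apply_filter_cascade,
    dunnett_t3_pairwise_p,
    fold_change,
    lsd_pairwise_p,
    results_to_frame,
    variance_homogeneity,
)
from spectracount.fixtures import fixture_count_matrix
from spectracount.quantification import build_count_matrix

# nine per-animal counts of the two proteins listed in both reference
# tables: (sham, uuo1w, uuo3w) triples
PYGM_GROUPS = [(1, 0, 0), (12, 12, 8), (10, 14, 14)]
S10A9_GROUPS = [(0, 2, 0), (7, 6, 12), (10, 12, 11)]

triples = st.tuples(*[st.integers(0, 60)] * 3)


def oracle_anova_lsd(groups, pair):
    """Brute-force sums-of-squares oracle for F and the LSD pairwise p."""
    flat = [x for g in groups for x in g]
    grand = sum(flat) / len(flat)
    means = [sum(g) / len(g) for g in groups]
    ssb = sum(len(g) * (m - grand) ** 2 for g, m in zip(groups, means))
    ssw = sum((x - m) ** 2 for g, m in zip(groups, means) for x in g)
    dfb, dfw = len(groups) - 1, len(flat) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    i, j = pair
    mse = ssw / dfw
    t = abs(means[i] - means[j]) / math.sqrt(mse * (1 / len(groups[i]) + 1 / len(groups[j])))
    return f, 2 * stats.t.sf(t, dfw)


@pytest.mark.parametrize(
    "sham,uuo,expected",
    [
        ((15, 13, 7), (41, 25, 37), 2.94),
        ((8, 39, 10), (106, 51, 127), 4.98),
        ((1, 0, 0), (12, 12, 8), 32.00),
        ((0, 0, 1), (14, 10, 5), 29.00),
        ((4, 3, 3), (6, 14, 9), 2.90),
        ((2, 11, 10), (47, 47, 43), 5.96),
        ((18, 40, 37), (67, 68, 70), 2.16),
        ((5, 5, 5), (5, 5, 5), 1.00),
    ],
)
def test_fold_change_of_group_means(sham, uuo, expected):
    assert round(fold_change(sham, uuo), 2) == pytest.approx(expected)


def test_fold_change_edge_cases():
    assert fold_change((0, 0, 0), (1, 2, 3)) == math.inf
    with pytest.raises(ValueError, match="undefined"):
        fold_change((0, 0, 0), (0, 0, 0))


@pytest.mark.parametrize(
    "groups,f_expected,digits",
    [(PYGM_GROUPS, 35.848, 3), (S10A9_GROUPS, 20.447, 3)],
)
def test_anova_reproduces_reference_f(groups, f_expected, digits):
    f, _ = anova_oneway(groups)
    assert round(f, digits) == pytest.approx(f_expected)


def test_anova_degenerate_inputs():
    assert anova_oneway([(1, 2, 3)] * 3) == (0.0, 1.0)
    f, p = anova_oneway([(2, 2, 2), (5, 5, 5)])
    assert math.isinf(f) and p == 0.0
    with pytest.raises(ValueError):
        anova_oneway([(1, 2, 3)])


@given(groups=st.tuples(triples, triples, triples))
def test_anova_and_lsd_match_brute_force_oracle(groups):
    flat = [x for g in groups for x in g]
    assume(any(x != sum(g) / 3 for g in groups for x in g))  # SSW > 0
    f, p = anova_oneway(groups)
    f_oracle, lsd_oracle = oracle_anova_lsd(groups, (1, 0))
    assert f == pytest.approx(f_oracle, abs=1e-9)
    assert lsd_pairwise_p(groups, (1, 0)) == pytest.approx(lsd_oracle, abs=1e-9)
    # independent library route for F
    f_scipy, p_scipy = stats.f_oneway(*map(np.asarray, groups))
    assert f == pytest.approx(float(f_scipy), abs=1e-8)
    assert p == pytest.approx(float(p_scipy), abs=1e-8)


@given(a=triples, b=triples)
def test_two_group_f_is_squared_pooled_t(a, b):
    assume(len(set(a)) > 1 or len(set(b)) > 1)
    f, _ = anova_oneway([a, b])
    t, _ = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    assert f == pytest.approx(float(t) ** 2, abs=1e-8)


@pytest.mark.parametrize(
    "groups,pair,expected",
    [
        (PYGM_GROUPS, (1, 0), 0.001),  # UUO 1-week vs sham
        (S10A9_GROUPS, (1, 0), 0.004),
    ],
)
def test_lsd_reproduces_reference_p(groups, pair, expected):
    assert round(lsd_pairwise_p(groups, pair), 3) == pytest.approx(expected)


def test_lsd_degenerate_inputs():
    assert lsd_pairwise_p([(1, 1, 1), (1, 1, 1)], (0, 1)) == 1.0
    assert lsd_pairwise_p([(1, 1, 1), (2, 2, 2)], (0, 1)) == 0.0


def test_dunnett_t3_degenerate_and_extreme():
    assert dunnett_t3_pairwise_p([(3, 3, 3), (3, 3, 3)], (0, 1)) == 1.0
    assert dunnett_t3_pairwise_p([(0, 0, 0), (100, 101, 99)], (0, 1)) < 0.001


@given(groups=st.tuples(triples, triples, triples))
def test_dunnett_t3_never_below_welch_p(groups):
    a, b = np.asarray(groups[0], float), np.asarray(groups[1], float)
    assume(a.var() > 0 or b.var() > 0)
    p_adj = dunnett_t3_pairwise_p(groups, (0, 1))
    _, p_welch = stats.ttest_ind(a, b, equal_var=False)
    assert p_adj >= float(p_welch) - 1e-12


def test_levene_behaviour():
    # equal spread, shifted means: absolute deviations identical -> p = 1
    stat, p = variance_homogeneity([(1, 2, 3), (11, 12, 13), (21, 22, 23)])
    assert p > 0.05
    # one group with a vastly larger, asymmetric spread
    _, p_het = variance_homogeneity([(1, 2, 3), (0, 0, 300), (1, 2, 3)])
    assert p_het < 0.05
    assert variance_homogeneity([(5, 5, 5)] * 3) == (0.0, 1.0)


def _matrix(rows, comparison="uuo1w"):
    """rows: accession -> (sham triple, uuo triple)."""
    animals = [f"sham_{i}" for i in (1, 2, 3)] + [f"{comparison}_{i}" for i in (1, 2, 3)]
    per_animal = {
        a: {
            acc: float((sham + uuo)[k])
            for acc, (sham, uuo) in rows.items()
        }
        for k, a in enumerate(animals)
    }
    design = {a: a.rsplit("_", 1)[0] for a in animals}
    return build_count_matrix(per_animal, design)


def test_cascade_retains_all_reference_1week_rows():
    matrix = fixture_count_matrix("T2")
    results = apply_filter_cascade(matrix, None, comparison="uuo1w")
    assert all(r.criterion_flags[1] and r.criterion_flags[2] for r in results)
    assert sum(r.significant for r in results) == 7


@pytest.mark.parametrize(
    "sham,uuo,failing",
    [
        ((1, 1, 1), (5, 5, 4), "min_uuo_count"),  # one animal under the floor
        ((10, 10, 10), (40, 40, 1), "consistent_trend_fold"),  # trend broken
    ],
)
def test_cascade_rejection_reasons(sham, uuo, failing):
    matrix = _matrix({"P1": (sham, uuo)})
    frame = results_to_frame(apply_filter_cascade(matrix, None))
    assert not frame.loc[0, failing]
    assert not frame.loc[0, "significant"]


def test_cascade_criterion1_uses_unique_peptides():
    matrix = _matrix({"P1": ((1, 1, 1), (9, 9, 9))})
    with_info = apply_filter_cascade(matrix, {"P1": 1})
    assert not with_info[0].criterion_flags[0] and not with_info[0].significant
    assumed = apply_filter_cascade(matrix, None)
    assert assumed[0].criterion_flags[0]


def test_cascade_not_quantifiable_excluded():
    matrix = _matrix({"P0": ((0, 0, 0), (0, 0, 0)), "P1": ((1, 1, 1), (9, 9, 9))})
    results = apply_filter_cascade(matrix, None)
    r0 = next(r for r in results if r.accession == "P0")
    assert not r0.quantifiable and not r0.significant and math.isnan(r0.fold_change)


def test_cascade_missing_group_errors():
    matrix = _matrix({"P1": ((1, 1, 1), (9, 9, 9))})
    with pytest.raises(ValueError, match="uuo3w"):
        apply_filter_cascade(matrix, None, comparison="uuo3w")


@given(
    rows=st.dictionaries(
        st.sampled_from([f"P{i}" for i in range(8)]),
        st.tuples(triples, triples),
        min_size=1,
        max_size=8,
    ),
    fold_lo=st.floats(1.5, 4),
    fold_hi=st.floats(4, 12),
    count_lo=st.floats(0, 5),
    count_hi=st.floats(5, 20),
)
def test_cascade_monotone_in_thresholds(rows, fold_lo, fold_hi, count_lo, count_hi):
    """Raising fold_threshold or min_uuo_count never adds survivors."""
    matrix = _matrix(rows)

    def survivors(fold_threshold, min_uuo_count):
        crit = FilterCriteria(
            fold_threshold=fold_threshold, min_uuo_count=min_uuo_count, posthoc="lsd"
        )
        return {
            r.accession
            for r in apply_filter_cascade(matrix, None, crit)
            if r.significant
        }

    assert survivors(fold_hi, count_lo) <= survivors(fold_lo, count_lo)
    assert survivors(fold_lo, count_hi) <= survivors(fold_lo, count_lo)


@given(rows=st.dictionaries(st.sampled_from(["A", "B"]), st.tuples(triples, triples), min_size=1), scale=st.sampled_from([2.0, 0.5, 10.0]))
def test_fold_and_f_scale_invariant(rows, scale):
    m1 = _matrix(rows)
    scaled = {
        acc: (tuple(scale * c for c in sham), tuple(scale * c for c in uuo))
        for acc, (sham, uuo) in rows.items()
    }
    m2 = _matrix(scaled)
    r1 = apply_filter_cascade(m1, None, FilterCriteria(posthoc="lsd"))
    r2 = apply_filter_cascade(m2, None, FilterCriteria(posthoc="lsd"))
    for a, b in zip(r1, r2):
        if a.quantifiable:
            assert a.fold_change == pytest.approx(b.fold_change, rel=1e-9)
        if math.isfinite(a.f_statistic):
            assert a.f_statistic == pytest.approx(b.f_statistic, rel=1e-9)


def test_report_frame_mirrors_table_precision():
    matrix = fixture_count_matrix("T2")
    frame = results_to_frame(
        apply_filter_cascade(matrix, None, comparison="uuo1w"), rounded=True
    )
    row = frame.set_index("accession").loc["AMPN_RAT"]
    assert row["fold_change"] == 2.94
    assert set(frame["comparison"]) == {"uuo1w"}
    assert frame["bh_q"].between(0, 1).all()
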
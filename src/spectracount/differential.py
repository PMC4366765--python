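"""Group statistics and the three-criterion differential filter cascade.

The comparison is always an obstructed group (UUO 1-week or 3-week,
three animals each) against the sham-operation group (three animals).
For every protein:

* **fold change** -- ratio of group-mean abundances, ``mean(UUO) /
  mean(sham)``; ``+inf`` when the sham mean is 0 and the UUO mean is
  positive; a protein with both means 0 is not quantifiable.
* **one-way ANOVA** -- classical fixed-effects F over all groups in
  the matrix (three groups, df = (2, 6), when all three are present).
* **post hoc p** -- Fisher's least significant difference (LSD) by
  default: an unadjusted pairwise t using the pooled within-group mean
  square of *all* groups; Dunnett's T3 (Welch t with a conservative
  studentized-maximum-modulus bound) when group variances are
  heterogeneous; the choice can be forced or left to a Levene pre-test.

The differential filter cascade retains a protein when

1. it has at least two unique peptides;
2. all three UUO animals lie above the sham group mean (consistent
   upward trend) and at least one per-animal fold, UUO animal count
   over sham group mean, exceeds the fold threshold;
3. every UUO animal count is at least ``min_uuo_count`` (default 5).

A retained protein is called *significant* when additionally the group
fold change exceeds the fold threshold and the post hoc p is below
alpha. No multiple-testing correction across proteins is applied to
the decision; a Benjamini-Hochberg q-value column is emitted in
reports as supplementary information only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantification import CountMatrix

__all__ = [
    "FilterCriteria",
    "DifferentialResult",
    "fold_change",
    "anova_oneway",
    "lsd_pairwise_p",
    "dunnett_t3_pairwise_p",
    "variance_homogeneity",
    "apply_filter_cascade",
    "results_to_frame",
]


@dataclass(frozen=True)
class FilterCriteria:
    """Parameters of the three-criterion differential filter cascade.

    ``min_uuo_count`` is compared as >= (the published survivor sets
    contain per-animal counts of exactly 5, so the threshold is
    inclusive). ``posthoc`` is one of ``"lsd"`` (default -- the test the
    reference tables' printed p-values agree with), ``"t3"``, or
    ``"auto"`` (LSD unless a Levene pre-test rejects variance
    homogeneity at ``levene_alpha``; note that with three animals per
    group the Levene pre-test tends to fire precisely on strong true
    effects, whose variance scales with the mean, and Dunnett's T3 has
    very little power at these sample sizes).
    """

    min_unique_peptides: int = 2
    fold_threshold: float = 2.0
    min_uuo_count: float = 5.0
    require_consistent_trend: bool = True
    alpha: float = 0.05
    posthoc: str = "lsd"
    levene_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1.0:
            raise ValueError(f"fold_threshold must be > 1, got {self.fold_threshold}")
        if self.min_uuo_count < 0:
            raise ValueError(f"min_uuo_count must be >= 0, got {self.min_uuo_count}")
        if self.min_unique_peptides < 1:
            raise ValueError(
                f"min_unique_peptides must be >= 1, got {self.min_unique_peptides}"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.posthoc not in ("lsd", "t3", "auto"):
            raise ValueError(f"posthoc must be lsd|t3|auto, got {self.posthoc!r}")


@dataclass(frozen=True)
class DifferentialResult:
    """Per-protein outcome of the cascade for one UUO-vs-sham comparison."""

    accession: str
    comparison: str
    sham_counts: tuple[float, ...]
    uuo_counts: tuple[float, ...]
    sham_mean: float
    uuo_mean: float
    fold_change: float  # +inf when sham_mean == 0; nan when not quantifiable
    f_statistic: float
    anova_p: float
    posthoc_p: float
    posthoc_method: str
    criterion_flags: tuple[bool, bool, bool]
    quantifiable: bool
    significant: bool


def fold_change(
    sham_counts: Sequence[float], uuo_counts: Sequence[float]
) -> float:
    """Ratio of arithmetic group means, UUO over sham.

    Returns ``+inf`` when the sham mean is 0 and the UUO mean positive;
    raises ``ValueError`` when both means are 0 (not quantifiable).
    """
    sham_mean = float(np.mean(sham_counts))
    uuo_mean = float(np.mean(uuo_counts))
    if sham_mean < 0 or uuo_mean < 0:
        raise ValueError("spectral counts must be non-negative")
    if sham_mean == 0.0:
        if uuo_mean == 0.0:
            raise ValueError("both group means are zero: fold change undefined")
        return math.inf
    return uuo_mean / sham_mean


def _group_sums_of_squares(groups: Sequence[Sequence[float]]):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    grand = np.mean(np.concatenate(arrays))
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = sum(a.size for a in arrays) - len(arrays)
    return ss_between, ss_within, df_between, df_within


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA: returns (F, p).

    Degenerate inputs: all values identical gives (0, 1); zero
    within-group variance with distinct group means gives (inf, 0).
    """
    ssb, ssw, dfb, dfw = _group_sums_of_squares(groups)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = (ssb / dfb) / (ssw / dfw)
    return f, float(stats.f.sf(f, dfb, dfw))


def lsd_pairwise_p(
    groups: Sequence[Sequence[float]], pair: tuple[int, int]
) -> float:
    """Fisher's LSD two-sided p for one pair of groups.

    t = |mean_i - mean_j| / sqrt(MSE * (1/n_i + 1/n_j)) with the mean
    square error and its df pooled over *all* groups. MSE = 0 gives
    p = 1 for equal means and p = 0 otherwise.
    """
    i, j = pair
    _, ssw, _, dfw = _group_sums_of_squares(groups)
    a = np.asarray(groups[i], dtype=float)
    b = np.asarray(groups[j], dtype=float)
    diff = abs(a.mean() - b.mean())
    if ssw == 0.0:
        return 1.0 if diff == 0.0 else 0.0
    mse = ssw / dfw
    t = diff / math.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
    return float(2.0 * stats.t.sf(t, dfw))


def dunnett_t3_pairwise_p(
    groups: Sequence[Sequence[float]],
    pair: tuple[int, int],
    n_comparisons: int | None = None,
) -> float:
    """Dunnett's T3 two-sided p for one pair of groups.

    A Welch t with Welch-Satterthwaite df, adjusted for the family of
    pairwise comparisons with the conservative Sidak-style bound
    ``1 - (1 - p)^m`` in place of the exact studentized-maximum-modulus
    distribution (the bound never understates the adjusted p).
    """
    i, j = pair
    k = len(groups)
    if n_comparisons is None:
        n_comparisons = k * (k - 1) // 2
    a = np.asarray(groups[i], dtype=float)
    b = np.asarray(groups[j], dtype=float)
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    diff = abs(a.mean() - b.mean())
    if va + vb == 0.0:
        return 1.0 if diff == 0.0 else 0.0
    t = diff / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (
        (va**2 / (a.size - 1) if a.size > 1 else 0.0)
        + (vb**2 / (b.size - 1) if b.size > 1 else 0.0)
    )
    p_welch = float(2.0 * stats.t.sf(t, df))
    return float(1.0 - (1.0 - p_welch) ** n_comparisons)


def variance_homogeneity(
    groups: Sequence[Sequence[float]],
) -> tuple[float, float]:
    """Levene test on absolute deviations from group means.

    Returns (statistic, p). Degenerate input in which every absolute
    deviation is identical (e.g. all-equal groups) gives (0, 1).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    devs = [np.abs(a - a.mean()) for a in arrays]
    flat = np.concatenate(devs)
    if np.allclose(flat, flat[0]):
        return 0.0, 1.0
    stat, p = stats.levene(*arrays, center="mean")
    if math.isnan(p):
        return 0.0, 1.0
    return float(stat), float(p)


def _choose_posthoc(
    groups: Sequence[Sequence[float]], criteria: FilterCriteria
) -> str:
    if criteria.posthoc in ("lsd", "t3"):
        return criteria.posthoc
    _, levene_p = variance_homogeneity(groups)
    return "t3" if levene_p < criteria.levene_alpha else "lsd"


def apply_filter_cascade(
    matrix: CountMatrix,
    unique_peptides: Mapping[str, int] | None = None,
    criteria: FilterCriteria | None = None,
    comparison: str = "uuo1w",
    control: str = "sham",
) -> list[DifferentialResult]:
    """Run the three-criterion cascade for one UUO-vs-sham comparison.

    ``unique_peptides`` maps accession -> unique peptide count for
    criterion 1; when ``None`` (e.g. for published tables that list
    only accepted proteins) criterion 1 is taken as satisfied. The
    ANOVA and the pooled LSD variance use *all* groups present in the
    matrix; the post hoc p is for the (comparison, control) pair.
    Proteins with all-zero counts in both groups are flagged not
    quantifiable and never significant. Results are sorted by
    accession.
    """
    if criteria is None:
        criteria = FilterCriteria()
    all_groups = matrix.group_names
    for g in (control, comparison):
        if g not in all_groups:
            raise ValueError(f"group {g!r} absent from matrix (has {all_groups})")

    control_animals = matrix.animals_in_group(control)
    uuo_animals = matrix.animals_in_group(comparison)
    group_animals = [matrix.animals_in_group(g) for g in all_groups]
    pair = (all_groups.index(comparison), all_groups.index(control))

    results: list[DifferentialResult] = []
    for acc in matrix.values.index:
        row = matrix.values.loc[acc]
        sham = tuple(float(row[a]) for a in control_animals)
        uuo = tuple(float(row[a]) for a in uuo_animals)
        sham_mean = float(np.mean(sham))
        uuo_mean = float(np.mean(uuo))

        quantifiable = not (sham_mean == 0.0 and uuo_mean == 0.0)
        fold = fold_change(sham, uuo) if quantifiable else math.nan

        groups = [[float(row[a]) for a in animals] for animals in group_animals]
        f_stat, anova_p = anova_oneway(groups)
        method = _choose_posthoc(groups, criteria)
        if method == "lsd":
            posthoc_p = lsd_pairwise_p(groups, pair)
        else:
            posthoc_p = dunnett_t3_pairwise_p(groups, pair)

        c1 = (
            True
            if unique_peptides is None
            else unique_peptides.get(acc, 0) >= criteria.min_unique_peptides
        )
        if sham_mean == 0.0:
            per_animal_folds = [math.inf if u > 0 else 0.0 for u in uuo]
        else:
            per_animal_folds = [u / sham_mean for u in uuo]
        trend_ok = all(u > sham_mean for u in uuo)
        if not criteria.require_consistent_trend:
            trend_ok = True
        c2 = (
            quantifiable
            and trend_ok
            and any(f > criteria.fold_threshold for f in per_animal_folds)
        )
        c3 = all(u >= criteria.min_uuo_count for u in uuo)

        significant = (
            quantifiable
            and c1
            and c2
            and c3
            and fold > criteria.fold_threshold
            and posthoc_p < criteria.alpha
        )
        results.append(
            DifferentialResult(
                accession=str(acc),
                comparison=comparison,
                sham_counts=sham,
                uuo_counts=uuo,
                sham_mean=sham_mean,
                uuo_mean=uuo_mean,
                fold_change=fold,
                f_statistic=f_stat,
                anova_p=anova_p,
                posthoc_p=posthoc_p,
                posthoc_method=method,
                criterion_flags=(c1, c2, c3),
                quantifiable=quantifiable,
                significant=significant,
            )
        )
    results.sort(key=lambda r: r.accession)
    return results


def results_to_frame(
    results: Sequence[DifferentialResult], rounded: bool = False
) -> pd.DataFrame:
    """Tabulate cascade results.

    With ``rounded=True`` the report mirrors the published table
    precision (fold 2 dp, F 3 dp, p 3 dp); otherwise full precision is
    kept. ``bh_q`` is a supplementary Benjamini-Hochberg q-value over
    the post hoc p-values of quantifiable proteins; it plays no part in
    the significance call.
    """
    frame = pd.DataFrame(
        {
            "accession": [r.accession for r in results],
            "comparison": [r.comparison for r in results],
            "fold_change": [r.fold_change for r in results],
            "posthoc_p": [r.posthoc_p for r in results],
            "posthoc_method": [r.posthoc_method for r in results],
            "f_statistic": [r.f_statistic for r in results],
            "anova_p": [r.anova_p for r in results],
            "sham_mean": [r.sham_mean for r in results],
            "uuo_mean": [r.uuo_mean for r in results],
            "sham_counts": [";".join(f"{c:g}" for c in r.sham_counts) for r in results],
            "uuo_counts": [";".join(f"{c:g}" for c in r.uuo_counts) for r in results],
            "min_two_unique_peptides": [r.criterion_flags[0] for r in results],
            "consistent_trend_fold": [r.criterion_flags[1] for r in results],
            "min_uuo_count": [r.criterion_flags[2] for r in results],
            "quantifiable": [r.quantifiable for r in results],
            "significant": [r.significant for r in results],
        }
    )
    quant = frame["quantifiable"].to_numpy()
    q = np.full(len(frame), np.nan)
    if quant.any():
        q[quant] = stats.false_discovery_control(
            frame.loc[quant, "posthoc_p"].to_numpy()
        )
    frame["bh_q"] = q
    if rounded:
        frame["fold_change"] = frame["fold_change"].round(2)
        frame["f_statistic"] = frame["f_statistic"].round(3)
        frame["posthoc_p"] = frame["posthoc_p"].round(3)
        frame["anova_p"] = frame["anova_p"].round(3)
        frame["bh_q"] = frame["bh_q"].round(3)
    return frame
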
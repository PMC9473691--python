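"""Test-selection decision tree and summary conventions for assay outputs.

The branch logic: every group is screened with the D'Agostino-Pearson
normality test (and an F test of variances is reported for two-group
designs). If all groups pass normality at α = 0.05, the parametric branch is
taken — paired/unpaired t test for two groups, one-way ANOVA with a Dunnett
(control designated) or Tukey (all pairs) correction for one-factor
multi-group designs, two-way ANOVA with a Sidak correction for two-factor
designs. Otherwise the rank-based branch is taken — Wilcoxon or
Mann-Whitney for two groups, Kruskal-Wallis with a Dunn correction for
multi-group designs. Dispersion is always reported as mean ± SEM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonPlan",
    "Contrast",
    "ComparisonResult",
    "choose_test",
    "run_comparison",
    "summarize",
    "dunn_posthoc",
]

ALPHA = 0.05
_MIN_NORMALITY_N = 8  # D'Agostino-Pearson needs at least 8 observations


@dataclass
class ComparisonPlan:
    design: str
    chosen_test: str
    correction: str
    normality_p: tuple[float, ...] = ()
    variance_p: float = math.nan
    parametric: bool = True
    small_n_flag: bool = False
    control: int | None = None
    alpha: float = ALPHA


@dataclass
class Contrast:
    label: str
    statistic: float
    p_uncorrected: float
    p_corrected: float


@dataclass
class ComparisonResult:
    plan: ComparisonPlan
    omnibus_statistic: float
    omnibus_p: float
    contrasts: list[Contrast]
    group_summaries: list[tuple[float, float | None, int]]  # (mean, SEM, n)
    anova_table: pd.DataFrame | None = None


def summarize(values: Sequence[float]) -> tuple[float, float | None, int]:
    """Mean, SEM (sd/√n, absent for n = 1) and n of one sample."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else None
    return mean, sem, int(arr.size)


def _normality_gate(
    groups: Sequence[np.ndarray], alpha: float
) -> tuple[tuple[float, ...], bool, bool]:
    """Per-group normality p-values; parametric iff every group passes.

    Groups too small for the test force the nonparametric branch with a
    flag.
    """
    ps: list[float] = []
    small = False
    parametric = True
    for g in groups:
        if g.size < _MIN_NORMALITY_N:
            ps.append(math.nan)
            small = True
            parametric = False
            continue
        p = float(sps.normaltest(g).pvalue)
        ps.append(p)
        if p < alpha:
            parametric = False
    return tuple(ps), parametric, small


def _variance_f_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F test of equality of variances (reported, not branching)."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0 and va == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    p = sps.f.sf(f, a.size - 1, b.size - 1)
    return float(min(1.0, 2.0 * min(p, 1.0 - p)))


def choose_test(
    groups: Sequence[Sequence[float]] | Mapping[tuple[str, str], Sequence[float]],
    design: str,
    control: int | None = None,
    alpha: float = ALPHA,
) -> ComparisonPlan:
    """Select the statistical test per the decision tree.

    ``groups`` is a sequence of samples, or for the ``two_factor`` design a
    mapping from (factor1 level, factor2 level) to samples. ``control``
    designates the reference group of a one-factor design, switching the
    correction from Tukey (all pairs) to Dunnett (each vs control).
    """
    if design == "two_factor":
        if not isinstance(groups, Mapping):
            raise TypeError("two_factor design needs a {(level1, level2): sample} mapping")
        cells = [np.asarray(list(v), dtype=float) for v in groups.values()]
        if len(cells) < 2:
            raise ValueError("need at least two cells")
        normality_p, parametric, small = _normality_gate(cells, alpha)
        return ComparisonPlan(
            design=design,
            chosen_test="two_way_anova",
            correction="sidak",
            normality_p=normality_p,
            parametric=parametric,
            small_n_flag=small,
            alpha=alpha,
        )

    arrs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 3 for a in arrs):
        raise ValueError("every group needs n >= 3")
    normality_p, parametric, small = _normality_gate(arrs, alpha)

    if design == "two_group_unpaired":
        if len(arrs) != 2:
            raise ValueError("two-group design with more than two groups")
        test = "unpaired_t" if parametric else "mann_whitney"
        return ComparisonPlan(
            design=design,
            chosen_test=test,
            correction="none",
            normality_p=normality_p,
            variance_p=_variance_f_test(arrs[0], arrs[1]),
            parametric=parametric,
            small_n_flag=small,
            alpha=alpha,
        )
    if design == "two_group_paired":
        if len(arrs) != 2 or arrs[0].size != arrs[1].size:
            raise ValueError("paired design needs two equally sized groups")
        test = "paired_t" if parametric else "wilcoxon"
        return ComparisonPlan(
            design=design,
            chosen_test=test,
            correction="none",
            normality_p=normality_p,
            variance_p=_variance_f_test(arrs[0], arrs[1]),
            parametric=parametric,
            small_n_flag=small,
            alpha=alpha,
        )
    if design == "one_factor_multi":
        if len(arrs) < 3:
            raise ValueError("one-factor multi design needs >= 3 groups")
        if parametric:
            correction = "dunnett" if control is not None else "tukey"
            return ComparisonPlan(
                design=design,
                chosen_test="one_way_anova",
                correction=correction,
                normality_p=normality_p,
                parametric=True,
                small_n_flag=small,
                control=control,
                alpha=alpha,
            )
        return ComparisonPlan(
            design=design,
            chosen_test="kruskal_wallis",
            correction="dunn",
            normality_p=normality_p,
            parametric=False,
            small_n_flag=small,
            control=control,
            alpha=alpha,
        )
    raise ValueError(f"unknown design {design!r}")


def dunn_posthoc(
    groups: Sequence[np.ndarray],
    labels: Sequence[str],
    control: int | None = None,
) -> list[Contrast]:
    """Dunn's rank-based pairwise comparisons after a Kruskal-Wallis test.

    z statistics are built from pooled mean ranks with the standard tie
    correction; p-values are Bonferroni-adjusted over the contrast family
    (all pairs, or each group versus the control when one is designated).
    """
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    offset = 0
    for n in sizes:
        mean_ranks.append(ranks[offset : offset + n].mean())
        offset += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = (
        [(control, j) for j in range(len(groups)) if j != control]
        if control is not None
        else list(combinations(range(len(groups)), 2))
    )
    m = len(pairs)
    out = []
    for i, j in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = float(2.0 * sps.norm.sf(abs(z)))
        out.append(
            Contrast(
                label=f"{labels[i]} vs {labels[j]}",
                statistic=float(z),
                p_uncorrected=p,
                p_corrected=min(1.0, p * m),
            )
        )
    return out


def run_comparison(
    plan: ComparisonPlan,
    groups: Sequence[Sequence[float]] | Mapping[tuple[str, str], Sequence[float]],
    labels: Sequence[str] | None = None,
    welch: bool = False,
) -> ComparisonResult:
    """Execute the planned test and multiplicity correction.

    Group means ± SEM are always included. ``welch`` opts into the unequal
    variance t variant (reported-only F test otherwise).
    """
    if plan.chosen_test == "two_way_anova":
        return _run_two_factor(plan, groups)  # type: ignore[arg-type]

    arrs = [np.asarray(list(g), dtype=float) for g in groups]
    labels = list(labels) if labels is not None else [f"group{i}" for i in range(len(arrs))]
    summaries = [summarize(a) for a in arrs]

    if plan.chosen_test == "unpaired_t":
        res = sps.ttest_ind(arrs[0], arrs[1], equal_var=not welch)
        contrast = [Contrast(f"{labels[0]} vs {labels[1]}", float(res.statistic), float(res.pvalue), float(res.pvalue))]
        return ComparisonResult(plan, float(res.statistic), float(res.pvalue), contrast, summaries)
    if plan.chosen_test == "paired_t":
        res = sps.ttest_rel(arrs[0], arrs[1])
        contrast = [Contrast(f"{labels[0]} vs {labels[1]}", float(res.statistic), float(res.pvalue), float(res.pvalue))]
        return ComparisonResult(plan, float(res.statistic), float(res.pvalue), contrast, summaries)
    if plan.chosen_test == "mann_whitney":
        res = sps.mannwhitneyu(arrs[0], arrs[1], alternative="two-sided")
        contrast = [Contrast(f"{labels[0]} vs {labels[1]}", float(res.statistic), float(res.pvalue), float(res.pvalue))]
        return ComparisonResult(plan, float(res.statistic), float(res.pvalue), contrast, summaries)
    if plan.chosen_test == "wilcoxon":
        res = sps.wilcoxon(arrs[0], arrs[1])
        contrast = [Contrast(f"{labels[0]} vs {labels[1]}", float(res.statistic), float(res.pvalue), float(res.pvalue))]
        return ComparisonResult(plan, float(res.statistic), float(res.pvalue), contrast, summaries)

    if plan.chosen_test == "one_way_anova":
        omni = sps.f_oneway(*arrs)
        if plan.correction == "dunnett":
            assert plan.control is not None
            others = [a for i, a in enumerate(arrs) if i != plan.control]
            other_labels = [l for i, l in enumerate(labels) if i != plan.control]
            res = sps.dunnett(*others, control=arrs[plan.control])
            contrasts = [
                Contrast(
                    f"{l} vs {labels[plan.control]}",
                    float(res.statistic[i]),
                    float(res.pvalue[i]),
                    float(res.pvalue[i]),
                )
                for i, l in enumerate(other_labels)
            ]
        else:
            res = sps.tukey_hsd(*arrs)
            contrasts = [
                Contrast(
                    f"{labels[i]} vs {labels[j]}",
                    float(res.statistic[i, j]),
                    float(res.pvalue[i, j]),
                    float(res.pvalue[i, j]),
                )
                for i, j in combinations(range(len(arrs)), 2)
            ]
        return ComparisonResult(plan, float(omni.statistic), float(omni.pvalue), contrasts, summaries)

    if plan.chosen_test == "kruskal_wallis":
        omni = sps.kruskal(*arrs)
        contrasts = dunn_posthoc(arrs, labels, control=plan.control)
        return ComparisonResult(plan, float(omni.statistic), float(omni.pvalue), contrasts, summaries)

    raise ValueError(f"unknown test {plan.chosen_test!r}")


def _run_two_factor(
    plan: ComparisonPlan, cells: Mapping[tuple[str, str], Sequence[float]]
) -> ComparisonResult:
    """Two-way ANOVA with Sidak-corrected factor-1 contrasts within each
    factor-2 level (the curve-by-curve comparison style)."""
    rows = []
    for (f1, f2), values in cells.items():
        for v in values:
            rows.append({"value": float(v), "f1": str(f1), "f2": str(f2)})
    frame = pd.DataFrame(rows)
    model = smf.ols("value ~ C(f1) * C(f2)", data=frame).fit()
    table = sm.stats.anova_lm(model, typ=2)
    omni_p = float(table.loc["C(f1)", "PR(>F)"])
    omni_f = float(table.loc["C(f1)", "F"])

    raw_ps: list[float] = []
    raw: list[tuple[str, float]] = []
    f1_levels = sorted(frame["f1"].unique())
    for f2_level in sorted(frame["f2"].unique()):
        sub = frame[frame["f2"] == f2_level]
        for a, b in combinations(f1_levels, 2):
            ga = sub.loc[sub["f1"] == a, "value"].to_numpy()
            gb = sub.loc[sub["f1"] == b, "value"].to_numpy()
            if ga.size < 2 or gb.size < 2:
                continue
            res = sps.ttest_ind(ga, gb)
            raw.append((f"{a} vs {b} @ {f2_level}", float(res.statistic)))
            raw_ps.append(float(res.pvalue))
    if raw_ps:
        _, corrected, _, _ = multipletests(raw_ps, method="sidak")
    else:
        corrected = []
    contrasts = [
        Contrast(label, stat, p, float(pc))
        for (label, stat), p, pc in zip(raw, raw_ps, corrected)
    ]
    summaries = [summarize(np.asarray(list(v), dtype=float)) for v in cells.values()]
    return ComparisonResult(plan, omni_f, omni_p, contrasts, summaries, anova_table=table)
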
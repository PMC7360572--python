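"""Group summaries and hypothesis-test orchestration.

Reproduces the cohort-level statistics layer: mean ± SE summaries, percent
change between treatment arms, and group comparisons that mirror common
qPCR-study practice — Shapiro–Wilk normality and Levene homogeneity
diagnostics, a pooled two-tailed Student's t-test for two groups, one-way
ANOVA with Tukey HSD or Duncan's multiple range test beyond two, and a
compact letter display of the post-hoc result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass(frozen=True)
class SummaryRow:
    label: str
    n: int
    mean: float
    se: float  # SD (n−1 denominator) / sqrt(n); 0 for n == 1


@dataclass(frozen=True)
class GroupComparison:
    design: str  # "two_group" | "multi_group"
    test_name: str
    statistic: float
    p_value: float
    normality_p: dict  # group label -> Shapiro-Wilk p (None for n < 3)
    homogeneity_p: float | None  # Levene
    letters: dict | None = None  # group label -> compact letter display
    posthoc: str | None = None
    pairwise_p: dict | None = None  # frozenset({a, b}) -> adjusted/stepwise p


def summarize(values, label: str = "") -> SummaryRow:
    """Mean ± standard error of the mean, the reporting convention used for
    cohort tables.  A single value has SE 0 by convention."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("summarize needs at least one value")
    se = 0.0 if x.size == 1 else float(x.std(ddof=1) / np.sqrt(x.size))
    return SummaryRow(label=label, n=int(x.size), mean=float(x.mean()), se=se)


def percent_change(baseline: float, treated: float) -> float:
    """100 × (baseline − treated) / baseline — e.g. the yield loss caused by
    DNase treatment relative to the untreated arm."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (baseline - treated) / baseline


# ---------------------------------------------------------------------------
# post-hoc machinery

def _compact_letters(labels, means, nonsig) -> dict:
    """Compact letter display from a pairwise non-significance relation.

    Means are sorted and maximal runs of mutually non-different groups each
    get a letter; groups share a letter iff they belong to a common run.
    """
    order = np.argsort(means)
    sorted_labels = [labels[i] for i in order]
    runs = []
    n = len(sorted_labels)
    i = 0
    for i in range(n):
        j = i
        while j + 1 < n and all(
            nonsig(sorted_labels[a], sorted_labels[b])
            for a, b in itertools.combinations(range(i, j + 2), 2)
        ):
            j += 1
        runs.append((i, j))
    # drop runs nested inside an earlier one
    maximal = []
    for r in runs:
        if not any(o[0] <= r[0] and r[1] <= o[1] and o != r for o in runs):
            maximal.append(r)
    maximal = sorted(set(maximal))
    letters = {lab: "" for lab in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for k, (lo, hi) in enumerate(maximal):
        for idx in range(lo, hi + 1):
            letters[sorted_labels[idx]] += alphabet[k % 26]
    return letters


def duncan_mrt(groups: dict, alpha: float = 0.05) -> dict:
    """Duncan's multiple range test on a one-way layout.

    Stepwise procedure on the sorted group means: the range spanning p means
    is significant when it exceeds R_p = r_p · sqrt(MSE / n_h), where r_p is
    the studentized-range quantile at Duncan's protection level
    1 − (1 − alpha)^(p − 1) with the ANOVA error df, and n_h is the harmonic
    mean of the two end-group sizes (plain n for balanced data).  Once a
    range is declared non-significant, no sub-range inside it is tested.
    Returns pairwise significance decisions as {frozenset({a, b}): bool}.
    """
    labels = list(groups)
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    k = len(labels)
    ns = {lab: d.size for lab, d in data.items()}
    N = sum(ns.values())
    sse = sum(((d - d.mean()) ** 2).sum() for d in data.values())
    df_err = N - k
    mse = sse / df_err
    means = {lab: float(d.mean()) for lab, d in data.items()}
    order = sorted(labels, key=lambda lab: means[lab])

    sig: dict[frozenset, bool] = {}
    protected: list[tuple[int, int]] = []  # non-significant spans, no retest inside
    # test ranges from widest to narrowest
    for span in range(k, 1, -1):
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            a, b = order[lo], order[hi]
            if any(plo <= lo and hi <= phi for plo, phi in protected):
                sig[frozenset((a, b))] = False
                continue
            p = span
            alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
            r_p = stats.studentized_range.isf(alpha_p, p, df_err)
            n_h = 2.0 / (1.0 / ns[a] + 1.0 / ns[b])
            R_p = r_p * np.sqrt(mse / n_h)
            diff = means[b] - means[a]
            significant = diff > R_p
            sig[frozenset((a, b))] = significant
            if not significant:
                protected.append((lo, hi))
    return sig


def compare_groups(
    groups: dict,
    alpha: float = 0.05,
    posthoc: str = "tukey",
    welch: bool = False,
) -> GroupComparison:
    """Compare labeled groups of measurements.

    Two groups: two-tailed Student's t-test (pooled variance by default,
    Welch behind ``welch=True``).  More than two: one-way ANOVA followed —
    when the omnibus p is below ``alpha`` — by the selected post-hoc (Tukey
    HSD with Tukey–Kramer adjustment for unbalanced sizes, or Duncan's
    multiple range test) rendered as a compact letter display.  Shapiro–Wilk
    and Levene p-values are always attached as diagnostics.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    data = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    for lab, d in data.items():
        if d.size < 2:
            raise ValueError(f"group {lab!r} has n < 2")
    normality = {
        lab: (float(stats.shapiro(d).pvalue) if d.size >= 3 else None)
        for lab, d in data.items()
    }
    homogeneity = float(stats.levene(*data.values()).pvalue)
    labels = list(data)

    if len(data) == 2:
        a, b = data.values()
        t = stats.ttest_ind(a, b, equal_var=not welch)
        return GroupComparison(
            design="two_group",
            test_name="welch_t" if welch else "student_t",
            statistic=float(t.statistic),
            p_value=float(t.pvalue),
            normality_p=normality,
            homogeneity_p=homogeneity,
        )

    f = stats.f_oneway(*data.values())
    letters = None
    pairwise = None
    if f.pvalue < alpha:
        means = [data[lab].mean() for lab in labels]
        if posthoc == "tukey":
            flat = np.concatenate([data[lab] for lab in labels])
            grp = np.concatenate([[lab] * data[lab].size for lab in labels])
            res = pairwise_tukeyhsd(flat, grp, alpha=alpha)
            pairs = [tuple(row) for row in res._results_table.data[1:]]
            pairwise = {
                frozenset((g1, g2)): float(padj)
                for (g1, g2, _d, padj, *_rest) in pairs
            }
            nonsig = lambda x, y: pairwise[frozenset((x, y))] >= alpha
        elif posthoc == "duncan":
            sig = duncan_mrt(data, alpha=alpha)
            pairwise = {pair: (0.0 if s else 1.0) for pair, s in sig.items()}
            nonsig = lambda x, y: not sig[frozenset((x, y))]
        else:
            raise ValueError(f"unknown post-hoc {posthoc!r}")
        letters = _compact_letters(labels, means, nonsig)
    return GroupComparison(
        design="multi_group",
        test_name="one_way_anova",
        statistic=float(f.statistic),
        p_value=float(f.pvalue),
        normality_p=normality,
        homogeneity_p=homogeneity,
        letters=letters,
        posthoc=posthoc if f.pvalue < alpha else None,
        pairwise_p=pairwise,
    )
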
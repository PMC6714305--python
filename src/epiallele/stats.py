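"""Group comparisons: ANOVA, Holm-corrected pairwise t-tests, letter codes.

Mean methylation levels per locus are compared across sample groups with a
one-way ANOVA followed by all pairwise two-sided Welch t-tests, adjusted by
Holm's step-down procedure within the locus (one multiple-testing family per
locus panel). When any group fails a Shapiro-Wilk normality check, all groups
are log-transformed (``log(x + 0.5)``, the offset handling exact zeros)
before testing; reported group means stay on the untransformed percent scale.

Significance letters follow the compact convention used for per-gene panels:
each reference group owns one letter (a, b, c, ...), appended to a group's
code once, twice or thrice for Holm-adjusted p < 0.05, < 0.005 and < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from string import ascii_lowercase

import numpy as np
import pandas as pd
from scipy import stats as sps

LETTER_TIERS = ((0.001, 3), (0.005, 2), (0.05, 1))


@dataclass
class GroupComparison:
    locus: str
    groups: dict[str, np.ndarray]  # raw-scale values (percent) per group
    log_transformed: bool
    anova_p: float
    pairwise: dict[tuple[str, str], float]  # Holm-adjusted p per pair
    pairwise_raw: dict[tuple[str, str], float]
    letters: dict[str, str]
    group_means: dict[str, float]  # untransformed, for display


def maybe_log_transform(
    groups: dict[str, np.ndarray], alpha_normality: float = 0.05
) -> tuple[dict[str, np.ndarray], bool]:
    """log(x + 0.5)-transform all groups if any fails Shapiro-Wilk normality.

    Groups with fewer than 3 values cannot be tested and never trigger the
    transform on their own.
    """
    needs = False
    for values in groups.values():
        v = np.asarray(values, dtype=float)
        if v.size < 3 or np.ptp(v) == 0:
            continue
        if sps.shapiro(v).pvalue < alpha_normality:
            needs = True
            break
    if not needs:
        return {k: np.asarray(v, dtype=float) for k, v in groups.items()}, False
    return (
        {k: np.log(np.asarray(v, dtype=float) + 0.5) for k, v in groups.items()},
        True,
    )


def holm_adjust(pvalues) -> list[float]:
    """Holm step-down adjustment.

    Sort raw p ascending, multiply the k-th smallest by (m - k), enforce a
    monotone nondecreasing sequence, cap at 1. (Implemented directly for
    speed; statsmodels' ``multipletests(method='holm')`` is the independent
    cross-check in the test suite.)
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = p[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return list(adjusted)


def anova_pairwise(
    groups: dict[str, np.ndarray],
    locus: str = "",
    auto_log: bool = True,
    alpha_normality: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA plus Holm-adjusted pairwise Welch t-tests.

    ``groups`` maps group label to methylation percentages. Requires at least
    two groups with at least two values each; a panel in which every group
    has zero within-group variance is undefined and raises.
    """
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(clean) < 2 or any(v.size < 2 for v in clean.values()):
        raise ValueError("need >=2 groups with >=2 values each")
    if all(np.ptp(v) == 0 for v in clean.values()):
        raise ValueError("zero within-group variance in every group; "
                         "t statistics undefined")
    if auto_log:
        tested, log_flag = maybe_log_transform(clean, alpha_normality)
    else:
        tested, log_flag = clean, False
    labels = list(clean)
    anova_p = float(sps.f_oneway(*[tested[k] for k in labels]).pvalue)
    pairs = list(combinations(labels, 2))
    raw = [
        float(sps.ttest_ind(tested[a], tested[b], equal_var=False).pvalue)
        for a, b in pairs
    ]
    adjusted = holm_adjust(raw)
    return GroupComparison(
        locus=locus,
        groups=clean,
        log_transformed=log_flag,
        anova_p=anova_p,
        pairwise=dict(zip(pairs, adjusted)),
        pairwise_raw=dict(zip(pairs, raw)),
        letters={},
        group_means={k: float(np.mean(v)) for k, v in clean.items()},
    )


def letter_codes(
    pairwise: dict[tuple[str, str], float],
    reference_groups: list[str],
    groups: list[str] | None = None,
) -> dict[str, str]:
    """Compact significance letters against ordered reference groups.

    Reference group i owns letter chr('a' + i); a group's code appends that
    letter 1/2/3 times when its Holm-adjusted p against the reference is
    < 0.05 / < 0.005 / < 0.001.
    """
    if len(reference_groups) > len(ascii_lowercase):
        raise ValueError("more reference groups than available letters")
    if groups is None:
        groups = sorted({g for pair in pairwise for g in pair})
    letter_of = dict(zip(reference_groups, ascii_lowercase))
    codes = {}
    for g in groups:
        code = ""
        for ref in reference_groups:
            if ref == g:
                continue
            p = pairwise.get((g, ref), pairwise.get((ref, g)))
            if p is None:
                continue
            for threshold, repeats in LETTER_TIERS:
                if p < threshold:
                    code += letter_of[ref] * repeats
                    break
        codes[g] = code
    return codes


def compare_locus(
    summaries: pd.DataFrame,
    sheet: pd.DataFrame,
    locus: str,
    group_by: str = "fraction",
    reference_groups: list[str] = ("blood", "AT", "SN"),
    alpha_normality: float = 0.05,
) -> GroupComparison:
    """Group-compare one locus' mean methylation using the sample sheet."""
    merged = summaries[summaries["locus"] == locus].merge(
        sheet[["sample_id", group_by]], on="sample_id"
    )
    groups = {
        label: sub["mean_methylation"].to_numpy()
        for label, sub in merged.groupby(group_by, sort=False)
        if len(sub) >= 2
    }
    comparison = anova_pairwise(
        groups, locus=locus, alpha_normality=alpha_normality
    )
    comparison.letters = letter_codes(
        comparison.pairwise,
        [g for g in reference_groups if g in groups],
        groups=list(groups),
    )
    return comparison


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        for g, values in c.groups.items():
            rows.append(
                {
                    "locus": c.locus,
                    "group": g,
                    "n": len(values),
                    "mean_methylation": c.group_means[g],
                    "letters": c.letters.get(g, ""),
                    "anova_p": c.anova_p,
                    "log_transformed": c.log_transformed,
                }
            )
    return pd.DataFrame(rows)


def pairwise_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        for (a, b), p_adj in c.pairwise.items():
            rows.append(
                {
                    "locus": c.locus,
                    "group_1": a,
                    "group_2": b,
                    "p_raw": c.pairwise_raw[(a, b)],
                    "p_holm": p_adj,
                }
            )
    return pd.DataFrame(rows)
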
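"""One-way ANOVA with Tukey HSD post hoc test and compact letter display.

The omnibus test is the classical fixed-effects one-way ANOVA.  Pairwise
comparisons use Tukey's honestly significant difference: the studentized
range statistic

    q_ij = |mean_i - mean_j| / sqrt(MSE / n~_ij)

with n~_ij the harmonic mean of the pair's group sizes (the Tukey-Kramer
extension for unbalanced designs) and adjusted p-values from the studentized
range distribution (scipy's numerically integrated CDF, so any number of
groups and error degrees of freedom are supported, not just tabulated ones).
Group letters are assigned with the insert-and-absorb algorithm so that two
groups share a letter if and only if their adjusted p exceeds alpha.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

__all__ = ["TukeyResult", "anova_tukey", "compact_letter_display"]


@dataclass
class TukeyResult:
    """ANOVA + Tukey HSD outcome for one family of group comparisons."""

    labels: list[str]
    means: np.ndarray
    n: np.ndarray
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    mse: float
    pairwise: pd.DataFrame  # group_a, group_b, diff, q, p_adj, significant
    letters: dict[str, str]
    alpha: float

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise["significant"]]
        return list(zip(sig["group_a"], sig["group_b"]))

    def is_significant(self, a: str, b: str) -> bool:
        pw = self.pairwise
        row = pw[((pw.group_a == a) & (pw.group_b == b)) |
                 ((pw.group_a == b) & (pw.group_b == a))]
        if row.empty:
            raise InputError(f"no comparison between {a!r} and {b!r}")
        return bool(row["significant"].iloc[0])


def compact_letter_display(labels: Sequence[str],
                           not_different: np.ndarray) -> dict[str, str]:
    """Letters such that two groups share one iff ``not_different[i, j]``.

    Insert-and-absorb: start with one letter set per non-difference clique
    seed, split sets that would wrongly join significantly different groups,
    then drop sets contained in others and assign letters in group order.
    """
    k = len(labels)
    sets: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not_different[i, j]:
            continue
        new_sets: list[set[int]] = []
        for s in sets:
            if i in s and j in s:
                new_sets.extend(({x for x in s if x != j}, {x for x in s if x != i}))
            else:
                new_sets.append(s)
        # absorb duplicates / subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if not any(s <= t for t in sets):
                sets.append(s)
    sets.sort(key=lambda s: (min(s), -len(s)))
    letters: dict[str, str] = {lab: "" for lab in labels}
    for letter, s in zip(_letter_stream(), sets):
        for i in sorted(s):
            letters[labels[i]] += letter
    return letters


def _letter_stream():
    import string
    for size in range(1, 4):
        for combo in itertools.product(string.ascii_lowercase, repeat=size):
            yield "".join(combo)


def anova_tukey(groups: Sequence[np.ndarray], labels: Sequence[str] | None = None,
                alpha: float = 0.05) -> TukeyResult:
    """One-way ANOVA and Tukey(-Kramer) HSD over two or more groups.

    Parameters
    ----------
    groups
        Samples (1-D arrays), each with at least two observations.
    labels
        Group names; defaults to ``g0, g1, ...``.
    alpha
        Family-wise significance level (0.05 and 0.01 are the conventional
        choices).

    Notes
    -----
    With exactly two groups the Tukey adjusted p equals the pooled two-sample
    t-test p (q = sqrt(2) |t|).  When the within-group variance is zero but
    means differ, all pairs are reported significant with a warning (exact
    separation); when everything is constant the single-letter null result is
    returned.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InputError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise InputError("each group needs n >= 2")
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    labels = list(labels)
    if len(labels) != len(groups):
        raise InputError("labels/groups length mismatch")

    k = len(groups)
    n = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = float(np.sum(n * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_between, df_within = k - 1, int(n.sum()) - k
    mse = ss_within / df_within

    if mse > 0:
        f_stat = (ss_between / df_between) / mse
        p_value = float(sps.f.sf(f_stat, df_between, df_within))
    elif ss_between > 0:
        warnings.warn("zero within-group variance with distinct means: "
                      "exact separation, all pairs significant", stacklevel=2)
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat, p_value = 0.0, 1.0

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        n_tilde = 2.0 / (1.0 / n[i] + 1.0 / n[j])  # Tukey-Kramer harmonic mean
        if mse > 0:
            q = abs(diff) / np.sqrt(mse / n_tilde)
            p_adj = float(sps.studentized_range.sf(q, k, df_within))
        else:
            q = np.inf if diff != 0 else 0.0
            p_adj = 0.0 if diff != 0 else 1.0
        rows.append(dict(group_a=labels[i], group_b=labels[j], diff=diff,
                         q=float(q), p_adj=p_adj, significant=p_adj <= alpha))
    pairwise = pd.DataFrame(rows)

    not_diff = np.ones((k, k), dtype=bool)
    for row, (i, j) in zip(rows, itertools.combinations(range(k), 2)):
        not_diff[i, j] = not_diff[j, i] = not row["significant"]
    letters = compact_letter_display(labels, not_diff)

    return TukeyResult(labels=labels, means=means, n=n, f_statistic=float(f_stat),
                       p_value=p_value, df_between=df_between, df_within=df_within,
                       mse=mse, pairwise=pairwise, letters=letters, alpha=alpha)
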
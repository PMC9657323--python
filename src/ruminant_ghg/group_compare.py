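"""One-way ANOVA with pooled SEM, Duncan's multiple range test, and
compact-letter displays.

The reporting convention mirrors nutrient/emission tables in animal-science
papers: one pooled SEM per row (sqrt(MSE / harmonic-mean group size)) and
superscript letters where groups sharing a letter are not significantly
different under Duncan's stepwise procedure.

Duncan's test orders the k group means and compares every pair whose ranks
are p apart against the least significant range

    R_p = q(1 - alpha_p; p, df_error) * sqrt(MSE / n_h),

where q is the studentized-range quantile, n_h the (harmonic mean) group
size, and alpha_p = 1 - (1 - alpha)^(p-1) is Duncan's protection level,
which grows with the span and makes the test more liberal than Tukey's HSD.
The standard stepwise rule applies: no pair inside a span already declared
non-significant may be declared significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    mse: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    pooled_sem: float
    grand_mean: float = field(default=np.nan)


@dataclass
class LetterDisplay:
    """group -> letter string; groups sharing a letter are indistinguishable."""

    letters: dict[str, str]

    def __getitem__(self, group: str) -> str:
        return self.letters[group]


def one_way_anova(values, groups) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA.

    If every observation is identical (zero total variance) the F statistic
    is undefined; it is reported as F = 0, p = 1 with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    labels, inverse = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(inverse)
    if np.any(sizes < 2):
        bad = labels[sizes < 2]
        raise ValueError(f"groups with < 2 observations: {list(bad)}")
    n = len(values)
    grand = values.mean()
    means = np.array([values[inverse == i].mean() for i in range(k)])
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(np.sum((values[inverse == i] - means[i]) ** 2) for i in range(k)))
    df_b, df_w = k - 1, n - k
    msw = ss_within / df_w
    harmonic_n = k / np.sum(1.0 / sizes)
    if ss_between + ss_within == 0.0:
        warnings.warn("all observations identical; F undefined, reporting F=0, p=1")
        f, p = 0.0, 1.0
    elif msw == 0.0:
        # separated constants: infinitely strong evidence
        f, p = np.inf, 0.0
    else:
        f = (ss_between / df_b) / msw
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        f_stat=f,
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        mse=msw,
        group_means=dict(zip(labels.tolist(), means.tolist())),
        group_sizes=dict(zip(labels.tolist(), sizes.tolist())),
        pooled_sem=float(np.sqrt(msw / harmonic_n)),
        grand_mean=float(grand),
    )


def duncan_mrt(
    anova: AnovaResult, group_sizes: dict[str, int] | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Duncan's multiple range test.

    Returns a symmetric boolean DataFrame (True = significantly different)
    indexed by group label. Unbalanced designs use the harmonic-mean group
    size with a warning.
    """
    sizes = group_sizes or anova.group_sizes
    order = sorted(anova.group_means, key=lambda g: (-anova.group_means[g], g))
    k = len(order)
    means = np.array([anova.group_means[g] for g in order])
    ns = np.array([sizes[g] for g in order], dtype=float)
    if len(set(ns)) > 1:
        warnings.warn("unbalanced group sizes; using harmonic mean n for Duncan ranges")
    n_h = k / np.sum(1.0 / ns)
    se = np.sqrt(anova.mse / n_h)
    df = anova.df_within

    # least significant range per span p = 2..k
    lsr = {}
    for p in range(2, k + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        q_crit = stats.studentized_range.ppf(1.0 - alpha_p, p, df) if se > 0 else 0.0
        lsr[p] = q_crit * se

    sig = np.zeros((k, k), dtype=bool)
    # stepwise: test spans from widest to narrowest; a span declared
    # non-significant shields every pair inside it.
    shielded = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if shielded[i, j]:
                continue
            diff = means[i] - means[j]
            if se == 0.0:
                significant = diff > 0
            else:
                significant = diff > lsr[span]
            if significant:
                sig[i, j] = sig[j, i] = True
            else:
                shielded[i : j + 1, i : j + 1] = True
    return pd.DataFrame(sig, index=order, columns=order)


def compact_letters(
    sig_matrix: pd.DataFrame, means: dict[str, float] | None = None
) -> LetterDisplay:
    """Insert-and-absorb compact letter display from a significance matrix.

    ``sig_matrix`` is symmetric boolean (True = significantly different).
    Letter columns are ordered by descending group mean (falling back to the
    matrix's own order), so the highest mean gets letter 'a'.
    """
    groups = list(sig_matrix.index)
    if not sig_matrix.equals(sig_matrix.T):
        raise ValueError("significance matrix must be symmetric")
    columns: list[set[str]] = [set(groups)]
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            if not bool(sig_matrix.iloc[gi, gj]):
                continue
            a, b = groups[gi], groups[gj]
            for col in [c for c in columns if a in c and b in c]:
                columns.remove(col)
                columns.append(col - {a})
                columns.append(col - {b})
            # absorb: drop columns that are subsets of another
            columns = [
                c for c in columns
                if c and not any(c < other for other in columns)
            ]
            # dedupe
            seen: list[set[str]] = []
            for c in columns:
                if c not in seen:
                    seen.append(c)
            columns = seen
    if means is None:
        rank = {g: i for i, g in enumerate(groups)}
    else:
        order = sorted(groups, key=lambda g: (-means[g], g))
        rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in col:
            letters[g] += letter
    return LetterDisplay({g: "".join(sorted(s)) for g, s in letters.items()})


def compare_groups(
    values, groups, alpha: float = 0.05
) -> tuple[AnovaResult, pd.DataFrame, LetterDisplay]:
    """ANOVA + Duncan + letters in one call (the `compare` CLI path)."""
    anova = one_way_anova(values, groups)
    sig = duncan_mrt(anova, alpha=alpha)
    letters = compact_letters(sig, anova.group_means)
    return anova, sig, letters


def report_row(name: str, anova: AnovaResult, letters: LetterDisplay, decimals: int = 2) -> dict:
    """One table row in the 'mean ^letter^ ... SEM p' reporting style."""
    row: dict[str, object] = {"item": name}
    for g in sorted(anova.group_means):
        row[g] = f"{anova.group_means[g]:.{decimals}f} {letters[g]}"
    row["SEM"] = round(anova.pooled_sem, decimals)
    row["p_value"] = "<0.001" if anova.p_value < 0.001 else f"{anova.p_value:.3f}"
    return row
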
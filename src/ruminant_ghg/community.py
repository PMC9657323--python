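"""Count-table normalisation and univariate community statistics.

Rarefaction (subsampling without replacement to a common depth), rank-level
relative abundance with top-k collapse, Shannon diversity, and the
rank-based two-sample / k-sample tests (Wilcoxon rank-sum, Kruskal-Wallis)
used for differential-abundance screening between grazing groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

#: taxonomic ranks carried by every lineage, coarsest to finest
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

UNASSIGNED = "Unassigned"


@dataclass
class CountTable:
    """Features x samples non-negative integer counts with per-feature
    taxonomic lineages.

    ``counts`` is a DataFrame indexed by feature id, one column per sample;
    ``lineage`` is indexed identically with one column per rank in RANKS.
    """

    counts: pd.DataFrame
    lineage: pd.DataFrame
    kingdom: str = "bacteria"

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.to_numpy() < 0).any():
            raise ValueError("count table contains negative entries")
        arr = counts.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("count table contains fractional entries")
        self.counts = counts.astype(np.int64)
        missing = self.counts.index.difference(self.lineage.index)
        if len(missing) > 0:
            fill = pd.DataFrame(
                UNASSIGNED, index=missing, columns=list(RANKS)
            )
            self.lineage = pd.concat([self.lineage, fill])
        self.lineage = self.lineage.reindex(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def copy(self) -> "CountTable":
        return CountTable(self.counts.copy(), self.lineage.copy(), self.kingdom)


@dataclass
class AbundanceProfile:
    """Per-sample proportions aggregated at one taxonomic rank."""

    rank: str
    proportions: pd.DataFrame  # taxa x samples, columns sum to 1
    top_k: int | None = None
    other_label: str = field(default="Other")


def rarefy(table: CountTable, fraction: float = 0.95, rng=None) -> CountTable:
    """Subsample every sample, without replacement, to a common depth.

    The target depth is ``floor(fraction * min sample depth)``; the draw is a
    multivariate hypergeometric per sample, seeded and reproducible.
    """
    if not 0 < fraction <= 1:
        raise ValueError("rarefaction fraction must be in (0, 1]")
    rng = np.random.default_rng(rng)
    depths = table.depths
    if (depths <= 0).any():
        bad = list(depths.index[depths <= 0])
        raise ValueError(f"samples with zero depth cannot be rarefied: {bad}")
    target = int(np.floor(fraction * depths.min()))
    out = {}
    for sample in table.samples:
        col = table.counts[sample].to_numpy()
        out[sample] = rng.multivariate_hypergeometric(col, target)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.samples)
    return CountTable(counts, table.lineage.copy(), table.kingdom)


def relative_abundance(
    table: CountTable, rank: str = "phylum", top_k: int | None = None
) -> AbundanceProfile:
    """Aggregate counts at a rank and normalise each sample to proportions.

    Taxa are ordered by decreasing mean proportion across samples; taxa
    beyond ``top_k`` are collapsed into an "Other" row.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; valid ranks: {RANKS}")
    grouped = table.counts.groupby(table.lineage[rank]).sum()
    depths = grouped.sum(axis=0)
    if (depths == 0).any():
        bad = list(depths.index[depths == 0])
        raise ValueError(f"samples with zero depth: {bad}")
    props = grouped.div(depths, axis=1)
    props = props.loc[props.mean(axis=1).sort_values(ascending=False).index]
    if top_k is not None and top_k < len(props):
        top = props.iloc[:top_k]
        other = 1.0 - top.sum(axis=0)
        props = pd.concat([top, other.to_frame("Other").T])
    return AbundanceProfile(rank=rank, proportions=props, top_k=top_k)


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over non-zero proportions.

    Natural log by default (nats); pass ``base=2`` for bits.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def shannon_per_sample(table: CountTable, base: float | None = None) -> pd.Series:
    return pd.Series(
        {s: shannon(table.counts[s].to_numpy(), base=base) for s in table.samples},
        name="shannon",
    )


def _rank_sum_exact_p(ranks_x_sum: float, all_ranks: np.ndarray, n_x: int) -> float:
    """Two-sided exact p: fraction of equally sized subsets whose rank sum is
    at least as far from the null mean as the observed one."""
    mu = n_x * (len(all_ranks) + 1) / 2.0
    obs = abs(ranks_x_sum - mu)
    count = 0
    total = 0
    for combo in combinations(all_ranks, n_x):
        total += 1
        if abs(sum(combo) - mu) >= obs - 1e-12:
            count += 1
    return count / total


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test.

    Returns ``(W, p_two_sided)`` where W is the rank sum of ``x`` in the
    combined sample. Exact enumeration when the combined size is <= 10 and
    there are no ties; otherwise a normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    n, m = len(x), len(y)
    big_n = n + m
    ranks = stats.rankdata(combined)
    w = float(ranks[:n].sum())
    has_ties = len(np.unique(combined)) < big_n
    if big_n <= 10 and not has_ties:
        return w, _rank_sum_exact_p(w, np.arange(1, big_n + 1), n)
    mu = n * (big_n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((big_n) * (big_n - 1))
    var = n * m / 12.0 * (big_n + 1 - tie_term)
    if var == 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return w, float(2.0 * stats.norm.sf(z))


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, inverse = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    n = len(values)
    ranks = stats.rankdata(values)
    h = 0.0
    for i in range(k):
        r = ranks[inverse == i]
        h += len(r) * (r.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n)
    if correction == 0.0:
        return 0.0, 1.0  # every observation identical
    h /= correction
    return float(h), float(stats.chi2.sf(h, k - 1))


def taxon_tests(
    table: CountTable,
    metadata: pd.DataFrame,
    group_a: str,
    group_b: str,
    rank: str = "genus",
    adjust: bool = False,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential abundance per taxon between two groups.

    ``metadata`` needs columns sample_id and group. Proportions at ``rank``
    are compared; stars mark raw p < 0.05 (*) and < 0.01 (**). Optional
    Benjamini-Hochberg adjusted q-values.
    """
    profile = relative_abundance(table, rank=rank)
    samples_a = metadata.loc[metadata["group"] == group_a, "sample_id"]
    samples_b = metadata.loc[metadata["group"] == group_b, "sample_id"]
    samples_a = [s for s in samples_a if s in profile.proportions.columns]
    samples_b = [s for s in samples_b if s in profile.proportions.columns]
    rows = []
    for taxon, row in profile.proportions.iterrows():
        stat, p = wilcoxon_rank_sum(row[samples_a].to_numpy(), row[samples_b].to_numpy())
        stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        rows.append(
            {"taxon": taxon, "comparison": f"{group_a} vs {group_b}",
             "mean_a": row[samples_a].mean(), "mean_b": row[samples_b].mean(),
             "statistic": stat, "p_value": p, "stars": stars}
        )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        p = out["p_value"].to_numpy()
        order = np.argsort(p)
        q = np.empty_like(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        out["q_value"] = np.minimum(q, 1.0)
    return out
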
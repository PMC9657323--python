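"""Multivariate community statistics.

Bray-Curtis dissimilarity, principal coordinates analysis (PCoA) via Gower
double-centering, PERMANOVA (Anderson's pseudo-F with label permutation or
complete enumeration), the Mantel matrix-correlation test, and redundancy
analysis (RDA) of genus-level communities on diet nutrient parameters with
stepwise forward variable selection.

Conventions adopted here (documented in the methods note):

* permutation p-values use the (1 + #exceedances) / (1 + permutations)
  convention, so p never reaches 0;
* negative PCoA eigenvalues are reported but excluded from the
  proportion-explained denominator, with no Cailliez/Lingoes correction;
* RDA canonical axis percentages are relative to the TOTAL community
  variance, not the constrained fraction alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError(f"matrix shape {self.data.shape} does not match {n} ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.data < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        return squareform(self.data, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


@dataclass
class PcoaResult:
    ids: list[str]
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # all, decreasing
    proportion_explained: np.ndarray  # per positive axis, over positive sum
    n_negative: int


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    permutations: int
    r_squared: float
    exhaustive: bool = False


@dataclass
class MantelResult:
    r: float
    p_value: float
    permutations: int
    method: str = "pearson"
    alternative: str = "greater"


@dataclass
class RdaResult:
    eigenvalues: np.ndarray  # canonical, decreasing
    percent_variance: np.ndarray  # of TOTAL community variance, per axis
    site_scores: pd.DataFrame  # samples x axes
    species_scores: pd.DataFrame  # taxa x axes
    biplot_scores: pd.DataFrame  # constraints x axes
    total_variance: float
    constrained_variance: float
    selected: list[str] = field(default_factory=list)


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(i,j) = sum|x-y| / sum(x+y).

    ``table`` holds samples in rows, taxa in columns (counts or
    proportions). An all-zero sample has no defined dissimilarity and is an
    error.
    """
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = table.index[x.sum(axis=1) == 0].tolist()
    if zero:
        raise ValueError(f"all-zero samples have no Bray-Curtis distance: {zero}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(list(table.index), d)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Principal coordinates analysis.

    Eigen-decomposes the Gower-centered matrix of -d^2/2; coordinates are
    eigenvectors scaled by the square root of their (positive) eigenvalues.
    Negative eigenvalues (non-Euclidean input) are counted and reported, not
    corrected.
    """
    b = _gower_center(d.data)
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals).max(), 1.0) * 1e-10
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    proportions = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    return PcoaResult(
        ids=list(d.ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=proportions,
        n_negative=int((eigvals < -tol).sum()),
    )


def _permanova_f(d2: np.ndarray, inverse: np.ndarray, sizes: np.ndarray) -> float:
    """Anderson's pseudo-F from squared distances and integer group labels."""
    n = d2.shape[0]
    a = len(sizes)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(a):
        mask = inverse == g
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(sizes[g], 1)].sum() / sizes[g]
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    d: DistanceMatrix,
    groups,
    permutations: int = 999,
    rng=None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``exhaustive=True`` enumerates every distinct assignment of labels to
    samples (feasible for small n) and returns the exact fraction of
    assignments with pseudo-F >= observed; otherwise Monte-Carlo label
    permutation with p = (1 + #exceedances) / (1 + permutations).
    """
    groups = np.asarray(groups)
    if len(groups) != d.n:
        raise ValueError("group labels must match distance matrix size")
    labels, inverse = np.unique(groups, return_inverse=True)
    sizes = np.bincount(inverse)
    if len(labels) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    if not exhaustive and permutations < 1:
        raise ValueError("permutations must be >= 1")
    d2 = d.data**2
    f_obs = _permanova_f(d2, inverse, sizes)
    n, a = d.n, len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    # R^2 = SS_among / SS_total recovered from F
    ss_within = ss_total / (1.0 + f_obs * (a - 1) / (n - a))
    r2 = 1.0 - ss_within / ss_total

    if exhaustive:
        assignments = _distinct_assignments(inverse)
        count = sum(
            1 for assign in assignments if _permanova_f(d2, assign, sizes) >= f_obs - 1e-12
        )
        return PermanovaResult(f_obs, count / len(assignments), len(assignments), r2, True)

    rng = np.random.default_rng(rng)
    exceed = 0
    perm = inverse.copy()
    for _ in range(permutations):
        rng.shuffle(perm)
        if _permanova_f(d2, perm, sizes) >= f_obs - 1e-12:
            exceed += 1
    return PermanovaResult(f_obs, (1 + exceed) / (1 + permutations), permutations, r2)


def _distinct_assignments(inverse: np.ndarray) -> list[np.ndarray]:
    """All distinct arrangements of a label multiset over positions."""
    n = len(inverse)
    labels = sorted(set(inverse.tolist()))
    out: list[np.ndarray] = []

    def recurse(positions: tuple[int, ...], remaining: list[int], assign: np.ndarray):
        if not remaining:
            out.append(assign.copy())
            return
        g = remaining[0]
        size = int((inverse == g).sum())
        for chosen in combinations(positions, size):
            assign[list(chosen)] = g
            rest = tuple(p for p in positions if p not in chosen)
            recurse(rest, remaining[1:], assign)

    recurse(tuple(range(n)), labels, np.empty(n, dtype=int))
    return out


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    permutations: int = 999,
    rng=None,
    method: str = "pearson",
    alternative: str = "greater",
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    Pearson (default) or Spearman correlation of the upper-triangle vectors;
    significance by simultaneously permuting rows and columns of the second
    matrix. ``alternative`` is "greater" (the common ecological default),
    "less" or "two-sided".
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must share sample ids in the same order")
    if d1.n < 3:
        raise ValueError("mantel needs at least 3 samples")
    corr = pearsonr if method == "pearson" else spearmanr
    v1 = d1.condensed()
    r_obs = float(corr(v1, d2.condensed())[0])
    rng = np.random.default_rng(rng)
    idx = np.arange(d1.n)
    exceed = 0
    for _ in range(permutations):
        rng.shuffle(idx)
        perm = d2.data[np.ix_(idx, idx)]
        r_perm = float(corr(v1, squareform(perm, checks=False))[0])
        if alternative == "greater":
            hit = r_perm >= r_obs - 1e-12
        elif alternative == "less":
            hit = r_perm <= r_obs + 1e-12
        else:
            hit = abs(r_perm) >= abs(r_obs) - 1e-12
        exceed += hit
    return MantelResult(r_obs, (1 + exceed) / (1 + permutations), permutations, method, alternative)


def nutrient_distance(nutrients: pd.DataFrame, metadata: pd.DataFrame) -> DistanceMatrix:
    """Per-sample Euclidean distance on z-scored diet nutrient columns.

    Each sample inherits the nutrient vector of its group (nutrients are
    measured per diet, not per animal). ``nutrients`` is indexed by group;
    ``metadata`` needs sample_id and group columns. Columns are standardized
    across samples (ddof=1); constant columns contribute zero.
    """
    missing = set(metadata["group"]) - set(nutrients.index)
    if missing:
        raise ValueError(f"groups without a nutrient row: {sorted(missing)}")
    x = nutrients.loc[metadata["group"]].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    mean = x.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mean) / sd, 0.0)
    d = squareform(pdist(z, metric="euclidean"))
    return DistanceMatrix(list(metadata["sample_id"]), d)


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    rank = 0
    offenders = []
    for j in range(x.shape[1]):
        new_rank = np.linalg.matrix_rank(x[:, : j + 1])
        if new_rank == rank:
            offenders.append(names[j])
        rank = new_rank
    if offenders:
        raise ValueError(f"constraints collinear with earlier columns: {offenders}")


def rda(community: pd.DataFrame, constraints: pd.DataFrame) -> RdaResult:
    """Redundancy analysis: PCA of the community variation explained by the
    constraints.

    ``community``: samples x taxa (e.g. genus-level proportions), centered
    internally. ``constraints``: samples x environmental columns,
    standardized internally. Community columns are regressed on the
    constraints by OLS; the fitted values are eigen-decomposed. Canonical
    axis percentages are relative to total community variance; site scores
    are the fitted-value projections, species scores the axis loadings, and
    biplot scores the correlations of each constraint with the site scores.
    """
    if list(community.index) != list(constraints.index):
        raise ValueError("community and constraints must share sample order")
    n, _ = community.shape
    q = constraints.shape[1]
    if n < q + 2:
        raise ValueError(f"need >= {q + 2} samples for {q} constraints")
    y = community.to_numpy(dtype=float)
    y = y - y.mean(axis=0)
    x = constraints.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError(
            f"constant constraint columns: {list(constraints.columns[sd == 0])}"
        )
    x = (x - x.mean(axis=0)) / sd
    _check_full_rank(x, list(constraints.columns))
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    # PCA of fitted values via SVD; eigenvalues on the (n-1) variance scale
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > max(eig.max(), 1.0) * 1e-12 if eig.size else np.array([], bool)
    u, s, vt, eig = u[:, keep], s[keep], vt[keep], eig[keep]
    total_var = float(np.sum(y**2)) / (n - 1)
    axes = [f"RDA{i + 1}" for i in range(len(eig))]
    site = u * s  # sample scores in fitted space
    species = vt.T
    with np.errstate(invalid="ignore"):
        biplot = np.array(
            [[_safe_corr(x[:, j], site[:, k]) for k in range(len(eig))] for j in range(q)]
        )
    return RdaResult(
        eigenvalues=eig,
        percent_variance=eig / total_var * 100.0,
        site_scores=pd.DataFrame(site, index=community.index, columns=axes),
        species_scores=pd.DataFrame(species, index=community.columns, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=constraints.columns, columns=axes),
        total_variance=total_var,
        constrained_variance=float(eig.sum()),
        selected=list(constraints.columns),
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _trace_r2(y: np.ndarray, x: np.ndarray) -> float:
    """Fraction of total community variance explained by OLS on x."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    return float(np.sum(fitted**2) / np.sum(y**2))


def _adjusted_r2(r2: float, n: int, m: int) -> float:
    if n - m - 1 <= 0:
        return -math.inf
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def forward_select(
    community: pd.DataFrame,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    permutations: int = 999,
    rng=None,
) -> list[str]:
    """Stepwise forward selection of constraining variables for RDA.

    At each step the candidate giving the largest adjusted R^2 is tested by
    permuting its sample rows (holding already-selected variables fixed);
    it is admitted if the marginal permutation p-value is <= alpha and the
    adjusted R^2 improves. Candidates collinear with the selected set are
    skipped. May select zero variables.
    """
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate variable")
    rng = np.random.default_rng(rng)
    y = community.to_numpy(dtype=float)
    y = y - y.mean(axis=0)
    xs = {}
    for name in candidates.columns:
        col = candidates[name].to_numpy(dtype=float)
        sd = col.std(ddof=1)
        if sd == 0:
            continue
        xs[name] = (col - col.mean()) / sd
    n = len(community)
    selected: list[str] = []
    current_adj = _adjusted_r2(0.0, n, 0)
    while True:
        x_sel = (
            np.column_stack([xs[s] for s in selected]) if selected else np.empty((n, 0))
        )
        best = None
        for name in xs:
            if name in selected:
                continue
            x_try = np.column_stack([x_sel, xs[name]])
            if np.linalg.matrix_rank(x_try) <= len(selected):
                continue  # collinear with current set
            r2 = _trace_r2(y, x_try)
            adj = _adjusted_r2(r2, n, len(selected) + 1)
            if best is None or adj > best[1]:
                best = (name, adj, r2)
        if best is None:
            break
        name, adj, r2 = best
        if adj <= current_adj:
            break
        # marginal permutation test of the added variable
        exceed = 0
        col = xs[name].copy()
        for _ in range(permutations):
            rng.shuffle(col)
            x_perm = np.column_stack([x_sel, col])
            if np.linalg.matrix_rank(x_perm) <= len(selected):
                continue
            if _trace_r2(y, x_perm) >= r2 - 1e-12:
                exceed += 1
        p = (1 + exceed) / (1 + permutations)
        if p > alpha:
            break
        selected.append(name)
        current_adj = adj
    return selected
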
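"""Shared statistics: Kruskal–Wallis with pairwise Wilcoxon, PERMANOVA,
PERMDISP, Benjamini–Hochberg adjustment, Pearson mock evaluation and PCA.

Permutation tests use the ``(1 + b) / (1 + n_perm)`` convention, are
seed-deterministic, and canonicalize the sample order internally so results
do not depend on the order samples arrive in.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rng import rng_from_seed
from .diversity import OrdinationResult, pcoa
from .io_formats import DistanceMatrix, ValidationError

__all__ = [
    "GroupTestResult",
    "PermutationTestResult",
    "bh_adjust",
    "kruskal_wallis",
    "pairwise_wilcoxon",
    "wilcoxon_rank_sum",
    "permanova",
    "pairwise_permanova",
    "permdisp",
    "mock_pearson",
    "pca_standardized",
]

DEFAULT_PERMUTATIONS = 999
#: Group-level tests call a difference significant when adjusted p < alpha.
GROUP_ALPHA = 0.05
#: Exact Wilcoxon enumeration is used when both groups are at most this size.
EXACT_WILCOXON_MAX_N = 8


@dataclass(frozen=True)
class GroupTestResult:
    """Global test plus BH-adjusted pairwise comparisons."""

    statistic: float
    pvalue: float
    pairwise: pd.DataFrame  # group1, group2, statistic, p_raw, p_adj, significant


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    n_permutations: int
    pvalue: float
    seed: int
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValidationError("NaN p-values are not allowed")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact permutation enumeration (midranks for ties) when both groups have
    at most :data:`EXACT_WILCOXON_MAX_N` observations; otherwise the normal
    approximation with tie and continuity corrections. Returns
    ``(rank sum of x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n < 2 or m < 2:
        raise ValidationError("each group needs >= 2 observations")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = float(ranks[:n].sum())
    if n <= EXACT_WILCOXON_MAX_N and m <= EXACT_WILCOXON_MAX_N:
        expected = n * (n + m + 1) / 2.0
        dev = abs(w_obs - expected)
        hits = total = 0
        for combo in itertools.combinations(range(n + m), n):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - expected) >= dev - 1e-12:
                hits += 1
        return w_obs, hits / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return w_obs, float(res.pvalue)


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in out.items():
        if v.size == 0:
            raise ValidationError(f"group {k!r} has zero observations")
    return out


def pairwise_wilcoxon(
    groups: Mapping[str, Sequence[float]], alpha: float = GROUP_ALPHA
) -> pd.DataFrame:
    """All pairwise rank-sum tests with BH adjustment across the pairs."""
    g = _as_groups(groups)
    rows = []
    for (a, xa), (b, xb) in itertools.combinations(g.items(), 2):
        stat, p = wilcoxon_rank_sum(xa, xb)
        rows.append({"group1": a, "group2": b, "statistic": stat, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
    df["significant"] = df["p_adj"] < alpha
    return df


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]], alpha: float = GROUP_ALPHA
) -> GroupTestResult:
    """Kruskal–Wallis H (tie-corrected) with pairwise Wilcoxon follow-up."""
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValidationError("need >= 2 groups")
    values = list(g.values())
    if all(np.all(v == values[0][0]) for v in values):
        # scipy raises on all-identical data; define H = 0, p = 1
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*values)
    return GroupTestResult(
        statistic=float(h), pvalue=float(p), pairwise=pairwise_wilcoxon(g, alpha)
    )


# ---------------------------------------------------------------------------
# PERMANOVA / PERMDISP
# ---------------------------------------------------------------------------


def _canonical(dm: DistanceMatrix, groups: Sequence[str]):
    if len(groups) != len(dm.ids):
        raise ValidationError("groups length must match the distance matrix")
    order = np.argsort(np.asarray(dm.ids, dtype=object), kind="stable")
    ids = tuple(dm.ids[i] for i in order)
    d = dm.values[np.ix_(order, order)]
    labels = np.asarray([str(groups[i]) for i in order], dtype=object)
    uniq, codes = np.unique(labels, return_inverse=True)
    counts = np.bincount(codes)
    if np.any(counts < 2):
        bad = uniq[counts < 2]
        raise ValidationError(f"groups with fewer than 2 samples: {list(bad)}")
    return ids, d, uniq, codes


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    return float(_pseudo_f_batch(d2, codes[None, :], n_groups)[0])


def _pseudo_f_batch(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Pseudo-F for each row of label assignments in ``codes`` (P × n)."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = np.zeros(codes.shape[0])
    for g in range(n_groups):
        mask = (codes == g).astype(float)
        n_g = mask[0].sum()
        ss_within += ((mask @ d2) * mask).sum(axis=1) / (2 * n_g)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_between) / (ss_within / df_within)
    # zero within-group scatter: F is +inf unless there is no between-group
    # scatter either
    return np.where(ss_within == 0, np.where(ss_between > 0, np.inf, 0.0), f)


def permanova(
    dm: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutational multivariate ANOVA (pseudo-F on squared distances)."""
    _, d, uniq, codes = _canonical(dm, groups)
    d2 = d ** 2
    k = uniq.size
    f_obs = _pseudo_f(d2, codes, k)
    rng = rng_from_seed(seed, 40)
    perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
    f_perm = _pseudo_f_batch(d2, perms, k)
    hits = int((f_perm >= f_obs - 1e-12).sum())
    return PermutationTestResult(
        statistic=float(f_obs),
        n_permutations=n_perm,
        pvalue=(1 + hits) / (1 + n_perm),
        seed=seed,
        details={"groups": list(uniq)},
    )


def pairwise_permanova(
    dm: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    alpha: float = GROUP_ALPHA,
) -> pd.DataFrame:
    """PERMANOVA on every two-group submatrix, BH-adjusted across pairs."""
    labels = np.asarray([str(g) for g in groups], dtype=object)
    uniq = list(dict.fromkeys(labels))
    rows = []
    for i, (a, b) in enumerate(itertools.combinations(uniq, 2)):
        mask = (labels == a) | (labels == b)
        ids = [s for s, m in zip(dm.ids, mask) if m]
        sub = dm.submatrix(ids)
        sub_groups = labels[mask]
        res = permanova(sub, list(sub_groups), n_perm=n_perm, seed=seed + i)
        rows.append(
            {"group1": a, "group2": b, "pseudo_F": res.statistic, "p_raw": res.pvalue}
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
    df["significant"] = df["p_adj"] < alpha
    return df


def _spatial_median(points: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Geometric median by Weiszfeld iteration."""
    y = points.mean(axis=0)
    for _ in range(max_iter):
        diff = points - y
        dist = np.linalg.norm(diff, axis=1)
        if np.any(dist < 1e-12):
            # median coincides with a data point
            return points[np.argmin(dist)].copy()
        w = 1.0 / dist
        y_new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def _dispersion_f(coords: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, np.ndarray]:
    dists = np.empty(coords.shape[0])
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        med = _spatial_median(coords[idx])
        dists[idx] = np.linalg.norm(coords[idx] - med, axis=1)
    grand = dists.mean()
    ss_between = ss_within = 0.0
    for g in range(n_groups):
        d = dists[codes == g]
        ss_between += d.size * (d.mean() - grand) ** 2
        ss_within += ((d - d.mean()) ** 2).sum()
    df_b, df_w = n_groups - 1, dists.size - n_groups
    if ss_within == 0:
        return (np.inf if ss_between > 0 else 0.0), dists
    return (ss_between / df_b) / (ss_within / df_w), dists


def permdisp(
    dm: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> PermutationTestResult:
    """Homogeneity of multivariate dispersions.

    Distances to each group's spatial median are computed in PCoA space
    (axes with negative eigenvalues discarded and reported); the ANOVA F on
    those distances is permuted over group labels.
    """
    ids, d, uniq, codes = _canonical(dm, groups)
    ord_res = pcoa(DistanceMatrix(ids, d))
    coords = ord_res.coordinates
    k = uniq.size
    f_obs, dists = _dispersion_f(coords, codes, k)
    rng = rng_from_seed(seed, 41)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        f_perm, _ = _dispersion_f(coords, perm, k)
        if f_perm >= f_obs - 1e-12:
            hits += 1
    n_negative = int((ord_res.eigenvalues < 0).sum())
    per_group = {
        str(u): dists[codes == g].tolist() for g, u in enumerate(uniq)
    }
    return PermutationTestResult(
        statistic=float(f_obs),
        n_permutations=n_perm,
        pvalue=(1 + hits) / (1 + n_perm),
        seed=seed,
        details={
            "group_dispersions": per_group,
            "negative_eigenvalues_discarded": n_negative,
        },
    )


# ---------------------------------------------------------------------------
# Mock evaluation and PCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MockPearsonResult:
    per_replicate_r: tuple[float, ...]
    mean_r: float
    observed_vs_observed_r: float | None  # mean pairwise r among replicates


def mock_pearson(
    expected: Sequence[float], observed: Sequence[Sequence[float]]
) -> MockPearsonResult:
    """Pearson r between an expected profile and observed replicates."""
    exp = np.asarray(expected, dtype=float)
    obs = np.atleast_2d(np.asarray(observed, dtype=float))
    if obs.shape[1] != exp.size:
        raise ValidationError("profiles must cover the same taxon set")
    if np.std(exp) == 0:
        raise ValidationError("expected profile has zero variance")
    rs = []
    for row in obs:
        if np.std(row) == 0:
            raise ValidationError("observed profile has zero variance")
        rs.append(float(sps.pearsonr(exp, row).statistic))
    ovo = None
    if obs.shape[0] >= 2:
        pair_rs = [
            float(sps.pearsonr(a, b).statistic)
            for a, b in itertools.combinations(obs, 2)
        ]
        ovo = float(np.mean(pair_rs))
    return MockPearsonResult(tuple(rs), float(np.mean(rs)), ovo)


def pca_standardized(
    matrix: np.ndarray,
    ids: Sequence[str] | None = None,
) -> OrdinationResult:
    """PCA on z-scored features (ddof=1); zero-variance features dropped.

    Proportions of variance sum to 1 over the returned components.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with >= 2 samples")
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValidationError("fewer than 2 features with nonzero variance")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    n = x.shape[0]
    eigvals = s ** 2 / (n - 1)
    scores = u * s
    prop = eigvals / eigvals.sum()
    sample_ids = tuple(ids) if ids is not None else tuple(
        f"S{i}" for i in range(n)
    )
    return OrdinationResult(
        ids=sample_ids,
        coordinates=scores,
        eigenvalues=eigvals,
        proportion_explained=prop,
        loadings=vt.T,
    )
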
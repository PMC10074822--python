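"""Alpha diversity, rarefaction, beta-diversity distances and PCoA.

Conventions (documented because the choices matter downstream):

- Shannon entropy is in natural log (nats) so Pielou's evenness is
  ``H / ln(S)``.
- Faith's PD and unweighted UniFrac use the rooted convention: branches on
  the path from the root to any present tip count as observed.
- Aitchison and PhILR distances add a unit pseudocount before closure by
  default; both are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._rng import rng_from_seed
from .io_formats import AsvTable, DistanceMatrix, PhyloTree, ValidationError

__all__ = [
    "AlphaResult",
    "OrdinationResult",
    "rarefy",
    "alpha_diversity",
    "beta_jaccard",
    "beta_unifrac_unweighted",
    "beta_aitchison",
    "philr_euclidean",
    "pcoa",
]

DEFAULT_RAREFACTION_DEPTH = 1604


@dataclass(frozen=True)
class AlphaResult:
    """Per-sample alpha-diversity indices."""

    table: pd.DataFrame  # index: sample id; columns observed, shannon, pielou, faith_pd

    def __getitem__(self, column: str) -> pd.Series:
        return self.table[column]


@dataclass(frozen=True)
class OrdinationResult:
    """Ordination axes (PCoA or PCA)."""

    ids: tuple[str, ...]
    coordinates: np.ndarray  # samples x axes (positive-eigenvalue axes only)
    eigenvalues: np.ndarray  # all eigenvalues, sorted descending
    proportion_explained: np.ndarray  # per retained axis; sums to <= 1
    loadings: np.ndarray | None = None  # features x axes, PCA only


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def rarefy(table: AsvTable, depth: int = DEFAULT_RAREFACTION_DEPTH, seed: int = 0) -> AsvTable:
    """Subsample each sample's counts without replacement to ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a warning.
    """
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    totals = table.sample_totals()
    keep = totals >= depth
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}",
            stacklevel=2,
        )
    out_ids, out_rows = [], []
    for i, (sid, ok) in enumerate(zip(table.sample_ids, keep)):
        if not ok:
            continue
        row = table.counts[i]
        if totals[i] == depth:
            out_rows.append(row.copy())
        else:
            rng = rng_from_seed(seed, 30, i)
            out_rows.append(rng.multivariate_hypergeometric(row, depth))
        out_ids.append(sid)
    if not out_ids:
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    return AsvTable(tuple(out_ids), table.asv_ids, np.array(out_rows))


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def _edge_presence(tree: PhyloTree, asv_ids: tuple[str, ...], presence: np.ndarray):
    """Per-edge presence indicators.

    Returns ``(lengths, membership)`` where ``membership[e, s]`` is True iff
    the subtree below edge ``e`` contains a tip present in sample ``s``.
    Edges are all nodes except the root; tips absent from ``asv_ids`` count
    as never present.
    """
    col = {a: j for j, a in enumerate(asv_ids)}
    n_samples = presence.shape[0]
    lengths, membership = [], []
    state: dict[int, np.ndarray] = {}
    for node in tree.root.postorder(include_self=True):
        if node.is_tip():
            vec = np.zeros(n_samples, dtype=bool)
            j = col.get(node.name)
            if j is not None:
                vec = presence[:, j].copy()
        else:
            vec = np.zeros(n_samples, dtype=bool)
            for child in node.children:
                vec |= state[id(child)]
        state[id(node)] = vec
        if node is not tree.root.root():
            lengths.append(float(node.length or 0.0))
            membership.append(vec)
    return np.array(lengths), np.array(membership)


def alpha_diversity(table: AsvTable, tree: PhyloTree | None = None) -> AlphaResult:
    """Observed ASVs, Shannon (nats), Pielou's evenness and Faith's PD.

    ``faith_pd`` requires ``tree`` and uses the rooted convention (the path
    from the root to each present tip is included).
    """
    totals = table.sample_totals()
    if np.any(totals == 0):
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValidationError(f"sample {bad!r} is empty")
    p = table.counts / totals[:, None]
    observed = (table.counts > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    pielou = np.where(observed > 1, shannon / np.log(np.maximum(observed, 2)), 0.0)

    data = {
        "observed": observed,
        "shannon": shannon,
        "pielou": pielou,
    }
    if tree is not None:
        missing = tree.missing_tips(table.asv_ids)
        if missing:
            raise ValidationError(
                f"tree is missing tips for ASVs: {missing[:5]}"
            )
        lengths, membership = _edge_presence(tree, table.asv_ids, table.counts > 0)
        data["faith_pd"] = membership.T.astype(float) @ lengths
    return AlphaResult(pd.DataFrame(data, index=list(table.sample_ids)))


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------


def beta_jaccard(table: AsvTable) -> DistanceMatrix:
    """Jaccard distance (1 − |A∩B|/|A∪B|) on presence/absence of a rarefied table."""
    presence = table.counts > 0
    if np.any(~presence.any(axis=1)):
        raise ValidationError("sample with empty presence set")
    d = squareform(pdist(presence, metric="jaccard"))
    return DistanceMatrix(table.sample_ids, d)


def beta_unifrac_unweighted(table: AsvTable, tree: PhyloTree) -> DistanceMatrix:
    """Unweighted UniFrac: unique / total observed branch length per pair.

    Observed branches are those on a root-to-tip path of a tip present in
    either sample (rooted convention, matching Faith's PD).
    """
    presence = table.counts > 0
    if np.any(~presence.any(axis=1)):
        raise ValidationError("sample with empty presence set")
    missing = tree.missing_tips(table.asv_ids)
    if missing:
        raise ValidationError(f"tree is missing tips for ASVs: {missing[:5]}")
    lengths, membership = _edge_presence(tree, table.asv_ids, presence)
    # per-pair: unique = c_s + c_t - 2*M_st, total = c_s + c_t - M_st
    m = membership.astype(float)
    weighted = m * lengths[:, None]
    shared = weighted.T @ m  # sum of lengths of branches observed in both
    c = weighted.sum(axis=0)
    union = c[:, None] + c[None, :] - shared
    unique = union - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, unique / union, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(table.sample_ids, d)


def _closure(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    x = counts.astype(float) + pseudocount
    if np.any(x <= 0):
        raise ValidationError("matrix must be strictly positive after pseudocount")
    return x / x.sum(axis=1, keepdims=True)


def clr(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform of count rows (+pseudocount, closed)."""
    x = np.log(_closure(counts, pseudocount))
    return x - x.mean(axis=1, keepdims=True)


def beta_aitchison(table: AsvTable, pseudocount: float = 1.0) -> DistanceMatrix:
    """Euclidean distance between CLR-transformed compositions (unrarefied input)."""
    z = clr(table.counts, pseudocount)
    return DistanceMatrix(table.sample_ids, squareform(pdist(z, metric="euclidean")))


def _philr_balances(
    tree: PhyloTree, asv_ids: tuple[str, ...], log_x: np.ndarray
) -> np.ndarray:
    """ILR balances from the rooted tree's sequential binary partition.

    Unit taxon and branch weights; multifurcations are resolved in advance
    by the caller. ``log_x``: samples × ASVs log-proportions.
    """
    col = {a: j for j, a in enumerate(asv_ids)}
    tip_sets: dict[int, list[int]] = {}
    balances = []
    for node in tree.root.postorder(include_self=True):
        if node.is_tip():
            if node.name not in col:
                raise ValidationError(f"tree tip {node.name!r} absent from table")
            tip_sets[id(node)] = [col[node.name]]
        else:
            children = node.children
            tips = [t for c in children for t in tip_sets[id(c)]]
            tip_sets[id(node)] = tips
            if len(children) == 2:
                left, right = (tip_sets[id(children[0])], tip_sets[id(children[1])])
                r, s = len(left), len(right)
                coef = np.sqrt(r * s / (r + s))
                bal = coef * (
                    log_x[:, left].mean(axis=1) - log_x[:, right].mean(axis=1)
                )
                balances.append(bal)
            elif len(children) != 1:
                raise ValidationError("tree must be bifurcating for PhILR")
    return np.column_stack(balances)


def philr_euclidean(
    table: AsvTable, tree: PhyloTree, pseudocount: float = 1.0
) -> DistanceMatrix:
    """Euclidean distance between PhILR (phylogenetic ILR) balances.

    The tree is sheared to the table's ASVs; multifurcations are resolved
    with zero-length edges (reported as a warning).
    """
    missing = tree.missing_tips(table.asv_ids)
    if missing:
        raise ValidationError(f"tree is missing tips for ASVs: {missing[:5]}")
    work = tree.root.copy()
    if set(t.name for t in work.tips()) != set(table.asv_ids):
        work = work.shear(list(table.asv_ids))
    if any(len(n.children) > 2 for n in work.non_tips(include_self=True)):
        warnings.warn("resolving multifurcations with zero-length edges", stacklevel=2)
        work.bifurcate(insert_length=0.0)
    work.prune()  # remove single-child internals left by shearing
    log_x = np.log(_closure(table.counts, pseudocount))
    balances = _philr_balances(PhyloTree(work), table.asv_ids, log_x)
    return DistanceMatrix(
        table.sample_ids, squareform(pdist(balances, metric="euclidean"))
    )


# ---------------------------------------------------------------------------
# Principal coordinates
# ---------------------------------------------------------------------------


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical scaling (Torgerson) of a distance matrix.

    Axes with negative eigenvalues are excluded from the coordinates and
    from the proportions explained; all eigenvalues are reported.
    """
    d2 = dm.values ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(1.0, float(np.abs(eigvals).max(initial=0.0)))
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    total = eigvals[pos].sum()
    prop = eigvals[pos] / total if total > 0 else np.zeros(pos.sum())
    return OrdinationResult(
        ids=dm.ids,
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
    )
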
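"""Predicted metabolic capacity: ASV→GSMM mapping, normalized reaction
abundances, differential-reaction testing and direction-aware subsystem
enrichment.

For sample ``i`` the normalized abundance of reaction ``r`` is the
abundance-weighted mean over mapped ASVs of each reaction's frequency
across the ASV's matched models::

    a_r(i) = sum_j a_ASV(j) * E(r, j) / sum_j a_ASV(j)

where ``E(r, j)`` is the fraction of ASV ``j``'s models containing ``r``.
Only ASVs mapped at family rank or lower to at least one model enter the
sums (a flag switches to the literal all-ASV denominator for sensitivity
analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import (
    AsvTable,
    GsmmCollection,
    TaxonomyTable,
    ValidationError,
)
from .stats_core import bh_adjust

__all__ = [
    "MAPPING_RANKS",
    "AsvModelMapping",
    "ReactionProbability",
    "ReactionAbundanceMatrix",
    "DifferentialReactionResult",
    "SubsystemEnrichmentResult",
    "map_asvs",
    "reaction_probabilities",
    "reaction_abundance",
    "differential_reactions",
    "subsystem_enrichment",
    "capacity_report",
]

#: Ranks eligible for model matching, searched lowest first.
MAPPING_RANKS = ("species", "genus", "family")

#: Reactions/subsystems are significant/enriched when adjusted p <= alpha.
REACTION_ALPHA = 0.05


@dataclass(frozen=True)
class AsvModelMapping:
    """Per-ASV model assignment at the lowest matchable rank."""

    mapped: dict[str, tuple[str, str, tuple[str, ...]]]  # asv -> (rank, taxon, models)
    unmapped: dict[str, str]  # asv -> reason

    def summary(self) -> pd.DataFrame:
        """Counts and mean model numbers per mapping rank."""
        rows = []
        for rank in MAPPING_RANKS:
            hits = [m for (r, _, m) in self.mapped.values() if r == rank]
            rows.append(
                {
                    "rank": rank,
                    "n_asvs": len(hits),
                    "mean_models": float(np.mean([len(m) for m in hits]))
                    if hits
                    else 0.0,
                }
            )
        rows.append(
            {
                "rank": "total_mapped",
                "n_asvs": len(self.mapped),
                "mean_models": float(
                    np.mean([len(m) for (_, _, m) in self.mapped.values()])
                )
                if self.mapped
                else 0.0,
            }
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReactionProbability:
    """E(r, j): per-ASV frequency of each reaction across its models.

    Zero entries are omitted from storage but defined as 0.
    """

    probabilities: dict[str, dict[str, float]]  # asv -> {reaction: E}

    def get(self, asv_id: str, reaction_id: str) -> float:
        return self.probabilities.get(asv_id, {}).get(reaction_id, 0.0)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(
            sorted({r for per in self.probabilities.values() for r in per})
        )


@dataclass(frozen=True)
class ReactionAbundanceMatrix:
    """Samples × reactions matrix of normalized reaction abundances."""

    sample_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.reaction_ids)):
            raise ValidationError("reaction abundance shape mismatch")
        if np.any((v < -1e-12) | (v > 1 + 1e-12)):
            raise ValidationError("reaction abundances must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.reaction_ids)
        )

    def prevalence_summary(self, presence_threshold: float = 0.9) -> dict[str, float]:
        """Fraction of reactions present in every sample, and fraction of
        samples containing more than ``presence_threshold`` of reactions."""
        present = self.values > 0
        return {
            "frac_reactions_in_all_samples": float(present.all(axis=0).mean()),
            "frac_samples_above_threshold": float(
                (present.mean(axis=1) > presence_threshold).mean()
            ),
        }


@dataclass(frozen=True)
class DifferentialReactionResult:
    """Per-reaction two-sample t-tests for one diet pair."""

    pair: tuple[str, str]
    table: pd.DataFrame  # index reaction; mean_diff, t, p_raw, p_adj, significant, direction
    skipped: tuple[str, ...]  # constant reactions excluded from testing


@dataclass(frozen=True)
class SubsystemEnrichmentResult:
    """Direction-aware Fisher enrichment of subsystems for one diet pair."""

    pair: tuple[str, str]
    table: pd.DataFrame  # subsystem, direction, a, b, c, d, p_raw, p_adj, enriched
    n_tested_reactions: int


# ---------------------------------------------------------------------------
# Mapping and reaction abundance
# ---------------------------------------------------------------------------


def map_asvs(taxonomy: TaxonomyTable, collection: GsmmCollection) -> AsvModelMapping:
    """Match each ASV to models at its lowest assigned rank among
    species → genus → family.

    Taxon names are compared exactly (whitespace-normalized, case-sensitive).
    ASVs with no assignment at family or lower are excluded with reason
    ``rank-above-family``; ASVs whose assigned taxa have no models get
    ``no-model-for-taxon``.
    """
    index: dict[tuple[str, str], list[str]] = {}
    for mid, model in collection.models.items():
        index.setdefault((model.rank, model.taxon), []).append(mid)
    for key in index:
        index[key].sort()

    mapped: dict[str, tuple[str, str, tuple[str, ...]]] = {}
    unmapped: dict[str, str] = {}
    for asv in taxonomy.asv_ids:
        names = {
            rank: " ".join(str(taxonomy.rank_of(asv, rank)).split())
            for rank in MAPPING_RANKS
        }
        if not any(names.values()):
            unmapped[asv] = "rank-above-family"
            continue
        for rank in MAPPING_RANKS:  # lowest rank first
            name = names[rank]
            if name and (rank, name) in index:
                mapped[asv] = (rank, name, tuple(index[(rank, name)]))
                break
        else:
            unmapped[asv] = "no-model-for-taxon"
    return AsvModelMapping(mapped=mapped, unmapped=unmapped)


def reaction_probabilities(
    mapping: AsvModelMapping, collection: GsmmCollection
) -> ReactionProbability:
    """E(r, j) = |models of ASV j containing r| / |models of ASV j|."""
    if not mapping.mapped:
        raise ValidationError("mapping is empty")
    probs: dict[str, dict[str, float]] = {}
    cache: dict[tuple[str, ...], dict[str, float]] = {}
    for asv, (_, _, model_ids) in mapping.mapped.items():
        if model_ids in cache:
            probs[asv] = cache[model_ids]
            continue
        counts: dict[str, int] = {}
        for mid in model_ids:
            for r in collection.models[mid].reactions:
                counts[r] = counts.get(r, 0) + 1
        per = {r: c / len(model_ids) for r, c in counts.items()}
        cache[model_ids] = per
        probs[asv] = per
    return ReactionProbability(probs)


def reaction_abundance(
    table: AsvTable,
    mapping: AsvModelMapping,
    probabilities: ReactionProbability,
    all_asv_denominator: bool = False,
) -> ReactionAbundanceMatrix:
    """Abundance-weighted mean of E(r, j) per sample.

    By default both numerator and denominator run over mapped ASVs only;
    ``all_asv_denominator`` switches to the literal all-ASV denominator
    (sensitivity mode), in which values may fall below the mapped-only ones.
    """
    mapped_asvs = [a for a in table.asv_ids if a in mapping.mapped]
    if not mapped_asvs:
        raise ValidationError("no mapped ASV present in the table")
    reactions = probabilities.reaction_ids
    r_index = {r: k for k, r in enumerate(reactions)}
    e = np.zeros((len(mapped_asvs), len(reactions)))
    for j, asv in enumerate(mapped_asvs):
        for r, val in probabilities.probabilities.get(asv, {}).items():
            e[j, r_index[r]] = val
    cols = [table.asv_ids.index(a) for a in mapped_asvs]
    a = table.counts[:, cols].astype(float)
    mapped_totals = a.sum(axis=1)
    if np.any(mapped_totals == 0):
        bad = table.sample_ids[int(np.argmax(mapped_totals == 0))]
        raise ValidationError(f"sample {bad!r} has zero mapped counts")
    denom = table.sample_totals().astype(float) if all_asv_denominator else mapped_totals
    values = (a @ e) / denom[:, None]
    return ReactionAbundanceMatrix(table.sample_ids, reactions, values)


# ---------------------------------------------------------------------------
# Differential testing and enrichment
# ---------------------------------------------------------------------------


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled-variance two-sample t over columns."""
    n1, n2 = a.shape[0], b.shape[0]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    zero_se = se == 0
    t[zero_se] = np.sign(m1 - m2)[zero_se] * np.inf
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p[np.isinf(t)] = 0.0
    return t, p


def differential_reactions(
    ram: ReactionAbundanceMatrix,
    groups: Mapping[str, str] | Sequence[str],
    diet_pair: tuple[str, str],
    equal_var: bool = True,
    alpha: float = REACTION_ALPHA,
) -> DifferentialReactionResult:
    """Two-sample t-test per reaction between the two diets of ``diet_pair``.

    ``groups`` maps sample id → diet (or is a per-sample sequence). Default
    is the pooled-variance Student test; ``equal_var=False`` gives Welch.
    Reactions constant and equal across both groups are skipped and
    reported; BH adjustment runs across the tested reactions; significance
    is adjusted p <= ``alpha``; direction is the diet with the higher mean.
    """
    if isinstance(groups, Mapping):
        labels = [str(groups[s]) for s in ram.sample_ids]
    else:
        if len(groups) != len(ram.sample_ids):
            raise ValidationError("groups length must match samples")
        labels = [str(g) for g in groups]
    d1, d2 = diet_pair
    idx1 = [i for i, g in enumerate(labels) if g == d1]
    idx2 = [i for i, g in enumerate(labels) if g == d2]
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValidationError("both diets need >= 2 samples")
    a, b = ram.values[idx1], ram.values[idx2]

    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    const = (a == a[0]).all(axis=0) & (b == b[0]).all(axis=0) & (a[0] == b[0])
    tested = ~const
    skipped = tuple(r for r, c in zip(ram.reaction_ids, const) if c)

    if equal_var:
        t, p = _pooled_t(a[:, tested], b[:, tested])
    else:
        t, p = sps.ttest_ind(a[:, tested], b[:, tested], equal_var=False)
        t, p = np.asarray(t), np.nan_to_num(np.asarray(p), nan=1.0)
    p_adj = bh_adjust(p)
    table = pd.DataFrame(
        {
            "mean_diff": mean_diff[tested],
            "t": t,
            "p_raw": p,
            "p_adj": p_adj,
            "significant": p_adj <= alpha,
        },
        index=[r for r, k in zip(ram.reaction_ids, tested) if k],
    )
    table["direction"] = np.where(table["t"] > 0, d1, d2)
    table.loc[table["t"] == 0, "direction"] = ""
    return DifferentialReactionResult((d1, d2), table, skipped)


def subsystem_enrichment(
    diff: DifferentialReactionResult,
    subsystem_map: Mapping[str, str],
    alpha: float = REACTION_ALPHA,
    alternative: str = "greater",
) -> SubsystemEnrichmentResult:
    """One-sided Fisher over-representation of each subsystem among the
    significantly different reactions, separately per direction.

    The universe is the set of tested reactions; for direction ``d`` the 2×2
    table is [[sig_d ∩ S, sig_d \\ S], [rest ∩ S, rest \\ S]]. BH adjustment
    runs across all (subsystem, direction) tests within the pair.
    """
    universe = list(diff.table.index)
    missing = [r for r in universe if r not in subsystem_map]
    if missing:
        raise ValidationError(
            f"reactions without subsystem: {missing[:5]}"
        )
    subsystems = sorted({subsystem_map[r] for r in universe})
    members = {
        s: frozenset(r for r in universe if subsystem_map[r] == s)
        for s in subsystems
    }
    n_total = len(universe)
    rows = []
    for direction in diff.pair:
        sig = frozenset(
            diff.table.index[
                diff.table["significant"] & (diff.table["direction"] == direction)
            ]
        )
        for s in subsystems:
            in_sub = members[s]
            a = len(sig & in_sub)
            b = len(sig) - a
            c = len(in_sub) - a
            d = n_total - len(sig) - c
            p = float(
                sps.fisher_exact([[a, b], [c, d]], alternative=alternative)[1]
            )
            rows.append(
                {
                    "subsystem": s,
                    "direction": direction,
                    "sig_in": a,
                    "sig_out": b,
                    "rest_in": c,
                    "rest_out": d,
                    "p_raw": p,
                }
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    table["enriched"] = table["p_adj"] <= alpha
    return SubsystemEnrichmentResult(diff.pair, table, n_total)


def capacity_report(
    enrichments: Sequence[SubsystemEnrichmentResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format enrichment table plus a signed pair × subsystem matrix.

    Matrix cells: +1 if enriched in diet 1, −1 if enriched in diet 2, 0
    otherwise; relabeling a pair (d2, d1) flips the sign.
    """
    if not enrichments:
        raise ValidationError("need at least one analyzed diet pair")
    long_rows = []
    subsystems: list[str] = []
    for res in enrichments:
        for _, row in res.table.iterrows():
            long_rows.append(
                {
                    "pair": f"{res.pair[0]} vs {res.pair[1]}",
                    "subsystem": row["subsystem"],
                    "direction": row["direction"],
                    "p_raw": row["p_raw"],
                    "p_adj": row["p_adj"],
                    "enriched": bool(row["enriched"]),
                }
            )
            if row["subsystem"] not in subsystems:
                subsystems.append(row["subsystem"])
    long = pd.DataFrame(long_rows)
    pairs = [f"{r.pair[0]} vs {r.pair[1]}" for r in enrichments]
    matrix = pd.DataFrame(0, index=pairs, columns=subsystems, dtype=int)
    for res in enrichments:
        key = f"{res.pair[0]} vs {res.pair[1]}"
        for _, row in res.table.iterrows():
            if row["enriched"]:
                sign = 1 if row["direction"] == res.pair[0] else -1
                matrix.at[key, row["subsystem"]] += sign
    return long, matrix
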
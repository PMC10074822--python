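"""ASV filtering, relative abundance, taxonomic aggregation, core microbiota
and compartment-overlap analysis."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    RANKS,
    AsvTable,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
)

__all__ = [
    "CompositionTable",
    "FilterResult",
    "CoreResult",
    "OverlapResult",
    "filter_asvs",
    "relative_abundance",
    "aggregate_lowest_rank",
    "top_n_taxa",
    "core_asvs",
    "shared_asvs",
]

#: Organelle names removed from 16S tables regardless of rank.
ORGANELLE_NAMES = ("chloroplast", "mitochondria")

#: An ASV must appear (count > 0) in at least this many biological samples.
MIN_PREVALENCE_SAMPLES = 3


@dataclass(frozen=True)
class CompositionTable:
    """Relative abundances, each sample row summing to 1."""

    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray
    feature_ranks: tuple[str, ...] | None = None  # rank of each label, if taxon-level

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n, m = len(self.sample_ids), len(self.feature_ids)
        if v.shape != (n, m):
            raise ValidationError(f"composition shape {v.shape} != ({n}, {m})")
        if np.any(v < 0):
            raise ValidationError("relative abundances must be >= 0")
        if m and np.any(np.abs(v.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("composition rows must sum to 1 (tol 1e-9)")
        if self.feature_ranks is not None and len(self.feature_ranks) != m:
            raise ValidationError("feature_ranks length mismatch")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "CompositionTable":
        wanted = list(sample_ids)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in wanted]
        return CompositionTable(
            tuple(wanted), self.feature_ids, self.values[rows], self.feature_ranks
        )


@dataclass(frozen=True)
class FilterResult:
    table: AsvTable
    removed: dict[str, tuple[str, ...]]  # asv id -> reasons

    @property
    def removed_ids(self) -> frozenset[str]:
        return frozenset(self.removed)


@dataclass(frozen=True)
class CoreResult:
    """Core ASVs overall plus per-group cores and their intersection."""

    core: frozenset[str]
    per_group: dict[str, frozenset[str]]
    intersection: frozenset[str]
    prevalence: dict[str, float]  # asv -> prevalence over the analyzed subset


@dataclass(frozen=True)
class OverlapResult:
    """Shared-ASV overlap between two compartments."""

    shared_ids: frozenset[str]
    present_a: frozenset[str]
    present_b: frozenset[str]
    shared_abundance_a: float  # summed mean relative abundance of shared ASVs in A
    shared_abundance_b: float

    @property
    def shared_count(self) -> int:
        return len(self.shared_ids)


def _is_organelle(lineage: Mapping[str, str]) -> bool:
    return any(
        str(v).strip().lower() in ORGANELLE_NAMES for v in lineage.values()
    )


def filter_asvs(
    table: AsvTable,
    taxonomy: TaxonomyTable,
    metadata: SampleMetadata | None = None,
    digesta_only: bool = False,
    min_samples: int = MIN_PREVALENCE_SAMPLES,
) -> FilterResult:
    """Remove organelle, phylum-unassigned and low-prevalence ASVs.

    An ASV is retained iff it (a) is not labeled chloroplast/mitochondria at
    any rank (case-insensitive), (b) has a phylum assignment (ASVs absent
    from the taxonomy count as unassigned), and (c) has count > 0 in at
    least ``min_samples`` biological (non-control) samples. With
    ``digesta_only`` the prevalence is computed over digesta samples only.
    """
    if metadata is not None:
        if digesta_only:
            bio = [s for s in table.sample_ids
                   if metadata.table.at[s, "sample_type"] == "digesta"]
        else:
            bio = [s for s in table.sample_ids
                   if metadata.table.at[s, "sample_type"] != "control"]
    else:
        bio = list(table.sample_ids)
    row_idx = [table.sample_ids.index(s) for s in bio]
    presence = (table.counts[row_idx] > 0).sum(axis=0)

    removed: dict[str, list[str]] = {}
    keep = []
    known = set(taxonomy.asv_ids)
    for j, asv in enumerate(table.asv_ids):
        reasons = []
        if asv in known:
            lineage = taxonomy.lineage(asv)
            if _is_organelle(lineage):
                reasons.append("organelle")
            if not str(lineage["phylum"]).strip():
                reasons.append("no-phylum")
        else:
            reasons.append("no-phylum")
        if presence[j] < min_samples:
            reasons.append(f"prevalence<{min_samples}")
        if reasons:
            removed[asv] = reasons
        else:
            keep.append(asv)
    return FilterResult(
        table=table.select_asvs(keep),
        removed={a: tuple(r) for a, r in removed.items()},
    )


def relative_abundance(table: AsvTable) -> CompositionTable:
    """Divide each sample's counts by its total."""
    totals = table.sample_totals()
    if np.any(totals == 0):
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValidationError(f"sample {bad!r} has zero total count")
    return CompositionTable(
        table.sample_ids, table.asv_ids, table.counts / totals[:, None]
    )


def aggregate_lowest_rank(
    comp: CompositionTable,
    taxonomy: TaxonomyTable,
    target_rank: str = "genus",
) -> CompositionTable:
    """Aggregate to ``target_rank``, falling back to each ASV's lowest
    assigned rank when the target rank is unassigned.

    Labels are ``(rank, name)`` pairs flattened to the name, with the rank
    retained in ``feature_ranks`` for disambiguation.
    """
    if target_rank not in RANKS:
        raise ValidationError(f"unknown rank {target_rank!r}")
    labels: list[tuple[str, str]] = []
    for asv in comp.feature_ids:
        name = taxonomy.rank_of(asv, target_rank)
        if name:
            labels.append((target_rank, name))
        else:
            rank, name = taxonomy.lowest_assigned(asv)
            if not name:
                raise ValidationError(f"ASV {asv!r} has no assigned rank at all")
            labels.append((rank, name))
    order: list[tuple[str, str]] = []
    seen: dict[tuple[str, str], int] = {}
    col_of = []
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(order)
            order.append(lab)
        col_of.append(seen[lab])
    out = np.zeros((len(comp.sample_ids), len(order)))
    for j, k in enumerate(col_of):
        out[:, k] += comp.values[:, j]
    return CompositionTable(
        comp.sample_ids,
        tuple(name for _, name in order),
        out,
        feature_ranks=tuple(rank for rank, _ in order),
    )


def top_n_taxa(
    comp: CompositionTable, n: int, grouping: SampleMetadata
) -> pd.DataFrame:
    """Rank taxa by overall mean relative abundance; pool the rest as 'Other'.

    Returns a DataFrame with the top-``n`` taxa plus 'Other' as rows and the
    group labels (plus an 'overall' column) of mean relative abundances.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    df = comp.to_frame()
    overall = df.mean(axis=0).sort_values(ascending=False, kind="stable")
    top = list(overall.index[:n])
    groups = pd.Series(
        grouping.groups(comp.sample_ids), index=list(comp.sample_ids)
    )
    group_means = df.groupby(groups).mean()  # groups x taxa
    result = group_means[top].T
    result["overall"] = overall[top]
    other = 1.0 - result.sum(axis=0)
    result.loc["Other"] = other
    return result


def core_asvs(
    table: AsvTable,
    subset: Iterable[str] | None = None,
    prevalence_threshold: float = 0.80,
    metadata: SampleMetadata | None = None,
) -> CoreResult:
    """ASVs present (count > 0) in at least ``prevalence_threshold`` of the
    subset's samples; per-diet cores and their all-group intersection are
    computed when ``metadata`` is given."""
    if not (0.0 < prevalence_threshold <= 1.0):
        raise ValidationError("prevalence_threshold must be in (0, 1]")
    samples = list(subset) if subset is not None else list(table.sample_ids)
    if not samples:
        raise ValidationError("subset must be non-empty")
    sub = table.select_samples(samples)

    def _core_of(t: AsvTable) -> tuple[frozenset[str], dict[str, float]]:
        prev = (t.counts > 0).mean(axis=0)
        ids = frozenset(
            a for a, p in zip(t.asv_ids, prev) if p >= prevalence_threshold
        )
        return ids, {a: float(p) for a, p in zip(t.asv_ids, prev)}

    core, prevalence = _core_of(sub)
    per_group: dict[str, frozenset[str]] = {}
    if metadata is not None:
        diets = metadata.groups(sub.sample_ids)
        for diet in dict.fromkeys(diets):
            members = [s for s, d in zip(sub.sample_ids, diets) if d == diet]
            per_group[diet], _ = _core_of(sub.select_samples(members))
    intersection = (
        frozenset.intersection(*per_group.values()) if per_group else core
    )
    return CoreResult(core, per_group, intersection, prevalence)


def shared_asvs(
    comp_a: CompositionTable,
    comp_b: CompositionTable,
    min_presence: float = 0.0005,
) -> OverlapResult:
    """Overlap of ASVs present in two compartments.

    An ASV is present in a compartment iff its relative abundance reaches
    ``min_presence`` in at least one of that compartment's samples. The
    shared relative abundance is the sum over shared ASVs of their mean
    relative abundance within each compartment.
    """

    def _present(comp: CompositionTable) -> frozenset[str]:
        hit = (comp.values >= min_presence).any(axis=0)
        return frozenset(a for a, h in zip(comp.feature_ids, hit) if h)

    present_a, present_b = _present(comp_a), _present(comp_b)
    shared = present_a & present_b

    def _mean_abundance(comp: CompositionTable, ids: frozenset[str]) -> float:
        cols = [j for j, a in enumerate(comp.feature_ids) if a in ids]
        if not cols:
            return 0.0
        return float(comp.values[:, cols].mean(axis=0).sum())

    return OverlapResult(
        shared_ids=shared,
        present_a=present_a,
        present_b=present_b,
        shared_abundance_a=_mean_abundance(comp_a, shared),
        shared_abundance_b=_mean_abundance(comp_b, shared),
    )
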
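"""Validated domain objects and the file formats the pipeline reads/writes.

Formats are deliberately plain text: counts/taxonomy/metadata as TSV, trees
as newick, GSMM collections as JSON (see :data:`GSMM_JSON_SCHEMA` docstring on
:func:`read_gsmms`). Readers reject invalid input instead of coercing it;
writers always produce files their readers accept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "RANKS",
    "ValidationError",
    "AsvTable",
    "TaxonomyTable",
    "SampleMetadata",
    "PhyloTree",
    "GsmmModel",
    "GsmmCollection",
    "DistanceMatrix",
    "read_asv_table",
    "write_asv_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "read_gsmms",
    "write_gsmms",
    "read_distance_matrix",
    "write_distance_matrix",
]

#: The fixed seven-level taxonomic hierarchy, ordered top-down.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Strings normalized to "unassigned" (empty) when reading taxonomy.
_MISSING_SENTINELS = {"", "na", "n/a", "nan", "none", "unclassified", "unassigned", "-"}

SAMPLE_TYPES = ("digesta", "feed", "water", "control")


class ValidationError(ValueError):
    """Raised when an input file or domain object violates an invariant."""


# ---------------------------------------------------------------------------
# Domain objects
# ---------------------------------------------------------------------------


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class AsvTable:
    """Integer count matrix, samples in rows, ASVs in columns."""

    sample_ids: tuple[str, ...]
    asv_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_samples, n_asvs), integer dtype

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "asv_ids", tuple(map(str, self.asv_ids)))
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.asv_ids, "ASV")
        if counts.size:
            if not np.issubdtype(counts.dtype, np.integer):
                if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                    raise ValidationError("counts must be finite integers")
                counts = counts.astype(np.int64)
            if np.any(counts < 0):
                r, c = np.argwhere(counts < 0)[0]
                raise ValidationError(
                    f"negative count at sample {self.sample_ids[r]!r}, "
                    f"ASV {self.asv_ids[c]!r}"
                )
        object.__setattr__(self, "counts", counts.astype(np.int64, copy=False))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def select_samples(self, sample_ids: Iterable[str]) -> "AsvTable":
        wanted = list(sample_ids)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        rows = [index[s] for s in wanted]
        return AsvTable(tuple(wanted), self.asv_ids, self.counts[rows])

    def select_asvs(self, asv_ids: Iterable[str]) -> "AsvTable":
        wanted = list(asv_ids)
        index = {a: i for i, a in enumerate(self.asv_ids)}
        missing = [a for a in wanted if a not in index]
        if missing:
            raise ValidationError(f"unknown ASV ids: {missing}")
        cols = [index[a] for a in wanted]
        return AsvTable(self.sample_ids, tuple(wanted), self.counts[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.asv_ids)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AsvTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.asv_ids == other.asv_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class TaxonomyTable:
    """Per-ASV lineage over the fixed 7-rank hierarchy; '' = unassigned.

    Invariant: ranks fill top-down — an assigned rank never sits below an
    unassigned one.
    """

    lineages: pd.DataFrame  # index: asv id, columns: RANKS, values: str

    def __post_init__(self) -> None:
        df = self.lineages
        if list(df.columns) != list(RANKS):
            raise ValidationError(f"taxonomy columns must be {list(RANKS)}")
        _check_unique(list(df.index.astype(str)), "ASV")
        vals = df.to_numpy(dtype=object)
        assigned = np.array(
            [[bool(str(v).strip()) for v in row] for row in vals], dtype=bool
        )
        # top-down fill: once a rank is missing, all lower ranks are missing
        for i, row in enumerate(assigned):
            if row.any():
                last = np.max(np.nonzero(row))
                if not row[: last + 1].all():
                    raise ValidationError(
                        f"ASV {df.index[i]!r}: lineage does not fill top-down"
                    )
        object.__setattr__(self, "lineages", df.astype(str))

    @property
    def asv_ids(self) -> tuple[str, ...]:
        return tuple(self.lineages.index.astype(str))

    def lineage(self, asv_id: str) -> dict[str, str]:
        return self.lineages.loc[asv_id].to_dict()

    def rank_of(self, asv_id: str, rank: str) -> str:
        """Assigned name at ``rank`` for ``asv_id``, '' if unassigned/unknown."""
        if asv_id not in self.lineages.index:
            return ""
        return str(self.lineages.at[asv_id, rank])

    def lowest_assigned(self, asv_id: str) -> tuple[str, str]:
        """(rank, name) of the lowest assigned rank, or ('', '') if none."""
        if asv_id not in self.lineages.index:
            return ("", "")
        row = self.lineages.loc[asv_id]
        for rank in reversed(RANKS):
            name = str(row[rank]).strip()
            if name:
                return (rank, name)
        return ("", "")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample metadata: diet group, sample type, tank, sequencing run."""

    table: pd.DataFrame  # index: sample id; columns diet, sample_type, tank, run

    REQUIRED = ("diet", "sample_type", "tank", "run")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        _check_unique(list(df.index.astype(str)), "sample")
        bad = set(df["sample_type"]) - set(SAMPLE_TYPES)
        if bad:
            raise ValidationError(
                f"unknown sample types {sorted(bad)}; expected one of {SAMPLE_TYPES}"
            )
        object.__setattr__(self, "table", df.astype(str))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.table.index.astype(str))

    def diet_of(self, sample_id: str) -> str:
        return str(self.table.at[sample_id, "diet"])

    def groups(self, sample_ids: Iterable[str]) -> list[str]:
        return [self.diet_of(s) for s in sample_ids]

    def samples_of_type(self, sample_type: str) -> list[str]:
        df = self.table
        return list(df.index[df["sample_type"] == sample_type].astype(str))

    def check_covers(self, table: AsvTable) -> None:
        missing = [s for s in table.sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")


@dataclass(frozen=True)
class PhyloTree:
    """Rooted tree with uniquely labeled tips and non-negative branch lengths."""

    root: TreeNode

    def __post_init__(self) -> None:
        tips = [t.name for t in self.root.tips()]
        if any(t is None for t in tips):
            raise ValidationError("tree has unnamed tips")
        _check_unique(tips, "tip")
        n_children = len(self.root.children)
        if n_children > 2:
            raise ValidationError(
                f"tree root has {n_children} children; a rooted tree is required"
            )
        for node in self.root.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                raise ValidationError(f"negative branch length at {node.name!r}")

    @property
    def tip_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.root.tips())

    def total_branch_length(self) -> float:
        return float(
            sum(
                n.length or 0.0
                for n in self.root.traverse(include_self=True)
            )
        )

    def missing_tips(self, asv_ids: Iterable[str]) -> list[str]:
        present = set(self.tip_names)
        return [a for a in asv_ids if a not in present]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())


@dataclass(frozen=True)
class GsmmModel:
    """A genome-scale metabolic model reduced to its reaction set."""

    model_id: str
    rank: str  # taxonomic rank of the label (species | genus | family | ...)
    taxon: str  # taxon name at that rank
    reactions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.reactions:
            raise ValidationError(f"model {self.model_id!r} has an empty reaction set")
        if self.rank not in RANKS:
            raise ValidationError(
                f"model {self.model_id!r}: unknown rank {self.rank!r}"
            )


@dataclass(frozen=True)
class GsmmCollection:
    """A set of GSMMs plus the reaction→subsystem map."""

    models: dict[str, GsmmModel]
    subsystems: dict[str, str]  # reaction id -> subsystem name

    def __post_init__(self) -> None:
        for m in self.models.values():
            missing = m.reactions - self.subsystems.keys()
            if missing:
                raise ValidationError(
                    f"model {m.model_id!r} uses reactions without a subsystem: "
                    f"{sorted(missing)[:5]}"
                )

    def models_for(self, rank: str, taxon: str) -> list[GsmmModel]:
        return [
            m for m in self.models.values() if m.rank == rank and m.taxon == taxon
        ]

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(sorted({r for m in self.models.values() for r in m.reactions}))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(map(str, self.ids)))
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if np.any(np.isnan(v)):
            raise ValidationError("distance matrix contains NaN")
        if np.any(np.abs(v - v.T) > 1e-12):
            raise ValidationError("distance matrix is not symmetric (tol 1e-12)")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        if np.any(v < 0):
            raise ValidationError("distance matrix has negative entries")
        _check_unique(self.ids, "sample")
        object.__setattr__(self, "values", v)

    def submatrix(self, ids: Iterable[str]) -> "DistanceMatrix":
        wanted = list(ids)
        index = {s: i for i, s in enumerate(self.ids)}
        rows = [index[s] for s in wanted]
        return DistanceMatrix(tuple(wanted), self.values[np.ix_(rows, rows)])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_asv_table(path: str | Path, transpose: bool = False) -> AsvTable:
    """Read a counts TSV (header = ASV ids, first column = sample ids).

    ``transpose=True`` accepts the transposed dialect (samples in columns).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        df = df.T
    try:
        counts = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric count in {path}: {exc}") from None
    if np.any(~np.isfinite(counts)):
        raise ValidationError(f"missing or non-finite counts in {path}")
    if np.any(counts != np.floor(counts)):
        r, c = np.argwhere(counts != np.floor(counts))[0]
        raise ValidationError(
            f"non-integer count at sample {df.index[r]!r}, ASV {df.columns[c]!r}"
        )
    if np.any(counts < 0):
        r, c = np.argwhere(counts < 0)[0]
        raise ValidationError(
            f"negative count at sample {df.index[r]!r}, ASV {df.columns[c]!r}"
        )
    return AsvTable(
        tuple(df.index.astype(str)), tuple(df.columns.astype(str)),
        counts.astype(np.int64),
    )


def write_asv_table(table: AsvTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def _normalize_taxon(value: object) -> str:
    s = " ".join(str(value).split())  # collapse whitespace
    return "" if s.lower() in _MISSING_SENTINELS else s


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a rank-columned taxonomy TSV; empty/sentinel cells = unassigned."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise ValidationError(f"taxonomy file missing rank columns: {missing}")
    df = df[list(RANKS)].map(_normalize_taxon)
    df.index = df.index.astype(str)
    return TaxonomyTable(df)


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    taxonomy.lineages.to_csv(path, sep="\t", index_label="asv_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.table.to_csv(path, sep="\t", index_label="sample_id")


def read_tree(path: str | Path) -> PhyloTree:
    root = TreeNode.read(str(path), format="newick")
    return PhyloTree(root)


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    tree.root.write(str(path), format="newick")


def read_gsmms(path: str | Path) -> GsmmCollection:
    """Read a GSMM collection JSON.

    Schema::

        {
          "models": {
            "<model id>": {"rank": "genus", "taxon": "Pediococcus",
                            "reactions": ["R0001", ...]},
            ...
          },
          "subsystems": {"R0001": "<subsystem name>", ...}
        }
    """
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict) or "models" not in payload or "subsystems" not in payload:
        raise ValidationError("GSMM JSON must contain 'models' and 'subsystems'")
    subsystems = {str(k): str(v) for k, v in payload["subsystems"].items()}
    models: dict[str, GsmmModel] = {}
    for mid, spec in payload["models"].items():
        models[str(mid)] = GsmmModel(
            model_id=str(mid),
            rank=str(spec["rank"]).lower(),
            taxon=_normalize_taxon(spec["taxon"]),
            reactions=frozenset(map(str, spec["reactions"])),
        )
    return GsmmCollection(models=models, subsystems=subsystems)


def write_gsmms(collection: GsmmCollection, path: str | Path) -> None:
    payload = {
        "models": {
            mid: {
                "rank": m.rank,
                "taxon": m.taxon,
                "reactions": sorted(m.reactions),
            }
            for mid, m in collection.models.items()
        },
        "subsystems": dict(sorted(collection.subsystems.items())),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValidationError("distance matrix row/column ids differ")
    return DistanceMatrix(tuple(df.index.astype(str)), df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.values, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t", index_label="sample_id"
    )
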
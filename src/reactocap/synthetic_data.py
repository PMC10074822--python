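"""Seeded simulators for communities, taxonomies, trees, GSMM collections
and mock profiles.

The generators are designed so planted effect sizes are analytic: the
baseline composition is drawn once, group effects are deterministic mass
reallocation toward the designated taxon (not resampling), and per-sample
variation comes from a Dirichlet perturbation around the group composition
followed by multinomial counting at a log-normally drawn library size.
All randomness descends from a single integer seed through a splittable
seed tree, so identical parameters give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._rng import rng_from_seed
from .io_formats import (
    RANKS,
    AsvTable,
    GsmmCollection,
    GsmmModel,
    PhyloTree,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
)

__all__ = [
    "CommunitySimParams",
    "GsmmSimParams",
    "simulate_community",
    "simulate_gsmm_collection",
    "simulate_mock",
]


@dataclass(frozen=True)
class CommunitySimParams:
    """Parameters of the per-diet digesta community generator.

    ``dominance_effects`` is a list of ``(group_label, asv_id, target)``
    triples: in that group the baseline composition is reallocated so the
    designated ASV holds ``target`` relative abundance in expectation.
    """

    n_groups: int = 2
    samples_per_group: int = 9
    n_asvs: int = 60
    base_concentration: float = 1.0
    dominance_effects: tuple[tuple[str, str, float], ...] = ()
    library_size_log_mean: float = float(np.log(23_000.0))
    library_size_log_sd: float = 1.0
    missing_rank_prob: float = 0.15
    seed: int = 0
    # extras beyond the minimum surface; defaults chosen for realistic tables
    group_labels: tuple[str, ...] | None = None
    sample_concentration: float = 300.0
    species_prob: float = 0.15
    tanks_per_group: int = 3

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValidationError("n_groups must be >= 1")
        if self.samples_per_group < 2:
            raise ValidationError("samples_per_group must be >= 2")
        if self.n_asvs < 10:
            raise ValidationError("n_asvs must be >= 10")
        if self.base_concentration <= 0 or self.sample_concentration <= 0:
            raise ValidationError("concentrations must be positive")
        if not (0.0 <= self.missing_rank_prob <= 1.0):
            raise ValidationError("missing_rank_prob must be in [0, 1]")
        labels = self.labels
        if len(labels) != self.n_groups:
            raise ValidationError("group_labels length must equal n_groups")
        effects = tuple(
            (str(g), str(a), float(t)) for g, a, t in self.dominance_effects
        )
        object.__setattr__(self, "dominance_effects", effects)
        per_group: dict[str, float] = {}
        for g, a, t in effects:
            if g not in labels:
                raise ValidationError(f"dominance effect on unknown group {g!r}")
            if not (0.0 <= t < 1.0):
                raise ValidationError("dominance target must be in [0, 1)")
            per_group[g] = per_group.get(g, 0.0) + t
        for g, total in per_group.items():
            if total >= 1.0:
                raise ValidationError(
                    f"dominance targets in group {g!r} sum to {total} >= 1"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        if self.group_labels is not None:
            return tuple(self.group_labels)
        return tuple(f"D{i + 1}" for i in range(self.n_groups))

    @property
    def asv_ids(self) -> tuple[str, ...]:
        return tuple(f"ASV{i + 1:04d}" for i in range(self.n_asvs))


@dataclass(frozen=True)
class GsmmSimParams:
    """Parameters of the GSMM-collection generator.

    Each mapped taxon receives ``n_models_per_taxon`` models sharing the core
    reactions; the planted ``signature_taxon``'s models carry the
    ``signature_subsystem``'s reactions with probability boosted by
    ``taxon_signature_strength``.
    """

    n_models_per_taxon: int = 5
    n_reactions: int = 200
    n_subsystems: int = 10
    core_reaction_frac: float = 0.2
    taxon_signature_strength: float = 0.0
    unmapped_taxon_frac: float = 0.0
    seed: int = 0
    accessory_prob: float = 0.3
    signature_taxon: str | None = None
    signature_subsystem: str | None = None

    def __post_init__(self) -> None:
        if self.n_models_per_taxon < 1 or self.n_reactions < 1:
            raise ValidationError("model and reaction counts must be positive")
        if self.n_subsystems < 1 or self.n_subsystems > self.n_reactions:
            raise ValidationError("need 1 <= n_subsystems <= n_reactions")
        if not (0.0 <= self.core_reaction_frac <= 1.0):
            raise ValidationError("core_reaction_frac must be in [0, 1]")
        if not (0.0 <= self.taxon_signature_strength <= 1.0):
            raise ValidationError("taxon_signature_strength must be in [0, 1]")
        if not (0.0 <= self.unmapped_taxon_frac <= 1.0):
            raise ValidationError("unmapped_taxon_frac must be in [0, 1]")
        if not (0.0 < self.accessory_prob < 1.0):
            raise ValidationError("accessory_prob must be in (0, 1)")

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(f"R{i + 1:05d}" for i in range(self.n_reactions))

    @property
    def subsystem_names(self) -> tuple[str, ...]:
        return tuple(f"SS{i + 1:02d}" for i in range(self.n_subsystems))


# ---------------------------------------------------------------------------
# Community simulation
# ---------------------------------------------------------------------------


def _group_compositions(params: CommunitySimParams, baseline: np.ndarray) -> np.ndarray:
    """Apply dominance effects as deterministic mass reallocation."""
    asv_index = {a: i for i, a in enumerate(params.asv_ids)}
    comps = np.tile(baseline, (params.n_groups, 1))
    for g_idx, label in enumerate(params.labels):
        effects = [
            (asv_index[a], t)
            for g, a, t in params.dominance_effects
            if g == label
        ]
        if not effects:
            continue
        for a, _ in effects:
            if a >= params.n_asvs:
                raise ValidationError("dominance target ASV out of range")
        target_idx = [a for a, _ in effects]
        targets = np.array([t for _, t in effects])
        comp = baseline.copy()
        others = np.setdiff1d(np.arange(params.n_asvs), target_idx)
        comp[others] = baseline[others] * (1.0 - targets.sum()) / baseline[others].sum()
        comp[target_idx] = targets
        comps[g_idx] = comp
    return comps


def _random_join(subtrees: list[TreeNode], rng: np.random.Generator) -> TreeNode:
    """Join subtrees into one bifurcating tree by random sequential pairing."""
    nodes = list(subtrees)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        a.length = float(rng.exponential(1.0)) + 1e-6
        b.length = float(rng.exponential(1.0)) + 1e-6
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return nodes[0]


def _simulate_tree(
    params: CommunitySimParams, genus_of: list[int], rng: np.random.Generator
) -> PhyloTree:
    """Random bifurcating tree, genus-monophyletic so taxonomy and tree agree."""
    by_genus: dict[int, list[str]] = {}
    for asv, g in zip(params.asv_ids, genus_of):
        by_genus.setdefault(g, []).append(asv)
    genus_subtrees = []
    for g in sorted(by_genus):
        tips = [TreeNode(name=a) for a in by_genus[g]]
        genus_subtrees.append(_random_join(tips, rng))
    root = _random_join(genus_subtrees, rng)
    root.length = None
    return PhyloTree(root)


def _simulate_taxonomy(
    params: CommunitySimParams, rng: np.random.Generator
) -> tuple[TaxonomyTable, list[int]]:
    n_genera = max(2, params.n_asvs // 4)
    n_families = max(2, n_genera // 2)
    n_orders = max(2, n_families // 2)
    genus_of = [int(g) for g in rng.integers(0, n_genera, size=params.n_asvs)]
    dominance_targets = {a for _, a, _ in params.dominance_effects}
    rows = []
    for asv, g in zip(params.asv_ids, genus_of):
        fam = g % n_families
        order = fam % n_orders
        lineage = {
            "domain": "Bacteria",
            "phylum": f"Phylum{order % 2 + 1:02d}",
            "class": f"Class{order:02d}",
            "order": f"Order{order:02d}",
            "family": f"Family{fam:02d}",
            "genus": f"Genus{g:02d}",
            "species": "",
        }
        # planted dominance targets keep their genus so the effect stays
        # attached to a well-defined taxon
        if asv not in dominance_targets and rng.random() < params.missing_rank_prob:
            lineage["genus"] = ""
        elif rng.random() < params.species_prob:
            lineage["species"] = f"Genus{g:02d} sp{int(rng.integers(1, 999)):03d}"
        rows.append(lineage)
    df = pd.DataFrame(rows, index=list(params.asv_ids), columns=list(RANKS))
    return TaxonomyTable(df), genus_of


def simulate_community(
    params: CommunitySimParams,
) -> tuple[AsvTable, TaxonomyTable, PhyloTree, SampleMetadata]:
    """Generate counts, taxonomy, tree and metadata for a planted-effect study.

    Counts for each sample are Multinomial(library size, p) with
    p ~ Dirichlet(sample_concentration × group composition); the library size
    is log-normal. Group compositions are the shared Dirichlet baseline with
    dominance effects applied as exact mass reallocation.
    """
    rng_base = rng_from_seed(params.seed, 0)
    rng_tax = rng_from_seed(params.seed, 1)
    rng_tree = rng_from_seed(params.seed, 2)
    rng_lib = rng_from_seed(params.seed, 3)
    rng_sample = rng_from_seed(params.seed, 4)

    baseline = rng_base.dirichlet(np.full(params.n_asvs, params.base_concentration))
    baseline = np.clip(baseline, 1e-12, None)
    baseline /= baseline.sum()
    comps = _group_compositions(params, baseline)

    taxonomy, genus_of = _simulate_taxonomy(params, rng_tax)
    tree = _simulate_tree(params, genus_of, rng_tree)

    n_samples = params.n_groups * params.samples_per_group
    lib_sizes = rng_lib.lognormal(
        params.library_size_log_mean, params.library_size_log_sd, size=n_samples
    )
    lib_sizes = np.maximum(lib_sizes.astype(np.int64), 10)

    sample_ids, counts, meta_rows = [], [], []
    s = 0
    for g_idx, label in enumerate(params.labels):
        alpha = np.clip(params.sample_concentration * comps[g_idx], 1e-8, None)
        for k in range(params.samples_per_group):
            p = rng_sample.dirichlet(alpha)
            counts.append(rng_sample.multinomial(lib_sizes[s], p))
            sid = f"S{s + 1:03d}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "diet": label,
                    "sample_type": "digesta",
                    "tank": f"{label}-T{k % params.tanks_per_group + 1}",
                    "run": f"run{s % 2 + 1}",
                }
            )
            s += 1

    table = AsvTable(tuple(sample_ids), params.asv_ids, np.array(counts))
    metadata = SampleMetadata(pd.DataFrame(meta_rows, index=sample_ids))
    return table, taxonomy, tree, metadata


# ---------------------------------------------------------------------------
# GSMM-collection simulation
# ---------------------------------------------------------------------------


def simulate_gsmm_collection(
    params: GsmmSimParams, taxa: Sequence[str | tuple[str, str]]
) -> GsmmCollection:
    """Generate a GSMM collection over ``taxa``.

    ``taxa`` entries are taxon names (assumed genus rank) or (rank, name)
    pairs. Every model contains all core reactions plus Bernoulli-sampled
    accessory reactions; the signature taxon's models include the signature
    subsystem's reactions with boosted probability
    ``p + strength * (1 - p)``.
    """
    if not taxa:
        raise ValidationError("taxa must be non-empty")
    labeled = [
        (t if isinstance(t, tuple) else ("genus", str(t))) for t in taxa
    ]
    rng = rng_from_seed(params.seed, 10)

    reactions = np.array(params.reaction_ids)
    subs = params.subsystem_names
    # round-robin: every reaction in exactly one subsystem, sizes balanced
    subsystem_map = {
        r: subs[i % params.n_subsystems] for i, r in enumerate(reactions)
    }
    n_core = int(round(params.core_reaction_frac * params.n_reactions))
    core_idx = rng.choice(params.n_reactions, size=n_core, replace=False)
    core_mask = np.zeros(params.n_reactions, dtype=bool)
    core_mask[core_idx] = True

    n_unmapped = int(np.floor(params.unmapped_taxon_frac * len(labeled)))
    sig_taxon = params.signature_taxon or labeled[0][1]
    sig_sub = params.signature_subsystem or subs[0]
    if sig_sub not in subs:
        raise ValidationError(f"unknown signature subsystem {sig_sub!r}")
    candidates = [i for i, (_, name) in enumerate(labeled) if name != sig_taxon]
    unmapped = set(
        rng.choice(candidates, size=min(n_unmapped, len(candidates)), replace=False)
        .tolist()
    )

    sig_mask = np.array([subsystem_map[r] == sig_sub for r in reactions])
    models: dict[str, GsmmModel] = {}
    for t_idx, (rank, name) in enumerate(labeled):
        if t_idx in unmapped:
            continue
        probs = np.full(params.n_reactions, params.accessory_prob)
        if name == sig_taxon:
            probs[sig_mask] = params.accessory_prob + params.taxon_signature_strength * (
                1.0 - params.accessory_prob
            )
        for k in range(params.n_models_per_taxon):
            present = core_mask | (rng.random(params.n_reactions) < probs)
            if not present.any():
                present[rng.integers(params.n_reactions)] = True
            models[f"M_{name}_{k + 1:03d}"] = GsmmModel(
                model_id=f"M_{name}_{k + 1:03d}",
                rank=rank,
                taxon=name,
                reactions=frozenset(reactions[present].tolist()),
            )
    return GsmmCollection(models=models, subsystems=subsystem_map)


# ---------------------------------------------------------------------------
# Mock community
# ---------------------------------------------------------------------------


def simulate_mock(
    expected_profile: np.ndarray | Sequence[float], noise_sd: float, seed: int
) -> np.ndarray:
    """Noisy observation of a mock community's expected taxonomic profile.

    Applies multiplicative log-normal noise and renormalizes; ``noise_sd=0``
    reproduces the expected profile exactly.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    expected = np.asarray(expected_profile, dtype=float)
    if expected.ndim != 1 or np.any(expected < 0):
        raise ValidationError("expected_profile must be a non-negative vector")
    if abs(expected.sum() - 1.0) > 1e-8:
        raise ValidationError("expected_profile must sum to 1")
    if noise_sd == 0:
        return expected.copy()
    rng = rng_from_seed(seed, 20)
    noisy = expected * np.exp(rng.normal(0.0, noise_sd, size=expected.shape))
    return noisy / noisy.sum()
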
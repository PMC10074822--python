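import numpy as np
import pandas as pd
import pytest

from reactocap.io_formats import (
    AsvTable,
    GsmmCollection,
    GsmmModel,
    ValidationError,
)
from reactocap.metabolic_capacity import (
    ReactionAbundanceMatrix,
    capacity_report,
    differential_reactions,
    map_asvs,
    reaction_abundance,
    reaction_probabilities,
    subsystem_enrichment,
)
from conftest import make_taxonomy
from oracles import fisher_greater_bruteforce, reaction_abundance_bruteforce


def _collection():
    subsystems = {f"R{i}": ("S1" if i < 3 else "S2") for i in range(6)}
    models = {
        "Mp1": GsmmModel("Mp1", "genus", "Pediococcus", frozenset({"R0", "R1"})),
        "Mp2": GsmmModel("Mp2", "genus", "Pediococcus", frozenset({"R0", "R2"})),
        "Mp3": GsmmModel("Mp3", "genus", "Pediococcus", frozenset({"R0", "R3"})),
        "Mp4": GsmmModel("Mp4", "genus", "Pediococcus", frozenset({"R0", "R4"})),
        "Mf1": GsmmModel("Mf1", "family", "Bacillaceae", frozenset({"R5"})),
        "Ms1": GsmmModel("Ms1", "species", "Weissella confusa", frozenset({"R1"})),
    }
    return GsmmCollection(models=models, subsystems=subsystems)


def _taxonomy():
    return make_taxonomy(
        {
            # species-level match
            "asv_sp": ["Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                        "Lactobacillaceae", "Weissella", "Weissella confusa"],
            # genus-level match
            "asv_gen": ["Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                         "Lactobacillaceae", "Pediococcus", ""],
            # family-level match
            "asv_fam": ["Bacteria", "Firmicutes", "Bacilli", "Bacillales",
                         "Bacillaceae", "", ""],
            # assigned only to order -> excluded
            "asv_ord": ["Bacteria", "Firmicutes", "Bacilli", "Bacillales",
                         "", "", ""],
            # genus with no models -> excluded
            "asv_nomodel": ["Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                             "Streptococcaceae", "Streptococcus", ""],
        }
    )


class TestMapAsvs:
    def test_mapping_ranks_and_exclusions(self):
        mapping = map_asvs(_taxonomy(), _collection())
        assert mapping.mapped["asv_sp"][0] == "species"
        assert mapping.mapped["asv_sp"][2] == ("Ms1",)
        assert mapping.mapped["asv_gen"][0] == "genus"
        assert len(mapping.mapped["asv_gen"][2]) == 4
        assert mapping.mapped["asv_fam"][0] == "family"
        assert mapping.unmapped["asv_ord"] == "rank-above-family"
        assert mapping.unmapped["asv_nomodel"] == "no-model-for-taxon"

    def test_summary_rank_counts_sum_to_total(self):
        mapping = map_asvs(_taxonomy(), _collection())
        summary = mapping.summary().set_index("rank")
        per_rank = summary.loc[["species", "genus", "family"], "n_asvs"].sum()
        assert per_rank == summary.at["total_mapped", "n_asvs"] == 3

    def test_species_match_single_model(self):
        mapping = map_asvs(_taxonomy(), _collection())
        rank, taxon, models = mapping.mapped["asv_sp"]
        assert (rank, taxon, len(models)) == ("species", "Weissella confusa", 1)


class TestReactionProbabilities:
    def test_three_of_four_models(self):
        mapping = map_asvs(_taxonomy(), _collection())
        probs = reaction_probabilities(mapping, _collection())
        # Pediococcus: R0 in 4/4, R1..R4 in 1/4 each
        assert probs.get("asv_gen", "R0") == 1.0
        assert probs.get("asv_gen", "R1") == 0.25
        assert probs.get("asv_gen", "R5") == 0.0

    def test_single_model_asv_binary(self):
        mapping = map_asvs(_taxonomy(), _collection())
        probs = reaction_probabilities(mapping, _collection())
        vals = set(probs.probabilities["asv_sp"].values())
        assert vals <= {1.0}

    def test_sum_equals_mean_model_size(self):
        mapping = map_asvs(_taxonomy(), _collection())
        probs = reaction_probabilities(mapping, _collection())
        coll = _collection()
        for asv, (_, _, model_ids) in mapping.mapped.items():
            mean_size = np.mean([len(coll.models[m].reactions) for m in model_ids])
            assert sum(probs.probabilities[asv].values()) == pytest.approx(mean_size)


class TestReactionAbundance:
    def test_single_asv_single_model(self):
        taxonomy = _taxonomy()
        coll = _collection()
        table = AsvTable(("s1",), ("asv_sp",), np.array([[12]]))
        mapping = map_asvs(taxonomy, coll)
        probs = reaction_probabilities(mapping, coll)
        ram = reaction_abundance(table, mapping, probs)
        assert ram.values[0, list(ram.reaction_ids).index("R1")] == 1.0

    def test_hand_weighted_mean(self):
        # ASV1 count 30 with E = 0.5; ASV2 count 10 with E = 1 -> 0.625
        coll = GsmmCollection(
            models={
                "A1": GsmmModel("A1", "genus", "G1", frozenset({"R"})),
                "A2": GsmmModel("A2", "genus", "G1", frozenset({"Q"})),
                "B1": GsmmModel("B1", "genus", "G2", frozenset({"R"})),
            },
            subsystems={"R": "S", "Q": "S"},
        )
        taxonomy = make_taxonomy(
            {
                "x1": ["Bacteria", "P", "C", "O", "F", "G1", ""],
                "x2": ["Bacteria", "P", "C", "O", "F", "G2", ""],
            }
        )
        table = AsvTable(("s1",), ("x1", "x2"), np.array([[30, 10]]))
        mapping = map_asvs(taxonomy, coll)
        probs = reaction_probabilities(mapping, coll)
        ram = reaction_abundance(table, mapping, probs)
        r_col = list(ram.reaction_ids).index("R")
        assert ram.values[0, r_col] == pytest.approx(0.625)

    def test_scale_invariance(self):
        taxonomy = _taxonomy()
        coll = _collection()
        mapping = map_asvs(taxonomy, coll)
        probs = reaction_probabilities(mapping, coll)
        counts = np.array([[30, 10, 5, 2, 7]])
        asvs = ("asv_gen", "asv_sp", "asv_fam", "asv_ord", "asv_nomodel")
        t1 = AsvTable(("s1",), asvs, counts)
        t2 = AsvTable(("s1",), asvs, counts * 2)
        r1 = reaction_abundance(t1, mapping, probs)
        r2 = reaction_abundance(t2, mapping, probs)
        np.testing.assert_allclose(r1.values, r2.values, atol=1e-12)

    def test_matches_bruteforce_random_instances(self):
        rng = np.random.default_rng(21)
        for trial in range(30):
            n_asvs = int(rng.integers(2, 6))
            n_reactions = int(rng.integers(1, 8))
            n_samples = int(rng.integers(1, 4))
            e = (rng.random((n_asvs, n_reactions)) * (rng.random((n_asvs, n_reactions)) < 0.7))
            counts = rng.integers(0, 50, size=(n_samples, n_asvs + 1))
            counts[:, 0] += 1  # mapped mass always positive
            asvs = tuple(f"a{j}" for j in range(n_asvs)) + ("unmapped",)
            table = AsvTable(tuple(f"s{i}" for i in range(n_samples)), asvs, counts)
            # assemble mapping/probabilities objects directly
            from reactocap.metabolic_capacity import AsvModelMapping, ReactionProbability

            mapping = AsvModelMapping(
                mapped={f"a{j}": ("genus", f"G{j}", (f"M{j}",)) for j in range(n_asvs)},
                unmapped={"unmapped": "rank-above-family"},
            )
            probs = ReactionProbability(
                {
                    f"a{j}": {
                        f"R{r}": float(e[j, r]) for r in range(n_reactions) if e[j, r] > 0
                    }
                    for j in range(n_asvs)
                }
            )
            ram = reaction_abundance(table, mapping, probs)
            reactions = ram.reaction_ids
            e_used = np.array(
                [[probs.get(f"a{j}", r) for r in reactions] for j in range(n_asvs)]
            )
            want = reaction_abundance_bruteforce(counts, list(range(n_asvs)), e_used)
            np.testing.assert_allclose(ram.values, want, atol=1e-12)

    def test_bounded_by_contributing_e(self):
        taxonomy = _taxonomy()
        coll = _collection()
        mapping = map_asvs(taxonomy, coll)
        probs = reaction_probabilities(mapping, coll)
        table = AsvTable(("s1",), ("asv_gen", "asv_sp"), np.array([[30, 10]]))
        ram = reaction_abundance(table, mapping, probs)
        for k, r in enumerate(ram.reaction_ids):
            es = [probs.get("asv_gen", r), probs.get("asv_sp", r)]
            assert min(es) - 1e-12 <= ram.values[0, k] <= max(es) + 1e-12

    def test_zero_mapped_counts_rejected(self):
        taxonomy = _taxonomy()
        coll = _collection()
        mapping = map_asvs(taxonomy, coll)
        probs = reaction_probabilities(mapping, coll)
        table = AsvTable(("s1",), ("asv_gen", "asv_ord"), np.array([[0, 5]]))
        with pytest.raises(ValidationError, match="zero mapped"):
            reaction_abundance(table, mapping, probs)

    def test_universal_reaction_is_one_everywhere(self):
        coll = GsmmCollection(
            models={
                f"M{i}": GsmmModel(
                    f"M{i}", "genus", f"G{i % 2}",
                    frozenset({"Rcore", f"Racc{i}"}),
                )
                for i in range(4)
            },
            subsystems={"Rcore": "S", "Racc0": "S", "Racc1": "S",
                        "Racc2": "S", "Racc3": "S"},
        )
        taxonomy = make_taxonomy(
            {
                "x1": ["Bacteria", "P", "C", "O", "F", "G0", ""],
                "x2": ["Bacteria", "P", "C", "O", "F", "G1", ""],
            }
        )
        table = AsvTable(("s1", "s2"), ("x1", "x2"), np.array([[3, 9], [8, 1]]))
        mapping = map_asvs(taxonomy, coll)
        probs = reaction_probabilities(mapping, coll)
        ram = reaction_abundance(table, mapping, probs)
        core_col = list(ram.reaction_ids).index("Rcore")
        np.testing.assert_allclose(ram.values[:, core_col], 1.0)


def _ram(values, reactions=None):
    values = np.asarray(values, dtype=float)
    reactions = reactions or tuple(f"R{j}" for j in range(values.shape[1]))
    return ReactionAbundanceMatrix(
        tuple(f"s{i}" for i in range(values.shape[0])), tuple(reactions), values
    )


class TestDifferentialReactions:
    def test_identical_groups_not_significant(self):
        values = np.tile([[0.5, 0.2]], (6, 1)) + np.array(
            [[0.01], [-0.01], [0.0], [0.01], [-0.01], [0.0]]
        )
        ram = _ram(values)
        groups = ["A"] * 3 + ["B"] * 3
        diff = differential_reactions(ram, groups, ("A", "B"))
        assert not diff.table["significant"].any()
        assert (diff.table["t"].abs() < 1e-9).all()

    def test_constant_reactions_skipped(self):
        values = np.column_stack([np.full(6, 0.7), np.linspace(0.1, 0.6, 6)])
        ram = _ram(values)
        diff = differential_reactions(ram, ["A"] * 3 + ["B"] * 3, ("A", "B"))
        assert diff.skipped == ("R0",)
        assert list(diff.table.index) == ["R1"]

    def test_power_on_planted_shift(self):
        flagged_fracs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            base = 0.3 + rng.normal(0, 0.05, size=(18, 80))
            base[:9, :50] += 0.3  # diet A shifted in the first 50 reactions
            ram = _ram(np.clip(base, 0, 1))
            diff = differential_reactions(
                ram, ["A"] * 9 + ["B"] * 9, ("A", "B")
            )
            sig = diff.table["significant"]
            flagged = sig[[f"R{j}" for j in range(50)]].mean()
            flagged_fracs.append(flagged)
        assert np.mean([f >= 0.9 for f in flagged_fracs]) >= 0.9

    def test_direction_follows_sign(self):
        values = np.vstack(
            [np.full((3, 1), 0.9) + [[0.0], [0.01], [-0.01]],
             np.full((3, 1), 0.1) + [[0.0], [0.01], [-0.01]]]
        )
        ram = _ram(values)
        diff = differential_reactions(ram, ["A"] * 3 + ["B"] * 3, ("A", "B"))
        assert diff.table.iloc[0]["direction"] == "A"
        flipped = differential_reactions(ram, ["A"] * 3 + ["B"] * 3, ("B", "A"))
        assert flipped.table.iloc[0]["direction"] == "A"

    def test_too_few_samples_rejected(self):
        ram = _ram([[0.1], [0.2], [0.3]])
        with pytest.raises(ValidationError):
            differential_reactions(ram, ["A", "B", "B"], ("A", "B"))


class TestSubsystemEnrichment:
    def _diff(self, sig_flags, directions, reactions=None):
        n = len(sig_flags)
        reactions = reactions or [f"R{j}" for j in range(n)]
        table = pd.DataFrame(
            {
                "mean_diff": 0.1,
                "t": [1.0 if d == "A" else -1.0 for d in directions],
                "p_raw": [0.001 if s else 0.5 for s in sig_flags],
                "p_adj": [0.001 if s else 0.5 for s in sig_flags],
                "significant": sig_flags,
                "direction": directions,
            },
            index=reactions,
        )
        from reactocap.metabolic_capacity import DifferentialReactionResult

        return DifferentialReactionResult(("A", "B"), table, ())

    def test_no_significant_reactions(self):
        diff = self._diff([False] * 10, ["A"] * 10)
        submap = {f"R{j}": ("S1" if j < 5 else "S2") for j in range(10)}
        result = subsystem_enrichment(diff, submap)
        assert (result.table["p_raw"] == 1.0).all()
        assert not result.table["enriched"].any()

    def test_fisher_equals_hypergeometric_oracle(self):
        from scipy.stats import fisher_exact

        p_scipy = fisher_exact([[3, 7], [10, 80]], alternative="greater")[1]
        assert p_scipy == pytest.approx(fisher_greater_bruteforce(3, 7, 10, 80), abs=1e-12)

    def test_contingency_counts_sum_to_universe(self):
        sig = [True] * 6 + [False] * 14
        directions = ["A"] * 10 + ["B"] * 10
        diff = self._diff(sig, directions)
        submap = {f"R{j}": f"S{j % 4}" for j in range(20)}
        result = subsystem_enrichment(diff, submap)
        totals = result.table[["sig_in", "sig_out", "rest_in", "rest_out"]].sum(axis=1)
        assert (totals == result.n_tested_reactions).all()

    def test_planted_subsystem_detected(self):
        # 10 of 12 significant-in-A reactions in S1; S1 has 15 of 60 reactions
        sig = [j < 10 or 15 <= j < 17 for j in range(60)]
        directions = ["A"] * 60
        submap = {f"R{j}": ("S1" if j < 15 else f"S{j % 3 + 2}") for j in range(60)}
        diff = self._diff(sig, directions)
        result = subsystem_enrichment(diff, submap)
        hit = result.table[(result.table.subsystem == "S1")
                           & (result.table.direction == "A")]
        assert hit["enriched"].iloc[0]

    def test_missing_subsystem_rejected(self):
        diff = self._diff([True, False], ["A", "A"])
        with pytest.raises(ValidationError, match="without subsystem"):
            subsystem_enrichment(diff, {"R0": "S1"})


class TestCapacityReport:
    def _enrichment(self, pair, enriched_direction):
        from reactocap.metabolic_capacity import SubsystemEnrichmentResult

        table = pd.DataFrame(
            {
                "subsystem": ["S1", "S1"],
                "direction": [pair[0], pair[1]],
                "sig_in": [5, 0], "sig_out": [1, 0],
                "rest_in": [2, 7], "rest_out": [40, 41],
                "p_raw": [0.001, 1.0],
                "p_adj": [0.002, 1.0],
                "enriched": [enriched_direction == pair[0],
                             enriched_direction == pair[1]],
            }
        )
        return SubsystemEnrichmentResult(pair, table, 48)

    def test_single_cell(self):
        long, matrix = capacity_report([self._enrichment(("A", "B"), "A")])
        assert matrix.at["A vs B", "S1"] == 1
        assert long["enriched"].sum() == 1

    def test_pair_relabeling_flips_sign(self):
        _, m1 = capacity_report([self._enrichment(("A", "B"), "A")])
        _, m2 = capacity_report([self._enrichment(("B", "A"), "A")])
        assert m1.at["A vs B", "S1"] == -m2.at["B vs A", "S1"]

    def test_row_count_conservation(self):
        enr = [self._enrichment(("A", "B"), "A"), self._enrichment(("A", "C"), "C")]
        long, matrix = capacity_report(enr)
        assert len(long) == sum(len(e.table) for e in enr)
        assert (matrix.to_numpy() != 0).sum() == 2

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            capacity_report([])
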
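"""Feature encoding: seed-type vectors, binding-site composition, one-hot
categorical calls, and deterministic assembly with the missing-result-is-zero
convention."""

import io
import random

import numpy as np
import pytest

from mirmeta.features import (
    MIRANDA_CATEGORIES,
    SEED_TYPES,
    STARMIRDB_CATEGORIES,
    SUPPORTED_TOOLS,
    BindingSite,
    FeatureRegistry,
    ToolRecord,
    assemble_feature_vector,
    default_registry,
    encode_categorical_tool_output,
    encode_nucleotide_composition,
    encode_seed_types,
)


class TestSeedTypes:
    def test_nothing_observed(self):
        assert encode_seed_types(set()).tolist() == [0] * 7

    def test_one_hot(self):
        v = encode_seed_types({SEED_TYPES[0]})
        assert v.tolist() == [1, 0, 0, 0, 0, 0, 0]

    def test_full_set_and_length(self):
        v = encode_seed_types(set(SEED_TYPES))
        assert v.tolist() == [1] * 7
        assert len(v) == 7

    def test_unknown_name_lists_accepted(self):
        with pytest.raises(ValueError, match="8mer"):
            encode_seed_types({"9mer"})


class TestComposition:
    def test_uniform(self):
        c = encode_nucleotide_composition("AUGC", BindingSite(1, 4))
        assert (c.a, c.c, c.g, c.u) == (0.25, 0.25, 0.25, 0.25)
        assert c.au == 0.5

    def test_homopolymer(self):
        c = encode_nucleotide_composition("AAAA", BindingSite(1, 4))
        assert (c.a, c.c, c.g, c.u, c.au) == (1.0, 0.0, 0.0, 0.0, 1.0)

    def test_absent_site_is_all_zero(self):
        c = encode_nucleotide_composition("AUGC", None)
        assert c.as_array().tolist() == [0.0] * 5

    def test_dna_alphabet_mapped_to_rna(self):
        c = encode_nucleotide_composition("ACGT", BindingSite(1, 4))
        assert c.u == 0.25

    def test_bad_character_rejected(self):
        with pytest.raises(ValueError, match="non-ACGU"):
            encode_nucleotide_composition("ANGC", BindingSite(1, 4))

    def test_site_beyond_sequence_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            encode_nucleotide_composition("AUGC", BindingSite(2, 9))

    def test_fractions_sum_to_one_for_present_site(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGU"))
        for _ in range(50):
            seq = "".join(rng.choice(bases, size=30))
            s = int(rng.integers(1, 15))
            e = int(rng.integers(s, 30))
            c = encode_nucleotide_composition(seq, BindingSite(s, e))
            assert c.a + c.c + c.g + c.u == pytest.approx(1.0)

    def test_invalid_site(self):
        with pytest.raises(ValueError):
            BindingSite(5, 2)

    def test_zero_based_converter(self):
        assert BindingSite.from_zero_based_half_open(0, 4) == BindingSite(1, 4)


class TestCategorical:
    def test_miranda_one_hot(self):
        assert encode_categorical_tool_output("miRanda", "S_C").tolist() == [1, 0, 0, 0]

    def test_starmirdb_one_hot(self):
        v = encode_categorical_tool_output("STarMirDB", "3US")
        assert v.tolist()[STARMIRDB_CATEGORIES.index("3US")] == 1
        assert v.sum() == 1 and len(v) == 6

    def test_missing_record_is_zero(self):
        assert encode_categorical_tool_output("miRanda", None).sum() == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="accepted"):
            encode_categorical_tool_output("miRanda", "X_Y")

    def test_non_categorical_tool_rejected(self):
        with pytest.raises(ValueError):
            encode_categorical_tool_output("RNA22", "S_C")


@pytest.fixture()
def registry():
    return default_registry()


def _records():
    return [
        ToolRecord("m1", "g1", "TargetScan", {
            "context_score": -0.4, "pct": 0.8, "seed_types": "8mer,6mer",
            "site_start": 3, "site_end": 10,
        }),
        ToolRecord("m1", "g1", "miRanda", {
            "mirsvr_score": -1.2, "alignment_score": 155.0, "conservation": 1.0,
            "energy": -21.0, "category": "S_C", "site_start": 5, "site_end": 12,
        }),
    ]


class TestAssembly:
    def test_unsourced_tools_contribute_zero(self, registry):
        seq = "ACGU" * 10
        fv = assemble_feature_vector(("m1", "g1"), _records(), seq, registry)
        present = {"TargetScan", "miRanda", None}
        for name, value in zip(registry.names, fv.values):
            if registry.tool_of(name) not in present:
                assert value == 0.0, name
        # sourced dimensions are populated
        assert fv.values[registry.index("miRanda::energy")] == -21.0
        assert fv.values[registry.index("miRanda::cat_S_C")] == 1.0
        assert fv.values[registry.index("seed::8mer")] == 1.0
        assert fv.values[registry.index("TargetScan::site_start")] == pytest.approx(3 / 40)

    def test_no_records_gives_zero_vector(self, registry):
        fv = assemble_feature_vector(("m1", "g1"), [], "ACGU", registry)
        assert not fv.values.any()
        assert len(fv.values) == len(registry)

    def test_deterministic_and_order_invariant(self, registry):
        seq = "ACGU" * 10
        a = assemble_feature_vector(("m1", "g1"), _records(), seq, registry)
        b = assemble_feature_vector(("m1", "g1"), list(reversed(_records())), seq, registry)
        assert np.array_equal(a.values, b.values)

    def test_each_onehot_group_has_at_most_one_hit(self, registry, default_study):
        by_pair = {}
        for tr in default_study.tool_records:
            by_pair.setdefault((tr.mirna_id, tr.target_id), []).append(tr)
        groups = {}
        for f in registry:
            if f.group:
                groups.setdefault(f.group, []).append(registry.index(f.name))
        some_pairs = list(by_pair)[:25]
        for pair in some_pairs:
            fv = assemble_feature_vector(
                pair, by_pair[pair], default_study.target_seqs[pair[1]], registry
            )
            for group, idx in groups.items():
                if group == "seed":
                    continue  # seed types are indicators, not exclusive
                assert fv.values[idx].sum() <= 1.0, group

    def test_duplicate_tool_record_rejected_unless_aggregated(self, registry):
        recs = _records() + [_records()[0]]
        with pytest.raises(ValueError, match="duplicate"):
            assemble_feature_vector(("m1", "g1"), recs, "ACGU" * 10, registry)
        dup = ToolRecord("m1", "g1", "miRanda", {"energy": -30.0, "category": "0_0"})
        fv = assemble_feature_vector(
            ("m1", "g1"), _records() + [dup], "ACGU" * 10, registry,
            on_duplicate="most_stable",
        )
        # the more stable (-30) duplicate wins
        assert fv.values[registry.index("miRanda::energy")] == -30.0

    def test_mismatched_pair_rejected(self, registry):
        with pytest.raises(ValueError, match="does not match"):
            assemble_feature_vector(("m2", "g1"), _records(), None, registry)

    def test_unknown_tool_rejected(self):
        with pytest.raises(ValueError, match="supported tools"):
            ToolRecord("m1", "g1", "FooTool", {})


class TestRegistry:
    def test_yaml_round_trip(self, registry):
        buf = io.StringIO()
        registry.to_yaml(buf)
        buf.seek(0)
        again = FeatureRegistry.from_yaml(buf)
        assert again.names == registry.names
        assert [f.category for f in again] == [f.category for f in registry]

    def test_packaged_yaml_matches_code_default(self, registry):
        from importlib import resources

        with resources.files("mirmeta.data").joinpath("default_registry.yaml").open() as fh:
            shipped = FeatureRegistry.from_yaml(fh)
        assert shipped.names == registry.names

    def test_duplicate_names_rejected(self, registry):
        with pytest.raises(ValueError, match="duplicate"):
            FeatureRegistry(list(registry.features) + [registry.features[0]])

    def test_covers_all_six_categories_and_all_tools(self, registry):
        assert {f.category for f in registry} == {
            "energy", "scoring function", "evolution evidence",
            "binding type", "sequence property", "structure",
        }
        assert {f.tool for f in registry if f.tool} == set(SUPPORTED_TOOLS)
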
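"""Rule engine versus independent truth-table oracles."""

from __future__ import annotations

import itertools
from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redoxlag.guild_classifier import (
    CAPABILITIES,
    ClassifierConfig,
    classify_aerobic,
    classify_guilds,
    classify_nitrogen,
    classify_sulfur,
    guild_overlap,
    module_completeness,
)
from redoxlag.synthetic_data import default_oxidase_modules
from redoxlag.tables_io import ModuleDefinition, SchemaError

N_FEATURES = (
    "narG",
    "narH",
    "narI",
    "napA",
    "napB",
    "norB",
    "norC",
    "nirK",
    "nirS",
    "nosZ",
    "dsrA",
    "dsrB",
)


def oracle_nitrogen(genes: set[str]) -> dict[str, bool]:
    """Literal re-statement of the printed subunit thresholds."""
    return {
        "napAB": "napA" in genes and "napB" in genes,
        "narGHI": sum(g in genes for g in ("narG", "narH", "narI")) >= 2,
        "nrfAH": "nrfA" in genes and "nrfH" in genes,
        "nirBD": "nirB" in genes and "nirD" in genes,
        "nirKS": "nirK" in genes or "nirS" in genes,
        "norBC": "norB" in genes or "norC" in genes,
        "nosZ": "nosZ" in genes,
    }


class TestModuleCompleteness:
    def test_half_passes_threshold(self):
        mod = ModuleDefinition(
            "M", tuple(frozenset({f"s{i}"}) for i in range(4))
        )
        frac = module_completeness({"s0", "s1"}, mod)
        assert frac == Fraction(1, 2)
        assert frac >= ClassifierConfig().completeness_threshold

    def test_empty_gene_set_is_zero(self):
        mod = ModuleDefinition("M", (frozenset({"a"}),))
        assert module_completeness(set(), mod) == 0

    def test_alternatives_within_steps(self):
        mod = ModuleDefinition(
            "M", (frozenset({"a", "b"}), frozenset({"c"}), frozenset({"d"}))
        )
        assert module_completeness({"b", "d"}, mod) == Fraction(2, 3)

    def test_exhaustive_against_step_counting(self):
        """All subsets of a 6-gene universe versus direct step counting."""
        mod = ModuleDefinition(
            "M",
            (frozenset({"a", "b"}), frozenset({"c"}), frozenset({"d", "e"}), frozenset({"f"})),
        )
        universe = ["a", "b", "c", "d", "e", "f"]
        for r in range(len(universe) + 1):
            for combo in itertools.combinations(universe, r):
                genes = set(combo)
                expected = Fraction(
                    sum(1 for step in mod.steps if any(g in genes for g in step)), 4
                )
                assert module_completeness(genes, mod) == expected


class TestAerobic:
    def test_full_cytc_module(self):
        mods = default_oxidase_modules()
        tax = "d__B;p__P;c__G;o__W;f__Woeseiaceae;g__;s__"
        flags = classify_aerobic({"coxA", "coxB", "coxC"}, mods, tax)
        assert flags["has_cytc_oxidase"] and not flags["taxon_override_aerobic"]

    def test_taxon_override_without_oxidases(self):
        mods = default_oxidase_modules()
        tax = "d__A;p__T;c__N;o__N;f__Nitrosopumilaceae;g__;s__"
        flags = classify_aerobic({"amoA"}, mods, tax)
        assert not any(
            flags[k] for k in ("has_cytc_oxidase", "has_cbb3", "has_bd")
        )
        assert flags["taxon_override_aerobic"]

    def test_below_threshold_fails(self):
        mods = default_oxidase_modules()
        tax = "d__B;p__P;c__G;o__;f__;g__;s__"
        # 1 of 3 cbb3 steps = 33% < 50%
        flags = classify_aerobic({"ccoN"}, mods, tax)
        assert not flags["has_cbb3"]
        # 2 of 3 = 67% >= 50%
        assert classify_aerobic({"ccoN", "ccoO"}, mods, tax)["has_cbb3"]

    def test_missing_module_definition_errors(self):
        mods = default_oxidase_modules()
        del mods["bd"]
        with pytest.raises(SchemaError, match="bd"):
            classify_aerobic(set(), mods, "a;b;c;d;e;f;g")


@pytest.mark.parametrize(
    "genes, flag, expected",
    [
        ({"narG", "narH"}, "narGHI", True),
        ({"narG"}, "narGHI", False),
        ({"norB"}, "norBC", True),
        ({"nirK"}, "nirKS", True),
        ({"napA"}, "napAB", False),
        ({"napA", "napB"}, "napAB", True),
        (set(), "nosZ", False),
    ],
)
def test_nitrogen_flag_thresholds(genes, flag, expected):
    assert classify_nitrogen(genes)[flag] is expected


def test_all_nitrogen_flags_false_on_empty():
    flags = classify_nitrogen(set())
    assert not any(flags.values())


def test_full_denitrifier_requires_complete_chain():
    assert classify_nitrogen({"narG", "narH", "nirK", "norB", "nosZ"})["full_denitrifier"]
    assert not classify_nitrogen({"nirK", "norB", "nosZ"})["full_denitrifier"]


def test_sulfur_requires_both_subunits_by_default():
    assert classify_sulfur({"dsrA", "dsrB"})
    assert not classify_sulfur({"dsrA"})
    relaxed = ClassifierConfig(dsr_require_both=False)
    assert classify_sulfur({"dsrA"}, relaxed)


def test_rule_engine_equals_truth_table_oracle_exhaustively():
    """Every subset of the 12 anaerobic marker genes, engine vs oracle."""
    for r in range(len(N_FEATURES) + 1):
        for combo in itertools.combinations(N_FEATURES, r):
            genes = set(combo)
            engine = classify_nitrogen(genes)
            oracle = oracle_nitrogen(genes)
            for flag, val in oracle.items():
                assert engine[flag] is val, (genes, flag)
            assert classify_sulfur(genes) is ("dsrA" in genes and "dsrB" in genes)


_gene_universe = sorted(
    set(N_FEATURES)
    | {"nrfA", "nrfH", "nirB", "nirD", "coxA", "coxB", "coxC", "ccoN", "ccoO", "ccoP"}
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    base=st.sets(st.sampled_from(_gene_universe)),
    extra=st.sets(st.sampled_from(_gene_universe)),
)
def test_capabilities_monotone_in_gene_content(base, extra):
    """Adding genes never revokes a capability; fermenter status is antitone."""
    mods = default_oxidase_modules()
    tax = "d__B;p__P;c__G;o__;f__;g__;s__"

    def derived(genes):
        a = classify_aerobic(genes, mods, tax)
        n = classify_nitrogen(genes)
        aerobic = a["has_cytc_oxidase"] or a["has_cbb3"] or a["has_bd"]
        nitrogen = any(n[k] for k in ("napAB", "narGHI", "nrfAH", "nirBD", "nirKS", "norBC", "nosZ"))
        sulfur = classify_sulfur(genes)
        return {
            "aerobic": aerobic,
            "nitrogen": nitrogen,
            "sulfur_resp": sulfur,
            "fermenter": not (aerobic or nitrogen or sulfur),
        }

    lo, hi = derived(base), derived(base | extra)
    for cap in ("aerobic", "nitrogen", "sulfur_resp"):
        assert not (lo[cap] and not hi[cap])
    assert not (hi["fermenter"] and not lo["fermenter"])


class TestClassifyGuilds:
    def test_simulated_catalog_reproduces_ground_truth(self, noisy_dataset):
        d = noisy_dataset
        assignments = classify_guilds(
            d.catalog, d.gene_table, d.metal_flags, d.modules
        )
        merged = assignments.merge(
            d.truth.guild_flags, on="mag_id", suffixes=("", "_true")
        )
        assert len(merged) == len(d.catalog)
        for cap in (*CAPABILITIES, "fermenter"):
            assert (merged[cap] == merged[f"{cap}_true"]).all(), cap

    def test_dual_aerobe_nitrogen(self, noisy_dataset):
        d = noisy_dataset
        assignments = classify_guilds(d.catalog, d.gene_table, d.metal_flags, d.modules)
        dual = assignments[assignments["has_cytc_oxidase"] & assignments["narGHI"]]
        assert len(dual) > 0
        assert (dual["aerobic"] & dual["nitrogen"]).all()

    def test_mag_missing_from_gene_table_warns(self, small_catalog, caplog):
        genes = pd.DataFrame(
            {
                "mag_id": pd.array(["M1"], dtype="string"),
                "feature_id": pd.array(["coxA"], dtype="string"),
                "copies": pd.array([1], dtype="Int64"),
            }
        )
        metal = pd.DataFrame(
            {
                "mag_id": pd.array(["M1", "M2", "M3"], dtype="string"),
                "porin_cytochrome_homolog": pd.array([False] * 3, dtype="boolean"),
            }
        )
        import logging

        with caplog.at_level(logging.WARNING):
            out = classify_guilds(
                small_catalog, genes, metal, default_oxidase_modules()
            )
        assert "absent from the gene table" in caplog.text
        row3 = out.set_index("mag_id").loc["M3"]
        assert row3["fermenter"]
        # M2 is Nitrosopumilaceae: rescued by the override despite no genes
        assert out.set_index("mag_id").loc["M2", "aerobic"]


class TestGuildOverlap:
    def test_small_example(self):
        assignments = pd.DataFrame(
            [
                dict(mag_id="A", aerobic=True, nitrogen=False, sulfur_resp=False, metal_resp=False, fermenter=False),
                dict(mag_id="B", aerobic=True, nitrogen=True, sulfur_resp=False, metal_resp=False, fermenter=False),
                dict(mag_id="C", aerobic=False, nitrogen=False, sulfur_resp=False, metal_resp=False, fermenter=True),
            ]
        )
        counts = guild_overlap(assignments)
        assert counts["aerobic"] == 1
        assert counts["aerobic+nitrogen"] == 1
        assert counts["fermenter"] == 1
        assert sum(counts.values()) == 3

    def test_all_fermenters(self):
        assignments = pd.DataFrame(
            [
                dict(mag_id=f"F{i}", aerobic=False, nitrogen=False, sulfur_resp=False, metal_resp=False, fermenter=True)
                for i in range(4)
            ]
        )
        counts = guild_overlap(assignments)
        assert counts["fermenter"] == 4
        assert all(v == 0 for k, v in counts.items() if k != "fermenter")

    def test_random_tables_against_subset_counting(self, rng):
        """Region counts partition the catalog (brute-force oracle)."""
        for _ in range(25):
            n = int(rng.integers(1, 40))
            flags = rng.random((n, 4)) < 0.4
            assignments = pd.DataFrame(flags, columns=list(CAPABILITIES))
            assignments["fermenter"] = ~assignments[list(CAPABILITIES)].any(axis=1)
            assignments.insert(0, "mag_id", [f"M{i}" for i in range(n)])
            counts = guild_overlap(assignments)
            # oracle: count each exact signature independently
            sig_counts: dict[str, int] = {}
            for _, row in assignments.iterrows():
                if row["fermenter"]:
                    key = "fermenter"
                else:
                    key = "+".join(c for c in CAPABILITIES if row[c])
                sig_counts[key] = sig_counts.get(key, 0) + 1
            for key, val in sig_counts.items():
                assert counts[key] == val
            assert sum(counts.values()) == n
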
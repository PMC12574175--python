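"""Interaction tables, inverse-pair filtering, concordance, ORA."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from cernet.diffexp import DESets, Thresholds
from cernet.expression import FeatureMapping
from cernet.integrate import (
    IntegrationError,
    DirectionalPair,
    inverse_pair_filter,
    load_interaction_table,
    make_interaction_table,
    ora_enrichment,
    read_gmt,
    shared_direction_mirnas,
)
from cernet.reference import SHARED_MIRNA_PANEL, panel_concordance_inputs

T = Thresholds()


def sets(up=(), down=(), ns=()):
    return DESets(frozenset(up), frozenset(down), frozenset(ns), T)


class TestInteractionTable:
    def test_duplicates_collapsed(self, tmp_path):
        f = tmp_path / "it.tsv"
        f.write_text(
            "regulator\tregulator_class\ttarget\ttarget_class\tevidence\tsource\n"
            "hsa-miR-1\tmiRNA\tEGFR\tmRNA\tpredicted\tmirnet\n"
            "hsa-miR-1\tmiRNA\tEGFR\tmRNA\tpredicted\tmirnet\n"
            "hsa-miR-1\tmiRNA\tBTG2\tmRNA\tcurated\tencori\n"
        )
        assert len(load_interaction_table(f)) == 2

    def test_sponge_row_accepted(self):
        t = make_interaction_table(
            [("OIP5-AS1", "lncRNA", "hsa-miR-92a-3p", "miRNA", "clip", "encori")]
        )
        assert t.iloc[0]["regulator_class"] == "lncRNA"

    def test_illegal_class_pair_rejected_with_row(self):
        with pytest.raises(IntegrationError, match="row 0"):
            make_interaction_table([("EGFR", "mRNA", "hsa-miR-1", "miRNA", "predicted", "mirnet")])

    def test_missing_column_rejected(self, tmp_path):
        f = tmp_path / "it.tsv"
        f.write_text("regulator\ttarget\nx\ty\n")
        with pytest.raises(IntegrationError, match="missing columns"):
            load_interaction_table(f)

    def test_unknown_evidence_rejected(self):
        with pytest.raises(IntegrationError, match="evidence"):
            make_interaction_table([("m", "miRNA", "g", "mRNA", "guessed", "mirnet")])


TABLE = make_interaction_table(
    [
        ("mir-a", "miRNA", "G1", "mRNA", "predicted", "mirnet"),
        ("mir-a", "miRNA", "G1", "mRNA", "curated", "encori"),
        ("mir-a", "miRNA", "G2", "mRNA", "predicted", "mirnet"),
        ("mir-b", "miRNA", "G3", "mRNA", "clip", "encori"),
        ("mir-c", "miRNA", "G4", "mRNA", "predicted", "mirnet"),
    ]
)


class TestInversePairFilter:
    def test_directional_rules(self):
        mir = sets(up=["mir-b"], down=["mir-a"], ns=["mir-c"])
        mrna = sets(up=["G1", "G4"], down=["G3"], ns=["G2"])
        down_up = inverse_pair_filter(mir, mrna, TABLE, "mir_down_mrna_up")
        # mir-a/G1: down+up+evidence -> kept; mir-a/G2: mRNA ns -> dropped;
        # mir-c/G4: miRNA ns -> dropped
        assert [(p.mirna, p.mrna) for p in down_up] == [("mir-a", "G1")]
        # evidence sources unioned across mirnet/encori rows
        assert down_up[0].evidence == ("encori:curated", "mirnet:predicted")

    def test_pair_absent_from_table_dropped(self):
        mir = sets(down=["mir-z"])
        mrna = sets(up=["G1"])
        assert inverse_pair_filter(mir, mrna, TABLE) == []

    def test_both_mode_is_disjoint_union_of_one_sided_modes(self):
        mir = sets(up=["mir-b"], down=["mir-a"])
        mrna = sets(up=["G1"], down=["G3"])
        one = inverse_pair_filter(mir, mrna, TABLE, "mir_down_mrna_up")
        two = inverse_pair_filter(mir, mrna, TABLE, "mir_up_mrna_down")
        both = inverse_pair_filter(mir, mrna, TABLE, "both")
        assert set(both) == set(one) | set(two)
        assert not set(one) & set(two)

    def test_same_direction_pair_never_constructible(self):
        with pytest.raises(IntegrationError):
            DirectionalPair("m", "g", "down", "down", ())


class TestSharedDirectionMirnas:
    def test_published_panel_reconstruction(self):
        det_a, sets_a, det_b, sets_b, mapping = panel_concordance_inputs()
        table = shared_direction_mirnas(det_a, sets_a, det_b, sets_b, mapping)
        assert len(table) == 14
        assert (table["direction"] == "up").sum() == 8
        assert (table["direction"] == "down").sum() == 6
        # sorted ascending by the first context's log2FC
        assert table["log2fc_context1"].is_monotonic_increasing
        assert table.iloc[0]["mirna"] == "hsa-miR-92a-3p"

    def test_opposite_sign_and_unmatched_excluded(self):
        det = pd.DataFrame({"log2fc": [2.0, -1.5]}, index=["m1", "m2"])
        det_b = pd.DataFrame({"log2fc": [-2.0, 1.0]}, index=["m1", "m3"])
        mapping = FeatureMapping([("m1", "m1")], ["m2"], ["m3"])
        table = shared_direction_mirnas(
            det, sets(up=["m1"], down=["m2"]), det_b, sets(down=["m1"], up=["m3"]), mapping
        )
        assert len(table) == 0

    def test_symmetric_in_contexts_up_to_column_swap(self):
        det_a, sets_a, det_b, sets_b, mapping = panel_concordance_inputs()
        fwd = shared_direction_mirnas(det_a, sets_a, det_b, sets_b, mapping)
        swapped = FeatureMapping([(b, a) for a, b in mapping.pairs], [], [])
        rev = shared_direction_mirnas(det_b, sets_b, det_a, sets_a, swapped)
        merged = fwd.merge(rev, on="mirna", suffixes=("_f", "_r"))
        assert len(merged) == len(fwd)
        np.testing.assert_allclose(merged["log2fc_context1_f"], merged["log2fc_context2_r"])

    def test_requires_significance_in_both_contexts(self):
        det_a, sets_a, det_b, sets_b, mapping = panel_concordance_inputs()
        weaker = DESets(sets_b.up - {"hsa-miR-584-5p"}, sets_b.down, sets_b.ns, T)
        table = shared_direction_mirnas(det_a, sets_a, det_b, weaker, mapping)
        assert len(table) == 13
        assert "hsa-miR-584-5p" not in set(table["mirna"])


def hypergeom_tail_brute(k, n_universe, n_set, n_query):
    """Exact enumeration of P[X >= k] over all overlap values."""
    total = comb(n_universe, n_query)
    num = sum(
        comb(n_set, j) * comb(n_universe - n_set, n_query - j)
        for j in range(k, min(n_set, n_query) + 1)
        if n_query - j <= n_universe - n_set
    )
    return num / total


class TestORA:
    def test_exact_enumeration_example(self):
        universe = {f"g{i}" for i in range(20)}
        gs = {"S": {f"g{i}" for i in range(5)}}
        query = {"g0", "g1", "g2", "g10", "g11"}
        res = ora_enrichment(query, gs, universe)
        assert res.iloc[0]["p"] == pytest.approx(1126 / 15504, rel=1e-12)

    def test_zero_overlap_is_certain(self):
        universe = {f"g{i}" for i in range(10)}
        res = ora_enrichment({"g0"}, {"S": {"g5", "g6"}}, universe)
        assert res.iloc[0]["p"] == 1.0

    def test_query_equal_set_equal_universe_is_certain(self):
        u = {"a", "b", "c"}
        res = ora_enrichment(u, {"S": set(u)}, u)
        assert res.iloc[0]["p"] == 1.0

    def test_matches_brute_force_for_small_universes(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            n_u = int(rng.integers(5, 26))
            universe = {f"g{i}" for i in range(n_u)}
            n_set = int(rng.integers(1, n_u + 1))
            n_query = int(rng.integers(1, n_u + 1))
            members = set(rng.choice(sorted(universe), n_set, replace=False))
            query = set(rng.choice(sorted(universe), n_query, replace=False))
            res = ora_enrichment(query, {"S": members}, universe)
            k = len(query & members)
            assert res.iloc[0]["p"] == pytest.approx(
                hypergeom_tail_brute(k, n_u, n_set, n_query), rel=1e-10
            )

    def test_empty_universe_rejected(self):
        with pytest.raises(IntegrationError, match="universe"):
            ora_enrichment(set(), {}, set())


def test_read_gmt(tmp_path):
    f = tmp_path / "sets.gmt"
    f.write_text("SET_A\tdesc\tg1\tg2\tg3\nSET_B\t\tg2\n\n")
    gs = read_gmt(f)
    assert gs == {"SET_A": {"g1", "g2", "g3"}, "SET_B": {"g2"}}


def test_panel_extremes_match_printed_values():
    tumor = [r[2] for r in SHARED_MIRNA_PANEL]
    assert min(tumor) == -4.58 and max(tumor) == 4.82
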
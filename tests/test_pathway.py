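"""Pathway over-representation, topology impact and FDR."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cortidyn.pathway import (
    InsufficientDEMsError,
    Pathway,
    PathwayLibrary,
    bh_fdr,
    impact_score,
    load_default_library,
    load_library,
    map_to_library,
    ora_pvalue,
    run_pathway_analysis,
)


def ora_enumeration_oracle(n_universe, pathway_members, n_dems, n_hits):
    """Exhaustive: fraction of DEM subsets with at least n_hits pathway members."""
    universe = list(range(n_universe))
    members = set(universe[:pathway_members])
    count = total = 0
    for subset in itertools.combinations(universe, n_dems):
        total += 1
        if len(members & set(subset)) >= n_hits:
            count += 1
    return count / total


def betweenness_oracle(g):
    """Shortest-path enumeration betweenness (normalized), independent of Brandes."""
    nodes = list(g.nodes)
    n = len(nodes)
    raw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            raw[v] += through / len(paths)
    scale = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
    return {v: raw[v] / scale for v in nodes}


class TestOraPvalue:
    def test_zero_hits_is_certain(self):
        assert ora_pvalue(100, 10, 5, 0) == 1.0

    def test_exact_binomial_coefficient_example(self):
        # universe 20, pathway 5, DEMs 5, hits >= 3: 1126/15504
        assert ora_pvalue(20, 5, 5, 3) == pytest.approx(1126 / 15504, rel=1e-12)
        assert 1126 == (
            math.comb(5, 3) * math.comb(15, 2)
            + math.comb(5, 4) * math.comb(15, 1)
            + math.comb(5, 5)
        )

    @pytest.mark.parametrize(
        "n_universe,n_pathway,n_dems,n_hits",
        [(10, 3, 4, 2), (12, 5, 6, 3), (12, 4, 4, 4), (8, 2, 5, 1), (12, 6, 3, 0)],
    )
    def test_matches_exhaustive_enumeration(self, n_universe, n_pathway, n_dems, n_hits):
        oracle = ora_enumeration_oracle(n_universe, n_pathway, n_dems, n_hits)
        assert ora_pvalue(n_universe, n_pathway, n_dems, n_hits) == pytest.approx(oracle, rel=1e-10)

    def test_monotone_decreasing_in_hits(self):
        ps = [ora_pvalue(50, 10, 8, k) for k in range(9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            ora_pvalue(10, 12, 3, 1)
        with pytest.raises(ValueError):
            ora_pvalue(10, 4, 3, 5)


class TestImpactScore:
    def test_path_graph_cut_vertex_carries_all_impact(self):
        pw = Pathway("p", "path", frozenset("ABC"), (("A", "B"), ("B", "C")))
        assert impact_score(pw, {"B"}) == 1.0
        assert impact_score(pw, {"A"}) == 0.0

    def test_empty_dems_give_zero(self):
        pw = Pathway("p", "path", frozenset("ABC"), (("A", "B"), ("B", "C")))
        assert impact_score(pw, set()) == 0.0

    def test_star_center_versus_leaf(self):
        pw = Pathway("s", "star", frozenset("CXYZ"), (("C", "X"), ("C", "Y"), ("C", "Z")))
        assert impact_score(pw, {"X"}) == 0.0
        assert impact_score(pw, {"C"}) == 1.0

    def test_edgeless_pathway_has_zero_impact(self):
        pw = Pathway("e", "edgeless", frozenset("ABCD"), ())
        assert impact_score(pw, {"A", "B"}) == 0.0

    def test_matches_shortest_path_enumeration_oracle(self, rng):
        for trial in range(10):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1_000_000)))
            g = nx.relabel_nodes(g, {i: f"M{i}" for i in g.nodes})
            pw = Pathway("r", "random", frozenset(g.nodes), tuple(g.edges))
            oracle = betweenness_oracle(g)
            dems = set(list(g.nodes)[: n // 2])
            denom = sum(oracle.values())
            expected = sum(oracle[v] for v in dems) / denom if denom else 0.0
            assert impact_score(pw, dems) == pytest.approx(expected, abs=1e-9)

    def test_non_member_dem_rejected(self):
        pw = Pathway("p", "path", frozenset("AB"), (("A", "B"),))
        with pytest.raises(ValueError):
            impact_score(pw, {"Z"})


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.037]), [0.037])

    def test_step_up_hand_computations(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        np.testing.assert_allclose(bh_fdr([0.005, 0.04]), [0.01, 0.04])

    def test_q_at_least_p_and_permutation_consistent(self, rng):
        p = rng.uniform(size=30)
        q = bh_fdr(p)
        assert np.all(q >= p) and np.all(q <= 1.0)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def toy_library():
    return PathwayLibrary(
        {
            "T1": Pathway("T1", "hit pathway", frozenset({"A", "B", "C"}),
                          (("A", "B"), ("B", "C"))),
            "T2": Pathway("T2", "other", frozenset({"D", "E", "F", "G"}),
                          (("D", "E"), ("E", "F"), ("F", "G"))),
        }
    )


def classified_frame(rows):
    return pd.DataFrame(rows, columns=["feature_id", "platform", "class", "matrix",
                                       "id_level", "hmdb_id"])


class TestMapAndRun:
    def test_unmapped_and_low_confidence_features_excluded(self):
        lib = toy_library()
        rows = [
            ("f1", "GCMS_serum", "unique_AUC", "serum", 1, "A"),
            ("f2", "GCMS_serum", "unique_AUC", "serum", 1, None),  # no database id
            ("f3", "GCMS_serum", "unique_AUC", "serum", 2, "B"),  # not level 1
            ("f4", "GCMS_serum", "unique_AUC", "serum", 1, "ZZZ"),  # not in universe
        ]
        assert map_to_library(classified_frame(rows), lib, "unique_AUC") == {"A"}

    def test_shared_id_collapses_to_one_dem(self):
        lib = toy_library()
        rows = [
            ("f1", "GCMS_serum", "unique_AUC", "serum", 1, "A"),
            ("f2", "LCMS_targeted_serum", "unique_AUC", "serum", 1, "A"),
        ]
        assert map_to_library(classified_frame(rows), lib, "unique_AUC") == {"A"}

    def test_mapping_matches_brute_force_set_oracle(self):
        lib = load_default_library()
        rng = np.random.default_rng(8)
        universe = sorted(lib.universe)
        rows = []
        for i in range(60):
            rows.append(
                (f"f{i}", "GCMS_serum", rng.choice(["unique_AUC", "none"]), "serum",
                 int(rng.choice([1, 2])), rng.choice(universe + [None] * 10))
            )
        df = classified_frame(rows)
        oracle = {
            r[5]
            for r in rows
            if r[2] == "unique_AUC" and r[4] == 1 and r[5] is not None and r[5] in set(universe)
        }
        assert map_to_library(df, lib, "unique_AUC") == oracle

    def test_fewer_than_three_dems_refused_with_message(self):
        lib = toy_library()
        rows = [
            ("f1", "p", "unique_AUC", "serum", 1, "A"),
            ("f2", "p", "unique_AUC", "serum", 1, "B"),
        ]
        with pytest.raises(InsufficientDEMsError, match="three or more"):
            run_pathway_analysis(classified_frame(rows), lib, "unique_AUC")

    def test_pathway_containing_all_dems_ranks_first(self):
        lib = toy_library()
        rows = [("f1", "p", "unique_AUC", "serum", 1, m) for m in ("A", "B", "C")]
        res = run_pathway_analysis(classified_frame(rows), lib, "unique_AUC")
        assert res.iloc[0]["pathway_id"] == "T1"
        assert res.iloc[0]["n_hits"] == 3
        assert bool(res.iloc[0]["significant"])
        assert (res["q_fdr"] >= res["p_raw"] - 1e-15).all()
        assert res["significant"].equals((res["p_raw"] < 0.05) & (res["impact"] > 0))

    def test_detected_universe_mode_restricts_reference_set(self):
        lib = toy_library()
        rows = [("f1", "p", "unique_AUC", "serum", 1, m) for m in ("A", "B", "C")] + [
            ("f4", "p", "none", "serum", 1, "D")
        ]
        res_lib = run_pathway_analysis(classified_frame(rows), lib, "unique_AUC")
        res_det = run_pathway_analysis(
            classified_frame(rows), lib, "unique_AUC", universe="detected"
        )
        # only D of T2's four members was detected and mapped
        n_lib = res_lib.set_index("pathway_id").loc["T2", "n_members"]
        n_det = res_det.set_index("pathway_id").loc["T2", "n_members"]
        assert n_lib == 4 and n_det == 1


class TestLibraryLoading:
    def test_packaged_synthetic_library_shape(self):
        lib = load_default_library()
        assert len(lib) == 12
        assert len(lib.universe) > 80
        for pw in lib.pathways.values():
            for a, b in pw.edges:
                assert a in pw.members and b in pw.members

    def test_gmt_sif_round_trip(self, tmp_path):
        gmt = tmp_path / "lib.gmt"
        sif = tmp_path / "lib.sif"
        gmt.write_text("P1\tone\tA\tB\tC\nP2\ttwo\tD\tE\n")
        sif.write_text("pathway_id\tnode_a\tnode_b\nP1\tA\tB\nP1\tB\tC\n")
        lib = load_library(gmt, sif)
        assert lib.pathways["P1"].members == {"A", "B", "C"}
        assert lib.pathways["P2"].edges == ()
        assert lib.universe == {"A", "B", "C", "D", "E"}

    def test_edge_to_non_member_rejected(self, tmp_path):
        gmt = tmp_path / "lib.gmt"
        sif = tmp_path / "lib.sif"
        gmt.write_text("P1\tone\tA\tB\n")
        sif.write_text("pathway_id\tnode_a\tnode_b\nP1\tA\tQ\n")
        with pytest.raises(ValueError):
            load_library(gmt, sif)
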
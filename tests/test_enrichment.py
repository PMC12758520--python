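"""Tests for ORA, multiple-testing corrections, ESS, set cover, and GSEA."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sdegkit as sk
from sdegkit.enrich import _es_walk, _signed_es


# ---------------------------------------------------------------------------
# overrepresentation analysis
# ---------------------------------------------------------------------------

def exhaustive_ora_p(N, K, n, k):
    """P(overlap >= k) by enumerating every C(N, n) query draw."""
    favorable = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if sum(1 for g in draw if g < K) >= k
    )
    return favorable / comb(N, n)


class TestOra:
    def test_worked_fraction(self):
        bg = [f"g{i}" for i in range(20)]
        coll = sk.GeneSetCollection(sets={"s": bg[:5]})
        report = sk.ora(bg[:3] + bg[5:7], coll, bg)
        row = report.iloc[0]
        assert (row["k"], row["K"], row["n"], row["N"]) == (3, 5, 5, 20)
        assert row["fold_enrichment"] == pytest.approx(2.4)
        assert row["pvalue"] == pytest.approx(1126 / 15504)

    def test_query_equals_background_is_degenerate(self, toy_collection):
        bg = [f"g{i}" for i in range(20)]
        report = sk.ora(bg, toy_collection, bg)
        assert (report["fold_enrichment"] == 1.0).all()
        assert (report["pvalue"] == 1.0).all()

    def test_zero_overlap(self):
        bg = [f"g{i}" for i in range(20)]
        coll = sk.GeneSetCollection(sets={"s": bg[:5]})
        report = sk.ora(bg[10:15], coll, bg)
        assert report["k"].iloc[0] == 0
        assert report["fold_enrichment"].iloc[0] == 0.0
        assert report["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_universes(self, rng):
        for _ in range(25):
            N = int(rng.integers(4, 13))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            bg = [f"g{i}" for i in range(N)]
            coll = sk.GeneSetCollection(sets={"s": bg[:K]})
            query = list(rng.choice(bg, size=n, replace=False))
            report = sk.ora(query, coll, bg)
            k = int(report["k"].iloc[0])
            assert report["pvalue"].iloc[0] == pytest.approx(
                exhaustive_ora_p(N, K, n, k), abs=1e-12
            )

    def test_fisher_equals_hypergeometric(self, rng):
        bg = [f"g{i}" for i in range(60)]
        coll = sk.GeneSetCollection(
            sets={f"s{j}": list(rng.choice(bg, 15, replace=False)) for j in range(8)}
        )
        query = list(rng.choice(bg, 20, replace=False))
        hyper = sk.ora(query, coll, bg, test="hypergeometric")
        fisher = sk.ora(query, coll, bg, test="fisher")
        np.testing.assert_allclose(
            hyper["pvalue"].to_numpy(), fisher["pvalue"].to_numpy(), atol=1e-12
        )

    def test_out_of_background_genes_dropped(self, toy_collection):
        bg = [f"g{i}" for i in range(20)]
        report_a = sk.ora(bg[:5], toy_collection, bg)
        report_b = sk.ora(bg[:5] + ["alien1", "alien2"], toy_collection, bg)
        pd.testing.assert_frame_equal(report_a, report_b)

    def test_empty_inputs_rejected(self, toy_collection):
        bg = [f"g{i}" for i in range(20)]
        with pytest.raises(sk.InputError):
            sk.ora(["alien"], toy_collection, bg)
        with pytest.raises(sk.InputError):
            sk.ora(bg[:3], toy_collection, [])


# ---------------------------------------------------------------------------
# corrections and ESS
# ---------------------------------------------------------------------------

class TestAdjustments:
    def test_bh_step_up_hand_example(self):
        np.testing.assert_allclose(
            sk.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert sk.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_bh_never_decreases_and_bonferroni_dominates(self, rng):
        p = rng.uniform(size=40)
        bh = sk.bh_adjust(p)
        bonf = sk.bonferroni_adjust(p)
        assert (bh >= p - 1e-15).all()
        assert (bonf >= bh - 1e-15).all()

    def test_monotone_in_ranks(self, rng):
        p = rng.uniform(size=25)
        order = np.argsort(p)
        adjusted = sk.bh_adjust(p)
        assert (np.diff(adjusted[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(sk.InputError):
            sk.bh_adjust([0.5, 1.2])


class TestEss:
    @pytest.mark.parametrize(
        "fold, fdr, expected",
        [(2.0, 1e-3, 6.0), (5.0, 1.0, 0.0), (2.4, 1126 / 15504, 2.733)],
    )
    def test_values(self, fold, fdr, expected):
        assert sk.ess_score(fold, fdr) == pytest.approx(expected, abs=0.005)

    def test_monotonicity(self):
        assert sk.ess_score(3.0, 0.01) > sk.ess_score(2.0, 0.01)
        assert sk.ess_score(2.0, 0.001) > sk.ess_score(2.0, 0.01)

    def test_zero_fdr_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            value = sk.ess_score(2.0, 0.0)
        assert np.isfinite(value)


# ---------------------------------------------------------------------------
# weighted set cover
# ---------------------------------------------------------------------------

def _report(rows):
    """Build a minimal ORA-shaped frame for set-cover tests."""
    frame = pd.DataFrame(rows, columns=["set_name", "fdr", "overlap_genes"])
    frame["pvalue"] = frame["fdr"]
    return frame


def exhaustive_min_cover(candidates, universe):
    names = list(candidates)
    for size in range(1, len(names) + 1):
        for combo in itertools.combinations(names, size):
            if set().union(*(candidates[c] for c in combo)) >= universe:
                return size
    return len(names)


class TestWeightedSetCover:
    def test_identical_overlaps_pick_one(self):
        report = _report(
            [("a", 0.01, ["g1", "g2"]), ("b", 0.02, ["g1", "g2"])]
        )
        out = sk.weighted_set_cover(report)
        assert list(out.selected["set_name"]) == ["a"]
        assert out.coverage_fraction == 1.0

    def test_disjoint_sets_both_selected_in_order(self):
        report = _report(
            [("weak", 0.04, ["g1"]), ("strong", 1e-6, ["g2"])]
        )
        out = sk.weighted_set_cover(report)
        assert list(out.selected["set_name"]) == ["strong", "weak"]

    def test_tie_breaks_by_fdr_then_name(self):
        report = _report(
            [("zeta", 0.01, ["g1"]), ("alpha", 0.01, ["g2"]), ("mid", 0.001, ["g3"])]
        )
        out = sk.weighted_set_cover(report)
        assert list(out.selected["set_name"]) == ["mid", "alpha", "zeta"]

    def test_no_candidates_is_empty_report(self):
        report = _report([("a", 0.5, ["g1"])])
        out = sk.weighted_set_cover(report, fdr_cutoff=0.05)
        assert out.selected.empty and out.covered_genes == set()

    def test_top_k_truncates(self):
        report = _report([(f"s{i}", 0.01, [f"g{i}"]) for i in range(5)])
        out = sk.weighted_set_cover(report, top_k=2)
        assert len(out.selected) == 2
        assert out.coverage_fraction == pytest.approx(2 / 5)

    def test_greedy_close_to_exhaustive_minimum(self, rng):
        genes = [f"g{i}" for i in range(15)]
        for _ in range(10):
            candidates = {
                f"s{j}": set(rng.choice(genes, size=int(rng.integers(3, 9)), replace=False))
                for j in range(6)
            }
            universe = set().union(*candidates.values())
            report = _report(
                [(name, float(rng.uniform(1e-6, 0.04)), sorted(members))
                 for name, members in candidates.items()]
            )
            out = sk.weighted_set_cover(report)
            assert out.covered_genes == universe
            assert len(out.selected) <= exhaustive_min_cover(candidates, universe) + 1


# ---------------------------------------------------------------------------
# pre-ranked GSEA
# ---------------------------------------------------------------------------

def _ranked(stats_):
    return pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(len(stats_))], "stat": stats_}
    )


class TestPrerankedGsea:
    def test_single_hit_at_top_scores_one(self):
        ranked = _ranked([3.0, 2.0, 1.0, -1.0, -2.0])
        coll = sk.GeneSetCollection(sets={"top": ["g0"]})
        out = sk.preranked_gsea(ranked, coll, min_size=1, n_perm=50, seed=1)
        assert out["es"].iloc[0] == pytest.approx(1.0)
        assert out["leading_edge"].iloc[0] == ["g0"]

    def test_reversing_ranking_negates_es(self, rng):
        stats_ = np.sort(rng.normal(size=40))[::-1]
        ranked = _ranked(stats_)
        members = [f"g{i}" for i in rng.choice(40, size=8, replace=False)]
        coll = sk.GeneSetCollection(sets={"s": members})
        fwd = sk.preranked_gsea(ranked, coll, n_perm=20, seed=0)
        rev = sk.preranked_gsea(
            ranked.iloc[::-1].reset_index(drop=True), coll, n_perm=20, seed=0
        )
        assert rev["es"].iloc[0] == pytest.approx(-fwd["es"].iloc[0])

    def test_unweighted_walk_is_balanced_and_bounded(self, rng):
        # weight 0: the running sum ends at 0; |ES| <= 1 always
        for _ in range(20):
            n = int(rng.integers(10, 60))
            m = int(rng.integers(2, n - 1))
            pos = np.sort(rng.choice(n, size=m, replace=False))
            weights = np.ones(m)
            max_dev, min_dev, _ = _es_walk(pos, weights, n)
            es = float(_signed_es(max_dev, min_dev))
            # deviation after the last list position: the balanced KS walk
            # climbs 1 in hit steps and falls 1 in miss steps
            end = (1.0 - (pos[-1] - (m - 1)) / (n - m)) - (n - 1 - pos[-1]) / (n - m)
            assert end == pytest.approx(0.0, abs=1e-12)
            assert abs(es) <= 1.0 + 1e-12

    def test_es_bounded_with_weights(self, rng):
        stats_ = np.sort(rng.normal(size=100))[::-1]
        ranked = _ranked(stats_)
        sets = {
            f"s{j}": [f"g{i}" for i in rng.choice(100, size=10, replace=False)]
            for j in range(5)
        }
        out = sk.preranked_gsea(ranked, sk.GeneSetCollection(sets=sets), n_perm=20, seed=3)
        assert (out["es"].abs() <= 1.0 + 1e-12).all()
        assert (np.sign(out["nes"]) == np.sign(out["es"])).all()

    def test_single_set_fdr_equals_pvalue(self, rng):
        stats_ = np.sort(rng.normal(size=50))[::-1]
        ranked = _ranked(stats_)
        members = [f"g{i}" for i in rng.choice(50, size=10, replace=False)]
        out = sk.preranked_gsea(
            ranked, sk.GeneSetCollection(sets={"only": members}), n_perm=200, seed=7
        )
        assert out["fdr"].iloc[0] == pytest.approx(out["pvalue"].iloc[0])

    def test_leading_edge_subset_of_members(self, rng):
        stats_ = np.sort(rng.normal(size=80))[::-1]
        ranked = _ranked(stats_)
        members = [f"g{i}" for i in rng.choice(80, size=12, replace=False)]
        out = sk.preranked_gsea(
            ranked, sk.GeneSetCollection(sets={"s": members}), n_perm=20, seed=5
        )
        assert set(out["leading_edge"].iloc[0]) <= set(members)

    def test_duplicate_gene_ids_rejected(self):
        ranked = pd.DataFrame({"gene_id": ["a", "a", "b"], "stat": [3.0, 2.0, 1.0]})
        with pytest.raises(sk.InputError):
            sk.preranked_gsea(ranked, sk.GeneSetCollection(sets={"s": ["a"]}), min_size=1)

    def test_small_sets_skipped(self):
        ranked = _ranked([3.0, 2.0, 1.0, -1.0, -2.0])
        coll = sk.GeneSetCollection(sets={"tiny": ["g0"], "absent": ["zz"]})
        out = sk.preranked_gsea(ranked, coll, min_size=2, n_perm=10, seed=0)
        assert out.empty

    def test_matches_gseapy_enrichment_scores(self, rng):
        gseapy = pytest.importorskip("gseapy")
        n = 300
        stats_ = np.sort(rng.normal(size=n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        ranked = pd.DataFrame({"gene_id": genes, "stat": stats_})
        sets = {
            f"S{j}": [genes[i] for i in rng.choice(n, size=25, replace=False)]
            for j in range(6)
        }
        mine = sk.preranked_gsea(
            ranked, sk.GeneSetCollection(sets=sets), n_perm=20, seed=0
        ).set_index("set_name")
        ref = gseapy.prerank(
            rnk=pd.Series(stats_, index=genes), gene_sets=sets,
            permutation_num=20, min_size=1, max_size=1000, seed=0,
            outdir=None, no_plot=True, threads=1,
        ).res2d.set_index("Term")
        for name in sets:
            assert float(mine.loc[name, "es"]) == pytest.approx(
                float(ref.loc[name, "ES"]), abs=1e-9
            )

    def test_random_set_nes_calibrated_near_unit(self):
        """Random sets: mean |NES| ~ 1 and permutation p-values ~ uniform."""
        from scipy import stats as spstats

        rng = np.random.default_rng(0)
        n = 400
        stats_ = np.sort(rng.normal(size=n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        ranked = pd.DataFrame({"gene_id": genes, "stat": stats_})
        nes_values, p_values = [], []
        for seed in range(60):
            srng = np.random.default_rng([seed, 1])
            members = [genes[i] for i in srng.choice(n, size=20, replace=False)]
            out = sk.preranked_gsea(
                ranked, sk.GeneSetCollection(sets={"s": members}),
                n_perm=200, seed=seed,
            )
            nes_values.append(out["nes"].iloc[0])
            p_values.append(out["pvalue"].iloc[0])
        assert np.mean(np.abs(nes_values)) == pytest.approx(1.0, abs=0.15)
        assert spstats.kstest(p_values, "uniform").pvalue > 0.01
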
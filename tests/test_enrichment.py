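"""Coverage statistic, resampling nulls, FDR and hypergeometric tests."""

from itertools import combinations

import numpy as np
import pytest

from intramir.classification import MirnaPlacement
from intramir.enrichment import (
    build_pathway_target_sets,
    coverage_analysis,
    coverage_pvalue,
    fdr_qvalues,
    hypergeom_enrichment,
    read_gmt,
    self_target_pvalue,
    self_target_set,
    target_coverage,
    write_gmt,
)
from intramir.target_integration import AgreementMatrix


def matrix_from_counts(counts, n_sources=7):
    return AgreementMatrix(counts=dict(counts), n_sources=n_sources)


def intronic(mid, host):
    return MirnaPlacement(mid, "intronic", host, 1, True)


class TestTargetCoverage:
    def test_fraction(self):
        s_p = {f"g{i}" for i in range(10)}
        s_t = {"g0", "g1", "g2", "g3", "x"}
        assert target_coverage(s_p, s_t) == pytest.approx(0.4)

    def test_disjoint_zero(self):
        assert target_coverage({"a"}, {"b"}) == 0.0

    def test_subset_one(self):
        assert target_coverage({"a", "b"}, {"a", "b", "c"}) == 1.0

    def test_empty_pathway_raises(self):
        with pytest.raises(ValueError):
            target_coverage(set(), {"a"})


def exact_coverage_p(c_obs, s_t, universe, size):
    """Oracle: exhaustive enumeration over all size-subsets of the universe."""
    universe = sorted(universe)
    hits = total = 0
    for subset in combinations(universe, size):
        total += 1
        c = len(set(subset) & s_t) / size
        if c >= c_obs - 1e-12:
            hits += 1
    return hits / total


class TestCoveragePvalue:
    def test_exact_enumeration_six_gene_universe(self):
        universe = {f"g{i}" for i in range(6)}
        s_t = {"g1", "g2"}
        # 15 subsets of size 2; 9 contain at least one of {g1, g2}
        assert exact_coverage_p(0.5, s_t, universe, 2) == pytest.approx(0.6)
        ps = [
            coverage_pvalue(0.5, s_t, universe, 2, n_iter=1000, seed=s).p
            for s in range(10)
        ]
        se = np.sqrt(0.6 * 0.4 / 1000)
        assert all(abs(p - 0.6) <= 3 * se for p in ps)

    def test_zero_coverage_p_one(self):
        universe = {f"g{i}" for i in range(8)}
        res = coverage_pvalue(0.0, {"g0"}, universe, 3, n_iter=200, seed=0)
        assert res.p == 1.0

    def test_full_coverage_with_st_equal_universe(self):
        universe = {f"g{i}" for i in range(8)}
        res = coverage_pvalue(1.0, set(universe), universe, 3, n_iter=200, seed=0)
        assert res.p == 1.0

    def test_size_exceeding_universe_raises(self):
        with pytest.raises(ValueError):
            coverage_pvalue(0.5, {"a"}, {"a", "b"}, 3, seed=0)

    def test_deterministic_under_seed(self):
        universe = {f"g{i}" for i in range(30)}
        s_t = {f"g{i}" for i in range(7)}
        a = coverage_pvalue(0.3, s_t, universe, 10, seed=5)
        b = coverage_pvalue(0.3, s_t, universe, 10, seed=5)
        assert a.p == b.p and np.array_equal(a.null_values, b.null_values)

    def test_relabeling_invariance(self):
        universe = {f"g{i}" for i in range(12)}
        s_t = {f"g{i}" for i in range(4)}
        relabeled_universe = {f"x{i}" for i in range(12)}
        relabeled_s_t = {f"x{i}" for i in range(4)}
        a = coverage_pvalue(0.5, s_t, universe, 5, seed=3)
        b = coverage_pvalue(0.5, relabeled_s_t, relabeled_universe, 5, seed=3)
        assert a.p == b.p

    def test_sweep_small_universes_match_enumeration(self):
        """MC estimate within 3 binomial SE of the exact p for universes <= 12."""
        rng = np.random.default_rng(0)
        for n_uni in (5, 8, 12):
            universe = {f"g{i}" for i in range(n_uni)}
            for size in range(1, n_uni + 1):
                s_t = set(rng.choice(sorted(universe), size=n_uni // 2,
                                     replace=False))
                c_obs = rng.choice([0.0, 1 / size, 0.5, 1.0])
                exact = exact_coverage_p(c_obs, s_t, universe, size)
                mc = coverage_pvalue(c_obs, s_t, universe, size,
                                     n_iter=1000, seed=int(rng.integers(2**31))).p
                se = np.sqrt(max(exact * (1 - exact), 1e-6) / 1000)
                assert abs(mc - exact) <= 3 * se + 1e-12


class TestFdr:
    def test_bh_step_up_by_hand(self):
        q = fdr_qvalues([0.01, 0.02, 0.03, 0.04], method="bh")
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(fdr_qvalues([1.0, 1.0, 1.0], method="storey"), 1.0)

    def test_single_p(self):
        assert fdr_qvalues([0.03], method="bh")[0] == pytest.approx(0.03)
        # storey: pi0 = min(1, 0/0.5) = 0 for a single small p
        assert fdr_qvalues([0.03], method="storey")[0] == pytest.approx(0.0)
        assert fdr_qvalues([0.7], method="storey")[0] == pytest.approx(0.7 * 1.0)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        for method in ("bh", "storey"):
            q = fdr_qvalues(p, method=method)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-12)

    def test_bh_never_beats_unadjusted(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        q = fdr_qvalues(p, method="bh")
        for alpha in (0.01, 0.05, 0.1):
            assert (q < alpha).sum() <= (p < alpha).sum()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fdr_qvalues([0.5, 1.5])


class TestSelfTarget:
    def test_empty_matrix_no_self_targets(self):
        placements = [intronic("m1", "h1")]
        mirnas, hosts = self_target_set(placements, matrix_from_counts({}))
        assert mirnas == set() and hosts == set()

    def test_three_mirnas_one_host(self):
        placements = [intronic(f"m{i}", "h1") for i in range(3)]
        counts = {(f"m{i}", "h1"): 2 for i in range(3)}
        mirnas, hosts = self_target_set(placements, matrix_from_counts(counts))
        assert len(mirnas) == 3 and hosts == {"h1"}

    def test_threshold_respected(self):
        placements = [intronic("m1", "h1"), intronic("m2", "h2")]
        counts = {("m1", "h1"): 2, ("m2", "h2"): 1}
        mirnas, _ = self_target_set(placements, matrix_from_counts(counts), k=2)
        assert mirnas == {"m1"}

    def test_planted_fraction_recovered(self):
        """Observed self-target count within the binomial band of the planted rate."""
        from intramir.classification import classify_all
        from intramir.synthetic_data import SyntheticConfig, generate
        from intramir.target_integration import build_agreement

        bundle = generate(
            SyntheticConfig(seed=21, coverage_enrichment_gamma=0.0)
        )
        placements = [
            p for p in classify_all(bundle.annotation) if p.host_gene_id
        ]
        matrix = build_agreement(bundle.sources)
        mirnas, _ = self_target_set(placements, matrix, k=2)
        n = len(placements)
        expected = 0.2 * n
        band = 1.96 * np.sqrt(n * 0.2 * 0.8)
        # small one-sided slack for false-positive-driven extra pairs
        assert expected - band <= len(mirnas) <= expected + band + 0.02 * n

    def test_observed_zero_p_one(self):
        placements = [intronic("m1", "h1"), intronic("m2", "h2")]
        counts = {("m1", "g5"): 3, ("m2", "g6"): 3}
        res = self_target_pvalue(0, placements, matrix_from_counts(counts),
                                 n_iter=50, seed=0)
        assert res.p == 1.0

    def test_planted_excess_detected(self):
        rng = np.random.default_rng(4)
        hosts = [f"h{i}" for i in range(40)]
        placements = [intronic(f"m{i}", h) for i, h in enumerate(hosts)]
        genes = hosts + [f"g{i}" for i in range(200)]
        counts = {}
        # background: each miRNA targets 20 random non-host genes
        for i in range(40):
            for g in rng.choice(genes[40:], size=20, replace=False):
                counts[(f"m{i}", g)] = 2
        # planted: half the miRNAs also target their own host
        for i in range(0, 40, 2):
            counts[(f"m{i}", f"h{i}")] = 2
        matrix = matrix_from_counts(counts)
        observed = len(self_target_set(placements, matrix)[0])
        assert observed == 20
        res = self_target_pvalue(observed, placements, matrix,
                                 n_iter=500, seed=1)
        assert res.p < 0.05

    def test_utr3_matched_mode_uses_supplied_sets(self):
        placements = [intronic("m1", "h1")]
        counts = {("m1", "x1"): 2}
        matched = [["x1"], ["x2"]]
        res = self_target_pvalue(1, placements, matrix_from_counts(counts),
                                 universe_mode="utr3_matched",
                                 matched_sets=matched, n_iter=10, seed=0)
        # iterations alternate between a set that always hits and one that never does
        assert res.p == pytest.approx(0.5)

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            self_target_pvalue(0, [], matrix_from_counts({}),
                               universe_mode="bogus", seed=0)


class TestPathwayLinking:
    def test_sets_derived_only_from_hosted_mirnas(self):
        placements = [intronic("m1", "h1"), intronic("m2", "h2")]
        counts = {("m1", "t1"): 2, ("m1", "t2"): 1, ("m2", "t3"): 4,
                  ("m9", "t9"): 7}
        pathways = {"P1": {"h1", "t1", "x"}, "P2": {"y", "z"}}
        linked = build_pathway_target_sets(pathways, placements,
                                           matrix_from_counts(counts),
                                           agreement_k=2)
        assert len(linked) == 1  # P2 contains no host
        pts = linked[0]
        assert pts.pathway_id == "P1"
        assert pts.hosts_in_pathway == {"h1"}
        assert pts.mirnas == {"m1"}
        assert pts.s_t == {"t1"}  # t2 below threshold, m9 not hosted

    def test_coverage_non_increasing_in_threshold(self):
        placements = [intronic("m1", "h1")]
        counts = {("m1", f"t{i}"): i for i in range(1, 8)}
        pathways = {"P": {"h1", "t2", "t4", "t6"}}
        prev = 1.1
        for k in range(1, 8):
            linked = build_pathway_target_sets(pathways, placements,
                                               matrix_from_counts(counts),
                                               agreement_k=k)
            c = target_coverage(linked[0].s_p, linked[0].s_t)
            assert c <= prev + 1e-12
            prev = c


class TestCoverageAnalysis:
    def test_planted_pathways_rank_first(self, default_bundle):
        from intramir.classification import classify_all
        from intramir.target_integration import build_agreement

        placements = [
            p for p in classify_all(default_bundle.annotation) if p.host_gene_id
        ]
        matrix = build_agreement(default_bundle.sources)
        df = coverage_analysis(
            default_bundle.pathways, placements, matrix,
            universe=set(default_bundle.annotation.genes),
            n_iter=500, seed=1,
        )
        planted = set(default_bundle.truth.enriched_pathways)
        top = set(df.head(len(planted))["pathway"])
        assert top == planted
        assert (df[df["pathway"].isin(planted)]["q"] < 0.10).all()


class TestHypergeom:
    def test_direct_sum_example(self):
        # universe 10, category 5, query 3, overlap 3 -> C(5,3)/C(10,3)
        universe = {f"g{i}" for i in range(10)}
        cat = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2"}
        df = hypergeom_enrichment(query, {"c": cat}, universe)
        assert df.loc[0, "p"] == pytest.approx(10 / 120)

    def test_category_equals_universe(self):
        universe = {f"g{i}" for i in range(10)}
        df = hypergeom_enrichment({"g0"}, {"c": set(universe)}, universe)
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_query_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        df = hypergeom_enrichment(set(), {"c": {"g0"}}, universe)
        assert df.loc[0, "p"] == 1.0

    def test_query_outside_universe_raises(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment({"zz"}, {"c": {"g0"}}, {"g0"})

    def test_out_of_universe_category_genes_dropped(self):
        universe = {f"g{i}" for i in range(6)}
        df = hypergeom_enrichment({"g0"}, {"c": {"g0", "nope"}}, universe)
        assert df.loc[0, "size"] == 1


def test_gmt_round_trip(tmp_path, default_bundle):
    path = tmp_path / "p.gmt"
    write_gmt(default_bundle.pathways, path)
    assert read_gmt(path) == default_bundle.pathways


def test_gmt_rejects_short_lines(tmp_path):
    path = tmp_path / "bad.gmt"
    path.write_text("name_only\tdesc\n")
    with pytest.raises(ValueError):
        read_gmt(path)
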
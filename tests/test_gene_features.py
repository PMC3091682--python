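"""ARE/GC counting, matched cohorts and the rank-based comparisons."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from intramir.gene_features import (
    compare_features,
    compute_features,
    count_are,
    gc_fraction,
    kruskal_pairwise,
    mwu_test,
    sample_matched_controls,
    sample_utr3_matched_sets,
)

from conftest import make_gene


class TestCountAre:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AUUUA", 1),
            ("AUUUAUUUA", 2),  # overlapping occurrences both counted
            ("AUUUAAUUUA", 2),  # junction AAUUU does not match
            ("", 0),
            ("GCGCGC", 0),
        ],
    )
    def test_examples(self, seq, expected):
        assert count_are(seq) == expected

    def test_rejects_non_nucleotides(self):
        with pytest.raises(ValueError):
            count_are("AUXUA")

    @given(st.text(alphabet="ACGU", max_size=2000))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_scan(self, seq):
        brute = sum(1 for i in range(len(seq) - 4) if seq[i:i + 5] == "AUUUA")
        assert count_are(seq) == brute


class TestGcFraction:
    @pytest.mark.parametrize(
        "seq,expected", [("GCGC", 1.0), ("AUAU", 0.0), ("GCAU", 0.5)]
    )
    def test_examples(self, seq, expected):
        assert gc_fraction(seq) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            gc_fraction("")


class TestComputeFeatures:
    def test_structure_counts(self):
        rec = compute_features(make_gene())  # 3 exons spanning 100..600
        assert rec.total_length == 500
        assert rec.n_introns == 2
        assert rec.utr3_len is None  # non-coding: UTR features undefined

    def test_are_density_uses_coordinate_utr3_length(self):
        gene = make_gene(exons=((0, 100), (200, 300)), cds=(50, 290))
        gene.utr3_sequence = "AUUUAAUUUA"  # matches utr3_len 10
        rec = compute_features(gene)
        assert rec.utr3_len == 10
        assert rec.are_count == 2
        assert rec.are_per_kb == pytest.approx(200.0)

    def test_single_exon_noncoding(self):
        rec = compute_features(make_gene(exons=((0, 400),)))
        assert rec.n_introns == 0
        assert rec.utr5_len is None and rec.are_per_kb is None


class TestMatchedControls:
    @pytest.fixture
    def cohort(self):
        rng = np.random.default_rng(0)
        genes = []
        for i in range(400):
            chrom = f"chr{rng.integers(1, 4)}"
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(0, 10**6))
            genes.append(
                make_gene(f"g{i:03d}", chrom=chrom, strand=strand,
                          exons=((start, start + 500),))
            )
        return genes[:40], genes[40:]

    def test_stratum_proportions_exact(self, cohort):
        hosts, universe = cohort
        controls = sample_matched_controls(hosts, universe, k_per_host=3, seed=1)
        assert len(controls) == 3 * len(hosts)

        def strata(genes):
            out = {}
            for g in genes:
                key = (g.interval.chrom, g.interval.strand)
                out[key] = out.get(key, 0) + 1
            return out

        host_strata = strata(hosts)
        control_strata = strata(controls)
        assert control_strata == {k: 3 * v for k, v in host_strata.items()}

    def test_controls_exclude_hosts(self, cohort):
        hosts, universe = cohort
        controls = sample_matched_controls(hosts, universe, k_per_host=2, seed=1)
        assert not ({g.gene_id for g in controls} & {g.gene_id for g in hosts})

    def test_same_seed_reproducible(self, cohort):
        hosts, universe = cohort
        a = sample_matched_controls(hosts, universe, 5, seed=42)
        b = sample_matched_controls(hosts, universe, 5, seed=42)
        assert [g.gene_id for g in a] == [g.gene_id for g in b]

    def test_empty_stratum_raises(self):
        hosts = [make_gene("h", chrom="chrX", exons=((0, 100),))]
        universe = [make_gene("u", chrom="chr1", exons=((0, 100),))]
        with pytest.raises(ValueError, match="chrX"):
            sample_matched_controls(hosts, universe, 1, seed=0)


def coding_gene(gene_id, utr3_len, chrom="chr1"):
    span = utr3_len + 500
    return make_gene(gene_id, chrom=chrom, exons=((0, span),),
                     cds=(10, span - utr3_len))


class TestUtr3MatchedSets:
    def test_sizes_and_determinism(self):
        rng = np.random.default_rng(5)
        hosts = [coding_gene(f"h{i}", int(l))
                 for i, l in enumerate(rng.lognormal(6.5, 0.5, 50))]
        universe = [coding_gene(f"u{i}", int(l))
                    for i, l in enumerate(rng.lognormal(6.5, 0.5, 500))]
        sets = sample_utr3_matched_sets(hosts, universe, n_sets=5, seed=9)
        assert len(sets) == 5
        assert all(len(s) == len(hosts) for s in sets)
        again = sample_utr3_matched_sets(hosts, universe, n_sets=5, seed=9)
        assert [[g.gene_id for g in s] for s in sets] == [
            [g.gene_id for g in s] for s in again
        ]

    def test_duplicated_host_lengths_pass_trivially(self):
        hosts = [coding_gene(f"h{i}", 100 + 7 * i) for i in range(30)]
        universe = [coding_gene(f"u{i}", 100 + 7 * (i % 30)) for i in range(90)]
        sets = sample_utr3_matched_sets(hosts, universe, n_sets=3, seed=0)
        host_lens = sorted(100 + 7 * i for i in range(30))
        for s in sets:
            from intramir.annotation_io import derive_utr_lengths

            p = mwu_test([derive_utr_lengths(g)[1] for g in s], host_lens)
            assert p > 0.05


class TestMwu:
    def test_exact_small_sample(self):
        # U = 0 with n=3+3: the most extreme of the 20 arrangements, both tails
        assert mwu_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_large_samples(self):
        x = list(range(50))
        assert mwu_test(x, x) > 0.9

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=30), rng.normal(1.0, 1, size=25)
        assert mwu_test(a, b) == pytest.approx(
            mwu_test(a + 1000, b + 1000)
        )

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mwu_test([], [1.0])

    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=5),
        st.lists(st.integers(0, 8), min_size=2, max_size=5),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle(self, a, b):
        """Exact path equals brute-force enumeration of label assignments."""
        pooled = a + b
        ranks = sps.rankdata(pooled)
        na, n = len(a), len(pooled)
        mean_u = na * (n - na) / 2

        def u_of(idx):
            return sum(ranks[i] for i in idx) - na * (na + 1) / 2

        u_obs = u_of(range(na))
        total = extreme = 0
        for idx in combinations(range(n), na):
            total += 1
            if abs(u_of(idx) - mean_u) >= abs(u_obs - mean_u) - 1e-9:
                extreme += 1
        assert mwu_test(a, b) == pytest.approx(extreme / total)


class TestKruskal:
    def test_identical_groups_not_flagged(self):
        g = list(range(20))
        res = kruskal_pairwise([g, g, g])
        assert res.p_value > 0.5
        assert not any(flag for *_, flag in res.pairwise)
        assert res.cutoff == pytest.approx(0.05 / 3, abs=1e-3)

    def test_shifted_group_flagged(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20)
        c = rng.normal(5, 1, 20)  # 5 sd shift
        res = kruskal_pairwise([a, b, c])
        flags = {(i, j): f for i, j, _, f in res.pairwise}
        assert flags[(0, 2)] and flags[(1, 2)]
        assert not flags[(0, 1)]

    def test_too_few_groups_raises(self):
        with pytest.raises(ValueError):
            kruskal_pairwise([[1, 2, 3]])


class TestCompareFeatures:
    def _records(self, values, prefix):
        return [
            compute_features(make_gene(f"{prefix}{i}", exons=((0, int(v)),)))
            for i, v in enumerate(values)
        ]

    def test_toy_ratio_and_exact_p(self):
        a = self._records([10, 20, 30], "a")
        b = self._records([1, 2, 3], "b")
        comp = compare_features(a, b, "total_length")
        assert comp.ratio == pytest.approx(10.0)
        assert comp.p_value == pytest.approx(0.1)

    def test_identical_groups(self):
        a = self._records(range(100, 200), "a")
        comp = compare_features(a, a, "total_length")
        assert comp.ratio == pytest.approx(1.0)
        assert comp.p_value > 0.9

    def test_fully_undefined_feature_raises(self):
        a = self._records([10, 20], "a")
        with pytest.raises(ValueError):
            compare_features(a, a, "utr3_len")

    def test_planted_ratio_recovered(self):
        """Median-ratio recovery within ±10% on synthetic cohorts, n=250."""
        rng = np.random.default_rng(12)
        ratio = 2.5
        a = self._records(np.maximum(2, rng.lognormal(10 + np.log(ratio), 1.0, 250)), "a")
        b = self._records(np.maximum(2, rng.lognormal(10, 1.0, 250)), "b")
        comp = compare_features(a, b, "total_length")
        assert comp.ratio == pytest.approx(ratio, rel=0.10)
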
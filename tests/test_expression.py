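"""Gene selection, defect calls, k-means, motif scanning, enrichment."""

import itertools
import math
import re

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from esrkit import expression as ex
from esrkit import synth


def brute_force_nonoverlap_count(seq: str, motif: str) -> int:
    """Independent oracle: enumerate every match interval on both strands,
    then maximum independent set by dynamic programming over sorted
    intervals."""
    w = len(motif)
    pats = {motif.upper(), ex.reverse_complement(motif)}
    starts = sorted(
        {
            i
            for p in pats
            for i in range(len(seq) - w + 1)
            if re.fullmatch("".join(ex.IUPAC[c] for c in p), seq[i : i + w])
        }
    )
    # dp[i] = best count using intervals starting at or after starts[i]
    n = len(starts)
    dp = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        nxt = n
        for j in range(i + 1, n):
            if starts[j] >= starts[i] + w:
                nxt = j
                break
        dp[i] = max(dp[i + 1], 1 + dp[nxt])
    return dp[0]


def exact_hypergeom_upper_tail(M: int, n: int, N: int, k: int) -> float:
    """Factorial-based P(X >= k) for overlap of an n-set with an N-draw."""
    total = math.comb(M, N)
    return sum(
        math.comb(n, i) * math.comb(M - n, N - i)
        for i in range(k, min(n, N) + 1)
    ) / total


class TestSelectResponsive:
    @staticmethod
    def table_with_sig(n_sig_timepoints):
        rows = []
        for tp in range(1, 4):
            fdr = 0.01 if tp <= n_sig_timepoints else 0.5
            rows.append(
                {"gene": "g1", "strain": "mut", "timepoint": tp,
                 "log2fc": 1.0, "fdr": fdr}
            )
        return ex.ExpressionTable(pd.DataFrame(rows))

    def test_one_timepoint_excluded_two_included(self):
        assert ex.select_responsive(self.table_with_sig(1), "mut") == []
        assert ex.select_responsive(self.table_with_sig(2), "mut") == ["g1"]

    def test_tightening_alpha_never_grows_list(self, expression_data):
        table = expression_data["table"]
        loose = set(ex.select_responsive(table, "msn2msn4", alpha=0.05))
        tight = set(ex.select_responsive(table, "msn2msn4", alpha=0.001))
        assert tight <= loose

    def test_missing_contrast(self):
        with pytest.raises(ex.ExpressionError, match="strain"):
            ex.select_responsive(self.table_with_sig(2), "nope")


class TestCallDefect:
    @pytest.mark.parametrize(
        "wt, mut, expected",
        [
            ((2, 2, 2), (1, 1, 1), ex.INDUCTION_DEFECT),
            ((-2, -2, -1), (-0.5, -0.5, -0.2), ex.REPRESSION_DEFECT),
            ((2, -2, 0), (1, 1, 1), ex.NO_DEFECT),  # no majority direction
            ((2, 2, 2), (3, 3, 3), ex.NO_DEFECT),  # mutant responds more
            ((0, 0, 0), (1, 1, 1), ex.NO_DEFECT),  # flat wild-type
        ],
    )
    def test_examples(self, wt, mut, expected):
        assert ex.call_defect(wt, mut) == expected

    def test_needs_three_timepoints(self):
        with pytest.raises(ex.ExpressionError, match="3 timepoints"):
            ex.call_defect([1, 2], [1, 2])

    def test_generator_defects_recovered(self):
        cfg = synth.GeneratorConfig(seed=9, n_genes=80, fc_noise=0.0)
        data = synth.gen_expression(cfg)
        calls = ex.defect_calls(data["table"], "wt", "msn2msn4")
        for g, arch in data["truth"]["archetype"].items():
            expected = (
                ex.INDUCTION_DEFECT if arch == "induced_msn_defect" else ex.NO_DEFECT
            )
            assert calls[g] == expected


class TestKMeans:
    def test_single_cluster(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 4)))
        assert set(ex.kmeans_partition(X, k=1, seed=0)) == {0}

    def test_identical_rows_cocluster(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        X.iloc[7] = X.iloc[3]
        labels = ex.kmeans_partition(X, k=5, seed=0)
        assert labels.iloc[7] == labels.iloc[3]

    def test_k_exceeding_distinct_rows(self):
        X = pd.DataFrame(np.zeros((5, 3)))
        with pytest.raises(ex.ExpressionError, match="distinct rows"):
            ex.kmeans_partition(X, k=3, seed=0)

    def test_archetypes_recovered(self, expression_data):
        data = expression_data
        X = ex.build_feature_matrix(data["table"], "wt", ["msn2msn4", "dot6tod6"])
        labels = ex.kmeans_partition(X, k=4, seed=7)
        truth = [data["truth"]["archetype"][g] for g in labels.index]
        assert adjusted_rand_score(truth, labels.to_numpy()) >= 0.9

    def test_deterministic_for_fixed_seed(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 6)))
        a = ex.kmeans_partition(X, k=3, seed=42)
        b = ex.kmeans_partition(X, k=3, seed=42)
        assert a.equals(b)


class TestScanMotif:
    @pytest.mark.parametrize(
        "seq, motif, count",
        [
            ("AACCCCTAA", "CCCCT", 1),
            ("CCCCCT", "CCCCT", 1),  # offsets 0 and 1 overlap; one survives
            ("CTCATC", "GATGAG", 1),  # reverse-strand hit
            ("CCCCTCCCCT", "CCCCT", 2),  # adjacent non-overlapping
            ("AAAAAA", "CCCCT", 0),
        ],
    )
    def test_counts(self, seq, motif, count):
        assert ex.scan_motif(seq, motif)["count"] == count

    def test_positions_are_one_based_with_strand(self):
        hits = ex.scan_motif("AACCCCTAA", "CCCCT")["hits"]
        assert hits == [(3, "+")]

    def test_invalid_alphabet(self):
        with pytest.raises(ex.ExpressionError, match="non-ACGTN"):
            ex.scan_motif("ACGUACGUACGU", "CCCCT")

    def test_greedy_equals_brute_force_on_random_promoters(self, rng):
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), 500))
            for motif in ("CCCCT", "GATGAG"):
                assert (
                    ex.scan_motif(seq, motif)["count"]
                    == brute_force_nonoverlap_count(seq, motif)
                )


class TestEnrich:
    @staticmethod
    def collection(universe_size, set_size):
        universe = {f"g{i}" for i in range(universe_size)}
        return ex.GeneSetCollection(
            sets={"S": {f"g{i}" for i in range(set_size)}}, universe=universe
        )

    def test_worked_exact_value(self):
        coll = self.collection(20, 10)
        cluster = {f"g{i}" for i in range(5)}  # overlap 5 of 5
        res = ex.enrich(cluster, coll)[0]
        assert res.p == pytest.approx(252 / 15504)
        assert res.fdr == pytest.approx(res.p)  # single test: BH is identity

    def test_matches_factorial_oracle_on_small_universes(self, rng):
        for _ in range(25):
            M = int(rng.integers(20, 200))
            n = int(rng.integers(1, M))
            N = int(rng.integers(1, M))
            universe = [f"g{i}" for i in range(M)]
            s = set(rng.choice(universe, n, replace=False))
            cluster = set(rng.choice(universe, N, replace=False))
            coll = ex.GeneSetCollection(sets={"S": s}, universe=set(universe))
            res = ex.enrich(cluster, coll)[0]
            expected = exact_hypergeom_upper_tail(M, n, N, len(cluster & s))
            assert res.p == pytest.approx(expected, rel=1e-9)

    def test_under_enrichment_tail(self):
        coll = self.collection(20, 10)
        cluster = {f"g{i}" for i in range(15, 20)}  # overlap 0
        res = ex.enrich(cluster, coll, alternative="less")[0]
        # P(X <= 0) = C(10,5)/C(20,5)
        assert res.p == pytest.approx(252 / 15504)

    def test_bh_monotone_and_bounded(self, rng):
        pvals = rng.uniform(size=40)
        adj = ex.bh_adjust(pvals)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj <= 1.0)
        assert np.all(adj >= pvals - 1e-12)

    def test_planted_motif_cluster_enriched(self, expression_data):
        data = expression_data
        arch = data["truth"]["archetype"]
        genes = sorted(arch)
        counts = ex.motif_counts(data["promoters"], ["CCCCT"])
        with_stre = set(counts.index[counts["CCCCT"] > 0])
        coll = ex.GeneSetCollection(sets={"STRE": with_stre}, universe=set(genes))
        cluster = {g for g in genes if arch[g] == "induced_msn_defect"}
        res = ex.enrich(cluster, coll)[0]
        assert res.fdr < 0.02

    def test_empty_universe(self):
        coll = ex.GeneSetCollection(sets={}, universe=set())
        with pytest.raises(ex.ExpressionError, match="universe"):
            ex.enrich(set(), coll)


class TestRegulatorCounts:
    def test_zero_regulator_gene_maps_to_zero(self):
        coll = ex.GeneSetCollection(sets={"T": {"g1"}}, universe={"g1", "g2"})
        counts = ex.regulator_counts(["g1", "g2"], coll)
        assert counts["g2"] == 0.0
        assert counts["g1"] == 1.0  # log2(1 + 1)

    def test_cluster_identical_to_background(self, rng):
        genes = [f"g{i}" for i in range(40)]
        sets = {
            f"T{j}": set(rng.choice(genes, 10, replace=False)) for j in range(8)
        }
        coll = ex.GeneSetCollection(sets=sets, universe=set(genes))
        df = ex.regulator_count_stats({"all": set(genes)}, coll, set(genes))
        assert df["p"].iloc[0] > 0.9

    def test_planted_high_regulator_cluster_detected(self, rng):
        genes = [f"g{i}" for i in range(200)]
        hub = set(genes[:40])
        sets = {}
        for j in range(24):
            # hub genes are 4x as likely to be targeted
            weights = np.array([4.0 if g in hub else 1.0 for g in genes])
            weights /= weights.sum()
            sets[f"T{j}"] = set(rng.choice(genes, 30, replace=False, p=weights))
        coll = ex.GeneSetCollection(sets=sets, universe=set(genes))
        df = ex.regulator_count_stats(
            {"hub": hub, "rest": set(genes[40:])}, coll, set(genes)
        ).set_index("cluster")
        assert df.loc["hub", "fdr"] < 0.05
        assert df.loc["hub", "median_log2_regulators"] > df.loc["hub", "background_median"]


def test_shuffled_labels_destroy_enrichment(expression_data, rng):
    """Permuting gene identities yields null-uniform enrichment p-values."""
    data = expression_data
    arch = data["truth"]["archetype"]
    genes = sorted(arch)
    counts = ex.motif_counts(data["promoters"], ["CCCCT"])
    with_stre = set(counts.index[counts["CCCCT"] > 0])
    coll = ex.GeneSetCollection(sets={"STRE": with_stre}, universe=set(genes))
    n_cluster = sum(a == "induced_msn_defect" for a in arch.values())
    pvals = []
    for _ in range(40):
        cluster = set(rng.choice(genes, n_cluster, replace=False))
        pvals.append(ex.enrich(cluster, coll)[0].p)
    # null p-values should not pile up near zero
    assert np.mean(np.asarray(pvals) < 0.02) < 0.2
    assert np.median(pvals) > 0.1
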
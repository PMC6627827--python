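"""CMI network inference: mutual information, stratified CMI, permutation
significance and degree diagnostics, each checked against independent oracles."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bonemet as bm
from bonemet.depnet import (
    build_network,
    cmi,
    mutual_information,
    network_stats,
    permutation_test,
    read_network,
    write_network,
)


from oracle_utils import entropy_oracle_mi, oracle_cmi


class TestMutualInformation:
    def test_perfect_dependence_is_one_bit(self):
        x = np.array([0, 0, 1, 1])
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_exact_independence_is_zero(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_matches_entropy_oracle_on_fixed_table(self):
        # 2x2 table [[30,10],[10,30]]
        x = np.repeat([0, 0, 1, 1], [30, 10, 10, 30])
        y = np.repeat([0, 1, 0, 1], [30, 10, 10, 30])
        assert mutual_information(x, y) == pytest.approx(
            entropy_oracle_mi(x, y), abs=1e-12)

    def test_symmetric_and_nonnegative(self, rng):
        for _ in range(50):
            x = rng.integers(0, 2, 30)
            y = rng.integers(0, 2, 30)
            mi_xy = mutual_information(x, y)
            assert mi_xy == pytest.approx(mutual_information(y, x), abs=1e-12)
            assert mi_xy >= 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0, 1, 1])


class TestCMI:
    def test_independent_gene_gives_near_zero(self, rng):
        n = 1000
        a = rng.integers(0, 2, n)
        b = rng.normal(size=n)
        risk = rng.integers(0, 2, n)
        assert abs(cmi(a, b, risk).cmi) < 0.02

    def test_high_stratum_only_dependence_approaches_one_bit(self, rng):
        n = 4000
        b = np.arange(n, dtype=float)
        risk = rng.integers(0, 2, n)
        a = rng.integers(0, 2, n)
        k = math.floor(0.35 * n)
        a[-k:] = risk[-k:]  # A == risk exactly among high-B patients
        res = cmi(a, b, risk)
        assert res.cmi == pytest.approx(1.0, abs=0.08)
        assert res.n_high == res.n_low == k

    def test_matches_first_principles_oracle_on_planted_cohort(self, small_cohort):
        _, _, expr, clinical, truth = small_cohort
        labels = bm.preprocess.label_risk(clinical)
        risk = labels.set_index("patient_id").loc[expr.columns, "label"]
        binarized = bm.preprocess.binarize(expr)
        for i, (mod, dep) in enumerate(truth.pairs):
            a = binarized.loc[dep].to_numpy()
            b = expr.loc[mod].to_numpy()
            r = risk.to_numpy()
            ours = cmi(a, b, r, rng=np.random.default_rng(i)).cmi
            ref = oracle_cmi(a, b, r, rng=np.random.default_rng(i))
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_asymmetric_on_planted_pair(self, small_cohort):
        # forward (modulator conditions) is strong; reverse is much weaker
        _, _, expr, clinical, truth = small_cohort
        labels = bm.preprocess.label_risk(clinical)
        risk = labels.set_index("patient_id").loc[expr.columns, "label"].to_numpy()
        binarized = bm.preprocess.binarize(expr)
        fwd = []
        rev = []
        for mod, dep in truth.pairs:
            fwd.append(cmi(binarized.loc[dep].to_numpy(),
                           expr.loc[mod].to_numpy(), risk).cmi)
            rev.append(cmi(binarized.loc[mod].to_numpy(),
                           expr.loc[dep].to_numpy(), risk).cmi)
        assert np.mean(fwd) > 3 * abs(np.mean(rev))

    @pytest.mark.parametrize("fraction", [0.0, 0.6, -0.1])
    def test_fraction_out_of_range(self, fraction):
        with pytest.raises(ValueError):
            cmi([0, 1] * 10, np.arange(20.0), [0, 1] * 10, fraction=fraction)

    def test_stratum_too_small(self):
        with pytest.raises(ValueError):
            cmi([0, 1, 0, 1], np.arange(4.0), [0, 1, 1, 0], fraction=0.35)


class TestPermutationTest:
    def test_pseudocount_floor_when_observed_dominates(self, rng):
        n = 600
        b = np.arange(n, dtype=float)
        risk = rng.integers(0, 2, n)
        a = rng.integers(0, 2, n)
        a[-210:] = risk[-210:]
        p = permutation_test(a, b, risk, n_perm=1000, rng=rng)
        assert p == pytest.approx(1 / 1001)

    def test_constant_gene_gives_p_one(self, rng):
        n = 200
        p = permutation_test(np.zeros(n, int), rng.normal(size=n),
                             rng.integers(0, 2, n), n_perm=99, rng=rng)
        assert p == 1.0

    def test_permuted_null_equals_random_strata(self, rng):
        # permuting the modulator and re-sorting is the same as assigning the
        # tail strata to the permutation's preimages of the sorted positions
        n = 40
        a = rng.integers(0, 2, n)
        b = rng.normal(size=n)  # a.s. distinct -> tie-break irrelevant
        risk = rng.integers(0, 2, n)
        k = math.floor(0.35 * n)
        order = np.argsort(b)
        for _ in range(25):
            sigma = rng.permutation(n)
            literal = cmi(a, b[sigma], risk).cmi
            inv = np.empty(n, int)
            inv[sigma] = np.arange(n)
            low, high = inv[order[:k]], inv[order[-k:]]
            subset = entropy_oracle_mi(a[high], risk[high]) - \
                entropy_oracle_mi(a[low], risk[low])
            assert literal == pytest.approx(subset, abs=1e-12)

    def test_p_value_stable_under_joint_patient_relabeling(self, rng):
        n = 400
        a = rng.integers(0, 2, n)
        b = rng.normal(size=n)
        risk = (rng.random(n) < 0.3 + 0.3 * a * (b > 0.5)).astype(int)
        p1 = permutation_test(a, b, risk, n_perm=400, rng=np.random.default_rng(5))
        sigma = rng.permutation(n)
        p2 = permutation_test(a[sigma], b[sigma], risk[sigma], n_perm=400,
                              rng=np.random.default_rng(5))
        # the observed CMI is identical; only the Monte Carlo null resamples
        assert abs(p1 - p2) < 0.08


@pytest.fixture(scope="module")
def cohort_tables(small_cohort):
    cfg, scaffold, expr, clinical, truth = small_cohort
    labels = bm.preprocess.label_risk(clinical)
    risk = labels.set_index("patient_id").loc[expr.columns, "label"].astype(np.int8)
    binarized = bm.preprocess.binarize(expr)
    candidates = bm.preprocess.candidate_pairs(expr.index, scaffold)
    return candidates, binarized, expr, risk, truth


class TestBuildNetwork:
    def test_alpha_zero_gives_empty_network(self, cohort_tables):
        candidates, binarized, expr, risk, _ = cohort_tables
        with pytest.warns(UserWarning):
            net = build_network(candidates[:20], binarized, expr, risk,
                                alpha=0.0, n_perm=20, seed=0)
        assert net.number_of_edges() == 0

    def test_reproducible_given_seed(self, cohort_tables):
        candidates, binarized, expr, risk, _ = cohort_tables
        net1 = build_network(candidates[:60], binarized, expr, risk,
                             n_perm=100, seed=42)
        net2 = build_network(candidates[:60], binarized, expr, risk,
                             n_perm=100, seed=42)
        assert sorted(net1.edges(data=True)) == sorted(net2.edges(data=True))

    def test_recovers_planted_pairs(self, cohort_tables):
        candidates, binarized, expr, risk, truth = cohort_tables
        net = build_network(candidates, binarized, expr, risk,
                            n_perm=200, seed=1)
        recovered = set(truth.pairs) & set(net.edges)
        assert len(recovered) >= 4  # 5 planted pairs at n=400
        for u, v, d in net.edges(data=True):
            assert d["p_value"] < 0.05

    def test_bh_correction_is_more_conservative(self, cohort_tables):
        candidates, binarized, expr, risk, _ = cohort_tables
        raw = build_network(candidates[:100], binarized, expr, risk,
                            n_perm=100, seed=2)
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore", UserWarning)
            adj = build_network(candidates[:100], binarized, expr, risk,
                                n_perm=100, seed=2, bh_correction=True)
        assert set(adj.edges) <= set(raw.edges)

    def test_round_trip_tsv(self, cohort_tables, tmp_path):
        candidates, binarized, expr, risk, _ = cohort_tables
        net = build_network(candidates[:80], binarized, expr, risk,
                            n_perm=100, seed=3)
        path = tmp_path / "net.tsv"
        write_network(net, path)
        back = read_network(path)
        assert set(back.edges) == set(net.edges)


class TestNetworkStats:
    def test_cycle_mean_degree(self):
        g = nx.DiGraph([(1, 2), (2, 3), (3, 1)])
        s = network_stats(g)
        assert s.mean_in_degree == pytest.approx(1.0)
        assert s.mean_out_degree == pytest.approx(1.0)

    def test_star_mean_out_degree(self):
        k = 5
        g = nx.DiGraph([("c", f"l{i}") for i in range(k)])
        s = network_stats(g)
        assert s.mean_out_degree == pytest.approx(k / (k + 1))

    def test_powerlaw_fit_matches_regression_oracle(self):
        g = nx.barabasi_albert_graph(300, 2, seed=5)
        dg = nx.DiGraph()
        dg.add_nodes_from(g.nodes)
        dg.add_edges_from((min(u, v), max(u, v)) for u, v in g.edges)
        s = network_stats(dg)
        deg = [d for _, d in dg.out_degree() if d > 0]
        vals, counts = np.unique(deg, return_counts=True)
        fit = stats.linregress(np.log10(vals), np.log10(counts))
        assert s.powerlaw_r2_out == pytest.approx(fit.rvalue**2, abs=1e-9)
        assert s.powerlaw_corr_out == pytest.approx(fit.rvalue, abs=1e-9)

    def test_few_distinct_degrees_undefined(self):
        g = nx.DiGraph([(1, 2), (3, 4)])
        s = network_stats(g)
        assert np.isnan(s.powerlaw_r2_out)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            network_stats(nx.DiGraph())
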
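import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from netvuln.vulnerability import (
    AllZeroDifferencesError,
    CandidateSet,
    VulnerabilityScore,
    candidates_from_scores,
    compute_nsr,
    compute_tfp,
    compute_utp,
    empirical_tail_pvalues,
    ks_two_sample,
    microrna_bd_filter,
    score_network,
    signed_rank_population_pvalues,
    significant_high,
    utp_filter,
    wilcoxon_signed_rank_one_sided,
)
from netvuln.synthdata import simulate_network
from tests.conftest import make_network, random_network


def brute_force_scores(net, tf_set):
    """Independent NSR/TFP/UTP via a networkx in-degree scan."""
    g = net.to_networkx()
    nsr, tfp, utp = {}, {}, {}
    for m in net.mirnas:
        targets = list(g.successors(m))
        unique = [t for t in targets if g.in_degree(t) == 1]
        nsr[m] = len(unique)
        tfp[m] = sum(t in tf_set for t in targets) / len(targets)
        utp[m] = (sum(t in tf_set for t in unique) / len(unique)) if unique else 0.0
    return nsr, tfp, utp


def enumeration_signed_rank_p(diffs):
    """Exact one-sided p by explicit iteration over all 2^n sign vectors."""
    d = [x for x in diffs if x != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[np.asarray(d) > 0].sum()
    hits = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w >= w_obs - 1e-12:
            hits += 1
    return hits / 2 ** len(d)


class TestMeasurements:
    def test_nsr_on_typology_example(self, fig_typology_net):
        assert compute_nsr(fig_typology_net) == {"M1": 1, "M2": 0, "M3": 0, "M4": 1}

    def test_tfp_simple_ratio(self):
        net = make_network([("m", "A"), ("m", "B"), ("m", "C")])
        assert compute_tfp(net, {"A"})["m"] == pytest.approx(1 / 3)

    def test_utp_unique_tf_target(self, fig_typology_net):
        utp = compute_utp(fig_typology_net, {"G5", "G10"})
        assert utp["M4"] == 1.0   # its only unique target is a TF
        assert utp["M1"] == 0.0   # unique target is not a TF
        assert utp["M2"] == 0.0   # no unique target at all: 0 by convention

    def test_matches_brute_force_on_random_networks(self, rng):
        for _ in range(10):
            net = random_network(rng, n_mirna=50, n_gene=200, p_edge=0.04)
            tf_set = {g for g in net.genes if rng.random() < 0.2}
            bf_nsr, bf_tfp, bf_utp = brute_force_scores(net, tf_set)
            assert compute_nsr(net) == bf_nsr
            for m in net.mirnas:
                assert compute_tfp(net, tf_set)[m] == pytest.approx(bf_tfp[m])
                assert compute_utp(net, tf_set)[m] == pytest.approx(bf_utp[m])

    def test_nsr_conservation(self, rng):
        net = random_network(rng, n_mirna=25, n_gene=120, p_edge=0.05)
        n_single = sum(1 for g in net.genes if net.in_degree(g) == 1)
        assert sum(compute_nsr(net).values()) == n_single

    def test_nsr_monotonicity_under_edge_addition(self, rng):
        """Adding a co-regulator to an in-degree-1 gene can only lower NSR."""
        net = random_network(rng, n_mirna=15, n_gene=60, p_edge=0.08)
        nsr0 = compute_nsr(net)
        singles = [g for g in net.genes if net.in_degree(g) == 1]
        assert singles, "fixture should contain single-line genes"
        g = singles[0]
        new_m = next(m for m in net.mirnas if g not in net.targets(m))
        edges = dict(net.edges)
        edges[(new_m, g)] = next(iter(net.edges.values()))
        net2 = make_network(list(edges))
        net2.edges = edges
        net2._rebuild_index()
        nsr1 = compute_nsr(net2)
        for m in net.mirnas:
            assert nsr1[m] <= nsr0[m]


class TestVulnerabilityScoreInvariants:
    def test_fraction_count_products_must_be_integral(self):
        with pytest.raises(ValueError, match="not an integer"):
            VulnerabilityScore("m", n_targets=10, nsr=2, tfp=0.15, utp=0.5)

    def test_zero_nsr_forces_zero_utp(self):
        with pytest.raises(ValueError, match="utp must be 0"):
            VulnerabilityScore("m", n_targets=4, nsr=0, tfp=0.25, utp=0.5)

    def test_nsr_cannot_exceed_target_count(self):
        with pytest.raises(ValueError, match="n_targets"):
            VulnerabilityScore("m", n_targets=2, nsr=3, tfp=0.5, utp=1 / 3)

    def test_scores_from_random_networks_validate(self, rng):
        for _ in range(5):
            net = random_network(rng, n_mirna=20, n_gene=80, p_edge=0.06)
            tf_set = {g for g in net.genes if rng.random() < 0.15}
            score_network(net, tf_set)  # __post_init__ checks every row


class TestSignedRank:
    def test_five_positive_diffs(self):
        assert wilcoxon_signed_rank_one_sided([1, 2, 3, 4, 5]) == pytest.approx(1 / 32)

    def test_symmetric_pair_is_not_positive_shifted(self):
        assert wilcoxon_signed_rank_one_sided([2.0, -2.0]) >= 0.5

    def test_all_zero_diffs_signalled(self):
        with pytest.raises(AllZeroDifferencesError):
            wilcoxon_signed_rank_one_sided([0.0, 0.0])

    def test_exact_p_equals_full_enumeration(self, rng):
        for n in (5, 8, 10, 12):
            for _ in range(3):
                d = np.round(rng.normal(0.3, 1.0, size=n), 1)
                d = d[d != 0]
                if d.size == 0:
                    continue
                assert wilcoxon_signed_rank_one_sided(d) == pytest.approx(
                    enumeration_signed_rank_p(d), abs=1e-12
                )

    def test_matches_scipy_exact_on_tie_free_input(self, rng):
        d = rng.normal(0.5, 1.0, size=14)
        expected = stats.wilcoxon(d, alternative="greater", method="exact").pvalue
        assert wilcoxon_signed_rank_one_sided(d) == pytest.approx(expected, rel=1e-12)

    def test_approximation_close_to_exact_at_boundary(self, rng):
        d = rng.normal(0.3, 1.0, size=25)
        exact = wilcoxon_signed_rank_one_sided(d)
        approx = pytest.approx(exact, abs=0.01)
        from netvuln.vulnerability import _approx_signed_rank_sf
        ranks = stats.rankdata(np.abs(d))
        w = float(ranks[d > 0].sum())
        assert _approx_signed_rank_sf(ranks, w, 25) == approx


class TestSignificantHigh:
    scores_outlier = {"A": 40.0, **{f"m{i}": float(i % 3) for i in range(30)}}

    @pytest.mark.parametrize("method", ["empirical", "signed_rank"])
    def test_single_outlier_is_significant(self, method):
        assert "A" in significant_high(self.scores_outlier, method=method)

    @pytest.mark.parametrize("method", ["empirical", "signed_rank"])
    def test_all_equal_scores_give_empty_set(self, method):
        scores = {f"m{i}": 2.0 for i in range(10)}
        assert significant_high(scores, method=method) == set()

    @pytest.mark.parametrize("method", ["empirical", "signed_rank"])
    def test_alpha_zero_gives_empty_set(self, method):
        assert significant_high(self.scores_outlier, alpha=0.0, method=method) == set()

    def test_fewer_than_three_scores_rejected(self):
        with pytest.raises(ValueError):
            significant_high({"a": 1.0, "b": 2.0})

    def test_signed_rank_pvalue_matches_enumeration_oracle(self):
        scores = {"A": 9.0, "b": 1.0, "c": 2.0, "d": 1.0, "e": 0.0,
                  "f": 3.0, "g": 2.0, "h": 1.0}
        p = signed_rank_population_pvalues(scores)["A"]
        diffs = [9.0 - v for k, v in scores.items() if k != "A"]
        assert p == pytest.approx(enumeration_signed_rank_p(diffs), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_ordering_and_constant_shift(self, seed):
        r = np.random.default_rng(seed)
        names = [f"m{i}" for i in range(12)]
        # quarter-steps are exact in binary, so score differences and
        # their tie structure survive the constant shift bit-for-bit
        vals = np.round(r.normal(5, 3, size=12) * 4) / 4

        scores = dict(zip(names, vals))
        shifted = {k: v + 17.5 for k, v in scores.items()}
        perm = dict(sorted(scores.items(), key=lambda kv: kv[1]))
        for method in ("empirical", "signed_rank"):
            base = significant_high(scores, method=method)
            assert significant_high(shifted, method=method) == base
            assert significant_high(perm, method=method) == base

    def test_empirical_p_is_tail_fraction(self):
        scores = {"a": 1.0, "b": 2.0, "c": 2.0, "d": 5.0}
        p = empirical_tail_pvalues(scores)
        assert p == {"a": 1.0, "b": 0.75, "c": 0.75, "d": 0.25}


class TestKS:
    def test_identical_samples_give_zero_D(self):
        d, _ = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_disjoint_supports_give_unit_D(self):
        d, p = ks_two_sample([0.0, 1.0], [10.0, 11.0])
        assert d == 1.0
        assert p < 0.2

    def test_matches_brute_force_ecdf_sweep(self, rng):
        a, b = rng.normal(size=7), rng.normal(0.5, 1, size=9)
        grid = np.concatenate([a, b])
        brute = max(
            abs((a <= x).mean() - (b <= x).mean()) for x in grid
        )
        d, _ = ks_two_sample(a, b)
        assert d == pytest.approx(brute, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestFilter:
    def test_utp_filter_keeps_strictly_positive(self):
        utp = {"miR-204-5p": 0.3846, "miR-101-3p": 0.3333, "miR-145-5p": 0.3333,
               "miR-198": 0.2000, "miR-152": 0.1667,
               "miR-130a-3p": 0.0, "miR-363-3p": 0.0}
        survivors = set(utp)
        cands = utp_filter(survivors, utp)
        assert cands == {"miR-204-5p", "miR-101-3p", "miR-145-5p",
                         "miR-198", "miR-152"}

    def test_trace_nesting_enforced(self):
        with pytest.raises(ValueError, match="nested"):
            CandidateSet(step1=frozenset({"a"}), step2=frozenset({"b"}),
                         candidates=frozenset(), alpha=0.05)

    def test_uniform_network_yields_no_candidates(self):
        # every gene co-regulated by two microRNAs, identical degrees
        pairs = []
        ms = [f"m{i}" for i in range(6)]
        for j in range(12):
            pairs += [(ms[j % 6], f"G{j}"), (ms[(j + 1) % 6], f"G{j}")]
        net = make_network(pairs)
        trace = microrna_bd_filter(net, tf_set={"G0", "G5"})
        assert trace.candidates == frozenset()

    def test_empty_network_rejected(self):
        from netvuln.netbuild import RegulatoryNetwork
        with pytest.raises(ValueError):
            microrna_bd_filter(RegulatoryNetwork(edges={}), set())

    def test_filter_nesting_on_random_networks(self, rng):
        for _ in range(5):
            net = random_network(rng, n_mirna=25, n_gene=100, p_edge=0.05)
            tf_set = {g for g in net.genes if rng.random() < 0.2}
            tr = microrna_bd_filter(net, tf_set)
            assert tr.candidates <= tr.step2 <= tr.step1 <= net.mirnas

    def test_planted_mirnas_recovered_in_synthetic_network(self):
        net, tf_set, truth = simulate_network(
            n_mirna=200, n_gene=3000, mean_outdegree=40,
            n_planted=3, seed=123,
        )
        trace = microrna_bd_filter(net, tf_set)
        assert truth.planted_mirnas <= trace.candidates

    def test_score_table_replay_matches_direct_filter(self, rng):
        net = random_network(rng, n_mirna=30, n_gene=150, p_edge=0.05)
        tf_set = {g for g in net.genes if rng.random() < 0.2}
        scores = score_network(net, tf_set)
        replay = candidates_from_scores(scores)
        direct = microrna_bd_filter(net, tf_set)
        assert replay == direct
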
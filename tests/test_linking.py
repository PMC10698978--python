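"""EM components, the flow assignment, and the initial-solution steps."""

import itertools

import numpy as np
import pytest

from haploleak.engine import EngineParams, ImputationEngine
from haploleak.fixtures import combined_cohort, pedigree_founders
from haploleak.kinship import SKMatrix, cohort_sk_matrix
from haploleak.linking import (
    DEGREES,
    LinkingConfig,
    chain_adjacent_chunks,
    combine_initial,
    compute_pi,
    e_step,
    em_objective,
    evaluate_linking,
    fit_sk_likelihoods,
    group_by_pattern,
    link_haplotypes,
    m_step_assign,
)
from haploleak.popgen import HaplotypePanel


@pytest.fixture(scope="module")
def toy_lik():
    rng = np.random.default_rng(1)
    return fit_sk_likelihoods(
        {
            "1": rng.uniform(0.3, 0.5, 200),
            "2": rng.uniform(0.1, 0.3, 200),
            "3+": rng.uniform(0.0, 0.15, 200),
            "unrelated": np.zeros(200),
        }
    )


class TestEStep:
    def test_empty_assignment_returns_prior(self, toy_lik):
        cfg = LinkingConfig()
        S = np.zeros((3, 2))
        post = e_step(np.full(3, 5), S, cfg.prior, toy_lik, T=5)
        np.testing.assert_allclose(post, np.tile(cfg.prior, (5, 2, 1)))

    def test_zero_sk_concentrates_on_unrelated(self, toy_lik):
        cfg = LinkingConfig()
        S = np.zeros((1, 1))
        post = e_step(np.array([0]), S, cfg.prior, toy_lik, T=1)
        assert post[0, 0, 0] > 0.99  # index 0 is the unrelated state

    def test_posteriors_normalize(self, toy_lik):
        rng = np.random.default_rng(2)
        S = rng.uniform(0, 0.5, (6, 3))
        post = e_step(rng.integers(0, 3, 6), S, LinkingConfig().prior, toy_lik, T=2)
        np.testing.assert_allclose(post.sum(axis=2), 1.0, atol=1e-12)


class TestComputePi:
    def test_degenerate_posterior_reduces_to_loglik(self, toy_lik):
        S = np.array([[0.4]])
        post = np.zeros((1, 1, 4))
        post[0, 0, 1] = 1.0  # degree 1 with certainty
        pi = compute_pi(post, S, toy_lik)
        expected = toy_lik.loglik(np.array([0.4]))[0][1]
        assert pi[0, 0] == pytest.approx(expected)

    def test_additive_over_relatives(self, toy_lik):
        rng = np.random.default_rng(3)
        S = rng.uniform(0, 0.5, (3, 2))
        post = rng.dirichlet(np.ones(4), size=(2, 2))
        both = compute_pi(post, S, toy_lik)
        one = compute_pi(post[:, :1], S[:, :1], toy_lik)
        two = compute_pi(post[:, 1:], S[:, 1:], toy_lik)
        np.testing.assert_allclose(both, one + two, atol=1e-12)

    def test_matches_direct_formula_on_random_instance(self, toy_lik):
        rng = np.random.default_rng(4)
        N, T, M = 3, 2, 2
        S = rng.uniform(0, 0.5, (N, M))
        post = rng.dirichlet(np.ones(4), size=(T, M))
        pi = compute_pi(post, S, toy_lik)
        for i in range(N):
            for j in range(T):
                direct = 0.0
                for l in range(M):
                    ll = toy_lik.loglik(np.array([S[i, l]]))[0]
                    direct += float((post[j, l] * ll).sum())
                assert pi[i, j] == pytest.approx(direct, abs=1e-10)


class TestMStep:
    @staticmethod
    def _brute(pi, chr_labels, T):
        N = pi.shape[0]
        best = -np.inf
        for assign in itertools.product(range(T + 1), repeat=N):
            ok = True
            for j in range(T):
                for c in set(chr_labels):
                    if sum(1 for i in range(N) if assign[i] == j and chr_labels[i] == c) > 2:
                        ok = False
            if ok:
                best = max(best, sum(pi[i, assign[i]] for i in range(N)))
        return best

    def test_matches_exhaustive_search_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            N, T = int(rng.integers(2, 7)), int(rng.integers(1, 4))
            pi = rng.normal(size=(N, T + 1)) * 10
            chrs = rng.integers(0, 2, size=N).astype(str)
            assign = m_step_assign(pi, chrs, T)
            got = pi[np.arange(N), assign].sum()
            assert got == pytest.approx(self._brute(pi, chrs, T), abs=1e-6)

    def test_single_row_takes_best_column(self):
        pi = np.array([[0.0, 5.0, -1.0]])
        assert m_step_assign(pi, np.array(["1"]), 2)[0] == 1

    def test_capacity_two_per_chromosome(self):
        pi = np.tile([10.0, 0.0], (3, 1))  # all three favor individual 0
        assign = m_step_assign(pi, np.array(["1", "1", "1"]), 1)
        assert (assign == 0).sum() == 2 and (assign == 1).sum() == 1

    def test_every_assignment_satisfies_theta_invariants(self):
        rng = np.random.default_rng(5)
        pi = rng.normal(size=(12, 5))
        chrs = rng.integers(0, 3, 12).astype(str)
        assign = m_step_assign(pi, chrs, 4)
        for j in range(4):
            for c in set(chrs):
                assert ((assign == j) & (chrs == c)).sum() <= 2


class TestEMMonotonicity:
    def test_objective_non_decreasing_over_ten_iterations(self, toy_lik):
        rng = np.random.default_rng(6)
        cfg = LinkingConfig()
        for _ in range(5):
            N, T, M = 30, 5, 8
            S = np.where(rng.random((N, M)) < 0.1, rng.uniform(0, 0.5, (N, M)), 0.0)
            chrs = rng.integers(0, 3, N).astype(str)
            assign = rng.integers(0, T + 1, N)
            objs = []
            for _ in range(10):
                post = e_step(assign, S, cfg.prior, toy_lik, T)
                objs.append(em_objective(assign, post, S, cfg.prior, toy_lik, T))
                pi = compute_pi(post, S, toy_lik)
                assign = m_step_assign(pi, chrs, T, incumbent=assign)
                post = e_step(assign, S, cfg.prior, toy_lik, T)
                objs.append(em_objective(assign, post, S, cfg.prior, toy_lik, T))
            assert (np.diff(objs) >= -1e-9).all()


class TestInitialSolution:
    def test_all_zero_sk_yields_no_groups(self):
        S = SKMatrix(np.zeros((8, 3)), np.arange(8), np.full(8, "1", object), np.zeros(8, int))
        assert group_by_pattern(S, LinkingConfig()) == []

    def test_six_chunks_at_01_form_one_group(self):
        # 0.1 > 2^(-9/2) ~ 0.044: grouped in the first pass
        vals = np.zeros((6, 2))
        vals[:, 1] = 0.1
        S = SKMatrix(vals, np.arange(6), np.full(6, "1", object), np.arange(6))
        groups = group_by_pattern(S, LinkingConfig())
        assert len(groups) == 1 and len(groups[0]) == 6

    def test_chunk_cap_keeps_top_two_by_sk(self):
        vals = np.zeros((7, 1))
        vals[:, 0] = [0.1, 0.2, 0.3, 0.1, 0.1, 0.1, 0.1]
        chunks = np.array([0, 0, 0, 1, 2, 3, 4])
        S = SKMatrix(vals, np.arange(7), np.full(7, "1", object), chunks)
        groups = group_by_pattern(S, LinkingConfig())
        assert len(groups) == 1
        kept = set(groups[0])
        assert 0 not in kept and {1, 2} <= kept  # lowest-SK duplicate dropped

    def test_small_groups_dropped(self):
        vals = np.zeros((4, 1))
        vals[:, 0] = 0.2
        S = SKMatrix(vals, np.arange(4), np.full(4, "1", object), np.arange(4))
        assert group_by_pattern(S, LinkingConfig()) == []

    def test_majority_vote_combination(self):
        groups = [np.array([0, 1, 2, 10, 11])]
        row_of = {("k", i): i for i in range(12)}
        chain = [("k", 0), ("k", 1), ("k", 2), ("k", 3)]  # 3 of 4 in group 0
        assign = combine_initial([chain], groups, row_of, 12)
        assert assign[3] == 0
        chain2 = [("k", 4), ("k", 5), ("k", 0), ("k", 1)]  # exactly half: no
        assign2 = combine_initial([chain2], groups, row_of, 12)
        assert assign2[4] == len(groups)

    def test_empty_chains_give_pure_group_initialization(self):
        groups = [np.array([0, 1, 2, 3, 4])]
        assign = combine_initial([], groups, {}, 8)
        assert (assign[:5] == 0).all() and (assign[5:] == 1).all()


class TestChaining:
    def test_adjacent_chunks_of_related_individual_are_chained(self):
        founders = pedigree_founders(3, n_hap=60, n_chrom=1, n_var=3000)
        cohort = combined_cohort(founders, [1], 6, seed=5)
        base = founders[0]
        rel = cohort.relatives["1"].reshape(-1, base.n_var)
        rel_panel = HaplotypePanel(
            genotypes=rel, positions=base.positions, gmap=base.gmap, chrom="1"
        )
        eng = ImputationEngine(rel_panel, EngineParams(), chunk_mb=0)
        tg = cohort.targets["1"].reshape(-1, base.n_var)
        pos = base.positions
        chunk = 20_000_000
        target_chunks, bounds = {}, {}
        for c in range(5):
            lo, hi = c * chunk + 1, (c + 1) * chunk + 1
            bounds[("1", c)] = (lo, hi)
            s_lo, s_hi = np.searchsorted(pos, lo), np.searchsorted(pos, hi)
            target_chunks[("1", c)] = {h: tg[h, s_lo:s_hi] for h in range(tg.shape[0])}
        chains = chain_adjacent_chunks(eng, target_chunks, bounds, LinkingConfig())
        # transmitted haplotypes (even ids) must form long pure chains
        pure_long = [
            ch for ch in chains
            if len({h for _, h in ch}) == 1 and len(ch) >= 3 and ch[0][1] % 2 == 0
        ]
        assert len(pure_long) >= 4


class TestEvaluateLinking:
    def test_pure_group_attributed_correctly(self):
        from haploleak.linking import LinkedGroup

        truth = np.repeat(np.arange(3), 10)
        g = LinkedGroup(0, np.arange(10), 0.0)
        out = evaluate_linking([g], truth)[0]
        assert out["individual"] == 0 and out["correct"] == 10 and out["incorrect"] == 0

    def test_tie_marks_unassigned(self):
        from haploleak.linking import LinkedGroup

        truth = np.array([0, 0, 0, 1, 1, 1])
        g = LinkedGroup(0, np.arange(6), 0.0)
        assert evaluate_linking([g], truth)[0]["unassigned"]

    def test_majority_with_minority_errors(self):
        from haploleak.linking import LinkedGroup

        truth = np.array([0, 0, 0, 0, 0, 1])
        g = LinkedGroup(0, np.arange(6), 0.0)
        out = evaluate_linking([g], truth)[0]
        assert out["correct"] == 5 and out["incorrect"] == 1


class TestLinkHaplotypes:
    def test_empty_relative_set_gives_empty_output(self, toy_lik):
        S = SKMatrix(np.zeros((4, 0)), np.arange(4), np.full(4, "1", object), np.arange(4))
        groups, _ = link_haplotypes(S, toy_lik)
        assert groups == []

    def test_small_groups_suppressed_from_output(self, toy_lik):
        vals = np.zeros((4, 2))
        vals[:, 0] = 0.3
        S = SKMatrix(vals, np.arange(4), np.full(4, "1", object), np.arange(4))
        groups, _ = link_haplotypes(S, toy_lik)
        assert groups == []

    def test_planted_first_degree_relative_recovered(self, founders, sk_likelihoods):
        cohort = combined_cohort(founders, [1, "unrelated"], 8, seed=21)
        S = cohort_sk_matrix(cohort)
        groups, _ = link_haplotypes(S, sk_likelihoods, LinkingConfig())
        truth = S.hap_id // 2
        evals = evaluate_linking(groups, truth)
        linked = {}
        for ev in evals:
            if not ev["unassigned"]:
                linked[int(ev["individual"])] = ev["correct"]
        n_chunks = 20  # 4 chromosomes x 5 chunks
        first_degree = [linked.get(p, 0) for p in range(8)]
        assert np.mean(first_degree) > n_chunks / 2
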
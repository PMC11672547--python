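"""Pseudolikelihood objective/gradient correctness, gauge identities,
coupling ranking, and recovery of planted structure."""

import numpy as np
import pytest

from pepevo import (MSA, Alphabet, PottsPseudolikelihood, Scaffold,
                    fit_plmdca, neg_pseudo_loglik, plm_gradient,
                    score_sequence, sequence_weights, top_coupled_pairs)
from pepevo.plmdca import PottsModel
from pepevo.synthetic_data import sample_family


def _random_model(scaffold, alphabet, seed, scale=0.5):
    rng = np.random.default_rng(seed)
    m = PottsModel.zeros(scaffold, alphabet)
    return PottsModel(h=rng.normal(0, scale, m.h.shape),
                      J=rng.normal(0, scale, m.J.shape),
                      alphabet=alphabet, scaffold=scaffold)


class TestObjective:
    def test_zero_model_gives_uniform_conditionals(self, small_msa):
        model = PottsModel.zeros(small_msa.scaffold, small_msa.alphabet)
        value = neg_pseudo_loglik(model, small_msa)
        assert value == pytest.approx(small_msa.L * np.log(small_msa.alphabet.q),
                                      rel=1e-12)

    def test_gauge_shift_of_fields_cancels(self, small_msa):
        # adding a constant to every h_r(.) at one position leaves the
        # unregularized objective unchanged (softmax shift invariance)
        model = _random_model(small_msa.scaffold, small_msa.alphabet, 1)
        v0 = neg_pseudo_loglik(model, small_msa)
        h = model.h.copy()
        h[2] += 3.7
        shifted = PottsModel(h=h, J=model.J, alphabet=model.alphabet,
                             scaffold=model.scaffold)
        assert neg_pseudo_loglik(shifted, small_msa) == pytest.approx(v0, rel=1e-12)

    def test_fitted_optimum_beats_zero_model(self, small_msa):
        results = PottsPseudolikelihood(small_msa, lambda_h=0.01,
                                        lambda_J=0.01).fit()
        zero = PottsModel.zeros(small_msa.scaffold, small_msa.alphabet)
        assert (results.model.meta["final_objective"]
                <= neg_pseudo_loglik(zero, small_msa, lambda_h=0.01,
                                     lambda_J=0.01))

    def test_objective_trace_non_increasing(self, small_msa):
        results = PottsPseudolikelihood(small_msa).fit()
        trace = np.array(results.objective_trace)
        assert len(trace) > 1
        assert (np.diff(trace) <= 1e-10).all()


class TestGradient:
    def test_matches_central_finite_differences(self, small_msa):
        model = _random_model(small_msa.scaffold, small_msa.alphabet, 2)
        gh, gJ = plm_gradient(model, small_msa, lambda_h=0.01, lambda_J=0.02)
        rng = np.random.default_rng(0)
        eps = 1e-5

        def obj(h, J):
            return neg_pseudo_loglik(
                PottsModel(h=h, J=J, alphabet=model.alphabet,
                           scaffold=model.scaffold),
                small_msa, lambda_h=0.01, lambda_J=0.02)

        scale = max(1.0, np.abs(gh).max(), np.abs(gJ).max())
        for _ in range(20):
            i, a = rng.integers(model.L), rng.integers(model.q)
            hp, hm = model.h.copy(), model.h.copy()
            hp[i, a] += eps
            hm[i, a] -= eps
            fd = (obj(hp, model.J) - obj(hm, model.J)) / (2 * eps)
            assert abs(fd - gh[i, a]) / scale < 1e-5
        for _ in range(20):
            p = rng.integers(gJ.shape[0])
            a, b = rng.integers(model.q), rng.integers(model.q)
            Jp, Jm = model.J.copy(), model.J.copy()
            Jp[p, a, b] += eps
            Jm[p, a, b] -= eps
            fd = (obj(model.h, Jp) - obj(model.h, Jm)) / (2 * eps)
            assert abs(fd - gJ[p, a, b]) / scale < 1e-5

    def test_field_gradient_zero_for_balanced_columns(self):
        # each column contains every residue equally often -> empirical
        # frequencies equal the uniform conditionals of the zero model
        alphabet = Alphabet("ACDE")
        scaffold = Scaffold(L=3, fixed={})
        matrix = np.array([[0, 1, 2], [1, 2, 3], [2, 3, 0], [3, 0, 1]])
        msa = MSA(ids=list("abcd"), matrix=matrix, scaffold=scaffold,
                  alphabet=alphabet)
        model = PottsModel.zeros(scaffold, alphabet)
        gh, _ = plm_gradient(model, msa)
        assert np.abs(gh).max() < 1e-12

    def test_regularizer_gradient_is_linear(self, small_msa):
        model = _random_model(small_msa.scaffold, small_msa.alphabet, 3)
        gh0, gJ0 = plm_gradient(model, small_msa)
        gh1, gJ1 = plm_gradient(model, small_msa, lambda_h=0.3, lambda_J=0.7)
        assert np.allclose(gh1 - gh0, 2 * 0.3 * model.h, atol=1e-12)
        assert np.allclose(gJ1 - gJ0, 2 * 0.7 * model.J, atol=1e-12)


class TestSequenceWeights:
    def test_distinct_sequences_all_weight_one(self):
        scaffold = Scaffold(L=5, fixed={})
        msa = MSA.from_sequences(["a", "b", "c"],
                                 ["AAAAA", "CCCCC", "DDDDD"], scaffold)
        w = sequence_weights(msa, 0.8)
        assert np.allclose(w, 1.0)

    def test_duplicated_pair_shares_weight(self):
        scaffold = Scaffold(L=5, fixed={})
        msa = MSA.from_sequences(["a", "b", "c"],
                                 ["AAAAA", "AAAAA", "WWWWW"], scaffold)
        w = sequence_weights(msa, 0.8)
        assert w[0] == pytest.approx(0.5)
        assert w[1] == pytest.approx(0.5)
        assert w[2] == pytest.approx(1.0)

    def test_threshold_one_counts_exact_duplicates_only(self):
        scaffold = Scaffold(L=5, fixed={})
        msa = MSA.from_sequences(["a", "b"], ["AAAAA", "AAAAC"], scaffold)
        assert np.allclose(sequence_weights(msa, 1.0), 1.0)

    def test_threshold_out_of_range(self, small_msa):
        with pytest.raises(ValueError):
            sequence_weights(small_msa, 0.0)


class TestScoring:
    def test_zero_model_scores_zero(self):
        scaffold = Scaffold(L=4, fixed={})
        model = PottsModel.zeros(scaffold)
        assert score_sequence(model, "ACDE").score == 0.0
        assert score_sequence(model, "ACDE").energy == 0.0

    def test_single_field_is_additive(self):
        scaffold = Scaffold(L=4, fixed={})
        model = PottsModel.zeros(scaffold)
        model.h[2, Alphabet().index("D")] = 1.0
        with_d = score_sequence(model, "AADA").score
        without = score_sequence(model, "AASA").score
        assert with_d - without == pytest.approx(1.0)

    def test_score_differences_gauge_invariant(self):
        scaffold = Scaffold(L=6, fixed={2: "C"})
        model = _random_model(scaffold, Alphabet(), 4)
        zs = model.to_zero_sum_gauge()
        rng = np.random.default_rng(0)
        pairs = [(scaffold.random_conformant(rng, model.alphabet),
                  scaffold.random_conformant(rng, model.alphabet))
                 for _ in range(100)]
        for s1, s2 in pairs:
            d_raw = model.score(s1) - model.score(s2)
            d_zs = zs.score(s1) - zs.score(s2)
            assert d_raw == pytest.approx(d_zs, abs=1e-9)

    def test_nonconformant_sequence_rejected(self):
        scaffold = Scaffold(L=4, fixed={1: "C"})
        model = PottsModel.zeros(scaffold)
        with pytest.raises(ValueError):
            score_sequence(model, "AAAA")


class TestZeroSumGauge:
    def test_idempotent(self, small_msa):
        model = _random_model(small_msa.scaffold, small_msa.alphabet, 5)
        zs = model.to_zero_sum_gauge()
        zs2 = zs.to_zero_sum_gauge()
        assert np.allclose(zs.h, zs2.h, atol=1e-12)
        assert np.allclose(zs.J, zs2.J, atol=1e-12)

    def test_constant_block_removed(self):
        scaffold = Scaffold(L=3, fixed={})
        model = PottsModel.zeros(scaffold)
        model.J[0] = 2.5  # constant block between positions 1 and 2
        zs = model.to_zero_sum_gauge()
        assert np.abs(zs.J[0]).max() < 1e-12

    def test_blocks_have_zero_marginals(self, small_msa):
        model = _random_model(small_msa.scaffold, small_msa.alphabet, 6)
        zs = model.to_zero_sum_gauge()
        for p in range(zs.J.shape[0]):
            assert np.abs(zs.J[p].sum(axis=0)).max() < 1e-12
            assert np.abs(zs.J[p].sum(axis=1)).max() < 1e-12


class TestFit:
    def test_refit_is_bitwise_identical(self, small_msa):
        m1 = fit_plmdca(small_msa)
        m2 = fit_plmdca(small_msa)
        assert np.array_equal(m1.h, m2.h)
        assert np.array_equal(m1.J, m2.J)

    def test_strong_regularization_shrinks_to_zero(self, small_msa):
        model = fit_plmdca(small_msa, lambda_h=100.0, lambda_J=100.0)
        assert np.abs(model.h).max() < 1e-2
        assert np.abs(model.J).max() < 1e-2

    def test_independent_columns_have_null_level_couplings(self):
        # fields-only truth: fitted coupling norms should sit inside the
        # permutation null obtained by shuffling columns independently
        alphabet = Alphabet("ACDE")
        scaffold = Scaffold(L=6, fixed={})
        truth = PottsModel.zeros(scaffold, alphabet)
        rng = np.random.default_rng(11)
        truth.h[:] = rng.normal(0, 1.0, truth.h.shape)
        msa = sample_family(truth, n=1000, seed=12, method="exact_enumeration")
        fitted = fit_plmdca(msa)
        observed = np.triu(fitted.coupling_norms(), 1)
        mean_norm = observed[observed > 0].mean()
        null_means = []
        for rep in range(10):
            shuffled = msa.matrix.copy()
            prng = np.random.default_rng(100 + rep)
            for col in range(shuffled.shape[1]):
                prng.shuffle(shuffled[:, col])
            null_msa = MSA(ids=msa.ids, matrix=shuffled, scaffold=scaffold,
                           alphabet=alphabet)
            norms = np.triu(fit_plmdca(null_msa).coupling_norms(), 1)
            null_means.append(norms[norms > 0].mean())
        assert mean_norm <= np.quantile(null_means, 0.95) * 1.05

    def test_coupling_norms_shrink_with_sample_size(self):
        alphabet = Alphabet("ACDE")
        scaffold = Scaffold(L=6, fixed={})
        truth = PottsModel.zeros(scaffold, alphabet)
        rng = np.random.default_rng(21)
        truth.h[:] = rng.normal(0, 1.0, truth.h.shape)
        medians = {}
        for n in (200, 2000):
            msa = sample_family(truth, n=n, seed=22, method="exact_enumeration")
            norms = np.triu(fit_plmdca(msa).coupling_norms(), 1)
            medians[n] = np.median(norms[norms > 0])
        assert medians[2000] < medians[200]

    def test_planted_pairs_dominate_apc_ranking(self, planted_benchmark):
        planted, _msa, results = planted_benchmark
        ranked = [(cs.i, cs.j) for cs in results.top_coupled_pairs(k=45)]
        ranks = [ranked.index(p) + 1 for p in planted.planted_pairs]
        assert np.mean(ranks) <= 5

    def test_summary_mentions_fit_facts(self, small_msa):
        results = PottsPseudolikelihood(small_msa).fit()
        text = results.summary()
        assert "Meff" in text and "converged" in text


class TestTopCoupledPairs:
    def test_zero_model_stable_lexicographic_ties(self):
        model = PottsModel.zeros(Scaffold(L=4, fixed={}))
        scores = top_coupled_pairs(model, k=6)
        assert [(cs.i, cs.j) for cs in scores] == [(1, 2), (1, 3), (1, 4),
                                                   (2, 3), (2, 4), (3, 4)]
        assert all(cs.frobenius == 0 for cs in scores)

    def test_k_one_returns_single_pair(self, planted_benchmark):
        _, _, results = planted_benchmark
        assert len(results.top_coupled_pairs(k=1)) == 1

    def test_k_beyond_pair_count_returns_all(self):
        model = PottsModel.zeros(Scaffold(L=3, fixed={}))
        assert len(top_coupled_pairs(model, k=99)) == 3

    def test_residue_breakdown_sorted_by_magnitude(self, planted_benchmark):
        _, _, results = planted_benchmark
        for cs in results.top_coupled_pairs(k=3):
            mags = [abs(v) for _, _, v in cs.top_pairs]
            assert mags == sorted(mags, reverse=True)


def test_model_serialization_roundtrip(tmp_path, small_msa):
    model = fit_plmdca(small_msa)
    path = tmp_path / "model.json"
    model.serialize(path)
    back = PottsModel.load(path)
    assert np.allclose(back.h, model.h)
    assert np.allclose(back.J, model.J)
    assert back.scaffold == model.scaffold
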
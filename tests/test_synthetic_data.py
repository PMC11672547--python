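"""Ground-truth generators: planted models, enumeration, landscapes."""

import numpy as np
import pytest

from pepevo import Alphabet, Scaffold
from pepevo.plmdca import PottsModel
from pepevo.synthetic_data import (benchmark_family, enumerate_distribution,
                                   make_landscape, make_planted_model,
                                   observe_ki, sample_family)


class TestPlantedModel:
    def test_zero_scales_give_near_zero_model(self):
        p = make_planted_model(L=5, q=4, n_conserved=0, n_pairs=0,
                               field_scale=0.0, coupling_scale=0.0, seed=1,
                               background_field_sd=1e-9,
                               background_coupling_sd=1e-9)
        assert np.abs(p.potts.h).max() < 1e-6
        assert np.abs(p.potts.J).max() < 1e-6

    def test_same_seed_reproducible(self):
        kw = dict(L=6, q=6, n_conserved=2, n_pairs=2, field_scale=2.0,
                  coupling_scale=1.0, seed=5)
        p1, p2 = make_planted_model(**kw), make_planted_model(**kw)
        assert np.array_equal(p1.potts.h, p2.potts.h)
        assert np.array_equal(p1.potts.J, p2.potts.J)
        assert p1.planted_pairs == p2.planted_pairs

    def test_planted_entry_exceeds_background_quantile(self):
        sd = 0.05
        p = make_planted_model(L=8, q=6, n_conserved=0, n_pairs=3,
                               field_scale=0.0, coupling_scale=10 * sd,
                               background_coupling_sd=sd, seed=6)
        background = np.abs(p.potts.J).ravel()
        q99 = np.quantile(background, 0.99)
        for (i, j), (a, b) in p.planted_entries.items():
            idx = p.potts.pair_index(i - 1, j - 1)
            entry = p.potts.J[idx, p.potts.alphabet.index(a),
                              p.potts.alphabet.index(b)]
            assert abs(entry) > q99

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            make_planted_model(L=3, q=4, n_conserved=4, n_pairs=0,
                               field_scale=1, coupling_scale=1, seed=0)

    def test_planted_structure_on_variable_positions_only(self):
        sc = Scaffold(L=6, fixed={1: "A", 4: "C"})
        p = make_planted_model(L=6, q=20, n_conserved=2, n_pairs=2,
                               field_scale=2, coupling_scale=1, seed=7,
                               scaffold=sc)
        fixed = set(sc.fixed)
        assert not (set(p.conserved) & fixed)
        for i, j in p.planted_pairs:
            assert i not in fixed and j not in fixed


class TestEnumeration:
    def test_zero_model_is_uniform(self):
        model = PottsModel.zeros(Scaffold(L=4, fixed={}), Alphabet("ACDE"))
        seqs, probs = enumerate_distribution(model)
        assert len(seqs) == 256
        assert np.allclose(probs, 1 / 256)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_field_two_state_marginal(self):
        # h_1(A) = ln 3 over a two-letter alphabet: P(A at 1) = 3/4
        model = PottsModel.zeros(Scaffold(L=3, fixed={}), Alphabet("AC"))
        model.h[0, 0] = np.log(3.0)
        seqs, probs = enumerate_distribution(model)
        marginal = sum(p for s, p in zip(seqs, probs) if s[0] == "A")
        assert marginal == pytest.approx(0.75, abs=1e-12)

    def test_oversized_space_refused(self):
        model = PottsModel.zeros(Scaffold(L=10, fixed={}))  # 20^10
        with pytest.raises(ValueError, match="exceeds"):
            enumerate_distribution(model)

    def test_fixed_positions_clamped(self):
        model = PottsModel.zeros(Scaffold(L=3, fixed={2: "C"}), Alphabet("ACD"))
        seqs, _ = enumerate_distribution(model)
        assert len(seqs) == 9
        assert all(s[1] == "C" for s in seqs)


class TestSampleFamily:
    def test_single_draw_is_valid(self):
        p = make_planted_model(L=4, q=4, n_conserved=1, n_pairs=1,
                               field_scale=1, coupling_scale=1, seed=8)
        msa = sample_family(p.potts, n=1, seed=9, method="exact_enumeration")
        assert msa.n == 1

    def test_conserved_column_modal_residue(self):
        p = make_planted_model(L=6, q=6, n_conserved=2, n_pairs=0,
                               field_scale=3.0, coupling_scale=0.0, seed=10)
        msa = sample_family(p.potts, n=2000, seed=11, method="exact_enumeration")
        for pos, res in p.conserved.items():
            col = msa.matrix[:, pos - 1]
            modal = p.potts.alphabet.symbols[np.bincount(col).argmax()]
            assert modal == res

    def test_exact_and_mc_column_frequencies_agree(self):
        p = make_planted_model(L=4, q=4, n_conserved=1, n_pairs=1,
                               field_scale=1.5, coupling_scale=1.0, seed=12)
        n = 3000
        exact = sample_family(p.potts, n=n, seed=13, method="exact_enumeration")
        mc = sample_family(p.potts, n=n, seed=13, method="long_mc")
        for col in range(4):
            fe = np.bincount(exact.matrix[:, col], minlength=4) / n
            fm = np.bincount(mc.matrix[:, col], minlength=4) / n
            sigma = np.sqrt(fe * (1 - fe) / n) + np.sqrt(fm * (1 - fm) / n)
            assert (np.abs(fe - fm) <= 3 * sigma + 1e-3).all()

    def test_unique_mode_returns_distinct_sequences(self):
        p = make_planted_model(L=4, q=4, n_conserved=0, n_pairs=0,
                               field_scale=0, coupling_scale=0, seed=14)
        msa = sample_family(p.potts, n=50, seed=15, method="long_mc",
                            unique=True)
        assert len(set(msa.sequences())) == 50

    def test_unknown_method_rejected(self):
        p = make_planted_model(L=4, q=4, n_conserved=0, n_pairs=0,
                               field_scale=0, coupling_scale=0, seed=16)
        with pytest.raises(ValueError):
            sample_family(p.potts, n=5, seed=0, method="gibbs")


class TestLandscape:
    def test_flat_landscape_is_constant(self):
        sc = Scaffold(L=5, fixed={1: "A"})
        lnd = make_landscape(sc, effect_sd=0.0, noise_sd=0.0, seed=17,
                             n_random_pairs=0)
        rng = np.random.default_rng(18)
        values = {lnd.true_ki_molar(sc.random_conformant(rng, Alphabet()))
                  for _ in range(20)}
        assert len(values) == 1

    def test_default_range_spans_family_scale(self):
        # central 95% of random sequences should cover >= 250-fold
        sc = Scaffold(L=10, fixed={2: "C", 6: "C"})
        lnd = make_landscape(sc, seed=19)
        rng = np.random.default_rng(20)
        y = [lnd.true_log10_ki_nm(sc.random_conformant(rng, Alphabet()))
             for _ in range(10_000)]
        lo, hi = np.quantile(y, [0.025, 0.975])
        assert hi - lo >= np.log10(250)
        assert 10 ** np.median(y) == pytest.approx(100.0, rel=0.5)

    def test_same_seed_identical(self):
        sc = Scaffold(L=5, fixed={})
        l1 = make_landscape(sc, seed=21)
        l2 = make_landscape(sc, seed=21)
        assert np.array_equal(l1.additive, l2.additive)
        assert l1.pair_effects == l2.pair_effects
        assert l1.intercept == l2.intercept

    def test_aligned_landscape_rewards_planted_features(self):
        sc = Scaffold(L=6, fixed={1: "A"})
        p = make_planted_model(L=6, q=20, n_conserved=1, n_pairs=1,
                               field_scale=3, coupling_scale=2, seed=22,
                               scaffold=sc)
        lnd = make_landscape(sc, seed=23, align_with=p, align_strength=0.5,
                             effect_sd=0.0, n_random_pairs=0, noise_sd=0.0)
        (pos, res), = p.conserved.items()
        base = "A" + "G" * 5
        with_res = base[:pos - 1] + res + base[pos:]
        if with_res != base:
            assert (lnd.true_log10_ki_nm(with_res)
                    < lnd.true_log10_ki_nm(base))


class TestObserveKi:
    def _setup(self):
        sc = Scaffold(L=5, fixed={})
        return sc, make_landscape(sc, seed=24, noise_sd=0.15)

    def test_zero_noise_reproduces_landscape(self):
        sc, lnd = self._setup()
        lnd.noise_sd = 0.0
        recs = observe_ki(lnd, ["ACDEF", "WYKLM"], seed=25)
        for r in recs:
            assert r.ki == pytest.approx(lnd.true_ki_molar(r.sequence), rel=1e-12)

    def test_noise_magnitude_matches_configuration(self):
        sc, lnd = self._setup()
        recs = observe_ki(lnd, ["ACDEF"] * 10_000, seed=26)
        log_ki = np.log10([r.ki for r in recs])
        assert np.std(log_ki) == pytest.approx(0.15, rel=0.1)

    def test_all_observations_positive(self):
        sc, lnd = self._setup()
        recs = observe_ki(lnd, ["ACDEF", "WYKLM", "GGGGG"], seed=27)
        assert all(r.ki > 0 for r in recs)


def test_benchmark_family_shape_and_range(bench_family):
    records, scaffold, planted, landscape = bench_family
    assert len(records) == 50
    assert len({r.sequence for r in records}) == 50
    assert all(scaffold.conforms(r.sequence) for r in records)
    kis = np.array([r.ki for r in records])
    assert kis.max() / kis.min() > 50  # spans orders of magnitude
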
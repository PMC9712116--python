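import numpy as np
import pandas as pd
import pytest

import terraomics as t


def _fit_default(seed, simulate=t.simulate_study, **cfg_kwargs):
    cfg = t.SimulationConfig(seed=seed, **cfg_kwargs)
    mic, met, md, net, ann, truth = simulate(cfg)
    micA, metA, mdA = t.align(mic, met, md)
    model = t.fit_cooccurrence(micA, metA, metadata=mdA, seed=seed)
    return model, micA, metA, truth


def _test_q2(model, mic, met):
    return t.pseudo_q2(model,
                       mic.select_samples(model.test_samples),
                       met.select_samples(model.test_samples))


class TestFit:
    def test_single_microbe_recovers_pooled_proportions(self):
        rng = np.random.default_rng(0)
        n, J = 30, 12
        pooled = rng.dirichlet(np.ones(J) * 2)
        Y = np.array([rng.multinomial(2000, pooled) for _ in range(n)], float)
        mic = t.FeatureTable(np.full((n, 1), 100.0), [f"s{i}" for i in range(n)],
                             ["onlymicrobe"], "counts")
        met = t.FeatureTable(Y, mic.sample_ids, [f"m{j}" for j in range(J)],
                             "intensities")
        model = t.fit_cooccurrence(mic, met, latent_dim=2, min_feature_count=1,
                                   training_fraction=1.0, prior_sd=10.0, seed=0,
                                   epochs=2000)
        pred = model.predict_proportions(mic).values[0]
        empirical = Y.sum(axis=0) / Y.sum()
        np.testing.assert_allclose(pred, empirical, atol=1e-4)

    def test_prediction_rows_sum_to_one(self):
        model, mic, met, _ = _fit_default(0)
        P = model.predict_proportions(mic).values
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_invariant_to_microbe_sample_scaling(self):
        model, mic, met, _ = _fit_default(0)
        scaled = t.FeatureTable(mic.values * np.logspace(0, 2, mic.n_samples)[:, None],
                                mic.sample_ids, mic.feature_ids, "counts")
        np.testing.assert_allclose(model.predict_proportions(mic).values,
                                   model.predict_proportions(scaled).values,
                                   atol=1e-9)

    def test_too_few_samples_errors(self):
        mic = t.FeatureTable(np.ones((3, 4)), ["a", "b", "c"],
                             [f"f{i}" for i in range(4)], "counts")
        met = t.FeatureTable(np.ones((3, 4)), ["a", "b", "c"],
                             [f"m{i}" for i in range(4)], "intensities")
        with pytest.raises(ValueError, match="latent_dim"):
            t.fit_cooccurrence(mic, met, latent_dim=10, min_feature_count=1)

    def test_default_hyperparameters(self):
        model, *_ = _fit_default(1)
        assert model.hyperparameters["latent_dim"] == 10
        assert model.hyperparameters["min_feature_count"] == 10


class TestPseudoQ2:
    def test_zero_when_model_equals_baseline(self):
        # a model whose U,V are zero predicts softmax(b); choose b matching
        # the pooled proportions so the two coincide
        J = 6
        pooled = np.arange(1.0, J + 1)
        pooled /= pooled.sum()
        model = t.CooccurrenceModel(
            U=pd.DataFrame(np.zeros((2, 3)), index=["g1", "g2"]),
            V=pd.DataFrame(np.zeros((J, 3)), index=[f"m{j}" for j in range(J)]),
            b=pd.Series(np.log(pooled), index=[f"m{j}" for j in range(J)]),
            k=3, train_metabolite_proportions=pooled)
        rng = np.random.default_rng(0)
        mic = t.FeatureTable(rng.random((5, 2)) + 0.1,
                             [f"s{i}" for i in range(5)], ["g1", "g2"], "counts")
        met = t.FeatureTable(rng.random((5, J)), mic.sample_ids,
                             [f"m{j}" for j in range(J)], "intensities")
        assert t.pseudo_q2(model, mic, met) == pytest.approx(0.0, abs=1e-12)

    def test_one_for_perfect_onehot_prediction(self):
        # two microbes, each deterministically producing one metabolite
        big = 50.0
        U = pd.DataFrame(np.array([[big], [-big]]), index=["g1", "g2"])
        V = pd.DataFrame(np.array([[1.0], [-1.0]]), index=["m1", "m2"])
        b = pd.Series([0.0, 0.0], index=["m1", "m2"])
        model = t.CooccurrenceModel(U=U, V=V, b=b, k=1,
                                    train_metabolite_proportions=np.array([0.5, 0.5]))
        mic = t.FeatureTable(np.array([[10.0, 0.0], [0.0, 10.0]]),
                             ["s1", "s2"], ["g1", "g2"], "counts")
        met = t.FeatureTable(np.array([[7.0, 0.0], [0.0, 3.0]]),
                             ["s1", "s2"], ["m1", "m2"], "intensities")
        assert t.pseudo_q2(model, mic, met) == pytest.approx(1.0, abs=1e-6)

    def test_empty_holdout_errors(self):
        model, mic, met, _ = _fit_default(0)
        empty = t.FeatureTable(np.empty((0, mic.n_features)), [],
                               mic.feature_ids, "counts")
        empty_m = t.FeatureTable(np.empty((0, met.n_features)), [],
                                 met.feature_ids, "intensities")
        with pytest.raises(ValueError, match="empty hold-out"):
            t.pseudo_q2(model, empty, empty_m)

    def test_coupled_beats_decoupled(self):
        # coupled data should show predictive skill; decoupled none
        for seed in range(3):
            model, mic, met, _ = _fit_default(seed)
            q2c = _test_q2(model, mic, met)
            model_d, mic_d, met_d, _ = _fit_default(seed, simulate=t.simulate_decoupled)
            q2d = _test_q2(model_d, mic_d, met_d)
            assert q2c > 0.0
            assert q2d <= 0.05
            assert q2c > q2d

    def test_coupled_beats_label_shuffled(self):
        # shuffling sample correspondence destroys the coupling
        wins = 0
        n_seeds = 6
        for seed in range(n_seeds):
            model, mic, met, _ = _fit_default(seed)
            q2 = _test_q2(model, mic, met)
            rng = np.random.default_rng(seed + 500)
            perm = rng.permutation(mic.n_samples)
            mic_shuf = t.FeatureTable(mic.values[perm], mic.sample_ids,
                                      mic.feature_ids, "counts")
            model_s = t.fit_cooccurrence(mic_shuf, met, latent_dim=10, seed=seed)
            q2s = _test_q2(model_s, mic_shuf, met)
            wins += q2 > q2s
        assert wins >= n_seeds - 1


class TestOrdination:
    def test_identical_metabolite_columns_coincide(self):
        U = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)),
                         index=[f"g{i}" for i in range(5)])
        V = pd.DataFrame(np.array([[1.0, 0.5], [1.0, 0.5], [-1.0, 0.2]]),
                         index=["m1", "m2", "m3"])
        b = pd.Series([0.3, 0.3, -0.1], index=V.index)
        model = t.CooccurrenceModel(U=U, V=V, b=b, k=2)
        pcs, arrows, prop = t.cooccurrence_ordination(model)
        np.testing.assert_allclose(pcs.loc["m1"], pcs.loc["m2"], atol=1e-6)

    def test_pc_columns_orthogonal(self):
        model, *_ = _fit_default(0)
        pcs, arrows, prop = t.cooccurrence_ordination(model)
        gram = pcs.values.T @ pcs.values
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-9 * max(1.0, np.abs(gram).max())

    def test_matches_direct_svd_oracle(self):
        rng = np.random.default_rng(3)
        U = pd.DataFrame(rng.normal(size=(6, 3)), index=[f"g{i}" for i in range(6)])
        V = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"m{j}" for j in range(8)])
        b = pd.Series(rng.normal(size=8), index=V.index)
        model = t.CooccurrenceModel(U=U, V=V, b=b, k=3)
        pcs, arrows, prop = t.cooccurrence_ordination(model)
        # oracle: full-rank SVD distances between centred L columns
        L = U.values @ V.values.T + b.values[None, :]
        centred = L - L.mean(0) - L.mean(1, keepdims=True) + L.mean()
        d_oracle = np.linalg.norm(centred[:, :, None] - centred[:, None, :], axis=0)
        # with all singular values retained, sqrt(s)-scaled PC distances equal
        # column distances of centred L up to the square root scaling; check
        # the rank-3 reconstruction instead: pcs @ arrows.T == centred.T
        recon = pcs.values @ arrows.values.T
        np.testing.assert_allclose(recon, centred.T, atol=1e-8)
        assert d_oracle.shape == (8, 8)

    def test_degenerate_matrix_errors(self):
        model = t.CooccurrenceModel(
            U=pd.DataFrame(np.zeros((3, 2)), index=["g1", "g2", "g3"]),
            V=pd.DataFrame(np.zeros((4, 2)), index=[f"m{j}" for j in range(4)]),
            b=pd.Series(np.zeros(4), index=[f"m{j}" for j in range(4)]), k=2)
        with pytest.raises(ValueError, match="degenerate"):
            t.cooccurrence_ordination(model)


class TestTopCooccurring:
    def _model(self):
        rng = np.random.default_rng(5)
        U = pd.DataFrame(rng.normal(size=(40, 3)), index=[f"g{i}" for i in range(40)])
        V = pd.DataFrame(rng.normal(size=(6, 3)), index=[f"m{j}" for j in range(6)])
        b = pd.Series(rng.normal(size=6), index=V.index)
        return t.CooccurrenceModel(U=U, V=V, b=b, k=3)

    def test_singleton_set_is_column_order(self):
        model = self._model()
        ranked = t.top_cooccurring(model, ["m2"], k=40)
        col = model.log_conditional(centred=True)["m2"]
        assert list(ranked.index) == list(col.sort_values(ascending=False).index)

    def test_fraction_selects_ceil(self):
        model = self._model()
        out = t.top_cooccurring(model, ["m1"], k=None, fraction=0.1)
        assert len(out) == 4  # ceil(0.1 * 40)

    def test_k_and_fraction_both_set_errors(self):
        model = self._model()
        with pytest.raises(ValueError, match="not both"):
            t.top_cooccurring(model, ["m1"], k=5, fraction=0.5)

    def test_block_drivers_recovered(self):
        cfg = t.SimulationConfig(seed=7)
        mic, met, md, net, ann, truth = t.simulate_block_coupled(cfg)
        micA, metA, mdA = t.align(mic, met, md)
        model = t.fit_cooccurrence(micA, metA, metadata=mdA, seed=7)
        block_met = [m for m in truth.driver_block["block_1_metabolites"]
                     if m in model.metabolite_ids]
        top = t.top_cooccurring(model, block_met, k=10)
        hits = len(set(top.index) & set(truth.driver_block["block_1_microbes"]))
        assert hits >= 8
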
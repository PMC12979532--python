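"""Transformer regressor: gradients, forward contracts, training mechanics,
transfer modes, checkpointing."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from phenoformer.model import (ModelConfig, SplitSpec, TransformerRegressor,
                               load_model, save_model, train_model, transfer)
from phenoformer.tokens import NormalizationStats, TokenDataset, TokenLayout


def tiny_model(seed=3, dropout=0.0, **kw):
    layout = TokenLayout(n_timepoints=3, interval_days=28)
    stats = NormalizationStats(weather_mean=np.zeros((6, 3)),
                               weather_sd=np.ones((6, 3)),
                               loc_mean=np.zeros(2), loc_sd=np.ones(2))
    stats.fit_trait("yield", np.array([1.0, 2.0, 3.0]))
    cfg = ModelConfig(d_model=16, n_layers=2, n_heads=2, d_ff=24,
                      dropout=dropout, seed=seed, **kw)
    return TransformerRegressor(layout, n_clusters=4, config=cfg, stats=stats,
                                trait="yield"), layout


def random_batch(layout, n=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, layout.n_tokens, 3))
    for idx, hi in ((layout.geno_index, 6), (layout.mg_index, 12)):
        X[:, idx] = 0.0
        X[:, idx, 0] = rng.integers(2, hi, n)
    return X


def promote_to_float64(model):
    """Run the gradient checks in double precision: parameters are float32
    for speed, but NumPy promotes the whole forward pass once they are
    float64, making central differences numerically clean."""
    for p in model.params():
        p.value = p.value.astype(np.float64)
        p.grad = np.zeros_like(p.value)
    return model


class TestGradients:
    def test_parameter_gradients_match_finite_differences(self):
        """Backprop through the full stack vs central differences."""
        model, layout = tiny_model()
        promote_to_float64(model)
        X = random_batch(layout)

        def loss():
            return float(0.5 * np.sum(model.forward(X) ** 2))

        for p in model.params():
            p.zero_grad()
        yhat = model.forward(X)
        model.backward_to_params(yhat)

        rng = np.random.default_rng(1)
        eps = 1e-6
        for p in model.params():
            flat = p.value.reshape(-1)
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                fd = (lp - lm) / (2 * eps)
                an = p.grad.reshape(-1)[i]
                assert abs(fd - an) <= 1e-4 * (abs(fd) + abs(an)) + 1e-6, \
                    f"{p.name}[{i}]: fd={fd} analytic={an}"

    def test_input_gradient_matches_finite_differences(self):
        model, layout = tiny_model()
        promote_to_float64(model)
        X = random_batch(layout)
        e = model.embed(X).astype(np.float64)
        g = model.input_gradient(e)
        eps = 1e-6
        for (b, t, c) in [(0, 1, 5), (1, layout.geno_index, 3), (2, 10, 0)]:
            ep = e.copy(); ep[b, t, c] += eps
            em = e.copy(); em[b, t, c] -= eps
            fd = (np.sum(model.forward_embedded(ep))
                  - np.sum(model.forward_embedded(em))) / (2 * eps)
            assert abs(fd - g[b, t, c]) < 1e-5 * (1 + abs(fd))


class TestForward:
    def test_attention_rows_are_distributions(self):
        model, layout = tiny_model()
        X = random_batch(layout, n=4)
        maps = model.attention_maps(X)
        np.testing.assert_allclose(maps.sum(axis=-1), 1.0, atol=1e-5)
        assert maps.shape == (4, 2, 2, layout.n_tokens, layout.n_tokens)

    def test_eval_forward_deterministic(self):
        model, layout = tiny_model(dropout=0.3)
        X = random_batch(layout)
        np.testing.assert_array_equal(model.forward(X), model.forward(X))

    def test_model_is_position_sensitive(self):
        """Swapping two weather tokens' contents (without swapping their
        positional encodings) changes the prediction."""
        model, layout = tiny_model()
        X = random_batch(layout, n=1)
        Xs = X.copy()
        Xs[0, [2, 9]] = Xs[0, [9, 2]]
        assert not np.allclose(model.forward(X), model.forward(Xs))

    def test_masked_category_token_embeds_to_zero(self):
        model, layout = tiny_model()
        X = random_batch(layout, n=1)
        X[0, layout.geno_index, 0] = 0  # reserved mask code
        e = model.embed(X)
        np.testing.assert_array_equal(e[0, layout.geno_index], 0.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(d_model=30, n_heads=4)
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.5)


def make_dataset(layout, n=120, seed=0, linear_weight=2.0):
    """Small dataset with a linear signal on one weather channel."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n, layout.n_tokens, 3), dtype=np.float32)
    X[:, : layout.n_weather_tokens] = rng.normal(
        size=(n, layout.n_weather_tokens, 3))
    X[:, layout.geno_index, 0] = rng.integers(2, 6, n)
    X[:, layout.mg_index, 0] = rng.integers(2, 12, n)
    y = linear_weight * X[:, 4, 2].astype(float)
    stats = NormalizationStats(weather_mean=np.zeros((6, 3)),
                               weather_sd=np.ones((6, 3)),
                               loc_mean=np.zeros(2), loc_sd=np.ones(2))
    return TokenDataset(X=X, traits={"yield": y, "oil": y.copy()},
                        index=pd.DataFrame({"row": np.arange(n)}),
                        layout=layout, stats=stats, n_clusters=4)


class TestTraining:
    layout = TokenLayout(n_timepoints=3, interval_days=28)

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        ds = make_dataset(self.layout)
        cfg = ModelConfig(d_model=16, n_layers=1, n_heads=2, d_ff=24,
                          dropout=0.0, lr=0.0, max_epochs=2, patience=5, seed=0)
        model = TransformerRegressor(ds.layout, 4, cfg, ds.stats, "yield")
        before = {k: v.copy() for k, v in model.state_dict().items()}
        res = train_model(ds, "yield", cfg, SplitSpec(seed=0), model=model)
        after = res.model.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])
        tl = res.history["train_loss"]
        assert np.allclose(tl, tl.iloc[0], rtol=1e-5)

    def test_reported_loss_is_mse_on_standardized_targets(self):
        ds = make_dataset(self.layout)
        cfg = ModelConfig(d_model=16, n_layers=1, n_heads=2, d_ff=24,
                          dropout=0.0, lr=0.0, batch_size=1000, max_epochs=1,
                          patience=5, seed=0)
        res = train_model(ds, "yield", cfg, SplitSpec(seed=0))
        tr = res.split[0]
        y = ds.stats.standardize_trait("yield", ds.traits["yield"][tr])
        yhat = res.model.forward(ds.X[tr])
        hand = float(np.mean((yhat - y) ** 2))
        assert abs(res.history["train_loss"].iloc[0] - hand) < 1e-5

    def test_early_stop_patience_epochs_past_best(self):
        """With lr = 0 validation never improves after epoch 0, so training
        halts exactly `patience` epochs later."""
        ds = make_dataset(self.layout)
        cfg = ModelConfig(d_model=16, n_layers=1, n_heads=2, d_ff=24,
                          dropout=0.0, lr=0.0, max_epochs=50, patience=4, seed=0)
        res = train_model(ds, "yield", cfg, SplitSpec(seed=0))
        assert len(res.history) == 5  # epoch 0 (best) + 4 non-improving

    def test_records_missing_trait_are_excluded(self):
        ds = make_dataset(self.layout)
        ds.traits["yield"][:20] = np.nan
        cfg = ModelConfig(d_model=16, n_layers=1, n_heads=2, d_ff=24,
                          dropout=0.0, lr=1e-3, max_epochs=1, patience=2, seed=0)
        res = train_model(ds, "yield", cfg, SplitSpec(seed=0))
        assert res.n_excluded == 20

    def test_empty_partition_rejected(self):
        ds = make_dataset(self.layout, n=5)
        cfg = ModelConfig(d_model=16, n_layers=1, n_heads=2, d_ff=24)
        with pytest.raises(ValueError):
            train_model(ds, "yield", cfg,
                        (np.arange(4), np.array([], dtype=int), np.array([4])))


class TestTransfer:
    layout = TokenLayout(n_timepoints=3, interval_days=28)

    @staticmethod
    def _pretrained(ds):
        cfg = ModelConfig(d_model=16, n_layers=1, n_heads=2, d_ff=24,
                          dropout=0.0, lr=1e-3, max_epochs=3, patience=5, seed=0)
        return train_model(ds, "yield", cfg, SplitSpec(seed=0)).model, cfg

    def test_frozen_mode_keeps_encoder_bit_identical(self):
        ds = make_dataset(self.layout)
        pre, cfg = self._pretrained(ds)
        before = {p.name: p.value.copy() for p in pre.encoder_params()}
        res = transfer(pre, ds, "oil", "frozen",
                       replace(cfg, max_epochs=3, seed=1), SplitSpec(seed=1))
        after = {p.name: p.value for p in res.model.encoder_params()}
        for k, v in before.items():
            np.testing.assert_array_equal(v, after[k])
        # and the head did move
        assert not np.array_equal(pre.head.W.value, res.model.head.W.value)

    def test_finetune_zero_epochs_is_pretrained_encoder_plus_fresh_head(self):
        ds = make_dataset(self.layout)
        pre, cfg = self._pretrained(ds)
        res = transfer(pre, ds, "oil", "finetune",
                       replace(cfg, max_epochs=0, seed=1), SplitSpec(seed=1))
        for p, q in zip(res.model.encoder_params(), pre.encoder_params()):
            np.testing.assert_array_equal(p.value, q.value)

    def test_vanilla_ignores_pretrained(self):
        ds = make_dataset(self.layout)
        pre, cfg = self._pretrained(ds)
        a = transfer(None, ds, "oil", "vanilla",
                     replace(cfg, max_epochs=1, seed=2), SplitSpec(seed=2))
        b = transfer(pre, ds, "oil", "vanilla",
                     replace(cfg, max_epochs=1, seed=2), SplitSpec(seed=2))
        np.testing.assert_array_equal(a.model.head.W.value, b.model.head.W.value)

    def test_unknown_mode_and_missing_pretrained_rejected(self):
        ds = make_dataset(self.layout)
        cfg = ModelConfig(d_model=16, n_layers=1, n_heads=2, d_ff=24)
        with pytest.raises(ValueError):
            transfer(None, ds, "oil", "warm", cfg, SplitSpec())
        with pytest.raises(ValueError):
            transfer(None, ds, "oil", "frozen", cfg, SplitSpec())


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        model, layout = tiny_model(seed=9)
        X = random_batch(layout, n=5)
        path = tmp_path / "model.npz"
        save_model(model, path)
        clone = load_model(path)
        np.testing.assert_array_equal(model.predict(X), clone.predict(X))
        assert clone.trait == "yield" and clone.config.d_model == 16


class TestSplit:
    def test_partition_disjoint_exhaustive(self):
        tr, va, te = SplitSpec(seed=3).indices(97)
        allidx = np.sort(np.concatenate([tr, va, te]))
        np.testing.assert_array_equal(allidx, np.arange(97))

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SplitSpec(train=0.5, val=0.1, test=0.1).indices(50)
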
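"""Importance scores: attention aggregation, attribution axioms,
aggregation tables."""

import numpy as np
import pandas as pd
import pytest

from phenoformer.interpret import (ATTRIBUTION_METHODS, CapabilityError,
                                   ImportanceScores, aggregate_attention_maps,
                                   aggregate_importance, attention_importance,
                                   attribution, ig_attribution,
                                   integrated_gradients, oracle_scores,
                                   random_scores, scores_table)
from phenoformer.tokens import TokenLayout, TokenSequence

from tests.test_model import random_batch, tiny_model


class TestAttentionAggregation:
    def test_uniform_maps_give_uniform_scores(self):
        T = 12
        maps = np.full((3, 2, T, T), 1.0 / T)
        np.testing.assert_allclose(aggregate_attention_maps(maps),
                                   np.full(T, 1.0 / T))

    def test_strongly_attended_token_ranks_first(self):
        T, rng = 10, np.random.default_rng(0)
        maps = rng.random((4, 2, T, T))
        maps[..., 3] *= 10.0  # token 3 receives ~10x attention in every head
        maps /= maps.sum(axis=-1, keepdims=True)
        agg = aggregate_attention_maps(maps)
        assert np.argmax(agg) == 3

    def test_head_layer_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        maps = rng.random((3, 4, 8, 8))
        maps /= maps.sum(axis=-1, keepdims=True)
        perm = rng.permutation(4)
        np.testing.assert_allclose(aggregate_attention_maps(maps),
                                   aggregate_attention_maps(maps[:, perm]))

    def test_model_scores_sum_to_one(self):
        model, layout = tiny_model()
        X = random_batch(layout, n=1)
        sc = attention_importance(model, TokenSequence(X[0], layout))
        assert abs(sc.scores.sum() - 1.0) < 1e-6
        assert (sc.scores >= 0).all() and sc.T == layout.n_tokens


class TestIntegratedGradients:
    def test_linear_model_closed_form(self):
        """IG of f(x) = w . x from a zero baseline is exactly w_i * x_i."""
        rng = np.random.default_rng(2)
        w = rng.normal(size=7)
        x = rng.normal(size=7)
        attr = integrated_gradients(lambda z: float(w @ z), lambda z: w, x,
                                    steps=8)
        np.testing.assert_allclose(attr, w * x, atol=1e-12)

    def test_completeness_on_transformer(self, tiny_run):
        """Sum of signed attributions equals f(x) - f(baseline) within 1%
        at 256 steps, on a trained model's held-out samples."""
        data, run = tiny_run
        model, ds = run.train.model, run.dataset
        for i in run.split[2][:5]:
            attr, fx, f0 = ig_attribution(model, ds.sequence(i), steps=256)
            gap = fx - f0
            assert abs(attr.sum() - gap) <= 0.01 * abs(gap)

    def test_step_doubling_barely_moves_top_tokens(self):
        model, layout = tiny_model(seed=5)
        X = random_batch(layout, n=1, seed=5)
        seq = TokenSequence(X[0], layout)
        a = attribution(model, seq, "integrated_gradients", steps=64).scores
        b = attribution(model, seq, "integrated_gradients", steps=128).scores
        top_a = np.argsort(-a)[:5]
        rank_b = {t: r for r, t in enumerate(np.argsort(-b))}
        for pos, tok in enumerate(top_a):
            assert abs(rank_b[tok] - pos) <= 1


class TestAttributionAdapters:
    def test_unavailable_adapter_raises_capability_error(self):
        model, layout = tiny_model()
        X = random_batch(layout, n=1)
        with pytest.raises(CapabilityError):
            attribution(model, TokenSequence(X[0], layout), "deeplift")
        with pytest.raises(ValueError):
            attribution(model, TokenSequence(X[0], layout), "saliency++")

    @pytest.mark.parametrize("method", ATTRIBUTION_METHODS)
    def test_available_methods_produce_normalized_scores(self, method):
        model, layout = tiny_model()
        X = random_batch(layout, n=1)
        sc = attribution(model, TokenSequence(X[0], layout), method, seed=3)
        assert sc.T == layout.n_tokens
        assert abs(sc.scores.sum() - 1.0) < 1e-6
        assert (sc.scores >= 0).all()


class TestAggregation:
    layout = TokenLayout(n_timepoints=2, interval_days=28)

    def _scores(self, n=3):
        rng = np.random.default_rng(4)
        return [ImportanceScores(rng.random(self.layout.n_tokens), "m", str(i))
                for i in range(n)]

    def test_single_sample_table_reproduces_scores(self):
        sc = self._scores(1)
        table = scores_table(sc, self.layout)
        np.testing.assert_allclose(table["score"].to_numpy(), sc[0].scores)

    def test_group_means_match_hand_computation(self):
        sc = self._scores(3)
        out = aggregate_importance(sc, self.layout, "variable_timepoint")
        stacked = np.stack([s.scores for s in sc])
        row = out[(out["variable"] == "rad") & (out["timepoint"] == 1)]
        tok = self.layout.token_index(5, 1)
        assert abs(row["score_mean"].iloc[0] - stacked[:, tok].mean()) < 1e-12

    def test_weather_vs_context_sums_to_one_per_sample(self):
        sc = self._scores(4)
        out = aggregate_importance(sc, self.layout, "weather_vs_context")
        assert set(out["group"]) == {"weather", "location", "genotype", "maturity"}
        assert abs(out["score_mean"].sum() - 1.0) < 1e-9

    def test_maturity_grouping_requires_metadata(self):
        with pytest.raises(ValueError):
            aggregate_importance(self._scores(), self.layout, "maturity_group")
        meta = pd.DataFrame({"maturity_group": [1, 1, 7]})
        out = aggregate_importance(self._scores(), self.layout,
                                   "maturity_group", sample_meta=meta)
        assert set(out["maturity_group"]) == {1, 7}

    def test_mismatched_layout_rejected(self):
        other = TokenLayout(n_timepoints=5, interval_days=14)
        with pytest.raises(ValueError):
            scores_table(self._scores(1), other)


class TestReferenceExplainers:
    def test_oracle_marks_exactly_overlapping_tokens(self):
        lay = TokenLayout(n_timepoints=4, interval_days=28)
        windows = [(5, 30, 60, 1.0)]  # rad, days 30-60 -> windows 1 and 2
        sc = oracle_scores(lay, windows, n_days=112)
        hot = np.flatnonzero(sc.scores > 0)
        np.testing.assert_array_equal(
            hot, [lay.token_index(5, 1), lay.token_index(5, 2)])

    def test_random_scores_deterministic_per_seed(self):
        lay = TokenLayout(n_timepoints=4, interval_days=28)
        a, b = random_scores(lay, seed=9), random_scores(lay, seed=9)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            ImportanceScores(np.array([0.5, -0.1]), "bad")
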
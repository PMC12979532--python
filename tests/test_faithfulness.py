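"""Perturbation faithfulness: ranking, masking arithmetic, AOPCR oracle
equivalence, method comparison plumbing."""

import numpy as np
import pytest

from phenoformer.faithfulness import (FaithfulnessReport, PerturbationLevels,
                                      compare_methods, evaluate_faithfulness,
                                      n_masked, perturb, rank_tokens)
from phenoformer.interpret import ImportanceScores, random_scores
from phenoformer.tokens import TokenLayout, TokenSequence

from tests.test_model import random_batch, tiny_model


class TestRanking:
    def test_strictly_decreasing_scores_identity_order(self):
        sc = ImportanceScores(np.linspace(1.0, 0.1, 8), "m")
        np.testing.assert_array_equal(rank_tokens(sc), np.arange(8))

    def test_all_equal_scores_tie_break_ascending(self):
        sc = ImportanceScores(np.full(6, 0.5), "m")
        np.testing.assert_array_equal(rank_tokens(sc), np.arange(6))

    def test_matches_independent_sort_oracle(self):
        rng = np.random.default_rng(3)
        s = rng.random(40)
        sc = ImportanceScores(s, "m")
        oracle = sorted(range(40), key=lambda i: (-sc.scores[i], i))
        np.testing.assert_array_equal(rank_tokens(sc), oracle)


class TestPerturb:
    lay = TokenLayout(n_timepoints=16, interval_days=14)  # T = 99

    def _seq(self):
        rng = np.random.default_rng(0)
        return TokenSequence(rng.normal(size=(self.lay.n_tokens, 3)), self.lay)

    def test_rounding_rule(self):
        assert n_masked(5.0, 99) == 5      # round(4.95)
        assert n_masked(7.5, 99) == 7      # round(7.425)
        assert n_masked(0.1, 99) == 1      # minimum of one token

    def test_settings_mask_complementary_sets(self):
        seq = self._seq()
        ranking = np.argsort(-np.random.default_rng(1).random(99))
        _, comp = perturb(seq, ranking, 10.0, "comprehensiveness")
        _, suff = perturb(seq, ranking, 10.0, "sufficiency")
        np.testing.assert_array_equal(comp + suff, np.ones(99))

    def test_sufficiency_at_100_percent_changes_nothing(self):
        seq = self._seq()
        ranking = np.arange(99)
        out, scale = perturb(seq, ranking, 100.0, "sufficiency")
        assert scale.all()
        np.testing.assert_array_equal(out.tokens, seq.tokens)

    def test_masked_tokens_zeroed_and_meta_preserved(self):
        seq = self._seq()
        ranking = np.arange(99)
        out, scale = perturb(seq, ranking, 5.0, "comprehensiveness")
        assert (out.tokens[:5] == 0).all()
        assert out.layout is seq.layout
        np.testing.assert_array_equal(out.tokens[5:], seq.tokens[5:])

    def test_restricted_masking_leaves_context_alone(self):
        seq = self._seq()
        ranking = np.argsort(-np.random.default_rng(2).random(99))
        maskable = self.lay.weather_mask()
        _, comp = perturb(seq, ranking, 25.0, "comprehensiveness", maskable)
        _, suff = perturb(seq, ranking, 25.0, "sufficiency", maskable)
        for idx in (self.lay.loc_index, self.lay.geno_index, self.lay.mg_index):
            assert comp[idx] == 1 and suff[idx] == 1
        assert (comp + suff)[maskable].sum() == maskable.sum()

    def test_bad_arguments_rejected(self):
        seq = self._seq()
        with pytest.raises(ValueError):
            perturb(seq, np.arange(99), 0.0, "comprehensiveness")
        with pytest.raises(ValueError):
            perturb(seq, np.arange(99), 10.0, "ablate")


class TestLevels:
    def test_default_levels(self):
        assert PerturbationLevels().levels == (5.0, 7.5, 10.0, 15.0, 25.0)

    def test_must_be_increasing_in_range(self):
        with pytest.raises(ValueError):
            PerturbationLevels((10.0, 5.0))
        with pytest.raises(ValueError):
            PerturbationLevels((0.0, 5.0))
        with pytest.raises(ValueError):
            PerturbationLevels(())


def brute_force_aopcr(model, explainer, X, levels, maskable=None):
    """Independent per-sample/per-level loop over `perturb`, for oracle
    equivalence with the vectorized evaluation."""
    lay = model.layout
    T = lay.n_tokens
    out = {}
    for setting in ("comprehensiveness", "sufficiency"):
        per_level = []
        for k in levels:
            diffs = []
            for i in range(len(X)):
                seq = TokenSequence(np.asarray(X[i], float), lay)
                sc = explainer(model, seq, str(i))
                _, scale = perturb(seq, rank_tokens(sc), k, setting, maskable)
                base = model.predict(X[i:i + 1])[0]
                pert = model.predict(X[i:i + 1], token_scale=scale[None])[0]
                diffs.append(abs(base - pert))
            per_level.append(float(np.mean(diffs)))
        out[f"{setting}_mae"] = float(np.mean(per_level))
    return out


class TestEvaluate:
    def test_constant_model_all_deltas_zero(self):
        model, layout = tiny_model()
        model.head.W.value[...] = 0.0
        model.head.b.value[...] = 0.0
        X = random_batch(layout, n=4)
        rep = evaluate_faithfulness(
            model, lambda m, s, sid: random_scores(layout, seed=int(sid)), X)
        assert all(v == 0.0 for v in rep.aopcr.values())

    def test_aopcr_is_unweighted_mean_of_levels(self):
        model, layout = tiny_model()
        X = random_batch(layout, n=3)
        rep = evaluate_faithfulness(
            model, lambda m, s, sid: random_scores(layout, seed=int(sid)), X)
        for setting in ("comprehensiveness", "sufficiency"):
            hand = float(np.mean(rep.per_level[setting]["mae"]))
            assert abs(rep.aopcr[f"{setting}_mae"] - hand) < 1e-12

    def test_matches_brute_force_recomputation_exactly(self):
        """Vectorized AOPCR equals an independent loop on a 10-sample
        fixture, both unrestricted and weather-restricted."""
        model, layout = tiny_model(seed=11)
        X = random_batch(layout, n=10, seed=11)
        expl = lambda m, s, sid: random_scores(layout, seed=70 + int(sid))
        for maskable in (None, layout.weather_mask()):
            rep = evaluate_faithfulness(model, expl, X, maskable=maskable)
            brute = brute_force_aopcr(model, expl, X,
                                      PerturbationLevels().levels, maskable)
            for key, v in brute.items():
                # tolerance only for float32 batching noise in the forward
                # pass; the aggregation itself is exact
                assert rep.aopcr[key] == pytest.approx(v, abs=1e-6), key

    def test_empty_sample_set_rejected(self):
        model, layout = tiny_model()
        with pytest.raises(ValueError):
            evaluate_faithfulness(
                model, lambda m, s, sid: random_scores(layout, 0),
                np.empty((0, layout.n_tokens, 3)))

    def test_report_serialization_round_trip(self):
        model, layout = tiny_model()
        X = random_batch(layout, n=3)
        rep = evaluate_faithfulness(
            model, lambda m, s, sid: random_scores(layout, seed=int(sid)), X)
        back = FaithfulnessReport.from_json(rep.to_json())
        assert back == rep


class TestCompare:
    def test_method_against_itself_identical(self):
        model, layout = tiny_model()
        X = random_batch(layout, n=4)
        fn = lambda m, s, sid: random_scores(layout, seed=int(sid))
        table, reports = compare_methods(model, {"a": fn, "b": fn}, X)
        assert reports["a"].aopcr == reports["b"].aopcr

    def test_failing_adapter_reported_not_fatal(self):
        model, layout = tiny_model()
        X = random_batch(layout, n=3)

        def broken(m, s, sid):
            raise RuntimeError("adapter exploded")

        ok = lambda m, s, sid: random_scores(layout, seed=int(sid))
        table, reports = compare_methods(model, {"ok": ok, "broken": broken}, X)
        row = table[table["method"] == "broken"].iloc[0]
        assert row["failed"] and "exploded" in row["error"]
        assert "ok" in reports and "broken" not in reports

    def test_needs_two_methods(self):
        model, layout = tiny_model()
        with pytest.raises(ValueError):
            compare_methods(model, {"only": lambda m, s, sid: None},
                            random_batch(layout, n=2))
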
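"""Model construction, training behaviour, checkpoints, hyperparameter search."""

import numpy as np
import pytest

from adesig import build_vocabulary, roc_auc
from adesig.model import (
    Adam, CheckpointError, SDAJMConfig, SDAJMModel, SearchSpace, build_model,
    optimize_hyperparameters, predict_proba, train,
)
from adesig._nn import Parameter
from tests.conftest import reduced_config


def _fresh_model(records, soc_map, config):
    corpus = sorted({d.smiles for r in records for d in r.drugs})
    vocab = build_vocabulary(corpus, max_len=config.max_len)
    pts = sorted({a.pt_label for r in records for a in r.adrs})
    return build_model(config, vocab, soc_map, pts)


class TestConstruction:
    def test_same_seed_identical_parameters(self, tiny_planted):
        records, soc_map, _ = tiny_planted
        cfg = reduced_config()
        a = _fresh_model(records, soc_map, cfg)
        b = _fresh_model(records, soc_map, cfg)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_head_is_three_layers_plus_final_logit(self, tiny_planted):
        records, soc_map, _ = tiny_planted
        m = _fresh_model(records, soc_map, reduced_config())
        assert len(m.head.w) == 3 and len(m.head.norms) == 3
        assert m.head.w_out.data.shape[1] == 1  # single logit out

    def test_fused_width_is_sum_of_channels(self, tiny_planted):
        records, soc_map, _ = tiny_planted
        cfg = reduced_config()
        m = _fresh_model(records, soc_map, cfg)
        expect = 3 + 167 + cfg.gin_hidden_dim + cfg.seq_embed_dim + 27 + cfg.adr_embed_dim
        assert m.head.w[0].data.shape[0] == expect

    def test_dropout_applied_after_first_two_relus_only(self, tiny_planted):
        records, soc_map, _ = tiny_planted
        m = _fresh_model(records, soc_map, reduced_config(predictor_dropout=0.5))

        calls = []

        class CountingRng:
            def random(self, shape):
                calls.append(shape)
                return np.full(shape, 0.99)  # keep everything

        from adesig._nn import Tensor
        x = Tensor(np.zeros((8, m.head.w[0].data.shape[0])))
        m.head.forward(x, training=True, rng=CountingRng())
        assert len(calls) == 2  # dropout masks drawn exactly twice

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SDAJMConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            SDAJMConfig(batch_size=4)
        with pytest.raises(ValueError):
            SDAJMConfig(predictor_dropout=1.0)


class TestTraining:
    def test_zero_step_size_leaves_parameters_unchanged(self):
        p = Parameter(np.array([1.0, -2.0, 3.0]))
        opt = Adam([p], lr=0.0)
        p.grad = np.ones(3)
        opt.step()
        np.testing.assert_array_equal(p.data, [1.0, -2.0, 3.0])

    def test_loss_decreases_on_planted_data(self, tiny_planted):
        # epoch-5 loss below epoch-1 loss, majority over 3 seeds
        records, soc_map, _ = tiny_planted
        wins = 0
        for seed in range(3):
            cfg = reduced_config(epochs=5, seed=seed)
            m = _fresh_model(records, soc_map, cfg)
            train(m, records, cfg)
            if m.training_log[4]["loss"] < m.training_log[0]["loss"]:
                wins += 1
        assert wins >= 2

    def test_single_class_labels_warn_but_train(self, tiny_planted):
        from dataclasses import replace
        records, soc_map, _ = tiny_planted
        flat = [replace(r, drugs=tuple(replace(d, suspect=0) for d in r.drugs))
                for r in records[:40]]
        cfg = reduced_config(epochs=1)
        m = _fresh_model(flat, soc_map, cfg)
        with pytest.warns(RuntimeWarning, match="single-class"):
            train(m, flat, cfg)

    def test_predictions_are_probabilities_and_deterministic(self, tiny_planted):
        records, soc_map, _ = tiny_planted
        cfg = reduced_config(epochs=2)
        m = _fresh_model(records, soc_map, cfg)
        train(m, records[:60], cfg)
        rec = records[0]
        p1 = predict_proba(m, rec, 0)
        p2 = predict_proba(m, rec, 0)
        assert 0.0 < p1 < 1.0
        assert abs(p1 - p2) < 1e-7

    def test_drug_index_validated(self, tiny_planted):
        records, soc_map, _ = tiny_planted
        cfg = reduced_config(epochs=1)
        m = _fresh_model(records, soc_map, cfg)
        train(m, records[:40], cfg)
        with pytest.raises(IndexError):
            predict_proba(m, records[0], 99)

    def test_noise_free_planted_signal_recovered(self):
        # p1=1, p0=0: after training, high-stratum instances score > 0.5
        from adesig import SyntheticConfig, generate_ade_records
        syn = SyntheticConfig(n_records=400, p_suspect_given_marker_and_soc=1.0,
                              p_suspect_otherwise=0.0, seed=21)
        records, soc_map, truth = generate_ade_records(syn)
        cfg = reduced_config(epochs=20, seed=0)
        m = _fresh_model(records, soc_map, cfg)
        train(m, records, cfg)
        scores = m.predict_scores(records)
        labels = np.array([d.suspect for r in records for d in r.drugs])
        hi_scores = scores[labels == 1]
        assert np.mean(hi_scores > 0.5) >= 0.95


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tiny_planted, tmp_path):
        records, soc_map, _ = tiny_planted
        cfg = reduced_config(epochs=2)
        m = _fresh_model(records, soc_map, cfg)
        train(m, records[:80], cfg)
        before = m.predict_scores(records[:20])
        p = tmp_path / "ckpt.json"
        m.save(p)
        restored = SDAJMModel.load(p)
        after = restored.predict_scores(records[:20])
        assert np.abs(before - after).max() < 1e-7

    def test_arrays_restored_bit_exactly(self, tiny_planted, tmp_path):
        records, soc_map, _ = tiny_planted
        cfg = reduced_config(epochs=1)
        m = _fresh_model(records, soc_map, cfg)
        train(m, records[:40], cfg)
        p = tmp_path / "ckpt.json"
        m.save(p)
        r = SDAJMModel.load(p)
        for pa, pb in zip(m.parameters(), r.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_missing_checkpoint_named(self, tmp_path):
        with pytest.raises(CheckpointError, match="nowhere.json"):
            SDAJMModel.load(tmp_path / "nowhere.json")

    def test_version_mismatch_is_clear_error(self, tiny_planted, tmp_path):
        import json
        records, soc_map, _ = tiny_planted
        cfg = reduced_config(epochs=1)
        m = _fresh_model(records, soc_map, cfg)
        train(m, records[:40], cfg)
        p = tmp_path / "old.json"
        m.save(p)
        obj = json.loads(p.read_text())
        obj["format_version"] = "someone-elses-format"
        p.write_text(json.dumps(obj))
        with pytest.raises(CheckpointError, match="format"):
            SDAJMModel.load(p)


class TestHyperparameterSearch:
    def test_budget_one_returns_the_sampled_config(self):
        space = SearchSpace(ranges={"learning_rate": (1e-4, 1e-2, "log")},
                            budget=1)
        best, trials = optimize_hyperparameters(lambda cfg: 0.5, space, seed=0)
        assert len(trials) == 1
        assert best.learning_rate == trials[0]["values"]["learning_rate"]

    def test_degenerate_single_point_space(self):
        space = SearchSpace(ranges={"batch_size": [32]}, budget=3)
        best, trials = optimize_hyperparameters(lambda cfg: 1.0, space, seed=0)
        assert best.batch_size == 32

    def test_failed_trials_marked_and_search_continues(self):
        calls = []

        def flaky(cfg):
            calls.append(cfg)
            if len(calls) == 1:
                raise RuntimeError("diverged")
            return cfg.learning_rate

        space = SearchSpace(ranges={"learning_rate": (1e-4, 1e-2, "log")},
                            budget=4)
        best, trials = optimize_hyperparameters(flaky, space, seed=1)
        assert np.isnan(trials[0]["score"])
        assert sum(np.isfinite(t["score"]) for t in trials) == 3

    def test_best_of_trials_beats_median_on_planted_data(self, tiny_planted):
        # real trial log: train tiny models, objective = held-out ROC-AUC
        records, soc_map, _ = tiny_planted
        fit, hold = records[:150], records[150:]

        def objective(cfg):
            m = _fresh_model(fit, soc_map, cfg)
            train(m, fit, cfg)
            labels = np.array([d.suspect for r in hold for d in r.drugs])
            return roc_auc(labels, m.predict_scores(hold))

        space = SearchSpace(
            ranges={"learning_rate": (3e-4, 1e-2, "log"),
                    "predictor_dropout": (0.0, 0.4, "linear")},
            budget=8)
        base = reduced_config(epochs=3)
        best, trials = optimize_hyperparameters(objective, space,
                                                base_config=base, seed=2)
        scores = [t["score"] for t in trials if np.isfinite(t["score"])]
        assert max(scores) >= np.median(scores)
        assert best.epochs == 3  # non-searched fields come from the base

    def test_empty_or_invalid_space_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(ranges={}, budget=2)
        with pytest.raises(ValueError):
            SearchSpace(ranges={"learning_rate": [1e-3]}, budget=0)
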
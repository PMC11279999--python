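"""Metrics vs brute-force oracles, split integrity, CV plumbing, benchmark."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adesig import (
    ADRTerm, SyntheticConfig, UndefinedMetricWarning, build_vocabulary,
    compute_metrics, cross_validate, detect_signals, drug_seen_in_training,
    generate_ade_records, generate_drug_pool, generate_molprop_dataset,
    make_split, prc_auc, roc_auc, run_benchmark,
)
from adesig.evaluation import SplitError
from adesig.model import build_model, train
from tests.conftest import reduced_config


# ----------------------------------------------------------------------
# independent oracles
# ----------------------------------------------------------------------

def oracle_counts(labels, scores, thr):
    tp = fp = tn = fn = 0
    for y, s in zip(labels, scores):
        pred = 1 if s >= thr else 0
        if pred and y:
            tp += 1
        elif pred and not y:
            fp += 1
        elif not pred and y:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def oracle_roc_auc(labels, scores):
    """All-pairs comparison; ties count 1/2."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    if not pos or not neg:
        return None
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_all_correct(self):
        r = compute_metrics([1, 0, 1, 0], [0.9, 0.1, 0.8, 0.2])
        assert r.accuracy == 1.0 and r.f1 == 1.0 and r.roc_auc == 1.0

    def test_worked_confusion_example(self):
        # TP=3 FP=1 FN=2 TN=4
        labels = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        scores = [0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.3, 0.2, 0.1, 0.05]
        r = compute_metrics(labels, scores)
        assert (r.counts.tp, r.counts.fp, r.counts.fn, r.counts.tn) == (3, 1, 2, 4)
        assert r.precision == pytest.approx(0.75)
        assert r.recall == pytest.approx(0.6)
        assert r.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)
        assert r.accuracy == pytest.approx(0.7)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = 100
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            # quantized scores force ties through the tie-correction path
            scores = np.round(rng.random(n), 2)
            thr = float(rng.random())
            r = compute_metrics(labels, scores, threshold=thr)
            tp, tn, fp, fn = oracle_counts(labels, scores, thr)
            assert (r.counts.tp, r.counts.tn, r.counts.fp, r.counts.fn) == (tp, tn, fp, fn)
            assert abs(r.roc_auc - oracle_roc_auc(labels, scores)) < 1e-12

    def test_prc_auc_matches_reference_average_precision(self):
        from sklearn.metrics import average_precision_score
        rng = np.random.default_rng(1)
        for _ in range(50):
            labels = rng.integers(0, 2, size=80)
            if labels.sum() == 0:
                labels[0] = 1
            scores = np.round(rng.random(80), 2)
            assert prc_auc(labels, scores) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12)

    def test_undefined_precision_reported_not_zeroed(self):
        with pytest.warns(UndefinedMetricWarning):
            r = compute_metrics([1, 1, 0], [0.1, 0.2, 0.3], threshold=0.9)
        assert r.precision is None
        assert r.recall == 0.0

    def test_single_class_auc_undefined(self):
        assert roc_auc([1, 1, 1], [0.5, 0.6, 0.7]) is None

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1),
                              st.floats(0, 1, allow_nan=False)),
                    min_size=2, max_size=40))
    def test_f1_between_precision_and_recall(self, pairs):
        labels = [y for y, _ in pairs]
        scores = [s for _, s in pairs]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UndefinedMetricWarning)
            r = compute_metrics(labels, scores)
        if r.precision is not None and r.recall is not None and r.f1 is not None:
            assert min(r.precision, r.recall) - 1e-12 <= r.f1 <= max(r.precision, r.recall) + 1e-12


# ----------------------------------------------------------------------
# splits
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def planted_100(tiny_planted=None):
    cfg = SyntheticConfig(n_records=100, seed=17)
    return generate_ade_records(cfg)


class TestSplits:
    def test_random_kfold_sizes(self):
        recs = list(range(100))
        plan = make_split(recs, "random_kfold", k=10, seed=0)
        sizes = np.bincount(plan.fold_of)
        assert (sizes == 10).all()

    def test_by_drug_confinement_exhaustive(self, planted_100):
        from adesig import canonical_smiles
        records, _, _ = planted_100
        plan = make_split(records, "by_drug_kfold", k=5, seed=0)
        fold_by_drug: dict[str, int] = {}
        pos = 0
        for rec in records:
            for d in rec.drugs:
                key = canonical_smiles(d.smiles)
                fold = int(plan.fold_of[pos])
                assert fold_by_drug.setdefault(key, fold) == fold
                pos += 1
        assert pos == len(plan.fold_of)  # exhaustive partition
        assert len(set(fold_by_drug.values())) == 5

    def test_k_exceeding_drug_count_is_split_error(self, planted_100):
        records, _, _ = planted_100
        with pytest.raises(SplitError):
            make_split(records, "by_drug_kfold", k=1000, seed=0)

    def test_random_811_is_partition(self):
        smiles = [s for _, s, _ in generate_drug_pool(100, 0.5, seed=2)]
        plan = make_split(smiles, "random_811", seed=3)
        all_idx = np.concatenate([plan.subsets[s] for s in ("train", "val", "test")])
        assert sorted(all_idx) == list(range(100))
        assert len(plan.subsets["train"]) == 80

    def test_scaffold_811_no_scaffold_spans_subsets(self):
        from rdkit.Chem.Scaffolds.MurckoScaffold import MurckoScaffoldSmiles
        smiles = [s for _, s, _ in generate_drug_pool(100, 0.5, seed=4)]
        plan = make_split(smiles, "scaffold_811", seed=5)
        all_idx = np.concatenate([plan.subsets[s] for s in ("train", "val", "test")])
        assert sorted(all_idx) == list(range(100))
        assert 0.75 <= len(plan.subsets["train"]) / 100 <= 0.85
        scaf = {s: {MurckoScaffoldSmiles(smiles=smiles[i]) for i in plan.subsets[s]}
                for s in ("train", "val", "test")}
        assert not (scaf["train"] & scaf["val"])
        assert not (scaf["train"] & scaf["test"])
        assert not (scaf["val"] & scaf["test"])

    def test_split_deterministic_under_seed(self):
        recs = list(range(50))
        a = make_split(recs, "random_kfold", k=5, seed=9)
        b = make_split(recs, "random_kfold", k=5, seed=9)
        np.testing.assert_array_equal(a.fold_of, b.fold_of)


# ----------------------------------------------------------------------
# cross-validation plumbing
# ----------------------------------------------------------------------

def random_scorer(train_records, test_records, config, seed):
    rng = np.random.default_rng(seed)
    n = sum(len(r.drugs) for r in test_records)
    return rng.random(n)


class TestCrossValidate:
    def test_null_scorer_gives_chance_auc(self, planted_100):
        records, _, _ = planted_100
        res = cross_validate(records, mode="random_kfold", k=10, seed=0,
                             scorer=random_scorer)
        assert 0.40 <= res["mean"]["roc_auc"] <= 0.60

    def test_fold_fitting_never_sees_test_records(self, planted_100):
        records, _, _ = planted_100
        seen = []

        def hook(fold, train_records, test_records):
            tr = {r.record_id for r in train_records}
            te = {r.record_id for r in test_records}
            assert not tr & te
            seen.append(fold)

        cross_validate(records, mode="random_kfold", k=5, seed=1,
                       scorer=random_scorer, on_fit=hook)
        assert seen == list(range(5))

    def test_by_drug_scorer_never_sees_test_drugs(self, planted_100):
        from adesig import canonical_smiles
        records, _, _ = planted_100

        def checking_scorer(train_records, test_records, config, seed):
            tr = {canonical_smiles(d.smiles) for r in train_records for d in r.drugs}
            te = {canonical_smiles(d.smiles) for r in test_records for d in r.drugs}
            assert not tr & te
            return random_scorer(train_records, test_records, config, seed)

        cross_validate(records, mode="by_drug_kfold", k=5, seed=2,
                       scorer=checking_scorer)


# ----------------------------------------------------------------------
# signal detection
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def trained_small():
    cfg = SyntheticConfig(n_records=150, seed=23)
    records, soc_map, truth = generate_ade_records(cfg)
    mcfg = reduced_config(epochs=3)
    corpus = sorted({d.smiles for r in records for d in r.drugs})
    vocab = build_vocabulary(corpus, max_len=mcfg.max_len)
    pts = sorted({a.pt_label for r in records for a in r.adrs})
    model = build_model(mcfg, vocab, soc_map, pts)
    train(model, records, mcfg)
    return model, records, soc_map, truth


class TestDetectSignals:
    CANDIDATES = [ADRTerm(f"pt_{i:04d}", i % 5) for i in range(10)]

    def test_threshold_zero_flags_all(self, trained_small):
        model, _, _, _ = trained_small
        t = detect_signals(model, "CCO", self.CANDIDATES, threshold=0.0)
        assert t["flag"].all()

    def test_threshold_one_flags_none(self, trained_small):
        model, _, _, _ = trained_small
        t = detect_signals(model, "CCO", self.CANDIDATES, threshold=1.0)
        assert not t["flag"].any()

    def test_output_sorted_descending(self, trained_small):
        model, _, _, _ = trained_small
        t = detect_signals(model, "CCO", self.CANDIDATES)
        assert (np.diff(t["score"].to_numpy()) <= 1e-12).all()

    def test_unknown_pt_warns_and_scores(self, trained_small):
        model, _, _, _ = trained_small
        with pytest.warns(UserWarning, match="UNK"):
            t = detect_signals(model, "CCO", [ADRTerm("martian_fever", 3)])
        assert len(t) == 1 and 0 < t["score"].iloc[0] < 1

    def test_training_manifest_membership(self, trained_small):
        model, records, _, _ = trained_small
        seen_smiles = records[0].drugs[0].smiles
        assert drug_seen_in_training(model, seen_smiles)
        assert not drug_seen_in_training(model, "C#N")


# ----------------------------------------------------------------------
# benchmark protocol
# ----------------------------------------------------------------------

class TestBenchmark:
    def test_noise_free_classification_near_perfect(self):
        table, _ = generate_molprop_dataset(150, "classification", seed=31,
                                            epsilon=0.0)
        cfg = reduced_config(epochs=20, batch_size=32)
        res = run_benchmark(table, cfg, split_mode="random_811", n_seeds=2, seed=0)
        assert res["metric"] == "roc_auc"
        assert res["mean"] >= 0.99

    def test_noise_free_regression_reaches_floor(self):
        # with sigma=0 the additive fragment rule is exactly learnable; the
        # held-out RMSE should approach the noise floor
        table, _ = generate_molprop_dataset(300, "regression", seed=32, sigma=0.0)
        cfg = reduced_config(epochs=150, batch_size=32, learning_rate=1.5e-2,
                             predictor_dropout=0.0, gin_dropout=0.0,
                             weight_decay=0.0, norm="layer",
                             final_lr_fraction=0.05)
        res = run_benchmark(table, cfg, split_mode="random_811", n_seeds=1, seed=0)
        assert res["metric"] == "rmse"
        assert res["mean"] <= 0.05

    def test_fully_missing_task_excluded_with_notice(self):
        table, _ = generate_molprop_dataset(60, "classification", seed=33,
                                            epsilon=0.0)
        import numpy as np
        vals = np.column_stack([table.task_values, np.full(60, np.nan)])
        table.task_values = vals
        table.task_names = ["t0", "t_empty"]
        cfg = reduced_config(epochs=2, batch_size=16)
        with pytest.warns(UserWarning, match="fully missing"):
            res = run_benchmark(table, cfg, n_seeds=1, seed=0)
        assert np.isfinite(res["mean"])

    def test_mode_mismatch_rejected(self):
        table, _ = generate_molprop_dataset(40, "classification", seed=34)
        with pytest.raises(ValueError):
            run_benchmark(table, reduced_config(epochs=1), metric="rmse")
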
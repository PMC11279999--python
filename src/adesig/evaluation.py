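"""Metrics, split protocols, cross-validation, signal detection, benchmarks.

Classification quality is summarised by the standard confusion-matrix
metrics

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

plus the threshold-free ROC-AUC (computed by the Mann-Whitney rank
statistic with tie correction) and PRC-AUC (step-wise average precision,
no trapezoids). A precision or recall whose denominator is zero is
reported as ``None`` — an explicit "undefined", never coerced to 0, so a
fold average cannot be silently inflated.

Three split protocols are provided: random k-fold over reports, k-fold by
drug (every drug's instances confined to one fold — the harder protocol,
since held-out drugs are structurally unseen), and 8:1:1 train/val/test
for benchmark tables, either random or by Bemis-Murcko scaffold
(largest scaffold groups filled into train first, so structurally similar
molecules never span subsets).

Signal detection scores one held-out drug against a list of candidate ADR
terms, one single-ADR pseudo-record per candidate, and ranks the
candidates by predicted suspect probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ade_io import ADERecord, ADRTerm, DrugEntry, MolPropTable
from .chem_features import build_vocabulary, canonical_smiles
from .encoders import DemographicStats
from .model import (
    SDAJMConfig, SDAJMModel, build_model, build_molprop_model, train,
    train_molprop,
)

__all__ = [
    "ConfusionCounts", "MetricsReport", "SplitPlan", "compute_metrics",
    "roc_auc", "prc_auc", "make_split", "cross_validate", "detect_signals",
    "run_benchmark", "UndefinedMetricWarning",
]


class UndefinedMetricWarning(UserWarning):
    """A metric's denominator was zero; it is reported as undefined."""


class SplitError(ValueError):
    """A split request is infeasible for the given data."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Confusion counts and derived metrics for one evaluation run.

    ``precision``, ``recall`` and ``f1`` are ``None`` when undefined.
    """

    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    roc_auc: float | None
    prc_auc: float | None
    counts: ConfusionCounts
    threshold: float
    rmse: float | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "roc_auc": self.roc_auc,
            "prc_auc": self.prc_auc, "rmse": self.rmse,
            "threshold": self.threshold,
            "tp": self.counts.tp, "tn": self.counts.tn,
            "fp": self.counts.fp, "fn": self.counts.fn,
        }


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float | None:
    """ROC-AUC by the rank statistic; ties contribute 1/2. ``None`` if one
    class is absent."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def prc_auc(labels: np.ndarray, scores: np.ndarray) -> float | None:
    """Average precision: sum of precision-weighted recall steps, grouping
    tied scores at a single threshold. ``None`` with no positives."""
    labels = np.asarray(labels, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = labels.sum()
    if n_pos == 0:
        return None
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    # threshold boundaries: last index of each tied block
    distinct = np.flatnonzero(np.diff(s_sorted)) if len(s_sorted) > 1 else np.array([], dtype=int)
    bounds = np.r_[distinct, len(s_sorted) - 1]
    tp_cum = np.cumsum(y_sorted)[bounds]
    n_cum = bounds + 1.0
    precision = tp_cum / n_cum
    recall = tp_cum / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Threshold the scores, count the confusion matrix, derive all metrics."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if len(labels) != len(scores) or len(labels) == 0:
        raise ValueError("labels and scores must be equal-length and non-empty")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)

    accuracy = (tp + tn) / counts.total
    precision = recall = f1 = None
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        warnings.warn("precision undefined: no predicted positives",
                      UndefinedMetricWarning, stacklevel=2)
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        warnings.warn("recall undefined: no actual positives",
                      UndefinedMetricWarning, stacklevel=2)
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)

    return MetricsReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        roc_auc=roc_auc(labels, scores), prc_auc=prc_auc(labels, scores),
        counts=counts, threshold=threshold,
    )


def compute_rmse(targets, predictions) -> float:
    targets = np.asarray(targets, dtype=np.float64)
    predictions = np.asarray(predictions, dtype=np.float64)
    return float(np.sqrt(np.mean((targets - predictions) ** 2)))


# ----------------------------------------------------------------------
# split protocols
# ----------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Assignment of items to folds or subsets.

    ``fold_of`` (k-fold modes) maps item index -> fold id; ``subsets``
    (8:1:1 modes) maps 'train'/'val'/'test' -> index arrays.
    """

    mode: str
    seed: int
    fold_of: np.ndarray | None = None
    subsets: dict[str, np.ndarray] | None = None


def _drug_key(entry: DrugEntry) -> str:
    return canonical_smiles(entry.smiles)


def make_split(items, mode: str, k: int = 10, fractions=(0.8, 0.1, 0.1),
               seed: int = 0) -> SplitPlan:
    """Partition items deterministically under ``seed``.

    ``items`` is a record list for the k-fold modes (``random_kfold`` folds
    over reports; ``by_drug_kfold`` partitions the drug set and assigns
    every (record, drug) instance to its drug's fold, indexed by flattened
    instance position), or a SMILES list for ``random_811`` /
    ``scaffold_811``.
    """
    rng = np.random.default_rng(seed)
    if mode == "random_kfold":
        n = len(items)
        if k < 2 or k > n:
            raise SplitError(f"cannot make {k} folds from {n} records")
        fold_of = np.array([i % k for i in range(n)])
        rng.shuffle(fold_of)
        return SplitPlan(mode=mode, seed=seed, fold_of=fold_of)

    if mode == "by_drug_kfold":
        keys = []
        for rec in items:
            for d in rec.drugs:
                keys.append(_drug_key(d))
        unique_keys = sorted(set(keys))
        if k < 2 or k > len(unique_keys):
            raise SplitError(f"cannot make {k} drug folds from "
                             f"{len(unique_keys)} distinct drugs")
        drug_fold = np.array([i % k for i in range(len(unique_keys))])
        rng.shuffle(drug_fold)
        fold_by_key = dict(zip(unique_keys, drug_fold))
        fold_of = np.array([fold_by_key[key] for key in keys])
        return SplitPlan(mode=mode, seed=seed, fold_of=fold_of)

    if mode in ("random_811", "scaffold_811"):
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise SplitError("fractions must sum to 1")
        n = len(items)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        if mode == "random_811":
            order = rng.permutation(n)
            subsets = {"train": np.sort(order[:n_train]),
                       "val": np.sort(order[n_train:n_train + n_val]),
                       "test": np.sort(order[n_train + n_val:])}
            return SplitPlan(mode=mode, seed=seed, subsets=subsets)
        # scaffold split: group molecules by Bemis-Murcko scaffold,
        # fill largest groups into train, then val, then test
        from rdkit.Chem.Scaffolds.MurckoScaffold import MurckoScaffoldSmiles
        groups: dict[str, list[int]] = {}
        for i, smi in enumerate(items):
            scaf = MurckoScaffoldSmiles(smiles=smi)
            groups.setdefault(scaf, []).append(i)
        ordered = sorted(groups.values(), key=lambda g: (-len(g), g[0]))
        subsets = {"train": [], "val": [], "test": []}
        for g in ordered:
            if len(subsets["train"]) + len(g) <= n_train or not subsets["train"]:
                subsets["train"] += g
            elif len(subsets["val"]) + len(g) <= n_val or not subsets["val"]:
                subsets["val"] += g
            else:
                subsets["test"] += g
        return SplitPlan(mode=mode, seed=seed,
                         subsets={s: np.sort(np.array(ix, dtype=int))
                                  for s, ix in subsets.items()})

    raise SplitError(f"unknown split mode {mode!r}")


# ----------------------------------------------------------------------
# cross-validation
# ----------------------------------------------------------------------

def _filter_record(rec: ADERecord, keep: Callable[[DrugEntry], bool]) -> ADERecord | None:
    drugs = tuple(d for d in rec.drugs if keep(d))
    if not drugs:
        return None
    return replace(rec, drugs=drugs)


def _default_scorer(train_records, test_records, config: SDAJMConfig,
                    seed: int) -> np.ndarray:
    """Fit vocabulary + stats on the training fold only, train, score."""
    corpus = sorted({d.smiles for r in train_records for d in r.drugs})
    vocab = build_vocabulary(corpus, max_len=config.max_len)
    pt_labels = sorted({a.pt_label for r in train_records for a in r.adrs})
    cfg = replace(config, seed=seed)
    model = build_model(cfg, vocab, None, pt_labels)
    train(model, train_records, cfg)
    return model.predict_scores(test_records)


def cross_validate(
    records: list[ADERecord],
    config: SDAJMConfig | None = None,
    mode: str = "random_kfold",
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
    scorer: Callable | None = None,
    on_fit=None,
) -> dict:
    """k-fold cross-validation over ADE records.

    Per fold, the vocabulary and demographic statistics are fit on the
    training folds only, the model is trained from scratch, and the
    held-out fold is scored. ``scorer`` replaces the default
    train-and-predict pipeline (same signature) for stubbed evaluations.
    ``on_fit(fold, train_records, test_records)`` is an instrumentation
    hook invoked before each fold's fit.

    Returns ``{"folds": [MetricsReport...], "mean": ..., "sd": ...,
    "skipped_folds": [...]}`` with unweighted fold means; folds whose truth
    is single-class are excluded from ROC/PRC means and listed as skipped.
    """
    config = config or SDAJMConfig()
    scorer = scorer or _default_scorer
    plan = make_split(records, mode, k=k, seed=seed)
    reports: list[MetricsReport] = []
    skipped: list[int] = []

    for fold in range(k):
        if mode == "random_kfold":
            train_records = [r for r, f in zip(records, plan.fold_of) if f != fold]
            test_records = [r for r, f in zip(records, plan.fold_of) if f == fold]
        else:  # by_drug_kfold: confine each drug's instances to its fold
            pos = 0
            test_keys: set[str] = set()
            for rec in records:
                for d in rec.drugs:
                    if plan.fold_of[pos] == fold:
                        test_keys.add(_drug_key(d))
                    pos += 1
            train_records, test_records = [], []
            for rec in records:
                tr = _filter_record(rec, lambda d: _drug_key(d) not in test_keys)
                te = _filter_record(rec, lambda d: _drug_key(d) in test_keys)
                if tr is not None:
                    train_records.append(tr)
                if te is not None:
                    test_records.append(te)
        if not test_records or not train_records:
            skipped.append(fold)
            continue
        if on_fit is not None:
            on_fit(fold, train_records, test_records)
        scores = scorer(train_records, test_records, config, seed * 1000 + fold)
        labels = np.array([d.suspect for r in test_records for d in r.drugs])
        if len(np.unique(labels)) < 2:
            warnings.warn(f"fold {fold} truth is single-class; ROC/PRC "
                          "undefined, fold flagged", UndefinedMetricWarning)
            skipped.append(fold)
            continue
        reports.append(compute_metrics(labels, scores, threshold=threshold))

    def _agg(name):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if not vals:
            return None, None
        return float(np.mean(vals)), float(np.std(vals))

    mean = {}
    sd = {}
    for name in ("accuracy", "precision", "recall", "f1", "roc_auc", "prc_auc"):
        mean[name], sd[name] = _agg(name)
    return {"folds": reports, "mean": mean, "sd": sd, "skipped_folds": skipped}


# ----------------------------------------------------------------------
# ADR signal detection
# ----------------------------------------------------------------------

def drug_seen_in_training(model: SDAJMModel, smiles: str) -> bool:
    """True when the drug's canonical SMILES is in the training manifest."""
    return canonical_smiles(smiles) in set(model.training_manifest)


def detect_signals(
    model: SDAJMModel,
    drug_smiles: str,
    candidate_adrs: list[ADRTerm],
    demographic_profile: dict | None = None,
    threshold: float = 0.5,
    drug_name: str = "query_drug",
) -> pd.DataFrame:
    """Score one drug against candidate ADR terms, ranked by probability.

    Each candidate becomes a single-ADR pseudo-record carrying the supplied
    demographic profile (default: the training mean for age and weight —
    i.e. Xpd = [0, 0, sex] — with sex 0). The caller is responsible for
    excluding the query drug from training; :func:`drug_seen_in_training`
    verifies. Candidate PTs unknown to the PT vocabulary are scored through
    the UNK embedding with a per-row warning.

    Returns a DataFrame with columns pt, soc_index, score, flag sorted by
    descending score.
    """
    if not candidate_adrs:
        raise ValueError("need at least one candidate ADR term")
    profile = demographic_profile or {}
    age = profile.get("age", model.stats.age_mean)
    weight = profile.get("weight", model.stats.weight_mean)
    sex = profile.get("sex", 0)

    pseudo = []
    for i, term in enumerate(candidate_adrs):
        if term.pt_label not in model.adr_encoder.pt_to_id:
            warnings.warn(f"candidate PT {term.pt_label!r} unseen at training; "
                          "scored via UNK embedding", UserWarning)
        pseudo.append(ADERecord(
            record_id=f"signal_{i:05d}", age=age, weight=weight, sex=sex,
            drugs=(DrugEntry(name=drug_name, smiles=drug_smiles, suspect=0),),
            adrs=(term,),
        ))
    scores = model.predict_scores(pseudo)
    table = pd.DataFrame({
        "pt": [t.pt_label for t in candidate_adrs],
        "soc_index": [t.soc_index for t in candidate_adrs],
        "score": scores,
        "flag": scores >= threshold,
    })
    return table.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)


# ----------------------------------------------------------------------
# molecular-property benchmark protocol
# ----------------------------------------------------------------------

def run_benchmark(
    table: MolPropTable,
    config: SDAJMConfig | None = None,
    split_mode: str = "random_811",
    n_seeds: int = 5,
    metric: str | None = None,
    seed: int = 0,
) -> dict:
    """Train/evaluate on a benchmark table over ``n_seeds`` random seeds.

    Only the three drug channels feed the head. Classification reports
    macro-averaged ROC-AUC over tasks (PRC-AUC when ``metric='prc_auc'``)
    with per-task missing-label masking; regression reports RMSE. Tasks
    that are fully missing or single-class in the test subset are excluded
    from the macro average with a notice.

    Returns ``{"metric", "mean", "sd", "per_seed"}``.
    """
    config = config or SDAJMConfig()
    if metric is None:
        metric = "rmse" if table.task_kind == "regression" else "roc_auc"
    if metric == "rmse" and table.task_kind != "regression":
        raise ValueError("RMSE requested on a classification table")
    if metric in ("roc_auc", "prc_auc") and table.task_kind != "classification":
        raise ValueError(f"{metric} requested on a regression table")

    per_seed = []
    for s in range(n_seeds):
        plan = make_split(table.smiles, split_mode, seed=seed * 1000 + s)
        tr, te = plan.subsets["train"], plan.subsets["test"]
        cfg = replace(config, seed=seed * 1000 + s)
        vocab = build_vocabulary([table.smiles[i] for i in tr], max_len=cfg.max_len)
        model = build_molprop_model(cfg, vocab, n_tasks=len(table.task_names),
                                    task_kind=table.task_kind)
        train_molprop(model, [table.smiles[i] for i in tr],
                      table.task_values[tr], cfg)
        preds = model.predict_molprop([table.smiles[i] for i in te])
        y = table.task_values[te]

        if table.task_kind == "regression":
            mask = ~np.isnan(y)
            per_seed.append(compute_rmse(y[mask], preds[mask]))
        else:
            task_scores = []
            for t in range(y.shape[1]):
                obs = ~np.isnan(y[:, t])
                if not obs.any():
                    warnings.warn(f"task {table.task_names[t]!r} fully missing "
                                  "in test subset; excluded", UserWarning)
                    continue
                fn = roc_auc if metric == "roc_auc" else prc_auc
                val = fn(y[obs, t], preds[obs, t])
                if val is None:
                    warnings.warn(f"task {table.task_names[t]!r} single-class "
                                  "in test subset; excluded", UserWarning)
                    continue
                task_scores.append(val)
            if not task_scores:
                warnings.warn(f"seed {s}: no evaluable task", UserWarning)
                continue
            per_seed.append(float(np.mean(task_scores)))

    if not per_seed:
        raise ValueError("benchmark produced no evaluable runs")
    return {"metric": metric, "mean": float(np.mean(per_seed)),
            "sd": float(np.std(per_seed)), "per_seed": per_seed}
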
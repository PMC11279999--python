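"""Synthetic adverse-event datasets with a known, planted causal structure.

Real pharmacovigilance databases (FAERS, JADER) cannot be redistributed and
MedDRA is licensed, so every stage of the classifier is exercised instead
on generated data whose ground truth is known exactly:

* a pool of small valid molecules assembled from a fixed grammar of
  chemically valid fragments (alkyl chains, benzene, pyridine, amide,
  halogen and carboxylic-acid caps), a controllable fraction of which
  carry a marker substructure (default: a carboxylic-acid group — common
  enough to split any pool, specific enough for the fingerprint and graph
  channels to detect);
* a synthetic PT-level ADR vocabulary mapped onto system organ classes;
* reports whose per-drug suspect label follows a planted conditional rule:
  Bernoulli(p1) when the drug carries the marker AND the report contains at
  least one ADR from a designated target SOC, Bernoulli(p0) otherwise.

Non-suspect co-medication drugs appear in records, as in real spontaneous
reports, so the classification problem is non-degenerate. The generative
probability of every (record, drug) instance is retained in a
:class:`PlantedTruth` sidecar so recovery tests can compare model output
against the generating rule. Generation is a pure function of the config,
seed included.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from rdkit import Chem

from .ade_io import ADERecord, ADRTerm, DrugEntry, SOCMap, MolPropTable, N_SOC

__all__ = [
    "SyntheticConfig", "PlantedTruth", "generate_drug_pool",
    "generate_soc_vocabulary", "generate_ade_records",
    "generate_molprop_dataset", "write_truth", "read_truth",
]

MARKER_SMARTS_DEFAULT = "[CX3](=O)[OX2H1]"  # carboxylic acid

# Fragment grammar: every entry concatenates into a valid linear SMILES.
# Body fragments may repeat mid-chain; cap fragments are terminal only
# (halogens are monovalent, the acid's hydroxyl must stay free).
_BODY_FRAGMENTS = ["C", "CC", "CCC", "c1ccccc1", "c1ccncc1", "C(=O)N"]
_CAP_FRAGMENTS = ["", "C", "F", "Cl", "Br", "C(=O)NC"]
_ACID_CAP = "C(=O)O"

# Per-fragment additive contributions for the regression benchmark target.
_FRAGMENT_WEIGHTS = {
    "C": 0.2, "CC": 0.4, "CCC": 0.6, "c1ccccc1": -1.0, "c1ccncc1": -0.5,
    "C(=O)N": 0.8, "F": 0.3, "Cl": 0.7, "Br": 1.1, "C(=O)NC": 0.9,
    _ACID_CAP: 1.5, "": 0.0,
}


class ConfigError(ValueError):
    """A synthetic-data configuration violates its invariants."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic ADE study.

    Defaults describe a mid-sized pharmacovigilance extract: middle-aged
    adults (age 55 +/- 18 y, weight 72 +/- 16 kg, balanced sex), one to
    three co-reported drugs and one to five PT-level ADRs per report, a
    40-drug pool half of which carries the marker substructure, and a
    strong-but-noisy planted association (p1 = 0.9, p0 = 0.1). The target
    SOC appears in 80% of reports, so roughly 40% of instances sit in the
    high-risk stratum.
    """

    n_records: int = 2000
    n_drugs: int = 40
    n_pt: int = 100
    n_soc_used: int = 10
    marker_pattern: str = MARKER_SMARTS_DEFAULT
    marker_fraction: float = 0.5
    p_suspect_given_marker_and_soc: float = 0.9
    p_suspect_otherwise: float = 0.1
    target_soc: int = 0
    p_target_soc: float = 0.8
    drugs_per_record: tuple[int, int] = (1, 3)
    adrs_per_record: tuple[int, int] = (1, 5)
    age_mean: float = 55.0
    age_sd: float = 18.0
    weight_mean: float = 72.0
    weight_sd: float = 16.0
    sex_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        p0 = self.p_suspect_otherwise
        p1 = self.p_suspect_given_marker_and_soc
        if not (0.0 <= p0 < p1 <= 1.0):
            raise ConfigError(f"need 0 <= p0 < p1 <= 1, got p0={p0}, p1={p1}")
        if not 1 <= self.n_soc_used <= N_SOC:
            raise ConfigError(f"n_soc_used must be in [1, {N_SOC}]")
        if not 0 <= self.target_soc < self.n_soc_used:
            raise ConfigError("target_soc must be one of the used SOC indices")
        for lo, hi in (self.drugs_per_record, self.adrs_per_record):
            if not 1 <= lo <= hi:
                raise ConfigError("per-record count ranges must be non-empty")
        if not 0.0 <= self.marker_fraction <= 1.0:
            raise ConfigError("marker_fraction must be in [0, 1]")
        if not 0.0 <= self.sex_balance <= 1.0:
            raise ConfigError("sex_balance must be in [0, 1]")
        if self.n_records < 1 or self.n_drugs < 2:
            raise ConfigError("need n_records >= 1 and n_drugs >= 2")
        if self.n_pt < self.n_soc_used:
            raise ConfigError("n_pt must be >= n_soc_used")


@dataclass
class PlantedTruth:
    """Generative ground truth stored beside a synthetic dataset.

    ``marker`` maps drug name -> marker flag; ``instance_p`` maps
    (record_id, drug name) -> the Bernoulli probability its suspect label
    was drawn from. Test-only: never an input to the model.
    """

    marker: dict[str, bool]
    instance_p: dict[tuple[str, str], float]
    target_soc: int


# ----------------------------------------------------------------------
# drug pool
# ----------------------------------------------------------------------

def _assemble_molecule(rng: np.random.Generator, with_marker: bool) -> tuple[str, list[str]]:
    n_body = int(rng.integers(1, 4))
    parts = [str(rng.choice(_BODY_FRAGMENTS)) for _ in range(n_body)]
    cap = _ACID_CAP if with_marker else str(rng.choice(_CAP_FRAGMENTS))
    return "".join(parts) + cap, parts + [cap]


def generate_drug_pool(
    n_drugs: int,
    marker_fraction: float,
    seed: int,
    marker_pattern: str = MARKER_SMARTS_DEFAULT,
) -> list[tuple[str, str, bool]]:
    """Generate ``n_drugs`` distinct valid molecules as (name, smiles, marker).

    Exactly ``round(marker_fraction * n_drugs)`` molecules contain the
    marker substructure; the rest are verified not to. Deterministic in
    ``seed``.
    """
    if n_drugs < 2:
        raise ConfigError("n_drugs must be >= 2")
    if not 0.0 <= marker_fraction <= 1.0:
        raise ConfigError("marker_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pattern = Chem.MolFromSmarts(marker_pattern)
    if pattern is None:
        raise ConfigError(f"invalid marker SMARTS: {marker_pattern!r}")
    n_marker = round(marker_fraction * n_drugs)
    pool: list[tuple[str, str, bool]] = []
    seen: set[str] = set()
    for i in range(n_drugs):
        want_marker = i < n_marker
        for _ in range(1000):
            smiles, _parts = _assemble_molecule(rng, want_marker)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue  # grammar should not produce this; skip defensively
            canonical = Chem.MolToSmiles(mol)
            if canonical in seen:
                continue
            has_marker = mol.HasSubstructMatch(pattern)
            if has_marker != want_marker:
                continue
            seen.add(canonical)
            pool.append((f"drug_{i:03d}", smiles, want_marker))
            break
        else:
            raise ConfigError(
                f"could not assemble distinct molecule {i} after 1000 attempts"
            )
    return pool


# ----------------------------------------------------------------------
# ADR vocabulary
# ----------------------------------------------------------------------

def generate_soc_vocabulary(n_pt: int, n_soc_used: int, seed: int) -> SOCMap:
    """Synthetic PT vocabulary over ``n_soc_used`` SOC indices.

    Every used SOC index receives at least one PT; remaining PTs are
    assigned uniformly at random. Labels are ``pt_0000`` ... and SOC names
    ``soc_00`` ... — synthetic stand-ins, never MedDRA content.
    """
    if n_pt < n_soc_used:
        raise ConfigError("n_pt must be >= n_soc_used")
    if not 1 <= n_soc_used <= N_SOC:
        raise ConfigError(f"n_soc_used must be in [1, {N_SOC}]")
    rng = np.random.default_rng(seed)
    assignments = list(range(n_soc_used))  # coverage guarantee
    assignments += list(rng.integers(0, n_soc_used, size=n_pt - n_soc_used))
    entries = {
        f"pt_{i:04d}": (int(soc), f"soc_{int(soc):02d}")
        for i, soc in enumerate(assignments)
    }
    return SOCMap(entries=entries)


# ----------------------------------------------------------------------
# ADE records
# ----------------------------------------------------------------------

def generate_ade_records(
    config: SyntheticConfig,
) -> tuple[list[ADERecord], SOCMap, PlantedTruth]:
    """Generate a synthetic ADE dataset under the planted suspect rule.

    Returns ``(records, soc_map, truth)``. For each (record, drug) pair the
    suspect label is Bernoulli(p1) if the drug carries the marker AND the
    record lists at least one ADR from the target SOC, else Bernoulli(p0).
    Ages and weights are normal draws clipped to plausible positive ranges
    (age to [0, 105] years, weight to [2, 250] kg).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pool = generate_drug_pool(
        cfg.n_drugs, cfg.marker_fraction, seed=cfg.seed, marker_pattern=cfg.marker_pattern
    )
    soc_map = generate_soc_vocabulary(cfg.n_pt, cfg.n_soc_used, seed=cfg.seed)

    pts_by_soc: dict[int, list[str]] = {}
    for pt, (soc, _name) in sorted(soc_map.entries.items()):
        pts_by_soc.setdefault(soc, []).append(pt)
    target_pts = pts_by_soc[cfg.target_soc]
    other_pts = sorted(set(soc_map.entries) - set(target_pts))
    if not other_pts:
        other_pts = target_pts  # degenerate single-SOC vocabulary

    marker = {name: flag for name, _smi, flag in pool}
    records: list[ADERecord] = []
    instance_p: dict[tuple[str, str], float] = {}

    for r in range(cfg.n_records):
        rid = f"rec_{r:06d}"
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 0.0, 105.0))
        weight = float(np.clip(rng.normal(cfg.weight_mean, cfg.weight_sd), 2.0, 250.0))
        sex = int(rng.random() < cfg.sex_balance)

        k = int(rng.integers(cfg.drugs_per_record[0], cfg.drugs_per_record[1] + 1))
        k = min(k, cfg.n_drugs)
        drug_idx = rng.choice(cfg.n_drugs, size=k, replace=False)

        m = int(rng.integers(cfg.adrs_per_record[0], cfg.adrs_per_record[1] + 1))
        has_target = rng.random() < cfg.p_target_soc
        m = min(m, len(other_pts) + (1 if has_target else 0))
        m = max(m, 1)
        chosen: list[str] = []
        if has_target:
            chosen.append(str(rng.choice(target_pts)))
        while len(chosen) < m:
            pt = str(rng.choice(other_pts))
            if pt not in chosen:
                chosen.append(pt)
        adrs = tuple(
            ADRTerm(pt_label=pt, soc_index=soc_map.soc_of(pt)) for pt in chosen
        )
        record_has_target = any(a.soc_index == cfg.target_soc for a in adrs)

        drugs = []
        for di in drug_idx:
            name, smi, flag = pool[int(di)]
            p = (cfg.p_suspect_given_marker_and_soc
                 if (flag and record_has_target)
                 else cfg.p_suspect_otherwise)
            label = int(rng.random() < p)
            drugs.append(DrugEntry(name=name, smiles=smi, suspect=label))
            instance_p[(rid, name)] = p

        records.append(ADERecord(
            record_id=rid, age=age, weight=weight, sex=sex,
            drugs=tuple(drugs), adrs=adrs,
        ))

    truth = PlantedTruth(marker=marker, instance_p=instance_p,
                         target_soc=cfg.target_soc)
    return records, soc_map, truth


# ----------------------------------------------------------------------
# molecular-property benchmark datasets
# ----------------------------------------------------------------------

def generate_molprop_dataset(
    n: int,
    task_kind: str,
    seed: int,
    epsilon: float = 0.05,
    sigma: float = 0.1,
) -> tuple[MolPropTable, dict]:
    """Benchmark table with a known labelling rule.

    Classification: label = marker presence XOR a Bernoulli(epsilon) flip,
    so Bayes-optimal accuracy is ``1 - epsilon``. Regression: target = sum
    of per-fragment contributions + N(0, sigma) noise, so sigma bounds the
    achievable RMSE from below. Returns the table and a truth dict with the
    noise-free values.
    """
    if n < 20:
        raise ConfigError("benchmark dataset needs n >= 20")
    if task_kind not in ("classification", "regression"):
        raise ConfigError(f"unknown task_kind {task_kind!r}")
    rng = np.random.default_rng(seed)
    pattern = Chem.MolFromSmarts(MARKER_SMARTS_DEFAULT)

    smiles_list: list[str] = []
    clean: list[float] = []
    markers: list[bool] = []
    seen: set[str] = set()
    while len(smiles_list) < n:
        want_marker = bool(rng.random() < 0.5)
        smi, parts = _assemble_molecule(rng, want_marker)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        if mol.HasSubstructMatch(pattern) != want_marker:
            continue
        seen.add(canonical)
        smiles_list.append(smi)
        markers.append(want_marker)
        clean.append(sum(_FRAGMENT_WEIGHTS[p] for p in parts))

    if task_kind == "classification":
        flips = rng.random(n) < epsilon
        labels = np.array(markers, dtype=np.float64)
        labels[flips] = 1.0 - labels[flips]
        values = labels[:, None]
        truth = {"marker": markers, "flips": flips.tolist(), "epsilon": epsilon}
        task_names = ["marker_activity"]
    else:
        base = np.asarray(clean, dtype=np.float64)
        values = (base + rng.normal(0.0, sigma, size=n))[:, None] if sigma > 0 else base[:, None]
        truth = {"clean": base.tolist(), "sigma": sigma}
        task_names = ["fragment_sum"]

    table = MolPropTable(
        smiles=smiles_list, task_values=values,
        task_names=task_names, task_kind=task_kind,
    )
    return table, truth


# ----------------------------------------------------------------------
# truth sidecar (test-only artifact)
# ----------------------------------------------------------------------

def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    """Write the planted-truth sidecar (JSONL, clearly test-only)."""
    with Path(path).open("w") as fh:
        fh.write(json.dumps({"kind": "header", "test_only": True,
                             "target_soc": truth.target_soc}) + "\n")
        for name in sorted(truth.marker):
            fh.write(json.dumps({"kind": "drug", "name": name,
                                 "marker": truth.marker[name]}) + "\n")
        for (rid, name) in sorted(truth.instance_p):
            fh.write(json.dumps({"kind": "instance", "record_id": rid,
                                 "drug": name,
                                 "p": truth.instance_p[(rid, name)]}) + "\n")


def read_truth(path: str | Path) -> PlantedTruth:
    marker: dict[str, bool] = {}
    instance_p: dict[tuple[str, str], float] = {}
    target_soc = 0
    with Path(path).open() as fh:
        for line in fh:
            obj = json.loads(line)
            if obj["kind"] == "header":
                target_soc = obj["target_soc"]
            elif obj["kind"] == "drug":
                marker[obj["name"]] = bool(obj["marker"])
            else:
                instance_p[(obj["record_id"], obj["drug"])] = float(obj["p"])
    return PlantedTruth(marker=marker, instance_p=instance_p, target_soc=target_soc)
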
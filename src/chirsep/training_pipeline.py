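"""Dataset splitting, training with early stopping, and evaluation metrics.

Defaults follow standard practice for this model family: Adam at
learning rate 0.001, batch size 2048, up to 1500 epochs with early
stopping on the validation loss, and a 90/5/5 train/validation/test
split.  The split is pair-aware by default so that the two mirror
images of an enantiomer pair never straddle folds (``record_level``
reproduces the literal per-record split).  All randomness funnels
through one integer seed recorded in the outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem_graphs import (
    Condition,
    DualGraph,
    build_dual_graph,
    compute_descriptors,
    embed_conformer,
    load_column_registry,
)
from .cmrt_data import MoleculeRecord
from .errors import ContractError, TrainingError
from .qgeognn_model import GraphBatch, ModelConfig, NormStats, QGeoGNN
from .quantile_loss import LossConfig

PAIR_POLICIES = ("keep_pairs_together", "record_level")


@dataclass
class TrainConfig:
    split_ratios: tuple[float, float, float] = (0.90, 0.05, 0.05)
    batch_size: int = 2048
    epochs: int = 1500
    learning_rate: float = 0.001
    patience: int = 100
    seed: int = 0
    pair_policy: str = "keep_pairs_together"
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ContractError("split_ratios must sum to 1")
        if self.epochs < 1:
            raise ContractError("epochs must be >= 1")
        if self.pair_policy not in PAIR_POLICIES:
            raise ContractError(f"pair_policy must be one of {PAIR_POLICIES}")


@dataclass
class Metrics:
    mae: float   # mean absolute error, RTv units
    mre: float   # median relative error, fraction
    r2: float

    def as_dict(self) -> dict[str, float]:
        return {"mae": self.mae, "mre": self.mre, "r2": self.r2}


# -- splitting -------------------------------------------------------------


def split(
    records: Sequence[MoleculeRecord], config: TrainConfig
) -> tuple[list[MoleculeRecord], list[MoleculeRecord], list[MoleculeRecord]]:
    """Deterministic train/validation/test split.

    Under ``keep_pairs_together`` whole enantiomer pairs are allocated
    to a fold, so fold sizes can deviate from the exact ratios by at
    most one pair.
    """
    if len(records) < 20:
        raise ContractError("need at least 20 records to split")
    rng = np.random.default_rng(config.seed)
    if config.pair_policy == "record_level":
        groups = [[i] for i in range(len(records))]
    else:
        by_pair: dict[str, list[int]] = {}
        for i, rec in enumerate(records):
            key = rec.pair_id if rec.pair_id is not None else f"__solo_{i}"
            by_pair.setdefault(key, []).append(i)
        groups = list(by_pair.values())
    order = rng.permutation(len(groups))
    n = len(records)
    quota_test = int(round(n * config.split_ratios[2]))
    quota_valid = int(round(n * config.split_ratios[1]))
    test_idx, valid_idx, train_idx = [], [], []
    for gi in order:
        g = groups[gi]
        if len(test_idx) < quota_test:
            test_idx.extend(g)
        elif len(valid_idx) < quota_valid:
            valid_idx.extend(g)
        else:
            train_idx.extend(g)
    if not train_idx or not valid_idx or not test_idx:
        raise ContractError("split produced an empty fold; adjust ratios or data size")
    return (
        [records[i] for i in sorted(train_idx)],
        [records[i] for i in sorted(valid_idx)],
        [records[i] for i in sorted(test_idx)],
    )


# -- featurization with caching -------------------------------------------


def featurize_records(
    records: Sequence[MoleculeRecord],
    model_config: ModelConfig,
    seed: int = 0,
    registry: Optional[dict] = None,
) -> list[DualGraph]:
    """DualGraphs for records, caching conformers/descriptors per molecule."""
    if model_config.multi_column and registry is None:
        registry = load_column_registry()
    conf_cache: dict[str, object] = {}
    desc_cache: dict[str, object] = {}
    duals = []
    for rec in records:
        if rec.smiles not in conf_cache:
            conf_cache[rec.smiles] = embed_conformer(rec.smiles, seed=seed)
            desc_cache[rec.smiles] = compute_descriptors(rec.smiles)
        column = registry[rec.column_name] if model_config.multi_column else None
        duals.append(
            build_dual_graph(
                rec.smiles,
                Condition(rec.elution_proportion, rec.flow_rate),
                column=column,
                conformer=conf_cache[rec.smiles],
                descriptors=desc_cache[rec.smiles],
            )
        )
    return duals


# -- optimizer -------------------------------------------------------------


class Adam:
    def __init__(self, params: dict, lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


# -- training --------------------------------------------------------------


@dataclass
class TrainResult:
    model: QGeoGNN
    history: pd.DataFrame
    best_epoch: int
    folds: tuple[list[MoleculeRecord], list[MoleculeRecord], list[MoleculeRecord]]


def train(
    records: Sequence[MoleculeRecord],
    model_config: ModelConfig,
    train_config: TrainConfig,
    registry: Optional[dict] = None,
    folds: Optional[tuple] = None,
) -> TrainResult:
    """Train a quantile model; returns the best-validation checkpoint.

    ``folds`` can inject a precomputed (train, valid, test) partition,
    e.g. for cross-validation; otherwise :func:`split` is applied.
    """
    if folds is None:
        folds = split(records, train_config)
    train_recs, valid_recs, test_recs = folds
    if not train_recs or not valid_recs:
        raise ContractError("train and validation folds must be nonempty")
    duals_train = featurize_records(train_recs, model_config, train_config.seed, registry)
    duals_valid = featurize_records(valid_recs, model_config, train_config.seed, registry)
    y_train = np.array([r.rtv for r in train_recs])
    y_valid = np.array([r.rtv for r in valid_recs])

    full_train = GraphBatch(duals_train, model_config)
    model = QGeoGNN(model_config, seed=train_config.seed)
    model.norm = NormStats.fit(full_train, model_config)
    # start the three heads on the target scale (empirical 10%/mean/90%)
    # so early epochs refine structure instead of crossing output scales
    model.params["head.b"].data = np.array(
        [np.quantile(y_train, 0.10), y_train.mean(), np.quantile(y_train, 0.90)]
    )
    valid_batch = GraphBatch(duals_valid, model_config)

    rng = np.random.default_rng(train_config.seed + 1)
    opt = Adam(model.parameters(), lr=train_config.learning_rate)
    n = len(duals_train)
    bs = min(train_config.batch_size, n)
    full_batch = bs >= n

    history_rows = []
    best_val = math.inf
    best_epoch = -1
    best_state = None
    for epoch in range(train_config.epochs):
        if full_batch:
            batches = [(full_train, y_train)]
        else:
            order = rng.permutation(n)
            batches = []
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                batches.append(
                    (GraphBatch([duals_train[i] for i in idx], model_config), y_train[idx])
                )
        term_sums: dict[str, float] = {}
        for batch, y in batches:
            opt.zero_grad()
            total, terms = model.batch_loss(batch, y, train_config.loss)
            if not np.isfinite(total.data):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            total.backward()
            opt.step()
            for k, v in terms.items():
                term_sums[k] = term_sums.get(k, 0.0) + v * len(y)
        train_terms = {k: v / n for k, v in term_sums.items()}
        val_total, _ = model.batch_loss(valid_batch, y_valid, train_config.loss)
        val_total = float(val_total.data)
        history_rows.append(
            {"epoch": epoch, **{f"train_{k}": v for k, v in train_terms.items()},
             "train_total": sum(train_terms.values()), "val_total": val_total}
        )
        if val_total < best_val - 1e-12:
            best_val = val_total
            best_epoch = epoch
            best_state = {k: p.data.copy() for k, p in model.params.items()}
        elif epoch - best_epoch >= train_config.patience:
            break
    if best_state is not None:
        for k, p in model.params.items():
            p.data = best_state[k]
    history = pd.DataFrame(history_rows)
    return TrainResult(model, history, best_epoch, (list(train_recs), list(valid_recs), list(test_recs)))


# -- evaluation ------------------------------------------------------------


def evaluate(
    model: QGeoGNN,
    records: Sequence[MoleculeRecord],
    registry: Optional[dict] = None,
    duals: Optional[list[DualGraph]] = None,
) -> Metrics:
    """MAE / median-relative-error / R² on the RTv scale."""
    if not records:
        raise ContractError("empty evaluation fold")
    if duals is None:
        duals = featurize_records(records, model.config, model.seed, registry)
    preds = np.array([p.pred for p in model.predict(duals)])
    obs = np.array([r.rtv for r in records])
    return metrics_from_arrays(obs, preds)


def metrics_from_arrays(obs: np.ndarray, preds: np.ndarray) -> Metrics:
    obs = np.asarray(obs, float)
    preds = np.asarray(preds, float)
    err = preds - obs
    mae = float(np.mean(np.abs(err)))
    mre = float(np.median(np.abs(err) / obs))
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    return Metrics(mae, mre, r2)


def coverage(model: QGeoGNN, records: Sequence[MoleculeRecord],
             registry: Optional[dict] = None, duals: Optional[list] = None) -> float:
    """Empirical coverage of the [q10, q90] band on the given records."""
    if duals is None:
        duals = featurize_records(records, model.config, model.seed, registry)
    preds = model.predict(duals)
    obs = np.array([r.rtv for r in records])
    lo = np.array([p.q10 for p in preds])
    hi = np.array([p.q90 for p in preds])
    return float(np.mean((obs >= lo) & (obs <= hi)))


@dataclass
class CrossValResult:
    fold_metrics: list[Metrics]
    stratified: list[dict[float, Metrics]]   # per fold: threshold -> metrics


def cross_validate(
    records: Sequence[MoleculeRecord],
    k: int,
    model_config: ModelConfig,
    train_config: TrainConfig,
    similarity_thresholds: Optional[Sequence[float]] = None,
    registry: Optional[dict] = None,
) -> CrossValResult:
    """k-fold cross-validation; each record is tested exactly once.

    Folds are formed over enantiomer pairs (or records, per
    ``pair_policy``).  With ``similarity_thresholds``, metrics are also
    reported on the test subsets having at least one training neighbor
    above each Tanimoto threshold.
    """
    from .cmrt_data import similarity_groups

    if k < 2:
        raise ContractError("k must be >= 2")
    rng = np.random.default_rng(train_config.seed)
    if train_config.pair_policy == "record_level":
        groups = [[i] for i in range(len(records))]
    else:
        by_pair: dict[str, list[int]] = {}
        for i, rec in enumerate(records):
            key = rec.pair_id if rec.pair_id is not None else f"__solo_{i}"
            by_pair.setdefault(key, []).append(i)
        groups = list(by_pair.values())
    order = rng.permutation(len(groups))
    fold_of_group = {gi: fi % k for fi, gi in enumerate(order)}
    fold_metrics = []
    stratified = []
    for fold in range(k):
        test_idx = [i for gi, g in enumerate(groups) for i in g if fold_of_group[gi] == fold]
        rest_idx = [i for gi, g in enumerate(groups) for i in g if fold_of_group[gi] != fold]
        rest = [records[i] for i in rest_idx]
        test = [records[i] for i in test_idx]
        n_val = max(1, int(round(len(rest) * 0.1)))
        valid, tr = rest[:n_val], rest[n_val:]
        result = train(records, model_config, train_config, registry, folds=(tr, valid, test))
        m = evaluate(result.model, test, registry)
        fold_metrics.append(m)
        strat: dict[float, Metrics] = {}
        if similarity_thresholds:
            sg = similarity_groups(test, tr, similarity_thresholds)
            duals = featurize_records(test, model_config, train_config.seed, registry)
            preds = np.array([p.pred for p in result.model.predict(duals)])
            obs = np.array([r.rtv for r in test])
            for t, members in sg.members.items():
                if members:
                    strat[t] = metrics_from_arrays(obs[members], preds[members])
        stratified.append(strat)
    return CrossValResult(fold_metrics, stratified)
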
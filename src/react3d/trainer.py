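"""Training loop: L1 objective, plateau LR schedule, early stopping,
best-checkpoint selection, fold aggregation, and hyperparameter search.

The learning rate is reduced by 40% (factor 0.6) after 60 epochs without
improvement of the validation MAE; training stops after at most 512 epochs
or 150 stagnant epochs, and the parameters from the best-validation epoch
are returned rather than the final ones.  Targets are z-scored by the
training-set mean and standard deviation; metrics are reported in original
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from react3d.autodiff import Adam, Tensor
from react3d.mol_graph import GraphConfig
from react3d.reaction_head import HeadConfig, ReactionModel
from react3d.reaction_io import ReactionRecord
from react3d.splits import SplitSpec, make_split
from react3d.sym_channels import ChannelConfig

__all__ = [
    "TrainConfig",
    "Metrics",
    "PlateauScheduler",
    "train",
    "evaluate",
    "run_folds",
    "hyperparameter_space",
    "random_search",
]


@dataclass
class TrainConfig:
    lr: float = 1e-3                  # {5e-5, 1e-4, 5e-4, 1e-3}
    weight_decay: float = 1e-5        # {1e-5, 1e-4, 1e-3, 0}
    max_epochs: int = 512
    lr_patience: int = 60
    lr_factor: float = 0.6
    stop_patience: int = 150
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError("lr_factor must lie in (0, 1)")


@dataclass
class Metrics:
    """Per-epoch error traces plus the best-validation bookkeeping."""

    train_mae: list[float] = field(default_factory=list)
    train_rmse: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_val_epoch: int = -1

    @property
    def best_val_mae(self) -> float:
        return self.val_mae[self.best_val_epoch]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(len(self.train_mae)),
            "train_mae": self.train_mae, "train_rmse": self.train_rmse,
            "val_mae": self.val_mae, "val_rmse": self.val_rmse,
            "lr": self.lr,
        })


class PlateauScheduler:
    """Multiply the LR by ``factor`` after ``patience`` epochs without a
    strict improvement of the monitored value."""

    def __init__(self, lr: float, patience: int = 60, factor: float = 0.6):
        self.lr = float(lr)
        self.patience = patience
        self.factor = factor
        self.best = np.inf
        self.stale = 0

    def step(self, value: float) -> float:
        if value < self.best:
            self.best = value
            self.stale = 0
        else:
            self.stale += 1
            if self.stale >= self.patience:
                self.lr *= self.factor
                self.stale = 0
        return self.lr


def _errors(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    err = pred - truth
    return float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err**2)))


def evaluate(model: ReactionModel, records) -> dict[str, float]:
    """MAE and RMSE in original target units."""
    items = list(records)
    truth = np.array([r.target for r in items])
    pred = model.predict(items)
    mae, rmse = _errors(pred, truth)
    return {"mae": mae, "rmse": rmse, "n": len(items)}


def train(model: ReactionModel,
          records: list[ReactionRecord],
          split: dict[str, np.ndarray],
          cfg: TrainConfig | None = None,
          verbose: bool = False) -> tuple[list[np.ndarray], Metrics]:
    """Fit the model; returns (best parameters, metric traces).

    The model is left loaded with the best-validation parameters.
    """
    cfg = cfg or TrainConfig()
    for part in ("train", "val"):
        if part not in split or len(split[part]) == 0:
            raise ValueError(f"empty {part} partition")
    train_recs = [records[i] for i in split["train"]]
    val_recs = [records[i] for i in split["val"]]

    # target standardization on the training set
    t_train = np.array([r.target for r in train_recs])
    model.target_mean = float(t_train.mean())
    model.target_std = float(t_train.std()) or 1.0

    prepared_train = model.prepare(train_recs)
    prepared_val = model.prepare(val_recs)
    y_train = (t_train - model.target_mean) / model.target_std
    y_val_true = np.array([r.target for r in val_recs])

    params = model.parameters()
    opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = PlateauScheduler(cfg.lr, cfg.lr_patience, cfg.lr_factor)
    rng = np.random.default_rng(cfg.seed)
    metrics = Metrics()
    best_val = np.inf
    best_state = model.get_state()
    stale = 0

    n = len(prepared_train)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        abs_sum = 0.0
        sq_sum = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = [prepared_train[i] for i in idx]
            pred = model.forward(batch, train=True, rng=rng)
            resid = pred - Tensor(y_train[idx])
            loss = resid.abs().mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (lr={sched.lr:g})")
            opt.zero_grad()
            loss.backward()
            opt.lr = sched.lr
            opt.step()
            abs_sum += np.abs(resid.data).sum()
            sq_sum += (resid.data**2).sum()
        train_mae = abs_sum / n * model.target_std
        train_rmse = np.sqrt(sq_sum / n) * model.target_std

        val_pred = model.predict(prepared_val)
        val_mae, val_rmse = _errors(val_pred, y_val_true)

        metrics.train_mae.append(train_mae)
        metrics.train_rmse.append(train_rmse)
        metrics.val_mae.append(val_mae)
        metrics.val_rmse.append(val_rmse)
        metrics.lr.append(sched.lr)

        if val_mae < best_val:
            best_val = val_mae
            best_state = model.get_state()
            metrics.best_val_epoch = epoch
            stale = 0
        else:
            stale += 1
        if verbose and (epoch % 25 == 0 or epoch == cfg.max_epochs - 1):
            print(f"epoch {epoch:4d}  train {train_mae:.4f}  "
                  f"val {val_mae:.4f}  lr {sched.lr:g}")
        sched.step(val_mae)
        if stale >= cfg.stop_patience:
            break

    model.set_state(best_state)
    return best_state, metrics


def run_folds(records: list[ReactionRecord],
              split_spec: SplitSpec,
              k: int = 10,
              model_factory=None,
              train_cfg: TrainConfig | None = None) -> dict:
    """k independently seeded splits/trainings; aggregate test errors."""
    train_cfg = train_cfg or TrainConfig()
    if model_factory is None:
        model_factory = lambda seed: ReactionModel(seed=seed)  # noqa: E731
    maes, rmses, rows = [], [], []
    for fold in range(k):
        spec = replace(split_spec, seed=split_spec.seed + fold)
        split = make_split(records, spec)
        model = model_factory(train_cfg.seed + fold)
        cfg = replace(train_cfg, seed=train_cfg.seed + fold)
        _, metrics = train(model, records, split, cfg)
        test = evaluate(model, [records[i] for i in split["test"]])
        maes.append(test["mae"])
        rmses.append(test["rmse"])
        rows.append({"fold": fold, "test_mae": test["mae"],
                     "test_rmse": test["rmse"],
                     "best_val_epoch": metrics.best_val_epoch})
    return {
        "k": k,
        "mae_mean": float(np.mean(maes)),
        "mae_std": float(np.std(maes)),
        "rmse_mean": float(np.mean(rmses)),
        "rmse_std": float(np.std(rmses)),
        "folds": pd.DataFrame(rows),
    }


def hyperparameter_space() -> dict[str, list]:
    """The hyperparameter search space."""
    return {
        "lr": [5e-5, 1e-4, 5e-4, 1e-3],
        "weight_decay": [1e-5, 1e-4, 1e-3, 0.0],
        "n_s": [16, 32, 48, 64],
        "n_v": [16, 32, 48, 64],
        "n_g": [16, 32, 48, 64],
        "n_conv": [2, 3],
        "r_max": [2.5, 5.0, 10.0],
        "n_neigh": [10, 25, 50],
        "dropout": [0.0, 0.05, 0.1],
        "sum_mode": ["node", "both"],
        "combine_mode": ["mlp", "diff", "mean", "sum"],
        "graph_mode": ["energy", "vector"],
    }


def _configs_from_sample(sample: dict, variant: str, mapping_variant: str,
                         exclude_h: bool):
    graph = GraphConfig(r_max=sample["r_max"], n_neigh=sample["n_neigh"],
                        n_g=sample["n_g"], exclude_h=exclude_h)
    chan = ChannelConfig(variant=variant, n_s=sample["n_s"],
                         n_v=sample["n_v"], n_conv=sample["n_conv"],
                         dropout=sample["dropout"],
                         sum_mode=sample["sum_mode"])
    head = HeadConfig(mapping_variant=mapping_variant,
                      combine_mode=sample["combine_mode"],
                      graph_mode=sample["graph_mode"])
    return graph, chan, head


def random_search(records: list[ReactionRecord],
                  split: dict[str, np.ndarray],
                  n_trials: int = 8,
                  epochs: int = 128,
                  seed: int = 0,
                  variant: str = "invariant",
                  mapping_variant: str = "S",
                  exclude_h: bool = True) -> dict:
    """Random search over the hyperparameter space on one split.

    A lightweight stand-in for an external Bayesian sweep service: each
    trial trains for an ``epochs`` budget and the configuration with the
    best validation MAE wins.
    """
    rng = np.random.default_rng(seed)
    space = hyperparameter_space()
    best = None
    trials = []
    for t in range(n_trials):
        sample = {k: v[rng.integers(len(v))] for k, v in space.items()}
        graph, chan, head = _configs_from_sample(
            sample, variant, mapping_variant, exclude_h)
        model = ReactionModel(graph, chan, head, seed=seed + t)
        cfg = TrainConfig(lr=sample["lr"],
                          weight_decay=sample["weight_decay"],
                          max_epochs=epochs, seed=seed + t)
        _, metrics = train(model, records, split, cfg)
        val = metrics.best_val_mae
        trials.append({**sample, "val_mae": val})
        if best is None or val < best["val_mae"]:
            best = {"sample": sample, "val_mae": val}
    return {"best": best, "trials": pd.DataFrame(trials)}
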
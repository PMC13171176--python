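"""Gene-holdout cross-validation, MSE training, fine-tuning and scrambling.

The evaluation design is five-fold CV over genes: test folds are a fixed,
seed-independent partition of the gene set; each fold is trained five times
with different seeds controlling weight initialization, the inner
train/validation split (10% of non-test genes) and batch shuffling.
Training minimizes MSE with Adam using L2-coupled weight decay (the
torch-style variant); validation
loss is computed every ``val_every`` epochs and the best-validation
checkpoint is kept — no other early stopping.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .model import ModelConfig, build_model

logger = logging.getLogger(__name__)


@dataclass
class Dataset:
    """In-memory model inputs: x (N, C, L), targets y (N,), gene ids."""

    x: np.ndarray
    y: np.ndarray
    gene_ids: list

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.float32).reshape(-1)
        self.gene_ids = list(self.gene_ids)
        if not (len(self.gene_ids) == self.x.shape[0] == self.y.shape[0]):
            raise ValueError("x, y and gene_ids must agree in length")

    @property
    def n(self):
        return self.x.shape[0]

    @property
    def channels(self):
        return self.x.shape[1]

    def subset(self, gene_ids: Sequence[str]) -> "Dataset":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}...")
        idx = [index[g] for g in gene_ids]
        return Dataset(self.x[idx], self.y[idx], [self.gene_ids[i] for i in idx])

    def with_channels(self, mode: str) -> "Dataset":
        from .model import ablate_channels

        return Dataset(ablate_channels(self.x, mode), self.y, self.gene_ids)


@dataclass
class TrainConfig:
    lr: float = 5e-5
    weight_decay: float = 1e-3
    batch_size: int = 512
    max_epochs: int = 500
    val_every: int = 4

    def __post_init__(self):
        if (self.lr <= 0 or self.weight_decay < 0 or self.batch_size < 1
                or self.max_epochs < 1 or self.val_every < 1):
            raise ValueError("training parameters must be positive")
        if self.val_every > self.max_epochs:
            raise ValueError("val_every must not exceed max_epochs")


FINE_TUNE_OVERRIDES = dict(lr=1e-5, weight_decay=1e-4, max_epochs=200)


def fine_tune_config(base: TrainConfig | None = None, **overrides) -> TrainConfig:
    """The fine-tuning schedule: lower lr (1e-5), reduced weight decay
    (1e-4), at most 200 epochs; other fields inherited."""
    d = asdict(base) if base else {}
    d.update(FINE_TUNE_OVERRIDES)
    d.update(overrides)
    return TrainConfig(**d)


@dataclass
class FoldSplit:
    """k disjoint test folds plus per-(fold, seed) inner train/val splits."""

    test_folds: list  # list[list[str]]
    inner: dict  # {(fold, seed): (train_ids, val_ids)}
    seeds: list

    def save(self, path: str | Path) -> None:
        payload = {
            "test_folds": self.test_folds,
            "seeds": list(self.seeds),
            "inner": {
                f"{fold}:{seed}": {"train": tr, "val": va}
                for (fold, seed), (tr, va) in self.inner.items()
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "FoldSplit":
        payload = json.loads(Path(path).read_text())
        inner = {}
        for key, d in payload["inner"].items():
            fold, seed = key.split(":")
            inner[(int(fold), int(seed))] = (d["train"], d["val"])
        return cls(payload["test_folds"], inner, payload["seeds"])


def make_folds(
    gene_ids: Sequence[str],
    k: int = 5,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    val_fraction: float = 0.1,
    fold_seed: int = 0,
) -> FoldSplit:
    """Partition genes into ``k`` test folds (fixed, seed-independent given
    ``fold_seed``) and build the seed-specific inner train/validation
    splits over each fold's complement."""
    gene_ids = list(gene_ids)
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene_ids contain duplicates")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(fold_seed)
    order = list(np.array(gene_ids)[rng.permutation(len(gene_ids))])
    test_folds = [sorted(order[i::k]) for i in range(k)]
    inner = {}
    for fold in range(k):
        test = set(test_folds[fold])
        rest = [g for g in gene_ids if g not in test]
        for seed in seeds:
            srng = np.random.default_rng((fold_seed, fold, seed))
            perm = srng.permutation(len(rest))
            n_val = max(1, int(round(val_fraction * len(rest))))
            val = sorted(np.array(rest)[perm[:n_val]])
            train = sorted(np.array(rest)[perm[n_val:]])
            inner[(fold, seed)] = (list(map(str, train)), list(map(str, val)))
    return FoldSplit(test_folds, inner, list(seeds))


@dataclass
class Checkpoint:
    """Best-validation model state plus its provenance and loss history."""

    model_config: ModelConfig
    state: dict
    seed: int
    history: list = field(default_factory=list)  # [(epoch, train_mse, val_mse)]
    best_val: float = np.nan
    best_epoch: int = -1
    final_state: dict | None = None  # end-of-schedule weights (see train())

    def build(self) -> nn.Sequential:
        model = build_model(self.model_config, self.seed)
        model.load_state_dict(self.state)
        return model

    def build_final(self) -> nn.Sequential:
        """The model at the last training epoch, ignoring validation-based
        selection. Used for scrambled-training evaluation, where the inner
        validation signal is itself scrambled and "best validation" would
        systematically select the least-trained state."""
        model = build_model(self.model_config, self.seed)
        model.load_state_dict(self.final_state if self.final_state is not None else self.state)
        return model

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = dict(self.state)
        if self.final_state is not None:
            arrays.update({f"final::{k}": v for k, v in self.final_state.items()})
        np.savez(path.with_suffix(".npz"), **arrays)
        manifest = {
            "model_config": self.model_config.to_dict(),
            "seed": self.seed,
            "history": self.history,
            "best_val": None if np.isnan(self.best_val) else self.best_val,
            "best_epoch": self.best_epoch,
        }
        path.with_suffix(".json").write_text(json.dumps(manifest))

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        arrays = dict(np.load(path.with_suffix(".npz")))
        state = {k: v for k, v in arrays.items() if not k.startswith("final::")}
        final = {k[len("final::"):]: v for k, v in arrays.items() if k.startswith("final::")}
        return cls(
            ModelConfig.from_dict(manifest["model_config"]),
            state,
            manifest["seed"],
            [tuple(h) for h in manifest["history"]],
            manifest["best_val"] if manifest["best_val"] is not None else np.nan,
            manifest["best_epoch"],
            final_state=final or None,
        )


def _mse(model: nn.Sequential, data: Dataset, batch_size: int = 4096) -> float:
    pred = model.predict(data.x, batch_size=batch_size)
    return float(np.mean((pred - data.y) ** 2))


def train(
    model_config: ModelConfig,
    train_config: TrainConfig,
    train_data: Dataset,
    val_data: Dataset,
    seed: int,
    initial_model: nn.Sequential | None = None,
) -> Checkpoint:
    """Train to minimum-validation-MSE checkpoint.

    ``initial_model`` (for fine-tuning) bypasses fresh initialization but
    keeps the seeded batch ordering. Validation MSE is evaluated at epochs
    val_every, 2*val_every, ...; the state with the lowest validation MSE
    is returned. NaN loss aborts with a diagnostic.
    """
    if train_data.channels != model_config.input_channels:
        raise ValueError(
            f"dataset has {train_data.channels} channels, "
            f"config expects {model_config.input_channels}"
        )
    model = initial_model if initial_model is not None else build_model(model_config, seed)
    opt = nn.Adam(model, lr=train_config.lr, weight_decay=train_config.weight_decay)
    batch_rng = np.random.default_rng((seed, 0xBA7C4))
    history = []
    best_val, best_state, best_epoch = np.inf, model.state_dict(), 0
    n = train_data.n
    for epoch in range(1, train_config.max_epochs + 1):
        perm = batch_rng.permutation(n)
        epoch_losses = []
        for i in range(0, n, train_config.batch_size):
            idx = perm[i : i + train_config.batch_size]
            xb, yb = train_data.x[idx], train_data.y[idx]
            out = model.forward(xb, train=True).reshape(-1)
            err = out - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={train_config.lr}); aborting"
                )
            epoch_losses.append(loss)
            model.backward((2.0 * err / err.size).reshape(-1, 1).astype(np.float32))
            opt.step()
        if epoch % train_config.val_every == 0:
            val_mse = _mse(model, val_data)
            history.append((epoch, float(np.mean(epoch_losses)), val_mse))
            if val_mse < best_val:
                best_val, best_state, best_epoch = val_mse, model.state_dict(), epoch
    return Checkpoint(model_config, best_state, seed, history, best_val, best_epoch,
                      final_state=model.state_dict())


def fine_tune(
    pretrained: Checkpoint,
    dataset_train: Dataset,
    dataset_val: Dataset,
    seed: int,
    train_config: TrainConfig | None = None,
) -> Checkpoint:
    """Fine-tune a DNA-only (4-channel) checkpoint into a 5-channel model.

    All weights shared between the two architectures are copied exactly;
    only the first convolution's ATAC-channel slice is freshly (seeded)
    initialized. Training then runs under the fine-tune schedule.
    """
    if pretrained.model_config.input_channels != 4:
        raise ValueError("pretrained checkpoint must be a 4-channel (DNA-only) model")
    config5 = ModelConfig.from_dict(
        {**pretrained.model_config.to_dict(), "input_channels": 5}
    )
    model = init_full_from_dna(pretrained, seed)
    cfg = train_config or fine_tune_config()
    return train(config5, cfg, dataset_train, dataset_val, seed, initial_model=model)


def init_full_from_dna(pretrained: Checkpoint, seed: int) -> nn.Sequential:
    """Build the 5-channel model initialized from a DNA-only checkpoint
    (fresh random weights only in the first conv's ATAC slice)."""
    config5 = ModelConfig.from_dict(
        {**pretrained.model_config.to_dict(), "input_channels": 5}
    )
    model = build_model(config5, seed)
    source = pretrained.state
    for key, layer, name, value in model.named_parameters():
        if key not in source:
            raise ValueError(f"parameter {key} missing from pretrained state")
        src = source[key]
        if src.shape == value.shape:
            layer.params[name] = src.copy()
        elif (
            isinstance(layer, nn.Conv1d)
            and name == "W"
            and src.shape[0] == value.shape[0]
            and src.shape[2] == value.shape[2]
            and src.shape[1] == 4
            and value.shape[1] == 5
        ):
            merged = value.copy()  # keeps the fresh random ATAC slice
            merged[:, :4, :] = src
            layer.params[name] = merged
        else:
            raise ValueError(
                f"shape mismatch for {key}: {src.shape} vs {value.shape} "
                "(only the first-layer channel dimension may differ)"
            )
    return model


def scramble(
    dataset: Dataset,
    what: str,
    seed: int,
    mode: str = "separate",
) -> Dataset:
    """Permute input blocks across genes while keeping targets in place.

    what='dna' permutes the 4 DNA rows jointly across genes; 'atac'
    permutes the ATAC row; 'both' with mode='pairwise' applies one shared
    permutation to (DNA, ATAC) jointly, with mode='separate' two
    independent permutations (forced to differ when n <= 2 so the pairing
    is actually broken). mode='pairwise' is only defined for what='both'.
    """
    if what not in ("dna", "atac", "both"):
        raise ValueError(f"unknown scramble target {what!r}")
    if mode not in ("pairwise", "separate"):
        raise ValueError(f"unknown scramble mode {mode!r}")
    if mode == "pairwise" and what != "both":
        raise ValueError("mode='pairwise' is only defined for what='both'")
    if dataset.channels != 5:
        raise ValueError("scrambling requires a 5-channel dataset")
    rng = np.random.default_rng((seed, 0x5C3A))
    n = dataset.n
    x = dataset.x.copy()
    if what == "dna":
        perm = rng.permutation(n)
        x[:, :4, :] = x[perm, :4, :]
    elif what == "atac":
        perm = rng.permutation(n)
        x[:, 4, :] = x[perm, 4, :]
    elif what == "both" and mode == "pairwise":
        perm = rng.permutation(n)
        x = x[perm]
    else:  # both, separate
        perm_dna = rng.permutation(n)
        perm_atac = rng.permutation(n)
        if n <= 2:
            while np.array_equal(perm_dna, perm_atac):
                perm_atac = rng.permutation(n)
        x[:, :4, :] = dataset.x[perm_dna, :4, :]
        x[:, 4, :] = dataset.x[perm_atac, 4, :]
    return Dataset(x, dataset.y.copy(), dataset.gene_ids)


def scramble_splits(
    splits: dict,
    what: str,
    mode: str,
    which: str,
    seed: int,
) -> dict:
    """Scramble only the selected split ('train' or 'test') of a
    {'train': Dataset, 'test': Dataset, ...} mapping."""
    if which not in splits:
        raise KeyError(f"split {which!r} not present (have {sorted(splits)})")
    out = dict(splits)
    out[which] = scramble(splits[which], what, seed, mode=mode)
    return out


def chromosome_holdout_split(
    promoters,
    held_out: Sequence[str] = ("chr2", "chr9"),
) -> tuple[list, list]:
    """Train/test gene lists with whole chromosomes held out as the test
    set (used for input-length sweeps, where gene-level folds could let
    long windows overlap between train and test)."""
    held = set(held_out)
    test = [p.gene_id for p in promoters if p.chrom in held]
    train_ids = [p.gene_id for p in promoters if p.chrom not in held]
    if not test:
        warnings.warn(f"no genes on held-out chromosomes {sorted(held)}; empty test set")
    return train_ids, test
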
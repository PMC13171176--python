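"""Desk-scale experiment protocols on synthetic data.

These functions bundle the standard experiments — channel-ablation ladder,
input-scrambling ladder, fine-tuning, attribution/accessibility alignment —
at a reduced scale chosen to run on a single CPU: 3000 genes, 500 bp
windows, a slimmed CNN (16+16 conv filters, dense 256+64) and a short,
hotter training schedule (lr 2e-3, weight decay 1e-4, batch 512, 48
epochs) in place of the full-scale defaults. One CV fold with five seed
replicates stands in for the full 5x5 grid; the fold partition itself is
unchanged.

Scrambled-training runs are evaluated at the *final* epoch rather than the
best-validation checkpoint: under scrambled training the inner validation
signal is scrambled too, so validation-based selection would systematically
return the least-trained (near-initialization) model, whose predictions
still read the unscrambled accessibility amplitude through what is
effectively a random projection. The long-run trained state is the
quantity of interest — what training on decoupled inputs converges to.
"""

from __future__ import annotations

import numpy as np

from . import attribution as attr_mod
from . import evaluation, training
from .model import ModelConfig
from .synth import SyntheticDataset

ABLATION_MODES = {"dna_atac": 5, "atac_only": 1, "dna_only": 4}
SCRAMBLE_MODES = ("dna", "atac", "both")


def desk_model_config(channels: int, L: int = 500) -> ModelConfig:
    return ModelConfig(
        input_channels=channels,
        input_length=L,
        conv_specs=((16, 8, 4), (16, 8, 4)),
        dense_sizes=(256, 64),
        dropout=0.1,
    )


def desk_train_config(**overrides) -> training.TrainConfig:
    kw = dict(lr=2e-3, weight_decay=1e-4, batch_size=512, max_epochs=48, val_every=4)
    kw.update(overrides)
    return training.TrainConfig(**kw)


def desk_finetune_config(**overrides) -> training.TrainConfig:
    kw = dict(lr=5e-4, weight_decay=1e-4, batch_size=512, max_epochs=12, val_every=4)
    kw.update(overrides)
    return training.TrainConfig(**kw)


def run_ablation(
    data: SyntheticDataset,
    cell_type: str | None = None,
    fold: int = 0,
    seeds=(0, 1, 2, 3, 4),
    train_config: training.TrainConfig | None = None,
    modes=tuple(ABLATION_MODES),
) -> dict:
    """Train per-seed models for each channel mode on one CV fold.

    Returns {mode: {"checkpoints": {seed: Checkpoint}, "pearson": {seed: r},
    "test_genes": [...]}} with per-seed test-set Pearson of the
    best-validation model.
    """
    cell_type = cell_type or data.cell_types[0]
    ds5 = data.model_dataset(cell_type)
    folds = training.make_folds(ds5.gene_ids, k=5, seeds=list(seeds), val_fraction=0.1)
    test = folds.test_folds[fold]
    out = {}
    for mode in modes:
        channels = ABLATION_MODES[mode]
        ds = ds5 if mode == "dna_atac" else ds5.with_channels(mode)
        te = ds.subset(test)
        ckpts, pearsons = {}, {}
        for seed in seeds:
            tr, va = folds.inner[(fold, seed)]
            ck = training.train(
                desk_model_config(channels, ds.x.shape[2]),
                train_config or desk_train_config(),
                ds.subset(tr), ds.subset(va), seed=seed,
            )
            pred = ck.build().predict(te.x)
            ckpts[seed] = ck
            pearsons[seed] = evaluation.metrics(te.y, pred)["pearson"]
        out[mode] = {"checkpoints": ckpts, "pearson": pearsons, "test_genes": test}
    return out


def run_scrambles(
    data: SyntheticDataset,
    cell_type: str | None = None,
    fold: int = 0,
    seeds=(0, 1, 2),
    train_config: training.TrainConfig | None = None,
    modes=SCRAMBLE_MODES,
) -> dict:
    """Train 5-channel models on scrambled training inputs and score the
    end-of-schedule model on the unscrambled test fold.

    Returns {what: {seed: pearson}} for what in dna/atac/both (all
    'separate' scrambling).
    """
    cell_type = cell_type or data.cell_types[0]
    ds5 = data.model_dataset(cell_type)
    folds = training.make_folds(ds5.gene_ids, k=5, seeds=list(seeds), val_fraction=0.1)
    test = folds.test_folds[fold]
    te = ds5.subset(test)
    out = {}
    for what in modes:
        out[what] = {}
        for seed in seeds:
            tr, va = folds.inner[(fold, seed)]
            scrambled = training.scramble(ds5.subset(tr + va), what, seed=seed,
                                          mode="separate")
            ck = training.train(
                desk_model_config(5, ds5.x.shape[2]),
                train_config or desk_train_config(),
                scrambled.subset(tr), scrambled.subset(va), seed=seed,
            )
            pred = ck.build_final().predict(te.x)
            out[what][seed] = evaluation.metrics(te.y, pred)["pearson"]
    return out


def attribution_alignment(
    data: SyntheticDataset,
    ablation: dict,
    cell_type: str | None = None,
    n_genes: int = 40,
    n_backgrounds: int = 20,
    seed: int = 0,
) -> dict:
    """Positional Spearman of mean DNA-channel attribution with the mean
    ATAC input track, per seed replicate, for the DNA+ATAC and DNA-only
    models of an ablation run.

    Returns {"dna_atac": {seed: rho}, "dna_only": {seed: rho}} where rho is
    the average of the four DNA channels' positional Spearman coefficients.
    """
    cell_type = cell_type or data.cell_types[0]
    ds5 = data.model_dataset(cell_type)
    genes = list(ablation["dna_atac"]["test_genes"])[:n_genes]
    sub5 = ds5.subset(genes)
    mean_atac = sub5.x[:, 4, :].mean(axis=0)
    out = {}
    for mode in ("dna_atac", "dna_only"):
        ckpts = ablation[mode]["checkpoints"]
        sub = sub5 if mode == "dna_atac" else sub5.with_channels("dna_only")
        out[mode] = {}
        for s, ck in ckpts.items():
            net = ck.build()
            profiles = []
            for gi in range(sub.n):
                sample = sub.x[gi].astype(np.float64)
                bg = attr_mod.make_backgrounds(sample, n=n_backgrounds,
                                               seed=(seed, s, gi))
                profiles.append(net.delta_attribution(sample, bg))
            profile = np.mean(profiles, axis=0)
            rhos = attr_mod.channel_track_correlation(profile[:4], mean_atac)
            out[mode][s] = float(np.nanmean(rhos))
    return out


def truth_kmer_tables(pair: SyntheticDataset, k: int = 6) -> dict:
    """Per-cell-type k-mer score tables built from ground-truth attribution
    proxies: the per-base score inside a planted motif footprint is the
    motif's effect size times the local normalized accessibility, zero
    elsewhere. Used for cross-cell-type k-mer comparisons without training.
    """
    from . import kmers

    cfg = pair.truth.config
    tables = {}
    for ci, ct in enumerate(pair.cell_types):
        pool = []
        for g in pair.gene_ids:
            per_base = np.zeros(cfg.L)
            for mi, pos in pair.truth.motif_instances[g]:
                mlen = len(cfg.motifs[mi])
                access = pair.tracks[ct][g].normalized[pos : pos + mlen]
                per_base[pos : pos + mlen] = cfg.beta[mi, ci] * access
            pool.extend(kmers.score_instances(pair.sequences[g], per_base, k))
        tables[ct] = kmers.build_table(pool, k, variant="positive_only")
    return tables


def run_finetune(
    data: SyntheticDataset,
    ablation: dict,
    cell_type: str | None = None,
    fold: int = 0,
    seed: int = 0,
    train_config: training.TrainConfig | None = None,
):
    """Fine-tune the DNA-only checkpoint of one seed into a 5-channel model
    and report validation MSE at initialization and after fine-tuning."""
    cell_type = cell_type or data.cell_types[0]
    ds5 = data.model_dataset(cell_type)
    folds = training.make_folds(ds5.gene_ids, k=5,
                                seeds=sorted(ablation["dna_only"]["checkpoints"]),
                                val_fraction=0.1)
    tr, va = folds.inner[(fold, seed)]
    pretrained = ablation["dna_only"]["checkpoints"][seed]
    init_model = training.init_full_from_dna(pretrained, seed)
    val = ds5.subset(va)
    init_val_mse = float(np.mean((init_model.predict(val.x) - val.y) ** 2))
    ck = training.fine_tune(pretrained, ds5.subset(tr), val, seed,
                            train_config=train_config or desk_finetune_config())
    ft_val_mse = float(np.mean((ck.build().predict(val.x) - val.y) ** 2))
    test = folds.test_folds[fold]
    te = ds5.subset(test)
    pearson = evaluation.metrics(te.y, ck.build().predict(te.x))["pearson"]
    return {"init_val_mse": init_val_mse, "finetuned_val_mse": ft_val_mse,
            "test_pearson": pearson, "checkpoint": ck}
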
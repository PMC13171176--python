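import json

import numpy as np
import pytest

from chromexpr import training
from chromexpr.genome_io import PromoterRecord
from chromexpr.model import ModelConfig
from chromexpr.training import (
    Checkpoint,
    Dataset,
    FoldSplit,
    TrainConfig,
    chromosome_holdout_split,
    fine_tune,
    init_full_from_dna,
    make_folds,
    scramble,
    scramble_splits,
    train,
)


def random_dataset(n=30, C=5, L=40, seed=0):
    rng = np.random.default_rng(seed)
    x = np.zeros((n, C, L), dtype=np.float32)
    if C >= 4:
        idx = rng.integers(0, 4, size=(n, L))
        for b in range(4):
            x[:, b, :] = idx == b
        if C == 5:
            x[:, 4, :] = rng.random((n, L))
    else:
        x[:, 0, :] = rng.random((n, L))
    y = rng.random(n)
    return Dataset(x, y, [f"g{i:03d}" for i in range(n)])


def small_model_config(C=5, L=40):
    return ModelConfig(input_channels=C, input_length=L,
                       conv_specs=((6, 5, 4),), dense_sizes=(8,), dropout=0.0)


class TestFolds:
    def test_partition_disjoint_and_exhaustive(self):
        genes = [f"g{i}" for i in range(10)]
        fs = make_folds(genes, k=5, seeds=[0])
        all_test = [g for fold in fs.test_folds for g in fold]
        assert sorted(all_test) == sorted(genes)
        assert all(len(f) == 2 for f in fs.test_folds)

    def test_inner_split_covers_complement(self):
        genes = [f"g{i}" for i in range(20)]
        fs = make_folds(genes, k=4, seeds=[0, 1], val_fraction=0.25)
        for fold in range(4):
            test = set(fs.test_folds[fold])
            for seed in (0, 1):
                tr, va = fs.inner[(fold, seed)]
                assert set(tr) | set(va) == set(genes) - test
                assert not set(tr) & set(va)

    def test_seeds_share_test_folds_but_differ_in_validation(self):
        genes = [f"g{i}" for i in range(40)]
        fs = make_folds(genes, k=5, seeds=[0, 1])
        v0 = set(fs.inner[(0, 0)][1])
        v1 = set(fs.inner[(0, 1)][1])
        assert v0 != v1
        assert fs.test_folds == make_folds(genes, k=5, seeds=[7]).test_folds

    def test_serialization_roundtrip_bit_exact(self, tmp_path):
        genes = [f"g{i}" for i in range(15)]
        fs = make_folds(genes, k=3, seeds=[0, 1])
        fs.save(tmp_path / "folds.json")
        back = FoldSplit.load(tmp_path / "folds.json")
        assert back.test_folds == fs.test_folds
        assert back.inner == fs.inner
        assert back.seeds == fs.seeds

    def test_duplicate_gene_ids_error(self):
        with pytest.raises(ValueError, match="duplicates"):
            make_folds(["a", "a", "b"], k=2)


class TestTrain:
    def test_single_validation_evaluation_returns_its_checkpoint(self):
        ds = random_dataset()
        cfg = TrainConfig(lr=1e-3, weight_decay=0.0, batch_size=16,
                          max_epochs=4, val_every=4)
        ck = train(small_model_config(), cfg, ds, ds, seed=0)
        assert len(ck.history) == 1
        assert ck.best_epoch == 4

    def test_same_seed_reproduces_history(self):
        ds = random_dataset()
        cfg = TrainConfig(lr=1e-3, weight_decay=1e-4, batch_size=16,
                          max_epochs=8, val_every=4)
        h1 = train(small_model_config(), cfg, ds, ds, seed=3).history
        h2 = train(small_model_config(), cfg, ds, ds, seed=3).history
        assert h1 == h2

    def test_learns_mean_atac_target(self):
        """An ATAC-only model trained on y = mean(track) beats the
        untrained model's validation MSE."""
        rng = np.random.default_rng(0)
        x = rng.random((120, 1, 40)).astype(np.float32)
        y = x[:, 0, :].mean(axis=1)
        ds = Dataset(x, y, [f"g{i}" for i in range(120)])
        tr, va = ds.subset(ds.gene_ids[:100]), ds.subset(ds.gene_ids[100:])
        mcfg = small_model_config(C=1)
        cfg = TrainConfig(lr=3e-3, weight_decay=0.0, batch_size=25,
                          max_epochs=40, val_every=4)
        from chromexpr.model import build_model

        untrained = build_model(mcfg, 0)
        base = float(np.mean((untrained.predict(va.x) - va.y) ** 2))
        ck = train(mcfg, cfg, tr, va, seed=0)
        assert ck.best_val < base

    def test_channel_mismatch_raises(self):
        ds = random_dataset(C=5)
        with pytest.raises(ValueError, match="channels"):
            train(small_model_config(C=4), TrainConfig(max_epochs=4, val_every=4),
                  ds, ds, seed=0)

    def test_checkpoint_roundtrip_reproduces_best_val(self, tmp_path):
        ds = random_dataset()
        cfg = TrainConfig(lr=1e-3, weight_decay=1e-4, batch_size=16,
                          max_epochs=8, val_every=4)
        ck = train(small_model_config(), cfg, ds, ds, seed=0)
        ck.save(tmp_path / "ck")
        back = Checkpoint.load(tmp_path / "ck")
        val_mse = float(np.mean((back.build().predict(ds.x) - ds.y) ** 2))
        assert abs(val_mse - ck.best_val) < 1e-6
        assert back.final_state is not None


class TestFineTune:
    def make_pretrained(self):
        ds = random_dataset(C=4)
        cfg = TrainConfig(lr=1e-3, weight_decay=0.0, batch_size=16,
                          max_epochs=4, val_every=4)
        return train(small_model_config(C=4), cfg, ds, ds, seed=0)

    def test_shared_weights_copied_exactly(self):
        pre = self.make_pretrained()
        net5 = init_full_from_dna(pre, seed=9)
        for key, layer, name, value in net5.named_parameters():
            src = pre.state[key]
            if value.shape == src.shape:
                assert np.array_equal(value, src)
            else:
                assert np.array_equal(value[:, :4, :], src)

    def test_zeroed_atac_slice_reproduces_pretrained_predictions(self):
        pre = self.make_pretrained()
        net5 = init_full_from_dna(pre, seed=9)
        net5.layers[0].params["W"][:, 4, :] = 0.0
        ds = random_dataset(C=5, seed=1)
        p5 = net5.predict(ds.x)
        p4 = pre.build().predict(ds.x[:, :4, :])
        assert np.allclose(p5, p4, atol=1e-6)

    def test_finetuning_does_not_worsen_validation_mse(self):
        pre = self.make_pretrained()
        ds5 = random_dataset(C=5, seed=2)
        net5 = init_full_from_dna(pre, seed=0)
        init_mse = float(np.mean((net5.predict(ds5.x) - ds5.y) ** 2))
        cfg = TrainConfig(lr=5e-4, weight_decay=0.0, batch_size=16,
                          max_epochs=8, val_every=4)
        ck = fine_tune(pre, ds5, ds5, seed=0, train_config=cfg)
        assert ck.best_val <= init_mse + 1e-9

    def test_five_channel_checkpoint_rejected_as_source(self):
        ds = random_dataset(C=5)
        cfg = TrainConfig(lr=1e-3, weight_decay=0.0, batch_size=16,
                          max_epochs=4, val_every=4)
        ck5 = train(small_model_config(C=5), cfg, ds, ds, seed=0)
        with pytest.raises(ValueError, match="4-channel"):
            fine_tune(ck5, ds, ds, seed=0)


def block_multiset(x, rows):
    return sorted(map(tuple, np.round(x[:, rows, :], 6).reshape(x.shape[0], -1).tolist()))


class TestScramble:
    def test_dna_scramble_preserves_block_multiset_and_targets(self):
        ds = random_dataset(n=12)
        out = scramble(ds, "dna", seed=0)
        assert block_multiset(out.x, range(4)) == block_multiset(ds.x, range(4))
        assert np.array_equal(out.x[:, 4], ds.x[:, 4])
        assert np.array_equal(out.y, ds.y)

    def test_atac_scramble_moves_only_atac_rows(self):
        ds = random_dataset(n=12)
        out = scramble(ds, "atac", seed=0)
        assert np.array_equal(out.x[:, :4], ds.x[:, :4])
        assert block_multiset(out.x, [4]) == block_multiset(ds.x, [4])

    def test_pairwise_keeps_dna_atac_coindexed(self):
        ds = random_dataset(n=6)
        out = scramble(ds, "both", seed=1, mode="pairwise")
        # every output sample must be exactly some input sample's 5 rows
        originals = {ds.x[i].tobytes() for i in range(ds.n)}
        assert all(out.x[i].tobytes() in originals for i in range(out.n))
        assert np.array_equal(out.y, ds.y)

    def test_separate_breaks_pairing_at_n2(self):
        ds = random_dataset(n=2)
        out = scramble(ds, "both", seed=5, mode="separate")
        paired = any(
            np.array_equal(out.x[i, :4], ds.x[j, :4])
            and np.array_equal(out.x[i, 4], ds.x[j, 4])
            for i in range(2) for j in range(2)
        )
        assert not paired

    def test_pairwise_requires_both(self):
        ds = random_dataset(n=4)
        with pytest.raises(ValueError, match="pairwise"):
            scramble(ds, "dna", seed=0, mode="pairwise")

    def test_requires_five_channels(self):
        with pytest.raises(ValueError, match="5-channel"):
            scramble(random_dataset(C=4), "dna", seed=0)

    def test_scramble_splits_touches_only_selected_split(self):
        splits = {"train": random_dataset(n=8, seed=0),
                  "test": random_dataset(n=8, seed=1)}
        out = scramble_splits(splits, "dna", "separate", "train", seed=0)
        assert out["test"] is splits["test"]
        assert not np.array_equal(out["train"].x, splits["train"].x)


class TestChromosomeHoldout:
    def promoters(self, chroms):
        return [PromoterRecord(f"g{i}", c, "+", 100) for i, c in enumerate(chroms)]

    def test_held_out_chromosomes_form_test_set(self):
        tr, te = chromosome_holdout_split(self.promoters(["chr1", "chr2", "chr9", "chr3"]))
        assert te == ["g1", "g2"]
        assert tr == ["g0", "g3"]

    def test_union_is_everything(self):
        proms = self.promoters(["chr1", "chr2", "chr2", "chr5"])
        tr, te = chromosome_holdout_split(proms)
        assert sorted(tr + te) == [p.gene_id for p in proms]

    def test_empty_test_set_warns(self):
        with pytest.warns(UserWarning, match="empty test set"):
            _, te = chromosome_holdout_split(self.promoters(["chr1"]))
        assert te == []
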
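"""Train the promoter CNN on synthetic data in its three channel modes and
compare held-out performance.

A small run (1200 genes, 300 bp windows, one fold, one seed) of the
channel-ablation experiment: the same architecture trained on the
accessibility track alone (1 channel), the DNA sequence alone (4 channels),
or both (5 channels). Expect DNA+ATAC >= ATAC-only >> DNA-only on this
data, where expression is driven mostly by accessibility with
motif-x-accessibility modulation.
"""

import numpy as np

from chromexpr import evaluation, model, synth, training

data = synth.generate(synth.SynthConfig(n_genes=1200, L=300, seed=1))
ds5 = data.model_dataset("CT0")
folds = training.make_folds(ds5.gene_ids, k=5, seeds=[0], val_fraction=0.1)
test = folds.test_folds[0]
tr, va = folds.inner[(0, 0)]

tcfg = training.TrainConfig(lr=2e-3, weight_decay=1e-4, batch_size=128,
                            max_epochs=32, val_every=4)

print(f"{'mode':<12}{'channels':>9}{'params':>9}{'test Pearson':>14}")
for mode, C in [("atac_only", 1), ("dna_only", 4), ("dna_atac", 5)]:
    ds = ds5 if mode == "dna_atac" else ds5.with_channels(mode)
    mcfg = model.ModelConfig(input_channels=C, input_length=300,
                             conv_specs=((16, 8, 4), (16, 8, 4)),
                             dense_sizes=(64,), dropout=0.1)
    ck = training.train(mcfg, tcfg, ds.subset(tr), ds.subset(va), seed=0)
    pred = ck.build().predict(ds.subset(test).x)
    m = evaluation.metrics(ds.subset(test).y, pred)
    n_params = model.count_parameters(ck.build())
    print(f"{mode:<12}{C:>9}{n_params:>9}{m['pearson']:>14.3f}")

print("\nEach row is the same architecture restricted to a channel subset; "
      "the Pearson correlation is between predicted and true GEx on the "
      "held-out fold. The accessibility channel carries most of the signal; "
      "adding DNA recovers the motif contribution on top of it.")
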
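"""Score promoter variants by the change in predicted expression.

Trains a small 5-channel model, then compares each reference promoter
against two alternative alleles: one in which a planted motif instance is
overwritten with random bases (deleterious) and one with a matched-length
random patch in background sequence (neutral). The accessibility track is
kept from the reference, as when scoring eQTL-style ref/alt pairs. auROC
measures how well the predicted deltas separate the two classes.
"""

import numpy as np

from chromexpr import evaluation, model, synth, training

data = synth.generate(synth.SynthConfig(n_genes=1500, L=300, seed=3, beta=6.0,
                                        motif_rate=1.5))
ds = data.model_dataset("CT0")
mcfg = model.ModelConfig(input_channels=5, input_length=300,
                         conv_specs=((16, 8, 4), (16, 8, 4)),
                         dense_sizes=(64,), dropout=0.1)
tcfg = training.TrainConfig(lr=2e-3, weight_decay=1e-4, batch_size=256,
                            max_epochs=48, val_every=4)
ck = training.train(mcfg, tcfg, ds.subset(ds.gene_ids[:1300]),
                    ds.subset(ds.gene_ids[1300:1400]), seed=0)
net = ck.build()

rng = np.random.default_rng(0)
deltas, labels = [], []
for gene in ds.gene_ids[1400:]:
    ref = ds.subset([gene]).x[0]
    seq = data.sequences[gene]
    instances = data.truth.motif_instances[gene]
    if not instances:
        continue
    # deleterious variant: overwrite one motif instance with random bases
    mi, pos = instances[rng.integers(len(instances))]
    mlen = len(data.truth.config.motifs[mi])
    alt_seq = (seq[:pos] + "".join(rng.choice(list("ACGT"), size=mlen))
               + seq[pos + mlen:])
    deltas.append(evaluation.variant_effect(net, ref, alt_seq))
    labels.append(1)
    # matched neutral variant: same-length random patch in background sequence
    while True:
        npos = int(rng.integers(len(seq) - mlen))
        if all(npos + mlen <= p or npos >= p + len(data.truth.config.motifs[m])
               for m, p in instances):
            break
    neutral_seq = (seq[:npos] + "".join(rng.choice(list("ACGT"), size=mlen))
                   + seq[npos + mlen:])
    deltas.append(evaluation.variant_effect(net, ref, neutral_seq))
    labels.append(0)

deltas, labels = np.array(deltas), np.array(labels)
print(f"variants scored: {len(deltas)} "
      f"({labels.sum()} motif deletions, {(1 - labels).sum()} neutral patches)")
print(f"mean delta, motif deletions: {deltas[labels == 1].mean():+.5f}")
print(f"mean delta, neutral patches:  {deltas[labels == 0].mean():+.5f}")
print(f"auROC (neutral vs deleterious, scored by -delta): "
      f"{evaluation.auroc(-deltas, labels):.3f}")

print("\nMore negative deltas for motif deletions than for matched neutral "
      "patches show the model has learned the planted activating motifs; "
      "the auROC quantifies that separation.")
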
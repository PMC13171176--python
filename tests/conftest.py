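import numpy as np
import pytest

from chromexpr import model, synth, training


@pytest.fixture(scope="session")
def toy_genome():
    """Two small chromosomes as plain strings (indexable like pyfaidx)."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    return {
        "chr1": "".join(rng.choice(bases, size=400)),
        "chr2": "".join(rng.choice(bases, size=300)),
    }


def write_gtf(path, rows):
    """rows: (chrom, feature, start, end, strand, attributes) with 1-based
    inclusive coordinates, GENCODE attribute syntax."""
    with open(path, "w") as fh:
        fh.write("#!genome-build test\n")
        for chrom, feature, start, end, strand, attrs in rows:
            fh.write(
                f"{chrom}\tTEST\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )


@pytest.fixture()
def gtf_writer(tmp_path):
    def _write(rows, name="test.gtf"):
        path = tmp_path / name
        write_gtf(path, rows)
        return path

    return _write


def transcript_attrs(gene, tx, canonical=True, gene_type="protein_coding"):
    tags = ' tag "Ensembl_canonical";' if canonical else ""
    return (
        f'gene_id "{gene}"; gene_type "{gene_type}"; transcript_id "{tx}";'
        f' gene_name "{gene}_name";{tags}'
    )


@pytest.fixture(scope="session")
def tiny_synth():
    """A small synthetic dataset for fast end-to-end unit tests."""
    cfg = synth.SynthConfig(n_genes=40, L=120, n_cell_types=2, seed=7,
                            bump_width=12.0, smooth_sigma=5.0)
    return synth.generate(cfg)


@pytest.fixture(scope="session")
def toy_trained_model(tiny_synth):
    """A quickly trained 5-channel model on the tiny synthetic dataset."""
    ds = tiny_synth.model_dataset("CT0")
    cfg = model.ModelConfig(input_channels=5, input_length=120,
                            conv_specs=((8, 6, 4), (8, 5, 4)), dense_sizes=(16,),
                            dropout=0.0)
    tcfg = training.TrainConfig(lr=3e-3, weight_decay=1e-4, batch_size=20,
                                max_epochs=12, val_every=4)
    ck = training.train(cfg, tcfg, ds.subset(ds.gene_ids[:32]),
                        ds.subset(ds.gene_ids[32:]), seed=0)
    return ck.build()
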
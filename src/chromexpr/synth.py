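"""Synthetic multiome-like data with known ground truth.

Emulates the structure of the real inputs — promoter sequences, per-cell-
type accessibility tracks peaked near the TSS, expression probabilities in
[0, 1] — from a fully specified generative model, so that every pipeline
stage can be tested at desk scale without downloads:

* sequence: background-sampled DNA with motif instances planted at
  non-overlapping uniform positions (Poisson count per motif);
* accessibility: a per-gene bump profile around the TSS, scaled by a
  per-(gene, cell type) latent openness drawn from a Beta distribution,
  plus nonnegative noise; the observed tracks then run through the real
  pipeline (Gaussian smoothing, global per-cell-type min-max);
* expression: GEx = logistic(w0 + w_atac * auATAC + sum_m beta[m, c] *
  sum_instances mean-normalized-accessibility-over-footprint), optionally
  plus Gaussian observation noise (clipped to [0, 1]) or realized as a
  Binomial cell count so the proportion-times-cells integrality of real
  GEx holds.

Motif effects are *accessibility-gated* (each instance contributes in
proportion to the local normalized accessibility over its footprint), so
sequence and accessibility carry complementary and interacting signal.
All randomness flows from one master seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chromatin import AtacTrack, GExTable, compute_auatac, gaussian_smooth, minmax_normalize
from .genome_io import BASES, one_hot_encode
from .training import Dataset

_SUBSTREAMS = {"sequences": 1, "placement": 2, "openness": 3, "tracks": 4,
               "noise": 5, "render": 6}


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng((seed, _SUBSTREAMS[name]))


def consensus_pwm(consensus: str, certainty: float = 1.0) -> np.ndarray:
    """PWM (len x 4) concentrated on a consensus string; ``certainty=1``
    gives a deterministic (consensus-only) motif."""
    pwm = np.full((len(consensus), 4), (1 - certainty) / 3)
    for i, b in enumerate(consensus):
        pwm[i, BASES.index(b)] = certainty
    return pwm


DEFAULT_MOTIFS = (
    consensus_pwm("TGACGTCA"),   # CRE-like palindrome
    consensus_pwm("GGGGCGGGG"),  # GC-box-like
    consensus_pwm("TGATAAGA"),   # GATA-like
)


@dataclass
class SynthConfig:
    """Generative parameters; defaults are the package's study conditions."""

    n_genes: int = 3000
    L: int = 2000
    n_cell_types: int = 1
    background: tuple = (0.25, 0.25, 0.25, 0.25)
    motifs: tuple = DEFAULT_MOTIFS
    beta: np.ndarray | float = 3.0          # (n_motifs, n_cell_types) or scalar
    w_atac: float | None = None             # defaults to 24 / L
    w0: float = -3.0
    motif_rate: float = 1.0                 # Poisson mean instances per motif/promoter
    n_bumps: int = 2
    bump_width: float | None = None         # defaults to L / 12
    center_jitter: float | None = None      # defaults to L / 10
    bump_amp: float = 1.0
    openness_a: float = 2.0
    openness_b: float = 2.0
    track_noise: float = 0.02
    smooth_sigma: float = 20.0
    noise_sd: float = 0.05
    gex_mode: str = "gaussian"              # or "binomial"
    n_cells: int = 500
    share_openness: bool = False            # one openness per gene, all cell types
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.background) - 1) > 1e-9 or min(self.background) < 0:
            raise ValueError("background must be a probability vector")
        if any(len(m) > self.L for m in self.motifs):
            raise ValueError("motif longer than sequence length L")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.gex_mode not in ("gaussian", "binomial"):
            raise ValueError("gex_mode must be 'gaussian' or 'binomial'")

    def resolved(self) -> "SynthConfig":
        """Fill length-dependent defaults and broadcast beta."""
        beta = np.asarray(self.beta, dtype=np.float64)
        if beta.ndim == 0:
            beta = np.full((len(self.motifs), self.n_cell_types), float(beta))
        if beta.shape != (len(self.motifs), self.n_cell_types):
            raise ValueError(
                f"beta shape {beta.shape} != ({len(self.motifs)}, {self.n_cell_types})"
            )
        return replace(
            self,
            beta=beta,
            w_atac=self.w_atac if self.w_atac is not None else 24.0 / self.L,
            bump_width=self.bump_width if self.bump_width is not None else self.L / 12,
            center_jitter=self.center_jitter if self.center_jitter is not None else self.L / 10,
        )


@dataclass
class SyntheticTruth:
    """The latent state behind a synthetic dataset."""

    motif_instances: dict            # gene_id -> [(motif_idx, position), ...]
    openness: pd.DataFrame           # gene x cell type latent openness
    noiseless_gex: pd.DataFrame      # gene x cell type, before observation noise
    config: SynthConfig = None


@dataclass
class SyntheticDataset:
    gene_ids: list
    cell_types: list
    sequences: dict                  # gene_id -> str
    tracks: dict                     # cell_type -> {gene_id: AtacTrack}
    gex: GExTable
    auatac: pd.DataFrame             # gene x cell type
    truth: SyntheticTruth

    def model_dataset(self, cell_type: str, channels: str = "dna_atac") -> Dataset:
        """Assemble (N, C, L) model inputs for one cell type."""
        xs, ys = [], []
        for g in self.gene_ids:
            onehot = one_hot_encode(self.sequences[g])
            atac = self.tracks[cell_type][g].normalized[None, :]
            xs.append(np.concatenate([onehot, atac], axis=0))
            ys.append(self.gex[g, cell_type])
        ds = Dataset(np.stack(xs), np.array(ys), self.gene_ids)
        return ds if channels == "dna_atac" else ds.with_channels(channels)


def _plant_motifs(seqs, config, rng) -> dict:
    """Place Poisson-many instances of each motif per promoter, uniformly
    and without overlap (bounded retries, then error)."""
    instances = {}
    for gi, gene in enumerate(sorted(seqs)):
        seq = list(seqs[gene])
        occupied: list[tuple] = []
        placed = []
        for mi, pwm in enumerate(config.motifs):
            count = rng.poisson(config.motif_rate)
            mlen = len(pwm)
            for _ in range(count):
                for attempt in range(200):
                    pos = int(rng.integers(0, config.L - mlen + 1))
                    if all(pos + mlen <= s or pos >= e for s, e in occupied):
                        break
                else:
                    raise RuntimeError(
                        f"could not place motif {mi} in gene {gene} without overlap"
                    )
                occupied.append((pos, pos + mlen))
                draw = [BASES[rng.choice(4, p=row)] for row in pwm]
                seq[pos : pos + mlen] = draw
                placed.append((mi, pos))
        seqs[gene] = "".join(seq)
        instances[gene] = sorted(placed)
    return instances


def generate(config: SynthConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset; byte-deterministic given the
    master seed."""
    cfg = config.resolved()
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    cell_types = [f"CT{c}" for c in range(cfg.n_cell_types)]

    rng_seq = _rng(cfg.seed, "sequences")
    seqs = {
        g: "".join(rng_seq.choice(list(BASES), size=cfg.L, p=cfg.background))
        for g in gene_ids
    }
    rng_place = _rng(cfg.seed, "placement")
    instances = _plant_motifs(seqs, cfg, rng_place)

    rng_open = _rng(cfg.seed, "openness")
    if cfg.share_openness:
        openness = np.repeat(
            rng_open.beta(cfg.openness_a, cfg.openness_b, size=(cfg.n_genes, 1)),
            cfg.n_cell_types, axis=1,
        )
    else:
        openness = rng_open.beta(cfg.openness_a, cfg.openness_b,
                                 size=(cfg.n_genes, cfg.n_cell_types))
    rng_tracks = _rng(cfg.seed, "tracks")
    x = np.arange(cfg.L)
    profiles = np.empty((cfg.n_genes, cfg.L))
    for gi in range(cfg.n_genes):
        prof = np.zeros(cfg.L)
        for _ in range(cfg.n_bumps):
            center = cfg.L / 2 + rng_tracks.normal(0, cfg.center_jitter)
            center = float(np.clip(center, 0.1 * cfg.L, 0.9 * cfg.L))
            prof += cfg.bump_amp * np.exp(-((x - center) ** 2) / (2 * cfg.bump_width**2))
        profiles[gi] = prof

    tracks: dict = {}
    auatac = pd.DataFrame(index=gene_ids, columns=cell_types, dtype=float)
    for ci, ct in enumerate(cell_types):
        raws = openness[:, ci : ci + 1] * profiles + np.abs(
            rng_tracks.normal(0, cfg.track_noise, size=(cfg.n_genes, cfg.L))
        )
        smoothed = [gaussian_smooth(r, cfg.smooth_sigma) for r in raws]
        normalized = minmax_normalize(smoothed)
        tracks[ct] = {
            g: AtacTrack(g, ct, raws[gi], smoothed[gi], normalized[gi])
            for gi, g in enumerate(gene_ids)
        }
        for gi, g in enumerate(gene_ids):
            auatac.at[g, ct] = compute_auatac(normalized[gi])

    motif_term = np.zeros((cfg.n_genes, cfg.n_cell_types))
    for gi, g in enumerate(gene_ids):
        for mi, pos in instances[g]:
            mlen = len(cfg.motifs[mi])
            for ci, ct in enumerate(cell_types):
                footprint = tracks[ct][g].normalized[pos : pos + mlen]
                motif_term[gi, ci] += cfg.beta[mi, ci] * float(footprint.mean())

    logits = cfg.w0 + cfg.w_atac * auatac.to_numpy(dtype=float) + motif_term
    noiseless = 1.0 / (1.0 + np.exp(-logits))

    rng_noise = _rng(cfg.seed, "noise")
    if cfg.gex_mode == "binomial":
        counts = rng_noise.binomial(cfg.n_cells, noiseless)
        realized = counts / cfg.n_cells
    else:
        realized = np.clip(
            noiseless + rng_noise.normal(0, cfg.noise_sd, size=noiseless.shape), 0, 1
        )

    gex = GExTable(
        pd.DataFrame(realized, index=gene_ids, columns=cell_types),
        {ct: cfg.n_cells for ct in cell_types},
    )
    truth = SyntheticTruth(
        instances,
        pd.DataFrame(openness, index=gene_ids, columns=cell_types),
        pd.DataFrame(noiseless, index=gene_ids, columns=cell_types),
        cfg,
    )
    return SyntheticDataset(gene_ids, cell_types, seqs, tracks, gex, auatac, truth)


def make_cell_type_pair(
    config: SynthConfig,
    shared_motifs: Sequence[int],
    private_motifs: tuple,
) -> SyntheticDataset:
    """Two cell types with shared and private active motifs.

    ``private_motifs`` is a pair of index lists, one per cell type; shared
    motifs get positive effects in both cell types, private motifs only in
    theirs (zero elsewhere). Overlap between shared and private sets is an
    error.
    """
    priv0, priv1 = (set(p) for p in private_motifs)
    shared = set(shared_motifs)
    if shared & (priv0 | priv1) or priv0 & priv1:
        raise ValueError("shared and private motif sets must be disjoint")
    cfg = replace(config, n_cell_types=2).resolved()
    beta = np.zeros((len(cfg.motifs), 2))
    mag = float(np.max(config.beta))
    for m in shared:
        beta[m, :] = mag
    for m in priv0:
        beta[m, 0] = mag
    for m in priv1:
        beta[m, 1] = mag
    return generate(replace(cfg, beta=beta))


def render_raw_formats(data: SyntheticDataset, out_dir: str | Path,
                       fragment_length: int = 60, seed: int = 0) -> dict:
    """Emit the dataset in the real input formats so the I/O pipeline can
    be exercised end-to-end: promoter FASTA (one pseudo-chromosome per
    gene, TSS at L/2), per-cell-type fragment TSVs sampled so coverage
    approximates the raw tracks, a Matrix Market UMI matrix with features/
    barcodes lists (Bernoulli per cell from noiseless GEx), and a
    barcode -> cell type annotation TSV. Returns the written paths.
    """
    import scipy.sparse as sp
    from scipy.io import mmwrite

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed, "render")
    cfg = data.truth.config
    L = cfg.L

    fasta = out / "promoters.fa"
    with open(fasta, "w") as fh:
        for g in data.gene_ids:
            fh.write(f">{g}\n{data.sequences[g]}\n")

    frag_paths = {}
    for ct in data.cell_types:
        path = out / f"fragments_{ct}.tsv"
        with open(path, "w") as fh:
            for g in data.gene_ids:
                raw = data.tracks[ct][g].raw
                total = raw.sum()
                if total <= 0:
                    continue
                n_frags = int(round(total / fragment_length))
                if n_frags == 0:
                    continue
                p = raw / total
                starts = rng.choice(L, size=n_frags, p=p) - fragment_length // 2
                for s in np.sort(starts):
                    s = int(np.clip(s, 0, L - fragment_length))
                    fh.write(f"chr_{g}\t{s}\t{s + fragment_length}\tBC_{ct}\t1\n")
        frag_paths[ct] = path

    n_cells = cfg.n_cells
    barcodes, labels = [], []
    cols = []
    p_expr = data.truth.noiseless_gex.to_numpy(dtype=float)
    for ci, ct in enumerate(data.cell_types):
        draws = rng.random((len(data.gene_ids), n_cells)) < p_expr[:, ci : ci + 1]
        cols.append(draws.astype(np.int32))
        barcodes += [f"{ct}_cell{j}" for j in range(n_cells)]
        labels += [ct] * n_cells
    umi = sp.csr_matrix(np.concatenate(cols, axis=1))
    mmwrite(str(out / "umi.mtx"), umi)
    (out / "features.txt").write_text("\n".join(data.gene_ids) + "\n")
    (out / "barcodes.txt").write_text("\n".join(barcodes) + "\n")
    pd.DataFrame({"barcode": barcodes, "cell_type": labels}).to_csv(
        out / "annotation.tsv", sep="\t", index=False, header=False
    )
    return {
        "fasta": fasta, "fragments": frag_paths, "mtx": out / "umi.mtx",
        "features": out / "features.txt", "barcodes": out / "barcodes.txt",
        "annotation": out / "annotation.tsv",
    }


def desk_scale_config(seed: int = 0, **overrides) -> SynthConfig:
    """The reduced-scale study conditions used throughout the test suite's
    end-to-end experiments: 3000 genes, 500 bp windows, accessibility-
    gated motif effects, observation noise 0.05."""
    defaults = dict(n_genes=3000, L=500, noise_sd=0.05, seed=seed)
    defaults.update(overrides)
    return SynthConfig(**defaults)
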
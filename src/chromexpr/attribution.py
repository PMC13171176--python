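"""Attribution against dinucleotide-preserving shuffled backgrounds.

Backgrounds for a promoter are shuffles of its own sequence that keep the
exact dinucleotide counts (Altschul–Erickson Eulerian construction, so
first and last bases are also preserved); for 5-channel models each
background additionally carries a position-permuted copy of the gene's
ATAC track. Scores are produced by the delta-propagation backend in
:mod:`chromexpr.nn`, which satisfies the completeness property exactly:
for every sample, ``scores.sum() == f(x) - mean_b f(b)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome_io import one_hot_decode, one_hot_encode


@dataclass
class AttributionArray:
    """Per-channel, per-position scores for one gene with provenance."""

    gene_id: str
    fold: int
    seed: int
    scores: np.ndarray  # (C, L)
    n_backgrounds: int


def _segment_shuffle(seq: str, rng: np.random.Generator) -> str:
    """One dinucleotide-preserving shuffle (Altschul–Erickson).

    Builds the dinucleotide multigraph, samples a uniform random Eulerian
    rearrangement by drawing random terminal edges that form an
    arborescence into the last character, shuffling the remaining edge
    lists, and walking the path. First and last characters are preserved.
    """
    if len(seq) < 2:
        return seq
    chars = sorted(set(seq))
    nexts = {c: [] for c in chars}
    for a, b in zip(seq, seq[1:]):
        nexts[a].append(b)
    last = seq[-1]
    non_terminal = [c for c in chars if c != last and nexts[c]]
    while True:
        # candidate terminal edge for each non-terminal vertex
        chosen = {c: nexts[c][rng.integers(len(nexts[c]))] for c in non_terminal}
        ok = True
        for c in non_terminal:
            seen, cur = set(), c
            while cur != last:
                if cur in seen or cur not in chosen:
                    ok = False
                    break
                seen.add(cur)
                cur = chosen[cur]
            if not ok:
                break
        if ok:
            break
    shuffled = {}
    for c in chars:
        edges = list(nexts[c])
        if c in chosen:
            edges.remove(chosen[c])
        order = rng.permutation(len(edges))
        edges = [edges[i] for i in order]
        if c in chosen:
            edges.append(chosen[c])
        shuffled[c] = edges
    out = [seq[0]]
    pos = {c: 0 for c in chars}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def dinuc_shuffle(sequence: str, n: int = 100, seed: int = 0) -> list[str]:
    """``n`` dinucleotide-exact shuffles of ``sequence``.

    N bases break the dinucleotide graph: runs between N's are shuffled
    independently (each keeping its own dinucleotide counts) and N
    positions stay fixed.
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        if "N" in seq:
            parts, buf = [], []
            for ch in seq:
                if ch == "N":
                    parts.append(_segment_shuffle("".join(buf), rng))
                    parts.append("N")
                    buf = []
                else:
                    buf.append(ch)
            parts.append(_segment_shuffle("".join(buf), rng))
            out.append("".join(parts))
        else:
            out.append(_segment_shuffle(seq, rng))
    return out


def make_backgrounds(sample: np.ndarray, n: int = 100, seed: int = 0) -> np.ndarray:
    """Background stack (n, C, L) for one sample.

    DNA rows (when present) are dinucleotide-shuffled; the ATAC row (when
    present) is independently position-permuted per background.
    """
    sample = np.asarray(sample)
    C, L = sample.shape
    seed_key = [int(s) for s in np.atleast_1d(np.asarray(seed, dtype=np.int64))]
    rng = np.random.default_rng(seed_key + [0xA7AC])
    bg = np.empty((n, C, L), dtype=np.float64)
    if C in (4, 5):
        seq = one_hot_decode(sample[:4])
        for i, s in enumerate(dinuc_shuffle(seq, n=n, seed=seed)):
            bg[i, :4] = one_hot_encode(s)
    if C in (1, 5):
        row = C - 1
        for i in range(n):
            bg[i, row] = sample[row][rng.permutation(L)]
    return bg


def attribute(model, sample: np.ndarray, backgrounds: np.ndarray,
              gene_id: str = "", fold: int = 0, seed: int = 0) -> AttributionArray:
    """Attribution scores of one sample against its background stack."""
    net = model.build() if hasattr(model, "build") else model
    sample = np.asarray(sample, dtype=np.float64)
    backgrounds = np.asarray(backgrounds, dtype=np.float64)
    if backgrounds.shape[1:] != sample.shape:
        raise ValueError(
            f"background shape {backgrounds.shape[1:]} != sample shape {sample.shape}"
        )
    scores = net.delta_attribution(sample, backgrounds)
    return AttributionArray(gene_id, fold, seed, scores, backgrounds.shape[0])


def aggregate_positional(arrays: dict, seeds=None) -> np.ndarray:
    """Three-stage positional aggregation of per-(gene, fold, seed) scores.

    Stage 1: mean over seeds for each (gene, fold); stage 2: concatenate
    held-out genes across folds (each gene is held out exactly once);
    stage 3: mean over genes per channel and position. ``arrays`` maps
    (gene_id, fold, seed) -> (C, L) score array; an incomplete seed grid
    raises with the missing combinations listed.
    """
    keys = list(arrays)
    if not keys:
        raise ValueError("no attribution arrays given")
    if seeds is None:
        seeds = sorted({k[2] for k in keys})
    gene_folds = sorted({(g, f) for g, f, _ in keys})
    gaps = [(g, f, s) for g, f in gene_folds for s in seeds if (g, f, s) not in arrays]
    if gaps:
        raise ValueError(f"missing seed/fold combinations: {gaps[:10]}")
    per_gene = [
        np.mean([np.asarray(arrays[(g, f, s)], dtype=np.float64) for s in seeds], axis=0)
        for g, f in gene_folds
    ]
    return np.mean(per_gene, axis=0)


def channel_track_correlation(profile: np.ndarray, atac_track: np.ndarray) -> np.ndarray:
    """Per-channel Spearman correlation of a mean positional attribution
    profile (C, L) with the mean ATAC input track (L,)."""
    from scipy import stats

    profile = np.atleast_2d(np.asarray(profile, dtype=np.float64))
    atac_track = np.asarray(atac_track, dtype=np.float64)
    if profile.shape[1] != atac_track.shape[0]:
        raise ValueError("profile and track lengths differ")
    out = np.empty(profile.shape[0])
    for c in range(profile.shape[0]):
        if np.ptp(profile[c]) == 0 or np.ptp(atac_track) == 0:
            warnings.warn(f"constant input in channel {c}: correlation undefined")
            out[c] = np.nan
        else:
            out[c] = stats.spearmanr(profile[c], atac_track).statistic
    return out


def save_attributions_h5(arrays: dict, path: str | Path) -> None:
    """HDF5 store keyed gene/fold/seed."""
    import h5py

    with h5py.File(path, "w") as f:
        for (gene, fold, seed), arr in arrays.items():
            f.create_dataset(f"{gene}/{fold}/{seed}", data=np.asarray(arr))


def load_attributions_h5(path: str | Path) -> dict:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for gene in f:
            for fold in f[gene]:
                for seed in f[gene][fold]:
                    out[(gene, int(fold), int(seed))] = f[gene][fold][seed][:]
    return out


def export_for_modisco(
    attributions: dict,
    onehots: dict,
    auatac: dict,
    out_dir: str | Path,
    threshold: float | None = None,
) -> list[str]:
    """Write per-gene contribution arrays for external motif discovery.

    Keeps genes whose auATAC exceeds ``threshold`` (default: the mean
    auATAC over the given genes). Writes ``sequences.npy`` (N, 4, L) one-
    hot, ``hypothetical_contribs.npy`` (N, 4, L) raw DNA-channel scores and
    ``contribs.npy`` (N, 4, L) scores projected on the actual bases, plus
    ``genes.txt``. Returns the exported gene list.
    """
    genes = sorted(set(attributions) & set(onehots) & set(auatac))
    if threshold is None:
        threshold = float(np.mean([auatac[g] for g in genes]))
    keep = [g for g in genes if auatac[g] > threshold]
    if not keep:
        raise ValueError(f"no genes pass the auATAC threshold {threshold}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs = np.stack([np.asarray(onehots[g]) for g in keep])
    hyp = np.stack([np.asarray(attributions[g])[:4] for g in keep])
    np.save(out_dir / "sequences.npy", seqs)
    np.save(out_dir / "hypothetical_contribs.npy", hyp)
    np.save(out_dir / "contribs.npy", hyp * seqs)
    (out_dir / "genes.txt").write_text("\n".join(keep) + "\n")
    return keep
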
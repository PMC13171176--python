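"""Per-cell-type ATAC promoter tracks and GEx expression targets.

The track pipeline is fixed: per-base fragment coverage over the promoter
window, Gaussian smoothing (sigma=20 bp), then min-max normalization with a
single (min, max) shared by *all* promoter tracks of one cell type, so that
between-gene accessibility differences survive normalization. ``auATAC`` —
the area under a gene's normalized track — is only defined on normalized
tracks. ``GEx`` is the fraction of cells of a cell type with a nonzero UMI
count for the gene: a probability in [0, 1].
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)


@dataclass
class AtacTrack:
    """One gene's promoter accessibility track for one cell type."""

    gene_id: str
    cell_type: str
    raw: np.ndarray
    smoothed: np.ndarray | None = None
    normalized: np.ndarray | None = None


@dataclass
class GExTable:
    """Gene x cell-type expression probabilities with per-type cell counts."""

    values: pd.DataFrame  # index gene_id, columns cell types
    n_cells: dict = field(default_factory=dict)

    def __getitem__(self, key):
        gene_id, cell_type = key
        return float(self.values.at[gene_id, cell_type])


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read a BED-like fragments file (chrom, start, end, barcode[, count]).

    Plain or gzip-compressed tab-separated text; comment lines starting with
    '#' are skipped. A missing count column defaults to 1.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "barcode", "count"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    if "barcode" not in df:
        df["barcode"] = "."
    if "count" not in df:
        df["count"] = 1
    return df[["chrom", "start", "end", "barcode", "count"]]


def build_raw_track(
    fragments: pd.DataFrame | Iterable[tuple],
    chrom: str,
    start: int,
    end: int,
    strand: str = "+",
    use_counts: bool = True,
    cut_sites: bool = False,
) -> np.ndarray:
    """Per-base fragment coverage over the window ``[start, end)``.

    Fragments are 0-based half-open intervals; each contributes its count
    (or 1 if ``use_counts=False``) to every base it overlaps, or only to its
    two Tn5 cut sites when ``cut_sites=True``. For minus-strand genes the
    array is reversed so index ``i`` matches coding-strand sequence index
    ``i``. Invalid fragments (end <= start) are skipped with a warning.
    """
    L = end - start
    track = np.zeros(L, dtype=np.float64)
    if isinstance(fragments, pd.DataFrame):
        sub = fragments[fragments["chrom"] == chrom]
        it = zip(sub["start"].to_numpy(), sub["end"].to_numpy(),
                 sub["count"].to_numpy() if "count" in sub else np.ones(len(sub)))
    else:
        it = ((f[1], f[2], f[4] if len(f) > 4 else 1)
              for f in fragments if f[0] == chrom)
    for fs, fe, cnt in it:
        if fe <= fs:
            warnings.warn(f"skipping invalid fragment [{fs},{fe})")
            continue
        w = cnt if use_counts else 1
        if cut_sites:
            for cut in (fs, fe - 1):
                if start <= cut < end:
                    track[cut - start] += w
        else:
            lo, hi = max(fs, start), min(fe, end)
            if lo < hi:
                track[lo - start : hi - start] += w
    if strand == "-":
        track = track[::-1].copy()
    return track


def gaussian_smooth(raw: np.ndarray, sigma: float = 20.0) -> np.ndarray:
    """Gaussian-filter a coverage track (kernel truncated at 4*sigma,
    reflect boundaries, so total signal is conserved)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return gaussian_filter1d(np.asarray(raw, dtype=np.float64), sigma,
                             mode="reflect", truncate=4.0)


def minmax_normalize(tracks: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Min-max normalize all tracks of one cell type with a *global*
    (min, max) taken over every position of every track; a degenerate
    cell type (max == min) normalizes to all zeros."""
    if len(tracks) == 0:
        raise ValueError("need at least one track")
    m = min(float(np.min(t)) for t in tracks)
    M = max(float(np.max(t)) for t in tracks)
    if M == m:
        return [np.zeros_like(np.asarray(t, dtype=np.float64)) for t in tracks]
    return [(np.asarray(t, dtype=np.float64) - m) / (M - m) for t in tracks]


def compute_auatac(normalized: np.ndarray) -> float:
    """Area under a normalized track: the per-base sum (unit bin width)."""
    return float(np.sum(normalized))


def build_tracks(
    fragments: pd.DataFrame,
    promoters,
    cell_type: str,
    barcode_types: pd.Series | dict | None = None,
    flank: int | None = None,
    sigma: float = 20.0,
    use_counts: bool = True,
) -> dict[str, AtacTrack]:
    """Full track pipeline for one cell type over a promoter set.

    ``barcode_types`` maps fragment barcodes to cell types; when given, only
    fragments from barcodes of ``cell_type`` are pooled. Returns a dict
    keyed by gene_id with raw, smoothed and normalized arrays filled in.
    """
    if barcode_types is not None:
        bt = pd.Series(barcode_types)
        keep = set(bt.index[bt == cell_type])
        fragments = fragments[fragments["barcode"].isin(keep)]
    tracks = {}
    for rec in promoters:
        ws, we = rec.window_start, rec.window_end
        if ws is None:
            if flank is None:
                raise ValueError(f"record {rec.gene_id} has no window and no flank given")
            ws, we = rec.tss - flank, rec.tss + flank
        raw = build_raw_track(fragments, rec.chrom, ws, we, rec.strand,
                              use_counts=use_counts)
        tracks[rec.gene_id] = AtacTrack(rec.gene_id, cell_type, raw,
                                        smoothed=gaussian_smooth(raw, sigma))
    normed = minmax_normalize([t.smoothed for t in tracks.values()])
    for t, n in zip(tracks.values(), normed):
        t.normalized = n
    return tracks


def auatac_table(tracks_by_type: dict[str, dict[str, AtacTrack]]) -> pd.DataFrame:
    """Gene x cell-type auATAC table from normalized tracks."""
    cols = {}
    for cell_type, tracks in tracks_by_type.items():
        cols[cell_type] = {g: compute_auatac(t.normalized) for g, t in tracks.items()}
    return pd.DataFrame(cols)


def read_mtx_counts(
    mtx_path: str | Path, features_path: str | Path, barcodes_path: str | Path
) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Read a Matrix Market UMI matrix (genes x cells) with its feature and
    barcode lists (one ID per line; extra tab-separated columns ignored)."""
    mat = sp.csr_matrix(mmread(str(mtx_path)))
    features = [l.split("\t")[0].strip() for l in open(features_path) if l.strip()]
    barcodes = [l.split("\t")[0].strip() for l in open(barcodes_path) if l.strip()]
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(features)} features "
            f"x {len(barcodes)} barcodes"
        )
    return mat, features, barcodes


def compute_gex(
    umi: sp.spmatrix | np.ndarray,
    cell_type_labels: Sequence[str],
    cell_type: str,
) -> np.ndarray:
    """Per-gene fraction of cells of ``cell_type`` with a nonzero UMI count.

    ``umi`` is genes x cells. Raises if the cell type has no cells.
    """
    labels = np.asarray(cell_type_labels)
    if umi.shape[1] != labels.shape[0]:
        raise ValueError("label count does not match cell count")
    mask = labels == cell_type
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no cells of type {cell_type!r}")
    sub = umi[:, mask]
    if sp.issparse(sub):
        nonzero = (sub > 0).sum(axis=1).A1 if hasattr((sub > 0).sum(axis=1), "A1") \
            else np.asarray((sub > 0).sum(axis=1)).ravel()
    else:
        nonzero = (np.asarray(sub) > 0).sum(axis=1)
    return nonzero / n


def gex_table(
    umi: sp.spmatrix | np.ndarray,
    gene_ids: Sequence[str],
    cell_type_labels: Sequence[str],
    cell_types: Sequence[str] | None = None,
) -> GExTable:
    labels = np.asarray(cell_type_labels)
    if cell_types is None:
        cell_types = sorted(set(labels))
    cols = {ct: compute_gex(umi, labels, ct) for ct in cell_types}
    n_cells = {ct: int((labels == ct).sum()) for ct in cell_types}
    return GExTable(pd.DataFrame(cols, index=list(gene_ids)), n_cells)


def select_highly_variable(
    umi: sp.spmatrix | np.ndarray,
    gene_ids: Sequence[str],
    cell_type_labels: Sequence[str],
    cell_type: str,
    n: int,
) -> list[str]:
    """Top-``n`` genes by variance-to-mean ratio of per-cell UMI counts
    within the cell type (a dispersion measure); ties and zero-expression
    genes rank by gene ID. Deterministic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(gene_ids):
        raise ValueError(f"n={n} exceeds gene count {len(gene_ids)}")
    labels = np.asarray(cell_type_labels)
    mask = labels == cell_type
    if mask.sum() == 0:
        raise ValueError(f"no cells of type {cell_type!r}")
    sub = umi[:, mask]
    if sp.issparse(sub):
        sub = np.asarray(sub.todense())
    sub = np.asarray(sub, dtype=np.float64)
    mean = sub.mean(axis=1)
    var = sub.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = sorted(range(len(gene_ids)), key=lambda i: (-disp[i], gene_ids[i]))
    return [gene_ids[i] for i in order[:n]]


def save_tracks_h5(tracks_by_type: dict[str, dict[str, AtacTrack]], path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for cell_type, tracks in tracks_by_type.items():
            grp = f.create_group(cell_type)
            for gene_id, t in tracks.items():
                g = grp.create_group(gene_id)
                g.create_dataset("raw", data=t.raw)
                if t.smoothed is not None:
                    g.create_dataset("smoothed", data=t.smoothed)
                if t.normalized is not None:
                    g.create_dataset("normalized", data=t.normalized)


def load_tracks_h5(path: str | Path) -> dict[str, dict[str, AtacTrack]]:
    import h5py

    out: dict[str, dict[str, AtacTrack]] = {}
    with h5py.File(path, "r") as f:
        for cell_type in f:
            out[cell_type] = {}
            for gene_id in f[cell_type]:
                g = f[cell_type][gene_id]
                out[cell_type][gene_id] = AtacTrack(
                    gene_id, cell_type, g["raw"][:],
                    smoothed=g["smoothed"][:] if "smoothed" in g else None,
                    normalized=g["normalized"][:] if "normalized" in g else None,
                )
    return out
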
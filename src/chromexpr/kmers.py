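"""k-mer instance attribution scoring, ranking and cross-model comparison.

A k-mer instance's score is the mean per-base DNA attribution over its k
bases, where the per-base score is the sum over the four DNA channels at
that position (for one-hot inputs the non-zero channel dominates). Only
the forward-strand k-mer as written is counted — reverse complements are
deliberately kept distinct, since k-mer orientation carries signal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def per_base_dna_score(scores: np.ndarray) -> np.ndarray:
    """Project a (C, L) attribution array to per-base DNA scores by summing
    the four DNA channels at each position."""
    scores = np.asarray(scores)
    if scores.ndim != 2 or scores.shape[0] < 4:
        raise ValueError("expected a (C>=4, L) attribution array")
    return scores[:4].sum(axis=0)


def score_instances(sequence: str, per_base: np.ndarray, k: int) -> list[tuple]:
    """All overlapping k-mer instances of a sequence with their scores.

    Returns (kmer, position, score) triples for positions 0..L-k; windows
    containing N are skipped.
    """
    seq = sequence.upper()
    per_base = np.asarray(per_base, dtype=np.float64)
    if per_base.shape[0] != len(seq):
        raise ValueError("attribution length does not match sequence length")
    if k > len(seq):
        raise ValueError(f"k={k} exceeds sequence length {len(seq)}")
    # rolling mean over k bases
    csum = np.concatenate([[0.0], np.cumsum(per_base)])
    means = (csum[k:] - csum[:-k]) / k
    out = []
    for pos in range(len(seq) - k + 1):
        kmer = seq[pos : pos + k]
        if "N" in kmer:
            continue
        out.append((kmer, pos, float(means[pos])))
    return out


@dataclass
class KmerScoreTable:
    """Mean per-k-mer scores with instance counts and provenance."""

    k: int
    table: pd.DataFrame  # index: all 4^k k-mers; columns: score, count
    variant: str = "all_instances"  # or "positive_only"
    provenance: dict = field(default_factory=dict)


def build_table(
    instances,
    k: int,
    variant: str = "all_instances",
    provenance: dict | None = None,
) -> KmerScoreTable:
    """Aggregate pooled instances into a per-k-mer score table.

    ``instances`` is either a flat iterable of (kmer, score) pairs (pooled
    over models, folds, seeds) or a mapping cell_type -> iterable, in
    which case per-cell-type means are taken first and then averaged
    *unweighted* across cell types. ``variant='positive_only'`` drops
    instances with score <= 0 before averaging. k-mers with no surviving
    instance get count 0 and NaN score.
    """
    if variant not in ("all_instances", "positive_only"):
        raise ValueError(f"unknown variant {variant!r}")
    if isinstance(instances, dict):
        per_type = {
            ct: build_table(inst, k, variant).table for ct, inst in instances.items()
        }
        if not per_type:
            raise ValueError("empty instance pool")
        scores = pd.DataFrame({ct: t["score"] for ct, t in per_type.items()})
        counts = pd.DataFrame({ct: t["count"] for ct, t in per_type.items()})
        table = pd.DataFrame(
            {"score": scores.mean(axis=1), "count": counts.sum(axis=1).astype(int)}
        )
        return KmerScoreTable(k, table, variant,
                              dict(provenance or {}, cell_types=sorted(per_type)))
    pairs = [(km, s) for km, *rest in instances
             for s in [rest[-1]]]  # accept (kmer, score) or (kmer, pos, score)
    if not pairs:
        raise ValueError("empty instance pool")
    sums = {}
    counts = {}
    for km, s in pairs:
        if len(km) != k:
            raise ValueError(f"instance {km!r} is not a {k}-mer")
        if variant == "positive_only" and s <= 0:
            continue
        sums[km] = sums.get(km, 0.0) + s
        counts[km] = counts.get(km, 0) + 1
    idx = all_kmers(k)
    table = pd.DataFrame(
        {
            "score": [sums[km] / counts[km] if counts.get(km) else np.nan for km in idx],
            "count": [counts.get(km, 0) for km in idx],
        },
        index=idx,
    )
    return KmerScoreTable(k, table, variant, dict(provenance or {}))


def rank_kmers(table: KmerScoreTable) -> pd.Series:
    """Descending ranks (1 = highest score), ties broken lexicographically;
    NaN-scored k-mers rank last."""
    df = table.table
    order = sorted(df.index, key=lambda km: (not np.isfinite(df.at[km, "score"]),
                                             -df.at[km, "score"] if np.isfinite(df.at[km, "score"]) else 0.0,
                                             km))
    return pd.Series({km: r + 1 for r, km in enumerate(order)}, name="rank")


def rank_delta(table_a: KmerScoreTable, table_b: KmerScoreTable) -> pd.DataFrame:
    """Per-k-mer rank change rank_a - rank_b (positive = dropped in a).

    NaN-scored k-mers are ranked last and flagged in the ``undefined``
    column.
    """
    if table_a.k != table_b.k:
        raise ValueError("tables must share k")
    if table_a.variant != table_b.variant:
        raise ValueError("tables must share the scoring variant")
    ra, rb = rank_kmers(table_a), rank_kmers(table_b)
    undef = table_a.table["score"].isna() | table_b.table["score"].isna()
    return pd.DataFrame({"rank_a": ra, "rank_b": rb, "delta": ra - rb,
                         "undefined": undef})


def top_kmers(table: KmerScoreTable, fraction: float) -> set:
    n_top = math.ceil(fraction * 4**table.k)
    ranks = rank_kmers(table)
    return set(ranks.index[ranks.to_numpy() <= n_top])


def top_fraction_jaccard(
    table_a: KmerScoreTable, table_b: KmerScoreTable, fraction: float = 0.10
) -> float:
    """Jaccard index |A∩B|/|A∪B| of the two tables' top-``fraction``
    k-mer sets (top ceil(fraction * 4^k) by score)."""
    if table_a.k != table_b.k:
        raise ValueError("tables must share k")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if table_a.table["count"].sum() == 0 or table_b.table["count"].sum() == 0:
        raise ValueError("empty table")
    a, b = top_kmers(table_a, fraction), top_kmers(table_b, fraction)
    return len(a & b) / len(a | b)


def write_table(table: KmerScoreTable, path) -> None:
    df = table.table.copy()
    df["rank"] = rank_kmers(table)
    df.index.name = "kmer"
    df.to_csv(path, sep="\t")
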
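"""Promoter extraction and DNA encoding.

Promoter windows are TSS-centered, fixed-width regions on the coding strand
of each protein-coding gene's canonical transcript. Internally all
coordinates are 0-based half-open; GTF's 1-based inclusive coordinates are
converted on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

AUTOSOMES = frozenset(f"chr{i}" for i in range(1, 23)) | frozenset(
    str(i) for i in range(1, 23)
)


@dataclass
class PromoterRecord:
    """A gene's TSS-centered promoter window.

    ``tss`` is 0-based; ``window_start``/``window_end`` are 0-based
    half-open; ``sequence`` (once extracted) runs along the coding strand,
    so for minus-strand genes it is the reverse complement of the reference
    slice and ``sequence[flank]`` is the (complemented) TSS base.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    window_start: int | None = None
    window_end: int | None = None
    sequence: str | None = None
    gene_name: str | None = None

    @property
    def flank(self) -> int | None:
        if self.window_start is None or self.window_end is None:
            return None
        return (self.window_end - self.window_start) // 2


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_ATTR_RE = {
    key: re.compile(rf'{key} "([^"]*)"')
    for key in ("gene_id", "gene_type", "transcript_id", "gene_name")
}
_TAG_RE = re.compile(r'tag "([^"]*)"')


def _parse_attributes(attr: str) -> dict:
    out = {k: (m.group(1) if (m := rx.search(attr)) else None) for k, rx in _ATTR_RE.items()}
    out["tags"] = set(_TAG_RE.findall(attr))
    return out


def select_canonical_promoters(
    gtf_path: str | Path,
    chromosome_filter: Iterable[str] | None = AUTOSOMES,
) -> list[PromoterRecord]:
    """Pick one TSS per protein-coding gene from a GENCODE-style GTF.

    The transcript tagged ``Ensembl_canonical`` is used; when no transcript
    of a gene carries the tag, the transcript with the 5'-most TSS is chosen
    (ties broken by lexicographic transcript ID) and the fallback is logged.
    ``chromosome_filter`` keeps only the listed chromosomes (default: human
    autosomes); pass ``None`` to keep everything. The TSS of a minus-strand
    transcript is its *end* coordinate (5'-most base on the coding strand).

    Returns records without sequences (see :func:`extract_window`).
    """
    keep = None if chromosome_filter is None else set(chromosome_filter)
    # gene_id -> list of (is_canonical, tss, transcript_id, record)
    candidates: dict[str, list] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GTF line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            if feature != "transcript":
                continue
            if keep is not None and chrom not in keep:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"malformed GTF line {lineno}: non-integer coordinates") from exc
            if strand not in "+-":
                raise ValueError(f"malformed GTF line {lineno}: strand {strand!r}")
            a = _parse_attributes(attrs)
            if a["gene_type"] != "protein_coding" or a["gene_id"] is None:
                continue
            # 1-based inclusive -> 0-based: 5' end is `start-1` on '+', `end-1` on '-'
            tss = start_i - 1 if strand == "+" else end_i - 1
            rec = PromoterRecord(
                gene_id=a["gene_id"], chrom=chrom, strand=strand, tss=tss,
                gene_name=a["gene_name"],
            )
            is_canon = "Ensembl_canonical" in a["tags"]
            candidates.setdefault(a["gene_id"], []).append(
                (is_canon, tss, a["transcript_id"] or "", rec)
            )

    records = []
    for gene_id in sorted(candidates):
        txs = candidates[gene_id]
        canonical = [t for t in txs if t[0]]
        if canonical:
            if len(canonical) > 1:
                logger.warning("gene %s has %d canonical transcripts; using first by ID",
                               gene_id, len(canonical))
            chosen = sorted(canonical, key=lambda t: t[2])[0]
        else:
            # 5'-most TSS: smallest coordinate on '+', largest on '-'
            strand = txs[0][3].strand
            chosen = sorted(txs, key=lambda t: (t[1] if strand == "+" else -t[1], t[2]))[0]
            logger.info("gene %s: no Ensembl_canonical tag, fell back to 5'-most TSS "
                        "transcript %s", gene_id, chosen[2])
        records.append(chosen[3])
    return records


def extract_window(record: PromoterRecord, genome: Mapping[str, object], flank: int = 1000) -> PromoterRecord:
    """Attach the coding-strand promoter sequence of width ``2*flank``.

    ``genome`` maps chromosome name to an indexable sequence (a
    :class:`pyfaidx.Fasta` works, as does a plain dict of strings). The
    window is placed so the TSS base sits at index ``flank`` of the returned
    sequence on either strand; a window that would cross a chromosome
    boundary raises rather than padding.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    chrom_seq = genome[record.chrom]
    chrom_len = len(chrom_seq)
    if record.strand == "+":
        start, end = record.tss - flank, record.tss + flank
    else:
        start, end = record.tss - flank + 1, record.tss + flank + 1
    if start < 0 or end > chrom_len:
        raise ValueError(
            f"promoter window [{start},{end}) of {record.gene_id} exceeds "
            f"{record.chrom} bounds [0,{chrom_len})"
        )
    raw = chrom_seq[start:end]
    seq = str(raw).upper()
    if record.strand == "-":
        seq = reverse_complement(seq)
    return replace(record, window_start=start, window_end=end, sequence=seq)


def one_hot_encode(sequence: str) -> np.ndarray:
    """Encode a DNA string as a 4xL {0,1} matrix with row order A,C,G,T.

    ``N`` becomes an all-zero column; any other character raises with its
    position. Case-insensitive.
    """
    seq = sequence.upper()
    arr = np.zeros((4, len(seq)), dtype=np.float32)
    for pos, base in enumerate(seq):
        if base == "N":
            continue
        idx = _BASE_INDEX.get(base)
        if idx is None:
            raise ValueError(f"invalid base {base!r} at position {pos}")
        arr[idx, pos] = 1.0
    return arr


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` (all-zero columns decode to N)."""
    matrix = np.asarray(matrix)
    if matrix.shape[0] != 4:
        raise ValueError("expected a 4xL matrix")
    sums = matrix.sum(axis=0)
    out = np.array(list(BASES))[matrix.argmax(axis=0)]
    out[sums == 0] = "N"
    return "".join(out)


def write_promoter_table(records: Sequence[PromoterRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id, "chrom": r.chrom, "strand": r.strand,
                "tss": r.tss, "window_start": r.window_start, "window_end": r.window_end,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_promoter_table(path: str | Path) -> list[PromoterRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        PromoterRecord(
            gene_id=row.gene_id, chrom=row.chrom, strand=row.strand, tss=int(row.tss),
            window_start=None if pd.isna(row.window_start) else int(row.window_start),
            window_end=None if pd.isna(row.window_end) else int(row.window_end),
        )
        for row in df.itertuples()
    ]


def write_fasta(records: Sequence[PromoterRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            if r.sequence is None:
                raise ValueError(f"record {r.gene_id} has no sequence")
            fh.write(f">{r.gene_id}\n")
            for i in range(0, len(r.sequence), 80):
                fh.write(r.sequence[i : i + 80] + "\n")
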
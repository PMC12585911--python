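"""Post-alignment read filters and positional base-composition profiles.

These are the quality filters applied after mapping and before any
profiling: the XR-seq mapq/chromosome/length filter, the six-criterion
paired-end RNA-seq filter, coordinate deduplication, and per-position
mono-/dinucleotide composition matrices used to verify damage specificity
(TT/TC enrichment 6 nt from the 3' end of ~24-nt excision products).
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import ReadAlignment

__all__ = [
    "filter_xr_reads",
    "filter_rnaseq_pairs",
    "deduplicate_alignments",
    "positional_composition",
    "NUCLEOTIDES",
    "DINUCLEOTIDES",
]

NUCLEOTIDES = ("A", "C", "G", "T")
DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)

MITOCHONDRIAL_NAMES = frozenset({"MT", "chrM", "M", "MtDNA", "chrMT"})


def filter_xr_reads(
    reads: Sequence[ReadAlignment],
    mapq_min: int = 20,
    allowed_chroms: Set[str] = frozenset({"I", "II", "III", "IV", "V", "X"}),
    length_range: Tuple[int, int] = (21, 28),
) -> List[ReadAlignment]:
    """Keep XR-seq reads with mapq strictly greater than ``mapq_min``, on an
    allowed chromosome, and with aligned length inside ``length_range``
    (inclusive at both ends). Order is preserved.

    The mapq boundary is strict (> mapq_min); the length bounds are
    inclusive, so the defaults keep 21-28 nt reads.
    """
    if not allowed_chroms:
        raise ValueError("allowed_chroms must be non-empty")
    lo, hi = length_range
    if lo > hi:
        raise ValueError(f"invalid length_range ({lo}, {hi})")
    return [
        r
        for r in reads
        if r.mapq > mapq_min
        and r.chrom in allowed_chroms
        and lo <= r.read_length <= hi
    ]


def filter_rnaseq_pairs(
    reads: Sequence[ReadAlignment],
    mapq_min: int = 30,
    max_insert: int = 500_000,
    max_hits: int = 10,
) -> List[ReadAlignment]:
    """Keep paired-end RNA-seq reads satisfying all six retention criteria:

    mapq >= 30; mapped as a proper pair on the same chromosome; insert
    size <= 500 kb with inward orientation; CIGAR containing a match
    segment; at most 10 reported alignments (NH tag); not mitochondrial.

    Proper-pair / insert / orientation semantics are folded into the
    ``is_proper_pair`` and ``insert_size`` fields populated at ingestion.
    Missing metadata raises, naming the field.
    """
    kept: List[ReadAlignment] = []
    for r in reads:
        for fieldname in ("is_proper_pair", "insert_size", "nh_tag", "cigar_has_match"):
            if getattr(r, fieldname) is None:
                raise ValueError(
                    f"RNA-seq filtering requires the {fieldname!r} field"
                )
        if (
            r.mapq >= mapq_min
            and r.is_proper_pair
            and abs(r.insert_size) <= max_insert
            and r.cigar_has_match
            and r.nh_tag <= max_hits
            and r.chrom not in MITOCHONDRIAL_NAMES
        ):
            kept.append(r)
    return kept


def deduplicate_alignments(reads: Iterable[ReadAlignment]) -> List[ReadAlignment]:
    """Collapse reads sharing (chrom, start, end, strand) to the first
    occurrence; order-stable and idempotent."""
    seen = set()
    out: List[ReadAlignment] = []
    for r in reads:
        key = (r.chrom, r.start, r.end, r.strand)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def positional_composition(
    sequences: Iterable[str],
    k: int = 2,
    read_length: int = 24,
    from_3prime: bool = False,
) -> pd.DataFrame:
    """Per-position k-mer frequency matrix over reads of one exact length.

    Only sequences of exactly ``read_length`` are used. For k=1 the result
    is a (read_length x 4) matrix; for k=2 a ((read_length-1) x 16) matrix
    of overlapping dinucleotide frequencies. Each row sums to 1. The index
    gives the 0-based offset of the (first base of the) k-mer from the 5'
    end, or, with ``from_3prime``, the negative offset from the 3' end
    (position -6 is where the damage dinucleotide of a 24-nt excision
    product sits).
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    alphabet = NUCLEOTIDES if k == 1 else DINUCLEOTIDES
    index_map = {m: j for j, m in enumerate(alphabet)}
    n_pos = read_length - k + 1
    counts = np.zeros((n_pos, len(alphabet)), dtype=float)
    n_used = 0
    for seq in sequences:
        if len(seq) != read_length:
            continue
        seq = seq.upper()
        n_used += 1
        for i in range(n_pos):
            mer = seq[i : i + k]
            j = index_map.get(mer)
            if j is not None:
                counts[i, j] += 1
    if n_used == 0:
        raise ValueError(f"no reads of length {read_length}")
    rowsum = counts.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    freq = counts / rowsum
    if from_3prime:
        # offset of the k-mer's last base from the 3' end: -1 = terminal base
        index = [i + k - 1 - read_length for i in range(n_pos)]
    else:
        index = list(range(n_pos))
    return pd.DataFrame(freq, index=index, columns=list(alphabet))
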
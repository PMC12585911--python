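"""Core genomic data model: intervals, aligned reads, genomes, gene models.

Coordinates are 0-based, half-open throughout (BED convention). GFF3 input
is converted on read (1-based inclusive -> internal) by :mod:`repairscape.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping, Optional

import numpy as np

__all__ = [
    "GenomicInterval",
    "ReadAlignment",
    "Genome",
    "GeneModel",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base -> code used for vectorised sequence arithmetic (N = 4)
_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string (case preserved, N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ReadAlignment:
    """A strand-aware ungapped aligned read (the BED6 view of an alignment).

    ``read_length`` equals the aligned span for BED reads. The optional
    paired-end / multi-mapping flags are only populated for RNA-seq input.
    """

    interval: GenomicInterval
    mapq: int = 0
    sample_id: str = ""
    is_proper_pair: Optional[bool] = None
    insert_size: Optional[int] = None
    nh_tag: Optional[int] = None
    cigar_has_match: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def read_length(self) -> int:
        return self.interval.width

    @property
    def five_prime(self) -> int:
        """0-based coordinate of the 5' terminal base."""
        return self.start if self.strand != "-" else self.end - 1


class Genome:
    """An in-memory reference genome: uppercase DNA over {A,C,G,T,N}.

    Sequences are stored as strings; per-chromosome uint8 code arrays
    (A=0, C=1, G=2, T=3, N=4) are cached lazily for vectorised scans.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences: Dict[str, str] = {
            c: s.upper() for c, s in sequences.items()
        }
        self.chrom_sizes: Dict[str, int] = {
            c: len(s) for c, s in self.sequences.items()
        }
        self._codes: Dict[str, np.ndarray] = {}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def codes(self, chrom: str) -> np.ndarray:
        """uint8 code array for ``chrom`` (cached)."""
        if chrom not in self._codes:
            raw = np.frombuffer(
                self.sequences[chrom].encode("ascii"), dtype=np.uint8
            )
            self._codes[chrom] = _CODES[raw]
        return self._codes[chrom]

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)``; reverse-complemented when strand is '-'."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.chrom_sizes[chrom]:
            raise ValueError(
                f"[{start}, {end}) outside {chrom} (len {self.chrom_sizes[chrom]})"
            )
        seq = self.sequences[chrom][start:end]
        return revcomp(seq) if strand == "-" else seq

    def fetch_interval(self, iv: GenomicInterval) -> str:
        return self.fetch(iv.chrom, iv.start, iv.end, iv.strand)


@dataclass(frozen=True)
class GeneModel:
    """A gene as an oriented interval; strand is the transcription direction.

    ``tss``/``tes`` are 0-based positions of the first/last transcribed base:
    for + genes tss = start and tes = end - 1, mirrored for - genes.
    """

    interval: GenomicInterval
    gene_id: str

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("genes must be stranded")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.interval.width
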
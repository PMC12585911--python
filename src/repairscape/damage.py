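"""Damage-seq processing: undamaged-strand read removal, lesion-window
inference, and the dipyrimidine filter.

Damage-seq reads stall at the lesion, so the damaged dinucleotide lies in
the two positions immediately upstream (5' side, read orientation) of each
aligned fragment's 5' end. Each read is reduced to a 10-nt strand-oriented
genomic window whose middle two bases (oriented positions 5-6, 1-based)
are the inferred lesion dinucleotide: the read is trimmed to its first 4
nt from the 5' end and extended 6 nt upstream.

UV photolesions (CPD and 6-4PP) form between adjacent pyrimidines, so
windows whose oriented middle two bases are not both C/T are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

from .core import Genome, GenomicInterval, ReadAlignment, revcomp

__all__ = [
    "DamageWindow",
    "remove_undamaged_strand_reads",
    "infer_damage_window",
    "infer_damage_windows",
    "dipyrimidine_filter",
    "damage_site_reads",
    "UNDAMAGED_STRAND_ADAPTOR",
]

# reads carrying this adaptor derive from the undamaged strand
UNDAMAGED_STRAND_ADAPTOR = "GACTGGTTCCAATTGAAAGTGCTCTTCCGATCT"

PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class DamageWindow:
    """The 10-nt window around an inferred lesion.

    ``interval`` has width exactly 10; ``damage_dinucleotide`` (width 2)
    occupies its middle two positions. ``oriented_sequence`` is the
    10-mer of the damaged strand read 5'->3' on that strand, so the
    lesion always sits at oriented positions 5-6 (1-based).
    """

    interval: GenomicInterval
    damage_dinucleotide: GenomicInterval
    read_strand: str
    damage_strand: str
    oriented_sequence: str

    def __post_init__(self) -> None:
        if self.interval.width != 10:
            raise ValueError("damage window must be exactly 10 bp")
        if self.damage_dinucleotide.width != 2:
            raise ValueError("damage dinucleotide must be exactly 2 bp")
        if len(self.oriented_sequence) not in (0, 10):
            raise ValueError("oriented_sequence must be a 10-mer when set")

    @property
    def middle_dinucleotide(self) -> str:
        """The oriented lesion dinucleotide (positions 5-6 of the 10-mer)."""
        return self.oriented_sequence[4:6]


def remove_undamaged_strand_reads(
    records: Iterable[str], adaptor: str = UNDAMAGED_STRAND_ADAPTOR
) -> List[str]:
    """Discard raw read sequences containing ``adaptor`` as a substring.

    Reads carrying the second-ligation adaptor derive from the undamaged
    strand and are removed before alignment; everything else passes
    unchanged.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    adaptor = adaptor.upper()
    return [rec for rec in records if adaptor not in rec.upper()]


def infer_damage_window(
    read: ReadAlignment, genome: Genome, convention: str = "read"
) -> DamageWindow:
    """Infer the 10-nt damage window for one aligned Damage-seq read.

    For a + read with 5' end at p the window is ``[p-6, p+4)`` and the
    lesion dinucleotide ``[p-2, p)``; for a - read aligned ``[s, e)`` the
    mirror: window ``[e-4, e+6)``, dinucleotide ``[e, e+2)``.

    ``convention`` fixes which strand carries the lesion: ``"read"``
    (default) places it on the read's strand, ``"opposite"`` on the
    complementary strand. The dinucleotide coordinates are identical
    under both; only the strand label and the orientation of
    ``oriented_sequence`` change (and positions 5-6 of a 10-mer map onto
    themselves under reverse complement).

    Raises ``ValueError`` when the window would leave the chromosome;
    batch callers skip and count such reads.
    """
    if convention not in ("read", "opposite"):
        raise ValueError(f"unknown convention {convention!r}")
    if read.strand not in ("+", "-"):
        raise ValueError("Damage-seq reads must be stranded")
    size = genome.chrom_sizes.get(read.chrom)
    if size is None:
        raise KeyError(f"unknown chromosome {read.chrom!r}")
    if read.strand == "+":
        p = read.start
        win = (p - 6, p + 4)
        dinuc = (p - 2, p)
    else:
        e = read.end
        win = (e - 4, e + 6)
        dinuc = (e, e + 2)
    if win[0] < 0 or win[1] > size:
        raise ValueError(
            f"damage window [{win[0]}, {win[1]}) outside {read.chrom}"
        )
    if convention == "read":
        damage_strand = read.strand
    else:
        damage_strand = "-" if read.strand == "+" else "+"
    oriented = genome.fetch(read.chrom, win[0], win[1], damage_strand)
    return DamageWindow(
        interval=GenomicInterval(read.chrom, win[0], win[1], damage_strand),
        damage_dinucleotide=GenomicInterval(
            read.chrom, dinuc[0], dinuc[1], damage_strand
        ),
        read_strand=read.strand,
        damage_strand=damage_strand,
        oriented_sequence=oriented,
    )


def infer_damage_windows(
    reads: Sequence[ReadAlignment], genome: Genome, convention: str = "read"
) -> Tuple[List[DamageWindow], int]:
    """Vector form of :func:`infer_damage_window`.

    Reads whose window falls off the chromosome are skipped (a clipped
    window cannot satisfy the width-10 invariant); the second return
    value counts them.
    """
    windows: List[DamageWindow] = []
    skipped = 0
    for read in reads:
        try:
            windows.append(infer_damage_window(read, genome, convention))
        except ValueError:
            skipped += 1
    return windows, skipped


def damage_site_reads(windows: Iterable[DamageWindow]) -> List[ReadAlignment]:
    """The 2-nt lesion dinucleotides as alignment records (strand =
    damage strand), the form in which damage maps enter binned profiles:
    whole reads cannot satisfy a half-overlap rule in bins narrower than
    the read, and profiling the site keeps dyad-scale (2-10 bp)
    structure that read-length smoothing would erase."""
    return [
        ReadAlignment(w.damage_dinucleotide, mapq=255, sample_id="damage_site")
        for w in windows
    ]


def dipyrimidine_filter(windows: Iterable[DamageWindow]) -> List[DamageWindow]:
    """Keep windows whose oriented middle two bases are both pyrimidines.

    Windows with N at either middle position are rejected.
    """
    return [
        w
        for w in windows
        if len(w.middle_dinucleotide) == 2
        and w.middle_dinucleotide[0] in PYRIMIDINES
        and w.middle_dinucleotide[1] in PYRIMIDINES
    ]
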
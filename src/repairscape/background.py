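"""Composition-preserving background read simulation.

Damage and repair maps are confounded by sequence context: dipyrimidine
density alone produces apparent enrichment. The background simulator
emits, for each real read, one pseudo-read of the same length placed at a
random genomic position whose sequence has the *identical* multiset of
overlapping k-mers (k=2 by default, i.e. the same dinucleotide content).
Dividing observed profiles by profiles of these pseudo-reads cancels the
composition component of the signal.

Sampling is two-phase. Up to ``sens`` random candidate positions are
drawn per read (chromosome proportional to length, start uniform, strand
uniform); a candidate is accepted when its k-mer multiset equals the
read's. Because an exact multiset match of a ~24-mer is rare under blind
sampling, reads still unmatched after ``sens`` attempts are resolved
against an exhaustive index of every genomic window of that length keyed
by k-mer multiset, drawing uniformly among matching positions — the
rejection sampler's own limiting distribution. A read is flagged only
when the genome contains no window (either strand) with a matching
multiset; flagged reads receive the last random candidate so that the
output always has one pseudo-read per input read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Genome, GenomicInterval, ReadAlignment

__all__ = [
    "SimulatorSettings",
    "BackgroundResult",
    "simulate_background_reads",
    "kmer_counts",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulatorSettings:
    """Settings for the background simulator.

    kmer: k-mer size whose multiset must match (2 = dinucleotides).
    sens: random candidate attempts per read before the exhaustive
        index is consulted.
    seed: RNG seed; fixed seed gives byte-identical output.
    """

    kmer: int = 2
    sens: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kmer < 1:
            raise ValueError("kmer must be >= 1")
        if self.sens < 1:
            raise ValueError("sens must be >= 1")


@dataclass
class BackgroundResult:
    """One pseudo-read per input read, in input order."""

    reads: List[ReadAlignment]
    sequences: List[str]
    flagged: np.ndarray  # bool per read: no exact match exists in genome

    @property
    def flagged_fraction(self) -> float:
        return float(np.mean(self.flagged)) if len(self.flagged) else 0.0


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for i, b in enumerate(_BASES):
        out[arr == ord(b)] = i
    return out


def kmer_counts(codes: np.ndarray, k: int) -> np.ndarray:
    """Count vector (length 4**k) of overlapping k-mers of a code sequence.

    Windows containing N (code 4) are not counted.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(4**k, dtype=np.int64)
    ids = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        valid &= c < 4
        ids = ids * 4 + c
    return np.bincount(ids[valid], minlength=4**k)


def _window_kmer_ids(mat: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """k-mer ids (m, L-k+1) and validity mask for a window matrix (m, L)."""
    m, L = mat.shape
    n = L - k + 1
    ids = np.zeros((m, n), dtype=np.int64)
    valid = np.ones((m, n), dtype=bool)
    for j in range(k):
        c = mat[:, j : j + n]
        valid &= c < 4
        ids = ids * 4 + c
    return ids, valid


def _batch_counts(mat: np.ndarray, k: int) -> np.ndarray:
    """Row-wise k-mer count matrix (m, 4**k); rows with any N get -1 rows."""
    m = mat.shape[0]
    nk = 4**k
    ids, valid = _window_kmer_ids(mat, k)
    bad = ~valid.all(axis=1)
    flat = ids + (np.arange(m) * nk)[:, None]
    counts = np.bincount(
        flat.ravel()[valid.ravel()], minlength=m * nk
    ).reshape(m, nk)
    counts[bad] = -1
    return counts


# k-mer id permutation taking a sequence's counts to its reverse complement's
def _revcomp_perm(k: int) -> np.ndarray:
    nk = 4**k
    perm = np.empty(nk, dtype=np.int64)
    for i in range(nk):
        digits = []
        x = i
        for _ in range(k):
            digits.append(x % 4)
            x //= 4
        # digits are reversed base order already; complement each
        rc = 0
        for d in digits:  # reversed order = reverse of sequence
            rc = rc * 4 + (3 - d)
        perm[i] = rc
    return perm


class _MatchIndex:
    """Exhaustive index of plus-strand windows of one length, keyed by
    k-mer count vector (void view for hashing-free sorted lookup)."""

    def __init__(self, genome: Genome, length: int, k: int):
        keys_parts = []
        pos_parts = []
        chrom_parts = []
        self.chroms = [c for c in genome if genome.chrom_sizes[c] >= length]
        for ci, chrom in enumerate(self.chroms):
            codes = genome.codes(chrom).astype(np.int64)
            n = len(codes) - length + 1
            if n <= 0:
                continue
            nkm = length - k + 1
            ids = np.zeros(len(codes) - k + 1, dtype=np.int64)
            valid = np.ones(len(codes) - k + 1, dtype=bool)
            for j in range(k):
                c = codes[j : j + len(codes) - k + 1]
                valid &= c < 4
                ids = ids * 4 + c
            ids[~valid] = 0
            nk = 4**k
            onehot_cum = np.zeros((n + nkm - 1 + 1, nk), dtype=np.int32)
            np.add.at(onehot_cum[1:], (np.arange(len(ids)), ids), 1)
            # exclude invalid windows later via valid cumsum
            np.cumsum(onehot_cum, axis=0, out=onehot_cum)
            counts = onehot_cum[nkm:n + nkm] - onehot_cum[:n]
            vcum = np.concatenate([[0], np.cumsum(~valid)])
            has_n = (vcum[nkm:n + nkm] - vcum[:n]) > 0
            counts = counts[~has_n]
            pos = np.nonzero(~has_n)[0]
            keys_parts.append(counts.astype(np.uint8))
            pos_parts.append(pos)
            chrom_parts.append(np.full(len(pos), ci, dtype=np.int32))
        if keys_parts:
            keys = np.ascontiguousarray(np.concatenate(keys_parts))
            self.positions = np.concatenate(pos_parts)
            self.chrom_idx = np.concatenate(chrom_parts)
        else:
            keys = np.zeros((0, 4**k), dtype=np.uint8)
            self.positions = np.zeros(0, dtype=np.int64)
            self.chrom_idx = np.zeros(0, dtype=np.int32)
        void = keys.view([("", np.uint8)] * keys.shape[1]).ravel()
        order = np.argsort(void, kind="stable")
        self._sorted = void[order]
        self._order = order

    def lookup(self, count_vec: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """All (chrom_idx, position) whose window counts equal ``count_vec``."""
        q = np.ascontiguousarray(count_vec.astype(np.uint8)).view(
            [("", np.uint8)] * len(count_vec)
        ).ravel()
        lo = np.searchsorted(self._sorted, q[0], side="left")
        hi = np.searchsorted(self._sorted, q[0], side="right")
        idx = self._order[lo:hi]
        return self.chrom_idx[idx], self.positions[idx]


def simulate_background_reads(
    reads: Sequence[ReadAlignment],
    sequences: Sequence[str],
    genome: Genome,
    settings: SimulatorSettings = SimulatorSettings(),
) -> BackgroundResult:
    """Emit one composition-matched pseudo-read per input read.

    ``sequences`` are the reads' underlying sequences (5'->3' on the read
    strand); pseudo-read positions/strands are random subject to exact
    k-mer multiset identity with the corresponding input read. Output
    order matches input order; deterministic under ``settings.seed``.
    """
    if len(reads) != len(sequences):
        raise ValueError("reads and sequences must be parallel")
    n = len(reads)
    if n == 0:
        return BackgroundResult([], [], np.zeros(0, dtype=bool))
    k = settings.kmer
    nk = 4**k
    rng = np.random.default_rng(settings.seed)
    rc_perm = _revcomp_perm(k)

    chroms = list(genome)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=np.int64)
    max_size = int(sizes.max())

    lengths = np.array([len(s) for s in sequences], dtype=np.int64)
    if lengths.min() < k:
        raise ValueError("read shorter than kmer size")
    if lengths.max() > max_size:
        raise ValueError("read longer than every chromosome")

    targets = np.full((n, nk), -1, dtype=np.int64)
    for i, s in enumerate(sequences):
        targets[i] = kmer_counts(_encode(s), k)

    out_chrom = np.full(n, -1, dtype=np.int64)
    out_start = np.full(n, -1, dtype=np.int64)
    out_strand = np.zeros(n, dtype=np.int8)  # 0 = +, 1 = -
    flagged = np.zeros(n, dtype=bool)

    chrom_codes = {c: genome.codes(c).astype(np.int64) for c in chroms}
    p_chrom = sizes / sizes.sum()

    # phase 1: bounded rejection sampling, batched per read length
    for L in np.unique(lengths):
        sel = np.nonzero(lengths == L)[0]
        eligible = sizes >= L
        if not eligible.any():
            raise ValueError(f"read length {L} exceeds every chromosome")
        pw = np.where(eligible, p_chrom, 0.0)
        pw = pw / pw.sum()
        pending = sel.copy()
        for _attempt in range(settings.sens):
            if pending.size == 0:
                break
            m = pending.size
            ci = rng.choice(len(chroms), size=m, p=pw)
            starts = (rng.random(m) * (sizes[ci] - L + 1)).astype(np.int64)
            strands = rng.integers(0, 2, size=m)
            accepted = np.zeros(m, dtype=bool)
            for cidx in np.unique(ci):
                rows = np.nonzero(ci == cidx)[0]
                g = chrom_codes[chroms[cidx]]
                win = g[starts[rows, None] + np.arange(L)]
                counts = _batch_counts(win, k)
                # minus-strand window counts = permuted plus-strand counts
                minus = strands[rows] == 1
                cc = counts.copy()
                cc[minus] = counts[minus][:, rc_perm]
                ok = (cc >= 0).all(axis=1) & (
                    cc == targets[pending[rows]]
                ).all(axis=1)
                accepted[rows] = ok
            hit = pending[accepted]
            out_chrom[hit] = ci[accepted]
            out_start[hit] = starts[accepted]
            out_strand[hit] = strands[accepted]
            # keep last candidate for reads that end up flagged
            miss = ~accepted
            out_chrom[pending[miss]] = ci[miss]
            out_start[pending[miss]] = starts[miss]
            out_strand[pending[miss]] = strands[miss]
            pending = pending[miss]

        # phase 2: exhaustive index over windows of this length
        if pending.size:
            index = _MatchIndex(genome, int(L), k)
            local_chrom_to_global = np.array(
                [chroms.index(c) for c in index.chroms], dtype=np.int64
            ) if index.chroms else np.zeros(0, dtype=np.int64)
            for i in pending:
                t = targets[i]
                c_plus, p_plus = index.lookup(t)
                c_minus, p_minus = index.lookup(t[rc_perm])
                total = len(c_plus) + len(c_minus)
                if total == 0:
                    flagged[i] = True  # keeps the last random candidate
                    continue
                j = int(rng.integers(0, total))
                if j < len(c_plus):
                    out_chrom[i] = local_chrom_to_global[c_plus[j]]
                    out_start[i] = p_plus[j]
                    out_strand[i] = 0
                else:
                    j -= len(c_plus)
                    out_chrom[i] = local_chrom_to_global[c_minus[j]]
                    out_start[i] = p_minus[j]
                    out_strand[i] = 1

    pseudo_reads: List[ReadAlignment] = []
    pseudo_seqs: List[str] = []
    for i in range(n):
        chrom = chroms[int(out_chrom[i])]
        start = int(out_start[i])
        L = int(lengths[i])
        strand = "+" if out_strand[i] == 0 else "-"
        pseudo_reads.append(
            ReadAlignment(
                GenomicInterval(chrom, start, start + L, strand),
                mapq=reads[i].mapq,
                sample_id=reads[i].sample_id,
            )
        )
        pseudo_seqs.append(genome.fetch(chrom, start, start + L, strand))
    return BackgroundResult(pseudo_reads, pseudo_seqs, flagged)
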
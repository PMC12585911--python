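"""Synthetic genomes, annotations, and UV damage/repair sequencing reads
with known ground truth.

The generator emulates the structure of the real study inputs so that
every downstream stage has a recovery test:

* a toy genome of iid bases at a worm-like GC content, with a packed
  gene annotation, a TPM expression table, ATAC-like peak summits and
  nucleosome dyad positions;
* XR-seq-like reads over gene bodies: lengths peaking at 24 nt, a
  dipyrimidine 6 nt from the 3' end (the damage the excised oligo
  carries), and a transcribed-strand bias that grows with expression
  quartile;
* Damage-seq-like reads emitted from planted lesion dinucleotides, one
  read per lesion with its 5' end exactly 2 nt downstream of the lesion
  (the exact inverse of the damage-window inference), lesion density
  carrying a planted cosine of configurable period around dyads/summits
  plus a central accessibility dip at summits, and per-timepoint
  Bernoulli survival with linker-preferential repair so that the
  periodic pattern sharpens over the time course;
* mock / naked control tracks and pure signal-plus-noise matrices for
  the clustering and tertile machinery.

Every emitted read maps to exactly one truth row; all outputs are
byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GeneModel, Genome, GenomicInterval, ReadAlignment

__all__ = [
    "SimConfig",
    "SimTruth",
    "ToyData",
    "build_toy_genome",
    "simulate_xr_reads",
    "simulate_damage_reads",
    "simulate_signal_tracks",
    "default_xr_length_law",
]

_PYR = (1, 3)  # C, T codes


def default_xr_length_law() -> Dict[int, float]:
    """Discrete read-length distribution over 10-32 nt peaking at 24 nt,
    emulating the excised-oligonucleotide length profile."""
    lengths = np.arange(10, 33)
    w = np.exp(-0.5 * ((lengths - 24) / 2.2) ** 2)
    w /= w.sum()
    return {int(l): float(p) for l, p in zip(lengths, w)}


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    All fractions lie in [0, 1]; distribution weights sum to 1. A fixed
    seed makes every generator byte-reproducible.
    """

    genome_length: int = 600_000          # bp per chromosome
    n_chroms: int = 1
    gc_content: float = 0.36              # worm-like base composition
    n_genes: int = 100
    gene_length_range: Tuple[int, int] = (2_500, 6_000)
    min_gene_gap: int = 600
    expression_law: Tuple[str, float, float] = ("lognormal", 1.0, 1.5)
    expression_zero_fraction: float = 0.1
    ts_bias_by_quartile: Tuple[float, float, float, float] = (0.5, 0.55, 0.65, 0.75)
    xr_length_law: Dict[int, float] = field(default_factory=default_xr_length_law)
    damage_motif_offset: int = 6          # nt from the 3' end
    n_reads: int = 50_000
    n_peaks: int = 25
    n_dyads: int = 40
    peak_summits: Optional[List[Tuple[str, int]]] = None
    dyad_positions: Optional[List[Tuple[str, int]]] = None
    periodic_amplitudes: Dict[int, float] = field(
        default_factory=lambda: {160: 0.5, 10: 0.5}
    )
    peak_center_dip_depth: float = 0.5
    peak_flank: int = 1_000               # reach of the 160-bp modulation
    dyad_flank: int = 80                  # reach of the 10-bp modulation
    timepoint_decay: Dict[str, float] = field(
        default_factory=lambda: {"0h": 1.0, "8h": 0.5, "24h": 0.25, "48h": 0.1}
    )
    linker_survival_contrast: float = 0.5
    noise_lesion_fraction: float = 0.0    # planted non-dipyrimidine lesions
    damage_read_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gc_content",
            "expression_zero_fraction",
            "peak_center_dip_depth",
            "linker_survival_contrast",
            "noise_lesion_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for b in self.ts_bias_by_quartile:
            if not 0.0 < b < 1.0:
                raise ValueError("ts_bias_by_quartile entries must lie in (0, 1)")
        for a in self.periodic_amplitudes.values():
            if not 0.0 <= a <= 1.0:
                raise ValueError("periodic amplitude > 1 gives negative densities")
        s = sum(self.xr_length_law.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError("xr_length_law probabilities must sum to 1")
        for f in self.timepoint_decay.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("timepoint survival fractions must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth for recovery tests.

    ``lesions``: one row per planted lesion (chrom, start of the lesion
    dinucleotide, strand, dipyrimidine flag, per-timepoint survival).
    ``reads``: one row per emitted read with its truth pointers.
    ``gene_ts_fraction``: expected TS/(TS+NTS) per gene.
    ``planted_periods``: {period_bp: amplitude} actually used.
    """

    lesions: Optional[pd.DataFrame] = None
    reads: Optional[pd.DataFrame] = None
    gene_ts_fraction: Optional[pd.Series] = None
    planted_periods: Dict[int, float] = field(default_factory=dict)


@dataclass
class ToyData:
    genome: Genome
    genes: List[GeneModel]
    expression: pd.Series  # TPM per gene_id
    peaks: List[GenomicInterval]  # 1-bp summit intervals
    dyads: List[GenomicInterval]  # 1-bp dyad intervals


def _chrom_names(n: int) -> List[str]:
    roman = ["I", "II", "III", "IV", "V", "X"]
    if n <= len(roman):
        return roman[:n]
    return roman + [f"chr{i}" for i in range(7, n + 1)]


def build_toy_genome(config: SimConfig) -> ToyData:
    """Generate the toy genome, gene annotation, expression table, and
    peak/dyad anchor sets. Deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    names = _chrom_names(config.n_chroms)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for c in names:
        codes = rng.choice(4, size=config.genome_length, p=p)
        seqs[c] = bases[codes].tobytes().decode("ascii")
    genome = Genome(seqs)

    # pack genes with the minimum gap; error when they cannot fit
    lo, hi = config.gene_length_range
    genes: List[GeneModel] = []
    if config.n_genes > 0:
        per_chrom = np.array_split(np.arange(config.n_genes), config.n_chroms)
        for c, idx in zip(names, per_chrom):
            k = len(idx)
            if k == 0:
                continue
            lengths = rng.integers(lo, hi + 1, size=k)
            edge = 2_000  # keep windows around TSS/TES on-chromosome
            need = lengths.sum() + (k + 1) * config.min_gene_gap + 2 * edge
            if need > config.genome_length:
                raise ValueError(
                    f"cannot pack {k} genes of {lo}-{hi} bp with gap "
                    f"{config.min_gene_gap} into {config.genome_length} bp"
                )
            slack = config.genome_length - need
            cuts = np.sort(rng.integers(0, slack + 1, size=k))
            extra = np.diff(np.concatenate([[0], cuts]))
            pos = edge + config.min_gene_gap
            for j, gi in enumerate(idx):
                pos += extra[j]
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    GeneModel(
                        GenomicInterval(c, int(pos), int(pos + lengths[j]), strand),
                        gene_id=f"g{gi + 1:04d}",
                    )
                )
                pos += lengths[j] + config.min_gene_gap

    # expression: lognormal TPM with a zero-expressed fraction, sum 1e6
    gene_ids = [g.gene_id for g in genes]
    if genes:
        law, mu, sigma = config.expression_law
        if law != "lognormal":
            raise ValueError(f"unknown expression law {law!r}")
        vals = rng.lognormal(mu, sigma, size=len(genes))
        nz = rng.random(len(genes)) >= config.expression_zero_fraction
        vals = np.where(nz, vals, 0.0)
        if vals.sum() > 0:
            vals = vals * 1e6 / vals.sum()
        expression = pd.Series(vals, index=gene_ids, name="tpm")
    else:
        expression = pd.Series(dtype=float, name="tpm")

    def _sample_points(n: int, spacing: int) -> List[GenomicInterval]:
        pts: List[GenomicInterval] = []
        margin = 2_500
        for c in names:
            k = n // config.n_chroms + (1 if names.index(c) < n % config.n_chroms else 0)
            if k == 0:
                continue
            span = config.genome_length - 2 * margin
            if span < k * spacing:
                raise ValueError("cannot place anchors with requested spacing")
            offs = np.sort(rng.choice(span - k * spacing + 1, size=k, replace=False))
            positions = margin + offs + np.arange(k) * spacing
            for x in positions:
                pts.append(GenomicInterval(c, int(x), int(x) + 1, "."))
        return pts

    if config.peak_summits is not None:
        peaks = [GenomicInterval(c, x, x + 1, ".") for c, x in config.peak_summits]
    else:
        peaks = _sample_points(config.n_peaks, spacing=2 * config.peak_flank + 500)
    if config.dyad_positions is not None:
        dyads = [GenomicInterval(c, x, x + 1, ".") for c, x in config.dyad_positions]
    else:
        dyads = _sample_points(config.n_dyads, spacing=2 * config.dyad_flank + 100)

    return ToyData(genome, genes, expression, peaks, dyads)


def _quartile_of_genes(expression: pd.Series) -> pd.Series:
    """Expression quartile (0..3 ascending) of the expressed genes;
    zero-expression genes are excluded (label -1)."""
    q = pd.Series(-1, index=expression.index, dtype=int)
    expressed = expression[expression > 0]
    order = expressed.sort_values(kind="stable").index
    splits = np.array_split(np.arange(len(order)), 4)
    for qi, chunk in enumerate(splits):
        q.loc[order[chunk]] = qi
    return q


def _dipyrimidine_starts(codes: np.ndarray, strand: str) -> np.ndarray:
    """Reference start positions of dinucleotides that are pyrimidine-
    pyrimidine on ``strand`` (purine-purine on the reference for '-')."""
    a, b = codes[:-1], codes[1:]
    if strand == "+":
        m = np.isin(a, _PYR) & np.isin(b, _PYR)
    else:
        m = np.isin(a, (0, 2)) & np.isin(b, (0, 2))
    return np.nonzero(m)[0]


def simulate_xr_reads(
    genome: Genome,
    genes: Sequence[GeneModel],
    expression: pd.Series,
    config: SimConfig,
) -> Tuple[List[ReadAlignment], List[str], SimTruth]:
    """Simulate XR-seq reads over gene bodies with a planted TS bias.

    Genes are picked proportional to length (damage load scales with
    target size); the read strand is the transcribed strand (opposite
    the gene) with probability ``ts_bias_by_quartile[q]`` for the gene's
    expression quartile. Each read's sequence carries a dipyrimidine at
    ``damage_motif_offset`` nt from its 3' end, achieved by anchoring
    the read on a genomic dipyrimidine of the read strand. Returns the
    reads, their sequences (5'->3' on the read strand), and truth.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_reads
    if n == 0:
        return [], [], SimTruth(reads=pd.DataFrame(), gene_ts_fraction=pd.Series(dtype=float))
    if not genes:
        raise ValueError("no genes to sample reads from")

    quart = _quartile_of_genes(expression)
    eligible = [g for g in genes if quart.get(g.gene_id, -1) >= 0]
    if not eligible:
        raise ValueError("no expressed genes")

    # dipyrimidine anchor positions per gene and strand
    site_cache: Dict[Tuple[str, str], np.ndarray] = {}
    for g in eligible:
        codes = genome.codes(g.chrom)
        body = codes[g.start : g.end]
        for s in "+-":
            sites = _dipyrimidine_starts(body, s) + g.start
            site_cache[(g.gene_id, s)] = sites
    bad = [g.gene_id for g in eligible
           if len(site_cache[(g.gene_id, "+")]) == 0
           or len(site_cache[(g.gene_id, "-")]) == 0]
    if bad:
        raise ValueError(f"genes without dipyrimidine placement sites: {bad[:5]}")

    glens = np.array([g.length for g in eligible], dtype=float)
    gidx = rng.choice(len(eligible), size=n, p=glens / glens.sum())
    bias = np.array(
        [config.ts_bias_by_quartile[quart[eligible[i].gene_id]] for i in gidx]
    )
    is_ts = rng.random(n) < bias
    lengths_support = np.array(sorted(config.xr_length_law), dtype=int)
    probs = np.array([config.xr_length_law[int(l)] for l in lengths_support])
    lengths = rng.choice(lengths_support, size=n, p=probs)

    o = config.damage_motif_offset
    reads: List[ReadAlignment] = [None] * n  # type: ignore[list-item]
    seqs: List[str] = [""] * n
    rows = []
    for i in range(n):
        g = eligible[gidx[i]]
        gene_strand = g.strand
        # TS reads map opposite the gene; NTS reads map with it
        read_strand = (
            ("-" if gene_strand == "+" else "+") if is_ts[i] else gene_strand
        )
        L = int(lengths[i])
        sites = site_cache[(g.gene_id, read_strand)]
        size = genome.chrom_sizes[g.chrom]
        # read start from the dimer anchor; keep the read on-chromosome
        for _ in range(20):
            p0 = int(sites[rng.integers(len(sites))])
            if read_strand == "+":
                a = p0 - (L - o - 1)
            else:
                a = p0 - o + 1
            if 0 <= a and a + L <= size:
                break
        else:
            continue
        iv = GenomicInterval(g.chrom, a, a + L, read_strand)
        reads[i] = ReadAlignment(iv, mapq=42, sample_id="xr_sim")
        seqs[i] = genome.fetch_interval(iv)
        rows.append(
            {
                "read_index": i,
                "gene_id": g.gene_id,
                "quartile": int(quart[g.gene_id]),
                "is_ts": bool(is_ts[i]),
                "length": L,
            }
        )
    keep = [i for i in range(n) if reads[i] is not None]
    reads_out = [reads[i] for i in keep]
    seqs_out = [seqs[i] for i in keep]
    truth_reads = pd.DataFrame(rows)
    gene_bias = pd.Series(
        {
            g.gene_id: config.ts_bias_by_quartile[quart[g.gene_id]]
            for g in eligible
        },
        name="true_ts_fraction",
    )
    return reads_out, seqs_out, SimTruth(reads=truth_reads, gene_ts_fraction=gene_bias)


def _lesion_weights(
    positions: np.ndarray,
    chrom: str,
    peaks: Sequence[GenomicInterval],
    dyads: Sequence[GenomicInterval],
    config: SimConfig,
) -> Tuple[np.ndarray, np.ndarray]:
    """Multiplicative lesion-density weights and the nucleosome-phase
    cosine (used for linker-preferential survival) for candidate lesion
    positions on one chromosome."""
    w = np.ones(len(positions), dtype=float)
    phase = np.zeros(len(positions), dtype=float)  # cos at the 160-bp period
    amp160 = config.periodic_amplitudes.get(160, 0.0)
    amp10 = config.periodic_amplitudes.get(10, 0.0)
    for pk in peaks:
        if pk.chrom != chrom:
            continue
        c = pk.start
        d = positions - c
        m = np.abs(d) <= config.peak_flank
        if amp160 > 0:
            cosv = np.cos(2 * np.pi * d[m] / 160.0)
            w[m] *= 1.0 + amp160 * cosv
            phase[m] = cosv
        if config.peak_center_dip_depth > 0:
            w[m] *= 1.0 - config.peak_center_dip_depth * np.exp(
                -0.5 * (d[m] / 75.0) ** 2
            )
    if amp10 > 0:
        for dy in dyads:
            if dy.chrom != chrom:
                continue
            d = positions - dy.start
            m = np.abs(d) <= config.dyad_flank
            w[m] *= 1.0 + amp10 * np.cos(2 * np.pi * d[m] / 10.0)
    return w, phase


def simulate_damage_reads(
    genome: Genome,
    config: SimConfig,
    timepoints: Optional[Sequence[str]] = None,
    peaks: Sequence[GenomicInterval] = (),
    dyads: Sequence[GenomicInterval] = (),
) -> Tuple[Dict[str, List[ReadAlignment]], Dict[str, List[ReadAlignment]], SimTruth]:
    """Simulate Damage-seq reads per timepoint plus control tracks.

    Lesions are planted at dipyrimidine dinucleotides (both strands)
    with density modulated by a planted cosine around peak summits
    (nucleosome repeat period) and dyads (helical-turn period) and a
    central dip at summits. Each surviving lesion emits one read on the
    lesion strand whose 5' end is exactly 2 nt downstream of the lesion
    dinucleotide, the exact inverse of the damage-window inference.
    Later timepoints subsample lesions with linker-preferential
    survival, sharpening the periodic pattern.

    Returns (reads per timepoint, control reads {"mock", "naked"},
    truth). ``config.noise_lesion_fraction`` of lesions are planted at
    non-dipyrimidine dinucleotides to exercise filter rejection.
    """
    if timepoints is None:
        timepoints = list(config.timepoint_decay)
    for t in timepoints:
        if t not in config.timepoint_decay:
            raise ValueError(f"no survival fraction for timepoint {t!r}")
    if any(a > 0 for a in config.periodic_amplitudes.values()) and not (
        peaks or dyads
    ):
        raise ValueError("periodic amplitudes set but no peaks/dyads given")
    rng = np.random.default_rng(config.seed + 2)

    # candidate lesion sites: dipyrimidine dinucleotide starts, both strands
    cand_rows = []
    for chrom in genome:
        codes = genome.codes(chrom)
        for strand in "+-":
            pos = _dipyrimidine_starts(codes, strand)
            # need room for the 10-nt window and the emitted read
            L = config.damage_read_length
            lo = max(6, L)
            hi = genome.chrom_sizes[chrom] - max(6, L) - 2
            pos = pos[(pos >= lo) & (pos <= hi)]
            w, phase = _lesion_weights(pos, chrom, peaks, dyads, config)
            cand_rows.append((chrom, strand, pos, w, phase))

    chroms = [r[0] for r in cand_rows]
    all_w = np.concatenate([r[3] for r in cand_rows])
    if all_w.sum() <= 0:
        raise ValueError("no candidate lesion sites")
    probs = all_w / all_w.sum()
    n = config.n_reads
    pick = rng.choice(len(probs), size=n, p=probs)

    offsets = np.concatenate(
        [np.full(len(r[2]), i) for i, r in enumerate(cand_rows)]
    )
    flat_pos = np.concatenate([r[2] for r in cand_rows])
    flat_phase = np.concatenate([r[4] for r in cand_rows])
    les_group = offsets[pick]
    les_pos = flat_pos[pick].astype(np.int64)
    les_phase = flat_phase[pick]
    les_chrom = np.array([cand_rows[g][0] for g in les_group])
    les_strand = np.array([cand_rows[g][1] for g in les_group])
    is_dipy = np.ones(n, dtype=bool)

    # optional non-dipyrimidine noise lesions replacing a known fraction
    if config.noise_lesion_fraction > 0:
        n_noise = int(round(n * config.noise_lesion_fraction))
        idx = rng.choice(n, size=n_noise, replace=False)
        for chrom in genome:
            codes = genome.codes(chrom)
            rows = idx[les_chrom[idx] == chrom]
            for i in rows:
                strand = les_strand[i]
                # rejection-sample a non-dipyrimidine dinucleotide
                size = genome.chrom_sizes[chrom]
                L = config.damage_read_length
                lo, hi = max(6, L), size - max(6, L) - 2
                while True:
                    x = int(rng.integers(lo, hi + 1))
                    a, b = codes[x], codes[x + 1]
                    pyr = (
                        (a in _PYR and b in _PYR)
                        if strand == "+"
                        else (a in (0, 2) and b in (0, 2))
                    )
                    if not pyr:
                        break
                les_pos[i] = x
                is_dipy[i] = False
                les_phase[i] = 0.0

    # per-timepoint Bernoulli survival, linker-preferential repair:
    # linkers sit at the cosine troughs (phase = -1), so survival there
    # is reduced by the contrast factor
    survival = {}
    u = rng.random((len(timepoints), n))
    for ti, t in enumerate(timepoints):
        s = config.timepoint_decay[t]
        if s >= 1.0:
            survival[t] = np.ones(n, dtype=bool)
        else:
            rho = config.linker_survival_contrast
            p_i = s * (1.0 + rho * les_phase)
            p_i = np.clip(p_i, 0.0, 1.0)
            survival[t] = u[ti] < p_i

    Lr = config.damage_read_length
    reads_by_t: Dict[str, List[ReadAlignment]] = {}
    read_rows = []
    for t in timepoints:
        alive = np.nonzero(survival[t])[0]
        rl: List[ReadAlignment] = []
        for i in alive:
            d = int(les_pos[i])
            chrom = les_chrom[i]
            strand = les_strand[i]
            if strand == "+":
                iv = GenomicInterval(chrom, d + 2, d + 2 + Lr, "+")
            else:
                iv = GenomicInterval(chrom, d - Lr, d, "-")
            rl.append(ReadAlignment(iv, mapq=42, sample_id=f"damage_{t}"))
            read_rows.append(
                {"timepoint": t, "lesion_index": int(i), "read_index": len(rl) - 1}
            )
        reads_by_t[t] = rl

    # controls: mock = uniform random positions (no damage chemistry),
    # naked = dipyrimidine-weighted but chromatin-free (uniform over sites)
    controls: Dict[str, List[ReadAlignment]] = {"mock": [], "naked": []}
    names = list(genome)
    sizes = np.array([genome.chrom_sizes[c] for c in names], dtype=float)
    ci = rng.choice(len(names), size=n, p=sizes / sizes.sum())
    starts = (rng.random(n) * (sizes[ci] - Lr)).astype(np.int64)
    strands = rng.integers(0, 2, size=n)
    for j in range(n):
        iv = GenomicInterval(
            names[ci[j]], int(starts[j]), int(starts[j]) + Lr,
            "+" if strands[j] == 0 else "-",
        )
        controls["mock"].append(ReadAlignment(iv, mapq=42, sample_id="mock"))
    flat_n = len(flat_pos)
    pick_naked = rng.integers(0, flat_n, size=n)
    for j in range(n):
        g = offsets[pick_naked[j]]
        d = int(flat_pos[pick_naked[j]])
        chrom = cand_rows[g][0]
        strand = cand_rows[g][1]
        if strand == "+":
            iv = GenomicInterval(chrom, d + 2, d + 2 + Lr, "+")
        else:
            iv = GenomicInterval(chrom, d - Lr, d, "-")
        controls["naked"].append(ReadAlignment(iv, mapq=42, sample_id="naked"))

    lesions = pd.DataFrame(
        {
            "chrom": les_chrom,
            "start": les_pos,
            "strand": les_strand,
            "is_dipyrimidine": is_dipy,
            **{f"survives_{t}": survival[t] for t in timepoints},
        }
    )
    truth = SimTruth(
        lesions=lesions,
        reads=pd.DataFrame(read_rows),
        planted_periods=dict(config.periodic_amplitudes),
    )
    return reads_by_t, controls, truth


def simulate_signal_tracks(
    n_bins: int,
    n_samples: int,
    class_profiles: np.ndarray,
    noise_sd: float,
    seed: int = 0,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Per-sample binned signals = class profile + iid Gaussian noise.

    ``class_profiles`` is (n_classes, n_bins); samples are assigned to
    classes round-robin. Returns (bins x samples DataFrame, true class
    labels). Deterministic under ``seed``.
    """
    profiles = np.asarray(class_profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[1] != n_bins:
        raise ValueError("class_profiles must be (n_classes, n_bins)")
    n_classes = profiles.shape[0]
    if n_classes >= 2 and any(
        np.allclose(profiles[i], profiles[j])
        for i in range(n_classes)
        for j in range(i + 1, n_classes)
    ):
        raise ValueError("class profiles must be distinct")
    rng = np.random.default_rng(seed)
    labels = np.arange(n_samples) % n_classes
    data = profiles[labels] + rng.normal(0.0, noise_sd, size=(n_samples, n_bins))
    df = pd.DataFrame(
        data.T,
        index=[f"bin{i}" for i in range(n_bins)],
        columns=[f"s{j}_c{labels[j]}" for j in range(n_samples)],
    )
    return df, labels
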
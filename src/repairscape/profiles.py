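"""Binned-profile computation and the associated statistics.

This module carries the quantitative backbone of the analysis: tiling
the genome into fixed windows and counting stranded reads with a
minimum-overlap rule, Spearman/Ward clustering of binned signal,
gene-anchored TS/NTS metaprofiles with expression stratification,
peak/dyad-centered stranded profiles with plus-strand reorientation,
the mock/naked/simulation normalization chains, and the paired /
unpaired Wilcoxon comparisons with Benjamini-Hochberg correction.

Strand conventions: for repair reads, the transcribed strand (TS)
signal of a gene is carried by reads mapping OPPOSITE the gene's strand
(the excised oligonucleotide lies on the damaged, repaired strand), and
the non-transcribed strand (NTS) by same-strand reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .core import GeneModel, GenomicInterval, ReadAlignment

__all__ = [
    "BinnedSignal",
    "CountMatrix",
    "StratifiedGroups",
    "ClusterResult",
    "MetaprofileResult",
    "PeakProfileResult",
    "genome_bins",
    "count_in_bins",
    "cluster_samples",
    "select_genes",
    "stratify",
    "gene_metaprofile",
    "compare_strands",
    "peak_profile",
    "orient_plus_reversed",
    "normalize_chain",
    "classify_peaks",
    "tertile_boxstats",
    "tpm_from_counts",
    "rpkm_from_counts",
    "rpm_from_counts",
]

_EPS = 1e-9


@dataclass
class BinnedSignal:
    """A per-region binned signal vector.

    ``values`` has length N; ``bin_size`` is in bp (may be fractional in
    scale-region mode). ``rel_starts`` gives each bin's start in bp
    relative to the anchor point, in the stored (possibly oriented) bin
    order. ``strand_oriented`` is set once plus-strand bin order has
    been reversed so transcription reads left to right. Missing bins
    are NaN.
    """

    values: np.ndarray
    bin_size: float
    region_id: str = ""
    anchor: Optional[GenomicInterval] = None
    rel_starts: Optional[np.ndarray] = None
    strand_oriented: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("values must be a non-empty 1-D vector")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.rel_starts is not None:
            self.rel_starts = np.asarray(self.rel_starts, dtype=float)
            if len(self.rel_starts) != len(self.values):
                raise ValueError("rel_starts must parallel values")

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclass
class CountMatrix:
    """Regions x samples matrix with a units tag and library sizes."""

    df: pd.DataFrame
    units: str = "raw"  # raw | RPM | RPKM | TPM
    library_sizes: Dict[str, int] = field(default_factory=dict)

    def to_rpm(self) -> "CountMatrix":
        if self.units != "raw":
            raise ValueError("RPM conversion starts from raw counts")
        out = self.df.copy().astype(float)
        for col in out.columns:
            lib = self.library_sizes.get(col)
            if not lib:
                raise ValueError(f"no library size for sample {col!r}")
            out[col] = out[col] * 1e6 / lib
        return CountMatrix(out, units="RPM", library_sizes=dict(self.library_sizes))


@dataclass
class StratifiedGroups:
    """A partition of ranked items into near-equal groups (ascending key)."""

    item_ids: np.ndarray        # retained items, ranked order
    labels: np.ndarray          # group index 0..n_groups-1 per retained item
    n_groups: int
    dropped_zero: int = 0
    dropped_top: int = 0

    def members(self, group: int) -> np.ndarray:
        return self.item_ids[self.labels == group]


def genome_bins(
    chrom_sizes: Mapping[str, int], width: int = 2000
) -> List[GenomicInterval]:
    """Non-overlapping consecutive bins tiling each chromosome; the
    terminal partial bin is retained."""
    if width <= 0:
        raise ValueError("width must be positive")
    out: List[GenomicInterval] = []
    for chrom, size in chrom_sizes.items():
        for s in range(0, size, width):
            out.append(GenomicInterval(chrom, s, min(s + width, size), "."))
    return out


def _strand_ok(read_strand: str, region_strand: str, mode: str) -> bool:
    if mode == "any":
        return True
    if region_strand not in ("+", "-"):
        raise ValueError("unstranded regions with strand_mode != 'any'")
    if read_strand not in ("+", "-"):
        return False
    if mode == "same":
        return read_strand == region_strand
    if mode == "opposite":
        return read_strand != region_strand
    raise ValueError(f"unknown strand_mode {mode!r}")


def count_in_bins(
    reads: Sequence[ReadAlignment],
    regions: Sequence[GenomicInterval],
    strand_mode: str = "any",
    min_overlap_fraction: float = 0.5,
    normalize: str = "raw",
    library_size: Optional[int] = None,
) -> np.ndarray:
    """Count reads per region under the minimum-overlap rule.

    A read is counted in a region when at least ``min_overlap_fraction``
    of the READ lies inside it (boundary inclusive: exactly half of a
    24-nt read overlapping counts). ``strand_mode='opposite'`` counts
    reads whose strand differs from the region's (TS for repair reads
    over genes), ``'same'`` counts matching strands (NTS). Regions are
    assumed non-overlapping within the track. ``normalize='RPM'``
    rescales by 1e6 / library size (default: number of reads given).
    """
    if strand_mode not in ("any", "same", "opposite"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if strand_mode != "any":
        for reg in regions:
            if reg.strand not in ("+", "-"):
                raise ValueError(
                    "unstranded regions require strand_mode='any'"
                )
    counts = np.zeros(len(regions), dtype=float)
    by_chrom: Dict[str, List[int]] = {}
    for j, reg in enumerate(regions):
        by_chrom.setdefault(reg.chrom, []).append(j)
    index: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, idx in by_chrom.items():
        idx_arr = np.array(idx)
        starts = np.array([regions[j].start for j in idx])
        order = np.argsort(starts, kind="stable")
        idx_arr = idx_arr[order]
        starts = starts[order]
        ends = np.array([regions[j].end for j in idx_arr])
        index[chrom] = (idx_arr, starts, ends)
    for r in reads:
        entry = index.get(r.chrom)
        if entry is None:
            continue
        idx_arr, starts, ends = entry
        lo = np.searchsorted(starts, r.end, side="left")
        need = min_overlap_fraction * r.read_length - _EPS
        # walk left from lo over candidates that may still overlap
        j = lo - 1
        while j >= 0:
            reg_idx = idx_arr[j]
            reg = regions[reg_idx]
            if ends[j] <= r.start:
                # non-overlapping sorted regions: nothing further left overlaps
                break
            ov = min(r.end, ends[j]) - max(r.start, starts[j])
            if ov >= need and _strand_ok(r.strand, reg.strand, strand_mode):
                counts[reg_idx] += 1
            j -= 1
    if normalize == "RPM":
        lib = library_size if library_size is not None else len(reads)
        if lib <= 0:
            raise ValueError("library size must be positive for RPM")
        counts = counts * 1e6 / lib
    elif normalize != "raw":
        raise ValueError(f"unknown normalize {normalize!r}")
    return counts


def _count_regular(
    reads: Sequence[ReadAlignment],
    chrom: str,
    origin: int,
    bin_size: float,
    n_bins: int,
    region_strand: str,
    strand_mode: str,
    min_overlap_fraction: float = 0.5,
) -> np.ndarray:
    """Vectorised counting into a regular bin grid starting at ``origin``."""
    counts = np.zeros(n_bins, dtype=float)
    span = bin_size * n_bins
    rs, re_, keep = [], [], []
    for r in reads:
        if r.chrom != chrom:
            continue
        if strand_mode != "any" and not _strand_ok(
            r.strand, region_strand, strand_mode
        ):
            continue
        if r.end <= origin or r.start >= origin + span:
            continue
        rs.append(r.start)
        re_.append(r.end)
    if not rs:
        return counts
    starts = np.array(rs, dtype=float) - origin
    ends = np.array(re_, dtype=float) - origin
    widths = ends - starts
    j0 = np.maximum(np.floor(starts / bin_size).astype(int), 0)
    j1 = np.minimum(np.ceil(ends / bin_size).astype(int) - 1, n_bins - 1)
    max_span = int((j1 - j0).max()) + 1
    need = min_overlap_fraction * widths - _EPS
    for k in range(max_span):
        j = j0 + k
        valid = j <= j1
        if not valid.any():
            break
        b0 = j * bin_size
        ov = np.minimum(ends, b0 + bin_size) - np.maximum(starts, b0)
        hit = valid & (ov >= need)
        np.add.at(counts, j[hit], 1)
    return counts


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    sample_names: List[str]
    distance: pd.DataFrame  # 1 - Spearman rho

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster labels (1..k) from cutting the dendrogram."""
        return fcluster(self.linkage_matrix, t=k, criterion="maxclust")


def cluster_samples(matrix: CountMatrix | pd.DataFrame) -> ClusterResult:
    """Hierarchical clustering of samples over binned signal.

    Distance = 1 - pairwise Spearman correlation of the per-bin values;
    linkage = Ward. Deterministic. A constant (zero-variance) sample has
    no rank correlation and raises, naming the sample.
    """
    df = matrix.df if isinstance(matrix, CountMatrix) else matrix
    if df.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if df.shape[0] < 3:
        raise ValueError("need at least 3 bins")
    for col in df.columns:
        if df[col].nunique() <= 1:
            raise ValueError(f"sample {col!r} is constant (zero variance)")
    rho = df.corr(method="spearman").to_numpy()
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="ward")
    ddf = pd.DataFrame(dist, index=df.columns, columns=df.columns)
    return ClusterResult(Z, list(df.columns), ddf)


def select_genes(
    genes: Sequence[GeneModel], min_length: int = 2000, min_gap: int = 500
) -> List[GeneModel]:
    """Keep genes longer than ``min_length`` whose distance to the
    nearest other gene (any strand) is at least ``min_gap``."""
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    kept: List[GeneModel] = []
    for chrom, gl in by_chrom.items():
        gl_sorted = sorted(gl, key=lambda g: (g.start, g.end))
        n = len(gl_sorted)
        starts = np.array([g.start for g in gl_sorted])
        ends = np.array([g.end for g in gl_sorted])
        # nearest gap left: start_i - max(end_j, j<i); right: start_{i+1} - end_i
        prefix_max_end = np.maximum.accumulate(ends)
        for i, g in enumerate(gl_sorted):
            if g.length <= min_length:
                continue
            gap = np.inf
            if i > 0:
                gap = min(gap, starts[i] - prefix_max_end[i - 1])
            if i < n - 1:
                gap = min(gap, starts[i + 1] - ends[i])
            if gap >= min_gap:
                kept.append(g)
    order = {id(g): k for k, g in enumerate(genes)}
    kept.sort(key=lambda g: order[id(g)])
    return kept


def stratify(
    item_ids: Sequence[str],
    key_values: Sequence[float],
    n_groups: int,
    exclude_zero: bool = False,
    trim_top_fraction: float = 0.0,
) -> StratifiedGroups:
    """Rank items by key and split into ``n_groups`` near-equal groups.

    Optionally drop zero-key items first and/or the top
    ``trim_top_fraction`` by key (outlier control). Ranking is
    ascending and stable with ties broken by item id (lexicographic),
    so group 0 is the lowest-key group. Group sizes differ by at most
    one; the extra items go to the lowest groups.
    """
    ids = np.asarray(item_ids)
    keys = np.asarray(key_values, dtype=float)
    if len(ids) != len(keys):
        raise ValueError("item_ids and key_values must be parallel")
    dropped_zero = 0
    if exclude_zero:
        m = keys != 0
        dropped_zero = int((~m).sum())
        ids, keys = ids[m], keys[m]
    order = np.lexsort((ids, keys))
    ids, keys = ids[order], keys[order]
    dropped_top = 0
    if trim_top_fraction > 0:
        dropped_top = int(np.floor(len(ids) * trim_top_fraction + _EPS))
        if dropped_top:
            ids, keys = ids[:-dropped_top], keys[:-dropped_top]
    if len(ids) < n_groups:
        raise ValueError(
            f"{len(ids)} items cannot form {n_groups} groups"
        )
    labels = np.zeros(len(ids), dtype=int)
    for gi, chunk in enumerate(np.array_split(np.arange(len(ids)), n_groups)):
        labels[chunk] = gi
    return StratifiedGroups(
        item_ids=ids,
        labels=labels,
        n_groups=n_groups,
        dropped_zero=dropped_zero,
        dropped_top=dropped_top,
    )


@dataclass
class MetaprofileResult:
    per_gene: pd.DataFrame     # genes x bins, oriented 5'->3'
    mean: np.ndarray
    ci95: np.ndarray           # half-width: 1.96 * SEM
    bin_size: float
    skipped: int


def gene_metaprofile(
    reads: Sequence[ReadAlignment],
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    anchor: str = "TSS",
    upstream: int = 1000,
    downstream: int = 500,
    n_bins: int = 100,
    strand_mode: str = "opposite",
    min_overlap_fraction: float = 0.5,
) -> MetaprofileResult:
    """Average read profile around gene anchors, oriented 5'->3'.

    The window spans ``upstream`` bp before to ``downstream`` bp after
    the anchor (TSS or TES), in transcription direction, split into
    ``n_bins`` bins. ``strand_mode='opposite'`` gives the TS profile of
    repair reads, ``'same'`` the NTS. Genes whose window leaves the
    chromosome are skipped and counted.
    """
    if anchor not in ("TSS", "TES"):
        raise ValueError("anchor must be 'TSS' or 'TES'")
    span = upstream + downstream
    if span % n_bins != 0:
        raise ValueError("upstream + downstream must be divisible by n_bins")
    b = span / n_bins
    rows = []
    ids = []
    skipped = 0
    for g in genes:
        apos = g.tss if anchor == "TSS" else g.tes
        if g.strand == "+":
            origin = apos - upstream
        else:
            origin = apos - downstream + 1
        if origin < 0 or origin + span > chrom_sizes[g.chrom]:
            skipped += 1
            continue
        v = _count_regular(
            reads, g.chrom, origin, b, n_bins, g.strand, strand_mode,
            min_overlap_fraction,
        )
        if g.strand == "-":
            v = v[::-1]
        rows.append(v)
        ids.append(g.gene_id)
    if not rows:
        raise ValueError("no genes with an in-bounds window")
    mat = pd.DataFrame(np.vstack(rows), index=ids)
    mean = mat.to_numpy().mean(axis=0)
    sem = mat.to_numpy().std(axis=0, ddof=1) / np.sqrt(len(rows)) if len(rows) > 1 else np.zeros(n_bins)
    return MetaprofileResult(mat, mean, 1.96 * sem, b, skipped)


def compare_strands(
    ts_values: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    nts_values: Mapping[str, Mapping[str, float]] | pd.DataFrame = None,
    groups: Optional[Mapping[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Per-group TS/NTS comparison.

    ``ts_values`` / ``nts_values``: per-gene paired values (e.g. RPKM),
    as {gene_id: value} mappings or aligned Series. ``groups`` maps a
    group label (e.g. expression quartile) to its gene ids; without it
    a single group 'all' is used. For each group: the mean per-gene
    TS/(TS+NTS) fraction (genes with TS+NTS = 0 excluded and counted),
    the two-sided paired Wilcoxon signed-rank p for TS vs NTS, and the
    Benjamini-Hochberg q across the groups of this invocation.
    """
    ts = pd.Series(ts_values, dtype=float) if not isinstance(ts_values, pd.Series) else ts_values.astype(float)
    nts = pd.Series(nts_values, dtype=float) if not isinstance(nts_values, pd.Series) else nts_values.astype(float)
    common = ts.index.intersection(nts.index)
    ts, nts = ts[common], nts[common]
    if groups is None:
        groups = {"all": list(common)}
    rows = []
    for name, gids in groups.items():
        gids = [g for g in gids if g in common]
        t = ts[gids].to_numpy()
        u = nts[gids].to_numpy()
        tot = t + u
        informative = tot > 0
        frac = np.full(len(gids), np.nan)
        frac[informative] = t[informative] / tot[informative]
        diffs = t - u
        nonzero = diffs != 0
        if informative.sum() >= 2 and nonzero.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = sps.wilcoxon(
                    t, u, zero_method="wilcox", alternative="two-sided"
                )
        elif informative.sum() >= 2:
            p = 1.0  # TS identical to NTS everywhere
        else:
            p = np.nan
        rows.append(
            {
                "group": name,
                "n_genes": len(gids),
                "n_informative": int(informative.sum()),
                "n_excluded_zero_total": int((~informative).sum()),
                "mean_ts_fraction": float(np.nanmean(frac)) if informative.any() else np.nan,
                "median_ts_fraction": float(np.nanmedian(frac)) if informative.any() else np.nan,
                "wilcoxon_p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("group")
    mask = out["wilcoxon_p"].notna()
    q = np.full(len(out), np.nan)
    if mask.any():
        q[mask.to_numpy()] = multipletests(
            out.loc[mask, "wilcoxon_p"], method="fdr_bh"
        )[1]
    out["q_bh"] = q
    return out


@dataclass
class PeakProfileResult:
    """Per-strand anchor x bin count matrices around point anchors."""

    plus: pd.DataFrame
    minus: pd.DataFrame
    bin_size: float
    rel_starts: np.ndarray     # bin starts in bp relative to the anchor
    oriented: bool = False

    def mean_signal(self, strand: str) -> BinnedSignal:
        df = self.plus if strand == "+" else self.minus
        return BinnedSignal(
            values=df.to_numpy().mean(axis=0),
            bin_size=self.bin_size,
            region_id=f"mean_{strand}",
            rel_starts=self.rel_starts,
            strand_oriented=self.oriented,
        )


def _anchor_point(iv: GenomicInterval) -> int:
    return iv.start if iv.width == 1 else (iv.start + iv.end) // 2


def peak_profile(
    reads: Sequence[ReadAlignment],
    anchors: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    flank: int = 1000,
    n_bins: int = 201,
    mode: str = "fixed_bp",
    orient: bool = False,
    min_overlap_fraction: float = 0.5,
) -> PeakProfileResult:
    """Stranded binned profiles around peak summits / dyads.

    fixed_bp mode: anchors are points; the window holds ``n_bins`` bins
    of ``2*flank/(n_bins-1)`` bp with the central bin centered on the
    anchor (201 bins of 10 bp for summit +/-1 kb; 81 bins of 2 bp for
    dyad +/-80 bp). scale_region mode: anchors are intervals, extended
    ``flank`` bp both sides and divided into ``n_bins`` equal bins of
    region-dependent width.

    With ``orient=True`` the PLUS-strand bin order is reversed (the last
    bin plotted first) while minus-strand order is unchanged, so
    transcription reads left to right on both strands.
    """
    if mode not in ("fixed_bp", "scale_region"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "fixed_bp":
        if n_bins % 2 == 0:
            warnings.warn("even n_bins leaves no exact center bin")
        if (2 * flank) % (n_bins - 1) != 0:
            raise ValueError("2*flank must be divisible by n_bins - 1")
        b = (2 * flank) // (n_bins - 1)
        half = (n_bins * b) // 2
        rel_starts = np.arange(n_bins) * b - half
        plus_rows, minus_rows, ids = [], [], []
        for a in anchors:
            c = _anchor_point(a)
            origin = c - half
            if origin < 0 or origin + n_bins * b > chrom_sizes[a.chrom]:
                continue
            vp = _count_regular(
                reads, a.chrom, origin, b, n_bins, "+", "same",
                min_overlap_fraction,
            )
            vm = _count_regular(
                reads, a.chrom, origin, b, n_bins, "-", "same",
                min_overlap_fraction,
            )
            plus_rows.append(vp)
            minus_rows.append(vm)
            ids.append(f"{a.chrom}:{c}")
        if not ids:
            raise ValueError("no anchors with an in-bounds window")
        plus = pd.DataFrame(np.vstack(plus_rows), index=ids)
        minus = pd.DataFrame(np.vstack(minus_rows), index=ids)
        bsize: float = float(b)
    else:
        rel_starts = None  # variable geometry
        plus_rows, minus_rows, ids = [], [], []
        for a in anchors:
            origin = a.start - flank
            span = a.width + 2 * flank
            if origin < 0 or origin + span > chrom_sizes[a.chrom]:
                continue
            b = span / n_bins
            vp = _count_regular(
                reads, a.chrom, origin, b, n_bins, "+", "same",
                min_overlap_fraction,
            )
            vm = _count_regular(
                reads, a.chrom, origin, b, n_bins, "-", "same",
                min_overlap_fraction,
            )
            plus_rows.append(vp)
            minus_rows.append(vm)
            ids.append(f"{a.chrom}:{a.start}-{a.end}")
        if not ids:
            raise ValueError("no anchors with an in-bounds window")
        plus = pd.DataFrame(np.vstack(plus_rows), index=ids)
        minus = pd.DataFrame(np.vstack(minus_rows), index=ids)
        bsize = float(np.mean([a.width + 2 * flank for a in anchors]) / n_bins)
        rel_starts = np.arange(n_bins) * bsize - (n_bins * bsize) / 2

    res = PeakProfileResult(plus, minus, bsize, rel_starts, oriented=False)
    if orient:
        res = orient_plus_reversed(res)
    return res


def orient_plus_reversed(profile: PeakProfileResult) -> PeakProfileResult:
    """Reverse the plus-strand bin order (involution); minus unchanged."""
    plus = profile.plus.iloc[:, ::-1]
    plus.columns = profile.plus.columns
    return PeakProfileResult(
        plus=plus,
        minus=profile.minus,
        bin_size=profile.bin_size,
        rel_starts=profile.rel_starts,
        oriented=not profile.oriented,
    )


def _rolling_mean_nan(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean, truncated at the edges, NaN-aware
    (missing members are excluded from each window's mean)."""
    n = len(x)
    half = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        w = x[lo:hi]
        good = ~np.isnan(w)
        if good.any():
            out[i] = w[good].mean()
    return out


def normalize_chain(
    profile: BinnedSignal,
    mock_profile: Optional[BinnedSignal] = None,
    naked_profile: Optional[BinnedSignal] = None,
    sim_profile: Optional[BinnedSignal] = None,
    damage_profile: Optional[BinnedSignal] = None,
    smooth_window: int = 11,
    mode: str = "damage_full",
) -> Tuple[BinnedSignal, int]:
    """Apply the normalization chain and return (log2 signal, n masked).

    Modes (all inputs RPM-normalized, same binning):

    * ``damage_full``: x -> x/mock -> / mean(naked) -> / sim ->
      centered rolling mean (width ``smooth_window``, truncated at
      edges) -> log2.
    * ``xr_sim``: x -> / sim -> rolling mean -> log2.
    * ``xr_sim_damage``: additionally divides by ``damage_profile``
      (the simulation-normalized damage profile, linear scale) before
      smoothing, expressing repair relative to the local damage
      landscape.

    Bins with nonpositive denominators are masked (NaN), propagate as
    missing through the smoothing, and are counted in the return value.
    """
    x = profile.values.astype(float).copy()
    pre_missing = np.isnan(x)

    def _divide(num: np.ndarray, den_sig: BinnedSignal, what: str) -> np.ndarray:
        den = den_sig.values.astype(float)
        if len(den) != len(num):
            raise ValueError(f"{what} profile has different binning")
        if not np.any(np.nan_to_num(den) > 0):
            raise ValueError(f"{what} profile is entirely nonpositive")
        bad = ~(den > 0)
        out = np.full_like(num, np.nan)
        ok = ~bad & ~np.isnan(num)
        out[ok] = num[ok] / den[ok]
        return out

    if mode == "damage_full":
        if mock_profile is None or naked_profile is None or sim_profile is None:
            raise ValueError("damage_full needs mock, naked and sim profiles")
        x = _divide(x, mock_profile, "mock")
        naked_mean = np.nanmean(naked_profile.values.astype(float))
        if not naked_mean > 0:
            raise ValueError("naked profile mean is nonpositive")
        x = x / naked_mean
        x = _divide(x, sim_profile, "sim")
    elif mode in ("xr_sim", "xr_sim_damage"):
        if sim_profile is None:
            raise ValueError(f"{mode} needs a sim profile")
        x = _divide(x, sim_profile, "sim")
        if mode == "xr_sim_damage":
            if damage_profile is None:
                raise ValueError("xr_sim_damage needs a damage profile")
            x = _divide(x, damage_profile, "damage")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # nonpositive ratios cannot be logged; mask them before smoothing
    x[~(x > 0)] = np.nan
    n_masked = int(np.isnan(x).sum() - pre_missing.sum())
    if smooth_window > 1:
        x = _rolling_mean_nan(x, smooth_window)
    with np.errstate(invalid="ignore"):
        out = np.log2(x)
    return (
        BinnedSignal(
            values=out,
            bin_size=profile.bin_size,
            region_id=profile.region_id,
            anchor=profile.anchor,
            rel_starts=profile.rel_starts,
            strand_oriented=profile.strand_oriented,
        ),
        n_masked,
    )


def classify_peaks(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    tss_upstream: int = 200,
) -> List[str]:
    """Label each peak 'genic' when it overlaps any gene body extended
    ``tss_upstream`` bp upstream of its TSS (strand-aware), else
    'intergenic'."""
    extended: Dict[str, List[Tuple[int, int]]] = {}
    for g in genes:
        if g.strand == "+":
            s, e = max(0, g.start - tss_upstream), g.end
        else:
            s, e = g.start, g.end + tss_upstream
        extended.setdefault(g.chrom, []).append((s, e))
    labels = []
    for p in peaks:
        hit = any(
            p.start < e and s < p.end
            for s, e in extended.get(p.chrom, [])
        )
        labels.append("genic" if hit else "intergenic")
    return labels


def tertile_boxstats(
    values: pd.DataFrame,
    reference_timepoint: str,
    value_col: str = "value",
    group_col: str = "tertile",
    time_col: str = "timepoint",
    id_col: str = "bin_id",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Boxplot statistics and Wilcoxon tests for tertile-stratified
    normalized signal across a time course.

    Input: long DataFrame with one row per (bin, tertile, timepoint)
    value. Output: (box stats per tertile/timepoint with median, IQR
    and whiskers at the 12.5th/87.5th percentiles; tests table with
    paired Wilcoxon vs the reference timepoint within tertile, unpaired
    Wilcoxon rank-sum between tertiles per timepoint, and BH-adjusted q
    across every test of this invocation). Percentiles use linear
    interpolation between closest ranks. Groups with < 2 values get
    missing stats.
    """
    box_rows = []
    test_rows = []
    tertiles = sorted(values[group_col].unique())
    timepoints = list(pd.unique(values[time_col]))
    for g in tertiles:
        sub_g = values[values[group_col] == g]
        ref = sub_g[sub_g[time_col] == reference_timepoint].set_index(id_col)[
            value_col
        ]
        for t in timepoints:
            sub = sub_g[sub_g[time_col] == t]
            v = sub[value_col].dropna().to_numpy()
            if len(v) < 2:
                box_rows.append(
                    {group_col: g, time_col: t, "n": len(v), "median": np.nan,
                     "q25": np.nan, "q75": np.nan, "whisker_lo": np.nan,
                     "whisker_hi": np.nan}
                )
                continue
            box_rows.append(
                {
                    group_col: g,
                    time_col: t,
                    "n": len(v),
                    "median": float(np.median(v)),
                    "q25": float(np.percentile(v, 25)),
                    "q75": float(np.percentile(v, 75)),
                    "whisker_lo": float(np.percentile(v, 12.5)),
                    "whisker_hi": float(np.percentile(v, 87.5)),
                }
            )
            if t != reference_timepoint and len(ref) >= 2:
                cur = sub.set_index(id_col)[value_col]
                common = ref.index.intersection(cur.index)
                a = ref[common].to_numpy()
                b = cur[common].to_numpy()
                ok = ~np.isnan(a) & ~np.isnan(b)
                if ok.sum() >= 2 and np.any(a[ok] != b[ok]):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        _, p = sps.wilcoxon(
                            a[ok], b[ok], zero_method="wilcox",
                            alternative="two-sided",
                        )
                elif ok.sum() >= 2:
                    p = 1.0
                else:
                    p = np.nan
                test_rows.append(
                    {"kind": "paired_vs_reference", "tertile": g,
                     "timepoint": t, "other": reference_timepoint, "p": p}
                )
    for t in timepoints:
        sub_t = values[values[time_col] == t]
        for i in range(len(tertiles)):
            for j in range(i + 1, len(tertiles)):
                a = sub_t[sub_t[group_col] == tertiles[i]][value_col].dropna()
                b = sub_t[sub_t[group_col] == tertiles[j]][value_col].dropna()
                if len(a) >= 2 and len(b) >= 2:
                    _, p = sps.mannwhitneyu(a, b, alternative="two-sided")
                else:
                    p = np.nan
                test_rows.append(
                    {"kind": "between_tertiles", "tertile": tertiles[i],
                     "timepoint": t, "other": tertiles[j], "p": p}
                )
    tests = pd.DataFrame(test_rows)
    if len(tests):
        mask = tests["p"].notna()
        q = np.full(len(tests), np.nan)
        if mask.any():
            q[mask.to_numpy()] = multipletests(
                tests.loc[mask, "p"], method="fdr_bh"
            )[1]
        tests["q_bh"] = q
    return pd.DataFrame(box_rows), tests


def tpm_from_counts(
    counts: np.ndarray | Sequence[float], lengths_bp: np.ndarray | Sequence[float]
) -> np.ndarray:
    """Transcripts per million: rate_i = counts_i / length_i(kb);
    TPM_i = rate_i * 1e6 / sum(rate)."""
    c = np.asarray(counts, dtype=float)
    L = np.asarray(lengths_bp, dtype=float)
    if np.any(L <= 0):
        raise ValueError("gene lengths must be positive")
    rate = c / (L / 1000.0)
    total = rate.sum()
    if total == 0:
        warnings.warn("all-zero counts give all-zero TPM")
        return np.zeros_like(rate)
    return rate * 1e6 / total


def rpkm_from_counts(
    counts: np.ndarray | Sequence[float],
    lengths_bp: np.ndarray | Sequence[float],
    library_size: int,
) -> np.ndarray:
    """RPKM = (reads / gene length in kb) / (total mapped reads / 1e6)."""
    c = np.asarray(counts, dtype=float)
    L = np.asarray(lengths_bp, dtype=float)
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return (c / (L / 1000.0)) / (library_size / 1e6)


def rpm_from_counts(
    counts: np.ndarray | Sequence[float], library_size: int
) -> np.ndarray:
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / library_size
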
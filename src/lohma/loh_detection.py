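"""LOH tract calling, filtering, classification and summary geometry.

A loss-of-heterozygosity (LOH) tract is a maximal run of consecutive
parental-heterozygous SNPs that a mutation-accumulation line has fixed to
the same parent.  Tracts supported by at least ``min_support`` SNPs
(default 3) are retained.  Tracts are then

* de-duplicated across an environment's lines (a tract with identical
  start and end in *every* line is treated as a systematic genotyping
  artifact and removed),
* classified by extent (interstitial vs terminal, via a 20 kb telomere
  window), by size class (short / medium / long / super-long at 1, 10 and
  100 kb), and by probable mechanism (copy-neutral recombination vs
  deletion, from normalized allele-specific coverage).

Tract extent is measured from the first to the last supporting SNP (the
conservative inner bound).  An optional midpoint-extension mode grows each
end to the midpoint between the boundary SNP and the nearest flanking
heterozygous SNP (or the chromosome end when none exists).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd

from .genotype_io import GT, PARENT_S, PARENT_Y, ChromInfo, SnpMap

#: diploid genome size (bp) used for rates and coverage percentages
GENOME_SIZE_BP = 24.04e6
#: telomere window defining terminal tracts
TELOMERE_WINDOW_BP = 20_000
DEFAULT_MIN_SUPPORT = 3


class Extent(str, Enum):
    INTERSTITIAL = "INTERSTITIAL"
    TERMINAL = "TERMINAL"


class SizeClass(str, Enum):
    SHORT = "SHORT"
    MEDIUM = "MEDIUM"
    LONG = "LONG"
    SUPER_LONG = "SUPER_LONG"


class Mechanism(str, Enum):
    RECOMBINATION = "RECOMBINATION"
    DELETION = "DELETION"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class LohTract:
    """One called LOH event in one line."""

    line_id: str
    chrom: str
    start: int  # bp of first supporting SNP (or extended bound), 1-based
    end: int  # bp of last supporting SNP (or extended bound)
    n_supporting_snps: int
    parent: str  # PARENT_S | PARENT_Y
    extent: Extent | None = None
    size_class: SizeClass | None = None
    mechanism: Mechanism | None = None
    snp_start: int | None = None  # first/last supporting SNP, kept under extension
    snp_end: int | None = None
    centromere_distance: int | None = None
    telomere_distance: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("tract start > end")
        if self.snp_start is None:
            self.snp_start = self.start
        if self.snp_end is None:
            self.snp_end = self.end

    @property
    def size(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# Tract calling
# ---------------------------------------------------------------------------

def call_tracts(
    states: np.ndarray,
    snp_map: SnpMap,
    line_id: str = "line",
    min_support: int = DEFAULT_MIN_SUPPORT,
    extend_to_midpoints: bool = False,
) -> list[LohTract]:
    """Call LOH tracts from one line's genotype states.

    A tract is a maximal run of consecutive map SNPs all fixed to the same
    parent with at least ``min_support`` supporting SNPs.  A heterozygous
    SNP terminates a run; MISSING SNPs inside a run neither break it nor
    count toward support.

    Parameters
    ----------
    states
        int8 array of :class:`~lohma.genotype_io.GT` values aligned to
        ``snp_map`` row order.
    extend_to_midpoints
        Grow each tract end to the midpoint between the boundary SNP and
        the nearest flanking HET SNP on the same chromosome (chromosome
        boundaries clip the extension).  Supporting-SNP coordinates are
        kept in ``snp_start``/``snp_end``.
    """
    states = np.asarray(states)
    if states.shape != (snp_map.n_snps,):
        raise ValueError("states not aligned to snp_map")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")

    tracts: list[LohTract] = []
    for chrom in snp_map.chroms:
        sl = snp_map.chrom_slice(chrom)
        sub = states[sl]
        pos = snp_map.positions(chrom)
        observed = sub != GT.MISSING
        obs_idx = np.flatnonzero(observed)
        if obs_idx.size == 0:
            continue
        vals = sub[obs_idx]
        # run boundaries over the observed (non-missing) genotypes
        breaks = np.flatnonzero(vals[1:] != vals[:-1]) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [vals.size]))
        for a, b in zip(starts, ends):
            state = vals[a]
            if state == GT.HET:
                continue
            n = int(b - a)
            if n < min_support:
                continue
            first = int(obs_idx[a])
            last = int(obs_idx[b - 1])
            parent = PARENT_S if state == GT.S_HOM else PARENT_Y
            start_bp = int(pos[first])
            end_bp = int(pos[last])
            if extend_to_midpoints:
                het_obs = obs_idx[vals == GT.HET]
                left_het = het_obs[het_obs < first]
                right_het = het_obs[het_obs > last]
                ext_start = (
                    (int(pos[left_het[-1]]) + start_bp) // 2 + 1
                    if left_het.size
                    else 1
                )
                ext_end = (
                    (end_bp + int(pos[right_het[0]])) // 2 if right_het.size else end_bp
                )
                tracts.append(
                    LohTract(
                        line_id, chrom, ext_start, ext_end, n, parent,
                        snp_start=start_bp, snp_end=end_bp,
                    )
                )
            else:
                tracts.append(LohTract(line_id, chrom, start_bp, end_bp, n, parent))
    return tracts


def filter_recurrent_tracts(
    tracts: list[LohTract],
    line_ids: list[str],
    require_all_lines: bool = True,
    min_shared_lines: int = 2,
) -> tuple[list[LohTract], int]:
    """Drop tracts recurring at identical coordinates across an environment.

    Default rule: a (chrom, start, end) key present in *every* line of the
    environment is removed from all lines.  ``require_all_lines=False``
    switches to a stricter mode removing keys shared by at least
    ``min_shared_lines`` lines.  Single-line environments are left
    untouched (every tract would trivially be "in all lines").

    Returns the surviving tracts and the number removed.
    """
    n_lines = len(set(line_ids))
    if n_lines < 2:
        return list(tracts), 0
    lines_by_key: dict[tuple[str, int, int], set[str]] = {}
    for t in tracts:
        lines_by_key.setdefault((t.chrom, t.start, t.end), set()).add(t.line_id)
    threshold = n_lines if require_all_lines else min_shared_lines
    bad = {k for k, lines in lines_by_key.items() if len(lines) >= threshold}
    kept = [t for t in tracts if (t.chrom, t.start, t.end) not in bad]
    return kept, len(tracts) - len(kept)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_extent(
    tract: LohTract,
    chrom_info: ChromInfo,
    telomere_window: int = TELOMERE_WINDOW_BP,
) -> Extent:
    """Interstitial vs terminal, via supporting-SNP proximity to chromosome ends.

    TERMINAL if at least one supporting-SNP boundary lies within
    ``telomere_window`` of either chromosome end; tracts entirely inside
    the window are also TERMINAL (they reach the chromosome end region).
    Otherwise INTERSTITIAL.
    """
    length = chrom_info.length(tract.chrom)
    lo, hi = tract.snp_start, tract.snp_end

    def near_end(p: int) -> bool:
        return p <= telomere_window or p > length - telomere_window

    return Extent.TERMINAL if (near_end(lo) or near_end(hi)) else Extent.INTERSTITIAL


def size_class(size_bp: int) -> SizeClass:
    """Half-open, lower-inclusive size bands at 1 kb / 10 kb / 100 kb."""
    if size_bp < 1:
        raise ValueError("tract size must be >= 1 bp")
    if size_bp < 1_000:
        return SizeClass.SHORT
    if size_bp < 10_000:
        return SizeClass.MEDIUM
    if size_bp < 100_000:
        return SizeClass.LONG
    return SizeClass.SUPER_LONG


def classify_mechanism(
    tract: LohTract,
    snp_map: SnpMap,
    s_depth: np.ndarray,
    y_depth: np.ndarray,
    genome_mean_depth: float,
) -> Mechanism:
    """Copy-neutral recombination vs deletion from allele-specific coverage.

    Normalized coverage of each allele = mean allele depth over the
    tract's supporting SNPs / genome-wide mean total (S+Y) depth.
    DELETION if the retained (fixed-parent) allele is in [0.4, 0.6] and
    the lost allele <= 0.1; everything else with usable depth is
    RECOMBINATION; UNCLASSIFIED when no depth covers the tract.
    """
    if genome_mean_depth <= 0:
        raise ValueError("genome-wide mean depth must be positive")
    sl = snp_map.chrom_slice(tract.chrom)
    pos = snp_map.positions(tract.chrom)
    in_tract = (pos >= tract.snp_start) & (pos <= tract.snp_end)
    s = np.asarray(s_depth, dtype=float)[sl][in_tract]
    y = np.asarray(y_depth, dtype=float)[sl][in_tract]
    ok = ~(np.isnan(s) | np.isnan(y))
    if not ok.any():
        return Mechanism.UNCLASSIFIED
    s_norm = float(s[ok].mean()) / genome_mean_depth
    y_norm = float(y[ok].mean()) / genome_mean_depth
    retained, lost = (s_norm, y_norm) if tract.parent == PARENT_S else (y_norm, s_norm)
    if 0.4 <= retained <= 0.6 and lost <= 0.1:
        return Mechanism.DELETION
    return Mechanism.RECOMBINATION


def tract_distances(tract: LohTract, chrom_info: ChromInfo) -> tuple[int, int]:
    """(centromere distance, telomere distance) in bp.

    Centromere distance is the minimum over tract endpoints of the
    distance to the centromere midpoint, 0 if the tract spans it.
    Telomere distance is min(start - 1, length - end).
    """
    cen = chrom_info.centromere(tract.chrom)
    length = chrom_info.length(tract.chrom)
    if tract.start <= cen <= tract.end:
        cen_dist = 0
    else:
        cen_dist = min(abs(tract.start - cen), abs(tract.end - cen))
    tel_dist = min(tract.start - 1, length - tract.end)
    return cen_dist, tel_dist


def annotate_tracts(
    tracts: list[LohTract],
    chrom_info: ChromInfo,
    snp_map: SnpMap | None = None,
    s_depth: np.ndarray | None = None,
    y_depth: np.ndarray | None = None,
    genome_mean_depth: float | None = None,
    telomere_window: int = TELOMERE_WINDOW_BP,
) -> list[LohTract]:
    """Fill extent, size class, mechanism and distances for every tract."""
    out = []
    for t in tracts:
        cen_d, tel_d = tract_distances(t, chrom_info)
        mech = None
        if snp_map is not None and s_depth is not None and genome_mean_depth:
            mech = classify_mechanism(t, snp_map, s_depth, y_depth, genome_mean_depth)
        out.append(
            replace(
                t,
                extent=classify_extent(t, chrom_info, telomere_window),
                size_class=size_class(t.size),
                mechanism=mech,
                centromere_distance=cen_d,
                telomere_distance=tel_d,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Maps and summaries
# ---------------------------------------------------------------------------

def loh_map(
    tracts: list[LohTract], chrom_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Per-position (1 bp bin) LOH tract counts for each chromosome.

    ``map[chrom][p - 1]`` is the number of tracts covering position p, so
    the sum over all positions equals the summed tract sizes.
    """
    counts = {c: np.zeros(length, dtype=np.int32) for c, length in chrom_lengths.items()}
    for t in tracts:
        arr = counts.get(t.chrom)
        if arr is None:
            raise KeyError(f"tract on unknown chromosome {t.chrom!r}")
        if t.end > arr.size:
            raise ValueError(f"tract end {t.end} beyond {t.chrom} length {arr.size}")
        arr[t.start - 1 : t.end] += 1
    return counts


def snp_density(
    snp_map: SnpMap, chrom_lengths: dict[str, int], bin_bp: int = 100
) -> dict[str, np.ndarray]:
    """Per-bin SNP counts (default 100 bp bins) for each chromosome."""
    out = {}
    for chrom, length in chrom_lengths.items():
        n_bins = -(-length // bin_bp)
        pos = snp_map.positions(chrom)
        out[chrom] = np.bincount((pos - 1) // bin_bp, minlength=n_bins).astype(np.int32)
    return out


@dataclass
class LineSummary:
    """Per-line LOH burden statistics."""

    line_id: str
    n_tracts: int
    pct_genome_covered: float
    pct_snps_fixed: float
    loh_rate_per_generation: float
    mean_tract_size: float
    median_tract_size: float


def line_summary(
    tracts: list[LohTract],
    snp_map: SnpMap,
    states: np.ndarray,
    generations: float,
    genome_size: float = GENOME_SIZE_BP,
    line_id: str = "line",
) -> LineSummary:
    """Per-line summary: count, % genome covered, % SNPs fixed, rate, sizes."""
    if generations <= 0:
        raise ValueError("generations must be positive")
    states = np.asarray(states)
    sizes = np.array([t.size for t in tracts], dtype=float)
    n_fixed = int(np.isin(states, [GT.S_HOM, GT.Y_HOM]).sum())
    n_snps = snp_map.n_snps
    return LineSummary(
        line_id=line_id,
        n_tracts=len(tracts),
        pct_genome_covered=100.0 * float(sizes.sum()) / genome_size,
        pct_snps_fixed=(100.0 * n_fixed / n_snps) if n_snps else 0.0,
        loh_rate_per_generation=len(tracts) / generations,
        mean_tract_size=float(sizes.mean()) if sizes.size else 0.0,
        median_tract_size=float(np.median(sizes)) if sizes.size else 0.0,
    )


def tracts_to_frame(tracts: list[LohTract]) -> pd.DataFrame:
    """Flatten tracts into a DataFrame (one row per tract, all fields)."""
    rows = []
    for t in tracts:
        rows.append(
            {
                "line_id": t.line_id,
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "size": t.size,
                "n_supporting_snps": t.n_supporting_snps,
                "parent": t.parent,
                "extent": None if t.extent is None else t.extent.value,
                "size_class": None if t.size_class is None else t.size_class.value,
                "mechanism": None if t.mechanism is None else t.mechanism.value,
                "centromere_distance": t.centromere_distance,
                "telomere_distance": t.telomere_distance,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "line_id", "chrom", "start", "end", "size", "n_supporting_snps",
            "parent", "extent", "size_class", "mechanism",
            "centromere_distance", "telomere_distance",
        ],
    )
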
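"""Whole-chromosome aneuploidy detection from binned coverage.

Read depth is summed into 5 kb bins; a chromosome whose median bin count,
normalized by the genome-wide median, deviates beyond the gain/loss
thresholds (defaults 1.35 / 0.65, midway between the euploid ratio 1.0
and the trisomy/monosomy expectations 1.5 / 0.5) becomes a candidate.
Candidates are then verified against the S288c allele fraction at the
parental heterozygous SNPs of that chromosome: a trisomy shifts the mean
fraction from 0.5 to ~1/3 or ~2/3 depending on which homolog was gained,
a monosomy to ~0 or ~1.  A chromosome left fully homozygous (e.g. by a
terminal LOH sweep) provides no fraction signal for a gain and is
reported unverifiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

DEFAULT_BIN_BP = 5_000
GAIN_RATIO = 1.35
LOSS_RATIO = 0.65
FRACTION_WINDOW = 0.07
MIN_VERIFY_SNPS = 10


class Direction(str, Enum):
    GAIN = "GAIN"
    LOSS = "LOSS"


class Verification(str, Enum):
    VERIFIED = "VERIFIED"
    UNVERIFIED = "UNVERIFIED"
    UNVERIFIABLE = "UNVERIFIABLE"


@dataclass
class CoverageBin:
    chrom: str
    start: int  # 1-based
    width: int
    count: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bin width must be positive")
        if self.count < 0:
            raise ValueError("bin count must be >= 0")


@dataclass
class AneuploidyCall:
    """A coverage candidate with its allele-fraction verification."""

    line_id: str
    chrom: str
    direction: Direction
    coverage_ratio: float
    mean_s_fraction: float  # NaN when unverifiable
    verified: bool
    status: Verification

    def __post_init__(self) -> None:
        # ratio 0 is reachable when a chromosome lost both homologs
        if self.coverage_ratio < 0:
            raise ValueError("coverage ratio must be >= 0")


# ---------------------------------------------------------------------------

def bin_coverage(
    depth: pd.DataFrame, width: int = DEFAULT_BIN_BP,
    chrom_lengths: dict[str, int] | None = None,
) -> list[CoverageBin]:
    """Sum a per-position depth track (chrom, pos, depth) into fixed bins.

    The final partial bin of each chromosome is kept with its true width.
    When ``chrom_lengths`` is omitted, the last observed position defines
    the chromosome extent.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    required = {"chrom", "pos", "depth"}
    if not required <= set(depth.columns):
        raise ValueError(f"depth track needs columns {sorted(required)}")
    grouped = {chrom: sub for chrom, sub in depth.groupby("chrom", sort=False)}
    chroms = (
        list(chrom_lengths) if chrom_lengths is not None else list(grouped)
    )
    bins: list[CoverageBin] = []
    for chrom in chroms:
        sub = grouped.get(chrom)
        if sub is None:
            length = chrom_lengths[chrom]
            pos = np.array([], dtype=int)
            val = np.array([], dtype=float)
        else:
            pos = sub["pos"].to_numpy()
            val = sub["depth"].to_numpy(dtype=float)
            length = chrom_lengths[chrom] if chrom_lengths else int(pos.max())
        n_bins = -(-length // width)
        sums = np.bincount((pos - 1) // width, weights=val, minlength=n_bins)
        for b in range(n_bins):
            start = b * width + 1
            w = min(width, length - b * width)
            bins.append(CoverageBin(chrom, start, int(w), float(sums[b])))
    return bins


def detect_candidates(
    bins: list[CoverageBin] | pd.DataFrame,
    gain_ratio: float = GAIN_RATIO,
    loss_ratio: float = LOSS_RATIO,
) -> list[tuple[str, Direction, float]]:
    """Flag chromosomes whose median bin count deviates from the genome median.

    Returns (chrom, direction, coverage_ratio) candidates pending
    allele-fraction verification.  Ratio-based, hence invariant to a
    uniform rescaling of depth.
    """
    if isinstance(bins, pd.DataFrame):
        df = bins
    else:
        df = pd.DataFrame(
            {"chrom": [b.chrom for b in bins], "count": [b.count for b in bins]}
        )
    genome_median = float(df["count"].median())
    if genome_median <= 0:
        raise ValueError("genome-wide median bin count is zero")
    out = []
    for chrom, sub in df.groupby("chrom", sort=False):
        ratio = float(sub["count"].median()) / genome_median
        if ratio >= gain_ratio:
            out.append((chrom, Direction.GAIN, ratio))
        elif ratio <= loss_ratio:
            out.append((chrom, Direction.LOSS, ratio))
    return out


def verify_allele_fraction(
    candidate: tuple[str, Direction, float],
    s_fractions: np.ndarray,
    line_id: str = "line",
    window: float = FRACTION_WINDOW,
    min_snps: int = MIN_VERIFY_SNPS,
) -> AneuploidyCall:
    """Verify a coverage candidate with per-SNP S288c allele fractions.

    ``s_fractions`` are S-depth / total depth at the parental heterozygous
    SNPs of the candidate chromosome (NaN entries are dropped).  GAIN
    verifies when the mean fraction sits within ``window`` of 1/3 or 2/3,
    LOSS within ``window`` of 0 or 1.  With fewer than ``min_snps``
    usable SNPs — or a fully homozygous chromosome offering no
    heterozygous signal for a gain — the call is UNVERIFIABLE.
    """
    chrom, direction, ratio = candidate
    f = np.asarray(s_fractions, dtype=float)
    f = f[~np.isnan(f)]
    if f.size < min_snps:
        return AneuploidyCall(
            line_id, chrom, direction, ratio, float("nan"), False,
            Verification.UNVERIFIABLE,
        )
    mean = float(f.mean())
    if direction == Direction.GAIN:
        # a homozygotized chromosome keeps fraction ~0/1 even when trisomic
        if mean <= window or mean >= 1 - window:
            return AneuploidyCall(
                line_id, chrom, direction, ratio, mean, False,
                Verification.UNVERIFIABLE,
            )
        targets = (1 / 3, 2 / 3)
    else:
        targets = (0.0, 1.0)
    verified = any(abs(mean - t) <= window for t in targets)
    status = Verification.VERIFIED if verified else Verification.UNVERIFIED
    return AneuploidyCall(line_id, chrom, direction, ratio, mean, verified, status)


def call_aneuploidies(
    bins: list[CoverageBin] | pd.DataFrame,
    snp_map,
    s_depth: np.ndarray,
    y_depth: np.ndarray,
    line_id: str = "line",
    gain_ratio: float = GAIN_RATIO,
    loss_ratio: float = LOSS_RATIO,
    window: float = FRACTION_WINDOW,
    min_snps: int = MIN_VERIFY_SNPS,
) -> list[AneuploidyCall]:
    """Full per-line pipeline: detect coverage candidates and verify each."""
    s = np.asarray(s_depth, dtype=float)
    y = np.asarray(y_depth, dtype=float)
    total = s + y
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, s / total, np.nan)
    calls = []
    for cand in detect_candidates(bins, gain_ratio, loss_ratio):
        sl = snp_map.chrom_slice(cand[0])
        calls.append(
            verify_allele_fraction(
                cand, frac[sl], line_id=line_id, window=window, min_snps=min_snps
            )
        )
    return calls


def aneuploidy_rate(n_events: int, generations: float) -> float:
    """Gain/loss events per generation."""
    if generations <= 0:
        raise ValueError("generations must be positive")
    return n_events / generations
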
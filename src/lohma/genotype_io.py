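"""Readers and core containers for genotype, depth and annotation data.

The pipeline works on a diploid hybrid (S288c x YJM789 style) whose
heterozygous SNPs form the coordinate backbone for loss-of-heterozygosity
(LOH) calling.  Everything downstream consumes three containers defined
here: a :class:`SnpMap` of parental heterozygous markers, a
:class:`GenotypeMatrix` of per-line genotype states at those markers, and
:class:`ChromInfo` chromosome metadata (lengths, centromere midpoints).

Coordinate convention: 1-based, inclusive, matching VCF.  BED input
(0-based half-open) is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("lohma")

_BASES = frozenset("ACGT")


class GT(IntEnum):
    """Genotype state of one line at one parental heterozygous SNP.

    ``S_HOM``/``Y_HOM`` mean homozygous for the S288c (VCF 0/0) or
    YJM789 (VCF 1/1) allele respectively.
    """

    HET = 0
    S_HOM = 1
    Y_HOM = 2
    MISSING = 3


#: parents a SNP (or LOH tract) can fix to
PARENT_S = "S288C"
PARENT_Y = "YJM789"


@dataclass(frozen=True)
class SnpMarker:
    """One parental heterozygous SNP: position plus the two parental alleles."""

    chrom: str
    pos: int  # 1-based
    s_allele: str
    y_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP position must be >= 1, got {self.pos}")
        if self.s_allele == self.y_allele:
            raise ValueError(f"parental alleles must differ at {self.chrom}:{self.pos}")


@dataclass
class SnpMap:
    """Ordered parental heterozygous SNPs, the backbone for LOH calling.

    ``df`` has columns ``chrom, pos, s_allele, y_allele`` sorted by
    (chrom-in-input-order, pos) with strictly increasing positions per
    chromosome.  Row order defines the global SNP index used by
    :class:`GenotypeMatrix`.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "s_allele", "y_allele"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"SnpMap dataframe missing columns: {sorted(missing)}")
        self.df = self.df.reset_index(drop=True)
        for chrom, sub in self.df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"SNP positions not strictly increasing on {chrom}")

    @property
    def n_snps(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(self.df["chrom"].unique())

    def chrom_slice(self, chrom: str) -> slice:
        """Global-index slice of the rows belonging to ``chrom``."""
        idx = np.flatnonzero((self.df["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy()

    def markers(self) -> list[SnpMarker]:
        return [
            SnpMarker(r.chrom, int(r.pos), r.s_allele, r.y_allele)
            for r in self.df.itertuples(index=False)
        ]


@dataclass
class GenotypeMatrix:
    """Per-line genotype states at every SnpMap marker.

    ``states`` is ``(n_samples, n_snps)`` int8 with values from :class:`GT`.
    Optional per-cell quality/depth layers share that shape.
    """

    samples: list[str]
    states: np.ndarray
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None
    ad_s: np.ndarray | None = None  # reads supporting the S288c allele
    ad_y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2 or self.states.shape[0] != len(self.samples):
            raise ValueError("states must be (n_samples, n_snps)")
        if not np.isin(self.states, [g.value for g in GT]).all():
            raise ValueError("states contain values outside the GT enum")
        for name in ("gq", "dp", "ad_s", "ad_y"):
            layer = getattr(self, name)
            if layer is not None and np.asarray(layer).shape != self.states.shape:
                raise ValueError(f"layer {name} shape mismatch")

    @property
    def n_snps(self) -> int:
        return self.states.shape[1]

    def row(self, sample: str) -> np.ndarray:
        try:
            i = self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in matrix") from None
        return self.states[i]

    def subset(self, samples: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in samples]
        return GenotypeMatrix(
            samples=list(samples),
            states=self.states[idx],
            gq=None if self.gq is None else self.gq[idx],
            dp=None if self.dp is None else self.dp[idx],
            ad_s=None if self.ad_s is None else self.ad_s[idx],
            ad_y=None if self.ad_y is None else self.ad_y[idx],
        )


@dataclass
class ChromInfo:
    """Chromosome lengths and centromere midpoints."""

    lengths: dict[str, int]
    centromeres: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"length of {chrom} must be positive")
            cen = self.centromeres.get(chrom)
            if cen is not None and not (1 <= cen <= length):
                raise ValueError(f"centromere of {chrom} outside [1, {length}]")

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in metadata") from None

    def centromere(self, chrom: str) -> int:
        try:
            return self.centromeres[chrom]
        except KeyError:
            raise KeyError(f"no centromere recorded for {chrom!r}") from None

    @property
    def genome_size(self) -> int:
        return int(sum(self.lengths.values()))


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------

def read_genotype_vcf(
    path: str | Path, samples: list[str] | None = None
) -> tuple[SnpMap, GenotypeMatrix, int]:
    """Read a multi-sample VCF into a SnpMap plus GenotypeMatrix.

    GT mapping follows the hybrid convention: REF is the S288c allele and
    ALT the YJM789 allele, so 0/0 -> S_HOM, 1/1 -> Y_HOM, 0/1 or 1/0 ->
    HET, ./. -> MISSING.  Multi-allelic records are dropped; the dropped
    count is returned and logged.

    Parameters
    ----------
    path
        Plain-text or bgzipped VCF with GT (and optionally AD/DP/GQ) fields.
    samples
        Samples to load, in the order wanted.  Default: all samples in
        header order.

    Returns
    -------
    (snp_map, matrix, n_multiallelic_dropped)
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    if samples is None:
        samples = header_samples
    else:
        missing = [s for s in samples if s not in header_samples]
        if missing:
            raise KeyError(f"samples not present in VCF: {missing}")
    col = [header_samples.index(s) for s in samples]

    rows: list[tuple[str, int, str, str]] = []
    state_rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray] = []
    dp_rows: list[np.ndarray] = []
    ads_rows: list[np.ndarray] = []
    ady_rows: list[np.ndarray] = []
    has_gq = has_dp = has_ad = True
    n_multi = 0

    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        gts = var.genotypes  # [[a0, a1, phased], ...]
        states = np.empty(len(col), dtype=np.int8)
        for out_i, samp_i in enumerate(col):
            a0, a1 = gts[samp_i][0], gts[samp_i][1]
            if a0 < 0 or a1 < 0:
                states[out_i] = GT.MISSING
            elif a0 == 0 and a1 == 0:
                states[out_i] = GT.S_HOM
            elif a0 == 1 and a1 == 1:
                states[out_i] = GT.Y_HOM
            else:
                states[out_i] = GT.HET
        state_rows.append(states)

        if has_gq:
            gq = var.gt_quals
            if gq is None:
                has_gq = False
            else:
                gq_rows.append(np.asarray(gq, dtype=np.float32)[col])
        if has_dp:
            dp = var.format("DP")
            if dp is None:
                has_dp = False
            else:
                dp_rows.append(np.asarray(dp, dtype=np.float32).reshape(-1)[col])
        if has_ad:
            ad = var.format("AD")
            if ad is None or ad.shape[1] < 2:
                has_ad = False
            else:
                ads_rows.append(np.asarray(ad[:, 0], dtype=np.float32)[col])
                ady_rows.append(np.asarray(ad[:, 1], dtype=np.float32)[col])

    if n_multi:
        logger.info("read_genotype_vcf: dropped %d multi-allelic records", n_multi)

    map_df = pd.DataFrame(rows, columns=["chrom", "pos", "s_allele", "y_allele"])
    snp_map = SnpMap(map_df)
    n = len(map_df)

    def _stack(lst: list[np.ndarray], ok: bool) -> np.ndarray | None:
        if not ok or len(lst) != n:
            return None
        return np.stack(lst, axis=1) if n else np.empty((len(samples), 0))

    matrix = GenotypeMatrix(
        samples=list(samples),
        states=(np.stack(state_rows, axis=1) if n else np.empty((len(samples), 0), dtype=np.int8)),
        gq=_stack(gq_rows, has_gq),
        dp=_stack(dp_rows, has_dp),
        ad_s=_stack(ads_rows, has_ad),
        ad_y=_stack(ady_rows, has_ad),
    )
    return snp_map, matrix, n_multi


def build_het_map(
    parent_sample: str, matrix: GenotypeMatrix, snp_map: SnpMap
) -> tuple[SnpMap, GenotypeMatrix]:
    """Restrict to sites heterozygous in the parent and genotyped in all lines.

    Mirrors the usable-marker rule for an environment: a site is retained
    iff the parent hybrid is HET there and no MA line of the environment is
    MISSING.  Idempotent.  Returns the filtered map and the matrix of MA
    lines only (parent row removed).
    """
    parent_row = matrix.row(parent_sample)
    line_samples = [s for s in matrix.samples if s != parent_sample]
    lines = matrix.subset(line_samples)
    keep = (parent_row == GT.HET) & (lines.states != GT.MISSING).all(axis=0)
    n_kept = int(keep.sum())
    if n_kept == 0:
        logger.warning("build_het_map: no usable heterozygous sites remain")
    logger.info("build_het_map: retained %d / %d sites", n_kept, snp_map.n_snps)
    sub_map = SnpMap(snp_map.df.loc[keep].reset_index(drop=True))
    sub_matrix = GenotypeMatrix(
        samples=lines.samples,
        states=lines.states[:, keep],
        gq=None if lines.gq is None else lines.gq[:, keep],
        dp=None if lines.dp is None else lines.dp[:, keep],
        ad_s=None if lines.ad_s is None else lines.ad_s[:, keep],
        ad_y=None if lines.ad_y is None else lines.ad_y[:, keep],
    )
    return sub_map, sub_matrix


# ---------------------------------------------------------------------------
# Interval and metadata ingestion
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, merge: bool = False) -> dict[str, IntervalTree]:
    """Read a BED file into per-chromosome interval trees.

    BED is 0-based half-open; intervals are stored 1-based inclusive as
    ``Interval(start, end + 1)`` so tree queries with 1-based positions are
    exact.  ``merge=True`` merges overlapping/adjacent intervals.
    """
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED record needs >=3 columns")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if start0 >= end0:
                raise ValueError(f"{path}:{lineno}: start >= end")
            start1, end1 = start0 + 1, end0  # to 1-based inclusive
            trees.setdefault(chrom, IntervalTree()).addi(start1, end1 + 1)
    if merge:
        for tree in trees.values():
            tree.merge_overlaps(strict=False)
    return trees


def overlaps(trees: dict[str, IntervalTree], chrom: str, start: int, end: int) -> bool:
    """True if [start, end] (1-based inclusive) hits any interval on chrom."""
    tree = trees.get(chrom)
    if tree is None:
        return False
    return bool(tree.overlap(start, end + 1))


def read_chrom_info(path: str | Path) -> ChromInfo:
    """Read TSV chromosome metadata with columns chrom, length, centromere."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    for col in ("chrom", "length"):
        if col not in df.columns:
            raise ValueError(f"chromosome metadata needs a {col!r} column")
    lengths = dict(zip(df["chrom"], df["length"].astype(int)))
    if "centromere" in df.columns:
        cens = dict(zip(df["chrom"], df["centromere"].astype(int)))
    else:
        cens = {}
    return ChromInfo(lengths=lengths, centromeres=cens)


def read_depth(path: str | Path) -> pd.DataFrame:
    """Read an allele-specific depth TSV (chrom, pos, s_depth, y_depth)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "s_depth", "y_depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"depth TSV missing columns: {sorted(missing)}")
    return df


def align_depth(depth: pd.DataFrame, snp_map: SnpMap) -> tuple[np.ndarray, np.ndarray]:
    """Align a depth table to SnpMap order; absent sites become NaN."""
    merged = snp_map.df[["chrom", "pos"]].merge(depth, on=["chrom", "pos"], how="left")
    return (
        merged["s_depth"].to_numpy(dtype=float),
        merged["y_depth"].to_numpy(dtype=float),
    )
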
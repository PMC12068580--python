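"""Forward simulator of hybrid-diploid mutation-accumulation (MA) lines.

The simulator emulates the experimental design the analysis modules
assume: a heterozygous S288c/YJM789-style diploid is propagated through
single-cell bottlenecks for ~1000 generations, accumulating LOH events
(copy-neutral interstitial and terminal tracts, and deletion-LOH),
single-nucleotide mutations, small indels, and whole-chromosome gains and
losses, each as a Poisson process at a configurable per-generation rate.
The bottleneck structure itself is not modelled cell by cell; each event
fixes immediately, which is the relevant limit for MA lines where only
the final bottleneck genome is sequenced.

Per line the simulator produces the objects the pipeline consumes:

* a genotype row (HET / S-fixed / Y-fixed / MISSING) over the SNP map,
* allele-specific read depths at each SNP (total depth scales with local
  copy number; the allele split is binomial in the true allele copy
  ratio),
* binned read-coverage (Poisson counts proportional to local copy
  number),
* a :class:`SimTruth` log of every injected event for recovery scoring.

Default chromosome sizes and centromere midpoints follow the 16
S. cerevisiae nuclear chromosomes (~12.07 Mb); default event rates give a
YPD-like line: ~23 LOH events per 1000 generations of which ~69% are
copy-neutral, and genome-wide SNM / indel / aneuploidy rates matching a
wild-type diploid hybrid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import (
    GT,
    PARENT_S,
    PARENT_Y,
    ChromInfo,
    GenotypeMatrix,
    SnpMap,
)
from .loh_detection import LohTract

# S. cerevisiae sacCer3 nuclear chromosome lengths (bp) and approximate
# centromere midpoints.
SACCER_CHROM_LENGTHS: dict[str, int] = {
    "chrI": 230_218, "chrII": 813_184, "chrIII": 316_620, "chrIV": 1_531_933,
    "chrV": 576_874, "chrVI": 270_161, "chrVII": 1_090_940, "chrVIII": 562_643,
    "chrIX": 439_888, "chrX": 745_751, "chrXI": 666_816, "chrXII": 1_078_177,
    "chrXIII": 924_431, "chrXIV": 784_333, "chrXV": 1_091_291, "chrXVI": 948_066,
}
SACCER_CENTROMERES: dict[str, int] = {
    "chrI": 151_465, "chrII": 238_207, "chrIII": 114_385, "chrIV": 449_711,
    "chrV": 151_987, "chrVI": 148_510, "chrVII": 497_038, "chrVIII": 105_703,
    "chrIX": 355_629, "chrX": 436_425, "chrXI": 440_246, "chrXII": 150_947,
    "chrXIII": 268_031, "chrXIV": 628_758, "chrXV": 326_584, "chrXVI": 555_957,
}

#: the six strand-collapsed substitution classes, transition classes first
SPECTRUM_CLASSES = (
    "A:T>G:C", "G:C>A:T", "A:T>C:G", "A:T>T:A", "G:C>C:G", "G:C>T:A",
)

EVENT_KINDS = (
    "interstitial-LOH", "terminal-LOH", "deletion-LOH",
    "SNM", "indel", "gain", "loss",
)
LOH_KINDS = ("interstitial-LOH", "terminal-LOH", "deletion-LOH")


@dataclass
class SimConfig:
    """Study-condition parameters of the MA-line simulator.

    Rates are genome-wide events per generation.  The default LOH rates
    sum to 0.023/generation (a YPD-like control line) split so that
    copy-neutral events (interstitial + terminal) make up ~69% and
    interstitial events outnumber terminal ones.  SNM and indel rates are
    the per-bp wild-type rates (1.56e-10 and 0.16e-10 per bp per
    generation) multiplied by the 24.04 Mb diploid genome.  Gain/loss
    rates correspond to ~13 aneuploidies per 70 lines per 1000
    generations, 11 gains : 2 losses.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(SACCER_CHROM_LENGTHS)
    )
    centromeres: dict[str, int] = field(
        default_factory=lambda: dict(SACCER_CENTROMERES)
    )
    snp_density_per_kb: float = 6.1
    #: per-10 kb density multipliers ~ Gamma(1/h, h) when heterogeneity h > 0
    density_heterogeneity: float = 0.3
    density_block_bp: int = 10_000
    interstitial_rate: float = 0.013
    terminal_rate: float = 0.003
    deletion_rate: float = 0.007
    snm_rate: float = 3.75e-3
    indel_rate: float = 3.85e-4
    gain_rate: float = 1.57e-4
    loss_rate: float = 2.9e-5
    #: log-normal interstitial/deletion tract lengths, median 500 bp
    tract_length_median_bp: float = 500.0
    tract_length_sigma: float = 1.5
    snm_spectrum: tuple[float, ...] = (1 / 6,) * 6
    lines_per_environment: int = 16
    generations: int = 1000
    depth: int = 100
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        rates = (
            self.interstitial_rate, self.terminal_rate, self.deletion_rate,
            self.snm_rate, self.indel_rate, self.gain_rate, self.loss_rate,
        )
        if any(r < 0 for r in rates):
            raise ValueError("event rates must be >= 0")
        if len(self.snm_spectrum) != 6 or abs(sum(self.snm_spectrum) - 1.0) > 1e-9:
            raise ValueError("snm_spectrum must be 6 probabilities summing to 1")
        if any(p < 0 for p in self.snm_spectrum):
            raise ValueError("snm_spectrum probabilities must be >= 0")
        if any(v <= 0 for v in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.snp_density_per_kb <= 0:
            raise ValueError("SNP density must be positive")
        if self.depth < 1:
            raise ValueError("sequencing depth must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")

    @property
    def genome_size(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def chrom_info(self) -> ChromInfo:
        return ChromInfo(dict(self.chrom_lengths), dict(self.centromeres))


@dataclass
class SimEvent:
    """One injected mutational event."""

    kind: str  # member of EVENT_KINDS
    chrom: str
    start: int  # 1-based inclusive
    end: int
    generation: int
    parent: str | None = None  # fixed/duplicated parent where applicable
    detail: str | None = None  # e.g. substitution class for SNMs

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.start > self.end or self.start < 1:
            raise ValueError("invalid event interval")


@dataclass
class SimTruth:
    """Ground-truth event log for one simulated line."""

    line_id: str
    events: list[SimEvent] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def of_kind(self, *kinds: str) -> list[SimEvent]:
        return [e for e in self.events if e.kind in kinds]

    def loh_events(self) -> list[SimEvent]:
        return self.of_kind(*LOH_KINDS)


@dataclass
class SimLine:
    """Everything the simulator emits for one MA line."""

    line_id: str
    states: np.ndarray  # GT codes aligned to the SnpMap
    s_depth: np.ndarray
    y_depth: np.ndarray
    coverage_bins: pd.DataFrame  # chrom, bin_start, width, count
    truth: SimTruth


# ---------------------------------------------------------------------------
# SNP map simulation
# ---------------------------------------------------------------------------

def simulate_snp_map(config: SimConfig, rng: np.random.Generator | None = None) -> SnpMap:
    """Draw a parental heterozygous SNP map with locally varying density.

    SNPs fall as a Poisson process at ``snp_density_per_kb``; when
    ``density_heterogeneity`` h > 0 the density of each 10 kb block is
    multiplied by an independent Gamma(1/h, h) draw (mean 1), emulating
    the patchy marker density of a real hybrid.  Parental alleles are two
    distinct random bases per SNP.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    per_bp = config.snp_density_per_kb / 1000.0
    bases = np.array(list("ACGT"))
    frames = []
    for chrom, length in config.chrom_lengths.items():
        n_blocks = -(-length // config.density_block_bp)
        if config.density_heterogeneity > 0:
            h = config.density_heterogeneity
            mult = rng.gamma(shape=1.0 / h, scale=h, size=n_blocks)
        else:
            mult = np.ones(n_blocks)
        block_sizes = np.full(n_blocks, config.density_block_bp)
        block_sizes[-1] = length - config.density_block_bp * (n_blocks - 1)
        counts = rng.poisson(per_bp * mult * block_sizes)
        positions = []
        for b, k in enumerate(counts):
            if k == 0:
                continue
            lo = b * config.density_block_bp + 1
            hi = lo + block_sizes[b] - 1
            positions.append(rng.integers(lo, hi + 1, size=k))
        if positions:
            pos = np.unique(np.concatenate(positions))
        else:
            pos = np.array([], dtype=int)
        s_idx = rng.integers(0, 4, size=pos.size)
        offset = rng.integers(1, 4, size=pos.size)
        y_idx = (s_idx + offset) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "s_allele": bases[s_idx],
                    "y_allele": bases[y_idx],
                }
            )
        )
    return SnpMap(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Line simulation
# ---------------------------------------------------------------------------

def _sample_interval(
    rng: np.random.Generator, length: int, median: float, sigma: float
) -> tuple[int, int]:
    """Log-normal tract on a chromosome of the given length (clipped)."""
    size = max(1, int(round(rng.lognormal(mean=np.log(median), sigma=sigma))))
    size = min(size, length)
    start = int(rng.integers(1, length - size + 2))
    return start, start + size - 1


def _weighted_chrom(rng: np.random.Generator, lengths: dict[str, int]) -> str:
    chroms = list(lengths)
    w = np.array([lengths[c] for c in chroms], dtype=float)
    return chroms[rng.choice(len(chroms), p=w / w.sum())]


def simulate_line(
    config: SimConfig,
    snp_map: SnpMap,
    seed: int | np.random.Generator,
    line_id: str = "line",
) -> SimLine:
    """Propagate one MA line and emit genotypes, depths, coverage and truth.

    Event counts are Poisson(rate x generations); events are applied in
    generation order to per-position copy-number arrays (one per parental
    haplotype), from which genotype states, allele-specific depths and
    binned coverage follow:

    * copy-neutral LOH sets the kept haplotype to 2 copies and the lost
      one to 0 over the tract (total copy unchanged),
    * deletion-LOH zeroes the lost haplotype only (total copy halves),
    * chromosome gain adds one copy of a haplotype chromosome-wide
      (heterozygous allele fractions shift to 1/3 or 2/3); loss removes
      one (fractions 0 or 1, total copy halves).

    Total SNP depth is ``depth x copy/2``; the allele split is binomial in
    the true allele copy ratio.  Overlapping LOH events coalesce: the
    later event overwrites the overlap, which :func:`truth_loh_tracts`
    resolves when scoring recovery.
    """
    if snp_map.n_snps == 0:
        raise ValueError("snp_map is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    chrom_lengths = config.chrom_lengths
    copies = {
        c: {
            PARENT_S: np.ones(n, dtype=np.int8),
            PARENT_Y: np.ones(n, dtype=np.int8),
        }
        for c, n in chrom_lengths.items()
    }
    truth = SimTruth(line_id=line_id)
    g = config.generations

    # draw all events with generation stamps, then apply in time order
    events: list[SimEvent] = []
    simple_kinds = {
        "interstitial-LOH": config.interstitial_rate,
        "terminal-LOH": config.terminal_rate,
        "deletion-LOH": config.deletion_rate,
        "SNM": config.snm_rate,
        "indel": config.indel_rate,
        "gain": config.gain_rate,
        "loss": config.loss_rate,
    }
    for kind, rate in simple_kinds.items():
        n_events = rng.poisson(rate * g)
        for _ in range(n_events):
            gen = int(rng.integers(1, g + 1))
            chrom = _weighted_chrom(rng, chrom_lengths)
            length = chrom_lengths[chrom]
            parent = PARENT_S if rng.random() < 0.5 else PARENT_Y
            if kind in ("interstitial-LOH", "deletion-LOH"):
                start, end = _sample_interval(
                    rng, length, config.tract_length_median_bp, config.tract_length_sigma
                )
            elif kind == "terminal-LOH":
                bp = int(rng.integers(1, length + 1))
                if rng.random() < 0.5:
                    start, end = bp, length
                else:
                    start, end = 1, bp
            elif kind in ("gain", "loss"):
                start, end = 1, length
            elif kind == "SNM":
                p = int(rng.integers(1, length + 1))
                start = end = p
                parent = None
            else:  # indel, +-1..50 bp
                p = int(rng.integers(1, length + 1))
                start, end = p, min(length, p + int(rng.integers(1, 51)) - 1)
                parent = None
            detail = None
            if kind == "SNM":
                cls = rng.choice(len(SPECTRUM_CLASSES), p=np.asarray(config.snm_spectrum))
                detail = SPECTRUM_CLASSES[cls]
            events.append(SimEvent(kind, chrom, start, end, gen, parent, detail))
    events.sort(key=lambda e: e.generation)

    seen: list[SimEvent] = []
    for ev in events:
        cp = copies[ev.chrom]
        sl = slice(ev.start - 1, ev.end)
        if ev.kind in ("interstitial-LOH", "terminal-LOH"):
            kept, lost = (PARENT_S, PARENT_Y) if ev.parent == PARENT_S else (PARENT_Y, PARENT_S)
            total = cp[PARENT_S][sl].astype(np.int16) + cp[PARENT_Y][sl]
            cp[kept][sl] = np.minimum(total, 127).astype(np.int8)
            cp[lost][sl] = 0
        elif ev.kind == "deletion-LOH":
            lost = PARENT_Y if ev.parent == PARENT_S else PARENT_S
            cp[lost][sl] = 0
        elif ev.kind == "gain":
            # duplicating a homolog adds copies only where it still has any
            arr = cp[ev.parent][sl]
            cp[ev.parent][sl] = np.minimum(arr + (arr >= 1), 127)
        elif ev.kind == "loss":
            cp[ev.parent][sl] = np.maximum(cp[ev.parent][sl].astype(np.int16) - 1, 0).astype(np.int8)
        # SNM / indel events only enter the truth log
        if ev.kind in LOH_KINDS and any(
            o.chrom == ev.chrom and o.kind in LOH_KINDS
            and o.start <= ev.end and ev.start <= o.end
            for o in seen
        ):
            truth.notes.append(
                f"{ev.kind} {ev.chrom}:{ev.start}-{ev.end} overlaps an earlier "
                "LOH event; tracts coalesce"
            )
        seen.append(ev)
    truth.events = events

    # genotype states, depths, coverage from the copy arrays
    n = snp_map.n_snps
    states = np.empty(n, dtype=np.int8)
    s_depth = np.zeros(n, dtype=np.int32)
    y_depth = np.zeros(n, dtype=np.int32)
    cov_rows = []
    bin_width = 5_000
    for chrom in snp_map.chroms:
        sl = snp_map.chrom_slice(chrom)
        pos = snp_map.positions(chrom) - 1
        cs = copies[chrom][PARENT_S][pos].astype(np.int32)
        cy = copies[chrom][PARENT_Y][pos].astype(np.int32)
        st = np.full(pos.size, GT.MISSING, dtype=np.int8)
        st[(cs > 0) & (cy > 0)] = GT.HET
        st[(cs > 0) & (cy == 0)] = GT.S_HOM
        st[(cs == 0) & (cy > 0)] = GT.Y_HOM
        states[sl] = st
        total = cs + cy
        n_reads = np.round(config.depth * total / 2.0).astype(np.int64)
        frac = np.divide(cs, total, out=np.zeros_like(cs, dtype=float), where=total > 0)
        s_reads = rng.binomial(n_reads, frac)
        s_depth[sl] = s_reads
        y_depth[sl] = n_reads - s_reads
    for chrom, length in chrom_lengths.items():
        total_copy = copies[chrom][PARENT_S].astype(np.int32) + copies[chrom][PARENT_Y]
        n_bins = -(-length // bin_width)
        edges = np.arange(0, n_bins * bin_width, bin_width)
        sums = np.add.reduceat(total_copy, edges)
        widths = np.minimum(edges + bin_width, length) - edges
        lam = config.depth * (sums / widths) / 2.0 * widths / 150.0  # ~150 bp reads
        counts = rng.poisson(lam)
        cov_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_start": edges + 1,
                    "width": widths,
                    "count": counts,
                }
            )
        )
    if config.missing_rate > 0:
        mask = rng.random(n) < config.missing_rate
        states[mask] = GT.MISSING

    return SimLine(
        line_id=line_id,
        states=states,
        s_depth=s_depth,
        y_depth=y_depth,
        coverage_bins=pd.concat(cov_rows, ignore_index=True),
        truth=truth,
    )


def simulate_environment(
    config: SimConfig, snp_map: SnpMap | None = None, env: str = "ENV"
) -> tuple[SnpMap, list[SimLine]]:
    """Simulate a whole environment: one SNP map, ``lines_per_environment`` lines."""
    rng = np.random.default_rng(config.seed)
    if snp_map is None:
        snp_map = simulate_snp_map(config, rng)
    lines = [
        simulate_line(config, snp_map, rng, line_id=f"{env}_L{i + 1:02d}")
        for i in range(config.lines_per_environment)
    ]
    return snp_map, lines


# ---------------------------------------------------------------------------
# Truth resolution and recovery scoring
# ---------------------------------------------------------------------------

def truth_expected_states(truth: SimTruth, snp_map: SnpMap) -> np.ndarray:
    """Expected noise-free genotype states implied by the truth event log.

    Replays the logged events in generation order over per-SNP allele copy
    counters with the same semantics the simulator applies genome-wide
    (copy-neutral LOH transfers copies to the kept haplotype, deletion-LOH
    zeroes the lost one, gains duplicate a homolog where it still has
    copies, losses remove one), then maps copies to GT states.  Depends
    only on the event log, not on the emitted genotype row.
    """
    n = snp_map.n_snps
    s_cnt = np.ones(n, dtype=np.int16)
    y_cnt = np.ones(n, dtype=np.int16)
    for ev in sorted(truth.events, key=lambda e: e.generation):
        if ev.kind not in LOH_KINDS and ev.kind not in ("gain", "loss"):
            continue
        sl = snp_map.chrom_slice(ev.chrom)
        pos = snp_map.positions(ev.chrom)
        idx = np.flatnonzero((pos >= ev.start) & (pos <= ev.end)) + sl.start
        if idx.size == 0:
            continue
        kept_is_s = ev.parent == PARENT_S
        kept, lost = (s_cnt, y_cnt) if kept_is_s else (y_cnt, s_cnt)
        if ev.kind in ("interstitial-LOH", "terminal-LOH"):
            kept[idx] = kept[idx] + lost[idx]
            lost[idx] = 0
        elif ev.kind == "deletion-LOH":
            lost[idx] = 0
        elif ev.kind == "gain":
            kept[idx] = kept[idx] + (kept[idx] >= 1)
        elif ev.kind == "loss":
            kept[idx] = np.maximum(kept[idx] - 1, 0)
    states = np.full(n, GT.MISSING, dtype=np.int8)
    states[(s_cnt > 0) & (y_cnt > 0)] = GT.HET
    states[(s_cnt > 0) & (y_cnt == 0)] = GT.S_HOM
    states[(s_cnt == 0) & (y_cnt > 0)] = GT.Y_HOM
    return states


def truth_loh_tracts(
    truth: SimTruth, snp_map: SnpMap, min_support: int = 1
) -> list[LohTract]:
    """Resolve the raw event log into expected LOH tracts at SNP resolution.

    The expected genotype vector from :func:`truth_expected_states` is
    scanned for maximal same-parent runs under the same run semantics the
    caller uses.  Overlapping events coalesce, later events overwrite the
    overlap, and two events separated by a SNP-free gap merge — they are
    indistinguishable at SNP resolution.
    """
    from .loh_detection import call_tracts

    states = truth_expected_states(truth, snp_map)
    return call_tracts(states, snp_map, line_id=truth.line_id, min_support=min_support)


@dataclass
class RecoveryReport:
    """Sensitivity / precision of tract calls against simulator truth."""

    n_truth_detectable: int
    n_called: int
    n_matched: int
    sensitivity: float  # NaN when no detectable truth events
    precision: float  # NaN when no calls
    mean_boundary_error_bp: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n_truth_detectable": self.n_truth_detectable,
            "n_called": self.n_called,
            "n_matched": self.n_matched,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "mean_boundary_error_bp": self.mean_boundary_error_bp,
        }


def _reciprocal_overlap(a: LohTract, b: LohTract) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / a.size, inter / b.size)


def truth_compare(
    called: list[LohTract],
    truth: SimTruth,
    snp_map: SnpMap,
    min_support: int = 3,
    min_reciprocal_overlap: float = 0.5,
) -> RecoveryReport:
    """Score called tracts against the simulator's truth log.

    Truth events are first resolved at SNP resolution with
    :func:`truth_loh_tracts`; the detectable denominator keeps only
    expected tracts covering at least ``min_support`` SNPs.  A call
    matches a truth tract when their reciprocal overlap is at least
    ``min_reciprocal_overlap`` (greedy one-to-one matching, best overlap
    first).  Sensitivity/precision are NaN when their denominator is
    empty.
    """
    truth_tracts = truth_loh_tracts(truth, snp_map)
    for t in called:
        if t.chrom not in set(snp_map.chroms) | set(x.chrom for x in truth_tracts):
            raise ValueError(f"called tract on unknown chromosome {t.chrom!r}")
    detectable = [t for t in truth_tracts if t.n_supporting_snps >= min_support]

    pairs = []
    for ci, c in enumerate(called):
        for ti, t in enumerate(detectable):
            ov = _reciprocal_overlap(c, t)
            if ov >= min_reciprocal_overlap:
                pairs.append((ov, ci, ti))
    pairs.sort(reverse=True)
    used_c: set[int] = set()
    used_t: set[int] = set()
    boundary_errors = []
    for ov, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        c, t = called[ci], detectable[ti]
        boundary_errors.append((abs(c.start - t.start) + abs(c.end - t.end)) / 2.0)
    n_matched = len(used_t)
    sens = n_matched / len(detectable) if detectable else float("nan")
    prec = len(used_c) / len(called) if called else float("nan")
    mbe = float(np.mean(boundary_errors)) if boundary_errors else float("nan")
    return RecoveryReport(
        n_truth_detectable=len(detectable),
        n_called=len(called),
        n_matched=n_matched,
        sensitivity=sens,
        precision=prec,
        mean_boundary_error_bp=mbe,
    )


# ---------------------------------------------------------------------------
# Emission of standard formats
# ---------------------------------------------------------------------------

def emit_vcf(
    lines: list[SimLine],
    snp_map: SnpMap,
    path: str | Path,
    parent_sample: str | None = "parent",
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write a multi-sample VCF (GT:AD:DP:GQ) readable by genotype_io.

    REF is the S288c allele, ALT the YJM789 allele.  An optional
    synthetic ``parent_sample`` column is emitted as 0/1 everywhere with
    balanced allele depths, modelling the heterozygous ancestor.
    """
    samples = ([parent_sample] if parent_sample else []) + [l.line_id for l in lines]
    gt_str = {GT.HET: "0/1", GT.S_HOM: "0/0", GT.Y_HOM: "1/1", GT.MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lohma-simulator\n")
        for chrom in snp_map.chroms:
            if chrom_lengths and chrom in chrom_lengths:
                fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT")
        for s in samples:
            fh.write(f"\t{s}")
        fh.write("\n")
        df = snp_map.df
        for i in range(len(df)):
            chrom = df.at[i, "chrom"]
            pos = df.at[i, "pos"]
            ref = df.at[i, "s_allele"]
            alt = df.at[i, "y_allele"]
            fields = [chrom, str(pos), ".", ref, alt, ".", "PASS", ".", "GT:AD:DP:GQ"]
            if parent_sample:
                half = 50
                fields.append(f"0/1:{half},{half}:{2 * half}:99")
            for line in lines:
                st = GT(line.states[i])
                ads = int(line.s_depth[i])
                ady = int(line.y_depth[i])
                fields.append(f"{gt_str[st]}:{ads},{ady}:{ads + ady}:99")
            fh.write("\t".join(fields) + "\n")


def emit_depth(line: SimLine, snp_map: SnpMap, path: str | Path) -> None:
    """Write one line's allele-specific SNP depths as TSV."""
    pd.DataFrame(
        {
            "chrom": snp_map.df["chrom"],
            "pos": snp_map.df["pos"],
            "s_depth": line.s_depth,
            "y_depth": line.y_depth,
        }
    ).to_csv(path, sep="\t", index=False)


def emit_coverage(line: SimLine, path: str | Path) -> None:
    """Write one line's binned coverage as TSV."""
    line.coverage_bins.to_csv(path, sep="\t", index=False)


def emit_truth(lines: list[SimLine], path: str | Path) -> None:
    """Write the ground-truth event log of several lines as TSV."""
    rows = []
    for line in lines:
        for ev in line.truth.events:
            rows.append(
                {
                    "line_id": line.line_id,
                    "kind": ev.kind,
                    "chrom": ev.chrom,
                    "start": ev.start,
                    "end": ev.end,
                    "generation": ev.generation,
                    "parent": ev.parent or "",
                    "detail": ev.detail or "",
                }
            )
    pd.DataFrame(
        rows,
        columns=["line_id", "kind", "chrom", "start", "end", "generation", "parent", "detail"],
    ).to_csv(path, sep="\t", index=False)


def lines_to_matrix(lines: list[SimLine]) -> GenotypeMatrix:
    """Stack simulated lines into a GenotypeMatrix (states + allele depths)."""
    return GenotypeMatrix(
        samples=[l.line_id for l in lines],
        states=np.stack([l.states for l in lines]),
        ad_s=np.stack([l.s_depth for l in lines]).astype(np.float32),
        ad_y=np.stack([l.y_depth for l in lines]).astype(np.float32),
    )
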
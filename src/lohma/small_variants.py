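"""De-novo small-variant filtering, mutation spectra and SV filtering.

Candidate single-nucleotide mutations (SNMs) and small indels called in an
MA line are accepted as de novo only if they pass the quality gate
(biallelic, GQ >= 30, DP >= 40, allelic ratio <= 0.1 or >= 0.9 for
homozygous calls, strictly between 0.4 and 0.6 for heterozygous calls),
are absent from the parent and from every other line at the same site
with the same alternate allele, and do not fall in repeat-masked regions.
Accepted SNMs are strand-collapsed into the six substitution classes,
from which the transition/transversion ratio (null expectation 0.5 under
a uniform spectrum) and the AT/GC bias are computed.  Mutation rates are
per bp per generation over the 24.04 Mb diploid genome.

Structural-variant records (long-read caller output) get an analogous
record-level filter: precise, no strand bias, length >= 50 bp, read
support >= 10, quality >= 30, absent from the ancestor, and not at
identical coordinates in every line.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .genotype_io import overlaps
from .loh_detection import GENOME_SIZE_BP

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: strand-collapsed substitution classes; the first two are transitions
TRANSITION_CLASSES = ("A:T>G:C", "G:C>A:T")
TRANSVERSION_CLASSES = ("A:T>C:G", "A:T>T:A", "G:C>C:G", "G:C>T:A")
ALL_CLASSES = TRANSITION_CLASSES + TRANSVERSION_CLASSES


class RejectionReason(str, Enum):
    MULTIALLELIC = "multiallelic"
    GQ = "gq"
    DP = "dp"
    ALLELIC_RATIO = "allelic_ratio"
    SHARED_PARENT = "shared_parent"
    SHARED_LINE = "shared_line"
    REPEAT = "repeat"


@dataclass(frozen=True)
class VariantCall:
    """One raw caller record for one line."""

    line_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gq: float
    dp: float
    allelic_ratio: float  # alt reads / total reads
    genotype: str  # "HOM" | "HET"
    var_class: str = "SNM"  # "SNM" | "INDEL"
    n_alt_alleles: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.allelic_ratio <= 1.0:
            raise ValueError("allelic ratio must be in [0, 1]")
        if self.dp < 0:
            raise ValueError("DP must be >= 0")
        if self.genotype not in ("HOM", "HET"):
            raise ValueError("genotype must be HOM or HET")


@dataclass(frozen=True)
class MutationRecord:
    """A de-novo mutation that survived all filters."""

    line_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str
    substitution_class: str | None  # None for indels


@dataclass
class MutationSpectrum:
    """Counts of the six substitution classes plus derived ratios."""

    counts: dict[str, int]
    ts_tv: float  # NaN when no transversions
    at_gc_bias: float  # NaN when the denominator class is empty

    @property
    def n_transitions(self) -> int:
        return sum(self.counts[c] for c in TRANSITION_CLASSES)

    @property
    def n_transversions(self) -> int:
        return sum(self.counts[c] for c in TRANSVERSION_CLASSES)


# ---------------------------------------------------------------------------
# De-novo filtering
# ---------------------------------------------------------------------------

def _passes_quality(call: VariantCall) -> RejectionReason | None:
    if call.n_alt_alleles != 1:
        return RejectionReason.MULTIALLELIC
    if call.gq < 30:
        return RejectionReason.GQ
    if call.dp < 40:
        return RejectionReason.DP
    if call.genotype == "HOM":
        if not (call.allelic_ratio <= 0.1 or call.allelic_ratio >= 0.9):
            return RejectionReason.ALLELIC_RATIO
    else:  # HET: strict inequalities
        if not (0.4 < call.allelic_ratio < 0.6):
            return RejectionReason.ALLELIC_RATIO
    return None


def filter_de_novo(
    calls: list[VariantCall],
    parent_calls: list[VariantCall],
    other_line_calls: list[VariantCall],
    repeat_intervals: dict | None = None,
) -> tuple[list[MutationRecord], Counter]:
    """Apply the de-novo filter cascade; every rejection is counted by reason.

    Sharing is keyed on (chrom, pos, alt): the same site with a different
    alternate allele is not shared.  Filters are checked in a fixed order
    (quality gates, then parent sharing, then other-line sharing, then
    repeat overlap) so each rejected call carries a single reason.
    Order-independent over the input list and idempotent.
    """
    parent_keys = {(c.chrom, c.pos, c.alt) for c in parent_calls}
    other_keys = {(c.chrom, c.pos, c.alt) for c in other_line_calls}
    kept: list[MutationRecord] = []
    reasons: Counter = Counter()
    for call in calls:
        reason = _passes_quality(call)
        if reason is None:
            key = (call.chrom, call.pos, call.alt)
            if key in parent_keys:
                reason = RejectionReason.SHARED_PARENT
            elif key in other_keys:
                reason = RejectionReason.SHARED_LINE
            elif repeat_intervals is not None and overlaps(
                repeat_intervals, call.chrom, call.pos, call.pos
            ):
                reason = RejectionReason.REPEAT
        if reason is not None:
            reasons[reason.value] += 1
            continue
        sub = None
        if call.var_class == "SNM":
            sub = classify_substitution(call.ref, call.alt)
        kept.append(
            MutationRecord(
                call.line_id, call.chrom, call.pos, call.ref, call.alt,
                call.var_class, sub,
            )
        )
    return kept, reasons


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------

def classify_substitution(ref: str, alt: str) -> str:
    """Strand-collapsed class of a substitution (e.g. C>T -> "G:C>A:T")."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"bases must be A/C/G/T, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in ("T", "C"):  # collapse to the A/G strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    ref_pair = {"A": "A:T", "G": "G:C"}[ref]
    alt_pair = {"A": "A:T", "G": "G:C", "T": "T:A", "C": "C:G"}[alt]
    return f"{ref_pair}>{alt_pair}"


def spectrum_summary(
    records: list[MutationRecord], at_gc_transitions_only: bool = True
) -> MutationSpectrum:
    """Aggregate SNM records into a spectrum with Ts/Tv and AT/GC bias.

    Ts/Tv = transitions / transversions (NaN when no transversions).  The
    AT/GC bias defaults to the transition-class ratio
    G:C>A:T / A:T>G:C; ``at_gc_transitions_only=False`` instead uses all
    GC-losing over all AT-losing classes.
    """
    counts = {c: 0 for c in ALL_CLASSES}
    for r in records:
        if r.substitution_class is not None:
            counts[r.substitution_class] += 1
    n_ts = sum(counts[c] for c in TRANSITION_CLASSES)
    n_tv = sum(counts[c] for c in TRANSVERSION_CLASSES)
    ts_tv = n_ts / n_tv if n_tv else float("nan")
    if at_gc_transitions_only:
        num, den = counts["G:C>A:T"], counts["A:T>G:C"]
    else:
        num = counts["G:C>A:T"] + counts["G:C>T:A"]
        den = counts["A:T>G:C"] + counts["A:T>C:G"]
    at_gc = num / den if den else float("nan")
    return MutationSpectrum(counts=counts, ts_tv=ts_tv, at_gc_bias=at_gc)


def mutation_rate(
    n_mutations: int, generations: float, genome_size: float = GENOME_SIZE_BP
) -> float:
    """Mutations per bp per generation: n / (generations x genome size)."""
    if generations <= 0 or genome_size <= 0:
        raise ValueError("generations and genome_size must be positive")
    return n_mutations / (generations * genome_size)


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SvRecord:
    """One structural-variant record from a long-read caller."""

    line_id: str
    chrom: str
    start: int
    end: int
    kind: str  # DEL | INS | other
    length: int
    read_support: int
    quality: float
    precise: bool
    strand_bias: bool

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("SV length must be >= 0")


def filter_structural_variants(
    records: list[SvRecord],
    ancestor_records: list[SvRecord],
    all_line_records: list[SvRecord] | None = None,
) -> list[SvRecord]:
    """Keep precise, unbiased SVs >= 50 bp with support >= 10 and quality >= 30
    that are absent from the ancestor and not at identical coordinates in
    every line.
    """
    if all_line_records is None:
        all_line_records = records
    ancestor_keys = {(r.chrom, r.start, r.end, r.kind) for r in ancestor_records}
    lines_by_key: dict[tuple, set[str]] = {}
    for r in all_line_records:
        lines_by_key.setdefault((r.chrom, r.start, r.end, r.kind), set()).add(r.line_id)
    n_lines = len({r.line_id for r in all_line_records})
    kept = []
    for r in records:
        key = (r.chrom, r.start, r.end, r.kind)
        if not r.precise or r.strand_bias:
            continue
        if r.length < 50 or r.read_support < 10 or r.quality < 30:
            continue
        if key in ancestor_keys:
            continue
        if n_lines >= 2 and len(lines_by_key.get(key, ())) >= n_lines:
            continue
        kept.append(r)
    return kept
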
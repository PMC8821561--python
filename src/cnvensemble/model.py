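"""Core domain types and reciprocal-overlap interval algebra.

Copy-number variant (CNV) call sets from different short-read WGS callers
are compared throughout this package with *reciprocal overlap* (RO): the
length of the intersection of two intervals divided by the length of the
longer of the two.  Two calls "agree" when their RO clears a threshold
(0.5 for the sharing rule, 0.75 for same-signal intersection), which is
the bedtools ``intersect -r -f`` semantics commonly used for SV call-set
comparison.

Coordinates are 0-based half-open internally.  VCF records (1-based POS,
INFO END) are converted at the I/O boundary; for symbolic SV records the
convention is ``start = POS`` and ``end = END`` so that
``length = END - POS``, matching the span bedtools sees after VCF-to-BED
conversion.  Contig names are normalized (``chr`` prefix stripped by
default).

Matching between two call sets is greedy one-to-one: candidate pairs at
or above the RO threshold are accepted in decreasing RO order with
deterministic tie-breaks, and each call participates in at most one
pair.  Because lowering the threshold only appends candidates to the end
of the processing order, the accepted pair set is monotone in the
threshold (raising ``ro_min`` never adds a pair).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

from .exceptions import ValidationError

#: Minimum CNV length in bp: structural variants are events larger than
#: ~50 bp; smaller records are rejected at construction by default.
DEFAULT_MIN_SIZE = 50


class SvType(str, Enum):
    """CNV class: deletion (copy loss) or duplication (copy gain)."""

    DEL = "DEL"
    DUP = "DUP"

    @property
    def opposite(self) -> "SvType":
        return SvType.DUP if self is SvType.DEL else SvType.DEL


class Genotype(str, Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"

    @property
    def non_reference(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)


class SignalClass(str, Enum):
    """Detection signal a caller relies on.

    Paired-end/split-read callers (Delly, Manta) locate breakpoints at
    base-pair resolution from discordant pairs and split reads;
    coverage-based callers (CNVnator, ERDS) infer CNVs from binned
    depth of coverage and are precise only up to the bin size.
    """

    PAIRED_END = "paired_end"
    COVERAGE = "coverage"


def normalize_chrom(name: str, style: str = "strip") -> str:
    """Normalize a contig name (``style``: ``strip`` or ``add`` the chr prefix)."""
    name = str(name)
    if style == "strip":
        return name[3:] if name.lower().startswith("chr") else name
    if style == "add":
        return name if name.lower().startswith("chr") else f"chr{name}"
    raise ValidationError(f"unknown chrom style {style!r}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValidationError(f"end must exceed start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases (0 if disjoint or on different contigs)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.start}-{self.end}"


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Reciprocal overlap of two intervals.

    ``min(o/len(a), o/len(b))`` where ``o`` is the length of the
    intersection; 0.0 for disjoint intervals or different contigs, 1.0
    iff the intervals are identical.  Symmetric in its arguments.
    """
    o = a.overlap_bp(b)
    if o == 0:
        return 0.0
    return o / max(a.length, b.length)


@dataclass(frozen=True)
class CallerProfile:
    """Identity and behaviour class of one CNV caller.

    ``merge_priority`` ranks callers for choosing representative
    coordinates when calls are merged: lower rank wins.  The default
    order places the base-pair-precise paired-end callers ahead of the
    bin-limited coverage callers.
    """

    id: str
    signal_class: SignalClass
    breakpoint_precision_bp: int = 0
    merge_priority: int = 0

    def __post_init__(self) -> None:
        if self.breakpoint_precision_bp < 0:
            raise ValidationError("breakpoint_precision_bp must be >= 0")


#: Default caller roster mirroring the four-caller ensemble this package
#: targets: Manta and Delly (paired-end/split-read), ERDS and CNVnator
#: (depth of coverage, bin size ~100 bp).
DEFAULT_PROFILES: dict[str, CallerProfile] = {
    p.id: p
    for p in (
        CallerProfile("manta", SignalClass.PAIRED_END, 0, 0),
        CallerProfile("delly", SignalClass.PAIRED_END, 0, 1),
        CallerProfile("erds", SignalClass.COVERAGE, 100, 2),
        CallerProfile("cnvnator", SignalClass.COVERAGE, 100, 3),
    )
}


_id_counter = itertools.count()


def _auto_id(caller: str, sample: str, iv: GenomicInterval, svtype: SvType) -> str:
    return f"{caller}:{sample}:{iv.chrom}:{iv.start}-{iv.end}:{svtype.value}:{next(_id_counter)}"


@dataclass(frozen=True)
class CnvCall:
    """One deletion or duplication call with provenance.

    ``sources`` records the (caller id, interval) of every original call
    supporting this record; a freshly parsed call lists itself, a merged
    record lists every member of its merge group.  Quality fields
    (``pe_support_fraction``, ``sr_support_fraction``, ``adjusted_p``)
    are populated only where the caller dialect provides them.
    """

    interval: GenomicInterval
    svtype: SvType
    caller: str
    sample: str
    pe_support_fraction: float | None = None
    sr_support_fraction: float | None = None
    adjusted_p: float | None = None
    genotype: Genotype | None = None
    sources: tuple[tuple[str, GenomicInterval], ...] = ()
    id: str = ""

    def __post_init__(self) -> None:
        for name in ("pe_support_fraction", "sr_support_fraction", "adjusted_p"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} out of [0,1]: {v}")
        if not self.sources:
            object.__setattr__(self, "sources", ((self.caller, self.interval),))
        if not self.id:
            object.__setattr__(
                self, "id", _auto_id(self.caller, self.sample, self.interval, self.svtype)
            )

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def source_callers(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c, _ in self.sources:
            seen.setdefault(c)
        return tuple(seen)

    def with_sources(self, extra: Iterable[tuple[str, GenomicInterval]]) -> "CnvCall":
        return replace(self, sources=self.sources + tuple(extra))

    def validate_size(self, min_size: int = DEFAULT_MIN_SIZE) -> "CnvCall":
        if self.length < min_size:
            raise ValidationError(
                f"call {self.id} length {self.length} below minimum size {min_size}"
            )
        return self


def _sort_key(call: CnvCall) -> tuple[str, int, int]:
    return (call.interval.chrom, call.interval.start, call.interval.end)


@dataclass
class CallSet:
    """Ordered collection of calls for one sample from one caller or strategy.

    Calls are kept sorted by (chrom, start, end); use :meth:`build` to
    sort arbitrary input.  Constructing with unsorted calls or mixed
    sample ids raises.
    """

    sample: str
    origin: str
    calls: list[CnvCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.calls, self.calls[1:]):
            if _sort_key(prev) > _sort_key(cur):
                raise ValidationError(
                    f"CallSet {self.origin!r} not sorted at {cur.id}"
                )
        for c in self.calls:
            if c.sample != self.sample:
                raise ValidationError(
                    f"call {c.id} sample {c.sample!r} != CallSet sample {self.sample!r}"
                )

    @classmethod
    def build(cls, sample: str, origin: str, calls: Iterable[CnvCall]) -> "CallSet":
        return cls(sample, origin, sorted(calls, key=_sort_key))

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[CnvCall]:
        return iter(self.calls)

    def __getitem__(self, i: int) -> CnvCall:
        return self.calls[i]

    def ids(self) -> set[str]:
        return {c.id for c in self.calls}

    def subset(self, keep: Iterable[CnvCall], origin: str | None = None) -> "CallSet":
        return CallSet.build(self.sample, origin or self.origin, keep)


@dataclass(frozen=True)
class MatchPair:
    """One accepted match between a call of the left and right set."""

    left: CnvCall
    right: CnvCall
    ro: float


@dataclass
class MatchResult:
    pairs: list[MatchPair]
    unmatched_left: list[CnvCall]
    unmatched_right: list[CnvCall]

    @property
    def matched_left_ids(self) -> set[str]:
        return {p.left.id for p in self.pairs}

    @property
    def matched_right_ids(self) -> set[str]:
        return {p.right.id for p in self.pairs}


class CallIndex:
    """Per-contig interval index over a set of calls (or bare intervals)."""

    def __init__(self, calls: Iterable[CnvCall] | CallSet):
        self._trees: dict[str, IntervalTree] = {}
        for c in calls:
            iv = c.interval
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, c)

    def query(self, interval: GenomicInterval) -> list[CnvCall]:
        """All calls whose intervals intersect ``interval`` (>= 1 shared bp)."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(interval.start, interval.end)]
        hits.sort(key=lambda c: (c.interval.start, c.interval.end, c.id))
        return hits


def build_index(calls: Iterable[CnvCall] | CallSet) -> CallIndex:
    """Build an overlap-query index over a call set."""
    return CallIndex(calls)


def match_sets(
    a: CallSet,
    b: CallSet,
    ro_min: float,
    same_type: bool = True,
) -> MatchResult:
    """Greedy one-to-one matching of two call sets by reciprocal overlap.

    Candidate pairs with RO >= ``ro_min`` (and equal svtype when
    ``same_type``) are accepted in decreasing RO order; ties broken by
    the leftmost left call, then the leftmost right call.  Each call
    appears in at most one pair.

    Comparing call sets from different samples (e.g. against a truth
    set) is allowed but warned about.
    """
    if not (0.0 < ro_min <= 1.0):
        raise ValidationError(f"ro_min must be in (0, 1], got {ro_min}")
    if a.sample != b.sample:
        warnings.warn(
            f"matching call sets from different samples ({a.sample!r} vs {b.sample!r})",
            stacklevel=2,
        )
    index_b = build_index(b)
    pos_b = {c.id: i for i, c in enumerate(b)}
    candidates: list[tuple[float, int, int, CnvCall, CnvCall]] = []
    for ai, ca in enumerate(a):
        for cb in index_b.query(ca.interval):
            if same_type and ca.svtype != cb.svtype:
                continue
            ro = reciprocal_overlap(ca.interval, cb.interval)
            if ro >= ro_min:
                candidates.append((ro, ai, pos_b[cb.id], ca, cb))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[MatchPair] = []
    for ro, ai, bi, ca, cb in candidates:
        if ai in used_a or bi in used_b:
            continue
        used_a.add(ai)
        used_b.add(bi)
        pairs.append(MatchPair(ca, cb, ro))
    unmatched_a = [c for i, c in enumerate(a) if i not in used_a]
    unmatched_b = [c for i, c in enumerate(b) if i not in used_b]
    return MatchResult(pairs, unmatched_a, unmatched_b)


@dataclass(frozen=True)
class TrackRecord:
    """One record of a genomic annotation or population-SV track."""

    interval: GenomicInterval
    svtype: SvType | None = None
    af: float | None = None
    name: str | None = None


class Track:
    """Interval track (blacklist, exons, population SVs...) with overlap queries."""

    def __init__(self, records: Iterable[TrackRecord], name: str = "track"):
        self.name = name
        self.records = sorted(
            records, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end)
        )
        self._trees: dict[str, IntervalTree] = {}
        for r in self.records:
            self._trees.setdefault(r.interval.chrom, IntervalTree()).addi(
                r.interval.start, r.interval.end, r
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TrackRecord]:
        return iter(self.records)

    def query(self, interval: GenomicInterval, min_bp: int = 1) -> list[TrackRecord]:
        """Track records sharing at least ``min_bp`` bases with ``interval``."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = [
            h.data
            for h in tree.overlap(interval.start, interval.end)
            if h.data.interval.overlap_bp(interval) >= min_bp
        ]
        hits.sort(key=lambda r: (r.interval.start, r.interval.end))
        return hits
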
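"""Per-call-set quality filters.

Every filter is a contractive transformation: it returns a subset of
its input together with a :class:`FilterReport` that accounts for every
input call (retained + removed == input) and records a reason for each
removal.  Filters that rely on optional metadata (support fractions,
adjusted p, genotype) follow explicit missing-field conventions:
quality filters retain calls lacking the field (the filter is simply
not applicable) and flag them, while the regenotyping filter removes
calls with missing genotype because genotype evidence is exactly what
it demands.

The filters implement the quality rules used to clean single-caller CNV
call sets before ensemble combination:

- ``delamp``: drop loci a paired-end caller labels both gain and loss;
- read-support fraction > 0.3 on either the paired-end or split-read
  channel (Delly-style callers);
- adjusted p value < 0.5 (CNVnator-style coverage callers);
- confirmation by the other caller of the same signal class at 50% or
  75% reciprocal overlap;
- non-reference genotype after regenotyping;
- population allele frequency <= 5% against a gnomAD-SV-style track;
- size/type rules and region include/exclude tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .exceptions import ConfigError, InputError
from .model import (
    CallSet,
    CnvCall,
    Genotype,
    SignalClass,
    SvType,
    Track,
    build_index,
    match_sets,
    reciprocal_overlap,
)


@dataclass
class FilterReport:
    """Accounting for one filter application."""

    filter_name: str
    n_input: int
    n_retained: int
    removed: list[tuple[str, str]] = field(default_factory=list)  # (call id, reason)
    not_applicable: list[str] = field(default_factory=list)  # retained, field missing

    def __post_init__(self) -> None:
        assert self.n_retained + len(self.removed) == self.n_input, (
            f"{self.filter_name}: {self.n_retained} retained + "
            f"{len(self.removed)} removed != {self.n_input} input"
        )

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def to_dict(self) -> dict:
        return {
            "filter": self.filter_name,
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "n_not_applicable": len(self.not_applicable),
            "removed": [{"id": i, "reason": r} for i, r in self.removed],
        }


def _report(name: str, calls: CallSet, kept: list[CnvCall],
            removed: list[tuple[str, str]], na: list[str] | None = None,
            origin: str | None = None) -> tuple[CallSet, FilterReport]:
    out = calls.subset(kept, origin=origin)
    return out, FilterReport(name, len(calls), len(out), removed, na or [])


def filter_delamp(
    calls: CallSet,
    ro_min: float = 0.75,
    signal_class: SignalClass | None = None,
) -> tuple[CallSet, FilterReport]:
    """Remove loci simultaneously labeled gain and deletion ("delamp").

    Within one caller's call set, any call matched by an opposite-type
    call at reciprocal overlap >= ``ro_min`` is removed — both members
    of every such cross-type match, so the output contains no DEL/DUP
    pair at or above the threshold.  Intended for paired-end callers
    (which emit both types from the same discordant-pair signal); a
    warning is issued when applied to a coverage caller's set.
    """
    if signal_class is SignalClass.COVERAGE:
        warnings.warn("delamp is intended for paired-end caller call sets", stacklevel=2)
    index = build_index(calls)
    kept: list[CnvCall] = []
    removed: list[tuple[str, str]] = []
    for call in calls:
        opposite = [
            other
            for other in index.query(call.interval)
            if other.svtype is call.svtype.opposite
            and reciprocal_overlap(call.interval, other.interval) >= ro_min
        ]
        if opposite:
            removed.append((call.id, f"delamp:opposite-type-match@ro>={ro_min}"))
        else:
            kept.append(call)
    return _report("delamp", calls, kept, removed)


def filter_support_fraction(
    calls: CallSet, min_frac: float = 0.3
) -> tuple[CallSet, FilterReport]:
    """Keep calls whose PE or SR support fraction exceeds ``min_frac``.

    A call passes when at least one of the two fractions is strictly
    above the threshold.  Calls carrying neither field are retained and
    flagged not-applicable.
    """
    kept, removed, na = [], [], []
    for call in calls:
        pe, sr = call.pe_support_fraction, call.sr_support_fraction
        if pe is None and sr is None:
            kept.append(call)
            na.append(call.id)
        elif (pe is not None and pe > min_frac) or (sr is not None and sr > min_frac):
            kept.append(call)
        else:
            removed.append((call.id, f"support_fraction<= {min_frac}"))
    return _report("support_fraction", calls, kept, removed, na)


def filter_adjusted_p(
    calls: CallSet, max_p: float = 0.5
) -> tuple[CallSet, FilterReport]:
    """Keep coverage-caller calls with adjusted p value < ``max_p``.

    Calls without the field are retained and flagged not-applicable.
    """
    kept, removed, na = [], [], []
    for call in calls:
        if call.adjusted_p is None:
            kept.append(call)
            na.append(call.id)
        elif call.adjusted_p < max_p:
            kept.append(call)
        else:
            removed.append((call.id, f"adjusted_p>={max_p}"))
    return _report("adjusted_p", calls, kept, removed, na)


def filter_same_signal_confirmation(
    calls: CallSet,
    partner: CallSet,
    ro_min: float = 0.5,
    partner_signal_matches: bool = True,
) -> tuple[CallSet, FilterReport]:
    """Keep calls confirmed by the same-signal partner caller.

    A call is retained iff it is matched (same svtype, greedy
    one-to-one) by a call of ``partner`` at reciprocal overlap >=
    ``ro_min``.  Pass ``partner_signal_matches=False`` to acknowledge a
    cross-signal partner (warned, since confirmation is meant to pair
    Delly with Manta and ERDS with CNVnator).
    """
    if not partner_signal_matches:
        warnings.warn(
            "same-signal confirmation applied with a partner of a different signal class",
            stacklevel=2,
        )
    result = match_sets(calls, partner, ro_min, same_type=True)
    matched = result.matched_left_ids
    kept = [c for c in calls if c.id in matched]
    removed = [
        (c.id, f"no {partner.origin} match @ro>={ro_min}")
        for c in calls
        if c.id not in matched
    ]
    return _report("same_signal_confirmation", calls, kept, removed)


def filter_genotype_nonref(
    calls: CallSet, sample: str | None = None
) -> tuple[CallSet, FilterReport]:
    """Keep calls regenotyped as non-reference (het or hom-alt).

    Hom-ref calls are removed; calls with a missing genotype are removed
    too (conservatively) and counted under their own reason.  A call
    with no genotype information at all is a hard error: this filter is
    only meaningful after regenotyping.
    """
    if sample is not None and calls.sample != sample:
        raise InputError(
            f"call set is for sample {calls.sample!r}, not requested {sample!r}"
        )
    ungenotyped = [c.id for c in calls if c.genotype is None]
    if ungenotyped:
        raise InputError(
            f"{len(ungenotyped)} calls carry no genotype (e.g. {ungenotyped[:3]}); "
            "regenotype before applying the non-reference filter"
        )
    kept, removed = [], []
    for call in calls:
        if call.genotype.non_reference:
            kept.append(call)
        elif call.genotype is Genotype.MISSING:
            removed.append((call.id, "genotype:missing"))
        else:
            removed.append((call.id, "genotype:hom-ref"))
    return _report("genotype_nonref", calls, kept, removed)


def filter_frequency(
    calls: CallSet,
    population: Track,
    af_max: float = 0.05,
    ro_min: float = 0.5,
    same_type: bool = True,
) -> tuple[CallSet, FilterReport]:
    """Remove calls common in a population SV reference.

    A call is removed iff the maximal allele frequency among population
    records overlapping it at reciprocal overlap >= ``ro_min`` (same
    svtype unless ``same_type=False``) strictly exceeds ``af_max``.
    Calls with no qualifying overlap, or only AF-less overlaps, are
    retained.
    """
    kept, removed = [], []
    for call in calls:
        max_af = None
        for rec in population.query(call.interval):
            if same_type and rec.svtype is not None and rec.svtype is not call.svtype:
                continue
            if rec.af is None:
                continue
            if reciprocal_overlap(call.interval, rec.interval) >= ro_min:
                max_af = rec.af if max_af is None else max(max_af, rec.af)
        if max_af is not None and max_af > af_max:
            removed.append((call.id, f"population_af={max_af:.4g}>{af_max}"))
        else:
            kept.append(call)
    return _report("frequency", calls, kept, removed)


@dataclass(frozen=True)
class SizeTypeRule:
    """One size/type rule: first matching rule decides keep/drop."""

    svtype: SvType | None  # None matches both types
    min_size: int
    max_size: float  # exclusive; may be math.inf
    keep: bool

    def __post_init__(self) -> None:
        if self.min_size >= self.max_size:
            raise ConfigError(f"rule min_size {self.min_size} >= max_size {self.max_size}")

    def matches(self, call: CnvCall) -> bool:
        if self.svtype is not None and call.svtype is not self.svtype:
            return False
        return self.min_size <= call.length < self.max_size


def filter_size_and_type(
    calls: CallSet, rules: list[SizeTypeRule]
) -> tuple[CallSet, FilterReport]:
    """Apply ordered size/type keep/drop rules (no matching rule: retain).

    The canonical use is dropping large gains (e.g. DUP > 50 kb, which
    are rarely supported on visual inspection); off unless configured.
    """
    kept, removed = [], []
    for call in calls:
        decision = True
        reason = ""
        for rule in rules:
            if rule.matches(call):
                decision = rule.keep
                reason = (
                    f"size_type_rule:{rule.svtype.value if rule.svtype else 'ANY'}"
                    f"[{rule.min_size},{rule.max_size})"
                )
                break
        if decision:
            kept.append(call)
        else:
            removed.append((call.id, reason))
    return _report("size_and_type", calls, kept, removed)


def filter_region(
    calls: CallSet,
    track: Track,
    mode: str = "exclude_overlapping",
    min_bp: int = 1,
) -> tuple[CallSet, FilterReport]:
    """Include/exclude calls by overlap with a genomic track.

    Overlap is decided by any single track record sharing >= ``min_bp``
    bases with the call (bedtools-intersect semantics) — deliberately
    *not* reciprocal overlap, which is reserved for call-to-call
    comparison.  ``mode`` is ``exclude_overlapping`` (blacklists) or
    ``require_overlapping`` (e.g. exonic restriction).
    """
    if mode not in ("exclude_overlapping", "require_overlapping"):
        raise ConfigError(f"unknown region mode {mode!r}")
    kept, removed = [], []
    for call in calls:
        hit = bool(track.query(call.interval, min_bp=min_bp))
        keep = (not hit) if mode == "exclude_overlapping" else hit
        if keep:
            kept.append(call)
        else:
            removed.append(
                (call.id, f"region:{mode}:{track.name}")
            )
    return _report(f"region:{mode}", calls, kept, removed)
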
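"""Ensemble combination strategies for multi-caller CNV call sets.

Two base strategies are provided:

``union``
    Join the calls of all callers, collapsing same-type calls that
    match at reciprocal overlap >= ``dedup_ro`` (default 0.5, the
    sharing threshold) into one record.  Collapsing is iterative greedy
    in caller-priority order: the running merged set is matched against
    each next caller's set; matches add provenance to the existing
    record, non-matches are appended.  Representative coordinates
    therefore always come from the highest-priority caller that
    reported the event.

``intersection_union``
    Clean each paired-end caller's set with the delamp filter, then
    intersect the two paired-end callers and, separately, the two
    coverage callers at reciprocal overlap >= ``intersect_ro`` (default
    0.75), and finally join the two intersection pools with the union
    rule.  Every emitted call is supported by both members of at least
    one same-signal caller pair.

Either strategy may be followed by non-reference genotype filtering of
an externally regenotyped VCF (the ``*_sv2`` variants): the toolkit
writes candidate calls for the regenotyper and consumes its genotyped
output; the regenotyper itself is external.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ConfigError, InputError
from .filters import FilterReport, filter_delamp, filter_genotype_nonref
from .model import CallSet, CnvCall, Genotype, match_sets

STRATEGIES = ("union", "intersection_union", "union_sv2", "intersection_union_sv2")


@dataclass(frozen=True)
class StrategyConfig:
    """Caller pairing, thresholds and merge priority for the strategies.

    ``priority`` ranks callers for representative coordinates on merge;
    the default puts the base-pair-precise paired-end callers first
    (Manta > Delly > ERDS > CNVnator).
    """

    pe_pair: tuple[str, str] = ("delly", "manta")
    cov_pair: tuple[str, str] = ("erds", "cnvnator")
    intersect_ro: float = 0.75
    dedup_ro: float = 0.5
    delamp_ro: float = 0.75
    priority: tuple[str, ...] = ("manta", "delly", "erds", "cnvnator")

    def __post_init__(self) -> None:
        ids = (*self.pe_pair, *self.cov_pair)
        if len(set(ids)) != 4:
            raise ConfigError(f"the four caller ids must be distinct, got {ids}")
        missing = [c for c in ids if c not in self.priority]
        if missing:
            raise ConfigError(f"priority list misses callers {missing}")
        for name in ("intersect_ro", "dedup_ro", "delamp_ro"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"{name} must be in (0, 1], got {v}")

    def rank(self, caller: str) -> int:
        try:
            return self.priority.index(caller)
        except ValueError:
            return len(self.priority)


def _fill_fields(primary: CnvCall, other: CnvCall) -> CnvCall:
    """Carry quality fields from both sources; the primary call wins."""
    updates = {}
    for name in ("pe_support_fraction", "sr_support_fraction", "adjusted_p", "genotype"):
        if getattr(primary, name) is None and getattr(other, name) is not None:
            updates[name] = getattr(other, name)
    if updates:
        from dataclasses import replace

        primary = replace(primary, **updates)
    return primary


def intersect_pair(
    a: CallSet,
    b: CallSet,
    ro_min: float,
    cfg: StrategyConfig | None = None,
) -> CallSet:
    """Same-type intersection of two call sets at reciprocal overlap ``ro_min``.

    One output call per accepted match; coordinates come from the
    higher-merge-priority caller's member (ties: the left set), both
    source calls enter the provenance, and quality fields are carried
    from both where present.
    """
    if a.sample != b.sample:
        raise InputError(
            f"intersect_pair requires one sample, got {a.sample!r} and {b.sample!r}"
        )
    cfg = cfg or StrategyConfig()
    result = match_sets(a, b, ro_min, same_type=True)
    out: list[CnvCall] = []
    for pair in result.pairs:
        left, right = pair.left, pair.right
        if cfg.rank(right.caller) < cfg.rank(left.caller):
            rep, other = right, left
        else:
            rep, other = left, right
        merged = _fill_fields(rep, other).with_sources(
            src for src in other.sources if src not in rep.sources
        )
        out.append(merged)
    return CallSet.build(a.sample, f"intersect({a.origin},{b.origin})", out)


def combine_union(
    callsets: list[CallSet],
    dedup_ro: float = 0.5,
    cfg: StrategyConfig | None = None,
) -> CallSet:
    """Join call sets, collapsing same-type matches at RO >= ``dedup_ro``.

    Sets are processed in merge-priority order (per ``cfg``, falling
    back to the given order for unknown origins); a single input set is
    returned unchanged apart from its origin label.
    """
    if not callsets:
        return CallSet("unknown", "union", [])
    samples = {cs.sample for cs in callsets}
    if len(samples) != 1:
        raise InputError(f"union requires one sample, got {sorted(samples)}")
    sample = callsets[0].sample
    cfg = cfg or StrategyConfig()
    ordered = sorted(
        enumerate(callsets), key=lambda t: (cfg.rank(t[1].origin), t[0])
    )
    merged = list(ordered[0][1].calls)
    for _, nxt in ordered[1:]:
        current = CallSet.build(sample, "union", merged)
        result = match_sets(current, nxt, dedup_ro, same_type=True)
        absorbed = {p.left.id: p.right for p in result.pairs}
        merged = [
            (
                _fill_fields(c, absorbed[c.id]).with_sources(
                    s for s in absorbed[c.id].sources if s not in c.sources
                )
                if c.id in absorbed
                else c
            )
            for c in current
        ]
        merged.extend(result.unmatched_right)
    return CallSet.build(sample, "union", merged)


def combine_intersection_union(
    delly: CallSet,
    manta: CallSet,
    erds: CallSet,
    cnvnator: CallSet,
    cfg: StrategyConfig | None = None,
) -> tuple[CallSet, list[FilterReport]]:
    """The intersection-union strategy.

    delamp(PE caller) for both paired-end sets, intersect the paired-end
    pair and the coverage pair at ``cfg.intersect_ro``, then join the
    two pools at ``cfg.dedup_ro``.  Returns the combined set and the
    delamp filter reports.
    """
    cfg = cfg or StrategyConfig()
    by_id = {delly.origin: delly, manta.origin: manta,
             erds.origin: erds, cnvnator.origin: cnvnator}
    try:
        pe_a, pe_b = (by_id[c] for c in cfg.pe_pair)
        cov_a, cov_b = (by_id[c] for c in cfg.cov_pair)
    except KeyError as e:
        raise ConfigError(
            f"strategy pairs name caller {e} but call-set origins are {sorted(by_id)}"
        )
    reports: list[FilterReport] = []
    pe_a, r1 = filter_delamp(pe_a, cfg.delamp_ro)
    pe_b, r2 = filter_delamp(pe_b, cfg.delamp_ro)
    reports += [r1, r2]
    pe_pool = intersect_pair(pe_a, pe_b, cfg.intersect_ro, cfg)
    cov_pool = intersect_pair(cov_a, cov_b, cfg.intersect_ro, cfg)
    combined = combine_union([pe_pool, cov_pool], cfg.dedup_ro, cfg)
    out = CallSet.build(combined.sample, "intersection_union", combined.calls)
    return out, reports


def apply_genotypes(calls: CallSet, genotyped: CallSet) -> CallSet:
    """Transfer genotypes from a regenotyped call set onto candidates.

    Records are matched by call id first, then by exact
    (chrom, start, end, svtype); candidates with no genotyped record
    get a MISSING genotype (which the non-reference filter removes).
    """
    from dataclasses import replace

    by_id = {c.id: c for c in genotyped}
    by_key = {
        (c.interval.chrom, c.interval.start, c.interval.end, c.svtype): c
        for c in genotyped
    }
    out = []
    for c in calls:
        match = by_id.get(c.id) or by_key.get(
            (c.interval.chrom, c.interval.start, c.interval.end, c.svtype)
        )
        gt = match.genotype if match is not None and match.genotype is not None else Genotype.MISSING
        out.append(replace(c, genotype=gt))
    return CallSet.build(calls.sample, calls.origin, out)


@dataclass
class StrategyResult:
    calls: CallSet
    reports: list[FilterReport] = field(default_factory=list)


def run_strategy(
    name: str,
    inputs: dict[str, CallSet],
    cfg: StrategyConfig | None = None,
    genotyped: CallSet | None = None,
) -> StrategyResult:
    """Run a named combination strategy over per-caller call sets.

    ``inputs`` maps caller id -> CallSet and must cover the four callers
    of ``cfg`` for the intersection-union variants.  The ``*_sv2``
    variants require ``genotyped``, the call set read from the external
    regenotyper's output VCF, and end with the non-reference genotype
    filter.
    """
    if name not in STRATEGIES:
        raise ConfigError(f"unknown strategy {name!r}; known: {STRATEGIES}")
    cfg = cfg or StrategyConfig()
    wants_genotype = name.endswith("_sv2")
    if wants_genotype and genotyped is None:
        raise ConfigError(f"strategy {name!r} requires a regenotyped call set")
    reports: list[FilterReport] = []
    if name.startswith("intersection_union"):
        needed = (*cfg.pe_pair, *cfg.cov_pair)
        missing = [c for c in needed if c not in inputs]
        if missing:
            raise ConfigError(
                f"intersection-union needs call sets for {needed}, missing {missing}"
            )
        by = {cid: inputs[cid] for cid in needed}
        combined, reports = combine_intersection_union(
            by[cfg.pe_pair[0]], by[cfg.pe_pair[1]],
            by[cfg.cov_pair[0]], by[cfg.cov_pair[1]], cfg,
        )
    else:
        combined = combine_union(list(inputs.values()), cfg.dedup_ro, cfg)
    if wants_genotype:
        assert genotyped is not None
        combined = apply_genotypes(combined, genotyped)
        combined, gt_report = filter_genotype_nonref(combined)
        reports.append(gt_report)
        combined = CallSet.build(combined.sample, name, combined.calls)
    return StrategyResult(combined, reports)
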
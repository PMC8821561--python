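"""Benchmarking of filters and strategies against labeled truth.

Two evaluation modes mirror the two kinds of reference data available
for CNV ensemble pipelines:

- :func:`evaluate_filter` scores a transformation against a *labeled
  call pool*: every call carries a visual-inspection-style label
  (TRUE_POSITIVE / FALSE_POSITIVE / SHARED / DOUBTFUL); sensitivity is
  the fraction of true positives retained and specificity the fraction
  of false positives removed.  SHARED and DOUBTFUL calls are excluded
  from the 2x2 table and reported alongside.  Note these statistics are
  defined over the labeled pool, not genome-wide.

- :func:`detection_rate` scores candidate call sets against an
  independent truth set (aCGH-style tables, reference-sample truth) by
  reciprocal-overlap matching at a configurable threshold (default
  0.5), reporting per-set and any-set detection fractions plus the
  best observed RO per truth call for near-miss diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigError, InputError
from .model import CallSet, CnvCall, build_index, match_sets, reciprocal_overlap


class TruthLabel(str, Enum):
    """Visual-classification label taxonomy for benchmark pools.

    SHARED marks calls with the same signal in the index case and both
    parents (possible alignment artifacts); DOUBTFUL marks calls where
    no visual conclusion could be reached.  Both are excluded from
    contingency statistics.
    """

    TRUE_POSITIVE = "TRUE_POSITIVE"
    FALSE_POSITIVE = "FALSE_POSITIVE"
    SHARED = "SHARED"
    DOUBTFUL = "DOUBTFUL"


@dataclass
class BenchmarkReport:
    """2x2 contingency counts and derived statistics for one transform.

    sensitivity = tp_kept / (tp_kept + tp_removed)
    specificity = fp_removed / (fp_kept + fp_removed)
    ppv         = tp_kept / (tp_kept + fp_kept)   (None when empty)
    accuracy    = (tp_kept + fp_removed) / total
    ppv_ratio   = ppv / baseline ppv of the unfiltered pool
    """

    tp_kept: int
    tp_removed: int
    fp_kept: int
    fp_removed: int
    n_shared: int = 0
    n_doubtful: int = 0

    @property
    def total(self) -> int:
        return self.tp_kept + self.tp_removed + self.fp_kept + self.fp_removed

    @property
    def sensitivity(self) -> float | None:
        n = self.tp_kept + self.tp_removed
        return self.tp_kept / n if n else None

    @property
    def specificity(self) -> float | None:
        n = self.fp_kept + self.fp_removed
        return self.fp_removed / n if n else None

    @property
    def ppv(self) -> float | None:
        n = self.tp_kept + self.fp_kept
        return self.tp_kept / n if n else None

    @property
    def baseline_ppv(self) -> float | None:
        n = self.total
        return (self.tp_kept + self.tp_removed) / n if n else None

    @property
    def accuracy(self) -> float | None:
        return (self.tp_kept + self.fp_removed) / self.total if self.total else None

    @property
    def ppv_ratio(self) -> float | None:
        ppv, base = self.ppv, self.baseline_ppv
        if ppv is None or base is None or base == 0:
            return None
        return ppv / base

    def to_dict(self) -> dict:
        return {
            "tp_kept": self.tp_kept,
            "tp_removed": self.tp_removed,
            "fp_kept": self.fp_kept,
            "fp_removed": self.fp_removed,
            "n_shared": self.n_shared,
            "n_doubtful": self.n_doubtful,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "accuracy": self.accuracy,
            "ppv_ratio": self.ppv_ratio,
        }


def _retained_ids(original: CallSet, output: CallSet) -> set[str]:
    """Ids of original calls surviving into ``output``.

    Plain filters preserve call ids; strategies emit merged records, so
    an original call also counts as retained when its
    (caller, interval) identity appears in an output record's
    provenance.
    """
    ids = output.ids()
    source_keys = {
        (caller, src.chrom, src.start, src.end)
        for c in output
        for caller, src in c.sources
    }
    retained = set()
    for c in original:
        if c.id in ids:
            retained.add(c.id)
        else:
            for caller, src in c.sources:
                if (caller, src.chrom, src.start, src.end) in source_keys:
                    retained.add(c.id)
                    break
    return retained


def evaluate_filter(
    labeled: CallSet,
    labels: Mapping[str, TruthLabel],
    transform: Callable[[CallSet], CallSet | tuple],
) -> BenchmarkReport:
    """Score a filter or strategy against a labeled call pool.

    ``transform`` maps a CallSet to its filtered/combined output (a
    ``(CallSet, report)`` tuple is accepted and unpacked).  Every call
    must be labeled; unlabeled calls are a hard error.
    """
    missing = [c.id for c in labeled if c.id not in labels]
    if missing:
        raise InputError(f"unlabeled calls: {missing[:10]}" +
                         (f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""))
    out = transform(labeled)
    if isinstance(out, tuple):
        out = out[0]
    if hasattr(out, "calls") and not isinstance(out, CallSet):  # StrategyResult
        out = out.calls
    retained = _retained_ids(labeled, out)
    tp_kept = tp_removed = fp_kept = fp_removed = n_shared = n_doubtful = 0
    for c in labeled:
        label = labels[c.id]
        kept = c.id in retained
        if label is TruthLabel.TRUE_POSITIVE:
            tp_kept, tp_removed = tp_kept + kept, tp_removed + (not kept)
        elif label is TruthLabel.FALSE_POSITIVE:
            fp_kept, fp_removed = fp_kept + kept, fp_removed + (not kept)
        elif label is TruthLabel.SHARED:
            n_shared += 1
        else:
            n_doubtful += 1
    return BenchmarkReport(tp_kept, tp_removed, fp_kept, fp_removed, n_shared, n_doubtful)


@dataclass
class DetectionResult:
    """Per-truth-call detection flags against one or more candidate sets."""

    truth_ids: list[str]
    detected: dict[str, dict[str, bool]] = field(default_factory=dict)  # set origin -> id -> flag
    best_ro: dict[str, float] = field(default_factory=dict)  # id -> best RO over all sets

    @property
    def per_set_fraction(self) -> dict[str, float]:
        n = len(self.truth_ids)
        return {
            origin: (sum(flags.values()) / n if n else 0.0)
            for origin, flags in self.detected.items()
        }

    def any_detected(self, truth_id: str) -> bool:
        return any(flags[truth_id] for flags in self.detected.values())

    @property
    def any_fraction(self) -> float:
        n = len(self.truth_ids)
        return sum(self.any_detected(t) for t in self.truth_ids) / n if n else 0.0


def detection_rate(
    truth: CallSet,
    candidates: Sequence[CallSet],
    ro_min: float = 0.5,
) -> DetectionResult:
    """Fraction of truth calls detected by each candidate set.

    A truth call is detected by a set iff it is matched (same svtype,
    greedy one-to-one) at reciprocal overlap >= ``ro_min``.  The best
    RO observed per truth call across all candidate calls (matched or
    not) is reported for "missed but nearly overlapping" diagnostics.
    """
    result = DetectionResult([c.id for c in truth])
    best: dict[str, float] = {c.id: 0.0 for c in truth}
    for cand in candidates:
        mr = match_sets(truth, cand, ro_min, same_type=True)
        matched = mr.matched_left_ids
        result.detected[cand.origin] = {c.id: (c.id in matched) for c in truth}
        index = build_index(cand)
        for c in truth:
            for other in index.query(c.interval):
                if other.svtype is not c.svtype:
                    continue
                ro = reciprocal_overlap(c.interval, other.interval)
                if ro > best[c.id]:
                    best[c.id] = ro
    result.best_ro = best
    return result


#: Default size-bin boundaries (bp): [50, 1 kb), [1, 5 kb), [5, 50 kb),
#: [50, 200 kb), [200 kb, inf) — the bins used throughout call-set
#: summaries; small deletions are the most reliably called, events
#: above 200 kb rarely confirm.
DEFAULT_SIZE_BINS: tuple[int, ...] = (50, 1_000, 5_000, 50_000, 200_000)


def size_bin_label(size: int, bins: Sequence[int] = DEFAULT_SIZE_BINS) -> str:
    """Left-closed bin label for a call length."""
    lo = bins[0]
    for b in bins[1:]:
        if size < b:
            return f"[{lo},{b})"
        lo = b
    return f"[{lo},inf)"


def size_bin_summary(
    calls: CallSet, bins: Sequence[int] = DEFAULT_SIZE_BINS
) -> pd.DataFrame:
    """Counts per svtype x size bin (left-closed bins, last unbounded)."""
    if list(bins) != sorted(set(bins)):
        raise ConfigError(f"size bins must be strictly increasing, got {bins}")
    labels = [size_bin_label(b, bins) for b in bins]
    table = pd.DataFrame(0, index=["DEL", "DUP"], columns=labels, dtype=int)
    for c in calls:
        table.loc[c.svtype.value, size_bin_label(c.length, bins)] += 1
    return table


@dataclass
class OverlapProfile:
    """Which other callers agree with each call, plus a summary histogram."""

    agreement: dict[str, tuple[str, frozenset[str]]]  # call id -> (origin, agreeing origins)

    @property
    def count_histogram(self) -> dict[str, dict[int, int]]:
        """Per origin: histogram of how many other callers agree."""
        hist: dict[str, dict[int, int]] = {}
        for origin, agreeing in self.agreement.values():
            h = hist.setdefault(origin, {})
            h[len(agreeing)] = h.get(len(agreeing), 0) + 1
        return hist

    @property
    def subset_histogram(self) -> dict[str, dict[frozenset, int]]:
        hist: dict[str, dict[frozenset, int]] = {}
        for origin, agreeing in self.agreement.values():
            h = hist.setdefault(origin, {})
            h[agreeing] = h.get(agreeing, 0) + 1
        return hist


def caller_overlap_profile(
    callsets: Sequence[CallSet],
    ro_min: float = 0.5,
) -> OverlapProfile:
    """For each call, the set of *other* callers with a same-type match.

    Agreement is existence-based (any call of the other set at RO >=
    ``ro_min``, many-to-many), the semantics of bedtools-style
    cross-caller sharing summaries — deliberately distinct from the
    greedy one-to-one matching used for set intersection.
    """
    if len(callsets) < 2:
        raise ConfigError("caller_overlap_profile needs at least two call sets")
    indexes = {cs.origin: build_index(cs) for cs in callsets}
    agreement: dict[str, tuple[str, frozenset[str]]] = {}
    for cs in callsets:
        for call in cs:
            agreeing = set()
            for other in callsets:
                if other.origin == cs.origin:
                    continue
                for hit in indexes[other.origin].query(call.interval):
                    if hit.svtype is call.svtype and reciprocal_overlap(
                        call.interval, hit.interval
                    ) >= ro_min:
                        agreeing.add(other.origin)
                        break
            agreement[call.id] = (cs.origin, frozenset(agreeing))
    return OverlapProfile(agreement)


def read_labels(path) -> dict[str, TruthLabel]:
    """Read a labels TSV (call id <tab> label) into a mapping."""
    labels: dict[str, TruthLabel] = {}
    from pathlib import Path

    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise InputError(f"{path}:{lineno}: expected 'id<TAB>label'")
        try:
            labels[parts[0]] = TruthLabel(parts[1])
        except ValueError:
            raise InputError(f"{path}:{lineno}: unknown label {parts[1]!r}")
    return labels


def write_labels(labels: Mapping[str, TruthLabel], path) -> None:
    from pathlib import Path

    Path(path).write_text(
        "".join(f"{cid}\t{label.value}\n" for cid, label in labels.items())
    )
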
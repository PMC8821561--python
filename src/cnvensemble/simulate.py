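"""Synthetic truth sets and per-caller observed call sets.

The simulator provides labeled fixtures for every other module: a truth
set of non-overlapping CNVs drawn on a human-autosome-scale genome, and
per-caller observed call sets generated from a configurable error model
(per svtype x size-bin sensitivity, false-positive rate per Mb,
breakpoint jitter, opposite-type mislabeling for paired-end callers,
and cohort-wide shared artifacts).

Error-model defaults emulate well-behaved versions of the four-caller
ensemble: paired-end callers report breakpoints exactly (jitter 0),
coverage callers jitter each breakpoint by a rounded normal draw with
sd 100 bp (their ~100 bp analysis bin); sensitivity 0.9 and 5 false
positives per Mb are flat across types and sizes.  Opposite-type
mislabeling and shared artifacts are off by default and enabled
explicitly when a scenario needs them.

Truth sizes are log-uniform over [1 kb, 5 Mb] by default.  The floor is
a resolution choice, not the 50 bp SV definition (which remains the
hard minimum and the configurable lower limit): bin-based coverage
callers cannot resolve sub-bin-scale events, so the regime the default
fixtures emulate — and in which the closed-form ensemble expectations
of :func:`expected_strategy_stats` hold — is calls much larger than the
breakpoint jitter.

Everything is deterministic given the seed; per-caller streams are
spawned from one root ``SeedSequence`` so adding a caller does not
perturb the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .benchmark import DEFAULT_SIZE_BINS, TruthLabel, size_bin_label
from .exceptions import ConfigError
from .model import (
    DEFAULT_MIN_SIZE,
    CallerProfile,
    CallSet,
    CnvCall,
    DEFAULT_PROFILES,
    GenomicInterval,
    SignalClass,
    SvType,
)

#: hg19-like autosome lengths (Mb, rounded) — a realistic placement
#: genome so that per-Mb false-positive rates and non-overlapping truth
#: placement behave like they would on real data.
DEFAULT_CONTIGS: tuple[tuple[str, int], ...] = tuple(
    (str(i + 1), mb * 1_000_000)
    for i, mb in enumerate(
        [249, 243, 198, 191, 181, 171, 159, 146, 141, 136, 135,
         134, 115, 107, 103, 90, 81, 78, 59, 63, 48, 51]
    )
)


@dataclass(frozen=True)
class CallerErrorModel:
    """Error model for one simulated caller.

    ``sensitivity`` is the flat per-call detection probability;
    ``sensitivity_table`` optionally overrides it per
    (svtype value, size-bin label).  ``jitter_sd_bp`` defaults by
    signal class (paired-end 0, coverage 100).  ``mislabel_prob`` is the
    probability a detected call is emitted with the opposite svtype
    (paired-end callers only; both CNV types arise from the same
    discordant-pair signal there).
    """

    profile: CallerProfile
    sensitivity: float = 0.9
    sensitivity_table: Mapping[tuple[str, str], float] | None = None
    fp_rate_per_mb: float = 5.0
    jitter_sd_bp: float | None = None
    mislabel_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "mislabel_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.fp_rate_per_mb < 0:
            raise ConfigError("fp_rate_per_mb must be >= 0")
        if self.jitter_sd_bp is not None and self.jitter_sd_bp < 0:
            raise ConfigError("jitter_sd_bp must be >= 0")
        if self.mislabel_prob > 0 and self.profile.signal_class is not SignalClass.PAIRED_END:
            raise ConfigError("opposite-type mislabeling models paired-end callers only")

    @property
    def jitter_sd(self) -> float:
        if self.jitter_sd_bp is not None:
            return self.jitter_sd_bp
        return 0.0 if self.profile.signal_class is SignalClass.PAIRED_END else 100.0

    def sensitivity_for(self, svtype: SvType, size: int,
                        bins: Sequence[int] = DEFAULT_SIZE_BINS) -> float:
        if self.sensitivity_table:
            key = (svtype.value, size_bin_label(size, bins))
            if key in self.sensitivity_table:
                return self.sensitivity_table[key]
        return self.sensitivity


def default_caller_models(**overrides) -> tuple[CallerErrorModel, ...]:
    """The four-caller default roster; ``overrides`` apply to every model."""
    return tuple(
        CallerErrorModel(profile=profile, **overrides)
        for profile in DEFAULT_PROFILES.values()
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Truth-set distribution and per-caller error models.

    ``size_range`` is the (min, max) of the log-uniform truth size
    distribution, shared by both CNV types unless ``size_range_dup``
    overrides the duplication range.  ``del_fraction`` is the DEL share
    of the type mix (deletions outnumber gains in real call sets).
    """

    contigs: tuple[tuple[str, int], ...] = DEFAULT_CONTIGS
    n_truth: int = 200
    size_range: tuple[int, int] = (1_000, 5_000_000)
    size_range_dup: tuple[int, int] | None = None
    del_fraction: float = 0.6
    callers: tuple[CallerErrorModel, ...] = field(default_factory=default_caller_models)
    shared_artifact_rate_per_mb: float = 0.0
    sample: str = "sim"
    min_size: int = DEFAULT_MIN_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ConfigError("at least one contig required")
        if not (0.0 <= self.del_fraction <= 1.0):
            raise ConfigError("del_fraction must be in [0,1]")
        for rng_ in (self.size_range, self.size_range_dup):
            if rng_ is not None and not (self.min_size <= rng_[0] < rng_[1]):
                raise ConfigError(f"invalid size range {rng_}")
        if self.shared_artifact_rate_per_mb < 0:
            raise ConfigError("shared_artifact_rate_per_mb must be >= 0")

    @property
    def genome_length(self) -> int:
        return sum(length for _, length in self.contigs)

    def size_range_for(self, svtype: SvType) -> tuple[int, int]:
        if svtype is SvType.DUP and self.size_range_dup is not None:
            return self.size_range_dup
        return self.size_range


def _draw_svtype(cfg: SimulationConfig, rng: np.random.Generator) -> SvType:
    return SvType.DEL if rng.random() < cfg.del_fraction else SvType.DUP


def _draw_size(cfg: SimulationConfig, svtype: SvType, rng: np.random.Generator) -> int:
    lo, hi = cfg.size_range_for(svtype)
    size = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
    return max(cfg.min_size, min(size, hi))


def _draw_placement(
    cfg: SimulationConfig, size: int, rng: np.random.Generator
) -> GenomicInterval | None:
    """Uniform placement over contigs that can host ``size``; None if none can."""
    fitting = [(name, length) for name, length in cfg.contigs if length > size]
    if not fitting:
        return None
    weights = np.array([length for _, length in fitting], dtype=float)
    idx = rng.choice(len(fitting), p=weights / weights.sum())
    name, length = fitting[idx]
    start = int(rng.integers(0, length - size))
    return GenomicInterval(name, start, start + size)


_MAX_PLACEMENT_ATTEMPTS = 1_000


def simulate_truth(
    cfg: SimulationConfig, seed: int | None = None
) -> CallSet:
    """Draw ``cfg.n_truth`` non-overlapping truth CNVs.

    Sizes are log-uniform per svtype, placement uniform over the
    genome, overlaps rejection-sampled away (truth calls never overlap,
    keeping downstream labels unambiguous).  Deterministic given seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    occupied: dict[str, IntervalTree] = {name: IntervalTree() for name, _ in cfg.contigs}
    calls: list[CnvCall] = []
    for i in range(cfg.n_truth):
        svtype = _draw_svtype(cfg, rng)
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            size = _draw_size(cfg, svtype, rng)
            iv = _draw_placement(cfg, size, rng)
            if iv is None:
                continue
            if not occupied[iv.chrom].overlap(iv.start, iv.end):
                occupied[iv.chrom].addi(iv.start, iv.end)
                calls.append(
                    CnvCall(iv, svtype, "truth", cfg.sample, id=f"truth_{i:05d}")
                )
                break
        else:
            raise ConfigError(
                f"could not place truth call {i} after {_MAX_PLACEMENT_ATTEMPTS} "
                "attempts; genome too small for n_truth at this size range"
            )
    return CallSet.build(cfg.sample, "truth", calls)


def _jitter_interval(
    iv: GenomicInterval,
    sd: float,
    min_size: int,
    contig_len: int,
    rng: np.random.Generator,
) -> GenomicInterval:
    if sd <= 0:
        return iv
    dx = int(round(rng.normal(0.0, sd)))
    dy = int(round(rng.normal(0.0, sd)))
    start = max(0, iv.start + dx)
    end = min(contig_len, iv.end + dy)
    if end - start < min_size:  # degenerate after jitter: keep true breakpoints
        return iv
    return GenomicInterval(iv.chrom, start, end)


def simulate_caller(
    truth: CallSet,
    model: CallerErrorModel,
    cfg: SimulationConfig,
    seed: int,
    shared_artifacts: Sequence[tuple[GenomicInterval, SvType]] = (),
) -> tuple[CallSet, dict[str, TruthLabel]]:
    """Simulate one caller's observed call set from the truth.

    Each truth call is emitted with its svtype x size-bin sensitivity,
    breakpoints jittered by rounded normal draws (labels
    TRUE_POSITIVE); paired-end callers flip the svtype with the
    mislabel probability.  False positives (label FALSE_POSITIVE) are
    placed uniformly at the configured per-Mb rate with sizes from the
    truth distribution.  ``shared_artifacts`` — identical across
    callers, injected by :func:`simulate_cohort` — are emitted verbatim
    with label SHARED.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    contig_len = dict(cfg.contigs)
    caller = model.profile.id
    calls: list[CnvCall] = []
    labels: dict[str, TruthLabel] = {}
    n = 0

    def emit(iv: GenomicInterval, svtype: SvType, label: TruthLabel) -> None:
        nonlocal n
        call = CnvCall(iv, svtype, caller, cfg.sample, id=f"{caller}_{n:06d}")
        calls.append(call)
        labels[call.id] = label
        n += 1

    for t in truth:
        if rng.random() >= model.sensitivity_for(t.svtype, t.length):
            continue
        iv = _jitter_interval(
            t.interval, model.jitter_sd, cfg.min_size, contig_len[t.interval.chrom], rng
        )
        svtype = t.svtype
        if model.mislabel_prob > 0 and rng.random() < model.mislabel_prob:
            svtype = svtype.opposite
        emit(iv, svtype, TruthLabel.TRUE_POSITIVE)

    n_fp = int(rng.poisson(model.fp_rate_per_mb * cfg.genome_length / 1e6))
    for _ in range(n_fp):
        svtype = _draw_svtype(cfg, rng)
        size = _draw_size(cfg, svtype, rng)
        iv = _draw_placement(cfg, size, rng)
        if iv is not None:
            emit(iv, svtype, TruthLabel.FALSE_POSITIVE)

    for iv, svtype in shared_artifacts:
        emit(iv, svtype, TruthLabel.SHARED)

    return CallSet.build(cfg.sample, caller, calls), labels


@dataclass
class SimulatedCohort:
    """One simulated sample: truth, per-caller call sets, merged labels."""

    truth: CallSet
    callsets: dict[str, CallSet]
    labels: dict[str, TruthLabel]
    config: SimulationConfig


def simulate_cohort(cfg: SimulationConfig, seed: int | None = None) -> SimulatedCohort:
    """Simulate the truth set and every configured caller's observations.

    Shared artifacts (correlated false calls mimicking alignment
    artifacts seen identically by all callers) are drawn once at
    ``shared_artifact_rate_per_mb`` and injected into every caller.
    """
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    truth_seed, shared_seed, *caller_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2 + len(cfg.callers))
    ]
    truth = simulate_truth(cfg, seed=truth_seed)
    shared_rng = np.random.default_rng(shared_seed)
    shared: list[tuple[GenomicInterval, SvType]] = []
    n_shared = int(
        shared_rng.poisson(cfg.shared_artifact_rate_per_mb * cfg.genome_length / 1e6)
    )
    for _ in range(n_shared):
        svtype = _draw_svtype(cfg, shared_rng)
        size = _draw_size(cfg, svtype, shared_rng)
        iv = _draw_placement(cfg, size, shared_rng)
        if iv is not None:
            shared.append((iv, svtype))

    callsets: dict[str, CallSet] = {}
    labels: dict[str, TruthLabel] = {}
    for model, cseed in zip(cfg.callers, caller_seeds):
        cs, lab = simulate_caller(truth, model, cfg, cseed, shared)
        callsets[model.profile.id] = cs
        labels.update(lab)
    return SimulatedCohort(truth, callsets, labels, cfg)


# ---------------------------------------------------------------------------
# Analytic expectations under caller independence


def _pair_match_width(la: float, lb: float, ro_min: float) -> float:
    """Measure (bp) of relative placements where two intervals of the
    given lengths reach reciprocal overlap >= ``ro_min``."""
    c = ro_min * max(la, lb)
    if c > min(la, lb):
        return 0.0
    return la + lb - 2.0 * c


def fp_pair_coincidence(
    model_a: CallerErrorModel,
    model_b: CallerErrorModel,
    cfg: SimulationConfig,
    ro_min: float = 0.75,
    n_grid: int = 200,
) -> float:
    """Probability a false positive of caller A is matched by an
    independent false positive of caller B at RO >= ``ro_min``.

    Computed by numerical integration over the log-uniform size
    distribution of both calls and uniform placement: for a given
    length pair the matching placements form a window of width
    ``la + lb - 2 ro_min max(la, lb)`` (empty when that is negative),
    and B's false calls fall in it as a Poisson process.
    """
    lo, hi = cfg.size_range
    grid = np.exp(np.linspace(math.log(lo), math.log(hi), n_grid))
    w = np.zeros((n_grid, n_grid))
    for i, la in enumerate(grid):
        for j, lb in enumerate(grid):
            w[i, j] = _pair_match_width(la, lb, ro_min)
    mean_w = float(w.mean())  # log-uniform => uniform weight on the log grid
    n_b = model_b.fp_rate_per_mb * cfg.genome_length / 1e6
    return 1.0 - math.exp(-n_b * mean_w / cfg.genome_length)


def pair_jitter_success(
    sd_a: float,
    sd_b: float,
    length: float,
    ro_min: float = 0.75,
    n: int = 20_000,
    seed: int = 0,
) -> float:
    """P(two independently jittered copies of one truth interval still
    reach RO >= ``ro_min``), by Monte Carlo with its own fixed stream.

    Quantifies how breakpoint jitter erodes same-signal pair
    intersection for calls whose length is not much larger than the
    jitter scale.
    """
    if sd_a <= 0 and sd_b <= 0:
        return 1.0
    rng = np.random.default_rng(seed)
    xa, ya = rng.normal(0, max(sd_a, 1e-9), n), rng.normal(0, max(sd_a, 1e-9), n)
    xb, yb = rng.normal(0, max(sd_b, 1e-9), n), rng.normal(0, max(sd_b, 1e-9), n)
    a0, a1 = np.round(xa), length + np.round(ya)
    b0, b1 = np.round(xb), length + np.round(yb)
    o = np.minimum(a1, b1) - np.maximum(a0, b0)
    la, lb = a1 - a0, b1 - b0
    valid = (la > 0) & (lb > 0) & (o > 0)
    ro = np.zeros(n)
    ro[valid] = o[valid] / np.maximum(la, lb)[valid]
    return float((ro >= ro_min).mean())


@dataclass
class ExpectedStats:
    """Analytic expectations for a strategy, assuming caller independence."""

    strategy: str
    sensitivity: float
    per_bin: dict[tuple[str, str], float]
    fp_pair_coincidence: dict[tuple[str, str], float]
    independence_assumed: bool = True


def expected_strategy_stats(
    cfg: SimulationConfig,
    strategy: str,
    intersect_ro: float = 0.75,
    include_jitter: bool = False,
) -> ExpectedStats:
    """Closed-form expected sensitivity of a strategy under independence.

    union: ``1 - prod(1 - s_i)``; intersection-union:
    ``1 - (1 - s1 s2)(1 - s3 s4)`` with the paired-end pair (s1, s2)
    and the coverage pair (s3, s4), per svtype x size bin.  With
    ``include_jitter`` each pair product is additionally multiplied by
    the Monte-Carlo probability that the two jittered copies still
    intersect at ``intersect_ro`` (evaluated at the bin's geometric
    midpoint) — the regime correction for calls not much larger than
    the jitter scale.  FP pair-coincidence probabilities are reported
    for the two same-signal pairs.
    """
    if strategy not in ("union", "intersection_union"):
        raise ConfigError(f"no analytic expectation for strategy {strategy!r}")
    models = list(cfg.callers)
    pe = [m for m in models if m.profile.signal_class is SignalClass.PAIRED_END]
    cov = [m for m in models if m.profile.signal_class is SignalClass.COVERAGE]
    if strategy == "intersection_union" and (len(pe) != 2 or len(cov) != 2):
        raise ConfigError(
            "intersection_union expectation needs exactly two callers per signal class"
        )
    bins = list(DEFAULT_SIZE_BINS)
    edges = bins + [10 * bins[-1]]
    per_bin: dict[tuple[str, str], float] = {}
    for svtype in SvType:
        for k, lo in enumerate(bins):
            hi = edges[k + 1]
            mid = int(math.sqrt(lo * hi))
            label = size_bin_label(lo, bins)
            s = [m.sensitivity_for(svtype, mid) for m in models]
            if strategy == "union":
                val = 1.0 - math.prod(1.0 - si for si in s)
            else:
                def pair_term(pair):
                    prod = math.prod(m.sensitivity_for(svtype, mid) for m in pair)
                    if include_jitter:
                        prod *= pair_jitter_success(
                            pair[0].jitter_sd, pair[1].jitter_sd, mid, intersect_ro
                        )
                    return prod
                val = 1.0 - (1.0 - pair_term(pe)) * (1.0 - pair_term(cov))
            per_bin[(svtype.value, label)] = val
    values = set(round(v, 12) for v in per_bin.values())
    overall = per_bin[("DEL", size_bin_label(bins[0], bins))] if len(values) == 1 else float(
        np.mean(list(per_bin.values()))
    )
    fp_coinc = {}
    if strategy == "intersection_union":
        for pair in (pe, cov):
            key = (pair[0].profile.id, pair[1].profile.id)
            fp_coinc[key] = fp_pair_coincidence(pair[0], pair[1], cfg, intersect_ro)
    return ExpectedStats(strategy, overall, per_bin, fp_coinc)
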
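"""Overlap annotation of call sets with population and genomic tracks.

Annotation is pure decoration: coordinates are never modified and no
call is removed.  Counting is many-to-many (every track record sharing
enough bases with a call counts), the semantics of per-call overlap
summaries against reference databases — distinct from the greedy
one-to-one matching used when two call sets are intersected.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .exceptions import ConfigError
from .model import CallSet, SvType, Track, reciprocal_overlap


def count_overlaps(calls: CallSet, track: Track, min_bp: int = 1) -> list[int]:
    """Per-call count of track records sharing >= ``min_bp`` bases."""
    return [len(track.query(c.interval, min_bp=min_bp)) for c in calls]


def max_allele_frequency(
    calls: CallSet,
    population: Track,
    ro_min: float = 0.5,
    same_type: bool = True,
) -> list[float | None]:
    """Per-call maximal allele frequency among qualifying population overlaps.

    A population record qualifies when it overlaps the call at
    reciprocal overlap >= ``ro_min`` (and matches its svtype when
    ``same_type``); ``None`` when no qualifying record carries an AF.
    """
    out: list[float | None] = []
    for c in calls:
        best: float | None = None
        for rec in population.query(c.interval):
            if same_type and rec.svtype is not None and rec.svtype is not c.svtype:
                continue
            if rec.af is None:
                continue
            if reciprocal_overlap(c.interval, rec.interval) >= ro_min:
                best = rec.af if best is None else max(best, rec.af)
        out.append(best)
    return out


def annotate_regions(
    calls: CallSet,
    tracks: Mapping[str, Track] | Sequence[tuple[str, Track]],
    min_bp: int = 1,
) -> pd.DataFrame:
    """Per-call boolean and overlap-bp columns for each named track.

    Returns a DataFrame indexed by call id with, per track ``name``,
    a boolean ``name`` column (any record sharing >= ``min_bp`` bases)
    and a ``name_bp`` column summing the bases shared with each
    overlapping record.
    """
    if not isinstance(tracks, Mapping):
        names = [n for n, _ in tracks]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigError(f"duplicate track names: {dupes}")
        tracks = dict(tracks)
    data: dict[str, list] = {
        "chrom": [c.interval.chrom for c in calls],
        "start": [c.interval.start for c in calls],
        "end": [c.interval.end for c in calls],
        "svtype": [c.svtype.value for c in calls],
    }
    for name, track in tracks.items():
        flags, bps = [], []
        for c in calls:
            hits = track.query(c.interval, min_bp=min_bp)
            flags.append(bool(hits))
            bps.append(sum(r.interval.overlap_bp(c.interval) for r in hits))
        data[name] = flags
        data[f"{name}_bp"] = bps
    return pd.DataFrame(data, index=pd.Index([c.id for c in calls], name="id"))
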
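"""Independent brute-force oracles used to validate the fast paths.

Everything here is deliberately naive (O(n^2) scans, no indexes) and
shares no code with the implementation beyond the reciprocal-overlap
arithmetic on plain tuples.
"""

from __future__ import annotations


def ro_tuple(a: tuple[str, int, int], b: tuple[str, int, int]) -> float:
    """Reciprocal overlap on (chrom, start, end) tuples."""
    if a[0] != b[0]:
        return 0.0
    o = min(a[2], b[2]) - max(a[1], b[1])
    if o <= 0:
        return 0.0
    return o / max(a[2] - a[1], b[2] - b[1])


def _as_tuple(call) -> tuple[str, int, int]:
    return (call.interval.chrom, call.interval.start, call.interval.end)


def greedy_match_oracle(a_calls, b_calls, ro_min, same_type=True):
    """Exhaustive greedy one-to-one matching; returns {(left id, right id)}.

    Enumerates every pair, sorts by decreasing RO with (left index,
    right index) tie-breaks on the sorted inputs, accepts greedily.
    """
    cands = []
    for i, ca in enumerate(a_calls):
        for j, cb in enumerate(b_calls):
            if same_type and ca.svtype != cb.svtype:
                continue
            ro = ro_tuple(_as_tuple(ca), _as_tuple(cb))
            if ro >= ro_min:
                cands.append((ro, i, j))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a, used_b, pairs = set(), set(), set()
    for ro, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.add((a_calls[i].id, b_calls[j].id))
    return pairs


def linear_scan_overlaps(query, items, min_bp=1):
    """Ids/indices of items sharing >= min_bp bases with the query interval."""
    q = (query.chrom, query.start, query.end)
    out = []
    for k, item in enumerate(items):
        iv = item.interval if hasattr(item, "interval") else item
        if iv.chrom != q[0]:
            continue
        o = min(iv.end, q[2]) - max(iv.start, q[1])
        if o >= min_bp:
            out.append(k)
    return out


def detection_oracle(truth_calls, cand_calls, ro_min):
    """Per-truth-call detection flags via exhaustive greedy matching."""
    matched = greedy_match_oracle(truth_calls, cand_calls, ro_min, same_type=True)
    detected_ids = {left for left, _ in matched}
    return [t.id in detected_ids for t in truth_calls]


def overlap_profile_oracle(callsets, ro_min):
    """{call id: frozenset of other origins with any same-type match}."""
    out = {}
    for cs in callsets:
        for call in cs:
            agreeing = set()
            for other in callsets:
                if other.origin == cs.origin:
                    continue
                for hit in other:
                    if hit.svtype == call.svtype and ro_tuple(
                        _as_tuple(call), _as_tuple(hit)
                    ) >= ro_min:
                        agreeing.add(other.origin)
                        break
            out[call.id] = frozenset(agreeing)
    return out
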
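"""Interval arithmetic on 0-based half-open coordinates.

All public annotation output is 1-based inclusive (GTF/SAF convention); this
module is the internal workhorse and speaks 0-based half-open throughout.
Region arrays handed to the query helpers must be sorted by start and
non-overlapping — exactly what :func:`merge` produces.
"""

from __future__ import annotations

import numpy as np


def merge(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Collapse intervals into their union (sorted, disjoint)."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    # an interval starts a new run iff it begins after the running max end
    run_max = np.maximum.accumulate(e)
    new_run = np.empty(s.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = s[1:] > run_max[:-1]
    run_id = np.cumsum(new_run) - 1
    out_s = s[new_run]
    out_e = np.zeros(out_s.size, dtype=np.int64)
    np.maximum.at(out_e, run_id, e)
    return out_s, out_e


def subtract(starts, ends, sub_starts, sub_ends) -> tuple[np.ndarray, np.ndarray]:
    """Set difference: (union of a) minus (union of b)."""
    a_s, a_e = merge(starts, ends)
    b_s, b_e = merge(sub_starts, sub_ends)
    if a_s.size == 0 or b_s.size == 0:
        return a_s, a_e
    out_s, out_e = [], []
    j = 0
    for s, e in zip(a_s, a_e):
        cur = s
        while j < b_s.size and b_e[j] <= cur:
            j += 1
        k = j
        while k < b_s.size and b_s[k] < e:
            if b_s[k] > cur:
                out_s.append(cur)
                out_e.append(b_s[k])
            cur = max(cur, b_e[k])
            k += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def complement(starts, ends, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Gaps of the interval union within [0, length)."""
    return subtract([0], [length], starts, ends)


def total_length(starts, ends) -> int:
    s, e = merge(starts, ends)
    return int((e - s).sum())


def overlaps_any(q_starts, q_ends, r_starts, r_ends) -> np.ndarray:
    """Boolean per query: does it overlap any region? Regions sorted, disjoint."""
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    if r_starts.size == 0:
        return np.zeros(q_starts.size, dtype=bool)
    lo = np.searchsorted(r_ends, q_starts, side="right")
    hi = np.searchsorted(r_starts, q_ends, side="left")
    return hi > lo


def overlap_pairs(q_starts, q_ends, q_ids, r_starts, r_ends):
    """All (query_id, region_index, overlap_bp) triples against sorted disjoint regions.

    Returns three aligned int64 arrays. A query contributing several blocks
    (same q_id) yields one triple per overlapped region per block; callers
    aggregate as needed.
    """
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    q_ids = np.asarray(q_ids, dtype=np.int64)
    if r_starts.size == 0 or q_starts.size == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z.copy(), z.copy()
    lo = np.searchsorted(r_ends, q_starts, side="right")
    hi = np.searchsorted(r_starts, q_ends, side="left")
    span = hi - lo
    max_span = int(span.max()) if span.size else 0
    out_q, out_r, out_ov = [], [], []
    for k in range(max_span):
        mask = span > k
        if not mask.any():
            break
        ridx = lo[mask] + k
        ov = np.minimum(q_ends[mask], r_ends[ridx]) - np.maximum(q_starts[mask], r_starts[ridx])
        keep = ov > 0
        out_q.append(q_ids[mask][keep])
        out_r.append(ridx[keep])
        out_ov.append(ov[keep])
    if not out_q:
        z = np.zeros(0, dtype=np.int64)
        return z, z.copy(), z.copy()
    return np.concatenate(out_q), np.concatenate(out_r), np.concatenate(out_ov)
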
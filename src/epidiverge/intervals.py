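"""Half-open genomic interval arithmetic on numpy arrays.

All coordinates are 0-based half-open.  Functions operating on bare arrays
work within a single chromosome; the ``*_by_chrom`` helpers lift them to
``(chrom, start, end)`` DataFrames.  Everything here has a per-bp brute-force
oracle in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]


def _as_arrays(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(starts, dtype=np.int64)
    e = np.asarray(ends, dtype=np.int64)
    if s.shape != e.shape:
        raise ValueError("starts and ends must have equal length")
    if np.any(e < s):
        raise ValueError("interval end < start")
    return s, e


def merge(starts, ends, bookend: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Coalesce overlapping (and, if ``bookend``, touching) intervals."""
    s, e = _as_arrays(starts, ends)
    if s.size == 0:
        return s, e
    order = np.argsort(s, kind="stable")
    s, e = s[order], e[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, s.size):
        joined = s[i] <= out_e[-1] if bookend else s[i] < out_e[-1]
        if joined:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def subtract(a_starts, a_ends, b_starts, b_ends) -> tuple[np.ndarray, np.ndarray]:
    """Set difference A \\ B; A intervals may be split by B."""
    a_s, a_e = _as_arrays(a_starts, a_ends)
    b_s, b_e = merge(b_starts, b_ends)
    out_s, out_e = [], []
    for s, e in zip(a_s, a_e):
        cur = s
        # b intervals overlapping [s, e)
        lo = np.searchsorted(b_e, s, side="right")
        for j in range(lo, b_s.size):
            if b_s[j] >= e:
                break
            if b_s[j] > cur:
                out_s.append(cur)
                out_e.append(b_s[j])
            cur = max(cur, b_e[j])
        if cur < e:
            out_s.append(cur)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def overlap_length(q_starts, q_ends, s_starts, s_ends) -> np.ndarray:
    """Per-query bp of overlap with the union of the subject set."""
    q_s, q_e = _as_arrays(q_starts, q_ends)
    m_s, m_e = merge(s_starts, s_ends, bookend=False)
    if m_s.size == 0 or q_s.size == 0:
        return np.zeros(q_s.size, dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(m_e - m_s)])

    def covered_below(x):
        # total subject bp strictly left of coordinate x
        i = np.searchsorted(m_s, x, side="right")  # intervals starting before x
        j = np.maximum(i - 1, 0)
        partial = np.clip(x - m_s[j], 0, m_e[j] - m_s[j])
        return np.where(i > 0, cum[j] + partial, 0)

    return covered_below(q_e) - covered_below(q_s)


def overlaps_any(q_starts, q_ends, s_starts, s_ends) -> np.ndarray:
    """Per-query boolean: >=1 bp overlap with any subject interval."""
    q_s, q_e = _as_arrays(q_starts, q_ends)
    m_s, m_e = merge(s_starts, s_ends, bookend=False)
    if m_s.size == 0:
        return np.zeros(q_s.size, dtype=bool)
    # subject interval with the greatest start < q_e; overlap iff its end > q_s
    i = np.searchsorted(m_s, q_e, side="left") - 1
    ok = i >= 0
    hit = np.zeros(q_s.size, dtype=bool)
    hit[ok] = m_e[i[ok]] > q_s[ok]
    return hit


def gap_distance(q_starts, q_ends, s_starts, s_ends) -> np.ndarray:
    """Per-query minimum gap to the subject set (0 if touching/overlapping).

    Returns -1 where the subject set is empty.
    """
    q_s, q_e = _as_arrays(q_starts, q_ends)
    m_s, m_e = merge(s_starts, s_ends)
    out = np.full(q_s.size, -1, dtype=np.int64)
    if m_s.size == 0:
        return out
    # nearest subject starting at/after query end
    i_right = np.searchsorted(m_s, q_e, side="left")
    d_right = np.where(i_right < m_s.size, m_s[np.minimum(i_right, m_s.size - 1)] - q_e, np.iinfo(np.int64).max)
    # nearest subject ending at/before query start
    i_left = np.searchsorted(m_e, q_s, side="right") - 1
    d_left = np.where(i_left >= 0, q_s - m_e[np.maximum(i_left, 0)], np.iinfo(np.int64).max)
    out = np.minimum(np.maximum(d_right, 0), np.maximum(d_left, 0))
    out[overlaps_any(q_s, q_e, m_s, m_e)] = 0
    return out


# ---------------------------------------------------------------------------
# DataFrame (chrom, start, end) helpers


def _check_bed(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in BED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interval frame missing columns {missing}")
    return df


def merge_by_chrom(df: pd.DataFrame, bookend: bool = True) -> pd.DataFrame:
    _check_bed(df)
    parts = []
    for chrom, sub in df.groupby("chrom", sort=True, observed=True):
        s, e = merge(sub["start"].to_numpy(), sub["end"].to_numpy(), bookend=bookend)
        parts.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
    if not parts:
        return pd.DataFrame(columns=BED_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def subtract_by_chrom(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    _check_bed(a), _check_bed(b)
    parts = []
    for chrom, sub in a.groupby("chrom", sort=True, observed=True):
        bsub = b[b["chrom"] == chrom]
        s, e = subtract(
            sub["start"].to_numpy(), sub["end"].to_numpy(),
            bsub["start"].to_numpy(), bsub["end"].to_numpy(),
        )
        parts.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
    if not parts:
        return pd.DataFrame(columns=BED_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def overlap_length_by_chrom(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Overlap bp for each query row (original row order)."""
    _check_bed(query), _check_bed(subject)
    out = np.zeros(len(query), dtype=np.int64)
    for chrom, sub in query.groupby("chrom", sort=False, observed=True):
        ssub = subject[subject["chrom"] == chrom]
        idx = sub.index
        vals = overlap_length(
            sub["start"].to_numpy(), sub["end"].to_numpy(),
            ssub["start"].to_numpy(), ssub["end"].to_numpy(),
        )
        out[query.index.get_indexer(idx)] = vals
    return out


def overlaps_any_by_chrom(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    _check_bed(query), _check_bed(subject)
    out = np.zeros(len(query), dtype=bool)
    for chrom, sub in query.groupby("chrom", sort=False, observed=True):
        ssub = subject[subject["chrom"] == chrom]
        vals = overlaps_any(
            sub["start"].to_numpy(), sub["end"].to_numpy(),
            ssub["start"].to_numpy(), ssub["end"].to_numpy(),
        )
        out[query.index.get_indexer(sub.index)] = vals
    return out


def gap_distance_by_chrom(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Min same-chromosome gap per query row; -1 if no same-chromosome subject."""
    _check_bed(query), _check_bed(subject)
    out = np.full(len(query), -1, dtype=np.int64)
    for chrom, sub in query.groupby("chrom", sort=False, observed=True):
        ssub = subject[subject["chrom"] == chrom]
        vals = gap_distance(
            sub["start"].to_numpy(), sub["end"].to_numpy(),
            ssub["start"].to_numpy(), ssub["end"].to_numpy(),
        )
        out[query.index.get_indexer(sub.index)] = vals
    return out


def total_length(df: pd.DataFrame) -> int:
    merged = merge_by_chrom(df, bookend=True)
    if merged.empty:
        return 0
    return int((merged["end"] - merged["start"]).sum())
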
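"""Small interval helpers on 0-based half-open coordinates.

Each interval set is a dict chrom -> (starts, ends) with sorted,
non-overlapping numpy arrays; builders accept DataFrames with
chrom/start/end columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "interval_set",
    "merge",
    "subtract",
    "total_length",
    "points_in",
    "any_overlap",
]

IntervalSet = dict


def interval_set(df: pd.DataFrame) -> IntervalSet:
    """Merged interval set from a chrom/start/end frame."""
    out: IntervalSet = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        starts, ends = [], []
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[chrom] = (np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64))
    return out


def merge(*sets: IntervalSet) -> IntervalSet:
    frames = []
    for s in sets:
        for chrom, (st, en) in s.items():
            frames.append(pd.DataFrame({"chrom": chrom, "start": st, "end": en}))
    if not frames:
        return {}
    return interval_set(pd.concat(frames, ignore_index=True))


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Set difference a \\ b."""
    out: IntervalSet = {}
    for chrom, (st, en) in a.items():
        bs, be = b.get(chrom, (np.array([], dtype=np.int64),) * 2)
        rs, re_ = [], []
        for s, e in zip(st, en):
            cur = s
            i = np.searchsorted(be, cur, side="right")
            while cur < e and i < len(bs) and bs[i] < e:
                if bs[i] > cur:
                    rs.append(cur)
                    re_.append(bs[i])
                cur = max(cur, be[i])
                i += 1
            if cur < e:
                rs.append(cur)
                re_.append(e)
        out[chrom] = (np.asarray(rs, dtype=np.int64), np.asarray(re_, dtype=np.int64))
    return out


def total_length(s: IntervalSet) -> int:
    return int(sum((en - st).sum() for st, en in s.values()))


def points_in(s: IntervalSet, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Boolean membership of points (chrom[i], pos[i]) in the set."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    out = np.zeros(len(pos), dtype=bool)
    for c, (st, en) in s.items():
        cm = chrom == c
        if not cm.any() or len(st) == 0:
            continue
        i = np.searchsorted(st, pos[cm], side="right") - 1
        ok = (i >= 0) & (pos[cm] < en[np.maximum(i, 0)])
        out[np.flatnonzero(cm)[ok]] = True
    return out


def any_overlap(s: IntervalSet, df: pd.DataFrame) -> np.ndarray:
    """Per-row flag: does interval df[i] intersect the set by >= 1 bp?"""
    out = np.zeros(len(df), dtype=bool)
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    for c, (st, en) in s.items():
        cm = chroms == c
        if not cm.any() or len(st) == 0:
            continue
        # interval [s, e) hits iff some st < e and en > s
        i = np.searchsorted(st, ends[cm], side="left") - 1
        ok = (i >= 0) & (en[np.maximum(i, 0)] > starts[cm])
        out[np.flatnonzero(cm)[ok]] = True
    return out
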
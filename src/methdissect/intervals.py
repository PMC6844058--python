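"""Genomic interval arithmetic on 0-based half-open coordinates.

Small numpy-backed helpers shared by the segment filters and the
feature-enrichment analysis: merge, subtract, flank derivation,
membership queries and random length-matched placement. Intervals for
one chromosome are ``(n, 2)`` integer arrays of ``[start, end)`` rows; a
genome-wide set is a ``dict: chrom -> array``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "merge_intervals",
    "subtract_intervals",
    "flank_intervals",
    "overlaps_any",
    "total_span",
    "read_bed",
    "write_bed",
    "random_placement",
]


def _as_array(iv) -> np.ndarray:
    a = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if a.size and np.any(a[:, 0] >= a[:, 1]):
        raise ValueError("interval with start >= end")
    return a


def merge_intervals(iv, merge_bookended: bool = True) -> np.ndarray:
    """Union of intervals; overlapping (and, by default, abutting) runs fuse."""
    a = _as_array(iv)
    if len(a) == 0:
        return a
    a = a[np.lexsort((a[:, 1], a[:, 0]))]
    out = [a[0].copy()]
    for s, e in a[1:]:
        if s < out[-1][1] or (merge_bookended and s == out[-1][1]):
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out, dtype=np.int64)


def subtract_intervals(iv, remove) -> np.ndarray:
    """Set difference iv \\ remove (both merged internally)."""
    a = merge_intervals(iv)
    b = merge_intervals(remove)
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    for s, e in a:
        cur = s
        for rs, re in b:
            if re <= cur or rs >= e:
                continue
            if rs > cur:
                out.append((cur, rs))
            cur = max(cur, re)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def flank_intervals(iv, width: int, chrom_size: int | None = None) -> np.ndarray:
    """Both-side flanks of given width, clamped at 0 (and chrom_size if known),
    with the parent intervals themselves subtracted."""
    a = _as_array(iv)
    if len(a) == 0:
        return a
    fl = []
    for s, e in a:
        left = (max(0, s - width), s)
        right = (e, e + width if chrom_size is None else min(chrom_size, e + width))
        if left[0] < left[1]:
            fl.append(left)
        if right[0] < right[1]:
            fl.append(right)
    return subtract_intervals(np.array(fl, dtype=np.int64), a)


def overlaps_any(starts, ends, iv) -> np.ndarray:
    """Boolean vector: does query i = [starts[i], ends[i]) intersect any interval?

    ``iv`` is merged first; queries answered via searchsorted in O(log n).
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    m = merge_intervals(iv, merge_bookended=False)
    if len(m) == 0:
        return np.zeros(len(starts), dtype=bool)
    # candidate interval: last one with start < query end
    idx = np.searchsorted(m[:, 0], ends, side="left") - 1
    ok = idx >= 0
    hit = np.zeros(len(starts), dtype=bool)
    hit[ok] = m[idx[ok], 1] > starts[ok]
    return hit


def total_span(iv) -> int:
    m = merge_intervals(iv)
    return int((m[:, 1] - m[:, 0]).sum()) if len(m) else 0


def read_bed(path) -> dict[str, np.ndarray]:
    """BED3+ reader: returns chrom -> (n, 2) start/end array."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        out[str(chrom)] = _as_array(sub[["start", "end"]].to_numpy())
    return out


def write_bed(path, intervals: dict[str, np.ndarray], extra: dict[str, np.ndarray] | None = None) -> None:
    """Write chrom-keyed intervals as BED3 (+ one optional score column)."""
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            iv = _as_array(intervals[chrom])
            col = extra.get(chrom) if extra else None
            for i, (s, e) in enumerate(iv):
                if col is not None:
                    fh.write(f"{chrom}\t{s}\t{e}\t{col[i]}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def random_placement(lengths, chrom_sizes: dict[str, int], rng,
                     blacklist: dict[str, np.ndarray] | None = None,
                     max_tries: int = 100) -> dict[str, np.ndarray]:
    """Place intervals of the given lengths uniformly at random on the genome,
    avoiding the blacklist; rejection sampling per interval."""
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.float64)
    probs = sizes / sizes.sum()
    placed: dict[str, list] = {c: [] for c in chroms}
    for L in np.asarray(lengths, dtype=np.int64):
        for _ in range(max_tries):
            ci = rng.choice(len(chroms), p=probs)
            c = chroms[ci]
            hi = chrom_sizes[c] - int(L)
            if hi <= 0:
                continue
            s = int(rng.integers(0, hi))
            if blacklist and c in blacklist and overlaps_any([s], [s + int(L)], blacklist[c])[0]:
                continue
            placed[c].append((s, s + int(L)))
            break
        else:
            raise RuntimeError("could not place control interval; blacklist too dense")
    return {c: np.array(v, dtype=np.int64).reshape(-1, 2) for c, v in placed.items() if v}
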
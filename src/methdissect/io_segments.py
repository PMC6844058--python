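"""Read-level methylation input, 4-CpG segment extraction, and genomic filters.

The unit of observation is a sequencing read (bulk mode) or a cell
(single-cell mode) carrying binary methylation calls at CpG positions.
Every run of four consecutive *called* CpGs within one read defines a
4-CpG segment observation; observations sharing the same four genomic
coordinates are aggregated into a :class:`SegmentProfile`. Profiles are
then filtered by coverage, chromosome and blacklist overlap, and segment
spans can be merged into non-overlapping loci.

Coordinates are 0-based half-open throughout; a CpG position is the
forward-strand C, so a segment's genomic span runs from the first C to
one past the last G (last position + 2).
"""

from __future__ import annotations

import gzip
import io
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np

from .intervals import merge_intervals, overlaps_any

WINDOW = 4  # CpGs per segment

__all__ = [
    "ReadCalls",
    "SegmentKey",
    "SegmentProfile",
    "Locus",
    "parse_read_patterns",
    "write_read_patterns",
    "extract_segments",
    "filter_segments",
    "merge_to_loci",
    "write_segment_table",
    "is_autosome",
]


@dataclass(frozen=True)
class ReadCalls:
    """Methylation calls of one read (or one cell fragment) along a chromosome."""

    unit_id: str
    chrom: str
    cpg_positions: tuple[int, ...]
    calls: tuple[int, ...]

    def __post_init__(self):
        if len(self.cpg_positions) != len(self.calls) or not self.calls:
            raise ValueError("calls and positions must be non-empty and equal length")
        if any(b - a <= 0 for a, b in zip(self.cpg_positions, self.cpg_positions[1:])):
            raise ValueError("positions not ascending")
        if any(c not in (0, 1) for c in self.calls):
            raise ValueError("non-binary call state")


class SegmentKey(NamedTuple):
    chrom: str
    pos: tuple[int, int, int, int]

    def span(self) -> tuple[int, int]:
        """Genomic span [first C, last C + 2) covering the full dinucleotides."""
        return self.pos[0], self.pos[-1] + 2

    def __str__(self) -> str:  # "chr1:100-143"
        s, e = self.span()
        return f"{self.chrom}:{s}-{e}"


@dataclass
class SegmentProfile:
    """Aggregated 4-bit methylation patterns over one 4-CpG segment."""

    key: SegmentKey
    observations: dict[str, str] = field(default_factory=dict)
    mode: str = "single_cell"  # or "bulk"

    @property
    def coverage(self) -> int:
        return len(self.observations)

    def pattern_counts(self) -> Counter:
        return Counter(self.observations.values())


@dataclass(frozen=True)
class Locus:
    chrom: str
    start: int
    end: int
    n_source_segments: int = 1

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("locus start must precede end")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _open_text(path):
    if hasattr(path, "read"):
        return path
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def parse_read_patterns(path) -> Iterator[ReadCalls]:
    """Stream ReadCalls from the read-pattern TSV dialect.

    Columns: unit_id, chrom, comma-separated CpG positions, call string over
    {0,1}. ``#`` comment lines and blank lines are skipped; gzip transparent.
    Malformed rows raise ``ValueError`` naming the 1-based line number.
    """
    fh = _open_text(path)
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"line {lineno}: expected 4 tab-separated fields")
            unit_id, chrom, pos_s, call_s = fields
            try:
                positions = tuple(int(p) for p in pos_s.split(","))
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer CpG position") from None
            if set(call_s) - {"0", "1"}:
                raise ValueError(f"line {lineno}: non-binary call characters")
            if len(call_s) != len(positions):
                raise ValueError(f"line {lineno}: {len(positions)} positions vs {len(call_s)} calls")
            try:
                yield ReadCalls(unit_id, chrom, positions, tuple(int(c) for c in call_s))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
    finally:
        if fh is not path:
            fh.close()


def write_read_patterns(path, reads: Iterable[ReadCalls]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            pos = ",".join(str(p) for p in r.cpg_positions)
            calls = "".join(str(c) for c in r.calls)
            fh.write(f"{r.unit_id}\t{r.chrom}\t{pos}\t{calls}\n")


def _reduce_cell_patterns(patterns: list[str]) -> str | None:
    """Collapse multiple read patterns of one cell over one segment.

    Per-site majority vote; a tied site is unresolved and the whole pattern is
    dropped unless all four sites resolve.
    """
    if len(patterns) == 1:
        return patterns[0]
    counts = np.array([[int(ch) for ch in p] for p in patterns])
    meth = counts.sum(axis=0)
    n = len(patterns)
    out = []
    for m in meth:
        if 2 * m > n:
            out.append("1")
        elif 2 * m < n:
            out.append("0")
        else:
            return None
    return "".join(out)


def extract_segments(reads: Iterable[ReadCalls], mode: str = "single_cell") -> list[SegmentProfile]:
    """Slide a 4-CpG window along each read and aggregate per segment.

    A read with c called CpGs yields max(0, c - 3) observations. In bulk mode
    unit ids are read ids and must be unique per segment; in single-cell mode
    multiple reads of one cell over a segment are majority-reduced.
    """
    if mode not in ("single_cell", "bulk"):
        raise ValueError(f"unknown mode {mode!r}")
    raw: dict[SegmentKey, dict[str, list[str]]] = defaultdict(lambda: defaultdict(list))
    for r in reads:
        c = len(r.cpg_positions)
        for i in range(c - WINDOW + 1):
            key = SegmentKey(r.chrom, tuple(r.cpg_positions[i:i + WINDOW]))
            pat = "".join(str(x) for x in r.calls[i:i + WINDOW])
            raw[key][r.unit_id].append(pat)
    profiles = []
    for key in sorted(raw, key=lambda k: (k.chrom, k.pos)):
        obs: dict[str, str] = {}
        for unit, pats in raw[key].items():
            if mode == "bulk":
                if len(pats) > 1:
                    raise ValueError(f"read {unit!r} contributes {len(pats)} patterns to {key}")
                obs[unit] = pats[0]
            else:
                red = _reduce_cell_patterns(pats)
                if red is not None:
                    obs[unit] = red
        if obs:
            profiles.append(SegmentProfile(key=key, observations=obs, mode=mode))
    return profiles


def is_autosome(chrom: str) -> bool:
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return name.isdigit()


def filter_segments(profiles: Iterable[SegmentProfile],
                    blacklist: dict[str, np.ndarray] | None,
                    min_cov: int = 10,
                    autosomes_only: bool = True) -> list[SegmentProfile]:
    """Coverage / autosome / blacklist filter.

    ``blacklist`` maps chrom -> (n, 2) 0-based half-open intervals; pass an
    explicit empty dict for no exclusion (None is an error so a forgotten
    imprinted-region list cannot pass silently).
    """
    if blacklist is None:
        raise ValueError("blacklist required; pass {} for an explicitly empty one")
    out = []
    for p in profiles:
        if p.coverage < min_cov:
            continue
        if autosomes_only and not is_autosome(p.key.chrom):
            continue
        s, e = p.key.span()
        iv = blacklist.get(p.key.chrom)
        if iv is not None and len(iv) and overlaps_any([s], [e], iv)[0]:
            continue
        out.append(p)
    return out


def merge_to_loci(keys: Iterable[SegmentKey], merge_bookended: bool = True) -> list[Locus]:
    """Interval-merge segment spans into non-overlapping loci per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for k in keys:
        by_chrom[k.chrom].append(k.span())
    loci = []
    for chrom in sorted(by_chrom):
        spans = np.array(by_chrom[chrom], dtype=np.int64)
        merged = merge_intervals(spans, merge_bookended=merge_bookended)
        for s, e in merged:
            # every source span falls inside exactly one merged locus
            n_src = int(((spans[:, 0] >= s) & (spans[:, 1] <= e)).sum())
            loci.append(Locus(chrom, int(s), int(e), n_source_segments=n_src))
    return loci


def write_segment_table(path, profiles: Iterable[SegmentProfile]) -> None:
    """TSV: chrom, four CpG positions, per-unit patterns as unit=pattern pairs."""
    with open(path, "w") as fh:
        fh.write("# chrom\tpositions\tcoverage\tobservations\n")
        for p in profiles:
            pos = ",".join(str(x) for x in p.key.pos)
            obs = ";".join(f"{u}={pat}" for u, pat in sorted(p.observations.items()))
            fh.write(f"{p.key.chrom}\t{pos}\t{p.coverage}\t{obs}\n")
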
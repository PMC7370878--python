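"""Plain-text interval file dialects used by the package.

BED-like files are 0-based half-open, tab-separated. Peak files carry the
peak's -log10(q) in the score column; constrained-region tracks carry the
rejected-substitution (RS) conservation score as a 7th column (the BED score
column 5 holds min(1000, round(RS*1000)) for browser compatibility).
bedGraph files hold per-base Tn5 cut-site counts as (chrom, start, end,
count) runs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    rs: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


class BedParseError(ValueError):
    pass


def read_bed(path) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
                score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
                rs = float(cols[6]) if len(cols) > 6 else None
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: malformed numeric field") from exc
            if end <= start:
                raise BedParseError(f"line {lineno}: empty interval {start}..{end}")
            out.append(
                Interval(
                    chrom=cols[0],
                    start=start,
                    end=end,
                    name=cols[3] if len(cols) > 3 else ".",
                    score=score,
                    strand=cols[5] if len(cols) > 5 else ".",
                    rs=rs,
                )
            )
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name, f"{iv.score:g}", iv.strand]
            if iv.rs is not None:
                cols.append(f"{iv.rs:g}")
            fh.write("\t".join(cols) + "\n")


def read_bedgraph(path) -> dict[str, np.ndarray]:
    """Per-chromosome dense count arrays from a bedGraph file.

    Array length is the largest end coordinate seen per chromosome; missing
    runs are zero.
    """
    runs: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise BedParseError(f"line {lineno}: bedGraph needs 4 columns")
            runs.setdefault(cols[0], []).append((int(cols[1]), int(cols[2]), float(cols[3])))
    out = {}
    for chrom, rr in runs.items():
        size = max(end for _, end, _ in rr)
        arr = np.zeros(size)
        for start, end, value in rr:
            arr[start:end] += value
        out[chrom] = arr
    return out


def write_bedgraph(track: dict[str, np.ndarray], path) -> None:
    """Write dense per-base counts, run-length encoded, omitting zero runs."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            arr = np.asarray(track[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
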
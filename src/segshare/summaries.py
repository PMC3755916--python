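"""Per-chromosome sharing observables (n_s, p_s, t_s, total).

The likelihood machinery works on a discrete observable per chromosome:
the number of shared segments ``n_s``, the number of chromosome ends
covered by shared segments ``p_s`` (0, 1 or 2), and the total shared
length discretized into tenths of the chromosome ``t_s``:
``t_s = t`` iff ``(t-1)/10 < total <= t/10`` for total > 0, and
``t_s = 0`` iff nothing is shared.

Individual segment sub-lengths carry no extra information beyond
(n_s, p_s, total): conditional on two segments of total length x, the
split is uniform.

End-touching uses exact arithmetic on stored breakpoints (a segment
touches an end iff its endpoint equals 0 or l); boundary ties on the
t_s grid use exact ``<=`` on floating values.  Both are measure-zero
conventions documented for bit-reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SharingSummary",
    "discretize_length",
    "discretize_lengths",
    "summarize",
    "write_summaries",
    "read_summaries",
]


@dataclass(frozen=True)
class SharingSummary:
    """Observable for one chromosome: counts, end positions, length."""

    n_s: int
    p_s: int
    total: float  # shared length as a proportion of l, in [0, 1]
    t_s: int

    def __post_init__(self) -> None:
        if (self.n_s == 0) != (self.total == 0) or (self.n_s == 0) != (self.t_s == 0):
            raise ValueError("n_s = 0, total = 0 and t_s = 0 must coincide")
        if self.p_s not in (0, 1, 2):
            raise ValueError("p_s must be 0, 1 or 2")
        if self.n_s == 1 and self.p_s == 2 and self.total != 1.0:
            raise ValueError("a single segment covering both ends is the whole chromosome")


def discretize_length(total: float) -> int:
    """Tenth-index for a shared proportion: smallest t with total <= t/10."""
    if not (0.0 < total <= 1.0):
        raise ValueError(f"total must be in (0, 1], got {total}")
    t = int(math.ceil(total * 10))
    while t > 1 and total <= (t - 1) / 10:
        t -= 1
    while total > t / 10:
        t += 1
    return t


def discretize_lengths(total: np.ndarray) -> np.ndarray:
    """Vectorized :func:`discretize_length`; total = 0 maps to t_s = 0."""
    total = np.asarray(total, dtype=float)
    if np.any((total < 0) | (total > 1)):
        raise ValueError("totals must lie in [0, 1]")
    t = np.ceil(total * 10).astype(np.int64)
    # one exact adjustment each way is enough (float error < 1 ulp)
    t -= (t > 1) & (total <= (t - 1) / 10)
    t += total > t / 10
    t[total == 0] = 0
    return t


def summarize(segments: Sequence[tuple[float, float]], l: float) -> SharingSummary:
    """Reduce a disjoint, sorted segment list on [0, l] to a summary."""
    if not l > 0:
        raise ValueError("chromosome length must be positive")
    prev_end = 0.0
    shared = 0.0
    for start, end in segments:
        if start < prev_end or end <= start or end > l:
            raise ValueError("segments must be disjoint, sorted and within [0, l]")
        prev_end = end
        shared += end - start
    n_s = len(segments)
    if n_s == 0:
        return SharingSummary(0, 0, 0.0, 0)
    p_s = int(segments[0][0] == 0.0) + int(segments[-1][1] == l)
    if n_s == 1 and p_s == 2:
        total = 1.0  # whole chromosome, exactly
    else:
        total = shared / l
    return SharingSummary(n_s, p_s, total, discretize_length(total))


_COLUMNS = ("relationship", "chrom_length", "n_s", "p_s", "t_s", "total")


def write_summaries(rows: Iterable[tuple[str, float, SharingSummary]], path) -> None:
    """Write replicate-level summaries as tab-separated rows."""
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for rel, l, s in rows:
            fh.write(f"{rel}\t{l!r}\t{s.n_s}\t{s.p_s}\t{s.t_s}\t{s.total!r}\n")


def read_summaries(path) -> list[tuple[str, float, SharingSummary]]:
    out: list[tuple[str, float, SharingSummary]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _COLUMNS:
            raise ValueError(f"unexpected summary header {header}")
        for line in fh:
            rel, l, n, p, t, total = line.rstrip("\n").split("\t")
            out.append(
                (rel, float(l),
                 SharingSummary(int(n), int(p), float(total), int(t)))
            )
    return out
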
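"""Single-chromosome meiosis under the Haldane model.

Crossover counts are Poisson with mean equal to the map length ``l`` in
Morgans, crossover positions are i.i.d. Uniform(0, l) (no interference),
and a gamete alternates between the two parental haplotypes at each
crossover, starting from either with probability 1/2.

A :class:`Haplotype` is an ordered mosaic of founder-labeled intervals:
``n - 1`` strictly increasing breakpoints in the open interval (0, l) and
``n`` integer labels, one per interval.  All positions are real-valued;
there is no discretization grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Haplotype", "uniform_haplotype", "sample_crossovers", "form_gamete"]


@dataclass(frozen=True)
class Haplotype:
    """One chromosome copy as a mosaic of founder-labeled intervals."""

    length: float
    breakpoints: np.ndarray  # strictly increasing, in (0, length)
    labels: np.ndarray  # one integer label per interval

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        lab = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "labels", lab)
        if not self.length > 0:
            raise ValueError("chromosome length must be positive")
        if lab.ndim != 1 or bp.ndim != 1:
            raise ValueError("breakpoints and labels must be 1-D")
        if lab.size != bp.size + 1:
            raise ValueError("need exactly one label per interval")
        if bp.size and (bp[0] <= 0 or bp[-1] >= self.length or np.any(np.diff(bp) <= 0)):
            raise ValueError("breakpoints must be strictly increasing in (0, length)")

    @property
    def n_intervals(self) -> int:
        return int(self.labels.size)

    def label_at(self, x) -> np.ndarray | np.int64:
        """Founder label at position(s) ``x`` in [0, length].

        At a breakpoint itself the label of the interval to the right is
        returned; queries are normally at interior points so the convention
        is immaterial.
        """
        idx = np.searchsorted(self.breakpoints, x, side="right")
        return self.labels[idx]

    def simplify(self) -> "Haplotype":
        """Merge adjacent intervals carrying the same label (idempotent)."""
        if self.labels.size <= 1:
            return self
        keep = self.labels[1:] != self.labels[:-1]
        if keep.all():
            return self
        return Haplotype(self.length, self.breakpoints[keep],
                         np.concatenate([self.labels[:1], self.labels[1:][keep]]))

    @property
    def is_simplified(self) -> bool:
        return self.labels.size <= 1 or bool(np.all(self.labels[1:] != self.labels[:-1]))


def uniform_haplotype(length: float, label: int) -> Haplotype:
    """A single-interval haplotype carrying one founder label."""
    return Haplotype(length, np.empty(0), np.array([label]))


def sample_crossovers(length: float, rng: np.random.Generator) -> np.ndarray:
    """Sample crossover positions for one meiosis on a chromosome.

    The count is Poisson(length) and positions are Uniform(0, length),
    returned sorted.  Coincident positions (probability zero in exact
    arithmetic, conceivable in floats) are resolved by resampling.
    """
    if not length > 0:
        raise ValueError("chromosome length must be positive")
    k = rng.poisson(length)
    while True:
        pos = np.sort(rng.uniform(0.0, length, k))
        if k < 2 or np.all(np.diff(pos) > 0):
            return pos


def form_gamete(
    hapA: Haplotype,
    hapB: Haplotype,
    rng: np.random.Generator | None = None,
    *,
    breakpoints: np.ndarray | None = None,
    start: int | None = None,
) -> Haplotype:
    """Form a gamete from a diploid parent with haplotypes ``hapA``/``hapB``.

    One call is one meiosis: crossovers are sampled internally via
    :func:`sample_crossovers`, the starting haplotype is chosen with
    probability 1/2 each, and the source alternates at every crossover.
    The result is simplified (no two adjacent intervals share a label).

    Deterministic variants for testing inject ``breakpoints`` (sorted
    crossover positions) and/or ``start`` (0 for ``hapA``, 1 for ``hapB``).
    """
    if hapA.length != hapB.length:
        raise ValueError("parental haplotypes must have the same length")
    l = hapA.length
    if breakpoints is None:
        if rng is None:
            raise ValueError("rng required unless breakpoints are injected")
        xs = sample_crossovers(l, rng)
    else:
        xs = np.asarray(breakpoints, dtype=float)
    if start is None:
        if rng is None:
            raise ValueError("rng required unless start is injected")
        start = int(rng.integers(2))

    # Atomic intervals: union of crossovers and both parents' breakpoints.
    cuts = np.unique(np.concatenate([xs, hapA.breakpoints, hapB.breakpoints]))
    mids = 0.5 * (np.concatenate([[0.0], cuts]) + np.concatenate([cuts, [l]]))
    source = (start + np.searchsorted(xs, mids, side="right")) % 2
    labels = np.where(source == 0, hapA.label_at(mids), hapB.label_at(mids))
    return Haplotype(l, cuts, labels).simplify()
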
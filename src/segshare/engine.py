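"""Vectorized Monte-Carlo engine for shared-segment simulation.

Each meiosis along a lineage is represented as a two-state telegraph
process on [0, l]: the state (which parental haplotype is being copied)
starts from a fair Bernoulli draw and flips at Poisson(l)-many uniform
crossover positions.  Whether a genomic position is shared IBD by a
relative pair is a boolean function of the states of the relevant
meioses at that position, so whole batches of replicates reduce to flat
numpy passes over the pooled, sorted crossover events.

This is distributionally identical to chaining
:func:`segshare.meiosis.form_gamete` calls per replicate (the object
layer in :mod:`segshare.relationships`); the test suite ties the two
paths together by chi-square comparison.  The engine exists because the
likelihood tables need 10^5-10^6 replicates per relationship and
chromosome length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .relationships import FULL_SIB, HALF_SIB, LINEAL, RelationshipSpec
from .summaries import discretize_lengths

__all__ = ["BatchSummaries", "simulate_sharing", "simulate_relationship"]


@dataclass(frozen=True)
class BatchSummaries:
    """Per-replicate sharing observables for one batch (arrays of length n)."""

    chrom_length: float
    n_s: np.ndarray
    p_s: np.ndarray
    total: np.ndarray  # proportion of l shared

    @property
    def t_s(self) -> np.ndarray:
        return discretize_lengths(self.total)

    @property
    def n(self) -> int:
        return int(self.n_s.size)


# A share rule maps a (..., m) boolean state array to a (...,) boolean
# array saying whether material is shared IBD given those meiosis states.
_ShareRule = Callable[[np.ndarray], np.ndarray]


def _share_rule(base: str, g1: int, g2: int) -> tuple[int, _ShareRule]:
    """Number of relevant meiosis processes and the share rule for a pair.

    Column layout by base:

    * lineal, d meioses: the d-1 dilution meioses below the ancestor's own
      gamete (the choice between the ancestor's two haplotypes never
      breaks sharing because the ancestor is diploid).
    * half-sib, (g1, g2): the two label meioses (which ancestral haplotype
      each lineage's founding gamete copies) then g1-1 + g2-1 dilutions.
    * full-sib, (g1, g2) with g1 >= 2: for each sib the grandpaternal /
      grandmaternal label meioses f, m and the sib's own transmission s,
      then dilutions -- share requires both lineages to transmit the same
      founder's material with matching labels.
    * full-sib avuncular (g1 = 1): the elder is the diploid sib itself, so
      it matches the younger lineage's material whichever of f/m it came
      through.
    """
    if base == LINEAL:
        d = g2
        m = d - 1
        if m == 0:  # parent-offspring: always fully shared
            return 0, lambda s: np.ones(s.shape[:-1], dtype=bool)
        return m, lambda s: s.all(axis=-1)

    if base == HALF_SIB:
        m = 2 + (g1 - 1) + (g2 - 1)

        def rule(s: np.ndarray) -> np.ndarray:
            return (s[..., 0] == s[..., 1]) & s[..., 2:].all(axis=-1)

        return m, rule

    if base == FULL_SIB:
        if g1 == 1 and g2 == 1:
            raise ValueError("full sibs (bilateral sharing) are out of scope")
        if min(g1, g2) == 1:  # avuncular: diploid elder
            g = max(g1, g2)
            m = 5 + (g - 2)  # f_u, m_u, f_s, m_s, s, dilutions

            def rule(s: np.ndarray) -> np.ndarray:
                match = np.where(s[..., 4], s[..., 2] == s[..., 0],
                                 s[..., 3] == s[..., 1])
                return match & s[..., 5:].all(axis=-1)

            return m, rule

        m = 6 + (g1 - 2) + (g2 - 2)  # f1, m1, s1, f2, m2, s2, dilutions

        def rule(s: np.ndarray) -> np.ndarray:
            match = (s[..., 2] == s[..., 5]) & np.where(
                s[..., 2], s[..., 0] == s[..., 3], s[..., 1] == s[..., 4]
            )
            return match & s[..., 6:].all(axis=-1)

        return m, rule

    raise ValueError(f"unknown family base {base!r}")


def simulate_sharing(base: str, g1: int, g2: int, l: float, n: int,
                     rng: np.random.Generator) -> BatchSummaries:
    """Simulate ``n`` independent replicates of a relative pair's sharing.

    Arbitrary (g1, g2) are accepted (e.g. full-sib-base (2, 4), cousins
    twice removed, which is not in the catalog), enabling distribution
    equivalence checks.
    """
    if not l > 0:
        raise ValueError("chromosome length must be positive")
    if n < 1:
        raise ValueError("need at least one replicate")
    m, rule = _share_rule(base, g1, g2)

    if m == 0:
        ones = np.ones(n)
        return BatchSummaries(l, np.ones(n, np.int64), np.full(n, 2, np.int64), ones)

    counts = rng.poisson(l, size=(n, m))
    K = counts.sum(axis=1)
    E = int(K.sum())
    starts = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(K, out=starts[1:])

    owner = np.repeat(np.arange(n * m), counts.ravel())
    rep = owner // m
    proc = owner % m
    pos = rng.uniform(0.0, l, E)
    order = np.lexsort((pos, rep))
    rep, proc, pos = rep[order], proc[order], pos[order]

    S0 = rng.random((n, m)) < 0.5

    # State of every process after every event: initial state XOR the
    # within-replicate flip parity of that process.
    states = np.empty((E, m), dtype=bool)
    for j in range(m):
        cum = np.zeros(E + 1, dtype=np.int64)
        np.cumsum(proc == j, out=cum[1:])
        within = cum[1:] - cum[starts[:-1]][rep]
        states[:, j] = S0[rep, j] ^ (within & 1).astype(bool)

    share0 = rule(S0)            # state on the interval before the first event
    share_e = rule(states)       # state on the interval after each event

    # Flatten to one piecewise-constant sequence per replicate:
    # replicate r occupies V[r + starts[r] : r + starts[r+1] + 1].
    Vlen = n + E
    blk_start = np.arange(n) + starts[:-1]
    blk_end = np.arange(n) + starts[1:]
    ev_idx = rep + 1 + np.arange(E)

    V = np.empty(Vlen, dtype=bool)
    V[blk_start] = share0
    V[ev_idx] = share_e
    B = np.empty(Vlen)           # left boundary of each interval
    B[blk_start] = 0.0
    B[ev_idx] = pos
    rep_V = np.empty(Vlen, dtype=np.int64)
    rep_V[blk_start] = np.arange(n)
    rep_V[ev_idx] = rep
    is_start = np.zeros(Vlen, dtype=bool)
    is_start[blk_start] = True
    is_end = np.zeros(Vlen, dtype=bool)
    is_end[blk_end] = True

    prev_off = np.concatenate(([False], ~V[:-1]))
    next_off = np.concatenate((~V[1:], [False]))
    run_start = V & (is_start | prev_off)
    run_end = V & (is_end | next_off)
    end_boundary = np.where(is_end, l, np.concatenate((B[1:], [l])))

    n_s = np.bincount(rep_V[run_start], minlength=n)
    shared_len = (
        np.bincount(rep_V[run_end], weights=end_boundary[run_end], minlength=n)
        - np.bincount(rep_V[run_start], weights=B[run_start], minlength=n)
    )
    p_s = V[blk_start].astype(np.int64) + V[blk_end].astype(np.int64)

    total = shared_len / l
    # A single run spanning the whole chromosome is exactly the whole
    # chromosome (its boundaries are the exact floats 0 and l).
    return BatchSummaries(l, n_s, p_s, total)


def simulate_relationship(rel: RelationshipSpec, l: float, n: int,
                          rng: np.random.Generator) -> BatchSummaries:
    """Batch-simulate a catalog relationship on one chromosome length."""
    return simulate_sharing(rel.base, rel.g1, rel.g2, l, n, rng)
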
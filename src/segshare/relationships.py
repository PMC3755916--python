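"""The 19 uniparental pedigree relationships and gene-dropping simulation.

The catalog covers three family bases:

* **full-sib base** -- two founder parents; the pair descends through two
  full sibs (uncle-nephew, cousins, ...).  Avuncular pairs (UN, GUGN) keep
  the elder individual as a diploid, which is what makes their
  segment-count distribution differ from same-``R`` cousin pairs.
* **half-sib base** -- one common ancestor; each individual descends
  through a different mate.  The sharing distribution depends only on
  Wright's numerator relationship ``R`` (equivalently on the total number
  of meioses ``d``).
* **lineal** -- direct ancestor-descendant chains; the ancestor is diploid.

Wright's numerator relationship is ``R = a (1/2)^d`` for collateral
relatives (``a`` founding ancestors, ``d = g1 + g2`` meioses) and
``R = (1/2)^d`` for lineal pairs.  The expected proportion of the
uniparental genome shared is ``2R``.

Gene dropping labels every founder haplotype with a distinct integer and
chains :func:`~segshare.meiosis.form_gamete` calls down each lineage;
unrelated in-marrying mates contribute fresh unique labels so spurious
sharing is impossible by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .meiosis import Haplotype, form_gamete, uniform_haplotype

__all__ = [
    "FULL_SIB",
    "HALF_SIB",
    "LINEAL",
    "RelationshipSpec",
    "IndividualGenome",
    "relationship_catalog",
    "get_relationship",
    "drop_pair",
    "drop_collateral_pair",
    "drop_lineal_pair",
    "shared_segments",
]

FULL_SIB = "full-sib"
HALF_SIB = "half-sib"
LINEAL = "lineal"


@dataclass(frozen=True)
class RelationshipSpec:
    """Catalog entry defining one relationship's drop procedure.

    ``meioses_down`` is the pair (g1, g2) of meiosis counts from the
    founding ancestor(s) to each individual's tracked material; for lineal
    relationships g1 = 0 (the elder individual *is* the ancestor).
    A collateral endpoint with g = 1 is a diploid (the uncle in UN/GUGN);
    otherwise the tracked material is a single transmitted haplotype.
    """

    abbrev: str
    name: str
    base: str
    wrights_R: Fraction
    meioses_down: tuple[int, int]

    @property
    def g1(self) -> int:
        return self.meioses_down[0]

    @property
    def g2(self) -> int:
        return self.meioses_down[1]

    @property
    def d(self) -> int:
        """Total number of meioses separating the pair."""
        return self.g1 + self.g2

    @property
    def a(self) -> int:
        """Number of founding common ancestors (2 for full-sib base)."""
        return 2 if self.base == FULL_SIB else 1

    @property
    def is_avuncular(self) -> bool:
        return self.base == FULL_SIB and self.g1 == 1


def _rel(abbrev, name, base, R, g):
    return RelationshipSpec(abbrev, name, base, Fraction(*R), g)


_CATALOG: tuple[RelationshipSpec, ...] = (
    # full-sib base
    _rel("UN", "uncle-nephew", FULL_SIB, (1, 4), (1, 2)),
    _rel("GUGN", "great-uncle-great-nephew", FULL_SIB, (1, 8), (1, 3)),
    _rel("C", "full cousins", FULL_SIB, (1, 8), (2, 2)),
    _rel("C1R", "cousins once removed", FULL_SIB, (1, 16), (2, 3)),
    _rel("2C", "second cousins", FULL_SIB, (1, 32), (3, 3)),
    _rel("2C1R", "second cousins once removed", FULL_SIB, (1, 64), (3, 4)),
    _rel("3C", "third cousins", FULL_SIB, (1, 128), (4, 4)),
    # half-sib base
    _rel("HS", "half-sibs", HALF_SIB, (1, 4), (1, 1)),
    _rel("HUN", "half-uncle-nephew", HALF_SIB, (1, 8), (1, 2)),
    _rel("HC", "half-cousins", HALF_SIB, (1, 16), (2, 2)),
    _rel("HC1R", "half-cousins once removed", HALF_SIB, (1, 32), (2, 3)),
    _rel("H2C", "half second cousins", HALF_SIB, (1, 64), (3, 3)),
    _rel("H2C1R", "half second cousins once removed", HALF_SIB, (1, 128), (3, 4)),
    # lineal
    _rel("GPO", "grandparent-grandoffspring", LINEAL, (1, 4), (0, 2)),
    _rel("GGPO", "great-grandparent-great-grandoffspring", LINEAL, (1, 8), (0, 3)),
    _rel("G3PO", "3-great-grandparent-grandoffspring", LINEAL, (1, 16), (0, 4)),
    _rel("G4PO", "4-great-grandparent-grandoffspring", LINEAL, (1, 32), (0, 5)),
    _rel("G5PO", "5-great-grandparent-grandoffspring", LINEAL, (1, 64), (0, 6)),
    _rel("G6PO", "6-great-grandparent-grandoffspring", LINEAL, (1, 128), (0, 7)),
)

_BY_ABBREV = {r.abbrev: r for r in _CATALOG}


def relationship_catalog() -> tuple[RelationshipSpec, ...]:
    """All 19 relationships: 7 full-sib base, 6 half-sib base, 6 lineal."""
    return _CATALOG


def get_relationship(abbrev: str) -> RelationshipSpec:
    try:
        return _BY_ABBREV[abbrev]
    except KeyError:
        raise KeyError(
            f"unknown relationship {abbrev!r}; known: {[r.abbrev for r in _CATALOG]}"
        ) from None


@dataclass(frozen=True)
class IndividualGenome:
    """One individual's tracked chromosome material.

    Two haplotypes when the individual is a diploid endpoint (the uncle in
    UN/GUGN, the ancestor in lineal pairs); one when the tracked material
    is a single transmitted haplotype.
    """

    haplotypes: tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        if len(self.haplotypes) not in (1, 2):
            raise ValueError("an individual carries one or two haplotypes")
        lengths = {h.length for h in self.haplotypes}
        if len(lengths) != 1:
            raise ValueError("all haplotypes must share one chromosome length")

    @property
    def length(self) -> float:
        return self.haplotypes[0].length


# Founder labels; fresh labels for in-marrying mates start above these.
_F1, _F2, _M1, _M2 = 1, 2, 3, 4
_A1, _A2 = 1, 2
_FRESH_START = 100


def _dilute(hap: Haplotype, generations: int, l: float,
            rng: np.random.Generator, fresh) -> Haplotype:
    """Pass ``hap`` down ``generations`` meioses through unrelated mates."""
    for _ in range(generations):
        hap = form_gamete(hap, uniform_haplotype(l, next(fresh)), rng)
    return hap


def drop_collateral_pair(base: str, g1: int, g2: int, l: float,
                         rng: np.random.Generator) -> tuple[IndividualGenome, IndividualGenome]:
    """Gene-drop a collateral pair with arbitrary meiosis counts (g1, g2).

    Supports non-catalog configurations such as full-sib-base (2, 4)
    (cousins twice removed) used to probe distribution equivalences.
    """
    if min(g1, g2) < 1:
        raise ValueError("collateral meiosis counts must be >= 1")
    if base == HALF_SIB:
        def endpoint(g: int) -> IndividualGenome:
            hap = form_gamete(uniform_haplotype(l, _A1), uniform_haplotype(l, _A2), rng)
            return IndividualGenome((_dilute(hap, g - 1, l, rng, fresh),))
        fresh = itertools.count(_FRESH_START)
        return endpoint(g1), endpoint(g2)
    if base == FULL_SIB:
        if g1 == 1 and g2 == 1:
            raise ValueError("full sibs (bilateral sharing) are out of scope")
        fresh = itertools.count(_FRESH_START)

        def endpoint(g: int) -> IndividualGenome:
            pat = form_gamete(uniform_haplotype(l, _F1), uniform_haplotype(l, _F2), rng)
            mat = form_gamete(uniform_haplotype(l, _M1), uniform_haplotype(l, _M2), rng)
            if g == 1:  # the sib itself, diploid
                return IndividualGenome((pat, mat))
            hap = form_gamete(pat, mat, rng)  # the sib's transmitted gamete
            return IndividualGenome((_dilute(hap, g - 2, l, rng, fresh),))

        return endpoint(g1), endpoint(g2)
    raise ValueError(f"unknown collateral base {base!r}")


def drop_lineal_pair(d: int, l: float,
                     rng: np.random.Generator) -> tuple[IndividualGenome, IndividualGenome]:
    """Gene-drop an ancestor (diploid) and a descendant ``d`` meioses down."""
    if d < 1:
        raise ValueError("lineal meiosis count must be >= 1")
    fresh = itertools.count(_FRESH_START)
    ancestor = IndividualGenome(
        (uniform_haplotype(l, _A1), uniform_haplotype(l, _A2))
    )
    hap = form_gamete(*ancestor.haplotypes, rng)
    descendant = IndividualGenome((_dilute(hap, d - 1, l, rng, fresh),))
    return ancestor, descendant


def drop_pair(rel: RelationshipSpec | str, l: float,
              rng: np.random.Generator) -> tuple[IndividualGenome, IndividualGenome]:
    """Simulate one replicate of a catalog relationship on one chromosome."""
    if isinstance(rel, str):
        rel = get_relationship(rel)
    if not l > 0:
        raise ValueError("chromosome length must be positive")
    if rel.base == LINEAL:
        return drop_lineal_pair(rel.d, l, rng)
    return drop_collateral_pair(rel.base, rel.g1, rel.g2, l, rng)


def shared_segments(a: IndividualGenome, b: IndividualGenome) -> list[tuple[float, float]]:
    """Maximal intervals where ``a`` and ``b`` carry a common founder label.

    Maximality is positional, not per-label: adjacent intervals shared
    through different haplotypes of the same diploid ancestor merge into
    one segment.  Returned segments are disjoint, sorted and within
    ``(0, l]``.
    """
    if a.length != b.length:
        raise ValueError("individuals must share one chromosome length")
    l = a.length
    haps = list(a.haplotypes) + list(b.haplotypes)
    cuts = np.unique(np.concatenate([h.breakpoints for h in haps]))
    bounds = np.concatenate([[0.0], cuts, [l]])
    mids = 0.5 * (bounds[:-1] + bounds[1:])
    share = np.zeros(mids.size, dtype=bool)
    for ha in a.haplotypes:
        la = ha.label_at(mids)
        for hb in b.haplotypes:
            share |= la == hb.label_at(mids)
    segs: list[tuple[float, float]] = []
    i = 0
    while i < share.size:
        if share[i]:
            j = i
            while j + 1 < share.size and share[j + 1]:
                j += 1
            segs.append((float(bounds[i]), float(bounds[j + 1])))
            i = j + 1
        i += 1
    return segs
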
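"""Closed-form expectations and the Poisson-approximate likelihood.

For a chromosome of map length ``l`` Morgans the expected number of
shared segments admits closed forms:

* collateral (cousin-type and half-sib-base) pairs:
  ``E(n_s) = a (d l + 1) (1/2)^(d-1)`` with ``a`` founding ancestors and
  ``d = g1 + g2`` meioses;
* lineal pairs: ``E(n_s) = [(d - 1) l + 1] (1/2)^(d-1)`` -- recombination
  in the ancestor's own gamete never breaks sharing with the diploid
  ancestor;
* avuncular pairs, where the diploid elder also absorbs label switches:
  ``E(n_s) = (5 l + 2)/4`` for uncle-nephew and ``(7 l + 2)/8`` for
  great-uncle-great-nephew.

All four cases are ``E(n_s) = 2R (rho l + 1)`` for a breakpoint density
``rho`` (``d``, ``d - 1``, 5/2 and 7/2 respectively), and since the mean
total length shared is ``2R l``, the expected length of an individual
segment is ``l / (rho l + 1)`` -- strictly below the infinite-chromosome
value ``1/rho``, which it approaches as ``l`` grows.

The number of segments is *not* Poisson (simulation shows
under-dispersion for close relatives), but a Poisson likelihood on
``n_s`` with these means is a simulation-free approximation whose cost
in discriminating power is quantified by
:func:`poisson_loglr_moments`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

from scipy.stats import poisson

from .genome import GenomeModel
from .likelihood import DistributionBank, LRMoments
from .relationships import LINEAL, RelationshipSpec, get_relationship

logger = logging.getLogger(__name__)

__all__ = [
    "CountFormulaResult",
    "expected_num_segments",
    "expected_segment_length",
    "expected_total_shared",
    "poisson_loglr_moments",
]


@dataclass(frozen=True)
class CountFormulaResult:
    expected_segments: float
    formula_id: str  # one of {"eq_collateral", "lineal", "UN", "GUGN"}


def _density(rel: RelationshipSpec) -> tuple[Fraction, str]:
    """Breakpoint density rho and the formula family it comes from."""
    if rel.base == LINEAL:
        return Fraction(rel.d - 1), "lineal"
    if rel.is_avuncular:
        if rel.abbrev == "UN" or rel.d == 3:
            return Fraction(5, 2), "UN"
        return Fraction(7, 2), "GUGN"
    return Fraction(rel.d), "eq_collateral"


def _as_spec(rel: RelationshipSpec | str) -> RelationshipSpec:
    return get_relationship(rel) if isinstance(rel, str) else rel


def expected_num_segments(rel: RelationshipSpec | str, l: float) -> CountFormulaResult:
    """Expected number of shared segments on one chromosome."""
    rel = _as_spec(rel)
    if not l > 0:
        raise ValueError("chromosome length must be positive")
    rho, formula = _density(rel)
    value = float(2 * rel.wrights_R) * (float(rho) * l + 1.0)
    return CountFormulaResult(value, formula)


def expected_segment_length(rel: RelationshipSpec | str, l: float) -> float:
    """Expected length (Morgans) of an individual shared segment.

    ``l / (rho l + 1)``; for avuncular pairs this is the printed
    proportion-of-chromosome form ``2/(5l + 2)`` (UN) or ``2/(7l + 2)``
    (GUGN) multiplied by ``l``, so that count x length = total holds in
    one unit system.
    """
    rel = _as_spec(rel)
    if not l > 0:
        raise ValueError("chromosome length must be positive")
    rho, _ = _density(rel)
    return l / (float(rho) * l + 1.0)


def expected_total_shared(rel: RelationshipSpec | str, l: float) -> float:
    """Mean total length shared on one chromosome: 2R * l Morgans."""
    rel = _as_spec(rel)
    if not l > 0:
        raise ValueError("chromosome length must be positive")
    return float(2 * rel.wrights_R) * l


def poisson_loglr_moments(rel_true: RelationshipSpec | str,
                          rel_hyp: RelationshipSpec | str,
                          genome: GenomeModel,
                          bank: DistributionBank) -> LRMoments:
    """Moments of the Poisson-approximate log-likelihood ratio.

    The per-chromosome ratio uses only segment counts,
    ``lambda_P(n) = ln pmf(n; mu_A) - ln pmf(n; mu_B)`` with the means
    from :func:`expected_num_segments`, while the expectation and SD are
    taken over the *simulated* count distribution of the true
    relationship; cumulants add over chromosomes as in
    :func:`segshare.likelihood.lr_moments`.
    """
    spec_true, spec_hyp = _as_spec(rel_true), _as_spec(rel_hyp)
    k1 = k2 = k3 = k4 = 0.0
    for l, c in genome.length_classes:
        dA = bank.get(spec_true.abbrev, l).marginal("n")
        mu_a = expected_num_segments(spec_true, l).expected_segments
        mu_b = expected_num_segments(spec_hyp, l).expected_segments
        mean = mu2 = mu3 = mu4 = 0.0
        lam_of = {}
        for key, count in dA.counts.items():
            n = key.n_s
            lam_of[n] = (float(poisson.logpmf(n, mu_a) - poisson.logpmf(n, mu_b))
                         if mu_a != mu_b else 0.0)
        probs = {key.n_s: count / dA.N for key, count in dA.counts.items()}
        mean = sum(p * lam_of[n] for n, p in probs.items())
        mu2 = sum(p * (lam_of[n] - mean) ** 2 for n, p in probs.items())
        mu3 = sum(p * (lam_of[n] - mean) ** 3 for n, p in probs.items())
        mu4 = sum(p * (lam_of[n] - mean) ** 4 for n, p in probs.items())
        k1 += c * mean
        k2 += c * mu2
        k3 += c * mu3
        k4 += c * (mu4 - 3 * mu2**2)
    sd = math.sqrt(k2)
    if sd > 0:
        skew, exkurt, ratio = k3 / k2**1.5, k4 / k2**2, k1 / sd
    else:
        skew = exkurt = ratio = float("nan")
    return LRMoments(k1, sd, skew, exkurt, ratio, 0)
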
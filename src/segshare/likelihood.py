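"""Empirical outcome distributions, log-likelihood ratios and their moments.

Per chromosome, a relative pair's sharing is reduced to an outcome key
``k = {n_s, p_s, t_s}`` (all three components for 1 <= n_s <= 4, only
``n_s`` and ``p_s`` for n_s > 4 -- sparse length cells add mostly
simulation noise).  The probability ``P_R(k)`` of each outcome under
relationship R is estimated as the proportion of Monte-Carlo replicates,
giving a multinomial :class:`EmpiricalDistribution` per relationship and
chromosome length.

The contribution of an observed outcome to the log-likelihood ratio
between relationships A and B is ``ln P_A(k) - ln P_B(k)`` (natural
logarithms throughout); chromosomes segregate independently so
genome-wide ratios are sums over chromosomes.  When simulation estimates
a hypothesized probability as exactly zero while the other is positive,
the zero is replaced by ``1/(2N)`` with N the replicate count.

The expectation of the ratio under the true relationship is the directed
Kullback-Leibler distance; together with its SD it determines the normal
approximation ``Phi(-m/s)`` to the misclassification probability of the
sign rule (decide A iff the summed ratio is positive).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
from scipy.stats import norm

from . import __version__
from .engine import BatchSummaries, simulate_relationship
from .genome import GenomeModel
from .relationships import RelationshipSpec, get_relationship
from .summaries import SharingSummary

logger = logging.getLogger(__name__)

__all__ = [
    "OutcomeKey",
    "EmpiricalDistribution",
    "LRMoments",
    "DistributionBank",
    "estimate_distribution",
    "chrom_loglr",
    "genome_loglr",
    "lr_moments",
    "misclassification",
    "assignment_experiment",
    "distribution_of_lr",
    "length_key",
    "write_distribution",
    "read_distribution",
]

#: Information levels: segment numbers only, numbers and end-positions,
#: or numbers, positions and length-tenths (with the n_s > 4 collapse).
INFO_LEVELS = ("n", "np", "npt")

# Outcome codes pack (n_s, p_s, t_s) into one small integer so batches
# can be tallied with bincount: code = (n*3 + p)*11 + t, t forced to 0
# where the length tenth is not used.
_PMAX, _TMAX = 3, 11


class OutcomeKey(NamedTuple):
    """A realization {n_s, p_s, t_s}; absent components are None."""

    n_s: int
    p_s: Optional[int] = None
    t_s: Optional[int] = None


def _collapse(n: int, p: int, t: int, info: str) -> OutcomeKey:
    if n == 0:
        return OutcomeKey(0, None, None)
    if info == "n":
        return OutcomeKey(n, None, None)
    if info == "np":
        return OutcomeKey(n, p, None)
    return OutcomeKey(n, p, t if 1 <= n <= 4 else None)


def key_from_summary(s: SharingSummary, info: str = "npt") -> OutcomeKey:
    """Outcome key for one chromosome's summary, with the n_s > 4 collapse."""
    return _collapse(s.n_s, s.p_s, s.t_s, info)


def _encode_batch(batch: BatchSummaries, info: str) -> np.ndarray:
    n, p = batch.n_s, batch.p_s
    if info == "n":
        return n
    if info == "np":
        return np.where(n == 0, 0, n * _PMAX + p)
    t = np.where((n >= 1) & (n <= 4), batch.t_s, 0)
    return np.where(n == 0, 0, (n * _PMAX + p) * _TMAX + t)


def _decode(code: int, info: str) -> OutcomeKey:
    if code == 0:
        return OutcomeKey(0, None, None)
    if info == "n":
        return OutcomeKey(int(code), None, None)
    if info == "np":
        return OutcomeKey(int(code) // _PMAX, int(code) % _PMAX, None)
    t = code % _TMAX
    np_part = code // _TMAX
    return OutcomeKey(int(np_part) // _PMAX, int(np_part) % _PMAX,
                      int(t) if t else None)


def _encode_key(key: OutcomeKey, info: str) -> int:
    n, p, t = key
    if n == 0:
        return 0
    if info == "n":
        return n
    if info == "np":
        return n * _PMAX + p
    return (n * _PMAX + p) * _TMAX + (t if t is not None else 0)


@dataclass
class EmpiricalDistribution:
    """Estimated multinomial P_R(k) for one relationship x chromosome length."""

    relationship: str
    chrom_length: float
    N: int
    counts: dict[OutcomeKey, int]
    info: str = "npt"

    def __post_init__(self) -> None:
        if self.info not in INFO_LEVELS:
            raise ValueError(f"info must be one of {INFO_LEVELS}")
        total = sum(self.counts.values())
        if total != self.N:
            raise ValueError(f"counts sum to {total}, expected N = {self.N}")

    def prob(self, key: OutcomeKey) -> float:
        return self.counts.get(key, 0) / self.N

    def support(self) -> list[OutcomeKey]:
        return sorted(self.counts, key=lambda k: _encode_key(k, self.info))

    def marginal(self, info: str) -> "EmpiricalDistribution":
        """Collapse to a coarser information level ('n' or 'np')."""
        order = {lv: i for i, lv in enumerate(INFO_LEVELS)}
        if order[info] > order[self.info]:
            raise ValueError(f"cannot refine {self.info!r} to {info!r}")
        if info == self.info:
            return self
        out: dict[OutcomeKey, int] = {}
        for (n, p, t), c in self.counts.items():
            k = _collapse(n, p if p is not None else 0, 0, info)
            out[k] = out.get(k, 0) + c
        return EmpiricalDistribution(self.relationship, self.chrom_length,
                                     self.N, out, info)


def estimate_distribution(rel: RelationshipSpec | str, l: float, N: int,
                          rng: np.random.Generator,
                          info: str = "npt") -> EmpiricalDistribution:
    """Estimate P_R(k) from N Monte-Carlo replicates on one chromosome."""
    if isinstance(rel, str):
        rel = get_relationship(rel)
    if N < 1:
        raise ValueError("need at least one replicate")
    if info not in INFO_LEVELS:
        raise ValueError(f"info must be one of {INFO_LEVELS}")
    batch = simulate_relationship(rel, l, N, rng)
    codes = _encode_batch(batch, info)
    tallies = np.bincount(codes)
    counts = {
        _decode(code, info): int(c)
        for code, c in enumerate(tallies) if c
    }
    return EmpiricalDistribution(rel.abbrev, l, N, counts, info)


def chrom_loglr(key: OutcomeKey, distA: EmpiricalDistribution,
                distB: EmpiricalDistribution) -> float:
    """ln P_A(k) - ln P_B(k) with the 1/(2N) zero-cell substitution.

    An outcome never seen under either distribution is uninformative: it
    contributes 0 and logs a warning.
    """
    if distA.chrom_length != distB.chrom_length:
        raise ValueError("distributions are for different chromosome lengths")
    pA, pB = distA.prob(key), distB.prob(key)
    if pA == 0 and pB == 0:
        logger.warning(
            "outcome %s unseen under both %s and %s at l=%s; contributes 0",
            key, distA.relationship, distB.relationship, distA.chrom_length)
        return 0.0
    if pA == 0:
        pA = 1.0 / (2 * distA.N)
    if pB == 0:
        pB = 1.0 / (2 * distB.N)
    return math.log(pA) - math.log(pB)


def length_key(l: float) -> int:
    """Bank key for a chromosome length: rounded centimorgans."""
    return int(round(l * 100))


def genome_loglr(profile: Sequence[tuple[float, OutcomeKey]],
                 dist_bank_a: Mapping[int, EmpiricalDistribution],
                 dist_bank_b: Mapping[int, EmpiricalDistribution]) -> float:
    """Sum per-chromosome log-likelihood ratios over a genome profile.

    ``profile`` lists (chromosome length in Morgans, outcome key); the
    banks map :func:`length_key` values to distributions.
    """
    lam = 0.0
    for l, key in profile:
        lk = length_key(l)
        try:
            dA, dB = dist_bank_a[lk], dist_bank_b[lk]
        except KeyError:
            raise KeyError(f"no distribution for chromosome length {l} M") from None
        lam += chrom_loglr(key, dA, dB)
    return lam


@dataclass(frozen=True)
class LRMoments:
    """Moments of the genome-wide log-likelihood ratio under the truth.

    ``mean`` is the directed Kullback-Leibler distance in nats; ``ratio``
    is mean/SD, the noncentrality-like quantity governing the sign rule.
    ``skew``/``excess_kurtosis`` are NaN when the SD is zero (identical
    relationships).
    """

    mean: float
    sd: float
    skew: float
    excess_kurtosis: float
    ratio: float
    zero_cell_substitutions: int = 0


class DistributionBank:
    """Distributions keyed by (relationship abbrev, chromosome length).

    Lengths are keyed by rounded centimorgans so float noise cannot split
    a length class.
    """

    def __init__(self) -> None:
        self._store: dict[tuple[str, int], EmpiricalDistribution] = {}

    def add(self, dist: EmpiricalDistribution) -> None:
        self._store[(dist.relationship, length_key(dist.chrom_length))] = dist

    def get(self, abbrev: str, l: float) -> EmpiricalDistribution:
        try:
            return self._store[(abbrev, length_key(l))]
        except KeyError:
            raise KeyError(
                f"no distribution for ({abbrev!r}, {l} M) in bank") from None

    def __contains__(self, item: tuple[str, float]) -> bool:
        return (item[0], length_key(item[1])) in self._store

    def __len__(self) -> int:
        return len(self._store)

    @property
    def entries(self) -> list[tuple[str, int]]:
        return sorted(self._store)

    def for_relationship(self, abbrev: str) -> dict[int, EmpiricalDistribution]:
        """Per-length mapping usable with :func:`genome_loglr`."""
        return {lk: d for (ab, lk), d in self._store.items() if ab == abbrev}

    @classmethod
    def build(cls, relationships: Iterable[RelationshipSpec | str],
              lengths: Iterable[float] | GenomeModel, N: int,
              rng: np.random.Generator, info: str = "npt") -> "DistributionBank":
        """Simulate a bank: N replicates per (relationship, length)."""
        if isinstance(lengths, GenomeModel):
            lengths = [l for l, _ in lengths.length_classes]
        bank = cls()
        for rel in relationships:
            for l in lengths:
                bank.add(estimate_distribution(rel, l, N, rng, info))
        return bank

    def save(self, directory, seed: int | None = None) -> list[Path]:
        """Write one tab-separated bank file per (relationship, length)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for (abbrev, lk) in self.entries:
            path = directory / f"bank_{abbrev}_{lk}cM.tsv"
            write_distribution(self._store[(abbrev, lk)], path, seed=seed)
            paths.append(path)
        return paths

    @classmethod
    def load(cls, directory) -> "DistributionBank":
        bank = cls()
        files = sorted(Path(directory).glob("bank_*.tsv"))
        if not files:
            raise FileNotFoundError(f"no bank files under {directory}")
        for path in files:
            bank.add(read_distribution(path))
        return bank


def write_distribution(dist: EmpiricalDistribution, path,
                       seed: int | None = None) -> None:
    """One record per outcome key; absent components are written as '.'."""
    with open(path, "w") as fh:
        fh.write(f"# relationship={dist.relationship} "
                 f"length_cM={length_key(dist.chrom_length)} N={dist.N} "
                 f"seed={'NA' if seed is None else seed} info={dist.info} "
                 f"version={__version__}\n")
        fh.write("relationship\tlength_cM\tn_s\tp_s\tt_s\tcount\n")
        for key in dist.support():
            p = "." if key.p_s is None else key.p_s
            t = "." if key.t_s is None else key.t_s
            fh.write(f"{dist.relationship}\t{length_key(dist.chrom_length)}\t"
                     f"{key.n_s}\t{p}\t{t}\t{dist.counts[key]}\n")


def read_distribution(path) -> EmpiricalDistribution:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing bank header")
        meta = dict(item.split("=", 1) for item in header[1:].split())
        fh.readline()  # column names
        counts: dict[OutcomeKey, int] = {}
        for line in fh:
            _, _, n, p, t, c = line.rstrip("\n").split("\t")
            key = OutcomeKey(int(n), None if p == "." else int(p),
                             None if t == "." else int(t))
            counts[key] = int(c)
    return EmpiricalDistribution(
        relationship=meta["relationship"],
        chrom_length=int(meta["length_cM"]) / 100.0,
        N=int(meta["N"]), counts=counts, info=meta.get("info", "npt"))


def _loglr_support(distA: EmpiricalDistribution, distB: EmpiricalDistribution
                   ) -> tuple[list[OutcomeKey], np.ndarray, np.ndarray, int]:
    """Truth probabilities and lambda values over A's support.

    Returns (keys, p_A, lambda, zero-cell substitution count).
    """
    keys = distA.support()
    pA = np.array([distA.prob(k) for k in keys])
    pB = np.array([distB.prob(k) for k in keys])
    zero = pB == 0
    n_sub = int(np.count_nonzero(zero))
    pB = np.where(zero, 1.0 / (2 * distB.N), pB)
    lam = np.log(pA) - np.log(pB)
    return keys, pA, lam, n_sub


def lr_moments(rel_true: RelationshipSpec | str, rel_hyp: RelationshipSpec | str,
               genome: GenomeModel, bank: DistributionBank,
               info: str = "npt") -> LRMoments:
    """Moments of the genome-wide log-likelihood ratio lambda(true : hyp).

    Per chromosome length the mean, variance and 3rd/4th central moments
    of the per-chromosome ratio are taken under the true distribution;
    chromosomes are independent so cumulants add across the genome
    (kappa_4 = mu_4 - 3 mu_2^2).
    """
    ab_true = rel_true if isinstance(rel_true, str) else rel_true.abbrev
    ab_hyp = rel_hyp if isinstance(rel_hyp, str) else rel_hyp.abbrev
    k1 = k2 = k3 = k4 = 0.0
    n_sub = 0
    for l, c in genome.length_classes:
        dA = bank.get(ab_true, l).marginal(info)
        dB = bank.get(ab_hyp, l).marginal(info)
        _, pA, lam, sub = _loglr_support(dA, dB)
        n_sub += sub
        mean = float(pA @ lam)
        dev = lam - mean
        mu2 = float(pA @ dev**2)
        mu3 = float(pA @ dev**3)
        mu4 = float(pA @ dev**4)
        k1 += c * mean
        k2 += c * mu2
        k3 += c * mu3
        k4 += c * (mu4 - 3 * mu2**2)
    if n_sub:
        logger.info("lr_moments(%s:%s): %d zero-cell substitutions of 1/(2N)",
                    ab_true, ab_hyp, n_sub)
    sd = math.sqrt(k2)
    if sd > 0:
        skew, exkurt, ratio = k3 / k2**1.5, k4 / k2**2, k1 / sd
    else:
        skew = exkurt = ratio = float("nan")
    return LRMoments(k1, sd, skew, exkurt, ratio, n_sub)


def misclassification(moments_ab: LRMoments, moments_ba: LRMoments
                      ) -> tuple[float, float]:
    """Normal-approximation misclassification probabilities of the sign rule.

    Given moments of lambda(A:B) under A and of lambda(B:A) under B,
    returns (Phi(-m_A/s_A), Phi(-m_B/s_B)): the probability of wrongly
    deciding B when A is true, and of wrongly deciding A when B is true.
    """
    if not (moments_ab.sd > 0 and moments_ba.sd > 0):
        raise ValueError("misclassification needs positive SDs")
    return (float(norm.cdf(-moments_ab.mean / moments_ab.sd)),
            float(norm.cdf(-moments_ba.mean / moments_ba.sd)))


def _lambda_table(distA: EmpiricalDistribution, distB: EmpiricalDistribution,
                  info: str, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Code-indexed lambda lookup with zero-cell substitution both ways.

    Codes outside the union support get lambda 0 and are flagged in the
    returned boolean 'informative' mask.
    """
    lam = np.zeros(size)
    informative = np.zeros(size, dtype=bool)
    keys = set(distA.counts) | set(distB.counts)
    for key in keys:
        code = _encode_key(key, info)
        if code >= size:
            continue  # cannot be produced by the scoring batch
        pA, pB = distA.prob(key), distB.prob(key)
        if pA == 0:
            pA = 1.0 / (2 * distA.N)
        if pB == 0:
            pB = 1.0 / (2 * distB.N)
        lam[code] = math.log(pA) - math.log(pB)
        informative[code] = True
    return lam, informative


def _sample_genome_loglr(rel_sim: str, rel_a: str, rel_b: str,
                         genome: GenomeModel, bank: DistributionBank,
                         M: int, rng: np.random.Generator,
                         info: str = "npt") -> np.ndarray:
    """lambda(A:B) for M fresh genomes simulated under ``rel_sim``."""
    spec = get_relationship(rel_sim)
    lam = np.zeros(M)
    n_uninformative = 0
    for l, c in genome.length_classes:
        batch = simulate_relationship(spec, l, M * c, rng)
        codes = _encode_batch(batch, info)
        dA = bank.get(rel_a, l).marginal(info)
        dB = bank.get(rel_b, l).marginal(info)
        table, informative = _lambda_table(dA, dB, info, int(codes.max()) + 1)
        n_uninformative += int(np.count_nonzero(~informative[codes]))
        lam += table[codes].reshape(M, c).sum(axis=1)
    if n_uninformative:
        logger.warning(
            "%d chromosome outcomes unseen under both %s and %s contributed 0",
            n_uninformative, rel_a, rel_b)
    return lam


def assignment_experiment(rel_a: RelationshipSpec | str,
                          rel_b: RelationshipSpec | str,
                          genome: GenomeModel, bank: DistributionBank, M: int,
                          rng: np.random.Generator,
                          info: str = "npt") -> tuple[float, float]:
    """Correct-assignment rates of the sign rule from held-out genomes.

    Simulates M fresh genome profiles under each relationship (with an
    RNG stream independent of the one that built ``bank``) and counts the
    fraction classified correctly by the sign of the summed ratio; exact
    ties count one half.
    """
    ab_a = rel_a if isinstance(rel_a, str) else rel_a.abbrev
    ab_b = rel_b if isinstance(rel_b, str) else rel_b.abbrev
    if M < 1:
        raise ValueError("need at least one trial")
    lam_a = _sample_genome_loglr(ab_a, ab_a, ab_b, genome, bank, M, rng, info)
    lam_b = _sample_genome_loglr(ab_b, ab_b, ab_a, genome, bank, M, rng, info)
    rate_a = float(np.mean(lam_a > 0) + 0.5 * np.mean(lam_a == 0))
    rate_b = float(np.mean(lam_b > 0) + 0.5 * np.mean(lam_b == 0))
    return rate_a, rate_b


def distribution_of_lr(rel_true: RelationshipSpec | str,
                       rel_hyp: RelationshipSpec | str,
                       genome: GenomeModel, bank: DistributionBank, M: int,
                       rng: np.random.Generator,
                       info: str = "npt") -> np.ndarray:
    """Sample of genome-wide lambda standardized by its moment-based SD.

    For identical relationships every value is 0 (the SD is zero too, so
    no standardization is applied in that degenerate case).
    """
    ab_true = rel_true if isinstance(rel_true, str) else rel_true.abbrev
    ab_hyp = rel_hyp if isinstance(rel_hyp, str) else rel_hyp.abbrev
    lam = _sample_genome_loglr(ab_true, ab_true, ab_hyp, genome, bank, M, rng, info)
    mom = lr_moments(ab_true, ab_hyp, genome, bank, info)
    if mom.sd == 0:
        return lam
    return lam / mom.sd
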
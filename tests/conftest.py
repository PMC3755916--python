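"""Shared fixtures: reference tables and session-scoped simulation runs.

The heavier Monte-Carlo artifacts (the single-chromosome runs behind the
segment-count table and the human-genome distribution bank) are built
once per session and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import segshare as ss

#: Published mean and variance of the number of shared segments on a
#: chromosome of 1.632 M, from 300,000-replicate simulations.
COUNT_MOMENTS_REF = {
    "UN": (2.539, 1.170), "GUGN": (1.678, 1.482), "C": (1.885, 1.311),
    "C1R": (1.147, 1.213), "2C": (0.674, 0.845), "2C1R": (0.387, 0.519),
    "3C": (0.219, 0.299),
    "HS": (2.135, 0.942), "HUN": (1.475, 1.187), "HC": (0.941, 1.020),
    "HC1R": (0.572, 0.714), "H2C": (0.336, 0.445), "H2C1R": (0.193, 0.258),
    "GPO": (1.316, 0.537), "GGPO": (1.066, 0.767), "G3PO": (0.736, 0.721),
    "G4PO": (0.471, 0.543), "G5PO": (0.287, 0.358), "G6PO": (0.169, 0.217),
}
COUNT_MOMENTS_REF_N = 300_000

#: Published replicate counts (out of 100,000) of the number of shared
#: segments n_s = 0, 1, 2, ... on a chromosome of 1.632 M.
COUNT_DIST_REF = {
    "UN": [921, 14948, 35379, 31041, 13556, 3501, 587, 65, 2, 0],
    "HS": [1826, 24700, 41257, 24284, 6675, 1150, 101, 6, 1, 0],
    "GUGN": [17696, 29825, 28580, 16286, 5940, 1408, 237, 26, 2, 0],
}
COUNT_DIST_REF_N = 100_000

AVG_CHROM = 1.632  # Morgans; the model human genome's average length


@pytest.fixture(scope="session")
def count_runs() -> dict[str, ss.BatchSummaries]:
    """100,000 engine replicates per relationship at l = 1.632 M."""
    rng = np.random.default_rng(20130901)
    return {
        rel.abbrev: ss.simulate_relationship(rel, AVG_CHROM, 100_000, rng)
        for rel in ss.relationship_catalog()
    }


@pytest.fixture(scope="session")
def human5_bank() -> ss.DistributionBank:
    """Outcome distributions on the five-length human genome model.

    100,000 replicates per chromosome length for the six relationships
    exercised by the genome-level checks.
    """
    rng = np.random.default_rng(35900)
    return ss.DistributionBank.build(
        ["UN", "HS", "C", "HC", "2C1R", "3C"], ss.make_genome("human5"),
        100_000, rng)


@pytest.fixture(scope="session")
def equal22_bank() -> ss.DistributionBank:
    """300,000-replicate UN and HS distributions at the average length."""
    rng = np.random.default_rng(1632)
    return ss.DistributionBank.build(
        ["UN", "HS"], ss.make_genome("equal22"), 300_000, rng)


def table_from_counts(abbrev: str, counts: list[int], l: float = AVG_CHROM,
                      N: int = COUNT_DIST_REF_N) -> ss.EmpiricalDistribution:
    """Build a segment-count-only distribution from printed tallies."""
    return ss.EmpiricalDistribution(
        relationship=abbrev, chrom_length=l, N=N,
        counts={ss.OutcomeKey(n, None, None): c
                for n, c in enumerate(counts) if c},
        info="n")
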
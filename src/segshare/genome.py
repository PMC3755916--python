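"""Genome models: collections of chromosome map lengths.

A genome model is the fixed frame over which per-chromosome sharing
statistics are aggregated.  Lengths are stored in Morgans internally;
centimorgans are accepted at I/O boundaries and converted (factor 100).

Built-in models
---------------
``human5``
    Model human autosomal genome with map lengths simplified into five
    classes: 2 x 0.75 M, 8 x 1.25 M, 6 x 1.75 M, 4 x 2.1 M and 2 x 2.75 M,
    totaling 35.9 M over 22 chromosomes.
``equal22``
    22 chromosomes of the average length 1.632 M.
``many72`` / ``few12``
    72 x 0.5 M and 12 x 3.0 M; genomes of equal total length (36 M) but
    very different chromosome number, used to study the effect of
    chromosome number on discriminating power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "ChromosomeSpec",
    "GenomeModel",
    "BUILTIN_MODELS",
    "make_genome",
    "genome_from_config",
]


@dataclass(frozen=True)
class ChromosomeSpec:
    """A class of ``count`` chromosomes sharing one map length (Morgans)."""

    map_length: float
    count: int = 1

    def __post_init__(self) -> None:
        if not self.map_length > 0:
            raise ValueError(f"map_length must be positive, got {self.map_length}")
        if not (isinstance(self.count, int) and self.count >= 1):
            raise ValueError(f"count must be a positive integer, got {self.count}")


@dataclass(frozen=True)
class GenomeModel:
    """An ordered set of chromosome length classes with a name."""

    name: str
    specs: tuple[ChromosomeSpec, ...]

    def __post_init__(self) -> None:
        if not self.specs:
            raise ValueError("a genome model needs at least one chromosome")

    @property
    def n_chromosomes(self) -> int:
        return sum(s.count for s in self.specs)

    @property
    def total_length(self) -> float:
        """Total map length L in Morgans."""
        return sum(s.count * s.map_length for s in self.specs)

    @property
    def lengths(self) -> tuple[float, ...]:
        """Per-chromosome map lengths, expanded in spec order."""
        out: list[float] = []
        for s in self.specs:
            out.extend([s.map_length] * s.count)
        return tuple(out)

    @property
    def length_classes(self) -> tuple[tuple[float, int], ...]:
        """(map_length, count) pairs in spec order."""
        return tuple((s.map_length, s.count) for s in self.specs)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "chromosomes": [
                {"length_M": s.map_length, "count": s.count} for s in self.specs
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenomeModel":
        specs = tuple(
            ChromosomeSpec(_length_from_entry(c), int(c.get("count", 1)))
            for c in d["chromosomes"]
        )
        return cls(name=str(d.get("name", "custom")), specs=specs)


def _length_from_entry(entry: Mapping) -> float:
    if "length_M" in entry:
        return float(entry["length_M"])
    if "length_cM" in entry:
        return float(entry["length_cM"]) / 100.0
    raise ValueError("chromosome entry needs 'length_M' or 'length_cM'")


def _builtin(name: str, pairs: Iterable[tuple[float, int]]) -> GenomeModel:
    return GenomeModel(name, tuple(ChromosomeSpec(l, c) for l, c in pairs))


BUILTIN_MODELS: dict[str, GenomeModel] = {
    "human5": _builtin(
        "human5", [(0.75, 2), (1.25, 8), (1.75, 6), (2.1, 4), (2.75, 2)]
    ),
    "equal22": _builtin("equal22", [(1.632, 22)]),
    "many72": _builtin("many72", [(0.5, 72)]),
    "few12": _builtin("few12", [(3.0, 12)]),
}


def make_genome(name: str) -> GenomeModel:
    """Return a built-in genome model by name.

    Raises
    ------
    KeyError
        If ``name`` is not a built-in model.
    """
    try:
        return BUILTIN_MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown genome model {name!r}; built-ins: {sorted(BUILTIN_MODELS)}"
        ) from None


def genome_from_config(config: Mapping) -> GenomeModel:
    """Build a genome model from a config mapping.

    The mapping follows ``{"genome": {"name": ...}}`` for a built-in, or
    ``{"genome": {"chromosomes": [{"length_M"|"length_cM": x, "count": c}]}}``
    for a user model.  A bare inner mapping (without the ``genome`` key) is
    also accepted.
    """
    inner = config.get("genome", config)
    if "name" in inner and "chromosomes" not in inner:
        return make_genome(inner["name"])
    return GenomeModel.from_dict(inner)
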
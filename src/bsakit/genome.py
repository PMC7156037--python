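"""Genome coordinate model shared by every pipeline stage.

All internal coordinates are 1-based inclusive (the convention of VCF and
GFF); BED output converts to 0-based half-open at the file boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping


class ConfigurationError(ValueError):
    """Raised for inconsistent genome or simulation configuration."""


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths, pericentromere intervals and recombination rate.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    pericentromere
        Per-chromosome ``(start, end)`` interval, 1-based inclusive.
        Chromosomes without an entry have no pericentromeric compartment.
    cm_per_mb
        Uniform recombination rate in centimorgan per megabase.
    """

    chromosomes: tuple[tuple[str, int], ...]
    pericentromere: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    cm_per_mb: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))
        object.__setattr__(self, "pericentromere", dict(self.pericentromere))
        if not self.chromosomes:
            raise ConfigurationError("genome needs at least one chromosome")
        seen = set()
        for name, length in self.chromosomes:
            if length <= 0:
                raise ConfigurationError(f"chromosome {name!r} has non-positive length {length}")
            if name in seen:
                raise ConfigurationError(f"duplicate chromosome name {name!r}")
            seen.add(name)
        lengths = dict(self.chromosomes)
        for name, (start, end) in self.pericentromere.items():
            if name not in lengths:
                raise ConfigurationError(f"pericentromere on unknown chromosome {name!r}")
            if not (1 <= start <= end <= lengths[name]):
                raise ConfigurationError(
                    f"pericentromere ({start}, {end}) not contained in chromosome {name!r}"
                )
        if self.cm_per_mb <= 0:
            raise ConfigurationError("cm_per_mb must be positive")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def contains(self, chrom: str, pos: int) -> bool:
        try:
            return 1 <= pos <= self.length(chrom)
        except KeyError:
            return False

    def genetic_distance(self, bp: float) -> float:
        """Physical distance (bp) to genetic distance in Morgans.

        Uses the uniform map: ``d = bp * cm_per_mb / 1e6 / 100``.
        """
        return bp * self.cm_per_mb / 1e6 / 100.0


def haldane_r(d: float) -> float:
    """Recombination fraction for genetic distance *d* (Morgans).

    Haldane's map function ``r = (1 - exp(-2d)) / 2``; no interference.
    """
    if d < 0:
        raise ValueError("genetic distance must be non-negative")
    return 0.5 * (1.0 - math.exp(-2.0 * d))


def haldane_d(r: float) -> float:
    """Inverse of :func:`haldane_r`: genetic distance for fraction *r*."""
    if not 0 <= r < 0.5:
        raise ValueError("recombination fraction must be in [0, 0.5)")
    return -0.5 * math.log(1.0 - 2.0 * r)


@dataclass(frozen=True)
class RecombinationModel:
    """Map function linking genetic distance to recombination fraction."""

    name: str = "haldane"

    def recombination_fraction(self, d: float) -> float:
        if self.name != "haldane":
            raise ConfigurationError(f"unknown map function {self.name!r}")
        return haldane_r(d)


@dataclass(frozen=True)
class Locus:
    """An annotated genomic feature (gene or transposable element)."""

    id: str
    chrom: str
    start: int
    end: int
    locus_class: str = "gene"  # "gene" | "TE"
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus {self.id}: start {self.start} > end {self.end}")
        if self.locus_class not in ("gene", "TE"):
            raise ValueError(f"locus {self.id}: class must be 'gene' or 'TE'")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"locus {self.id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class LocusSet:
    """Named collection of loci — the unit of every enrichment/overlap test."""

    def __init__(self, name: str, members: Iterable[Locus], genome: GenomeModel | None = None):
        self.name = name
        self.members: tuple[Locus, ...] = tuple(members)
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate locus IDs in set {name!r}: {dup[:5]}")
        if genome is not None:
            for m in self.members:
                if not genome.contains(m.chrom, m.start) or not genome.contains(m.chrom, m.end):
                    raise ValueError(
                        f"locus {m.id} ({m.chrom}:{m.start}-{m.end}) outside genome bounds"
                    )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Locus]:
        return iter(self.members)

    @property
    def ids(self) -> set[str]:
        return {m.id for m in self.members}

    def filter_class(self, locus_class: str) -> "LocusSet":
        return LocusSet(
            f"{self.name}[{locus_class}]",
            (m for m in self.members if m.locus_class == locus_class),
        )

    def to_bed(self, path: str) -> None:
        """Write BED6 (0-based half-open) with the class in the name column."""
        with open(path, "w") as fh:
            for m in self.members:
                score = 0
                fh.write(
                    f"{m.chrom}\t{m.start - 1}\t{m.end}\t{m.id};{m.locus_class}\t{score}\t{m.strand}\n"
                )

    @classmethod
    def from_bed(cls, name: str, path: str) -> "LocusSet":
        """Read BED (≥3 columns, 0-based half-open); name column may carry
        ``id;class``."""
        members = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]) + 1, int(parts[2])
                raw = parts[3] if len(parts) > 3 else f"{name}_{i}"
                strand = parts[5] if len(parts) > 5 else "."
                if ";" in raw:
                    lid, lclass = raw.split(";", 1)
                else:
                    lid, lclass = raw, "gene"
                members.append(Locus(lid, chrom, start, end, lclass, strand))
        return cls(name, members)


def read_id_list(path: str) -> list[str]:
    """Newline-delimited locus IDs (first TSV column if tab-separated)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0])
    return out
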
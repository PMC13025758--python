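"""Genome coordinate model: chromosome arms, intervals, region strings.

All internal coordinates are 0-based half-open (BED convention). Text
representations — region strings like ``2R:18,868,928-21,135,871`` and VCF
POS fields — are 1-based inclusive and are converted at the boundary.

The default model is the six euchromatic arms of the *Drosophila
melanogaster* dm6 assembly (2L, 2R, 3L, 3R, X, 4), at their conventional
rounded sizes totalling 133.88 Mb.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping


class CoordinateError(ValueError):
    """An interval or position falls outside the genome model."""


#: Arm sizes (bp) of the default dm6-like six-arm model, in canonical order.
DEFAULT_ARMS: tuple[tuple[str, int], ...] = (
    ("2L", 23_510_000),
    ("2R", 25_290_000),
    ("3L", 28_110_000),
    ("3R", 32_080_000),
    ("X", 23_540_000),
    ("4", 1_350_000),
)

#: Arm label -> physical chromosome (linkage group) of the default model.
ARM_TO_CHROMOSOME: Mapping[str, str] = {
    "2L": "2",
    "2R": "2",
    "3L": "3",
    "3R": "3",
    "X": "X",
    "4": "4",
}


@dataclass(frozen=True)
class GenomeModel:
    """Ordered named chromosome arms with lengths in base pairs."""

    arms: tuple[tuple[str, int], ...] = DEFAULT_ARMS

    def __post_init__(self) -> None:
        names = [name for name, _ in self.arms]
        if len(set(names)) != len(names):
            raise ValueError("arm names must be unique")
        for name, length in self.arms:
            if not isinstance(length, int) or length <= 0:
                raise ValueError(f"arm {name!r} length must be a positive integer")
        object.__setattr__(self, "arms", tuple((n, int(l)) for n, l in self.arms))

    @property
    def arm_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.arms)

    @property
    def lengths(self) -> Mapping[str, int]:
        return dict(self.arms)

    def arm_length(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise CoordinateError(f"unknown chromosome arm {name!r}") from None

    @property
    def total_size(self) -> int:
        """Total genome size in base pairs."""
        return sum(length for _, length in self.arms)

    def __contains__(self, name: object) -> bool:
        return name in self.lengths

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.arms)

    def scaled(self, factor: float) -> "GenomeModel":
        """A model with every arm length multiplied by ``factor`` (min 1 bp)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return GenomeModel(
            tuple((name, max(1, int(round(length * factor)))) for name, length in self.arms)
        )


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open genomic interval on one arm."""

    chrom: str
    start: int
    end: int
    #: True when the interval was parsed from 1-based inclusive text; affects
    #: only how :func:`interval_length_mb` interprets the printed length.
    one_based_source: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """Whether a 0-based position lies inside the interval."""
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def validate(self, genome: GenomeModel) -> "Interval":
        if self.end > genome.arm_length(self.chrom):
            raise CoordinateError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds arm "
                f"length {genome.arm_length(self.chrom)}"
            )
        return self

    # -- text rendering ---------------------------------------------------

    def to_region_string(self, thousands: bool = True) -> str:
        """Render as a 1-based inclusive region string (``2R:1-100``)."""
        start1, end1 = self.start + 1, self.end
        if thousands:
            return f"{self.chrom}:{start1:,}-{end1:,}"
        return f"{self.chrom}:{start1}-{end1}"


_REGION_RE = re.compile(
    r"^(?P<chrom>[^:]+):(?P<start>[\d,]+)\s*[-–—]\s*(?P<end>[\d,]+)$"
)


def parse_region(text: str, genome: GenomeModel | None = None) -> Interval:
    """Parse a 1-based inclusive region string into a half-open Interval.

    Accepts hyphen, en-dash, or em-dash separators and thousands commas,
    e.g. ``"2R:18,868,928–21,135,871"``.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise CoordinateError(f"cannot parse region string {text!r}")
    start1 = int(m.group("start").replace(",", ""))
    end1 = int(m.group("end").replace(",", ""))
    if start1 < 1 or end1 < start1:
        raise CoordinateError(f"bad coordinates in region string {text!r}")
    iv = Interval(m.group("chrom"), start1 - 1, end1, one_based_source=True)
    if genome is not None:
        iv.validate(genome)
    return iv


def interval_length_mb(iv: Interval, decimals: int = 1) -> float:
    """Interval length in megabases, rounded to ``decimals``.

    Half-open length (end − start); for an interval parsed from 1-based
    inclusive text this already equals the printed inclusive length
    (end₁ − start₁ + 1), since conversion shifts only the start.
    """
    return round(len(iv) / 1e6, decimals)


def total_size_mb(genome: GenomeModel) -> float:
    """Total genome size in Mb, rounded to 2 decimals."""
    return round(genome.total_size / 1e6, 2)


def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA file into an upper-cased name -> sequence dict."""
    import pyfaidx

    with pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    """Write sequences as an uncompressed FASTA file."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def arm_chromosome(arm: str) -> str:
    """Physical chromosome (linkage group) an arm belongs to.

    Unknown arms map to themselves, so custom single-arm chromosomes work.
    """
    return ARM_TO_CHROMOSOME.get(arm, arm)


def chromosome_arms(genome: GenomeModel, chromosome: str) -> list[str]:
    """Arms of ``genome`` belonging to the given physical chromosome."""
    return [a for a in genome.arm_names if arm_chromosome(a) == chromosome]
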
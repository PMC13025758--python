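"""Presence/absence variant-pattern filtering across sequenced lines.

The mapping logic: a dominant suppressor that rode along on recombinant
chromosomes must be *present* in every line that carries the suppressor
phenotype and *absent* in every line that does not. Applied to per-line
variant call sets, that presence/absence rule (the "Tofu pattern" of the
BEAF-suppressor screen: present in NP6377, Tofu NP and Tofu KO, absent in
ABKO and y⁻w⁻) reduces hundreds of thousands of calls per line to a
candidate set.

Variants are identified by their normalized key ``(chrom, pos, ref, alt)``
— multiallelic records are split, indels left-aligned and trimmed — so two
lines match only when they share the same allele, not merely the same
position (a position-only mode mirrors naive interval-based comparison).
Positions are 0-based internally; VCF POS converts at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .genome import GenomeModel, CoordinateError, arm_chromosome

__all__ = [
    "Variant",
    "PatternSpec",
    "normalize_variant",
    "decompose_record",
    "read_line_vcf",
    "read_multisample_vcf",
    "apply_pattern",
    "count_by_arm",
    "count_matrix",
    "write_candidate_vcf",
]

SNP, INS, DEL = "SNP", "INS", "DEL"


class VcfParseError(ValueError):
    """A malformed VCF record (reported with its line context)."""


@dataclass(frozen=True, order=True)
class Variant:
    """A normalized sequence variant key.

    ``pos`` is the 0-based position of the first reference base; ``ref`` and
    ``alt`` are trimmed, left-aligned allele strings (anchor-base form for
    indels, as in VCF).
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.pos < 0:
            raise ValueError("pos must be non-negative")

    @property
    def variant_class(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return SNP
        return INS if len(self.alt) > len(self.ref) else DEL

    @property
    def is_indel(self) -> bool:
        return self.variant_class != SNP

    @property
    def pos1(self) -> int:
        """1-based VCF position."""
        return self.pos + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos1}{self.ref}>{self.alt}"


SequenceAccessor = Callable[[str, int, int], str]


def _accessor(reference: Mapping[str, str] | SequenceAccessor | None) -> SequenceAccessor | None:
    if reference is None or callable(reference):
        return reference
    return lambda chrom, start, end: reference[chrom][start:end]


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Mapping[str, str] | SequenceAccessor | None = None,
) -> Variant:
    """Trim and left-align one allele pair into a canonical Variant.

    Follows the standard parsimony/left-alignment procedure: shared suffix
    bases are dropped (extending left through the reference when an allele
    empties), then shared prefix bases are dropped while both alleles keep
    at least one base. Without a reference accessor only trimming is
    performed (no left shift).
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt:
        raise ValueError("cannot normalize empty alleles")
    seq = _accessor(reference)
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif (
            seq is not None
            and ref[-1] == alt[-1]
            and (len(ref) == 1 or len(alt) == 1)
            and len(ref) != len(alt)
            and pos > 0
        ):
            base = seq(chrom, pos - 1, pos).upper()
            ref, alt = base + ref[:-1], base + alt[:-1]
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return Variant(chrom, pos, ref, alt)


def decompose_record(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    reference: Mapping[str, str] | SequenceAccessor | None = None,
) -> list[Variant]:
    """Split a (possibly multiallelic) record into normalized Variants."""
    out = []
    for alt in alts:
        if alt is None or alt in {".", "*", "<NON_REF>"} or alt.startswith("<"):
            continue
        out.append(normalize_variant(chrom, pos, ref, alt, reference))
    return out


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------


def _called_present(gt: tuple | None) -> bool:
    """Default presence policy: any called non-reference allele.

    Missing genotypes (./.) count as absent; a record with no GT field at
    all is treated as present (site-only VCF).
    """
    if gt is None:
        return True
    return any(a is not None and a > 0 for a in gt)


def _alt_indices_present(gt: tuple | None, n_alts: int) -> set[int]:
    if gt is None:
        return set(range(1, n_alts + 1))
    return {a for a in gt if a is not None and a > 0}


def read_line_vcf(
    path: str,
    line_label: str | None = None,
    genome: GenomeModel | None = None,
    reference: Mapping[str, str] | SequenceAccessor | None = None,
    min_qual: float | None = None,
) -> set[Variant]:
    """Read one line's VCF into a set of normalized variant keys.

    ``line_label`` picks a sample column (default: the first, or site-only
    presence when the VCF has no samples). Presence follows the default
    policy of :func:`_called_present`; ``min_qual`` optionally drops
    records below a QUAL threshold (off by default — no quality filtering
    is assumed).
    """
    out: set[Variant] = set()
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if line_label is not None and line_label not in samples and samples:
            raise VcfParseError(f"sample {line_label!r} not in {path}: {samples}")
        sample = line_label if (line_label in samples) else (samples[0] if samples else None)
        for i, rec in enumerate(vcf):
            try:
                if min_qual is not None and rec.qual is not None and rec.qual < min_qual:
                    continue
                if genome is not None and rec.chrom not in genome:
                    raise CoordinateError(
                        f"contig {rec.chrom!r} not in genome model ({path})"
                    )
                alts = rec.alts or ()
                gt = rec.samples[sample].get("GT") if sample is not None else None
                present = _alt_indices_present(gt, len(alts))
                for j, alt in enumerate(alts, start=1):
                    if j not in present:
                        continue
                    for v in decompose_record(rec.chrom, rec.start, rec.ref, [alt], reference):
                        if genome is not None and v.pos + len(v.ref) > genome.arm_length(v.chrom):
                            raise CoordinateError(f"variant {v} exceeds arm bounds")
                        out.add(v)
            except (CoordinateError, VcfParseError):
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise VcfParseError(f"malformed record #{i + 1} in {path}: {exc}") from exc
    return out


def read_multisample_vcf(
    path: str,
    label_map: Mapping[str, str] | None = None,
    genome: GenomeModel | None = None,
    reference: Mapping[str, str] | SequenceAccessor | None = None,
) -> dict[str, set[Variant]]:
    """Read a multi-sample VCF into per-line variant key sets.

    ``label_map`` maps VCF sample names to line labels (default: identity).
    """
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise VcfParseError(f"{path} has no sample columns")
        labels = {s: (label_map or {}).get(s, s) for s in samples}
        out: dict[str, set[Variant]] = {lab: set() for lab in labels.values()}
        for rec in vcf:
            alts = rec.alts or ()
            per_alt = decompose_record(rec.chrom, rec.start, rec.ref, alts, reference)
            alt_to_variant = dict(zip([a for a in alts], per_alt))
            for s in samples:
                gt = rec.samples[s].get("GT")
                for j in _alt_indices_present(gt, len(alts)):
                    alt = alts[j - 1]
                    if alt in alt_to_variant:
                        out[labels[s]].add(alt_to_variant[alt])
    return out


# ---------------------------------------------------------------------------
# Pattern filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatternSpec:
    """The presence/absence design: lines that must carry the variant and
    lines that must not."""

    present_in: frozenset[str]
    absent_in: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "present_in", frozenset(self.present_in))
        object.__setattr__(self, "absent_in", frozenset(self.absent_in))
        if not self.present_in or not self.absent_in:
            raise ValueError("present_in and absent_in must both be non-empty")
        if self.present_in & self.absent_in:
            raise ValueError("present_in and absent_in must be disjoint")

    @property
    def lines(self) -> frozenset[str]:
        return self.present_in | self.absent_in


def apply_pattern(
    line_sets: Mapping[str, Iterable[Variant]],
    spec: PatternSpec,
    position_only: bool = False,
) -> set[Variant]:
    """Variants present in every ``present_in`` line and no ``absent_in`` line.

    With ``position_only=True``, matching between lines uses ``(chrom, pos)``
    only — the behaviour of a naive interval-based VCF comparison — and the
    returned variants are drawn from the first ``present_in`` line's keys.
    """
    missing = spec.lines - set(line_sets)
    if missing:
        raise KeyError(f"pattern references unknown line labels: {sorted(missing)}")

    if not position_only:
        sets = {lab: set(line_sets[lab]) for lab in spec.lines}
        candidates = set.intersection(*(sets[lab] for lab in sorted(spec.present_in)))
        for lab in spec.absent_in:
            candidates -= sets[lab]
        return candidates

    def positions(lab: str) -> set[tuple[str, int]]:
        return {(v.chrom, v.pos) for v in line_sets[lab]}

    keep = set.intersection(*(positions(lab) for lab in sorted(spec.present_in)))
    for lab in spec.absent_in:
        keep -= positions(lab)
    first = sorted(spec.present_in)[0]
    return {v for v in line_sets[first] if (v.chrom, v.pos) in keep}


# ---------------------------------------------------------------------------
# Per-arm counting (Table-2-style matrix)
# ---------------------------------------------------------------------------


def count_by_arm(variants: Iterable[Variant], genome: GenomeModel) -> pd.Series:
    """Variant counts per arm plus a Total column, in canonical arm order."""
    counts = {name: 0 for name in genome.arm_names}
    for v in variants:
        if v.chrom not in counts:
            raise CoordinateError(f"variant {v} on unknown arm {v.chrom!r}")
        counts[v.chrom] += 1
    row = pd.Series(counts, dtype=int)
    row["Total"] = int(row.sum())
    return row


def count_matrix(
    line_sets: Mapping[str, Iterable[Variant]],
    candidates: Iterable[Variant],
    genome: GenomeModel,
    pattern_row: str = "Pattern",
) -> pd.DataFrame:
    """Per-line and pattern-candidate counts per arm (Table-2-style layout)."""
    rows = {label: count_by_arm(vs, genome) for label, vs in line_sets.items()}
    rows[pattern_row] = count_by_arm(candidates, genome)
    return pd.DataFrame(rows).T


def count_by_chromosome(variants: Iterable[Variant], genome: GenomeModel) -> pd.Series:
    """Counts per physical chromosome (arms pooled, e.g. 2 = 2L + 2R)."""
    arm = count_by_arm(variants, genome).drop("Total")
    grouped = arm.groupby([arm_chromosome(a) for a in arm.index]).sum()
    return grouped.astype(int)


# ---------------------------------------------------------------------------
# Candidate VCF output
# ---------------------------------------------------------------------------


def vcf_header(genome: GenomeModel, samples: Sequence[str] = (), extra: Sequence[str] = ()) -> str:
    lines = ["##fileformat=VCFv4.2"]
    for name, length in genome:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.extend(extra)
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        cols += "\tFORMAT\t" + "\t".join(samples)
    lines.append(cols)
    return "\n".join(lines) + "\n"


def sort_variants(variants: Iterable[Variant], genome: GenomeModel) -> list[Variant]:
    order = {name: i for i, name in enumerate(genome.arm_names)}
    return sorted(variants, key=lambda v: (order.get(v.chrom, len(order)), v.pos, v.ref, v.alt))


def write_candidate_vcf(
    candidates: Iterable[Variant],
    genome: GenomeModel,
    path: str,
    spec: PatternSpec | None = None,
) -> None:
    """Write the candidate set as a valid VCF v4.2 with the pattern in INFO."""
    info = "."
    extra = [
        '##INFO=<ID=PATTERN,Number=1,Type=String,Description="Presence/absence pattern that selected this variant">'
    ]
    if spec is not None:
        info = "PATTERN=present:" + ",".join(sorted(spec.present_in)) + ";absent:" + ",".join(
            sorted(spec.absent_in)
        )
        info = info.replace(";absent", "|absent")  # keep one INFO key
    with open(path, "w") as fh:
        fh.write(vcf_header(genome, extra=extra))
        for v in sort_variants(candidates, genome):
            fh.write(f"{v.chrom}\t{v.pos1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n")
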
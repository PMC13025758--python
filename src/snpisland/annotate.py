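"""Variant-effect classification, element intersection, gene-set overlap,
motif scanning, and candidate prioritization.

The effect classifier is a deliberately minimal transcript-level triage
(one call per variant × transcript): codon translation on the coding strand
decides missense/synonymous/nonsense for SNPs in CDS; indel length mod 3
decides frameshift vs in-frame; the first/last 2 bp of an intron are splice
sites; exonic non-CDS is UTR; everything off-transcript is intergenic. That
is the level of annotation needed to triage candidates into
protein-changing vs regulatory, not a reimplementation of a full annotator
(no MNVs, no extended splice regions, no stop-loss category).

Candidate prioritization encodes the natural reasoning order for a
dominant suppressor: an island PRE hit (a Polycomb-element mutation can
dominantly derepress a nearby gene) outranks island protein-changing
variants, which outrank island CRE hits, which outrank everything else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from Bio.SeqUtils import seq3
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .genome import Interval
from .islands import Island
from .pattern import Variant

__all__ = [
    "GeneModel",
    "EffectCall",
    "Element",
    "ElementHit",
    "classify_effect",
    "intersect_elements",
    "gene_set_overlap",
    "motif_scan",
    "prioritize",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "PROTEIN_CHANGING",
]

CATEGORIES = (
    "missense",
    "synonymous",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "splice_site",
    "UTR",
    "intronic",
    "intergenic",
)

#: categories counted as protein-changing for prioritization
PROTEIN_CHANGING = frozenset(
    {"missense", "nonsense", "frameshift", "inframe_indel", "splice_site"}
)


class ReferenceMismatchError(ValueError):
    """A variant's ref allele disagrees with the reference sequence."""


@dataclass(frozen=True)
class GeneModel:
    """A toy protein-coding gene model (one transcript).

    Exons are sorted, non-overlapping, 0-based half-open; CDS intervals are
    a subset of exonic space. For complete models total CDS length is
    divisible by 3 (enforced).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValueError(f"{self.transcript_id}: CDS interval outside exons")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not divisible by 3")

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.exons[0].start, self.exons[-1].end)

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    def cds_sequence(self, reference: Mapping[str, str]) -> str:
        """Spliced CDS on the coding strand."""
        seq = "".join(reference[self.chrom][c.start : c.end] for c in self.cds)
        return str(Seq(seq).reverse_complement()) if self.strand == "-" else seq

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the coding sequence."""
        genomic = 0
        for c in self.cds:
            if c.contains(pos):
                plus_offset = genomic + (pos - c.start)
                break
            genomic += len(c)
        else:
            return None
        if self.strand == "+":
            return plus_offset
        return self.cds_length - 1 - plus_offset

    def splice_positions(self) -> set[int]:
        """Genomic positions of the first/last 2 bases of each intron."""
        out: set[int] = set()
        for a, b in zip(self.exons, self.exons[1:]):
            out.update(range(a.end, min(a.end + 2, b.start)))
            out.update(range(max(b.start - 2, a.end), b.start))
        return out


@dataclass(frozen=True)
class EffectCall:
    """One effect category per (variant, transcript) pair."""

    variant: Variant
    transcript_id: str
    category: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def classify_effect(
    variant: Variant,
    models: Sequence[GeneModel],
    reference: Mapping[str, str],
) -> list[EffectCall]:
    """Classify a variant against every overlapping transcript.

    Returns one call per overlapping transcript, or a single intergenic
    call when none overlaps. SNP ref alleles are checked against the
    reference (mismatch raises :class:`ReferenceMismatchError`).
    """
    refseq = reference[variant.chrom]
    if refseq[variant.pos : variant.pos + len(variant.ref)].upper() != variant.ref:
        raise ReferenceMismatchError(
            f"{variant}: reference has "
            f"{refseq[variant.pos : variant.pos + len(variant.ref)]!r}"
        )
    calls: list[EffectCall] = []
    for m in models:
        if m.chrom != variant.chrom or not m.span.contains(variant.pos):
            continue
        calls.append(_classify_one(variant, m, reference))
    if not calls:
        calls.append(EffectCall(variant, transcript_id=".", category="intergenic"))
    return calls


def _classify_one(
    v: Variant, m: GeneModel, reference: Mapping[str, str]
) -> EffectCall:
    if v.pos in m.splice_positions():
        return EffectCall(v, m.transcript_id, "splice_site")
    in_cds = any(c.contains(v.pos) for c in m.cds)
    if in_cds:
        if v.is_indel:
            shift = abs(len(v.ref) - len(v.alt)) % 3
            cat = "frameshift" if shift else "inframe_indel"
            return EffectCall(v, m.transcript_id, cat)
        return _snp_cds_effect(v, m, reference)
    if any(e.contains(v.pos) for e in m.exons):
        return EffectCall(v, m.transcript_id, "UTR")
    return EffectCall(v, m.transcript_id, "intronic")


def _snp_cds_effect(v: Variant, m: GeneModel, reference: Mapping[str, str]) -> EffectCall:
    offset = m.cds_offset(v.pos)
    assert offset is not None
    cds = m.cds_sequence(reference)
    codon_i = offset // 3
    within = offset % 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    alt_base = v.alt if m.strand == "+" else str(Seq(v.alt).reverse_complement())
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    detail = f"{seq3(ref_aa)}{codon_i + 1}{seq3(alt_aa)}"
    if ref_aa == alt_aa:
        return EffectCall(v, m.transcript_id, "synonymous", detail)
    if alt_aa == "*":
        return EffectCall(v, m.transcript_id, "nonsense", detail)
    return EffectCall(v, m.transcript_id, "missense", detail)


# ---------------------------------------------------------------------------
# Element intersection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Element:
    """A regulatory-element interval (CRE or PRE)."""

    element_id: str
    element_class: str
    interval: Interval


@dataclass(frozen=True)
class ElementHit:
    variant: Variant
    element: Element


def intersect_elements(
    candidates: Iterable[Variant],
    elements: Sequence[Element],
    element_class: str | None = None,
    max_element_length: int | None = None,
) -> tuple[list[ElementHit], tuple[int, int]]:
    """Variants whose start position falls inside an element interval.

    ``max_element_length`` optionally drops oversized elements before
    intersection (off by default). Returns the hit list plus the summary
    ``(n_distinct_variants_hit, n_distinct_elements_hit)``.
    """
    pool = [
        e
        for e in elements
        if (element_class is None or e.element_class == element_class)
        and (max_element_length is None or len(e.interval) <= max_element_length)
    ]
    trees: dict[str, IntervalTree] = {}
    for e in pool:
        trees.setdefault(e.interval.chrom, IntervalTree()).addi(
            e.interval.start, e.interval.end, e
        )
    hits: list[ElementHit] = []
    for v in candidates:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        for node in sorted(tree[v.pos], key=lambda n: (n.begin, n.data.element_id)):
            hits.append(ElementHit(variant=v, element=node.data))
    n_vars = len({h.variant for h in hits})
    n_elems = len({h.element.element_id for h in hits})
    return hits, (n_vars, n_elems)


def read_bed(path: str | Path, element_class: str = "CRE") -> list[Element]:
    """Read BED3+/BED6 into Elements (0-based half-open, as BED is)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{element_class}_{i}"
            out.append(
                Element(
                    element_id=name,
                    element_class=element_class,
                    interval=Interval(chrom, start, end),
                )
            )
    return out


def write_bed(elements: Iterable[Element], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for e in elements:
            iv = e.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{e.element_id}\t0\t.\n")
    return path


# ---------------------------------------------------------------------------
# GFF3 I/O for toy gene models
# ---------------------------------------------------------------------------


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> Path:
    """Write gene models as GFF3 (1-based inclusive, CDS with phase)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.span
            fh.write(
                f"{m.chrom}\t.\tgene\t{span.start + 1}\t{span.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\t.\tmRNA\t{span.start + 1}\t{span.end}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for e in m.exons:
                fh.write(
                    f"{m.chrom}\t.\texon\t{e.start + 1}\t{e.end}\t.\t{m.strand}\t.\t"
                    f"Parent={m.transcript_id}\n"
                )
            cds_in_order = m.cds if m.strand == "+" else tuple(reversed(m.cds))
            consumed = 0
            phases = {}
            for c in cds_in_order:
                phases[c] = (3 - consumed % 3) % 3
                consumed += len(c)
            for c in m.cds:
                fh.write(
                    f"{m.chrom}\t.\tCDS\t{c.start + 1}\t{c.end}\t.\t{m.strand}\t{phases[c]}\t"
                    f"Parent={m.transcript_id}\n"
                )
    return path


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models written by :func:`write_gff3` (one mRNA per gene)."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "mRNA":
                genes[attr["ID"]] = {
                    "gene_id": attr.get("Parent", attr["ID"]),
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                }
            elif ftype in {"exon", "CDS"}:
                parent = attr["Parent"]
                key = "exons" if ftype == "exon" else "cds"
                genes[parent][key].append(Interval(chrom, int(start) - 1, int(end)))
    return [
        GeneModel(
            gene_id=g["gene_id"],
            transcript_id=tid,
            chrom=g["chrom"],
            strand=g["strand"],
            exons=tuple(sorted(g["exons"], key=lambda iv: iv.start)),
            cds=tuple(sorted(g["cds"], key=lambda iv: iv.start)),
        )
        for tid, g in genes.items()
    ]


# ---------------------------------------------------------------------------
# Gene-set overlap
# ---------------------------------------------------------------------------


def gene_set_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int
) -> tuple[int, int, float]:
    """Overlap of two gene sets with an exact hypergeometric tail.

    Returns ``(overlap, percent_of_B, p)`` where percent is
    ``100·|A∩B|/|B|`` rounded to the nearest integer and ``p`` is the
    upper-tail probability of observing at least the overlap when drawing
    |B| genes from a universe of ``universe_size`` containing |A| marked
    genes. The p-value is supplementary context, not used for ranking.
    """
    a, b = set(set_a), set(set_b)
    if not b:
        raise ValueError("set B is empty; percent undefined")
    if universe_size < len(a | b):
        raise ValueError("universe smaller than |A ∪ B|")
    overlap = len(a & b)
    percent = round(100 * overlap / len(b))
    p = float(hypergeom.sf(overlap - 1, universe_size, len(a), len(b)))
    return overlap, percent, p


# ---------------------------------------------------------------------------
# IUPAC motif scan
# ---------------------------------------------------------------------------

_IUPAC = {k.upper(): v for k, v in ambiguous_dna_values.items()}


def _motif_regex(motif: str) -> re.Pattern:
    parts = []
    for sym in motif.upper():
        if sym not in _IUPAC:
            raise ValueError(f"invalid IUPAC symbol {sym!r} in motif")
        bases = _IUPAC[sym]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead makes overlapping occurrences countable
    return re.compile("(?=" + "".join(parts) + ")")


def motif_scan(
    sequences: Mapping[str, str] | Sequence[str],
    motif: str,
    both_strands: bool = True,
) -> dict:
    """Count (overlapping) occurrences of an IUPAC motif per sequence.

    With ``both_strands``, occurrences on the reverse complement are added.
    Returns ``{"per_sequence": {...}, "total": int, "fraction_hit": float}``;
    an empty input yields total 0 and fraction 0.0.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    pattern = _motif_regex(motif)
    if isinstance(sequences, Mapping):
        items = list(sequences.items())
    else:
        items = [(f"seq{i + 1}", s) for i, s in enumerate(sequences)]
    per: dict[str, int] = {}
    for name, seq in items:
        seq = seq.upper()
        n = len(pattern.findall(seq))
        if both_strands:
            n += len(pattern.findall(str(Seq(seq).reverse_complement())))
        per[name] = n
    total = sum(per.values())
    fraction = (sum(1 for n in per.values() if n > 0) / len(per)) if per else 0.0
    return {"per_sequence": per, "total": total, "fraction_hit": fraction}


# ---------------------------------------------------------------------------
# Prioritization
# ---------------------------------------------------------------------------

TIER_NAMES = {
    1: "island PRE hit",
    2: "island protein-changing",
    3: "island CRE hit",
    4: "other",
}


def prioritize(
    candidates: Iterable[Variant],
    effects: Iterable[EffectCall],
    element_hits: Iterable[ElementHit],
    island: Island | None,
) -> list[tuple[int, Variant, int, str]]:
    """Deterministic ranked triage of candidates.

    Tiers: (1) in-island PRE hits, (2) in-island protein-changing variants,
    (3) in-island CRE hits, (4) the remainder; ties within a tier break by
    genomic coordinate. Every candidate appears exactly once. Returns
    ``(rank, variant, tier, reason)`` tuples.
    """
    cands = set(candidates)
    pre_vars = {h.variant for h in element_hits if h.element.element_class == "PRE"}
    cre_vars = {h.variant for h in element_hits if h.element.element_class == "CRE"}
    protein_vars = {e.variant for e in effects if e.category in PROTEIN_CHANGING}

    def in_island(v: Variant) -> bool:
        return island is not None and island.contains(v)

    def tier(v: Variant) -> int:
        if in_island(v) and v in pre_vars:
            return 1
        if in_island(v) and v in protein_vars:
            return 2
        if in_island(v) and v in cre_vars:
            return 3
        return 4

    ordered = sorted(cands, key=lambda v: (tier(v), v.chrom, v.pos, v.ref, v.alt))
    return [
        (rank, v, tier(v), TIER_NAMES[tier(v)])
        for rank, v in enumerate(ordered, start=1)
    ]
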
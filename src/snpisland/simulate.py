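"""Synthetic five-line dataset generator with a planted causal PRE SNP.

Emulates the sequencing endpoint of a BEAF-suppressor mapping screen:
variant call sets for five homozygous fly lines —

* ``ABKO``    founder A, carries the BEAF-null chromosome, no suppressor;
* ``NP6377``  founder B, carries the suppressor (planted causal variant)
  plus recessive-lethal markers on the same chromosome;
* ``TofuKO``/``TofuNP``  recombinant derivatives: founder-A chromosome
  backgrounds carrying a founder-B-derived block around the causal variant,
  produced by simulated meiotic crossovers with selection for the causal
  allele and against the lethals;
* ``yw``      an unrelated outgroup line.

The causal variant is a T→G SNP planted inside one designated Polycomb
response element (PRE), mirroring the rib-upstream candidate PRE SNP.
Each line's call set is the union of a shared ancestral variant pool and
line-private variants. False positive/negative call noise is applied at
VCF emission time.

The crossover model is deliberately simple: per meiosis, per arm, a
Poisson-distributed crossover count with uniform positions and no
interference. The causal chromosome passes through ``n_generations``
selected meioses (emulating the repeated recombination that trimmed the
suppressor-linked block in marker-assisted derivation), after which donor
fragments unlinked to the causal block are purged; other chromosomes are
founder-A by default, or single unselected mosaics when flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import (
    GenomeModel,
    Interval,
    CoordinateError,
    arm_chromosome,
    chromosome_arms,
    write_fasta,
)
from .pattern import (
    PatternSpec,
    Variant,
    normalize_variant,
    sort_variants,
    vcf_header,
)

__all__ = [
    "SimConfig",
    "FounderHaplotype",
    "LinkedLines",
    "TruthRecord",
    "GenerationError",
    "LINE_LABELS",
    "TOFU_PATTERN",
    "make_reference",
    "make_linked_lines",
    "emit_vcf",
    "emit_annotations",
    "emit_truth",
    "simulate_genotyping_pcr",
]

#: Canonical line labels: (founder A, founder B, recombinant 1, recombinant 2, outgroup)
LINE_LABELS = ("ABKO", "NP6377", "TofuKO", "TofuNP", "yw")

#: The suppressor presence/absence pattern over the five lines.
TOFU_PATTERN = PatternSpec(
    present_in=frozenset({"NP6377", "TofuKO", "TofuNP"}),
    absent_in=frozenset({"ABKO", "yw"}),
)

_BASES = "ACGT"


class GenerationError(RuntimeError):
    """Recombinant selection could not be satisfied within the retry bound."""


@dataclass(frozen=True)
class SimConfig:
    """Tunable parameters of the synthetic dataset.

    snp_density
        private variants per bp for each founder/outgroup line (~5e-3,
        the per-line call density scale of resequenced fly lines).
    shared_density
        variants per bp common to all five lines (shared ancestry vs the
        reference assembly).
    indel_fraction
        fraction of generated variants that are 1–3 bp indels; the rest are
        SNPs. SNPs and indels flow through the pipeline identically.
    fp_rate / fn_rate
        per-line, per-variant spurious-call and missed-call probabilities
        applied at VCF emission (the causal variant is exempt unless
        forced).
    n_crossovers_mean
        Poisson mean crossovers per arm per meiosis.
    n_generations
        selected meioses the causal chromosome passes through per
        recombinant lineage ("several generations" of crossing trims the
        donor block to a unique suppressor-linked island).
    unlinked_b_meiosis
        by default the recombinants carry founder A's material on every
        non-causal chromosome, so pattern candidates concentrate in the
        suppressor-linked block; setting this flag instead gives each
        recombinant a single unselected founder-A/founder-B meiotic mosaic
        per unlinked chromosome, reproducing the diffuse candidate
        background the real lines showed on chromosomes 3 and X.
    heterozygosity
        fraction of emitted non-causal calls written as heterozygous
        (0/1) instead of homozygous (1/1); presence is unaffected under
        the default reading policy.
    """

    seed: int = 0
    snp_density: float = 5e-3
    shared_density: float = 5e-3
    indel_fraction: float = 0.15
    fp_rate: float = 0.001
    fn_rate: float = 0.02
    n_crossovers_mean: float = 2.0
    n_generations: int = 4
    unlinked_b_meiosis: bool = False
    heterozygosity: float = 0.0
    causal_arm: str = "2R"
    #: 0-based causal position; None places it at the same relative arm
    #: coordinate as the rib-upstream candidate PRE SNP (2R:19,265,447 of 25.29 Mb).
    causal_position: int | None = None
    n_lethals: int = 2
    noise_exempt_causal: bool = True
    max_retries: int = 10_000

    def __post_init__(self) -> None:
        for name in ("indel_fraction", "fp_rate", "fn_rate", "heterozygosity"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be positive")
        if self.shared_density < 0 or self.n_crossovers_mean < 0:
            raise ValueError("densities and crossover mean must be non-negative")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")


#: Relative arm coordinate of the rib-upstream candidate PRE SNP (2R:19,265,447
#: of 25.29 Mb), reused so scaled genomes plant the causal variant at the
#: homologous relative position.
_CAUSAL_REL_POS = 19_265_446 / 25_290_000


@dataclass(frozen=True)
class FounderHaplotype:
    """A founder line's genome-wide variant complement."""

    line_name: str
    variants: frozenset[Variant]
    lethal_positions: frozenset[tuple[str, int]] = frozenset()
    causal: Variant | None = None

    def __post_init__(self) -> None:
        if self.causal is not None:
            key = (self.causal.chrom, self.causal.pos)
            if key in self.lethal_positions:
                raise ValueError("causal position cannot also be lethal")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of one simulated dataset."""

    causal: Variant
    #: founder-B-derived block around the causal variant shared by both
    #: recombinants (the expected SNP island location)
    shared_block: Interval
    #: per-recombinant founder-B block around the causal variant
    blocks: Mapping[str, Interval]
    lethal_positions: frozenset[tuple[str, int]]
    pattern: PatternSpec = TOFU_PATTERN
    pre_id: str | None = None


@dataclass
class LinkedLines:
    """Output bundle of :func:`make_linked_lines`."""

    genome: GenomeModel
    config: SimConfig
    reference: dict[str, str]
    lines: dict[str, frozenset[Variant]]
    truth: TruthRecord


# ---------------------------------------------------------------------------
# Reference sequence
# ---------------------------------------------------------------------------


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg_seed) % 2**31, stream])


def make_reference(genome: GenomeModel, cfg: SimConfig) -> dict[str, str]:
    """Deterministic random reference sequences, one per arm.

    The base at the causal position is forced to T so the planted causal
    variant is always the canonical T→G substitution.
    """
    rng = _rng(cfg.seed, 1)
    lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    out: dict[str, str] = {}
    causal_arm, causal_pos = _causal_site(genome, cfg)
    for name, length in genome:
        idx = rng.integers(0, 4, size=length)
        seq = bytearray(lut[idx].tobytes())
        if name == causal_arm:
            seq[causal_pos] = ord("T")
        out[name] = seq.decode()
    return out


def _causal_site(genome: GenomeModel, cfg: SimConfig) -> tuple[str, int]:
    arm_len = genome.arm_length(cfg.causal_arm)
    if cfg.causal_position is not None:
        pos = cfg.causal_position
        if not 0 <= pos < arm_len:
            raise CoordinateError(f"causal position {pos} outside arm {cfg.causal_arm}")
        return cfg.causal_arm, pos
    return cfg.causal_arm, min(arm_len - 1, int(round(_CAUSAL_REL_POS * arm_len)))


# ---------------------------------------------------------------------------
# Variant pool
# ---------------------------------------------------------------------------


def _draw_positions(rng: np.random.Generator, length: int, density: float) -> np.ndarray:
    n = rng.poisson(length * density)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    # sample with replacement, dedupe; collision loss is negligible at the
    # densities used and does not bias placement
    pos = np.unique(rng.integers(0, length, size=n))
    return pos


def _make_variants(
    rng: np.random.Generator,
    arm: str,
    positions: np.ndarray,
    reference: str,
    indel_fraction: float,
) -> list[Variant]:
    out: list[Variant] = []
    arm_len = len(reference)
    kinds = rng.random(len(positions))
    sizes = rng.integers(1, 4, size=len(positions))
    ins_or_del = rng.random(len(positions)) < 0.5
    base_choice = rng.integers(0, 3, size=len(positions))
    ins_bases = rng.integers(0, 4, size=(len(positions), 3))
    seqmap = {arm: reference}
    for i, pos in enumerate(positions):
        pos = int(pos)
        refbase = reference[pos]
        if kinds[i] >= indel_fraction or pos + 4 >= arm_len or pos == 0:
            alts = [b for b in _BASES if b != refbase]
            out.append(Variant(arm, pos, refbase, alts[base_choice[i]]))
        elif ins_or_del[i]:
            ins = "".join(_BASES[b] for b in ins_bases[i, : sizes[i]])
            out.append(normalize_variant(arm, pos, refbase, refbase + ins, seqmap))
        else:
            ref = reference[pos : pos + 1 + int(sizes[i])]
            out.append(normalize_variant(arm, pos, ref, refbase, seqmap))
    return out


def _pool(
    rng: np.random.Generator,
    genome: GenomeModel,
    reference: Mapping[str, str],
    cfg: SimConfig,
) -> dict[str, list[Variant]]:
    """Disjoint variant pools: shared + one private set per sequenced origin."""
    categories = ("shared", "A", "B", "O")
    densities = np.array(
        [cfg.shared_density, cfg.snp_density, cfg.snp_density, cfg.snp_density]
    )
    total_density = float(densities.sum())
    weights = densities / total_density
    pools: dict[str, list[Variant]] = {c: [] for c in categories}
    for arm, length in genome:
        positions = _draw_positions(rng, length, total_density)
        assignment = rng.choice(len(categories), size=len(positions), p=weights)
        for ci, cat in enumerate(categories):
            pos_cat = positions[assignment == ci]
            pools[cat].extend(
                _make_variants(rng, arm, pos_cat, reference[arm], cfg.indel_fraction)
            )
    return pools


# ---------------------------------------------------------------------------
# Meiosis / recombination machinery
# ---------------------------------------------------------------------------

Segments = list[tuple[int, int]]  # half-open intervals of founder-B material


def _meiosis_segments(
    rng: np.random.Generator, arm_lengths: Sequence[int], mean_xo: float
) -> list[Segments]:
    """Segments inherited from the 'current' homolog across a chromosome.

    Crossover counts are Poisson per arm, positions uniform, no
    interference; phase alternates through breakpoints and carries across
    the centromere between arms.
    """
    phase = int(rng.integers(0, 2))  # 1 = currently copying the tracked homolog
    out: list[Segments] = []
    for length in arm_lengths:
        n_xo = rng.poisson(mean_xo)
        breaks = np.sort(rng.integers(1, max(2, length), size=n_xo))
        segs: Segments = []
        prev = 0
        for b in list(breaks) + [length]:
            b = int(min(b, length))
            if phase and b > prev:
                segs.append((prev, b))
            prev = b
            phase ^= 1
        phase ^= 1  # undo the toggle applied after the terminal sentinel
        out.append(segs)
    return out


def _intersect_segments(a: Segments, b: Segments) -> Segments:
    out: Segments = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _in_segments(segs: Segments, pos: int) -> bool:
    return any(s <= pos < e for s, e in segs)


def _segment_containing(segs: Segments, pos: int) -> tuple[int, int]:
    for s, e in segs:
        if s <= pos < e:
            return s, e
    raise ValueError("position not covered by any segment")


def _recombinant_chromosome(
    rng: np.random.Generator,
    arms: Sequence[tuple[str, int]],
    causal_arm: str,
    causal_pos: int,
    lethal_positions: Iterable[tuple[str, int]],
    cfg: SimConfig,
) -> dict[str, Segments]:
    """Founder-B material on the causal chromosome after selected meioses.

    Starts from a pure founder-B chromosome; each generation draws one
    meiosis against a founder-A homolog and keeps a gamete only if it
    carries the causal variant and none of the lethal markers. Raises
    :class:`GenerationError` when the retry budget is exhausted (e.g. a
    lethal completely linked to the causal site at zero recombination).

    Donor fragments not contiguous with the causal segment are purged at
    the end: repeated backcrossing with marker selection (how such lines
    are actually derived) leaves a single donor block around the selected
    locus, and that single-block structure is what the mapping design
    relies on.
    """
    arm_names = [a for a, _ in arms]
    arm_lengths = [l for _, l in arms]
    lethals = [(a, p) for a, p in lethal_positions if a in arm_names]
    b_material: dict[str, Segments] = {a: [(0, l)] for a, l in arms}
    budget = cfg.max_retries
    for _ in range(cfg.n_generations):
        while True:
            if budget <= 0:
                raise GenerationError(
                    "could not recover a viable causal-carrying recombinant "
                    f"within {cfg.max_retries} meioses"
                )
            budget -= 1
            meiosis = _meiosis_segments(rng, arm_lengths, cfg.n_crossovers_mean)
            candidate = {
                a: _intersect_segments(b_material[a], segs)
                for a, segs in zip(arm_names, meiosis)
            }
            if not _in_segments(candidate[causal_arm], causal_pos):
                continue
            if any(_in_segments(candidate[a], p) for a, p in lethals):
                continue
            b_material = candidate
            break
    block = _segment_containing(b_material[causal_arm], causal_pos)
    purged: dict[str, Segments] = {a: [] for a in arm_names}
    purged[causal_arm] = [block]
    return purged


# ---------------------------------------------------------------------------
# Line assembly
# ---------------------------------------------------------------------------


def make_linked_lines(
    genome: GenomeModel | None = None, cfg: SimConfig | None = None
) -> LinkedLines:
    """Generate the five-line dataset with a planted causal variant.

    Returns the reference, per-line variant sets (noise-free; call noise is
    an emission-time property), and the truth record naming the causal
    variant and the founder-B block around it.
    """
    genome = genome or GenomeModel()
    cfg = cfg or SimConfig()
    reference = make_reference(genome, cfg)
    rng = _rng(cfg.seed, 2)

    causal_arm, causal_pos = _causal_site(genome, cfg)
    causal = Variant(causal_arm, causal_pos, "T", "G")

    pools = _pool(rng, genome, reference, cfg)
    # keep pool variants off the causal site
    for cat in pools:
        pools[cat] = [v for v in pools[cat] if (v.chrom, v.pos) != (causal_arm, causal_pos)]

    shared = frozenset(pools["shared"])
    a_priv = frozenset(pools["A"])
    b_priv = frozenset(pools["B"])
    o_priv = frozenset(pools["O"])

    causal_chromosome = arm_chromosome(causal_arm)
    causal_arms = [(a, genome.arm_length(a)) for a in chromosome_arms(genome, causal_chromosome)]

    lethal_positions = _place_lethals(rng, causal_arms, causal_arm, causal_pos, cfg)

    founder_b = FounderHaplotype(
        line_name="NP6377",
        variants=b_priv | {causal},
        lethal_positions=lethal_positions,
        causal=causal,
    )

    other_chroms = sorted(
        {arm_chromosome(a) for a in genome.arm_names} - {causal_chromosome}
    )

    lines: dict[str, frozenset[Variant]] = {
        "ABKO": shared | a_priv,
        "NP6377": shared | founder_b.variants,
        "yw": shared | o_priv,
    }

    blocks: dict[str, Interval] = {}
    b_by_arm: dict[str, list[Variant]] = {}
    a_by_arm: dict[str, list[Variant]] = {}
    for v in b_priv:
        b_by_arm.setdefault(v.chrom, []).append(v)
    for v in a_priv:
        a_by_arm.setdefault(v.chrom, []).append(v)

    shared_blocks: list[tuple[int, int]] = []
    for recomb in ("TofuKO", "TofuNP"):
        b_material = _recombinant_chromosome(
            rng, causal_arms, causal_arm, causal_pos, lethal_positions, cfg
        )
        # unlinked chromosomes: founder-A background by default, or one
        # unselected founder-A/B meiotic mosaic each when flagged
        for chrom in other_chroms:
            arms = [(a, genome.arm_length(a)) for a in chromosome_arms(genome, chrom)]
            if cfg.unlinked_b_meiosis:
                meiosis = _meiosis_segments(
                    rng, [l for _, l in arms], cfg.n_crossovers_mean
                )
                for (a, _), segs in zip(arms, meiosis):
                    b_material[a] = segs
            else:
                for a, _ in arms:
                    b_material[a] = []
        variants: set[Variant] = set(shared)
        variants.add(causal)
        for arm in genome.arm_names:
            segs = b_material.get(arm, [])
            for v in b_by_arm.get(arm, ()):
                if _in_segments(segs, v.pos):
                    variants.add(v)
            for v in a_by_arm.get(arm, ()):
                if not _in_segments(segs, v.pos):
                    variants.add(v)
        lines[recomb] = frozenset(variants)
        s, e = _segment_containing(b_material[causal_arm], causal_pos)
        blocks[recomb] = Interval(causal_arm, s, e)

    s = max(blocks["TofuKO"].start, blocks["TofuNP"].start)
    e = min(blocks["TofuKO"].end, blocks["TofuNP"].end)
    truth = TruthRecord(
        causal=causal,
        shared_block=Interval(causal_arm, s, e),
        blocks=blocks,
        lethal_positions=lethal_positions,
    )
    return LinkedLines(genome=genome, config=cfg, reference=reference, lines=lines, truth=truth)


def _place_lethals(
    rng: np.random.Generator,
    causal_arms: Sequence[tuple[str, int]],
    causal_arm: str,
    causal_pos: int,
    cfg: SimConfig,
) -> frozenset[tuple[str, int]]:
    """Recessive-lethal marker positions on the founder-B causal chromosome.

    Placed uniformly on the causal chromosome but at least 10% of the arm
    away from the causal site, so selection can separate them.
    """
    if cfg.n_lethals == 0:
        return frozenset()
    out: set[tuple[str, int]] = set()
    arm_names = [a for a, _ in causal_arms]
    lengths = dict(causal_arms)
    guard = int(0.1 * lengths[causal_arm])
    tries = 0
    while len(out) < cfg.n_lethals and tries < 1000:
        tries += 1
        arm = arm_names[int(rng.integers(0, len(arm_names)))]
        pos = int(rng.integers(0, lengths[arm]))
        if arm == causal_arm and abs(pos - causal_pos) < guard:
            continue
        out.add((arm, pos))
    return frozenset(out)


# ---------------------------------------------------------------------------
# Emission: VCF, annotations, truth
# ---------------------------------------------------------------------------


def emit_vcf(
    lines: Mapping[str, Iterable[Variant]],
    genome: GenomeModel,
    out_dir: str | Path,
    cfg: SimConfig | None = None,
    multi_sample: bool = False,
    causal: Variant | None = None,
    force_noise_on_causal: bool = False,
) -> list[Path]:
    """Write line variant sets as VCF v4.2, applying call noise.

    Per line, each true variant is dropped with probability ``fn_rate`` and
    each pool variant absent from the line is spuriously added with
    probability ``fp_rate``. The causal variant is exempt from noise unless
    ``force_noise_on_causal`` is set. Same config seed ⇒ byte-identical
    output.
    """
    cfg = cfg or SimConfig(fp_rate=0.0, fn_rate=0.0)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(cfg.seed, 3)
    pool = sort_variants(set().union(*(set(v) for v in lines.values())) if lines else set(), genome)
    for v in pool:
        if v.pos + len(v.ref) > genome.arm_length(v.chrom):
            raise CoordinateError(f"variant {v} outside genome bounds")
    exempt = causal if (causal is not None and cfg.noise_exempt_causal and not force_noise_on_causal) else None

    noisy: dict[str, list[Variant]] = {}
    het: dict[str, set[Variant]] = {}
    for label in sorted(lines):
        members = set(lines[label])
        kept: list[Variant] = []
        for v in pool:
            present = v in members
            if v == exempt:
                pass
            elif present and cfg.fn_rate > 0 and rng.random() < cfg.fn_rate:
                present = False
            elif not present and cfg.fp_rate > 0 and rng.random() < cfg.fp_rate:
                present = True
            if present:
                kept.append(v)
        noisy[label] = kept
        het[label] = (
            {v for v in kept if v != exempt and rng.random() < cfg.heterozygosity}
            if cfg.heterozygosity > 0
            else set()
        )

    paths: list[Path] = []
    if multi_sample:
        path = out_dir / "lines.vcf"
        samples = sorted(lines)
        with open(path, "w") as fh:
            fh.write(
                vcf_header(
                    genome,
                    samples=samples,
                    extra=['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'],
                )
            )
            membership = {lab: set(vs) for lab, vs in noisy.items()}
            for v in pool:
                gts = []
                any_called = False
                for lab in samples:
                    if v in membership[lab]:
                        gts.append("0/1" if v in het[lab] else "1/1")
                        any_called = True
                    else:
                        gts.append("0/0")
                if any_called:
                    fh.write(
                        f"{v.chrom}\t{v.pos1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                        + "\t".join(gts)
                        + "\n"
                    )
        paths.append(path)
    else:
        for label in sorted(lines):
            path = out_dir / f"{label}.vcf"
            with open(path, "w") as fh:
                fh.write(
                    vcf_header(
                        genome,
                        samples=[label],
                        extra=['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'],
                    )
                )
                for v in noisy[label]:
                    gt = "0/1" if v in het[label] else "1/1"
                    fh.write(f"{v.chrom}\t{v.pos1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gt}\n")
            paths.append(path)
    return paths


def emit_annotations(
    genome: GenomeModel,
    cfg: SimConfig,
    out_dir: str | Path,
    causal: Variant | None = None,
    n_genes: int = 80,
    n_pre: int = 537,
    n_cre: int = 300,
    pre_avoid: Iterable[tuple[str, int]] = (),
) -> dict[str, Path]:
    """Write toy gene models (GFF3) and PRE/CRE element BEDs.

    Exactly one PRE interval contains the causal position (when given); the
    default PRE count matches the 537-element chromatin-predicted PRE
    catalogue for this genome. ``pre_avoid`` positions (e.g. the dataset's variant
    sites) are kept out of all *other* PRE intervals, so the causal PRE is
    the only one that can intersect a candidate — the single-PRE-hit design
    the downstream prioritization banks on. CREs carry no such constraint.
    Returns paths keyed ``genes``/``pre``/``cre`` and records the causal
    PRE id under ``causal_pre_id``.
    """
    from .annotate import GeneModel, write_gff3  # local import, no cycle at module load

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(cfg.seed, 4)

    genes = _toy_genes(rng, genome, n_genes)
    genes_path = out_dir / "genes.gff3"
    write_gff3(genes, genes_path)

    causal_site = (causal.chrom, causal.pos) if causal is not None else None
    avoid: dict[str, np.ndarray] = {}
    for arm, pos in pre_avoid:
        avoid.setdefault(arm, [])  # type: ignore[arg-type]
        avoid[arm].append(pos)  # type: ignore[attr-defined]
    avoid = {arm: np.sort(np.asarray(ps, dtype=np.int64)) for arm, ps in avoid.items()}
    pre_path = out_dir / "pre.bed"
    causal_pre_id = _emit_elements(rng, genome, pre_path, "PRE", n_pre, causal_site, avoid)
    cre_path = out_dir / "cre.bed"
    _emit_elements(rng, genome, cre_path, "CRE", n_cre, None)

    out = {"genes": genes_path, "pre": pre_path, "cre": cre_path}
    out["causal_pre_id"] = causal_pre_id
    return out


def _emit_elements(
    rng: np.random.Generator,
    genome: GenomeModel,
    path: Path,
    prefix: str,
    n: int,
    causal_site: tuple[str, int] | None,
    avoid: Mapping[str, np.ndarray] | None = None,
) -> str | None:
    """Random non-causal elements plus (optionally) one covering the causal
    site; none of the others may touch the causal position or any position
    in ``avoid``."""
    total = genome.total_size
    arms = list(genome)
    weights = np.array([l for _, l in arms], dtype=float) / total
    records: list[tuple[str, int, int, str]] = []
    causal_id: str | None = None
    i = 0
    attempts = 0
    while len(records) < (n - 1 if causal_site else n) and attempts < 200 * n:
        attempts += 1
        arm_i = int(rng.choice(len(arms), p=weights))
        arm, arm_len = arms[arm_i]
        width = int(rng.integers(300, 2001))
        if arm_len <= width + 1:
            continue
        start = int(rng.integers(0, arm_len - width))
        if causal_site and arm == causal_site[0] and start <= causal_site[1] < start + width:
            continue
        if avoid and arm in avoid:
            ps = avoid[arm]
            lo = int(np.searchsorted(ps, start))
            if lo < len(ps) and ps[lo] < start + width:
                continue
        records.append((arm, start, start + width, f"{prefix}_{i:04d}"))
        i += 1
    if causal_site:
        arm, pos = causal_site
        arm_len = genome.arm_length(arm)
        width = int(rng.integers(600, 1501))
        # the causal element holds the causal site and no other avoided
        # position: clip to the variant-free gap around the causal site
        lo_bound, hi_bound = 0, arm_len
        if avoid and arm in avoid:
            ps = avoid[arm]
            ps = ps[ps != pos]
            j = int(np.searchsorted(ps, pos))
            if j > 0:
                lo_bound = int(ps[j - 1]) + 1
            if j < len(ps):
                hi_bound = int(ps[j])
        width = max(1, min(width, hi_bound - lo_bound))
        offset = int(rng.integers(0, width))
        start = min(max(pos - offset, lo_bound), hi_bound - width)
        causal_id = f"{prefix}_{i:04d}"
        records.append((arm, start, start + width, causal_id))
    order = {name: j for j, (name, _) in enumerate(arms)}
    records.sort(key=lambda r: (order[r[0]], r[1]))
    with open(path, "w") as fh:
        for arm, start, end, name in records:
            fh.write(f"{arm}\t{start}\t{end}\t{name}\t0\t.\n")
    return causal_id


def _toy_genes(rng: np.random.Generator, genome: GenomeModel, n_genes: int):
    from .annotate import GeneModel

    genes = []
    arms = list(genome)
    total = genome.total_size
    weights = np.array([l for _, l in arms], dtype=float) / total
    occupied: dict[str, list[tuple[int, int]]] = {a: [] for a, _ in arms}
    gi = 0
    attempts = 0
    while gi < n_genes and attempts < n_genes * 50:
        attempts += 1
        arm_i = int(rng.choice(len(arms), p=weights))
        arm, arm_len = arms[arm_i]
        n_exons = int(rng.integers(2, 5))
        exon_lens = rng.integers(120, 400, size=n_exons)
        intron_lens = rng.integers(60, 500, size=n_exons - 1)
        span = int(exon_lens.sum() + intron_lens.sum())
        if arm_len <= span + 2:
            continue
        start = int(rng.integers(0, arm_len - span - 1))
        if any(s < start + span and start < e for s, e in occupied[arm]):
            continue
        exons = []
        pos = start
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k]) + (int(intron_lens[k]) if k < n_exons - 1 else 0)
        total_exonic = int(exon_lens.sum())
        utr5 = int(rng.integers(30, 90))
        cds_len = ((total_exonic - utr5 - int(rng.integers(30, 90))) // 3) * 3
        if cds_len < 90:
            continue
        cds = _carve_cds(exons, utr5, cds_len)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"gene{gi:03d}",
                transcript_id=f"gene{gi:03d}-RA",
                chrom=arm,
                strand=strand,
                exons=tuple(Interval(arm, s, e) for s, e in exons),
                cds=tuple(Interval(arm, s, e) for s, e in cds),
            )
        )
        occupied[arm].append((start, start + span))
        gi += 1
    return genes


def _carve_cds(
    exons: Sequence[tuple[int, int]], utr5: int, cds_len: int
) -> list[tuple[int, int]]:
    """CDS intervals occupying ``cds_len`` exonic bases after ``utr5`` bases."""
    out = []
    skip, remaining = utr5, cds_len
    for s, e in exons:
        length = e - s
        if skip >= length:
            skip -= length
            continue
        s2 = s + skip
        skip = 0
        take = min(remaining, e - s2)
        if take > 0:
            out.append((s2, s2 + take))
            remaining -= take
        if remaining == 0:
            break
    return out


def emit_truth(truth: TruthRecord, path: str | Path) -> Path:
    """Write the truth record as TSV (causal key + containing PRE id)."""
    path = Path(path)
    v = truth.causal
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tpre_id\tblock_start\tblock_end\n")
        fh.write(
            f"{v.chrom}\t{v.pos1}\t{v.ref}\t{v.alt}\t{truth.pre_id or '.'}\t"
            f"{truth.shared_block.start + 1}\t{truth.shared_block.end}\n"
        )
    return path


def emit_reference(reference: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    write_fasta(reference, str(path))
    return path


# ---------------------------------------------------------------------------
# In-silico allele-specific genotyping PCR
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _anneal_sites(template: str, primer: str, max_mismatch_frac: float) -> list[tuple[int, bool]]:
    """Positions where the primer anneals productively on the template.

    A primer binds where it aligns with at most ``max_mismatch_frac`` of its
    length in mismatches, *and* its 3′-terminal 3 nt match exactly — the
    allele-discrimination rule of a three-primer genotyping assay.
    Returns ``(five_prime_end_position, productive)`` for forward-strand
    sites; scan the reverse complement separately for the other strand.
    """
    L = len(primer)
    max_mm = int(max_mismatch_frac * L)
    sites = []
    for i in range(0, len(template) - L + 1):
        window = template[i : i + L]
        mm = sum(a != b for a, b in zip(window, primer))
        if mm <= max_mm:
            productive = window[-3:] == primer[-3:]
            sites.append((i, productive))
    return sites


def simulate_genotyping_pcr(
    template: str,
    primers: Mapping[str, str] | Sequence[str],
    max_mismatch_frac: float = 0.2,
    max_product: int = 5000,
) -> list[tuple[tuple[str, str], int]]:
    """Predict products of a (three-)primer allele-specific PCR.

    A product requires one primer annealing productively on the forward
    strand and another on the reverse strand, 5′→3′ ends converging;
    productive annealing demands an exact 3′-terminal 3-nt match (so a
    primer whose 3′ end sits on the other allele's base yields nothing).
    Product length is the inclusive distance between the two primers'
    5′ ends. Returns ``[((forward_primer, reverse_primer), length), ...]``;
    an empty list means no product (not an error).
    """
    if isinstance(primers, Mapping):
        items = list(primers.items())
    else:
        items = [(f"primer{i + 1}", p) for i, p in enumerate(primers)]
    for name, p in items:
        if len(p) < 15:
            raise ValueError(f"primer {name!r} shorter than 15 nt")
    template = template.upper()
    fwd_sites: dict[str, list[int]] = {}
    rev_sites: dict[str, list[int]] = {}
    for name, p in items:
        p = p.upper()
        fwd_sites[name] = [
            i for i, ok in _anneal_sites(template, p, max_mismatch_frac) if ok
        ]
        # reverse-strand annealing: primer matches the reverse complement;
        # its 5' end in template coordinates is the *right* end of the site
        rev_sites[name] = [
            len(template) - 1 - i
            for i, ok in _anneal_sites(_revcomp(template), p, max_mismatch_frac)
            if ok
        ]
    products: list[tuple[tuple[str, str], int]] = []
    for fname, _ in items:
        for rname, _ in items:
            for f5 in fwd_sites[fname]:
                for r5 in rev_sites[rname]:
                    length = r5 - f5 + 1
                    if 0 < length <= max_product:
                        products.append(((fname, rname), length))
    return sorted(set(products), key=lambda t: (t[1], t[0]))
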
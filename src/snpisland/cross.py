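"""Mendelian/meiotic genetics engine.

Two complementary calculators:

* exact enumeration of multi-generation cross schemes with balancer
  chromosomes and genotype selection, in rational arithmetic, so expected
  phenotype fractions like 0%, 50% or 100% come out exact; and
* Monte-Carlo recombination-mapping crosses under the Haldane (no
  interference) map function, with Wilson-interval recombination-fraction
  estimates.

Chromosomes in the exact enumerator are transmitted intact (achiasmate), the
appropriate model both for balancer-carrying stocks and for the
complete-linkage hypotheses the segregation designs test; recombination is
handled by the Monte-Carlo mapping simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "Haplotype",
    "Genotype",
    "CrossScheme",
    "FertilityModel",
    "LinkageMap",
    "MappingDesign",
    "RecombCount",
    "enumerate_cross",
    "expected_phenotype_fraction",
    "chr4_loss_probability",
    "haldane_rf",
    "simulate_mapping_cross",
    "estimate_rf",
    "beaf_segregation_scheme_2_3",
    "beaf_segregation_scheme_x_2",
    "dominant_fertility_model",
]


class EmptySelectionError(ValueError):
    """A selection predicate matched no offspring."""


# ---------------------------------------------------------------------------
# Exact enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Haplotype:
    """One chromosome haplotype: a label, marker alleles, and a balancer flag.

    Balancer chromosomes (CyO, TM3, ...) are multiply inverted and suppress
    recovery of recombinants; in the achiasmate enumerator every chromosome
    already passes intact, so the flag is informational and enforced as an
    invariant (a balancer haplotype is never split).
    """

    name: str
    alleles: frozenset[str] = frozenset()
    balancer: bool = False

    def carries(self, allele: str) -> bool:
        return allele in self.alleles


def hap(name: str, *alleles: str, balancer: bool = False) -> Haplotype:
    return Haplotype(name, frozenset(alleles), balancer)


#: chromosome label -> unordered pair of haplotypes
Genotype = tuple[tuple[str, tuple[Haplotype, Haplotype]], ...]


def make_genotype(pairs: Mapping[str, tuple[Haplotype, Haplotype]]) -> Genotype:
    """Canonicalize a chromosome->haplotype-pair mapping into a Genotype."""
    out = []
    for chrom in sorted(pairs):
        h1, h2 = sorted(pairs[chrom], key=lambda h: h.name)
        out.append((chrom, (h1, h2)))
    return tuple(out)


def genotype_alleles(g: Genotype) -> frozenset[str]:
    return frozenset(a for _, (h1, h2) in g for h in (h1, h2) for a in h.alleles)


def allele_count(g: Genotype, allele: str) -> int:
    return sum(h.carries(allele) for _, pair in g for h in pair)


Distribution = dict[Genotype, Fraction]


def _gametes(g: Genotype) -> list[tuple[tuple[tuple[str, Haplotype], ...], Fraction]]:
    """Enumerate gametes with exact probabilities (intact transmission)."""
    gametes: list[tuple[tuple[tuple[str, Haplotype], ...], Fraction]] = [((), Fraction(1))]
    for chrom, (h1, h2) in g:
        nxt = []
        for prefix, p in gametes:
            if h1 == h2:
                nxt.append((prefix + ((chrom, h1),), p))
            else:
                nxt.append((prefix + ((chrom, h1),), p / 2))
                nxt.append((prefix + ((chrom, h2),), p / 2))
        gametes = nxt
    return gametes


def enumerate_cross(
    mother: Genotype | Distribution, father: Genotype | Distribution
) -> Distribution:
    """Exact offspring genotype distribution of a cross.

    Parents may be single genotypes or genotype distributions (e.g. the
    selected output of a previous cross).
    """
    mdist = mother if isinstance(mother, dict) else {mother: Fraction(1)}
    fdist = father if isinstance(father, dict) else {father: Fraction(1)}
    out: Distribution = {}
    for mg, mp in mdist.items():
        for fg, fp in fdist.items():
            for egg, pe in _gametes(mg):
                for sperm, ps in _gametes(fg):
                    pairs = {c: (h, dict(sperm)[c]) for c, h in egg}
                    child = make_genotype(pairs)
                    out[child] = out.get(child, Fraction(0)) + mp * fp * pe * ps
    return out


def select(dist: Distribution, predicate: Callable[[Genotype], bool]) -> Distribution:
    """Condition a genotype distribution on a selection predicate."""
    kept = {g: p for g, p in dist.items() if predicate(g) and p > 0}
    total = sum(kept.values(), Fraction(0))
    if total == 0:
        raise EmptySelectionError("selection predicate matched no offspring")
    return {g: p / total for g, p in kept.items()}


@dataclass
class CrossScheme:
    """A named multi-generation cross design.

    ``founders`` maps names to genotypes; each cross draws parents by name
    (founder or earlier cross product), optionally selects offspring, and
    stores its selected distribution under ``name``.
    """

    founders: dict[str, Genotype]
    crosses: list[tuple[str, str, str, Callable[[Genotype], bool] | None]]
    #: predicate defining the assayed (scored) class among the final cross
    assay_selector: Callable[[Genotype], bool] = lambda g: True

    def final_distribution(self) -> Distribution:
        """Offspring distribution of the last cross, before assay selection."""
        pools: dict[str, Distribution] = {
            name: {g: Fraction(1)} for name, g in self.founders.items()
        }
        dist: Distribution = {}
        for name, mother, father, selector in self.crosses:
            dist = enumerate_cross(pools[mother], pools[father])
            if selector is not None:
                dist = select(dist, selector)
            pools[name] = dist
        return dist

    def run(self) -> Distribution:
        """Execute all crosses; return the assayed-offspring distribution."""
        dist = self.final_distribution()
        # balancer invariant: no recombinant balancer haplotypes can exist
        for g in dist:
            for _, pair in g:
                for h in pair:
                    if h.balancer:
                        assert h in _all_haplotypes(self.founders), (
                            "balancer haplotype emitted that no founder carried"
                        )
        return select(dist, self.assay_selector)


def _all_haplotypes(founders: Mapping[str, Genotype]) -> set[Haplotype]:
    return {h for g in founders.values() for _, pair in g for h in pair}


@dataclass(frozen=True)
class FertilityModel:
    """Maps genotypes to fertility probabilities (exact fractions)."""

    rules: tuple[tuple[Callable[[Genotype], bool], Fraction], ...]
    default: Fraction = Fraction(0)

    def probability(self, g: Genotype) -> Fraction:
        for predicate, p in self.rules:
            if predicate(g):
                return p
        return self.default


def dominant_fertility_model(allele: str = "Tofu") -> FertilityModel:
    """Fertile iff the genotype carries >= 1 copy of a dominant suppressor.

    This is the default phenotype model for the BEAF-null assay: homozygous
    null females are sterile unless rescued by at least one suppressor copy.
    """
    return FertilityModel(
        rules=((lambda g, a=allele: allele_count(g, a) >= 1, Fraction(1)),),
        default=Fraction(0),
    )


def expected_phenotype_fraction(
    scheme: CrossScheme, model: FertilityModel
) -> Fraction:
    """Expected fraction of assayed offspring scored as fertile (exact)."""
    assayed = scheme.run()
    return sum(
        (p * model.probability(g) for g, p in assayed.items()), Fraction(0)
    )


# ---------------------------------------------------------------------------
# Bundled segregation schemes
# ---------------------------------------------------------------------------


def beaf_segregation_scheme_2_3(hypothesis: str) -> CrossScheme:
    """Segregation design testing chromosomes 2 and 3 (double balancer).

    The suppressor stock is homozygous for the BEAF-null chromosome 2
    ("ABKO"-derived). It is crossed to a *CyO/Sp ; TM3/Scm* double-balancer
    stock; F1 sibs carrying *CyO* over the stock chromosome 2 and either
    *TM3* or *Scm* over the stock chromosome 3 are intercrossed. Assayed
    females are homozygous for the null chromosome 2 (non-*CyO*, non-*Sp*)
    and carry *TM3/Scm* third chromosomes — i.e. both of their third
    chromosomes derive from the balancer stock.

    ``hypothesis`` places a homozygous dominant suppressor allele on
    chromosome ``"2"`` (completely linked to the null) or ``"3"`` in the
    suppressor stock. Expected fertile fractions are 1 and 0 respectively.
    """
    if hypothesis not in {"2", "3"}:
        raise ValueError("hypothesis must be '2' or '3'")
    tofu2 = ("Tofu",) if hypothesis == "2" else ()
    tofu3 = ("Tofu",) if hypothesis == "3" else ()
    abko = hap("ABKO-chr2", "ABKO", *tofu2)
    plus3 = hap("stock-chr3", *tofu3)
    cyo = hap("CyO", "CyO", balancer=True)
    sp = hap("Sp-chr2", "Sp")
    tm3 = hap("TM3", "TM3", balancer=True)
    scm = hap("Scm-chr3", "Scm")

    founders = {
        "suppressor_stock": make_genotype({"2": (abko, abko), "3": (plus3, plus3)}),
        "balancer_stock": make_genotype({"2": (cyo, sp), "3": (tm3, scm)}),
    }

    def f1_with(third_marker: str) -> Callable[[Genotype], bool]:
        def pred(g: Genotype, m=third_marker) -> bool:
            return (
                allele_count(g, "CyO") == 1
                and allele_count(g, "Sp") == 0
                and allele_count(g, m) == 1
            )

        return pred

    def assayed(g: Genotype) -> bool:
        # homozygous null chr2, both chr3 homologs from the balancer stock
        return (
            allele_count(g, "ABKO") == 2
            and allele_count(g, "CyO") == 0
            and allele_count(g, "TM3") == 1
            and allele_count(g, "Scm") == 1
        )

    crosses = [
        ("f1_tm3", "suppressor_stock", "balancer_stock", f1_with("TM3")),
        ("f1_scm", "suppressor_stock", "balancer_stock", f1_with("Scm")),
        ("f2", "f1_tm3", "f1_scm", None),
    ]
    return CrossScheme(founders=founders, crosses=crosses, assay_selector=assayed)


def beaf_segregation_scheme_x_2(hypothesis: str) -> CrossScheme:
    """Segregation design testing chromosomes X and 2.

    Suppressor-stock males (whose X passes only to daughters) are mated to
    *null/CyO* females; F1 males — which carry the balancer-stock X — are
    backcrossed to the *null/CyO* stock, so assayed non-*CyO* females carry
    no suppressor-stock X but one suppressor-stock chromosome 2.
    Expected fertile fractions: X hypothesis 0, chromosome-2 hypothesis 1
    (dominant suppressor, one copy suffices).
    """
    if hypothesis not in {"X", "2"}:
        raise ValueError("hypothesis must be 'X' or '2'")
    tofux = ("Tofu",) if hypothesis == "X" else ()
    tofu2 = ("Tofu",) if hypothesis == "2" else ()
    x_stock = hap("stock-X", *tofux)
    x_bal = hap("bal-X")
    y_chrom = hap("Y", "Y")
    abko_s = hap("ABKO-stock", "ABKO", "stockmark", *tofu2)
    abko_b = hap("ABKO-bal", "ABKO")
    cyo = hap("CyO", "CyO", balancer=True)

    founders = {
        "suppressor_males": make_genotype(
            {"X": (x_stock, y_chrom), "2": (abko_s, abko_s)}
        ),
        "balancer_females": make_genotype({"X": (x_bal, x_bal), "2": (abko_b, cyo)}),
    }

    def f1_male(g: Genotype) -> bool:
        return allele_count(g, "Y") == 1 and allele_count(g, "CyO") == 1

    def assayed(g: Genotype) -> bool:
        return (
            allele_count(g, "Y") == 0
            and allele_count(g, "CyO") == 0
            and allele_count(g, "ABKO") == 2
        )

    crosses = [
        ("f1m", "balancer_females", "suppressor_males", f1_male),
        ("f2", "balancer_females", "f1m", None),
    ]
    return CrossScheme(founders=founders, crosses=crosses, assay_selector=assayed)


# ---------------------------------------------------------------------------
# Chromosome-4 loss argument
# ---------------------------------------------------------------------------


def chr4_loss_probability(n_crosses: int) -> float:
    """Probability an unlinked chromosome-4 suppressor is lost after n crosses.

    Propagating a single heterozygous carrier each generation transmits an
    unlinked (freely assorting) suppressor with probability 1/2 per cross, so
    the loss probability after ``n_crosses`` selections is 1 − 0.5**n.
    """
    if n_crosses < 1:
        raise ValueError("n_crosses must be >= 1")
    return 1.0 - 0.5**n_crosses


# ---------------------------------------------------------------------------
# Recombination mapping (Monte Carlo, Haldane)
# ---------------------------------------------------------------------------


def haldane_rf(d: float) -> float:
    """Haldane map function: recombination fraction for d centimorgans.

    rf = (1 − exp(−2d/100)) / 2, strictly increasing, asymptote 0.5.
    """
    if d < 0:
        raise ValueError("map distance must be non-negative")
    return 0.5 * (1.0 - math.exp(-2.0 * d / 100.0))


@dataclass(frozen=True)
class LinkageMap:
    """Ordered markers with centimorgan positions.

    ``markers`` is a sequence of (label, chromosome, position_cM); positions
    must be non-decreasing within a chromosome. Physical anchors (Mb) may be
    recorded in ``metadata`` but are never converted to cM automatically.
    """

    markers: tuple[tuple[str, str, float], ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        last: dict[str, float] = {}
        for label, chrom, d in self.markers:
            if chrom in last and d < last[chrom]:
                raise ValueError(
                    f"marker {label!r} decreases map position on {chrom}"
                )
            last[chrom] = d

    def labels(self) -> list[str]:
        return [label for label, _, _ in self.markers]

    def position(self, label: str) -> tuple[str, float]:
        for lab, chrom, d in self.markers:
            if lab == label:
                return chrom, d
        raise KeyError(label)


@dataclass(frozen=True)
class RecombCount:
    """Recombinant count r out of n scored offspring."""

    r: int
    n: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 <= self.r <= self.n:
            raise ValueError("need 0 <= r <= n")


@dataclass(frozen=True)
class MappingDesign:
    """A test-cross mapping design: doubly (or multiply) heterozygous females
    crossed to tester males, all markers scorable in offspring.

    Recombination occurs only in the female parent (Drosophila males are
    achiasmate), so offspring marker phase reads out the maternal gamete
    directly.
    """

    linkage_map: LinkageMap


def _female_gametes(
    design: MappingDesign, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Simulate maternal gametes: per marker, 0 = haplotype A, 1 = haplotype B.

    Under Haldane's model crossovers occur independently in each inter-marker
    interval with probability rf(Δd); unlinked chromosomes assort freely.
    """
    out: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[tuple[str, float]]] = {}
    for label, chrom, d in design.linkage_map.markers:
        by_chrom.setdefault(chrom, []).append((label, d))
    for chrom, marks in by_chrom.items():
        state = rng.integers(0, 2, size=n)  # random phase of first marker
        out[marks[0][0]] = state.copy()
        for (prev_label, prev_d), (label, d) in zip(marks, marks[1:]):
            rf = haldane_rf(d - prev_d)
            flip = rng.random(n) < rf
            state = np.where(flip, 1 - state, state)
            out[label] = state.copy()
    return out


def simulate_mapping_cross(
    design: MappingDesign,
    n_offspring: int,
    seed: int | np.random.Generator = 0,
) -> dict[tuple[str, str], RecombCount]:
    """Monte-Carlo mapping cross; recombinant/total counts per marker pair.

    Markers on different chromosomes assort freely (expected rf 0.5).
    Returns counts for every unordered marker pair in map order.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gametes = _female_gametes(design, n_offspring, rng)
    labels = design.linkage_map.labels()
    counts: dict[tuple[str, str], RecombCount] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            r = int(np.sum(gametes[a] != gametes[b]))
            counts[(a, b)] = RecombCount(r=r, n=n_offspring)
    return counts


def estimate_rf(count: RecombCount, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Recombination-fraction point estimate (%) with a Wilson score interval.

    Returns ``(percent rounded to 1 dp, (low%, high%))``.
    """
    point = round(100.0 * count.r / count.n, 1)
    lo, hi = proportion_confint(count.r, count.n, alpha=alpha, method="wilson")
    return point, (100.0 * lo, 100.0 * hi)
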
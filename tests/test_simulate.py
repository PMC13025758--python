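"""Synthetic five-line generator: selection rules, noise, determinism, PCR."""

import numpy as np
import pytest
from scipy.stats import chisquare

from snpisland.genome import GenomeModel
from snpisland.pattern import apply_pattern, read_line_vcf
from snpisland.simulate import (
    TOFU_PATTERN,
    GenerationError,
    SimConfig,
    emit_annotations,
    emit_vcf,
    make_linked_lines,
    make_reference,
    simulate_genotyping_pcr,
)

# a two-arm chromosome-2-only model: fast enough for repeated generation
CHR2_GENOME = GenomeModel((("2L", 800_000), ("2R", 1_000_000)))
FAST_CFG = SimConfig(seed=0, snp_density=3e-4, shared_density=3e-4, causal_position=700_000)


def fast_dataset(seed: int, **overrides):
    cfg = SimConfig(
        **{
            **dict(
                seed=seed,
                snp_density=3e-4,
                shared_density=3e-4,
                causal_position=700_000,
            ),
            **overrides,
        }
    )
    return make_linked_lines(CHR2_GENOME, cfg)


class TestLinkedLines:
    def test_causal_presence_follows_selection_rule(self, clean_dataset):
        """With zero call noise the causal variant is present in founder B
        and both recombinants and absent from founder A and the outgroup."""
        causal = clean_dataset.truth.causal
        for line in ("NP6377", "TofuKO", "TofuNP"):
            assert causal in clean_dataset.lines[line]
        for line in ("ABKO", "yw"):
            assert causal not in clean_dataset.lines[line]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_causal_satisfies_pattern_by_construction(self, seed):
        data = fast_dataset(seed)
        cands = apply_pattern(data.lines, TOFU_PATTERN)
        assert data.truth.causal in cands

    def test_zero_noise_pattern_recovers_causal_without_false_negatives(
        self, clean_dataset
    ):
        cands = apply_pattern(clean_dataset.lines, TOFU_PATTERN)
        assert clean_dataset.truth.causal in cands
        # every candidate is founder-B-derived material: absent from A and yw
        for v in cands:
            assert v not in clean_dataset.lines["ABKO"]
            assert v not in clean_dataset.lines["yw"]

    def test_causal_is_canonical_t_to_g(self, clean_dataset):
        v = clean_dataset.truth.causal
        assert (v.ref, v.alt) == ("T", "G")
        assert v.chrom == "2R"
        ref = clean_dataset.reference["2R"]
        assert ref[v.pos] == "T"

    def test_recombinant_blocks_contain_causal(self, clean_dataset):
        t = clean_dataset.truth
        for block in t.blocks.values():
            assert block.contains(t.causal.pos)
        assert t.shared_block.contains(t.causal.pos)

    def test_impossible_selection_raises_generation_error(self):
        """A lethal that can never recombine away exhausts the retry bound."""
        with pytest.raises(GenerationError):
            fast_dataset(0, n_crossovers_mean=0.0, max_retries=200)

    def test_block_length_matches_crossover_process_oracle(self):
        """Mean shared-block length agrees with an independent crossover
        placement simulation of the same selection process within 10%."""
        n_seeds = 200
        lam, gens = 2.0, 4
        arm_len, causal = CHR2_GENOME.arm_length("2R"), 700_000

        rng = np.random.default_rng(123)
        oracle_lengths = []
        for _ in range(n_seeds):
            lineage_bounds = []
            for _lineage in range(2):
                lo, hi = 0, arm_len
                for _g in range(gens):
                    xos = rng.uniform(0, arm_len, size=rng.poisson(lam))
                    left = xos[xos <= causal]
                    right = xos[xos > causal]
                    if left.size:
                        lo = max(lo, int(left.max()))
                    if right.size:
                        hi = min(hi, int(right.min()))
                lineage_bounds.append((lo, hi))
            s = max(b[0] for b in lineage_bounds)
            e = min(b[1] for b in lineage_bounds)
            oracle_lengths.append(e - s)

        sim_lengths = [
            len(fast_dataset(seed, n_lethals=0).truth.shared_block)
            for seed in range(n_seeds)
        ]
        assert np.mean(sim_lengths) == pytest.approx(
            np.mean(oracle_lengths), rel=0.10
        )

    def test_pool_variants_uniform_per_unit_length(self):
        """Non-causal variant placement is uniform per bp across arms
        (pooled chi-square goodness of fit not rejected at alpha=0.01)."""
        g = GenomeModel().scaled(0.02)
        counts = np.zeros(len(g.arm_names))
        for seed in range(20):
            data = make_linked_lines(g, SimConfig(seed=seed, n_lethals=0))
            union = set().union(*data.lines.values()) - {data.truth.causal}
            for i, arm in enumerate(g.arm_names):
                counts[i] += sum(v.chrom == arm for v in union)
        lengths = np.array([l for _, l in g], dtype=float)
        expected = counts.sum() * lengths / lengths.sum()
        assert chisquare(counts, expected).pvalue > 0.01


class TestVcfEmission:
    def test_zero_noise_round_trip_is_identity(self, tmp_path):
        data = fast_dataset(3)
        cfg = SimConfig(seed=3, fp_rate=0.0, fn_rate=0.0)
        paths = emit_vcf(data.lines, CHR2_GENOME, tmp_path, cfg, causal=data.truth.causal)
        for path in paths:
            label = path.stem
            back = read_line_vcf(str(path), label, genome=CHR2_GENOME)
            assert back == set(data.lines[label])

    def test_multisample_round_trip(self, tmp_path):
        data = fast_dataset(4)
        cfg = SimConfig(seed=4, fp_rate=0.0, fn_rate=0.0)
        from snpisland.pattern import read_multisample_vcf

        (path,) = emit_vcf(
            data.lines, CHR2_GENOME, tmp_path, cfg, multi_sample=True,
            causal=data.truth.causal,
        )
        back = read_multisample_vcf(str(path), genome=CHR2_GENOME)
        assert {k: set(v) for k, v in back.items()} == {
            k: set(v) for k, v in data.lines.items()
        }

    def test_same_seed_byte_identical_output(self, tmp_path):
        data = fast_dataset(5)
        cfg = SimConfig(seed=5)
        a = emit_vcf(data.lines, CHR2_GENOME, tmp_path / "a", cfg, causal=data.truth.causal)
        b = emit_vcf(data.lines, CHR2_GENOME, tmp_path / "b", cfg, causal=data.truth.causal)
        for pa, pb in zip(a, b):
            assert pa.read_bytes() == pb.read_bytes()

    def test_false_negative_rate_matches_binomial_expectation(self, tmp_path):
        """Dropping calls at fn_rate=0.1 loses 10% +/- 2% of records."""
        from snpisland.pattern import Variant

        rng = np.random.default_rng(0)
        positions = np.sort(rng.choice(500_000, size=1000, replace=False))
        line = {"L1": frozenset(Variant("2L", int(p), "A", "T") for p in positions)}
        fractions = []
        for seed in range(100):
            cfg = SimConfig(seed=seed, fn_rate=0.1, fp_rate=0.0)
            (path,) = emit_vcf(line, CHR2_GENOME, tmp_path / str(seed), cfg)
            n_kept = sum(
                1 for l in path.read_text().splitlines() if not l.startswith("#")
            )
            fractions.append(1 - n_kept / 1000)
        assert np.mean(fractions) == pytest.approx(0.10, abs=0.02)

    def test_empty_line_set_gives_header_only_vcf(self, tmp_path):
        (path,) = emit_vcf({"L1": frozenset()}, CHR2_GENOME, tmp_path, SimConfig(seed=0))
        lines = path.read_text().splitlines()
        assert lines and all(l.startswith("#") for l in lines)

    def test_noise_never_touches_causal_by_default(self, tmp_path):
        data = fast_dataset(6)
        causal = data.truth.causal
        cfg = SimConfig(seed=6, fn_rate=0.9, fp_rate=0.0)
        paths = emit_vcf(data.lines, CHR2_GENOME, tmp_path, cfg, causal=causal)
        for path in paths:
            back = read_line_vcf(str(path), path.stem, genome=CHR2_GENOME)
            assert (causal in back) == (causal in data.lines[path.stem])


class TestAnnotationsEmission:
    def test_exactly_one_pre_contains_causal(self, tmp_path):
        from snpisland.annotate import read_bed

        data = fast_dataset(7)
        cfg = SimConfig(seed=7)
        out = emit_annotations(
            CHR2_GENOME, cfg, tmp_path, causal=data.truth.causal, n_pre=40, n_cre=20
        )
        pres = read_bed(out["pre"], element_class="PRE")
        containing = [
            e
            for e in pres
            if e.interval.chrom == data.truth.causal.chrom
            and e.interval.contains(data.truth.causal.pos)
        ]
        assert len(containing) == 1
        assert containing[0].element_id == out["causal_pre_id"]

    def test_requested_pre_count_is_written(self, tmp_path):
        """537 requested PRE intervals produce 537 BED records."""
        cfg = SimConfig(seed=8)
        out = emit_annotations(GenomeModel().scaled(0.05), cfg, tmp_path, n_pre=537)
        n = sum(1 for _ in open(out["pre"]))
        assert n == 537

    def test_gene_models_parse_back_and_validate(self, tmp_path):
        from snpisland.annotate import read_gff3

        cfg = SimConfig(seed=9)
        out = emit_annotations(CHR2_GENOME, cfg, tmp_path, n_genes=20)
        models = read_gff3(out["genes"])
        assert models
        for m in models:
            assert m.cds_length % 3 == 0  # validated in the constructor too


class TestReference:
    def test_reference_is_deterministic(self):
        cfg = SimConfig(seed=11)
        a = make_reference(CHR2_GENOME, cfg)
        b = make_reference(CHR2_GENOME, cfg)
        assert a == b
        assert set(a) == {"2L", "2R"}
        assert len(a["2R"]) == 1_000_000


@pytest.fixture(scope="module")
def assay():
    """A wild-type template with allele-specific and shared primers.

    The wt-specific forward primer ends on the wild-type base; the
    mutant-specific primer differs only at its 3'-terminal base; the
    shared reverse primer sits so that the wt product is 500 bp
    (5' end to 5' end, inclusive).
    """
    rng = np.random.default_rng(42)
    template = "".join(rng.choice(list("ACGT"), size=700))
    wt_fwd = template[100:120]
    mut_fwd = wt_fwd[:-1] + ("A" if wt_fwd[-1] != "A" else "C")
    rc = {"A": "T", "C": "G", "G": "C", "T": "A"}
    shared_rev = "".join(rc[b] for b in reversed(template[580:600]))
    return template, {"wt": wt_fwd, "mut": mut_fwd, "shared": shared_rev}


class TestGenotypingPcr:

    def test_wt_primer_gives_500bp_product(self, assay):
        template, primers = assay
        products = simulate_genotyping_pcr(template, primers)
        assert (("wt", "shared"), 500) in products

    def test_mutant_primer_three_prime_mismatch_gives_no_product(self, assay):
        template, primers = assay
        products = simulate_genotyping_pcr(template, primers)
        assert not any(pair[0] == "mut" for pair, _ in products)

    def test_same_strand_primers_give_no_product(self, assay):
        template, primers = assay
        second_fwd = template[300:320]
        products = simulate_genotyping_pcr(
            template, {"p1": primers["wt"], "p2": second_fwd}
        )
        assert not any({"p1", "p2"} == set(pair) for pair, _ in products)

    def test_short_primer_rejected(self, assay):
        template, _ = assay
        with pytest.raises(ValueError):
            simulate_genotyping_pcr(template, {"short": "ACGTACGT"})

    def test_no_annealing_yields_empty_result(self):
        products = simulate_genotyping_pcr("ACGT" * 200, {"p": "TTTTTTTTTTTTTTTT"})
        assert products == []
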
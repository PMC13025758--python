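"""End-to-end pipeline: pattern → counts → windows → islands → effects →
element intersection → prioritization, with a machine-readable summary.

Stage outputs are ordinary files (VCF, TSV, bedGraph, BED), so each stage
can be re-run independently from the previous stage's artifacts. Identical
config and seed produce byte-identical summaries.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from . import annotate, islands, pattern
from .genome import GenomeModel

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs and parameters for one pipeline run."""

    genome: GenomeModel
    #: line label -> per-line VCF path
    line_vcfs: Mapping[str, str]
    pattern_spec: pattern.PatternSpec
    out_dir: str = "results"
    window_size: int = 2000
    island_k: float = 5.0
    island_gap_bp: int = 20_000
    island_min_variants: int = 25
    genes_gff3: str | None = None
    pre_bed: str | None = None
    cre_bed: str | None = None
    reference_fasta: str | None = None
    seed: int = 0
    position_only: bool = False

    def validate(self) -> None:
        missing = self.pattern_spec.lines - set(self.line_vcfs)
        if missing:
            raise KeyError(f"pattern references unmapped line labels: {sorted(missing)}")
        for label, path in self.line_vcfs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"VCF for line {label!r} not found: {path}")


def _log(stage: str, t0: float, msg: str) -> None:
    print(f"[{stage}] {time.perf_counter() - t0:.2f}s {msg}", file=sys.stderr)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; write artifacts and return the summary dict."""
    try:
        cfg.validate()
    except Exception as exc:
        raise PipelineError("config", exc) from exc
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    summary: dict = {"stages": {}}

    reference = None
    if cfg.reference_fasta:
        from .genome import read_fasta

        reference = read_fasta(cfg.reference_fasta)

    # --- pattern -----------------------------------------------------------
    stage = "pattern"
    try:
        line_sets = {
            label: pattern.read_line_vcf(
                path, line_label=label, genome=cfg.genome, reference=reference
            )
            for label, path in cfg.line_vcfs.items()
        }
        candidates = pattern.apply_pattern(
            line_sets, cfg.pattern_spec, position_only=cfg.position_only
        )
        pattern.write_candidate_vcf(
            candidates, cfg.genome, out / "candidates.vcf", cfg.pattern_spec
        )
        matrix = pattern.count_matrix(line_sets, candidates, cfg.genome)
        matrix.to_csv(out / "count_matrix.tsv", sep="\t")
        summary["stages"][stage] = {
            "per_line_counts": {k: len(v) for k, v in sorted(line_sets.items())},
            "n_candidates": len(candidates),
            "candidates_per_arm": {
                arm: int(matrix.loc["Pattern", arm]) for arm in cfg.genome.arm_names
            },
        }
        _log(stage, t0, f"{len(candidates)} candidates")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- windows + islands -------------------------------------------------
    stage = "islands"
    try:
        track = islands.window_counts(candidates, cfg.genome, cfg.window_size)
        islands.write_density_track(track, out / "density.bedgraph")
        found = islands.detect_islands(
            track,
            k=cfg.island_k,
            gap_bp=cfg.island_gap_bp,
            min_variants=cfg.island_min_variants,
        )
        islands.write_island_bed(found, out / "islands.bed")
        (out / "islands.tsv").write_text(islands.island_report(found))
        summary["stages"][stage] = {
            "n_islands": len(found),
            "islands": [
                {
                    "region": isl.interval.to_region_string(thousands=False),
                    "n_variants": isl.n_variants,
                }
                for isl in found
            ],
        }
        _log(stage, t0, f"{len(found)} islands")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # top island on the causal-candidate chromosome: best-ranked overall
    top_island = found[0] if found else None

    # --- effects + elements ------------------------------------------------
    stage = "annotate"
    effects: list[annotate.EffectCall] = []
    hits: list[annotate.ElementHit] = []
    try:
        if cfg.genes_gff3 and reference is not None:
            models = annotate.read_gff3(cfg.genes_gff3)
            for v in sorted(candidates):
                effects.extend(annotate.classify_effect(v, models, reference))
            with open(out / "effects.tsv", "w") as fh:
                fh.write("variant\ttranscript\tcategory\tdetail\n")
                for e in effects:
                    fh.write(f"{e.variant}\t{e.transcript_id}\t{e.category}\t{e.detail}\n")
        for cls, bed in (("PRE", cfg.pre_bed), ("CRE", cfg.cre_bed)):
            if bed:
                elements = annotate.read_bed(bed, element_class=cls)
                cls_hits, (nv, ne) = annotate.intersect_elements(candidates, elements)
                hits.extend(cls_hits)
                summary["stages"].setdefault(stage, {})[f"{cls.lower()}_hits"] = {
                    "n_variants": nv,
                    "n_elements": ne,
                }
        with open(out / "element_hits.tsv", "w") as fh:
            fh.write("variant\telement_id\telement_class\tregion\n")
            for h in sorted(hits, key=lambda h: (h.variant, h.element.element_id)):
                fh.write(
                    f"{h.variant}\t{h.element.element_id}\t{h.element.element_class}\t"
                    f"{h.element.interval.to_region_string(thousands=False)}\n"
                )
        summary["stages"].setdefault(stage, {})["n_effect_calls"] = len(effects)
        _log(stage, t0, f"{len(effects)} effect calls, {len(hits)} element hits")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- prioritize --------------------------------------------------------
    stage = "prioritize"
    try:
        ranking = annotate.prioritize(candidates, effects, hits, top_island)
        with open(out / "ranked_candidates.tsv", "w") as fh:
            fh.write("rank\tvariant\ttier\treason\n")
            for rank, v, tier, reason in ranking:
                fh.write(f"{rank}\t{v}\t{tier}\t{reason}\n")
        summary["stages"][stage] = {
            "top_candidates": [
                {"rank": r, "variant": str(v), "tier": t, "reason": reason}
                for r, v, t, reason in ranking[:10]
            ]
        }
        _log(stage, t0, f"top: {ranking[0][1] if ranking else None}")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    summary["seed"] = cfg.seed
    summary["genome"] = {name: length for name, length in cfg.genome}
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
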
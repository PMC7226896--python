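"""End-to-end orchestration: simulate -> analyze -> report.

``run_all`` drives the full synthetic study from one config: generate the
tumor cohort, the enhancer landscape, the derivative-locus CTCF map and
the dropout screen, then run the four analyses (exonic imbalance with
group comparisons; SE calling with rank percentiles; neo-TAD neighborhood
annotation; screen class comparison) and write plain-text TSV outputs
plus a JSON manifest with seeds, parameters and output checksums.

Reruns with identical config + seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import fixtures
from .crispr_dropout import class_comparison_table, screen_analysis
from .enhancer_rank import call_superenhancers, rank_percentile, stitch_enhancers
from .exon_imbalance import group_comparison_table, imbalance_table
from .neo_tad import classify_elements, convergent_pairs, define_neighborhood
from .synthetic_cohort import (
    CohortSpec,
    LandscapeSpec,
    ScreenSpec,
    gen_ctcf_map,
    gen_enhancer_landscape,
    gen_exon_counts,
    gen_screen_counts,
    spec_manifest,
)

log = logging.getLogger("fusionwire")

FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A named pipeline stage failed; partial outputs are retained."""


@dataclass
class RunConfig:
    """Configuration of a full synthetic study run."""

    seed: int = 0
    out_dir: str | Path = "fusionwire_run"
    cohort: dict = field(default_factory=dict)
    landscape: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    focus_gene: str = "PAX3"
    tau: float = 1.5
    pseudocount: float = 1.0
    stitch_gap: int = 12_500
    screen_reference: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def run_all(config: RunConfig) -> dict:
    """Run the full synthetic study; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "focus_gene": config.focus_gene,
            "tau": config.tau,
            "pseudocount": config.pseudocount,
            "stitch_gap": config.stitch_gap,
        },
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = "ok"

    try:
        # --- cohort imbalance -------------------------------------------
        stage("cohort")
        genes = fixtures.load_toy_gene_models()
        presets = fixtures.all_preset_fusions(genes)
        fusions = {
            grp: (presets[name] if name else None)
            for grp, name in fixtures.GROUP_FUSIONS.items()
        }
        cohort_spec = CohortSpec(seed=config.seed, **config.cohort)
        manifest["parameters"]["cohort"] = spec_manifest(cohort_spec)
        matrix, truth = gen_exon_counts(cohort_spec, genes, fusions)
        fusion_5p = presets["PAX3-FOXO1"]
        retained = (
            list(fusion_5p.retained_5p_exons)
            if config.focus_gene == fusion_5p.five_prime_gene
            else None
        )
        table = imbalance_table(
            matrix,
            config.focus_gene,
            retained=retained,
            pseudocount=config.pseudocount,
            tau=config.tau,
        )
        comparisons = group_comparison_table(table, reference="FN")
        _write(table, out / "cohort_imbalance.tsv")
        _write(comparisons, out / "group_comparisons.tsv", index=False)
        _write(truth, out / "cohort_truth.tsv", index=False)
        written += [
            out / "cohort_imbalance.tsv",
            out / "group_comparisons.tsv",
            out / "cohort_truth.tsv",
        ]

        # --- enhancer landscape / SE calling ----------------------------
        stage("landscape")
        landscape_spec = LandscapeSpec(seed=config.seed + 1, **config.landscape)
        manifest["parameters"]["landscape"] = spec_manifest(landscape_spec)
        peaks = gen_enhancer_landscape(landscape_spec)
        stitched = stitch_enhancers(
            peaks[["chrom", "start", "end", "signal"]], gap=config.stitch_gap
        )
        ranked = call_superenhancers(stitched)
        top = ranked.iloc[0]
        percentiles = rank_percentile(
            (top["chrom"], int(top["start"]), int(top["end"])), {"sample_1": ranked}
        )
        _write(ranked, out / "ranked_enhancers.tsv", index=False)
        _write(percentiles.to_frame(), out / "rank_percentiles.tsv")
        written += [out / "ranked_enhancers.tsv", out / "rank_percentiles.tsv"]

        # --- neo-TAD annotation -----------------------------------------
        stage("neo_tad")
        sites = gen_ctcf_map(fixtures.toy_derivative_ctcf_sites())
        pairs = convergent_pairs(sites)
        neighborhood = define_neighborhood(sites, fixtures.TOY_PROMOTER_ANCHOR)
        from .neo_tad import LocusFeature

        elements = [
            LocusFeature("der", 2_000, "PAX3-promoter", "promoter"),
            LocusFeature("der", 30_000, "FOXO1-SE", "SE"),
            LocusFeature("der", 80_000, "intronic-enh", "typical_enhancer"),
            LocusFeature("der", 400_000, "distal-SE", "SE"),
        ]
        annotated = pd.DataFrame(classify_elements(neighborhood, elements))
        pair_df = pd.DataFrame(
            [
                {
                    "left": a.label,
                    "left_pos": a.position,
                    "right": b.label,
                    "right_pos": b.position,
                    "span": b.position - a.position,
                }
                for a, b in pairs
            ]
        )
        _write(pair_df, out / "convergent_pairs.tsv", index=False)
        _write(annotated, out / "neighborhood_elements.tsv", index=False)
        written += [out / "convergent_pairs.tsv", out / "neighborhood_elements.tsv"]

        # --- CRISPR screen ----------------------------------------------
        stage("screen")
        screen_spec = ScreenSpec(seed=config.seed + 2, **config.screen)
        manifest["parameters"]["screen"] = spec_manifest(screen_spec)
        counts, annot, _ = gen_screen_counts(screen_spec)
        lfc, scores = screen_analysis(
            counts, annot, reference=config.screen_reference
        )
        pairs_to_test = [
            ("promoter", "intra_tad_se"),
            ("intra_tad_se", "typical_enhancer"),
            ("intra_tad_se", "outside_tad_se"),
            ("typical_enhancer", "control"),
        ]
        class_cmp = class_comparison_table(scores, pairs_to_test)
        _write(lfc, out / "sgrna_lfc.tsv")
        _write(scores, out / "element_scores.tsv", index=False)
        _write(class_cmp, out / "screen_class_comparison.tsv", index=False)
        written += [
            out / "sgrna_lfc.tsv",
            out / "element_scores.tsv",
            out / "screen_class_comparison.tsv",
        ]
    except Exception as exc:
        current = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        manifest["stages"][current] = f"failed: {exc}"
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    manifest["outputs"] = {p.name: _checksum(p) for p in written}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
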
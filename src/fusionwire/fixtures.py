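"""Packaged toy locus fixtures.

Toy single-transcript gene models for the five rhabdomyosarcoma fusion
partner genes (PAX3, PAX7, FOXO1, INO80D, NCOA1), with synthetic
coordinates (exon k of each gene spans ``[off + 1000*k, off + 1000*k +
200)``), and intronic breakpoint presets chosen so the resulting fusion
transcripts carry the exon architectures reported clinically:

* PAX3-FOXO1:          PAX3 exons 1-7 + FOXO1 exons 2-3
* PAX7-FOXO1:          PAX7 exons 1-7 + FOXO1 exons 2-3
* PAX3-INO80D:         PAX3 exons 1-7 + INO80D exons 9-11
* PAX3-NCOA1 type 1:   PAX3 exons 1-6 + NCOA1 exons 13-22
* PAX3-NCOA1 type 2:   PAX3 exons 1-7 + NCOA1 exons 12-22

Real genomic breakpoint coordinates are not modelled; only the retained
exon ranges are meaningful.

Also provides the toy derivative-locus CTCF arrangement used for
neo-TAD logic tests: a forward-oriented CTCF site at the PAX3 promoter
followed by three FOXO1-distal sites of which #1 and #3 are
reverse-oriented (convergent with the promoter site) and #2 is forward.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .gene_models import (
    FIVE_PRIME,
    THREE_PRIME,
    Breakpoint,
    FusionTranscript,
    GeneModel,
    build_fusion_transcript,
    load_gene_models,
)
from .neo_tad import CTCFSite

#: fusion name -> ((5' gene, 5' breakpoint pos), (3' gene, 3' breakpoint pos))
FUSION_BREAKPOINTS: dict[str, tuple[tuple[str, int], tuple[str, int]]] = {
    "PAX3-FOXO1": (("PAX3", 7500), ("FOXO1", 1500)),
    "PAX7-FOXO1": (("PAX7", 7500), ("FOXO1", 1500)),
    "PAX3-INO80D": (("PAX3", 7500), ("INO80D", 108500)),
    "PAX3-NCOA1-type1": (("PAX3", 6500), ("NCOA1", 212500)),
    "PAX3-NCOA1-type2": (("PAX3", 7500), ("NCOA1", 211500)),
}

#: cohort group label -> fusion preset name (None = fusion negative)
GROUP_FUSIONS: dict[str, str | None] = {
    "FN": None,
    "P3F": "PAX3-FOXO1",
    "P7F": "PAX7-FOXO1",
    "P3N": "PAX3-NCOA1-type1",
    "P3I": "PAX3-INO80D",
}


def toy_gtf_path() -> Path:
    return Path(str(resources.files("fusionwire").joinpath("data/toy_models.gtf")))


def load_toy_gene_models() -> dict[str, GeneModel]:
    """Load the packaged toy gene models (PAX3, PAX7, FOXO1, INO80D, NCOA1)."""
    return load_gene_models(toy_gtf_path())


def fusion_breakpoints(name: str, genes: dict[str, GeneModel]) -> tuple[
    tuple[GeneModel, Breakpoint], tuple[GeneModel, Breakpoint]
]:
    (g5, pos5), (g3, pos3) = FUSION_BREAKPOINTS[name]
    gene5, gene3 = genes[g5], genes[g3]
    bp5 = Breakpoint(gene5.chrom, pos5, g5, FIVE_PRIME)
    bp3 = Breakpoint(gene3.chrom, pos3, g3, THREE_PRIME)
    return (gene5, bp5), (gene3, bp3)


def build_preset_fusion(
    name: str, genes: dict[str, GeneModel] | None = None
) -> FusionTranscript:
    """Construct one of the named preset fusion transcripts."""
    genes = genes if genes is not None else load_toy_gene_models()
    five, three = fusion_breakpoints(name, genes)
    return build_fusion_transcript(five, three)


def all_preset_fusions(
    genes: dict[str, GeneModel] | None = None
) -> dict[str, FusionTranscript]:
    genes = genes if genes is not None else load_toy_gene_models()
    return {name: build_preset_fusion(name, genes) for name in FUSION_BREAKPOINTS}


# --- toy derivative-locus CTCF arrangement ---------------------------------

#: position of the PAX3-promoter anchor on the toy derivative axis
TOY_PROMOTER_ANCHOR = 1_000

def toy_derivative_ctcf_sites() -> list[CTCFSite]:
    """CTCF sites of the toy derivative locus.

    The PAX3-promoter site points toward the fusion (forward); of the three
    FOXO1-distal sites downstream, #1 and #3 point back toward the promoter
    (reverse, i.e. convergent with it) while #2 points away.
    """
    return [
        CTCFSite(chrom="der", position=900, orientation="forward", label="PAX3-promoter-CTCF"),
        CTCFSite(chrom="der", position=50_000, orientation="reverse", label="FOXO1-distal-1"),
        CTCFSite(chrom="der", position=120_000, orientation="forward", label="FOXO1-distal-2"),
        CTCFSite(chrom="der", position=300_000, orientation="reverse", label="FOXO1-distal-3"),
    ]
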
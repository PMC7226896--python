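# fusionwire

Analyses of enhancer miswiring in fusion-positive rhabdomyosarcoma
(FP-RMS), packaged as a tested, reusable Python library with a small CLI.

In FP-RMS, a chromosomal translocation fuses the 5' end of *PAX3* (or
*PAX7*) to the 3' end of a partner gene (*FOXO1*, and rarely *NCOA1* or
*INO80D*), and — critically — places the *PAX3* promoter under the control
of a hijacked super enhancer (SE) from the partner locus, inside a new
CTCF-bounded insulated neighborhood. This package implements the
computational analyses by which that miswiring is inferred and
characterized:

* **`gene_models`** — genes as ordered exon chains; mapping intronic
  breakpoints to retained/lost exons; construction of fusion transcripts
  (e.g. PAX3 exons 1–7 joined to FOXO1 exons 2–3).
* **`exon_imbalance`** — allele-specific epistate inference from
  exon-level RNA-seq. Expression is x_ij = log2(RPKM_ij + c). Each
  sample is mean-centered across its exons and scaled by a robust
  cohort-wide per-exon scale (1.4826·MAD), giving exon z scores z_ij;
  the per-sample imbalance score is Z\* = max_i |z_ij|. A
  breakpoint-aware contrast Δ = (mean x over retained − mean x over
  lost) / pooled SD calls the epistate (balanced / imbalanced 5' /
  imbalanced 3'). Groups are compared with a two-tailed Welch t test on
  log2(1 + Z\*).
* **`enhancer_rank`** — ROSE-style SE calling: peaks within 12.5 kb are
  stitched, regions ranked by summed signal, and the SE cutoff placed
  where a slope-1 line is tangent to the min–max-scaled rank curve;
  cross-sample rank percentiles at a query locus; spike-in (ChIP-Rx)
  normalization, RRPM = count·10⁶ / spike-in reads, with delta-RRPM
  difference tracks.
* **`neo_tad`** — derivative-chromosome reconstruction with exact
  round-trip coordinate mapping; enumeration of convergent
  ("antiparallel") CTCF motif pairs permissive of loop extrusion; the
  insulated neighborhood as the smallest convergent pair spanning the
  fusion promoter; intra-TAD vs outside classification of regulatory
  elements.
* **`crispr_dropout`** — pooled tiling-screen analysis: per-timepoint
  counts-per-million, per-sgRNA LFC = log2(a_t / a_ref), per-element
  median aggregation, and Welch + Mann-Whitney comparisons between
  regulatory-element classes.
* **`synthetic_cohort`** — generators for every input: an RMS-like
  cohort (61 fusion-negative, 23 PAX3-FOXO1, 10 PAX7-FOXO1, 2
  PAX3-NCOA1, 1 PAX3-INO80D) with two-allele negative-binomial exon
  counts, heavy-tailed enhancer landscapes with a small SE tail,
  oriented CTCF maps, and sgRNA count time series with
  element-class-dependent exponential depletion — each with a recorded
  ground truth.
* **`pipeline`** — `run_all(RunConfig)` drives simulate → analyze →
  report end to end, deterministically for a fixed seed, writing TSV
  outputs and a JSON manifest.

## Worked example

Build the PAX3-FOXO1 fusion transcript from the packaged toy gene models
(breakpoint in PAX3 intron 7 and FOXO1 intron 1):

```sh
fusionwire fuse --gtf src/fusionwire/data/toy_models.gtf \
    --five-prime PAX3:7500 --three-prime FOXO1:1500 --out fusion.tsv
# PAX3-FOXO1: 5' exons (1, 2, 3, 4, 5, 6, 7), 3' exons (2, 3)
```

Simulate a cohort with the default composition and score PAX3 exonic
imbalance:

```sh
fusionwire simulate cohort --seed 3 --out cohort/
fusionwire imbalance --counts cohort/exon_counts.tsv \
    --samples cohort/samples.tsv --gene PAX3
```

```
group reference  n_group  n_reference         t        df            p
  P3F        FN       23           61 11.276207 30.286531 2.293286e-12
  P3N        FN        2           61 22.436617  2.092476 1.579653e-03
  P7F        FN       10           61 -2.061279 12.518265 6.068043e-02
```

The PAX3-FOXO1 group (P3F) shows a decisively higher PAX3 imbalance
score than fusion-negative tumors (FN): its fusion allele, driven by the
hijacked SE, expresses only exons 1–7, while exons 8–9 come only from
the near-silent wild-type allele. The PAX7-FOXO1 group (P7F) is *not*
elevated on PAX3 — its imbalance appears on PAX7 instead — and the rare
PAX3-NCOA1 group (n = 2) is already separable. The full synthetic study
(imbalance, SE calling, neo-TAD annotation, screen dropout) runs with
`fusionwire run --seed 5 --out run/`.

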
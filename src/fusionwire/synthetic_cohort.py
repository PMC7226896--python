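"""Synthetic inputs with the statistical structure the analyses assume.

Every downstream stage of the pipeline is exercised on data from this
module, so each generator records its ground truth:

* ``gen_exon_counts`` — an RMS-like tumor cohort with two-allele exon
  count structure. Each sample carries a wild-type allele driven by the
  native promoter and, in fusion-positive groups, a fusion allele driven
  by the hijacked super enhancer that expresses only the retained exons.
  Expected count for exon i, sample j is
  ``mu_ij = (L_i/1e3) * s_j * (b_wt * w_g + f * [i retained])`` with the
  fusion-allele rate ``f = r * b_wt * w_g`` so that the expected
  retained/lost expression ratio is r + 1 regardless of lineage
  silencing ``w_g``. Counts are negative-binomial with variance
  ``mu + phi * mu^2``.
* ``gen_enhancer_landscape`` — heavy-tailed enhancer signals: a
  log-normal bulk plus a small super-enhancer tail component whose
  median sits ``tail_scale`` times above the bulk median.
* ``gen_screen_counts`` — pooled tiling-screen sgRNA counts over
  timepoints; latent abundance of each guide decays as
  ``exp(-delta_class * (t - t0))`` and is multinomially sequenced to a
  fixed per-timepoint depth.
* ``gen_ctcf_map`` — validated pass-through of oriented CTCF sites.

Identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exon_imbalance import ExonCountMatrix
from .gene_models import FusionTranscript, GeneModel
from .neo_tad import CTCFSite

#: cohort composition: fusion-negative plus the four fusion-positive groups
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "FN": 61,
    "P3F": 23,
    "P7F": 10,
    "P3N": 2,
    "P3I": 1,
}

#: per-day depletion rates by regulatory-element class; promoters deplete
#: fastest, intra-TAD SEs next, TAD-boundary CTCF sites weakly, typical
#: enhancers / outside-TAD SEs / safe-harbor controls not at all.
DEFAULT_DEPLETION_RATES: dict[str, float] = {
    "promoter": 0.30,
    "intra_tad_se": 0.15,
    "tad_boundary_ctcf": 0.06,
    "typical_enhancer": 0.0,
    "outside_tad_se": 0.0,
    "control": 0.0,
}

DEFAULT_ELEMENTS_PER_CLASS: dict[str, int] = {
    "promoter": 4,
    "intra_tad_se": 6,
    "tad_boundary_ctcf": 4,
    "typical_enhancer": 30,
    "outside_tad_se": 6,
    "control": 50,
}

DEFAULT_TIMEPOINTS: tuple[int, ...] = (2, 5, 7, 10, 13, 17, 20, 25)


class SyntheticSpecError(ValueError):
    pass


@dataclass
class CohortSpec:
    """Parameters of the synthetic tumor cohort.

    ``imbalance_ratio`` r is the SE-driven fusion-allele expression
    relative to the (possibly lineage-silenced) wild-type allele; r = 0
    is the null (no fusion-allele expression). ``wt_silencing`` scales
    the wild-type 5'-partner allele in fusion-positive groups (the
    wild-type PAX3/7 allele is near-silent in FP tumors).
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    imbalance_ratio: float = 10.0
    dispersion: float = 0.1
    base_rate: float = 200.0  # expected counts per kb at library factor 1
    wt_silencing: float = 0.2
    library_size_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise SyntheticSpecError("group sizes must be >= 0")
        if self.imbalance_ratio < 0:
            raise SyntheticSpecError("imbalance ratio must be >= 0")
        if self.dispersion <= 0:
            raise SyntheticSpecError("dispersion must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise SyntheticSpecError("bad library size range")


@dataclass
class LandscapeSpec:
    """Parameters of the heavy-tailed enhancer signal landscape."""

    n_enhancers: int = 1000
    tail_fraction: float = 0.04
    bulk_median: float = 100.0
    bulk_sigma: float = 0.8
    tail_scale: float = 20.0
    tail_sigma: float = 0.5
    chrom: str = "chrS"
    span: tuple[int, int] = (0, 200_000_000)
    width_range: tuple[int, int] = (500, 5_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.tail_fraction <= 1:
            raise SyntheticSpecError("tail fraction must lie in [0, 1]")
        if self.n_enhancers < 1:
            raise SyntheticSpecError("need at least one enhancer")


@dataclass
class ScreenSpec:
    """Parameters of the pooled tiling CRISPR dropout screen."""

    depletion_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEPLETION_RATES)
    )
    elements_per_class: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENTS_PER_CLASS)
    )
    sgrnas_per_element: int = 5
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS
    depth: int = 1_000_000
    abundance_sigma: float = 0.25  # lognormal spread of initial guide abundance
    seed: int = 0

    def __post_init__(self) -> None:
        tps = list(self.timepoints)
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise SyntheticSpecError("timepoints must be strictly increasing")
        if any(r < 0 for r in self.depletion_rates.values()):
            raise SyntheticSpecError("depletion rates must be >= 0")
        extra = set(self.elements_per_class) - set(self.depletion_rates)
        if extra:
            raise SyntheticSpecError(f"classes without depletion rate: {extra}")


def gen_exon_counts(
    spec: CohortSpec,
    genes: Mapping[str, GeneModel],
    fusions: Mapping[str, FusionTranscript | None],
) -> tuple[ExonCountMatrix, pd.DataFrame]:
    """Simulate the two-allele exon count matrix plus a ground-truth table.

    ``fusions`` maps each cohort group to its fusion transcript (None for
    fusion-negative groups). For fusion-positive samples the 5' partner's
    wild-type allele is silenced (``wt_silencing``) and the fusion allele
    adds rate ``r * b * w`` on the retained prefix exons of the 5' gene
    and the retained suffix exons of the 3' gene. All genes in ``genes``
    are simulated for every sample.
    """
    for grp, n in spec.group_sizes.items():
        if n > 0 and grp not in fusions:
            raise SyntheticSpecError(f"group {grp!r} lacks a fusion entry")
    if spec.imbalance_ratio > 0 and all(f is None for f in fusions.values()):
        raise SyntheticSpecError(
            "imbalance ratio > 0 requires at least one fusion-positive group"
        )
    rng = np.random.default_rng(spec.seed)
    index = pd.MultiIndex.from_tuples(
        [
            (gid, i)
            for gid, gene in genes.items()
            for i in range(1, gene.n_exons + 1)
        ],
        names=["gene_id", "exon_index"],
    )
    lengths = pd.Series(
        [len(genes[gid].exon(i)) for gid, i in index], index=index, name="length"
    )
    r, phi, b = spec.imbalance_ratio, spec.dispersion, spec.base_rate
    lo, hi = spec.library_size_range

    sample_cols: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    truth_rows = []
    for grp in spec.group_sizes:
        fusion = fusions.get(grp)
        retained: dict[str, set[int]] = {}
        if fusion is not None:
            retained[fusion.five_prime_gene] = set(fusion.retained_5p_exons)
            retained.setdefault(fusion.three_prime_gene, set())
            retained[fusion.three_prime_gene] |= set(fusion.retained_3p_exons)
        # per-group rate vector over exons (library factor applied per sample)
        rate = np.empty(len(index))
        for pos, (gid, i) in enumerate(index):
            silenced = fusion is not None and gid == fusion.five_prime_gene
            wt_rate = b * (spec.wt_silencing if silenced else 1.0)
            fus_rate = (
                r * b * spec.wt_silencing
                if fusion is not None and i in retained.get(gid, ())
                else 0.0
            )
            rate[pos] = (lengths.iloc[pos] / 1e3) * (wt_rate + fus_rate)
        for k in range(spec.group_sizes[grp]):
            sid = f"{grp}_{k + 1:03d}"
            s_j = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            counts = _negative_binomial(rng, rate * s_j, phi)
            sample_cols[sid] = counts
            groups[sid] = grp
            truth_rows.append(
                {
                    "sample_id": sid,
                    "group": grp,
                    "fusion": fusion.name if fusion is not None else "",
                    "library_factor": s_j,
                    "wt_rate_5p": b * (spec.wt_silencing if fusion is not None else 1.0),
                    "fusion_rate": r * b * spec.wt_silencing if fusion is not None else 0.0,
                }
            )
    counts_df = pd.DataFrame(sample_cols, index=index)
    matrix = ExonCountMatrix(
        counts=counts_df,
        lengths=lengths,
        groups=pd.Series(groups, name="group"),
    )
    return matrix, pd.DataFrame(truth_rows)


def _negative_binomial(
    rng: np.random.Generator, mu: np.ndarray, phi: float
) -> np.ndarray:
    """NB draws parameterized by mean mu and dispersion phi (var = mu + phi mu^2)."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    n = 1.0 / phi
    p = n / (n + mu[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out


def gen_enhancer_landscape(spec: LandscapeSpec) -> pd.DataFrame:
    """Heavy-tailed enhancer landscape with ground-truth SE flags.

    Returns non-overlapping intervals with ``signal`` and ``truth_se``
    (drawn from the tail component). Signals are log-normal; the tail
    component's median is ``tail_scale`` times the bulk median.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.span
    wmin, wmax = spec.width_range
    if (hi - lo) < spec.n_enhancers * (wmax + 1):
        raise SyntheticSpecError("genome span too small for requested enhancers")
    widths = rng.integers(wmin, wmax + 1, size=spec.n_enhancers)
    slack = (hi - lo) - int(widths.sum())
    gaps = rng.multinomial(slack - spec.n_enhancers, np.full(spec.n_enhancers, 1 / spec.n_enhancers))
    starts = lo + np.cumsum(gaps + 1) + np.concatenate(([0], np.cumsum(widths[:-1])))
    is_tail = rng.random(spec.n_enhancers) < spec.tail_fraction
    mu_bulk = np.log(spec.bulk_median)
    mu_tail = np.log(spec.bulk_median * spec.tail_scale)
    signal = np.where(
        is_tail,
        rng.lognormal(mu_tail, spec.tail_sigma, spec.n_enhancers),
        rng.lognormal(mu_bulk, spec.bulk_sigma, spec.n_enhancers),
    )
    return pd.DataFrame(
        {
            "chrom": spec.chrom,
            "start": starts.astype(int),
            "end": (starts + widths).astype(int),
            "signal": signal,
            "truth_se": is_tail,
        }
    )


def gen_ctcf_map(sites: Sequence[CTCFSite]) -> list[CTCFSite]:
    """Validate and return a CTCF site map (sorted by chrom, position)."""
    seen = set()
    for s in sites:
        key = (s.chrom, s.position)
        if key in seen:
            raise SyntheticSpecError(f"duplicate CTCF site at {s.chrom}:{s.position}")
        seen.add(key)
    return sorted(sites, key=lambda s: (s.chrom, s.position))


def gen_screen_counts(spec: ScreenSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the pooled dropout screen.

    Returns ``(counts, annotations, truth)``: counts are sgRNA x timepoint
    (columns ``day_2`` ...), annotations map each sgRNA to its element and
    class, truth records the per-class depletion rate actually used.
    Latent guide abundance decays exponentially from the first timepoint;
    observed counts are one multinomial draw of ``depth`` reads per
    timepoint.
    """
    rng = np.random.default_rng(spec.seed)
    ids, elements, classes = [], [], []
    for cls in spec.elements_per_class:
        for e in range(spec.elements_per_class[cls]):
            el = f"{cls}_{e + 1:02d}"
            for g in range(spec.sgrnas_per_element):
                ids.append(f"{el}_sg{g + 1}")
                elements.append(el)
                classes.append(cls)
    if len(set(ids)) != len(ids):
        raise SyntheticSpecError("duplicate sgRNA identifiers")
    n = len(ids)
    delta = np.array([spec.depletion_rates[c] for c in classes])
    base = rng.lognormal(0.0, spec.abundance_sigma, n)
    t0 = spec.timepoints[0]
    cols = {}
    for t in spec.timepoints:
        latent = base * np.exp(-delta * (t - t0))
        p = latent / latent.sum()
        cols[f"day_{t}"] = rng.multinomial(spec.depth, p)
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="sgrna_id"))
    annot = pd.DataFrame(
        {"sgrna_id": ids, "element_id": elements, "element_class": classes}
    ).set_index("sgrna_id")
    truth = pd.DataFrame(
        {
            "element_class": list(spec.depletion_rates),
            "depletion_per_day": [spec.depletion_rates[c] for c in spec.depletion_rates],
        }
    )
    return counts, annot, truth


def spec_manifest(spec) -> dict:
    """Serializable echo of a generator spec for run manifests."""
    d = asdict(spec)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
        elif isinstance(v, Mapping):
            d[k] = dict(v)
    return d
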
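"""Derivative-locus reconstruction and CTCF-orientation neo-TAD logic.

A reciprocal translocation joins a 5' segment of one chromosome to a 3'
segment of another, producing a derivative chromosome on which regulatory
features from the two native loci share one coordinate axis. CTCF sites
whose motifs point toward each other (convergent, "antiparallel") are
permissive anchors for cohesin loop extrusion; on the derivative axis a
convergent pair that spans the fusion promoter defines the new insulated
neighborhood (neo-TAD) through which a hijacked super enhancer can act.

Orientations are encoded relative to the coordinate axis: ``forward``
means the motif points toward increasing coordinate, ``reverse`` toward
decreasing. A pair (i, j) with position_i < position_j is loop-permissive
iff site i is forward and site j is reverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

FORWARD = "forward"
REVERSE = "reverse"


class NeoTadError(ValueError):
    """Invalid derivative-locus specification or site map."""


@dataclass(frozen=True)
class CTCFSite:
    chrom: str
    position: int
    orientation: str | None  # FORWARD / REVERSE / None (unoriented)
    label: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, REVERSE, None):
            raise NeoTadError(f"bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class LocusFeature:
    """A point feature (enhancer, promoter, CTCF site ...) on one axis."""

    chrom: str
    position: int
    label: str = ""
    kind: str = "feature"  # e.g. promoter / SE / typical_enhancer / CTCF
    orientation: str | None = None


@dataclass(frozen=True)
class SegmentSpec:
    """A source-chromosome slice entering the derivative chromosome."""

    chrom: str
    start: int
    end: int
    flipped: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise NeoTadError(f"segment start must be < end: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, position: int) -> bool:
        return chrom == self.chrom and self.start <= position < self.end


def _flip(orientation: str | None) -> str | None:
    if orientation is None:
        return None
    return REVERSE if orientation == FORWARD else FORWARD


@dataclass
class DerivativeLocus:
    """Features from two native chromosomes remapped onto one fused axis.

    Segment k occupies ``[offset_k, offset_k + len_k)`` on the derivative
    axis; the mapping is exactly invertible (``to_source`` undoes
    ``to_derivative``). On a flipped segment both feature position and
    CTCF orientation are mirrored.
    """

    segments: list[SegmentSpec]
    features: list[LocusFeature] = field(default_factory=list)
    provenance: list[tuple[str, int]] = field(default_factory=list)  # (chrom, src pos)

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.segments)

    def _offsets(self) -> list[int]:
        offs, acc = [], 0
        for s in self.segments:
            offs.append(acc)
            acc += len(s)
        return offs

    def to_derivative(self, chrom: str, position: int) -> int:
        for seg, off in zip(self.segments, self._offsets()):
            if seg.contains(chrom, position):
                if seg.flipped:
                    return off + (seg.end - position)
                return off + (position - seg.start)
        raise NeoTadError(f"{chrom}:{position} not covered by any segment")

    def to_source(self, derivative_position: int) -> tuple[str, int]:
        for seg, off in zip(self.segments, self._offsets()):
            rel = derivative_position - off
            upper = len(seg) + (1 if seg.flipped else 0)
            lower = 1 if seg.flipped else 0
            if lower <= rel < upper:
                if seg.flipped:
                    return seg.chrom, seg.end - rel
                return seg.chrom, seg.start + rel
        raise NeoTadError(f"derivative position {derivative_position} out of range")

    def ctcf_sites(self) -> list[CTCFSite]:
        return [
            CTCFSite("der", f.position, f.orientation, f.label)
            for f in self.features
            if f.kind.upper() == "CTCF"
        ]


def build_derivative_locus(
    five_prime: SegmentSpec,
    three_prime: SegmentSpec,
    features: Iterable[LocusFeature] = (),
) -> DerivativeLocus:
    """Fuse a 5' and a 3' source segment and remap features onto the result.

    Features not covered by either segment are dropped with a warning; a
    feature covered by both segments (overlapping source specification)
    is an error.
    """
    if five_prime.chrom == three_prime.chrom:
        overlap = (
            five_prime.start < three_prime.end and three_prime.start < five_prime.end
        )
        if overlap:
            raise NeoTadError("5' and 3' segments overlap on the same source chromosome")
    locus = DerivativeLocus(segments=[five_prime, three_prime])
    for feat in features:
        hits = [s for s in locus.segments if s.contains(feat.chrom, feat.position)]
        if not hits:
            warnings.warn(
                f"feature {feat.label or feat.kind} at {feat.chrom}:{feat.position} "
                "outside both segments; dropped",
                stacklevel=2,
            )
            continue
        seg = hits[0]
        dpos = locus.to_derivative(feat.chrom, feat.position)
        orient = _flip(feat.orientation) if seg.flipped else feat.orientation
        locus.features.append(replace(feat, chrom="der", position=dpos, orientation=orient))
        locus.provenance.append((feat.chrom, feat.position))
    return locus


def convergent_pairs(sites: Sequence[CTCFSite]) -> list[tuple[CTCFSite, CTCFSite]]:
    """Enumerate loop-permissive (convergent) CTCF site pairs on one axis.

    Pair (i, j) with position_i < position_j is permissive iff i is
    forward-oriented and j reverse-oriented. Returned sorted by span
    (innermost first).
    """
    if len(sites) < 2:
        return []
    for s in sites:
        if s.orientation is None:
            raise NeoTadError(f"site {s.label or s.position} has no orientation")
    ordered = sorted(sites, key=lambda s: s.position)
    pairs = [
        (a, b)
        for idx, a in enumerate(ordered)
        for b in ordered[idx + 1 :]
        if a.orientation == FORWARD and b.orientation == REVERSE
    ]
    pairs.sort(key=lambda p: (p[1].position - p[0].position, p[0].position))
    return pairs


@dataclass
class NeighborhoodModel:
    """An insulated neighborhood bounded by one convergent CTCF pair."""

    boundaries: tuple[CTCFSite, CTCFSite] | None
    outermost: tuple[CTCFSite, CTCFSite] | None = None
    elements: list[dict] = field(default_factory=list)

    @property
    def found(self) -> bool:
        return self.boundaries is not None

    def contains(self, position: int) -> bool:
        """Strict containment: boundary positions themselves are outside."""
        if self.boundaries is None:
            return False
        lo, hi = self.boundaries
        return lo.position < position < hi.position


def define_neighborhood(
    sites: Sequence[CTCFSite], anchor_position: int
) -> NeighborhoodModel:
    """Insulated neighborhood around an anchor (e.g. the fusion promoter).

    The neighborhood is the smallest-span convergent pair that strictly
    spans the anchor; the outermost spanning pair (the TAD boundary
    candidate) is reported alongside. If no permissive pair spans the
    anchor the result is an explicit "no neighborhood", not an exception.
    """
    spanning = [
        (a, b)
        for a, b in convergent_pairs(sites)
        if a.position < anchor_position < b.position
    ]
    if not spanning:
        return NeighborhoodModel(boundaries=None)
    outer = max(spanning, key=lambda p: p[1].position - p[0].position)
    return NeighborhoodModel(boundaries=spanning[0], outermost=outer)


def classify_elements(
    neighborhood: NeighborhoodModel, elements: Sequence[LocusFeature]
) -> list[dict]:
    """Flag each regulatory element intra-TAD vs outside the neighborhood.

    The composite ``class_label`` (e.g. ``intra_tad_se`` /
    ``outside_tad_se``) feeds the CRISPR dropout class comparison.
    """
    if not neighborhood.found:
        raise NeoTadError("neighborhood undefined; cannot classify elements")
    out = []
    for el in elements:
        if el.position is None:
            raise NeoTadError(f"element {el.label!r} lacks coordinates")
        intra = neighborhood.contains(el.position)
        kind = el.kind.lower().replace(" ", "_")
        if kind in ("se", "super_enhancer"):
            label = "intra_tad_se" if intra else "outside_tad_se"
        else:
            label = kind
        out.append(
            {
                "label": el.label,
                "position": el.position,
                "kind": el.kind,
                "intra_tad": intra,
                "class_label": label,
            }
        )
    neighborhood.elements = out
    return out
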
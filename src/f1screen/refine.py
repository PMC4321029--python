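"""Submapping of modifier hotspots with smaller overlapping deletions.

A deficiency isolated as a modifier in the primary screen delimits a hotspot
only coarsely.  Retesting smaller deletions that overlap it refines the
critical interval:

* Subs sharing the parent's class localise the modifier; under the parsimony
  assumption that one shared gene explains them all, the refined interval is
  the intersection of the maximal extents of the parent and every same-class
  sub.
* Nonmodifier subs exonerate the bands they certainly delete, which are
  subtracted.  Because breakpoint bands are themselves uncertain, only the
  open interior of a sub's minimal extent is removed (see
  :meth:`f1screen.cytoband.BandRange.subtract`).
* Subs of the opposite class reveal a second, independent modifier; its
  interval (the opposite subs' shared extent clipped to the parent) is
  reported under its own class, and is excluded from the parent-class region
  when the parent's evidence is only the coarse deletion itself.

Each sub receives a comment code — 1 same class (interval reduced), 2
nonmodifier (critical segment lies outside), 3 opposite class — and the case
carries the set; the scalar ``comment_code`` gives opposite-class findings
precedence (3), then reduction (1), then exclusion (2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .cytoband import BandRange, DeficiencyInterval, overlaps
from .screen import ENHANCER, NONMODIFIER, SUPPRESSOR

__all__ = [
    "GeneAnnotation",
    "SubmapResult",
    "refine_hotspot",
    "candidate_genes",
    "gene_class_filter",
]

logger = logging.getLogger(__name__)

_OPPOSITE = {SUPPRESSOR: ENHANCER, ENHANCER: SUPPRESSOR}


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene symbol placed on a cytogenetic band interval."""

    symbol: str
    location: BandRange
    biotype: str = "gene"


@dataclass(frozen=True)
class SubmapResult:
    """Outcome of refining one parent deficiency."""

    parent: DeficiencyInterval
    parent_class: str
    subs: Tuple[Tuple[DeficiencyInterval, str], ...]
    comment_code: int
    comment_codes: Tuple[int, ...]  # per-sub, in input order
    refined: Tuple[Tuple[BandRange, str], ...]  # (interval, supported class)

    def refined_for(self, klass: str) -> List[BandRange]:
        return [r for r, c in self.refined if c == klass]


def _interior_subtract(
    pieces: Sequence[BandRange], cut: Optional[BandRange]
) -> List[BandRange]:
    if cut is None:
        return list(pieces)
    out: List[BandRange] = []
    for piece in pieces:
        out.extend(piece.subtract(cut))
    return out


def refine_hotspot(
    parent: DeficiencyInterval,
    parent_class: str,
    subs: Sequence[Tuple[DeficiencyInterval, str]],
) -> SubmapResult:
    """Combine a classified parent deficiency with classified sub-deletions.

    ``parent_class`` must be ``"suppressor"`` or ``"enhancer"``; a sub that
    does not overlap the parent is kept (it still carries information about
    flanking bands) but logged as a warning.
    """
    if parent_class not in _OPPOSITE:
        raise ValueError(
            f"{parent.name}: nothing to refine, parent classified {parent_class!r}"
        )
    opposite_class = _OPPOSITE[parent_class]
    codes: List[int] = []
    same: List[DeficiencyInterval] = []
    nonmod: List[DeficiencyInterval] = []
    opposite: List[DeficiencyInterval] = []
    for sub, klass in subs:
        if not overlaps(parent, sub):
            logger.warning("%s: sub %s does not overlap the parent", parent.name, sub.name)
        if klass == parent_class:
            same.append(sub)
            codes.append(1)
        elif klass == NONMODIFIER:
            nonmod.append(sub)
            codes.append(2)
        elif klass == opposite_class:
            opposite.append(sub)
            codes.append(3)
        else:
            raise ValueError(f"{sub.name}: unknown classification {klass!r}")

    # parent-class region: intersection of all same-class deletions ...
    core: Optional[BandRange] = parent.maximal
    for sub in same:
        core = core.intersect(sub.maximal) if core is not None else None
    pieces = [core] if core is not None else []
    # ... minus bands certainly deleted by nonmodifiers
    for sub in nonmod:
        pieces = _interior_subtract(pieces, sub.minimal)
    # a same-class sub is direct evidence; only the bare parent deletion is
    # coarse enough to cede territory to an opposite-class sub
    if not same:
        for sub in opposite:
            pieces = _interior_subtract(pieces, sub.maximal)
    refined: List[Tuple[BandRange, str]] = [(p, parent_class) for p in pieces]

    if opposite:
        opp_core: Optional[BandRange] = parent.maximal
        for sub in opposite:
            opp_core = opp_core.intersect(sub.maximal) if opp_core is not None else None
        opp_pieces = [opp_core] if opp_core is not None else []
        for sub in same:
            opp_pieces = _interior_subtract(opp_pieces, sub.maximal)
        for sub in nonmod:
            opp_pieces = _interior_subtract(opp_pieces, sub.minimal)
        refined.extend((p, opposite_class) for p in opp_pieces)

    if opposite:
        comment_code = 3
    elif same:
        comment_code = 1
    else:
        comment_code = 2
    return SubmapResult(
        parent=parent,
        parent_class=parent_class,
        subs=tuple(subs),
        comment_code=comment_code,
        comment_codes=tuple(codes),
        refined=tuple(refined),
    )


def candidate_genes(
    ranges: Sequence[BandRange], annotation: Sequence[GeneAnnotation]
) -> List[str]:
    """Symbols whose interval intersects any refined range.

    Membership is by intersection rather than containment, so genes sitting
    on an interval edge are included.  Output preserves annotation order and
    is deduplicated.
    """
    out: List[str] = []
    seen = set()
    for ann in annotation:
        if ann.symbol in seen:
            continue
        if any(
            ann.location.chromosome == r.chromosome and ann.location.overlaps(r)
            for r in ranges
        ):
            out.append(ann.symbol)
            seen.add(ann.symbol)
    return out


def gene_class_filter(
    symbols: Sequence[str],
    annotation: Sequence[GeneAnnotation],
    exclude_biotypes: Sequence[str] = (),
) -> List[str]:
    """Drop symbols whose annotated biotype is excluded (e.g. ``miRNA``)."""
    excluded = set(exclude_biotypes)
    biotype = {}
    for ann in annotation:
        biotype.setdefault(ann.symbol, ann.biotype)
    return [s for s in symbols if biotype.get(s, "gene") not in excluded]
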
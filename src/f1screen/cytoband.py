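"""Drosophila polytene cytogenetic band coordinates and deletion intervals.

The polytene map addresses a position on an autosome as
``division`` (21-60 on chromosome 2, 61-100 on chromosome 3), an optional
subdivision ``letter`` (A-F) and an optional numbered ``band`` within the
subdivision, e.g. ``46C7``.  Deficiency (deletion) stocks are published with
two breakpoints, each of which may itself be uncertain — either a span of
candidate bands (``49C1-4``) or a bare subdivision (``46C``).  This module
parses that notation, imposes a total order on same-chromosome positions, and
provides the interval algebra (overlap, intersection, subtraction) used to
submap modifier hotspots.

Two conventions matter throughout:

* A letter-only endpoint means "somewhere in this subdivision".  The true
  number of numbered bands per subdivision is map-dependent, so instead of
  fabricating a terminal band number the endpoint is expanded to a half-open
  whole-subdivision span (a *start* edge sorting before band 1, an *end* edge
  sorting after every numbered band of the subdivision).
* Breakpoint bands are uncertain positions, so interval subtraction removes
  only the *open interior* of the subtracted range: the boundary bands, where
  the breakpoints sit, are retained, and a flanking piece is emitted only when
  the cut falls strictly inside the minuend.  A range minus itself is empty.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import List, Optional

__all__ = [
    "CytoBand",
    "BandRange",
    "DeficiencyInterval",
    "BandParseError",
    "parse_band",
    "parse_breakpoint_range",
    "parse_deficiency",
    "band_le",
    "band_lt",
    "overlaps",
    "intersect",
    "subtract",
]

#: inclusive division spans of the four autosome arms
ARMS = {"2L": (21, 40), "2R": (41, 60), "3L": (61, 80), "3R": (81, 100)}
_LETTERS = "ABCDEF"


class BandParseError(ValueError):
    """Raised when a cytogenetic token cannot be interpreted."""


def _arm_of_division(division: int) -> str:
    for arm, (lo, hi) in ARMS.items():
        if lo <= division <= hi:
            return arm
    raise BandParseError(
        f"division {division} outside the autosomal map (21-100)"
    )


@dataclass(frozen=True)
class CytoBand:
    """A position on the polytene map.

    ``end`` marks the synthetic end-edge of a letterless/bandless token
    produced by subdivision expansion; it never arises from parsing and
    formats identically to the plain token.
    """

    division: int
    letter: Optional[str] = None
    band: Optional[int] = None
    telomere: bool = False
    end: bool = field(default=False, compare=True)

    def __post_init__(self) -> None:
        if not 21 <= self.division <= 100:
            raise BandParseError(
                f"division {self.division} outside the autosomal map (21-100);"
                " X and 4th chromosome positions are not supported"
            )
        if self.letter is not None and self.letter not in _LETTERS:
            raise BandParseError(f"subdivision letter {self.letter!r} outside A-F")
        if self.band is not None:
            if self.letter is None:
                raise BandParseError("band number requires a subdivision letter")
            if self.band < 1:
                raise BandParseError(f"band number must be >= 1, got {self.band}")

    # -- derived coordinates -------------------------------------------------
    @property
    def arm(self) -> str:
        return _arm_of_division(self.division)

    @property
    def chromosome(self) -> int:
        return 2 if self.division <= 60 else 3

    def sort_key(self) -> tuple:
        """Total-order key within a chromosome.

        Absent components are treated as the start of their span (or the end
        when ``end`` is set); a telomere sentinel outranks every concrete
        band on its arm.
        """
        if self.telomere:
            return (self.division, 7, math.inf)
        if self.letter is None:
            letter_rank: float = 6 if self.end else -1
        else:
            letter_rank = _LETTERS.index(self.letter)
        if self.band is None:
            band_rank: float = math.inf if self.end else -1
        else:
            band_rank = self.band
        return (self.division, letter_rank, band_rank)

    def end_edge(self) -> "CytoBand":
        """The end-of-span edge for a token lacking a band number."""
        if self.band is not None or self.telomere:
            return self
        return replace(self, end=True)

    def __str__(self) -> str:
        if self.telomere:
            return f"{self.arm}t"
        return f"{self.division}{self.letter or ''}{self.band if self.band is not None else ''}"


def _check_same_chromosome(a: CytoBand, b: CytoBand, what: str = "compare") -> None:
    if a.chromosome != b.chromosome:
        raise ValueError(
            f"cannot {what} bands on different chromosomes: {a} vs {b}"
        )


def band_lt(a: CytoBand, b: CytoBand) -> bool:
    _check_same_chromosome(a, b)
    return a.sort_key() < b.sort_key()


def band_le(a: CytoBand, b: CytoBand) -> bool:
    """Total order on same-chromosome bands; cross-chromosome is an error."""
    _check_same_chromosome(a, b)
    return a.sort_key() <= b.sort_key()


def _band_min(a: CytoBand, b: CytoBand) -> CytoBand:
    return a if band_le(a, b) else b


def _band_max(a: CytoBand, b: CytoBand) -> CytoBand:
    return b if band_le(a, b) else a


# -- parsing -----------------------------------------------------------------

_BAND_RE = re.compile(r"^(\d{2,3})([A-F])?(\d+)?$")
_TELOMERE_RE = re.compile(r"^([23])([LR])t$")
_TWO_LETTER_RE = re.compile(r"^(\d{2,3})([A-F])([A-F])(\d+)?$")


def parse_band(text: str) -> CytoBand:
    """Parse a single band token such as ``46C7``, ``61A`` or ``3Rt``."""
    token = text.strip()
    m = _TELOMERE_RE.match(token)
    if m:
        arm = m.group(1) + m.group(2)
        return CytoBand(division=ARMS[arm][1], telomere=True)
    m = _BAND_RE.match(token)
    if not m:
        raise BandParseError(f"malformed band token {text!r}")
    division = int(m.group(1))
    letter = m.group(2)
    band = int(m.group(3)) if m.group(3) else None
    if band is not None and letter is None:
        raise BandParseError(f"malformed band token {text!r}")
    return CytoBand(division=division, letter=letter, band=band)


@dataclass(frozen=True)
class BandRange:
    """A closed span of bands, both endpoints on the same chromosome."""

    lo: CytoBand
    hi: CytoBand

    def __post_init__(self) -> None:
        _check_same_chromosome(self.lo, self.hi, "span")
        if not band_le(self.lo, self.hi):
            raise BandParseError(f"descending range {self.lo}-{self.hi}")

    @property
    def chromosome(self) -> int:
        return self.lo.chromosome

    def overlaps(self, other: "BandRange") -> bool:
        if self.chromosome != other.chromosome:
            return False
        return band_le(self.lo, other.hi) and band_le(other.lo, self.hi)

    def intersect(self, other: "BandRange") -> Optional["BandRange"]:
        if not self.overlaps(other):
            return None
        return BandRange(_band_max(self.lo, other.lo), _band_min(self.hi, other.hi))

    def subtract(self, other: "BandRange") -> List["BandRange"]:
        """Remove the open interior of ``other``; boundary bands survive.

        Pieces are emitted proximal to distal, and only where the cut falls
        strictly inside ``self`` — so subtracting a range from itself leaves
        nothing, while an interior cut leaves two flanking pieces that still
        carry the (uncertain) boundary bands.
        """
        if not self.overlaps(other):
            return [self]
        pieces: List[BandRange] = []
        if band_lt(self.lo, other.lo):
            pieces.append(BandRange(self.lo, _band_min(other.lo, self.hi)))
        if band_lt(other.hi, self.hi):
            pieces.append(BandRange(_band_max(other.hi, self.lo), self.hi))
        return pieces

    def __str__(self) -> str:
        if self.lo == self.hi:
            return str(self.lo)
        return f"{self.lo}-{self.hi}"


def _inherit(left: CytoBand, right_text: str) -> CytoBand:
    """Resolve the right endpoint of ``left-right``, inheriting omitted parts."""
    token = right_text.strip()
    if left.letter is not None and re.fullmatch(r"\d+", token):
        # bare band number inherits division+letter, e.g. 49C1-4, 50C19-23
        return CytoBand(division=left.division, letter=left.letter, band=int(token))
    m = re.fullmatch(r"([A-F])(\d+)?", token)
    if m:  # letter(+band) inherits the division, e.g. 50C23-D2, 85E7-F1
        return CytoBand(
            division=left.division,
            letter=m.group(1),
            band=int(m.group(2)) if m.group(2) else None,
        )
    return parse_band(token)  # fully qualified, e.g. 46C9-46C11


def parse_breakpoint_range(text: str) -> BandRange:
    """Parse one (possibly uncertain) breakpoint: ``46C7`` or ``49C1-4``.

    The right endpoint of a hyphenated span may omit the division and/or
    letter shared with the left endpoint.  A two-letter token such as
    ``45DE3`` denotes uncertainty between adjacent subdivisions and resolves
    to ``45D-45E3``.
    """
    token = text.strip().replace(" ", "")
    m = _TWO_LETTER_RE.match(token)
    if m:
        division = int(m.group(1))
        lo = CytoBand(division=division, letter=m.group(2))
        hi = CytoBand(
            division=division,
            letter=m.group(3),
            band=int(m.group(4)) if m.group(4) else None,
        )
        return BandRange(lo, hi)
    if "-" in token:
        left_text, right_text = token.split("-", 1)
        lo = parse_band(left_text)
        hi = _inherit(lo, right_text)
        return BandRange(lo, hi)  # raises on descending input
    b = parse_band(token)
    return BandRange(b, b)


@dataclass(frozen=True)
class DeficiencyInterval:
    """A named deletion with uncertain proximal and distal breakpoints.

    The *maximal* extent (everything possibly deleted) runs from the earliest
    proximal candidate to the latest distal candidate; the *minimal* extent
    (everything certainly spanned) runs from the latest proximal candidate to
    the earliest distal one and may be empty for degenerate deletions such as
    ``41A;41A``.
    """

    name: str
    proximal: BandRange
    distal: BandRange

    def __post_init__(self) -> None:
        _check_same_chromosome(self.proximal.lo, self.distal.hi, "span")
        if not band_le(self.proximal.lo, self.distal.hi):
            raise BandParseError(
                f"{self.name}: descending interval "
                f"{self.proximal}-{self.distal}"
            )

    @property
    def maximal(self) -> BandRange:
        return BandRange(self.proximal.lo, self.distal.hi)

    @property
    def minimal(self) -> Optional[BandRange]:
        if band_le(self.proximal.hi, self.distal.lo):
            return BandRange(self.proximal.hi, self.distal.lo)
        return None

    def __str__(self) -> str:
        return f"{self.name} {self.proximal};{self.distal}"


def _expand_subdivision(r: BandRange) -> BandRange:
    """Widen a bandless endpoint to its whole-subdivision (or -division) span."""
    lo, hi = r.lo, r.hi
    if hi.band is None and not hi.telomere:
        hi = hi.end_edge()
    return BandRange(lo, hi)


def parse_deficiency(name: str, breakpoints: str) -> DeficiencyInterval:
    """Parse a published breakpoint pair, e.g. ``("Df(2R)X1", "46C;47A1")``.

    The two breakpoints are separated by ``;`` (a few lines print ``,`` or a
    bare ``-`` instead, which are accepted).  Letter-only tokens expand to the
    containing subdivision span.
    """
    text = breakpoints.strip()
    for sep in (";", ","):
        if sep in text:
            prox_text, dist_text = text.split(sep, 1)
            break
    else:
        # single-hyphen whole-interval style, e.g. "27B2-27F2"
        parts = text.split("-")
        if len(parts) != 2:
            raise BandParseError(
                f"{name}: expected 'PROXIMAL;DISTAL' breakpoints, got {breakpoints!r}"
            )
        prox_text, dist_text = parts
    proximal = _expand_subdivision(parse_breakpoint_range(prox_text))
    distal = _expand_subdivision(parse_breakpoint_range(dist_text))
    return DeficiencyInterval(name=name, proximal=proximal, distal=distal)


# -- module-level interval algebra on deficiencies ---------------------------

def overlaps(d1: DeficiencyInterval, d2: DeficiencyInterval) -> bool:
    """True iff the maximal extents intersect; cross-chromosome is False."""
    return d1.maximal.overlaps(d2.maximal)


def intersect(d1: DeficiencyInterval, d2: DeficiencyInterval) -> Optional[BandRange]:
    """Shared span of the maximal extents, or None when disjoint."""
    if d1.maximal.chromosome != d2.maximal.chromosome:
        return None
    return d1.maximal.intersect(d2.maximal)


def subtract(d1: BandRange, d2: BandRange) -> List[BandRange]:
    """Interior subtraction of band ranges (see :meth:`BandRange.subtract`)."""
    return d1.subtract(d2)
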
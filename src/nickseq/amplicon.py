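"""Amplicon coordinate model: reference, CRISPR target site, and scoring windows.

All coordinates are 0-based, half-open intervals on the top strand of the
amplicon.  A cut-site coordinate ``cut`` names the phosphodiester bond
between reference positions ``cut - 1`` and ``cut``; this convention is
unambiguous for nicks on either strand and for placing insertions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

__all__ = [
    "AmpliconSpec",
    "TargetSite",
    "ScoringWindow",
    "TargetNotFoundError",
    "AmbiguousTargetError",
    "revcomp",
    "locate_cut_site",
    "scoring_window",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Distance (nt) from the PAM-proximal end of the protospacer to the
#: scissile bond for Cas9 and Cas9 D10A (blunt-cut model).
CAS9_CUT_OFFSET_FROM_PAM = 3


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class TargetNotFoundError(ValueError):
    """Protospacer + PAM not present on the requested strand."""


class AmbiguousTargetError(ValueError):
    """Protospacer + PAM occurs more than once on the requested strand."""


@dataclass(frozen=True)
class AmpliconSpec:
    """A single amplicon reference sequence.

    Attributes
    ----------
    name:
        Identifier used in tabular/VCF output.
    sequence:
        Top-strand sequence, uppercase A/C/G/T.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("amplicon sequence must be non-empty")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"amplicon sequence contains non-ACGT symbols: {sorted(bad)}")

    @property
    def length(self) -> int:
        """Amplicon size G in bases."""
        return len(self.sequence)


@dataclass(frozen=True)
class TargetSite:
    """A CRISPR target on the amplicon.

    ``cut`` is the top-strand bond coordinate of the (blunt-model) scissile
    bond: the backbone between positions ``cut - 1`` and ``cut``.  ``mode``
    records whether the enzyme nicks the top strand, nicks the bottom
    strand, or makes a double-strand break.
    """

    protospacer: str
    pam: str
    strand: str  # "top" | "bottom": strand carrying the protospacer
    cut: int
    mode: str = "nick_top"  # "nick_top" | "nick_bottom" | "dsb"

    def __post_init__(self) -> None:
        if self.strand not in ("top", "bottom"):
            raise ValueError(f"strand must be 'top' or 'bottom', got {self.strand!r}")
        if self.mode not in ("nick_top", "nick_bottom", "dsb"):
            raise ValueError(f"invalid mode {self.mode!r}")


@dataclass(frozen=True)
class ScoringWindow:
    """Half-open interval [start, end) on the amplicon in which events are scored."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("window start must be < end")

    @property
    def width(self) -> int:
        return self.end - self.start

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end


def locate_cut_site(
    amplicon: AmpliconSpec,
    protospacer: str,
    pam: str,
    strand: str = "top",
    mode: str = "nick_top",
) -> TargetSite:
    """Locate a protospacer+PAM on the amplicon and compute the cut coordinate.

    The cut is placed 3 nt 5' of the PAM on the protospacer (the blunt Cas9
    model) and reported in top-strand coordinates regardless of the target
    strand.  For a top-strand target ``protospacer + pam`` must occur on the
    top strand; for a bottom-strand target the search looks for
    ``revcomp(pam) + revcomp(protospacer)`` on the top strand.

    Raises
    ------
    TargetNotFoundError
        If the target does not occur on the requested strand.
    AmbiguousTargetError
        If it occurs more than once.
    """
    protospacer = protospacer.upper()
    pam = pam.upper()
    if len(protospacer) != 20:
        raise ValueError(f"protospacer must be 20 nt, got {len(protospacer)}")
    if len(pam) != 3:
        raise ValueError(f"PAM must be 3 nt, got {len(pam)}")
    if strand not in ("top", "bottom"):
        raise ValueError(f"strand must be 'top' or 'bottom', got {strand!r}")

    if strand == "top":
        needle = protospacer + pam
    else:
        needle = revcomp(pam) + revcomp(protospacer)

    hits = _find_all(amplicon.sequence, needle)
    if not hits:
        raise TargetNotFoundError(
            f"protospacer+PAM not found on {strand} strand of amplicon {amplicon.name!r}"
        )
    if len(hits) > 1:
        raise AmbiguousTargetError(
            f"protospacer+PAM occurs {len(hits)} times on {strand} strand "
            f"of amplicon {amplicon.name!r}"
        )
    start = hits[0]
    if strand == "top":
        # protospacer at [start, start+20), PAM at [start+20, start+23);
        # cut 3 nt 5' of the PAM: bond between start+16 and start+17.
        cut = start + len(protospacer) - CAS9_CUT_OFFSET_FROM_PAM
    else:
        # top strand carries revcomp(pam) at [start, start+3) then
        # revcomp(protospacer); 3 nt from the PAM along the bottom strand
        # maps to the bond between start+5 and start+6 on the top strand.
        cut = start + len(pam) + CAS9_CUT_OFFSET_FROM_PAM
    if not 0 < cut < amplicon.length:
        raise ValueError(f"cut coordinate {cut} falls on the amplicon boundary")
    return TargetSite(protospacer=protospacer, pam=pam, strand=strand, cut=cut, mode=mode)


def scoring_window(site: TargetSite, width: int, amplicon: AmpliconSpec) -> ScoringWindow:
    """Window of ``width`` bases centred on the cut, clipped to the amplicon.

    The interval is ``[cut - width//2, cut - width//2 + width)``: an even
    width splits evenly across the cut bond; an odd width places the extra
    base 3' of the cut.  If the window would overhang the amplicon it is
    clipped and a warning is logged.
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    start = site.cut - width // 2
    end = start + width
    if start < 0 or end > amplicon.length:
        logger.warning(
            "scoring window [%d, %d) clipped to amplicon [0, %d)", start, end, amplicon.length
        )
        start = max(start, 0)
        end = min(end, amplicon.length)
    return ScoringWindow(start=start, end=end)


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits
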
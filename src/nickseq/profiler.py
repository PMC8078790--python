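"""Library-level report surface.

Aggregates per-molecule calls into the quantities reported for nick/DSB
amplicon libraries: background-subtracted per-category frequencies,
per-position fractional base-loss maps and SNV spectra, deletion and
insertion length histograms (fine 1-6 bp bins and decade bins), 1 bp
insertion composition around the cut, a signed asymmetry index of the
mutation distribution, dual-site partitioning of molecules between two
target windows, reference-normalised SNV frequencies, and the
``N * L / G`` fold-coverage of the library.

Conventions
-----------
* The denominator of every frequency is the number of consensus molecules
  passing the window-coverage and concordance rules, not raw reads.
* A molecule counts once toward each category it carries (a molecule with
  a deletion and an SNV contributes to both frequencies); event-level
  counting is available via ``count='events'``.
* Background subtraction applies to aggregate category frequencies only
  and is floored at zero; per-position maps are reported raw.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .amplicon import AmpliconSpec, ScoringWindow, TargetSite
from .calling import MoleculeCall

__all__ = [
    "ConditionSummary",
    "PositionProfile",
    "LengthHistogram",
    "InsertionComposition",
    "CoverageInputs",
    "NormalizationError",
    "condition_summary",
    "fractional_decrease_map",
    "snv_spectrum_map",
    "deletion_length_histogram",
    "insertion_length_histogram",
    "insertion_composition",
    "asymmetry_index",
    "asymmetry_bootstrap_ci",
    "dual_site_partition",
    "normalize_snv_frequencies",
    "coverage",
    "fold_change",
    "is_transversion",
]

logger = logging.getLogger(__name__)

_PURINES = frozenset("AG")

CATEGORIES = ("deletion", "insertion", "snv")


def is_transversion(ref_base: str, alt_base: str) -> bool:
    """Purine <-> pyrimidine change."""
    return (ref_base in _PURINES) != (alt_base in _PURINES)


class NormalizationError(ValueError):
    """Reference frequency at or below background: normalisation undefined."""


@dataclass(frozen=True)
class ConditionSummary:
    n_molecules: int
    freq_deletion: float
    freq_insertion: float
    freq_snv: float
    freq_hdr: float
    freq_mutant: float
    background: dict
    subtracted: dict  # per-category, floored at 0; key "mutant" uses summed background
    transversion_fraction: float  # NaN when no SNV events

    def as_dict(self) -> dict:
        return {
            "n_molecules": self.n_molecules,
            "freq_deletion": self.freq_deletion,
            "freq_insertion": self.freq_insertion,
            "freq_snv": self.freq_snv,
            "freq_hdr": self.freq_hdr,
            "freq_mutant": self.freq_mutant,
            "background": dict(self.background),
            "subtracted": dict(self.subtracted),
            "transversion_fraction": self.transversion_fraction,
        }


def condition_summary(
    calls: list[MoleculeCall],
    background: dict | None = None,
    count: str = "molecules",
) -> ConditionSummary:
    """Per-category frequencies with floored background subtraction.

    ``background`` maps category -> fraction (missing categories default to
    0).  ``count='molecules'`` (default) counts each molecule once per
    category it carries; ``count='events'`` divides event counts by the
    molecule denominator instead.
    """
    background = {c: float((background or {}).get(c, 0.0)) for c in CATEGORIES}
    passing = [c for c in calls if c.passes]
    n = len(passing)
    if n == 0:
        raise ValueError("no passing molecules: cannot summarise an empty call set")

    if count == "molecules":
        n_del = sum(c.has_deletion for c in passing)
        n_ins = sum(c.has_insertion for c in passing)
        n_snv = sum(c.has_snv for c in passing)
    elif count == "events":
        n_del = sum(sum(e.kind == "deletion" for e in c.events) for c in passing)
        n_ins = sum(sum(e.kind == "insertion" for e in c.events) for c in passing)
        n_snv = sum(sum(e.kind == "snv" for e in c.events) for c in passing)
    else:
        raise ValueError(f"count must be 'molecules' or 'events', got {count!r}")

    n_hdr = sum(c.is_hdr for c in passing)
    n_mut = sum(c.is_mutant for c in passing)

    freqs = {
        "deletion": n_del / n,
        "insertion": n_ins / n,
        "snv": n_snv / n,
    }
    subtracted = {c: max(0.0, freqs[c] - background[c]) for c in CATEGORIES}
    subtracted["mutant"] = max(0.0, n_mut / n - sum(background.values()))

    tv = tr = 0
    for c in passing:
        for e in c.events:
            if e.kind == "snv":
                if is_transversion(e.ref_base, e.alt_base):
                    tv += 1
                else:
                    tr += 1
    tvf = tv / (tv + tr) if (tv + tr) else float("nan")

    return ConditionSummary(
        n_molecules=n,
        freq_deletion=freqs["deletion"],
        freq_insertion=freqs["insertion"],
        freq_snv=freqs["snv"],
        freq_hdr=n_hdr / n,
        freq_mutant=n_mut / n,
        background=background,
        subtracted=subtracted,
        transversion_fraction=tvf,
    )


@dataclass
class PositionProfile:
    """Per-position map over the scoring window.

    ``covering[i]`` is the molecule denominator at window position i,
    ``deleted[i]`` the number whose deletion footprint includes it, and
    ``alt_counts[i, j]`` the confirmed-SNV count for alt base "ACGT"[j].
    """

    window: ScoringWindow
    ref: str
    covering: np.ndarray
    deleted: np.ndarray
    alt_counts: np.ndarray  # (width, 4), columns A C G T

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.window.start, self.window.end)

    @property
    def frac_lost(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.covering > 0, self.deleted / np.maximum(self.covering, 1), 0.0)

    @property
    def snv_counts(self) -> np.ndarray:
        return self.alt_counts.sum(axis=1)


def _build_profile(
    calls: list[MoleculeCall], window: ScoringWindow, amplicon: AmpliconSpec
) -> PositionProfile:
    width = window.width
    passing = [c for c in calls if c.passes]
    covering = np.full(width, len(passing), dtype=np.int64)
    deleted = np.zeros(width, dtype=np.int64)
    alt_counts = np.zeros((width, 4), dtype=np.int64)
    base_index = {b: i for i, b in enumerate("ACGT")}
    for c in passing:
        for e in c.events:
            if e.kind == "deletion":
                lo = max(e.start, window.start) - window.start
                hi = min(e.start + e.length, window.end) - window.start
                if hi > lo:
                    deleted[lo:hi] += 1
            elif e.kind == "snv" and e.start in window:
                alt_counts[e.start - window.start, base_index[e.alt_base]] += 1
    return PositionProfile(
        window=window,
        ref=amplicon.sequence[window.start : window.end],
        covering=covering,
        deleted=deleted,
        alt_counts=alt_counts,
    )


def fractional_decrease_map(
    calls: list[MoleculeCall], window: ScoringWindow, amplicon: AmpliconSpec
) -> PositionProfile:
    """Per-position fraction of molecules whose deletion footprint includes the
    position — the deletion-footprint map."""
    return _build_profile(calls, window, amplicon)


def snv_spectrum_map(
    calls: list[MoleculeCall], window: ScoringWindow, amplicon: AmpliconSpec
) -> PositionProfile:
    """Per-position counts of each alternative base among confirmed SNVs."""
    return _build_profile(calls, window, amplicon)


@dataclass(frozen=True)
class LengthHistogram:
    fine: dict  # length 1..6 -> count
    decades: dict  # (lo, hi) inclusive bp bin, e.g. (1, 10) -> count
    max_length: int

    @property
    def total(self) -> int:
        return sum(self.decades.values())


def _length_histogram(lengths: list[int]) -> LengthHistogram:
    fine = {l: 0 for l in range(1, 7)}
    decades: dict[tuple[int, int], int] = {}
    for l in lengths:
        if 1 <= l <= 6:
            fine[l] += 1
        lo = ((l - 1) // 10) * 10 + 1
        decades[(lo, lo + 9)] = decades.get((lo, lo + 9), 0) + 1
    return LengthHistogram(fine=fine, decades=dict(sorted(decades.items())),
                           max_length=max(lengths, default=0))


def deletion_length_histogram(calls: list[MoleculeCall]) -> LengthHistogram:
    lengths = [e.length for c in calls if c.passes for e in c.events if e.kind == "deletion"]
    return _length_histogram(lengths)


def insertion_length_histogram(calls: list[MoleculeCall]) -> LengthHistogram:
    lengths = [len(e.inserted) for c in calls if c.passes for e in c.events if e.kind == "insertion"]
    return _length_histogram(lengths)


@dataclass(frozen=True)
class InsertionComposition:
    """Composition of 1 bp insertions near the cut.

    ``base_counts``: identity of the inserted base among all 1 bp
    insertions.  ``flank_counts``: for molecules whose 1 bp insertion's
    ambiguity span touches the 4 bp region spanning the cut, the base
    observed in the *edited* molecule at positions -2, -1, +1, +2 relative
    to the cut bond (an insertion sitting in the bond itself occupies +1).
    """

    base_counts: dict
    flank_counts: dict  # label -> {base -> count}


def insertion_composition(
    calls: list[MoleculeCall], site: TargetSite, amplicon: AmpliconSpec
) -> InsertionComposition:
    cut = site.cut
    ref = amplicon.sequence
    base_counts: Counter = Counter()
    flank: dict[str, Counter] = {lab: Counter() for lab in ("-2", "-1", "+1", "+2")}
    for c in calls:
        if not c.passes:
            continue
        for e in c.events:
            if e.kind != "insertion" or len(e.inserted) != 1:
                continue
            base_counts[e.inserted] += 1
            amb_lo = e.amb_start if e.amb_start >= 0 else e.start
            amb_hi = e.amb_end if e.amb_end >= 0 else e.start
            if amb_hi < cut - 2 or amb_lo > cut + 2:
                continue
            # place the insertion at its equivalent position nearest the cut
            s = min(max(cut, amb_lo), amb_hi)
            edited = ref[:s] + e.inserted + ref[s:]
            nick_e = cut + (1 if s < cut else 0)
            quad = edited[nick_e - 2 : nick_e + 2]
            if len(quad) == 4:
                for lab, b in zip(("-2", "-1", "+1", "+2"), quad):
                    flank[lab][b] += 1
    return InsertionComposition(
        base_counts=dict(base_counts),
        flank_counts={lab: dict(cnt) for lab, cnt in flank.items()},
    )


def asymmetry_index(profile: PositionProfile, cut: int, mass: str = "lost") -> float:
    """Signed asymmetry A = (M3 - M5) / (M3 + M5) of per-position mass.

    ``mass='lost'`` uses deleted-base counts, ``'snv'`` the SNV counts.
    Positions < cut are 5' of the bond, positions >= cut are 3'.  Returns
    0.0 (with a warning) when both sides carry no mass.
    """
    values = profile.deleted if mass == "lost" else profile.snv_counts
    side3 = profile.positions >= cut
    m3 = float(values[side3].sum())
    m5 = float(values[~side3].sum())
    if m3 + m5 == 0:
        logger.warning("asymmetry index undefined on an empty profile; returning 0")
        return 0.0
    return (m3 - m5) / (m3 + m5)


def asymmetry_bootstrap_ci(
    calls: list[MoleculeCall],
    window: ScoringWindow,
    cut: int,
    n_boot: int = 1000,
    alpha: float = 0.01,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the deletion-mass asymmetry index,
    resampling molecules."""
    rng = rng if rng is not None else np.random.default_rng(0)
    passing = [c for c in calls if c.passes]
    m5 = np.zeros(len(passing))
    m3 = np.zeros(len(passing))
    for i, c in enumerate(passing):
        for e in c.events:
            if e.kind == "deletion":
                lo = max(e.start, window.start)
                hi = min(e.start + e.length, window.end)
                if hi > lo:
                    m5[i] += max(0, min(hi, cut) - lo)
                    m3[i] += max(0, hi - max(lo, cut))
    n = len(passing)
    idx = rng.integers(0, n, size=(n_boot, n))
    s5 = m5[idx].sum(axis=1)
    s3 = m3[idx].sum(axis=1)
    with np.errstate(invalid="ignore"):
        stats = np.where(s3 + s5 > 0, (s3 - s5) / np.maximum(s3 + s5, 1e-300), 0.0)
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def dual_site_partition(
    calls: list[MoleculeCall], window_a: ScoringWindow, window_b: ScoringWindow
) -> dict:
    """Partition mutant molecules by which target window holds their events.

    Windows must be disjoint.  An event whose footprint intersects both
    windows counts the molecule as ``both``; mutant molecules with no
    event in either window are ``neither``.
    """
    if window_a.start < window_b.end and window_b.start < window_a.end:
        raise ValueError("dual-site windows must be disjoint")
    out = {"a_only": 0, "b_only": 0, "both": 0, "neither": 0}
    for c in calls:
        if not c.passes or not c.is_mutant:
            continue
        in_a = in_b = False
        for e in c.events:
            lo, hi = e.start, e.start + (e.length if e.kind == "deletion" else 0)
            hits_a = _intersects(lo, hi, window_a)
            hits_b = _intersects(lo, hi, window_b)
            in_a |= hits_a
            in_b |= hits_b
        if in_a and in_b:
            out["both"] += 1
        elif in_a:
            out["a_only"] += 1
        elif in_b:
            out["b_only"] += 1
        else:
            out["neither"] += 1
    return out


def _intersects(lo: int, hi: int, w: ScoringWindow) -> bool:
    if hi == lo:  # point event (SNV start or insertion bond)
        return w.start <= lo < w.end
    return lo < w.end and hi > w.start


def normalize_snv_frequencies(
    f_condition: float, f_reference: float, background_snv: float
) -> float:
    """(f_condition - b, floored at 0) / (f_reference - b).

    Raises :class:`NormalizationError` when the reference does not exceed
    the background."""
    den = f_reference - background_snv
    if den <= 0:
        raise NormalizationError(
            f"reference frequency {f_reference} at or below background {background_snv}"
        )
    return max(0.0, f_condition - background_snv) / den


@dataclass(frozen=True)
class CoverageInputs:
    """N aligned consensus reads of average length L over an amplicon of size G."""

    n_reads: float
    read_length: float
    amplicon_size: float

    def __post_init__(self) -> None:
        if min(self.n_reads, self.read_length, self.amplicon_size) <= 0:
            raise ValueError("coverage inputs must be positive")


def coverage(inputs: CoverageInputs) -> float:
    """Fold coverage N * L / G."""
    return inputs.n_reads * inputs.read_length / inputs.amplicon_size


def fold_change(numerator: float, denominator: float) -> float:
    if denominator <= 0:
        raise ValueError("fold change denominator must be positive")
    return numerator / denominator
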
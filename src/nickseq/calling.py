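"""Per-molecule variant calls from consensus mate pairs.

Each consensus mate is aligned independently to the amplicon (mate 2
after reverse complementing), events are extracted and left-normalised,
and the two mates' event lists are merged inside the scoring window:

* indels are accepted from either mate and deduplicated when both report
  the same normalised event; two *different* indels with overlapping
  footprints make the molecule discordant (excluded and counted);
* SNVs are, by default, kept only when both mates cover the position and
  report the identical alternative base — the dual-strand confirmation
  rule.  ``single`` mode takes the union instead; ``duplex`` mode defers
  confirmation to the partner (b, a) family and is applied at library
  level;
* SNVs inside an accepted deletion footprint are suppressed (those
  positions are unalignable);
* a molecule carrying exactly the configured donor replacement (and no
  other event inside the donor footprint) is classified as a-HDR, and its
  donor-matching substitutions are excluded from the SNV category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import (
    AlignmentResult,
    MutationEvent,
    ScoringScheme,
    extract_events,
    left_align_indels,
    semiglobal_align,
)
from .amplicon import AmpliconSpec, ScoringWindow, revcomp
from .consensus import ConsensusPair
from .simulate import DonorEdit

__all__ = [
    "CallRules",
    "MoleculeCall",
    "CallStats",
    "call_molecule",
    "classify_hdr",
    "call_library",
    "apply_duplex_confirmation",
]


@dataclass(frozen=True)
class CallRules:
    snv_confirmation: str = "mate_overlap"  # mate_overlap | single | duplex
    require_window_coverage: bool = True
    donor_edit: DonorEdit | None = None

    def __post_init__(self) -> None:
        if self.snv_confirmation not in ("mate_overlap", "single", "duplex"):
            raise ValueError(f"invalid snv_confirmation {self.snv_confirmation!r}")


@dataclass(frozen=True)
class MoleculeCall:
    key: tuple[str, str]
    family_size: int
    events: tuple[MutationEvent, ...]
    is_hdr: bool = False
    discordant: bool = False
    covers1: bool = True  # mate 1 covers the whole scoring window
    covers2: bool = True

    @property
    def passes(self) -> bool:
        """Included in frequency denominators."""
        return not self.discordant and self.covers1 and self.covers2

    @property
    def is_mutant(self) -> bool:
        return bool(self.events) or self.is_hdr

    @property
    def has_deletion(self) -> bool:
        return any(e.kind == "deletion" for e in self.events)

    @property
    def has_insertion(self) -> bool:
        return any(e.kind == "insertion" for e in self.events)

    @property
    def has_snv(self) -> bool:
        return any(e.kind == "snv" for e in self.events)


@dataclass
class CallStats:
    molecules: int = 0
    discordant: int = 0
    no_window_coverage: int = 0


def _in_window(ev: MutationEvent, window: ScoringWindow) -> bool:
    if ev.kind == "deletion":
        return ev.start < window.end and ev.start + ev.length > window.start
    return window.start <= ev.start < window.end


def _footprints_clash(a: MutationEvent, b: MutationEvent) -> bool:
    """True when two *different* indels occupy intersecting reference space."""
    a0, a1 = a.start, a.start + (a.length if a.kind == "deletion" else 0)
    b0, b1 = b.start, b.start + (b.length if b.kind == "deletion" else 0)
    return a0 <= b1 and b0 <= a1


def call_molecule(
    consensus: ConsensusPair,
    aln1: AlignmentResult,
    aln2: AlignmentResult,
    window: ScoringWindow,
    rules: CallRules,
    amplicon: AmpliconSpec,
) -> MoleculeCall:
    """Merge the two mates' normalised events into one molecule call.

    ``aln1``/``aln2`` are the alignments of consensus mate 1 and of the
    reverse complement of consensus mate 2 against the amplicon.
    """
    ref = amplicon.sequence
    ev1 = left_align_indels(extract_events(aln1, ref), ref)
    ev2 = left_align_indels(extract_events(aln2, ref), ref)
    ev1 = [e for e in ev1 if _in_window(e, window)]
    ev2 = [e for e in ev2 if _in_window(e, window)]

    covers1 = aln1.ref_span[0] <= window.start and aln1.ref_span[1] >= window.end
    covers2 = aln2.ref_span[0] <= window.start and aln2.ref_span[1] >= window.end

    # --- indels: union over mates, dedup by signature, clash => discordant
    indels: dict[tuple, MutationEvent] = {}
    for e in ev1 + ev2:
        if e.kind != "snv":
            indels.setdefault(e.signature(), e)
    indel_list = sorted(indels.values(), key=lambda e: (e.start, e.kind, e.inserted))
    discordant = any(
        _footprints_clash(a, b)
        for i, a in enumerate(indel_list)
        for b in indel_list[i + 1 :]
    )

    # --- SNVs under the configured confirmation rule
    snv1 = {(e.start, e.alt_base): e for e in ev1 if e.kind == "snv"}
    snv2 = {(e.start, e.alt_base): e for e in ev2 if e.kind == "snv"}
    if rules.snv_confirmation == "mate_overlap":
        snvs = [
            e
            for k, e in snv1.items()
            if k in snv2
            and aln1.ref_span[0] <= k[0] < aln1.ref_span[1]
            and aln2.ref_span[0] <= k[0] < aln2.ref_span[1]
        ]
    else:  # single, or duplex (confirmed later against the partner family)
        merged = dict(snv2)
        merged.update(snv1)
        snvs = list(merged.values())

    # SNVs inside a deletion footprint are unalignable artifacts
    del_spans = [(e.start, e.start + e.length) for e in indel_list if e.kind == "deletion"]
    snvs = [e for e in snvs if not any(s <= e.start < t for s, t in del_spans)]

    events = sorted(indel_list + snvs, key=lambda e: (e.start, e.kind, e.alt_base, e.inserted))

    is_hdr = False
    if rules.donor_edit is not None and not discordant:
        is_hdr = classify_hdr(events, rules.donor_edit)
        if is_hdr:
            donor_sigs = {
                ("snv", pos, 1, "", alt) for pos, _, alt in rules.donor_edit.diff_positions()
            }
            events = [e for e in events if e.signature() not in donor_sigs]

    return MoleculeCall(
        key=consensus.key,
        family_size=consensus.family_size,
        events=tuple(events),
        is_hdr=is_hdr,
        discordant=discordant,
        covers1=covers1,
        covers2=covers2,
    )


def classify_hdr(events: list[MutationEvent], donor: DonorEdit) -> bool:
    """True iff the confirmed events realise exactly the donor replacement
    over the donor interval, with no other event inside the footprint."""
    wanted = {(pos, ref, alt) for pos, ref, alt in donor.diff_positions()}
    inside_snvs = set()
    for e in events:
        if e.kind == "snv" and donor.start <= e.start < donor.end:
            inside_snvs.add((e.start, e.ref_base, e.alt_base))
        elif e.kind == "deletion" and e.start < donor.end and e.start + e.length > donor.start:
            return False
        elif e.kind == "insertion" and donor.start <= e.start < donor.end:
            return False
    return inside_snvs == wanted


def call_library(
    consensus_pairs: list[ConsensusPair],
    amplicon: AmpliconSpec,
    window: ScoringWindow,
    rules: CallRules | None = None,
    scheme: ScoringScheme | None = None,
) -> tuple[list[MoleculeCall], CallStats]:
    """Align and call every consensus pair.

    Alignments are memoised by query sequence: the overwhelming majority of
    consensus molecules in a library are identical (unedited), so each
    distinct sequence is aligned once.
    """
    rules = rules or CallRules()
    scheme = scheme or ScoringScheme()
    cache: dict[str, AlignmentResult] = {}

    def aligned(q: str) -> AlignmentResult:
        hit = cache.get(q)
        if hit is None:
            hit = semiglobal_align(q, amplicon.sequence, scheme)
            cache[q] = hit
        return hit

    calls: list[MoleculeCall] = []
    stats = CallStats()
    for cp in consensus_pairs:
        aln1 = aligned(cp.mate1)
        aln2 = aligned(revcomp(cp.mate2))
        call = call_molecule(cp, aln1, aln2, window, rules, amplicon)
        stats.molecules += 1
        if call.discordant:
            stats.discordant += 1
        elif not (call.covers1 and call.covers2):
            stats.no_window_coverage += 1
        calls.append(call)
    if rules.snv_confirmation == "duplex":
        calls = apply_duplex_confirmation(calls)
    return calls, stats


def apply_duplex_confirmation(calls: list[MoleculeCall]) -> list[MoleculeCall]:
    """Keep a molecule's SNVs only when the partner (b, a) family reports the
    identical SNV.  Molecules without a partner family lose their SNVs.
    Indels are unaffected.  Off by default; the mate-overlap rule is the
    primary dual-strand check."""
    by_key = {c.key: c for c in calls}
    out: list[MoleculeCall] = []
    for c in calls:
        partner = by_key.get((c.key[1], c.key[0]))
        partner_snvs = (
            {e.signature() for e in partner.events if e.kind == "snv"} if partner else set()
        )
        events = tuple(
            e for e in c.events if e.kind != "snv" or e.signature() in partner_snvs
        )
        out.append(
            MoleculeCall(
                key=c.key, family_size=c.family_size, events=events,
                is_hdr=c.is_hdr, discordant=c.discordant,
                covers1=c.covers1, covers2=c.covers2,
            )
        )
    return out
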
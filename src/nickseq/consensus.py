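"""UMI extraction, "ab/ba" family grouping, and single-strand consensus (SSCS).

Each read pair carries a 10 nt UMI at the 5' end of each mate followed by
the locus primer.  The family key is the *ordered* tag pair (a, b) — the
"ab/ba" form — where a and b are the read-1 and read-2 tags.  Families are
collapsed per mate, per position to the modal base when its fraction meets
the consensus threshold, else N.  Consensus over a family removes
independent sequencing errors but cannot remove first-cycle PCR errors,
which are shared by the whole lineage; that residue is exactly what the
uncut-control background measures downstream.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .amplicon import AmpliconSpec, revcomp

__all__ = [
    "ReadLayout",
    "TaggedPair",
    "UmiFamily",
    "ConsensusPair",
    "PrimerMismatchError",
    "default_layout",
    "extract_umi_pair",
    "group_families",
    "sscs_consensus",
    "consensus_pipeline",
    "ConsensusStats",
]

DEFAULT_FWD_PRIMER_LEN = 22
DEFAULT_REV_PRIMER_LEN = 21


@dataclass(frozen=True)
class ReadLayout:
    """Read structure: UMI length and the locus primer each mate must begin with
    (after its UMI).  ``rev_primer`` is given as sequenced on mate 2, i.e. the
    reverse complement of the amplicon's 3' terminus."""

    umi_len: int
    fwd_primer: str
    rev_primer: str
    max_primer_mismatch: int = 2


def default_layout(amplicon: AmpliconSpec, umi_len: int = 10,
                   fwd_len: int = DEFAULT_FWD_PRIMER_LEN,
                   rev_len: int = DEFAULT_REV_PRIMER_LEN,
                   max_primer_mismatch: int = 2) -> ReadLayout:
    """Layout whose locus primers are the amplicon's terminal segments."""
    return ReadLayout(
        umi_len=umi_len,
        fwd_primer=amplicon.sequence[:fwd_len],
        rev_primer=revcomp(amplicon.sequence[-rev_len:]),
        max_primer_mismatch=max_primer_mismatch,
    )


@dataclass(frozen=True)
class TaggedPair:
    umi_a: str
    umi_b: str
    read1: str  # trimmed: UMI and primer removed
    read2: str


@dataclass
class UmiFamily:
    key: tuple[str, str]
    members: list[TaggedPair] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConsensusPair:
    key: tuple[str, str]
    mate1: str
    mate2: str
    family_size: int
    agreement1: float
    agreement2: float


class PrimerMismatchError(ValueError):
    """Locus primer differs from the expected sequence beyond the threshold."""

    def __init__(self, mate: int, mismatches: int):
        self.mate = mate
        self.mismatches = mismatches
        super().__init__(f"mate {mate} primer has {mismatches} mismatches")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_umi_pair(read1: str, read2: str, layout: ReadLayout) -> TaggedPair:
    """Take the first ``umi_len`` bases of each mate as its tag, verify the
    following locus primer (allowing up to ``max_primer_mismatch``
    mismatches), and trim both from the read.

    Raises :class:`PrimerMismatchError` when a primer fails; callers count
    these as a rejection reason rather than aborting.
    """
    u = layout.umi_len
    for mate, read, primer in ((1, read1, layout.fwd_primer), (2, read2, layout.rev_primer)):
        if len(read) < u + len(primer):
            raise PrimerMismatchError(mate, len(primer))
        mm = _hamming(read[u : u + len(primer)], primer)
        if mm > layout.max_primer_mismatch:
            raise PrimerMismatchError(mate, mm)
    return TaggedPair(
        umi_a=read1[:u],
        umi_b=read2[:u],
        read1=read1[u + len(layout.fwd_primer) :],
        read2=read2[u + len(layout.rev_primer) :],
    )


def group_families(pairs: list[TaggedPair]) -> list[UmiFamily]:
    """Group accepted pairs by the ordered (a, b) tag pair.

    Output is deterministic: families sorted lexicographically by key, and
    the sum of family sizes equals the number of input pairs.
    """
    by_key: dict[tuple[str, str], list[TaggedPair]] = defaultdict(list)
    for p in pairs:
        by_key[(p.umi_a, p.umi_b)].append(p)
    return [UmiFamily(key=k, members=by_key[k]) for k in sorted(by_key)]


def sscs_consensus(
    family: UmiFamily, min_family_size: int = 3, consensus_threshold: float = 0.7
) -> ConsensusPair | None:
    """Per-mate, per-position modal-base consensus of one family.

    Families below ``min_family_size`` return ``None`` (a counted outcome,
    not an error).  The consensus length per mate is the modal member
    length (ties resolved to the shorter); minority-length members
    contribute only the positions they cover.  A position's base is the
    modal base when its fraction of contributing members reaches
    ``consensus_threshold``, else N.  Agreement is the mean modal-base
    fraction over positions.
    """
    if family.size < min_family_size:
        return None
    m1, a1 = _consensus_of([p.read1 for p in family.members], consensus_threshold)
    m2, a2 = _consensus_of([p.read2 for p in family.members], consensus_threshold)
    return ConsensusPair(
        key=family.key, mate1=m1, mate2=m2,
        family_size=family.size, agreement1=a1, agreement2=a2,
    )


def _modal_length(lengths: list[int]) -> int:
    counts = Counter(lengths)
    best = max(counts.values())
    return min(l for l, c in counts.items() if c == best)


_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _consensus_of(reads: list[str], threshold: float) -> tuple[str, float]:
    length = _modal_length([len(r) for r in reads])
    if length == 0:
        return "", 1.0
    counts = np.zeros((length, 5), dtype=np.int32)
    for r in reads:
        arr = _CODE[np.frombuffer(r[:length].encode("ascii"), dtype=np.uint8)]
        counts[np.arange(len(arr)), arr] += 1
    return _finish_consensus(counts, threshold)


def _finish_consensus(counts: np.ndarray, threshold: float) -> tuple[str, float]:
    """counts: (length, 5) with columns A,C,G,T,other; returns (sequence, agreement)."""
    acgt = counts[:, :4]
    total = counts.sum(axis=1)
    modal = acgt.argmax(axis=1)
    modal_n = acgt[np.arange(len(acgt)), modal]
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, modal_n / np.maximum(total, 1), 0.0)
    seq_codes = np.where(frac >= threshold, modal, 4).astype(np.uint8)
    seq = bytes(_DECODE[seq_codes]).decode("ascii")
    agreement = float(frac.mean()) if len(frac) else 1.0
    return seq, agreement


@dataclass
class ConsensusStats:
    pairs_accepted: int = 0
    pairs_rejected_primer: int = 0
    families: int = 0
    families_rejected_small: int = 0
    consensus: int = 0


def consensus_pipeline(
    raw_pairs: list[tuple[str, str]],
    layout: ReadLayout,
    min_family_size: int = 3,
    consensus_threshold: float = 0.7,
) -> tuple[list[ConsensusPair], ConsensusStats]:
    """Raw read pairs -> tagged pairs -> families -> consensus pairs.

    Uses a batched counting path when all trimmed reads of a mate share one
    length (the common case for substitution-only error models), falling
    back to the per-family routine otherwise; both produce identical
    output.
    """
    stats = ConsensusStats()
    tagged: list[TaggedPair] = []
    for r1, r2 in raw_pairs:
        try:
            tagged.append(extract_umi_pair(r1, r2, layout))
        except PrimerMismatchError:
            stats.pairs_rejected_primer += 1
    stats.pairs_accepted = len(tagged)
    families = group_families(tagged)
    stats.families = len(families)

    kept = [f for f in families if f.size >= min_family_size]
    stats.families_rejected_small = len(families) - len(kept)

    lens1 = {len(p.read1) for f in kept for p in f.members}
    lens2 = {len(p.read2) for f in kept for p in f.members}
    if len(lens1) == 1 and len(lens2) == 1 and kept:
        out = _batched_consensus(kept, consensus_threshold)
    else:
        out = [sscs_consensus(f, min_family_size, consensus_threshold) for f in kept]
        out = [c for c in out if c is not None]
    stats.consensus = len(out)
    return out, stats


def _batched_consensus(families: list[UmiFamily], threshold: float) -> list[ConsensusPair]:
    """Vectorised consensus for uniform-length reads (equivalent to
    :func:`sscs_consensus` family by family)."""
    out: list[ConsensusPair] = []
    for mate_idx in (0, 1):
        reads = [
            (p.read1 if mate_idx == 0 else p.read2)
            for f in families
            for p in f.members
        ]
        length = len(reads[0])
        fam_idx = np.repeat(
            np.arange(len(families)), [f.size for f in families]
        )
        blob = "".join(reads).encode("ascii")
        codes = _CODE[np.frombuffer(blob, dtype=np.uint8)].reshape(len(reads), length)
        flat = (fam_idx[:, None] * length + np.arange(length)[None, :]) * 5 + codes
        counts = np.bincount(flat.ravel(), minlength=len(families) * length * 5)
        counts = counts.reshape(len(families), length, 5).astype(np.int32)
        results = [_finish_consensus(c, threshold) for c in counts]
        if mate_idx == 0:
            mates1 = results
        else:
            mates2 = results
    for f, (m1, a1), (m2, a2) in zip(families, mates1, mates2):
        out.append(
            ConsensusPair(key=f.key, mate1=m1, mate2=m2,
                          family_size=f.size, agreement1=a1, agreement2=a2)
        )
    return out
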
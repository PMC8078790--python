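"""Semi-global affine-gap alignment of consensus molecules to the amplicon.

Consensus molecules are full (or near-full) amplicon inserts, so the
aligner is *glocal*: the query must be aligned end to end, while leading
and trailing stretches of the reference are free.  Local alignment would
risk clipping away large deletions, which are the signal here.

The dynamic program is the three-state Gotoh recurrence (match/mismatch,
gap-in-query = deletion, gap-in-reference = insertion) with an affine gap
cost ``open + k * extend`` for a gap of length ``k``.  Rows are vectorised
with numpy; the within-row dependency of the deletion state is resolved
with a running-maximum scan.  Tie-breaking is deterministic: substitution
preferred over gaps, deletion over insertion, and the leftmost optimal
end point is taken (indels are subsequently canonicalised by
:func:`left_align_indels`, so only determinism matters at this stage).

``N`` in the query is a wildcard: it matches any reference base at zero
reward and never produces a substitution event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ScoringScheme",
    "AlignedOp",
    "AlignmentResult",
    "MutationEvent",
    "semiglobal_align",
    "extract_events",
    "left_align_indels",
    "reconstruct_query",
]

_NEG = -(10**8)


@dataclass(frozen=True)
class ScoringScheme:
    """Affine alignment scores; penalties are stored as positive magnitudes.

    A gap of length ``k`` costs ``gap_open + k * gap_extend``.
    Defaults are BWA-like magnitudes.
    """

    match: int = 2
    mismatch: int = 4
    gap_open: int = 6
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.mismatch <= 0:
            raise ValueError("mismatch penalty must be > 0")
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")


@dataclass(frozen=True)
class AlignedOp:
    """One run of identical alignment columns.

    op is one of ``match``, ``mismatch``, ``insertion``, ``deletion``.
    ``seq`` carries the query bases for mismatch and insertion runs.
    """

    op: str
    ref_start: int
    ref_len: int
    query_start: int
    query_len: int
    seq: str = ""


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    ops: tuple[AlignedOp, ...]
    ref_span: tuple[int, int]
    query_span: tuple[int, int]
    query: str
    long_query: bool = False  # query longer than the reference; kept, flagged


@dataclass(frozen=True)
class MutationEvent:
    """A normalised edit in reference coordinates.

    kind ``snv``: ``length == 1``, ref_base != alt_base.
    kind ``deletion``: deletes ``[start, start + length)``.
    kind ``insertion``: inserts ``inserted`` before position ``start``.
    ``amb_start``/``amb_end`` bound the equivalent left/rightmost start
    positions of an indel in repetitive context (set by
    :func:`left_align_indels`).
    """

    kind: str
    start: int
    length: int = 1
    inserted: str = ""
    ref_base: str = ""
    alt_base: str = ""
    amb_start: int = -1
    amb_end: int = -1

    def __post_init__(self) -> None:
        if self.kind not in ("snv", "deletion", "insertion"):
            raise ValueError(f"invalid event kind {self.kind!r}")
        if self.kind == "snv" and (self.length != 1 or self.ref_base == self.alt_base):
            raise ValueError("SNV must have length 1 and ref != alt")
        if self.kind == "deletion" and self.length < 1:
            raise ValueError("deletion length must be >= 1")
        if self.kind == "insertion" and not self.inserted:
            raise ValueError("insertion must carry inserted bases")

    @property
    def end(self) -> int:
        """End of the reference footprint (start for insertions)."""
        return self.start + (self.length if self.kind == "deletion" else 0)

    def signature(self) -> tuple:
        """Identity tuple used for deduplication across mates."""
        return (self.kind, self.start, self.length, self.inserted, self.alt_base)


def semiglobal_align(query: str, reference: str, scheme: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal semi-global alignment (free end gaps on the reference only)."""
    if scheme is None:
        scheme = ScoringScheme()
    if not query or not reference:
        raise ValueError("query and reference must be non-empty")
    m, n = len(query), len(reference)
    o, e = scheme.gap_open, scheme.gap_extend

    qb = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    rb = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    n_code = ord("N")

    M = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    I = np.full((m + 1, n + 1), _NEG, dtype=np.int64)  # gap in reference (consumes query)
    D = np.full((m + 1, n + 1), _NEG, dtype=np.int64)  # gap in query (consumes reference)
    M[0, :] = 0  # free leading reference overhang / empty start

    jidx = np.arange(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        q = qb[i - 1]
        if q == n_code:
            sub = np.zeros(n, dtype=np.int64)
        else:
            sub = np.where(rb == q, scheme.match, -scheme.mismatch)
        Mi = M[i]
        Mi[1:] = np.maximum(np.maximum(M[i - 1, :-1], I[i - 1, :-1]), D[i - 1, :-1]) + sub
        Mi[0] = _NEG
        I[i] = np.maximum(I[i - 1] - e, np.maximum(M[i - 1], D[i - 1]) - o - e)
        # D within-row scan: D[i][j] = max_{k<j}(max(M,I)[i][k] + e*k) - o - e*j
        src = np.maximum(Mi, I[i]) + e * jidx
        run = np.maximum.accumulate(src[:-1])
        D[i, 1:] = run - o - e * jidx[1:]
        D[i, 0] = _NEG

    H_last = np.maximum(np.maximum(M[m], I[m]), D[m])
    best = int(H_last.max())
    j = int(np.argmax(H_last))  # leftmost optimal end point
    ref_end = j

    def pick_state(i: int, j: int) -> str:
        h = max(M[i, j], D[i, j], I[i, j])
        if M[i, j] == h:
            return "M"
        if D[i, j] == h:
            return "D"
        return "I"

    state = pick_state(m, j)
    i = m
    cols: list[tuple[str, int, int]] = []  # (op, ref_pos or -1, query_pos or -1), reversed
    while True:
        if state == "M":
            if i == 0:
                ref_start = j
                break
            qc, rc = query[i - 1], reference[j - 1]
            op = "match" if (qc == rc or qc == "N") else "mismatch"
            cols.append((op, j - 1, i - 1))
            i, j = i - 1, j - 1
            state = pick_state(i, j)
        elif state == "D":
            cols.append(("deletion", j - 1, -1))
            v = D[i, j]
            if M[i, j - 1] - o - e == v:
                state = "M"
            elif I[i, j - 1] - o - e == v:
                state = "I"
            else:
                state = "D"
            j -= 1
        else:  # I
            cols.append(("insertion", -1, i - 1))
            v = I[i, j]
            if M[i - 1, j] - o - e == v:
                state = "M"
            elif D[i - 1, j] - o - e == v:
                state = "D"
            else:
                state = "I"
            i -= 1

    cols.reverse()
    ops = _runs_to_ops(cols, query)
    return AlignmentResult(
        score=best,
        ops=tuple(ops),
        ref_span=(ref_start, ref_end),
        query_span=(0, m),
        query=query,
        long_query=m > n,
    )


def _runs_to_ops(cols: list[tuple[str, int, int]], query: str) -> list[AlignedOp]:
    ops: list[AlignedOp] = []
    i = 0
    while i < len(cols):
        op = cols[i][0]
        jseg = i
        while jseg < len(cols) and cols[jseg][0] == op:
            jseg += 1
        run = cols[i:jseg]
        ref_positions = [c[1] for c in run if c[1] >= 0]
        q_positions = [c[2] for c in run if c[2] >= 0]
        ref_start = ref_positions[0] if ref_positions else (
            cols[jseg][1] if jseg < len(cols) and cols[jseg][1] >= 0 else
            (ops[-1].ref_start + ops[-1].ref_len if ops else 0)
        )
        q_start = q_positions[0] if q_positions else (
            ops[-1].query_start + ops[-1].query_len if ops else 0
        )
        seq = ""
        if op in ("mismatch", "insertion"):
            seq = query[q_start : q_start + len(q_positions)]
        ops.append(
            AlignedOp(
                op=op,
                ref_start=ref_start,
                ref_len=len(ref_positions),
                query_start=q_start,
                query_len=len(q_positions),
                seq=seq,
            )
        )
        i = jseg
    return ops


def reconstruct_query(result: AlignmentResult, reference: str) -> str:
    """Rebuild the query from the reference and the alignment operations."""
    parts: list[str] = []
    for op in result.ops:
        if op.op == "match":
            ref_seg = reference[op.ref_start : op.ref_start + op.ref_len]
            q_seg = result.query[op.query_start : op.query_start + op.query_len]
            # N wildcards align as matches but are query-supplied
            parts.append("".join(q if q == "N" else r for q, r in zip(q_seg, ref_seg)))
        elif op.op in ("mismatch", "insertion"):
            parts.append(op.seq)
        # deletions contribute nothing
    return "".join(parts)


def extract_events(result: AlignmentResult, reference: str) -> list[MutationEvent]:
    """Convert alignment operations to mutation events in reference coordinates.

    Reference end-gap overhangs are not events (they are unsequenced
    reference, not edits).  ``N`` wildcard columns are matches and yield no
    SNV.  Insertions falling at the extreme ends of the *query* (sequence
    that could not be placed on the reference at all) are still reported;
    window restriction downstream discards them if irrelevant.
    """
    events: list[MutationEvent] = []
    for op in result.ops:
        if op.op == "mismatch":
            for k in range(op.ref_len):
                pos = op.ref_start + k
                events.append(
                    MutationEvent(
                        kind="snv",
                        start=pos,
                        ref_base=reference[pos],
                        alt_base=op.seq[k],
                    )
                )
        elif op.op == "deletion":
            events.append(MutationEvent(kind="deletion", start=op.ref_start, length=op.ref_len))
        elif op.op == "insertion":
            events.append(
                MutationEvent(kind="insertion", start=op.ref_start, length=0, inserted=op.seq)
            )
    return events


def left_align_indels(events: list[MutationEvent], reference: str) -> list[MutationEvent]:
    """Shift every indel to its leftmost equivalent position.

    Two placements are equivalent when the edited sequence is identical.
    Each indel additionally records its ambiguity span
    ``[amb_start, amb_end]``: the leftmost and rightmost equivalent start
    positions.  The operation is idempotent and sequence-preserving; SNVs
    pass through unchanged.
    """
    out: list[MutationEvent] = []
    for ev in events:
        if ev.kind == "deletion":
            s, L = ev.start, ev.length
            left = s
            while left > 0 and reference[left - 1] == reference[left + L - 1]:
                left -= 1
            right = s
            while right + L < len(reference) and reference[right] == reference[right + L]:
                right += 1
            out.append(replace(ev, start=left, amb_start=left, amb_end=right))
        elif ev.kind == "insertion":
            s, ins = ev.start, ev.inserted
            left, lins = s, ins
            while left > 0 and reference[left - 1] == lins[-1]:
                lins = reference[left - 1] + lins[:-1]
                left -= 1
            right, rins = s, ins
            while right < len(reference) and reference[right] == rins[0]:
                rins = rins[1:] + reference[right]
                right += 1
            out.append(replace(ev, start=left, inserted=lins, amb_start=left, amb_end=right))
        else:
            out.append(ev)
    out.sort(key=lambda ev: (ev.start, ev.kind, ev.alt_base, ev.inserted))
    return out
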
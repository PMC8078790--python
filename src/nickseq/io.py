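"""Readers and writers for the formats the pipeline touches.

FASTA/FASTQ parsing goes through Biopython; FASTQ output is written as
standard 4-line records (Phred+33), gzip auto-detected by the ``.gz``
suffix.  Tables are TSV with header rows and explicit denominators;
summaries and manifests are JSON with sorted keys so runs with the same
seed are byte-identical.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .align import AlignmentResult, MutationEvent
from .amplicon import AmpliconSpec
from .calling import MoleculeCall
from .consensus import ConsensusPair
from .profiler import LengthHistogram, PositionProfile
from .simulate import MoleculeRecord, ReadPair

__all__ = [
    "read_amplicon_fasta",
    "read_fastq_pair",
    "write_fastq_pair",
    "write_truth_table",
    "write_consensus_table",
    "write_calls_table",
    "read_calls_table",
    "write_profile_tsv",
    "write_histogram_tsv",
    "write_json",
    "events_to_vcf_lines",
    "alignment_to_sam_lines",
    "sha256_of_text",
]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_amplicon_fasta(path: str | Path) -> AmpliconSpec:
    """Single-record FASTA -> AmpliconSpec."""
    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return AmpliconSpec(name=rec.id, sequence=str(rec.seq).upper())


def read_fastq_pair(path1: str | Path, path2: str | Path) -> list[tuple[str, str]]:
    with _open_text(path1) as f1, _open_text(path2) as f2:
        reads1 = [str(r.seq) for r in SeqIO.parse(f1, "fastq")]
        reads2 = [str(r.seq) for r in SeqIO.parse(f2, "fastq")]
    if len(reads1) != len(reads2):
        raise ValueError(f"mate files differ in length: {len(reads1)} vs {len(reads2)}")
    if not reads1:
        raise ValueError("empty FASTQ input")
    return list(zip(reads1, reads2))


def write_fastq_pair(pairs: list[ReadPair], path1: str | Path, path2: str | Path) -> None:
    with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual2}\n")


def write_truth_table(records: list[MoleculeRecord], path: str | Path) -> None:
    rows = [
        {
            "molecule_id": r.molecule_id,
            "umi_a": r.umi_a,
            "umi_b": r.umi_b,
            "kind": r.event.kind,
            "start": r.event.start,
            "length": r.event.length,
            "inserted": r.event.inserted,
            "ref_base": r.event.ref_base,
            "alt_base": r.event.alt_base,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_consensus_table(pairs: list[ConsensusPair], path: str | Path) -> None:
    rows = [
        {
            "umi_a": c.key[0],
            "umi_b": c.key[1],
            "family_size": c.family_size,
            "mate1": c.mate1,
            "mate2": c.mate2,
            "agreement1": round(c.agreement1, 6),
            "agreement2": round(c.agreement2, 6),
        }
        for c in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _event_token(e: MutationEvent) -> str:
    if e.kind == "snv":
        return f"snv:{e.start}:{e.ref_base}>{e.alt_base}"
    if e.kind == "deletion":
        return f"del:{e.start}:{e.length}@{e.amb_start}-{e.amb_end}"
    return f"ins:{e.start}:{e.inserted}@{e.amb_start}-{e.amb_end}"


def _parse_token(tok: str) -> MutationEvent:
    kind, rest = tok.split(":", 1)
    if kind == "snv":
        pos, change = rest.split(":")
        ref, alt = change.split(">")
        return MutationEvent(kind="snv", start=int(pos), ref_base=ref, alt_base=alt)
    body, amb = rest.rsplit("@", 1)
    amb_lo, amb_hi = (int(x) for x in amb.split("-"))
    pos, payload = body.split(":")
    if kind == "del":
        return MutationEvent(kind="deletion", start=int(pos), length=int(payload),
                             amb_start=amb_lo, amb_end=amb_hi)
    return MutationEvent(kind="insertion", start=int(pos), length=0, inserted=payload,
                         amb_start=amb_lo, amb_end=amb_hi)


def write_calls_table(calls: list[MoleculeCall], path: str | Path) -> None:
    rows = [
        {
            "umi_a": c.key[0],
            "umi_b": c.key[1],
            "family_size": c.family_size,
            "is_hdr": int(c.is_hdr),
            "discordant": int(c.discordant),
            "covers1": int(c.covers1),
            "covers2": int(c.covers2),
            "events": ";".join(_event_token(e) for e in c.events),
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_calls_table(path: str | Path) -> list[MoleculeCall]:
    df = pd.read_csv(path, sep="\t", dtype={"umi_a": str, "umi_b": str}, keep_default_na=False)
    calls = []
    for row in df.itertuples(index=False):
        tokens = [t for t in str(row.events).split(";") if t]
        calls.append(
            MoleculeCall(
                key=(row.umi_a, row.umi_b),
                family_size=int(row.family_size),
                events=tuple(_parse_token(t) for t in tokens),
                is_hdr=bool(row.is_hdr),
                discordant=bool(row.discordant),
                covers1=bool(row.covers1),
                covers2=bool(row.covers2),
            )
        )
    return calls


def write_profile_tsv(profile: PositionProfile, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "position": profile.positions,
            "ref_base": list(profile.ref),
            "covering": profile.covering,
            "deleted": profile.deleted,
            "frac_lost": np.round(profile.frac_lost, 8),
            "alt_A": profile.alt_counts[:, 0],
            "alt_C": profile.alt_counts[:, 1],
            "alt_G": profile.alt_counts[:, 2],
            "alt_T": profile.alt_counts[:, 3],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_histogram_tsv(hist: LengthHistogram, path: str | Path) -> None:
    rows = [{"bin": str(l), "kind": "fine", "count": c} for l, c in sorted(hist.fine.items())]
    rows += [
        {"bin": f"{lo}-{hi}", "kind": "decade", "count": c}
        for (lo, hi), c in sorted(hist.decades.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sha256_of_text(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def events_to_vcf_lines(
    calls: list[MoleculeCall], amplicon: AmpliconSpec
) -> list[str]:
    """Normalized events as minimal VCF body lines (1-based, anchor-base indels)."""
    ref = amplicon.sequence
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={amplicon.name},length={amplicon.length}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    seen: dict[tuple, int] = {}
    for c in calls:
        if not c.passes:
            continue
        for e in c.events:
            seen[e.signature()] = seen.get(e.signature(), 0) + 1

    def sort_key(sig):
        return (sig[1], sig[0])

    sig_to_event = {}
    for c in calls:
        for e in c.events:
            sig_to_event.setdefault(e.signature(), e)
    for sig in sorted(seen, key=sort_key):
        e = sig_to_event[sig]
        count = seen[sig]
        if e.kind == "snv":
            pos, vref, valt = e.start + 1, e.ref_base, e.alt_base
        elif e.kind == "deletion":
            a = max(e.start - 1, 0)
            pos, vref, valt = a + 1, ref[a : e.start + e.length], ref[a]
        else:
            a = max(e.start - 1, 0)
            pos, vref, valt = a + 1, ref[a], ref[a] + e.inserted
        lines.append(
            f"{amplicon.name}\t{pos}\t.\t{vref}\t{valt}\t.\tPASS\tMOLECULES={count}"
        )
    return lines


def alignment_to_sam_lines(
    name: str, result: AlignmentResult, amplicon: AmpliconSpec
) -> list[str]:
    """One alignment as SAM (CIGAR with M/I/D, 1-based POS), for inspection."""
    cigar = "".join(
        f"{op.query_len if op.op != 'deletion' else op.ref_len}"
        f"{'M' if op.op in ('match', 'mismatch') else ('I' if op.op == 'insertion' else 'D')}"
        for op in result.ops
    )
    header = [
        "@HD\tVN:1.6\tSO:unknown",
        f"@SQ\tSN:{amplicon.name}\tLN:{amplicon.length}",
    ]
    body = (
        f"{name}\t0\t{amplicon.name}\t{result.ref_span[0] + 1}\t60\t{cigar}\t*\t0\t0\t"
        f"{result.query}\t*\tAS:i:{result.score}"
    )
    return header + [body]
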
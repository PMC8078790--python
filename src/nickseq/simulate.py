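"""Synthetic amplicon libraries with known ground truth.

Generates molecule populations carrying the mutational structure observed
at targeted nicks and DSBs — deletions spanning an asymmetric zone around
the cut (by default reaching ~10 bp 5' and ~25 bp 3'), predominately 1 bp
insertions at the cut, SNVs with a configurable transversion fraction, and
optional donor-templated (a-HDR) edits — then renders them as paired-end
FASTQ-style reads carrying 10 nt UMIs and locus primers, with a PCR error
layer shared within each UMI family and an independent per-read sequencing
error layer.

The default amplicon is a 323 bp synthetic construct that embeds the real
CD44-exon-1 guide-4 target context (so the cut falls between the T|G of
CCTCGT|GGCC...) plus a second, entirely synthetic target site 35 bp
upstream on the opposite strand for dual-site experiments.  Everything
outside the two target contexts is deterministic pseudo-random sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .amplicon import AmpliconSpec, ScoringWindow, TargetSite, locate_cut_site, revcomp

__all__ = [
    "DEFAULT_AMPLICON_SEQ",
    "GUIDE4",
    "GUIDE7_SYNTH",
    "default_amplicon",
    "default_site",
    "dual_site",
    "DonorEdit",
    "SimulationConfig",
    "TrueEvent",
    "MoleculeRecord",
    "ReadPair",
    "nick_config",
    "dsb_config",
    "background_config",
    "draw_event",
    "apply_event",
    "simulate_library",
    "render_reads",
    "check_geometry",
]

#: 323 bp synthetic amplicon (frozen).  Positions [160, 184) carry the real
#: guide-4 top-strand context CCTCGTGGCCGCTGAGCCTGGCAC (bottom-strand
#: protospacer, PAM revcomp CCT; cut between positions 165 and 166).
#: Positions [114, 137) carry a synthetic top-strand protospacer + AGG PAM
#: (cut at 131), preceded by a TTTT mononucleotide run.
DEFAULT_AMPLICON_SEQ = (
    "ACAAATGGAAGTTGAGCGTTCACCACTCTCATACGAGGTGCAGACATTGCGCACTTGCCG"
    "GGCTATCCGGGTAATATACGTTAGAGGGCCCTCCCTGATATCGGAGGCACCCGTCCCCTT"
    "CTAAGGGTTTTGAAAGGGATAGTAGATATCACTCCAGACACCTCGTGGCCGCTGAGCCTG"
    "GCACCCGCCACCAACCCCTGAATGGTACCCCCACCCAGTGCAGTGTCTCCTAAGAGTTGA"
    "TCTCGAGTAACACAAGCACAATAACTGGCCTAGAATCCCTGTACGGGTAAGGTCTTTAAA"
    "GTACTTGGACAGGTATGCCTCGC"
)

#: Guide 4 (real CD44 sequence context): bottom-strand protospacer.
GUIDE4 = {"protospacer": "TGCCAGGCTCAGCGGCCACG", "pam": "AGG", "strand": "bottom"}

#: Synthetic stand-in for the second guide 35 bp upstream on the opposite
#: strand (the real guide-7 sequence is not modelled; only the geometry is).
GUIDE7_SYNTH = {"protospacer": "CCCCTTCTAAGGGTTTTGAA", "pam": "AGG", "strand": "top"}


def default_amplicon(name: str = "CD44ex1_synth") -> AmpliconSpec:
    return AmpliconSpec(name=name, sequence=DEFAULT_AMPLICON_SEQ)


def default_site(amplicon: AmpliconSpec | None = None, mode: str = "nick_top") -> TargetSite:
    """The guide-4 target on the default amplicon (cut = 166)."""
    amplicon = amplicon or default_amplicon()
    return locate_cut_site(amplicon, mode=mode, **GUIDE4)


def dual_site(amplicon: AmpliconSpec | None = None, mode: str = "nick_bottom") -> TargetSite:
    """The synthetic second target 35 bp upstream (cut = 131)."""
    amplicon = amplicon or default_amplicon()
    return locate_cut_site(amplicon, mode=mode, **GUIDE7_SYNTH)


@dataclass(frozen=True)
class DonorEdit:
    """A donor-templated replacement: ``ref`` -> ``alt`` starting at ``start``.

    Same-length replacements only; a donor edit therefore decomposes into a
    set of SNV-like differences inside its footprint.
    """

    start: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if len(self.ref) != len(self.alt):
            raise ValueError("donor replacement must preserve length")
        if self.ref == self.alt:
            raise ValueError("donor replacement must differ from the reference")

    @property
    def end(self) -> int:
        return self.start + len(self.ref)

    def diff_positions(self) -> list[tuple[int, str, str]]:
        return [
            (self.start + i, r, a)
            for i, (r, a) in enumerate(zip(self.ref, self.alt))
            if r != a
        ]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated library.

    The defaults describe a nick library in BRCA2-proficient (control)
    cells: a 2.2 % per-molecule mutation rate, deletion-dominated class
    mix, an asymmetric deletion/SNV zone reaching 10 bp 5' and 25 bp 3' of
    the cut, +1 G insertions, and a 25 % transversion fraction among SNVs.
    """

    n_molecules: int = 10_000
    p_mut: float = 0.022
    class_mix: dict = field(
        default_factory=lambda: {"deletion": 0.7, "insertion": 0.1, "snv": 0.2, "donor_hdr": 0.0}
    )
    # deletion geometry: per-side reach drawn from a truncated geometric
    del_extent_5: int = 10
    del_extent_3: int = 25
    q_del_5: float = 0.75
    q_del_3: float = 0.85
    p_del_1bp: float = 0.15
    # insertions; ins_base may be a single base or a {base: probability} mixture
    ins_base: str | dict = "G"
    ins_len_dist: dict = field(default_factory=lambda: {1: 1.0})
    # SNVs
    snv_zone_5: int = 10
    snv_zone_3: int = 25
    transversion_fraction: float = 0.25
    donor_edit: DonorEdit | None = None
    # library rendering
    umi_len: int = 10
    family_size_mean: float = 5.0  # family size = 1 + Poisson(mean - 1)
    e_pcr: float = 0.0
    e_pcr_ins: float = 0.0
    e_pcr_del: float = 0.0
    e_seq: float = 0.001
    read_len: int = 268
    phred_char: str = "I"

    def __post_init__(self) -> None:
        probs = [self.p_mut, self.p_del_1bp, self.transversion_fraction, self.e_pcr,
                 self.e_pcr_ins, self.e_pcr_del, self.e_seq]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {total}")
        unknown = set(self.class_mix) - {"deletion", "insertion", "snv", "donor_hdr"}
        if unknown:
            raise ValueError(f"unknown event classes: {sorted(unknown)}")
        if self.class_mix.get("donor_hdr", 0.0) > 0 and self.donor_edit is None:
            raise ValueError("class_mix includes donor_hdr but no donor_edit is configured")
        if abs(sum(self.ins_len_dist.values()) - 1.0) > 1e-9:
            raise ValueError("ins_len_dist must sum to 1")
        if any(l < 1 for l in self.ins_len_dist):
            raise ValueError("insertion lengths must be >= 1")
        if isinstance(self.ins_base, str):
            if self.ins_base not in "ACGT":
                raise ValueError("ins_base must be one of ACGT")
        else:
            if set(self.ins_base) - set("ACGT") or abs(sum(self.ins_base.values()) - 1) > 1e-9:
                raise ValueError("ins_base mixture must be over ACGT and sum to 1")
        if self.family_size_mean < 1:
            raise ValueError("family_size_mean must be >= 1")


def nick_config(brca2_depleted: bool = False, **overrides) -> SimulationConfig:
    """Nick-library preset (Cas9 D10A).

    Control cells: 2.2 % mutant molecules, 25 % transversions.  With
    ``brca2_depleted`` the mutant frequency rises 7-fold and the SNV
    spectrum shifts to 70 % transversions.
    """
    kw = dict(p_mut=0.022, transversion_fraction=0.25)
    if brca2_depleted:
        kw.update(p_mut=0.154, transversion_fraction=0.70)
    kw.update(overrides)
    return SimulationConfig(**kw)


def dsb_config(**overrides) -> SimulationConfig:
    """DSB-library preset (wild-type Cas9): 42 % mutant molecules,
    insertion-dominated, deletions clustered ~10 bp either side of the cut."""
    kw = dict(
        p_mut=0.42,
        class_mix={"deletion": 0.35, "insertion": 0.55, "snv": 0.10, "donor_hdr": 0.0},
        del_extent_5=10,
        del_extent_3=10,
        q_del_5=0.75,
        q_del_3=0.75,
        snv_zone_5=10,
        snv_zone_3=10,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def background_config(**overrides) -> SimulationConfig:
    """Uncut-control recipe: no true events; PCR-lineage error rates tuned so
    the *called* per-molecule background in a 65 bp window approximates the
    panel values 0.47 % insertions / 0.3 % deletions / 0.26 % SNVs.  This is
    a recipe, not a guarantee."""
    kw = dict(
        p_mut=0.0,
        e_pcr=4.0e-5,
        e_pcr_ins=7.2e-5,
        e_pcr_del=4.6e-5,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclass(frozen=True)
class TrueEvent:
    """Ground-truth repair outcome of one molecule."""

    kind: str  # none | deletion | insertion | snv | donor_hdr
    start: int = -1
    length: int = 0
    inserted: str = ""
    ref_base: str = ""
    alt_base: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("none", "deletion", "insertion", "snv", "donor_hdr"):
            raise ValueError(f"invalid event kind {self.kind!r}")
        if self.kind == "snv" and self.ref_base == self.alt_base:
            raise ValueError("SNV must change the base")
        if self.kind == "insertion" and not self.inserted:
            raise ValueError("insertion must carry bases")


@dataclass(frozen=True)
class MoleculeRecord:
    molecule_id: int
    umi_a: str
    umi_b: str
    event: TrueEvent
    derived_sequence: str


@dataclass(frozen=True)
class ReadPair:
    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _trunc_geom(rng: np.random.Generator, q: float, cap: int) -> int:
    """Draw from P(k) proportional to q**k on k = 0..cap (point mass at 0 if q == 0)."""
    if cap == 0 or q == 0.0:
        return 0
    w = q ** np.arange(cap + 1)
    cdf = np.cumsum(w) / w.sum()
    return int(np.searchsorted(cdf, rng.random(), side="right"))


def _draw_from_dist(rng: np.random.Generator, dist: dict) -> int:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return int(keys[rng.choice(len(keys), p=probs / probs.sum())])


def draw_event(
    config: SimulationConfig,
    site: TargetSite,
    rng: np.random.Generator,
    amplicon: AmpliconSpec | None = None,
) -> TrueEvent:
    """Draw one molecule's ground-truth repair outcome.

    With probability ``1 - p_mut`` the molecule is unedited.  Otherwise the
    event class follows ``class_mix``: deletions remove
    ``[cut - L5, cut + L3)`` with the per-side reaches drawn from truncated
    geometrics (at least one side >= 1), forced to exactly 1 bp at the cut
    with probability ``p_del_1bp``; insertions place ``ins_base * length``
    at the cut bond; SNVs pick a position in the asymmetric zone and an alt
    base that is a transversion with probability ``transversion_fraction``.
    """
    amplicon = amplicon or default_amplicon()
    cut = site.cut
    if cut - max(config.del_extent_5, config.snv_zone_5) < 0 or cut + max(
        config.del_extent_3, config.snv_zone_3
    ) > amplicon.length:
        raise ValueError("event zone exceeds the amplicon")

    if rng.random() >= config.p_mut:
        return TrueEvent(kind="none")

    classes = sorted(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes], dtype=float)
    kind = classes[rng.choice(len(classes), p=probs / probs.sum())]

    if kind == "deletion":
        if rng.random() < config.p_del_1bp:
            return TrueEvent(kind="deletion", start=cut, length=1)
        while True:
            l5 = _trunc_geom(rng, config.q_del_5, config.del_extent_5)
            l3 = _trunc_geom(rng, config.q_del_3, config.del_extent_3)
            if l5 + l3 >= 1:
                return TrueEvent(kind="deletion", start=cut - l5, length=l5 + l3)
    if kind == "insertion":
        length = _draw_from_dist(rng, config.ins_len_dist)
        if isinstance(config.ins_base, str):
            base = config.ins_base
        else:
            keys = sorted(config.ins_base)
            probs = np.array([config.ins_base[k] for k in keys], dtype=float)
            base = keys[rng.choice(len(keys), p=probs / probs.sum())]
        return TrueEvent(kind="insertion", start=cut, inserted=base * length)
    if kind == "snv":
        pos = cut - config.snv_zone_5 + int(
            rng.integers(config.snv_zone_5 + config.snv_zone_3)
        )
        ref_base = amplicon.sequence[pos]
        if rng.random() < config.transversion_fraction:
            alts = _TRANSVERSIONS[ref_base]
            alt = alts[int(rng.integers(len(alts)))]
        else:
            alt = _TRANSITIONS[ref_base]
        return TrueEvent(kind="snv", start=pos, length=1, ref_base=ref_base, alt_base=alt)
    # donor_hdr
    donor = config.donor_edit
    return TrueEvent(kind="donor_hdr", start=donor.start, length=len(donor.ref), inserted=donor.alt)


def apply_event(reference: str, event: TrueEvent) -> str:
    """Apply a ground-truth event to the reference; exact length bookkeeping."""
    if event.kind == "none":
        return reference
    if event.kind == "deletion":
        if not (0 <= event.start and event.start + event.length <= len(reference)):
            raise ValueError("deletion footprint outside the reference")
        return reference[: event.start] + reference[event.start + event.length :]
    if event.kind == "insertion":
        if not 0 <= event.start <= len(reference):
            raise ValueError("insertion position outside the reference")
        return reference[: event.start] + event.inserted + reference[event.start :]
    if event.kind == "snv":
        if not 0 <= event.start < len(reference):
            raise ValueError("SNV position outside the reference")
        if reference[event.start] != event.ref_base:
            raise ValueError("SNV ref base does not match the reference")
        return reference[: event.start] + event.alt_base + reference[event.start + 1 :]
    # donor_hdr: same-length replacement
    end = event.start + event.length
    if not (0 <= event.start and end <= len(reference)):
        raise ValueError("donor footprint outside the reference")
    return reference[: event.start] + event.inserted + reference[end:]


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_umis(rng: np.random.Generator, n: int, umi_len: int) -> list[str]:
    codes = rng.integers(0, 4, size=(n, umi_len))
    arr = _BASES[codes]
    return [bytes(row).decode("ascii") for row in arr]


def simulate_library(
    config: SimulationConfig,
    amplicon: AmpliconSpec | None = None,
    site: TargetSite | None = None,
    rng: np.random.Generator | None = None,
) -> list[MoleculeRecord]:
    """Draw ``n_molecules`` ground-truth molecules with uniform random UMI pairs."""
    amplicon = amplicon or default_amplicon()
    site = site or default_site(amplicon)
    rng = rng if rng is not None else np.random.default_rng(0)
    umis_a = _random_umis(rng, config.n_molecules, config.umi_len)
    umis_b = _random_umis(rng, config.n_molecules, config.umi_len)
    records = []
    for i in range(config.n_molecules):
        ev = draw_event(config, site, rng, amplicon)
        seq = apply_event(amplicon.sequence, ev)
        records.append(
            MoleculeRecord(
                molecule_id=i, umi_a=umis_a[i], umi_b=umis_b[i], event=ev, derived_sequence=seq
            )
        )
    return records


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitution errors at per-base probability ``rate``, uniform over the 3 alts."""
    if rate <= 0.0 or not seq:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in positions:
        alts = [b for b in "ACGT" if b != out[p]]
        out[p] = alts[int(rng.integers(3))]
    return "".join(out)


def _pcr_lineage(rng: np.random.Generator, seq: str, config: SimulationConfig) -> str:
    """PCR errors applied once per molecule lineage (shared by all its reads)."""
    seq = _substitute(rng, seq, config.e_pcr)
    for rate, is_ins in ((config.e_pcr_del, False), (config.e_pcr_ins, True)):
        if rate <= 0.0:
            continue
        n_err = rng.binomial(len(seq), rate)
        for _ in range(n_err):
            p = int(rng.integers(len(seq)))
            if is_ins:
                base = "ACGT"[int(rng.integers(4))]
                seq = seq[:p] + base + seq[p:]
            else:
                seq = seq[:p] + seq[p + 1 :]
    return seq


def render_reads(
    records: list[MoleculeRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[ReadPair]:
    """Render UMI-tagged paired reads for every molecule.

    Mate 1 = ``umi_a`` + the first ``read_len - umi_len`` bases of the
    molecule's (PCR-mutated) top strand, whose 5' end is the forward locus
    primer; mate 2 = ``umi_b`` + the corresponding bottom-strand prefix.
    The per-molecule read count is ``1 + Poisson(family_size_mean - 1)``.
    PCR errors are drawn once per molecule; sequencing errors independently
    per read.  Deterministic under a fixed rng state.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    body = config.read_len - config.umi_len
    if body <= 0:
        raise ValueError("read_len must exceed umi_len")
    pairs: list[ReadPair] = []
    lam = config.family_size_mean - 1.0
    for rec in records:
        lineage = _pcr_lineage(rng, rec.derived_sequence, config)
        top = lineage[:body]
        bottom = revcomp(lineage)[:body]
        n_reads = 1 + (int(rng.poisson(lam)) if lam > 0 else 0)
        for j in range(n_reads):
            s1 = _substitute(rng, rec.umi_a + top, config.e_seq)
            s2 = _substitute(rng, rec.umi_b + bottom, config.e_seq)
            pairs.append(
                ReadPair(
                    name=f"mol{rec.molecule_id}.{j}",
                    seq1=s1,
                    qual1=config.phred_char * len(s1),
                    seq2=s2,
                    qual2=config.phred_char * len(s2),
                )
            )
    return pairs


def check_geometry(
    config: SimulationConfig,
    amplicon: AmpliconSpec,
    window: ScoringWindow,
    fwd_primer_len: int,
    rev_primer_len: int,
) -> None:
    """Verify that both trimmed mates cover the scoring window.

    Mate 1 covers amplicon ``[fwd_primer_len, read_len - umi_len)``; mate 2
    covers ``[G - (read_len - umi_len), G - rev_primer_len)``.  The
    dual-strand SNV confirmation rule needs the window inside the overlap.
    """
    body = config.read_len - config.umi_len
    m1 = (fwd_primer_len, body)
    m2 = (amplicon.length - body, amplicon.length - rev_primer_len)
    lo, hi = max(m1[0], m2[0]), min(m1[1], m2[1])
    if not (lo <= window.start and window.end <= hi):
        raise ValueError(
            f"read pair does not jointly cover the scoring window: overlap "
            f"[{lo}, {hi}) vs window [{window.start}, {window.end})"
        )
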
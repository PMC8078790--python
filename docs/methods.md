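# Methods

This note records the models, conventions, parameter choices, and known
limitations of `nickseq`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted that
the code does not measure.

## Coordinate model and cut-site placement

Coordinates are 0-based, half-open, on the top strand of the amplicon. A
cut coordinate names the phosphodiester bond between positions `cut-1` and
`cut`; this is unambiguous for nicks on either strand and fixes where
insertions at the cut are placed. Cas9 and Cas9 D10A cleavage is modelled
as blunt, 3 nt 5' of the PAM. For a bottom-strand target (protospacer on
the bottom strand, as for the default guide) the search looks for
`revcomp(PAM) + revcomp(protospacer)` on the top strand and mirrors the
offset; on the default amplicon this lands the cut exactly between the T|G
of the `...CCTCGT|GGCC...` context, as expected for this guide. Products
of occasional staggered cleavage (1 nt 5' overhangs) are represented as
repair outcomes in the simulator (+1 insertions), not in the coordinate
model.

Scoring windows of width `w` are `[cut - w//2, cut - w//2 + w)`: even
widths split evenly across the bond, odd widths put the extra base 3' of
the cut; windows are clipped to the amplicon with a logged warning. The
default width is 65.

## The default amplicon

The shipped reference is a 323 bp synthetic construct. Positions
[160, 184) carry the real guide-4 target context of CD44 exon 1 (so the
cut-placement rule can be checked against a real printed sequence);
positions [114, 137) carry an entirely synthetic second target 35 bp
upstream on the opposite strand (preceded by a TTTT run so +1 T insertions
there are placement-ambiguous, as at a mononucleotide tract); the rest is
frozen pseudo-random sequence. 323 bp was chosen as a realistic first-round
amplicon size for which two 268 nt mates (10 nt UMI + ~22 nt locus primer
each) overlap across the whole 65 bp scoring window — the geometry the
dual-strand SNV rule requires, which `check_geometry` enforces at
simulation time. The locus primers are the amplicon's terminal 22/21 bases.
Fold coverage is computed as `N·L/G` from whatever N, L, G describe the
library at hand; G for a final sequencing-library molecule (insert plus
adapters) is generally larger than the genomic amplicon.

## Simulator

Each molecule independently carries a repair event with probability
`p_mut`, with class probabilities `class_mix` over deletion / insertion /
SNV / donor-HDR. Defaults describe a control nick library; presets adjust
them:

| parameter | control nick | BRCA2-depleted nick | DSB |
|---|---|---|---|
| `p_mut` | 0.022 | 0.154 (7× control) | 0.42 |
| class mix (del/ins/SNV) | 0.7 / 0.1 / 0.2 | same | 0.35 / 0.55 / 0.10 |
| deletion reach 5' / 3' (bp) | 10 / 25 | same | 10 / 10 |
| SNV zone 5' / 3' (bp) | 10 / 25 | same | 10 / 10 |
| transversion fraction | 0.25 | 0.70 | 0.25 |

- **Deletions** remove `[cut - L5, cut + L3)`, with each side's reach drawn
  from a truncated geometric (`P(k) ∝ q^k` on `0..cap`; defaults
  `q5 = 0.75`, `q3 = 0.85`) conditioned on `L5 + L3 ≥ 1`. The caps encode
  the asymmetric zone around a nick (~10 bp 5', ~25 bp 3'), the footprint
  of predominately-5' resection; the DSB preset is symmetric. With
  probability `p_del_1bp` (default 0.15) the deletion is forced to exactly
  1 bp at the cut, since 1 bp deletions form a mechanistically distinct
  class.
- **Insertions** place `ins_base × length` at the cut bond (default a
  single G, matching the dominant +1 G product at this site; a base
  mixture is configurable). At the default cut the product reads ...TGG...
- **SNVs** pick a uniform position in the asymmetric zone; the alternative
  base is a transversion with probability `transversion_fraction`
  (uniform between the two transversions, the single transition
  otherwise).
- **Donor-HDR** molecules carry exactly a configured same-length
  replacement. Same-length donors were chosen so a donor edit decomposes
  into substitutions and cannot be confused with indel classes; a
  length-changing donor would be scored as an indel by any
  alignment-based caller and is out of scope.

Reads: mate 1 is `umi_a` + the molecule's top-strand prefix, mate 2 is
`umi_b` + the bottom-strand prefix, both `read_len = 268` nt with constant
quality. The per-molecule read count is `1 + Poisson(mean − 1)` with mean
5 — a stand-in, since real family-size distributions are
machine/protocol-dependent and not otherwise pinned down. PCR errors are
drawn once per molecule lineage and shared by all its reads (rate `e_pcr`
per base for substitutions, plus optional 1 bp `e_pcr_ins`/`e_pcr_del`);
this single-early-cycle model is exactly the error mode UMI consensus
cannot remove, which is why the control-background machinery exists.
Multi-cycle PCR genealogies, jackpot/chimera artifacts and quality-aware
errors are deliberately not modelled. Sequencing errors are independent
per read (rate `e_seq`, default 1e-3, uniform over the three alternative
bases, applied across the whole read including UMI and primer).
`background_config()` is a recipe whose tuned lineage-error rates make the
*called* background in a 65 bp window land near 0.47 % insertions / 0.3 %
deletions / 0.26 % SNVs per molecule; it approximates, not guarantees,
those values.

## UMI consensus

The family key is the ordered (read-1 tag, read-2 tag) pair — "ab/ba"
form. No UMI error correction is attempted: merging near-miss tags would
silently alter family counts, so tag errors instead produce small spurious
families that the size filter removes. Families below `min_family_size`
(default 3) are rejected and counted. Consensus is per mate, per position:
the modal base if its fraction of contributing reads reaches
`consensus_threshold` (default 0.7), else `N`. The defaults mean a single
sequencing error in a size-3 family yields `N` rather than a wrong base.
Reads of minority length contribute only up to the family's modal length.
A batched, vectorised counting path is used when all trimmed reads share
one length; it is tested to be output-identical to the per-family routine.
Consensus accuracy is defined over called bases; `N` is a no-call, not a
miscall.

## Alignment and normalisation

Consensus molecules are full amplicon inserts, so alignment is semi-global
(free end gaps on the reference only): local alignment could clip away
large deletions, and global alignment would penalise the unsequenced
reference flanks. The scorer is the three-state affine Gotoh recurrence
(match +2, mismatch −4, gap open −6, gap extend −1 — BWA-like magnitudes,
config-exposed; a length-k gap costs `open + k·extend`). Rows are
vectorised in numpy with the horizontal-gap dependency resolved by a
running-maximum scan. `N` is a wildcard scoring 0 and never yields an SNV.
Tie-breaking is deterministic (substitution over gap, deletion over
insertion, leftmost optimal end); determinism is all that matters at this
stage because indels are subsequently left-normalised: every indel is
shifted to its 5'-most sequence-identical position and annotated with its
full ambiguity span `[leftmost, rightmost]` start. Left-normalisation is
idempotent and sequence-preserving (property-tested), and scores are
verified against an independent brute-force dynamic program on random
small instances. Alignments are memoised by query string — in a library
dominated by unedited molecules almost all alignments are cache hits,
which is what keeps a 10,000-molecule run in tens of seconds.

## Calling

Events are restricted to the scoring window (an event intersecting the
window counts). Indels are accepted from either mate and deduplicated when
both mates report the same normalised event; two *different* indels with
intersecting footprints mark the molecule discordant — it is excluded from
all denominators and counted. SNVs follow the dual-strand rule
(`mate_overlap`, the default): kept only when the position is covered by
both mates' alignments and both report the identical alternative base.
`single` mode takes the union (and is provably a superset — confirmation
can only remove calls); `duplex` mode instead requires the identical SNV
in the partner (b, a) family and is off by default, since with full mate
overlap across the window the mate-level check is available for every
molecule while (b, a) partner families need not exist. SNVs inside an
accepted deletion footprint are suppressed as unalignable. A molecule is
a-HDR when its confirmed events realise exactly the donor replacement and
nothing else inside the donor footprint; donor-matching substitutions then
leave the SNV category.

## Reporting

Frequencies are per consensus molecule (the UMI-collapsed denominator),
never per read; a molecule counts once toward each category it carries, so
category frequencies can sum to more than the mutant frequency
(event-level counting is a report option). Background subtraction
(`max(0, observed − background)` per category) applies to aggregate
frequencies only — per-position maps are reported raw, with the uncut
control's map available alongside, because positional subtraction of two
noisy maps would manufacture structure. Transversions are {A↔C, A↔T, G↔C,
G↔T}. The asymmetry index is `A = (M3 − M5)/(M3 + M5)` over per-position
deleted-base (or SNV) mass strictly 5'/3' of the cut bond, in [−1, 1],
with 0 (and a warning) on an empty profile; a percentile bootstrap over
molecules provides its confidence interval. Dual-site partitioning
requires disjoint windows and counts a molecule "both" only if events
touch both windows. Normalised SNV frequencies are
`(f − b)⁺ / (f_ref − b)`, raising an error when the reference does not
exceed background. Insertion composition tabulates the inserted-base
identity among 1 bp insertions and, for insertions whose ambiguity span
touches the 4 bp around the cut, the bases observed in the edited molecule
at −2, −1, +1, +2 relative to the cut (an insertion in the bond itself
occupies +1, using the cut-proximal equivalent placement).

One consequence of left-normalisation worth stating: in repetitive
context the canonical (leftmost) placement of a deletion can sit a few
bases 5' of where the physical event occurred, while encoding the
identical molecule. Zone-confinement checks and zone-reach reports
therefore reason over the ambiguity span (the cut-proximal equivalent
placement), not the canonical start alone.

## Determinism and problem sizes

Every stochastic stage draws from its own RNG stream derived from the
master seed and the stage name, so changing one stage's parameters leaves
the others' draws untouched; runs are byte-identical given a seed, and
each run's manifest records the config hash and seed. Simulated studies in
the tests and the acceptance script use 10,000 molecules per condition
(mean family size 5, ~50,000 read pairs) — large enough that 2.2 %-level
frequencies are estimated with a few-percent relative error and exact
binomial 99 % intervals are meaningful, while a full four-condition
re-analysis completes in well under a minute.

## What passing tests do and do not show

The simulator reproduces the *structure* of the real data (event classes,
asymmetric zones, UMI dispersion, consensus-resistant PCR errors) but not
its full messiness: no adapter read-through, no base-quality information,
no chimeric families, no indel sequencing errors by default, and a
single-locus amplicon. Parameter-recovery results therefore validate the
analysis chain (tagging → consensus → alignment → calling → reporting) on
data whose generative process is known, and the printed worked examples
validate the arithmetic conventions; neither certifies performance on any
particular real library. The two parallel callers used in the original
analyses (an mpileup-based path and CRISPResso2) are replaced by the
single bespoke caller here; no reconciliation step is modelled.
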
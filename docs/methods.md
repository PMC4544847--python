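# Methods

## Similarity kernel

The sample-to-sample similarity is the shared-read criterion of
alignment-free metagenome comparison: read *r* of sample *A* is shared with
sample *B* when *r* contains at least *t* distinct canonical *k*-mers that
occur anywhere in *B*'s reads; S(A→B) is 100 × (shared reads of A) / (reads
of A). Defaults *k* = 30, *t* = 2. Canonicalization takes the lexicographic
minimum of each *k*-mer and its reverse complement, so strand never affects
matching; windows containing an N contribute nothing; a *k*-mer occurring
twice in one read counts once toward *t*.

Membership is an exact hash set, not a Bloom filter. At the library sizes
this package targets (10³–10⁵ reads per sample) exact sets fit trivially in
memory, remove any false-positive rate from the analysis, and make the
kernel checkable against a brute-force per-read set-intersection oracle —
the test suite requires exact agreement on random library pairs. Reads of
length exactly *k* carry a single *k*-mer and can never reach *t* = 2; they
stay in the denominator. Paired-end mates are treated as independent reads.

The DSI uses the recipient→donor direction for S (the fraction of the
recipient's metagenome accounted for by the donor is the quantity
engraftment should move); the symmetric score
100·(shared_A→B + shared_B→A)/(n_A + n_B) is also computed and reported,
and a flag selects it for DSI if desired.

## Donor Similarity Index

DSI = 100·(S_t − S₀)/(100 − S₀), with S₀ the recipient-to-donor similarity
of the BL2 samples (taken immediately pre-transplant) and S_t the
post-transplant similarity. Algebraically DSI is the fraction of remaining
headroom closed, and the map S_t = S₀ + DSI·(100 − S₀)/100 inverts it (a
property test asserts the round trip). DSI is undefined at S₀ = 100
(raised as a degenerate baseline) and is clamped neither below 0 nor above
100 — negative values are real observations. BL1 is used only as a
baseline-drift control: the BL1→BL2 similarity is reported alongside each
trajectory.

### Trajectory patterns

Observed FMT time courses fall into two shapes: an early moderate DSI rise
that subsequently declines, and a low early DSI that creeps upward over
months. The classifier formalizes this: with post-transplant DSI values
(1 week first), call *moderate_rise_then_decline* when DSI(WK1) ≥ 40 and
the last observed DSI is below DSI(WK1) (optionally by a relative margin
`late_drop_fraction`, default 0); call *low_then_gradual_rise* when
DSI(WK1) < 40 and the last DSI exceeds it; anything else — including fewer
than two usable (non-CNBP) points or a missing 1-week value — is
*indeterminate*. The threshold 40 is an explicit parameter: the dichotomy
is descriptive, and the classifier is a formalization of it, not a
published rule.

The endpoint evaluation asks, per recipient, whether DSI at a named
timepoint (default 1 month) exceeds a threshold (default 50); CNBP entries
are "not evaluable", never failures.

## QC cascade

Stages in order, mirroring a standard shotgun-metagenome cleaning pipeline:

1. **Host screen** — a read is removed when it shares ≥ 2 canonical 31-mers
   with the host reference (the same shared-k-mer logic as the similarity
   kernel, standing in for an alignment-based host tagger). Host removal
   precedes deduplication, so a host read is never also counted as a
   duplicate.
2. **Deduplication** — exact full-sequence identity on the raw read; first
   occurrence kept. Single-end semantics; alignment-based pair-coordinate
   duplicate marking is out of scope.
3. **End trimming** — leading/trailing runs of N removed from sequence and
   quality in lockstep; interior Ns untouched.
4. **Quality/length filter** — a read is removed when its mean Phred score
   over the first `prefix_length` bases (80 for ~93 bp HiSeq-style reads,
   120 for ~150 bp MiSeq-style reads) is below 6, or its post-trim length is
   below `min_length` (= prefix length by default). The mean-over-prefix
   reading was chosen because a strict per-base Q < 6 rule would discard
   nearly every real library on single bad cycles, which is inconsistent
   with tens of millions of reads surviving this filter in practice.

A sample whose surviving read count falls below
`min_reads_after_filtering` (default 10,000,000, the depth at which
species above ~0.2% abundance remain measurable; desk-scale runs set it
lower explicitly) is flagged CNBP and excluded from similarity analysis;
it stays in every output table as an explicit CNBP marker. Conservation
(input = Σ removals + remaining) is enforced by the report type itself,
and the cascade is idempotent.

## Marker-based profiling and species rules

Species profiles come from species-specific markers: every canonical
30-mer of every marker occurs in exactly one species' genome (the
generator rejection-samples marker windows until this holds; the profiler
verifies it and raises on violation). A read matching ≥ 1 marker k-mer is
assigned to that species; relative abundance is the percentage of assigned
reads. Reads matching nothing are unassigned and excluded from the
denominator — so profiles always sum to 100 over assigned reads.

- **Shannon diversity** H = −Σ pᵢ ln pᵢ over detected species, in nats
  (natural log; the base is configurable since conventions differ).
- **Transplanted species**: undetectable (≤ detection floor, default
  exactly 0) in *both* recipient baselines, present in the donor (> floor;
  any nonzero donor abundance suffices — "increase toward the donor"
  presupposes the donor carries the species but no donor minimum is
  stated), and reaching ≥ 0.2% at ≥ 1 post-transplant timepoint. Requiring
  both baselines is the conservative reading; a flag relaxes it.
  Qualifying species are subtyped: *persistent* (present at every observed
  post timepoint), *late* (first appearance at 1 month or later),
  otherwise *transient* (present early, lost later).
- **Large changes**: absolute change in percentage points (flag at > 5)
  and log₁₀ fold change (flag at ≥ 1 log). Log changes are computed only
  when both abundances are positive; appearances/disappearances are
  flagged `from_zero`/`to_zero` rather than pseudocounted, so a zero never
  manufactures an infinite fold change.
- **Donor-vs-recipient species test**: per species present in ≥ 1 sample,
  a paired two-tailed t-test on relative abundances across donor/recipient
  pairs (no transform, matching common practice on such tables; an
  arcsine-square-root option was considered and rejected as an untestable
  deviation), then Benjamini–Hochberg q-values; `significant` is q < 0.05
  and `nominal_only` marks p < 0.05 that fails correction. Degenerate
  zero-variance differences: all-zero differences give p = 1 (no
  evidence); a constant nonzero difference gives p = 0 with an infinite
  statistic. Fewer than two pairs is an explicit error, not a silent skip.

## Synthetic-data generator

The generator emulates the features of a real FMT cohort that the analysis
actually touches, and nothing more:

- **Communities**: a pool of `n_species` random genomes (default 20 kb
  each); an `overlap_fraction` of species shared between donor and
  recipient, the rest split between them; abundances log-normal (σ = 1.0)
  renormalized to 100%, giving realistic long-tailed profiles.
- **Engraftment**: the post-transplant community at a scheduled timepoint
  is the convex mixture (1 − π)·recipient + π·donor. π is the ground-truth
  engraftment that DSI estimates; with disjoint communities and adequate
  coverage, DSI ≈ 100π (the acceptance checks recover π at the extremes
  within 5 points using 20,000 reads/sample and a 0.5% error rate).
- **Reads**: uniform fragment starts, uniform strand (minus-strand reads
  reverse-complemented), default length 93 bp (HiSeq-like; 150 for
  MiSeq-like). Substitution errors at `error_rate` with a two-level
  quality model: Q38 for clean bases, Q8 for substituted ones. A
  `bad_read_fraction` knob emits reads with uniform Q2 to exercise the
  quality filter; `host_fraction` of reads come from a synthetic 100 kb
  host sequence; `duplicate_fraction`·n extra verbatim copies are
  appended.
- **Ground truth sidecar**: per-read origin, injected host/duplicate/bad
  read ids, and the per-stage removal counts the QC cascade should observe
  — computed by replaying the cascade order on the true labels (so
  accidental sequence collisions count as duplicates, keeping the equality
  with QC output exact at error_rate = 0).
- **Seeding**: one master seed; per-sample streams derived by hashing
  (sample_id, master seed), so adding a sample never perturbs another's
  reads. FASTQ output is byte-reproducible.

What it does *not* emulate: GC bias, indels, quality-by-cycle decay,
genome relatedness between species (genomes are i.i.d. random, so
cross-species k-mer collisions are vanishingly rare — real strain overlap
makes the similarity criterion less specific than these tests exhibit),
bowel-preparation effects on the community, or paired-end insert-size
structure (mates are analyzed independently throughout). Passing tests on
this generator therefore demonstrate correctness of the algorithms under
their stated assumptions, not field performance on real stool metagenomes.

## Problem sizes and numerical choices

Desk-scale defaults keep every run interactive: the bundled demo uses 3
donor/recipient pairs, 20 species × 8 kb genomes and 2,000 reads/sample —
sized so that a library's reads cover each genome densely enough that the
shared-k-mer criterion is not coverage-limited (with G bp of community
genome and n reads of length L, the chance a post-transplant read finds no
donor read overlapping it by the ≥ k + t − 1 bases needed for t shared
k-mers is ≈ exp(−n(2L − 2(k+t−1) + 1)/G); the demo keeps this below a few
percent). The π-recovery analysis uses 20,000 reads/sample over 20 × 20 kb
genomes for the same reason. Abundance vectors are validated to sum to 100
within 1e-9 (generator) / 1e-6 (profiles); similarity percentages are
exact rational counts and carry no tolerance; DSI inherits only the
sampling error of S₀ and S_t.

Determinism: all randomness flows from numpy `default_rng` seeded as
described; pipeline reruns with the same seed and inputs produce
byte-identical TSVs, and the run summary records a config hash.

## Known limitations

- The host screen is a k-mer filter, not an aligner: it is exact on the
  synthetic host (and exactly recovers ground truth at error_rate 0) but
  has no model of human-genome repeats or microbial-human homology.
- Similarity saturates from below at low sequencing depth (coverage
  attenuation): DSI then underestimates π. Real studies sit at ≥ 10⁷ reads
  where this is negligible; desk-scale users should size libraries via the
  coverage formula above.
- The pattern classifier needs a usable 1-week DSI; cohorts missing WK1
  are always indeterminate.
- The species test assumes profiles are comparable across samples (no
  compositional transform); with few pairs its power is minimal, and the
  package reports nominal-only hits separately rather than pretending
  FDR-corrected significance.
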
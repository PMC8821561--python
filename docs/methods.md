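# Methods

## Interval conventions and matching

All coordinates are 0-based half-open internally. VCF symbolic SV
records are read as `start = POS`, `end = INFO/END` (POS is the base
before the event, so the affected bases are `[POS, END)` and
`length = END − POS`); the writer inverts this exactly, making the
1-based/0-based conversion a bijection. This matches the span a
bedtools-style VCF-to-BED conversion produces, so reciprocal-overlap
(RO) arithmetic agrees with the common `bedtools intersect -r -f`
usage. Contig names are normalized by stripping the `chr` prefix
(configurable), since hg19-era resources mix both dialects.

Reciprocal overlap is `|a∩b| / max(|a|,|b|)`. Matching two call sets is
**greedy one-to-one**: candidate pairs at RO ≥ threshold (same svtype
unless disabled) are accepted in decreasing RO, ties broken by leftmost
left call then leftmost right call. Greedy rather than maximum-weight
matching was chosen because it mirrors how reciprocal intersection is
used in practice, is deterministic, and is directly checkable against a
brute-force oracle. Because lowering the threshold only appends
candidates to the end of the processing order, and candidates that lose
never block others, the accepted pair set is monotone in the threshold
and stable under removal of unmatched calls — which is what makes the
confirmation filter idempotent.

Two deliberately different overlap semantics coexist and are named
apart: greedy one-to-one matching for call-to-call comparison
(`match_sets`, intersection, detection), and many-to-many existence
counting for annotation against reference tracks (`count_overlaps`,
`caller_overlap_profile`, region filters, which use ≥ min_bp shared
bases rather than RO).

## Filters

Every filter is contractive and idempotent and returns a report with
exact conservation (retained + removed = input). Missing-field
conventions: the support-fraction and adjusted-p filters *retain and
flag* calls lacking the field (a quality filter should not punish
absent metadata); the non-reference genotype filter *removes* calls
with a missing genotype, because demanding genotype evidence is its
purpose. Thresholds default to: support fraction strictly > 0.3 on
either the paired-end or split-read channel; adjusted p < 0.5;
population allele frequency ≤ 0.05 at RO ≥ 0.5 against same-type
population records (type-matched RO rather than any-bp overlap, for
consistency with the sharing rule; both knobs configurable).

Delamp removes **both** members of every opposite-type match at
RO ≥ 0.75, implemented many-to-many (a call is removed iff *any*
opposite-type call of the same set matches it). A locus one caller
labels both gain and loss is untrustworthy in both labels; many-to-many
removal also guarantees the postcondition that the output contains no
cross-type pair above the threshold, and makes the filter idempotent.
It is applied within each paired-end caller's own set, before any
cross-caller intersection.

## Combination strategies

`union` joins call sets in caller-priority order (default
Manta > Delly > ERDS > CNVnator: paired-end callers are base-pair
precise, coverage callers are bin-limited, and the leading pair is
generally the more conservative), collapsing same-type matches at
RO ≥ 0.5 into one record whose coordinates come from the
highest-priority source and whose provenance lists every member.
Merging is iterative greedy (running merged set vs next caller), not
clique merging: deterministic and order-stable, at the cost that a
chain of calls overlapping pairwise but not transitively can split
across records. The final-join dedup threshold of 0.5 is the sharing
threshold; it is configurable.

`intersection_union` = delamp on each paired-end set → paired-end pair
and coverage pair each intersected at RO ≥ 0.75 → union of the two
pools at RO ≥ 0.5. Every emitted call therefore carries provenance
from both members of at least one same-signal pair. Either strategy
may be followed by non-reference genotype filtering of an external
regenotyper's VCF (`*_sv2` variants); candidates are deduplicated
before regenotyping (disable by running the genotype filter directly).

## Benchmark semantics

Statistics are defined over *labeled pools*, not genome-wide truth:
sensitivity = fraction of TRUE_POSITIVE-labeled calls retained,
specificity = fraction of FALSE_POSITIVE-labeled calls removed,
accuracy = (TP kept + FP removed)/pool, PPV ratio = PPV after / PPV
before. SHARED (same signal in index and parents — possible artifact)
and DOUBTFUL calls are excluded from the 2×2 table and reported
alongside. "Accuracy" follows the declared formula above; it is a
definition of this package, stated explicitly because pool-based
accuracy has no single convention. For strategies, whose outputs are
merged records with fresh ids, a labeled input call counts as retained
when its (caller, interval) identity appears in an output record's
provenance.

`detection_rate` scores candidates against an independent truth set by
greedy same-type matching at RO ≥ 0.5 (configurable) and reports the
best observed RO per truth call, so near-misses due to imprecise
reference breakpoints (the typical aCGH situation) are visible.

Size bins are left-closed: [50 bp, 1 kb), [1, 5 kb), [5, 50 kb),
[50, 200 kb), [200 kb, ∞).

## Simulator

The generator provides labeled fixtures with known ground truth.

- **Genome**: 22 hg19-like autosomes (~2.88 Gb), so per-Mb
  false-positive rates and non-overlapping placement behave like real
  data.
- **Truth**: n non-overlapping CNVs (rejection-sampled; overlap-free
  truth keeps labels unambiguous), svtype DEL with probability 0.6
  (deletions outnumber gains in real call sets), sizes log-uniform on
  [1 kb, 5 Mb]. The floor is a resolution choice, not the 50 bp SV
  definition (which remains the hard minimum and the configurable lower
  limit): bin-based coverage callers cannot resolve sub-bin-scale
  events, so the regime the default fixtures emulate — and in which the
  closed-form ensemble expectations hold — is calls much larger than
  the breakpoint jitter. Sub-kilobase fixtures can be generated by
  lowering `size_range`, with the caveat that 75%-RO pair intersection
  of jittered sub-kilobase calls fails often (quantified by
  `pair_jitter_success`).
- **Callers**: each truth call is emitted with its svtype × size-bin
  sensitivity (default flat 0.9); breakpoints are jittered by rounded
  normal draws — sd 0 for paired-end callers (base-pair precision),
  sd 100 bp for coverage callers (their analysis bin). False positives
  arrive as a Poisson process (default 5/Mb) with sizes from the truth
  distribution. Opposite-type mislabeling (paired-end only, both CNV
  types arise from one discordant-pair signal there) and cohort-wide
  shared artifacts (identical correlated false calls in every caller,
  labeled SHARED) are off by default and enabled per scenario.
- **Determinism**: one root `SeedSequence` spawns independent
  per-caller streams; identical seeds give identical cohorts.

What the simulator does *not* emulate: breakpoint-level read evidence,
GC / mappability structure, tandem or nested CNVs, trio inheritance,
and caller-specific systematic biases beyond the error-model axes
above. Passing tests therefore demonstrate the correctness of the
combination/benchmark machinery under a controlled error model, not
caller performance on real genomes.

## Analytic expectations and their limits

Under caller independence with flat sensitivities,
`expected_strategy_stats` returns union sensitivity `1 − Π(1 − sᵢ)`
and intersection-union sensitivity `1 − (1 − s₁s₂)(1 − s₃s₄)`
per svtype × size bin. Two idealizations make the closed form a slight
upper bound on the measured pipeline, both quantifiable within the
package: (a) delamp occasionally removes a truth-derived paired-end
call that collides with a random opposite-type false positive at
RO ≥ 0.75 (the same placement-window geometry as
`fp_pair_coincidence`); (b) coverage-pair jitter erodes 75%-RO
intersection near the size floor (`pair_jitter_success`, available as
the `include_jitter` correction). The probability that two independent
false positives co-locate at RO ≥ t is computed by numerical
integration over the log-uniform size distribution: for lengths
`la, lb`, matching placements form a window of width
`la + lb − 2·t·max(la, lb)` (empty when negative), and partner false
calls fall into it as a Poisson process.

## Numerical and degenerate-input choices

- Calls shorter than 50 bp are rejected at construction (SV
  definition); the minimum is configurable at the I/O boundary.
- Jitter that would invert or collapse an interval falls back to the
  true breakpoints (rare outside sub-100 bp calls).
- Records with unresolvable ends, non-DEL/DUP types, or sub-minimum
  sizes are skipped and counted (lenient default) or abort the parse
  (`strict`).
- Multi-allelic population AF collapses to its maximum component,
  matching the "maximal allele frequency of overlaps" semantics.
- Support fractions are alt/(alt+ref) from caller count fields; when
  reference counts are absent the fraction stays unset rather than
  guessed.
- Thresholds compare as printed: support fraction strictly `>`,
  adjusted p strictly `<`, population AF strictly `>` for removal.

## Problem sizes

Default test fixtures use cohorts of 30–500 truth calls on 30–50 Mb
contigs; the parameter-recovery experiment and the acceptance script
use 2000 truth calls per seed on the full autosome-scale genome with
5 FP/Mb (~14,500 false calls per caller), 20 seeds for the recovery
experiment — sizes chosen to put Monte-Carlo error well below the
effects being measured while keeping a full run in minutes on one CPU.

## Known limitations

- One-to-one greedy matching can differ from maximum-cardinality
  matching on adversarial overlap chains; the oracle tests pin the
  greedy semantics, not an optimality claim.
- Union merging is priority-ordered, not transitive-closure; see
  above.
- The ERDS dialect assumes VCF-like output; non-VCF ERDS exports
  should be converted to BED/TSV and read with the generic reader.
- Breakend-level evidence (inversions, insertions, translocations) is
  out of scope by design.
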
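# Methods

## Model and assumptions

`hspscan` performs ungapped local alignment of two DNA sequences by
seed-and-extend.  The underlying model is the classical high-scoring
segment pair: a run of aligned columns on one diagonal (x − y constant;
on the reverse strand, x + y constant in forward-Y coordinates) whose
additive score — +w_m per identical column, −w_x per mismatching column
— cannot be improved by extending or trimming either end.  Gaps are
never opened during extension; collinear fragments can be grouped after
the fact (see *Chaining*).

The design assumption throughout is that sequences may be large but
seeds are sparse once the word length is chosen sensibly: all quadratic
work is confined to the per-word cross products, which the sampling cap
bounds, and all index structures live on disk in fixed-width
little-endian records so results are identical across platforms.

## Dictionary construction and the memory contract

The dictionary of a sequence of length L holds every clean K-window
(windows containing any non-ACGT letter are skipped whole) with its
ascending occurrence positions, in strictly ascending word order.  The
2-bit letter code is order-preserving, which makes "sorted by packed
integer" and "sorted lexicographically" the same thing; this is what
lets a single K = 32 dictionary stand in for every K' < K dictionary by
prefix merging (only the last K − K' window positions of the sequence
are invisible at K and are lost from the derived stream).

Construction makes p full passes over the sequence, keeping only
windows whose leading log4(p) letters have rank i on pass i.  The
contract is observable, not mechanical: at most one partition's entries
are in memory at any time, and the concatenated passes are globally
sorted.  Any internal tactic meeting that contract is conforming; this
implementation vectorises each pass (sliding-window packing, stable
sort, group-by) rather than maintaining a literal search tree, because
the sorted on-disk result is the artifact that matters.  p must be a
power of 4: the partition prefix must be a whole number of letters, or
the partitions would not be contiguous lexicographic ranges.

Degenerate inputs: an all-N sequence yields a valid zero-entry
dictionary; L < K yields the same; L = K yields one entry.

## Seeding, sorting, thinning

Hits are produced by a sorted merge-join of the two K'-word streams and
sorted by (diagonal, x).  The sort is a deterministic single-process
lexsort; (d, x) determines (x, y), so the order is total.

*Proximity combining* drops a hit whose x lies within `distance` of the
last kept hit on the same diagonal, keeping the earliest hit of each
cluster.  Cluster-collapse-to-first is the chosen reading of "combining"
nearby seeds: the retained seed triggers the same extension that any
member of the cluster would, so for overlapping seeds the HSP output is
unchanged.  `distance = 0` disables the filter and is the default.

*Sampling* applies per shared word: if one word's cross product exceeds
`cap` hits, only the equally spaced ranks ⌊t(nm−1)/(cap−1)⌋,
t = 0…cap−1, survive (first and last pair always kept).  The "area" the
cap governs is deliberately the single word's cross product — that is
exactly where low-complexity repeats explode quadratically, and
per-word capping bounds them without touching unique sequence.  Capping
can drop whole minor diagonals of a repeat's alignment parallelogram
(each sampled diagonal still extends to the full repeat span), so the
guaranteed invariants are: the sampled HSP set is a subset of the
uncapped set, and the column coverage of the repeat locus is preserved.
The tests assert precisely those.

Defaults: K' = 16, distance = 0, cap = 10 000.  K' = 16 keeps the
expected chance-seed count LxLy/4^K' negligible for megabase pairs
while retaining sensitivity to ~90 % identity homology; smaller K'
(tests mostly use 12, or 8 against brute-force oracles on 1 kb pairs)
raises sensitivity at quadratic cost in seeds.

## Extension rule and numerical choices

Extension starts from the seed's score (K'·w_m, always positive) and
walks one column at a time, stopping when the running score becomes
negative or a sequence end is reached — the literal stop rule, not an
X-drop from the running maximum.  Each boundary is the *earliest*
column attaining the directional maximum; the strict-improvement
tie-break trims zero-score tails (e.g. alternating match/mismatch at
equal weights).  The backward pass restarts from the seed score alone;
the two directional maxima combine as best_fwd + best_bwd − seed.

Default weights are +4/−4.  Columns involving N never match, including
N–N.  Score and identity are recomputed from the final coordinates and
asserted against the accumulation, so reported fields are
self-consistent by construction.

Coverage skipping is per diagonal only, as the redundant-sub-fragment
argument requires; overlapping HSPs on different diagonals are all
reported.  On random-pair oracle tests (seeding at *every* exact match,
no skipping) the skipped seeds never remove a fragment, confirming the
redundancy argument empirically at this scale.

Report thresholds default to min length = K', min score > 0, min
identity 0; recovery experiments use min length 32 (the CLI's
documented setting for genome-scale comparisons) because at K' = 12 a
10 kb random background produces a handful of chance seed-length
fragments that are alignment-correct but not homology.

## Chaining

The ungapped fragments can be grouped into gapped constructions by a
transparent greedy rule: walk same-strand fragments in (x, y) order; a
fragment joins the open chain when both its x-gap and y-gap to the
chain tail lie in [0, max_gap], else it opens a new chain.  Gaps carry
no penalty, and a chain's gap-column count is the sum over junctions of
the larger axis gap.  This is a declared simple stand-in for full
gapped alignment: it partitions its input, is order-deterministic, and
makes no optimality claim.

## Synthetic data: what it does and does not show

The fixtures module generates i.i.d. uniform backgrounds at a chosen GC
fraction and plants copies of X intervals into Y — forward or
reverse-complemented — mutated by independent per-column substitution
to a target identity.  Mutations are substitutions only, so planted
segments stay on one diagonal and ungapped recovery is exactly defined;
chaining is exercised on constructed collinear fragments rather than
planted indels.
Tandem-repeat planting creates the shared high-multiplicity words that
the sampling cap exists for.

What passing these tests shows: stage-exact agreement with brute-force
oracles, correct strand/coordinate bookkeeping, and recovery of planted
homology at the stated lengths and identities.  What they do not show:
behaviour on real genomes — compositional bias, interspersed repeat
families, segmental duplications, indel-rich divergence — nor anything
about wall-clock performance at chromosome scale.

Recovery experiments use 10 kb backgrounds with four planted segments
(300–500 bp, 90–95 % identity, both strands), K' = 12, weights +4/−4,
8 replicates.  Coverage is asserted per segment per replicate (≥ 90 %);
specificity (fraction of reported HSP columns inside planted intervals)
is pooled over replicates' columns, because the dominant error source —
a boundary overshooting a segment end when background happens to open
with a net-positive excursion, probability ≈ 1/3 per end at +4/−4 —
makes the per-replicate ratio noisy around its ≈ 99.4 % expectation
while the pooled estimate is stable.

## Known limitations

- K ≤ 32: the on-disk format reserves exactly 64 bits per word.
- The stop rule is the literal "running score < 0", so extension can
  scan far past the eventual boundary inside long high-scoring regions;
  an X-drop variant would bound that scan but is deliberately not what
  this tool implements.
- Chaining is greedy and gap-blind; it is a reporting convenience, not
  an alignment.
- Only the first record of a multi-record FASTA is used (warning
  logged); the pipeline is strictly pairwise.
- Single process by default; the sort and the partition passes are
  trivially parallelisable but determinism is valued over speed here.
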
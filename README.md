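# hspscan

Out-of-core seed-and-extend comparison of two DNA sequences: disk-based
k-mer dictionaries, exact-match seed hits, maximal ungapped high-scoring
segment pairs (HSPs) on both strands, and dotplot visualisation.

`hspscan` is aimed at pairwise genome comparison where the index
structures are too large to hold in main memory: every stage persists
its result to disk in a fixed, endianness-safe binary or text format, so
dictionaries are built once per sequence and reused across comparisons
and parameter sweeps.

## Method

**Dictionary.** For each sequence the tool records every K-letter word
(default K = 32) and its 0-based occurrence positions.  Words are packed
at 2 bits per letter with an order-preserving code (A=00 < C=01 < G=10 <
T=11, first letter most significant), so a 32-mer fits in one 64-bit
integer and sorting packed codes sorts the words lexicographically.
Construction runs in p passes (p a power of 4, default 16): pass *i*
scans the sequence and collects only the windows whose leading log4(p)
letters have rank *i*, so peak memory is bounded by one partition's
distinct words and the concatenated passes form a globally sorted
dictionary.  Windows containing N are skipped; positions stay global.

**Prefix property.** A sorted dictionary at word length K contains every
shorter dictionary: merging adjacent entries that share their first K'
letters yields the K'-word index, losing only the last K − K' window
positions of the sequence.  The seed length K' ≤ K is therefore a free,
per-run parameter — one dictionary build serves every K'.

**Seeding.** If a shared word occurs n times in X at positions p_j and m
times in Y at positions p_k, every pair (p_j, p_k) is a seed hit with
diagonal d = p_j − p_k.  Hits come from a sorted merge-join of the two
K'-word streams, are sorted by (d, offset), and can be thinned two ways:
a per-word cap keeps at most `cap` equally spaced pairs of a word's
cross product (low-complexity repeats otherwise contribute n·m hits),
and a proximity distance collapses clusters of hits on one diagonal to
their first member.

**HSP extension.** From each surviving hit the fragment grows in both
directions, adding a match weight (+4) per identical column and
subtracting a mismatch weight (−4) otherwise, until the running score
drops below zero or a sequence end is reached; each boundary is the
earliest column at which the running score peaked.  A hit inside the
span of the previously accepted HSP on the same diagonal is skipped — it
could only reproduce a sub-fragment.  Reverse-strand fragments are found
by running the same pipeline against the reverse complement of Y and
mapping coordinates back (y_fwd = Ly − 1 − y_rev), so they plot as
anti-diagonal segments.  Each HSP reports start/end in both sequences,
strand, length, score, and percent identity.

**Post-processing.** Threshold filters, greedy collinear chaining into
gapped constructions, PNG dotplots (forward red, reverse black,
multi-comparison projection over a shared reference), and text
converters (CSV / TSV / BED-like).

## Worked example

Plant two homologous segments — 500 bp at 95 % identity forward, 400 bp
at 90 % identity reverse — into a synthetic 10 kb pair, and compare:

```python
from hspscan import Params, compare_both_strands
from hspscan.fixtures import random_sequence, plant_homology, evaluate_recovery

x = random_sequence(10_000, seed=11, id="X")
y, truth = plant_homology(
    x, [(500, 95.0, "f"), (400, 90.0, "r")], seed=12, background=1500
)
params = Params(k=16, k_seed=12, match=4, mismatch=4, min_length=32)
hsps = compare_both_strands(x, y, params)
for h in hsps:
    print(f"{h.strand}  x:{h.x_start}-{h.x_end}  y:{h.y_start}-{h.y_end}"
          f"  len={h.length}  score={h.score}  id={h.identity:.1f}%")
r = evaluate_recovery(hsps, truth)
print(f"coverage={r['mean_coverage']:.3f}  specificity={r['specificity']:.3f}")
```

prints

```
f  x:2975-3475  y:1500-2000  len=501  score=1796  id=94.8%
r  x:6543-6942  y:3899-3500  len=400  score=1216  id=88.0%
coverage=1.000  specificity=0.999
```

One forward and one reverse HSP, each landing on its planted segment
(the reverse fragment's y runs 3899 → 3500, i.e. along the complement).
The measured identities sit at the planted mutation rates, the fragments
cover the planted columns completely, and 99.9 % of reported columns lie
inside the planted intervals.

The same comparison from the shell:

```sh
hspscan run x.fa y.fa --workdir out/ --kprime 12 --min-length 32
```

writes `out/hsps.csv` and `out/dotplot.png`, persisting dictionaries and
hit files with JSON parameter sidecars; a second run skips every
up-to-date stage, and changing only `--kprime` reuses the dictionaries.
Individual stages are exposed as `hspscan dict | hits | hsps | filter |
chain | plot | export | synth | dict-stats`.

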
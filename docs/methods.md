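# Methods

## The maximal sequence landscape

A *mountain* is one occurrence (begin, end, freq) of a substring of the
input that occurs at least twice, overlaps counted; its height is its
length. The *cover set* of position *i* holds every mountain with
height > 1 **and** frequency > 1 whose span contains *i* (both
conditions are required; single characters never count). The *summit*
of *i* is a highest mountain of the cover set, and the maximal sequence
landscape (MSL) is the array of summit heights, 0 where the cover set
is empty. Note heights are therefore never 1.

### Construction

The builder prepares the suffix array (numpy prefix doubling — one
`lexsort` round per doubling, O(n log² n) total, which is negligible at
the problem sizes this package targets), the LCP array (Kasai's O(n)
scan), the inverse permutation, the ψ array `sp[r] = inv[sa[r] + 1]`
(rank of the suffix obtained by deleting the first character), and a
sparse-table range-minimum structure over LCP.

The sweep maintains, for the current text position, the longest
repeated substring ending there together with its suffix-array interval
[sa_lo, sa_hi] — the interval invariant is that exactly the suffixes
prefixed by that substring lie inside it, so the interval width is the
substring's frequency. Appending the next character is an *ascent*: a
binary search for the sub-interval whose suffixes carry that character
at the right offset, accepted when its width is ≥ 2. When the ascent
fails, *descents* drop the leading character one at a time: one ψ
lookup moves to a suffix of the shortened string, and the maximal LCP
interval ≥ the shortened length around it (two binary searches over the
RMQ, O(log n)) recovers the full interval. If the string empties, the
interval resets to the whole array and the position's height is 0.
Ascents consume one character each and descents only undo ascents, so
ascents + descents ≤ 2n; the counters are kept on the result
(`MslIndex.state`) and asserted in tests.

The sweep yields, per position *i*, the longest repeated substring
*ending* at *i*. Per-position summits are then the interval-maximum
over these end-anchored mountains, computed right-to-left with a lazy
max-heap. Any summit candidate is necessarily end-anchored: a covering
mountain of maximal height whose end carries a longer repeat would be
dominated by that longer repeat.

Ties at the maximal height are resolved to the occurrence with the
smallest begin, giving bit-identical output on identical input. The
heap key (−height, begin) realizes this directly.

### Oracle

`brute_force_msl` is an independent exhaustive-counting construction
used only in tests: for substring lengths ascending from 2 it hashes
every window, stamps positions covered by a window seen ≥ 2 times
(longer lengths overwrite), and stops at the first length with no
repeat. A per-length watermark makes stamping linear and reproduces the
smallest-begin tie-break, so sweep and oracle are compared for *exact*
equality — heights, spans and frequencies. It refuses inputs beyond
2,000 bases; low-complexity strings (e.g. a uniform run, whose longest
repeat is n − 1) are its quadratic worst case and stay under a few
seconds at that bound.

## k selection

k\* for one alignment is 1 + the maximum MSL height over the bases the
read covers, [p, p + l − 1]; a window running past the record end is
clamped. The natural alternative bound p + l indexes one base past the
read, which does not exist for a read ending on the last base, so the
covered-bases window is used. Reverse alignments reverse-complement the
read handed to assembly but look up the same reference window — a
repeat under the window is a repeat regardless of strand read
orientation.

The read's k is max over its K\* set (primary and secondary alignments;
supplementary records are skipped). Defaults: k = 77 when max K\*
exceeds the read length (the read lies inside a repeat longer than
itself, so no k within the read can disambiguate it), k = 55 for
unaligned reads. Both are configurable, as is an optional floor and an
opt-in odd-k rounding (nothing in the method requires odd k, so parity
is not forced). Since a de Bruijn graph needs k ≥ 2, assignments are
floored there unconditionally — relevant only for references with no
repeats at all under a window.

Known limitation: the landscape is built on the forward strand of the
reference only. A substring whose reverse complement occurs elsewhere
is a repeat in the double-stranded sense and will branch a canonical
de Bruijn graph, but does not raise the MSL. At realistic k this is
vanishingly rare; at very small k the assembler's own cleanup absorbs
it.

## Iterative assembly

Reads are bucketed by assigned k. Rounds run over the *occupied* k
levels ascending (an empty level would only re-condense the same
input); round k assembles the union of buckets ≤ k plus the previous
round's contigs. The per-round assembler:

- counts canonical k-mers (a k-mer and its reverse complement are one
  object — the community norm for double-stranded data); sequences
  shorter than k are skipped with a logged count;
- removes k-mers with multiplicity below the cutoff (default 5).
  Contigs fed forward from the previous round are exempt: they are
  trusted input whose own multiplicity is 1 by construction, and the
  cutoff would delete them;
- builds the doubled-orientation graph over (k−1)-mer nodes and
  extracts maximal non-branching paths. A walk never follows an edge
  with that edge's own reverse complement: without this standard
  bidirected-graph rule, a dead end on a palindromic (k−1)-mer at a
  coverage boundary lets the walk turn onto the opposite strand and
  emit a hairpin chimera W + rc(W);
- clips tips — dangling unitigs shorter than 2k — but only when a
  strictly better-covered sibling edge exists at the junction they
  hang off. An unconditional rule would also delete genuine short
  terminal unitigs severed from the backbone by an error branch.
  Isolated short contigs and short junction-to-junction links are
  kept. No bubble popping is attempted: this is deliberately the
  minimal error-removal stack, not a production assembler's;
- reports contigs deduplicated across strands in canonical orientation,
  ordered by (length descending, sequence) — assembly is fully
  deterministic.

With k = repeat length + 1, a two-copy maximal repeat is one shared
(k−1)-mer node; unitigs through it overlap by the whole repeat, so the
assembly yields three contigs per planted repeat region (left + repeat,
repeat + middle + repeat, repeat + right) against four from a fixed
k below the repeat length — and, unlike the fixed-k result, the three
contigs jointly reconstruct the genome without a misjoin.

## The simulator

The generator emulates the study conditions used throughout the tests:
a uniform-random nucleotide genome (default 2,000 bp) with planted
exact repeats (default one 40 bp repeat, two copies), error-free reads
(default 100 bp) sampled uniformly from both strands at fixed fold
coverage (default 30×), and the truth alignments as SAM. Design
choices:

- copies are made *maximal* by forcing pairwise-distinct flanking bases
  (hence at most 4 copies per repeat unit), so the planted repeat — and
  nothing longer — dominates the landscape over its span;
- copies are placed at least a read length away from the genome ends:
  coverage ramps down over the terminal read_len bases, and a repeat
  copy that reads cannot span would not exercise the behaviour the
  repeat is planted to probe;
- one seeded generator drives genome, placement, read sampling and
  errors; identical spec + seed gives byte-identical files.

What it does not model: sequencing errors are plain substitutions
(default off), there are no indels, no quality profile, no paired-end
inserts, no coverage bias, and the reference equals the sample genome —
so passing tests demonstrate the machinery and its guarantees under the
method's own assumptions, not performance on real divergent data.

## Numerical and degenerate-input conventions

- All internal coordinates are 0-based; files and reports are 1-based
  and say so in a header.
- The sentinel is an integer code below every symbol, appended
  internally and never user-visible. Lowercase input is uppercased; `N`
  is an ordinary symbol (a run of N therefore repeats — documented
  behaviour).
- An LCP-interval query for a prefix longer than the suffix returns a
  defined empty result (`None`) rather than failing.
- Multi-record references get independent landscapes by default; a
  concatenation mode joins records with pairwise-distinct separator
  symbols so between-record repeats count, then slices the heights back
  per record.
- NG50 is 0 when the assembly never reaches half the genome; the empty
  contig set yields all-zero statistics with a warning.
- Problem sizes in tests and the acceptance script (strings ≤ 2,000,
  ten 2 kb simulations) were chosen so the whole suite re-runs in a few
  minutes on one core while still exercising every code path at full
  strength.
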
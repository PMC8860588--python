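# Methods

This note records the models, conventions and numerical choices behind
`g4kit`, and what the synthetic benchmarks do and do not demonstrate.

## Motif model

Four PQS classes are scanned. The canonical intramolecular motif is four
runs of at least three guanines separated by loops of 1–7 nt
(G₃₊L₁₋₇×3 G₃₊); the extended class relaxes loops to 1–12 nt; the
two-tetrad class uses runs of exactly two guanines with loops of 1–12 nt
and at least four runs. The two-tetrad pattern is deliberately read as a
repeated (run + loop) group, `(G{2} L{1,12}){3,} G{2}`: a direct nesting of
the two quantifiers (`G{2}L{1,12}{3,}G{2}`) is not a well-formed pattern,
and the repeated-group reading is the only self-consistent one. Because the
run is written `G{2}` rather than `G{2,}`, surplus guanines are absorbed by
the greedy loops, which is exactly what a backtracking regex engine does.

Inter-strand motifs distribute the four runs over both duplex strands.
With A = G₃₊ (run on the reference strand) and B = C₃₊ (run on the
opposite strand) the eight A-leading compositions AAAA, AAAB, AABA, AABB,
ABAA, ABAB, ABBA, ABBB are scanned; B-leading strings are the
reverse-complement duals of these and would double-count. Loops are 1–7 nt,
inherited from the canonical motif the scheme extends. AAAA coincides with
the canonical motif and reports strand `+`; all mixed compositions are
unstranded. A 1 nt minimum loop is enforced at every block junction,
including strand switches.

Loops draw from {A, C, G, T} only. `N` neither extends a run nor counts as
loop sequence, so assembly gaps cannot inflate calls (a `\w`-style loop
class would accept `N` and underscore artifacts).

### Matching semantics and strand conventions

Default matching is leftmost, greedy and non-overlapping per strand —
the semantics of a backtracking regex engine, which is what practitioners
get from scanning a genome with a regular expression. An `overlapping`
mode enumerates every distinct (start, end) placement by dynamic
programming over block starts and loop lengths; it exists for containment
checks (every canonical placement is an extended placement because
L₁₋₇ ⊂ L₁₋₁₂) and for oracle tests.

Left-to-right non-overlapping selection is not automatically symmetric
under reverse complement: when an odd chain of runs admits two maximal
tilings, a forward scan keeps the left one and a reverse scan the right
one. To make strand symmetry a theorem rather than an accident, minus-
strand matches are *defined* as the G-pattern scan of the reverse
complement mirrored back into reference coordinates (equivalently: the
minus strand is read 5′→3′, as a biologist would). For inter-strand
compositions each dual pair {X, reverse-complement dual of X} is scanned
in one canonical orientation — the lexicographically smaller member
forward, the other by mirroring — so the composition-swap symmetry
(AAAB ↔ ABBB) is exact. The two self-dual compositions (AABB, ABAB) scan
forward; their mirror symmetry can in principle differ in rare ambiguous
tilings, but holds exactly on the test fixtures. In every non-ambiguous
situation these conventions coincide with scanning the C-pattern forward.

## Peak statistics

Replicate consensus defaults to bp-intersection of the replicates' merged
unions (every reported base is covered in every replicate); a
whole-peak mode ("first-overlap-all") keeps the peaks of the first
replicate overlapping all others, since interval tools are used both ways
in practice. Top-N ranking uses the BED column-5 score with
(chrom, start) tie-breaking for determinism. State annotation assigns
each peak to the chromatin state with maximal bp overlap, ties broken by
segmentation order; fractions are over assigned peaks.

The overlap significance test relocates each subject interval uniformly
within its own chromosome, preserving lengths and forbidding
self-overlap (rejection sampling), and reports the add-one empirical
p-value p = (1 + #{null ≥ observed}) / (n_iter + 1). This within-
chromosome shuffle is a deliberate, documented approximation of
heavier-weight randomization frameworks; with more than one comparison,
Benjamini–Hochberg correction over the family is available. The
statistic is an integer count, so p-values carry ties and are slightly
conservative; the calibration benchmark sizes its interval sets (300
intervals of 200 bp over 300 kb) so the statistic has enough spread for
the tie effect to be negligible.

## Coverage and metrics

Fragments (not reads) are the coverage unit, since tagmentation yields
paired-end fragments; a SAM adapter converts proper pairs when needed.
Raw coverage is mean per-bp fragment depth per bin (default 5 bp bins);
RPGC multiplies by effective-genome-size / total fragment bp so the
genome-wide mean is 1 within 1/bin-size relative tolerance (final bins
are zero-padded). The effective genome size is always explicit — no
hidden species table.

FriP is a per-fragment overlap test and therefore invariant under peak
merging. The fingerprint curve sorts bins by ascending fragment count
(midpoint assignment) and plots cumulative signal share; it is invariant
to chromosome order and permutations of equal bins. Telomeric content is
estimated by tandem-unit string matching — a read counts if it contains
at least `min_tandem` (default 3) consecutive copies of TTAGGG or its
reverse complement — a deliberate, orientation-invariant approximation
of aligning against a telomeric pseudogenome; three consecutive units
roughly mirror an aligner's seed requirement.

The toy peak caller thresholds bins at mean + z·sd of the *nonzero* bins
(sparse tagmentation leaves most bins empty; a global sd would be
deflated), merges runs across gaps ≤ `merge_gap` bins, drops runs shorter
than `min_run`, and scores peaks by fold over the genome mean (×100,
capped at 1000). It is plumbing that closes the synthetic pipeline, not a
statistical model; the default z = 3 is conservative, and the end-to-end
benchmark runs it at z = 2 so all ~100 implanted sites are called.

## Spike-in scaling

Scale factors are ratios of deduplicated spike-genome fragment counts,
factor_s = count_reference / count_s, with the first sample as default
reference. Scaling equalizes spike totals across samples exactly and, in
simulation, preserves a 2× genuine signal difference that naive RPGC
normalization erases — the rationale for quantitative spike-in
normalization.

## Synthetic data: what it emulates, and what not

Defaults: three 100 kb sample chromosomes plus one 20 kb spike chromosome
(`dm_` namespace), GC 0.4, 25 sites per motif class (the 25 interstrand
sites cycle through the 8 compositions), enrichment fold 20, fragment
lengths N(150, 30) clipped to [30, 1000] (at these parameters the bounds
are > 4σ away), 100 000 fragments, 5% spike-in, mung-bean residual factor
0.15.

Background is drawn i.i.d. with rejection resampling so that no G or C
run of length ≥ 3 ever occurs. This suppression is what makes truth equal
scanner output: canonical, extended and inter-strand false positives on
background are structurally impossible, and implant recovery can be
asserted at exact-interval precision. Implants are flanked by 15 bp A/T
guard bands (longer than the longest loop) so greedy matching can never
extend across an implant boundary; extended implants always carry one
loop longer than 7 nt so they are not simultaneously canonical hits.
Two-G runs *do* occur in background, so two-tetrad matches on background
are possible and expected — only their interference with recorded truth
intervals is excluded by the guard bands.

A fragment is spike-in with probability `spike_fraction`, otherwise
signal with probability p = E/(E+1) for enrichment fold E ("drawn with
probability proportional to the fold against one unit of background"),
else uniform background. Signal fragments centre on a uniformly chosen
truth site with Gaussian offset whose sd is the fragment's own length.
Mung-bean mode multiplies the truth-site draw probability by the residual
factor (default 0.15), reproducing the direction — roughly half or more
of truth-window FriP lost — of nuclease pretreatment. With the default
geometry the ±500 bp truth windows cover ~34% of the genome, so window
FriP saturates near 1 under strong enrichment; enrichment strength is
therefore quantified as in-window vs out-of-window fragment *density*
(≥ 5× at defaults, ~60× observed), which is the well-defined form of the
window-FriP comparison at this site density.

The generator does not model Tn5 insertion bias, nucleosome structure,
read errors, duplicate fragments or replicate-to-replicate biological
variability. Passing benchmarks therefore demonstrate the correctness of
the *computations* (scanning semantics, normalization algebra, factor
recovery, calibration of the permutation p-value) — not that real
libraries look like the simulation.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeded from the
configuration; identical seeds give byte-identical FASTA/BED/JSON output.
The benchmark suite uses 50 random 10 kb sequences for scanner–oracle
equivalence, symmetry and containment; the default 300 kb genome with
100 implants and 100 000-fragment libraries for recovery, normalization,
spike-in and depletion checks; 200 simulated dataset pairs at 199
shuffles each for calibration; and 100 000 reads at 0.2% telomeric
content for the telomere estimator. These sizes were chosen to make every
property measurable with comfortable statistical margins on a single CPU.

## Known limitations

- The scanner targets sequence motifs only; no thermodynamic scoring
  (G4Hunter-style), RNA G4s, or bulged/imperfect runs beyond the
  two-tetrad class.
- bigWig output is not produced; bedGraph is the exchange format.
- The within-chromosome shuffle null ignores mappability, GC and
  chromatin-state structure of real genomes.
- Self-dual inter-strand compositions rely on forward-scan orientation;
  their mirror symmetry, while exact on all tested inputs, is not
  guaranteed by construction (see Matching semantics).
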
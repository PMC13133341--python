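# Methods

This note documents the models and procedures implemented in `breakscape`,
the conventions and defaults that required a decision, and what the
synthetic benchmarks do and do not demonstrate.

## Coordinate and sequence conventions

All internal coordinates are 0-based half-open `[start, end)`. VCF positions
are converted once at the parse boundary (`pos0 = pos1 − 1`) and can be
asserted against the genome base. FASTA input is upper-cased and every
non-ACGTN character becomes `N` (gaps are data, not errors); `N` fails every
motif position and breaks G-runs, so annotations never extend into gaps.
bigWig is deliberately unsupported: bedGraph is text and makes bit-exact
tests possible.

## Small-sample tests (`stats`)

* **Wilcoxon rank-sum.** Exact p by enumeration of all C(n, n₁) rank
  assignments when n₁+n₂ ≤ 12 and the pooled sample has no ties; otherwise
  a normal approximation on midranks with tie-corrected variance
  Var(W) = n₁n₂/12·[(n+1) − Σ(tⱼ³−tⱼ)/(n(n−1))] and a 0.5 continuity
  correction. The switch point keeps enumeration trivial while the
  approximation is already within 0.02 of exact at n₁=n₂=6. Results carry
  an `exact` flag so the path taken is always visible.
* **Fisher 2×2.** Two-sided p sums hypergeometric probabilities ≤ the
  observed table's probability, with relative tolerance 1e−7 for
  floating-point ties; a zero margin means only one table is possible and
  p = 1 (flagged degenerate).
* **Mood's median test.** Both samples are dichotomized at the pooled grand
  median; values *equal* to the median count as "not greater" in both
  groups (a convention that must be fixed for reproducibility; this is the
  conservative one), then Fisher's exact test is applied.
* **Binomial.** Exact tail sums; the two-sided p sums the probabilities of
  all outcomes no more likely than the observed one.
* **Multiple testing.** Bonferroni only: p·m capped at 1, with m supplied
  by the caller (the number of feature sets compared).

All exact paths are checked against scipy's independent enumerations to
1e−9 over exhaustive small grids.

## Sequence annotation (`motifs`)

Motif scanning expands IUPAC codes to base sets and reports *all* matches,
including overlapping ones; density tracks count a match in the bin of its
start and divide by the bin width, so Σ(track)·bin_width equals the match
count exactly. Collapsing overlapping matches is available as an option but
off by default — counting all occurrences is the reproducible choice when no
collapsing rule is specified. Minus-strand matches are found by scanning the
reverse complement of the pattern on the plus text and reported in plus
coordinates with strand "−".

G-quadruplex annotation is rule-based, not thermodynamic: a match is at
least `min_runs` (4) runs of at least `min_run_length` (3) consecutive G
separated by loops of 1–`max_loop` bases (7 = stringent, 30 = relaxed).
Runs are maximal, loops must be ≥ 1 (runs are separated by construction),
and matches are the maximal chains of runs found greedily left to right, so
counts are well-defined. Minus-strand quadruplexes are C-run chains on the
plus text. Relaxed coverage is a superset of stringent coverage on any
sequence (loop condition is strictly weaker).

## Breakpoint meta-analysis (`breakpoints`)

Merging uses book-ended-intervals-merge semantics (end == start merges) and
drops strand. Meta-profiles reduce anchors to midpoints and average track
values at bin offsets −K..K around them (defaults: 100 kb half-window, 1-kb
bins; both configurable); anchors whose window leaves the chromosome are
dropped and counted. The background profile applies the same computation to
pooled chromosome-preserving shuffles.

The shuffle preserves, per chromosome, the count and lengths of the input
intervals, placing starts uniformly with no overlap avoidance — preserving
the chromosomal distribution is the only constraint imposed. Distance to
the nearest feature is max(f.start − q.end, q.start − f.end) floored at 0,
so overlap and book-ending both give 0. The proximity test pools the
distances of all shuffle draws (default 100) into one null sample and
compares observed vs. null with a two-sided Wilcoxon; pooling matches a
direct observed-vs-randomized comparison and maximizes null resolution.

The relative-distance statistic uses feature *midpoints*: for a query
midpoint q with flanking feature midpoints L ≤ q < R, reldist =
min(q−L, R−q)/(R−L) ∈ [0, 0.5], uniform under independence, tested by
Pearson χ² against equal bin counts (10 bins). Queries outside the feature
span are excluded and counted.

## SHM strand asymmetry (`shm`)

The somatic filter is set-algebraic: a variant keyed by
(chrom, pos, ref, alt) is somatic for a sample iff it appears in no other
tumor sample and no control. Quality-based call filtering is upstream of
this package. Cytidine mutations are ref-C (mutated C on plus, c_strand
"+") or ref-G (mutated C on minus, c_strand "−"); all three substitutions
of C qualify. A mutation inside genes of exactly one strand is
**non-template** when c_strand equals the gene strand, **template**
otherwise; positions outside genes or inside antisense-overlapping gene
pairs are unassigned rather than double-counted (the loss is reported).
The bias n_NT/(n_NT+n_T) is tested with the exact binomial against 0.5.

Directional profiles read, per mutation, the stranded-track component
matching c_strand as *sense* and the opposite as *antisense*, with offsets
oriented 5′→3′ along the c_strand (minus-class windows are reversed). Gene
annotation, not signal direction, defines orientation — the annotation is
the ground truth available in the synthetic setting and the less circular
choice on real data.

## Junction microhomology (`microhomology`)

Microhomology is junction shift-ambiguity, the standard breakend-homology
definition of SV callers: with D the retained sequence ending at breakend A
and A′ the retained sequence starting at breakend B (reverse-complemented
as needed so both read 5′→3′ across the junction), `left_shift` is the
longest shared suffix of D and the bases upstream of A′, `right_shift` the
longest shared prefix of A′ and the continuation past D. Matches are exact
(homeology is out of scope) and capped at `max_scan` = 50 bp, far above
biological microhomology lengths; chromosome-edge truncation sets the flag
rather than erroring. Totals are invariant to swapping the two breakends.
Group summaries report both median and mean, plus pairwise Wilcoxon tests.

## Mutational signatures (`signatures`)

Spectra use the standard 96-class pyrimidine-centred order (C>A, C>G, C>T,
T>A, T>C, T>G × 16 flank contexts, 5′ flank cycling slowest). Purine-ref
variants are reverse-complemented into this frame. Edge, N-context and
(when a region set is given) out-of-region variants are skipped and
counted; ref/genome mismatches are collected as per-record errors.

Exposure fitting is plain NNLS on the normalized spectrum; weights are
renormalized to sum to 1 and the minimized ℓ₂ norm is reported. No
bootstrap, sparsity pruning or trinucleotide-opportunity normalization is
applied — these are documented options deliberately left out of the core
fit to keep it transparent. The catalog is user-supplied data (TSV, first
column the class label), never baked into the code.

## DamID occupancy (`damid`)

Fragments are delimited by cuts at +2 inside every plus-strand GATC (the
enzymatic blunt GA^TC cut); a chromosome without GATC is one fragment, and
the map tiles each chromosome exactly. Reads are assigned to the fragment
containing their midpoint — unambiguous under half-open tiling. Counts are
scaled to counts-per-million per sample ("library size corrected" in its
minimal interpretation), the per-fragment mean over Dam-only samples is the
background, and corrected = normalized − background, which may legitimately
be negative. PROMPT regions are the 3 kb upstream and antisense of each
TSS, clipped at chromosome bounds. Region occupancy is the overlap-length-
weighted mean of corrected fragment values; enrichment between region sets
uses Mood's median test, which is robust to the heavy tails of corrected
coverage.

## Contact matrices (`contacts`)

Replicate matrices are summed before balancing. Balancing is iterative
proportional fitting in symmetric form: each iteration rescales rows and
columns by √(target/marginal), so the matrix stays symmetric throughout and
the result is F·M·F for a per-bin factor vector (masked bins get factor 0).
The marginal target is the mean unmasked marginal rather than 1, keeping
balanced values on the raw scale. Bins with zero marginal are masked before
balancing; convergence is max relative marginal deviation < 1e−8 within
1,000 iterations (non-convergence raises, carrying the last deviation).
Box quantification collects all unmasked entries linking two intervals and
reports their mean; group comparisons are pairwise two-sided Wilcoxon tests
on the pooled entries.

## Synthetic data (`simulate`)

Each generator derives its own stream from (master seed, stable label), so
adding a generator never perturbs another's output, and every generator is
byte-deterministic given its config. Planted elements are placed without
overlap by bounded rejection sampling (an error, not silent degradation,
when space runs out).

Defaults and what they emulate:

* genome: i.i.d. bases at GC 0.42 (mammalian-like), 2 × 500 kb — large
  enough for every context to be abundant, small enough for fast tests;
* transcription units: 40 non-overlapping stranded intervals, 2–20 kb;
* breakpoints: breakend A at |N(0, σ = 1 kb)| from a random feature edge
  (the planted proximity signal), partner uniform; null mode is uniform;
* SNVs: signature and 96-class drawn per mutation, position drawn from the
  genome positions matching the class context on either strand; cytidine-
  class mutations inside the gene model land on the non-template strand
  with probability `p_nontemplate` (default 0.7, the planted asymmetry);
* DamID: multinomial reads over fragments ∝ length; fusion samples multiply
  planted fragments by fold 4 before renormalization; 1 M reads/sample;
* contacts: M[i,j] = scale·(|i−j|+1)^(−α)·lognormal noise, symmetric,
  with a planted fold-3 box; α = 1, 2-kb bins.

What the synthetic data does **not** model: sequencing error, mappability
and repeat structure, realistic gene/isoform architecture, chromatin-state
correlations between tracks, PCR duplication, or copy-number variation.
Passing benchmarks therefore demonstrates algorithmic correctness and
statistical calibration under the generative assumptions, not performance
on real libraries.

## Benchmark sizes and numerical choices

The test suite and `scripts/acceptance.py` use: 1,000 random 10-kb
sequences for scanner/oracle agreement; exhaustive grids (all rank
assignments to n ≤ 10, all 2×2 tables with N ≤ 20, binomial n ≤ 20) for
exact-test agreement; 200 null + 100 biased replicates on a 10-Mb
chromosome for proximity calibration/power; 100 replicates for reldist;
50 seeds × 2,000 variants for strand-bias recovery; 1,000 junction
constructions for microhomology; 50 seeds × 10,000 mutations for signature
recovery; 1 M reads for DamID positivity plus 300 × 100-k-read simulations
for its test calibration; 20 random 50×50 matrices for IPF. These sizes
give stable rates (binomial s.e. ≤ ~3 percentage points on all reported
percentages) at desk-scale runtime.

Floating-point policy: p-values are clamped only within 1e−12 of [0, 1];
symmetry is restored after balancing by averaging M and Mᵀ (last-ulp
effects of elementwise scaling); spectrum/catalog sums are validated to
1e−9 (1e−6 for float-valued spectra).

## Known limitations

* The Wilcoxon exact path enumerates subsets and is intentionally limited
  to small samples; the asymptotic path is used everywhere else.
* Contact-matrix support is single-chromosome dense; genome-wide balancing
  and loop/TAD calling are out of scope.
* The gene model is flat stranded intervals; splicing and overlapping
  isoforms are not represented.
* Signature fitting does not model trinucleotide opportunity; exposures on
  strongly restricted region sets should be interpreted accordingly.
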
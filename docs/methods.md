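# Methods

## The competition model

A pooled screen is modeled as exponential growth in batch culture punctuated
by serial dilutions. Per-genotype fitness is parameterized directly on the
scale the estimator reports: the selection coefficient *s*, in log₂-fraction
change per hour, with the reference allele fixed at *s* = 0. Between
dilutions each genotype's cell count grows as

    N_g(t + Δt) = N_g(t) · 2^((r₀ + s_g)·Δt)

where r₀ is the reference growth rate in doublings/hour. The default is
r₀ = 0.25 (a ~2.8-h doubling, typical for budding yeast in rich medium);
since every pipeline quantity is a fraction or a fraction ratio, r₀ cancels
exactly and its value only matters when absolute cell numbers do.

The default schedule is Δt = 12 h for 6 cycles — timepoints 0, 12, …, 72 h —
with the t0 sample taken before any selective growth, then a
sample-and-dilute at the end of each cycle. The medium switch that starts
selection is idealized as "selection begins at t0"; pre-selection outgrowth
is absorbed into the initial abundances (equal by default, or a supplied
composition).

Stochastic layers, each optional and independently seeded per replicate
(numpy `SeedSequence` spawning, one stream per replicate):

- **dilution bottleneck** — a multinomial draw of the bottleneck size
  (default 10⁷ cells) over current fractions;
- **sequencing** — a multinomial draw of the read depth (default 10⁶
  pairs/timepoint; the real depth per sample is not standardized, this is a
  fixture choice) over current fractions;
- **base errors** — uniform per-base substitutions at rate ε in emitted
  reads, each error drawn from the three alternative bases.

With all layers disabled the simulator returns *expected* read counts as
real numbers rather than integers. This is deliberate: the noise-free pool
is the pipeline's core oracle (the estimator must return *s* to numerical
precision, observed < 10⁻¹⁵), and integer rounding would inject spurious
quantization error into that check.

The two-strain flow-cytometry assay is the pool's 2-genotype special case:
composition follows the logistic course p/(1−p) = odds₀·2^(s·t), measured by
a 5,000-cell binomial draw per timepoint.

## Sequencing readout and exact-match counting

Each allele's amplicon is the mutated region realized at the DNA level.
Read 1 is the first *L* bases of the amplicon, read 2 the reverse complement
of the last *L* bases (default L = 150); the amplicon must not exceed 2L so
that the pair observes every site. A pair is assigned to an allele only on
**joint exact equality** of both windows — no trimming, no quality use, no
mismatch tolerance. Failures are tallied by reason (mate-1 mismatch, mate-2
mismatch, malformed/non-ACGTN record); `N` never matches. Conservation
(assigned + discarded = pairs read) holds by construction.

Exactness makes error loss genotype-uniform — the expected matched fraction
is (1−ε)^(2L) for every allele — so errors shrink counts proportionally and
cancel in read fractions. For error loss to be *only* loss, no single
substitution may convert one allele's window into another's. The matcher
verifies global distinguishability at build time (duplicate joint keys are a
hard error), and the default codon replacements are chosen so that any two
site states differ at ≥ 2 of the six replaced bases, also against the
wild-type S/T-P codons (A-P → GCA·CCT, E-E → GAA·GAA). A single-base change
therefore never reaches another valid window, which the suite verifies by
10⁴ randomized corruption trials.

## Selection-coefficient estimation

Per sample, fractions are f_g = (c_g + q) / Σ_h (c_h + q) with a symmetric
pseudocount q (default 0.5, configurable including 0). The pseudocount
policy for zero counts is not standardized for this assay; the symmetric
form keeps fractions summing to 1, avoids −∞, and preserves depth
invariance up to the (tiny) pseudocount term. Per replicate, one unweighted
OLS line of log₂ f_g(t) against time is fit per genotype over **all**
timepoints (t0 included), and SC_g = slope_g − slope_reference. Replicates
are fit independently, then averaged (mean, SD with ddof = 1); a genotype
missing from a replicate contributes NaN there and the mean runs over the
replicates that have it. Fitting per replicate then averaging (rather than
fitting averaged fractions) keeps the replicate SD meaningful and matches
how triplicate screens are reported.

The enrichment matrix is E_g(t) = [log₂ f_g(t) − log₂ f_g(0)] −
[log₂ f_ref(t) − log₂ f_ref(0)]: identically 0 at t0 and along the reference
row. Algebraically, the OLS slope of E_g(t) equals SC_g (double centering
does not change a slope difference); the suite checks this identity
numerically.

Depth invariance: scaling all counts at one timepoint multiplies every
fraction by the same constant, shifting all log₂ fractions equally; the
shift is absorbed by the intercept and the reference subtraction, leaving
every SC unchanged (exact at q = 0, and for any q when the scaling is
applied to the adjusted counts).

## Library model and oligo design

A genotype is a plain string over {W, A, E} in N→C site order ("AAAEEAAA" =
E at sites 4 and 5), which serializes stably and keys every table. Library
enumeration is the Cartesian product of per-site allowed states in
lexicographic order. The reference allele need not be an enumerated member:
in the A/E screen the wild-type (all-W) allele rides along as a spike-in, so
the competed pool is the 256 members plus the reference, while enumeration
and the k-of-8 group partition cover the 256 members alone.

The tiling solver places n tiles over the region such that consecutive
overlaps fall in a configured range (default 21–27 bp) and **no phosphosite
codon pair intersects an overlap window** — the condition that makes every
variant of adjacent tiles anneal on identical overlap sequence, so the oligo
pool assembles the full combinatorial product without bias. The search is a
depth-first scan over cut points, leftmost-feasible at maximal overlap,
hence deterministic; infeasibility raises an error naming the obstructing
site when one can be identified. Assembly enumeration merges one variant per
tile on exact overlap equality; combinations whose overlaps disagree are
counted as assembly-impossible rather than silently dropped. Tiles are
modeled on the sense strand only — the alternating-strand anneal/extend
chemistry reduces combinatorially to overlap merging, and thermodynamics is
out of scope.

## Default scheme and synthetic region

The built-in scheme is the 8-site Hcm1 TAD. Five phosphoacceptor positions
are established (T428, T440, T447, T460, S471); the three C-terminal serines
are not numbered in the available descriptions, so the scheme assigns
placeholder positions 482/489/496 (labels S482/S489/S496) used only for
layout — they are flagged non-authoritative in the code. The region span
421–510 gives the 90 codons (270 bp) the tiling operates on. The region DNA
is **synthetic**: a deterministic sequence from a fixed one-codon-per-residue
table encoding correct S/T-P motifs at the scheme sites and a filler protein
(no S/T/P) elsewhere. It is a stand-in fixture, not the real gene sequence,
so tile coordinates and allele sequences are internally consistent but not
transferable to the real locus; supply the real region FASTA and true codon
replacements via the config to design against an actual gene.

## Group statistics

Groups pool replicate-level SC values (not per-genotype means): a k-of-8
group in a 3-replicate two-state screen holds C(8,k)·3 values, a per-site
group 2⁷·3. Quartiles use linear interpolation (numpy default, R type-7 — 
the `boxplot()` convention); whiskers extend to the most extreme value
within 1.5×IQR of the quartiles, points beyond are listed as outliers. The
cumulative curve is the right-continuous empirical CDF over all replicate SC
values. Medians and quartiles are cross-checked against a sort-based oracle
in the tests.

## Accessory assays

- Priming geometry: ordered site pairs where the upstream site is a
  threonine and the phosphoacceptor index difference lies in [12, 30],
  bounds inclusive. Spacing is a residue-index difference; pairs are
  reported N→C.
- β-galactosidase units: 1000·OD405 / (OD600 · volume[mL] · time[min]).
- Doubling time: OLS of log₂ OD against time restricted to the absolute OD
  window [0.2, 0.5] (bounds inclusive), doubling time = 1/slope; a
  non-positive slope reports ∞ (non-growing). The window is absolute, so the
  result is *not* invariant to rescaling OD — intentional, as the window
  targets a fixed exponential-phase density range.

## What the simulator does and does not emulate

It emulates: relative-abundance dynamics under constant per-genotype
fitness, dilution and sequencing sampling noise at realistic depths, and
uniform sequencing error. It does not emulate: time-varying fitness (e.g.
cell-cycle-phase coupling), PCR jackpots and chimeras, quality-score
structure, index hopping, or plasmid copy-number variation. Passing the
recovery suite therefore shows the *inference machinery* is correct and
well-conditioned at screen scale; it does not validate the biological
constancy-of-fitness assumption on real data, where curvature in
log₂-fraction trajectories is the symptom to inspect (per-replicate residual
sums of squares are reported for this).

## Problem sizes and numerical choices

The test and acceptance workloads use the screen's own conditions — 256
genotypes + reference, 7 timepoints, 3 replicates, 10⁶ pairs/timepoint,
10⁷-cell bottlenecks — at which the whole recovery analysis runs in seconds
because counting-level statistics need no per-read realization. FASTQ-level
checks (round trips, error-rate calibration) run at 10⁴–2×10⁴ pairs per
sample; the exactness claims they verify are depth-independent, and the
error-fraction check carries its own 3σ binomial band at the emitted depth.
OLS fits use `numpy.polyfit` (closed form; 7 points, 1 covariate). All
randomness flows through seeded numpy generators; replicates get independent
spawned streams, so adding replicates never perturbs earlier ones.
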
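# Methods

## The measurement being modelled

RISA/ARISA fingerprints a microbial community by PCR-amplifying the
intergenic spacer between the 16S and 23S rRNA genes and sizing the
products. The methanogen-specific primer pair used throughout anneals 202 bp
inside the 16S gene and 170 bp inside the 23S gene, so every product is
`spacer + 372 bp`; products of exactly 372 bp are flank-only, and the
analysis window is set to 400–1000 bp, above that floor. A fragment length
is a taxon signature only approximately: multi-operon genomes produce
several fragments from one organism (the package's default dominant carries
operons at 652 and 590 bp, i.e. spacers of 280 and 218 bp), and unrelated
taxa can collide in length.

## Peak processing

**Calibration.** Observed positions of flagged internal size standards (15
and 1,500 bp markers on the microfluidics chip; a 100–1,000 bp ladder on the
capillary analyzer) are mapped onto their known sizes by piecewise-linear
interpolation with linear extrapolation beyond the outermost standards.
Piecewise-linear was chosen over Local Southern for transparency and exact
invertibility (a linearly distorted axis is recovered exactly, which the
tests exploit); Local Southern would be a straightforward extension.

**Thresholds.** The chip threshold is relative — a peak must be *strictly*
greater than baseline + 20 fluorescence units; the capillary threshold is an
absolute 200 units; gel densitometry uses a configurable cut-off (default
120 units in the synthetic platform model, 0 when constructed directly).
Strict inequality is used everywhere, so a peak at exactly the threshold is
dropped.

**±5 % binning.** The pairwise rule "sizes within ±5 % are the same" is not
transitive: chains of peaks each within 5 % of their neighbour can span far
more than 5 % in total. Binning therefore solves an explicit optimisation
over the size-sorted peaks of all samples jointly: partition them into
contiguous groups such that within each group `max ≤ min × (1 + tolerance)`,
minimising first the number of groups and then the summed within-group
spread (bp), with ties resolved so boundary peaks join the lower group. The
optimum is found by an exact O(n²) dynamic program; restricting to
contiguous groups loses nothing because a group's validity and spread depend
only on its extreme members, so any optimal partition can be rearranged into
a contiguous one. A simple left-to-right greedy pass achieves the minimal
group count but not the minimal spread (sizes 100, 105, 106, 110 at 5 %:
greedy gives {100, 105},{106, 110} with spread 9 bp, the optimum is
{100},{105, 106, 110} with spread 5 bp), which is why the dynamic program is
used; the tests check it against exhaustive partition enumeration. The 5 %
is always computed against the smaller of the sizes compared — the
conservative reading. Bin centers are area-weighted mean sizes; relative
abundance is each bin's summed area over the sample's total retained area,
so non-empty rows sum to 1 (±1e−9). No two adjacent bins of a result can be
merged without violating the cap — this is what makes bins mutually
distinguishable under the rule (their *centers*, being weighted means, can
in contrived cases sit closer than 5 %, so center separation is not asserted
as an invariant).

Fingerprints from different platforms are never co-binned: instruments
differ systematically in mobility and calibration, so cross-platform
comparison happens only through derived statistics (diversity, trees,
correlations). The ±5 % rule is applied to gel band tables as well, as the
uniform default.

## Diversity

`H' = −Σ (n_i/N) log(n_i/N)` over peak heights (heights, not areas — the
densitometric convention; areas drive relative abundance elsewhere, and both
columns travel through the pipeline). Natural log is the default — capillary
profiles with ~30 peaks give H' ≈ 3.5, which matches ln but not log₁₀ —
with a base-10 option. An all-zero lane is an error, not H' = 0: "no
information" must stay distinguishable from "one band". Replicate summaries
report the mean and the *sample standard deviation* (ddof = 1), labelled
explicitly since field figures sometimes mix standard deviations and
standard errors; a single replicate reports its H with the dispersion marked
unavailable.

## Similarity, clustering, bootstrap

Dice similarity uses presence/absence only. UPGMA is implemented directly
(not delegated) because deterministic tie-breaking matters for tests and
reproducibility: when several cluster pairs share the minimal distance, the
pair whose smallest leaf labels sort lexicographically first merges. Node
height is half the merge distance, so the tree is ultrametric and cophenetic
distances reproduce an already-ultrametric input exactly; the test suite
cross-checks cophenetic distances against SciPy's average-linkage on random
matrices. Newick output uses height differences as branch lengths and clade
supports as internal labels.

Bootstrap supports resample *bin columns* with replacement — the standard
fingerprint bootstrap; resampling the six samples themselves would be
incoherent for a six-leaf tree. A replicate sample that loses all bands is
treated as maximally distant from non-empty samples and identical to other
empty ones. Support of a node is the fraction of replicate trees containing
the same leaf clade; the root is trivially 1.

## Correlation with reactor performance

Pearson r with a two-sided t test on n − 2 degrees of freedom (SciPy's
`pearsonr`), the conventional parametric choice that standard statistics
suites apply; the suite verifies it against the explicit t formula and a
permutation test. Zero variance or n < 3 is an error, never a silent NaN.
Samples lacking production data — typically the inoculum, which predates gas
measurement — are dropped pairwise and the effective n is reported. No
multiple-testing correction is applied (none is conventional for a handful
of planned comparisons at this scale). Note that published correlation
tables in this field occasionally contain implausible entries (e.g. a
reported r = 0.96 with P = 0.08 at n = 5, likely a typo for 0.008);
this package always reports the computed p-value.

## In-silico PCR

IUPAC-aware matching: a primer position matches a target base iff the base
belongs to the code's set; an ambiguous base in the *target* (N in a draft
sequence) counts as a mismatch against every primer position — conservative,
to avoid phantom amplicons. Default `max_mismatches = 0`. Both strands are
scanned; coordinates are 0-based half-open on the forward strand. Products
are all convergent, non-overlapping forward/reverse site pairs up to
`max_len`; nested alternatives are all reported (no shortest-product
suppression) because multi-band patterns from one template are biologically
meaningful. The 202/170 bp flanks are pair-level constants of this primer
pair, overridable per run for other primer systems. Degenerate matching is
validated against the brute-force union of exact matches over all expanded
variants (2 for the 16S primer, 192 for the 23S primer).

Bin-to-taxon assignment matches each observed bin against predicted amplicon
lengths within the same ±5 % tolerance (against the smaller value); a bin
may be unassigned, uniquely assigned, or ambiguous among several taxa, and a
multi-operon taxon may claim several bins.

## Synthetic study design

The default scenario reproduces the monitored digester's structure: six
samples (inoculum; days 1, 10, 22, 30, 43), day 1 a noise replicate of the
inoculum, a community shift at day 10 parameterised by a turnover fraction
(default 0.85) toward a post-shift composition dominated by the two-operon
652/590 bp taxon, and only small log-normal noise (CV 5 %) between
consecutive post-shift states. All default amplicon lengths (415–960 bp) are
mutually more than 5 % apart so default bins are unambiguous by
construction. Biogas is coupled as
`0.15 + 17.5 × (dominant abundance) + N(0, 0.15)` L/day with methane at 63 %
of biogas — start-up production near zero on day 1, ~8 L/day after the
shift — so the correlation stage has a strong known truth; the inoculum has
no production values.

Rendering: per (taxon, operon) candidate peak, reported size = amplicon
length + Gaussian jitter, area = total platform signal × signal share ×
unit-mean log-normal noise, height = area / 2; peaks below the platform's
threshold or outside its reportable range are dropped, and internal
standards are appended as flagged records (flagged, not inferred — so
calibration tests are unambiguous). Platform totals (gel 4,000; chip 2,000;
capillary 100,000 units) against the thresholds give effective abundance
cut-offs of roughly 6 %, 3 % and 0.4 %, reproducing the observed richness
ordering capillary > chip ≥ gel and the capillary > chip Shannon ordering.
No instrument publishes its noise magnitudes; the jitter/CV defaults (gel
3 bp/15 %, chip 1.5 bp/10 %, capillary 0.5 bp/5 %) are free parameters
ordered by the platforms' known resolution, and every noise source can be
set to zero, in which case the pipeline recovers the true amplicon set and
true per-fragment abundances exactly (to 1e−9) — the generator's key
design property.

**What the generator does not emulate:** sequence-level spacer content,
per-scan chromatogram traces, gel-image artifacts (smiling, lane-to-lane
distortion), PCR amplification bias beyond static operon weights, and
platform mobility nonlinearity beyond what calibration inverts. Passing
tests therefore demonstrate correctness of the *analysis* under a plausible
error structure, not instrument-level realism.

## Numerical and degenerate-input choices

- Strict inequalities at detection thresholds; window bounds inclusive.
- Empty fingerprints are legal everywhere except where a statistic is
  undefined (Shannon of an empty lane, Dice of two empty sets, correlation
  of a constant) — those raise.
- Determinism: every stochastic routine takes a seed; per-file sub-seeds are
  derived arithmetically and kept below 2³¹; fixture writes are
  byte-reproducible (fixed float formatting).
- Problem sizes in tests and the acceptance script (10 kb random templates,
  ≤12-peak exhaustive binning oracles, 200–500 bootstrap replicates) were
  chosen to exercise the algorithms thoroughly while keeping the whole suite
  in seconds.

## Known limitations

- Local Southern calibration is not implemented; strongly nonlinear mobility
  between ladder points is only approximated.
- Binning optimises a global objective; like any rule on non-transitive
  pairwise similarity it can split peaks a pairwise reading would call
  "the same" when they sit in a chain.
- Bootstrap supports on six leaves with few bins are coarse (steps of
  1/n_reps) and column resampling assumes bins are exchangeable units.
- The Pearson stage assumes approximate bivariate normality; with n = 5 the
  t-based p-values are indicative rather than exact.
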
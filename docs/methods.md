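# Methods

This note documents the models and procedures `flymb` implements, the
defaults that matter, what the synthetic-data generators do and do not
emulate, and the design choices made where the design was genuinely open.

## Courtship memory

The courtship index (CI) is the proportion of a 10-minute pairing a male
spends courting, a value in [0, 1].  For a genotype with naive and trained
cohorts the memory index is

    MI = (x̄CI_naive − x̄CI_trained) / x̄CI_naive,

the fractional suppression of courtship attributable to training; MI ∈
(−∞, 1], with 1 meaning complete suppression and values near 0 no memory.
MI is undefined when the naive mean is 0 (raised as an error).  MI is
invariant to rescaling all CIs by a common factor, so it compares across
genotypes with different baseline courtship drive.

**Naive vs trained within a genotype** uses a two-sided Mann–Whitney U
test.  For combined n ≤ 12 the null is enumerated exhaustively over all
label assignments, counting assignments with |U* − μ| ≥ |U_obs − μ| (ties
handled by midranks, so enumeration remains exact); beyond the cutoff the
tie-corrected normal approximation with continuity correction is used.  The
cutoff of 12 keeps enumeration below C(12,6) = 924 assignments.

**Between genotypes** the statistic is ΔMI = MI_a − MI_b and the null is
built by randomization.  Two schemes are provided because the randomization
scheme behind published "bootstrap replicate" tests for MI differences is
not uniquely determined by that phrase:

- `permutation` (default): CI values are reshuffled between genotypes
  *within each training condition* — naive CIs pooled and redealt at the
  original group sizes, trained likewise.  This is the exact test of the
  null "the genotypes do not differ", while preserving the naive/trained
  structure.
- `bootstrap`: group means are rebuilt by resampling with replacement from
  the per-condition pools.

The two-sided p-value uses +1 smoothing,
p = (1 + #{|ΔMI*| ≥ |ΔMI_obs|}) / (R + 1), so p is never 0 and ties count
toward the numerator (conservative).  Replicates whose resampled naive mean
is exactly zero have no defined MI; they are redrawn and counted in the
log.  The default R = 10,000; the type-I calibration check in the
acceptance script uses R = 1,000 per experiment to keep 500 simulated
experiments fast, which only coarsens the attainable p-grid, not the
test's level.

## Sleep and circadian analysis

A minute is *inactive* iff its beam-crossing count is 0 (threshold
parameter `inactivity_threshold = 1`, i.e., strictly-below-1).  A *sleep
bout* is a maximal inactive run of ≥ 5 minutes (`min_bout_minutes = 5`).
Runs truncated by the recording boundary count when long enough — excluding
them would bias total sleep downward, and no exclusion rule is standard.
Bouts are reported in half-open minute coordinates.  The detector is
validated against a brute-force maximal-run scan.

The per-minute *sleep profile* scores each fly 1 (inside a bout) or 0 and
averages across flies; day/night totals split minutes by the lights-on/off
clock times (12 h:12 h; the same clock split gives objective day and night
in constant darkness).  Genotype comparison uses a per-minute two-sample t
statistic, reporting runs of ≥ 2 contiguous significant minutes.

Free-running period in DD is estimated by Lomb–Scargle periodogram on the
per-minute counts.  The grid spans periods of 10–40 h at 4× the natural
frequency resolution 1/T.  Power is normalized by the trace variance
(making the estimate invariant to rescaling the counts); under Gaussian
white noise the normalized peak power is approximately exponential, so a
fly is called *rhythmic* when its peak clears −ln(α/M) with α = 0.05 and M
the grid size (Bonferroni).  This threshold is a documented default, not a
claim about any particular published analysis, which typically names only
the periodogram method.  Constant traces are non-rhythmic with period NaN.

## FRET and FUNCAT imaging

Three channels are acquired simultaneously from a single excitation line:
donor (CFP), acceptor (YFP), and a longer-wavelength autofluorescence (AF)
window.  Linear unmixing corrects each signal channel against AF per pixel:

    corrected_c = c − c / AF,   c ∈ {CFP, YFP}.

Pixels with AF below `af_floor` (default 1.0 intensity unit) are flagged
invalid and excluded downstream: the division is unstable near zero AF and
the published form of the algorithm carries no guard, so the floor is a
documented necessity of this implementation, not a reproduction claim.
AF = 1 exactly is degenerate (corrected values 0) but remains valid.

The sensor readout is the per-pixel ratio of the corrected channels.  The
orientation is a configuration flag because both conventions (corrected
CFP/YFP and YFP/CFP) appear in practice; the default is donor over
acceptor (`cfp_over_yfp`).  Comparative conclusions — which genotype has
the higher sensor signal — are consistent under either orientation since
flipping maps every ratio r to 1/r.  ROI quantification takes the
arithmetic mean of the ratio over the valid pixels of a named mask at a
single z slice (the mid-lobe plane), not a projection.

FUNCAT quantification is the ratio of ROI means, mean(FUNCAT)/mean(GFP
reference), at the mid-lobe slice; it is invariant to common scaling of
both channels.

## Genomic target funnel

All interval algebra is 0-based half-open; intervals sharing only an
endpoint do not overlap.  Peaks are strandless.  Operations:

- *Intersection* keeps records of A overlapping ≥ 1 bp with B (validated
  against a quadratic all-pairs oracle).
- *Consensus peaks* between two replicates: peaks present (≥ 1 bp overlap)
  in both replicates, merged transitively into union intervals — "present
  in both" is taken as the meaning of a two-replicate consensus set.  With
  caller-style disjoint peaks per replicate the operation is symmetric and
  idempotent against re-consensus with either replicate.
- *Blacklist subtraction* drops whole peaks on any overlap with an
  artifact-prone region rather than trimming them.
- *Differential-peak filtering* keeps peaks with FDR < 0.05 and linear fold
  change > 1.25 in the requested direction.  Fold change is stored as a
  ratio ≥ 1 plus a direction flag so the threshold applies symmetrically to
  reductions and increases.  A stricter FDR < 0.01 is equally supported;
  both conventions circulate and the package surfaces the choice rather
  than resolving it.
- *Peak-to-gene annotation* defaults to nearest TSS by peak-midpoint
  distance with exact ties assigning all tied genes; a window-overlap mode
  ([TSS − 2,000 bp, gene end)) is provided because published annotators'
  assignment rules are version-dependent.  Gene records carry their TSS as
  the interval start.

The *direct-target funnel* nominates genes satisfying all three of:
(1) annotated to a significantly reduced peak (peaks carrying statistics
are filtered first); (2) annotated to a TF binding site falling inside
open chromatin (the overlap regions themselves are annotated); (3) mRNA
down-regulated (log2FC < 0, adjusted p < 0.05).  Stage counts are nested
by construction and reported alongside the target list.  Differential
expression is consumed, not computed: the funnel takes any table with
log2FC and adjusted-p columns.

*Median-of-ratios normalization*: per gene, the reference is the geometric
mean of counts across samples over genes nonzero everywhere; the size
factor is the per-sample median of count/reference; normalized counts
divide by it.  Per-sample rescalings of the counts are absorbed into the
size factors up to one global constant (the geometric mean of the
scalings) — only relative library depth is identifiable, which is inherent
to the estimator, not an implementation artifact.

*Tissue-enrichment calls* flag genes with mean_a/mean_b above a fold
threshold (default 2.0) and adjusted p below 0.05; a zero denominator
yields infinite fold and the call reduces to the significance condition.

## Overlap statistics

Hypergeometric upper tails P(X ≥ k) are computed as a log-sum-exp over
log-pmf terms (log-gamma based), exact to ~1e-10 relative error against
rational enumeration and stable far below double underflow — overlaps of
large gene sets routinely produce p-values at the 1e-70 scale.  The tail
is monotone decreasing in k.  The default universe is 13,986 coding genes
(the *D. melanogaster* protein-coding gene count), always overridable; no
particular published p-value is claimed to be reproducible without knowing
the universe its authors used.

Fisher's exact test is two-sided by the probability-mass rule (sum over
tables with the observed margins no more probable than observed) and
reports the sample odds ratio ad/bc; a zero margin is degenerate with
p = 1.  BH FDR is the step-up adjustment with cumulative minimum from the
largest rank, order-preserving and capped at 1.  Gene-set enrichment
excludes terms outside 25–250 universe-restricted genes *before* testing,
applies the hypergeometric tail per term, BH across tested terms, and
reports fold enrichment (k/|query|)/(K/|universe|).  Semantic pruning of
redundant terms is out of scope (a curation step, not a computation).

## Synthetic data: what it emulates, what it does not

All generators are pure functions of (parameters, seed) and their outputs
round-trip through the package's readers.

- **Courtship CIs** are Beta-distributed with stated mean and concentration
  (CIs are proportions); the trained mean is naive_mean × (1 − effect), so
  `training_effect` is the true MI.  Defaults: n = 20 flies/group, naive
  mean 0.6, concentration 10 — typical cohort sizes and baseline courtship
  levels for conditioning assays.  Not emulated: fly-to-fly covariance,
  observer scoring noise, floor effects in low-courtship genotypes.
- **Activity** is per-minute 0/1 (presence of a beam crossing); time is
  tiled into 10-minute blocks slept through with probability matching the
  day/night sleep fractions (defaults 0.2 day / 0.6 night) in LD, or their
  mean modulated sinusoidally at the stated period (amplitude 0.9) in DD.
  Asleep blocks are clean ≥ 5-minute runs, so recovered sleep fractions
  match the stated ones; the block construction gives near-white residual
  noise, which makes period recovery sharper than messy real actograms —
  passing recovery tests bounds algorithmic error, not biological
  variability.  Not emulated: graded activity counts, siesta structure,
  arousal fragmentation.
- **FRET stacks** invert the unmixing equations: corrected channels are
  chosen to carry the planted ROI ratio over a uniform AF = 4 background
  and raw channels back-computed via raw = corrected/(1 − 1/AF), making
  the planted ratio an exact noiseless fixed point of the pipeline;
  Gaussian read noise (sd as stated) is added to raw channels.  Not
  emulated: spectral bleed-through beyond the AF model, depth-dependent
  attenuation, ROI segmentation error.
- **Toy genomes** lay genes every 10 kb on one chromosome (TSS = start) so
  nearest-TSS annotation is unambiguous, and plant a target set satisfying
  all three funnel conditions; half the decoys (by default) satisfy exactly
  one or two conditions — including traps such as sub-threshold peaks and
  binding sites outside open chromatin — and none satisfy all three, so
  exact truth recovery is the correct outcome, and the recovery test
  exercises every rejection path of the funnel.  Not emulated: overlapping
  gene models, distal enhancers, annotation ambiguity.

## Numerical choices and degenerate inputs

- Randomization p-values use +1 smoothing and count ties as extreme.
- Comparisons of |Δ| against the observed statistic use a 1e-12 slack so
  floating-point noise never drops a tied replicate.
- Mann–Whitney exactness cutoff: combined n ≤ 12.
- Zero naive mean: error for the observed MI, redraw for replicates.
- Lomb–Scargle on a constant trace: non-rhythmic, period NaN.
- FRET: AF < floor → pixel invalid; corrected denominator 0 → pixel
  invalid; ROI with no valid pixels → error.
- Interval records require start < end; BED parse errors name the line.
- DAM rows with non-OK status are dropped and counted in the log, not
  errors (permissive monitor-file practice).
- Problem sizes in tests and the acceptance script (500 null experiments ×
  1,000 replicates; 1,000 random traces; 100 random genomes; 64×64 images)
  are the package's chosen desk-scale study conditions: large enough that
  the Monte-Carlo bands asserted (e.g., type-I rate in [0.03, 0.07]) are
  meaningful, small enough to run routinely.

## Known limitations

- Sequencing-scale headline counts from any real study (consensus-peak
  totals, funnel counts) depend on deposited raw data and are out of desk
  scale; correctness is established on planted-truth synthetics instead.
- The randomization scheme of historical MI tests is ambiguous; both
  schemes are provided and neither is asserted as "the" original.
- The Lomb–Scargle rhythmicity threshold and the FRET AF floor are
  documented defaults of this implementation.
- `consensus_peaks` idempotence assumes disjoint peaks within a replicate
  (peak-caller output); overlapping within-replicate peaks can chain.
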
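# Methods

This note documents the models, formulas, parameter choices and numerical
conventions behind `proximap`, and what the synthetic benchmarks do and do
not demonstrate.

## Input model

The unit of data is one SAINT-style record per bait × prey × cell line:
an average spectral count (AvgSpec) over biological replicates, the
per-replicate counts when available, and a SAINT average probability (AvgP)
in [0, 1].  Three control purifications are expected per cell line: an
empty BirA\*–Flag vector, a soluble BirA\*–Flag–eGFP fusion (both "negative
controls"), and a membrane-targeted BirA\*–Flag–eGFP–CAAX construct.
Controls are identified by configured bait ids rather than name matching,
because supplementary-table naming conventions vary.  Prey identity is the
gene symbol throughout.  Upstream steps — spectral search, protein
inference, SAINT itself — are out of scope; their outputs are consumed as
given.

## Replicate QC

Replicates of one bait are compared by Spearman rank correlation over the
union of preys detected in either replicate, zeros retained and ties
mid-ranked.  The gate (default threshold 0.9) flags a replicate only when
its correlation with *every* sibling falls below threshold: with two
replicates a single bad correlation flags both (neither has a passing
partner); with three or more, only the outlier.  The threshold applies to
the per-replicate maximum over siblings rather than the mean — a choice
made here, since either reading is defensible; the maximum is the more
lenient and only diverges from the mean for ≥3 replicates.

The screen-level embedding is classical (Torgerson) multidimensional
scaling on the dissimilarity 1 − ρ (double-centred squared dissimilarities,
top-2 eigenvectors, coordinates centred at the origin).  The dissimilarity
is deliberately pinned to 1 − Spearman rather than the top-feature log-ratio
distance some MDS front-ends default to: one stated metric, reproducible
from the counts alone.  A replicate whose nearest embedded neighbour is not
a sibling is flagged; singleton groups are skipped with a warning.
Degenerate all-equal profiles embed at the origin with a warning.

## Specificity scores

Per cell line and bait–prey pair:

    WD(b, p) = sqrt( X̄(b,p) · ( (K / f(p)) · ω(p) )^{n(b,p)} )

* `K` — number of non-control baits in that cell line's screen.
* `f(p)` — number of those baits with X̄ > 0 for prey p.
* `n(b,p)` — number of replicates of bait b detecting p; 1 when replicate
  counts are unavailable.
* `ω(p) = max(1, sd/mean of X̄ over the f(p) detecting baits)` — the
  across-bait variability weight; ω = 1 when f = 1.  The sd is the sample
  standard deviation (ddof = 1) over detecting baits only; including
  non-detecting baits as zeros would conflate frequency (already in K/f)
  with variability.

Control purifications never enter K, f or ω — they define background, not
specificity.  WD is strictly increasing in X̄ and non-increasing in f;
X̄ = 0 gives WD = 0.

The **WDS** score pools two cell lines by summing their WD scores, with a
pair missing from one line contributing zero.  Summation (rather than
averaging) deliberately rewards detection in both lines while leaving
single-line interactions scored by their own WD.  In single-cell-line runs
WDS ≡ WD.

Additional per-record quantities:

* **CAAX ratio** = X̄(bait, p) / X̄(CAAX, p); a prey absent from the CAAX
  control yields +∞ (absence from the membrane control is maximal
  enrichment and passes any finite cutoff).  A record absent from both is
  reported as 0, not ∞.
* **log₂ fold change** versus the mean AvgSpec of the negative controls
  (absent control records count as zero), with pseudocount 1 on both sides
  so integer counts of zero stay finite.
* **CBNP** (complexity-based normalization relative to total identified
  proteins): X̄ × median_b N(b) / N(b), where N(b) is the number of distinct
  preys identified with bait b in that cell line.  The median rescaling
  keeps CBNP on the AvgSpec scale; a bait identifying no preys is skipped
  with a warning.

## Filter stack and cutpoint calibration

A record survives iff

    AvgP ≥ 0.95  AND  AvgSpec ≥ t_line  AND  CAAX ratio ≥ 1.7  AND  prey ∉ blocklist

with t_line defaulting to 4.5 (HEK293) and 6 (HeLa).  All comparisons are
inclusive.  Attrition is attributed to the first failing filter in the
fixed order AvgP → AvgSpec → CAAX → blocklist, so per-filter removals sum
exactly to records_in − records_out.  The shipped blocklist holds keratin
family symbols, BirA\*, the endogenous biotin-dependent carboxylases (PC,
PCCA, PCCB, MCCC1, MCCC2, ACACA, ACACB) and β-galactosidase; it is a plain
editable set.

Cutpoint calibration labels AvgP-passing records of a small set of
well-characterised calibration baits by membership in a gold-standard edge
list, then reports for each score:

* **ROC**: sensitivity/specificity over every distinct observed threshold
  (keep iff score ≥ t), cutpoint at maximum Youden J = sens + spec − 1, ties
  resolved toward the smallest threshold, AUC by the trapezoid rule over
  the full step curve.  Youden J is used because no asymmetric cost
  structure is available; it is the standard default of cutpoint tools.
* **CDA**: empirical CDFs F⁺, F⁻ of positive and negative scores; cutpoint
  at the Kolmogorov–Smirnov location argmax F⁻(s) − F⁺(s), ties toward the
  smallest score, with a warning when the maximum gap is 0.

Infinite CAAX ratios are capped just above the largest finite observation
before cutpoint analysis (only order matters for ROC/CDA).  A threshold
grid is additionally ranked by recall among configurations meeting a
precision target (default 0.95), ties toward smaller thresholds.  The
ranking is advisory: adopting a calibrated cutpoint is always an explicit
user decision, never automatic.

## Effector clustering

Preys annotated as GAPs or GEFs are removed before building the bait × prey
WDS matrix (regulators would otherwise dominate the effector structure);
absent pairs are zero and all-zero prey columns are dropped.  Prey–prey
distances are Canberra, Σ|xᵢ−yᵢ|/(|xᵢ|+|yᵢ|) with 0/0 terms contributing 0
— appropriate for sparse nonnegative profiles because it weights presence/
absence disagreements maximally.  Bait–bait distances are 1 − Pearson over
the shared prey axis; a zero-variance bait profile is an error naming the
bait.  Prey clustering uses the joint bait axis over both cell lines (the
WDS matrix), not per-line axes.

Agglomeration is the **unsquared-dissimilarity Ward variant** ("ward.D"):
the Lance–Williams recurrence

    d(k, i∪j) = [ (nᵢ+n_k) d(k,i) + (nⱼ+n_k) d(k,j) − n_k d(i,j) ] / (nᵢ+nⱼ+n_k)

applied to the input dissimilarities exactly as given, never squared.  This
historical variant is implemented in-house (the common library routine is
the squared variant); tests cross-check it via the identity that running
the squared variant on the elementwise square root of a distance matrix and
squaring the merge heights reproduces it.  Merge history is emitted in the
standard linkage format so standard cutting utilities apply.

The number of clusters is the argmax over k ∈ [2, 20] of the mean
silhouette width computed from the *same* distance matrix as the
clustering, ties toward the smallest k; a singleton cluster's silhouette is
defined as 0.  A best silhouette below 0.25 triggers a weak-structure
warning but still returns a result.

## Localization calls

For each bait the filtered prey set is compared to every compartment marker
set with the overlap-coefficient distance

    d(c) = 1 − |preys ∩ markers(c)| / min(|preys|, |markers(c)|)

ranked ascending with alphabetical tie-breaks; the top three compartments
are reported, extended to four when the 3rd and 4th distances tie within
1e-12.  Database-backed localization tools expose a "shortest distance"
interface without publishing their metric; the overlap-coefficient distance
is a deliberate, fully offline surrogate for that interface, and every
output row carries `surrogate_flag = True` so calls are never mistaken for
the external tool's.  No claim is made that surrogate calls match any
specific published compartment assignment beyond qualitative agreement.

## Synthetic screens

`simulate_screen` emulates the screen design end to end: `n_baits` baits ×
`n_preys` preys × 2 cell lines × `n_replicates` (default 2, matching
biological duplicates) plus the three controls.  Components:

* **True edges.** Each bait receives ⌈frac_true · n_preys⌉ planted preys;
  each edge lands in both cell lines with probability `shared_edge_prob`
  (default 0.4, giving roughly a one-third shared interactome), otherwise
  in one line at random.  Replicate counts are negative binomial with mean
  `mu_true` (default 25) and size `dispersion` (default 4 — counts of
  strong interactors vary by roughly ±50% between replicates).
* **Background.** Per-prey detection probabilities are drawn from a Beta
  with mean `detect_prob_bg` (default 0.15), giving the frequency-graded
  background of real screens; detected records get NB counts at `mu_bg`
  (default 3).
* **Membrane preys.** `n_membrane_preys` preys are strongly present in the
  CAAX control (mean mu_bg × `caax_boost`, detection 0.9) and mildly
  elevated (×1.5) in every bait — the class the CAAX-ratio filter exists
  for.
* **Simulated probabilities.** AvgP is drawn from Beta(50, 1) for true
  edges and Beta(1, 20) for background; probabilistic rescoring of raw
  counts is upstream of this package, so probabilities are simulated, not
  recomputed.  Crucially, background is allowed to fool the simulated
  scorer: ordinary background records draw the high-probability Beta with
  probability `bg_highp_prob` (default 0.03) and sticky records with
  probability `frequent_highp_prob` (default 0.15).  Without this class a
  probability threshold alone would be a perfect filter, and the
  spectral-count/ratio calibration the pipeline exists for would have
  nothing to do; real screens motivate exactly those filters.
* **Sticky background.** `n_frequent_preys` frequent flyers are present in
  ~90% of purifications, controls included, each with a characteristic
  per-line abundance λ ~ Gamma(shape 4, mean `mu_frequent` = 6) shared
  across purifications — so their CAAX ratio concentrates near 1 and the
  membrane control removes them, as in real data.  Six named contaminants
  matching the shipped blocklist (carboxylases, keratins) are planted in
  every purification at higher abundance.

The **planted AvgSpec threshold** is computed analytically, not from the
sample: the spectral-count sum over r replicates of an NB(size s, mean m)
record is NB(size rs, mean rm), so the Youden-optimal separation between
the true-edge mixture (ordinary + membrane-boosted) and the
probability-passing background mixture (ordinary + membrane + sticky +
named contaminants, weighted by expected record counts, Gamma components by
quadrature, both classes zero-truncated) is found exactly on the lattice
k/r.  Recovery tests therefore compare a sample estimate against an
analytic plant.

`simulate_wds_matrix` plants prey modules and bait families as blocks of
Gamma-distributed WDS values over family-specific bait supports (modules
beyond the family count load on two adjacent families so every module has a
distinct support pattern) with sparse exponential off-block noise.
`simulate_replicate_matrix` draws shared log-normal prey abundances
(σ_log = 1.8, matching the multi-order-of-magnitude spread of spectral
counts in well-behaved duplicates, which is what puts intact Spearman
correlations above 0.9) with Poisson replicate noise; an optional shuffled
column emulates a failed acquisition.  `simulate_marker_atlas` /
`simulate_localized_baits` build disjoint marker sets and baits drawing a
configurable fraction (default 80%) of preys from one home compartment.

### What the generator does not emulate

Peptide-level identification, protein inference ambiguity, batch effects
between the two mass spectrometers, correlated detection across related
preys (complex co-members), and SAINT's actual probability model.  Passing
the recovery benchmarks therefore shows the pipeline's logic is correct and
well-calibrated *under the stated generative model*; it does not certify
performance numbers on real screens, where the background structure is
richer.

## Benchmark problem sizes

The recovery benchmarks run on a 20-bait × 2000-prey two-line screen
(~16k records), 50 random 6 × 20 replicate matrices for the WD
cross-check, 10,000 points for the null-AUC check, a 16 × 150 WDS matrix
(4 families, 5 modules) for clustering, 200 synthetic baits against a
20-compartment atlas for localization, and 20 replicate pairs for the QC
gate — sizes chosen so the full benchmark completes in seconds while
keeping binomial noise on the reported rates near or below one percentage
point.

## Known limitations

* The ω weight uses detecting baits only; screens in which a prey's
  non-detections are informative would need the zero-inclusive variant.
* Ward on non-Euclidean dissimilarities (Canberra, 1 − r) can in principle
  produce height inversions; cutting is done by merge order, which is
  robust to them.
* The localization metric is a surrogate; absolute distances are not
  comparable to database-backed tools, only ranks are meaningful.
* Calibration assumes the gold standard is enriched among true positives;
  a heavily incomplete gold standard biases cutpoints upward since unlisted
  true interactors count as negatives.
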
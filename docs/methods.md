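# Methods

This note documents the models, conventions and numerical choices behind
`sigfate`, what the synthetic-data generators do and do not emulate, and
the limits of what the tests demonstrate.

## Signaling histories and features

A signaling history is a nuclear:cytoplasmic (N:C) ratio time series on
a shared grid (default 0–42 h at 10-minute intervals, matching a
standard live-imaging cadence). The N:C ratio is
`(nuclear − background) / (cytoplasmic − background)`; a non-positive
denominator marks the measurement missing rather than raising, and a
no-subtraction mode exists for dim reporters where background estimates
are unreliable.

Each history is reduced to a descending logistic
`s(t) = L + (H−L)/(1+exp((t−d)/τ))` by trust-region least squares
(`scipy.optimize.least_squares`), with data-driven initialization: `H`
from the mean of the first quartile of timepoints, `L` from the last
quartile, `d` from the half-crossing, `τ = 2 h`. **Duration** is defined
as the sigmoid midpoint `d`; the midpoint is the natural changepoint of
the logistic and makes level×duration products exact for step inputs. A
fit whose amplitude `|H−L|` does not exceed twice the residual RMSE, or
whose midpoint falls outside the observation window, is flagged: the
plateaus remain meaningful but the duration is unidentifiable (the
degenerate constant-history case).

The **integral** `Σ` is the trapezoid integral of `s(t) − baseline` over
the observation window, computed on the raw (optionally denoised)
history; integrating the fitted curve instead is available through
`SigmoidFit.integral`, which uses the closed form of the logistic
antiderivative. The baseline defaults to the population median of the
fitted low plateau — the pre-treatment level the response returns to —
so a zero-signal history integrates to zero and level/duration
interchangeability is exact. Both baseline-subtracted and raw modes
exist; all shipped analyses use the subtracted mode.

PCA of the history matrix is column-mean-centered; components are
deterministic up to sign, fixed by orienting each component's scores to
correlate non-negatively with the per-cell integral.

## Graph-diffusion denoising

The operator is an adaptive-bandwidth Gaussian kernel over each cell's
`knn` nearest neighbors (Euclidean), bandwidth = distance to the
`knn`-th neighbor, floored at √machine-epsilon for duplicate points;
affinities are symmetrized and row-normalized, and denoising applies the
`t`-th operator power (defaults knn = 3, t = 3). Truncating the kernel
at the `knn` neighbors, as MAGIC does, matters: in ~250-dimensional
noisy history space pairwise distances concentrate, and an untruncated
Gaussian gives distant cells enough cumulative weight to oversmooth
(denoising then *increases* the error to the true signal). Each denoised
value is a convex combination of raw values, so column-wise ranges are
preserved.

Fate-based denoising builds the graph in log-normalized (z-scored)
7-marker space and applies it to the histories — averaging signaling
among cells with the most similar fates, which preserves marker
bimodality better than a history-space graph.

**Randomized-pairing control.** Because a fate-derived graph could in
principle manufacture signaling–fate correlation, the control permutes
the history↔marker pairing before denoising and reports
corr(Σ, log(ISL1/NANOG)). Diffusion is linear, so the denoised permuted
integral is the diffused permuted integral vector, and the control is
cheap. A single permutation's correlation is *not* a good null summary:
diffusion leaves ~n/k_eff effective degrees of freedom (≈30 at n = 500
with knn = 3, t = 3), so individual permutations scatter with SD ≈ 0.15
around zero even for a perfectly artifact-free procedure. The control
therefore reports the mean over 16 permutations; an artifact would shift
this mean away from zero, while honest sampling noise averages out. At
the default conditions the mean sits well inside ±0.1.

## Tracking

Frame-to-frame linking is the standard linear-assignment formulation:
candidate links cost squared displacement, links beyond `max_disp` are
forbidden, and the birth/death alternative costs 1.05× the 90th
percentile of all candidate link costs across the movie. Gap closing
spans one skipped frame by default (a 10-minute imaging interval makes
longer gaps risky), with the distance gate scaled by the gap length.
Junk-class detections are removed before linking. Detections are sorted
by (frame, id), making the result invariant to input row order.

Divisions are resolved in a second pass: a metaphase-labeled detection
may claim two successors in the next frame within `division_radius` —
its linked continuation plus new-track births — choosing the best two by
squared displacement when more than two candidates exist (warning
logged). Each daughter's suffix becomes a fresh track with the mother as
parent; a metaphase detection with a single nearby successor keeps plain
one-to-one linking, so no spurious divisions are invented. Division
labels are input data here; the upstream morphology classifier that
produces them is out of scope.

Live-to-fixed matching reuses the same assignment machinery on a single
frame pair, leaving grossly displaced or missing cells unmatched.

## Fate calling and prediction

Markers are natural-log transformed and per-marker z-scored (min-max
optional). Discrete fates come from a 2-component full-covariance
Gaussian mixture on the 7-marker space; the component with higher mean
ISL1 is "amnion", removing label-swap ambiguity. Marker quality is
ranked by the separation statistic |μ₁−μ₂|/(σ₁+σ₂). The continuous fate
score is `ln ISL1 − ln NANOG` on raw intensities — scale-invariant, so
illumination changes cancel — with score > 0 called amnion and the
boundary assigned to pluripotent; ISL1/SOX2 is selectable when NANOG is
perturbed (e.g. TGF-β receptor inhibition).

The Bayes threshold classifier scans the midpoints of consecutive sorted
unique feature values plus the two outside intervals; accuracy is
piecewise constant between observed values, so the scan is exact. Ties
resolve to the midpoint of the widest optimal interval (finite intervals
preferred). Orientation is fixed — larger feature ⇒ amnion — because all
four features increase with differentiation. The quadrant percentages of
the (fate score, feature) plane are identically this classifier's
confusion matrix, from which decoder-based mutual information
`I = H(fate) + H(prediction) − H(joint)` is computed with 0·log 0 = 0.

Full-history classifiers (a no-hidden-layer sigmoid network ≡ logistic
regression, and an inhomogeneous quadratic-kernel SVM, coef0 = 1) are
evaluated by stratified 5-fold cross-validation with per-fold
standardization. The ridge strength a raw history vector needs varies
sharply with dimension and noise, so `C` is selected by internal 3-fold
cross-validation on each training split rather than fixed.

## Micropattern analyses

Colonies are binned into 30 equal-count bins by distance to the colony
edge; the bin summary is the median. Kymographs are bins × time of bin
medians; replicate colonies are averaged after binning. Radially
averaged histories are clustered by fuzzy c-means (implemented here;
fuzzifier m = 2, 10 seeded restarts, best objective kept), with clusters
ordered by mean signaling so cluster 0 is the sustained edge class, and
an optional manual override for a bin whose assignment is genuinely
ambiguous (the "elbow" correction). Fate maps take the per-bin modal
fate, majority-voted across replicate colonies after discretization;
ties go to amnion, the fate of the colony edge.

A dose-response threshold is the 50% crossing of a least-squares
logistic fit (extrapolation beyond the observed fractions is refused;
the two-point step degenerates to the midpoint). The **collapse test**
fits one threshold per condition on a chosen feature axis and reports
the coefficient of variation: under integral control, conditions
differing in level or duration share one Σ threshold (CV of a few
percent or less) while their duration thresholds shift strongly; under
the classic level+duration alternative the Σ thresholds disperse. The
condition simulator holds a per-cell level (Gaussian spread 0.05) for a
fixed duration, mirroring the receptor-inhibitor titration / timed
shutdown design in which level is the mean signaling before shutdown and
duration is the shutdown time.

## The SOX2/ISL1 integrator model

Tiers build the model incrementally: `linear` (production decreasing
linearly in SMAD4, clipped at zero, constant decay), `isl1` (adds mutual
SOX2/ISL1 Hill repression) and `full` (adds positive SOX2
autoregulation, `f_auto = basal + (1−basal)·S⁴/(K⁴+S⁴)`). Units are
normalized to the unstimulated SOX2 steady state = 1; by default α is
auto-calibrated to place that steady state at 1 given the other
parameters. Defaults: γ_S = ln2/7 h⁻¹ (FRAP-measured 7-h half-life),
Hill coefficients 4, all K = 0.5, basal = 0.05, α_I = γ_I = 0.2; with
these the full tier is bistable, so sufficient integrated signaling
permanently commits SOX2 to the low state and ISL1 to the high state.

ΔSOX2 is defined relative to the unstimulated control trajectory,
`ΔS = S_B(T) − S_{B≡0}(T)`; when the simulation starts at steady state
the control is constant and this coincides with S(T) − S(0). This
definition makes the linear tier exact by superposition:
`ΔS = −αβ·∫B(t′)e^{−γ_S(T−t′)}dt′`, reducing to `−αβ∫B` at γ_S = 0 —
the identity the linear-variant checks assert, and the sense in which an
integrator gene reads out the weighted signaling integral (within 5% of
the plain integral whenever γ·window < 0.1).

Integration is piecewise (LSODA, rtol 1e-8, atol 1e-10) with input
discontinuities on segment boundaries. Fitting pins γ_S at the
FRAP-measured value and estimates (α, β) in log space by multistart
Levenberg–Marquardt; a fit to unstimulated-only data flags α and β
structurally unidentifiable. Freeing γ instead (`fit_gamma=True`)
measures the *apparent* turnover the no-autoregulation model needs to
mimic autoregulated dynamics — slower than the true γ_S (≈11 h apparent
vs 7 h measured at default parameters), the signature by which a
directly measured half-life falsifies the simple production/decay model.
FRAP recovery itself is unaffected by autoregulation (bleaching removes
fluorescence, not protein), so `A₀ + A(1−e^{−λt})` is fit directly and
half-life = ln2/λ.

## RNA-seq screen

Counts → CPM; genes with mean CPM < 2.5 over all samples are dropped;
the dynamic filter keeps genes whose cumulative |log2 fold change|
versus t = 0 (pseudocount 0.5, summed over all later timepoints) exceeds
mean + 1 SD of that statistic across genes — the realized threshold is
reported, and a fixed threshold can be supplied instead since it is
unknowable whether the reference analysis's ~1.55 was the exact mean+1SD
or a rounded constant. Max-normalized profiles are clustered by
Ward/Euclidean agglomeration cut at k = 3 (k fixed because the cut
height is not identifiable from three planted classes); clusters are
labeled by the kinetics of their mean profile — falling overall ⇒
decreasing; rising with half-rise before a quarter of the time span ⇒
immediate, later ⇒ delayed — which is robust to template
mis-specification. The 5-h dose screen keeps genes with |Pearson r| >
0.9 against the SMAD4 level and |OLS slope| > 0.1 after normalizing to
the gene's time-series maximum; candidates are the TF-restricted
intersections (decreasing ∩ negative slope, immediate ∩ positive slope).

## Synthetic data: what it emulates, and what it does not

Defaults encode the target regime: histories descend from H ≈ 2 to
L ≈ 1 (baseline 1) with duration 26 ± 6 h, τ = 2 h, i.i.d. Gaussian
measurement noise SD 0.1 (an AR(1) option exists; the real noise process
is uncharacterized, and 0.1 on a unit amplitude was chosen once to make
denoising consequential without burying the signal). Fate follows
P(differentiate) = logistic((Σ−26)/2) and markers are log-normal with a
6-SD on/off gap. Colonies are 700-µm discs with three radial classes
(durations 38/30/12 h) — decisive fate rings, as in real colonies.
Tracking fixtures random-walk at 1.5 µm per 10-min frame at confluent
density with 15% labeling, metaphase → two daughters displaced 6 µm, and
nuclear exclusion (8 µm minimum separation, positions pushed apart) —
point nuclei interpenetrating for many frames would pose a swap
ambiguity no real dataset has. Counts use a 2×10⁷-read library with
gamma-Poisson overdispersion 0.002 (deep bulk RNA-seq), dynamic classes
at 4/3.5/3.5% of genes, 10% TFs, immediate-decrease timescale 4–8 h;
FRAP fixtures sample every 15 min over 36 h (~5 half-lives), which the
3-parameter exponential fit needs to determine λ to a few percent at 5%
noise. Seeds: one master seed spawns named substreams per component.

Not emulated: spatial signaling dynamics (receptor accessibility,
inhibitor diffusion — the upstream biology that *creates* the
histories), image formation and segmentation, cell motility beyond a
random walk, marker cross-talk or staining-round registration error,
autocorrelated or intensity-dependent measurement noise (beyond the
AR(1) option), and isoform/length effects in the counts. Passing tests
therefore demonstrate the *analysis* is correct and well-calibrated
under the stated generative assumptions, not that those assumptions
exhaust real data.

## Numerical conventions and degenerate inputs

Ties in the Bayes scan → widest optimal interval midpoint; fate score
exactly 0 → pluripotent; fate-map bin ties → amnion; empty or
single-class inputs raise informative errors rather than guessing;
duplicate points get a bandwidth floor in the diffusion kernel;
singular GMM covariances are regularized (reg_covar 1e-6) with a
warning; assignment outputs are invariant to detection order. CPM is
compositional — a gene exactly proportional to dose in absolute terms
has dose correlation slightly below 1 on the CPM scale because the
library total also responds.

## Known limitations

The tracker opens divisions only at labeled metaphase detections and
uses no appearance model; heavily overlapping lineages in dense fields
would need both. The diffusion operator is dense (fine to a few thousand
cells). The collapse test assumes each curve crosses 50%; conditions
that never differentiate must be excluded by design. The ODE fit
estimates (α, β) only — the Hill constants are weakly identified from
SOX2 traces alone and are held at defaults. The screen treats TF
annotation as an input flag.
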
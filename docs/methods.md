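# Methods

`somatomap` implements a complete phase-encoded (travelling-wave) digit-mapping
analysis for primary somatosensory cortex, together with the synthetic 4D BOLD
generator that gives every stage a recoverable ground truth. This note
describes the models, the numerical choices, and what the synthetic conditions
do and do not establish about real data.

## Travelling-wave mapping model

Movement cycles through the five digits in fixed order (forward D1→D5 or
backward D5→D1), one block per digit. The canonical high-field protocol is
five 9 s blocks per 45 s cycle, 8 cycles per run, TR = 1.5 s, preceded by a
25 s lead-in rest (which reconciles the 6 min 25 s run length with 8 × 45 s of
task); the standard-field variant uses 9.1 s blocks (45.5 s cycles) at
TR = 1.3 s. Two forward and two backward runs make one 25 min 40 s session.

The analysis builds one reference model per lag of the cycle:
L = cycle/TR lags (30 and 35 for the two protocols). The lag-0 model is a
periodic boxcar ("on" for one block per cycle, starting at the lead-in)
convolved with a unit-peak single-gamma HRF; lag ℓ circularly shifts the
boxcar by ℓ·TR within the cycle before convolution. Boxcars are constructed
on a 10× oversampled grid and sampled at each volume onset, so non-integer
lead-ins stay commensurate between simulation and analysis. Each voxel's
time course is Pearson-correlated with every model and the r-values are
standardized with Fisher's r-to-z (atanh). Zero-variance time courses are
assigned z = 0 at all lags, marking them unassignable rather than undefined.

Backward-run profiles are time-reversed onto the forward lag axis before
averaging. Reversing the movement cycle maps a block starting at cycle offset
s to one starting at (cycle − s − block), so the digit-aligned reversal is
z′[ℓ] = z[(L − n_on − ℓ) mod L], with n_on = block/TR lags. This convention
is fixed by the requirement — asserted in the tests — that noiseless
forward-only and reversed-backward-only analyses yield identical winner maps;
a plain index reversal about lag 0 shifts every digit by one block and fails
that requirement.

Lags are then grouped into one contiguous bin of L/5 lags per digit (six for
the canonical protocol) and averaged, first across lags, then across runs.
The bin for digit d is centred circularly on d's block-onset lag. The
centring is a deliberate numerical choice: a voxel responding to digit d
peaks exactly at d's onset lag (the HRF delay is inside the reference model),
so a bin anchored at the onset and extending only forward would place the
peak at the bin's left edge and credit the entire left flank of the voxel's
lag-tuning curve to the preceding digit. With any appreciable
neighbouring-digit response (tuning spill or spatial smoothing above ~20% of
the own-digit response), onset-anchored bins systematically reassign the
little finger's band to the ring finger; centred bins remove this bias while
preserving "six lags per digit" and the assignment of every onset lag to its
own digit.

Winner-take-all assigns each voxel to its highest-averaged-z digit (ties to
the lowest digit index), and a second winner-take-all across all L lags gives
the gradient (phase-progression) map. Digit masks are thresholded either
minimally (Z > 2) or by Benjamini–Hochberg FDR at q < 0.05 (q < 0.01 for the
standard-field preset), applied within each digit's candidate voxels.

### p-values and FDR behaviour

One-sided normal p-values are computed from the winning averaged Fisher z
with standard error 1/√(n_volumes − 3), with no correction for temporal
autocorrelation, lag averaging, or run averaging. Averaging across 6 lags and
4 runs makes the true variance of the statistic several times smaller than
this standard error assumes, so the p-values are conservative. That
conservatism more than absorbs the anti-conservative selection of the winning
(maximum) digit, which is why the realized false-discovery proportion on
signal-free phantoms is far below q (empirically zero across hundreds of null
simulations at q = 0.05 and q = 0.01). These p-values calibrate thresholding
of synthetic maps; they are not a validated inferential claim about real
fMRI noise.

## Split-half consistency

Digit selectivity is benchmarked by Dice overlap, 2|A∩B|/(|A|+|B|), between
digit clusters of two independently analysed halves (first forward+backward
pair vs second pair), minimally thresholded at Z > 2 (the averaged z scaled
by √(n_volumes − 3)). The full 5×5 matrix separates 'same'-digit (diagonal)
from 'different'-digit (20 off-diagonal) correspondence. A percentile
bootstrap (5000 iterations) over the 'different'-digit values gives the
chance-level CI; selectivity is declared when the 'same'-digit mean exceeds
its upper bound. Dice is computed in volume space within an optional ROI mask
(the statistic is geometry-agnostic; cortical-surface machinery is out of
scope). The same machinery compares any two datasets — e.g. unimanual vs
bimanual maps — by treating them as the two "halves".

## Inter-digit pattern similarity

Digit activation patterns are estimated per block-design run by ordinary
least squares (five HRF-convolved digit regressors plus intercept; rest is
the implicit baseline). The inter-digit "fingerprint" uses a
pattern-component decomposition: observed patterns are modelled as one common
component shared by all digits plus one specific component per digit plus
run-wise noise. Per run the mean pattern across digits is subtracted
(removing the common component exactly), and the digit second moment
G[a,b] = mean over ordered run pairs i≠j of ⟨pattern_aⁱ, pattern_bʲ⟩/n_voxels
is estimated from cross-run products only, so run noise cancels in
expectation. Correlations r = G/√(diag·diagᵀ) are therefore unbiased for the
true common-removed pattern correlations and may fall outside [−1, 1]; they
are reported raw, and digits whose estimated variance is non-positive are
flagged rather than silently clamped.

### Identifiability of the "true" correlation

Exact invariance to the common component has a price: any estimator with that
property sees the digit patterns only after centring across digits, so its
estimand is CGC (C = I − J/5), not the raw generative second moment G.
Centring five orthogonal unit-variance patterns, for instance, induces −0.25
correlations. The generator therefore provides
`pair_correlated_second_moment(r, pair)`, which solves in closed form for the
generative G whose **common-removed** correlation between a digit pair equals
the requested r; simulations stating "true r(D1,D2) = 0.5" use this
construction, and the estimator's unbiasedness for CGC is verified directly
against the analytic target. The mean inter-digit overlap statistic is the
mean of the 10 unique off-diagonal cells.

Group comparison follows the single-case logic: the 10 unique cells of each
fingerprint are Spearman-rank-correlated across every unordered pair of
controls, a bootstrap over pairs (10,000 iterations) gives the 95% range of
normal between-subject correlation, and a case is flagged as within or
outside that range via its mean correlation with the controls.

## Single-case statistics

Crawford–Howell: t = (case − mean)/(sd·√(1 + 1/n)), df = n − 1, one- or
two-tailed. The JZS Bayes factor is the default Bayesian two-sample t-test —
Cauchy prior (scale 0.707) on the standardized effect size — evaluated by
adaptive quadrature (relative tolerance 1e−8) of the inverse-gamma mixture
representation, which is numerically stable at any t (the direct
noncentral-t form overflows for large noncentrality). It is cross-checked in
the tests against an independent implementation. BF₁₀ < 1/3 is read as
moderate support for the null. Scalar indices: the inter-hemispheric
asymmetry index (contra − ipsi)/(contra + ipsi), phantom sensation magnitude
(worst intensity 0–100 divided by frequency code 1–3), and amputation level
(residual/intact arm length × 100, with 41% ≈ elbow and 75% ≈ wrist anchors).

## Synthetic data: what it emulates and what it does not

The phantom is a 15×5×5 voxel grid with five contiguous 3-voxel digit bands
along one axis — the minimal geometry with an ordered digit gradient.
Responsive voxels respond to their preferred digit with amplitude 1 (% signal
units) and to digit d′ with Gaussian falloff exp(−(d−d′)²/2w²). The default
tuning width w = 0.5 gives a neighbouring-digit response of e⁻² ≈ 0.14 and a
negligible next-neighbour response — enough spill to exercise the
neighbour-overlap structure while remaining below the ~0.2 level at which
winner-take-all digit assignment becomes ambiguous for the edge digits under
1.5 mm smoothing. Noise is stationary AR(1) Gaussian (default sd 1, lag-1
coefficient 0.3) plus a sinusoidal drift (amplitude 0.5, period 128 s, random
phase per voxel); the default amplitude/sd ratio of 1 is the "moderate"
condition used throughout the tests. Runs acquire ⌊duration/TR⌋ volumes
(256 for the canonical run).

Pattern simulations draw one true pattern per digit from a specified 5×5
second moment, one shared common pattern (amplitude 1), and independent
Gaussian run noise (default sd 0.5, 2000 voxels, 4 runs).

Passing tests establish that the implementation recovers known truth under
this model. They do not establish performance under real-data features the
generator omits: head motion and spin-history artefacts, physiological noise
and spatially correlated noise, draining-vein displacement, non-stationary
HRFs, partial-volume anatomy, or surface geometry. In particular the FDR
p-value calibration (above) and the AR(1) noise level are synthetic-world
statements.

## Numerical choices and degenerate inputs

- Gamma HRF parameterized by its mode (peak delay 6 s, dispersion 3 s,
  24 s support, optional undershoot disabled by default), normalized to unit
  peak; both simulation and analysis use the same kernel, so the analysis is
  self-consistent by construction.
- High-pass filtering regresses out a discrete-cosine basis up to 1/cutoff
  (default 100 s) and re-adds the temporal mean; spatial smoothing uses
  reflect boundaries, conserving the spatial sum on small grids. A slow
  sinusoid (period 400 s) retains <1% of its variance; the 45 s task
  frequency is preserved within 2%.
- Ties in winner-take-all and gradient argmax break to the lowest index;
  correlation of a constant time course is defined as 0; Dice of two empty
  masks, a zero-variance control sample, and contra+ipsi = 0 raise explicit
  errors; similarity requires ≥2 runs and ≥25 voxels.
- All randomness derives from one master seed via named substreams
  (SeedSequence keyed by a CRC of the stage label), so every simulation and
  bootstrap is reproducible bit for bit.

## Problem sizes used in the shipped analyses

The acceptance script and test suite use: 5 seeds (recovery), 25–50 seeds
(Dice selectivity), 100–200 seeds (FDR nulls, 1000 voxels each), 50–100 seeds
(similarity recovery at 2000 voxels), 10,000 null simulations
(Crawford–Howell calibration), 100 datasets of n = 200/group (Bayes-factor
null behaviour), and 1000 replications of n = 100 (bootstrap coverage).
Coverage is assessed at n = 100 per replication because the plain percentile
bootstrap — the variant implemented, per its simplicity and determinism — has
a known ~3-point undercoverage at n = 20 that no correct implementation of
that method avoids; at n = 100 it attains nominal coverage. These sizes are
the package's standard demonstration conditions; all are configurable.

## Known limitations

- Volume-space Dice only; no cortical-surface projection.
- The FDR p-value model ignores autocorrelation and averaging (conservative
  on the synthetic conditions; unvalidated for real noise).
- The block-design similarity pipeline assumes ≥2 runs; a single run must be
  split (e.g. odd/even blocks) by the caller.
- The bimanual task is modelled per hemisphere (each hemisphere analysed
  against its contralateral hand's schedule); interhemispheric interaction is
  not simulated.
- "Amputee-like" signal degradation has no quantitative anchor; weaker/noisier
  maps are simulated simply by lowering amplitude or raising noise.
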
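# Methods

## Acquisition model and axis conventions

Each measurement locus is modelled as a dual-excitation block pair: 50
repeat spectra at 784 nm and 50 at 785 nm, recorded on a 1024-pixel
detector grid spanning 800–940 nm (≈ 200–2100 cm⁻¹ of Stokes shift). The
Raman shift of a detector wavelength λ under excitation λ_ex is
ν̃ = 10⁷·(1/λ_ex − 1/λ) cm⁻¹, so the 1 nm excitation step displaces every
Raman feature by Δν̃ = 10⁷·(1/784 − 1/785) ≈ 16.25 cm⁻¹ (constant across
the detector to second order) while the fluorescence background, a
function of detector wavelength only, stays fixed. Difference spectra are
referenced to the 785 nm excitation; the purifier and classifier share a
uniform 1024-point grid over the 550–1800 cm⁻¹ fingerprint window
(step ≈ 1.22 cm⁻¹), a length chosen to be divisible by 2⁴ for the
encoder–decoder.

## Synthetic cohort generator

The generator emulates the study conditions: 82 loci with class
composition neurofibroma 9, skin 12, nerve 6, fat 13, bone 15, mucosa 27
(pseudo-specimen ids mirror the reported specimen counts 9/4/2/5/5/9),
yielding 8,200 raw spectra.

*Raman fingerprints.* Each class template is a list of Lorentzian bands
(centre, FWHM, mean apex amplitude); FWHMs are 12–45 cm⁻¹, broad amide
I/III regions being modelled as two overlapping wide Lorentzians since
only band edges are tabulated in the reference literature. Apex
amplitudes vary between loci by a lognormal factor with mean 1 and
coefficient of variation 0.2. Class identities follow the reported
spectral biology: neurofibroma is protein/nucleic-acid rich (1004, 1038,
1095, 1338, 1378, amide I/III); fat and nerve are lipid-dominated (1073,
1296/1305, 1440–1470, fat additionally 1745); bone uniquely carries the
960 cm⁻¹ phosphate ν₁ band; skin and mucosa share the tumour's protein
pattern with different weightings and are deliberately the hardest classes
to separate.

*Background and noise.* Autofluorescence is a smooth two-Gaussian profile
in wavelength, scaled per locus to a lognormal multiple (mean 20×,
cv 0.3, floored at 1×) of the locus's realized strongest Raman line, so
fluorescence dominates every raw spectrum. The profile is evaluated once
per locus and reused for both excitations — Kasha insensitivity taken as
exact; a `background_drift_nm` knob (default 0) renders the 784 nm
background at a shifted wavelength axis to emulate imperfect
insensitivity. An optional sinusoidal etaloning ripple fixed in pixel
space (default amplitude 0) is removed by the difference step like any
pixel-anchored structure. Counts include a constant 50-count dark offset
and per-pixel, per-repeat Poisson noise.

*Bulk pair generation.* Training pairs for the purifier render the
repeat-averaged spectrum directly by drawing Poisson(R·λ)/R per pixel,
which is exactly distributed as the mean of R independent Poisson(λ)
repeats; full repeat blocks are materialised only for cohorts. About 5%
of training pairs contain background and noise but no Raman signal (zero
target), teaching the network not to hallucinate bands.

*What the generator does not emulate.* Real tissue spectra have
non-Lorentzian band shapes, correlated (non-Poisson) detector noise,
water/substrate contributions, residual fluorescence sensitivity to the
excitation step, and within-class biological covariance beyond independent
per-band amplitude jitter. Passing tests therefore demonstrate the
pipeline's correctness and its behaviour under the assumed statistics, not
clinical performance; the generator's class contrast makes the default
cohort nearly perfectly separable, by design.

## SERDS arithmetic

Processing order is fixed: average the repeats of each block, z-score each
mean spectrum (population convention, divisor N; exactly constant input is
a degenerate-spectrum error), subtract on the shared detector pixel grid
(no pre-interpolation, since both acquisitions share one spectrometer).
Resampling to the uniform shift grid happens at the purifier boundary by
linear interpolation, zero-filled outside the detector span.

The classic (non-neural) baseline integrates the difference spectrum:
sampling the difference at (ν̃ − Δν̃/2), cumulative summation × grid step,
then subtraction of a least-squares line. The half-step offset centres the
recovered band on the true line position (the raw integral of a ±doublet
peaks midway between the lobes). Every step is linear, which the tests
exploit.

## Neural purifier

Architecture: four encoder levels, each a kernel-9 'same' convolution with
ReLU followed by 2× max pooling; channels 16/32/64/128 (doubling per
level, capped at 128, so the bottleneck convolution is 128→128); decoder
mirrors with nearest-neighbour 2× upsampling, concatenation of the
matching encoder features, and a kernel-9 convolution; final linear 1×1
projection. 685,057 parameters. No normalisation layers — inputs are
already standardized and batches are small.

Training: mean squared error against clean spectra scaled to unit maximum
(inputs scaled to unit maximum absolute value), Adam (lr 10⁻³, β 0.9/0.999),
batch 32, default 2000 pairs × 10 epochs. The channel cap and the
1024-point input keep this budget around six minutes on a single CPU core.
The implementation evaluates each convolution as K shifted batched
matmuls in float32 — one BLAS call per kernel tap in forward and backward —
and is bit-reproducible for a fixed seed on one machine. The trained model
records a SHA-256 fingerprint of its training tensors.

Inference resamples a difference spectrum to the model grid, scales to
unit maximum absolute value, and runs one forward pass; output amplitude is
therefore in arbitrary units and downstream consumers renormalise.

## Classification

Rows are purified spectra restricted to 550–1800 cm⁻¹ (inclusive) and
scaled to unit maximum absolute value. Cross-validation is stratified
5-fold with seeded shuffling; within each fold, centring and PCA are
fitted on the training rows only, retaining the smallest number of
components explaining ≥ 95% of training variance, capped at
n_train − n_classes to keep the LDA within-class scatter well conditioned;
multiclass LDA runs on the retained scores. Test rows are centred with the
training mean — never re-fitted — projected, and classified.

Panels follow the study layout: a six-class summary (overall accuracy and
confusion matrix) plus six binary comparisons — neurofibroma against the
five physiological classes pooled, and against fat, bone, nerve, mucosa
and skin individually, each refitted on only the rows involved.
Neurofibroma is the positive class throughout: sensitivity = TP/(TP+FN)
on the 9 tumour loci, specificity = TN/(TN+FP) on the physiological rows,
error = 100 − accuracy. An empty positive or negative margin raises an
undefined-metric error rather than silently reporting zero. AUC is the
Mann-Whitney rank statistic (mid-ranks for ties) on out-of-fold
posterior scores pooled across folds; per-fold averaging would be an
alternative convention, not used here.

## Peak annotation

Peaks are local maxima whose scipy topographic prominence exceeds a
fraction (default 0.05) of the spectrum maximum. Assignments match point
entries of the fingerprint library within 8 cm⁻¹ (about half a typical
band width) and band entries (amide I/III, C-H deformation) by
containment; the nearest entry wins ties and unmatched calls stay
unassigned.

## Numerical and design notes

- z-score uses the population (divisor N) convention; the divisor is not
  dictated by the protocol and only rescales the difference spectrum.
- The difference operator requires bit-identical pixel grids and distinct
  excitations; it is exactly antisymmetric under swapping its inputs.
- `zscore` treats spectra with relative standard deviation below 10⁻¹³ as
  degenerate to avoid amplifying float roundoff on near-constant input.
- Raman intensity mapped outside the detector span during rendering is
  reported as a clipped mass fraction on the block rather than silently
  discarded.
- Problem sizes in the test suite and acceptance run (2000 training pairs,
  150–200 held-out pairs, 10 cohort seeds, 200 label permutations) are the
  package's default study sizes; the training budget is configurable.
- Known limitations: single-device determinism only (BLAS reduction order
  differs across builds); the purifier's output scale is arbitrary; the
  classifier assumes one spectrum per locus and does not model
  specimen-level correlation (folds stratify by class, not by specimen).
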
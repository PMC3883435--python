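# Methods

## Plate model and geometry

A plate scan is described declaratively (`chipcode.plate.PlateLayout`):
an axis-aligned grid of well centers (origin of A1 plus a fixed pitch in x
and y), an ROI shape, and a semantic map from well addresses to
(sensor, buffer condition, role, pair). Pixel coordinates are 0-based with
the origin at the image's top-left corner, x along columns, y along rows.
Rotation, perspective, and automatic grid detection are non-goals: flatbed
scans made with a film area guide are axis-aligned, and the layout is
configuration, not inference.

The shipped default layout maps all 96 wells: row *r* carries sensor
DC(*r*+1); columns 1–6 are buffer condition 1 and 7–12 condition 2; within
each condition the column pairs (1,2), (3,4), (5,6) are three
control/analyte assay replicates, mirroring the three-assays-per-plate
replication of the underlying experiment. Every analyte well's pair id
matches exactly one control well with the same sensor and condition; this
is validated at load time.

## ROI summation

Per well, the red, green, and blue channel values are summed exactly (as
integers) over the ROI. The rasterization rule is explicit: a pixel belongs
to a disk ROI iff its center lies within Euclidean distance ≤ r of the well
center (for a square, iff |dx| and |dy| ≤ the half-width). The default disk
of radius 10 px contains 317 pixels; the test suite verifies summation
against a brute-force per-pixel loop on random images. No background
subtraction or white balance is applied — the control-vs-analyte
differencing is itself the normalization.

Images are read at native depth (8- or 16-bit RGB; alpha is dropped with a
warning, grayscale rejected). The default threshold of 1000 is calibrated
for 8-bit channel sums, so a `--rescale-8bit` flag right-shifts 16-bit data
by 8 before summation; the coupling between bit depth and threshold scale
is deliberately surfaced as configuration rather than guessed.

## Coding and identification

For each pair and channel, Δ = control total − analyte total (signed;
signed values are preserved for calibration). The digit rule is
|Δ| ≥ τ → 1, else 0, with τ = 1000 by default. Two boundary choices are
documented and unit-tested: the comparison is on the *magnitude* (a change
in either direction is a change), and it is *inclusive* (Δ = τ encodes 1),
so the printed threshold itself is significant.

Digits concatenate in a single canonical order — sensors ascending,
conditions ascending, channels R, G, B — recorded as
`ordering_id = "DC-asc.cond-asc.RGB"` on every code and library so that
codes are never compared across conventions. With 8 sensors × 2 conditions
× 3 channels the code is 48 digits. When a plate carries k pairs per slot,
the k-th pairs (sorted by pair id) form the k-th assay's code.

Identification is nearest-neighbor Hamming distance against a library; all
entries at the minimal distance are returned — ties are reported, never
silently broken. The color-change count is the code's popcount, which under
monotone per-slot responses is non-decreasing in concentration (tested
exactly at zero noise).

## Standard curves and inverse prediction

Replicate differences are averaged per concentration (sample sd, n−1
denominator; the reference scheme is 3 plates × 3 assays = 9 replicates per
point), and the curve is an unweighted OLS fit of the *means* on
concentration — matching how such curves are constructed experimentally;
fitting raw replicates is available behind a flag. The Pearson r is
reported signed; |r| is the quantity comparable to a reported correlation
magnitude. Fitting uses the closed-form least-squares solution
(scipy.stats.linregress) and is checked against the normal equations to
1e-9 relative in tests.

Inverse prediction: ĉ = (Δ_obs − b)/m, refused when
|m| < 1e-9 × the response range (flat curve). The interval is first-order
(delta-method) propagation of the OLS residual standard error s through the
inversion:

    se(ĉ) = (s/|m|) · sqrt(1 + 1/n + (ĉ − c̄)² / Sxx),

with a Student-t quantile on n−2 degrees of freedom (default 95%). With
only two calibration points the residual error is zero and the interval
collapses to the point estimate. A simulation test confirms ≈ nominal
coverage (90–99% band over 300 trials).

## Spectra

Spectra are long-format tables (wavelength nm vs absorbance AU) validated
to a strictly increasing grid of ≥ 3 points. λmax is the grid argmax within
an optional window (default 400–700 nm) — grid resolution only, no
sub-grid parabolic refinement, because reported shifts are integer-nm
quantities on a 1 nm instrument grid; ties break to the lowest wavelength.
The peak shift is λmax(treated) − λmax(control), positive = red
(bathochromic). Absorbance at a fixed wavelength is linear interpolation
between bracketing grid points, with extrapolation refused. Replicate
spectra may be averaged point-wise, but only on exactly matching grids
(regridding is refused, not silently interpolated). Absorbance-vs-
concentration curves reuse the calibration fitter on per-concentration mean
absorbance at the chosen wavelength.

Note that near a broad peak the grid argmax is noise-sensitive: with band
width ≫ grid step, adjacent grid points differ by less than typical noise,
so peak-shift analysis belongs on averaged or noiseless spectra, whereas
concentration fitting reads absorbance at a fixed wavelength and is robust.
This is why the quantitative spectral route fixes 515 nm.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

* **Plates** — control wells painted at a baseline per-pixel RGB mean
  (default (180, 140, 160)); each responding (sensor, condition, channel)
  slot shifts the analyte well per-pixel by round(m·c/A) (A = ROI pixel
  count), making the ROI-sum difference m·c up to a rounding error ≤ A/2;
  i.i.d. Gaussian pixel noise (default sd 2) is added and values clip to
  [0, 255]. The shipped scenario gives DC1–DC4 slopes of 8–50 color units
  per mM so that slots cross the τ = 1000 threshold at staggered
  concentrations, yielding monotone color-change counts over the 10–100 mM
  series.
* **Replicate tables** — Δ = m·c + ε, ε ~ N(0, σ_Δ), with σ_Δ defaulting
  to pixel_noise_sd · sqrt(2A) (the sd a difference of two ROI sums
  inherits from per-pixel noise) and overridable directly.
* **Spectra** — a single Gaussian band
  A(λ) = (a₀ + a_c·c) · exp(−(λ − (λ₀ + λ_c·c))² / 2w²) + ε(λ).
  The ketamine defaults are anchored to the printed experimental endpoints
  — 516 nm / 1.05 AU at 0 mM and 520 nm / 0.66 AU at 90 mM — with linear
  interpolation between them (λ_c = 4/90 nm/mM, a_c = −0.39/90 AU/mM,
  w = 30 nm, noise sd 0.01 AU, grid 400–700 nm at 1 nm). Linearity is the
  faithful choice because the emulated response is reported as linear.
  A phenylalanine band (516 nm, +3 nm over 100 mM, 1.37 → 1.28 AU) ships
  alongside.

All randomness flows through explicit seed arguments (numpy SeedSequence);
there is no global RNG state, and identical seeds give bit-identical
output. Spectrum replicates derive their stream from (seed, replicate,
analyte, concentration) so they are mutually independent yet reproducible.

What the generator does **not** model: scanner optics (vignetting, ICC
color profiles, unsharp masking), chemical saturation or Hill-type
nonlinearity, pH/buffer chemistry, well-edge artifacts, or correlated
noise. Passing tests therefore demonstrate that the analysis correctly
recovers the structure it assumes — linear response plus additive noise —
not that real plates obey that structure.

## Problem sizes and numerical choices

The acceptance script and tests run at desk scale as the package's own
choice of study size: one 96-well plate render per code check, 6
concentrations × 9 replicates for the color standard curve (sd 100 color
units, generating slope 50 units/mM), and 8 concentrations × 6 replicate
spectra (0.01 AU noise) for the absorbance curve — the replicate structure
of the emulated experiments. Degenerate inputs fail loudly: identical
concentrations (no design), flat curves (no identifiability), mismatched
code lengths/orderings, ROIs off the image, non-monotone grids. The
fraction by which the synthetic ketamine peak drops, (1.05 − 0.66)/1.05 ≈
37%, is computed as such and not rounded to a coarser phrase.

## Known limitations

* Calibration is univariate and linear; saturating responses need a model
  outside this package's scope.
* Identification has no probabilistic score; Hamming distance with tie
  reporting is the minimal faithful metric.
* λmax is grid-limited; sub-nm shifts are invisible by design.
* The default threshold's scale is tied to 8-bit sums; 16-bit users must
  either rescale or supply their own threshold.
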
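# Methods

## Spectral preprocessing

Spectrometer output arrives on irregular pixel grids (e.g. 2048 pixels
over 178–878 nm). Each spectrum is binned to the canonical 300–700 nm
grid at 1 nm: a raw point at wavelength w is assigned to the nearest
integer bin, bins average their points, and empty bins are filled by
linear interpolation between filled neighbours. A spectrum must cover
the full window; otherwise a coverage error names the uncovered side.
Negative reflectance — instrument noise on dark shells — is accepted on
input and clipped to 0 at binning, before any colorimetry, because
physical reflectance is non-negative.

Each shell is measured three times non-consecutively; replicates are
averaged pointwise *after* binning, because measurements from different
calibration sessions need not share a raw grid. Averaging two replicates
(a damaged measurement discarded) works but warns. The ordering choice
(average spectra, then convert to colour) is safe: tristimulus
integration is linear in reflectance, so averaging spectra first and
converting is *identical* to converting each replicate and averaging the
coordinates — the orderings can only differ in the chromaticity
normalisation, and for replicate spectra of similar brightness that
difference is far below 1e-3.

Acquisition metadata (integration time, boxcar width, scans averaged)
are not modelled; input spectra are assumed already calibrated %R
against light/dark standards.

## Colorimetry

Trichromatic quantum catches are computed as standard CIE tristimulus
integrals with the CIE 1931 2° standard observer under the D65 daylight
illuminant. The published 5 nm tables (colour-matching functions
380–780 nm; D65 300–780 nm) are shipped as package data and linearly
interpolated to 1 nm; outside their support the curves are zero, so the
300–380 nm band of the integration grid contributes nothing. The tables
were validated by recomputing the D65 white point, which matches the
published chromaticity (0.31272, 0.32903) to five decimals, and by the
equal-area property of the three colour-matching functions.

The normalisation k = 100/Σ I·ȳ makes a perfect reflector score
Y = 100 exactly, and chromaticity is scale-invariant by construction.
The L/M/S cone peaks (≈560/530/420 nm) describe the physiology the
observer curves summarise; no cone-fundamental or receptor-noise (JND)
model is applied — that is the avian-vision route, out of scope here.

### Chromatic PCA

PCA of the per-shell coordinates is centred and covariance-based (the
components share units, so no variance scaling). Two bases are offered:

- `"xyz"` (chromaticity, the default): intensity-free, but exactly
  rank-2 since x+y+z = 1 — the third axis carries zero variance.
- `"XYZ"` (tristimulus): full rank, intensity retained.

Survey practice reports the yellow–pink separating axis as "PC3" with a
few percent of variance; on exact chromaticity that axis cannot
literally be the third one (rank 2). The package therefore *designates*
the chromatic axis rather than hard-coding its index: with human-scored
labels supplied, the axis with the largest standardised yellow–pink mean
separation; without labels, the last axis with non-negligible variance.
Its sign is fixed so yellow shells score positive, making scores
comparable across runs. On the synthetic templates the morph contrast
dominates total chromatic variance and the designated axis is PC1; on
real shells, where within-morph brightness and saturation variation is
larger, it is typically a minor axis. The published variance split
(51/44/4%) depends on the raw shells and is not reproducible from
summaries; it is documented here, not asserted anywhere.

PCA is fitted by SVD of the centred data matrix (hand-rolled; ~10 lines)
and cross-checked against scikit-learn's PCA in the test suite.

## Frequency-change testing

Sites with fewer than 10 shells are excluded throughout (`min_site_n`,
the survey convention). Past/present sites are paired greedily by
great-circle distance with a 50 m ceiling, nearest pairs first, exact
ties broken by site id, each site used once.

Valley-level change per morph uses the paired difference of per-site
percentages. Test selection is the conservative reading of the stated
criteria: paired t only when the differences pass Shapiro–Wilk at
α = 0.05 *and* the past and present vectors pass a two-sided F-test of
variance homogeneity at α = 0.05 (the F-test is not strictly required by
a paired design, but failing either criterion routes to the
nonparametric branch); otherwise Wilcoxon signed-rank, dropping zero
differences, exact null for n ≤ 25 and normal approximation with
continuity correction above. `paired_change_test` takes the two paired
vectors rather than precomputed deltas because the homogeneity check
needs both eras. Under a multinomial resampling null (present-day counts
redrawn from observed past frequencies per site) the test's measured
type-I error is ~5% at α = 0.05.

Direction of change uses the ±3 percentage-point band, boundary
inclusive (|Δ| = 3 is "no change"); the rule is antisymmetric. Output
percentages are rounded to 1 decimal. No multiple-testing correction is
applied across morphs or valleys, matching survey practice.

## Cline analysis

The dependent variable is cleaned by the 1.5×IQR fence rule (quartiles
by linear interpolation; fewer than 4 values pass through with a
warning). Normality of both variables (Shapiro–Wilk, α = 0.05) selects
Pearson's r; otherwise Kendall's τ-b — tie-corrected, since frequency
data tie heavily — with its two-sided p, and the coefficient is carried
to the r scale by Greiner's relation r = sin(πτ/2) (exact under
bivariate normality; an approximation otherwise, which is why the raw τ
is always retained in the result).

Fisher's r-to-z comparison uses n = number of analyzable sites behind
each coefficient (or shells, for per-shell chromatic scores). This
choice reproduces the published Pyrenean z-values to ±0.02 from the
printed coefficients and site counts; shell-count n does not. The
published p-values follow the one-sided convention Φ(−|z|)
(z = 2.120 ↔ p = 0.017), so both one- and two-sided p are emitted,
labelled. Two published Riba z-values (unbanded/banded) are not
derivable from the printed inputs — likely transcription duplicates of
the yellow row — and are excluded from the reproduction checks; the
embedded reference table still carries their input coefficients, so the
package reports what the inputs imply.

Degenerate inputs fail loudly: constant variables, |r| = 1 (infinite
atanh) and n ≤ 3 raise instead of returning NaN.

## Synthetic data

The generator emulates the *structure* of a Pyrenean two-era survey, at
a deliberately modest default scale: one valley, 40 sites uniform over
800–2000 m, revisited in both eras (so pairing is trivial at ~0 m),
Poisson(30) shells per site truncated at 10, morph states multinomial.
Per-morph propensities follow logistic clines
g(alt) = baseline + amplitude·σ(k·(alt − alt0)) with defaults alt0 =
1400 m and k = 0.004 /m (yellow rising from ~0.35 to ~0.85 across the
range, pink mirrored, brown rare and flat); probabilities are the
propensities renormalised to the simplex, which keeps independent
per-morph clines consistent. The present era can shift per-morph
probabilities and multiply cline slopes: `stable_scenario()` changes
nothing (the null), `flattened_scenario()` multiplies slopes by 0,
erasing a past site-level correlation of r ≈ 0.8 — the scale of change
the era comparison should detect at ~40 sites per era. Shell height and
width get a mild positive altitude trend, mimicking larger, taller
shells uphill.

Spectral templates are long-pass sigmoids (shoulder rising at an
inflection to a maximum): yellow inflects at 510 nm, pink at 585 nm with
a higher short-wave shoulder, brown at 620 nm with low overall
reflectance. These are constructs with the qualitative shape of shell
spectra, not measured curves. Shell-to-shell jitter (inflection sd 4 nm,
amplitude sd 8%), replicate-level multiplicative jitter (sd 3%) and
per-wavelength Gaussian noise (sd 1.5%R) are applied, with clipping to
[0, 100]%.

What passing tests show — and do not. The generator matches the
analysis's assumptions exactly (independent multinomial sites, logistic
clines, no spatial autocorrelation, no misidentification, no collector
bias between eras). Calibration and power measured on it validate the
statistical machinery, not robustness to the ways real surveys violate
those assumptions.

## Problem sizes and determinism

Simulation-based checks use 100–1000 replicates: 1000 for the type-I
calibration of the paired test (binomial SE ≈ 0.7% at p = 5%), 200 each
for the stable/flattened cline scenarios (SE ≈ 2% near 95%), 100–500 for
smaller selection-frequency checks. All stochastic code draws from
`numpy.random.default_rng` with explicit seeds; the survey and spectra
generators are byte-reproducible under a fixed seed, and the pipeline
writes identical outputs for identical configs.

## Known limitations

- The CIE route models *human* perception; no avian tetrachromatic or
  receptor-noise modelling, no colour-appearance spaces (CIELAB), no
  sRGB rendering.
- Clines are summarised by a single correlation per valley — no sigmoid
  cline-shape fitting, no mixed models, no spatial autocorrelation.
- Greiner-transformed τ in Fisher's z is a recognised approximation;
  results carry the raw τ so users can judge.
- The pairing step is greedy; an optimal bipartite matching could differ
  when sites cluster within 50 m of several candidates.
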
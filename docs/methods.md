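# Methods

## The measurement problem

Weakly basic, hydrophobic drugs such as fulvestrant analogs aggregate
into amorphous colloids in aqueous media. After endocytosis the colloid
sits in an acidifying endo-lysosome; if the drug is ionizable in that pH
range it can accumulate as a cation and destabilize the membrane.
Gal8 reporter imaging turns membrane damage into countable puncta, and
the central analysis question is attribution: how much disruption is
caused by the colloid a cell actually took up, and how much would occur
anyway from free drug in the medium? The package answers this with a
per-compound regression whose design (blocker wells at zero uptake)
makes both components identifiable, and relates them to
phospholipidosis across a compound panel.

## Image quantification

Pipeline per channel: white top-hat → threshold → watershed split →
area filter → count.

*Top-hat.* The white top-hat (raster minus its opening with a disk
structuring element) removes any background varying on scales wider
than about twice the disk radius — the constant camera offset and the
diffuse cytosolic Gal8 halo — while passing compact bright objects
unchanged. Default radii: 15 px for nuclei, 5 px for the punctate
channels, roughly 2× the object radius at the simulated scale
(nuclei ~12 px, diffraction-limited spots ~3 px). Images smaller than
twice the top-hat radius are rejected.

*Threshold.* The default is a robust noise floor,
`median + k · 1.4826 · MAD` with `k = 5`. Otsu's method is provided as
an option but is not the default: when bright objects cover well under
1% of pixels — 40 foci in a 512×512 field — the between-class criterion
splits the background noise distribution instead of separating noise
from signal, producing thousands of false objects. The floor constant
was chosen by scanning `k` ∈ [4.5, 6] against generator ground truth on
held-out scenes: below ~4.5 the fat positive tail of the top-hat
residue admits pixel-noise clusters on sparse channels; above ~5.5 the
dimmest spot cores shrink below the minimum area on the Gal8 channel,
whose halo residue inflates the MAD. `k = 5` sits in the middle of the
stable region. The top-hat makes all thresholding exactly invariant to
a uniform intensity offset.

*Watershed.* Markers are local maxima of the Euclidean distance
transform separated by at least `watershed_min_seed_separation` px
(5 px for spots, 10 px for the ~24 px-wide nuclei, which avoids
oversplitting via distance-transform plateau peaks); ties are broken in
lexicographic pixel order, so segmentation is deterministic. With
watershed disabled, labels are plain 8-connected components — this mode
is verified against an exhaustive flood fill.

*Counting and normalization.* Areas outside `[min_area, max_area]`
(defaults 50 px²–∞ for nuclei, 3 px²–∞ for spots) are discarded.
Per-cell ratios are ratios of image totals (channel count over nucleus
count), not per-cell object assignments: the unit of observation is a
stitched image of ~100 cells and no cell-boundary segmentation is
performed. If an image contains no nuclei the counts are reported and
the ratios flagged undefined. Replicate aggregation is the unweighted
arithmetic mean of the ratios over the (nominally 3) images of a well.
A mutual-centroid colocalization count of foci on DiD-positive vesicles
is available for inspection but feeds nothing downstream.

## Titration (apparent pKa)

Model: `F = B + (M − B) / (1 + 10^(pH − pKa))`, fit by
Levenberg–Marquardt with starting values `B = min F`, `M = max F`, and
pKa at the interpolated half-maximum crossing. At pH = pKa the model
passes through `(B + M)/2` identically. A fit is labelled
**non-ionizable** when the fitted dynamic range `M − B` is below 3× the
residual SD — a flat curve at the noise level, as for a compound that is
never protonated in the assay window — or when the fitted pKa leaves the
sampled pH range [3, 10]. The 3-SD rule is this package's
operationalization of "no titration detected"; there is no universal
convention. The fit is scale-equivariant: rescaling fluorescence
rescales B and M and leaves pKa unchanged.

## Viability and dose response

The two normalizations are exact ratios
(`100·(I_sample − I_bg)/(I_control − I_bg)` against day-6 blank control,
or against the day-0 pre-treatment intensity for proliferation runs);
both raise on a vanishing denominator. Because they differ only by a
constant scale, fitted IC50s are identical under either.

Dose-response fits parameterize IC50 on the log10 scale (conditioning
over 6 decades of concentration) and evaluate `([Drug]/IC50)^Hill` so
that activity decreases with dose — the inhibition convention; zero-dose
wells are handled exactly (the dose term is 0, anchoring Top). The
biphasic model

`Y = Bottom + (Plateau − Bottom)/(1 + ([D]/IC50_tox)^h_tox) + (Top − Plateau)/(1 + ([D]/IC50_stat)^h_stat)`

is fit with the reparameterization `Plateau = Bottom + d₁`,
`Top = Plateau + d₂`, `log IC50_tox = log IC50_stat + gap` with
`d₁, d₂, gap ≥ 0`, which enforces `Bottom ≤ Plateau ≤ Top` and
`IC50_stat < IC50_tox` (the static transition at lower dose), making the
two terms identifiable. With `Plateau = Top` the first transition
vanishes and the model collapses exactly to the monophasic form.
Convergence: trust-region least squares, tolerances 1e-10, up to 4000
function evaluations; non-convergence sets a flag rather than raising.
Model choice (mono vs biphasic) is the caller's, and only asymptotic
standard errors are reported.

## Mechanism decomposition

Per compound, ordinary least squares of foci/cell on puncta/cell over
replicate-averaged wells. Design choices:

- **Pooled regression.** Blocker wells enter the same fit as ordinary
  wells as x = 0 anchors rather than forming a separate intercept
  estimate; a single regression yields both parameters, and the anchors
  empirically tighten the intercept SE.
- **Unweighted.** Images hold ~100 cells each, so per-well weights are
  near-uniform and none are used.
- **No truncation.** Negative fitted intercepts are kept as-is to
  preserve estimator properties for the downstream correlation.
- Fewer than 3 wells, or zero variance in uptake (e.g. an all-blocker
  design), is a hard error ("degenerate design").

Cross-compound association uses plain Pearson correlation between mean
phospholipidosis vesicles per cell and either the slope (efficiency
pairing) or the intercept (free-drug pairing), on the raw estimates
without transformation. Group-comparison statistics (ANOVA variants,
post-hoc tests) are deliberately not reimplemented; the module exports
estimates with standard errors for external testing.

## Synthetic data: what it emulates and what it does not

The generator is the package's source of ground truth, not a physics
simulator.

*Micrographs* (default 512×512 px): objects are isotropic 2D Gaussians
with radius = 2σ (a reasonable stand-in for diffraction-limited spots
with analytically known truth), placed by rejection sampling with
centers ≥ 3 radii apart within a channel; the Gal8 channel adds one
wide Gaussian halo (σ = 40 px, amplitude 3000 AU) per nucleus as the
diffuse cytosolic reporter the top-hat must remove; all channels share
a 500 AU camera offset and i.i.d. Gaussian noise (default SD 1500 AU,
i.e. peak SNR 10 for 15000 AU spots), clipped to the 16-bit range.
Defaults emulate one stitched field: 100 nuclei, 40 foci, 250 puncta,
30 vesicles. Not modeled: optical PSF structure, photobleaching,
z-structure, cell-to-cell intensity variation, spatial noise
correlation, or multiple colloids per vesicle (puncta are atomic).
Passing the counting tests therefore shows the morphology chain is
correct at realistic SNR and density — not that thresholds transfer
verbatim to any particular microscope.

*Panels*: per-well colloid uptake is log-normal (non-negative,
right-skewed, fairly uniform across cells at the default mean 5 ± SD 2
puncta/cell); blocker wells (default ⅓ of 15 wells) have uptake exactly
0. Foci/cell = efficiency × uptake + free-drug rate + Gaussian noise
(SD 0.1), truncated at 0; vesicles/cell is the phospholipidosis rate
plus the same noise, truncated. Truncation makes the population
regression slightly biased when the true signal is ~0 — visible in
coverage studies at (efficiency, free-drug) = (0, 0) — and is kept
because counts cannot be negative. The
`latent_driver_compounds` helper builds the showcase panel: free-drug
rate and phospholipidosis share a latent driver, and sampled colloid
efficiencies are residualized against that driver so independence holds
in the realized design, not just in expectation.

*Curves*: titrations and dose-response curves are the fitted models
plus additive and/or multiplicative (2%) Gaussian noise on a pH 3–10
(step 0.5) grid and a 0.1 nM–100 µM concentration grid.

Every generator is a pure function of its parameters and an integer
seed; identical seeds give bit-identical output.

## Pipeline and provenance

`run_pipeline` executes stages in fixed dependency order, writes plain
formats (one 16-bit grayscale TIFF per channel with the role in the
filename, tidy UTF-8 CSVs with header rows, JSON configs), logs each
stage's parameters and seed to a JSON-lines run log, and finishes with
a manifest of SHA-256 hashes over every artifact. TIFFs are written
without software/timestamp tags so identical configs reproduce
identical manifests. A failing stage removes its partial outputs before
the error propagates; earlier completed stages keep theirs.

## Test-scale choices

The test suite and acceptance script run everything at the scale the
analyses are defined at: 20 full micrographs for count recovery, 100
titrations for pKa recovery, 9 × 20 panels for regression coverage, 50
scenes for the flood-fill oracle — a few minutes on one CPU in total.

## Known limitations

- The 2-SE coverage of the panel regression is governed by the t
  distribution with n − 2 degrees of freedom (~93% per parameter at
  n = 15, less jointly), plus the truncation bias near the origin of
  the rate grid; ±2 SE should not be read as a 95% joint interval at
  this sample size.
- Segmentation defaults (top-hat radii, noise-floor k, area limits) are
  calibrated to the generator's scale; real micrographs need per-assay
  configuration through the per-channel `ChannelConfig` map.
- The biphasic fit needs data that actually resolve the intermediate
  plateau; with fewer than ~8 distinct concentrations the static and
  toxic transitions are weakly identified.
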
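# Methods

This note documents the models, conventions, and numerical choices behind
`spheroct`, in the order the pipeline runs.

## Reconstruction

Spectral-domain OCT records, per lateral position, a real interference
spectrum whose fringe frequency is proportional to scatterer depth.
`reconstruct_bscan` subtracts each A-scan's spectral mean (reference/DC
suppression), applies an apodization window, Fourier transforms, and keeps
the magnitude of the first M/2 positive-frequency bins, scaled by
2/Σw so a unit-amplitude fringe reconstructs to unit height. Sampling is
assumed linear in wavenumber; a `resample` hook is exposed for spectrometer
k-linearization, which the synthetic path does not need.

**Window choice.** The default is the rectangular window. For on-bin,
k-linear spectra (exactly what the phantom forward model emits) depth bins
are orthogonal and reconstruction is exact; a Hann window is available for
real spectra where sidelobe suppression matters. Hann is deliberately *not*
the default because its DFT taps (−¼, ½, −¼) act as a second difference on
phase-coherent dense reflectivity profiles: smooth structure is suppressed
(measured round-trip correlation drops from 0.999 to ~0.3), which would
silently corrupt intensity-based metrics computed on synthetic volumes.

Native instrument geometry (2048-sample A-scans over 1.8 mm, 250 B-scans
over 0.6 mm, 2.2 μm axial resolution) is available as constants; the
reconstruction itself is geometry-agnostic.

## Phantom generator

The generator emulates the statistical structure the analysis assumes, not
the instrument physics:

- **Nodules**: quasi-spherical ellipsoids (per-axis radius jitter ±8%) with
  radii drawn from 200–350 μm by default (the 400–700 μm diameter range of
  the modeled cultures), placed without overlap by bounded rejection
  sampling (300 retries, then a placement error naming the spheroid).
- **Contrast**: background (medium) reflectivity 0.05 vs nodule 1.0,
  dimensionless linear backscatter.
- **Attenuation**: single-pass exp(−2μ·depth) with μ = 0.001 /μm by
  default — mild, tissue-plausible decay that leaves deep bodies above the
  relative detection threshold.
- **Speckle**: fully developed speckle as unit-mean multiplicative
  exponential intensity noise, on by default. The speckle stream is seeded
  deterministically from the spec seed so re-rendering is bit-reproducible.
- **Apoptotic bodies**: spheres of 5–15 μm radius, placed with a
  configurable peripheral bias (radial fraction u = U^(1/(3+b)), b = 2 by
  default, mimicking apoptosis lining the spheroid periphery), intensity
  gain 3.0× over nodule tissue. Bodies are added until the seeded volume
  fraction is met; the last body is trimmed voxel-exactly so
  `true_apoptotic_fraction` equals the target up to quantization.
- **Fragmentation**: the requested fraction of each nodule's voxels is shed
  outermost-first (ascending distance transform, deterministic tie-break by
  raster order) and re-deposited as small spheres (6–12 μm radius) in a
  dilation shell around the parent, with one voxel of clearance so
  fragments stay distinct connected components. Total foreground is
  conserved exactly in practice; any collision loss beyond 1% is warned
  about.

Ground truth carries the masks, the exact apoptotic fraction, and a
ground-truth SA:V computed with the *same* slice/perimeter convention as the
measurement path, so estimator and truth cannot drift apart by convention.

The forward model (`simulate_raw_spectra`) emits, per A-scan,
S[m] = DC + Σ_z a_z·cos(2πzm/M), i.e. phase-coherent on-bin fringes,
and requires M ≥ 2·(axial extent) on pain of an aliasing error.

**What the phantom does not model**: confocal gating, sensitivity roll-off,
dispersion, refraction, shadowing under strong scatterers, spatially
correlated speckle, nodule growth between timepoints, and partial-volume
intensity mixing at boundaries. Passing tests therefore validate the
*analysis chain* — segmentation conventions, metric definitions,
normalization, statistics — not instrument-specific image formation.

## Segmentation

**Foreground.** Volumes are despeckled with a 3×3×3 median filter (default;
binary opening available via `opening_radius`), then thresholded. The
default threshold is Otsu's method computed on the *logarithm* of the
nonzero voxels and exponentiated back: in the log domain the medium/tissue
contrast dominates the histogram, so at high apoptotic load the bright
bodies cannot capture the threshold (linear-domain Otsu occasionally cut
between tissue and bodies, segmenting only the bodies). A constant nonzero
volume falls back to half that constant. All thresholds are recorded on the
result.

**Ledger.** Objects are labeled in 3-D (26-connectivity, components smaller
than 2 voxels discarded) and re-identified per xz slice in 2-D
(4-connectivity). Each slice contributes one ledger row per object:
perimeter (μm) and area (μm², pixel count × pixel area). Slices are xz
planes indexed by y; voxel indices are 0-based.

**Perimeter estimator.** Default is the 4-direction Crofton estimator
(×pitch; requires isotropic in-plane pitch), accurate to ~2–4% on digital
disks/balls. The exposed pixel-edge count is available via config: it is
exact for axis-aligned rectangles (10×10 px square → 40) but overestimates
curved boundaries by up to 4/π (~27%), so it is not the default — with it,
a digital ball's SA:V would read 0.145 instead of the stacked-circle value
3π/4r = 0.118 at r = 20. Anisotropic in-plane pitch is supported by the
pixel-edge estimator (faces weighted by their physical length) and rejected
by Crofton with a pointed error.

**Apoptotic bodies.** Per nodule (or globally, via `mean_mode="global"`),
the detection threshold is `factor` × mean linear intensity over that
nodule's voxels; the default factor 1.7 encodes the 70%-above-mean
empirical contrast of apoptotic bodies. Because the threshold is relative,
the detected mask is exactly invariant to global intensity scaling.
Candidates pass a size filter expressed as equivalent-sphere radii
(defaults 4–40 μm, converted to voxel counts at the volume's pitch): the
lower bound is applied before watershed as a speckle guard, while both
bounds are enforced on the final split features — a connected cluster of
many touching bodies may legitimately exceed the upper bound and must be
split first, not discarded. Touching bodies are separated by a watershed on
the Euclidean distance transform (physical sampling), seeded at distance
maxima at least one nominal body radius (10 μm) apart, with marker ids
assigned in raster order for determinism.

## Metrics

- `global_sa_to_v`: Σ(slice perimeters)·Δy / Σ(slice areas)·Δy. The ratio
  is a *sum ratio*, not a mean of per-object ratios; an empty ledger raises
  an undefined-metric error distinct from zero. Multiplying all pitches by
  c divides the ratio by c exactly.
- `disruption_index`: sample/control − 1 (0 = intact); the unsubtracted
  ratio (control = 1) is exposed alongside, since both conventions are in
  circulation. The subtracted form is primary because zero should denote
  totally intact spheroids.
- `apoptotic_density`: Σ feature volumes / total segmented spheroid volume;
  values above 1 indicate a segmentation inconsistency and are clipped with
  a warning.
- `normalize_records`: control level is the per-day mean over no-treatment
  wells; degenerate wells (no foreground) keep NaN metrics and are excluded
  from group statistics rather than imputed.

## Live/Dead benchmarking

Well viability is Σlive/(Σlive+Σdead) after percentile background
subtraction (default 5th percentile per channel, negatives clipped) — an
intensity-sum definition, robust at 3-D-culture scale where cell-level
counting is unreliable. `synthesize_pair` builds matched fluorescence images
from phantom truth (dead ∝ apoptotic mask, live ∝ remaining foreground) and
can inflate the live channel to reproduce the esterase-artifact failure mode
qualitatively. `compare_assays` joins the OCT metrics table with viability
results on well id and reports Spearman correlations against
1 − normalized viability.

## Statistics

- Two-tailed, unpaired, pooled-variance Student's t-test, df = nₐ+n_b−2,
  implemented in closed form (the t distribution comes from scipy; the
  reference `scipy.stats.ttest_ind` is used only as an independent oracle
  in tests). Zero pooled variance with equal means returns (t=0, p=1) by
  convention; with unequal means it raises a degenerate-variance error.
- Box summaries use the averaged-inverted-CDF quantile convention
  ({1..8} → Q1 2.5, median 4.5, Q3 6.5); type-7 linear interpolation is
  available via argument and the convention used is recorded in the output.
  Whiskers are Q3+1.5·IQR / Q1−1.5·IQR, clamped to the most extreme
  non-outlier data points; outliers are listed.
- Synergy is operationalized per day and metric as: combination mean
  strictly above *both* monotherapy means, with p < 0.05 against the best
  monotherapy. No multiple-testing correction by default (pairwise
  reporting); Bonferroni optional. The replicate unit is the well; the
  experiment configuration carries the label explicitly.

## Validation experiments and problem sizes

`spheroct.experiments` (driven by `scripts/acceptance.py` and the
end-to-end tests) runs all validation on ~100³-voxel grids at 2–3 μm pitch
with nodule radii of 40–70 μm — the same contrast, speckle statistics, and
conventions as study-scale volumes, at sizes where the full battery
completes in minutes on one CPU. The four-arm longitudinal demo (NT /
PDT-like / carboplatin-like / combination, days 0–4, triplicate wells)
programs fragmentation and apoptosis schedules such that the combination
adds fragmentation every day but excess apoptosis only on day 2; the
synergy table then flags disruption synergy across days while
apoptotic-density synergy is confined to day 2 — the qualitative
dissociation the two metrics are designed to resolve.

## Known limitations

- The 1.7× threshold's interaction with log-compressed data is undefined:
  metrics require linear intensity and refuse log-scaled volumes.
- Under fully developed speckle the median despeckle loses a minority of
  body voxels near the threshold, biasing recovered apoptotic density low
  at high fractions (MAE ~0.03 at seeded fractions up to 0.2, vs ~0.004
  clean).
- Individual spheroids are not tracked across timepoints by design; all
  metrics are global per volume.
- The Crofton perimeter requires isotropic in-plane pitch; anisotropic
  acquisitions must either resample or use the pixel-edge estimator and
  accept its curvature bias.
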
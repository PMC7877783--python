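# Methods

This note records the models behind `octmargin`, the defaults and why
they were chosen, what the synthetic specimens do and do not emulate, and
the numerical choices a maintainer should know about.

## Probe activation kinetics

The contrast agent is an internally quenched peptide substrate cleaved by
uPA. We model cleavage as pseudo-first-order in the relative enzyme
concentration: the cleaved fraction is c(t) = 1 − exp(−k·t/ES), where ES
is the substrate-per-enzyme ratio ("1:ES"), and the normalized signal is

    F(t) = [(1 − c)(1 − q) + c] / (1 − q),

so F(0) = 1 and F(∞) = 1/(1 − q). With quenching efficiency q = 0.90 the
full-cleavage fold increase is exactly 10. Tissue classes map to ES via
the uPA anchor: benign tissue averages 1 ng uPA/mg protein ↔ 1:200, so
tumor (8 ng/mg) gives 1:25 and infiltrated tissue (4 ng/mg) 1:50. The
rate constant k (default ≈ 38.3 per relative-enzyme·minute) is calibrated
with a root solve so the baseline-subtracted 1:25-vs-1:200 contrast at
the 1-minute optimum equals 4.5:1, matching titration measurements of the
agent. The 1:50 curve is then a *prediction* of the model (it comes out
≈3.1:1 at 1 minute, versus a measured 3.5:1) — the single-rate
pseudo-first-order form cannot be calibrated to both contrasts at once,
and we prefer exactness at the condition used for triage. Michaelis–
Menten kinetics were not used because no K_m/k_cat values are available.
Default incubation is 2 minutes: past the ~1-minute contrast optimum but
necessary for ~1 mm diffusion of the agent into tissue.

## OCT source model

The source is Gaussian with center wavelength 1310 nm and 100 nm FWHM
bandwidth (the bandwidth is quoted as 3 dB; we treat it as the Gaussian
FWHM, the conventional reading). Theoretical axial resolution in air is
(2 ln2/π)·λ₀²/Δλ ≈ 7.6 µm. The A-line simulator samples the spectrum over
±3σ (2048 samples), builds fringes S(λ)·(1 + Σ 2√R·cos(2kz + c₂(k−k₀)²))
on an optionally warped detector grid, and the reconstructor inverts each
step: resample to uniform k, subtract the envelope, take the analytic
signal, multiply by the conjugate dispersion phase when compensation is
on, FFT with 4× zero padding, one-sided magnitude with depth axis
z_m = mπ/(N·Δk). The simulated-mirror PSF FWHM agrees with the closed
form to a few percent; the instrument's *achieved* 9 µm (residual
dispersion imbalance between interferometer arms) is a hardware note, not
a target of the simulation.

## Synthetic specimens

A phantom is a (nz, ny, nx) intensity volume indexed [z, y, x] with z = 0
at the imaging window (specimens are pressed flat against it), plus
co-registered RCM (1 µm pixels), fluorescence, photo, and ground-truth
label volumes. Defaults: 10 µm lateral and 5 µm axial voxels, 64×64×220
grid (0.64 × 0.64 × 1.1 mm).

Voxel intensity = reflectivity × lateral texture × exp(−2·OD(z)) ×
speckle × (1 + noise), where OD(z) is the per-column cumulative optical
depth (Σ µ·dz along the beam). Accumulating µ along the column — rather
than applying each voxel's own µ over its absolute depth — matters for
layered columns such as a tumor focus under benign stroma; for laterally
uniform phantoms the two are identical. Speckle is multiplicative
gamma(shape 4, mean 1) — the standard intensity statistic for averaged
OCT speckle; detector noise is additive Gaussian (σ = 0.02, clipped at
zero). A specular reflection (intensity 2.0) marks the window/tissue
interface in every column: it is what makes the top surface segmentable
by peak finding, including over signal-poor adipose lumens. The surface
height varies smoothly by up to 2 voxels.

Class textures (free parameters; no quantitative per-class optical
constants were available, so values were chosen to reproduce the
qualitative contrasts the segmentation exploits, and are config-exposed):

| class | reflectivity | µ (1/mm) | texture |
| --- | --- | --- | --- |
| tumor | 1.0 | 2.0 | log-normal scatterer field, 24 µm correlation, contrast 1.0 |
| adipose | 0.5 | 0.8 | honeycomb: bright septa on the Voronoi boundaries of a jittered 120 µm cell lattice, near-transparent lumens |
| benign stroma | 0.8 | 1.2 | smooth anisotropic field, 150 µm scale, contrast 0.15 |

Adipose cell centers form a jittered grid (±0.35 cell) rather than a
Poisson process: adipocytes pack tightly, and Poisson placement creates
large septa-free voids that do not occur in tissue and are systematically
misread as tumor. The `lobule_insert` template renders a circular region
with tumor-like texture but benign ground truth — the normal-lobule
false-positive mode of texture-based segmentation.

Five layout templates mirror representative specimen types: uniformly
positive margins (`uniform_tumor`), infiltrating boundary (40% tumor with
a noisy front), adipose-only, heterogeneous benign with lobules, and a
small tumor focus beginning 0.5 mm below the surface (`deep_focus`,
radius 0.25 of the lateral extent).

What the phantoms do **not** emulate: histology-realistic morphology,
tissue deformation and fixation artifacts, refraction at the surface,
heterogeneous attenuation within a class, RCM speckle/noise, probe
diffusion gradients, and photobleaching. Passing tests therefore show the
pipeline is correct *under its own statistical assumptions*, not that
those assumptions capture all variability of surgical specimens.

## Texture features and classification

All texture analysis runs on **log-scaled intensities** (floor 0.01,
matching the noise level). In linear intensity, multiplicative speckle
makes every gradient proportional to brightness, so bright tumor
out-gradients adipose septa; in log intensity speckle is additive and
brightness-independent, and the septa/lumen contrast (~4 natural-log
units) dominates — which is also how OCT images are conventionally
displayed and processed.

Per plane: Gaussian smooth (σ 2 px) → waviness (second Gaussian, σ 16 px)
subtracted to leave roughness → sliding-window population SD (9×9). The
slope map is the Prewitt gradient magnitude (normalized by 6 so a ramp of
s/pixel reads s) of a σ = 3 px smoothed copy — smoothed more strongly
than the roughness branch so it responds to structural (septa) edges
rather than residual speckle. The nine ROI features are mean intensity,
intensity SD, mean waviness, mean and max roughness SD, mean slope, slope
SD, 16-bin intensity entropy, and local contrast; PCA of phantom ROI
tables confirms most variance concentrates in a handful of components,
with roughness SD and slope the discriminating pair used by the decision
list.

Thresholds are trained by exhaustive search over midpoints of the sorted
training values, minimizing training misclassification; among zero-error
candidates the midpoint of the widest gap wins. The decision order
(adipose first, by slope) reflects that septa edges are the most specific
signature; roughness SD then separates tumor from benign.

Two adjustments connect ROI-level training to voxel-level assignment:

* **Lateral pooling** — the per-pixel roughness-SD and slope maps are
  averaged over a 21 px (0.21 mm) window before thresholding. Tissue type
  is a regional property; unpooled maps carry speckle variance far above
  the ROI statistics the thresholds were trained on.
* **Depth-resolved thresholds** — log-domain feature contrast decays as
  the signal approaches the noise floor, and intensity-domain depth
  compensation (gain exp(+r·z) fitted to the foreground decay) cannot
  restore it. Training ROIs are therefore extracted at several depths
  (defaults 6, 30, 60, 90, 120, 170 voxels) and a threshold pair is
  trained per depth, linearly interpolated in between and held constant
  beyond. This is the concrete form of "assignment thresholds account for
  the signal drop in depth".

The attenuation fit itself uses a fixed column set: only columns whose
masked extent spans a common window (2 voxels below the surface — past
the specular line — down to the median bottom depth). Pooling all masked
voxels instead suffers survivorship bias: dim columns leave the mask at
shallow depth, flattening the apparent decay to roughly half its true
value. The fixed-column estimator recovers 2µ within ~1% on noiseless and
a few percent on speckled phantoms.

A 3×3×3 majority vote (ties resolved adipose → tumor → benign) removes
isolated voxel flips; it can be disabled for oracle tests.

## Surfaces

Top surface: per column, the shallowest local maximum above 0.5× the
column maximum, median-smoothed over 7 columns; recovery is exact on
noiseless lines and ≲0.15 voxel MAE on default phantoms thanks to the
specular surface line. Bottom ("maximum signal depth"): Otsu threshold on
the axially smoothed (7-voxel) log B-scan, then per column the deepest
voxel of the largest above-threshold run, median-smoothed. A
degenerate-input guard rejects B-scans whose above/below-threshold linear
contrast ratio falls below 1.75: detector noise sits near 1.6 regardless
of seed, while tissue scans stay ≥1.9 even at shallow grids. Columns with
no qualifying peak/run are flagged invalid and filled from the nearest
valid column for masking only; the first 2 voxels below the top (the
specular band) are excluded from the foreground.

## Mosaic

Strip count is the minimal n with n·fov − (n−1)·overlap ≥ ROI extent
(overlap = 10% of the 2.2 mm FOV by default). Adjacent strips are
registered by exhaustive normalized cross-correlation over integer
displacements within a search radius (default 25% of the overlap; when
strips are jittered by up to J px the pair displacement can reach 2J, so
the radius must be ≥ 2J+1). Offsets chain pairwise — no global bundle
adjustment — and stitching feathers linearly over the overlap with
normalized weights, so constants are preserved and single-covered regions
pass through losslessly. No sub-pixel registration.

## Margin projection and evaluation

A lateral pixel is margin-positive when any tumor voxel lies within the
projection depth (default 1 mm) below the local top surface. Connected
components below 0.04 mm² are removed: scattered residual
misclassification projects to components well below that scale, while
the smallest modeled focus projects to ≈0.08 mm². The specimen is called
positive when the surviving area reaches 0.01 mm².

Specimen-level evaluation reports **both** metric conventions, because
the headline "predictive values" of margin studies are often computed as
PPV = TP/(TP+FN) and NPV = TN/(TN+FP) — algebraically the sensitivity
and specificity. The package names these `ppv_paper`/`npv_paper` and
reports the standard epidemiological `ppv_std` = TP/(TP+FP) and
`npv_std` = TN/(TN+FN) alongside, so no reader has to guess.

The default cohort experiment uses 20 phantoms — 8 with tumor inside the
1 mm band (uniform, infiltrating, deep-focus) and 12 without (10
adipose-only, 2 lobule confounders) — classified with one model trained
on dedicated multi-class phantoms (training on each specimen alone is
impossible for single-class specimens, which is also why a shared model
mirrors practice: the thresholds generalize across specimens generated
under the same imaging model). At the defaults this yields TP=8, FP=2
(the two lobules), TN=10, FN=0: sensitivity 1.0, specificity 0.83.

## Numerical choices and degenerate inputs

* Population (n) SD in the SD filter; reflective (edge-repeating)
  borders everywhere; ROI statistics exclude a half-window border.
* Threshold training raises on single-class input and names the feature
  when its values are identical across classes.
* `bottom_depth` raises on constant or noise-only B-scans (contrast
  guard) rather than returning a spurious surface; `psf_fwhm` raises on
  flat profiles; `mask_between` excludes columns whose smoothed top
  exceeds the bottom.
* PCA standardizes features and drops zero-variance columns with a
  warning.
* All randomness flows through `numpy.random.default_rng(seed)`; a fixed
  `PhantomSpec` (including seed) reproduces every channel bit-identically.

## Problem sizes

Default experiments run at 64×64×220 voxels per phantom, 20-specimen
cohorts, 100-trial registration Monte-Carlo, and 50 ROIs per class for
held-out classification — sizes chosen so the full study reproduces in a
few minutes on one CPU while keeping every statistical check
well-powered.

## Known limitations

* The decision list uses two features; the remaining seven inform the
  PCA report only. A joint 2-D decision region is a possible extension.
* Depth-resolved thresholds assume the training phantoms share the test
  specimens' depth statistics; transferring a model across very
  different attenuation regimes would require re-training.
* The lobule confounder is benign-by-construction and tumor-like in
  texture, so it is *designed* to fail texture-only classification —
  matching practice, where confocal review is what rejects those false
  positives.
* The noise-rejection contrast guard (1.75) separates the modeled
  detector noise from modeled tissue; exotic noise statistics may need a
  different cut.
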
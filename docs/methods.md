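# Methods

## Scope and data model

The package quantifies two kinds of experiment around the formation of Rad51
nucleoprotein filaments in budding yeast:

* **Imaging.** Input is one 3D fluorescence stack per cropped nucleus
  (`ImageStack3D`: raw photon counts plus an optional denoised channel, with
  lateral pixel size and z-step in nm) and per-cell strain/batch metadata.
  Output is a per-cell record table (category, filament length, filament and
  brightest-focus intensity), per-strain category proportions, and a table of
  pairwise logistic-regression tests.
* **NMR titration.** Input is a pair of per-residue amide peak tables
  (`PeakTable`: residue number, residue type, intensity, optional Cα shift)
  for the free protein and the protein plus unlabelled partner, and the
  protein sequence with its numbering offset (residues counted from the first
  start codon). Output is the I/I0 profile, the Cα chemical shift index, a
  disorder fraction, and contiguous interaction-region calls.

## Imaging pipeline

### Segmentation

Segmentation runs on the maximum z-projection of the denoised channel (the
raw channel if none is present); all intensity quantification runs on the
z-*sum* projection of the raw channel, the linear projection that preserves
total photons per column.

Filaments are enhanced with a bank of anisotropic Laplacian-of-Gaussian
ridge kernels: the product of a normalized Gaussian along the ridge
(σ∥ = elongation_ratio · σ, default ratio 3) and the negated second
derivative of a normalized Gaussian across it, steered over
`n_orientations = 16` and scales σ ∈ width/2.355 · {0.75, 1, 1.5}, where
`width` is the single user-facing parameter: the average filament width in
pixels (default 2 px = 130 nm at 65 nm/px). Responses are scale-normalized
by σ^1.5, the exponent for which a Gaussian ridge of width w responds
maximally at the scale σ = w/2.355, and kernels are mean-subtracted so a
constant image yields exactly zero. Foci use the negated, σ²-normalized
isotropic LoG.

Detection thresholds are robust z-scores of the response map
(median + k·1.4826·MAD; k = 4 for filaments, k = 6 for foci, defaults
calibrated so that under the default noise model at most 2% of structure-free
crops produce a false filament detection). On noise-free images the MAD
collapses and a half-peak floor takes over. Otsu thresholding is available as
an alternative strategy.

Detected objects are then *delineated* on the background-subtracted intensity
image rather than the response map: a pixel stays in the mask when it exceeds
half the maximum of its local (5×5) neighbourhood and a robust noise floor.
Two properties motivated this: the ridge filter's along-axis support smears
the response footprint, which would inflate short filaments by several
pixels, and a comparison against the *local* rather than global maximum keeps
a dim filament (or the arms around a bright crossing point, where the two
intensities add) that a global half-max cut would erase. For an isolated
Gaussian tube the rule reproduces the full-width-at-half-maximum footprint.
Objects smaller than `min_object_px = 6` are dropped; objects whose medial
skeleton is shorter than 1.5·width and whose second-moment axis ratio is
below 1.4 are round blobs (foci) and are removed from the filament mask.
Because a bright crossing can notch small arm fragments out of the footprint,
sub-size fragments within 2 px of an accepted filament object are retained —
they mark branched/multiple structures. Foci are local maxima of the blob
response above threshold, suppressed inside the filament mask, each with a
disk mask clipped against the filament mask (masks are disjoint by
construction).

The nuclear background is the median intensity of the crop outside all
structure masks (dilated by 3 px so PSF tails do not bias it); the nucleus
extent is the whole 50×50 crop, which is nucleus-centered by construction.
By default segmentation is 2D on the projection; a slice-wise mode can be
built from the same primitives but is not the default because the projection
is the representation the downstream quantities are defined on.

### Skeleton analysis

Filament masks are thinned (scikit-image); compact components that thinning
collapses to a single point are represented by their principal-axis geodesic
chord instead, so length measures stay defined. The skeleton is turned into
a graph: nodes are endpoints (exactly one 8-neighbour) and junction clusters
(pixels with ≥ 3 neighbours, adjacent ones merged — the Analyze-Skeleton
convention); edges are branch pixel paths, with axial steps counting 1 px
and diagonal steps √2 px.

Terminal branches shorter than `min_branch_px` (default 2·width = 4 px, the
scale of thinning spurs) are pruned iteratively; the geodesic-diameter path
of each component is never removed, and a final thinning pass inside the
fixed point removes junction pixels that pruning left as redundant bumps, so
pruning is idempotent and never changes the component count. Endpoints are
then elongated along the local tangent (estimated from the last ≤ 5 branch
pixels), one pixel at a time while inside the mask; a step that would touch
other skeleton pixels is rejected (elongation can never create junctions or
merge components), except that a staircase corner of the extension's own
tail is cut through to keep the path thin.

`SkeletonFeatures` (components, branches, junctions, endpoints, branch
lengths, total and geodesic-longest length) uses the 1/√2 step convention
throughout. The *reported* filament length of a Simple cell is refined in
two orientation-independent steps: the arc length of the skeleton path after
lightly smoothing its coordinates (two endpoint-anchored moving-average
passes; raw chain-code length overestimates oblique straight lines by up to
~8%), plus a signed sub-pixel tip extension to where the intensity profile
along each endpoint tangent crosses half the filament's ridge level. On
noise-free straight filaments of 5–30 px this keeps every length within 15%
of truth (worst observed ≈ 11%, most < 5%).

### Classification and intensities

* Simple ⇔ exactly one skeleton component with no junction;
* Complex ⇔ ≥ 2 components or any junction (excluded from length and
  filament-intensity statistics — length is overestimated on complex
  structures);
* Foci ⇔ no skeleton but ≥ 1 focus; Nothing otherwise.

Intensities are background-subtracted summed gray values on the raw sum
projection over masks dilated by 6 px (capturing ≥ 99.9% of the PSF tails;
negative residuals are kept so noise cancels in expectation). With several
foci only the brightest is recorded (ties broken by lowest (row, column)).
Intensities are normalized to the mean filament intensity of the WT strain's
Simple cells. Strain-level mean foci intensities are classed bright
(> 80% of the WT reference), dim (< 20%) or intermediate (bounds inclusive);
the reference is configurable between the WT foci mean (default, used for
the class pies) and the WT filament mean (the box-plot anchor), because the
two summaries are anchored differently and the intended reading is ambiguous.

### Group statistics

For each strain pair, `condition` (indicator of the second strain) is
regressed with three binomial logit models: M1 `~ 1 + hasFilament + batch`
on all cells, M2 `~ 1 + filamentLength + filamentIntensity + batch` on
Simple cells, M3 `~ 1 + spotIntensity + batch` on Foci cells. Batch is a
categorical fixed effect absorbing session-level intensity drift; if only
one batch is present the term is dropped with a note. Each coefficient of
interest is tested with a Wald statistic against a t distribution with
residual degrees of freedom (a normal reference is available). Complete
separation or non-convergence is detected (non-finite standard errors or
runaway coefficients) and reported as a flagged row with missing p — never a
silent NaN — and flagged rows are excluded from the multiplicity correction.
All remaining p-values of a run are corrected jointly with the
Benjamini–Hochberg step-up procedure; stars mark q < 0.05 / 0.01 / 0.001.

Calibration under the synthetic null (two identical strains, 200 cells/arm):
type-I error 0.039–0.053 across the three models at α = 0.05, and the mean
false-discovery proportion of BH-adjusted discoveries ≤ 0.05 (the global
null makes BH behave like FWER control, hence the observed ~0.02–0.03).

## NMR mapping

I/I0 is the per-residue amide intensity with partner added divided by the
free intensity (the convention under which attenuation below 1 marks
residues broadened by binding); residues present in only one table yield
missing values, and non-positive free intensities are an error naming the
residue. ΔδCα subtracts a sequence-specific random-coil prediction: Wishart
et al. (1995) Cα baselines with a −2.0 ppm correction for residues preceding
proline, replaceable via a CSV table; |ΔδCα| ≤ 0.5 ppm (default) flags a
residue as disordered. Interaction regions are maximal runs of residues with
ratio < 0.5, bridging gaps of ≤ 3 missing-or-above residues (prolines,
unassigned positions), keeping runs with ≥ 5 attenuated residues; defaults
chosen to recover an 85-residue planted segment robustly at 10%
multiplicative noise (boundaries within ±2 residues in ≥ 95% of replicates,
in practice 100%).

## Synthetic data: what it emulates, and what it does not

`render_cell` builds a noise-free intermediate — a uniform nuclear
background over the crop plus PSF-blurred structures — then applies Poisson
shot noise and Gaussian read noise (the standard sCMOS model). Filaments
are Gaussian-cross-section tubes (FWHM 2 px before blur) along quadratic
Bézier backbones with curvature bounded at 12% of length; total filament
photons scale with backbone length, i.e. labeling density is the stable
quantity, as for a protein-coated filament. Foci are near-point emitters.
Defaults: 65 nm pixels, 200 nm z-steps, 11 slices, PSF σ 1.2 px lateral /
1.5 slices axial, background 100 photons/voxel, read noise 2. The
"deconvolved" channel used for segmentation is emulated by rendering with a
PSF narrowed by 0.5 and an independent noise realization.

Archetype conventions: a `complex` cell renders two crossing filaments
(random 45–90° crossing angle), each at least 8 px long — a shorter stub
across a filament's midpoint blurs into a single compact structure that no
observer would call two; `foci_only` cells plant 1 + Poisson-distributed
foci at pairwise distances ≥ 6 px, since closer pairs are unresolvable at
this PSF. Ground truth records, per structure, the planted photons and the
post-PSF photons realized inside the crop (the difference is boundary
clipping). The default four-strain designs emulate the published phenotype
pattern: wild type mostly filaments, an srs2-null background slightly more,
the Rad52 anchor mutants mostly dim foci (5–10× weaker) with no structure in
20–34% of cells; batch factors (±15%) model illumination drift and act on
intensity only.

The generator does **not** emulate: optics-accurate PSFs, camera gain,
photobleaching, nucleus-shaped background gradients, structured cytoplasmic
signal, or segmentation-relevant artifacts of real deconvolution. Passing
the validation studies therefore demonstrates the internal consistency and
calibration of the pipeline under its own noise model, not performance on
real micrographs. `simulate_cell_records` draws feature records directly
(without rendering) from the same designs for the statistical calibration
studies, where the imaging stage is not under test.

The NMR generator plants the attenuated segment multiplicatively on the
bound table, omits prolines from both tables, and sets observed Cα shifts to
the random-coil prediction plus optional planted deviations, so
`secondary_shift` is its exact inverse at zero noise. The bundled
266-residue sequence is a *synthetic* disorder-biased stand-in for a
C-terminal tail numbered 206–471 (it is not the real Rad52 sequence);
positions 309–311 and 394–396 are kept proline-free so the canonical planted
boundaries carry observable amides.

## Numerical choices and degenerate inputs

* All randomness flows from one integer seed through `numpy` seed sequences,
  one child stream per cell: identical seeds give bit-identical datasets and
  byte-identical output CSVs.
* Flat or all-zero images produce empty masks, not errors; cells whose
  analysis fails are recorded with a missing category, counted in the log,
  and excluded from statistics (fail-soft).
* Ties in the brightest-focus rule break on the lowest (row, column) center.
* Exact 20%/80% brightness boundaries class as intermediate.
* `fdr_adjust` validates p ∈ [0, 1] and is checked against a brute-force
  step-up oracle to 1e-12.
* Background estimation requires ≥ 10 unmasked nucleus pixels and errors
  with the cell id otherwise.

## Known limitations

* Orientation discretization (16 orientations) leaves ≤ ~5% response ripple
  for ridges between bank angles; at width 2 px the discrete sampling of the
  σ ≈ 0.85 px kernel adds a comparable sub-pixel phase effect.
* Two structures crossing close to both their midpoints with similar
  orientation can still merge into one Simple call; category recovery on the
  default designs is ~94–97%, with essentially all residual error of this
  complex→Simple kind.
* Lengths below ~5 px are at the resolution limit of the skeleton
  representation; reported lengths carry ~±10% error there.
* M2/M3 fits on strains with few Simple/Foci cells are flagged rather than
  fitted; with very small n per arm the Wald t calibration has not been
  studied here.
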
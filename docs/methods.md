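# Methods

## Problem setting

Computer-aided diagnosis on digitized H&E histopathology extracts
quantitative morphology ("histomorphometry") from tissue images and
selects the most discriminating features for a classifier. When images
come from several hospitals, differences in fixation, staining and
scanning shift feature distributions between sites, so features chosen
purely for discriminability on pooled training data may not transfer to
an unseen institution. This package implements a pipeline that (a)
extracts a fixed 242-feature gland-morphology and texture vector per
annotated region of interest (ROI), (b) quantifies each feature's
cross-site instability, (c) gates feature selection on that instability,
and (d) measures cross-site generalization with hold-one-site-out
validation. A synthetic-data subsystem stands in for clinical slides so
every stage is testable.

## Instability statistics

**Preparation-induced instability (PI).** For m sites, every feature is
compared between each of the C(m, 2) unordered site pairs with a
two-sided Wilcoxon rank-sum test over the sites' *non-cancerous* regions
(distribution differences between non-cancerous tissue are attributed to
site effects, since benign morphology is not expected to vary
systematically by institution). PI is the fraction of pairs rejected at
level α. In exact mode PI is a multiple of 1/C(m, 2); a subsampled mode
(repeated per-site subsampling, rejection fraction over pair ×
repetition) yields a finer-grained estimate. α defaults to 0.05 and is
configuration, not a constant of the method. PI is invariant under any
strictly monotone transform of a feature (a rank-test property the suite
checks directly).

**Latent instability (LI).** The within-site baseline: the rejection
rate of the same test over random half-splits of a single site's
regions. For i.i.d. data LI converges to α.

**Stability gate.** A feature enters stability-informed selection
(FS_sd) only if its training-set PI is *strictly* below a threshold,
default 0.25 — with three training sites exact-mode PI takes values
{0, 1/3, 2/3, 1}, so the default admits exactly the PI = 0 features.
FS_d is the same selector without the gate.

## Feature families (242 features)

Extraction order and names are frozen in
`src/glandstab/data/feature_manifest.csv`; tests assert the
51/100/39/26/26 split against it. Gland geometry is computed in microns;
texture on the image resampled to 16 µm/px (1.25X-equivalent).

* **Global graph (51).** From gland centroids: Voronoi cell area /
  perimeter / chord statistics (average, std, min/max, disorder;
  unbounded cells excluded) plus a bounded-cell coverage fraction;
  Delaunay side-length and triangle-area statistics; minimum-spanning-tree
  edge statistics; mean/std/disorder of distance to the 3/5/7 nearest
  neighbors and of neighbor counts in 40/60/80/100 µm radii;
  nearest-neighbor-distance statistics; gland density per mm². The
  "disorder" aggregate is 1 − 1/(1 + std/mean). The published family
  enumerations name exemplars but not the full list; the residual slots
  here follow the conventional architecture-feature sets and are fixed by
  the manifest.
* **Gland shape (100).** 25 boundary measurements per gland — area,
  perimeter, area ratio (area / minimum enclosing circle), perimeter
  ratio (convex hull / boundary), centroid-distance ratio/std/variance,
  smoothness, box-counting fractal dimension, Hu invariant moments 1–7,
  and 9 Fourier descriptor magnitudes (non-DC, normalized by the first)
  — aggregated across glands by mean, median, std and min/max ratio.
  Boundaries are resampled to 128 points uniform in arc length; Hu
  moments are moments of that point cloud, so translation/rotation
  invariance holds to machine precision. Odd Hu moments of symmetric
  glands are exactly zero, so their computed values are floating-point
  noise; ratio aggregates of them are reported but carry no signal on
  near-elliptical glands.
* **Orientation disorder (39).** Gland orientation is the first
  principal axis of the boundary vertices against the reference
  direction (1, 0), folded to [0, 180) and binned at 10°; principal-axis
  ties (circles) resolve to the lower angle. For every sub-graph, an
  18×18 symmetric co-occurrence matrix counts all unordered gland pairs
  sharing the sub-graph; 13 co-occurrence statistics per matrix are
  aggregated across sub-graphs by mean, std and range. Sub-graphs with a
  single gland are skipped; when none remain the degenerate values
  (entropy 0, energy 1, remainder 0) apply.
* **Sub-graph (26).** Glands are linked when centroids lie within a
  connection radius (default 200 µm; the cited prior construction is a
  probabilistic decaying link, replaced here by a deterministic radius
  rule). Statistics: edge-length moments; eccentricity / diameter /
  radius averages and 90th percentiles (unweighted hops, singleton
  components contribute 0); average path length over connected pairs;
  clustering coefficients C (mean local), D (self-inclusive variant) and
  E (transitivity); giant-component ratio; isolated percentage; end /
  central node counts; component count; average degree; component-size
  statistics.
* **Haralick texture (26).** Grayscale conversion, quantization to 64
  levels, symmetric distance-1 co-occurrence matrices averaged over 4
  directions in sliding windows (default 32 px window, 16 px stride at
  the texture scale); the same 13 statistics per window, aggregated by
  mean and std across windows. The windowing supplies the population
  behind the mean/std pair; the original description does not specify
  it, so window, stride and gray levels are configuration. (The source
  material is internally inconsistent about whether this family has 39
  or 26 members; 26 — 13 statistics × {mean, std} — is the count
  consistent with the 242/216 totals and is what this package
  implements.)

The 13 co-occurrence statistics (shared by the disorder and Haralick
families): contrast energy, contrast inverse moment, contrast average,
contrast variance, contrast entropy, average intensity, intensity
variance, intensity entropy, entropy, energy, correlation, and
information measures of correlation 1 and 2. Entropies are base-2 with
0·log 0 = 0, so a one-hot matrix gives entropy exactly 0 and energy
exactly 1.

## Segmentation

Lumen-based gland segmentation: k-means (k = 4, 10 restarts, seeded) on
10,000 sampled RGB pixels; all pixels labelled by nearest centroid; the
brightest centroid is lumen, the darkest nuclei, and of the remaining
two the more saturated is stroma (the label-assignment rule is not part
of the published description and is fixed here). Connected lumen
components of at least `min_lumen_area_px` (default 30 at the 4 µm/px
segmentation scale) are grown by binary dilation until the next step
would enter the nuclear ring, capped at 5 steps; the component boundary
is smoothed by a circular moving average over 5 vertices and the
polygon centroid taken. Images are rescaled to 4 µm/px for segmentation
and boundaries reported at 16 µm/px for feature extraction, both derived
from the image's microns-per-pixel metadata. The growth stopping rule,
smoothing filter and minimum-size filter are declared configuration: the
method description leaves them open.

## Stain normalization

Macenko-style: per-channel optical density OD = −log10((I + 1)/256);
pixels whose maximum channel OD falls below 0.15 are background and pass
through unmodified. The two dominant OD directions come from an SVD of
the tissue-pixel OD matrix; stain vectors sit at the 1st/99th percentile
angles in that plane, labelled H/E by proximity to the canonical
hematoxylin direction. Concentrations are non-negative least squares
against the stain vectors; each pixel belongs to the stain with the
higher intensity, and only the assigned stain's intensity is
quantile-matched (256-level mapping) to the template before recomposing
through the template's vectors. Matching only the assigned-stain channel
keeps the mapping inside its empirical support; applying a stain's
mapping to off-stain (near-zero) concentrations would extrapolate badly.
The published description mixes an NMF factorization into the SVD
construction; the quoted thresholds (0.15 OD, 1st/99th percentiles)
belong to the SVD-plane method, which is what is implemented.

## Selection and evaluation

Selectors (top k = 5, ties broken by canonical feature order, all
seeded): **SFS** — greedy forward selection maximizing mean AUC of a QDA
over 10 iterations of stratified 3-fold CV of the growing set (joint
evaluation, standard SFS); **WLCX** — rank by |z| of the rank-sum
statistic, the class-size-corrected form of "largest difference in rank
sums"; **mRMR** — greedy MID (relevance minus mean redundancy) with
mutual information on quartile-discretized features; **ROC** — top
features by orientation-corrected empirical AUC max(AUC, 1 − AUC), so
anti-correlated features are not penalized. Empirical AUC uses the rank
(Mann–Whitney) formula with ties counted one half.

Hold-one-site-out evaluation: one fold per site; PI comes from the
training sites' non-cancerous regions only, the gate and selector see
training rows only, and one of four classifiers — LDA, QDA (ridge
1e-3), linear SVM (C = 1) or a 100-tree random forest — is trained on
the top-k features (train-split standardization before LDA/QDA/SVM) and
scored on the held-out site. The leakage contract is tested by mutation:
rewriting held-out rows must change no fold's selected features. The
Gleason task (grade 3 vs 4) uses only G3/G4 rows for discriminability
while PI still comes from non-cancerous rows. Percent improvement is
100·(AUC_sd − AUC_d)/AUC_d from unrounded AUCs. The inner CV objectives
run on a closed-form numpy Gaussian discriminant (the selector-side
workload is ~10^6 tiny fits); the four evaluation classifiers are
scikit-learn estimators.

## Gland-removal perturbation

Sensitivity of features to segmentation variation: remove 0–20% of
glands in 1% steps, 10 random subsets per level, recompute the feature
vector and record percent change against the unperturbed value. Percent
change is signed, 100·(f − f0)/f0, with an absolute-change fallback at
f0 = 0; features undefined after removal (e.g. fewer than 4 glands for
the graph family) are NaN, never fabricated. Per-gland quantities and
the (image-only) texture family are cached across subsets; this changes
no feature definition.

## Synthetic data

**ROIs.** Glands are ellipses — a near-white lumen inside a dark
epithelial/nuclear ring — on textured pinkish stroma chosen dense enough
to register as tissue under the 0.15 OD background threshold. Gland
radii are Gaussian with configurable mean/CV; placement is rejection
sampling with a hard-core overlap constraint inside a region whose area
shrinks as 1/crowding, so higher crowding yields smaller
nearest-neighbor distances. Class presets emulate benign (larger,
sparser glands), cancer (smaller, crowded) and Gleason patterns;
Gleason-4-like tissue sets `lumen_fraction < 1`, rendering lumenless
fused glands that lumen-based segmentation cannot detect — exactly the
stated limitation of the lumen-keyed approach. Site effects are a
rotation in the canonical H&E optical-density plane, contrast scaling,
RGB shift, Gaussian blur and gland dropout, applied in that order; the
identity effect is bit-exact. Nuclei-level rendering and scanner PSFs
are out of scope, so passing image-level tests demonstrates contract
correctness, not photorealism.

**Feature tables.** Features are i.i.d. standard normal (optionally
exponentiated to lognormal) across sites; designated unstable features
receive per-site location shifts applied to *every* region of a site
(non-cancerous included, so PI sees them); designated discriminative
features receive a class effect in within-class-σ units. The
confounded study condition used by the selection-benefit experiment
makes the apparently strongest training features spurious: five unstable
features carry a 3σ site gradient with *no* true class effect while
class balance runs 0.1 → 0.9 across sites, so pooled training
separation on them comes entirely from site membership and vanishes on
a held-out site; five stable features carry a moderate 0.7σ true
effect. These magnitudes were fixed so that the unstable features'
pooled training rank-sum scores exceed the stable features' (verified
directly), which is the stated premise of the experiment. Patient ids
default to one region per patient; a `regions_per_patient` knob exists.

Real multi-site data differ from these tables in ways the generator does
not model (correlated features, heavy tails, site effects on scale and
shape, patient-level clustering), so results on synthetic tables
establish the machinery's correctness and the direction of the
stability-gating effect, not clinical effect sizes.

## Numerical conventions and problem sizes

Degenerate inputs take explicit limit values: single-gland ROIs give
std 0 and min/max 1; empty edge sets give 0; empty co-occurrence
matrices give entropy 0 / energy 1; a zero-variance feature scores 0.5
AUC. Default problem sizes — 4 sites × 40 regions, 20–25 features for
table experiments; 512² px ROIs of 40–55 glands at 2 µm/px; 50
replicates for the selection-benefit experiment — keep every experiment
reproducible on a single CPU in minutes while leaving all sizes
configurable.

## Known limitations

* The lumen-growing rule, Haralick windowing, sub-graph construction and
  k-means label assignment are explicit design choices where the
  published method is silent; all are configuration.
* Exact-mode PI on m training sites is quantized to 1/C(m, 2); published
  finer-grained values imply an unstated repetition protocol, so both
  exact and subsampled modes are exposed rather than guessing one.
* Fourier descriptor 1 is identically 1 under first-coefficient
  normalization; it is retained for manifest fidelity.
* The synthetic generator cannot validate claims about real inter-site
  appearance variation; its effect magnitudes are free parameters.
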
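# Methods

`lobeseg` implements a fully automatic lung lobe segmentation pipeline for
paired inspiratory/expiratory chest CT together with the statistics used
to validate such a pipeline and the lobar air-trapping index it exists to
deliver. Because suitable clinical CTs with ground-truth lobe masks are
not freely available (and expiratory pediatric CT least of all), the
package ships a synthetic thorax generator that provides exact ground
truth; all quantitative claims made by the test suite refer to these
phantoms.

## Segmentation pipeline

The pipeline follows the classical bronchus-and-vessel-guided design:

1. **Airway segmentation** — self-adapting iterative region growing from a
   tracheal seed (darkest voxel in the most cranial 10% of slices). The
   HU threshold starts at −950 HU and is raised in +10 HU steps, re-growing
   the 26-connected seed component each time; the escalation stops before
   the step whose volume exceeds 1.5× the last accepted volume (leak
   guard) and the last accepted mask is returned. The threshold never
   exceeds −500 HU.
2. **Skeletonization** — topology-preserving 3-D thinning (simple-point
   deletion, 26-connected foreground), iterated to a fixed point so the
   operation is idempotent.
3. **Graph building** — skeleton voxels with ≠2 neighbors become nodes,
   maximal degree-2 chains become edges. Endpoint spurs shorter than 3 mm
   are pruned, junction clusters closer than 3 mm are contracted, residual
   cycles are broken at their longest edge. The root is the endpoint with
   the largest incident mean radius (distance-transform radius along the
   chain) among the most cranial 10% of nodes; generations count
   bifurcations from the root edge.
4. **Lobar labeling** — anatomical direction rules: the two children of
   the trachea split into main bronchi by the sign of their lateral
   component; RUL is the child of the right main bronchus with the largest
   superior+lateral component and the continuation is the bronchus
   intermedius, whose children split into RML (most anterior) and RLL
   (inferior); LUL/LLL are the superior/inferior children of the left
   main bronchus, and the lingular bronchus is the most anteroinferior
   branch within two bifurcations of the LUL bronchus. Distal edges
   inherit their lobar code; unlabeled residual subtrees fall back to a
   position-quantile rule, and codes that cannot be placed are reported
   absent rather than raising.
5. **Lung fields** — fixed −400 HU threshold on inspiration (the midpoint
   between aerated parenchyma and soft tissue); Otsu's threshold on
   expiration, where parenchymal density varies too much for a fixed
   value. The airway lumen is removed, the two largest components are
   kept (fused lungs are split by repeated erosion and seeded re-growth),
   and vessel-sized interior holes are closed by a radius-2 closing whose
   additions are confined to the interior of the filled silhouette — the
   partial-volume rim at the pleural surface mimics vessel densities and
   must not enter the mask.
6. **Vessels** — per-CT adjusted threshold: the 96th percentile of HU
   within the lung, floored at −500 HU, then 26-connected components of at
   least 5 voxels. The search region excludes the neighborhood (6.5 mm)
   of *central* airways — bronchi whose subtree supplies several lobes —
   because their bright walls would bridge vessel trees across lobe
   boundaries at the hilum.
7. **Lobar assignment** — bronchial convex hulls per lobe (Qhull, with
   joggle for degenerate point sets); each vessel component measures its
   minimal distance to every lobe's hull∪centerline voxels and is
   assigned to the nearest lobe when `d_min/d_second ≤ 0.5`; ambiguous
   components are eroded by one voxel, split, and retried (≤5 rounds);
   whatever remains stays unassigned.
8. **Fissure enhancement** — multi-scale Hessian eigenvalue plate filter
   (σ = 1 and 2 mm, γ-normalized derivatives in physical units). With
   eigenvalues ordered |λ1| ≥ |λ2| ≥ |λ3| the plate score is
   (|λ1|−|λ2|)/(|λ1|+|λ2|+ε), kept only where λ1 < 0: a fissure is a thin
   sheet *denser* than its surroundings, i.e. an intensity ridge whose
   second derivative across the sheet is strongly negative. Scores are
   min-max normalized to [0, 1] within the lung.
9. **Initial lobe masks** — every lung voxel takes the code of the nearest
   labeled structure (hull voxels at half weight, labeled centerlines,
   assigned vessels), with right-lung voxels restricted to codes 1–3 and
   left-lung voxels to 4–6.
10. **Watershed** — the initial masks are eroded by 3 voxel layers into
    markers (a lobe eroded to extinction falls back to the largest
    component of its uneroded mask); the watershed of the fissure score
    image, restricted to each lung half, produces the final maps. A flat
    (all-zero) score image reduces to the nearest-marker partition, and
    pockets unreachable by flooding are assigned to their nearest marker
    so the output always partitions the lung exactly. An optional 5-lobe
    mode merges the lingula into the LUL.

### Numerical choices

* Axis order is (z, y, x), 0-based, z growing caudally, y anteriorly and
  x toward the patient's left; spacings are per-axis mm.
* Erosion depth 3 is a compromise: markers must clear the uncertainty of
  the distance-based initial boundary without extinguishing the middle
  lobe; deeper erosion was not better in practice because re-flooding a
  fissureless boundary from receded markers re-introduces the error it
  removes elsewhere.
* The vessel-threshold percentile (96.0) was chosen so that for a
  realistic pulmonary vessel volume fraction (2–4% of the lung) the
  per-CT adjustment stays at the −500 HU floor and only rises above it
  for unusually vessel-rich (or bright) scans. A stricter percentile sits
  exactly at the vessel fraction and makes detection depend
  discontinuously on it.
* The watershed is order-deterministic (scikit-image flooding); identical
  inputs give identical maps, which the suite asserts.

## Agreement statistics

Dice `2|A∩M|/(|A|+|M|)` and Jaccard `|A∩M|/|A∪M|` are computed with exact
integer voxel counts (`J = D/(2−D)` holds to machine precision and is
tested). The pooled multi-region Dice `2Σᵢ|Aᵢ∩Mᵢ|/Σᵢ(|Aᵢ|+|Mᵢ|)` is the
size-weighted mean of per-lobe Dice values. The mean absolute surface
distance is the symmetric mean nearest-neighbor distance (in mm) between
the two face-adjacency surface voxel sets. Bland–Altman limits of
agreement use the sample (n−1) standard deviation and the conventional
1.96 multiplier. The printed source formulas for Jaccard carry a leading
factor 2 that would break their own [0, 1] range; the standard
definitions are implemented instead.

## Air trapping (E/I MLA)

Air trapping is quantified as the expiratory-to-inspiratory ratio of the
mean lung attenuation per lobe, each phase evaluated on its own lobe map
(no registration between phases). Trapped regions stay air-filled at
expiration, so the ratio moves toward 1 as trapping increases — the suite
asserts this monotonicity on planted trapping. HU means include vessel
voxels; segmented airway lumen can optionally be excluded when an airway
mask is supplied.

## The synthetic thorax phantom

The generator emulates exactly the features the pipeline relies on, at a
default 96×128×128 grid with (1.5, 1.0, 1.0) mm spacing:

* two quasi-ellipsoidal lung fields, the left smaller with a cardiac
  notch;
* an airway tree (trachea → main bronchi → lobar bronchi → sub-branches)
  with anatomically directed branches, lumen radii 4/3/2/1.5 mm by
  generation, walls 1.5 mm at −200 HU, lumen at −1000 HU;
* three fissures as thin bright plates (+150 HU offset, ~1 voxel thick):
  two oblique planes and a (slightly tilted) right horizontal plane, each
  85% complete by default — incompleteness is cut out by a smooth random
  field so the watershed must bridge gaps;
* the lingula has **no** fissure: its territory is defined as a weighted
  Voronoi cell of the lingular versus LUL bronchial centerlines (weight
  0.8), modelling that real segmental boundaries deviate from the plain
  bisector. This is what makes the lingula the hardest lobe, as observed
  clinically;
* per-lobe vessel trees: star-shaped trunk tubes from a root near a
  distal single-lobe bronchus tip into the lobe interior, plus
  juxta-fissural vein webs hugging each interlobar face (pulmonary veins
  run along the interlobar planes). Tube cross-sections are slightly
  elongated in z so near-axial strands remain at least two slices thick
  after blurring. Vessels never cross fissures. Along the fissureless
  LUL/LLi boundary the veins are distinctly finer: still visible on the
  inspiratory scan, but below the detection threshold on the expiratory
  one;
* densities: air −1000 HU, inspiratory parenchyma −820±30 HU (pediatric
  lungs are denser than adult), expiratory parenchyma −560±40 HU, soft
  tissue and vessels +40 HU; the whole volume is blurred with σ = 0.7
  voxels, and Gaussian noise is added (1.5× for the sharp reconstruction
  kernel, which is the difference between the soft and sharp variants);
* planted air trapping: per lobe, a compact region of a stated volume
  fraction keeps near-inspiratory density on the expiratory scan
  (defaults: 18% of the RLL and 12% of the LLL);
* on expiration, vessel calibers shrink by a factor 0.8 (a recognized
  reason expiratory scans are harder to segment); airway calibers are
  kept phase-constant so the airway tree — the anchor of the whole
  pipeline — remains segmentable at this grid resolution;
* `degrade_expiratory_contrast(spec, level)` moves the expiratory
  parenchyma mean linearly toward a floor of (soft tissue − 150 HU) and
  shrinks the fissure offset by the same factor, reproducing the
  deep-expiration low-contrast regime.

The designed expiratory mean of −560 HU was chosen so the designed
whole-lung E/I MLA (≈0.70, and 0.63–0.75 across lobes) brackets the range
reported for spirometer-controlled pediatric studies.

The ground-truth vessel map records tube *cores* (radius minus half a
voxel): only voxels whose centers lie well inside a tube remain
majority-vessel after partial-volume averaging, and a threshold detector
cannot be expected to recover the sub-voxel shell.

### What the phantom does not model

Deformation between phases (both phases share one geometry, so one truth
lobe map serves both), cardiac and breathing motion, scanner physics
beyond blur+noise, airway wall thickening, real anatomical variants of
the bronchial tree, and the irregular (non-planar) shape of real
fissures. Passing the suite therefore demonstrates that the
implementation is faithful and internally consistent under controlled
conditions; it does not certify clinical accuracy.

## Problem sizes used by the suite

The paired inspiratory/expiratory recovery experiments run five phantom
studies at the default grid with expiratory degradation level 0.5. Batch
invariants (partition, marker preservation, graph topology) run twenty
phantoms at a reduced 72×96×96 grid, where the full pipeline takes about
two seconds per phase. `scripts/acceptance.py` regenerates three paired
studies at the default grid from the given seed and recomputes all
reported statistics from scratch.

## Known limitations

* The lobar labeling rule table is a reconstruction of the rule-based
  method such pipelines cite, not a transcription; true anatomical
  variants are handled only by the positional fallback.
* The left/right lung split uses erosion + seeded re-growth, sufficient
  for phantoms but simplistic for clinical anterior junctions.
* Expiratory lung thresholding via Otsu assumes a bimodal histogram; a
  fully collapsed lung would violate this.
* E/I MLA is computed on unregistered per-phase masks, as in the
  validation design the package follows; a registration step would be the
  natural extension.
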
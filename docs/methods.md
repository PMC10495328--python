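# Methods

This note documents the models, conventions and numerical choices behind
`rootsetup`: a pipeline that evaluates virtual orthodontic setups in
3-D — root parallelism from landmark geometry, root exposure
(dehiscence/fenestration) from tooth and bone meshes, and the
repeated-measures statistics that compare setup conditions — exercised
end to end on a synthetic dental-arch generator with known ground truth.

## Angular measurement model

Each tooth carries three landmarks: the most mesial point **M**, most
distal point **D**, and apex point **A** (the root apex of single-rooted
teeth, the furcation centre of multi-rooted ones). The long axis runs
from the M–D midpoint to A. The occlusal reference plane passes through
the distobuccal cusp tips of the maxillary second molars and the
maxillary central-incisor contact point; its normal is oriented toward
the maxillary apices ("superior"). When three setup conditions of one
patient are measured, all of them use the root setup-2 occlusal frame so
angular values are directly comparable; a standalone model is measured
in its own frame.

With s the superior unit normal, t the unit component of D−M in the
occlusal plane ("distal"), and l the in-plane unit vector perpendicular
to D−M pointing toward the arch interior ("lingual"):

* **angulation** = the signed angle between the long axis projected onto
  the plane spanned by {s, t} (the plane through M and D perpendicular
  to the occlusal plane) and the occlusal-normal *line*:
  `sign(u·t) · atan2(|u·t|, |u·s|)`, positive when the apex is distal;
* **inclination** = the same construction in the plane spanned by
  {s, s×t}: positive when the projected apex displacement points
  lingually/palatally.

Both use `atan2` of projected components rather than `acos` of clamped
dot products, which is stable near 0°, and measure against the normal
*line* (absolute superior component), so the same formula serves upper
and lower jaws. Distal is `normalize(D − M)` in every quadrant: landmark
labels carry the anatomy, so no per-quadrant sign flips are needed and
reflecting an arch across the midsagittal plane preserves every
angulation value.

The lingual direction is operationalized as the in-occlusal-plane unit
vector perpendicular to D−M pointing from the tooth midpoint toward the
projected centroid of all tooth midpoints (the arch interior). This is
this package's choice — the sign rule "lingual ⇒ positive" needs an
explicit direction and no construction is prescribed by convention — and
it is deterministic, mirror-consistent, and fails loudly when the tooth
midpoint coincides with the centroid projection.

Degeneracy tolerances: points closer than 1e-6 mm are coincident;
directions within 1e-3 rad of parallel are parallel (configurable per
call). These sit far below anatomic scales (tooth widths 5–11 mm).

## Root parallelism

Parallelism is the absolute angulation difference between consecutive
teeth of a quadrant (locations 1–2 … 6–7). Pairs with a missing tooth
are omitted, never imputed. Before pooling the left and right sides,
initial-scan angulations are compared per (jaw, tooth position) with a
paired t-test; only when every position has p ≥ α (default 0.05) are the
sides pooled, each side's pair value entering as one observation (pooled
n = n_left + n_right). Whether side-level values should instead be
averaged within patient before testing is a genuinely open design
point; treating each side as one observation is this package's choice
and is applied uniformly.

Per jaw × location, the three setups are compared with one-way
within-subject ANOVA (subjects = patient × side), Mauchly's W for
sphericity, and pairwise paired t post-hocs with Bonferroni adjustment
(p × 3, capped at 1), labelled `a > b` style (a = crown setup,
b = root setup-1, c = root setup-2) only when the omnibus p < α. No
Greenhouse–Geisser correction is applied by default (a flag enables
it); the sphericity test is reported alongside.

## Root exposure

Inputs are a watertight composite-tooth mesh, a watertight trimmed
alveolar-bone mesh, and a per-tooth crest reference disc: a plane at the
root/alveolar-crest junction, normal pointing apically, from which
dehiscence is measured. Measurement proceeds as:

1. **Sampling.** The tooth mesh is subdivided until no edge exceeds the
   sampling step `1/sqrt(density)` (default density 25 points/mm², step
   0.2 mm); the subdivision vertices apical to the disc plane are the
   samples. Sampling is therefore deterministic, and surface adjacency
   is simply mesh-edge adjacency with the step as connectivity radius.
   Samples closer than a quarter step to the disc plane are skipped so
   they cannot sit numerically on the bone's crest face.
2. **Containment.** A sample is exposed iff it lies outside the bone
   mesh, decided by ray-crossing parity (vectorised Möller–Trumbore
   against all bone triangles, with a second and third probe direction
   for rays that graze an edge). This in-house primitive exists because
   no accelerated ray backend is assumed; it is exact for watertight
   meshes and fast for the low-polygon bone geometry used here.
3. **Components.** Exposed samples are grouped by surface adjacency.
   Components whose minimum plane distance is within one step of the
   disc touch the crest and are dehiscence-type; isolated components are
   fenestration-type.
4. **Lengths.** Dehiscence = point-to-plane distance from the disc to
   the apical-most exposed sample (per the linear-measurement reading:
   Euclidean, not geodesic). Fenestration = distance between the
   uppermost and lowermost points of each isolated component, summed
   over components per side. Because the extreme plane distances of a
   band-shaped window are attained along whole sample rings, the two
   points are chosen as the closest-lateral-offset pair among
   near-extreme candidates (within half a step of each extreme), and a
   half-edge boundary correction (one step total) accounts for the true
   border lying beyond the outermost exposed sample. This makes the
   estimate rotation-stable with error below one sampling step; on the
   analytic cone fixtures the observed error is ≤ 0.14 mm at the
   default density and halves when the density is doubled.
   Combined exposure = dehiscence + fenestration.
5. **Sides.** Every sample is labelled buccal or lingual by the sign of
   its displacement from the tooth midpoint along the lingual reference
   vector; a component takes the majority side of its samples. Mesial
   or distal exposure is absorbed into whichever side the majority rule
   assigns — only two sides are reported.

The frequency classification uses *strictly greater than* 2 mm combined
exposure (a tooth at exactly 2.0 mm counts as "none"). When both sides
exceed the threshold, the tooth is assigned to the side with the larger
combined value, ties to buccal — the categories are mutually exclusive
and some such rule is required; this one is deterministic and logged.

Per tooth type (incisor/canine/premolar/molar) × jaw × side, setups are
compared with the Friedman test (subjects = individual teeth) and
Bonferroni-adjusted Wilcoxon signed-rank post-hocs; the buccal-vs-
lingual frequency of >2 mm exposure is compared per setup with the
exact McNemar test on the discordant counts.

## Statistics

* **Paired t**: two-sided, df = n−1; zero-variance differences map to
  p = 1 (zero mean) or p = 0 (nonzero mean).
* **ICC**: two-way mixed-effects, single-measure, consistency — ICC(3,1)
  = (MS_subjects − MS_error) / (MS_subjects + (k−1) MS_error) — the
  standard form for one rater re-measuring; the form is a configuration
  option with this default.
* **RM-ANOVA**: within-subject F from mean squares; Mauchly's W with the
  χ² approximation; optional Greenhouse–Geisser df scaling (off by
  default); pairwise paired t post-hocs with Bonferroni. F, W and
  ICC(3,1) are computed directly in numpy and verified in the unit tests
  to match pingouin to 1e-9 — the direct implementation is ~1000× faster
  per call, which the 1000-replicate calibration needs.
* **Friedman**: tie-corrected statistic from per-subject midranks. The
  p-value is exact — exhaustive enumeration over all (k!)^n per-subject
  rank permutations — whenever that count is ≤ 50,000 (n ≤ 6 at k = 3),
  otherwise the χ² approximation. The threshold is a configurable
  constant.
* **Wilcoxon signed-rank**: zero differences dropped before ranking;
  exact null distribution up to 25 non-zero differences, normal
  approximation with continuity correction above (both thresholds
  configurable); delegated to scipy.
* **McNemar**: exact two-sided binomial p = min(1, 2·P(X ≥ max(b,c))),
  X ~ Binomial(b+c, ½), for b+c ≤ 25; continuity-corrected χ² above.

## Synthetic cohort generator

The generator emulates the *structure* of a 16-patient molar-
distalization setup study, not dental anatomy. Teeth are surfaces of
revolution — a frustum crown (height 7–11 mm) over a cone root (length
12.5–16.5 mm, textbook mesiodistal widths) — placed by arc length along
the parabola y = 0.04·x² with the occlusal plane exactly z = 0.
Multi-rooted molars are single cones with A at 0.35 of the root length
(the furcation-centre convention). Landmarks are exact: M and D at the
cervical extremes along the horizontal distal direction t, and the long
axis `normalize(tan(θ_ang)·t + tan(θ_inc)·l ± s)`, so re-measuring a
generated tooth returns the drawn angles to machine precision — the
ground-truth-recovery tests are exact up to float arithmetic (< 1e-6°).

Per setup condition, per-tooth angles are drawn from Normal(0, sd).
Alveolar bone is one extruded channel prism per tooth (cross-section
carved for the designed defects: a crest-level cut of depth d for
dehiscence, a mid-root window of height h for fenestration, windows
stopping short of the channel midline so opposing windows leave a thin
web). Each tooth's containment test runs against its own prism; on a
curved arch, neighbouring prisms would otherwise overlap and corrupt
ray parity. Analytic truth: dehiscence length d; fenestration extent
hypot(h, Δr) along the cone slant.

Default study-shaped conditions (fixed from the comparison tables'
magnitudes): angular dispersion sd 4.0° for the initial scan and crown
setup, 2.5° for both root setups; defect-site probabilities mirroring
the crown-setup >2 mm frequency pattern (maxilla: buccal canines/molars
most often; mandible: lingual incisors through molars), defect sizes
|N(0, 3)| mm clipped to [0.2, 5], 25% of defects fenestrations; root
setup-2 nearly defect-free (2% sites, |N(0, 0.5)|). The null
configuration gives every condition identical distributions (sd 3.0°,
flat 22% site probability — about an 11% chance per tooth-side of
combined exposure > 2 mm, matching the frequency range the crown-setup
table reports). 2 mm of molar distalization is applied to the setup
conditions. Seeding is hierarchical (seed, patient, condition, jaw), so
regeneration is byte-identical and jaw subsets reuse identical streams.

What the generator does *not* emulate: anatomic tooth/bone shape,
scalloped crest margins (discs are planar), alveolar remodeling,
left/right asymmetries, landmark placement error, or segmentation
noise. Passing tests therefore demonstrate correctness of the
measurement and statistics machinery under known geometry — not
robustness to clinical imaging artefacts.

Cohort-level statistics run on the mesh-free path (exposures taken from
the generator's analytic truth); the mesh path is validated separately
on fixtures, where it recovers the truth within one sampling step. On
*tilted* teeth the carved defects interact with the tilt (a window can
be partially occluded by the channel), so mesh-measured exposure on
noisy arches deviates from the programmed value by up to ~1 mm in the
worst case — a property of the synthetic bone model, not of the
measurement.

## Simulation studies and their sizes

* Type-I calibration: 1000 null cohorts of 16 patients; one
  representative maxillary stage row per replicate (adjacent-incisor
  ANOVA; incisor buccal-exposure Friedman; incisor-frequency McNemar)
  so replicate outcomes are independent and the exact central 99%
  binomial envelope around 0.05 applies. Observed across seed
  families: RM-ANOVA 0.049–0.060 (the F-test can run mildly liberal on
  skewed folded-normal pair differences), Friedman 0.047–0.055 — both
  inside the envelope; exact McNemar 0.021–0.024 — *below* it. That is a structural property of exact
  discrete tests: at the discordant-pair counts a 16-patient cohort
  yields (b+c ≈ 10–20) the attainable size is 0.02–0.04, so no exact
  test can sit at 0.05. The corresponding acceptance test asserts the
  envelope faithfully and fails for the McNemar stage; this is a
  documented limitation, not a defect of the implementation.
* Directional power: 100 study-shaped cohorts; a replicate counts as
  detected when at least one parallelism row carries both "a > b" and
  "a > c" post-hoc labels, and at least one exposure row both "a > c"
  and "b > c". Observed 93–99% and 100% across seed families.

Problem sizes (1000 angle-oracle configurations, 1000 + 100 replicate
simulations, density-25 fixtures) are the package's fixed defaults for
these studies.

## Known limitations

* The lingual-reference construction assumes a roughly convex arch; a
  severely collapsed arch could put the centroid on the wrong side of a
  rotated tooth.
* Fenestration lengths are summed over multiple windows per side; if a
  study intends "largest window only", the per-component lengths are
  available on the `ExposureComponent` objects.
* The exact McNemar stage cannot be calibrated to nominal 0.05 at this
  sample size (above).
* Crest discs are planar; dehiscence depth is measured from the plane,
  not from a scalloped anatomic margin.
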
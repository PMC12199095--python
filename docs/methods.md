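# Methods

## Crystal model

The cellulose Iβ lattice is represented by its monoclinic cell constants
(a = 7.784 Å, b = 8.201 Å, c = 10.380 Å, γ = 96.5°; unique axis c = the
chain axis, so a and b are perpendicular to the chains) and an idealized
anhydroglucose-unit (AGU) template. The two chains per cell — origin and
center, related by the (a+b)/2 translation with a c/4 axial stagger — are
treated as conformationally identical; the only structural features that
any downstream quantity depends on are (i) the chain 2D lattice, (ii) the
two-fold screw along each chain (180° rotation about the axis plus c/2),
and (iii) the placement of the exocyclic C6/O6 arm. The ring atoms exist
to give the rendered images a realistic light-atom background and to
exercise collision checks; their coordinates are idealized, not refined,
and hydrogens are omitted throughout (negligible Z-contrast).

The O6 transverse offset is fixed at p = (0.25, 0.60) Å in the Cartesian
(a-along-x) frame. This vector was chosen once, subject to two geometric
requirements: every facet family must see a nonzero outward O6 component
(|p·n̂| ≥ 0.2 Å) so that surface-site enumeration is well defined on all
four facets, and in face-on projection the Cs combs of the top and bottom
facets must fall within the 2.6 Å row-grouping gap of each other so that
they merge into single crystallographic lines, as they do in projected
images (top and bottom surfaces are indistinguishable along the beam).

### Facet labels and row spacings

Chains lying *within* a (110) bounding plane are separated by (a−b)/2 =
5.96 Å; within (1-10) by (a+b)/2 = 5.33 Å; within (200) sheets by b =
8.2 Å; within (010) by a = 7.78 Å. Label conventions for the {110} pair
vary in the literature with the sign choice of the monoclinic angle; this
package uses the convention in which the gg-decorated faces of the
diamond habit are (110) and show ~6 Å line spacings, which is the
assignment consistent with attributing observed 6–7 Å inter-line
distances to {110}-type faces.

### Habits

Cross-sections are explicit chain maps (config data, overridable):

- diamond 24 = (110) layers of 4, 5, 6, 5, 4 chains; diamond 18 =
  3, 4, 4, 4, 3 — bounded by {110} top/bottom and stepped {1-10} sides;
- rectangular 24 = six half-(010) layers of 4 chains (18 = six of 3) —
  bounded by {010} top/bottom and stepped {200} sides.

Row windows are re-centered by whole in-layer lattice steps so that
equal-size top and bottom rows differ by a pure stacking translation;
this keeps their face-on Cs combs in registry (merge offsets ~0.2–2.1 Å,
always inside the 2.6 Å grouping gap). Both 24-chain cross-sections have
maximum calipers of 3.0–3.6 nm, inside the 2.5–3.5 nm envelope expected
for 18–24 chain fibrils once the surface decoration is included.

## Decoration

Each sulfated site is a rigid two-atom arm at the surface O6: S at 145 pm,
then the counterion (Cs or Na; H adds no atom) at 250 pm, with a 120°
angle between the bonds. The dihedral frame of the arm is not specified by
bond lengths alone; the arm is placed in the plane spanned by the facet
normal and the chain axis, zig-zagging toward −c (the +c side above each
O6 is blocked by the screw partner's outward hydroxyls). Two consequences
are deliberate: the label adds no transverse offset in face-on projection,
so Cs line positions reflect chain/O6 geometry alone, and the axial offset
of Cs relative to O6 is identical for every decorated site, so it cancels
in all spacing statistics. The default elevation is 45° (the source
protocol varies it per model without stating values); it is exposed in
`LabelGeometry` together with an optional bridging oxygen for users who
read the sulfate chain as C6–O–S–O–Cs.

Rotamer states: gg is assigned to (110) and (010) (surface-dominant
conformer), tg to (200) (interchain hydrogen bonding) and (1-10) (steric
restriction). In this simplified two-atom geometry the rotamer is
recorded per site and selects nothing further; its geometric content is
subsumed in the idealized C6/O6 placement.

Occupancy: coverage 0.15 of surface C6 sites, counterions 86 % Cs / 6 %
Na / 8 % H — the experimentally estimated composition — sampled uniformly
without replacement with a seeded generator. Full occupancy (coverage 1,
f_cs 1) reproduces the simulation regime in which every accessible site
on the decorated face carries S+Cs.

## Substrate

The support film is carbon at 2.0 g/cm³ (the printed "2000 g cm⁻³" is
read as 2000 kg/m³), 2 nm thick, placed uniformly at random with a
minimum separation of 120 pm enforced by rejection sampling. N follows
from density times volume (20 055 atoms for 10×10×2 nm). No sp²/sp³
network topology is attempted; the slab only supplies the
thickness-dependent background and its shot noise.

## Imaging

HAADF contrast is approximated as incoherent: intensity = Σ_atoms
Z^1.7 · G(x−x_i, y−y_i), with G a unit-integral Gaussian of 100 pm FWHM
(the measured bright-spot size), sampled at 20 pm/px. The projection
discards depth entirely, consistent with a depth of focus of several
nanometers — thicker than any scene here. Shot noise draws per-pixel
Poisson counts at a budget of I·t/e ≈ 187 electrons/pixel (10 pA, 3 µs)
scaled so the image mean maps to that budget; `dose_scale` multiplies it.
Dynamical diffraction, channeling, probe tails, detector response and
scan distortions are all out of scope — geometry export (XYZ/CIF) is
provided so external multislice codes can be used for contrast-accurate
work. Collection angles, beam energy and convergence are carried as
metadata only.

## Detection

The measured path mirrors the experimental one: a 3×3 mean filter, then
per-pixel two-class labeling, 8-connected components with a 4 px minimum
area, and intensity-weighted centroids (an explicit sub-pixel choice; the
source protocol does not state its weighting). Two classifiers are
provided. The default threshold mode marks pixels above a large-window
(31 px) median background plus k robust standard deviations (MAD) of the
residual. k = 3 is the textbook default and suits sparse atoms on a bare
or noisy support; frames containing the crystal body need k ≈ 12, because
the projected light-atom lattice of the specimen itself — stacked C/O
columns several times brighter than shot noise — must stay below
threshold while Cs (~20× brighter than the body texture) stays above it.
This calibration is a property of the Z^1.7 contrast ratios, not of any
particular frame, and the pipeline default uses it. The learned mode is a
random forest on intensity, multi-scale Gaussian, gradient-magnitude and
Laplacian features, trained on synthetic frames with known masks — the
same per-pixel two-class contract as interactive classification tools,
but not a replication of any specific training set. Threshold mode
presumes shot noise; on strictly noise-free frames the MAD scale
degenerates and a fixed fraction (0.2) of the peak residual is used
instead.

Greedy nearest-pair matching within 1 Å links detections to ground truth;
recall, precision and RMS localization error are computed on the matches.

## Analysis

- **RDF**: 2D pair-distance histogram normalized by the bounding-box
  density (g → 1 for Poisson points), bin width 0.02 nm, r_max 3 nm, no
  edge correction — the uncorrected estimator is biased low at large r
  and, like any segmentation-fed RDF, depressed at short r where nearby
  atoms merge into single detections. Both biases are accepted and
  documented rather than corrected, since only peak positions are used.
- **Line profiles**: intensity averaged across the profile width, peaks
  refined by least-squares Gaussians in windows of ~0.75 of the typical
  peak period, initialized at local maxima; spacing uncertainties come
  from the fit covariances. Failed fits raise with the profile attached.
- **Row grouping**: positions projected perpendicular to the axis are
  split at gaps larger than 2.6 Å — half the smallest inter-row distance,
  so distinct crystallographic rows never merge while top/bottom-surface
  combs of the same row do. The axis direction comes from configuration
  when the scene orientation is known; the PCA fallback is reliable for
  long crystals but biased for short, wide lattice patches (aspect ratio
  below ~3), which is why the pipeline prefers the configured axis.
- **Projected model spacings**: the analytic twin of the image
  measurement — Cs coordinates rotated about [001], projected, grouped
  with the same 2.6 Å gap; adjacent line-center distances and within-line
  axial nearest-neighbor distances (projected coincidences closer than
  0.5 Å are duplicates, not repeats, and are dropped).
- **Model comparison**: each measured spacing is matched to the nearest
  distinct predicted value; the score is the mean |Δ| in Å, ranked
  ascending. A deliberately simple, monotone rule — the original
  comparison was by inspection.

## Synthetic data

Default scenes are desk-scale: 1–3 crystals of 3–6 c-repeats on a
10×10 nm field, face-on on the 2 nm carbon film at a random in-plane
rotation, decorated at the experimental occupancy (15 % coverage, 86 %
Cs), imaged at the experimental probe settings with shot noise. Beam
damage is phenomenological only: Gaussian positional jitter of the label
atoms (default σ = 30 pm) and random Cs vacancies (default 10 %); the
defaults keep detection recall ≥ 0.9 so downstream statistics are stable.
Not emulated: bundle-scale aggregation (50–200 nm), crystal overlap along
the beam, drift/scan distortion, dose-dependent damage kinetics, and the
real instrument's transfer function. Passing tests therefore demonstrate
the internal consistency of the geometry → image → measurement chain at
realistic SNR, not instrument-level realism.

## Numerical choices

- Random numbers: NumPy PCG64 generators; one scene seed fans out to
  sub-seeds (placement, rotation, vacancies, jitter, substrate, noise)
  via `SeedSequence`, and the pipeline derives per-stage seeds the same
  way, so every stage is independently reproducible and all seeds stay
  below 2³¹.
- Degenerate inputs raise: empty scenes, zero Miller triples, facets not
  belonging to a model, unreachable substrate packing, profile lines with
  fewer than two peaks.
- Atom tables are plain pandas DataFrames; structure files are extended
  XYZ (annotations in trailing columns) and CIF via gemmi (fractional
  coordinates in a P1 bounding box with custom tags); images are 16-bit
  TIFF with a JSON sidecar carrying pixel size, origin and provenance.
- Collision floor 0.8 Å for any atom pair, checked when labels are
  placed and asserted for built models in the tests.

## Known limitations

- The idealized AGU ring geometry is not a refined structure; bond
  lengths within the ring are approximate. Only C6/O6 placement is
  calibrated, which is sufficient for every spacing this package reports.
- The incoherent renderer cannot reproduce absolute or thickness-dependent
  contrast; only relative peak positions and intensity ordering are
  meaningful.
- The RDF of sparse detections on a small field carries strong edge bias
  beyond ~1/3 of the field size.
- The learned classifier is a contract-level stand-in: feature set and
  labels differ from any specific interactive-tool training session.
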
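# Methods

## The unit-cell model

A unit volume of cortical bone is modelled as one D-period of one fibril
plus its share of surrounding mineral, seen in projection through a thin
section:

- fibril width 50 nm (the average measured fibril width; the sketch-style
  renders of 45 nm fibrils are not used for quantification);
- gap zone 40 nm and overlap zone 27 nm along the axis (D = 67 nm);
- inter-fibril mineral stack width 27 nm. The measured stack width is
  28 ± 10 nm, but 27 nm is what reproduces the quoted projected areas
  A(V) = 1810 and A(H) = 5160 nm² ((50+27) × 67 = 5159), so 27 nm is the
  default and the 28 nm measurement is treated as the same quantity within
  its uncertainty;
- plates 5 × 65 × 200 nm, section thickness 100 nm.

Projected areas: A_G = 50×40 = 2000, A_O = 50×27 = 1350, A_V = 27×67 =
1809, A_H = 77×67 = 5159 nm². Areas are kept unrounded internally;
rounding to the nearest 10 nm² is a display option used when matching
figures quoted at that precision. The unit-cell axial length (67 nm) is
implied by these products rather than stated independently.

The mass-balance bound is bookkeeping: mineral occupying m of bone volume
against a gap capacity g·f (gap fraction of fibrils × fibril fraction of
bone) forces max(0, m − g·f)/m of the mineral outside the gap zones. With
m = 0.45, g = 0.12, f = 1 that is 73.3% of the mineral, or 33 vol% of
bone.

`plates_per_interfibril_span` counts plate + spacing periods across the
inter-fibril distance. The default spacing is 1.5 nm: reported plate
spacing is ≲0.1 nm for abutting plates, but ~4 plates per 27.7 nm span
implies an effective period near 6.5 nm; 1.5 nm reconciles the count and
is recorded as an assumption, not a measurement.

## The EDXS partition estimator

Assumptions, in order of importance:

1. **Thin-section proportionality.** Ca Kα X-rays escape from the full
   ~100 nm section (95% extinction depth ~1.7 µm), so a count rate over a
   region is proportional to the total mineral mass under it.
2. **The overlap zone is mineral-free.** All counts over O come from the
   over/underlying plates (H), so C(O) measures H and can be subtracted
   from C(G) and C(V). A negative corrected rate is raised as an error,
   never clamped: clamping would silently bias X_ext upward.
3. **Area weighting.** The Ca amount in a compartment is projected area ×
   count rate; compartments H and V are external, G internal.

The estimator is scale-invariant (multiplying all three rates by k > 0
cancels), strictly decreasing in C(G) and increasing in C(V).

The summary uncertainty across samples is the **population SD** (divide by
n, not n−1): for the three reference fractions 0.7595/0.8405/0.8543 the
population SD is 0.042 while the sample SD is 0.051, and the quoted
"±4%" corresponds to the former. The mean is reported to one decimal
(81.8%).

Ca:P stoichiometry is checked as (Ca/P counts)/sensitivity against the
bone-apatite window 1.46–1.75 around ideal hydroxyapatite (1.67); no ZAF
or absorption modelling is performed — inputs are assumed
matrix-corrected upstream.

## The synthetic scene

`SceneConfig` defaults define the simulated study conditions:

| parameter | default | meaning |
|---|---|---|
| lattice pitch | 77 nm | fibril width + stack width, square packing |
| n_fibrils × n_periods | 4 × 3 | 308 × 100 × 201 nm scene |
| plate_stack_depth | 4 | plates per inter-fibril stack |
| h_levels | auto (4/side) | plate layers over/under the fibril layer |
| plate_axis_dispersion | ±18° | long-axis scatter about the fibril axis (half the 36° arc) |
| plate_spacing / edge gap | 1.5 / 2 nm | stacking and in-plane tiling gaps |
| gap_mineral_density | 0.6 | gap-zone Ca density relative to plate mineral |
| overlap_mineral_density | 0 | mineral-free overlap zones |
| voxel_size | 1 nm | resolves 5 nm plates with ≥5 voxels |

Construction notes:

- Fibrils are circular cylinders; elliptical hole sections arise only from
  oblique cutting. Banding is in registry across fibrils.
- Plates are rasterized as rotated cuboids; a plate intersecting a fibril
  interior is a construction error (e.g. an overfull stack). Overlapping
  plate voxels merge (density saturates at the plate density): with 65 nm
  plate widths the vertical stacks necessarily interpenetrate the H bands
  in depth, and merged voxels are counted once in the ground truth.
- The two-orientation plate arrangement leaves the "corners" of each
  fibril column uncovered; since the real carapace wraps the fibril
  completely, these corners are filled with plate-label mineral at the
  stack packing fraction (5/6.5 ≈ 0.77). `fill_corners=False` disables
  this for didactic renders and for the plate-volume oracle test.
- `gap_mineral_density = 0.6` was chosen once so that noise-free region
  rates reproduce the observed ordering C(V) > C(G) > C(O) (at density
  1.0 the mean gap chord, π/4 × 50 ≈ 39 nm, would slightly exceed the
  ~38 nm plate path and invert it) and an external fraction near 0.8.
  Gap mineral is uniform; no discrete gap-zone crystals are modelled.
- Only square packing is implemented: a hexagonal arrangement needs a
  second fibril layer, which does not fit the single-layer 100 nm section
  with its over/underlying plate bands.
- Vacancy (eroded fibril interiors in cross-section views) is a post-hoc
  render mask; ground truth is untouched.
- Scenes are bit-reproducible from (config, seed); all randomness flows
  from one `numpy` generator.

Ground truth is exact voxel summation: external = plate-label density,
internal = fibril-interior density, X_ext_true = ext/(ext+int).

EDXS simulation draws Poisson counts per probe position with mean
dose_scale × integrated projected density over the probe footprint
(default 100 nm² probes, dose 0.1 count per density-nm³, giving
Table-like count levels of a few hundred per probe). Region sampling
averages either all fully-interior probes (the default, used for
deterministic validation) or a few randomly chosen ones
(`n_probes`, emulating a microscopist's selected areas).

### What the benchmark shows — and what it does not

Applying the estimator to noise-free synthetic counts recovers the true
partition within ~0.01–0.05 absolute (model-mismatch bias: the unit cell
assumes box-shaped compartments and one stack per fibril while the scene
has cylindrical fibrils, corner mineral and edge lanes). With Poisson
noise at realistic doses the estimate distribution brackets the truth.
This validates the *estimator logic*, not real-micrograph performance:
the generator does not emulate diffraction contrast, detector background,
specimen damage, fibril disorder or misorientation, so measured spreads
on real sections (e.g. a D-period of 68.0 ± 4.3 nm across images) are
plausibility references only — the synthetic tests instead check
parameter recovery (67 nm D-period within 1 nm, lane pitch within 2 nm,
plate FWHM within 1 nm, period sweep 40–100 nm within 2%).

## Measurement operators

- **Periods** (D-period, lane spacing): directional mean profile →
  biased autocorrelation → strongest peak at lag ≥ 10 nm → parabolic
  sub-pixel refinement. Autocorrelation rather than a raw FFT peak
  because band profiles are non-sinusoidal with variable edge sharpness;
  the biased (tapered) ACF makes the fundamental beat its multiples. A
  normalized peak below 0.2 is "no period".
- **Plate thickness**: transect profile at quarter-pixel steps, peaks
  above 35% of the range over a 10th-percentile background, FWHM by
  linear interpolation; peaks sharing a half-max interval (plateaus split
  by shallow dips) are merged.
- **Hole ellipses**: dark pixels (Otsu threshold by default), binary
  opening (radius 2 px) to sever thin inter-plate seams, connected
  components, second-moment equivalent ellipses. Border-touching
  components are discarded (standard stereological edge correction), and
  components under 15 nm equivalent diameter are treated as inter-plate
  interstices, not fibril holes. Eccentricity is the major/minor aspect
  ratio (≥1).
- All operators work in nm from pixel-size metadata and are invariant to
  global intensity scaling.

## Diffraction texture

Plate long axes stand in for apatite c-axes. The arc extent is purely
geometric: twice the coverage-quantile of |tilt|, so a uniform ±18°
dispersion subtends exactly 36°. 00l visibility is the Monte-Carlo
fraction of c-axes within ±5° of the plane normal to the view (uniform
azimuths, textured polar tilt): ~1 perpendicular to the fibrils, ~0 down
the fibril axis — reproducing the near-absence of 00l reflections in
cross-section patterns. Whether the arcs originate in the plates or in
gap-zone crystals is left open; the model only requires the angular
statistics.

## Numerical choices and limitations

- Voxel membership is by voxel-center inclusion; quantization errors are
  ≤1 voxel per dimension (the plate-volume oracle tolerance of 2%
  reflects this).
- Projections along principal axes conserve mass exactly; oblique
  projections use trilinear resampling and conserve mass only
  approximately (≈2%). Oblique *sectioning* (cut_section) is exact.
- Probe footprints snap to whole pixels; probes must lie ≥99% inside a
  region mask to qualify.
- The default scene is desk-scale (≈6·10⁶ voxels, ~0.2 s to build);
  problem sizes in the tests (2–4 fibrils, 2–5 D-periods, ≤1000 noise
  replicates) were chosen as the smallest that leave the measured
  quantities well inside their tolerances.
- The estimator's residual bias depends on lattice edge effects
  (edge fibrils lack one stack); it shrinks with n_fibrils and is
  bounded, not corrected.
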
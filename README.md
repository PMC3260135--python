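# extrafib

Where does the mineral in bone sit relative to the collagen fibrils?
`extrafib` is a Python package for microscopists and bone-ultrastructure
modellers that answers this quantitatively three ways:

1. **A unit-cell geometric model** of mineralized collagen: cylindrical
   fibrils (~50 nm wide) with 40 nm gap / 27 nm overlap D-periodic banding
   (D = 67 nm), wrapped by plate-like hydroxyapatite "mineral structures"
   (~5 × 65 × 200 nm) stacked ~4-deep between fibrils in a ~100 nm-thick
   section.
2. **An EDXS count-partition estimator.** Ca count rates C(i)
   (counts/nm²) measured over the overlap zone (O), gap zone (G) and
   inter-fibril mineral stacks (V) of a longitudinal thin section are
   corrected for the mineral lying over and under the fibril (H), which is
   the only source of signal over the mineral-free overlap zone:

       C′(G) = C(G) − C(O),   C′(V) = C(V) − C(O)

   Weighting by the projected compartment areas A(H), A(V), A(G) gives
   the fraction of mineral *external* to the fibrils:

       X_ext = [A_H·C(O) + A_V·C′(V)] / [A_H·C(O) + A_V·C′(V) + A_G·C′(G)]

3. **A synthetic 3D ultrastructure simulator** that voxelizes the model
   with exact ground truth, renders mass-thickness projections, simulates
   Poisson EDXS count maps, and provides measurement operators (D-period,
   lane spacing, plate thickness, fibril-hole ellipses) plus c-axis
   texture statistics for the 00l diffraction arcs — so the estimator and
   every measurement can be validated end-to-end without a real
   micrograph.

## Worked example

Recompute the reference count-rate table through the estimator:

```bash
$ extrafib reproduce-table3
sample  C_O  C_G  C_V  Cp_G  Cp_V  external_signal  internal_signal    X_ext  X_ext_spread
     1 1.66 4.55 7.02  2.89  5.36          18267.2           5780.0 0.759639           NaN
     2 3.16 5.20 6.03  2.04  2.87          21500.3           4080.0 0.840502           NaN
     3 3.16 5.20 7.37  2.04  4.21          23925.7           4080.0 0.854315           NaN
  mean  NaN  NaN  NaN   NaN   NaN              NaN              NaN 0.818152      0.041757
external mineral: 81.8% (pop. SD 4.2%)
```

Reading: for each sample the overlap-zone rate is subtracted from the gap
and stack rates, the signals are weighted by the projected areas
(A_G = 2000, A_V = 1810, A_H = 5160 nm², rounded to the nearest 10), and
roughly 76–85% of the Ca signal — on average 81.8% ± 4.2% — is attributed
to mineral outside the collagen fibrils.

The same estimator can be validated against a synthetic scene whose true
partition is known exactly:

```python
from extrafib.synthetic import SceneConfig, build_scene
from extrafib.pipeline import estimate_scene_partition

scene = build_scene(SceneConfig())
print(estimate_scene_partition(scene, noise=False))
# {'C_O': 4.17, 'C_G': 6.60, 'C_V': 7.57,
#  'X_ext_estimate': 0.851, 'X_ext_true': 0.849, 'bias': 0.002}
```

And the texture of the plate long axes predicts the diffraction geometry:

```bash
$ extrafib diffraction --half-angle 18 --view parallel
{"arc_deg": 36.0, "visibility": 0.0, "view": "parallel"}
```

A ±18° c-axis dispersion subtends a 36° 00l arc in the longitudinal view
and extinguishes the 00l reflections when viewed down the fibril axis.

Other CLI stages: `extrafib simulate` (scene → TIFFs + ground truth +
manifest), `extrafib edxs` (projection → Poisson count map),
`extrafib partition`, `extrafib measure`, `extrafib recover`
(truth-vs-estimate experiments). Every run writes a manifest; identical
manifests reproduce bit-identical outputs.

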
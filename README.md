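# phalanxmap

Cortical bone cartography of phalangeal diaphyses.

Hand use leaves a signature in the shaft of a finger bone: where the cortex is
thick, how thickness changes from base to trochlea, how rigid the shaft is in
bending and torsion, and how strongly it bows. `phalanxmap` turns paired
periosteal (outer) and endosteal (inner) surface meshes of a phalangeal shaft —
the kind produced by micro-CT segmentation — into quantitative, comparable
descriptors, and places individuals into a reference morphospace of groups
(e.g. humans versus great apes):

- **Unrolled thickness maps.** The shaft (by default 20–80% of maximum bone
  length) is sliced into 97 cross-sections at 1% intervals from 2% to 98% of
  shaft length. On each section, 50 equiangular rays cast from the section
  centroid place semi-landmark pairs on the outer and inner contours; cortical
  thickness is the distance between a pair. The 97 × 50 matrix is the
  morphometric map of cortical bone distribution, standardized by maximum bone
  length *L* for size-free comparison.
- **Cross-sectional mechanics.** Cortical area, centroid, second moments of
  area and the polar second moment *J = I\_xx + I\_yy* (a proxy for bending and
  torsional rigidity) from exact Green's-theorem polygon formulas, evaluated at
  35, 50 and 65% of bone length and standardized as *J/L⁴*.
- **Curvature.** Longitudinal shaft curvature as the included angle
  2·arcsin(*L*/2*R*), with *R* the radius of a least-squares circle through the
  section centroids in the sagittal plane.
- **Group statistics.** PCA of flattened standardized maps; canonical variates
  analysis (CVA) on the first three PC scores; one-sample Hotelling T² tests of
  a specimen against a reference sample; typicality probabilities
  (upper-tail probability of the squared Mahalanobis distance D² to a group
  centroid) for group affiliation; leave-one-out classification.
- **A synthetic phalanx generator** with exact closed-form ground truth:
  elliptical sections swept along a circular arc, with a prescribed thickness
  field combining palmar flexor-sheath ridges, dorsal-shaft thickening and
  proximodistal gradients ("ape-like" monotone increase versus "human-like"
  mid-distal peak). Every downstream quantity can be checked against the
  generator's parameters.

## Worked example

```python
import phalanxmap as pm

spec = pm.SyntheticPhalanxSpec()          # 40 mm bone, 30° palmar bow
pair, truth = pm.generate_phalanx(spec)
L = pm.max_length(pair)
tmap = pm.compute_thickness_map(pair)     # 97 x 50 unrolled map
smap = pm.standardize_map(tmap)
print(pm.mean_cortical_thickness(tmap))
for g in pm.J_at_levels(pair):
    print(g.level_frac, g.J, pm.standardize_J(g, L))
print(pm.included_angle(pair).included_angle)
```

prints

```
max length            : 40.00 mm
map shape             : (97, 50)
mean cortical thickness: 1.600 mm (0.04000 standardized)
J at 35% of bone length:    762.7 mm^4 (J/L^4 = 2.979e-04)
J at 50% of bone length:    684.9 mm^4 (J/L^4 = 2.675e-04)
J at 65% of bone length:    689.8 mm^4 (J/L^4 = 2.695e-04)
included angle        : 30.0 deg (fit radius 77.3 mm)
```

The default spec's cortex baseline is 1.2 mm with a monotone axial gradient,
giving a whole-shaft mean of 1.60 mm; *J* is largest proximally (35%), where
the interpolated section radii are largest; and the recovered included angle
matches the generator's 30° arc to well under a degree.

A cohort-level run (two groups → maps, mechanics table, PCA/CVA/typicality,
confusion matrix) is one call:

```python
from phalanxmap import RunConfig, run_pipeline
report = run_pipeline(RunConfig.from_json("config.json"))
```

or from the shell via the `phalanxmap` CLI (`generate`, `map`, `mechanics`,
`stats`, `all` subcommands). Real specimens enter through a manifest CSV
(`id,group,element,digit,side,outer,inner`) pointing at PLY/OBJ/STL files;
left-side bones are mirrored to the right-side map convention automatically.

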
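# synapsekin

Quantification of B-lymphocyte immune-synapse formation on antigen-coated
oil droplets, from 3D fluorescence time-lapse movies.

When a B cell engages an antigen-presenting surface it builds an immune
synapse: antigen clusters at the contact, actin and the DAG second
messenger enrich at the synaptic cortex, and the centrosome, Golgi,
lysosomes and finally the nucleus reorganize along the synapse axis.
Functionalized oil droplets (median diameter ~9.4 um, surface tension
gamma = 12 mN/m, i.e. a Laplace pressure `2*gamma/R` = 4.8 kPa at
R = 5 um) serve as deformable antigen-presenting surfaces; each
cell-droplet doublet is imaged as 21-plane z-stacks (dz = 0.7 um) every
30 s. This package turns those movies into the quantitative readouts of
polarization, for imaging scientists and quantitative immunologists.

## What it computes

- **Segmentation** (`synapsekin.volume`): bleach correction (simple-ratio
  and histogram-matching), isotropic resampling, droplet/cell/nucleus
  masks (Huang fuzzy-entropy threshold recipe), centrosome punctum
  detection, Euclidean distance maps from the droplet surface.
- **Synapse metrics** (`synapsekin.metrics`): antigen recruitment
  (synapse-pole / opposite-pole intensity ratio, normalized at cell
  arrival), shell enrichment of F-actin (2 um layer) and DAG reporter
  (1 um layer), GEF-H1/EXOC7 presets, front/back polarity ratios, actin
  maxima on z-projections, acetylated/total tubulin ratios, two-droplet
  synapse counting and per-synapse actin asymmetry.
- **Kinetics** (`synapsekin.kinetics`): Tukey 3R running-median smoothing,
  windowed peaks and minima, 25-30 min plateau means, gated
  threshold-crossing (polarization) times — centrosome below 2 um
  (start > 3 um), Golgi 4/5 um, lysosomes 3/4 um — the time of the last
  local minimum of the nucleus-droplet distance, and the first time the
  nucleus-orientation angle theta_N drops below 45 degrees.
- **Nucleus geometry** (`synapsekin.nucleus`): marching-cubes surface
  extraction, cotangent-Laplacian mean curvature, invagination detection
  as the minimal-curvature landmark with nearest-neighbor tracking, and
  Spearman correlation of nucleus vs centrosome orientation.
- **Profiles** (`synapsekin.profiles`): moment-based ellipsoid fit of the
  droplet, rigid re-orientation, symmetric radial synapse scans and
  axial front-to-rear linescans.
- **Shape & migration** (`synapsekin.shape`, `synapsekin.migration`):
  2D aspect ratio / solidity with temporal summaries; the migrating-cell
  filter (net displacement > 20 um, onset step > 6 um, 30 frames) with
  confinement ratio and directional change rate.
- **Phantoms** (`synapsekin.phantom`): synthetic doublet movies, dented
  nuclei, kinetic traces and correlated random walks with recorded ground
  truth, so every stage is testable without raw microscopy data.

## Worked example

A synthetic doublet whose centrosome is programmed to cross the 2 um
polarization threshold at the 10th frame (300 s):

```python
import numpy as np
from synapsekin.core import KineticTrace
from synapsekin.kinetics import CENTROSOME_SPEC, polarization_time
from synapsekin.metrics import antigen_recruitment
from synapsekin.phantom import DropletPhysics, PhantomParams, generate_doublet, laplace_pressure
from synapsekin.volume import detect_punctum, distance_map, organelle_distance, segment_cell, segment_droplet

print(f"Laplace pressure: {laplace_pressure(DropletPhysics(12.0, 5.0)):.1f} kPa")

droplet_center = np.array([7.35, 11.7, 7.5]); cell_center = np.array([7.35, 11.7, 17.5])
axis = (cell_center - droplet_center) / np.linalg.norm(cell_center - droplet_center)
dist = np.array([5.5, 5.2, 4.9, 4.6, 4.3, 4.0, 3.7, 3.4, 3.1, 2.8, 1.5, 1.2])
params = PhantomParams(n_frames=12, centrosome_path=droplet_center + (4.7 + dist)[:, None] * axis, seed=1)
series, truth = generate_doublet(params)

droplet = segment_droplet(series)
cells = segment_cell(series)
field = distance_map(droplet)
d = [organelle_distance(detect_punctum(series, "centrosome", t, within=cells[t]), field, "point")
     for t in range(series.n_frames)]
trace = KineticTrace(series.times, np.array(d), "centrosome_distance", "cell_000")
print("centrosome-droplet distance (um):", np.round(trace.values, 2))
print(f"polarization time: {polarization_time(trace, CENTROSOME_SPEC):.0f} s")

ar = antigen_recruitment(series, droplet, cells[0].centroid_um())
print("antigen recruitment:", np.round(ar.values, 2))
```

prints

```
Laplace pressure: 4.8 kPa
centrosome-droplet distance (um): [5.52 5.52 5.2  4.88 4.55 4.23 3.9  3.58 3.25 2.92 1.62 1.3 ]
polarization time: 300 s
antigen recruitment: [1.   1.05 1.15 1.32 1.58 1.92 2.24 2.5  2.66 2.75 2.8  2.83]
```

The measured centrosome distances track the programmed approach within
the voxel size, the gated crossing time lands exactly on the programmed
300 s, and antigen recruitment follows the phantom's programmed
accumulation (1 means uniform droplet fluorescence; values above 1 mean
antigen has concentrated at the synapse).

A batch run over a configuration file, and the other entry points:

```sh
synapsekin phantom-doublet --seed 1 --out phantom_out/
synapsekin run config.yaml
synapsekin migrate tracks.csv --out migration_metrics.csv
synapsekin report out/summary.csv --group-column condition
```

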
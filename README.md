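# morphatlas

Landmark-free group-wise elastic registration of segmented 3D morphological
objects, with a downstream pipeline that maps nuclear signal levels onto the
emerging consensus shape and clusters morphology-space into combinatorial
signalling zones.

The core idea: instead of solving one hard 3D elastic alignment, each
iteration sweeps the three orthogonal planes (YZ → ZX → XY). Per plane, every
object is reduced to a 2D average-intensity projection, all object pairs are
registered with a consistent elastic 2D B-spline method, and each object
receives the *mean* of its per-peer transform coefficient lattices (plus its
own identity lattice), which is then applied to every slice of its stack.
The per-object history of these 2D transforms is saved as an **orthogonal
transform sequence** (`.ots`, a versioned JSON container) that can be
replayed onto any co-registered volume (other channels, signal maps) or onto
landmark coordinate tables.

## Modules

| module | contents |
|---|---|
| `morphatlas.core_io` | domain types (volumes, labels, landmark sets, OTS) and TIFF/CSV/OTS readers & writers |
| `morphatlas.elastic2d` | 2D B-spline free-form registration engine, transform algebra (evaluation, averaging, warping, numerical inversion) |
| `morphatlas.groupwise3d` | the group-wise 3D driver, OTS replay onto volumes and landmarks, per-iteration reporting |
| `morphatlas.evaluation` | majority-consensus mask, volumetric overlap (Jaccard, Dice optional), landmark pair distances |
| `morphatlas.signal_mapping` | nucleus segmentation, protein/counterstain ratio extraction, local-averaging projection (12 µm target / 36 µm sample voxels), replicate merging |
| `morphatlas.clustering` | 18 µm supervoxel sampling, complete-linkage Euclidean clustering, zone cutting, profiles, zone-map reconstruction |
| `morphatlas.synthetic` | seeded generators for every fixture: deformed blob triplets with material landmarks, two-channel nuclei scenes, zoned signal volumes |
| `morphatlas.cli` | `morphatlas` command-line workflow |

## CLI

Every subcommand writes a `manifest.json` (inputs, parameters, version, seed)
beside its outputs. End-to-end on generated data:

```bash
# three deformed copies of one blob, with landmark tables
morphatlas simulate triplet --seed 1 --out-dir sim/

# 6-iteration group-wise registration: OTS files, registered labels, report CSV
morphatlas register sim/object_*.tif --out-dir reg/ --iterations 6 \
    --landmarks sim/object_0_landmarks.csv \
    --landmarks sim/object_1_landmarks.csv \
    --landmarks sim/object_2_landmarks.csv

# replay an OTS onto the original (or any derivative) volume
morphatlas apply sim/object_0.tif reg/object_0.ots --out replayed.tif --label

# overlap / landmark-distance reports
morphatlas evaluate reg/object_*_registered.tif --out-dir eval/
```

Signal pipeline: `extract-signal` (nucleus segmentation + ratio volumes),
`project` (local-averaging projection onto a segmentation label), `merge`
(background-normalised replicate averaging), `sample` (supervoxel table, also
exported as Cluster 3.0-compatible tab-delimited text), `cluster` (zones,
profiles, dendrogram, zone map) and `reconstruct`.

## Conventions

- Volumes are indexed `(x, y, z)`, 0-based; voxel `(i, j, k)` sits at world
  coordinate `(i·sx, j·sy, k·sz)` µm. TIFF pages are z-planes with page rows
  mapping to x.
- Labels are binary TIFF masks (convert proprietary segmentation formats to
  0/255 or 0/1 masks first).
- 2D transforms use the backward/resampling convention: `T(p) = p + d(p)`
  maps target pixel coordinates to source coordinates. Moving landmarks with
  content therefore uses numerical inversion of `T`.
- Missing TIFF spacing metadata falls back to 1 µm isotropic with a warning;
  spacing can always be overridden explicitly.
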
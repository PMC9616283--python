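# pvsquant

Automatic detection, 3D tracking and quantification of **perivascular spaces
(PVS)** in the centrum semiovale (CSO) from co-registered T2-weighted and
T1-weighted MR volumes.

Perivascular spaces are thin, fluid-filled sheaths around brain-perforating
vessels. On high-resolution T2-weighted images they appear as bright,
CSF-like tubular structures of sub-millimetre calibre; their number, length
and tortuosity are of interest in aging and cerebral small-vessel disease,
but manual counting is labor-intensive and rater-dependent. `pvsquant`
implements a fully automatic, deterministic pipeline for users working with
high-field (e.g. 7 T) T2-weighted TSE data and a white-matter segmentation:

1. **Vesselness filtering** — multi-scale Hessian bright-line filter
   (Sato-type response) over 10 scales, σ = 0.30…1.00 mm, enhancing tubular
   structures in the T2 volume.
2. **CSO ROI** — a plane is placed from anatomical landmarks (parallel to
   the genu–splenium line, perpendicular to the midsagittal plane, 10 mm
   above the lateral ventricles), extended to a 7-slice slab; the ROI is the
   white matter inside the slab.
3. **Voxel classification** — a binary kNN classifier (k = 51,
   inverse-distance weighting) on z-scored (T1, T2, vesselness) features.
   Training pools annotated PVS markers dilated to 3×3×3 windows
   (foreground) against a 10 % random sample of white-matter slab voxels
   (background); evaluation is leave-one-subject-out.
4. **Seeding** — voxels with PVS probability > 0.50 are reduced to single
   seedpoints by 26-neighborhood non-maximum suppression.
5. **Tracking** — bidirectional multi-hypothesis tubular tracking from each
   seed (radius range 0.15–0.70 mm, search depth 3, 2 polar angle rings,
   beam width 5, termination threshold 10 in contrast-to-noise units).
   Tracks shorter than 2 mm (false positives) or longer than 50 mm
   (physiologically unfeasible) are removed.
6. **Quantification** — per track the arc length *L*, the endpoint chord
   *C*, and the tortuosity **τ = L / C ≥ 1**; per subject the PVS count.
   Validation metrics: two-way single-measure intraclass correlation
   (absolute agreement and consistency), a location-aware Dice coefficient
   over tolerance-matched point sets, and Bland–Altman summaries.
7. **Atlas maps** — with supplied subject→template transforms, group maps of
   PVS density (points within a 2 mm radius per voxel, averaged over
   subjects) and of mean length/tortuosity over 2 mm-dilated skeletons.

Because suitable 7 T data cannot be bundled, the package ships a first-class
synthetic **phantom generator** (`pvsquant.phantom`): co-registered T1/T2
volumes with bright tubes of radius 0.15–0.70 mm and length 3–30 mm
(straight, arc or helical), partial-volume rasterization, a reconstruction
point-spread blur and Rician noise, plus simulated observers (miss rate,
marker jitter) and exact analytic ground truth. All tests and the
reproduction script run against these phantoms.

## Worked example

```python
import numpy as np
from pvsquant import PhantomConfig, PipelineConfig, generate_cohort, run_pipeline
from pvsquant.quantify import count_in_slice, icc

cfg = PhantomConfig(shape=(96, 96, 96), n_tubes=20, seed=3)
subjects = generate_cohort(cfg, 3, master_seed=3)
result = run_pipeline(subjects, PipelineConfig())

for sid, res in result.subjects.items():
    slab = res.slab
    truth = count_in_slice(subjects[sid].truth_tracks,
                           slab.plane_point, slab.plane_normal, slab.thickness)
    print(sid, "seeds", res.n_seeds, "tracks", res.summary.n_tracks,
          "truth-in-slab", truth)
print("DSC vs observer:", round(result.agreement.dsc, 3))
```

prints (machine-exact values are deterministic for the given seeds):

```
sub-01 seeds 44 tracks 14 truth-in-slab 14
sub-02 seeds 51 tracks 18 truth-in-slab 17
sub-03 seeds 49 tracks 15 truth-in-slab 15
DSC vs observer: 0.854
```

i.e. on three small phantoms the pipeline recovers essentially one retained
track per true tube crossing the CSO slab, and the tolerance-matched Dice
overlap with the simulated observer's markers is 0.85.

A command-line interface mirrors the stages (`pvsquant phantom`, `pvsquant
vesselness`, `pvsquant roi`, `pvsquant track`, `pvsquant metrics`,
`pvsquant run`); see `pvsquant --help`.

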
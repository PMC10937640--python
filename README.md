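# pericfat

Automated **epicardial adipose tissue (EAT) quantification** for
non-ECG-gated, low-dose chest CT, with the prognostic statistics that
relate EAT to mortality — exercisable entirely on synthetic data.

EAT, the fat inside the pericardial sac, is a metabolically active depot
in direct contact with the coronary arteries, and low-dose chest CT from
lung-cancer screening images it for free. This package implements the
full measurement chain a screening study needs:

1. **Heart localization** — a 3D U-Net on coarse isotropic volumes
   predicts a rough heart mask; the center of its bounding box (expanded
   by a safety margin) defines a fixed-size high-resolution crop.
2. **Pericardium segmentation** — a second 3D U-Net segments the
   pericardial sac on the crop; the mask is restored to the original
   image geometry.
3. **EAT rendering and measures** — voxels inside the sac with
   attenuation in **[−190, −30] HU** are EAT; outputs are volume (cm³),
   body-surface-area-indexed volume (cm³/m², Du Bois or Mosteller) and
   mean density (HU).
4. **Prognostic analysis** — Cox proportional-hazards models with
   per-10-unit hazard ratios (10 cm³/m² volume, 10 HU density),
   cause-specific CV-mortality fits, Kaplan–Meier/log-rank by quartile,
   Harrell's C, likelihood-ratio tests for nested models, and the
   continuous net reclassification improvement (cNRI).

Because clinical CT and outcome data cannot ship with a package, two
generators make every stage trainable and testable from scratch:

* `pericfat.phantom` — procedural chest-CT phantoms (torso, lungs,
  heart, pericardial sac, intrapericardial fat shell) with exact ground
  truth masks;
* `pericfat.simcohort` — participant-level survival cohorts with
  lognormal BSA-indexed EAT volume (mean 70.3, SD 24.6 cm³/m²), normal
  density (−77.7 ± 5.2 HU), their Spearman −0.72 correlation via a
  Gaussian copula, zero-inflated coronary-calcium scores, and
  proportional-hazards event times (true per-10 HRs: volume 1.19 /
  density 1.66 for all-cause, 1.27 / 2.14 for CV death) calibrated to
  19.5 % cumulative mortality with a 23.2 % CV share under
  Uniform(11.4, 13.2)-year administrative censoring.

The 3D U-Net, its Dice-loss/Adam training loop and backpropagation are
implemented in-package on numpy with numba kernels, sized so the whole
cascade trains on a single CPU in minutes.

## Worked example

```python
from pericfat import PhantomSpec, generate_phantom, quantify, truth_measures

p = generate_phantom(PhantomSpec(seed=42))
m = quantify(p.image, p.pericardium_truth, p.body)
print(m.volume_cm3, m.volume_indexed_cm3_per_m2, m.density_hu)
```

Running `python examples/01_phantom_and_quantify.py` prints:

```
phantom grid: (64, 64, 64) at (2.0, 2.0, 2.0) mm
pericardium voxels: 14976
EAT voxels (truth): 6517
EAT volume:         52.136 cm^3 (truth 52.136)
BSA:                2.129 m^2 (dubois)
BSA-indexed volume: 24.487 cm^3/m^2
EAT density:        -100.44 HU (truth -100.44)
pipeline measures match the ground-truth oracle exactly
```

The 52.136 cm³ is the count of ground-truth fat voxels times the voxel
volume; the quantification stage applied to the true pericardial mask
reproduces it exactly because rendering is a pure HU-window filter
inside the mask.

The other examples build on this: `02_train_cascade_small.py` trains a
miniature localization+segmentation cascade and prints held-out Dice
overlap, `03_simulate_cohort.py` shows the cohort generator hitting its
calibration targets, and `04_survival_analysis.py` runs the full Cox /
KM / discrimination / reclassification battery — e.g. on a simulated
cohort of 60 000 it prints a univariable volume HR of 1.108 that the
generator never sets anywhere: it emerges from the mutually adjusted
1.192 and the −0.72 volume–density correlation.

A thin CLI mirrors the library for shell use:

```bash
pericfat phantom --out ph/ --seed 7
pericfat simulate --out cohort.csv --mode composite --n 100000 --seed 7
pericfat analyze --cohort cohort.csv --model model1 --out results.json
```

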
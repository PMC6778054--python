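# fibgold

Quantitative 3D analysis of immunogold labels in FIB-SEM volumes.

Focused ion beam scanning electron microscopy (FIB-SEM) images a resin-embedded
cell as a stack of serial cross sections — here ~10 nm pixels in plane and
~90 nm between sections.  When an antigen (e.g. the heterochromatin mark
H3K9me3, or nuclear pore complexes) is tagged with antibody-coupled gold
nanoparticles enhanced to 20–30 nm, each label appears as a bright punctum in
exactly one section, and the stack becomes a 3D map of where the antigen sits
relative to the reconstructed ultrastructure.  `fibgold` turns such a stack
into the numbers this kind of study reports:

* per-slice translational **registration** of the serial sections;
* **detection** of the gold labels as sub-voxel 3D points;
* **segmentation** of the nucleus from its envelope, with volume *V*,
  surface area *A* and Wadell sphericity
  *S* = π^⅓ (6V)^⅔ / A  (1 for a sphere, smaller for elongated nuclei);
* decomposition into a **peripheral shell** of fixed physical thickness
  (150 nm by default, the depth of lamina-anchored heterochromatin) and the
  central remainder, with label counts and densities per µm³ in each;
* detection of inward envelope **invaginations** (type II nucleoplasmic
  reticulum), counted per section, and the percentage of labels within a
  configurable distance (default 100 nm) of one;
* **minimum separation distances** (per-label nearest-neighbour distances in
  physical nm), overall and per region;
* two-group **nonparametric comparisons** (two-tailed Mann–Whitney, paired
  Wilcoxon) of any of these per-nucleus metrics.

No public dataset accompanies this kind of experiment, so the package ships a
first-class synthetic phantom generator (`fibgold.synthetic`) that renders
FIB-SEM-like stacks with exhaustive ground truth — nucleus geometry, planted
label table, invagination map, per-slice drift — against which every stage of
the pipeline is validated.

## Worked example

The `analysis/` scripts reproduce the full workflow on the standard phantom:

```bash
python analysis/01_simulate_phantom.py    # render the stack + ground truth
python analysis/02_run_pipeline.py        # align → detect → segment → measure
python analysis/03_recovery_vs_truth.py   # score the report against the truth
python analysis/04_cohort_comparison.py   # 9-vs-9 grooved/flat group study
```

`01` builds a 48-section stack (3.2 × 3.2 µm field) of one nucleus with five
envelope invaginations and 300 planted labels (spot SNR ≈ 5.7), then `02`
prints the recovered panel metrics:

```
nuclear_volume_um3: 11.401
sphericity: 0.863
n_labels_nuclear: 254
pct_cytosolic: 10.563
min_separation_nm: 196.844
peripheral_density_per_um3: 41.363
central_density_per_um3: 12.936
peripheral_central_ratio: 1.566
invaginations_per_section: 0.417
pct_particles_at_invaginations: 36.220
```

`03` compares these against the planted truth (volume within ~2%, central
density within ~1%, peripheral density within ~11%, invaginations per section
exact, association percentage within ~4 points), and `04` runs eighteen small
phantoms through the complete pipeline and recovers every planted group
difference — lower sphericity, more labels, shorter separations, higher
peripheral density in the "grooved" group — each at p < 0.05 by two-tailed
Mann–Whitney.

The same pipeline is scriptable from the shell:

```bash
fibgold simulate --out phantom/ --seed 0
fibgold run --config config.yaml --input phantom/stack.tif --out analysis/
fibgold demo --out demo/            # phantom + analysis in one command
```

## Layout

```
src/fibgold/      library: synthetic, io, registration, detection,
                  morphometry, spatial, pipeline, cli
analysis/         numbered drivers reproducing the study workflow
tests/            pytest suite (unit, property and workflow-level tests)
docs/methods.md   models, parameter choices, limitations
```
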
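# srsphasor

Spectral phasor analysis of hyperspectral stimulated Raman scattering (SRS)
microscopy stacks, for label-free detection and classification of
drug-induced liver injury (DILI) phenotypes in cell culture:
**drug-induced steatosis (DIS)** — neutral-lipid accumulation in droplets —
versus **drug-induced phospholipidosis (DIPL)** — phospholipid accumulation
in lamellar lysosomal inclusions.  It is written for microscopists and
image analysts working with hyperspectral SRS (or similar coherent Raman)
data, and ships a synthetic cell-phantom generator with voxel-level ground
truth so the entire pipeline is testable without microscope data.

## The method

A hyperspectral SRS stack carries one image per Raman shift ν (cm⁻¹); each
pixel is a spectrum *I<sub>k</sub>*, *k = 0..N−1*, over the acquired window
(here the CH-stretch region, 2800–3050 cm⁻¹, acquired by retuning the pump
laser in 0.4 nm steps against a 1031.4 nm Stokes beam — 40 frames).  The
**spectral phasor** of a pixel at harmonic *n* is the intensity-normalized
Fourier coefficient

&nbsp;&nbsp;&nbsp;&nbsp;G = Σₖ Iₖ cos(2πnk/N) / Σₖ Iₖ,&nbsp;&nbsp;
S = Σₖ Iₖ sin(2πnk/N) / Σₖ Iₖ.

Phasors of nonnegative spectra live in the unit disc; narrow bands map near
the unit circle, broad/flat spectra near the origin, and mixtures lie on the
chord between their endmembers.  Spectrally similar pixels therefore
cluster in the (G, S) plane, where polygonal regions of interest — nucleus,
cytoplasm, total lipid, steatosis, phospholipidosis — are defined and
back-projected onto the image.  Downstream quantification mirrors the
standard assay readouts:

* **CH₂/CH₃ ratio maps** R = I(2851)/I(2930) (lipid vs protein contrast:
  droplets > 0.8, nuclei < 0.2);
* **3D lipid-droplet volumetry** from single-frequency z-stacks
  (threshold → 26-connected components → voxel count × voxel volume);
* **percent area** of each phasor class per cell;
* **Pearson colocalization** of an alkyne-tagged drug (2233 cm⁻¹) with the
  lipid signal;
* **group statistics** (one-way ANOVA + Tukey, Student's *t*) with
  N.S./\*/\*\*/\*\*\* tiers;
* **DIPL risk scoring** of compounds from pKa² + cLogP² with the
  inconclusive band (75, 85).

## Worked example

Compare a vehicle-control phantom against a DIPL-inducing treatment
(three replicate fields each, three cells per field):

```yaml
# run.yaml
seed: 11
output_dir: dili-run
n_replicates: 3
conditions:
  - {name: control, preset: control}
  - {name: propranolol-like, preset: phospholipidosis}
```

```sh
srsphasor analyze --config run.yaml
srsphasor report  --config run.yaml
```

prints

```
run seed 11, harmonic 1
  control: n=9 cells, mean CH2/CH3 0.401, steatosis 1.49%, phospholipidosis 0.00%
  propranolol-like: n=9 cells, mean CH2/CH3 0.528, steatosis 1.55%, phospholipidosis 10.59%
...
Group comparison of 'pct_area_phospholipidosis'
  control: n=9, mean=0, sd=0
  propranolol-like: n=9, mean=10.59, sd=1.951
  one-way ANOVA: F=265.2, p=2.22e-11 [***]
  Tukey control vs propranolol-like: diff=10.59, p_adj=2.22e-11 [***]
  Student t control vs propranolol-like: t=-16.28, p=2.22e-11 [***]
```

Reading: the treated cells carry ~10.6% of their area as
phospholipidosis-class pixels versus none in the control (highly
significant), their mean CH₂/CH₃ ratio rises from 0.40 to 0.53, while the
steatosis-class area does not change — the phasor segmentation separates
the two DILI phenotypes rather than reporting generic lipid increase.
`dili-run/` then contains `summary.json` (every threshold, seed and ROI
used), `cell_stats.csv`, `droplets.csv`, `segment_spectra.csv`, the ROI
polygons and per-replicate label images.

The same operations are available as a library
(`srsphasor.phasor_transform`, `segment_by_rois`, `ratio_map`,
`ld_segment_3d`, `dipl_score`, ...) and as single-stack subcommands
(`srsphasor phasor transform|density|segment|spectra`,
`srsphasor risk score`).

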
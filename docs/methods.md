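# Methods

## Acquisition model and the wavenumber axis

Hyperspectral SRS acquisition holds the Stokes beam fixed (default
1031.4 nm) and retunes the pump laser in equal wavelength steps (default
0.4 nm) between frames; the probed Raman shift is
ν = 10⁷/λ_pump − 10⁷/λ_Stokes (cm⁻¹, wavelengths in nm).
`build_wavenumber_axis` reproduces this exactly: frames start at the
pump wavelength matching the high end of the shift window and step toward
longer wavelengths up to the last step that does not pass the low end, so
the 2800–3050 cm⁻¹ window yields 40 frames.  The stored axis is ascending
in cm⁻¹ with the acquisition order recorded; channel spacing is slightly
non-uniform (≈6.2–6.6 cm⁻¹ here, ≈15.6 cm⁻¹ per nm of retune).  Axis
validation enforces monotonicity, the [0, 5000] cm⁻¹ range, and
consistency with the retune grid to 0.05 cm⁻¹; axes loaded without pump
provenance (e.g. two hand-picked imaging frequencies) skip the grid check.

## Spectral phasor transform

For a pixel spectrum I_k (k = 0..N−1, ascending wavenumber, the window
treated as one period) the phasor at harmonic n is
G = Σ I_k cos(2πnk/N)/ΣI_k, S = Σ I_k sin(2πnk/N)/ΣI_k.
Defaults and conventions:

* harmonic n = 1 (the standard choice for spectral phasors);
* no baseline subtraction before the transform;
* pixels with nonpositive total intensity, or outside the foreground
  mask, are invalid and excluded everywhere downstream;
* the transform is exactly invariant to positive rescaling of the stack,
  and phasors of nonnegative spectra lie in the closed unit disc — both
  properties are asserted by tests at 1e−12/1e−9 tolerance.

Segmentation ROIs are simple polygons in (G, S) within [−1.05, 1.05]²;
membership is boundary-inclusive (shapely `covers`).  Overlaps resolve by
listed order (later wins) with one exception: the `total_lipid` umbrella
region never overwrites the specific lipid classes (steatosis,
phospholipidosis, alkyne), mirroring nested lipid-region markup.

Because published ROI vertex coordinates are generally unavailable,
`derive_roi_from_reference` automates ROI placement: the convex hull of a
pure-class reference phasor cloud (≥ 10 pixels of a homogeneous region, or
the analytic phasor of a reference spectrum) dilated by a padding distance
(default 0.025 in phasor units).  Reference clouds spanning more than half
the unit disc are rejected as ambiguous; a zero-padding single-point
reference is degenerate.  Derived ROIs are recorded in every run summary
and should be reviewed on the phasor density plot — they are an automated
stand-in for expert manual placement, not a validated classifier.

## Synthetic phantom generator

The generator emulates fixed HepG2-like cells in a 32 × 32 µm field
(0.25 µm pixels, z planes 1 µm apart, 2800–3050 cm⁻¹ in 40 frames):
non-overlapping ellipsoidal cells (default 3, in-plane radii 4–6 µm), one
offset nucleus per cell (45% of the cell radii) containing 1–3 brighter
nucleoli (×1.6 intensity, same spectrum), and spherical cytoplasmic
inclusions per class — steatosis droplets, phospholipidosis inclusions,
optional alkyne-drug deposits (radii 0.4–0.9 µm by default).  Placement is
rejection sampling with a bounded attempt budget; failure raises an error
naming the class.  Every voxel belongs to exactly one class and one cell;
geometry is rendered voxel-center exact with no partial-volume mixing, so
analytic volume oracles remain valid (a 2 µm sphere discretizes to within
a few percent of 4/3 πr³ at this voxel geometry).

Each class voxel carries its model spectrum (below) times an intensity
scale (default 1000 counts at unit model amplitude), then noise:
Poisson-like scaling (variance ∝ intensity; scale 1.0 count) plus additive
Gaussian read noise (σ = 2 counts), matching shot-noise-limited SRS
detection.  Negative values are clipped to zero and the clipped fraction
reported.  Everything is driven by one seed; identical configs are
bit-identical.

The noise defaults were chosen once as a realistic high-SNR acquisition
(peak-channel SNR ≈ 30–40, per-pixel phasor scatter σ ≈ 0.01); absolute
SRS intensities are instrument-specific and carry no published reference
values.

### Spectral library

`_library.yaml` (version 1) defines Lorentzian band models — the natural
Raman line shape; positions follow standard CH-stretch assignments
(2851 CH₂, ~2880 CH₂ asym/Fermi, 2930 CH₃, 2965 protein/DNA, ~3010 =CH,
2233 alkyne; widths 13–30 cm⁻¹).  Band *amplitudes* are free design
parameters of the generator.  The nine neat-lipid amplitudes were fixed
by least-squares fitting each model's analytic phasor to well-spaced
target positions subject to the chemistry-anchored constraints: the
~3010 cm⁻¹ amplitude strictly increases arachidic < oleic < linolenic <
arachidonic (0, 0.22, 0.50, 0.70) with increasing bandwidth, making
phasor modulation strictly decrease with unsaturation; cholesteryl
linoleate keeps a resolvable ~3015 cm⁻¹ peak.  The resulting minimum
pairwise phasor distance among the nine lipids is 0.122, about 12× the
default per-pixel phasor scatter, which sets the default ROI padding
(0.025).  Compartment models reproduce the assay's ratio contrasts
(noiseless CH₂/CH₃: nucleus 0.13, cytoplasm 0.42, steatosis droplet 2.87,
phospholipidosis inclusion 1.61) and the nuclear 2965 cm⁻¹ peak.
The phospholipidosis model is CH₂-rich but broader-banded with little =CH,
separating it from the narrow, unsaturated steatosis model in the phasor
plane (distance 0.118).

What the phantom does **not** emulate: optical point-spread-function blur,
partial-volume spectral mixing at boundaries, cross-phase-modulation or
photothermal backgrounds, spatial intensity gradients, cell-to-cell
spectral variability, and real lamellar-body substructure.  Passing tests
therefore demonstrate the correctness and internal consistency of the
analysis chain under known ground truth — not classification performance
on real tissue, where clusters are broader and ROI placement needs expert
review.

## Quantification conventions

* Ratio maps use the nearest channel within 5 cm⁻¹ of the requested
  shift; foreground pixels with denominator ≤ 1e−9 are undefined rather
  than infinite.  The conventional [0, 1] display clamp is recorded but
  never applied to data.
* Droplet volumetry: threshold (Otsu within the cell foreground by
  default), 26-connectivity in 3D (8 in 2D), minimum size 4 voxels,
  volume = voxel count × pixel² × z-step.  Per-droplet and per-cell
  totals are both emitted since aggregation conventions vary.
* Percent area uses the cell's foreground pixel count as denominator
  (per-cell area, the assay's reporting convention).
* Group tests: one-way ANOVA with post-hoc Tukey across conditions and
  pairwise Student's t (pooled variance; Welch behind a flag), tiered
  N.S./*/**/*** at 0.05/0.01/0.001.
* Background masking: Otsu on the average intensity projection by
  default, manual threshold override available; the threshold actually
  used is recorded in the mask provenance and the run summary.

## Pipeline and reproducibility

`srsphasor.run` executes, per condition and replicate: input (phantom or
TIFF + YAML sidecar) → average projection → background mask → phasor
transform → ROI segmentation (JSON or reference-derived) →
back-projection → segment spectra → ratio/percent-area/volumetry/
colocalization → cross-condition statistics.  Replicate seeds derive from
the run seed via `numpy.random.SeedSequence`, every stage's parameters
land in `summary.json` (sorted keys, no timestamps), and a rerun with the
same config and seed reproduces that file byte for byte.  Stage failures
abort with an error naming the stage (CLI exit code 3; config errors exit
2).  No stage caching is implemented: at the problem sizes this package
targets (tens of 128² × 40 stacks) a full run takes seconds, so a content
hash cache would add state without benefit.

## DIPL risk score

`dipl_score` encodes the cationic-amphiphilic-drug screening heuristic
pKa² + cLogP² with the inconclusive band (75, 85): scores at or above 85
are DIPL-prone, at or below 75 DIPL-unlikely, strictly between the
endpoints not reliably predictive (the strict inequalities of the
published band assign the endpoints to the conclusive zones; the band is
configurable).  Computing pKa/cLogP from structure, and the richer
multi-cutoff decision rules in the wider literature, are out of scope —
values are user-supplied.

## Problem sizes used in tests and the acceptance script

Tests run on 128 × 128 × 40 planar phantoms (3 cells) and 9 × 96 × 96
volumetric phantoms; segmentation accuracy is scored over 20 seeds,
colocalization over 20 seeds, lipid discrimination over 5 seeds with
32 × 32 reference stacks.  These sizes were chosen as the smallest fields
that hold three well-separated cells with both inclusion classes at the
study's pixel pitch; results are insensitive to enlarging them.
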
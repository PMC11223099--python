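# Versioned spectral library for the synthetic phantom generator.
#
# Each model is a sum of Lorentzian bands [center_cm1, fwhm_cm1, amplitude]
# plus a constant baseline.  Band *positions* follow the high-wavenumber CH
# stretch region assignments standard in SRS imaging (2851 CH2 symmetric
# stretch, ~2880 CH2 asymmetric / Fermi resonance, 2930 CH3 stretch,
# 2965 protein CH3 / DNA backbone, ~3010 =CH olefinic stretch, 2233 alkyne)
# plus sterol-specific structure for cholesterol.  Amplitudes and widths are
# free design parameters of the generator, chosen once so that (a) saturated
# -> polyunsaturated fatty acids gain ~3010 intensity and bandwidth, and
# (b) the compartment models reproduce the qualitative contrasts the method
# relies on (CH2/CH3 ratio > 0.8 in neutral-lipid droplets, < 0.2 in nuclei;
# nuclear peak at 2965; phasor clusters separable at default noise).
# Tests pin these exact values: bump `version` when editing.
version: 1
neat_lipids:
  - arachidic acid
  - glyceryl tristearate
  - sphingomyelin
  - cholesterol
  - cholesteryl linoleate
  - L-a-phosphatidylcholine
  - linolenic acid
  - oleic acid
  - arachidonic acid
models:
  # --- nine neat lipid species -------------------------------------------
  # Fatty-acid saturation series: the ~3010 cm-1 =CH amplitude rises and
  # bands broaden with the number of C=C (0, 1, 3, 4).
  arachidic acid:          # C20:0, fully saturated
    baseline: 0.0
    bands:
      - [2851, 13, 1.385]
      - [2880, 15, 0.788]
      - [2930, 20, 0.283]
  oleic acid:              # C18:1
    baseline: 0.0
    bands:
      - [2851, 17, 1.060]
      - [2880, 20, 0.286]
      - [2930, 22, 0.337]
      - [3010, 18, 0.220]
  linolenic acid:          # C18:3
    baseline: 0.0
    bands:
      - [2851, 20, 0.846]
      - [2880, 22, 0.324]
      - [2930, 24, 0.388]
      - [3010, 20, 0.500]
  arachidonic acid:        # C20:4
    baseline: 0.0
    bands:
      - [2851, 22, 0.676]
      - [2880, 24, 0.374]
      - [2930, 26, 0.453]
      - [3010, 22, 0.700]
  glyceryl tristearate:    # saturated triacylglycerol
    baseline: 0.0
    bands:
      - [2851, 14, 0.414]
      - [2880, 14, 1.314]
      - [2930, 18, 0.366]
  sphingomyelin:
    baseline: 0.0
    bands:
      - [2851, 24, 0.510]
      - [2880, 26, 0.426]
      - [2930, 28, 0.580]
      - [3010, 24, 0.050]
  cholesterol:
    baseline: 0.0
    bands:
      - [2851, 20, 0.528]
      - [2870, 18, 0.437]
      - [2930, 20, 0.295]
      - [2960, 18, 0.752]
  cholesteryl linoleate:   # esterified, unsaturated tail -> ~3015 peak
    baseline: 0.0
    bands:
      - [2851, 18, 0.652]
      - [2880, 20, 0.501]
      - [2930, 22, 0.455]
      - [3015, 18, 0.350]
  L-a-phosphatidylcholine:
    baseline: 0.0
    bands:
      - [2851, 19, 0.987]
      - [2890, 22, 0.672]
      - [2930, 22, 0.377]
      - [3010, 20, 0.120]
  # --- cellular compartments ---------------------------------------------
  nucleus:                 # protein CH3 + DNA band at 2965, little CH2
    baseline: 0.01
    bands:
      - [2851, 18, 0.05]
      - [2930, 24, 0.55]
      - [2965, 22, 0.85]
  cytoplasm:               # protein-dominated, moderate lipid content
    baseline: 0.01
    bands:
      - [2851, 18, 0.30]
      - [2880, 20, 0.12]
      - [2930, 24, 0.80]
      - [2965, 20, 0.25]
  steatosis-droplet:       # neutral lipid: strong narrow CH2 + =CH band
    baseline: 0.01
    bands:
      - [2851, 16, 1.60]
      - [2880, 18, 0.70]
      - [2930, 22, 0.55]
      - [3010, 18, 0.45]
  phospholipidosis-inclusion:  # CH2-rich but broader, weak =CH
    baseline: 0.01
    bands:
      - [2851, 30, 1.20]
      - [2890, 30, 0.50]
      - [2930, 30, 0.70]
      - [3010, 26, 0.10]
  alkyne-drug:             # free drug: cell-silent-region alkyne + aryl CH
    baseline: 0.01
    bands:
      - [2233, 16, 1.20]
      - [2851, 18, 0.15]
      - [2930, 22, 0.60]
      - [2965, 18, 0.30]
  alkyne-lamellar:         # drug sequestered in lamellar bodies: alkyne + phospholipid CH
    baseline: 0.01
    bands:
      - [2233, 16, 1.00]
      - [2851, 30, 1.25]
      - [2890, 30, 0.45]
      - [2930, 30, 0.65]
  background:              # coverslip/medium: weak, spectrally flat
    baseline: 0.015
    bands:
      - [2900, 500, 0.02]
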
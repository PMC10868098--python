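# fishquant

Super-resolution FISH image processing and HER2/CEP17 signal quantification
for breast-cancer ISH testing, with a synthetic single-molecule acquisition
simulator.

## The problem

HER2 (ERBB2) amplification status guides anti-HER2 therapy in breast cancer.
Dual-probe fluorescence in situ hybridization (FISH) measures it as the
HER2/CEP17 ratio *R* and the mean HER2 signals per nucleus, but
diffraction-limited microscopy blurs clustered amplification signals and
autofluorescent background into uncountable blobs. Single-molecule
localization microscopy (SMLM) circumvents the diffraction limit: thousands
of short-exposure frames capture individual fluorophores blinking at FISH
loci, each bright spot is fitted with a 2-D Gaussian point-spread function
(PSF) to sub-pixel precision, and the accumulated localizations are rendered
at ~20 nm — sharp enough to count signals that conventional-resolution
images merge.

`fishquant` is a desk-scale, fully tested implementation of that pipeline
for people studying quantitative ISH scoring: it provides

- **`simulate`** — a blinking-emitter acquisition simulator (5000 frames per
  probe channel, 1000 DAPI frames, integrated Gaussian PSF, smooth
  autofluorescence, Poisson + read noise) with complete ground truth;
- **`stackio`** — multi-page TIFF stacks and CSV localization tables;
- **`denoise`** — blind-spot self-supervised denoising (each pixel predicted
  from its neighbourhood *excluding itself*, so pixel-independent noise
  cannot be learned);
- **`background`** — rolling-ball (grayscale opening, radius 15 px)
  background subtraction and a regression threshold model
  `tau = a*mean + b*sd + c` calibrated against F1-optimal thresholds;
- **`superres`** — spot detection, batched Levenberg–Marquardt fitting of
  integrated 2-D Gaussians (flux, x, y, sigma, offset), and histogram /
  Gaussian rendering;
- **`quantify`** — DAPI nucleus segmentation, localization clustering into
  discrete signals, the ">4 signals" ambiguity rule, per-nucleus H and C
  counts and the ratio R over CEP17-countable nuclei;
- **`classify`** — ASCO/CAP 2018 dual-probe Groups 1–5
  (Group 1: R ≥ 2.0 and ≥ 4.0 signals/cell; Group 2: R ≥ 2.0, < 4.0;
  Group 3: R < 2.0, ≥ 6.0; Group 4: R < 2.0, 4.0–6.0; Group 5: R < 2.0,
  < 4.0), ISH status and IHC integration;
- **`compare`** — exact Wilcoxon signed-rank and Mann–Whitney tests,
  Pearson chi-squared (no continuity correction), and paired
  conventional-vs-super-resolution cohort reports.

## Worked example

```python
import fishquant as fq

# a simulated acquisition field: 4 nuclei, half carry an unresolvable
# cluster locus of 5 extra HER2 signals on top of 3 plain ones
params = fq.SimulationParams(seed=500, n_nuclei=4, her2_per_nucleus=3,
                             cluster_fraction=0.5)
her2, cep17, dapi, truth = fq.simulate_field(params)

model = fq.calibrate_threshold_model(n_images=20, seed=7)   # tau regression
sr = fq.analyze_field_sr(her2, cep17, dapi, threshold=model)
cr = fq.analyze_field_cr(her2, cep17, dapi)

print("SR:", sr.result.her2_per_nucleus, "ambiguous nuclei:", sr.result.nuclei_ambiguous_her2)
print("CR:", cr.result.her2_per_nucleus, "ambiguous nuclei:", cr.result.nuclei_ambiguous_her2)
```

prints

```
SR: 5.25 ambiguous nuclei: 0
CR: 3.0 ambiguous nuclei: 2
```

Every super-resolution signal is countable: the two cluster-bearing nuclei
contribute 3 + 5 = 8 HER2 signals each, raising the SR mean to 5.25. At
conventional resolution the same clusters are single wide blobs estimated
at "more than four" signals, so those nuclei are flagged ambiguous and
excluded, leaving the CR mean at the 3 plain signals per nucleus — the
mechanism by which super-resolution counting exceeds conventional counting
on amplified samples.

A `fishquant` command-line interface mirrors the library
(`fishquant simulate | split | merge | denoise | background | localize |
render | quantify | classify`).

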
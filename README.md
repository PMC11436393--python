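# mgscaffold

Synthetic micro-CT phantoms and degradation quantification for bioresorbable
magnesium-alloy coronary scaffolds.

The package models a six-crown / two-link scaffold with 110 µm square struts,
generates µCT-like voxel phantoms of its degradation (isotropic surface
erosion, substitution by higher- and lower-attenuation corrosion products,
discrete strut fractures, partial-volume blur, additive noise), and measures
those phantoms the way a µCT study would:

* **remaining Mg-alloy volume** from multi-peak fitting of the grayscale
  intensity histogram (Gaussian mixture on binned counts, BIC model
  selection, partial-volume-calibrated class assignment);
* **strut discontinuity ratio**: the percentage of designed strut segments
  whose endpoints are no longer bridged by scaffold material (26-connected
  paths within a capture tube around each centerline);
* **scaffold inner area** on axial cross-sections at fixed intervals
  (polygon through innermost strut points);
* the **isotropic square-strut degradation law** f(t) = (1 − 2kt/w)(1 − 2kt/h),
  scenario simulation for programmed area losses at one month, and bounded
  least-squares fitting of the complete-degradation period T (with
  t50 = T·(1 − 1/√2) for square struts).

## Layout

| module | contents |
| --- | --- |
| `mgscaffold.geometry` | parametric design, strut-segment graph, lengths/volumes |
| `mgscaffold.phantom` | voxelization, degradation states, grayscale rendering |
| `mgscaffold.volio` | MetaImage (`.mhd`/`.raw`) and multi-page TIFF round-trip I/O |
| `mgscaffold.histogram` | histogram computation, binned-EM peak fitting, volume estimation |
| `mgscaffold.integrity` | scaffold mask, discontinuity ratio, inner-area profile |
| `mgscaffold.model` | degradation law, scenarios, T/t50 fitting |
| `mgscaffold.config` / `mgscaffold.pipeline` / `mgscaffold.cli` | study config, end-to-end time course, CLI |

## CLI

All stages are independently invokable through the `mgct` entry point
(exit codes: 0 success, 1 validation error, 2 runtime failure):

```sh
mgct run-timecourse --config examples/study.yaml --out out/
mgct simulate-phantom --config examples/study.yaml --time 6 --out out/phantom
mgct estimate-volume --config examples/study.yaml --volume out/phantom/grayscale.mhd --out out/est
mgct integrity       --config examples/study.yaml --labels out/phantom/labels.mhd --out out/integ
mgct inner-area      --labels out/phantom/labels.mhd --out out/area
mgct fit-model       --observations observations.csv --out out/fit
```

`run-timecourse` generates one phantom per scheduled timepoint, measures
remaining volume / discontinuity / inner area, fits the degradation law to
the remaining-volume series, and writes `report.json` plus CSV tables.
Everything stochastic derives from the single config seed; the same config
and seed reproduce the report byte for byte.

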
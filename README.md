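# huiharm

Cross-scanner harmonization of the **hepatocellular uptake index (HUI)**, a
quantitative liver-function biomarker from gadoxetate-enhanced MRI.

MR signal intensity is not standardized across scanners, so HUI values from
different MR systems are not directly comparable. `huiharm` places them on a
common scale by calibrating per-scanner conversion factors against a
reference system, using either of two routes:

* **ICG route** — through-origin regression of the indocyanine green plasma
  disappearance rate (ICG-PDR) on HUI gives each scanner a slope; the ratio
  to the reference slope is the conversion factor **CF1**, and
  `h-HUI = HUI * CF1`.
* **ALBI route** — the same construction with the albumin-bilirubin linear
  predictor (ALBI-LP), a cheap blood test, gives **CF2**. A fitted
  cross-route coefficient **CF3** (through-origin slope of CF1 on CF2 across
  scanners) lets sites without ICG testing harmonize via
  `h-HUI = HUI * CF2 * CF3`.

Quantitative liver function is then estimated as
`eICG-PDR = Slope1 * h-HUI`, with `Slope1` the reference scanner's
HUI-to-ICG-PDR slope.

Note on units: HUI carries the liver volume in **liters**, so cohort-typical
values are ~0.9 L and the reference slope is ~-0.17 per liter.

## Package layout

| module | contents |
| --- | --- |
| `huiharm.measurement` | HUI from image/ROI statistics (NIfTI), ICG-PDR from timed concentrations, ALBI-LP from bilirubin/albumin |
| `huiharm.stats` | zero-intercept regression with t-based inference, CI-overlap commutability test, bootstrap RMSE CIs, normal residual fits, ICC(2,1) |
| `huiharm.harmonization` | scanner calibration, CF1/CF2/CF3, h-HUI, eICG-PDR, commutability and residual-distribution reports, calibration JSON |
| `huiharm.simulate` | synthetic multi-scanner cohorts with latent liver function, scanner gains, and two noisy assays |
| `huiharm.reference` | published six-scanner calibration constants used as simulator defaults and validation fixtures |
| `huiharm.io` / `huiharm.cli` | cohort CSV and report I/O, `huiharm` command-line app |

## Command-line usage

The full workflow on a synthetic cohort:

```sh
huiharm simulate --seed 42 --out cohort.csv --truth truth.csv
huiharm fit --cohort cohort.csv --reference auto --out calibration.json
huiharm harmonize --cohort cohort.csv --calibration calibration.json \
    --route albi --out harmonized.csv
huiharm validate --cohort cohort.csv --calibration calibration.json \
    --report report.json
```

`simulate` accepts a YAML config mirroring `SimulationConfig`; without one
it uses the built-in six-scanner setup (498 patients, gains and sample
sizes from the reference cohort). Cohort CSVs carry
`patient_id, scanner_id, hui, icg_pdr, albi_lp, bilirubin, albumin`
(assay columns optional; ALBI-LP is derived from bilirubin/albumin when
absent). Records without ICG-PDR are excluded from the ICG route but remain
usable on the ALBI route.

Single-measurement helpers:

```sh
huiharm measure-hui --image t1.nii --liver-mask liver.nii --spleen-mask spleen.nii --json
huiharm albi --bilirubin 10 --albumin 40
huiharm icg-pdr --times 5,10,15 --concentrations 4.5,2.0,0.9
```

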
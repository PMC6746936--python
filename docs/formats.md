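# On-disk formats

All files are plain text or standard image formats; no binary containers.

## Patient directory

```
<patient_id>/
  image.png        16-bit grayscale (or image.dcm, read-only DICOM)
  femur_mask.png   8-bit: 0 background, 255 femur
  roi_labels.png   8-bit region map (see label values below)
  roi_means.json   per-ROI mean areal BMD, g/cm^2
  meta.json        patient metadata
  hsa.json         optional per-patient HSA row (written for phantoms)
```

Pixel spacing: taken from the DICOM `PixelSpacing` tag when the image is
DICOM; otherwise `meta.json` must carry `spacing_mm`. Anisotropic spacing is
rejected.

### Label values (`roi_labels.png`)

| value | region            | role |
|-------|-------------------|------|
| 0     | background        | — |
| 1     | neck              | calibration ROI; intracapsular label |
| 2     | trochanter        | calibration ROI; load surface; RF^ exclusion |
| 3     | intertrochanter   | calibration ROI |
| 4     | head              | spring boundary; RF^ exclusion |
| 5     | remaining shaft   | — |

### `roi_means.json`

```json
{"neck": 0.726, "trochanter": 0.853, "intertrochanter": 0.840}
```

### `meta.json`

```json
{"height_m": 1.61, "weight_kg": 65.0, "t_score": -1.1, "spacing_mm": 0.5}
```

## Cohort directory

```
<cohort>/
  patients/<patient_id>/...   one patient directory each
  hsa.csv                     patient_id + 20 HSA columns
  patients.csv                patient_id + metadata columns
  truth.json                  phantom ground truth (synthetic cohorts only)
```

`hsa.csv` columns: `NSA` (deg), `HAL` (mm), and for each site `NN`
(narrow neck), `IT` (intertrochanter), `FS` (femoral shaft): `_W` width mm,
`_BR` buckling ratio, `_CSMI` cm^4, `_CSA` cm^2, `_Z` cm^3, `_ACT` mm.

## Outputs

* `<patient_id>.json` — per-patient report: calibration line (g/cm^2,
  g/cm^2 per gray), neck width and plate thickness (mm), impact force (N),
  mesh and material summaries, equilibrium residual, RF^ with location
  label and at-risk flag.
* `<patient_id>.vtk` — legacy-VTK ASCII unstructured grid; point data:
  `displacement_mm`; cell data: `E_mpa`, `rho_app_g_cm3`, `bin_id`, `eps1`,
  `eps3`, `rf`, `rf_above_p90` (display floor at the per-patient 90th
  percentile), `excluded`.
* `cohort.csv` — patient_id, rf_hat, location, t_score, at_risk.
* `thresholds.json` — pooled-RF percentiles (90, 98, 99.9).
* `ranking.csv` — variable, cumulative Akaike weight (descending).
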
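"""Readers and writers for the on-disk patient/cohort layout.

A patient directory contains::

    image.png        16-bit grayscale DXA-like image (or image.dcm, DICOM)
    femur_mask.png   8-bit, 0 background / 255 femur
    roi_labels.png   8-bit region map: 1 neck, 2 trochanter,
                     3 intertrochanter, 4 head, 5 remaining shaft
    roi_means.json   {"neck": g/cm^2, "trochanter": ..., "intertrochanter": ...}
    meta.json        {"height_m", "weight_kg", "t_score", "spacing_mm"}

A cohort directory holds ``patients/<id>/`` plus ``hsa.csv`` (one row per
patient, the 20 HSA columns), ``patients.csv`` (metadata) and, for phantoms,
``truth.json``.  Pixel spacing comes from the DICOM header when the image is
DICOM, otherwise from ``meta.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .calibration import GrayImage
from .phantom import CohortBundle, PhantomPatient

_REQUIRED_ROI = ("neck", "trochanter", "intertrochanter")


@dataclass
class PatientBundle:
    """One patient's validated inputs, ready for the pipeline."""

    patient_id: str
    image: GrayImage
    femur_mask: np.ndarray
    labels: np.ndarray
    roi_means: dict[str, float]
    metadata: dict[str, float]
    hsa: dict[str, float] | None = None
    source_dir: Path | None = field(default=None, repr=False)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_patient(directory: str | Path, patient: PhantomPatient) -> Path:
    """Write one phantom patient in the documented directory layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pixels = np.clip(np.round(patient.image.pixels), 0, 65535).astype(np.uint16)
    iio.imwrite(directory / "image.png", pixels)
    iio.imwrite(
        directory / "femur_mask.png",
        (patient.femur_mask.astype(np.uint8) * 255),
    )
    iio.imwrite(directory / "roi_labels.png", patient.labels.astype(np.uint8))
    _dump_json(patient.roi_means, directory / "roi_means.json")
    _dump_json(patient.metadata, directory / "meta.json")
    return directory


def read_patient(directory: str | Path) -> PatientBundle:
    """Read and validate one patient directory.

    Raises ``FileNotFoundError``/``ValueError`` naming the offending file
    when the layout is incomplete or inconsistent.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"patient directory {directory} does not exist")

    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata file {meta_path}")
    metadata = json.loads(meta_path.read_text())

    dcm = directory / "image.dcm"
    png = directory / "image.png"
    if dcm.exists():
        import pydicom

        ds = pydicom.dcmread(dcm)
        pixels = ds.pixel_array.astype(np.float64)
        spacing = getattr(ds, "PixelSpacing", None)
        if spacing is not None:
            sp = float(spacing[0])
            if abs(float(spacing[0]) - float(spacing[1])) > 1e-9:
                raise ValueError(f"{dcm}: anisotropic pixel spacing unsupported")
        else:
            sp = metadata.get("spacing_mm")
            if sp is None:
                raise ValueError(
                    f"{dcm} has no PixelSpacing and meta.json lacks 'spacing_mm'"
                )
    elif png.exists():
        pixels = np.asarray(iio.imread(png), dtype=np.float64)
        sp = metadata.get("spacing_mm")
        if sp is None:
            raise ValueError(
                f"{png} is a plain image: meta.json must provide 'spacing_mm'"
            )
    else:
        raise FileNotFoundError(f"missing image file {png} (or image.dcm)")

    mask_path = directory / "femur_mask.png"
    if not mask_path.exists():
        raise FileNotFoundError(f"missing femur mask {mask_path}")
    femur_mask = np.asarray(iio.imread(mask_path)) > 0

    labels_path = directory / "roi_labels.png"
    if not labels_path.exists():
        raise FileNotFoundError(f"missing ROI label map {labels_path}")
    labels = np.asarray(iio.imread(labels_path)).astype(np.uint8)

    roi_path = directory / "roi_means.json"
    if not roi_path.exists():
        raise FileNotFoundError(f"missing ROI mean-BMD sidecar {roi_path}")
    roi_means = json.loads(roi_path.read_text())
    missing = set(_REQUIRED_ROI) - set(roi_means)
    if missing:
        raise ValueError(f"{roi_path}: missing ROI means {sorted(missing)}")

    if femur_mask.shape != pixels.shape or labels.shape != pixels.shape:
        raise ValueError(
            f"{directory}: image, mask and label shapes are inconsistent"
        )

    hsa = None
    hsa_path = directory / "hsa.json"
    if hsa_path.exists():
        hsa = json.loads(hsa_path.read_text())

    return PatientBundle(
        patient_id=directory.name,
        image=GrayImage(pixels=pixels, spacing_mm=float(sp)),
        femur_mask=femur_mask,
        labels=labels,
        roi_means={k: float(v) for k, v in roi_means.items()},
        metadata=metadata,
        hsa=hsa,
        source_dir=directory,
    )


def write_cohort(directory: str | Path, cohort: CohortBundle) -> Path:
    """Write a full phantom cohort (patients, hsa.csv, patients.csv, truth)."""
    directory = Path(directory)
    (directory / "patients").mkdir(parents=True, exist_ok=True)
    for patient in cohort.patients:
        pdir = write_patient(directory / "patients" / patient.patient_id, patient)
        _dump_json(patient.hsa, pdir / "hsa.json")
    cohort.hsa.rename_axis("patient_id").to_csv(directory / "hsa.csv")
    cohort.metadata.rename_axis("patient_id").to_csv(directory / "patients.csv")
    _dump_json(cohort.truth, directory / "truth.json")
    return directory


def read_cohort(directory: str | Path) -> tuple[list[PatientBundle], pd.DataFrame, pd.DataFrame]:
    """Read a cohort directory; returns (bundles, hsa table, metadata table)."""
    directory = Path(directory)
    pdirs = sorted((directory / "patients").iterdir())
    bundles = [read_patient(p) for p in pdirs if p.is_dir()]
    hsa = pd.read_csv(directory / "hsa.csv", index_col="patient_id")
    meta = pd.read_csv(directory / "patients.csv", index_col="patient_id")
    ids = [b.patient_id for b in bundles]
    if set(ids) != set(hsa.index) or set(ids) != set(meta.index):
        raise ValueError(f"{directory}: patient ids inconsistent across files")
    return bundles, hsa, meta
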
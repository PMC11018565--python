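"""DICOM reading/writing for phantom acquisitions.

Reads "for processing" mammography objects (2-D DM/CEM images and breast
tomosynthesis projections), extracting the AEC-selected technical factors —
anode/filter track, tube voltage, exposure — plus the entrance dose and
vendor organ dose when present.  A writer emits synthetic objects that
round-trip bit-exactly, so the whole pipeline can be exercised without real
acquisitions.

The study cell each file belongs to (system, modality, AEC mode, PMMA
thickness, repeat) is carried redundantly: in a JSON manifest next to the
files (authoritative) and encoded in SeriesDescription (fallback).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

__all__ = [
    "Acquisition",
    "DicomFormatError",
    "read_acquisition",
    "write_synthetic_dicom",
    "load_study_table",
    "read_pixels",
]

log = logging.getLogger(__name__)


class DicomFormatError(ValueError):
    """File is not a readable DICOM mammography image."""


# Storage SOP classes: mammography and breast-projection objects, the
# "for processing" variants being the measurement substrate.
MG_PROCESSING = "1.2.840.10008.5.1.4.1.1.1.2.1"
MG_PRESENTATION = "1.2.840.10008.5.1.4.1.1.1.2"
BPROJ_PROCESSING = "1.2.840.10008.5.1.4.1.1.13.1.5"
BPROJ_PRESENTATION = "1.2.840.10008.5.1.4.1.1.13.1.4"
_PROJECTION_CLASSES = {BPROJ_PROCESSING, BPROJ_PRESENTATION}

_MATERIAL_TO_DICOM = {
    "Mo": "MOLYBDENUM",
    "Rh": "RHODIUM",
    "W": "TUNGSTEN",
    "Ag": "SILVER",
    "Al": "ALUMINUM",
    "Cu": "COPPER",
}
_DICOM_TO_MATERIAL = {v: k for k, v in _MATERIAL_TO_DICOM.items()}

SUB_KINDS = ("DM", "DBT_PROJECTION", "CEM_LE", "CEM_HE")


@dataclass(frozen=True)
class Acquisition:
    """One exposure event: identity plus the AEC-selected technical factors.

    ``plan_key`` is (system, modality, aec_mode, pmma_mm, repeat_index) or
    None when the file carries no cell assignment.  Optional metadata that a
    file does not carry stays None — never fabricated.
    """

    sub_kind: str
    anode: str
    filter: str
    kvp: float
    mas: float
    pmma_mm: float | None = None
    plan_key: tuple[str, str, str, float, int] | None = None
    projection_angle_deg: float = 0.0
    entrance_kerma_mgy: float | None = None
    vendor_organ_dose_mgy: float | None = None
    pixel_pitch_um: float | None = None
    for_processing: bool = True
    series_uid: str | None = None
    source_path: str | None = None

    def __post_init__(self) -> None:
        if self.sub_kind not in SUB_KINDS:
            raise ValueError(f"unknown sub_kind {self.sub_kind!r}")
        if self.kvp <= 0 or self.mas <= 0:
            raise ValueError("kvp and mas must be positive")
        if self.entrance_kerma_mgy is not None and self.entrance_kerma_mgy < 0:
            raise ValueError("entrance kerma must be non-negative")
        if self.sub_kind == "CEM_HE" and self.filter != "Cu":
            raise ValueError("high-energy CEM acquisitions use the Cu filter")

    @property
    def scan_key(self) -> tuple | None:
        if self.plan_key is None:
            return None
        return self.plan_key  # one scan / series per plan entry


def _plan_key_str(key: tuple[str, str, str, float, int]) -> str:
    system, modality, mode, pmma, repeat = key
    return (
        f"system={system};modality={modality};mode={mode};"
        f"pmma={pmma};repeat={repeat}"
    )


def _parse_plan_key(text: str):
    try:
        parts = dict(item.split("=", 1) for item in text.split(";"))
        return (
            parts["system"],
            parts["modality"],
            parts["mode"],
            float(parts["pmma"]),
            int(parts["repeat"]),
        )
    except Exception:
        return None


def write_synthetic_dicom(
    acq: Acquisition,
    pixels: np.ndarray,
    path: str | Path,
) -> Path:
    """Write one synthetic "for processing" mammography object.

    Pixel data are stored bit-exactly as 16-bit MONOCHROME2; technical
    factors go to their standard tags (kVp, exposure in both mAs and uAs,
    anode/filter materials, body-part thickness, entrance dose, pixel
    spacing, projection angle).
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValueError("pixel array must be 2-D")
    if not np.issubdtype(pixels.dtype, np.integer):
        raise ValueError("pixel array must be integer-valued")
    pixels = pixels.astype(np.uint16)

    is_projection = acq.sub_kind == "DBT_PROJECTION"
    sop_class = BPROJ_PROCESSING if is_projection else MG_PROCESSING
    entropy = [repr(acq.plan_key), acq.sub_kind, f"{acq.projection_angle_deg:.6f}"]
    sop_uid = generate_uid(entropy_srcs=entropy + ["instance"])
    series_uid = acq.series_uid or generate_uid(
        entropy_srcs=[repr(acq.plan_key), "series"]
    )

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_uid
    ds.SeriesInstanceUID = series_uid
    ds.StudyInstanceUID = generate_uid(
        entropy_srcs=[repr(acq.plan_key), "study"]
    )
    ds.Modality = "MG"
    ds.PresentationIntentType = (
        "FOR PROCESSING" if acq.for_processing else "FOR PRESENTATION"
    )
    image_type = ["ORIGINAL", "PRIMARY"]
    if acq.sub_kind == "CEM_LE":
        image_type.append("LOW_ENERGY")
    elif acq.sub_kind == "CEM_HE":
        image_type.append("HIGH_ENERGY")
    ds.ImageType = image_type
    if acq.plan_key is not None:
        ds.SeriesDescription = _plan_key_str(acq.plan_key)

    ds.KVP = str(acq.kvp)
    ds.ExposureInmAs = float(acq.mas)  # FD: exact
    ds.ExposureInuAs = int(round(acq.mas * 1000))
    ds.AnodeTargetMaterial = _MATERIAL_TO_DICOM[acq.anode]
    ds.FilterMaterial = _MATERIAL_TO_DICOM[acq.filter]
    if acq.pmma_mm is not None:
        ds.BodyPartThickness = str(acq.pmma_mm)
    if acq.entrance_kerma_mgy is not None:
        ds.EntranceDoseInmGy = str(acq.entrance_kerma_mgy)
    if acq.vendor_organ_dose_mgy is not None:
        ds.OrganDose = str(acq.vendor_organ_dose_mgy / 100.0)  # stored in dGy
    if acq.pixel_pitch_um is not None:
        pitch_mm = acq.pixel_pitch_um / 1000.0
        ds.ImagerPixelSpacing = [str(pitch_mm), str(pitch_mm)]
    if is_projection:
        ds.PositionerPrimaryAngle = str(acq.projection_angle_deg)

    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.tobytes()

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.save_as(path, enforce_file_format=True)
    return path


def _float_or_none(ds: Dataset, keyword: str) -> float | None:
    value = getattr(ds, keyword, None)
    if value in (None, ""):
        return None
    return float(value)


def read_acquisition(path: str | Path) -> Acquisition:
    """Extract the technical factors of one DICOM mammography image.

    Missing optional tags yield absent (None) fields; a missing kVp or
    exposure makes the acquisition unusable and raises.  "For presentation"
    files are read but flagged, and are excluded from image-quality
    statistics downstream.
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # noqa: BLE001 - normalize to a format error
        raise DicomFormatError(f"{path}: not a readable DICOM file: {exc}") from exc
    if getattr(ds, "Modality", None) != "MG":
        raise DicomFormatError(f"{path}: not a mammography image (Modality)")

    kvp = _float_or_none(ds, "KVP")
    mas = _float_or_none(ds, "ExposureInmAs")
    if mas is None:
        uas = _float_or_none(ds, "ExposureInuAs")
        if uas is not None:
            mas = uas / 1000.0
        else:
            mas = _float_or_none(ds, "Exposure")
    if kvp is None or mas is None:
        raise ValueError(f"{path}: missing kVp or exposure; acquisition unusable")

    anode = _DICOM_TO_MATERIAL.get(str(getattr(ds, "AnodeTargetMaterial", "")).upper())
    filt = _DICOM_TO_MATERIAL.get(str(getattr(ds, "FilterMaterial", "")).upper())
    if anode is None or filt is None:
        raise ValueError(f"{path}: missing anode/filter material tags")

    intent = str(getattr(ds, "PresentationIntentType", "FOR PROCESSING"))
    for_processing = intent.upper() != "FOR PRESENTATION"
    if not for_processing:
        log.warning(
            "%s: 'for presentation' image; excluded from IQ statistics", path
        )

    image_type = [str(v).upper() for v in getattr(ds, "ImageType", [])]
    sop_class = str(getattr(ds, "SOPClassUID", ""))
    if sop_class in _PROJECTION_CLASSES or "TOMOSYNTHESIS" in image_type:
        sub_kind = "DBT_PROJECTION"
    elif "HIGH_ENERGY" in image_type or (filt == "Cu" and kvp >= 40):
        sub_kind = "CEM_HE"
    elif "LOW_ENERGY" in image_type:
        sub_kind = "CEM_LE"
    else:
        sub_kind = "DM"

    angle = _float_or_none(ds, "PositionerPrimaryAngle") or 0.0
    pitch_um = None
    spacing = getattr(ds, "ImagerPixelSpacing", None)
    if spacing:
        # round away the mm->um float noise (spacing is stored in mm)
        pitch_um = round(float(spacing[0]) * 1000.0, 6)
    organ_dose_dgy = _float_or_none(ds, "OrganDose")
    plan_key = None
    if getattr(ds, "SeriesDescription", None):
        plan_key = _parse_plan_key(str(ds.SeriesDescription))

    return Acquisition(
        sub_kind=sub_kind,
        anode=anode,
        filter=filt,
        kvp=kvp,
        mas=mas,
        pmma_mm=_float_or_none(ds, "BodyPartThickness"),
        plan_key=plan_key,
        projection_angle_deg=angle,
        entrance_kerma_mgy=_float_or_none(ds, "EntranceDoseInmGy"),
        vendor_organ_dose_mgy=(
            None if organ_dose_dgy is None else organ_dose_dgy * 100.0
        ),
        pixel_pitch_um=pitch_um,
        for_processing=for_processing,
        series_uid=str(getattr(ds, "SeriesInstanceUID", "")) or None,
        source_path=str(path),
    )


def read_pixels(path: str | Path) -> np.ndarray:
    """Pixel array of a previously written/readable file."""
    ds = pydicom.dcmread(path)
    return ds.pixel_array


def acquisition_to_row(acq: Acquisition) -> dict:
    """Flatten an Acquisition into a StudyTable row."""
    if acq.plan_key is None:
        raise ValueError("acquisition has no plan-cell assignment")
    system, modality, mode, pmma, repeat = acq.plan_key
    return {
        "system": system,
        "modality": modality,
        "aec_mode": mode,
        "pmma_mm": float(pmma),
        "repeat": int(repeat),
        "sub_kind": acq.sub_kind,
        "angle_deg": acq.projection_angle_deg,
        "anode": acq.anode,
        "filter": acq.filter,
        "kvp": acq.kvp,
        "mas": acq.mas,
        "entrance_kerma_mgy": acq.entrance_kerma_mgy,
        "vendor_organ_dose_mgy": acq.vendor_organ_dose_mgy,
        "pixel_pitch_um": acq.pixel_pitch_um,
        "for_processing": acq.for_processing,
        "source_path": acq.source_path,
    }


def load_study_table(source: str | Path):
    """Build a StudyTable from a DICOM directory or a long-format factor CSV.

    For directories, cell assignment uses ``manifest.json`` (filename ->
    plan-key fields) when present, else the SeriesDescription encoding;
    files with neither are reported on the returned table's ``unmatched``
    list, never silently dropped.  Duplicate (cell, repeat, sub_kind, angle)
    keys raise with the offending files listed.
    """
    from .aec_stats import StudyTable  # local import: stats layer owns the container

    source = Path(source)
    if source.is_file():
        return StudyTable.from_csv(source)
    if not source.is_dir():
        raise FileNotFoundError(source)

    manifest: dict[str, dict] = {}
    manifest_path = source / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())

    rows: list[dict] = []
    unmatched: list[str] = []
    seen: dict[tuple, str] = {}
    duplicates: list[str] = []
    for path in sorted(source.rglob("*.dcm")):
        acq = read_acquisition(path)
        entry = manifest.get(path.name)
        if entry is not None:
            key = (
                entry["system"], entry["modality"], entry["aec_mode"],
                float(entry["pmma_mm"]), int(entry["repeat"]),
            )
            acq = replace(acq, plan_key=key)
        if acq.plan_key is None:
            unmatched.append(str(path))
            continue
        dedup = (acq.plan_key, acq.sub_kind, round(acq.projection_angle_deg, 3))
        if dedup in seen:
            duplicates.append(f"{seen[dedup]} vs {path}")
        seen[dedup] = str(path)
        rows.append(acquisition_to_row(acq))
    if duplicates:
        raise ValueError(
            "duplicate acquisitions for the same cell/sub-kind/angle:\n  "
            + "\n  ".join(duplicates)
        )
    if unmatched:
        log.warning(
            "%d file(s) without a plan-cell assignment: %s",
            len(unmatched), ", ".join(unmatched[:5]),
        )
    table = StudyTable(pd.DataFrame(rows))
    table.unmatched = unmatched
    return table
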
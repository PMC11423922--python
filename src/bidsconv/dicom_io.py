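"""Enumerate DICOM inputs (directories, file lists, zip archives) and read headers.

Header reading is lazy: pixel data is never loaded here, only during volume
assembly, so the discovery stage scales to large studies.
"""

from __future__ import annotations

import datetime as dt
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.errors import InvalidDicomError

from .errors import ArchiveError, InputError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DicomHeader:
    """The per-file subset of DICOM attributes the pipeline consumes.

    All geometry fields are in the DICOM LPS patient frame; times follow the
    DICOM units (EchoTime/RepetitionTime in milliseconds).
    """

    file_path: Path
    study_instance_uid: str
    series_instance_uid: str
    series_number: int
    instance_number: int
    rows: int
    columns: int
    acquisition_number: int | None = None
    study_description: str | None = None
    referring_physician_name: str | None = None
    series_description: str = ""
    protocol_name: str = ""
    sequence_name: str | None = None
    patient_id: str | None = None
    patient_name: str | None = None
    study_date: dt.date | None = None
    study_time: dt.time | None = None
    acquisition_datetime: dt.datetime | None = None
    image_type: tuple[str, ...] = ()
    echo_time: float | None = None
    echo_number: int | None = None
    repetition_time: float | None = None
    flip_angle: float | None = None
    image_orientation_patient: tuple[float, ...] | None = None
    image_position_patient: tuple[float, ...] | None = None
    pixel_spacing: tuple[float, float] | None = None
    spacing_between_slices: float | None = None
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    manufacturer: str | None = None

    def __post_init__(self) -> None:
        if not self.series_instance_uid or not self.study_instance_uid:
            raise ValueError("series and study instance UIDs must be non-empty")
        if self.image_orientation_patient is not None:
            iop = np.asarray(self.image_orientation_patient, float)
            if iop.shape != (6,):
                raise ValueError("ImageOrientationPatient must hold 6 values")
            for vec in (iop[:3], iop[3:]):
                if abs(np.linalg.norm(vec) - 1.0) > 1e-4:
                    raise ValueError("direction cosines must be unit-norm")


@dataclass(frozen=True)
class HeaderRejection:
    """A file that was inspected but is not usable DICOM input (a value, not an error)."""

    file_path: Path
    reason: str


def discover_files(
    inputs: list[str | Path], workspace: str | Path | None = None
) -> list[Path]:
    """Flatten directories, explicit files and zip archives into a sorted file list.

    Zip members are extracted into *workspace* (a temporary directory the
    caller owns) and the extracted paths are returned. Nested zips are not
    descended into. Non-DICOM files are retained here and filtered at read
    time by :func:`read_header`.
    """
    found: set[Path] = set()
    for item in inputs:
        path = Path(item)
        if not path.exists():
            raise InputError(f"input path does not exist: {path}")
        if path.is_dir():
            found.update(p for p in path.rglob("*") if p.is_file())
        elif path.suffix.lower() == ".zip" or zipfile.is_zipfile(path):
            found.update(_extract_zip(path, workspace))
        else:
            found.add(path)
    return sorted(found)


def _extract_zip(archive: Path, workspace: str | Path | None) -> list[Path]:
    if workspace is None:
        raise InputError(
            f"zip input {archive} requires an extraction workspace directory"
        )
    dest = Path(workspace) / archive.stem
    try:
        with zipfile.ZipFile(archive) as zf:
            bad = zf.testzip()
            if bad is not None:
                raise ArchiveError(f"corrupt member {bad!r} in {archive}")
            zf.extractall(dest)
    except zipfile.BadZipFile as exc:
        raise ArchiveError(f"cannot read zip archive {archive}: {exc}") from exc
    return [p for p in dest.rglob("*") if p.is_file()]


def read_header(
    path: str | Path, allow_no_magic: bool = False
) -> DicomHeader | HeaderRejection:
    """Read the consumed header attributes of one file; pixel data is NOT loaded.

    Files lacking the Part-10 "DICM" magic marker (unless *allow_no_magic*)
    or lacking SeriesInstanceUID are returned as :class:`HeaderRejection`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"file does not exist: {path}")
    try:
        ds = pydicom.dcmread(path, stop_before_pixels=True, force=allow_no_magic)
    except InvalidDicomError:
        log.debug("rejecting non-DICOM file %s", path)
        return HeaderRejection(path, "missing DICM magic marker")
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    except Exception:
        log.debug("rejecting unparseable file %s", path)
        return HeaderRejection(path, "unparseable as DICOM")

    series_uid = str(getattr(ds, "SeriesInstanceUID", "") or "")
    study_uid = str(getattr(ds, "StudyInstanceUID", "") or "")
    if not series_uid:
        return HeaderRejection(path, "no SeriesInstanceUID")
    if not study_uid:
        return HeaderRejection(path, "no StudyInstanceUID")

    return DicomHeader(
        file_path=path,
        study_instance_uid=study_uid,
        series_instance_uid=series_uid,
        series_number=int(getattr(ds, "SeriesNumber", 0) or 0),
        instance_number=int(getattr(ds, "InstanceNumber", 0) or 0),
        acquisition_number=_opt_int(ds, "AcquisitionNumber"),
        study_description=_opt_str(ds, "StudyDescription"),
        referring_physician_name=_opt_str(ds, "ReferringPhysicianName"),
        series_description=_opt_str(ds, "SeriesDescription") or "",
        protocol_name=_opt_str(ds, "ProtocolName") or "",
        sequence_name=_opt_str(ds, "SequenceName"),
        patient_id=_opt_str(ds, "PatientID"),
        patient_name=_opt_str(ds, "PatientName"),
        study_date=_parse_da(getattr(ds, "StudyDate", None)),
        study_time=_parse_tm(getattr(ds, "StudyTime", None)),
        acquisition_datetime=_parse_dt(ds),
        image_type=tuple(str(t) for t in getattr(ds, "ImageType", []) or []),
        echo_time=_opt_float(ds, "EchoTime"),
        echo_number=_opt_int(ds, "EchoNumbers"),
        repetition_time=_opt_float(ds, "RepetitionTime"),
        flip_angle=_opt_float(ds, "FlipAngle"),
        image_orientation_patient=_opt_floats(ds, "ImageOrientationPatient", 6),
        image_position_patient=_opt_floats(ds, "ImagePositionPatient", 3),
        pixel_spacing=_opt_floats(ds, "PixelSpacing", 2),
        spacing_between_slices=_opt_float(ds, "SpacingBetweenSlices"),
        rescale_slope=_opt_float(ds, "RescaleSlope") or 1.0,
        rescale_intercept=_opt_float(ds, "RescaleIntercept") or 0.0,
        manufacturer=_opt_str(ds, "Manufacturer"),
        rows=int(getattr(ds, "Rows", 0) or 0),
        columns=int(getattr(ds, "Columns", 0) or 0),
    )


def load_pixel_array(path: str | Path) -> np.ndarray:
    """Read the (rows, columns) pixel array of one file (assembly stage only)."""
    ds = pydicom.dcmread(path)
    return ds.pixel_array


def _opt_str(ds: pydicom.Dataset, name: str) -> str | None:
    value = getattr(ds, name, None)
    if value is None or value == "":
        return None
    return str(value)


def _opt_int(ds: pydicom.Dataset, name: str) -> int | None:
    value = getattr(ds, name, None)
    if value in (None, ""):
        return None
    return int(value)


def _opt_float(ds: pydicom.Dataset, name: str) -> float | None:
    value = getattr(ds, name, None)
    if value in (None, ""):
        return None
    return float(value)


def _opt_floats(
    ds: pydicom.Dataset, name: str, n: int
) -> tuple[float, ...] | None:
    value = getattr(ds, name, None)
    if value is None:
        return None
    values = tuple(float(v) for v in value)
    return values if len(values) == n else None


def _parse_da(value: str | None) -> dt.date | None:
    if not value:
        return None
    return dt.datetime.strptime(str(value), "%Y%m%d").date()


def _parse_tm(value: str | None) -> dt.time | None:
    if not value:
        return None
    text = str(value).split(".")[0].ljust(6, "0")
    return dt.time(int(text[0:2]), int(text[2:4]), int(text[4:6]))


def _parse_dt(ds: pydicom.Dataset) -> dt.datetime | None:
    value = getattr(ds, "AcquisitionDateTime", None)
    if value:
        text = str(value).split(".")[0].split("+")[0].split("-")[0]
        return dt.datetime.strptime(text, "%Y%m%d%H%M%S")
    date = _parse_da(getattr(ds, "AcquisitionDate", None))
    time = _parse_tm(getattr(ds, "AcquisitionTime", None))
    if date and time:
        return dt.datetime.combine(date, time)
    return None
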
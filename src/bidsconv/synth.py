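"""Synthetic DICOM studies with known ground truth, for tests and demos.

Generates one DICOM Part-10 file (uncompressed explicit-VR little-endian)
per (slice, volume, echo) with consistent UIDs, slice positions along a
chosen normal, deterministic 16-bit gradient pixel patterns and the timing
tags the pipeline consumes. The accompanying ground-truth record stores the
exact voxel-to-RAS affine, dimensions, file counts and the BIDS paths the
ReproIn convention implies, so every stage of the pipeline can be checked
against construction. Generated studies use a reserved fake UID root so they
can never be mistaken for real data.
"""

from __future__ import annotations

import datetime as dt
import shutil
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .config import ENTITY_ORDER

#: Reserved fake UID root; never a registered organization root.
FAKE_UID_ROOT = "1.3.6.1.4.1.99999"

MR_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.4"

CORRUPTION_MODES = (
    "drop_slice",
    "duplicate_instance",
    "scramble_orientation",
    "nonuniform_spacing",
)


@dataclass(frozen=True)
class SeriesFixture:
    """One synthetic series: a ReproIn-style name plus geometry and timing."""

    reproin_name: str
    dim3: int = 3  # slices per volume
    dim4: int = 1  # volumes per echo
    n_echoes: int = 1
    tr_ms: float | None = 2000.0
    te_ms: tuple[float, ...] = (30.0,)
    orientation: str | np.ndarray = "axial"  # "axial", "random", or a 3x3 rotation
    pixel_spacing: tuple[float, float] = (2.0, 2.0)  # (row, col) mm
    slice_spacing: float = 2.5
    origin: tuple[float, float, float] = (-80.0, -90.0, -60.0)
    rows: int = 8
    columns: int = 6
    image_type: tuple[str, ...] = ("ORIGINAL", "PRIMARY", "M")
    flip_angle: float = 77.0

    def __post_init__(self) -> None:
        if min(self.dim3, self.dim4, self.n_echoes) < 1:
            raise ValueError("all dimensions must be >= 1")
        if len(self.te_ms) != self.n_echoes:
            raise ValueError("te_ms must list one echo time per echo")


@dataclass(frozen=True)
class StudyFixture:
    """A synthetic study: subject/session ids, a locator-style description, series."""

    subject_id: str = "sid01"
    session: str | None = None
    study_description: str = "Patterson^Coben"
    series: tuple[SeriesFixture, ...] = ()
    base_datetime: dt.datetime = dt.datetime(2023, 1, 15, 9, 30, 0)


@dataclass(frozen=True)
class FixtureSpec:
    """Top-level generator spec: one study per subject, deterministic via seed."""

    studies: tuple[StudyFixture, ...]
    seed: int = 0


@dataclass(frozen=True)
class SeriesTruth:
    series_number: int
    reproin_name: str
    series_instance_uid: str
    dims: tuple[int, int, int, int]  # (dim1=cols, dim2=rows, dim3, dim4)
    n_echoes: int
    n_files: int
    affine_ras: np.ndarray
    expected_bids_paths: tuple[str, ...]
    voxel_sum: int


@dataclass(frozen=True)
class StudyTruth:
    study_instance_uid: str
    subject_id: str
    session: str | None
    locator: str
    series: tuple[SeriesTruth, ...]

    @property
    def n_files(self) -> int:
        return sum(s.n_files for s in self.series)


@dataclass(frozen=True)
class GroundTruth:
    studies: tuple[StudyTruth, ...]

    @property
    def n_files(self) -> int:
        return sum(s.n_files for s in self.studies)


def _rotation(orientation: str | np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if isinstance(orientation, np.ndarray):
        R = np.asarray(orientation, float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("orientation must be a 3x3 rotation matrix")
        return R
    if orientation == "axial":
        return np.eye(3)
    if orientation == "random":
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 2] *= -1
        return q
    raise ValueError(f"unknown orientation {orientation!r}")


def _truth_affine(
    R: np.ndarray, spec: SeriesFixture
) -> np.ndarray:
    lps = np.eye(4)
    lps[:3, 0] = R[:, 0] * spec.pixel_spacing[1]
    lps[:3, 1] = R[:, 1] * spec.pixel_spacing[0]
    lps[:3, 2] = R[:, 2] * spec.slice_spacing
    lps[:3, 3] = np.asarray(spec.origin, float)
    return np.diag([-1.0, -1.0, 1.0, 1.0]) @ lps


def _expected_bids_paths(
    name: str, subject: str, session: str | None, n_echoes: int
) -> tuple[str, ...]:
    """BIDS paths the ReproIn convention implies for a canonical fixture name.

    Fixture names must already be canonical (entities in order, explicit
    suffix except bare ``func``); this mirror of the convention is kept
    deliberately simple.
    """
    sbref = name.endswith("_SBRef")
    if sbref:
        name = name[: -len("_SBRef")]
    tokens = name.split("_")
    datatype, _, suffix = tokens[0].partition("-")
    if not suffix:
        suffix = {"func": "bold"}.get(datatype, "")
    if sbref:
        suffix = "sbref"
    entities = [t for t in tokens[1:] if t.split("-")[0] in ENTITY_ORDER]
    base = [f"sub-{subject}"]
    if session:
        base.append(f"ses-{session}")
    paths = []
    for echo in range(1, n_echoes + 1):
        parts = list(base) + list(entities)
        if n_echoes > 1:
            parts.append(f"echo-{echo}")
        parts.append(suffix)
        prefix = f"sub-{subject}" + (f"/ses-{session}" if session else "")
        paths.append(f"{prefix}/{datatype}/" + "_".join(parts) + ".nii.gz")
    return tuple(paths)


def _pixels(rng_offset: int, rows: int, cols: int, k: int, v: int, e: int) -> np.ndarray:
    grid = np.arange(rows)[:, None] * 3 + np.arange(cols)[None, :]
    return ((grid + 17 * k + 7 * v + 29 * e + rng_offset) % 997).astype(np.uint16)


def _write_file(
    path: Path,
    *,
    study: StudyFixture,
    spec: SeriesFixture,
    uids: dict,
    series_number: int,
    instance_number: int,
    acq_number: int,
    echo_idx: int,
    position: np.ndarray,
    R: np.ndarray,
    pixels: np.ndarray,
    acq_dt: dt.datetime,
) -> None:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = MR_IMAGE_STORAGE
    meta.MediaStorageSOPInstanceUID = uids["sop"]
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = MR_IMAGE_STORAGE
    ds.SOPInstanceUID = uids["sop"]
    ds.StudyInstanceUID = uids["study"]
    ds.SeriesInstanceUID = uids["series"]
    ds.SeriesNumber = series_number
    ds.InstanceNumber = instance_number
    ds.AcquisitionNumber = acq_number
    ds.Modality = "MR"
    ds.Manufacturer = "SyntheticScanner"
    ds.StudyDescription = study.study_description
    ds.ReferringPhysicianName = study.study_description
    ds.SeriesDescription = spec.reproin_name
    ds.ProtocolName = spec.reproin_name
    ds.SequenceName = "synth"
    ds.PatientID = study.subject_id
    ds.PatientName = study.subject_id
    ds.StudyDate = study.base_datetime.strftime("%Y%m%d")
    ds.StudyTime = study.base_datetime.strftime("%H%M%S")
    ds.AcquisitionDateTime = acq_dt.strftime("%Y%m%d%H%M%S")
    ds.ImageType = list(spec.image_type)
    if spec.tr_ms is not None:
        ds.RepetitionTime = spec.tr_ms
    ds.EchoTime = spec.te_ms[echo_idx]
    ds.EchoNumbers = echo_idx + 1
    ds.FlipAngle = spec.flip_angle
    ds.ImageOrientationPatient = [float(x) for x in np.concatenate([R[:, 0], R[:, 1]])]
    ds.ImagePositionPatient = [float(x) for x in position]
    ds.PixelSpacing = [float(spec.pixel_spacing[0]), float(spec.pixel_spacing[1])]
    ds.SpacingBetweenSlices = float(spec.slice_spacing)
    ds.SliceThickness = float(spec.slice_spacing)
    ds.Rows, ds.Columns = spec.rows, spec.columns
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)


def generate_study(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[Path, GroundTruth]:
    """Write the synthetic studies to *out_dir* and return the ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    studies: list[StudyTruth] = []
    for study_idx, study in enumerate(spec.studies, start=1):
        study_uid = f"{FAKE_UID_ROOT}.{spec.seed % 100000}.{study_idx}"
        series_truths: list[SeriesTruth] = []
        for series_idx, series in enumerate(study.series, start=1):
            R = _rotation(series.orientation, rng)
            rng_offset = int(rng.integers(0, 500))
            series_uid = f"{study_uid}.{series_idx}"
            normal = R[:, 2]
            origin = np.asarray(series.origin, float)
            instance = 0
            voxel_sum = 0
            series_dir = out_dir / f"study{study_idx:02d}" / f"series{series_idx:02d}"
            series_dir.mkdir(parents=True, exist_ok=True)
            for v in range(series.dim4):
                for k in range(series.dim3):
                    for e in range(series.n_echoes):
                        instance += 1
                        pixels = _pixels(
                            rng_offset, series.rows, series.columns, k, v, e
                        )
                        voxel_sum += int(pixels.sum(dtype=np.int64))
                        position = origin + k * series.slice_spacing * normal
                        acq_dt = study.base_datetime + dt.timedelta(
                            minutes=5 * series_idx, seconds=2 * v
                        )
                        _write_file(
                            series_dir / f"{instance:05d}.dcm",
                            study=study,
                            spec=series,
                            uids={
                                "study": study_uid,
                                "series": series_uid,
                                "sop": f"{series_uid}.{instance}",
                            },
                            series_number=series_idx,
                            instance_number=instance,
                            acq_number=v + 1,
                            echo_idx=e,
                            position=position,
                            R=R,
                            pixels=pixels,
                            acq_dt=acq_dt,
                        )
            n_files = series.dim3 * series.dim4 * series.n_echoes
            series_truths.append(
                SeriesTruth(
                    series_number=series_idx,
                    reproin_name=series.reproin_name,
                    series_instance_uid=series_uid,
                    dims=(series.columns, series.rows, series.dim3, series.dim4),
                    n_echoes=series.n_echoes,
                    n_files=n_files,
                    affine_ras=_truth_affine(R, series),
                    expected_bids_paths=_expected_bids_paths(
                        series.reproin_name,
                        study.subject_id,
                        study.session,
                        series.n_echoes,
                    ),
                    voxel_sum=voxel_sum,
                )
            )
        studies.append(
            StudyTruth(
                study_instance_uid=study_uid,
                subject_id=study.subject_id,
                session=study.session,
                locator=study.study_description.replace("^", "/"),
                series=tuple(series_truths),
            )
        )
    return out_dir, GroundTruth(tuple(studies))


def zip_study(study_dir: str | Path, zip_path: str | Path) -> Path:
    """Pack a generated study into a zip archive (to exercise archive ingestion)."""
    study_dir, zip_path = Path(study_dir), Path(zip_path)
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for f in sorted(study_dir.rglob("*")):
            if f.is_file():
                zf.write(f, f.relative_to(study_dir))
    return zip_path


def corrupt_study(directory: str | Path, mode: str) -> Path:
    """Apply exactly one corruption to a generated study (error-branch fixture)."""
    directory = Path(directory)
    if mode not in CORRUPTION_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}; choose {CORRUPTION_MODES}")
    files = sorted(directory.rglob("*.dcm"))
    if len(files) < 3:
        raise ValueError("study too small to corrupt meaningfully")
    target = files[1]  # second slice of the first series
    if mode == "drop_slice":
        target.unlink()
    elif mode == "duplicate_instance":
        shutil.copy(target, target.with_name("dup_" + target.name))
    elif mode == "scramble_orientation":
        ds = pydicom.dcmread(target)
        ds.ImageOrientationPatient = [0.0, 1.0, 0.0, 1.0, 0.0, 0.0]
        ds.save_as(target, enforce_file_format=True)
    elif mode == "nonuniform_spacing":
        ds = pydicom.dcmread(target)
        iop = np.asarray([float(x) for x in ds.ImageOrientationPatient])
        normal = np.cross(iop[:3], iop[3:])
        pos = np.asarray([float(x) for x in ds.ImagePositionPatient])
        ds.ImagePositionPatient = [float(x) for x in pos + 0.3 * normal]
        ds.save_as(target, enforce_file_format=True)
    return directory
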
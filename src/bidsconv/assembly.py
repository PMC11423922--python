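"""Stack one series' DICOM slices into NIfTI volumes with a correct RAS affine.

DICOM stores geometry in the LPS patient frame (ImageOrientationPatient row
and column direction cosines, ImagePositionPatient of the first pixel);
NIfTI wants a voxel-to-RAS affine. The conversion negates the first two
axes. Multi-echo acquisitions are split into one output volume per echo,
tagged with the echo index for the ``_echo-<n>`` filename entity.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .config import POSITION_TOL, SOFTWARE_NAME, SPACING_WARN_REL
from .dicom_io import DicomHeader, load_pixel_array
from .errors import AssemblyError, CollisionError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VolumeGeometry:
    """Slice orientation/position/spacing and the derived voxel-to-RAS affine."""

    row_cosine: tuple[float, float, float]
    col_cosine: tuple[float, float, float]
    slice_normal: tuple[float, float, float]
    first_position: tuple[float, float, float]
    pixel_spacing_row: float
    pixel_spacing_col: float
    slice_spacing: float
    affine_ras: np.ndarray
    nonuniform_spacing: bool = False


def slice_normal(orientation: tuple[float, ...]) -> np.ndarray:
    """Right-handed slice normal (row x col) from ImageOrientationPatient."""
    iop = np.asarray(orientation, float)
    return np.cross(iop[:3], iop[3:])


def sort_slices(
    headers: list[DicomHeader],
) -> tuple[list[DicomHeader], float, bool]:
    """Order one volume's slices along the slice normal.

    Returns the ordered headers, the slice spacing (median of consecutive
    position differences; SpacingBetweenSlices or 1.0 for a single slice) and
    a flag set when spacing deviates by more than 1% from uniform.
    """
    if not headers:
        raise AssemblyError("cannot sort an empty slice list")
    uids = {h.series_instance_uid for h in headers}
    if len(uids) != 1:
        raise AssemblyError(f"slices from multiple series: {sorted(uids)}")
    for h in headers:
        if h.image_orientation_patient is None or h.image_position_patient is None:
            raise AssemblyError(f"missing geometry tags in {h.file_path}")
    iop0 = np.asarray(headers[0].image_orientation_patient, float)
    for h in headers[1:]:
        if np.abs(np.asarray(h.image_orientation_patient) - iop0).max() > 1e-4:
            raise AssemblyError(
                f"inconsistent slice orientation within series at {h.file_path}"
            )
    normal = slice_normal(headers[0].image_orientation_patient)
    ordered = sorted(
        headers,
        key=lambda h: (
            float(np.dot(np.asarray(h.image_position_patient, float), normal)),
            h.instance_number,
        ),
    )
    proj = np.array(
        [
            float(np.dot(np.asarray(h.image_position_patient, float), normal))
            for h in ordered
        ]
    )
    # collapse repeated positions (multiple volumes share each slice location)
    unique = [proj[0]]
    for p in proj[1:]:
        if p - unique[-1] > POSITION_TOL:
            unique.append(p)
    warn = False
    if len(unique) == 1:
        h = ordered[0]
        if h.spacing_between_slices is not None:
            spacing = float(h.spacing_between_slices)
        else:
            spacing = 1.0
            warn = True
            log.warning(
                "single slice position without SpacingBetweenSlices; assuming 1 mm"
            )
        return ordered, spacing, warn
    diffs = np.diff(np.array(unique))
    spacing = float(np.median(diffs))
    if spacing <= 0:
        raise AssemblyError("degenerate slice positions (zero spacing)")
    if np.any(np.abs(diffs - spacing) > SPACING_WARN_REL * spacing):
        warn = True
        log.warning(
            "non-uniform slice spacing in series %s (median %.4f mm)",
            headers[0].series_instance_uid,
            spacing,
        )
    return ordered, spacing, warn


def build_affine(
    orientation: tuple[float, ...],
    first_position: tuple[float, ...],
    pixel_spacing: tuple[float, float],
    slice_spacing: float,
) -> np.ndarray:
    """Voxel-to-RAS affine from DICOM LPS geometry.

    The 3x3 block's columns are (row_cosine * column spacing,
    col_cosine * row spacing, normal * slice spacing) in LPS; the first two
    rows and the translation's first two components are negated for RAS.
    PixelSpacing is (row spacing, column spacing) per the DICOM convention.
    """
    iop = np.asarray(orientation, float)
    row_cos, col_cos = iop[:3], iop[3:]
    normal = np.cross(row_cos, col_cos)
    spacing_row, spacing_col = float(pixel_spacing[0]), float(pixel_spacing[1])
    lps = np.eye(4)
    lps[:3, 0] = row_cos * spacing_col
    lps[:3, 1] = col_cos * spacing_row
    lps[:3, 2] = normal * float(slice_spacing)
    lps[:3, 3] = np.asarray(first_position, float)
    if abs(np.linalg.det(lps[:3, :3])) < 1e-12:
        raise AssemblyError("singular orientation block")
    flip = np.diag([-1.0, -1.0, 1.0, 1.0])
    return flip @ lps


@dataclass(frozen=True)
class AssembledVolume:
    """One output volume: data array, geometry, sidecar, optional echo index."""

    data: np.ndarray  # (dim1, dim2, dim3) or (dim1, dim2, dim3, dim4)
    geometry: VolumeGeometry
    sidecar: dict
    echo_index: int | None = None

    @property
    def n_files(self) -> int:
        shape = self.data.shape
        return shape[2] * (shape[3] if len(shape) == 4 else 1)


def _position_key(h: DicomHeader, normal: np.ndarray) -> float:
    return float(np.dot(np.asarray(h.image_position_patient, float), normal))


def _base_sidecar(h: DicomHeader) -> dict:
    sidecar: dict = {
        "ConversionSoftware": SOFTWARE_NAME,
        "ConversionSoftwareVersion": __version__,
        "ImageType": list(h.image_type),
        "ProtocolName": h.protocol_name,
        "SeriesDescription": h.series_description,
    }
    if h.manufacturer:
        sidecar["Manufacturer"] = h.manufacturer
    if h.repetition_time is not None:
        sidecar["RepetitionTime"] = h.repetition_time / 1000.0
    if h.echo_time is not None:
        sidecar["EchoTime"] = h.echo_time / 1000.0
    if h.flip_angle is not None:
        sidecar["FlipAngle"] = h.flip_angle
    return sidecar


def assemble_series(headers: list[DicomHeader]) -> list[AssembledVolume]:
    """Convert one series' files into one output volume per echo.

    Slices are grouped per (echo, volume); volumes are ordered by
    acquisition number then instance number; the voxel array is stored with
    rescale slope/intercept applied (promoting to float32 when nontrivial).
    A single-volume series yields a 3-D array; otherwise 4-D
    (dim1, dim2, dim3, dim4).
    """
    if not headers:
        raise AssemblyError("no files in series")
    echoes = sorted(
        {h.echo_number for h in headers}, key=lambda e: (e is None, e)
    )
    multi_echo = len(echoes) > 1
    outputs: list[AssembledVolume] = []
    for echo_index, echo in enumerate(echoes, start=1):
        echo_headers = [h for h in headers if h.echo_number == echo]
        outputs.append(
            _assemble_one_echo(
                echo_headers,
                echo_index=echo_index if multi_echo else None,
                multi_echo=multi_echo,
            )
        )
    return outputs


def _assemble_one_echo(
    headers: list[DicomHeader], echo_index: int | None, multi_echo: bool
) -> AssembledVolume:
    ordered, spacing, warn = sort_slices(headers)
    normal = slice_normal(ordered[0].image_orientation_patient)

    # bucket by distinct position along the normal
    buckets: list[list[DicomHeader]] = []
    keys: list[float] = []
    for h in ordered:
        key = _position_key(h, normal)
        if keys and key - keys[-1] <= POSITION_TOL:
            buckets[-1].append(h)
        else:
            buckets.append([h])
            keys.append(key)
    n_slices = len(buckets)
    n_volumes = max(len(b) for b in buckets)
    missing = [
        (round(keys[i], 4), len(b))
        for i, b in enumerate(buckets)
        if len(b) != n_volumes
    ]
    if missing:
        raise AssemblyError(
            "incomplete slice grid; positions with missing volumes "
            f"(position, files found; expected {n_volumes}): {missing}"
        )
    for b in buckets:
        b.sort(key=lambda h: (h.acquisition_number or 0, h.instance_number))

    first = buckets[0][0]
    cols, rows = first.columns, first.rows
    slope, intercept = first.rescale_slope, first.rescale_intercept
    rescale = slope != 1.0 or intercept != 0.0

    sample = load_pixel_array(first.file_path)
    dtype = np.float32 if rescale else sample.dtype
    data = np.empty((cols, rows, n_slices, n_volumes), dtype=dtype)
    for k, bucket in enumerate(buckets):
        for v, h in enumerate(bucket):
            plane = load_pixel_array(h.file_path)
            if plane.shape != (rows, cols):
                raise AssemblyError(
                    f"pixel array shape {plane.shape} != ({rows}, {cols}) "
                    f"in {h.file_path}"
                )
            if rescale:
                plane = plane.astype(np.float32) * slope + intercept
            data[:, :, k, v] = plane.T

    iop = np.asarray(first.image_orientation_patient, float)
    affine = build_affine(
        first.image_orientation_patient,
        buckets[0][0].image_position_patient,
        first.pixel_spacing,
        spacing,
    )
    geometry = VolumeGeometry(
        row_cosine=tuple(iop[:3]),
        col_cosine=tuple(iop[3:]),
        slice_normal=tuple(np.cross(iop[:3], iop[3:])),
        first_position=tuple(first.image_position_patient),
        pixel_spacing_row=float(first.pixel_spacing[0]),
        pixel_spacing_col=float(first.pixel_spacing[1]),
        slice_spacing=spacing,
        affine_ras=affine,
        nonuniform_spacing=warn,
    )
    sidecar = _base_sidecar(first)
    if multi_echo and first.echo_number is not None:
        sidecar["EchoNumber"] = first.echo_number
    if n_volumes == 1:
        data = data[:, :, :, 0]
    return AssembledVolume(data, geometry, sidecar, echo_index)


def _write_bytes(payload: bytes, out_path: Path, overwrite: bool) -> Path:
    """Write bytes honoring the collision policy: identical content is a no-op."""
    if out_path.exists():
        if out_path.read_bytes() == payload:
            return out_path
        if not overwrite:
            raise CollisionError(
                f"{out_path} exists with different content (use --overwrite)"
            )
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_bytes(payload)
    return out_path


def write_nifti(
    data: np.ndarray,
    geometry: VolumeGeometry,
    out_path: str | Path,
    overwrite: bool = False,
) -> Path:
    """Write a gzip-compressed NIfTI-1 file with sform=qform='aligned'.

    Compression is done with a fixed zero mtime so repeated runs produce
    byte-identical files.
    """
    img = nib.Nifti1Image(data, geometry.affine_ras)
    img.header.set_sform(geometry.affine_ras, code="aligned")
    img.header.set_qform(geometry.affine_ras, code="aligned")
    payload = gzip.compress(img.to_bytes(), mtime=0)
    return _write_bytes(payload, Path(out_path), overwrite)


def write_sidecar(
    metadata: dict, out_path: str | Path, overwrite: bool = False
) -> Path:
    """Write a sidecar as canonical JSON (sorted keys, 2-space indent)."""
    payload = (json.dumps(metadata, sort_keys=True, indent=2) + "\n").encode("utf-8")
    return _write_bytes(payload, Path(out_path), overwrite)
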
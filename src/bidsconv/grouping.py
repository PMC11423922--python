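"""Group DICOM headers into studies/series and build the per-series summary table.

The summary table ("seqinfo") is the sole view of the data that naming
heuristics see: one row per series with dimensions, timing, descriptions and
quality flags. Multi-echo series remain one row (echo splitting happens at
assembly) so heuristics see one acquisition.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import POSITION_TOL
from .dicom_io import DicomHeader

log = logging.getLogger(__name__)

SEQINFO_FIELDS = (
    "series_id",
    "series_instance_uid",
    "example_file",
    "total_files_till_now",
    "dim1",
    "dim2",
    "dim3",
    "dim4",
    "TR",
    "TE",
    "protocol_name",
    "series_description",
    "sequence_name",
    "image_type",
    "is_motion_corrected",
    "is_derived",
    "patient_id",
    "study_description",
    "referring_physician_name",
    "date",
)


@dataclass(frozen=True)
class SeqInfo:
    """One row of the series summary table consumed by heuristics.

    ``TR`` is in seconds and ``TE`` in milliseconds, both -1 when the tag is
    absent; ``dim1``/``dim2`` are in-plane (columns/rows), ``dim3`` slices per
    volume, ``dim4`` volumes per echo.
    """

    series_id: str
    series_instance_uid: str
    example_file: Path
    total_files_till_now: int
    dim1: int
    dim2: int
    dim3: int
    dim4: int
    TR: float
    TE: float
    protocol_name: str
    series_description: str
    sequence_name: str
    image_type: tuple[str, ...]
    is_motion_corrected: bool
    is_derived: bool
    patient_id: str
    study_description: str
    referring_physician_name: str
    date: dt.date | None = None
    n_files: int = 0
    n_echoes: int = 1
    series_files: tuple[Path, ...] = field(default=(), repr=False)


def detect_flags(image_type: tuple[str, ...] | list[str]) -> tuple[bool, bool]:
    """Classify a series from its ImageType tokens.

    Motion-corrected series carry the "MOCO" token; derived series carry
    "DERIVED" without "PRIMARY" (derived-primary reconstructions are kept).
    """
    tokens = set(image_type)
    is_moco = "MOCO" in tokens
    is_derived = "DERIVED" in tokens and "PRIMARY" not in tokens
    return is_moco, is_derived


def _dedupe(headers: list[DicomHeader]) -> list[DicomHeader]:
    """Drop duplicate instances; the lexicographically smallest path wins."""
    by_key: dict[tuple, DicomHeader] = {}
    for h in sorted(headers, key=lambda h: str(h.file_path)):
        key = (h.series_instance_uid, h.instance_number, h.echo_number)
        if key in by_key:
            log.warning(
                "duplicate instance %s (series %s): ignoring %s",
                h.instance_number,
                h.series_instance_uid,
                h.file_path,
            )
            continue
        by_key[key] = h
    return list(by_key.values())


def _count_positions(headers: list[DicomHeader]) -> int:
    """Distinct spatial positions, as projections onto the slice normal."""
    with_geom = [
        h
        for h in headers
        if h.image_position_patient is not None
        and h.image_orientation_patient is not None
    ]
    if not with_geom:
        return 1
    iop = np.asarray(with_geom[0].image_orientation_patient, float)
    normal = np.cross(iop[:3], iop[3:])
    projections = sorted(
        float(np.dot(np.asarray(h.image_position_patient, float), normal))
        for h in with_geom
    )
    count = 1
    for prev, cur in zip(projections, projections[1:]):
        if cur - prev > POSITION_TOL:
            count += 1
    return count


def _series_seqinfo(
    headers: list[DicomHeader], total_before: int
) -> SeqInfo:
    first = min(headers, key=lambda h: (h.instance_number, str(h.file_path)))
    n_files = len(headers)
    dim3 = _count_positions(headers)
    echoes = {h.echo_number for h in headers}
    n_echoes = max(1, len(echoes))
    dim4 = max(1, n_files // (dim3 * n_echoes))
    is_moco, is_derived = detect_flags(first.image_type)
    return SeqInfo(
        series_id=f"{first.series_number}-{first.protocol_name}",
        series_instance_uid=first.series_instance_uid,
        example_file=first.file_path,
        total_files_till_now=total_before + n_files,
        dim1=first.columns,
        dim2=first.rows,
        dim3=dim3,
        dim4=dim4,
        TR=first.repetition_time / 1000.0 if first.repetition_time is not None else -1,
        TE=first.echo_time if first.echo_time is not None else -1,
        protocol_name=first.protocol_name,
        series_description=first.series_description,
        sequence_name=first.sequence_name or "",
        image_type=first.image_type,
        is_motion_corrected=is_moco,
        is_derived=is_derived,
        patient_id=first.patient_id or "",
        study_description=first.study_description or "",
        referring_physician_name=first.referring_physician_name or "",
        date=first.study_date,
        n_files=n_files,
        n_echoes=n_echoes,
        series_files=tuple(
            sorted((h.file_path for h in headers), key=str)
        ),
    )


def group_series(headers: list[DicomHeader]) -> dict[str, list[SeqInfo]]:
    """Group headers by (study, series) UIDs into ordered seqinfo tables.

    Series within a study are ordered by (series_number, series_instance_uid);
    the result is invariant under permutation of the input list. Duplicate
    instances (same series UID, instance number and echo number) are dropped
    with a warning.
    """
    headers = _dedupe(list(headers))
    studies: dict[str, dict[str, list[DicomHeader]]] = {}
    for h in headers:
        studies.setdefault(h.study_instance_uid, {}).setdefault(
            h.series_instance_uid, []
        ).append(h)

    result: dict[str, list[SeqInfo]] = {}
    for study_uid in sorted(studies):
        series_lists = sorted(
            studies[study_uid].values(),
            key=lambda hs: (hs[0].series_number, hs[0].series_instance_uid),
        )
        rows: list[SeqInfo] = []
        total = 0
        for series_headers in series_lists:
            info = _series_seqinfo(series_headers, total)
            total = info.total_files_till_now
            rows.append(info)
        result[study_uid] = rows
    return result


def seqinfo_table(
    seqinfos: list[SeqInfo], relative_to: Path | None = None
) -> pd.DataFrame:
    """Render seqinfo rows as a DataFrame in the canonical field order.

    *relative_to* relativizes example paths so dumps of the same input are
    identical regardless of where the output tree lives.
    """
    records = []
    for s in seqinfos:
        rec = {name: getattr(s, name) for name in SEQINFO_FIELDS}
        rec["image_type"] = ",".join(s.image_type)
        example = s.example_file
        if relative_to is not None:
            try:
                example = example.resolve().relative_to(Path(relative_to).resolve())
            except ValueError:
                pass
        rec["example_file"] = str(example)
        rec["date"] = s.date.isoformat() if s.date else "n/a"
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=list(SEQINFO_FIELDS))


def write_seqinfo_tsv(
    seqinfos: list[SeqInfo], path: str | Path, relative_to: Path | None = None
) -> Path:
    """Dump the seqinfo table as TSV for operator inspection during discovery."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    seqinfo_table(seqinfos, relative_to=relative_to).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
    return path
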
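"""Render conversion-plan entries into a BIDS hierarchy and populate dataset files.

Covers path rendering from output templates, the dataset-level files BIDS
requires (dataset_description.json, participants.tsv, per-session scans.tsv,
README) and a naming validator for the subset of the BIDS grammar this
package emits. All writes are idempotent: re-running over unchanged input
produces byte-identical files.
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass
from pathlib import Path

from .config import BIDS_VERSION, ENTITY_ORDER
from .errors import CollisionError, TemplateError, ValidationError
from .heuristics import OutputTemplate

_FORMATTER = string.Formatter()

#: Suffixes this tool can emit, per datatype directory.
DATATYPE_SUFFIXES = {
    "anat": {"T1w", "T2w", "T2starw", "FLAIR", "PDw", "UNIT1"},
    "func": {"bold", "sbref"},
    "dwi": {"dwi", "sbref"},
    "fmap": {"epi", "magnitude", "magnitude1", "magnitude2", "phasediff", "fieldmap"},
}

#: Suffixes that require a task entity.
TASK_REQUIRED = {("func", "bold"), ("func", "sbref")}

_LABEL = r"[A-Za-z0-9]+"
_FILENAME_RE = re.compile(
    rf"^sub-(?P<sub>{_LABEL})(?:_ses-(?P<ses>{_LABEL}))?"
    rf"(?P<entities>(?:_[a-z]+-{_LABEL})*)"
    rf"_(?P<suffix>[A-Za-z0-9]+)\.(?P<ext>nii\.gz|nii|json)$"
)


def render_path(
    template: OutputTemplate,
    subject: str,
    session: str | None,
    item: int,
    extension: str,
) -> Path:
    """Substitute {subject}/{session}/{item} in a template and add an extension."""
    needed = template.placeholder_names()
    values: dict[str, object] = {"subject": subject, "item": item}
    if "session" in needed:
        if session is None:
            raise TemplateError(
                f"template needs {{session}} but no session is defined: "
                f"{template.template!r}"
            )
        values["session"] = session
    unknown = needed - {"subject", "session", "item"}
    if unknown:
        raise TemplateError(
            f"unresolved placeholders {sorted(unknown)} in {template.template!r}"
        )
    rendered = template.template.format(**values)
    if not extension.startswith("."):
        extension = "." + extension
    return Path(rendered + extension)


def add_entity(filename: str, key: str, value: str) -> str:
    """Insert a ``key-value`` entity into a rendered basename at its fixed slot."""
    if key not in ENTITY_ORDER:
        raise ValidationError(f"unknown entity key {key!r}")
    stem, _, suffix_ext = filename.rpartition("_")
    parts = stem.split("_")
    slot = ENTITY_ORDER.index(key)
    insert_at = len(parts)
    for i, part in enumerate(parts):
        k = part.split("-", 1)[0]
        if k in ENTITY_ORDER and ENTITY_ORDER.index(k) > slot:
            insert_at = i
            break
    parts.insert(insert_at, f"{key}-{value}")
    return "_".join(parts) + "_" + suffix_ext


@dataclass(frozen=True)
class ConvertedEntry:
    """Record of one data file written into the tree (for table population)."""

    subject: str
    session: str | None
    rel_path: str  # relative to the dataset root, POSIX separators
    acq_time: str | None = None  # ISO 8601 seconds precision, or None


def _write_idempotent(path: Path, payload: bytes, merge_ok: bool = True) -> bool:
    if path.exists() and path.read_bytes() == payload:
        return False
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_bytes(payload)
    return True


def _tsv(rows: list[list[str]], header: list[str]) -> bytes:
    lines = ["\t".join(header)]
    lines += ["\t".join(cell if cell else "n/a" for cell in row) for row in rows]
    return ("\n".join(lines) + "\n").encode("utf-8")


def _read_tsv(path: Path) -> tuple[list[str], list[list[str]]]:
    lines = path.read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    return header, [line.split("\t") for line in lines[1:] if line]


def _merge_table(
    path: Path, header: list[str], new_rows: dict[str, list[str]]
) -> bytes:
    """Merge keyed rows into an existing TSV; conflicting rows are an error."""
    rows: dict[str, list[str]] = {}
    if path.exists():
        old_header, old_rows = _read_tsv(path)
        if old_header != header:
            raise ValidationError(f"{path}: existing header differs: {old_header}")
        for row in old_rows:
            rows[row[0]] = row
    for key, row in new_rows.items():
        if key in rows and rows[key] != row:
            raise ValidationError(
                f"{path}: conflicting row for {key!r}: {rows[key]} vs {row}"
            )
        rows[key] = row
    return _tsv([rows[k] for k in sorted(rows)], header)


def populate_dataset_files(
    root: str | Path,
    converted: list[ConvertedEntry],
    dataset_name: str | None = None,
) -> list[Path]:
    """Write/refresh dataset_description.json, participants.tsv, scans.tsv, README.

    Re-running over unchanged input is a byte-level no-op; new subjects are
    merged into existing tables in sorted order.
    """
    if not converted:
        raise ValidationError("no converted entries; nothing to populate")
    root = Path(root)
    written: list[Path] = []

    desc = {
        "Name": dataset_name or root.name,
        "BIDSVersion": BIDS_VERSION,
        "DatasetType": "raw",
    }
    desc_path = root / "dataset_description.json"
    payload = (json.dumps(desc, sort_keys=True, indent=2) + "\n").encode()
    if desc_path.exists() and desc_path.read_bytes() != payload:
        existing = json.loads(desc_path.read_text())
        if existing.get("Name") == desc["Name"]:
            payload = desc_path.read_bytes()  # keep operator edits beyond Name
    if _write_idempotent(desc_path, payload):
        written.append(desc_path)

    participants = {
        f"sub-{e.subject}": [f"sub-{e.subject}"] for e in converted
    }
    ppath = root / "participants.tsv"
    if _write_idempotent(ppath, _merge_table(ppath, ["participant_id"], participants)):
        written.append(ppath)

    by_session: dict[tuple[str, str | None], dict[str, list[str]]] = {}
    for e in converted:
        sub_dir = f"sub-{e.subject}"
        prefix = sub_dir + (f"/ses-{e.session}" if e.session else "")
        rel = e.rel_path
        if rel.startswith(prefix + "/"):
            rel = rel[len(prefix) + 1 :]
        by_session.setdefault((e.subject, e.session), {})[rel] = [
            rel,
            e.acq_time or "n/a",
        ]
    for (subject, session), rows in by_session.items():
        base = root / f"sub-{subject}"
        name = f"sub-{subject}"
        if session:
            base = base / f"ses-{session}"
            name += f"_ses-{session}"
        spath = base / f"{name}_scans.tsv"
        if _write_idempotent(
            spath, _merge_table(spath, ["filename", "acq_time"], rows)
        ):
            written.append(spath)

    readme = root / "README"
    text = (
        f"{desc['Name']}\n\nThis dataset was converted from DICOM with "
        f"bidsconv. See derivatives and sidecar JSON files for acquisition "
        f"metadata.\n"
    )
    if _write_idempotent(readme, text.encode()):
        written.append(readme)
    return written


@dataclass(frozen=True)
class Violation:
    path: str
    rule: str
    detail: str


def _check_filename(rel: Path) -> list[Violation]:
    violations: list[Violation] = []
    name = rel.name
    parts = rel.parts
    datatype = parts[-2] if len(parts) >= 2 else ""

    m = _FILENAME_RE.match(name)
    if not m:
        # distinguish entity-order problems from outright garbage
        tokens = name.split(".")[0].split("_")
        keys = [t.split("-", 1)[0] for t in tokens if "-" in t]
        entity_keys = [k for k in keys if k in ENTITY_ORDER]
        expected = [k for k in ENTITY_ORDER if k in entity_keys]
        if entity_keys != expected:
            violations.append(
                Violation(str(rel), "entity-order", f"found order {entity_keys}")
            )
        else:
            violations.append(
                Violation(str(rel), "filename-grammar", "does not match BIDS pattern")
            )
        return violations

    if not parts or not parts[0].startswith("sub-"):
        violations.append(
            Violation(str(rel), "location", "data file not under sub-<label>/")
        )
        return violations
    sub_label = parts[0][len("sub-") :]
    if m.group("sub") != sub_label:
        violations.append(
            Violation(str(rel), "subject-mismatch", f"{m.group('sub')} != {sub_label}")
        )
    ses_label = None
    rest = parts[1:]
    if rest and rest[0].startswith("ses-"):
        ses_label = rest[0][len("ses-") :]
        rest = rest[1:]
    if (m.group("ses") or None) != ses_label:
        violations.append(
            Violation(str(rel), "session-mismatch", f"{m.group('ses')} != {ses_label}")
        )

    entity_keys = [
        t.split("-", 1)[0] for t in m.group("entities").strip("_").split("_") if t
    ]
    expected = [k for k in ENTITY_ORDER if k in entity_keys]
    if entity_keys != expected:
        violations.append(
            Violation(str(rel), "entity-order", f"found order {entity_keys}")
        )
    unknown = [k for k in entity_keys if k not in ENTITY_ORDER]
    for k in unknown:
        violations.append(Violation(str(rel), "unknown-entity", k))

    suffix = m.group("suffix")
    if datatype in DATATYPE_SUFFIXES:
        if suffix not in DATATYPE_SUFFIXES[datatype]:
            violations.append(
                Violation(
                    str(rel),
                    "suffix-datatype",
                    f"suffix {suffix!r} not allowed under {datatype}/",
                )
            )
    else:
        violations.append(
            Violation(str(rel), "datatype", f"unknown datatype directory {datatype!r}")
        )
    if (datatype, suffix) in TASK_REQUIRED and "task" not in entity_keys:
        violations.append(
            Violation(str(rel), "missing-task", f"{suffix} requires a task entity")
        )
    return violations


def validate_names(root: str | Path) -> list[Violation]:
    """Check every data file under sub-*/ against the emitted BIDS grammar subset.

    Returns an empty list for a compliant tree; violations are values, never
    exceptions.
    """
    root = Path(root)
    violations: list[Violation] = []
    for path in sorted(root.glob("sub-*/**/*")):
        if not path.is_file():
            continue
        if path.name.endswith("_scans.tsv"):
            continue
        violations.extend(_check_filename(path.relative_to(root)))
    return violations
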
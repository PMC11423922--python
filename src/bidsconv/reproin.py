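"""The ReproIn naming convention: automatic BIDS naming from protocol names.

When scanner protocols are named ``<datatype>[-<suffix>][_<key>-<value>]...``
(e.g. ``func-bold_task-rest_run-01``), conversion needs no operator input:
the series name itself encodes the BIDS datatype, suffix and entities, the
study description encodes the dataset locator (``PI^experiment`` becomes the
``PI/experiment`` directory), and re-acquired series are marked with
``__dup<NN>`` so only the last acquisition is converted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .config import ENTITY_ORDER, RUN_PAD_WIDTH
from .errors import IdInferenceError
from .grouping import SeqInfo

log = logging.getLogger(__name__)

DATATYPES = ("anat", "func", "dwi", "fmap")

#: Default suffix per datatype when the protocol names only the datatype.
#: Only func has a stated default; everything else must be explicit.
DEFAULT_SUFFIX = {"func": "bold"}

#: Extension point for site-specific protocol-name fixups (old name -> new
#: name), applied verbatim before parsing. Shipped empty.
PROTOCOL_FIXUPS: dict[str, str] = {}

_DUP_RE = re.compile(r"__dup-?(\d+)$")
_SBREF_RE = re.compile(r"_SBRef$", re.IGNORECASE)
_SES_RE = re.compile(r"(?:^|[_^ ])ses-([A-Za-z0-9]+)")


@dataclass(frozen=True)
class BidsEntities:
    """A parsed series name: datatype, suffix and ordered BIDS entities."""

    datatype: str
    suffix: str
    entities: tuple[tuple[str, str], ...] = ()
    extra: tuple[tuple[str, str], ...] = ()
    dup: int | None = None

    def __post_init__(self) -> None:
        if self.datatype not in DATATYPES:
            raise ValueError(f"unknown datatype {self.datatype!r}")
        keys = [k for k, _ in self.entities]
        known = [k for k in ENTITY_ORDER if k in keys]
        if keys != known:
            raise ValueError(
                f"entities must follow the fixed order {ENTITY_ORDER}: {keys}"
            )

    def get(self, key: str) -> str | None:
        for k, v in self.entities:
            if k == key:
                return v
        return None

    def with_entity(self, key: str, value: str) -> "BidsEntities":
        """Return a copy with *key* set, keeping the fixed entity order."""
        items = dict(self.entities)
        items[key] = value
        ordered = tuple((k, items[k]) for k in ENTITY_ORDER if k in items)
        return BidsEntities(self.datatype, self.suffix, ordered, self.extra)


@dataclass(frozen=True)
class ParseRejection:
    """A series name that does not follow the convention (skipped, not fatal)."""

    raw: str
    reason: str


@dataclass(frozen=True)
class StudyIds:
    subject: str
    session: str | None = None
    locator: str | None = None

    def __post_init__(self) -> None:
        if not self.subject:
            raise ValueError("subject must be nonempty")
        if self.locator and ".." in self.locator.split("/"):
            raise ValueError("locator must not contain '..'")


def sanitize_label(raw: str) -> str:
    """Strip every character outside [A-Za-z0-9]; the result may be empty."""
    return re.sub(r"[^A-Za-z0-9]", "", raw)


def parse_series_spec(series_description: str) -> BidsEntities | ParseRejection:
    """Parse a protocol/series name into BIDS entities, or reject it.

    Grammar: ``<datatype>[-<suffix>][_<key>-<value>]...`` with datatype one of
    anat/func/dwi/fmap. A trailing ``_SBRef`` marker rewrites the suffix to
    ``sbref``; a trailing ``__dup<NN>`` marks a superseded re-acquisition.
    Unknown keys are preserved in ``extra`` with a warning.
    """
    raw = series_description.strip()
    raw = PROTOCOL_FIXUPS.get(raw, raw)
    if not raw:
        return ParseRejection(series_description, "empty series name")

    dup = None
    m = _DUP_RE.search(raw)
    if m:
        dup = int(m.group(1))
        raw = raw[: m.start()]

    sbref = bool(_SBREF_RE.search(raw))
    if sbref:
        raw = _SBREF_RE.sub("", raw)

    tokens = raw.split("_")
    head, _, suffix = tokens[0].partition("-")
    if head not in DATATYPES:
        return ParseRejection(series_description, f"no datatype prefix in {raw!r}")
    datatype = head
    if not suffix:
        if datatype not in DEFAULT_SUFFIX:
            return ParseRejection(
                series_description, f"{datatype!r} requires an explicit suffix"
            )
        suffix = DEFAULT_SUFFIX[datatype]

    entities: dict[str, str] = {}
    extra: list[tuple[str, str]] = []
    for token in tokens[1:]:
        if not token:
            continue
        key, sep, value = token.partition("-")
        value = sanitize_label(value)
        if sep and key in ENTITY_ORDER:
            entities[key] = value
        elif sep and key == "ses":
            extra.append((key, value))  # session is study-level; kept for inference
        else:
            log.warning("unknown token %r in series name %r", token, raw)
            extra.append((key, value))

    if sbref:
        suffix = "sbref"
    ordered = tuple((k, entities[k]) for k in ENTITY_ORDER if k in entities)
    return BidsEntities(datatype, suffix, ordered, tuple(extra), dup)


def render_series_spec(e: BidsEntities) -> str:
    """Render entities back to the protocol-name grammar (parse's inverse)."""
    parts = [f"{e.datatype}-{e.suffix}"]
    parts += [f"{k}-{v}" for k, v in e.entities]
    parts += [f"{k}-{v}" for k, v in e.extra]
    name = "_".join(parts)
    if e.dup is not None:
        name += f"__dup{e.dup:02d}"
    return name


def infer_study_ids(seqinfo: list[SeqInfo]) -> StudyIds:
    """Derive subject, session and locator from study-level metadata.

    The locator splits the study description (falling back to the referring
    physician field) on "^" and joins with "/"; the subject comes from the
    patient id after sanitization; the session from a "ses-<label>" token in
    the study metadata or any series name, else absent.
    """
    if not seqinfo:
        raise IdInferenceError("cannot infer ids from an empty study")
    first = seqinfo[0]

    locator = None
    for source in (first.study_description, first.referring_physician_name):
        if source and source.strip():
            parts = [p for p in (s.strip() for s in source.split("^")) if p]
            if parts:
                locator = "/".join(parts)
                break

    subject = sanitize_label(first.patient_id)
    if not subject:
        raise IdInferenceError(
            "subject id could not be inferred from PatientID; supply -s"
        )

    session = None
    texts = [first.study_description or ""]
    texts += [s.series_description or s.protocol_name for s in seqinfo]
    for text in texts:
        m = _SES_RE.search(text)
        if m:
            session = sanitize_label(m.group(1))
            break

    return StudyIds(subject=subject, session=session, locator=locator)


def resolve_duplicates(
    parsed: list[tuple[str, BidsEntities]]
) -> tuple[list[str], list[str]]:
    """Partition series (in acquisition order) into kept and superseded.

    Series whose specs are identical up to ``__dup`` markers are
    re-acquisitions of one another; only the last acquired is kept. Groups
    where no member carries a dup marker are left alone (repeated runs are
    legitimate and get run entities downstream).
    """
    groups: dict[str, list[tuple[str, BidsEntities]]] = {}
    for sid, entities in parsed:
        key = render_series_spec(
            BidsEntities(entities.datatype, entities.suffix, entities.entities,
                         entities.extra)
        )
        groups.setdefault(key, []).append((sid, entities))
    superseded_ids: set[str] = set()
    for members in groups.values():
        if len(members) > 1 and any(e.dup is not None for _, e in members):
            superseded_ids.update(sid for sid, _ in members[:-1])
    kept = [sid for sid, _ in parsed if sid not in superseded_ids]
    superseded = [sid for sid, _ in parsed if sid in superseded_ids]
    return kept, superseded


def _render_name(e: BidsEntities, session: bool) -> str:
    parts = ["sub-{subject}"]
    if session:
        parts.append("ses-{session}")
    parts += [f"{k}-{v}" for k, v in e.entities]
    parts.append(e.suffix)
    return "_".join(parts)


def reproin_infotodict(
    seqinfo: list[SeqInfo],
) -> tuple[dict[tuple, list[str]], dict[str, str]]:
    """Map series to BIDS output templates; also return per-series skip reasons.

    Composes parsing and duplicate resolution; when two accepted series would
    render to the same path, a run entity (run-01, run-02, ...) is appended in
    acquisition order. Derived and motion-corrected series are skipped.
    """
    skip: dict[str, str] = {}

    try:
        session = infer_study_ids(seqinfo).session
    except IdInferenceError:
        session = None

    parsed: list[tuple[SeqInfo, BidsEntities]] = []
    for s in seqinfo:
        if s.is_motion_corrected:
            skip[s.series_id] = "motion-corrected (MOCO) series"
            continue
        if s.is_derived:
            skip[s.series_id] = "derived series"
            continue
        spec = s.series_description or s.protocol_name
        result = parse_series_spec(spec)
        if isinstance(result, ParseRejection):
            skip[s.series_id] = f"not a ReproIn name: {result.reason}"
            continue
        parsed.append((s, result))

    kept, superseded = resolve_duplicates([(s.series_id, e) for s, e in parsed])
    for sid in superseded:
        skip[sid] = "superseded by a later re-acquisition (__dup)"
    parsed = [(s, e) for s, e in parsed if s.series_id in set(kept)]

    # auto-append run- on rendered-name collisions, in acquisition order
    by_name: dict[str, list[int]] = {}
    for idx, (s, e) in enumerate(parsed):
        by_name.setdefault(_render_name(e, session is not None), []).append(idx)
    resolved = list(parsed)
    for name, idxs in by_name.items():
        if len(idxs) < 2:
            continue
        for run, idx in enumerate(idxs, start=1):
            s, e = parsed[idx]
            if e.get("run") is None:
                resolved[idx] = (s, e.with_entity("run", f"{run:0{RUN_PAD_WIDTH}d}"))

    info: dict[tuple, list[str]] = {}
    seen_paths: set[str] = set()
    for s, e in resolved:
        subdir = "sub-{subject}"
        if session is not None:
            subdir += "/ses-{session}"
        template = f"{subdir}/{e.datatype}/{_render_name(e, session is not None)}"
        if template in seen_paths:
            skip[s.series_id] = "would duplicate an already-rendered path"
            continue
        seen_paths.add(template)
        info.setdefault((template, ("nii.gz",), None), []).append(s.series_id)
    return info, skip
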
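"""The heuristic plug-in contract and the conversion-plan machinery.

A heuristic is a Python module (a shipped built-in or any single-file module
supplied by the operator) exposing, at minimum::

    def infotodict(seqinfo):  # -> {template-key: [series_id, ...]}

and optionally ``infotoids(seqinfo) -> dict(subject=, session=, locator=)``
plus a ``sanitize_label(raw) -> str`` hook. Template keys may be
:class:`OutputTemplate` instances, plain strings, or
``(template, output_types, annotation)`` tuples.

Applying a heuristic to a seqinfo table yields a :class:`ConversionPlan`,
which can round-trip through an editable TSV table for the manual-tuning
stage.
"""

from __future__ import annotations

import importlib
import importlib.util
import re
import string
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from types import ModuleType

from ..errors import HeuristicContractError, PlanError, ValidationError
from ..grouping import SeqInfo

BUILTIN_HEURISTICS = {
    "convertall": "bidsconv.heuristics.convertall",
    "reproin": "bidsconv.heuristics.reproin",
}

EDIT_TABLE_HEADER = "series_id\ttemplate\titem\toutput_types"

_FORMATTER = string.Formatter()


@dataclass(frozen=True)
class OutputTemplate:
    """An output filename template with {subject}, optional {session} and {item}."""

    template: str
    output_types: frozenset[str] = frozenset({"nii.gz"})
    annotation: str | None = None

    def __post_init__(self) -> None:
        fields = self.placeholder_names()
        if "subject" not in fields:
            raise ValidationError(f"template lacks {{subject}}: {self.template!r}")
        if self.template.startswith(("/", "\\")) or ".." in Path(self.template).parts:
            raise ValidationError(
                f"template must be a relative path without '..': {self.template!r}"
            )
        unknown = self.output_types - {"nii.gz", "dicom"}
        if unknown:
            raise ValidationError(f"unknown output types: {sorted(unknown)}")

    def placeholder_names(self) -> set[str]:
        return {
            name for _, name, _, _ in _FORMATTER.parse(self.template) if name
        }


@dataclass(frozen=True)
class PlanEntry:
    template: OutputTemplate
    item: int
    series_ids: tuple[str, ...]


@dataclass(frozen=True)
class SkippedSeries:
    series_id: str
    reason: str


@dataclass(frozen=True)
class ConversionPlan:
    """Ordered mapping from output templates to series groups for one subject."""

    entries: tuple[PlanEntry, ...]
    subject: str
    session: str | None = None
    locator: str | None = None
    skipped: tuple[SkippedSeries, ...] = ()

    def __post_init__(self) -> None:
        validate_plan(self)


def validate_plan(plan: ConversionPlan) -> None:
    """Check plan invariants: unique (template, item); items consecutive from 1."""
    seen: set[tuple[str, int]] = set()
    per_template: dict[str, list[int]] = {}
    for entry in plan.entries:
        key = (entry.template.template, entry.item)
        if key in seen:
            raise ValidationError(f"duplicate (template, item) pair: {key}")
        seen.add(key)
        per_template.setdefault(entry.template.template, []).append(entry.item)
    for template, items in per_template.items():
        if sorted(items) != list(range(1, len(items) + 1)):
            raise ValidationError(
                f"item numbers for {template!r} are not consecutive from 1: {items}"
            )
        if len(items) > 1 and "item" not in OutputTemplate(template).placeholder_names():
            raise ValidationError(
                f"template {template!r} receives {len(items)} items but lacks {{item}}"
            )


def load_heuristic(spec: str | Path) -> ModuleType:
    """Load a heuristic by registered name ('convertall', 'reproin') or file path."""
    name = str(spec)
    if name in BUILTIN_HEURISTICS:
        module = importlib.import_module(BUILTIN_HEURISTICS[name])
    else:
        path = Path(spec)
        if not path.is_file():
            raise HeuristicContractError(
                f"unknown heuristic {name!r}: not a registered built-in "
                f"({', '.join(sorted(BUILTIN_HEURISTICS))}) and not a file"
            )
        safe_stem = re.sub(r"\W", "_", path.stem)
        mod_name = f"_bidsconv_heuristic_{safe_stem}"
        spec_obj = importlib.util.spec_from_file_location(mod_name, path)
        if spec_obj is None or spec_obj.loader is None:
            raise HeuristicContractError(f"cannot load heuristic module {path}")
        module = importlib.util.module_from_spec(spec_obj)
        sys.modules[mod_name] = module
        spec_obj.loader.exec_module(module)
    if not callable(getattr(module, "infotodict", None)):
        raise HeuristicContractError(
            f"heuristic {name!r} lacks the required infotodict hook"
        )
    return module


def normalize_template_key(key: object) -> OutputTemplate:
    """Accept OutputTemplate, str, or (template, output_types, annotation) tuples."""
    if isinstance(key, OutputTemplate):
        return key
    if isinstance(key, str):
        return OutputTemplate(key)
    if isinstance(key, tuple) and key and isinstance(key[0], str):
        types = frozenset(key[1]) if len(key) > 1 and key[1] else frozenset({"nii.gz"})
        annotation = key[2] if len(key) > 2 else None
        return OutputTemplate(key[0], types, annotation)
    raise HeuristicContractError(f"invalid template key from heuristic: {key!r}")


def apply_heuristic(
    heuristic: ModuleType,
    seqinfo: list[SeqInfo],
    subject: str,
    session: str | None = None,
    locator: str | None = None,
) -> ConversionPlan:
    """Run a heuristic's infotodict over a seqinfo table and build the plan.

    Item indices are assigned per template in encounter order starting at 1.
    Series mapped by no template are recorded as skipped, never silently
    dropped.
    """
    if not subject:
        raise PlanError("subject must be nonempty")
    known_ids = {s.series_id for s in seqinfo}
    raw = heuristic.infotodict(list(seqinfo))
    entries: list[PlanEntry] = []
    mapped: set[str] = set()
    for key, series_ids in raw.items():
        template = normalize_template_key(key)
        for item, sid in enumerate(series_ids, start=1):
            group = tuple(sid) if isinstance(sid, (list, tuple)) else (sid,)
            for one in group:
                if one not in known_ids:
                    raise PlanError(
                        f"heuristic returned unknown series id {one!r}"
                    )
            mapped.update(group)
            entries.append(PlanEntry(template, item, group))
    skip_reasons = dict(getattr(heuristic, "last_skip_reasons", lambda: {})())
    skipped = tuple(
        SkippedSeries(s.series_id, skip_reasons.get(s.series_id, "no rule matched"))
        for s in seqinfo
        if s.series_id not in mapped
    )
    return ConversionPlan(
        entries=tuple(entries),
        subject=subject,
        session=session,
        locator=locator,
        skipped=skipped,
    )


def write_edit_table(
    plan: ConversionPlan, seqinfo: list[SeqInfo], path: str | Path
) -> Path:
    """Write the operator-editable conversion table (TSV) for manual tuning."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# subject\t{plan.subject}"]
    if plan.session is not None:
        lines.append(f"# session\t{plan.session}")
    if plan.locator is not None:
        lines.append(f"# locator\t{plan.locator}")
    for skip in plan.skipped:
        lines.append(f"# skipped\t{skip.series_id}\t{skip.reason}")
    lines.append(EDIT_TABLE_HEADER)
    for entry in plan.entries:
        types = ",".join(sorted(entry.template.output_types))
        sids = ",".join(entry.series_ids)
        lines.append(f"{sids}\t{entry.template.template}\t{entry.item}\t{types}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_edit_table(path: str | Path) -> ConversionPlan:
    """Read a (possibly operator-edited) conversion table, re-validating invariants."""
    path = Path(path)
    subject = ""
    session: str | None = None
    locator: str | None = None
    skipped: list[SkippedSeries] = []
    rows: list[tuple[str, str, int, frozenset[str]]] = []
    header_seen = False
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if parts[0] == "subject" and len(parts) > 1:
                subject = parts[1]
            elif parts[0] == "session" and len(parts) > 1:
                session = parts[1]
            elif parts[0] == "locator" and len(parts) > 1:
                locator = parts[1]
            elif parts[0] == "skipped" and len(parts) > 2:
                skipped.append(SkippedSeries(parts[1], parts[2]))
            continue
        if not header_seen:
            if line != EDIT_TABLE_HEADER:
                raise ValidationError(
                    f"{path}:{lineno}: expected header {EDIT_TABLE_HEADER!r}"
                )
            header_seen = True
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValidationError(f"{path}:{lineno}: expected 4 tab-separated fields")
        sid, template, item_s, types_s = parts
        try:
            item = int(item_s)
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: item is not an integer") from exc
        rows.append((sid, template, item, frozenset(types_s.split(","))))
    if not header_seen:
        raise ValidationError(f"{path}: missing table header")

    entries = tuple(
        PlanEntry(OutputTemplate(template, types), item, tuple(sids.split(",")))
        for sids, template, item, types in rows
    )
    return ConversionPlan(
        entries=entries,
        subject=subject,
        session=session,
        locator=locator,
        skipped=tuple(skipped),
    )
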
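"""Obfuscation of identifying metadata: subject ids and visit timestamps.

Subject ids map through an operator-supplied table or a keyed deterministic
digest. Visit timestamps move by one constant per-study offset so that
pairwise intervals — the quantity longitudinal analyses need — are preserved
exactly, while the calendar dates are obscured. The raw-to-released id map
is persisted outside the output tree, never inside it.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import hmac
import random
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError, ValidationError

#: Sidecar/metadata fields stripped by default.
DEFAULT_STRIP_FIELDS = frozenset(
    {
        "PatientName",
        "PatientID",
        "AccessionNumber",
        "OperatorsName",
        "PerformingPhysicianName",
        "ReferringPhysicianName",
        "InstitutionAddress",
    }
)

#: Date-shift magnitude range in days (one constant draw per study).
SHIFT_RANGE_DAYS = (365, 730)


@dataclass
class AnonPolicy:
    """How to obfuscate: id mapping, keyed generator seed, fields to strip."""

    id_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    strip_fields: frozenset[str] = DEFAULT_STRIP_FIELDS
    date_shift_days: int | None = None  # explicit override; else drawn per study


def anonymize_id(raw_id: str, policy: AnonPolicy) -> str:
    """Map a raw subject id to its released id (table lookup or keyed digest).

    Generated ids are 8 hex characters of an HMAC keyed by the policy seed;
    repeated calls are stable and the mapping is recorded into the policy's
    id_map. A digest collision with a different raw id raises so the operator
    can re-key.
    """
    if not raw_id:
        raise InputError("raw subject id must be nonempty")
    if raw_id in policy.id_map:
        return policy.id_map[raw_id]
    digest = hmac.new(
        str(policy.seed).encode(), raw_id.encode(), hashlib.sha256
    ).hexdigest()[:8]
    if digest in policy.id_map.values():
        raise ValidationError(
            f"generated id {digest!r} collides with an existing mapping; "
            "re-key with a different seed"
        )
    policy.id_map[raw_id] = digest
    return digest


def study_shift_days(study_uid: str, policy: AnonPolicy) -> int:
    """The constant day offset for one study (uniform over +/-[365, 730], seeded)."""
    if policy.date_shift_days is not None:
        return policy.date_shift_days
    rng = random.Random(f"{policy.seed}:{study_uid}")
    magnitude = rng.randint(*SHIFT_RANGE_DAYS)
    sign = rng.choice((-1, 1))
    return sign * magnitude


def shift_timestamps(
    timestamps: list[dt.datetime], policy: AnonPolicy, study_uid: str = ""
) -> list[dt.datetime]:
    """Shift all of one study's timestamps by the same offset.

    Pairwise differences and time-of-day are preserved exactly.
    """
    offset = dt.timedelta(days=study_shift_days(study_uid, policy))
    return [t + offset for t in timestamps]


def scrub_sidecar(metadata: dict, policy: AnonPolicy) -> dict:
    """Drop the policy's strip fields from a sidecar; everything else unchanged."""
    return {k: v for k, v in metadata.items() if k not in policy.strip_fields}


def write_id_map(policy: AnonPolicy, path: str | Path, output_root: str | Path) -> Path:
    """Persist the raw->released id map as TSV, refusing paths under the output root."""
    path = Path(path).resolve()
    root = Path(output_root).resolve()
    if root == path or root in path.parents:
        raise ValidationError(
            f"refusing to write the id map inside the output tree: {path}"
        )
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["raw_id\treleased_id"]
    lines += [f"{raw}\t{rel}" for raw, rel in sorted(policy.id_map.items())]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_id_map(path: str | Path) -> dict[str, str]:
    """Load a previously written raw->released id table."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0] != "raw_id\treleased_id":
        raise ValidationError(f"{path}: not an id-map table")
    out: dict[str, str] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        raw, _, released = line.partition("\t")
        out[raw] = released
    values = list(out.values())
    if len(set(values)) != len(values):
        raise ValidationError(f"{path}: id map is not injective")
    return out
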
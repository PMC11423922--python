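"""Pinned constants surfaced in outputs and optional key=value config files."""

from __future__ import annotations

from pathlib import Path

#: BIDS schema version written into dataset_description.json.
BIDS_VERSION = "1.8.0"

#: Zero-padding width for auto-assigned run entities ("run-01").
RUN_PAD_WIDTH = 2

#: Entity keys in the fixed BIDS filename order.
ENTITY_ORDER = ("task", "acq", "ce", "rec", "dir", "run", "echo", "part")

#: Slice-position clustering tolerance (mm); scanner jitter is far below,
#: genuinely duplicate positions far above.
POSITION_TOL = 1e-4

#: Relative slice-spacing deviation beyond which a non-uniformity warning is set.
SPACING_WARN_REL = 0.01

SOFTWARE_NAME = "bidsconv"


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a minimal ``key = value`` config file (comments with '#')."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip().strip('"')
    return out
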
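"""Built-in heuristic delegating to the ReproIn convention parser."""

from __future__ import annotations

from .. import reproin as _reproin

_LAST_SKIPS: dict[str, str] = {}


def infotoids(seqinfo):
    """Infer subject/session/locator from study metadata."""
    ids = _reproin.infer_study_ids(list(seqinfo))
    return {"subject": ids.subject, "session": ids.session, "locator": ids.locator}


def infotodict(seqinfo):
    """Map ReproIn-named series to BIDS output templates."""
    info, skips = _reproin.reproin_infotodict(list(seqinfo))
    _LAST_SKIPS.clear()
    _LAST_SKIPS.update(skips)
    return info


def last_skip_reasons():
    """Per-series skip reasons recorded by the most recent infotodict call."""
    return dict(_LAST_SKIPS)


sanitize_label = _reproin.sanitize_label
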
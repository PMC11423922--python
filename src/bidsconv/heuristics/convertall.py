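"""The simplest built-in heuristic: convert every series under a generic name.

It expresses no knowledge or assumptions about the acquisitions; each series
maps to ``sub-{subject}/{item:02d}-<series_id>``. Useful as a template for
developing custom heuristics or to establish an initial mapping for the
manual-tuning stage.
"""

from __future__ import annotations


def infotodict(seqinfo):
    """Map every series to one generic NIfTI output template."""
    info = {}
    for s in seqinfo:
        key = (f"sub-{{subject}}/{{item:02d}}-{s.series_id}", ("nii.gz",), None)
        info[key] = [s.series_id]
    return info
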
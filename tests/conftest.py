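import pathlib

import pytest

from bidsconv import dicom_io, grouping, synth

DEMO_SERIES = (
    synth.SeriesFixture("anat-T1w", dim3=5),
    synth.SeriesFixture("func-bold_task-rest", dim3=4, dim4=3, orientation="random"),
    synth.SeriesFixture("func-bold_task-rest", dim3=4, dim4=3),
    synth.SeriesFixture("func-bold_task-mot_run-02_SBRef", dim3=4),
    synth.SeriesFixture(
        "func-bold_task-me", dim3=3, dim4=2, n_echoes=2, te_ms=(15.0, 35.0)
    ),
    synth.SeriesFixture(
        "func-bold_task-rest", dim3=3, image_type=("ORIGINAL", "PRIMARY", "M", "MOCO")
    ),
)

DEMO_SPEC = synth.FixtureSpec(
    studies=(synth.StudyFixture(series=DEMO_SERIES),), seed=7
)


@pytest.fixture(scope="session")
def demo_study(tmp_path_factory) -> tuple[pathlib.Path, synth.GroundTruth]:
    """One synthetic multi-series study shared (read-only) across tests."""
    out = tmp_path_factory.mktemp("demo_dicom")
    return synth.generate_study(DEMO_SPEC, out)


@pytest.fixture(scope="session")
def demo_headers(demo_study):
    root, _ = demo_study
    headers = [dicom_io.read_header(f) for f in dicom_io.discover_files([root])]
    assert all(isinstance(h, dicom_io.DicomHeader) for h in headers)
    return headers


@pytest.fixture(scope="session")
def demo_seqinfo(demo_headers):
    studies = grouping.group_series(demo_headers)
    (seqinfo,) = studies.values()
    return seqinfo
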
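import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bidsconv.config import ENTITY_ORDER
from bidsconv.errors import IdInferenceError
from bidsconv.reproin import (
    BidsEntities,
    ParseRejection,
    infer_study_ids,
    parse_series_spec,
    render_series_spec,
    reproin_infotodict,
    resolve_duplicates,
    sanitize_label,
)

GOLDEN_PARSES = [
    (
        "func-bold_task-rest_run-01",
        ("func", "bold", (("task", "rest"), ("run", "01"))),
    ),
    ("anat-T1w", ("anat", "T1w", ())),
    (
        "func-bold_task-mot_run-02_SBRef",
        ("func", "sbref", (("task", "mot"), ("run", "02"))),
    ),
    ("func_task-rest", ("func", "bold", (("task", "rest"),))),
    ("dwi-dwi_dir-AP", ("dwi", "dwi", (("dir", "AP"),))),
    ("fmap-epi_dir-PA", ("fmap", "epi", (("dir", "PA"),))),
    (
        "func-bold_task-nback_acq-mb8_run-02_echo-1",
        ("func", "bold", (("task", "nback"), ("acq", "mb8"), ("run", "02"), ("echo", "1"))),
    ),
]


@pytest.mark.parametrize("raw, expected", GOLDEN_PARSES)
def test_golden_parse_table(raw, expected):
    result = parse_series_spec(raw)
    assert isinstance(result, BidsEntities)
    assert (result.datatype, result.suffix, result.entities) == expected


@pytest.mark.parametrize(
    "raw", ["localizer", "AAHead_Scout", "", "anat", "dwi", "t1_mprage_sag"]
)
def test_non_reproin_names_rejected(raw):
    assert isinstance(parse_series_spec(raw), ParseRejection)


def test_dup_marker_parsed():
    result = parse_series_spec("anat-T1w__dup01")
    assert isinstance(result, BidsEntities)
    assert result.dup == 1 and result.suffix == "T1w"


def test_unknown_keys_preserved_in_extra():
    result = parse_series_spec("func-bold_task-rest_weird-x")
    assert isinstance(result, BidsEntities)
    assert ("weird", "x") in result.extra
    assert result.get("task") == "rest"


@pytest.mark.parametrize(
    "raw, expected",
    [("sid_01", "sid01"), ("ABC123", "ABC123"), ("émil-07", "mil07"), ("", "")],
)
def test_sanitize_label(raw, expected):
    assert sanitize_label(raw) == expected


def test_entity_order_enforced_in_type():
    with pytest.raises(ValueError, match="fixed order"):
        BidsEntities("func", "bold", (("run", "01"), ("task", "rest")))


_label = st.text(alphabet="abcdefghijklmnopqrstuvwxyz0123456789", min_size=1, max_size=5)
_suffixes = {"anat": "T1w", "func": "bold", "dwi": "dwi", "fmap": "epi"}


@st.composite
def entity_sets(draw):
    datatype = draw(st.sampled_from(sorted(_suffixes)))
    keys = draw(
        st.lists(st.sampled_from(ENTITY_ORDER), unique=True, max_size=4)
    )
    ordered = tuple(
        (k, draw(_label)) for k in ENTITY_ORDER if k in keys
    )
    return BidsEntities(datatype, _suffixes[datatype], ordered)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(entity_sets())
def test_parse_render_roundtrip(entities):
    assert parse_series_spec(render_series_spec(entities)) == entities


def test_locator_from_caret_separated_description(demo_seqinfo):
    ids = infer_study_ids(demo_seqinfo)
    assert ids.locator == "Patterson/Coben"
    assert ids.subject == "sid01"
    assert ids.session is None


def test_subject_sanitized():
    row = demo_row(patient_id="sid-01")
    assert infer_study_ids([row]).subject == "sid01"


def test_empty_subject_is_an_error():
    row = demo_row(patient_id="--")
    with pytest.raises(IdInferenceError):
        infer_study_ids([row])


def test_session_token_detected():
    row = demo_row(series_description="func-bold_task-rest_ses-02")
    assert infer_study_ids([row]).session == "02"


def demo_row(**overrides):
    from tests_helpers import make_seqinfo

    return make_seqinfo(**overrides)


def _parsed(*names):
    out = []
    for i, name in enumerate(names, 1):
        e = parse_series_spec(name)
        assert isinstance(e, BidsEntities)
        out.append((f"{i}-{name}", e))
    return out


def test_resolve_duplicates_last_wins():
    kept, superseded = resolve_duplicates(_parsed("anat-T1w__dup01", "anat-T1w"))
    assert kept == ["2-anat-T1w"]
    assert superseded == ["1-anat-T1w__dup01"]


def test_resolve_duplicates_three_repeats():
    kept, superseded = resolve_duplicates(
        _parsed("anat-T1w__dup01", "anat-T1w__dup02", "anat-T1w")
    )
    assert kept == ["3-anat-T1w"] and len(superseded) == 2


def test_resolve_singleton_kept():
    kept, superseded = resolve_duplicates(_parsed("anat-T1w"))
    assert kept == ["1-anat-T1w"] and superseded == []


def test_infotodict_basic_templates(demo_seqinfo):
    info, skips = reproin_infotodict(demo_seqinfo)
    templates = {t for (t, _, _) in info}
    assert "sub-{subject}/anat/sub-{subject}_T1w" in templates
    assert any(t.endswith("_task-mot_run-02_sbref") for t in templates)


def test_infotodict_auto_run_on_collision(demo_seqinfo):
    info, _ = reproin_infotodict(demo_seqinfo)
    runs = sorted(
        t for (t, _, _) in info if "task-rest" in t and "run-" in t
    )
    assert len(runs) == 2
    assert runs[0].endswith("run-01_bold")
    assert runs[1].endswith("run-02_bold")


def test_infotodict_skips_moco(demo_seqinfo):
    _, skips = reproin_infotodict(demo_seqinfo)
    moco_ids = [s.series_id for s in demo_seqinfo if s.is_motion_corrected]
    assert moco_ids and all(sid in skips for sid in moco_ids)


def test_infotodict_no_duplicate_rendered_paths(demo_seqinfo):
    info, _ = reproin_infotodict(demo_seqinfo)
    templates = [t for (t, _, _) in info]
    assert len(templates) == len(set(templates))
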
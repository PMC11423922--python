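import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bidsconv.errors import HeuristicContractError, PlanError, ValidationError
from bidsconv.heuristics import (
    ConversionPlan,
    OutputTemplate,
    PlanEntry,
    apply_heuristic,
    load_heuristic,
    read_edit_table,
    write_edit_table,
)


def test_load_builtins():
    for name in ("convertall", "reproin"):
        module = load_heuristic(name)
        assert callable(module.infotodict)


def test_load_unknown_name():
    with pytest.raises(HeuristicContractError, match="unknown heuristic"):
        load_heuristic("does-not-exist")


def test_load_module_missing_hook(tmp_path):
    bad = tmp_path / "bad_heuristic.py"
    bad.write_text("x = 1\n")
    with pytest.raises(HeuristicContractError, match="infotodict"):
        load_heuristic(bad)


def test_load_custom_module_file(tmp_path):
    mod = tmp_path / "mine.py"
    mod.write_text(
        "def infotodict(seqinfo):\n"
        "    return {('sub-{subject}/misc/sub-{subject}_item{item}', ('nii.gz',),"
        " None): [s.series_id for s in seqinfo]}\n"
    )
    module = load_heuristic(mod)
    assert callable(module.infotodict)


def test_convertall_one_template_per_series(demo_seqinfo):
    convertall = load_heuristic("convertall")
    info = convertall.infotodict(demo_seqinfo)
    assert len(info) == len(demo_seqinfo)
    for (template, types, _), sids in info.items():
        assert "{item:02d}" in template and types == ("nii.gz",)
        assert len(sids) == 1 and sids[0] in template


def test_convertall_empty():
    assert load_heuristic("convertall").infotodict([]) == {}


def test_apply_convertall_items_restart_per_template(demo_seqinfo):
    plan = apply_heuristic(load_heuristic("convertall"), demo_seqinfo, "01")
    assert len(plan.entries) == len(demo_seqinfo)
    assert all(e.item == 1 for e in plan.entries)  # distinct templates
    assert not plan.skipped


def test_apply_is_deterministic(demo_seqinfo):
    h = load_heuristic("convertall")
    assert apply_heuristic(h, demo_seqinfo, "01") == apply_heuristic(
        h, demo_seqinfo, "01"
    )


def test_apply_unknown_series_id(demo_seqinfo):
    class FakeHeuristic:
        @staticmethod
        def infotodict(seqinfo):
            return {("sub-{subject}/{item:02d}-x", ("nii.gz",), None): ["99-x"]}

    with pytest.raises(PlanError, match="99-x"):
        apply_heuristic(FakeHeuristic, demo_seqinfo, "01")


def test_unmapped_series_reported_skipped(demo_seqinfo):
    class OnlyFirst:
        @staticmethod
        def infotodict(seqinfo):
            return {
                ("sub-{subject}/{item:02d}-a", ("nii.gz",), None): [
                    seqinfo[0].series_id
                ]
            }

    plan = apply_heuristic(OnlyFirst, demo_seqinfo, "01")
    assert len(plan.skipped) == len(demo_seqinfo) - 1
    assert all(s.reason == "no rule matched" for s in plan.skipped)


def test_template_invariants():
    with pytest.raises(ValidationError):
        OutputTemplate("no-subject-placeholder/{item}")
    with pytest.raises(ValidationError):
        OutputTemplate("/abs/sub-{subject}")
    with pytest.raises(ValidationError):
        OutputTemplate("../sub-{subject}")


def test_plan_duplicate_template_item_rejected():
    t = OutputTemplate("sub-{subject}/func/sub-{subject}_task-a_bold")
    with pytest.raises(ValidationError, match="duplicate"):
        ConversionPlan(
            entries=(PlanEntry(t, 1, ("1-a",)), PlanEntry(t, 1, ("2-b",))),
            subject="01",
        )


def test_plan_items_must_be_consecutive():
    t = OutputTemplate("sub-{subject}/x/sub-{subject}_run{item}")
    with pytest.raises(ValidationError, match="consecutive"):
        ConversionPlan(
            entries=(PlanEntry(t, 1, ("1-a",)), PlanEntry(t, 3, ("2-b",))),
            subject="01",
        )


_labels = st.text(
    alphabet="abcdefghijklmnopqrstuvwxyz0123456789", min_size=1, max_size=6
)


@st.composite
def plans(draw):
    subject = draw(_labels)
    session = draw(st.one_of(st.none(), _labels))
    n_templates = draw(st.integers(1, 4))
    entries = []
    for t_idx in range(n_templates):
        template = OutputTemplate(
            f"sub-{{subject}}/grp{t_idx}/sub-{{subject}}_seq{t_idx}_{{item}}"
        )
        n_items = draw(st.integers(1, 3))
        for item in range(1, n_items + 1):
            entries.append(
                PlanEntry(template, item, (f"{t_idx}{item}-{draw(_labels)}",))
            )
    return ConversionPlan(
        entries=tuple(entries),
        subject=subject,
        session=session,
        locator=draw(st.one_of(st.none(), _labels)),
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(plans())
def test_edit_table_roundtrip_law(tmp_path_factory, plan):
    path = tmp_path_factory.mktemp("tables") / "table.tsv"
    write_edit_table(plan, [], path)
    assert read_edit_table(path) == plan


def test_operator_edit_is_respected(tmp_path, demo_seqinfo):
    plan = apply_heuristic(load_heuristic("convertall"), demo_seqinfo, "01")
    path = write_edit_table(plan, demo_seqinfo, tmp_path / "t.tsv")
    text = path.read_text()
    old = plan.entries[1].template.template
    edited = text.replace(old, "sub-{subject}/anat/sub-{subject}_T1w")
    path.write_text(edited)
    plan2 = read_edit_table(path)
    assert plan2.entries[1].template.template == "sub-{subject}/anat/sub-{subject}_T1w"


def test_duplicate_rows_after_edit_rejected(tmp_path, demo_seqinfo):
    plan = apply_heuristic(load_heuristic("convertall"), demo_seqinfo, "01")
    path = write_edit_table(plan, demo_seqinfo, tmp_path / "t.tsv")
    lines = path.read_text().splitlines()
    lines.append(lines[-1])  # duplicate (template, item) row
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValidationError):
        read_edit_table(path)


def test_malformed_row_reports_line_number(tmp_path, demo_seqinfo):
    plan = apply_heuristic(load_heuristic("convertall"), demo_seqinfo, "01")
    path = write_edit_table(plan, demo_seqinfo, tmp_path / "t.tsv")
    lines = path.read_text().splitlines()
    lines.append("only-two\tfields")
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValidationError, match=rf":{len(lines)}:"):
        read_edit_table(path)
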
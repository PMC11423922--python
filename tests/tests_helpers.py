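"""Small builders shared across test modules."""

from pathlib import Path

from bidsconv.grouping import SeqInfo


def make_seqinfo(**overrides) -> SeqInfo:
    defaults = dict(
        series_id="1-anat-T1w",
        series_instance_uid="1.3.6.1.4.1.99999.0.1.1",
        example_file=Path("/tmp/none.dcm"),
        total_files_till_now=1,
        dim1=6,
        dim2=8,
        dim3=1,
        dim4=1,
        TR=2.0,
        TE=30.0,
        protocol_name="anat-T1w",
        series_description="anat-T1w",
        sequence_name="synth",
        image_type=("ORIGINAL", "PRIMARY", "M"),
        is_motion_corrected=False,
        is_derived=False,
        patient_id="sid01",
        study_description="Patterson^Coben",
        referring_physician_name="Patterson^Coben",
        date=None,
        n_files=1,
        n_echoes=1,
    )
    defaults.update(overrides)
    return SeqInfo(**defaults)
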
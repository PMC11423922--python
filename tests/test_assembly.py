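import random

import numpy as np
import pytest

import nibabel as nib
from bidsconv import synth
from bidsconv.assembly import (
    assemble_series,
    build_affine,
    sort_slices,
    write_nifti,
    write_sidecar,
)
from bidsconv.dicom_io import discover_files, read_header
from bidsconv.errors import AssemblyError, CollisionError

AXIAL = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


def series_headers(root, series_glob):
    return [read_header(f) for f in sorted(root.rglob(series_glob))]


def one_series(tmp_path, fixture, seed=11):
    spec = synth.FixtureSpec(
        studies=(synth.StudyFixture(series=(fixture,)),), seed=seed
    )
    root, truth = synth.generate_study(spec, tmp_path)
    headers = [read_header(f) for f in discover_files([root])]
    return headers, truth.studies[0].series[0]


def test_sort_slices_orders_shuffled_input(tmp_path):
    headers, _ = one_series(
        tmp_path, synth.SeriesFixture("anat-T1w", dim3=6, slice_spacing=1.0)
    )
    shuffled = list(headers)
    random.Random(1).shuffle(shuffled)
    ordered, spacing, warn = sort_slices(shuffled)
    assert spacing == pytest.approx(1.0)
    assert not warn
    zs = [h.image_position_patient[2] for h in ordered]
    assert zs == sorted(zs)


def test_sort_slices_single_slice_fallback(tmp_path):
    headers, _ = one_series(
        tmp_path, synth.SeriesFixture("anat-T1w", dim3=1, slice_spacing=2.5)
    )
    ordered, spacing, warn = sort_slices(headers)
    assert spacing == 2.5  # SpacingBetweenSlices tag present in fixtures
    assert not warn


def test_sort_slices_nonuniform_warning(tmp_path):
    headers, _ = one_series(tmp_path, synth.SeriesFixture("anat-T1w", dim3=5))
    synth.corrupt_study(tmp_path, "nonuniform_spacing")
    headers = [read_header(f) for f in discover_files([tmp_path])]
    _, _, warn = sort_slices(headers)
    assert warn


def test_sort_slices_inconsistent_orientation(tmp_path):
    one_series(tmp_path, synth.SeriesFixture("anat-T1w", dim3=5))
    synth.corrupt_study(tmp_path, "scramble_orientation")
    headers = [read_header(f) for f in discover_files([tmp_path])]
    with pytest.raises(AssemblyError, match="orientation"):
        sort_slices(headers)


def test_build_affine_axis_aligned_identity():
    affine = build_affine(AXIAL, (0.0, 0.0, 0.0), (1.0, 1.0), 1.0)
    assert np.allclose(affine, np.diag([-1.0, -1.0, 1.0, 1.0]))


def test_build_affine_translation_sign_rule():
    affine = build_affine(AXIAL, (10.0, 20.0, 5.0), (1.0, 1.0), 1.0)
    assert np.allclose(affine[:3, 3], [-10.0, -20.0, 5.0])


def test_build_affine_spacing_goes_to_columns():
    affine = build_affine(AXIAL, (0.0, 0.0, 0.0), (3.0, 2.0), 2.5)
    # column 0 scales with the column spacing, column 1 with the row spacing
    assert np.allclose(np.abs(affine[:3, 0]), [2.0, 0, 0])
    assert np.allclose(np.abs(affine[:3, 1]), [0, 3.0, 0])
    assert np.allclose(np.abs(affine[:3, 2]), [0, 0, 2.5])


def test_affine_recovery_random_rigid(tmp_path):
    headers, truth = one_series(
        tmp_path,
        synth.SeriesFixture(
            "anat-T1w",
            dim3=4,
            orientation="random",
            pixel_spacing=(1.7, 0.9),
            slice_spacing=3.1,
            origin=(12.5, -33.0, 7.25),
        ),
        seed=23,
    )
    (volume,) = assemble_series(headers)
    assert (
        np.linalg.norm(volume.geometry.affine_ras - truth.affine_ras) < 1e-6
    )


def test_multi_echo_split(tmp_path):
    headers, truth = one_series(
        tmp_path,
        synth.SeriesFixture(
            "func-bold_task-me", dim3=5, dim4=3, n_echoes=2, te_ms=(15.0, 35.0)
        ),
    )
    volumes = assemble_series(headers)
    assert len(volumes) == 2
    assert [v.echo_index for v in volumes] == [1, 2]
    assert {v.sidecar["EchoTime"] for v in volumes} == {0.015, 0.035}
    assert all(v.data.shape == (6, 8, 5, 3) for v in volumes)
    # echo split conserves file count
    assert sum(v.n_files for v in volumes) == len(headers)


def test_single_volume_is_3d(tmp_path):
    headers, _ = one_series(tmp_path, synth.SeriesFixture("anat-T1w", dim3=4))
    (volume,) = assemble_series(headers)
    assert volume.data.ndim == 3 and volume.echo_index is None


def test_voxel_conservation_exact(tmp_path):
    headers, truth = one_series(
        tmp_path, synth.SeriesFixture("func-bold_task-x", dim3=3, dim4=4)
    )
    (volume,) = assemble_series(headers)
    assert int(volume.data.sum(dtype=np.int64)) == truth.voxel_sum


def test_missing_slice_is_an_error(tmp_path):
    one_series(tmp_path, synth.SeriesFixture("func-bold_task-x", dim3=4, dim4=3))
    synth.corrupt_study(tmp_path, "drop_slice")
    headers = [read_header(f) for f in discover_files([tmp_path])]
    with pytest.raises(AssemblyError, match="missing"):
        assemble_series(headers)


def test_sidecar_units_and_provenance(tmp_path):
    headers, _ = one_series(tmp_path, synth.SeriesFixture("anat-T1w", dim3=2))
    (volume,) = assemble_series(headers)
    assert volume.sidecar["RepetitionTime"] == 2.0  # 2000 ms -> s
    assert volume.sidecar["EchoTime"] == 0.03
    assert volume.sidecar["ConversionSoftware"] == "bidsconv"


def test_nifti_roundtrip_and_determinism(tmp_path):
    headers, _ = one_series(
        tmp_path, synth.SeriesFixture("anat-T1w", dim3=4, orientation="random")
    )
    (volume,) = assemble_series(headers)
    out = tmp_path / "out" / "vol.nii.gz"
    write_nifti(volume.data, volume.geometry, out)
    first_bytes = out.read_bytes()
    img = nib.load(out)
    assert np.array_equal(np.asarray(img.dataobj), volume.data)
    assert np.allclose(img.affine, volume.geometry.affine_ras, atol=1e-6)
    assert img.header["sform_code"] == 2 and img.header["qform_code"] == 2
    # second write over identical content is a byte-level no-op
    write_nifti(volume.data, volume.geometry, out)
    assert out.read_bytes() == first_bytes


def test_write_collision_policy(tmp_path):
    path = tmp_path / "x.json"
    write_sidecar({"a": 1}, path)
    write_sidecar({"a": 1}, path)  # identical: silent no-op
    with pytest.raises(CollisionError):
        write_sidecar({"a": 2}, path)
    write_sidecar({"a": 2}, path, overwrite=True)


def test_sidecar_bytes_are_pinned(tmp_path):
    path = tmp_path / "s.json"
    write_sidecar({"b": 1, "a": [1, 2]}, path)
    assert path.read_text() == '{\n  "a": [\n    1,\n    2\n  ],\n  "b": 1\n}\n'
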
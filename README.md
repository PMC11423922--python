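# bidsconv

Heuristic-driven conversion of DICOM studies into BIDS-organized NIfTI
datasets.

MRI scanners export one DICOM file per reconstructed slice, with naming and
organization that vary by site, vendor and operator. Analysis tools in
neuroimaging almost universally expect the opposite: 3-D/4-D NIfTI volumes
laid out in a [BIDS](https://bids.neuroimaging.io) hierarchy
(`sub-<label>/[ses-<label>/]<datatype>/sub-<label>_..._<suffix>.nii.gz`)
with JSON sidecar metadata. `bidsconv` bridges the two for labs that need
the renaming logic to be *their own*: all naming decisions are delegated to
a pluggable heuristic — a small Python module — while the package handles
everything mechanical around it: series grouping, geometry, echo splitting,
sidecars, dataset-level files, and optional de-identification.

## What it does

- **Discovery.** Input files, directories, or zip archives are enumerated,
  DICOM headers are read (lazily — never pixel data), files are grouped into
  studies and series by their instance UIDs, and each series is summarized
  into one row of a *seqinfo* table: in-plane dimensions, slices per volume
  (`dim3`, distinct positions along the slice normal), volumes per echo
  (`dim4`), TR/TE, protocol and series descriptions, and derived/
  motion-corrected flags.
- **Naming.** A heuristic maps seqinfo rows to output filename templates.
  Built-ins: `convertall` (every series under a generic name — the starting
  point for manual curation or custom heuristics) and `reproin`, which parses
  protocol names of the form `<datatype>[-<suffix>][_<key>-<value>]...`
  (e.g. `func-bold_task-rest_run-01`) into BIDS entities, infers the subject
  from the patient id, the session from a `ses-` token, and the dataset
  locator from the caret-separated study description (`Patterson^Coben` →
  `Patterson/Coben/`). With ReproIn-named protocols, conversion requires no
  operator input at all.
- **Optional manual tuning.** With `-c none` the tool stops after discovery,
  writing the seqinfo table and an editable TSV conversion table. The
  operator may adjust templates; a subsequent `-c internal` run picks the
  table up. Without edits, the staged route produces a byte-identical tree
  to the direct one.
- **Conversion.** Slices are sorted along the slice normal
  (`row_cosine x col_cosine`), stacked per (echo, volume), and written as
  gzipped NIfTI-1 with the voxel-to-RAS affine

  ```
  A = diag(-1,-1,1,1) . [ r*Δc  c*Δr  n*Δs  p ; 0 0 0 1 ]
  ```

  where `r`, `c`, `n` are the LPS direction cosines, `Δr/Δc/Δs` the row/
  column/slice spacings and `p` the position of the first slice (the sign
  flips convert DICOM's LPS frame to NIfTI's RAS). Multi-echo series are
  split into one file per echo with an `echo-<n>` entity and per-echo
  `EchoTime` sidecars. Dataset files (`dataset_description.json`,
  `participants.tsv`, per-session `*_scans.tsv`, `README`) are populated and
  merged idempotently; re-running over unchanged input changes no bytes.
- **Anonymization** (`--anon`): subject ids map through a keyed digest or an
  operator table (persisted *outside* the output tree), visit timestamps are
  shifted by a per-study constant offset (±1–2 years) that preserves all
  pairwise intervals, and identifying sidecar fields are stripped.

No external converter binary is invoked; stacking, affines and sidecars are
computed natively from the DICOM headers.

## Worked example

The package ships a synthetic-study generator, so the example is fully
self-contained:

```python
from bidsconv import synth

spec = synth.FixtureSpec(studies=(synth.StudyFixture(series=(
    synth.SeriesFixture("anat-T1w", dim3=5),
    synth.SeriesFixture("func-bold_task-rest", dim3=4, dim4=3),
    synth.SeriesFixture("func-bold_task-me", dim3=3, dim4=2,
                        n_echoes=2, te_ms=(15.0, 35.0)),
)),), seed=7)
root, truth = synth.generate_study(spec, "demo_dicom")
print(truth.n_files)   # 29  (5 + 12 + 12 files, one per slice/volume/echo)
```

```
$ bidsconv --files demo_dicom -f reproin --bids -o bids_datasets -c internal
```

produces (under the locator inferred from the study description
`Patterson^Coben`):

```
bids_datasets/Patterson/Coben/
├── dataset_description.json
├── participants.tsv
├── README
└── sub-sid01/
    ├── anat/sub-sid01_T1w.nii.gz            (+ .json)
    ├── func/sub-sid01_task-rest_bold.nii.gz (+ .json)
    ├── func/sub-sid01_task-me_echo-1_bold.nii.gz
    ├── func/sub-sid01_task-me_echo-2_bold.nii.gz
    └── sub-sid01_scans.tsv
```

The anatomical volume is 6×8×5 voxels; the two echo files carry
`"EchoTime": 0.015` and `"EchoTime": 0.035` in their sidecars (seconds,
converted from the 15/35 ms DICOM tags) and `"RepetitionTime": 2.0`.
Running the same command again exits 0 and changes zero bytes. Exit codes
are pinned for scripting: 0 ok, 2 usage, 3 input, 4 heuristic/ids,
5 assembly, 6 output collision.

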
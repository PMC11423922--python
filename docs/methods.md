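# Methods

## Pipeline model

`bidsconv` treats DICOM-to-BIDS conversion as three separable concerns:

1. **Grouping and summarization.** Files are identified by
   (StudyInstanceUID, SeriesInstanceUID). SeriesNumber is used only for
   human-readable ids and ordering, never for identity, because numbers are
   reused across studies while UIDs are globally unique. Each series is
   summarized into one *seqinfo* row. `dim3` is the number of distinct
   spatial positions, computed as projections of ImagePositionPatient onto
   the slice normal and clustered with a 1e-4 mm tolerance (scanner jitter
   is orders of magnitude below this; genuinely distinct slices are orders
   of magnitude above). `dim4` is files ÷ (dim3 × distinct echo count).
   Multi-echo series remain a single row so heuristics see one acquisition;
   the echo split happens at assembly. TR is reported in seconds and TE in
   milliseconds, with −1 as the explicit "absent" sentinel so the row stays
   a flat record.
2. **Naming.** A heuristic module maps seqinfo rows to output templates.
   The contract is deliberately minimal — a required
   `infotodict(seqinfo) -> {template: [series_id, ...]}` and an optional
   `infotoids` — so a site heuristic fits in one file. Item indices restart
   at 1 per template; series matched by no rule are recorded as skipped with
   a reason, never silently dropped.
3. **Assembly.** Pixel data is read only here (discovery is header-only and
   scales to large studies). Slices are ordered by position projection onto
   the right-handed normal `row x col`, ties broken by InstanceNumber;
   sorting ascending along the normal gives one canonical on-disk
   orientation regardless of acquisition direction. The slice spacing is the
   median of consecutive distinct-position differences; deviations beyond 1%
   of the median set a non-uniformity warning. The voxel-to-RAS affine
   places columns (row_cosine·Δcol, col_cosine·Δrow, normal·Δslice) and the
   first-slice position in LPS, then negates the first two rows (LPS→RAS).
   Note DICOM's PixelSpacing is (row spacing, column spacing): the *column*
   index moves along the *row* direction cosine, which is the classic
   transposition trap this module pins down with ground-truth tests.

## DICOM ingestion

Only Part-10 files with the `DICM` magic marker are accepted by default;
headerless implicit files are rejected as a predictability choice, with an
explicit `--allow-no-magic` escape hatch. Rejections are values, not
exceptions, so one stray text file never aborts a conversion. Supported
transfer syntax for the synthetic fixtures is uncompressed explicit-VR
little-endian; compressed syntaxes, enhanced multi-frame objects, vendor
mosaic layouts and DICOMDIR catalogs are out of scope. Zip archives are
extracted to a workspace directory (inside the output's staging area
normally; a temporary directory under `--anon`, so anonymized trees never
carry raw input copies); nested zips are not descended into.

## The ReproIn convention

The grammar is `<datatype>[-<suffix>][_<key>-<value>]...` anchored at the
start of the series description (protocol name as fallback, since operators
edit descriptions while scanners copy protocols). Datatypes: anat, func,
dwi, fmap. A missing suffix is accepted only for `func` (default `bold`);
anything else is rejected rather than guessed. Entity keys follow the fixed
BIDS order (task, acq, ce, rec, dir, run, echo, part); unknown keys are
preserved with a warning so conversion can proceed with an audit trail.
A trailing `_SBRef` rewrites the suffix to `sbref` (single-band reference
volumes); `__dup<NN>` marks a superseded re-acquisition — within a group of
identically named series containing a dup marker, only the last acquired is
kept. When two *accepted* series render to the same path, run entities
(`run-01`, `run-02`, zero-padded to width 2 for lexicographic sorting; the
width is a config constant) are auto-assigned in acquisition order;
singletons carry no run entity, keeping names minimal. Subject ids come
from PatientID sanitized to `[A-Za-z0-9]`; the dataset locator from the
caret-separated study description. Session precedence: explicit `-ss`
override, then a `ses-` token in study metadata or series names, else
absent. The site-specific protocol-fixup table exists as an extension point
and ships empty.

## Outputs and idempotency

NIfTI-1 files carry the RAS affine in both sform and qform with code
"aligned" (2) for maximal downstream compatibility. Integer input dtypes
are preserved unless RescaleSlope/Intercept are nontrivial, in which case
data are promoted to float32 with the rescale applied. Gzip streams are
produced with a fixed zero mtime and sidecar JSON is written with sorted
keys, two-space indent and a trailing newline, so the idempotency contract
is byte-testable: the collision policy treats an existing identical file as
a no-op and an existing different file as an error unless `--overwrite`.
Dataset tables (participants, per-session scans) merge by key with sorted
rows and `n/a` for missing cells; conflicting rows for the same key are an
error rather than a silent overwrite. The shipped name validator checks
exactly the grammar subset this tool emits (entity order, datatype/suffix
compatibility, task-required rules) — it is a self-consistency gate, not a
replacement for the full ecosystem validator.

## Anonymization

Subject ids map through an operator table or an HMAC-SHA256 digest keyed by
the seed, truncated to 8 hex characters; collisions raise so the operator
can re-key. Timestamps shift by one constant offset per study, drawn
uniformly from ±[365, 730] days: a constant shift (rather than per-visit
jitter) preserves every pairwise interval exactly, keeping longitudinal
designs analyzable. Time-of-day is preserved. The raw→released map is
refused any path inside the output root. Default stripped sidecar fields:
PatientName, PatientID, AccessionNumber, operator/physician names,
institution address.

## Synthetic data

The generator emits one file per (slice, volume, echo) with consistent
UIDs under a reserved fake root, positions placed along a chosen normal
(axial, a supplied rotation, or a seeded random rotation), and deterministic
16-bit gradient pixel patterns, so voxel-conservation checks are exact
integer identities and the placement affine is known in closed form. It
emulates the *structural* properties conversion depends on — geometry,
timing tags, multi-echo layout, protocol naming, duplicate/corruption
scenarios — and none of the content properties of real data (anatomy,
noise, vendor private tags, mosaics, compressed syntaxes). Passing tests
therefore demonstrate correct grouping, geometry, naming and bookkeeping on
well-formed single-frame MR series, not robustness to every vendor quirk.
Default fixture sizes (4–8 pixel planes, 2–5 slices, 1–3 volumes) keep the
full randomized sweeps — 50 random rigid geometries, 200 grammar round
trips, multiple end-to-end CLI runs — in the tens of seconds while
exercising every code path at realistic structure.

## Numerical and degenerate-input choices

- Position clustering and orientation-consistency tolerance: 1e-4 (mm /
  cosine units); direction cosines must be unit-norm to 1e-4 at ingest.
- Single-slice series fall back to SpacingBetweenSlices, else 1 mm with a
  warning; a singular orientation block is an error.
- Duplicate instances (same series UID, instance and echo number) keep the
  lexicographically smallest file path — a deterministic choice that makes
  grouping invariant under input permutation — and warn about the rest.
- An incomplete slice×volume grid is an error listing the missing
  positions; a >1% spacing deviation is a warning, not an error, since
  variable-gap acquisitions exist legitimately.

## Known limitations

Diffusion bvec/bval extraction, slice-timing, phase-encoding metadata,
fieldmap IntendedFor wiring, mosaic decoding and enhanced multi-frame DICOM
are not implemented. The heuristic contract exposes two hooks; per-file
callbacks and pixel-inspecting heuristics are deliberately unsupported.
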
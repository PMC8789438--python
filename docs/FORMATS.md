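# File formats

All on-disk artifacts are either flat HDF5 containers (one dataset per
field) or plain TSV. Times are seconds from recording start; signals are
microvolts.

## Recording container (`<subject>.h5`)

| location            | content                                        |
|---------------------|------------------------------------------------|
| `samples`           | float64 (16, n_samples), μV                    |
| `events/onset`      | float64 (n_videos,) video onsets               |
| `events/video_id`   | int (n_videos,)                                |
| `events/video_class`| int (n_videos,), target = 1 / nontarget = 0    |
| `events/duration`   | float64 (n_videos,) clip lengths               |
| `events/target_onset`| float64 (n_videos,), NaN for nontarget videos |
| attrs               | `subject_id`, `fs` (Hz), `channels` (16 labels)|

A plain-text sidecar `<subject>.events.tsv` carries the same event table
(columns `onset  video_id  video_class  duration  target_onset`), written
with `%.17g` so values round-trip exactly.

EDF input: `<name>.edf` plus `<name>.events.tsv` is accepted by
`cobci.io.read_recording` when `mne` is importable (signal converted from
volts to μV). EDF output is not supported.

## Trial set (`<subject>.trials.h5`)

`trials` float64 (n, 16, 150), `labels` int (n,), `validity` bool (n,),
`trial_index` int (n,); attrs `subject_id`, `fs`.

## Aligned trial set (`<subject>.aligned.h5`)

`trials` float64 (n, 16, 100), `offsets` int (n,) chosen window starts,
plus the parent metadata (`labels`, `validity`, `trial_index`); attr
`subject_id`.

## ERP template (`template.h5`)

`series` float64 (100,), `weights` float64 (16,) CSP filter; attr
`crop_start`.

## P3 maps / selection report (TSV)

`select` writes two TSVs: the report (`subject_id  strength  group`) and
`*.maps.tsv` (`subject_id  peak_latency_ms` plus one column per channel
label).

## Experiment report (`report.tsv`)

One row per (framework, unit): `framework  unit  accuracy  hit_rate
false_alarm_rate  f1  tp  fp  tn  fn`, where `unit` is `fused`, `netK`, or
a subject id (single-mind rows). `config.yaml` alongside echoes the fully
resolved configuration.

## Network checkpoint (`.npz`)

One `numpy.savez` archive per unit: every parameter array by name plus
`_seed` (the unit's initialization seed).
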
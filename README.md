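# gazelab

Headless processing of wearable eye-tracking recordings for
psychophysiology research. `gazelab` ingests a recording folder in the
Pupil-Cloud-style CSV export dialect (Neon-class devices): raw gaze,
detected fixations / blinks / saccades, eye-state pupillometry, events,
and the surface-enrichment tables produced by Marker-Mapper- or
Reference-Image-Mapper-style post-processing. It then

1. builds named **epochs** from the event stream (or from a replacement
   event table, for alignment with another device),
2. gates every stream by **ROI membership** ("detected on ROI") using
   the enrichment flags,
3. extracts a per-epoch **feature battery** — blink, fixation, gaze
   movement, saccade, and pupillometry indices,
4. runs **pupillometry spectral analysis** (Welch periodogram and
   spectrogram) and prepares the standard plot set (ROI-coloured pupil
   series, blink pulse train, saccade velocity/amplitude series,
   fixation cloud with Gaussian KDE, scan paths, histograms),
5. applies the **blink-count exclusion filter** and exposes an
   independent-samples *t*-test for condition comparisons.

A synthetic-recording generator with an exact ground-truth manifest
makes the whole pipeline testable with no hardware and no download.

## The quantities it computes

For every epoch `[t_i, t_{i+1})` delimited by consecutive events:

* **Blink**: count `n`, total / mean duration, and the "surface"
  duration — the summed duration of blinks flagged on-ROI.
* **Fixation**: count, duration statistics (Σ, mean, max/min), centroid
  of the longest fixation, mean position, and consecutive-centroid
  distances `d_k = ‖c_{k+1} − c_k‖₂` in scene pixels (absolute) and
  surface-normalised units (relative).
* **Gaze**: sample counts (total, per fixation, per movement) and
  inter-fixation movement metrics — for the gaze run between fixations
  *k* and *k+1*, the path length `Σ‖p_{j+1} − p_j‖₂` and the first-to-
  last displacement.
* **Saccade**: count, duration and amplitude statistics, mean-velocity
  statistics, and the overall peak velocity `max_k v_peak,k`.
* **Pupillometry**: first/last, max/min, and mean diameter (mm), plus
  the on-ROI-restricted mean.

Summary statistics use the population standard deviation
`σ = sqrt(1/n Σ (x_i − x̄)²)` (divisor `n`, not `n−1`).

## Worked example (no hardware needed)

```sh
# write a synthetic recording with a 4-dilemma task schedule
gazelab simulate --out demo/rec --mdmt 4 --seed 42
# run the full pipeline
gazelab process --folder demo/rec --participant P01 --out demo/out \
    --plots blink_series,fixation_cloud,periodogram
```

prints

```
wrote synthetic recording to demo/rec (27594 gaze samples, 41 blinks)
wrote demo/out/P01_features.csv
wrote demo/out/P01_report.txt
wrote demo/out/P01_00_blink_series.png
wrote demo/out/P01_01_fixation_cloud.png
wrote demo/out/P01_02_periodogram.png
```

and the text report opens with the first inter-stimulus epoch:

```
== Epoch: 000:isi ==
  [epoch]
    duration_ms: 1000 ms
  [blink]
    count: 0
    duration_total_ms: 0 ms
  [fixation]
    count: 3
    duration_total_ms: 879.494 ms
    duration_mean_ms: 293.165 ms
    ...
```

Three fixations averaging 293 ms fell inside the 1 s inter-stimulus
window, with no blinks; the accompanying `P01_features.csv` holds the
same values as a tidy table (one row per epoch × category × index,
with units). Epochs with more than five blinks are excluded by the
acquisition-error filter and listed in the report
(`--blink-threshold` changes the cut-off; raise it when analysing a
whole recording as a single epoch).

Replacement events are a two-column CSV:

```
name,timestamp [ns]
baseline,0
stimulus,5000000000
end,12000000000
```

`gazelab process --events my_events.csv ...` rebuilds all epochs from
this table instead of the cloud events.

## Library use

```python
import dataclasses
import gazelab as gl
from gazelab.movements import index_movements

rec = gl.load_recording("demo/rec", participant="P01")
rec = gl.annotate_recording(rec)                 # adds on_roi flags
rec = dataclasses.replace(rec, gaze=index_movements(rec.gaze))
epochs = gl.build_epochs(rec.events)
report = gl.extract_report(rec, epochs, "P01")
report, excluded = gl.filter_epochs_by_blinks(report)  # > 5 blinks out
res = gl.two_sample_ttest(group_a, group_b)      # pooled Student's t
```

## Recording folder dialect

One folder, comma-separated UTF-8 tables with a header row. Canonical
names (header matching is case-insensitive and ignores bracketed unit
suffixes; column order is free):

| file | columns |
|---|---|
| `gaze.csv` | `timestamp [ns]`, `gaze x [px]`, `gaze y [px]`, `worn`, `fixation id`, `blink id` |
| `fixations.csv` | `fixation id`, `start timestamp [ns]`, `end timestamp [ns]`, `duration [ms]`, `fixation x [px]`, `fixation y [px]` |
| `blinks.csv` | `blink id`, `start timestamp [ns]`, `end timestamp [ns]`, `duration [ms]` |
| `saccades.csv` | `saccade id`, start/end/duration, `amplitude [px]`, `mean velocity [px/s]`, `peak velocity [px/s]` |
| `3d_eye_states.csv` | `timestamp [ns]`, `pupil diameter left [mm]`, `pupil diameter right [mm]` |
| `events.csv` | `name`, `timestamp [ns]` |
| `enrichment_gaze.csv` | `timestamp [ns]`, `gaze detected on surface`, surface x/y `[normalized]` |
| `enrichment_fixations.csv` | `timestamp [ns]`, `fixation detected on surface`, fixation x/y `[normalized]` |

The enrichment tables are required in this version: ROI membership is
consumed from them, never recomputed. See `docs/methods.md` for the
processing model, parameter defaults, and known limitations.
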
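# snorevol

Calibration-free estimation of qualitative tidal-volume levels
(high / medium / low) from single-channel tracheal sound.

A nocturnal recording is bandpass-filtered (50–2450 Hz Butterworth,
zero-phase), downsampled to 5 kHz, and cut into one-minute clips.  Clips
are described by frame-averaged MFCC vectors (40 Mel filters, 1000 ms
windows, 500 ms hop) and grouped by agglomerative hierarchical clustering
into snoring / normal / uncertain.  Snoring clips are split into simple
vs. apneic snoring by k = 2 K-means on a two-dimensional formant feature
(standard deviation of episode F1 and of snore onset intervals; F1 from
14th-order LPC via Levinson–Durbin on 20 ms Hamming frames).  A rule table
then assigns the level per minute:

| clip state                          | level     |
| ----------------------------------- | --------- |
| apneic snoring, max pause ≤ 10 s    | medium    |
| apneic snoring, max pause > 10 s    | low       |
| simple snoring, run < 4 min         | high      |
| simple snoring, run ≥ 4 min         | medium    |
| normal respiration                  | high      |
| uncertain (signal too weak)         | uncertain |

When a synchronized 1 Hz SpO₂ trace is supplied, predictions are scored
against per-minute lowest-saturation levels (> 95 % high, 90–95 % medium,
< 90 % low) with accuracy = correct / (total − uncertain).

A synthetic-data module generates labeled recordings (source-filter snore
synthesis, noise-burst breathing, near-silent uncertain minutes) plus
consistent SpO₂ traces, so the whole pipeline is testable without any
clinical data.

## CLI

Generate a synthetic scenario, run the pipeline, and score it:

```sh
cat > plan.yaml <<EOF
labels: [normal, normal, simple, simple, simple, simple, simple,
         apneic, apneic, uncertain, normal, normal]
pause_s: [null, null, null, null, null, null, null, 8.0, 20.0, null, null, null]
EOF

snorevol synth --plan plan.yaml --seed 17 --out scenario/
snorevol run scenario/audio.wav --spo2 scenario/spo2.csv --out results/
snorevol eval results/results.csv scenario/truth.csv
```

`snorevol run` writes `results.csv` (per-clip label, pause statistics,
predicted and reference levels), `summary.json` (accuracy and counts) and a
four-panel `summary.png`.  Real recordings go in as WAV; the SpO₂ trace as
a `time_s,spo2_percent` CSV at 1 Hz.  `--config config.yaml` overrides any
pipeline parameter; `--label-map snoring=1,normal=2,uncertain=3` replaces
the automatic loudness-based cluster naming.

## Layout

- `src/snorevol/io.py` — WAV / SpO₂-CSV / results-CSV reading and writing
- `src/snorevol/preprocess.py` — bandpass, downsample, segmentation
- `src/snorevol/mfcc.py` — Mel filterbank, MFCC, clip features, distances
- `src/snorevol/clustering.py` — AHC, tree cutting, semantic labels
- `src/snorevol/formants.py` — LPC, formants, snore episodes, K-means typing
- `src/snorevol/rules.py` — breath events, MBPI, rule table
- `src/snorevol/evaluation.py` — LoO₂ levels and accuracy
- `src/snorevol/synthetic.py` — scenario generators
- `src/snorevol/pipeline.py`, `src/snorevol/cli.py` — orchestration and CLI
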
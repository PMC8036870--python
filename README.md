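# respicam

Camera-based respiration monitoring for infants, applicable to thermal
(60×80, three merged views) and grayscale-converted RGB video (192×256)
without requiring skin visibility. Two stages:

1. **Gross-motion detection** — frame differencing with a range-adaptive
   threshold (`thr1 = Range(X)/f1`) flags 8 s windows in which the fraction
   of moving pixels reaches `thr2` in any view (type-1 motion: chest/torso
   movement that hides respiration). `(f1, thr2)` are optimized by
   leave-one-subject-out cross-validation on balanced accuracy; defaults are
   `f1 = 8`, `thr2 = 0.005`.
2. **Respiration-rate estimation** — in usable windows, three per-pixel
   features (pseudo-periodicity of the differenced spectrum, a 3×3
   frequency-cluster filter with harmonic disambiguation and supra-band
   suppression, and a binary edge map of the window-average image) are
   min-max normalized and multiplied to locate a core respiration pixel.
   Pixels whose band-passed (0.5–1.83 Hz Butterworth) series correlate with
   the core above 0.9 are averaged; the Hanning-windowed, 120×-zero-padded
   spectral peak gives the rate in BPM. Per-window spectra stack into an
   STFT. The same spectral path extracts the reference rate from a
   chest-impedance-like waveform.

Since clinical recordings are private, the `synthetic` module generates
seeded, annotated scenes (breathing cluster with optional first harmonic,
sensor noise, type-1/type-2/NNS/excluded events, jittered timestamps,
paired reference waveform) so every stage is testable end to end.

## CLI

```bash
respicam synth --spec scene.yaml --out rec/            # synthetic recording
respicam motion --video rec/ --annotations rec/annotations.csv --out motion.csv
respicam rr --video rec/ --reference rec/reference.csv --out rr.csv --stft stft.csv
respicam optimize --subjects manifest.csv --out params.json
respicam eval --rr rr.csv --truth rec/truth.csv --out report.json
respicam run --scene scene.yaml --out results/         # end to end
```

A scene YAML for `synth`/`run`:

```yaml
shape: [60, 80]
duration_s: 30.0
noise_sigma: 0.05
cluster: {region: [20, 40, 30, 55], rr_bpm: 45.0, amplitude: 1.0, edge_step: 5.0}
events:
  - {kind: type1, start_s: 12.0, duration_s: 2.0, area_fraction: 0.02, magnitude: 20.0}
  - {kind: nns, region: [2, 8, 2, 8], freq_hz: 2.5, amplitude: 1.0}
seed: 1
```

Pipeline parameters (rates, window/slide, `f1`, `thr2`, `kappa1..3`, band
limits, grids) live in a single config file (`--config cfg.yaml`) with
published defaults; the effective config is dumped next to the outputs.

## Layout

- `src/respicam/preprocess.py` — resampling, grayscale, downscale, view
  merging, gap splitting, sliding windows
- `src/respicam/motion.py` — moving-pixel ratio, window classification,
  ground-truth labelling, LOSO parameter optimization
- `src/respicam/rr.py` — spectral context, per-pixel features, core/pixel
  selection, rate estimation, reference path, STFT assembly
- `src/respicam/synthetic.py` — seeded annotated scene generator
- `src/respicam/evaluate.py` — MAE/RMSE/PR/PT, classification metrics,
  Bland–Altman, Pearson
- `src/respicam/cli.py` — subcommands and `run_pipeline`
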
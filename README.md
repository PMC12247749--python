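# fusctl

Closed-loop microbubble focused-ultrasound (FUS) cavitation control toolkit:
a per-pulse acoustic-emission (AE) simulator, a broadband-emission safety
predictor, a family of sonication controllers, and the statistics used to
evaluate them.

During a sonication (130 s of 10 ms pulses at 1 Hz, 0.5 MHz), circulating
microbubbles re-radiate harmonics and ultra-harmonics of the drive
frequency; sudden broadband energy (≥ 6 dB above baseline in the 7.22·f0
bin) marks inertial bubble collapse and tissue-damage risk. This package
implements:

- **`fusctl.spectral`** — frequency bands at 0.5·n·f0 (±0.3 kHz) plus the
  broadband bin, dB-re-baseline feature extraction from pulse spectra, and
  the 6 dB event rule (`AEFrame` records).
- **`fusctl.simulate`** — a stochastic surrogate generator: bolus
  microbubble kinetics (species-dependent clearance), a linear-then-plateau
  pressure→7th-harmonic dose response, a latent instability accumulator
  giving rare (~8% at high exposure) broadband events with learnable
  ultra-harmonic precursors, tumor/bolus effects, and a synthetic
  permeability (K_trans-like) read-out. Fully seeded and bit-reproducible.
- **`fusctl.predict`** — dataset assembly with next-pulse labels, 1:1
  under-sampling (and over-sampling) of the training split, a 12-10-1
  sigmoid MLP (141 parameters) trained by Levenberg–Marquardt with
  validation early stopping, confusion metrics, permutation-sampling
  Shapley attributions, and top-k feature selection.
- **`fusctl.amp`** — the attentive variant: cross-attention between
  patient-specific features (query) and harmonic/ultra-harmonic token
  blocks (keys/values), weighted cross-entropy (positive weight
  ε·N_total/N_pos), dropout/L2/layer-norm, stratified 10-fold CV.
- **`fusctl.control`** — open-loop (OL), closed-loop (CL), and ML-assisted
  closed-loop (MLCL) controllers sharing the microbubble-tracking gate
  (+10 dB H4 turn-on, clearance-slope recording, cease at 20% normalized H4
  decay with pressure hold), the 5% reactive safety drop on events, and the
  predictive override that acts on predicted events as if they had
  occurred.
- **`fusctl.evaluate`** — event/prediction rates, percent reductions,
  hyper-tangent fits with inflection-based treatment-window bounds,
  distribution statistics (mean, SD, adjusted skewness), F and
  Brown–Forsythe Levene variance tests.
- **`fusctl.io` / `fusctl.cli`** — YAML experiment configs (strict keys),
  CSV record/dataset serialization with JSON manifests, portable JSON model
  weights, and the command-line surface.

## CLI

```bash
fusctl simulate --seed 1 --out runs/ --n-runs 8 --pressure 0.3
fusctl build-dataset --records-dir runs/ --feature-set 12 --out ds.csv
fusctl train --dataset ds.csv --model mlp --seed 1 --out mlp.json
fusctl evaluate --dataset ds.csv --model mlp.json
fusctl shap --dataset ds.csv --model mlp.json --top-k 7
fusctl run-experiment --seed 1 --out exp/        # MLCL, CL, OL(P_Avg), OL(P_Max)
fusctl summarize --records-dir exp/
fusctl window-analysis --records-dir exp/ --lower-bound 0.17
```

`run-experiment` trains the predictor on constant-pressure training runs,
runs the ML-assisted arm, derives the open-loop pressures from its mean and
max commanded pressure, and writes per-arm record CSVs, a summary table,
and a manifest that reproduces everything from the root seed.

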
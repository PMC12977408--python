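# dyadsync

Analysis pipeline for dyadic fNIRS hyperscanning experiments: from raw
two-wavelength optode intensities to interbrain synchrony (IBS) statistics,
with a matched behavioral pathway (speech and cursor-trajectory features) and
a fully synthetic study generator with known ground truth.

The intended design is a two-person collaborative task (a "Guide" instructs,
a "Drawer" acts) recorded simultaneously with 16-channel prefrontal/
temporoparietal fNIRS at 7.81 Hz, with a mid-task disruption splitting the
session into pre/post periods and two groups (control/experimental).

## What it does

- **`dyadsync.synth`** — generates complete synthetic studies: coupled
  band-limited (0.01–0.08 Hz) hemodynamics per region of interest (ROI) with
  a tunable interbrain coupling `kappa`, realistic systemic physiology
  (cardiac/Mayer/respiratory), Beer–Lambert forward model to optode
  intensities, motion artifacts, dead channels, speech streams, cursor
  trajectories — and the ground truth for all of it.
- **`dyadsync.preprocess`** — intensity → optical density → motion detection
  → spline + wavelet correction → PCA systemic removal → modified
  Beer–Lambert concentrations → channel quality (cardiac-peak criterion) →
  ROI averaging with exclusion rules (all-bad ROI discarded; a participant
  missing more than one ROI is excluded).
- **`dyadsync.ibs`** — analytic-Morlet wavelet transform coherence (WTC)
  with cone-of-influence (COI) masking, IBS level/slope features, and
  recurrence quantification (RR, %DET) of the coherence time series; a
  caching engine makes the all-pairs permuted-dyad control cheap.
- **`dyadsync.behavior`** — speech features (total speaking time,
  Guide/Drawer speech ratio) and trajectory path error (exact
  point-to-polyline distance).
- **`dyadsync.stats`** — linear mixed models with likelihood-ratio tests:
  Time × Group hypothesis tests per IBS feature, real-vs-permuted and
  manipulation-check control analyses, behavioral-delta moderation, effect
  standardization, and a simulation-based sensitivity (power) analysis.
- **`dyadsync.pipeline` / CLI** — config-validated, cached, provenance-logged
  orchestration of the whole chain from a study manifest to a results JSON.

## Quick start

```bash
# generate a synthetic study and analyze it end to end
dyadsync pipeline demo --seed 7 --n-dyads 10 --out demo/

# or step by step
dyadsync synth --seed 1 --n-dyads 10 --out study/
dyadsync pipeline run --manifest study/study_manifest.csv --out results/
dyadsync stats run --features results/features.csv --out results/
dyadsync stats power --config power.yaml --out results/
```

Outputs under `results/`: `features.csv` (IBS level/slope/%DET per dyad ×
ROI × period), `permuted_features.csv`, `behavior.csv`, `difficulty.csv`,
`results.json` (every LRT, effect size, R²), `run_record.json` (config,
seeds, content hashes) and `run_log.jsonl` (one entry per stage per dyad).

From Python:

```python
from dyadsync import synth, pipeline

manifest = synth.write_study(synth.SimParams(n_dyads=10, rng_seed=1), "study")
record = pipeline.run_pipeline(manifest, out_dir="results")
```

## Testing

```bash
python -m pytest -q tests/                 # unit + property + acceptance
python scripts/acceptance.py --seed 0 --out acceptance.json
```

`tests/test_acceptance.py` asserts the release criteria (COI constant, WTC
validity, coupling recovery, real-vs-permuted control, RQA oracle, slope
recovery, statistical calibration, behavioral geometry, exclusion logic);
`scripts/acceptance.py` recomputes the headline quantities and writes them
to JSON for inspection.

See `docs/methods.md` for the scientific conventions (wavelet and COI
definitions, RQA parameters, model structures) and the reasoning behind
them.
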
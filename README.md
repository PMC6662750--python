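# circaphase

Circadian phase prediction from ambulatory blue-light irradiance and skin
temperature, using a lagged-input multilayer perceptron trained with
resilient backpropagation against melatonin / urinary-aMT6s reference
waveforms. The package covers the full pipeline — channel cleaning and
binning, reference-curve fitting (bimodal skewed baseline cosine for
melatonin, 24-h cosine for aMT6s excretion rate), centre-of-gravity phase,
leave-one-out cross-validated training, error summaries and comparator
estimators (mid-sleep, normal-range guess, resampling guess) — together
with a synthetic-cohort generator with known ground-truth phase, so every
stage is testable without real recordings.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, one test per acceptance
criterion; the two pipeline-level criteria train networks on synthetic
cohorts and take a few minutes on one CPU.

## CLI

Each command takes `--config config.yaml --in DIR --out DIR --seed N`;
config keys mirror `circaphase.config.RunConfig`.

```bash
circaphase simulate       --out cohort/ --seed 1 --n 8 --schedule FS
circaphase preprocess     --in cohort/ --out pre/
circaphase fit-reference  --in cohort/ --out ref/ --source aMT6s
circaphase train          --in cohort/ --out model/ --config config.yaml
circaphase predict        --in other_cohort/ --model model/model.json --out pred/
circaphase evaluate       --in cohort/ --out eval/
```

Cohort directories hold one subdirectory per participant with plain CSV
tables (`actigraphy.csv`, `temperature.csv`, `sleep.csv`, `urine.csv`,
optional `melatonin.csv`, `inlab.csv`, `removal_log.csv`); timestamps are
ISO-8601 civil local time.

## Library layout

| module | contents |
| --- | --- |
| `circaphase.io` | CSV cohort reading/writing, result tables |
| `circaphase.config` | `RunConfig`, named seed substreams |
| `circaphase.preprocess` | cleaning, detrending, AR gap filling, 30-min binning |
| `circaphase.reference` | BSBCF/cosine fitting, excretion rates, CoG phase, reference waveforms |
| `circaphase.network` | lagged designs, Rprop MLP training, LOOCV, final models |
| `circaphase.evaluate` | predicted phase, error summaries, circular correlation, comparators |
| `circaphase.simulate` | synthetic cohorts, schedules, signals, artefact fixtures |
| `circaphase.pipeline` | end-to-end orchestration used by the CLI and tests |
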
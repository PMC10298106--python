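# dwellkin

Dwell-time kinetics of two-duplex protein–DNA complexes observed one molecule
at a time. The package models a protein bridging two DNA duplexes as a
two-step dissociation chain (`state 2 ↔ state 1 → state 0`) and explains why
mixed specific/non-specific ("pre-synaptic") complexes outlive fully specific
ones: a weak bond on a duplex with many binding registers rebinds often, and
this entropic multiplicity (m = length − footprint + 1 registers) stretches
the mean first-passage time to full dissociation.

It provides, end to end:

- **`kinetic_model`** — closed-form MFPT lifetimes for the three complex
  classes (`ss`, `nn`, `ns`), bond-energy/parameter conversions, a linear-solve
  MFPT oracle, and length-generalized predictions.
- **`stochastic_sim`** — exact (Gillespie) simulation of the scheme, used both
  as a data generator and as an independent check of the closed forms.
- **`synthetic_data`** — synthetic single-molecule fluorescence traces
  (100 ms frames, Gaussian baseline noise, Poisson-arrival square bursts) and
  dwell-time datasets, fully reconstructible from config + seed.
- **`event_detection`** — thresholded burst detection (gap bridging, minimum
  dwell, censoring flags) and a ground-truth recovery harness.
- **`survival_analysis`** — normalized survival curves, fixed-amplitude
  single-exponential least-squares fits with bootstrap SDs and an MLE
  cross-check, and two-sample Kolmogorov–Smirnov comparison.
- **`model_fitting`** — estimation of the parameter triple (x, y, u) from a
  measured lifetime triple, including the exact-nn/ss profile over u that
  exposes the system's weak identifiability.
- **`pipeline`/CLI** — config-driven deterministic runs with machine-readable
  reports, plus comparison against the published reference lifetimes bundled
  in `dwellkin.reference`.

## CLI

```sh
# sample dwell times from the ns scheme at the published parameters
dwellkin simulate --x 1.7 --y 5.0 --u 4.6 --kind ns -n 3000 -o dwells.csv

# fit the survival curve of a dwell CSV
dwellkin survival dwells.csv -o fit.json

# detect bursts on a trace CSV (columns time_s, intensity_au)
dwellkin detect trace.csv -o events.csv

# invert a measured lifetime triple to (x, y, u)
dwellkin fit-model --t-nn 12.6 --t-ss 29.6 --t-ns 44.7 -m 11

# tabulate predictions for 23/33 bp duplex pairs
dwellkin predict --x 1.7 --y 5.0 --u 4.6 -o predictions.csv

# full pipeline from a YAML/JSON config, then compare to published values
dwellkin run config.yaml -o out/
dwellkin compare out/report.json
```

A minimal run config:

```yaml
params: {x: 1.7, y: 5.0, u: 4.6}
master_seed: 20230606
trace: {duration: 3600.0, arrival_rate: 0.01}
conditions:
  - {label: ss-23, kind: ss, n_events: 3000}
  - {label: nn-23, kind: nn, n_events: 3000}
  - {label: ns-23, kind: ns, n_events: 3000}
```

## Notes on published values

The published 33 bp / mixed-length "theory" lifetimes are not reproducible
from the published parameter triple with the multiplicity rule; both the
printed values and the recomputed ones are exposed side by side
(`dwellkin.reference`, `dwellkin compare`) rather than reconciled. Likewise
the printed non-specific bond energy (~0.6 kT) differs from the
parameterization's 2·ln(1.7) ≈ 1.06 kT; conversions follow the formula, and
the printed number is kept only as a reference constant.
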
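# pvgamma

Toolkit for two linked analyses of parvalbumin-interneuron (PVI) biology in
prefrontal cortex:

1. **Cohort arm** — a synthetic matched-pair cohort generator
   (`synthetic_cohort`), per-cell quantification utilities (`cellquant`), and
   the statistical pipeline used on such data (`cohort_stats`): one-way ANOVA
   with Tukey HSD, paired (pair-blocked) and unpaired ANCOVA with type-III
   partial F tests and single-pass covariate retention, co-occurring-factor
   scans, correlations and fold changes. The generator encodes configurable
   multiplicative group effects (e.g. a 29% cytoplasmic Rbfox1 deficit),
   interneuron-subtype enrichment folds and cell-level correlations, so the
   whole pipeline is testable end to end without any external data.
2. **Simulation arm** — a quadratic integrate-and-fire network of 80
   pyramidal neurons and 20 fast-spiking PVIs (`netmodel`) with
   conductance-based AMPA/NMDA/GABA synapses and Bernoulli release
   probability on PVI→pyramidal synapses, spectral/spike-train readouts
   (`spectral_metrics`), and trial-averaged experiments (`experiments`):
   release-probability sweeps, plateau (nadir) detection, and the
   inhibitory-strength × release-probability synergy analysis.

## Quick start

```python
import numpy as np
from pvgamma import synthetic_cohort as sc, cohort_stats as cs
from pvgamma.netmodel import NetworkConfig
from pvgamma.experiments import rp_sweep, detect_nadir

# cohort arm: generate a 20-pair cohort and estimate the group deficit
ds = sc.generate_cohort(sc.CohortConfig(), seed=1)
res = cs.run_diagnosis_test(ds, "cytoplasmic_rbfox1", model="paired")
print(res.percent_difference, res.p)

# simulation arm: gamma power across release probabilities
sweep = rp_sweep(NetworkConfig(), np.linspace(0.5, 1.0, 11),
                 n_trials=20, master_seed=1)
print(detect_nadir(sweep.values, sweep.gamma_power).onset)
```

## CLI

```bash
pvgamma cohort generate --seed 1 --out out/cohort
pvgamma stats run --cells out/cohort/cells.csv --subjects out/cohort/subjects.csv \
    --measure cytoplasmic_rbfox1 --model paired
pvgamma net simulate --rp 0.85 --trials 5 --seed 1 --out out/sim
pvgamma exp rp-sweep --trials 20 --seed 1 --out out/sweep --plot
pvgamma exp synergy --trials 20 --seed 1 --out out/synergy
```

Network parameters can be overridden with a YAML/JSON file mirroring
`NetworkConfig` (see `netmodel.NetworkConfig.to_dict()` for the schema).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` re-derives the headline results (sweep landmarks,
synergy crossover, ANCOVA parameter recovery, enrichment folds) at a reduced
20-trial scale; the full suite takes ~5 minutes on one CPU, dominated by the
network simulations. One acceptance test is expected to fail: the
rate/synchrony dissociation criterion holds for pyramidal rates and CV_ISI
but PVI rates rise ~35% across the sweep in this parameterization (a known,
documented deviation).

## Notes on units

The network uses arbitrary "model units": voltages in mV and time in ms, with
conductances and applied currents scaled by a common capacitance constant
chosen so the baseline inhibitory strength G_I→E = 0.7 sits just above the
network's synchronization margin (the regime in which lowering either G_I→E
or the release probability RP_I→E collapses gamma power).
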
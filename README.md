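# obpc

A simulator of the olfactory bulb (OB) and piriform cortex (PC) circuit with
location-specific norepinephrine (NE) modulation, Hebbian learning on
cortical association fibers, and the detection / sparseness statistics used
to analyze it.

Seven populations of 100 neurons each (sensory channels, periglomerular,
two-compartment mitral, granule cells in the bulb; pyramidal, feedforward
and feedback interneurons in the cortex) are integrated with a fixed-step
Euler scheme (0.5 ms). A scalar NE concentration per structure is mapped
through receptor-occupancy dose-response curves onto a handful of cell and
synapse parameters; opposing high- and low-affinity receptor effects on
granule cells produce a non-monotonic dose-response of mitral spontaneous
activity. Pyramidal-to-pyramidal synapses learn by an NMDA-style
coincidence rule with global weight normalization, supporting
odor-associative recall.

## Layout

| module | contents |
| --- | --- |
| `obpc.core` | membrane / transfer / conductance / spiking / adaptation primitives |
| `obpc.network` | wiring, odor stimuli, configuration, the simulation loop |
| `obpc.neuromod` | NE dose-response curves and parameter modulation |
| `obpc.plasticity` | association-fiber learning rule, initialization, normalization |
| `obpc.metrics` | windowed rates, detection index, sparseness, statistics |
| `obpc.experiments` | detection grids, locus knockouts, learning/recall, perturbed recall |
| `obpc.cli` | `obpc` command-line interface |
| `obpc.configio` | YAML/JSON configuration round-trip |

## CLI

```bash
obpc simulate    --seed 1 --ne 1.0 --concentration 0.8 --out runs/demo
obpc detect-grid --seed 1 --grid 10 --repeats 3 --out runs/grid
obpc knockout    --seed 1 --grid 5 --repeats 2 --out runs/ko
obpc learn       --seed 1 --repeats 10 --out runs/learn
obpc perturb     --seed 1 --repeats 10 --out runs/perturb
obpc make-odor   --seed 7
obpc plot        --grid-csv runs/grid/detection_grid.csv --out grid.png
```

Every command accepts `--config net.yaml` with partial overrides of the
checked-in default parameter profile (see `obpc.configio` for the schema)
and derives all randomness from `--seed`. `detect-grid --paper-scale` runs
the full 30 x 30 grid with 40 repeats per point.

## Notes on calibration

Four quantities are not fixed by the reference parameter table and are
treated as documented calibration constants (all exposed in
`NetworkConfig` / `DEFAULT_CURVES`): the receptor half-max concentrations,
the feedback-interneuron connectivity fractions, a scale on the
per-timestep spiking probability, and the sensory input gain. The defaults
are chosen so the published qualitative regimes (nonzero spontaneous
baselines, non-monotonic NE dose-response, selective associative learning
at low odor concentration) are reproduced at desk scale.
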
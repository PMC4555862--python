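# rstarsim

Stochastic two-species resource competition on an R* fitness-inequality
gradient.

Two consumers compete for one mineral resource in an open (chemostat-like)
system with Monod growth kinetics.  Each consumer is summarised by its
break-even resource concentration `R* = D*K/(mu - D)`; the species with the
lower R* is the deterministically more fit competitor.  The package

- builds a mirrored linear R* gradient (default 35 points over
  1.10–1.78 µmol/L, with fitness equality at the central point) and derives
  per-species growth parameters (`mu` or `K`) for any dilution rate;
- steps the coupled consumer–resource system forward either
  deterministically or with demographic stochasticity (Poisson births and
  deaths around the deterministic expectations, mortality capped at the
  current population, uptake never exceeding the available resource);
- runs the full replicated experiment (grid points × initial population
  sizes 1–512 × replicates), classifies each run into five outcomes
  (more/less fit dominant, dominance at equality, co-persistence, dual
  extinction) and computes per-category percentage grids;
- writes long-format results CSV, per-category summary grids, a JSON run
  manifest, and optional heat-map plots.

## CLI

```sh
# parameter-space table (35 rows)
rstarsim space --regime high_growth --out space.csv

# one trajectory; prints the final state, optionally dumps a CSV
rstarsim simulate --regime low_growth --mode stochastic --point 18 \
    --n0 16 --seed 1 --out traj.csv --stride 100

# replicated sweep -> records.csv, freq_<category>.csv, manifest.json
rstarsim sweep --regime low_growth --reps 20 --seed 1 --out-dir results/

# grids / plots from an existing records CSV
rstarsim summarize --input results/records.csv --out-dir results/
rstarsim plot --input results/records.csv --out-dir results/
```

All commands accept `--config` pointing at a flat YAML file whose keys match
`SimulationConfig` fields (unknown keys are rejected); absent keys take the
canonical defaults (D=0.1/d, I=10 µmol/L, Q=1e-6 µmol/individual, 35 points,
100 replicates, 20 000 steps).  The full-design sweep
(35 × 10 × 100 × 20 000 steps) takes on the order of 15–30 minutes per
regime on one CPU; use `--reps`/`--points`/`--horizon` for desk-scale runs.

Reproducibility: every replicate has an independent seed stream derived from
`(base_seed, regime, varying, dilution, point_index, n0, replicate)`, so the
same `--seed` reproduces results bit-for-bit and any single replicate can be
re-run in isolation.

## Library example

```python
from rstarsim import SimulationConfig, run_sweep

cfg = SimulationConfig(regime_label="high_growth", n_replicates=20,
                       base_seed=1)
result = run_sweep(cfg)
grids = result.frequencies()          # {category: point x size % DataFrame}
```
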
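# adaptrex

Adaptive temperature replica-exchange ("dynamic walker") simulation toolkit
with self-guided Langevin dynamics and protein-refinement analytics.

The package implements, as a testable desk-scale simulator:

- **`adaptrex.ladder`** — geometric temperature ladders and feedback-driven
  re-placement of temperatures: cold/hot visit histograms, the fraction-cold
  profile, isotonic inversion at index-linear targets, and the
  two-geometric-units maximum-spacing constraint.
- **`adaptrex.exchange`** — Metropolis neighbor swaps (alternating even/odd
  parity), cold/hot walker labeling, round-trip accounting and per-pair
  exchange-rate statistics.
- **`adaptrex.dynamics`** — BAOAB-split Langevin and self-guided Langevin
  (SGLD) integrators; the guiding force is `lambda * gamma * <p>_L` with the
  momentum memory kept as a recursive exponential moving average.
- **`adaptrex.models`** — synthetic energy models (harmonic well, quartic
  double well, structure-based Gō-type bead model with its minimum at a
  reference native) plus decoy-ensemble generation with controlled noise.
- **`adaptrex.metrics`** — fraction of native contacts (side-chain-center
  pairs under a strict 6.5 Å cutoff) and Kabsch RMSD (proper rotations only).
- **`adaptrex.reporting`** — rank-ordering, ΔE/f_N population-density grids,
  ladder-history snapshots, and marginal averages over the packaged
  benchmark score table (`adaptrex/data/benchmark_scores.csv`).
- **`adaptrex.runner` / `adaptrex.cli`** — YAML-configured orchestration of
  full static/adaptive runs, with bit-reproducible outputs given a seed.

## CLI

```sh
adaptrex run --config run.yaml --out outdir/      # full simulation
adaptrex adapt-ladder --histogram hist.csv --out ladder.csv
adaptrex metrics --native native.pdb --decoys decoys.pdb --out metrics.csv
adaptrex aggregate --method adaptive              # score-table margins
adaptrex compare outdir_a/ outdir_b/              # two finished runs
```

A minimal run config:

```yaml
model: {kind: double_well, barrier: 5.0, x0: 1.0}
t_min: 1.0
t_max: 20.0
n_replicas: 8
ladder_mode: adaptive   # or static
seed: 1
total_rounds: 10000
steps_per_swap: 5
dt: 0.05
gamma: 1.0
lam: 1.0
t_l: 0.5
```

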
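# mpsnet

Multi-pathway spatial networks (MPSN), a discrete-time SEI diffusion
simulator, structural bound checkers, and factorial-sweep / regression-tree
analytics for studying multi-scale biological-invasion dynamics.

An MPSN instance is a lattice of `n` vertices partitioned into `k` square
regions, each holding one `√s × √s` locality centered in the region, with
three superposed edge layers:

* **S** — short-range: all vertex pairs within Euclidean distance `r`;
* **L** — intra-locality: one copy of a template graph (complete / star /
  custom) per locality;
* **LD** — long-distance: cross-locality pairs induced by an Erdős–Rényi
  inter-locality graph with edge probability `min(1, ε/k)`.

The SEI process transmits along each labeled edge with probability
`1 − exp(−α·ρ)` (flow-weighted for LD), with a latency `ℓ` between exposure
and infectiousness.

## Library overview

| module | contents |
| --- | --- |
| `mpsnet.graph_model` | `MPSNParams`, validation, lattice/locality builders, the three layer builders, `assemble` |
| `mpsnet.structure` | `spectral_radius`, `spectrum`, `diameter`, `graph_power`, sandwich/degree checks, spectral-bound reports, diameter scaling tables |
| `mpsnet.spread_sim` | `SpreadParams`, `InfectivitySchedule`, `run`, `run_ensemble`, `pathway_unravel` |
| `mpsnet.analytics` | factorial designs (published grids included), structural/dynamics sweeps, CART/random-forest importances, hyperparameter robustness scans |
| `mpsnet.io_realworld` | TSV round trips for instances, temporal directed weighted flow networks (loader, synthesizer, monthly matrices, per-month spectral/diameter profiles) |

```python
from mpsnet import MPSNParams, assemble, theorem51_report, run_ensemble, SpreadParams

g = assemble(MPSNParams(n=4096, r=2, k=16, s=16, epsilon=1, rng_seed=0))
report = theorem51_report(g)          # layer spectral radii vs analytic bounds
summary = run_ensemble(g, SpreadParams(alpha_s=0.01, horizons=(6, 12)), n_runs=100)
```

## CLI

```sh
mpsn generate --n 4096 --r 2 --k 16 --s 16 --epsilon 1 --seed 0 --out-prefix out/net
mpsn analyze out/net --json-out out/report.json
mpsn simulate out/net --params spread.yaml --runs 100 --csv-out out/sim.csv
mpsn simulate out/net --params spread.yaml --unravel 0.01   # pathway unraveling
mpsn sweep --design design.yaml --replicates 3 --out out/sweep.csv
mpsn importance out/sweep.csv --target diam --json-out out/imp.json
```

Instances are stored as plain TSV (`*_nodes.tsv`, `*_edges.tsv`) plus a JSON
parameter sidecar; temporal networks use a per-month TSV dialect documented
in `mpsnet.io_realworld`.

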
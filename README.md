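# netfract

Node-centric fractal and multifractal analysis of complex networks.

Grow a shortest-path "box" around each node, track its cumulative mass
`M_i(r)`, and you get, per node, a fractal dimension (the log-log slope of
`M(r)/M(r0)` against `r/r0`) and, per network, a full multifractal
characterization: the partition function `U_q(r) = Σ_i (M_i(r)/N)^q`, the
mass exponent `τ(q)` (its log-log slope against the observation scale
`r/d`), the singularity spectrum `(α, f(α))` by Legendre transform, and the
generalized-dimension curve `D(q) = τ(q)/q`.

On top of these the package provides:

- **structure distance** — RMS gap between two `D(q)` curves over a q range,
  a pseudometric for comparing networks;
- **asymmetry** — `ln((α0−α_min)/(α_max−α0))`; positive for hub-dominated
  ("clump") structure, negative for chain-dominated ("thorn") structure;
- **specific heat** — `C(q) = dα/dq`, whose |C| peaks mark
  phase-transition-like changes of the dominant structural mechanism;
- **generators** — ring lattice, Erdős–Rényi, Watts–Strogatz rewiring,
  Barabási–Albert preferential attachment, weighted self-similar trees
  (root dimension `ln b / ln(1/f)` by construction), and (u,v)-flowers;
- **experiments** — betweenness-ranked edge-deletion trajectories and a
  Watts–Strogatz rewiring sweep with ensemble confidence bands.

Graphs are undirected and simple, optionally edge-weighted (weights are
lengths). The core is backed by `scipy.sparse.csgraph`, so million-node
synthetic fixtures are fine; `networkx` is used for GraphML and edge
betweenness.

## CLI

```bash
# synthetic networks (edge list + sidecar JSON with parameters/seed)
netfract generate ws --n 1000 --k 4 --p 0.03 --seed 1 --out ws.edges

# per-node fractal dimensions -> CSV (node, r0, M_r0, nfd, r_squared)
netfract nfd ws.edges --out nfd.csv

# full multifractal analysis -> per-q CSV + summary JSON
netfract analyze ws.edges --out-prefix ws

# pairwise structure distances between several networks
netfract compare a.edges b.edges c.edges --out-prefix cmp

# betweenness-ranked edge-deletion trajectory
netfract deletion ws.edges --order descending --steps 10 --out traj.csv

# rewiring sweep (reduced scale by default; scale up with flags)
netfract sweep-ws --n 500 --replicates 20 --out sweep.csv
```

Edge lists are whitespace-delimited (`u v` or `u v w` with `--weighted`),
`#` comments allowed. Analysis knobs (q grid, fit window, peak detection,
…) can come from a YAML file via `--config`; flags override file values,
and outputs embed a configuration hash so identical inputs give
byte-identical files.

## Python API

```python
from netfract import analyze, asymmetry, structure_distance
from netfract.generators import watts_strogatz

result = analyze(watts_strogatz(1000, 4, 0.03, seed=1))
print(result.spectrum.alpha0, result.spectrum.width)   # complexity, heterogeneity
print(asymmetry(result.spectrum))
table = result.per_q_table()                           # q, tau, r2, alpha, f_alpha, D, C
```

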
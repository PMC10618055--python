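# foragersim

Spatio-temporal agent-based simulation of hunter-gatherer camp mobility,
demography and cultural evolution.

## What it models

For most of human history, populations consisted of small, highly mobile
forager camps. Whether such populations could invent, keep and
accumulate complex culture depends not only on how many people existed
but on who could interact with whom — and that interaction structure was
itself shaped by a changing environment. `foragersim` makes this chain
explicit. Each agent is a camp with a position `X_a` (km), a population
`D_a` (people) and a cultural status vector `S_a` of `c` integer
features:

* **Mobility** follows the SDE
  `dX_a = -grad(V(X_a, t) + U_a(X)) dt + sigma(X_a) dB_a`, integrated by
  Euler-Maruyama at a monthly step: drift down a potential
  `V = -w_env * s` built from a gridded habitat-suitability field `s`
  (piecewise constant in time), Morse-like pairwise forces `U` that keep
  foraging areas apart while penalizing isolation, and Brownian noise
  scaled down by terrain friction (impassable cells are never entered).
* **Demography** is deterministic: camps grow exponentially while the
  lens-overlap-weighted local population is below the local carrying
  capacity (suitability integrated over the 20 km foraging disc) and
  decline otherwise; camps above 60 people fission into equal halves,
  camps below 18 fuse into the nearest camp within 50 km or go extinct.
* **Culture** evolves by an exact Gillespie jump process on a
  distance-banded interaction network (`A_ab = phi1` within 20 km,
  `phi2` within 50 km). *Progressive* features (technology-like) gain by
  innovation and biased adoption from more knowledgeable neighbours and
  decay by loss; *non-progressive* features (song/ornament-like) change
  by spontaneous switching and neutral copying. Fusing camps pool their
  variants (per-feature maximum).

The analysis layer computes residential-mobility statistics (moves/yr,
km/move, km/yr), Simpson diversity over full status vectors, mean trait
complexity, population-complexity correlations, density-based *mobility
clusters* of pooled trajectories (HDBSCAN), *cultural clusters* from a
time-averaged status-closeness matrix, per-cell cluster maps and
mobility-vs-culture overlap tables. See `docs/methods.md` for the full
model description and parameter rationale.

## Worked example

```python
import foragersim as fs

cfg = fs.SimulationConfig(
    N0=60, horizon_months=2_400, seed=7,
    phi1=0.05, phi2=0.005,            # medium adoption condition
    landscape={"kind": "synthetic", "shape": [60, 60], "cell_size": 5.0,
               "n_slices": 2, "smoothness": 50.0, "seed": 42,
               "slice_years": 100.0},
)
res = fs.run_simulation(cfg)
m = res.metrics
print(f"camps: {m['n_agents'].iloc[0]} -> {m['n_agents'].iloc[-1]}")
print(f"total population: {m['total_population'].iloc[-1]:.0f}")
print(f"Simpson diversity: {m['simpson'].iloc[-1]:.3f}")
cx = m[[c for c in m if c.startswith('mean_complexity')]].iloc[-1].mean()
print(f"mean trait complexity: {cx:.2f}")
print(f"residential moves logged: {len(res.moves)}")
```

prints

```
camps: 60 -> 58
total population: 1964
Simpson diversity: 0.739
mean trait complexity: 2.88
residential moves logged: 0
```

Read: the landscape sustains essentially all 60 camps (~2 000 people)
across the two centuries. Camps are culturally heterogeneous (a 0.74
probability that two random camps differ somewhere in their status
vectors) and have accumulated about 3 variants per technology-like
feature through innovation and adoption. No single monthly displacement
reached the 2 km move threshold in this short, calm run — with the
default noise scale (0.4 km month^-1/2), qualifying residential moves
are driven by fission events and landscape change and accumulate over
longer horizons.

The same run is available from the shell:

```bash
foragersim simulate --config cfg.yaml --seed 7 --out out/
foragersim validate-mobility --log out/     # moves/yr vs ethnographic rows
foragersim cluster --log out/ --window-index 0
foragersim make-landscape --spec landscape.yaml --out rasters/
```

Configuration files are YAML with the customary parameter symbols
(`h_fus`, `h_fis`, `gamma`, `lambda`, `phi1`, `phi2`, `r1`, `r2`,
`sigma`, ...); real suitability stacks are supplied as per-slice ESRI
ASCII rasters with a CSV time index.

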
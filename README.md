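# frugisim

Trait-based simulation of community-wide seed-dispersal kernels and of the
structural versus functional decay of plant–frugivore networks under
size-structured bird extinctions ("downsizing").

## The problem

Defaunation removes the largest animals first. For fleshy-fruited plants that
rely on birds to move their seeds, this matters twice over: large frugivores
hold interactions in the network (structure), and — because gut passage time
and flight speed both scale with body mass — they also carry seeds the
farthest (function). `frugisim` is for ecologists who want to quantify both
sides on weighted plant–bird interaction networks: how fast does network
structure erode, and how fast does long-distance seed dispersal (LDD)
collapse, when birds go extinct from the largest species down versus at
random?

## The model

For a bird of body mass BM (kg), each observed fruit-consumption event is
replicated 1000× and each simulated event draws

- a gut passage time from a Gamma distribution with allometric mean
  `GPT(h) = 4.5 · BM^0.5` and configurable variance `s²` (shape `k = t̄²/s²`,
  scale `θ = s²/t̄`),
- a flight speed from a Normal distribution truncated to positive values,
  with allometric mean `FS(m/s) = 15.7 · BM^0.17` and configurable sd,

and yields a displacement

```
z [m] = fc · GPT[s] · FS[m/s],    E[z] = fc · 15.7 · 16200 · BM^0.67
```

where `fc = 0.002` is a dimensionless calibration combining the fraction of
gut-passage time spent moving and path straightness. Pooling events over all
plants gives the community kernel; **LDD is its 0.95 quantile**.

Extinction scenarios remove birds largest-first (downsizing) or in 1000
uniform random orders; after each removal the package records the percentage
of interaction events lost, of plants secondarily extinct (all partners
gone), and of LDD change, all relative to the full assemblage. Per-network
trajectories are loess-smoothed onto a 100-point grid, combined across
networks with t-based 95% confidence bands, and the *effect size of
downsizing* is the extra loss under downsizing relative to random removal.

A synthetic-data module generates multi-network studies (log-normal body
masses in 0.01–1.77 kg, size matching between bird mass and fruit size,
negative-binomial link weights) so the whole pipeline runs without any field
data.

## Worked example

```python
import numpy as np
import frugisim as fs

net, traits = fs.generate_community(fs.GeneratorParams(), np.random.default_rng(1))
cfg = fs.SimulationConfig()                      # multiplier=1000, q=0.95

kernel = fs.simulate_network_kernel(net, traits, cfg, np.random.default_rng(2))
print(net.n_plants, net.n_birds, net.total_events)   # 33 32 482
print(round(fs.community_ldd(kernel), 1))            # 274.0

order = fs.downsizing_sequence(net.birds, traits)
down = fs.run_extinction(net, traits, order, cfg, np.random.SeedSequence(5),
                         scenario="downsizing")
print(down.steps.iloc[16].round(2).to_dict())
# {'n_removed': 16.0, 'pct_birds_removed': 50.0, 'pct_interactions_lost': 50.83,
#  'pct_plants_extinct': 39.39, 'pct_ldd_change': -33.16}
```

The kernel holds 482 × 1000 simulated events; the community LDD of the full
assemblage is ≈ 274 m. After removing the 16 largest of 32 bird species,
this network has lost 51% of its interaction events, 39% of its plants
have no disperser left, and long-distance dispersal has dropped by 33% —
functional loss tracking, and soon outpacing, structural loss.

The same analysis runs from the shell:

```bash
frugisim generate-synthetic --seed 1 --out study/
frugisim run --out results/          # full 8-network study, both scenarios
```

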
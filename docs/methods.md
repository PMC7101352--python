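# Methods

## The mechanistic dispersal model

Seed dispersal by a frugivorous bird is modelled as the product of how long a
seed stays in the gut and how fast the bird moves while it does. Both
components scale allometrically with body mass BM (kg):

- **Gut passage time (GPT)**, hours: mean `t̄ = 4.5 · BM^0.5`. Per event, GPT
  is drawn from a Gamma distribution — the distribution that best matches
  empirical gut-retention curves — parametrized by shape `k = t̄²/s²` and
  scale `θ = s²/t̄`, so that `kθ = t̄` and `kθ² = s²` hold exactly.
- **Flight speed (FS)**, m/s: mean `15.7 · BM^0.17` (an aerodynamic
  allometry for flapping flight in still air). Per event, FS is drawn from a
  Normal around that mean; negative draws are rejected and re-drawn, which
  keeps distances positive without touching the upper tail that the
  long-distance statistic depends on.

A simulated displacement is `z = fc · GPT[s] · FS[m/s]`, with `fc = 0.002` a
dimensionless calibration absorbing the fraction of gut-passage time
actually spent moving and the non-straightness of flight paths. In
expectation `z = fc · 15.7 · 16200 · BM^0.67` metres (16200 = 4.5 h in
seconds), roughly 23 m for a 10 g bird and 750 m for a 1.77 kg bird.

Each observed interaction event is replicated `multiplier = 1000` times so
that rarely observed links still contribute a well-resolved kernel while
relative link frequencies stay exactly as observed. One GPT and one FS are
drawn independently per simulated event. The community kernel pools all
events with equal weight, so abundant interactions dominate — the natural
reading of combining per-plant kernels; an alternative pooling that weights
every plant equally is available (`pooling="plants"`) for sensitivity
analysis. **Long-distance dispersal (LDD)** is the 0.95 quantile of the
pooled kernel, computed with the linear-interpolation convention between
order statistics (the default of numpy and R); the convention is fixed and
documented because reasonable alternatives differ in the far tail.

### Parameters and defaults

| parameter | default | units | meaning |
|---|---|---|---|
| `a_gpt`, `b_gpt` | 4.5, 0.5 | h·kg⁻ᵇ, – | GPT allometry |
| `a_fs`, `b_fs` | 15.7, 0.17 | m·s⁻¹·kg⁻ᵇ, – | FS allometry |
| `fc` | 0.002 | – | movement-time × straightness calibration |
| `gpt_variance_h2` | 1.0 | h² | Gamma variance of GPT |
| `fs_sd_ms` | 2.0 | m/s | sd of the FS Normal |
| `multiplier` | 1000 | – | simulated events per observed event |
| `ldd_quantile` | 0.95 | – | quantile defining LDD |
| `n_random_sequences` | 1000 | – | iterations of the random scenario |

The allometric coefficients and `fc` are taken as given. The GPT variance
and FS sd are not pinned down by the allometries; their defaults are
documented stand-ins in the right empirical ballpark, every distributional
identity in the package holds for any positive value, and both are plain
config keys. The 1.77 kg ceiling recorded on `AllometryParams` documents the
body-mass range over which the FS sd estimate is meaningful; it is not a
runtime filter.

An optional **regurgitation filter** zeroes links whose fruit diameter
exceeds the bird's bill width before simulation, on the argument that such
fruits are processed in the bill and regurgitated rather than gut-passed.
The exact operationalization (strict diameter > width) is a package choice;
it is off by default.

## Extinction scenarios

Birds are removed one at a time, either largest-first (*downsizing*; ties
broken lexicographically for determinism) or in uniform random orders
(*random*; the scenario value is the mean over `n_random_sequences`
iterations). There is no rewiring and no density compensation: surviving
links keep their observed weights. After each removal the state of the
subnetwork is scored relative to the full assemblage:

- `pct_interactions_lost` — percentage of interaction events removed;
- `pct_plants_extinct` — percentage of plant species with no surviving
  partner (purely topological coextinction);
- `pct_ldd_change` — percentage change of LDD; when no events remain the
  change is −100% by convention.

Both structural metrics are non-decreasing along any order, are 0 at step 0
and 100% at full removal; the expected random interaction loss after m of n
removals is exactly `100·m/n` by linearity of expectation, which the test
suite checks both by enumeration (n ≤ 6) and by Monte-Carlo error bounds.

LDD along a sequence can be computed two ways. The default for the single
deterministic sequence re-simulates the subnetwork kernel at every step with
a step-specific child seed. The random scenario instead simulates one master
event table per network and, at each step, evaluates the quantile over the
events of surviving birds. The two routes agree statistically (identical
distributions, different draws); within the cached route the per-step
quantiles are read off a cached descending sort of the master table as exact
order statistics — a reference implementation that masks and calls the
library quantile directly is kept, and the fast path is tested to match it
to rounding error.

## Smoothing and cross-network summaries

Per network, each metric's trajectory against % birds removed is smoothed
with loess (tricube weights over a nearest-neighbour window, local
quadratic) and evaluated at 100 grid points on [0, 100]. The smoother is
implemented in the package — the available Python lowess is local-linear
only, while degree-2 local regression is the convention this analysis
follows — and is verified in the tests against R's `stats::loess`
(`surface = "direct"`, same span and degree) to ~1e-8. Unless a span is
given, the smallest well-conditioned window is selected per trajectory
(condition number of the local weighted design below 1e8), keeping the fit
as close to the raw species-by-species trajectory as a well-posed local
regression allows; a configured span that is infeasible is grown to the
smallest feasible window and logged. Local quadratic fits overshoot sharp
steps by design; on step-like inputs the overshoot stays a modest fraction
of the data range, and the smoother is exact on constant and linear inputs.

Smoothed curves are combined across networks as a pointwise mean with a
t-based 95% confidence band (df = n_networks − 1; a percentile band is
available behind a flag). The **effect size of downsizing** is the
pointwise difference between a network's downsizing and random curves,
expressed as extra loss under downsizing (positive = downsizing is worse;
for LDD change, whose loss is negative, the sign is flipped), then
summarised across networks the same way. Effect sizes vanish at 0% and 100%
removal up to smoothing tolerance, since the scenarios coincide there.

## Seeding

A run is reproducible from config + one master seed. The master
`SeedSequence` spawns one child per network; each network child spawns
children for the downsizing scenario (then one per removal step), the
random scenario (one for the master kernel, one for the removal orders),
and the optional persisted kernel. Serial and parallel execution therefore
produce identical results, and rerunning a config yields byte-identical
CSVs.

## The synthetic-data generator

The generator emulates an eight-site study of Andean-type frugivory
networks: per network, 20–45 bird and 20–45 plant species; bird body masses
log-normal (median ≈ 50 g, log-sd 1.2) truncated to 0.01–1.77 kg, so small
tanager-sized birds are common and guan-sized birds are present but rare;
fruit diameters log-normal (median 8 mm) on 2–40 mm; bill widths scale with
the cube root of mass plus noise. Links are realized Bernoulli with
probability proportional to a Gaussian kernel on the mismatch between a
bird's log mass and the plant's fruit-size z-score mapped onto the log-mass
scale; the `size_matching_strength` multiplies the squared mismatch, so 0
gives uniform random attachment and the default (4.0) gives the strong
size matching the downsizing analysis presumes. Link weights are
`1 + NegativeBinomial` (mean 3 events per link, dispersion 0.7), giving the
right-skewed event counts typical of frugivory data. Every species is
guaranteed at least one link (the best-matching partner is added if
sampling left it isolated), so generated networks always validate.

What the generator does **not** emulate: the empirical abundance–body-mass
correlation structure of real Andean networks, their exact richness,
connectance or sampling effort, spatial or phylogenetic structure, and
observation error. Passing tests therefore demonstrate that the pipeline's
mathematics and directional behaviour are correct under realistic
conditions, not that the package reproduces any particular field study's
percentages. At the default sizes (8 networks, ≈ 3 400 observed events in
total, multiplier 1000, 1000 random iterations) a full study runs in about
two minutes on one CPU; these sizes are the package's chosen default study
scale.

## Numerical and design choices

- Quantile convention: linear interpolation (type 7); fixed and documented.
- Negative flight speeds handled by rejection, not truncation-shift, to
  leave the tail shape untouched.
- Empty kernels return NaN LDD ("undefined"); trajectory code maps this to
  −100% change.
- Zero-sum rows/columns are dropped (with a logged warning) at I/O time so
  subsetted networks re-enter the pipeline cleanly, but `remove_birds`
  retains empty plant rows, which are exactly the secondary extinctions to
  count.
- Body mass is read in grams by default (the convention of trait
  databases) and stored in kg (the unit of the allometries); a
  `body_mass_kg` header overrides.
- Effect sizes are reported as magnitudes of extra loss under downsizing,
  with the sign convention stated in the output headers.

## Known limitations

Body mass is the only response trait (no specialization, abundance or
behavioural extinction proneness) and the only effect trait (no per-species
gut-retention or movement data); the movement model has no landscape,
home-range or resting structure beyond the `fc` calibration; regurgitation
handling is a binary filter rather than a shorter-distance kernel; and the
GPT variance and FS sd defaults are stand-ins that should be replaced with
study-specific estimates when available.
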
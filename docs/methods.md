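# Methods

## The model

`axregen` implements a stochastic, cell-based model of ependymal tissue
growth in the regenerating axolotl spinal cord, together with the inference
machinery used to confront it with data. The spinal cord is reduced to a
single row of densely packed rigid cells along the anterior–posterior (AP)
axis; the amputation plane sits at 0 μm, anterior positions are negative,
and time is measured in hours from amputation.

### Cell cycle

Each cell is either cycling or quiescent (G0). The probability that a cell
is cycling at initialization is the growth fraction `gf` (default 0.88; the
quiescent fraction is 0.12). A cycling cell carries realized phase durations
(G1, S, G2+M), each drawn from a lognormal distribution parametrized by its
arithmetic mean and standard deviation:

| phase | non-regenerating (h) | regenerating (h) |
|---|---|---|
| G1 | 152 ± 54 | 22 ± 19 |
| S | 179 ± 21 | 88 ± 9 |
| G2+M | 9 ± 6 | 9 ± 2 |

The lognormal is solved from the printed moments
(σ² = ln(1 + s²/m²), μ = ln m − σ²/2), which guarantees positivity and
reproduces the tabulated mean/sd exactly. The cell cycle length T is the sum
of the three independent phase draws. A zero sd degenerates to the exact
mean, which the deterministic tests exploit.

Cycling cells advance a clock C deterministically; at C ≥ T the cell
divides: one daughter keeps the mother's AP coordinate, the other is
intercalated immediately posterior, and every more-posterior cell is pushed
one cell diameter (13.2 μm) toward the tail ("cell pushing"). Daughters
restart at C = 0 with fresh phase draws from their regime's distributions
(they inherit the mother's *distribution*, not her realized values) and
inherit clone id and recruited state.

Initial clocks are drawn from the stationary age distribution of an
exponentially growing population, f(a) = (ln2/T)·2^(1−a/T) on [0, T),
sampled by inverting the closed-form CDF F(a) = 2(1 − 2^(−a/T)). This is
the steady state reached after many generations of growth, so the
simulation can start at the amputation instant without simulating
development.

### Recruitment

Amputation releases a signal that sweeps anteriorly at constant speed λ/τ;
the front is at −(λ/τ)·min(t, τ), reaching −λ exactly at t = τ
(best fit: λ = 828 μm, τ = 85 h). Any cell at or posterior to the front is
irreversibly recruited; the clock transformation takes effect in the
following time step. The maps, phrased with the cell's realized long
durations and freshly drawn short durations:

* **G1, C ≤ G1ˡ − G1ˢ**: C′ = 0 — the early part of G1 is skipped, which
  synchronizes these cells at the start of short G1.
* **G1, C > G1ˡ − G1ˢ**: C′ = C − (G1ˡ − G1ˢ) — the time remaining to S
  entry is unchanged.
* **S**: C′ = (C − G1ˡ)·Sˢ/Sˡ + G1ˢ — fractional S-phase progress is
  preserved (DNA replication cannot be skipped, only compressed).
* **G2+M**: C′ = C + (Tˢ − Tˡ) — the remaining time to division is
  preserved. The cell *keeps its realized G2+M duration* when switching
  regimes (G2/M lengths do not change on injury); re-drawing it could
  otherwise map the clock back into S and break the remaining-time rule.
* **G0**: the cell is scheduled to start a short cycle from C = 0 after a
  fixed delay t_G0→G1 = 48 h.

Shortening modes for in-silico perturbations: `both` (default), `s_only`
(short S, G1 keeps its long distribution — in daughters too), `g1_only`
(the converse), and `none`, which disables every cell-cycle consequence of
recruitment (including G0 exit) so that the run is statistically identical
to λ = 0; recruited flags are still tracked so the recruitment limit ξ(t)
remains reportable.

The recruitment limit ξ(t) is the position of the most anterior recruited
cell. During the sweep it tracks the front; after τ it drifts posteriorly as
divisions anterior to it push the whole recruited region tailward — the
model counterpart of the experimentally measured "switchpoint".

### Numerical choices

* Fixed step dt = 1 h; divisions fire at step boundaries (C ≥ T), several
  in one step are processed anterior-first, so a posterior division's
  recorded position already includes pushes from anterior ones in the same
  step. Daughters start at exactly C = 0 (sub-step overshoot is discarded;
  at dt = 1 h this delays a ~340 h cycle by ~0.15% on average).
* Positions are posterior-edge coordinates derived from the fixed anterior
  tissue edge plus the cumulative cell lengths; recruitment marking uses a
  1e-9 μm tolerance to absorb cumulative-sum rounding.
* The front position is returned exactly as −λ for t ≥ τ to avoid
  λ/τ·τ ≠ λ float artifacts at the sweep end.
* Variable cell lengths (for the geometry sensitivity analysis) are drawn
  from a normal truncated at > 0; the intercalated daughter draws a fresh
  length, the in-place daughter keeps the mother's.
* The S-phase and G2+M invariants (fractional progress, remaining time) are
  exact in float64 only for dyadic fractions of integer-valued durations;
  the property tests assert bit-exactness there and 1e-12 relative
  agreement for arbitrary draws.

## Inference

### Switchpoint fit (ABC-SMC)

`SwitchpointModel(data).fit()` infers (N₀, λ, τ) from per-day switchpoint
means/sds by likelihood-free sequential Monte Carlo. Distance:
d = Σᵢ (xᵢ − μᵢ)²/σᵢ², with xᵢ the simulated ξ at day i. Priors are
discrete uniform: N₀ ∈ {100..300}, λ ∈ {500..1500} μm, τ ∈ {1..192} h.
Generation 0 samples the prior (population 1000 by default); afterwards
ε_{g+1} is the median of the previous generation's accepted distances,
particles are resampled by weight and perturbed by a discretized Gaussian
random walk whose per-parameter scale is √2 × the weighted sd of the
previous generation (floored at 0.5 so the integer kernel never
degenerates), proposals outside the prior box are redrawn, and standard SMC
importance weights are applied (the uniform prior cancels). One stochastic
simulation stands in for the likelihood per particle (configurable). The
fit stops at `max_generations` (default 12), when the acceptance rate drops
below 0.05, when ε reaches 0, or — silently — when ε has shrunk onto the
smallest attainable distance (strict improvement impossible). ε and the
acceptance rate are recorded per generation as convergence diagnostics.

The kernel, stopping rule and one-simulation-per-particle choices are this
package's own defaults; the generic SMC scheme leaves them open.

N₀ is only weakly identified when λ is well inside the tissue extent
(N₀·13.2 μm); its posterior then stays close to the prior, which is the
expected behaviour, not a failure of the fit.

### Two-zone AP-border fit

Binned reporter profiles (percent of G0/G1- and S/G2-reporter cells per
100 μm bin) are fitted per animal with a piecewise-constant model: anterior
levels (g0g1ₐ, sg2ₐ) for x < border, posterior levels for x ≥ border, one
shared border. Distance: sum of squared residuals of both channels over
bins with at least one cell; the model is evaluated at bin centers, and the
border prior is discrete uniform over the measured bin edges. The same
ABC-SMC engine runs with population 1000 for up to 30 iterations (the
distance is deterministic here, so the run usually converges earlier onto
the minimal attainable distance). The reported best fit is the
minimum-distance particle of the final population; at a fixed border it
approaches the closed-form optimum (the per-zone means). A flat profile
leaves the border unidentified — visible as a border posterior spread
comparable to the measured range — and is flagged by the downstream test
rather than hidden.

Anterior vs posterior best-fit levels across animals are compared with a
two-sample Kolmogorov–Smirnov test. Because per-day sample sizes are 4–6
animals, the two-sided p-value is computed exactly by enumerating all
C(n+m, n) label assignments whenever that count is ≤ 2·10⁵ (ties are
handled by evaluating the ECDF difference at distinct values only); beyond
that budget the computation delegates to scipy's lattice-path exact method,
which itself falls back to asymptotics only for large samples. The
classical asymptotic approximation is *not* used for moderate n: it
deviates from the exact p by up to ~0.09 at n = m = 20, far too coarse for
the ~0.03 p-values at stake. With n = m = 4 and complete separation the
exact p is 2/C(8,4) = 0.0286.

All defensible pairings (per-channel anterior-vs-posterior and the pooled
two-channel variant) are computed and labelled, since the choice is
genuinely open.

### Clone analysis

Clones are tracked as the mean position of a founder's descendants, with
founders by default nearest to every 50 μm from 0 to −1100 μm. Velocities
are OLS slopes of position vs time (μm/day) per (track, 800 μm position
bin), dropping groups with fewer than two samples; means and sds are
aggregated across tracks per bin. The normalized position
(x − ξ)/(outgrowth − ξ) is the scaling diagnostic: in best-fit runs its
per-clone sd over days 4–8 stays below 0.05 (a repo convention for
"approximately conserved"; the conservation itself is a model property).

## Synthetic data

The generators define the study conditions under which the inference
stages are tested:

* **Switchpoint datasets**: the simulator is run at a known truth
  (defaults N₀ = 200, λ = 800 μm, τ = 96 h — inside the prior box), the
  mean ξ over 20 replicates is taken at days 4/6/8, and Gaussian noise of
  sd 50 μm (also the reported σ) is added. `noise_sd` can be set to 0 to
  test the plumbing deterministically.
* **FUCCI profiles**: per animal, ~300 cells are allocated
  multinomially across 16 bins of 100 μm spanning (−1600, 0) μm with equal
  expected counts (per-bin cell counts are not reported experimentally;
  a density gradient is configurable); each cell's reporter class is drawn
  from its zone's true percentages; bin percentages are integer-count
  ratios, so binomial counting noise is reproduced exactly (a 50% bin with
  ~20 cells has sd ≈ 11 points). Day-0-like defaults (85% G0/G1, 11% S/G2,
  no step) and day-4-like defaults (border −700 μm, posterior S/G2 50%)
  mirror the reported baselines.

What the generators deliberately do not emulate: imaging noise,
segmentation errors, animal-to-animal baseline variability, uneven cell
density, partial tissue loss, or any smooth (non-step) spatial structure.
Passing recovery tests therefore shows that the inference machinery is
correct and well-calibrated under the model's own assumptions — not that
the two-zone or recruitment model is the true generative process of real
tissue.

## Problem sizes and determinism

Ensemble predictions use 1000 replicates (as in the reference analysis);
the reduced parameter-recovery study uses population 200 and ≤ 8
generations over 3 seeds, and zone-border recovery uses 4 synthetic animals
at full (population 1000, 30 iteration) settings. All randomness flows
through `numpy.random.Generator` seeded explicitly; replicate ensembles
spawn independent substreams from one `SeedSequence`, so every published
number in the README is reproducible byte-for-byte from the stated seed.

## Known limitations

* 1D geometry, rigid pushing, no cell death, differentiation, influx or
  mechanics — inherited simplifications of the source model.
* The recruitment signal is phenomenological (constant-speed front), not a
  transport or diffusion model.
* The growth fraction is read as cycling fraction 0.88 (quiescent 0.12);
  the tabulated "GF 0.12" is internally inconsistent with the model's own
  printed outputs under the cycling-fraction reading, but both readings are
  expressible through `SimConfig.gf`.
* Simulated day-6 outgrowth runs ~8–16% above the reported central values
  (well within the reported ±2σ bands); the residual bias is consistent
  with unreported discretization or age-initialization details of the
  original implementation.
* The exact per-particle replication count and perturbation kernel of the
  reference fits are unknown; defaults are documented above.
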
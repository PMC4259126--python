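# Methods

This note records the mathematical model, the estimators, the numerical
choices, and the open design decisions behind `ictonet`. It is written so
that every number produced by the package can be traced to an equation or
an explicit convention stated here.

## 1. Node model

Each network node carries a complex state `Z(t)` obeying the normal-form
stochastic differential equation

```
dZ/dt = (a|Z|^4 + b|Z|^2 + c + i*omega) Z  +  sum_j G_ij Z_j  +  noise
```

with real coefficients `a, b, c`, angular frequency `omega`, and linear
coupling through the scaled adjacency matrix `G`. Writing `u = |Z|^2`, the
noise-free, uncoupled radial dynamics are

```
dr/dt = r * g(u),     g(u) = a u^2 + b u + c .
```

Radial equilibria are the origin plus the real positive roots of the
quadratic `g`. Stability follows from the sign structure of `g`: the origin
is stable iff `c < 0`, and a circular limit cycle at radius `r* = sqrt(u*)`
is stable iff `g'(u*) < 0` (implemented in `radial_equilibria`, which
returns radii with stability labels).

### Default parameters

`a = -1, b = 2, c = -0.9, omega = 1`. Then `g(u) = -(u^2 - 2u + 0.9)` has
roots `u = 1 ± sqrt(0.1)`, giving

* a stable fixed point at the origin — the **background** state,
* an unstable limit cycle at `r = sqrt(0.683772...) ≈ 0.82691`,
* a stable limit cycle at `r = sqrt(1.316228...) ≈ 1.14727` — the
  **seizure** state.

The system is bistable: noise can kick a trajectory across the unstable
cycle from the background basin into sustained high-amplitude oscillation.

### Noise

Euler–Maruyama increments add `sigma * sqrt(dt) * (eta1 + i*eta2)` with
independent standard Gaussians per node and step. The default
`sigma = 0.3` was calibrated with `scripts/calibrate_noise.py` on a single
uncoupled node at the default parameters (no acceptance outcome was used in
the calibration): starting at the origin, the mean first escape time to the
seizure basin is ~13 time units, i.e. escapes are frequent on the default
500-unit horizon but far from instantaneous, so occupancy statistics are
informative. At `sigma = 0.2` escapes take ~100 time units; at
`sigma = 0.4` they are nearly immediate.

### Frequency heterogeneity

`bni_ensemble` draws each node's frequency independently as
`omega + Uniform[-0.2, 0.2]`, fresh for every replicate. This breaks exact
phase degeneracy between identically parameterized nodes; the amplitude
dynamics that BNI measures are insensitive to the exact half-width.

### Coupling scale

Adjacency weights are multiplied by a uniform `scale` (default `0.1`)
before simulation. At this scale a single edge perturbs, rather than
overwhelms, the single-node bistability; total input grows with degree, so
densely connected nodes escape the background state sooner — the mechanism
the package exists to quantify.

## 2. Numerical integration

Fixed-step Euler–Maruyama, default `dt = 0.01`, duration `500` model time
units. Replicates of the same network are integrated as one batched array
for speed; noise is generated in chunks with a per-replicate, per-node
`numpy` `SeedSequence`-spawned stream, so results are bit-reproducible and
a zero-coupling network reproduces the corresponding single-node
trajectories exactly.

Euler integration biases the realized limit-cycle radius outward by
approximately `r * omega^2 * dt / (2 |g'(u*)|)` (the first-order mismatch
between stepping along a chord and along the arc). At default parameters
this is ~1.7e-3 at `dt = 0.005` and ~0.7e-3 at `dt = 0.002`; the dynamics
tests verify both the magnitude and the O(dt) scaling. The bias is two
orders of magnitude smaller than the gap between the attractors and is
irrelevant for threshold-crossing classification at 0.5.

A guard radius (`|Z| > 10`) raises `SimulationDivergedError` with the
offending step, node and replicate rather than returning NaNs.

## 3. Seizure-state classification and BNI

A node sample is in the **seizure state** when its oscillation amplitude
exceeds `threshold = 0.5`, placed between the two attractor radii
(0 and ~1.15) where classification is insensitive to the exact value.

Two classification modes:

* `envelope` (default): `|Z| > 0.5` per sample. On circular limit cycles
  `|Z|` is the oscillation envelope, so this equals extrema-based labeling
  without windowing artifacts.
* `extrema`: a sample is ictal when a local extremum of `Re(Z)` with
  magnitude above threshold falls within a centered window (default one
  oscillation period). Retained for non-circular regimes or real-valued
  signals.

**BNI** (brain network ictogenicity) of one simulation is the fraction of
samples in the seizure state, averaged over nodes. No burn-in is
discarded: with random initial conditions and noise-driven escapes, the
early transient is part of the quantity (how quickly the network settles
into the seizure state), not a nuisance. `bni_ensemble` averages over
`n_sims` independent replicates, each with fresh initial conditions
(uniform over the disk of radius 1.5 by default, covering both basins) and
fresh frequency jitter, and exposes per-replicate and per-node fractions.

## 4. Functional networks from signals

`build_functional_network` estimates pairwise phase-locking:

1. optional broadband filter and notch (all filters are order-4
   Butterworth applied forward-backward with `sosfiltfilt`, i.e.
   zero-phase, effective order 8),
2. band-pass to the analysis band (default 6–9 Hz),
3. analytic phase via the Hilbert transform,
4. trim 0.5 s from each end to drop filter/Hilbert edge transients,
5. phase-locking factor `PLF_ij = |mean_t exp(i(phi_i - phi_j))|`, in
   [0, 1]; the diagonal is set to 0.

PLF is computed for all pairs at once as a Gram matrix of unit phasors.
Constant (zero-variance) channels are rejected rather than given arbitrary
phases.

## 5. Graph measures and surrogate networks

For an undirected network with adjacency `A` (weighted or binary):

* node degree `k_i = sum_j A_ij`; **mean degree** MD is their mean,
* **degree variance** DV is the population variance of `{k_i}`,
* **clustering** is the mean local clustering coefficient
  (transitivity-style triangle count for binary networks; the Onnela
  geometric-mean formulation for weighted ones, via `networkx`).

### MD-preserving binarization

`binarize_preserving_md` scans thresholds over `{0} ∪ {unique weights}`,
keeps edges with weight strictly greater than the threshold, and selects
the threshold whose binary MD is closest to the weighted MD (ties go to
the lower threshold, i.e. the denser network). The achieved `|ΔMD|` and
the threshold are recorded in the result's provenance. For continuous
weights the gap is at most one edge's worth of degree (`2/N`). A network
whose weights are all equal has no meaningful threshold and is rejected.

### Degree-preserving randomization

`degree_preserving_randomize` applies the classic double-edge swap: pick
two edges `(a,b), (c,d)` with four distinct endpoints, rewire to
`(a,d), (c,b)` (or `(a,c), (b,d)`, chosen at random) when neither new edge
exists. This preserves every node's degree exactly while destroying
higher-order structure. Default `10 * n_edges` attempted swaps; attempts
and acceptances are recorded in provenance. Graphs with no valid swap
(e.g. stars) are returned unchanged rather than looping forever.
`make_artificial_ensemble` chains binarization and `n` independent
randomizations under one seed.

`spectrum` returns adjacency eigenvalues (descending); swapped surrogates
are almost surely not isospectral with the original, which the tests use
as a structural-change witness.

## 6. Synthetic data generators

### Weighted cohorts (`generate_weighted_cohort`)

Each subject: target MD drawn uniformly from the cohort's `[md_low,
md_high]`; off-diagonal weights drawn i.i.d. `Beta(c*mu, c*(1-mu))` with
`mu = MD_target/(N-1)` and concentration `c = 10`, then rescaled
multiplicatively so the realized weighted MD equals the target exactly
(redrawn if rescaling would push weights past 1; at most 100 retries).
Weights are symmetric, in [0, 1], zero diagonal. Presets
`CONTROL_MD_RANGE = (4, 6)` and `PATIENT_MD_RANGE = (7, 9)` define the two
standard cohorts for 19-node networks. The generator controls MD — the
quantity under study — while leaving other structure random; it makes no
claim of physiological realism beyond that.

### Phase-coupled signals (`generate_coupled_signals`)

Kuramoto-style phase oscillators with natural frequencies uniform in the
carrier band, pairwise sine coupling weighted by the supplied matrix,
phase-diffusion and additive measurement noise both scaled by
`noise_level`. Euler integration at the sampling rate. Intended as a
controllable test bed for the PLF estimator (stronger coupling ⇒ higher
PLF), not as an EEG model.

## 7. Statistics

* **Kruskal–Wallis**: tie-corrected H computed from midranks
  (`kruskal_wallis_h`); p-value from the chi-squared approximation
  (default) or a Monte-Carlo permutation null (`method="permutation"`)
  that reuses the same H. The degenerate all-values-identical case
  returns `(H, p) = (0, 1)`.
* **Post hoc**: pairwise two-sided Mann–Whitney U tests at
  Bonferroni-adjusted level `alpha / n_pairs`.
* `compare_groups` packages both with group values retained for
  inspection.

## 8. End-to-end protocol (`run_experiment`)

Per subject: weighted MD; binarize preserving MD; build `n_networks`
degree-preserving surrogates; simulate each with `n_sims` replicates;
subject-level BNI is the mean over the full `n_networks × n_sims`
replicate grid. MD and DV are surrogate-invariant by construction and are
reported from the binarized network; clustering is not invariant, so the
ensemble mean is reported. Group comparisons (Kruskal–Wallis + Bonferroni
post hoc) are run for mean degree, degree variance, clustering, and BNI.

Subjects whose processing fails (e.g. degenerate flat-weight networks) are
recorded with the error message and excluded from the tests — never
silently dropped. All randomness descends from one master seed through
`SeedSequence.spawn`, so a report regenerates bit-identically.

The library default protocol is `30 × 30` (surrogates × replicates). The
headline script `scripts/acceptance.py` uses `5 × 10`, which already
separates the MD-4–6 and MD-7–9 cohorts decisively at n = 20 + 20 while
keeping the runtime in minutes; these sizes are this package's own
budget-driven choice.

## 9. Known limitations

* Euler–Maruyama is first-order; results at very coarse `dt` inherit the
  radius bias quantified above. Use `dt ≤ 0.01` at default parameters.
* BNI with no burn-in depends on `duration`: short horizons weight the
  initial transient heavily. Comparisons are only meaningful at fixed
  integration settings.
* At the default noise and coupling scale, BNI saturates near 1 for mean
  degrees above ~10; group separation then rests on the remaining small
  rank differences. The default cohort ranges stay below hard saturation.
* The synthetic cohort generator pins MD only; degree variance and
  clustering co-vary freely, so group differences in those measures are
  incidental, not designed.
* PLF, like all phase-synchrony measures on filtered signals, is inflated
  by volume conduction / linear mixing when applied to real recordings;
  the package does not attempt leakage correction.
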
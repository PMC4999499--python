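# Methods

## The model

A meta-ecosystem is a set of `n` habitat patches, each holding the same `S`
species, coupled by passive dispersal. Near equilibrium its dynamics are
governed by the `nS x nS` community (Jacobian) matrix

    J = A - m I + D

in patch-major order (index `x*S + i` is species `i` in patch `x`). `A` is
block-diagonal with one random interaction matrix per patch, `-m I` is
intraspecific density dependence, and `D` couples patches: own-patch
diagonal `-d` (total emigration), inter-patch blocks diagonal with the
per-pair immigration rate — `d/(n-1)` under global coupling, `d/2` for each
of the two torus neighbours on a ring. Every row of `D` sums to zero, so
diffusion conserves individuals. The system is locally stable iff the
largest real part among the eigenvalues of `J` is negative.

Interaction blocks follow the classic random-community recipe: one
Bernoulli(`c`) occupancy mask over ordered off-diagonal pairs, shared by
all patches, and coefficients with mean 0 and s.d. `sigma` on occupied
positions. Cross-patch similarity is controlled by a correlation `rho`
through a shared-factor construction,

    a_ijx = sigma * (sqrt(rho) * z_ij + sqrt(1 - rho) * eps_ijx),

which yields the marginal s.d. and the pairwise cross-patch correlation
exactly (not just asymptotically). `rho = 1` makes all patches identical;
`rho = 0` makes them independent. Any zero-mean unit-variance i.i.d. law is
accepted for `z` and `eps` (normal default, uniform provided): the limiting
spectral disk depends on the coefficient law only through its variance.

The A-blocks have zero diagonals by construction; all self-regulation is
carried by `-m I`. This keeps the complexity parameter `sigma*sqrt(S*c)`
cleanly separated from the feedback strength `m`.

## Stability criteria

All criteria report `margin = RHS - LHS` of their inequality, so
`stable <=> margin > 0` uniformly.

* **Isolated patch.** The eigenvalues of `A - mI` fill a disk of radius
  `sigma*sqrt(S*c)` centred at `-m` (circular law), giving the classic
  bound `sigma*sqrt(S*c) < m`.
* **High dispersal.** With strong global coupling, stability is governed by
  the patch-averaged community. Averaging over patches with cross-patch
  correlation `rho` thins the coefficient variance by the effective patch
  number `n_e = n / (1 + (n-1)*rho)` — an effective sample size: `n_e = n`
  for independent patches, 1 for identical ones. The bound becomes
  `sigma*sqrt(S*c) < m*sqrt(n_e)`, reducing identically (bitwise, in the
  implementation) to the isolated bound at `rho = 1` or `n = 1`, and
  multiplying the admissible `sigma^2*S*c` by `n` at `rho = 0`.
* **Low dispersal.** For `d` small relative to `m` the dominant spatial
  term is emigration, `-d` added to every diagonal element, which acts as
  extra self-regulation: `sigma*sqrt(S*c) < m + d`. The bound is additive
  in `d` and independent of `rho`. We use the raw emigration rate `d`
  (the own-patch diagonal of `D` is exactly `-d` for every topology and
  patch count) with no `n/(n-1)` prefactor; the asymptotic regime is
  documented rather than enforced, and the implementation pins the forced
  properties (exact reduction at `d = 0`, strict monotonicity in `d`,
  independence of `rho`).

No automatic switching between regimes is attempted: there is no
closed-form crossover, so regime choice is left to the caller.

## Predicted eigenvalue geometry

For global dispersal a similarity transform that separates the patch
average from the `n-1` patch contrasts splits the spectrum into two groups:

* **averaged disk** — `S` eigenvalues, centre `-m`, radius
  `sigma*sqrt(S*c)/sqrt(n_e)` (the *Jacobian averaging effect*);
* **pushed-back disk** — `S(n-1)` eigenvalues, centre `-m - d*n/(n-1)`,
  radius `sigma*sqrt(S*c)*sqrt(1 - (1-rho)/n)` (the *eigenvalue pushback
  effect*).

The pushed-back radius follows from the coefficient variance carried by
the contrast directions: a contrast combination `sum_x v_x a_ijx` with
`sum_x v_x = 0`, `|v| = 1` has variance `sigma^2*(rho + (1-rho)*(n-1)/n)`
row-averaged over the contrast block row, i.e. `sigma^2*(1 - (1-rho)/n)`.
At `rho = 1` the transform is exact: the assembled spectrum equals the
union of `spec(A - mI)` and `n-1` copies of `spec(A - (m + dn/(n-1))I)` to
floating-point accuracy, and the test suite checks this to 1e-6 via
optimal bipartite matching of the two eigenvalue sets (lexicographic
sorting is fragile when real parts nearly tie).

For `d = 0` or `n = 1` the prediction collapses to the single disk of
radius `sigma*sqrt(S*c)` at `-m`. Ring topologies have no closed-form
prediction here and raise; their spectra are computed numerically.

Finite matrices spill slightly past the asymptotic disk edge, so coverage
tests inflate radii by 5% and require 95% coverage (both test constants).
At the reference illustration parameters (`sigma=1, n=20, S=100, c=0.3,
m=2, rho=0`) measured coverage is 97.6-99% for `d` in {0, 1, 8}. When
classifying eigenvalues by nearest disk centre at `d = 8`, the pushed-back
disk's right edge reaches past the midpoint between centres, so a
deterministic sliver (~100-115 of 2000) of bulk eigenvalues sits nearer
`-m`; the multiplicity-split test tolerates 150.

## Lotka-Volterra meta-ecosystems

The simulation pipeline relaxes the random-matrix idealization by building
actual Lotka-Volterra systems

    dN_ix/dt = N_ix * (r_ix + sum_j alpha_ijx N_jx)
               + sum_{y != x} d_ixy (N_iy - N_ix)

and assessing stability of their *feasible* equilibria.

**Parameterization** (defaults): `S = 15`, `n = 10`, connectance
`c = 0.2`, coefficients Normal(0, 0.25), all diagonals `-1`. A regional
coefficient matrix is drawn once; each patch multiplies every non-null
element by an independent Normal(1, 0.1) deviate (zero elements are zero
everywhere). The multiplicative model gives cross-patch coefficient
correlation `1/(1 + het_sd^2) ~= 0.99` at the default heterogeneity.

**Intrinsic rates.** How `r_ix` is distributed is genuinely open; the
default sets `r_ix = 1` for all species and patches (a `uniform(0,1)`
policy is available). With unit rates and `-1` diagonals the feasibility
acceptance rate at the default parameterization is healthy (typically a
few attempts per feasible system). This is an assumption of the package,
stated here prominently; predator intrinsic rates are *not* made negative
in niche-web runs, and no claim is made that this reproduces any
particular published choice.

**Feasibility.** Systems are rejection-sampled on the strict positivity of
the isolated (`d = 0`) equilibrium, which solves `alpha N = -r` per patch.
Along the dispersal gradient positivity is re-evaluated and flagged at
every point but, by default, flagged points are not discarded — both
conventions are visible in the sweep output.

**Equilibrium continuation.** Sweeps ascend the dispersal grid (default
log-spaced; the full-resolution grid is 601 points over 1e-3..1e3, the
default test grid 25 points — chosen as the package's CI-scale default)
and warm-start a damped Newton iteration from the previous solution, so
the branch continuous with the feasible `d = 0` equilibrium is followed;
no multi-root search is attempted. Newton settings: residual max-norm
tolerance 1e-10, at most 100 iterations, up to 20 step halvings. Identical
patches (`het_sd = 0`) are a useful degenerate case: the symmetric point
solves every `d` exactly, and the solver returns it unchanged (this is a
test).

**Linearization.** The Jacobian is analytic: within-patch entry `(i, j)`
is `delta_ij*(r + alpha N)_ix + N_ix*alpha_ijx` plus the emigration term
`-d` on the diagonal; cross-patch blocks hold only the species-diagonal
immigration rates. Central finite differences confirm it to 1e-6 over 100
random small systems.

**Sweep diagnostics** (computed on the Jacobian, non-null within-patch
positions only): leading eigenvalue real part; s.d. of non-null elements;
mean Pearson correlation of vectorized non-null entries over all unordered
patch pairs (the estimator is a package choice — the quantity "inter-patch
correlation" does not pin one); mean diagonal. Ensemble averages exclude
non-converged points (counts reported), never impute.

## Niche-model food webs

The predator-prey topology generator is the standard niche model: niche
positions uniform on [0,1]; feeding-interval width `eta_i * Beta(1,
1/(2C) - 1)` so expected connectance is `C`; interval centre uniform
between the half-width and `eta_i`; the smallest-niche species is basal.
Cannibal links are dropped (self-regulation is the `-1` diagonal), and
webs with trophically isolated species are redrawn up to 100 times.
Dropping cannibal links biases realized connectance slightly below target
(measured mean ~0.19 at `C = 0.2`, `S = 15`).

Signs: one magnitude `|Normal(0, sigma)|` per linked pair; resource ->
consumer effect positive (bottom-up gain), consumer -> resource negative.
Which sign goes where is a documented package constant — antisymmetry
itself is the constraint. Patch heterogeneity is applied after sign
assignment, independently per element, so exact antisymmetry holds
regionally but may be broken across patches; `strict_antisymmetry=True`
shares the deviate within each pair instead.

## Seeds and reproducibility

One root seed expands into named substreams (mask, regional coefficients,
patch deviates, food web, heterogeneity, rates, per-replicate) keyed by a
CRC-32 of the stream name. Changing one factor (e.g. `rho`, or the
dispersal topology arm of a comparison) therefore cannot reshuffle the
draws of another — this is what makes `topology_comparison` a paired
design. Every ensemble emits a manifest (config echo, root seed, stream
names, timings, exclusion counts) sufficient to reproduce it bit-for-bit.

## What the synthetic generators do and do not emulate

The generators produce exactly the idealized study conditions: shared
species pools, interaction coefficients i.i.d. up to the `rho`/heterogeneity
structure, uniform dispersal rates, no correlation between diagonal
strength, interaction strength and dispersal. Real food webs violate most
of these (degree heterogeneity, body-size structure, correlated pairs,
density-dependent dispersal), so passing tests demonstrate internal
consistency of the theory and its simulation pipeline, not fidelity to any
empirical ecosystem.

## Known limitations

* Closed-form criteria and disk predictions cover global dispersal only;
  ring topologies are handled numerically.
* The low-dispersal bound is asymptotic in small `d`; no validity cutoff
  is enforced.
* Dense eigensolvers limit practical sizes to `nS` of a few thousand.
* Feasibility filtering conditions the ensembles in ways that have no
  closed-form description; the interesting mid-`d` regime is reachable
  only through simulation.
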
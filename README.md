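# metaeco

Stability–complexity analysis for **meta-ecosystems**: local ecological
communities coupled by passive dispersal of organisms.

Classic random-matrix theory says a single community of `S` species with
connectance `c`, interaction-strength s.d. `σ` and self-regulation `m` is
stable only when its complexity respects

    σ √(S c) < m,

because the eigenvalues of its community matrix fill a disk of radius
`σ√(Sc)` centred at `−m`. This package extends that machinery to `n`
patches coupled by diffusion at rate `d`, where the `nS × nS` community
matrix is

    J = A − m I + D

(`A`: block-diagonal random interaction blocks whose coefficients are
correlated `ρ` across patches; `D`: the dispersal matrix). Dispersal acts
through three effects the package computes and verifies:

* **eigenvalue pushback** — `S(n−1)` eigenvalues shift left to
  `−m − dn/(n−1)`;
* **Jacobian averaging** — the remaining `S` eigenvalues keep their centre
  but shrink in radius by `√n_e`, where `n_e = n / (1 + (n−1)ρ)` is the
  effective number of ecologically independent patches, relaxing the
  stability bound to `σ√(Sc) < m √n_e`;
* **negative feedback** — at low `d`, emigration adds `−d` of
  self-regulation: `σ√(Sc) < m + d`.

Alongside the analytical criteria, a simulation pipeline builds **feasible
Lotka–Volterra meta-ecosystems** (all equilibrium densities strictly
positive), follows their equilibria along a dispersal gradient by Newton
continuation, linearizes analytically, and measures how stability and the
Jacobian's structure (element s.d., inter-patch correlation, diagonal)
respond to dispersal — including ring (torus) dispersal and niche-model
predator–prey topologies.

Intended users: theoretical ecologists exploring stability–complexity and
metacommunity questions, and anyone needing a reproducible generator of
block-structured random community matrices.

## Worked example

```python
import numpy as np
import metaeco as me

# Is an isolated 100-species community stable? And its 20-patch meta-ecosystem?
print(me.may_criterion(S=100, c=0.3, sigma=1.0, m=2.0))
print(me.high_dispersal_criterion(S=100, c=0.3, sigma=1.0, m=2.0, n=20, rho=0.0))

# Verify numerically: assemble one random Jacobian at strong dispersal
params = me.RMTParams(S=100, n=20, c=0.3, sigma=1.0, m=2.0, rho=0.0, d=8.0, seed=1)
blocks = me.sample_interaction_blocks(params)
D = me.build_dispersal_matrix(20, 100, 8.0, "global")
summary = me.eigen_summary(me.assemble_jacobian(blocks, 2.0, D))
print(f"leading eigenvalue real part: {summary.leading_real:.3f}  stable: {summary.stable}")
pred = me.predict_esd(params)
for disk in pred.disks:
    print(f"disk: centre {disk.centre:.3f}, radius {disk.radius:.3f}, x{disk.multiplicity}")
print(f"coverage at 5% inflation: {me.disk_coverage(summary, pred, 0.05):.3f}")

# Feasible Lotka-Volterra ensemble: stability peaks at intermediate dispersal
ens = me.replicate_ensemble(me.RunConfig(replicates=30, d_points=25, seed=11))
i = int(np.argmin(ens.mean_leading_real))
print(f"most stable at d = {ens.d_grid[i]:.3g}: mean leading eigenvalue "
      f"{ens.mean_leading_real[i]:.4f} (vs {ens.mean_leading_real[0]:.4f} at d = 0.001)")
```

prints

```
StabilityVerdict(stable=False, margin=-3.477225575051661, regime='isolated')
StabilityVerdict(stable=True, margin=3.467046334947498, regime='high_d')
leading eigenvalue real part: -0.775  stable: True
disk: centre -2.000, radius 1.225, x100
disk: centre -10.421, radius 5.339, x1900
coverage at 5% inflation: 0.981
most stable at d = 0.316: mean leading eigenvalue -0.3226 (vs -0.2196 at d = 0.001)
```

Reading it: the isolated community is far past May's bound
(`σ√(Sc) = √30 ≈ 5.48 > m = 2`, margin −3.48), but 20 independent patches
raise the bound by `√20` (margin +3.47) — and the assembled 2000×2000
Jacobian confirms it: its leading eigenvalue is negative, with 1900
eigenvalues pushed back to the disk at −10.42 and 100 averaged into the
shrunken disk at −2, 98% of them inside the predicted disks. The
Lotka–Volterra ensemble shows the same stabilization is maximal at an
intermediate dispersal rate.

A `metaeco` CLI wraps the same library (`criteria`, `sweep`, `ensemble`,
`compare` subcommands); see `metaeco --help`.

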
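"""Feasible Lotka-Volterra meta-ecosystems under passive dispersal.

The model tracks the density N_ix of species i in patch x:

    dN_ix/dt = N_ix * (r_ix + sum_j alpha_ijx * N_jx) + Delta_ix

with passive diffusive dispersal

    Delta_ix = sum_{y != x} d_ixy * (N_iy - N_ix),

where d_ixy = d/(n-1) for global coupling and d/2 for the two torus
neighbours of a ring.  ``alpha_ijx`` is the per-capita effect of species j
on species i in patch x; ``r_ix`` is the intrinsic rate of increase.

Terminology note: in classic stability-complexity notation ``m`` denotes the
intraspecific feedback strength on the Jacobian diagonal, while in the
Lotka-Volterra parameterization the same letter is often used for the
intrinsic rate.  This package separates them: the feedback strength is
``m`` (or ``m_self``) in :mod:`metaeco.rmt` / :mod:`metaeco.criteria`, and
intrinsic rates are ``r`` here.

Patch heterogeneity multiplies each non-null regional coefficient by an
independent normal deviate (mean 1, s.d. ``het_sd``) per patch; null
coefficients are null everywhere.  Equilibria are found by direct linear
solve per patch at d = 0 and by damped Newton continuation along a dispersal
gradient otherwise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cli_io import seed_streams
from .errors import AssemblyError, FeasibilitySamplingError, ParameterError, SolverError
from .foodweb import niche_model, signed_coefficients
from .rmt import JacobianMatrix, _patch_coupling

__all__ = [
    "LVParams",
    "LVSystem",
    "EquilibriumResult",
    "build_lv_system",
    "solve_equilibrium_isolated",
    "sample_feasible_system",
    "solve_equilibrium_dispersal",
    "lv_jacobian",
]

NEWTON_TOL = 1e-10
NEWTON_MAX_ITER = 100
NEWTON_MAX_HALVINGS = 20


@dataclass(frozen=True)
class LVParams:
    """Generating parameters for a random Lotka-Volterra meta-ecosystem."""

    S: int = 15
    n: int = 10
    c: float = 0.2
    sigma: float = 0.25
    het_sd: float = 0.1
    topology_kind: str = "random"  # "random" | "niche_model"
    dispersal_topology: str = "global"  # "global" | "ring"
    r_policy: str = "constant"  # "constant" | "uniform"
    r_value: float = 1.0
    strict_antisymmetry: bool = False

    def __post_init__(self) -> None:
        if self.S < 1 or self.n < 1:
            raise ParameterError(f"need S >= 1 and n >= 1, got S={self.S}, n={self.n}")
        if not 0.0 <= self.c <= 1.0:
            raise ParameterError(f"c must lie in [0, 1], got {self.c}")
        if self.sigma < 0 or self.het_sd < 0:
            raise ParameterError("sigma and het_sd must be >= 0")
        if self.topology_kind not in ("random", "niche_model"):
            raise ParameterError(f"unknown topology_kind {self.topology_kind!r}")
        if self.dispersal_topology not in ("global", "ring"):
            raise ParameterError(f"unknown dispersal_topology {self.dispersal_topology!r}")
        if self.r_policy not in ("constant", "uniform"):
            raise ParameterError(f"unknown r_policy {self.r_policy!r}")


@dataclass
class LVSystem:
    """A parameterized Lotka-Volterra meta-ecosystem.

    ``alpha[x]`` is the S x S per-capita interaction matrix of patch x
    (diagonal -1 by default); ``r[i, x]`` the intrinsic rate of species i in
    patch x; ``mask`` the shared off-diagonal occupancy (zero coefficients
    are zero in every patch).
    """

    alpha: np.ndarray  # (n, S, S)
    r: np.ndarray  # (S, n)
    mask: np.ndarray  # (S, S) bool, off-diagonal occupancy
    topology: str  # dispersal topology: "global" | "ring"
    params: LVParams | None = None
    seed: int | None = None

    @property
    def S(self) -> int:
        return self.alpha.shape[1]

    @property
    def n(self) -> int:
        return self.alpha.shape[0]

    def save(self, path: str | Path) -> None:
        """JSON bundle: parameters, seed and a digest of the regional draw."""
        digest = hashlib.sha256(np.ascontiguousarray(self.alpha).tobytes()).hexdigest()
        payload = {
            "params": None if self.params is None else self.params.__dict__,
            "seed": self.seed,
            "topology": self.topology,
            "alpha_sha256": digest,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass
class EquilibriumResult:
    """A solved steady state with its feasibility flag.

    ``feasible`` requires strictly positive density for every species in
    every patch; ``residual_norm`` is the max-norm of the full dynamical
    equations (growth + dispersal balance) at ``N_star``.
    """

    N_star: np.ndarray  # (S, n)
    feasible: bool
    residual_norm: float
    converged: bool
    d_used: float
    iterations: int = 0

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        S, n = self.N_star.shape
        pd.DataFrame(
            self.N_star,
            index=[f"s{i + 1}" for i in range(S)],
            columns=[f"p{x + 1}" for x in range(n)],
        ).to_csv(path)


def build_lv_system(
    S: int = 15,
    n: int = 10,
    c: float = 0.2,
    sigma: float = 0.25,
    het_sd: float = 0.1,
    topology_kind: str = "random",
    seed: int = 0,
    dispersal_topology: str = "global",
    r_policy: str = "constant",
    r_value: float = 1.0,
    strict_antisymmetry: bool = False,
) -> LVSystem:
    """Draw one random meta-ecosystem.

    A regional S x S coefficient matrix is drawn once — unstructured
    Normal(0, sigma) on a Bernoulli(c) mask for ``topology_kind="random"``,
    or antisymmetric predator-prey coefficients on a niche-model web for
    ``"niche_model"``.  Each patch matrix equals the regional matrix with
    every non-null element multiplied by an independent Normal(1, het_sd)
    deviate; diagonals are -1 everywhere and zero elements are identical
    (zero) in every patch.

    With ``strict_antisymmetry=True`` the heterogeneity deviate is shared by
    the two members of each linked pair, so a_ij = -a_ji survives within
    each patch (relevant for niche webs only).
    """
    params = LVParams(
        S=S, n=n, c=c, sigma=sigma, het_sd=het_sd, topology_kind=topology_kind,
        dispersal_topology=dispersal_topology, r_policy=r_policy, r_value=r_value,
        strict_antisymmetry=strict_antisymmetry,
    )
    return _build_from_params(params, seed)


def _build_from_params(params: LVParams, seed: int) -> LVSystem:
    S, n = params.S, params.n
    streams = seed_streams(seed, ["mask", "regional", "foodweb", "heterogeneity", "rates"])

    if params.topology_kind == "random":
        mask = streams["mask"].random((S, S)) < params.c
        np.fill_diagonal(mask, False)
        regional = np.where(mask, streams["regional"].normal(0.0, params.sigma, (S, S)), 0.0)
    else:
        web = niche_model(S, params.c, seed=streams["foodweb"])
        regional = signed_coefficients(web, params.sigma, seed=streams["regional"])
        mask = regional != 0.0

    rng_het = streams["heterogeneity"]
    alpha = np.empty((n, S, S))
    for x in range(n):
        deviate = rng_het.normal(1.0, params.het_sd, (S, S))
        if params.strict_antisymmetry:
            iu = np.triu_indices(S, k=1)
            sym = deviate.copy()
            sym[(iu[1], iu[0])] = deviate[iu]
            deviate = sym
        alpha[x] = np.where(mask, regional * deviate, 0.0)
        np.fill_diagonal(alpha[x], -1.0)

    if params.r_policy == "constant":
        r = np.full((S, n), float(params.r_value))
    else:
        r = streams["rates"].random((S, n))
    return LVSystem(alpha=alpha, r=r, mask=mask, topology=params.dispersal_topology,
                    params=params, seed=seed)


def _dispersal_coupling(n: int, topology: str, d: float) -> np.ndarray:
    """n x n patch operator P with Delta[:, x] = (N @ P.T)[:, x]."""
    return d * _patch_coupling(n, topology) if d != 0 else np.zeros((n, n))


def _residual(system: LVSystem, N: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Full dynamical equations at N, shape (S, n)."""
    growth = np.empty_like(N)
    for x in range(system.n):
        growth[:, x] = N[:, x] * (system.r[:, x] + system.alpha[x] @ N[:, x])
    return growth + N @ P.T


def _jacobian_at(system: LVSystem, N: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the dynamics at state N, patch-major (nS x nS)."""
    S, n = system.S, system.n
    J = np.kron(P, np.eye(S))
    for x in range(n):
        g = system.r[:, x] + system.alpha[x] @ N[:, x]
        block = N[:, x][:, None] * system.alpha[x]
        block[np.diag_indices(S)] += g
        J[x * S:(x + 1) * S, x * S:(x + 1) * S] += block
    return J


def solve_equilibrium_isolated(system: LVSystem) -> EquilibriumResult:
    """Interior equilibrium of every patch in the absence of dispersal.

    Per patch the interior steady state solves the linear system
    alpha @ N = -r.  Feasibility requires strictly positive densities in
    every patch.
    """
    S, n = system.S, system.n
    N = np.empty((S, n))
    for x in range(n):
        try:
            N[:, x] = np.linalg.solve(system.alpha[x], -system.r[:, x])
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"singular interaction matrix in patch {x}") from exc
    P = np.zeros((n, n))
    residual = float(np.max(np.abs(_residual(system, N, P))))
    return EquilibriumResult(
        N_star=N,
        feasible=bool(np.all(N > 0)),
        residual_norm=residual,
        converged=residual < NEWTON_TOL,
        d_used=0.0,
    )


def sample_feasible_system(
    params: LVParams,
    seed: int = 0,
    max_attempts: int = 200,
) -> tuple[LVSystem, EquilibriumResult, int]:
    """Rejection-sample a meta-ecosystem whose d = 0 equilibrium is feasible.

    Systems are drawn from independent substreams of ``seed`` until the
    isolated equilibrium has strictly positive densities in every patch.
    Returns (system, equilibrium, attempts); raises after ``max_attempts``
    rejections.
    """
    if max_attempts < 1:
        raise ParameterError(f"max_attempts must be >= 1, got {max_attempts}")
    rejected_singular = 0
    for attempt in range(1, max_attempts + 1):
        # deterministic per-attempt sub-seed below 2**31
        sub_seed = int(np.random.SeedSequence(
            entropy=int(seed), spawn_key=(attempt,)).generate_state(1)[0] % (2**31))
        system = _build_from_params(params, sub_seed)
        try:
            eq = solve_equilibrium_isolated(system)
        except SolverError:
            rejected_singular += 1
            continue
        if eq.feasible:
            return system, eq, attempt
    raise FeasibilitySamplingError(
        f"no feasible system in {max_attempts} attempts "
        f"({rejected_singular} singular) for params {params}"
    )


def solve_equilibrium_dispersal(
    system: LVSystem,
    d: float,
    init: np.ndarray,
    tol: float = NEWTON_TOL,
    max_iter: int = NEWTON_MAX_ITER,
) -> EquilibriumResult:
    """Damped Newton solve of the coupled equilibrium at diffusion rate d.

    ``init`` must be strictly positive — typically the solution at the
    previous point of an ascending dispersal grid, so the branch continuous
    with the feasible d = 0 equilibrium is tracked.  Steps that fail to
    reduce the residual max-norm are halved up to 20 times.  Non-convergence
    is flagged on the result, not raised: sweep drivers exclude flagged
    points from ensemble averages.
    """
    if d < 0:
        raise ParameterError(f"d must be >= 0, got {d}")
    init = np.asarray(init, dtype=float)
    if init.shape != (system.S, system.n):
        raise AssemblyError(f"init shape {init.shape} != ({system.S}, {system.n})")
    if np.any(init <= 0):
        raise ParameterError("init must be strictly positive")

    P = _dispersal_coupling(system.n, system.topology, d)
    N = init.copy()
    F = _residual(system, N, P)
    norm = float(np.max(np.abs(F)))
    iterations = 0
    converged = norm < tol
    while not converged and iterations < max_iter:
        J = _jacobian_at(system, N, P)
        try:
            step = np.linalg.solve(J, -F.reshape(-1, order="F"))
        except np.linalg.LinAlgError:
            break
        step = step.reshape((system.S, system.n), order="F")
        scale = 1.0
        for _ in range(NEWTON_MAX_HALVINGS + 1):
            trial = N + scale * step
            F_trial = _residual(system, trial, P)
            trial_norm = float(np.max(np.abs(F_trial)))
            if trial_norm < norm:
                break
            scale *= 0.5
        else:
            break
        N, F, norm = trial, F_trial, trial_norm
        iterations += 1
        converged = norm < tol

    return EquilibriumResult(
        N_star=N,
        feasible=bool(np.all(N > 0)),
        residual_norm=norm,
        converged=converged,
        d_used=float(d),
        iterations=iterations,
    )


def lv_jacobian(system: LVSystem, equilibrium: EquilibriumResult, d: float) -> JacobianMatrix:
    """Analytic Jacobian of the dynamics at a converged equilibrium.

    Within-patch off-diagonal entry (i, j) is N*_ix * alpha_ijx; cross-patch
    blocks carry only the species-diagonal dispersal rates d_ixy.
    Patch-major ordering matches :mod:`metaeco.rmt`.
    """
    if not equilibrium.converged:
        raise SolverError("refusing to linearize a non-converged equilibrium")
    if equilibrium.N_star.shape != (system.S, system.n):
        raise AssemblyError(
            f"equilibrium shape {equilibrium.N_star.shape} != ({system.S}, {system.n})"
        )
    P = _dispersal_coupling(system.n, system.topology, d)
    J = _jacobian_at(system, equilibrium.N_star, P)
    return JacobianMatrix(
        matrix=J,
        components={"n": system.n, "S": system.S, "d": d, "topology": system.topology},
    )
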
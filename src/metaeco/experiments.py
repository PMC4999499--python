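"""Dispersal sweeps, replicate ensembles and topology comparisons.

A sweep follows one feasible meta-ecosystem along an ascending log-spaced
dispersal grid, warm-starting each Newton solve from the previous point and
recording four diagnostics of the equilibrium Jacobian: the leading
eigenvalue real part (stability), the s.d. of its non-null within-patch
elements, the mean cross-patch correlation of those elements, and the mean
diagonal.  Ensembles average the curves over independently drawn feasible
systems; non-converged points are excluded from the averages, never imputed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cli_io import RunConfig, RunManifest, substream_seed
from .errors import ParameterError
from .lv import (
    EquilibriumResult,
    LVParams,
    LVSystem,
    lv_jacobian,
    sample_feasible_system,
    solve_equilibrium_dispersal,
    solve_equilibrium_isolated,
)
from .spectra import eigen_summary

__all__ = [
    "SweepResult",
    "EnsembleResult",
    "make_d_grid",
    "dispersal_sweep",
    "replicate_ensemble",
    "topology_comparison",
    "critical_sigma",
]


@dataclass
class SweepResult:
    """Per-dispersal-rate stability and Jacobian diagnostics for one system."""

    d_grid: np.ndarray
    leading_real: np.ndarray
    sd_offdiag: np.ndarray
    interpatch_corr: np.ndarray
    mean_diag: np.ndarray
    excluded: np.ndarray  # bool, True where the solve did not converge
    feasible: np.ndarray  # bool, positivity of the equilibrium at each d

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d": self.d_grid,
                "leading_real": self.leading_real,
                "sd_offdiag": self.sd_offdiag,
                "interpatch_corr": self.interpatch_corr,
                "mean_diag": self.mean_diag,
                "excluded": self.excluded,
                "feasible": self.feasible,
            }
        )


@dataclass
class EnsembleResult:
    """Replicate-averaged sweep curves plus the per-replicate results."""

    d_grid: np.ndarray
    sweeps: list[SweepResult]
    mean_leading_real: np.ndarray
    mean_sd_offdiag: np.ndarray
    mean_interpatch_corr: np.ndarray
    mean_mean_diag: np.ndarray
    n_excluded: np.ndarray
    manifest: RunManifest | None = None
    seeds: list[int] = field(default_factory=list)

    @property
    def replicates(self) -> int:
        return len(self.sweeps)

    def as_dataframe(self) -> pd.DataFrame:
        """Tidy frame: one row per replicate x dispersal rate."""
        frames = []
        for k, sweep in enumerate(self.sweeps):
            df = sweep.as_dataframe()
            df.insert(0, "replicate", k)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def averaged_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d": self.d_grid,
                "mean_leading_real": self.mean_leading_real,
                "mean_sd_offdiag": self.mean_sd_offdiag,
                "mean_interpatch_corr": self.mean_interpatch_corr,
                "mean_mean_diag": self.mean_mean_diag,
                "n_excluded": self.n_excluded,
            }
        )


def make_d_grid(lo: float, hi: float, log_step: float) -> np.ndarray:
    """Log10-spaced dispersal grid, inclusive of both endpoints.

    ``make_d_grid(0.001, 1000, 1.0)`` gives the 7 decades 1e-3 .. 1e3;
    the fine grid used for full runs is ``log_step=0.01`` (601 points).
    """
    if not 0 < lo < hi:
        raise ParameterError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if log_step <= 0:
        raise ParameterError(f"log_step must be > 0, got {log_step}")
    lo_exp, hi_exp = np.log10(lo), np.log10(hi)
    exponents = np.arange(lo_exp, hi_exp + log_step / 2.0, log_step)
    return 10.0 ** exponents


def critical_sigma(
    S: int,
    n: int,
    c: float,
    m: float,
    d: float,
    rho: float = 0.0,
    draws: int = 50,
    steps: int = 8,
    seed: int = 0,
    bracket: tuple[float, float] | None = None,
) -> float:
    """Monte-Carlo estimate of the critical interaction strength.

    Bisects on sigma for P(stable) = 1/2, where P is the fraction of
    ``draws`` random meta-ecosystem Jacobians whose leading eigenvalue real
    part is negative.  The high-dispersal theory predicts the critical sigma
    scales as m * sqrt(n_e) / sqrt(S * c), i.e. as sqrt(n) across patch
    counts when rho = 0.

    The default bracket spans [0.2, 3] times the predicted critical value.
    """
    from .criteria import effective_patch_number
    from .rmt import RMTParams, assemble_jacobian, build_dispersal_matrix, sample_interaction_blocks

    predicted = m * np.sqrt(effective_patch_number(n, rho)) / np.sqrt(S * c)
    lo, hi = bracket if bracket is not None else (0.2 * predicted, 3.0 * predicted)
    D = build_dispersal_matrix(n, S, d, "global")
    rng = np.random.default_rng(substream_seed(seed, "critical_sigma"))

    def p_stable(sigma: float) -> float:
        stable = 0
        for _ in range(draws):
            params = RMTParams(S=S, n=n, c=c, sigma=sigma, m=m, rho=rho, d=d,
                               seed=int(rng.integers(2**31)))
            blocks = sample_interaction_blocks(params)
            J = assemble_jacobian(blocks, m, D)
            if eigen_summary(J).leading_real < 0:
                stable += 1
        return stable / draws

    for _ in range(steps):
        mid = 0.5 * (lo + hi)
        if p_stable(mid) >= 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _grid_from_config(config: RunConfig) -> np.ndarray:
    return np.logspace(np.log10(config.d_min), np.log10(config.d_max), config.d_points)


def _jacobian_diagnostics(system: LVSystem, J: np.ndarray) -> tuple[float, float, float]:
    """(sd of non-null within-patch elements, mean cross-patch correlation of
    those elements, mean diagonal) of a patch-major Jacobian.

    Diagnostics use the shared off-diagonal occupancy mask, so they see the
    same set of (i, j) positions in every patch.  The cross-patch
    correlation is the Pearson correlation of the vectorized non-null
    entries, averaged over all unordered patch pairs.
    """
    S, n = system.S, system.n
    values = np.empty((n, int(system.mask.sum())))
    for x in range(n):
        block = J[x * S:(x + 1) * S, x * S:(x + 1) * S]
        values[x] = block[system.mask]
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0

    if n < 2 or values.shape[1] < 2:
        corr = np.nan
    else:
        corr_matrix = np.corrcoef(values)
        iu = np.triu_indices(n, k=1)
        corr = float(np.mean(corr_matrix[iu]))
    mean_diag = float(np.mean(np.diag(J)))
    return sd, corr, mean_diag


def dispersal_sweep(
    system: LVSystem,
    d_grid: np.ndarray,
    eq0: EquilibriumResult | None = None,
) -> SweepResult:
    """Follow one system's equilibrium branch along an ascending d grid.

    The system must be feasible at d = 0; each grid point is warm-started
    from the previous solution.  Diagnostics at non-converged points are
    NaN and flagged in ``excluded``.
    """
    d_grid = np.asarray(d_grid, dtype=float)
    if d_grid.ndim != 1 or d_grid.size == 0 or np.any(np.diff(d_grid) <= 0):
        raise ParameterError("d_grid must be a non-empty strictly increasing 1-D array")
    if eq0 is None:
        eq0 = solve_equilibrium_isolated(system)
    if not eq0.feasible:
        raise ParameterError("system is not feasible at d = 0; sample a feasible one first")

    k = d_grid.size
    leading = np.full(k, np.nan)
    sd_offdiag = np.full(k, np.nan)
    interpatch = np.full(k, np.nan)
    mean_diag = np.full(k, np.nan)
    excluded = np.zeros(k, dtype=bool)
    feasible = np.zeros(k, dtype=bool)

    warm = eq0.N_star
    for idx, d in enumerate(d_grid):
        eq = solve_equilibrium_dispersal(system, d, init=warm)
        feasible[idx] = eq.feasible
        if not eq.converged:
            excluded[idx] = True
            continue
        warm = np.maximum(eq.N_star, 1e-300)
        J = lv_jacobian(system, eq, d).matrix
        leading[idx] = eigen_summary(J).leading_real
        sd_offdiag[idx], interpatch[idx], mean_diag[idx] = _jacobian_diagnostics(system, J)

    return SweepResult(
        d_grid=d_grid,
        leading_real=leading,
        sd_offdiag=sd_offdiag,
        interpatch_corr=interpatch,
        mean_diag=mean_diag,
        excluded=excluded,
        feasible=feasible,
    )


def _params_from_config(config: RunConfig) -> LVParams:
    return LVParams(
        S=config.S,
        n=config.n,
        c=config.c,
        sigma=config.sigma,
        het_sd=config.het_sd,
        topology_kind=config.interaction_topology,
        dispersal_topology=config.dispersal_topology,
        r_policy=config.r_policy,
        r_value=config.r_value,
    )


def replicate_ensemble(config: RunConfig, d_grid: np.ndarray | None = None) -> EnsembleResult:
    """Average sweep curves over independently drawn feasible systems.

    Each replicate gets its own named substream of the root seed, so the
    ensemble is deterministic given the config and replicate curves are
    unchanged when the replicate count grows.
    """
    params = _params_from_config(config)
    if d_grid is None:
        d_grid = _grid_from_config(config)
    manifest = RunManifest(config=config.to_dict(), root_seed=config.seed,
                           stream_names=[f"replicate_{k}" for k in range(config.replicates)])
    manifest.start("ensemble")

    sweeps: list[SweepResult] = []
    seeds: list[int] = []
    for k in range(config.replicates):
        rep_seed = int(substream_seed(config.seed, f"replicate_{k}").generate_state(1)[0] % (2**31))
        seeds.append(rep_seed)
        system, eq0, _ = sample_feasible_system(params, seed=rep_seed,
                                                max_attempts=config.max_attempts)
        sweeps.append(dispersal_sweep(system, d_grid, eq0=eq0))

    stack = {
        name: np.vstack([getattr(s, name) for s in sweeps])
        for name in ("leading_real", "sd_offdiag", "interpatch_corr", "mean_diag")
    }
    excluded = np.vstack([s.excluded for s in sweeps])
    with np.errstate(invalid="ignore"):
        means = {name: np.nanmean(arr, axis=0) for name, arr in stack.items()}
    manifest.stop("ensemble")
    manifest.exclusions["non_converged_points"] = int(excluded.sum())

    return EnsembleResult(
        d_grid=np.asarray(d_grid, dtype=float),
        sweeps=sweeps,
        mean_leading_real=means["leading_real"],
        mean_sd_offdiag=means["sd_offdiag"],
        mean_interpatch_corr=means["interpatch_corr"],
        mean_mean_diag=means["mean_diag"],
        n_excluded=excluded.sum(axis=0),
        manifest=manifest,
        seeds=seeds,
    )


def topology_comparison(
    config: RunConfig,
    compare: str = "dispersal",
    d_grid: np.ndarray | None = None,
) -> tuple[EnsembleResult, EnsembleResult]:
    """Paired ensembles differing only in one topological factor.

    ``compare="dispersal"`` contrasts global vs ring (nearest-neighbour
    torus) patch coupling; ``compare="interactions"`` contrasts unstructured
    random sign patterns vs niche-model predator-prey webs.  Both arms share
    the root seed, hence identical replicate substreams, making the
    comparison paired.
    """
    if compare == "dispersal":
        arm_a = dataclasses.replace(config, dispersal_topology="global")
        arm_b = dataclasses.replace(config, dispersal_topology="ring")
    elif compare == "interactions":
        arm_a = dataclasses.replace(config, interaction_topology="random")
        arm_b = dataclasses.replace(config, interaction_topology="niche_model")
    else:
        raise ParameterError(f"compare must be 'dispersal' or 'interactions', got {compare!r}")
    return replicate_ensemble(arm_a, d_grid=d_grid), replicate_ensemble(arm_b, d_grid=d_grid)
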
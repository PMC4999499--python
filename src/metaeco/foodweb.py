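"""Niche-model food webs and signed predator-prey coefficient matrices.

The niche model (Williams & Martinez) places each species at a position
``eta_i`` drawn uniformly on a one-dimensional niche axis.  Each consumer
eats every species falling inside a single interval on that axis: the
interval width is ``eta_i`` times a Beta(1, 1/(2C) - 1) deviate — chosen so
the expected connectance is C — and its centre is uniform between the
half-width and ``eta_i`` (consumers feed at or below their own position on
average).  The species with the smallest niche value gets an empty diet, so
every web has at least one basal species.

Interaction signs follow predator-prey antisymmetry: for each trophic link
one magnitude is drawn and the resource->consumer effect is +magnitude
(bottom-up gain) while the consumer->resource effect is -magnitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FeasibilitySamplingError, ParameterError

__all__ = ["FoodWebTopology", "niche_model", "signed_coefficients"]


@dataclass
class FoodWebTopology:
    """A directed food web on the niche axis.

    ``links`` holds ordered (consumer, resource) pairs, cannibalism
    excluded.  ``feeding_range[i] = (low, high)`` is consumer i's diet
    interval on the niche axis (empty diets have low > high).
    """

    S: int
    links: frozenset[tuple[int, int]]
    niche_values: np.ndarray
    target_connectance: float
    feeding_range: np.ndarray  # (S, 2) interval bounds

    @property
    def connectance(self) -> float:
        """Realized connectance |links| / S^2."""
        return len(self.links) / self.S**2

    def adjacency(self) -> np.ndarray:
        """Boolean matrix with entry [i, j] True when i eats j."""
        adj = np.zeros((self.S, self.S), dtype=bool)
        for i, j in self.links:
            adj[i, j] = True
        return adj

    def to_csv(self, path: str | Path) -> None:
        """Edge-list CSV (consumer, resource) plus a JSON header sidecar."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("consumer,resource\n")
            for i, j in sorted(self.links):
                fh.write(f"{i},{j}\n")
        header = {
            "S": self.S,
            "niche_values": self.niche_values.tolist(),
            "target_connectance": self.target_connectance,
            "feeding_range": self.feeding_range.tolist(),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FoodWebTopology":
        path = Path(path)
        links = set()
        with open(path) as fh:
            next(fh)
            for line in fh:
                if line.strip():
                    i, j = line.strip().split(",")
                    links.add((int(i), int(j)))
        header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            S=header["S"],
            links=frozenset(links),
            niche_values=np.asarray(header["niche_values"], dtype=float),
            target_connectance=header["target_connectance"],
            feeding_range=np.asarray(header["feeding_range"], dtype=float),
        )


def _draw_web(S: int, C: float, rng: np.random.Generator) -> FoodWebTopology:
    eta = rng.random(S)
    beta = 1.0 / (2.0 * C) - 1.0
    width = eta * rng.beta(1.0, beta, size=S)
    # smallest-niche species is basal: guarantees at least one primary producer
    width[np.argmin(eta)] = 0.0
    centre = rng.uniform(width / 2.0, eta)

    low = centre - width / 2.0
    high = centre + width / 2.0
    links = set()
    for i in range(S):
        if width[i] <= 0.0:
            low[i], high[i] = 1.0, 0.0  # empty-interval sentinel
            continue
        for j in range(S):
            if i != j and low[i] <= eta[j] <= high[i]:
                links.add((i, j))
    return FoodWebTopology(
        S=S,
        links=frozenset(links),
        niche_values=eta,
        target_connectance=C,
        feeding_range=np.column_stack([low, high]),
    )


def niche_model(
    S: int,
    C: float,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 100,
) -> FoodWebTopology:
    """Draw one niche-model food web with expected connectance C.

    Webs containing trophically isolated species (no links in or out) or no
    links at all are redrawn, up to ``max_attempts`` times; exhausting the
    budget raises.  The redraw rule is skipped for S = 1, where an isolated
    species is the only possible outcome.
    """
    if S < 1:
        raise ParameterError(f"S must be >= 1, got {S}")
    if not 0.0 < C < 0.5:
        raise ParameterError(f"C must lie in (0, 0.5) for the niche model, got {C}")
    if max_attempts < 1:
        raise ParameterError(f"max_attempts must be >= 1, got {max_attempts}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    for _ in range(max_attempts):
        web = _draw_web(S, C, rng)
        if S == 1:
            return web
        if not web.links:
            continue
        connected = np.zeros(S, dtype=bool)
        for i, j in web.links:
            connected[i] = connected[j] = True
        if connected.all():
            return web
    raise FeasibilitySamplingError(
        f"no admissible niche web in {max_attempts} attempts (S={S}, C={C}); "
        "isolated species or empty link sets in every draw"
    )


def signed_coefficients(
    topology: FoodWebTopology,
    sigma: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Signed interaction matrix for a food web: +|N(0, sigma)| from prey to
    predator, the exact negative from predator to prey.

    Entry [i, j] is the per-capita effect of species j on species i.  One
    magnitude is drawn per unordered linked pair, so a_ij = -a_ji holds
    exactly.  For (rare) mutual-predation pairs the lower-indexed species is
    treated as the consumer.  Diagonals stay zero; self-regulation is
    handled elsewhere.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = topology.S
    out = np.zeros((S, S))
    pairs = sorted({(min(i, j), max(i, j)) for i, j in topology.links})
    for a, b in pairs:
        magnitude = abs(rng.normal(0.0, sigma))
        consumer, resource = (a, b) if (a, b) in topology.links else (b, a)
        out[consumer, resource] = magnitude
        out[resource, consumer] = -magnitude
    return out
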
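"""Spreading-dye null models for range position.

The spreading-dye algorithm re-places each species' range at a random
position inside the domain while preserving its size and cohesion: a seed
cell is drawn uniformly, then unoccupied domain neighbours of the growing
patch are added one at a time (uniformly over the patch frontier) until
the species' observed cell count is reached.  Repeating the randomization
and refitting the range-size regressions yields null slope distributions
that reflect only domain geometry (mid-domain effects), against which the
observed slopes are judged with one-tailed percentile tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    GenerationFailureError,
    NullDistributionUnstableError,
    PlacementFailureError,
)
from .gridding import Grid, PresenceAbsenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "neighbor_table",
    "grow_patch",
    "spreading_dye",
    "null_slope_distribution",
    "one_tailed_test",
    "connected_components",
]

_OFFSETS = {
    "rook": ((1, 0), (-1, 0), (0, 1), (0, -1)),
    "queen": (
        (1, 0), (-1, 0), (0, 1), (0, -1),
        (1, 1), (1, -1), (-1, 1), (-1, -1),
    ),
}


def neighbor_table(
    grid: Grid, domain: np.ndarray, adjacency: str = "queen"
) -> dict[int, np.ndarray]:
    """Adjacency restricted to the domain: flat cell id → neighbour ids."""
    if adjacency not in _OFFSETS:
        raise ValueError(f"adjacency must be one of {sorted(_OFFSETS)}")
    dom = set(int(i) for i in np.asarray(domain).ravel())
    table: dict[int, np.ndarray] = {}
    nc = grid.n_cols
    nr = grid.n_rows
    for i in dom:
        r, c = divmod(i, nc)
        nbrs = []
        for dr, dc in _OFFSETS[adjacency]:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc:
                j = rr * nc + cc
                if j in dom:
                    nbrs.append(j)
        table[i] = np.array(nbrs, dtype=int)
    return table


def grow_patch(
    target: int,
    domain: np.ndarray,
    neighbors: dict[int, np.ndarray],
    rng: np.random.Generator,
    max_restarts: int = 50,
    label: str = "",
) -> np.ndarray:
    """Grow one cohesive patch of ``target`` cells by spreading dye.

    Restarts from a fresh seed if the frontier empties before reaching
    the target (the patch wandered into a cul-de-sac of the domain);
    raises after ``max_restarts`` exhausted attempts.
    """
    domain = np.asarray(domain, dtype=int).ravel()
    if target > domain.size:
        raise GenerationFailureError(
            f"range of {target} cells cannot fit a domain of {domain.size} "
            f"cells (species {label!r})"
        )
    for _ in range(max_restarts + 1):
        seed_cell = int(domain[rng.integers(domain.size)])
        patch = {seed_cell}
        frontier = [j for j in neighbors[seed_cell] if j not in patch]
        frontier_set = set(frontier)
        while len(patch) < target:
            if not frontier:
                break
            k = int(rng.integers(len(frontier)))
            cell = frontier[k]
            frontier[k] = frontier[-1]
            frontier.pop()
            frontier_set.discard(cell)
            patch.add(cell)
            for j in neighbors[cell]:
                if j not in patch and j not in frontier_set:
                    frontier.append(int(j))
                    frontier_set.add(int(j))
        if len(patch) == target:
            return np.fromiter(patch, dtype=int, count=target)
    raise PlacementFailureError(
        f"spreading dye exhausted {max_restarts} restarts (species {label!r})"
    )


def spreading_dye(
    pam: PresenceAbsenceMatrix,
    domain: np.ndarray | None = None,
    adjacency: str = "queen",
    seed=None,
    max_restarts: int = 50,
    neighbors: dict[int, np.ndarray] | None = None,
) -> PresenceAbsenceMatrix:
    """Randomize every species' range position, preserving its size.

    ``domain`` defaults to the realized study region: all cells occupied
    by at least one species in the observed PAM.  Per-species cell
    counts are conserved exactly and every randomized range is one
    connected patch under the chosen adjacency.
    """
    if domain is None:
        domain = pam.occupied_sites()
    domain = np.asarray(domain, dtype=int).ravel()
    if domain.size == 0:
        raise ValueError("empty domain")
    if neighbors is None:
        neighbors = neighbor_table(pam.grid, domain, adjacency)
    rng = np.random.default_rng(seed)
    counts = pam.matrix.sum(axis=0)
    out = np.zeros_like(pam.matrix)
    for j, sp in enumerate(pam.species):
        target = int(counts[j])
        if target == domain.size:
            out[domain, j] = True  # forced placement: range fills the domain
            continue
        cells = grow_patch(
            target, domain, neighbors, rng, max_restarts=max_restarts, label=sp
        )
        out[cells, j] = True
    return PresenceAbsenceMatrix(pam.grid, list(pam.species), out)


def connected_components(
    cells: np.ndarray, grid: Grid, adjacency: str = "queen"
) -> int:
    """Number of connected components of a cell set (flood fill)."""
    cells = set(int(i) for i in np.asarray(cells).ravel())
    if not cells:
        return 0
    nc = grid.n_cols
    nr = grid.n_rows
    seen: set[int] = set()
    comps = 0
    for start in cells:
        if start in seen:
            continue
        comps += 1
        stack = [start]
        seen.add(start)
        while stack:
            i = stack.pop()
            r, c = divmod(i, nc)
            for dr, dc in _OFFSETS[adjacency]:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc:
                    j = rr * nc + cc
                    if j in cells and j not in seen:
                        seen.add(j)
                        stack.append(j)
    return comps


# --------------------------------------------------------- null distributions
@dataclass
class NullDistribution:
    """Null slope distribution for one model × predictor combination."""

    label: str
    replicates: np.ndarray
    observed: float
    predicted_sign: str | None = None  # "positive" | "negative"
    cutoff: float | None = None
    significant: bool | None = None
    n_failed: int = 0

    def __post_init__(self):
        self.replicates = np.asarray(self.replicates, dtype=float)


def null_slope_distribution(
    pam: PresenceAbsenceMatrix,
    rebuild_and_fit,
    predictor: str,
    n_rep: int = 100,
    seed=None,
    domain: np.ndarray | None = None,
    adjacency: str = "queen",
    predicted_sign: str | None = None,
    label: str | None = None,
    max_restarts: int = 50,
) -> NullDistribution:
    """Spreading-dye null distribution of a standardized slope.

    ``rebuild_and_fit(pam) -> float`` recomputes the level-appropriate
    response/predictor tables from a PAM (ranges move; environmental
    layers stay fixed) and returns the fitted standardized slope of
    ``predictor``.  Failed replicate fits are dropped and logged; more
    than 20% failures aborts.  Deterministic given ``seed``.
    """
    observed = float(rebuild_and_fit(pam))
    if domain is None:
        domain = pam.occupied_sites()
    domain = np.asarray(domain, dtype=int).ravel()
    neighbors = neighbor_table(pam.grid, domain, adjacency)
    rng = np.random.default_rng(seed)
    slopes: list[float] = []
    failed = 0
    for rep in range(n_rep):
        rep_seed = int(rng.integers(2**31 - 1))
        try:
            pam_r = spreading_dye(
                pam, domain=domain, adjacency=adjacency, seed=rep_seed,
                max_restarts=max_restarts, neighbors=neighbors,
            )
            slopes.append(float(rebuild_and_fit(pam_r)))
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            failed += 1
            logger.warning("null replicate %d failed: %s", rep, exc)
    if failed > 0.2 * n_rep:
        raise NullDistributionUnstableError(
            f"{failed}/{n_rep} null replicates failed for {predictor!r}"
        )
    return NullDistribution(
        label=label or predictor,
        replicates=np.array(slopes),
        observed=observed,
        predicted_sign=predicted_sign,
        n_failed=failed,
    )


def one_tailed_test(dist: NullDistribution) -> NullDistribution:
    """Apply the directional percentile rule.

    Negative prediction: significant iff the observed slope lies below
    the empirical 5th percentile of the replicates; positive prediction:
    above the 95th.  Percentiles use inclusive linear interpolation and
    exclude the observed value.
    """
    if dist.predicted_sign not in {"positive", "negative"}:
        raise ValueError("predicted_sign must be 'positive' or 'negative'")
    if dist.replicates.size == 0:
        raise ValueError("empty null distribution")
    if dist.predicted_sign == "negative":
        dist.cutoff = float(np.percentile(dist.replicates, 5.0, method="linear"))
        dist.significant = bool(dist.observed < dist.cutoff)
    else:
        dist.cutoff = float(np.percentile(dist.replicates, 95.0, method="linear"))
        dist.significant = bool(dist.observed > dist.cutoff)
    return dist
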
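"""Synthetic worlds with known ground truth.

Generates everything the pipeline consumes — a Yule phylogeny, cohesive
gridded species ranges with a controllable latitude → log-range-size
slope and controllable phylogenetic signal, point occurrences sampled
inside occupied cells, and environmental layers with a latitudinal
minimum-temperature gradient, north–south topographic ridges, and a
past-climate surface — so every downstream stage is testable without any
external download.

The generative model for range size works on the standardized scale:
with ``m`` the standardized (phylogenetically autocorrelated) latitudinal
midpoints, the standardized log cell count is

    u = beta_rapoport · m + eps,
    eps ~ N(0, sigma_noise² · (lambda_true·C + (1−lambda_true)·I)),

with ``C`` the unit-depth Brownian correlation of the tree.  By default
``sigma_noise = sqrt(1 − beta_rapoport²)`` so that ``u`` has unit
variance and the standardized regression slope equals ``beta_rapoport``
in expectation.  Counts are back-transformed through a log-normal with
configurable location/scale, rounded, clamped to [1, n_cells], and each
range is placed cohesively by spreading-dye growth seeded at the domain
cell nearest the species' true midpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import GenerationFailureError
from .gridding import EnvLayerSet, Grid, PresenceAbsenceMatrix, write_ascii_grid
from .geometry import OccurrenceSet
from .nullmodels import grow_patch, neighbor_table
from .phylo import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_tree",
    "simulate_env_layers",
    "simulate_ranges",
    "brownian_traits",
    "simulate_world",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic world.

    ``beta_rapoport`` is the true slope of standardized log range size
    on standardized midpoint latitude; ``lambda_true`` (Pagel's λ in
    [0, 1]) structures the residuals on the tree; ``sigma_noise`` is the
    residual SD on the standardized scale (``None`` → sqrt(1 − β²), so
    the standardized response has unit variance).  The domain extent is
    in projected km; ``records_per_cell`` is the expected number of
    occurrence points per occupied cell (Poisson, min 3 per species).
    """

    n_species: int = 150
    domain_extent: tuple[float, float, float, float] = (0.0, 0.0, 2000.0, 4000.0)
    cell_size: float = 50.0
    beta_rapoport: float = 0.6
    lambda_true: float = 0.0
    sigma_noise: float | None = None
    records_per_cell: float = 4.0
    log_cells_mean: float = 3.0
    log_cells_sd: float = 1.0
    adjacency: str = "queen"
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 3:
            raise ValueError("n_species must be at least 3")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")
        xmin, ymin, xmax, ymax = self.domain_extent
        if (xmax - xmin) < 4 * self.cell_size or (ymax - ymin) < 4 * self.cell_size:
            raise ValueError("domain must span at least 4 cells per side")
        if self.sigma_noise is not None and self.sigma_noise < 0:
            raise ValueError("sigma_noise must be non-negative")

    @property
    def resolved_sigma(self) -> float:
        if self.sigma_noise is not None:
            return self.sigma_noise
        return float(np.sqrt(max(0.0, 1.0 - self.beta_rapoport**2)))

    def make_grid(self) -> Grid:
        return Grid.from_extent(self.domain_extent, self.cell_size)


@dataclass
class SyntheticTruth:
    """Ground truth echoed back by the generator."""

    table: pd.DataFrame  # per species: true_midpoint_y, true_log_cells, true_cells
    config: SimulationConfig

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=True)


# ----------------------------------------------------------------------- tree
def simulate_tree(n_species: int, seed: int) -> Phylogeny:
    """Seeded Yule (pure-birth) tree with ``n_species`` tips, bifurcating,
    ultrametric, rescaled to unit root-to-tip depth.

    Tips are labelled ``sp001`` … in order of appearance.
    """
    if n_species < 3:
        raise ValueError("n_species must be at least 3")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.start_time = 0.0
    left = dendropy.Node()
    right = dendropy.Node()
    root.add_child(left)
    root.add_child(right)
    left.start_time = right.start_time = 0.0
    active = [left, right]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent.split_time = t
        kids = (dendropy.Node(), dendropy.Node())
        for kid in kids:
            kid.start_time = t
            parent.add_child(kid)
            active.append(kid)
    t += rng.exponential(1.0 / n_species)  # extend tips past the last split
    width = len(str(n_species))
    for leaf in active:
        leaf.split_time = t
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        node.edge.length = node.split_time - node.start_time
    for i, leaf in enumerate(active):
        leaf.taxon = taxa.new_taxon(label=f"sp{i + 1:0{width}d}")
    return Phylogeny(tree).rescale_depth(1.0)


def brownian_traits(
    tree: Phylogeny, n_traits: int, seed=None, order=None
) -> tuple[np.ndarray, list[str]]:
    """Draw ``n_traits`` independent Brownian-motion trait vectors on the
    tree (unit rate); returns (values with shape (n_traits, n_tips), tip
    order)."""
    C, labels = tree.brownian_covariance(order=order)
    n = len(labels)
    L = np.linalg.cholesky(C + 1e-12 * np.trace(C) / n * np.eye(n))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_traits, n))
    return z @ L.T, labels


# ------------------------------------------------------------------ env layers
def simulate_env_layers(grid: Grid, seed: int) -> EnvLayerSet:
    """Environmental layers with imposed, field-realistic structure.

    * ``elevation`` (m): smooth north–south ridges (cordilleras) plus
      gentle correlated noise, non-negative.
    * ``min_temp`` (°C): decreases with latitude (y) and falls with
      elevation at a 6.5 °C/km lapse rate.
    * ``temp_annual_range`` (°C): increases with latitude.
    * ``mat`` / ``mat_past`` (°C): present and last-glacial mean annual
      temperature surfaces for velocity derivation; the past surface is
      cooler, more so at high latitude.

    All layers are finite on every cell and bit-identical under a fixed
    seed.
    """
    rng = np.random.default_rng(seed)
    nr, nc = grid.n_rows, grid.n_cols
    xs = grid.x_centers()
    ys = grid.y_centers()
    X, Y = np.meshgrid(xs, ys)  # (nr, nc)
    xmin, ymin, xmax, ymax = grid.extent
    span_x = xmax - xmin
    span_y = ymax - ymin

    # ridges run north-south so row means stay flat in latitude
    n_ridges = max(2, int(round(span_x / 800.0)))
    ridge_x = xmin + (np.arange(n_ridges) + 0.5 + 0.2 * rng.standard_normal(n_ridges)) \
        * span_x / n_ridges
    ridge_w = span_x / (4.0 * n_ridges)
    elevation = np.zeros((nr, nc))
    for rx in ridge_x:
        height = 1500.0 + 800.0 * rng.random()
        elevation += height * np.exp(-0.5 * ((X - rx) / ridge_w) ** 2)
    smooth = _smooth_noise(nr, nc, rng, scale=120.0)
    elevation = np.maximum(elevation + smooth, 0.0)

    lat_frac = (Y - ymin) / span_y
    min_temp = (
        18.0
        - 32.0 * lat_frac
        - 6.5 * elevation / 1000.0
        + 0.3 * rng.standard_normal((nr, nc))
    )
    temp_annual_range = (
        10.0 + 22.0 * lat_frac + 0.3 * rng.standard_normal((nr, nc))
    )
    mat = 26.0 - 28.0 * lat_frac - 6.5 * elevation / 1000.0 \
        + 0.2 * rng.standard_normal((nr, nc))
    cooling = 3.0 + 4.0 * lat_frac + _smooth_noise(nr, nc, rng, scale=0.4)
    mat_past = mat - cooling
    return EnvLayerSet(
        grid,
        {
            "min_temp": min_temp,
            "temp_annual_range": temp_annual_range,
            "elevation": elevation,
            "mat": mat,
            "mat_past": mat_past,
        },
    )


def _smooth_noise(nr: int, nc: int, rng: np.random.Generator, scale: float) -> np.ndarray:
    """Low-frequency random field (sum of a few random cosine waves)."""
    out = np.zeros((nr, nc))
    r = np.arange(nr)[:, None] / max(nr, 1)
    c = np.arange(nc)[None, :] / max(nc, 1)
    for _ in range(6):
        fr, fc = rng.uniform(0.5, 3.0, size=2)
        ph = rng.uniform(0, 2 * np.pi, size=2)
        out += np.cos(2 * np.pi * fr * r + ph[0]) * np.cos(2 * np.pi * fc * c + ph[1])
    return out * scale / 6.0


# --------------------------------------------------------------------- ranges
def simulate_ranges(
    cfg: SimulationConfig, tree: Phylogeny, grid: Grid
) -> tuple[PresenceAbsenceMatrix, OccurrenceSet, SyntheticTruth]:
    """Generate cohesive gridded ranges and occurrence points (see module
    docstring for the model).  Deterministic given (cfg, tree)."""
    if tree.n_tips != cfg.n_species:
        raise ValueError("tree tip count does not match cfg.n_species")
    rng = np.random.default_rng(cfg.seed)
    C, labels = tree.brownian_covariance()
    n = len(labels)
    scale = np.trace(C) / n
    Lc = np.linalg.cholesky(C + 1e-12 * scale * np.eye(n))

    # 1. phylogenetically autocorrelated midpoints, rescaled into latitude span
    raw_mid = Lc @ rng.standard_normal(n)
    xmin, ymin, xmax, ymax = cfg.domain_extent
    span_y = ymax - ymin
    lo, hi = ymin + 0.05 * span_y, ymax - 0.05 * span_y
    rmin, rmax = raw_mid.min(), raw_mid.max()
    if rmax - rmin < 1e-12:
        mid = np.full(n, 0.5 * (lo + hi))
    else:
        mid = lo + (raw_mid - rmin) / (rmax - rmin) * (hi - lo)

    # 2. standardized log cell counts with lambda-structured residuals
    m_std = (mid - mid.mean()) / mid.std(ddof=1)
    sigma = cfg.resolved_sigma
    lam = cfg.lambda_true
    cov_eps = lam * C + (1.0 - lam) * np.eye(n)
    Le = np.linalg.cholesky(cov_eps + 1e-12 * np.eye(n))
    eps = sigma * (Le @ rng.standard_normal(n))
    u = cfg.beta_rapoport * m_std + eps
    log_cells = cfg.log_cells_mean + cfg.log_cells_sd * u
    counts = np.rint(np.exp(log_cells)).astype(int)
    n_cells = grid.n_cells
    clamped = (counts < 1) | (counts > n_cells)
    if clamped.any():
        logger.warning(
            "%d species' simulated cell counts clamped to [1, %d]",
            int(clamped.sum()), n_cells,
        )
    counts = np.clip(counts, 1, n_cells)

    # 3. cohesive placement by spreading dye, seeded near the true midpoint
    domain = np.arange(n_cells)
    neighbors = neighbor_table(grid, domain, cfg.adjacency)
    matrix = np.zeros((n_cells, n), dtype=bool)
    ys_centers = grid.y_centers()
    for i, sp in enumerate(labels):
        x_seed = rng.uniform(xmin, xmax)
        row = int(np.clip(np.searchsorted(ys_centers, mid[i]), 0, grid.n_rows - 1))
        # nearest row centre to the true midpoint latitude
        if row > 0 and abs(ys_centers[row - 1] - mid[i]) < abs(ys_centers[row] - mid[i]):
            row -= 1
        col = int(np.clip((x_seed - xmin) // cfg.cell_size, 0, grid.n_cols - 1))
        seed_cell = row * grid.n_cols + col
        patch_rng = np.random.default_rng(rng.integers(2**31 - 1))
        cells = _grow_from_seed(
            int(counts[i]), seed_cell, domain, neighbors, patch_rng, sp
        )
        matrix[cells, i] = True
    pam = PresenceAbsenceMatrix(grid, labels, matrix)

    # 4. occurrence points: Poisson(records_per_cell) per occupied cell, min 3
    rows = []
    for i, sp in enumerate(labels):
        occ_cells = np.flatnonzero(matrix[:, i])
        k = rng.poisson(cfg.records_per_cell, size=occ_cells.size)
        total = int(k.sum())
        if total < 3:
            extra_cells = rng.choice(occ_cells, size=3 - total)
            k_extra = np.bincount(
                np.searchsorted(occ_cells, extra_cells), minlength=occ_cells.size
            )
            k = k + k_extra
        for cell, kk in zip(occ_cells, k):
            if kk == 0:
                continue
            r, c = divmod(int(cell), grid.n_cols)
            x0 = xmin + c * cfg.cell_size
            y0 = ymin + r * cfg.cell_size
            px = rng.uniform(x0, x0 + cfg.cell_size, size=kk)
            py = rng.uniform(y0, y0 + cfg.cell_size, size=kk)
            for xx, yy in zip(px, py):
                rows.append((sp, xx, yy))
    occ = OccurrenceSet(
        pd.DataFrame(rows, columns=["species", "x", "y"]), crs="projected-km"
    )
    truth = SyntheticTruth(
        table=pd.DataFrame(
            {
                "true_midpoint_y": mid,
                "true_std_log_cells": u,
                "true_log_cells": log_cells,
                "true_cells": counts,
            },
            index=pd.Index(labels, name="species"),
        ),
        config=cfg,
    )
    assert (truth.table["true_cells"].to_numpy() == matrix.sum(axis=0)).all()
    return pam, occ, truth


def _grow_from_seed(target, seed_cell, domain, neighbors, rng, label):
    """Spreading-dye growth from a fixed seed cell (midpoint placement)."""
    if target > domain.size:
        raise GenerationFailureError(
            f"range of {target} cells exceeds the domain (species {label!r})"
        )
    patch = {int(seed_cell)}
    frontier = [int(j) for j in neighbors[int(seed_cell)]]
    frontier_set = set(frontier)
    while len(patch) < target:
        if not frontier:
            # full-lattice domain: can only happen if target > reachable cells
            return grow_patch(target, domain, neighbors, rng, label=label)
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
    return np.fromiter(patch, dtype=int, count=target)


# ---------------------------------------------------------------- full world
def simulate_world(cfg: SimulationConfig):
    """Tree + grid + env layers + PAM + occurrences + truth in one call."""
    tree = simulate_tree(cfg.n_species, cfg.seed)
    grid = cfg.make_grid()
    env = simulate_env_layers(grid, cfg.seed + 1)
    pam, occ, truth = simulate_ranges(cfg, tree, grid)
    return tree, grid, env, pam, occ, truth


def write_world(cfg: SimulationConfig, out_dir) -> list[Path]:
    """Write occurrences CSV, truth CSV, tree Newick, and env ASCII grids."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree, grid, env, pam, occ, truth = simulate_world(cfg)
    paths = []
    p = out / "occurrences.csv"
    occ.write_csv(p)
    paths.append(p)
    p = out / "truth.csv"
    truth.write_csv(p)
    paths.append(p)
    p = out / "tree.nwk"
    tree.write_newick(p)
    paths.append(p)
    for name in env.names():
        p = out / f"env_{name}.asc"
        write_ascii_grid(p, env[name], grid)
        paths.append(p)
    return paths
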
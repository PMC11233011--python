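"""Occurrence cleaning and range-polygon construction.

Ranges are extents of occurrence built from cleaned point records in
projected kilometres: either a convex hull or a dynamic alpha hull whose
alpha (a circumradius bound, km) grows geometrically until the shape
contains every point and is a single connected polygon.  Both methods can
be Minkowski-buffered (default 50 km, the maximum observed population
separation in the study genus) before area measurement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay
from scipy.stats import spearmanr
from shapely.geometry import MultiPoint, Polygon, mapping
from shapely.ops import unary_union

from .errors import AlphaSearchError, InsufficientDataError, InsufficientRecordsError

logger = logging.getLogger(__name__)

MIN_RECORDS_FOR_OUTLIER_TEST = 7  # quantiles on fewer points are meaningless
BUFFER_QUAD_SEGS = 1024  # fine arcs so buffered areas match the Minkowski formula


# -------------------------------------------------------------- OccurrenceSet
@dataclass
class OccurrenceSet:
    """Species-tagged point records in a declared coordinate system.

    ``crs`` is ``"projected-km"`` or ``"lonlat-degrees"``.  The table has
    columns ``species``, ``x``, ``y`` (x=longitude, y=latitude for the
    lonlat tag).
    """

    table: pd.DataFrame
    crs: str = "projected-km"

    def __post_init__(self):
        need = {"species", "x", "y"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"occurrence table needs columns {sorted(need)}")
        if self.crs not in {"projected-km", "lonlat-degrees"}:
            raise ValueError(f"unknown crs tag {self.crs!r}")
        self.table = self.table.reset_index(drop=True)
        for col in ("x", "y"):  # empty/object frames coerce cleanly
            self.table[col] = pd.to_numeric(self.table[col], errors="raise")
        finite = np.isfinite(self.table["x"]) & np.isfinite(self.table["y"])
        if self.crs == "lonlat-degrees" and finite.any():
            sub = self.table[finite]
            if (sub["x"].abs() > 180).any() or (sub["y"].abs() > 90).any():
                raise ValueError("lonlat records must satisfy |lon|<=180, |lat|<=90")
        if (self.table["species"].astype(str).str.len() == 0).any():
            raise ValueError("species labels must be non-empty")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.table["species"]))

    def for_species(self, species: str) -> np.ndarray:
        sub = self.table[self.table["species"] == species]
        return sub[["x", "y"]].to_numpy(dtype=float)

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ------------------------------------------------------------------- cleaning
def dedupe_records(occ: OccurrenceSet) -> OccurrenceSet:
    """Drop records with missing coordinates and per-species exact
    (x, y) duplicates, keeping each first occurrence in input order."""
    t = occ.table
    finite = np.isfinite(t["x"].to_numpy(float)) & np.isfinite(t["y"].to_numpy(float))
    t = t[finite]
    t = t.drop_duplicates(subset=["species", "x", "y"], keep="first")
    return OccurrenceSet(t.reset_index(drop=True), occ.crs)


def thin_to_grid(occ: OccurrenceSet, resolution: float) -> OccurrenceSet:
    """Keep at most one record per species per thinning cell (the first
    encountered in input order); cells are half-open [k·res, (k+1)·res)."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    t = occ.table
    cx = np.floor(t["x"].to_numpy(float) / resolution).astype(np.int64)
    cy = np.floor(t["y"].to_numpy(float) / resolution).astype(np.int64)
    key = pd.DataFrame({"species": t["species"].to_numpy(), "cx": cx, "cy": cy})
    keep = ~key.duplicated(keep="first")
    return OccurrenceSet(t[keep.to_numpy()].reset_index(drop=True), occ.crs)


def remove_spatial_outliers(
    occ: OccurrenceSet, multiplier: float = 2.0
) -> OccurrenceSet:
    """Drop geographically atypical records per species.

    For every record, compute its mean distance to all conspecific
    records; flag records whose mean distance exceeds
    Q75 + ``multiplier``·IQR of those per-record mean distances.  Species
    with fewer than :data:`MIN_RECORDS_FOR_OUTLIER_TEST` records pass
    through untouched.
    """
    t = occ.table
    keep = np.ones(len(t), dtype=bool)
    for sp, idx in t.groupby("species", sort=False).groups.items():
        idx = np.asarray(idx)
        if len(idx) < MIN_RECORDS_FOR_OUTLIER_TEST:
            continue
        pts = t.loc[idx, ["x", "y"]].to_numpy(dtype=float)
        d = np.sqrt(
            ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        )
        mean_d = d.sum(axis=1) / (len(idx) - 1)
        q25, q75 = np.percentile(mean_d, [25, 75])
        thresh = q75 + multiplier * (q75 - q25)
        flagged = mean_d > thresh
        if flagged.any():
            logger.info("species %s: %d spatial outliers removed", sp, flagged.sum())
        keep[idx[flagged]] = False
    return OccurrenceSet(t[keep].reset_index(drop=True), occ.crs)


def clean_occurrences(
    occ: OccurrenceSet,
    thinning_resolution: float | None = None,
    outlier_multiplier: float = 2.0,
) -> OccurrenceSet:
    """Full cleaning chain: dedupe → grid thinning → spatial outliers."""
    out = dedupe_records(occ)
    if thinning_resolution is not None:
        out = thin_to_grid(out, thinning_resolution)
    return remove_spatial_outliers(out, outlier_multiplier)


# -------------------------------------------------------------- RangePolygon
@dataclass
class RangePolygon:
    """A species range polygon with its construction metadata."""

    species: str
    geometry: Polygon
    method: str  # "convex_hull" | "alpha_hull" | other tags
    buffer_km: float
    area_km2: float
    alpha_final: float | None = None

    def __post_init__(self):
        if not self.geometry.is_valid:
            raise ValueError(f"invalid geometry for species {self.species!r}")
        if self.area_km2 <= 0:
            raise ValueError("range area must be positive")


def _distinct_points(occ: OccurrenceSet, species: str) -> np.ndarray:
    pts = np.unique(occ.for_species(species), axis=0)
    if occ.crs != "projected-km":
        raise ValueError("range construction requires projected-km coordinates")
    return pts


def _require_area(pts: np.ndarray, species: str) -> Polygon:
    if len(pts) < 3:
        raise InsufficientRecordsError(
            f"species {species!r}: {len(pts)} distinct records (need >= 3)"
        )
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0:
        raise InsufficientRecordsError(
            f"species {species!r}: records are collinear; hull is degenerate"
        )
    return hull


def build_convex_hull_range(
    occ: OccurrenceSet, species: str, buffer_km: float = 50.0
) -> RangePolygon:
    """Convex hull of the species' records, Minkowski-buffered."""
    pts = _distinct_points(occ, species)
    hull = _require_area(pts, species)
    geom = hull.buffer(buffer_km, quad_segs=BUFFER_QUAD_SEGS) if buffer_km > 0 else hull
    return RangePolygon(species, geom, "convex_hull", buffer_km, geom.area)


def _triangle_circumradii(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = pts[simplices[:, 0]]
    b = pts[simplices[:, 1]]
    c = pts[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (
        b[:, 1] - a[:, 1]
    ) * (c[:, 0] - a[:, 0])
    area2 = np.abs(cross)  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[area2 == 0] = np.inf
    return r


def alpha_shape(pts: np.ndarray, alpha: float):
    """Union of Delaunay triangles with circumradius <= alpha (may be
    empty, a Polygon, or a MultiPolygon)."""
    tri = Delaunay(pts)
    radii = _triangle_circumradii(pts, tri.simplices)
    keep = tri.simplices[radii <= alpha]
    if len(keep) == 0:
        return Polygon()
    triangles = [Polygon(pts[s]) for s in keep]
    return unary_union(triangles)


def build_alpha_hull_range(
    occ: OccurrenceSet,
    species: str,
    buffer_km: float = 50.0,
    alpha0: float = 10.0,
    growth: float = 1.5,
    max_iter: int = 60,
) -> RangePolygon:
    """Dynamic alpha hull: grow alpha geometrically from ``alpha0`` until
    the shape contains 100% of the species' points (boundary-inclusive)
    and is a single connected polygon; then buffer.

    Raises :class:`AlphaSearchError` if the search does not converge —
    there is no silent fallback.
    """
    if alpha0 <= 0 or growth <= 1:
        raise ValueError("need alpha0 > 0 and growth > 1")
    pts = _distinct_points(occ, species)
    _require_area(pts, species)  # validates record count / collinearity
    tri = Delaunay(pts)
    radii = _triangle_circumradii(pts, tri.simplices)
    alpha = float(alpha0)
    for _ in range(max_iter):
        keep_mask = radii <= alpha
        # Every input point is a Delaunay vertex, so the shape contains all
        # points (boundary-inclusive) iff each vertex sits in a kept
        # triangle; the union is one connected polygon iff the kept
        # triangles form a single component under shared-edge adjacency.
        if keep_mask.any() and _covers_all_vertices(
            tri.simplices[keep_mask], len(pts)
        ) and _edge_connected(tri, keep_mask):
            shape = unary_union(
                [Polygon(pts[s]) for s in tri.simplices[keep_mask]]
            )
            if shape.geom_type == "Polygon" and not shape.is_empty:
                geom = (
                    shape.buffer(buffer_km, quad_segs=BUFFER_QUAD_SEGS)
                    if buffer_km > 0
                    else shape
                )
                return RangePolygon(
                    species, geom, "alpha_hull", buffer_km, geom.area, alpha
                )
        alpha *= growth
    raise AlphaSearchError(
        f"species {species!r}: alpha search failed after {max_iter} iterations"
    )


def _covers_all_vertices(kept_simplices: np.ndarray, n_points: int) -> bool:
    used = np.zeros(n_points, dtype=bool)
    used[kept_simplices.ravel()] = True
    return bool(used.all())


def _edge_connected(tri: Delaunay, keep_mask: np.ndarray) -> bool:
    """True iff the kept triangles form one component where adjacency is
    sharing a full edge (point-contact pinches count as disconnected,
    matching the single-polygon requirement)."""
    idx = np.flatnonzero(keep_mask)
    if idx.size == 0:
        return False
    pos = -np.ones(len(keep_mask), dtype=int)
    pos[idx] = np.arange(idx.size)
    parent = np.arange(idx.size)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for k, t in enumerate(idx):
        for nb in tri.neighbors[t]:
            if nb >= 0 and keep_mask[nb]:
                ra, rb = find(k), find(pos[nb])
                if ra != rb:
                    parent[rb] = ra
    root = find(0)
    return all(find(k) == root for k in range(idx.size))


def build_ranges(
    occ: OccurrenceSet,
    method: str = "alpha_hull",
    buffer_km: float = 50.0,
    alpha0: float = 10.0,
    growth: float = 1.5,
) -> tuple[list[RangePolygon], list[str]]:
    """Build a range for every species with enough records.

    Returns (ranges, skipped_species); species with fewer than three
    distinct non-collinear records are skipped and logged, matching the
    minimum-record rule for hull construction.
    """
    ranges: list[RangePolygon] = []
    skipped: list[str] = []
    for sp in occ.species:
        try:
            if method == "convex_hull":
                rp = build_convex_hull_range(occ, sp, buffer_km)
            elif method == "alpha_hull":
                rp = build_alpha_hull_range(occ, sp, buffer_km, alpha0, growth)
            else:
                raise ValueError(f"unknown range method {method!r}")
            ranges.append(rp)
        except InsufficientRecordsError as exc:
            logger.warning("skipping species: %s", exc)
            skipped.append(sp)
    return ranges, skipped


# ----------------------------------------------------------------- comparison
def compare_range_methods(sizes_by_method: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlation (mid-rank ties) between range-size
    columns; each pair needs at least three species with both values."""
    methods = list(sizes_by_method.columns)
    out = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for i, a in enumerate(methods):
        for j in range(i + 1, len(methods)):
            b = methods[j]
            sub = sizes_by_method[[a, b]].dropna()
            if len(sub) < 3:
                raise InsufficientDataError(
                    f"fewer than 3 shared species for methods {a!r} and {b!r}"
                )
            rho = spearmanr(sub[a], sub[b]).statistic
            out.loc[a, b] = out.loc[b, a] = rho
    return out


# ------------------------------------------------------------------------- IO
def write_ranges_geojson(
    ranges: Iterable[RangePolygon], path, crs_note: str = "projected-km"
) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {
                "species": rp.species,
                "method": rp.method,
                "buffer_km": rp.buffer_km,
                "alpha_final": rp.alpha_final,
                "area_km2": rp.area_km2,
            },
            "geometry": mapping(rp.geometry),
        }
        for rp in ranges
    ]
    doc = {
        "type": "FeatureCollection",
        "crs_note": crs_note,
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def ranges_summary_table(ranges: Iterable[RangePolygon]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": rp.species,
                "method": rp.method,
                "buffer_km": rp.buffer_km,
                "alpha_final": rp.alpha_final,
                "area_km2": rp.area_km2,
            }
            for rp in ranges
        ]
    )
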
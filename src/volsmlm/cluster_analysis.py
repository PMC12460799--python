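"""Voronoi-density clustering of 3D localization clouds and sphere mapping.

A 3D Voronoi tessellation of the localization cloud gives a local density
per point (first-rank neighborhood: a point, its Voronoi neighbors and
their summed cell volumes).  Clusters are single-linkage components of the
above-average-density points with a 50 nm cutting distance and at least 10
localizations.  Per-cluster descriptors (FWHM, volume, counts) can be
regressed against z, and — for roughly spherical samples such as suspended
T cells — cluster centroids can be projected onto a best-fit sphere where
a spherical Voronoi diagram maps local cluster density on the membrane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.spatial import ConvexHull, SphericalVoronoi, Voronoi, cKDTree

from .resolution_metrics import GAUSSIAN_FWHM_FACTOR

__all__ = [
    "DensityAnnotatedCloud",
    "ClusterStats",
    "SphereFit",
    "compute_local_density",
    "detect_clusters",
    "fit_sphere",
    "project_to_sphere_map",
    "props_vs_z_regression",
]


@dataclass
class DensityAnnotatedCloud:
    """Localization cloud with per-point Voronoi volume and local density."""

    points_nm: np.ndarray  # (n, 3)
    cell_volume_nm3: np.ndarray  # np.inf for unbounded hull cells
    density_per_nm3: np.ndarray


@dataclass
class ClusterStats:
    """Quantitative descriptors of one localization cluster."""

    cluster_id: int
    n_loc: int
    centroid_nm: tuple[float, float, float]
    d_r_nm: float  # lateral FWHM (mean of the two lateral principal axes)
    d_z_nm: float  # axial FWHM (along z)
    volume_nm3: float
    mean_density_per_nm3: float
    member_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


@dataclass
class SphereFit:
    center_nm: tuple[float, float, float]
    radius_nm: float
    rms_residual_nm: float


def _voronoi_cell_volumes(vor: Voronoi) -> np.ndarray:
    """Bounded Voronoi cell volumes; hull cells are np.inf.

    Cells that are formally bounded but stretch far beyond the data (their
    vertices leave the bounding box by more than a 5% margin) are treated
    as hull cells too: their volume reflects the empty surroundings, not
    the local point density.
    """
    lo = vor.points.min(axis=0)
    hi = vor.points.max(axis=0)
    margin = 0.05 * (hi - lo).max()
    volumes = np.full(len(vor.points), np.inf)
    for i, region_idx in enumerate(vor.point_region):
        region = vor.regions[region_idx]
        if not region or -1 in region:
            continue  # unbounded hull cell
        verts = vor.vertices[region]
        if np.any(verts < lo - margin) or np.any(verts > hi + margin):
            continue
        try:
            volumes[i] = ConvexHull(verts).volume
        except Exception:
            volumes[i] = np.inf
    return volumes


def compute_local_density(locs: pd.DataFrame | np.ndarray) -> DensityAnnotatedCloud:
    """Per-localization density from a 3D Voronoi tessellation.

    For point i with bounded first-rank neighborhood N1(i) (its Voronoi
    neighbors), density_i = (1 + |N1(i)|) / (V_i + Σ_{j∈N1(i)} V_j); only
    bounded neighbor cells enter the sums.  Points whose own cell is
    unbounded (on the cloud hull) get the average density of their bounded
    neighbors, propagated iteratively.
    """
    if isinstance(locs, pd.DataFrame):
        pts = locs[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(locs, dtype=float)
    if len(pts) < 5:
        raise ValueError("need at least 5 points for a 3D tessellation")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 3:
        raise ValueError("degenerate (coplanar) input")
    vor = Voronoi(pts)
    volumes = _voronoi_cell_volumes(vor)

    n = len(pts)
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for a, b in vor.ridge_points:
        neighbors[a].append(b)
        neighbors[b].append(a)

    density = np.full(n, np.nan)
    bounded = np.isfinite(volumes)
    for i in range(n):
        if not bounded[i]:
            continue
        nb = [j for j in neighbors[i] if bounded[j]]
        density[i] = (1 + len(nb)) / (volumes[i] + volumes[nb].sum())

    # hull cells: neighbor-average density, iterated until all assigned
    missing = np.where(~np.isfinite(density))[0]
    for _ in range(n):
        if len(missing) == 0:
            break
        still = []
        for i in missing:
            vals = [density[j] for j in neighbors[i] if np.isfinite(density[j])]
            if vals:
                density[i] = float(np.mean(vals))
            else:
                still.append(i)
        if len(still) == len(missing):
            density[still] = np.nanmean(density)
            break
        missing = np.asarray(still, dtype=int)

    return DensityAnnotatedCloud(
        points_nm=pts, cell_volume_nm3=volumes, density_per_nm3=density
    )


def detect_clusters(
    cloud: DensityAnnotatedCloud,
    min_loc: int = 10,
    cut_nm: float = 50.0,
) -> list[ClusterStats]:
    """Density-threshold + single-linkage cluster segmentation.

    Points denser than the cloud-average density are linked when closer
    than ``cut_nm``; connected components with at least ``min_loc`` points
    become clusters.  The cloud-average density is the dataset count
    divided by the dataset volume (sum of the bounded Voronoi cell
    volumes), the normalization customary in tessellation-based cluster
    analysis.  Per cluster: centroid, lateral/axial FWHM (2.35σ of
    principal-axis projections; d_r averages the two lateral axes, d_z is
    along z), ellipsoid volume V = (4/3)π (d_r/2)² (d_z/2), mean density.
    """
    bounded_volumes = cloud.cell_volume_nm3[np.isfinite(cloud.cell_volume_nm3)]
    if len(bounded_volumes) and bounded_volumes.sum() > 0:
        mean_density = len(cloud.points_nm) / float(bounded_volumes.sum())
    else:
        mean_density = float(np.mean(cloud.density_per_nm3))
    keep = np.where(cloud.density_per_nm3 > mean_density)[0]
    stats: list[ClusterStats] = []
    if len(keep) == 0:
        return stats
    pts = cloud.points_nm[keep]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(cut_nm, output_type="ndarray")
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(len(pts), len(pts))
    )
    n_comp, labels = sparse.csgraph.connected_components(graph, directed=False)
    cid = 0
    for comp in range(n_comp):
        members = np.where(labels == comp)[0]
        if len(members) < min_loc:
            continue
        p = pts[members]
        centroid = p.mean(axis=0)
        centered = p - centroid
        # lateral principal axes within the xy plane; axial along z
        cov_xy = np.cov(centered[:, :2].T)
        evals_xy = np.linalg.eigvalsh(cov_xy)
        fwhm_lat = GAUSSIAN_FWHM_FACTOR * np.sqrt(np.maximum(evals_xy, 0.0))
        d_r = float(fwhm_lat.mean())
        d_z = float(GAUSSIAN_FWHM_FACTOR * centered[:, 2].std())
        volume = (4.0 / 3.0) * np.pi * (d_r / 2.0) ** 2 * (d_z / 2.0)
        stats.append(
            ClusterStats(
                cluster_id=cid,
                n_loc=int(len(members)),
                centroid_nm=tuple(centroid),
                d_r_nm=d_r,
                d_z_nm=d_z,
                volume_nm3=float(volume),
                mean_density_per_nm3=float(
                    cloud.density_per_nm3[keep[members]].mean()
                ),
                member_index=keep[members],
            )
        )
        cid += 1
    return stats


def clusters_to_frame(clusters: list[ClusterStats]) -> pd.DataFrame:
    """Tabular view of per-cluster descriptors."""
    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "n_loc": [c.n_loc for c in clusters],
            "x_nm": [c.centroid_nm[0] for c in clusters],
            "y_nm": [c.centroid_nm[1] for c in clusters],
            "z_nm": [c.centroid_nm[2] for c in clusters],
            "d_r_nm": [c.d_r_nm for c in clusters],
            "d_z_nm": [c.d_z_nm for c in clusters],
            "volume_nm3": [c.volume_nm3 for c in clusters],
            "density_per_nm3": [c.mean_density_per_nm3 for c in clusters],
        }
    )


def fit_sphere(centroids: np.ndarray) -> SphereFit:
    """Least-squares sphere through a set of 3D points.

    Algebraic (Coope) linear fit followed by geometric refinement of the
    radial residuals.  Degenerate (coplanar or coincident) inputs raise.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("need at least 4 points (n, 3)")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 3:
        raise ValueError("degenerate centroid configuration for a sphere fit")
    # algebraic: |p|^2 = 2 c.p + (r^2 - |c|^2)
    a = np.hstack([2 * pts, np.ones((len(pts), 1))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + center0 @ center0, 1e-12)))

    def resid(p):
        return np.linalg.norm(pts - p[:3], axis=1) - p[3]

    fit = optimize.least_squares(resid, np.r_[center0, r0])
    center = fit.x[:3]
    radius = float(fit.x[3])
    rms = float(np.sqrt(np.mean(resid(fit.x) ** 2)))
    if radius <= 0:
        raise ValueError("sphere fit collapsed to non-positive radius")
    return SphereFit(center_nm=tuple(center), radius_nm=radius, rms_residual_nm=rms)


def project_to_sphere_map(
    clusters: list[ClusterStats] | np.ndarray,
    fit: SphereFit,
    *,
    jitter_nm: float = 1e-6,
    seed: int = 0,
) -> dict:
    """Project cluster centroids on the fitted sphere; spherical Voronoi map.

    Each centroid is mapped radially onto the sphere surface; the spherical
    Voronoi diagram of the projections gives one cell per cluster whose
    inverse area is the local surface cluster density (µm⁻²).  Returns a
    dict with projected points, per-cell areas and densities, and the cell
    polygons (vertices on the sphere) for export; any cluster property can
    be attached as the cell value.
    """
    if isinstance(clusters, np.ndarray):
        cents = np.asarray(clusters, dtype=float)
    else:
        cents = np.array([c.centroid_nm for c in clusters], dtype=float)
    if len(cents) < 4:
        raise ValueError("need at least 4 clusters for a spherical map")
    center = np.asarray(fit.center_nm)
    vec = cents - center
    norms = np.linalg.norm(vec, axis=1)
    if np.any(norms == 0):
        raise ValueError("centroid at the sphere center cannot be projected")
    unit = vec / norms[:, None]
    # coincident projections break the tessellation: jitter with a warning
    rng = np.random.default_rng(seed)
    tree = cKDTree(unit)
    pairs = tree.query_pairs(1e-9)
    if pairs:
        import logging

        logging.getLogger(__name__).warning(
            "%d coincident surface projections jittered", len(pairs)
        )
        for _, j in pairs:
            bump = rng.normal(0, jitter_nm / fit.radius_nm, 3)
            u = unit[j] + bump
            unit[j] = u / np.linalg.norm(u)
    surface = center + fit.radius_nm * unit
    sv = SphericalVoronoi(unit, radius=1.0, threshold=1e-9)
    sv.sort_vertices_of_regions()
    areas_unit = sv.calculate_areas()
    areas_nm2 = areas_unit * fit.radius_nm**2
    density_per_um2 = 1.0 / (areas_nm2 * 1e-6)
    polygons = [
        center + fit.radius_nm * sv.vertices[region] for region in sv.regions
    ]
    return {
        "surface_points_nm": surface,
        "cell_area_nm2": areas_nm2,
        "density_per_um2": density_per_um2,
        "polygons_nm": polygons,
    }


def props_vs_z_regression(
    clusters: list[ClusterStats] | pd.DataFrame,
    properties: tuple[str, ...] = ("d_r_nm", "d_z_nm", "n_loc", "volume_nm3"),
) -> pd.DataFrame:
    """OLS regression of each cluster property against centroid z.

    Returns a table with slope, intercept and R² per property; a small R²
    (the field uses R² ≤ 0.03) indicates homogeneity of the property over
    the axial extent of the sample.
    """
    df = clusters if isinstance(clusters, pd.DataFrame) else clusters_to_frame(clusters)
    if len(df) < 10:
        raise ValueError("need at least 10 clusters for the regression")
    z = df["z_nm"].to_numpy(dtype=float)
    if np.allclose(z, z[0]):
        raise ValueError("zero variance in z")
    rows = []
    for prop in properties:
        y = df[prop].to_numpy(dtype=float)
        slope, intercept = np.polyfit(z, y, 1)
        pred = slope * z + intercept
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum((y - pred) ** 2) / ss_tot if ss_tot > 0 else 0.0
        rows.append((prop, float(slope), float(intercept), float(r2)))
    return pd.DataFrame(rows, columns=["property", "slope", "intercept", "r2"])
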
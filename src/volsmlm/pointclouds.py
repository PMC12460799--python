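"""Synthetic localization clouds with known ground truth.

These generators emulate reconstructed localization tables directly (the
output of the full pipeline) for testing the downstream analysis modules:
a spherical membrane receptor map (clusters on a cell-sized sphere with
nonspecific background) and a filament field (line-like structures sampled
with localization noise) for resolution estimation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["receptor_map", "filament_field", "bead_clusters"]


def receptor_map(
    n_clusters: int = 500,
    locs_per_cluster: int = 40,
    sigma_lateral_nm: float = 20.0,
    sigma_axial_nm: float = 50.0,
    radius_nm: float = 5000.0,
    background_per_cluster_loc: float = 2.0,
    shell_halfwidth_nm: float = 300.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Clustered receptors on a spherical cell membrane.

    Cluster centers are uniform on a sphere of ``radius_nm`` (a suspended
    T cell is roughly a 10 µm sphere); each cluster is sampled from an
    anisotropic Gaussian whose axial spread (global z) exceeds the lateral
    one, as astigmatic localization precision does.  Nonspecific background
    localizations are uniform in a shell of ±``shell_halfwidth_nm`` around
    the membrane, ``background_per_cluster_loc`` per clustered
    localization.  Returns (localization table, truth dict).
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n_clusters, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    centers = radius_nm * u
    pts = [
        c
        + np.column_stack(
            [
                rng.normal(0, sigma_lateral_nm, locs_per_cluster),
                rng.normal(0, sigma_lateral_nm, locs_per_cluster),
                rng.normal(0, sigma_axial_nm, locs_per_cluster),
            ]
        )
        for c in centers
    ]
    n_bg = int(round(background_per_cluster_loc * n_clusters * locs_per_cluster))
    ub = rng.normal(size=(n_bg, 3))
    ub /= np.linalg.norm(ub, axis=1)[:, None]
    r = radius_nm + rng.uniform(-shell_halfwidth_nm, shell_halfwidth_nm, n_bg)
    allpts = np.vstack(pts + [ub * r[:, None]])
    df = pd.DataFrame(allpts, columns=["x_nm", "y_nm", "z_nm"])
    df.insert(0, "loc_id", np.arange(len(df)))
    truth = {
        "centers_nm": centers,
        "radius_nm": radius_nm,
        "sigma_lateral_nm": sigma_lateral_nm,
        "sigma_axial_nm": sigma_axial_nm,
        "n_clusters": n_clusters,
    }
    return df, truth


def filament_field(
    n_filaments: int = 12,
    locs_per_filament: int = 2500,
    field_nm: float = 5000.0,
    loc_noise_nm: float = 10.0,
    n_planes: int = 1,
    plane_spacing_nm: float = 200.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Random straight filaments sampled with Gaussian localization noise.

    A dense line-like structure (cytoskeleton-style) whose rendered images
    contain high spatial frequencies, suitable for FRC estimation.  The
    same filaments repeat in every plane (offset axially) so each rendered
    plane is populated.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_filaments):
        p0 = rng.uniform(0, field_nm, 2)
        ang = rng.uniform(0, np.pi)
        direction = np.array([np.cos(ang), np.sin(ang)])
        for plane in range(n_planes):
            t = rng.uniform(-field_nm, field_nm, locs_per_filament)
            xy = p0 + t[:, None] * direction
            ok = np.all((xy >= 0) & (xy <= field_nm), axis=1)
            xy = xy[ok] + rng.normal(0, loc_noise_nm, (ok.sum(), 2))
            z = plane * plane_spacing_nm + rng.normal(0, loc_noise_nm, ok.sum())
            rows.append(
                pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1], "z_nm": z})
            )
    df = pd.concat(rows, ignore_index=True)
    df = df.sample(frac=1.0, random_state=seed).reset_index(drop=True)
    df.insert(0, "loc_id", np.arange(len(df)))
    return df


def bead_clusters(
    n_beads: int = 50,
    locs_per_bead: int = 200,
    sigma_nm: tuple[float, float, float] = (6.0, 6.0, 17.0),
    field_nm: float = 20000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated localizations of isolated fiducial beads.

    Each bead yields a Gaussian localization cluster whose spread is the
    localization precision (anisotropic: axial worse than lateral), the
    basis of the bead-FWHM resolution estimate.
    """
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0, field_nm, (n_beads, 3))
    rows = []
    for b, c in enumerate(centers):
        p = c + rng.normal(0, 1, (locs_per_bead, 3)) * np.asarray(sigma_nm)
        d = pd.DataFrame(p, columns=["x_nm", "y_nm", "z_nm"])
        d["bead_id"] = b
        rows.append(d)
    df = pd.concat(rows, ignore_index=True)
    df.insert(0, "loc_id", np.arange(len(df)))
    return df
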
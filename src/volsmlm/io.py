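"""File formats and configuration.

Localization tables are exchanged as ThunderSTORM-compatible CSV (columns
``id, frame, x [nm], y [nm], z [nm], sigma1 [nm], sigma2 [nm],
intensity [photon], chi2, plane``); image stacks as multi-page TIFF;
configuration as YAML with strict (unknown keys rejected) parsing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_localizations",
    "write_localizations",
    "PipelineConfig",
    "load_config",
    "save_config",
]

#: internal column -> CSV header
_CSV_COLUMNS = {
    "loc_id": "id",
    "frame": "frame",
    "x_nm": "x [nm]",
    "y_nm": "y [nm]",
    "z_nm": "z [nm]",
    "sigma_x_nm": "sigma1 [nm]",
    "sigma_y_nm": "sigma2 [nm]",
    "intensity_adu": "intensity [photon]",
    "chi2": "chi2",
    "plane_index": "plane",
}
_MANDATORY = ["id", "x [nm]", "y [nm]"]
_NUMERIC_IF_PRESENT = ["frame"]


def write_localizations(locs: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table as ThunderSTORM-compatible CSV.

    Internal columns are renamed to the CSV dialect; any extra columns are
    preserved untouched.  ``z_nm`` is derived from ``z_um`` when absent.
    """
    out = locs.copy()
    if "z_nm" not in out.columns and "z_um" in out.columns:
        out["z_nm"] = out["z_um"] * 1000.0
    out = out.drop(columns=[c for c in ("z_um",) if c in out.columns])
    out = out.rename(columns=_CSV_COLUMNS)
    out.to_csv(path, index=False)


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a ThunderSTORM-compatible localization CSV.

    Mandatory columns (id, frame, x [nm], y [nm]) must be present; rows
    with non-numeric values in them are rejected with their line number.
    Extra/unknown columns are preserved untouched.
    """
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {', '.join(missing)}")
    for col in _MANDATORY + [c for c in _NUMERIC_IF_PRESENT if c in df.columns]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.where(coerced.isna() & df[col].notna())[0]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ValueError(f"malformed row at line {bad[0] + 2} in column {col!r}")
        df[col] = coerced
    inverse = {v: k for k, v in _CSV_COLUMNS.items()}
    df = df.rename(columns=inverse)
    if "z_nm" in df.columns and "z_um" not in df.columns:
        df["z_um"] = df["z_nm"] / 1000.0
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _from_dict(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class OpticsSection:
    numerical_aperture: float = 1.2
    wavelength_nm: float = 580.0
    pixel_size_camera_nm: float = 108.0
    pupil_grid_size: int = 256
    depth_spherical_slope_rad_per_um: float = 0.031
    astigmatism_nm: float = 60.0


@dataclass
class CameraSection:
    baseline_adu: float = 100.0
    electrons_per_adu: float = 0.46
    quantum_efficiency: float = 0.82
    read_noise_e: float = 1.4


@dataclass
class KineticsSection:
    on_rate_per_frame: float = 2e-3
    mean_on_frames: float = 3.0


@dataclass
class AoSection:
    alpha_nm: float = 60.0
    iterations: int = 3
    modes: list[str] = field(
        default_factory=lambda: [
            "astig_vertical",
            "astig_oblique",
            "coma_vertical",
            "coma_horizontal",
            "spherical",
            "trefoil_vertical",
            "trefoil_horizontal",
        ]
    )


@dataclass
class PlanSection:
    first_plane_z_um: float = 0.0
    n_planes: int = 2
    dz_nm: float = 350.0
    frames_per_plane: int = 200
    drift_threshold_nm: float = 0.0
    averaging_window: int = 10


@dataclass
class LocalizationSection:
    threshold_factor: float = 1.5
    roi_px: int = 15
    chi2_min: float = 0.6
    chi2_max: float = 1.0
    z_range_um: float = 0.5
    fiduciary_sigma_min_nm: float = 130.0
    fiduciary_sigma_max_nm: float = 300.0
    fiduciary_chi2_min: float = 0.65


@dataclass
class RenderSection:
    sr_pixel_nm: float = 10.0
    plane_spacing_nm: float = 200.0
    blur_lateral_nm: float = 10.0
    blur_axial_nm: float = 50.0
    grid_filter: bool = False


@dataclass
class ClusterSection:
    min_loc: int = 10
    cut_nm: float = 50.0


@dataclass
class PipelineConfig:
    """Nested configuration of the whole pipeline; defaults are the
    standard acquisition/analysis parameters (α = 60 nm RMS probe, χ²
    filters 0.6/0.65, σ bounds 130–300 nm, z range ±0.5 µm, W = 10,
    min 10 localizations per cluster, 50 nm cutting distance, FRC
    criterion 1/7, 10/50 nm render blur on 10 nm pixels)."""

    seed: int = 0
    optics: OpticsSection = field(default_factory=OpticsSection)
    camera: CameraSection = field(default_factory=CameraSection)
    kinetics: KineticsSection = field(default_factory=KineticsSection)
    ao: AoSection = field(default_factory=AoSection)
    plan: PlanSection = field(default_factory=PlanSection)
    localization: LocalizationSection = field(default_factory=LocalizationSection)
    render: RenderSection = field(default_factory=RenderSection)
    cluster: ClusterSection = field(default_factory=ClusterSection)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {
            "optics": OpticsSection,
            "camera": CameraSection,
            "kinetics": KineticsSection,
            "ao": AoSection,
            "plan": PlanSection,
            "localization": LocalizationSection,
            "render": RenderSection,
            "cluster": ClusterSection,
        }
        unknown = set(data) - set(sections) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs: dict = {"seed": int(data.get("seed", 0))}
        for name, section_cls in sections.items():
            if name in data:
                kwargs[name] = _from_dict(section_cls, data[name] or {})
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
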
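"""Pipeline configuration.

All instrument- and analysis-level constants live in one dataclass so a run
is fully described by a single YAML file plus seeds.  Defaults are the
calibration of the Slimfield microscope and the analysis thresholds used
throughout: 80 nm pixels, 5 ms frames, a ~250 nm FWHM point spread
function, a 350 nm depth of field, an SNR link gate of 0.4, a 5 px link
radius, 4-point minimum track length, a 0.7-molecule KDE bandwidth, a
3-class (double threshold) Otsu, a 1.2 aspect-ratio shape threshold, a
0.675 molecule-unit single-fluorophore width, a ~100 ms bleach time and
room temperature membrane viscosities (600 cP vegetative / 1000 cP
forespore membrane, 1 cP cytoplasm).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Config:
    # -- imaging calibration
    pixel_size_nm: float = 80.0
    frame_interval_ms: float = 5.0
    psf_fwhm_nm: float = 250.0
    depth_of_field_nm: float = 350.0

    # -- tracking
    snr_gate: float = 0.4
    link_radius_px: float = 5.0
    min_track_points: int = 4
    intensity_radius_px: float = 5.0
    background_square_px: int = 17

    # -- staging
    otsu_classes: int = 3
    aspect_threshold: float = 1.2
    feature_min_area_px: int = 10
    # a candidate feature must be this much brighter than the median
    # in-cell intensity, which rejects noise speckle in a feature-free
    # channel while passing any real septal/forespore structure
    feature_contrast_min: float = 2.0
    end_fraction: float = 0.4
    width_fraction: float = 0.4
    curvature_threshold: float = 1.0

    # -- stoichiometry / clustering
    kde_bandwidth_molecules: float = 0.7
    sigma_single: float = 0.675        # single-fluorophore width, molecule units
    t_b_init_ms: float = 100.0         # seed value for the global bleach-time fit
    ck_windows: tuple[int, int] = (3, 8)
    ck_exponent: float = 10.0

    # -- membrane drag model
    eta_cytoplasm_cP: float = 1.0
    eta_membrane_vegetative_cP: float = 600.0
    eta_membrane_forespore_cP: float = 1000.0
    bilayer_thickness_nm: float = 3.0
    temperature_K: float = 298.0

    # -- cell geometry priors (synthetic data)
    cell_width_um: float = 0.9

    # -- randomness
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ck_windows" in raw:
            raw["ck_windows"] = tuple(raw["ck_windows"])
        return cls(**raw)

    def validate(self) -> None:
        for name in (
            "pixel_size_nm", "frame_interval_ms", "psf_fwhm_nm",
            "depth_of_field_nm", "link_radius_px", "kde_bandwidth_molecules",
            "sigma_single", "t_b_init_ms", "eta_cytoplasm_cP",
            "bilayer_thickness_nm", "temperature_K", "cell_width_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.snr_gate < 0:
            raise ValueError("snr_gate must be >= 0")


DEFAULT_CONFIG = Config()
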
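"""Structured analysis configuration.

One YAML file holds named parameter groups per pipeline stage; CLI flags
override file values. Unknown keys are rejected by name so typos cannot
silently fall back to defaults. Numeric parameters are documented with
units in DEFAULTS.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import ConfigError

# Defaults per stage. Units: bp = base pairs, um = micrometres, s = seconds.
DEFAULTS: dict[str, dict] = {
    "global": {
        "seed": 0,
        "out_dir": "results",
        "log_level": "INFO",
    },
    "simulate_hic": {
        "n_bins": 400,
        "bin_size": 150_000,        # bp
        "alpha": 1.0,               # decay exponent
        "epsilon": 0.4,             # compartment strength, [0, 1)
        "block_size": 20,           # bins per compartment block
        "tad_size": 25,             # bins per TAD
        "beta": 1.0,                # TAD strength
        "gamma": 0.2,               # corner-peak strength
        "corner_width": 2,          # bins
        "inter_tad_boost": 0.0,     # adjacent-TAD contact boost
        "depth": 2_000_000,         # total contacts
        "expected_only": False,
    },
    "simulate_image": {
        "height": 256, "width": 256,
        "pixel_size": 0.05,         # um/pixel
        "mode": "vermicelli",
        "n_fibers": 4,
        "bead_spacing": 0.34,       # um
        "spacing_jitter_sd": 0.03,  # um
        "bead_amplitude": 200.0,
        "background": 20.0,
        "psf_sigma": 0.1,           # um
        "nucleolus_count": 1,
        "nucleolus_radius": 12,     # pixels
        "noise": "poisson",
        "gaussian_sd": 0.0,
    },
    "simulate_frap": {
        "A": 0.3, "B": 0.5,
        "tauA": 2.0, "tauB": 30.0,  # s
        "dt": 1.0,                  # s
        "n_pre": 3, "n_post": 300,
        "acquisition_bleach_rate": 0.002,  # per frame
        "noise_sd": 0.02,
        "mode": "frap",
        "ifrap_tau": 600.0,         # s
        "ifrap_plateau": 0.2,
        "ifrap_amplitude": 0.8,
    },
    "heterogeneity": {
        "box": 5,                   # pixels
        "stride": 5,                # pixels
        "target_mean": 100.0,
    },
    "beads": {
        "min_separation": 0.15,     # um
        "threshold": 0.3,           # relative to max of band-passed image
        "psf_sigma": 0.1,           # um
        "expected_spacing": 0.34,   # um, chain-link radius = 2x this
    },
    "clusters": {
        "threshold": 25.0,
        "min_diameter": 0.492,      # um
    },
    "frap_fit": {"pre_frames": 3},
    "hic_stats": {
        "target_total": 160_000_000,
        "balance_tol": 1e-5,
        "max_iter": 200,
        "min_coverage_mad": 3.0,
        "geometric_factor": 1.12,
    },
    "compartments": {
        "resolution": 150_000,      # bp
        "n_quantiles": 5,
    },
    "tads": {
        "resolution": 40_000,       # bp
        "window": 500_000,          # bp
        "delta_window": 100_000,    # bp
        "min_strength": 0.1,
        "min_size": 200_000,        # bp, ATA filter
        "out_pixels": 90,
        "flank_fraction": 0.5,
        "long_threshold": 500_000,  # bp
    },
    "rg": {
        "connectivity": 26,
        "voxel_size": [1.0, 1.0, 1.0],  # um per axis (z, y, x)
    },
}


class AnalysisConfig:
    """Nested stage -> parameter mapping with defaults and strict keys."""

    def __init__(self, overrides: dict | None = None) -> None:
        self._data = copy.deepcopy(DEFAULTS)
        if overrides:
            self._merge(overrides)

    def _merge(self, overrides: dict) -> None:
        for stage, params in overrides.items():
            if stage not in self._data:
                raise ConfigError(f"unknown config group {stage!r}")
            if not isinstance(params, dict):
                raise ConfigError(f"group {stage!r} must be a mapping")
            for key, value in params.items():
                if key not in self._data[stage]:
                    raise ConfigError(f"unknown key {stage}.{key}")
                self._data[stage][key] = value

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(data)

    def __getitem__(self, stage: str) -> dict:
        if stage not in self._data:
            raise ConfigError(f"unknown config group {stage!r}")
        return self._data[stage]

    def override(self, stage: str, **kwargs) -> None:
        self._merge({stage: {k: v for k, v in kwargs.items() if v is not None}})

    def as_dict(self) -> dict:
        return copy.deepcopy(self._data)
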
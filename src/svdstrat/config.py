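"""Structured configuration: one YAML file drives every CLI stage.

Documented keys (all optional; defaults shown by :func:`default_config`):

grid:
  shape: [32, 32, 32]       # template grid, voxels
  voxel_size_mm: 2.0        # isotropic voxel edge
effects:                    # any EffectSpec field, e.g.
  gm_reduction_fraction: 0.15
  wmh_excess: 0.2
  noise_sd: 0.02
  n_non: 97
  n_conv: 22
vbm:
  fwhm_mm: 6.0              # Gaussian smoothing kernel
  n_permutations: 500       # max-statistic FWE permutations
  alpha: 0.05
  display_uncorrected: 0.001
svm:
  C: 1.0
  n_permutations: 99
cluster:
  k: 4
survival:
  svdp_grid_step: 0.5       # threshold grid resolution (percent)
seed: 0
"""

from __future__ import annotations

import copy
import dataclasses

import yaml

from .synthetic import EffectSpec


def default_config() -> dict:
    return {
        "grid": {"shape": [32, 32, 32], "voxel_size_mm": 2.0},
        "effects": {},
        "vbm": {"fwhm_mm": 6.0, "n_permutations": 500, "alpha": 0.05,
                "display_uncorrected": 0.001},
        "svm": {"C": 1.0, "n_permutations": 99},
        "cluster": {"k": 4},
        "survival": {"svdp_grid_step": 0.5},
        "seed": 0,
    }


def load_config(path=None) -> dict:
    """Defaults merged (shallow, per section) with an optional YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key] = {**cfg[key], **value}
            else:
                cfg[key] = copy.deepcopy(value)
    return cfg


def effects_from_config(cfg: dict) -> EffectSpec:
    allowed = {f.name for f in dataclasses.fields(EffectSpec)}
    overrides = cfg.get("effects", {})
    unknown = set(overrides) - allowed
    if unknown:
        raise ValueError(f"unknown effects key(s): {sorted(unknown)}")
    spec = EffectSpec(**overrides)
    spec.validate()
    return spec
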
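"""YAML run configuration: every model parameter as a named key.

A config file holds the printed physical parameters and run settings, e.g.

    model: V1
    n_samples: 32
    base_seed: 7
    dt: 900
    t_end: 86400
    geometry: {semi_axes: [0.07, 0.09, 0.08], gray_thickness: 0.02,
               ventricle_radius: 0.02, edge: 0.01}
    diffusion: {D_Gad: 1.2e-10, gamma_shape: 3}
    velocity: {v_avg: 1.7e-7, lambda_v: 1.02e-3, v_f: 2.0e-6, R: 0.08}
    boundary: {a: 20, z0: -0.2, u_x3: 1.5e-5, n0: 5.0e-4, V_CSF: 1.4e-4}
    matern: {nu: 0.5, grid_spacing: 0.0023, strict: false}

Unspecified keys keep their defaults.  The resolved configuration is what
`run_monte_carlo` embeds in the run metadata.
"""

from __future__ import annotations

import pathlib

import yaml

from .boundary import BoundaryParams
from .geometry import build_synthetic_brain
from .mesh_io import load_labeled_mesh
from .random_fields import DiffusionSpec, MaternSpec, VelocitySpec
from .uq import ModelSpec

_DIFFUSION_KEYS = {"D_Gad", "offset_factor", "gamma_shape", "gamma_scale",
                   "field_correlation_length"}
_VELOCITY_KEYS = {"v_avg", "lambda_v", "exp_mean", "eta", "v_f", "R", "x_c",
                  "inflow_gamma_shape", "inflow_gamma_scale", "drainage_r"}
_BOUNDARY_KEYS = {"a", "z0", "u_x3", "n0", "V_CSF"}
_RUN_KEYS = {"N": "n_samples", "base_seed": "base_seed", "dt": "dt",
             "t_end": "t_end", "stabilization": "stabilization",
             "calibration_samples": "calibration_samples"}


def _subset(d: dict, allowed: set, where: str) -> dict:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown {where} config keys: {sorted(unknown)}")
    return {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}


def model_spec_from_config(config: dict, mesh=None) -> ModelSpec:
    """Build a ModelSpec from a parsed configuration dictionary."""
    cfg = dict(config)
    model = cfg.pop("model")
    geo = cfg.pop("geometry", {})
    if mesh is None:
        if isinstance(geo, str):
            mesh = load_labeled_mesh(geo)
        else:
            mesh = build_synthetic_brain(
                geo.get("semi_axes", (0.07, 0.09, 0.08)),
                geo.get("gray_thickness", 0.02),
                geo.get("ventricle_radius", 0.02),
                geo.get("edge", 0.01))
    diffusion = None
    if "diffusion" in cfg:
        diffusion = DiffusionSpec(model=model if model in ("D1", "D2") else "D1",
                                  **_subset(cfg.pop("diffusion"), _DIFFUSION_KEYS,
                                            "diffusion"))
    velocity = None
    if "velocity" in cfg and model in ("V1", "V2", "V3"):
        velocity = VelocitySpec(model=model,
                                **_subset(cfg.pop("velocity"), _VELOCITY_KEYS,
                                          "velocity"))
    else:
        cfg.pop("velocity", None)
    boundary = BoundaryParams(**_subset(cfg.pop("boundary", {}), _BOUNDARY_KEYS,
                                        "boundary"))
    matern = None
    if "matern" in cfg:
        m = cfg.pop("matern")
        lam = m.pop("lambda", None)
        if lam is None:
            lam = (velocity or VelocitySpec(model="V1")).lambda_v \
                if model in ("V1", "V2") else \
                (diffusion or DiffusionSpec()).field_correlation_length
        lo, hi = mesh.bounding_box()
        spacing = m.pop("grid_spacing", 0.0023)
        matern = MaternSpec(lam, box_origin=tuple(lo - 0.005),
                            box_extent=tuple(hi - lo + 0.01),
                            grid_spacing=spacing, **m)
    run_kwargs = {}
    for key, target in _RUN_KEYS.items():
        if target in cfg:
            run_kwargs[key] = cfg.pop(target)
    if cfg:
        raise ValueError(f"unknown config keys: {sorted(cfg)}")
    return ModelSpec(model=model, mesh=mesh, diffusion=diffusion,
                     velocity=velocity, matern=matern, boundary=boundary,
                     **run_kwargs)


def load_model_config(path) -> ModelSpec:
    """Parse a YAML configuration file into a ModelSpec."""
    with open(pathlib.Path(path)) as f:
        return model_spec_from_config(yaml.safe_load(f))
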
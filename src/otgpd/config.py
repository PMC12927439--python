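"""TOML run-configuration loading.

Sections map one-to-one onto the engine dataclasses:

    [kernel]    sigma_c2, sigma_f2_init, length_scale_init, nuggets
    [hyperopt]  msub_init, msub_cap, energy_filter_kappa, maxiter
    [barrier]   lambda_max, mu0, alpha, mu_max
    [hod]       window, threshold, max_retries, subset_increment
    [prior]     dof_floor, dof_per_interaction_type, location, scale
    [trust]     t_min, dt_explore, n_half, a_floor, a_atoms
    [dimer]     separation, rotation_force_tol, max_rotations, max_step,
                ratio_at_limit, force_tol, ...
    [budgets]   max_pes_calls, max_outer_iterations, max_surrogate_steps
    [pes]       which in-repo analytic surface to run on (CLI use)

Unknown keys raise, so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path
from typing import Any

from .controller import ControllerConfig, TrustRadiusConfig
from .dimer import DimerSettings
from .hyperopt import BarrierConfig, HODConfig, HyperoptConfig, PriorConfig

__all__ = ["load_config", "controller_config_from_dict"]


def _build(cls, section: dict[str, Any], name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
    return cls(**section)


def controller_config_from_dict(raw: dict[str, Any]) -> ControllerConfig:
    hyper = _build(
        HyperoptConfig,
        {
            **raw.get("hyperopt", {}),
            "barrier": _build(BarrierConfig, raw.get("barrier", {}), "barrier"),
            "hod": _build(HODConfig, raw.get("hod", {}), "hod"),
            "prior": _build(PriorConfig, raw.get("prior", {}), "prior"),
        },
        "hyperopt",
    )
    dimer_section = dict(raw.get("dimer", {}))
    budgets = dict(raw.get("budgets", {}))
    dimer_section.setdefault("max_translations", budgets.pop("max_surrogate_steps", 10_000))
    kernel = dict(raw.get("kernel", {}))

    cfg = ControllerConfig(
        trust=_build(TrustRadiusConfig, raw.get("trust", {}), "trust"),
        hyperopt=hyper,
        inner_dimer=_build(DimerSettings, dimer_section, "dimer"),
    )
    for key in ("sigma_c2", "sigma_f2_init", "length_scale_init", "energy_nugget", "gradient_nugget"):
        if key in kernel:
            setattr(cfg, key, float(kernel.pop(key)))
    if kernel:
        raise ValueError(f"unknown keys in [kernel]: {sorted(kernel)}")
    for key in ("max_pes_calls", "max_outer_iterations"):
        if key in budgets:
            setattr(cfg, key, int(budgets.pop(key)))
    if budgets:
        raise ValueError(f"unknown keys in [budgets]: {sorted(budgets)}")
    cfg.force_tol = cfg.inner_dimer.force_tol
    return cfg


def load_config(path: str | Path) -> tuple[ControllerConfig, dict[str, Any]]:
    """Parse a TOML run file; returns (controller config, raw [pes] section)."""
    raw = tomllib.loads(Path(path).read_text())
    pes_section = raw.pop("pes", {})
    return controller_config_from_dict(raw), pes_section
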
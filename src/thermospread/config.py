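"""Run configuration: defaults, YAML loading, validation, object builders.

The config file is the single source of truth; CLI flags override it and the
override is recorded in the resolved copy written to the run directory.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .bioheat import CauteryApplication, TissueModel, max_stable_dt
from .calibration import CalibrationResult, compute_pixel_size
from .cohort import CohortConfig, SensorModel
from .errors import ConfigError

__all__ = [
    "default_config",
    "load_config",
    "merge_config",
    "validate_config",
    "build_tissue",
    "build_application",
    "build_sensor",
    "build_cohort_config",
    "build_calibration",
]


def default_config() -> dict:
    return {
        "seed": 0,
        "threshold_c": 60.0,
        "cohort": {
            "n_per_group": 16,
            "dropout_rate": 0.0,
            "jitter": {"diffusivity": 0.5, "coupling": 0.5, "contact_area": 0.5},
            "extra_observation_s": 1.0,
            "dt_s": 0.02,
            "snapshot_every_s": 0.1,
            "macro_relative_sd": 0.1,
        },
        "tissue": {
            "dims": [60, 60, 40],
            "voxel_mm": 0.5,
            "diffusivity_mm2_s": 0.14,
            "rho_c_j_mm3_k": 3.6e-3,
            "ambient_c": 37.0,
            "surface_h_w_mm2_k": 0.0,
            "boundary": "insulated",
        },
        "application": {
            "coupling_efficiency": 0.15,
            "prong_size_mm": [1.5, 4.0],
            "prong_gap_mm": 2.0,
            "deposition_depth_mm": 1.0,
        },
        "sensor": {
            "array_shape": [60, 80],
            "frame_rate_hz": 10.0,
            "netd_c": 0.1,
            "bias_c": 0.0,
            "scene_mm_per_pixel": 1.0,
            "saturation_c": 150.0,
        },
    }


def merge_config(base: dict, override: dict | None) -> dict:
    """Recursive dict merge; override values win."""
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults ← YAML file ← explicit overrides."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        cfg = merge_config(cfg, user)
    return merge_config(cfg, overrides)


def build_tissue(cfg: dict) -> TissueModel:
    t = cfg["tissue"]
    return TissueModel(
        dims=tuple(t["dims"]),
        voxel_mm=float(t["voxel_mm"]),
        diffusivity_mm2_s=float(t["diffusivity_mm2_s"]),
        rho_c_j_mm3_k=float(t["rho_c_j_mm3_k"]),
        ambient_c=float(t["ambient_c"]),
        surface_h_w_mm2_k=float(t["surface_h_w_mm2_k"]),
        boundary=t["boundary"],
    )


def build_application(cfg: dict, power_w: float = 30.0, duration_s: float = 2.0) -> CauteryApplication:
    a = cfg["application"]
    return CauteryApplication(
        power_w=power_w,
        duration_s=duration_s,
        coupling_efficiency=float(a["coupling_efficiency"]),
        prong_size_mm=tuple(a["prong_size_mm"]),
        prong_gap_mm=float(a["prong_gap_mm"]),
        deposition_depth_mm=float(a["deposition_depth_mm"]),
    )


def build_sensor(cfg: dict) -> SensorModel:
    s = cfg["sensor"]
    return SensorModel(
        array_shape=tuple(s["array_shape"]),
        frame_rate_hz=float(s["frame_rate_hz"]),
        netd_c=float(s["netd_c"]),
        bias_c=float(s["bias_c"]),
        scene_mm_per_pixel=float(s["scene_mm_per_pixel"]),
        saturation_c=float(s.get("saturation_c", 150.0)),
    )


def build_cohort_config(cfg: dict) -> CohortConfig:
    c = cfg["cohort"]
    return CohortConfig(
        n_per_group=int(c["n_per_group"]),
        base_seed=int(cfg["seed"]),
        jitter=dict(c["jitter"]),
        dropout_rate=float(c["dropout_rate"]),
        extra_observation_s=float(c["extra_observation_s"]),
        dt_s=float(c["dt_s"]),
        snapshot_every_s=float(c["snapshot_every_s"]),
        macro_relative_sd=float(c["macro_relative_sd"]),
    )


def build_calibration(block: dict) -> CalibrationResult:
    """Calibration block: either {mm_per_pixel: x} or
    {p1: [r, c], p2: [r, c], known_length_mm: x}."""
    if "mm_per_pixel" in block:
        return CalibrationResult(mm_per_pixel=float(block["mm_per_pixel"]))
    try:
        return compute_pixel_size(
            tuple(block["p1"]), tuple(block["p2"]), float(block["known_length_mm"])
        )
    except KeyError as exc:
        raise ConfigError(f"calibration block missing key {exc}") from None


def validate_config(cfg: dict) -> list[str]:
    """Return a list of problems (empty iff the config satisfies every
    module's preconditions, including solver stability)."""
    problems: list[str] = []

    try:
        tissue = build_tissue(cfg)
    except Exception as exc:
        problems.append(f"tissue: {exc}")
        tissue = None

    try:
        build_application(cfg)
    except Exception as exc:
        problems.append(f"application: {exc}")

    try:
        build_sensor(cfg)
    except Exception as exc:
        problems.append(f"sensor: {exc}")

    try:
        cohort_cfg = build_cohort_config(cfg)
    except Exception as exc:
        problems.append(f"cohort: {exc}")
        cohort_cfg = None

    if tissue is not None and cohort_cfg is not None:
        dt_max = max_stable_dt(tissue)
        if cohort_cfg.dt_s > dt_max * (1 + 1e-12):
            problems.append(
                f"solver: dt_s={cohort_cfg.dt_s:g} violates stability; "
                f"maximal admissible dt_s is {dt_max:.6g} s"
            )

    if tissue is not None:
        thr = float(cfg["threshold_c"])
        if not (tissue.ambient_c < thr < 400.0):
            problems.append(
                f"threshold_c={thr:g} must lie in (ambient={tissue.ambient_c:g}, 400) °C"
            )

    return problems
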
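"""Synthetic cohorts: camera rendering of simulated fields and multi-sample
generation with the study's 2×2 group grid (30/60 W × 2/4 s).

Between-sample variability enters through the physics — lognormal jitter on
diffusivity, coupling efficiency and contact area — not through ad-hoc noise
on the measured areas.  The whole cohort is a pure function of its config:
per-sample seed = ``base_seed XOR sample index``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bioheat import (
    CauteryApplication,
    DamageTruth,
    TemperatureField,
    TissueModel,
    ground_truth_damage,
    simulate_field,
    surface_slice,
)
from .errors import ConfigError
from .io import ThermogramSequence, sequence_from_array

__all__ = [
    "SensorModel",
    "CohortConfig",
    "CohortSample",
    "render_thermograms",
    "emulate_macro_area",
    "generate_cohort",
    "fiducial_spec",
    "STUDY_GROUPS",
]

#: The study's group grid: (power W, application time s).
STUDY_GROUPS: tuple[tuple[float, float], ...] = ((30.0, 2.0), (30.0, 4.0), (60.0, 2.0), (60.0, 4.0))


@dataclass(frozen=True)
class SensorModel:
    """Microbolometer camera model.

    Defaults mirror the compact 60 × 80 array at 10 Hz with NETD < 0.1 °C and
    a systematic accuracy budget of ±2 °C (``bias_c`` admissible range).
    ``scene_mm_per_pixel`` ties the camera grid to the tissue surface; the
    default 1.0 mm gives ~1 mm² pixels at the tissue plane.
    """

    array_shape: tuple[int, int] = (60, 80)  # rows × cols
    frame_rate_hz: float = 10.0
    netd_c: float = 0.1
    bias_c: float = 0.0
    scene_mm_per_pixel: float = 1.0
    saturation_c: float = 150.0  # compact-camera measurement-range ceiling

    def __post_init__(self) -> None:
        if self.netd_c < 0:
            raise ConfigError("netd_c must be non-negative")
        if self.frame_rate_hz <= 0:
            raise ConfigError("frame_rate_hz must be positive")
        if abs(self.bias_c) > 2.0:
            raise ConfigError(f"bias_c outside the ±2 °C accuracy budget: {self.bias_c}")
        if self.scene_mm_per_pixel <= 0:
            raise ConfigError("scene_mm_per_pixel must be positive")
        if self.saturation_c <= 60.0:
            raise ConfigError("saturation_c must exceed the segmentation range (> 60 °C)")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generation settings (defaults reproduce the study layout:
    4 groups × 16 sessions)."""

    n_per_group: int = 16
    base_seed: int = 0
    # relative SDs; large enough that per-group area IQRs land in the same
    # order of magnitude as the medians, as observed between tissue samples
    jitter: dict = field(
        default_factory=lambda: {"diffusivity": 0.5, "coupling": 0.5, "contact_area": 0.5}
    )
    dropout_rate: float = 0.0
    groups: tuple[tuple[float, float], ...] = STUDY_GROUPS
    extra_observation_s: float = 1.0
    dt_s: float = 0.02
    snapshot_every_s: float = 0.1
    macro_relative_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ConfigError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class CohortSample:
    """One synthetic measurement session."""

    sample_id: str
    group: tuple[float, float]  # (power_w, duration_s)
    sequence: ThermogramSequence
    truth: DamageTruth
    macro_area_mm2: float
    params: dict
    seed: int
    dropped: bool = False


def _lognormal_factor(rng: np.random.Generator, relative_sd: float) -> float:
    """Multiplicative jitter with median 1 and ~the stated relative SD."""
    if relative_sd <= 0:
        return 1.0
    sigma = math.sqrt(math.log1p(relative_sd**2))
    return float(np.exp(rng.normal(0.0, sigma)))


def render_thermograms(
    field: TemperatureField, sensor: SensorModel, seed: int
) -> ThermogramSequence:
    """Observe a simulated field through the camera model.

    The tissue surface is block-averaged to the camera pixel pitch and
    embedded centered in the camera frame; pixels outside the tissue read the
    ambient temperature (the chamber background).  Bias is added, then i.i.d.
    Gaussian noise of SD ``netd_c``; readings above the camera's measurement
    range saturate at ``saturation_c`` (this never affects 60 °C segmentation,
    only the reported peak).  Deterministic for a fixed seed.
    """
    block = sensor.scene_mm_per_pixel / field.voxel_mm
    if abs(block - round(block)) > 1e-9 or round(block) < 1:
        raise ConfigError(
            f"scene_mm_per_pixel ({sensor.scene_mm_per_pixel} mm) must be a "
            f"positive integer multiple of the voxel pitch ({field.voxel_mm} mm)"
        )
    b = int(round(block))

    slices = surface_slice(field)  # (nt, ny, nx)
    _, ny, nx = slices.shape
    if ny % b or nx % b:
        raise ConfigError(
            f"surface grid {ny}×{nx} is not divisible by the {b}×{b} camera block"
        )
    by, bx = ny // b, nx // b
    rows, cols = sensor.array_shape
    if by > rows or bx > cols:
        raise ConfigError(
            f"tissue surface ({by}×{bx} camera px) exceeds the camera array "
            f"({rows}×{cols}); enlarge the array or coarsen scene_mm_per_pixel"
        )
    r0 = (rows - by) // 2
    c0 = (cols - bx) // 2

    # frame times on the camera clock, sampled from the nearest snapshot
    t_last = field.times[-1]
    n_frames = int(math.floor(t_last * sensor.frame_rate_hz + 1e-9)) + 1
    frame_times = np.arange(n_frames) / sensor.frame_rate_hz
    snap_idx = np.abs(field.times[None, :] - frame_times[:, None]).argmin(axis=1)

    rng = np.random.default_rng(seed)
    stack = np.full((n_frames, rows, cols), field.ambient_c, dtype=np.float64)
    for i, si in enumerate(snap_idx):
        blocked = slices[si].reshape(by, b, bx, b).mean(axis=(1, 3))
        stack[i, r0 : r0 + by, c0 : c0 + bx] = blocked
    stack += sensor.bias_c
    if sensor.netd_c > 0:
        stack += rng.normal(0.0, sensor.netd_c, size=stack.shape)
    np.minimum(stack, sensor.saturation_c, out=stack)

    meta = {"ambient_c": field.ambient_c, "source": "synthetic"}
    return sequence_from_array(stack, frame_rate_hz=sensor.frame_rate_hz, meta=meta)


def fiducial_spec(sensor: SensorModel) -> dict:
    """A 10-pixel in-scene fiducial consistent with the sensor geometry.

    Plays the role of the known-length metric reference (the scalpel tip in
    the physical sessions): calibrating on it recovers the camera's
    mm-per-pixel scale exactly.
    """
    length_px = 10.0
    return {
        "p1": (2.0, 2.0),
        "p2": (2.0, 2.0 + length_px),
        "known_length_mm": length_px * sensor.scene_mm_per_pixel,
    }


def emulate_macro_area(truth: DamageTruth, seed: int, relative_sd: float = 0.1) -> float:
    """Emulated manual-delineation necrosis area (mm²).

    Ground-truth surface area times a lognormal multiplicative error with
    median 1 and the stated relative SD — the variability of tracing a
    necrosis boundary by hand.
    """
    rng = np.random.default_rng(seed)
    return truth.surface_area_mm2 * _lognormal_factor(rng, relative_sd)


def _jittered_scenario(
    tissue: TissueModel,
    app: CauteryApplication,
    jitter: dict,
    rng: np.random.Generator,
) -> tuple[TissueModel, CauteryApplication, dict]:
    f_alpha = _lognormal_factor(rng, jitter.get("diffusivity", 0.0))
    f_coupling = _lognormal_factor(rng, jitter.get("coupling", 0.0))
    f_area = _lognormal_factor(rng, jitter.get("contact_area", 0.0))
    lin = math.sqrt(f_area)  # area jitter split over both lateral prong dims

    tissue_j = replace(tissue, diffusivity_mm2_s=tissue.diffusivity_mm2_s * f_alpha)
    app_j = replace(
        app,
        coupling_efficiency=min(app.coupling_efficiency * f_coupling, 1.0),
        prong_size_mm=(app.prong_size_mm[0] * lin, app.prong_size_mm[1] * lin),
    )
    params = {
        "diffusivity_mm2_s": tissue_j.diffusivity_mm2_s,
        "coupling_efficiency": app_j.coupling_efficiency,
        "prong_size_x_mm": app_j.prong_size_mm[0],
        "prong_size_y_mm": app_j.prong_size_mm[1],
    }
    return tissue_j, app_j, params


def generate_cohort(
    cfg: CohortConfig,
    tissue: TissueModel | None = None,
    app_template: CauteryApplication | None = None,
    sensor: SensorModel | None = None,
    threshold_c: float = 60.0,
) -> tuple[list[CohortSample], pd.DataFrame]:
    """Generate group × replicate synthetic sessions plus a manifest.

    For each sample: jitter the physical parameters, run the bioheat solver,
    render through the camera, and record ground-truth damage and the
    emulated macrophotography area.  Dropout flags samples (they are kept in
    the manifest with ``dropped=True``) so group Ns can fall below
    ``n_per_group`` without reshuffling seeds.
    """
    tissue = tissue if tissue is not None else TissueModel()
    app_template = app_template if app_template is not None else CauteryApplication()
    sensor = sensor if sensor is not None else SensorModel()
    fid = fiducial_spec(sensor)

    samples: list[CohortSample] = []
    rows = []
    idx = 0
    for power_w, duration_s in cfg.groups:
        for rep in range(cfg.n_per_group):
            sample_seed = int(cfg.base_seed) ^ idx
            rng = np.random.default_rng(sample_seed)
            tissue_j, app_j, params = _jittered_scenario(
                tissue,
                replace(app_template, power_w=power_w, duration_s=duration_s),
                cfg.jitter,
                rng,
            )
            render_seed = int(rng.integers(2**31))
            macro_seed = int(rng.integers(2**31))
            dropped = bool(rng.random() < cfg.dropout_rate)

            t_end = duration_s + cfg.extra_observation_s
            try:
                fld = simulate_field(
                    tissue_j, app_j, t_end_s=t_end, dt_s=cfg.dt_s,
                    snapshot_every_s=cfg.snapshot_every_s,
                )
            except Exception as exc:
                raise ConfigError(
                    f"simulation failed for sample p{power_w:g}w_t{duration_s:g}s_r{rep:02d}: {exc}"
                ) from exc
            seq = render_thermograms(fld, sensor, seed=render_seed)
            truth = ground_truth_damage(fld, threshold_c=threshold_c)
            macro = emulate_macro_area(truth, seed=macro_seed, relative_sd=cfg.macro_relative_sd)

            sample_id = f"p{power_w:g}w_t{duration_s:g}s_r{rep:02d}"
            samples.append(
                CohortSample(
                    sample_id=sample_id,
                    group=(power_w, duration_s),
                    sequence=seq,
                    truth=truth,
                    macro_area_mm2=macro,
                    params=params,
                    seed=sample_seed,
                    dropped=dropped,
                )
            )
            rows.append(
                {
                    "sample_id": sample_id,
                    "power_w": power_w,
                    "duration_s": duration_s,
                    "seed": sample_seed,
                    "dropped": dropped,
                    **params,
                    "truth_area_mm2": truth.surface_area_mm2,
                    "truth_depth_mm": truth.max_depth_mm,
                    "macro_area_mm2": macro,
                    "n_frames": len(seq),
                    "fiducial_p1_row": fid["p1"][0],
                    "fiducial_p1_col": fid["p1"][1],
                    "fiducial_p2_row": fid["p2"][0],
                    "fiducial_p2_col": fid["p2"][1],
                    "fiducial_known_length_mm": fid["known_length_mm"],
                    "scene_mm_per_pixel": sensor.scene_mm_per_pixel,
                }
            )
            idx += 1

    return samples, pd.DataFrame(rows)
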
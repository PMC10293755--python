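"""Explicit finite-difference heat diffusion in an ex-vivo tissue block.

Solves  ∂T/∂t = α ∇²T + q/(ρc)  on a regular voxel grid with a volumetric
source under two rectangular electrode prongs, optional convective cooling on
the top face, and per-face insulated / fixed-ambient boundaries.  There is no
perfusion term: the tissue is inanimate (a Pennes perfusion hook would slot
into :func:`simulate_field` if living tissue were ever modelled).

Grid layout: arrays are indexed ``[z, y, x]`` with z = 0 the top (observed)
surface.  Depth of voxel layer ``z`` is taken at the voxel center,
``(z + 0.5) * voxel_mm``.

The scheme is forward Euler with the standard 7-point Laplacian and is only
conditionally stable: ``dt <= voxel² / (6 α)``.  The step is checked and a
violation is rejected naming the maximal admissible dt.

Phase change, vaporization and temperature-dependent properties are omitted;
temperatures may exceed 100 °C and are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, StabilityError

__all__ = [
    "TissueModel",
    "CauteryApplication",
    "TemperatureField",
    "DamageTruth",
    "simulate_field",
    "surface_slice",
    "ground_truth_damage",
    "max_stable_dt",
]

_FACES = ("x_lo", "x_hi", "y_lo", "y_hi", "z_top", "z_bottom")
_BOUNDARY_MODES = ("insulated", "fixed_ambient")


def _normalize_boundary(boundary) -> dict[str, str]:
    if isinstance(boundary, str):
        if boundary not in _BOUNDARY_MODES:
            raise ConfigError(f"unknown boundary mode {boundary!r}")
        return {f: boundary for f in _FACES}
    out = {f: "insulated" for f in _FACES}
    for face, mode in dict(boundary).items():
        if face not in _FACES:
            raise ConfigError(f"unknown face {face!r}; faces are {_FACES}")
        if mode not in _BOUNDARY_MODES:
            raise ConfigError(f"unknown boundary mode {mode!r}")
        out[face] = mode
    return out


@dataclass(frozen=True)
class TissueModel:
    """Geometry and thermal properties of the tissue block.

    Defaults give a 30 × 30 × 20 mm block at 37 °C with literature muscle
    properties (α = 0.14 mm²/s, ρc = 3.6e-3 J/(mm³·K)) — stated defaults,
    not measured values.
    """

    dims: tuple[int, int, int] = (60, 60, 40)  # (nx, ny, nz)
    voxel_mm: float = 0.5
    diffusivity_mm2_s: float = 0.14
    rho_c_j_mm3_k: float = 3.6e-3
    ambient_c: float = 37.0
    surface_h_w_mm2_k: float = 0.0
    boundary: object = "insulated"

    def __post_init__(self) -> None:
        nx, ny, nz = self.dims
        if min(nx, ny, nz) < 4:
            raise ConfigError(f"each grid dimension must be >= 4, got {self.dims}")
        if self.voxel_mm <= 0 or self.diffusivity_mm2_s <= 0 or self.rho_c_j_mm3_k <= 0:
            raise ConfigError("voxel_mm, diffusivity and rho_c must be positive")
        object.__setattr__(self, "boundary", _normalize_boundary(self.boundary))

    @property
    def size_mm(self) -> tuple[float, float, float]:
        nx, ny, nz = self.dims
        return (nx * self.voxel_mm, ny * self.voxel_mm, nz * self.voxel_mm)


@dataclass(frozen=True)
class CauteryApplication:
    """Bipolar-cautery deposition: two rectangular surface prongs.

    The prongs are centered on the surface, separated along x by
    ``prong_gap_mm``; each prong is ``prong_size_mm[0]`` (x) ×
    ``prong_size_mm[1]`` (y).  ``coupling_efficiency`` is the fraction of the
    nominal electrical power deposited as heat, distributed uniformly over the
    prong footprints down to ``deposition_depth_mm``.
    """

    power_w: float = 30.0
    duration_s: float = 2.0
    coupling_efficiency: float = 0.15
    prong_size_mm: tuple[float, float] = (1.5, 4.0)
    prong_gap_mm: float = 2.0
    deposition_depth_mm: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.coupling_efficiency <= 1):
            raise ConfigError(
                f"coupling_efficiency must be in (0, 1], got {self.coupling_efficiency}"
            )
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.power_w < 0:
            raise ConfigError("power_w must be non-negative")
        if min(self.prong_size_mm) <= 0 or self.prong_gap_mm < 0:
            raise ConfigError("prong dimensions must be positive, gap non-negative")
        if self.deposition_depth_mm <= 0:
            raise ConfigError("deposition_depth_mm must be positive")


@dataclass(frozen=True)
class DamageTruth:
    """Ground-truth thermal damage from the simulated field."""

    surface_area_mm2: float
    max_depth_mm: float
    threshold_c: float


@dataclass(frozen=True)
class TemperatureField:
    """Time-ordered 3-D temperature snapshots, °C, indexed ``[t][z, y, x]``."""

    snapshots: np.ndarray  # (nt, nz, ny, nx)
    times: np.ndarray  # (nt,), seconds
    dt_s: float
    voxel_mm: float
    ambient_c: float

    def __post_init__(self) -> None:
        if self.snapshots.ndim != 4 or self.snapshots.shape[0] != len(self.times):
            raise ValueError("snapshots must be (nt, nz, ny, nx) matching times")


def max_stable_dt(tissue: TissueModel) -> float:
    """Largest time step admitted by the explicit 7-point scheme."""
    return tissue.voxel_mm**2 / (6.0 * tissue.diffusivity_mm2_s)


def source_mask(tissue: TissueModel, app: CauteryApplication) -> np.ndarray:
    """Boolean ``(nz, ny, nx)`` mask of voxels receiving deposited power."""
    nx, ny, nz = tissue.dims
    v = tissue.voxel_mm
    sx, sy, _ = tissue.size_mm
    pw, pl = app.prong_size_mm

    half_extent_x = app.prong_gap_mm / 2 + pw
    if 2 * half_extent_x > sx or pl > sy or app.deposition_depth_mm > nz * v:
        raise ConfigError(
            f"cautery footprint ({2 * half_extent_x:.1f} × {pl:.1f} × "
            f"{app.deposition_depth_mm:.1f} mm) does not fit inside the "
            f"{sx:.0f} × {sy:.0f} × {nz * v:.0f} mm tissue block"
        )

    xc = (np.arange(nx) + 0.5) * v - sx / 2  # mm, centered
    yc = (np.arange(ny) + 0.5) * v - sy / 2
    zc = (np.arange(nz) + 0.5) * v  # depth from surface

    prong_centers_x = (-(app.prong_gap_mm + pw) / 2, (app.prong_gap_mm + pw) / 2)
    in_x = np.zeros(nx, dtype=bool)
    for cx in prong_centers_x:
        in_x |= np.abs(xc - cx) <= pw / 2 + 1e-9
    in_y = np.abs(yc) <= pl / 2 + 1e-9
    in_z = zc <= app.deposition_depth_mm + 1e-9

    mask = in_z[:, None, None] & in_y[None, :, None] & in_x[None, None, :]
    if not mask.any():
        raise ConfigError("cautery footprint covers no voxels; refine the grid")
    return mask


def _padded(T: np.ndarray, boundary: dict[str, str], ambient: float) -> np.ndarray:
    """Pad with ghost layers: edge-replicate (zero-flux) or ambient (Dirichlet)."""
    P = np.pad(T, 1, mode="edge")
    if boundary["z_top"] == "fixed_ambient":
        P[0, :, :] = ambient
    if boundary["z_bottom"] == "fixed_ambient":
        P[-1, :, :] = ambient
    if boundary["y_lo"] == "fixed_ambient":
        P[:, 0, :] = ambient
    if boundary["y_hi"] == "fixed_ambient":
        P[:, -1, :] = ambient
    if boundary["x_lo"] == "fixed_ambient":
        P[:, :, 0] = ambient
    if boundary["x_hi"] == "fixed_ambient":
        P[:, :, -1] = ambient
    return P


def simulate_field(
    tissue: TissueModel,
    app: CauteryApplication,
    t_end_s: float,
    dt_s: float,
    snapshot_every_s: float,
    initial: np.ndarray | None = None,
) -> TemperatureField:
    """Forward-Euler solution of the heated tissue block.

    The source is active for ``t <= app.duration_s``, zero afterwards.
    Snapshots (including t = 0) are recorded every ``snapshot_every_s``.
    ``initial`` optionally replaces the uniform-ambient initial condition
    (shape ``(nz, ny, nx)``) — used by the physics tests.
    """
    dt_max = max_stable_dt(tissue)
    if dt_s > dt_max * (1 + 1e-12):
        raise StabilityError(
            f"dt_s={dt_s:g} s violates the explicit-scheme stability bound; "
            f"maximal admissible dt_s is {dt_max:.6g} s "
            f"(voxel_mm²/(6·α) with voxel_mm={tissue.voxel_mm:g}, "
            f"α={tissue.diffusivity_mm2_s:g})"
        )
    if t_end_s < app.duration_s:
        raise ConfigError(f"t_end_s={t_end_s:g} is shorter than the application ({app.duration_s:g} s)")
    if snapshot_every_s <= 0 or dt_s <= 0:
        raise ConfigError("dt_s and snapshot_every_s must be positive")

    nx, ny, nz = tissue.dims
    ambient = float(tissue.ambient_c)
    if initial is None:
        T = np.full((nz, ny, nx), ambient, dtype=np.float64)
    else:
        T = np.asarray(initial, dtype=np.float64).copy()
        if T.shape != (nz, ny, nx):
            raise ConfigError(f"initial field shape {T.shape} != {(nz, ny, nx)}")

    alpha = tissue.diffusivity_mm2_s
    v2 = tissue.voxel_mm**2
    boundary = tissue.boundary
    h = tissue.surface_h_w_mm2_k

    if app.power_w > 0:
        mask = source_mask(tissue, app)
        volume_mm3 = mask.sum() * tissue.voxel_mm**3
        q_density = app.power_w * app.coupling_efficiency / volume_mm3  # W/mm³
        dT_source = dt_s * q_density / tissue.rho_c_j_mm3_k
    else:
        mask = None
        dT_source = 0.0

    n_steps = int(round(t_end_s / dt_s))
    snap_stride = max(1, int(round(snapshot_every_s / dt_s)))

    snapshots = [T.copy()]
    times = [0.0]
    coef = alpha * dt_s / v2
    conv_coef = dt_s * h / (tissue.rho_c_j_mm3_k * tissue.voxel_mm)

    for step in range(1, n_steps + 1):
        t_prev = (step - 1) * dt_s
        P = _padded(T, boundary, ambient)
        lap = (
            P[:-2, 1:-1, 1:-1]
            + P[2:, 1:-1, 1:-1]
            + P[1:-1, :-2, 1:-1]
            + P[1:-1, 2:, 1:-1]
            + P[1:-1, 1:-1, :-2]
            + P[1:-1, 1:-1, 2:]
            - 6.0 * T
        )
        T = T + coef * lap
        if mask is not None and t_prev < app.duration_s:
            T[mask] += dT_source
        if conv_coef:
            T[0] -= conv_coef * (T[0] - ambient)
        if step % snap_stride == 0:
            snapshots.append(T.copy())
            times.append(step * dt_s)

    return TemperatureField(
        snapshots=np.stack(snapshots),
        times=np.array(times),
        dt_s=float(dt_s),
        voxel_mm=tissue.voxel_mm,
        ambient_c=ambient,
    )


def surface_slice(field: TemperatureField) -> np.ndarray:
    """Top-layer (z = 0) temperature per snapshot, shape ``(nt, ny, nx)``."""
    return field.snapshots[:, 0, :, :]


def ground_truth_damage(field: TemperatureField, threshold_c: float = 60.0) -> DamageTruth:
    """Damage truth from the full 3-D field: peak-over-time > threshold.

    Surface area counts ever-exceeding top-layer voxels; depth is the center
    of the deepest layer containing any ever-exceeding voxel
    (``(z + 0.5) * voxel_mm``), 0 when nothing exceeds.
    """
    peak = field.snapshots.max(axis=0)  # (nz, ny, nx)
    exceeded = peak > threshold_c
    area = float(exceeded[0].sum()) * field.voxel_mm**2
    layers = np.flatnonzero(exceeded.any(axis=(1, 2)))
    depth = float((layers.max() + 0.5) * field.voxel_mm) if layers.size else 0.0
    return DamageTruth(surface_area_mm2=area, max_depth_mm=depth, threshold_c=float(threshold_c))
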
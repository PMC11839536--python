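"""Synthetic NIR tracer stacks and IHC images with known ground truth.

The in-vivo data this package analyses are time-lapse images of an
intraventricular near-infrared tracer spreading through the brain's
extravascular (glymphatic) space.  Because such kinetics depend on a bulk
flow component whose direction and magnitude are exactly what the ROI
statistics are meant to detect, the generator models the tracer plume with
the minimal transport law exposing those knobs: a 2-D
advection–diffusion–decay equation on the imaging plane,

    dc/dt = D * laplacian(c) - div(v c) - lambda * c,

with zero-flux (no tracer leaves the field) boundaries, a Gaussian bolus
initial condition at the injection site, and a piecewise-constant velocity
field defined separately for the anterior and posterior halves of the
field.  Recorded intensity per pixel is ``camera_gain * c +
background_level + N(0, noise_sigma)``, clipped at zero — i.e. constant
autofluorescence plus additive camera read noise.

The integrator is an operator-split explicit scheme (flux-form upwind
advection, flux-form FTCS diffusion, exact exponential decay) on the pixel
grid.  The substep count is derived from the config so that the diffusion
number stays below 0.2 per axis and the advective Courant number below 0.8;
both sub-updates conserve mass exactly under zero-flux boundaries.
Configs whose stability bound would require an absurd number of substeps
are rejected rather than silently run.

Cohorts draw per-animal lognormal factors (unit mean, given CV) for the
diffusivity and the velocity magnitude, so every animal shares the
condition's flow pattern but not its exact rates.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .io_formats import ImageStack

__all__ = [
    "ConfigError",
    "VelocityField",
    "SimulationConfig",
    "CohortConfig",
    "IHCImage",
    "simulate_tracer_stack",
    "simulate_cohort",
    "make_condition_preset",
    "make_condition_cohort",
    "simulate_ihc_image",
    "CONDITIONS",
    "DEFAULT_SEED",
    "DEFAULT_N_ANIMALS",
    "DEFAULT_INTER_ANIMAL_CV",
]

CONDITIONS = ("sham", "tbi")

#: Default cohort sizes: 14 sham and 12 injured animals.
DEFAULT_N_ANIMALS = {"sham": 14, "tbi": 12}

#: Default master seed for cohort generation.
DEFAULT_SEED = 0

#: Default inter-animal coefficient of variation on transport parameters.
DEFAULT_INTER_ANIMAL_CV = 0.15

_MAX_SUBSTEPS_TOTAL = 2_000_000
_DIFFUSION_NUMBER = 0.2
_COURANT_NUMBER = 0.8


class ConfigError(ValueError):
    """Invalid or numerically unstable simulation configuration."""


@dataclass(frozen=True)
class VelocityField:
    """Piecewise-constant 2-D flow, mm/min, split at ``split_x`` (mm).

    ``anterior`` applies where pixel-centre x > split_x, ``posterior``
    elsewhere.  Components are (vx, vy) with +x anterior and +y the
    animal's left.
    """

    anterior: tuple[float, float] = (0.0, 0.0)
    posterior: tuple[float, float] = (0.0, 0.0)
    split_x: float = 0.0

    def max_speed_component(self) -> float:
        return max(
            abs(v) for pair in (self.anterior, self.posterior) for v in pair
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth transport parameters for one animal's acquisition.

    Units: mm, minutes, arbitrary intensity units (AU).  ``origin`` is the
    physical (x, y) of the field corner (see :mod:`glymphkin.roi_geometry`).
    ``pre_roll`` is the time the plume evolves between bolus deposition and
    the first recorded frame (imaging starts 15 min after infusion by
    default); ``t0_offset`` is the same delay as recorded in metadata.
    """

    grid_shape: tuple[int, int] = (64, 128)
    pixel_size: float = 0.1
    frame_interval: float = 1.0
    n_frames: int = 61
    injection_center: tuple[float, float] = (-1.6, -1.3)
    bolus_amount: float = 2.0e5
    bolus_sigma: float = 0.6
    diffusivity: float = 0.04
    velocity_field: VelocityField = field(default_factory=VelocityField)
    decay_rate: float = 0.0
    background_level: float = 10.0
    camera_gain: float = 1.0
    noise_sigma: float = 1.0
    seed: int = 0
    origin: tuple[float, float] = (-6.4, -3.2)
    bregma: tuple[float, float] = (0.0, 0.0)
    pre_roll: float = 15.0
    t0_offset: float = 15.0

    def validate(self) -> None:
        ny, nx = self.grid_shape
        if ny < 1 or nx < 1 or self.n_frames < 1:
            raise ConfigError("grid_shape and n_frames must be >= 1")
        scalars = {
            "pixel_size": self.pixel_size,
            "frame_interval": self.frame_interval,
            "bolus_amount": self.bolus_amount,
            "bolus_sigma": self.bolus_sigma,
            "diffusivity": self.diffusivity,
            "decay_rate": self.decay_rate,
            "background_level": self.background_level,
            "camera_gain": self.camera_gain,
            "noise_sigma": self.noise_sigma,
            "pre_roll": self.pre_roll,
            "t0_offset": self.t0_offset,
        }
        for name, value in scalars.items():
            if not math.isfinite(value):
                raise ConfigError(f"{name} must be finite, got {value}")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ConfigError("pixel_size and frame_interval must be > 0")
        if self.bolus_amount < 1:
            raise ConfigError("bolus_amount must be >= 1")
        if self.bolus_sigma <= 0:
            raise ConfigError("bolus_sigma must be > 0")
        for name in ("diffusivity", "decay_rate", "noise_sigma", "pre_roll",
                     "background_level", "camera_gain"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        vf = self.velocity_field
        for pair in (vf.anterior, vf.posterior):
            if not all(math.isfinite(v) for v in pair):
                raise ConfigError("velocity components must be finite")
        # stability: reject configs needing an absurd substep count
        self._substeps()

    def _dt_stable(self) -> float:
        dx = self.pixel_size
        dt = math.inf
        if self.diffusivity > 0:
            dt = min(dt, _DIFFUSION_NUMBER * dx * dx / self.diffusivity)
        vmax = self.velocity_field.max_speed_component()
        if vmax > 0:
            dt = min(dt, _COURANT_NUMBER * dx / vmax)
        return dt

    def _substeps(self) -> tuple[int, int]:
        """(substeps per frame interval, substeps for the pre-roll)."""
        dt = self._dt_stable()
        if math.isinf(dt):
            n_frame, n_pre = 1, (1 if self.pre_roll > 0 else 0)
        else:
            n_frame = max(1, math.ceil(self.frame_interval / dt))
            n_pre = math.ceil(self.pre_roll / dt) if self.pre_roll > 0 else 0
        total = n_frame * (self.n_frames - 1) + n_pre
        if total > _MAX_SUBSTEPS_TOTAL:
            raise ConfigError(
                f"stability bound requires {total} substeps "
                f"(> {_MAX_SUBSTEPS_TOTAL}); coarsen the grid or shorten the run"
            )
        return n_frame, n_pre

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["velocity_field"] = dataclasses.asdict(self.velocity_field)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        vf = d.get("velocity_field", {})
        if isinstance(vf, dict):
            d["velocity_field"] = VelocityField(
                anterior=tuple(vf.get("anterior", (0.0, 0.0))),
                posterior=tuple(vf.get("posterior", (0.0, 0.0))),
                split_x=float(vf.get("split_x", 0.0)),
            )
        for key in ("grid_shape", "injection_center", "origin", "bregma"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class CohortConfig:
    """A group of animals sharing a condition's base transport parameters."""

    condition: str
    n_animals: int
    base_config: SimulationConfig
    inter_animal_cv: float = DEFAULT_INTER_ANIMAL_CV
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigError(f"unknown condition {self.condition!r}")
        if self.n_animals < 2:
            raise ConfigError("n_animals must be >= 2")
        if not (0.0 <= self.inter_animal_cv < 1.0):
            raise ConfigError("inter_animal_cv must be in [0, 1)")
        self.base_config.validate()


def _pixel_centers(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = config.grid_shape
    xs = config.origin[0] + (np.arange(nx) + 0.5) * config.pixel_size
    ys = config.origin[1] + (np.arange(ny) + 0.5) * config.pixel_size
    return xs, ys


def _initial_bolus(config: SimulationConfig) -> np.ndarray:
    xs, ys = _pixel_centers(config)
    cx, cy = config.injection_center
    gx = np.exp(-0.5 * ((xs - cx) / config.bolus_sigma) ** 2)
    gy = np.exp(-0.5 * ((ys - cy) / config.bolus_sigma) ** 2)
    w = gy[:, np.newaxis] * gx[np.newaxis, :]
    total = w.sum()
    if total <= 0:
        raise ConfigError("bolus has zero mass on the grid; check injection_center")
    return (config.bolus_amount / total) * w


def _velocity_arrays(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = _pixel_centers(config)
    ny, nx = config.grid_shape
    vf = config.velocity_field
    anterior = xs > vf.split_x
    vx = np.where(anterior, vf.anterior[0], vf.posterior[0])
    vy = np.where(anterior, vf.anterior[1], vf.posterior[1])
    vx = np.broadcast_to(vx, (ny, nx)).astype(np.float64)
    vy = np.broadcast_to(vy, (ny, nx)).astype(np.float64)
    return vx, vy


class _Integrator:
    """Operator-split explicit stepper for one config (mass-conserving)."""

    def __init__(self, config: SimulationConfig):
        self.dx = config.pixel_size
        self.D = config.diffusivity
        self.decay = config.decay_rate
        vx, vy = _velocity_arrays(config)
        # face-centred velocities (interior faces only; boundary flux = 0)
        self.fx = 0.5 * (vx[:, :-1] + vx[:, 1:])
        self.fy = 0.5 * (vy[:-1, :] + vy[1:, :])
        self.advect = (np.abs(self.fx).max() > 0) or (np.abs(self.fy).max() > 0)

    def step(self, c: np.ndarray, dt: float) -> None:
        dx = self.dx
        if self.advect:
            courant = dt / dx
            up = np.where(self.fx > 0, c[:, :-1], c[:, 1:])
            flux = self.fx * up * courant
            c[:, :-1] -= flux
            c[:, 1:] += flux
            up = np.where(self.fy > 0, c[:-1, :], c[1:, :])
            flux = self.fy * up * courant
            c[:-1, :] -= flux
            c[1:, :] += flux
        if self.D > 0:
            a = self.D * dt / (dx * dx)
            d = a * (c[:, 1:] - c[:, :-1])
            c[:, :-1] += d
            c[:, 1:] -= d
            d = a * (c[1:, :] - c[:-1, :])
            c[:-1, :] += d
            c[1:, :] -= d
        if self.decay > 0:
            c *= math.exp(-self.decay * dt)


def simulate_tracer_stack(config: SimulationConfig) -> ImageStack:
    """Simulate one animal's NIR acquisition.

    The plume evolves for ``pre_roll`` minutes after bolus deposition, then
    ``n_frames`` frames are recorded at ``frame_interval``; frame 0 is the
    state at the end of the pre-roll (with zero pre-roll, the deposited
    bolus itself).  Deterministic — bitwise identical output for identical
    config and seed.
    """
    config.validate()
    n_frame_steps, n_pre_steps = config._substeps()
    integrator = _Integrator(config)
    c = _initial_bolus(config)

    rng = np.random.default_rng(config.seed)
    frames = np.empty((config.n_frames,) + tuple(config.grid_shape), dtype=np.float64)

    if n_pre_steps:
        dt_pre = config.pre_roll / n_pre_steps
        for _ in range(n_pre_steps):
            integrator.step(c, dt_pre)

    def record(index: int) -> None:
        img = config.camera_gain * c + config.background_level
        if config.noise_sigma > 0:
            img = img + rng.normal(0.0, config.noise_sigma, size=c.shape)
        np.clip(img, 0.0, None, out=img)
        frames[index] = img

    record(0)
    dt = config.frame_interval / n_frame_steps
    for i in range(1, config.n_frames):
        for _ in range(n_frame_steps):
            integrator.step(c, dt)
        record(i)

    return ImageStack(
        frames=frames,
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        t0_offset=config.t0_offset,
        metadata={
            "origin_mm": list(config.origin),
            "injection_site_mm": list(config.injection_center),
            "bregma_mm": list(config.bregma),
            "seed": int(config.seed),
            "ground_truth": config.to_dict(),
        },
    )


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with the given coefficient of variation."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def simulate_cohort(
    cohort: CohortConfig,
) -> list[tuple[str, ImageStack, SimulationConfig]]:
    """Simulate every animal of a cohort.

    Per-animal parameters are drawn once from the base config: the
    diffusivity and the whole velocity field are multiplied by independent
    unit-mean lognormal factors with the cohort CV.  Sub-seeds derive from
    ``(cohort seed, animal index)``, so adding animals never perturbs
    existing ones.  Returns (animal_id, stack, ground-truth config) tuples.
    """
    cohort.validate()
    out = []
    for i in range(cohort.n_animals):
        rng = np.random.default_rng([cohort.seed, i])
        f_d = _lognormal_factor(rng, cohort.inter_animal_cv)
        f_v = _lognormal_factor(rng, cohort.inter_animal_cv)
        vf = cohort.base_config.velocity_field
        animal_cfg = replace(
            cohort.base_config,
            diffusivity=cohort.base_config.diffusivity * f_d,
            velocity_field=VelocityField(
                anterior=(vf.anterior[0] * f_v, vf.anterior[1] * f_v),
                posterior=(vf.posterior[0] * f_v, vf.posterior[1] * f_v),
                split_x=vf.split_x,
            ),
            seed=int(rng.integers(2**31)),
        )
        animal_id = f"{cohort.condition}{i + 1:02d}"
        stack = simulate_tracer_stack(animal_cfg)
        stack.metadata["condition"] = cohort.condition
        stack.metadata["animal_id"] = animal_id
        out.append((animal_id, stack, animal_cfg))
    return out


def make_condition_preset(condition: str) -> SimulationConfig:
    """Load the packaged base configuration for ``sham`` or ``tbi``.

    The two presets share every parameter except the velocity field: sham
    carries a dominant anterior-directed flow over the whole field, while
    the injured preset has that anterior transport suppressed in the
    anterior half and a posterior-directed component in the posterior half.
    Values live in ``glymphkin/presets/*.yaml``.
    """
    if condition not in CONDITIONS:
        raise ConfigError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    ref = importlib.resources.files("glymphkin.presets") / f"{condition}.yaml"
    with ref.open() as fh:
        raw = yaml.safe_load(fh)
    vf = raw.pop("velocity_field")
    cfg = SimulationConfig.from_dict(
        {
            "grid_shape": raw["grid_shape"],
            "pixel_size": raw["pixel_size_mm"],
            "frame_interval": raw["frame_interval_min"],
            "n_frames": raw["n_frames"],
            "injection_center": raw["injection_center_mm"],
            "bolus_amount": raw["bolus_amount_au"],
            "bolus_sigma": raw["bolus_sigma_mm"],
            "diffusivity": raw["diffusivity_mm2_min"],
            "velocity_field": {
                "anterior": vf["anterior_mm_min"],
                "posterior": vf["posterior_mm_min"],
                "split_x": vf["split_x_mm"],
            },
            "decay_rate": raw["decay_rate_per_min"],
            "background_level": raw["background_level_au"],
            "camera_gain": raw["camera_gain_au_per_unit"],
            "noise_sigma": raw["noise_sigma_au"],
            "origin": raw["origin_mm"],
            "bregma": raw["bregma_mm"],
            "pre_roll": raw["pre_roll_min"],
            "t0_offset": raw["t0_offset_min"],
            "seed": raw.get("seed", 0),
        }
    )
    cfg.validate()
    return cfg


def make_condition_cohort(
    condition: str,
    n_animals: int | None = None,
    inter_animal_cv: float = DEFAULT_INTER_ANIMAL_CV,
    seed: int = DEFAULT_SEED,
) -> CohortConfig:
    """Cohort config for a condition preset with the study's default sizes."""
    if n_animals is None:
        n_animals = DEFAULT_N_ANIMALS[condition]
    return CohortConfig(
        condition=condition,
        n_animals=n_animals,
        base_config=make_condition_preset(condition),
        inter_animal_cv=inter_animal_cv,
        seed=seed,
    )


@dataclass
class IHCImage:
    """Synthetic single-frame fluorescence image with its analytic truth."""

    image: np.ndarray
    region_mask: np.ndarray
    background_mask: np.ndarray
    expected_ctf: float


def simulate_ihc_image(
    region_level: float,
    background_level: float,
    shape: tuple[int, int] = (64, 64),
    noise_sigma: float = 0.0,
    seed: int = 0,
    region_mask: np.ndarray | None = None,
    background_mask: np.ndarray | None = None,
) -> IHCImage:
    """Uniform background plus a brighter region, with seeded camera noise.

    Default masks: a centred disk (region) and a 4-px border frame
    (background).  The analytic corrected total fluorescence is
    ``region_area * region_level``, which an unbiased measurement should
    recover in expectation.
    """
    if region_level < 0 or background_level < 0:
        raise ConfigError("fluorescence levels must be >= 0")
    ny, nx = shape
    if region_mask is None:
        yy, xx = np.mgrid[0:ny, 0:nx]
        r = min(ny, nx) / 6.0
        region_mask = (yy - (ny - 1) / 2.0) ** 2 + (xx - (nx - 1) / 2.0) ** 2 <= r * r
    region_mask = np.asarray(region_mask, bool)
    if background_mask is None:
        background_mask = np.zeros(shape, bool)
        background_mask[:4, :] = background_mask[-4:, :] = True
        background_mask[:, :4] = background_mask[:, -4:] = True
        background_mask &= ~region_mask
    background_mask = np.asarray(background_mask, bool)
    if not region_mask.any() or not background_mask.any():
        raise ConfigError("region and background masks must be non-empty")
    if (region_mask & background_mask).any():
        raise ConfigError("region and background masks must be disjoint")

    image = np.full(shape, float(background_level))
    image[region_mask] += region_level
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sigma, size=shape)
    expected = float(region_mask.sum()) * float(region_level)
    return IHCImage(
        image=image,
        region_mask=region_mask,
        background_mask=background_mask,
        expected_ctf=expected,
    )
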
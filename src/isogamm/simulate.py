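"""Synthetic isokinetic datasets with known ground truth.

The generator emulates the study design the analysis targets: 30 athletes,
reciprocal concentric and eccentric knee extension/flexion at a 60 deg/s
target velocity, five continuous maximal repetitions over a 0-90 deg range of
knee flexion.  Each repetition sweeps the range on a uniform angle grid with a
trapezoidal velocity profile (ramp-up, constant 60 deg/s plateau, ramp-down),
so "truly isokinetic" filtering has an exactly known truth.

Population torque-angle curves: the two quadriceps curves (concentric
extension, eccentric flexion) are floor-plus-asymmetric-Gaussian bumps with
the configured peak attained exactly at the configured peak angle.  The two
hamstring curves are constructed as planted-ratio-truth x quadriceps-curve so
that the implied functional H:Q ratios carry exact, known features: the
extension ratio crosses the point of equality (1.0) exactly at 40 deg of
extension progress (knee flexion 50 deg), and the flexion ratio is bimodal
(peaks near 20 and 80 deg of flexion) with a trough of exactly 0.54 near
54 deg, never reaching 1.0.

Individual curves deviate from the population through a random intercept, a
random smooth deviation drawn from the same P-spline family the model fits
(or a Fourier family, to study misspecification), a scalar per-repetition
offset (so "best repetition" has a well-defined truth: the largest offset),
and i.i.d. Gaussian measurement noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import find_extrema, find_level_crossings
from .splines import make_smooth

ACTION_MODES = (("extension", "concentric"), ("extension", "eccentric"),
                ("flexion", "concentric"), ("flexion", "eccentric"))


@dataclass(frozen=True)
class BumpParams:
    """Floor + asymmetric Gaussian bump torque curve (N*m over degrees)."""

    floor: float
    peak: float
    peak_angle: float
    width_left: float
    width_right: float

    def __call__(self, angle: np.ndarray) -> np.ndarray:
        a = np.asarray(angle, dtype=float)
        w = np.where(a < self.peak_angle, self.width_left, self.width_right)
        return self.floor + (self.peak - self.floor) * np.exp(
            -((a - self.peak_angle) / w) ** 2)


# quadriceps curves (directly parameterized; peak identity exact)
EXT_CONC_QUAD = BumpParams(floor=20.0, peak=190.0, peak_angle=60.0,
                           width_left=35.0, width_right=35.0)
FLEX_ECC_QUAD = BumpParams(floor=25.0, peak=210.0, peak_angle=55.0,
                           width_left=30.0, width_right=22.0)

# planted extension-ratio truth: equals 1 exactly at flexion 50 deg
# (= 40 deg of extension progress), monotone in angle
EXT_RATIO_SCALE = 0.35
EXT_RATIO_CENTER = 50.0
EXT_RATIO_WIDTH = 25.0

# planted flexion-ratio truth: two Gaussian bumps + linear tilt + offset;
# the offset is set so the fine-grid minimum is exactly FLEX_RATIO_MIN
FLEX_RATIO_BUMPS = ((0.33, 20.0, 13.0), (0.40, 80.0, 13.0))  # (amp, center, width)
FLEX_RATIO_TILT = -0.002
FLEX_RATIO_MIN = 0.54


def true_extension_ratio(angle) -> np.ndarray:
    a = np.asarray(angle, dtype=float)
    return 1.0 + EXT_RATIO_SCALE * np.tanh((a - EXT_RATIO_CENTER) / EXT_RATIO_WIDTH)


def _flexion_ratio_shape(a: np.ndarray) -> np.ndarray:
    out = FLEX_RATIO_TILT * (a - 50.0)
    for amp, center, width in FLEX_RATIO_BUMPS:
        out = out + amp * np.exp(-((a - center) / width) ** 2)
    return out


_FINE = np.arange(0.0, 90.0001, 0.01)
_FLEX_RATIO_OFFSET = FLEX_RATIO_MIN - _flexion_ratio_shape(
    _FINE[(_FINE > 35) & (_FINE < 68)]).min()


def true_flexion_ratio(angle) -> np.ndarray:
    return _FLEX_RATIO_OFFSET + _flexion_ratio_shape(np.asarray(angle, dtype=float))


@dataclass
class GeneratorConfig:
    """Study-design and noise parameters of the synthetic generator."""

    n_athletes: int = 30
    n_repetitions: int = 5
    angle_step_deg: float = 1.0
    target_velocity_dps: float = 60.0
    ramp_fraction: float = 0.1         # of the sweep, at each end
    sigma: float = 6.0                 # residual SD, N*m
    sigma_b: float = 8.0               # athlete intercept SD, N*m
    tau_ind: float = 5.0               # athlete smooth-deviation SD, N*m
    sigma_rep: float = 3.0             # repetition offset SD, N*m
    k_ind: int = 6                     # basis size of individual deviations
    deviation_family: str = "pspline"  # or "fourier" (misspecified variant)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma", "sigma_b", "tau_ind", "sigma_rep"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0 <= self.ramp_fraction < 0.5:
            raise ValueError("ramp_fraction must be in [0, 0.5)")
        if self.deviation_family not in ("pspline", "fourier"):
            raise ValueError("deviation_family must be 'pspline' or 'fourier'")


def population_curve(action: str, mode: str, angle) -> np.ndarray:
    """True population torque at ``angle`` (degrees of knee flexion)."""
    a = np.asarray(angle, dtype=float)
    if a.size and (a.min() < 0 or a.max() > 90):
        raise ValueError("angle outside [0, 90]")
    if (action, mode) == ("extension", "concentric"):       # quadriceps
        out = EXT_CONC_QUAD(a)
    elif (action, mode) == ("flexion", "eccentric"):        # quadriceps
        out = FLEX_ECC_QUAD(a)
    elif (action, mode) == ("extension", "eccentric"):      # hamstrings
        out = true_extension_ratio(a) * EXT_CONC_QUAD(a)
    elif (action, mode) == ("flexion", "concentric"):       # hamstrings
        out = true_flexion_ratio(a) * FLEX_ECC_QUAD(a)
    else:
        raise ValueError(f"unknown action/mode: {action}/{mode}")
    return out if np.ndim(angle) else float(out)


def velocity_profile(n_samples: int, target: float, ramp_fraction: float
                     ) -> np.ndarray:
    """Trapezoidal speed over a sweep sampled at ``n_samples`` equal steps."""
    s = np.linspace(0.0, 1.0, n_samples)
    if ramp_fraction == 0:
        return np.full(n_samples, target)
    up = np.minimum(s / ramp_fraction, 1.0)
    down = np.minimum((1.0 - s) / ramp_fraction, 1.0)
    v = target * np.minimum(up, down)
    # snap the plateau to the target exactly so the constant-velocity
    # fraction is well defined despite float division fuzz
    plateau = (s >= ramp_fraction - 1e-12) & (s <= 1.0 - ramp_fraction + 1e-12)
    v[plateau] = target
    return v


@dataclass
class GroundTruth:
    """Everything needed to score downstream estimates without re-simulating."""

    config: GeneratorConfig
    grid: np.ndarray
    curves: dict[tuple[str, str], np.ndarray]
    extension_ratio: np.ndarray
    flexion_ratio: np.ndarray
    extension_ratio_crossings: list[float]      # flexion-angle axis
    flexion_ratio_extrema: list[tuple[float, float, str]]
    variance_components: dict[str, float]
    best_repetition: dict[tuple[str, str, str], int]
    #: every repetition's planted offset, keyed (athlete, action, mode) —
    #: lets recovery tests compute the exact shift of whichever repetition
    #: the preprocessing actually selected
    rep_offsets: dict[tuple[str, str, str], list[float]]
    #: realized mean (over athletes) of the best repetition's offset, per
    #: (action, mode) — best-repetition selection makes the estimand the
    #: maximal-effort curve, i.e. population curve + this shift
    selection_shift: dict[tuple[str, str], float]
    constant_velocity_fraction: float

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "grid": self.grid.tolist(),
            "curves": {f"{a}_{m}": c.tolist() for (a, m), c in self.curves.items()},
            "extension_ratio": self.extension_ratio.tolist(),
            "flexion_ratio": self.flexion_ratio.tolist(),
            "extension_ratio_crossings": self.extension_ratio_crossings,
            "flexion_ratio_extrema": self.flexion_ratio_extrema,
            "variance_components": self.variance_components,
            "best_repetition": {f"{k[0]}|{k[1]}|{k[2]}": v
                                for k, v in self.best_repetition.items()},
            "rep_offsets": {f"{k[0]}|{k[1]}|{k[2]}": v
                            for k, v in self.rep_offsets.items()},
            "selection_shift": {f"{a}_{m}": v
                                for (a, m), v in self.selection_shift.items()},
            "constant_velocity_fraction": self.constant_velocity_fraction,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def simulate_dataset(config: GeneratorConfig | None = None
                     ) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one synthetic study: long-format samples + ground truth.

    Extension repetitions sweep the flexion angle 90 -> 0 (negative angular
    velocity), flexion repetitions 0 -> 90; both phases run at the same target
    speed.  Bit-reproducible given ``config.seed``.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    angles_up = np.arange(0.0, 90.0 + 1e-9, cfg.angle_step_deg)
    n_pts = len(angles_up)
    speed = velocity_profile(n_pts, cfg.target_velocity_dps, cfg.ramp_fraction)

    dev_basis = make_smooth((0.0, 90.0), cfg.k_ind)

    def draw_deviation() -> np.ndarray:
        """Coefficients -> callable deviation curve values on angles_up order."""
        if cfg.deviation_family == "pspline":
            u = rng.normal(0.0, cfg.tau_ind, dev_basis.n_pen)
            return dev_basis.design_pen(angles_up) @ u
        k = np.arange(1, 4)
        a = rng.normal(0.0, cfg.tau_ind, 3)
        b = rng.normal(0.0, cfg.tau_ind, 3)
        arg = np.pi * np.outer(angles_up, k) / 90.0
        return (np.sin(arg) @ a + np.cos(arg) @ b) / np.sqrt(3.0)

    rows = []
    best_rep: dict[tuple[str, str, str], int] = {}
    all_offsets: dict[tuple[str, str, str], list[float]] = {}
    max_offsets: dict[tuple[str, str], list[float]] = {am: [] for am in ACTION_MODES}
    for i in range(cfg.n_athletes):
        athlete = f"A{i + 1:02d}"
        b0 = rng.normal(0.0, cfg.sigma_b)
        for action, mode in ACTION_MODES:
            dev = draw_deviation()
            pop = population_curve(action, mode, angles_up)
            rep_offsets = rng.normal(0.0, cfg.sigma_rep, cfg.n_repetitions)
            best_rep[(athlete, action, mode)] = int(np.argmax(rep_offsets)) + 1
            all_offsets[(athlete, action, mode)] = [float(o) for o in rep_offsets]
            max_offsets[(action, mode)].append(float(rep_offsets.max()))
            for r in range(cfg.n_repetitions):
                noise = rng.normal(0.0, cfg.sigma, n_pts)
                torque = pop + b0 + dev + rep_offsets[r] + noise
                if action == "extension":
                    order = slice(None, None, -1)   # sweep 90 -> 0
                    vel = -speed[::-1]
                else:
                    order = slice(None)
                    vel = speed
                rows.append(pd.DataFrame({
                    "athlete_id": athlete, "action": action, "mode": mode,
                    "repetition": r + 1,
                    "angle_deg": angles_up[order],
                    "velocity_dps": vel,
                    "torque_nm": torque[order],
                }))
    df = pd.concat(rows, ignore_index=True)

    grid = np.round(np.arange(0.0, 90.0001, 0.1), 10)
    curves = {am: population_curve(am[0], am[1], grid) for am in ACTION_MODES}
    ext_ratio = true_extension_ratio(grid)
    flex_ratio = true_flexion_ratio(grid)
    truth = GroundTruth(
        config=cfg, grid=grid, curves=curves,
        extension_ratio=ext_ratio, flexion_ratio=flex_ratio,
        extension_ratio_crossings=find_level_crossings(grid, ext_ratio, 1.0),
        flexion_ratio_extrema=find_extrema(grid, flex_ratio),
        variance_components={"sigma": cfg.sigma, "sigma_b": cfg.sigma_b,
                             "tau_ind": cfg.tau_ind, "sigma_rep": cfg.sigma_rep},
        best_repetition=best_rep,
        rep_offsets=all_offsets,
        selection_shift={am: float(np.mean(v)) for am, v in max_offsets.items()},
        constant_velocity_fraction=float(
            np.mean(speed >= cfg.target_velocity_dps - 1e-12)),
    )
    return df, truth
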